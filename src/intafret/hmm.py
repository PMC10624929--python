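"""Variational-Bayes Gaussian hidden Markov idealization of FRET traces.

Each trace is fit independently with a K-state HMM with Gaussian
emissions under conjugate priors (Dirichlet on the initial distribution
and transition rows, Normal-Gamma on each state's mean/precision), in
the style of the vbFRET family of smFRET idealizers.  Variational EM
alternates a forward-backward E-step using geometric-mean ("tilde")
parameters with conjugate M-step updates; the variational lower bound is
guaranteed non-decreasing and is asserted per iteration.

Four states are the default initial guess; states that end up with an
expected occupancy below one frame are pruned.  The Viterbi path under
the tilde parameters gives the idealized trace, after which the zero
override forces frames whose raw channels approached zero into the zero
state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.cluster.vq import kmeans2
from scipy.special import digamma, gammaln

from .traces import FretTrace

__all__ = ["VbPriors", "HmmModel", "IdealizedTrace", "fit_vbhmm", "apply_zero_override", "viterbi_path"]


@dataclass
class VbPriors:
    """Weak conjugate hyperparameters.

    ``u_pi``/``u_A`` are symmetric Dirichlet counts; the Normal-Gamma
    emission prior has mean ``m0`` (mid-range FRET), pseudo-count
    ``beta0`` and Gamma shape/rate ``a0``/``b0`` chosen broad enough to
    admit both the tight zero state and diffuse bound states.
    """

    u_pi: float = 1.0
    u_A: float = 1.0
    m0: float = 0.5
    beta0: float = 0.25
    a0: float = 2.5
    b0: float = 0.01


@dataclass
class HmmModel:
    """Posterior summary of a converged (or halted) VB fit."""

    K: int
    means: np.ndarray          # posterior emission means m_k
    sds: np.ndarray            # posterior-mean emission s.d. sqrt(b_k/a_k)
    transition: np.ndarray     # posterior-mean transition matrix
    startprob: np.ndarray
    lower_bound: float
    lower_bounds: np.ndarray   # per-iteration ELBO trajectory
    occupancy: np.ndarray      # expected frames per state
    converged: bool
    active: np.ndarray         # states surviving the occupancy prune


@dataclass
class IdealizedTrace:
    """Discrete state path and per-frame idealized FRET level."""

    frame_interval: float
    states: np.ndarray         # per-frame state index
    levels: np.ndarray         # idealized FRET level per state index
    E_ideal: np.ndarray        # levels[states] with zero override applied
    zero_assigned: np.ndarray

    def __len__(self) -> int:
        return self.states.size


def _init_responsibilities(y: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded k-means initialization of soft assignments."""
    n = y.size
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, labels = kmeans2(y.astype(float), K, minit="++", seed=rng)
    except Exception:
        # degenerate data (e.g. fewer distinct values than K)
        qs = np.quantile(y, np.linspace(0, 1, K))
        labels = np.argmin(np.abs(y[:, None] - qs[None, :]), axis=1)
    gamma = np.full((n, K), 0.1 / max(K - 1, 1))
    gamma[np.arange(n), labels] = 0.9
    return gamma / gamma.sum(axis=1, keepdims=True)


def _dirichlet_kl(w: np.ndarray, u: np.ndarray) -> float:
    """KL(Dir(w) || Dir(u)) for 1-D parameter vectors."""
    w0, u0 = w.sum(), u.sum()
    return float(
        gammaln(w0) - gammaln(u0)
        - np.sum(gammaln(w) - gammaln(u))
        + np.sum((w - u) * (digamma(w) - digamma(w0)))
    )


def _normal_gamma_kl(m, beta, a, b, m0, beta0, a0, b0) -> float:
    """KL between Normal-Gamma posteriors and the shared prior, summed over states."""
    # KL for Gamma(a,b) vs Gamma(a0,b0)
    kl_gamma = (
        (a - a0) * digamma(a) - gammaln(a) + gammaln(a0)
        + a0 * (np.log(b) - np.log(b0)) + a * (b0 - b) / b
    )
    # E_q[ KL(N(m,1/(beta lam)) || N(m0,1/(beta0 lam))) ]
    e_lam = a / b
    kl_normal = 0.5 * (
        np.log(beta / beta0) + beta0 / beta - 1.0 + beta0 * e_lam * (m - m0) ** 2
    )
    return float(np.sum(kl_gamma + kl_normal))


def _forward_backward(log_start, log_trans, log_emit):
    """Scaled forward-backward; returns gamma, xi-sum, log normalizer."""
    T, K = log_emit.shape
    alpha = np.zeros((T, K))
    c = np.zeros(T)
    b = np.exp(log_emit - log_emit.max(axis=1, keepdims=True))
    corr = log_emit.max(axis=1)
    A = np.exp(log_trans)
    pi = np.exp(log_start)
    alpha[0] = pi * b[0]
    c[0] = alpha[0].sum()
    alpha[0] /= c[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ A) * b[t]
        c[t] = alpha[t].sum()
        alpha[t] /= c[t]
    beta = np.zeros((T, K))
    beta[-1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (b[t + 1] * beta[t + 1])) / c[t + 1]
        xi = alpha[t][:, None] * A * (b[t + 1] * beta[t + 1])[None, :] / c[t + 1]
        xi_sum += xi
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    log_z = float(np.sum(np.log(c)) + np.sum(corr))
    return gamma, xi_sum, log_z


def viterbi_path(log_start: np.ndarray, log_trans: np.ndarray, log_emit: np.ndarray) -> np.ndarray:
    """Most probable state path by dynamic programming."""
    T, K = log_emit.shape
    delta = log_start + log_emit[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + log_trans
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(K)] + log_emit[t]
    path = np.zeros(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def fit_vbhmm(
    fret: FretTrace,
    K_init: int = 4,
    priors: Optional[VbPriors] = None,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    min_occupancy: float = 1.0,
    zero_mode: str = "include",
) -> tuple[HmmModel, IdealizedTrace]:
    """Fit the variational-Bayes Gaussian HMM and idealize the trace.

    ``zero_mode="include"`` fits on the full E sequence (zero-assigned
    frames carry their assigned E=0 and naturally populate the zero
    state); ``"exclude"`` gives zero-assigned frames a flat emission
    likelihood so they do not inform any state's parameters.  In both
    modes :func:`apply_zero_override` afterwards pins flagged frames to
    the zero state.

    Returns the posterior model summary and the Viterbi-idealized trace
    (zero override already applied).  A non-converged fit is returned
    with ``converged=False`` and a warning.
    """
    if priors is None:
        priors = VbPriors()
    y = np.asarray(fret.E, dtype=float)
    T = y.size
    if T < 2:
        raise ValueError("trace too short for HMM fitting")
    K = int(K_init)
    rng = np.random.default_rng(seed)
    gamma = _init_responsibilities(y, K, rng)
    mask = np.ones(T, dtype=bool)  # frames contributing emission likelihood
    if zero_mode == "exclude":
        mask = ~fret.zero_assigned
        if mask.sum() < 2:
            raise ValueError("fewer than 2 usable frames after zero exclusion")
    elif zero_mode != "include":
        raise ValueError("zero_mode must be 'include' or 'exclude'")

    u_pi = np.full(K, priors.u_pi)
    u_A = np.full((K, K), priors.u_A)
    xi_sum = None
    elbos = []
    prev = -np.inf
    converged = False
    for it in range(max_iter):
        # ---- M-step (conjugate updates from current responsibilities) ----
        gm = gamma * mask[:, None]
        Nk = gm.sum(axis=0) + 1e-12
        ybar = (gm * y[:, None]).sum(axis=0) / Nk
        Sk = (gm * (y[:, None] - ybar[None, :]) ** 2).sum(axis=0)
        beta_k = priors.beta0 + Nk
        m_k = (priors.beta0 * priors.m0 + Nk * ybar) / beta_k
        a_k = priors.a0 + 0.5 * Nk
        b_k = priors.b0 + 0.5 * Sk + 0.5 * priors.beta0 * Nk * (ybar - priors.m0) ** 2 / beta_k
        w_pi = u_pi + gamma[0]
        w_A = u_A + (xi_sum if xi_sum is not None else np.zeros((K, K)))

        # ---- E-step with tilde (geometric-mean) parameters ----
        ln_pi = digamma(w_pi) - digamma(w_pi.sum())
        ln_A = digamma(w_A) - digamma(w_A.sum(axis=1, keepdims=True))
        e_ln_lam = digamma(a_k) - np.log(b_k)
        e_lam = a_k / b_k
        log_emit = 0.5 * (
            e_ln_lam[None, :]
            - np.log(2 * np.pi)
            - 1.0 / beta_k[None, :]
            - e_lam[None, :] * (y[:, None] - m_k[None, :]) ** 2
        )
        log_emit = np.where(mask[:, None], log_emit, 0.0)
        gamma, xi_sum, log_z = _forward_backward(ln_pi, ln_A, log_emit)

        # ---- lower bound ----
        kl = _dirichlet_kl(w_pi, u_pi)
        for k in range(K):
            kl += _dirichlet_kl(w_A[k], u_A[k])
        kl += _normal_gamma_kl(m_k, beta_k, a_k, b_k, priors.m0, priors.beta0, priors.a0, priors.b0)
        elbo = log_z - kl
        elbos.append(elbo)
        if it > 0 and elbo < prev - 1e-8 * max(1.0, abs(prev)):
            raise RuntimeError(f"variational lower bound decreased at iteration {it}")
        if it > 0 and abs(elbo - prev) < tol * max(1.0, abs(prev)):
            converged = True
            break
        prev = elbo
    if not converged:
        warnings.warn("VB-HMM did not converge within max_iter", RuntimeWarning)

    occupancy = (gamma * mask[:, None]).sum(axis=0)
    active = occupancy >= min_occupancy
    if not active.any():
        active = occupancy == occupancy.max()

    path = viterbi_path(ln_pi, ln_A, log_emit)
    model = HmmModel(
        K=K,
        means=m_k,
        sds=np.sqrt(b_k / a_k),
        transition=w_A / w_A.sum(axis=1, keepdims=True),
        startprob=w_pi / w_pi.sum(),
        lower_bound=float(elbos[-1]),
        lower_bounds=np.asarray(elbos),
        occupancy=occupancy,
        converged=converged,
        active=active,
    )
    ideal = IdealizedTrace(
        frame_interval=fret.frame_interval,
        states=path,
        levels=m_k.copy(),
        E_ideal=m_k[path],
        zero_assigned=fret.zero_assigned.copy(),
    )
    ideal = apply_zero_override(ideal, fret)
    return model, ideal


def apply_zero_override(ideal: IdealizedTrace, fret: FretTrace) -> IdealizedTrace:
    """Force zero-assigned frames to the zero state.

    The zero state is the fitted state whose level is closest to 0; its
    idealized level is set to exactly 0 so that unbound/bleached frames
    idealize to E=0 irrespective of the HMM output.
    """
    if len(ideal) != len(fret):
        raise ValueError("idealized trace and FRET trace lengths differ")
    levels = ideal.levels.copy()
    zero_state = int(np.argmin(np.abs(levels)))
    levels[zero_state] = 0.0
    states = ideal.states.copy()
    states[fret.zero_assigned] = zero_state
    E_ideal = levels[states]
    return IdealizedTrace(
        frame_interval=ideal.frame_interval,
        states=states,
        levels=levels,
        E_ideal=E_ideal,
        zero_assigned=fret.zero_assigned.copy(),
    )
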