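"""Ensemble (cohort-level) smFRET statistics.

Transition-density plots, post-synchronized histograms, normalized FRET
histograms with Gaussian decomposition, and strand-transfer frequency
statistics including the dual-label assembly correction.

Conventions:

* The %STC error bar is computed exactly as sigma = sqrt(p(1-p)*100)
  with p = n/N.  This is the form that reproduces the published
  per-condition uncertainties; it differs from the standard binomial
  standard error of a percentage (100*sqrt(p(1-p)/N)), which is exposed
  separately as :func:`stc_frequency_stderr` for comparison.
* FRET histograms default to 0.02-wide bins, fine enough to separate
  the ~0.06 aggregate pseudo-FRET peak from specific binding near 0.16.
* Printed-value comparisons round half-up at the displayed precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import argrelmax

from .hmm import IdealizedTrace
from .traces import FretTrace

__all__ = [
    "TransitionDensity",
    "PostSyncHistogram",
    "FretHistogram",
    "GaussianComponent",
    "GaussianModel",
    "StcSummary",
    "LabelMix",
    "transition_density",
    "post_synchronized_histogram",
    "fret_histogram",
    "fit_gaussians",
    "stc_frequency",
    "stc_frequency_stderr",
    "infer_event_count",
    "correct_label_mixing",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero at ``decimals`` places (table convention)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------------
# Transition density
# --------------------------------------------------------------------------

@dataclass
class TransitionDensity:
    """2-D histogram of (initial FRET, final FRET) over all state changes."""

    counts: np.ndarray
    edges: np.ndarray
    bin_width: float
    total: int


def transition_density(ideals: Sequence[IdealizedTrace], bin_width: float = 0.02) -> TransitionDensity:
    """Accumulate every idealized state change into a (before, after) histogram.

    Each frame pair whose idealized level changes contributes one count
    at (E_before, E_after); self-transitions (no level change) are
    excluded by construction.
    """
    befores, afters = [], []
    for ideal in ideals:
        E = ideal.E_ideal
        change = E[1:] != E[:-1]
        befores.append(E[:-1][change])
        afters.append(E[1:][change])
    before = np.concatenate(befores) if befores else np.empty(0)
    after = np.concatenate(afters) if afters else np.empty(0)
    nbins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, nbins + 1)
    counts, _, _ = np.histogram2d(before, after, bins=[edges, edges])
    return TransitionDensity(counts=counts, edges=edges, bin_width=bin_width, total=int(before.size))


# --------------------------------------------------------------------------
# Post-synchronized histogram
# --------------------------------------------------------------------------

@dataclass
class PostSyncHistogram:
    """2-D (time since injection, FRET) histogram; zero-FRET frames excluded."""

    counts: np.ndarray          # shape (n_time_bins, n_fret_bins)
    time_edges: np.ndarray
    fret_edges: np.ndarray
    frame_interval: float
    total: int


def post_synchronized_histogram(
    frets: Sequence[FretTrace],
    injection_frames: Sequence[int],
    frame_interval: float,
    fret_bin: float = 0.01,
    time_bin: Optional[float] = None,
) -> PostSyncHistogram:
    """Accumulate a cohort's nonzero-FRET frames against time since injection.

    Time bins default to 300 ms for 100 ms data and 910 ms for 1 s data.
    All traces must share one frame rate; the assigned-zero (unbound)
    frames are dropped for clarity.
    """
    if time_bin is None:
        time_bin = 0.3 if np.isclose(frame_interval, 0.1) else 0.91
    ts, es = [], []
    max_t = 0.0
    for fret, inj in zip(frets, injection_frames):
        if not np.isclose(fret.frame_interval, frame_interval):
            raise ValueError("mixed frame rates in post-synchronized cohort")
        keep = (fret.E > 0) & ~fret.zero_assigned
        idx = np.flatnonzero(keep)
        t = (idx - inj) * frame_interval
        ts.append(t)
        es.append(fret.E[idx])
        max_t = max(max_t, (len(fret) - inj) * frame_interval)
    t_all = np.concatenate(ts) if ts else np.empty(0)
    e_all = np.concatenate(es) if es else np.empty(0)
    n_tbins = max(int(np.ceil(max_t / time_bin)), 1)
    time_edges = np.arange(n_tbins + 1) * time_bin
    n_fbins = int(round(1.0 / fret_bin))
    fret_edges = np.linspace(0.0, 1.0, n_fbins + 1)
    counts, _, _ = np.histogram2d(t_all, e_all, bins=[time_edges, fret_edges])
    return PostSyncHistogram(
        counts=counts,
        time_edges=time_edges,
        fret_edges=fret_edges,
        frame_interval=frame_interval,
        total=int(e_all.size),
    )


# --------------------------------------------------------------------------
# 1-D FRET histograms
# --------------------------------------------------------------------------

@dataclass
class FretHistogram:
    """1-D histogram of nonzero per-frame FRET across a cohort."""

    counts: np.ndarray
    edges: np.ndarray
    bin_width: float
    n_molecules: int
    per_dna: bool
    pseudo_norm: Optional[float] = None  # pseudo-peak area used for renormalization

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def area(self, window: tuple) -> float:
        """Integrated counts within a FRET window (inclusive of bins whose
        center falls inside)."""
        c = self.centers
        sel = (c >= window[0]) & (c <= window[1])
        return float(self.counts[sel].sum())


def fret_histogram(
    frets: Sequence[FretTrace],
    bin_width: float = 0.02,
    per_dna: bool = False,
    renormalize_pseudo: bool = False,
    pseudo_window: tuple = (0.03, 0.09),
) -> FretHistogram:
    """Build the cohort FRET histogram from the >0 FRET frames.

    ``per_dna`` divides counts by the number of molecules, removing the
    dependence on cohort size.  ``renormalize_pseudo`` divides the whole
    histogram by the integrated counts inside ``pseudo_window`` (the
    aggregate pseudo-FRET peak near 0.06), which acts as an internal
    standard when comparing conditions recorded at matched aggregate
    levels.
    """
    if len(frets) == 0:
        raise ValueError("empty cohort")
    values = []
    for fret in frets:
        keep = (fret.E > 0) & ~fret.zero_assigned
        values.append(fret.E[keep])
    v = np.concatenate(values)
    nbins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, nbins + 1)
    counts, _ = np.histogram(v, bins=edges)
    counts = counts.astype(float)
    if per_dna:
        counts = counts / len(frets)
    hist = FretHistogram(
        counts=counts,
        edges=edges,
        bin_width=bin_width,
        n_molecules=len(frets),
        per_dna=per_dna,
    )
    if renormalize_pseudo:
        norm = hist.area(pseudo_window)
        if norm <= 0:
            raise ValueError("empty pseudo-FRET peak; cannot renormalize")
        hist.counts = hist.counts / norm
        hist.pseudo_norm = norm
    return hist


# --------------------------------------------------------------------------
# Gaussian decomposition
# --------------------------------------------------------------------------

@dataclass
class GaussianComponent:
    mean: float
    sd: float
    amplitude: float


@dataclass
class GaussianModel:
    components: list
    r_squared: float

    def __iter__(self):
        return iter(self.components)


def _gauss_mixture(x, *params):
    y = np.zeros_like(x, dtype=float)
    for i in range(0, len(params), 3):
        amp, mu, sd = params[i : i + 3]
        y = y + amp / np.sqrt(2 * np.pi * sd**2) * np.exp(-((x - mu) ** 2) / (2 * sd**2))
    return y


def fit_gaussians(hist: FretHistogram, n: int = 1) -> GaussianModel:
    """Least-squares n-component Gaussian fit to a FRET histogram.

    Components are unit-area normal densities scaled by free amplitudes;
    the reported quantities are each component's mean and s.d. (the
    E +/- sigma convention).  ``n`` in 1..3; requires at least 5 occupied
    bins and enough bins to constrain 3n parameters.
    """
    if not 1 <= n <= 3:
        raise ValueError("n must be 1, 2 or 3")
    x = hist.centers
    y = hist.counts.astype(float)
    occupied = y > 0
    if occupied.sum() < 5:
        raise ValueError("fewer than 5 occupied bins")
    if occupied.sum() < 3 * n:
        raise ValueError(f"too few occupied bins to constrain {n} components")
    # initialize component means at the n tallest local maxima (fall back
    # to quantiles of the mass distribution)
    peaks = argrelmax(np.pad(y, 1), order=1)[0] - 1
    peaks = peaks[(peaks >= 0) & (peaks < y.size)]
    peaks = peaks[np.argsort(y[peaks])[::-1]][:n]
    if peaks.size < n:
        w = y / y.sum()
        qs = np.quantile(np.repeat(x, np.maximum((w * 1000).astype(int), 1)), np.linspace(0.2, 0.8, n))
        mus = np.sort(qs)
    else:
        mus = np.sort(x[peaks])
    span = x[occupied].max() - x[occupied].min() + hist.bin_width
    p0, lo, hi = [], [], []
    total_area = float(y.sum() * hist.bin_width)
    for mu in mus:
        p0 += [total_area / n, float(mu), span / 6]
        lo += [0.0, float(x.min()), hist.bin_width / 4]
        hi += [np.inf, float(x.max()), 1.0]
    try:
        popt, _ = curve_fit(_gauss_mixture, x[occupied], y[occupied], p0=p0, bounds=(lo, hi), maxfev=20000)
    except RuntimeError as err:
        raise ValueError(f"Gaussian fit failed: {err}") from err
    comps = [
        GaussianComponent(mean=float(popt[i + 1]), sd=float(popt[i + 2]), amplitude=float(popt[i]))
        for i in range(0, len(popt), 3)
    ]
    comps.sort(key=lambda c: c.mean)
    resid = y[occupied] - _gauss_mixture(x[occupied], *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y[occupied] - y[occupied].mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return GaussianModel(components=comps, r_squared=r2)


# --------------------------------------------------------------------------
# Strand-transfer frequency statistics
# --------------------------------------------------------------------------

@dataclass
class StcSummary:
    """Strand-transfer frequency for one target-DNA condition."""

    n: int
    N: int
    pct: float
    sigma: float
    condition: str = ""


def stc_frequency(n: int, N: int, condition: str = "") -> StcSummary:
    """%STC = n/N*100 with its uncertainty sigma = sqrt((n/N)(1-n/N)*100).

    n is the number of molecules showing strand transfer, N the total
    molecules analyzed.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    if not 0 <= n <= N:
        raise ValueError("need 0 <= n <= N")
    p = n / N
    return StcSummary(n=n, N=N, pct=100.0 * p, sigma=float(np.sqrt(p * (1 - p) * 100.0)), condition=condition)


def stc_frequency_stderr(n: int, N: int) -> float:
    """Standard binomial standard error of the percentage, 100*sqrt(p(1-p)/N).

    Comparison variant; the reported per-condition sigma uses
    :func:`stc_frequency`.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    p = n / N
    return float(100.0 * np.sqrt(p * (1 - p) / N))


def infer_event_count(pct_printed: float, N: int, decimals: int = 1) -> int:
    """Invert %STC = n/N*100: the integer n whose rounded percentage matches.

    Scans n = 0..N and collects every n with round(100*n/N, decimals) ==
    pct_printed (half-up rounding).  Returns the unique solution; raises
    ``ValueError`` when no n matches or when several do.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    matches = [
        n for n in range(N + 1)
        if round_half_up(100.0 * n / N, decimals) == round_half_up(pct_printed, decimals)
    ]
    if not matches:
        raise ValueError(f"no event count reproduces {pct_printed}% at N={N}")
    if len(matches) > 1:
        raise ValueError(f"ambiguous event count for {pct_printed}% at N={N}: {matches}")
    return matches[0]


# --------------------------------------------------------------------------
# Dual-label stoichiometry correction
# --------------------------------------------------------------------------

@dataclass
class LabelMix:
    """Species fractions from equimolar two-label intasome assembly.

    Mixing equimolar donor- and acceptor-labeled viral DNA during
    assembly yields 50% dual-labeled, 25% donor/donor and 25%
    acceptor/acceptor intasomes.
    """

    p_dual: float = 0.50
    p_donor_only: float = 0.25
    p_acceptor_only: float = 0.25

    def __post_init__(self) -> None:
        total = self.p_dual + self.p_donor_only + self.p_acceptor_only
        if not np.isclose(total, 1.0):
            raise ValueError("label-mix probabilities must sum to 1")


def correct_label_mixing(observed_pct: float, mix: LabelMix = LabelMix()) -> tuple[float, float]:
    """Scale an observed %STC for the undetectable acceptor-only species.

    ``observed_pct`` counts events from the detectable species only
    (dual-labeled plus donor/donor bleed-through).  Returns
    (total_pct, undetectable_pct): the total frequency after dividing by
    the detectable fraction, and the contribution of the acceptor-only
    species that the donor-excitation FRET measurement cannot see.
    """
    f = mix.p_dual + mix.p_donor_only
    if f <= 0:
        raise ValueError("detectable fraction is zero")
    total = observed_pct / f
    undetectable = observed_pct * mix.p_acceptor_only / f
    return total, undetectable
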