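"""Dwell-time kinetics of target capture and strand transfer.

Bound (E > 0.1) and unbound (idealized E = 0) dwell times are read off
the idealized state paths; their histograms, binned at a
Shimazaki-Shinomoto-optimized width, are fit with single exponentials
Counts = A * exp(-t / tau) to yield the binding lifetime tau_on (1/k_off)
and the dissociated-state lifetime tau_off (1/k_on).  Strand-transfer
times are the per-molecule delays from the injection to the first stable
bound signal, summarized by mean and (n-1)-denominator sample s.d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .hmm import IdealizedTrace

__all__ = [
    "DwellSet",
    "ExpFit",
    "TransferTimes",
    "extract_dwells",
    "optimize_bins",
    "shimazaki_cost",
    "fit_exponential",
    "fit_exponential_mle",
    "count_transitions",
    "strand_transfer_times",
    "first_stable_event_frame",
]

BOUND_THRESHOLD = 0.1


@dataclass
class DwellSet:
    """Bound/unbound dwell durations with boundary-censoring flags."""

    t_on: np.ndarray
    t_off: np.ndarray
    censored_on: np.ndarray   # True where the run touches a trace boundary
    censored_off: np.ndarray
    frame_interval: float = 1.0

    def uncensored_on(self) -> np.ndarray:
        return self.t_on[~self.censored_on]

    def uncensored_off(self) -> np.ndarray:
        return self.t_off[~self.censored_off]


@dataclass
class ExpFit:
    """Single-exponential fit Counts = A * exp(-t/tau) to a dwell histogram."""

    tau: float
    amplitude: float
    tau_se: float
    amplitude_se: float
    bin_width: float
    n_dwells: int
    warning: Optional[str] = None


@dataclass
class TransferTimes:
    """Per-molecule strand-transfer times and their summary statistics."""

    t_st: np.ndarray
    mean: float
    sd: Optional[float]  # None when n == 1 (n-1 denominator undefined)
    n: int


def _runs(values: np.ndarray) -> list:
    """(start, stop, value) for maximal constant runs of a boolean array."""
    out = []
    start = 0
    for i in range(1, values.size + 1):
        if i == values.size or values[i] != values[start]:
            out.append((start, i, bool(values[start])))
            start = i
    return out


def extract_dwells(ideal: IdealizedTrace, threshold: float = BOUND_THRESHOLD) -> DwellSet:
    """Read bound and unbound dwell times off an idealized path.

    Maximal runs with idealized E > ``threshold`` become t_on entries;
    maximal zero-level runs become t_off entries.  Runs clipped by the
    start or end of the trace are flagged censored (the true dwell is
    longer than observed) and are excluded from exponential fits by
    default.  Frames at intermediate levels (0 < E <= threshold)
    contribute to neither set.
    """
    E = ideal.E_ideal
    dt = ideal.frame_interval
    n = E.size
    t_on, t_off, cen_on, cen_off = [], [], [], []
    for start, stop, _ in _runs(E > threshold):
        seg = E[start:stop]
        censored = start == 0 or stop == n
        if seg[0] > threshold:
            t_on.append((stop - start) * dt)
            cen_on.append(censored)
        elif np.all(seg == 0.0):
            t_off.append((stop - start) * dt)
            cen_off.append(censored)
        else:
            # mixed sub-threshold run: split into zero / intermediate runs
            for s2, e2, is_zero in _runs(seg == 0.0):
                if is_zero:
                    t_off.append((e2 - s2) * dt)
                    cen_off.append(start + s2 == 0 or start + e2 == n)
    return DwellSet(
        t_on=np.asarray(t_on, dtype=float),
        t_off=np.asarray(t_off, dtype=float),
        censored_on=np.asarray(cen_on, dtype=bool),
        censored_off=np.asarray(cen_off, dtype=bool),
        frame_interval=dt,
    )


def shimazaki_cost(samples: np.ndarray, width: float) -> float:
    """Shimazaki-Shinomoto histogram cost C(D) = (2*mean - var) / D^2.

    mean and (biased) variance are of the bin counts at bin width D; the
    optimal width minimizes C.
    """
    samples = np.asarray(samples, dtype=float)
    lo, hi = samples.min(), samples.max()
    nbins = max(int(np.ceil((hi - lo) / width)), 1)
    counts, _ = np.histogram(samples, bins=nbins, range=(lo, lo + nbins * width))
    k = counts.mean()
    v = counts.var()  # biased, per the original cost
    return (2.0 * k - v) / width**2


def optimize_bins(samples: Sequence[float], n_grid: int = 199) -> float:
    """Optimal histogram bin width by the Shimazaki-Shinomoto criterion.

    Scans bin counts 2..200 over the sample range and returns the width
    minimizing the cost.  With fewer than 20 samples falls back to the
    Freedman-Diaconis rule with a warning.  Constant samples return the
    largest width on the grid (zero count variance favors one wide bin).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 20:
        warnings.warn("fewer than 20 samples; falling back to Freedman-Diaconis", UserWarning)
        iqr = np.subtract(*np.percentile(samples, [75, 25]))
        if iqr == 0:
            return 1.0
        return float(2.0 * iqr / samples.size ** (1 / 3))
    span = samples.max() - samples.min()
    if span == 0:
        span = 1.0
    widths = span / np.arange(2, 2 + n_grid)
    costs = np.array([shimazaki_cost(samples, w) for w in widths])
    return float(widths[np.argmin(costs)])


def fit_exponential(
    dwells: Sequence[float],
    bin_width: Optional[float] = None,
    frame_interval: Optional[float] = None,
) -> ExpFit:
    """Least-squares fit of binned dwell counts to A * exp(-t/tau).

    Dwell times are histogrammed (bin width from :func:`optimize_bins`
    unless given) and the occupied-bin counts are fit against bin
    centers.  Requires at least 3 occupied bins.  When ``frame_interval``
    is supplied and the fitted tau is below 5 frames the fit is flagged:
    dwells near the frame rate are undersampled and tau is biased.
    """
    dwells = np.asarray(dwells, dtype=float)
    if dwells.size < 3:
        raise ValueError("need at least 3 dwell times for an exponential fit")
    if bin_width is None:
        bin_width = optimize_bins(dwells)
    lo = dwells.min()
    nbins = max(int(np.ceil((dwells.max() - lo) / bin_width)), 1)
    counts, edges = np.histogram(dwells, bins=nbins, range=(lo, lo + nbins * bin_width))
    centers = 0.5 * (edges[:-1] + edges[1:])
    occupied = counts > 0
    if occupied.sum() < 3:
        raise ValueError("fewer than 3 occupied histogram bins; widen the data or bins")

    def model(t, A, tau):
        return A * np.exp(-t / tau)

    p0 = (float(counts.max()), float(dwells.mean()))
    try:
        popt, pcov = curve_fit(model, centers[occupied], counts[occupied], p0=p0, maxfev=10000)
    except RuntimeError as err:
        raise ValueError(f"exponential fit failed to converge: {err}") from err
    if popt[1] <= 0 or popt[0] <= 0:
        raise ValueError("exponential fit returned non-positive tau or amplitude")
    perr = np.sqrt(np.diag(pcov))
    warning = None
    if frame_interval is not None and popt[1] < 5 * frame_interval:
        warning = (
            f"tau = {popt[1]:.3g} s is below 5 frame intervals; dwells at the "
            "frame rate are truncated and the lifetime is biased"
        )
        warnings.warn(warning, UserWarning)
    return ExpFit(
        tau=float(popt[1]),
        amplitude=float(popt[0]),
        tau_se=float(perr[1]),
        amplitude_se=float(perr[0]),
        bin_width=float(bin_width),
        n_dwells=int(dwells.size),
        warning=warning,
    )


def fit_exponential_mle(dwells: Sequence[float]) -> float:
    """Maximum-likelihood exponential lifetime (the sample mean).

    Diagnostic cross-check for the binned least-squares fit; not used in
    reported lifetimes.
    """
    dwells = np.asarray(dwells, dtype=float)
    if dwells.size == 0:
        raise ValueError("no dwells")
    return float(dwells.mean())


def count_transitions(ideal: IdealizedTrace, threshold: float = BOUND_THRESHOLD) -> int:
    """Number of upward crossings of the FRET threshold in the idealized path."""
    E = ideal.E_ideal
    below = E[:-1] <= threshold
    above = E[1:] > threshold
    return int(np.sum(below & above))


def first_stable_event_frame(
    ideal: IdealizedTrace,
    threshold: float = BOUND_THRESHOLD,
    min_duration: float = 10.0,
) -> Optional[int]:
    """First frame of the first bound run lasting >= ``min_duration`` s,
    or running to the end of the trace; None if no qualifying event."""
    E = ideal.E_ideal
    dt = ideal.frame_interval
    for start, stop, is_above in _runs(E > threshold):
        if not is_above:
            continue
        if (stop - start) * dt >= min_duration or stop == E.size:
            return start
    return None


def strand_transfer_times(
    ideals: Sequence[IdealizedTrace],
    injection_frames: Sequence[int],
    min_duration: float = 10.0,
) -> TransferTimes:
    """Per-molecule times from injection to the first stable bound signal.

    Each input trace must belong to the STC cohort (a qualifying stable
    event exists).  The mean uses the number of strand-transfer-positive
    molecules n; the s.d. uses the n-1 denominator and is undefined
    (None) for a single molecule.
    """
    if len(ideals) == 0:
        raise ValueError("empty STC cohort")
    t_st = []
    for ideal, inj in zip(ideals, injection_frames):
        f = first_stable_event_frame(ideal, min_duration=min_duration)
        if f is None:
            raise ValueError("trace has no qualifying stable event; not an STC trace")
        t_st.append((f - inj) * ideal.frame_interval)
    t_st = np.asarray(t_st, dtype=float)
    n = t_st.size
    sd = float(np.std(t_st, ddof=1)) if n > 1 else None
    return TransferTimes(t_st=t_st, mean=float(t_st.mean()), sd=sd, n=n)
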