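# Methods

`intafret` analyzes two-channel single-molecule FRET recordings of
surface-tethered target DNA during real-time injection of donor-labeled
retroviral intasomes, and ships a ground-truth simulator so that every
stage of the analysis is testable without raw movie data.

## The experiment being modeled

A Cy5 (acceptor) sits on the immobilized target DNA near a defined lesion
(nick or 1–2 nt gap, with a 5'-phosphate or 5'-hydroxyl); Cy3
(donor)-labeled intasomes are infused while recording at 100 ms or 1 s
frame intervals. Transient binding near the lesion (target-capture
complex, TCC) produces reversible FRET bursts; covalent strand transfer
(strand-transfer complex, STC) produces a stable FRET level lasting up to
minutes, usually ended by photobleaching. Free intasome aggregates
sweeping through the evanescent field saturate the donor channel and
bleed into the acceptor channel, producing a spurious "pseudo-FRET" level
near E ≈ 0.06 that serves as an internal intensity standard.

## Synthetic-data generator (`simulate`)

Binding is a memoryless two-state process: unbound dwell ~ Exp(k_on),
bound dwell ~ Exp(k_off), no events before the injection time, and each
binding converts to an absorbing STC state with probability
`p_stc_per_binding`. Only exponential kinetics are simulated because the
downstream analysis is a single-exponential fit; multi-state binding
would add parameters the analysis cannot resolve.

Defaults are chosen to emulate the most active condition (a 1 nt gap
target) at the slow frame rate: τ_on = 1/k_off = 0.5 s (published range
0.3–0.75 s), τ_off = 1/k_on = 15 s (published range 7–24 s), TCC/STC
FRET 0.16 (σ ≈ 0.05), 10 min traces with injection at 30 s. Total bound
emission is 1000 counts/frame with per-channel Gaussian noise σ = 50,
giving a FRET noise s.d. of ≈ 0.05 at E = 0.16; backgrounds are 50
counts/channel with a +200 step at injection.

Emission exists only while bound — the donor dye rides on the intasome —
and is partitioned by the occupying state's true FRET: acceptor =
E·I_total, donor = (1−E)·I_total, integrated exactly over sub-frame
state changes (at 1 s frames with 0.5 s dwells, time-averaging visibly
lowers apparent FRET, which is why the fast/slow frame-rate comparison
matters). Photobleaching is a single step per fluorophore: a donor
bleach silences both channels; an acceptor bleach stops transfer and
returns the full intensity to the donor.

Pseudo-FRET excursions are Poisson-placed over the post-injection window
(default 0.01 s⁻¹, independent of the binding kinetics, matching the
observation that their frequency does not track the DNA substrate) with
exponential durations of mean 1 s — the duration is a free parameter
because no measured value exists. During an excursion the donor pins at
a saturation ceiling (10⁴ counts) and the acceptor receives bleed-through
sized so the corrected ratio is exactly 0.06.

RNG consumption order is fixed and documented in the module docstring
(path stream, then noise stream, then excursion stream, spawned from one
seed), so identical seed + config is bit-reproducible and cohort traces
are independent.

What the generator does **not** emulate: donor blinking/triplet states,
spectral crosstalk beyond the aggregate bleed-through, diffusing
background particles, stage drift, or non-exponential binding. Passing
tests therefore demonstrate correctness of the analysis under the
stated model, not robustness to every pathology of real recordings.

## Movie rendering and extraction (`movie`)

Rendered movies place each trace as a symmetric Gaussian spot
(σ = 1 px by default) on a flat noisy background in both channels.
Detection applies the quantitative selection rules: difference-of-
Gaussians candidates above a median + 6·MAD adaptive threshold (the
paper's manual inspection replaced by its stated numeric rules), a 3 px
integration radius, 5 px minimum separation between molecules and from
field edges (both members of a close pair are dropped, so crowding never
splits a molecule into two calls), and an eccentricity ceiling of 0.2.

Eccentricity is computed from intensity-weighted second central moments
over a fixed circular patch and reported as the circularity deviation
1 − minor/major axis ratio. Binary-mask moments were tried first and
rejected: on ~10-pixel diffraction-limited regions, pixelation noise
pushes the conventional ellipse eccentricity sqrt(1 − λ₂/λ₁) of
perfectly circular spots past 0.6, which would make a 0.2 ceiling
unusable. Under the circularity-deviation definition, rendered circular
spots score ≤ 0.1 and a 4:1.2 axis-ratio blob scores ≈ 0.7.

Channel registration fits an affine map to bead centroids matched by
nearest neighbor after a coarse phase-correlation shift; the RMS
residual is reported and is < 0.1 px on synthetic fixtures.

## Trace processing (`traces`)

The injection frame is found as the earliest statistically significant
sustained increase of the channel sum (depth-3 binary segmentation;
median-filtered and outlier-clipped first, because saturating aggregate
excursions and stable strand-transfer steps otherwise dominate a single
global change point). Tolerance is ±2 frames on synthetic steps.

The subtracted background per channel is the pre-injection median plus
the injection step. Per trace, the step can be estimated from a 20-frame
window after the injection; for cohorts it should be estimated once with
`estimate_injection_step` (cross-trace median), because molecules that
bind within seconds of the injection — precisely the strand-transfer
cohort — contaminate their own window. The step is a property of the
illuminated field, so sharing it across traces is the physically
correct pooling.

100 ms traces get a centered 3-point moving average; 1 s traces are not
smoothed. FRET is I_A/(I_D + I_A), with E = 0 forced wherever a channel
"approaches zero": below `zero_floor`, either-channel rule by default
(the sum rule is available; the wording in the source protocol is
ambiguous between the two). The default floor is 2× the robust noise
s.d. — at 3× the floor collides with the acceptor level of an E ≈ 0.16
bound state at the simulated SNR and wrongly zeroes ~40% of bound
frames.

Molecules are STC if any E > 0.1 segment lasts ≥ `stc_min_duration`
(default 30 s; the protocol says only "prolonged … up to minutes") or if
a segment ≥ 10 s runs to the trace end (donor-bleach-terminated events
count). On raw traces, segments separated by sub-threshold gaps ≤ 3 s
are merged first; otherwise single-frame noise dropouts fragment
minutes-long events. Set `max_gap=0` on idealized input. Traces with
fewer than 100 usable post-injection frames are excluded, and up to 100
frames can be head-truncated to remove injection photophysics.

## VB-HMM idealization (`hmm`)

Each trace is fit independently with a K = 4 Gaussian-emission HMM under
conjugate priors (symmetric Dirichlet(1) on the initial distribution and
transition rows; Normal-Gamma with m₀ = 0.5, β₀ = 0.25, a₀ = 2.5,
b₀ = 0.01 on emissions — weak enough to admit both the tight zero state
and broad bound states). Variational EM alternates a forward-backward
E-step under geometric-mean ("tilde") parameters with conjugate M-step
updates; the evidence lower bound is computed every iteration and
asserted non-decreasing. Convergence: relative ELBO change < 1e-6 or
500 iterations (non-convergence returns the fit with a warning flag).
Initialization is seeded k-means (scipy `kmeans2`, quantile fallback for
degenerate data). States with expected occupancy below one frame are
pruned from the active set; K is not scanned, matching the
"initial guess" usage. The Viterbi path under tilde parameters is the
idealization; the zero override then pins flagged frames to the state
nearest zero and sets that state's level to exactly 0.

Zero-assigned frames are included in the emission likelihood by default
(they carry the assigned E = 0 and populate the zero state); an
"exclude" mode masks them instead. On noiseless two-level traces the fit
recovers the levels to within prior shrinkage (~β₀/N) and the path
exactly; on σ = 0.05 noise the bound-level error at 1000 frames is
< 0.01 in almost all seeds. Overfitting shows up as a lightly populated
intermediate state between 0 and the bound level — the classic
off-diagonal artifact — with the two dominant states always holding
≥ 85% of frames in testing.

## Kinetics (`kinetics`)

Bound dwells are maximal idealized E > 0.1 runs; unbound dwells are
maximal zero-level runs; runs touching a trace boundary are censored and
excluded from fits (the observation is a lower bound on the true
dwell). Histogram bin widths come from the Shimazaki–Shinomoto cost
C(Δ) = (2·mean − var)/Δ² over a 2–200-bin grid (Freedman–Diaconis
fallback with a warning under 20 samples; constant samples select the
widest grid width because zero count-variance always favors one bin).
Lifetimes are least-squares fits of binned counts to A·exp(−t/τ), as the
analysis formulas prescribe; a maximum-likelihood cross-check (the
sample mean) is exposed for diagnostics only. When τ̂ < 5 frame
intervals the fit warns: dwells at the frame rate are truncated and the
lifetime biased, the regime reported for the 2 nt gap substrates.

Transition counts are upward threshold crossings of the idealized path.
Strand-transfer times are (first frame of the first stable bound event −
injection frame) × frame interval; the mean divides by the number of
strand-transfer-positive molecules n and the s.d. uses n − 1 (undefined,
reported as None, for a single molecule).

## Ensemble statistics (`ensemble`)

The transition-density plot accumulates every idealized level change at
(E_before, E_after); self-transitions cannot occur by construction. The
post-synchronized histogram re-indexes nonzero-FRET frames to time since
injection on a fixed grid (0.01 FRET bins; 300 ms time bins for 100 ms
data, 910 ms for 1 s data); total counts equal the cohort's nonzero
frames, asserted as an invariant.

1-D FRET histograms accumulate nonzero frames at 0.02-bin resolution by
default (the protocol's literal "0.2 FRET bins" cannot resolve the 0.06
vs 0.16 peaks in the corresponding figures and is treated as a slip; 0.2
remains available as an override). Optional per-molecule normalization
removes cohort-size dependence; optional renormalization divides the
histogram by the integrated pseudo-FRET peak (window [0.03, 0.09],
symmetric about 0.06), using the aggregate background as an internal
standard for cross-condition comparison. Gaussian decomposition fits
1–3 unit-area normal components with free amplitudes (the printed
formula omits amplitudes, but histogram counts are not unit-area, so
amplitudes must be free); reported quantities are each component's
mean ± σ.

Strand-transfer frequency: %STC = 100·n/N with σ = sqrt(p(1−p)·100)
implemented exactly as printed — this reproduces the published
per-condition uncertainties (0.6 at 2/564; 4.0 at 125/614; 4.3 at
134/547) even though it is not the binomial standard error of a
percentage, which is provided separately as `stc_frequency_stderr`.
`infer_event_count` inverts the percentage to the unique integer count
(half-up rounding at the displayed precision), reporting ambiguity
rather than guessing. The dual-label assembly correction divides an
observed frequency by the detectable species fraction (dual + donor-only
= 0.75 under the equimolar 50/25/25 mix) and reports the invisible
acceptor-only share.

## Förster predictions (`forster`)

E = 1/(1 + (R/R₀)⁶) with R₀ = 6 nm for Cy3→Cy5 under κ² = 2/3 (free
rotation). Structures with a donor on either viral DNA end produce two
FRET states whose expectation is the arithmetic mean of the two
*efficiencies* — never the efficiency of the mean distance; the sixth
power makes the difference larger than 0.05 at realistic separations,
and a test asserts the non-linearity. Distances are measured between
user-named attachment atoms (chain/residue/atom) in PDB coordinates via
gemmi, in Å converted to nm. The attachment atom is a mandatory input
because no measured choice is recorded; virtual extension of missing
target-DNA base pairs is out of scope — coordinates must already contain
the labeled positions (the packaged synthetic fixture does).

## Integration-site mapping (`sitemap`)

site = product_length − vDNA_length − correction, the correction being
2 nt exactly when the fragment carries both FRET dyes (dual-dye gel
mobility shift); the marker dye never triggers it. Positions are 1-based
from an explicitly named anchor end, because the source material mixes
3'- and 5'-anchored counts. The constructor/inverse pair round-trips
over all sites of a 60 nt strand. Partner-site prediction places the
second strand-transfer event `spacing` = 4 bp away across the duplex; a
partner whose required phosphate falls inside the lesion interval is
chemically impossible and the call degrades to half-site, with
feasibility monotone in lesion size. Product classification distinguishes
unreacted substrate, alcoholysis candidates (shorter than the intact
strand, lacking the viral-DNA label or at a known alcoholysis length),
half-site products, and an explicit "unknown" class that is never
silently dropped. Band efficiency is the fractional lane intensity.

## Numerical and testing choices

Problem sizes in the stochastic tests: 2000 generator-simulated dwells
per lifetime fit with 10 replicates (τ = 0.5 s and 15 s, 10% tolerance,
≥ 90% hit rate); 100 seeded 1000-frame traces for the VB-HMM 0.16-state
recovery (0.02 tolerance, ≥ 95% hit rate); 81 rendered spots for the
detection round trip (≥ 95% recall, zero false positives). The Viterbi
brute-force oracle enumerates all 2¹² paths of a 12-frame instance.
Seeds are fixed throughout; hypothesis property tests are bounded and
deadline-free. The full suite runs in about five minutes on one CPU.

## Known limitations

Per-trace independent HMM fits do not share statistical strength across
a cohort; dwells shorter than one frame are unobservable and bias τ
toward the frame interval in the fast-binding regime; injection
detection assumes a single dominant background step; the simulator's
Gaussian camera noise has no EM-gain excess factor; and the gel module
takes band lengths as input — densitometry and ladder alignment are out
of scope.
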