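# intafret

Single-molecule FRET analysis of retroviral intasome–target DNA
dynamics: a tested, reusable implementation of the full trajectory
pipeline used to study how DNA strand breaks and gaps recruit intasome
binding and strand transfer — plus a ground-truth simulator so every
stage is verifiable without raw movie data.

**Who it is for.** Single-molecule biophysicists analyzing two-channel
(donor/acceptor) TIRF recordings of surface-tethered DNA with a labeled
binding partner injected in real time, and anyone who needs a
benchmarked reference implementation of the standard smFRET trajectory
workflow: trace extraction → background correction → variational-Bayes
HMM idealization → dwell-time kinetics → ensemble histograms.

## The model

A donor (Cy3)-labeled intasome binds target DNA carrying an acceptor
(Cy5) near a defined lesion. Binding is a memoryless two-state process
with an absorbing strand-transfer branch:

    unbound --k_on--> bound --k_off--> unbound
                      bound --p_stc--> STC (absorbing)

FRET efficiency per frame is E = I_Cy5 / (I_Cy3 + I_Cy5) after
background correction, with E := 0 wherever either channel approaches
zero (unbound or photobleached). Traces are idealized with a
variational-Bayes Gaussian-emission HMM (4-state initial guess,
conjugate Normal-Gamma/Dirichlet priors, monotone evidence lower
bound). Dwell-time histograms, binned at the Shimazaki–Shinomoto
optimal width, are fit with single exponentials

    Counts_bound   = A1 · exp(−t_on / τ_on)
    Counts_unbound = A2 · exp(−t_off / τ_off)

Strand-transfer frequency per condition is %STC = 100·n/N with
σ = sqrt((n/N)(1 − n/N)·100), and structural FRET predictions follow
the Förster equation E = 1 / (1 + (R/R₀)⁶) with R₀ = 6 nm (Cy3→Cy5,
κ² = 2/3). Gel product lengths map to integration sites as
site = length − vDNA − (2 nt if the fragment carries both dyes).

See `docs/methods.md` for the full account of the model, parameter
defaults and design choices.

## Worked example

Simulate a 40-molecule cohort (1 s frames, 300 s traces, injection at
30 s, τ_on = 0.5 s, τ_off = 15 s, strand-transfer probability 0.05 per
binding event) and run the full pipeline:

```python
from intafret.pipeline import RunConfig, run_pipeline
from intafret.simulate import SimConfig

cfg = RunConfig(
    sim=SimConfig(duration=300.0, injection_time=30.0,
                  p_stc_per_binding=0.05, seed=0),
    n_traces=40, seed=7,
)
print(run_pipeline(cfg))
```

which prints (abridged):

```
n_analyzed: 40        n_stc: 23
pct_stc: 57.5         sigma_pct_stc: 4.94
tau_on_fit:  tau 0.570 ± 0.040 s   (53 dwells)
tau_off_fit: tau 23.0  ± 6.9  s    (43 dwells)
n_transitions: 594    tdp_total: 1187   psh_total: 3378
```

Reading the numbers: 23/40 molecules formed a stable strand-transfer
complex — with ~17 binding opportunities per 270 s trace at 0.05
conversion probability each, the expected per-molecule rate is
1 − 0.95¹⁷ ≈ 58%, and 57.5 ± 4.9% matches. The bound-state lifetime
fit (0.57 s vs the generating 0.5 s) sits in the frame-rate-limited
regime the fitter warns about: at 1 s frames most 0.5 s dwells are
sub-frame and the survivors are the long tail. The unbound lifetime
(23 ± 7 s) is consistent with the generating 15 s. The transition
bookkeeping identity holds: 1187 total transition-density counts =
594 upward + 593 downward threshold crossings.

The same stages are scriptable from the shell:

```bash
intafret simulate --n-traces 10 --outdir sim/     # traces + ground truth
intafret run --seed 7                              # full pipeline, JSON report
intafret fixtures stc_counts --outdir fixtures/        # worked-example tables
```

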