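# Methods

## Problem

Source localization from EEG solves the inverse of the linear forward model

    y = M x + ε,        y ∈ R^{d×K},  M ∈ R^{d×n},  x ∈ R^{n×K},

where `y` are the potentials at `d` electrodes over `K` samples, `M` the
lead field of `n` fixed-orientation cortical sources, and `ε` measurement
noise. High-density montages (hundreds of channels) localize best, but most
of those channels contribute little for any *particular* source
configuration. `eegsel` searches for the minimal electrode subsets that
retain high-density accuracy by coupling NSGA-II with linear inverse
solvers: the objectives, all minimized, are the number of selected channels
and the localization error of each target source — `O = s + 1` objectives
for `s` sources. Evaluating all subsets of `C` channels would need
`2^C − 1` inverse solutions for one source (`s·2^C − 1` for `s`), about
3.4·10³⁸ already at C = 128, which is why a heuristic multi-objective
search is used.

## Spherical head-model fixture

All tests and examples run on an analytic three-shell conductor so nothing
has to be downloaded. Shells (brain/skull/scalp) have radii 80/86/92 mm and
conductivities 0.33/0.0042/0.33 S/m — standard textbook values, the skull
two orders of magnitude more resistive. Sources sit on a 70 mm "cortical"
sphere with radial orientations (distributed models conventionally fix the
orientation normal to the cortical surface); electrodes sit on the outer
shell. Both layouts are golden-angle (Fibonacci) lattices, rigidly rotated
by a seeded random rotation: quasi-uniform, and bit-reproducible per seed.

For a radial unit dipole at radius `b`, the scalp potential is the Legendre
series `V = Σ_l c_l P_l(cos γ)` with `γ` the dipole–electrode angle. Per
degree `l` the five piecewise expansion constants are fixed by
potential/current continuity at the two interior interfaces and zero radial
current at the scalp; the 5×5 system is solved in radii normalized by the
outer radius so that `r^l` stays within floating-point range at high
degree. The series is truncated at `l = 80` by default: coefficients decay
like `(b/R)^l ≈ 0.76^l`, leaving a relative truncation error below 1e-6
(verified against a 4× longer truncation). In the homogeneous limit
(equal conductivities) the coefficients reduce to the classic
`(2l+1) (b/R)^{l-1} / (4πσ)` single-sphere series, which the tests check to
machine precision. Potentials are expressed in µV for a 10 nA·m dipole;
all downstream metrics except the millimetre localization error are
invariant to this scale.

Montage constraints never subset the matrix: a mask only clamps the
corresponding genes to zero, because the inverse operator is deliberately
kept at full dimension (see below). Packaged `sub128`/`sub60` label lists
provide quasi-uniform sub-montages of the default 231-channel fixture.

## Synthetic EEG generator

Each source is a Gaussian-windowed sinusoid

    x_i(t) = exp(−((t − c_i)² / (2σ²))) · sin(2π f_i t).

The default plan has six sources: occipital 19 Hz (beta) at c = 0.5 s,
sensorimotor 10 Hz (mu) at 1.0 s, frontal 7 Hz (theta) at 1.5 s, and the
same three locations/frequencies repeated at 2.0/2.5/3.0 s. All widths are
σ = 0.12 s, which makes adjacent sources overlap in time; trials are 3.5 s
at 200 Hz (K = 700 samples); datasets default to 150 trials. Only the
first three sources are used as optimization objectives in the
multi-source setting; the repeats stay in the signal as structured
interference.

Per region (occipital / sensorimotor / frontal) twelve candidate vertices
(six per hemisphere) are predefined; each trial draws one vertex per region
uniformly, so trials differ in source placement. On the fixture the sets
are selected by spatial criteria — most posterior, most superior, most
anterior vertices per hemisphere, kept disjoint — computed
deterministically from the source grid rather than shipped as static
indices, so they remain valid for any grid size.

Noise is i.i.d. Gaussian per channel and sample, then rescaled globally so
that `10·log10(P_signal/P_noise)` equals the configured SNR *exactly*, with
`P` the mean squared amplitude pooled over all channels and samples
(default 0 dB: signal and noise with the same power). The exact rescaling
makes error levels comparable across trials and lets the realized SNR be
asserted rather than estimated. Per-trial seeds are spawned from the
dataset seed, and a JSON manifest records every trial's vertices,
positions and seed.

What the generator does **not** emulate: ongoing-EEG background (pink
noise, alpha rhythm), spatially correlated noise, artifacts, realistic
cortical folding (sources sit on a sphere at a single depth), or
subject-to-subject forward-model variability. Passing tests therefore show
the *method* behaves as designed under controlled conditions, not that any
particular error level transfers to recordings from real heads.

## Inverse solvers

Both solvers are linear and are applied to the full-dimension epoch;
channels excluded by a chromosome arrive as all-zero data rows. Keeping
the operator at full dimension avoids increasing the ill-posedness of a
subsetted lead field and — practically — lets one precomputed kernel serve
tens of thousands of candidate evaluations per trial.

* **wMNE** — depth-weighted Tikhonov solution
  `x̂ = W⁻¹Mᵀ(MW⁻¹Mᵀ + λI)⁻¹ y` with `W = diag(‖m_j‖^{2p})`; the depth
  exponent `p` defaults to 1 (p = 0 gives plain MNE). The SPD system is
  solved by Cholesky factorization; at λ = 0 with a rank-deficient Gram
  matrix the solver falls back to the pseudo-inverse and flags the
  estimate.
* **sLORETA** — minimum-norm estimate `x̂_mn = Mᵀ(MMᵀ + λI)⁻¹ y`
  standardized per source by `√R_ii`, `R = Mᵀ(MMᵀ + λI)⁻¹M`. For a single
  noiseless dipole the standardized power peaks exactly at the true vertex
  for any λ ≥ 0 (Cauchy–Schwarz on the PSD matrix R); the tests verify
  this exhaustively over the fixture. Sources invisible to the montage
  (vanishing `R_ii`) are zeroed with a warning.

Regularization defaults to an SNR-based rule,
`λ = trace(MW⁻¹Mᵀ) / (d·10^{SNR_dB/10})` — the mean eigenvalue of the
(weighted) Gram matrix divided by the linear SNR, with SNR 0 dB matching
the simulator default; a fixed λ can be set instead, and results do depend
on this choice. A common-average-reference projection is applied to data
and lead field by default (standard EEG convention; can be disabled). No
noise-covariance whitening is applied — the simulator's noise is white.
Additional solvers can be registered as kernel factories
(`register_solver`), which is how a Bayesian or beamformer method would be
plugged into the same pipeline.

## Metrics

Localization uses the element-wise power `x̂²` averaged over a
time-of-interest; the vertex with the highest mean power is the estimate,
ties resolving to the lowest vertex index, and the localization error is
the Euclidean distance in mm to the true position. TOIs map to half-open
sample windows `[round(start·fs), round(end·fs))`, so a boundary shared by
two consecutive windows (e.g. 750 ms) belongs to the later one only — no
sample is counted twice. The standard TOIs for the three-source setting
are 250–750, 750–1250 and 1250–1750 ms.

Waveform similarity between reconstructions uses the relative error
`‖x₁ − x₂‖/‖x₁‖` (reference `x₁` = the reconstruction with more
electrodes) and the Pearson correlation; no sign alignment is applied
before comparison. The **accuracy index** is the percentage of trials in
which a subset's error is ≤ the all-channel baseline's for the same trial
— exact floating `≤`, ties counting as success. Summary tables use the
sample standard deviation (ddof = 1; reported as 0 for a single trial) and
keep full precision on disk, rounding only for display.

## NSGA-II

Chromosomes have one gene per lead-field channel; genes outside the
montage mask are clamped to zero. Two operator suites are provided:

* **real** (default): SBX crossover and polynomial mutation act on gene
  proxies in [0, 1], thresholded at 0.5 at evaluation time — the behavior
  of real-coded NSGA-II solvers adapted to binary gene vectors;
* **binary**: uniform crossover and per-gene bit flips.

Defaults: population 100, 400 generations, crossover probability 0.9,
mutation probability 1/C, distribution indices 20. Selection is binary
tournament on (rank, crowding); survivors are the best P of the merged
2P parent+offspring pool via non-dominated sorting with crowding-distance
truncation. Evaluations are cached on the thresholded chromosome since
duplicates recur. Every evaluated candidate is logged with its
generation: the initial population as generation 0, then exactly P
offspring per generation — a default run therefore logs 40,000 offspring
evaluations (40,100 including generation 0).

Two further design choices matter in practice:

* The all-zero chromosome is degenerate (no data at all); it receives
  penalty objectives (0 channels, 10⁶ mm per source) so it never survives
  selection while keeping the operator pipeline uniform.
* The initial population is anchored with the full-montage chromosome.
  Without it the selection pressure toward few channels means high channel
  counts are abandoned almost immediately and the logged front never
  covers them; with it the log always contains the high-density reference
  and the front spans the full channel range.

**Representation benchmark.** On an enumerable 8-channel instance (255
subsets, exhaustive optimum known per channel count), binary-mode runs of
64×150 with pm = 2/C recovered the exhaustive optimum at *every* channel
count in 20/20 seeded runs, while equally long real-proxy runs managed
6/20: with distribution index 20 a mutated proxy rarely crosses the 0.5
threshold, so the real representation under-explores small binary spaces.
The GA-behavior tests therefore run the binary suite; the real suite
remains the default for fidelity to the classic operator definitions and
behaves equivalently on larger instances where the front is dominated by
low channel counts.

## Pipeline

Per candidate: weight the EEG (`y_w = y ⊙ chromosome` row-wise), invert
with the precomputed kernel, localize each target source in its own TOI,
return `[channel count, locE₁ … locE_s]`. Since only TOI samples reach the
power average, the epoch is cropped once to the TOI span. Per trial: run
the GA, evaluate the all-channels baseline, and extract the
**pseudo-Pareto front** — the best logged candidate per channel count over
*all* generations, ranked by the mean of the per-source errors (the error
itself for s = 1), ties broken by earliest generation then
lexicographically smallest bitstring. Per dataset: per channel count, the
mean and sample SD of front errors across the trials whose fronts contain
that count, plus the accuracy index against the paired baselines. Trials
are optimized independently (independent seeds), so results do not depend
on scheduling order.

## Problem sizes used by the test suite

The packaged checks are desk-scale by design: fixtures of 8–64 channels
and 30–400 sources, datasets of 1–150 trials, GA runs up to 100×400. The
plateau check uses a 32-channel fixture, 20 noisy single-source trials,
sLORETA, forward grid of 400 sources and inversion grid of 240 (distinct
grids avoid the "inverse crime" of inverting on the simulation grid), and
compares channel counts 5–16 against the 32-channel baseline. The whole
suite runs in under two minutes on one CPU.

## Known limitations

* The spherical fixture has a single source depth; depth-weighting in
  wMNE is therefore nearly inert in the packaged tests, and absolute
  error levels are set largely by the inversion-grid spacing.
* λ selection, referencing and whitening choices shift absolute errors;
  only behavioral properties (plateau shape, accuracy indices, exact
  noiseless localization) are asserted, not specific millimetre values.
* The real-proxy operator suite under-explores very small search spaces
  (see the representation benchmark above).
* Bayesian sparse-prior solvers are not implemented; the plug-in kernel
  interface is the intended extension point.
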