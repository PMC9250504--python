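# eegsel

Minimal EEG electrode subsets for accurate source localization, found by
multi-objective optimization.

High-density EEG (hundreds of electrodes) gives the most accurate estimates
of where in the brain a signal originates, but for any *particular* source
configuration most of those electrodes are redundant. `eegsel` answers two
questions for researchers working on EEG source imaging, wearable/low-density
EEG and source-based BCIs: *how few electrodes are enough to localize a given
source as well as the full montage, and which ones are they?*

## Method

EEG measurements follow the linear forward model `y = Mx + ε`, with
`y ∈ R^{d×K}` the potentials at `d` electrodes, `M ∈ R^{d×n}` the lead field
of `n` cortical sources and `x` the source activity. The package couples the
elitist non-dominated sorting genetic algorithm **NSGA-II** with linear
inverse solvers (**wMNE**, depth-weighted Tikhonov; **sLORETA**,
variance-standardized minimum norm). Each chromosome is a binary vector with
one gene per electrode; a candidate subset is evaluated by zeroing the
excluded channels (`y_w = y · chromosome`, the operator keeps its full
dimension), solving the inverse problem, and localizing each target source as
the vertex of highest mean estimated power inside its time-of-interest. The
GA simultaneously minimizes the number of channels and the localization error
of each of the `s` sources (`s + 1` objectives, e.g. distance
`LocE = ‖P_x − P_x̂‖₂` in mm per source). From the log of all evaluated
candidates, the best subset per channel count forms the **pseudo-Pareto
front** (ranked by mean per-source error), and the **accuracy index** reports
the percentage of trials in which a subset did at least as well as the
all-channel baseline.

Everything runs download-free: an analytic three-shell spherical head model
(80/86/92 mm, 0.33/0.0042/0.33 S/m) provides lead fields, and a simulator
generates ground-truth trials of Gaussian-windowed sinusoidal sources
(occipital 19 Hz, sensorimotor 10 Hz, frontal 7 Hz, σ = 0.12 s, 3.5 s at
200 Hz) with exactly 0 dB white channel noise. Externally computed
lead-field archives (HDF5) can be loaded through a field-name mapping.
See `docs/methods.md` for the full model description and design choices.

## Worked example

`examples/optimize_channels.py` optimizes electrode subsets for one noisy
single-source trial on a 32-channel fixture (forward grid 400 sources,
inversion grid 240):

```
offspring evaluations: 40000, unique subsets tried: 5219
all-channel baseline: locE 3.40 mm with 32 channels
pseudo-Pareto front (best subset per channel count, up to 10 channels):
   1 channels  locE  20.50 mm   00000000000000100000000000000000
   2 channels  locE   3.40 mm   00000010000000100000000000000000
   3 channels  locE   3.40 mm   00000010000001100000000000000000
   4 channels  locE   3.40 mm   00000010000010100000000000000010
   5 channels  locE   3.40 mm   00000010000000100100011000000000
   ...
```

One electrode is not enough (20.5 mm error), but already two well-placed
electrodes match the full 32-channel montage (3.40 mm, the floor set by the
inversion-grid spacing) — the characteristic plateau of the pseudo-Pareto
front. The bitstrings show which channels are on. The other examples cover
dataset simulation (`simulate_dataset.py`) and plain source reconstruction
with both solvers (`localize_single_trial.py`); a thin CLI
(`eegsel simulate|optimize|summarize`) wraps the same library calls for
shell use.

```python
import eegsel as es

lf = es.build_spherical_leadfield(32, 240, seed=0)
trials, _ = es.generate_dataset(lf, n_trials=1, seed=42)
cfg = es.RunConfig(
    solver=es.SolverConfig(method="sloreta"),
    ga=es.GAConfig(population=100, generations=400, seed=0),
    tois=(es.TOI(0.25, 0.75),),
)
result = es.run_optimization(trials[0], lf, cfg)
print(result.front.head())
```

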