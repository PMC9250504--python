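"""Reconstruct the sources of one noisy trial with sLORETA and wMNE.

Simulates one trial on a dense forward grid, inverts it on a coarser grid
(different grids avoid the 'inverse crime') and reports per-source
localization errors using each source's own time-of-interest window.
"""

import numpy as np

import eegsel as es

lf_forward = es.build_spherical_leadfield(64, 400, seed=0)
lf_inverse = es.build_spherical_leadfield(64, 240, seed=0)  # same electrodes, coarser sources

trials, _ = es.generate_dataset(lf_forward, n_trials=1, seed=3)
trial = trials[0]
tois = [es.TOI(0.25, 0.75), es.TOI(0.75, 1.25), es.TOI(1.25, 1.75)]

for method in ("sloreta", "wmne"):
    estimate = es.solve(trial.y, lf_inverse, es.SolverConfig(method=method))
    errors = []
    for spec, toi in zip(trial.sources, tois):
        res = es.estimate_location(estimate.x_hat, lf_inverse.source_positions, toi, trial.fs)
        errors.append(es.loc_error(spec.position, res.estimated_position))
    print(f"{method:8s} lambda={estimate.lambda_used:9.2f}  locE per source (mm): "
          + "  ".join(f"{e:6.2f}" for e in errors)
          + f"   mean {np.mean(errors):6.2f}")
print("(localization error = distance between the true dipole and the vertex of "
      "highest TOI-mean estimated power; the coarser inversion grid sets a floor "
      "of a few mm)")
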