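"""Two-cell Metropolis model: asymmetric vs symmetric attractor wells.

Runs small replicate ensembles of both model variants and prints the
final-axis deviation and trajectory-noise readouts that distinguish
them.  The asymmetric model (wells at opposite poles of the A-P axis)
terminates aligned with the axis and rotates smoothly; the symmetric
model (both wells on one side, the cells compete) terminates off-axis
and is noisier.
"""

import numpy as np

from dyadrot import make_asymmetric_config, make_symmetric_config, run_ensemble
from dyadrot.config import RunConfig
from dyadrot.simulator import _ensemble_readouts, final_axis_deviation, relative_well_depth

N_REPS = 60  # a quick look; the full replicate sweeps use 100

for factory in (make_asymmetric_config, make_symmetric_config):
    cfg = factory(seed=4)
    out = run_ensemble(cfg, n_reps=N_REPS, seed=4)
    dev = final_axis_deviation(out["final_theta1"], out["final_theta2"])
    reads = _ensemble_readouts(out, cfg, RunConfig())
    noise = reads.loc[~reads.noise_excluded, "noise"]
    name = "asymmetric" if factory is make_asymmetric_config else "symmetric "
    print(f"{name} model (relative well depth {relative_well_depth(cfg):.1f}):")
    print(f"  median final-axis deviation: {np.median(dev):5.1f} deg "
          f"(IQR {np.percentile(dev, 25):.1f}-{np.percentile(dev, 75):.1f})")
    print(f"  median trajectory noise:     {np.median(noise):5.1f}")
print()
print("Opposed wells terminate closer to the A-P axis with lower")
print("rotational noise; competing wells on one side scatter the final")
print("axis further off-axis and make the dynamics noisier — relative")
print("asymmetry of the attractors, not their absolute depth, sets the")
print("precision of the inversion.")
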