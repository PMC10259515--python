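"""Three-phase segmentation of a rotation by a 4-parameter logistic.

Fits c + (d - c)/(1 + exp(-b (t - a))) to a cumulative-angle curve and
derives the phase boundaries Ic = a - 2/b and Id = a + 2/b where the
inflection tangent meets the asymptotes.
"""

import numpy as np

from dyadrot import CellPairRecord, angle_series, center_pair, fit_phase_logistic
from dyadrot.synth import PairSynthesisParams, generate_pair_tracks

true = dict(a_min=120.0, b_per_min=0.06, c_deg=0.0, d_deg=165.0)
params = PairSynthesisParams(**true, wobble_sd_deg=3.0, seed=2)
rec = CellPairRecord.from_track_table(
    generate_pair_tracks(params), "cell_a", "cell_b"
)
series = angle_series(center_pair(rec))
fit = fit_phase_logistic(series)

print("true parameters:   a=120.0 min  b=0.060 /min  span=165.0 deg")
print(
    f"fitted parameters: a={fit.a:.1f} min  b={fit.b:.3f} /min  "
    f"span={fit.d_high - fit.c:.1f} deg  (residual RMS {fit.residual_rms:.2f} deg)"
)
print(f"phase boundaries:  Ic={fit.ic:.1f} min  Id={fit.id_:.1f} min")
print(f"  Phase 1 (pre-rotation):    0 .. {fit.ic:.0f} min")
print(f"  Phase 2 (active rotation): {fit.ic:.0f} .. {fit.id_:.0f} min "
      f"(duration 4/b = {4 / fit.b:.0f} min)")
print(f"  Phase 3 (settled):         {fit.id_:.0f} min .. end")
print()
print("Despite 3 deg of frame-to-frame wobble the midpoint and steepness")
print("are recovered to within a few percent; the tangent construction")
print("turns them into objective phase boundaries.")
assert np.isfinite(fit.ic)
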