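"""Rotation metrics of one synthetic sibling pair.

Generates a noisy inverting pair (logistic angular progression with
per-frame wobble), runs the full kinematic pipeline and prints the
scalar statistics a tracking experiment would yield.
"""

from dyadrot import (
    CellPairRecord,
    PairSynthesisParams,
    compute_rotation_metrics,
    generate_pair_tracks,
)

params = PairSynthesisParams(
    a_min=100.0,      # rotation midpoint, minutes after birth
    b_per_min=0.08,   # logistic steepness
    d_deg=170.0,      # total angular progression
    wobble_sd_deg=2.0,
    seed=11,
)
table = generate_pair_tracks(params)
pair = CellPairRecord.from_track_table(table, "cell_a", "cell_b", genotype="synthetic")
m = compute_rotation_metrics(pair)

print(f"pair {m.pair_id} ({m.genotype})")
print(f"  inverting:      {m.inverting} (final turn {m.final_turn:.1f} deg > 90 deg)")
print(f"  handedness:     {m.handedness}  (positive = anti-clockwise)")
print(f"  starting/final angle: {m.starting_angle:.1f} / {m.final_angle:.1f} deg")
print(f"  overshoot:      {m.overshoot:.1f} deg  (max turn minus final turn)")
print(f"  wobbling:       {m.wobbling:.1f} deg  (arc length minus final turn)")
print(f"  noise:          {m.noise:.3f}     (path/chord; 1 = perfectly directed)")
print(f"  phase boundaries: onset {m.onset:.0f} min, duration {m.duration:.0f} min")
print()
print("The pair performs one net ~170 deg inversion; the per-frame wobble")
print("adds recurrent to-and-fro swings that the wobbling and noise")
print("statistics accumulate, and the phase fit places the active rotation")
print(f"between {m.fit.ic:.0f} and {m.fit.id_:.0f} min.")
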