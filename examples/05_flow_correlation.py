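"""Epithelium-wide movement correlation along the A-P axis.

Embeds a mirror-rotating sibling pair in a jittering epithelium and
correlates frame-to-frame x displacements for the three pairing
classes: the rotating pair itself, rotating-vs-bystander and
bystander-vs-bystander.
"""

from dyadrot import correlate_classes, summarize_correlations
from dyadrot.synth import EpitheliumSynthesisParams, PairSynthesisParams, generate_epithelium

pair = PairSynthesisParams(track_ids=("hc1", "hc2"), wobble_sd_deg=2.0, seed=5)
table = generate_epithelium(
    EpitheliumSynthesisParams(n_cells=10, n_frames=150, seed=5), embedded_pair=pair
)
report = correlate_classes(table, ("hc1", "hc2"))
summary = summarize_correlations(report).set_index("pair_class")

for cls, row in summary.iterrows():
    print(f"{cls:12s}: mean R = {row['mean_r']:+.3f}  median R = {row['median_r']:+.3f}  "
          f"({int(row['n_pairings'])} pairings)")
print()
print("The two rotating cells are almost perfectly anticorrelated (they")
print("move mirror-symmetrically about their centroid), while their")
print("movement is uncorrelated with the surrounding epithelium — the")
print("rotation is a local, autonomous movement, not tissue flow.")
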