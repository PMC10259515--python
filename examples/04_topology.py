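"""Cumulative neighbor difference and the "popular" cell.

Compares a symmetric neighbor-exchange sequence with a biased one in
which one sibling persistently keeps an extra neighbor, the signature
the dynamic-network analysis detects.
"""

import numpy as np

from dyadrot import cumulative_neighbor_difference, popular_cell
from dyadrot.synth import generate_neighbor_series
from dyadrot.topology import cumulative_difference_series, smooth_difference

balanced = generate_neighbor_series(80, bias=0, p_exchange=0.4, seed=3)
biased = generate_neighbor_series(80, bias=1, seed=3)

d_bal = cumulative_difference_series(balanced)
d_bias = cumulative_difference_series(biased)

print(f"balanced exchange:  D(80) = {cumulative_neighbor_difference(balanced, 80)}, "
      f"max |D| = {np.max(np.abs(d_bal))}")
print(f"biased (+1):        D(80) = {cumulative_neighbor_difference(biased, 80)}")
label, slope = popular_cell(balanced)
print(f"popularity call, balanced: {label} (slope {slope:+.3f} per frame)")
label, slope = popular_cell(biased)
print(f"popularity call, biased:   {label} (slope {slope:+.3f} per frame)")

sm = smooth_difference({"balanced": [d_bal], "biased": [d_bias]}, span=0.4)
end = sm.groupby("group")["smoothed"].last()
print(f"LOESS-smoothed |D| at T=80: balanced {end['balanced']:.1f}, "
      f"biased {end['biased']:.1f}")
print()
print("Symmetric exchange keeps the cumulative difference bounded near")
print("zero; a persistent one-neighbor surplus makes D(T) grow linearly,")
print("naming sibling A the popular cell.")
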