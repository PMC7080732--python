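"""The φ transform and Cohen's h on a tiny count table.

Shows how counts become proportions, how φ = 2·arcsin(√p) stabilises them,
and how the difference of two φ values is Cohen's h.
"""

import math

import pandas as pd

from tqrank import CountMatrix, cohens_h, phi, phi_transform, to_proportions

counts = CountMatrix(pd.DataFrame(
    {"cellA": [80, 15, 5, 12], "cellB": [5, 20, 75, 11]},
    index=["g1", "g2", "g3", "ERCC-1"],
))
props = to_proportions(counts)  # spike-in row excluded from totals
print("proportions (spike excluded):")
print(props.values.round(3))

mat = phi_transform(props)
print("\nφ values (range 0..π):")
print(mat.values.round(3))

h = cohens_h(0.8, 0.05)
print(f"\nCohen's h between p=0.80 and p=0.05: {h:.3f} "
      f"(φ units; {h / math.pi:.0%} of the maximal contrast π)")
print(f"small-p behaviour: φ(1e-6) = {phi(1e-6):.6f} ≈ 2·√1e-6 = 0.002000")
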