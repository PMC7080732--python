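"""Quality-control surfaces on a simulated dataset.

Detection tallies, the within- versus cross-embryo correlation contrast
(the batch-effect signature) and PCA variance fractions.
"""

from tqrank import (
    SimConfig,
    correlation_structure,
    detected_genes_per_sample,
    pca_variance_explained,
    phi_transform,
    simulate_dataset,
    to_proportions,
)

counts, sheet, _ = simulate_dataset(SimConfig(seed=3))
detected = detected_genes_per_sample(counts)
print(f"genes detected per sample (count > 0): median {detected.median():.0f}, "
      f"range {detected.min()}–{detected.max()}")

norm = phi_transform(to_proportions(counts))
cs = correlation_structure(norm, sheet)
print(f"mean correlation within embryos:            {cs['within_embryo']:.3f}")
print(f"mean correlation across embryos, same cell: "
      f"{cs['cross_embryo_same_celltype']:.3f}")
print("samples from one embryo correlate more strongly than the same cell "
      "type does across embryos — the batch effect the design averages out.")

frac = pca_variance_explained(norm)
print(f"\nPC1+PC2 explain {100 * (frac[0] + frac[1]):.1f}% of the variance")
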