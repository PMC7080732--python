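# tqrank

ON/OFF expression-pattern discovery and **Transquartile Range (TQR)**
ranking for small, fully-annotated single-cell RNA-seq designs — the kind
of experiment where every cell's identity is known in advance, such as the
eight named blastomeres (a5.3, a5.4, b5.3, b5.4, A5.1, A5.2, B5.1, B5.2)
of the 16-cell ascidian (*Ciona*) embryo sampled across a handful of
embryos.

## Who this is for

Developmental biologists and computational groups who want to turn a
genes × cells count table into a ranked list of cell-specific expression
patterns without fitting a parametric noise model: which genes are ON in
which cells, and how reliably. The package also ships a synthetic-embryo
count generator with planted ground truth, so the whole pipeline can be
exercised and benchmarked without any sequencing data.

## The method

1. **Depth normalisation.** Counts are divided by the per-sample total
   (spike-in rows excluded by default): `p_ij = k_ij / N_j`. No across-gene
   normalisation is applied — the analysis compares the same gene across
   cell types.
2. **φ transform.** Proportions are variance-stabilised with
   `φ(p) = 2·arcsin(√p)` (range 0..π). The difference of two φ values is
   Cohen's *h*, the standard effect size for proportions, so distances in φ
   space are effect-size distances.
3. **Per-gene two-cluster cut.** For each gene, the Euclidean distances
   between the cell types' replicate vectors (one φ value per embryo) are
   clustered by single-linkage agglomeration, stopping before the final
   merge. The two top-level clusters define the gene's ON and OFF cells
   (ON = larger pooled mean). This is equivalent to deleting the heaviest
   edge of a minimum spanning tree over the cell types.
4. **TQR ranking.** Each call is scored with the Transquartile Range

   `TQR = Q1(ON values) − Q3(OFF values)`

   using type-5 ("hydrologist") quantiles over the pooled replicate
   values. The TQR grows with the separation of the clusters and shrinks
   with their spread; genes are ranked by TQR descending.
5. **Catalogue comparison.** Ranked calls can be tallied against a
   catalogue of known patterns (exact 8-bit equality, with alternate
   acceptable patterns for cross-hybridising probes), reporting matches,
   distinct patterns, and novel patterns in the top N.

## Worked example

```python
from tqrank import SimConfig, simulate_dataset, run_discovery, evaluate_recovery

counts, sheet, truth = simulate_dataset(SimConfig(seed=1))
calls = run_discovery(counts, sheet)
for c in calls[:3]:
    print(c.rank, c.gene_id, c.pattern_string, round(c.tqr, 4))
m = evaluate_recovery(calls, truth, top_n=40)
print(m.fraction_in_top, m.fraction_exact_pattern)
```

prints

```
1 SIMG00416 00000001 0.0868
2 SIMG00713 00000001 0.0784
3 SIMG00085 11110000 0.0782
0.95 1.0
```

The top-ranked gene is called ON only in B5.2 (last bit of the pattern)
with a TQR of 0.087 φ units — its ON cluster's lower quartile clears the
OFF cluster's upper quartile by that margin. 95% of the 40 planted genes
land in the top 40 ranks, all with exactly the planted bit vector.

The same workflow is available from the shell:

```bash
tqrank simulate --out sim/ --seed 1
tqrank discover --counts sim/counts.tsv --samples sim/samples.tsv --out calls.tsv
tqrank compare --calls calls.tsv --top-n 40
tqrank qc --counts sim/counts.tsv --samples sim/samples.tsv --out qc.json
```

See `examples/` for short narrative scripts covering each capability.

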