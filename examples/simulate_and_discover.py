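"""Simulate a synthetic 16-cell embryo experiment and rank its patterns.

Generates 1,000 genes (40 with planted ON/OFF patterns) over 8 cell types
× 4 embryos, runs the discovery pipeline and scores how well the planted
genes are recovered in the top 40 ranks.
"""

from tqrank import SimConfig, evaluate_recovery, run_discovery, simulate_dataset

cfg = SimConfig(seed=1)
counts, sheet, truth = simulate_dataset(cfg)
print(f"simulated {counts.shape[0]} genes × {counts.shape[1]} samples "
      f"({int(counts.is_spike.sum())} spike-in rows)")

calls = run_discovery(counts, sheet)
print("\ntop 5 calls (pattern bits follow the canonical cell order):")
for c in calls[:5]:
    truth_pat = truth.table.loc[c.gene_id, "pattern"]
    print(f"  rank {c.rank:>2}  {c.gene_id}  {c.pattern_string}  "
          f"TQR={c.tqr:.4f}  planted={truth_pat or 'none'}")

m = evaluate_recovery(calls, truth, top_n=40)
print(f"\n{m.fraction_in_top:.0%} of the 40 planted genes are in the top 40;"
      f" {m.fraction_exact_pattern:.0%} of those carry the exact planted pattern.")
print("A high TQR means the ON cluster's lower quartile clears the OFF "
      "cluster's upper quartile — a reliable, well-separated pattern.")
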