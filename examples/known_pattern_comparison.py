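"""Compare ranked calls against a known-pattern catalogue.

Runs discovery on a simulated dataset, then tallies the top-40 calls
against the packaged (synthetic stand-in) catalogue of marker genes.
"""

from tqrank import (
    SimConfig,
    compare_to_catalogue,
    default_catalogue,
    run_discovery,
    simulate_dataset,
)

counts, sheet, truth = simulate_dataset(SimConfig(seed=2))
calls = run_discovery(counts, sheet)
report = compare_to_catalogue(calls, default_catalogue(), top_n=40)
print(report.to_text())
print("\nSimulated gene ids are absent from the catalogue, so they appear "
      "as 'not in catalogue' candidates; distinct/novel pattern counts show "
      "how many different bit vectors the top 40 calls contain and which "
      "are outside the nine named reference patterns.")
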