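"""In-memory sort-seq experiment: sort, sequence, and map the footprint.

Simulates FACS sorting of a planted library into high/low GFP bins,
preprocesses the per-bin reads, and prints the strongest positions of the
mutual-information footprint together with extreme enrichment entries.
"""

import sortseq_footprint as sf
from sortseq_footprint.pipeline import PipelineConfig, analyze_stage, simulate_stage

reference = sf.bmo_reference()
config = PipelineConfig(seed=1, n_variants=10_000, n_cells=100_000,
                        n_reads_per_bin=50_000)
sim = simulate_stage(config, reference)
analysis = analyze_stage(sim["reads"], reference, config)

footprint = analysis["footprint"]
top = sf.rank_positions(footprint, 10)
print("top-10 MI positions (bits):")
for pos in top:
    print(f"  P{pos}: {footprint.mi_bits[pos]:.4f}")

high = analysis["enrichment"]["high"].to_long()
best = high.loc[high["log2_ratio"].idxmax()]
print(f"most enriched identity in the high bin: "
      f"P{int(best['position'])}{best['base']} (log2 ratio {best['log2_ratio']:+.2f})")
# Peaks mark positions whose base identity controls expression: the
# essential core (P199-P201) and its flanking band dominate, and the
# beneficial G(205)A identity is enriched among high-GFP cells.
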