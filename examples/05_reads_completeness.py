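"""Completeness straight from long reads, without an assembly.

Simulates 20x coverage of 8 kb reads (5% substitution errors) from a
synthetic genome, groups them into blocks, reservoir-samples the blocks,
and scans them iteratively: each block may reveal new marker families, and
scanning stops after 20 consecutive blocks reveal nothing new — the
rarefaction curve has plateaued, so more sequencing would add little.
"""

import mycocheck as mc

markerset = mc.make_marker_set(n_families=15, n_multicopy=0, n_hde=0, rng_seed=25)
assembly, _ = mc.make_genome(markerset, rng_seed=26, target_length=600_000, n_contigs=3)
n_reads = 20 * assembly.total_length // 8000
reads = mc.simulate_reads(assembly, n_reads, length_mean=8000, error_rate=0.05, rng_seed=27)
print(f"simulated {n_reads} reads (~20x coverage)")

params = mc.Params(block_size=100, rng_seed=28)
result = mc.reads_completeness(iter(reads), markerset, params)
curve = result["curve"]
print(f"detected {result['pct_detected']:.0f}% of families")
print(f"stopped after {curve.stopped_at} blocks ({curve.stop_reason})")
print()
print("rarefaction (first 6 iterations):")
for rec in curve.per_iteration[:6]:
    print(f"  block {rec.block_id:3d}: +{rec.new_markers:2d} new, "
          f"{rec.cumulative_markers:2d} cumulative")
print()
print("Most families appear in the first few blocks; the long tail of")
print("zero-gain blocks is what triggers the stop rule.")
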