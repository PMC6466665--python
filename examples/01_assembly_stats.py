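"""Contiguity statistics: N50, L50, and the N fraction of an assembly.

Builds a toy assembly of five contigs and prints its statistics. N50 is the
length of the contig at which the descending cumulative length first
reaches half the assembly; L50 is that contig's rank — a long N50 with a
small L50 means the assembly is held by a few large pieces.
"""

import mycocheck as mc

assembly = mc.Assembly(
    [
        mc.SeqRecord("c1", "A" * 10_000),
        mc.SeqRecord("c2", "C" * 8_000),
        mc.SeqRecord("c3", "G" * 6_000 + "N" * 500),
        mc.SeqRecord("c4", "T" * 4_000),
        mc.SeqRecord("c5", "A" * 2_000),
    ]
)
stats = mc.assembly_stats(assembly)
print(f"contigs        {stats.n_contigs}")
print(f"total length   {stats.total_length}")
print(f"N50 length     {stats.n50_length}")
print(f"L50 count      {stats.l50_count}")
print(f"N fraction     {stats.n_fraction:.4f}")
print()
print("Half the assembly is contained in the", stats.l50_count, "largest contigs,")
print("the shortest of which is", stats.n50_length, "bases long.")
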