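"""Synthetic marker sets, genomes, truncations and long reads.

Every pipeline stage is testable against constructed ground truth: marker
families are simulated as an ancestral peptide with independently diverged
member copies, genomes are random-background contigs with the marker genes
(reverse-translated with uniform codon choice) and conserved DNA elements
inserted at recorded loci, truncation removes random windows of sequence
the way real assembly gaps lose loci, and long reads are drawn with
substitution errors in the error regime of single-molecule sequencers.

Deliberate simplifications: read errors are substitutions only (the
homology engine is not frameshift tolerant, so indels would test an
undefined behavior), codon usage is uniform, and backgrounds are i.i.d.
nucleotides — none of which affect the recovery properties being tested.
Generators are bit-reproducible given (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .homology import reverse_complement
from .markers import HdeElement, MarkerFamily, MarkerSet, Params
from .seqio import AMINO_ACIDS, Assembly, SeqRecord

_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in sorted(standard_dna_table.forward_table.items()):
    _CODONS_FOR.setdefault(_aa, []).append(_codon)


@dataclass(frozen=True)
class Locus:
    id: str
    contig_id: str
    strand: str
    genome_start: int
    genome_end: int
    kind: str  # "protein" | "hde"


@dataclass
class TruthTable:
    loci: list[Locus]
    genome_params: dict
    introns: list[tuple[str, str, int, int]] = field(default_factory=list)

    def loci_for(self, marker_id: str) -> list[Locus]:
        return [l for l in self.loci if l.id == marker_id]

    def to_tsv(self) -> str:
        lines = ["#id\tcontig_id\tstrand\tgenome_start\tgenome_end\tkind"]
        for l in self.loci:
            lines.append(
                f"{l.id}\t{l.contig_id}\t{l.strand}\t{l.genome_start}\t{l.genome_end}\t{l.kind}"
            )
        return "\n".join(lines) + "\n"


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate_peptide(rng: np.random.Generator, seq: str, divergence: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < divergence:
            choices = [a for a in AMINO_ACIDS if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def make_marker_families(
    n_families: int,
    n_members: int = 8,
    mean_length: int = 200,
    divergence: float = 0.1,
    rng_seed: int = 0,
    params: Params = Params(),
) -> list[MarkerFamily]:
    """Simulate protein families: a random ancestor plus diverged members.

    Members carry independent substitutions at the given per-site rate
    (no indels, so the trivial ungapped alignment is exact). Profiles and
    the 80%-of-minimum thresholds are built the same way user-supplied
    alignments would be.
    """
    if n_families < 1:
        raise ValueError("need at least one family")
    if not 0 <= divergence < 0.5:
        raise ValueError("divergence must be in [0, 0.5)")
    rng = np.random.default_rng(rng_seed)
    families = []
    for f in range(n_families):
        length = int(rng.integers(int(mean_length * 0.9), int(mean_length * 1.1) + 1))
        ancestor = _random_peptide(rng, length)
        rows = [
            SeqRecord(f"sp{m:02d}", _mutate_peptide(rng, ancestor, divergence))
            for m in range(n_members)
        ]
        families.append(MarkerFamily.build(f"fam{f:03d}", rows, params=params))
    return families


def make_hde_elements(
    n_elements: int,
    n_members: int = 5,
    length: int = 300,
    divergence: float = 0.1,
    rng_seed: int = 0,
    params: Params = Params(),
) -> list[HdeElement]:
    """Simulate conserved DNA elements (>= 200 bp, members >= 70% identity)."""
    if not 0 <= divergence <= 0.3:
        raise ValueError("HDE divergence must keep members at >= 70% identity")
    rng = np.random.default_rng(rng_seed)
    elements = []
    bases = "ACGT"
    for e in range(n_elements):
        ancestor = "".join(rng.choice(list(bases), size=length))
        rows = []
        for m in range(n_members):
            out = list(ancestor)
            for i in range(len(out)):
                if rng.random() < divergence:
                    choices = [b for b in bases if b != out[i]]
                    out[i] = choices[rng.integers(len(choices))]
            rows.append(SeqRecord(f"sp{m:02d}", "".join(out)))
        elements.append(
            HdeElement.build(
                f"hde{e:03d}", rows, params, min_length=200, source_identity=1.0 - divergence
            )
        )
    return elements


def make_marker_set(
    n_families: int = 20,
    n_multicopy: int = 0,
    multicopy_copies: int = 2,
    n_hde: int = 5,
    n_members: int = 8,
    mean_length: int = 200,
    divergence: float = 0.1,
    rng_seed: int = 0,
    params: Params = Params(),
) -> MarkerSet:
    """A complete synthetic bundle: families (some multi-copy) + elements."""
    families = make_marker_families(
        n_families, n_members, mean_length, divergence, rng_seed, params
    )
    for fam in families[:n_multicopy]:
        fam.expected_min_copies = multicopy_copies
    elements = (
        make_hde_elements(n_hde, rng_seed=rng_seed + 1, params=params) if n_hde else []
    )
    return MarkerSet(
        families={f.id: f for f in families},
        hde_elements={e.id: e for e in elements},
        params=params,
    )


def _reverse_translate(rng: np.random.Generator, peptide: str) -> str:
    return "".join(
        _CODONS_FOR[aa][rng.integers(len(_CODONS_FOR[aa]))] for aa in peptide
    )


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def make_genome(
    markerset: MarkerSet,
    rng_seed: int = 0,
    target_length: int = 2_000_000,
    n_contigs: int = 5,
    gc: float = 0.5,
    intron_rate: float = 0.0,
) -> tuple[Assembly, TruthTable]:
    """Embed every marker at recorded loci in random-background contigs.

    Each family's first member is reverse-translated (uniform codon
    choice) and inserted ``expected_min_copies`` times; each element's
    first member is inserted verbatim; strands are random. With
    ``intron_rate`` > 0 a gene may get one or two 50-500 bp random introns
    (recorded in the truth table). Loci never overlap by construction.
    """
    rng = np.random.default_rng(rng_seed)
    inserts: list[tuple[str, str, str]] = []  # (marker id, kind, sequence)
    intron_spans: dict[int, list[tuple[int, int]]] = {}
    for fid in sorted(markerset.families):
        fam = markerset.families[fid]
        peptide = fam.members[0].sequence
        for _ in range(fam.expected_min_copies):
            gene = _reverse_translate(rng, peptide)
            spans: list[tuple[int, int]] = []
            if intron_rate > 0 and rng.random() < intron_rate:
                for _k in range(int(rng.integers(1, 3))):
                    ilen = int(rng.integers(50, 501))
                    codon_pos = int(rng.integers(1, len(peptide))) * 3
                    gene = gene[:codon_pos] + _random_dna(rng, ilen, gc) + gene[codon_pos:]
                    spans.append((codon_pos, codon_pos + ilen))
            idx = len(inserts)
            inserts.append((fid, "protein", gene))
            if spans:
                intron_spans[idx] = spans
    for eid in sorted(markerset.hde_elements):
        inserts.append((eid, "hde", markerset.hde_elements[eid].members[0].sequence))

    total_insert = sum(len(s) for _, _, s in inserts)
    if total_insert >= target_length:
        raise ValueError("loci cannot fit in requested genome size")
    order = rng.permutation(len(inserts))
    contig_of = {int(i): int(j % n_contigs) for j, i in enumerate(order)}
    background_total = target_length - total_insert
    n_gaps = len(inserts) + n_contigs
    gap_sizes = rng.multinomial(background_total, np.full(n_gaps, 1.0 / n_gaps))

    records = []
    loci: list[Locus] = []
    introns: list[tuple[str, str, int, int]] = []
    gap_iter = iter(gap_sizes)
    for c in range(n_contigs):
        contig_id = f"contig{c:02d}"
        parts = [_random_dna(rng, int(next(gap_iter)), gc)]
        pos = len(parts[0])
        for j in order:
            if contig_of[int(j)] != c:
                continue
            marker_id, kind, seq = inserts[int(j)]
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = seq if strand == "+" else reverse_complement(seq)
            start, end = pos, pos + len(inserted)
            loci.append(Locus(marker_id, contig_id, strand, start, end, kind))
            for a, b in intron_spans.get(int(j), []):
                if strand == "+":
                    introns.append((marker_id, contig_id, start + a, start + b))
                else:
                    introns.append((marker_id, contig_id, end - b, end - a))
            parts.append(inserted)
            gap = _random_dna(rng, int(next(gap_iter)), gc)
            parts.append(gap)
            pos = end + len(gap)
        sequence = "".join(parts)
        if sequence:
            records.append(SeqRecord(contig_id, sequence))
    truth = TruthTable(
        loci=sorted(loci, key=lambda l: (l.contig_id, l.genome_start)),
        genome_params={
            "n_contigs": n_contigs,
            "target_length": target_length,
            "gc": gc,
            "rng_seed": rng_seed,
        },
        introns=introns,
    )
    return Assembly(records, source_path=f"<synthetic:{rng_seed}>"), truth


def excise_intervals(
    assembly: Assembly, intervals: Sequence[tuple[str, int, int]]
) -> Assembly:
    """Delete intervals, splitting each affected contig at the cut points."""
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig_id, start, end in intervals:
        by_contig.setdefault(contig_id, []).append((start, end))
    records = []
    for rec in assembly:
        cuts = sorted(by_contig.get(rec.id, []))
        if not cuts:
            records.append(rec)
            continue
        pos = 0
        part = 0
        for start, end in cuts:
            if start > pos:
                records.append(SeqRecord(f"{rec.id}.{part}", rec.sequence[pos:start]))
                part += 1
            pos = max(pos, end)
        if pos < len(rec):
            records.append(SeqRecord(f"{rec.id}.{part}", rec.sequence[pos:]))
    return Assembly(records, source_path=assembly.source_path + ":excised")


def truncate_assembly(
    assembly: Assembly,
    fraction: float,
    window: int = 5000,
    rng_seed: int = 0,
) -> tuple[Assembly, list[tuple[str, int, int]]]:
    """Remove ~``fraction`` of the sequence in random non-overlapping windows.

    Windows are drawn uniformly across contigs (length-weighted) until the
    removed total first reaches the target; each deletion splits its
    contig into separate records, as a lost genomic segment would in a
    degraded assembly. Returns the truncated assembly and the deletion log
    as (contig_id, start, end) intervals.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    if window < 1:
        raise ValueError("window must be >= 1")
    if fraction == 0:
        return Assembly(list(assembly.records), assembly.source_path), []
    rng = np.random.default_rng(rng_seed)
    target = fraction * assembly.total_length
    lengths = np.array([len(r) for r in assembly], dtype=float)
    chosen: dict[str, list[tuple[int, int]]] = {}
    removed = 0
    attempts = 0
    max_attempts = 100_000
    while removed < target and attempts < max_attempts:
        attempts += 1
        ci = int(rng.choice(len(lengths), p=lengths / lengths.sum()))
        rec = assembly.records[ci]
        if len(rec) <= window:
            continue
        start = int(rng.integers(0, len(rec) - window + 1))
        end = min(start + window, len(rec))
        overlaps = any(
            s < end and start < e for s, e in chosen.get(rec.id, [])
        )
        if overlaps:
            continue
        chosen.setdefault(rec.id, []).append((start, end))
        removed += end - start
    if removed < target:
        raise ValueError("could not place enough deletion windows")
    log = sorted(
        (cid, s, e) for cid, spans in chosen.items() for s, e in spans
    )
    return excise_intervals(assembly, log), log


def simulate_reads(
    assembly: Assembly,
    n_reads: int,
    length_mean: int = 8000,
    length_sd: int = 1000,
    error_rate: float = 0.05,
    rng_seed: int = 0,
) -> list[SeqRecord]:
    """Draw long reads with substitution errors from an assembly.

    Positions are uniform over the genome (contigs length-weighted),
    strands random, lengths normal truncated to [500, contig length], and
    errors are substitutions at ``error_rate`` per base. Quality strings
    are flat (the pipeline never uses them).
    """
    if not 0 <= error_rate < 0.3:
        raise ValueError("error_rate must be in [0, 0.3)")
    if length_mean <= 0:
        raise ValueError("length_mean must be positive")
    if max(len(r) for r in assembly) < 500:
        raise ValueError("assembly shorter than minimum read length")
    rng = np.random.default_rng(rng_seed)
    lengths = np.array([len(r) for r in assembly], dtype=float)
    eligible = lengths >= 500
    p = np.where(eligible, lengths, 0.0)
    p /= p.sum()
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    reads = []
    for i in range(n_reads):
        ci = int(rng.choice(len(lengths), p=p))
        rec = assembly.records[ci]
        rlen = int(np.clip(rng.normal(length_mean, length_sd), 500, len(rec)))
        start = int(rng.integers(0, len(rec) - rlen + 1))
        seq = rec.sequence[start : start + rlen]
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        if error_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            errs = np.flatnonzero(rng.random(arr.size) < error_rate)
            for j in errs:
                choices = bases[bases != arr[j]]
                arr[j] = choices[rng.integers(len(choices))]
            seq = arr.tobytes().decode()
        reads.append(SeqRecord(f"read{i:06d}", seq, "I" * len(seq)))
    return reads
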