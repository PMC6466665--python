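"""Sequence I/O: FASTA/FASTQ reading with the toolkit's normalization rules.

All nucleotide sequences are normalized on input: uppercased, ``U`` mapped to
``T``, and IUPAC ambiguity codes other than ``N`` mapped to ``N`` (with a
warning). Record ids are the FASTA/FASTQ header token before the first
whitespace; long free-text headers are therefore harmless but ids must be
unique after truncation because they key every downstream table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PEPTIDE_ALPHABET = frozenset(AMINO_ACIDS + "X*")

_AMBIGUITY = set("RYSWKMBDHV")


class SeqIOError(ValueError):
    """Raised for malformed sequence input."""


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence.

    ``id`` is the header token before the first whitespace and is never
    empty. ``sequence`` is uppercase over {A,C,G,T,N} for nucleotide records
    or the 20 amino acids plus {X,*} for peptides; the two alphabets are
    never mixed within one record. ``quality`` keeps FASTQ per-base quality
    strings (unused downstream, retained for round trips).
    """

    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SeqIOError(f"invalid record id: {self.id!r}")
        if not self.sequence:
            raise SeqIOError(f"empty record: {self.id}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Assembly:
    """An ordered collection of nucleotide records with unique ids."""

    records: list[SeqRecord]
    source_path: str = "<memory>"
    _index: dict[str, SeqRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for rec in self.records:
            if rec.id in self._index:
                raise SeqIOError(f"duplicate record id after truncation: {rec.id}")
            self._index[rec.id] = rec
        if self.total_length == 0:
            raise SeqIOError("assembly has no sequence")

    def __getitem__(self, record_id: str) -> SeqRecord:
        return self._index[record_id]

    def __iter__(self) -> Iterator[SeqRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self.records)


def _normalize_nucleotide(seq: str, rec_id: str, gapped: bool = False) -> str:
    s = seq.upper().replace("U", "T")
    allowed = NUCLEOTIDE_ALPHABET | ({"-", "."} if gapped else set())
    if not set(s) <= allowed:
        bad = set(s) - allowed
        if bad <= _AMBIGUITY:
            warnings.warn(
                f"record {rec_id}: ambiguity codes {sorted(bad)} mapped to N",
                stacklevel=3,
            )
            s = "".join(c if c in allowed else "N" for c in s)
        else:
            raise SeqIOError(f"record {rec_id}: non-nucleotide characters {sorted(bad)}")
    return s


def _header_token(header: str) -> str:
    token = header.split()[0] if header.split() else ""
    if not token:
        raise SeqIOError("malformed FASTA: empty header")
    return token


def read_fasta(
    source: IO[str] | str, alphabet: str = "nucleotide", gapped: bool = False
) -> list[SeqRecord]:
    """Parse FASTA into a list of records.

    Parameters
    ----------
    source
        Open text stream, or a path.
    alphabet
        ``"nucleotide"`` (default, normalized as module docstring describes)
        or ``"peptide"`` (uppercased, validated against the peptide alphabet).
    gapped
        Allow '-' and '.' (alignment rows).
    """
    if isinstance(source, str):
        with open(source) as fh:
            return read_fasta(fh, alphabet=alphabet, gapped=gapped)
    records = []
    seen: set[str] = set()
    first = source.read(1)
    while first in ("\n", "\r", " ", "\t"):
        first = source.read(1)
    if first == "":
        raise SeqIOError("no records")
    if first != ">":
        raise SeqIOError("malformed FASTA: sequence before header")
    # SimpleFastaParser expects the '>' we already consumed; feed a shim.
    stream = _chain_streams(">", source)
    for header, seq in SimpleFastaParser(stream):
        rec_id = _header_token(header)
        if not seq:
            raise SeqIOError(f"empty record: {rec_id}")
        if alphabet == "peptide":
            seq = seq.upper()
            allowed = PEPTIDE_ALPHABET | ({"-", "."} if gapped else set())
            if not set(seq) <= allowed:
                raise SeqIOError(f"record {rec_id}: non-peptide characters")
        else:
            seq = _normalize_nucleotide(seq, rec_id, gapped=gapped)
        if rec_id in seen:
            raise SeqIOError(f"duplicate record id after truncation: {rec_id}")
        seen.add(rec_id)
        records.append(SeqRecord(rec_id, seq))
    if not records:
        raise SeqIOError("no records")
    return records


class _chain_streams:
    """One-shot line iterator prepending a string to another text stream."""

    def __init__(self, head: str, tail: IO[str]):
        self._gen = self._lines(head, tail)

    @staticmethod
    def _lines(head: str, tail: IO[str]) -> Iterator[str]:
        line = head + (tail.readline() or "")
        while line:
            yield line
            line = tail.readline()

    def __iter__(self) -> "_chain_streams":
        return self

    def __next__(self) -> str:
        return next(self._gen)

    def readline(self) -> str:
        return next(self._gen, "")

    def read(self, size: int = -1) -> str:
        if size == 0:
            return ""
        return "".join(self._gen)


def read_fastx(source: IO[str] | str) -> Iterator[SeqRecord]:
    """Lazily yield records from FASTA or FASTQ, sniffed from the first byte.

    Streaming: one record is materialized at a time, so arbitrarily large
    read sets can be consumed without loading them in memory. FASTQ quality
    strings are kept on the record but unused downstream.
    """
    if isinstance(source, str):
        with open(source) as fh:
            yield from read_fastx(fh)
        return
    first = source.read(1)
    while first in ("\n", "\r", " ", "\t"):
        first = source.read(1)
    if first == "":
        return
    stream = _chain_streams(first, source)
    if first == ">":
        seen: set[str] = set()
        for header, seq in SimpleFastaParser(stream):
            rec_id = _header_token(header)
            if not seq:
                raise SeqIOError(f"empty record: {rec_id}")
            if rec_id in seen:
                raise SeqIOError(f"duplicate record id after truncation: {rec_id}")
            seen.add(rec_id)
            yield SeqRecord(rec_id, _normalize_nucleotide(seq, rec_id))
    elif first == "@":
        try:
            for header, seq, qual in FastqGeneralIterator(stream):
                rec_id = _header_token(header)
                if len(qual) != len(seq):
                    raise SeqIOError(f"malformed FASTQ: record {rec_id}")
                yield SeqRecord(rec_id, _normalize_nucleotide(seq, rec_id), qual)
        except ValueError as exc:  # Biopython's own malformed-FASTQ errors
            if isinstance(exc, SeqIOError):
                raise
            raise SeqIOError(f"malformed FASTQ: {exc}") from exc
    else:
        raise SeqIOError("unrecognized format: expected '>' or '@'")


def write_fasta(records: Iterable[SeqRecord], dest: IO[str], width: int = 70) -> None:
    for rec in records:
        dest.write(f">{rec.id}\n")
        for i in range(0, len(rec.sequence), width):
            dest.write(rec.sequence[i : i + width] + "\n")


def write_fastq(records: Iterable[SeqRecord], dest: IO[str]) -> None:
    for rec in records:
        qual = rec.quality if rec.quality is not None else "I" * len(rec)
        dest.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Completeness report serialization. The report object lives in
# mycocheck.completeness; serialization stays here with the other formats.

_SUMMARY_FIELDS = (
    "pct_complete",
    "pct_complete_or_partial",
    "pct_aberrant",
    "pct_missing",
    "hde_detected",
    "hde_total",
    "pct_hde",
)


def write_report(report, style: str = "tsv") -> str:
    """Serialize a CompletenessReport to TSV (human-facing) or JSON.

    JSON output round-trips through :func:`read_report_json` to an equal
    report; serialization is deterministic (sorted keys, fixed field order).
    """
    if not report.per_family:
        raise SeqIOError("empty marker set")
    if style == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    if style != "tsv":
        raise ValueError(f"unknown report style: {style}")
    lines = ["#family_id\tstatus\tn_copies\tbest_score\tbest_peptide_length"]
    for fam_id in sorted(report.per_family):
        entry = report.per_family[fam_id]
        best = entry.best_model
        score = f"{best.total_score:.2f}" if best is not None else "NA"
        plen = str(len(best.model_peptide)) if best is not None else "NA"
        lines.append(f"{fam_id}\t{entry.status}\t{entry.n_copies}\t{score}\t{plen}")
    lines.append("")
    for name in _SUMMARY_FIELDS:
        value = getattr(report, name)
        if isinstance(value, float):
            lines.append(f"# {name}\t{value:.4f}")
        else:
            lines.append(f"# {name}\t{value}")
    stats = report.assembly_stats
    lines.append(f"# n_contigs\t{stats.n_contigs}")
    lines.append(f"# total_length\t{stats.total_length}")
    lines.append(f"# n50_length\t{stats.n50_length}")
    lines.append(f"# l50_count\t{stats.l50_count}")
    lines.append(f"# n_fraction\t{stats.n_fraction:.6f}")
    if report.collapse_flags:
        lines.append("# collapsed_families\t" + ",".join(sorted(report.collapse_flags)))
    else:
        lines.append("# collapsed_families\t-")
    lines.append(
        "# note\tcopy counts cannot distinguish independent copies from unassembled duplicates"
    )
    return "\n".join(lines) + "\n"


def read_report_json(text: str):
    """Parse :func:`write_report` JSON output back into a CompletenessReport."""
    from .completeness import CompletenessReport

    return CompletenessReport.from_dict(json.loads(text))
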