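"""Marker resources: protein family profiles, conserved-element profiles,
detection thresholds, and the marker-set bundle format.

A marker family is a set of orthologous proteins summarized as a
position-specific scoring matrix (PSSM) of per-column log-odds scores in
bits, plus a detection threshold set to 80% of the lowest member self-score
— so every member of the family passes its own family's threshold by
construction, while unrelated sequences fall well short.

Highly conserved DNA elements (HDEs) get the same treatment at the
nucleotide level (4-letter alphabet, >= 200 bp, members sharing >= 70%
identity), and multi-copy families carry the minimum copy count observed
across surveyed genomes as their expectation.
"""

from __future__ import annotations

import io
import json
import math
import tarfile
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from .seqio import AMINO_ACIDS, SeqRecord

NUCLEOTIDES = "ACGT"
GAP_CHARS = frozenset("-.")
SKIP_PENALTY = 2.0  # bits, per skipped profile column or peptide residue
STOP_SCORE = -8.0  # bits, for '*' in a translated frame at any column


@dataclass(frozen=True)
class Params:
    """All numeric knobs of the pipeline, with their defaults.

    seed_k
        Exact-match seed length (residues) for translated search.
    xdrop
        Extension stops once the running score falls this many bits below
        the running maximum.
    aberrant_factor
        A gene model at least this multiple of the family mean length is
        classified aberrant.
    coverage_complete
        Minimum fraction of profile columns a model must cover (together
        with reaching the family threshold) to be called complete.
    partial_floor
        Fraction of the family threshold a model (or read hit) must reach
        to be called partial / detected.
    presence_fraction
        A candidate family must span at least this fraction of the
        reference species to be retained (ceil applied).
    paralog_margin
        Bits by which a member's self-score must exceed its score against
        every other retained family for the family to count as unambiguous.
    block_size / n_blocks / stop_patience
        Read-mode sampling: reads are grouped in blocks of ``block_size``,
        ``n_blocks`` blocks are reservoir-sampled, and scanning stops after
        ``stop_patience`` consecutive blocks yield no new marker.
    truncation_fraction
        Default fraction of sequence removed by the truncation benchmark.
    """

    seed_k: int = 4
    xdrop: float = 20.0
    aberrant_factor: float = 2.0
    coverage_complete: float = 0.70
    partial_floor: float = 0.30
    presence_fraction: float = 0.99
    paralog_margin: float = 0.0
    min_hsp_score: float = 15.0
    max_intron: int = 10_000
    max_profile_overlap: int = 10
    hde_seed_k: int = 12
    block_size: int = 10_000
    n_blocks: int = 1000
    stop_patience: int = 20
    truncation_fraction: float = 0.10
    pseudocount_weight: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("coverage_complete", "partial_floor", "presence_fraction", "truncation_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]: {v}")
        for name in ("seed_k", "block_size", "n_blocks", "stop_patience"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


class Pssm:
    """Log-odds position-specific scoring matrix (bits, base 2).

    ``matrix`` has one row per retained alignment column and one column per
    alphabet letter. Characters outside the alphabet (X for peptides, N for
    nucleotides) score 0 everywhere; '*' scores ``STOP_SCORE``.
    """

    __slots__ = ("matrix", "alphabet", "background", "pseudocount_weight", "kept_columns", "_charmap", "_ext")

    def __init__(
        self,
        matrix: np.ndarray,
        alphabet: str,
        background: np.ndarray,
        pseudocount_weight: float,
        kept_columns: np.ndarray,
    ):
        a = len(alphabet)
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.ndim != 2 or matrix.shape[1] != a:
            raise ValueError("matrix shape must be (length, len(alphabet))")
        if not np.all(np.isfinite(matrix)):
            raise ValueError("non-finite profile scores")
        background = np.asarray(background, dtype=np.float64)
        if abs(background.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")
        self.matrix = matrix
        self.alphabet = alphabet
        self.background = background
        self.pseudocount_weight = float(pseudocount_weight)
        self.kept_columns = np.asarray(kept_columns, dtype=np.int64)
        charmap = np.full(128, a, dtype=np.int64)  # unknown -> score-0 slot
        for i, c in enumerate(alphabet):
            charmap[ord(c)] = i
        charmap[ord("*")] = a + 1
        self._charmap = charmap
        ext = np.zeros((matrix.shape[0], a + 2))
        ext[:, :a] = matrix
        ext[:, a + 1] = STOP_SCORE
        self._ext = ext

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def encode(self, sequence: str) -> np.ndarray:
        return self._charmap[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]

    def scores_for(self, sequence: str) -> np.ndarray:
        """(len(sequence), profile length) per-position score lookup."""
        return self._ext[:, self.encode(sequence)].T

    def column_scores(self, encoded: np.ndarray, columns: np.ndarray) -> np.ndarray:
        """Scores of encoded residues placed at specific profile columns."""
        return self._ext[columns, encoded]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Pssm)
            and self.alphabet == other.alphabet
            and np.array_equal(self.matrix, other.matrix)
            and np.array_equal(self.kept_columns, other.kept_columns)
        )


def build_profile(
    alignment: Sequence[str],
    pseudocount_weight: float = 1.0,
    background: np.ndarray | None = None,
    alphabet: str = AMINO_ACIDS,
) -> Pssm:
    """Build a log-odds PSSM from equal-length gapped alignment rows.

    Columns with >= 50% gap characters are dropped. Retained column scores
    are ``log2((count(a) + w*bg(a)) / (n_eff + w) / bg(a))`` where n_eff is
    the number of alphabet residues observed in the column and w the
    pseudocount weight.
    """
    if not alignment:
        raise ValueError("empty alignment")
    width = len(alignment[0])
    if width == 0 or any(len(row) != width for row in alignment):
        raise ValueError("alignment rows must be equal, non-zero length")
    a = len(alphabet)
    if background is None:
        background = np.full(a, 1.0 / a)
    background = np.asarray(background, dtype=np.float64)
    rows = np.array([list(r.upper()) for r in alignment])
    gap_frac = np.mean(np.isin(rows, list(GAP_CHARS)), axis=0)
    kept = np.flatnonzero(gap_frac < 0.5)
    if kept.size == 0:
        raise ValueError("all columns are gappy")
    counts = np.zeros((kept.size, a))
    for i, c in enumerate(alphabet):
        counts[:, i] = (rows[:, kept] == c).sum(axis=0)
    n_eff = counts.sum(axis=1, keepdims=True)
    w = float(pseudocount_weight)
    with np.errstate(divide="ignore"):
        matrix = np.log2((counts + w * background) / (n_eff + w) / background)
    return Pssm(matrix, alphabet, background, w, kept)


def score_sequence(profile: Pssm, sequence: str) -> float:
    """Best local alignment score (bits) of a sequence against a profile.

    Dynamic programming over (residues x columns) with skip penalties of
    ``SKIP_PENALTY`` bits per skipped profile column or sequence residue;
    the empty alignment scores 0, so the result is never negative.
    """
    if not sequence:
        return 0.0
    scores = profile.scores_for(sequence)
    length = len(profile)
    offsets = SKIP_PENALTY * np.arange(1, length + 1)
    h = np.zeros(length + 1)
    best = 0.0
    for row in scores:
        cand = np.maximum(np.maximum(h[:-1] + row, h[1:] - SKIP_PENALTY), 0.0)
        new_h = np.empty(length + 1)
        new_h[0] = 0.0
        new_h[1:] = np.maximum.accumulate(cand + offsets) - offsets
        h = new_h
        m = h.max()
        if m > best:
            best = float(m)
    return best


def family_threshold(member_scores: Iterable[float]) -> float:
    """Detection threshold: 80% of the lowest member self-score."""
    scores = list(member_scores)
    if not scores:
        raise ValueError("no member scores")
    return 0.8 * min(scores)


@dataclass
class MarkerFamily:
    """One orthologous protein family with its profile and thresholds."""

    id: str
    members: list[SeqRecord]
    species: list[str]
    alignment: list[str]
    profile: Pssm
    member_scores: list[float]
    mean_length: float
    score_threshold: float
    expected_min_copies: int = 1
    member_col_maps: list[np.ndarray] = field(default_factory=list, repr=False)

    @property
    def single_copy(self) -> bool:
        return self.expected_min_copies == 1

    @classmethod
    def build(
        cls,
        family_id: str,
        alignment: Sequence[SeqRecord],
        species: Sequence[str] | None = None,
        params: Params = Params(),
        background: np.ndarray | None = None,
    ) -> "MarkerFamily":
        """Build a family from gapped peptide alignment rows.

        Species tags default to the member ids. Member sequences are the
        ungapped rows; each member also gets a residue-to-profile-column
        map used to place alignment seeds.
        """
        rows = [rec.sequence for rec in alignment]
        profile = build_profile(rows, params.pseudocount_weight, background)
        members = []
        col_maps = []
        kept = profile.kept_columns
        for rec in alignment:
            residue_cols = np.array(
                [i for i, c in enumerate(rec.sequence) if c not in GAP_CHARS], dtype=np.int64
            )
            seq = "".join(rec.sequence[i] for i in residue_cols)
            members.append(SeqRecord(rec.id, seq))
            pos = np.searchsorted(kept, residue_cols)
            in_profile = (pos < kept.size) & (kept[np.minimum(pos, kept.size - 1)] == residue_cols)
            col_map = np.where(in_profile, pos, -1)
            col_maps.append(col_map)
        scores = [score_sequence(profile, m.sequence) for m in members]
        return cls(
            id=family_id,
            members=members,
            species=list(species) if species is not None else [m.id for m in members],
            alignment=list(rows),
            profile=profile,
            member_scores=scores,
            mean_length=float(np.mean([len(m) for m in members])),
            score_threshold=family_threshold(scores),
            member_col_maps=col_maps,
        )


@dataclass
class HdeElement:
    """A highly conserved DNA element: nucleotide profile + threshold."""

    id: str
    members: list[SeqRecord]
    alignment: list[str]
    profile: Pssm
    member_scores: list[float]
    score_threshold: float
    consensus: str
    min_length: int = 200
    source_identity: float = 0.70

    @classmethod
    def build(
        cls,
        element_id: str,
        alignment: Sequence[SeqRecord],
        params: Params = Params(),
        min_length: int = 200,
        source_identity: float = 0.70,
    ) -> "HdeElement":
        rows = [rec.sequence for rec in alignment]
        profile = build_profile(rows, params.pseudocount_weight, alphabet=NUCLEOTIDES)
        if len(profile) < min_length:
            raise ValueError(
                f"element {element_id}: profile length {len(profile)} < {min_length}"
            )
        if source_identity < 0.70:
            raise ValueError("HDE members must share at least 70% identity")
        members = [
            SeqRecord(rec.id, "".join(c for c in rec.sequence if c not in GAP_CHARS))
            for rec in alignment
        ]
        scores = [score_sequence(profile, m.sequence) for m in members]
        consensus = "".join(NUCLEOTIDES[i] for i in np.argmax(profile.matrix, axis=1))
        return cls(
            id=element_id,
            members=members,
            alignment=list(rows),
            profile=profile,
            member_scores=scores,
            score_threshold=family_threshold(scores),
            consensus=consensus,
            min_length=min_length,
            source_identity=source_identity,
        )


@dataclass
class MarkerSet:
    """A user-buildable bundle of protein families and HDE elements."""

    families: dict[str, MarkerFamily]
    hde_elements: dict[str, HdeElement] = field(default_factory=dict)
    params: Params = field(default_factory=Params)

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError("marker set needs at least one family")


@dataclass(frozen=True)
class Cluster:
    """A candidate family before filtering: gapped rows + species tags."""

    id: str
    alignment: tuple[SeqRecord, ...]
    species: tuple[str, ...]


def filter_families(
    clusters: Sequence[Cluster], n_species: int, params: Params = Params()
) -> list[MarkerFamily]:
    """Apply the marker retention rules to candidate clusters.

    A cluster is retained iff (i) its members span at least
    ``ceil(presence_fraction * n_species)`` distinct species and (ii) it is
    unambiguous: every member's self-score exceeds its score against every
    other candidate family's profile by more than ``paralog_margin`` bits.
    Symmetric near-duplicate clusters therefore eliminate each other.
    """
    if n_species <= 0:
        raise ValueError("n_species must be positive")
    required = math.ceil(params.presence_fraction * n_species)
    present = [
        c for c in sorted(clusters, key=lambda c: c.id)
        if len(set(c.species)) >= required
    ]
    built = [
        MarkerFamily.build(c.id, c.alignment, c.species, params) for c in present
    ]
    retained = []
    for fam in built:
        ambiguous = False
        for other in built:
            if other.id == fam.id:
                continue
            for member, self_score in zip(fam.members, fam.member_scores):
                cross = score_sequence(other.profile, member.sequence)
                if self_score - cross <= params.paralog_margin:
                    ambiguous = True
                    break
            if ambiguous:
                break
        if not ambiguous:
            retained.append(fam)
    return retained


def set_copy_expectations(
    families: Iterable[MarkerFamily], survey: dict[str, Sequence[int]]
) -> None:
    """Set each family's expected copy number from a per-genome copy survey.

    The expectation is the *minimum* copy count over surveyed genomes,
    floored at 1 (a genome where the family was undetected does not push
    the expectation to zero; it triggers a warning instead).
    """
    for fam in families:
        counts = survey.get(fam.id)
        if not counts:
            warnings.warn(f"family {fam.id} absent from copy survey; expecting 1 copy")
            fam.expected_min_copies = 1
            continue
        lowest = min(counts)
        if lowest < 1:
            warnings.warn(f"family {fam.id} undetected in some surveyed genome; flooring at 1")
            lowest = 1
        fam.expected_min_copies = int(lowest)


# ---------------------------------------------------------------------------
# Marker-set archive: a tar of plain-text FASTA alignments plus a JSON
# manifest carrying params, thresholds and copy expectations.


def _add_text(tar: tarfile.TarFile, name: str, text: str) -> None:
    data = text.encode()
    info = tarfile.TarInfo(name)
    info.size = len(data)
    info.mtime = 0
    tar.addfile(info, io.BytesIO(data))


def _alignment_fasta(ids: Sequence[str], rows: Sequence[str]) -> str:
    return "".join(f">{i}\n{r}\n" for i, r in zip(ids, rows))


def save_markerset(markerset: MarkerSet, path: str) -> None:
    """Write a marker set as a tar archive of FASTA files + manifest.json."""
    manifest = {
        "format": "mycocheck-markerset/1",
        "params": asdict(markerset.params),
        "families": {},
        "hde_elements": {},
    }
    with tarfile.open(path, "w") as tar:
        for fam in markerset.families.values():
            manifest["families"][fam.id] = {
                "species": fam.species,
                "score_threshold": fam.score_threshold,
                "mean_length": fam.mean_length,
                "expected_min_copies": fam.expected_min_copies,
                "member_scores": fam.member_scores,
            }
            _add_text(
                tar,
                f"families/{fam.id}.afa",
                _alignment_fasta([m.id for m in fam.members], fam.alignment),
            )
        for elem in markerset.hde_elements.values():
            manifest["hde_elements"][elem.id] = {
                "score_threshold": elem.score_threshold,
                "min_length": elem.min_length,
                "source_identity": elem.source_identity,
                "member_scores": elem.member_scores,
            }
            _add_text(
                tar,
                f"hde/{elem.id}.afa",
                _alignment_fasta([m.id for m in elem.members], elem.alignment),
            )
        _add_text(tar, "manifest.json", json.dumps(manifest, indent=2, sort_keys=True))


_FAMILY_FIELDS = ("species", "score_threshold", "mean_length", "expected_min_copies")


def load_markerset(path: str) -> MarkerSet:
    """Load a marker-set archive, rebuilding profiles from the alignments.

    Thresholds are taken from the manifest (they round-trip bit-identically)
    and sanity-checked against the required fields; a manifest missing any
    of them raises "corrupt marker set".
    """
    from .seqio import read_fasta

    with tarfile.open(path, "r") as tar:
        names = tar.getnames()
        if "manifest.json" not in names:
            raise ValueError("corrupt marker set: no manifest")
        manifest = json.loads(tar.extractfile("manifest.json").read().decode())
        if not manifest.get("families"):
            raise ValueError("corrupt marker set: no families")
        params = Params(**manifest["params"])
        families: dict[str, MarkerFamily] = {}
        for fam_id, meta in sorted(manifest["families"].items()):
            for fld in _FAMILY_FIELDS:
                if fld not in meta:
                    raise ValueError(f"corrupt marker set: family {fam_id} missing {fld}")
            member_name = f"families/{fam_id}.afa"
            rows = read_fasta(
                io.StringIO(tar.extractfile(member_name).read().decode()),
                alphabet="peptide",
                gapped=True,
            )
            fam = MarkerFamily.build(fam_id, rows, meta["species"], params)
            fam.score_threshold = meta["score_threshold"]
            fam.mean_length = meta["mean_length"]
            fam.expected_min_copies = meta["expected_min_copies"]
            fam.member_scores = meta.get("member_scores", fam.member_scores)
            families[fam_id] = fam
        hde: dict[str, HdeElement] = {}
        for elem_id, meta in sorted(manifest.get("hde_elements", {}).items()):
            rows = read_fasta(
                io.StringIO(tar.extractfile(f"hde/{elem_id}.afa").read().decode()),
                gapped=True,
            )
            elem = HdeElement.build(
                elem_id, rows, params, meta["min_length"], meta["source_identity"]
            )
            elem.score_threshold = meta["score_threshold"]
            elem.member_scores = meta.get("member_scores", elem.member_scores)
            hde[elem_id] = elem
    return MarkerSet(families=families, hde_elements=hde, params=params)
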