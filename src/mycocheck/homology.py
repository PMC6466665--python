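"""Translated homology search: find marker homologs in an assembly.

The search is a native seed-extend-chain pipeline. Each contig is
conceptually translated in all six frames; exact seed-length k-mer matches
between family member peptides and a frame peptide are extended in both
directions against the family PSSM with X-drop termination, giving local
ungapped hits (HSPs). HSPs for one family on one contig and strand are then
chained by dynamic programming into a colinear gene model (introns appear
as genome gaps between HSPs), and each model is classified complete,
partial or aberrant against the family's threshold, coverage and length
statistics.

Coordinates are 0-based, half-open, and always reported on the forward
strand, regardless of the strand the hit lies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .markers import MarkerFamily, MarkerSet, Params, Pssm
from .seqio import AMINO_ACIDS, Assembly, SeqRecord

# --- nucleotide / peptide integer encodings -------------------------------

_NT = "ACGTN"
_NT_CODE = np.full(128, 4, dtype=np.int8)
for _i, _c in enumerate(_NT):
    _NT_CODE[ord(_c)] = _i
_NT_COMP = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # A<->T, C<->G, N->N

_AA_ORDER = AMINO_ACIDS + "X*"
_PEP_CODE = np.full(128, 20, dtype=np.int8)  # unknown -> X slot
for _i, _c in enumerate(_AA_ORDER):
    _PEP_CODE[ord(_c)] = _i

# 125-entry codon table over base codes 0..4 (N=4); any codon with N -> X
_CODON_AA = np.full(125, _AA_ORDER.index("X"), dtype=np.int8)
for _codon, _aa in standard_dna_table.forward_table.items():
    _idx = _NT_CODE[ord(_codon[0])] * 25 + _NT_CODE[ord(_codon[1])] * 5 + _NT_CODE[ord(_codon[2])]
    _CODON_AA[_idx] = _AA_ORDER.index(_aa)
for _codon in standard_dna_table.stop_codons:
    _idx = _NT_CODE[ord(_codon[0])] * 25 + _NT_CODE[ord(_codon[1])] * 5 + _NT_CODE[ord(_codon[2])]
    _CODON_AA[_idx] = _AA_ORDER.index("*")
_AA_BYTES = np.frombuffer(_AA_ORDER.encode(), dtype=np.uint8)


def encode_nucleotide(sequence: str) -> np.ndarray:
    return _NT_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def reverse_complement(sequence: str) -> str:
    enc = _NT_COMP[encode_nucleotide(sequence)][::-1]
    return bytes(np.frombuffer(_NT.encode(), dtype=np.uint8)[enc]).decode()


@dataclass(frozen=True)
class Frame:
    """One translation frame of a contig, with its coordinate mapping.

    For strand '+', peptide index i covers genome bases
    [offset + 3i, offset + 3i + 3). For strand '-', the peptide is the
    translation of the reverse complement starting at ``offset``, so
    peptide index i covers forward-strand bases
    [L - offset - 3i - 3, L - offset - 3i) where L is the contig length.
    """

    contig_id: str
    strand: str
    offset: int
    peptide: str
    contig_length: int

    def genome_span(self, pep_start: int, pep_end: int) -> tuple[int, int]:
        """Forward-strand genome interval covered by peptide [start, end)."""
        if self.strand == "+":
            return self.offset + 3 * pep_start, self.offset + 3 * pep_end
        return (
            self.contig_length - self.offset - 3 * pep_end,
            self.contig_length - self.offset - 3 * pep_start,
        )


def _translate_encoded(enc: np.ndarray, offset: int) -> str:
    n_codons = (enc.size - offset) // 3
    if n_codons <= 0:
        return ""
    codons = enc[offset : offset + 3 * n_codons].reshape(-1, 3).astype(np.int64)
    idx = codons[:, 0] * 25 + codons[:, 1] * 5 + codons[:, 2]
    return bytes(_AA_BYTES[_CODON_AA[idx]]).decode()


def six_frame_translate(record: SeqRecord) -> list[Frame]:
    """All six conceptual translations of a contig (standard genetic code).

    Stop codons are retained as '*'; codons containing N translate to 'X';
    trailing bases not filling a codon are dropped.
    """
    enc = encode_nucleotide(record.sequence)
    rc = _NT_COMP[enc][::-1]
    frames = []
    for offset in range(3):
        frames.append(
            Frame(record.id, "+", offset, _translate_encoded(enc, offset), len(enc))
        )
    for offset in range(3):
        frames.append(
            Frame(record.id, "-", offset, _translate_encoded(rc, offset), len(enc))
        )
    return frames


@dataclass(frozen=True)
class Hsp:
    """A local ungapped hit between a marker profile and a translated frame."""

    family_id: str
    contig_id: str
    strand: str
    genome_start: int
    genome_end: int
    profile_start: int
    profile_end: int
    score: float
    peptide: str

    def __post_init__(self) -> None:
        assert self.genome_start < self.genome_end
        assert (self.genome_end - self.genome_start) % 3 == 0
        assert self.score > 0

    @property
    def n_columns(self) -> int:
        return self.profile_end - self.profile_start

    def oriented_span(self) -> tuple[int, int]:
        """Genome interval in gene orientation (profile direction)."""
        if self.strand == "+":
            return self.genome_start, self.genome_end
        return -self.genome_end, -self.genome_start


@dataclass
class GeneModel:
    """A chained, classified gene prediction for one marker family."""

    family_id: str
    contig_id: str
    strand: str
    exons: list[Hsp]
    model_peptide: str
    total_score: float
    coverage: float
    status: str | None = None

    @property
    def genome_start(self) -> int:
        return min(e.genome_start for e in self.exons)

    @property
    def genome_end(self) -> int:
        return max(e.genome_end for e in self.exons)


# --- seed tables ----------------------------------------------------------

_KMER_BASE = 22  # 20 amino acids + X + stop slots


def _peptide_kmer_codes(encoded: np.ndarray, k: int) -> np.ndarray:
    """Rolling base-22 codes of all k-windows; windows with X/stop -> -1."""
    n = encoded.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    e = encoded.astype(np.int64)
    for j in range(k):
        codes = codes * _KMER_BASE + e[j : j + n]
        valid &= e[j : j + n] < 20
    return np.where(valid, codes, -1)


def _family_seed_table(family: MarkerFamily, k: int) -> dict[int, list[int]]:
    """Map member k-mer codes to the profile column where the k-mer starts.

    Only k-mers whose residues map to k consecutive retained profile
    columns are usable as seeds (gaps in a member's row break the diagonal
    correspondence the extension relies on).
    """
    table: dict[int, set[int]] = {}
    for member, col_map in zip(family.members, family.member_col_maps):
        enc = _PEP_CODE[np.frombuffer(member.sequence.encode(), dtype=np.uint8)]
        codes = _peptide_kmer_codes(enc, k)
        for m in range(codes.size):
            if codes[m] < 0:
                continue
            c0 = col_map[m]
            if c0 < 0 or not np.array_equal(col_map[m : m + k], np.arange(c0, c0 + k)):
                continue
            table.setdefault(int(codes[m]), set()).add(int(c0))
    return {code: sorted(cols) for code, cols in table.items()}


# --- vectorized X-drop extension ------------------------------------------


def _directional_gain(
    scores: np.ndarray, xdrop: float
) -> tuple[np.ndarray, np.ndarray]:
    """Best cumulative gain and its extent under X-drop, per row.

    ``scores[r, t]`` is the score of taking step t in some direction for
    seed r (out-of-range steps hold -inf). Returns (gain >= 0, number of
    steps taken to reach it), stopping each row at the first step where the
    running score drops ``xdrop`` below its running maximum.
    """
    n, w = scores.shape
    cs = np.cumsum(scores, axis=1)
    runmax = np.maximum.accumulate(cs, axis=1)
    dead = runmax - cs > xdrop
    first_dead = np.where(dead.any(axis=1), np.argmax(dead, axis=1), w)
    allowed = np.arange(w)[None, :] < first_dead[:, None]
    masked = np.where(allowed, cs, -np.inf)
    best = masked.max(axis=1)
    best_t = masked.argmax(axis=1)
    gain = np.maximum(best, 0.0)
    steps = np.where(best > 0, best_t + 1, 0)
    return gain, steps


def _extend_seeds(
    ext: np.ndarray,
    enc: np.ndarray,
    seeds_p: np.ndarray,
    seeds_c: np.ndarray,
    k: int,
    xdrop: float,
    window: int = 64,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Extend seed diagonals both ways against a profile score table.

    ``ext`` is the (profile length, alphabet+2) score table, ``enc`` the
    encoded subject sequence. Returns per-seed (pep_start, pep_end,
    col_start, col_end, score). Rows still un-terminated at the window edge
    are re-extended with a window covering the whole profile.
    """
    length = ext.shape[0]
    n = seeds_p.size
    if n == 0:
        z = np.empty(0, dtype=np.int64)
        return z, z, z, z, np.empty(0)
    # seed score
    t = np.arange(k)
    seed_scores = ext[seeds_c[:, None] + t, enc[seeds_p[:, None] + t]].sum(axis=1)

    def direction(sign: int, origin_p: np.ndarray, origin_c: np.ndarray, w: int):
        steps = np.arange(1, w + 1)
        cols = origin_c[:, None] + sign * steps
        poss = origin_p[:, None] + sign * steps
        ok = (cols >= 0) & (cols < length) & (poss >= 0) & (poss < enc.size)
        sc = np.full((n, w), -1e9)  # out-of-range steps kill the extension
        cc = np.clip(cols, 0, length - 1)
        pp = np.clip(poss, 0, enc.size - 1)
        sc[ok] = ext[cc, enc[pp]][ok]
        return _directional_gain(sc, xdrop)

    def both(w: int):
        rg, rs = direction(+1, seeds_p + k - 1, seeds_c + k - 1, w)
        lg, ls = direction(-1, seeds_p, seeds_c, w)
        return rg, rs, lg, ls

    rg, rs, lg, ls = both(window)
    # re-run rows that hit the window edge without terminating
    if window < length:
        unfinished = (rs == window) | (ls == window)
        if unfinished.any():
            idx = np.flatnonzero(unfinished)
            sub = _extend_seeds(
                ext, enc, seeds_p[idx], seeds_c[idx], k, xdrop, window=length
            )
            pep_s, pep_e, col_s, col_e, score = _assemble(
                seeds_p, seeds_c, k, seed_scores, rg, rs, lg, ls
            )
            pep_s[idx], pep_e[idx], col_s[idx], col_e[idx], score[idx] = sub
            return pep_s, pep_e, col_s, col_e, score
    return _assemble(seeds_p, seeds_c, k, seed_scores, rg, rs, lg, ls)


def _assemble(seeds_p, seeds_c, k, seed_scores, rg, rs, lg, ls):
    pep_s = seeds_p - ls
    pep_e = seeds_p + k + rs
    col_s = seeds_c - ls
    col_e = seeds_c + k + rs
    score = seed_scores + rg + lg
    return pep_s, pep_e, col_s, col_e, score


def _merge_diagonal_hits(
    pep_s: np.ndarray,
    pep_e: np.ndarray,
    col_s: np.ndarray,
    score: np.ndarray,
) -> np.ndarray:
    """Indices of hits kept after merging same-diagonal overlaps (max score)."""
    diag = pep_s - col_s
    order = np.lexsort((-score, pep_s, diag))
    keep = []
    cur_diag = None
    cur_end = -1
    cur_best_idx = -1
    cur_best_score = -np.inf
    for i in order:
        d = diag[i]
        if d != cur_diag or pep_s[i] >= cur_end:
            if cur_best_idx >= 0:
                keep.append(cur_best_idx)
            cur_diag, cur_end = d, pep_e[i]
            cur_best_idx, cur_best_score = i, score[i]
        else:
            cur_end = max(cur_end, pep_e[i])
            if score[i] > cur_best_score:
                cur_best_idx, cur_best_score = i, score[i]
    if cur_best_idx >= 0:
        keep.append(cur_best_idx)
    return np.array(sorted(keep), dtype=np.int64)


def seed_and_extend(
    family: MarkerFamily, frames: Sequence[Frame], params: Params = Params()
) -> list[Hsp]:
    """Find the family's HSPs across a set of translation frames.

    Exact ``seed_k``-mer matches between member peptides and a frame
    peptide start ungapped extensions against the family PSSM, terminated
    by X-drop; same-diagonal overlaps keep the best-scoring hit, and hits
    below ``min_hsp_score`` bits are discarded.
    """
    table = _family_seed_table(family, params.seed_k)
    hsps: list[Hsp] = []
    for frame in frames:
        hsps.extend(_scan_frame_for_family(family, table, frame, None, params))
    return sorted(hsps, key=lambda h: (h.contig_id, h.strand, h.genome_start, h.profile_start))


def _scan_frame_for_family(
    family: MarkerFamily,
    table: dict[int, list[int]],
    frame: Frame,
    seed_hits: tuple[np.ndarray, np.ndarray] | None,
    params: Params,
) -> list[Hsp]:
    """Extend this family's seeds in one frame into HSPs.

    ``seed_hits`` may carry precomputed (positions, columns) pairs from a
    shared multi-family scan; otherwise seeds are found here.
    """
    if seed_hits is None:
        enc = _PEP_CODE[np.frombuffer(frame.peptide.encode(), dtype=np.uint8)]
        codes = _peptide_kmer_codes(enc, params.seed_k)
        ps, cs = [], []
        for p in range(codes.size):
            cols = table.get(int(codes[p]))
            if cols:
                for c in cols:
                    ps.append(p)
                    cs.append(c)
        seeds_p = np.array(ps, dtype=np.int64)
        seeds_c = np.array(cs, dtype=np.int64)
    else:
        seeds_p, seeds_c = seed_hits
        enc = _PEP_CODE[np.frombuffer(frame.peptide.encode(), dtype=np.uint8)]
    if seeds_p.size == 0:
        return []
    uniq = np.unique(np.stack([seeds_p, seeds_c], axis=1), axis=0)
    seeds_p, seeds_c = uniq[:, 0], uniq[:, 1]
    ext = family.profile._ext
    pep_s, pep_e, col_s, col_e, score = _extend_seeds(
        ext, enc, seeds_p, seeds_c, params.seed_k, params.xdrop
    )
    good = score >= params.min_hsp_score
    if not good.any():
        return []
    keep = _merge_diagonal_hits(pep_s[good], pep_e[good], col_s[good], score[good])
    gi = np.flatnonzero(good)[keep]
    hsps = []
    for i in gi:
        gs, ge = frame.genome_span(int(pep_s[i]), int(pep_e[i]))
        hsps.append(
            Hsp(
                family_id=family.id,
                contig_id=frame.contig_id,
                strand=frame.strand,
                genome_start=gs,
                genome_end=ge,
                profile_start=int(col_s[i]),
                profile_end=int(col_e[i]),
                score=float(score[i]),
                peptide=frame.peptide[int(pep_s[i]) : int(pep_e[i])],
            )
        )
    return hsps


# --- chaining -------------------------------------------------------------


def _overlap_penalty(a: Hsp, b: Hsp, overlap: int) -> float:
    """Score not double-counted on profile overlap: trim the weaker HSP."""
    if overlap <= 0:
        return 0.0
    rate_a = a.score / a.n_columns
    rate_b = b.score / b.n_columns
    return overlap * min(rate_a, rate_b)


def _link_ok(a: Hsp, b: Hsp, params: Params) -> bool:
    ao = a.oriented_span()
    bo = b.oriented_span()
    if bo[0] < ao[1]:  # exons must not overlap in the genome
        return False
    if bo[0] - ao[1] > params.max_intron:
        return False
    if b.profile_end <= a.profile_end or b.profile_start < a.profile_start:
        return False
    overlap = a.profile_end - b.profile_start
    return overlap <= params.max_profile_overlap


def chain_hsps(hsps: Sequence[Hsp], params: Params = Params()) -> tuple[list[Hsp], float]:
    """Best colinear chain of HSPs for one family/contig/strand.

    Successors must advance strictly in both genome (gene orientation) and
    profile coordinates, with genome gaps capped at ``max_intron`` and
    profile overlaps capped at ``max_profile_overlap`` columns (overlapped
    columns are charged to the lower-scoring HSP's per-column rate so no
    score is double-counted). Ties are broken toward the lexicographically
    smallest exon coordinate fingerprint.
    """
    if not hsps:
        return [], 0.0
    fam = {(h.family_id, h.contig_id, h.strand) for h in hsps}
    if len(fam) != 1:
        raise ValueError("chain_hsps expects HSPs of one family/contig/strand")
    order = sorted(
        range(len(hsps)),
        key=lambda i: (hsps[i].oriented_span(), hsps[i].profile_start, hsps[i].profile_end),
    )
    items = [hsps[i] for i in order]
    n = len(items)
    best_score = [h.score for h in items]
    parent = [-1] * n
    if n <= 24:
        # exact path with full fingerprint tie-breaking
        for j in range(n):
            for i in range(j):
                if not _link_ok(items[i], items[j], params):
                    continue
                overlap = items[i].profile_end - items[j].profile_start
                cand = best_score[i] + items[j].score - _overlap_penalty(items[i], items[j], overlap)
                if cand > best_score[j] + 1e-12 or (
                    abs(cand - best_score[j]) <= 1e-12
                    and _fingerprint(items, parent, i, j) < _fingerprint(items, parent, parent[j], j)
                ):
                    best_score[j] = cand
                    parent[j] = i
        end = 0
        for j in range(1, n):
            if best_score[j] > best_score[end] + 1e-12:
                end = j
            elif abs(best_score[j] - best_score[end]) <= 1e-12 and _fingerprint(
                items, parent, parent[j], j
            ) < _fingerprint(items, parent, parent[end], end):
                end = j
    else:
        # windowed path: predecessors are confined by the intron cap, so
        # only HSPs starting within (max_intron + longest span) need checking.
        # Ties resolve to the first candidate in canonical sort order.
        from bisect import bisect_left

        ostarts = [it.oriented_span()[0] for it in items]
        oends = [it.oriented_span()[1] for it in items]
        pss = [it.profile_start for it in items]
        pes = [it.profile_end for it in items]
        scores = [it.score for it in items]
        rates = [it.score / it.n_columns for it in items]
        max_span = max(e - s for s, e in zip(ostarts, oends))
        max_ov = params.max_profile_overlap
        max_gap = params.max_intron
        for j in range(n):
            lo = bisect_left(ostarts, ostarts[j] - max_gap - max_span)
            oj, psj, pej, sj, rj = ostarts[j], pss[j], pes[j], scores[j], rates[j]
            bj = best_score[j]
            for i in range(lo, j):
                if oends[i] > oj or oj - oends[i] > max_gap:
                    continue
                if pes[i] >= pej or pss[i] > psj or pes[i] - psj > max_ov:
                    continue
                cand = best_score[i] + sj
                ov = pes[i] - psj
                if ov > 0:
                    cand -= ov * (rates[i] if rates[i] < rj else rj)
                if cand > bj + 1e-12:
                    bj = cand
                    parent[j] = i
            best_score[j] = bj
        end = max(range(n), key=lambda j: best_score[j])
    chain_idx = []
    j = end
    while j != -1:
        chain_idx.append(j)
        j = parent[j]
    chain_idx.reverse()
    return [items[j] for j in chain_idx], float(best_score[end])


def _fingerprint(items: list[Hsp], parent: list[int], i: int, j: int) -> tuple:
    coords = [(items[j].genome_start, items[j].genome_end)]
    while i != -1:
        coords.append((items[i].genome_start, items[i].genome_end))
        i = parent[i]
    return tuple(sorted(coords))


def build_model(chain: list[Hsp], total_score: float, family: MarkerFamily) -> GeneModel:
    covered = sum(h.n_columns for h in chain)
    # subtract profile overlaps so coverage counts distinct columns
    for a, b in zip(chain, chain[1:]):
        covered -= max(0, a.profile_end - b.profile_start)
    peptide = "".join(h.peptide for h in chain)
    return GeneModel(
        family_id=family.id,
        contig_id=chain[0].contig_id,
        strand=chain[0].strand,
        exons=list(chain),
        model_peptide=peptide,
        total_score=total_score,
        coverage=covered / len(family.profile),
    )


def classify_model(
    model: GeneModel, family: MarkerFamily, params: Params = Params()
) -> str | None:
    """Complete / partial / aberrant classification of one gene model.

    Aberrant: peptide at least ``aberrant_factor`` times the family mean
    length. Complete: reaches the family threshold with at least
    ``coverage_complete`` of profile columns aligned. Partial: reaches
    ``partial_floor`` of the threshold. Otherwise the model is discarded
    (None). Boundaries are inclusive.
    """
    if len(model.model_peptide) >= params.aberrant_factor * family.mean_length:
        return "aberrant"
    if (
        model.total_score >= family.score_threshold
        and model.coverage >= params.coverage_complete
    ):
        return "complete"
    if model.total_score >= params.partial_floor * family.score_threshold:
        return "partial"
    return None


# --- whole-assembly scan --------------------------------------------------

_MAX_MODELS_PER_LOCUS_GROUP = 8


def _models_for_group(
    family: MarkerFamily, hsps: list[Hsp], params: Params
) -> list[GeneModel]:
    """Peel successive best chains so multiple gene copies are reported.

    After extracting the best chain, its HSPs are removed and chaining
    repeats, so two copies of a family on the same contig/strand yield two
    models instead of one. Peeling continues while extracted chains reach
    the family threshold (copy candidates); the first sub-threshold chain
    is still reported if it classifies (a genuine fragment), after which
    the group is exhausted — weaker chains cannot change the family status
    or the copy count.
    """
    models = []
    pool = list(hsps)
    for _ in range(_MAX_MODELS_PER_LOCUS_GROUP):
        if not pool:
            break
        chain, total = chain_hsps(pool, params)
        if not chain:
            break
        model = build_model(chain, total, family)
        status = classify_model(model, family, params)
        used = set(map(id, chain))
        pool = [h for h in pool if id(h) not in used]
        if status is not None:
            model.status = status
            models.append(model)
        if total < family.score_threshold:
            break
    return models


def scan_assembly(
    assembly: Assembly, markerset: MarkerSet, params: Params | None = None
) -> list[GeneModel]:
    """Find, chain and classify gene models for every family in the set.

    Contigs are translated once and shared across families; family seed
    k-mers are merged into one lookup so each frame is scanned a single
    time regardless of family count. Models are returned in deterministic
    order (family id, contig id, strand, genome start).
    """
    if params is None:
        params = markerset.params
    if len(assembly) == 0 or assembly.total_length == 0:
        raise ValueError("empty assembly")
    families = [markerset.families[k] for k in sorted(markerset.families)]
    k = params.seed_k
    merged: dict[int, list[tuple[int, int]]] = {}
    for fi, fam in enumerate(families):
        for code, cols in _family_seed_table(fam, k).items():
            merged.setdefault(code, []).extend((fi, c) for c in cols)
    lookup = np.zeros(_KMER_BASE**k, dtype=bool)
    lookup[np.array(list(merged), dtype=np.int64)] = True

    models: list[GeneModel] = []
    per_family_hsps: dict[int, dict[tuple[str, str], list[Hsp]]] = {
        fi: {} for fi in range(len(families))
    }
    for record in assembly:
        for frame in six_frame_translate(record):
            if not frame.peptide:
                continue
            enc = _PEP_CODE[np.frombuffer(frame.peptide.encode(), dtype=np.uint8)]
            codes = _peptide_kmer_codes(enc, k)
            valid = codes >= 0
            hit_pos = np.flatnonzero(valid & np.where(valid, lookup[np.maximum(codes, 0)], False))
            if hit_pos.size == 0:
                continue
            fam_seeds: dict[int, tuple[list[int], list[int]]] = {}
            for p in hit_pos:
                for fi, c in merged[int(codes[p])]:
                    slot = fam_seeds.setdefault(fi, ([], []))
                    slot[0].append(int(p))
                    slot[1].append(c)
            for fi, (ps, cs) in fam_seeds.items():
                hits = _scan_frame_for_family(
                    families[fi],
                    {},
                    frame,
                    (np.array(ps, dtype=np.int64), np.array(cs, dtype=np.int64)),
                    params,
                )
                if hits:
                    key = (frame.contig_id, frame.strand)
                    per_family_hsps[fi].setdefault(key, []).extend(hits)
    for fi, fam in enumerate(families):
        for key in sorted(per_family_hsps[fi]):
            models.extend(_models_for_group(fam, per_family_hsps[fi][key], params))
    models.sort(key=lambda m: (m.family_id, m.contig_id, m.strand, m.genome_start))
    return models


def write_gff3(models: Iterable[GeneModel], dest) -> None:
    """Dump gene models as GFF3 (1-based inclusive; exons as CDS features)."""
    dest.write("##gff-version 3\n")
    for i, m in enumerate(models, start=1):
        gid = f"model{i:05d}.{m.family_id}"
        dest.write(
            "\t".join(
                [
                    m.contig_id,
                    "mycocheck",
                    "gene",
                    str(m.genome_start + 1),
                    str(m.genome_end),
                    f"{m.total_score:.2f}",
                    m.strand,
                    ".",
                    f"ID={gid};family={m.family_id};status={m.status}",
                ]
            )
            + "\n"
        )
        for j, exon in enumerate(sorted(m.exons, key=lambda e: e.genome_start), start=1):
            phase = "0"
            dest.write(
                "\t".join(
                    [
                        exon.contig_id,
                        "mycocheck",
                        "CDS",
                        str(exon.genome_start + 1),
                        str(exon.genome_end),
                        f"{exon.score:.2f}",
                        exon.strand,
                        phase,
                        f"ID={gid}.cds{j};Parent={gid}",
                    ]
                )
                + "\n"
            )
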