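"""Completeness reporting: per-marker status, HDE detection, collapse audit.

The completeness percentage is the fraction of marker families whose best
gene model is complete; the complete-or-partial percentage is reported
alongside it, since fragmented assemblies often recover gene fragments that
clear the partial floor without reaching full score and coverage. Aberrant
models (suspiciously long fusions or run-ons) never count toward
completeness but are tallied. Multi-copy families found at fewer distinct
loci than their expected minimum copy number are flagged as potentially
collapsed repeats; note the copy count cannot distinguish genuinely
independent copies from unassembled duplicated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .assembly_metrics import AssemblyStats, assembly_stats
from .homology import (
    GeneModel,
    Hsp,
    _extend_seeds,
    scan_assembly,
)
from .markers import HdeElement, MarkerSet, Params
from .seqio import Assembly


@dataclass
class FamilyEntry:
    status: str
    n_copies: int
    best_model: GeneModel | None = None


@dataclass(frozen=True)
class HdeHit:
    element_id: str
    contig_id: str
    strand: str
    genome_start: int
    genome_end: int
    score: float
    detected: bool


@dataclass
class CompletenessReport:
    per_family: dict[str, FamilyEntry]
    pct_complete: float
    pct_complete_or_partial: float
    pct_aberrant: float
    pct_missing: float
    hde_detected: int
    hde_total: int
    pct_hde: float
    collapse_flags: list[str]
    assembly_stats: AssemblyStats
    hde_hits: list[HdeHit] = field(default_factory=list)

    def to_dict(self) -> dict:
        def model_dict(m: GeneModel | None):
            if m is None:
                return None
            return {
                "family_id": m.family_id,
                "contig_id": m.contig_id,
                "strand": m.strand,
                "status": m.status,
                "total_score": m.total_score,
                "coverage": m.coverage,
                "model_peptide": m.model_peptide,
                "exons": [
                    {
                        "genome_start": e.genome_start,
                        "genome_end": e.genome_end,
                        "profile_start": e.profile_start,
                        "profile_end": e.profile_end,
                        "score": e.score,
                        "peptide": e.peptide,
                    }
                    for e in m.exons
                ],
            }

        return {
            "per_family": {
                fid: {
                    "status": e.status,
                    "n_copies": e.n_copies,
                    "best_model": model_dict(e.best_model),
                }
                for fid, e in sorted(self.per_family.items())
            },
            "pct_complete": self.pct_complete,
            "pct_complete_or_partial": self.pct_complete_or_partial,
            "pct_aberrant": self.pct_aberrant,
            "pct_missing": self.pct_missing,
            "hde_detected": self.hde_detected,
            "hde_total": self.hde_total,
            "pct_hde": self.pct_hde,
            "collapse_flags": sorted(self.collapse_flags),
            "hde_hits": [
                {
                    "element_id": h.element_id,
                    "contig_id": h.contig_id,
                    "strand": h.strand,
                    "genome_start": h.genome_start,
                    "genome_end": h.genome_end,
                    "score": h.score,
                    "detected": h.detected,
                }
                for h in self.hde_hits
            ],
            "assembly_stats": {
                "n_contigs": self.assembly_stats.n_contigs,
                "total_length": self.assembly_stats.total_length,
                "n50_length": self.assembly_stats.n50_length,
                "l50_count": self.assembly_stats.l50_count,
                "max_length": self.assembly_stats.max_length,
                "n_fraction": self.assembly_stats.n_fraction,
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CompletenessReport":
        def model_from(d):
            if d is None:
                return None
            exons = [
                Hsp(
                    family_id=d["family_id"],
                    contig_id=d["contig_id"],
                    strand=d["strand"],
                    **e,
                )
                for e in d["exons"]
            ]
            return GeneModel(
                family_id=d["family_id"],
                contig_id=d["contig_id"],
                strand=d["strand"],
                exons=exons,
                model_peptide=d["model_peptide"],
                total_score=d["total_score"],
                coverage=d["coverage"],
                status=d["status"],
            )

        return cls(
            per_family={
                fid: FamilyEntry(e["status"], e["n_copies"], model_from(e["best_model"]))
                for fid, e in data["per_family"].items()
            },
            pct_complete=data["pct_complete"],
            pct_complete_or_partial=data["pct_complete_or_partial"],
            pct_aberrant=data["pct_aberrant"],
            pct_missing=data["pct_missing"],
            hde_detected=data["hde_detected"],
            hde_total=data["hde_total"],
            pct_hde=data["pct_hde"],
            collapse_flags=list(data["collapse_flags"]),
            hde_hits=[HdeHit(**h) for h in data["hde_hits"]],
            assembly_stats=AssemblyStats(**data["assembly_stats"]),
        )


def _same_locus(a: GeneModel, b: GeneModel) -> bool:
    """Two models share a locus if they overlap >= 50% of the shorter one."""
    if a.contig_id != b.contig_id:
        return False
    lo = max(a.genome_start, b.genome_start)
    hi = min(a.genome_end, b.genome_end)
    if hi <= lo:
        return False
    shorter = min(a.genome_end - a.genome_start, b.genome_end - b.genome_start)
    return (hi - lo) >= 0.5 * shorter


def _distinct_copies(models: Sequence[GeneModel]) -> list[GeneModel]:
    accepted: list[GeneModel] = []
    for m in sorted(models, key=lambda m: (-m.total_score, m.contig_id, m.genome_start)):
        if not any(_same_locus(m, other) for other in accepted):
            accepted.append(m)
    return accepted


def select_final_models(
    models: Sequence[GeneModel], markerset: MarkerSet
) -> dict[str, FamilyEntry]:
    """Pick each family's representative model and per-family status.

    Aberrant models are excluded from the representative choice (they are
    filtered before the longest-model rule) but a family with only
    aberrant models is reported as aberrant rather than missing. Among the
    rest the longest peptide wins; ties go to the higher score, then the
    smaller genome start. Copy counts use threshold-passing non-aberrant
    models at distinct loci.
    """
    by_family: dict[str, list[GeneModel]] = {fid: [] for fid in markerset.families}
    for m in models:
        by_family[m.family_id].append(m)
    selection: dict[str, FamilyEntry] = {}
    for fid, fam_models in by_family.items():
        family = markerset.families[fid]
        candidates = [m for m in fam_models if m.status != "aberrant"]
        strong = [
            m
            for m in candidates
            if m.total_score >= family.score_threshold
        ]
        n_copies = len(_distinct_copies(strong))
        if candidates:
            best = sorted(
                candidates,
                key=lambda m: (-len(m.model_peptide), -m.total_score, m.contig_id, m.genome_start),
            )[0]
            selection[fid] = FamilyEntry(best.status, n_copies, best)
        elif fam_models:
            best = max(fam_models, key=lambda m: m.total_score)
            selection[fid] = FamilyEntry("aberrant", n_copies, best)
        else:
            selection[fid] = FamilyEntry("missing", 0, None)
    return selection


def protein_completeness(selection: dict[str, FamilyEntry]) -> dict[str, float]:
    """Aggregate per-family statuses into percentages."""
    n = len(selection)
    if n == 0:
        raise ValueError("empty selection")
    counts = {"complete": 0, "partial": 0, "aberrant": 0, "missing": 0}
    for entry in selection.values():
        counts[entry.status] += 1
    return {
        "pct_complete": 100.0 * counts["complete"] / n,
        "pct_complete_or_partial": 100.0 * (counts["complete"] + counts["partial"]) / n,
        "pct_aberrant": 100.0 * counts["aberrant"] / n,
        "pct_missing": 100.0 * counts["missing"] / n,
    }


# --- HDE detection --------------------------------------------------------


def _nt_kmer_codes(enc: np.ndarray, k: int) -> np.ndarray:
    """Rolling base-4 codes over pure-ACGT windows; windows with N -> -1."""
    n = enc.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    e = enc.astype(np.int64)
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        codes = codes * 4 + np.minimum(e[j : j + n], 3)
        valid &= e[j : j + n] < 4
    return np.where(valid, codes, -1)


def hde_search(
    assembly: Assembly,
    elements: dict[str, HdeElement],
    params: Params = Params(),
) -> tuple[list[HdeHit], float]:
    """Scan both strands for conserved DNA elements.

    Seeds are exact 12-mer matches to each element's profile consensus,
    extended under the same X-drop scheme as the protein search but at the
    nucleotide level. An element is detected when its best hit reaches 80%
    of the lowest member self-score — the same threshold rule the protein
    families use.
    """
    if not elements:
        raise ValueError("no HDE elements")
    k = params.hde_seed_k
    elems = [elements[key] for key in sorted(elements)]
    merged: dict[int, list[tuple[int, int]]] = {}
    for ei, elem in enumerate(elems):
        enc = elem.profile.encode(elem.consensus)
        codes = _nt_kmer_codes(enc, k)
        for c0 in range(codes.size):
            if codes[c0] >= 0:
                merged.setdefault(int(codes[c0]), []).append((ei, c0))
    lookup = np.zeros(4**k, dtype=bool)
    if merged:
        lookup[np.array(list(merged), dtype=np.int64)] = True
    best_hits: dict[int, HdeHit | None] = {ei: None for ei in range(len(elems))}
    for record in assembly:
        length = len(record)
        for strand in "+-":
            if strand == "+":
                seq_enc = elems[0].profile.encode(record.sequence)
            else:
                from .homology import reverse_complement

                seq_enc = elems[0].profile.encode(reverse_complement(record.sequence))
            codes = _nt_kmer_codes(seq_enc, k)
            if codes.size == 0:
                continue
            valid = codes >= 0
            hit_pos = np.flatnonzero(valid & np.where(valid, lookup[np.maximum(codes, 0)], False))
            fam_seeds: dict[int, tuple[list[int], list[int]]] = {}
            for p in hit_pos:
                for ei, c0 in merged[int(codes[p])]:
                    slot = fam_seeds.setdefault(ei, ([], []))
                    slot[0].append(int(p))
                    slot[1].append(c0)
            for ei, (ps, cs) in fam_seeds.items():
                elem = elems[ei]
                pep_s, pep_e, col_s, col_e, score = _extend_seeds(
                    elem.profile._ext,
                    seq_enc,
                    np.array(ps, dtype=np.int64),
                    np.array(cs, dtype=np.int64),
                    k,
                    params.xdrop,
                )
                if score.size == 0:
                    continue
                i = int(np.argmax(score))
                if score[i] < params.min_hsp_score:
                    continue
                s, e = int(pep_s[i]), int(pep_e[i])
                if strand == "-":
                    s, e = length - e, length - s
                hit_obj = HdeHit(
                    element_id=elem.id,
                    contig_id=record.id,
                    strand=strand,
                    genome_start=s,
                    genome_end=e,
                    score=float(score[i]),
                    detected=bool(score[i] >= elem.score_threshold),
                )
                prev = best_hits[ei]
                if prev is None or hit_obj.score > prev.score:
                    best_hits[ei] = hit_obj
    hits = [h for h in best_hits.values() if h is not None]
    hits.sort(key=lambda h: h.element_id)
    detected = sum(h.detected for h in hits)
    pct = 100.0 * detected / len(elems)
    return hits, pct


def multicopy_audit(
    selection: dict[str, FamilyEntry], markerset: MarkerSet
) -> list[str]:
    """Flag multi-copy families found at fewer loci than expected."""
    flags = []
    for fid, entry in selection.items():
        family = markerset.families[fid]
        if family.expected_min_copies > 1 and entry.n_copies < family.expected_min_copies:
            flags.append(fid)
    return sorted(flags)


def full_report(
    assembly: Assembly, markerset: MarkerSet, params: Params | None = None
) -> CompletenessReport:
    """Run the whole pipeline on an assembly and assemble the report."""
    if params is None:
        params = markerset.params
    models = scan_assembly(assembly, markerset, params)
    selection = select_final_models(models, markerset)
    pct = protein_completeness(selection)
    if markerset.hde_elements:
        hde_hits, pct_hde = hde_search(assembly, markerset.hde_elements, params)
        n_detected = sum(h.detected for h in hde_hits)
    else:
        hde_hits, pct_hde, n_detected = [], 0.0, 0
    flags = multicopy_audit(selection, markerset)
    return CompletenessReport(
        per_family=selection,
        pct_complete=pct["pct_complete"],
        pct_complete_or_partial=pct["pct_complete_or_partial"],
        pct_aberrant=pct["pct_aberrant"],
        pct_missing=pct["pct_missing"],
        hde_detected=n_detected,
        hde_total=len(markerset.hde_elements),
        pct_hde=pct_hde,
        collapse_flags=flags,
        assembly_stats=assembly_stats(assembly),
        hde_hits=hde_hits,
    )
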