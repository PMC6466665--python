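"""Completeness from unassembled reads: reservoir sampling + rarefaction.

Long reads are grouped into blocks of ``block_size`` sequences; a fixed
number of blocks is drawn uniformly from the stream by single-pass
reservoir sampling (Algorithm R), so the read file is never held in memory
and never needs a second pass. Sampled blocks are then scanned one at a
time for marker families not seen yet; scanning stops once
``stop_patience`` consecutive blocks contribute no new marker (the
rarefaction curve has plateaued) or the blocks run out.

A family counts as detected when any read yields an HSP reaching the
partial floor (30%) of its threshold — individual reads cover gene
fragments, so the full-length score is not expected.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .homology import (
    _KMER_BASE,
    _PEP_CODE,
    _extend_seeds,
    _family_seed_table,
    _peptide_kmer_codes,
    six_frame_translate,
)
from .markers import MarkerSet, Params
from .seqio import SeqRecord

Block = tuple[int, list[SeqRecord]]


@dataclass(frozen=True)
class IterationRecord:
    iteration: int
    block_id: int
    new_markers: int
    cumulative_markers: int


@dataclass
class RarefactionCurve:
    per_iteration: list[IterationRecord]
    stopped_at: int
    stop_reason: str  # "patience_exhausted" | "blocks_exhausted"

    def __post_init__(self) -> None:
        cum = 0
        for rec in self.per_iteration:
            cum += rec.new_markers
            assert rec.cumulative_markers == cum

    def to_tsv(self) -> str:
        lines = ["#iteration\tblock_id\tnew_markers\tcumulative_markers"]
        for rec in self.per_iteration:
            lines.append(
                f"{rec.iteration}\t{rec.block_id}\t{rec.new_markers}\t{rec.cumulative_markers}"
            )
        lines.append(f"# stopped_at\t{self.stopped_at}")
        lines.append(f"# stop_reason\t{self.stop_reason}")
        return "\n".join(lines) + "\n"


def block_stream(reads: Iterable[SeqRecord], block_size: int) -> Iterator[Block]:
    """Group consecutive reads into (block_id, reads) blocks.

    The final block may be smaller; an empty stream yields nothing.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    buffer: list[SeqRecord] = []
    block_id = 0
    for read in reads:
        buffer.append(read)
        if len(buffer) == block_size:
            yield block_id, buffer
            buffer = []
            block_id += 1
    if buffer:
        yield block_id, buffer


def reservoir_sample(blocks: Iterable[Block], k: int, rng_seed: int) -> list[Block]:
    """Uniform single-pass sample of k blocks (Algorithm R).

    The first k blocks fill the reservoir; block i (1-based, i > k)
    replaces a uniformly random slot with probability k/i. Output order is
    randomized by a final shuffle. Deterministic for a fixed seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = random.Random(rng_seed)
    reservoir: list[Block] = []
    for i, block in enumerate(blocks, start=1):
        if i <= k:
            reservoir.append(block)
        else:
            j = rng.randrange(i)
            if j < k:
                reservoir[j] = block
    rng.shuffle(reservoir)
    return reservoir


def iterative_scan(
    blocks: Sequence[Block], markerset: MarkerSet, params: Params | None = None
) -> tuple[RarefactionCurve, set[str]]:
    """Scan sampled blocks one at a time, accumulating detected families.

    An iteration is one block scanned; an unsuccessful attempt is an
    iteration detecting no new family. The consecutive-failure counter
    resets on any gain and scanning stops when it reaches
    ``stop_patience``.
    """
    if params is None:
        params = markerset.params
    if not blocks:
        raise ValueError("no blocks to scan")
    families = [markerset.families[key] for key in sorted(markerset.families)]
    k = params.seed_k
    merged: dict[int, list[tuple[int, int]]] = {}
    for fi, fam in enumerate(families):
        for code, cols in _family_seed_table(fam, k).items():
            merged.setdefault(code, []).extend((fi, c) for c in cols)
    lookup = np.zeros(_KMER_BASE**k, dtype=bool)
    if merged:
        lookup[np.array(list(merged), dtype=np.int64)] = True
    floors = [params.partial_floor * fam.score_threshold for fam in families]

    detected: set[int] = set()
    records: list[IterationRecord] = []
    failures = 0
    stop_reason = "blocks_exhausted"
    iteration = 0
    for block_id, block_reads in blocks:
        iteration += 1
        gained = _scan_block(block_reads, families, merged, lookup, floors, detected, params)
        detected.update(gained)
        records.append(
            IterationRecord(iteration, block_id, len(gained), len(detected))
        )
        failures = 0 if gained else failures + 1
        if failures >= params.stop_patience:
            stop_reason = "patience_exhausted"
            break
    curve = RarefactionCurve(records, stopped_at=iteration, stop_reason=stop_reason)
    return curve, {families[fi].id for fi in detected}


def _scan_block(
    block_reads: Sequence[SeqRecord],
    families,
    merged,
    lookup,
    floors,
    already: set[int],
    params: Params,
) -> set[int]:
    gained: set[int] = set()
    k = params.seed_k
    for read in block_reads:
        for frame in six_frame_translate(read):
            if len(frame.peptide) < k:
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
                    if fi in already or fi in gained:
                        continue
                    slot = fam_seeds.setdefault(fi, ([], []))
                    slot[0].append(int(p))
                    slot[1].append(c)
            for fi, (ps, cs) in fam_seeds.items():
                *_, score = _extend_seeds(
                    families[fi].profile._ext,
                    enc,
                    np.array(ps, dtype=np.int64),
                    np.array(cs, dtype=np.int64),
                    k,
                    params.xdrop,
                )
                if score.size and score.max() >= floors[fi]:
                    gained.add(fi)
    return gained


def reads_completeness(
    reads: Iterable[SeqRecord], markerset: MarkerSet, params: Params | None = None
) -> dict:
    """Estimate completeness directly from a read stream.

    Composes block grouping, reservoir sampling and the iterative scan;
    returns the detected-family percentage together with the rarefaction
    curve and the detected family ids.
    """
    if params is None:
        params = markerset.params
    blocks = block_stream(reads, params.block_size)
    sampled = reservoir_sample(blocks, params.n_blocks, params.rng_seed)
    if not sampled:
        raise ValueError("no reads provided")
    curve, detected = iterative_scan(sampled, markerset, params)
    pct = 100.0 * len(detected) / len(markerset.families)
    return {"pct_detected": pct, "curve": curve, "detected_families": sorted(detected)}
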