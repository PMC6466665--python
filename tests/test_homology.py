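"""Six-frame translation, seed-and-extend, chaining, and classification."""

import itertools

import numpy as np
import pytest

import mycocheck as mc
from mycocheck.homology import (
    Frame,
    Hsp,
    build_model,
    reverse_complement,
    seed_and_extend,
    six_frame_translate,
)
from mycocheck.markers import Params
from mycocheck.seqio import SeqRecord
from mycocheck.synthetic import _reverse_translate


class TestSixFrameTranslate:
    @pytest.mark.parametrize(
        "seq, strand, offset, expected",
        [
            ("ATGGCCTAA", "+", 0, "MA*"),
            ("CAT", "-", 0, "M"),  # reverse complement ATG
            ("ATNGGC", "+", 0, "XG"),  # N codon -> X
        ],
    )
    def test_examples(self, seq, strand, offset, expected):
        frames = six_frame_translate(SeqRecord("x", seq))
        frame = next(f for f in frames if f.strand == strand and f.offset == offset)
        assert frame.peptide == expected

    def test_six_frames_with_trailing_bases_dropped(self):
        frames = six_frame_translate(SeqRecord("x", "ATGGCCTAAC"))
        assert len(frames) == 6
        assert all(len(f.peptide) == (10 - f.offset) // 3 for f in frames)

    def test_mapping_is_invertible(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=100))
        for frame in six_frame_translate(SeqRecord("x", seq)):
            for i in range(len(frame.peptide)):
                start, end = frame.genome_span(i, i + 1)
                codon = seq[start:end]
                if frame.strand == "-":
                    codon = reverse_complement(codon)
                assert six_frame_translate(SeqRecord("c", codon))[0].peptide == frame.peptide[i]


def _embed(gene: str, rng: np.random.Generator, flank: int = 300) -> tuple[str, int]:
    left = "".join(rng.choice(list("ACGT"), size=flank))
    right = "".join(rng.choice(list("ACGT"), size=flank))
    return left + gene + right, len(left)


@pytest.fixture(scope="module")
def extend_family():
    return mc.make_marker_families(1, n_members=4, mean_length=80, rng_seed=9)[0]


class TestSeedAndExtend:
    def test_embedded_member_recovered_with_self_score(self, extend_family):
        family = extend_family
        rng = np.random.default_rng(1)
        member = family.members[0].sequence
        gene = _reverse_translate(rng, member)
        seq, start = _embed(gene, rng)
        # pad so the gene sits in frame +0
        seq = "N" * ((3 - start % 3) % 3) + seq
        frames = six_frame_translate(SeqRecord("c", seq))
        hsps = seed_and_extend(family, frames)
        best = max(hsps, key=lambda h: h.score)
        assert best.peptide == member
        assert best.strand == "+"
        enc = family.profile.encode(member)
        ungapped_self = float(
            family.profile.column_scores(enc, np.arange(len(member))).sum()
        )
        assert best.score == pytest.approx(ungapped_self)

    def test_no_shared_kmer_yields_nothing(self):
        poly_w = mc.MarkerFamily.build(
            "w", [SeqRecord(f"m{i}", "W" * 50) for i in range(3)]
        )
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("AT"), size=2000))  # no G: no Trp codon
        hsps = seed_and_extend(poly_w, six_frame_translate(SeqRecord("c", seq)))
        assert hsps == []

    def test_reverse_strand_coordinates_round_trip(self, extend_family):
        family = extend_family
        rng = np.random.default_rng(3)
        member = family.members[0].sequence
        gene = _reverse_translate(rng, member)
        seq, _ = _embed(reverse_complement(gene), rng)
        record = SeqRecord("c", seq)
        hsps = seed_and_extend(family, six_frame_translate(record))
        best = max(hsps, key=lambda h: h.score)
        assert best.strand == "-"
        segment = reverse_complement(seq[best.genome_start : best.genome_end])
        assert six_frame_translate(SeqRecord("s", segment))[0].peptide == best.peptide
        assert best.peptide == member


def _random_hsp(rng, strand="+"):
    start = 3 * int(rng.integers(0, 200))
    length = 3 * int(rng.integers(1, 25))
    ps = int(rng.integers(0, 80))
    pe = ps + int(rng.integers(1, 40))
    return Hsp(
        family_id="f",
        contig_id="c",
        strand=strand,
        genome_start=start,
        genome_end=start + length,
        profile_start=ps,
        profile_end=pe,
        score=float(rng.uniform(1, 50)),
        peptide="A" * (length // 3),
    )


def oracle_best_chain(hsps, params):
    """Exhaustive enumeration over all subsets, from the chaining contract:
    successors advance strictly in gene-oriented genome coordinates and in
    profile coordinates; genome gap <= max_intron; profile overlap <=
    max_profile_overlap, charged at the lower-scoring HSP's per-column rate.
    """

    def ospan(h):
        if h.strand == "+":
            return (h.genome_start, h.genome_end)
        return (-h.genome_end, -h.genome_start)

    def link(a, b):
        ao, bo = ospan(a), ospan(b)
        return (
            bo[0] >= ao[1]
            and bo[0] - ao[1] <= params.max_intron
            and b.profile_end > a.profile_end
            and b.profile_start >= a.profile_start
            and a.profile_end - b.profile_start <= params.max_profile_overlap
        )

    best = 0.0
    for r in range(1, len(hsps) + 1):
        for subset in itertools.combinations(hsps, r):
            chain = sorted(subset, key=ospan)
            if all(link(a, b) for a, b in zip(chain, chain[1:])):
                score = sum(h.score for h in chain)
                for a, b in zip(chain, chain[1:]):
                    ov = a.profile_end - b.profile_start
                    if ov > 0:
                        score -= ov * min(
                            a.score / (a.profile_end - a.profile_start),
                            b.score / (b.profile_end - b.profile_start),
                        )
                best = max(best, score)
    return best


class TestChainHsps:
    def test_colinear_pair_is_additive(self):
        a = Hsp("f", "c", "+", 0, 30, 0, 10, 30.0, "A" * 10)
        b = Hsp("f", "c", "+", 60, 90, 15, 25, 40.0, "A" * 10)
        chain, total = mc.chain_hsps([a, b])
        assert chain == [a, b]
        assert total == pytest.approx(70.0)

    def test_mutually_exclusive_pair_takes_max(self):
        a = Hsp("f", "c", "+", 0, 30, 0, 10, 30.0, "A" * 10)
        b = Hsp("f", "c", "+", 60, 90, 0, 10, 40.0, "A" * 10)
        chain, total = mc.chain_hsps([a, b])
        assert chain == [b]
        assert total == pytest.approx(40.0)

    def test_empty_input(self):
        assert mc.chain_hsps([]) == ([], 0.0)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_exhaustive_oracle(self, strand):
        params = Params()
        rng = np.random.default_rng(17 if strand == "+" else 18)
        for _ in range(40):
            hsps = [_random_hsp(rng, strand) for _ in range(int(rng.integers(1, 9)))]
            _, total = mc.chain_hsps(hsps, params)
            assert total == pytest.approx(oracle_best_chain(hsps, params), abs=1e-9)

    def test_mixed_groups_rejected(self):
        a = Hsp("f", "c", "+", 0, 30, 0, 10, 30.0, "A" * 10)
        b = Hsp("g", "c", "+", 60, 90, 15, 25, 40.0, "A" * 10)
        with pytest.raises(ValueError):
            mc.chain_hsps([a, b])


@pytest.fixture(scope="module")
def family():
    return mc.make_marker_families(1, n_members=4, mean_length=100, rng_seed=4)[0]


class TestClassifyModel:
    def _model(self, family, peptide_len, score, coverage):
        hsp = Hsp(
            family.id, "c", "+", 0, 3 * peptide_len, 0, max(1, int(coverage * len(family.profile))),
            score, "A" * peptide_len,
        )
        model = build_model([hsp], score, family)
        model.coverage = coverage
        return model

    def test_twice_mean_length_is_aberrant(self, family):
        model = self._model(family, int(2.0 * family.mean_length), 50.0, 0.5)
        assert mc.classify_model(model, family) == "aberrant"

    def test_threshold_and_coverage_boundary_is_complete(self, family):
        model = self._model(family, 100, family.score_threshold, 0.70)
        assert mc.classify_model(model, family) == "complete"

    def test_half_threshold_low_coverage_is_partial(self, family):
        model = self._model(family, 50, 0.5 * family.score_threshold, 0.2)
        assert mc.classify_model(model, family) == "partial"

    def test_below_partial_floor_is_discarded(self, family):
        model = self._model(family, 10, 0.1 * family.score_threshold, 0.05)
        assert mc.classify_model(model, family) is None


class TestScanAssembly:
    def test_embedded_families_all_complete(self, small_markerset, small_genome, small_report):
        statuses = {f: e.status for f, e in small_report.per_family.items()}
        assert all(s == "complete" for s in statuses.values())

    def test_random_genome_has_no_complete_models(self, small_markerset):
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            seq = "".join(rng.choice(list("ACGT"), size=100_000))
            asm = mc.Assembly([SeqRecord("r", seq)])
            models = mc.scan_assembly(asm, small_markerset)
            assert all(m.status != "complete" for m in models)

    def test_gene_split_across_contigs_is_partial(self, small_markerset, small_genome):
        assembly, truth = small_genome
        fam_id = "fam005"  # single-copy in this fixture
        locus = truth.loci_for(fam_id)[0]
        mid = (locus.genome_start + locus.genome_end) // 2
        contig = assembly[locus.contig_id]
        halves = mc.Assembly(
            [
                SeqRecord("left", contig.sequence[: mid]),
                SeqRecord("right", contig.sequence[mid:]),
            ]
        )
        single = mc.MarkerSet(
            families={fam_id: small_markerset.families[fam_id]},
            params=small_markerset.params,
        )
        models = mc.scan_assembly(halves, single)
        assert models, "split gene should still leave fragments"
        assert all(m.status != "complete" for m in models)
        assert any(m.status == "partial" for m in models)

    def test_deleting_a_contig_never_adds_complete_models(
        self, small_markerset, small_genome
    ):
        assembly, _ = small_genome
        full = sum(
            m.status == "complete" for m in mc.scan_assembly(assembly, small_markerset)
        )
        reduced = mc.Assembly(list(assembly.records)[1:])
        fewer = sum(
            m.status == "complete" for m in mc.scan_assembly(reduced, small_markerset)
        )
        assert fewer <= full

    def test_empty_assembly_rejected(self, small_markerset):
        with pytest.raises(Exception):
            mc.scan_assembly(mc.Assembly([]), small_markerset)

    def test_coordinate_round_trip_for_all_exons(self, small_markerset, small_genome):
        assembly, _ = small_genome
        models = mc.scan_assembly(assembly, small_markerset)
        assert models
        for model in models:
            for exon in model.exons:
                segment = assembly[exon.contig_id].sequence[
                    exon.genome_start : exon.genome_end
                ]
                if exon.strand == "-":
                    segment = reverse_complement(segment)
                translated = six_frame_translate(SeqRecord("s", segment))[0].peptide
                assert translated == exon.peptide
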