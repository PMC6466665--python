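"""Profiles, thresholds, family filtering, and the marker-set archive."""

import io
import math

import numpy as np
import pytest

import mycocheck as mc
from mycocheck.markers import (
    SKIP_PENALTY,
    STOP_SCORE,
    Cluster,
    build_profile,
    family_threshold,
    score_sequence,
)
from mycocheck.seqio import AMINO_ACIDS, SeqRecord


def oracle_local_score(profile, sequence):
    """Plain-python local alignment DP, written from the scoring contract:
    match consumes one residue and one column; skipping either costs
    SKIP_PENALTY bits; X scores 0; '*' scores STOP_SCORE; empty alignment
    scores 0.
    """

    def col_score(j, ch):
        if ch == "*":
            return STOP_SCORE
        if ch in profile.alphabet:
            return float(profile.matrix[j][profile.alphabet.index(ch)])
        return 0.0

    n, L = len(sequence), len(profile)
    h = [[0.0] * (L + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, L + 1):
            h[i][j] = max(
                0.0,
                h[i - 1][j - 1] + col_score(j - 1, sequence[i - 1]),
                h[i - 1][j] - SKIP_PENALTY,
                h[i][j - 1] - SKIP_PENALTY,
            )
            best = max(best, h[i][j])
    return best


class TestBuildProfile:
    def test_single_row_closed_form(self):
        """With vanishing pseudocounts the observed residue scores log2(20)."""
        p = build_profile(["MK"], pseudocount_weight=1e-12)
        assert len(p) == 2
        for j, ch in enumerate("MK"):
            assert p.matrix[j][AMINO_ACIDS.index(ch)] == pytest.approx(
                math.log2(20), abs=1e-6
            )

    def test_identical_column_dominates(self):
        rows = ["W" * 3] * 10
        p = build_profile(rows)
        w = AMINO_ACIDS.index("W")
        for j in range(len(p)):
            others = [p.matrix[j][a] for a in range(20) if a != w]
            assert p.matrix[j][w] > max(others)

    def test_gappy_column_dropped(self):
        rows = ["M-K", "M-K", "MAK", "MAK", "M-K"]  # middle column 60% gaps
        p = build_profile(rows)
        assert len(p) == 2
        assert list(p.kept_columns) == [0, 2]

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            build_profile([])

    def test_all_gappy_rejected(self):
        with pytest.raises(ValueError, match="gappy"):
            build_profile(["--", "--", "AA"])


class TestScoreSequence:
    def test_self_alignment_sums_column_scores(self):
        p = build_profile(["MKWC"])
        expected = sum(
            p.matrix[j][AMINO_ACIDS.index(ch)] for j, ch in enumerate("MKWC")
        )
        assert score_sequence(p, "MKWC") == pytest.approx(expected)

    def test_empty_peptide_scores_zero(self):
        p = build_profile(["MKWC"])
        assert score_sequence(p, "") == 0.0

    def test_matches_independent_dp_oracle(self):
        rng = np.random.default_rng(7)
        aas = list(AMINO_ACIDS)
        for _ in range(10):
            rows = ["".join(rng.choice(aas, size=50))]
            p = build_profile(rows)
            peptide = "".join(rng.choice(aas + ["X", "*"], size=50))
            assert score_sequence(p, peptide) == pytest.approx(
                oracle_local_score(p, peptide), abs=1e-9
            )

    def test_score_never_negative(self):
        p = build_profile(["WWWW"])
        assert score_sequence(p, "DDDD") >= 0.0


class TestFamilyThreshold:
    @pytest.mark.parametrize(
        "scores, expected",
        [([100, 90, 50], 40.0), ([12.5], 10.0), ([0], 0.0)],
    )
    def test_eighty_percent_of_minimum(self, scores, expected):
        assert family_threshold(scores) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            family_threshold([])

    def test_every_member_passes_its_own_threshold(self):
        """80% of the minimum guarantees all members clear the bar."""
        fams = mc.make_marker_families(20, n_members=6, mean_length=80, rng_seed=5)
        for fam in fams:
            assert fam.score_threshold == pytest.approx(0.8 * min(fam.member_scores))
            assert all(s >= fam.score_threshold for s in fam.member_scores)


def _cluster(name, seqs, species=None):
    rows = tuple(SeqRecord(f"m{i}", s) for i, s in enumerate(seqs))
    return Cluster(name, rows, tuple(species or (f"sp{i}" for i in range(len(seqs)))))


class TestFilterFamilies:
    def test_species_presence_rule(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=60))
        wide = _cluster("wide", [seq] * 99, [f"s{i}" for i in range(99)])
        narrow_seq = "".join(rng.choice(list(AMINO_ACIDS), size=60))
        narrow = _cluster("narrow", [narrow_seq] * 98, [f"s{i}" for i in range(98)])
        kept = mc.filter_families([wide, narrow], n_species=100)
        assert [f.id for f in kept] == ["wide"]

    def test_identical_clusters_are_mutually_ambiguous(self):
        seq = "MKWCLAVNDERT" * 5
        a = _cluster("a", [seq] * 3)
        b = _cluster("b", [seq] * 3)
        assert mc.filter_families([a, b], n_species=3) == []

    def test_disjoint_alphabet_clusters_both_kept(self):
        a = _cluster("polyK", ["K" * 40] * 3)
        b = _cluster("polyD", ["D" * 40] * 3)
        kept = mc.filter_families([a, b], n_species=3)
        assert sorted(f.id for f in kept) == ["polyD", "polyK"]

    def test_order_independence(self):
        rng = np.random.default_rng(11)
        clusters = [
            _cluster(f"c{i}", ["".join(rng.choice(list(AMINO_ACIDS), size=50))] * 3)
            for i in range(4)
        ]
        fwd = [f.id for f in mc.filter_families(clusters, n_species=3)]
        rev = [f.id for f in mc.filter_families(clusters[::-1], n_species=3)]
        assert fwd == rev

    def test_zero_species_rejected(self):
        with pytest.raises(ValueError):
            mc.filter_families([], n_species=0)


class TestCopyExpectations:
    def test_minimum_over_genomes(self):
        fams = mc.make_marker_families(1, rng_seed=1, mean_length=60)
        mc.set_copy_expectations(fams, {fams[0].id: [2, 3, 2, 5]})
        assert fams[0].expected_min_copies == 2
        assert not fams[0].single_copy

    def test_single_copy(self):
        fams = mc.make_marker_families(1, rng_seed=1, mean_length=60)
        mc.set_copy_expectations(fams, {fams[0].id: [1, 1, 1]})
        assert fams[0].expected_min_copies == 1
        assert fams[0].single_copy

    def test_floor_at_one_with_warning(self):
        fams = mc.make_marker_families(1, rng_seed=1, mean_length=60)
        with pytest.warns(UserWarning, match="flooring"):
            mc.set_copy_expectations(fams, {fams[0].id: [0, 2]})
        assert fams[0].expected_min_copies == 1

    def test_absent_family_warns(self):
        fams = mc.make_marker_families(1, rng_seed=1, mean_length=60)
        with pytest.warns(UserWarning, match="absent"):
            mc.set_copy_expectations(fams, {})
        assert fams[0].expected_min_copies == 1


class TestMarkerSetArchive:
    def test_round_trip(self, small_markerset, tmp_path):
        path = str(tmp_path / "set.tar")
        mc.save_markerset(small_markerset, path)
        loaded = mc.load_markerset(path)
        assert sorted(loaded.families) == sorted(small_markerset.families)
        for fid, fam in small_markerset.families.items():
            other = loaded.families[fid]
            assert other.score_threshold == fam.score_threshold  # bit-identical
            assert other.expected_min_copies == fam.expected_min_copies
            assert other.profile == fam.profile
        assert sorted(loaded.hde_elements) == sorted(small_markerset.hde_elements)
        assert loaded.params == small_markerset.params

    def test_missing_manifest_field_rejected(self, small_markerset, tmp_path):
        import json
        import tarfile

        path = str(tmp_path / "set.tar")
        mc.save_markerset(small_markerset, path)
        broken = str(tmp_path / "broken.tar")
        with tarfile.open(path) as src, tarfile.open(broken, "w") as dst:
            for member in src.getmembers():
                data = src.extractfile(member).read()
                if member.name == "manifest.json":
                    manifest = json.loads(data)
                    for meta in manifest["families"].values():
                        meta.pop("score_threshold")
                    data = json.dumps(manifest).encode()
                    member.size = len(data)
                dst.addfile(member, io.BytesIO(data))
        with pytest.raises(ValueError, match="corrupt marker set"):
            mc.load_markerset(broken)

    def test_empty_archive_rejected(self, tmp_path):
        import tarfile

        path = str(tmp_path / "empty.tar")
        with tarfile.open(path, "w"):
            pass
        with pytest.raises(ValueError, match="corrupt marker set"):
            mc.load_markerset(path)
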