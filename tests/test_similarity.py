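import math
import random

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from conftest import make_proteome, mutate, mutated_copy, random_protein
from mpass.errors import UserInputError
from mpass.seqio import Proteome, ProteinRecord
from mpass.similarity import (
    DistanceParams,
    ScoreIndex,
    ScoringScheme,
    align_score,
    best_hits,
    build_distance_matrix,
    distance_from_T,
    estimate_constants,
    normalized_avg_dissimilarity,
    poisson_corrected_rate,
    read_phylip,
    write_phylip,
)

# Sequences of disjoint, mutually-penalized composition: their local
# alignment score is 0, which falls below the reporting threshold.
NOHIT_A = "W" * 120
NOHIT_B = "P" * 120


class TestAlignScore:
    def test_self_hit_dominates_mutated_copy(self, scoring):
        rng = random.Random(1)
        x = random_protein(rng, 150)
        y = mutate(x, 0.5, rng)
        sx, _ = align_score(x, x, scoring)
        sy, _ = align_score(x, y, scoring)
        assert sx > sy

    def test_identity_score_is_blosum_diagonal_in_bits(self, scoring):
        seq = "ACDEFGHIKL"
        m = substitution_matrices.load("BLOSUM62")
        raw = sum(m[a, a] for a in seq)  # = 57
        expected_bits = (scoring.ka_lambda * raw - math.log(scoring.ka_k)) / math.log(2)
        bits, _ = align_score(seq, seq, scoring)
        assert bits == pytest.approx(expected_bits, abs=1e-12)

    def test_evalue_decreases_with_score(self, scoring):
        evs = [scoring.evalue(bits, 100, 10000) for bits in (10, 20, 40)]
        assert evs[0] > evs[1] > evs[2]

    def test_illegal_characters_rejected(self, scoring):
        with pytest.raises(UserInputError):
            align_score("MK1V", "MKLV", scoring)


class TestBestHits:
    def test_self_comparison_hits_self(self, scoring):
        p = make_proteome("p", n=5, seed=2)
        table = best_hits(p, p, scoring)
        for rec in p:
            hit = table.hits[rec.id]
            assert hit.target_id == rec.id
            assert hit.best_score == pytest.approx(hit.self_score)

    def test_no_hit_recorded(self, scoring):
        q = Proteome("q", [ProteinRecord("w", NOHIT_A)])
        t = Proteome("t", [ProteinRecord("p", NOHIT_B)])
        hit = best_hits(q, t, scoring).hits["w"]
        assert not hit.is_hit
        assert hit.similarity == 0.0

    def test_agrees_with_exhaustive_scoring(self, scoring):
        """Best hit per query equals the arg-max of all query x target scores."""
        rng = random.Random(3)
        q = make_proteome("q", n=5, length=80, seed=4)
        base = make_proteome("t", n=5, length=80, seed=4)
        t = mutated_copy(base, "t2", rate=0.3, seed=5)
        table = best_hits(q, t, scoring)
        for rec in q:
            raw = {tr.id: scoring.raw_score(rec.sequence, tr.sequence) for tr in t}
            best = max(sorted(raw), key=lambda k: raw[k])
            assert table.hits[rec.id].target_id == best

    def test_every_query_covered_once(self, scoring):
        q = make_proteome("q", n=7, seed=6)
        t = make_proteome("t", n=4, seed=7)
        table = best_hits(q, t, scoring)
        assert set(table.hits) == {r.id for r in q}

    def test_empty_proteome_rejected(self, scoring):
        p = make_proteome("p", n=2, seed=8)
        with pytest.raises(UserInputError):
            best_hits(p, Proteome("empty", []), scoring)

    def test_score_index_matches_best_hits(self, scoring):
        a = make_proteome("a", n=6, length=90, seed=9)
        b = mutated_copy(a, "b", rate=0.2, seed=10)
        index = ScoreIndex([a, b], scoring)
        ab, ba = index.pair_tables(a, b)
        ref_ab = best_hits(a, b, scoring)
        ref_ba = best_hits(b, a, scoring)
        for table, ref in ((ab, ref_ab), (ba, ref_ba)):
            assert set(table.hits) == set(ref.hits)
            for k in table.hits:
                assert table.hits[k].target_id == ref.hits[k].target_id
                assert table.hits[k].best_score == pytest.approx(ref.hits[k].best_score)


class TestNormalizedAvgDissimilarity:
    def test_identical_proteomes_give_zero(self, scoring):
        p = make_proteome("p", n=4, seed=11, coverage=2.0)
        q = Proteome("q", [ProteinRecord(r.id.replace("p_", "q_"), r.sequence, 7.0) for r in p])
        T = normalized_avg_dissimilarity(
            best_hits(p, q, scoring), best_hits(q, p, scoring),
            p.coverage_map(), q.coverage_map(),
        )
        assert T == pytest.approx(0.0, abs=1e-12)

    def test_fully_nonmatching_give_one(self, scoring):
        a = Proteome("a", [ProteinRecord("a1", NOHIT_A)])
        b = Proteome("b", [ProteinRecord("b1", NOHIT_B)])
        T = normalized_avg_dissimilarity(
            best_hits(a, b, scoring), best_hits(b, a, scoring),
            a.coverage_map(), b.coverage_map(),
        )
        assert T == 1.0

    def test_hand_weighted_mean(self, scoring):
        """Genes with d = (0, 1) and coverages (3, 1): T = (3*0 + 1*1)/4 = 0.25."""
        shared = random_protein(random.Random(12), 120)
        a = Proteome("a", [ProteinRecord("g1", shared, 3.0), ProteinRecord("g2", NOHIT_A, 1.0)])
        b = Proteome("b", [ProteinRecord("h1", shared, 3.0), ProteinRecord("h2", NOHIT_B, 1.0)])
        T = normalized_avg_dissimilarity(
            best_hits(a, b, scoring), best_hits(b, a, scoring),
            a.coverage_map(), b.coverage_map(),
        )
        assert T == pytest.approx(0.25, abs=1e-9)

    def test_coverage_scale_invariance(self, scoring):
        a = make_proteome("a", n=4, seed=13)
        b = mutated_copy(a, "b", rate=0.15, seed=14)
        cov_a = {r.id: 1.0 + i for i, r in enumerate(a)}
        cov_b = {r.id: 2.0 + i for i, r in enumerate(b)}
        ab, ba = best_hits(a, b, scoring), best_hits(b, a, scoring)
        t1 = normalized_avg_dissimilarity(ab, ba, cov_a, cov_b)
        t2 = normalized_avg_dissimilarity(
            ab, ba, {k: 10 * v for k, v in cov_a.items()}, {k: 0.5 * v for k, v in cov_b.items()}
        )
        assert t1 == pytest.approx(t2, abs=1e-12)

    def test_zero_total_coverage_rejected(self, scoring):
        a = make_proteome("a", n=2, seed=15, coverage=0.0)
        b = make_proteome("b", n=2, seed=16)
        with pytest.raises(UserInputError, match="coverage"):
            normalized_avg_dissimilarity(
                best_hits(a, b, scoring), best_hits(b, a, scoring),
                a.coverage_map(), b.coverage_map(),
            )


class TestDistanceTransform:
    def test_at_zero_equals_const1(self):
        assert distance_from_T(0.0) == pytest.approx(4.142, abs=0)

    def test_at_one(self):
        assert distance_from_T(1.0) == pytest.approx(4.142 * math.exp(2.824), rel=1e-12)

    def test_strictly_increasing(self):
        grid = np.linspace(0, 1, 101)
        vals = [distance_from_T(t) for t in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_degenerate_constants_flat(self):
        params = DistanceParams(const1=1.0, const2=0.0)
        assert distance_from_T(0.3, params) == 1.0

    def test_domain_checked(self):
        with pytest.raises(UserInputError):
            distance_from_T(1.5)
        with pytest.raises(UserInputError):
            DistanceParams(const1=-1.0)


class TestPoissonCorrectedRate:
    @pytest.mark.parametrize(
        "matched,aln,gapped,expected",
        [
            (100, 100, 0, 0.0),
            (50, 100, 0, 100 * math.log(2)),
            (90, 110, 10, -math.log(0.9) * 100),  # S1' = 0.1 -> ~10.54
        ],
    )
    def test_closed_forms(self, matched, aln, gapped, expected):
        assert poisson_corrected_rate(matched, aln, gapped) == pytest.approx(expected, rel=1e-12)

    def test_preconditions(self):
        with pytest.raises(UserInputError):
            poisson_corrected_rate(10, 10, 10)
        with pytest.raises(UserInputError):
            poisson_corrected_rate(0, 100, 0)
        with pytest.raises(UserInputError):
            poisson_corrected_rate(101, 100, 0)


class TestEstimateConstants:
    def test_noiseless_recovery(self):
        t = np.linspace(0.05, 1.0, 40)
        s = 4.142 * np.exp(2.824 * t)
        params, diag = estimate_constants(np.column_stack([t, s]))
        assert params.const1 == pytest.approx(4.142, rel=1e-6)
        assert params.const2 == pytest.approx(2.824, rel=1e-6)
        assert diag["n_used"] == 40

    def test_noisy_recovery_within_ten_percent(self):
        rng = np.random.default_rng(42)
        t = rng.uniform(0.02, 1.0, 90)
        s = 4.142 * np.exp(2.824 * t) * (1 + 0.05 * rng.standard_normal(90))
        params, _ = estimate_constants(np.column_stack([t, s]))
        assert params.const1 == pytest.approx(4.142, rel=0.10)
        assert params.const2 == pytest.approx(2.824, rel=0.10)

    def test_too_few_points(self):
        with pytest.raises(UserInputError):
            estimate_constants([(0.1, 5.0), (0.2, 6.0)])

    def test_nonpositive_excluded_with_warning(self, caplog):
        pts = [(0.1, 5.0), (0.2, 6.0), (0.3, 8.0), (0.4, -1.0)]
        import logging

        with caplog.at_level(logging.WARNING):
            params, diag = estimate_constants(pts)
        assert diag["n_used"] == 3
        assert "non-positive" in caplog.text

    def test_constant_T_unidentifiable(self):
        with pytest.raises(UserInputError):
            estimate_constants([(0.3, 5.0), (0.3, 6.0), (0.3, 7.0)])


class TestBuildDistanceMatrix:
    def test_identical_proteomes_all_const1(self, scoring):
        base = make_proteome("a", n=3, seed=20)
        ps = [base] + [
            Proteome(s, [ProteinRecord(r.id.replace("a_", s + "_"), r.sequence, r.coverage) for r in base])
            for s in ("b", "c")
        ]
        dm, log = build_distance_matrix(ps, scoring=scoring)
        off = dm.data[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 4.142)
        assert np.allclose(np.diag(dm.data), 0.0)
        assert len(log) == 3

    def test_symmetry_and_provenance(self, scoring):
        a = make_proteome("a", n=4, seed=21)
        ps = [a, mutated_copy(a, "b", 0.1, seed=22), mutated_copy(a, "c", 0.3, seed=23)]
        dm, log = build_distance_matrix(ps, scoring=scoring)
        assert np.array_equal(dm.data, dm.data.T)
        assert set(log.columns) == {"sample_a", "sample_b", "T", "similarity", "S"}
        # larger mutation load -> larger distance
        assert dm["a", "c"] > dm["a", "b"]

    def test_duplicate_labels_rejected(self, scoring):
        a = make_proteome("a", n=3, seed=24)
        with pytest.raises(UserInputError, match="duplicate"):
            build_distance_matrix([a, a, make_proteome("c", n=3, seed=25)], scoring=scoring)

    def test_needs_three(self, scoring):
        a = make_proteome("a", n=3, seed=26)
        with pytest.raises(UserInputError):
            build_distance_matrix([a, mutated_copy(a, "b", 0.1)], scoring=scoring)


def test_phylip_roundtrip(tmp_path, scoring):
    a = make_proteome("a", n=3, seed=30)
    ps = [a, mutated_copy(a, "b", 0.1, seed=31), mutated_copy(a, "c", 0.2, seed=32)]
    dm, _ = build_distance_matrix(ps, scoring=scoring)
    path = tmp_path / "dist.phy"
    write_phylip(dm, path)
    back = read_phylip(path)
    assert list(back.ids) == list(dm.ids)
    assert np.allclose(back.data, dm.data, atol=1e-6)
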