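"""Profile construction, column scoring, local alignment, calibration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fragvocab.data import AA_ALPHABET, AA_INDEX, BACKGROUND_FREQS
from fragvocab.profiles import (
    NullModel,
    Profile,
    align_profiles_local,
    build_profile,
    calibrate_null,
    column_score,
    match_significance,
    probability_from_pvalue,
    score_fixed_alignment,
    score_matrix,
)
from fragvocab.synthetic import synthesize_msa


def dirichlet_profile(rng, L):
    cols = rng.dirichlet(np.ones(20), size=L)
    return Profile(columns=cols, neff=np.ones(L), background=BACKGROUND_FREQS)


class TestBuildProfile:
    def test_single_sequence_no_pseudocounts_is_one_hot(self):
        p = build_profile(["AAA"], pseudocount_weight=0.0)
        expected = np.zeros(20)
        expected[AA_INDEX["A"]] = 1.0
        for col in p.columns:
            np.testing.assert_allclose(col, expected)

    def test_full_pseudocount_uniform_background_gives_uniform_columns(self):
        uniform = np.full(20, 0.05)
        p = build_profile(["ACD"], pseudocount_weight=1.0, background=uniform)
        np.testing.assert_allclose(p.columns, np.full((3, 20), 0.05))

    def test_columns_normalized_and_positive(self, bench_records):
        p = build_profile(bench_records[0].msa)
        np.testing.assert_allclose(p.columns.sum(axis=1), 1.0, atol=1e-9)
        assert (p.columns > 0).all()
        assert len(p) == len(bench_records[0])

    def test_majority_residue_dominates_divergent_msa(self, rng):
        from fragvocab.synthetic import random_sequence

        seq = random_sequence(60, rng)
        msa = synthesize_msa(seq, depth=50, mutation_rate=0.3, rng=rng)
        p = build_profile(msa)
        hits = sum(
            1 for j, aa in enumerate(seq) if np.argmax(p.columns[j]) == AA_INDEX[aa]
        )
        assert hits >= 0.9 * len(seq)

    def test_empty_msa_rejected(self):
        with pytest.raises(ValueError):
            build_profile([])

    def test_alphabet_violation_names_symbol(self):
        with pytest.raises(ValueError, match="'Z'"):
            build_profile(["AZA"])


class TestColumnScore:
    def test_matched_one_hot_closed_form(self):
        p = np.zeros(20)
        p[0] = 1.0  # alanine
        f = np.full(20, 0.05)
        assert column_score(p, p, f) == pytest.approx(np.log2(1 / 0.05), abs=1e-12)

    def test_uniform_columns_uniform_background_zero_bits(self):
        u = np.full(20, 0.05)
        assert column_score(u, u, u) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_summation(self, rng):
        f = BACKGROUND_FREQS
        for _ in range(20):
            p = rng.dirichlet(np.ones(20))
            q = rng.dirichlet(np.ones(20))
            brute = np.log2(sum(p[a] * q[a] / f[a] for a in range(20)))
            assert column_score(p, q, f) == pytest.approx(brute, abs=1e-12)

    def test_symmetry(self, rng):
        f = BACKGROUND_FREQS
        p = rng.dirichlet(np.ones(20))
        q = rng.dirichlet(np.ones(20))
        assert column_score(p, q, f) == pytest.approx(column_score(q, p, f), abs=1e-12)


class TestLocalAlignment:
    def test_self_alignment_is_identity_with_self_score(self, bench_profiles):
        p = next(iter(bench_profiles.values()))
        aln, raw = align_profiles_local(p, p)
        assert aln == [(i, i) for i in range(len(p))]
        diag = sum(column_score(p.columns[i], p.columns[i], p.background) for i in range(len(p)))
        assert raw == pytest.approx(diag, abs=1e-9)

    def test_symmetric_raw_score(self, bench_profiles):
        profs = list(bench_profiles.values())
        _, ab = align_profiles_local(profs[0], profs[1])
        _, ba = align_profiles_local(profs[1], profs[0])
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_planted_block_recovered(self, rng):
        # two profiles sharing an identical 25-column block amid noise
        a = dirichlet_profile(rng, 80)
        b = dirichlet_profile(rng, 80)
        block = rng.dirichlet(np.full(20, 0.2), size=25)
        a.columns[30:55] = block
        b.columns[10:35] = block
        aln, _ = align_profiles_local(a, b)
        inside = [(i, j) for i, j in aln if 30 <= i < 55 and 10 <= j < 35 and j - i == -20]
        assert len(inside) >= 20

    def test_self_match_dominates_equal_length_profiles(self, rng):
        p = dirichlet_profile(rng, 40)
        _, self_raw = align_profiles_local(p, p)
        for _ in range(5):
            q = dirichlet_profile(rng, 40)
            _, cross = align_profiles_local(p, q)
            assert self_raw >= cross

    def test_unrelated_profiles_score_within_null(self, bench_null, rng):
        from fragvocab.synthetic import random_sequence

        a = build_profile(synthesize_msa(random_sequence(100, rng), 20, 0.3, rng))
        b = build_profile(synthesize_msa(random_sequence(100, rng), 20, 0.3, rng))
        _, raw = align_profiles_local(a, b)
        # below the null's 99th percentile
        p99 = bench_null.location(100, 100) - np.log(-np.log(0.99)) / bench_null.lam
        assert raw < p99


class TestCalibration:
    def test_determinism(self, bench_profiles):
        profs = list(bench_profiles.values())
        n1 = calibrate_null(profs, n_pairs=500, seed=7)
        n2 = calibrate_null(profs, n_pairs=500, seed=7)
        assert (n1.mu, n1.lam, n1.length_coef) == (n2.mu, n2.lam, n2.length_coef)

    def test_constant_scores_rejected(self):
        # identical single-column uniform profiles give degenerate scores
        u = Profile(np.full((1, 20), 0.05), np.ones(1), np.full(20, 0.05))
        with pytest.raises(ValueError, match="degenerate|samples"):
            calibrate_null([u] * 12, n_pairs=500, seed=0)

    def test_too_few_profiles_rejected(self, bench_profiles):
        profs = list(bench_profiles.values())[:5]
        with pytest.raises(ValueError):
            calibrate_null(profs, n_pairs=500, seed=0)

    def test_gumbel_parameter_recovery(self):
        # scores from a known Gumbel: the fit wiring recovers the parameters
        from scipy import stats

        rng = np.random.default_rng(42)
        draws = stats.gumbel_r.rvs(loc=5.0, scale=1 / 0.7, size=2000, random_state=rng)
        mu, beta = stats.gumbel_r.fit(draws)
        null = NullModel(mu=float(mu), lam=float(1 / beta), n_samples=2000, seed=42)
        assert null.mu == pytest.approx(5.0, abs=0.2)
        assert null.lam == pytest.approx(0.7, abs=0.1)


class TestSignificance:
    def test_pvalue_at_location_is_gumbel_cdf_complement(self):
        null = NullModel(mu=10.0, lam=0.5, n_samples=1000, seed=0)
        # 1 - exp(-exp(0)) = 0.6321...
        p, _ = match_significance(10.0, null)
        assert p == pytest.approx(1 - np.exp(-1), abs=1e-9)

    def test_anchor_maps_to_seventy(self):
        assert probability_from_pvalue(5e-5) == pytest.approx(70.0, abs=1e-9)

    def test_probability_monotone_in_score(self):
        null = NullModel(mu=8.0, lam=0.6, n_samples=1000, seed=0)
        raws = np.linspace(0, 40, 50)
        results = [match_significance(r, null) for r in raws]
        ps = [r[0] for r in results]
        probs = [r[1] for r in results]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))
        assert all(q1 <= q2 for q1, q2 in zip(probs, probs[1:]))

    @given(st.floats(min_value=1e-12, max_value=1.0))
    def test_probability_bounded(self, p):
        assert 0.0 <= probability_from_pvalue(p) <= 100.0


class TestFixedAlignmentScore:
    def test_identity_alignment_self_score_positive(self, bench_profiles):
        p = next(iter(bench_profiles.values()))
        aln = [(i, i) for i in range(len(p))]
        assert score_fixed_alignment(p, p, aln) > 0

    def test_single_pair_equals_column_score(self, rng):
        a = dirichlet_profile(rng, 10)
        b = dirichlet_profile(rng, 10)
        s = score_fixed_alignment(a, b, [(3, 7)])
        assert s == pytest.approx(
            column_score(a.columns[3], b.columns[7], b.background), abs=1e-12
        )

    def test_equals_mean_of_per_pair_scores(self, rng):
        a = dirichlet_profile(rng, 30)
        b = dirichlet_profile(rng, 30)
        aln = [(i, (i * 3) % 30) for i in range(0, 30, 2)]
        manual = np.mean(
            [column_score(a.columns[i], b.columns[j], b.background) for i, j in aln]
        )
        assert score_fixed_alignment(a, b, aln) == pytest.approx(manual, abs=1e-12)

    def test_empty_alignment_rejected(self, rng):
        a = dirichlet_profile(rng, 5)
        with pytest.raises(ValueError):
            score_fixed_alignment(a, a, [])
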