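"""Superposition, TM-score, structural alignment, SSE assignment."""

import numpy as np
import pytest

from fragvocab.data import SegmentInterval
from fragvocab.structure import (
    assign_sse,
    count_sse_elements,
    kabsch_superpose,
    struct_align,
    tm_d0,
    tm_score,
)
from fragvocab.synthetic import (
    PlantedFragmentSpec,
    build_domain,
    make_analog_decoy,
    make_fragment_template,
    make_ideal_sse,
    plant_fragment_instance,
)


def random_rigid(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return R, rng.normal(scale=5.0, size=3)


class TestKabsch:
    def test_identity_when_equal(self, rng):
        X = rng.normal(size=(10, 3))
        sup = kabsch_superpose(X, X)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_recovers_constructed_rotation(self, rng):
        X = rng.normal(size=(12, 3))
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        Y = X @ Rz.T + np.array([1.0, 2.0, 3.0])
        sup = kabsch_superpose(X, Y)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.apply(Y), X, atol=1e-9)

    def test_rotation_proper_orthonormal(self, rng):
        X = rng.normal(size=(8, 3))
        Y = rng.normal(size=(8, 3))
        sup = kabsch_superpose(X, Y)
        np.testing.assert_allclose(
            sup.rotation @ sup.rotation.T, np.eye(3), atol=1e-9
        )
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            kabsch_superpose(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            kabsch_superpose(line + 0.0, line * 2.0)


class TestTMScore:
    def test_rigid_copy_scores_one(self, rng):
        X = np.cumsum(rng.normal(scale=2, size=(20, 3)), axis=0)
        R, t = random_rigid(rng)
        Y = X @ R.T + t
        pairs = [(i, i) for i in range(20)]
        assert tm_score(X, Y, pairs, 20) == pytest.approx(1.0, abs=1e-9)

    def test_all_pairs_at_d0_gives_half(self):
        # a rotation about the z axis moves every point on a z-axis-centred
        # ring by the same chord length; pick the angle so that chord = d0
        n = 30
        d0 = tm_d0(n)
        radius = 10.0
        ang = np.linspace(0, 4 * np.pi, n)
        X = np.column_stack(
            [radius * np.cos(ang), radius * np.sin(ang), np.linspace(0, 20, n)]
        )
        theta = 2 * np.arcsin(d0 / (2 * radius))
        Rz = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        Y = X @ Rz.T
        pairs = [(i, i) for i in range(n)]
        d = np.sqrt(np.sum((Y - X) ** 2, axis=1))
        np.testing.assert_allclose(d, d0, atol=1e-9)
        # the fixed (unsuperposed) score would be exactly 0.5; maximization
        # over superpositions can only raise it
        assert tm_score(X, Y, pairs, n) >= 0.5 - 1e-9

    def test_invariant_under_rigid_transforms(self, rng):
        X = np.cumsum(rng.normal(scale=2, size=(15, 3)), axis=0)
        Y = X + rng.normal(scale=1.0, size=X.shape)
        pairs = [(i, i) for i in range(15)]
        base = tm_score(X, Y, pairs, 15)
        for _ in range(3):
            R, t = random_rigid(rng)
            assert tm_score(X @ R.T + t, Y, pairs, 15) == pytest.approx(base, abs=1e-9)
            assert tm_score(X, Y @ R.T + t, pairs, 15) == pytest.approx(base, abs=1e-9)

    def test_d0_clamped_for_short_lengths(self):
        assert tm_d0(10) == 0.5
        assert tm_d0(21) == 0.5
        assert tm_d0(100) > 2.0

    def test_empty_pairs_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        with pytest.raises(ValueError):
            tm_score(X, X, [], 5)


class TestStructAlign:
    def test_self_alignment_identity(self, rng):
        X, _, _ = build_domain("H-E", rng)
        sa = struct_align(X, X)
        assert sa.tm_query == pytest.approx(1.0, abs=1e-6)
        assert sa.pairs == [(i, i) for i in range(len(X))]

    def test_planted_fragment_found_across_scaffolds(self):
        # a mixed alpha/beta fragment planted into an all-helix and an
        # all-strand scaffold: the fragment is the only shared substructure
        spec = PlantedFragmentSpec(
            "fx", 24, [0, 1], topology=[("E", 8), ("C", 4), ("H", 12)]
        )
        tc, ts, mut = make_fragment_template(spec, np.random.default_rng(3))
        r1, r2 = np.random.default_rng(10), np.random.default_rng(20)
        i1 = plant_fragment_instance(tc, ts, 0.4, 0.5, r1, mut)
        i2 = plant_fragment_instance(tc, ts, 0.4, 0.5, r2, mut)
        c1, _, iv1 = build_domain("H-H", r1, insert=i1)
        c2, _, iv2 = build_domain("E-E", r2, insert=i2)
        sa = struct_align(c1, c2)
        inside = sum(
            1
            for qi, ti in sa.pairs
            if iv1[0] - 1 <= qi <= iv1[1] - 1 and iv2[0] - 1 <= ti <= iv2[1] - 1
        )
        assert inside >= 0.8 * 24

    def test_decoy_backbone_matches_template(self):
        spec = PlantedFragmentSpec(
            "fy", 24, [0, 1], topology=[("H", 10), ("C", 4), ("H", 10)]
        )
        tc, ts, _ = make_fragment_template(spec, np.random.default_rng(8))
        dc, _ = make_analog_decoy(tc, ts, np.random.default_rng(9))
        sa = struct_align(tc, dc)
        assert sa.tm_query >= 0.8

    def test_unrelated_topologies_stay_below_fold_similarity(self):
        worst = 0.0
        for s in range(5):
            c1, _, _ = build_domain("H-H-H", np.random.default_rng(1000 + s))
            c2, _, _ = build_domain("E-E-E-E", np.random.default_rng(2000 + s))
            sa = struct_align(c1, c2)
            worst = max(worst, min(sa.tm_query, sa.tm_target))
        assert worst < 0.5

    def test_final_tm_never_below_seed_alignments(self, rng):
        X, _, _ = build_domain("H-E", rng)
        Y, _, _ = build_domain("E-H", rng)
        sa = struct_align(X, Y)
        k = min(len(X), len(Y))
        seed = [(t, t) for t in range(k)]
        assert tm_score(X, Y, sa.pairs, k) >= tm_score(X, Y, seed, k) - 1e-9

    def test_pairing_roughly_symmetric(self, bench_by_id, bench_truth):
        homs = [p for p in bench_truth.instances if p.kind == "homolog"]
        a, b = homs[0], homs[1]
        X = bench_by_id[a.interval.domain_id].coords
        Y = bench_by_id[b.interval.domain_id].coords
        fwd = set(struct_align(X, Y).pairs)
        rev = {(q, t) for t, q in struct_align(Y, X).pairs}
        agree = len(fwd & rev) / max(len(fwd), len(rev))
        assert agree >= 0.9

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError):
            struct_align(rng.normal(size=(4, 3)), rng.normal(size=(20, 3)))


class TestAssignSSE:
    def test_ideal_helix(self):
        sse = assign_sse(make_ideal_sse("H", 12))
        assert sse.count("H") >= 8
        assert set(sse) <= {"H", "C"}

    def test_ideal_strand(self):
        sse = assign_sse(make_ideal_sse("E", 8))
        assert sse.count("E") >= 6
        assert set(sse) <= {"E", "C"}

    def test_short_fragment_is_all_coil(self):
        assert assign_sse(make_ideal_sse("H", 4)) == "CCCC"

    def test_two_sse_domain_yields_two_runs(self, rng):
        coords, _, _ = build_domain("H-H", rng)
        sse = assign_sse(coords)
        runs = [r for r in sse.replace("E", "H").split("C") if len(r) >= 3]
        assert len(runs) >= 2


class TestCountSSEElements:
    @pytest.mark.parametrize(
        "sse,start,end,expected",
        [
            ("CCHHHHHCCEEEECC", 1, 15, 2),
            ("HHHHHH", 1, 6, 1),
            ("CCCC", 1, 4, 0),
            ("CCHHHHHCCEEEECC", 1, 5, 1),  # only the helix run intersects
            ("HHCHH", 1, 5, 0),  # runs below minimum length
        ],
    )
    def test_run_counting(self, sse, start, end, expected):
        assert count_sse_elements(sse, SegmentInterval("d", start, end)) == expected

    def test_segment_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            count_sse_elements("HHH", SegmentInterval("d", 1, 4))
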