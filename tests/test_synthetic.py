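"""The synthetic generator: geometry, divergence model, ground truth."""

import numpy as np
import pytest

from fragvocab.data import AA_ALPHABET
from fragvocab.ligands import detect_contacts
from fragvocab.structure import assign_sse
from fragvocab.synthetic import (
    CHAIN_STEP,
    PlantedFragmentSpec,
    SyntheticConfig,
    add_coordinate_noise,
    build_domain,
    generate_library,
    make_analog_decoy,
    make_fragment_template,
    make_ideal_sse,
    make_motif_library,
    place_ligand,
    plant_fragment_instance,
    random_sequence,
    synthesize_msa,
)


def seq_identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


class TestIdealSSE:
    def test_helix_consecutive_distances(self):
        h = make_ideal_sse("H", 10)
        d = np.linalg.norm(np.diff(h, axis=0), axis=1)
        assert ((3.7 <= d) & (d <= 3.9)).all()

    def test_helix_returns_after_five_turns(self):
        # 18 * 100 degrees = 5 full turns: same azimuth directly above start
        h = make_ideal_sse("H", 19)
        np.testing.assert_allclose(h[18][:2], h[0][:2], atol=1e-9)

    def test_strand_extended(self):
        e = make_ideal_sse("E", 8)
        d = np.linalg.norm(np.diff(e, axis=0), axis=1)
        assert ((3.7 <= d) & (d <= 3.9)).all()
        assert np.linalg.norm(e[-1] - e[0]) > 0.9 * 7 * 3.4

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            make_ideal_sse("H", 2)


class TestBuildDomain:
    def test_same_seed_identical(self):
        c1, s1, _ = build_domain("H-E-H", np.random.default_rng(3))
        c2, s2, _ = build_domain("H-E-H", np.random.default_rng(3))
        np.testing.assert_array_equal(c1, c2)
        assert s1 == s2

    def test_no_clashes_over_seeded_builds(self):
        for s in range(30):
            c, _, _ = build_domain("H-E-E-H", np.random.default_rng(s))
            d = np.sqrt(np.sum((c[:, None] - c[None, :]) ** 2, axis=2))
            n = len(c)
            np.fill_diagonal(d, np.inf)
            d[np.arange(n - 1), np.arange(1, n)] = np.inf
            d[np.arange(1, n), np.arange(n - 1)] = np.inf
            assert d.min() >= 3.0

    def test_sequence_matches_length(self, rng):
        c, s, _ = build_domain("E-H", rng)
        assert len(c) == len(s)
        assert set(s) <= set(AA_ALPHABET)


class TestPlanting:
    def _template(self, seed=3):
        spec = PlantedFragmentSpec(
            "t", 25, [0, 1], topology=[("H", 10), ("C", 5), ("H", 10)]
        )
        return spec, make_fragment_template(spec, np.random.default_rng(seed))

    def test_identity_one_no_noise_is_verbatim(self):
        _, (tc, ts, _) = self._template()
        c, s = plant_fragment_instance(tc, ts, 1.0, 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(c, tc)
        assert s == ts

    def test_mutation_count_hits_target(self):
        _, (tc, ts, _) = self._template()
        for seed in range(10):
            _, s = plant_fragment_instance(
                tc, ts, 0.4, 0.0, np.random.default_rng(seed)
            )
            n_diff = sum(a != b for a, b in zip(s, ts))
            assert abs(n_diff - 15) <= 1  # 60% of 25 positions

    def test_noise_calibrated_to_rmsd(self):
        _, (tc, ts, _) = self._template()
        rmsds = []
        for seed in range(200):
            c = add_coordinate_noise(tc, 0.5, np.random.default_rng(seed))
            rmsds.append(np.sqrt(np.mean(np.sum((c - tc) ** 2, axis=1))))
        assert 0.4 <= np.mean(rmsds) <= 0.6

    def test_conserved_core_shared_between_instances(self):
        spec, (tc, ts, mut) = self._template()
        a = plant_fragment_instance(tc, ts, 0.4, 0.0, np.random.default_rng(1), mut)
        b = plant_fragment_instance(tc, ts, 0.4, 0.0, np.random.default_rng(2), mut)
        conserved = sorted(set(range(25)) - set(mut.tolist()))
        assert all(a[1][p] == ts[p] == b[1][p] for p in conserved)


class TestDecoys:
    def test_low_sequence_identity(self):
        spec = PlantedFragmentSpec(
            "t", 24, [0, 1], topology=[("H", 10), ("C", 4), ("H", 10)]
        )
        tc, ts, _ = make_fragment_template(spec, np.random.default_rng(3))
        ids = [
            seq_identity(make_analog_decoy(tc, ts, np.random.default_rng(s))[1], ts)
            for s in range(20)
        ]
        assert np.mean(ids) < 0.15

    def test_backbone_close_to_template(self):
        spec = PlantedFragmentSpec(
            "t", 24, [0, 1], topology=[("H", 10), ("C", 4), ("H", 10)]
        )
        tc, ts, _ = make_fragment_template(spec, np.random.default_rng(3))
        dc, _ = make_analog_decoy(tc, ts, np.random.default_rng(4))
        rmsd = np.sqrt(np.mean(np.sum((dc - tc) ** 2, axis=1)))
        assert rmsd <= 1.0


class TestSynthesizeMSA:
    def test_zero_rate_identical_rows(self, rng):
        seq = random_sequence(30, rng)
        msa = synthesize_msa(seq, 10, 0.0, rng)
        assert all(row == seq for row in msa)

    def test_divergence_matches_rate(self, rng):
        seq = random_sequence(100, rng)
        msa = synthesize_msa(seq, 50, 0.3, rng)
        ids = [seq_identity(row, seq) for row in msa[1:]]
        assert 0.65 <= np.mean(ids) <= 0.75

    def test_same_seed_identical(self):
        seq = random_sequence(40, np.random.default_rng(1))
        m1 = synthesize_msa(seq, 20, 0.3, np.random.default_rng(5))
        m2 = synthesize_msa(seq, 20, 0.3, np.random.default_rng(5))
        assert m1 == m2

    def test_row_one_is_input(self, rng):
        seq = random_sequence(25, rng)
        assert synthesize_msa(seq, 5, 0.5, rng)[0] == seq


@pytest.fixture(scope="module")
def host():
    records, truth = generate_library(SyntheticConfig(seed=2))
    inst = truth.homolog_instances("frag1")[0]
    rec = next(r for r in records if r.domain_id == inst.interval.domain_id)
    return rec, inst.interval


class TestPlaceLigand:

    def test_exact_three_contacts(self, host):
        rec, iv = host
        lig = place_ligand(rec, iv, "metal", 3, 2.9, np.random.default_rng(0))
        assert detect_contacts(rec.fragment_atoms(iv), lig) == (True, 3)

    def test_two_contacts_below_rule(self, host):
        rec, iv = host
        lig = place_ligand(rec, iv, "metal", 2, 2.9, np.random.default_rng(0))
        assert detect_contacts(rec.fragment_atoms(iv), lig) == (False, 2)

    def test_distant_placement_no_contacts(self, host):
        rec, iv = host
        lig = place_ligand(rec, iv, "metal", 0, 5.0, np.random.default_rng(0))
        assert detect_contacts(rec.fragment_atoms(iv), lig) == (False, 0)


class TestGenerateLibrary:
    def test_counts_and_labels(self, bench_records, bench_truth):
        assert len(bench_records) == 20
        folds = {}
        for r in bench_records:
            folds.setdefault(r.label.fold_id, set()).add(r.domain_id)
        assert len(folds) == 5
        assert all(len(v) == 4 for v in folds.values())
        # each planted fragment spans at least 2 fold ids
        for fid in bench_truth.fragment_ids():
            fold_ids = {
                next(r for r in bench_records if r.domain_id == pi.interval.domain_id).label.fold_id
                for pi in bench_truth.homolog_instances(fid)
            }
            assert len(fold_ids) >= 2

    def test_instances_within_bounds(self, bench_records, bench_truth):
        by_id = {r.domain_id: r for r in bench_records}
        for pi in bench_truth.instances:
            assert 1 <= pi.interval.start <= pi.interval.end <= len(
                by_id[pi.interval.domain_id]
            )

    def test_same_seed_reproduces(self):
        r1, t1 = generate_library(SyntheticConfig(seed=9))
        r2, t2 = generate_library(SyntheticConfig(seed=9))
        for a, b in zip(r1, r2):
            assert a.sequence == b.sequence
            np.testing.assert_array_equal(a.coords, b.coords)
        assert [p.interval for p in t1.instances] == [p.interval for p in t2.instances]

    def test_planted_instance_recoverable_from_template(self, bench_records, bench_truth):
        # generator self-calibration: struct_align recovers every planted
        # instance from its template with TM >= 0.7 at 0.5 A noise
        from fragvocab.structure import struct_align

        by_id = {r.domain_id: r for r in bench_records}
        for pi in bench_truth.homolog_instances():
            tc = bench_truth.templates[pi.fragment_id][0]
            seg = by_id[pi.interval.domain_id].segment_coords(pi.interval)
            sa = struct_align(tc, seg)
            assert sa.tm_query >= 0.7


class TestMotifLibraryGeneration:
    def test_schema_and_ordering(self):
        lib = make_motif_library(n_clusters=8, seed=7)
        freqs = [c["frequency"] for c in lib]
        assert freqs == sorted(freqs, reverse=True)
        for c in lib:
            for m in c["members"]:
                assert len(m["sse"]) == len(m["coords"])
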