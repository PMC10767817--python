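"""Kabsch superposition, CDR RMSD and structure search."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import make_domain, oracle_cdr_rmsd
from pairedab.struct_search import (
    AntibodyModel,
    ScaffoldModelBackend,
    build_models,
    cdr_rmsd,
    cdr_sequence_identity,
    kabsch_superpose,
    read_model_pdb,
    search_by_structure,
    write_model_pdb,
)
from pairedab.synth_fixtures import generate_toy_models

TUPLE_A = (8, 8, 10, 6, 3, 9)
TUPLE_B = (8, 8, 12, 6, 3, 9)


def rigid_copy(model, rng, name="copy"):
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-30, 30, size=3)
    return AntibodyModel(
        entry_id=name,
        ca_coords={k: R @ v + t for k, v in model.ca_coords.items()},
        residues=dict(model.residues),
    )


@pytest.fixture(scope="module")
def toy_set():
    return generate_toy_models(24, [TUPLE_A, TUPLE_B], perturbation_scale=0.5, seed=5)


class TestKabsch:
    def test_self_superposition_is_identity(self, rng):
        pts = rng.normal(size=(10, 3))
        R, t, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(R, np.eye(3), atol=1e-9)
        assert np.allclose(t, 0.0, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_rigid_copy_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(15, 3)) * 5
        R_true = Rotation.random(random_state=rng).as_matrix()
        t_true = rng.uniform(-10, 10, size=3)
        moved = pts @ R_true.T + t_true
        R, t, rmsd = kabsch_superpose(pts, moved)
        assert rmsd < 1e-6
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(R, R_true, atol=1e-8)

    def test_rotation_always_proper_even_for_reflected_clouds(self, rng):
        pts = rng.normal(size=(12, 3))
        reflected = pts * np.array([-1.0, 1.0, 1.0])
        R, _, _ = kabsch_superpose(pts, reflected)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_displaced_point_matches_independent_fit(self, rng):
        # four points; one displaced after the others fit exactly -> compare
        # the minimised RMSD with scipy's independent least-squares rotation
        base = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]], dtype=float)
        target = base.copy()
        target[3] += np.array([0.0, 0.0, 2.0])
        _, _, rmsd = kabsch_superpose(base, target)
        rot, rssd = Rotation.align_vectors(
            target - target.mean(axis=0), base - base.mean(axis=0)
        )
        assert rmsd == pytest.approx(rssd / np.sqrt(len(base)), abs=1e-9)

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[float(i), 0.0, 0.0] for i in range(5)])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)


class TestCdrRmsd:
    def test_self_is_zero(self, toy_set):
        assert cdr_rmsd(toy_set.models[0], toy_set.models[0]) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_copy_is_zero(self, toy_set, rng):
        model = toy_set.models[0]
        assert cdr_rmsd(model, rigid_copy(model, rng)) < 1e-6

    def test_uniform_cdr_displacement_gives_exactly_d(self, toy_set):
        model = toy_set.models[0]
        d = 1.7
        shifted = AntibodyModel(
            entry_id="shifted",
            ca_coords={
                k: v + (np.array([0.0, 0.0, d]) if k in model.cdr_keys() else 0.0)
                for k, v in model.ca_coords.items()
            },
        )
        assert cdr_rmsd(model, shifted) == pytest.approx(d, abs=1e-9)

    def test_invariant_under_rigid_motion_of_either_model(self, toy_set, rng):
        a, b = toy_set.models[0], toy_set.models[2]  # same length tuple
        baseline = cdr_rmsd(a, b)
        assert cdr_rmsd(rigid_copy(a, rng), b) == pytest.approx(baseline, abs=1e-6)
        assert cdr_rmsd(a, rigid_copy(b, rng)) == pytest.approx(baseline, abs=1e-6)

    def test_symmetric(self, toy_set):
        a, b = toy_set.models[0], toy_set.models[2]
        assert cdr_rmsd(a, b) == pytest.approx(cdr_rmsd(b, a), abs=1e-6)

    def test_mismatched_length_tuple_is_contract_violation(self, toy_set):
        a, b = toy_set.models[0], toy_set.models[1]  # tuples A and B
        with pytest.raises(ValueError, match="length tuples differ"):
            cdr_rmsd(a, b)

    def test_agrees_with_scipy_oracle(self, toy_set):
        a, b = toy_set.models[0], toy_set.models[2]
        assert cdr_rmsd(a, b) == pytest.approx(oracle_cdr_rmsd(a, b), abs=1e-8)

    def test_true_perturbation_rmsd_recovered(self, toy_set):
        # framework is noise-free, so superposition must recover exactly the
        # RMS of the planted CDR displacements
        for model, true_rmsd in zip(toy_set.models, toy_set.true_rmsds):
            tup = model.cdr_length_tuple
            parent = toy_set.parents[tup]
            assert cdr_rmsd(parent, model) == pytest.approx(true_rmsd, abs=1e-8)


class TestSearch:
    def test_identical_model_rank_one_rmsd_zero(self, toy_set, rng):
        query = rigid_copy(toy_set.models[4], rng, "query")
        hits = search_by_structure(toy_set.models, query, rmsd_threshold=1.25)
        assert hits and hits[0].entry_id == toy_set.models[4].entry_id
        assert hits[0].cdr_rmsd < 1e-6

    def test_different_cdr_length_never_returned(self, toy_set):
        query = toy_set.models[0]  # tuple A
        hits = search_by_structure(toy_set.models, query, rmsd_threshold=1e9)
        tuple_b_ids = {m.entry_id for m in toy_set.models
                       if m.cdr_length_tuple == TUPLE_B}
        assert tuple_b_ids.isdisjoint({h.entry_id for h in hits})

    def test_membership_and_order_match_bruteforce(self, toy_set):
        query = toy_set.models[6]
        hits = search_by_structure(toy_set.models, query, rmsd_threshold=1.5)
        oracle = []
        for m in toy_set.models:
            if m.cdr_length_tuple != query.cdr_length_tuple:
                continue
            r = oracle_cdr_rmsd(query, m)
            if r < 1.5:
                oracle.append((r, m.entry_id))
        oracle.sort(key=lambda x: (x[0], x[1]))
        assert [h.entry_id for h in hits] == [e for _, e in oracle]
        for h, (r, _) in zip(hits, oracle):
            assert h.cdr_rmsd == pytest.approx(r, abs=1e-8)

    def test_identity_filter_is_strict(self, toy_set):
        query = toy_set.models[0]
        loose = search_by_structure(toy_set.models, query, rmsd_threshold=1e9)
        tight = search_by_structure(toy_set.models, query, rmsd_threshold=1e9,
                                    identity_filter=0.8)
        assert {h.entry_id for h in tight} <= {h.entry_id for h in loose}
        for h in tight:
            assert h.cdr_identity is not None and h.cdr_identity > 0.8

    def test_failed_models_skipped(self, toy_set):
        failed = AntibodyModel(entry_id="broken", status="FAILED")
        hits = search_by_structure([failed] + toy_set.models, toy_set.models[0],
                                   rmsd_threshold=1e9)
        assert "broken" not in {h.entry_id for h in hits}


class TestModelBackend:
    def test_duplicate_sequence_pairs_modelled_once(self, small_db):
        calls = []

        class Counting(ScaffoldModelBackend):
            def build(self, entry_id, heavy, light):
                calls.append(entry_id)
                return super().build(entry_id, heavy, light)

        from pairedab.pairing import entry_from_row, entry_to_row

        dup = entry_from_row(entry_to_row(small_db.entries[0]))
        dup.pair_id = "zz-dup"
        entries = list(small_db.entries) + [dup]
        models = build_models(entries, Counting())
        assert len(models) == len(entries)
        assert len(calls) == len({e.sequence_pair for e in entries})
        assert models["zz-dup"].entry_id == "zz-dup"

    def test_nonstandard_residue_yields_failed_status(self):
        backend = ScaffoldModelBackend()
        heavy = make_domain("H", mutations={70: "X"})
        light = make_domain("L")
        from pairedab.pairing import PairedEntry

        entry = PairedEntry(pair_id="px", heavy=heavy, light=light,
                            pairing_method="same_entry", source_id="S")
        log = []
        models = build_models([entry], backend, log=log)
        assert models["px"].status == "FAILED"
        assert "non-standard" in models["px"].diagnostic
        assert log

    def test_identical_cdr_sequences_superpose_exactly(self, small_db):
        backend = ScaffoldModelBackend()
        e = small_db.entries[0]
        m1 = backend.build("a", e.heavy, e.light)
        m2 = backend.build("b", e.heavy, e.light)
        assert cdr_rmsd(m1, m2) == pytest.approx(0.0, abs=1e-9)
        assert cdr_sequence_identity(m1, m2) == 1.0


class TestPdbIO:
    def test_roundtrip_preserves_geometry_and_residues(self, tmp_path, toy_set):
        model = toy_set.models[0]
        path = tmp_path / "model.pdb"
        write_model_pdb(model, path)
        loaded = read_model_pdb(path, entry_id=model.entry_id)
        assert set(loaded.ca_coords) == set(model.ca_coords)
        for k in model.ca_coords:
            assert np.allclose(loaded.ca_coords[k], model.ca_coords[k], atol=1e-3)
        assert loaded.residues == model.residues
        # PDB coordinate precision is 0.001 A; RMSD must be tiny
        assert cdr_rmsd(model, loaded) < 1e-2
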