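import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from structqa import synthetic
from structqa.metrics import (
    kabsch_superpose,
    lddt_ca,
    lddt_ca_arrays,
    tm_d0,
    tm_score,
    weighted_aggregate,
)
from structqa.structure_io import Residue, StructureModel

import oracles


def ca_array(model):
    return np.array([r.ca_coord for r in model.residues])


def rigid(coords, seed=0):
    rot = Rotation.random(random_state=seed).as_matrix()
    return coords @ rot.T + np.array([5.0, -3.0, 12.0])


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(1).normal(size=(8, 3))
        sup = kabsch_superpose(pts, pts)
        assert sup.rmsd < 1e-12
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-10)

    def test_recovers_known_transform(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(12, 3))
        rot = Rotation.random(random_state=3).as_matrix()
        trans = np.array([1.0, -2.0, 0.5])
        sup = kabsch_superpose(pts, pts @ rot.T + trans)
        assert sup.rmsd < 1e-8
        np.testing.assert_allclose(sup.rotation, rot, atol=1e-8)
        assert abs(np.linalg.det(sup.rotation) - 1.0) < 1e-9

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        assert kabsch_superpose(a, b).rmsd == pytest.approx(
            oracles.quaternion_rmsd(a, b), abs=1e-6
        )

    def test_degenerate_inputs_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        target = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(ValueError):
            kabsch_superpose(line, target)
        with pytest.raises(ValueError):
            kabsch_superpose(target[:2], target[:2])


class TestLddt:
    def test_identity_scores_100(self, walk_model):
        res = lddt_ca(walk_model, walk_model)
        np.testing.assert_allclose(res.per_residue, 100.0)
        assert res.global_lddt == 100.0

    def test_fully_displaced_scores_zero(self):
        from conftest import simple_model

        ref = simple_model([90.0] * 10)
        coords = ca_array(ref)
        model = simple_model([90.0] * 10)
        for r, c in zip(model.residues, coords * 3.0):  # every pair distance changes > 4 A
            r.ca_coord = c
        assert lddt_ca(ref, model).global_lddt == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_pair_enumeration(self, seed):
        chain = synthetic.make_chain(30, "random_walk", seed=seed)
        model = synthetic.perturb(chain, 1.0 + 0.2 * seed, seed=seed + 100)
        got = lddt_ca(chain, model)
        exp_per, exp_global = oracles.brute_lddt(ca_array(chain), ca_array(model))
        np.testing.assert_allclose(got.per_residue, exp_per, atol=1e-9)
        assert got.global_lddt == pytest.approx(exp_global, abs=1e-9)

    def test_rigid_transform_invariance(self, walk_model):
        model = synthetic.perturb(walk_model, 1.0, seed=5)
        base = lddt_ca(walk_model, model).global_lddt
        moved = StructureModel(
            residues=[
                Residue(r.chain_id, r.entity_id, r.seq_index, r.aa_code,
                        rigid(r.ca_coord[None])[0], None, r.plddt)
                for r in model.residues
            ]
        )
        assert lddt_ca(walk_model, moved).global_lddt == pytest.approx(base, abs=1e-9)

    def test_directional_asymmetry_on_partially_resolved_reference(self):
        chain = synthetic.make_chain(20, "random_walk", seed=3)
        model = synthetic.perturb(chain, 0.8, seed=4)
        # reference missing residues 1-5: swapping roles changes the scored set
        partial = StructureModel(
            residues=[
                Residue(r.chain_id, r.entity_id, r.seq_index, r.aa_code,
                        None if r.seq_index <= 5 else r.ca_coord, r.cb_coord,
                        r.plddt, resolved=r.seq_index > 5)
                for r in chain.residues
            ]
        )
        forward = lddt_ca(partial, model)
        backward = lddt_ca(model, partial)
        assert np.isnan(forward.per_residue[:5]).all()
        assert not np.isnan(backward.per_residue[:5]).any()
        assert forward.global_lddt != pytest.approx(backward.global_lddt)

    def test_unscorable_residue_excluded(self):
        # two clusters > 15 A apart: a lone residue has no pairs in radius
        ref = np.array([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0], [100.0, 0, 0]], dtype=float)
        res = lddt_ca_arrays(ref, ref.copy())
        assert np.isnan(res.per_residue[3])
        assert res.global_lddt == 100.0


class TestTmScore:
    def test_d0_closed_form(self):
        assert tm_d0(15) == 0.5
        assert tm_d0(21) == 0.5
        for L in (30, 143, 500):
            assert tm_d0(L) == pytest.approx(1.24 * (L - 15) ** (1 / 3) - 1.8, abs=1e-12)

    def test_identity_scores_one(self, walk_model):
        coords = ca_array(walk_model)
        res = tm_score(coords, coords)
        assert res.score == pytest.approx(1.0, abs=1e-9)
        assert res.d0 == tm_d0(len(coords))

    @pytest.mark.parametrize("seed,sigma", [(i, s) for i in range(5) for s in (0.3, 0.6)])
    def test_matches_exhaustive_seed_oracle(self, seed, sigma):
        chain = synthetic.make_chain(20, "random_walk", seed=400 + seed)
        ref = ca_array(chain)
        mod = ca_array(synthetic.perturb(chain, sigma, seed=500 + seed))
        assert tm_score(ref, mod).score == pytest.approx(
            oracles.exhaustive_tm(ref, mod), abs=1e-6
        )

    def test_rigid_transform_invariance(self):
        chain = synthetic.make_chain(25, "random_walk", seed=6)
        ref = ca_array(chain)
        mod = ca_array(synthetic.perturb(chain, 0.5, seed=7))
        assert tm_score(ref, rigid(mod, seed=8)).score == pytest.approx(
            tm_score(ref, mod).score, abs=1e-6
        )

    def test_too_few_pairs_rejected(self):
        pts = np.random.default_rng(0).normal(size=(3, 3))
        with pytest.raises(ValueError):
            tm_score(pts, pts)


class TestMonotonicity:
    def test_increasing_noise_degrades_both_metrics(self):
        """Median lDDT and TM over 20 replicates are non-increasing in sigma."""
        sigmas = (0.5, 2.0, 8.0)
        med_lddt, med_tm = [], []
        for sigma in sigmas:
            lddts, tms = [], []
            for rep in range(20):
                chain = synthetic.make_chain(30, "random_walk", seed=700 + rep)
                pert = synthetic.perturb(chain, sigma, seed=800 + rep)
                lddts.append(lddt_ca(chain, pert).global_lddt)
                tms.append(tm_score(ca_array(chain), ca_array(pert)).score)
            med_lddt.append(np.median(lddts))
            med_tm.append(np.median(tms))
        assert med_lddt[0] >= med_lddt[1] >= med_lddt[2]
        assert med_tm[0] >= med_tm[1] >= med_tm[2]


class TestWeightedAggregate:
    def test_uniform_weights_give_mean(self):
        s = np.array([0.2, 0.4, 0.9])
        assert weighted_aggregate(s, np.ones(3)) == pytest.approx(s.mean())

    def test_one_hot_selects_residue(self):
        s = np.array([0.2, 0.4, 0.9])
        w = np.array([0.0, 1.0, 0.0])
        assert weighted_aggregate(s, w) == 0.4

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40),
        st.integers(min_value=0, max_value=10**6),
    )
    @settings(max_examples=60, derandomize=True)
    def test_matches_direct_summation(self, scores, seed):
        s = np.asarray(scores)
        w = np.random.default_rng(seed).uniform(0.01, 1.0, size=s.size)
        direct = sum(wi * si for wi, si in zip(w, s)) / sum(w)
        assert weighted_aggregate(s, w) == pytest.approx(direct, abs=1e-12)

    def test_resolved_flags_equal_unweighted_mean_over_resolved(self):
        rng = np.random.default_rng(4)
        s = rng.uniform(0, 1, 50)
        resolved = rng.random(50) > 0.3
        assert weighted_aggregate(s, resolved.astype(float)) == pytest.approx(
            s[resolved].mean()
        )

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_aggregate(np.ones(3), np.zeros(3))
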