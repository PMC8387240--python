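import json

import numpy as np
import pytest

from structqa import synthetic
from structqa.benchmark import LabelledScores, calibration_fit, roc_auc
from structqa.confidence import disorder_score
from structqa.metrics import lddt_ca
from structqa.structure_io import write_structure


def ca_array(model):
    return np.array([r.ca_coord for r in model.residues])


class TestMakeChain:
    def test_minimal_chain_bond_length(self):
        for topology in ("helix", "strand", "random_walk"):
            m = synthetic.make_chain(2, topology, seed=1)
            d = np.linalg.norm(m.residues[1].ca_coord - m.residues[0].ca_coord)
            assert d == pytest.approx(3.8, abs=1e-9)

    def test_consecutive_spacing_everywhere(self):
        for topology in ("helix", "strand", "coil"):
            ca = ca_array(synthetic.make_chain(40, topology, seed=2))
            d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
            np.testing.assert_allclose(d, 3.8, atol=1e-9)

    def test_helix_regularity(self):
        """All |i-j| = 4 C-alpha distances of an ideal helix fall in a narrow band."""
        ca = ca_array(synthetic.make_chain(20, "helix", seed=3))
        d4 = np.linalg.norm(ca[4:] - ca[:-4], axis=1)
        assert d4.max() - d4.min() < 1e-9
        assert 5.0 < d4[0] < 7.0

    def test_walk_self_avoidance(self):
        ca = ca_array(synthetic.make_chain(80, "random_walk", seed=4))
        d = np.linalg.norm(ca[:, None] - ca[None, :], axis=-1)
        mask = ~np.eye(len(ca), dtype=bool) & (np.abs(np.subtract.outer(
            np.arange(len(ca)), np.arange(len(ca)))) > 1)
        assert d[mask].min() >= 3.4

    def test_same_seed_identical_coordinates(self):
        a = ca_array(synthetic.make_chain(30, "random_walk", seed=5))
        b = ca_array(synthetic.make_chain(30, "random_walk", seed=5))
        np.testing.assert_array_equal(a, b)

    def test_glycines_have_no_cb(self):
        m = synthetic.make_chain(200, "random_walk", seed=6, glycine_fraction=0.3)
        for r in m.residues:
            assert (r.cb_coord is None) == (r.aa_code == "G")

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            synthetic.make_chain(1)


class TestPerturb:
    def test_zero_sigma_is_identity(self, walk_model):
        p = synthetic.perturb(walk_model, 0.0, seed=1)
        np.testing.assert_array_equal(ca_array(p), ca_array(walk_model))
        assert lddt_ca(walk_model, p).global_lddt == 100.0

    def test_large_sigma_destroys_local_structure(self, walk_model):
        p = synthetic.perturb(walk_model, 25.0, seed=2)
        assert lddt_ca(walk_model, p).global_lddt < 10.0

    def test_noise_monotonically_degrades_lddt(self, walk_model):
        medians = []
        for sigma in (0.5, 2.0, 8.0):
            scores = [
                lddt_ca(walk_model, synthetic.perturb(walk_model, sigma, seed=rep)).global_lddt
                for rep in range(20)
            ]
            medians.append(np.median(scores))
        assert medians[0] > medians[1] > medians[2]

    def test_negative_sigma_rejected(self, walk_model):
        with pytest.raises(ValueError):
            synthetic.perturb(walk_model, -1.0)


class TestSimulatePlddt:
    def test_noiseless_identity_mapping(self):
        true = np.array([10.0, 50.0, 90.0])
        prof = synthetic.simulate_plddt(true, slope=1.0, intercept=0.0, noise_sd=0.0)
        np.testing.assert_allclose(prof.plddt, true, atol=1e-12)

    def test_output_truncated_to_range(self):
        true = np.array([0.0, 100.0])
        prof = synthetic.simulate_plddt(true, slope=0.9, intercept=5.0, noise_sd=30.0, seed=1)
        assert prof.plddt.min() >= 0.0 and prof.plddt.max() <= 100.0

    def test_calibration_recovery_within_bootstrap_ci(self):
        x, y = synthetic.make_calibration_pairs(50_000, 0.95, 2.0, 5.0, seed=12)
        fit = calibration_fit(x, y, n_boot=200, seed=12)
        assert fit.ci_slope[0] <= 0.95 <= fit.ci_slope[1]
        assert fit.slope == pytest.approx(0.95, abs=0.01)


class TestMakeComplex:
    def test_distant_chains_have_no_cross_contacts(self):
        model, truth = synthetic.make_complex(2, ("1", "2"), seed=1, interface=False)
        assert truth["contact_counts"]["heterotypic"] == 0
        assert truth["contact_counts"]["homomeric"] == 0

    def test_homodimer_never_heterotypic(self):
        model, truth = synthetic.make_complex(2, ("1", "1"), seed=2, interface=True)
        assert truth["contact_counts"]["heterotypic"] == 0

    def test_same_entity_chains_share_sequence(self):
        model, _ = synthetic.make_complex(3, ("1", "1", "2"), seed=3)
        assert model.chain_sequence("A") == model.chain_sequence("B")

    def test_interface_produces_cross_chain_contacts(self):
        _, truth = synthetic.make_complex(2, ("1", "2"), seed=4, interface=True)
        assert truth["contact_counts"]["heterotypic"] > 0


class TestDisorderProteome:
    def test_zero_fraction_all_ordered(self):
        spec = synthetic.GeneratorSpec(seed=1, n_proteins=5, disorder_fraction=0.0)
        proteins, truth = synthetic.make_disorder_proteome(spec)
        assert all((p["labels"] == 0).all() for p in proteins)
        assert truth["realized_disorder_fraction"] == 0.0

    def test_realized_fraction_near_target(self):
        spec = synthetic.GeneratorSpec(seed=2, n_proteins=200, disorder_fraction=0.4)
        _, truth = synthetic.make_disorder_proteome(spec)
        assert abs(truth["realized_disorder_fraction"] - 0.4) < 0.01

    def test_confidence_separates_disorder(self):
        spec = synthetic.GeneratorSpec(seed=3, n_proteins=50)
        proteins, _ = synthetic.make_disorder_proteome(spec)
        scores = np.concatenate([disorder_score(p["profile"]) for p in proteins])
        labels = np.concatenate([p["labels"] for p in proteins])
        assert roc_auc(LabelledScores(scores, labels)) > 0.95

    def test_segments_match_labels(self):
        spec = synthetic.GeneratorSpec(seed=4, n_proteins=10)
        proteins, _ = synthetic.make_disorder_proteome(spec)
        for p in proteins:
            rebuilt = np.zeros_like(p["labels"])
            for start, end in p["segments"]:
                rebuilt[start - 1 : end] = 1
            np.testing.assert_array_equal(rebuilt, p["labels"])


class TestDeterminism:
    def test_disorder_proteome_bit_identical(self):
        spec = synthetic.GeneratorSpec(seed=9, n_proteins=20)
        a, ta = synthetic.make_disorder_proteome(spec)
        b, tb = synthetic.make_disorder_proteome(spec)
        assert ta == tb
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa["profile"].plddt, pb["profile"].plddt)
            assert pa["sequence"] == pb["sequence"]

    def test_structure_files_byte_identical(self, tmp_path):
        for run in ("x", "y"):
            model, _ = synthetic.make_complex(3, ("1", "1", "2"), seed=13)
            write_structure(model, tmp_path / f"{run}.cif", "mmcif")
        assert (tmp_path / "x.cif").read_bytes() == (tmp_path / "y.cif").read_bytes()

    def test_ground_truth_json_serializable_and_stable(self):
        _, t1 = synthetic.make_complex(3, ("1", "1", "2"), seed=17)
        _, t2 = synthetic.make_complex(3, ("1", "1", "2"), seed=17)
        assert json.dumps(t1, sort_keys=True) == json.dumps(t2, sort_keys=True)


class TestGeneratorSpecValidation:
    def test_length_bounds_enforced(self):
        with pytest.raises(ValueError):
            synthetic.GeneratorSpec(length_distribution=(10, 100))
        with pytest.raises(ValueError):
            synthetic.GeneratorSpec(length_distribution=(100, 3000))

    def test_band_targets_must_sum_to_one(self):
        with pytest.raises(ValueError):
            synthetic.GeneratorSpec(band_targets={"very_high": 0.5, "confident": 0.4,
                                                  "low": 0.05, "very_low": 0.0})
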