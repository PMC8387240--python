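import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from structqa.confidence import (
    BAND_LABELS,
    MultidomainEntry,
    assign_band,
    band_summary,
    confident_fraction,
    disorder_score,
    find_regions,
    fraction_mostly_confident,
    multidomain_candidates,
)
from structqa.structure_io import ConfidenceProfile
from structqa import synthetic

import oracles


def prof(values, pid="p"):
    return ConfidenceProfile(protein_id=pid, plddt=np.asarray(values, dtype=float))


class TestAssignBand:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (100.0, "very_high"),
            (90.0001, "very_high"),
            (90.0, "confident"),   # strict > at the boundary
            (70.0001, "confident"),
            (70.0, "low"),
            (50.0, "low"),
            (49.9999, "very_low"),
            (0.0, "very_low"),
        ],
    )
    def test_boundaries(self, value, expected):
        assert assign_band(value) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            assign_band(100.5)
        with pytest.raises(ValueError):
            assign_band(-0.1)

    def test_matches_threshold_enumeration(self):
        """Band assignment agrees with brute-force comparison against the cut-offs."""
        for v in np.linspace(0, 100, 401):
            if v > 90:
                expected = "very_high"
            elif v > 70:
                expected = "confident"
            elif v >= 50:
                expected = "low"
            else:
                expected = "very_low"
            assert assign_band(float(v)) == expected


class TestBandSummary:
    def test_one_residue_per_band(self):
        s = band_summary([prof([95, 80, 60, 30])])
        assert s.residue_counts == {"very_high": 1, "confident": 1, "low": 1, "very_low": 1}
        assert s.total_residues == 4

    def test_fractions_sum_to_one_and_permutation_invariance(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 100, 500)
        s1 = band_summary([prof(values)])
        s2 = band_summary([prof(rng.permutation(values))])
        assert s1.residue_counts == s2.residue_counts
        assert abs(sum(s1.fractions.values()) - 1.0) < 1e-12

    def test_designed_band_fractions_recovered_exactly(self):
        spec = synthetic.GeneratorSpec(seed=11, n_proteins=40)
        profiles, truth = synthetic.make_banded_proteome(spec)
        s = band_summary(profiles)
        assert s.residue_counts == truth["band_counts"]

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            band_summary([])


class TestConfidentFraction:
    def test_examples(self):
        p = prof([80, 80, 80, 60])
        assert confident_fraction(p) == pytest.approx(0.75)
        assert fraction_mostly_confident([p]) == 1.0
        assert confident_fraction(prof([100] * 5)) == 1.0

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            confident_fraction(prof([]))

    def test_designed_aggregate_fraction(self):
        profiles, truth = synthetic.make_coverage_proteome(n_proteins=100, pass_fraction=0.4, seed=2)
        assert fraction_mostly_confident(profiles) == pytest.approx(truth["pass_fraction"])
        assert truth["pass_fraction"] == pytest.approx(0.40)


class TestDisorderScore:
    def test_formula(self):
        np.testing.assert_allclose(
            disorder_score(prof([100, 0, 72.5])), [0.0, 1.0, 0.275], atol=1e-12
        )

    def test_strictly_decreasing_in_plddt(self):
        values = np.linspace(0, 100, 101)
        scores = disorder_score(prof(values))
        assert np.all(np.diff(scores) < 0)


class TestFindRegions:
    def test_basic_example(self):
        regions = find_regions(prof([30, 30, 80, 80, 80, 30]), "gt", 70, min_len=3)
        assert [(r.start, r.end) for r in regions] == [(3, 5)]

    def test_all_pass_single_region(self):
        regions = find_regions(prof([90] * 7), "gt", 70)
        assert [(r.start, r.end, r.length) for r in regions] == [(1, 7, 7)]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 100, rng.integers(1, 80))
        predicate = rng.choice(["gt", "ge", "lt", "le"])
        threshold = float(rng.uniform(20, 80))
        min_len = int(rng.integers(1, 6))
        got = find_regions(prof(values), predicate, threshold, min_len)
        assert [(r.start, r.end) for r in got] == oracles.brute_regions(
            values, predicate, threshold, min_len
        )

    @given(st.lists(st.floats(min_value=0, max_value=100), min_size=1, max_size=60))
    @settings(max_examples=60, derandomize=True)
    def test_regions_partition_predicate_set(self, values):
        """With min_len=1 the regions are disjoint and union to the predicate-true set."""
        p = prof(values)
        regions = find_regions(p, "gt", 70.0, min_len=1)
        covered = set()
        for r in regions:
            idx = set(range(r.start, r.end + 1))
            assert not covered & idx  # disjoint
            covered |= idx
        true_set = {i + 1 for i, v in enumerate(p.plddt) if v > 70.0}
        assert covered == true_set
        for r in regions:  # maximality
            assert r.start == 1 or p.plddt[r.start - 2] <= 70.0
            assert r.end == p.length or p.plddt[r.end] <= 70.0


class TestMultidomainCandidates:
    def entry(self, n_conf, length, identity=0.0, pid="x", wtm=None):
        values = np.full(length, 40.0)
        values[:n_conf] = 85.0
        return MultidomainEntry(pid, prof(values, pid), identity, wtm)

    def test_rule_boundaries(self):
        kept = multidomain_candidates([self.entry(700, 1000)]).kept
        assert len(kept) == 1
        assert not multidomain_candidates([self.entry(599, 1000)]).kept
        # 600 confident residues but not over half of a 1300-residue chain
        assert not multidomain_candidates([self.entry(600, 1300)]).kept
        # high-coverage template present -> excluded
        assert not multidomain_candidates([self.entry(700, 1000, identity=45.0)]).kept

    def test_missing_template_info_skipped(self):
        res = multidomain_candidates([MultidomainEntry("m", prof([85] * 700), None)])
        assert res.skipped == ["m"] and not res.kept

    def test_sorting_and_tm_subsets(self):
        entries = [
            self.entry(650, 1000, pid="a", wtm=0.75),
            self.entry(900, 1000, pid="b", wtm=0.85),
            self.entry(700, 1000, pid="c", wtm=0.5),
        ]
        res = multidomain_candidates(entries)
        assert [e.protein_id for e in res.kept] == ["b", "c", "a"]
        assert res.n_above == {0.7: 2, 0.8: 1}

    def test_generator_pass_set_recovered(self):
        entries, truth = synthetic.make_multidomain_cohort(n=60, seed=9)
        res = multidomain_candidates(
            [
                MultidomainEntry(
                    e["protein_id"], e["profile"], e["best_high_coverage_identity"], e["weighted_tm"]
                )
                for e in entries
            ]
        )
        assert sorted(e.protein_id for e in res.kept) == sorted(truth["pass_ids"])
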