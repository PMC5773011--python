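"""Null hypergraph ensembles, impact deviations and deviation ratios."""

import numpy as np
import pandas as pd
import pytest

import musclenet as mn
from musclenet.nulls import NullEnsemble


def make_ensemble_from_tables(tables):
    """Ensemble stub carrying pre-computed impact tables."""
    return NullEnsemble("free_rewire", [], [], impact_tables=tables)


class TestTriadPartition:
    def test_fully_connected_three_muscles_single_group(self):
        h = mn.parse_incidence([("m1", "b1"), ("m1", "b2"),
                                ("m2", "b1"), ("m2", "b2"),
                                ("m3", "b1"), ("m3", "b2")])
        tp = mn.triad_partition(mn.project(h, "muscle_centric"), K=1)
        assert tp.K == 1
        assert len(set(tp.groups)) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_triads_recovered(self, fixtures, seed):
        h = fixtures["planted_triads"]["hypergraph"]
        planted = fixtures["planted_triads"]["planted"]
        tp = mn.triad_partition(mn.project(h, "muscle_centric"), K=3,
                                rng_seed=seed)
        for g in range(3):
            assert len(set(tp.groups[planted == g])) == 1

    def test_group_sizes_bounded(self, small_body):
        h, _, _ = small_body
        tp = mn.triad_partition(mn.project(h, "muscle_centric"))
        sizes = tp.sizes()
        sizes = sizes[sizes > 0]
        assert sizes.min() >= 2 and sizes.max() <= 5

    def test_k_larger_than_muscle_count_rejected(self, fixtures):
        h = fixtures["planted_triads"]["hypergraph"]
        with pytest.raises(ValueError):
            mn.triad_partition(mn.project(h, "muscle_centric"), K=99)


class TestRewiring:
    def test_singleton_groups_identity(self, small_body):
        h, _, _ = small_body
        grouping = {m: i for i, m in enumerate(h.muscle_labels)}
        assert mn.rewire_within_groups(h, grouping, rng_seed=3) == h

    def test_two_muscle_group_preserves_degrees_and_bones(self):
        h = mn.parse_incidence([("m1", "b1"), ("m1", "b2"),
                                ("m2", "b3"), ("m2", "b4")])
        for seed in range(20):
            hr = mn.rewire_within_groups(h, {"m1": 0, "m2": 0},
                                         rng_seed=seed)
            assert list(hr.degrees()) == [2, 2]
            assert np.array_equal(hr.incidence.sum(axis=1),
                                  h.incidence.sum(axis=1))

    def test_degree_sequence_preserved_every_replicate(self, small_body):
        h, _, _ = small_body
        grouping = {m: 0 for m in h.muscle_labels}
        for seed in range(25):
            hr = mn.rewire_within_groups(h, grouping, rng_seed=seed)
            assert np.array_equal(hr.degrees(), h.degrees())

    def test_seeded_determinism(self, small_body):
        h, _, _ = small_body
        grouping = {m: 0 for m in h.muscle_labels}
        a = mn.rewire_within_groups(h, grouping, rng_seed=11)
        b = mn.rewire_within_groups(h, grouping, rng_seed=11)
        assert a == b
        assert not (a == mn.rewire_within_groups(h, grouping, rng_seed=12))

    def test_uncovered_muscle_rejected(self, small_body):
        h, _, _ = small_body
        with pytest.raises(ValueError):
            mn.rewire_within_groups(h, {h.muscle_labels[0]: 0}, rng_seed=0)

    def test_triad_rewiring_perturbs_less_than_free(self, small_body):
        h, _, _ = small_body
        B0 = mn.project(h, "muscle_centric").weights
        tp = mn.triad_partition(mn.project(h, "muscle_centric"), rng_seed=0)
        free_grouping = {m: 0 for m in h.muscle_labels}
        d_triad, d_free = [], []
        for seed in range(20):
            ht = mn.rewire_within_groups(h, tp.as_mapping(), rng_seed=seed)
            hf = mn.rewire_within_groups(h, free_grouping, rng_seed=seed)
            d_triad.append(np.linalg.norm(
                mn.project(ht, "muscle_centric").weights - B0))
            d_free.append(np.linalg.norm(
                mn.project(hf, "muscle_centric").weights - B0))
        assert np.mean(d_triad) < np.mean(d_free)


class TestRandomHypergraph:
    def test_total_attachments_preserved(self, small_body):
        h, _, _ = small_body
        hr = mn.random_hypergraph(h, rng_seed=0)
        assert hr.incidence.sum() == h.incidence.sum()
        assert hr.incidence.shape == h.incidence.shape

    def test_expected_degree_matches_binomial_theory(self, small_body):
        h, _, _ = small_body
        total, M = h.incidence.sum(), h.n_muscles
        n_rep = 300
        means = [mn.random_hypergraph(h, rng_seed=s).degrees().mean()
                 for s in range(n_rep)]
        expect = total / M
        se = np.std(means, ddof=1) / np.sqrt(n_rep)
        assert abs(np.mean(means) - expect) < max(3 * se, 1e-9)

    def test_degree_distribution_differs_from_real(self, small_body):
        # KS against the random-attachment control rejects equality
        h, _, _ = small_body
        null_deg = np.concatenate(
            [mn.random_hypergraph(h, rng_seed=s).degrees()
             for s in range(20)])
        ks, p = mn.ks_degree_test(h.degrees(), null_deg)
        assert ks > 0.1 and p < 0.05


class TestImpactDeviation:
    def _fake(self, null_impacts, degree=2):
        tables = [pd.DataFrame({"muscle": ["m1"], "degree": [degree],
                                "impact": [v]}) for v in null_impacts]
        return make_ensemble_from_tables(tables)

    def test_hand_computed_z(self):
        # null draws {1,2,3}: mean 2, sample std 1 -> impact 3 gives z=1
        ens = self._fake([1.0, 2.0, 3.0])
        real = pd.DataFrame({"muscle": ["m1"], "degree": [2], "impact": [3.0]})
        dev = mn.impact_deviation(real, ens)
        assert dev["deviation"].iloc[0] == pytest.approx(1.0)
        assert not dev["significant"].iloc[0]

    def test_zero_deviation_at_null_mean(self):
        ens = self._fake([1.0, 2.0, 3.0])
        real = pd.DataFrame({"muscle": ["m1"], "degree": [2], "impact": [2.0]})
        assert mn.impact_deviation(real, ens)["deviation"].iloc[0] == 0.0

    def test_significance_flag_at_1_96(self):
        ens = self._fake(list(np.linspace(0, 2, 30)))
        obs = np.array([0.0, 2.0, 3.0, 10.0])
        real = pd.DataFrame({"muscle": [f"x{i}" for i in range(4)],
                             "degree": [2] * 4, "impact": obs})
        dev = mn.impact_deviation(real, ens)
        assert list(dev["significant"]) == list(abs(dev["deviation"]) > 1.96)
        assert dev["significant"].iloc[3]

    def test_ci_reference_zero_inside_interval(self):
        ens = self._fake(list(np.linspace(0, 2, 30)))
        real = pd.DataFrame({"muscle": ["m1", "m2"], "degree": [2, 2],
                             "impact": [1.1, 10.0]})
        dev = mn.impact_deviation(real, ens, reference="ci")
        assert dev["deviation"].iloc[0] == 0.0
        assert dev["deviation"].iloc[1] > 0

    def test_sparse_degree_pools_neighbours(self):
        tables = [pd.DataFrame({"muscle": ["a", "b"], "degree": [2, 3],
                                "impact": [1.0 + 0.1 * s, 2.0 + 0.1 * s]})
                  for s in range(5)]
        ens = make_ensemble_from_tables(tables)
        real = pd.DataFrame({"muscle": ["q"], "degree": [4], "impact": [2.0]})
        dev = mn.impact_deviation(real, ens, min_null_obs=2)
        assert "pooled" in dev["binning"].iloc[0]
        assert np.isfinite(dev["deviation"].iloc[0])

    def test_missing_category_gives_na_with_warning(self):
        ens = self._fake([1.0])  # a single observation is not enough
        real = pd.DataFrame({"muscle": ["m1"], "degree": [2], "impact": [1.0]})
        with pytest.warns(UserWarning, match="insufficient"):
            dev = mn.impact_deviation(real, ens)
        assert np.isnan(dev["deviation"].iloc[0])

    def test_null_self_consistency_rate(self):
        # a replicate scored against its own ensemble should flag ~5%
        # of muscles; checked loosely via the pooled flag fraction
        h, emb, _ = mn.generate_body(mn.BodySpec(n_bones=16, n_muscles=20,
                                                 seed=4))
        ens = NullEnsemble.generate(h, "free_rewire", n_replicates=40,
                                    seed=9).compute_impacts(emb)
        flags = []
        for table in ens.impact_tables[:10]:
            dev = mn.impact_deviation(table, ens)
            flags.extend(dev["significant"][np.isfinite(dev["deviation"])])
        rate = np.mean(flags)
        assert 0.0 <= rate < 0.15


class TestDeviationRatio:
    def test_all_positive_category_gives_one(self):
        dev = pd.DataFrame({"muscle": ["a", "b", "c"],
                            "deviation": [0.5, 1.2, -0.3]})
        cats = {"a": 1, "b": 1, "c": 2}
        out = mn.deviation_ratio(dev, cats)
        assert out.set_index("category_id").loc[1, "ratio"] == 1.0
        assert out.set_index("category_id").loc[2, "ratio"] == 0.0

    def test_uncategorized_muscle_rejected(self):
        dev = pd.DataFrame({"muscle": ["a"], "deviation": [1.0]})
        with pytest.raises(ValueError):
            mn.deviation_ratio(dev, {})

    def test_na_category_excluded_with_warning(self):
        dev = pd.DataFrame({"muscle": ["a", "b"],
                            "deviation": [np.nan, 1.0]})
        with pytest.warns(UserWarning, match="excluded"):
            out = mn.deviation_ratio(dev, {"a": 1, "b": 2})
        assert list(out["category_id"]) == [2]
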