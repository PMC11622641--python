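from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from ssdkit.landscape import Landscape, OTUTable, split_landscape
from ssdkit.permutation import (
    assemblages_from_classifications,
    classify_species,
    negative_control,
    sdp_test,
    sp_frame,
    sp_test,
)
from ssdkit.simulate import SimulationConfig, generate_landscape
from ssdkit.specificity import species_specificity
from .conftest import make_landscape


class TestClassify:
    @pytest.mark.parametrize(
        "s_a, s_b, q, expected",
        [
            (0.4, 0.2, 0.20, "IDS"),   # not significant regardless of sizes
            (0.4, 0.0, 0.01, "US-A"),  # significant, absent on one side
            (0.0, 0.4, 0.01, "US-B"),
            (0.4, 0.1, 0.01, "ES-A"),
            (0.1, 0.4, 0.01, "ES-B"),
        ],
    )
    def test_categories(self, s_a, s_b, q, expected):
        assert classify_species(s_a, s_b, q, alpha=0.05) == expected

    def test_equal_specificity_cannot_be_significant(self):
        with pytest.raises(RuntimeError):
            classify_species(0.3, 0.3, 0.001, alpha=0.05)


def exhaustive_oracle(landscape):
    """Brute-force permutation p-values via the public specificity routine.

    Enumerates every way to choose m of the m+n samples as habitat A,
    rebuilds a landscape for each, and counts assignments whose statistic
    reaches the observed one.  Fully independent of the vectorised path.
    """
    table = landscape.table
    cols = np.concatenate([landscape.idx_a, landscape.idx_b])
    obs = species_specificity(landscape)
    t_obs = np.abs(
        obs.S[landscape.habitat_a].to_numpy()
        - obs.S[landscape.habitat_b].to_numpy()
    )
    hits = np.zeros(table.n_species)
    total = 0
    for chosen in combinations(range(cols.size), landscape.m):
        idx_a = cols[list(chosen)]
        idx_b = cols[[i for i in range(cols.size) if i not in chosen]]
        ls = Landscape(table, "A*", "B*", idx_a, idx_b)
        spec = species_specificity(ls)
        t = np.abs(spec.S["A*"].to_numpy() - spec.S["B*"].to_numpy())
        hits += t >= t_obs - 1e-12
        total += 1
    return hits / total


class TestSPTest:
    def test_exhaustive_matches_brute_force_oracle(self):
        counts = np.array(
            [
                [9, 1, 0, 2],
                [5, 5, 5, 5],
                [0, 7, 3, 0],
            ]
        )
        ls = make_landscape(counts, m=2)
        expected = exhaustive_oracle(ls)
        cls = sp_test(ls, method="exhaustive", seed=0)
        got = {c.species_id: c.p_value for c in cls}
        for i, sid in enumerate(ls.table.species_ids):
            assert got[sid] == pytest.approx(expected[i], abs=1e-12)

    def test_monte_carlo_converges_to_exhaustive(self):
        counts = np.array(
            [
                [9, 1, 0, 2],
                [0, 7, 3, 0],
            ]
        )
        ls = make_landscape(counts, m=2)
        exact = {
            c.species_id: c.p_value for c in sp_test(ls, method="exhaustive")
        }
        mc = {
            c.species_id: c.p_value
            for c in sp_test(ls, n_perm=4000, seed=11)
        }
        for sid, p in exact.items():
            assert mc[sid] == pytest.approx(p, abs=0.03)

    def test_duplicated_scheme_forces_p_one(self, tiny_table):
        ls = split_landscape(tiny_table, "duplicated")
        cls = sp_test(ls, n_perm=200, seed=3)
        assert all(c.p_value == 1.0 for c in cls)
        assert all(c.category == "IDS" for c in cls)

    @settings(max_examples=15, deadline=None)
    @given(
        hnp.arrays(np.int64, (4, 8), elements=st.integers(0, 40)),
        st.integers(0, 2**31 - 1),
    )
    def test_duplicated_forces_zero_positives_property(self, counts, seed):
        counts[0] = np.maximum(counts[0], 1)
        table = OTUTable(
            [f"sp{i}" for i in range(4)], [f"s{j}" for j in range(8)], counts
        )
        ls = split_landscape(table, "duplicated")
        cls = sp_test(ls, n_perm=50, seed=seed)
        assert sum(c.category != "IDS" for c in cls) == 0

    def test_planted_unique_species_recovered(self):
        config = SimulationConfig(
            n_species=150, m=30, n=30, n_us_a=1, depth=5000, seed=7
        )
        table, _, truth = generate_landscape(config)
        ls = Landscape(table, "A", "B", np.arange(30), np.arange(30, 60))
        # a lone true effect among ~150 tested species needs
        # min attainable p = 1/(1+n_perm) < alpha / n_tested to pass BH
        cls = sp_test(ls, n_perm=5000, alpha=0.05, seed=8)
        planted = truth.planted("US-A")[0]
        record = next(c for c in cls if c.species_id == planted)
        assert record.category == "US-A"
        assert record.q_value < 0.05

    def test_pvalue_bounds_and_bh_monotonicity(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 30, size=(40, 12))
        counts[0] = np.maximum(counts[0], 1)
        ls = make_landscape(counts, m=6)
        cls = sp_test(ls, n_perm=99, seed=6)
        frame = sp_frame(cls).sort_values("p")
        assert (frame["p"] >= 1.0 / 100).all()
        assert (frame["p"] <= 1.0).all()
        assert (frame["q"] >= frame["p"] - 1e-12).all()
        assert frame["q"].is_monotonic_increasing

    def test_determinism(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 20, size=(20, 10))
        counts[0] = np.maximum(counts[0], 1)
        ls = make_landscape(counts, m=5)
        a = sp_frame(sp_test(ls, n_perm=100, seed=4))
        b = sp_frame(sp_test(ls, n_perm=100, seed=4))
        assert a.equals(b)

    def test_zero_total_species_excluded(self):
        counts = np.array([[3, 4, 5, 6], [0, 0, 0, 0]])
        ls = make_landscape(counts, m=2)
        cls = sp_test(ls, n_perm=20, seed=0)
        assert [c.species_id for c in cls] == ["sp1"]

    def test_bad_parameters(self, tiny_landscape):
        with pytest.raises(ValueError):
            sp_test(tiny_landscape, n_perm=0, seed=0)
        with pytest.raises(ValueError):
            sp_test(tiny_landscape, alpha=1.5, seed=0)


class TestAssemblages:
    def test_partition_into_six_groups(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 30, size=(30, 12))
        counts[0] = np.maximum(counts[0], 1)
        ls = make_landscape(counts, m=6)
        cls = sp_test(ls, n_perm=99, seed=1)
        groups = assemblages_from_classifications(cls)
        assert set(groups) == {"US-A", "US-B", "ES-A", "ES-B", "DS", "ALL"}
        four = sum(len(groups[g]) for g in ("US-A", "US-B", "ES-A", "ES-B"))
        assert len(groups["DS"]) == four
        assert len(groups["ALL"]) == len(cls)


class TestSDPTest:
    def test_duplicated_all_assemblage_p_one(self, tiny_table):
        ls = split_landscape(tiny_table, "duplicated")
        cls = sp_test(ls, n_perm=100, seed=1)
        res = sdp_test(
            ls, assemblages_from_classifications(cls), n_perm=100, seed=2
        )
        all_res = next(r for r in res if r.assemblage == "ALL")
        assert all_res.testable
        assert all(p == 1.0 for p in all_res.p.values())

    def test_empty_and_singleton_assemblages_not_testable(self, tiny_landscape):
        counts = np.array([[5, 6, 0, 0], [1, 1, 1, 1]])
        ls = make_landscape(counts, m=2)
        res = sdp_test(
            ls, {"empty": [], "single": ["sp1"]}, n_perm=50, seed=0
        )
        by_name = {r.assemblage: r for r in res}
        assert not by_name["empty"].testable
        assert not by_name["single"].testable

    def test_planted_enrichment_detected(self):
        config = SimulationConfig(
            n_species=200, m=30, n=30, n_es_a=40, es_effect=8.0,
            depth=10_000, seed=12,
        )
        table, _, truth = generate_landscape(config)
        ls = Landscape(table, "A", "B", np.arange(30), np.arange(30, 60))
        res = sdp_test(
            ls, {"ES-A": truth.planted("ES-A")}, n_perm=300, seed=13
        )
        r = res[0]
        assert r.testable
        for q in (1, 2, 3, 4):
            assert r.p[q] < 0.05

    def test_observed_sd_matches_profile_path(self):
        rng = np.random.default_rng(21)
        counts = rng.integers(0, 30, size=(15, 10))
        counts[0] = np.maximum(counts[0], 1)
        ls = make_landscape(counts, m=5)
        spec = species_specificity(ls)
        members = [f"sp{i}" for i in range(1, 8)]
        res = sdp_test(ls, {"grp": members}, n_perm=20, seed=0)[0]
        from ssdkit.diversity import sd_hill

        for q in (0, 1, 2):
            expected = sd_hill(spec.S.loc[members, "A"].to_numpy(), q)
            assert res.sd_a[q] == pytest.approx(expected)


class TestNegativeControl:
    def test_duplicated_reports_no_detections(self):
        rng = np.random.default_rng(31)
        counts = rng.integers(0, 25, size=(30, 10))
        counts[0] = np.maximum(counts[0], 1)
        table = OTUTable(
            [f"sp{i}" for i in range(30)], [f"s{j}" for j in range(10)], counts
        )
        report = negative_control(table, "duplicated", n_perm=100, seed=1)
        assert report.n_significant_species == 0
        assert report.n_sdp_significant == 0

    def test_half_divided_null_consistent_with_fdr(self):
        config = SimulationConfig(n_species=150, m=30, n=30, depth=5000, seed=41)
        table, _, _ = generate_landscape(config)
        report = negative_control(table, "half_divided", n_perm=200, seed=42)
        # after BH, detections on a null split should be (near) zero
        assert report.n_significant_species <= 2

    def test_same_seed_identical_report(self, tiny_table):
        a = negative_control(tiny_table, "half_divided", n_perm=50, seed=9)
        b = negative_control(tiny_table, "half_divided", n_perm=50, seed=9)
        assert a.summary() == b.summary()
        assert sp_frame(a.classifications).equals(sp_frame(b.classifications))


class TestVectorisedPathConsistency:
    def test_identity_assignment_reproduces_observed_specificity(self):
        """The permutation machinery at the identity labeling must equal the
        public specificity computation exactly."""
        from ssdkit.permutation import _pair_stats, _presence_relab

        rng = np.random.default_rng(17)
        counts = rng.integers(0, 40, size=(12, 9))
        counts[0] = np.maximum(counts[0], 1)
        ls = make_landscape(counts, m=4)
        spec = species_specificity(ls)
        presence, relab = _presence_relab(ls.table)
        za = np.zeros((9, 1))
        za[:4, 0] = 1.0
        s_a, s_b = _pair_stats(presence, relab, za, 4, 5)
        np.testing.assert_allclose(s_a[:, 0], spec.S["A"].to_numpy(), atol=1e-12)
        np.testing.assert_allclose(s_b[:, 0], spec.S["B"].to_numpy(), atol=1e-12)
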