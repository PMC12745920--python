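"""Delta-K, the admixture filter and geo-genetic-group validation."""

import numpy as np
import pytest

from refugia.grouping import (GroupCriteria, QMatrix, admixture_filter,
                              assign_geo_genetic_groups, evanno_delta_k,
                              isolation_helper)
from refugia.simulate import simulate_q_matrices


def traces_with(means, sd):
    """Two replicates per K giving exactly the requested mean and sample
    standard deviation (ddof=1)."""
    return {k + 1: [m - sd / np.sqrt(2), m + sd / np.sqrt(2)]
            for k, m in enumerate(means)}


class TestEvannoDeltaK:
    def test_fixture_values(self):
        tr = traces_with([-1000, -900, -880, -875], sd=2.0)
        dk = evanno_delta_k(tr)
        assert dk[2] == pytest.approx(40.0)
        assert dk[3] == pytest.approx(7.5)
        assert max(dk, key=dk.get) == 2

    def test_linear_likelihood_gives_zero(self):
        tr = traces_with([-100, -90, -80, -70], sd=1.0)
        assert all(v == pytest.approx(0.0)
                   for v in evanno_delta_k(tr).values())

    def test_boundaries_undefined(self):
        tr = traces_with([-10, -9, -8], sd=1.0)
        dk = evanno_delta_k(tr)
        assert set(dk) == {2}

    def test_needs_three_k(self):
        with pytest.raises(ValueError):
            evanno_delta_k(traces_with([-10, -9], sd=1.0))

    def test_zero_sd_warns_and_returns_inf(self):
        tr = traces_with([-100, -90, -70], sd=1.0)
        tr[2] = [-90.0, -90.0]
        with pytest.warns(UserWarning):
            dk = evanno_delta_k(tr)
        assert dk[2] == np.inf

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(8)
        tr = {k: rng.normal(-500 + 30 * k, 5, size=10).tolist()
              for k in range(1, 7)}
        dk = evanno_delta_k(tr)
        for k in range(2, 6):
            num = abs(np.mean(tr[k + 1]) - 2 * np.mean(tr[k])
                      + np.mean(tr[k - 1]))
            assert dk[k] == pytest.approx(num / np.std(tr[k], ddof=1))


class TestAdmixtureFilter:
    @pytest.mark.parametrize("row,expected", [
        ((0.6, 0.3, 0.1), True),     # clear majority
        ((0.45, 0.40, 0.15), False),  # major <= 0.5
        ((0.55, 0.40, 0.05), False),  # second >= 0.35
        ((0.5, 0.3, 0.2), False),     # threshold is strict
        ((0.6, 0.35, 0.05), False),   # threshold is strict
    ])
    def test_threshold_rules(self, row, expected):
        q = QMatrix([row], ["p"])
        kept, excluded = admixture_filter(q)
        assert (kept == ["p"]) is expected

    def test_idempotent_and_order_independent(self):
        rows = np.array([[0.7, 0.2, 0.1], [0.4, 0.4, 0.2],
                         [0.9, 0.05, 0.05]])
        q1 = QMatrix(rows, ["a", "b", "c"])
        q2 = QMatrix(rows[::-1], ["c", "b", "a"])
        assert set(admixture_filter(q1)[0]) == set(admixture_filter(q2)[0])

    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            QMatrix([[0.5, 0.4]], ["p"])


class TestQMatrixFixtures:
    def test_identity_profile(self):
        prof = np.eye(3)
        out = simulate_q_matrices(3, 3, prof)
        assert np.array_equal(out, prof)

    def test_jitter_rows_still_sum_to_one(self):
        prof = np.array([[0.6, 0.3, 0.1], [0.2, 0.5, 0.3]])
        out = simulate_q_matrices(2, 3, prof, seed=1, jitter=0.05)
        assert np.allclose(out.sum(axis=1), 1.0)
        assert not np.array_equal(out, prof)

    def test_bad_profile_rejected(self):
        with pytest.raises(ValueError):
            simulate_q_matrices(1, 2, [[0.7, 0.2]])

    def test_profiles_flow_through_filter(self):
        prof = np.array([[0.6, 0.3, 0.1], [0.45, 0.40, 0.15]])
        q = QMatrix(simulate_q_matrices(2, 3, prof), ["keepme", "admixed"])
        kept, excluded = admixture_filter(q)
        assert kept == ["keepme"] and excluded == ["admixed"]


class TestGeoGeneticGroups:
    @pytest.mark.parametrize("flags,valid", [
        ((True, True, False), True),
        ((True, False, False), False),
        ((False, True, True), True),
        ((True, True, True), True),
        ((False, False, False), False),
    ])
    def test_two_of_three_rule(self, flags, valid):
        crit = {"p1": GroupCriteria(*flags)}
        rep = assign_geo_genetic_groups(crit, {"G": ["p1"]})
        assert ("G" in rep["validated"]) is valid

    def test_group_flags_are_member_conjunction(self):
        crit = {"p1": GroupCriteria(True, True, False),
                "p2": GroupCriteria(True, False, False)}
        rep = assign_geo_genetic_groups(crit, {"G": ["p1", "p2"]})
        assert "G" in rep["rejected"]
        assert set(rep["rejected"]["G"]["failed"]) == {
            "divergent_branch", "geographically_isolated"}

    def test_overlapping_partition_rejected(self):
        crit = {"p1": GroupCriteria(True, True, True)}
        with pytest.raises(ValueError):
            assign_geo_genetic_groups(crit, {"G1": ["p1"], "G2": ["p1"]})

    def test_incomplete_partition_rejected(self):
        crit = {"p1": GroupCriteria(True, True, True),
                "p2": GroupCriteria(True, True, True)}
        with pytest.raises(ValueError):
            assign_geo_genetic_groups(crit, {"G1": ["p1"]})

    def test_isolation_helper(self):
        # distance to the nearest population of ANOTHER group decides
        coords = {"lone": (0.0, 0.0), "hub_a": (10.0, 0.0),
                  "hub_b": (11.0, 0.0)}
        groups = {"lone": "G1", "hub_a": "G2", "hub_b": "G3"}
        flags = isolation_helper(coords, groups, threshold=5.0)
        assert flags["lone"] is True       # nearest out-group at 10
        assert flags["hub_a"] is False     # hub_b (other group) at 1
        assert flags["hub_b"] is False
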