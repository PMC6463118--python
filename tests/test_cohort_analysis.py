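"""Endpoint derivation, control classification and group contrasts."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from htnpgx import (
    BPVisit,
    PatientRecord,
    compare_groups,
    control_status,
    current_year_delta,
    interval_average,
    match_status,
    mean_arterial_pressure,
    nadir_delta,
)
from htnpgx.cohort_analysis import group_contrast

D0 = dt.date(2020, 1, 1)


def visit(months, sbp, dbp):
    return BPVisit(D0 + dt.timedelta(days=round(months * 30.4375)), sbp, dbp)


def record(visits, diag=(160.0, 95.0), classes=("diuretic",), n_drugs=None, pid="p1"):
    return PatientRecord(
        patient_id=pid,
        diagnosis_bp=BPVisit(D0, *diag),
        visits=list(visits),
        current_classes=frozenset(classes),
        n_current_drugs=n_drugs if n_drugs is not None else len(classes),
    )


class TestMap:
    @pytest.mark.parametrize(
        "sbp,dbp,expected",
        [(128, 79, 95.33), (100, 100, 100.0), (120, 80, 93.33)],
    )
    def test_formula(self, sbp, dbp, expected):
        assert mean_arterial_pressure(sbp, dbp) == pytest.approx(expected, abs=0.005)

    @given(
        sbp=st.floats(60, 280),
        dbp=st.floats(40, 180),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounded_between_components(self, sbp, dbp):
        if dbp > sbp:
            sbp, dbp = dbp, sbp
        m = mean_arterial_pressure(sbp, dbp)
        assert dbp - 1e-9 <= m <= sbp + 1e-9


class TestIntervalAverage:
    def test_single_visit_per_bin_is_identity(self):
        visits = [visit(3, 150, 90), visit(9, 140, 85)]
        bins = interval_average(visits, D0)
        assert list(bins.index) == [0, 1]
        assert bins.loc[0, "sbp"] == 150 and bins.loc[1, "dbp"] == 85

    def test_two_visits_in_one_bin_are_averaged(self):
        visits = [visit(1, 130, 80), visit(2, 110, 70)]
        bins = interval_average(visits, D0)
        assert bins.loc[0, "sbp"] == pytest.approx(120)
        assert bins.loc[0, "dbp"] == pytest.approx(75)

    def test_fourteen_visit_fixture_hand_binned(self):
        # visits every ~2.6 months over 36 months: months 0,2.77,...,36
        months = [36 * k / 13 for k in range(14)]
        visits = [visit(m, 150 - k, 90 - k) for k, m in enumerate(months)]
        bins = interval_average(visits, D0)
        # hand binning: bin k holds visits with floor(month/6) == k
        expected = {}
        for k, m in enumerate(months):
            expected.setdefault(int(m // 6) if m < 36 else 6, []).append(k)
        # month exactly 36 lands in bin 6
        assert list(bins.index) == sorted(expected)
        for b, idxs in expected.items():
            assert bins.loc[b, "sbp"] == pytest.approx(
                np.mean([150 - i for i in idxs])
            )
        assert int(bins["n_visits"].sum()) == 14

    def test_empty_visits_error(self):
        with pytest.raises(ValueError):
            interval_average([], D0)


class TestDeltas:
    def test_monotone_falling_nadir_is_last_interval(self):
        visits = [visit(6 * k, 160 - 5 * k, 95 - 2 * k) for k in range(1, 7)]
        dsbp, ddbp, dmap = nadir_delta(record(visits))
        assert dsbp == pytest.approx(-30.0)
        assert ddbp == pytest.approx(-12.0)

    def test_flat_trajectory_deltas_zero(self):
        visits = [visit(6 * k, 160, 95) for k in range(1, 7)]
        assert nadir_delta(record(visits)) == pytest.approx((0.0, 0.0, 0.0))
        assert current_year_delta(record(visits)) == pytest.approx((0.0, 0.0, 0.0))

    def test_nadir_fixture_hand_computed(self):
        # diagnosis 160/95 (MAP 116.67); interval means: bin0 150/90
        # (MAP 110), bin2 130/83 (MAP 98.67, the nadir), bin4 135/85
        # hand deltas: (-30, -12, -18)
        visits = [visit(3, 150, 90), visit(15, 130, 83), visit(27, 135, 85)]
        dsbp, ddbp, dmap = nadir_delta(record(visits))
        assert (dsbp, ddbp) == (-30.0, -12.0)
        assert dmap == pytest.approx(-18.0)

    def test_nadir_on_map_not_on_sbp(self):
        # bin with lowest SBP is NOT the lowest-MAP bin
        visits = [visit(3, 118, 92), visit(15, 125, 70)]
        dsbp, _, _ = nadir_delta(record(visits))  # MAP picks the second bin
        assert dsbp == pytest.approx(125 - 160)
        dsbp_pc, _, _ = nadir_delta(record(visits), component="per_component")
        assert dsbp_pc == pytest.approx(118 - 160)

    def test_current_year_delta_single_recent_visit(self):
        visits = [visit(6, 150, 90), visit(30, 131, 78)]
        dsbp, ddbp, _ = current_year_delta(record(visits))
        assert dsbp == pytest.approx(131 - 160)
        assert ddbp == pytest.approx(78 - 95)


class TestControlStatus:
    @pytest.mark.parametrize(
        "sbp,dbp,jnc,sprint",
        [
            (128, 79, True, False),
            (119, 79, True, True),
            (140, 80, False, False),  # boundary is uncontrolled (strict)
            (130, 90, False, False),
        ],
    )
    def test_examples(self, sbp, dbp, jnc, sprint):
        assert control_status(sbp, dbp, "JNC") is jnc
        assert control_status(sbp, dbp, "SPRINT") is sprint

    @given(sbp=st.floats(60, 250), dbp=st.floats(40, 150))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_sprint_implies_jnc(self, sbp, dbp):
        if control_status(sbp, dbp, "SPRINT"):
            assert control_status(sbp, dbp, "JNC")


class TestMatchStatus:
    def test_depth_semantics(self):
        visits = [visit(6, 150, 90)]
        r_arb = record(visits, classes=("arb",))
        order = ["diuretic", "arb", "beta_blocker", "ace_inhibitor"]
        assert match_status(r_arb, order, depth=1) is False
        assert match_status(r_arb, order, depth=2) is True
        r_diur = record(visits, classes=("diuretic",))
        assert match_status(r_diur, order, depth=1) is True

    @given(
        classes=st.sets(
            st.sampled_from(["diuretic", "ace_inhibitor", "arb", "beta_blocker"]),
            min_size=1,
            max_size=3,
        ),
        perm=st.permutations(
            ["diuretic", "ace_inhibitor", "arb", "beta_blocker"]
        ),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_depth_monotone(self, classes, perm):
        r = record([visit(6, 150, 90)], classes=tuple(classes))
        if match_status(r, perm, depth=1):
            assert match_status(r, perm, depth=2)


class TestCompareGroups:
    @staticmethod
    def _cohort(n=24, matched_shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        records, orders = [], {}
        for i in range(n):
            matched = i % 2 == 0
            drop = 30 - matched * matched_shift + rng.normal(0, 2)
            dbp_drop = 10 + rng.normal(0, 1.5)
            visits = [
                visit(6 * k, 160 - drop * k / 6, 95 - dbp_drop * k / 6)
                for k in range(1, 7)
            ]
            pid = f"c{i:02d}"
            records.append(
                record(visits, classes=("diuretic" if matched else "arb",), pid=pid)
            )
            orders[pid] = ["diuretic", "ace_inhibitor", "beta_blocker", "arb"]
        return records, orders

    def test_identical_groups_show_no_effect(self):
        records, orders = self._cohort(matched_shift=0.0)
        rep = compare_groups(records, rankings=orders)
        c = rep.deltas["nadir"]["sbp"]
        assert abs(c["ols_coef"]) < 3
        assert c["p_bonferroni"] > 0.05
        assert rep.n_matched + rep.n_unmatched == rep.n_analyzed

    def test_injected_matched_advantage_recovered(self):
        records, orders = self._cohort(n=40, matched_shift=-12.0)
        rep = compare_groups(records, rankings=orders)
        c = rep.deltas["nadir"]["sbp"]
        assert c["ols_coef"] == pytest.approx(-12.0, abs=3.0)
        assert c["p_bonferroni"] < 0.05
        # OLS slope equals the group mean difference
        assert c["ols_coef"] == pytest.approx(
            c["matched_mean"] - c["unmatched_mean"]
        )

    def test_other_only_patients_excluded_and_counted(self):
        records, orders = self._cohort(n=20)
        extra = record(
            [visit(6 * k, 150, 90) for k in range(1, 7)],
            classes=("other",),
            pid="zz",
        )
        orders["zz"] = ["diuretic", "ace_inhibitor", "beta_blocker", "arb"]
        rep = compare_groups(records + [extra], rankings=orders)
        assert rep.n_excluded_other == 1
        assert rep.n_analyzed == 20

    def test_degenerate_group_raises(self):
        records, orders = self._cohort(n=20)
        unmatched_only = [r for r in records if "arb" in r.current_classes]
        with pytest.raises(ValueError, match="matched"):
            compare_groups(unmatched_only, rankings=orders)

    def test_monotherapy_subset_filters(self):
        records, orders = self._cohort(n=24)
        for r in records[:6]:  # six patients gain a second drug class
            r.current_classes = r.current_classes | {"beta_blocker"}
            r.n_current_drugs = 2
        rep = compare_groups(records, rankings=orders, subset="monotherapy")
        assert rep.n_analyzed == 18

    def test_permutation_null_sanity(self):
        """Label shuffles give a contrast centred on zero with honest spread."""
        records, orders = self._cohort(n=60, matched_shift=-10.0, seed=4)
        deltas = np.array([nadir_delta(r)[0] for r in records])
        matched = np.array(
            [match_status(r, orders[r.patient_id], 1) for r in records]
        )
        observed = deltas[matched].mean() - deltas[~matched].mean()
        rng = np.random.default_rng(99)
        perm = np.empty(1000)
        for i in range(1000):
            lab = rng.permutation(matched)
            perm[i] = deltas[lab].mean() - deltas[~lab].mean()
        assert abs(perm.mean()) < 0.5
        # the real labelling is far outside the permutation null
        assert np.mean(np.abs(perm) >= abs(observed)) < 0.01
        # and the null spread covers ~95% of shuffles within 2 SD
        inside = np.mean(np.abs(perm) < 2 * perm.std())
        assert 0.90 < inside < 0.99


def test_bp_visit_validation():
    with pytest.raises(ValueError):
        BPVisit(D0, 40, 30)  # SBP too low
    with pytest.raises(ValueError):
        BPVisit(D0, 120, 130)  # DBP above SBP
    with pytest.raises(ValueError):
        PatientRecord(
            patient_id="x",
            diagnosis_bp=BPVisit(D0, 160, 95),
            visits=[],
            current_classes=frozenset({"diuretic"}),
            n_current_drugs=0,
        )
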