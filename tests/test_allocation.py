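"""Therapy-allocation groups and Kaplan-Meier estimation."""

import numpy as np
import pytest

import receptorcall as rc
from receptorcall.allocation import AllocationGroup, SurvivalRecord
from receptorcall.errors import EmptyInputError

NEG, POS, MISS = rc.IHCStatus.NEGATIVE, rc.IHCStatus.POSITIVE, rc.IHCStatus.MISSING
GN, GZ, GP = rc.GeneState.GE_NEG, rc.GeneState.GE_ZERO, rc.GeneState.GE_POS


class TestAssignGroup:
    @pytest.mark.parametrize(
        "er_ihc,pgr_ihc,er_ge,pgr_ge,expected",
        [
            # hormone-positive confirmed: an IHC+ receptor with compatible GE
            (POS, NEG, GP, GN, AllocationGroup.HORMONE_POSITIVE_CONFIRMED),
            (POS, MISS, GZ, GN, AllocationGroup.HORMONE_POSITIVE_CONFIRMED),
            (NEG, POS, GN, GP, AllocationGroup.HORMONE_POSITIVE_CONFIRMED),
            # negative confirmed: both IHC-, GE nowhere crisply positive
            (NEG, NEG, GN, GN, AllocationGroup.NEGATIVE_CONFIRMED),
            (NEG, NEG, GZ, GZ, AllocationGroup.NEGATIVE_CONFIRMED),
            # positive contradicted: IHC says hormone positive, GE crisply double negative
            (POS, NEG, GN, GN, AllocationGroup.POSITIVE_CONTRADICTED),
            (NEG, POS, GN, GN, AllocationGroup.POSITIVE_CONTRADICTED),
            # negative contradicted: both IHC-, some GE crisply positive
            (NEG, NEG, GP, GN, AllocationGroup.NEGATIVE_CONTRADICTED),
            (NEG, NEG, GZ, GP, AllocationGroup.NEGATIVE_CONTRADICTED),
            # unassignable
            (MISS, MISS, GP, GP, None),
            (POS, MISS, GN, GZ, None),  # ER contradicted but PGR not crisply negative
        ],
    )
    def test_group_logic(self, er_ihc, pgr_ihc, er_ge, pgr_ge, expected):
        assert rc.assign_group(er_ihc, pgr_ihc, er_ge, pgr_ge) is expected

    def test_contradiction_takes_precedence_over_confirmation(self):
        """A patient whose PGR confirms but whose combined GE crisply negates
        the hormone-positive IHC status is flagged, not confirmed."""
        # ER IHC+ with GE-, PGR IHC+ with GE-: satisfies the confirmation
        # clause for neither receptor but the contradiction clause for both
        assert rc.assign_group(POS, POS, GN, GN) is AllocationGroup.POSITIVE_CONTRADICTED

    def test_pure_function_of_inputs(self):
        args = (POS, NEG, GP, GN)
        assert all(rc.assign_group(*args) is rc.assign_group(*args) for _ in range(5))

    def test_faithful_cohort_has_no_contradiction_groups(self):
        """When GE components are widely separated and IHC carries no label
        noise, no patient lands in a contradiction group."""
        model = rc.TwoComponentModel(
            neg=rc.GaussianComponent(0.0, 0.5),
            pos=rc.GaussianComponent(10.0, 0.5),
            weight_pos=0.4,
        )
        domain = rc.critical_domain(model, alpha=0.05)
        cfg = rc.SimConfig(n_samples=400, model=model, seed=3)
        expr_er, ihc_er, _ = rc.simulate_cohort(cfg)
        cfg2 = rc.SimConfig(n_samples=400, model=model, seed=4)
        expr_pgr, ihc_pgr, _ = rc.simulate_cohort(cfg2)
        er_calls = rc.call_cohort(model, domain, expr_er.values)
        pgr_calls = rc.call_cohort(model, domain, expr_pgr.values)
        groups = [
            rc.assign_group(ei, pi, ec, pc)
            for ei, pi, ec, pc in zip(ihc_er, ihc_pgr, er_calls, pgr_calls)
        ]
        assert AllocationGroup.POSITIVE_CONTRADICTED not in groups
        assert AllocationGroup.NEGATIVE_CONTRADICTED not in groups
        assert AllocationGroup.HORMONE_POSITIVE_CONFIRMED in groups


def hand_product_limit(times, events, t):
    """Direct product over risk sets at time t."""
    s = 1.0
    for u in sorted(set(times[events])):
        if u > t:
            break
        n_at_risk = np.sum(times >= u)
        d = np.sum((times == u) & events)
        s *= 1 - d / n_at_risk
    return s


class TestKaplanMeier:
    def test_all_censored_flat_at_one(self):
        curve = rc.kaplan_meier([SurvivalRecord(t, False) for t in [1, 2, 5, 9]])
        assert np.all(curve.survival == 1.0)
        assert np.all(curve.lower == 1.0)
        assert np.all(curve.upper == 1.0)

    def test_two_events_no_censoring(self):
        curve = rc.kaplan_meier([SurvivalRecord(1, True), SurvivalRecord(2, True)])
        assert np.allclose(curve.times, [0, 1, 2])
        assert np.allclose(curve.survival, [1.0, 0.5, 0.0])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_hand_product_limit(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        times = rng.integers(1, 6, n).astype(float)
        events = rng.random(n) < 0.7
        records = [SurvivalRecord(t, e) for t, e in zip(times, events)]
        curve = rc.kaplan_meier(records)
        for t in [0.5, 1, 2.5, 4, 6]:
            assert curve.at(t) == pytest.approx(hand_product_limit(times, events, t))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_lifelines_estimate_and_greenwood_variance(self, seed):
        """Cross-check the survival estimate against lifelines and the bands
        against Greenwood's formula computed from lifelines' event table."""
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(10 + seed)
        n = 40
        times = np.round(rng.exponential(20, n), 1) + 0.1
        events = rng.random(n) < 0.6
        curve = rc.kaplan_meier([SurvivalRecord(t, e) for t, e in zip(times, events)])
        kmf = KaplanMeierFitter().fit(times, events)
        for t in np.quantile(times, [0.1, 0.5, 0.9]):
            assert curve.at(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-10
            )
        et = kmf.event_table
        cum = ((et["observed"] / (et["at_risk"] * (et["at_risk"] - et["observed"])))
               .replace([np.inf], np.nan).fillna(0).cumsum())
        t_check = float(np.quantile(times, 0.5))
        s = float(kmf.predict(t_check))
        var = s**2 * float(cum[cum.index <= t_check].iloc[-1])
        idx = np.searchsorted(curve.times, t_check, side="right") - 1
        half_width = curve.survival[idx] - curve.lower[idx]
        assert half_width == pytest.approx(1.96 * np.sqrt(var), abs=1e-8)

    def test_curve_monotone_and_bands_bounded(self):
        rng = np.random.default_rng(99)
        records = [SurvivalRecord(t, e) for t, e in
                   zip(rng.exponential(10, 50), rng.random(50) < 0.5)]
        curve = rc.kaplan_meier(records)
        assert curve.survival[0] == 1.0
        assert np.all(np.diff(curve.survival) <= 0)
        assert np.all((curve.lower >= 0) & (curve.upper <= 1))
        assert np.all(curve.lower <= curve.survival)

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            rc.kaplan_meier([])

    def test_degenerate_all_zero_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            rc.kaplan_meier([SurvivalRecord(0.0, False), SurvivalRecord(0.0, False)])
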