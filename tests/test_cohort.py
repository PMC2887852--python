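"""Tests for paired comparisons, the add-up score and cohort summaries."""

import numpy as np
import pytest

from perfcmr.cohort import (
    COMPARISON_PARAMS,
    addup_score,
    paired_difference,
    summarize_cohort,
)
from perfcmr.curves import MYOCARDIAL_SEGMENT, PerfusionParams
from perfcmr.errors import DegenerateReferenceError
from perfcmr.territories import TerritoryDef


def params(rel_upslope=18.0, rel_si_max=22.0, t50=7.0, tmax=12.0, hr=77.0, roi="t"):
    return PerfusionParams(
        roi_id=roi, roi_kind=MYOCARDIAL_SEGMENT,
        upslope_abs=rel_upslope / 4, si_max_abs=rel_si_max * 5,
        t50=t50, tmax=tmax, rel_upslope=rel_upslope, rel_si_max=rel_si_max,
        t50_beats=t50 * hr / 60, tmax_beats=tmax * hr / 60,
    )


class TestPairedDifference:
    def test_longer_graft_time_is_negative(self):
        comp = paired_difference(params(t50=7.0), params(t50=8.0))
        assert comp.d_t50 == pytest.approx(-1.0)

    def test_lower_graft_upslope_is_negative(self):
        comp = paired_difference(params(rel_upslope=18.0), params(rel_upslope=16.0))
        assert comp.d_rel_upslope == pytest.approx(-2.0)

    def test_identical_params_all_zero(self):
        comp = paired_difference(params(), params())
        for f in ("d_rel_upslope", "d_rel_si_max", "d_t50", "d_tmax",
                  "d_t50_beats", "d_tmax_beats", "beat_delay"):
            assert getattr(comp, f) == 0.0

    def test_beat_delay_positive_when_graft_late(self):
        comp = paired_difference(params(tmax=12.0), params(tmax=13.0))
        assert comp.beat_delay == pytest.approx(1.0 * 77 / 60)
        assert comp.d_tmax_beats == pytest.approx(-comp.beat_delay)

    def test_swapping_arms_negates_every_delta(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a = params(*rng.uniform(5, 30, size=4))
            b = params(*rng.uniform(5, 30, size=4))
            ab, ba = paired_difference(a, b), paired_difference(b, a)
            for f in ("d_rel_upslope", "d_rel_si_max", "d_t50", "d_tmax",
                      "d_t50_beats", "d_tmax_beats", "beat_delay"):
                assert getattr(ab, f) == pytest.approx(-getattr(ba, f))


class TestAddupScore:
    def test_identical_params_score_zero(self):
        assert addup_score(params(), params()) == pytest.approx(0.0)

    def test_uniformly_worse_graft_strictly_negative(self):
        nat = params(rel_upslope=18, rel_si_max=22, t50=7.0)
        grf = params(rel_upslope=15, rel_si_max=20, t50=8.0)
        assert addup_score(nat, grf) < 0

    def test_hand_computed_value(self):
        nat = params(rel_upslope=20, rel_si_max=25, t50=8.0)
        grf = params(rel_upslope=18, rel_si_max=30, t50=6.0)
        want = (18 - 20) / 20 + (30 - 25) / 25 - (6 - 8) / 8
        assert addup_score(nat, grf) == pytest.approx(want)

    def test_opposite_signs_when_all_deltas_agree(self):
        rng = np.random.default_rng(8)
        checked = 0
        for _ in range(300):
            a = params(*rng.uniform(5, 30, size=3))
            b = params(*rng.uniform(5, 30, size=3))
            deltas = (
                b.rel_upslope - a.rel_upslope,
                b.rel_si_max - a.rel_si_max,
                -(b.t50 - a.t50),
            )
            if not (all(d > 0 for d in deltas) or all(d < 0 for d in deltas)):
                continue
            checked += 1
            assert addup_score(a, b) * addup_score(b, a) < 0
        assert checked > 10

    def test_zero_reference_rejected(self):
        nat = params(rel_upslope=0.0)
        with pytest.raises(DegenerateReferenceError):
            addup_score(nat, params())

    def test_weights_and_term_selection(self):
        nat, grf = params(t50=8.0), params(t50=10.0)
        only_t50 = addup_score(nat, grf, terms=("t50",))
        assert only_t50 == pytest.approx(-0.25)
        assert addup_score(nat, grf, terms=("t50",), weights=(2.0,)) == pytest.approx(-0.5)


def _territory(tid, kind="venous_graft", status="occluded"):
    return TerritoryDef(
        territory_id=tid, supply_kind=kind, native_vessel="LAD",
        native_status="not_applicable" if kind == "native" else status,
        segment_ids=frozenset([1]),
    )


class TestSummaries:
    def test_single_pair_per_patient_matches_pooled_means(self):
        rng = np.random.default_rng(4)
        pairs = {}
        for i in range(8):
            nat = params(*rng.uniform(10, 30, size=4), roi=f"n{i}")
            grf = params(*rng.uniform(10, 30, size=4), roi=f"g{i}")
            pairs[f"p{i}"] = [(_territory(f"g{i}"), nat, grf)]
        out = summarize_cohort(pairs, {})
        arms = out["arms"]
        row = arms[(arms.comparison == "native_vs_all_cabg") & (arms.arm == "native")]
        pooled = np.mean([plist[0][1].rel_si_max for plist in pairs.values()])
        assert row.rel_si_max_mean.iloc[0] == pytest.approx(pooled)

    def test_all_zero_deltas_flagged_not_crashing(self):
        pairs = {
            f"p{i}": [(_territory(f"g{i}"), params(roi="n"), params(roi="g"))]
            for i in range(5)
        }
        out = summarize_cohort(pairs, {})
        pv = out["pvalues"]
        row = pv[pv.comparison == "native_vs_all_cabg"].iloc[0]
        assert np.isnan(row["p_t50"])  # degenerate: every difference zero
        arms = out["arms"]
        sub = arms[arms.comparison == "native_vs_all_cabg"]
        assert sub.t50_mean.nunique() == 1  # means equal across arms

    def test_insufficient_n_flagged(self):
        pairs = {
            "p0": [(_territory("g0", kind="lima_graft"), params(), params(t50=8.0))],
            "p1": [(_territory("g1", kind="venous_graft"), params(), params(t50=8.5))],
        }
        out = summarize_cohort(pairs, {})
        pv = out["pvalues"].set_index("comparison")
        assert bool(pv.loc["native_vs_lima", "insufficient_n"])
        assert np.isnan(pv.loc["native_vs_lima", "p_t50"])

    def test_no_cad_vessel_classes_present(self):
        rng = np.random.default_rng(6)
        vessels = {
            f"c{i}": {
                v: params(*rng.uniform(10, 30, size=4), roi=v)
                for v in ("LAD", "LCX", "RCA")
            }
            for i in range(6)
        }
        out = summarize_cohort({}, vessels)
        comps = set(out["pvalues"].comparison)
        assert {"no_cad_LAD_vs_LCX", "no_cad_LAD_vs_RCA", "no_cad_LCX_vs_RCA"} <= comps
        row = out["arms"][(out["arms"].comparison == "no_cad_LAD_vs_LCX")]
        assert set(row.arm) == {"LAD", "LCX"} and (row.n == 6).all()
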