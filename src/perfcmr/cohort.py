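"""Paired native-vs-graft comparisons, the add-up score and cohort summaries.

The unit of comparison is a graft territory paired against the same patient's
native reference territory.  Differences follow a fixed sign convention: a
graft territory that enhances less (lower upslope or SImax) or later (longer
T_SI50%max or T_SImax) than the native territory yields a *negative* value,
so a uniformly worse graft is uniformly negative.  The per-patient "add-up
score" combines the upslope, SImax and T_SI50%max differences into one signed
composite to probe whether small deficits accumulate.

Separately, ``beat_delay`` records the graft-minus-native time-to-peak in
heart beats (positive = graft later), the quantity a reader perceives as
"images of delay" when scrolling the dynamic series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .curves import PerfusionParams, SignalTimeCurve
from .errors import DegenerateReferenceError, UndefinedTestError
from .stats import TestResult, mann_whitney_u, wilcoxon_signed_rank
from .territories import TerritoryDef

__all__ = [
    "PatientRecord",
    "PairedComparison",
    "ADDUP_TERMS_DEFAULT",
    "paired_difference",
    "addup_score",
    "COMPARISON_PARAMS",
    "summarize_class",
    "summarize_cohort",
]

#: parameters reported per comparison class (column order of summary tables)
COMPARISON_PARAMS = (
    "rel_si_max",
    "rel_upslope",
    "t50",
    "t50_beats",
    "tmax",
    "tmax_beats",
)

#: parameter -> reference-normalized signed term of the add-up score; timing
#: terms enter with a negative sign (longer time = worse)
ADDUP_TERMS_DEFAULT = ("rel_upslope", "rel_si_max", "t50")
_ADDUP_SIGN = {"rel_upslope": 1.0, "rel_si_max": 1.0, "t50": -1.0, "tmax": -1.0}

MIN_CLASS_N = 3


@dataclass
class PatientRecord:
    """All inputs of one patient: curves, heart rate, territories, LGE flags.

    ``group`` is ``"cabg"`` (post-bypass study group) or ``"no_cad"``
    (invasive exclusion of coronary disease, the normal-range group).
    ``lv_curve`` is the mid short-axis LV blood-pool curve used as timing and
    normalization reference.
    """

    patient_id: str
    group: str
    hr_adenosine: float
    lv_curve: SignalTimeCurve
    segment_curves: Dict[int, SignalTimeCurve]
    lge: Dict[int, bool]
    territories: List[TerritoryDef]

    def __post_init__(self) -> None:
        if self.group not in ("cabg", "no_cad"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.hr_adenosine <= 0:
            raise ValueError("heart rate must be positive")
        seen: set = set()
        for t in self.territories:
            if seen & t.segment_ids:
                raise ValueError(
                    f"{self.patient_id}: territories overlap on segments "
                    f"{sorted(seen & t.segment_ids)}"
                )
            seen |= t.segment_ids


@dataclass
class PairedComparison:
    """Signed graft-minus-native parameter differences for one graft.

    ``d_t50``/``d_tmax`` (and their beat versions) are negated so that a
    longer graft time is negative, aligning all parameters on the
    "negative = graft worse" convention.  ``beat_delay`` is the raw
    graft-minus-native time-to-peak in beats (positive = graft later).
    """

    patient_id: str
    territory_id: str
    graft_kind: str
    native_status: str
    d_rel_upslope: float
    d_rel_si_max: float
    d_t50: float
    d_tmax: float
    d_t50_beats: float
    d_tmax_beats: float
    beat_delay: float
    addup_score: Optional[float] = None


def paired_difference(
    native: PerfusionParams,
    graft: PerfusionParams,
    patient_id: str = "?",
    graft_kind: str = "venous_graft",
    native_status: str = "occluded",
) -> PairedComparison:
    """Component-wise graft-vs-native differences with the sign convention
    described in the module docstring.  The add-up score is left unset."""
    return PairedComparison(
        patient_id=patient_id,
        territory_id=graft.roi_id,
        graft_kind=graft_kind,
        native_status=native_status,
        d_rel_upslope=graft.rel_upslope - native.rel_upslope,
        d_rel_si_max=graft.rel_si_max - native.rel_si_max,
        d_t50=-(graft.t50 - native.t50),
        d_tmax=-(graft.tmax - native.tmax),
        d_t50_beats=-(graft.t50_beats - native.t50_beats),
        d_tmax_beats=-(graft.tmax_beats - native.tmax_beats),
        beat_delay=graft.tmax_beats - native.tmax_beats,
    )


def addup_score(
    native: PerfusionParams,
    graft: PerfusionParams,
    terms: Sequence[str] = ADDUP_TERMS_DEFAULT,
    weights: Optional[Sequence[float]] = None,
) -> float:
    """Patient-level composite of upslope, SImax and T_SI50%max differences.

    Each term is the graft-minus-native difference as a fraction of the
    native reference value, signed so that a worse graft contributes
    negatively (timing terms are negated: longer is worse)::

        score = (rUp_g - rUp_n)/rUp_n + (rSImax_g - rSImax_n)/rSImax_n
                - (t50_g - t50_n)/t50_n

    A graft territory uniformly worse than the native one therefore yields a
    strictly negative score, and identical parameters yield zero.  ``terms``
    and ``weights`` let alternative compositions be explored.
    """
    if weights is None:
        weights = [1.0] * len(terms)
    if len(weights) != len(terms):
        raise ValueError("weights and terms must have equal length")
    total = 0.0
    for term, w in zip(terms, weights):
        if term not in _ADDUP_SIGN:
            raise ValueError(f"unknown add-up term {term!r}")
        ref = getattr(native, term)
        val = getattr(graft, term)
        if ref is None or val is None:
            raise ValueError(f"missing parameter {term!r} for add-up score")
        if ref <= 0:
            raise DegenerateReferenceError(
                f"native reference {term} must be positive, got {ref:.3g}"
            )
        total += w * _ADDUP_SIGN[term] * (val - ref) / ref
    return total


# ---------------------------------------------------------------------------
# cohort summaries (Table-2/3-style)
# ---------------------------------------------------------------------------


def _mean_params(values: Sequence[PerfusionParams], roi_id: str) -> PerfusionParams:
    out = {}
    for name in PerfusionParams.MEAN_FIELDS:
        vals = [getattr(p, name) for p in values]
        out[name] = None if any(v is None for v in vals) else float(np.mean(vals))
    return PerfusionParams(roi_id=roi_id, roi_kind="territory", **out)


def _arm_stats(values: Sequence[float]) -> Tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0


def summarize_class(
    label: str,
    arm_a: str,
    arm_b: str,
    pairs: Sequence[Tuple[PerfusionParams, PerfusionParams]],
    params: Sequence[str] = COMPARISON_PARAMS,
) -> Tuple[List[dict], dict]:
    """Mean +/- SD per arm and paired Wilcoxon p per parameter for one
    comparison class.

    ``pairs`` holds (arm_a params, arm_b params) tuples, one per contributing
    patient/territory.  Classes with fewer than 3 pairs are flagged
    ``insufficient_n`` and reported without p-values rather than dropped;
    parameters whose differences are all zero are flagged ``degenerate``.
    Returns (list of two arm rows, p-value row).
    """
    n = len(pairs)
    rows = []
    pvals: dict = {"comparison": label, "n": n, "insufficient_n": n < MIN_CLASS_N}
    for arm_name, idx in ((arm_a, 0), (arm_b, 1)):
        row = {"comparison": label, "arm": arm_name, "n": n}
        for par in params:
            vals = [getattr(p[idx], par) for p in pairs]
            if n == 0 or any(v is None for v in vals):
                row[f"{par}_mean"], row[f"{par}_sd"] = np.nan, np.nan
            else:
                row[f"{par}_mean"], row[f"{par}_sd"] = _arm_stats(vals)
        rows.append(row)
    for par in params:
        key = f"p_{par}"
        if n < MIN_CLASS_N:
            pvals[key] = np.nan
            continue
        a = [getattr(p[0], par) for p in pairs]
        b = [getattr(p[1], par) for p in pairs]
        try:
            pvals[key] = wilcoxon_signed_rank(b, a).pvalue
        except UndefinedTestError:
            pvals[key] = np.nan  # degenerate: differences all zero
    return rows, pvals


def summarize_cohort(
    patient_pairs: Mapping[str, Sequence[Tuple[TerritoryDef, PerfusionParams, PerfusionParams]]],
    no_cad_vessels: Mapping[str, Mapping[str, PerfusionParams]],
    comparisons: Optional[pd.DataFrame] = None,
    holm: bool = False,
) -> Dict[str, pd.DataFrame]:
    """Build the full set of comparison tables of the analysis.

    Parameters
    ----------
    patient_pairs
        Per CABG patient: list of (graft territory, native params, graft
        params) tuples, already LGE-filtered.
    no_cad_vessels
        Per no-CAD patient: vessel name -> territory params (expected keys
        LAD/LCX/RCA when present).
    comparisons
        Optional per-graft :class:`PairedComparison` table; when given, delta
        and beat-delay statistics per class are summarized alongside.
    holm
        Apply a Holm step-down correction across the parameter p-values of
        each comparison class (off by default; the primary analysis reports
        unadjusted p-values).

    Returns a dict of DataFrames: ``arms`` (mean +/- SD per class and arm),
    ``pvalues`` (paired Wilcoxon per class and parameter), ``deltas``
    (per-class difference and beat-delay statistics, including add-up score),
    ``between_groups`` (native CABG vs. no-CAD Mann-Whitney).
    """
    arm_rows: List[dict] = []
    p_rows: List[dict] = []

    def add_class(label, arm_a, arm_b, pairs):
        rows, pvals = summarize_class(label, arm_a, arm_b, pairs)
        arm_rows.extend(rows)
        p_rows.append(pvals)

    # --- within-patient classes on the CABG group -------------------------
    all_pairs = [
        (nat, grf)
        for plist in patient_pairs.values()
        for (_t, nat, grf) in plist
    ]
    add_class("native_vs_all_cabg", "native", "cabg", all_pairs)
    for kind, label in (("lima_graft", "native_vs_lima"), ("venous_graft", "native_vs_venous")):
        pairs = [
            (nat, grf)
            for plist in patient_pairs.values()
            for (t, nat, grf) in plist
            if t.supply_kind == kind
        ]
        add_class(label, "native", kind.split("_")[0], pairs)
    # LIMA vs venous: within-kind patient means, patients with both kinds
    lima_venous = []
    for plist in patient_pairs.values():
        lima = [grf for (t, _n, grf) in plist if t.supply_kind == "lima_graft"]
        ven = [grf for (t, _n, grf) in plist if t.supply_kind == "venous_graft"]
        if lima and ven:
            lima_venous.append(
                (_mean_params(lima, "lima_mean"), _mean_params(ven, "venous_mean"))
            )
    add_class("lima_vs_venous", "lima", "venous", lima_venous)
    # stratified by the state of the bypassed native vessel (Table-3 logic)
    for status in ("stenosed", "occluded"):
        pairs = [
            (nat, grf)
            for plist in patient_pairs.values()
            for (t, nat, grf) in plist
            if t.native_status == status
        ]
        add_class(f"native_vs_cabg_{status}", "native", "cabg", pairs)

    # --- no-CAD group: LAD vs LCX vs RCA ----------------------------------
    for va, vb in (("LAD", "LCX"), ("LAD", "RCA"), ("LCX", "RCA")):
        pairs = [
            (v[va], v[vb])
            for v in no_cad_vessels.values()
            if va in v and vb in v
        ]
        add_class(f"no_cad_{va}_vs_{vb}", va, vb, pairs)

    result: Dict[str, pd.DataFrame] = {
        "arms": pd.DataFrame(arm_rows),
        "pvalues": pd.DataFrame(p_rows),
    }
    if holm:
        result["pvalues"] = _holm_rows(result["pvalues"])

    # --- per-class delta summaries (Figure-4/5/6-style) -------------------
    if comparisons is not None and len(comparisons):
        delta_rows = []
        classes = [("all_cabg", comparisons)]
        for kind in ("lima_graft", "venous_graft"):
            classes.append((kind, comparisons[comparisons.graft_kind == kind]))
        for status in ("stenosed", "occluded"):
            classes.append(
                (f"cabg_{status}", comparisons[comparisons.native_status == status])
            )
        for label, sub in classes:
            row = {"class": label, "n": len(sub)}
            for col in (
                "d_rel_upslope",
                "d_rel_si_max",
                "d_t50",
                "d_tmax",
                "d_tmax_beats",
                "beat_delay",
                "addup_score",
            ):
                if len(sub) == 0:
                    row[f"{col}_mean"], row[f"{col}_sd"], row[f"p_{col}"] = (
                        np.nan, np.nan, np.nan,
                    )
                    continue
                row[f"{col}_mean"] = float(sub[col].mean())
                row[f"{col}_sd"] = float(sub[col].std(ddof=1)) if len(sub) > 1 else 0.0
                try:
                    row[f"p_{col}"] = (
                        wilcoxon_signed_rank(sub[col].to_numpy()).pvalue
                        if len(sub) >= MIN_CLASS_N
                        else np.nan
                    )
                except UndefinedTestError:
                    row[f"p_{col}"] = np.nan
            delta_rows.append(row)
        result["deltas"] = pd.DataFrame(delta_rows)

    # --- between-group comparison (Mann-Whitney) --------------------------
    bg_rows = []
    native_cabg = [nat for plist in patient_pairs.values() for (_t, nat, _g) in plist]
    pooled_no_cad = [p for v in no_cad_vessels.values() for p in v.values()]
    for par in COMPARISON_PARAMS:
        a = [getattr(p, par) for p in native_cabg if getattr(p, par) is not None]
        b = [getattr(p, par) for p in pooled_no_cad if getattr(p, par) is not None]
        row = {"parameter": par, "n_cabg_native": len(a), "n_no_cad": len(b)}
        if len(a) >= MIN_CLASS_N and len(b) >= MIN_CLASS_N:
            res = mann_whitney_u(a, b)
            row["mean_cabg_native"], row["mean_no_cad"] = float(np.mean(a)), float(np.mean(b))
            row["p"] = res.pvalue
        else:
            row["mean_cabg_native"] = float(np.mean(a)) if a else np.nan
            row["mean_no_cad"] = float(np.mean(b)) if b else np.nan
            row["p"] = np.nan
        bg_rows.append(row)
    result["between_groups"] = pd.DataFrame(bg_rows)
    return result


def _holm_rows(pvalues: pd.DataFrame) -> pd.DataFrame:
    """Holm step-down correction within each comparison row."""
    out = pvalues.copy()
    pcols = [c for c in out.columns if c.startswith("p_")]
    for i in out.index:
        ps = out.loc[i, pcols].astype(float)
        mask = ps.notna()
        if mask.sum() == 0:
            continue
        order = ps[mask].sort_values().index
        m = len(order)
        adj_prev = 0.0
        for rank, col in enumerate(order):
            adj = min(1.0, (m - rank) * ps[col])
            adj_prev = max(adj_prev, adj)
            out.loc[i, col] = adj_prev
    return out
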