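"""16-segment model, perfusion territories, LGE exclusion and averaging.

Regional analysis uses the standard AHA 16-segment division of the three
short-axis slices: segments 1-6 basal, 7-12 mid-ventricular, 13-16 apical
(the apical-cap segment 17 of the 17-segment model is not used, since the
apex is not covered by short-axis perfusion slices).

Because coronary anatomy varies widely — especially after bypass surgery —
territories are defined per patient as explicit segment sets for each supply
route (native vessel, LIMA graft or venous graft) rather than from a fixed
atlas.  Segments with any late gadolinium enhancement (LGE), the imaging
marker of infarction, are excluded so that differences reflect the epicardial
supply route and not the myocardium itself.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

import numpy as np

from .curves import PerfusionParams
from .errors import InvalidCurveError, NoNativeReferenceError

__all__ = [
    "NATIVE",
    "LIMA_GRAFT",
    "VENOUS_GRAFT",
    "SUPPLY_KINDS",
    "NATIVE_VESSELS",
    "slice_level_of_segment",
    "AhaSegment",
    "TerritoryDef",
    "TerritoryExclusion",
    "average_territory",
    "select_native_reference",
]

NATIVE = "native"
LIMA_GRAFT = "lima_graft"
VENOUS_GRAFT = "venous_graft"
SUPPLY_KINDS = (NATIVE, LIMA_GRAFT, VENOUS_GRAFT)

NATIVE_VESSELS = ("LAD", "LCX", "RCA", "diagonal", "marginal")
NATIVE_STATUSES = ("patent", "stenosed", "occluded", "not_applicable")

#: deterministic preference order used to break ties between equally large
#: native territories
_VESSEL_PRIORITY = {v: i for i, v in enumerate(NATIVE_VESSELS)}


def slice_level_of_segment(segment_id: int) -> str:
    """Short-axis slice of an AHA segment: 1-6 basal, 7-12 mid, 13-16 apical."""
    if 1 <= segment_id <= 6:
        return "basal"
    if 7 <= segment_id <= 12:
        return "mid"
    if 13 <= segment_id <= 16:
        return "apical"
    raise ValueError(f"segment id must be 1-16, got {segment_id}")


@dataclass(frozen=True)
class AhaSegment:
    """One segment of the 16-segment model with its LGE status."""

    segment_id: int
    lge: bool = False
    slice_level: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "slice_level", slice_level_of_segment(self.segment_id))


@dataclass(frozen=True)
class TerritoryDef:
    """A vessel or graft and the 16-segment-model segments it supplies.

    ``native_status`` records the state of the bypassed native vessel for
    graft territories (``stenosed`` or ``occluded``; a functioning graft over
    a stenosed vessel admits competitive flow).  Native territories carry
    ``not_applicable``.
    """

    territory_id: str
    supply_kind: str
    native_vessel: str
    segment_ids: frozenset
    native_status: str = "not_applicable"

    def __post_init__(self) -> None:
        if self.supply_kind not in SUPPLY_KINDS:
            raise ValueError(f"unknown supply kind {self.supply_kind!r}")
        if self.native_vessel not in NATIVE_VESSELS:
            raise ValueError(f"unknown vessel {self.native_vessel!r}")
        if self.native_status not in NATIVE_STATUSES:
            raise ValueError(f"unknown native status {self.native_status!r}")
        segs = frozenset(int(s) for s in self.segment_ids)
        object.__setattr__(self, "segment_ids", segs)
        if not segs:
            raise ValueError(f"{self.territory_id}: empty segment set")
        for s in segs:
            slice_level_of_segment(s)  # validates range
        if self.supply_kind == NATIVE and self.native_status != "not_applicable":
            raise ValueError(
                f"{self.territory_id}: native territory cannot carry native_status "
                f"{self.native_status!r}"
            )


@dataclass(frozen=True)
class TerritoryExclusion:
    """Marker returned when a territory drops out of the analysis."""

    territory_id: str
    reason: str
    n_segments: int
    n_lge: int


def average_territory(
    params_by_segment: Mapping[int, PerfusionParams],
    territory: TerritoryDef,
    lge_flags: Mapping[int, bool],
    policy: str = "territory",
    min_clean_segments: int = 2,
) -> Union[PerfusionParams, TerritoryExclusion]:
    """Average segment parameters over a territory, honouring LGE exclusion.

    ``policy="territory"`` (default) excludes the whole territory as soon as
    any of its segments shows LGE, which matches whole-vessel exclusion
    accounting.  ``policy="segment"`` drops only the LGE segments and averages
    the rest, requiring at least ``min_clean_segments`` clean segments.

    Returns territory-mean :class:`PerfusionParams` (arithmetic mean of every
    numeric field over the clean segments) or a :class:`TerritoryExclusion`
    marker — exclusion is an expected outcome, not an error.
    """
    if policy not in ("territory", "segment"):
        raise ValueError(f"unknown LGE policy {policy!r}")
    segs = sorted(territory.segment_ids)
    for s in segs:
        if s not in params_by_segment:
            raise InvalidCurveError(
                f"{territory.territory_id}: no parameters for segment {s}"
            )
        if s not in lge_flags:
            raise InvalidCurveError(
                f"{territory.territory_id}: no LGE flag for segment {s}"
            )
    n_lge = sum(bool(lge_flags[s]) for s in segs)
    clean = [s for s in segs if not lge_flags[s]]
    if policy == "territory" and n_lge > 0:
        return TerritoryExclusion(
            territory.territory_id, "lge", n_segments=len(segs), n_lge=n_lge
        )
    if policy == "segment" and len(clean) < min_clean_segments:
        return TerritoryExclusion(
            territory.territory_id,
            f"fewer than {min_clean_segments} LGE-free segments",
            n_segments=len(segs),
            n_lge=n_lge,
        )

    out: Dict[str, Optional[float]] = {}
    for name in PerfusionParams.MEAN_FIELDS:
        vals = [getattr(params_by_segment[s], name) for s in clean]
        out[name] = None if any(v is None for v in vals) else float(np.mean(vals))
    first = params_by_segment[clean[0]]
    return PerfusionParams(
        roi_id=territory.territory_id,
        roi_kind="territory",
        t_arrival=first.t_arrival,
        peak_truncated=any(params_by_segment[s].peak_truncated for s in clean),
        **out,
    )


def select_native_reference(
    territories: Sequence[TerritoryDef],
    clean_segment_counts: Mapping[str, int],
    patient_id: str = "?",
) -> TerritoryDef:
    """Choose the native reference territory for paired graft comparisons.

    When a patient has more than one unbypassed native vessel, the one with
    the larger perfusion territory (most LGE-free segments, per
    ``clean_segment_counts`` keyed by territory id) is used.  Ties break by
    the fixed vessel order LAD > LCX > RCA (> diagonal > marginal).
    """
    natives = [t for t in territories if t.supply_kind == NATIVE]
    if not natives:
        raise NoNativeReferenceError(f"patient {patient_id}: no native territory")
    return min(
        natives,
        key=lambda t: (
            -clean_segment_counts.get(t.territory_id, 0),
            _VESSEL_PRIORITY[t.native_vessel],
        ),
    )
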