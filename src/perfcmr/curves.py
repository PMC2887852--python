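"""Semiquantitative parameters of first-pass perfusion signal-intensity curves.

A first-pass perfusion CMR acquisition samples each short-axis slice once per
heartbeat while a gadolinium bolus transits the left-ventricular (LV) cavity
and the myocardium.  The ROI-averaged signal-intensity (SI) time curve of the
LV blood pool and of each myocardial segment is reduced to a handful of
semiquantitative parameters:

* ``upslope`` — maximal rate of signal rise, from a sliding ordinary
  least-squares fit over a fixed number of consecutive frames (5 for
  myocardium, 3 for the shorter LV bolus);
* ``SImax`` — peak baseline-corrected enhancement;
* ``T_SI50%max`` / ``T_SImax`` — time from contrast arrival in the LV blood
  pool to 50% of peak / to peak myocardial enhancement;
* relative upslope and relative SImax — myocardial values in percent of the
  mid-slice LV blood-pool values, which normalizes away bolus and gain
  differences between patients;
* beat-converted times — timing parameters divided by the RR interval, since
  one frame per slice is acquired per heartbeat and reader impressions are
  formed in "images", not seconds.

All functions operate on :class:`SignalTimeCurve` and assume the baseline
(pre-contrast) mean has been subtracted with :func:`subtract_baseline` unless
stated otherwise.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import (
    DegenerateReferenceError,
    InconsistentInputError,
    InvalidCurveError,
    NoEnhancementError,
)

__all__ = [
    "LV_BLOOD_POOL",
    "MYOCARDIAL_SEGMENT",
    "SignalTimeCurve",
    "PerfusionParams",
    "ArrivalResult",
    "UpslopeResult",
    "PeakResult",
    "TruncatedPeakWarning",
    "subtract_baseline",
    "detect_lv_arrival",
    "max_upslope",
    "peak",
    "time_to_fraction",
    "relative_params",
    "seconds_to_beats",
    "lv_reference_params",
    "myocardial_params",
]

LV_BLOOD_POOL = "lv_blood_pool"
MYOCARDIAL_SEGMENT = "myocardial_segment"


class TruncatedPeakWarning(UserWarning):
    """Peak enhancement found on the final frame: the first pass may be cut."""


@dataclass(frozen=True)
class SignalTimeCurve:
    """One ROI's SI samples on a heartbeat-gated time grid.

    Parameters
    ----------
    roi_id
        Identifier of the ROI, e.g. ``"LV"`` or ``"seg07"``.
    roi_kind
        ``"lv_blood_pool"`` or ``"myocardial_segment"``.
    times
        Sample times in seconds, strictly increasing, one per cardiac cycle.
    si
        Signal intensity in arbitrary units, same length as ``times``.
    n_baseline
        Number of pre-contrast frames at the start of the series (>= 2).
    slice_level
        Short-axis slice the ROI belongs to (``basal``/``mid``/``apical``).
    """

    roi_id: str
    roi_kind: str
    times: np.ndarray
    si: np.ndarray
    n_baseline: int
    slice_level: str = "mid"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        si = np.asarray(self.si, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "si", si)
        if times.ndim != 1 or si.ndim != 1:
            raise InvalidCurveError(f"{self.roi_id}: times and si must be 1-D")
        if len(times) != len(si):
            raise InvalidCurveError(
                f"{self.roi_id}: times ({len(times)}) and si ({len(si)}) differ in length"
            )
        if self.n_baseline < 2:
            raise InvalidCurveError(
                f"{self.roi_id}: need at least 2 baseline frames, got {self.n_baseline}"
            )
        if len(times) < self.n_baseline + 5:
            raise InvalidCurveError(
                f"{self.roi_id}: curve of {len(times)} frames too short for "
                f"{self.n_baseline} baseline frames plus first pass"
            )
        if not (np.isfinite(times).all() and np.isfinite(si).all()):
            raise InvalidCurveError(f"{self.roi_id}: non-finite values in curve")
        if np.any(np.diff(times) <= 0):
            raise InvalidCurveError(f"{self.roi_id}: times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def baseline_mean(self) -> float:
        return float(np.mean(self.si[: self.n_baseline]))

    @property
    def baseline_sd(self) -> float:
        """Sample SD (ddof=1) of the pre-contrast frames."""
        return float(np.std(self.si[: self.n_baseline], ddof=1))

    @property
    def rr(self) -> float:
        """Median frame spacing in seconds (the RR interval)."""
        return float(np.median(np.diff(self.times)))

    def check_rr_jitter(self, rel_tol: float = 0.25) -> None:
        """Raise if frame spacings deviate from the median RR by more than
        ``rel_tol`` (fractional), i.e. the series is not heartbeat-gated."""
        dt = np.diff(self.times)
        if np.any(np.abs(dt - self.rr) > rel_tol * self.rr):
            raise InvalidCurveError(
                f"{self.roi_id}: frame spacing jitter exceeds {rel_tol:.0%} of RR"
            )


@dataclass
class PerfusionParams:
    """Semiquantitative perfusion parameters of one ROI (or territory mean).

    Times ``t50``/``tmax`` are measured from contrast arrival in the LV blood
    pool; ``*_beats`` are the same times divided by the RR interval of the
    patient's adenosine heart rate.  Relative fields are percent of the
    mid-slice LV blood-pool value and are defined for myocardial ROIs only.
    """

    roi_id: str
    roi_kind: str
    upslope_abs: float
    si_max_abs: float
    t_arrival: Optional[float] = None
    t50: Optional[float] = None
    tmax: Optional[float] = None
    rel_upslope: Optional[float] = None
    rel_si_max: Optional[float] = None
    t50_beats: Optional[float] = None
    tmax_beats: Optional[float] = None
    peak_truncated: bool = False

    #: numeric fields averaged when pooling segments into a territory
    MEAN_FIELDS = (
        "upslope_abs",
        "si_max_abs",
        "t50",
        "tmax",
        "rel_upslope",
        "rel_si_max",
        "t50_beats",
        "tmax_beats",
    )


@dataclass(frozen=True)
class ArrivalResult:
    time: float
    index: int


@dataclass(frozen=True)
class UpslopeResult:
    slope: float
    start_index: int


@dataclass(frozen=True)
class PeakResult:
    value: float
    time: float
    index: int
    truncated: bool


def subtract_baseline(curve: SignalTimeCurve) -> SignalTimeCurve:
    """Subtract the mean pre-contrast SI from the whole series.

    The mean of the first ``n_baseline`` frames is removed from every frame so
    that enhancement is measured from zero.  Idempotent on noise-free input.
    """
    mean = curve.baseline_mean
    return dataclasses.replace(curve, si=curve.si - mean)


def detect_lv_arrival(lv_curve: SignalTimeCurve, k_sigma: float = 3.0) -> ArrivalResult:
    """Detect contrast arrival in the LV blood pool.

    Arrival is the first frame at or after the baseline window whose SI
    exceeds ``baseline mean + k_sigma * baseline SD`` and whose successor also
    exceeds it.  The two-frame confirmation rejects single-frame noise spikes.
    With a noise-free baseline (SD = 0) the criterion degenerates to the first
    sustained strictly positive frame.

    Returns the arrival frame's time and index; raises
    :class:`NoEnhancementError` if no frame qualifies.
    """
    if k_sigma <= 0:
        raise ValueError(f"k_sigma must be positive, got {k_sigma}")
    threshold = lv_curve.baseline_mean + k_sigma * lv_curve.baseline_sd
    si = lv_curve.si
    for i in range(lv_curve.n_baseline, len(si) - 1):
        if si[i] > threshold and si[i + 1] > threshold:
            return ArrivalResult(time=float(lv_curve.times[i]), index=i)
    raise NoEnhancementError(
        f"{lv_curve.roi_id}: no sustained enhancement above baseline + "
        f"{k_sigma}*SD (threshold {threshold:.3g})"
    )


def _ols_slopes(times: np.ndarray, si: np.ndarray, window: int) -> np.ndarray:
    """OLS slope of si on times for every contiguous window, vectorized."""
    tw = np.lib.stride_tricks.sliding_window_view(times, window)
    yw = np.lib.stride_tricks.sliding_window_view(si, window)
    tc = tw - tw.mean(axis=1, keepdims=True)
    yc = yw - yw.mean(axis=1, keepdims=True)
    return np.einsum("ij,ij->i", tc, yc) / np.einsum("ij,ij->i", tc, tc)


def max_upslope(
    curve: SignalTimeCurve,
    window: int,
    mode: str = "max",
    arrival_index: Optional[int] = None,
) -> UpslopeResult:
    """Maximal windowed upslope of a baseline-corrected curve.

    Fits an ordinary least-squares line of SI on time to every run of
    ``window`` consecutive frames and returns the steepest slope in SI-units
    per second, together with the winning window's start index.  Windows may
    start no earlier than ``n_baseline - (window - 1)`` so a fit can bridge
    the bolus foot but cannot lie wholly inside the baseline.  Ties are broken
    toward the earliest start.

    ``mode="anchored"`` instead fits the single window starting at
    ``arrival_index`` (the bolus foot), the alternative convention for this
    parameter.
    """
    if window < 2:
        raise InvalidCurveError(f"upslope window must be >= 2, got {window}")
    if len(curve) < window:
        raise InvalidCurveError(
            f"{curve.roi_id}: curve of {len(curve)} frames shorter than window {window}"
        )
    slopes = _ols_slopes(curve.times, curve.si, window)
    if mode == "anchored":
        if arrival_index is None:
            raise ValueError("anchored mode requires arrival_index")
        start = min(arrival_index, len(slopes) - 1)
        return UpslopeResult(slope=float(slopes[start]), start_index=start)
    if mode != "max":
        raise ValueError(f"unknown upslope mode {mode!r}")
    start_min = max(0, curve.n_baseline - (window - 1))
    if start_min >= len(slopes):
        raise InvalidCurveError(f"{curve.roi_id}: no admissible upslope window")
    eligible = slopes[start_min:]
    best = int(np.argmax(eligible))  # argmax returns the first maximum: earliest tie wins
    return UpslopeResult(slope=float(eligible[best]), start_index=start_min + best)


def peak(
    curve: SignalTimeCurve,
    search_start: Optional[int] = None,
    first_pass_end: Optional[int] = None,
) -> PeakResult:
    """Peak enhancement (SImax) and its frame time within the first pass.

    The search range runs from ``search_start`` (default: the first
    post-baseline frame) to ``first_pass_end`` (exclusive; default: end of
    series).  Ties go to the earliest frame.  A peak on the final searched
    frame is flagged ``truncated`` and a :class:`TruncatedPeakWarning` is
    emitted, since the true maximum may lie beyond the acquisition.
    """
    lo = curve.n_baseline if search_start is None else search_start
    hi = len(curve) if first_pass_end is None else min(first_pass_end, len(curve))
    if not 0 <= lo < hi:
        raise InvalidCurveError(
            f"{curve.roi_id}: empty peak search range [{lo}, {hi})"
        )
    seg = curve.si[lo:hi]
    idx = lo + int(np.argmax(seg))
    truncated = idx == hi - 1
    if truncated:
        warnings.warn(
            f"{curve.roi_id}: peak on final searched frame; first pass may be truncated",
            TruncatedPeakWarning,
            stacklevel=2,
        )
    return PeakResult(
        value=float(curve.si[idx]),
        time=float(curve.times[idx]),
        index=idx,
        truncated=truncated,
    )


def time_to_fraction(
    curve: SignalTimeCurve,
    arrival_time: float,
    fraction: float = 0.5,
    interpolate: bool = True,
    peak_result: Optional[PeakResult] = None,
    search_start: Optional[int] = None,
    first_pass_end: Optional[int] = None,
) -> float:
    """Time from LV contrast arrival to ``fraction`` of peak enhancement.

    For ``fraction < 1`` the curve is walked forward to the first frame at or
    above ``fraction * SImax``; with ``interpolate=True`` (default) the
    crossing time is refined by linear interpolation between the straddling
    frames, giving sub-frame precision.  ``fraction == 1`` reproduces the time
    to peak, frame-snapped by definition.

    Raises :class:`InconsistentInputError` if ``arrival_time`` lies after the
    peak frame.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    pk = peak_result or peak(curve, search_start=search_start, first_pass_end=first_pass_end)
    if arrival_time > pk.time:
        raise InconsistentInputError(
            f"{curve.roi_id}: arrival time {arrival_time:.3f}s after peak {pk.time:.3f}s"
        )
    if fraction == 1.0:
        return pk.time - arrival_time
    target = fraction * pk.value
    si, times = curve.si, curve.times
    lo = curve.n_baseline if search_start is None else search_start
    for i in range(lo, pk.index + 1):
        if si[i] >= target:
            if interpolate and i > 0 and si[i] > si[i - 1] and si[i - 1] < target:
                t_star = times[i - 1] + (target - si[i - 1]) / (si[i] - si[i - 1]) * (
                    times[i] - times[i - 1]
                )
            else:
                t_star = times[i]
            return float(t_star) - arrival_time
    # peak frame itself reaches target by construction, so this is unreachable
    raise InconsistentInputError(f"{curve.roi_id}: no {fraction:.0%}-of-peak crossing found")


def relative_params(myo: PerfusionParams, lv_mid_slice: PerfusionParams) -> PerfusionParams:
    """Myocardial upslope and SImax in percent of the mid-slice LV values.

    Returns a copy of ``myo`` with ``rel_upslope`` and ``rel_si_max`` filled
    in.  Both LV references must be strictly positive.
    """
    if lv_mid_slice.upslope_abs <= 0 or lv_mid_slice.si_max_abs <= 0:
        raise DegenerateReferenceError(
            f"nonpositive LV reference (upslope {lv_mid_slice.upslope_abs:.3g}, "
            f"SImax {lv_mid_slice.si_max_abs:.3g})"
        )
    return dataclasses.replace(
        myo,
        rel_upslope=100.0 * myo.upslope_abs / lv_mid_slice.upslope_abs,
        rel_si_max=100.0 * myo.si_max_abs / lv_mid_slice.si_max_abs,
    )


def seconds_to_beats(t: float, hr: float) -> float:
    """Convert a time in seconds to heart beats (= images of one slice).

    One frame per slice is acquired every RR interval of ``60 / hr`` seconds,
    so ``t`` seconds corresponds to ``t * hr / 60`` beats (real-valued).
    """
    if hr <= 0:
        raise ValueError(f"heart rate must be positive, got {hr}")
    if t < 0:
        raise ValueError(f"time must be nonnegative, got {t}")
    return t * hr / 60.0


def lv_reference_params(
    lv_curve: SignalTimeCurve,
    window: int = 3,
    k_sigma: float = 3.0,
    upslope_mode: str = "max",
    first_pass_end: Optional[int] = None,
) -> PerfusionParams:
    """Full parameter extraction for the mid-slice LV blood-pool curve.

    Subtracts the baseline, detects contrast arrival, and measures upslope
    (3-frame window by default, matching the shorter LV bolus) and peak
    enhancement.  The returned params carry ``t_arrival``, the time origin
    for all myocardial timing parameters of the same patient.
    """
    corr = subtract_baseline(lv_curve)
    arrival = detect_lv_arrival(corr, k_sigma=k_sigma)
    ups = max_upslope(corr, window=window, mode=upslope_mode, arrival_index=arrival.index)
    pk = peak(corr, search_start=arrival.index, first_pass_end=first_pass_end)
    return PerfusionParams(
        roi_id=lv_curve.roi_id,
        roi_kind=LV_BLOOD_POOL,
        upslope_abs=ups.slope,
        si_max_abs=pk.value,
        t_arrival=arrival.time,
        peak_truncated=pk.truncated,
    )


def myocardial_params(
    curve: SignalTimeCurve,
    lv: PerfusionParams,
    hr: float,
    window: int = 5,
    fraction: float = 0.5,
    interpolate: bool = True,
    upslope_mode: str = "max",
    arrival_index: Optional[int] = None,
    first_pass_end: Optional[int] = None,
) -> PerfusionParams:
    """Full parameter extraction for one myocardial segment curve.

    ``lv`` must come from :func:`lv_reference_params` of the same patient: its
    ``t_arrival`` is the timing origin and its upslope/SImax the normalization
    reference.  ``hr`` is the heart rate under adenosine, used to convert
    timing parameters to beats.
    """
    if lv.t_arrival is None:
        raise InconsistentInputError("LV reference params carry no arrival time")
    corr = subtract_baseline(curve)
    ups = max_upslope(corr, window=window, mode=upslope_mode, arrival_index=arrival_index)
    pk = peak(corr, search_start=arrival_index, first_pass_end=first_pass_end)
    t50 = time_to_fraction(
        corr,
        arrival_time=lv.t_arrival,
        fraction=fraction,
        interpolate=interpolate,
        peak_result=pk,
    )
    tmax = pk.time - lv.t_arrival
    params = PerfusionParams(
        roi_id=curve.roi_id,
        roi_kind=MYOCARDIAL_SEGMENT,
        upslope_abs=ups.slope,
        si_max_abs=pk.value,
        t_arrival=lv.t_arrival,
        t50=t50,
        tmax=tmax,
        t50_beats=seconds_to_beats(max(t50, 0.0), hr),
        tmax_beats=seconds_to_beats(max(tmax, 0.0), hr),
        peak_truncated=pk.truncated,
    )
    return relative_params(params, lv)
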