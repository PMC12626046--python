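"""Vascular occlusion test (VOT) segmentation, biomarker extraction, and
baseline metabolism indices.

The VOT is a 3 min baseline, a 3 min supra-systolic arterial occlusion
(systolic + 50 mmHg) and a 5 min recovery.  Biomarkers: the deoxygenation
slope DeO2 (%/min, OLS over the first minute of occlusion), the
reoxygenation slope ReO2 (%/s, OLS from the StO2 minimum at deflation to the
first return to the recovery baseline), and the areas of the hyperemic
overshoot above the recovery baseline for StO2 (%*min) and BFI (cm^2).
Traces whose StO2 never regains the recovery baseline are flagged and their
ReO2/AUC values excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class VOTProtocol:
    baseline_s: float = 180.0
    occlusion_s: float = 180.0
    recovery_s: float = 300.0
    pressure_margin_mmhg: float = 50.0  # applied above systolic
    extension_step_s: float = 30.0

    def __post_init__(self) -> None:
        if min(self.baseline_s, self.occlusion_s, self.recovery_s) <= 0:
            raise ValueError("protocol durations must be positive")

    @property
    def total_s(self) -> float:
        return self.baseline_s + self.occlusion_s + self.recovery_s


@dataclass
class VOTTrace:
    """Synchronized multichannel VOT time series on a common time base."""

    t_s: np.ndarray
    sto2_pct: np.ndarray
    bfi_cm2_s: np.ndarray
    spo2_pct: np.ndarray | None = None
    hr_bpm: np.ndarray | None = None
    cuff_pressure_mmhg: np.ndarray | None = None
    markers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.sto2_pct = np.asarray(self.sto2_pct, dtype=float)
        self.bfi_cm2_s = np.asarray(self.bfi_cm2_s, dtype=float)
        n = self.t_s.size
        for name in ("sto2_pct", "bfi_cm2_s", "spo2_pct", "hr_bpm", "cuff_pressure_mmhg"):
            arr = getattr(self, name)
            if arr is not None and np.asarray(arr).size != n:
                raise ValueError(f"channel {name} does not share the time base")
        if self.markers:
            inf = self.markers.get("inflation")
            def_ = self.markers.get("deflation")
            if inf is not None and def_ is not None and not inf < def_:
                raise ValueError("markers must be ordered inflation < deflation")


@dataclass
class PhaseWindows:
    inflation_s: float
    deflation_s: float
    end_s: float
    baseline_sto2: float
    baseline_bfi: float
    recovery_baseline_sto2: float
    recovery_baseline_bfi: float


@dataclass
class VOTBiomarkers:
    baseline_sto2: float
    baseline_bfi: float
    deo2_pct_min: float
    min_sto2: float
    recovery_baseline_sto2: float
    valid_recovery: bool
    reo2_pct_s: float | None = None
    auc_sto2_pct_min: float | None = None
    auc_bfi_cm2: float | None = None


@dataclass
class MetabolismIndices:
    """Fick-law baseline metabolism: MMRO2 = [Hb]*(SpO2-StO2)/(gamma*SpO2)*BFI."""

    mmro2: float
    oef_pct: float
    gamma: float
    hb_gdl: float
    warning: bool = False


# ---------------------------------------------------------------------------


def _infer_markers_from_pressure(t: np.ndarray, pressure: np.ndarray) -> tuple[float, float]:
    """Inflation/deflation at the half-maximum crossings of the cuff pressure."""
    half = pressure.max() / 2.0
    above = pressure > half
    edges = np.diff(above.astype(int))
    rises = np.nonzero(edges == 1)[0]
    falls = np.nonzero(edges == -1)[0]
    if rises.size == 0 or falls.size == 0:
        raise ValueError("cuff-pressure channel has no occlusion plateau")
    t_inf = 0.5 * (t[rises[0]] + t[rises[0] + 1])
    t_def = 0.5 * (t[falls[-1]] + t[falls[-1] + 1])
    return float(t_inf), float(t_def)


def segment_and_baseline(
    trace: VOTTrace,
    protocol: VOTProtocol = VOTProtocol(),
    baseline_window_s: float = 30.0,
    recovery_window_s: float = 60.0,
) -> PhaseWindows:
    """Locate the VOT phases and compute the two baselines.

    The pre-occlusion baseline is the mean over the 30 s immediately before
    inflation; the recovery ("second") baseline is the mean over the final
    60 s of the recovery.  Markers are trusted when present, otherwise they
    are inferred from the cuff-pressure channel.
    """
    t = trace.t_s
    if "inflation" in trace.markers and "deflation" in trace.markers:
        t_inf = trace.markers["inflation"]
        t_def = trace.markers["deflation"]
    elif trace.cuff_pressure_mmhg is not None:
        t_inf, t_def = _infer_markers_from_pressure(t, trace.cuff_pressure_mmhg)
    else:
        raise ValueError("no inflation/deflation markers and no cuff-pressure channel")
    t_end = trace.markers.get("end", float(t[-1]))

    pre = (t >= t_inf - baseline_window_s) & (t < t_inf)
    if not pre.any():
        raise ValueError("no samples in the pre-occlusion baseline window")
    tail = t >= t_end - recovery_window_s
    return PhaseWindows(
        inflation_s=float(t_inf),
        deflation_s=float(t_def),
        end_s=float(t_end),
        baseline_sto2=float(trace.sto2_pct[pre].mean()),
        baseline_bfi=float(trace.bfi_cm2_s[pre].mean()),
        recovery_baseline_sto2=float(trace.sto2_pct[tail].mean()),
        recovery_baseline_bfi=float(trace.bfi_cm2_s[tail].mean()),
    )


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    slope, _ = np.polyfit(t, y, 1)
    return float(slope)


def compute_deo2(trace: VOTTrace, inflation_s: float, fit_span_s: float = 60.0) -> float:
    """Deoxygenation slope: OLS over the first minute of occlusion, in %/min."""
    sel = (trace.t_s >= inflation_s) & (trace.t_s <= inflation_s + fit_span_s)
    if sel.sum() < 10:
        raise ValueError("fewer than 10 samples in the DeO2 fit span")
    return _ols_slope(trace.t_s[sel], trace.sto2_pct[sel]) * 60.0


def _min_sto2_index(trace: VOTTrace, inflation_s: float, deflation_s: float) -> int:
    """Index of the occlusion StO2 minimum; ties resolve to the latest sample
    before deflation."""
    sel = np.nonzero((trace.t_s >= inflation_s) & (trace.t_s <= deflation_s))[0]
    vals = trace.sto2_pct[sel]
    return int(sel[np.nonzero(vals == vals.min())[0][-1]])


def compute_reo2(
    trace: VOTTrace,
    inflation_s: float,
    deflation_s: float,
    recovery_baseline: float,
) -> tuple[float | None, bool]:
    """Reoxygenation slope in %/s, or (None, False) if StO2 never regains the
    recovery baseline (the excluded-as-unreliable case)."""
    i_min = _min_sto2_index(trace, inflation_s, deflation_s)
    after = np.nonzero((np.arange(trace.t_s.size) >= i_min) & (trace.sto2_pct >= recovery_baseline))[0]
    if after.size == 0:
        return None, False
    i_cross = int(after[0])
    if i_cross - i_min < 2:
        return None, False
    seg = slice(i_min, i_cross + 1)
    return _ols_slope(trace.t_s[seg], trace.sto2_pct[seg]), True


def _interp_crossing(t0, t1, y0, y1, level):
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def compute_auc(
    trace: VOTTrace,
    deflation_s: float,
    recovery_baseline: float,
    channel: str = "sto2",
) -> tuple[float | None, bool]:
    """Area of the hyperemic overshoot above the recovery baseline.

    Integrates (signal - baseline) by the trapezoid rule between the first
    upward and the subsequent downward baseline crossing after deflation,
    with the crossing times located by linear interpolation.  StO2 area in
    %*min, BFI area in cm^2.  Missing second crossing -> excluded.
    """
    if channel == "sto2":
        y_full = trace.sto2_pct
    elif channel == "bfi":
        y_full = trace.bfi_cm2_s
    else:
        raise ValueError("channel must be 'sto2' or 'bfi'")
    sel = trace.t_s >= deflation_s
    t = trace.t_s[sel]
    y = y_full[sel] - recovery_baseline

    # tolerance guards against float rounding of the baseline mean
    tol = 1e-9 * np.max(np.abs(y), initial=0.0)
    y = np.where(np.abs(y) <= tol, 0.0, y)
    above = y > 0
    if not above.any():
        return 0.0, True  # signal never exceeds the baseline: zero excursion
    # first upward crossing; a jump at deflation counts from the first sample
    ups = np.nonzero(~above[:-1] & above[1:])[0]
    y_start = 0.0
    if above[0]:
        t_up = t[0]
        i_up = 0
        y_start = y[0]
    elif ups.size:
        i_up = int(ups[0])
        t_up = _interp_crossing(t[i_up], t[i_up + 1], y[i_up], y[i_up + 1], 0.0)
    else:
        return None, False
    downs = np.nonzero(above[:-1] & ~above[1:])[0]
    downs = downs[downs >= i_up]
    if downs.size == 0:
        return None, False
    i_dn = int(downs[0])
    if y[i_dn + 1] == 0.0:
        t_dn = t[i_dn + 1]
    else:
        t_dn = _interp_crossing(t[i_dn], t[i_dn + 1], y[i_dn], y[i_dn + 1], 0.0)

    # assemble the excursion with interpolated end points
    inner = (t > t_up) & (t < t_dn)
    tt = np.concatenate([[t_up], t[inner], [t_dn]])
    yy = np.concatenate([[y_start], y[inner], [0.0]])
    area = float(np.trapezoid(yy, tt))  # signal-units * s
    if channel == "sto2":
        area /= 60.0  # % * min
    return area, True


def extract_biomarkers(trace: VOTTrace, protocol: VOTProtocol = VOTProtocol()) -> VOTBiomarkers:
    """Full biomarker panel for one VOT trace."""
    phases = segment_and_baseline(trace, protocol)
    deo2 = compute_deo2(trace, phases.inflation_s)
    i_min = _min_sto2_index(trace, phases.inflation_s, phases.deflation_s)
    reo2, ok_reo2 = compute_reo2(
        trace, phases.inflation_s, phases.deflation_s, phases.recovery_baseline_sto2
    )
    auc_sto2, ok_a1 = compute_auc(trace, phases.deflation_s, phases.recovery_baseline_sto2, "sto2")
    auc_bfi, ok_a2 = compute_auc(trace, phases.deflation_s, phases.recovery_baseline_bfi, "bfi")
    valid = ok_reo2 and ok_a1
    return VOTBiomarkers(
        baseline_sto2=phases.baseline_sto2,
        baseline_bfi=phases.baseline_bfi,
        deo2_pct_min=deo2,
        min_sto2=float(trace.sto2_pct[i_min]),
        recovery_baseline_sto2=phases.recovery_baseline_sto2,
        valid_recovery=valid,
        reo2_pct_s=reo2 if valid else None,
        auc_sto2_pct_min=auc_sto2 if valid else None,
        auc_bfi_cm2=auc_bfi if (valid and ok_a2) else None,
    )


def compute_metabolism(
    sto2_pct: float,
    bfi_cm2_s: float,
    spo2_pct: float,
    hb_gdl: float,
    gamma: float = 0.75,
) -> MetabolismIndices:
    """Baseline metabolism indices from Fick's law.

    MMRO2 = [Hb] * (SpO2 - StO2) / (gamma * SpO2) * BFI, with [Hb] in g/dL
    and gamma the venous blood fraction; OEF = 100 * (SpO2 - StO2) /
    (gamma * SpO2).  SpO2 < StO2 yields a negative result with a warning
    flag rather than an error.
    """
    if spo2_pct <= 0:
        raise ValueError("SpO2 must be positive")
    if not 0 < gamma <= 1:
        raise ValueError("gamma must lie in (0, 1]")
    extraction = (spo2_pct - sto2_pct) / (gamma * spo2_pct)
    return MetabolismIndices(
        mmro2=hb_gdl * extraction * bfi_cm2_s,
        oef_pct=100.0 * extraction,
        gamma=gamma,
        hb_gdl=hb_gdl,
        warning=bool(spo2_pct < sto2_pct),
    )
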