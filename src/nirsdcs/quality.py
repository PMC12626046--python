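"""Quality-assessment-phase (QP) evaluation, optical interference analysis,
and longitudinal IRF/phantom trending.

During the QP the device alternates the DCS and TD-NIRS sources ON and OFF
in 10 s segments after an equalization phase; verdicts compare the measured
per-segment light levels against fixed thresholds.  Band limits are treated
as pass-inclusive at the edges and the dark/cross-talk ceilings as strict
upper bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import cv_series, group_compare


@dataclass(frozen=True)
class QPThresholds:
    dcs_dark_max_khz: float = 2.0
    dcs_signal_min_khz: float = 10.0
    dcs_signal_max_khz: float = 200.0
    dcs_crosstalk_dark_max_khz: float = 3.0
    tdnirs_count_min_mcps: float = 0.8
    tdnirs_count_max_mcps: float = 1.2
    tdnirs_dark_max_kcps: float = 30.0
    segment_s: float = 10.0

    def __post_init__(self) -> None:
        if not self.dcs_signal_min_khz < self.dcs_signal_max_khz:
            raise ValueError("DCS signal band must have min < max")
        if not self.tdnirs_count_min_mcps < self.tdnirs_count_max_mcps:
            raise ValueError("TD-NIRS count band must have min < max")
        if min(self.dcs_dark_max_khz, self.dcs_crosstalk_dark_max_khz, self.tdnirs_dark_max_kcps) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class QPResult:
    verdicts: dict[str, bool]  # {"TRS": ..., "DCS": ..., "Oxi": ...}
    measured: dict[str, float]
    blocking: bool
    failures: list[str] = field(default_factory=list)


def _segment_mean(counts: pd.DataFrame, column: str, t0: float, dur: float, trim_s: float = 1.0) -> float:
    """Mean level over the central part of a segment (transients trimmed)."""
    sel = (counts["t_s"] >= t0 + trim_s) & (counts["t_s"] < t0 + dur - trim_s)
    if not sel.any():
        raise ValueError(f"no samples in segment at t={t0}")
    return float(counts.loc[sel, column].mean())


def evaluate_qp(
    segments: pd.DataFrame,
    counts: pd.DataFrame,
    thresholds: QPThresholds = QPThresholds(),
    oxi_valid: bool | None = None,
) -> QPResult:
    """Evaluate the quality-assessment phase.

    ``segments`` has one row per labeled segment (``t_s, label,
    duration_s`` with labels equalization / all_off / dcs_on / td_on);
    ``counts`` the count-level channels (``dcs_khz``, ``td685_mcps``,
    ``td828_mcps``, optionally ``oxi_valid``).  Segment means use the
    central 8 s of each 10 s segment to skip switching transients.  Any
    failed indicator blocks the measurement.
    """
    required = {"all_off", "dcs_on", "td_on"}
    labels = set(segments["label"])
    missing = required - labels
    if missing:
        raise ValueError(f"QP session is missing segment labels: {sorted(missing)}")

    def level(label: str, column: str) -> float:
        rows = segments[segments["label"] == label]
        vals = [
            _segment_mean(counts, column, float(r["t_s"]), float(r["duration_s"]))
            for _, r in rows.iterrows()
        ]
        return float(np.mean(vals))

    measured = {
        "dcs_dark_khz": level("all_off", "dcs_khz"),
        "dcs_signal_khz": level("dcs_on", "dcs_khz"),
        "dcs_crosstalk_khz": level("td_on", "dcs_khz"),
        "td685_signal_mcps": level("td_on", "td685_mcps"),
        "td828_signal_mcps": level("td_on", "td828_mcps"),
        "td685_dark_kcps": level("all_off", "td685_mcps") * 1e3,
        "td828_dark_kcps": level("all_off", "td828_mcps") * 1e3,
    }

    failures: list[str] = []
    th = thresholds
    if not measured["dcs_dark_khz"] < th.dcs_dark_max_khz:
        failures.append("dcs_dark")
    if not th.dcs_signal_min_khz <= measured["dcs_signal_khz"] <= th.dcs_signal_max_khz:
        failures.append("dcs_signal")
    if not measured["dcs_crosstalk_khz"] < th.dcs_crosstalk_dark_max_khz:
        failures.append("dcs_crosstalk")
    dcs_pass = not any(f.startswith("dcs") for f in failures)

    for wl in ("685", "828"):
        if not th.tdnirs_count_min_mcps <= measured[f"td{wl}_signal_mcps"] <= th.tdnirs_count_max_mcps:
            failures.append(f"td{wl}_signal")
        if not measured[f"td{wl}_dark_kcps"] < th.tdnirs_dark_max_kcps:
            failures.append(f"td{wl}_dark")
    trs_pass = not any(f.startswith("td") for f in failures)

    if oxi_valid is None:
        oxi_valid = bool(counts["oxi_valid"].all()) if "oxi_valid" in counts else True
    if not oxi_valid:
        failures.append("oxi")

    verdicts = {"TRS": trs_pass, "DCS": dcs_pass, "Oxi": bool(oxi_valid)}
    return QPResult(
        verdicts=verdicts,
        measured=measured,
        blocking=not all(verdicts.values()),
        failures=failures,
    )


@dataclass
class InterferenceResult:
    comparison: str
    statistic: float
    p_value: float
    significant: bool


def interference_test(
    comparisons: dict[str, tuple[np.ndarray, np.ndarray]],
    alpha: float = 0.05,
) -> list[InterferenceResult]:
    """Mann-Whitney comparison of background counts with the counterpart
    laser OFF vs ON, one entry per (module, wavelength) comparison."""
    results = []
    for name, (off, on) in comparisons.items():
        off = np.asarray(off, dtype=float)
        on = np.asarray(on, dtype=float)
        if off.size < 3 or on.size < 3:
            raise ValueError(f"comparison {name!r}: each group needs >= 3 observations")
        r = group_compare(off, on, paired=False, alpha=alpha)
        results.append(InterferenceResult(name, r.statistic, r.p_value, r.significant))
    return results


@dataclass
class TrendReport:
    fwhm_cv_pct: dict[float, float | None]
    barycenter_sd_ns: dict[float, float]
    mua_cv_pct: dict[float, float | None]
    musp_cv_pct: dict[float, float | None]
    thb_ph_cv_pct: float | None
    sto2_ph_cv_pct: float | None
    n_sessions: int


def phantom_trending(sessions: pd.DataFrame) -> TrendReport:
    """Longitudinal stability of the IRF and phantom metrics.

    ``sessions`` has one row per session with columns ``fwhm_685, fwhm_828``
    (ps), ``barycenter_685, barycenter_828`` (ns), ``mua_685, mua_828,
    musp_685, musp_828`` (cm^-1), ``thb_ph`` (uM), ``sto2_ph`` (%).
    Reports the CV over sessions (sd for the barycenter, in ns).
    """
    if len(sessions) < 2:
        raise ValueError("trending requires at least 2 sessions")

    def cv(col):
        return cv_series(sessions[col]).cv_pct

    return TrendReport(
        fwhm_cv_pct={685.0: cv("fwhm_685"), 828.0: cv("fwhm_828")},
        barycenter_sd_ns={
            685.0: float(sessions["barycenter_685"].std(ddof=1)),
            828.0: float(sessions["barycenter_828"].std(ddof=1)),
        },
        mua_cv_pct={685.0: cv("mua_685"), 828.0: cv("mua_828")},
        musp_cv_pct={685.0: cv("musp_685"), 828.0: cv("musp_828")},
        thb_ph_cv_pct=cv("thb_ph"),
        sto2_ph_cv_pct=cv("sto2_ph"),
        n_sessions=len(sessions),
    )


def compare_calibrations(daily: np.ndarray, monthly_first: np.ndarray, alpha: float = 0.05):
    """Paired signed-rank comparison of a metric processed with the daily
    IRF vs the first IRF of the month.  Identical outputs give p = 1."""
    daily = np.asarray(daily, dtype=float)
    monthly_first = np.asarray(monthly_first, dtype=float)
    if daily.size != monthly_first.size:
        raise ValueError("unmatched session pairs in the paired comparison")
    return group_compare(daily, monthly_first, paired=True, alpha=alpha)
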