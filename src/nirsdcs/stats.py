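"""Precision and agreement statistics.

Coefficient-of-variation summaries, test-retest (repositioning) analysis,
limb-occlusion-pressure step precision with rank correlations, device
resampling, Bland-Altman agreement, and rank-based group comparison.
Sample standard deviations use the n-1 denominator throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class CVResult:
    mean: float
    sd: float
    cv_pct: float | None  # None when the mean is zero (undefined)
    n: int

    @property
    def defined(self) -> bool:
        return self.cv_pct is not None


@dataclass(frozen=True)
class LOPProtocol:
    """Stepped partial-occlusion protocol: 60 s holds at fractions of the
    limb occlusion pressure, precision evaluated over the last 15 s."""

    step_fractions: tuple[float, ...] = (0.40, 0.60, 0.80, 1.00)
    step_s: float = 60.0
    eval_window_s: float = 15.0
    lop_mmhg: float | None = None

    def __post_init__(self) -> None:
        if any(not 0 < f <= 1 for f in self.step_fractions):
            raise ValueError("step fractions must lie in (0, 1]")
        if self.eval_window_s > self.step_s:
            raise ValueError("evaluation window cannot exceed the step duration")


@dataclass
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    slope: float
    slope_r: float
    slope_p: float
    n: int


@dataclass
class RankTestResult:
    test: str
    statistic: float
    p_value: float
    significant: bool
    alpha: float = 0.05


def cv_series(x) -> CVResult:
    """Coefficient of variation: 100 * sd / mean (sample sd)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("CV requires at least 2 samples")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    cv = None if mean == 0 else 100.0 * sd / mean
    return CVResult(mean=mean, sd=sd, cv_pct=cv, n=int(x.size))


@dataclass
class TestRetestResult:
    intra_cv_pct: list[float]
    intra_cv_max_pct: float
    inter_cv_pct: float | None
    block_means: list[float]


def test_retest(blocks: list[np.ndarray]) -> TestRetestResult:  # noqa: the field calls this analysis "test-retest"
    """Repositioning variability: within-block CVs and the CV of block means."""
    if len(blocks) < 2:
        raise ValueError("test-retest requires at least 2 repositionings")
    intra = []
    means = []
    for b in blocks:
        b = np.asarray(b, dtype=float)
        if b.size < 2:
            raise ValueError("each repositioning block needs at least 2 samples")
        r = cv_series(b)
        intra.append(r.cv_pct if r.cv_pct is not None else np.nan)
        means.append(r.mean)
    inter = cv_series(np.asarray(means))
    return TestRetestResult(
        intra_cv_pct=intra,
        intra_cv_max_pct=float(np.nanmax(intra)),
        inter_cv_pct=inter.cv_pct,
        block_means=means,
    )


# not a pytest case despite the field-conventional name
test_retest.__test__ = False


def _exact_spearman_p(rho_obs: float, n: int) -> float:
    """Two-sided permutation p-value for Spearman rho at small n."""
    ranks = np.arange(n, dtype=float)
    denom = np.sum((ranks - ranks.mean()) ** 2)
    count = 0
    total = 0
    for perm in permutations(range(n)):
        r = np.asarray(perm, dtype=float)
        rho = 1 - 6 * np.sum((ranks - r) ** 2) / (n * (n**2 - 1))
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Spearman rank correlation with an exact permutation p at small n.

    Exact enumeration is used for n <= ``exact_max_n`` (ties broken by
    average ranks as usual); the large-sample approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), 1.0  # correlation undefined for a constant input
    rho, p_approx = sps.spearmanr(x, y)
    n = x.size
    if n <= exact_max_n and not np.isnan(rho):
        return float(rho), float(_exact_spearman_p(rho, n))
    return float(rho), float(p_approx)


@dataclass
class LOPStepResult:
    phase: str
    lop_fraction: float
    sto2_mean: float
    sto2_cv_pct: float | None
    bfi_mean: float
    bfi_cv_pct: float | None
    count_rate_khz: float | None = None
    dynamic_range: float | None = None


@dataclass
class LOPPrecisionReport:
    steps: list[LOPStepResult]
    correlations: dict[str, tuple[float, float]]


def lop_precision(
    trace: pd.DataFrame,
    steps: pd.DataFrame,
    protocol: LOPProtocol = LOPProtocol(),
) -> LOPPrecisionReport:
    """Per-step precision of StO2 and BFI plus rank-correlation structure.

    ``trace`` needs columns ``t_s, sto2, bfi``; ``steps`` one row per
    inflation/deflation hold with ``t_s`` (start), ``phase``,
    ``lop_fraction`` and optional ``count_rate_khz`` / ``dynamic_range``.
    CVs are computed over the final ``eval_window_s`` of each hold, and
    Spearman rho/p are reported between the CVs and the mean values and
    signal-quality metrics.
    """
    results: list[LOPStepResult] = []
    for _, row in steps.iterrows():
        t0 = row["t_s"]
        t_end = t0 + protocol.step_s
        sel = (trace["t_s"] >= t_end - protocol.eval_window_s) & (trace["t_s"] < t_end)
        if not sel.any():
            raise ValueError(f"no samples for the step starting at t={t0}")
        sto2 = cv_series(trace.loc[sel, "sto2"])
        bfi = cv_series(trace.loc[sel, "bfi"])
        results.append(
            LOPStepResult(
                phase=str(row["phase"]),
                lop_fraction=float(row["lop_fraction"]),
                sto2_mean=sto2.mean,
                sto2_cv_pct=sto2.cv_pct,
                bfi_mean=bfi.mean,
                bfi_cv_pct=bfi.cv_pct,
                count_rate_khz=float(row["count_rate_khz"]) if "count_rate_khz" in row else None,
                dynamic_range=float(row["dynamic_range"]) if "dynamic_range" in row else None,
            )
        )
    correlations: dict[str, tuple[float, float]] = {}
    cv_bfi = [r.bfi_cv_pct for r in results]
    cv_sto2 = [r.sto2_cv_pct for r in results]
    pairs = {
        "cv_bfi_vs_bfi": (cv_bfi, [r.bfi_mean for r in results]),
        "cv_sto2_vs_sto2": (cv_sto2, [r.sto2_mean for r in results]),
    }
    if all(r.count_rate_khz is not None for r in results):
        pairs["cv_bfi_vs_count_rate"] = (cv_bfi, [r.count_rate_khz for r in results])
    if all(r.dynamic_range is not None for r in results):
        pairs["cv_sto2_vs_dynamic_range"] = (cv_sto2, [r.dynamic_range for r in results])
    for name, (a, b) in pairs.items():
        correlations[name] = spearman(a, b)
    return LOPPrecisionReport(steps=results, correlations=correlations)


def bland_altman(device_a, device_b, alpha_sd: float = 1.96) -> BlandAltmanResult:
    """Bland-Altman agreement of two paired series.

    Reports the bias (mean difference a-b), the +/-1.96 sd limits of
    agreement, and the OLS slope of difference on mean with its correlation
    and p-value (the proportional-bias test).
    """
    a = np.asarray(device_a, dtype=float)
    b = np.asarray(device_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired series must have equal lengths")
    if a.size < 3:
        raise ValueError("Bland-Altman requires n >= 3")
    diff = a - b
    mean = 0.5 * (a + b)
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if np.ptp(mean) == 0:
        slope, r, p = 0.0, 0.0, 1.0
    else:
        fit = sps.linregress(mean, diff)
        slope, r, p = float(fit.slope), float(fit.rvalue), float(fit.pvalue)
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - alpha_sd * sd,
        loa_high=bias + alpha_sd * sd,
        slope=slope,
        slope_r=r,
        slope_p=p,
        n=int(a.size),
    )


def resample_to_device(t_src, x_src, t_target, method: str = "hold"):
    """Resample a series onto a slower device's timestamps.

    Default is nearest-preceding (sample-and-hold), mimicking a slow display
    device; ``method='linear'`` interpolates instead.  Values at coincident
    timestamps are preserved exactly; extrapolation outside the source span
    raises.
    """
    t_src = np.asarray(t_src, dtype=float)
    x_src = np.asarray(x_src, dtype=float)
    t_target = np.asarray(t_target, dtype=float)
    if t_target.min() < t_src.min() or t_target.max() > t_src.max():
        raise ValueError("target times extend beyond the source span")
    if method == "linear":
        return np.interp(t_target, t_src, x_src)
    if method != "hold":
        raise ValueError("method must be 'hold' or 'linear'")
    idx = np.searchsorted(t_src, t_target, side="right") - 1
    return x_src[idx]


def group_compare(group_a, group_b, paired: bool = False, alpha: float = 0.05) -> RankTestResult:
    """Rank-based group comparison: Mann-Whitney U (unpaired) or Wilcoxon
    signed-rank (paired), two-sided at the given significance level."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal lengths")
        d = a - b
        if np.all(d == 0):
            return RankTestResult("wilcoxon", 0.0, 1.0, False, alpha)
        stat, p = sps.wilcoxon(a, b)
        name = "wilcoxon"
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "mannwhitneyu"
    return RankTestResult(name, float(stat), float(p), bool(p < alpha), alpha)
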