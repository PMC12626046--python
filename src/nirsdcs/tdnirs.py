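"""TD-NIRS analysis: DTOF preprocessing, IRF metrics, convolution fitting
for absolute optical properties, and chromophore / StO2 computation.

The fit forward model is the semi-infinite diffusion solution circularly
convolved with the measured IRF over one laser period; amplitude is profiled
out analytically at every iteration and (mua, musp) are optimized in log
space by damped least squares with Poisson weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import extinction
from .forward import semi_infinite_reflectance
from .geometry import ProbeGeometry


# ---------------------------------------------------------------------------
# domain types


@dataclass
class DTOFHistogram:
    """Binned photon time-of-flight counts for one acquisition at one wavelength."""

    bin_edges_ns: np.ndarray
    counts: np.ndarray
    wavelength_nm: float
    timestamp_s: float = 0.0
    integration_time_s: float = 1.0
    background_window: tuple[int, int] = (0, 100)

    def __post_init__(self) -> None:
        self.bin_edges_ns = np.asarray(self.bin_edges_ns, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.size != self.bin_edges_ns.size - 1:
            raise ValueError("counts must have len(bin_edges) - 1 entries")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def bin_centers_ns(self) -> np.ndarray:
        e = self.bin_edges_ns
        return 0.5 * (e[:-1] + e[1:])


@dataclass
class IRFRecord:
    """Instrument response function histogram with its summary metrics.

    The barycenter tracks the stability of the laser/detection/timing chain;
    the FWHM is the temporal resolution of the system.
    """

    bin_edges_ns: np.ndarray
    histogram: np.ndarray
    barycenter_ns: float
    fwhm_ps: float
    acquisition_date: str | None = None

    def __post_init__(self) -> None:
        self.bin_edges_ns = np.asarray(self.bin_edges_ns, dtype=float)
        self.histogram = np.asarray(self.histogram, dtype=float)
        if self.fwhm_ps <= 0:
            raise ValueError("FWHM must be positive")
        if not (self.bin_edges_ns[0] <= self.barycenter_ns <= self.bin_edges_ns[-1]):
            raise ValueError("barycenter must lie within the time grid")

    @property
    def normalized(self) -> np.ndarray:
        return self.histogram / self.histogram.sum()


@dataclass(frozen=True)
class OpticalProperties:
    """Absolute absorption and reduced scattering at one wavelength (cm^-1)."""

    mua: float
    musp: float
    wavelength_nm: float

    def __post_init__(self) -> None:
        if self.mua <= 0 or self.musp <= 0:
            raise ValueError("optical properties must be positive")


@dataclass
class ChromophoreState:
    """Hemoglobin concentrations (uM) and microvascular saturation (%)."""

    hbo_um: float
    hbr_um: float
    negative_warning: bool = False

    @property
    def thb_um(self) -> float:
        return self.hbo_um + self.hbr_um

    @property
    def sto2_pct(self) -> float:
        return 100.0 * self.hbo_um / self.thb_um


@dataclass
class FitDiagnostics:
    reduced_chi2: float
    dynamic_range: float
    fit_window: tuple[int, int]
    iterations: int
    converged: bool
    background_mean: float = 0.0
    background_sd: float = 0.0


@dataclass
class PhantomQCRecord:
    """Effective hemoglobin-equivalent values of the solid phantom.

    The per-repetition mua pairs are pushed through the same chromophore
    inversion as tissue (water term zero), yielding 'effective' tHb and StO2
    used as day-to-day stability metrics rather than physical concentrations.
    """

    thb_ph_um: float
    sto2_ph_pct: float
    thb_cv_pct: float
    sto2_cv_pct: float
    per_repetition: list[ChromophoreState] = field(default_factory=list)
    session_date: str | None = None


# ---------------------------------------------------------------------------
# operations


def compute_irf_metrics(
    bin_edges_ns: np.ndarray,
    histogram: np.ndarray,
    background_bins: int = 100,
    acquisition_date: str | None = None,
) -> IRFRecord:
    """Barycenter and FWHM of an IRF histogram.

    The mean of the first ``background_bins`` bins is subtracted (clipped at
    zero) before the count-weighted barycenter; the FWHM is found by linear
    interpolation of the half-maximum crossings around the peak.
    """
    edges = np.asarray(bin_edges_ns, dtype=float)
    hist = np.asarray(histogram, dtype=float)
    if hist.size != edges.size - 1:
        raise ValueError("histogram must have len(bin_edges) - 1 entries")
    if hist.sum() <= 0:
        raise ValueError("IRF histogram has no counts")
    centers = 0.5 * (edges[:-1] + edges[1:])

    bg = hist[: min(background_bins, hist.size)].mean() if background_bins else 0.0
    clean = np.clip(hist - bg, 0.0, None)
    if clean.sum() <= 0:
        raise ValueError("IRF histogram is indistinguishable from background")

    barycenter = float(np.sum(clean * centers) / clean.sum())

    peak = int(np.argmax(clean))
    half = clean[peak] / 2.0
    # left crossing (grid edge used if the peak sits at the boundary)
    left = peak
    while left > 0 and clean[left] > half:
        left -= 1
    if clean[left] > half:
        t_left = centers[left]
    else:
        t_left = np.interp(half, [clean[left], clean[left + 1]], [centers[left], centers[left + 1]])
    # right crossing
    right = peak
    while right < clean.size - 1 and clean[right] > half:
        right += 1
    if clean[right] > half:
        t_right = centers[right]
    else:
        t_right = np.interp(
            half, [clean[right], clean[right - 1]], [centers[right], centers[right - 1]]
        )
    bin_width = float(np.diff(edges).mean())
    fwhm_ps = 1000.0 * max(t_right - t_left, bin_width)
    return IRFRecord(edges, hist, barycenter, fwhm_ps, acquisition_date)


def _circular_convolve(signal: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Circular convolution over the laser period (both sampled on the grid)."""
    return np.real(np.fft.ifft(np.fft.fft(signal) * np.fft.fft(kernel)))


def dtof_model(
    mua: float,
    musp: float,
    centers_ns: np.ndarray,
    irf_shape: np.ndarray,
    rho_cm: float,
    refractive_index: float = 1.4,
) -> np.ndarray:
    """Unit-area model DTOF: (diffusion reflectance) circularly convolved with the IRF."""
    theory = semi_infinite_reflectance(centers_ns, mua, musp, rho_cm, refractive_index)
    conv = _circular_convolve(theory, irf_shape / irf_shape.sum())
    total = conv.sum()
    if total <= 0:
        raise ValueError("degenerate forward model")
    return conv / total


def _fit_window(counts: np.ndarray, rise_frac: float, fall_frac: float) -> tuple[int, int]:
    peak = int(np.argmax(counts))
    peak_val = counts[peak]
    above = np.nonzero(counts[: peak + 1] >= rise_frac * peak_val)[0]
    lo = int(above[0]) if above.size else peak
    below = np.nonzero(counts[peak:] < fall_frac * peak_val)[0]
    hi = peak + int(below[0]) if below.size else counts.size
    return lo, hi


def fit_dtof(
    dtof: DTOFHistogram,
    irf: IRFRecord,
    geom: ProbeGeometry,
    refractive_index: float = 1.4,
    rise_fraction: float = 0.8,
    fall_fraction: float = 0.01,
    x0: tuple[float, float] = (0.1, 10.0),
    max_iterations: int = 200,
) -> tuple[OpticalProperties, FitDiagnostics]:
    """Convolution fit of a DTOF for absolute (mua, musp).

    The background (mean over the pre-peak window) is subtracted, the fit
    window runs from 80% of peak on the rising edge to 1% of peak on the
    falling edge, residuals are weighted by 1/sqrt(max(counts, 1)) (Poisson),
    and the amplitude is solved analytically per iteration.  Non-convergence
    is flagged, not raised.
    """
    counts = dtof.counts
    if counts.sum() <= 0:
        raise ValueError("empty DTOF histogram")
    if dtof.counts.size != irf.histogram.size:
        raise ValueError("DTOF and IRF must share the time grid")
    centers = dtof.bin_centers_ns

    b0, b1 = dtof.background_window
    bg_slice = counts[b0:b1]
    bg_mean = float(bg_slice.mean()) if bg_slice.size else 0.0
    bg_sd = float(bg_slice.std(ddof=1)) if bg_slice.size > 1 else 0.0
    clean = counts - bg_mean

    dynamic_range = float(counts.max() / bg_sd) if bg_sd > 0 else float("inf")

    lo, hi = _fit_window(clean, rise_fraction, fall_fraction)
    y = clean[lo:hi]
    w = 1.0 / np.sqrt(np.maximum(counts[lo:hi], 1.0))
    irf_shape = irf.normalized

    def shape(logp):
        mua, musp = np.exp(logp)
        return dtof_model(mua, musp, centers, irf_shape, geom.rho_cm, refractive_index)[lo:hi]

    def residuals(logp):
        m = shape(logp)
        wm = w * m
        amp = np.dot(wm, w * y) / np.dot(wm, wm)
        return w * (amp * m - y)

    result = optimize.least_squares(
        residuals,
        np.log(np.asarray(x0)),
        method="lm",
        xtol=1e-10,
        ftol=1e-10,
        gtol=1e-10,
        max_nfev=max_iterations * 4,
    )
    mua, musp = np.exp(result.x)
    dof = max(y.size - 3, 1)
    diag = FitDiagnostics(
        reduced_chi2=float(2.0 * result.cost / dof),
        dynamic_range=dynamic_range,
        fit_window=(lo, hi),
        iterations=int(result.nfev),
        converged=bool(result.success),
        background_mean=bg_mean,
        background_sd=bg_sd,
    )
    props = OpticalProperties(float(mua), float(musp), dtof.wavelength_nm)
    return props, diag


def dtof_objective(
    mua: float,
    musp: float,
    dtof: DTOFHistogram,
    irf: IRFRecord,
    geom: ProbeGeometry,
    refractive_index: float = 1.4,
    rise_fraction: float = 0.8,
    fall_fraction: float = 0.01,
) -> float:
    """The exact weighted SSE minimized by :func:`fit_dtof` at fixed (mua, musp).

    Exposed so a brute-force grid search can serve as an independent check of
    the optimizer.
    """
    counts = dtof.counts
    b0, b1 = dtof.background_window
    bg_mean = float(counts[b0:b1].mean()) if counts[b0:b1].size else 0.0
    clean = counts - bg_mean
    lo, hi = _fit_window(clean, rise_fraction, fall_fraction)
    y = clean[lo:hi]
    w = 1.0 / np.sqrt(np.maximum(counts[lo:hi], 1.0))
    m = dtof_model(mua, musp, dtof.bin_centers_ns, irf.normalized, geom.rho_cm, refractive_index)[lo:hi]
    wm = w * m
    amp = np.dot(wm, w * y) / np.dot(wm, wm)
    r = w * (amp * m - y)
    return float(np.dot(r, r))


def compute_chromophores(
    props_685: OpticalProperties,
    props_828: OpticalProperties,
    water_fraction: float = 0.0,
    ext_matrix: np.ndarray | None = None,
) -> ChromophoreState:
    """Solve the 2x2 linear system for (HbO, HbR) from mua at two wavelengths.

    The water contribution ``water_fraction * mua_water(lambda)`` is removed
    before inversion.  Negative concentrations are returned with a warning
    flag rather than raised.
    """
    wls = (props_685.wavelength_nm, props_828.wavelength_nm)
    E = extinction.extinction_matrix(wls) if ext_matrix is None else np.asarray(ext_matrix)
    if abs(np.linalg.det(E)) < 1e-300:
        raise ValueError("extinction matrix is singular")
    water = np.array([water_fraction * extinction.WATER_ABSORPTION[wl] for wl in wls])
    mua = np.array([props_685.mua, props_828.mua]) - water
    hbo, hbr = np.linalg.solve(E, mua)
    return ChromophoreState(float(hbo), float(hbr), negative_warning=bool(hbo < 0 or hbr < 0))


def interpolate_props(
    props_685: OpticalProperties,
    props_828: OpticalProperties,
    wavelength_nm: float = 785.0,
) -> OpticalProperties:
    """Linear-in-wavelength interpolation of (mua, musp) between the two
    pulsed wavelengths, used to supply properties to the DCS fit."""
    w0, w1 = props_685.wavelength_nm, props_828.wavelength_nm
    f = (wavelength_nm - w0) / (w1 - w0)
    return OpticalProperties(
        mua=(1 - f) * props_685.mua + f * props_828.mua,
        musp=(1 - f) * props_685.musp + f * props_828.musp,
        wavelength_nm=wavelength_nm,
    )


def compute_phantom_effective(
    fits_685: list[OpticalProperties],
    fits_828: list[OpticalProperties],
    session_date: str | None = None,
) -> PhantomQCRecord:
    """Effective tHb/StO2 of a phantom session from per-repetition mua pairs.

    Water term is zero (solid silicone phantom).  Reports the mean and the
    intra-phantom CV over repetitions.
    """
    if len(fits_685) != len(fits_828):
        raise ValueError("mismatched repetition counts between wavelengths")
    if len(fits_685) < 2:
        raise ValueError("phantom record needs at least 2 repetitions")
    states = [
        compute_chromophores(p6, p8, water_fraction=0.0)
        for p6, p8 in zip(fits_685, fits_828)
    ]
    thb = np.array([s.thb_um for s in states])
    sto2 = np.array([s.sto2_pct for s in states])

    def cv(x):
        return 100.0 * x.std(ddof=1) / x.mean()

    return PhantomQCRecord(
        thb_ph_um=float(thb.mean()),
        sto2_ph_pct=float(sto2.mean()),
        thb_cv_pct=float(cv(thb)),
        sto2_cv_pct=float(cv(sto2)),
        per_repetition=states,
        session_date=session_date,
    )
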