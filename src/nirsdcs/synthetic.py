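"""Synthetic-data generators standing in for the device.

Forward models plus noise produce every input the inverse pipeline
consumes: DTOF histograms (diffusion reflectance circularly convolved with
the IRF, Poisson counting noise, dark floor), g2 curves (Siegert relation
with count-rate-dependent Gaussian noise), VOT physiologic trajectories,
and complete on-disk sessions (phantom QC, IRF, VOT, test-retest, limb
occlusion pressure steps, quality-assessment phase).

All randomness flows from a single seed: ``simulate_session`` spawns one
``numpy.random.SeedSequence`` child per independent stream, in a fixed
documented order, so identical (kind, config, seed) produce bit-identical
sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dcs import G2Curve
from .forward import g1_semi_infinite, semi_infinite_reflectance
from .geometry import ForwardModelSpec, ProbeGeometry
from .tdnirs import DTOFHistogram, OpticalProperties, compute_irf_metrics, IRFRecord
from .vot import VOTProtocol, VOTTrace
from . import session as session_io

#: nominal optical properties of the solid quality-control phantom
PHANTOM_PROPS: dict[float, OpticalProperties] = {
    685.0: OpticalProperties(mua=0.23, musp=12.8, wavelength_nm=685.0),
    828.0: OpticalProperties(mua=0.19, musp=9.5, wavelength_nm=828.0),
}

#: healthy-muscle baseline optical properties (group means)
HEALTHY_TISSUE_PROPS: dict[float, OpticalProperties] = {
    685.0: OpticalProperties(mua=0.22, musp=8.62, wavelength_nm=685.0),
    828.0: OpticalProperties(mua=0.23, musp=8.18, wavelength_nm=828.0),
}


@dataclass(frozen=True)
class VOTPhysiology:
    """Parameters of the piecewise-analytic VOT trajectory.

    StO2: plateau at ``baseline_sto2``; linear decline at ``desat_rate``
    (%/min, negative) during occlusion floored at ``min_sto2``; after
    deflation a linear rise at ``resat_rate`` (%/s) to
    ``hyperemia_peak_sto2`` followed by an exponential relaxation
    (``recovery_tau``) toward baseline with a small undershoot
    (``undershoot_sto2``) clamped at baseline — the undershoot makes the
    second baseline crossing occur in finite time.  BFI: baseline, a small
    fraction of baseline during occlusion, then a hyperemic peak
    (``hyperemia_peak_bfi_ratio`` x baseline) relaxing analogously.

    Defaults reproduce the healthy-cohort group values (baseline StO2
    ~70%, DeO2 -4.6 %/min, ReO2 1.1 %/s, BFI 0.53e-8 cm^2/s).
    """

    baseline_sto2: float = 70.3
    baseline_bfi: float = 0.53e-8
    desat_rate: float = -4.6  # %/min, negative
    min_sto2: float = 40.0
    resat_rate: float = 1.1  # %/s
    hyperemia_peak_sto2: float = 78.3
    recovery_tau: float = 50.0  # s
    undershoot_sto2: float = 0.5  # %
    occlusion_bfi_fraction: float = 0.03
    hyperemia_peak_bfi_ratio: float = 3.5
    bfi_recovery_tau: float = 45.0  # s
    undershoot_bfi_relative: float = 0.02
    noise_sd_sto2: float = 0.5  # %
    noise_sd_bfi_relative: float = 0.08
    spo2: float = 99.0
    hr_bpm: float = 64.0
    systolic_mmhg: float = 120.0

    def __post_init__(self) -> None:
        if not 0 < self.baseline_sto2 < 100:
            raise ValueError("baseline StO2 must lie in (0, 100)%")
        if self.desat_rate >= 0:
            raise ValueError("desaturation rate must be negative")
        if self.min_sto2 >= self.baseline_sto2:
            raise ValueError("min StO2 must lie below baseline")
        if self.hyperemia_peak_sto2 <= self.baseline_sto2:
            raise ValueError("hyperemic peak must exceed baseline")
        if min(self.noise_sd_sto2, self.noise_sd_bfi_relative) < 0:
            raise ValueError("noise parameters must be nonnegative")
        if self.resat_rate <= 0 or self.recovery_tau <= 0:
            raise ValueError("recovery parameters must be positive")


# ---------------------------------------------------------------------------
# TD-NIRS forward generation


def gaussian_irf(
    bin_edges_ns: np.ndarray,
    center_ns: float = 3.9,
    fwhm_ps: float = 200.0,
) -> np.ndarray:
    """Unit-area Gaussian IRF histogram on the shared time grid."""
    edges = np.asarray(bin_edges_ns, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    sigma_ns = fwhm_ps * 1e-3 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    h = np.exp(-0.5 * ((centers - center_ns) / sigma_ns) ** 2)
    return h / h.sum()


def delta_irf(bin_edges_ns: np.ndarray, index: int = 0) -> np.ndarray:
    """Degenerate single-bin IRF (identity element of the convolution)."""
    h = np.zeros(np.asarray(bin_edges_ns).size - 1)
    h[index] = 1.0
    return h


def generate_dtof(
    props: OpticalProperties,
    geom: ProbeGeometry,
    spec: ForwardModelSpec,
    irf: np.ndarray,
    total_counts: float = 1e6,
    dark_rate_cps: float = 1000.0,
    integration_time_s: float = 1.0,
    rng: np.random.Generator | None = None,
    noise: bool = True,
    timestamp_s: float = 0.0,
) -> DTOFHistogram:
    """Simulate one DTOF: (theory (*) IRF) scaled to ``total_counts`` signal
    photons, plus a uniform dark floor, Poisson-sampled per bin.

    The convolution is circular over the laser period, as in the real
    repetitive-excitation measurement.
    """
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    irf = np.asarray(irf, dtype=float)
    nbins = spec.time_edges_ns.size - 1
    if irf.size != nbins:
        raise ValueError("IRF does not cover the time grid")
    centers = spec.bin_centers_ns
    theory = semi_infinite_reflectance(
        centers, props.mua, props.musp, geom.rho_cm, spec.refractive_index
    )
    conv = np.real(np.fft.ifft(np.fft.fft(theory) * np.fft.fft(irf / irf.sum())))
    conv = np.clip(conv, 0.0, None)
    expected = conv / conv.sum() * total_counts
    expected = expected + dark_rate_cps * integration_time_s / nbins
    if noise:
        if rng is None:
            rng = np.random.default_rng()
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    return DTOFHistogram(
        bin_edges_ns=spec.time_edges_ns.copy(),
        counts=counts,
        wavelength_nm=props.wavelength_nm,
        timestamp_s=timestamp_s,
        integration_time_s=integration_time_s,
    )


# ---------------------------------------------------------------------------
# DCS forward generation


def generate_g2(
    props_785: OpticalProperties,
    bfi_cm2_s: float,
    beta: float,
    geom: ProbeGeometry,
    spec: ForwardModelSpec,
    count_rate_khz: float = 50.0,
    avg_time_s: float = 1.0,
    rng: np.random.Generator | None = None,
    noise: bool = True,
    timestamp_s: float = 0.0,
) -> G2Curve:
    """Simulate one g2 curve: Siegert relation plus additive Gaussian noise.

    The per-lag noise standard deviation is beta * (1 + g1(tau)^2) /
    sqrt(N) with N = count_rate * avg_time the number of detected photons —
    a simplified shot-noise-inspired model that reproduces the 1/sqrt(N_ph)
    scaling of correlator noise.  Values are deliberately not clipped, so
    noise may carry g2 slightly outside the noiseless [1, 1+beta] band.
    """
    if not 0 < beta <= 1:
        raise ValueError("beta must lie in (0, 1]")
    if bfi_cm2_s <= 0:
        raise ValueError("BFI must be positive")
    if avg_time_s <= 0:
        raise ValueError("averaging time must be positive")
    tau = spec.lag_grid_s
    g1 = g1_semi_infinite(
        tau,
        props_785.mua,
        props_785.musp,
        bfi_cm2_s,
        geom.rho_cm,
        props_785.wavelength_nm,
        spec.refractive_index,
    )
    g2 = 1.0 + beta * g1**2
    if noise:
        if rng is None:
            rng = np.random.default_rng()
        n_photons = count_rate_khz * 1e3 * avg_time_s
        sd = beta * (1.0 + g1**2) / np.sqrt(n_photons)
        g2 = g2 + rng.normal(0.0, sd)
    return G2Curve(
        lag_s=tau.copy(),
        g2=g2,
        count_rate_khz=count_rate_khz,
        timestamp_s=timestamp_s,
        avg_time_s=avg_time_s,
    )


# ---------------------------------------------------------------------------
# VOT physiologic trajectory


def _sto2_noiseless(t: np.ndarray, proto: VOTProtocol, phys: VOTPhysiology) -> np.ndarray:
    t_inf = proto.baseline_s
    t_def = proto.baseline_s + proto.occlusion_s
    s = np.full_like(t, phys.baseline_sto2, dtype=float)

    occl = (t >= t_inf) & (t < t_def)
    s[occl] = np.maximum(
        phys.baseline_sto2 + phys.desat_rate / 60.0 * (t[occl] - t_inf), phys.min_sto2
    )
    s_def = max(phys.baseline_sto2 + phys.desat_rate / 60.0 * proto.occlusion_s, phys.min_sto2)

    rec = t >= t_def
    t_peak = t_def + (phys.hyperemia_peak_sto2 - s_def) / phys.resat_rate
    rise = rec & (t < t_peak)
    s[rise] = s_def + phys.resat_rate * (t[rise] - t_def)
    relax = t >= t_peak
    amp = phys.hyperemia_peak_sto2 - phys.baseline_sto2 + phys.undershoot_sto2
    s[relax] = np.maximum(
        phys.baseline_sto2
        + amp * np.exp(-(t[relax] - t_peak) / phys.recovery_tau)
        - phys.undershoot_sto2,
        phys.baseline_sto2,
    )
    return s


def _bfi_noiseless(t: np.ndarray, proto: VOTProtocol, phys: VOTPhysiology) -> np.ndarray:
    t_inf = proto.baseline_s
    t_def = proto.baseline_s + proto.occlusion_s
    b = np.full_like(t, phys.baseline_bfi, dtype=float)
    occl = (t >= t_inf) & (t < t_def)
    b[occl] = phys.occlusion_bfi_fraction * phys.baseline_bfi
    rec = t >= t_def
    peak = phys.hyperemia_peak_bfi_ratio * phys.baseline_bfi
    under = phys.undershoot_bfi_relative * phys.baseline_bfi
    amp = peak - phys.baseline_bfi + under
    b[rec] = np.maximum(
        phys.baseline_bfi + amp * np.exp(-(t[rec] - t_def) / phys.bfi_recovery_tau) - under,
        phys.baseline_bfi,
    )
    return b


def analytic_auc_sto2(phys: VOTPhysiology) -> float:
    """Closed-form area (in %*min) of the noiseless StO2 hyperemic overshoot
    above baseline, for checking the trapezoid extraction."""
    A = phys.hyperemia_peak_sto2 - phys.baseline_sto2
    d = phys.undershoot_sto2
    triangle = A**2 / (2.0 * phys.resat_rate)
    tail = phys.recovery_tau * A - d * phys.recovery_tau * np.log((A + d) / d)
    return (triangle + tail) / 60.0


def analytic_auc_bfi(phys: VOTPhysiology) -> float:
    """Closed-form area (cm^2) of the noiseless BFI overshoot above baseline."""
    A = (phys.hyperemia_peak_bfi_ratio - 1.0) * phys.baseline_bfi
    d = phys.undershoot_bfi_relative * phys.baseline_bfi
    return phys.bfi_recovery_tau * A - d * phys.bfi_recovery_tau * np.log((A + d) / d)


def simulate_vot_timecourse(
    protocol: VOTProtocol = VOTProtocol(),
    phys: VOTPhysiology = VOTPhysiology(),
    rate_hz: float = 1.0,
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> VOTTrace:
    """Simulate a synchronized VOT trace with markers and a rectangular
    cuff-pressure channel at systolic + 50 mmHg."""
    t = np.arange(0.0, protocol.total_s, 1.0 / rate_hz)
    sto2 = _sto2_noiseless(t, protocol, phys)
    bfi = _bfi_noiseless(t, protocol, phys)
    spo2 = np.full_like(t, phys.spo2)
    hr = np.full_like(t, phys.hr_bpm)
    t_inf = protocol.baseline_s
    t_def = protocol.baseline_s + protocol.occlusion_s
    cuff = np.where(
        (t >= t_inf) & (t < t_def), phys.systolic_mmhg + protocol.pressure_margin_mmhg, 0.0
    )
    if noise:
        if rng is None:
            rng = np.random.default_rng()
        sto2 = sto2 + rng.normal(0.0, phys.noise_sd_sto2, t.size)
        bfi = bfi + rng.normal(0.0, phys.noise_sd_bfi_relative * phys.baseline_bfi, t.size)
        spo2 = spo2 + rng.normal(0.0, 0.3, t.size)
        hr = hr + rng.normal(0.0, 1.0, t.size)
    return VOTTrace(
        t_s=t,
        sto2_pct=sto2,
        bfi_cm2_s=bfi,
        spo2_pct=spo2,
        hr_bpm=hr,
        cuff_pressure_mmhg=cuff,
        markers={"inflation": float(t_inf), "deflation": float(t_def), "end": float(protocol.total_s)},
    )


# ---------------------------------------------------------------------------
# full sessions on disk

SESSION_KINDS = ("phantom", "irf", "vot", "test_retest", "lop", "qp")


def _dtof_table(dtofs: list[DTOFHistogram]) -> pd.DataFrame:
    rows = []
    for i, d in enumerate(dtofs):
        row = {"t_s": d.timestamp_s, "rep": i}
        row.update({f"bin_{j:04d}": c for j, c in enumerate(d.counts)})
        rows.append(row)
    return pd.DataFrame(rows)


def _dtof_units(nbins: int) -> dict[str, str]:
    units = {"rep": "1"}
    units.update({f"bin_{j:04d}": "counts" for j in range(nbins)})
    return units


def _g2_table(curves: list[G2Curve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        row = {"t_s": c.timestamp_s, "count_rate_khz": c.count_rate_khz, "avg_time_s": c.avg_time_s}
        row.update({f"lag_{j:03d}": v for j, v in enumerate(c.g2)})
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_session(
    kind: str,
    out_dir,
    seed: int,
    config: dict | None = None,
    geom: ProbeGeometry = ProbeGeometry(),
    spec: ForwardModelSpec | None = None,
):
    """Write a complete synthetic session of the given kind to ``out_dir``.

    Returns the :class:`~nirsdcs.session.SessionManifest` of the written
    session.  ``config`` overrides kind-specific defaults (see the methods
    documentation for the condition each kind emulates).
    """
    if kind not in SESSION_KINDS:
        raise ValueError(f"unknown session kind {kind!r}; expected one of {SESSION_KINDS}")
    config = dict(config or {})
    if spec is None:
        spec = ForwardModelSpec()
    ss = np.random.SeedSequence(seed)
    channels: dict[str, pd.DataFrame] = {}
    units: dict[str, dict[str, str]] = {}
    protocol: dict = {}
    nbins = spec.time_edges_ns.size - 1

    if kind in ("phantom", "irf"):
        irf_shape = gaussian_irf(
            spec.time_edges_ns,
            config.get("irf_center_ns", 3.9),
            config.get("irf_fwhm_ps", 200.0),
        )
        irf_counts_rng = np.random.default_rng(ss.spawn(1)[0])
        irf_counts = irf_counts_rng.poisson(irf_shape * config.get("irf_total_counts", 1e6))
        for wl in geom.wavelengths_nm:
            name = f"irf_{int(wl)}"
            channels[name] = _dtof_table(
                [DTOFHistogram(spec.time_edges_ns, irf_counts.astype(float), wl)]
            )
            units[name] = _dtof_units(nbins)
        if kind == "phantom":
            n_rep = int(config.get("n_repetitions", 20))
            for wl in geom.wavelengths_nm:
                props = config.get("props", PHANTOM_PROPS)[wl]
                child = np.random.default_rng(ss.spawn(1)[0])
                dtofs = [
                    generate_dtof(
                        props, geom, spec, irf_shape,
                        total_counts=config.get("total_counts", 1e6),
                        dark_rate_cps=config.get("dark_rate_cps", 1000.0),
                        rng=child, timestamp_s=float(i),
                    )
                    for i in range(n_rep)
                ]
                name = f"dtof_{int(wl)}"
                channels[name] = _dtof_table(dtofs)
                units[name] = _dtof_units(nbins)
            protocol = {"n_repetitions": n_rep}

    elif kind == "vot":
        proto = config.get("protocol", VOTProtocol())
        phys = config.get("physiology", VOTPhysiology())
        rng = np.random.default_rng(ss.spawn(1)[0])
        trace = simulate_vot_timecourse(proto, phys, rng=rng, noise=config.get("noise", True))
        channels["hemodynamics"] = pd.DataFrame(
            {
                "t_s": trace.t_s,
                "sto2": trace.sto2_pct,
                "bfi": trace.bfi_cm2_s,
                "spo2": trace.spo2_pct,
                "hr": trace.hr_bpm,
            }
        )
        units["hemodynamics"] = {"sto2": "%", "bfi": "cm^2/s", "spo2": "%", "hr": "1/min"}
        channels["cuff"] = pd.DataFrame({"t_s": trace.t_s, "pressure": trace.cuff_pressure_mmhg})
        units["cuff"] = {"pressure": "mmHg"}
        channels["markers"] = pd.DataFrame(
            {"t_s": [trace.markers[k] for k in ("inflation", "deflation", "end")],
             "label": ["inflation", "deflation", "end"]}
        )
        units["markers"] = {"label": "label"}
        protocol = {
            "baseline_s": proto.baseline_s,
            "occlusion_s": proto.occlusion_s,
            "recovery_s": proto.recovery_s,
        }

    elif kind == "test_retest":
        n_blocks = int(config.get("n_blocks", 5))
        block_s = float(config.get("block_s", 200.0))
        sto2_mean = config.get("sto2_mean", 70.3)
        bfi_mean = config.get("bfi_mean", 0.53e-8)
        # between-repositioning variability and within-block noise
        sto2_between = config.get("sto2_between_sd", 0.012 * sto2_mean)
        bfi_between = config.get("bfi_between_sd", 0.126 * bfi_mean)
        sto2_within = config.get("sto2_within_sd", 0.008 * sto2_mean)
        bfi_within = config.get("bfi_within_sd", 0.15 * bfi_mean)
        rng = np.random.default_rng(ss.spawn(1)[0])
        frames = []
        for b in range(n_blocks):
            t = np.arange(block_s) + b * (block_s + 30.0)
            mu_s = sto2_mean + rng.normal(0.0, sto2_between)
            mu_b = bfi_mean + rng.normal(0.0, bfi_between)
            frames.append(
                pd.DataFrame(
                    {
                        "t_s": t,
                        "block": b,
                        "sto2": mu_s + rng.normal(0.0, sto2_within, t.size),
                        "bfi": mu_b + rng.normal(0.0, bfi_within, t.size),
                    }
                )
            )
        channels["retest"] = pd.concat(frames, ignore_index=True)
        units["retest"] = {"block": "1", "sto2": "%", "bfi": "cm^2/s"}
        protocol = {"n_blocks": n_blocks, "block_s": block_s}

    elif kind == "lop":
        from .stats import LOPProtocol

        lp: LOPProtocol = config.get("protocol", LOPProtocol())
        rng = np.random.default_rng(ss.spawn(1)[0])
        sto2_base = config.get("sto2_mean", 70.3)
        bfi_base = config.get("bfi_mean", 0.53e-8)
        seqs = []
        t0 = 60.0  # initial baseline
        t = np.arange(0.0, t0)
        steps = [("baseline", 0.0, t)]
        for frac in lp.step_fractions:
            for phase in ("inflation", "deflation"):
                tt = np.arange(t0, t0 + lp.step_s)
                steps.append((phase, frac, tt))
                t0 += lp.step_s
        rows = []
        quality = []
        for phase, frac, tt in steps:
            occluded = phase == "inflation"
            f = frac if occluded else 0.3 * frac  # partial recovery on deflation
            sto2_mu = sto2_base * (1.0 - 0.25 * f)
            bfi_mu = bfi_base * (1.0 - 0.9 * f)
            count_rate = config.get("count_rate_khz", 50.0) * (1.0 - 0.5 * f)
            dr = config.get("dynamic_range", 2000.0) * (1.0 - 0.5 * f)
            # noise inversely scaled with the available light level
            sto2_sd = 0.3 * np.sqrt(config.get("dynamic_range", 2000.0) / dr)
            bfi_sd = 0.05 * bfi_base * np.sqrt(config.get("count_rate_khz", 50.0) / count_rate)
            rows.append(
                pd.DataFrame(
                    {
                        "t_s": tt,
                        "sto2": sto2_mu + rng.normal(0.0, sto2_sd, tt.size),
                        "bfi": bfi_mu + rng.normal(0.0, bfi_sd, tt.size),
                        "cuff_fraction": f if occluded else 0.0,
                    }
                )
            )
            if phase != "baseline":
                quality.append(
                    {
                        "t_s": tt[0],
                        "phase": phase,
                        "lop_fraction": frac,
                        "count_rate_khz": count_rate,
                        "dynamic_range": dr,
                    }
                )
        channels["lop_trace"] = pd.concat(rows, ignore_index=True)
        units["lop_trace"] = {"sto2": "%", "bfi": "cm^2/s", "cuff_fraction": "1"}
        channels["lop_steps"] = pd.DataFrame(quality)
        units["lop_steps"] = {
            "phase": "label",
            "lop_fraction": "1",
            "count_rate_khz": "kHz",
            "dynamic_range": "1",
        }
        protocol = {"step_s": lp.step_s, "eval_window_s": lp.eval_window_s,
                    "fractions": list(lp.step_fractions)}

    elif kind == "qp":
        rng = np.random.default_rng(ss.spawn(1)[0])
        segs = [("equalization", 60.0)]
        n_cycles = int(config.get("n_cycles", 3))
        for _ in range(n_cycles):
            segs += [("all_off", 10.0), ("dcs_on", 10.0), ("td_on", 10.0)]
        levels = {
            "dcs_dark_khz": config.get("dcs_dark_khz", 1.0),
            "dcs_signal_khz": config.get("dcs_signal_khz", 50.0),
            "dcs_crosstalk_khz": config.get("dcs_crosstalk_khz", 2.5),
            "td_signal_mcps": config.get("td_signal_mcps", 1.0),
            "td_dark_kcps": config.get("td_dark_kcps", 10.0),
        }
        rel_noise = config.get("relative_noise", 0.02)
        t0 = 0.0
        seg_rows = []
        count_rows = []
        for label, dur in segs:
            tt = np.arange(t0, t0 + dur)
            if label in ("equalization", "td_on"):
                td685 = levels["td_signal_mcps"]
                td828 = levels["td_signal_mcps"]
                dcs = levels["dcs_crosstalk_khz"] if label == "td_on" else levels["dcs_dark_khz"]
            elif label == "dcs_on":
                td685 = td828 = levels["td_dark_kcps"] * 1e-3
                dcs = levels["dcs_signal_khz"]
            else:  # all_off
                td685 = td828 = levels["td_dark_kcps"] * 1e-3
                dcs = levels["dcs_dark_khz"]

            def noisy(level, size):
                if level == 0:
                    return np.zeros(size)
                return level * (1.0 + rng.normal(0.0, rel_noise, size))

            count_rows.append(
                pd.DataFrame(
                    {
                        "t_s": tt,
                        "dcs_khz": noisy(dcs, tt.size),
                        "td685_mcps": noisy(td685, tt.size),
                        "td828_mcps": noisy(td828, tt.size),
                        "oxi_valid": int(config.get("oxi_valid", True)),
                    }
                )
            )
            seg_rows.append({"t_s": t0, "label": label, "duration_s": dur})
            t0 += dur
        channels["qp_counts"] = pd.concat(count_rows, ignore_index=True)
        units["qp_counts"] = {
            "dcs_khz": "kHz",
            "td685_mcps": "Mcps",
            "td828_mcps": "Mcps",
            "oxi_valid": "bool",
        }
        channels["qp_segments"] = pd.DataFrame(seg_rows)
        units["qp_segments"] = {"label": "label", "duration_s": "s"}
        protocol = {"segment_s": 10.0, "n_cycles": n_cycles}

    manifest = session_io.SessionManifest(
        session_id=f"{kind}-{seed}",
        kind=kind,
        seed=seed,
        protocol=protocol,
        device_config={
            "rho_cm": geom.rho_cm,
            "wavelengths_nm": list(geom.wavelengths_nm),
            "dcs_wavelength_nm": geom.dcs_wavelength_nm,
            "rep_rate_mhz": geom.rep_rate_mhz,
            "refractive_index": spec.refractive_index,
        },
    )
    return session_io.write_session(out_dir, manifest, channels, units)


def dtofs_from_table(table: pd.DataFrame, spec: ForwardModelSpec, wavelength_nm: float) -> list[DTOFHistogram]:
    """Rebuild DTOF objects from a wide session channel table."""
    bins = [c for c in table.columns if c.startswith("bin_")]
    return [
        DTOFHistogram(
            spec.time_edges_ns,
            row[bins].to_numpy(dtype=float),
            wavelength_nm,
            timestamp_s=float(row["t_s"]),
        )
        for _, row in table.iterrows()
    ]


def irf_from_table(table: pd.DataFrame, spec: ForwardModelSpec) -> IRFRecord:
    bins = [c for c in table.columns if c.startswith("bin_")]
    hist = table.iloc[0][bins].to_numpy(dtype=float)
    return compute_irf_metrics(spec.time_edges_ns, hist)
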