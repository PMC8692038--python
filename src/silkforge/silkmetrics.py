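"""Silk fibre characterization: tensile-curve summaries and WAXS crystallinity.

Mechanical summaries follow the standard tensile-test definitions: toughness
is the area under the stress-strain curve (GPa x unit strain = 1000 MJ m^-3),
tensile strength the peak stress, strain at break the final strain (in %),
and Young's modulus the least-squares slope of the initial linear region.

Crystallinity is estimated from a background-subtracted 1-D WAXS radial
profile by decomposing it into narrow crystal-peak Gaussians plus one broad
amorphous-halo Gaussian; the degree of crystallinity is the crystal peak
area divided by the total (peaks + halo) area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "StressStrainCurve", "MechanicalSummary", "WAXSProfile",
    "CrystallinityFit", "mechanics_summary", "fit_crystallinity",
    "GPA_STRAIN_TO_MJ_M3",
]

# 1 GPa integrated over unit (dimensionless) strain is 1 GJ m^-3 = 1000 MJ m^-3
GPA_STRAIN_TO_MJ_M3 = 1000.0


@dataclass
class StressStrainCurve:
    strain: np.ndarray          # dimensionless, 0 = unstretched
    stress: np.ndarray          # GPa
    cross_section_um2: float = 1.0

    def __post_init__(self):
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape:
            raise ValueError("strain and stress must have equal length")
        if self.strain.size and self.strain[0] < 0:
            raise ValueError("strain must start at >= 0")


@dataclass
class MechanicalSummary:
    toughness_MJ_m3: float
    tensile_strength_GPa: float
    strain_at_break_pct: float
    youngs_modulus_GPa: float


@dataclass
class WAXSProfile:
    q: np.ndarray               # scattering vector, nm^-1, strictly increasing
    intensity: np.ndarray       # background-subtracted

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must have equal length")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")


@dataclass
class CrystallinityFit:
    peaks: list[tuple[float, float, float]]   # (center, width sigma, area)
    halo: tuple[float, float, float]
    crystallinity: float
    residual_norm: float


def mechanics_summary(curve: StressStrainCurve,
                      modulus_strain_cap: float = 0.02) -> MechanicalSummary:
    """Toughness, strength, strain at break and modulus of a tensile curve.

    The break point is the last sample.  The modulus is the least-squares
    slope (with free intercept) of stress vs strain over
    strain <= ``modulus_strain_cap``.
    """
    eps, sig = curve.strain, curve.stress
    if eps.size < 3:
        raise ValueError("need at least 3 samples")
    if np.any(np.diff(eps) < 0):
        raise ValueError("strain must be nondecreasing")
    toughness = float(np.trapezoid(sig, eps)) * GPA_STRAIN_TO_MJ_M3
    mask = eps <= modulus_strain_cap
    if mask.sum() >= 2:
        slope = float(np.polyfit(eps[mask], sig[mask], 1)[0])
    else:
        slope = float(sig[1] - sig[0]) / float(eps[1] - eps[0]) \
            if eps[1] != eps[0] else 0.0
    return MechanicalSummary(
        toughness_MJ_m3=toughness,
        tensile_strength_GPa=float(sig.max()),
        strain_at_break_pct=100.0 * float(eps[-1]),
        youngs_modulus_GPa=slope,
    )


def _gauss(q, amp, center, sigma):
    return amp * np.exp(-0.5 * ((q - center) / sigma) ** 2)


def fit_crystallinity(profile: WAXSProfile, n_peaks: int,
                      init: list[tuple[float, float]],
                      halo_init: tuple[float, float] | None = None,
                      ) -> CrystallinityFit:
    """Gaussian decomposition of a WAXS profile into crystal peaks + halo.

    ``init`` gives (center, sigma) starting values for each crystal peak;
    ``halo_init`` likewise for the amorphous halo (default: profile centre,
    3x the widest peak).  The halo width is lower-bounded above the widest
    allowed peak width so the broad component cannot collapse onto a
    crystal reflection.  Crystallinity = peak area / (peak + halo area).
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if len(init) != n_peaks:
        raise ValueError("init must provide (center, sigma) per peak")
    q, y = profile.q, profile.intensity
    for c, _ in init:
        if not (q[0] <= c <= q[-1]):
            raise ValueError(f"initialized center {c} outside profile range")
    max_peak_sigma = max(s for _, s in init)
    if halo_init is None:
        halo_init = (0.5 * (q[0] + q[-1]), 3.0 * max_peak_sigma)
    peak_sigma_cap = 2.0 * max_peak_sigma
    halo_sigma_floor = 1.05 * peak_sigma_cap
    amp0 = max(float(y.max()), 1e-6)

    p0, lo, hi = [], [], []
    for c, s in init:
        p0 += [0.5 * amp0, c, s]
        lo += [0.0, q[0], 1e-4]
        hi += [np.inf, q[-1], peak_sigma_cap]
    hc, hs = halo_init
    p0 += [0.5 * amp0, hc, max(hs, halo_sigma_floor)]
    lo += [0.0, q[0], halo_sigma_floor]
    hi += [np.inf, q[-1], np.inf]

    def model(qv, *p):
        out = np.zeros_like(qv)
        for i in range(n_peaks + 1):
            out = out + _gauss(qv, *p[3 * i: 3 * i + 3])
        return out

    try:
        popt, _ = curve_fit(model, q, y, p0=p0, bounds=(lo, hi), maxfev=20000)
    except RuntimeError as e:
        resid = float(np.linalg.norm(model(q, *p0) - y))
        raise RuntimeError(
            f"crystallinity fit did not converge (initial residual norm "
            f"{resid:.4g}): {e}") from e
    resid = float(np.linalg.norm(model(q, *popt) - y))
    sqrt2pi = float(np.sqrt(2.0 * np.pi))
    peaks = []
    for i in range(n_peaks):
        amp, c, s = popt[3 * i: 3 * i + 3]
        peaks.append((float(c), float(s), float(amp * s * sqrt2pi)))
    amp, c, s = popt[3 * n_peaks: 3 * n_peaks + 3]
    halo = (float(c), float(s), float(amp * s * sqrt2pi))
    peak_area = sum(a for _, _, a in peaks)
    denom = peak_area + halo[2]
    crystallinity = 0.0 if denom == 0 else peak_area / denom
    return CrystallinityFit(peaks=peaks, halo=halo,
                            crystallinity=float(crystallinity),
                            residual_norm=resid)
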