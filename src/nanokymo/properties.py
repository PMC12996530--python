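"""Physical conversions and Cramer-Rao precision bounds.

Covers the optical-mass conversion (integrated optical contrast iOC to
molecular weight via the polarizability constant a = 0.46 A^3/Da, i.e.
0.46 nm^3/kDa), the Stokes-Einstein diffusivity/hydrodynamic-radius pair
with optional hindered-diffusion corrections for wall drag in narrow
channels, dsDNA ladder calculators (0.34 nm and 660 g/mol per base pair),
and Fisher-information lower bounds on the precision of diffusivity and
contrast-amplitude estimation from N-frame trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ConversionConstants",
    "HindranceModel",
    "CRLBCurve",
    "ioc_to_mw",
    "mw_to_ioc",
    "d_to_rs",
    "rs_to_d",
    "dsdna_length",
    "dsdna_mw",
    "crlb_diffusivity",
    "crlb_amplitude",
    "increment_diffusivity_estimator",
    "matched_filter_amplitude",
    "precision_vs_n",
]

K_B = 1.380649e-23  # J/K


@dataclass(frozen=True)
class ConversionConstants:
    """Calibration constants for the optical-mass and size conversions.

    ``a`` converts molecular mass to polarizability volume
    (0.46 A^3/Da == 0.46 nm^3/kDa); ``kappa`` is the dimensionless optical
    calibration mapping iOC (contrast x nm) times channel area (nm^2) to
    polarizability volume (nm^3).
    """

    a: float = 0.46            # nm^3 / kDa
    kappa: float = 0.01
    temperature_K: float = 298.15
    viscosity_Pa_s: float = 8.9e-4

    def __post_init__(self):
        for name in ("a", "kappa", "temperature_K", "viscosity_Pa_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class HindranceModel:
    """Wall-drag correction H(Rs) in (0, 1] for diffusion in a nanochannel.

    mode "none" is free solution (H = 1); "parametric" uses a Renkin-style
    centerline hindrance for a pore of effective radius
    r_eff = sqrt(area/pi); "lookup" interpolates a measured calibration
    table of (rs_nm, H) pairs, which must be non-increasing in rs.
    """

    mode: Literal["none", "parametric", "lookup"] = "none"
    pore_radius_nm: float = 25.0
    lookup: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.mode == "lookup":
            if len(self.lookup) < 2:
                raise ValueError("lookup mode needs at least 2 table rows")
            rs = [r for r, _ in self.lookup]
            hs = [h for _, h in self.lookup]
            if any(b < a for a, b in zip(rs, rs[1:])):
                raise ValueError("lookup radii must be sorted ascending")
            if any(not (0.0 < h <= 1.0) for h in hs):
                raise ValueError("hindrance factors must lie in (0, 1]")
            if any(b > a for a, b in zip(hs, hs[1:])):
                raise ValueError("hindrance must be non-increasing in rs")

    def factor(self, rs_nm: float) -> float:
        if self.mode == "none":
            return 1.0
        if self.mode == "lookup":
            rs = np.array([r for r, _ in self.lookup])
            hs = np.array([h for _, h in self.lookup])
            return float(np.interp(rs_nm, rs, hs))
        lam = rs_nm / self.pore_radius_nm
        if lam >= 1.0:
            return 1e-12
        # Renkin centerline hindrance for a cylindrical pore
        h = (1.0 - lam) ** 2 * (1.0 - 2.104 * lam + 2.09 * lam**3 - 0.95 * lam**5)
        return max(h, 1e-12)


@dataclass(frozen=True)
class CRLBCurve:
    """Relative-sigma lower bounds vs. trajectory length N."""

    n_values: tuple[int, ...]
    sigma_rel_mw: tuple[float, ...]
    sigma_rel_rs: tuple[float, ...]
    snr: float | None = None

    def __post_init__(self):
        for bounds in (self.sigma_rel_mw, self.sigma_rel_rs):
            if any(b <= 0 for b in bounds):
                raise ValueError("bounds must be positive")
            if any(b2 > b1 for b1, b2 in zip(bounds, bounds[1:])):
                raise ValueError("bounds must be non-increasing in N")


# ---------------------------------------------------------------------------
# optical mass conversion
# ---------------------------------------------------------------------------

def ioc_to_mw(ioc: float, area_nm2: float, c: ConversionConstants) -> float:
    """MW (kDa) from integrated optical contrast: MW = kappa * iOC * A / a.

    Linear in both iOC and channel area; a single polarizability constant
    is used for all analytes (the <10% dn/dc spread between protein and
    dsDNA is deliberately not corrected).
    """
    if ioc <= 0 or area_nm2 <= 0:
        raise ValueError("ioc and area must be positive")
    return c.kappa * ioc * area_nm2 / c.a


def mw_to_ioc(mw_kDa: float, area_nm2: float, c: ConversionConstants) -> float:
    """Inverse of :func:`ioc_to_mw`."""
    if mw_kDa <= 0 or area_nm2 <= 0:
        raise ValueError("mw and area must be positive")
    return mw_kDa * c.a / (c.kappa * area_nm2)


# ---------------------------------------------------------------------------
# size conversion
# ---------------------------------------------------------------------------

def rs_to_d(rs_nm: float, c: ConversionConstants,
            h: HindranceModel | None = None) -> float:
    """Measured diffusivity (um^2/s) at radius rs: D = H(rs) kT/(6 pi eta rs)."""
    if rs_nm <= 0:
        raise ValueError("rs must be positive")
    hindrance = h.factor(rs_nm) if h is not None else 1.0
    d_m2s = hindrance * K_B * c.temperature_K / (
        6.0 * np.pi * c.viscosity_Pa_s * rs_nm * 1e-9
    )
    return d_m2s * 1e12  # m^2/s -> um^2/s


def d_to_rs(d_um2_s: float, c: ConversionConstants,
            h: HindranceModel | None = None,
            bracket_nm: tuple[float, float] = (0.1, 100.0)) -> float:
    """Hydrodynamic radius (nm) solving D = H(Rs) kT / (6 pi eta Rs).

    With no hindrance this is the closed-form Stokes-Einstein inversion;
    otherwise the monotone equation is solved by bracketed root finding.
    """
    if d_um2_s <= 0:
        raise ValueError("D must be positive")
    if h is None or h.mode == "none":
        rs_m = K_B * c.temperature_K / (
            6.0 * np.pi * c.viscosity_Pa_s * d_um2_s * 1e-12
        )
        return rs_m * 1e9
    f = lambda rs: rs_to_d(rs, c, h) - d_um2_s
    lo, hi = bracket_nm
    if f(lo) * f(hi) > 0:
        raise ValueError(f"no root in bracket {bracket_nm} nm")
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


# ---------------------------------------------------------------------------
# dsDNA ladder calculators
# ---------------------------------------------------------------------------

def dsdna_length(bp: int) -> float:
    """Contour length of B-form dsDNA: 0.34 nm per base pair."""
    if bp < 0:
        raise ValueError("base-pair count must be non-negative")
    return 0.34 * bp


def dsdna_mw(bp: int, per_bp_g_mol: float = 660.0) -> float:
    """dsDNA molecular weight (kDa) at the standard 660 g/mol per base pair."""
    if bp < 0:
        raise ValueError("base-pair count must be non-negative")
    return bp * per_bp_g_mol / 1000.0


# ---------------------------------------------------------------------------
# Cramer-Rao lower bounds
# ---------------------------------------------------------------------------

def crlb_diffusivity(n: int, d: float | None = None) -> float:
    """Relative-sigma bound for D from n Gaussian increments: sqrt(2/n).

    The Fisher information of n i.i.d. N(v dt, 2 D dt) increments in D is
    n / (2 D^2), so var(D_hat) >= 2 D^2 / n independent of D itself.
    """
    if n < 2:
        raise ValueError("need n >= 2 increments")
    return float(np.sqrt(2.0 / n))


def crlb_amplitude(n: int, per_frame_snr: float,
                   response_shape: np.ndarray | None = None,
                   noise_sd: float = 1.0) -> float:
    """Relative-sigma bound for a known-shape amplitude in white noise.

    For n frames each carrying the signal a*h(x) in additive white
    Gaussian noise, var(a_hat) >= sigma^2 / (n ||h||^2), i.e.
    sigma_rel >= 1 / (snr_eff sqrt(n)) with snr_eff = a ||h|| / sigma.
    If ``response_shape`` is given, snr_eff is computed from its energy;
    otherwise ``per_frame_snr`` is used directly.
    """
    if n < 1:
        raise ValueError("need n >= 1 frames")
    if response_shape is not None:
        energy = float(np.sum(np.asarray(response_shape) ** 2))
        snr_eff = per_frame_snr * np.sqrt(energy) / noise_sd
    else:
        snr_eff = per_frame_snr
    if snr_eff <= 0:
        raise ValueError("snr must be positive")
    return float(1.0 / (snr_eff * np.sqrt(n)))


def increment_diffusivity_estimator(positions_nm: np.ndarray, dt: float,
                                    v_um_s: float = 0.0) -> float:
    """Maximum-likelihood D (um^2/s) from trajectory increments.

    D_hat = sum((dx - v dt)^2) / (2 n dt); attains the CRLB, so it serves
    as the reference estimator in precision benchmarks.
    """
    dx = np.diff(np.asarray(positions_nm, dtype=np.float64))
    if dx.size < 1:
        raise ValueError("need at least 2 positions")
    resid = dx - v_um_s * 1e3 * dt
    d_nm2_s = float(np.sum(resid**2) / (2.0 * dx.size * dt))
    return d_nm2_s / 1e6


def matched_filter_amplitude(frames: np.ndarray, template: np.ndarray) -> float:
    """ML amplitude of a known per-frame template in white Gaussian noise."""
    frames = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    h = np.asarray(template, dtype=np.float64)
    energy = float(np.sum(h**2))
    if energy == 0:
        raise ValueError("template has zero energy")
    return float(np.sum(frames @ h) / (frames.shape[0] * energy))


def precision_vs_n(estimator: Callable[[object], float],
                   simulate: Callable[[int, np.random.Generator], object],
                   n_grid: Sequence[int], n_replicates: int,
                   rng: np.random.Generator,
                   bound: Callable[[int], float] | None = None,
                   ) -> tuple[np.ndarray, CRLBCurve | None]:
    """Empirical relative-sigma curve of an estimator vs. trajectory length.

    For each N, ``simulate(N, rng)`` produces one replicate input, the
    estimator maps it to a scalar, and sigma_rel = std/|mean| is computed
    across replicates (mean as the measure of centre).  A degenerate
    (constant) estimator yields sigma_rel = 0.  When ``bound`` is given,
    the matching theoretical curve is returned alongside.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates per N")
    sigma_rel = np.empty(len(n_grid))
    for i, n in enumerate(n_grid):
        vals = np.array([estimator(simulate(int(n), rng))
                         for _ in range(n_replicates)])
        centre = vals.mean()
        sigma_rel[i] = vals.std(ddof=1) / abs(centre) if centre != 0 else np.inf
    curve = None
    if bound is not None:
        b = tuple(float(bound(int(n))) for n in n_grid)
        curve = CRLBCurve(n_values=tuple(int(n) for n in n_grid),
                          sigma_rel_mw=b, sigma_rel_rs=b)
    return sigma_rel, curve
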