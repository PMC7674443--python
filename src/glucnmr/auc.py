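"""Sedimentation-equilibrium simulation and single-species global fitting.

At equilibrium, an ideal single species in a sector cell follows

    c(r) = c_ref * exp[ M (1 - vbar*rho) omega^2 (r^2 - r_ref^2) / (2 R T) ] + baseline

with M the molar mass (g/mol), vbar the partial specific volume (mL/g), rho
the solvent density (g/cm^3), omega the angular rotor speed (rad/s), r the
radius (cm), and R = 8.314e7 erg/(mol K) in the cgs convention.  ln c is
linear in r^2 with slope sigma/2 where sigma = M(1-vbar*rho)*omega^2/(R T).

The global fit shares a single M across all scans (different speeds and
loading concentrations) with per-scan reference concentration and baseline,
by nonlinear least squares — the ideal-species approximation to a
SEDPHAT-style multi-speed, multi-concentration analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "AucScan",
    "AucFit",
    "simulate_scan",
    "global_fit",
    "reduced_buoyancy",
    "R_GAS_CGS",
]

#: Gas constant, erg / (mol K).
R_GAS_CGS = 8.314e7


@dataclass
class AucScan:
    """One radial absorbance profile at a given rotor speed."""

    radii: np.ndarray  # cm, strictly increasing
    absorbance: np.ndarray  # AU
    rotor_speed: float  # rpm
    loading_conc: str = ""  # label, e.g. "0.3 mg/mL"

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")
        if self.rotor_speed < 0:
            raise ValueError("rotor speed must be non-negative")


@dataclass
class AucFit:
    """Global single-species fit result."""

    M: float  # g/mol
    c_ref: np.ndarray  # per scan
    baseline: np.ndarray  # per scan
    vbar: float
    rho: float
    temperature: float
    residual_rms: float
    identifiable: bool = True
    converged: bool = True
    ln_slope_diagnostic: np.ndarray = field(default_factory=lambda: np.array([]))


def reduced_buoyancy(
    M: float, vbar: float, rho: float, rpm: float, temperature: float
) -> float:
    """sigma = M (1 - vbar rho) omega^2 / (R T), 1/cm^2."""
    omega = rpm * 2.0 * np.pi / 60.0
    return M * (1.0 - vbar * rho) * omega**2 / (R_GAS_CGS * temperature)


def _profile(radii, M, vbar, rho, rpm, temperature, c_ref, r_ref, baseline):
    sigma = reduced_buoyancy(M, vbar, rho, rpm, temperature)
    return c_ref * np.exp(0.5 * sigma * (radii**2 - r_ref**2)) + baseline


def simulate_scan(
    M: float,
    vbar: float,
    rho: float,
    rpm: float,
    radii: np.ndarray,
    c_ref: float,
    r_ref: float | None = None,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    temperature: float = 293.15,
    loading_conc: str = "",
) -> AucScan:
    """Simulate one equilibrium scan; deterministic given the seed."""
    radii = np.asarray(radii, dtype=float)
    if r_ref is None:
        r_ref = float(radii[0])
    a = _profile(radii, M, vbar, rho, rpm, temperature, c_ref, r_ref, baseline)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        a = a + rng.normal(0.0, noise_sd, size=a.shape)
    return AucScan(radii=radii, absorbance=a, rotor_speed=rpm, loading_conc=loading_conc)


def global_fit(
    scans: list[AucScan],
    vbar: float,
    rho: float,
    temperature: float = 293.15,
    M0: float = 20_000.0,
) -> AucFit:
    """Fit one shared molar mass M with per-scan c_ref and baseline.

    Flat profiles (rotor at rest, or neutral buoyancy) carry no mass
    information: the fit is then flagged unidentifiable rather than
    returning a spurious M.  A negative fitted M raises.
    """
    if not scans:
        raise ValueError("need at least one scan")
    for s in scans:
        if len(s.radii) < 10:
            raise ValueError("each scan needs >= 10 points")
    r_refs = [float(s.radii[0]) for s in scans]

    def unpack(theta):
        return theta[0], theta[1 : 1 + len(scans)], theta[1 + len(scans) :]

    def residuals(theta):
        m, crefs, baselines = unpack(theta)
        out = []
        for s, cr, bl, rr in zip(scans, crefs, baselines, r_refs):
            out.append(
                _profile(s.radii, m, vbar, rho, s.rotor_speed, temperature, cr, rr, bl)
                - s.absorbance
            )
        return np.concatenate(out)

    spans = [float(s.absorbance.max() - s.absorbance.min()) for s in scans]
    theta0 = np.concatenate(
        [[M0], [max(sp, 0.01) for sp in spans], [float(s.absorbance.min()) for s in scans]]
    )
    sol = least_squares(residuals, theta0, method="lm", max_nfev=20_000)
    m, crefs, baselines = unpack(sol.x)
    res = residuals(sol.x)
    rms = float(np.sqrt(np.mean(res**2)))

    # identifiability: a perfectly flat data set cannot constrain M
    identifiable = True
    if all(sp < 1e-12 for sp in spans) or all(
        abs(reduced_buoyancy(1.0, vbar, rho, s.rotor_speed, temperature)) < 1e-30
        for s in scans
    ):
        identifiable = False
    if identifiable and m <= 0:
        raise ValueError(f"fitted molar mass is non-positive ({m:.3g} g/mol)")

    # linearized diagnostic: slope of ln(c - baseline) vs r^2 should be sigma/2
    slopes = []
    for s, bl in zip(scans, baselines):
        c = s.absorbance - bl
        mask = c > 1e-6
        if mask.sum() >= 2:
            slope = np.polyfit(s.radii[mask] ** 2, np.log(c[mask]), 1)[0]
        else:
            slope = np.nan
        slopes.append(slope)

    return AucFit(
        M=float(m),
        c_ref=np.asarray(crefs),
        baseline=np.asarray(baselines),
        vbar=vbar,
        rho=rho,
        temperature=temperature,
        residual_rms=rms,
        identifiable=identifiable,
        converged=bool(sol.success),
        ln_slope_diagnostic=np.asarray(slopes),
    )
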