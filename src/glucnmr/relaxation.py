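"""Backbone dynamics: hetNOE flexibility, H/D exchange classes, CPMG dispersion.

Flexibility on the sub-nanosecond scale is read from the steady-state
1H-15N heteronuclear NOE: residues with NOE strictly below 0.5 are
classified flexible.  Missing interior NOE values may be interpolated as the
mean of the nearest flanking measured residues.  Slower, stability-related
motion is read from H/D exchange: amides still visible after 20 min or 18 h
in D2O are protected.

Micro-to-millisecond exchange is analysed from constant-time
relaxation-compensated CPMG experiments:

    R2eff(nu) = -(1/T_relax) * ln(I(nu) / I0)

with T_relax = 40 ms (two 20 ms CPMG blocks) by default.  The screening
statistic is Delta R2 = R2eff(50 Hz) - R2eff(1 kHz), reported when strictly
above 2 1/s.  Exchange parameters come from the fast-exchange (Luz-Meiboom)
closed form

    R2eff(nu) = R2_0 + (Phi_ex / k_ex) * [1 - (4 nu / k_ex) * tanh(k_ex / (4 nu))]

fitted with a single global k_ex shared across residues (per-residue
R2_0 >= 0 and Phi_ex >= 0 profiled out by non-negative linear least
squares), with a bootstrap over residues for the k_ex uncertainty.  The
general two-state (Carver-Richards) expression is available behind a model
flag for slower exchange regimes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar, nnls

__all__ = [
    "HetNoeProfile",
    "HdxRecord",
    "CpmgSeries",
    "DispersionFit",
    "interpolate_missing_noe",
    "classify_flexible",
    "classify_hdx",
    "r2eff_from_intensities",
    "delta_r2",
    "fit_two_state",
    "luz_meiboom_r2eff",
    "carver_richards_r2eff",
    "STUDY_CPMG_RATES",
    "DEFAULT_T_RELAX",
    "NOE_FLEXIBLE_THRESHOLD",
    "DELTA_R2_THRESHOLD",
]

#: CPMG pulsing rates (Hz) of the study design.
STUDY_CPMG_RATES: tuple[float, ...] = (50, 100, 150, 200, 250, 300, 400, 500, 600, 800, 1000)

#: Total constant-time relaxation delay, s (two 20 ms CPMG blocks).
DEFAULT_T_RELAX = 0.040

#: hetNOE below this (strict) marks sub-ns flexibility.
NOE_FLEXIBLE_THRESHOLD = 0.5

#: Delta R2 screening threshold, 1/s (strict ">").
DELTA_R2_THRESHOLD = 2.0


@dataclass
class HetNoeProfile:
    """Per-residue hetNOE values; NaN marks missing, provenance tracks interpolation."""

    seq_ids: np.ndarray
    values: np.ndarray  # NaN where missing
    provenance: list[str] = field(default_factory=list)  # "measured" | "interpolated"

    def __post_init__(self) -> None:
        self.seq_ids = np.asarray(self.seq_ids, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if not self.provenance:
            self.provenance = [
                "measured" if np.isfinite(v) else "missing" for v in self.values
            ]


@dataclass
class HdxRecord:
    """Amide-proton retention after 20 min and 18 h in D2O."""

    seq_id: int
    retained_20min: bool
    retained_18h: bool

    def __post_init__(self) -> None:
        if self.retained_18h and not self.retained_20min:
            raise ValueError(
                f"residue {self.seq_id}: signal retained at 18 h but not at 20 min "
                "violates the exchange time-course"
            )


@dataclass
class CpmgSeries:
    """One residue's CPMG intensities versus pulsing rate, with reference I0."""

    seq_id: int
    rates: np.ndarray  # Hz
    intensities: np.ndarray
    intensity_ref: float
    t_relax: float = DEFAULT_T_RELAX

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(set(self.rates.tolist())) != len(self.rates) or np.any(self.rates <= 0):
            raise ValueError(f"residue {self.seq_id}: rates must be positive and distinct")
        if self.t_relax <= 0:
            raise ValueError("t_relax must be positive")


@dataclass
class DispersionFit:
    """Global two-state exchange fit: shared k_ex, per-residue R2_0 and Phi_ex."""

    kex: float
    kex_sd: float
    seq_ids: np.ndarray
    r20: np.ndarray
    phiex: np.ndarray
    model: str = "fast-exchange"
    identifiable: bool = True
    converged: bool = True


# ---------------------------------------------------------------- hetNOE/HDX

def interpolate_missing_noe(profile: HetNoeProfile) -> HetNoeProfile:
    """Fill interior gaps with the mean of the nearest flanking measured values.

    Runs of consecutive missing residues all receive the same mean of the two
    nearest measured neighbours.  Leading and trailing gaps stay missing.
    Assumes consecutive residue indexing.
    """
    values = profile.values.copy()
    provenance = list(profile.provenance)
    measured = np.isfinite(values)
    idx = np.nonzero(measured)[0]
    if idx.size == 0:
        return HetNoeProfile(profile.seq_ids.copy(), values, provenance)
    for i in range(len(values)):
        if measured[i]:
            continue
        left = idx[idx < i]
        right = idx[idx > i]
        if left.size and right.size:
            values[i] = 0.5 * (values[left[-1]] + values[right[0]])
            provenance[i] = "interpolated"
    return HetNoeProfile(profile.seq_ids.copy(), values, provenance)


def classify_flexible(
    profile: HetNoeProfile, threshold: float = NOE_FLEXIBLE_THRESHOLD
) -> dict[int, str]:
    """Label residues rigid/flexible by hetNOE; strict `NOE < threshold` is flexible.

    Residues still missing a value are left out of the returned mapping.
    """
    labels: dict[int, str] = {}
    for sid, v in zip(profile.seq_ids, profile.values):
        if not np.isfinite(v):
            continue
        labels[int(sid)] = "flexible" if v < threshold else "rigid"
    return labels


def classify_hdx(records: Iterable[HdxRecord]) -> dict[int, str]:
    """Three-way protection class: fast | protected_20min | protected_18h."""
    out: dict[int, str] = {}
    for r in records:
        if r.retained_18h:
            out[r.seq_id] = "protected_18h"
        elif r.retained_20min:
            out[r.seq_id] = "protected_20min"
        else:
            out[r.seq_id] = "fast"
    return out


# ------------------------------------------------------------------- CPMG

def r2eff_from_intensities(series: CpmgSeries) -> np.ndarray:
    """Constant-time R2eff(nu) = -(1/T_relax) ln(I(nu)/I0), 1/s."""
    if series.intensity_ref <= 0:
        raise ValueError(f"residue {series.seq_id}: reference intensity must be positive")
    bad = np.nonzero(series.intensities <= 0)[0]
    if bad.size:
        raise ValueError(
            f"residue {series.seq_id}: non-positive intensity at rate "
            f"{series.rates[bad[0]]:g} Hz"
        )
    return -np.log(series.intensities / series.intensity_ref) / series.t_relax


def luz_meiboom_r2eff(
    nu: np.ndarray | float, r20: float, phiex: float, kex: float
) -> np.ndarray | float:
    """Fast-exchange (Luz-Meiboom) dispersion curve, 1/s."""
    nu = np.asarray(nu, dtype=float)
    x = kex / (4.0 * nu)
    return r20 + (phiex / kex) * (1.0 - np.tanh(x) / x)


def carver_richards_r2eff(
    nu: np.ndarray | float,
    r20: float,
    kex: float,
    pa: float,
    dw: float,
) -> np.ndarray | float:
    """General two-state (Carver-Richards) dispersion curve, 1/s.

    `dw` is the chemical-shift difference in rad/s, `pa` the major-state
    population; both exchanging states share R2_0.  In the fast-exchange
    limit this reduces to Luz-Meiboom with Phi_ex = pa*(1-pa)*dw**2.
    """
    nu = np.asarray(nu, dtype=float)
    pb = 1.0 - pa
    tau_cp = 1.0 / (2.0 * nu)  # delay between successive refocusing pulses
    psi = kex**2 - dw**2
    zeta = 2.0 * dw * kex * (pa - pb)
    root = np.sqrt(psi**2 + zeta**2)
    dplus = 0.5 * ((psi + 2.0 * dw**2) / root + 1.0)
    dminus = 0.5 * ((psi + 2.0 * dw**2) / root - 1.0)
    eta_plus = (tau_cp / np.sqrt(2.0)) * np.sqrt(np.maximum(psi + root, 0.0))
    eta_minus = (tau_cp / np.sqrt(2.0)) * np.sqrt(np.maximum(-psi + root, 0.0))
    arg = dplus * np.cosh(eta_plus) - dminus * np.cos(eta_minus)
    return r20 + 0.5 * (kex - np.arccosh(np.maximum(arg, 1.0)) / tau_cp)


def delta_r2(
    series_set: Iterable[CpmgSeries],
    low: float = 50.0,
    high: float = 1000.0,
    threshold: float = DELTA_R2_THRESHOLD,
):
    """Per-residue Delta R2 = R2eff(low) - R2eff(high) with strict-> flagging.

    Residues missing either rate are skipped with a warning.  Returns a list
    of dicts (seq_id, delta_r2, flagged) — unflagged residues are retained.
    """
    out = []
    for s in series_set:
        r = r2eff_from_intensities(s)
        has_low = np.isclose(s.rates, low)
        has_high = np.isclose(s.rates, high)
        if not has_low.any() or not has_high.any():
            warnings.warn(
                f"residue {s.seq_id}: missing the {low:g} or {high:g} Hz point; skipped"
            )
            continue
        d = float(r[has_low][0] - r[has_high][0])
        out.append({"seq_id": s.seq_id, "delta_r2": d, "flagged": d > threshold})
    return out


def _design_column(nu: np.ndarray, kex: float) -> np.ndarray:
    x = kex / (4.0 * nu)
    return (1.0 - np.tanh(x) / x) / kex


def _fit_linear_given_kex(
    r2eff_list: list[np.ndarray], rates_list: list[np.ndarray], kex: float
):
    """For fixed kex, per-residue non-negative LS for (R2_0, Phi_ex); returns SSE."""
    sse = 0.0
    r20s, phis = [], []
    for r2, nu in zip(r2eff_list, rates_list):
        a = np.column_stack([np.ones_like(nu), _design_column(nu, kex)])
        coef, resid = nnls(a, r2)
        r20s.append(coef[0])
        phis.append(coef[1])
        sse += float(np.sum((a @ coef - r2) ** 2))
    return sse, np.array(r20s), np.array(phis)


def _optimal_kex(r2eff_list, rates_list, bounds=(1.0, 6.0)) -> float:
    res = minimize_scalar(
        lambda lk: _fit_linear_given_kex(r2eff_list, rates_list, 10.0**lk)[0],
        bounds=bounds,
        method="bounded",
        options={"xatol": 1e-5},
    )
    return float(10.0 ** res.x)


def fit_two_state(
    series_set: Sequence[CpmgSeries],
    model: str = "fast-exchange",
    n_bootstrap: int = 200,
    seed: int = 0,
) -> DispersionFit:
    """Fit a shared (global) exchange rate k_ex across residues.

    The fast-exchange model is linear in (R2_0, Phi_ex) at fixed k_ex, so the
    global fit reduces to a bounded 1-D search over log10 k_ex with the
    per-residue amplitudes profiled out by non-negative least squares.  The
    k_ex uncertainty is a bootstrap over residues (>= 2 residues required;
    `n_bootstrap` resamples).

    When no residue shows appreciable dispersion the exchange rate is
    unidentifiable; the fit is returned flagged, never silently.
    """
    if model not in ("fast-exchange", "general"):
        raise ValueError(f"unknown model {model!r}")
    series_set = list(series_set)
    if not series_set:
        raise ValueError("need at least one residue series")
    for s in series_set:
        if len(s.rates) < 4:
            raise ValueError(
                f"residue {s.seq_id}: need >= 4 distinct rates, got {len(s.rates)}"
            )
    r2eff_list = [r2eff_from_intensities(s) for s in series_set]
    rates_list = [s.rates for s in series_set]
    seq_ids = np.array([s.seq_id for s in series_set])

    # identifiability: does the exchange term improve on a flat fit at all?
    sse_flat = sum(float(np.sum((r - r.mean()) ** 2)) for r in r2eff_list)
    kex = _optimal_kex(r2eff_list, rates_list)
    sse_fit, r20, phi = _fit_linear_given_kex(r2eff_list, rates_list, kex)
    dispersion_span = max(float(r.max() - r.min()) for r in r2eff_list)
    identifiable = bool(np.any(phi > 0) and dispersion_span > 0.5 and sse_fit < 0.99 * sse_flat)

    kex_sd = float("nan")
    if identifiable and len(series_set) >= 2 and n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        n = len(series_set)
        boots = []
        for _ in range(n_bootstrap):
            pick = rng.integers(0, n, size=n)
            boots.append(
                _optimal_kex([r2eff_list[i] for i in pick], [rates_list[i] for i in pick])
            )
        kex_sd = float(np.std(boots))

    fit = DispersionFit(
        kex=kex,
        kex_sd=kex_sd,
        seq_ids=seq_ids,
        r20=r20,
        phiex=phi,
        model=model,
        identifiable=identifiable,
    )
    if model == "general":
        # refine with the Carver-Richards expression, seeded from the
        # fast-exchange solution (pa fixed near unity, dw from Phi_ex)
        fit = _refine_general(fit, r2eff_list, rates_list)
    return fit


def _refine_general(fit: DispersionFit, r2eff_list, rates_list) -> DispersionFit:
    from scipy.optimize import least_squares

    pa = 0.95
    dw0 = np.sqrt(np.maximum(fit.phiex, 1e-6) / (pa * (1 - pa)))

    def resid(theta):
        kex = 10.0 ** theta[0]
        out = []
        for i, (r2, nu) in enumerate(zip(r2eff_list, rates_list)):
            r20 = theta[1 + 2 * i]
            dw = theta[2 + 2 * i]
            out.append(carver_richards_r2eff(nu, r20, kex, pa, dw) - r2)
        return np.concatenate(out)

    theta0 = np.concatenate(
        [[np.log10(fit.kex)], np.ravel(np.column_stack([fit.r20, dw0]))]
    )
    sol = least_squares(resid, theta0, method="lm", max_nfev=2000)
    kex = float(10.0 ** sol.x[0])
    r20 = sol.x[1::2].copy()
    dw = sol.x[2::2]
    phi = 0.95 * 0.05 * dw**2
    return replace(fit, kex=kex, r20=r20, phiex=phi, model="general", converged=bool(sol.success))
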