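"""Synthetic-data generators with planted ground truth for every pipeline stage.

Each generator is a pure function of its spec + seed (bit-identical reruns)
and produces outputs satisfying the consuming module's preconditions by
construction:

* :func:`make_ensemble` — a multi-model ensemble shaped like a solution-NMR
  calculation pool: a smooth self-avoiding backbone trace (N, CA, C atoms;
  SG on cysteines), rigid ranges jittered with isotropic Gaussian noise,
  flexible ranges re-sampled with a larger smooth perturbation, and planted
  disulfide bonds whose S-gamma distance is drawn within bonding range
  ([1.9, 2.3] A) in an exactly controlled fraction of the models and kept
  >= 5 A otherwise.  Backbone realism is deliberately minimal (no
  Ramachandran enforcement); only the statistics the downstream analyses
  consume — distances, scatter, S-gamma geometry — are controlled.
* :func:`make_dispersion_dataset` — CPMG intensities from the forward
  Luz-Meiboom model with multiplicative noise.
* :func:`make_hetnoe_and_hdx` — hetNOE values drawn from a rigid band
  (0.7-0.9) and a flexible band (-0.3-0.4), with H/D protection assigned
  only inside rigid ranges.
* :func:`make_auc_scans` — Boltzmann-exponential sedimentation-equilibrium
  profiles over a speeds x concentrations design with additive noise.
* :func:`make_digest_sample` — observed-mass tables for disulfide-linked
  fragment groups, with optional Gaussian mass error.

`gluc_like_ensemble_spec` mirrors the study conditions: 19 models, 168
residues, rigid core 10-18/36-81/96-145 with ~1.4 A C-alpha scatter,
disordered termini/IDRs, and the five disulfides planted at satisfaction
fractions {0.92, 0.56, 1.0, 1.0, 1.0}.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .auc import AucScan, simulate_scan
from .msmap import Peptide, digest, enumerate_linked_species
from .relaxation import (
    DEFAULT_T_RELAX,
    STUDY_CPMG_RATES,
    CpmgSeries,
    HdxRecord,
    HetNoeProfile,
    luz_meiboom_r2eff,
)
from .sequences import (
    GLUC_CORE_RANGES,
    GLUC_DISULFIDES,
    GLUC_FLEXIBLE_RANGES,
    GLUC_MATURE,
)
from .structure_io import Atom, Ensemble, Model, ResidueRecord

__all__ = [
    "EnsembleSpec",
    "DispersionSpec",
    "GeometryError",
    "make_ensemble",
    "make_dispersion_dataset",
    "make_hetnoe_and_hdx",
    "make_auc_scans",
    "make_digest_sample",
    "gluc_like_ensemble_spec",
]


class GeometryError(ValueError):
    """Raised when a requested synthetic geometry cannot be realised."""


@dataclass
class EnsembleSpec:
    """Recipe for a synthetic NMR-style ensemble with planted disulfides."""

    n_models: int = 19
    n_residues: int = 168
    rigid_ranges: tuple[tuple[int, int], ...] = GLUC_CORE_RANGES
    flexible_ranges: tuple[tuple[int, int], ...] = GLUC_FLEXIBLE_RANGES
    #: (cys_i, cys_j, fraction of models in which the bond is satisfied)
    planted_bonds: tuple[tuple[int, int, float], ...] = ()
    sigma_core: float = 0.62  # A per coordinate; gives ~1.4 A C-alpha scatter
    sigma_flex: float = 5.0  # A, disordered-segment scatter
    seed: int = 0
    sequence: str | None = None  # default: poly-Ala with Cys at bond members
    #: "independent": each bond gets its own exact-size random model subset;
    #: "nested": subsets are prefixes of one permutation (intersection = min)
    subset_mode: str = "independent"

    def __post_init__(self) -> None:
        for lo, hi in list(self.rigid_ranges) + list(self.flexible_ranges):
            if not (1 <= lo <= hi <= self.n_residues):
                raise ValueError(f"range {lo}-{hi} outside 1..{self.n_residues}")
        for i, j, f in self.planted_bonds:
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"bond {i}/{j}: fraction {f} outside [0, 1]")
            if not (1 <= i <= self.n_residues and 1 <= j <= self.n_residues) or i == j:
                raise ValueError(f"invalid bond residues {i}/{j}")
        if self.sequence is not None and len(self.sequence) != self.n_residues:
            raise ValueError("sequence length must equal n_residues")
        if self.subset_mode not in ("independent", "nested"):
            raise ValueError(f"unknown subset_mode {self.subset_mode!r}")


@dataclass
class DispersionSpec:
    """Recipe for a synthetic CPMG data set: per-residue (R2_0, Phi_ex), shared kex."""

    residues: tuple[tuple[int, float, float], ...]  # (seq_id, r20, phiex)
    kex: float = 2500.0
    rates: tuple[float, ...] = STUDY_CPMG_RATES
    noise: float = 0.0  # multiplicative intensity noise fraction
    t_relax: float = DEFAULT_T_RELAX
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kex <= 0:
            raise ValueError("kex must be positive")
        for sid, r20, phi in self.residues:
            if r20 < 0 or phi < 0:
                raise ValueError(f"residue {sid}: parameters must be non-negative")


def gluc_like_ensemble_spec(seed: int = 0, subset_mode: str = "independent") -> EnsembleSpec:
    """The study-condition ensemble: 19 models, 168 residues, five planted bonds."""
    fractions = (0.92, 0.56, 1.0, 1.0, 1.0)
    return EnsembleSpec(
        n_models=19,
        n_residues=168,
        rigid_ranges=GLUC_CORE_RANGES,
        flexible_ranges=GLUC_FLEXIBLE_RANGES,
        planted_bonds=tuple(
            (i, j, f) for (i, j), f in zip(GLUC_DISULFIDES, fractions)
        ),
        sequence=GLUC_MATURE,
        seed=seed,
        subset_mode=subset_mode,
    )


# ------------------------------------------------------------- backbone trace

_CA_CA = 3.8  # A, consecutive C-alpha distance
_PAIR_TARGET = 5.5  # A, C-alpha distance of disulfide-bonded cysteines


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _embed_backbone(
    n: int, pairs: Sequence[tuple[int, int]], rng: np.random.Generator, iters: int = 500
) -> np.ndarray:
    """Smooth self-avoiding C-alpha trace with bonded pairs pulled together.

    Distance-geometry style iteration: planted pairs are sprung toward
    5.5 A with a Gaussian drag window (so whole chain segments follow and
    long-range contacts can close), chain bonds are projected back to
    3.8 A each sweep, and mild excluded-volume pushes keep the trace
    self-avoiding.  0-based pair indices.
    """
    # correlated random walk initialisation
    d = _unit(rng.normal(size=3))
    dirs = np.empty((n - 1, 3))
    for k in range(n - 1):
        d = _unit(d + 0.35 * rng.normal(size=3))
        dirs[k] = d
    pos = np.vstack([np.zeros(3), np.cumsum(dirs, axis=0) * _CA_CA])

    from scipy.spatial import cKDTree

    win = np.arange(-6, 7)
    wts = np.exp(-((win / 4.0) ** 2))
    for it in range(iters):
        for i, j in pairs:
            v = pos[j] - pos[i]
            dist = np.linalg.norm(v)
            corr = 0.3 * (dist - _PAIR_TARGET) / dist * v
            for k, w in zip(win, wts):
                if 0 <= i + k < n:
                    pos[i + k] += w * corr
                if 0 <= j + k < n:
                    pos[j + k] -= w * corr
        v = pos[1:] - pos[:-1]
        dist = np.linalg.norm(v, axis=1, keepdims=True)
        corr = 0.5 * (dist - _CA_CA) / dist * v
        pos[:-1] += corr
        pos[1:] -= corr
        if it % 20 == 10:
            tree = cKDTree(pos)
            for a, b in tree.query_pairs(3.2):
                if abs(a - b) <= 1 or (a, b) in pairs or (b, a) in pairs:
                    continue
                v = pos[b] - pos[a]
                dist = np.linalg.norm(v)
                if dist < 1e-9:
                    continue
                push = 0.3 * (3.2 - dist) / dist * v
                pos[a] -= push
                pos[b] += push
    for i, j in pairs:
        dist = np.linalg.norm(pos[j] - pos[i])
        if not (3.5 <= dist <= 7.5):
            raise GeometryError(
                f"planted bond between residues {i + 1} and {j + 1} is infeasible: "
                f"embedded C-alpha distance {dist:.2f} A"
            )
    return pos


def _smooth_noise(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    """Chain-correlated Gaussian displacement field with per-residue SD sigma."""
    w = rng.normal(size=(n + 4, 3))
    kernel = np.array([0.15, 0.2, 0.3, 0.2, 0.15])
    sm = np.empty((n, 3))
    for c in range(3):
        sm[:, c] = np.convolve(w[:, c], kernel, mode="valid")
    sm /= np.sqrt(np.sum(kernel**2))  # restore unit variance
    return sigma * sm


def _bond_subsets(spec: EnsembleSpec, rng: np.random.Generator) -> list[set[int]]:
    sizes = [int(round(f * spec.n_models)) for _, _, f in spec.planted_bonds]
    if spec.subset_mode == "nested":
        perm = rng.permutation(spec.n_models)
        return [set(perm[:k].tolist()) for k in sizes]
    return [
        set(rng.choice(spec.n_models, size=k, replace=False).tolist()) for k in sizes
    ]


def make_ensemble(spec: EnsembleSpec) -> Ensemble:
    """Generate a synthetic ensemble with planted disulfide connectivity."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    for i, j, _ in spec.planted_bonds:
        if abs(i - j) < 3:
            raise GeometryError(
                f"planted bond between residues {i} and {j} is infeasible: "
                "chain neighbours cannot reach disulfide geometry"
            )
    pairs0 = [(i - 1, j - 1) for i, j, _ in spec.planted_bonds]
    base = _embed_backbone(n, pairs0, rng)

    if spec.sequence is None:
        seq = ["A"] * n
        for i, j, _ in spec.planted_bonds:
            seq[i - 1] = seq[j - 1] = "C"
        sequence = "".join(seq)
    else:
        sequence = spec.sequence
        for i, j, _ in spec.planted_bonds:
            if sequence[i - 1] != "C" or sequence[j - 1] != "C":
                raise ValueError(f"bond {i}/{j} does not join two cysteines in the sequence")

    flexible = np.zeros(n, dtype=bool)
    for lo, hi in spec.flexible_ranges:
        flexible[lo - 1 : hi] = True

    subsets = _bond_subsets(spec, rng)

    # per-bond geometry drawn once so a zero-noise spec yields identical models
    bond_geom = []
    for i, j, _ in spec.planted_bonds:
        d = rng.uniform(1.9, 2.3)
        base_axis = _unit(base[j - 1] - base[i - 1])
        perp = rng.normal(size=3)
        perp -= perp.dot(base_axis) * base_axis
        bond_geom.append((d, _unit(perp)))
    free_cys_dirs = {
        ci: _unit(rng.normal(size=3))
        for ci, aa in enumerate(sequence)
        if aa == "C" and not any(ci in (i - 1, j - 1) for i, j, _ in spec.planted_bonds)
    }

    models: list[Model] = []
    for mi in range(spec.n_models):
        noise = rng.normal(0.0, spec.sigma_core, size=(n, 3))
        flex_noise = _smooth_noise(rng, n, spec.sigma_flex)
        ca = base + np.where(flexible[:, None], flex_noise, noise)

        sg: dict[int, np.ndarray] = {}
        bonded_here: set[int] = set()
        for bi, (i, j, _) in enumerate(spec.planted_bonds):
            ci, cj = i - 1, j - 1
            axis_u = _unit(ca[cj] - ca[ci])
            if mi in subsets[bi]:
                d, perp = bond_geom[bi]
                mid = 0.5 * (ca[ci] + ca[cj])
                sg[ci] = mid - 0.5 * d * perp
                sg[cj] = mid + 0.5 * d * perp
                bonded_here |= {ci, cj}
            else:
                if ci not in bonded_here and ci not in sg:
                    sg[ci] = ca[ci] - 2.4 * axis_u
                if cj not in bonded_here and cj not in sg:
                    sg[cj] = ca[cj] + 2.4 * axis_u
        for ci, direction in free_cys_dirs.items():
            if ci not in sg:
                sg[ci] = ca[ci] + 2.4 * direction

        residues = []
        for ri in range(n):
            prev_dir = _unit(ca[ri - 1] - ca[ri]) if ri > 0 else np.array([1.0, 0.0, 0.0])
            next_dir = _unit(ca[ri + 1] - ca[ri]) if ri < n - 1 else np.array([-1.0, 0.0, 0.0])
            atoms = [
                Atom("N", "N", ca[ri] + 0.75 * prev_dir),
                Atom("CA", "C", ca[ri].copy()),
                Atom("C", "C", ca[ri] + 0.75 * next_dir),
            ]
            if ri in sg:
                atoms.append(Atom("SG", "S", sg[ri]))
            residues.append(ResidueRecord(seq_id=ri + 1, aa=sequence[ri], atoms=atoms))
        models.append(Model(model_id=mi + 1, residues=residues))
    return Ensemble(models=models)


# -------------------------------------------------------------- other stages

def make_dispersion_dataset(spec: DispersionSpec) -> list[CpmgSeries]:
    """Forward Luz-Meiboom intensities I(nu) = I0 exp(-R2eff(nu) T_relax) + noise."""
    rng = np.random.default_rng(spec.seed)
    rates = np.asarray(spec.rates, dtype=float)
    out = []
    for sid, r20, phi in spec.residues:
        r2 = luz_meiboom_r2eff(rates, r20, phi, spec.kex)
        intens = np.exp(-r2 * spec.t_relax)
        if spec.noise > 0:
            intens = intens * (1.0 + rng.normal(0.0, spec.noise, size=intens.shape))
        out.append(
            CpmgSeries(
                seq_id=sid,
                rates=rates,
                intensities=intens,
                intensity_ref=1.0,
                t_relax=spec.t_relax,
            )
        )
    return out


def make_hetnoe_and_hdx(
    rigid_ranges: Sequence[tuple[int, int]],
    flexible_ranges: Sequence[tuple[int, int]],
    missing: Sequence[int] = (),
    seed: int = 0,
    n_residues: int | None = None,
) -> tuple[HetNoeProfile, list[HdxRecord]]:
    """hetNOE profile + H/D records emulating rigid-core/IDR patterns.

    Rigid residues draw NOE from 0.7-0.9, flexible from -0.3-0.4; requested
    residues are blanked.  H/D protection is assigned only inside rigid
    ranges (about half retain at 20 min, a subset of those at 18 h).
    """
    for lo, hi in rigid_ranges:
        for lo2, hi2 in flexible_ranges:
            if lo <= hi2 and lo2 <= hi:
                raise ValueError("rigid and flexible ranges must be disjoint")
    rng = np.random.default_rng(seed)
    if n_residues is None:
        n_residues = max(hi for _, hi in list(rigid_ranges) + list(flexible_ranges))
    flexible = np.zeros(n_residues, dtype=bool)
    for lo, hi in flexible_ranges:
        flexible[lo - 1 : hi] = True

    values = np.where(
        flexible,
        rng.uniform(-0.3, 0.4, size=n_residues),
        rng.uniform(0.7, 0.9, size=n_residues),
    )
    for sid in missing:
        values[sid - 1] = np.nan
    profile = HetNoeProfile(seq_ids=np.arange(1, n_residues + 1), values=values)

    records = []
    for sid in range(1, n_residues + 1):
        if flexible[sid - 1] or not np.isfinite(values[sid - 1]):
            r20, r18 = False, False
        else:
            r20 = bool(rng.random() < 0.5)
            r18 = bool(r20 and rng.random() < 0.4)
        records.append(HdxRecord(seq_id=sid, retained_20min=r20, retained_18h=r18))
    return profile, records


def make_auc_scans(
    M: float = 22_000.0,
    speeds_rpm: Sequence[float] = (12_000.0, 22_000.0, 37_000.0),
    concentrations: Sequence[float] = (1.2, 0.6, 0.3),
    noise_sd: float = 0.0,
    seed: int = 0,
    vbar: float = 0.73,
    rho: float = 1.006983,
    temperature: float = 293.15,
    radii: np.ndarray | None = None,
) -> list[AucScan]:
    """Speeds x concentrations equilibrium design (default 3 x 3 = 9 scans)."""
    if radii is None:
        radii = np.linspace(6.9, 7.2, 60)
    scans = []
    k = 0
    for conc in concentrations:
        for rpm in speeds_rpm:
            scans.append(
                simulate_scan(
                    M=M,
                    vbar=vbar,
                    rho=rho,
                    rpm=rpm,
                    radii=radii,
                    c_ref=conc,  # ~1 AU per mg/mL at 280 nm
                    baseline=0.0,
                    noise_sd=noise_sd,
                    seed=seed * 1000 + k,
                    temperature=temperature,
                    loading_conc=f"{conc:g} mg/mL",
                )
            )
            k += 1
    return scans


def make_digest_sample(
    sequence: str,
    linked_groups: Sequence[Sequence[tuple[int, int]]],
    seed: int = 0,
    mass_error_sd: float = 0.0,
    mass_type: str = "average",
    label: str = "none",
) -> pd.DataFrame:
    """Observed-mass table for groups of disulfide-linked fragment spans.

    Each group is a list of (start, end) spans referring to `sequence`
    numbering; the species mass follows the fully-oxidized linkage rules,
    with optional Gaussian mass error.  Returns a DataFrame with columns
    observed_mass_da / description.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group in linked_groups:
        peptides = [
            Peptide(
                span=(lo, hi),
                sequence=sequence[lo - 1 : hi],
                cys_positions=tuple(
                    k for k in range(lo, hi + 1) if sequence[k - 1] == "C"
                ),
            )
            for lo, hi in group
        ]
        if len(peptides) > 1 and any(p.n_cys == 0 for p in peptides):
            raise ValueError("every peptide of a multi-fragment group needs a cysteine")
        species = enumerate_linked_species(
            peptides, max_peptides=len(peptides), mass_type=mass_type, label=label
        )
        # the species joining the full group
        full = [s for s in species if len(s.peptides) == len(peptides)]
        target = full[0]
        mass = target.mass + (rng.normal(0.0, mass_error_sd) if mass_error_sd > 0 else 0.0)
        rows.append(
            {
                "observed_mass_da": mass,
                "description": "+".join(f"{lo}-{hi}" for lo, hi in group),
            }
        )
    return pd.DataFrame(rows, columns=["observed_mass_da", "description"])
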