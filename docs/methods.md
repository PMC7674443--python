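# Methods

This note records the models implemented in `glucnmr`, their assumptions,
the defaults that matter, and what the synthetic-data generators do and do
not emulate.

## Structure I/O

Multi-model PDB files are parsed with gemmi into typed containers
(`Atom`/`ResidueRecord`/`Model`/`Ensemble`).  Contract decisions:

* Residue numbering is taken verbatim from the file (for GLuc: mature-chain
  numbering from the first post-tag lysine).  No renumbering.
* Sequence identity across models is *enforced* at construction; the error
  names the first discrepant residue.
* Alternate locations: blank or 'A' kept, others dropped with a warning.
  Insertion codes are rejected — solution-NMR ensembles do not use them, and
  rejecting keeps the seq_id-keyed containers unambiguous.
* Hydrogens are read but excluded from heavy-atom geometry selections.
* The writer is a strict fixed-column formatter; coordinates that do not fit
  `%8.3f` raise instead of being clamped.  Round-trip fidelity is 0.001 Å
  (column precision), checked against Biopython as a second parser.
* Single-chain only; multi-chain files are out of scope and rejected.

## Ensemble geometry

Superposition is the closed-form least-squares rigid transform via SVD with
the determinant correction that excludes reflections.  Degenerate (fewer
than 3 atoms, collinear) configurations raise.  The pairwise RMSD matrix
superposes every model pair independently on the stated atom/residue
selection.  The representative is the argmin of the off-diagonal row mean;
ties break to the lowest model index.  Ensemble precision is reported as
mean ± SD of the RMSD of each *other* model to the representative.

Displacement profiles superpose each model on the representative using an
explicit rigid-core selection passed by the caller (no hidden default: the
choice of fitting frame changes the profile, so it is an argument), then
measure per-residue atom distances over all residues.  Heavy-atom RMSD uses
all non-hydrogen atoms of the selected residues; atoms missing from some
model are dropped pairwise with a warning.

Whether representative selection uses the restricted core ranges or all
residues is a caller choice; both are supported.

## Disulfide connectivity from ensembles

For each cysteine pair, the Sγ–Sγ Euclidean distance is recorded per model
and converted to the fraction of models strictly below a threshold
(default 3.0 Å).  Frequencies are counted *independently per pair* — one Sγ
may be within threshold of two partners in the same model — because that is
how per-pair observation statistics over a calculation pool are defined;
disjointness is imposed only afterwards, when the pairing is assigned as
the maximum-weight perfect matching over the frequencies (networkx
blossom algorithm; an exhaustive enumeration over all 945 matchings of 10
cysteines serves as the test oracle).  Bonds that are already unambiguous
can be fixed and are honored verbatim.  An odd number of free cysteines is
an error: the assignment model assumes a fully oxidized protein.  A model
"consistent" with a pairing satisfies *every* pair of the pairing below the
same threshold (the cutoff is configurable; 3.0 Å is the default here too).

## Backbone flexibility

hetNOE below 0.5 (strict `<`) labels a residue flexible.  Missing interior
values may be interpolated as the mean of the nearest measured flanking
residues — a run of consecutive gaps receives one shared value; leading and
trailing gaps stay missing and unlabeled, because one-sided extrapolation
at chain termini (precisely the flexible regions) would be circular.
Interpolated values carry a provenance flag.  H/D exchange is a three-way
class per residue (fast, protected at 20 min, protected at 18 h); retention
at 18 h without retention at 20 min violates the time-course and raises.

## CPMG relaxation dispersion

Effective transverse relaxation from constant-time relaxation-compensated
CPMG intensities: R₂eff(ν) = −ln(I(ν)/I₀)/T_relax with T_relax = 40 ms (two
20 ms CPMG blocks) by default.  The screen ΔR₂ = R₂eff(50 Hz) − R₂eff(1 kHz)
uses the two measured points, not model curves, and flags strictly above
2 s⁻¹.

The exchange fit defaults to the fast-exchange (Luz–Meiboom) closed form
with a single **global** kex: at kex ≈ 2500 s⁻¹ individual residues rarely
constrain their own rate, so per-residue analysis is unreliable and one
shared rate is the honest model; a per-residue mode exists for strong
dispersers.  At fixed kex the model is linear in (R₂⁰, Φex), so the global
fit is a bounded 1-D search over log₁₀ kex ∈ [1, 6] with the per-residue
amplitudes profiled out by non-negative least squares — no multistart, no
local-minimum risk.  Uncertainty is a bootstrap over residues (200
resamples by default), the natural resampling unit when the shared
parameter is identified across residues.  Identifiability is checked
explicitly: if no residue shows appreciable dispersion (span < 0.5 s⁻¹, or
the exchange term does not improve on a flat fit), the fit is returned
flagged rather than reporting a meaningless rate.  The general two-state
(Carver–Richards) expression is available behind `model="general"`; its
fast-exchange limit is verified against Luz–Meiboom in the tests.
Offset-effect handling is reduced to the caller supplying the per-peak
series with the smaller offset error; the tool does not re-implement
offset selection.

## Disulfide mapping by mass spectrometry

Digestion follows the plain trypsin rule (cleave C-terminal to K/R except
before P) through pyteomics' cleavage machinery with spans kept in original
numbering; fragments with 0…N missed cleavages are enumerated.  Peptide
masses come from residue mass tables shipped with the package (average and
monoisotopic; water 18.01528/18.010565, cystine correction 2 × 1.00794 /
2 × 1.0078250 per bond; uniform ¹⁵N adds 0.99703 Da per nitrogen).  Average
masses are the default — the printed 4259.01 Da is an average-scale value
(monoisotopic differs by ≈ 2.7 Da at this size) — and the LC–MS species is
assumed unlabeled, since the average-mass reconstruction only works
unlabeled.  Species of up to `max_peptides` fragments require every member
to carry a cysteine (the link must be covalent) and at least enough bonds
to hold the set together; the fully-oxidized default assigns
⌊total cys/2⌋ bonds, a free-thiol mode enumerates all counts.  Matching
returns all species within tolerance (default 0.5 Da) sorted by |Δ|.
Connectivity implications enumerate every perfect matching of the species'
cysteines that keeps the fragment graph connected (optionally restricted to
candidate pairs), reporting per-cysteine partner options and always/ever
pairs.

## Cavity detection

A cubic grid (0.6 Å default spacing) covers the model plus margin; cells
within (Bondi vdW radius + 1.4 Å probe) of a heavy atom are occupied;
flood fill from the box boundary (6-connectivity) marks the exterior; the
remaining empty components of ≥ 30 Å³ are interior cavities.  Open-mouthed
pockets are handled by a second mode: an exterior flood fill with an
enlarged probe (3.0 Å, sized so a substrate-scale mouth seals) defines a
closed envelope, and pocket voxels are envelope-interior cells empty at the
normal probe.  The grid algorithm is a reproducible, parameter-explicit
replacement for visualization-level surface analysis, so absolute volumes
depend on spacing/probe; the tests pin the discretization error on an
analytic hollow-shell fixture (volume within a few % of the enclosed
sphere, < 10 % change on halving the spacing).  Lining residues have a
heavy atom within 4.5 Å of a cavity voxel; composition classes are
positive {R,K,H}, negative {E,D}, hydrophobic {A,V,L,I,M,F,W,Y,P}, polar
(remainder).

## Sedimentation equilibrium

Single ideal species, cgs convention (R = 8.314×10⁷ erg mol⁻¹ K⁻¹, r in cm,
ρ in g/cm³, v̄ in mL/g):

    c(r) = c_ref · exp[ M(1 − v̄ρ) ω² (r² − r_ref²) / (2RT) ] + baseline

The global fit shares M across all scans with per-scan c_ref and baseline
(Levenberg–Marquardt).  Meniscus/bottom artifacts and mass-conservation
constraints are not modeled — the exponential ideal-species form is the
deliberate approximation to a full multi-experiment equilibrium analysis.
v̄ is a required input (0.73 mL/g is the generator default, a typical
protein value); ρ defaults to the measured buffer density 1.006983 g/cm³,
T to 293.15 K.  Flat data (rotor at rest, neutral buoyancy) cannot
constrain M; the fit flags itself unidentifiable instead of returning a
number.  A per-scan ln c vs r² slope diagnostic (= σ/2) is reported.

## Synthetic data: what it emulates, what it does not

All generators are pure functions of (spec, seed); reruns are
bit-identical.

`make_ensemble` builds a Cα trace as a correlated random walk refined by
distance-geometry iteration: chain bonds projected to 3.8 Å, planted
cysteine pairs sprung toward 5.5 Å Cα separation with a ±6-residue Gaussian
drag window (endpoint-only springs cannot close long-range contacts against
the chain projection), and mild excluded-volume pushes.  N and C atoms are
placed along the local chain directions; Sγ atoms of a planted bond are set
symmetric about the Cα midpoint at a bond distance drawn once per bond from
[1.9, 2.3] Å for the models in that bond's satisfaction subset, and pointed
apart (≥ 5 Å) otherwise, so pair frequencies are exact by counting.
Satisfaction subsets have exactly round(f·n_models) members, drawn
independently per bond by default; a "nested" mode (prefixes of one seeded
permutation) makes the count of fully-consistent models equal the minimum
over bonds when an exact joint count is needed.  Rigid ranges get isotropic
Gaussian noise (default σ = 0.62 Å per coordinate, calibrated once so the
19-model core shows the ~1.4 Å Cα scatter of the study conditions);
flexible ranges get a chain-smoothed field with σ = 5 Å.  Deliberately
*not* emulated: Ramachandran statistics, side chains, packing, realistic
bond geometry beyond the Cα spacing — only the statistics the downstream
analyses consume (distances, scatter, Sγ geometry) are controlled.
Consequently a passing pipeline demonstrates correct statistics and
inference logic, not robustness to real structural artifacts, and the
cavity stage is validated on analytic shell fixtures rather than on the
synthetic trace.

Dispersion sets are forward Luz–Meiboom intensities with multiplicative
Gaussian noise; hetNOE draws from a rigid band (0.7–0.9) and a flexible
band (−0.3–0.4) with H/D protection only inside rigid ranges; equilibrium
scans are the Boltzmann exponential with additive noise over the
3-speed × 3-loading design; digest samples compute linked-species masses
with optional Gaussian mass error.  Noise models are the simplest matching
each stage's assumptions.

## Numerical choices and degenerate inputs

* Strict inequalities throughout the thresholds (Sγ < 3.0 Å, NOE < 0.5,
  ΔR₂ > 2 s⁻¹); boundary cases are asserted exactly in the tests.
* Rotation matrices are proper to 1e-9; RMSD matrices symmetric with zero
  diagonal.
* kex search bracket [10, 10⁶] s⁻¹ in log space, tolerance 1e-5 decades.
* Representative ties break to the lowest index; mass-match ties order by
  |Δ| as computed.
* Degenerate inputs fail loudly: empty selections, missing Sγ atoms,
  non-positive intensities, odd cysteine counts, unwritable coordinates,
  flat AUC/dispersion data (flagged unidentifiable, never silent).

## Problem sizes used in the checks

The recovery studies run at the study's own scale — 19-model/168-residue
ensembles (100 seeded replicates for the assignment recovery rate; one
380-model pool for pair-frequency statistics), 5-residue × 11-rate
dispersion sets (50 noisy replicates), 9-scan equilibrium designs (50 noisy
replicates) — sizes at which each estimate is stable while the full suite
stays fast.

## Known limitations

* The disulfide generator controls planted-pair frequencies exactly but
  leaves decoy-pair frequencies to geometry; they are typically far below
  the planted ones, which is the regime the matching is designed for.
* The Carver–Richards path refines from the fast-exchange solution with a
  fixed major-state population; it is an option for slower exchange, not a
  full slow-exchange analysis with population fitting.
* Cavity volumes are grid-resolution dependent by construction; compare
  volumes only at matched spacing/probe.
* No mmCIF, no multi-chain, no peak picking, no docking, no
  sedimentation-velocity analysis.
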