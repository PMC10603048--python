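# Methods

This note documents the models implemented in `ppstab`, the defaults that
matter, the synthetic data the tests run on, and the limits of both.

## Structures and trajectories

Structures are parsed from PDB format into biotite `AtomArray`s.
Multi-MODEL files become trajectories: the first model is the topology
and every model contributes one coordinate frame; files whose models
disagree in atom count are rejected.  Alternate locations resolve to the
highest-occupancy conformer at parse time (ties go to the first-listed
conformer, conventionally "A"), so every downstream analysis sees exactly
one atom per name.  Waters and monatomic ions are dropped by default
while other HETATM groups (nucleotides, inhibitors) are kept, since
active-site ligands are part of the systems this package targets;
crystallographic waters can be retained with `drop_waters=False`.
Residue identity is `(chain, author number, insertion code)` throughout —
author numbering is what the literature on these systems quotes (T288,
K250, partner residues 61–89), so the package never renumbers.

Hydrogens are accepted on input but excluded from analysis selections by
default: every metric here is Cα/Cβ/heavy-atom based, which also makes
results indifferent to whether a model was protonated.

Partner bookkeeping (`fragment_stats`) counts residues by range
arithmetic — Σ(end − start + 1) over the declared segments — rather than
by atoms present, because construct sizes are quoted that way even when
interior residues are unmodelled; the heavy-atom count is what is
actually present.

## Ensemble PCA and fluctuation profiles

Superposition uses the closed-form Kabsch solution restricted to proper
rotations (mirror solutions are rejected by flipping the smallest
singular direction).  For an ensemble, members are first fitted to a
reference member and then twice re-fitted to the evolving ensemble mean —
the usual essential-dynamics convention; two mean-fit iterations are
enough for the fit to be stationary at the tolerances used here.

PCA runs on the 3N vector of core Cα coordinates (HETATM never
included).  The core is the set of residues carrying a Cα in every
member, minus caller-supplied exclusion windows; which residues to
exclude (e.g. a flexible activation loop that many crystal structures
leave unmodelled) is configuration, not a constant.  The decomposition
is an SVD of the mean-centred data matrix — numerically preferable to
forming the 3N×3N covariance — with eigenvalues λⱼ = sⱼ²/n.  The **1/n
normalisation is deliberate**: the per-residue fluctuation profile is
defined as

    F_i(k) = sqrt( Σ_{j≤k} λⱼ · |vⱼ(i)|² )

with |vⱼ(i)|² the squared 3-vector norm of residue i's loading, and with
k equal to the number of components this is *exactly* the Cα RMSF about
the ensemble mean (the test suite asserts the identity to 1e-6 Å).  The
default profile uses k = 5, matching the convention of reading the first
few PCs as the essential subspace; the exact per-PC weighting used by
other packages is not standardised, so the eigenvalue-weighted form that
guarantees the RMSF limit was chosen.

2D-RMSD matrices superpose every frame pair independently; exact
duplicate frames short-circuit to zero, so the identity of indiscernibles
holds exactly.

## Model completion

The completion workflow mirrors how a missing binding fragment is built
in practice: copy the backbone of a template partner that occupies the
same surface (the template must already be in the target's frame),
rename/renumber to the desired sequence, and grow any missing terminus.

* Grafted and mutated residues keep the backbone exactly (RMSD 0 by
  construction) and carry an idealized Cβ — 1.53 Å from Cα, tetrahedral
  (109.47°) to N and C, out-of-plane component chosen for L chirality
  (positive signed volume of (N−Cα, C−Cα, Cβ−Cα)).  Sidechains beyond
  Cβ are intentionally not built: every downstream metric is Cα/Cβ
  based, and rotamer building belongs to dedicated modelling software.
* Terminus extension places atoms by internal coordinates (NeRF) with
  ideal trans-peptide geometry: N–Cα 1.46 Å, Cα–C 1.52 Å, C–N 1.33 Å,
  ω = 180°; φ/ψ = (−140°, 135°) for "extended", (−57°, −47°) for
  "helical".  No energetics are applied; heavy-atom contacts under 2.0 Å
  against other chains are reported as clashes and left to the caller.
* No loop closure is attempted between a grafted fragment and a
  pre-existing one; `peptide_bond_lengths` reports the junction C–N
  distance so the gap is visible instead of silently absorbed.

## Interface metrics

* **Contact map**: residue pair in contact iff the minimum inter-residue
  distance is strictly below the cutoff (default 5 Å).  The default atom
  set is all heavy atoms — the field convention — with a `calpha` mode
  for backbone-only or Cβ-stub models; the choice is explicit in the
  result object because the two modes genuinely differ.
* **Separation change**: Δd(i,j) = d(first frame) − d(last frame) per
  receptor/partner Cα pair, so positive means approaching and negative
  means separation.  This two-snapshot design is a deliberately coarse
  summary (it discards the intervening frames); it answers "did the
  partner keep its pose" cheaply and is antisymmetric under swapping the
  frames, which the tests exploit.
* **Distance series**: Cβ–Cβ per frame, with glycine (or any Cβ-less
  residue) falling back to Cα and the series flagged as a surrogate.
  Distribution summaries use a fixed 0.25 Å histogram grid anchored at
  multiples of the bin width so histograms are comparable across series.
* **Salt bridges**: per-frame minimum over carboxylate oxygens
  (OD1/OD2/OE1/OE2) × basic nitrogens (NZ, NH1/NH2/NE).  The contact
  cutoff is 4.0 Å (N–O) and an interaction is labelled persistent when at
  least half the frames are below it — standard literature values, both
  configurable, since no single threshold is canonical.

## Tunnel proximity

Tunnel *detection* is out of scope; a tunnel is a named list of lining
residues on the receptor.  The two Aurora A kinase-domain tunnels that
overlap the partner interfaces ship as packaged definitions (author
numbering; tunnel 1: E183 I184 H187 L188 K250 V252 H280, tunnel 2:
K166 L169 L178 V182 V206 L208).  Engagement metrics are minima of
Cβ–Cβ distances over the tunnel residues; the engagement threshold
default of 8.0 Å sits midway between the tightly-interacting regime
(≲ 6 Å) and the clearly detached one (≳ 10 Å) seen in distance
distributions of such systems, and is configurable.  Residue-name
checking at resolution time guards against numbering mismatches.

## MM-GBSA scoring

Single-trajectory convention: the receptor and partner conformations are
the ones in the complex frame, so all intramolecular bonded energies
cancel in the difference and the MM term reduces to intermolecular
Coulomb + Lennard-Jones (k = 332.0637 kcal·Å/mol/e², AMBER-style
eps/Rmin/2 parameters with Lorentz–Berthelot combining, 18 Å nonbonded
cutoff).

Effective Born radii follow the OBC-II scheme: pairwise HCT descreening
integrals (closed form, validated against numerical quadrature in the
tests) summed into Ψ, then 1/Rᵢ = 1/ρ̃ᵢ − tanh(αΨ − βΨ² + γΨ³)/ρᵢ with
(α, β, γ) = (1.0, 0.8, 4.85) and ρ̃ = ρ − 0.09 Å.  A uniform descreening
scale factor of 0.8 is used (per-element scale factors are a refinement
the schematic parameter sets here do not carry).  The polar energy uses
the standard f_GB = sqrt(r² + RᵢRⱼ exp(−r²/4RᵢRⱼ)) including self terms,
ε_in = 1, ε_w = 78.5, zero salt.  The nonpolar term is γ·SASA with
γ = 0.005 kcal/mol/Å² and LCPO surface areas; per-atom areas are clamped
at zero, since the linear combination can undershoot for deeply buried
atoms.

Note an asymmetry worth stating: GB handles the *polar* solvation term
and LCPO/SASA the *nonpolar* one.  Source descriptions of such protocols
occasionally swap the two labels in prose; the implementation follows
the standard assignment.

Multi-pose scoring takes n poses (default 5) evenly spaced over the last
half of the trajectory — first pose at the midpoint frame, step
(last − midpoint) // (n−1), e.g. frames 50, 62, 74, 86, 98 of 100 — and
reports mean ± sample SD in kJ/mol.  Production MM-GBSA protocols
typically re-minimise each pose with the full force field first; here an
*optional* steepest-descent relaxation (≤ 500 steps, force tolerance
1 kcal/mol/Å) on the package's own nonbonded energy plus harmonic
positional restraints (10 kcal/mol/Å², standing in for the bonded terms
this function does not carry) is provided and off by default — the
rigid-geometry score is the reference behaviour.

Ligand efficiency divides the mean pose score by the partner heavy-atom
count and rounds half-away-from-zero to 2 decimals; the divisor is the
*MD-pose mean*, not the static-model score, which is the convention the
benchmark table arithmetic fixes.

Parameters come from a whitespace-delimited per-atom table
(chain/resnum/atomname keyed).  The built-in toy assignment — unit
charges on the charged-group atom (or Cβ stub) of Lys/Arg (+1) and
Asp/Glu (−1), element-based mbondi-like GB radii, LCPO coefficients
(1, −1, 0, 0) — is schematic bookkeeping, exact for isolated atoms and
pairwise overlaps, and is *not* a force field.  Absolute energies from
it are meaningful only relative to each other and to the closed-form
limits the tests pin down.

## Synthetic data: what it emulates and what it does not

The generators produce exactly the signal each analysis stage is meant
to detect, and nothing else:

* *Planted-mode ensembles*: members displaced along random orthonormal
  modes with Gaussian amplitudes of chosen variances.  Modes are
  orthogonalised against the six rigid-body motions of the base
  geometry, so planted variance cannot leak into (or be removed by) the
  superposition step — PCA must recover the planted variance ratio, and
  the acceptance run checks 9:1 → fractions 0.90/0.10 ± 0.03 at n = 500.
* *Bound trajectories*: i.i.d. Gaussian jitter of σ Å per atom
  coordinate about a fixed complex — stationary by construction.
* *Dissociating trajectories*: a rigid whole-chain partner translation
  of k·drift at frame k (default 0.05 Å/frame over 100 frames) plus
  optional jitter.  Jitter is per-atom and drift is per-chain, cleanly
  separating "fluctuation" from "dissociation".
* *Toy charge systems*: single ions, ion pairs and sphere pairs whose
  GB/SASA energies have closed forms.

Real dissociation is not a rigid translation, real fluctuations are
correlated along the chain, and none of these generators have solvent,
inertia or a force field.  Passing tests therefore demonstrate that the
*metrics* respond correctly to controlled signals — not that the toy
trajectories resemble microsecond MD.  All generators are bit-reproducible
from a seed.

For the dissociation acceptance check the partner is a translated copy
of the receptor chain: that construction guarantees Cα pairs exactly
parallel to the drift axis, for which the start-vs-end separation change
is analytically −(n−1)·drift (−4.95 Å at the defaults) with zero jitter.

## Numerical choices and degenerate inputs

* PCA on identical structures raises (zero variance) rather than
  returning an arbitrary basis; eigenvalues below 1e-12 of the leading
  one are dropped.
* Kabsch requires ≥ 3 points with nonzero spread; coincident atoms are
  rejected in energy kernels (r = 0 would be a parameterisation error,
  not a physical state).
* Ties: altloc ties keep the first-listed conformer; closest-residue
  ties resolve to the lower residue number; LE rounding is
  half-away-from-zero.
* PDB coordinates beyond ±9999.999 Å cannot be represented in the fixed
  field width and are rejected at write time; round-tripping quantises
  coordinates to 3 decimals, which the tests treat as the precision
  floor for any re-read analysis.
* The pipeline writes no timestamps into metric files, so reruns with
  the same config and seed are hash-identical.

## Problem sizes

The default test and acceptance runs use peptides of 10–25 residues,
ensembles of n = 500, trajectories of 100–1000 frames and pairwise
kernels on ≤ 60 atoms.  These sizes make every oracle (brute-force pair
scans, quadrature, Monte-Carlo resampling) cheap to evaluate exactly;
the algorithms themselves are O(n²) in atoms per frame and scale to
small-protein systems, but no effort was spent on neighbour lists or
other large-system machinery.

## Known limitations

* No entropy term: scores are binding *enthalpies*; for partners with
  large disorder the omitted −TΔS can be substantial, so score
  differences between constructs are more meaningful than absolute
  values.
* Cβ-stub models reduce salt bridges and tunnel contacts to Cβ–Cβ
  surrogates (flagged as such in the results).
* The two-snapshot separation map is sensitive to the particular first
  and last frames; a windowed variant would average frame blocks, and
  the per-frame distance series should be consulted alongside it.
* The LCPO implementation with the toy coefficients (P3 = P4 = 0)
  overestimates burial for triple overlaps; supplying published
  per-atom-type LCPO parameter rows in the parameter table recovers the
  full scheme.
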