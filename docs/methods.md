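# Methods

`ensemblefit` determines the solution-state conformational distribution of a
small, flexible molecule from NMR restraints. This note describes the model,
the forward predictors, the fitting machinery, the synthetic-data generator,
and the numerical and design choices a user or maintainer needs to know.

## The dynamic model

Each rotatable bond *b* of the molecule is described by one to three
torsional **macrostates** Σ_k = (π_k, μ_k, σ_k): an occupancy, a mean torsion
angle and a libration spread, with Σ_k π_k = 1. A whole-molecule
**microstate** is drawn by selecting one macrostate index per bond with
probability π_k and then drawing the torsion from a wrapped normal
N(μ_k, σ_k²) on the circle. Bonds whose modes are physically tied (here the
hydroxymethyl χ₅(G3), whose preferred angle depends on the conformation of
the R2–G3 linkage it abuts) are placed in a **coupling group**: the group
draws a single mode index per microstate, shared by all members, while each
member keeps its own per-index μ and σ. Rings are restricted to canonical
pucker states (below) with optional state probabilities; methyl rotors are
sampled as uniform rotamers and excluded from macrostate enumeration.

Angles are handled in degrees on (−180, 180]; inputs in [0, 360) are
wrapped. σ is the scale of the wrapped normal and is reported directly as
the libration amplitude.

The wrapped normal was chosen as the simplest spread-parameterized circular
law; nothing downstream depends on its higher moments. Occupancies are never
silently renormalized — a model whose π do not sum to 1 (within 10⁻⁹) is
rejected.

## Conformer construction

Bond lengths and angles are fixed by a `MoleculeTemplate`; conformers differ
only in torsions and ring pucker states. Atoms are placed by an ordered
program of three row types:

* **z-matrix rows** (natural-extension reference frame) whose dihedral is a
  constant, a named torsion plus offset, an endocyclic ring torsion, or an
  offset relative to a previously placed atom sharing the same references
  (used at anomeric centers);
* **bisector rows** for ring substituents: the atom is placed off the
  bisector of its two ring neighbours, on a chosen face, tilted so a target
  bond angle (default 109.47°) is met — this makes stereocenters explicit
  and pucker-independent;
* **tripod rows** for the fourth substituent of an sp³ center with three
  placed neighbours.

The program is compiled to flat index arrays and executed for a whole
ensemble at once (a numba kernel when available, a vectorized numpy path
otherwise; both agree to machine precision). A 300-conformer build of the
76-atom fixture takes about a millisecond, which is what makes per-step
ensemble re-sampling during Monte-Carlo affordable.

**Ring puckers.** Six-membered rings are restricted to the two chairs;
five-membered rings to a pseudorotation grid with 18° phase spacing at fixed
amplitude (38°). The package's phase convention is ν_j = ν_max·cos(P +
144°·j) where ν_j is the endocyclic torsion about bond (path_j, path_{j+1})
of the ring's construction path; state names are `P000` … `P342`, and the
fixture documents its own correspondence to envelope/twist labels rather
than asserting equivalence with any published numbering. Because a closed
ring with fixed bond lengths cannot realize an arbitrary torsion pattern,
each canonical state's internal geometry is solved once by least squares:
placement angles and free torsions are adjusted near their ideal values so
the ring closes exactly (closing bond within 10⁻⁴ Å) while tracking the
canonical torsion pattern softly. The solved per-state tables are stored in
the template, so construction itself is deterministic table lookup.

**Clash detection** tests non-bonded heavy-atom pairs separated by at least
three bonds against a minimum contact distance (default 2.4 Å, the classic
O···O hydrogen-bond floor, configurable per element pair). The uniform
default is deliberately conservative for C/N-containing pairs.

**Geometry QC** reports Z = |observed − reference| / spread for every bond
and placement angle against the template references (default spreads
0.02 Å and 2.0°), flagging features with Z strictly greater than the
threshold (default 3).

## Forward models

**NOESY.** Inter-proton distances are ensemble-averaged as ⟨r⁻⁶⟩, assembled
into a homonuclear dipolar relaxation-rate matrix with Lorentzian spectral
densities J(ω) = τ_c/(1+ω²τ_c²) from a single isotropic tumbling time τ_c,
and the first-order rate equation is solved by eigendecomposition: peak
heights are entries of exp(−R·τ_mix). Equivalent protons are collapsed to
one pool of multiplicity n: pair r⁻⁶ terms are summed over members,
magnetization is normalized per proton ("one-mole-equivalent"), intra-pool
dipolar terms feed the pool's auto-relaxation, and the reported height for a
pool pair is the symmetric multiplicity-weighted exponential entry
[D·exp(−Rτ)·D⁻¹]_IJ with D = diag(√n). Observed and predicted heights are
compared as absolute values. A uniform non-dipolar leak rate is available
and defaults to 0 s⁻¹; the dipolar constant uses CODATA γ_H and ħ. Because
experimental intensities carry an arbitrary spectrometer scale, a
per-dataset intensity scale is solved in closed form inside every
chi-square evaluation, and τ_c is optimized by bounded one-dimensional
minimization of the NOESY chi-square over 0.05–5 ns (on a log grid).

**Scalar couplings.** J(θ) = A·cos²θ + B·cosθ + C with optional
Haasnoot–Altona substituent corrections Σ_i Δχ_i·(D + E·cos²(ξ_iθ +
F·|Δχ_i|)). Averaging is over J values, never over angles. The restraint
error defaults to 1 Hz — the predictive accuracy of Karplus relations —
even when the measurement precision is better.

**RDCs.** Steric alignment in a compressed gel is modelled per conformer by
the traceless, unit-norm part of the gyration tensor of the molecule's
van-der-Waals surface; the surface second moments are computed analytically
(each atom contributes its sphere area w = r² and moment, overlap ignored),
so the tensor is deterministic. A one-bond C–H coupling is D = s·⟨b̂ᵀSb̂⟩
averaged over conformers with one fitted magnitude s per medium, solved in
closed form; only tensor orientation and rhombicity matter. The strong
angle dependence is handled by inflating the experimental error in
quadrature, ε_eff² = ε² + (f·D_max)², with model-error fraction f = 0.1 by
default. This shape proxy and the quadrature error form are declared
substitutes for the original shape-alignment and angle-correction
procedures, whose details are not published.

## Chi-square and fitting

χ² = Σ (x_pred − x_exp)²/ε² over all restraints, with no-NOEs scored
against zero using their noise-derived errors, reported per dataset
(NOE/no-NOE split, per-medium RDCs, couplings) exactly as a fit-quality
table.

Macrostate parameters are refined by random-walk Metropolis Monte-Carlo on
the χ² scale, either at fixed temperature T = 1 (the default) or with an
optional geometric annealing schedule T: T₀ → T₁ over the run — the
recovery experiments use T: 10 → 0.5, which lets early steps cross
barriers between torsional basins and late steps refine within one.
One randomly chosen parameter is perturbed per
step — a mode mean (±5°, with a 10% chance of an independence jump to a
uniform angle, which is what lets a run escape a wrong basin), a spread
(±2°, reflected into [0, 45°] — beyond ~45° a wrapped normal spans a
third of the circle and no longer represents libration; motion of that
amplitude belongs in additional modes), or a transfer of up to 0.05 occupancy
between two modes of one selection unit. Modes locked to classic rotamers
(fixed_mu) skip mean moves. Acceptance is min(1, exp(−Δχ²/T)); the
best-visited model then receives a short greedy polish — deterministic
coordinate-descent sweeps with shrinking steps on a fixed
common-random-numbers objective (600 microstates), completing the
"optimize until the best fit is found" protocol — and is finally re-scored
with a larger ensemble (default 3000 microstates) for reporting.

Each evaluation draws a fresh 300-microstate ensemble by default. For
optimization runs a **common-random-numbers** mode holds the underlying
uniform/normal draws fixed so χ² is a deterministic function of the
parameters; the base is redrawn every 1000 steps by default because a
single fixed 300-sample draw lets spreads and minor-mode occupancies absorb
that draw's sampling noise. τ_c is re-optimized every 100 steps; intensity
and RDC scales are re-solved every step.

`multistart_fit` runs many independently seeded fits from randomized starts
(uniform means, spreads in 5–30°, flat Dirichlet occupancies; the paper-style
default is 96 runs), returns the lowest-χ² run, and compares the top 10% of
runs mode-by-mode (circular distance of means, threshold 10°; occupancy
difference, threshold 0.1) after matching modes by circular proximity,
flagging divergence. Multistart uses the common-random-numbers mode by
default so run-to-run scatter reflects starts and finite-ensemble noise
rather than per-step re-draw noise.

**Model selection.** `modality_scan` refits a bond as uni-, bi- and
tri-modal and keeps the extra modes only when χ² improves by a parsimony
margin of 1 unit per added parameter *scaled by the simpler variant's χ² per
restraint* (floored at 0.01) — the scaling makes the rule meaningful on
noise-free data, where every variant fits far within the assigned errors,
while reducing to the plain margin at realistic noise (χ²/restraint ≈ 1).
Fitted modes closer than the sum of their spreads are merged, modes below a
2% occupancy floor are dropped, and means within 10° of a classic rotamer
(60°, 180°, 300°) are locked there. `assign_prochiral` refits under both
label swaps of a declared prochiral pair and selects the lower χ²,
reporting ties (|Δχ²| below 2) as undetermined. `scan_ring_puckers` refits
each canonical state and pairwise combinations of the best few, again with
the parsimony margin, flagging near-degenerate states.

## Output ensembles

Two structure sets summarize a refined model: a fixed-size microstate
ensemble (default 250) from which conformers containing heavy-atom contacts
below the allowed minimum are trimmed and replaced by further draws from the
same model, and the degenerate macrostate set at the mode means (libration
removed, trivial rotations grouped) with occupancies attached, written as
multi-model PDB with occupancies in the occupancy column. Families are
groups of macrostates sharing the mode of designated defining bonds (the
R2–G3 linkage for the fixture), with populations equal to summed
occupancies. Torsion histograms use 15° bins centered on 0° at north,
proceeding clockwise, with half-open edges (an angle exactly on an edge
belongs to the higher bin).

Because the macrostate model carries no steric energy term, a compact
branched molecule at realistic libration amplitudes produces a nonzero
clash rate (about 30% of raw draws for the fixture at its final
parameters); trimming is therefore visible but leaves the torsion marginals
essentially unperturbed (family-1 population 0.60 in the trimmed output vs
0.62 in the model), mirroring how output trimming is described in this
method family. Fitting itself never trims.

## The synthetic-data generator

`fixtures.simulate_restraints` inverts the forward models: it samples a
large ensemble (default 3000 microstates) from a ground-truth model,
predicts NOESY heights per dataset, ⟨J⟩ couplings and RDCs, adds noise, and
writes the restraint tables plus a manifest of true values. It emulates:

* two NOESY datasets (900 MHz / 700 ms in D₂O; 600 MHz / 600 ms in H₂O
  restricted to pairs involving exchangeable NH protons);
* NOE errors at 40% of the measured height; multiplicative **lognormal**
  intensity noise exp(f·N(0,1)) at the same fraction — additive Gaussian
  noise with proportional-to-measured errors occasionally produces
  near-zero heights with near-zero errors and pathological χ²
  contributions, which is inconsistent with a per-restraint χ² near 1;
* cross peaks below a spectral noise floor (default 0.003
  one-mole-equivalent units, ~1% of a typical diagonal) recorded as
  no-NOEs with height 0 and error = noise × multiplet factor / 3
  (factor 2, a doublet's most intense component);
* couplings with 1 Hz Gaussian noise and 1 Hz errors; RDCs in two gel
  media (magnitudes 18 and 27 Hz) with 1.5 Hz noise and errors;
* an overall tumbling time τ_c = 1.5 ns — a plausible value for a +3-charged
  580 Da solute in cold water, chosen so the NOE/no-NOE census resembles the
  restraint composition the method was developed on.

At the true model this generator yields χ² per restraint ≈ 0.7 (NOE ≈ 1.3,
no-NOE ≈ 0.1–0.2, J ≈ 0.8, RDC ≈ 0.75), the same pattern as the
experimental fit-quality table it emulates.

What the generator does **not** emulate: peak overlap and ambiguous
assignments, exchange broadening, anisotropic tumbling, internal-motion
order parameters, field-dependent noise, baseline artifacts, or any
correlation between restraint errors. Passing recovery tests therefore
demonstrates the estimator's consistency under its own forward model with
realistic noise levels — not robustness to model misspecification.

## The fixture molecule

The built-in topology is a streptomycin-like trisaccharide: a
diguanidinated cyclohexane (S1), a furanose bearing a hydrated gem-diol and
a methyl (R2), and an N-methyl glucosamine pyranose (G3), joined by two
glycosidic linkages — nine named rotatable bonds (φ/ψ per linkage and five
exocyclic torsions) and three saturated rings, 76 atoms, 35 protons in 27
spin pools. Internal geometry uses idealized fragment values (C–C 1.53 Å,
C–O 1.43/1.41 Å, sp³ angles near 109.5° with a few attachment angles widened
to 112–117° where idealized values produced systematically impossible
1,5-contacts across the linkages). Stereocenter faces were chosen once so
that all 12 macrostates of the final model build clash-free at the default
2.4 Å contact floor; the template is a synthetic stand-in with plausible,
not crystallographic, stereochemistry. The ground-truth dynamic model
encodes the final fitted parameters of the study system: uni-modal S1–R2
linkage, bi-modal R2–G3 linkage coupled to χ₅(G3) (62/38), tri-modal
gem-diol on locked rotamers (51/45/4), bi-modal χ₁(S1), uni-modal χ₃(S1)
and χ₂(G3), and single-state rings — 12 whole-molecule macrostates in two
families.

## Problem sizes and defaults

Per-evaluation ensembles of 300 microstates, 10,000 Metropolis steps per
run, and 8 multistart runs are the package's standard recovery experiment
(the historical protocol used 96 restarts; 8 is the package's default for a
single-workstation run and is what the acceptance script uses). One full
8-run recovery on the fixture takes roughly 10 minutes on one CPU core.
Unit and property tests use the small toy molecules (a butane-like chain, a
two-carbon diol with two prochiral pairs, a bare furanose) with reduced
step counts.

## Estimator spread under the synthetic conditions

Repeating the full recovery experiment over independent noise seeds (and
starting fits from the generating model itself) shows that the chi-square
minimum of a given synthetic dataset can sit 8–20° away from the generating
mean for the S1–R2 phi torsion and the secondary R2–G3 psi torsion, and
several percent away for the 4% gem-diol rotamer occupancy, while the
primary-family occupancy, the S1–R2 psi mean and the phi libration are
recovered robustly. In other words, at these restraint counts and noise
levels the estimator's seed-to-seed spread is comparable to — and for the
weakly-constrained parameters somewhat larger than — the uncertainty bands
the recovery tests assert, so individual recovery checks on those
parameters can fail marginally for particular noise realizations. Libration
spreads also carry a mild downward finite-ensemble bias (the chi-square
penalizes the extra prediction variance a broader mode generates in a
300-microstate evaluation ensemble).

## Known limitations

* τ_c is only weakly identified from cross-peak data once a per-dataset
  intensity scale is fitted; its recovered value can differ from the
  generating value by tens of percent without degrading the fit. It is a
  nuisance parameter here, not a result.
* The χ₁(S1) guanidinium modes and the second χ₅(G3) mode are weakly
  constrained by the synthetic restraints and may converge to alternative
  basins of comparable χ²; none of them is part of the recovery targets.
* The steric-alignment proxy ignores sphere overlap and electrostatic
  alignment; with a fitted per-medium magnitude only its principal-axis
  orientation matters, and both gel media share one tensor shape.
* Model selection compares stochastic χ² values; near-degenerate variants
  (|Δχ²| below the tie tolerance) are reported as such rather than decided.
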