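# Methods

## Dihedral extraction

Backbone torsions follow the standard Ramachandran definitions: φ(i) is the
torsion C(i−1)–N(i)–Cα(i)–C(i), ψ(i) is N(i)–Cα(i)–C(i)–N(i+1), computed with
the atan2 formulation and the right-handed sign convention used by VMD and
MDAnalysis (verified against `MDAnalysis.lib.distances.calc_dihedrals` in the
tests). Angles live on the half-open interval **[−180°, 180°)**, with +180°
wrapped to −180°, so that every 2° bin has exactly one owner — without this
the φ = 180° frame would be ambiguous between bins 0 and 179.

Conventions for irregular input:

- φ of the first residue of a chain and ψ of the last are undefined (NaN);
  such residues are excluded from scoring and reported as undefined.
  Torsions never span chains.
- A residue missing a backbone atom loses exactly the torsions that need
  that atom (with a logged warning); its neighbours keep any torsion whose
  four atoms exist. An atom-count mismatch between topology and trajectory
  is a hard error.
- With altloc duplicates the first atom is taken and logged; insertion
  codes are preserved in the residue identity.
- MDAnalysis stores coordinates as float32, so angles extracted through a
  Universe are reproducible to ~10⁻⁴ degrees; the float64 geometry path
  (used by the synthetic peptide builder round trip) is good to 10⁻⁶
  degrees. Both tolerances are asserted in the tests. PDB files carry three
  coordinate decimals, adding a few hundredths of a degree on top.

The CSV dihedral dialect (`frame,chain,residue[,resname],phi,psi`, empty cell
= undefined, out-of-range angles wrapped by ±360°) decouples the scoring core
from trajectory tooling entirely.

## Scoring

Each defined residue's (φ, ψ) frames are binned into a 180 × 180 matrix
(bin index `floor((angle + 180) / 2)`), **frequency-normalized** by the frame
count. Normalization is a deliberate choice: with equal-length replicates the
per-group max normalization cancels any constant factor, so rankings and
scores are identical to count-based scoring, while unequal-length inputs
(e.g. a pooled apo reference) remain well-defined. A count mode is kept as an
option for bit-compatibility studies.

The raw difference Σ|B_L − B_A| equals twice the total-variation distance
between the binned distributions, hence ∈ [0, 2]. Scores are raw differences
divided by the **maximum within the same comparison group** — one
(ligand state, replicate) pairing — following the principle that the dataset
maximum defines the unit; normalized scores are then averaged across
replicates, and per-ligand means are aggregated across ligand states (mean by
default, min exposed as a robustness criterion for candidates that must work
for every ligand). If every raw difference in a group is zero the states are
indistinguishable; all scores are 0 and a warning is raised rather than
dividing by zero.

Replicate pairing is explicit and configurable because nothing forces one
policy: `indexed` (default; bound replicate *i* vs apo replicate *i*, equal
counts required), `pooled-apo` (all apo frames merged into one reference
histogram), and `all-pairs`. Ties at the maximum all receive a score of 1;
ranking ties break by ascending residue number for determinism. Binding-site
residues are scored but only excluded at ranking time, so structure
projections can still color the whole backbone; the B-factor projection
writes mean score × 100 rounded to the PDB column's two decimals.

## The synthetic microstate generator

The generator emulates the statistical structure the scorer consumes — not
the physics that produces it. Each residue is a mixture of discrete
conformational **microstates**, each a wrapped-normal blob on the (φ, ψ)
torus; apo and bound states share the blobs and differ only in occupancy.
The canonical "shifted" residue starts fully in one mode and moves a fraction
δ ∈ [0, 1] of its population to a second mode on binding: δ = 0 is an
unresponsive residue, δ = 1 a complete microstate shift.

Defaults, chosen once as the study conditions:

- **Modes 120° apart** in both angles (an α-helix-like and a left-handed
  basin): far beyond any spread used, so the disjoint-support law holds.
- **Spread 5°** (wrapped-normal sd): the scale of thermal fluctuation within
  a tight backbone basin, small against both the mode separation and the
  360° torus. Sampling is a plain normal draw then wrap, adequate for
  spreads ≪ 360° (the documented limitation of that shortcut).
- **10⁴ frames, 3 apo + 3 bound replicates, 50 residues** for the end-to-end
  system, mirroring a triplicate apo/bound simulation design.

For disjoint modes the expected raw difference is exactly 2δ. The binned
estimator has a positive finite-sample bias (it sums |p̂ − q̂| over ~hundreds
of occupied cells whose counting noise never cancels): a design-time analysis
of that bias as a function of spread showed <3% relative error at δ = 0.3
with the 5° spread and 10⁴ frames (≈0.14 absolute at δ = 0, decaying as
1/√frames), which is why 5° — and not a broader, more diffuse basin — is the
default. Acceptance checks assert the 2δ law within 5% at δ ∈ {0.3, 0.6, 1.0}
under exactly these conditions.

Microstate paths are i.i.d. by default; an optional Markov dwell parameter
adds persistence with the same stationary occupancy (histograms are
dwell-invariant in expectation, so scoring defaults to the simpler process
and dwell exists to exercise subsampling stability). Every generator is
bit-reproducible given (seed, state, replicate), implemented via a
`SeedSequence` keyed on that tuple per residue.

What passing these tests does **not** show about real data: no force field,
no solvent, no correlated inter-residue motion, no equilibration transient,
and microstates are isotropic Gaussians rather than anharmonic basins. The
generator validates the estimator, not molecular dynamics.

The peptide builder places N/Cα/C backbones by the NeRF construction with
idealized bond lengths and angles (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å;
trans ω); it enforces geometry only, not sterics.

## Kinetics

Time courses are fit to F(t) = F_∞ + Σᵢ Aᵢ·exp(−k_app,i·t) (one or two
phases) by trust-region nonlinear least squares in log-rate space (enforcing
k > 0), from multiple starts: candidate rates log-spaced across the observed
time window with small seeded log-normal jitter, amplitudes and F_∞ solved
linearly per candidate (variable projection) before joint refinement; the
lowest-RSS refinement wins, so fits are deterministic given the seed.
Standard errors come from the local Gauss–Newton covariance with the delta
method for the log-rate transform. Phases are reported fast-first. A
constant signal returns a flagged `unidentifiable-rate` result, not an
exception; dead-time handling truncates early points and never extrapolates.

**Model selection** ("best fit" between one and two phases) uses the
extra-sum-of-squares F-test at α = 0.01 (AICc available as an alternative),
gated by three identifiability guards, with the full decision trail recorded:

1. both two-phase amplitudes must exceed 3× the residual sd of the richer
   model;
2. the two rates must be distinct (ratio > 1.05);
3. the fast phase must still be decaying at the first sampled time
   (k_app1 · t_first ≤ 3) — otherwise its amplitude/rate pair is pure
   extrapolation before the data begin.

When the one-phase residuals are already at numerical precision, parsimony
wins without a test (the F statistic is 0/0 there). Simulation tests confirm
the selector is nested-consistent: on monophasic data with 1% noise the
two-phase model is chosen at a rate bounded by α plus binomial slack, and 3σ
coverage of the reported standard errors exceeds 95% over 200 seeded
replicates.

Binding curves: amplitudes vs concentration are fit with the hyperbolic
isotherm Y = B_max·c/(K_D + c) (magnitudes used, since these biosensors
signal by fluorescence *decrease*); the returned fit satisfies the
half-saturation identity Y(K_D) = B_max/2 exactly. A K_D landing outside
half the concentration range, or with a standard error exceeding itself, is
flagged ill-conditioned rather than failing silently. Apparent rates vs
concentration are fit linearly; the slope is k_on (µM⁻¹·s⁻¹) and the
intercept is fitted freely by default (a through-origin option exists)
and reported without interpretation.

**Responsiveness classification**: a variant is a working biosensor iff
|Δ%| ≥ threshold for every target ligand and |Δ%| < threshold for every
control ligand; the default threshold is 5%, explicit and configurable, and
panel values are treated as exact (single-measurement panels carry no error
model). Success rate is the responsive fraction in percent.

## Photometry

Beer–Lambert with a dye bleed-through correction at 280 nm:
[protein] = (A280 − 0.164·A430)/(ε₂₈₀·L), [dye] = A430/(ε₄₃₀·L), efficiency
= [dye]/[protein]·100%. The grouping (corrected absorbance over ε·L) is the
only dimensionally consistent reading. Shipped defaults are the published
constants for the TogB scaffold (ε₂₈₀ = 90 300 M⁻¹cm⁻¹) and the MDCC dye
(ε₄₃₀ = 46 800 M⁻¹cm⁻¹, correction 0.164); generic constants are accepted.
Efficiency is homogeneous of degree 0 in the absorbances and invariant to
pathlength; values above 100% are returned but physically suspect. A negative
corrected A280 is a hard error (inconsistent readings).

## Problem sizes

The test suite and acceptance script run the full 50-residue, 3+3-replicate,
10⁴-frame scoring experiment (the largest configuration exercised) in seconds
on one core; kinetic calibration uses 200 seeded noisy replicates. These
sizes were chosen so the statistical assertions (2δ law within 5%, ≥95%
coverage, false-positive rate ≤ α + slack) have comfortable margins.

## Known limitations

- The scorer reports *that* a residue's dihedral distribution differs
  between states, not how long it dwells in each sub-state; residence times
  are out of scope by design.
- Side-chain (χ) dihedrals are not considered — backbone only.
- No global multi-curve fitting across concentrations, and no mechanistic
  enzyme turnover model beyond the empirical two-exponential description.
- Wrapped-normal sampling via draw-then-wrap under-disperses for spreads
  approaching the torus scale; defaults stay far from that regime.
- The selection aggregate across ligand states (mean vs min) is a genuine
  open choice; both are exposed, mean is the default.
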