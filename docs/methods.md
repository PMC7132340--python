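# Methods

`shiftdock` implements the quantitative inference chain used to establish
and characterize a chemokine–galectin heterodimer from solution data:
chemical-shift-perturbation (CSP) mapping of a binding interface from
¹H–¹⁵N HSQC peak lists, 1:1 single-site SPR affinity fitting, conversion
of CSP categories into ambiguous interface restraints, rigid-body docking
with energy ranking, per-residue energy decomposition, and in-silico
mutational scanning. Every stage is exercisable on synthetic data with
planted ground truth.

## CSP mapping

For each residue with an assigned backbone amide in both the apo and
bound spectra, the combined shift perturbation is

    quadrature (default):  Δδ = √((Δ¹H)² + (w_N·Δ¹⁵N)²)
    abs_sum:               Δδ = |Δ¹H| + w_N·|Δ¹⁵N|

in ¹H ppm, with nitrogen weight w_N = 0.25 (configurable). Both rules are
provided because the literature frequently typesets the combination
ambiguously; the field-standard quadrature form is the default and the
rule used is recorded in every output. Intensity loss is
ΔIntensity = 1 − Int_i/Int_0, undefined (flagged) when Int_0 = 0.

Residues are classified against the mean m and sample standard deviation
s (n−1 denominator, chosen because profiles are small) of Δδ over all
matched residues: `orange` for [m, m+s), `red` for [m+s, m+2s), and
`above_2sd` for ≥ m+2s, with half-open intervals. Residues beyond m+2s
get their own category and count as interface residues in restraint
generation. Prolines and unmatched residues never enter the statistics —
an HSQC cannot observe them. Matching is label-based only; a
nearest-neighbour chemical-shift fallback was deliberately rejected
because silent mis-assignment is worse than an explicit unmatched flag.
Degenerate rule: when s = 0, residues tied exactly at a nonzero mean are
orange and everything else is below_mean; an all-zero profile reports no
perturbation at all.

Sequence-averaged Δδ values order binding-site variants: a larger mean
perturbation at fixed conditions indicates a stronger intermolecular
interaction. `summarize_mean_csp` refuses to compare profiles computed
under different combine rules or nitrogen weights.

## SPR fitting

The binding model is the ideal 1:1 Langmuir interaction. For analyte
concentration C,

    association:   R(t) = R_eq·(1 − e^{−(k_a·C + k_d)·t}),
                   R_eq = k_a·C·R_max/(k_a·C + k_d)
    dissociation:  R(t) = R(t_assoc)·e^{−k_d·(t − t_assoc)}

and the steady-state isotherm is R_eq(C) = R_max·C/(K_D + C) with
K_D = k_d/k_a. The kinetic fit is global — one (k_a, k_d, R_max) shared
across the concentration series — because a single curve cannot jointly
identify k_a and R_max; a single-concentration request is refused.
No mass-transport, bulk-refractive-index or drift terms are modelled.

Numerics: parameters are optimized in log space (positivity and scale
equilibration) with `scipy.optimize.least_squares` at tolerances 1e-14.
Initialization is data-driven and deterministic: k_d from the log-linear
dissociation tail of the highest concentration, per-curve k_obs from the
log-linear approach to an estimated plateau, k_a from the slope of k_obs
vs C, R_max by rescaling the largest plateau through the isotherm.
Standard errors come from the Jacobian covariance at the optimum, mapped
back by the delta method; the K_D error uses the full covariance of
log k_d − log k_a. Non-convergence raises with solver diagnostics rather
than returning defaults. Steady-state extraction averages the last
`window` seconds of association and flags curves whose projected change
over the window, |slope|·window, exceeds 1 % of the plateau estimate.

## Surrogate interaction energy

Atomistic force-field energetics are out of scope; the docking stage uses
a deliberately coarse residue-level surrogate, clearly labelled in every
output, whose purpose is to preserve the *inferential structure* —
ranking poses, decomposing energy by residue, scanning mutations — with a
verifiable stand-in. Scores are on a kcal/mol-like scale but are not
molecular-mechanics binding free energies, and no calibration to MM/GBSA
values is attempted.

Each residue carries a backbone centroid (CA), a side-chain centroid,
an integer formal charge (K/R +1, D/E −1, H configurable via
`his_charge`, default 0) and a hydrophobicity class
(hydrophobic = {A,C,F,I,L,M,P,V,W}; charged; polar otherwise). For an
inter-chain residue pair at side-chain centroid distance r:

* **Screened Coulomb** w_e·q_i·q_j·e^{−r/λ_D}/r with λ_D = 10 Å, cut off
  at r_cut = 2·d_c = 16 Å, and w_e = 5·e^{1/2} calibrated so a +1/−1
  pair at 5 Å contributes exactly −1.0 score units. The term is
  evaluated at max(r, r_min) — a soft core. Without it the 1/r
  attraction is unbounded as r → 0 and rigid-body minimization collapses
  the chains into the singularity; capping at the clash onset leaves the
  calibration point and all cutoff behaviour unchanged. The cutoff at
  2·d_c makes "no pair within twice the contact cutoff" imply a ΔΔG of
  exactly zero in mutation scans.
* **Contact well** −w_c (w_c = 0.2) for hydrophobic–hydrophobic,
  polar–polar and opposite-charge pairs with r in [4.5, 8] Å
  ("polar-complementary" is implemented as these last two classes).
* **Clash** w_x·(r_min − r_bb)² (w_x = 10, r_min = 3.5 Å) on the
  *backbone* centroid distance r_bb — interface chemistry is side-chain
  dominated, so side-chain centroids handle attraction and backbones
  handle excluded volume.
* **Restraint penalty** w_r·(fraction of restraints violated)²
  (w_r = 5), a pose-level term reported separately from the pairwise
  decomposition.

The per-residue decomposition assigns half of each pairwise term to each
partner, so contributions over both chains sum exactly to the pairwise
total. A naive all-pairs double loop serves as the test oracle for the
vectorized implementation (agreement to 1e-9), and every term is
invariant under a global rigid transform of the whole system.

## Restraints, pose search, minimization

CSP categories at or above a chosen threshold (default `red`) become
ambiguous interface restraints, HADDOCK-style: an implicated residue must
have ≥1 partner side-chain centroid within d_c = 8 Å, with the partner
unspecified (CSPs identify residues, not pairings). Candidate poses aim
the ligand active-patch centroid at the receptor active-patch centroid
along a random approach axis from the hemisphere around the receptor
patch normal, spin the ligand about the axis by angles stratified over
[0, 2π), and slide to first heavy contact (minimum inter-centroid
distance 4 Å, located by bisection). A pose must satisfy ≥50 % of the
restraints or its axis is resampled, up to 100 attempts; the 50 % rule is
this package's explicit quantification of "consistent with the HSQC
data". Default pose count: 10.

Local minimization is coordinate descent over the six rigid-body degrees
of freedom (rotations about the posed ligand centroid along lab axes,
lab-axis translations), starting at 5°/1 Å, halving steps after any
sweep without improvement, terminating below 0.1°/0.02 Å or after 500
sweeps. Acceptance is greedy, so the score trace is monotone
non-increasing. Ranking is ascending by total score with ties broken by
lower pose index, making reported rankings fully deterministic.

Mutation scans replace only a residue's type-derived parameters (charge,
class); the side-chain centroid is retained — a rigid approximation. The
geometric restraint penalty is unchanged by mutation, so ΔΔG reflects
pairwise terms only.

## Synthetic data and what it does (not) show

The generator plants ground truth so every inference step can be tested
against a known answer:

* **Structures.** Chains are self-avoiding persistent random walks
  (3.8 Å virtual bonds, ≥3.5 Å separation) of two-centroid residues. A
  surface patch on the receptor carries K/R (+1) and the complementary
  ligand patch D/E (−1), emulating a cationic chemokine face against an
  acidic lectin F-face; patch side chains share a common outward normal
  so the interface is a contactable face. The planted pose is built by
  aiming the patches, settling contacts by coordinate descent on a hinge
  objective (all interface residues within 7.2 Å, overlap floor 3.6 Å),
  relaxing into a local minimum of the surrogate energy under full
  restraints, and deterministically re-minimizing from ±3°/±1 Å
  perturbations so the planted basin is locally dominant. The truth
  object guarantees every interface residue a partner side-chain
  centroid within 8 Å.
* **Peak lists.** Apo amide positions are uniform over the amide region
  (¹H 6.5–10.5, ¹⁵N 105–135 ppm). All bound peaks get independent
  Gaussian noise (SD `noise_ppm` in ¹H and 4× that in ¹⁵N, reflecting
  typical relative digital resolution — this exercises the 0.25 weight
  nontrivially); interface residues additionally move by a fixed
  combined magnitude in a random direction of the weighted shift plane
  and lose 10–70 % intensity. The intensity attenuation is a crude
  stand-in for intermediate-exchange line broadening; lineshapes,
  spectral overlap and exchange regimes are not modelled, so passing
  tests say nothing about peak-picking or assignment robustness on real
  spectra.
* **Sensorgrams.** Closed-form 1:1 curves at 10 Hz with additive i.i.d.
  Gaussian noise. Default acquisition is 60 s association (a 1-min
  injection) and 300 s dissociation, long enough to determine off-rates
  near 1e-3 s⁻¹; mass-transport limitation, drift and bulk jumps are not
  simulated, so recovery results bound only the regression error, not
  instrument artifacts.

Study conditions used by the tests and the acceptance script: kinetic
recovery at (k_a = 1e5 M⁻¹s⁻¹, R_max = 100 RU) over concentrations
{10, 30, 100, 300} nM with K_D ∈ {8, 34, 80} nM and 2 RU noise;
interface recovery on a 40-residue chain with 14 planted interface
residues at effect/noise = 5 (0.05 ppm effect over 0.01 ppm noise). The
14/40 interface fraction matters: the orange threshold sits at the
profile *mean*, and noise-only Δδ is Rayleigh-distributed with mean
≈1.25σ, so a sparse interface would drag the mean into the noise bulk
and flood the orange set with false positives. A fraction near one third
matches the breadth of perturbation seen in real chemokine CSP maps,
where two contact sites span much of a ~70-residue sequence. Docking
tests use 40/30-residue chains with 5+5-residue patches.

## Known limitations

* The surrogate energy has no solvation, entropy, or flexibility; its
  numbers are not comparable across systems with different sizes.
* Rigid-body minimization is a local greedy search; it is deterministic
  but can stop at the nearest shallow minimum for poses far from any
  interface.
* Peak matching requires consistent assignment labels between apo and
  bound lists; it will not rescue renumbered or re-referenced spectra.
* Histidine is neutral by default; at acidic experimental pH (~4.5) a
  protonated histidine may be more appropriate (`his_charge=1`).
* The steady-state plateau extractor assumes the final window of the
  association phase approaches equilibrium; it flags, but does not
  extrapolate, non-equilibrated curves.
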