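# shiftdock

Solution-data inference for protein heterodimers: map a binding interface
from NMR chemical-shift perturbations, measure the affinity from SPR
sensorgrams, and build a docked model from the NMR restraints — with
per-residue energy decomposition and in-silico mutational scanning on
top. The package was built around the workflow used to characterize
chemokine–galectin heterodimers (e.g. CXCL12 binding the galectin-3
carbohydrate-recognition domain through its sugar-free F-face), but every
stage is generic and fully testable on synthetic data with planted
ground truth.

## What it computes

**CSP mapping.** From apo/bound ¹H–¹⁵N HSQC peak lists (Sparky-style
text), the per-residue combined shift perturbation

> Δδ = √((Δ¹H)² + (0.25·Δ¹⁵N)²)  (¹H ppm; a sum-of-absolute-values
> variant is available as `combine="abs_sum"`)

and intensity loss ΔIntensity = 1 − Int_i/Int_0. Residues are classified
against the profile mean m and sample SD s: **orange** [m, m+s),
**red** [m+s, m+2s), **above_2sd** beyond — the coloring scheme of
interface maps — and sequence-averaged Δδ orders binding-site variants
by interaction strength.

**SPR fitting.** Global 1:1 Langmuir kinetics across a concentration
series — association R(t) = R_eq(1 − e^{−(k_aC+k_d)t}) with
R_eq = k_aC·R_max/(k_aC+k_d), mono-exponential dissociation — returning
k_a, k_d, R_max and K_D = k_d/k_a with standard errors; plus
steady-state isotherm fits R_eq(C) = R_max·C/(K_D + C).

**Restraint-guided docking.** Classified residues become ambiguous
interface restraints (each implicated residue must contact *some*
partner residue within 8 Å). Ten rigid-body orientations (by default)
are generated against the receptor, locally minimized, ranked by a
coarse residue-level surrogate energy (screened Coulomb + contact wells
+ clash + restraint penalty), decomposed per residue, and scanned by
point mutation (ΔΔG). Scores are on a kcal/mol-like scale but are
explicitly **not** molecular-mechanics binding free energies — see
`docs/methods.md`.

## Worked example

```python
from shiftdock import *

# synthetic heterodimer with a planted charge-complementary interface
receptor, ligand, truth = gen_structures(seed=1, n_receptor=40,
                                         n_ligand=30, patch_size=5)

# --- CSP mapping of the receptor face
apo, bound = gen_peaklists(receptor, truth.receptor_interface,
                           effect_ppm=0.05, noise_ppm=0.005, seed=1)
profile = classify_residues(compute_csp(match_peaks(apo, bound)))
print(f"mean Δδ = {profile.mean:.4f} ppm, SD = {profile.sd:.4f} ppm")
print("interface (orange+):", sorted(interface_residues(profile, 'orange')))

# --- 1:1 kinetic fit of a noisy concentration series
curves = gen_sensorgrams(ka=1e5, kd=8e-3, rmax=100.0,
                         concentrations=[1e-8, 3e-8, 1e-7, 3e-7],
                         noise_ru=1.0, seed=1)
fit = fit_kinetic_1to1(curves)
print(f"ka = {fit.ka:.3e}  kd = {fit.kd:.3e}  "
      f"KD = {fit.kd_equilibrium*1e9:.1f} nM")

# --- restraint-guided docking and mutation scan
rs = RestraintSet(truth.receptor_interface, truth.ligand_interface, d_c=8.0)
poses = [minimize_pose(receptor, ligand, p, rs)
         for p in generate_poses(receptor, ligand, rs, n=10, seed=1)]
ranked = rank_complexes([(p, score_pose(receptor, ligand, p, rs))
                         for p in poses])
best_pose, best_rep = ranked[0]
print(f"rank 1: pose {best_pose.index}, total {best_rep.total:.3f}")
```

prints

```
mean Δδ = 0.0121 ppm, SD = 0.0164 ppm
interface (orange+): [5, 29, 36, 37, 38, 39, 40]
ka = 9.952e+04  kd = 8.006e-03  KD = 80.5 nM
rank 1: pose 3, total -25.138
```

The planted interface is residues 36–40: the classifier recovers all
five and picks up two noise residues (5, 29) — with only five perturbed
residues in forty, the mean-based orange threshold sits close to the
noise floor, which is exactly the regime the classification thresholds
are designed around (see the methods note). The kinetic fit recovers the
simulated K_D = 80 nM to within 1 % at this noise level, and the
top-ranked pose satisfies 100 % of the ambiguous restraints, with the
planted salt-bridge residues dominating its per-residue energy
decomposition (`decompose_energy(best_rep)`).

The same pipeline runs from the shell:

```bash
shiftdock run-all --seed 3 --out results/run --mutations "B:1:K"
shiftdock spr-fit --sensorgrams results/run/sensorgrams.csv --out results/spr
```

Inputs can equally be real files: Sparky-style peak lists
(`K27N-H  120.512  8.231  1.03e+06`), sensorgram CSVs
(`conc_M,time_s,response_RU,phase`) and two-chain PDB files (CA as
backbone centroid, side-chain centroid from side-chain heavy atoms).

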