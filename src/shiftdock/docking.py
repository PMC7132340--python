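"""CSP-restraint-guided rigid-body docking with a coarse surrogate energy.

The workflow mirrors data-driven docking of an NMR-mapped heterodimer:
perturbed residues on each partner become ambiguous interface restraints
(an implicated residue must contact *some* residue of the partner, within
d_c = 8 Å between side-chain centroids, HADDOCK-style one-sided ambiguity);
candidate rigid-body orientations of the ligand chain are generated
against the receptor, locally minimized, ranked by energy, decomposed per
residue, and scanned by in-silico point mutation.

The scoring function is an invented coarse residue-level surrogate — a
screened Coulomb term between side-chain centroid charges, a finite
square-well contact attraction, a soft-sphere backbone clash penalty, and
a quadratic restraint-violation penalty. Scores are on a kcal/mol-like
scale but are NOT molecular-mechanics binding free energies and are not
comparable to MM/GBSA values; only the inferential structure (ranking,
decomposition, mutation signs) is meaningful.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .csp import CSPProfile, interface_residues
from .structures import (
    Pose,
    Structure,
    align_rotation,
    random_rotation,
    rotation_about_axis,
)

__all__ = [
    "RestraintSet",
    "EnergyWeights",
    "EnergyReport",
    "MutationScan",
    "PoseGenerationError",
    "build_restraints",
    "restraint_satisfaction",
    "generate_poses",
    "random_poses",
    "score_pose",
    "coordinate_descent",
    "minimize_pose",
    "rank_complexes",
    "decompose_energy",
    "mutate_and_score",
    "interface_rmsd",
    "write_complex_pdb",
]

DEFAULT_CONTACT_CUTOFF = 8.0   # Å, ambiguous-restraint satisfaction distance
DEFAULT_N_POSES = 10           # candidate rigid-body orientations


class PoseGenerationError(RuntimeError):
    """Raised when no restraint-consistent pose is found within the retry cap."""


@dataclass(frozen=True)
class RestraintSet:
    """Ambiguous interface restraints derived from CSP categories.

    Each active receptor residue must have ≥1 ligand side-chain centroid
    within ``d_c``; symmetrically for active ligand residues. The partner
    residue is deliberately unspecified (CSPs identify residues, not
    pairings).
    """

    active_receptor: frozenset[int]
    active_ligand: frozenset[int]
    d_c: float = DEFAULT_CONTACT_CUTOFF

    def __post_init__(self):
        if not self.active_receptor or not self.active_ligand:
            raise ValueError("active restraint sets must be non-empty")
        if self.d_c <= 0:
            raise ValueError("contact cutoff d_c must be positive")

    @property
    def n_restraints(self) -> int:
        return len(self.active_receptor) + len(self.active_ligand)

    def write_tsv(self, path: str | Path) -> None:
        rows = [("A", r, self.d_c) for r in sorted(self.active_receptor)]
        rows += [("B", r, self.d_c) for r in sorted(self.active_ligand)]
        pd.DataFrame(rows, columns=["chain", "resid", "d_c"]).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path,
                 receptor_chain: str = "A", ligand_chain: str = "B") -> "RestraintSet":
        table = pd.read_csv(path, sep="\t")
        rec = frozenset(int(r) for r in table.loc[table["chain"] == receptor_chain, "resid"])
        lig = frozenset(int(r) for r in table.loc[table["chain"] == ligand_chain, "resid"])
        d_c = float(table["d_c"].iloc[0]) if len(table) else DEFAULT_CONTACT_CUTOFF
        return cls(active_receptor=rec, active_ligand=lig, d_c=d_c)


def build_restraints(profile_receptor: CSPProfile, profile_ligand: CSPProfile,
                     min_category: str = "red",
                     d_c: float = DEFAULT_CONTACT_CUTOFF) -> RestraintSet:
    """Turn classified CSP profiles into an ambiguous restraint set.

    ``min_category`` selects residues at or above that threshold
    (orange | red | above_2sd) on each chain.
    """
    rec = interface_residues(profile_receptor, min_category)
    lig = interface_residues(profile_ligand, min_category)
    if not rec or not lig:
        side = "receptor" if not rec else "ligand"
        raise ValueError(
            f"no {side} residues at or above category {min_category!r}; "
            "lower min_category (e.g. orange)"
        )
    return RestraintSet(active_receptor=rec, active_ligand=lig, d_c=d_c)


def _validated_structures(receptor: Structure, ligand: Structure,
                          restraints: RestraintSet) -> None:
    missing_r = [r for r in restraints.active_receptor if r not in receptor.numbers]
    missing_l = [r for r in restraints.active_ligand if r not in ligand.numbers]
    if missing_r or missing_l:
        raise ValueError(
            f"restraint residues absent from structures: "
            f"receptor {sorted(missing_r)}, ligand {sorted(missing_l)}"
        )


def restraint_satisfaction(receptor: Structure, ligand: Structure, pose: Pose,
                           restraints: RestraintSet
                           ) -> tuple[float, dict[tuple[str, int], bool]]:
    """Fraction of ambiguous restraints satisfied in a pose, plus per-restraint flags."""
    _validated_structures(receptor, ligand, restraints)
    lig_sc = pose.apply(ligand.sidechain)
    d = cdist(receptor.sidechain, lig_sc)
    flags: dict[tuple[str, int], bool] = {}
    for r in sorted(restraints.active_receptor):
        flags[(receptor.chain_id, r)] = bool(
            d[receptor.index_of(r), :].min() <= restraints.d_c)
    for r in sorted(restraints.active_ligand):
        flags[(ligand.chain_id, r)] = bool(
            d[:, ligand.index_of(r)].min() <= restraints.d_c)
    frac = sum(flags.values()) / len(flags)
    return frac, flags


# ------------------------------------------------------------ energetics


@dataclass(frozen=True)
class EnergyWeights:
    """Parameters of the surrogate scoring function.

    The electrostatic prefactor is calibrated so a +1/−1 charge pair at
    ``calib_r`` = 5 Å contributes exactly −1.0 score units; the screened
    Coulomb term is cut off at ``r_cut`` (2·d_c by default) so residues
    with no partner within twice the contact cutoff contribute exactly
    nothing. The square well rewards hydrophobic–hydrophobic, polar–polar
    and opposite-charge pairs in the contact band [4.5, 8] Å.
    """

    lambda_debye: float = 10.0    # Å, screening length
    calib_r: float = 5.0          # Å, electrostatic calibration distance
    w_contact: float = 0.2        # depth of the square-well attraction
    w_clash: float = 10.0         # soft-sphere penalty weight
    w_restraint: float = 5.0      # restraint-violation penalty weight
    r_min: float = 3.5            # Å, backbone clash onset
    well_lo: float = 4.5          # Å, contact band
    well_hi: float = 8.0
    r_cut: float = 2 * DEFAULT_CONTACT_CUTOFF  # Å, electrostatic cutoff

    @property
    def w_elec(self) -> float:
        """Prefactor giving −1.0 for a +1/−1 pair at ``calib_r``."""
        return self.calib_r * math.exp(self.calib_r / self.lambda_debye)


@dataclass
class EnergyReport:
    """Surrogate interaction energy of one pose, with decomposition.

    ``total`` = electrostatic + contact + clash + restraint. The
    per-residue decomposition (symmetric half-split of each pairwise term)
    sums over both chains to ``total − restraint``; the restraint penalty
    is a pose-level quantity and is reported separately. Values are score
    units on a kcal/mol-like scale, not physical free energies.
    """

    total: float
    electrostatic: float
    contact: float
    clash: float
    restraint: float
    per_residue: dict[tuple[str, int], float]
    restraint_fraction_satisfied: float | None
    pose_index: int

    def __post_init__(self):
        if self.clash < 0 or self.restraint < 0:
            raise ValueError("clash and restraint penalties must be ≥ 0")

    @property
    def interaction(self) -> float:
        return self.total - self.restraint

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "score_units": "surrogate (kcal/mol-like; not MM/GBSA comparable)",
            "pose_index": self.pose_index,
            "total": self.total,
            "components": {
                "electrostatic": self.electrostatic,
                "contact": self.contact,
                "clash": self.clash,
                "restraint": self.restraint,
            },
            "restraint_fraction_satisfied": self.restraint_fraction_satisfied,
            "per_residue": {f"{c}:{r}": v for (c, r), v in self.per_residue.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _pair_energy_matrices(receptor: Structure, lig_sc: np.ndarray,
                          lig_bb: np.ndarray, ligand: Structure,
                          weights: EnergyWeights
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(electrostatic, contact, clash) matrices over inter-chain residue pairs."""
    d_sc = cdist(receptor.sidechain, lig_sc)
    d_bb = cdist(receptor.backbone, lig_bb)

    qq = np.outer(receptor.charges, ligand.charges)
    # soft core: the screened Coulomb is evaluated at max(r, r_min) so the
    # attraction stays bounded below clash range and minimization cannot
    # collapse the chains into the 1/r singularity
    d_eff = np.maximum(d_sc, weights.r_min)
    elec = weights.w_elec * qq * np.exp(-d_eff / weights.lambda_debye) / d_eff
    elec = np.where((d_sc <= weights.r_cut) & (qq != 0), elec, 0.0)

    rec_h = receptor.hydro
    lig_h = ligand.hydro
    both_hydro = (rec_h[:, None] == "hydrophobic") & (lig_h[None, :] == "hydrophobic")
    both_polar = (rec_h[:, None] == "polar") & (lig_h[None, :] == "polar")
    salt = qq < 0
    attractive = both_hydro | both_polar | salt
    in_band = (d_sc >= weights.well_lo) & (d_sc <= weights.well_hi)
    contact = np.where(attractive & in_band, -weights.w_contact, 0.0)

    clash = np.where(d_bb < weights.r_min,
                     weights.w_clash * (weights.r_min - d_bb) ** 2, 0.0)
    return elec, contact, clash


def score_pose(receptor: Structure, ligand: Structure, pose: Pose,
               restraints: RestraintSet | None = None,
               weights: EnergyWeights = EnergyWeights()) -> EnergyReport:
    """Score one rigid-body pose with the surrogate energy.

    Pairwise terms use the side-chain centroid distance (backbone
    centroids only for the clash term); the per-residue decomposition
    assigns half of each pairwise term to each partner. When a restraint
    set is given, a penalty w_r·(fraction violated)² is added at the pose
    level.
    """
    pose.validate()
    lig_sc = pose.apply(ligand.sidechain)
    lig_bb = pose.apply(ligand.backbone)
    elec, contact, clash = _pair_energy_matrices(
        receptor, lig_sc, lig_bb, ligand, weights)
    pair = elec + contact + clash

    per_residue: dict[tuple[str, int], float] = {}
    rec_half = 0.5 * pair.sum(axis=1)
    lig_half = 0.5 * pair.sum(axis=0)
    for i, num in enumerate(receptor.numbers):
        per_residue[(receptor.chain_id, num)] = float(rec_half[i])
    for j, num in enumerate(ligand.numbers):
        per_residue[(ligand.chain_id, num)] = float(lig_half[j])

    if restraints is not None:
        frac, _ = restraint_satisfaction(receptor, ligand, pose, restraints)
        restraint_term = weights.w_restraint * (1.0 - frac) ** 2
    else:
        frac = None
        restraint_term = 0.0

    return EnergyReport(
        total=float(pair.sum() + restraint_term),
        electrostatic=float(elec.sum()),
        contact=float(contact.sum()),
        clash=float(clash.sum()),
        restraint=float(restraint_term),
        per_residue=per_residue,
        restraint_fraction_satisfied=frac,
        pose_index=pose.index,
    )


def decompose_energy(report: EnergyReport) -> pd.DataFrame:
    """Per-residue contribution table (chain, residue, energy), sorted.

    Contributions over both chains sum to the interaction energy
    (``total`` minus the pose-level restraint penalty, which is reported
    separately).
    """
    rows = [
        {"chain": c, "residue": r, "energy": v}
        for (c, r), v in report.per_residue.items()
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["chain", "residue"], kind="mergesort")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------- pose search


def _patch_centroid(structure: Structure, residue_ids: Iterable[int]) -> np.ndarray:
    idx = [structure.index_of(r) for r in residue_ids]
    return structure.sidechain[idx].mean(axis=0)


def _all_centroids(structure: Structure) -> np.ndarray:
    return np.vstack([structure.backbone, structure.sidechain])


def aim_pose(receptor: Structure, ligand: Structure,
             rec_patch: Iterable[int], lig_patch: Iterable[int],
             axis: np.ndarray, spin: float, index: int = 1,
             contact_dist: float = 4.0, seed: int | None = None) -> Pose:
    """Aim the ligand active patch at the receptor active patch.

    The ligand is rotated so its patch outward direction opposes the
    approach ``axis``, spun about the axis by ``spin`` radians, and slid in
    along the axis to first heavy contact (minimum inter-chain centroid
    distance = ``contact_dist``).
    """
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    p_r = _patch_centroid(receptor, rec_patch)
    c_l = ligand.backbone.mean(axis=0)
    p_l = _patch_centroid(ligand, lig_patch)
    v_l = p_l - c_l
    if np.linalg.norm(v_l) < 1e-9:
        v_l = np.array([0.0, 0.0, 1.0])
    R = rotation_about_axis(axis, spin) @ align_rotation(v_l, -axis)

    rec_pts = _all_centroids(receptor)
    lig_local = _all_centroids(ligand)
    lig_rot = (lig_local - c_l) @ R.T  # patch now faces −axis

    def min_dist(s: float) -> float:
        return cdist(rec_pts, lig_rot + p_r + s * axis).min()

    s_hi = 80.0
    while min_dist(s_hi) <= contact_dist:
        s_hi *= 2.0
        if s_hi > 1e4:
            raise PoseGenerationError("cannot separate chains along approach axis")
    s_lo = -10.0
    # bisect min inter-centroid distance to the contact value
    for _ in range(80):
        mid = 0.5 * (s_lo + s_hi)
        if min_dist(mid) > contact_dist:
            s_hi = mid
        else:
            s_lo = mid
    s = s_hi
    # final map: y -> R (y − c_l) + p_r + s·axis
    t = p_r + s * axis - R @ c_l
    return Pose(index=index, rotation=R, translation=t, seed=seed)


def _hemisphere_axis(rng: np.random.Generator, outward: np.ndarray) -> np.ndarray:
    """Random unit vector in the hemisphere around the patch outward normal."""
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    if np.dot(v, outward) < 0:
        v = -v
    return v


def generate_poses(receptor: Structure, ligand: Structure,
                   restraints: RestraintSet, n: int = DEFAULT_N_POSES,
                   seed: int = 0, min_satisfaction: float = 0.5,
                   retry_cap: int = 100) -> list[Pose]:
    """Generate ``n`` restraint-consistent rigid-body candidate poses.

    Pose i aims the ligand active-patch centroid at the receptor
    active-patch centroid along a random approach axis (drawn from the
    hemisphere around the receptor patch's outward normal), spins the
    ligand about that axis by an angle stratified over [0, 2π), and slides
    to first heavy contact. A pose is accepted only if it satisfies at
    least ``min_satisfaction`` of the ambiguous restraints; otherwise the
    axis is resampled, up to ``retry_cap`` attempts per pose.
    """
    if n < 1:
        raise ValueError("n must be ≥ 1")
    _validated_structures(receptor, ligand, restraints)
    rng = np.random.default_rng(seed % 2**32)
    p_r = _patch_centroid(receptor, restraints.active_receptor)
    c_r = receptor.backbone.mean(axis=0)
    outward = p_r - c_r
    if np.linalg.norm(outward) < 1e-9:
        outward = np.array([0.0, 0.0, 1.0])
    outward = outward / np.linalg.norm(outward)

    poses: list[Pose] = []
    for i in range(n):
        base_spin = 2.0 * math.pi * i / n
        best = -1.0
        accepted = None
        for attempt in range(retry_cap):
            axis = outward if attempt == 0 and i == 0 else _hemisphere_axis(rng, outward)
            spin = base_spin + rng.uniform(0, 2.0 * math.pi / n)
            pose = aim_pose(receptor, ligand,
                            restraints.active_receptor, restraints.active_ligand,
                            axis, spin, index=i + 1, seed=seed)
            frac, _ = restraint_satisfaction(receptor, ligand, pose, restraints)
            best = max(best, frac)
            if frac >= min_satisfaction:
                accepted = pose
                break
        if accepted is None:
            raise PoseGenerationError(
                f"pose {i + 1}: no orientation reached satisfaction "
                f"{min_satisfaction:.0%} within {retry_cap} attempts "
                f"(best {best:.0%})"
            )
        poses.append(accepted)
    return poses


def random_poses(receptor: Structure, ligand: Structure, n: int,
                 seed: int = 0, contact_dist: float = 4.0) -> list[Pose]:
    """Unrestrained random contact poses (uniform orientation, random approach)."""
    rng = np.random.default_rng(seed % 2**32)
    c_r = receptor.backbone.mean(axis=0)
    c_l = ligand.backbone.mean(axis=0)
    rec_pts = _all_centroids(receptor)
    lig_local = _all_centroids(ligand)
    poses = []
    for i in range(n):
        R = random_rotation(rng)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        lig_rot = (lig_local - c_l) @ R.T

        def min_dist(s: float) -> float:
            return cdist(rec_pts, lig_rot + c_r + s * axis).min()

        s_hi = 80.0
        while min_dist(s_hi) <= contact_dist:
            s_hi *= 2.0
        s_lo = 0.0
        for _ in range(80):
            mid = 0.5 * (s_lo + s_hi)
            if min_dist(mid) > contact_dist:
                s_hi = mid
            else:
                s_lo = mid
        t = c_r + s_hi * axis - R @ c_l
        poses.append(Pose(index=i + 1, rotation=R, translation=t, seed=seed))
    return poses


def coordinate_descent(ligand: Structure, pose: Pose, objective,
                       step_rot_deg: float = 5.0, step_trans: float = 1.0,
                       min_step_rot_deg: float = 0.1, min_step_trans: float = 0.02,
                       max_sweeps: int = 500) -> Pose:
    """Greedy rigid-body descent of an arbitrary pose objective.

    The six degrees of freedom are rotations about the posed ligand's
    centroid along the lab axes and translations along the lab axes.
    Steps halve whenever a full sweep yields no improvement; termination
    when both steps fall below their floors or after ``max_sweeps``
    sweeps. The returned pose never scores worse than the input pose.
    """
    axes = np.eye(3)
    current = pose
    current_val = objective(current)
    rot_step = math.radians(step_rot_deg)
    trans_step = step_trans
    min_rot = math.radians(min_step_rot_deg)

    for _ in range(max_sweeps):
        improved = False
        center = current.apply(ligand.backbone).mean(axis=0)
        for k in range(3):
            for sign in (+1.0, -1.0):
                Rstep = rotation_about_axis(axes[k], sign * rot_step)
                cand = current.compose_after(Rstep, center - Rstep @ center)
                v = objective(cand)
                if v < current_val:
                    current, current_val = cand, v
                    improved = True
                    center = current.apply(ligand.backbone).mean(axis=0)
        for k in range(3):
            for sign in (+1.0, -1.0):
                cand = Pose(index=current.index, rotation=current.rotation,
                            translation=current.translation + sign * trans_step * axes[k],
                            seed=current.seed)
                v = objective(cand)
                if v < current_val:
                    current, current_val = cand, v
                    improved = True
        if not improved:
            rot_step *= 0.5
            trans_step *= 0.5
            if rot_step < min_rot and trans_step < min_step_trans:
                break
    return current


def minimize_pose(receptor: Structure, ligand: Structure, pose: Pose,
                  restraints: RestraintSet | None = None,
                  weights: EnergyWeights = EnergyWeights(),
                  step_rot_deg: float = 5.0, step_trans: float = 1.0,
                  min_step_rot_deg: float = 0.1, min_step_trans: float = 0.02,
                  max_sweeps: int = 500) -> Pose:
    """Local rigid-body minimization of the surrogate energy.

    Coordinate descent with shrinking steps starting at 5° / 1 Å; see
    :func:`coordinate_descent` for the schedule. The returned pose's
    score is ≤ the input pose's score.
    """
    return coordinate_descent(
        ligand, pose,
        lambda p: score_pose(receptor, ligand, p, restraints, weights).total,
        step_rot_deg=step_rot_deg, step_trans=step_trans,
        min_step_rot_deg=min_step_rot_deg, min_step_trans=min_step_trans,
        max_sweeps=max_sweeps)


def rank_complexes(reports: Sequence[tuple[Pose, EnergyReport]]
                   ) -> list[tuple[Pose, EnergyReport]]:
    """Sort pose/energy pairs ascending by total score; ties by lower pose index."""
    if not reports:
        raise ValueError("no reports to rank")
    return sorted(reports, key=lambda pr: (pr[1].total, pr[0].index))


# ------------------------------------------------------- mutation scan


@dataclass(frozen=True)
class Mutation:
    chain: str
    residue: int
    new_aa: str


@dataclass
class MutationScan:
    """In-silico point-mutation panel rescored in a fixed pose.

    ΔΔG = ΔG(mutant) − ΔG(wild type) in surrogate score units; negative
    values indicate the mutation is predicted to strengthen the interface.
    """

    wildtype_total: float
    entries: list[dict]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "score_units": "surrogate (kcal/mol-like; not MM/GBSA comparable)",
            "wildtype_total": self.wildtype_total,
            "mutations": self.entries,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def mutate_and_score(receptor: Structure, ligand: Structure, pose: Pose,
                     mutations: Sequence[tuple[str, int, str]],
                     restraints: RestraintSet | None = None,
                     weights: EnergyWeights = EnergyWeights(),
                     his_charge: int = 0) -> MutationScan:
    """Rescore single point mutations in a fixed pose.

    Each mutation replaces one residue's type-derived parameters (charge,
    hydrophobicity class) with the side-chain centroid retained — a rigid
    approximation. The restraint penalty, if any, is geometric and thus
    identical for mutant and wild type; ΔΔG reflects pairwise terms only.
    """
    wt = score_pose(receptor, ligand, pose, restraints, weights)
    entries = []
    for chain, resid, new_aa in mutations:
        if chain == receptor.chain_id:
            target, other = receptor, ligand
        elif chain == ligand.chain_id:
            target, other = ligand, receptor
        else:
            raise ValueError(f"unknown chain {chain!r}")
        old_aa = target.residue(resid).aa  # KeyError message names the residue
        mutated = target.with_mutation(resid, new_aa, his_charge)
        if target is receptor:
            rep = score_pose(mutated, ligand, pose, restraints, weights)
        else:
            rep = score_pose(receptor, mutated, pose, restraints, weights)
        entries.append({
            "chain": chain,
            "residue": int(resid),
            "from": old_aa,
            "to": new_aa,
            "dG_mut": rep.total,
            "ddG": rep.total - wt.total,
        })
    return MutationScan(wildtype_total=wt.total, entries=entries)


# ------------------------------------------------------------ utilities


def interface_rmsd(ligand: Structure, pose: Pose, reference: Pose,
                   residue_ids: Iterable[int] | None = None) -> float:
    """RMSD (Å) of ligand side-chain centroids between two poses.

    Restricted to ``residue_ids`` (e.g. the planted interface) when given.
    """
    if residue_ids is None:
        idx = slice(None)
    else:
        idx = [ligand.index_of(r) for r in residue_ids]
    a = pose.apply(ligand.sidechain)[idx]
    b = reference.apply(ligand.sidechain)[idx]
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def write_complex_pdb(receptor: Structure, ligand: Structure, pose: Pose,
                      path: str | Path) -> None:
    """Write the posed two-chain complex as PDB ATOM records."""
    posed = ligand.transformed(pose.rotation, pose.translation)
    text = receptor.to_pdb() + posed.to_pdb()
    Path(path).write_text(text)
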