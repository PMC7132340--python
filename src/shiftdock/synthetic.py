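"""Seeded synthetic inputs with planted ground truth.

Every downstream stage (CSP mapping, SPR fitting, restraint docking) is
exercisable without external data: this module generates

* toy two-chain residue-level structures with a planted charge- and
  shape-complementary interface — a cationic surface patch on the
  receptor chain (emulating a chemokine's basic β-sheet face) against an
  acidic patch on the ligand chain (emulating a galectin CRD F-face) —
  together with a truth object recording the interface sets and the
  planted rigid-body pose;
* apo/bound HSQC peak-list pairs in which a chosen interface subset
  carries binding-induced shifts of controlled magnitude above Gaussian
  noise, plus intensity attenuation of bound interface peaks (a crude
  stand-in for intermediate-exchange line broadening, which is not
  modelled);
* noisy 1:1 binding sensorgrams over a concentration series from the
  closed-form Langmuir model.

All generators are pure functions of their arguments including the seed:
the same call reproduces byte-identical output. ¹⁵N noise is 4× the ¹H
noise in ppm, reflecting typical relative digital resolution, so the 0.25
nitrogen weight is exercised nontrivially.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .csp import Peak, PeakList
from .docking import (
    EnergyWeights,
    PoseGenerationError,
    RestraintSet,
    aim_pose,
    coordinate_descent,
    minimize_pose,
    score_pose,
)
from .spr import Sensorgram
from .structures import Pose, Residue, Structure

__all__ = [
    "SyntheticComplexTruth",
    "gen_structures",
    "gen_peaklists",
    "gen_sensorgrams",
]

#: minimum separation between backbone centroids within a chain (Å)
MIN_INTRA_SEP = 3.5
#: virtual-bond step between consecutive backbone centroids (Å)
BACKBONE_STEP = 3.8
#: side-chain centroid offset from the backbone centroid (Å)
SIDECHAIN_OFFSET = 2.0
#: contact cutoff used for the planted-interface guarantee (Å)
CONTACT_CUTOFF = 8.0

_NEUTRAL_ALPHABET = tuple("ASTGLVNQFYP")
_POSITIVE_TYPES = ("K", "R")
_NEGATIVE_TYPES = ("D", "E")


@dataclass(frozen=True)
class SyntheticComplexTruth:
    """Planted ground truth for one synthetic heterodimer.

    ``planted_pose`` maps the ligand chain's stored (local-frame)
    coordinates into the complex frame; in that pose every interface
    residue on either chain has at least one partner side-chain centroid
    within ``contact_cutoff``.
    """

    receptor_interface: frozenset[int]
    ligand_interface: frozenset[int]
    planted_pose: Pose
    charge_map: dict
    contact_cutoff: float = CONTACT_CUTOFF


def _grow_chain(rng: np.random.Generator, n: int) -> np.ndarray:
    """Self-avoiding persistent random walk of backbone centroids."""
    while True:
        pts = [np.zeros(3)]
        direction = np.array([1.0, 0.0, 0.0])
        ok = True
        for _ in range(n - 1):
            placed = False
            for _attempt in range(200):
                step = direction + 0.9 * rng.normal(size=3)
                step /= np.linalg.norm(step)
                cand = pts[-1] + BACKBONE_STEP * step
                d = np.linalg.norm(np.asarray(pts) - cand, axis=1)
                if d.min() >= MIN_INTRA_SEP:
                    pts.append(cand)
                    direction = step
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.asarray(pts)


def _build_chain(rng: np.random.Generator, chain_id: str, n: int,
                 patch_size: int, patch_types: Sequence[str]) -> tuple[Structure, frozenset[int]]:
    bb = _grow_chain(rng, n)
    centroid = bb.mean(axis=0)
    # patch seeded at the most exposed residue, grown by proximity
    seed_idx = int(np.argmax(np.linalg.norm(bb - centroid, axis=1)))
    order = np.argsort(np.linalg.norm(bb - bb[seed_idx], axis=1))
    patch_idx = set(int(i) for i in order[:patch_size])

    patch_outward = bb[sorted(patch_idx)].mean(axis=0) - centroid
    patch_outward /= max(np.linalg.norm(patch_outward), 1e-9)
    residues = []
    for i in range(n):
        if i in patch_idx:
            aa = patch_types[i % len(patch_types)]
            # patch side chains point along the shared patch normal so the
            # planted interface presents a roughly flat contactable face
            outward = patch_outward + 0.15 * rng.normal(size=3)
        else:
            aa = str(rng.choice(_NEUTRAL_ALPHABET))
            outward = bb[i] - centroid + 0.5 * rng.normal(size=3)
        norm = np.linalg.norm(outward)
        if norm < 1e-9:
            outward, norm = np.array([0.0, 0.0, 1.0]), 1.0
        sc = bb[i] + SIDECHAIN_OFFSET * outward / norm
        residues.append(Residue.make(i + 1, aa, bb[i], sc))
    patch_numbers = frozenset(i + 1 for i in patch_idx)
    return Structure(chain_id, residues), patch_numbers


def gen_structures(seed: int, n_receptor: int, n_ligand: int, patch_size: int
                   ) -> tuple[Structure, Structure, SyntheticComplexTruth]:
    """Generate a receptor/ligand pair with a planted complementary interface.

    Chain A (receptor) carries a net-positive surface patch (K/R), chain B
    (ligand) the complementary net-negative patch (D/E). Backbone
    centroids within a chain are at least 3.5 Å apart. The returned truth
    object records both patches and a planted pose in which every
    interface residue has a partner side-chain centroid within 8 Å.

    The ligand structure is returned in its own local frame (centered away
    from the receptor); applying ``truth.planted_pose`` docks it.
    """
    if n_receptor < 10 or n_ligand < 10:
        raise ValueError("chains must have ≥10 residues")
    if patch_size < 3:
        raise ValueError("patch_size must be ≥3")
    if patch_size > min(n_receptor, n_ligand) / 2:
        raise ValueError(
            f"patch_size {patch_size} exceeds half the smaller chain "
            f"({min(n_receptor, n_ligand)} residues)"
        )
    rng = np.random.default_rng(seed % 2**32)
    receptor, rec_patch = _build_chain(rng, "A", n_receptor, patch_size, _POSITIVE_TYPES)
    ligand, lig_patch = _build_chain(rng, "B", n_ligand, patch_size, _NEGATIVE_TYPES)

    pose = _plant_pose(rng, receptor, ligand, rec_patch, lig_patch, seed)
    charge_map = {("A", r.number): r.charge for r in receptor.residues}
    charge_map.update({("B", r.number): r.charge for r in ligand.residues})
    truth = SyntheticComplexTruth(
        receptor_interface=rec_patch,
        ligand_interface=lig_patch,
        planted_pose=pose,
        charge_map=charge_map,
    )
    return receptor, ligand, truth


def _plant_pose(rng: np.random.Generator, receptor: Structure, ligand: Structure,
                rec_patch: frozenset[int], lig_patch: frozenset[int],
                seed: int) -> Pose:
    """Realize a pose with every interface residue in 8 Å contact.

    Three stages: aim the acidic patch at the basic patch and slide to
    first contact; settle any out-of-contact interface residues by
    coordinate descent on a hinge-loss contact objective (with a hard
    overlap penalty keeping centroids ≥ 3.6 Å apart); then relax into a
    local minimum of the surrogate energy under full restraints, so the
    planted pose is an energy-minimized structure of the complex. Starts
    are retried with jittered approach axes until the contact guarantee
    holds after relaxation.
    """
    c_r = receptor.backbone.mean(axis=0)
    p_r = receptor.sidechain[[receptor.index_of(r) for r in sorted(rec_patch)]].mean(axis=0)
    outward = p_r - c_r
    outward /= np.linalg.norm(outward)
    rec_idx = [receptor.index_of(r) for r in sorted(rec_patch)]
    lig_idx = [ligand.index_of(r) for r in sorted(lig_patch)]
    rec_all = np.vstack([receptor.backbone, receptor.sidechain])
    lig_all = np.vstack([ligand.backbone, ligand.sidechain])
    target = CONTACT_CUTOFF - 0.8   # settle comfortably inside the cutoff
    hard = 3.6                      # Å, overlap floor for all centroids

    def contact_objective(pose: Pose) -> float:
        d = cdist(receptor.sidechain, pose.apply(ligand.sidechain))
        viol = float(
            np.sum(np.clip(d[rec_idx, :].min(axis=1) - target, 0.0, None) ** 2)
            + np.sum(np.clip(d[:, lig_idx].min(axis=0) - target, 0.0, None) ** 2)
        )
        d_all = cdist(rec_all, pose.apply(lig_all))
        overlap = float(np.sum(np.clip(hard - d_all, 0.0, None) ** 2))
        return viol + 10.0 * overlap

    restraints = RestraintSet(rec_patch, lig_patch, CONTACT_CUTOFF)
    for attempt in range(20):
        if attempt == 0:
            axis = outward
            spin = 0.0
        else:
            axis = outward + 0.3 * rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            spin = 2.0 * math.pi * rng.uniform()
        pose = aim_pose(receptor, ligand, sorted(rec_patch), sorted(lig_patch),
                        axis, spin, index=0, seed=seed)
        pose = coordinate_descent(ligand, pose, contact_objective,
                                  step_rot_deg=4.0, step_trans=0.8,
                                  max_sweeps=120)
        if not _interface_in_contact(receptor, ligand, pose, rec_patch, lig_patch):
            continue
        relaxed = minimize_pose(receptor, ligand, pose, restraints)
        if not _interface_in_contact(receptor, ligand, relaxed, rec_patch, lig_patch):
            if _interface_in_contact(receptor, ligand, pose, rec_patch, lig_patch):
                return pose
            continue
        return _basin_refine(receptor, ligand, relaxed, rec_patch, lig_patch,
                             restraints)
    raise PoseGenerationError(
        "could not realize a planted pose with all interface residues "
        "in contact; try a smaller patch_size"
    )


def _basin_refine(receptor: Structure, ligand: Structure, pose: Pose,
                  rec_patch: frozenset[int], lig_patch: frozenset[int],
                  restraints: RestraintSet, max_rounds: int = 3) -> Pose:
    """Deterministically deepen the planted pose's energy basin.

    Re-minimizes from small single-axis perturbations (±3°, ±1 Å) and
    keeps any strictly better contact-preserving minimum. Makes the
    planted pose the dominant local minimum of its neighbourhood, so
    that descent from a nearby perturbed pose returns to it rather than
    sliding into an adjacent deeper basin.
    """
    from .structures import rotation_about_axis

    best = pose
    best_score = score_pose(receptor, ligand, best, restraints).total
    for _ in range(max_rounds):
        improved = False
        center = best.apply(ligand.backbone).mean(axis=0)
        candidates = []
        for k in range(3):
            axis = np.eye(3)[k]
            for sign in (+1.0, -1.0):
                R = rotation_about_axis(axis, sign * math.radians(3.0))
                candidates.append(best.compose_after(R, center - R @ center))
                candidates.append(Pose(index=best.index, rotation=best.rotation,
                                       translation=best.translation + sign * axis,
                                       seed=best.seed))
        for cand in candidates:
            relaxed = minimize_pose(receptor, ligand, cand, restraints)
            s = score_pose(receptor, ligand, relaxed, restraints).total
            if (s < best_score - 1e-9
                    and _interface_in_contact(receptor, ligand, relaxed,
                                              rec_patch, lig_patch)):
                best, best_score = relaxed, s
                improved = True
        if not improved:
            break
    return best


def _interface_in_contact(receptor: Structure, ligand: Structure, pose: Pose,
                          rec_patch: frozenset[int], lig_patch: frozenset[int],
                          cutoff: float = CONTACT_CUTOFF) -> bool:
    d = cdist(receptor.sidechain, pose.apply(ligand.sidechain))
    rec_ok = all(d[receptor.index_of(r), :].min() <= cutoff for r in rec_patch)
    lig_ok = all(d[:, ligand.index_of(r)].min() <= cutoff for r in lig_patch)
    return rec_ok and lig_ok


def gen_peaklists(structure: Structure, interface: Sequence[int] | frozenset[int],
                  effect_ppm: float, noise_ppm: float, seed: int
                  ) -> tuple[PeakList, PeakList]:
    """Generate an apo/bound HSQC peak-list pair with a planted interface.

    Apo peaks are uniform over the amide region (¹H 6.5–10.5 ppm, ¹⁵N
    105–135 ppm). Bound peaks add per-residue Gaussian noise (SD
    ``noise_ppm`` in ¹H, 4×``noise_ppm`` in ¹⁵N); interface residues
    additionally move by a combined magnitude ``effect_ppm`` in a random
    direction of the 0.25-weighted shift plane and lose intensity by a
    factor drawn uniformly from [0.3, 0.9]. Prolines have no backbone
    amide and are omitted; a proline named in ``interface`` raises a
    warning and is dropped from planting.
    """
    if effect_ppm < 0:
        raise ValueError("effect_ppm must be ≥ 0")
    if noise_ppm <= 0:
        raise ValueError("noise_ppm must be > 0")
    interface = set(int(r) for r in interface)
    unknown = interface - set(structure.numbers)
    if unknown:
        raise ValueError(f"interface residues not in structure: {sorted(unknown)}")
    prolines = {r.number for r in structure.residues if r.aa == "P"}
    dropped = interface & prolines
    if dropped:
        warnings.warn(
            f"interface residues {sorted(dropped)} are prolines (no backbone "
            "amide); dropped from planting", stacklevel=2)
        interface -= dropped

    rng = np.random.default_rng(seed % 2**32)
    apo_peaks, bound_peaks = [], []
    for res in structure.residues:
        if res.aa == "P":
            continue
        h_apo = rng.uniform(6.5, 10.5)
        n_apo = rng.uniform(105.0, 135.0)
        inten = rng.uniform(0.8e6, 1.2e6)
        h_b = h_apo + rng.normal(0.0, noise_ppm)
        n_b = n_apo + rng.normal(0.0, 4.0 * noise_ppm)
        inten_b = inten
        if res.number in interface:
            phi = rng.uniform(0.0, 2.0 * math.pi)
            # magnitude effect_ppm in the (Δ¹H, 0.25·Δ¹⁵N) plane
            h_b += effect_ppm * math.cos(phi)
            n_b += effect_ppm * math.sin(phi) / 0.25
            inten_b = inten * rng.uniform(0.3, 0.9)
        apo_peaks.append(Peak(res.aa, res.number, n_apo, h_apo, inten))
        bound_peaks.append(Peak(res.aa, res.number, n_b, h_b, inten_b))
    return (PeakList(apo_peaks, name="apo"), PeakList(bound_peaks, name="bound"))


def gen_sensorgrams(ka: float, kd: float, rmax: float,
                    concentrations: Sequence[float],
                    t_assoc: float = 60.0, t_dissoc: float = 300.0,
                    noise_ru: float = 0.0, seed: int = 0,
                    sample_rate: float = 10.0) -> list[Sensorgram]:
    """Simulate 1:1 sensorgrams over a concentration series.

    Association follows R(t) = R_eq·(1 − e^{−(k_a·C + k_d)·t}) with
    R_eq = k_a·C·R_max/(k_a·C + k_d); dissociation decays from the
    association endpoint with rate k_d. Additive i.i.d. Gaussian noise of
    SD ``noise_ru`` is applied to every sample. Default acquisition:
    1 min association, 5 min dissociation, 10 Hz.
    """
    if ka <= 0 or kd <= 0 or rmax <= 0:
        raise ValueError("ka, kd and Rmax must be positive")
    conc = [float(c) for c in concentrations]
    if not conc:
        raise ValueError("concentration series is empty")
    if any(c <= 0 for c in conc):
        raise ValueError("concentrations must be positive")
    if any(b <= a for a, b in zip(conc, conc[1:])):
        raise ValueError("concentrations must be strictly increasing")
    dt = 1.0 / sample_rate
    times = np.arange(0.0, t_assoc + t_dissoc + 0.5 * dt, dt)
    rng = np.random.default_rng(seed % 2**32)
    out = []
    for c in conc:
        kobs = ka * c + kd
        req = ka * c * rmax / kobs
        r_assoc = req * (1.0 - np.exp(-kobs * np.minimum(times, t_assoc)))
        r_end = req * (1.0 - math.exp(-kobs * t_assoc))
        r = np.where(times <= t_assoc, r_assoc,
                     r_end * np.exp(-kd * (times - t_assoc)))
        if noise_ru > 0:
            r = r + rng.normal(0.0, noise_ru, size=r.shape)
        out.append(Sensorgram(concentration=c, times=times.copy(),
                              responses=r, t_assoc_end=t_assoc))
    return out
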