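"""Residue-level protein structures and rigid-body poses.

Each residue is reduced to two pseudo-atoms: a backbone centroid (the CA
position) and a side-chain centroid (mean of the side-chain heavy atoms).
This coarse representation carries everything the restraint and scoring
logic needs — position, formal charge, and a hydrophobicity class — while
staying far below atomistic resolution.

Coordinates are in Å, right-handed, with PDB 1-based residue numbering.
By convention chain A is the receptor (chemokine role) and chain B the
ligand (lectin CRD role).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Residue",
    "Structure",
    "Pose",
    "residue_charge",
    "hydrophobicity_class",
    "rotation_about_axis",
    "align_rotation",
    "random_rotation",
    "ONE_TO_THREE",
    "THREE_TO_ONE",
]

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

#: formal charges at neutral pH; histidine is configurable (``his_charge``)
#: because acidic NMR conditions (pH 4.5) would protonate it.
_BASE_CHARGE = {"K": 1, "R": 1, "D": -1, "E": -1}

_HYDROPHOBIC = frozenset("ACFILMPVW")

#: backbone atom names excluded from the side-chain centroid
_BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: maximum distance between consecutive backbone centroids (chain sanity)
MAX_BACKBONE_STEP = 10.0


def residue_charge(aa: str, his_charge: int = 0) -> int:
    """Formal side-chain charge in e for a one-letter residue type."""
    if aa == "H":
        return int(his_charge)
    return _BASE_CHARGE.get(aa, 0)


def hydrophobicity_class(aa: str, his_charge: int = 0) -> str:
    """Coarse class of a residue type: ``charged``, ``hydrophobic`` or ``polar``."""
    if residue_charge(aa, his_charge) != 0:
        return "charged"
    if aa in _HYDROPHOBIC:
        return "hydrophobic"
    return "polar"


@dataclass(frozen=True)
class Residue:
    """One residue: number, one-letter type, two centroids, charge, class."""

    number: int
    aa: str
    backbone: tuple[float, float, float]
    sidechain: tuple[float, float, float]
    charge: int
    hydro: str

    @classmethod
    def make(cls, number: int, aa: str, backbone, sidechain,
             his_charge: int = 0) -> "Residue":
        if aa not in ONE_TO_THREE:
            raise ValueError(f"unknown residue type {aa!r}")
        return cls(
            number=int(number),
            aa=aa,
            backbone=tuple(float(x) for x in backbone),
            sidechain=tuple(float(x) for x in sidechain),
            charge=residue_charge(aa, his_charge),
            hydro=hydrophobicity_class(aa, his_charge),
        )


class Structure:
    """An ordered single chain of residue-level pseudo-atoms.

    Parameters
    ----------
    chain_id : str
        Single-character chain identifier (``A`` receptor, ``B`` ligand
        by convention).
    residues : sequence of Residue
        Ordered residues; numbers must be unique, coordinates finite, and
        consecutive backbone centroids within 10 Å of each other.
    """

    def __init__(self, chain_id: str, residues: Sequence[Residue]):
        self.chain_id = str(chain_id)
        self.residues: tuple[Residue, ...] = tuple(residues)
        if not self.residues:
            raise ValueError("structure must contain at least one residue")
        self.numbers: tuple[int, ...] = tuple(r.number for r in self.residues)
        if len(set(self.numbers)) != len(self.numbers):
            raise ValueError(f"duplicate residue numbers in chain {chain_id}")
        self.backbone = np.asarray([r.backbone for r in self.residues], float)
        self.sidechain = np.asarray([r.sidechain for r in self.residues], float)
        if not (np.isfinite(self.backbone).all() and np.isfinite(self.sidechain).all()):
            raise ValueError("non-finite coordinates")
        steps = np.linalg.norm(np.diff(self.backbone, axis=0), axis=1)
        if steps.size and steps.max() > MAX_BACKBONE_STEP:
            raise ValueError(
                f"chain {chain_id}: consecutive backbone centroids "
                f"{steps.max():.2f} Å apart exceed {MAX_BACKBONE_STEP} Å"
            )
        self.charges = np.asarray([r.charge for r in self.residues], float)
        self.hydro = np.asarray([r.hydro for r in self.residues], object)
        self._index = {n: i for i, n in enumerate(self.numbers)}

    def __len__(self) -> int:
        return len(self.residues)

    def __repr__(self) -> str:
        return f"Structure(chain={self.chain_id!r}, n={len(self)})"

    def index_of(self, number: int) -> int:
        try:
            return self._index[number]
        except KeyError:
            raise KeyError(
                f"residue {number} not in chain {self.chain_id}"
            ) from None

    def residue(self, number: int) -> Residue:
        return self.residues[self.index_of(number)]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with ``x -> R x + t`` applied to all centroids."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        bb = self.backbone @ R.T + t
        sc = self.sidechain @ R.T + t
        residues = [
            replace(r, backbone=tuple(bb[i]), sidechain=tuple(sc[i]))
            for i, r in enumerate(self.residues)
        ]
        return Structure(self.chain_id, residues)

    def with_mutation(self, number: int, new_aa: str, his_charge: int = 0) -> "Structure":
        """Return a copy with one residue's type (charge/class) replaced.

        The side-chain centroid is retained — a rigid approximation in
        which only the type-derived parameters change.
        """
        if new_aa not in ONE_TO_THREE:
            raise ValueError(f"unknown residue type {new_aa!r}")
        i = self.index_of(number)
        residues = list(self.residues)
        residues[i] = replace(
            residues[i],
            aa=new_aa,
            charge=residue_charge(new_aa, his_charge),
            hydro=hydrophobicity_class(new_aa, his_charge),
        )
        return Structure(self.chain_id, residues)

    # ---------------------------------------------------------------- PDB IO

    def to_pdb(self, path: str | Path | None = None) -> str:
        """Write minimal ATOM records (CA = backbone, CB = side-chain centroid)."""
        lines = []
        serial = 1
        for r in self.residues:
            res3 = ONE_TO_THREE[r.aa]
            for name, xyz, elem in (("CA", r.backbone, "C"), ("CB", r.sidechain, "C")):
                lines.append(
                    f"ATOM  {serial:5d} {name:^4s} {res3:>3s} {self.chain_id}"
                    f"{r.number:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"  1.00  0.00           {elem}"
                )
                serial += 1
        lines.append("TER")
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_pdb(cls, path: str | Path, chain_id: str | None = None,
                 his_charge: int = 0) -> "Structure":
        """Read one chain from PDB ATOM records.

        The backbone centroid is the CA position; the side-chain centroid
        is the mean of non-backbone heavy atoms, falling back to CB and
        then CA (glycine).
        """
        from Bio.PDB import PDBParser

        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("s", str(path))
        model = next(structure.get_models())
        chains = {c.id: c for c in model.get_chains()}
        if chain_id is None:
            if len(chains) != 1:
                raise ValueError(
                    f"file has chains {sorted(chains)}; specify chain_id"
                )
            chain_id = next(iter(chains))
        if chain_id not in chains:
            raise ValueError(f"chain {chain_id!r} not found (has {sorted(chains)})")
        residues = []
        for res in chains[chain_id].get_residues():
            hetflag, resseq, _ = res.get_id()
            if hetflag.strip():
                continue
            res3 = res.get_resname()
            if res3 not in THREE_TO_ONE:
                continue
            if "CA" not in res:
                continue
            ca = res["CA"].get_coord()
            side = [
                a.get_coord() for a in res.get_atoms()
                if a.get_name() not in _BACKBONE_ATOMS and a.element != "H"
            ]
            if side:
                sc = np.mean(side, axis=0)
            elif "CB" in res:
                sc = res["CB"].get_coord()
            else:
                sc = ca
            residues.append(
                Residue.make(resseq, THREE_TO_ONE[res3], ca, sc, his_charge)
            )
        return cls(chain_id, residues)


# -------------------------------------------------------------------- poses


@dataclass
class Pose:
    """A rigid transform of the ligand chain: ``x -> R x + t``.

    ``index`` is the 1-based generation-order index used for deterministic
    tie-breaking in rankings; ``seed`` records provenance.
    """

    index: int
    rotation: np.ndarray
    translation: np.ndarray
    seed: int | None = None

    _ORTHO_TOL = 1e-9

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, float).reshape(3, 3)
        self.translation = np.asarray(self.translation, float).reshape(3)
        self.validate()

    def validate(self) -> None:
        R = self.rotation
        err = np.abs(R @ R.T - np.eye(3)).max()
        det = np.linalg.det(R)
        if err > self._ORTHO_TOL or abs(det - 1.0) > self._ORTHO_TOL:
            raise ValueError(
                f"rotation not special-orthogonal (orthonormality dev {err:.2e}, "
                f"det {det:.12f})"
            )

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    def compose_after(self, rotation: np.ndarray, translation: np.ndarray) -> "Pose":
        """Return the pose ``x -> R2 (R x + t) + t2`` (apply another map after)."""
        R2 = np.asarray(rotation, float)
        t2 = np.asarray(translation, float)
        return Pose(
            index=self.index,
            rotation=_reorthonormalize(R2 @ self.rotation),
            translation=R2 @ self.translation + t2,
            seed=self.seed,
        )

    def conjugated(self, rotation: np.ndarray, translation: np.ndarray) -> "Pose":
        """Express this pose in globally transformed coordinates.

        If receptor and ligand coordinates are both mapped by ``y = G x + g``,
        the pose acting in the new frame is ``G ∘ pose ∘ G⁻¹``.
        """
        G = np.asarray(rotation, float)
        g = np.asarray(translation, float)
        R = _reorthonormalize(G @ self.rotation @ G.T)
        t = G @ self.translation + g - R @ g
        return Pose(index=self.index, rotation=R, translation=t, seed=self.seed)


def _reorthonormalize(R: np.ndarray) -> np.ndarray:
    """Project a near-rotation onto SO(3) (guards accumulated round-off)."""
    U, _, Vt = np.linalg.svd(R)
    out = U @ Vt
    if np.linalg.det(out) < 0:
        U[:, -1] *= -1
        out = U @ Vt
    return out


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis`` (radians)."""
    from scipy.spatial.transform import Rotation

    axis = np.asarray(axis, float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("zero rotation axis")
    return Rotation.from_rotvec(axis / n * angle).as_matrix()


def align_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking direction ``a`` to direction ``b``."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate π about any axis orthogonal to a
        helper = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, helper)
        return rotation_about_axis(axis, math.pi)
    return rotation_about_axis(v, math.atan2(np.linalg.norm(v), c))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    from scipy.spatial.transform import Rotation

    quat = rng.normal(size=4)
    quat /= np.linalg.norm(quat)
    return Rotation.from_quat(quat).as_matrix()
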