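"""Shared fixtures and independent oracles for the test suite."""

import math

import numpy as np
import pytest

from shiftdock import RestraintSet, gen_structures
from shiftdock.docking import EnergyWeights


@pytest.fixture(scope="session")
def planted_complex():
    """One synthetic heterodimer with planted complementary interface."""
    receptor, ligand, truth = gen_structures(2, 40, 30, 5)
    return receptor, ligand, truth


@pytest.fixture(scope="session")
def planted_restraints(planted_complex):
    _, _, truth = planted_complex
    return RestraintSet(truth.receptor_interface, truth.ligand_interface, 8.0)


def naive_score(receptor, ligand, pose, restraints=None,
                weights: EnergyWeights = EnergyWeights()):
    """Brute-force all-pairs double-loop surrogate energy.

    Independent re-implementation of the scoring definition using plain
    Python loops; returns (total, electrostatic, contact, clash,
    restraint, per_residue dict).
    """
    lig_sc = pose.apply(ligand.sidechain)
    lig_bb = pose.apply(ligand.backbone)
    elec = contact = clash = 0.0
    per = {(receptor.chain_id, r.number): 0.0 for r in receptor.residues}
    per.update({(ligand.chain_id, r.number): 0.0 for r in ligand.residues})
    for i, ri in enumerate(receptor.residues):
        for j, rj in enumerate(ligand.residues):
            r_sc = math.dist(receptor.sidechain[i], lig_sc[j])
            r_bb = math.dist(receptor.backbone[i], lig_bb[j])
            qq = ri.charge * rj.charge
            e = 0.0
            if qq != 0 and r_sc <= weights.r_cut:
                r_eff = max(r_sc, weights.r_min)
                e_el = (weights.w_elec * qq
                        * math.exp(-r_eff / weights.lambda_debye) / r_eff)
                elec += e_el
                e += e_el
            attractive = (
                (ri.hydro == "hydrophobic" and rj.hydro == "hydrophobic")
                or (ri.hydro == "polar" and rj.hydro == "polar")
                or qq < 0
            )
            if attractive and weights.well_lo <= r_sc <= weights.well_hi:
                contact += -weights.w_contact
                e += -weights.w_contact
            if r_bb < weights.r_min:
                e_cl = weights.w_clash * (weights.r_min - r_bb) ** 2
                clash += e_cl
                e += e_cl
            per[(receptor.chain_id, ri.number)] += 0.5 * e
            per[(ligand.chain_id, rj.number)] += 0.5 * e
    restraint = 0.0
    if restraints is not None:
        flags = []
        for rnum in sorted(restraints.active_receptor):
            i = receptor.index_of(rnum)
            dmin = min(math.dist(receptor.sidechain[i], lig_sc[j])
                       for j in range(len(ligand.residues)))
            flags.append(dmin <= restraints.d_c)
        for rnum in sorted(restraints.active_ligand):
            j = ligand.index_of(rnum)
            dmin = min(math.dist(receptor.sidechain[i], lig_sc[j])
                       for i in range(len(receptor.residues)))
            flags.append(dmin <= restraints.d_c)
        frac = sum(flags) / len(flags)
        restraint = weights.w_restraint * (1.0 - frac) ** 2
    total = elec + contact + clash + restraint
    return total, elec, contact, clash, restraint, per
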