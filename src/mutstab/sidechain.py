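"""Mutant model construction and ideal-geometry peptide building.

Sidechain replacement is deliberately minimal and deterministic: atoms the
wildtype and mutant sidechain topologies share stay at their wildtype
coordinates; atoms new to the mutant are taken from an ideal residue
template (CCD ideal coordinates shipped with biotite) superposed on the
site's backbone, with chi angles set to a single fixed most-common rotamer.
No repacking or minimisation is performed, so models are reproducible and
the perturbation is confined to the mutated residue.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import biotite.structure.info as struc_info

from .constants import (
    CHI_ATOMS,
    ONE_TO_THREE,
    ROTAMER_CHI,
    SIDECHAIN_ATOMS,
    vdw_radius,
)
from .errors import IncompleteResidueError
from .geometry import dihedral, place_atom, rotation_about_axis
from .structure import Atom, MutationSpec, ProteinStructure, Residue

__all__ = ["build_mutant_model", "ideal_residue_coords", "build_peptide"]


@lru_cache(maxsize=None)
def _template(res_type: str) -> dict[str, np.ndarray]:
    """Ideal heavy-atom coordinates for a residue type, keyed by atom name."""
    arr = struc_info.residue(res_type)
    coords = {}
    for name, element, xyz in zip(arr.atom_name, arr.element, arr.coord):
        if element == "H" or name == "OXT":
            continue
        coords[name] = np.array(xyz, dtype=float)
    return coords


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rotation/translation mapping ``mobile`` onto ``target``."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, mc, tc


def _set_chi_angles(coords: dict[str, np.ndarray], one_letter: str) -> None:
    """Rotate template sidechain atoms to the fixed most-common rotamer."""
    chis = ROTAMER_CHI.get(one_letter)
    defs = CHI_ATOMS.get(one_letter)
    if not chis or not defs:
        return
    order = SIDECHAIN_ATOMS[one_letter]
    for target, (a, b, c, d) in zip(chis, defs):
        if any(n not in coords for n in (a, b, c, d)):
            break
        current = dihedral(coords[a], coords[b], coords[c], coords[d])
        rot = rotation_about_axis(coords[b] - coords[c], target - current)
        pivot = coords[c]
        # rotate everything distal to the b-c bond (d and later atoms)
        start = order.index(d)
        moving = {d} | set(order[start:])
        moving.discard(b)
        moving.discard(c)
        for name in moving:
            if name in coords:
                coords[name] = pivot + rot @ (coords[name] - pivot)


def ideal_residue_coords(one_letter: str) -> dict[str, np.ndarray]:
    """Template heavy-atom coordinates with rotamer chis applied."""
    coords = {k: v.copy() for k, v in _template(ONE_TO_THREE[one_letter]).items()}
    if one_letter != "P":  # proline ring geometry kept as the template's
        _set_chi_angles(coords, one_letter)
    return coords


def _element_of(atom_name: str) -> str:
    return atom_name[0] if atom_name[0] in ("N", "O", "S", "C") else "C"


def build_sidechain(residue: Residue, mut_aa: str) -> list[Atom]:
    """Sidechain atoms for ``mut_aa`` grafted onto ``residue``'s backbone.

    Shared atoms keep wildtype coordinates; new atoms come from the ideal
    template superposed on N/CA/C (and CB when present in both).
    """
    if not residue.has_backbone():
        raise IncompleteResidueError(
            f"residue {residue.id} lacks N/CA/C backbone atoms"
        )
    wanted = SIDECHAIN_ATOMS[mut_aa]
    existing = {a.name: a for a in residue.heavy_atoms()}
    shared = [existing[n] for n in wanted if n in existing]
    missing = [n for n in wanted if n not in existing]

    new_atoms: dict[str, np.ndarray] = {}
    if missing:
        template = ideal_residue_coords(mut_aa)
        anchors = ["N", "CA", "C"]
        mobile = np.array([template[n] for n in anchors])
        target = np.array([existing[n].position for n in anchors])
        rot, mc, tc = _kabsch(mobile, target)
        for name in missing:
            pos = rot @ (template[name] - mc) + tc
            new_atoms[name] = pos

    atoms: list[Atom] = []
    for name in wanted:
        if name in existing:
            atoms.append(existing[name].copy())
        else:
            el = _element_of(name)
            atoms.append(Atom(name, el, new_atoms[name], vdw_radius(el)))
    return atoms


def build_mutant_model(
    structure: ProteinStructure, mutation: MutationSpec
) -> ProteinStructure:
    """Copy of ``structure`` with the mutation's sidechain replaced.

    All residues other than the mutation site are untouched; the site keeps
    its backbone (N, CA, C, O, OXT) coordinates bit-identically.
    """
    model = structure.copy()
    site = model.get_residue(
        mutation.chain_id, mutation.seq_number, mutation.insertion_code
    )
    if site is None:
        raise IncompleteResidueError(f"mutation site {mutation} absent")
    sidechain = build_sidechain(site, mutation.mut_aa)
    backbone = [a for a in site.atoms if a.name in ("N", "CA", "C", "O", "OXT")]
    site.atoms = backbone + sidechain
    site.res_type = ONE_TO_THREE[mutation.mut_aa]
    model.id = f"{structure.id}_{mutation}"
    model.metadata = dict(structure.metadata)
    model.metadata["mutant_protocol"] = (
        "common-atom retention + ideal-template sidechain at fixed rotamer; "
        "no repacking"
    )
    return model


# --- ideal-geometry peptide construction (fixture structures) -------------

_BB = {
    "N_CA": 1.458, "CA_C": 1.525, "C_N": 1.329, "C_O": 1.231,
    "N_CA_C": 111.2, "CA_C_N": 116.2, "C_N_CA": 121.7,
    "CA_C_O": 120.8,
}


def build_peptide(
    sequence: str,
    phi: float = -57.0,
    psi: float = -47.0,
    chain_id: str = "A",
    start_resnum: int = 1,
    structure_id: str = "peptide",
) -> ProteinStructure:
    """Build an ideal-geometry peptide with uniform (phi, psi) and trans
    omega; defaults give a canonical alpha helix.  Sidechains are grafted
    from the same ideal templates used for mutant modelling.
    """
    residues: list[Residue] = []
    # seed backbone for residue 1
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_BB["N_CA"], 0.0, 0.0])
    c = place_atom(
        np.array([0.0, 1.0, 0.0]), n, ca, _BB["CA_C"], _BB["N_CA_C"], phi
    )
    coords = [(n, ca, c)]
    for _ in range(1, len(sequence)):
        n_prev, ca_prev, c_prev = coords[-1]
        n_next = place_atom(n_prev, ca_prev, c_prev, _BB["C_N"], _BB["CA_C_N"], psi)
        ca_next = place_atom(ca_prev, c_prev, n_next, _BB["N_CA"], _BB["C_N_CA"], 180.0)
        c_next = place_atom(c_prev, n_next, ca_next, _BB["CA_C"], _BB["N_CA_C"], phi)
        coords.append((n_next, ca_next, c_next))

    for i, (aa, (npos, capos, cpos)) in enumerate(zip(sequence, coords)):
        # carbonyl O sits in the peptide plane, trans to the following N
        o_pos = place_atom(npos, capos, cpos, _BB["C_O"], _BB["CA_C_O"], psi + 180.0)
        res = Residue(
            chain_id=chain_id,
            seq_number=start_resnum + i,
            insertion_code="",
            res_type=ONE_TO_THREE[aa],
            atoms=[
                Atom("N", "N", npos, vdw_radius("N")),
                Atom("CA", "C", capos, vdw_radius("C")),
                Atom("C", "C", cpos, vdw_radius("C")),
                Atom("O", "O", o_pos, vdw_radius("O")),
            ],
        )
        res.atoms.extend(build_sidechain(res, aa))
        residues.append(res)
    return ProteinStructure(id=structure_id, residues=residues)
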