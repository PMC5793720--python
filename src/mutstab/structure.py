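"""Protein structure model: PDB parsing/writing, mutation specifications.

Parsing is delegated to Bio.PDB and the result converted into the package's
lightweight containers.  Only the first MODEL of multi-model files is kept;
for alternate locations the highest-occupancy conformer wins (ties broken
towards altloc 'A').  Hetero records (including waters) are excluded from
the protein residue list but retained separately so geometry routines can
optionally see them.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from .constants import (
    BACKBONE_ATOMS,
    NONSTANDARD_MAP,
    ONE_TO_THREE,
    THREE_TO_ONE,
    vdw_radius,
)
from .errors import (
    EmptyStructureError,
    MutationFormatError,
    PdbParseError,
    ResidueNotFoundError,
    WildtypeMismatchError,
)

__all__ = [
    "Atom",
    "Residue",
    "ProteinStructure",
    "MutationSpec",
    "parse_pdb",
    "write_pdb",
    "parse_mutation",
]


@dataclass
class Atom:
    """A heavy (or hydrogen) atom with coordinates and a vdW radius."""

    name: str
    element: str
    position: np.ndarray
    vdw_radius: float
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if self.vdw_radius <= 0:
            raise ValueError(f"non-positive vdW radius for atom {self.name}")

    def copy(self) -> "Atom":
        return replace(self, position=self.position.copy())


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    insertion_code: str
    res_type: str
    atoms: list[Atom] = field(default_factory=list)
    is_standard: bool = True

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_type, "X")

    @property
    def id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_backbone(self) -> bool:
        names = {a.name for a in self.atoms}
        return {"N", "CA", "C"} <= names

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element != "H"]

    def sidechain_atoms(self) -> list[Atom]:
        """Sidechain heavy atoms; glycine falls back to CA as proxy."""
        sc = [a for a in self.heavy_atoms() if a.name not in BACKBONE_ATOMS]
        if not sc:
            ca = self.atom("CA")
            return [ca] if ca is not None else []
        return sc

    def copy(self) -> "Residue":
        return Residue(
            self.chain_id,
            self.seq_number,
            self.insertion_code,
            self.res_type,
            [a.copy() for a in self.atoms],
            self.is_standard,
        )


@dataclass
class ProteinStructure:
    """Ordered protein residues grouped by chain, plus hetero leftovers."""

    id: str
    residues: list[Residue] = field(default_factory=list)
    hetero_residues: list[Residue] = field(default_factory=list)
    resolution: float | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def chain(self, chain_id: str) -> list[Residue]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def get_residue(
        self, chain_id: str, seq_number: int, insertion_code: str = ""
    ) -> Residue | None:
        for r in self.residues:
            if r.id == (chain_id, seq_number, insertion_code):
                return r
        return None

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def copy(self) -> "ProteinStructure":
        return ProteinStructure(
            self.id,
            [r.copy() for r in self.residues],
            [r.copy() for r in self.hetero_residues],
            self.resolution,
            dict(self.metadata),
        )


@dataclass(frozen=True)
class MutationSpec:
    """A validated single point mutation, e.g. A/282 R->W."""

    chain_id: str
    seq_number: int
    insertion_code: str
    wt_aa: str
    mut_aa: str

    def __post_init__(self) -> None:
        if self.wt_aa not in ONE_TO_THREE or self.mut_aa not in ONE_TO_THREE:
            raise MutationFormatError(
                f"unknown amino acid in {self.wt_aa}->{self.mut_aa}"
            )
        if self.wt_aa == self.mut_aa:
            raise MutationFormatError(
                f"wildtype and mutant residue are both {self.wt_aa}"
            )

    def inverted(self) -> "MutationSpec":
        return MutationSpec(
            self.chain_id, self.seq_number, self.insertion_code,
            self.mut_aa, self.wt_aa,
        )

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.seq_number}{self.insertion_code}{self.mut_aa}"


def _best_altloc(atoms) -> "object":
    """Highest occupancy wins; ties break towards altloc 'A'."""
    def key(a):
        occ = a.get_occupancy()
        return (-(occ if occ is not None else 0.0), a.get_altloc())

    return sorted(atoms, key=key)[0]


def parse_pdb(source: str | Path | io.TextIOBase, id: str = "") -> ProteinStructure:
    """Parse PDB-format text (path, text blob or handle) into a structure.

    Standard residues are ordered by chain then author sequence number as
    they appear in the file.  MSE is mapped to MET; all other non-standard
    residues go to the hetero list.
    """
    label = id
    if isinstance(source, io.TextIOBase):
        handle = source
    else:
        text = str(source)
        if "\n" not in text and Path(text).exists():
            handle = open(text)
            label = label or Path(text).stem
        elif "ATOM" in text or "HETATM" in text:
            handle = io.StringIO(text)
        else:
            raise PdbParseError(f"cannot read PDB input: {text[:80]!r}")

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            bio = PDBParser(QUIET=True).get_structure(label or "structure", handle)
    except Exception as exc:  # Bio.PDB raises assorted types on bad input
        raise PdbParseError(f"unreadable PDB input: {exc}") from exc
    finally:
        if handle is not source:
            handle.close()

    models = list(bio.get_models())
    if not models:
        raise PdbParseError("no MODEL found in input")
    model = models[0]

    structure = ProteinStructure(id=label or bio.id)
    nonstandard_seen: set[str] = set()
    for chain in model:
        for res in chain:
            hetflag, seqnum, icode = res.id
            resname = res.get_resname().strip()
            is_water = resname in ("HOH", "WAT", "DOD")
            mapped = NONSTANDARD_MAP.get(resname)
            standard = resname in THREE_TO_ONE or mapped is not None
            atoms: list[Atom] = []
            # group alternate locations by atom name, keep the best one
            by_name: dict[str, list] = {}
            for a in res.get_unpacked_list():
                by_name.setdefault(a.get_name(), []).append(a)
            for name, group in by_name.items():
                a = _best_altloc(group)
                element = (a.element or name[:1]).strip().upper()
                atom_name = name
                if mapped == "MET" and name == "SE":
                    atom_name, element = "SD", "S"
                atoms.append(
                    Atom(
                        name=atom_name,
                        element=element,
                        position=np.array(a.coord, dtype=float),
                        vdw_radius=vdw_radius(element),
                        altloc=(a.get_altloc() or "").strip(),
                        occupancy=a.get_occupancy() if a.get_occupancy() is not None else 1.0,
                    )
                )
            residue = Residue(
                chain_id=chain.id.strip() or "A",
                seq_number=seqnum,
                insertion_code=icode.strip(),
                res_type=mapped or resname,
                atoms=atoms,
                is_standard=standard,
            )
            if standard and hetflag.strip() in ("", f"H_{resname}"):
                structure.residues.append(residue)
            elif not is_water:
                if not standard and hetflag.strip():
                    nonstandard_seen.add(resname)
                structure.hetero_residues.append(residue)
    if nonstandard_seen:
        warnings.warn(
            "non-standard residues excluded from protein list: "
            + ", ".join(sorted(nonstandard_seen))
        )
    if not structure.residues:
        raise EmptyStructureError("no standard protein residues in input")
    return structure


_PDB_ATOM = (
    "ATOM  {serial:5d} {name:<4s}{altloc:1s}{resname:>3s} {chain:1s}"
    "{resnum:4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {element:>2s}\n"
)


def _format_atom_name(name: str, element: str) -> str:
    # PDB convention: element symbol right-justified in columns 13-14
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4s}"[:4]
    return f" {name:<3s}"


def write_pdb(structure: ProteinStructure, destination: str | Path | io.TextIOBase) -> None:
    """Write standard ATOM records; author numbering is preserved."""
    if not structure.residues:
        raise EmptyStructureError("refusing to write an empty structure")

    own = not isinstance(destination, io.TextIOBase)
    handle = open(destination, "w") if own else destination
    try:
        serial = 0
        last_chain = None
        for res in structure.residues:
            if last_chain is not None and res.chain_id != last_chain:
                handle.write("TER\n")
            last_chain = res.chain_id
            for atom in res.atoms:
                serial += 1
                handle.write(
                    _PDB_ATOM.format(
                        serial=serial,
                        name=_format_atom_name(atom.name, atom.element),
                        altloc=atom.altloc or " ",
                        resname=res.res_type,
                        chain=res.chain_id,
                        resnum=res.seq_number,
                        icode=res.insertion_code or " ",
                        x=atom.position[0],
                        y=atom.position[1],
                        z=atom.position[2],
                        occ=atom.occupancy,
                        b=0.0,
                        element=atom.element,
                    )
                )
        handle.write("TER\nEND\n")
    finally:
        if own:
            handle.close()


def pdb_string(structure: ProteinStructure) -> str:
    buf = io.StringIO()
    write_pdb(structure, buf)
    return buf.getvalue()


_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z]?)([A-Za-z])$")


def parse_mutation(
    spec: str, chain: str, structure: ProteinStructure
) -> MutationSpec:
    """Validate a mutation string like ``R282W`` (optionally ``R282aW`` with
    an insertion code) against a structure.
    """
    m = _MUTATION_RE.match(spec.strip())
    if m is None:
        raise MutationFormatError(
            f"mutation {spec!r} does not match <wt><number>[icode]<mut>"
        )
    wt, num, icode, mut = m.groups()
    wt, mut, icode = wt.upper(), mut.upper(), icode.upper()
    if wt not in ONE_TO_THREE or mut not in ONE_TO_THREE:
        raise MutationFormatError(f"unknown amino acid code in {spec!r}")
    if wt == mut:
        raise MutationFormatError(f"{spec!r}: wildtype equals mutant")
    residue = structure.get_residue(chain, int(num), icode)
    if residue is None:
        raise ResidueNotFoundError(
            f"no residue {chain}/{num}{icode} in structure {structure.id!r}"
        )
    if residue.one_letter != wt:
        raise WildtypeMismatchError(
            f"residue {chain}/{num}{icode} is {residue.one_letter}, not {wt}"
        )
    return MutationSpec(chain, int(num), icode, wt, mut)
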