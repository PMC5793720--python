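"""Per-residue structural environment descriptors and discrete classes.

Five descriptors are computed from heavy-atom geometry alone:

* relative sidechain solvent accessibility (RSA, %) — Shrake–Rupley dot
  SASA of the sidechain over its maximum in an extended Gly-X-Gly
  reference; glycine uses CA as sidechain proxy; residues with RSA < 17%
  are flagged buried;
* occluded surface packing (OSP, 0..1) — fraction of the residue's van
  der Waals surface whose outward normal rays strike a non-bonded atom of
  another residue within a 2.8 A (water diameter) shell, weighted by how
  short the ray is;
* residue depth (A) — mean distance of the residue's atoms from the
  solvent-accessible surface dot cloud, a deterministic stand-in for the
  nearest-surface-water convention;
* sidechain hydrogen-bonding class (0..7) — a 3-bit code for sidechain
  H-bonds to mainchain amide N (bit 0), mainchain carbonyl O (bit 1) and
  other sidechain/hetero partners (bit 2);
* mainchain conformation class (1..9) — a fixed Ramachandran partition
  covering helix, strand, polyproline, left-handed, cis-peptide and
  undefined conformations.

A scheme (e.g. the default ``216_OSP`` = 9 mainchain x 3 OSP x 8 H-bond)
maps the descriptor tuple to a single environment-class index used to
select substitution tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .constants import (
    MAX_SIDECHAIN_AREA,
    OCCLUSION_SHELL,
    SIDECHAIN_ACCEPTORS,
    SIDECHAIN_ATOMS,
    SIDECHAIN_DONORS,
    WATER_RADIUS,
)
from .errors import ConfigError
from .geometry import bond_angle, dihedral, unit_sphere_points
from .structure import ProteinStructure, Residue

__all__ = [
    "EnvironmentConfig",
    "EnvironmentAnnotation",
    "EnvironmentClassIndex",
    "Annotator",
    "compute_rsa",
    "compute_osp",
    "compute_depth",
    "classify_hbonds",
    "classify_mainchain",
    "classify_environment",
    "annotate_structure",
    "annotation_table",
    "n_classes",
]

_BOND_CUTOFF = 2.1  # heavy atoms closer than this are treated as bonded (A)

MAINCHAIN_LABELS = {
    1: "alpha", 2: "near-alpha", 3: "beta", 4: "polyproline",
    5: "coil-neg-phi", 6: "left-alpha", 7: "pos-phi", 8: "cis", 9: "undefined",
}
_LEVEL3 = ("low", "medium", "high")
_RSA_LEVELS = ("buried", "intermediate", "exposed")
_DEPTH_LEVELS = ("shallow", "medium", "deep")

SCHEMES = ("54_RSA", "216_OSP", "216_depth", "648_RSA_OSP_depth")


@dataclass(frozen=True)
class EnvironmentConfig:
    """Descriptor class boundaries, dot densities and H-bond criteria."""

    scheme: str = "216_OSP"
    probe_radius: float = WATER_RADIUS
    n_dots: int = 960           # SASA / depth surface dots per atom
    osp_dots: int = 960         # occlusion rays per atom
    osp_bounds: tuple[float, float] = (0.33, 0.56)
    rsa_bounds: tuple[float, float] = (17.0, 50.0)
    depth_bounds: tuple[float, float] = (4.0, 8.0)
    hbond_distance: float = 3.5
    hbond_angle: float = 90.0
    buried_rsa: float = 17.0

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ConfigError(f"unknown scheme {self.scheme!r}; choose from {SCHEMES}")
        for bounds in (self.osp_bounds, self.rsa_bounds, self.depth_bounds):
            if not bounds[0] < bounds[1]:
                raise ConfigError(f"class boundaries must increase: {bounds}")

    @property
    def factors(self) -> tuple[tuple[str, int], ...]:
        if self.scheme == "216_OSP":
            return (("mainchain", 9), ("osp", 3), ("hbond", 8))
        if self.scheme == "216_depth":
            return (("mainchain", 9), ("depth", 3), ("hbond", 8))
        if self.scheme == "54_RSA":
            return (("mainchain", 9), ("rsa", 3), ("hbond2", 2))
        return (("mainchain", 9), ("rsa", 3), ("packing", 3), ("hbond", 8))

    @property
    def n_classes(self) -> int:
        out = 1
        for _, n in self.factors:
            out *= n
        return out


def n_classes(config: EnvironmentConfig) -> int:
    return config.n_classes


@dataclass(frozen=True)
class EnvironmentClassIndex:
    index: int
    label: str


@dataclass
class EnvironmentAnnotation:
    """Computed descriptors for one residue."""

    chain_id: str
    seq_number: int
    insertion_code: str
    one_letter: str
    mainchain_class: int
    rsa: float
    osp: float
    depth: float
    hbond_class: int
    sidechain_area: float       # absolute sidechain SASA (A^2)
    partial: bool = False       # sidechain atoms were missing
    buried_rsa_cutoff: float = 17.0

    @property
    def buried(self) -> bool:
        return self.rsa < self.buried_rsa_cutoff

    @property
    def mainchain_label(self) -> str:
        return MAINCHAIN_LABELS[self.mainchain_class]

    def level(self, factor: str, config: EnvironmentConfig) -> int:
        if factor == "mainchain":
            return self.mainchain_class - 1
        if factor == "osp":
            return int(np.digitize(self.osp, config.osp_bounds))
        if factor == "rsa":
            return int(np.digitize(self.rsa, config.rsa_bounds))
        if factor == "depth":
            return int(np.digitize(self.depth, config.depth_bounds))
        if factor == "hbond":
            return self.hbond_class
        if factor == "hbond2":
            return int(self.hbond_class > 0)
        if factor == "packing":
            # majority vote of the OSP and depth classes; ties go to OSP
            o = self.level("osp", config)
            d = self.level("depth", config)
            return o if o == d else o
        raise ConfigError(f"unknown factor {factor!r}")

    def rsa_class(self, config: EnvironmentConfig) -> str:
        return _RSA_LEVELS[self.level("rsa", config)]

    def osp_class(self, config: EnvironmentConfig) -> str:
        return _LEVEL3[self.level("osp", config)]

    def depth_class(self, config: EnvironmentConfig) -> str:
        return _DEPTH_LEVELS[self.level("depth", config)]


def classify_environment(
    annotation: EnvironmentAnnotation, config: EnvironmentConfig
) -> EnvironmentClassIndex:
    """Mixed-radix index of the annotation's factor-level tuple."""
    levels = [annotation.level(name, config) for name, _ in config.factors]
    return levels_to_index(tuple(levels), config)


def levels_to_index(
    levels: tuple[int, ...], config: EnvironmentConfig
) -> EnvironmentClassIndex:
    factors = config.factors
    if len(levels) != len(factors):
        raise ConfigError(
            f"scheme {config.scheme} expects {len(factors)} levels, got {len(levels)}"
        )
    index = 0
    parts = []
    for (name, n), lv in zip(factors, levels):
        if not 0 <= lv < n:
            raise ConfigError(f"level {lv} out of range for factor {name}")
        index = index * n + lv
        parts.append(f"{name}{lv}")
    return EnvironmentClassIndex(index, "|".join(parts))


def index_to_levels(index: int, config: EnvironmentConfig) -> tuple[int, ...]:
    levels = []
    for _, n in reversed(config.factors):
        levels.append(index % n)
        index //= n
    if index:
        raise ConfigError("index out of range for scheme")
    return tuple(reversed(levels))


class Annotator:
    """Shared-geometry annotation engine for one structure.

    SASA and the solvent-accessible surface cloud are computed once per
    structure; per-residue descriptors reuse them.
    """

    def __init__(
        self,
        structure: ProteinStructure,
        config: EnvironmentConfig | None = None,
        include_hetero: bool = False,
    ) -> None:
        self.structure = structure
        self.config = config or EnvironmentConfig()
        residues = list(structure.residues)
        if include_hetero:
            residues = residues + list(structure.hetero_residues)
        self.residues = residues
        self._res_of_protein = {r.id: i for i, r in enumerate(structure.residues)}

        coords, radii, res_idx, names = [], [], [], []
        for i, res in enumerate(residues):
            for a in res.heavy_atoms():
                coords.append(a.position)
                radii.append(a.vdw_radius)
                res_idx.append(i)
                names.append(a.name)
        self.coords = np.asarray(coords, float).reshape(-1, 3)
        self.radii = np.asarray(radii, float)
        self.res_idx = np.asarray(res_idx, int)
        self.names = names
        self._tree = cKDTree(self.coords) if len(self.coords) else None
        self._sasa: np.ndarray | None = None
        self._surface: np.ndarray | None = None
        self._surface_tree: cKDTree | None = None

    # -- solvent-accessible surface -------------------------------------

    def _compute_sasa(self) -> None:
        cfg = self.config
        dots = unit_sphere_points(cfg.n_dots)
        n = len(self.coords)
        sasa = np.zeros(n)
        surface_chunks = []
        probe = cfg.probe_radius
        rmax = self.radii.max() if n else 0.0
        for i in range(n):
            ri = self.radii[i] + probe
            pts = self.coords[i] + ri * dots
            neighbors = self._tree.query_ball_point(
                self.coords[i], ri + rmax + probe
            )
            neighbors = [j for j in neighbors if j != i]
            if neighbors:
                nc = self.coords[neighbors]
                nr = self.radii[neighbors] + probe
                d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
                accessible = np.all(d2 > (nr ** 2)[None, :], axis=1)
            else:
                accessible = np.ones(len(pts), bool)
            frac = accessible.mean()
            sasa[i] = 4.0 * np.pi * ri * ri * frac
            if accessible.any():
                surface_chunks.append(pts[accessible])
        self._sasa = sasa
        self._surface = (
            np.concatenate(surface_chunks) if surface_chunks else np.zeros((0, 3))
        )
        self._surface_tree = (
            cKDTree(self._surface) if len(self._surface) else None
        )

    @property
    def sasa(self) -> np.ndarray:
        if self._sasa is None:
            self._compute_sasa()
        return self._sasa

    @property
    def surface_points(self) -> np.ndarray:
        if self._surface is None:
            self._compute_sasa()
        return self._surface

    # -- descriptors ----------------------------------------------------

    def _residue_index(self, residue: Residue) -> int:
        for i, r in enumerate(self.residues):
            if r is residue or r.id == residue.id:
                return i
        raise KeyError(f"residue {residue.id} not in structure")

    def rsa(self, residue: Residue) -> tuple[float, float, bool]:
        """(relative sidechain accessibility %, absolute area A^2, partial)."""
        i = self._residue_index(residue)
        sc = residue.sidechain_atoms()
        sc_names = {a.name for a in sc}
        mask = np.array(
            [
                self.res_idx[k] == i and self.names[k] in sc_names
                for k in range(len(self.coords))
            ]
        )
        area = float(self.sasa[mask].sum())
        expected = set(SIDECHAIN_ATOMS.get(residue.one_letter, [])) or {"CA"}
        partial = not expected <= {a.name for a in residue.heavy_atoms()}
        ref = MAX_SIDECHAIN_AREA.get(residue.one_letter)
        if ref is None:
            return 100.0, area, True
        return min(100.0, 100.0 * area / ref), area, partial

    def osp(self, residue: Residue) -> float:
        """Ray-weighted occluded fraction of the residue's vdW surface.

        Occluders are heavy atoms of *other* residues that are not
        covalently bonded to the originating atom; a surface ray is
        occluded when it reaches a neighbouring vdW surface within the
        2.8 A water-diameter shell, contributing 1 - length/2.8.
        """
        i = self._residue_index(residue)
        cfg = self.config
        dots = unit_sphere_points(cfg.osp_dots)
        own = self.res_idx == i
        total_area = 0.0
        occluded_area = 0.0
        for k in np.nonzero(own)[0]:
            r = self.radii[k]
            c = self.coords[k]
            total_area += 4.0 * np.pi * r * r
            patch = 4.0 * np.pi * r * r / cfg.osp_dots
            cand = self._tree.query_ball_point(
                c, r + OCCLUSION_SHELL + self.radii.max()
            )
            cand = [
                j
                for j in cand
                if not own[j]
                and np.linalg.norm(self.coords[j] - c) > _BOND_CUTOFF
            ]
            if not cand:
                continue
            oc = self.coords[cand]
            orad = self.radii[cand]
            pts = c + r * dots  # (n,3)
            # ray p + t*u, u = dots; sphere |x - oc| = orad
            rel = pts[:, None, :] - oc[None, :, :]
            b = (rel * dots[:, None, :]).sum(axis=2)
            cterm = (rel ** 2).sum(axis=2) - (orad ** 2)[None, :]
            disc = b * b - cterm
            hit = disc >= 0
            sq = np.sqrt(np.where(hit, disc, 0.0))
            t1 = -b - sq
            t2 = -b + sq
            t = np.where(t1 >= 0, t1, np.where(t2 >= 0, t2, np.inf))
            t = np.where(hit, t, np.inf)
            tmin = t.min(axis=1)
            occ = tmin <= OCCLUSION_SHELL
            weights = np.where(occ, 1.0 - tmin / OCCLUSION_SHELL, 0.0)
            occluded_area += patch * weights.sum()
        if total_area == 0.0:
            return 0.0
        return float(min(1.0, occluded_area / total_area))

    def depth(self, residue: Residue) -> float:
        """Mean distance of the residue's heavy atoms to the SAS dot cloud."""
        i = self._residue_index(residue)
        if self._surface_tree is None:
            self._compute_sasa()
        if self._surface_tree is None:
            return 0.0
        mask = self.res_idx == i
        dists, _ = self._surface_tree.query(self.coords[mask])
        return float(np.mean(dists))

    # -- hydrogen bonding ------------------------------------------------

    def _antecedent(self, res: Residue, atom) -> np.ndarray | None:
        best, best_d = None, np.inf
        for other in res.heavy_atoms():
            if other.name == atom.name:
                continue
            d = float(np.linalg.norm(other.position - atom.position))
            if d < _BOND_CUTOFF and d < best_d:
                best, best_d = other.position, d
        return best

    def _hbond_geometry(self, donor_res, donor, acceptor_res, acceptor) -> bool:
        cfg = self.config
        d = float(np.linalg.norm(donor.position - acceptor.position))
        if d > cfg.hbond_distance or d < 2.0:
            return False
        ant = self._antecedent(acceptor_res, acceptor)
        if ant is None:
            return True
        return bond_angle(donor.position, acceptor.position, ant) >= cfg.hbond_angle

    def hbond_class(self, residue: Residue) -> int:
        """3-bit sidechain H-bond pattern (mainchain N / mainchain O / other)."""
        aa = residue.one_letter
        donors = [
            a for a in residue.heavy_atoms()
            if a.name in SIDECHAIN_DONORS.get(aa, ())
        ]
        acceptors = [
            a for a in residue.heavy_atoms()
            if a.name in SIDECHAIN_ACCEPTORS.get(aa, ())
        ]
        if not donors and not acceptors:
            return 0
        bits = 0
        for partner_res in self.residues:
            if partner_res.id == residue.id:
                continue
            paa = partner_res.one_letter
            for atom in partner_res.heavy_atoms():
                if atom.element not in ("N", "O", "S"):
                    continue
                is_mc_n = partner_res.is_standard and atom.name == "N"
                is_mc_o = partner_res.is_standard and atom.name in ("O", "OXT")
                is_sc = partner_res.is_standard and not (is_mc_n or is_mc_o)
                bonded = False
                if is_mc_n:
                    bonded = any(
                        self._hbond_geometry(partner_res, atom, residue, acc)
                        for acc in acceptors
                    )
                elif is_mc_o:
                    bonded = any(
                        self._hbond_geometry(residue, don, partner_res, atom)
                        for don in donors
                    )
                elif is_sc:
                    ok_d = atom.name in SIDECHAIN_DONORS.get(paa, ())
                    ok_a = atom.name in SIDECHAIN_ACCEPTORS.get(paa, ())
                    bonded = (
                        ok_d
                        and any(
                            self._hbond_geometry(partner_res, atom, residue, acc)
                            for acc in acceptors
                        )
                    ) or (
                        ok_a
                        and any(
                            self._hbond_geometry(residue, don, partner_res, atom)
                            for don in donors
                        )
                    )
                else:  # hetero group: unknown chemistry, allow both roles
                    bonded = any(
                        self._hbond_geometry(partner_res, atom, residue, acc)
                        for acc in acceptors
                    ) or any(
                        self._hbond_geometry(residue, don, partner_res, atom)
                        for don in donors
                    )
                if bonded:
                    if is_mc_n:
                        bits |= 1
                    elif is_mc_o:
                        bits |= 2
                    else:
                        bits |= 4
            if bits == 7:
                break
        return bits

    # -- mainchain conformation ------------------------------------------

    def _neighbour(self, residue: Residue, offset: int) -> Residue | None:
        idx = self._res_of_protein.get(residue.id)
        if idx is None:
            return None
        j = idx + offset
        if not 0 <= j < len(self.structure.residues):
            return None
        other = self.structure.residues[j]
        if other.chain_id != residue.chain_id:
            return None
        # require a real peptide bond between consecutive residues
        prev, nxt = (other, residue) if offset == -1 else (residue, other)
        c, n = prev.atom("C"), nxt.atom("N")
        if c is None or n is None:
            return None
        if np.linalg.norm(c.position - n.position) > 2.5:
            return None
        return other

    def mainchain_class(self, residue: Residue) -> int:
        prev = self._neighbour(residue, -1)
        nxt = self._neighbour(residue, +1)
        needed = [residue.atom(n) for n in ("N", "CA", "C")]
        if prev is None or nxt is None or any(a is None for a in needed):
            return 9
        pc = prev.atom("C")
        pca = prev.atom("CA")
        nn = nxt.atom("N")
        if pc is None or nn is None:
            return 9
        n, ca, c = (a.position for a in needed)
        phi = dihedral(pc.position, n, ca, c)
        psi = dihedral(n, ca, c, nn.position)
        if pca is not None:
            omega = dihedral(pca.position, pc.position, n, ca)
            if abs(omega) <= 30.0:
                return 8
        if -120 <= phi < -30 and -80 <= psi < -5:
            return 1
        if -120 <= phi < -30 and -5 <= psi < 40:
            return 2
        if -180 <= phi < -45 and (85 <= psi < 180 or psi < -170):
            return 3
        if -120 <= phi < -45 and 40 <= psi < 85:
            return 4
        if phi < 0:
            return 5
        if 5 <= phi < 120 and -45 <= psi < 75:
            return 6
        return 7

    # -- assembly ---------------------------------------------------------

    def annotate(self, residue: Residue) -> EnvironmentAnnotation:
        rsa, area, partial = self.rsa(residue)
        return EnvironmentAnnotation(
            chain_id=residue.chain_id,
            seq_number=residue.seq_number,
            insertion_code=residue.insertion_code,
            one_letter=residue.one_letter,
            mainchain_class=self.mainchain_class(residue),
            rsa=rsa,
            osp=self.osp(residue),
            depth=self.depth(residue),
            hbond_class=self.hbond_class(residue),
            sidechain_area=area,
            partial=partial,
            buried_rsa_cutoff=self.config.buried_rsa,
        )

    def annotate_all(self) -> list[EnvironmentAnnotation]:
        return [self.annotate(r) for r in self.structure.residues]


def _single(structure, residue_id, config, method):
    ann = Annotator(structure, config)
    res = structure.get_residue(*_normalize_id(residue_id))
    if res is None:
        raise KeyError(f"no residue {residue_id} in structure")
    return getattr(ann, method)(res)


def _normalize_id(residue_id) -> tuple[str, int, str]:
    if len(residue_id) == 2:
        return (residue_id[0], residue_id[1], "")
    return tuple(residue_id)


def compute_rsa(structure, residue_id, config: EnvironmentConfig | None = None) -> float:
    """Relative sidechain solvent accessibility in percent (capped at 100)."""
    return _single(structure, residue_id, config or EnvironmentConfig(), "rsa")[0]


def compute_osp(structure, residue_id, config: EnvironmentConfig | None = None) -> float:
    """Occluded surface packing in [0, 1]."""
    return _single(structure, residue_id, config or EnvironmentConfig(), "osp")


def compute_depth(structure, residue_id, config: EnvironmentConfig | None = None) -> float:
    """Residue depth below the solvent-accessible surface (A)."""
    return _single(structure, residue_id, config or EnvironmentConfig(), "depth")


def classify_hbonds(structure, residue_id, config: EnvironmentConfig | None = None) -> int:
    return _single(structure, residue_id, config or EnvironmentConfig(), "hbond_class")


def classify_mainchain(structure, residue_id, config: EnvironmentConfig | None = None) -> int:
    return _single(structure, residue_id, config or EnvironmentConfig(), "mainchain_class")


def annotate_structure(
    structure: ProteinStructure, config: EnvironmentConfig | None = None
) -> list[EnvironmentAnnotation]:
    return Annotator(structure, config).annotate_all()


def annotation_table(
    structure: ProteinStructure, config: EnvironmentConfig | None = None
):
    """Annotation dump as a pandas DataFrame, one row per residue."""
    import pandas as pd

    config = config or EnvironmentConfig()
    rows = []
    for ann in annotate_structure(structure, config):
        idx = classify_environment(ann, config)
        rows.append(
            {
                "chain": ann.chain_id,
                "resnum": ann.seq_number,
                "icode": ann.insertion_code,
                "aa": ann.one_letter,
                "mainchain_class": ann.mainchain_class,
                "mainchain_label": ann.mainchain_label,
                "rsa": round(ann.rsa, 2),
                "rsa_class": ann.rsa_class(config),
                "osp": round(ann.osp, 4),
                "osp_class": ann.osp_class(config),
                "depth": round(ann.depth, 3),
                "depth_class": ann.depth_class(config),
                "hbond_class": ann.hbond_class,
                "buried": ann.buried,
                "sidechain_area": round(ann.sidechain_area, 2),
                "env_index": idx.index,
                "env_label": idx.label,
            }
        )
    return pd.DataFrame(rows)
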