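"""Deterministic synthetic fixtures: structures, families, benchmarks.

Real stability benchmarks require curated thermodynamic databases and many
experimental structures; none are shipped.  Instead this module states a
small synthetic world and generates it from a single integer seed:

* ideal-geometry structures — a canonical alpha helix (phi=-57, psi=-47)
  and a dense seven-helix bundle whose central leucines are genuinely
  buried (RSA < 17%, OSP > 0.33);
* family alignments drawn from a *known* environment-dependent
  substitution process (strongly conserving in packed environments,
  permissive at the surface), so table estimation can be tested as a
  parameter-recovery problem;
* mutation benchmarks in which buried bulky-hydrophobic -> small
  substitutions are assigned ddG = -2.5 kcal/mol and conservative surface
  substitutions ddG = 0, mimicking the qualitative structure of
  experimental datasets.

The generated world is idealised: no conformational relaxation, no
measurement noise on ddG, uniform backbone geometry.  Green tests built
on it validate the machinery, not agreement with any experimental survey.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import AA_INDEX, AA_ORDER
from .environment import (
    Annotator,
    EnvironmentConfig,
    classify_environment,
    index_to_levels,
)
from .esst import FamilyAlignment, link_structure
from .geometry import rotation_about_axis
from .benchmark import BenchmarkRecord
from .sidechain import build_mutant_model, build_peptide
from .structure import ProteinStructure, parse_mutation

__all__ = [
    "FixtureSpec",
    "generate_fixture_structure",
    "default_true_process",
    "generate_fixture_families",
    "generate_benchmark",
    "generate_mutant_structures",
]

# the bundle layout: a central helix with buried leucines, ringed by six
# poly-leucine helices at 9 A; chosen once so the core is buried under the
# default descriptors
_BUNDLE_CENTER = "AALAALLAALA"
_BUNDLE_OUTER = "LLLLLLLLLLL"
_BUNDLE_RADIUS = 9.0
_BUNDLE_N_OUTER = 6

# conservative substitution partners used for neutral surface mutations
_CONSERVATIVE = {"L": "I", "I": "L", "A": "S", "V": "I", "S": "T", "T": "S"}


@dataclass
class FixtureSpec:
    """A fully seeded description of the synthetic world."""

    seed: int = 0
    n_residues: int = 12
    geometry: str = "helix"            # "helix" or "cluster"
    family_size: int = 100             # homologues per family
    conserve_p: float = 0.9            # P(j|j) in packed environments
    permissive_p: float = 0.4          # P(j|j) in exposed environments
    n_destabilising: int = 10
    n_neutral: int = 10
    ddg_destabilising: float = -2.5    # kcal/mol
    ddg_neutral: float = 0.0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def generate_fixture_structure(spec: FixtureSpec) -> ProteinStructure:
    """Ideal helix or dense helix-bundle cluster; byte-deterministic."""
    if spec.geometry == "helix":
        s = build_peptide("A" * spec.n_residues, structure_id="helix")
        return s
    if spec.geometry != "cluster":
        raise ValueError(f"unknown fixture geometry {spec.geometry!r}")

    center = build_peptide(_BUNDLE_CENTER, chain_id="A", structure_id="cluster")
    cas = np.array([r.atom("CA").position for r in center.residues])
    axis = cas[-1] - cas[0]
    axis /= np.linalg.norm(axis)
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    residues = list(center.residues)
    for k in range(_BUNDLE_N_OUTER):
        rot = rotation_about_axis(axis, 360.0 * k / _BUNDLE_N_OUTER)
        offset = _BUNDLE_RADIUS * (rot @ perp)
        chain = "BCDEFG"[k]
        h = build_peptide(_BUNDLE_OUTER, chain_id=chain, structure_id="arm")
        for r in h.residues:
            for a in r.atoms:
                a.position = a.position + offset
        residues.extend(h.residues)
    s = ProteinStructure("cluster", residues)
    s.metadata["core_residue"] = ("A", 6, "")  # central leucine
    return s


def default_true_process(
    config: EnvironmentConfig,
    conserve_p: float = 0.9,
    permissive_p: float = 0.4,
) -> np.ndarray:
    """The known substitution process P*(k | j, env) of the synthetic world.

    Environments whose packing-like factor (OSP, depth, RSA burial or the
    composite) indicates burial conserve strongly; exposed environments
    substitute freely.  Off-diagonal mass is spread uniformly.
    """
    factors = [name for name, _ in config.factors]
    tables = np.zeros((config.n_classes, 20, 20))
    for env in range(config.n_classes):
        levels = index_to_levels(env, config)
        by_name = dict(zip(factors, levels))
        if "osp" in by_name:
            packed = by_name["osp"] >= 1
        elif "depth" in by_name:
            packed = by_name["depth"] >= 1
        elif "packing" in by_name:
            packed = by_name["packing"] >= 1
        else:
            packed = by_name.get("rsa", 2) == 0  # rsa level 0 = buried
        diag = conserve_p if packed else permissive_p
        off = (1.0 - diag) / 19.0
        tables[env] = np.full((20, 20), off)
        np.fill_diagonal(tables[env], diag)
    return tables


def generate_fixture_families(
    spec: FixtureSpec,
    structure: ProteinStructure,
    config: EnvironmentConfig | None = None,
    true_process: np.ndarray | None = None,
    annotator: Annotator | None = None,
) -> tuple[FamilyAlignment, np.ndarray, dict[int, int]]:
    """Sample a gapless family alignment from the known process.

    Returns the alignment (structure member ``wt`` linked to
    ``structure``), the true process tables, and the per-environment
    observation counts implied by the family (columns x homologues).
    ``annotator`` lets repeated calls reuse the structure's geometry.
    """
    config = config or EnvironmentConfig()
    if true_process is None:
        true_process = default_true_process(
            config, spec.conserve_p, spec.permissive_p
        )
    rng = spec.rng()
    ann = annotator or Annotator(structure, config)
    residues = list(structure.residues)
    envs = [
        classify_environment(ann.annotate(r), config).index for r in residues
    ]
    wt_seq = "".join(r.one_letter for r in residues)

    # one vectorized draw per column
    drawn = np.empty((len(residues), spec.family_size), dtype=int)
    for i, (res, env) in enumerate(zip(residues, envs)):
        j = AA_INDEX[res.one_letter]
        drawn[i] = rng.choice(20, size=spec.family_size, p=true_process[env, j])
    homologs = {
        f"hom{h:04d}": "".join(AA_ORDER[drawn[i, h]] for i in range(len(residues)))
        for h in range(spec.family_size)
    }

    members = {"wt": wt_seq, **homologs}
    link = link_structure(members, "wt", structure)
    alignment = FamilyAlignment(members=members, structure_links=[link])
    obs_per_env: dict[int, int] = {}
    for env in envs:
        obs_per_env[env] = obs_per_env.get(env, 0) + spec.family_size
    return alignment, true_process, obs_per_env


def generate_benchmark(
    spec: FixtureSpec,
    structure: ProteinStructure,
    config: EnvironmentConfig | None = None,
    annotator: Annotator | None = None,
) -> list[BenchmarkRecord]:
    """Synthetic mutation benchmark on one structure.

    Buried F/L/I residues are mutated to Ala and Val with a strongly
    destabilising assigned ddG; exposed residues get conservative partner
    substitutions with ddG = 0.  Selection order is deterministic.
    """
    config = config or EnvironmentConfig()
    ann = annotator or Annotator(structure, config)
    records: list[BenchmarkRecord] = []
    n_destab = n_neutral = 0
    for res in structure.residues:
        if n_destab >= spec.n_destabilising and n_neutral >= spec.n_neutral:
            break
        a = ann.annotate(res)
        aa = res.one_letter
        mutation = None
        if aa in "FLI" and a.rsa < config.buried_rsa and n_destab < spec.n_destabilising:
            for mut_aa in ("A", "V"):
                if n_destab < spec.n_destabilising:
                    records.append(
                        BenchmarkRecord(
                            structure.id, res.chain_id,
                            f"{aa}{res.seq_number}{mut_aa}",
                            spec.ddg_destabilising,
                        )
                    )
                    n_destab += 1
            continue
        if (
            a.rsa >= config.rsa_bounds[1]
            and aa in _CONSERVATIVE
            and n_neutral < spec.n_neutral
        ):
            records.append(
                BenchmarkRecord(
                    structure.id, res.chain_id,
                    f"{aa}{res.seq_number}{_CONSERVATIVE[aa]}",
                    spec.ddg_neutral,
                )
            )
            n_neutral += 1
    return records


def generate_mutant_structures(
    structure: ProteinStructure, records: list[BenchmarkRecord]
) -> dict[str, ProteinStructure]:
    """Mutant models for each benchmark record, keyed for reverse scoring."""
    out: dict[str, ProteinStructure] = {}
    for rec in records:
        mut = parse_mutation(rec.mutation, rec.chain, structure)
        out[f"{rec.structure_ref}:{rec.mutation}"] = build_mutant_model(
            structure, mut
        )
    return out
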