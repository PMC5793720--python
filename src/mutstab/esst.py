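"""Environment-specific substitution tables (ESSTs).

An ESST set holds, for every discrete structural environment class, a 20x20
conditional probability table P(k | j, env): the probability that a residue
of type ``j`` observed in environment ``env`` in a protein structure is
found as type ``k`` at the equivalent position of a homologue.  Tables are
estimated from structure-annotated family alignments by counting
structure-residue -> homologue-residue pairs, weighting each observing
sequence by 1/(cluster size) after single-linkage clustering at 60%
identity, masking functional columns, and smoothing with an additive
pseudocount over a background distribution.  Sparse environment classes
fall back to the environment-marginal distribution, which also serves as
the "unfolded state" baseline table.
"""

from __future__ import annotations

import datetime as _dt
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import AA_INDEX, AA_ORDER
from .environment import (
    Annotator,
    EnvironmentConfig,
    classify_environment,
)
from .errors import AnnotationError, ConfigError, EsstFormatError
from .structure import ProteinStructure

__all__ = [
    "StructureLink",
    "FamilyAlignment",
    "SubstitutionCounts",
    "ESSTSet",
    "read_alignment",
    "link_structure",
    "annotate_alignment",
    "sequence_weights",
    "accumulate_counts",
    "normalize_tables",
    "build_essts",
    "write_esst",
    "read_esst",
]


@dataclass
class StructureLink:
    """Associates one alignment member with a structure.

    ``column_map`` maps alignment column index -> residue id
    (chain, seq_number, insertion_code) for non-gap columns.
    """

    member_id: str
    structure: ProteinStructure
    column_map: dict[int, tuple[str, int, str]]

    def __post_init__(self) -> None:
        ids = list(self.column_map.values())
        if len(set(ids)) != len(ids):
            raise AnnotationError(
                f"{self.member_id}: residue<->column map is not injective"
            )


@dataclass
class FamilyAlignment:
    """A gapped family alignment with >=1 structure-linked member."""

    members: dict[str, str]                       # member id -> aligned sequence
    structure_links: list[StructureLink] = field(default_factory=list)
    functional_mask: dict[str, set[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.members.values()}
        if len(lengths) > 1:
            raise AnnotationError("aligned sequences have unequal lengths")
        self.length = lengths.pop() if lengths else 0
        for cols in self.functional_mask.values():
            bad = [c for c in cols if not 0 <= c < self.length]
            if bad:
                raise AnnotationError(f"masked columns outside alignment: {bad}")


@dataclass
class SubstitutionCounts:
    counts: np.ndarray  # (n_classes, 20, 20)

    @classmethod
    def zeros(cls, n_classes: int) -> "SubstitutionCounts":
        return cls(np.zeros((n_classes, 20, 20)))

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class ESSTSet:
    """Per-environment P(k|j) tables plus the environment-marginal table."""

    tables: np.ndarray        # (n_classes, 20, 20); axis 1 = j, axis 2 = k
    unfolded: np.ndarray      # (20, 20)
    config: EnvironmentConfig
    pseudocount: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tables.shape != (self.config.n_classes, 20, 20):
            raise ConfigError(
                f"tables shape {self.tables.shape} does not match scheme "
                f"{self.config.scheme} ({self.config.n_classes} classes)"
            )
        rows = self.tables.sum(axis=2)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ConfigError("substitution tables are not row-stochastic in k")

    def p(self, env: int, j: str, k: str) -> float:
        return float(self.tables[env, AA_INDEX[j], AA_INDEX[k]])

    def p_unfolded(self, j: str, k: str) -> float:
        return float(self.unfolded[AA_INDEX[j], AA_INDEX[k]])

    @classmethod
    def uniform(cls, config: EnvironmentConfig) -> "ESSTSet":
        """Information-free tables: every P(k|j) = 1/20."""
        t = np.full((config.n_classes, 20, 20), 1.0 / 20)
        return cls(t, np.full((20, 20), 1.0 / 20), config, metadata={"kind": "uniform"})


# ---------------------------------------------------------------------------
# alignment input


def read_alignment(source: str | Path, fmt: str = "fasta") -> dict[str, str]:
    """Read an alignment (FASTA or PIR) into {member id: aligned sequence}."""
    from Bio import AlignIO

    src = Path(source)
    handle = open(src) if src.exists() else io.StringIO(str(source))
    try:
        aln = AlignIO.read(handle, "pir" if fmt.lower() == "pir" else "fasta")
    finally:
        handle.close()
    return {rec.id: str(rec.seq).upper() for rec in aln}


def link_structure(
    members: dict[str, str],
    member_id: str,
    structure: ProteinStructure,
    chain: str | None = None,
) -> StructureLink:
    """Map a member's non-gap columns onto consecutive chain residues,
    verifying that residue types agree with the aligned sequence.
    """
    if member_id not in members:
        raise AnnotationError(f"{member_id!r} not in alignment")
    seq = members[member_id]
    residues = structure.chain(chain) if chain else list(structure.residues)
    ungapped = [(c, aa) for c, aa in enumerate(seq) if aa not in "-."]
    if len(ungapped) != len(residues):
        raise AnnotationError(
            f"{member_id}: {len(ungapped)} aligned residues but structure "
            f"has {len(residues)}"
        )
    column_map = {}
    for (col, aa), res in zip(ungapped, residues):
        if aa != "X" and res.one_letter != aa:
            raise AnnotationError(
                f"{member_id} column {col}: alignment says {aa}, structure "
                f"residue {res.id} is {res.one_letter}"
            )
        column_map[col] = res.id
    return StructureLink(member_id, structure, column_map)


# ---------------------------------------------------------------------------
# counting


def annotate_alignment(
    alignment: FamilyAlignment, config: EnvironmentConfig
) -> dict[str, dict[int, int]]:
    """Environment-class index per (structure member, column).

    Columns where the structure member is gapped, or whose mapped residue
    has no standard type, are simply absent from the result.
    """
    out: dict[str, dict[int, int]] = {}
    for link in alignment.structure_links:
        ann = Annotator(link.structure, config)
        per_col: dict[int, int] = {}
        missing = []
        for col, rid in link.column_map.items():
            res = link.structure.get_residue(*rid)
            if res is None:
                missing.append(col)
                continue
            if res.one_letter not in AA_INDEX:
                continue
            per_col[col] = classify_environment(ann.annotate(res), config).index
        if missing:
            raise AnnotationError(
                f"{link.member_id}: columns map to residues missing from the "
                f"structure: {sorted(missing)}"
            )
        out[link.member_id] = per_col
    return out


def _pairwise_identity(a: str, b: str) -> float:
    same = shared = 0
    for x, y in zip(a, b):
        if x in "-." or y in "-.":
            continue
        shared += 1
        same += x == y
    return same / shared if shared else 0.0


def sequence_weights(members: dict[str, str], threshold: float = 0.6) -> dict[str, float]:
    """1/(cluster size) weights from single-linkage clustering at
    ``threshold`` sequence identity.
    """
    ids = list(members)
    n = len(ids)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _pairwise_identity(members[ids[i]], members[ids[j]]) >= threshold:
                parent[find(i)] = find(j)
    sizes: dict[int, int] = {}
    for i in range(n):
        sizes[find(i)] = sizes.get(find(i), 0) + 1
    return {ids[i]: 1.0 / sizes[find(i)] for i in range(n)}


def accumulate_counts(
    alignment: FamilyAlignment,
    annotations: dict[str, dict[int, int]],
    counts: SubstitutionCounts,
    weights: dict[str, float] | None = None,
) -> SubstitutionCounts:
    """Tally structure-residue -> homologue-residue substitutions.

    For every structure member, every annotated non-masked column and every
    *other* member with a standard residue in that column, the cell
    (env, j = structure residue, k = observed residue) gains the observing
    sequence's weight.  Gap columns and masked columns contribute nothing.
    """
    if weights is None:
        weights = sequence_weights(alignment.members)
    for link in alignment.structure_links:
        per_col = annotations.get(link.member_id, {})
        masked = alignment.functional_mask.get(link.member_id, set())
        seq = alignment.members[link.member_id]
        for col, env in per_col.items():
            if col in masked:
                continue
            j = seq[col]
            if j not in AA_INDEX:
                continue
            ji = AA_INDEX[j]
            for mid, mseq in alignment.members.items():
                if mid == link.member_id:
                    continue
                k = mseq[col]
                if k not in AA_INDEX:
                    continue
                counts.counts[env, ji, AA_INDEX[k]] += weights.get(mid, 1.0)
    return counts


def normalize_tables(
    counts: SubstitutionCounts,
    pseudocount: float = 1.0,
    config: EnvironmentConfig | None = None,
    background: np.ndarray | None = None,
    min_counts: float = 100.0,
    metadata: dict | None = None,
) -> ESSTSet:
    """Smooth raw tallies into probability tables.

    P(k|j,env) = (c[env,j,k] + pc * B[j,k]) / (sum_k c[env,j,k] + pc);
    (env, j) rows with fewer than ``min_counts`` observations fall back to
    the environment-marginal distribution for that j, which is also the
    "unfolded" baseline table.
    """
    if pseudocount <= 0:
        raise ConfigError("pseudocount must be positive")
    config = config or EnvironmentConfig()
    if counts.n_classes != config.n_classes:
        raise ConfigError(
            f"counts have {counts.n_classes} classes, scheme "
            f"{config.scheme} expects {config.n_classes}"
        )
    if background is None:
        background = np.full((20, 20), 1.0 / 20)
    c = counts.counts

    def _norm(mat: np.ndarray) -> np.ndarray:
        totals = mat.sum(axis=-1, keepdims=True)
        return (mat + pseudocount * background) / (totals + pseudocount)

    marginal_counts = c.sum(axis=0)
    unfolded = _norm(marginal_counts)
    tables = _norm(c)
    sparse = c.sum(axis=2) < min_counts  # (n_classes, 20)
    tables[sparse] = unfolded[np.nonzero(sparse)[1]]
    meta = {
        "pseudocount": pseudocount,
        "min_counts": min_counts,
        "total_counts": counts.total(),
        "date": _dt.date.today().isoformat(),
    }
    meta.update(metadata or {})
    return ESSTSet(tables, unfolded, config, pseudocount, meta)


def build_essts(
    alignments: list[FamilyAlignment],
    config: EnvironmentConfig | None = None,
    pseudocount: float = 1.0,
    min_counts: float = 100.0,
) -> ESSTSet:
    """Convenience pipeline: annotate, count and smooth a set of families."""
    config = config or EnvironmentConfig()
    counts = SubstitutionCounts.zeros(config.n_classes)
    for aln in alignments:
        for link in aln.structure_links:
            if link.structure.resolution is not None and link.structure.resolution > 2.5:
                import warnings

                warnings.warn(
                    f"{link.structure.id}: resolution "
                    f"{link.structure.resolution} A worse than 2.5 A"
                )
        annotations = annotate_alignment(aln, config)
        accumulate_counts(aln, annotations, counts)
    return normalize_tables(
        counts, pseudocount, config, min_counts=min_counts,
        metadata={"n_families": len(alignments)},
    )


# ---------------------------------------------------------------------------
# text format


def write_esst(essts: ESSTSet, destination: str | Path | io.TextIOBase) -> None:
    """Plain-text ESST dump; blocks are 20x20 with columns = wildtype j in
    the fixed order ARNDCQEGHILKMFPSTWYV (columns sum to 1).
    """
    own = not isinstance(destination, io.TextIOBase)
    handle = open(destination, "w") if own else destination
    try:
        handle.write("# environment-specific substitution tables\n")
        handle.write(f"scheme: {essts.config.scheme}\n")
        handle.write(f"n_classes: {essts.config.n_classes}\n")
        handle.write(f"pseudocount: {essts.pseudocount!r}\n")
        prov = essts.metadata.get("provenance", essts.metadata.get("kind", "unspecified"))
        handle.write(f"provenance: {prov}\n")
        header = "      " + " ".join(f"{aa:>14s}" for aa in AA_ORDER) + "\n"

        def block(name: str, table: np.ndarray) -> None:
            handle.write(f">{name}\n")
            handle.write(header)
            for ki, k in enumerate(AA_ORDER):
                cells = " ".join(f"{table[ji, ki]:14.12f}" for ji in range(20))
                handle.write(f"{k:>5s} {cells}\n")

        for env in range(essts.config.n_classes):
            block(f"class {env}", essts.tables[env])
        block("unfolded", essts.unfolded)
    finally:
        if own:
            handle.close()


def read_esst(source: str | Path | io.TextIOBase) -> ESSTSet:
    """Parse the text format written by :func:`write_esst`."""
    own = not isinstance(source, io.TextIOBase)
    handle = open(source) if own else source
    try:
        lines = handle.read().splitlines()
    finally:
        if own:
            handle.close()

    headers: dict[str, str] = {}
    i = 0
    while i < len(lines) and not lines[i].startswith(">"):
        line = lines[i].strip()
        i += 1
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition(":")
        headers[key.strip()] = val.strip()
    try:
        config = EnvironmentConfig(scheme=headers["scheme"])
        pseudocount = float(headers.get("pseudocount", "1.0"))
        n_cls = int(headers["n_classes"])
    except (KeyError, ValueError) as exc:
        raise EsstFormatError(f"bad or missing header: {exc}") from exc
    if n_cls != config.n_classes:
        raise EsstFormatError(
            f"header claims {n_cls} classes but scheme {config.scheme} "
            f"has {config.n_classes}"
        )

    blocks: dict[str, np.ndarray] = {}
    while i < len(lines):
        if not lines[i].startswith(">"):
            i += 1
            continue
        name = lines[i][1:].strip()
        i += 2  # skip the column-header line
        rows = []
        while i < len(lines) and not lines[i].startswith(">"):
            if lines[i].strip():
                rows.append(lines[i].split())
            i += 1
        if len(rows) != 20 or any(len(r) != 21 for r in rows):
            raise EsstFormatError(f"block {name!r}: expected a 20x20 table")
        got_order = "".join(r[0] for r in rows)
        if got_order != AA_ORDER:
            raise EsstFormatError(f"block {name!r}: wrong residue order {got_order}")
        mat = np.array([[float(x) for x in r[1:]] for r in rows])  # (k, j)
        table = mat.T  # (j, k)
        sums = table.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise EsstFormatError(
                f"block {name!r}: probabilities for some wildtype do not sum "
                f"to 1 (min {sums.min():.4f}, max {sums.max():.4f})"
            )
        blocks[name] = table

    if "unfolded" not in blocks:
        raise EsstFormatError("missing 'unfolded' block")
    tables = np.zeros((config.n_classes, 20, 20))
    for env in range(config.n_classes):
        key = f"class {env}"
        if key not in blocks:
            raise EsstFormatError(f"missing block for {key}")
        tables[env] = blocks[key]
    return ESSTSet(
        tables, blocks["unfolded"], config, pseudocount,
        {"provenance": headers.get("provenance", "")},
    )
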