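"""Shared fixtures.

Expensive objects (the dense helix-bundle structure, the synthetic family
world and its substitution tables, the benchmark predictions) are built
once per session and treated as read-only by tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from mutstab.environment import Annotator, EnvironmentConfig
from mutstab.esst import (
    ESSTSet,
    SubstitutionCounts,
    accumulate_counts,
    annotate_alignment,
    normalize_tables,
)
from mutstab.fixtures import (
    FixtureSpec,
    generate_benchmark,
    generate_fixture_families,
    generate_fixture_structure,
)
from mutstab.scoring import predict
from mutstab.sidechain import build_peptide
from mutstab.structure import Atom, ProteinStructure, Residue, parse_mutation
from mutstab.constants import vdw_radius

ALA_GLY_PDB = """\
ATOM      1  N   ALA A   1      -0.525   1.362   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       1.520   0.000   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       2.197   1.042   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1      -0.507  -0.785  -1.206  1.00  0.00           C
ATOM      6  N   GLY A   2       2.083  -1.208   0.000  1.00  0.00           N
ATOM      7  CA  GLY A   2       3.528  -1.378   0.000  1.00  0.00           C
ATOM      8  C   GLY A   2       4.169  -0.760   1.240  1.00  0.00           C
ATOM      9  O   GLY A   2       3.511  -0.641   2.279  1.00  0.00           O
TER
END
"""


@pytest.fixture(scope="session")
def ala_gly_pdb() -> str:
    return ALA_GLY_PDB


@pytest.fixture(scope="session")
def config() -> EnvironmentConfig:
    return EnvironmentConfig()


@pytest.fixture(scope="session")
def helix12():
    return build_peptide("A" * 12, structure_id="helix12")


@pytest.fixture(scope="session")
def cluster():
    return generate_fixture_structure(FixtureSpec(seed=1, geometry="cluster"))


@pytest.fixture(scope="session")
def cluster_annotator(cluster, config):
    return Annotator(cluster, config)


@pytest.fixture(scope="session")
def world(cluster, cluster_annotator, config):
    """The synthetic world: family, recovered tables, benchmark."""
    spec = FixtureSpec(seed=1, geometry="cluster")
    alignment, true_process, observations = generate_fixture_families(
        spec, cluster, config, annotator=cluster_annotator
    )
    annotations = annotate_alignment(alignment, config)
    counts = SubstitutionCounts.zeros(config.n_classes)
    accumulate_counts(
        alignment, annotations, counts, {m: 1.0 for m in alignment.members}
    )
    essts = normalize_tables(counts, pseudocount=1.0, config=config)
    benchmark = generate_benchmark(spec, cluster, config, annotator=cluster_annotator)
    return {
        "spec": spec,
        "alignment": alignment,
        "annotations": annotations,
        "true_process": true_process,
        "observations": observations,
        "counts": counts,
        "essts": essts,
        "benchmark": benchmark,
    }


@pytest.fixture(scope="session")
def predictions(world, cluster, cluster_annotator, config):
    """Forward predictions (default weights) for every benchmark record."""
    essts = world["essts"]
    out = []
    for rec in world["benchmark"]:
        mutation = parse_mutation(rec.mutation, rec.chain, cluster)
        out.append(
            predict(
                cluster, mutation, essts, config,
                wt_annotator=cluster_annotator, keep_model=False,
            )
        )
    return out


@pytest.fixture(scope="session")
def random_tables(config):
    """Deterministic random (non-uniform, smoothed) substitution tables."""
    rng = np.random.default_rng(7)
    t = rng.random((config.n_classes, 20, 20)) + 0.05
    t /= t.sum(axis=2, keepdims=True)
    u = rng.random((20, 20)) + 0.05
    u /= u.sum(axis=1, keepdims=True)
    return ESSTSet(t, u, config, metadata={"kind": "random"})


def make_residue(chain, num, res_type, atoms: dict[str, tuple]) -> Residue:
    """Hand-built residue for geometric toys."""
    alist = []
    for name, pos in atoms.items():
        el = name[0] if name[0] in "NOSC" else "C"
        alist.append(Atom(name, el, np.asarray(pos, float), vdw_radius(el)))
    return Residue(chain, num, "", res_type, alist)


def make_structure(*residues) -> ProteinStructure:
    return ProteinStructure("toy", list(residues))
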