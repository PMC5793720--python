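"""Structural environment descriptors: RSA, OSP, depth, H-bonds, classes.

The occluded-surface implementation is checked against a brute-force
ray--sphere oracle written independently of the vectorized code path.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mutstab.environment import (
    Annotator,
    EnvironmentConfig,
    classify_environment,
    compute_depth,
    compute_osp,
    compute_rsa,
    index_to_levels,
    levels_to_index,
)
from mutstab.errors import ConfigError
from mutstab.geometry import unit_sphere_points
from mutstab.sidechain import build_peptide

from conftest import make_residue, make_structure


# ---------------------------------------------------------------------------
# independent OSP oracle: plain loops, explicit quadratic per dot and sphere

def osp_oracle(structure, residue_id, n_dots=960, shell=2.8, bond_cutoff=2.1):
    atoms = []
    target = None
    for res in structure.residues:
        heavy = [a for a in res.atoms if a.element != "H"]
        if res.id[:2] == residue_id[:2] or res.id == residue_id:
            if res.id[0] == residue_id[0] and res.id[1] == residue_id[1]:
                target = heavy
        atoms.append((res.id, heavy))
    assert target is not None
    others = [
        a for rid, heavy in atoms for a in heavy
        if not (rid[0] == residue_id[0] and rid[1] == residue_id[1])
    ]
    dots = unit_sphere_points(n_dots)
    total_area = 0.0
    occluded = 0.0
    for atom in target:
        r = atom.vdw_radius
        total_area += 4 * math.pi * r * r
        patch = 4 * math.pi * r * r / n_dots
        occluders = [
            o for o in others
            if np.linalg.norm(o.position - atom.position) > bond_cutoff
        ]
        for u in dots:
            p = atom.position + r * u
            best = math.inf
            for o in occluders:
                rel = p - o.position
                b = float(np.dot(rel, u))
                cterm = float(np.dot(rel, rel)) - o.vdw_radius ** 2
                disc = b * b - cterm
                if disc < 0:
                    continue
                sq = math.sqrt(disc)
                for t in (-b - sq, -b + sq):
                    if t >= 0:
                        best = min(best, t)
                        break
            if best <= shell:
                occluded += patch * (1.0 - best / shell)
    return occluded / total_area if total_area else 0.0


class TestOSP:
    def test_single_isolated_atom_zero(self):
        s = make_structure(make_residue("A", 1, "GLY", {"C": (0, 0, 0)}))
        assert compute_osp(s, ("A", 1)) == 0.0

    def test_isolated_residue_zero(self):
        leu = build_peptide("L", structure_id="leu")
        assert compute_osp(leu, ("A", 1)) == 0.0

    def test_contact_pair_symmetric_and_positive(self):
        s = make_structure(
            make_residue("A", 1, "GLY", {"C": (0, 0, 0)}),
            make_residue("A", 2, "GLY", {"C": (3.4, 0, 0)}),
        )
        o1 = compute_osp(s, ("A", 1))
        o2 = compute_osp(s, ("A", 2))
        assert o1 > 0 and o2 > 0
        assert o1 == pytest.approx(o2, rel=0.05)  # dot-lattice asymmetry only

    @pytest.mark.parametrize("coords", [
        # collinear 3-atom toy
        [("A", {"C": (0, 0, 0)}), ("B", {"C": (3.4, 0, 0)}), ("C", {"C": (6.8, 0, 0)})],
        # bent 4-atom toy with mixed elements
        [("A", {"C": (0, 0, 0), "O": (1.8, 0.5, 0)}),
         ("B", {"N": (3.0, 1.0, 0.5)}), ("C", {"S": (0.5, 3.0, 0.2)})],
        # 5-atom clump
        [("A", {"C": (0, 0, 0), "C2": (1.6, 0, 0)}),
         ("B", {"O": (0.4, 2.9, 0), "N": (2.2, 2.5, 1.0), "C": (-1.5, 1.5, -1.0)})],
    ])
    def test_matches_brute_force_oracle(self, coords):
        residues = [
            make_residue(ch, i + 1, "GLY", atoms)
            for i, (ch, atoms) in enumerate(coords)
        ]
        s = make_structure(*residues)
        for i, (ch, _) in enumerate(coords):
            mine = compute_osp(s, (ch, i + 1))
            ref = osp_oracle(s, (ch, i + 1))
            assert mine == pytest.approx(ref, abs=1e-6)

    def test_bounded_on_cluster(self, cluster, cluster_annotator):
        for res in cluster.residues[::7]:
            osp = cluster_annotator.osp(res)
            assert 0.0 <= osp <= 1.0


class TestRSA:
    def test_isolated_residue_capped_at_100(self):
        leu = build_peptide("L", structure_id="leu")
        assert compute_rsa(leu, ("A", 1)) == 100.0

    def test_core_residue_buried(self, cluster, cluster_annotator):
        core = cluster.get_residue(*cluster.metadata["core_residue"])
        rsa, _, _ = cluster_annotator.rsa(core)
        assert rsa < 17.0
        assert cluster_annotator.annotate(core).buried

    def test_dot_density_convergence(self, cluster):
        cfg2 = EnvironmentConfig(n_dots=1920)
        core_id = cluster.metadata["core_residue"]
        surf_id = ("C", 1, "")
        for rid in (core_id, surf_id):
            r1 = compute_rsa(cluster, rid)
            r2 = compute_rsa(cluster, rid, cfg2)
            assert abs(r1 - r2) < 2.0

    def test_anticorrelated_with_osp(self, cluster, cluster_annotator):
        from scipy.stats import spearmanr

        rsas, osps = [], []
        for res in cluster.residues:
            rsa, _, _ = cluster_annotator.rsa(res)
            rsas.append(rsa)
            osps.append(cluster_annotator.osp(res))
        rho = spearmanr(rsas, osps).statistic
        assert rho < 0


class TestDepth:
    def test_single_oxygen_closed_form(self):
        s = make_structure(make_residue("A", 1, "GLY", {"O": (0, 0, 0)}))
        # nearest accessible-surface point sits at r_vdW + probe from center
        assert compute_depth(s, ("A", 1)) == pytest.approx(1.52 + 1.4, abs=0.02)

    def test_core_deeper_than_surface(self, cluster, cluster_annotator, helix12):
        core = cluster.get_residue(*cluster.metadata["core_residue"])
        core_depth = cluster_annotator.depth(core)
        helix_ann = Annotator(helix12)
        surface_depth = helix_ann.depth(helix12.residues[5])
        assert surface_depth < core_depth

    def test_dot_density_convergence(self, cluster):
        core_id = cluster.metadata["core_residue"]
        d1 = compute_depth(cluster, core_id)
        d2 = compute_depth(cluster, core_id, EnvironmentConfig(n_dots=1920))
        assert abs(d1 - d2) < 0.1


class TestHbonds:
    def test_isolated_ala_class_zero(self):
        ala = build_peptide("A", structure_id="ala")
        ann = Annotator(ala)
        assert ann.hbond_class(ala.residues[0]) == 0

    def test_ser_to_mainchain_o_class_2(self):
        # SER OG placed 2.9 A from a mainchain O, donor-acceptor-antecedent
        # angle wide open
        gly = make_residue(
            "A", 1, "GLY",
            {"N": (0, 0, 0), "CA": (1.46, 0, 0), "C": (2.0, 1.3, 0), "O": (1.5, 2.4, 0)},
        )
        og = np.array([1.5, 2.4, 0]) + 2.9 * np.array([-0.414, 0.910, 0.0])
        ser = make_residue(
            "A", 5, "SER",
            {"N": (6, 6, 3), "CA": (7.4, 6, 3), "C": (8, 7.3, 3), "O": (7.4, 8.4, 3),
             "CB": tuple(og + np.array([0.0, 1.43, 0.0])), "OG": tuple(og)},
        )
        s = make_structure(gly, ser)
        ann = Annotator(s)
        assert ann.hbond_class(ser) == 2

    def test_asn_triple_class_7(self):
        asn = make_residue(
            "A", 1, "ASN",
            {"N": (0, 0, 0), "CA": (1.46, 0, 0), "C": (2.0, 1.3, 0), "O": (1.5, 2.4, 0),
             "CB": (2.0, -1.0, 1.0), "CG": (3.3, -1.4, 1.4),
             "OD1": (4.5, -1.4, 1.4), "ND2": (2.7, -2.6, 1.4)},
        )
        gly_n = make_residue(
            "A", 5, "GLY",
            {"N": (7.5, -1.4, 1.4), "CA": (8.9, -1.4, 1.4),
             "C": (9.4, -0.1, 1.4), "O": (8.9, 1.0, 1.4)},
        )
        gly_o = make_residue(
            "A", 10, "GLY",
            {"N": (0.9, -7.8, 1.4), "CA": (1.6, -7.0, 1.4),
             "C": (2.7, -6.83, 1.4), "O": (2.7, -5.6, 1.4)},
        )
        thr = make_residue(
            "A", 20, "THR",
            {"N": (8.0, 3.0, 1.4), "CA": (7.5, 2.2, 1.4), "C": (8.5, 1.8, 1.4),
             "O": (9.6, 2.3, 1.4), "CB": (6.5, 2.6, 1.4), "OG1": (5.5, 1.4, 1.4),
             "CG2": (6.9, 3.6, 2.4)},
        )
        s = make_structure(asn, gly_n, gly_o, thr)
        ann = Annotator(s)
        assert ann.hbond_class(asn) == 7


class TestMainchain:
    def test_helix_interior_class_1(self, helix12):
        ann = Annotator(helix12)
        for res in helix12.residues[1:-1]:
            assert ann.mainchain_class(res) == 1

    def test_strand_class_3(self):
        strand = build_peptide("A" * 6, phi=-120.0, psi=130.0, structure_id="strand")
        ann = Annotator(strand)
        for res in strand.residues[1:-1]:
            assert ann.mainchain_class(res) == 3

    def test_polyproline_class_4(self):
        ppii = build_peptide("A" * 6, phi=-75.0, psi=65.0, structure_id="ppii")
        ann = Annotator(ppii)
        assert ann.mainchain_class(ppii.residues[3]) == 4

    def test_left_handed_class_6(self):
        left = build_peptide("G" * 6, phi=60.0, psi=45.0, structure_id="left")
        ann = Annotator(left)
        assert ann.mainchain_class(left.residues[3]) == 6

    def test_termini_class_9(self, helix12):
        ann = Annotator(helix12)
        assert ann.mainchain_class(helix12.residues[0]) == 9
        assert ann.mainchain_class(helix12.residues[-1]) == 9


class TestEnvironmentClasses:
    @pytest.mark.parametrize("scheme,total", [
        ("216_OSP", 216), ("216_depth", 216), ("54_RSA", 54),
        ("648_RSA_OSP_depth", 648),
    ])
    def test_enumeration_and_bijection(self, scheme, total):
        cfg = EnvironmentConfig(scheme=scheme)
        assert cfg.n_classes == total
        seen = set()
        import itertools

        for levels in itertools.product(*(range(n) for _, n in cfg.factors)):
            idx = levels_to_index(levels, cfg)
            assert index_to_levels(idx.index, cfg) == levels
            seen.add(idx.index)
        assert seen == set(range(total))

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ConfigError):
            EnvironmentConfig(scheme="999_bogus")

    def test_annotation_maps_to_class(self, cluster, cluster_annotator, config):
        core = cluster.get_residue(*cluster.metadata["core_residue"])
        ann = cluster_annotator.annotate(core)
        idx = classify_environment(ann, config)
        assert 0 <= idx.index < 216

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        mc=st.integers(0, 8), pack=st.integers(0, 2), hb=st.integers(0, 7),
        scheme=st.sampled_from(["216_OSP", "216_depth"]),
    )
    def test_index_round_trip_property(self, mc, pack, hb, scheme):
        cfg = EnvironmentConfig(scheme=scheme)
        idx = levels_to_index((mc, pack, hb), cfg)
        assert index_to_levels(idx.index, cfg) == (mc, pack, hb)


class TestRigidMotionInvariance:
    def _transformed(self, structure, rot, shift):
        moved = structure.copy()
        for res in moved:
            for a in res.atoms:
                a.position = rot @ a.position + shift
        return moved

    def test_translation_exact(self, helix12):
        moved = self._transformed(helix12, np.eye(3), np.array([11.0, -7.0, 3.0]))
        a0 = Annotator(helix12)
        a1 = Annotator(moved)
        for r0, r1 in zip(helix12.residues[4:7], moved.residues[4:7]):
            assert a0.rsa(r0)[0] == pytest.approx(a1.rsa(r1)[0], abs=1e-9)
            assert a0.osp(r0) == pytest.approx(a1.osp(r1), abs=1e-9)
            assert a0.depth(r0) == pytest.approx(a1.depth(r1), abs=1e-9)
            assert a0.mainchain_class(r0) == a1.mainchain_class(r1)

    def test_rotation_within_dot_tolerance(self, helix12):
        rng = np.random.default_rng(3)
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = self._transformed(helix12, q, np.array([2.0, 0.5, -4.0]))
        a0 = Annotator(helix12)
        a1 = Annotator(moved)
        for r0, r1 in zip(helix12.residues[4:7], moved.residues[4:7]):
            assert a0.rsa(r0)[0] == pytest.approx(a1.rsa(r1)[0], abs=2.0)
            assert a0.osp(r0) == pytest.approx(a1.osp(r1), abs=0.02)
            assert a0.depth(r0) == pytest.approx(a1.depth(r1), abs=0.15)
            assert a0.mainchain_class(r0) == a1.mainchain_class(r1)
            assert a0.hbond_class(r0) == a1.hbond_class(r1)
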