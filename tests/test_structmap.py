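"""Structure-side measurements against brute-force geometric oracles."""

from __future__ import annotations

import numpy as np
import pytest

from lohfunnel.structmap import (
    Atom,
    Chain,
    ChainMappingError,
    ProximityResult,
    Residue,
    StructureChainSet,
    align_sequence_to_chain,
    classify_candidate_site,
    evaluate_variant_on_structures,
    min_distance_to_sites,
    relative_accessibility,
    shrake_rupley,
)
from lohfunnel.synthetic_data import _helix_coords, _shell_atoms

AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}

SEQ20 = "MKTAYIALLV DFEGHRWQNC".replace(" ", "")


def chain_for(seq: str, start_index: int = 0) -> Chain:
    residues = _helix_coords(seq)
    renamed = [
        Residue(name=AA3[aa], label=str(start_index + i + 1), atoms=res.atoms)
        for i, (aa, res) in enumerate(zip(seq, residues))
    ]
    return Chain(chain_id="A", residues=tuple(renamed))


class TestAlignment:
    def test_identical_sequence_identity_mapping(self):
        chain = chain_for(SEQ20)
        rmap = align_sequence_to_chain(SEQ20, chain)
        assert rmap.coverage == 1.0
        assert rmap.identity == 1.0
        for i in range(1, len(SEQ20) + 1):
            assert rmap.index_map[i] is chain.residues[i - 1]

    def test_disordered_n_terminus_offsets_map(self):
        chain = chain_for(SEQ20[3:])
        rmap = align_sequence_to_chain(SEQ20, chain)
        assert rmap.coverage == pytest.approx(17 / 20)
        assert 1 not in rmap.index_map and 4 in rmap.index_map
        assert rmap.index_map[4] is chain.residues[0]

    def test_internal_gap_excluded_from_map(self):
        # residues 8 and 9 unresolved in the crystal
        gapped = SEQ20[:7] + SEQ20[9:]
        chain = chain_for(gapped)
        rmap = align_sequence_to_chain(SEQ20, chain)
        missing = {i for i in range(1, 21) if i not in rmap.index_map}
        assert missing == {8, 9}
        # order-preserving, one-to-one
        labels = [rmap.index_map[i].label for i in sorted(rmap.index_map)]
        assert labels == sorted(labels, key=int)

    def test_low_identity_rejected(self):
        chain = chain_for("W" * 20)
        with pytest.raises(ChainMappingError, match="identity"):
            align_sequence_to_chain(SEQ20, chain)


def single_atom_residue(name, xyz, atom_name="CB"):
    return Residue(name=name, label="1", atoms=(Atom(atom_name, "C", np.array(xyz)),))


class TestMinDistance:
    def test_three_four_five_triangle(self):
        a = single_atom_residue("ALA", (0.0, 0.0, 0.0))
        b = single_atom_residue("ALA", (3.0, 4.0, 0.0))
        dist, nearest = min_distance_to_sites(a, [b], "all_heavy")
        assert dist == pytest.approx(5.0)
        assert nearest == 0

    def test_residue_against_itself_is_zero(self):
        a = single_atom_residue("ALA", (1.0, 2.0, 3.0))
        dist, _ = min_distance_to_sites(a, [a], "all_heavy")
        assert dist == 0.0

    def test_empty_site_list_raises(self):
        a = single_atom_residue("ALA", (0.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            min_distance_to_sites(a, [], "all_heavy")

    def test_helix_matches_brute_force_all_pairs(self):
        chain = chain_for(SEQ20[:5])
        variant = chain.residues[0]
        sites = [chain.residues[3], chain.residues[4]]
        for atom_set in ("all_heavy", "side_chain_heavy"):
            dist, _ = min_distance_to_sites(variant, sites, atom_set)
            pairs = [
                np.linalg.norm(a.coord - b.coord)
                for a in variant.atoms_for(atom_set)
                for site in sites
                for b in site.atoms_for(atom_set)
            ]
            assert dist == pytest.approx(min(pairs), abs=1e-12)

    def test_glycine_falls_back_to_ca(self):
        atoms = (
            Atom("N", "N", np.array([0.0, 0.0, 0.0])),
            Atom("CA", "C", np.array([1.5, 0.0, 0.0])),
            Atom("C", "C", np.array([3.0, 0.0, 0.0])),
        )
        gly = Residue(name="GLY", label="1", atoms=atoms)
        selected = gly.atoms_for("side_chain_heavy")
        assert [a.name for a in selected] == ["CA"]


class TestAccessibility:
    def test_isolated_residue_fully_exposed(self):
        chain = chain_for("A")
        rsa = relative_accessibility(chain, chain.residues[0])
        assert rsa >= 0.95

    def test_shell_enclosed_residue_buried(self):
        chain = chain_for("A")
        residue = chain.residues[0]
        center = np.mean([a.coord for a in residue.atoms], axis=0)
        shell = [
            Atom("C", "C", c)
            for radius, n in ((6.0, 200), (8.5, 400))
            for c in _shell_atoms(center, radius, n)
        ]
        rsa = relative_accessibility(chain, residue, environment=list(chain.atoms()) + shell)
        assert rsa < 0.05

    def test_point_count_convergence(self):
        chain = chain_for(SEQ20[:6])
        residue = chain.residues[2]
        rsa_960 = relative_accessibility(chain, residue, n_points=960)
        rsa_1920 = relative_accessibility(chain, residue, n_points=1920)
        assert abs(rsa_960 - rsa_1920) < 0.02

    def test_context_never_increases_exposure(self):
        chain = chain_for(SEQ20[:8])
        for residue in chain.residues:
            in_chain = relative_accessibility(chain, residue)
            alone = relative_accessibility(
                Chain(chain_id="A", residues=(residue,)), residue
            )
            assert in_chain <= alone + 1e-9

    def test_matches_independent_shrake_rupley(self):
        """Cross-check per-residue ASA against biotite's implementation with
        the same single-atom radii and probe."""
        import biotite.structure as struc

        chain = chain_for(SEQ20[:10])
        atoms = chain.atoms()
        n = len(atoms)
        array = struc.AtomArray(n)
        array.coord = np.array([a.coord for a in atoms])
        res_ids, res_names, names, elements = [], [], [], []
        for i, residue in enumerate(chain.residues):
            for atom in residue.atoms:
                res_ids.append(i + 1)
                res_names.append(residue.name)
                names.append(atom.name)
                elements.append(atom.element)
        array.res_id = np.array(res_ids)
        array.res_name = np.array(res_names)
        array.atom_name = np.array(names)
        array.element = np.array(elements)
        array.chain_id = np.array(["A"] * n)
        theirs = struc.sasa(array, probe_radius=1.4, point_number=1000, vdw_radii="Single")
        coords = np.array([a.coord for a in atoms])
        radii = np.array([a.radius for a in atoms])
        ours = shrake_rupley(coords, radii, probe=1.4, n_points=1000)
        per_res_ours = [ours[array.res_id == i].sum() for i in range(1, 11)]
        per_res_theirs = [theirs[array.res_id == i].sum() for i in range(1, 11)]
        np.testing.assert_allclose(per_res_ours, per_res_theirs, rtol=0.05, atol=2.0)


class TestClassification:
    @pytest.mark.parametrize(
        "d,rsa,expected",
        [(4.2, 0.5, True), (14.0, 0.5, False), (4.2, 0.05, False)],
    )
    def test_threshold_verdicts(self, d, rsa, expected):
        result = ProximityResult(
            residue_index=1, structure_id="s", chain_id="A",
            min_site_distance=d, nearest_site_residue=5, rsa=rsa,
        )
        assert classify_candidate_site(result).selected is expected


def random_rigid_transform(rng):
    # QR of a random matrix gives a uniform-ish rotation; fix determinant +1
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.normal(scale=20.0, size=3)
    return q, t


def transform_chain(chain: Chain, q: np.ndarray, t: np.ndarray) -> Chain:
    return Chain(
        chain_id=chain.chain_id,
        residues=tuple(
            Residue(
                name=r.name,
                label=r.label,
                atoms=tuple(
                    Atom(a.name, a.element, q @ a.coord + t) for a in r.atoms
                ),
            )
            for r in chain.residues
        ),
    )


class TestRigidInvariance:
    def test_distance_and_rsa_invariant(self):
        rng = np.random.default_rng(42)
        chain = chain_for(SEQ20[:8])
        variant, sites = chain.residues[1], [chain.residues[5], chain.residues[6]]
        d0, _ = min_distance_to_sites(variant, sites, "side_chain_heavy")
        rsa0 = relative_accessibility(chain, variant)
        for _ in range(3):
            q, t = random_rigid_transform(rng)
            moved = transform_chain(chain, q, t)
            d1, _ = min_distance_to_sites(
                moved.residues[1], [moved.residues[5], moved.residues[6]], "side_chain_heavy"
            )
            assert abs(d1 - d0) < 1e-6
            # sphere sampling is not rotation-invariant point-by-point, but the
            # estimate must be stable well inside the classification margin
            rsa1 = relative_accessibility(moved, moved.residues[1])
            assert abs(rsa1 - rsa0) < 0.02


class TestEvaluateVariant:
    def test_minimum_over_structures_kept(self):
        seq = SEQ20
        chain = chain_for(seq)
        structure = StructureChainSet("s1", (chain,))
        result = evaluate_variant_on_structures(
            "P", seq, residue_index=8, site_indices=[5], structures=[structure]
        )
        brute, _ = min_distance_to_sites(
            chain.residues[7], [chain.residues[4]], "side_chain_heavy"
        )
        assert result.min_site_distance == pytest.approx(brute)
        assert result.nearest_site_residue == 5
        assert result.selected

    def test_no_mappable_chain_returns_none(self):
        chain = chain_for("W" * 20)
        structure = StructureChainSet("s1", (chain,))
        assert (
            evaluate_variant_on_structures("P", SEQ20, 8, [5], [structure]) is None
        )
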