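"""Mapping variant residues onto crystal-structure chains and scoring them.

A candidate amino-acid substitution is interesting for allele-selective
inhibition when it sits on the protein surface close to the residues that do
the chemistry (catalytic, substrate-binding or cofactor-binding sites).  This
module provides the three measurements behind that judgement:

* sequence-to-chain residue mapping by global alignment (crystal structures
  routinely miss disordered termini and loops, so author numbering cannot be
  trusted);
* minimum inter-atomic distance from the variant residue to any annotated
  functional-site residue;
* relative solvent accessibility (RSA) by Shrake-Rupley sphere sampling,
  normalised with theoretical Gly-X-Gly maximum areas.

Thresholds (``d_max``, ``rsa_min``) turn the measurements into a selected /
rejected verdict; both are configuration, not constants of nature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import Align
from Bio.SeqUtils import seq1
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureChainSet",
    "ResidueMap",
    "ProximityResult",
    "ChainMappingError",
    "align_sequence_to_chain",
    "min_distance_to_sites",
    "shrake_rupley",
    "relative_accessibility",
    "classify_candidate_site",
    "evaluate_variant_on_structures",
]

#: heavy-atom van der Waals radii (Bondi), Angstrom; fallback 1.70
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

_MAX_ASA: dict[str, float] | None = None


def _max_asa_table() -> dict[str, float]:
    """Theoretical Gly-X-Gly maximum accessible surface areas (Tien et al.
    2013, PLoS ONE 8:e80635), used to normalise residue ASA into RSA."""
    global _MAX_ASA
    if _MAX_ASA is None:
        table = {}
        text = resources.files("lohfunnel.data").joinpath("max_asa.tsv").read_text()
        for line in text.splitlines():
            if not line or line.startswith("#"):
                continue
            name, value = line.split("\t")
            table[name] = float(value)
        _MAX_ASA = table
    return _MAX_ASA


class ChainMappingError(ValueError):
    """Raised when a protein sequence cannot be mapped onto a chain."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0

    def __post_init__(self):
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError(f"atom {self.name}: coordinates must be 3 finite numbers")
        object.__setattr__(self, "coord", coord)

    @property
    def radius(self) -> float:
        return VDW_RADII.get(self.element.upper(), 1.70)

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass(frozen=True)
class Residue:
    """One residue of a chain: 3-letter name, author numbering (insertion
    codes appended as opaque labels) and its atoms."""

    name: str
    label: str  # author residue number, possibly with insertion code
    atoms: tuple[Atom, ...]

    def __post_init__(self):
        if not self.atoms:
            raise ValueError(f"residue {self.name} {self.label} has no atoms")

    @property
    def one_letter(self) -> str:
        code = seq1(self.name.capitalize())
        return code if code else "X"

    def heavy_atoms(self) -> tuple[Atom, ...]:
        return tuple(a for a in self.atoms if a.is_heavy)

    def atoms_for(self, atom_set: str) -> tuple[Atom, ...]:
        """Atom selection for distance work.

        ``side_chain_heavy`` falls back to CA (then all heavy atoms) when a
        residue has no side chain, e.g. glycine.
        """
        heavy = self.heavy_atoms()
        if atom_set == "all_heavy":
            return heavy
        if atom_set == "side_chain_heavy":
            side = tuple(a for a in heavy if a.name not in BACKBONE_ATOMS)
            if side:
                return side
            ca = tuple(a for a in heavy if a.name == "CA")
            return ca if ca else heavy
        raise ValueError(f"unknown atom_set {atom_set!r}")


@dataclass(frozen=True)
class Chain:
    chain_id: str
    residues: tuple[Residue, ...]

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]


@dataclass(frozen=True)
class StructureChainSet:
    """Protein chains of one structure; non-water HETATM groups (cofactors,
    ligands) are kept apart from the polymer chains."""

    structure_id: str
    chains: tuple[Chain, ...]
    ligands: tuple[Residue, ...] = ()

    def get_chain(self, chain_id: str) -> Chain:
        for chain in self.chains:
            if chain.chain_id == chain_id:
                return chain
        raise KeyError(f"no chain {chain_id!r} in structure {self.structure_id}")

    def all_atoms(self) -> list[Atom]:
        atoms = [a for c in self.chains for a in c.atoms()]
        atoms.extend(a for r in self.ligands for a in r.atoms)
        return atoms


@dataclass(frozen=True)
class ResidueMap:
    """Alignment-derived bridge between 1-based sequence residue indices and
    structure residues of one chain."""

    protein_accession: str
    structure_id: str
    chain_id: str
    index_map: Mapping[int, Residue]
    coverage: float
    identity: float


@dataclass
class ProximityResult:
    residue_index: int
    structure_id: str
    chain_id: str
    min_site_distance: float  # Angstrom
    nearest_site_residue: int  # sequence index of the closest site
    rsa: float
    near_active_site: bool = False
    surface_exposed: bool = False

    @property
    def selected(self) -> bool:
        return self.near_active_site and self.surface_exposed


def align_sequence_to_chain(
    protein_seq: str,
    chain: Chain,
    *,
    protein_accession: str = "",
    structure_id: str = "",
    min_identity: float = 0.9,
) -> ResidueMap:
    """Globally align a protein sequence to a chain's observed residues.

    Scoring: match +1, mismatch -1, gap open -5, gap extend -0.5.  Unaligned
    and gapped positions are absent from the map.  A mapping with identity
    below ``min_identity`` over the aligned columns is rejected -- it almost
    always means the wrong chain or the wrong structure.
    """
    if not chain.residues:
        raise ChainMappingError("chain has no residues")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    chain_seq = chain.sequence
    alignment = aligner.align(protein_seq, chain_seq)[0]
    index_map: dict[int, Residue] = {}
    n_aligned = 0
    n_identical = 0
    for (qs, qe), (ts, te) in zip(*alignment.aligned):
        for offset in range(qe - qs):
            qi, ti = qs + offset, ts + offset
            index_map[qi + 1] = chain.residues[ti]
            n_aligned += 1
            if protein_seq[qi] == chain_seq[ti]:
                n_identical += 1
    if n_aligned == 0:
        raise ChainMappingError("no aligned positions")
    identity = n_identical / n_aligned
    if identity < min_identity:
        raise ChainMappingError(
            f"identity {identity:.2f} below {min_identity}; wrong chain?"
        )
    return ResidueMap(
        protein_accession=protein_accession,
        structure_id=structure_id,
        chain_id=chain.chain_id,
        index_map=index_map,
        coverage=n_aligned / len(protein_seq),
        identity=identity,
    )


def min_distance_to_sites(
    residue: Residue,
    site_residues: Sequence[Residue],
    atom_set: str = "side_chain_heavy",
) -> tuple[float, int]:
    """Minimum Euclidean distance (Angstrom) between a residue and a set of
    functional-site residues, over all atom pairs of the chosen atom sets.

    Returns ``(distance, index_of_nearest_site_in_the_input_list)``.
    """
    if not site_residues:
        raise ValueError("empty site residue list")
    query = np.array([a.coord for a in residue.atoms_for(atom_set)])
    best = (math.inf, -1)
    for i, site in enumerate(site_residues):
        coords = np.array([a.coord for a in site.atoms_for(atom_set)])
        d = float(cdist(query, coords).min())
        if d < best[0]:
            best = (d, i)
    return best


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = math.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom accessible surface area by rolling-probe sphere sampling.

    Each atom is wrapped in a sphere of radius ``vdw + probe`` carrying
    ``n_points`` deterministic test points; a point is accessible when it lies
    outside every neighbouring atom's probe-expanded sphere.  Deterministic
    for fixed ``n_points``.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    points = _sphere_points(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    asa = np.zeros(n)
    for i in range(n):
        r = expanded[i]
        neighbours = [j for j in tree.query_ball_point(coords[i], r + expanded.max()) if j != i]
        test = coords[i] + r * points
        if neighbours:
            nb_coords = coords[neighbours]
            nb_rad = expanded[neighbours]
            d = cdist(test, nb_coords)
            accessible = np.all(d >= nb_rad[None, :], axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        asa[i] = frac * 4.0 * math.pi * r * r
    return asa


def relative_accessibility(
    chain: Chain,
    residue: Residue,
    environment: Optional[Iterable[Atom]] = None,
    probe: float = 1.4,
    n_points: int = 960,
) -> float:
    """Relative solvent accessibility of one residue in its chain context.

    ``environment`` may supply additional occluding atoms (other chains,
    cofactors); by default only the residue's own chain occludes.  The
    residue's summed heavy-atom ASA is divided by the theoretical maximum for
    its amino-acid type, so values slightly above 1 are possible for exposed
    termini.
    """
    res_atoms = residue.heavy_atoms()
    if not res_atoms:
        raise ValueError(f"residue {residue.name} {residue.label} has no heavy atoms")
    env_atoms = list(chain.atoms()) if environment is None else list(environment)
    own_ids = {id(a) for a in residue.atoms}
    atoms = list(res_atoms) + [a for a in env_atoms if a.is_heavy and id(a) not in own_ids]
    coords = np.array([a.coord for a in atoms])
    radii = np.array([a.radius for a in atoms])
    asa = shrake_rupley(coords, radii, probe=probe, n_points=n_points)
    residue_asa = float(asa[: len(res_atoms)].sum())
    max_asa = _max_asa_table().get(residue.name.upper())
    if max_asa is None:
        # unknown residue type: normalise by the largest tabulated value so
        # the ratio stays a conservative lower bound on exposure
        max_asa = max(_max_asa_table().values())
    return residue_asa / max_asa


def classify_candidate_site(
    proximity: ProximityResult,
    d_max: float = 10.0,
    rsa_min: float = 0.2,
) -> ProximityResult:
    """Set the near-active-site / surface-exposed flags from the thresholds."""
    proximity.near_active_site = proximity.min_site_distance <= d_max
    proximity.surface_exposed = proximity.rsa >= rsa_min
    return proximity


def evaluate_variant_on_structures(
    protein_accession: str,
    protein_seq: str,
    residue_index: int,
    site_indices: Sequence[int],
    structures: Sequence[StructureChainSet],
    *,
    atom_set: str = "side_chain_heavy",
    d_max: float = 10.0,
    rsa_min: float = 0.2,
    n_points: int = 960,
) -> Optional[ProximityResult]:
    """Score a variant residue on every chain of every available structure.

    All chains that map (identity >= 0.9) and resolve both the variant residue
    and at least one site residue are evaluated; the result with the minimum
    site distance is reported (the most permissive reading: any structure
    showing proximity counts).  Returns None when no chain is evaluable.
    """
    if not site_indices:
        raise ValueError("no functional-site residues supplied")
    results: list[ProximityResult] = []
    for structure in structures:
        env = structure.all_atoms()
        for chain in structure.chains:
            try:
                rmap = align_sequence_to_chain(
                    protein_seq,
                    chain,
                    protein_accession=protein_accession,
                    structure_id=structure.structure_id,
                )
            except ChainMappingError:
                continue
            if residue_index not in rmap.index_map:
                continue
            mapped_sites = [
                (i, rmap.index_map[i]) for i in site_indices if i in rmap.index_map
            ]
            if not mapped_sites:
                continue
            variant_res = rmap.index_map[residue_index]
            dist, nearest = min_distance_to_sites(
                variant_res, [r for _, r in mapped_sites], atom_set
            )
            rsa = relative_accessibility(
                chain, variant_res, environment=env, n_points=n_points
            )
            result = ProximityResult(
                residue_index=residue_index,
                structure_id=structure.structure_id,
                chain_id=chain.chain_id,
                min_site_distance=dist,
                nearest_site_residue=mapped_sites[nearest][0],
                rsa=rsa,
            )
            results.append(classify_candidate_site(result, d_max=d_max, rsa_min=rsa_min))
    if not results:
        return None
    return min(results, key=lambda r: r.min_site_distance)
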