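"""Mapping cross-links onto structures and validating them against the
cross-linker distance restraint.

A lysine-reactive, MS-cleavable cross-linker such as Azide-A-DSBSO bridges
lysine side chains whose Cα atoms lie within roughly 35 Å of each other
(spacer arm plus two lysine side chains plus in-solution flexibility).
Mapping identified residue pairs onto a high-resolution structure and
measuring Cα–Cα Euclidean distances therefore validates the identifications:
the fraction of mapped links at or under the restraint ("agreement") is a
global fidelity measure for the dataset.

Homo-oligomers make the mapping ambiguous: a protein present in several
chain copies offers several candidate residues per endpoint.  The standard
resolution, used here, is the minimum distance over all admissible copy
pairs — the most permissive reading, since a cross-link only requires
*some* pair of copies to be in reach.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .xl_io import CrossLinkRecord

__all__ = [
    "StructureModel",
    "Chain",
    "Residue",
    "ChainAssignment",
    "MappedCrossLink",
    "DistanceReport",
    "load_structure",
    "build_chain_assignment",
    "ca_distance",
    "map_crosslink",
    "satisfaction_report",
    "distance_distribution",
    "kabsch_superpose",
]

#: Conventional maximum Cα–Cα distance compatible with the DSBSO spacer (Å).
DSBSO_MAX_DISTANCE = 35.0


@dataclass(frozen=True)
class Residue:
    number: int  # author residue number
    name: str  # 3-letter code
    ca: tuple[float, float, float] | None  # Cα coordinate in Å, None if absent

    @property
    def present(self) -> bool:
        return self.ca is not None


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        self._by_number = {res.number: res for res in self.residues}
        if len(self._by_number) != len(self.residues):
            raise ValueError(
                f"duplicate residue numbers in chain {self.chain_id}"
            )

    def residue(self, number: int) -> Residue | None:
        return self._by_number.get(number)

    def one_letter_sequence(self) -> str:
        return "".join(_three_to_one(res.name) for res in self.residues)


@dataclass
class StructureModel:
    """Cα coordinate set of a (multi-chain) structure or docked model."""

    id: str
    chains: dict[str, Chain]

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError(f"structure {self.id!r} has no chains")

    def ca(self, chain_id: str, number: int) -> np.ndarray:
        chain = self.chains.get(chain_id)
        if chain is None:
            raise KeyError(f"no chain {chain_id!r} in structure {self.id!r}")
        res = chain.residue(number)
        if res is None or res.ca is None:
            raise KeyError(
                f"residue {number} in chain {chain_id!r} of {self.id!r} "
                f"has no Cα"
            )
        return np.asarray(res.ca, dtype=float)


@dataclass
class ChainAssignment:
    """Protein accession → structure chains, with residue-number reconciliation.

    For each accession, a list of ``(chain_id, residue_map)`` where
    ``residue_map`` maps 1-based protein sequence positions to author
    residue numbers in that chain.  One accession may own several chains
    (homo-oligomer copies).
    """

    assignments: dict[str, list[tuple[str, dict[int, int]]]] = field(
        default_factory=dict
    )
    identities: dict[str, float] = field(default_factory=dict)  # per chain_id
    unassigned_chains: list[str] = field(default_factory=list)

    def chains_for(self, accession: str) -> list[tuple[str, dict[int, int]]]:
        return self.assignments.get(accession, [])


_AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common modified residues seen in coordinate files
    "MSE": "M", "SEC": "U", "PYL": "O",
}
AA1_TO_3 = {v: k for k, v in list(_AA3_TO_1.items())[:20]}


def _three_to_one(name: str) -> str:
    return _AA3_TO_1.get(name.upper(), "X")


def load_structure(path: str | Path) -> StructureModel:
    """Read a PDB or mmCIF file into a Cα-level :class:`StructureModel`.

    Only polymer ATOM records are considered; waters and heteroatoms are
    ignored.  Residues without a Cα are kept but flagged absent.  For
    alternate conformations the highest-occupancy Cα is taken (ties broken
    by altloc identifier order).  Chains without any Cα are dropped.
    """
    import gemmi

    path = Path(path)
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path.name}: {exc}") from exc
    structure.setup_entities()
    if len(structure) == 0:
        raise ValueError(f"structure file {path.name} contains no model")
    model = structure[0]
    chains: dict[str, Chain] = {}
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            if res.is_water() or res.het_flag == "H":
                continue
            best = None
            for atom in res:
                if atom.name != "CA" or atom.element == gemmi.Element("Ca"):
                    continue
                key = (-atom.occ, atom.altloc)
                if best is None or key < best[0]:
                    best = (key, atom)
            if best is None:
                residues.append(Residue(res.seqid.num, res.name, None))
            else:
                pos = best[1].pos
                residues.append(
                    Residue(res.seqid.num, res.name, (pos.x, pos.y, pos.z))
                )
        if any(r.present for r in residues):
            chains[chain.name] = Chain(chain.name, residues)
    if not chains:
        raise ValueError(f"no chain with Cα atoms in {path.name}")
    return StructureModel(id=path.stem, chains=chains)


def _align_chain(sequence: str, chain: Chain) -> tuple[float, dict[int, int]]:
    """Globally align a protein sequence to a chain's observed residues.

    Returns (identity relative to the full protein sequence, residue map
    from 1-based sequence position to author residue number).  Aligned
    mismatches are mapped too (point mutants, engineered tags); gaps are
    excluded.
    """
    from Bio import Align

    chain_seq = chain.one_letter_sequence()
    if not chain_seq:
        return 0.0, {}
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=2.0,
        mismatch_score=-1.0,
        open_gap_score=-5.0,
        extend_gap_score=-0.5,
    )
    # free end gaps: a chain usually covers a subrange of the full sequence
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    alignment = aligner.align(sequence, chain_seq)[0]
    identical = 0
    residue_map: dict[int, int] = {}
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        for offset in range(t1 - t0):
            seq_pos = t0 + offset  # 0-based
            res = chain.residues[q0 + offset]
            residue_map[seq_pos + 1] = res.number
            if sequence[seq_pos] == _three_to_one(res.name):
                identical += 1
    identity = identical / len(sequence) if sequence else 0.0
    return identity, residue_map


def build_chain_assignment(
    structure: StructureModel,
    sequences: Mapping[str, str],
    min_identity: float = 0.9,
) -> ChainAssignment:
    """Assign each chain to the best-matching protein sequence.

    Every chain is aligned to every sequence; it is assigned to the
    highest-identity protein provided the identity (fraction of the
    protein sequence matched identically) reaches ``min_identity``.
    A protein may own several chains — homo-oligomer copies.
    """
    if not sequences:
        raise ValueError("sequences must be non-empty")
    assignment = ChainAssignment()
    for chain_id in sorted(structure.chains):
        chain = structure.chains[chain_id]
        best: tuple[float, str, dict[int, int]] | None = None
        for accession in sorted(sequences):
            identity, residue_map = _align_chain(sequences[accession], chain)
            if best is None or identity > best[0]:
                best = (identity, accession, residue_map)
        if best is not None and best[0] >= min_identity:
            identity, accession, residue_map = best
            assignment.assignments.setdefault(accession, []).append(
                (chain_id, residue_map)
            )
            assignment.identities[chain_id] = identity
        else:
            assignment.unassigned_chains.append(chain_id)
    return assignment


def ca_distance(
    structure: StructureModel,
    endpoint1: tuple[str, int],
    endpoint2: tuple[str, int],
) -> float:
    """Euclidean Cα–Cα distance (Å) between two (chain, residue) endpoints."""
    a = structure.ca(*endpoint1)
    b = structure.ca(*endpoint2)
    return float(np.linalg.norm(a - b))


@dataclass
class MappedCrossLink:
    """A cross-link evaluated against one structure."""

    record: CrossLinkRecord
    status: str  # "mapped" | "endpoint_missing" | "protein_absent"
    chosen_pair: tuple[str, int, str, int] | None = None
    distance: float | None = None
    satisfied: bool | None = None

    def __post_init__(self) -> None:
        if (self.status == "mapped") != (self.distance is not None):
            raise ValueError("distance must be present iff status is 'mapped'")


def _endpoint_candidates(
    accession: str,
    residue: int,
    structure: StructureModel,
    assignment: ChainAssignment,
) -> list[tuple[str, int]]:
    """All (chain, author residue) placements of a protein residue that
    have a Cα in the structure."""
    candidates = []
    for chain_id, residue_map in assignment.chains_for(accession):
        number = residue_map.get(residue)
        if number is None:
            continue
        res = structure.chains[chain_id].residue(number)
        if res is not None and res.present:
            candidates.append((chain_id, number))
    return candidates


def map_crosslink(
    record: CrossLinkRecord,
    structure: StructureModel,
    assignment: ChainAssignment,
    max_distance: float = DSBSO_MAX_DISTANCE,
) -> MappedCrossLink:
    """Place one cross-link on the structure, resolving copy ambiguity.

    Every admissible combination of chain copies for the two endpoints is
    enumerated — including cross-copy combinations for intra-protein links
    in homo-oligomers, but never a residue paired with itself — and the
    minimum distance is taken.  Status encodes failure modes: a protein
    with no assigned chain gives ``protein_absent``; endpoints that never
    land on a present Cα give ``endpoint_missing``.
    """
    if not assignment.chains_for(record.protein_a) or not assignment.chains_for(
        record.protein_b
    ):
        return MappedCrossLink(record, status="protein_absent")
    cand_a = _endpoint_candidates(
        record.protein_a, record.residue_a, structure, assignment
    )
    cand_b = _endpoint_candidates(
        record.protein_b, record.residue_b, structure, assignment
    )
    best: tuple[float, tuple[str, int, str, int]] | None = None
    for ep_a in cand_a:
        for ep_b in cand_b:
            if ep_a == ep_b:
                continue  # same physical residue cannot cross-link to itself
            d = ca_distance(structure, ep_a, ep_b)
            if best is None or d < best[0]:
                best = (d, (*ep_a, *ep_b))
    if best is None:
        return MappedCrossLink(record, status="endpoint_missing")
    distance, chosen = best
    return MappedCrossLink(
        record,
        status="mapped",
        chosen_pair=chosen,
        distance=distance,
        satisfied=distance <= max_distance,
    )


@dataclass
class DistanceReport:
    """Per-complex restraint-satisfaction summary."""

    complex_id: str
    n_input: int
    n_mapped: int
    n_satisfied: int
    agreement: float | None  # n_satisfied / n_mapped; None when n_mapped == 0
    distances: list[float]
    max_distance: float
    n_endpoint_missing: int = 0
    n_protein_absent: int = 0

    def to_dict(self) -> dict:
        return {
            "complex_id": self.complex_id,
            "n_input": self.n_input,
            "n_mapped": self.n_mapped,
            "n_satisfied": self.n_satisfied,
            "agreement": self.agreement,
            "max_distance": self.max_distance,
            "n_endpoint_missing": self.n_endpoint_missing,
            "n_protein_absent": self.n_protein_absent,
        }


def satisfaction_report(
    mapped: Sequence[MappedCrossLink],
    max_distance: float = DSBSO_MAX_DISTANCE,
    complex_id: str = "",
) -> DistanceReport:
    """Aggregate mapped links into an agreement statistic.

    The agreement denominator is the number of *mapped* links only;
    unmappable links (absent proteins, missing residues) are counted
    separately and never dilute the fraction.  The satisfaction boundary
    is inclusive: distance == max_distance satisfies the restraint.
    """
    distances = [m.distance for m in mapped if m.status == "mapped"]
    n_satisfied = sum(1 for d in distances if d <= max_distance)
    n_mapped = len(distances)
    return DistanceReport(
        complex_id=complex_id,
        n_input=len(mapped),
        n_mapped=n_mapped,
        n_satisfied=n_satisfied,
        agreement=(n_satisfied / n_mapped) if n_mapped else None,
        distances=distances,
        max_distance=max_distance,
        n_endpoint_missing=sum(1 for m in mapped if m.status == "endpoint_missing"),
        n_protein_absent=sum(1 for m in mapped if m.status == "protein_absent"),
    )


def distance_distribution(
    mapped: Sequence[MappedCrossLink], bin_width: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of mapped distances: left-closed right-open bins from 0.

    A value exactly on a bin edge falls in the bin to its right, so the
    final bin is never a closed catch-all; counts always sum to the number
    of mapped links.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    distances = np.array(
        [m.distance for m in mapped if m.status == "mapped"], dtype=float
    )
    if distances.size == 0:
        return np.array([0.0, bin_width]), np.zeros(1, dtype=int)
    n_bins = int(np.floor(distances.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    counts = np.zeros(n_bins, dtype=int)
    idx = np.floor(distances / bin_width).astype(int)
    np.add.at(counts, idx, 1)
    return edges, counts


def kabsch_superpose(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired coordinate sets.

    Finds the proper rotation ``R`` and translation ``t`` minimising
    ``|| (coords_a @ R.T + t) - coords_b ||``; reflections are excluded by
    flipping the sign of the smallest singular vector when the optimal
    orthogonal transform is improper.  Returns ``(R, t, rmsd)`` with the
    RMSD attained after applying the transform to ``coords_a``.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must be equal-shape N×3 arrays")
    n = a.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 paired points")
    centroid_a = a.mean(axis=0)
    centroid_b = b.mean(axis=0)
    a0 = a - centroid_a
    b0 = b - centroid_b
    if np.linalg.matrix_rank(a0, tol=1e-9) < 2 or np.linalg.matrix_rank(
        b0, tol=1e-9
    ) < 2:
        raise ValueError("degenerate (collinear) coordinates: rotation not unique")
    h = a0.T @ b0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    rotation = vt.T @ correction @ u.T
    translation = centroid_b - rotation @ centroid_a
    transformed = a @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((transformed - b) ** 2, axis=1))))
    return rotation, translation, rmsd
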