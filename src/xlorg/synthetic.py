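"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is a pure function of its parameters and a 64-bit seed:
the seed feeds a named substream (one independent stream per generator)
so suites can regenerate any input independently and bit-reproducibly.

The generators emulate the *statistical shape* of the real inputs —
multi-chain Cα coordinate sets with lysines, cross-link tables mixing
restraint-satisfying, restraint-violating and decoy pairs, SILAC
protein-group tables with planted log2 enrichment, punctate and
ring-shaped two-channel images — not their biophysical detail; chains are
random walks, point-spread functions are Gaussian.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .imaging import ImageChannel
from .silac import ProteinGroupRecord
from .structure_map import (
    AA1_TO_3,
    Chain,
    Residue,
    StructureModel,
    build_chain_assignment,
    map_crosslink,
)
from .xl_io import CrossLinkRecord, CrossLinkTable

__all__ = [
    "substream",
    "make_complex",
    "structure_to_pdb",
    "structure_to_cif",
    "sample_crosslinks",
    "make_silac_dataset",
    "make_coloc_images",
    "make_membrane_image",
]

#: Lysine placement probability; mirrors typical yeast proteome frequency.
LYSINE_FREQUENCY = 0.08

CA_STEP = 3.8  # consecutive Cα–Cα distance of an extended backbone walk, Å

_NON_LYSINE = "ACDEFGHILMNPQRSTVWY"


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible random stream named after its consumer."""
    key = zlib.crc32(name.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform proper rotation via QR decomposition of a Gaussian matrix."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@dataclass
class SyntheticComplex:
    """A generated complex and everything needed to analyse it."""

    structure: StructureModel
    sequences: dict[str, str]
    chain_owner: dict[str, str]  # chain id -> accession


def make_complex(
    n_proteins: int = 3,
    copies: int | Mapping[str, int] = 1,
    n_residues: int = 150,
    seed: int = 0,
    box_size: float = 60.0,
) -> SyntheticComplex:
    """Generate a multi-chain Cα complex with lysines at seeded positions.

    Each protein is a 3-D random walk with fixed 3.8 Å steps (chains may
    self-intersect; only pairwise distances matter downstream).  Lysines
    are placed independently with probability 0.08.  Homo-oligomer copies
    are rigid transforms of one conformation, so copies superpose with
    zero RMSD.  Chain starting points are scattered in a box of edge
    ``box_size`` Å so inter-protein lysine pairs span both sides of the
    cross-linker restraint.
    """
    if n_proteins < 1 or n_residues < 1:
        raise ValueError("all counts must be >= 1")
    rng = substream(seed, "complex")
    sequences: dict[str, str] = {}
    chains: dict[str, Chain] = {}
    chain_owner: dict[str, str] = {}
    chain_labels = iter(
        [chr(ord("A") + i) for i in range(26)]
        + [f"{a}{b}" for a in "ABCD" for b in "ABCDEFGH"]
    )
    for p in range(n_proteins):
        accession = f"SYN{p + 1:03d}"
        is_lys = rng.random(n_residues) < LYSINE_FREQUENCY
        others = rng.integers(0, len(_NON_LYSINE), size=n_residues)
        sequence = "".join(
            "K" if is_lys[i] else _NON_LYSINE[others[i]] for i in range(n_residues)
        )
        sequences[accession] = sequence
        start = rng.uniform(-box_size / 2, box_size / 2, size=3)
        steps = rng.normal(size=(n_residues - 1, 3)) if n_residues > 1 else np.zeros((0, 3))
        if len(steps):
            steps = steps / np.linalg.norm(steps, axis=1, keepdims=True) * CA_STEP
        base = np.vstack([start, start + np.cumsum(steps, axis=0)]) if len(steps) else start[None, :]
        n_copies = copies.get(accession, 1) if isinstance(copies, Mapping) else copies
        for c in range(n_copies):
            if c == 0:
                coords = base
            else:
                rotation = _random_rotation(rng)
                translation = rng.uniform(-box_size / 2, box_size / 2, size=3)
                centroid = base.mean(axis=0)
                coords = (base - centroid) @ rotation.T + centroid + translation
            chain_id = next(chain_labels)
            residues = [
                Residue(i + 1, AA1_TO_3[sequence[i]], tuple(coords[i]))
                for i in range(n_residues)
            ]
            chains[chain_id] = Chain(chain_id, residues)
            chain_owner[chain_id] = accession
    structure = StructureModel(id=f"synthetic_complex_seed{seed}", chains=chains)
    return SyntheticComplex(structure, sequences, chain_owner)


def _to_gemmi(model: StructureModel):
    import gemmi

    structure = gemmi.Structure()
    structure.name = model.id
    gm = gemmi.Model("1")
    for chain_id in sorted(model.chains):
        chain = gemmi.Chain(chain_id)
        for res in model.chains[chain_id].residues:
            residue = gemmi.Residue()
            residue.name = res.name
            residue.seqid = gemmi.SeqId(res.number, " ")
            if res.ca is not None:
                atom = gemmi.Atom()
                atom.name = "CA"
                atom.element = gemmi.Element("C")
                atom.pos = gemmi.Position(*res.ca)
                atom.occ = 1.0
                residue.add_atom(atom)
            chain.add_residue(residue)
        gm.add_chain(chain)
    structure.add_model(gm)
    structure.setup_entities()
    return structure


def structure_to_pdb(model: StructureModel, path: str | Path) -> None:
    _to_gemmi(model).write_pdb(str(path))


def structure_to_cif(model: StructureModel, path: str | Path) -> None:
    _to_gemmi(model).make_mmcif_document().write_file(str(path))


def sample_crosslinks(
    complex_truth: SyntheticComplex,
    n_satisfying: int = 40,
    n_violating: int = 10,
    n_decoy_protein_pairs: int = 0,
    max_distance: float = 35.0,
    seed: int = 0,
) -> tuple[CrossLinkTable, pd.DataFrame]:
    """Draw planted cross-links of known distance class from a complex.

    Satisfying links are sampled from lysine pairs whose min-over-copies
    Cα–Cα distance is at most ``max_distance − 2`` Å, violating links
    from pairs beyond ``max_distance + 2`` Å (the 2 Å guard bands keep
    the classes unambiguous), and decoy links reference proteins absent
    from the structure.  All links are unique.  Returns the table plus a
    truth frame (one row per link: class, true distance).

    Raises when a distance class cannot supply the requested count,
    reporting the shortfall.
    """
    rng = substream(seed, "crosslinks")
    structure = complex_truth.structure
    sequences = complex_truth.sequences
    assignment = build_chain_assignment(structure, sequences, min_identity=0.99)
    lysines = {
        acc: [i + 1 for i, aa in enumerate(seq) if aa == "K"]
        for acc, seq in sequences.items()
    }
    accessions = sorted(sequences)
    satisfying_pool: list[tuple[CrossLinkRecord, float]] = []
    violating_pool: list[tuple[CrossLinkRecord, float]] = []
    for i, acc_a in enumerate(accessions):
        for acc_b in accessions[i:]:
            for res_a in lysines[acc_a]:
                for res_b in lysines[acc_b]:
                    if acc_a == acc_b and res_b <= res_a:
                        continue
                    record = CrossLinkRecord(acc_a, res_a, acc_b, res_b)
                    mapped = map_crosslink(record, structure, assignment, max_distance)
                    if mapped.status != "mapped":
                        continue
                    if mapped.distance <= max_distance - 2.0:
                        satisfying_pool.append((record, mapped.distance))
                    elif mapped.distance > max_distance + 2.0:
                        violating_pool.append((record, mapped.distance))
    if len(satisfying_pool) < n_satisfying or len(violating_pool) < n_violating:
        raise ValueError(
            f"not enough lysine pairs: need {n_satisfying} satisfying "
            f"(have {len(satisfying_pool)}) and {n_violating} violating "
            f"(have {len(violating_pool)}); grow the complex or the box"
        )
    records: list[CrossLinkRecord] = []
    truth_rows = []
    for pool, n_wanted, label in (
        (satisfying_pool, n_satisfying, "satisfying"),
        (violating_pool, n_violating, "violating"),
    ):
        chosen = rng.choice(len(pool), size=n_wanted, replace=False)
        for idx in sorted(chosen):
            record, distance = pool[idx]
            record = CrossLinkRecord(
                record.protein_a,
                record.residue_a,
                record.protein_b,
                record.residue_b,
                score=float(np.round(rng.uniform(50, 300), 2)),
                fdr=float(np.round(rng.uniform(0.0, 0.02), 5)),
                csm_count=int(rng.integers(1, 5)),
            )
            records.append(record)
            truth_rows.append(
                {
                    "protein_a": record.protein_a,
                    "residue_a": record.residue_a,
                    "protein_b": record.protein_b,
                    "residue_b": record.residue_b,
                    "link_class": label,
                    "true_distance": distance,
                }
            )
    for d in range(n_decoy_protein_pairs):
        acc_a, acc_b = f"DEC{2 * d + 1:03d}", f"DEC{2 * d + 2:03d}"
        record = CrossLinkRecord(
            acc_a,
            int(rng.integers(1, 300)),
            acc_b,
            int(rng.integers(1, 300)),
            score=float(np.round(rng.uniform(50, 300), 2)),
            fdr=float(np.round(rng.uniform(0.0, 0.02), 5)),
        )
        records.append(record)
        truth_rows.append(
            {
                "protein_a": record.protein_a,
                "residue_a": record.residue_a,
                "protein_b": record.protein_b,
                "residue_b": record.residue_b,
                "link_class": "decoy",
                "true_distance": np.nan,
            }
        )
    table = CrossLinkTable(
        records=records,
        source=f"synthetic_links_seed{seed}",
        deduplicated=True,
    )
    return table, pd.DataFrame(truth_rows)


def make_silac_dataset(
    n_proteins: int = 1000,
    n_enriched: int = 100,
    effect_log2: float = 2.0,
    noise_sd: float = 0.25,
    n_replicates: int = 3,
    seed: int = 0,
    orientation: str = "forward",
) -> tuple[list[ProteinGroupRecord], pd.DataFrame]:
    """SILAC protein-group table with planted log2 enrichment.

    Channel intensities are log-normal around a per-protein baseline;
    the first ``n_enriched`` proteins carry ``effect_log2`` on the
    heavy/light ratio (sign-flipped for the ``reverse`` label-swap
    orientation).  Per-channel log2 noise has SD ``noise_sd / √2`` so the
    log2 *ratio* noise SD equals ``noise_sd`` exactly.  Truth labels are
    returned alongside.
    """
    if n_enriched > n_proteins:
        raise ValueError("n_enriched cannot exceed n_proteins")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"orientation must be forward|reverse, got {orientation!r}")
    rng = substream(seed, f"silac_{orientation}")
    base_rng = substream(seed, "silac_base")
    sign = 1.0 if orientation == "forward" else -1.0
    channel_sd = noise_sd / np.sqrt(2.0)
    baselines = 10.0 ** base_rng.normal(6.0, 0.6, size=n_proteins)
    records, truth_rows = [], []
    for p in range(n_proteins):
        enriched = p < n_enriched
        effect = sign * effect_log2 if enriched else 0.0
        heavy, light = [], []
        for _ in range(n_replicates):
            light.append(baselines[p] * 2.0 ** rng.normal(0.0, channel_sd))
            heavy.append(baselines[p] * 2.0 ** (effect + rng.normal(0.0, channel_sd)))
        protein_id = f"PROT{p + 1:04d}"
        records.append(
            ProteinGroupRecord(
                protein_id, heavy, light, peptide_count=int(base_rng.integers(2, 30))
            )
        )
        truth_rows.append(
            {"protein_id": protein_id, "enriched": enriched, "true_log2": effect}
        )
    return records, pd.DataFrame(truth_rows).set_index("protein_id")


def _scatter_points(
    rng: np.random.Generator,
    n_points: int,
    size: int,
    margin: float,
    min_separation: float,
    max_tries: int = 20000,
) -> np.ndarray:
    points: list[np.ndarray] = []
    for _ in range(max_tries):
        if len(points) == n_points:
            break
        candidate = rng.uniform(margin, size - margin, size=2)
        if all(np.linalg.norm(candidate - p) >= min_separation for p in points):
            points.append(candidate)
    if len(points) < n_points:
        raise ValueError(
            f"could not place {n_points} puncta with separation "
            f"{min_separation} in a {size}×{size} image"
        )
    return np.array(points)


def _render_puncta(
    positions: np.ndarray, size: int, amplitude: float, psf_sigma: float
) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    image = np.zeros((size, size))
    for row, col in positions:
        image[int(round(row)), int(round(col))] += 1.0
    image = gaussian_filter(image, sigma=psf_sigma)
    # a unit impulse blurred by a Gaussian peaks at 1/(2πσ²); rescale so
    # each punctum peaks at `amplitude`
    return image * amplitude * 2.0 * np.pi * psf_sigma**2


def make_coloc_images(
    size: int = 256,
    n_puncta: int = 30,
    overlap_fraction: float = 0.5,
    psf_sigma: float = 2.0,
    noise_sd: float = 2.0,
    seed: int = 0,
    amplitude: float = 200.0,
    background: float = 10.0,
) -> tuple[ImageChannel, ImageChannel, dict]:
    """Two punctate channels with a planted signal-overlap fraction.

    Channel A gets ``n_puncta`` puncta; channel B gets the same number,
    of which ``round(overlap_fraction · n_puncta)`` sit exactly on A
    puncta and the rest are placed well away from every other punctum.
    All puncta share one amplitude, so in the noise-free limit the
    Manders coefficients equal the planted fraction of co-located puncta.
    Gaussian PSF blur and Gaussian read noise are applied on top of a
    uniform background.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    rng = substream(seed, "coloc")
    n_shared = int(round(overlap_fraction * n_puncta))
    separation = 8.0 * psf_sigma
    all_points = _scatter_points(
        rng, 2 * n_puncta - n_shared, size, margin=4 * psf_sigma,
        min_separation=separation,
    )
    pos_a = all_points[:n_puncta]
    pos_b = np.vstack([pos_a[:n_shared], all_points[n_puncta:]])
    channel_a = _render_puncta(pos_a, size, amplitude, psf_sigma) + background
    channel_b = _render_puncta(pos_b, size, amplitude, psf_sigma) + background
    channel_a = np.clip(channel_a + rng.normal(0, noise_sd, channel_a.shape), 0, None)
    channel_b = np.clip(channel_b + rng.normal(0, noise_sd, channel_b.shape), 0, None)
    truth = {
        "overlap_fraction": n_shared / n_puncta if n_puncta else 0.0,
        "n_puncta": n_puncta,
        "n_shared": n_shared,
        "snr": amplitude / noise_sd if noise_sd > 0 else np.inf,
    }
    return (
        ImageChannel(channel_a, label="channel_a"),
        ImageChannel(channel_b, label="channel_b"),
        truth,
    )


def make_membrane_image(
    size: int = 256,
    ring_radius: float = 60.0,
    ring_width: float = 5.0,
    enrichment_ratio: float = 4.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    background: float = 50.0,
) -> tuple[ImageChannel, dict, dict]:
    """Ring-shaped membrane signal over uniform background, plus ROIs.

    An annulus of the given radius and width carries
    ``enrichment_ratio × background`` intensity, emulating a protein
    enriched on the vacuole membrane over a cytosolic pool.  The ROI
    sidecar holds the membrane centerline polyline and three interior
    cytosol disks, in the JSON layout the analysis functions consume.
    """
    center = size / 2.0
    if ring_radius + ring_width / 2.0 >= center:
        raise ValueError("ring does not fit inside the image")
    from scipy.ndimage import gaussian_filter

    rng = substream(seed, "membrane")
    rows, cols = np.indices((size, size), dtype=float)
    radial = np.hypot(rows - center, cols - center)
    image = np.full((size, size), background, dtype=float)
    image[np.abs(radial - ring_radius) <= ring_width / 2.0] = (
        background * enrichment_ratio
    )
    image = gaussian_filter(image, sigma=0.7)
    image = np.clip(image + rng.normal(0, noise_sd, image.shape), 0, None)
    angles = np.linspace(0, 2 * np.pi, 73)
    polyline = [
        [center + ring_radius * np.sin(a), center + ring_radius * np.cos(a)]
        for a in angles
    ]
    disk_angles = np.deg2rad([90.0, 210.0, 330.0])
    disk_radius = 8.0
    disks = [
        {
            "center": [
                center + 0.45 * ring_radius * np.sin(a),
                center + 0.45 * ring_radius * np.cos(a),
            ],
            "radius": disk_radius,
        }
        for a in disk_angles
    ]
    rois = {"membrane_polyline": polyline, "cytosol_disks": disks}
    truth = {"enrichment_ratio": enrichment_ratio, "background": background}
    return ImageChannel(image, label="membrane"), rois, truth


def write_rois(rois: dict, path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(rois, handle, indent=1, sort_keys=True)


def read_rois(path: str | Path) -> dict:
    with open(path) as handle:
        return json.load(handle)
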