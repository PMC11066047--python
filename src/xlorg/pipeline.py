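"""End-to-end orchestration: config validation, stage execution, manifest.

A run is described by a single YAML (or dict) config: a seed, an output
directory and an ordered stage list.  Stages share an in-memory context
(the simulated complex feeds the mapper, the link table feeds the
network, ...) and write their outputs into the run directory.  The
manifest records stage order, parameters, output checksums and warnings;
for a fixed config and seed the checksums are bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import yaml

from . import imaging, network, silac, structure_map, synthetic, xl_io

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "load_config"]

KNOWN_STAGES = (
    "simulate_complex",
    "simulate_links",
    "map_links",
    "network",
    "silac",
    "coloc",
    "membrane",
)

# parameter -> (validator, description); applied wherever the key appears
_PARAM_RULES: dict[str, tuple[Callable[[Any], bool], str]] = {
    "max_distance": (lambda v: v > 0, "must be positive"),
    "bin_width": (lambda v: v > 0, "must be positive"),
    "fdr_threshold": (lambda v: 0 <= v <= 1, "must lie in [0, 1]"),
    "min_links": (lambda v: v >= 1, "must be >= 1"),
    "min_identity": (lambda v: 0 < v <= 1, "must lie in (0, 1]"),
    "overlap_fraction": (lambda v: 0 <= v <= 1, "must lie in [0, 1]"),
    "noise_sd": (lambda v: v > 0, "must be positive"),
    "enrichment_ratio": (lambda v: v > 0, "must be positive"),
    "n_proteins": (lambda v: v >= 1, "must be >= 1"),
    "n_residues": (lambda v: v >= 1, "must be >= 1"),
    "n_replicates": (lambda v: v >= 2, "must be >= 2"),
}


class ConfigError(ValueError):
    """Invalid run configuration; the message lists every offending field."""


@dataclass
class RunConfig:
    seed: int
    outdir: Path
    stages: list[dict] = field(default_factory=list)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        errors = []
        seed = raw.get("seed")
        if not isinstance(seed, int):
            errors.append("seed: required integer")
        outdir = raw.get("outdir")
        if not outdir:
            errors.append("outdir: required path")
        stages = raw.get("stages", [])
        if not stages:
            errors.append("stages: at least one stage required")
        seen = set()
        for i, stage in enumerate(stages):
            name = stage.get("name")
            if name not in KNOWN_STAGES:
                errors.append(f"stages[{i}].name: unknown stage {name!r}")
                continue
            seen.add(name)
            for key, value in (stage.get("params") or {}).items():
                rule = _PARAM_RULES.get(key)
                if rule is not None:
                    ok = False
                    try:
                        ok = rule[0](value)
                    except TypeError:
                        pass
                    if not ok:
                        errors.append(f"stages[{i}].params.{key}: {rule[1]} (got {value!r})")
        order = {name: i for i, name in enumerate(KNOWN_STAGES)}
        names = [s.get("name") for s in stages if s.get("name") in order]
        for need, by in (("simulate_complex", "simulate_links"),
                         ("simulate_links", "map_links"),
                         ("simulate_links", "network")):
            if by in seen and need not in seen:
                errors.append(f"stage {by!r} requires stage {need!r}")
        if names != sorted(names, key=order.__getitem__):
            errors.append("stages: not in dependency order")
        if errors:
            raise ConfigError("; ".join(errors))
        return cls(seed=seed, outdir=Path(outdir), stages=list(stages))


def load_config(path: str | Path) -> RunConfig:
    with open(path) as handle:
        return RunConfig.from_dict(yaml.safe_load(handle))


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def _write_fasta(sequences: dict[str, str], path: Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=acc, description="")
        for acc, seq in sorted(sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _stage_simulate_complex(ctx, params, outdir, seed):
    complex_truth = synthetic.make_complex(
        n_proteins=params.get("n_proteins", 3),
        copies=params.get("copies", 1),
        n_residues=params.get("n_residues", 150),
        seed=seed,
    )
    ctx["complex"] = complex_truth
    synthetic.structure_to_pdb(complex_truth.structure, outdir / "structure.pdb")
    _write_fasta(complex_truth.sequences, outdir / "sequences.fasta")
    return [outdir / "structure.pdb", outdir / "sequences.fasta"]


def _stage_simulate_links(ctx, params, outdir, seed):
    table, truth = synthetic.sample_crosslinks(
        ctx["complex"],
        n_satisfying=params.get("n_satisfying", 40),
        n_violating=params.get("n_violating", 10),
        n_decoy_protein_pairs=params.get("n_decoys", 0),
        max_distance=params.get("max_distance", 35.0),
        seed=seed,
    )
    ctx["links"] = table
    xl_io.write_crosslink_table(table, outdir / "links.tsv")
    truth.to_csv(outdir / "links_truth.tsv", sep="\t", index=False,
                 float_format="%.4f")
    return [outdir / "links.tsv", outdir / "links_truth.tsv"]


def _stage_map_links(ctx, params, outdir, seed):
    complex_truth = ctx["complex"]
    max_distance = params.get("max_distance", 35.0)
    assignment = structure_map.build_chain_assignment(
        complex_truth.structure,
        complex_truth.sequences,
        min_identity=params.get("min_identity", 0.9),
    )
    mapped = [
        structure_map.map_crosslink(
            rec, complex_truth.structure, assignment, max_distance
        )
        for rec in ctx["links"].records
    ]
    ctx["mapped"] = mapped
    report = structure_map.satisfaction_report(
        mapped, max_distance, complex_id=complex_truth.structure.id
    )
    edges, counts = structure_map.distance_distribution(
        mapped, bin_width=params.get("bin_width", 5.0)
    )
    _write_json(report.to_dict(), outdir / "distance_report.json")
    with open(outdir / "mapped_links.tsv", "w") as handle:
        handle.write(
            "protein_a\tresidue_a\tprotein_b\tresidue_b\tstatus\t"
            "chain_a\tchain_b\tdistance\tsatisfied\n"
        )
        for m in mapped:
            rec = m.record
            if m.status == "mapped":
                ca, ra, cb, rb = m.chosen_pair
                extra = f"{ca}\t{cb}\t{m.distance:.4f}\t{int(m.satisfied)}"
            else:
                extra = "\t\t\t"
            handle.write(
                f"{rec.protein_a}\t{rec.residue_a}\t{rec.protein_b}\t"
                f"{rec.residue_b}\t{m.status}\t{extra}\n"
            )
    with open(outdir / "distance_histogram.tsv", "w") as handle:
        handle.write("bin_left\tbin_right\tcount\n")
        for i, count in enumerate(counts):
            handle.write(f"{edges[i]:.1f}\t{edges[i + 1]:.1f}\t{count}\n")
    return [
        outdir / "distance_report.json",
        outdir / "mapped_links.tsv",
        outdir / "distance_histogram.tsv",
    ]


def _stage_network(ctx, params, outdir, seed):
    net = network.build_network(ctx["links"], min_links=params.get("min_links", 1))
    fmt = params.get("format", "graphml")
    suffix = {"graphml": "graphml", "sif": "sif", "tsv": "tsv"}[fmt]
    out = outdir / f"network.{suffix}"
    network.export_graph(net, out, fmt)
    network.write_residue_edge_table(net, outdir / "residue_edges.tsv")
    return [out, outdir / "residue_edges.tsv"]


def _stage_silac(ctx, params, outdir, seed):
    outputs = []
    frames = {}
    for orientation in ("forward", "reverse"):
        records, truth = synthetic.make_silac_dataset(
            n_proteins=params.get("n_proteins", 500),
            n_enriched=params.get("n_enriched", 50),
            effect_log2=params.get("effect_log2", 2.0),
            noise_sd=params.get("noise_sd", 0.25),
            n_replicates=params.get("n_replicates", 3),
            seed=seed,
            orientation=orientation,
        )
        pg_path = outdir / f"protein_groups_{orientation}.tsv"
        silac.write_protein_groups(records, pg_path)
        frame = silac.test_enrichment(records, mode=params.get("mode", "two_group"))
        frames[orientation] = frame
        enrich_path = outdir / f"enrichment_{orientation}.tsv"
        frame.drop(columns=["insufficient_replicates"]).to_csv(
            enrich_path, sep="\t", float_format="%.6g"
        )
        outputs += [pg_path, enrich_path]
    concordance = silac.label_swap_concordance(frames["forward"], frames["reverse"])
    _write_json(
        {k: v for k, v in concordance.items() if k != "pairs"},
        outdir / "label_swap.json",
    )
    ctx["silac"] = frames
    return outputs + [outdir / "label_swap.json"]


def _stage_coloc(ctx, params, outdir, seed):
    import tifffile

    channel_a, channel_b, truth = synthetic.make_coloc_images(
        size=params.get("size", 256),
        n_puncta=params.get("n_puncta", 30),
        overlap_fraction=params.get("overlap_fraction", 0.5),
        psf_sigma=params.get("psf_sigma", 2.0),
        noise_sd=params.get("noise_sd", 2.0),
        seed=seed,
    )
    tifffile.imwrite(outdir / "channel_a.tif", channel_a.pixels.astype(np.float32))
    tifffile.imwrite(outdir / "channel_b.tif", channel_b.pixels.astype(np.float32))
    mask_a = imaging.otsu_threshold(channel_a)
    mask_b = imaging.otsu_threshold(channel_b)
    result = imaging.manders(channel_a, mask_a, channel_b, mask_b)
    _write_json(
        {
            "m1": result.m1,
            "m2": result.m2,
            "n_mask_a": result.n_mask_a,
            "n_mask_b": result.n_mask_b,
            "planted_overlap": truth["overlap_fraction"],
        },
        outdir / "coloc.json",
    )
    return [outdir / "channel_a.tif", outdir / "channel_b.tif", outdir / "coloc.json"]


def _stage_membrane(ctx, params, outdir, seed):
    import tifffile

    channel, rois, truth = synthetic.make_membrane_image(
        size=params.get("size", 256),
        ring_radius=params.get("ring_radius", 60.0),
        enrichment_ratio=params.get("enrichment_ratio", 4.0),
        noise_sd=params.get("noise_sd", 1.0),
        seed=seed,
    )
    tifffile.imwrite(outdir / "membrane.tif", channel.pixels.astype(np.float32))
    synthetic.write_rois(rois, outdir / "membrane_rois.json")
    ratio = imaging.membrane_cytosol_ratio(
        channel,
        rois["membrane_polyline"],
        [(d["center"], d["radius"]) for d in rois["cytosol_disks"]],
    )
    _write_json(
        {"ratio": ratio, "planted_ratio": truth["enrichment_ratio"]},
        outdir / "membrane_ratio.json",
    )
    return [
        outdir / "membrane.tif",
        outdir / "membrane_rois.json",
        outdir / "membrane_ratio.json",
    ]


_STAGE_RUNNERS = {
    "simulate_complex": _stage_simulate_complex,
    "simulate_links": _stage_simulate_links,
    "map_links": _stage_map_links,
    "network": _stage_network,
    "silac": _stage_silac,
    "coloc": _stage_coloc,
    "membrane": _stage_membrane,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage and return the run manifest.

    The manifest holds the stage order, the parameters actually used, a
    SHA-256 checksum per output file, and accumulated warnings.  Identical
    config and seed give identical checksums; a stage failure aborts the
    run with the failing stage named.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ctx: dict = {}
    manifest: dict = {"seed": config.seed, "stages": [], "warnings": []}
    for stage in config.stages:
        name = stage["name"]
        params = stage.get("params") or {}
        runner = _STAGE_RUNNERS[name]
        try:
            outputs = runner(ctx, params, outdir, config.seed)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"].append(
            {
                "name": name,
                "params": params,
                "outputs": {p.name: _sha256(p) for p in outputs},
            }
        )
    links = ctx.get("links")
    if links is not None:
        manifest["warnings"].extend(links.warnings)
    _write_json(manifest, outdir / "manifest.json")
    return manifest
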