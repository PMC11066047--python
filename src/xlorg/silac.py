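"""SILAC enrichment statistics for pull-down and organelle proteomics.

Heavy/light intensity ratios quantify relative protein abundance between
two metabolically labelled conditions.  Per protein, the log2 ratio is
median-normalized per replicate, a two-tailed Student's t-test assesses
enrichment, and p-values are annotated in three significance tiers
(red p < 1e-14, orange p < 1e-4, dark blue p < 0.05).  Label-swap
repetitions (heavy and light strains exchanged) provide an orthogonal
specificity check: true enrichment flips sign with the labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProteinGroupRecord",
    "TIER_THRESHOLDS",
    "compute_log_ratios",
    "test_enrichment",
    "tier_significance",
    "label_swap_concordance",
    "benjamini_hochberg",
]

#: Significance tiers (name, strict upper p bound), most stringent first.
TIER_THRESHOLDS = (("red", 1e-14), ("orange", 1e-4), ("blue", 0.05))


@dataclass
class ProteinGroupRecord:
    """Per-protein SILAC channel intensities across replicates."""

    protein_id: str
    heavy: list[float]  # per-replicate heavy-channel intensity, arbitrary units
    light: list[float]
    peptide_count: int = 1

    def __post_init__(self) -> None:
        if len(self.heavy) != len(self.light):
            raise ValueError(
                f"{self.protein_id}: heavy and light replicate counts differ"
            )
        if any(v < 0 for v in self.heavy + self.light):
            raise ValueError(f"{self.protein_id}: negative intensity")

    @property
    def n_replicates(self) -> int:
        return len(self.heavy)

    def computable_replicates(self) -> list[int]:
        """Replicates where both channels are quantified (> 0).

        Zero-intensity channels make a replicate non-computable — no
        pseudocounts, mirroring disabled re-quantification in the
        upstream search.
        """
        return [
            i
            for i in range(self.n_replicates)
            if self.heavy[i] > 0 and self.light[i] > 0
        ]


def compute_log_ratios(
    records: Sequence[ProteinGroupRecord],
    normalization: Literal["median", "none"] = "median",
) -> pd.DataFrame:
    """Per-protein log2(H/L) ratios per replicate plus log10 total intensity.

    With median normalization, the per-replicate median of log2 ratios
    across proteins is subtracted, so each replicate's median ratio is 0
    (corrects unequal mixing of the two labelled cultures).  Proteins with
    no computable replicate are excluded (their ids are recorded in
    ``DataFrame.attrs['excluded']``).
    """
    if normalization not in ("median", "none"):
        raise ValueError(f"unknown normalization {normalization!r}")
    n_rep = max((r.n_replicates for r in records), default=0)
    rows, excluded = [], []
    for rec in records:
        usable = rec.computable_replicates()
        if not usable:
            excluded.append(rec.protein_id)
            continue
        ratios = [
            np.log2(rec.heavy[i] / rec.light[i]) if i in usable else np.nan
            for i in range(n_rep)
        ]
        intensity = sum(rec.heavy) + sum(rec.light)
        rows.append([rec.protein_id, np.log10(intensity)] + ratios)
    columns = ["protein_id", "log10_intensity"] + [
        f"log2_ratio_{i + 1}" for i in range(n_rep)
    ]
    frame = pd.DataFrame(rows, columns=columns).set_index("protein_id")
    ratio_cols = columns[2:]
    if normalization == "median" and not frame.empty:
        frame[ratio_cols] = frame[ratio_cols] - frame[ratio_cols].median(axis=0)
    frame["log2_ratio"] = frame[ratio_cols].mean(axis=1)
    frame.attrs["excluded"] = excluded
    frame.attrs["normalization"] = normalization
    return frame


def _two_group_p(rec: ProteinGroupRecord) -> tuple[float, int]:
    """Equal-variance two-tailed t-test of log heavy vs log light intensities."""
    usable = rec.computable_replicates()
    if len(usable) < 2:
        return np.nan, len(usable)
    heavy = np.log10([rec.heavy[i] for i in usable])
    light = np.log10([rec.light[i] for i in usable])
    t, p = stats.ttest_ind(heavy, light, equal_var=True)
    return float(p), len(usable)


def _one_sample_p(log2_ratios: np.ndarray) -> tuple[float, int]:
    """Two-tailed one-sample t-test of replicate log2 ratios against 0."""
    values = log2_ratios[~np.isnan(log2_ratios)]
    if values.size < 2:
        return np.nan, int(values.size)
    t, p = stats.ttest_1samp(values, 0.0)
    return float(p), int(values.size)


def test_enrichment(
    records: Sequence[ProteinGroupRecord],
    mode: Literal["two_group", "one_sample"] = "two_group",
    normalization: Literal["median", "none"] = "median",
) -> pd.DataFrame:
    """Per-protein enrichment statistics and significance tiers.

    ``two_group`` tests log heavy-channel against log light-channel
    intensities across replicates (equal-variance Student's t, two-tailed);
    ``one_sample`` tests replicate log2 ratios against 0.  Proteins with
    fewer than two computable replicates receive no p-value and tier
    ``ns`` with the ``insufficient_replicates`` flag.  A Benjamini–
    Hochberg q-value column is included for reference but never gates the
    tiers, which follow the raw-p thresholds.
    """
    if mode not in ("two_group", "one_sample"):
        raise ValueError(f"unknown test mode {mode!r}")
    ratios = compute_log_ratios(records, normalization=normalization)
    ratio_cols = [c for c in ratios.columns if c.startswith("log2_ratio_")]
    results = []
    for rec in records:
        if rec.protein_id not in ratios.index:
            continue
        if mode == "two_group":
            p, n_used = _two_group_p(rec)
        else:
            p, n_used = _one_sample_p(
                ratios.loc[rec.protein_id, ratio_cols].to_numpy(dtype=float)
            )
        results.append(
            {
                "protein_id": rec.protein_id,
                "log2_ratio": ratios.loc[rec.protein_id, "log2_ratio"],
                "log10_intensity": ratios.loc[rec.protein_id, "log10_intensity"],
                "p_value": p,
                "n_replicates_used": n_used,
                "insufficient_replicates": n_used < 2,
            }
        )
    frame = pd.DataFrame(results).set_index("protein_id")
    frame["tier"] = tier_significance(frame["p_value"].to_numpy())
    frame["q_value"] = benjamini_hochberg(frame["p_value"].to_numpy())
    frame.attrs["mode"] = mode
    frame.attrs["excluded"] = ratios.attrs["excluded"]
    return frame


def tier_significance(p_values: np.ndarray) -> list[str]:
    """Map p-values to the tier labels (strict upper bounds, exhaustive).

    red: p < 1e-14; orange: 1e-14 <= p < 1e-4; blue: 1e-4 <= p < 0.05;
    ns otherwise (including missing p).
    """
    tiers = []
    for p in np.asarray(p_values, dtype=float):
        if np.isnan(p):
            tiers.append("ns")
            continue
        for name, bound in TIER_THRESHOLDS:
            if p < bound:
                tiers.append(name)
                break
        else:
            tiers.append("ns")
    return tiers


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (NaNs passed through)."""
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        q[mask] = stats.false_discovery_control(p[mask], method="bh")
    return q


def write_protein_groups(records: Sequence[ProteinGroupRecord], path) -> None:
    """Write the wide protein-groups TSV layout (heavy_i/light_i columns)."""
    n_rep = max((r.n_replicates for r in records), default=0)
    columns = (
        ["protein_id"]
        + [f"heavy_{i + 1}" for i in range(n_rep)]
        + [f"light_{i + 1}" for i in range(n_rep)]
        + ["peptide_count"]
    )
    rows = []
    for rec in records:
        heavy = list(rec.heavy) + [np.nan] * (n_rep - rec.n_replicates)
        light = list(rec.light) + [np.nan] * (n_rep - rec.n_replicates)
        rows.append([rec.protein_id] + heavy + light + [rec.peptide_count])
    pd.DataFrame(rows, columns=columns).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_protein_groups(
    path, column_map: dict | None = None
) -> list[ProteinGroupRecord]:
    """Read a wide protein-groups TSV into records.

    ``column_map`` can rename ``protein_id`` and ``peptide_count`` and
    supply explicit heavy/light column lists
    (``{"heavy": [...], "light": [...]}``); by default columns named
    ``heavy_i`` / ``light_i`` are paired in numeric order.
    """
    column_map = column_map or {}
    frame = pd.read_csv(path, sep="\t")
    id_col = column_map.get("protein_id", "protein_id")
    heavy_cols = column_map.get(
        "heavy", sorted((c for c in frame.columns if c.startswith("heavy_")),
                        key=lambda c: int(c.split("_")[-1]))
    )
    light_cols = column_map.get(
        "light", sorted((c for c in frame.columns if c.startswith("light_")),
                        key=lambda c: int(c.split("_")[-1]))
    )
    if not heavy_cols or len(heavy_cols) != len(light_cols):
        raise ValueError("heavy/light replicate columns missing or unpaired")
    pep_col = column_map.get("peptide_count", "peptide_count")
    records = []
    for _, row in frame.iterrows():
        records.append(
            ProteinGroupRecord(
                str(row[id_col]),
                [0.0 if pd.isna(v) else float(v) for v in row[heavy_cols]],
                [0.0 if pd.isna(v) else float(v) for v in row[light_cols]],
                peptide_count=int(row[pep_col]) if pep_col in frame.columns else 1,
            )
        )
    return records


def label_swap_concordance(
    forward: pd.DataFrame, reverse: pd.DataFrame
) -> dict:
    """Concordance between forward and label-swapped enrichment runs.

    The reverse run's log2 ratios are sign-flipped (the labels are
    exchanged, so true enrichment appears with opposite sign) and compared
    to the forward run over shared proteins: Pearson r of forward log2
    versus −reverse log2, plus the fraction of proteins whose enrichment
    sign agrees.  Proteins missing from either run are excluded and
    counted.  Requires at least 3 shared proteins.
    """
    shared = forward.index.intersection(reverse.index)
    n_only_forward = len(forward.index.difference(reverse.index))
    n_only_reverse = len(reverse.index.difference(forward.index))
    if len(shared) < 3:
        raise ValueError(
            f"label-swap concordance needs >=3 shared proteins, got {len(shared)}"
        )
    fwd = forward.loc[shared, "log2_ratio"].to_numpy(dtype=float)
    rev_flipped = -reverse.loc[shared, "log2_ratio"].to_numpy(dtype=float)
    r = float(stats.pearsonr(fwd, rev_flipped).statistic)
    sign_agreement = float(np.mean(np.sign(fwd) == np.sign(rev_flipped)))
    return {
        "n_shared": int(len(shared)),
        "n_only_forward": n_only_forward,
        "n_only_reverse": n_only_reverse,
        "pearson_r": r,
        "sign_agreement": sign_agreement,
        "pairs": pd.DataFrame(
            {"forward_log2": fwd, "reverse_log2_flipped": rev_flipped}, index=shared
        ),
    }
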