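"""Cross-link identification tables: parsing, filtering, deduplication, classification.

The unit of the pipeline is a residue pair — two lysines, one on each
protein, bridged by the cross-linker.  Search engines report one row per
cross-link spectrum match (CSM) or per unique residue pair; this module
canonicalizes those rows so every downstream stage sees one deterministic
representation per pair.

Conventions
-----------
* Residue numbers are 1-based positions in the protein sequence (UniProt
  convention).
* A record's endpoints are stored in lexicographic order by
  ``(accession, residue)``, so ``A:K10 – B:K20`` and ``B:K20 – A:K10``
  canonicalize identically.
* FDR is a fraction in [0, 1].  Supplementary tables sometimes report
  percent; a dialect flag permits auto-rescaling when the column maximum
  exceeds 1.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

__all__ = [
    "CrossLinkRecord",
    "CrossLinkTable",
    "ColumnMapError",
    "TableParseError",
    "parse_crosslink_table",
    "write_crosslink_table",
    "filter_fdr",
    "deduplicate_unique_pairs",
    "classify_links",
]

#: Stable column order of the canonical cross-link TSV dialect.
CANONICAL_COLUMNS = (
    "protein_a",
    "residue_a",
    "protein_b",
    "residue_b",
    "score",
    "fdr",
    "csm_count",
)

MANDATORY_FIELDS = ("protein_a", "residue_a", "protein_b", "residue_b")


class ColumnMapError(ValueError):
    """A mandatory column is missing from the file or the column map."""


class TableParseError(ValueError):
    """A row could not be converted into a record; carries the line number."""


@dataclass(frozen=True)
class CrossLinkRecord:
    """One unique lysine–lysine connection (canonicalized endpoint order)."""

    protein_a: str
    residue_a: int
    protein_b: str
    residue_b: int
    score: float | None = None
    fdr: float | None = None
    csm_count: int = 1

    def __post_init__(self) -> None:
        if self.residue_a < 1 or self.residue_b < 1:
            raise ValueError(
                f"residue positions must be >= 1, got "
                f"{self.residue_a}/{self.residue_b}"
            )
        if self.fdr is not None and not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"fdr must lie in [0, 1], got {self.fdr}")
        if self.csm_count < 1:
            raise ValueError(f"csm_count must be >= 1, got {self.csm_count}")
        # canonical endpoint order: lexicographic by (accession, residue)
        if (self.protein_b, self.residue_b) < (self.protein_a, self.residue_a):
            pa, ra = self.protein_a, self.residue_a
            object.__setattr__(self, "protein_a", self.protein_b)
            object.__setattr__(self, "residue_a", self.residue_b)
            object.__setattr__(self, "protein_b", pa)
            object.__setattr__(self, "residue_b", ra)

    @property
    def pair_key(self) -> tuple[str, int, str, int]:
        return (self.protein_a, self.residue_a, self.protein_b, self.residue_b)

    @property
    def is_intra(self) -> bool:
        return self.protein_a == self.protein_b


#: Alias kept for symmetry with the parser's record construction path.
make_record = CrossLinkRecord


@dataclass
class CrossLinkTable:
    """An ordered collection of cross-link records plus provenance metadata."""

    records: list[CrossLinkRecord] = field(default_factory=list)
    source: str = ""
    fdr_threshold: float | None = None
    deduplicated: bool = False
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CrossLinkTable):
            return NotImplemented
        return self.records == other.records


def _parse_float(value: str) -> float | None:
    value = value.strip()
    return float(value) if value else None


def _first_accession(value: str) -> tuple[str, bool]:
    """Split a possibly multi-accession field; return (first, was_ambiguous)."""
    for sep in (";", ","):
        if sep in value:
            return value.split(sep)[0].strip(), True
    return value.strip(), False


def parse_crosslink_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    delimiter: str | None = None,
    fdr_percent_autodetect: bool = False,
) -> CrossLinkTable:
    """Read a TSV/CSV cross-link table into canonical records.

    Parameters
    ----------
    path
        Delimited text file, one row per cross-link (CSM or unique pair).
    column_map
        Maps canonical field names (``protein_a``, ``residue_a``,
        ``protein_b``, ``residue_b`` and optionally ``score``, ``fdr``,
        ``csm_count``) to the header names used in the file.  Identity
        mapping by default.
    delimiter
        Forced delimiter; sniffed from the header line when ``None``.
    fdr_percent_autodetect
        When set and the FDR column maximum exceeds 1, values are treated
        as percent and divided by 100.

    Raises
    ------
    ColumnMapError
        A mandatory endpoint column is absent.
    TableParseError
        A row has a non-integer residue or unreadable numeric field; the
        message carries the 1-based line number.
    """
    path = Path(path)
    column_map = dict(column_map or {})
    with open(path, newline="") as handle:
        header_line = handle.readline()
        if delimiter is None:
            delimiter = "\t" if "\t" in header_line else ","
        header = next(csv.reader([header_line], delimiter=delimiter))
        for fieldname in MANDATORY_FIELDS:
            col = column_map.get(fieldname, fieldname)
            if col not in header:
                raise ColumnMapError(
                    f"mandatory column {fieldname!r} (mapped to {col!r}) "
                    f"not found in header of {path.name}"
                )
        idx = {
            fieldname: header.index(column_map.get(fieldname, fieldname))
            for fieldname in CANONICAL_COLUMNS
            if column_map.get(fieldname, fieldname) in header
        }
        raw_rows: list[dict] = []
        warnings: list[str] = []
        reader = csv.reader(handle, delimiter=delimiter)
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            try:
                pa, amb_a = _first_accession(row[idx["protein_a"]])
                pb, amb_b = _first_accession(row[idx["protein_b"]])
                raw = {
                    "protein_a": pa,
                    "residue_a": int(row[idx["residue_a"]]),
                    "protein_b": pb,
                    "residue_b": int(row[idx["residue_b"]]),
                    "score": _parse_float(row[idx["score"]])
                    if "score" in idx
                    else None,
                    "fdr": _parse_float(row[idx["fdr"]]) if "fdr" in idx else None,
                    "csm_count": int(row[idx["csm_count"]])
                    if "csm_count" in idx and row[idx["csm_count"]].strip()
                    else 1,
                }
            except (ValueError, IndexError) as exc:
                raise TableParseError(
                    f"{path.name}, line {lineno}: {exc}"
                ) from exc
            if amb_a or amb_b:
                warnings.append(
                    f"line {lineno}: multi-accession field, first accession kept"
                )
            raw_rows.append(raw)

    fdr_values = [r["fdr"] for r in raw_rows if r["fdr"] is not None]
    if fdr_percent_autodetect and fdr_values and max(fdr_values) > 1.0:
        for raw in raw_rows:
            if raw["fdr"] is not None:
                raw["fdr"] = raw["fdr"] / 100.0
        warnings.append("fdr column interpreted as percent and rescaled to fraction")

    records = [make_record(**raw) for raw in raw_rows]
    return CrossLinkTable(records=records, source=path.name, warnings=warnings)


def _format_optional(value: float | None) -> str:
    if value is None:
        return ""
    return format(value, "g")


def write_crosslink_table(table: CrossLinkTable, path: str | Path) -> None:
    """Write the canonical cross-link TSV dialect (stable column order)."""
    path = Path(path)
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(CANONICAL_COLUMNS)
        for rec in table.records:
            writer.writerow(
                [
                    rec.protein_a,
                    rec.residue_a,
                    rec.protein_b,
                    rec.residue_b,
                    _format_optional(rec.score),
                    _format_optional(rec.fdr),
                    rec.csm_count,
                ]
            )


def filter_fdr(
    table: CrossLinkTable, threshold: float, *, permissive: bool = False
) -> CrossLinkTable:
    """Retain records with ``fdr <= threshold`` (inclusive boundary).

    Records lacking an FDR raise unless ``permissive`` is set, in which
    case they are kept and counted in the table warnings.
    """
    missing = sum(1 for rec in table.records if rec.fdr is None)
    if missing and not permissive:
        raise ValueError(
            f"{missing} records lack an fdr value; pass permissive=True to keep them"
        )
    kept = [
        rec
        for rec in table.records
        if rec.fdr is None or rec.fdr <= threshold
    ]
    warnings = list(table.warnings)
    if missing:
        warnings.append(f"{missing} records without fdr kept (permissive)")
    return CrossLinkTable(
        records=kept,
        source=table.source,
        fdr_threshold=threshold,
        deduplicated=table.deduplicated,
        warnings=warnings,
    )


def deduplicate_unique_pairs(table: CrossLinkTable) -> CrossLinkTable:
    """Collapse to one record per canonical endpoint pair.

    CSM counts are summed across collapsed rows; the best (lowest) FDR and
    the best (highest) score among duplicates are retained.
    """
    merged: dict[tuple, CrossLinkRecord] = {}
    for rec in table.records:
        prev = merged.get(rec.pair_key)
        if prev is None:
            merged[rec.pair_key] = rec
        else:
            score = (
                max(prev.score, rec.score)
                if prev.score is not None and rec.score is not None
                else prev.score if rec.score is None else rec.score
            )
            fdr = (
                min(prev.fdr, rec.fdr)
                if prev.fdr is not None and rec.fdr is not None
                else prev.fdr if rec.fdr is None else rec.fdr
            )
            merged[rec.pair_key] = replace(
                prev,
                score=score,
                fdr=fdr,
                csm_count=prev.csm_count + rec.csm_count,
            )
    return CrossLinkTable(
        records=list(merged.values()),
        source=table.source,
        fdr_threshold=table.fdr_threshold,
        deduplicated=True,
        warnings=list(table.warnings),
    )


def classify_links(table: CrossLinkTable) -> dict[str, int]:
    """Split a deduplicated table into intra-/inter-protein counts.

    Returns ``{"n_total", "n_intra", "n_inter", "n_proteins"}`` where
    intra means both endpoints lie on the same accession and n_proteins
    counts distinct accessions over all endpoints.
    """
    if not table.deduplicated:
        raise ValueError("classify_links expects a deduplicated table")
    n_intra = sum(1 for rec in table.records if rec.is_intra)
    proteins: set[str] = set()
    for rec in table.records:
        proteins.add(rec.protein_a)
        proteins.add(rec.protein_b)
    return {
        "n_total": len(table.records),
        "n_intra": n_intra,
        "n_inter": len(table.records) - n_intra,
        "n_proteins": len(proteins),
    }
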