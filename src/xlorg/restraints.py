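"""Docking restraint export and cross-link-based model ranking.

Cross-links are exported as unambiguous Cα–Cα distance restraints in the
``assign``-statement dialect consumed by integrative docking engines, and
candidate docked models are ranked by how many cross-links they satisfy
under the linker's maximum distance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from .structure_map import (
    DSBSO_MAX_DISTANCE,
    ChainAssignment,
    StructureModel,
    map_crosslink,
)
from .xl_io import CrossLinkRecord, CrossLinkTable

__all__ = [
    "Restraint",
    "ModelScore",
    "export_restraints",
    "parse_restraints",
    "score_model",
    "rank_models",
]

RESTRAINT_LINE = (
    "assign (segid {chain_a} and resid {residue_a} and name CA) "
    "(segid {chain_b} and resid {residue_b} and name CA) "
    "{target:.1f} {lower:.1f} {upper:.1f}"
)

_RESTRAINT_RE = re.compile(
    r"assign \(segid (?P<chain_a>\S+) and resid (?P<residue_a>\d+) and name CA\) "
    r"\(segid (?P<chain_b>\S+) and resid (?P<residue_b>\d+) and name CA\) "
    r"(?P<target>[\d.]+) (?P<lower>[\d.]+) (?P<upper>[\d.]+)"
)


@dataclass(frozen=True)
class Restraint:
    """One unambiguous Cα–Cα distance restraint.

    The allowed band is ``[target - lower, target + upper]``; the default
    geometry (target 35, lower 35, upper 0) encodes "anything up to 35 Å
    satisfies" for a lysine-reactive cross-linker.
    """

    chain_a: str
    residue_a: int
    chain_b: str
    residue_b: int
    target: float = DSBSO_MAX_DISTANCE
    lower: float = DSBSO_MAX_DISTANCE
    upper: float = 0.0

    def __post_init__(self) -> None:
        if self.target <= 0:
            raise ValueError("restraint target must be positive")
        if self.lower < 0 or self.upper < 0:
            raise ValueError("restraint margins must be non-negative")

    def to_line(self) -> str:
        return RESTRAINT_LINE.format(
            chain_a=self.chain_a,
            residue_a=self.residue_a,
            chain_b=self.chain_b,
            residue_b=self.residue_b,
            target=self.target,
            lower=self.lower,
            upper=self.upper,
        )


def export_restraints(
    links: CrossLinkTable,
    assignment: ChainAssignment,
    target: float = DSBSO_MAX_DISTANCE,
    lower: float = DSBSO_MAX_DISTANCE,
    upper: float = 0.0,
) -> tuple[str, list[Restraint], list[str]]:
    """Render cross-links as unambiguous restraint text.

    Docking restraints must name exactly one (chain, residue) per
    endpoint, so for proteins present in several chain copies the first
    chain in canonical (sorted) order is used; this choice is recorded in
    the returned warnings.  Links whose endpoints cannot be resolved are
    skipped with a warning.  Returns ``(text, restraints, warnings)``;
    raises if no link is resolvable.
    """
    restraints: list[Restraint] = []
    warnings: list[str] = []
    ordered = sorted(links.records, key=lambda r: r.pair_key)
    for rec in ordered:
        endpoints = []
        resolvable = True
        for accession, residue in (
            (rec.protein_a, rec.residue_a),
            (rec.protein_b, rec.residue_b),
        ):
            chains = assignment.chains_for(accession)
            placements = [
                (chain_id, residue_map[residue])
                for chain_id, residue_map in chains
                if residue in residue_map
            ]
            if not placements:
                warnings.append(
                    f"link {rec.pair_key}: endpoint {accession}:{residue} "
                    f"unresolvable, link skipped"
                )
                resolvable = False
                break
            placements.sort()
            if len(placements) > 1:
                warnings.append(
                    f"link {rec.pair_key}: endpoint {accession}:{residue} maps "
                    f"to {len(placements)} copies, using chain {placements[0][0]}"
                )
            endpoints.append(placements[0])
        if not resolvable:
            continue
        (ca, ra), (cb, rb) = endpoints
        restraints.append(Restraint(ca, ra, cb, rb, target, lower, upper))
    if not restraints:
        raise ValueError("no cross-link could be resolved into a restraint")
    text = "\n".join(r.to_line() for r in restraints) + "\n"
    return text, restraints, warnings


def parse_restraints(text: str) -> list[Restraint]:
    """Parse restraint text written by :func:`export_restraints` (round-trip)."""
    restraints = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("!"):
            continue
        match = _RESTRAINT_RE.fullmatch(line)
        if match is None:
            raise ValueError(f"unparseable restraint on line {lineno}: {line!r}")
        g = match.groupdict()
        restraints.append(
            Restraint(
                g["chain_a"],
                int(g["residue_a"]),
                g["chain_b"],
                int(g["residue_b"]),
                float(g["target"]),
                float(g["lower"]),
                float(g["upper"]),
            )
        )
    return restraints


@dataclass(frozen=True)
class ModelScore:
    """Cross-link agreement of one docked model."""

    model_id: str
    n_evaluated: int
    n_satisfied: int
    sum_violation: float  # Σ max(0, d − max_distance) over evaluated links, Å
    max_violation: float

    def __post_init__(self) -> None:
        if self.n_satisfied > self.n_evaluated:
            raise ValueError("n_satisfied cannot exceed n_evaluated")
        if self.sum_violation < 0:
            raise ValueError("sum_violation must be non-negative")


def score_model(
    structure: StructureModel,
    links: CrossLinkTable,
    assignment: ChainAssignment,
    max_distance: float = DSBSO_MAX_DISTANCE,
) -> ModelScore:
    """Score one docked model by cross-link agreement.

    Each link is placed with the min-over-copies rule; only links that map
    are evaluated.  Violations are measured beyond ``max_distance``.
    """
    n_evaluated = 0
    n_satisfied = 0
    sum_violation = 0.0
    max_violation = 0.0
    for rec in links.records:
        mapped = map_crosslink(rec, structure, assignment, max_distance)
        if mapped.status != "mapped":
            continue
        n_evaluated += 1
        violation = max(0.0, mapped.distance - max_distance)
        if violation == 0.0:
            n_satisfied += 1
        sum_violation += violation
        max_violation = max(max_violation, violation)
    return ModelScore(
        model_id=structure.id,
        n_evaluated=n_evaluated,
        n_satisfied=n_satisfied,
        sum_violation=sum_violation,
        max_violation=max_violation,
    )


def rank_models(scores: Sequence[ModelScore]) -> list[ModelScore]:
    """Order models by cross-link agreement (best first, total order).

    Sort key: satisfied count descending, then total violation ascending,
    then model id ascending — deterministic under any input permutation.
    """
    if not scores:
        raise ValueError("cannot rank an empty list of model scores")
    return sorted(
        scores, key=lambda s: (-s.n_satisfied, s.sum_violation, s.model_id)
    )
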