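"""Set algebra over the detection matrix.

Per-method and per-solubility totals, pairwise and k-way overlaps,
exclusivity percentages and full Venn-region tallies. Percentages are
reported to one decimal place with half-up rounding against the curated
total (or a supplied denominator).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

from .evidence import DetectionMatrix

#: The two protocol families compared by the study.
DEFAULT_METHOD_GROUPS: dict[str, tuple[str, ...]] = {
    "CF_combined": ("CF2", "CF4"),
    "ACT_combined": ("ACT1", "ACT3"),
}


def percent(count: int, total: int) -> float:
    """100 * count / total, rounded half-up to one decimal place."""
    if total == 0:
        return 0.0
    value = Decimal(count) * Decimal(100) / Decimal(total)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class FractionSummary:
    """Counts, overlaps and percentages for one family of protein sets.

    ``totals`` maps set labels (and derived labels such as ``union`` or
    ``<label>_exclusive``) to protein counts; ``overlaps`` maps tuples of
    labels to intersection counts; ``regions`` maps tuples of labels to
    exact Venn-region counts (in exactly those sets and no others);
    ``percentages`` mirrors ``totals`` keys against the reference total.
    """

    totals: dict[str, int] = field(default_factory=dict)
    overlaps: dict[tuple[str, ...], int] = field(default_factory=dict)
    regions: dict[tuple[str, ...], int] = field(default_factory=dict)
    percentages: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        """JSON-serializable form (tuple keys joined with '&')."""
        return {
            "totals": dict(sorted(self.totals.items())),
            "overlaps": {"&".join(k): v for k, v in sorted(self.overlaps.items())},
            "regions": {"&".join(k): v for k, v in sorted(self.regions.items())},
            "percentages": dict(sorted(self.percentages.items())),
        }


def combine_methods(
    matrix: DetectionMatrix,
    groups: Mapping[str, Iterable[str]] = DEFAULT_METHOD_GROUPS,
) -> dict[str, set[str]]:
    """Pool methods into labelled groups; a protein belongs to a group when it
    has a true cell in any of the group's methods, either solubility."""
    return {
        label: matrix.proteins_in_methods(methods) for label, methods in groups.items()
    }


def venn_counts(
    sets: Mapping[str, set[str]],
    total: int | None = None,
) -> FractionSummary:
    """Region counts, unions, exclusives and percentages for 2-4 named sets.

    Percentages are computed against ``total`` when given, else against the
    union size.
    """
    labels = list(sets)
    if not 1 <= len(labels) <= 4:
        raise ValueError("venn_counts expects between 1 and 4 named sets")

    union: set[str] = set().union(*sets.values())
    denominator = total if total is not None else len(union)

    summary = FractionSummary()
    summary.totals["union"] = len(union)
    for label in labels:
        summary.totals[label] = len(sets[label])
        others: set[str] = set().union(
            *(sets[l] for l in labels if l != label), set()
        )
        summary.totals[f"{label}_exclusive"] = len(sets[label] - others)

    # exact Venn regions: elements in all sets of the tuple and no others
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            inside: set[str] = set.intersection(*(sets[l] for l in combo))
            outside: set[str] = set().union(
                *(sets[l] for l in labels if l not in combo), set()
            )
            summary.regions[combo] = len(inside - outside)
            if r >= 2:
                summary.overlaps[combo] = len(inside)

    for key, value in summary.totals.items():
        summary.percentages[key] = percent(value, denominator)
    for combo, value in summary.overlaps.items():
        summary.percentages["&".join(combo)] = percent(value, denominator)
    return summary


def solubility_summary(matrix: DetectionMatrix, total: int | None = None) -> FractionSummary:
    """SSOM/ISOM totals, intersection and exclusives over the detection matrix."""
    ssom = matrix.proteins_in_solubility("SSOM")
    isom = matrix.proteins_in_solubility("ISOM")
    summary = venn_counts({"SSOM_all": ssom, "ISOM_all": isom}, total=total)
    summary.totals["both"] = summary.overlaps[("SSOM_all", "ISOM_all")]
    summary.percentages["both"] = summary.percentages["SSOM_all&ISOM_all"]
    return summary


def method_summary(
    matrix: DetectionMatrix,
    groups: Mapping[str, Iterable[str]] = DEFAULT_METHOD_GROUPS,
    total: int | None = None,
) -> FractionSummary:
    """Venn summary over pooled method groups (e.g. combined CF vs combined ACT)."""
    summary = venn_counts(combine_methods(matrix, groups), total=total)
    # per-method and per-cell totals alongside the pooled groups
    from .io_tables import FRACTIONS, METHODS

    for method in METHODS:
        summary.totals[method] = len(matrix.proteins_in_methods([method]))
    for method, solubility in FRACTIONS:
        col = f"{method}_{solubility}"
        if matrix.table.empty:
            summary.totals[col] = 0
        else:
            summary.totals[col] = int(matrix.table[col].sum())
    return summary
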