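"""Cross-proteome orthology overlap and its enrichment test.

The curated skeletal proteome is compared against previously published
skeletal proteomes through ortholog-pair tables (orthogroup pairs of every
multiplicity plus best BLASTP hits all count equally for set membership).
Whether the observed overlap exceeds chance is tested with the exact
upper-tail binomial probability (background given as a proportion of
skeletal matrix proteins in the reference proteomes) or the exact
hypergeometric tail (background given as counts); no normal approximation
is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from scipy import stats

from .io_tables import OrthologPair


@dataclass
class OverlapResult:
    """Ortholog-overlap sets and, optionally, the enrichment statistics."""

    per_proteome: dict[str, set[str]] = field(default_factory=dict)
    any_overlap: set[str] = field(default_factory=set)
    all_overlap: set[str] = field(default_factory=set)
    enrichment: dict | None = None

    def to_dict(self) -> dict:
        payload = {
            "per_proteome": {
                label: sorted(members) for label, members in sorted(self.per_proteome.items())
            },
            "per_proteome_counts": {
                label: len(members) for label, members in sorted(self.per_proteome.items())
            },
            "any_overlap": sorted(self.any_overlap),
            "any_overlap_count": len(self.any_overlap),
            "all_overlap": sorted(self.all_overlap),
            "all_overlap_count": len(self.all_overlap),
        }
        if self.enrichment is not None:
            payload["enrichment"] = self.enrichment
        return payload


def map_orthologs(
    curated: Iterable[str],
    pairs: Iterable[OrthologPair],
    proteomes: Iterable[str],
) -> OverlapResult:
    """Plain set algebra over pair endpoints restricted to curated accessions.

    ``any_overlap`` is the union over configured proteomes, ``all_overlap``
    the intersection (curated proteins with an ortholog in *every* proteome).
    """
    curated_set = set(curated)
    labels = sorted(set(proteomes))
    per_proteome: dict[str, set[str]] = {label: set() for label in labels}
    for pair in pairs:
        if pair.other_proteome not in per_proteome:
            raise KeyError(
                f"pair references unconfigured proteome label {pair.other_proteome!r}"
            )
        if pair.target_accession in curated_set:
            per_proteome[pair.other_proteome].add(pair.target_accession)
    any_overlap: set[str] = set().union(*per_proteome.values(), set())
    all_overlap = (
        set.intersection(*per_proteome.values()) if per_proteome else set()
    )
    return OverlapResult(
        per_proteome=per_proteome, any_overlap=any_overlap, all_overlap=all_overlap
    )


def enrichment_test(
    k: int,
    n: int,
    p: float | None = None,
    background_counts: tuple[int, int] | None = None,
) -> float:
    """Exact one-sided (upper-tail) probability of observing >= k overlaps.

    With a background *proportion* ``p``, the tail of Binomial(n, p); with
    ``background_counts=(K, N)`` (K known skeletal proteins among N reference
    proteins), the tail of Hypergeometric(N, K, n). Exact tail evaluation,
    no normal approximation.
    """
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if (p is None) == (background_counts is None):
        raise ValueError("give exactly one of p or background_counts")
    if k == 0:
        return 1.0
    if p is not None:
        if not 0 < p < 1:
            raise ValueError(f"require 0 < p < 1, got p={p}")
        return float(stats.binom.sf(k - 1, n, p))
    K, N = background_counts
    if not 0 <= K <= N:
        raise ValueError(f"require 0 <= K <= N, got K={K}, N={N}")
    if n > N:
        raise ValueError(f"sample n={n} exceeds population N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def overlap_with_enrichment(
    curated: Iterable[str],
    pairs: Iterable[OrthologPair],
    proteomes: Iterable[str],
    background_p: float | None = 0.002,
    background_counts: tuple[int, int] | None = None,
) -> OverlapResult:
    """Map orthologs and attach enrichment p-values for the any-proteome overlap."""
    curated_set = set(curated)
    result = map_orthologs(curated_set, pairs, proteomes)
    k = len(result.any_overlap)
    n = len(curated_set)
    enrichment: dict = {"observed_k": k, "sample_n": n}
    if n > 0 and background_p is not None:
        enrichment["background_p"] = background_p
        enrichment["p_value_binomial"] = enrichment_test(k, n, p=background_p)
    if n > 0 and background_counts is not None:
        K, N = background_counts
        enrichment["background_counts"] = {"K": K, "N": N}
        enrichment["p_value_hypergeometric"] = enrichment_test(
            k, n, background_counts=(K, N)
        )
    result.enrichment = enrichment
    return result
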