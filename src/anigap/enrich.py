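"""Category enrichment among genes not shared between close genome pairs.

Tests whether the genes that differ between very close pairs (ANI above
99.8%) are enriched in hypothetical/mobile functions relative to the
genes that differ between more divergent pairs of the same species,
using a pooled two-proportion z-test.  Non-shared gene occurrences are
counted once per pair by default (a gene differing in several pairs
contributes once per pair); a unique-gene counting mode is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .ani import AniPair, GeneShare
from .simulate import MOBILE


@dataclass(frozen=True)
class CategoryCounts:
    k_mobile: int
    n_total: int

    @property
    def proportion(self) -> float | None:
        return self.k_mobile / self.n_total if self.n_total else None


@dataclass(frozen=True)
class EnrichmentResult:
    close: CategoryCounts
    divergent: CategoryCounts
    pooled: float
    z: float | None
    p_value: float | None


def collect_nonshared(
    pairs: list[AniPair],
    gene_shares: dict[tuple[str, str], GeneShare],
    close_min: float = 99.8,
    divergent_max: float = 99.8,
    divergent_min: float = 96.0,
    unique_genes: bool = False,
) -> tuple[CategoryCounts, CategoryCounts]:
    """Pool non-shared gene category counts for close vs divergent pairs.

    Close pairs: ANI > close_min; divergent: divergent_min <= ANI <=
    divergent_max — the two strata are disjoint.  Raises when either
    stratum is empty.
    """
    counts = {"close": [0, 0], "divergent": [0, 0]}
    seen: dict[str, set[str]] = {"close": set(), "divergent": set()}
    for p in pairs:
        if p.ani is None:
            continue
        if p.ani > close_min:
            group = "close"
        elif divergent_min <= p.ani <= divergent_max:
            group = "divergent"
        else:
            continue
        key = tuple(sorted((p.query_id, p.ref_id)))
        share = gene_shares.get(key) or gene_shares.get((key[1], key[0]))
        if share is None:
            raise KeyError(f"no GeneShare for pair {key}")
        for gene in list(share.nonshared_a) + list(share.nonshared_b):
            if unique_genes:
                if gene.gene_id in seen[group]:
                    continue
                seen[group].add(gene.gene_id)
            counts[group][1] += 1
            if gene.category == MOBILE:
                counts[group][0] += 1
    close = CategoryCounts(*counts["close"])
    divergent = CategoryCounts(*counts["divergent"])
    if close.n_total == 0:
        raise ValueError("no non-shared genes among close pairs (ANI > close_min)")
    if divergent.n_total == 0:
        raise ValueError("no non-shared genes among divergent pairs")
    return close, divergent


def two_proportion_z(k_a: int, n_a: int, k_b: int, n_b: int) -> EnrichmentResult:
    """Pooled two-proportion z-test, two-sided.

    z = (p_a - p_b) / sqrt(p(1-p)(1/n_a + 1/n_b)) with the pooled
    proportion p = (k_a+k_b)/(n_a+n_b); z is undefined (None) when the
    pooled proportion is 0 or 1.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("both groups need n >= 1")
    if not (0 <= k_a <= n_a and 0 <= k_b <= n_b):
        raise ValueError("need 0 <= k <= n in each group")
    pooled = (k_a + k_b) / (n_a + n_b)
    if pooled in (0.0, 1.0):
        return EnrichmentResult(
            CategoryCounts(k_a, n_a), CategoryCounts(k_b, n_b), pooled, None, None
        )
    se = math.sqrt(pooled * (1 - pooled) * (1 / n_a + 1 / n_b))
    z = (k_a / n_a - k_b / n_b) / se
    p = 2 * float(norm.sf(abs(z)))
    return EnrichmentResult(
        CategoryCounts(k_a, n_a), CategoryCounts(k_b, n_b), pooled, z, p
    )


def enrichment_test(
    pairs: list[AniPair],
    gene_shares: dict[tuple[str, str], GeneShare],
    close_min: float = 99.8,
    divergent_max: float = 99.8,
    divergent_min: float = 96.0,
    unique_genes: bool = False,
) -> EnrichmentResult:
    """collect_nonshared + two_proportion_z in one call."""
    close, divergent = collect_nonshared(
        pairs, gene_shares, close_min, divergent_max, divergent_min, unique_genes
    )
    return two_proportion_z(
        close.k_mobile, close.n_total, divergent.k_mobile, divergent.n_total
    )
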