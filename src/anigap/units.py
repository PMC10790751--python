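"""Nested intra-species units from ANI thresholds.

Genomes are clustered by single linkage: a graph with an edge for every
pair at/above the threshold, clusters = connected components.  Because
the edge sets are nested across thresholds, the partitions are nested by
construction: every strain lies inside one genomovar, every genomovar
inside one genomospecies.  Following the proposed definitions, the
species and genomovar thresholds are inclusive (ANI >= 95, >= 99.5)
while the strain threshold is strict (ANI > 99.99).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .ani import AniPair


@dataclass(frozen=True)
class UnitThresholds:
    genomospecies: float = 95.0
    genomovar: float = 99.5
    strain: float = 99.99

    def validate(self) -> None:
        if not (0 < self.genomospecies < self.genomovar < self.strain <= 100):
            raise ValueError(
                "thresholds must satisfy genomospecies < genomovar < strain <= 100"
            )


@dataclass
class UnitAssignment:
    threshold: float
    strict: bool  # True: edges require ANI strictly above the threshold
    labels: dict[str, str]  # genome_id -> cluster label
    linkage: str = "single"

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))


def _genome_set(pairs: list[AniPair]) -> list[str]:
    return sorted({g for p in pairs for g in (p.query_id, p.ref_id)})


def cluster_by_ani(
    pairs: list[AniPair],
    threshold: float,
    genomes: list[str] | None = None,
    strict: bool = False,
) -> UnitAssignment:
    """Single-linkage clusters at an ANI threshold.

    Pairs with undefined ANI contribute no edge (treated as below the
    threshold).  Cluster labels are the smallest genome_id in each
    component.  ``genomes`` may add genomes absent from the pair list
    (singletons); duplicate pairs with conflicting ANI raise.
    """
    if not 0 < threshold <= 100:
        raise ValueError("threshold must lie in (0, 100]")
    seen: dict[tuple[str, str], float | None] = {}
    for p in pairs:
        key = tuple(sorted((p.query_id, p.ref_id)))
        if key in seen and seen[key] != p.ani:
            raise ValueError(f"conflicting duplicate pair {key}")
        seen[key] = p.ani
    g = nx.Graph()
    g.add_nodes_from(_genome_set(pairs))
    if genomes is not None:
        g.add_nodes_from(genomes)
    for (a, b), ani in seen.items():
        if ani is None:
            continue
        if (ani > threshold) if strict else (ani >= threshold):
            g.add_edge(a, b)
    labels: dict[str, str] = {}
    for comp in nx.connected_components(g):
        lab = min(comp)
        for node in comp:
            labels[node] = lab
    return UnitAssignment(threshold=threshold, strict=strict, labels=labels)


def nested_units(
    pairs: list[AniPair],
    thresholds: UnitThresholds = UnitThresholds(),
    genomes: list[str] | None = None,
) -> dict[str, UnitAssignment]:
    """Genomospecies / genomovar / strain partitions (nested)."""
    thresholds.validate()
    return {
        "genomospecies": cluster_by_ani(pairs, thresholds.genomospecies, genomes, strict=False),
        "genomovar": cluster_by_ani(pairs, thresholds.genomovar, genomes, strict=False),
        "strain": cluster_by_ani(pairs, thresholds.strain, genomes, strict=True),
    }


def is_refinement(fine: dict[str, str], coarse: dict[str, str]) -> bool:
    """True when every fine cluster lies inside exactly one coarse cluster."""
    rep: dict[str, str] = {}
    for g, lab in fine.items():
        if lab in rep:
            if coarse[g] != rep[lab]:
                return False
        else:
            rep[lab] = coarse[g]
    return True
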