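"""Synthetic bacterial species with planted intra-species structure.

A species is simulated as a set of genomes evolved on a two-level tree:
genomovar ancestors branch off the species root, and genomes branch off
their genomovar ancestor.  Substitution events are placed uniformly at
random over a shared master coordinate frame, so the expected pairwise
identity of any two genomes is an exact function of the number of events
on the path between them (a finite-genome Jukes–Cantor-style correction
for multiple hits).  Divergence bands are enforced in event-count space,
which makes planted identities land inside the configured ANI bands by
construction — in particular, a ``gapped`` scenario has exactly zero
planted pairs inside the 99.2–99.8% ANI gap.

Gene content is simulated as whole-gene blocks: a fixed complement of
core genes plus an accessory pool organised into islands of adjacent
genes that are gained and lost as one block along branches.  A
configurable fraction of the islands carries the "hypothetical/mobile"
category label (the rest, and all core genes, are "annotated").  Mobile
islands turn over fast on every branch regardless of its length, while
annotated islands turn over clock-like with branch divergence, so the
genes that differ between recently diverged genomes are enriched in the
mobile category.  Seven designated core genes act as MLST-analog loci.

Truth tables (lineage tree, planted identity matrix, genomovar/strain
labels, gene presence/absence, categories) are returned alongside the
genomes so every downstream stage can be scored against the plant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import decode, encode

DEFAULT_MLST_LOCI = ("adk", "fumC", "gyrB", "icd", "mdh", "purA", "recA")

ANNOTATED = "annotated"
MOBILE = "hypothetical/mobile"

_SCENARIOS = ("gapped", "gapless", "clonal")

# scenario-specific default identity bands (percent ANI)
_SCENARIO_BANDS = {
    "gapped": ((96.0, 99.2), (99.85, 99.99)),
    "gapless": ((96.0, 99.6), (99.2, 99.99)),
    "clonal": ((99.6, 99.85), (99.85, 99.99)),
}


class ConfigError(ValueError):
    """Raised for an infeasible or inconsistent simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic species.

    ``inter_unit_ani`` / ``intra_unit_ani`` are the percent-identity bands
    for between- and within-genomovar genome pairs; when ``None`` they are
    resolved from the scenario.  ``genome_length`` is the length of the
    master coordinate frame (core + accessory + intergenic); emitted
    genomes are shorter by their absent accessory genes.
    """

    seed: int = 0
    genome_length: int = 100_000
    n_genomovars: int = 8
    genomes_per_genomovar: int = 4
    inter_unit_ani: tuple[float, float] | None = None
    intra_unit_ani: tuple[float, float] | None = None
    strain_ani: float = 99.99
    scenario: str = "gapped"
    n_core_genes: int = 60
    n_accessory_pool: int = 40
    island_size: int = 4
    gene_length: int = 900
    gain_loss_prob: float = 0.08
    mobile_fraction: float = 0.5
    terminal_mobile_boost: float = 3.0
    mlst_loci: tuple[str, ...] = DEFAULT_MLST_LOCI
    mlst_locus_mutations: str = "free"  # "free" | "unit_only"
    n_contigs: int = 1

    def resolved(self) -> "SimConfig":
        """Fill scenario-dependent band defaults and validate."""
        if self.scenario not in _SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}")
        inter, intra = _SCENARIO_BANDS[self.scenario]
        cfg = replace(
            self,
            inter_unit_ani=tuple(self.inter_unit_ani or inter),
            intra_unit_ani=tuple(self.intra_unit_ani or intra),
        )
        cfg._validate()
        return cfg

    def _validate(self) -> None:
        inter, intra = self.inter_unit_ani, self.intra_unit_ani
        for name, band in (("inter_unit_ani", inter), ("intra_unit_ani", intra)):
            lo, hi = band
            if not (0.0 < lo <= hi <= 100.0):
                raise ConfigError(f"{name} must satisfy 0 < lo <= hi <= 100, got {band}")
        if intra[1] < inter[0]:
            raise ConfigError(
                "intra_unit_ani lies below inter_unit_ani: within-unit pairs "
                "cannot be more divergent than between-unit pairs"
            )
        if self.scenario == "gapped":
            if inter[1] > 99.2 or intra[0] < 99.8:
                raise ConfigError(
                    "gapped scenario requires inter_unit_ani <= 99.2 and "
                    "intra_unit_ani >= 99.8 so the 99.2-99.8 gap stays empty"
                )
        if self.scenario == "clonal" and inter[0] <= 99.5:
            raise ConfigError("clonal scenario requires all planted ANI > 99.5")
        if self.n_genomovars < 1 or self.genomes_per_genomovar < 1:
            raise ConfigError("need at least one genomovar and one genome per genomovar")
        if self.n_accessory_pool < 0:
            raise ConfigError("n_accessory_pool must be >= 0")
        if self.island_size < 1:
            raise ConfigError("island_size must be >= 1")
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ConfigError("mobile_fraction must lie in [0, 1]")
        if not 0.0 <= self.gain_loss_prob <= 1.0:
            raise ConfigError("gain_loss_prob must lie in [0, 1]")
        if len(self.mlst_loci) != 7:
            raise ConfigError("exactly 7 MLST loci are required")
        if len(set(self.mlst_loci)) != 7:
            raise ConfigError("MLST locus names must be unique")
        if self.n_core_genes < 7:
            raise ConfigError("need at least 7 core genes to host the MLST loci")
        if self.mlst_locus_mutations not in ("free", "unit_only"):
            raise ConfigError("mlst_locus_mutations must be 'free' or 'unit_only'")
        n_blocks = self.n_core_genes + self.n_accessory_pool
        if self.genome_length < n_blocks * self.gene_length + (n_blocks + 1) * 10:
            raise ConfigError("genome_length too small for the requested gene complement")
        if self.n_contigs < 1:
            raise ConfigError("n_contigs must be >= 1")


@dataclass(frozen=True)
class Gene:
    gene_id: str
    contig: str
    start: int  # 0-based, half-open
    end: int
    strand: str  # "+" | "-"
    category: str  # ANNOTATED | MOBILE
    is_core: bool


@dataclass
class GenomeRecord:
    """One genome: ordered contigs, gene annotations and MLST locus tags."""

    genome_id: str
    contigs: dict[str, str]  # contig name -> sequence (insertion-ordered)
    genes: list[Gene]
    locus_tags: dict[str, str]  # MLST locus name -> gene_id

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def gene_sequence(self, gene_id: str) -> str:
        """Annotated-strand nucleotide sequence of a gene."""
        for g in self.genes:
            if g.gene_id == gene_id:
                seq = self.contigs[g.contig][g.start:g.end]
                if g.strand == "-":
                    from ._seq import revcomp_str

                    return revcomp_str(seq)
                return seq
        raise KeyError(f"{gene_id} not annotated on {self.genome_id}")


@dataclass
class SpeciesTruth:
    """Ground truth for one simulated species.

    ``aligned`` holds each genome's sequence on the shared master
    coordinate frame (uint8-encoded) and ``presence_mask`` which master
    positions are present in the emitted genome; together they are the
    exact-alignment oracle for ANI estimators.
    """

    config: SimConfig
    tree_newick: str
    planted_identity: pd.DataFrame  # symmetric, % with 100 on the diagonal
    genomovar: dict[str, str]
    strain: dict[str, str]
    presence: pd.DataFrame  # genomes x gene ids (bool)
    category: dict[str, str]  # gene id -> category
    gap_interval: tuple[float, float] | None
    aligned: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    presence_mask: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def gap_midpoint(self) -> float | None:
        if self.gap_interval is None:
            return None
        return 0.5 * (self.gap_interval[0] + self.gap_interval[1])


def planted_identity_pct(n_events: int | np.ndarray, genome_length: int) -> np.ndarray | float:
    """Expected percent identity after ``n_events`` uniform substitution events.

    Each event hits a uniform site and shifts the base by a uniform nonzero
    amount (mod 4), so a site hit k times differs with probability
    3/4*(1-(-1/3)^k); averaging over the binomial hit counts gives
    p_diff = 3/4 * (1 - (1 - 4/(3L))^m).
    """
    r = 1.0 - 4.0 / (3.0 * genome_length)
    p_diff = 0.75 * (1.0 - np.power(r, n_events))
    return 100.0 * (1.0 - p_diff)


def events_for_identity(ani_pct: float, genome_length: int) -> float:
    """Inverse of :func:`planted_identity_pct` (real-valued)."""
    d = 1.0 - ani_pct / 100.0
    if d < 0 or d >= 0.75:
        raise ConfigError(f"identity {ani_pct} out of the invertible range")
    r = 1.0 - 4.0 / (3.0 * genome_length)
    if d == 0:
        return 0.0
    return math.log(1.0 - 4.0 * d / 3.0) / math.log(r)


# ---------------------------------------------------------------------------
# master genome layout


@dataclass(frozen=True)
class _Block:
    gene_id: str
    start: int
    end: int
    strand: str
    category: str
    is_core: bool
    island: int  # -1 for core genes


def _build_layout(cfg: SimConfig, rng: np.random.Generator) -> list[_Block]:
    """Interleave core genes and accessory islands along the master frame.

    Accessory genes are grouped into islands of ``island_size`` adjacent
    genes that are gained and lost as one block (mobile-element-like);
    islands are spread evenly among the core genes, with intergenic
    spacers between top-level units but not within an island.
    """
    n_core, n_acc = cfg.n_core_genes, cfg.n_accessory_pool
    n_isl = -(-n_acc // cfg.island_size) if n_acc else 0
    total_units = n_core + n_isl
    # Bresenham-style interleave so islands are spread evenly
    order: list[tuple[str, int]] = []
    ci = ii = 0
    for k in range(total_units):
        if ((k + 1) * n_isl) // total_units > ii:
            order.append(("island", ii))
            ii += 1
        else:
            order.append(("core", ci))
            ci += 1
    gene_total = (n_core + n_acc) * cfg.gene_length
    spacer = (cfg.genome_length - gene_total) // (total_units + 1)
    n_mobile = int(round(cfg.mobile_fraction * n_isl))
    mobile_islands = set(rng.choice(n_isl, size=n_mobile, replace=False)) if n_isl else set()
    blocks: list[_Block] = []
    pos = spacer
    for kind, idx in order:
        strand = "+" if rng.random() < 0.5 else "-"
        if kind == "core":
            blocks.append(
                _Block(f"core{idx:03d}", pos, pos + cfg.gene_length, strand, ANNOTATED, True, -1)
            )
            pos += cfg.gene_length + spacer
        else:
            cat = MOBILE if idx in mobile_islands else ANNOTATED
            first = idx * cfg.island_size
            last = min(n_acc, first + cfg.island_size)
            for ai in range(first, last):
                strand = "+" if rng.random() < 0.5 else "-"
                blocks.append(
                    _Block(f"acc{ai:03d}", pos, pos + cfg.gene_length, strand, cat, False, idx)
                )
                pos += cfg.gene_length
            pos += spacer
    return blocks


def _mutate(
    seq: np.ndarray,
    n_events: int,
    rng: np.random.Generator,
    forbidden: np.ndarray | None = None,
) -> np.ndarray:
    """Apply ``n_events`` uniform substitution events (composable mod-4 shifts).

    ``forbidden`` is a boolean mask of master positions where events are
    re-drawn (used to confine MLST-locus mutations to internal branches).
    """
    L = seq.size
    if n_events == 0:
        return seq.copy()
    pos = rng.integers(0, L, size=n_events)
    if forbidden is not None:
        bad = forbidden[pos]
        while bad.any():
            pos[bad] = rng.integers(0, L, size=int(bad.sum()))
            bad = forbidden[pos]
    shift = rng.integers(1, 4, size=n_events).astype(np.uint8)
    delta = np.zeros(L, dtype=np.uint8)
    np.add.at(delta, pos, shift)
    return ((seq + delta) % 4).astype(np.uint8)


def _event_bounds(cfg: SimConfig) -> tuple[int, int, int, int]:
    """Per-genome and per-unit event-count ranges that realize the bands."""
    L = cfg.genome_length
    inter, intra = cfg.inter_unit_ani, cfg.intra_unit_ani
    w_lo = math.ceil(events_for_identity(intra[1], L))
    w_hi = math.floor(events_for_identity(intra[0], L))
    g_lo = max(0, math.ceil(w_lo / 2))
    g_hi = max(g_lo, math.floor(w_hi / 2))
    m_lo = math.ceil(events_for_identity(inter[1], L))
    m_hi = math.floor(events_for_identity(inter[0], L))
    u_lo = max(0, math.ceil((m_lo - 2 * g_lo) / 2))
    # the upper unit depth leaves room for the deepest genome branches; for
    # degenerate (point) bands it collapses onto u_lo, biasing slightly toward
    # more divergence, which can only widen a planted gap
    u_hi = max(u_lo, math.floor((m_hi - 2 * g_hi) / 2))
    return g_lo, g_hi, u_lo, u_hi


def simulate_species(config: SimConfig) -> tuple[list[GenomeRecord], SpeciesTruth]:
    """Simulate one species; returns genomes plus machine-readable truth."""
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed)
    L = cfg.genome_length
    n_units, per = cfg.n_genomovars, cfg.genomes_per_genomovar

    blocks = _build_layout(cfg, rng)
    root_seq = rng.integers(0, 4, size=L, dtype=np.uint8)

    # --- event counts on branches -----------------------------------------
    g_lo, g_hi, u_lo, u_hi = _event_bounds(cfg)
    if cfg.scenario == "gapless":
        # star-like control: unit branches carry no events and genome depths
        # span the union of both bands, giving a broad gap-free distribution
        lo_id = min(cfg.inter_unit_ani[0], cfg.intra_unit_ani[0])
        hi_id = max(cfg.inter_unit_ani[1], cfg.intra_unit_ani[1])
        h_lo = max(0, math.ceil(events_for_identity(hi_id, L) / 2))
        h_hi = max(h_lo, math.floor(events_for_identity(lo_id, L) / 2))
        unit_events = np.zeros(n_units, dtype=np.int64)
        genome_events = rng.integers(h_lo, h_hi + 1, size=(n_units, per))
    elif cfg.scenario == "gapped" and n_units >= 2:
        # Two genomovars anchor the shallow end so the between-unit band is
        # attained up to its top edge (planted gap midpoint ~99.5 at the
        # defaults); the rest are stratified evenly across the band with
        # random jitter, tiling it without wide holes that would read as
        # spurious valleys.
        r = u_hi - u_lo
        k = n_units - 2
        if k > 0:
            base = u_lo + np.round(np.arange(1, k + 1) * r / k).astype(np.int64)
            half_step = max(r // (2 * k), 1)
            jitter = rng.integers(-half_step, half_step + 1, size=k)
            rest = np.clip(base + jitter, u_lo, u_hi)
        else:
            rest = np.zeros(0, dtype=np.int64)
        unit_events = np.concatenate([np.full(2, u_lo, dtype=np.int64), rest])
        genome_events = rng.integers(g_lo, g_hi + 1, size=(n_units, per))
    else:
        unit_events = rng.integers(u_lo, u_hi + 1, size=n_units)
        genome_events = rng.integers(g_lo, g_hi + 1, size=(n_units, per))

    # --- sequences ---------------------------------------------------------
    locus_core_idx = [round(i * (cfg.n_core_genes - 1) / 6) for i in range(7)]
    locus_gene_ids = [f"core{idx:03d}" for idx in locus_core_idx]
    in_locus = np.zeros(L, dtype=bool)
    for b in blocks:
        if b.gene_id in locus_gene_ids:
            in_locus[b.start:b.end] = True
    terminal_forbidden = in_locus if cfg.mlst_locus_mutations == "unit_only" else None

    genome_ids: list[str] = []
    unit_of: dict[str, str] = {}
    coords: dict[str, tuple[int, int]] = {}  # genome -> (unit idx, genome idx)
    aligned: dict[str, np.ndarray] = {}
    n_events_from_root: dict[str, int] = {}
    for u in range(n_units):
        unit_seq = _mutate(root_seq, int(unit_events[u]), rng)
        for g in range(per):
            gid = f"u{u + 1:02d}_g{g + 1:02d}"
            genome_ids.append(gid)
            unit_of[gid] = f"gv{u + 1:02d}"
            coords[gid] = (u, g)
            aligned[gid] = _mutate(
                unit_seq, int(genome_events[u, g]), rng, forbidden=terminal_forbidden
            )
            n_events_from_root[gid] = int(unit_events[u] + genome_events[u, g])

    # --- planted identity matrix ------------------------------------------
    n = len(genome_ids)
    unit_index = {gid: unit_of[gid] for gid in genome_ids}
    planted = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = genome_ids[i], genome_ids[j]
            ua, ga = coords[a]
            ub, gb = coords[b]
            if ua == ub:
                m = int(genome_events[ua, ga] + genome_events[ub, gb])
            else:
                m = n_events_from_root[a] + n_events_from_root[b]
            planted[i, j] = planted[j, i] = float(planted_identity_pct(m, L))
    planted_df = pd.DataFrame(planted, index=genome_ids, columns=genome_ids)

    # --- accessory island presence (whole islands gain/loss as one block) --
    # Two turnover regimes: mobile islands flip fast on every branch
    # regardless of its length (prophage-like turnover on ecological
    # timescales), annotated islands flip clock-like, with probability
    # growing with the branch's sequence divergence.  Recently diverged
    # pairs therefore differ almost exclusively in mobile content, while
    # divergent pairs accumulate annotated differences as well.
    acc_blocks = [b for b in blocks if not b.is_core]
    n_isl = max((b.island for b in acc_blocks), default=-1) + 1
    isl_of = np.array([b.island for b in acc_blocks], dtype=np.int64)
    root_presence = rng.random(n_isl) < 0.5 if n_isl else np.zeros(0, dtype=bool)
    isl_mobile = np.zeros(n_isl, dtype=bool)
    for b in acc_blocks:
        if b.category == MOBILE:
            isl_mobile[b.island] = True
    p_mobile = min(0.45, cfg.gain_loss_prob * cfg.terminal_mobile_boost)

    def p_flip(branch_events: int) -> np.ndarray:
        d = branch_events / L  # branch length, substitutions per site
        p_annot = 0.5 * (1.0 - math.exp(-2.0 * cfg.gain_loss_prob * d / 0.01))
        return np.where(isl_mobile, p_mobile, p_annot)

    presence_rows: dict[str, np.ndarray] = {}  # per accessory *gene*
    k = 0
    for u in range(n_units):
        unit_presence = root_presence ^ (rng.random(n_isl) < p_flip(int(unit_events[u])))
        for g in range(per):
            gid = genome_ids[k]
            isl_pres = unit_presence ^ (
                rng.random(n_isl) < p_flip(int(genome_events[u, g]))
            )
            presence_rows[gid] = isl_pres[isl_of] if n_isl else np.zeros(0, dtype=bool)
            k += 1

    # --- emit genomes -------------------------------------------------------
    cut_points = _contig_cuts(cfg, blocks)
    genomes: list[GenomeRecord] = []
    presence_mask: dict[str, np.ndarray] = {}
    all_gene_ids = [b.gene_id for b in blocks]
    pres_table = pd.DataFrame(True, index=genome_ids, columns=all_gene_ids)
    for gid in genome_ids:
        mask = np.ones(L, dtype=bool)
        pres = presence_rows[gid]
        for bi, b in enumerate(acc_blocks):
            if not pres[bi]:
                mask[b.start:b.end] = False
                pres_table.loc[gid, b.gene_id] = False
        presence_mask[gid] = mask
        genomes.append(_emit_genome(gid, aligned[gid], mask, blocks, cut_points, locus_gene_ids, cfg))

    # --- labels -------------------------------------------------------------
    strain_labels = _threshold_labels(planted_df, cfg.strain_ani, strict=True)
    genomovar = {gid: unit_of[gid] for gid in genome_ids}

    gap_interval = None
    if cfg.scenario == "gapped" and n_units > 1 and per > 1:
        same_unit = np.array(
            [[unit_index[a] == unit_index[b] for b in genome_ids] for a in genome_ids]
        )
        off = ~np.eye(n, dtype=bool)
        inter_vals = planted[off & ~same_unit]
        intra_vals = planted[off & same_unit]
        if inter_vals.size and intra_vals.size:
            gap_interval = (float(inter_vals.max()), float(intra_vals.min()))

    tree = _newick(genome_ids, unit_index, unit_events, genome_events, L)
    truth = SpeciesTruth(
        config=cfg,
        tree_newick=tree,
        planted_identity=planted_df,
        genomovar=genomovar,
        strain=strain_labels,
        presence=pres_table,
        category={b.gene_id: b.category for b in blocks},
        gap_interval=gap_interval,
        aligned=aligned,
        presence_mask=presence_mask,
    )
    return genomes, truth


def _contig_cuts(cfg: SimConfig, blocks: list[_Block]) -> list[int]:
    """Master-frame cut positions (inside intergenic spacers) for contigs."""
    if cfg.n_contigs == 1:
        return []
    L = cfg.genome_length
    # candidate cut sites: midpoints of the gaps between consecutive blocks
    gaps = []
    prev_end = 0
    for b in blocks:
        if b.start > prev_end:
            gaps.append((prev_end + b.start) // 2)
        prev_end = b.end
    cuts = []
    for i in range(1, cfg.n_contigs):
        target = i * L // cfg.n_contigs
        best = min(gaps, key=lambda g: abs(g - target))
        if best not in cuts:
            cuts.append(best)
    return sorted(cuts)


def _emit_genome(
    gid: str,
    seq: np.ndarray,
    mask: np.ndarray,
    blocks: list[_Block],
    cuts: list[int],
    locus_gene_ids: list[str],
    cfg: SimConfig,
) -> GenomeRecord:
    prefix = np.zeros(seq.size + 1, dtype=np.int64)
    np.cumsum(mask, out=prefix[1:])
    bounds = [0] + [int(prefix[c]) for c in cuts] + [int(prefix[-1])]
    contig_names = [f"{gid}_c{i + 1}" for i in range(len(bounds) - 1)]
    emitted = decode(seq[mask])
    contigs = {
        name: emitted[bounds[i]:bounds[i + 1]] for i, name in enumerate(contig_names)
    }
    genes: list[Gene] = []
    locus_tags: dict[str, str] = {}
    cut_arr = np.array(cuts, dtype=np.int64)
    for b in blocks:
        if not mask[b.start]:
            continue
        ci = int(np.searchsorted(cut_arr, b.start, side="right")) if cuts else 0
        s = int(prefix[b.start]) - bounds[ci]
        e = int(prefix[b.end]) - bounds[ci]
        genes.append(Gene(b.gene_id, contig_names[ci], s, e, b.strand, b.category, b.is_core))
    for name, gene_id in zip(cfg.mlst_loci, locus_gene_ids):
        locus_tags[name] = gene_id
    return GenomeRecord(gid, contigs, genes, locus_tags)


def _threshold_labels(planted: pd.DataFrame, threshold: float, strict: bool) -> dict[str, str]:
    """Connected components of the planted matrix above a threshold."""
    ids = list(planted.index)
    parent = {g: g for g in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    vals = planted.to_numpy()
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            v = vals[i, j]
            if (v > threshold) if strict else (v >= threshold):
                ra, rb = find(a), find(ids[j])
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    return {g: f"s_{find(g)}" for g in ids}


def _newick(
    genome_ids: list[str],
    unit_index: dict[str, str],
    unit_events: np.ndarray,
    genome_events: np.ndarray,
    L: int,
) -> str:
    units: dict[str, list[str]] = {}
    for gid in genome_ids:
        units.setdefault(unit_index[gid], []).append(gid)
    parts = []
    for unit, members in sorted(units.items()):
        u = int(unit[2:]) - 1  # "gvNN"
        leaf_parts = []
        for gid in members:
            g = int(gid.split("_g")[1]) - 1
            bl = genome_events[u, g] / L
            leaf_parts.append(f"{gid}:{bl:.8f}")
        ubl = unit_events[u] / L
        parts.append(f"({','.join(leaf_parts)}){unit}:{ubl:.8f}")
    return f"({','.join(parts)})root;"


# ---------------------------------------------------------------------------
# on-disk representation


def write_species(genomes: list[GenomeRecord], truth: SpeciesTruth, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA per genome plus truth tables (TSV), tree (Newick), config (TOML)."""
    if not genomes:
        raise ValueError("empty genome list")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    from . import io as _io

    for g in genomes:
        p = out / f"{g.genome_id}.fasta"
        _io.write_fasta(g.contigs, p)
        paths[g.genome_id] = p

    genes_rows = []
    loci_rows = []
    for g in genomes:
        for gene in g.genes:
            genes_rows.append(
                (g.genome_id, gene.gene_id, gene.contig, gene.start, gene.end,
                 gene.strand, gene.category, int(gene.is_core))
            )
        for locus, gene_id in g.locus_tags.items():
            loci_rows.append((g.genome_id, locus, gene_id))
    pd.DataFrame(
        genes_rows,
        columns=["genome_id", "gene_id", "contig", "start", "end", "strand", "category", "is_core"],
    ).to_csv(out / "genes.tsv", sep="\t", index=False)
    pd.DataFrame(loci_rows, columns=["genome_id", "locus", "gene_id"]).to_csv(
        out / "loci.tsv", sep="\t", index=False
    )

    labels = pd.DataFrame(
        {
            "genome_id": list(truth.genomovar),
            "genomovar": [truth.genomovar[g] for g in truth.genomovar],
            "strain": [truth.strain[g] for g in truth.genomovar],
        }
    )
    labels.to_csv(out / "labels.tsv", sep="\t", index=False)

    ids = list(truth.planted_identity.index)
    pair_rows = [
        (ids[i], ids[j], truth.planted_identity.iloc[i, j])
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
    ]
    pd.DataFrame(pair_rows, columns=["genome_a", "genome_b", "planted_ani"]).to_csv(
        out / "planted_pairs.tsv", sep="\t", index=False
    )
    truth.presence.rename_axis("genome_id").to_csv(out / "presence.tsv", sep="\t")
    (out / "tree.nwk").write_text(truth.tree_newick + "\n")
    (out / "config.toml").write_text(_config_toml(truth.config))
    paths["outdir"] = out
    return paths


def _config_toml(cfg: SimConfig) -> str:
    def fmt(v):
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, (int, float)):
            return repr(v)
        if isinstance(v, str):
            return f'"{v}"'
        if isinstance(v, (tuple, list)):
            return "[" + ", ".join(fmt(x) for x in v) + "]"
        raise TypeError(type(v))

    lines = ["[simulate]"]
    for k, v in vars(cfg).items():
        if v is None:
            continue
        lines.append(f"{k} = {fmt(v)}")
    return "\n".join(lines) + "\n"


def read_species(outdir: str | Path) -> list[GenomeRecord]:
    """Re-load genomes written by :func:`write_species` (lossless round-trip)."""
    out = Path(outdir)
    from . import io as _io

    genes = pd.read_csv(out / "genes.tsv", sep="\t")
    loci = pd.read_csv(out / "loci.tsv", sep="\t")
    genomes = []
    for gid, sub in genes.groupby("genome_id", sort=True):
        contigs = _io.read_fasta(out / f"{gid}.fasta")
        gene_list = [
            Gene(r.gene_id, r.contig, int(r.start), int(r.end), r.strand, r.category, bool(r.is_core))
            for r in sub.itertuples()
        ]
        ltags = {
            r.locus: r.gene_id for r in loci[loci.genome_id == gid].itertuples()
        }
        genomes.append(GenomeRecord(str(gid), contigs, gene_list, ltags))
    return genomes
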