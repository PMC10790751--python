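"""MLST-style sequence typing and its concordance with ANI units.

Sequence types (STs) are assigned from exact nucleotide identity over 7
designated core loci: each distinct allele sequence per locus gets a
number in order of first appearance, and each distinct 7-allele profile
gets an ST number, so identical profiles always share an ST.  Genomes
missing a locus remain untyped and are excluded (with a logged count)
from concordance.

Concordance treats the ST as the predictor and the ANI unit as the
reference, over unordered genome pairs: a same-ST pair at/above the ANI
threshold is a true positive, a same-ST pair below it a false positive,
and a different-ST pair at/above it a false negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .ani import AniPair
from .simulate import GenomeRecord

logger = logging.getLogger(__name__)


@dataclass
class StAssignment:
    loci: tuple[str, ...]
    allele_tables: dict[str, dict[str, int]]  # locus -> allele sequence -> number
    profiles: dict[str, tuple[int, ...] | None]  # genome -> allele profile
    st: dict[str, int | None]  # genome -> ST number (None: unassigned)

    @property
    def typed_genomes(self) -> list[str]:
        return [g for g, s in self.st.items() if s is not None]


@dataclass
class ConcordanceReport:
    threshold: float
    tp: int
    fp: int
    fn: int
    precision: float | None
    recall: float | None
    f1: float | None
    n_pairs: int
    n_excluded: int
    per_st: dict[int, dict[str, int]] = field(default_factory=dict)


def assign_st(genomes: list[GenomeRecord], loci: tuple[str, ...] | None = None) -> StAssignment:
    """Assign STs by exact allele matching over the 7 MLST loci.

    Allele comparison is case-insensitive on the annotated strand.
    Allele and ST numbers start at 1 in order of first appearance over
    the genome input order, which makes the numbering deterministic.
    """
    if loci is None:
        first = genomes[0].locus_tags if genomes else {}
        loci = tuple(first)
    if len(loci) != 7:
        raise ValueError("exactly 7 loci are required")
    if len(set(loci)) != 7:
        raise ValueError("duplicate locus names")
    allele_tables: dict[str, dict[str, int]] = {locus: {} for locus in loci}
    profiles: dict[str, tuple[int, ...] | None] = {}
    st_table: dict[tuple[int, ...], int] = {}
    st: dict[str, int | None] = {}
    for g in genomes:
        numbers = []
        for locus in loci:
            gene_id = g.locus_tags.get(locus)
            if gene_id is None:
                numbers = None
                break
            try:
                seq = g.gene_sequence(gene_id).upper()
            except KeyError:
                numbers = None
                break
            table = allele_tables[locus]
            if seq not in table:
                table[seq] = len(table) + 1
            numbers.append(table[seq])
        if numbers is None:
            profiles[g.genome_id] = None
            st[g.genome_id] = None
            logger.info("%s: missing MLST locus; ST unassigned", g.genome_id)
            continue
        prof = tuple(numbers)
        if prof not in st_table:
            st_table[prof] = len(st_table) + 1
        profiles[g.genome_id] = prof
        st[g.genome_id] = st_table[prof]
    return StAssignment(loci=loci, allele_tables=allele_tables, profiles=profiles, st=st)


def pairwise_concordance(
    st: StAssignment,
    pairs: list[AniPair],
    threshold: float = 99.5,
) -> ConcordanceReport:
    """Pairwise precision/recall/F1 of ST labels against an ANI threshold.

    Pairs involving an untyped genome, or with undefined ANI, are
    excluded and counted.  Precision is undefined (None) when no
    same-ST pair exists.
    """
    tp = fp = fn = 0
    n_excluded = 0
    per_st: dict[int, dict[str, int]] = {}
    n_pairs = 0
    for p in pairs:
        sa = st.st.get(p.query_id)
        sb = st.st.get(p.ref_id)
        if sa is None or sb is None or p.ani is None:
            n_excluded += 1
            continue
        n_pairs += 1
        same_st = sa == sb
        same_unit = p.ani >= threshold
        if same_st:
            bucket = per_st.setdefault(sa, {"tp": 0, "fp": 0})
            if same_unit:
                tp += 1
                bucket["tp"] += 1
            else:
                fp += 1
                bucket["fp"] += 1
        elif same_unit:
            fn += 1
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    f1 = None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    return ConcordanceReport(
        threshold=threshold,
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f1=f1,
        n_pairs=n_pairs,
        n_excluded=n_excluded,
        per_st=per_st,
    )
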