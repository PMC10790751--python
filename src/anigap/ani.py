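"""Fragment-based ANI between genome pairs, and gene-level shared content.

The estimator follows the fragment-mapping scheme popularised by fast
whole-genome ANI tools: the query genome is cut into consecutive,
non-overlapping fragments (default 3,000 bp; the terminal remainder of
each contig is discarded); each fragment is placed on the reference by
exact k-mer seeding (default k = 16) followed by ungapped extension over
the full fragment, and retained when its best identity reaches the
minimum mapping identity (default 80%).  A retained mapping counts as
*bidirectional* when the reference fragment containing the mapped
midpoint maps back — same procedure with the roles swapped — to within
half a fragment of the originating query fragment.  ANI is the mean
identity over bidirectional mappings and the shared genome fraction is
the number of bidirectional mappings over the total query fragments.

Fragments never span contig junctions, and a pair with no bidirectional
mapping has an *undefined* ANI (``None``), never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import encode, hamming_identity
from .simulate import Gene, GenomeRecord

_MAX_HITS_PER_SEED = 8  # skip hyper-repetitive seeds
_N_CANDIDATE_DIAGONALS = 3
_SEED_STRIDE = 59
_N_EVENNESS_WINDOWS = 20
_MIN_WINDOW_IDENTITY = 50.0


@dataclass(frozen=True)
class FragmentMap:
    """One query fragment's best placement on the reference."""

    fragment_index: int
    query_contig: str
    q_start: int
    q_end: int
    ref_contig: str
    r_start: int
    r_end: int
    identity: float
    bidirectional: bool


@dataclass
class AniPair:
    query_id: str
    ref_id: str
    ani: float | None  # percent; None when no bidirectional mapping exists
    shared_fraction: float
    n_fragments: int
    n_bidirectional: int
    fragments: list[FragmentMap] = field(default_factory=list, repr=False)


@dataclass
class GeneShare:
    genome_a: str
    genome_b: str
    shared_gene_fraction: float
    orthologs: list[tuple[str, str]]
    nonshared_a: list[Gene]
    nonshared_b: list[Gene]


class GenomeIndex:
    """Pre-encoded contigs plus a sorted k-mer index for one genome."""

    def __init__(self, record: GenomeRecord, seed_k: int = 16):
        self.record = record
        self.seed_k = seed_k
        self.contig_names = list(record.contigs)
        self.seqs = [encode(record.contigs[c]) for c in self.contig_names]
        # concatenated coordinates: contig c spans [offset[c], offset[c+1])
        self.offsets = np.concatenate([[0], np.cumsum([s.size for s in self.seqs])])
        self.concat = (
            np.concatenate(self.seqs) if self.seqs else np.zeros(0, dtype=np.uint8)
        )
        codes_parts = []
        pos_parts = []
        for ci, s in enumerate(self.seqs):
            if s.size < seed_k:
                continue
            codes_parts.append(_kmer_codes(s, seed_k))
            pos_parts.append(np.arange(s.size - seed_k + 1, dtype=np.int64) + self.offsets[ci])
        if codes_parts:
            codes = np.concatenate(codes_parts)
            pos = np.concatenate(pos_parts)
            order = np.argsort(codes, kind="stable")
            self.sorted_codes = codes[order]
            self.sorted_pos = pos[order]
        else:
            self.sorted_codes = np.zeros(0, dtype=np.uint64)
            self.sorted_pos = np.zeros(0, dtype=np.int64)

    @property
    def length(self) -> int:
        return int(self.offsets[-1])

    def contig_of(self, concat_pos: int) -> int:
        return int(np.searchsorted(self.offsets, concat_pos, side="right")) - 1

    def contig_bounds(self, ci: int) -> tuple[int, int]:
        return int(self.offsets[ci]), int(self.offsets[ci + 1])

    def fragment_starts(self, fragment_length: int) -> np.ndarray:
        """Concat-coordinate starts of all complete fragments, contig by contig."""
        starts = []
        for ci, s in enumerate(self.seqs):
            n = s.size // fragment_length
            if n:
                starts.append(self.offsets[ci] + np.arange(n, dtype=np.int64) * fragment_length)
        if not starts:
            return np.zeros(0, dtype=np.int64)
        return np.concatenate(starts)


def _kmer_codes(seq: np.ndarray, k: int) -> np.ndarray:
    codes = np.zeros(seq.size - k + 1, dtype=np.uint64)
    for i in range(k):
        codes <<= np.uint64(2)
        codes |= seq[i : seq.size - k + 1 + i].astype(np.uint64)
    return codes


def _map_fragments(
    query: GenomeIndex,
    ref: GenomeIndex,
    frag_starts: np.ndarray,
    fragment_length: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Best ungapped placement of each query fragment on the reference.

    Returns (best_ref_start, best_identity); ref start -1 where no seed
    candidate produced a placement.  A placement whose mismatches pile up
    in a short run — any of ~20 sub-windows below 50% identity, i.e. a
    locally random alignment — is chimeric (the fragment straddles
    content private to the query) and is rejected rather than scored:
    fragment identity is only meaningful for evenly-diverged homologs.
    """
    F = fragment_length
    k = query.seed_k
    n_frag = frag_starts.size
    best_start = np.full(n_frag, -1, dtype=np.int64)
    best_ident = np.zeros(n_frag, dtype=float)
    if n_frag == 0 or ref.sorted_codes.size == 0:
        return best_start, best_ident

    seed_off = np.arange(0, F - k + 1, _SEED_STRIDE, dtype=np.int64)
    # seed codes for every fragment, computed straight off the concat array:
    # fragments never cross contig junctions so neither do their seeds
    qcodes_full = _kmer_codes(query.concat, k) if query.concat.size >= k else None
    seed_pos = (frag_starts[:, None] + seed_off[None, :]).ravel()
    seed_frag = np.repeat(np.arange(n_frag), seed_off.size)
    codes = qcodes_full[seed_pos]

    left = np.searchsorted(ref.sorted_codes, codes, side="left")
    right = np.searchsorted(ref.sorted_codes, codes, side="right")
    counts = np.minimum(right - left, _MAX_HITS_PER_SEED)
    total = int(counts.sum())
    if total == 0:
        return best_start, best_ident
    # expand hit ranges
    rep_frag = np.repeat(seed_frag, counts)
    rep_off = np.repeat(seed_pos - frag_starts[seed_frag], counts)
    idx = np.repeat(left, counts) + (
        np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    )
    hit_ref_pos = ref.sorted_pos[idx]
    diag = hit_ref_pos - rep_off  # putative ref start of the aligned fragment

    # vote per (fragment, diagonal)
    key = rep_frag.astype(np.int64) * (2 * ref.length + 2) + (diag + ref.length)
    ukey, votes = np.unique(key, return_counts=True)
    ufrag = ukey // (2 * ref.length + 2)
    udiag = ukey % (2 * ref.length + 2) - ref.length

    order = np.lexsort((votes, ufrag))
    ufrag_o, udiag_o, votes_o = ufrag[order], udiag[order], votes[order]
    ref_offsets = ref.offsets
    for fi in range(n_frag):
        lo = np.searchsorted(ufrag_o, fi, side="left")
        hi = np.searchsorted(ufrag_o, fi, side="right")
        if lo == hi:
            continue
        cands = udiag_o[max(lo, hi - _N_CANDIDATE_DIAGONALS) : hi][::-1]
        qs = int(frag_starts[fi])
        qfrag = query.concat[qs : qs + F]
        for d in cands:
            d = int(d)
            if d < 0 or d + F > ref.length:
                continue
            ci = int(np.searchsorted(ref_offsets, d, side="right")) - 1
            if d + F > ref_offsets[ci + 1]:
                continue  # window would span a contig junction
            match = ref.concat[d : d + F] == qfrag
            ident = 100.0 * float(np.count_nonzero(match)) / F
            if ident > best_ident[fi]:
                wins = np.array_split(match, _N_EVENNESS_WINDOWS)
                if min(float(w.mean()) for w in wins) * 100.0 < _MIN_WINDOW_IDENTITY:
                    continue  # chimeric: divergence concentrated in a run
                best_ident[fi] = ident
                best_start[fi] = d
    return best_start, best_ident


def compute_ani(
    query: GenomeRecord | GenomeIndex,
    reference: GenomeRecord | GenomeIndex,
    fragment_length: int = 3000,
    min_fragment_identity: float = 80.0,
    seed_k: int = 16,
    max_reciprocal_identity_gap: float = 5.0,
    keep_fragments: bool = False,
) -> AniPair:
    """Fragment-mapping ANI of ``query`` against ``reference``.

    Besides positional reciprocity, a bidirectional mapping must be
    *consistent*: the forward and reverse fragment identities may differ
    by at most ``max_reciprocal_identity_gap`` points.  A fragment that
    straddles content private to one genome (an indel/gene-presence
    junction) aligns only partially and shows a strongly asymmetric
    identity; the consistency condition excludes it from the ANI mean, so
    such content counts as unshared instead of biasing ANI downward.

    Raises ``ValueError`` when either genome has no complete fragment.
    """
    if fragment_length < 2 * seed_k:
        raise ValueError("fragment_length must be at least 2*seed_k")
    qi = query if isinstance(query, GenomeIndex) else GenomeIndex(query, seed_k)
    ri = reference if isinstance(reference, GenomeIndex) else GenomeIndex(reference, seed_k)
    if qi.length == 0 or ri.length == 0:
        raise ValueError("empty genome")
    F = fragment_length

    q_starts = qi.fragment_starts(F)
    r_starts = ri.fragment_starts(F)
    if q_starts.size == 0 or r_starts.size == 0:
        raise ValueError("no fragments: genome shorter than fragment_length")

    fwd_start, fwd_ident = _map_fragments(qi, ri, q_starts, F)
    retained = (fwd_start >= 0) & (fwd_ident >= min_fragment_identity)

    # reverse pass, restricted to the reference fragments that received a
    # mapped midpoint (grid of complete reference fragments, per contig)
    mid = fwd_start + F // 2
    ref_frag_idx = np.full(q_starts.size, -1, dtype=np.int64)
    for i in np.nonzero(retained)[0]:
        j = int(np.searchsorted(r_starts, mid[i], side="right")) - 1
        if j >= 0 and mid[i] < r_starts[j] + F:
            ref_frag_idx[i] = j
    needed = np.unique(ref_frag_idx[ref_frag_idx >= 0])
    bidirectional = np.zeros(q_starts.size, dtype=bool)
    if needed.size:
        rev_start, rev_ident = _map_fragments(ri, qi, r_starts[needed], F)
        rev_ok = rev_ident >= min_fragment_identity
        back = {int(needed[t]): (int(rev_start[t]) + F // 2, float(rev_ident[t]))
                for t in range(needed.size) if rev_ok[t] and rev_start[t] >= 0}
        for i in np.nonzero(retained)[0]:
            j = int(ref_frag_idx[i])
            if j in back:
                back_mid, back_ident = back[j]
                if (abs(back_mid - (int(q_starts[i]) + F // 2)) <= F // 2
                        and abs(back_ident - fwd_ident[i]) <= max_reciprocal_identity_gap):
                    bidirectional[i] = True

    n_bi = int(bidirectional.sum())
    ani = float(fwd_ident[bidirectional].mean()) if n_bi else None
    pair = AniPair(
        query_id=qi.record.genome_id,
        ref_id=ri.record.genome_id,
        ani=ani,
        shared_fraction=n_bi / q_starts.size,
        n_fragments=int(q_starts.size),
        n_bidirectional=n_bi,
    )
    if keep_fragments:
        pair.fragments = _fragment_maps(qi, ri, q_starts, fwd_start, fwd_ident,
                                        retained, bidirectional, F)
    return pair


def _fragment_maps(qi, ri, q_starts, fwd_start, fwd_ident, retained, bidirectional, F):
    maps = []
    for i in range(q_starts.size):
        if not retained[i]:
            continue
        qci = qi.contig_of(int(q_starts[i]))
        rci = ri.contig_of(int(fwd_start[i]))
        q0 = int(q_starts[i] - qi.offsets[qci])
        r0 = int(fwd_start[i] - ri.offsets[rci])
        maps.append(
            FragmentMap(i, qi.contig_names[qci], q0, q0 + F,
                        ri.contig_names[rci], r0, r0 + F,
                        float(fwd_ident[i]), bool(bidirectional[i]))
        )
    return maps


def pair_table(
    genomes: list[GenomeRecord],
    fragment_length: int = 3000,
    min_fragment_identity: float = 80.0,
    seed_k: int = 16,
) -> list[AniPair]:
    """One AniPair per unordered genome pair, longer genome as reference.

    A length tie is broken by using the lexicographically smaller
    genome_id as the reference.
    """
    if len(genomes) < 2:
        return []
    ids = [g.genome_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome_ids in input")
    indexes = {g.genome_id: GenomeIndex(g, seed_k) for g in genomes}
    out = []
    ordered = sorted(genomes, key=lambda g: g.genome_id)
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            a, b = ordered[i], ordered[j]
            if a.length > b.length:
                ref, qry = a, b
            elif b.length > a.length:
                ref, qry = b, a
            else:
                ref, qry = (a, b) if a.genome_id < b.genome_id else (b, a)
            out.append(
                compute_ani(indexes[qry.genome_id], indexes[ref.genome_id],
                            fragment_length, min_fragment_identity, seed_k)
            )
    return out


# ---------------------------------------------------------------------------
# gene-level shared content


def shared_gene_fraction(
    a: GenomeRecord, b: GenomeRecord, min_gene_identity: float = 95.0
) -> GeneShare:
    """Reciprocal-best-hit orthologs over annotated gene sequences.

    Identity is ungapped over the annotated-strand sequences (genes of
    unequal length cannot match); the shared fraction is the ortholog
    count divided by the mean gene count of the two genomes.
    """
    if not a.genes or not b.genes:
        raise ValueError("shared_gene_fraction requires annotated genomes with >= 1 gene")
    seqs_a = [encode(a.gene_sequence(g.gene_id)) for g in a.genes]
    seqs_b = [encode(b.gene_sequence(g.gene_id)) for g in b.genes]
    na, nb = len(seqs_a), len(seqs_b)
    ident = np.zeros((na, nb), dtype=float)
    lens_a = np.array([s.size for s in seqs_a])
    lens_b = np.array([s.size for s in seqs_b])
    for length in np.unique(lens_a):
        ia = np.nonzero(lens_a == length)[0]
        ib = np.nonzero(lens_b == length)[0]
        if ib.size == 0:
            continue
        A = np.stack([seqs_a[i] for i in ia])
        B = np.stack([seqs_b[i] for i in ib])
        ident[np.ix_(ia, ib)] = 100.0 * (A[:, None, :] == B[None, :, :]).mean(axis=2)
    best_in_b = ident.argmax(axis=1)
    best_in_a = ident.argmax(axis=0)
    orthologs = []
    matched_a = np.zeros(na, dtype=bool)
    matched_b = np.zeros(nb, dtype=bool)
    for i in range(na):
        j = int(best_in_b[i])
        if int(best_in_a[j]) == i and ident[i, j] >= min_gene_identity:
            orthologs.append((a.genes[i].gene_id, b.genes[j].gene_id))
            matched_a[i] = True
            matched_b[j] = True
    frac = len(orthologs) / ((na + nb) / 2)
    return GeneShare(
        genome_a=a.genome_id,
        genome_b=b.genome_id,
        shared_gene_fraction=frac,
        orthologs=orthologs,
        nonshared_a=[g for i, g in enumerate(a.genes) if not matched_a[i]],
        nonshared_b=[g for j, g in enumerate(b.genes) if not matched_b[j]],
    )


def single_mismatch_identity_drop(read_length: int) -> float:
    """Identity resolution of direct read mapping, in percentage points.

    Computed by comparing a read to a copy carrying one mismatch: a single
    mismatch on a 100 bp read lowers identity from 100% to 99%, i.e. the
    resolution is 100/read_length points.
    """
    if read_length < 2:
        raise ValueError("read_length must be >= 2")
    rng = np.random.default_rng(read_length)
    read = rng.integers(0, 4, size=read_length).astype(np.uint8)
    mutated = read.copy()
    pos = read_length // 2
    mutated[pos] = (mutated[pos] + 1) % 4
    return 100.0 - hamming_identity(read, mutated)
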