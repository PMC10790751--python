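"""Statistics for gaps in intra-species ANI value distributions.

Covers the uniform-null expected counts and deficit ratios, Hartigan's
dip statistic with Monte-Carlo p-values, Gaussian-KDE valley detection,
per-species classification (gapped / shifted / clonal / no gap), the
cross-species gap mode, a fixed-size subsampling control, and the naive
divergence-time closed form.

The dip statistic D of a sample is the distance (in sup norm, halved)
between the empirical CDF and the closest unimodal CDF.  It is computed
here exactly via a greatest-convex-minorant / least-concave-majorant
characterisation: for every candidate modal position (at a sample point
or between two), the minimal band half-width t that admits a
convex-then-concave CDF through the ECDF's step corridor equals half the
largest deviation of the upper ECDF steps above the GCM of the lower
steps (prefix side), and mirrored on the suffix side; D is the minimum
over modal positions.  D always satisfies 1/(2n) <= D <= 1/4 for samples
with at least two distinct values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

GAP_WINDOW = (99.2, 99.8)  # the canonical intra-species ANI gap, percent


# ---------------------------------------------------------------------------
# uniform-null deficit statistics


@dataclass(frozen=True)
class UniformNullReport:
    n_total: int
    range_lo: float
    range_hi: float
    interval_lo: float
    interval_hi: float
    bin_width: float
    expected_per_bin: float
    expected_in_interval: float
    observed_in_interval: int
    deficit_ratio: float | None  # E/O; None when O = 0


def expected_uniform(n_total: int, a: float, b: float, l: float, r: float) -> float:
    """Expected count in [l, r) if ``n_total`` values were uniform on [a, b]."""
    if not (a < b):
        raise ValueError("degenerate range: need a < b")
    if not (a <= l < r <= b):
        raise ValueError("interval must satisfy a <= l < r <= b")
    if n_total < 0:
        raise ValueError("n_total must be >= 0")
    return n_total * (r - l) / (b - a)


def deficit_ratio(
    values: np.ndarray,
    interval: tuple[float, float] = GAP_WINDOW,
    value_range: tuple[float, float] = (96.0, 100.0),
    bin_width: float = 0.1,
) -> UniformNullReport:
    """Observed vs uniform-expected counts in an ANI interval.

    Counting is half-open [l, r) at the left edge except that the top of
    the overall range is closed (values exactly at the top edge count).
    """
    a, b = value_range
    l, r = interval
    v = np.asarray(values, dtype=float)
    in_range = (v >= a) & ((v < b) | (v == b))
    n_total = int(in_range.sum())
    expected = expected_uniform(n_total, a, b, l, r)
    observed = int(((v >= l) & (v < r)).sum())
    return UniformNullReport(
        n_total=n_total,
        range_lo=a,
        range_hi=b,
        interval_lo=l,
        interval_hi=r,
        bin_width=bin_width,
        expected_per_bin=expected_uniform(n_total, a, b, a, a + bin_width),
        expected_in_interval=expected,
        observed_in_interval=observed,
        deficit_ratio=(expected / observed) if observed >= 1 else None,
    )


# ---------------------------------------------------------------------------
# Hartigan's dip


def _convex_min_end(v: np.ndarray, low: np.ndarray, up: np.ndarray):
    """Minimal-end curve of convex band interpolation.

    For points ``v`` (increasing) with value bands [low_i, up_i], returns
    (feasible, e, e_relaxed): ``feasible[k]`` — whether a nondecreasing
    convex function through the bands of points 0..k exists; ``e[k]`` —
    the minimal achievable value at v_k of such a function; and
    ``e_relaxed[k]`` — the same with point k's own lower bound dropped
    (used for a modal atom at v_k, whose left limit obeys a shifted
    band).  Derivation: the minimal convex function above the lower
    bands and below the upper bands is the upper envelope of the support
    lines through each (v_p, low_p) with the steepest slope admitted by
    the earlier upper bands, s_p = max_{i<p} (low_p - up_i)/(v_p - v_i).
    """
    K = v.size
    e = np.array(low, dtype=float)
    e_relaxed = np.full(K, -np.inf)
    if K >= 2:
        dv = v[:, None] - v[None, :]  # dv[p, i] = v_p - v_i
        with np.errstate(divide="ignore", invalid="ignore"):
            slopes = (low[:, None] - up[None, :]) / dv
        iu = np.triu_indices(K)  # i >= p: not allowed
        slopes[iu[0], iu[1]] = -np.inf
        s = slopes.max(axis=1)  # steepest support-line slope per p
        # line values L_p(v_k) = low_p + s_p * (v_k - v_p) for p < k
        with np.errstate(invalid="ignore"):
            lines = low[None, :] + s[None, :] * (-dv.T)  # [k, p] -> low_p + s_p (v_k - v_p)
        lines[np.triu_indices(K)] = -np.inf  # keep p < k only
        lines[~np.isfinite(lines)] = -np.inf
        env = lines.max(axis=1)
        e_relaxed = env
        e = np.maximum(low, env)
    feasible = np.cumprod(e <= up).astype(bool)
    return feasible, e, e_relaxed


def _dip_feasible(v, before, after, n, t) -> bool:
    """Can a unimodal CDF pass within sup-distance t of the ECDF?"""
    T = t * n  # work in counts
    low = after - T
    up = before + T
    feas_c, e, e_rel = _convex_min_end(v, low, up)
    # concave side by reflecting the axis and complementing the counts
    rv = -v[::-1]
    rlow = (n - before - T)[::-1]
    rup = (n - after + T)[::-1]
    feas_r, b_r, b_rel_r = _convex_min_end(rv, rlow, rup)
    feas_s = feas_r[::-1]
    b = (n - b_r)[::-1]  # maximal start value of the concave suffix
    b_rel = (n - b_rel_r)[::-1]
    K = v.size
    # mode outside the sample range
    if feas_s[0] or feas_c[-1]:
        return True
    # mode strictly between v_k and v_{k+1}
    between = feas_c[:-1] & feas_s[1:] & (e[:-1] <= b[1:] + 1e-9)
    if between.any():
        return True
    # modal atom at v_k: left limit within T of before_k, value within T of
    # after_k, built on the full bands of the neighbours
    a_k = np.maximum(e_rel, before - T)
    bb_k = np.minimum(b_rel, after + T)
    ok = (a_k <= before + T + 1e-9) & (bb_k >= after - T - 1e-9) & (a_k <= bb_k + 1e-9)
    ok[1:] &= feas_c[:-1]
    ok[:-1] &= feas_s[1:]
    return bool(ok.any())


def _dip_bisect_numpy(v, before, after, n) -> float:
    lo, hi = 1.0 / (2.0 * n), 0.25
    if _dip_feasible(v, before, after, n, lo):
        return lo
    while hi - lo > 1e-12:
        mid = 0.5 * (lo + hi)
        if _dip_feasible(v, before, after, n, mid):
            hi = mid
        else:
            lo = mid
    return hi


def _build_numba_kernel():
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba is an optional accelerator
        return None

    @njit(cache=False, fastmath=False)
    def _feasible(v, before, after, n, t):
        K = v.size
        T = t * n
        e = np.empty(K)
        erel = np.empty(K)
        b = np.empty(K)
        brel = np.empty(K)
        feas_c = np.empty(K, dtype=np.bool_)
        feas_s = np.empty(K, dtype=np.bool_)
        s = np.empty(K)
        # convex side (prefixes, left to right)
        for p in range(K):
            best = -np.inf
            lp = after[p] - T
            for i in range(p):
                cand = (lp - (before[i] + T)) / (v[p] - v[i])
                if cand > best:
                    best = cand
            s[p] = best
        ok = True
        for k in range(K):
            env = -np.inf
            for p in range(k):
                if s[p] > -np.inf:
                    val = after[p] - T + s[p] * (v[k] - v[p])
                    if val > env:
                        env = val
            erel[k] = env
            ek = after[k] - T
            if env > ek:
                ek = env
            e[k] = ek
            if ek > before[k] + T + 1e-9:
                ok = False
            feas_c[k] = ok
        # concave side (suffixes, right to left) via reflection
        for p in range(K - 1, -1, -1):
            best = -np.inf
            lp = n - before[p] - T  # reflected lower
            for i in range(K - 1, p, -1):
                cand = (lp - (n - after[i] + T)) / (v[i] - v[p])
                if cand > best:
                    best = cand
            s[p] = best
        ok = True
        for k in range(K - 1, -1, -1):
            env = -np.inf
            for p in range(K - 1, k, -1):
                if s[p] > -np.inf:
                    val = (n - before[p] - T) + s[p] * (v[p] - v[k])
                    if val > env:
                        env = val
            brel[k] = n - env
            bk = n - max(n - before[k] - T, env)
            b[k] = bk
            if bk < after[k] - T - 1e-9:
                ok = False
            feas_s[k] = ok
        if feas_s[0] or feas_c[K - 1]:
            return True
        for k in range(K - 1):
            if feas_c[k] and feas_s[k + 1] and e[k] <= b[k + 1] + 1e-9:
                return True
        for k in range(K):
            a_k = max(erel[k], before[k] - T)
            bb_k = min(brel[k], after[k] + T)
            if a_k > before[k] + T + 1e-9 or bb_k < after[k] - T - 1e-9 or a_k > bb_k + 1e-9:
                continue
            if k > 0 and not feas_c[k - 1]:
                continue
            if k < K - 1 and not feas_s[k + 1]:
                continue
            return True
        return False

    @njit(cache=False, fastmath=False)
    def _bisect(v, before, after, n):
        lo = 1.0 / (2.0 * n)
        hi = 0.25
        if _feasible(v, before, after, n, lo):
            return lo
        while hi - lo > 1e-12:
            mid = 0.5 * (lo + hi)
            if _feasible(v, before, after, n, mid):
                hi = mid
            else:
                lo = mid
        return hi

    return _bisect


_dip_bisect_fast = None
_numba_tried = False


def dip_statistic(values) -> float:
    """Hartigan's dip statistic of a one-dimensional sample.

    Computed to ~1e-12 by bisecting the band half-width t and testing
    whether a unimodal CDF fits the ECDF's t-corridor.  Requires at
    least two distinct finite values; satisfies 1/(2n) <= D <= 0.25.
    """
    global _dip_bisect_fast, _numba_tried
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise ValueError("dip_statistic needs at least 2 values")
    if not np.isfinite(x).all():
        raise ValueError("dip_statistic requires finite values")
    v, counts = np.unique(x, return_counts=True)
    K = v.size
    if K < 2:
        raise ValueError("dip_statistic needs at least 2 distinct values")
    after = np.cumsum(counts).astype(float)
    before = after - counts
    if not _numba_tried:
        _numba_tried = True
        _dip_bisect_fast = _build_numba_kernel()
    if _dip_bisect_fast is not None:
        return float(_dip_bisect_fast(v, before, after, float(n)))
    return float(_dip_bisect_numpy(v, before, after, n))


def dip_null(n: int, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    """Sorted dip statistics of ``n_boot`` U(0,1) samples of size n."""
    return np.sort([dip_statistic(rng.random(n)) for _ in range(n_boot)])


def dip_test(
    values,
    n_boot: int = 2000,
    seed: int | None = None,
    null_dips: np.ndarray | None = None,
) -> tuple[float, float]:
    """Dip test of unimodality; returns (D, p).

    p is the Monte-Carlo fraction of U(0,1) samples of the same size
    whose dip reaches D, with a +1/(n_boot+1) continuity correction.  A
    pre-computed null table (from :func:`dip_null`) may be supplied.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 4:
        raise ValueError("dip_test needs at least 4 values")
    if np.unique(x).size < 2:
        raise ValueError("dip_test needs at least 2 distinct values")
    if n_boot < 100:
        logger.warning("dip_test with n_boot=%d < 100 gives a coarse p-value", n_boot)
    d = dip_statistic(x)
    if null_dips is None:
        null_dips = dip_null(x.size, n_boot, np.random.default_rng(seed))
    else:
        null_dips = np.asarray(null_dips)
        n_boot = null_dips.size
    n_ge = null_dips.size - int(np.searchsorted(null_dips, d, side="left"))
    p = (n_ge + 1) / (n_boot + 1)
    return d, float(p)


# ---------------------------------------------------------------------------
# KDE valley detection


@dataclass(frozen=True)
class Valley:
    left: float
    right: float
    midpoint: float  # argmin of the density
    depth_ratio: float  # density at minimum / lower flanking peak density


@dataclass
class GapReport:
    species_id: str
    n_values: int
    valleys: list[Valley]
    dip: float | None
    p_value: float | None
    classification: str  # gap_99.2_99.8 | shifted_gap | clonal | no_gap
    bandwidth: float | None
    grid: tuple[float, float, float] = (95.0, 100.0, 0.01)
    n_boot: int = 0


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    v = np.asarray(values, dtype=float)
    sd = float(np.std(v, ddof=1))
    q75, q25 = np.percentile(v, [75, 25])
    iqr = float(q75 - q25)
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale <= 0:
        scale = max(sd, 1e-3)
    return 0.9 * scale * v.size ** (-0.2)


def kde_density(values: np.ndarray, grid: np.ndarray, bandwidth: float) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    z = (grid[:, None] - v[None, :]) / bandwidth
    return np.exp(-0.5 * z * z).sum(axis=1) / (v.size * bandwidth * np.sqrt(2 * np.pi))


def find_valleys(
    values,
    bandwidth: float | None = None,
    grid: tuple[float, float, float] = (95.0, 100.0, 0.01),
    beta: float = 0.5,
) -> list[Valley]:
    """Valleys of the Gaussian-KDE density of an ANI sample.

    A local minimum flanked by two local maxima is reported as a valley
    when its density is at most ``beta`` times the lower flanking peak;
    the valley extent is the contiguous grid region around the minimum
    where the density stays below that bound.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        return []
    if v.size < 10:
        raise ValueError("find_valleys needs at least 10 values")
    from scipy.signal import find_peaks

    h = bandwidth if bandwidth is not None else silverman_bandwidth(v)
    lo, hi, step = grid
    g = np.arange(lo, hi + step / 2, step)
    dens = kde_density(v, g, h)

    maxima, _ = find_peaks(dens)
    minima, _ = find_peaks(-dens)
    valleys: list[Valley] = []
    for m in minima:
        left = maxima[maxima < m]
        right = maxima[maxima > m]
        if left.size == 0 or right.size == 0:
            continue
        lower_peak = min(float(dens[left[-1]]), float(dens[right[0]]))
        if lower_peak <= 0 or dens[m] > beta * lower_peak:
            continue
        bound = beta * lower_peak
        lo_i = m
        while lo_i > 0 and dens[lo_i - 1] <= bound:
            lo_i -= 1
        hi_i = m
        while hi_i < len(g) - 1 and dens[hi_i + 1] <= bound:
            hi_i += 1
        valleys.append(
            Valley(
                left=float(g[lo_i]),
                right=float(g[hi_i]),
                midpoint=float(g[m]),
                depth_ratio=float(dens[m] / lower_peak),
            )
        )
    return valleys


# ---------------------------------------------------------------------------
# classification and cross-species summaries


def classify_species(
    species_id: str,
    values,
    beta: float = 0.5,
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int | None = None,
    bandwidth: float | None = None,
    gap_window: tuple[float, float] = GAP_WINDOW,
    null_dips: np.ndarray | None = None,
) -> GapReport:
    """Classify one species' ANI distribution.

    ``clonal`` when every pair shows ANI above the gap midpoint (99.5);
    ``gap_99.2_99.8`` when a significant valley (KDE valley + dip test
    p < alpha) has its midpoint inside the canonical window; a
    significant valley only outside the window is a ``shifted_gap``;
    anything else (including too few pairs to test) is ``no_gap``.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    n = v.size
    if n == 0:
        return GapReport(species_id, 0, [], None, None, "no_gap", None)
    if float(v.min()) > 99.5:
        return GapReport(species_id, n, [], None, None, "clonal", None)
    if n < 10 or np.unique(v).size < 4:
        logger.info("%s: %d pairs is too few to test; deferring to no_gap", species_id, n)
        return GapReport(species_id, n, [], None, None, "no_gap", None)
    h = bandwidth if bandwidth is not None else silverman_bandwidth(v)
    valleys = find_valleys(v, bandwidth=h, beta=beta)
    dip, p = dip_test(v, n_boot=n_boot, seed=seed, null_dips=null_dips)
    classification = "no_gap"
    if valleys and p < alpha:
        if any(gap_window[0] <= w.midpoint <= gap_window[1] for w in valleys):
            classification = "gap_99.2_99.8"
        else:
            classification = "shifted_gap"
    return GapReport(species_id, n, valleys, dip, p, classification, h, n_boot=n_boot)


def gap_mode(reports: list[GapReport], resolution: float = 0.1) -> float:
    """Modal valley midpoint across species, at 0.1%-ANI resolution.

    Histogram bins are centred on multiples of the resolution (edges at
    x.x5 for 0.1), left-closed; ties break toward higher ANI.
    """
    mids = [w.midpoint for r in reports for w in r.valleys]
    if not mids:
        raise ValueError("no valleys in any report")
    n_bins = int(round(5.0 / resolution)) + 1
    counts = np.zeros(n_bins, dtype=int)
    for m in mids:
        # round-half-up to the nearest bin center (left-closed centred bins)
        k = int(np.floor((m - 95.0) / resolution + 0.5 + 1e-9))
        counts[min(max(k, 0), n_bins - 1)] += 1
    best = counts.max()
    k = int(np.nonzero(counts == best)[0][-1])  # tie -> higher ANI
    return float(round(95.0 + k * resolution, 10))


def subsample_species(
    values_by_pair: dict[tuple[str, str], float] | None = None,
    genomes: list[str] | None = None,
    k: int = 10,
    seed: int | None = None,
) -> tuple[list[str], np.ndarray] | None:
    """Uniformly subsample ``k`` genomes and restrict the pair values.

    Pairwise ANI depends only on the two genomes involved, so restricting
    the full pair table to the sampled genomes equals recomputing it on
    the subset.  Returns (sampled genome ids, pair values) or None (with
    a log entry) when fewer than ``k`` genomes are available.
    """
    if values_by_pair is None:
        raise ValueError("values_by_pair is required")
    if genomes is None:
        genomes = sorted({g for pair in values_by_pair for g in pair})
    if len(genomes) < k:
        logger.info("subsample skipped: %d < k=%d genomes", len(genomes), k)
        return None
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(np.asarray(genomes, dtype=object), size=k, replace=False))
    keep = set(chosen)
    vals = np.array(
        [v for (a, b), v in values_by_pair.items() if a in keep and b in keep], dtype=float
    )
    return list(chosen), vals


def divergence_time(
    divergence_fraction: float,
    mu: float = 4e-10,
    generations_per_year: float = 100.0,
    lineages: int = 2,
) -> float:
    """Years for ``lineages`` lineages to accumulate a divergence fraction.

    Naive fixed-substitution closed form d / (k * mu * g) with a per-site
    per-generation mutation rate mu; e.g. 0.5% divergence at mu = 4e-10
    and 100 generations/year over two lineages gives 62,500 years.
    """
    if mu <= 0 or generations_per_year <= 0:
        raise ValueError("rates must be positive")
    if lineages not in (1, 2):
        raise ValueError("lineages must be 1 or 2")
    if divergence_fraction < 0:
        raise ValueError("divergence must be >= 0")
    return divergence_fraction / (lineages * mu * generations_per_year)
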