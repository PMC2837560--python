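"""Two-class differential expression with a SAM-style moderated t-statistic.

Per probe i the statistic is d_i = r_i / (s_i + s0), with r_i the difference
of group means on the log2 scale (group B minus group A, so r_i is the log2
fold change), s_i the pooled standard error

    s_i = sqrt{ (1/n_a + 1/n_b) * [SS_a + SS_b] / (n_a + n_b - 2) },

and s0 a small positive "fudge factor" chosen to stabilize probes with tiny
variance (the coefficient-of-variation criterion of the original method).
Significance comes from a permutation null pooled across probes: group
labels are reassigned, d recomputed for every probe, and

    p_i = (1 + #{permuted |d| >= |d_i|, pooled}) / (1 + n_probes * n_perm).

When the number of distinct label assignments is small (a 3-vs-3 design has
C(6,3) = 20) the null is enumerated exhaustively. Selection follows the
study convention: significant at p < alpha, with two-fold gates logFC > 1
(up) and logFC < -1 (down).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

DEFAULT_EXHAUSTIVE_CAP = 2000
MIN_PERMUTATIONS = 10

S0_PERCENTILES = np.arange(0, 101, 5)


class SamError(ValueError):
    pass


@dataclass
class SamResult:
    """Per-probe SAM statistics plus the global permutation settings.

    ``table`` columns: r (mean_b - mean_a), s (pooled SE), d, logfc (== r),
    p, significant, up_twofold, down_twofold, degenerate. p columns are NaN
    until :func:`permutation_pvalues` fills them in.
    """

    table: pd.DataFrame
    group_a: str
    group_b: str
    s0: float
    n_permutations: int = 0
    exhaustive: bool = False
    null_abs_d: np.ndarray | None = None

    @property
    def probes(self) -> pd.Index:
        return self.table.index


def _group_columns(ann: pd.Series, m: pd.DataFrame, group: str) -> list[str]:
    cols = [s for s in m.columns if s in ann.index and ann[s] == group]
    if len(cols) < 2:
        raise SamError(f"group {group!r} needs >= 2 samples, found {len(cols)}")
    return cols


def _d_stats(x: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray,
             s0: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """r, s, d for one label assignment over the pooled sample block."""
    xa, xb = x[:, idx_a], x[:, idx_b]
    na, nb = xa.shape[1], xb.shape[1]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    ssa = ((xa - ma[:, None]) ** 2).sum(axis=1)
    ssb = ((xb - mb[:, None]) ** 2).sum(axis=1)
    r = mb - ma
    s = np.sqrt((1.0 / na + 1.0 / nb) * (ssa + ssb) / (na + nb - 2))
    denom = s + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, r / np.where(denom > 0, denom, 1.0), np.nan)
    d = np.where((denom == 0) & (r == 0), 0.0, d)
    return r, s, d


def sam_statistic(m: pd.DataFrame, ann: pd.Series, group_a: str, group_b: str,
                  s0: float | str = "auto") -> SamResult:
    """Compute r, s and d per probe for the contrast group_b vs group_a.

    ``s0="auto"`` selects the fudge factor with :func:`choose_s0`. Probes
    whose denominator s + s0 is zero with a nonzero numerator are flagged
    degenerate and get d = NaN rather than a silent infinity.
    """
    cols_a = _group_columns(ann, m, group_a)
    cols_b = _group_columns(ann, m, group_b)
    x = m[cols_a + cols_b].to_numpy(dtype=float)
    idx_a = np.arange(len(cols_a))
    idx_b = np.arange(len(cols_a), len(cols_a) + len(cols_b))

    r, s, _ = _d_stats(x, idx_a, idx_b, 0.0)
    s0_val = choose_s0(s, r) if isinstance(s0, str) else float(s0)
    if s0_val < 0:
        raise SamError("s0 must be non-negative")
    _, _, d = _d_stats(x, idx_a, idx_b, s0_val)

    table = pd.DataFrame(
        {
            "r": r, "s": s, "d": d, "logfc": r,
            "p": np.nan, "significant": False,
            "up_twofold": False, "down_twofold": False,
            "degenerate": ~np.isfinite(d),
        },
        index=m.index,
    )
    return SamResult(table=table, group_a=group_a, group_b=group_b, s0=s0_val)


def choose_s0(s_values: np.ndarray, d_numerators: np.ndarray,
              n_windows: int = 100) -> float:
    """Select the fudge factor by the coefficient-of-variation criterion.

    Candidates are the 0th, 5th, ..., 100th percentiles of s. For each
    candidate the probes are binned into windows by s-quantile, the median
    absolute deviation of d = r/(s + s0) is taken per window, and the
    candidate minimizing the coefficient of variation of those MADs wins
    (ties break toward the smallest candidate). This flattens the dependence
    of the spread of d on s.
    """
    s = np.asarray(s_values, dtype=float)
    r = np.asarray(d_numerators, dtype=float)
    n = len(s)
    if n < 100:
        warnings.warn(f"choose_s0 called with {n} probes; >= 100 recommended", stacklevel=2)
    candidates = np.percentile(s, S0_PERCENTILES)
    nbins = max(2, min(n_windows, n // 2))
    edges = np.percentile(s, np.linspace(0, 100, nbins + 1)[1:-1])
    bins = np.searchsorted(edges, s, side="left")

    best_cv, best = np.inf, float(candidates[0])
    for cand in candidates:
        denom = s + cand
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(denom > 0, r / np.where(denom > 0, denom, 1.0), 0.0)
        mads = []
        for b in range(nbins):
            db = d[bins == b]
            if len(db):
                mads.append(np.median(np.abs(db - np.median(db))) / 0.64)
        mads = np.array(mads)
        mean = mads.mean() if len(mads) else 0.0
        cv = mads.std(ddof=0) / mean if mean > 0 else np.inf
        if cv < best_cv - 1e-15:
            best_cv, best = cv, float(cand)
    return best


def _assignments(n: int, na: int, n_perm, cap: int, seed) -> tuple[list[tuple[int, ...]], bool]:
    total = comb(n, na)
    exhaustive = n_perm == "exhaustive" or (isinstance(n_perm, int) and total <= cap) or total <= cap
    if exhaustive:
        return [c for c in combinations(range(n), na)], True
    if not isinstance(n_perm, int):
        raise SamError("n_perm must be an integer or 'exhaustive'")
    if n_perm < MIN_PERMUTATIONS:
        raise SamError(f"n_perm={n_perm} is uninformative; need >= {MIN_PERMUTATIONS}")
    n_perm = min(n_perm, total)
    rng = np.random.default_rng(seed)
    chosen: set[tuple[int, ...]] = set()
    attempts = 0
    while len(chosen) < n_perm and attempts < 1000 * n_perm:
        pick = tuple(sorted(rng.choice(n, size=na, replace=False).tolist()))
        chosen.add(pick)
        attempts += 1
    return sorted(chosen), False


def permutation_pvalues(
    m: pd.DataFrame,
    ann: pd.Series,
    group_a: str,
    group_b: str,
    s0: float,
    n_perm: int | str = "exhaustive",
    seed: int | None = 0,
    exhaustive_cap: int = DEFAULT_EXHAUSTIVE_CAP,
) -> SamResult:
    """Permutation p-values from a pooled null of relabeled d statistics.

    All C(n_a + n_b, n_a) label assignments are enumerated when their count
    is at most ``exhaustive_cap``; otherwise ``n_perm`` distinct assignments
    are sampled without replacement (seeded). The observed assignment is a
    legitimate member of the null either way. p is pooled across probes and
    assignments with a +1 pseudocount, so p is in (0, 1].
    """
    res = sam_statistic(m, ann, group_a, group_b, s0=s0)
    cols_a = _group_columns(ann, m, group_a)
    cols_b = _group_columns(ann, m, group_b)
    x = m[cols_a + cols_b].to_numpy(dtype=float)
    n = len(cols_a) + len(cols_b)
    na = len(cols_a)

    assigns, exhaustive = _assignments(n, na, n_perm, exhaustive_cap, seed)
    all_idx = np.arange(n)
    null_abs: list[np.ndarray] = []
    for a_idx in assigns:
        ia = np.array(a_idx)
        ib = np.setdiff1d(all_idx, ia, assume_unique=True)
        _, _, d_perm = _d_stats(x, ia, ib, res.s0)
        null_abs.append(np.abs(d_perm))
    null_pool = np.concatenate(null_abs)
    null_pool = null_pool[np.isfinite(null_pool)]
    null_sorted = np.sort(null_pool)
    total = len(null_sorted)

    d_obs = res.table["d"].to_numpy()
    abs_d = np.abs(d_obs)
    finite = np.isfinite(abs_d)
    count_ge = np.full(len(abs_d), np.nan)
    count_ge[finite] = total - np.searchsorted(null_sorted, abs_d[finite], side="left")
    p = (1.0 + count_ge) / (1.0 + total)

    res.table["p"] = p
    res.n_permutations = len(assigns)
    res.exhaustive = exhaustive
    res.null_abs_d = np.array(null_abs)
    return res


@dataclass
class DeSelection:
    de: pd.Index
    up: pd.Index
    down: pd.Index
    alpha: float
    logfc_hi: float
    logfc_lo: float

    def counts(self) -> dict[str, int]:
        return {"n_de": len(self.de), "n_up_twofold": len(self.up),
                "n_down_twofold": len(self.down)}


def select_de(res: SamResult, alpha: float = 0.05,
              logfc_hi: float = 1.0, logfc_lo: float = -1.0) -> DeSelection:
    """Apply the significance and two-fold gates, updating the result flags.

    de = {p < alpha}; up = de and logFC > logfc_hi; down = de and
    logFC < logfc_lo. Up and down are disjoint subsets of de.
    """
    t = res.table
    if t["p"].isna().all():
        raise SamError("run permutation_pvalues before select_de")
    sig = t["p"] < alpha
    up = sig & (t["logfc"] > logfc_hi)
    down = sig & (t["logfc"] < logfc_lo)
    t["significant"] = sig
    t["up_twofold"] = up
    t["down_twofold"] = down
    return DeSelection(de=t.index[sig], up=t.index[up], down=t.index[down],
                       alpha=alpha, logfc_hi=logfc_hi, logfc_lo=logfc_lo)


def median_false_calls(res: SamResult, abs_d_threshold: float) -> float:
    """Median, over permutations, of probes with |d| at or above a cutoff.

    The optional SAM-style estimate of the median number of falsely called
    probes at a given |d| threshold.
    """
    if res.null_abs_d is None:
        raise SamError("permutation null not available; run permutation_pvalues")
    counts = (res.null_abs_d >= abs_d_threshold).sum(axis=1)
    return float(np.median(counts))
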