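"""Quality-control gates and normalization for expression matrices.

QC mirrors common array practice on summarized intensities: a present-call
proxy (fraction of probes above a background level must exceed 25%) and a
within-group Euclidean-distance check of biological replicates. QC only
reports; excluding samples is an explicit separate step. Normalization is
quantile normalization across samples; probe-set summarization uses Tukey's
median polish.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .io import InputError, validate_matrix

PRESENT_CALL_MIN_FRACTION = 0.25


def background_correct(m: pd.DataFrame, method=None) -> pd.DataFrame:
    """Hook for probe-level background correction; identity by default.

    Sequence-aware correction needs raw probe data, which summarized
    matrices no longer carry, so the default pipeline applies no correction;
    a callable taking and returning a matrix can be plugged in.
    """
    if method is None:
        return m
    out = method(m)
    return validate_matrix(out)


def default_background_threshold(m: pd.DataFrame) -> float:
    """Background level proxy: 25th percentile of the pooled intensities."""
    return float(np.percentile(m.to_numpy(dtype=float), 25))


def above_background_fraction(m: pd.DataFrame, threshold: float) -> pd.Series:
    """Per-sample fraction of probes with intensity strictly above threshold."""
    validate_matrix(m)
    if not np.isfinite(threshold):
        raise InputError("background threshold must be finite")
    frac = (m.to_numpy(dtype=float) > threshold).mean(axis=0)
    return pd.Series(frac, index=m.columns, name="above_background_fraction")


def present_call_gate(fractions: pd.Series,
                      min_fraction: float = PRESENT_CALL_MIN_FRACTION) -> pd.Series:
    """Pass iff the above-background fraction strictly exceeds the gate."""
    return (fractions > min_fraction).rename("present_call_pass")


@dataclass
class QcReport:
    """Per-sample QC outcome; gates report, they never mutate the matrix."""

    above_background: pd.Series
    present_call_pass: pd.Series
    distances: pd.DataFrame
    flagged: dict[str, str]
    unevaluable: list[str]

    def failed_samples(self) -> list[str]:
        failed = set(self.present_call_pass.index[~self.present_call_pass])
        failed |= set(self.flagged)
        return sorted(failed)

    def to_dict(self) -> dict:
        return {
            "above_background": {s: float(v) for s, v in self.above_background.items()},
            "present_call_pass": {s: bool(v) for s, v in self.present_call_pass.items()},
            "flagged": dict(self.flagged),
            "unevaluable": list(self.unevaluable),
            "failed_samples": self.failed_samples(),
        }


def replicate_distance_check(
    m: pd.DataFrame,
    ann: pd.Series,
    max_ratio: float = 2.0,
    background_threshold: float | None = None,
) -> QcReport:
    """Check within-group similarity of replicate profiles by Euclidean distance.

    A sample is flagged when its mean distance to the other members of its
    group exceeds ``max_ratio`` times the group's median within-group
    pairwise distance. Singleton groups are recorded as unevaluable, not
    failed. The report also carries the present-call proxy so one QC pass
    covers both gates.
    """
    validate_matrix(m)
    if background_threshold is None:
        background_threshold = default_background_threshold(m)
    frac = above_background_fraction(m, background_threshold)

    dist = pd.DataFrame(
        squareform(pdist(m.to_numpy(dtype=float).T, metric="euclidean")),
        index=m.columns, columns=m.columns,
    )
    flagged: dict[str, str] = {}
    unevaluable: list[str] = []
    for g in ann.loc[list(m.columns)].unique():
        members = [s for s in m.columns if ann[s] == g]
        if len(members) < 2:
            unevaluable.extend(members)
            continue
        sub = dist.loc[members, members]
        pairwise = sub.to_numpy()[np.triu_indices(len(members), k=1)]
        med = float(np.median(pairwise))
        for s in members:
            mean_d = float(sub.loc[s, [x for x in members if x != s]].mean())
            if mean_d > max_ratio * med:
                flagged[s] = (
                    f"mean within-group distance {mean_d:.4g} exceeds "
                    f"{max_ratio} x group median {med:.4g}"
                )
    return QcReport(
        above_background=frac,
        present_call_pass=present_call_gate(frac),
        distances=dist,
        flagged=flagged,
        unevaluable=unevaluable,
    )


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the common mean quantile distribution.

    The reference distribution is the row-wise mean of the column-sorted
    input. Ties within a column receive the mean of the reference values at
    their tied ranks (average ranks, linearly interpolated), which keeps the
    transform deterministic.
    """
    validate_matrix(m)
    if m.shape[1] < 2:
        raise InputError("quantile normalization needs at least 2 samples")
    x = m.to_numpy(dtype=float)
    n = x.shape[0]
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, reference)
    return pd.DataFrame(out, index=m.index, columns=m.columns)


@dataclass
class MedianPolishResult:
    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    converged: bool
    n_iter: int

    @property
    def summaries(self) -> np.ndarray:
        """Per-sample summary values: overall effect + column effect."""
        return self.overall + self.col_effects


def median_polish_summarize(
    probe_level: np.ndarray | pd.DataFrame, max_iter: int = 20, tol: float = 1e-9
) -> MedianPolishResult:
    """Tukey median polish of an additive two-way model, rows swept first.

    Iteratively subtracts row medians then column medians from the residuals
    (folding the medians of the accumulated effects into the overall term)
    until every sweep median is below ``tol`` in magnitude or ``max_iter`` is
    reached, in which case ``converged`` is False. The per-sample summary is
    overall + column effect, the usual probe-set summarization convention.
    """
    z = np.array(probe_level, dtype=float)
    if z.ndim != 2 or z.size == 0:
        raise InputError("median polish needs a non-empty 2-D matrix")
    if not np.isfinite(z).all():
        raise InputError("median polish input must be finite")
    nr, nc = z.shape
    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rdelta = np.median(z, axis=1)
        z -= rdelta[:, None]
        row += rdelta
        dr = np.median(row)
        row -= dr
        overall += dr

        cdelta = np.median(z, axis=0)
        z -= cdelta[None, :]
        col += cdelta
        dc = np.median(col)
        col -= dc
        overall += dc

        if max(np.abs(rdelta).max(), np.abs(cdelta).max()) < tol:
            converged = True
            break
    return MedianPolishResult(
        overall=overall, row_effects=row, col_effects=col,
        residuals=z, converged=converged, n_iter=it,
    )
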