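"""Nearest-shrunken-centroid classification (prediction analysis of microarrays).

For probe i and class k, the standardized centroid deviation is

    d_ik = (xbar_ik - xbar_i) / (m_k * (s_i + s0)),

with xbar_i the overall centroid, xbar_ik the class centroid, s_i the pooled
within-class standard deviation, s0 = median_i(s_i), and
m_k = sqrt(1/n_k - 1/n) (the variance factor of xbar_ik - xbar_i when the
overall centroid includes class k; the "+" form found in some presentations
is available via ``mk_form="plus"``). Soft thresholding

    d'_ik = sign(d_ik) * max(|d_ik| - Delta, 0)

shrinks the deviations; probes with any nonzero d'_ik survive and define the
classifier gene set. A sample x is assigned by the discriminant

    delta_k(x) = sum_{i in survivors} (x_i - xbar'_ik)^2 / (s_i + s0)^2
                 - 2 log pi_k,

minimized over classes, with class probabilities proportional to
exp(-delta_k / 2). The shrinkage threshold is chosen by stratified
cross-validation; see :func:`cross_validate` for the tie-break rule.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

DEFAULT_GRID_SIZE = 30


class PamError(ValueError):
    pass


def soft_threshold(d, delta: float):
    """sign(d) * max(|d| - delta, 0); accepts scalars or arrays."""
    if delta < 0:
        raise PamError("delta must be non-negative")
    d = np.asarray(d, dtype=float)
    out = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class PamModel:
    classes: list[str]
    priors: pd.Series
    n_per_class: pd.Series
    overall_centroid: pd.Series
    class_centroids: pd.DataFrame  # probes x classes
    pooled_sd: pd.Series
    s0: float
    m_k: pd.Series
    d: pd.DataFrame  # probes x classes, raw statistics
    mk_form: str = "minus"
    delta: float | None = None
    d_shrunk: pd.DataFrame | None = None
    shrunken_centroids: pd.DataFrame | None = None

    @property
    def survivors(self) -> pd.Index:
        if self.d_shrunk is None:
            raise PamError("model not shrunken; call shrink(model, delta) first")
        alive = (self.d_shrunk != 0).any(axis=1)
        return self.d_shrunk.index[alive]

    @property
    def max_abs_d(self) -> float:
        return float(np.abs(self.d.to_numpy()).max())


def fit(m: pd.DataFrame, ann: pd.Series, mk_form: str = "minus") -> PamModel:
    """Fit centroids and standardized deviations; Delta is chosen later.

    Requires at least two classes with at least two samples each. Probes for
    which the denominator vanishes (zero pooled variance everywhere and
    s0 = 0) get d = 0 rather than a silent infinity.
    """
    if mk_form not in ("minus", "plus"):
        raise PamError("mk_form must be 'minus' or 'plus'")
    labels = ann.loc[list(m.columns)]
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise PamError("need at least two classes")
    n = len(m.columns)
    n_k = labels.value_counts().reindex(classes)
    if (n_k < 2).any():
        raise PamError(f"every class needs >= 2 samples: {dict(n_k)}")

    x = m.to_numpy(dtype=float)
    overall = x.mean(axis=1)
    cent = {}
    within_ss = np.zeros(x.shape[0])
    for k in classes:
        cols = [j for j, s in enumerate(m.columns) if labels[s] == k]
        xk = x[:, cols]
        mk = xk.mean(axis=1)
        cent[k] = mk
        within_ss += ((xk - mk[:, None]) ** 2).sum(axis=1)
    pooled_sd = np.sqrt(within_ss / (n - len(classes)))
    s0 = float(np.median(pooled_sd))

    sign = -1.0 if mk_form == "minus" else 1.0
    m_k = pd.Series({k: float(np.sqrt(1.0 / n_k[k] + sign / n)) for k in classes})

    denom_base = pooled_sd + s0
    d = {}
    for k in classes:
        denom = m_k[k] * denom_base
        with np.errstate(divide="ignore", invalid="ignore"):
            dk = np.where(denom > 0, (cent[k] - overall) / np.where(denom > 0, denom, 1.0), 0.0)
        d[k] = dk

    return PamModel(
        classes=classes,
        priors=pd.Series({k: n_k[k] / n for k in classes}),
        n_per_class=n_k,
        overall_centroid=pd.Series(overall, index=m.index),
        class_centroids=pd.DataFrame(cent, index=m.index),
        pooled_sd=pd.Series(pooled_sd, index=m.index),
        s0=s0,
        m_k=m_k,
        d=pd.DataFrame(d, index=m.index),
        mk_form=mk_form,
    )


def shrink(model: PamModel, delta: float) -> PamModel:
    """Apply soft thresholding at Delta, producing shrunken centroids."""
    d_shrunk = pd.DataFrame(
        soft_threshold(model.d.to_numpy(), delta),
        index=model.d.index, columns=model.d.columns,
    )
    base = (model.pooled_sd + model.s0).to_numpy()[:, None]
    mk = model.m_k[model.d.columns].to_numpy()[None, :]
    shrunken = model.overall_centroid.to_numpy()[:, None] + mk * base * d_shrunk.to_numpy()
    return replace(
        model,
        delta=float(delta),
        d_shrunk=d_shrunk,
        shrunken_centroids=pd.DataFrame(shrunken, index=model.d.index, columns=model.d.columns),
    )


@dataclass
class ClassPrediction:
    label: str
    probabilities: pd.Series
    prior_fallback: bool = False


def classify(model: PamModel, x: pd.Series | np.ndarray) -> ClassPrediction:
    """Classify one profile with the shrunken-centroid discriminant.

    With zero surviving probes the discriminant is empty and the prediction
    falls back to the class priors, flagged as such.
    """
    if model.d_shrunk is None:
        raise PamError("model not shrunken; call shrink(model, delta) first")
    surv = model.survivors
    if len(surv) == 0:
        label = model.priors.idxmax()
        return ClassPrediction(label=label, probabilities=model.priors.copy(),
                               prior_fallback=True)
    if isinstance(x, pd.Series):
        xv = x.reindex(model.d.index).to_numpy(dtype=float)
    else:
        xv = np.asarray(x, dtype=float)
    pos = model.d.index.get_indexer(surv)
    xs = xv[pos]
    denom2 = ((model.pooled_sd + model.s0).to_numpy()[pos]) ** 2
    scores = {}
    for k in model.classes:
        cent = model.shrunken_centroids[k].to_numpy()[pos]
        scores[k] = float(((xs - cent) ** 2 / denom2).sum() - 2.0 * np.log(model.priors[k]))
    delta_k = pd.Series(scores)
    w = np.exp(-0.5 * (delta_k - delta_k.min()))
    probs = w / w.sum()
    return ClassPrediction(label=delta_k.idxmin(), probabilities=probs)


def predict(model: PamModel, m: pd.DataFrame) -> pd.DataFrame:
    """Classify every column of a matrix; returns labels and probabilities."""
    rows = {}
    for s in m.columns:
        pred = classify(model, m[s])
        rows[s] = {"label": pred.label, "prior_fallback": pred.prior_fallback,
                   **{f"p_{k}": pred.probabilities[k] for k in model.classes}}
    return pd.DataFrame.from_dict(rows, orient="index")


def infer_positive_class(classes: list[str], normal_label: str = "normal") -> str:
    """The disease (positive) class: the non-normal label of a 2-class problem."""
    if normal_label in classes and len(classes) == 2:
        return next(k for k in classes if k != normal_label)
    return sorted(classes)[-1]


def confusion_matrix(true: pd.Series, predicted: pd.Series, classes: list[str]) -> pd.DataFrame:
    cm = pd.DataFrame(0, index=classes, columns=classes)
    for s in true.index:
        cm.loc[true[s], predicted[s]] += 1
    cm.index.name = "true"
    cm.columns.name = "predicted"
    return cm


def sensitivity_specificity(cm: pd.DataFrame, positive: str) -> tuple[float, float]:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP), in percent."""
    tp = cm.loc[positive, positive]
    fn = cm.loc[positive].sum() - tp
    negatives = [k for k in cm.index if k != positive]
    tn = sum(cm.loc[k, k2] for k in negatives for k2 in negatives)
    fp = cm.loc[negatives].sum().sum() - tn
    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return float(sens), float(spec)


@dataclass
class CvResult:
    grid: np.ndarray
    cv_errors: np.ndarray
    survivor_counts: np.ndarray
    chosen_delta: float
    predictions: pd.Series  # held-out predicted class at chosen delta
    probabilities: pd.DataFrame  # held-out class probabilities at chosen delta
    confusion: pd.DataFrame
    sensitivity: float
    specificity: float
    positive_class: str
    model: PamModel  # full-data model shrunken at chosen delta


def _choose_delta(grid: np.ndarray, errors: np.ndarray, survivors: np.ndarray) -> float:
    """Pick Delta among the minimum-CV-error grid points.

    Minimum-error points are grouped into consecutive runs over which the
    full-data survivor count is constant; the run spanning the widest Delta
    interval wins (stability of the gene set under the threshold), and the
    largest Delta inside it is returned for parsimony. With a single
    minimizing point this reduces to that point; with several equally wide
    runs the higher-Delta run wins.
    """
    best = errors.min()
    cand = np.flatnonzero(errors == best)
    runs: list[list[int]] = []
    for i in cand:
        if runs and i == runs[-1][-1] + 1 and survivors[i] == survivors[runs[-1][-1]]:
            runs[-1].append(i)
        else:
            runs.append([i])
    widths = [grid[r[-1]] - grid[r[0]] for r in runs]
    best_run = max(range(len(runs)), key=lambda j: (widths[j], grid[runs[j][-1]]))
    return float(grid[runs[best_run][-1]])


def cross_validate(
    m: pd.DataFrame,
    ann: pd.Series,
    delta_grid: np.ndarray | str = "auto",
    k_folds: int = 10,
    seed: int = 0,
    positive_class: str | None = None,
    normal_label: str = "normal",
) -> CvResult:
    """Stratified k-fold cross-validation over a shrinkage grid.

    The grid (``"auto"``: 30 points from 0 to the full-data max |d_ik|) is
    evaluated on held-out predictions; sensitivity and specificity are
    reported at the chosen Delta with the disease class as positive. The
    fold count is capped at the smallest class size so no fold can lose an
    entire class.
    """
    labels = ann.loc[list(m.columns)]
    full = fit(m, ann)
    if isinstance(delta_grid, str):
        grid = np.linspace(0.0, full.max_abs_d, DEFAULT_GRID_SIZE)
    else:
        grid = np.sort(np.asarray(delta_grid, dtype=float))
    if len(grid) == 0:
        raise PamError("empty delta grid")

    k = min(k_folds, int(labels.value_counts().min()))
    if k < 2:
        raise PamError("need k_folds >= 2 and every class with >= 2 samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    samples = np.array(m.columns)

    pred = {d_i: {} for d_i in range(len(grid))}
    probs = {d_i: {} for d_i in range(len(grid))}
    for train_idx, test_idx in skf.split(samples, labels.to_numpy()):
        train, test = samples[train_idx], samples[test_idx]
        fold_model = fit(m[list(train)], ann)
        for d_i, delta in enumerate(grid):
            shrunk = shrink(fold_model, delta)
            for s in test:
                p = classify(shrunk, m[s])
                pred[d_i][s] = p.label
                probs[d_i][s] = p.probabilities

    errors = np.array([
        sum(pred[d_i][s] != labels[s] for s in samples) for d_i in range(len(grid))
    ])
    survivor_counts = np.array([
        len(shrink(full, delta).survivors) for delta in grid
    ])
    chosen = _choose_delta(grid, errors, survivor_counts)
    chosen_i = int(np.flatnonzero(grid == chosen)[0])

    predictions = pd.Series({s: pred[chosen_i][s] for s in samples}).reindex(samples)
    probabilities = pd.DataFrame({s: probs[chosen_i][s] for s in samples}).T.reindex(samples)
    cm = confusion_matrix(labels, predictions, full.classes)
    pos = positive_class or infer_positive_class(full.classes, normal_label)
    sens, spec = sensitivity_specificity(cm, pos)
    return CvResult(
        grid=grid, cv_errors=errors, survivor_counts=survivor_counts,
        chosen_delta=chosen, predictions=predictions, probabilities=probabilities,
        confusion=cm, sensitivity=sens, specificity=spec, positive_class=pos,
        model=shrink(full, chosen),
    )


def classifier_genes(
    model: PamModel,
    symbol_map: pd.Series | None = None,
    disease_class: str | None = None,
    normal_label: str = "normal",
) -> pd.DataFrame:
    """Surviving probes ordered by shrunken-deviation magnitude.

    ``direction`` is the sign of the disease-class shrunken deviation (+1 up
    in disease); ``disease_logfc`` is the raw disease-minus-normal centroid
    difference on the log2 scale. Duplicate symbols from a many-to-one probe
    map are retained at probe level.
    """
    surv = model.survivors
    disease = disease_class or infer_positive_class(model.classes, normal_label)
    others = [k for k in model.classes if k != disease]
    rows = []
    for probe in surv:
        d_row = model.d_shrunk.loc[probe]
        direction = int(np.sign(d_row[disease])) or int(-np.sign(d_row[others[0]]))
        ref = model.class_centroids.loc[probe, others].mean()
        rows.append({
            "probe_id": probe,
            "symbol": symbol_map[probe] if symbol_map is not None and probe in symbol_map.index else probe,
            "direction": direction,
            "score": float(d_row.abs().max()),
            "disease_logfc": float(model.class_centroids.loc[probe, disease] - ref),
        })
    out = pd.DataFrame(rows, columns=["probe_id", "symbol", "direction", "score", "disease_logfc"])
    if len(out):
        out = out.sort_values("score", ascending=False, kind="mergesort").reset_index(drop=True)
    return out
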