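"""Relative quantification of qPCR threshold cycles by the ddCT method.

Implements the standard comparative-CT workflow: technical-replicate QC
(a triple is accepted when its CT range is under half a cycle), an optional
assay-quality filter on the normalized-reporter signal (dRn), reference-gene
normalization (dCT = CT_target - CT_reference per sample), group comparison
(ddCT = mean dCT(case) - mean dCT(control), fold change = 2^-ddCT), a
pooled-variance two-sample t-test on the per-sample dCT values, and a
direction-concordance check against microarray fold changes.

Undetermined CTs (no amplification within the run's 40 cycles, encoded as
NaN) are excluded with a reason rather than imputed; imputing the cycle cap
would bias ddCT toward the cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

CT_MAX = 40.0

_REQUIRED_COLUMNS = ("sample_id", "gene", "replicate", "ct")


@dataclass
class CtTable:
    """Long-format threshold-cycle table.

    ``data`` has one row per (sample, gene, technical replicate) with columns
    sample_id, gene, replicate, ct and optionally delta_rn. ``groups`` maps
    sample_id to its histological group. NaN CT means undetermined.
    """

    data: pd.DataFrame
    reference_gene: str
    groups: pd.Series

    def __post_init__(self):
        missing = [c for c in _REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"CT table missing columns: {missing}")
        ct = self.data["ct"]
        bad = ct[(ct <= 0) | (ct > CT_MAX)].dropna()
        if len(bad):
            raise ValueError(
                f"{len(bad)} CT values outside (0, {CT_MAX}]; mark undetermined as NaN"
            )
        samples = set(self.data["sample_id"])
        unlabeled = samples - set(self.groups.index)
        if unlabeled:
            raise ValueError(f"samples without group label: {sorted(unlabeled)}")
        with_ref = set(self.data.loc[self.data["gene"] == self.reference_gene, "sample_id"])
        no_ref = samples - with_ref
        if no_ref:
            raise ValueError(f"reference gene {self.reference_gene!r} missing for: {sorted(no_ref)}")

    @property
    def has_delta_rn(self) -> bool:
        return "delta_rn" in self.data.columns and self.data["delta_rn"].notna().any()

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, reference_gene: str, groups: pd.Series) -> "CtTable":
        data = pd.read_csv(path)
        return cls(data=data, reference_gene=reference_gene, groups=groups)


@dataclass
class ReplicateQc:
    """Replicate-collapsed table plus the exclusion log."""

    accepted: pd.DataFrame  # one row per (sample_id, gene): mean ct
    exclusions: pd.DataFrame  # sample_id, gene, reason


def replicate_qc(t: CtTable, max_range: float = 0.5) -> ReplicateQc:
    """Collapse technical replicates, excluding over-dispersed triples.

    A replicate set is accepted iff max(CT) - min(CT) < ``max_range`` (the
    gate is strict: a range of exactly half a cycle fails). Undetermined CTs
    are dropped before the range is computed and logged; a (sample, gene)
    whose replicates are all undetermined is dropped with a reason.
    """
    accepted_rows, excluded_rows = [], []
    for (sample, gene), grp in t.data.groupby(["sample_id", "gene"], sort=False):
        cts = grp["ct"].dropna()
        n_und = grp["ct"].isna().sum()
        if n_und:
            excluded_rows.append(
                {"sample_id": sample, "gene": gene,
                 "reason": f"{n_und} undetermined replicate(s) dropped"}
            )
        if len(cts) == 0:
            excluded_rows.append(
                {"sample_id": sample, "gene": gene, "reason": "all replicates undetermined"}
            )
            continue
        rng = cts.max() - cts.min()
        if rng < max_range:
            accepted_rows.append({"sample_id": sample, "gene": gene, "ct": cts.mean()})
        else:
            excluded_rows.append(
                {"sample_id": sample, "gene": gene,
                 "reason": f"replicate range {rng:.3g} >= {max_range}"}
            )
    accepted = pd.DataFrame(accepted_rows, columns=["sample_id", "gene", "ct"])
    exclusions = pd.DataFrame(excluded_rows, columns=["sample_id", "gene", "reason"])
    return ReplicateQc(accepted=accepted, exclusions=exclusions)


def drn_outlier_filter(t: CtTable, k: float = 3.0) -> tuple[CtTable, pd.DataFrame]:
    """Exclude assays whose dRn deviates from the gene's mean by more than k SDs.

    The quality rule "significantly differing from the average dRn" is made
    concrete as a per-gene k-sigma filter. Tables without a dRn column pass
    through unchanged with an empty exclusion log.
    """
    if not t.has_delta_rn:
        return t, pd.DataFrame(columns=["sample_id", "gene", "replicate", "reason"])
    keep = pd.Series(True, index=t.data.index)
    excluded_rows = []
    for gene, grp in t.data.groupby("gene", sort=False):
        drn = grp["delta_rn"].astype(float)
        sd = drn.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            continue
        mean = drn.mean()
        out = grp.index[(drn - mean).abs() > k * sd]
        keep.loc[out] = False
        for i in out:
            excluded_rows.append(
                {"sample_id": t.data.at[i, "sample_id"], "gene": gene,
                 "replicate": t.data.at[i, "replicate"],
                 "reason": f"delta_rn deviates > {k} SD from gene mean"}
            )
    kept = CtTable(data=t.data[keep].reset_index(drop=True),
                   reference_gene=t.reference_gene, groups=t.groups)
    return kept, pd.DataFrame(excluded_rows, columns=["sample_id", "gene", "replicate", "reason"])


def _pooled_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Student's pooled-variance two-sample t-test (textbook form).

    Degenerate zero-variance cases are resolved explicitly: equal means give
    t=0, p=1; unequal means with zero pooled variance give infinite t, p=0.
    """
    nx, ny = len(x), len(y)
    diff = x.mean() - y.mean()
    ss = ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
    df = nx + ny - 2
    sp2 = ss / df
    se = np.sqrt(sp2 * (1 / nx + 1 / ny))
    if se == 0:
        return (0.0, 1.0) if diff == 0 else (np.inf if diff > 0 else -np.inf, 0.0)
    tstat = diff / se
    p = 2 * stats.t.sf(abs(tstat), df)
    return float(tstat), float(p)


@dataclass
class DdctResult:
    """Per-gene ddCT quantification between two groups."""

    case_group: str
    control_group: str
    per_gene: pd.DataFrame  # gene, ddct, fold_change, t_stat, p_value, n_case, n_control
    delta_ct: pd.DataFrame  # sample_id, gene, group, delta_ct
    exclusions: pd.DataFrame = field(default_factory=pd.DataFrame)


def ddct_quantify(qc: ReplicateQc | pd.DataFrame, t: CtTable,
                  case_group: str, control_group: str,
                  welch: bool = False) -> DdctResult:
    """Quantify relative expression by ddCT between two sample groups.

    Takes the replicate-collapsed table (one mean CT per sample and gene).
    Genes are normalized per sample against the reference gene; samples of
    the two requested groups enter the group means. A group with fewer than
    two samples for a gene still yields a fold change but no t-test.
    ``welch=True`` swaps the pooled-variance Student test for Welch's.
    """
    collapsed = qc.accepted if isinstance(qc, ReplicateQc) else qc
    wide = collapsed.pivot(index="sample_id", columns="gene", values="ct")
    if t.reference_gene not in wide.columns:
        raise ValueError(f"reference gene {t.reference_gene!r} absent after QC")
    ref = wide[t.reference_gene]
    genes = [g for g in wide.columns if g != t.reference_gene]

    delta_rows, gene_rows = [], []
    groups = t.groups
    for gene in genes:
        dct = (wide[gene] - ref).dropna()
        for sample, v in dct.items():
            delta_rows.append({"sample_id": sample, "gene": gene,
                               "group": groups[sample], "delta_ct": v})
        case = dct[[s for s in dct.index if groups[s] == case_group]].to_numpy()
        ctrl = dct[[s for s in dct.index if groups[s] == control_group]].to_numpy()
        if len(case) == 0 or len(ctrl) == 0:
            continue
        ddct = case.mean() - ctrl.mean()
        fc = 2.0 ** (-ddct)
        if len(case) >= 2 and len(ctrl) >= 2:
            if welch:
                res = stats.ttest_ind(case, ctrl, equal_var=False)
                tstat, p = float(res.statistic), float(res.pvalue)
            else:
                tstat, p = _pooled_t_test(case, ctrl)
        else:
            tstat, p = np.nan, np.nan
        gene_rows.append({"gene": gene, "ddct": ddct, "fold_change": fc,
                          "t_stat": tstat, "p_value": p,
                          "n_case": len(case), "n_control": len(ctrl)})
    per_gene = pd.DataFrame(gene_rows, columns=["gene", "ddct", "fold_change",
                                                "t_stat", "p_value", "n_case", "n_control"])
    delta_ct = pd.DataFrame(delta_rows, columns=["sample_id", "gene", "group", "delta_ct"])
    exclusions = qc.exclusions if isinstance(qc, ReplicateQc) else pd.DataFrame()
    return DdctResult(case_group=case_group, control_group=control_group,
                      per_gene=per_gene, delta_ct=delta_ct, exclusions=exclusions)


def microarray_concordance(d: DdctResult, microarray_fc: pd.Series) -> tuple[pd.DataFrame, dict]:
    """Direction concordance between qPCR and microarray fold changes.

    Two fold changes agree when both lie on the same side of 1. A fold change
    exactly 1 on either side is indeterminate and excluded from the
    denominator.
    """
    rows = []
    for _, r in d.per_gene.iterrows():
        gene = r["gene"]
        if gene not in microarray_fc.index:
            continue
        fc_pcr, fc_arr = float(r["fold_change"]), float(microarray_fc[gene])
        if fc_pcr == 1.0 or fc_arr == 1.0:
            same = None
        else:
            same = (fc_pcr - 1.0) * (fc_arr - 1.0) > 0
        rows.append({"gene": gene, "fold_change_pcr": fc_pcr,
                     "fold_change_microarray": fc_arr,
                     "p_value": r["p_value"], "same_direction": same})
    table = pd.DataFrame(rows, columns=["gene", "fold_change_pcr", "fold_change_microarray",
                                        "p_value", "same_direction"])
    evaluable = table["same_direction"].notna()
    counts = {
        "n_total": int(evaluable.sum()),
        "n_concordant": int(table.loc[evaluable, "same_direction"].sum()),
        "n_indeterminate": int((~evaluable).sum()),
    }
    return table, counts
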