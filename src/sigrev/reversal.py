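"""Directional reversal scoring of disease-classifier genes under treatment.

A classifier gene is "reversed" when the drug-induced change in the treated
cell line has the sign opposite to the gene's disease-vs-normal change and
exceeds a minimum magnitude (default 0: any opposite-sign change counts; a
treatment logFC of exactly zero is no change, never reversal). A reversal is
additionally "significant" when the treatment-contrast permutation p-value
is below alpha. The summary is the count triple (classifiers, reversed,
reversed and significant) per contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pam import PamModel, PamError
from .sam import SamResult


@dataclass
class ReversalRecord:
    probe_id: str
    symbol: str
    disease_direction: int
    treatment_logfc: float
    treatment_p: float
    reversed: bool
    reversed_significant: bool
    matched: bool = True
    ambiguous_match: bool = False


@dataclass
class ReversalSummary:
    contrast: str
    n_classifiers: int
    n_reversed: int
    n_reversed_significant: int
    records: list[ReversalRecord]
    unmatched: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "contrast": self.contrast,
            "n_classifiers": self.n_classifiers,
            "n_reversed": self.n_reversed,
            "n_reversed_significant": self.n_reversed_significant,
            "n_unmatched": len(self.unmatched),
            "unmatched": list(self.unmatched),
        }

    def records_frame(self) -> pd.DataFrame:
        cols = ["probe_id", "symbol", "disease_direction", "treatment_logfc",
                "treatment_p", "reversed", "reversed_significant", "matched",
                "ambiguous_match"]
        return pd.DataFrame([vars(r) for r in self.records], columns=cols)


def disease_direction(model: PamModel, probe: str) -> int:
    """Sign of the disease-vs-normal shrunken-centroid difference of a survivor.

    For a two-class model this equals the sign of the raw centroid
    difference whenever the probe survives (shrinkage moves deviations
    toward zero without crossing it).
    """
    if model.d_shrunk is None:
        raise PamError("model not shrunken")
    if probe not in set(model.survivors):
        raise KeyError(f"probe {probe!r} is not a surviving classifier gene")
    from .pam import infer_positive_class

    disease = infer_positive_class(model.classes)
    others = [k for k in model.classes if k != disease]
    diff = (model.shrunken_centroids.loc[probe, disease]
            - model.shrunken_centroids.loc[probe, others].mean())
    return int(np.sign(diff))


def _lookup(sam_table: pd.DataFrame, probe: str, symbol: str,
            match_by: str, symbol_map: pd.Series | None):
    """Resolve a classifier probe in the treatment DE table.

    Returns (logfc, p, matched, ambiguous). Probe-ID join first; under the
    symbol policy the probe with the largest |treatment logFC| among those
    sharing the symbol is taken and the match flagged ambiguous when several
    probes map to it.
    """
    if probe in sam_table.index:
        row = sam_table.loc[probe]
        return float(row["logfc"]), float(row["p"]), True, False
    if match_by == "symbol" and symbol_map is not None:
        cands = symbol_map.index[symbol_map == symbol]
        cands = [c for c in cands if c in sam_table.index]
        if cands:
            sub = sam_table.loc[cands]
            best = sub["logfc"].abs().idxmax()
            return (float(sub.loc[best, "logfc"]), float(sub.loc[best, "p"]),
                    True, len(cands) > 1)
    return np.nan, np.nan, False, False


def score_reversal(
    classifiers: pd.DataFrame,
    sam_result: SamResult,
    alpha: float = 0.05,
    min_change: float = 0.0,
    contrast: str = "",
    match_by: str = "probe",
    symbol_map: pd.Series | None = None,
) -> ReversalSummary:
    """Score each classifier gene for treatment-induced reversal.

    ``classifiers`` is the frame from :func:`sigrev.pam.classifier_genes`
    (columns probe_id, symbol, direction, ...). Unmatched probes are listed
    separately, never silently dropped, and do not enter the counts.
    """
    table = sam_result.table
    records: list[ReversalRecord] = []
    unmatched: list[str] = []
    for _, row in classifiers.iterrows():
        probe, symbol = row["probe_id"], row["symbol"]
        direction = int(row["direction"])
        logfc, p, matched, ambiguous = _lookup(table, probe, symbol, match_by, symbol_map)
        if not matched:
            unmatched.append(probe)
            records.append(ReversalRecord(probe, symbol, direction, np.nan, np.nan,
                                          False, False, matched=False))
            continue
        rev = direction * np.sign(logfc) < 0 and abs(logfc) > min_change
        rev_sig = bool(rev and p < alpha)
        records.append(ReversalRecord(probe, symbol, direction, logfc, p,
                                      bool(rev), rev_sig, matched=True,
                                      ambiguous_match=ambiguous))
    matched_records = [r for r in records if r.matched]
    return ReversalSummary(
        contrast=contrast,
        n_classifiers=len(matched_records),
        n_reversed=sum(r.reversed for r in matched_records),
        n_reversed_significant=sum(r.reversed_significant for r in matched_records),
        records=records,
        unmatched=unmatched,
    )


def reversal_report(
    summaries: list[ReversalSummary],
    classifier_frames: dict[str, pd.DataFrame] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabular report across contrasts: record table plus a paired-bar table.

    The paired table (one row per gene: disease logFC next to treatment
    logFC) is figure-ready for the disease-vs-treatment comparison when the
    classifier frames carrying ``disease_logfc`` are supplied.
    """
    if not summaries:
        raise ValueError("need at least one summary")
    rec_frames = []
    for s in summaries:
        f = s.records_frame()
        f.insert(0, "contrast", s.contrast)
        rec_frames.append(f)
    records = pd.concat(rec_frames, ignore_index=True)

    paired_rows = []
    for s in summaries:
        disease_lfc = None
        if classifier_frames and s.contrast in classifier_frames:
            cf = classifier_frames[s.contrast]
            disease_lfc = cf.set_index("probe_id")["disease_logfc"]
        for r in s.records:
            paired_rows.append({
                "contrast": s.contrast,
                "probe_id": r.probe_id,
                "symbol": r.symbol,
                "disease_logfc": (float(disease_lfc[r.probe_id])
                                  if disease_lfc is not None and r.probe_id in disease_lfc.index
                                  else np.nan),
                "treatment_logfc": r.treatment_logfc,
                "reversed": r.reversed,
            })
    paired = pd.DataFrame(paired_rows, columns=["contrast", "probe_id", "symbol",
                                                "disease_logfc", "treatment_logfc", "reversed"])
    return records, paired
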