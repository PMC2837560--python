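"""End-to-end pipeline: QC -> normalize -> classify -> DE -> reversal -> qPCR.

The runner sequences the stages over plain-text inputs and writes every
stage artifact (TSV/CSV/JSON) into the output directory so any stage can be
re-run or audited in isolation. All randomness derives from the single
config seed through fixed per-stage offsets; the report is a pure function
of the stage outputs and carries no timestamp, so identical config gives a
byte-identical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as sio
from . import preprocess, sam, pam, reversal as rev
from .ddct import CtTable, replicate_qc, drn_outlier_filter, ddct_quantify, microarray_concordance
from .simulate import SimulationConfig, simulate_biopsy_matrix, simulate_treatment_matrix, simulate_ct_table, make_symbol_map

log = logging.getLogger("sigrev.pipeline")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Paths, contrasts and thresholds of one pipeline run."""

    biopsy_matrix: str
    biopsy_annotation: str
    treatment_matrix: str
    treatment_annotation: str
    outdir: str
    ct_table: str | None = None
    ct_groups: str | None = None
    reference_gene: str = "RNA18S"
    contrasts: list[list[str]] = field(
        default_factory=lambda: [["adenoma", "normal"], ["crc", "normal"]]
    )
    treatment_contrast: list[str] = field(default_factory=lambda: ["control", "treated"])
    alpha: float = 0.05
    logfc_hi: float = 1.0
    logfc_lo: float = -1.0
    min_change: float = 0.0
    present_min_fraction: float = 0.25
    background_threshold: float | None = None
    distance_max_ratio: float = 2.0
    exclude_failed_qc: bool = False
    delta_grid: str = "auto"
    k_folds: int = 10
    n_perm: str | int = "exhaustive"
    seed: int = 0

    def __post_init__(self):
        for name in ("alpha", "logfc_hi", "logfc_lo", "min_change",
                     "present_min_fraction", "distance_max_ratio"):
            v = getattr(self, name)
            if v is None or not pd.notna(v):
                raise PipelineError(f"threshold {name} must be finite")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunReport:
    stages: dict
    version: str
    config_hash: str
    seed: int

    def to_dict(self) -> dict:
        return {"stages": self.stages, "version": self.version,
                "config_hash": self.config_hash, "seed": self.seed}

    def to_json(self, path: str | Path) -> None:
        sio.write_json(self.to_dict(), path)


def _preflight(config: PipelineConfig) -> None:
    required = {
        "biopsy_matrix": config.biopsy_matrix,
        "biopsy_annotation": config.biopsy_annotation,
        "treatment_matrix": config.treatment_matrix,
        "treatment_annotation": config.treatment_annotation,
    }
    if config.ct_table is not None:
        required["ct_table"] = config.ct_table
        required["ct_groups"] = config.ct_groups
    missing = {k: v for k, v in required.items() if v is None or not Path(v).exists()}
    if missing:
        raise PipelineError(f"missing stage inputs before any computation: {missing}")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage in order, halting with the failing stage named."""
    _preflight(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict = {}

    stage = "load"
    try:
        biopsy = sio.read_matrix(config.biopsy_matrix)
        biopsy_ann = sio.read_annotation(config.biopsy_annotation)
        treat = sio.read_matrix(config.treatment_matrix)
        treat_ann = sio.read_annotation(config.treatment_annotation)
        sio.check_annotation(biopsy, biopsy_ann)
        sio.check_annotation(treat, treat_ann)

        stage = "qc"
        qc_reports = {}
        for name, (mat, ann) in {
            "biopsy": (biopsy, biopsy_ann), "treatment": (treat, treat_ann)
        }.items():
            report = preprocess.replicate_distance_check(
                mat, ann, max_ratio=config.distance_max_ratio,
                background_threshold=config.background_threshold,
            )
            qc_reports[name] = report
            sio.write_json(report.to_dict(), outdir / f"qc_{name}.json")
            log.info("qc[%s]: %d samples, %d failed", name, mat.shape[1],
                     len(report.failed_samples()))
        if config.exclude_failed_qc:
            for name, report in qc_reports.items():
                failed = report.failed_samples()
                if name == "biopsy":
                    biopsy = biopsy.drop(columns=failed)
                else:
                    treat = treat.drop(columns=failed)
        stages["qc"] = {
            name: {"n_samples": len(r.above_background),
                   "failed_samples": r.failed_samples(),
                   "unevaluable": r.unevaluable}
            for name, r in qc_reports.items()
        }

        stage = "normalize"
        biopsy_n = preprocess.quantile_normalize(biopsy)
        treat_n = preprocess.quantile_normalize(treat)
        sio.write_matrix(biopsy_n, outdir / "biopsy_normalized.tsv")
        sio.write_matrix(treat_n, outdir / "treatment_normalized.tsv")
        stages["normalize"] = {
            "biopsy_shape": list(biopsy_n.shape), "treatment_shape": list(treat_n.shape)
        }

        stage = "classify"
        classifier_frames: dict[str, pd.DataFrame] = {}
        models = {}
        stages["classify"] = {}
        for disease, normal in config.contrasts:
            contrast = f"{disease}_vs_{normal}"
            cols = [s for s in biopsy_n.columns if biopsy_ann[s] in (disease, normal)]
            cv = pam.cross_validate(
                biopsy_n[cols], biopsy_ann, delta_grid=config.delta_grid,
                k_folds=config.k_folds, seed=config.seed,
                positive_class=disease, normal_label=normal,
            )
            genes = pam.classifier_genes(cv.model, disease_class=disease, normal_label=normal)
            genes.to_csv(outdir / f"classifiers_{contrast}.csv", index=False)
            pd.DataFrame({"delta": cv.grid, "cv_errors": cv.cv_errors,
                          "survivors": cv.survivor_counts}).to_csv(
                outdir / f"cv_{contrast}.csv", index=False)
            classifier_frames[contrast] = genes
            models[contrast] = cv.model
            stages["classify"][contrast] = {
                "n_classifiers": int(len(genes)),
                "chosen_delta": cv.chosen_delta,
                "sensitivity_pct": cv.sensitivity,
                "specificity_pct": cv.specificity,
                "confusion": {str(k): {str(c): int(v) for c, v in row.items()}
                              for k, row in cv.confusion.iterrows()},
            }
            log.info("classify[%s]: %d genes, sens %.2f%%, spec %.2f%%",
                     contrast, len(genes), cv.sensitivity, cv.specificity)

        stage = "de"
        ctrl, trt = config.treatment_contrast
        de_res = sam.permutation_pvalues(
            treat_n, treat_ann, ctrl, trt, s0="auto",
            n_perm=config.n_perm, seed=config.seed,
        )
        selection = sam.select_de(de_res, alpha=config.alpha,
                                  logfc_hi=config.logfc_hi, logfc_lo=config.logfc_lo)
        de_res.table.to_csv(outdir / "de_treatment.csv")
        stages["de"] = {
            **selection.counts(),
            "s0": de_res.s0,
            "n_permutations": de_res.n_permutations,
            "exhaustive": bool(de_res.exhaustive),
        }
        log.info("de: %d significant, %d up two-fold, %d down two-fold",
                 *selection.counts().values())

        stage = "reversal"
        summaries = []
        stages["reversal"] = {}
        for contrast, genes in classifier_frames.items():
            summary = rev.score_reversal(
                genes, de_res, alpha=config.alpha,
                min_change=config.min_change, contrast=contrast,
            )
            summaries.append(summary)
            stages["reversal"][contrast] = summary.to_dict()
            log.info("reversal[%s]: %d/%d reversed, %d significant", contrast,
                     summary.n_reversed, summary.n_classifiers,
                     summary.n_reversed_significant)
        records, paired = rev.reversal_report(summaries, classifier_frames)
        records.to_csv(outdir / "reversal_records.csv", index=False)
        paired.to_csv(outdir / "reversal_paired.csv", index=False)

        stage = "ddct"
        if config.ct_table is None:
            stages["ddct"] = {"status": "skipped", "reason": "no CT table provided"}
        else:
            groups = sio.read_annotation(config.ct_groups)
            ct = CtTable.read_csv(config.ct_table, reference_gene=config.reference_gene,
                                  groups=groups)
            ct_kept, drn_excluded = drn_outlier_filter(ct)
            qc = replicate_qc(ct_kept)
            stages["ddct"] = {"status": "run", "contrasts": {}}
            for disease, normal in config.contrasts:
                if disease not in set(groups.values) or normal not in set(groups.values):
                    continue
                contrast = f"{disease}_vs_{normal}"
                result = ddct_quantify(qc, ct_kept, case_group=disease, control_group=normal)
                ct_genes = list(result.per_gene["gene"])
                present = [g for g in ct_genes if g in biopsy_n.index]
                micro_fc = pd.Series(dtype=float)
                if present:
                    case_cols = [s for s in biopsy_n.columns if biopsy_ann[s] == disease]
                    ctrl_cols = [s for s in biopsy_n.columns if biopsy_ann[s] == normal]
                    micro_fc = 2.0 ** (
                        biopsy_n.loc[present, case_cols].mean(axis=1)
                        - biopsy_n.loc[present, ctrl_cols].mean(axis=1)
                    )
                table, counts = microarray_concordance(result, micro_fc)
                result.per_gene.to_csv(outdir / f"ddct_{contrast}.csv", index=False)
                table.to_csv(outdir / f"concordance_{contrast}.csv", index=False)
                stages["ddct"]["contrasts"][contrast] = {
                    "n_genes": int(len(result.per_gene)),
                    "n_replicate_exclusions": int(len(qc.exclusions)),
                    "n_drn_exclusions": int(len(drn_excluded)),
                    **counts,
                }
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    report = RunReport(stages=stages, version=__version__,
                       config_hash=config.config_hash(), seed=config.seed)
    report.to_json(outdir / "report.json")
    _write_markdown_report(report, outdir / "report.md")
    return report


def _write_markdown_report(report: RunReport, path: Path) -> None:
    lines = [f"# sigrev run report", "",
             f"- version: {report.version}",
             f"- config hash: {report.config_hash}",
             f"- seed: {report.seed}", ""]
    for stage, info in report.stages.items():
        lines.append(f"## {stage}")
        lines.append("```json")
        lines.append(json.dumps(info, indent=2, sort_keys=True, default=str))
        lines.append("```")
        lines.append("")
    path.write_text("\n".join(lines))


def write_dataset(config: SimulationConfig, outdir: str | Path,
                  n_ct_genes: int = 12) -> dict[str, Path]:
    """Simulate the full two-arm dataset and write every input file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    biopsy, biopsy_ann, truth = simulate_biopsy_matrix(config)
    treat, treat_ann = simulate_treatment_matrix(config, truth)
    ct_genes: list[str] = []
    for g in config.disease_groups:
        sig = list(truth.signature[g])
        ct_genes.extend(sig[: max(1, n_ct_genes // max(1, len(config.disease_groups)))])
    ct_genes = list(dict.fromkeys(ct_genes))[:n_ct_genes]
    ct = simulate_ct_table(truth, ct_genes, config)
    symbols = make_symbol_map(biopsy.index, seed=config.seed)

    paths = {
        "biopsy_matrix": outdir / "biopsy_matrix.tsv",
        "biopsy_annotation": outdir / "biopsy_annotation.tsv",
        "treatment_matrix": outdir / "treatment_matrix.tsv",
        "treatment_annotation": outdir / "treatment_annotation.tsv",
        "ct_table": outdir / "ct_table.csv",
        "ct_groups": outdir / "ct_groups.tsv",
        "ground_truth": outdir / "ground_truth.json",
        "symbol_map": outdir / "symbol_map.tsv",
        "sim_config": outdir / "sim_config.yaml",
    }
    sio.write_matrix(biopsy, paths["biopsy_matrix"])
    sio.write_annotation(biopsy_ann, paths["biopsy_annotation"])
    sio.write_matrix(treat, paths["treatment_matrix"])
    sio.write_annotation(treat_ann, paths["treatment_annotation"])
    ct.write_csv(paths["ct_table"])
    sio.write_annotation(ct.groups, paths["ct_groups"])
    truth.to_json(paths["ground_truth"])
    symbols.rename("symbol").rename_axis("probe_id").to_csv(paths["symbol_map"], sep="\t")
    paths["sim_config"].write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return paths


def pipeline_config_for_dataset(paths: dict[str, Path], outdir: str | Path,
                                sim_config: SimulationConfig, **overrides) -> PipelineConfig:
    contrasts = [[g, sim_config.normal_group] for g in sim_config.disease_groups]
    defaults = dict(
        biopsy_matrix=str(paths["biopsy_matrix"]),
        biopsy_annotation=str(paths["biopsy_annotation"]),
        treatment_matrix=str(paths["treatment_matrix"]),
        treatment_annotation=str(paths["treatment_annotation"]),
        ct_table=str(paths["ct_table"]),
        ct_groups=str(paths["ct_groups"]),
        reference_gene=sim_config.reference_gene,
        contrasts=contrasts,
        treatment_contrast=[sim_config.control_group, sim_config.treated_group],
        outdir=str(outdir),
        seed=sim_config.seed,
    )
    defaults.update(overrides)
    return PipelineConfig(**defaults)


def run_synthetic(sim_config: SimulationConfig, workdir: str | Path,
                  **overrides) -> RunReport:
    """Simulate a dataset and run the full pipeline on it."""
    workdir = Path(workdir)
    paths = write_dataset(sim_config, workdir / "data")
    config = pipeline_config_for_dataset(paths, workdir / "out", sim_config, **overrides)
    return run_pipeline(config)


def make_fixtures(outdir: str | Path, seed: int = 0) -> dict[str, dict[str, Path]]:
    """Emit the default synthetic dataset plus a miniature instance.

    The default dataset mirrors the emulated study design (53 biopsy and 6
    cell-line profiles); the miniature 30-probe instance exists so the full
    pipeline can be exercised in seconds.
    """
    outdir = Path(outdir)
    default_cfg = SimulationConfig(seed=seed)
    mini_cfg = SimulationConfig(
        n_probes=30,
        group_sizes={"normal": 4, "adenoma": 4},
        n_signature=5, n_reversed=3, noise_sd=0.3, seed=seed,
    )
    return {
        "default": write_dataset(default_cfg, outdir / "default"),
        "mini": write_dataset(mini_cfg, outdir / "mini", n_ct_genes=3),
    }
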