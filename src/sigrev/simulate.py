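"""Seeded synthetic data emulating a two-arm colorectal expression study.

The generator produces log2 expression matrices with the structure the
downstream analysis assumes: a biopsy arm (11 normal / 20 adenoma / 22
carcinoma profiles by default) carrying a planted classifier signature per
disease group, a cell-line treatment arm (3 treated / 3 control) in which a
configurable subset of the signature probes is shifted in the direction
opposite to the disease change, and matched triplicate qPCR threshold-cycle
tables with a high-abundance 18S-style reference gene.

Noise is i.i.d. Gaussian on the log2 scale. Background differential
expression in the treatment arm is a sparse two-sided shift on non-signature
probes so that reversal counting is exercised against a large unrelated DE
background. All randomness flows from ``SimulationConfig.seed``; identical
config gives bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .ddct import CtTable


class ConfigurationError(ValueError):
    """An invalid simulation configuration; the message names the field."""


def _default_group_sizes() -> dict[str, int]:
    return {"normal": 11, "adenoma": 20, "crc": 22}


def _default_cellline_sizes() -> dict[str, int]:
    return {"control": 3, "treated": 3}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    ``effect_size`` is the log2 shift planted on signature probes in their
    disease group; ``n_reversed`` of each contrast's signature probes receive
    a treatment shift of the opposite sign in the treated cell-line group,
    the rest a same-sign shift (``nonreversed_mode="same"``) or none
    (``"none"``).
    """

    n_probes: int = 2000
    group_sizes: Mapping[str, int] = field(default_factory=_default_group_sizes)
    cellline_sizes: Mapping[str, int] = field(default_factory=_default_cellline_sizes)
    normal_group: str = "normal"
    control_group: str = "control"
    treated_group: str = "treated"
    n_signature: int = 20
    effect_size: float = 2.0
    n_reversed: int = 17
    nonreversed_mode: str = "same"
    treatment_effect_size: float | None = None
    background_de_fraction: float = 0.10
    background_effect_size: float = 2.0
    noise_sd: float = 0.5
    baseline_mean_range: tuple[float, float] = (4.0, 12.0)
    ct_replicate_sd: float = 0.1
    reference_gene: str = "RNA18S"
    reference_ct: float = 12.0
    seed: int = 0

    def __post_init__(self):
        if self.n_probes <= 0:
            raise ConfigurationError("n_probes must be positive")
        if self.n_signature < 0 or self.n_signature > self.n_probes:
            raise ConfigurationError("n_signature must satisfy 0 <= n_signature <= n_probes")
        if self.n_reversed < 0 or self.n_reversed > self.n_signature:
            raise ConfigurationError("n_reversed must satisfy 0 <= n_reversed <= n_signature")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.ct_replicate_sd < 0:
            raise ConfigurationError("ct_replicate_sd must be non-negative")
        if not 0 <= self.background_de_fraction <= 1:
            raise ConfigurationError("background_de_fraction must be in [0, 1]")
        lo, hi = self.baseline_mean_range
        if not lo <= hi:
            raise ConfigurationError("baseline_mean_range must be (low, high) with low <= high")
        if self.nonreversed_mode not in ("same", "none"):
            raise ConfigurationError("nonreversed_mode must be 'same' or 'none'")
        if self.normal_group not in dict(self.group_sizes):
            raise ConfigurationError("normal_group must appear in group_sizes")
        for name, sizes in (("group_sizes", self.group_sizes), ("cellline_sizes", self.cellline_sizes)):
            for g, n in dict(sizes).items():
                if n < 2:
                    raise ConfigurationError(f"{name}[{g!r}] must be >= 2")
        n_contrasts = sum(1 for g in dict(self.group_sizes) if g != self.normal_group)
        if n_contrasts * self.n_signature > self.n_probes:
            raise ConfigurationError(
                "n_signature too large: disjoint signatures for all disease "
                "groups exceed n_probes"
            )
        if not self.reference_gene:
            raise ConfigurationError("reference_gene must be a non-empty name")

    @property
    def disease_groups(self) -> list[str]:
        return [g for g in dict(self.group_sizes) if g != self.normal_group]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["group_sizes"] = dict(self.group_sizes)
        d["cellline_sizes"] = dict(self.cellline_sizes)
        d["baseline_mean_range"] = list(self.baseline_mean_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "baseline_mean_range" in d:
            d["baseline_mean_range"] = tuple(d["baseline_mean_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """What was planted: recovery target for the downstream stages.

    ``signature`` maps each disease group to ``{probe_id: +1/-1}`` (sign of
    the planted disease-vs-normal shift); ``reversed_probes`` lists, per
    disease group, the signature probes whose treatment shift has the
    opposite sign.
    """

    baseline_means: pd.Series
    signature: dict[str, dict[str, int]]
    reversed_probes: dict[str, list[str]]

    def __post_init__(self):
        for group, rev in self.reversed_probes.items():
            sig = self.signature.get(group, {})
            bad = [p for p in rev if p not in sig]
            if bad:
                raise ValueError(f"reversed probes not in signature for {group}: {bad}")
        for group, sig in self.signature.items():
            if any(s == 0 for s in sig.values()):
                raise ValueError(f"zero disease-shift sign in signature for {group}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.baseline_means.index

    def all_signature_probes(self) -> set[str]:
        out: set[str] = set()
        for sig in self.signature.values():
            out |= set(sig)
        return out

    def to_json(self, path: str | Path) -> None:
        obj = {
            "baseline_means": {p: float(v) for p, v in self.baseline_means.items()},
            "signature": self.signature,
            "reversed_probes": self.reversed_probes,
        }
        Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        obj = json.loads(Path(path).read_text())
        return cls(
            baseline_means=pd.Series(obj["baseline_means"]).sort_index(),
            signature={g: {p: int(s) for p, s in sig.items()} for g, sig in obj["signature"].items()},
            reversed_probes={g: list(v) for g, v in obj["reversed_probes"].items()},
        )


def _probe_ids(n: int) -> pd.Index:
    return pd.Index([f"P{i:05d}" for i in range(n)], name="probe_id")


def _sample_ids(sizes: Mapping[str, int]) -> tuple[list[str], pd.Series]:
    samples, groups = [], []
    for g, n in dict(sizes).items():
        for j in range(n):
            samples.append(f"{g}_{j + 1:02d}")
            groups.append(g)
    ann = pd.Series(groups, index=pd.Index(samples, name="sample_id"), name="group")
    return samples, ann


def simulate_biopsy_matrix(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Simulate the biopsy arm and its ground truth.

    Returns ``(matrix, annotation, truth)`` where the matrix holds log2
    intensities (probes x samples). Each disease group receives a disjoint
    set of ``n_signature`` probes shifted by ``+/- effect_size`` relative to
    the shared per-probe baseline; all other probes share their mean across
    groups. ``n_reversed`` probes per contrast are pre-designated here so the
    truth is complete before the treatment arm is drawn.
    """
    rng = np.random.default_rng([config.seed, 0])
    probes = _probe_ids(config.n_probes)
    lo, hi = config.baseline_mean_range
    baseline = pd.Series(rng.uniform(lo, hi, config.n_probes), index=probes, name="baseline")

    perm = rng.permutation(config.n_probes)
    signature: dict[str, dict[str, int]] = {}
    reversed_probes: dict[str, list[str]] = {}
    pos = 0
    for g in config.disease_groups:
        idx = perm[pos:pos + config.n_signature]
        pos += config.n_signature
        signs = rng.choice([-1, 1], size=config.n_signature)
        sig_probes = [probes[i] for i in idx]
        signature[g] = {p: int(s) for p, s in zip(sig_probes, signs)}
        rev = rng.choice(len(sig_probes), size=config.n_reversed, replace=False)
        reversed_probes[g] = [sig_probes[i] for i in sorted(rev)]

    samples, ann = _sample_ids(config.group_sizes)
    shift = np.zeros((config.n_probes, len(samples)))
    col_of = {s: j for j, s in enumerate(samples)}
    probe_pos = {p: i for i, p in enumerate(probes)}
    for g, sig in signature.items():
        cols = [col_of[s] for s in ann.index[ann == g]]
        for p, s in sig.items():
            shift[probe_pos[p], cols] = s * config.effect_size

    values = baseline.to_numpy()[:, None] + shift
    values = values + rng.normal(0.0, config.noise_sd, size=values.shape) if config.noise_sd > 0 else values
    matrix = pd.DataFrame(values, index=probes, columns=samples)
    truth = GroundTruth(baseline_means=baseline, signature=signature, reversed_probes=reversed_probes)
    return matrix, ann, truth


def simulate_treatment_matrix(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate the cell-line treatment arm against an existing truth.

    In the treated group, each contrast's designated reversed probes are
    shifted opposite to their disease sign; the remaining signature probes
    follow ``nonreversed_mode``. A ``background_de_fraction`` of the
    non-signature probes receives an independent two-sided shift, emulating
    broad drug-induced differential expression unrelated to the signature.
    """
    if len(truth.probe_ids) != config.n_probes:
        raise ValueError(
            f"truth has {len(truth.probe_ids)} probes but config.n_probes={config.n_probes}"
        )
    rng = np.random.default_rng([config.seed, 1])
    te = config.treatment_effect_size if config.treatment_effect_size is not None else config.effect_size

    probes = truth.probe_ids
    probe_pos = {p: i for i, p in enumerate(probes)}
    treated_shift = np.zeros(config.n_probes)
    for g, sig in truth.signature.items():
        rev = set(truth.reversed_probes.get(g, []))
        for p, s in sig.items():
            if p in rev:
                treated_shift[probe_pos[p]] = -s * te
            elif config.nonreversed_mode == "same":
                treated_shift[probe_pos[p]] = s * te

    nonsig = [probe_pos[p] for p in probes if p not in truth.all_signature_probes()]
    n_bg = int(round(config.background_de_fraction * len(nonsig)))
    if n_bg:
        bg = rng.choice(nonsig, size=n_bg, replace=False)
        treated_shift[bg] = rng.choice([-1.0, 1.0], size=n_bg) * config.background_effect_size

    samples, ann = _sample_ids(config.cellline_sizes)
    shift = np.zeros((config.n_probes, len(samples)))
    treated_cols = [j for j, s in enumerate(samples) if ann.iloc[j] == config.treated_group]
    shift[:, treated_cols] = treated_shift[:, None]

    values = truth.baseline_means.to_numpy()[:, None] + shift
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    matrix = pd.DataFrame(values, index=probes, columns=samples)
    return matrix, ann


def simulate_ct_table(
    truth: GroundTruth,
    genes: list[str],
    config: SimulationConfig,
    fold_changes: Mapping[str, float] | None = None,
) -> CtTable:
    """Simulate a triplicate qPCR threshold-cycle table over the biopsy groups.

    The target CT of a gene encodes minus its planted log2 shift on top of a
    gene-specific base cycle, so the ddCT pipeline recovers the planted fold
    change in expectation (exactly at ``ct_replicate_sd=0``). The reference
    gene amplifies at ``reference_ct`` independently of group, mimicking a
    high-abundance ribosomal control. ``fold_changes`` overrides the planted
    shift with an explicit disease-vs-normal fold change per gene (applied to
    every non-normal group).
    """
    unknown = [g for g in genes if g not in set(truth.probe_ids)]
    if unknown:
        raise ConfigurationError(f"genes not in the simulated probe set: {unknown}")
    rng = np.random.default_rng([config.seed, 2])
    samples, ann = _sample_ids(config.group_sizes)
    ct_base = {g: rng.uniform(20.0, 30.0) for g in genes}

    rows = []
    for sample in samples:
        group = ann[sample]
        for gene in list(genes) + [config.reference_gene]:
            if gene == config.reference_gene:
                ct_true = config.reference_ct
            else:
                if fold_changes is not None and gene in fold_changes:
                    lfc = float(np.log2(fold_changes[gene])) if group != config.normal_group else 0.0
                else:
                    sign = truth.signature.get(group, {}).get(gene, 0)
                    lfc = sign * config.effect_size
                ct_true = ct_base[gene] - lfc
            noise = rng.normal(0.0, config.ct_replicate_sd, size=3) if config.ct_replicate_sd > 0 else np.zeros(3)
            for rep in range(1, 4):
                rows.append(
                    {
                        "sample_id": sample,
                        "gene": gene,
                        "replicate": rep,
                        "ct": ct_true + noise[rep - 1],
                        "delta_rn": 1.0,
                    }
                )
    data = pd.DataFrame(rows)
    return CtTable(data=data, reference_gene=config.reference_gene, groups=ann)


def make_symbol_map(
    probe_ids: pd.Index | list[str], seed: int = 0, duplicate_fraction: float = 0.05
) -> pd.Series:
    """Synthetic probe-to-symbol map with deliberate many-to-one entries.

    A ``duplicate_fraction`` of probes is remapped onto another probe's
    symbol, emulating platforms where several probe sets interrogate one gene
    (so duplicate-symbol handling downstream is exercised).
    """
    probes = list(probe_ids)
    rng = np.random.default_rng([seed, 3])
    symbols = {p: f"G{i:05d}" for i, p in enumerate(probes)}
    n_dup = int(round(duplicate_fraction * len(probes)))
    if n_dup and len(probes) >= 2:
        dups = rng.choice(len(probes), size=min(2 * n_dup, len(probes)), replace=False)
        for a, b in zip(dups[:n_dup], dups[n_dup:2 * n_dup]):
            symbols[probes[a]] = symbols[probes[b]]
    return pd.Series(symbols, name="symbol").reindex(probes)
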