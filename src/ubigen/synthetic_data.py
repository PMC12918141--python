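"""Synthetic expression matrices and drug-statistics tables with planted truth.

The generator plants four gene classes whose contrast is exactly what the
ubiquity score is built to detect:

* **ubiquitous** — detected in every sample, high log-normal level, small
  log-scale spread;
* **specific** — expressed in only a small fraction of samples (10% by
  default), moderate level;
* **variable** — detected broadly but with a large log-scale spread;
* **silent** — near-zero level with heavy dropout.

Values are log-normal where detected and exactly zero elsewhere; every
operation is a pure function of an explicit integer seed, so fixtures are
reproducible across platforms without any stored data files.

The paired-dataset generator emulates the contrast between a physiological
and a perturbed dataset: dataset B reuses A's generative parameters but
knocks down a random fraction of the planted ubiquitous genes (reduced
detection probability and level), the mechanism that moves a gene from
sector 11 into sector 10 of a two-dataset comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from ubigen.formats_io import DrugStatsTable, ExpressionMatrix, ValidationError

__all__ = [
    "SyntheticSpec",
    "TruthLabels",
    "PairedDatasets",
    "simulate_expression",
    "simulate_drug_stats",
    "simulate_paired_datasets",
]

CLASSES = ("ubiquitous", "specific", "variable", "silent")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters for one synthetic expression matrix.

    Level parameters are natural-log mean/sd of the log-normal expression
    model; detection probabilities give the chance a gene is observed
    (non-zero) in a sample.
    """

    n_samples: int = 100
    n_ubiquitous: int = 200
    n_specific: int = 600
    n_variable: int = 150
    n_silent: int = 50
    seed: int = 1
    # ubiquitous: always detected, high and stable
    ubiq_log_mean: float = 6.0
    ubiq_log_sd: float = 0.2
    ubiq_detection: float = 1.0
    # specific: expressed in a small fraction of samples
    specific_sample_fraction: float = 0.1
    specific_log_mean: float = 4.0
    specific_log_sd: float = 0.5
    # variable: broad detection at a substantial level, large spread
    variable_detection: float = 0.95
    variable_log_mean: float = 5.5
    variable_log_sd: float = 1.0
    # silent: near-zero with dropout
    silent_detection: float = 0.05
    silent_log_mean: float = -1.0
    silent_log_sd: float = 0.5

    def __post_init__(self) -> None:
        counts = (self.n_ubiquitous, self.n_specific, self.n_variable, self.n_silent)
        if any(c < 0 for c in counts) or self.n_samples < 2:
            raise ValidationError("class counts must be >= 0 and n_samples >= 2")
        if sum(counts) == 0:
            raise ValidationError("at least one gene class must be non-empty")

    @property
    def n_genes(self) -> int:
        return self.n_ubiquitous + self.n_specific + self.n_variable + self.n_silent


@dataclass(frozen=True)
class TruthLabels:
    """Gene ID -> planted class label; covers every generated gene."""

    labels: dict[str, str]

    def genes_of(self, cls: str) -> set[str]:
        return {g for g, c in self.labels.items() if c == cls}

    def __getitem__(self, gene_id: str) -> str:
        return self.labels[gene_id]

    def __len__(self) -> int:
        return len(self.labels)


class PairedDatasets(NamedTuple):
    a: ExpressionMatrix
    b: ExpressionMatrix
    labels: TruthLabels
    knocked_down: frozenset[str]


def _gene_ids(spec: SyntheticSpec) -> tuple[list[str], dict[str, str]]:
    ids: list[str] = []
    labels: dict[str, str] = {}
    counts = {
        "ubiquitous": spec.n_ubiquitous,
        "specific": spec.n_specific,
        "variable": spec.n_variable,
        "silent": spec.n_silent,
    }
    i = 0
    for cls in CLASSES:
        for _ in range(counts[cls]):
            gid = f"gene_{i:05d}"
            ids.append(gid)
            labels[gid] = cls
            i += 1
    return ids, labels


def _class_block(
    rng: np.random.Generator,
    n_genes: int,
    n_samples: int,
    detection: float,
    log_mean: float | np.ndarray,
    log_sd: float | np.ndarray,
) -> np.ndarray:
    if n_genes == 0:
        return np.zeros((0, n_samples))
    detected = rng.random((n_genes, n_samples)) < np.broadcast_to(
        np.asarray(detection, dtype=float).reshape(-1, 1), (n_genes, n_samples)
    )
    mu = np.broadcast_to(np.asarray(log_mean, dtype=float).reshape(-1, 1), (n_genes, n_samples))
    sd = np.broadcast_to(np.asarray(log_sd, dtype=float).reshape(-1, 1), (n_genes, n_samples))
    values = rng.lognormal(mean=mu, sigma=sd)
    return np.where(detected, values, 0.0)


def _specific_block(rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    n, s = spec.n_specific, spec.n_samples
    if n == 0:
        return np.zeros((0, s))
    k = max(1, round(spec.specific_sample_fraction * s))
    mask = np.zeros((n, s), dtype=bool)
    for i in range(n):
        mask[i, rng.choice(s, size=k, replace=False)] = True
    values = rng.lognormal(mean=spec.specific_log_mean, sigma=spec.specific_log_sd, size=(n, s))
    return np.where(mask, values, 0.0)


def simulate_expression(
    spec: SyntheticSpec,
    knocked_down: frozenset[str] | set[str] = frozenset(),
    seed: int | None = None,
) -> tuple[ExpressionMatrix, TruthLabels]:
    """Generate one expression matrix plus its planted class labels.

    ``knocked_down`` names planted ubiquitous genes to generate with
    strongly reduced detection probability and level (used by the paired
    generator).  ``seed`` overrides ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    ids, labels = _gene_ids(spec)
    kd = set(knocked_down)
    unknown_kd = kd - {g for g, c in labels.items() if c == "ubiquitous"}
    if unknown_kd:
        raise ValidationError("knocked_down must name planted ubiquitous genes")

    ubiq_ids = [g for g in ids if labels[g] == "ubiquitous"]
    kd_mask = np.array([g in kd for g in ubiq_ids])
    ubiq_det = np.where(kd_mask, 0.15, spec.ubiq_detection)
    ubiq_mu = np.where(kd_mask, spec.ubiq_log_mean - 2.5, spec.ubiq_log_mean)
    ubiq_sd = np.where(kd_mask, 1.0, spec.ubiq_log_sd)

    blocks = [
        _class_block(rng, spec.n_ubiquitous, spec.n_samples, ubiq_det, ubiq_mu, ubiq_sd),
        _specific_block(rng, spec),
        _class_block(
            rng, spec.n_variable, spec.n_samples,
            spec.variable_detection, spec.variable_log_mean, spec.variable_log_sd,
        ),
        _class_block(
            rng, spec.n_silent, spec.n_samples,
            spec.silent_detection, spec.silent_log_mean, spec.silent_log_sd,
        ),
    ]
    values = np.vstack(blocks)
    df = pd.DataFrame(
        values,
        index=pd.Index(ids, name="gene_id"),
        columns=[f"sample_{j:04d}" for j in range(spec.n_samples)],
    )
    matrix = ExpressionMatrix(df, meta={"source": "synthetic", "seed": spec.seed})
    return matrix, TruthLabels(labels)


def simulate_drug_stats(
    labels: TruthLabels,
    n_broad_drugs: int = 10,
    n_specific_drugs: int = 30,
    seed: int = 1,
    broad_hit_prob_ubiq: float = 0.6,
    broad_hit_prob_other: float = 0.3,
    specific_n_targets: int = 20,
    lfc_shape: float = 2.0,
    lfc_scale: float = 1.0,
) -> DrugStatsTable:
    """Per-(gene, drug) t-test summaries with planted broad/specific drugs.

    Broad drugs hit genes of every class but ubiquitous genes with elevated
    probability, so their non-ubiquitous:ubiquitous bias ratio is below 1;
    specific drugs hit a small random subset of non-ubiquitous genes only.
    Affected pairs get p <= 0.05 and |logFC| drawn from a gamma
    distribution; unaffected pairs get p uniform on (0.05, 1] and a small
    noise logFC.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(labels.labels)
    is_ubiq = np.array([labels[g] == "ubiquitous" for g in genes])
    non_ubiq_idx = np.flatnonzero(~is_ubiq)
    rows: list[tuple] = []

    def add_drug(drug_id: str, moa: str, affected: np.ndarray) -> None:
        n = len(genes)
        p = 1.0 - rng.random(n) * 0.95  # uniform on (0.05, 1]
        lfc = rng.normal(0.0, 0.1, size=n)
        p[affected] = rng.random(affected.sum()) * 0.05
        magnitude = rng.gamma(lfc_shape, lfc_scale, size=int(affected.sum()))
        sign = rng.choice([-1.0, 1.0], size=int(affected.sum()))
        lfc[affected] = magnitude * sign
        for g, pv, fc in zip(genes, p, lfc):
            rows.append((g, drug_id, "10uM", moa, pv, fc))

    for d in range(n_broad_drugs):
        probs = np.where(is_ubiq, broad_hit_prob_ubiq, broad_hit_prob_other)
        affected = rng.random(len(genes)) < probs
        add_drug(f"broad_{d:03d}", "broad-acting", affected)
    for d in range(n_specific_drugs):
        affected = np.zeros(len(genes), dtype=bool)
        if len(non_ubiq_idx):
            k = min(specific_n_targets, len(non_ubiq_idx))
            affected[rng.choice(non_ubiq_idx, size=k, replace=False)] = True
        add_drug(f"specific_{d:03d}", "narrow-acting", affected)

    df = pd.DataFrame(
        rows, columns=["gene_id", "drug_id", "concentration", "moa", "p_value", "log_fc"]
    )
    return DrugStatsTable(df)


def simulate_paired_datasets(
    spec: SyntheticSpec,
    perturb_fraction: float = 0.3,
    seed: int | None = None,
) -> PairedDatasets:
    """Two matrices sharing one gene universe, the second with knockdowns.

    Dataset A follows ``spec``; dataset B re-draws from the same generative
    parameters except that a random ``perturb_fraction`` of the planted
    ubiquitous genes is knocked down (detection 0.15, level reduced ~12x),
    emulating genes that lose ubiquity under perturbation.
    """
    if not (0 <= perturb_fraction <= 1):
        raise ValidationError("perturb_fraction must be in [0, 1]")
    base_seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    a, labels = simulate_expression(spec, seed=base_seed)
    ubiq = sorted(labels.genes_of("ubiquitous"))
    n_kd = round(perturb_fraction * len(ubiq))
    knocked = frozenset(
        np.array(ubiq, dtype=object)[rng.choice(len(ubiq), size=n_kd, replace=False)]
    ) if n_kd else frozenset()
    b, _ = simulate_expression(spec, knocked_down=knocked, seed=base_seed + 1_000_003)
    return PairedDatasets(a=a, b=b, labels=labels, knocked_down=knocked)
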