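"""Synthetic multi-cohort cohorts with planted cell-pair prognostic signal.

The generator emulates the statistical structure the pipeline assumes:
28 latent per-sample infiltration abundances drive metagene expression;
survival hazard is log-linear in a small set of planted pair-order
indicators; cohorts carry additive (optionally monotone nonlinear)
batch distortions; TNM stage is a noisy ordinal cut of latent risk; a
binary response label is linked to latent risk through a logistic model.

Defaults are the package's reference study conditions: 600 samples, 28
metagene sets of 30 genes plus 360 background genes, two cohorts, and
five planted pairs over ten distinct cell types with log-hazard weights
of magnitude 0.9-1.0 (mixed sign), yielding roughly 60-70% events under
a 0.02/month baseline hazard and a 120-month uniform censoring horizon.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import (GeneSetCollection, read_clinical, read_expression, read_gmt,
                 write_clinical, write_expression, write_gmt)
from .pairs import pair_id

__all__ = [
    "CELL_TYPES",
    "DEFAULT_PLANTED_PAIRS",
    "SimulationConfig",
    "GroundTruth",
    "CohortBundle",
    "generate_cohort",
    "monotone_distort",
    "write_fixture",
    "read_fixture",
]

#: the 28 immune-cell subpopulations scored by the infiltration step
CELL_TYPES: tuple[str, ...] = (
    "Activated B cell", "Activated CD4 T cell", "Activated CD8 T cell",
    "Activated dendritic cell", "CD56bright natural killer cell",
    "CD56dim natural killer cell", "Central memory CD4 T cell",
    "Central memory CD8 T cell", "Effector memory CD4 T cell",
    "Effector memory CD8 T cell", "Eosinophil", "Gamma delta T cell",
    "Immature B cell", "Immature dendritic cell", "Macrophage", "Mast cell",
    "MDSC", "Memory B cell", "Monocyte", "Natural killer cell",
    "Natural killer T cell", "Neutrophil", "Plasmacytoid dendritic cell",
    "Regulatory T cell", "T follicular helper cell", "Type 1 T helper cell",
    "Type 17 T helper cell", "Type 2 T helper cell",
)

#: five planted pairs over ten distinct cell types, mixed-sign weights
DEFAULT_PLANTED_PAIRS: tuple[tuple[str, str, float], ...] = (
    ("Macrophage", "Activated CD8 T cell", 1.0),
    ("Monocyte", "Eosinophil", 1.0),
    ("Mast cell", "Effector memory CD8 T cell", 0.9),
    ("MDSC", "Type 17 T helper cell", -1.0),
    ("Regulatory T cell", "Natural killer cell", -0.9),
)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic multi-cohort dataset."""

    n_samples: int = 600
    n_background_genes: int = 360
    genes_per_set: int = 30
    n_cohorts: int = 2
    planted_pairs: tuple[tuple[str, str, float], ...] = DEFAULT_PLANTED_PAIRS
    infiltration_spread: float = 1.0
    signal_gain: float = 2.0
    noise_sd: float = 1.0
    baseline_hazard: float = 0.02       # events per month
    censoring_horizon: float = 120.0    # months
    stage_noise_sd: float = 0.5
    response_logit_slope: float = 1.0
    batch_sd: float = 0.5               # scale of additive per-cohort gene offsets
    expr_baseline_sd: float = 1.0       # spread of per-gene baseline means
    cell_types: tuple[str, ...] = CELL_TYPES
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_samples", "n_background_genes", "genes_per_set",
                     "n_cohorts"):
            if getattr(self, name) < 1 and name != "n_background_genes":
                raise ValueError(f"{name} must be positive")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be nonnegative")
        for name in ("infiltration_spread", "noise_sd", "baseline_hazard",
                     "censoring_horizon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("signal_gain", "stage_noise_sd", "batch_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        known = set(self.cell_types)
        for a, b, beta in self.planted_pairs:
            if a not in known or b not in known:
                raise ValueError(f"planted pair ({a!r}, {b!r}) names unknown cell type")
            if a == b:
                raise ValueError(f"planted pair compares {a!r} with itself")
            if not np.isfinite(beta):
                raise ValueError("planted pair weight must be finite")


@dataclass
class GroundTruth:
    """Latent state behind one synthetic cohort."""

    latent_abundance: pd.DataFrame      # cells x samples
    latent_risk: pd.Series              # per-sample log-hazard offset
    planted_pairs: tuple[tuple[str, str, float], ...]
    true_group: pd.Series               # high/low by median latent risk
    cell_types: tuple[str, ...] = CELL_TYPES

    def canonical_pair_ids(self) -> list[str]:
        """Planted pairs in the canonical (cell-type-order) direction."""
        order = {c: i for i, c in enumerate(self.cell_types)}
        ids = []
        for a, b, _ in self.planted_pairs:
            ids.append(pair_id(a, b) if order[a] < order[b] else pair_id(b, a))
        return ids


@dataclass
class CohortBundle:
    expression: pd.DataFrame
    clinical: pd.DataFrame
    gene_sets: GeneSetCollection
    truth: GroundTruth


def _slug(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "_", name).strip("_")


def generate_cohort(config: SimulationConfig) -> CohortBundle:
    """Generate one multi-cohort dataset; bit-identical for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    cells = list(config.cell_types)
    n, n_cells = config.n_samples, len(cells)
    samples = [f"S{i:04d}" for i in range(n)]

    # latent infiltration abundances, independent log-normal
    abundance = rng.lognormal(mean=0.0, sigma=config.infiltration_spread,
                              size=(n_cells, n))
    abund = pd.DataFrame(abundance, index=cells, columns=samples)

    # planted-pair risk
    risk = np.zeros(n)
    for a, b, beta in config.planted_pairs:
        risk += beta * (abund.loc[a].to_numpy() > abund.loc[b].to_numpy())
    latent_risk = pd.Series(risk, index=samples, name="latent_risk")

    # exponential survival with uniform censoring
    rate = config.baseline_hazard * np.exp(risk)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.uniform(0.0, config.censoring_horizon, size=n)
    time = np.maximum(np.minimum(t_event, t_cens), 1e-3)
    event = (t_event <= t_cens).astype(int)

    # metagene sets and expression
    sets: dict[str, list[str]] = {}
    gene_rows, gene_ids = [], []
    for ci, cell in enumerate(cells):
        genes = [f"{_slug(cell)}_g{j:03d}" for j in range(config.genes_per_set)]
        sets[cell] = genes
        mu = rng.normal(5.0, config.expr_baseline_sd, size=config.genes_per_set)
        block = (mu[:, None] + config.signal_gain * abundance[ci][None, :])
        gene_rows.append(block)
        gene_ids.extend(genes)
    for j in range(config.n_background_genes):
        gene_ids.append(f"BG_g{j:04d}")
    mu_bg = rng.normal(5.0, config.expr_baseline_sd,
                       size=config.n_background_genes)
    gene_rows.append(np.repeat(mu_bg[:, None], n, axis=1))
    expr = np.vstack(gene_rows) if gene_rows else np.empty((0, n))

    cohort = rng.integers(0, config.n_cohorts, size=n)
    batch = rng.normal(0.0, config.batch_sd, size=(expr.shape[0], config.n_cohorts))
    expr = expr + batch[:, cohort]
    expr = expr + rng.normal(0.0, config.noise_sd, size=expr.shape)
    expression = pd.DataFrame(expr, index=gene_ids, columns=samples)

    # ordinal stage: quartile cut of noisy latent risk
    noisy = risk + rng.normal(0.0, config.stage_noise_sd, size=n)
    stage = np.ceil(4.0 * rankdata(noisy, method="ordinal") / n).astype(int)

    # response: responders concentrate in low latent risk for positive slope
    p_resp = 1.0 / (1.0 + np.exp(config.response_logit_slope * risk))
    response = (rng.uniform(size=n) < p_resp).astype(int)

    clinical = pd.DataFrame({
        "time_months": time,
        "event": event,
        "age": np.clip(rng.normal(60.0, 10.0, size=n), 18, 90).round(1),
        "gender": np.where(rng.uniform(size=n) < 0.5, "male", "female"),
        "tnm_stage": stage,
        "cohort": [f"cohort{c}" for c in cohort],
        "response": response,
    }, index=pd.Index(samples, name="sample_id"))

    median = float(np.median(risk))
    true_group = pd.Series(np.where(risk > median, "high", "low"),
                           index=samples, name="true_group")
    truth = GroundTruth(abund, latent_risk, tuple(config.planted_pairs),
                        true_group, tuple(config.cell_types))
    collection = GeneSetCollection(dict(sets),
                                   {c: "synthetic metagene set" for c in cells})
    return CohortBundle(expression, clinical, collection, truth)


def monotone_distort(expression: pd.DataFrame, cohorts: pd.Series,
                     seed: int = 0) -> pd.DataFrame:
    """Apply a per-cohort strictly increasing transform to expression.

    Each cohort gets ``y = b + a x + c x^3`` with a > 0 and c >= 0 —
    strictly increasing, so every sample's within-column ordering (and
    hence every rank-based downstream quantity) is preserved.
    """
    rng = np.random.default_rng(seed)
    out = expression.copy()
    for cohort in pd.unique(cohorts):
        a = rng.uniform(0.5, 2.0)
        b = rng.uniform(-2.0, 2.0)
        c = rng.uniform(0.0, 0.05)
        cols = cohorts.index[cohorts == cohort]
        x = out[cols].to_numpy()
        out[cols] = b + a * x + c * x**3
    return out


# ---------------------------------------------------------------------------
# Fixture round-trip

_FILES = {
    "expression": "expression.tsv",
    "clinical": "clinical.csv",
    "gmt": "gene_sets.gmt",
    "abundance": "truth_abundance.csv",
    "risk": "truth_samples.csv",
    "pairs": "truth_pairs.json",
}


def write_fixture(bundle: CohortBundle, directory: str | Path) -> None:
    """Write a bundle as plain-text files (TSV/CSV/GMT/JSON)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_expression(bundle.expression, d / _FILES["expression"])
    write_clinical(bundle.clinical, d / _FILES["clinical"])
    write_gmt(bundle.gene_sets, d / _FILES["gmt"])
    bundle.truth.latent_abundance.to_csv(d / _FILES["abundance"],
                                         index_label="cell_type")
    pd.DataFrame({
        "latent_risk": bundle.truth.latent_risk,
        "true_group": bundle.truth.true_group,
    }).to_csv(d / _FILES["risk"], index_label="sample_id")
    payload = {"planted_pairs": [list(p) for p in bundle.truth.planted_pairs],
               "cell_types": list(bundle.truth.cell_types)}
    (d / _FILES["pairs"]).write_text(json.dumps(payload, indent=2))


def read_fixture(directory: str | Path) -> CohortBundle:
    """Load a bundle written by :func:`write_fixture`."""
    d = Path(directory)
    for key, fname in _FILES.items():
        if not (d / fname).exists():
            raise FileNotFoundError(f"fixture file missing: {d / fname}")
    expression = read_expression(d / _FILES["expression"])
    clinical = read_clinical(d / _FILES["clinical"])
    if clinical.shape[0] == 0 or expression.shape[1] == 0:
        raise ValueError("fixture has no samples")
    gene_sets = read_gmt(d / _FILES["gmt"])
    abundance = pd.read_csv(d / _FILES["abundance"], index_col=0)
    truth_samples = pd.read_csv(d / _FILES["risk"], index_col=0)
    payload = json.loads((d / _FILES["pairs"]).read_text())
    truth = GroundTruth(
        abundance,
        truth_samples["latent_risk"],
        tuple(tuple(p) for p in payload["planted_pairs"]),
        truth_samples["true_group"],
        tuple(payload["cell_types"]),
    )
    if set(expression.columns) != set(clinical.index):
        raise ValueError("expression and clinical sample ids differ")
    return CohortBundle(expression, clinical, gene_sets, truth)
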