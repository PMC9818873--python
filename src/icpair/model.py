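"""Immune-cell-pair prognostic indices: signature training and composition.

``CellPairSignatureModel`` turns a binary pair matrix plus survival data
into a sparse Cox signature — the immune-cell-related prognostic index
(ICRPI): log-rank screening on the full cohort, a seeded 1:1
train/test split, LASSO-Cox selection and an unpenalized multivariate
Cox refit on the training half, and a classification cutoff taken from
the training-half time-dependent ROC at a fixed horizon (default 5
years = 60 months). The per-sample score is the linear form

    ICRPI(s) = sum_i coef_i * pair_i(s)

and samples are called high-risk when the score strictly exceeds the
cutoff.

``CompositeIndexModel`` augments the signature with clinical covariates
(age, gender, TNM stage) through a multivariable Cox fit, retaining the
covariates with Wald p < 0.05 — the composite prognostic index (ICPI).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pairs import PairMatrix, as_pair_frame, filter_pairs
from .roc import RocCurve, select_cutoff, time_dependent_roc
from .survival import (CoxFit, c_index, fit_cox, lasso_cox, logrank_test,
                       screen_pairs)

__all__ = [
    "SignatureModel",
    "CellPairSignatureModel",
    "SignatureResults",
    "CompositeIndexModel",
    "CompositeResults",
    "compute_icrpi",
    "linear_index",
    "assign_groups",
    "train_signature",
    "build_icpi",
]

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# Serializable signature (coefficients + cutoff)


@dataclass
class SignatureModel:
    """A fitted pair signature: ordered pair ids, Cox coefficients, cutoff."""

    pair_ids: list[str]
    coefficients: np.ndarray
    cutoff: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.pair_ids) != self.coefficients.size:
            raise ValueError("pair ids and coefficients differ in length")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite coefficient")
        if not np.isfinite(self.cutoff):
            raise ValueError("non-finite cutoff")

    def score(self, pairs: "PairMatrix | pd.DataFrame") -> pd.Series:
        return compute_icrpi(self, pairs)

    def assign(self, pairs: "PairMatrix | pd.DataFrame") -> pd.DataFrame:
        return assign_groups(self.score(pairs), self.cutoff)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "pair_ids": self.pair_ids,
            "coefficients": self.coefficients.tolist(),
            "cutoff": self.cutoff,
            "metadata": self.metadata,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SignatureModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        if payload.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {payload.get('schema_version')}")
        return cls(payload["pair_ids"], np.array(payload["coefficients"]),
                   float(payload["cutoff"]), payload.get("metadata", {}))


def compute_icrpi(model: SignatureModel, pairs: "PairMatrix | pd.DataFrame") -> pd.Series:
    """Per-sample linear risk score: sum of coefficient x pair indicator."""
    frame = as_pair_frame(pairs)
    missing = [p for p in model.pair_ids if p not in frame.index]
    if missing:
        raise KeyError(f"pair ids missing from pair matrix: {missing}")
    x = frame.loc[model.pair_ids].to_numpy(dtype=float)
    return pd.Series(model.coefficients @ x, index=frame.columns, name="ICRPI")


def linear_index(coefficients: pd.Series, covariates: pd.DataFrame) -> pd.Series:
    """Evaluate a linear prognostic index: sum of coefficient x covariate."""
    missing = [c for c in coefficients.index if c not in covariates.columns]
    if missing:
        raise KeyError(f"covariates missing from table: {missing}")
    x = covariates[list(coefficients.index)].to_numpy(dtype=float)
    return pd.Series(x @ coefficients.to_numpy(dtype=float),
                     index=covariates.index)


def assign_groups(scores: pd.Series, cutoff: float) -> pd.DataFrame:
    """High/low risk split; high iff score strictly exceeds the cutoff."""
    scores = pd.Series(scores)
    if not np.all(np.isfinite(scores.to_numpy(dtype=float))):
        raise ValueError("non-finite scores")
    group = np.where(scores.to_numpy(dtype=float) > cutoff, "high", "low")
    return pd.DataFrame({"score": scores, "group": group}, index=scores.index)


# ---------------------------------------------------------------------------
# Model / Results


class CellPairSignatureModel:
    """Signature model over a pair matrix and survival table.

    Parameters
    ----------
    pairs
        pairs x samples binary matrix (``PairMatrix`` or DataFrame).
    surv
        survival table indexed by sample id with ``time_months``/``event``.
    screen_alpha
        log-rank screening level (raw p by default).
    adjust
        'none' or 'BH' adjustment for the screen.
    n_folds
        folds for the LASSO-Cox penalty cross-validation.
    split_ratio
        fraction of samples in the training half (default 1:1).
    roc_time
        horizon in months for the cutoff ROC (default 60 = 5 years).
    min_prevalence
        pair-filter band; 0 removes only strictly constant pairs.
    prune_alpha
        optionally drop lasso-selected pairs whose multivariate Wald p
        exceeds this level and refit; None keeps the lasso selection.
    """

    def __init__(self, pairs, surv: pd.DataFrame, *, screen_alpha: float = 0.05,
                 adjust: str = "none", n_folds: int = 5, split_ratio: float = 0.5,
                 roc_time: float = 60.0, min_prevalence: float = 0.0,
                 prune_alpha: float | None = None):
        frame = as_pair_frame(pairs)
        if set(frame.columns) != set(surv.index):
            raise ValueError("pair matrix and survival table sample ids differ")
        self.pairs = pairs if isinstance(pairs, PairMatrix) else \
            PairMatrix(frame, pd.Series(0, index=frame.index))
        self.surv = surv
        self.screen_alpha = screen_alpha
        self.adjust = adjust
        self.n_folds = n_folds
        self.split_ratio = split_ratio
        self.roc_time = roc_time
        self.min_prevalence = min_prevalence
        self.prune_alpha = prune_alpha

    def fit(self, seed: int = 0) -> "SignatureResults":
        filtered, dropped = filter_pairs(self.pairs, self.min_prevalence)
        if len(filtered) == 0:
            raise ValueError("no pairs survive the prevalence filter")

        # screen on the entire cohort, then split 1:1 for selection/fitting
        screen = screen_pairs(filtered, self.surv, alpha=self.screen_alpha,
                              adjust=self.adjust)
        prognostic = list(screen.index[screen["selected"]])
        if len(prognostic) < 2:
            raise ValueError(
                f"only {len(prognostic)} pairs pass the log-rank screen; "
                "cannot run penalized selection")

        rng = np.random.default_rng(seed)
        samples = np.array(self.surv.index)
        train_ids, test_ids = self._split(samples, rng)
        surv_train = self.surv.loc[train_ids]
        surv_test = self.surv.loc[test_ids]
        pair_train = filtered.data.loc[prognostic, train_ids]
        # drop pairs that became constant within the training half
        nonconst = pair_train.std(axis=1) > 0
        pair_train = pair_train.loc[nonconst]

        lasso = lasso_cox(pair_train, surv_train, n_folds=self.n_folds,
                          seed=int(rng.integers(0, 2**31 - 1)))
        selected = lasso.selected
        if not selected:
            raise ValueError("LASSO-Cox selected no pairs")
        cox = fit_cox(pair_train.loc[selected], surv_train)
        if self.prune_alpha is not None:
            keep = list(cox.p_values.index[cox.p_values < self.prune_alpha])
            if keep and len(keep) < len(selected):
                selected = keep
                cox = fit_cox(pair_train.loc[selected], surv_train)

        model = SignatureModel(
            selected, cox.params.to_numpy(), cutoff=0.0,
            metadata={
                "seed": int(seed), "split_ratio": self.split_ratio,
                "screen_alpha": self.screen_alpha, "adjust": self.adjust,
                "penalty": lasso.penalty, "n_folds": self.n_folds,
                "roc_time": self.roc_time,
                "n_pairs_input": int(len(self.pairs)),
                "n_pairs_filtered": int(len(filtered)),
                "n_pairs_screened": int(len(prognostic)),
            },
        )
        train_scores = model.score(filtered.data.loc[:, train_ids])
        roc = time_dependent_roc(train_scores, surv_train, t_eval=self.roc_time)
        model.cutoff = select_cutoff(roc)
        model.metadata["train_auc"] = roc.auc

        return SignatureResults(self, model, cox, screen, lasso, roc,
                                train_ids=list(train_ids), test_ids=list(test_ids),
                                dropped_pairs=dropped)

    def _split(self, samples: np.ndarray,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        n_train = int(round(self.split_ratio * samples.size))
        events = self.surv["event"].to_numpy()
        for _ in range(100):
            perm = rng.permutation(samples.size)
            tr, te = samples[perm[:n_train]], samples[perm[n_train:]]
            if events[perm[:n_train]].sum() >= 2 and events[perm[n_train:]].sum() >= 2:
                return tr, te
        raise ValueError("could not split with events in both halves")


class SignatureResults:
    """Fitted signature with training diagnostics and held-out evaluation."""

    def __init__(self, parent: CellPairSignatureModel, model: SignatureModel,
                 cox: CoxFit, screen: pd.DataFrame, lasso, roc: RocCurve,
                 train_ids: list, test_ids: list, dropped_pairs: list[str]):
        self.model_spec = parent
        self.signature = model
        self.cox = cox
        self.screen = screen
        self.lasso = lasso
        self.roc = roc
        self.train_ids = train_ids
        self.test_ids = test_ids
        self.dropped_pairs = dropped_pairs

    # -- statsmodels-flavoured accessors
    @property
    def params(self) -> pd.Series:
        return pd.Series(self.signature.coefficients,
                         index=self.signature.pair_ids, name="coef")

    @property
    def cutoff(self) -> float:
        return self.signature.cutoff

    def predict(self, pairs: "PairMatrix | pd.DataFrame") -> pd.Series:
        return self.signature.score(pairs)

    def assign(self, pairs: "PairMatrix | pd.DataFrame") -> pd.DataFrame:
        return self.signature.assign(pairs)

    def heldout_evaluation(self) -> dict:
        """C-index, 5-year AUC and risk-group log-rank on the held-out half."""
        frame = as_pair_frame(self.model_spec.pairs)
        surv_test = self.model_spec.surv.loc[self.test_ids]
        scores = self.signature.score(frame.loc[:, self.test_ids])
        out = {"c_index": c_index(scores, surv_test)}
        try:
            roc = time_dependent_roc(scores, surv_test,
                                     t_eval=self.model_spec.roc_time)
            out["auc"] = roc.auc
        except ValueError:
            out["auc"] = float("nan")
        groups = assign_groups(scores, self.signature.cutoff)["group"]
        if groups.nunique() == 2:
            stat, p = logrank_test(surv_test["time_months"], surv_test["event"],
                                   groups.to_numpy())
            out["logrank_statistic"], out["logrank_p"] = stat, p
        else:
            out["logrank_statistic"] = out["logrank_p"] = float("nan")
        return out

    def summary(self) -> pd.DataFrame:
        tab = self.cox.summary().loc[self.signature.pair_ids].copy()
        tab["screen_p"] = self.screen["p_value"].reindex(tab.index)
        return tab

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<SignatureResults: {len(self.signature.pair_ids)} pairs, "
                f"cutoff={self.signature.cutoff:.4f}, "
                f"train AUC={self.roc.auc:.3f}>")


def train_signature(pairs, surv: pd.DataFrame, *, seed: int = 0,
                    **kwargs) -> SignatureResults:
    """Convenience wrapper: construct the model and fit in one call."""
    return CellPairSignatureModel(pairs, surv, **kwargs).fit(seed=seed)


# ---------------------------------------------------------------------------
# Composite clinical index


class CompositeIndexModel:
    """Composite of the pair signature score with clinical covariates.

    Fits a multivariable Cox model on the signature score plus age,
    gender and TNM stage (whichever are present in the survival table),
    retains covariates with Wald p below ``alpha``, and exposes the
    resulting linear index.
    """

    CLINICAL = ("age", "gender", "tnm_stage")

    def __init__(self, scores: pd.Series, surv: pd.DataFrame, alpha: float = 0.05):
        if set(scores.index) != set(surv.index):
            raise ValueError("scores and survival table sample ids differ")
        self.scores = scores[surv.index]
        self.surv = surv
        self.alpha = alpha

    def fit(self) -> "CompositeResults":
        covs = pd.DataFrame({"ICRPI": self.scores.astype(float)}, index=self.surv.index)
        for name in self.CLINICAL:
            if name not in self.surv.columns:
                continue
            col = self.surv[name]
            if name == "gender":
                col = (col.astype(str).str.lower() == "male").astype(float)
            col = pd.to_numeric(col, errors="coerce")
            if col.isna().any() or col.std() == 0:
                continue
            covs[name] = col.astype(float)
        cox = fit_cox(covs, self.surv)
        retained = list(cox.p_values.index[cox.p_values < self.alpha])
        if not retained:
            warnings.warn("no covariate significant; composite falls back to "
                          "the signature score alone", RuntimeWarning, stacklevel=2)
            retained = ["ICRPI"]
        if set(retained) != set(covs.columns):
            cox_final = fit_cox(covs[retained], self.surv)
        else:
            cox_final = cox
        return CompositeResults(self, cox, cox_final, retained, covs)


class CompositeResults:
    """Retained covariates and the composite linear index."""

    def __init__(self, parent: CompositeIndexModel, cox_full: CoxFit,
                 cox: CoxFit, retained: list[str], covariates: pd.DataFrame):
        self.model_spec = parent
        self.cox_full = cox_full
        self.cox = cox
        self.retained = retained
        self.covariates = covariates

    @property
    def params(self) -> pd.Series:
        return self.cox.params.loc[self.retained]

    def predict(self, scores: pd.Series | None = None,
                clinical: pd.DataFrame | None = None) -> pd.Series:
        """Composite score: sum of retained coefficient x covariate."""
        if scores is None and clinical is None:
            cov = self.covariates
        else:
            cov = pd.DataFrame(index=scores.index)
            for name in self.retained:
                if name == "ICRPI":
                    cov[name] = scores.astype(float)
                else:
                    col = clinical[name]
                    if name == "gender":
                        col = (col.astype(str).str.lower() == "male").astype(float)
                    cov[name] = pd.to_numeric(col).astype(float)
        return linear_index(self.params, cov).rename("ICPI")

    def formula(self) -> str:
        terms = [f"{name} x {coef:.3f}" for name, coef in self.params.items()]
        return " + ".join(terms)

    def summary(self) -> pd.DataFrame:
        tab = self.cox_full.summary().copy()
        tab["retained"] = [name in self.retained for name in tab.index]
        return tab


def build_icpi(scores: pd.Series, surv: pd.DataFrame,
               alpha: float = 0.05) -> CompositeResults:
    """Convenience wrapper around :class:`CompositeIndexModel`."""
    return CompositeIndexModel(scores, surv, alpha=alpha).fit()
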