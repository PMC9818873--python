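"""Binary immune-cell-pair (ICP) features from infiltration scores.

A pair ``A|B`` (A before B in the input cell-type order) scores 1 in a
sample when cell type A's infiltration strictly exceeds B's, else 0.
Because the indicator depends only on the within-sample ordering, the
pair matrix is invariant to any per-sample strictly monotone distortion
of the scores — the property that lets cohorts from different platforms
be pooled without normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = ["PairMatrix", "build_pairs", "filter_pairs", "pair_id"]

PAIR_SEP = "|"


def pair_id(cell_a: str, cell_b: str) -> str:
    return f"{cell_a}{PAIR_SEP}{cell_b}"


@dataclass
class PairMatrix:
    """Pairs x samples 0/1 indicator matrix with per-pair tie counts."""

    data: pd.DataFrame          # pairs x samples, int8 values in {0, 1}
    tie_counts: pd.Series       # per pair: samples where the two scores tied

    @property
    def prevalence(self) -> pd.Series:
        """Fraction of samples scoring 1, per pair."""
        return self.data.mean(axis=1)

    @property
    def pair_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return self.data.shape[0]


def build_pairs(infiltration: pd.DataFrame) -> PairMatrix:
    """All C(n_cells, 2) pairwise order indicators.

    Pair direction is canonical: the cell appearing first in the
    infiltration matrix's row order is the pair's left member. Ties score
    0 and are tallied in ``tie_counts``.
    """
    if infiltration.shape[0] < 2 or infiltration.shape[1] < 1:
        raise ValueError("need at least 2 cell types and 1 sample")
    values = infiltration.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("non-finite infiltration values")

    cells = list(infiltration.index)
    idx_pairs = list(combinations(range(len(cells)), 2))
    ids = [pair_id(cells[i], cells[j]) for i, j in idx_pairs]
    ia = np.array([i for i, _ in idx_pairs])
    ib = np.array([j for _, j in idx_pairs])
    a, b = values[ia], values[ib]
    data = pd.DataFrame((a > b).astype(np.int8), index=ids,
                        columns=infiltration.columns)
    ties = pd.Series((a == b).sum(axis=1), index=ids, name="ties")
    return PairMatrix(data, ties)


def filter_pairs(
    pairs: PairMatrix, min_prevalence: float = 0.0
) -> tuple[PairMatrix, list[str]]:
    """Drop uninformative pairs; returns (retained matrix, dropped ids).

    With the default ``min_prevalence = 0`` exactly the constant pairs
    (prevalence 0 or 1 over all samples) are removed; a positive value
    keeps only pairs with prevalence in [min_prevalence, 1 - min_prevalence].
    Idempotent for any fixed threshold.
    """
    if not 0.0 <= min_prevalence <= 0.5:
        raise ValueError(f"min_prevalence must be in [0, 0.5], got {min_prevalence}")
    prev = pairs.prevalence
    if min_prevalence == 0.0:
        keep = (prev > 0.0) & (prev < 1.0)
    else:
        keep = (prev >= min_prevalence) & (prev <= 1.0 - min_prevalence)
    kept = pairs.data.loc[keep]
    dropped = list(pairs.data.index[~keep])
    return PairMatrix(kept, pairs.tie_counts.loc[keep.index[keep]]), dropped


def as_pair_frame(pairs: "PairMatrix | pd.DataFrame") -> pd.DataFrame:
    """Accept a PairMatrix or a plain pairs x samples 0/1 DataFrame."""
    return pairs.data if isinstance(pairs, PairMatrix) else pairs
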