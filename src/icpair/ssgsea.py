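"""Single-sample gene set enrichment (ssGSEA) infiltration scoring.

Each sample is scored independently against each gene set using only the
within-sample ranking of gene expression, so scores are invariant to any
strictly increasing per-sample transform of the expression values — the
property that makes downstream rank-pair features portable across
platforms.

For one sample with N genes ranked by expression (rank 1 = highest,
ties given average ranks), walking the ranked list j = 1..N:

    P_in(j)  = sum_{i<=j, g_i in S} w_i / sum_{i in S} w_i,
               w_i = (N - rank_i + 1)^alpha
    P_out(j) = #{i<=j, g_i not in S} / (N - |S|)
    ES(S)    = sum_j [P_in(j) - P_out(j)]

``alpha`` defaults to 0.25, the conventional ssGSEA weight exponent.
Optional normalization divides the whole score matrix by its global
max - min.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import GeneSetCollection, _validate_expression

__all__ = ["ssgsea_scores"]

logger = logging.getLogger(__name__)


def ssgsea_scores(
    expression: pd.DataFrame,
    gene_sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """Score every sample against every gene set.

    Parameters
    ----------
    expression
        genes x samples matrix of log-scale expression.
    gene_sets
        named gene lists; genes absent from ``expression`` are dropped
        (count logged per set), but a set losing all its genes is an error.
    alpha
        nonnegative rank-weight exponent.
    normalize
        if True, divide the full score matrix by its global max - min.

    Returns
    -------
    DataFrame of enrichment scores, gene sets x samples, with
    ``alpha``/``normalize`` recorded in ``.attrs``.
    """
    _validate_expression(expression)
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")

    gene_index = pd.Index(expression.index)
    n_genes = len(gene_index)
    memberships: list[np.ndarray] = []
    for name, genes in gene_sets.items():
        locs = gene_index.get_indexer(genes)
        present = locs[locs >= 0]
        dropped = int((locs < 0).sum())
        if dropped:
            logger.info("gene set %s: dropped %d/%d genes absent from matrix",
                        name, dropped, len(genes))
        if present.size == 0:
            raise ValueError(f"gene set {name!r} has no genes in the expression matrix")
        if present.size == n_genes:
            raise ValueError(f"gene set {name!r} covers every gene; P_out is undefined")
        mask = np.zeros(n_genes, dtype=bool)
        mask[present] = True
        memberships.append(mask)

    values = expression.to_numpy(dtype=float)
    scores = np.empty((len(memberships), values.shape[1]))
    for s in range(values.shape[1]):
        col = values[:, s]
        # rank 1 = highest expression; ties share the average rank
        ranks = rankdata(-col, method="average")
        weights = (n_genes - ranks + 1.0) ** alpha
        # walk order: expression descending, stable on the input gene order
        order = np.argsort(-col, kind="stable")
        w_ord = weights[order]
        for k, mask in enumerate(memberships):
            in_ord = mask[order]
            size = int(mask.sum())
            p_in = np.cumsum(np.where(in_ord, w_ord, 0.0)) / w_ord[in_ord].sum()
            p_out = np.cumsum(~in_ord) / (n_genes - size)
            scores[k, s] = float(np.sum(p_in - p_out))

    out = pd.DataFrame(scores, index=list(gene_sets.names), columns=expression.columns)
    if normalize:
        span = float(out.to_numpy().max() - out.to_numpy().min())
        if span > 0:
            out = out / span
    out.attrs["alpha"] = alpha
    out.attrs["normalize"] = bool(normalize)
    return out
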