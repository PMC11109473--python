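"""PCA overview of samples on total abundances or fractional contributions."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .tables import TOTAL_ABUNDANCE, MetaboliteTable

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    """Scores (sample × PC), loadings (feature × PC), variance ratios."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    dropped_features: list[str]


def pca_overview(
    table: MetaboliteTable,
    *,
    scaling: str | None = None,
    n_components: int | None = None,
    log_transform: bool | None = None,
    samples: list[str] | None = None,
) -> PCAResult:
    """Principal component analysis of samples in metabolite space.

    Defaults follow the quantity: abundances are log10-transformed (offset
    = half the minimum positive value) and scaled to unit variance, since
    metabolite pools span orders of magnitude; fractional contributions
    are already bounded in [0, 1] and enter centered but unscaled.

    Zero-variance features are dropped (and reported on the result).
    Component signs are fixed by making each component's largest-magnitude
    loading positive, so results are fully deterministic.
    """
    data = table.data if samples is None else table.data[samples]
    data = data.dropna(axis=0, how="any")
    if data.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")

    if scaling is None:
        scaling = "unit_variance" if table.quantity == TOTAL_ABUNDANCE else "none"
    if scaling not in ("none", "unit_variance"):
        raise ValueError(f"unknown scaling {scaling!r}")
    if log_transform is None:
        log_transform = table.quantity == TOTAL_ABUNDANCE

    x = data.to_numpy(dtype=float).T  # samples × features
    if log_transform:
        positive = x[x > 0]
        offset = positive.min() / 2.0 if positive.size else 1.0
        x = np.log10(x + offset)
        logger.info("log10 transform applied with offset %.3g", offset)

    variances = x.var(axis=0)
    keep = variances > 0
    dropped = [f for f, k in zip(data.index, keep) if not k]
    if dropped:
        logger.info("dropping %d zero-variance features: %s", len(dropped), dropped)
    x = x[:, keep]
    features = data.index[keep]

    if scaling == "unit_variance":
        x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)

    max_rank = min(x.shape[0] - 1, x.shape[1])
    if n_components is None:
        n_components = max_rank
    elif n_components > max_rank:
        logger.warning(
            "requested %d components, clipping to rank limit %d", n_components, max_rank
        )
        n_components = max_rank

    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    loadings = model.components_.T  # features × components

    # deterministic sign: largest-|loading| entry of each PC is positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    scores = scores * flip
    loadings = loadings * flip

    pcs = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=data.columns, columns=pcs),
        loadings=pd.DataFrame(loadings, index=features, columns=pcs),
        explained_variance_ratio=model.explained_variance_ratio_,
        dropped_features=dropped,
    )
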