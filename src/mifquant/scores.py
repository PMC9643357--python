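"""Small tabular statistics for cytometry clusters and per-cell transcript counts.

* rare-cluster filter: clusters below 0.5% frequency are discarded
  (strict <; exactly 0.5% is retained);
* iMFI: per cluster x marker, mean fluorescence intensity x cluster
  frequency, min–max rescaled to [0, 100] across clusters within each
  marker;
* signature score: per cell, the fraction of transcript counts falling in
  a gene set, with an emphasis flag for scores strictly above the 80th
  percentile of the score distribution;
* cytolytic index: geometric mean of GZMA and PRF1 expression.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def filter_rare_clusters(
    frequencies: pd.Series | dict, min_frequency: float = 0.005
) -> list:
    """Clusters retained by the under-representation filter.

    A cluster is discarded iff its frequency is strictly below
    ``min_frequency`` (default 0.5%); frequencies are proportions in [0, 1].
    Returns the retained cluster labels in input order.
    """
    freqs = pd.Series(frequencies)
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValueError("frequencies must be proportions in [0, 1]")
    return list(freqs.index[freqs >= min_frequency])


def imfi(mfi: pd.DataFrame, frequencies: pd.Series) -> pd.DataFrame:
    """Integrated MFI per cluster x marker, rescaled to [0, 100].

    Raw value = MFI x cluster frequency.  Rescaling is min–max across
    clusters, independently per marker (column).  When all raw values of a
    marker are equal the scale is degenerate and every cluster maps to 0.

    ``mfi`` is clusters x markers; ``frequencies`` is indexed by cluster.
    """
    if mfi.empty:
        raise ValueError("need at least one cluster")
    freqs = frequencies.reindex(mfi.index)
    if freqs.isna().any():
        missing = list(mfi.index[freqs.isna()])
        raise ValueError(f"no frequency for cluster(s) {missing}")
    raw = mfi.mul(freqs, axis=0)
    lo = raw.min(axis=0)
    span = raw.max(axis=0) - lo
    out = pd.DataFrame(0.0, index=raw.index, columns=raw.columns)
    ok = span > 0
    out.loc[:, ok] = (raw.loc[:, ok] - lo[ok]) / span[ok] * 100.0
    return out


def signature_score(counts: pd.Series | dict, signature: set[str] | list[str]) -> float:
    """Fraction of a cell's transcript counts belonging to a gene set.

    score = sum of counts over signature genes / total counts of the cell.
    Genes absent from the cell contribute 0.  ``total_counts = 0`` is an
    error.
    """
    c = pd.Series(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be >= 0")
    total = c.sum()
    if total <= 0:
        raise ValueError("cell has zero total counts")
    return float(c.reindex(list(signature)).fillna(0.0).sum() / total)


def signature_scores(
    counts: pd.DataFrame, signature: set[str] | list[str]
) -> pd.DataFrame:
    """Signature scores for a genes x cells count matrix, with emphasis flags.

    Returns a per-cell table (score, emphasized); ``emphasized`` marks
    scores strictly greater than the 80th percentile (linear interpolation)
    of the scores across all cells.
    """
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"cell(s) with zero total counts: {bad}")
    in_sig = counts.index.isin(list(signature))
    scores = counts.loc[in_sig].sum(axis=0) / totals
    cutoff = float(np.quantile(scores.to_numpy(), 0.80, method="linear"))
    return pd.DataFrame({"score": scores, "emphasized": scores > cutoff})


def cytolytic_index(gzma: float, prf1: float) -> float:
    """Geometric mean of granzyme A and perforin expression: sqrt(gzma * prf1)."""
    if gzma < 0 or prf1 < 0:
        raise ValueError("expression values must be >= 0")
    return math.sqrt(gzma * prf1)
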