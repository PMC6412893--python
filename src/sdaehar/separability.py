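"""Class-separability diagnostics via scatter (dispersion) matrices.

The within-class scatter of class i is the biased covariance
``SW(i) = (1/Ni) sum (x - m_i)(x - m_i)^T`` and the total within-class
scatter is the prior-weighted sum ``SW = sum P(i) SW(i)`` with empirical
priors P(i) = Ni/N.  Between-class dispersion uses the pairwise rank-1
matrices ``SB(ij) = (m_i - m_j)(m_i - m_j)^T`` combined as
``SB = 1/2 sum_i sum_j P(i) P(j) SB(ij)``, which equals the prior-weighted
scatter of the class means about the grand mean.  Traces of these matrices
summarise compactness (within) and separation (between): a good feature
space has a small within-class trace and a large between-class trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScatterSummary",
    "DivergenceReport",
    "class_scatter",
    "total_inner_scatter",
    "pairwise_outer_scatter",
    "total_outer_scatter",
    "scatter_summary",
    "divergence_report",
]


@dataclass
class ScatterSummary:
    """All scatter statistics of one labelled point cloud."""

    classes: np.ndarray
    priors: np.ndarray
    means: np.ndarray          # (M, d) class means
    inner_per_class: np.ndarray  # (M, d, d)
    inner_total: np.ndarray      # (d, d)
    outer_pairwise: np.ndarray   # (M, M, d, d)
    outer_total: np.ndarray      # (d, d)

    @property
    def inner_trace(self) -> float:
        return float(np.trace(self.inner_total))

    @property
    def outer_trace(self) -> float:
        return float(np.trace(self.outer_total))

    def trace_table(self) -> pd.DataFrame:
        """Square class table: within-class traces on the diagonal,
        pairwise between-class traces off it."""
        m = len(self.classes)
        tab = np.empty((m, m))
        for i in range(m):
            for j in range(m):
                tab[i, j] = (
                    np.trace(self.inner_per_class[i])
                    if i == j
                    else np.trace(self.outer_pairwise[i, j])
                )
        names = [str(c) for c in self.classes]
        return pd.DataFrame(tab, index=names, columns=names)


def _class_rows(X: np.ndarray, y: np.ndarray, cls) -> np.ndarray:
    rows = X[np.asarray(y) == cls]
    if rows.shape[0] == 0:
        raise ValueError(f"unknown class {cls!r}")
    return rows


def class_scatter(X: np.ndarray, y: np.ndarray, cls) -> tuple[np.ndarray, np.ndarray]:
    """Mean and biased within-class scatter matrix of one class."""
    rows = _class_rows(np.asarray(X, dtype=float), y, cls)
    m = rows.mean(axis=0)
    d = rows - m
    sw = d.T @ d / rows.shape[0]
    return m, sw


def total_inner_scatter(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Prior-weighted total within-class scatter matrix and its trace."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    sw = np.zeros((X.shape[1], X.shape[1]))
    for cls, cnt in zip(*np.unique(y, return_counts=True)):
        _, swi = class_scatter(X, y, cls)
        sw += (cnt / n) * swi
    return sw, float(np.trace(sw))


def pairwise_outer_scatter(X: np.ndarray, y: np.ndarray, i, j) -> tuple[np.ndarray, float]:
    """Rank-1 between-class matrix (m_i - m_j)(m_i - m_j)^T and its trace."""
    mi, _ = class_scatter(X, y, i)
    mj, _ = class_scatter(X, y, j)
    d = mi - mj
    sb = np.outer(d, d)
    return sb, float(np.trace(sb))


def total_outer_scatter(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Half the double prior-weighted sum of pairwise between-class matrices."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    priors = counts / len(y)
    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    d = X.shape[1]
    sb = np.zeros((d, d))
    for a in range(len(classes)):
        for b in range(len(classes)):
            diff = means[a] - means[b]
            sb += priors[a] * priors[b] * np.outer(diff, diff)
    return 0.5 * sb, float(np.trace(0.5 * sb))


def scatter_summary(X: np.ndarray, y: np.ndarray) -> ScatterSummary:
    """Compute every scatter statistic of a labelled point cloud at once."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    priors = counts / len(y)
    means, inners = [], []
    for c in classes:
        m, sw = class_scatter(X, y, c)
        means.append(m)
        inners.append(sw)
    means = np.stack(means)
    inners = np.stack(inners)
    inner_total = np.einsum("i,ijk->jk", priors, inners)
    m_cls = len(classes)
    pairwise = np.empty((m_cls, m_cls, X.shape[1], X.shape[1]))
    for a in range(m_cls):
        for b in range(m_cls):
            diff = means[a] - means[b]
            pairwise[a, b] = np.outer(diff, diff)
    outer_total = 0.5 * np.einsum("i,j,ijkl->kl", priors, priors, pairwise)
    return ScatterSummary(
        classes=classes,
        priors=priors,
        means=means,
        inner_per_class=inners,
        inner_total=inner_total,
        outer_pairwise=pairwise,
        outer_total=outer_total,
    )


@dataclass
class DivergenceReport:
    """Raw-vs-feature scatter comparison, as emitted tables."""

    raw: ScatterSummary
    features: ScatterSummary

    def totals(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "raw": [self.raw.inner_trace, self.raw.outer_trace],
                "features": [self.features.inner_trace, self.features.outer_trace],
            },
            index=["inner_class_trace", "outer_class_trace"],
        )

    def raw_table(self) -> pd.DataFrame:
        return self.raw.trace_table()

    def feature_table(self) -> pd.DataFrame:
        return self.features.trace_table()


def divergence_report(
    raw: np.ndarray, features: np.ndarray, labels: np.ndarray
) -> DivergenceReport:
    """Compare class separability before and after feature extraction.

    ``raw`` and ``features`` must describe the same samples in the same
    order; ``labels`` applies to both.
    """
    if raw.shape[0] != features.shape[0]:
        raise ValueError("raw and feature row counts differ")
    return DivergenceReport(
        raw=scatter_summary(raw, labels),
        features=scatter_summary(features, labels),
    )
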