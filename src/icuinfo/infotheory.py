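"""Plug-in (maximum-likelihood) estimators of discrete information measures.

All quantities are in bits (logarithms base 2). The estimators substitute
empirical bin frequencies for the true probabilities; no bias correction is
applied by default. The plug-in mutual information of two variables binned
into ``Bx`` and ``By`` cells carries a positive bias of roughly
``(Bx - 1) * (By - 1) / (2 * N * ln 2)`` bits at sample size ``N``, which is
why several downstream tests compare against that bound rather than zero.

Conventions used throughout:

* ``0 * log2(0) = 0`` — empty bins contribute nothing.
* Marginals for mutual information are always the row/column sums of the
  joint itself, never a distribution estimated on a larger sample. This
  guarantees ``0 <= I <= min(H(X), H(Y))`` and hence non-negative
  conditional entropies, exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiscreteDistribution",
    "InfoDecomposition",
    "empirical_distribution",
    "entropy",
    "joint_distribution",
    "mutual_information",
    "conditional_entropy",
    "decompose",
    "oracle_mi",
]

_ATOL = 1e-9

# A DiscreteDistribution is a 1-D numpy array of probabilities; a
# JointDistribution is a 2-D array whose row sums are the X marginal and
# column sums the Y marginal. Plain arrays keep the estimators composable
# with numpy; validation lives in the functions that consume them.
DiscreteDistribution = np.ndarray


def _check_distribution(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty probability vector")
    if np.any(p < -_ATOL):
        raise ValueError("probabilities must be non-negative")
    total = float(p.sum())
    if abs(total - 1.0) > _ATOL:
        raise ValueError(f"probabilities sum to {total}, expected 1 within {_ATOL}")
    return np.clip(p, 0.0, None)


def empirical_distribution(bin_indices, n_bins: int) -> np.ndarray:
    """Empirical probability vector over ``n_bins`` bins.

    ``probabilities[k] = count(k) / n``; bins with no observations get
    probability zero.
    """
    idx = np.asarray(bin_indices, dtype=np.int64).ravel()
    if idx.size == 0:
        raise ValueError("cannot estimate a distribution from an empty sample")
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    if idx.min() < 0 or idx.max() >= n_bins:
        raise ValueError(f"bin indices must lie in [0, {n_bins - 1}]")
    counts = np.bincount(idx, minlength=n_bins)
    return counts / counts.sum()


def entropy(dist: np.ndarray) -> float:
    """Shannon entropy H = -sum p log2 p in bits, with 0 log2 0 = 0."""
    p = _check_distribution(dist)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def joint_distribution(x_bins, y_bins, n_bins_x: int, n_bins_y: int) -> np.ndarray:
    """Empirical joint probability matrix from paired bin indices."""
    x = np.asarray(x_bins, dtype=np.int64).ravel()
    y = np.asarray(y_bins, dtype=np.int64).ravel()
    if x.size == 0:
        raise ValueError("cannot estimate a joint distribution from an empty sample")
    if x.size != y.size:
        raise ValueError("x and y bin collections must have equal length")
    for arr, n_bins, name in ((x, n_bins_x, "x"), (y, n_bins_y, "y")):
        if arr.min() < 0 or arr.max() >= n_bins:
            raise ValueError(f"{name} bin indices must lie in [0, {n_bins - 1}]")
    counts = np.zeros((n_bins_x, n_bins_y), dtype=np.int64)
    np.add.at(counts, (x, y), 1)
    return counts / counts.sum()


def mutual_information(joint: np.ndarray) -> float:
    """I(X;Y) = sum_ij p_ij log2( p_ij / (p_i. p_.j) ) in bits.

    Marginals are taken from the joint's own row/column sums, so the result
    is non-negative and bounded by min(H(X), H(Y)) up to floating point.
    """
    p = np.asarray(joint, dtype=float)
    if p.ndim != 2:
        raise ValueError("joint distribution must be a 2-D matrix")
    _check_distribution(p.ravel())
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    outer = np.outer(px, py)
    mask = p > 0
    mi = float((p[mask] * np.log2(p[mask] / outer[mask])).sum())
    return max(mi, 0.0)


def conditional_entropy(h_x: float, mi: float) -> float:
    """H(X|Y) = H(X) - I(X;Y), floored at zero to absorb rounding."""
    if mi > h_x + _ATOL:
        raise ValueError(
            f"mutual information ({mi}) exceeds entropy ({h_x}): "
            "H and I were computed on inconsistent samples"
        )
    return max(h_x - mi, 0.0)


@dataclass(frozen=True)
class InfoDecomposition:
    """Entropy / mutual-information decomposition of one paired comparison.

    ``h_x_given_y`` is the expected novel information left in X once Y is
    known; ``mi`` is the redundant portion shared by both. All fields are in
    bits except ``n_pairs``, the number of within-patient pairs used.
    """

    h_x: float
    h_y: float
    mi: float
    h_x_given_y: float
    h_y_given_x: float
    n_pairs: int


def decompose(x_bins, y_bins, n_bins: int, *, miller_madow: bool = False) -> InfoDecomposition:
    """Full information decomposition of paired bin indices.

    H(X) and H(Y) are computed from the joint's own marginals, i.e. on the
    paired subset, which makes the chain identity H(X|Y) + I = H(X) exact.
    ``miller_madow=True`` applies the first-order Miller–Madow bias
    correction ``(occupied cells - 1) / (2 N ln 2)`` to each entropy (and
    hence to the MI via the identity I = H(X) + H(Y) - H(X,Y)); it is off by
    default, matching the plain plug-in analysis.
    """
    joint = joint_distribution(x_bins, y_bins, n_bins, n_bins)
    n = int(np.asarray(x_bins).size)
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    h_x = entropy(px)
    h_y = entropy(py)
    mi = mutual_information(joint)
    if miller_madow:
        ln2 = math.log(2.0)
        corr_x = (np.count_nonzero(px) - 1) / (2.0 * n * ln2)
        corr_y = (np.count_nonzero(py) - 1) / (2.0 * n * ln2)
        corr_xy = (np.count_nonzero(joint) - 1) / (2.0 * n * ln2)
        h_x += corr_x
        h_y += corr_y
        # I = H(X) + H(Y) - H(X,Y); each term gets its own correction.
        mi = max(mi + corr_x + corr_y - corr_xy, 0.0)
        mi = min(mi, h_x, h_y)
    return InfoDecomposition(
        h_x=h_x,
        h_y=h_y,
        mi=mi,
        h_x_given_y=conditional_entropy(h_x, mi),
        h_y_given_x=conditional_entropy(h_y, mi),
        n_pairs=n,
    )


def oracle_mi(joint_table) -> float:
    # Deliberately independent of mutual_information: explicit double loops
    # over the printed definition, python floats only. Test oracle — do not
    # use in the pipeline.
    table = [[float(v) for v in row] for row in joint_table]
    n_rows = len(table)
    n_cols = len(table[0])
    row_marg = [0.0] * n_rows
    col_marg = [0.0] * n_cols
    for i in range(n_rows):
        for j in range(n_cols):
            row_marg[i] += table[i][j]
            col_marg[j] += table[i][j]
    total = 0.0
    for i in range(n_rows):
        for j in range(n_cols):
            p = table[i][j]
            if p > 0.0:
                total += p * math.log2(p / (row_marg[i] * col_marg[j]))
    return total
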