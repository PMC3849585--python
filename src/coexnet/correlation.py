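"""Thresholded all-vs-all Pearson correlation with bounded memory.

Coexpression graphs are built from the pairs of probeset profiles whose
Pearson correlation reaches a save threshold.  For tens of thousands of
probesets the full correlation matrix does not fit in memory, so
:func:`pairwise_correlations` standardizes profiles once and computes the
matrix block by block, keeping only pairs at or above the threshold.

Conventions:

* Thresholds are one-sided: an edge requires ``r >= threshold``, never
  ``|r|``; anti-correlation is ignored.
* Ties at exactly ``r == threshold`` are included.
* Zero-variance profiles have undefined correlations; they are excluded
  from edge generation (the exclusion count is logged).
* Accumulation is in double precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from coexnet.expression import ExpressionMatrix

logger = logging.getLogger(__name__)

Edge = tuple[str, str, float]


@dataclass
class CorrelationEdgeList:
    """Unordered probeset (or sample) pairs with ``r >= save_threshold``.

    Each pair appears once, endpoints in lexicographic order, the list
    sorted by ``(node_a, node_b)``; the representation is therefore a
    deterministic function of the input matrix alone.
    """

    edges: list[Edge]
    save_threshold: float
    axis: str  # "probesets" or "samples"

    def __post_init__(self) -> None:
        if self.axis not in ("probesets", "samples"):
            raise ValueError(f"axis must be 'probesets' or 'samples', got {self.axis!r}")
        for a, b, r in self.edges:
            if a == b:
                raise ValueError(f"self-loop edge on {a!r}")
            if r < self.save_threshold:
                raise ValueError(
                    f"edge ({a!r}, {b!r}, {r}) below save threshold {self.save_threshold}"
                )

    def __len__(self) -> int:
        return len(self.edges)


def pearson(x, y) -> float:
    """Sample Pearson correlation of two equal-length vectors.

    Returns ``nan`` (undefined) when either vector has zero variance;
    undefined pairs never produce graph edges.  Requires length >= 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return float("nan")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _standardize_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center rows and scale to unit norm; rows of zero variance are zeroed.

    Returns (standardized matrix, boolean mask of valid rows).
    """
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    valid = norms > 0
    out = np.zeros_like(centered)
    out[valid] = centered[valid] / norms[valid, None]
    return out, valid


def pairwise_correlations(
    matrix: ExpressionMatrix,
    axis: str = "probesets",
    save_threshold: float = 0.70,
    chunk_size: int = 2000,
) -> CorrelationEdgeList:
    """All-vs-all Pearson correlations along ``axis``, keeping ``r >= save_threshold``.

    The computation proceeds over ``chunk_size`` x ``chunk_size`` blocks of
    the correlation matrix, so peak memory is bounded by the chunk size and
    never the full N x N matrix.  The result is independent of row/column
    order and of the chunking strategy.

    Parameters
    ----------
    matrix
        Expression matrix; needs >= 3 observations along the correlated axis.
    axis
        ``probesets`` correlates rows, ``samples`` correlates columns.
    save_threshold
        Pairs with ``r >= save_threshold`` are kept (one-sided; must be in
        (-1, 1]).
    chunk_size
        Block edge length; bounds peak memory at ~``chunk_size**2`` doubles.
    """
    if axis == "probesets":
        values = matrix.values
        ids = matrix.probeset_ids
    elif axis == "samples":
        values = matrix.values.T
        ids = matrix.sample_ids
    else:
        raise ValueError(f"axis must be 'probesets' or 'samples', got {axis!r}")
    if not (-1.0 < save_threshold <= 1.0):
        raise ValueError(f"save_threshold must be in (-1, 1], got {save_threshold}")
    n, n_obs = values.shape
    if n_obs < 3:
        raise ValueError(f"need at least 3 observations along {axis}, got {n_obs}")
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")

    z, valid = _standardize_rows(values.astype(float, copy=False))
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("excluded %d zero-variance profiles from edge generation", n_dropped)

    edges: list[Edge] = []
    for i0 in range(0, n, chunk_size):
        zi = z[i0 : i0 + chunk_size]
        for j0 in range(i0, n, chunk_size):
            block = np.clip(zi @ z[j0 : j0 + chunk_size].T, -1.0, 1.0)
            ii, jj = np.nonzero(block >= save_threshold)
            gi, gj = ii + i0, jj + j0
            keep = (gi < gj) & valid[gi] & valid[gj]
            for a, b, r in zip(gi[keep], gj[keep], block[ii[keep], jj[keep]]):
                u, v = ids[a], ids[b]
                if v < u:
                    u, v = v, u
                edges.append((u, v, float(r)))
    edges.sort(key=lambda e: (e[0], e[1]))
    return CorrelationEdgeList(edges=edges, save_threshold=save_threshold, axis=axis)


def sample_correlation_matrix(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Full symmetric samples x samples Pearson correlation matrix.

    Symmetric with unit diagonal; entries for zero-variance samples are
    ``nan`` off the diagonal.  Requires >= 3 probesets.
    """
    if matrix.n_probesets < 3:
        raise ValueError(f"need at least 3 probesets, got {matrix.n_probesets}")
    z, valid = _standardize_rows(matrix.values.T.astype(float))
    corr = np.clip(z @ z.T, -1.0, 1.0)
    corr[~valid, :] = np.nan
    corr[:, ~valid] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=matrix.sample_ids, columns=matrix.sample_ids)


def write_pearson_file(edges: CorrelationEdgeList, path) -> None:
    """Write a ``.pearson`` edge TSV: node_a, node_b, r (6-decimal fixed)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("node_a\tnode_b\tr\n")
        for a, b, r in edges.edges:
            fh.write(f"{a}\t{b}\t{r:.6f}\n")


def read_pearson_file(path, save_threshold: float, axis: str = "probesets") -> CorrelationEdgeList:
    """Read a ``.pearson`` edge TSV; tolerant of extra trailing columns."""
    raw: list[Edge] = []
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.lower().startswith("node_a"):
            fh.seek(0)  # headerless variant
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: expected >= 3 columns")
            a, b, r = fields[0], fields[1], float(fields[2])
            if b < a:
                a, b = b, a
            raw.append((a, b, r))
    raw.sort(key=lambda e: (e[0], e[1]))
    return CorrelationEdgeList(edges=raw, save_threshold=save_threshold, axis=axis)
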