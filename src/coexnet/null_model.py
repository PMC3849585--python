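"""Pseudo-probeset resampling null for correlation thresholds.

How likely is a correlation of ``r >= 0.75`` between two *unrelated*
expression profiles?  Parametric answers (the t-distribution of a Pearson
coefficient) assume normal marginals, which natural-scale intensity data
violate badly.  The empirical null used here sidesteps the assumption:
a *pseudo-probeset* is built by drawing, independently for each sample,
one observed value from that sample's column of the real matrix.  This
preserves every column's marginal distribution exactly while destroying
all cross-sample structure, so correlations between independent
pseudo-probesets estimate the chance-correlation tail under the data's own
(non-normal) distribution.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np

from coexnet.correlation import pairwise_correlations
from coexnet.expression import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class NullTailResult:
    """Simulated and observed tail fractions at a correlation threshold."""

    n_simulated: int
    threshold: float
    simulated_tail_fraction: float
    observed_tail_fraction: float
    seed: int
    n_observed_pairs_above: int = 0
    n_observed_pairs_total: int = 0
    n_redrawn: int = 0

    def __post_init__(self) -> None:
        if self.n_simulated < 1:
            raise ValueError("n_simulated must be >= 1")
        for name in ("simulated_tail_fraction", "observed_tail_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def expected_chance_pairs(self) -> float:
        """Expected count of observed pairs above threshold under the null."""
        return self.simulated_tail_fraction * self.n_observed_pairs_total

    def to_json(self, path) -> None:
        report = asdict(self)
        report["expected_chance_pairs"] = self.expected_chance_pairs
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2)


def generate_pseudo_probeset(matrix: ExpressionMatrix, rng: np.random.Generator) -> np.ndarray:
    """Draw one pseudo-probeset: per column, a uniformly random row's value.

    Row choices are independent across columns and drawn with replacement,
    so each column's marginal distribution is preserved while any
    cross-sample correlation structure is destroyed.
    """
    n_rows, n_cols = matrix.values.shape
    rows = rng.integers(n_rows, size=n_cols)
    return matrix.values[rows, np.arange(n_cols)]


def _pair_correlations(values: np.ndarray, rng: np.random.Generator, n_pairs: int) -> tuple[np.ndarray, int]:
    """Correlations of ``n_pairs`` independent pseudo-probeset pairs.

    Zero-variance draws give undefined correlations; those pairs are
    redrawn (the count is returned).
    """
    n_rows, n_cols = values.shape
    out = np.empty(n_pairs)
    filled = 0
    redrawn = 0
    while filled < n_pairs:
        batch = min(n_pairs - filled, 50_000)
        xi = values[rng.integers(n_rows, size=(batch, n_cols)), np.arange(n_cols)]
        yi = values[rng.integers(n_rows, size=(batch, n_cols)), np.arange(n_cols)]
        xc = xi - xi.mean(axis=1, keepdims=True)
        yc = yi - yi.mean(axis=1, keepdims=True)
        denom = np.sqrt((xc * xc).sum(axis=1) * (yc * yc).sum(axis=1))
        ok = denom > 0
        redrawn += int((~ok).sum())
        r = ((xc * yc).sum(axis=1)[ok] / denom[ok]).clip(-1.0, 1.0)
        take = min(r.size, n_pairs - filled)
        out[filled : filled + take] = r[:take]
        filled += take
    return out, redrawn


def simulate_null_tail(
    matrix: ExpressionMatrix,
    n_correlations: int = 1_000_000,
    threshold: float = 0.75,
    seed: int = 0,
    observed_chunk_size: int = 2000,
) -> NullTailResult:
    """Estimate the chance of correlations >= ``threshold`` by resampling.

    Draws ``n_correlations`` independent pairs of pseudo-probesets, computes
    the Pearson correlation of each pair, and reports the fraction at or
    above ``threshold``.  Also computes the observed tail: the fraction of
    all real probeset pairs (with defined correlation) at or above the same
    threshold.  Reproducible for a fixed ``seed``.

    Independent pairs (rather than all-vs-all among fewer pseudo-probesets)
    keep the draws independent, so the simulated fraction has a simple
    binomial error model.
    """
    if n_correlations < 1:
        raise ValueError("n_correlations must be >= 1")
    if matrix.n_samples < 3:
        raise ValueError(f"need at least 3 samples, got {matrix.n_samples}")
    rng = np.random.default_rng(seed)
    r, redrawn = _pair_correlations(matrix.values, rng, n_correlations)
    if redrawn:
        logger.info("redrew %d zero-variance pseudo-probeset pairs", redrawn)
    sim_fraction = float((r >= threshold).sum()) / n_correlations

    observed = pairwise_correlations(
        matrix, axis="probesets", save_threshold=threshold, chunk_size=observed_chunk_size
    )
    n_above = len(observed.edges)
    # total defined pairs: exclude zero-variance rows
    stds = matrix.values.std(axis=1)
    n_defined = int((stds > 0).sum())
    total_pairs = n_defined * (n_defined - 1) // 2
    obs_fraction = n_above / total_pairs if total_pairs else 0.0

    return NullTailResult(
        n_simulated=n_correlations,
        threshold=threshold,
        simulated_tail_fraction=sim_fraction,
        observed_tail_fraction=obs_fraction,
        seed=seed,
        n_observed_pairs_above=n_above,
        n_observed_pairs_total=total_pairs,
        n_redrawn=redrawn,
    )


def chance_expectation(
    observed_pairs_above: int, total_pairs: int, simulated_tail_fraction: float
) -> tuple[float, float]:
    """Expected chance pairs at the threshold: ``(count, fraction of total)``.

    The expected count is ``simulated_tail_fraction * total_pairs``; the
    fraction restates it relative to ``total_pairs``.  Both are reported
    explicitly — no further combination with the observed count is applied.
    """
    if total_pairs < 1:
        raise ValueError("total_pairs must be >= 1")
    expected_count = simulated_tail_fraction * total_pairs
    return expected_count, expected_count / total_pairs
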