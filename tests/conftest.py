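import numpy as np
import pytest

from coexnet.expression import ExpressionMatrix


def make_matrix(values, probeset_ids=None, sample_ids=None, gene_symbols=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    probeset_ids = probeset_ids or [f"{100000 + i}_at" for i in range(n)]
    sample_ids = sample_ids or [f"S{j + 1:03d}" for j in range(m)]
    gene_symbols = gene_symbols if gene_symbols is not None else [""] * n
    return ExpressionMatrix(probeset_ids, gene_symbols, values, sample_ids)


def naive_pairwise_correlations(values, threshold):
    """O(N^2) double-loop Pearson oracle: list of (i, j, r) with r >= threshold."""
    n = values.shape[0]
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            x, y = values[i], values[j]
            xc, yc = x - x.mean(), y - y.mean()
            denom = np.sqrt((xc @ xc) * (yc @ yc))
            if denom == 0:
                continue
            r = min(1.0, max(-1.0, (xc @ yc) / denom))
            if r >= threshold:
                out.append((i, j, r))
    return out


@pytest.fixture(scope="session")
def pinned_atlas():
    """The standard recovery fixture: 5 planted modules of 50 genes over 10
    cell types x 4 replicates, 500 background genes, 10% multiplicative noise."""
    from coexnet.synthetic import generate_atlas

    return generate_atlas(
        n_cell_types=10,
        replicates_per_type=4,
        module_sizes=[50] * 5,
        n_background=500,
        noise_sd=0.1,
        seed=1,
    )
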