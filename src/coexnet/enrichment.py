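"""Term over-representation per cluster: hypergeometric test + BH control.

For a cluster of ``n`` genes drawn from a background of ``N`` genes of
which ``K`` carry a term, the p-value for observing ``k`` or more
term-carrying genes in the cluster is the hypergeometric upper tail
``P(X >= k)``.  Within each cluster the Benjamini-Hochberg step-up
procedure controls the false discovery rate across the terms tested
(the per-cluster family mirrors testing clusters one at a time; a global
family is available via ``family="global"``).

Genes, not probesets, are the unit of testing: multiple probesets mapping
to one gene count once per cluster, avoiding pseudo-replication.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from coexnet.mcl import ClusterAssignment


@dataclass
class AnnotationMap:
    """Term -> gene-set map over a fixed background of genes."""

    genes_of_term: dict[str, set]
    background: set
    term_name: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.genes_of_term.items():
            if not genes:
                raise ValueError(f"term {term!r} annotates no genes")
            stray = genes - self.background
            if stray:
                raise ValueError(
                    f"term {term!r} annotates genes outside the background: "
                    f"{sorted(stray)[:5]}"
                )
        if not self.background:
            raise ValueError("empty background")


def read_annotation_map(term_gene_path, term_name_path=None, background=None) -> AnnotationMap:
    """Load annotations from a 2-column TSV ``(term_id, gene_id)``.

    ``background`` defaults to the union of annotated genes.  An optional
    2-column ``(term_id, name)`` TSV supplies display names.  No ontology
    structure is read and no ancestor propagation is performed.
    """
    df = pd.read_csv(term_gene_path, sep="\t", dtype=str, header=None,
                     names=["term_id", "gene_id"], comment="#")
    genes_of_term: dict[str, set] = {}
    for term, gene in zip(df.term_id, df.gene_id):
        genes_of_term.setdefault(term, set()).add(gene)
    bg = set(background) if background is not None else set(df.gene_id)
    names = {}
    if term_name_path is not None:
        ndf = pd.read_csv(term_name_path, sep="\t", dtype=str, header=None,
                          names=["term_id", "name"], comment="#")
        names = dict(zip(ndf.term_id, ndf.name))
    return AnnotationMap(genes_of_term=genes_of_term, background=bg, term_name=names)


def hypergeometric_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability ``P(X >= k)``.

    ``X`` counts term-carrying genes in a draw of ``n`` from a background of
    ``N`` genes of which ``K`` carry the term.  Evaluated through the
    survival function of :class:`scipy.stats.hypergeom`, which works in log
    space internally, so extreme tails (p ~ 1e-300) remain accurate.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    For sorted p-values ``p_(1) <= ... <= p_(m)`` the adjusted value is
    ``min_{j >= i} p_(j) * m / j``, capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_clusters(
    clusters: ClusterAssignment,
    annotation: AnnotationMap,
    alpha: float = 0.05,
    top_k: int = 10,
    gene_of_probeset=None,
    family: str = "per_cluster",
) -> pd.DataFrame:
    """Hypergeometric term enrichment for every numbered cluster.

    For each cluster, every term annotating at least one cluster gene is
    tested against the background; BH adjustment is applied within the
    cluster's family of tested terms (or globally across all clusters with
    ``family="global"``).  Rows with ``p_adjusted < alpha`` are flagged
    significant and each cluster's report is truncated to its ``top_k``
    rows by adjusted p-value.

    ``gene_of_probeset`` optionally maps cluster node ids (probesets) to
    gene ids; several probesets of one gene count once.  Cluster members
    that do not resolve to a background gene are dropped from ``n``.

    Returns a DataFrame with columns cluster_number, term_id, term_name,
    k, K, n, N, p_value, p_adjusted, significant, sorted by
    (cluster_number, p_adjusted).
    """
    if family not in ("per_cluster", "global"):
        raise ValueError(f"unknown family {family!r}")
    N = len(annotation.background)
    rows = []
    for cluster_number in sorted(clusters.cluster_sizes):
        members = clusters.members(cluster_number)
        if gene_of_probeset is not None:
            genes = {gene_of_probeset.get(p) for p in members} - {None}
        else:
            genes = set(members)
        genes &= annotation.background
        n = len(genes)
        if n == 0:
            continue
        for term in sorted(annotation.genes_of_term):
            term_genes = annotation.genes_of_term[term]
            k = len(genes & term_genes)
            if k == 0:
                continue
            K = len(term_genes)
            rows.append(
                dict(
                    cluster_number=cluster_number,
                    term_id=term,
                    term_name=annotation.term_name.get(term, ""),
                    k=k, K=K, n=n, N=N,
                    p_value=hypergeometric_p(k, K, n, N),
                )
            )
    table = pd.DataFrame(
        rows,
        columns=["cluster_number", "term_id", "term_name",
                 "k", "K", "n", "N", "p_value"],
    )
    if table.empty:
        table["p_adjusted"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
        return table
    if family == "global":
        table["p_adjusted"] = benjamini_hochberg(table.p_value)
    else:
        table["p_adjusted"] = (
            table.groupby("cluster_number", group_keys=False)
            .p_value.apply(lambda p: pd.Series(benjamini_hochberg(p), index=p.index))
        )
    table["significant"] = table.p_adjusted < alpha
    table = (
        table.sort_values(["cluster_number", "p_adjusted", "p_value", "term_id"])
        .groupby("cluster_number", group_keys=False)
        .head(top_k)
        .reset_index(drop=True)
    )
    return table


def write_enrichment_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
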