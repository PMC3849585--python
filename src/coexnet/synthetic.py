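"""Synthetic expression atlases with planted coexpression modules.

The generator emulates the structure of a normalized primary-cell atlas on
the natural (anti-logged) intensity scale: samples are grouped into cell
types with replicates, and each planted module of genes shares a
cell-type-restricted activity profile.  Gene ``g`` of module ``m`` takes
the value

    x[g, s] = scale_g * a_m(celltype(s)) * (1 + eps),   eps ~ N(0, noise_sd),

truncated at zero; replicates of a cell type differ only through the
multiplicative noise ``eps``.  Background genes have a gene-specific scale
and noise but no shared profile, hence no cross-gene correlation.  Activity
levels and gene scales are drawn from a non-negative heavy-tailed marginal
(lognormal by default, gamma optionally), so the data are deliberately
non-normal — the situation in which an empirical (resampling) null for
correlation thresholds differs most from the Gaussian one.

Every draw flows from a single :class:`numpy.random.Generator` seed, so a
fixed seed reproduces the atlas bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from coexnet.enrichment import AnnotationMap
from coexnet.expression import ExpressionMatrix, SampleAnnotation

#: module_of value for genes outside every planted module
BACKGROUND = "BACKGROUND"


@dataclass
class SyntheticTruth:
    """Ground truth of a generated atlas: module memberships and profiles."""

    module_of: dict[str, str]            # probeset id -> module id or BACKGROUND
    module_profiles: dict[str, np.ndarray]  # module id -> activity per cell type
    cell_type_of: dict[str, str]         # sample id -> cell type
    cell_types: list[str]
    gene_symbol_of: dict[str, str] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def module_members(self, module_id: str) -> set:
        return {p for p, m in self.module_of.items() if m == module_id}

    def background_genes(self) -> set:
        return self.module_members(BACKGROUND)

    def to_json(self, path) -> None:
        payload = {
            "module_of": self.module_of,
            "module_profiles": {m: list(map(float, v)) for m, v in self.module_profiles.items()},
            "cell_type_of": self.cell_type_of,
            "cell_types": self.cell_types,
            "gene_symbol_of": self.gene_symbol_of,
            "params": self.params,
        }
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def _draw_positive(rng: np.random.Generator, marginal: str, size, scale: float = 1.0):
    """Non-negative heavy-tailed draws with mean roughly ``scale``."""
    if marginal == "lognormal":
        # sigma=1 lognormal, rescaled to mean ~= scale
        return scale * rng.lognormal(mean=-0.5, sigma=1.0, size=size)
    if marginal == "gamma":
        return rng.gamma(shape=2.0, scale=scale / 2.0, size=size)
    raise ValueError(f"unknown marginal {marginal!r}")


def generate_atlas(
    n_cell_types: int = 10,
    replicates_per_type: int = 4,
    module_sizes: list[int] | None = None,
    n_background: int = 500,
    noise_sd: float = 0.1,
    marginal: str = "lognormal",
    seed: int = 0,
    baseline_activity: float = 1.0,
    active_fold: float = 8.0,
    gene_scale: float = 100.0,
) -> tuple[ExpressionMatrix, list[SampleAnnotation], SyntheticTruth]:
    """Generate a synthetic atlas with planted coexpression modules.

    Parameters
    ----------
    n_cell_types, replicates_per_type
        Sample layout: ``n_cell_types * replicates_per_type`` columns.  Each
        cell type is treated as one data series (one contributing study).
    module_sizes
        Genes per planted module (default ``[50] * 5``).
    n_background
        Genes with no shared profile (uncorrelated with everything).
    noise_sd
        Standard deviation of the multiplicative noise; 0.1 corresponds to a
        10% coefficient of variation, typical of replicate arrays.
    marginal
        ``lognormal`` (default) or ``gamma``: the non-negative distribution
        of activity levels and gene scales.
    baseline_activity, active_fold
        A module's activity is ``baseline_activity`` in inactive cell types
        and a draw with mean ``active_fold`` x baseline in its active types.
        Modules receive distinct active-type subsets, so planted modules are
        identifiable from expression alone.
    gene_scale
        Mean gene-specific intensity scale (arbitrary units of a normalized
        array).

    Returns ``(matrix, annotations, truth)``; deterministic for fixed seed.
    """
    module_sizes = [50] * 5 if module_sizes is None else list(module_sizes)
    if n_cell_types < 1 or replicates_per_type < 1:
        raise ValueError("cell type and replicate counts must be >= 1")
    if any(s < 1 for s in module_sizes):
        raise ValueError("module sizes must be >= 1")
    if n_background < 0:
        raise ValueError("n_background must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    n_modules = len(module_sizes)
    if n_modules > 0 and 2 ** n_cell_types - 1 < n_modules:
        raise ValueError("too few cell types to give every module a distinct active subset")

    rng = np.random.default_rng(seed)
    cell_types = [f"CT{t + 1:02d}" for t in range(n_cell_types)]
    sample_ids, annotations = [], []
    for t, ct in enumerate(cell_types):
        for rep in range(1, replicates_per_type + 1):
            sid = f"{ct}_r{rep}"
            sample_ids.append(sid)
            annotations.append(
                SampleAnnotation(
                    sample_id=sid,
                    series_id=f"SYN{t + 1:03d}",
                    cell_class=ct,
                    chip_description="synthetic array",
                    replicate_no=rep,
                )
            )
    type_of_sample = np.repeat(np.arange(n_cell_types), replicates_per_type)

    # Modules are planted as identifiable ground truth: a candidate activity
    # profile is redrawn if it correlates too strongly (r >= 0.6, over cell
    # types) with an already-planted module, since two modules with nearly
    # collinear profiles would be a single coexpression module in truth.
    module_ids = [f"M{m + 1}" for m in range(n_modules)]
    module_profiles: dict[str, np.ndarray] = {}
    seen: set[frozenset] = set()
    accepted: list[np.ndarray] = []
    max_active = max(1, n_cell_types // 3)
    for mid in module_ids:
        for _attempt in range(1000):
            k = int(rng.integers(1, max_active + 1))
            subset = frozenset(rng.choice(n_cell_types, size=k, replace=False).tolist())
            active = np.fromiter(subset, dtype=int)
            profile = np.full(n_cell_types, baseline_activity)
            profile[active] = baseline_activity * active_fold * _draw_positive(
                rng, marginal, size=active.size
            ).clip(min=0.25)  # keep active types clearly above baseline
            if subset in seen:
                continue
            if accepted and max(
                float(np.corrcoef(profile, p)[0, 1]) for p in accepted
            ) >= 0.6:
                continue
            seen.add(subset)
            accepted.append(profile)
            module_profiles[mid] = profile
            break
        else:
            raise ValueError(
                "could not plant identifiable module profiles; "
                "increase n_cell_types or reduce the number of modules"
            )

    probeset_ids: list[str] = []
    gene_symbols: list[str] = []
    module_of: dict[str, str] = {}
    rows: list[np.ndarray] = []
    n_samples = len(sample_ids)
    counter = 100000
    for mid, size in zip(module_ids, module_sizes):
        activity = module_profiles[mid][type_of_sample]
        for g in range(size):
            counter += 1
            pid = f"{counter}_at"
            sym = f"{mid}G{g + 1:03d}"
            scale = float(_draw_positive(rng, marginal, size=None, scale=gene_scale))
            eps = rng.normal(0.0, noise_sd, size=n_samples) if noise_sd > 0 else 0.0
            rows.append(np.clip(scale * activity * (1.0 + eps), 0.0, None))
            probeset_ids.append(pid)
            gene_symbols.append(sym)
            module_of[pid] = mid
    for g in range(n_background):
        counter += 1
        pid = f"{counter}_at"
        sym = f"BGG{g + 1:04d}"
        scale = float(_draw_positive(rng, marginal, size=None, scale=gene_scale))
        eps = rng.normal(0.0, noise_sd, size=n_samples) if noise_sd > 0 else 0.0
        rows.append(np.clip(scale * (1.0 + eps) * np.ones(n_samples), 0.0, None))
        probeset_ids.append(pid)
        gene_symbols.append(sym)
        module_of[pid] = BACKGROUND

    matrix = ExpressionMatrix(
        probeset_ids=probeset_ids,
        gene_symbols=gene_symbols,
        values=np.vstack(rows),
        sample_ids=sample_ids,
    )
    truth = SyntheticTruth(
        module_of=module_of,
        module_profiles=module_profiles,
        cell_type_of={a.sample_id: a.cell_class for a in annotations},
        cell_types=cell_types,
        gene_symbol_of=dict(zip(probeset_ids, gene_symbols)),
        params=dict(
            n_cell_types=n_cell_types,
            replicates_per_type=replicates_per_type,
            module_sizes=module_sizes,
            n_background=n_background,
            noise_sd=noise_sd,
            marginal=marginal,
            seed=seed,
        ),
    )
    return matrix, annotations, truth


def generate_term_annotation(
    truth: SyntheticTruth,
    background_term_rate: float = 0.0,
    seed: int = 0,
    n_background_terms: int = 20,
) -> AnnotationMap:
    """Ground-truth term annotation for end-to-end enrichment tests.

    One term per planted module covers exactly that module's genes.  In
    addition, ``n_background_terms`` random terms each include every gene
    independently with probability ``background_term_rate`` (rate 0: no
    background terms; rate 1: background terms cover all genes, which makes
    their enrichment p-values exactly 1).  Gene ids are the synthetic gene
    symbols; the background is the full gene universe of the atlas.
    """
    if not 0.0 <= background_term_rate <= 1.0:
        raise ValueError("background_term_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    all_genes = sorted(truth.gene_symbol_of.values())
    genes_of_term: dict[str, set] = {}
    names: dict[str, str] = {}
    for mid in sorted(truth.module_profiles):
        members = {truth.gene_symbol_of[p] for p in truth.module_members(mid)}
        if members:
            term = f"MOD_{mid}"
            genes_of_term[term] = members
            names[term] = f"planted module {mid}"
    for t in range(n_background_terms):
        if background_term_rate == 0.0:
            break
        mask = rng.random(len(all_genes)) < background_term_rate
        members = {g for g, keep in zip(all_genes, mask) if keep}
        if members:
            term = f"RND_{t + 1:02d}"
            genes_of_term[term] = members
            names[term] = f"random background term {t + 1}"
    return AnnotationMap(
        genes_of_term=genes_of_term,
        background=set(all_genes),
        term_name=names,
    )
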