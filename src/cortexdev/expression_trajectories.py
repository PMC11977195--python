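"""Per-gene age-trajectory analysis of bulk cortical expression data.

Workflow mirrored by the pipeline: fit penalized-spline age models to every
gene (dialect-aware covariates), select age-genes by Benjamini-Hochberg FDR
on the smooth-term p-values, summarize fitted curves per cell type, locate
peak growth (maximum of the first derivative) and the
astrocyte-to-oligodendrocyte crossover age per region, and test gene-set
enrichment of the age-genes with one-sided Fisher exact tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cortexdev.pspline import AgeSplineModel, SplineFit
from cortexdev.synthetic_data import CELL_TYPES, ExpressionDataset, GeneCatalog

__all__ = [
    "AgeGeneResult",
    "CellTypeTrajectory",
    "CrossoverResult",
    "EnrichmentResult",
    "fit_age_spline",
    "fit_all_genes",
    "select_age_genes",
    "replication_overlap",
    "celltype_trajectory",
    "peak_growth_age",
    "expression_ratio_crossover",
    "enrichment_test",
    "stage_gene_counts",
    "DEFAULT_STAGE_WINDOWS",
]

#: Postnatal developmental stage windows (years); configurable.
DEFAULT_STAGE_WINDOWS: dict[str, tuple[float, float]] = {
    "infancy": (0.0, 1.0),
    "childhood": (1.0, 12.0),
    "adolescence": (12.0, 20.0),
    "young_adulthood": (20.0, 40.0),
}


@dataclass(frozen=True)
class AgeGeneResult:
    gene: str
    p: float
    q: float
    selected: bool


@dataclass(frozen=True)
class CellTypeTrajectory:
    cell_type: str
    region: str  # region label or "pooled"
    age_grid: np.ndarray
    mean_curve: np.ndarray
    norm_curve: np.ndarray  # per-gene normalized (z or demeaned) then averaged
    band_low: np.ndarray
    band_high: np.ndarray
    mean_derivative: np.ndarray
    n_genes: int


@dataclass(frozen=True)
class CrossoverResult:
    region: str
    age: float | None  # first age where oligo first exceeds astro; None if no crossing


@dataclass(frozen=True)
class EnrichmentResult:
    gene_set: str
    a: int  # query & set
    b: int  # query only
    c: int  # set only
    d: int  # neither
    odds_ratio: float
    p: float
    q: float
    flagged: bool  # q < 0.001


# ---------------------------------------------------------------------------
# spline fitting


def _model_for(dataset: ExpressionDataset, k: int = 5, **kwargs) -> AgeSplineModel:
    """Dialect-appropriate design: bare smooth for the normalized dialect,
    region-wise smooths + RIN + sex + donor random effect for log2RPKM."""
    if len(dataset.samples) < k + 2:
        raise ValueError(f"need at least k+2 = {k + 2} samples, got {len(dataset.samples)}")
    if dataset.scale == "normalized":
        return AgeSplineModel(dataset.samples, k=k, **kwargs)
    multi = dataset.samples["region"].nunique() > 1
    # REML for the dialect with a donor random effect: GCV systematically
    # under-shrinks the ridge block (donor indicators absorb the donor-level
    # age trend), REML recovers the variance components
    kwargs.setdefault("method", "reml")
    return AgeSplineModel(
        dataset.samples, k=k, covariates=("RIN", "sex"),
        by_region=multi, donor_re=True, **kwargs,
    )


def fit_all_genes(dataset: ExpressionDataset, k: int = 5, **kwargs) -> dict[str, SplineFit]:
    """Fit the penalized-spline age model to every gene (shared design)."""
    model = _model_for(dataset, k=k, **kwargs)
    fits = model.fit_matrix(dataset.expression.T)
    return {f.name: f for f in fits}


def fit_age_spline(dataset: ExpressionDataset, gene: str, k: int = 5, **kwargs) -> SplineFit:
    """Fit one gene's age trajectory (same design rules as :func:`fit_all_genes`)."""
    if gene not in dataset.expression.index:
        raise KeyError(gene)
    model = _model_for(dataset, k=k, **kwargs)
    return model.fit(dataset.expression.loc[gene].to_numpy(), name=gene)


# ---------------------------------------------------------------------------
# age-gene selection and replication


def select_age_genes(fits: Mapping[str, SplineFit], alpha: float = 0.05) -> list[AgeGeneResult]:
    """Benjamini-Hochberg step-up over the smooth-term p-values; q < alpha selects."""
    if not fits:
        raise ValueError("no fits supplied")
    genes = list(fits)
    p = np.array([fits[g].p_smooth for g in genes])
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return [
        AgeGeneResult(gene=g, p=float(pi), q=float(qi), selected=bool(qi < alpha))
        for g, pi, qi in zip(genes, p, q)
    ]


def replication_overlap(discovery: set[str], validation: set[str]) -> tuple[int, float]:
    """Count and proportion of discovery genes replicated in validation.

    Proportion is count/|discovery| rounded to 3 significant figures.
    """
    if not discovery:
        raise ValueError("empty discovery set")
    count = len(set(discovery) & set(validation))
    prop = count / len(discovery)
    if prop > 0:
        from math import floor, log10

        ndigits = 2 - floor(log10(abs(prop)))
        prop = round(prop, ndigits)
    return count, prop


# ---------------------------------------------------------------------------
# cell-type trajectory summaries


def celltype_trajectory(
    fits: Mapping[str, SplineFit],
    catalog: GeneCatalog,
    cell_type: str,
    region: str = "pooled",
    normalize: str | bool = "zscore",
) -> CellTypeTrajectory:
    """Average fitted gene curves of one cell type on the common age grid.

    ``normalize``: "zscore" z-scores each gene's curve over the grid before
    averaging, "demean" only centers it, False averages raw curves. Constant
    curves normalize to identically zero. The 95% band is
    mean +- 1.96 * SE across genes.
    """
    if cell_type not in CELL_TYPES:
        raise ValueError(f"unknown cell type: {cell_type!r}")
    symbols = [
        s for s in catalog.genes.loc[catalog.genes["cell_type"] == cell_type, "symbol"]
        if s in fits
    ]
    if not symbols:
        raise ValueError(f"no fitted genes of cell type {cell_type!r}")
    f0 = fits[symbols[0]]
    if region not in f0.curves:
        raise ValueError(f"region {region!r} not present in fits (have {list(f0.curves)})")
    grid = f0.age_grid
    raw = np.vstack([fits[s].curves[region] for s in symbols])
    der = np.vstack([fits[s].derivatives[region] for s in symbols])
    if normalize in ("zscore", True):
        mu = raw.mean(axis=1, keepdims=True)
        sd = raw.std(axis=1, ddof=1, keepdims=True)
        norm = np.where(sd > 1e-12, (raw - mu) / np.where(sd > 1e-12, sd, 1.0), 0.0)
    elif normalize == "demean":
        norm = raw - raw.mean(axis=1, keepdims=True)
    elif normalize is False:
        norm = raw
    else:
        raise ValueError(f"normalize must be 'zscore', 'demean' or False: {normalize!r}")
    mean_curve = raw.mean(axis=0)
    norm_curve = norm.mean(axis=0)
    se = norm.std(axis=0, ddof=1) / np.sqrt(len(symbols)) if len(symbols) > 1 else np.zeros_like(norm_curve)
    return CellTypeTrajectory(
        cell_type=cell_type, region=region, age_grid=grid,
        mean_curve=mean_curve, norm_curve=norm_curve,
        band_low=norm_curve - 1.96 * se, band_high=norm_curve + 1.96 * se,
        mean_derivative=der.mean(axis=0), n_genes=len(symbols),
    )


def peak_growth_age(traj: CellTypeTrajectory, flat_tol: float = 1e-8) -> tuple[float | None, bool]:
    """Age of the global maximum of the mean first derivative.

    Returns (age, censored): ``censored`` is True when the maximum sits on a
    grid boundary (the true peak may lie outside the observed range). Ties
    break to the earliest age; an everywhere-flat derivative returns
    (None, False).
    """
    d = traj.mean_derivative
    if np.max(np.abs(d)) < flat_tol:
        return None, False
    i = int(np.argmax(d))  # argmax takes the first (earliest) maximum
    censored = i == 0 or i == len(d) - 1
    return float(traj.age_grid[i]), censored


def expression_ratio_crossover(
    traj_oligo: CellTypeTrajectory, traj_astro: CellTypeTrajectory, use_norm: bool = False
) -> CrossoverResult:
    """First age where the oligodendrocyte mean curve rises above the astrocyte one.

    Scans the shared grid for a negative-to-positive sign change of
    (oligo - astro) and refines the root by linear interpolation between the
    bracketing grid points. Never extrapolates: no sign change means None.
    """
    if traj_oligo.region != traj_astro.region:
        raise ValueError("trajectories are from different regions")
    if len(traj_oligo.age_grid) != len(traj_astro.age_grid) or not np.allclose(
        traj_oligo.age_grid, traj_astro.age_grid
    ):
        raise ValueError("trajectories are on mismatched age grids")
    a = traj_oligo.norm_curve if use_norm else traj_oligo.mean_curve
    b = traj_astro.norm_curve if use_norm else traj_astro.mean_curve
    diff = a - b
    grid = traj_oligo.age_grid
    if diff[0] > 0:
        # already above at the grid start: not a rise-above event within range
        below = np.where(diff < 0)[0]
        if below.size == 0:
            return CrossoverResult(region=traj_oligo.region, age=None)
        start = below[0]
    else:
        start = 0
    for i in range(start, len(diff) - 1):
        if diff[i] < 0 <= diff[i + 1]:
            if diff[i + 1] == diff[i]:
                age = grid[i]
            else:
                frac = -diff[i] / (diff[i + 1] - diff[i])
                age = grid[i] + frac * (grid[i + 1] - grid[i])
            return CrossoverResult(region=traj_oligo.region, age=float(age))
    return CrossoverResult(region=traj_oligo.region, age=None)


# ---------------------------------------------------------------------------
# enrichment and stage overlap


def enrichment_test(
    query: set[str],
    annotation: Mapping[str, Sequence[str]],
    background: set[str],
    flag_alpha: float = 0.001,
) -> list[EnrichmentResult]:
    """One-sided Fisher exact enrichment of ``query`` in each annotation set.

    2x2 table per set over the background universe; BH correction across all
    sets tested; sets with q < ``flag_alpha`` are flagged.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background universe")
    query = set(query)
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    names, tables = [], []
    for name, genes in annotation.items():
        gset = set(genes)
        if not gset <= background:
            raise ValueError(f"annotation set {name!r} not a subset of the background")
        a = len(query & gset)
        b = len(query - gset)
        c = len(gset - query)
        d = len(background) - a - b - c
        names.append(name)
        tables.append((a, b, c, d))
    pvals = np.array(
        [stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1] for a, b, c, d in tables]
    )
    _, q, _, _ = multipletests(pvals, method="fdr_bh")
    out = []
    for name, (a, b, c, d), p, qi in zip(names, tables, pvals, q):
        odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else 0.0
        out.append(
            EnrichmentResult(
                gene_set=name, a=a, b=b, c=c, d=d, odds_ratio=float(odds),
                p=float(p), q=float(qi), flagged=bool(qi < flag_alpha),
            )
        )
    return out


def stage_gene_counts(
    age_genes: Sequence[str],
    catalog: GeneCatalog,
    fits: Mapping[str, SplineFit],
    stage_windows: Mapping[str, tuple[float, float]] = DEFAULT_STAGE_WINDOWS,
    region: str = "pooled",
    activity_threshold: float = 0.02,
) -> pd.DataFrame:
    """Per-stage, per-cell-type counts and proportions of active age-genes.

    A gene overlaps a stage when |d expression / d age| exceeds
    ``activity_threshold`` (expression units per year) anywhere inside the
    stage window. Windows must be disjoint. Proportions are within-stage
    across cell types (0 where the stage is empty).
    """
    wins = sorted(stage_windows.items(), key=lambda kv: kv[1][0])
    for (_, (a1, b1)), (_, (a2, _)) in zip(wins[:-1], wins[1:]):
        if a2 < b1 - 1e-12:
            raise ValueError("stage windows overlap")
    ct_of = dict(zip(catalog.genes["symbol"], catalog.genes["cell_type"]))
    rows = []
    for stage, (lo, hi) in wins:
        counts = {ct: 0 for ct in CELL_TYPES}
        for g in age_genes:
            fit = fits[g]
            mask = (fit.age_grid >= lo) & (fit.age_grid < hi)
            if not mask.any():
                continue
            if np.max(np.abs(fit.derivatives[region][mask])) > activity_threshold:
                counts[ct_of.get(g, "unknown")] = counts.get(ct_of.get(g, "unknown"), 0) + 1
        total = sum(counts.values())
        for ct, cnt in counts.items():
            rows.append(
                {"stage": stage, "cell_type": ct, "count": cnt,
                 "proportion": (cnt / total if total else 0.0)}
            )
    return pd.DataFrame(rows)
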