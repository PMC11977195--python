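"""Voxel-composition simulation of the MR apparent soma radius.

A grey-matter voxel is modelled as a mixture of cell populations (microglia,
astrocytes, oligodendrocytes, neurons, endothelial cells), each with a count
density (cells per mm^3) and a Gaussian cell-body radius distribution. The
MR-visible effective radius of such a mixture is moment-weighted: for a
radius distribution R,

    r_app = sqrt( E[R^5] / E[R^3] ),

so large cells dominate the estimate far beyond their number share. Counts
evolve with age through per-type fractional slopes (linearly from a
reference age by default, exponentially via ``coupling="exponential"``),
emulating expression-slope-coupled composition change; sweeping age and
recomputing r_app yields the developmental trend of the apparent soma
radius. A Monte-Carlo estimator (count-weighted radius sampling, rejection
resampling to keep radii positive) is paired with a closed-form Gaussian
raw-moment oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellPopulation",
    "ApparentRadiusResult",
    "default_populations",
    "sample_radii",
    "sample_voxel_radii",
    "apparent_radius",
    "analytic_apparent_radius",
    "counts_at_age",
    "age_sweep",
    "DEFAULT_SLOPES",
]


@dataclass(frozen=True)
class CellPopulation:
    name: str
    count: float  # cells per mm^3
    radius_mean: float  # um
    radius_sd: float  # um

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"{self.name}: count must be >= 0")
        if self.radius_mean <= 0:
            raise ValueError(f"{self.name}: radius_mean must be > 0")
        if self.radius_sd < 0:
            raise ValueError(f"{self.name}: radius_sd must be >= 0")


@dataclass(frozen=True)
class ApparentRadiusResult:
    r_app: float  # um
    mc_se: float  # um (0 for the analytic method)
    n_samples: int
    method: Literal["monte_carlo", "analytic"]

    def __post_init__(self) -> None:
        if self.r_app <= 0:
            raise ValueError("apparent radius must be positive")


def default_populations() -> list[CellPopulation]:
    """Baseline human grey-matter voxel composition.

    Literature cell densities per mm^3 (endothelial = 0.35 x neurons) and
    Gaussian radius parameters per cell class.
    """
    n_neuro = 92_000.0
    return [
        CellPopulation("microglia", 6_500.0, 2.0, 0.5),
        CellPopulation("astrocyte", 15_700.0, 5.5, 1.5),
        CellPopulation("oligodendrocyte", 12_500.0, 5.5, 1.5),
        CellPopulation("neuron", n_neuro, 8.0, 2.0),
        CellPopulation("endothelial", 0.35 * n_neuro, 9.0, 0.5),
    ]


#: Default fractional count slopes (1/year) used by the pipeline's age sweep:
#: oligodendrocyte-dominant increase with astrocyte/microglia/endothelial
#: decline and fixed neurons, the qualitative pattern implied by the
#: cell-type expression trajectories. Magnitudes are a calibration choice
#: (config-exposed); see docs/methods.md.
DEFAULT_SLOPES: dict[str, float] = {
    "microglia": -0.005,
    "astrocyte": -0.010,
    "oligodendrocyte": 0.020,
    "neuron": 0.0,
    "endothelial": -0.005,
}


def sample_radii(pop: CellPopulation, n: int, rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Draw ``n`` radii from the population's Gaussian, rejecting non-positive draws.

    Rejection (rather than clipping) keeps the stated mean/SD essentially
    intact at the small sigma/mu ratios used here.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if pop.radius_sd == 0:
        return np.full(n, pop.radius_mean)
    out = rng.normal(pop.radius_mean, pop.radius_sd, size=n)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(pop.radius_mean, pop.radius_sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def sample_voxel_radii(
    pops: Sequence[CellPopulation], n_total: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Count-weighted concatenated radius sample across populations."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    total = sum(p.count for p in pops)
    if total <= 0:
        raise ValueError("total cell count must be > 0")
    chunks = []
    for p in pops:
        n_p = int(round(n_total * p.count / total))
        if n_p > 0:
            chunks.append(sample_radii(p, n_p, rng))
    return np.concatenate(chunks)


def apparent_radius(
    radii: np.ndarray, se_method: Literal["delta", "bootstrap"] = "delta",
    n_boot: int = 200, rng: np.random.Generator | int | None = None,
) -> ApparentRadiusResult:
    """Moment-based apparent radius sqrt(mean(r^5)/mean(r^3)) of a radius sample.

    The Monte-Carlo standard error comes from the delta method on the joint
    sampling variance of (mean r^3, mean r^5), or from a bootstrap.
    """
    r = np.asarray(radii, dtype=float)
    if r.size == 0:
        raise ValueError("empty radius sample")
    if (r <= 0).any():
        raise ValueError("all radii must be positive")
    r3, r5 = r**3, r**5
    m3, m5 = r3.mean(), r5.mean()
    r_app = float(np.sqrt(m5 / m3))
    n = r.size
    if se_method == "delta":
        cov = np.cov(np.vstack([r5, r3])) / n if n > 1 else np.zeros((2, 2))
        g = np.array([1.0 / (2.0 * r_app * m3), -r_app / (2.0 * m3)])
        var = float(g @ cov @ g)
        se = float(np.sqrt(max(var, 0.0)))
    elif se_method == "bootstrap":
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        reps = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.integers(0, n, size=n)
            reps[i] = np.sqrt(r5[idx].mean() / r3[idx].mean())
        se = float(reps.std(ddof=1))
    else:
        raise ValueError(f"unknown se_method: {se_method!r}")
    return ApparentRadiusResult(r_app=r_app, mc_se=se, n_samples=n, method="monte_carlo")


def analytic_apparent_radius(pops: Sequence[CellPopulation]) -> ApparentRadiusResult:
    """Closed-form apparent radius from Gaussian raw moments.

    Uses E[R^3] = mu^3 + 3 mu sigma^2 and
    E[R^5] = mu^5 + 10 mu^3 sigma^2 + 15 mu sigma^4, count-weighted across
    populations. The truncation applied by rejection sampling is ignored;
    a warning is emitted when sigma/mu > 0.4, where that approximation
    starts to matter.
    """
    total = sum(p.count for p in pops)
    if total <= 0:
        raise ValueError("total cell count must be > 0")
    num = den = 0.0
    for p in pops:
        if p.count == 0:
            continue
        if p.radius_sd / p.radius_mean > 0.4:
            warnings.warn(
                f"{p.name}: sigma/mu = {p.radius_sd / p.radius_mean:.2f} > 0.4; "
                "Gaussian-moment formula ignores positivity truncation",
                stacklevel=2,
            )
        mu, s2 = p.radius_mean, p.radius_sd**2
        e3 = mu**3 + 3.0 * mu * s2
        e5 = mu**5 + 10.0 * mu**3 * s2 + 15.0 * mu * s2**2
        num += p.count * e5
        den += p.count * e3
    return ApparentRadiusResult(
        r_app=float(np.sqrt(num / den)), mc_se=0.0, n_samples=0, method="analytic"
    )


def counts_at_age(
    pops: Sequence[CellPopulation],
    slopes: Mapping[str, float],
    age: float,
    ref_age: float = 8.0,
    coupling: Literal["linear", "exponential"] = "linear",
) -> list[CellPopulation]:
    """Cell counts evolved to ``age`` via per-type fractional slopes.

    linear: N(age) = N(ref) * (1 + s * (age - ref));
    exponential: N(age) = N(ref) * exp(s * (age - ref)).
    Radius distributions are never altered. Raises when any count would go
    negative.
    """
    out = []
    dt = age - ref_age
    for p in pops:
        s = slopes.get(p.name, 0.0)
        factor = float(np.exp(s * dt)) if coupling == "exponential" else 1.0 + s * dt
        if factor < 0:
            raise ValueError(f"negative count for {p.name!r} at age {age:g} (slope {s:g}/y)")
        out.append(replace(p, count=p.count * factor))
    return out


def age_sweep(
    pops: Sequence[CellPopulation],
    slopes: Mapping[str, float],
    ages: Sequence[float],
    n_samples: int = 100_000,
    seed: int | None = 0,
    ref_age: float = 8.0,
    coupling: Literal["linear", "exponential"] = "linear",
) -> tuple[pd.DataFrame, float]:
    """Monte-Carlo + analytic apparent radius across an age sweep.

    Returns (table, percent_change) where the table has one row per age with
    r_app (Monte-Carlo), mc_se, r_app_analytic, and percent_change is
    100 * (r_last - r_first) / r_first on the Monte-Carlo column. Each age
    re-seeds its sampler from the common seed so the sweep is reproducible
    age-by-age.
    """
    ages = list(ages)
    if len(ages) < 2:
        raise ValueError("need at least 2 ages")
    if any(b <= a for a, b in zip(ages[:-1], ages[1:])):
        raise ValueError("ages must be sorted ascending")
    rows = []
    for i, age in enumerate(ages):
        at_age = counts_at_age(pops, slopes, age, ref_age=ref_age, coupling=coupling)
        rng = np.random.default_rng(None if seed is None else np.random.SeedSequence(seed, spawn_key=(4, i)))
        mc = apparent_radius(sample_voxel_radii(at_age, n_samples, rng))
        an = analytic_apparent_radius(at_age)
        rows.append(
            {"age": age, "r_app": mc.r_app, "mc_se": mc.mc_se,
             "r_app_analytic": an.r_app, "n_samples": mc.n_samples}
        )
    table = pd.DataFrame(rows)
    pct = 100.0 * (table["r_app"].iloc[-1] - table["r_app"].iloc[0]) / table["r_app"].iloc[0]
    return table, float(pct)
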