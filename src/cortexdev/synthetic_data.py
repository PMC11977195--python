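"""Synthetic inputs for the developmental-cortex pipeline.

Three generators emulate the statistical structure of the study designs the
downstream analyses assume, so the whole pipeline is testable without any
external download:

``generate_cohort``
    A cross-sectional imaging cohort (default n=88, ages 8-19 y, 42/88 male)
    with per-network microstructure and morphology metrics. Each metric is
    driven by a standardized linear effect model so that the standardized age
    coefficient and the model R-squared recovered downstream converge to the
    values configured in :data:`default_effect_specs`.

``generate_repeatability``
    A subjects-by-sessions test-retest table (default 6 subjects, 5 sessions)
    from an additive two-way random-effects model, with a closed-form implied
    ICC of sigma_s^2 / (sigma_s^2 + sigma_sess^2 + sigma_e^2).

``generate_expression``
    Bulk cortical gene-expression datasets in two dialects: a single-region
    normalized (per-gene z-scored) dialect and a multi-region log2-RPKM
    dialect with donor effects, sex and RNA-integrity (RIN) covariates and
    region-specific developmental timing offsets ordered along the
    sensorimotor-to-association (S-A) axis.

All randomness flows from one integer seed through named
``numpy.random.SeedSequence`` sub-streams, so identical specs give
byte-identical tables and the generators stay decoupled from one another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Sequence

import numpy as np
import pandas as pd

YEO7_NETWORKS: tuple[str, ...] = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default_mode",
)

#: The 11 cortical regions of the multi-region expression dialect.
CORTICAL_REGIONS: tuple[str, ...] = (
    "A1C", "DLPFC", "IPC", "ITC", "M1", "MFC", "OFC", "S1", "STC", "V1", "VLPFC",
)

#: Regional developmental-timing offsets (years) along the S-A axis:
#: primary motor/visual earliest, medial frontal latest.
SA_AXIS_OFFSETS: dict[str, float] = {
    "M1": 0.0, "V1": 0.0, "S1": 1.0, "A1C": 1.5, "IPC": 3.0, "STC": 3.5,
    "ITC": 4.0, "OFC": 5.0, "VLPFC": 5.0, "DLPFC": 5.5, "MFC": 6.0,
}

CELL_TYPES: tuple[str, ...] = (
    "excitatory", "inhibitory", "oligodendrocyte", "OPC",
    "astrocyte", "microglia", "endothelial",
)

# Puberty-score calibration: pds = clip(round(a + b*age + eps), 1, 5) with the
# linear ramp spanning stages 1..5 over the age range. eps SD 0.67 was
# calibrated once (offline, 2000 simulated cohorts) so that a linear fit of
# pds on age over uniform ages attains R^2 ~= 0.72.
_PDS_NOISE_SD = 0.67


class ParameterizationError(ValueError):
    """Raised when an effect specification is internally inconsistent."""


@dataclass(frozen=True)
class EffectSpec:
    """Standardized generative effect for one network-metric pair.

    ``beta_age`` is the standardized age slope the downstream model should
    recover; ``r2_target`` the expected adjusted R-squared of the fitted
    model. With age as the only signal predictor the two are coupled
    (R^2 = beta^2), which the consistency check below enforces up to a 0.05
    tolerance.
    """

    network: str
    metric: str
    beta_age: float
    beta_sex: float = 0.0
    r2_target: float = 0.0
    baseline_mean: float = 0.0
    baseline_sd: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2_target < 1.0):
            raise ParameterizationError(f"r2_target must be in [0,1): {self.r2_target}")
        if abs(self.beta_age) > 1.0:
            raise ParameterizationError(f"|beta_age| > 1 implies R^2 > 1: {self.beta_age}")
        if self.beta_sex == 0.0 and self.beta_age**2 > self.r2_target + 0.05:
            raise ParameterizationError(
                f"beta_age^2 = {self.beta_age ** 2:.3f} exceeds r2_target + 0.05 "
                f"for {self.metric}/{self.network}"
            )
        if self.baseline_sd < 0:
            raise ParameterizationError("baseline_sd must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    n_subjects: int = 88
    age_range: tuple[float, float] = (8.0, 19.0)
    male_fraction: float = 42 / 88
    effects: tuple[EffectSpec, ...] = ()
    networks: tuple[str, ...] = YEO7_NETWORKS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must satisfy min < max")
        if not (0.0 <= self.male_fraction <= 1.0):
            raise ValueError("male_fraction must be in [0,1]")


@dataclass(frozen=True)
class RepeatabilitySpec:
    n_subjects: int = 6
    n_sessions: int = 5
    sigma_subject: float = 1.0
    sigma_session: float = 0.1
    sigma_error: float = 0.1
    metric: str = "f_neurite"
    mean: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_subject, self.sigma_session, self.sigma_error) < 0:
            raise ValueError("all SD components must be >= 0")
        if self.n_subjects < 2 or self.n_sessions < 2:
            raise ValueError("ICC is undefined for fewer than 2 subjects or 2 sessions")

    @property
    def implied_icc(self) -> float:
        """Closed-form ICC implied by the variance components."""
        num = self.sigma_subject**2
        den = num + self.sigma_session**2 + self.sigma_error**2
        return num / den if den > 0 else float("nan")


@dataclass(frozen=True)
class GeneCatalog:
    """Per-gene cell-type assignment and generative trajectory parameters.

    ``genes`` holds one row per gene: symbol, cell_type, shape
    (logistic_rise | exponential_decay | flat), midpoint_age (y), rate (1/y),
    amplitude and baseline (expression units). ``offsets`` is a gene-by-region
    table of regional timing offsets (years).
    """

    genes: pd.DataFrame
    offsets: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"symbol", "cell_type", "shape", "midpoint_age", "rate", "amplitude", "baseline"}
        missing = required - set(self.genes.columns)
        if missing:
            raise ValueError(f"catalog missing columns: {sorted(missing)}")
        bad = set(self.genes["cell_type"]) - set(CELL_TYPES)
        if bad:
            raise ValueError(f"unknown cell types: {sorted(bad)}")
        if not self.genes["symbol"].is_unique:
            raise ValueError("gene symbols must be unique (one cell type per gene)")
        if not (self.offsets.index == self.genes["symbol"]).all():
            raise ValueError("offsets index must match catalog gene symbols")

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.offsets.columns)

    def gene_sets(self) -> dict[str, list[str]]:
        """Cell-type gene sets, GMT-ready."""
        return {
            ct: list(self.genes.loc[self.genes["cell_type"] == ct, "symbol"])
            for ct in CELL_TYPES
            if (self.genes["cell_type"] == ct).any()
        }

    def curve(self, symbol: str, ages: np.ndarray, region: str | None = None) -> np.ndarray:
        """Noise-free generating trajectory of one gene (oracle for tests)."""
        row = self.genes.set_index("symbol").loc[symbol]
        offset = 0.0 if region is None else float(self.offsets.loc[symbol, region])
        return _shape_value(
            np.asarray(ages, dtype=float) - offset,
            row["shape"], row["midpoint_age"], row["rate"], row["amplitude"], row["baseline"],
        )


@dataclass(frozen=True)
class ExpressionCohortSpec:
    dialect: Literal["single_region_normalized", "multi_region_rpkm"] = "multi_region_rpkm"
    n_samples: int = 214
    n_donors: int = 20
    regions: tuple[str, ...] = CORTICAL_REGIONS
    age_range: tuple[float, float] = (0.5, 40.0)
    rin_mean: float = 8.45
    rin_sd: float = 0.79
    rin_coef: float = 0.10
    donor_sd: float = 0.20
    male_fraction: float = 0.5
    catalog: GeneCatalog | None = None
    noise_sd: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dialect not in ("single_region_normalized", "multi_region_rpkm"):
            raise ValueError(f"unknown dialect: {self.dialect}")
        if self.dialect == "multi_region_rpkm" and self.n_donors < 2:
            raise ValueError("multi-region dialect needs >= 2 donors for donor effects")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must satisfy min < max")


@dataclass(frozen=True)
class ExpressionDataset:
    """Gene-by-sample expression matrix plus sample metadata and a scale tag."""

    expression: pd.DataFrame  # genes x samples
    samples: pd.DataFrame  # index sample_id; columns age, region, donor, sex, RIN
    scale: Literal["normalized", "log2RPKM"]

    def __post_init__(self) -> None:
        if not (self.expression.columns == self.samples.index).all():
            raise ValueError("expression columns must match sample metadata index")


# ---------------------------------------------------------------------------
# imaging cohort


def _standardized_signal(
    spec: EffectSpec, z_age: np.ndarray, sex_code: np.ndarray,
    male_fraction: float, rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance latent outcome carrying the configured effects.

    Noise variance is chosen from r2_target so the population R-squared of
    the (age, sex) model equals r2_target; the outcome is then scaled to unit
    variance so the standardized age slope equals beta_age whenever
    r2_target = beta_age^2 + beta_sex^2 * Var(sex_code).
    """
    var_sex = male_fraction * (1.0 - male_fraction)  # sex_code = +-0.5
    signal_var = spec.beta_age**2 + spec.beta_sex**2 * var_sex
    n = len(z_age)
    if signal_var == 0.0:
        return rng.standard_normal(n)
    if spec.r2_target <= 0.0:
        raise ParameterizationError(
            f"nonzero effects need r2_target > 0 for {spec.metric}/{spec.network}"
        )
    noise_var = signal_var * (1.0 - spec.r2_target) / spec.r2_target
    y = spec.beta_age * z_age + spec.beta_sex * sex_code + math.sqrt(noise_var) * rng.standard_normal(n)
    return y / math.sqrt(signal_var + noise_var)


_FRACTION_METRICS = ("f_neurite", "f_soma", "f_extracellular")


def _simplex_fractions(
    base: dict[str, float], sd: dict[str, float],
    y_neurite: np.ndarray, y_soma: np.ndarray,
) -> dict[str, np.ndarray]:
    """Map two standardized latent signals onto the 2-simplex.

    Logistic-normal construction: Gaussian latents on the additive-log-ratio
    scale (f_extracellular as reference), pushed through a softmax so every
    row closes to exactly 1 with all fractions positive. The latents are
    premultiplied by the inverse softmax Jacobian at the baseline composition
    so that, at small dispersion, the observed f_neurite and f_soma tracks
    are ``base + sd * y`` to first order and the configured standardized
    effects survive the transform. f_extracellular is implied by closure.
    """
    fn, fs = base["f_neurite"], base["f_soma"]
    jac = np.array([[fn * (1 - fn), -fn * fs], [-fn * fs, fs * (1 - fs)]])
    targets = np.vstack([sd["f_neurite"] * y_neurite, sd["f_soma"] * y_soma])
    dz = np.linalg.solve(jac, targets)
    fe = 1.0 - fn - fs
    z1 = math.log(fn / fe) + dz[0]
    z2 = math.log(fs / fe) + dz[1]
    e1, e2 = np.exp(z1), np.exp(z2)
    denom = 1.0 + e1 + e2
    return {"f_neurite": e1 / denom, "f_soma": e2 / denom, "f_extracellular": 1.0 / denom}


def default_effect_specs() -> list[EffectSpec]:
    """Effect table packaged with the library (the emulated study conditions)."""
    with resources.files("cortexdev.data").joinpath("default_effects.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t")
    return [
        EffectSpec(
            network=r.network, metric=r.metric, beta_age=r.beta_age, beta_sex=r.beta_sex,
            r2_target=r.r2_target, baseline_mean=r.baseline_mean, baseline_sd=r.baseline_sd,
        )
        for r in table.itertuples()
        if r.role == "direct" or r.metric == "f_extracellular"
    ]


def reference_icc_values() -> dict[str, float]:
    """Packaged test-retest ICC reference values per metric."""
    with resources.files("cortexdev.data").joinpath("default_icc.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t")
    return dict(zip(table["metric"], table["icc"]))


def generate_pds(age: np.ndarray, age_range: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    """Pubertal stage 1-5 as a monotone noisy function of age.

    Linear ramp mapping the age range onto stages 1..5 plus Gaussian noise,
    rounded and clipped; calibrated so pds ~ age attains R^2 ~= 0.72.
    """
    lo, hi = age_range
    b = 4.0 / (hi - lo)
    a = 1.0 - b * lo
    raw = a + b * age + rng.normal(0.0, _PDS_NOISE_SD, size=len(age))
    return np.clip(np.round(raw), 1, 5).astype(int)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a long-format imaging cohort table.

    Returns rows of (subject_id, age, sex, pds, network, metric, value). The
    three signal fractions are generated jointly on the simplex per network
    and close to exactly 1; all other metrics follow the standardized linear
    effect model of their :class:`EffectSpec`.
    """
    ss = np.random.SeedSequence(spec.seed, spawn_key=(0,))
    rng_subj, rng_metrics = [np.random.default_rng(s) for s in ss.spawn(2)]

    n = spec.n_subjects
    age = rng_subj.uniform(*spec.age_range, size=n)
    sex = np.where(rng_subj.random(n) < spec.male_fraction, "M", "F")
    sex_code = np.where(sex == "M", 0.5, -0.5)
    pds = generate_pds(age, spec.age_range, rng_subj)
    z_age = (age - age.mean()) / age.std(ddof=1)
    subject_id = np.array([f"sub-{i + 1:03d}" for i in range(n)])

    effects = list(spec.effects) if spec.effects else default_effect_specs()
    by_network: dict[str, list[EffectSpec]] = {}
    for e in effects:
        by_network.setdefault(e.network, []).append(e)

    records: list[pd.DataFrame] = []
    for network in spec.networks:
        net_effects = {e.metric: e for e in by_network.get(network, [])}
        fracs = {m: net_effects.get(m) for m in _FRACTION_METRICS}
        values: dict[str, np.ndarray] = {}
        # Jointly generated compositional block (f_extracellular implied).
        if fracs["f_neurite"] is not None and fracs["f_soma"] is not None:
            yn = _standardized_signal(fracs["f_neurite"], z_age, sex_code, spec.male_fraction, rng_metrics)
            ys = _standardized_signal(fracs["f_soma"], z_age, sex_code, spec.male_fraction, rng_metrics)
            base = {m: fracs[m].baseline_mean if fracs[m] else 0.0 for m in _FRACTION_METRICS}
            base["f_extracellular"] = 1.0 - base["f_neurite"] - base["f_soma"]
            sd = {m: fracs[m].baseline_sd for m in ("f_neurite", "f_soma")}
            values.update(_simplex_fractions(base, sd, yn, ys))
        for metric, eff in net_effects.items():
            if metric in _FRACTION_METRICS:
                continue
            y = _standardized_signal(eff, z_age, sex_code, spec.male_fraction, rng_metrics)
            values[metric] = eff.baseline_mean + eff.baseline_sd * y
        for metric, vals in values.items():
            records.append(
                pd.DataFrame(
                    {
                        "subject_id": subject_id, "age": age, "sex": sex, "pds": pds,
                        "network": network, "metric": metric, "value": vals,
                    }
                )
            )
    if not records:
        raise ValueError("no effects defined for any requested network")
    return pd.concat(records, ignore_index=True)


def generate_repeatability(spec: RepeatabilitySpec) -> pd.DataFrame:
    """Simulate a subjects-by-sessions test-retest table.

    value_ij = mean + b_i + s_j + e_ij with independent zero-mean Gaussian
    components at the configured SDs.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(1,)))
    n, k = spec.n_subjects, spec.n_sessions
    b = rng.normal(0.0, spec.sigma_subject, size=n)[:, None]
    s = rng.normal(0.0, spec.sigma_session, size=k)[None, :]
    e = rng.normal(0.0, spec.sigma_error, size=(n, k))
    values = spec.mean + b + s + e
    subj, sess = np.meshgrid(np.arange(n), np.arange(k), indexing="ij")
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:02d}" for i in subj.ravel()],
            "session": sess.ravel() + 1,
            "metric": spec.metric,
            "value": values.ravel(),
        }
    )


# ---------------------------------------------------------------------------
# expression datasets


def _shape_value(t, shape, midpoint, rate, amplitude, baseline):
    t = np.asarray(t, dtype=float)
    if shape == "logistic_rise":
        return baseline + amplitude / (1.0 + np.exp(-rate * (t - midpoint)))
    if shape == "exponential_decay":
        return baseline + amplitude * np.exp(-rate * np.maximum(t, 0.0))
    if shape == "flat":
        return baseline + np.zeros_like(t)
    raise ValueError(f"unknown trajectory shape: {shape}")


#: Cell-type trajectory archetypes: (shape, baseline, amplitude, rate, midpoint,
#: regional timing). Levels roughly reproduce the relative expression
#: magnitudes of cortical cell classes on the log2-RPKM scale (neurons
#: highest, microglia lowest); rising types follow the S-A regional ordering.
_TYPE_ARCHETYPES: dict[str, tuple[str, float, float, float, float, bool]] = {
    "excitatory": ("logistic_rise", 3.90, 0.50, 0.25, 10.0, True),
    "inhibitory": ("flat", 2.94, 0.0, 0.0, 0.0, False),
    # midpoint 18.2 places the noise-free astrocyte/oligodendrocyte crossing
    # at age 20.0 in the earliest (M1/V1) regions and ~25.3 in MFC
    "oligodendrocyte": ("logistic_rise", 2.60, 1.40, 0.30, 18.2, True),
    "OPC": ("exponential_decay", 2.70, 0.60, 0.10, 0.0, False),
    "astrocyte": ("exponential_decay", 3.30, 0.90, 0.08, 0.0, False),
    "microglia": ("exponential_decay", 1.80, 0.35, 0.12, 0.0, False),
    "endothelial": ("exponential_decay", 2.30, 0.50, 0.10, 0.0, False),
}


def default_catalog(
    n_genes_per_type: int = 30,
    regions: Sequence[str] = CORTICAL_REGIONS,
    seed: int = 0,
    jitter: bool = True,
) -> GeneCatalog:
    """Synthetic gene catalog: per-type archetype curves with per-gene jitter.

    Rising cell types (excitatory, oligodendrocyte) carry regional timing
    offsets along the S-A axis; decaying and flat types are spatially
    uniform. ``jitter=False`` gives every gene its archetype exactly
    (useful for noiseless oracle checks).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    unknown = set(regions) - set(SA_AXIS_OFFSETS)
    if unknown:
        raise ValueError(f"no S-A offset defined for regions: {sorted(unknown)}")
    rows, offset_rows = [], []
    for ct in CELL_TYPES:
        shape, base, amp, rate, mid, regional = _TYPE_ARCHETYPES[ct]
        for i in range(n_genes_per_type):
            symbol = f"{ct[:4].upper()}{i + 1:04d}"
            if jitter:
                b = base + rng.normal(0.0, 0.2)
                a = amp * rng.uniform(0.8, 1.2) if amp else 0.0
                r = rate * rng.uniform(0.8, 1.2) if rate else 0.0
                m = mid + rng.uniform(-1.5, 1.5) if shape == "logistic_rise" else mid
            else:
                b, a, r, m = base, amp, rate, mid
            rows.append(
                {"symbol": symbol, "cell_type": ct, "shape": shape,
                 "midpoint_age": m, "rate": r, "amplitude": a, "baseline": b}
            )
            offset_rows.append(
                {reg: (SA_AXIS_OFFSETS[reg] if regional else 0.0) for reg in regions}
            )
    genes = pd.DataFrame(rows)
    offsets = pd.DataFrame(offset_rows, index=genes["symbol"])
    return GeneCatalog(genes=genes, offsets=offsets)


def generate_expression(spec: ExpressionCohortSpec) -> ExpressionDataset:
    """Simulate a bulk expression dataset in the requested dialect.

    Single-region dialect: independent samples from one region (DLPFC), no
    covariates, per-gene z-scored after generation (``scale='normalized'``).
    Multi-region dialect: one sample per donor-region pair, donor random
    effects, sex and RIN covariates (``scale='log2RPKM'``).
    """
    catalog = spec.catalog if spec.catalog is not None else default_catalog(seed=spec.seed)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(3,)))

    if spec.dialect == "single_region_normalized":
        region = "DLPFC"
        if region not in catalog.regions:
            raise ValueError(f"catalog has no offsets for region {region!r}")
        n = spec.n_samples
        meta = pd.DataFrame(
            {
                "age": rng.uniform(*spec.age_range, size=n),
                "region": region,
                "donor": [f"donor-{i + 1:03d}" for i in range(n)],
                "sex": np.where(rng.random(n) < spec.male_fraction, "M", "F"),
                "RIN": rng.normal(spec.rin_mean, spec.rin_sd, size=n),
            },
            index=pd.Index([f"s{i + 1:04d}" for i in range(n)], name="sample_id"),
        )
        expr = _expression_matrix(catalog, meta, spec, rng, donor_effects=False)
        mu = expr.mean(axis=1)
        sd = expr.std(axis=1, ddof=1).replace(0.0, 1.0)
        expr = expr.sub(mu, axis=0).div(sd, axis=0)
        return ExpressionDataset(expression=expr, samples=meta, scale="normalized")

    missing = set(spec.regions) - set(catalog.regions)
    if missing:
        raise ValueError(f"catalog has no offsets for regions: {sorted(missing)}")
    donors = [f"donor-{i + 1:03d}" for i in range(spec.n_donors)]
    donor_age = rng.uniform(*spec.age_range, size=spec.n_donors)
    donor_sex = np.where(rng.random(spec.n_donors) < spec.male_fraction, "M", "F")
    donor_rin = rng.normal(spec.rin_mean, spec.rin_sd, size=spec.n_donors)
    recs = []
    for d in range(spec.n_donors):
        for reg in spec.regions:
            recs.append(
                {"age": donor_age[d], "region": reg, "donor": donors[d],
                 "sex": donor_sex[d], "RIN": donor_rin[d]}
            )
    meta = pd.DataFrame(recs, index=pd.Index([f"s{i + 1:04d}" for i in range(len(recs))], name="sample_id"))
    expr = _expression_matrix(catalog, meta, spec, rng, donor_effects=True)
    return ExpressionDataset(expression=expr, samples=meta, scale="log2RPKM")


def _expression_matrix(
    catalog: GeneCatalog, meta: pd.DataFrame, spec: ExpressionCohortSpec,
    rng: np.random.Generator, donor_effects: bool,
) -> pd.DataFrame:
    genes = catalog.genes
    ages = meta["age"].to_numpy()
    rin_c = meta["RIN"].to_numpy() - spec.rin_mean
    offsets = catalog.offsets.loc[genes["symbol"], meta["region"]].to_numpy()
    t = ages[None, :] - offsets  # gene x sample effective age
    curves = np.empty_like(t)
    for shape in np.unique(genes["shape"]):
        idx = (genes["shape"] == shape).to_numpy()
        g = genes.loc[idx]
        curves[idx, :] = _shape_value(
            t[idx, :], shape,
            g["midpoint_age"].to_numpy()[:, None], g["rate"].to_numpy()[:, None],
            g["amplitude"].to_numpy()[:, None], g["baseline"].to_numpy()[:, None],
        )
    expr = curves + spec.rin_coef * rin_c[None, :]
    if donor_effects:
        donor_ids = meta["donor"].unique()
        eff = dict(zip(donor_ids, rng.normal(0.0, spec.donor_sd, size=len(donor_ids))))
        expr = expr + meta["donor"].map(eff).to_numpy()[None, :]
    expr = expr + rng.normal(0.0, spec.noise_sd, size=expr.shape)
    return pd.DataFrame(expr, index=pd.Index(genes["symbol"], name="gene"), columns=meta.index)


def dataset_to_long(ds: ExpressionDataset) -> pd.DataFrame:
    """Long-format TSV-friendly view (gene, sample_id, expression + metadata)."""
    long = ds.expression.stack().rename("expression").reset_index()
    long.columns = ["gene", "sample_id", "expression"]
    return long.merge(ds.samples.reset_index(), on="sample_id")
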