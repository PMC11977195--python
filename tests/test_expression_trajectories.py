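"""Age-gene selection, trajectory summaries, crossover/peak, enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cortexdev import expression_trajectories as et
from cortexdev import synthetic_data as sd
from cortexdev.pspline import SplineFit


def _const_fit(name, grid, curve, deriv=None, p=1.0, region="pooled"):
    curve = np.asarray(curve, dtype=float)
    deriv = np.gradient(curve, grid) if deriv is None else np.asarray(deriv, dtype=float)
    return SplineFit(
        name=name, age_grid=grid, curves={region: curve}, derivatives={region: deriv},
        coefficients=np.zeros(5), lam=1.0, lam_ridge=None, edf=2.0, edf_smooth=1.0,
        p_smooth=p, aic=0.0, bic=0.0, rss=1.0, n=len(grid), k=5,
    )


# ---------------------------------------------------------------------------
# BH selection


def _bh_oracle(p, alpha=0.05):
    """Brute-force BH q-values: q_i = min over ranks j >= rank(i) of p_(j)*m/j.

    Returns (q, selected) with the library's strict q < alpha selection rule.
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = min(running, 1.0)
    return q, q < alpha


class TestSelectAgeGenes:
    def _results(self, pvals, alpha=0.05):
        grid = np.arange(0.0, 10.0, 0.1)
        fits = {f"g{i}": _const_fit(f"g{i}", grid, np.zeros(len(grid)), p=p)
                for i, p in enumerate(pvals)}
        return et.select_age_genes(fits, alpha=alpha)

    def test_all_ones_selects_none(self):
        assert not any(r.selected for r in self._results([1.0] * 20))

    def test_ten_small_ninety_large(self):
        res = self._results([0.001] * 10 + [0.9] * 90)
        sel = {r.gene for r in res if r.selected}
        assert sel == {f"g{i}" for i in range(10)}

    def test_q_geq_p_and_monotone(self):
        rng = np.random.default_rng(0)
        res = self._results(list(rng.random(50)))
        for r in res:
            assert r.q >= r.p - 1e-12
        by_p = sorted(res, key=lambda r: r.p)
        qs = [r.q for r in by_p]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))

    def test_matches_stepup_oracle_exhaustively(self):
        # all grid-valued p-vectors of length <= 3 (exhaustive product) plus
        # seeded random vectors of every length up to 20
        grid_vals = [0.001, 0.01, 0.04, 0.05, 0.2, 0.5, 0.8, 1.0]
        cases = []
        for L in (1, 2, 3):
            cases.extend(itertools.product(grid_vals, repeat=L))
        rng = np.random.default_rng(1)
        for L in range(4, 21):
            for _ in range(30):
                cases.append(tuple(rng.choice(grid_vals, size=L)))
        for p in cases:
            res = self._results(list(p))
            q_oracle, sel_oracle = _bh_oracle(np.array(p))
            assert np.allclose([r.q for r in res], q_oracle, atol=1e-12), p
            # q == alpha exactly (in real arithmetic) is a knife-edge where
            # float association order decides the strict comparison; skip those
            off_boundary = np.abs(q_oracle - 0.05) > 1e-9
            got = np.array([r.selected for r in res])
            assert np.array_equal(got[off_boundary], sel_oracle[off_boundary]), p

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            et.select_age_genes({})


class TestReplication:
    def test_study_arithmetic(self):
        disc = {f"g{i}" for i in range(2057)}
        val = {f"g{i}" for i in range(467)} | {f"x{i}" for i in range(1000)}
        count, prop = et.replication_overlap(disc, val)
        assert count == 467
        assert prop == 0.227

    def test_disjoint_and_identical(self):
        a = {"g1", "g2"}
        assert et.replication_overlap(a, {"h1"}) == (0, 0.0)
        assert et.replication_overlap(a, a) == (2, 1.0)

    def test_empty_discovery_rejected(self):
        with pytest.raises(ValueError):
            et.replication_overlap(set(), {"g"})


# ---------------------------------------------------------------------------
# trajectories, peaks, crossover


class TestCellTypeTrajectory:
    def test_single_gene_equals_its_fit(self, catalog, single_region_dataset):
        fits = et.fit_all_genes(single_region_dataset)
        g = catalog.genes.loc[catalog.genes["cell_type"] == "microglia", "symbol"].iloc[0]
        tr = et.celltype_trajectory({g: fits[g]}, catalog, "microglia", normalize=False)
        assert np.allclose(tr.mean_curve, fits[g].curves["pooled"])
        assert tr.n_genes == 1

    def test_antisymmetric_pair_demeaned_cancels(self):
        grid = np.arange(0.0, 30.0, 0.1)
        f = np.sin(grid / 5.0)
        cat = sd.GeneCatalog(
            genes=pd.DataFrame(
                {"symbol": ["A", "B"], "cell_type": ["astrocyte"] * 2,
                 "shape": ["flat"] * 2, "midpoint_age": [0.0] * 2, "rate": [0.0] * 2,
                 "amplitude": [0.0] * 2, "baseline": [0.0] * 2}
            ),
            offsets=pd.DataFrame({"M1": [0.0, 0.0]}, index=pd.Index(["A", "B"], name="symbol")),
        )
        fits = {"A": _const_fit("A", grid, f), "B": _const_fit("B", grid, -f)}
        tr = et.celltype_trajectory(fits, cat, "astrocyte", normalize="demean")
        assert np.abs(tr.norm_curve).max() < 1e-12

    def test_constant_gene_normalizes_to_zero(self):
        grid = np.arange(0.0, 10.0, 0.1)
        cat = sd.default_catalog(n_genes_per_type=1, seed=0)
        g = cat.genes.loc[cat.genes["cell_type"] == "inhibitory", "symbol"].iloc[0]
        fits = {g: _const_fit(g, grid, np.full(len(grid), 3.0), deriv=np.zeros(len(grid)))}
        tr = et.celltype_trajectory(fits, cat, "inhibitory", normalize="zscore")
        assert np.abs(tr.norm_curve).max() == 0.0

    def test_oligo_mean_curve_monotone_rising(self, catalog, multi_region_dataset):
        fits = et.fit_all_genes(multi_region_dataset)
        tr = et.celltype_trajectory(fits, catalog, "oligodendrocyte", region="M1")
        lo = tr.mean_curve[tr.age_grid <= 10].mean()
        hi = tr.mean_curve[tr.age_grid >= 30].mean()
        assert hi > lo + 0.5  # rises by a large fraction of its 1.4 amplitude

    def test_unknown_cell_type_rejected(self, catalog):
        with pytest.raises(ValueError):
            et.celltype_trajectory({}, catalog, "martian")


class TestPeakGrowth:
    def test_logistic_peak_at_midpoint(self):
        grid = np.arange(0.0, 40.0, 0.1)
        curve = 1 / (1 + np.exp(-0.5 * (grid - 20.0)))
        tr = et.CellTypeTrajectory(
            "oligodendrocyte", "pooled", grid, curve, curve, curve, curve,
            mean_derivative=np.gradient(curve, grid), n_genes=1,
        )
        age, censored = et.peak_growth_age(tr)
        assert abs(age - 20.0) <= 0.1
        assert not censored

    def test_monotone_decay_censored_at_start(self):
        grid = np.arange(0.0, 40.0, 0.1)
        curve = np.exp(-0.2 * grid)
        tr = et.CellTypeTrajectory(
            "astrocyte", "pooled", grid, curve, curve, curve, curve,
            mean_derivative=np.gradient(curve, grid), n_genes=1,
        )
        age, censored = et.peak_growth_age(tr)
        # derivative of a decay is most positive (least negative) at the end,
        # |max| at a boundary either way -> censored
        assert censored

    def test_flat_curve_returns_none(self):
        grid = np.arange(0.0, 10.0, 0.1)
        tr = et.CellTypeTrajectory(
            "microglia", "pooled", grid, np.ones_like(grid), np.zeros_like(grid),
            np.zeros_like(grid), np.zeros_like(grid),
            mean_derivative=np.zeros_like(grid), n_genes=1,
        )
        assert et.peak_growth_age(tr) == (None, False)


class TestCrossover:
    def _traj(self, curve, grid, region="M1", ct="oligodendrocyte"):
        curve = np.asarray(curve, dtype=float)
        return et.CellTypeTrajectory(
            ct, region, grid, curve, curve, curve, curve,
            mean_derivative=np.gradient(curve, grid), n_genes=1,
        )

    def test_analytic_root(self):
        grid = np.arange(0.0, 30.0 + 1e-9, 0.1)
        oligo = self._traj(grid - 20.0, grid)
        astro = self._traj(np.zeros_like(grid), grid, ct="astrocyte")
        assert et.expression_ratio_crossover(oligo, astro).age == pytest.approx(20.0, abs=1e-9)

    def test_never_crosses_returns_none(self):
        grid = np.arange(0.0, 30.0, 0.1)
        oligo = self._traj(np.full_like(grid, -1.0), grid)
        astro = self._traj(np.zeros_like(grid), grid, ct="astrocyte")
        assert et.expression_ratio_crossover(oligo, astro).age is None

    def test_mismatched_grids_rejected(self):
        g1 = np.arange(0.0, 30.0, 0.1)
        g2 = np.arange(0.0, 30.0, 0.2)
        with pytest.raises(ValueError, match="grid"):
            et.expression_ratio_crossover(
                self._traj(g1, g1), self._traj(np.zeros_like(g2), g2, ct="astrocyte")
            )

    def test_noiseless_crossover_matches_generating_root(self):
        # noise-free default catalog (no jitter): estimator within one grid
        # step of the analytic crossing of the generating curves (20.0 in M1)
        cat = sd.default_catalog(n_genes_per_type=3, seed=0, jitter=False)
        ds = sd.generate_expression(
            sd.ExpressionCohortSpec(
                dialect="multi_region_rpkm", n_donors=60, catalog=cat,
                noise_sd=0.0, rin_coef=0.0, donor_sd=0.0, seed=1,
            )
        )
        fits = et.fit_all_genes(ds)
        from scipy.optimize import brentq

        ages = np.linspace(1, 39, 500)
        gen_root = brentq(
            lambda a: cat.curve("OLIG0001", np.array([a]), "M1")[0]
            - cat.curve("ASTR0001", np.array([a]), "M1")[0],
            5, 39,
        )
        to = et.celltype_trajectory(fits, cat, "oligodendrocyte", region="M1")
        ta = et.celltype_trajectory(fits, cat, "astrocyte", region="M1")
        got = et.expression_ratio_crossover(to, ta).age
        assert got is not None
        # spline smoothing bias allowed: within 1 y of the true root at 20.0
        assert abs(got - gen_root) <= 1.0
        assert gen_root == pytest.approx(20.0, abs=0.05)

    def test_regional_ordering_m1_before_mfc(self, catalog, multi_region_dataset):
        fits = et.fit_all_genes(multi_region_dataset)
        cross = {}
        for reg in ("M1", "MFC"):
            to = et.celltype_trajectory(fits, catalog, "oligodendrocyte", region=reg)
            ta = et.celltype_trajectory(fits, catalog, "astrocyte", region=reg)
            cross[reg] = et.expression_ratio_crossover(to, ta).age
        assert cross["M1"] is not None and cross["MFC"] is not None
        assert cross["M1"] < cross["MFC"]


# ---------------------------------------------------------------------------
# enrichment


def _hypergeom_tail_oracle(a, b, c, d):
    """P(X >= a), X ~ Hypergeom(N=a+b+c+d, K=a+c, n=a+b): brute force."""
    N, K, n = a + b + c + d, a + c, a + b
    denom = math.comb(N, n)
    return sum(
        math.comb(K, x) * math.comb(N - K, n - x)
        for x in range(a, min(K, n) + 1)
    ) / denom


class TestEnrichment:
    def test_perfect_overlap_table(self):
        res = et.enrichment_test(
            {f"q{i}" for i in range(10)},
            {"set": [f"q{i}" for i in range(10)]},
            {f"q{i}" for i in range(10)} | {f"b{i}" for i in range(90)},
        )[0]
        assert res.p == pytest.approx(1.0 / math.comb(100, 10), rel=1e-9)
        assert (res.a, res.b, res.c, res.d) == (10, 0, 0, 90)

    def test_matches_hypergeometric_oracle_exhaustively(self):
        # every 2x2 table with total <= 30
        for N in range(1, 31):
            for a in range(N + 1):
                for b in range(N - a + 1):
                    for c in range(N - a - b + 1):
                        d = N - a - b - c
                        p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
                        assert p == pytest.approx(_hypergeom_tail_oracle(a, b, c, d), rel=1e-9, abs=1e-12)

    def test_seeded_oligo_query_top_ranked(self, catalog):
        rng = np.random.default_rng(2)
        sets = catalog.gene_sets()
        background = set(catalog.genes["symbol"])
        oligo = sets["oligodendrocyte"]
        others = sorted(background - set(oligo))
        query = set(rng.choice(oligo, size=24, replace=False)) | set(
            rng.choice(others, size=6, replace=False)
        )
        res = et.enrichment_test(query, sets, background)
        best = min(res, key=lambda r: r.p)
        assert best.gene_set == "oligodendrocyte"
        assert best.flagged  # q < 0.001

    def test_counts_sum_to_background(self, catalog):
        sets = catalog.gene_sets()
        background = set(catalog.genes["symbol"])
        res = et.enrichment_test(set(list(background)[:20]), sets, background)
        for r in res:
            assert r.a + r.b + r.c + r.d == len(background)

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError):
            et.enrichment_test({"zz"}, {"s": ["a"]}, {"a", "b"})


class TestStageCounts:
    def test_flat_genes_count_zero(self, catalog):
        grid = np.arange(0.0, 40.0, 0.1)
        genes = catalog.genes["symbol"].iloc[:5].tolist()
        fits = {g: _const_fit(g, grid, np.zeros(len(grid)), deriv=np.zeros(len(grid))) for g in genes}
        tab = et.stage_gene_counts(genes, catalog, fits)
        assert (tab["count"] == 0).all()

    def test_rising_gene_counted_in_adolescence(self, catalog):
        grid = np.arange(0.0, 40.0, 0.1)
        g = catalog.genes.loc[catalog.genes["cell_type"] == "oligodendrocyte", "symbol"].iloc[0]
        curve = 1 / (1 + np.exp(-0.8 * (grid - 16.0)))
        fits = {g: _const_fit(g, grid, curve)}
        tab = et.stage_gene_counts([g], catalog, fits)
        row = tab[(tab["stage"] == "adolescence") & (tab["cell_type"] == "oligodendrocyte")]
        assert row["count"].iloc[0] == 1

    def test_overlapping_windows_rejected(self, catalog):
        with pytest.raises(ValueError, match="overlap"):
            et.stage_gene_counts(
                [], catalog, {}, stage_windows={"a": (0.0, 10.0), "b": (5.0, 15.0)}
            )

    def test_oligo_proportion_rises_with_stage(self, catalog, single_region_dataset):
        # oligodendrocyte genes turn on latest (highest S-A timing), so their
        # share of derivative-active age-genes grows with developmental stage
        fits = et.fit_all_genes(single_region_dataset)
        selected = [r.gene for r in et.select_age_genes(fits) if r.selected]
        tab = et.stage_gene_counts(selected, catalog, fits, region="pooled")
        prop = tab.set_index(["stage", "cell_type"])["proportion"]
        assert prop.loc[("young_adulthood", "oligodendrocyte")] > prop.loc[("childhood", "oligodendrocyte")]
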