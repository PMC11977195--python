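"""End-to-end pipeline orchestration.

Stages run in dependency order on one global seed:

1. ``simulate_cohort``      imaging cohort + repeatability tables
2. ``fit_networks``         standardized age models + ICC per metric
3. ``simulate_expression``  single-region normalized + multi-region RPKM sets
4. ``fit_trajectories``     per-gene splines, age-genes, replication,
                            cell-type trajectories, peaks, crossovers,
                            enrichment, stage counts
5. ``simulate_soma``        apparent-soma-radius age sweep

Every output is TSV with a ``# config_hash=... seed=...`` comment line; a
JSON manifest records the configuration hash, seed and produced files. A
stage whose outputs already exist is skipped when ``resume`` is on.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from cortexdev import expression_trajectories as et
from cortexdev import io as cio
from cortexdev import microstructure_stats as ms
from cortexdev import soma_sim
from cortexdev import synthetic_data as sd

log = logging.getLogger("cortexdev")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s:%(levelname)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)

STAGES = ("simulate_cohort", "fit_networks", "simulate_expression", "fit_trajectories", "simulate_soma")


def default_config() -> dict:
    return {
        "cohort": {"n_subjects": 88, "age_range": [8.0, 19.0], "male_fraction": 42 / 88},
        "repeatability": {
            "n_subjects": 6, "n_sessions": 5,
            "sigma_subject": float(np.sqrt(0.97)),
            "sigma_session": float(np.sqrt(0.015)),
            "sigma_error": float(np.sqrt(0.015)),
        },
        "networks": {"alpha": 0.005, "formula": ["age"]},
        "expression": {
            "n_samples": 214, "n_donors": 20, "noise_sd": 0.35,
            "n_genes_per_type": 30, "fdr_alpha": 0.05,
        },
        "soma": {
            "ages": [8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19],
            "n_samples": 100_000, "slopes": dict(soma_sim.DEFAULT_SLOPES),
            "coupling": "linear",
        },
    }


def _write(df: pd.DataFrame, out: Path, name: str, tag: str, manifest: dict) -> None:
    path = cio.write_table(df, out / name, header_comment=tag)
    manifest["outputs"].append(str(path.name))


def run_pipeline(
    config: dict | None = None,
    seed: int = 0,
    out_dir: str | Path = "results/pipeline",
    stages: tuple[str, ...] = STAGES,
    resume: bool = False,
) -> dict:
    """Run the requested stages; returns the manifest dict (also written to disk)."""
    cfg = default_config()
    for key, block in (config or {}).items():
        if key not in cfg:
            raise ValueError(f"unknown config block {key!r} (valid: {sorted(cfg)})")
        cfg[key].update(block)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cio.config_hash({**cfg, "seed": seed})
    tag = f"config_hash={chash} seed={seed}"
    manifest: dict = {"config_hash": chash, "seed": seed, "stages": list(stages), "outputs": []}

    def needs(*names: str) -> bool:
        if resume and all((out / n).exists() for n in names):
            log.info("resume: skipping existing %s", ", ".join(names))
            manifest["outputs"].extend(names)
            return False
        return True

    if "simulate_cohort" in stages and needs("cohort.tsv", "repeatability.tsv"):
        log.info("simulate_cohort: n=%d", cfg["cohort"]["n_subjects"])
        cohort = sd.generate_cohort(
            sd.CohortSpec(
                n_subjects=cfg["cohort"]["n_subjects"],
                age_range=tuple(cfg["cohort"]["age_range"]),
                male_fraction=cfg["cohort"]["male_fraction"],
                seed=seed,
            )
        )
        _write(cohort, out, "cohort.tsv", tag, manifest)
        rep = sd.generate_repeatability(sd.RepeatabilitySpec(seed=seed, **cfg["repeatability"]))
        _write(rep, out, "repeatability.tsv", tag, manifest)

    if "fit_networks" in stages:
        if not (out / "cohort.tsv").exists():
            raise FileNotFoundError("fit_networks needs cohort.tsv; run simulate_cohort first")
        if needs("network_fits.tsv", "icc.tsv"):
            cohort = cio.read_table(out / "cohort.tsv")
            fits = ms.fit_networks(
                cohort, formula=cfg["networks"]["formula"], alpha=cfg["networks"]["alpha"]
            )
            _write(fits, out, "network_fits.tsv", tag, manifest)
            rep = cio.read_table(out / "repeatability.tsv")
            icc_rows = []
            for metric in sorted(rep["metric"].unique()):
                r = ms.icc_absolute_agreement(rep, metric)
                icc_rows.append({"metric": metric, "icc": r.icc, "n": r.n, "k": r.k, "negative": r.negative})
            _write(pd.DataFrame(icc_rows), out, "icc.tsv", tag, manifest)

    catalog = sd.default_catalog(n_genes_per_type=cfg["expression"]["n_genes_per_type"], seed=seed)
    if "simulate_expression" in stages and needs("expression_single.tsv", "expression_multi.tsv", "gene_sets.gmt"):
        log.info("simulate_expression: %d genes", len(catalog.genes))
        single = sd.generate_expression(
            sd.ExpressionCohortSpec(
                dialect="single_region_normalized", n_samples=cfg["expression"]["n_samples"],
                age_range=(0.5, 72.0), noise_sd=cfg["expression"]["noise_sd"],
                catalog=catalog, seed=seed,
            )
        )
        multi = sd.generate_expression(
            sd.ExpressionCohortSpec(
                dialect="multi_region_rpkm", n_donors=cfg["expression"]["n_donors"],
                noise_sd=cfg["expression"]["noise_sd"], catalog=catalog, seed=seed + 1,
            )
        )
        _write(sd.dataset_to_long(single), out, "expression_single.tsv", tag, manifest)
        _write(sd.dataset_to_long(multi), out, "expression_multi.tsv", tag, manifest)
        cio.write_gmt(catalog.gene_sets(), out / "gene_sets.gmt")
        manifest["outputs"].append("gene_sets.gmt")
        manifest["_datasets"] = {"single": single, "multi": multi}

    if "fit_trajectories" in stages:
        ds = manifest.get("_datasets")
        if ds is None:
            if not (out / "expression_single.tsv").exists():
                raise FileNotFoundError("fit_trajectories needs expression tables; run simulate_expression")
            ds = {
                "single": _long_to_dataset(cio.read_table(out / "expression_single.tsv"), "normalized"),
                "multi": _long_to_dataset(cio.read_table(out / "expression_multi.tsv"), "log2RPKM"),
            }
        alpha = cfg["expression"]["fdr_alpha"]
        log.info("fit_trajectories: fitting %d genes x 2 datasets", len(catalog.genes))
        fits_single = et.fit_all_genes(ds["single"])
        fits_multi = et.fit_all_genes(ds["multi"])
        ag_single = et.select_age_genes(fits_single, alpha=alpha)
        ag_multi = et.select_age_genes(fits_multi, alpha=alpha)
        _write(pd.DataFrame([vars(a) for a in ag_single]), out, "age_genes_single.tsv", tag, manifest)
        _write(pd.DataFrame([vars(a) for a in ag_multi]), out, "age_genes_multi.tsv", tag, manifest)
        disc = {a.gene for a in ag_single if a.selected}
        val = {a.gene for a in ag_multi if a.selected}
        if disc:
            count, prop = et.replication_overlap(disc, val)
            manifest["replication"] = {"discovery": len(disc), "replicated": count, "proportion": prop}
            log.info("replication: %d/%d = %.3f", count, len(disc), prop)

        cross_rows, peak_rows, traj_rows = [], [], []
        for region in catalog.regions:
            to = et.celltype_trajectory(fits_multi, catalog, "oligodendrocyte", region=region)
            ta = et.celltype_trajectory(fits_multi, catalog, "astrocyte", region=region)
            cr = et.expression_ratio_crossover(to, ta)
            cross_rows.append({"region": region, "crossover_age": cr.age})
            age, censored = et.peak_growth_age(to)
            peak_rows.append({"region": region, "cell_type": "oligodendrocyte",
                              "peak_growth_age": age, "censored": censored})
        for ct in sd.CELL_TYPES:
            try:
                tr = et.celltype_trajectory(fits_single, catalog, ct, region="pooled")
            except ValueError:
                continue
            traj_rows.append(
                pd.DataFrame({"cell_type": ct, "age": tr.age_grid, "mean": tr.mean_curve,
                              "norm_mean": tr.norm_curve, "band_low": tr.band_low,
                              "band_high": tr.band_high})
            )
        _write(pd.DataFrame(cross_rows), out, "crossover.tsv", tag, manifest)
        _write(pd.DataFrame(peak_rows), out, "peak_growth.tsv", tag, manifest)
        _write(pd.concat(traj_rows, ignore_index=True), out, "celltype_trajectories.tsv", tag, manifest)

        # enrichment and stage overlap use the discovery (single-region)
        # age-genes: the multi-region design identifies age only across its
        # 20 donors and is deliberately low-powered per gene
        selected = [a.gene for a in ag_single if a.selected]
        if selected:
            enr = et.enrichment_test(
                set(selected), catalog.gene_sets(), set(catalog.genes["symbol"])
            )
            _write(pd.DataFrame([vars(e) for e in enr]), out, "enrichment.tsv", tag, manifest)
            stage_tab = et.stage_gene_counts(selected, catalog, fits_single, region="pooled")
            _write(stage_tab, out, "stage_counts.tsv", tag, manifest)

    if "simulate_soma" in stages and needs("soma_sweep.tsv"):
        pops = soma_sim.default_populations()
        sweep, pct = soma_sim.age_sweep(
            pops, cfg["soma"]["slopes"], cfg["soma"]["ages"],
            n_samples=cfg["soma"]["n_samples"], seed=seed, coupling=cfg["soma"]["coupling"],
        )
        _write(sweep, out, "soma_sweep.tsv", tag, manifest)
        manifest["soma_percent_change"] = pct
        log.info("simulate_soma: percent change %.2f%% over ages %s-%s",
                 pct, cfg["soma"]["ages"][0], cfg["soma"]["ages"][-1])

    manifest.pop("_datasets", None)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["out_dir"] = str(out)
    return manifest


def _long_to_dataset(long: pd.DataFrame, scale: str) -> sd.ExpressionDataset:
    expr = long.pivot(index="gene", columns="sample_id", values="expression")
    meta = (
        long.drop_duplicates("sample_id")
        .set_index("sample_id")[["age", "region", "donor", "sex", "RIN"]]
    )
    meta = meta.loc[expr.columns]
    return sd.ExpressionDataset(expression=expr, samples=meta, scale=scale)
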