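"""End-to-end orchestration: simulate, analyse, report.

Ties the stages together behind a single :class:`RunConfig`: respirometry
processing, AICc-selected scaling models for metabolic rate, feeding rate
and energetic efficiency, pairwise genetic differentiation (Table-shaped
output), and genotype clustering. Every stochastic step draws from seeds
recorded in the config, so a rerun with the same config reproduces every
table byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, efficiency, feeding, genepop, popgen, respirometry, scaling, synth
from .constants import R2_QC_THRESHOLD

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a full run needs: paths, constants, seeds, modes."""

    workdir: str = "thermotrout_run"
    seed: int = 20180520

    # respirometry
    chamber_volume_L: float = 7.2
    acclimation_min: float = 30.0
    analysis_min: float = 120.0
    r2_threshold: float = R2_QC_THRESHOLD

    # prey energetics [mean individual dry mass mg, J per mg]; site-specific,
    # so override from measurements where available
    prey_energetics: dict = field(
        default_factory=lambda: {
            "Radix balthica": [5.0, 18.0],
            "Simulium vittatum": [1.5, 22.0],
        }
    )

    # popgen settings
    n_bootstrap: int = 10_000
    dememorisation: int = 10_000
    batches: int = 100
    iter_per_batch: int = 5_000

    # clustering settings
    xval_repeats: int = 200
    kmeans_repeats: int = 20
    k_max: int = 7

    # 'pooled' = two-level cold/warm source factor; 'streams' = three-level
    source_mode: str = "pooled"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


# ---------------------------------------------------------------------------
# file formats (long respirometry CSV, metadata CSV, trials CSV)


def write_respirometry_csv(traces: list[list[respirometry.OxygenTrace]], path) -> None:
    rows = []
    for run_idx, run in enumerate(traces):
        for tr in run:
            for t, do, tc in zip(tr.timestamps, tr.do_mgL, tr.temp_C):
                rows.append(
                    {
                        "run_id": run_idx,
                        "chamber_id": tr.chamber_id,
                        "fish_id": tr.fish_id or "",
                        "minute": t,
                        "do_mgL": do,
                        "temp_C": tc,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_respirometry_csv(path) -> list[list[respirometry.OxygenTrace]]:
    df = pd.read_csv(path, keep_default_na=False)
    runs = []
    for _, run_df in df.groupby("run_id"):
        run = []
        for chamber, ch_df in run_df.groupby("chamber_id", sort=False):
            fish = str(ch_df["fish_id"].iloc[0])
            run.append(
                respirometry.OxygenTrace(
                    chamber_id=str(chamber),
                    fish_id=fish or None,
                    timestamps=ch_df["minute"].to_numpy(float),
                    do_mgL=ch_df["do_mgL"].to_numpy(float),
                    temp_C=ch_df["temp_C"].to_numpy(float),
                )
            )
        runs.append(run)
    return runs


def read_trials_csv(path) -> list[feeding.FeedingTrial]:
    df = pd.read_csv(path)
    return [
        feeding.FeedingTrial(
            fish_id=str(r.fish_id),
            prey_taxon=str(r.prey_taxon),
            n_offered=int(r.n_offered),
            n_eaten=int(r.n_eaten),
            duration_h=float(r.duration_h),
            trial_temp_C=float(r.trial_temp_C),
        )
        for r in df.itertuples()
    ]


def write_trials_csv(trials: list[feeding.FeedingTrial], path) -> None:
    pd.DataFrame([dataclasses.asdict(t) for t in trials]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# stages


def simulate(config: RunConfig, gen_config: synth.GeneratorConfig | None = None) -> Path:
    """Generate all synthetic inputs into the workdir."""
    work = Path(config.workdir)
    work.mkdir(parents=True, exist_ok=True)
    gc = gen_config or synth.GeneratorConfig(seed=config.seed)
    study = synth.generate_study(gc)
    study["cohort"].to_csv(work / "metadata.csv", index=False)
    write_respirometry_csv(study["respirometry"], work / "respirometry.csv")
    write_trials_csv(study["feeding_trials"], work / "trials.csv")
    genepop.write_genepop(study["genotypes"], work / "genotypes.gen")
    (work / "manifest.json").write_text(json.dumps(study["manifest"], indent=2))
    return work


def run_respirometry(config: RunConfig) -> pd.DataFrame:
    """Process every run; write rates CSV and an exclusion log."""
    work = Path(config.workdir)
    meta = pd.read_csv(work / "metadata.csv")
    specs = {
        str(r.fish_id): respirometry.ChamberSpec(config.chamber_volume_L, float(r.mass_mg))
        for r in meta.itertuples()
    }
    runs = read_respirometry_csv(work / "respirometry.csv")
    records, log = [], {"runs": len(runs), "excluded": []}
    for run in runs:
        result = respirometry.process_run(
            run, specs, config.acclimation_min, config.analysis_min
        )
        log["excluded"].extend(result.excluded_ids)
        records.extend(dataclasses.asdict(r) for r in result.rates)
    df = pd.DataFrame(records)
    df.to_csv(work / "metabolic_rates.csv", index=False)
    log["n_rates"] = len(df)
    log["n_excluded"] = len(log["excluded"])
    (work / "respirometry_log.json").write_text(json.dumps(log, indent=2))
    return df


def _source_column(meta: pd.DataFrame, mode: str) -> pd.Series:
    return meta["regime"] if mode == "pooled" else meta["source_stream"]


def run_metabolic_fit(config: RunConfig) -> scaling.ScalingFit:
    work = Path(config.workdir)
    rates = pd.read_csv(work / "metabolic_rates.csv")
    rates = rates[rates["qc_pass"]]
    meta = pd.read_csv(work / "metadata.csv").set_index("fish_id")
    meta["source"] = _source_column(meta, config.source_mode)
    joined = rates.join(meta, on="fish_id")
    rows = scaling.make_design(
        joined["mass_mg"], joined["mean_temp_C"], joined["source"],
        response=joined["rate_mgO2_per_h"],
    )
    best, fits = scaling.fit_all(rows)
    (work / "metabolic_model_table.json").write_text(
        json.dumps(scaling.model_table(fits), indent=2)
    )
    return best


def run_feeding_fits(config: RunConfig) -> dict[str, scaling.ScalingFit]:
    work = Path(config.workdir)
    meta = pd.read_csv(work / "metadata.csv")
    meta["source"] = _source_column(meta, config.source_mode)
    meta = meta.rename(columns={"regime": "_regime"}).rename(
        columns={"source": "regime"}
    )
    trials = read_trials_csv(work / "trials.csv")
    out = {}
    for taxon in sorted({t.prey_taxon for t in trials}):
        best, fits = feeding.fit_feeding_model(trials, meta, prey_taxon=taxon)
        out[taxon] = best
        safe = taxon.replace(" ", "_")
        (work / f"feeding_model_table_{safe}.json").write_text(
            json.dumps(scaling.model_table(fits), indent=2)
        )
    return out


def run_efficiency(config: RunConfig) -> dict[str, scaling.ScalingFit]:
    """Efficiency records per fish and prey, then their scaling fits."""
    work = Path(config.workdir)
    rates_df = pd.read_csv(work / "metabolic_rates.csv")
    rates_df = rates_df[rates_df["qc_pass"]]
    meta = pd.read_csv(work / "metadata.csv")
    meta["source"] = _source_column(meta, config.source_mode)
    meta_fit = meta.rename(columns={"regime": "_regime"}).rename(
        columns={"source": "regime"}
    )
    feeding_fits = run_feeding_fits(config)
    mass = meta.set_index("fish_id")["mass_mg"]

    records, fits_out = [], {}
    for taxon, ffit in feeding_fits.items():
        prey = efficiency.PreyEnergetics(taxon, *config.prey_energetics[taxon])
        recs = []
        for r in rates_df.itertuples():
            met = respirometry.MetabolicRate(
                fish_id=str(r.fish_id),
                rate_mgO2_per_h=float(r.rate_mgO2_per_h),
                rate_J_per_h=float(r.rate_J_per_h),
                mean_temp_C=float(r.mean_temp_C),
                r2=float(r.r2),
                qc_pass=bool(r.qc_pass),
            )
            source = meta_fit.set_index("fish_id").loc[str(r.fish_id), "regime"]
            F = scaling.predict(
                ffit, float(mass[str(r.fish_id)]), met.mean_temp_C, str(source)
            )
            recs.append(efficiency.energetic_efficiency(met, F, prey))
        records.extend(dataclasses.asdict(x) for x in recs)
        temps = {r.fish_id: r.mean_temp_C for r in rates_df.itertuples()}
        best, fits = efficiency.fit_efficiency_model(
            recs, meta_fit, temps_C=temps, prey_taxon=taxon
        )
        fits_out[taxon] = best
        safe = taxon.replace(" ", "_")
        (work / f"efficiency_model_table_{safe}.json").write_text(
            json.dumps(scaling.model_table(fits), indent=2)
        )
    pd.DataFrame(records).to_csv(work / "efficiency_records.csv", index=False)
    return fits_out


def run_popgen(config: RunConfig) -> pd.DataFrame:
    """Pairwise differentiation table: theta, D_EST, CIs, exact test."""
    work = Path(config.workdir)
    table = genepop.read_genepop(work / "genotypes.gen")
    pops = table.populations
    comparisons = [(a, b) for i, a in enumerate(pops) for b in pops[i + 1 :]]
    if len(pops) > 2:
        warm = [p for p in pops if p != pops[0]]
        pooled = popgen.pool_populations(table, {p: "warm" for p in warm})
        comparisons_tables = [(table, c) for c in comparisons]
        comparisons_tables.append((pooled, (pops[0], "warm")))
    else:
        comparisons_tables = [(table, c) for c in comparisons]

    rows = []
    for tab, pair in comparisons_tables:
        theta = popgen.differentiation_with_ci(
            tab, pair, "theta", n_boot=config.n_bootstrap, seed=config.seed
        )
        dest = popgen.differentiation_with_ci(
            tab, pair, "d_est", n_boot=config.n_bootstrap, seed=config.seed + 1
        )
        exact = popgen.exact_genic_test(
            tab,
            pair,
            dememorisation=config.dememorisation,
            batches=config.batches,
            iter_per_batch=config.iter_per_batch,
            seed=config.seed + 2,
        )
        rows.append(
            {
                "comparison": f"{pair[0]} v {pair[1]}",
                "theta": theta.estimate,
                "theta_ci5": theta.ci_low_5pct,
                "theta_ci95": theta.ci_high_95pct,
                "d_est": dest.estimate,
                "d_est_ci5": dest.ci_low_5pct,
                "d_est_ci95": dest.ci_high_95pct,
                "chi2": exact.chi2,
                "df": exact.df,
                "p_value": exact.p_combined,
                "loci_excluded": ";".join(theta.loci_excluded),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(work / "differentiation_table.csv", index=False)
    return df


def run_clustering(config: RunConfig) -> dict:
    """PCA, DAPC (optimised PC count + cross-validation) and k-means/BIC."""
    work = Path(config.workdir)
    table = genepop.read_genepop(work / "genotypes.gen")
    groups = np.asarray(table.pop_labels)
    _, pca = clustering.encode_and_pca(table)
    n95 = pca.n_pcs_for_variance(0.95)
    n_pcs = clustering.select_n_pcs(
        pca.scores[:, :n95], groups, mode="max_of_both", seed=config.seed
    )
    model = clustering.dapc_train(pca.scores, groups, n_pcs)
    xval = clustering.dapc_crossvalidate(
        pca.scores, groups, n_pcs, n_repeats=config.xval_repeats, seed=config.seed
    )
    solutions = clustering.kmeans_bic(
        pca.scores,
        n_pcs=n95,
        k_range=range(1, config.k_max + 1),
        n_repeats=config.kmeans_repeats,
        seed=config.seed,
    )
    best = clustering.best_k(solutions)
    sizes = [int((groups == g).sum()) for g in np.unique(groups)]
    summary = {
        "n_pcs_95pct_variance": n95,
        "n_pcs_retained": n_pcs,
        "variance_retained": float(np.sum(pca.variance_fractions[:n_pcs])),
        "training_accuracy": model.training_accuracy,
        "overall_training_accuracy": model.overall_training_accuracy,
        "xval_overall_accuracy": xval.overall_accuracy,
        "xval_per_group_accuracy": xval.per_group_accuracy,
        "null_expected_accuracy": clustering.null_accuracy(sizes),
        "bic_by_k": {s.k: s.bic for s in solutions},
        "stability_by_k": {s.k: s.repeat_stability for s in solutions},
        "best_k": best.k,
    }
    pd.DataFrame(
        {
            "individual": table.individuals,
            "prior_group": groups,
            "posterior_call": model.assign(pca.scores),
            "kmeans_cluster": best.assignments,
        }
    ).to_csv(work / "assignments.csv", index=False)
    (work / "clustering_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def run_all(config: RunConfig) -> dict:
    """Run every stage in order; inputs must already exist (or simulate first)."""
    results = {}
    results["respirometry"] = run_respirometry(config)
    results["metabolic_fit"] = run_metabolic_fit(config)
    results["efficiency_fits"] = run_efficiency(config)
    results["differentiation"] = run_popgen(config)
    results["clustering"] = run_clustering(config)
    logger.info("run complete: outputs in %s", config.workdir)
    return results
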