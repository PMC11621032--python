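"""End-to-end harness: simulate, fit, analyze, and benchmark.

These functions are the scriptable surface of the package (there is no
shell entry point; see the examples/ directory for narrative usage).  Each
run is reproducible from its config + seed; ``run_fit`` writes all bundles
plus a structured run log with ELBO checkpoints.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cv_io
from . import manifold as mfl
from . import posterior as pst
from . import simulate as sim
from . import velocity as vel
from .config import RunConfig
from .containers import CountDataset

__all__ = ["run_simulate", "run_fit", "run_benchmark"]


def run_simulate(config: RunConfig, outdir: str | Path) -> Path:
    """Simulate a structured dataset and write it with its truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data, truth = sim.sample_dataset(
        config.sim_n_cells, config.sim_n_genes, omega_gt=config.sim_omega,
        seed=config.seed,
    )
    path = outdir / "simulated.loom"
    cv_io.write_dataset(data, path, fmt="loom")
    pd.DataFrame(
        {
            "cell_id": data.cell_ids,
            "phi_true": truth.phi,
            "is_cycling": truth.is_cycling,
        }
    ).to_csv(outdir / "truth_cells.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "gene_id": data.gene_ids,
            "nu0": truth.nu[:, 0],
            "nu1_cos": truth.nu[:, 1],
            "nu1_sin": truth.nu[:, 2],
            "log_beta": truth.kin.log_beta,
            "log_gamma": truth.kin.log_gamma,
            "alpha_s": truth.alpha.alpha_s,
            "alpha_u": truth.alpha.alpha_u,
        }
    ).to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    (outdir / "truth_scalars.json").write_text(
        json.dumps({"omega": list(map(float, truth.nu_omega)), "seed": truth.seed})
    )
    return path


def run_fit(config: RunConfig, dataset: CountDataset | str | Path, outdir: str | Path) -> dict:
    """Filters -> manifold learning -> velocity learning -> posterior analysis."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    if not isinstance(dataset, CountDataset):
        dataset = cv_io.read_dataset(dataset)
    stage = "filtering"
    try:
        gene_set = cv_io.load_gene_set(config.gene_set) if config.gene_set else None
        data, report = cv_io.filter_genes(
            dataset, gene_set, min_mean_u=config.min_mean_u, min_mean_s=config.min_mean_s
        )
        (outdir / "filter_report.json").write_text(report.to_json())

        stage = "manifold learning"
        priors = mfl.init_priors(data, n_harmonics=config.n_harmonics, epsilon=config.epsilon)
        man = mfl.fit_manifold(
            data, priors, n_steps=config.n_steps_manifold, seed=config.seed,
            lr_start=config.lr_start, lr_end=config.lr_end, early_stop=config.early_stop,
        )

        stage = "velocity learning"
        guide = config.guide if config.guide in ("meanfield", "lrmn") else "meanfield"
        fit = vel.fit_velocity(
            data, man, model=config.model, guide=guide,
            n_steps=config.n_steps_velocity, seed=config.seed,
            n_posterior_samples=config.n_posterior_samples,
            early_stop=config.early_stop,
        )
        if config.guide == "mcmc":
            fit = vel.fit_velocity_mcmc(
                data, man, model=config.model, init=fit, seed=config.seed
            )
        # direction around the circle is a gauge choice; report it so the
        # speed is positive
        fit, man = vel.orient_positive(fit, man)
        cv_io.save_manifold_fit(man, outdir / "manifold")
        cv_io.save_velocity_fit(fit, outdir / "velocity")

        stage = "posterior analysis"
        est = pst.period(
            fit.samples, mean_half_life_hours=config.mean_half_life_hours,
            mode=config.timescale_mode, lo=config.ci_lo, hi=config.ci_hi,
        )
        nonzero = pst.test_nonzero(fit, 0, lo=config.ci_lo, hi=config.ci_hi,
                                   mode=config.timescale_mode)
        result = {
            "period_hours": {"mean": est.mean, "ci_lo": est.ci_lo, "ci_hi": est.ci_hi,
                             "n_excluded": est.n_excluded},
            "nonzero_velocity": nonzero,
            "n_genes_fit": data.n_genes,
        }
        if len(fit.condition_labels) == 2:
            result["condition_comparison"] = pst.compare_conditions(
                fit, fit.condition_labels[0], fit.condition_labels[1],
                lo=config.ci_lo, hi=config.ci_hi, mode=config.timescale_mode,
            )
        (outdir / "report.json").write_text(json.dumps(_jsonable(result)))
    except Exception as err:  # annotate with the failing stage
        raise RuntimeError(f"pipeline failed during {stage}: {err}") from err
    log = {
        "config": json.loads(json.dumps(config.__dict__, default=str)),
        "runtime_s": time.time() - t0,
        "elbo_checkpoints_manifold": list(map(float, man.elbo_trace[::100])),
        "elbo_checkpoints_velocity": list(map(float, fit.elbo_trace[::100]))
        if fit.elbo_trace.size else [],
    }
    (outdir / "run_log.json").write_text(json.dumps(log))
    return result


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items() if k != "fits"}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    return obj


def _one_recovery(n_cells, n_genes, omega, seed, n_steps_manifold, n_steps_velocity):
    data, truth = sim.sample_dataset(n_cells, n_genes, omega_gt=omega, seed=seed)
    priors = mfl.init_priors(data)
    man = mfl.fit_manifold(data, priors, n_steps=n_steps_manifold, seed=seed)
    man = mfl.align_to_truth(man, truth.phi)
    cc = sim.circular_corrcoef(man.phi_mean, truth.phi)
    fit = vel.fit_velocity(data, man, n_steps=n_steps_velocity, seed=seed)
    err = sim.velocity_percent_error(float(fit.nu_omega[0, 0]), omega) if omega else np.nan
    return cc, err, fit


def run_benchmark(
    config: RunConfig,
    cells_grid=(100, 500, 3000),
    genes_grid=(100, 300),
    omega_sweep=(0.1, 0.4, 0.8, 1.5),
    contamination=(0, 50, 100),
    n_replicates: int = 3,
    n_steps_manifold: int | None = None,
    n_steps_velocity: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Scaled-down sensitivity grids: dataset size, speed sweep, contamination.

    Returns three tidy tables with replicate seeds recorded.  Step counts
    default to the config values; pass smaller ones for quick runs.
    """
    nm = n_steps_manifold or config.n_steps_manifold
    nv = n_steps_velocity or config.n_steps_velocity
    rows_size = []
    for nc in cells_grid:
        for ng in genes_grid:
            for rep in range(n_replicates):
                seed = config.seed + 1000 * rep + 17
                cc, err, _ = _one_recovery(nc, ng, config.sim_omega, seed, nm, nv)
                rows_size.append(
                    {"n_cells": nc, "n_genes": ng, "replicate": rep, "seed": seed,
                     "circular_corr": cc, "velocity_pct_error": err}
                )
    rows_sweep = []
    for omega in omega_sweep:
        for rep in range(n_replicates):
            seed = config.seed + 1000 * rep + 31
            cc, err, _ = _one_recovery(
                config.sim_n_cells, config.sim_n_genes, omega, seed, nm, nv
            )
            rows_sweep.append(
                {"omega_gt": omega, "replicate": rep, "seed": seed,
                 "circular_corr": cc, "velocity_pct_error": err}
            )
    rows_cont = []
    for ratio in contamination:
        for rep in range(n_replicates):
            seed = config.seed + 1000 * rep + 47
            data, truth = sim.sample_dataset(
                config.sim_n_cells, config.sim_n_genes, omega_gt=config.sim_omega,
                seed=seed,
            )
            data, truth = sim.spike_noncycling(data, truth, ratio)
            priors = mfl.init_priors(data)
            man = mfl.fit_manifold(data, priors, n_steps=nm, seed=seed)
            man = mfl.align_to_truth(man, truth.phi)
            cyc = truth.is_cycling
            cc = sim.circular_corrcoef(man.phi_mean[cyc], truth.phi[cyc])
            fit = vel.fit_velocity(data, man, n_steps=nv, seed=seed)
            err = sim.velocity_percent_error(float(fit.nu_omega[0, 0]), config.sim_omega)
            rows_cont.append(
                {"noncycling_per_100": ratio, "replicate": rep, "seed": seed,
                 "circular_corr_cycling": cc, "velocity_pct_error": err}
            )
    return {
        "size_grid": pd.DataFrame(rows_size),
        "omega_sweep": pd.DataFrame(rows_sweep),
        "contamination": pd.DataFrame(rows_cont),
    }
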