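"""End-to-end study pipeline on synthetic data.

Reproduces the full study design: simulate a breeding program (basis
population tested over five years, three later forward-validation
populations, plus protein-only additional lines), compute across-trial
BLUEs and heritabilities, run marker QC and build the kinship matrix, run
the three validation schemes for every marker strategy, sweep the W-BLUP
inclusion threshold, evaluate the multi-trait information scenarios, and
estimate the response to direct, indirect, marker-assisted and genomic
selection.  Every stage writes tidy CSV/JSON under the output directory and
logs one structured line; a manifest records seeds, sizes, and stages run.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .containers import PhenotypeRecords
from .pheno import fit_across_trials, fit_trial, filter_trials, two_stage_protein
from .qc import compute_kinship, filter_markers, impute_missing, ld_prune
from .response import compare_strategies
from .simulate import (
    SimulationConfig,
    default_major_loci,
    degrade_markers,
    glu_marker_ids,
    simulate_genome,
    simulate_traits,
    simulate_trials,
)
from .validate import (
    run_inside_trading_suite,
    run_multitrait_scenarios,
    threshold_sweep,
)
from .models import fit_mas, fit_rrblup, fit_selection_index, select_mas_markers

logger = logging.getLogger("wheatgs")

RHEOLOGY_TRAITS = ["WAT", "DEV", "STAB", "FQN", "EXT", "RES", "ENG"]


@dataclass
class PipelineConfig:
    """Study-level configuration (populations, QC thresholds, validation plan)."""

    n_basis: int = 120
    n_forward: tuple[int, int, int] = (40, 40, 50)
    n_additional: int = 120
    n_markers: int = 1200
    n_chromosomes: int = 21
    trials_per_population: int = 8
    lines_per_trial: int = 30
    n_checks: int = 4
    check_reps_per_trial: int = 3
    degrade_missing_rate: float = 0.02
    call_rate_min: float = 0.90
    maf_min: float = 0.05
    missing_max: float = 0.10
    r2_max: float = 0.8
    h2_trial_min: float = 0.1
    reps_validation: int = 20
    reps_multitrait: int = 10
    mt_trait: str = "STAB"
    response_fractions: tuple = (0.10, 0.20, 0.30, 0.40, 0.50)
    seed: int = 0
    out_dir: str = "results/study"

    @property
    def n_lines_total(self) -> int:
        return self.n_basis + sum(self.n_forward) + self.n_additional


def _log_stage(name: str, t0: float, **counts) -> None:
    extra = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s elapsed=%.1fs %s", name, time.time() - t0, extra)


def _population_trials(cfg: PipelineConfig, sim: SimulationConfig, truth, lines,
                       first_year: int, n_years: int, n_trials: int, stream: str,
                       traits=None, entry_reps: int = 1) -> pd.DataFrame:
    """Simulate trials for one population (re-using the global truth)."""
    sub_truth = type(truth)(true_bv=truth.true_bv.loc[lines], qtl_effects=truth.qtl_effects)
    pop_cfg = SimulationConfig(
        n_lines=len(lines),
        n_markers=sim.n_markers,
        n_chromosomes=sim.n_chromosomes,
        trait_names=sim.trait_names,
        genetic_cov=sim.genetic_cov,
        residual_cov=sim.residual_cov,
        trait_means=sim.trait_means,
        major_loci=[],
        n_trials=n_trials,
        lines_per_trial=min(cfg.lines_per_trial, len(lines)),
        n_checks=min(cfg.n_checks, max(1, len(lines) // 10)),
        check_reps_per_trial=cfg.check_reps_per_trial,
        entry_reps=entry_reps,
        n_years=n_years,
        first_year=first_year,
        seed=int(np.random.SeedSequence([sim.seed, hashcode(stream)]).generate_state(1)[0] % 2**31),
    )
    ph = simulate_trials(sub_truth, pop_cfg)
    df = ph.records
    if traits is not None:
        df = df[df["trait"].isin(traits)].reset_index(drop=True)
    return df


def hashcode(stream: str) -> int:
    import zlib

    return zlib.crc32(stream.encode()) % (2**31)


def run_study(cfg: PipelineConfig) -> dict:
    """Run the whole synthetic study; returns a manifest dict (also written)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    manifest: dict = {"config": asdict(cfg), "stages": [], "seeds": {"root": cfg.seed}}

    # ---- stage 1: simulate ------------------------------------------------
    t0 = time.time()
    base = SimulationConfig(
        n_lines=cfg.n_lines_total, n_markers=cfg.n_markers,
        n_chromosomes=cfg.n_chromosomes, seed=cfg.seed,
        n_trials=cfg.trials_per_population, lines_per_trial=cfg.lines_per_trial,
        n_checks=cfg.n_checks, check_reps_per_trial=cfg.check_reps_per_trial,
    )
    sim = SimulationConfig(**{**asdict_shallow(base), "major_loci": default_major_loci(base)})
    markers, marker_map = simulate_genome(sim)
    truth = simulate_traits(markers, sim)

    lines = list(truth.true_bv.index)
    n_b = cfg.n_basis
    pops = {"basis": lines[:n_b]}
    cursor = n_b
    for i, nf in enumerate(cfg.n_forward):
        pops[f"vp{2014 + i}"] = lines[cursor : cursor + nf]
        cursor += nf
    pops["additional"] = lines[cursor:]

    frames = [
        _population_trials(cfg, sim, truth, pops["basis"], 2009, 5,
                           cfg.trials_per_population, "basis"),
    ]
    for i in range(3):
        frames.append(
            _population_trials(cfg, sim, truth, pops[f"vp{2014 + i}"], 2014 + i, 1,
                               max(2, cfg.trials_per_population // 3), f"vp{i}")
        )
    frames.append(
        _population_trials(cfg, sim, truth, pops["additional"], 2009, 5,
                           cfg.trials_per_population, "additional", traits=["PROT"], entry_reps=2)
    )
    pheno = PhenotypeRecords(pd.concat(frames, ignore_index=True))
    raw = degrade_markers(markers, missing_rate=cfg.degrade_missing_rate,
                          seed=cfg.seed + 1)
    io.write_genotypes(raw, out / "genotypes.tsv")
    io.write_map(marker_map, out / "map.tsv")
    io.write_phenotypes(pheno, out / "phenotypes.csv")
    io.write_truth(truth.true_bv, out / "truth.csv")
    io.write_json({k: v for k, v in (("populations", {p: l for p, l in pops.items()}),)},
                  out / "populations.json")
    manifest["stages"].append("simulate")
    manifest["populations"] = {p: len(l) for p, l in pops.items()}
    _log_stage("simulate", t0, lines=len(lines), markers=markers.n_markers,
               records=len(pheno.records))

    # ---- stage 2: phenotypic analysis ------------------------------------
    t0 = time.time()
    blues_by_pop: dict[str, pd.DataFrame] = {}
    components = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pop in [p for p in pops if p != "additional"]:
            pop_records = pheno.records[pheno.records["line"].isin(set(pops[pop]))]
            cols = {}
            for trait in ["PROT"] + RHEOLOGY_TRAITS:
                df = pop_records[pop_records["trait"] == trait]
                fits = [fit_trial(t, trait) for _, t in df.groupby("trial")]
                kept = set(filter_trials(fits, cfg.h2_trial_min))
                if kept:
                    df = df[df["trial"].isin(kept)]
                else:
                    warnings.warn(f"{pop}/{trait}: no trial passed h2 filter; keeping all")
                res = fit_across_trials(df, trait)
                cols[trait] = res.blues
                components.append(dict(population=pop, trait=trait,
                                       sigma_G2=res.sigma_G2, sigma_e2=res.sigma_e2,
                                       h2=res.h2, n_trials=res.n_trials))
            blues_by_pop[pop] = pd.DataFrame(cols)
        protein_two_stage = two_stage_protein(
            pheno.records[pheno.records["line"].isin(set(pops["additional"]))]
        )
    protein_additional = (
        pd.concat([r.blues for r in protein_two_stage.values()], axis=1).mean(axis=1)
        if protein_two_stage else pd.Series(dtype=float)
    )
    comp_df = pd.DataFrame(components)
    comp_df.to_csv(out / "variance_components.csv", index=False)
    all_blues = pd.concat(
        [df.assign(population=p) for p, df in blues_by_pop.items()]
    )
    io.write_blues(all_blues.drop(columns="population"), out / "blues.csv")
    manifest["stages"].append("pheno")
    _log_stage("pheno", t0, populations=len(blues_by_pop),
               protein_additional=len(protein_additional))

    # ---- stage 3: marker QC ----------------------------------------------
    t0 = time.time()
    filtered, qc_report = filter_markers(raw, cfg.call_rate_min, cfg.maf_min,
                                         cfg.missing_max)
    imputed = impute_missing(filtered, marker_map)
    pruned = ld_prune(imputed, r2_max=cfg.r2_max, seed=cfg.seed + 2,
                      marker_map=marker_map)
    K = compute_kinship(pruned)
    io.write_json(qc_report, out / "qc_report.json")
    io.write_kinship(K, out / "kinship.tsv")
    manifest["stages"].append("qc")
    manifest["qc"] = qc_report
    _log_stage("qc", t0, retained=pruned.n_markers)

    glu = [m for m in glu_marker_ids(sim) if m in set(pruned.marker_ids)]
    basis = blues_by_pop["basis"]
    forward_rheo = {
        p: blues_by_pop[p] for p in pops if p.startswith("vp")
    }

    # ---- stage 4: single-trait validation schemes -------------------------
    t0 = time.time()
    suites = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for trait in [cfg.mt_trait]:
            suite = run_inside_trading_suite(
                basis[trait].dropna(), pruned, marker_map, K,
                {p: f[trait].dropna() for p, f in forward_rheo.items()},
                glu_ids=glu, reps=cfg.reps_validation, seed=cfg.seed + 3,
            )
            suites.append(suite.assign(trait=trait))
    suite_df = pd.concat(suites, ignore_index=True)
    suite_df.to_csv(out / "validation_schemes.csv", index=False)
    manifest["stages"].append("validation_schemes")
    _log_stage("validation_schemes", t0, rows=len(suite_df))

    # ---- stage 5: threshold sweep ----------------------------------------
    t0 = time.time()
    trait = cfg.mt_trait
    h2_trait = float(comp_df.query("population=='basis' and trait==@trait")["h2"].iloc[0])
    h2_trait = min(max(h2_trait, 0.05), 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sweep = threshold_sweep(
            basis[trait].dropna(), pruned, glu,
            {p: f[trait].dropna() for p, f in forward_rheo.items()},
            h2=h2_trait, seed=cfg.seed + 4, ev_reps=25,
        )
    sweep.to_csv(out / "threshold_sweep.csv", index=False)
    manifest["stages"].append("threshold_sweep")
    manifest["operating_threshold_pct"] = sweep.attrs["operating_threshold_pct"]
    _log_stage("threshold_sweep", t0, thresholds=sweep["threshold_pct"].nunique())

    # ---- stage 6: multi-trait scenarios ----------------------------------
    t0 = time.time()
    mt_population = pd.concat([basis] + list(forward_rheo.values()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scen = run_multitrait_scenarios(
            mt_population[trait].dropna(), mt_population["PROT"].dropna(), K,
            reps=cfg.reps_multitrait, seed=cfg.seed + 5,
        )
    scen.to_csv(out / "multitrait_scenarios.csv", index=False)
    manifest["stages"].append("multitrait_scenarios")
    _log_stage("multitrait_scenarios", t0, rows=len(scen))

    # ---- stage 7: forward prediction + selection response -----------------
    t0 = time.time()
    h2_table = {
        r["trait"]: min(max(r["h2"] if r["h2"] is not None else 0.5, 0.0), 1.0)
        for _, r in comp_df.query("population=='basis'").iterrows()
    }
    response_frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pop, fblues in forward_rheo.items():
            gebv_sets = {}
            gs_base, gs_enh, mas_set = {}, {}, {}
            for tr in RHEOLOGY_TRAITS:
                train = basis[tr].dropna()
                gs_base[tr] = fit_rrblup(train, pruned)[0].gebv
                sel = select_mas_markers("glu_only", glu_ids=glu)
                mas_set[tr] = fit_mas(train, pruned, sel).gebv
                gs_enh[tr] = fit_selection_index(
                    train, pd.concat([basis["PROT"].dropna(), protein_additional]), K,
                    fixed_marker_calls=pruned.calls[glu] if glu else None,
                )[0].gebv
            gebv_sets["gs_baseline"] = pd.DataFrame(gs_base)
            gebv_sets["gs_enhanced"] = pd.DataFrame(gs_enh)
            gebv_sets["mas"] = pd.DataFrame(mas_set)
            resp = compare_strategies(
                fblues[RHEOLOGY_TRAITS].dropna(),
                gebv_sets,
                fblues["PROT"].dropna(),
                h2_table,
                fractions=cfg.response_fractions,
            )
            response_frames.append(resp.assign(population=pop))
    resp_df = pd.concat(response_frames, ignore_index=True)
    resp_df.to_csv(out / "selection_response.csv", index=False)
    manifest["stages"].append("selection_response")
    _log_stage("selection_response", t0, rows=len(resp_df))

    manifest["seeds"].update({
        "degrade": cfg.seed + 1, "ld_prune": cfg.seed + 2,
        "validation": cfg.seed + 3, "sweep": cfg.seed + 4,
        "multitrait": cfg.seed + 5,
    })
    manifest["elapsed_s"] = round(time.time() - t_start, 1)
    io.write_json(manifest, out / "manifest.json")
    return manifest


def asdict_shallow(cfg: SimulationConfig) -> dict:
    d = dict(cfg.__dict__)
    return d
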