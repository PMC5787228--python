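"""Simulate the breeding program and write its raw data files.

One genome for all lines; a basis population phenotyped in 2009-2013-style
trials, three later forward-validation populations (one year each), and
additional lines with protein data only.  Genotypes are lightly degraded
(2 % missing calls) so the QC step has real work to do.

Run:  python analysis/01_simulate_program.py [--seed 0] [--out results/study]
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from wheatgs import io
from wheatgs.containers import PhenotypeRecords
from wheatgs.pipeline import PipelineConfig, _population_trials
from wheatgs.simulate import (
    SimulationConfig, default_major_loci, degrade_markers, simulate_genome,
    simulate_traits,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results/study")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    cfg = PipelineConfig(seed=args.seed, out_dir=str(out))
    base = SimulationConfig(
        n_lines=cfg.n_lines_total, n_markers=cfg.n_markers,
        n_chromosomes=cfg.n_chromosomes, seed=cfg.seed,
        n_trials=cfg.trials_per_population, lines_per_trial=cfg.lines_per_trial,
        n_checks=cfg.n_checks, check_reps_per_trial=cfg.check_reps_per_trial,
    )
    sim = SimulationConfig(**{**dict(base.__dict__), "major_loci": default_major_loci(base)})
    markers, marker_map = simulate_genome(sim)
    truth = simulate_traits(markers, sim)

    lines = list(truth.true_bv.index)
    pops, cursor = {"basis": lines[: cfg.n_basis]}, cfg.n_basis
    for i, nf in enumerate(cfg.n_forward):
        pops[f"vp{2014 + i}"] = lines[cursor : cursor + nf]
        cursor += nf
    pops["additional"] = lines[cursor:]

    frames = [_population_trials(cfg, sim, truth, pops["basis"], 2009, 5,
                                 cfg.trials_per_population, "basis")]
    for i in range(3):
        frames.append(_population_trials(
            cfg, sim, truth, pops[f"vp{2014 + i}"], 2014 + i, 1,
            max(2, cfg.trials_per_population // 3), f"vp{i}"))
    frames.append(_population_trials(cfg, sim, truth, pops["additional"], 2009, 5,
                                     cfg.trials_per_population, "additional",
                                     traits=["PROT"], entry_reps=2))
    pheno = PhenotypeRecords(pd.concat(frames, ignore_index=True))
    raw = degrade_markers(markers, missing_rate=cfg.degrade_missing_rate,
                          seed=cfg.seed + 1)

    io.write_genotypes(raw, out / "genotypes.tsv")
    io.write_map(marker_map, out / "map.tsv")
    io.write_phenotypes(pheno, out / "phenotypes.csv")
    io.write_truth(truth.true_bv, out / "truth.csv")
    (out / "populations.json").write_text(json.dumps({"populations": pops}, indent=2))
    print(f"Simulated {len(lines)} lines ({ {p: len(l) for p, l in pops.items()} }), "
          f"{markers.n_markers} markers, {len(pheno.records)} phenotype records.")
    print(f"Files under {out}/: genotypes.tsv map.tsv phenotypes.csv truth.csv")


if __name__ == "__main__":
    main()
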