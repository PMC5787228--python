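"""Across-trial BLUEs, variance components, and heritabilities per population.

For every population and trait: per-trial fits, the h2 >= 0.1 trial filter,
then the across-trial mixed model with fixed trial effects.  The additional
protein-only lines go through the two-stage protein analysis (stage-1 trial
BLUEs, stage-2 per-year across-trial model with the stricter h2 > 0.3
filter).

Run after 01:  python analysis/02_phenotypic_analysis.py [--dir results/study]
"""

import argparse
import json
import warnings
from pathlib import Path

import pandas as pd

from wheatgs import io
from wheatgs.pheno import fit_across_trials, fit_trial, filter_trials, two_stage_protein
from wheatgs.pipeline import RHEOLOGY_TRAITS


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--dir", default="results/study")
    args = ap.parse_args()
    out = Path(args.dir)
    pheno = io.read_phenotypes(out / "phenotypes.csv")
    pops = json.loads((out / "populations.json").read_text())["populations"]

    blues, components = {}, []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pop, members in pops.items():
            if pop == "additional":
                continue
            records = pheno.records[pheno.records["line"].isin(set(members))]
            cols = {}
            for trait in ["PROT"] + RHEOLOGY_TRAITS:
                df = records[records["trait"] == trait]
                fits = [fit_trial(t, trait) for _, t in df.groupby("trial")]
                kept = set(filter_trials(fits, 0.1))
                res = fit_across_trials(
                    df[df["trial"].isin(kept)] if kept else df, trait)
                cols[trait] = res.blues
                components.append(dict(
                    population=pop, trait=trait, sigma_G2=res.sigma_G2,
                    sigma_e2=res.sigma_e2, h2=res.h2, n_trials=res.n_trials))
            blues[pop] = pd.DataFrame(cols)
        extra = pheno.records[pheno.records["line"].isin(set(pops["additional"]))]
        per_year = two_stage_protein(extra)

    comp = pd.DataFrame(components)
    comp.to_csv(out / "variance_components.csv", index=False)
    io.write_blues(pd.concat(blues.values()), out / "blues.csv")
    prot_add = (pd.concat([r.blues for r in per_year.values()], axis=1).mean(axis=1)
                if per_year else pd.Series(dtype=float))
    io.write_blues(prot_add.rename("blue"), out / "blues_protein_additional.csv",
                   trait="PROT")

    print("Across-trial variance components (basis population):")
    print(comp.query("population == 'basis'")
          [["trait", "sigma_G2", "sigma_e2", "h2"]].round(3).to_string(index=False))
    print(f"\nTwo-stage protein analysis retained {len(per_year)} years "
          f"({sorted(per_year)}) for {len(prot_add)} additional lines.")


if __name__ == "__main__":
    main()
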