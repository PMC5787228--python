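"""Marker QC and the genomic relationship matrix.

Applies the call-rate >= 90 % / MAF >= 0.05 / missingness <= 10 % filters,
imputes remaining missing calls per chromosome (iterated conditional
expectation), prunes marker pairs with r^2 > 0.8 (random member dropped,
seeded), and builds K = WW'/(2 sum p(1-p)).

Run after 01:  python analysis/03_marker_qc.py [--dir results/study] [--seed 0]
"""

import argparse
from pathlib import Path

import numpy as np

from wheatgs import io
from wheatgs.qc import compute_kinship, filter_markers, impute_missing, ld_prune, max_pairwise_r2


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--dir", default="results/study")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    out = Path(args.dir)

    raw = io.read_genotypes(out / "genotypes.tsv")
    mmap = io.read_map(out / "map.tsv", raw.marker_ids)
    filtered, report = filter_markers(raw)
    imputed = impute_missing(filtered, mmap)
    pruned = ld_prune(imputed, r2_max=0.8, seed=args.seed + 2, marker_map=mmap)
    K = compute_kinship(pruned)

    io.write_genotypes(pruned, out / "genotypes_qc.tsv")
    io.write_kinship(K, out / "kinship.tsv")
    io.write_json(report, out / "qc_report.json")

    print(f"QC: {report['n_input']} -> {report['n_retained']} after filters "
          f"(call rate {report['n_fail_call_rate']}, missing {report['n_fail_missing']}, "
          f"MAF {report['n_fail_maf']}), {pruned.n_markers} after LD pruning.")
    print(f"Max remaining pairwise r^2: {max_pairwise_r2(pruned):.3f}")
    print(f"Kinship: mean diagonal {np.diag(K.values).mean():.3f} "
          f"(~1+f for inbred lines), denominator {K.denominator:.1f}")


if __name__ == "__main__":
    main()
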