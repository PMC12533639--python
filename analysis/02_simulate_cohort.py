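#!/usr/bin/env python
"""Simulate a six-sample cohort of circle-enriched libraries.

Three low-burden samples (15 circles each, emulating healthy tissue) and
three high-burden samples (50 circles, emulating tissue under replication
stress), all at ~40x coverage per circle with 0.1% substitution errors and
1% linear background.  Truth SAMs and tables go under scratch/cohort/; a
per-sample simulation summary goes to results/.
"""

import os

from eccpipe.genome import read_fasta, read_gff3
from eccpipe.simulate import (
    SimConfig, sample_circles, simulate_reads, write_truth_sam, write_truth_table,
)

FIXDIR = "scratch/fixtures"
OUTDIR = "scratch/cohort"
RESULTS = "results"

GROUPS = {  # sample -> (group, n_circles, seed)
    "low1": ("low_burden", 12, 101),
    "low2": ("low_burden", 15, 102),
    "low3": ("low_burden", 18, 103),
    "high1": ("high_burden", 45, 201),
    "high2": ("high_burden", 50, 202),
    "high3": ("high_burden", 57, 203),
}


def main() -> None:
    assembly = read_fasta(os.path.join(FIXDIR, "reference.fa"))
    annotation = read_gff3(os.path.join(FIXDIR, "genes.gff3"))
    os.makedirs(OUTDIR, exist_ok=True)
    os.makedirs(RESULTS, exist_ok=True)
    rows = []
    for sample, (group, n_circles, seed) in GROUPS.items():
        cfg = SimConfig(n_circles=n_circles, seed=seed, n_read_pairs=0)
        circles = sample_circles(assembly, annotation, cfg)
        cfg.n_read_pairs = int(sum(c.length for c in circles) * 40 / 300)
        result = simulate_reads(assembly, circles, cfg)
        write_truth_sam(result, assembly, os.path.join(OUTDIR, f"{sample}.sam"))
        write_truth_table(result, os.path.join(OUTDIR, f"{sample}.truth.tsv"))
        rows.append((sample, group, n_circles, cfg.n_read_pairs, cfg.seed))
        print(f"{sample} ({group}): {n_circles} circles, "
              f"{cfg.n_read_pairs} read pairs (seed {seed})")
    with open(os.path.join(RESULTS, "cohort_simulation.tsv"), "w") as fh:
        fh.write("sample_id\tgroup\tn_true_circles\tn_read_pairs\tseed\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


if __name__ == "__main__":
    main()
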