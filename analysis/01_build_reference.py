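#!/usr/bin/env python
"""Build the synthetic reference genome and gene annotation.

Generates a seeded 2-chromosome assembly (1 Mb + 2 Mb, GC 0.42) with 40
non-overlapping genes and writes FASTA/GFF3 under scratch/fixtures/ for
the downstream steps, plus a small fixture summary under results/.
"""

import os

from eccpipe.genome import make_annotation, make_reference, write_fasta, write_gff3

SEED = 7
FIXDIR = "scratch/fixtures"
RESULTS = "results"


def main() -> None:
    os.makedirs(FIXDIR, exist_ok=True)
    os.makedirs(RESULTS, exist_ok=True)
    assembly = make_reference(2, [1_000_000, 2_000_000], gc=0.42, seed=SEED)
    annotation = make_annotation(assembly, 40, (2000, 10_000), (2, 5), seed=SEED + 1)
    write_fasta(assembly, os.path.join(FIXDIR, "reference.fa"))
    write_gff3(annotation, os.path.join(FIXDIR, "genes.gff3"))
    with open(os.path.join(RESULTS, "reference_summary.tsv"), "w") as fh:
        fh.write("chrom\tlength_bp\tn_genes\n")
        for chrom, length in assembly.lengths.items():
            n = sum(1 for g in annotation.genes if g.chrom == chrom)
            fh.write(f"{chrom}\t{length}\t{n}\n")
    print(f"reference: {len(assembly.names)} chromosomes, "
          f"{sum(assembly.lengths.values()):,} bp; {len(annotation)} genes")
    print(f"wrote {FIXDIR}/reference.fa and {FIXDIR}/genes.gff3")


if __name__ == "__main__":
    main()
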