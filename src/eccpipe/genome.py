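"""Synthetic reference genomes and gene annotations.

Everything downstream of this module works in a single coordinate frame:
0-based half-open intervals, so that ``length = end - start``.  GFF3 files
on disk use the standard 1-based inclusive convention and are converted on
read/write.

The generator produces small seeded assemblies (uniform base composition at
a target GC) and non-overlapping single-transcript gene models whose
features (5'UTR, exons, introns, 3'UTR) tile the gene span exactly.  These
stand in for a real mouse or human reference so the circle simulator and
caller can be exercised without downloads.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

FEATURE_KINDS = ("five_prime_utr", "exon", "intron", "three_prime_utr")

# GFF3 column-3 feature types <-> internal kinds; introns are implicit on
# disk (standard GFF3 practice) and materialized on read.
_KIND_TO_GFF = {
    "five_prime_utr": "five_prime_UTR",
    "exon": "exon",
    "three_prime_utr": "three_prime_UTR",
}
_GFF_TO_KIND = {v: k for k, v in _KIND_TO_GFF.items()}


class PlacementError(RuntimeError):
    """Raised when gene placement cannot satisfy the non-overlap constraint."""

    def __init__(self, placed: int, requested: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"placed only {placed} of {requested} genes without overlap; "
            "reduce n_genes or gene length range"
        )


class GFF3ParseError(ValueError):
    """Malformed GFF3 record, carrying the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"GFF3 line {lineno}: {message}")


@dataclass
class GenomeAssembly:
    """Ordered named chromosomes over the {A,C,G,T} alphabet."""

    chromosomes: list[tuple[str, str]]

    def __post_init__(self):
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, seq in self.chromosomes:
            if not seq:
                raise ValueError(f"chromosome {name} has empty sequence")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.chromosomes}

    def sequence(self, chrom: str) -> str:
        for n, s in self.chromosomes:
            if n == chrom:
                return s
        raise KeyError(f"unknown chromosome {chrom!r}")

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeAssembly) and self.chromosomes == other.chromosomes


@dataclass
class GeneModel:
    """A single-transcript gene whose features tile its span.

    ``features`` is an ordered list of ``(kind, (start, end))`` with kinds in
    :data:`FEATURE_KINDS`; intervals are 0-based half-open, disjoint, and
    their union equals ``[start, end)``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    features: list[tuple[str, tuple[int, int]]]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.validate_tiling()

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start

    def validate_tiling(self) -> None:
        """Check features are in-order, disjoint, and tile the span."""
        cursor = self.start
        for kind, (fs, fe) in self.features:
            if kind not in FEATURE_KINDS:
                raise ValueError(f"unknown feature kind {kind!r}")
            if fs != cursor or fe <= fs:
                raise ValueError(
                    f"gene {self.gene_id}: features do not tile the span "
                    f"(expected start {cursor}, got [{fs}, {fe}))"
                )
            cursor = fe
        if cursor != self.end:
            raise ValueError(
                f"gene {self.gene_id}: features end at {cursor}, span ends at {self.end}"
            )


@dataclass
class AnnotationSet:
    """Gene models with a per-chromosome interval index for overlap queries."""

    genes: list[GeneModel]
    _index: dict[str, IntervalTree] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self._index = {}
        for i, g in enumerate(self.genes):
            self._index.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, i)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        """Genes overlapping [start, end) on chrom, in genomic order."""
        tree = self._index.get(chrom)
        if tree is None:
            return []
        hits = sorted(iv.data for iv in tree.overlap(start, end))
        return [self.genes[i] for i in hits]

    def __eq__(self, other) -> bool:
        return isinstance(other, AnnotationSet) and self.genes == other.genes

    def __len__(self) -> int:
        return len(self.genes)


def make_reference(
    n_chroms: int, lengths: list[int], gc: float, seed: int
) -> GenomeAssembly:
    """Generate a seeded random assembly with the given chromosome lengths.

    Bases are i.i.d. with P(G) = P(C) = gc/2, so observed GC converges on
    the target (within ~2% for chromosomes of 100 kb and up).
    """
    if n_chroms <= 0:
        raise ValueError("n_chroms must be positive")
    if len(lengths) != n_chroms:
        raise ValueError(f"expected {n_chroms} lengths, got {len(lengths)}")
    if any(length <= 0 for length in lengths):
        raise ValueError("chromosome lengths must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    chroms = []
    for i, length in enumerate(lengths):
        draws = rng.choice(alphabet, size=length, p=probs)
        chroms.append((f"chr{i + 1}", draws.tobytes().decode("ascii")))
    return GenomeAssembly(chroms)


def _build_gene(
    gene_id: str,
    chrom: str,
    start: int,
    length: int,
    n_exons: int,
    strand: str,
    rng: np.random.Generator,
) -> GeneModel:
    # Partition the span into 5'UTR, exons with introns between, 3'UTR.
    # 2*n_exons + 1 parts, each at least 20 bp.
    n_parts = 2 * n_exons + 1
    min_part = 20
    if length < n_parts * min_part:
        n_exons = max(1, (length // min_part - 1) // 2)
        n_parts = 2 * n_exons + 1
    cuts = np.sort(rng.choice(length - n_parts * min_part + 1, size=n_parts - 1))
    sizes = np.diff(np.concatenate([[0], cuts, [length - n_parts * min_part + 1 - 1]]))
    sizes = sizes + min_part  # every part >= min_part
    # fix rounding so sizes sum to length
    sizes[-1] += length - int(sizes.sum())
    features: list[tuple[str, tuple[int, int]]] = []
    cursor = start
    kinds = ["five_prime_utr"]
    for i in range(n_exons):
        kinds.append("exon")
        if i < n_exons - 1:
            kinds.append("intron")
    kinds.append("three_prime_utr")
    for kind, size in zip(kinds, sizes):
        features.append((kind, (cursor, cursor + int(size))))
        cursor += int(size)
    return GeneModel(gene_id, chrom, start, start + length, strand, features)


def make_annotation(
    assembly: GenomeAssembly,
    n_genes: int,
    gene_len_range: tuple[int, int],
    n_exons_range: tuple[int, int],
    seed: int,
) -> AnnotationSet:
    """Place n_genes non-overlapping genes by rejection sampling.

    Retries are capped at 100 x n_genes; exceeding the cap raises
    :class:`PlacementError` reporting how many genes were placed.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be non-negative")
    if n_genes == 0:
        return AnnotationSet([])
    lo, hi = gene_len_range
    shortest = min(assembly.lengths.values())
    if hi >= shortest:
        raise ValueError(
            f"max gene length {hi} must be below the shortest chromosome ({shortest} bp)"
        )
    rng = np.random.default_rng(seed)
    names = assembly.names
    lens = assembly.lengths
    occupied: dict[str, IntervalTree] = {n: IntervalTree() for n in names}
    genes: list[GeneModel] = []
    attempts = 0
    cap = 100 * n_genes
    while len(genes) < n_genes:
        if attempts >= cap:
            raise PlacementError(len(genes), n_genes)
        attempts += 1
        chrom = names[rng.integers(len(names))]
        glen = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, lens[chrom] - glen))
        if occupied[chrom].overlap(start, start + glen):
            continue
        n_exons = int(rng.integers(n_exons_range[0], n_exons_range[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        gene = _build_gene(
            f"gene{len(genes) + 1:04d}", chrom, start, glen, n_exons, strand, rng
        )
        occupied[chrom].addi(start, start + glen)
        genes.append(gene)
    genes.sort(key=lambda g: (assembly.names.index(g.chrom), g.start))
    return AnnotationSet(genes)


# ---------------------------------------------------------------------------
# I/O


def write_fasta(assembly: GenomeAssembly, path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in assembly.chromosomes
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(records)


def read_fasta(path: str) -> GenomeAssembly:
    chroms = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]
    return GenomeAssembly(chroms)


def write_gff3(annotation: AnnotationSet, path: str) -> None:
    """Write genes and their UTR/exon features (introns implicit on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation.genes:
            fh.write(
                f"{g.chrom}\teccpipe\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for kind, (fs, fe) in g.features:
                if kind == "intron":
                    continue
                fh.write(
                    f"{g.chrom}\teccpipe\t{_KIND_TO_GFF[kind]}\t{fs + 1}\t{fe}\t.\t"
                    f"{g.strand}\t.\tParent={g.gene_id}\n"
                )


def _parse_attrs(col: str, lineno: int) -> dict[str, str]:
    attrs = {}
    for part in col.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            raise GFF3ParseError(lineno, f"bad attribute {part!r}")
        k, v = part.split("=", 1)
        attrs[k] = v
    return attrs


def read_gff3(path: str) -> AnnotationSet:
    """Read a GFF3 gene file, materializing introns as exon gaps.

    Coordinates convert from 1-based inclusive on disk to the internal
    0-based half-open frame.  Malformed rows raise :class:`GFF3ParseError`
    with the offending line number.
    """
    gene_rows: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GFF3ParseError(lineno, f"expected 9 columns, got {len(cols)}")
            chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attr_col = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GFF3ParseError(lineno, "non-integer coordinates") from None
            if end1 < start1:
                raise GFF3ParseError(lineno, f"end {end1} < start {start1}")
            start, end = start1 - 1, end1  # to 0-based half-open
            attrs = _parse_attrs(attr_col, lineno)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise GFF3ParseError(lineno, "gene record lacks ID attribute")
                gene_rows[gid] = {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "parts": [],
                }
            elif ftype in _GFF_TO_KIND:
                parent = attrs.get("Parent")
                if parent is None or parent not in gene_rows:
                    raise GFF3ParseError(lineno, f"feature with unknown Parent {parent!r}")
                gene_rows[parent]["parts"].append((_GFF_TO_KIND[ftype], (start, end)))
            # other feature types are ignored
    genes = []
    for gid, row in gene_rows.items():
        parts = sorted(row["parts"], key=lambda p: p[1][0])
        # materialize introns in the gaps between consecutive parts
        features: list[tuple[str, tuple[int, int]]] = []
        cursor = row["start"]
        for kind, (fs, fe) in parts:
            if fs > cursor:
                features.append(("intron", (cursor, fs)))
            features.append((kind, (fs, fe)))
            cursor = fe
        if cursor < row["end"]:
            features.append(("intron", (cursor, row["end"])))
        genes.append(
            GeneModel(gid, row["chrom"], row["start"], row["end"], row["strand"], features)
        )
    return AnnotationSet(genes)


def fasta_bytes(assembly: GenomeAssembly) -> bytes:
    """In-memory FASTA rendering (used for determinism checks)."""
    buf = io.StringIO()
    writer = SeqIO.FastaIO.FastaWriter(buf, wrap=80)
    writer.write_file(
        [SeqRecord(Seq(s), id=n, description="") for n, s in assembly.chromosomes]
    )
    return buf.getvalue().encode()
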