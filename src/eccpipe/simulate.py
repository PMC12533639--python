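"""Circle-enriched library simulator.

Models the cirSeq protocol computationally: ground-truth circular DNA
elements are drawn from a synthetic assembly, rolling-circle amplification
is modeled as tandem concatemerization (each circle's sequence repeated a
geometric number of times, minimum two copies), the concatemer is
fragmented uniformly, and 150-bp paired-end reads are taken from fragment
ends in standard Illumina FR orientation.

Two alignment signatures of circularity fall out of this geometry and are
what the caller downstream looks for:

* a read whose template crosses the circle's start/end junction aligns in
  two parts — a right-clipped segment at the circle end plus a left-clipped
  supplementary at the circle start (a split read);
* a fragment that spans the junction without either read crossing it puts
  its mates in outward-facing (RF) orientation in linear coordinates.

A configurable fraction of pairs comes from random linear genomic
fragments, standing in for incomplete exonuclease digestion of linear DNA.
The simulator emits the truth alignments itself (positions are known
exactly), so no external aligner is needed; FASTQ is also written for
users who want to run one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam
from scipy import stats

from .genome import AnnotationSet, GenomeAssembly

ORIGIN_CLASSES = ("intergenic", "partial_gene", "full_gene")

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class SamplingError(RuntimeError):
    """Could not place a circle of the requested origin class."""

    def __init__(self, origin_class: str):
        super().__init__(
            f"could not place a circle of class {origin_class!r} after bounded retries"
        )
        self.origin_class = origin_class


@dataclass(frozen=True)
class TrueCircle:
    """Ground-truth circular element: [start, end) on chrom, length = end - start."""

    circle_id: str
    chrom: str
    start: int
    end: int
    origin_class: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SimConfig:
    """Parameters of the simulated circle-enriched library.

    Circle lengths follow a log-normal (median ``exp(mu_log)``, shape
    ``sigma_log``) truncated to ``[min_len, max_len]``; the defaults put
    ~94% of the mass in the 400-6000 bp range that dominates real
    circle-enriched libraries.  ``rca_fold`` is the mean concatemer copy
    number of the rolling-circle amplification; insert sizes are normal
    (350 +/- 50) truncated to [200, 1000] bp.
    """

    n_circles: int = 50
    mu_log: float = float(np.log(1500.0))
    sigma_log: float = 0.8
    min_len: int = 300
    max_len: int = 10_000
    origin_mix: dict[str, float] = field(
        default_factory=lambda: {
            "intergenic": 0.600,
            "partial_gene": 0.396,
            "full_gene": 0.004,
        }
    )
    rca_fold: float = 10.0
    insert_mu: float = 350.0
    insert_sd: float = 50.0
    insert_min: int = 200
    insert_max: int = 1000
    read_len: int = 150
    error_rate: float = 0.001
    background_frac: float = 0.01
    n_read_pairs: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.origin_mix.values()) - 1.0) > 1e-9:
            raise ValueError("origin_mix probabilities must sum to 1")
        if set(self.origin_mix) - set(ORIGIN_CLASSES):
            raise ValueError(f"origin_mix keys must be among {ORIGIN_CLASSES}")
        for rate in (self.error_rate, self.background_frac):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.read_len > self.insert_min:
            raise ValueError("read_len must not exceed the minimum insert size")
        if self.min_len < self.read_len:
            raise ValueError(
                "min_len must be at least read_len: circles shorter than a read "
                "are rejected"
            )
        if self.min_len >= self.max_len:
            raise ValueError("min_len must be below max_len")
        if self.rca_fold < 2:
            raise ValueError("rca_fold must be at least 2 (minimum concatemer copies)")

    def length_distribution(self) -> stats.distributions.rv_frozen:
        """The truncated log-normal as a frozen scipy distribution (untruncated base)."""
        return stats.lognorm(s=self.sigma_log, scale=float(np.exp(self.mu_log)))

    def length_cdf(self, x) -> np.ndarray:
        """CDF of the truncated length distribution."""
        d = self.length_distribution()
        lo, hi = d.cdf(self.min_len), d.cdf(self.max_len)
        return np.clip((d.cdf(x) - lo) / (hi - lo), 0.0, 1.0)

    def length_mass(self, a: float, b: float) -> float:
        """Analytic probability mass of the truncated distribution on [a, b)."""
        return float(self.length_cdf(b) - self.length_cdf(a))


def _sample_lengths(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF sampling from the truncated log-normal, rounded to bp."""
    d = config.length_distribution()
    lo, hi = d.cdf(config.min_len), d.cdf(config.max_len)
    u = rng.uniform(lo, hi, size=n)
    return np.clip(np.rint(d.ppf(u)).astype(int), config.min_len, config.max_len)


# separation guard between placed circles so each call maps to one truth circle
_CIRCLE_GAP = 1000


def sample_circles(
    assembly: GenomeAssembly,
    annotation: AnnotationSet,
    config: SimConfig,
) -> list[TrueCircle]:
    """Draw ground-truth circles of the configured origin-class mixture.

    Circles are mutually non-overlapping (1 kb separation).  Placement of
    each class is by rejection sampling with a bounded retry budget;
    exhausting it raises :class:`SamplingError` naming the class.
    """
    config.validate()
    if config.n_circles == 0:
        return []
    gene_weight = config.origin_mix.get("partial_gene", 0) + config.origin_mix.get(
        "full_gene", 0
    )
    if gene_weight > 0 and len(annotation) == 0:
        raise ValueError("origin_mix gives weight to gene classes but annotation is empty")
    rng = np.random.default_rng(config.seed)
    classes = list(config.origin_mix)
    probs = np.array([config.origin_mix[c] for c in classes])
    chosen = rng.choice(len(classes), size=config.n_circles, p=probs)
    lengths = _sample_lengths(config, config.n_circles, rng)
    names = assembly.names
    chrom_lens = assembly.lengths
    chrom_w = np.array([chrom_lens[n] for n in names], dtype=float)
    chrom_w /= chrom_w.sum()

    placed: dict[str, list[tuple[int, int]]] = {n: [] for n in names}

    def clashes(chrom: str, s: int, e: int) -> bool:
        return any(
            s < pe + _CIRCLE_GAP and e + _CIRCLE_GAP > ps for ps, pe in placed[chrom]
        )

    def fully_contains_a_gene(chrom: str, s: int, e: int) -> bool:
        return any(g.start >= s and g.end <= e for g in annotation.overlapping(chrom, s, e))

    circles: list[TrueCircle] = []
    for i in range(config.n_circles):
        cls = classes[chosen[i]]
        length = int(lengths[i])
        ok = False
        for _ in range(2000):
            if cls == "full_gene":
                candidates = [g for g in annotation.genes if g.length + 20 <= length]
                if not candidates:
                    length = int(_sample_lengths(config, 1, rng)[0])
                    continue
                g = candidates[int(rng.integers(len(candidates)))]
                slack = length - g.length
                offset = int(rng.integers(10, slack - 10 + 1)) if slack > 20 else slack // 2
                s = g.end + offset - length
                chrom = g.chrom
            elif cls == "partial_gene":
                g = annotation.genes[int(rng.integers(len(annotation.genes)))]
                # overlap the gene by at least 50 bp without containing it
                lo = g.start - length + 50
                hi = g.end - 50
                if hi <= lo:
                    continue
                s = int(rng.integers(lo, hi))
                chrom = g.chrom
            else:
                chrom = names[int(rng.choice(len(names), p=chrom_w))]
                s = int(rng.integers(0, max(1, chrom_lens[chrom] - length)))
            e = s + length
            if s < 0 or e > chrom_lens[chrom]:
                continue
            if clashes(chrom, s, e):
                continue
            overlapping = annotation.overlapping(chrom, s, e)
            if cls == "intergenic" and overlapping:
                continue
            if cls == "partial_gene" and (
                not overlapping or fully_contains_a_gene(chrom, s, e)
            ):
                continue
            if cls == "full_gene" and not fully_contains_a_gene(chrom, s, e):
                continue
            ok = True
            break
        if not ok:
            raise SamplingError(cls)
        placed[chrom].append((s, e))
        circles.append(TrueCircle(f"circle{i + 1:04d}", chrom, s, e, cls))
    circles.sort(key=lambda c: (names.index(c.chrom), c.start))
    return circles


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class Segment:
    """One SAM alignment record of a simulated read (pre-flag assembly)."""

    chrom: str
    pos: int          # 0-based leftmost reference position
    strand: str       # '+' or '-'
    left_clip: int    # soft-clipped stored bases before the match
    match: int        # aligned bases
    is_supplementary: bool = False

    @property
    def cigar(self) -> str:
        right = self._read_len - self.left_clip - self.match
        parts = []
        if self.left_clip:
            parts.append(f"{self.left_clip}S")
        parts.append(f"{self.match}M")
        if right:
            parts.append(f"{right}S")
        return "".join(parts)

    _read_len: int = 150

    @property
    def end(self) -> int:
        return self.pos + self.match


@dataclass
class SimRead:
    """A simulated read: stored-orientation sequence plus its true segments."""

    qname: str
    is_read1: bool
    strand: str
    seq: str                 # forward-reference orientation (SAM SEQ)
    segments: list[Segment]  # ordered by stored-base offset
    crosses_junction: bool


@dataclass
class SimTruth:
    """Ground truth for one simulated library."""

    circles: list[TrueCircle]
    read_counts: dict[str, int]              # circle_id -> n read pairs
    provenance: list[tuple[str, str, bool]]  # (qname, circle_id|'background', junction?)

    def n_background_pairs(self) -> int:
        return sum(1 for _, origin, _ in self.provenance if origin == "background")


@dataclass
class SimResult:
    reads: list[tuple[SimRead, SimRead]]  # (read1, read2) per pair
    truth: SimTruth


def _segments_for(
    chrom: str, circ_start: int, clen: int, concat_off: int, read_len: int
) -> list[Segment]:
    """Split a read covering concatemer offsets [concat_off, concat_off+read_len)
    into reference segments at junction multiples of the circle length."""
    segs: list[Segment] = []
    done = 0
    off = concat_off
    while done < read_len:
        circ_off = off % clen
        take = min(read_len - done, clen - circ_off)
        segs.append(
            Segment(
                chrom=chrom,
                pos=circ_start + circ_off,
                strand="+",
                left_clip=done,
                match=take,
                _read_len=read_len,
            )
        )
        done += take
        off += take
    return segs


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hits) == 0:
        return seq
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = alphabet[alphabet != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def _make_read(
    qname: str,
    is_read1: bool,
    strand: str,
    chrom: str,
    seq_source: str,
    source_offset: int,
    circ_start: int,
    clen: int | None,
    concat_off: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> SimRead:
    """Build one read.  For circle reads, seq_source is the circle sequence and
    clen its length; for background, clen is None and concat_off is a direct
    genome offset into seq_source."""
    R = config.read_len
    if clen is None:
        seq = seq_source[concat_off : concat_off + R]
        segs = [
            Segment(chrom, source_offset + concat_off, strand, 0, R, _read_len=R)
        ]
        crosses = False
    else:
        pieces = []
        segs = _segments_for(chrom, circ_start, clen, concat_off, R)
        for s in segs:
            cs = s.pos - circ_start
            pieces.append(seq_source[cs : cs + s.match])
        seq = "".join(pieces)
        crosses = len(segs) > 1
        for s in segs:
            s.strand = strand
    seq = _apply_errors(seq, config.error_rate, rng)
    # the longest-match segment is the primary
    primary = max(range(len(segs)), key=lambda i: segs[i].match)
    for i, s in enumerate(segs):
        s.is_supplementary = i != primary
    segs = [segs[primary]] + [s for i, s in enumerate(segs) if i != primary]
    return SimRead(qname, is_read1, strand, seq, segs, crosses)


def simulate_reads(
    assembly: GenomeAssembly,
    circles: list[TrueCircle],
    config: SimConfig,
) -> SimResult:
    """Simulate the paired-end library for a set of ground-truth circles.

    Emits exactly ``config.n_read_pairs`` pairs.  Pairs are allocated to
    circles proportionally to circle length (rolling-circle amplification is
    modeled as unbiased), plus a binomial number of linear background pairs.
    Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    for c in circles:
        if c.length < config.read_len:
            raise ValueError(f"{c.circle_id} shorter than read_len")
    rng = np.random.default_rng(config.seed + 1)
    n_pairs = config.n_read_pairs
    n_bg = int(rng.binomial(n_pairs, config.background_frac)) if circles else n_pairs
    n_circ = n_pairs - n_bg
    if circles:
        lens = np.array([c.length for c in circles], dtype=float)
        alloc = rng.multinomial(n_circ, lens / lens.sum())
    else:
        alloc = np.array([], dtype=int)

    chrom_seq = dict(assembly.chromosomes)
    names = assembly.names
    chrom_lens = assembly.lengths
    chrom_w = np.array([chrom_lens[n] for n in names], dtype=float)
    chrom_w /= chrom_w.sum()

    geom_p = 1.0 / (config.rca_fold - 1.0)
    pairs: list[tuple[SimRead, SimRead]] = []
    provenance: list[tuple[str, str, bool]] = []
    read_counts: dict[str, int] = {c.circle_id: 0 for c in circles}
    serial = 0

    def sample_insert(upper: int) -> int:
        lo = max(config.read_len, config.insert_min)
        hi = min(config.insert_max, upper)
        if hi <= lo:
            return lo
        a = (lo - config.insert_mu) / config.insert_sd
        b = (hi - config.insert_mu) / config.insert_sd
        return int(
            np.rint(
                stats.truncnorm.ppf(
                    rng.random(), a, b, loc=config.insert_mu, scale=config.insert_sd
                )
            )
        )

    for ci, circle in enumerate(circles):
        cseq = chrom_seq[circle.chrom][circle.start : circle.end]
        clen = circle.length
        for _ in range(int(alloc[ci])):
            serial += 1
            qname = f"sim{serial:07d}"
            copies = 1 + int(rng.geometric(geom_p))  # min 2 concatemer copies
            concat_len = copies * clen
            insert = sample_insert(concat_len)
            f = int(rng.integers(0, concat_len - insert + 1))
            o1, o2 = f, f + insert - config.read_len
            # physical read A forward at the fragment start, B reverse at the end;
            # which is labeled read1 is random, as in a real library
            a_first = bool(rng.random() < 0.5)
            ra = _make_read(
                qname, a_first, "+", circle.chrom, cseq, 0, circle.start, clen, o1,
                config, rng,
            )
            rb = _make_read(
                qname, not a_first, "-", circle.chrom, cseq, 0, circle.start, clen, o2,
                config, rng,
            )
            pair = (ra, rb) if a_first else (rb, ra)
            pairs.append(pair)
            read_counts[circle.circle_id] += 1
            provenance.append(
                (qname, circle.circle_id, ra.crosses_junction or rb.crosses_junction)
            )

    for _ in range(n_bg):
        serial += 1
        qname = f"sim{serial:07d}"
        chrom = names[int(rng.choice(len(names), p=chrom_w))]
        insert = sample_insert(chrom_lens[chrom])
        pos = int(rng.integers(0, chrom_lens[chrom] - insert + 1))
        frag = chrom_seq[chrom][pos : pos + insert]
        a_first = bool(rng.random() < 0.5)
        ra = _make_read(qname, a_first, "+", chrom, frag, pos, 0, None, 0, config, rng)
        rb = _make_read(
            qname, not a_first, "-", chrom, frag, pos, 0, None,
            insert - config.read_len, config, rng,
        )
        pair = (ra, rb) if a_first else (rb, ra)
        pairs.append(pair)
        provenance.append((qname, "background", False))

    truth = SimTruth(circles=circles, read_counts=read_counts, provenance=provenance)
    return SimResult(reads=pairs, truth=truth)


# ---------------------------------------------------------------------------
# writers


def _sam_header(assembly: GenomeAssembly) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": n, "LN": assembly.lengths[n]} for n in assembly.names],
        }
    )


def _sa_tag(segs: list[Segment], skip: int) -> str:
    parts = []
    for i, s in enumerate(segs):
        if i == skip:
            continue
        parts.append(f"{s.chrom},{s.pos + 1},{s.strand},{s.cigar},60,0;")
    return "".join(parts)


def write_truth_sam(result: SimResult, assembly: GenomeAssembly, path: str) -> None:
    """Write the exact truth alignments as a SAM file (primary + supplementary
    records, SA tags, mate fields pointing at the mate's primary segment)."""
    header = _sam_header(assembly)
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r1, r2 in result.reads:
            p1, p2 = r1.segments[0], r2.segments[0]
            proper = (
                len(r1.segments) == 1
                and len(r2.segments) == 1
                and p1.chrom == p2.chrom
                and r1.strand != r2.strand
                and (
                    (p1.pos <= p2.pos and r1.strand == "+")
                    or (p2.pos <= p1.pos and r2.strand == "+")
                )
            )
            for read, mate_primary, mate in ((r1, p2, r2), (r2, p1, r1)):
                for si, seg in enumerate(read.segments):
                    a = pysam.AlignedSegment(header)
                    a.query_name = read.qname
                    a.reference_name = seg.chrom
                    a.reference_start = seg.pos
                    a.mapping_quality = 60
                    a.cigarstring = seg.cigar
                    a.query_sequence = read.seq
                    a.query_qualities = pysam.qualitystring_to_array("I" * len(read.seq))
                    flag = 1  # paired
                    if proper:
                        flag |= 2
                    if read.strand == "-":
                        flag |= 16
                    if mate.strand == "-":
                        flag |= 32
                    flag |= 64 if read.is_read1 else 128
                    if seg.is_supplementary:
                        flag |= 2048
                    a.flag = flag
                    a.next_reference_name = mate_primary.chrom
                    a.next_reference_start = mate_primary.pos
                    if len(read.segments) > 1:
                        a.set_tag("SA", _sa_tag(read.segments, si))
                    out.write(a)


def write_fastq(result: SimResult, path_r1: str, path_r2: str) -> None:
    """Write the pair as two FASTQ files; reverse-strand reads are written
    as sequenced (reverse complement of the stored orientation)."""
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for r1, r2 in result.reads:
            for read, fh, suffix in ((r1, f1, "/1"), (r2, f2, "/2")):
                seq = read.seq if read.strand == "+" else revcomp(read.seq)
                fh.write(f"@{read.qname}{suffix}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth_table(result: SimResult, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("circle_id\tchrom\tstart\tend\tlength\torigin_class\tn_reads\n")
        for c in result.truth.circles:
            fh.write(
                f"{c.circle_id}\t{c.chrom}\t{c.start}\t{c.end}\t{c.length}\t"
                f"{c.origin_class}\t{result.truth.read_counts.get(c.circle_id, 0)}\n"
            )


# ---------------------------------------------------------------------------
# expression co-simulation


def cosimulate_expression(
    sample_burdens: list[float],
    beta: float,
    sigma: float,
    seed: int,
    n_markers: int = 5,
    marker_prefix: str = "marker",
):
    """Simulate a samples x marker-genes expression table linearly coupled to
    per-sample circle burden: ``x_gs = alpha_g + beta * burden_s + N(0, sigma^2)``.

    With ``sigma=0`` every marker's sample Pearson correlation with burden
    is exactly 1 (for ``beta > 0``).
    """
    import pandas as pd

    if len(sample_burdens) < 3:
        raise ValueError("need at least 3 samples")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    burdens = np.asarray(sample_burdens, dtype=float)
    alphas = rng.uniform(0, 100, size=n_markers)
    data = {}
    for g in range(n_markers):
        noise = rng.normal(0.0, sigma, size=len(burdens)) if sigma > 0 else 0.0
        data[f"{marker_prefix}{g + 1}"] = alphas[g] + beta * burdens + noise
    return pd.DataFrame(data, index=[f"sample{i + 1}" for i in range(len(burdens))])
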