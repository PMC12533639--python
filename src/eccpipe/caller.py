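"""eccDNA detection from paired-end alignments.

Three evidence classes identify a circle on the linear reference:

* **split reads** — a read running off the circle end and continuing at the
  circle start aligns as a right-clipped segment at the end plus a
  left-clipped supplementary at the start (same chromosome and strand).
  The clip geometry places both breakpoints at base resolution.
* **outward-facing discordant pairs** — mates of a junction-spanning
  fragment point away from each other (RF) in linear coordinates; they
  bound the junction to within one insert length and corroborate split
  calls but never place breakpoints on their own.
* **coverage enrichment** — rolling-circle amplification piles reads onto
  the circle interval; depth relative to the genome-wide background
  (median bin depth plus a pseudocount) must clear a ratio threshold.

Split junctions are single-linkage clustered with a small breakpoint
tolerance; a cluster becomes a call if it has enough split support (or one
split plus corroborating discordant pairs) and is coverage-enriched.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field, asdict
from typing import Iterable, Iterator

import numpy as np
import pysam

# CIGAR op codes (SAM spec): consumes-query ops and consumes-reference ops
_ALLOWED_OPS = {0, 1, 2, 4, 5}  # M I D S H
_QUERY_OPS = {0, 1, 4}          # M I S
_REF_OPS = {0, 2}               # M D


class SAMParseError(ValueError):
    pass


@dataclass
class AlignmentRecord:
    """Minimal SAM-semantics record: position, strand, clip structure, mate."""

    qname: str
    chrom: str | None
    pos: int
    strand: str
    cigar: list[tuple[int, int]]  # (op, length) pysam codes
    is_supplementary: bool
    is_read1: bool
    mate_chrom: str | None
    mate_pos: int
    mate_strand: str
    is_proper_linear_pair: bool
    mapped: bool

    @property
    def left_clip(self) -> int:
        n = 0
        for op, ln in self.cigar:
            if op in (4, 5):
                n += ln
            else:
                break
        return n

    @property
    def right_clip(self) -> int:
        n = 0
        for op, ln in reversed(self.cigar):
            if op in (4, 5):
                n += ln
            else:
                break
        return n

    @property
    def ref_span(self) -> int:
        return sum(ln for op, ln in self.cigar if op in _REF_OPS)

    @property
    def query_len(self) -> int:
        return sum(ln for op, ln in self.cigar if op in (0, 1, 4, 5))

    @property
    def end(self) -> int:
        return self.pos + self.ref_span

    @property
    def clip_structure(self) -> tuple[int, int, int]:
        """(left_clip, aligned_query_bases, right_clip)."""
        return (
            self.left_clip,
            self.query_len - self.left_clip - self.right_clip,
            self.right_clip,
        )


@dataclass(frozen=True)
class JunctionEvidence:
    """One piece of circle evidence: candidate breakpoints on one chromosome."""

    chrom: str
    start: int  # circle start candidate
    end: int    # circle end candidate
    source: str  # 'split_read' | 'discordant_pair'
    qname: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"degenerate evidence interval [{self.start}, {self.end})")


@dataclass
class CircleCall:
    chrom: str
    start: int
    end: int
    split_support: int
    discordant_support: int
    mean_depth: float
    enrichment: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CircleCatalog:
    """Per-sample set of unique circle calls, sorted by (chrom, start)."""

    sample_id: str
    calls: list[CircleCall]

    @property
    def n_eccDNA(self) -> int:
        return len(self.calls)

    @property
    def mean_length(self) -> float | None:
        if not self.calls:
            return None
        return float(np.mean([c.length for c in self.calls]))


@dataclass
class CallerConfig:
    """Thresholds of the evidence model; the defaults favor precision on
    circle-enriched libraries, where split reads carry the decision."""

    epsilon: int = 5                      # breakpoint cluster tolerance, bp
    min_split: int = 2                    # split reads sufficient alone
    alt_min_split: int = 1                # alternative rule: 1 split ...
    alt_min_discordant: int = 2           # ... plus >= 2 discordant pairs
    min_enrichment: float = 2.0           # mean depth / background
    background_pseudocount: float = 0.01  # reads/bp added to background
    max_circle_len: int = 10_000_000
    min_circle_len: int = 200
    max_insert: int = 1000                # discordant-assignment slack, bp
    bin_size: int = 50                    # coverage bin width, bp

    def validate(self) -> None:
        for name in (
            "epsilon", "min_split", "alt_min_split", "alt_min_discordant",
            "min_enrichment", "background_pseudocount", "max_circle_len",
            "min_circle_len", "max_insert", "bin_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# SAM parsing


def parse_alignments(sam_path: str) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a SAM/BAM file in file order.

    Unmapped records are retained with ``mapped=False``.  CIGAR ops outside
    {M,I,D,S,H} raise :class:`SAMParseError`; hard clips are treated as soft
    for clip geometry (they consume no stored sequence but the geometry of
    the split is the same).
    """
    with pysam.AlignmentFile(sam_path, "r", check_sq=True) as fh:
        if not fh.header.get("SQ"):
            raise SAMParseError(f"{sam_path}: missing @SQ header lines")
        for a in fh:
            if a.is_unmapped:
                yield AlignmentRecord(
                    qname=a.query_name, chrom=None, pos=-1, strand="+",
                    cigar=[], is_supplementary=False,
                    is_read1=not a.is_read2, mate_chrom=None, mate_pos=-1,
                    mate_strand="+", is_proper_linear_pair=False, mapped=False,
                )
                continue
            cig = a.cigartuples or []
            bad = {op for op, _ in cig} - _ALLOWED_OPS
            if bad:
                raise SAMParseError(
                    f"{sam_path}: read {a.query_name}: unsupported CIGAR ops {bad}"
                )
            yield AlignmentRecord(
                qname=a.query_name,
                chrom=a.reference_name,
                pos=a.reference_start,
                strand="-" if a.is_reverse else "+",
                cigar=[(op, ln) for op, ln in cig],
                is_supplementary=a.is_supplementary,
                is_read1=not a.is_read2,
                mate_chrom=a.next_reference_name if a.is_paired else None,
                mate_pos=a.next_reference_start if a.is_paired else -1,
                mate_strand="-" if (a.is_paired and a.mate_is_reverse) else "+",
                is_proper_linear_pair=bool(a.is_paired and a.is_proper_pair),
                mapped=True,
            )


def alignment_qc(records: Iterable[AlignmentRecord]) -> dict:
    """Total records and mapped fraction (the standard alignment QC)."""
    total = mapped = 0
    for r in records:
        total += 1
        mapped += int(r.mapped)
    return {
        "total_records": total,
        "mapped_records": mapped,
        "mapped_fraction": (mapped / total) if total else None,
    }


# ---------------------------------------------------------------------------
# evidence extraction


def extract_split_junctions(
    records: Iterable[AlignmentRecord],
    tallies: dict | None = None,
) -> list[JunctionEvidence]:
    """Junction evidence from primary/supplementary split alignments.

    Circular geometry: the segment carrying the *leading* part of the stored
    read maps downstream (higher coordinate, right-clipped) and the trailing
    segment maps upstream (left-clipped).  Equivalently, in reference order
    the left segment is left-clipped and the right segment right-clipped.
    Linear split geometry (deletion-like) is the mirror image and yields
    nothing; splits across chromosomes or strands are tallied, not called.
    """
    if tallies is None:
        tallies = {}
    tallies.setdefault("non_circular_split", 0)
    tallies.setdefault("linear_split", 0)
    groups: dict[tuple[str, bool], list[AlignmentRecord]] = defaultdict(list)
    for r in records:
        if r.mapped and r.cigar:
            groups[(r.qname, r.is_read1)].append(r)
    out: list[JunctionEvidence] = []
    for (qname, _), recs in groups.items():
        if len(recs) < 2:
            continue
        primaries = [r for r in recs if not r.is_supplementary]
        supps = [r for r in recs if r.is_supplementary]
        if not primaries:
            continue
        prim = primaries[0]
        for supp in supps:
            if supp.chrom != prim.chrom or supp.strand != prim.strand:
                tallies["non_circular_split"] += 1
                continue
            rec_l, rec_r = (prim, supp) if prim.pos <= supp.pos else (supp, prim)
            if rec_l.left_clip > 0 and rec_r.right_clip > 0:
                out.append(
                    JunctionEvidence(
                        chrom=prim.chrom,
                        start=rec_l.pos,
                        end=rec_r.end,
                        source="split_read",
                        qname=qname,
                    )
                )
            else:
                tallies["linear_split"] += 1
    return out


def extract_discordant_pairs(
    records: Iterable[AlignmentRecord],
    max_circle_len: int = 10_000_000,
    tallies: dict | None = None,
) -> list[JunctionEvidence]:
    """Junction evidence from outward-facing (RF) mate pairs.

    The evidence interval (leftmost mate start, rightmost mate end) contains
    the circle junction but not at base resolution; it is flagged
    ``discordant_pair`` and used only to corroborate split-read candidates.
    """
    if tallies is None:
        tallies = {}
    tallies.setdefault("proper_fr_pairs", 0)
    tallies.setdefault("interchromosomal_pairs", 0)
    mates: dict[str, dict[bool, AlignmentRecord]] = defaultdict(dict)
    for r in records:
        if r.mapped and not r.is_supplementary:
            mates[r.qname][r.is_read1] = r
    out: list[JunctionEvidence] = []
    for qname, pair in mates.items():
        if True not in pair or False not in pair:
            continue
        r1, r2 = pair[True], pair[False]
        if r1.chrom != r2.chrom:
            tallies["interchromosomal_pairs"] += 1
            continue
        left, right = (r1, r2) if r1.pos <= r2.pos else (r2, r1)
        if left.strand == "-" and right.strand == "+":
            if right.end - left.pos <= max_circle_len and right.end > left.pos:
                out.append(
                    JunctionEvidence(
                        chrom=left.chrom,
                        start=left.pos,
                        end=right.end,
                        source="discordant_pair",
                        qname=qname,
                    )
                )
        else:
            tallies["proper_fr_pairs"] += 1
    return out


# ---------------------------------------------------------------------------
# coverage


@dataclass
class CoverageProfile:
    """Binned per-base depth per chromosome plus the genome-wide background."""

    bin_size: int
    depth: dict[str, np.ndarray]  # per-bin mean per-base depth
    background_depth: float

    def mean_depth(self, chrom: str, start: int, end: int) -> float:
        """Overlap-weighted mean per-base depth over [start, end)."""
        arr = self.depth.get(chrom)
        if arr is None or end <= start:
            return 0.0
        bs = self.bin_size
        first, last = start // bs, (end - 1) // bs
        total = 0.0
        for b in range(first, min(last, len(arr) - 1) + 1):
            lo = max(start, b * bs)
            hi = min(end, (b + 1) * bs)
            total += float(arr[b]) * (hi - lo)
        return total / (end - start)


def coverage_profile(
    records: Iterable[AlignmentRecord],
    assembly_lengths: dict[str, int],
    bin_size: int = 50,
    background_pseudocount: float = 0.01,
) -> CoverageProfile:
    """Binned depth of mapped aligned bases; background = genome-wide median
    bin depth + pseudocount (robust to the circle peaks by construction)."""
    counts = {
        chrom: np.zeros((length + bin_size - 1) // bin_size)
        for chrom, length in assembly_lengths.items()
    }
    for r in records:
        if not r.mapped or r.chrom not in counts:
            continue
        arr = counts[r.chrom]
        s, e = r.pos, r.end
        first, last = s // bin_size, (e - 1) // bin_size
        for b in range(first, min(last, len(arr) - 1) + 1):
            lo = max(s, b * bin_size)
            hi = min(e, (b + 1) * bin_size)
            arr[b] += hi - lo
    depth = {c: a / bin_size for c, a in counts.items()}
    all_bins = (
        np.concatenate(list(depth.values())) if depth else np.zeros(1)
    )
    background = float(np.median(all_bins)) + background_pseudocount
    return CoverageProfile(bin_size=bin_size, depth=depth, background_depth=background)


# ---------------------------------------------------------------------------
# clustering and calling


def _single_linkage_clusters(
    junctions: list[JunctionEvidence], epsilon: int
) -> list[list[JunctionEvidence]]:
    """Connected components of the graph linking junctions whose start AND end
    coordinates are each within epsilon.  Sorted sweep over starts; edges only
    exist between junctions with |delta start| <= epsilon, so scanning back
    within that window finds every edge."""
    if not junctions:
        return []
    order = sorted(range(len(junctions)), key=lambda i: (junctions[i].start, junctions[i].end))
    parent = list(range(len(junctions)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for oi in range(len(order)):
        i = order[oi]
        oj = oi - 1
        while oj >= 0:
            j = order[oj]
            if junctions[i].start - junctions[j].start > epsilon:
                break
            if abs(junctions[i].end - junctions[j].end) <= epsilon:
                union(i, j)
            oj -= 1
    comps: dict[int, list[JunctionEvidence]] = defaultdict(list)
    for i, j in enumerate(junctions):
        comps[find(i)].append(j)
    return list(comps.values())


def brute_force_clusters(
    junctions: list[JunctionEvidence], epsilon: int
) -> list[list[JunctionEvidence]]:
    """O(n^2) transitive-closure clustering; the reference oracle for
    :func:`_single_linkage_clusters` on small inputs."""
    n = len(junctions)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if (
                abs(junctions[i].start - junctions[j].start) <= epsilon
                and abs(junctions[i].end - junctions[j].end) <= epsilon
            ):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    comps: dict[int, list[JunctionEvidence]] = defaultdict(list)
    for i in range(n):
        comps[find(i)].append(junctions[i])
    return list(comps.values())


def cluster_and_call(
    junctions: list[JunctionEvidence],
    discordants: list[JunctionEvidence],
    coverage: CoverageProfile,
    config: CallerConfig,
    sample_id: str = "sample",
    tallies: dict | None = None,
) -> CircleCatalog:
    """Cluster split junctions, corroborate with discordant pairs, apply the
    evidence rule and emit the per-sample catalog.

    A candidate (per-cluster median breakpoints) becomes a call iff
    ``split_support >= min_split`` OR (``split_support >= alt_min_split`` AND
    ``discordant_support >= alt_min_discordant``), AND enrichment over
    background >= ``min_enrichment``, AND length within bounds.  Calls
    within epsilon on both breakpoints are merged with supports summed.
    """
    config.validate()
    if tallies is None:
        tallies = {}
    for key in ("rejected_support", "rejected_enrichment", "rejected_length"):
        tallies.setdefault(key, 0)

    by_chrom: dict[str, list[JunctionEvidence]] = defaultdict(list)
    for j in junctions:
        if j.source == "split_read":
            by_chrom[j.chrom].append(j)
    disc_by_chrom: dict[str, list[JunctionEvidence]] = defaultdict(list)
    for d in discordants:
        disc_by_chrom[d.chrom].append(d)

    eps = config.epsilon
    slack = config.max_insert + eps
    calls: list[CircleCall] = []
    for chrom in sorted(by_chrom):
        clusters = _single_linkage_clusters(by_chrom[chrom], eps)
        discs = disc_by_chrom.get(chrom, [])
        for cluster in clusters:
            start = int(np.median([j.start for j in cluster]))
            end = int(np.median([j.end for j in cluster]))
            split_support = len(cluster)
            disc_support = sum(
                1
                for d in discs
                if start - eps <= d.start <= start + slack
                and end - slack <= d.end <= end + eps
            )
            length = end - start
            passes_support = split_support >= config.min_split or (
                split_support >= config.alt_min_split
                and disc_support >= config.alt_min_discordant
            )
            if not passes_support:
                tallies["rejected_support"] += 1
                continue
            if not config.min_circle_len <= length <= config.max_circle_len:
                tallies["rejected_length"] += 1
                continue
            mean_depth = coverage.mean_depth(chrom, start, end)
            enrichment = mean_depth / coverage.background_depth
            if enrichment < config.min_enrichment:
                tallies["rejected_enrichment"] += 1
                continue
            calls.append(
                CircleCall(
                    chrom=chrom,
                    start=start,
                    end=end,
                    split_support=split_support,
                    discordant_support=disc_support,
                    mean_depth=mean_depth,
                    enrichment=enrichment,
                )
            )

    calls = _merge_calls(calls, eps)
    calls.sort(key=lambda c: (c.chrom, c.start, c.end))
    return CircleCatalog(sample_id=sample_id, calls=calls)


def _merge_calls(calls: list[CircleCall], epsilon: int) -> list[CircleCall]:
    """Merge calls agreeing within epsilon on both breakpoints (supports summed,
    breakpoints and depth from the higher-split-support member)."""
    merged: list[CircleCall] = []
    for call in sorted(
        calls, key=lambda c: (c.chrom, -c.split_support, c.start, c.end)
    ):
        hit = None
        for m in merged:
            if (
                m.chrom == call.chrom
                and abs(m.start - call.start) <= epsilon
                and abs(m.end - call.end) <= epsilon
            ):
                hit = m
                break
        if hit is None:
            merged.append(call)
        else:
            hit.split_support += call.split_support
            hit.discordant_support += call.discordant_support
    return merged


def call_circles(
    sam_path: str,
    assembly_lengths: dict[str, int],
    config: CallerConfig | None = None,
    sample_id: str = "sample",
) -> tuple[CircleCatalog, dict]:
    """End-to-end convenience: parse, extract evidence, profile coverage, call.

    Returns the catalog and a QC dict (alignment totals, evidence tallies,
    rejection reasons).
    """
    config = config or CallerConfig()
    records = list(parse_alignments(sam_path))
    qc = alignment_qc(records)
    tallies: dict = {}
    junctions = extract_split_junctions(records, tallies)
    discordants = extract_discordant_pairs(records, config.max_circle_len, tallies)
    coverage = coverage_profile(
        records, assembly_lengths, config.bin_size, config.background_pseudocount
    )
    catalog = cluster_and_call(
        junctions, discordants, coverage, config, sample_id, tallies
    )
    qc.update(
        {
            "n_split_junctions": len(junctions),
            "n_discordant_pairs": len(discordants),
            "background_depth": coverage.background_depth,
            "tallies": tallies,
            "config": asdict(config),
        }
    )
    return catalog, qc


# ---------------------------------------------------------------------------
# catalog I/O


_TSV_COLUMNS = (
    "chrom", "start", "end", "length",
    "split_support", "discordant_support", "mean_depth", "enrichment",
)


def write_catalog(catalog: CircleCatalog, bed_path: str, tsv_path: str) -> None:
    """BED6 (0-based half-open; name=call id, score=split support) + full TSV."""
    with open(bed_path, "w") as bed:
        for i, c in enumerate(catalog.calls, start=1):
            bed.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{catalog.sample_id}_ecc{i:05d}\t"
                f"{c.split_support}\t+\n"
            )
    with open(tsv_path, "w") as tsv:
        tsv.write(f"#sample_id={catalog.sample_id}\n")
        tsv.write("\t".join(_TSV_COLUMNS) + "\n")
        for c in catalog.calls:
            tsv.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.length}\t{c.split_support}\t"
                f"{c.discordant_support}\t{c.mean_depth!r}\t{c.enrichment!r}\n"
            )


def read_catalog(tsv_path: str) -> CircleCatalog:
    sample_id = "sample"
    calls: list[CircleCall] = []
    with open(tsv_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("#sample_id="):
                sample_id = line.split("=", 1)[1]
                continue
            if not line or line.startswith("chrom"):
                continue
            cols = line.split("\t")
            if len(cols) != len(_TSV_COLUMNS):
                raise ValueError(
                    f"{tsv_path} line {lineno}: expected {len(_TSV_COLUMNS)} columns, "
                    f"got {len(cols)}"
                )
            try:
                chrom = cols[0]
                start, end, length = int(cols[1]), int(cols[2]), int(cols[3])
                split_s, disc_s = int(cols[4]), int(cols[5])
                depth, enrich = float(cols[6]), float(cols[7])
            except ValueError:
                raise ValueError(f"{tsv_path} line {lineno}: malformed field") from None
            if length != end - start:
                raise ValueError(
                    f"{tsv_path} line {lineno}: length {length} != end - start"
                )
            calls.append(CircleCall(chrom, start, end, split_s, disc_s, depth, enrich))
    return CircleCatalog(sample_id=sample_id, calls=calls)


def write_qc(qc: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(qc, fh, indent=2, sort_keys=True)
        fh.write("\n")
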