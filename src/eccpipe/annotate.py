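"""Catalog characterization: length histograms, chromosomal origin, gene content.

A circle is classified by its interval's relationship to the gene models:
``full_gene`` if it fully contains at least one gene span (containment
wins even when other genes are only partially overlapped), ``intergenic``
if it overlaps no gene span, and otherwise ``partial_gene`` with a subtype
given by the feature kind (5'UTR / exon / intron / 3'UTR) contributing the
most overlapped bases, ties broken intronic > exonic > 5'UTR > 3'UTR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .caller import CircleCall, CircleCatalog
from .genome import AnnotationSet

PARTIAL_SUBTYPES = ("five_prime_utr", "three_prime_utr", "exonic", "intronic")
_SUBTYPE_OF_KIND = {
    "five_prime_utr": "five_prime_utr",
    "three_prime_utr": "three_prime_utr",
    "exon": "exonic",
    "intron": "intronic",
}
# tie order: higher rank wins on equal overlap
_TIE_RANK = {"intronic": 3, "exonic": 2, "five_prime_utr": 1, "three_prime_utr": 0}


@dataclass(frozen=True)
class ContentClass:
    kind: str  # full_gene | partial_gene | intergenic
    subtype: str | None = None  # partial_gene only

    def __post_init__(self):
        if self.kind == "partial_gene":
            if self.subtype not in PARTIAL_SUBTYPES:
                raise ValueError(f"partial_gene requires a subtype, got {self.subtype!r}")
        elif self.subtype is not None:
            raise ValueError(f"{self.kind} takes no subtype")


def classify_circle(
    call: CircleCall,
    annotation: AnnotationSet,
    known_chroms: set[str] | None = None,
) -> ContentClass:
    """Gene-content class of one call (see module docstring for the rule)."""
    if known_chroms is not None and call.chrom not in known_chroms:
        raise KeyError(f"unknown chromosome {call.chrom!r}")
    genes = annotation.overlapping(call.chrom, call.start, call.end)
    if not genes:
        return ContentClass("intergenic")
    if any(g.start >= call.start and g.end <= call.end for g in genes):
        return ContentClass("full_gene")
    overlap_by_subtype = {s: 0 for s in PARTIAL_SUBTYPES}
    for g in genes:
        for kind, (fs, fe) in g.features:
            ov = min(fe, call.end) - max(fs, call.start)
            if ov > 0:
                overlap_by_subtype[_SUBTYPE_OF_KIND[kind]] += ov
    best = max(
        PARTIAL_SUBTYPES,
        key=lambda s: (overlap_by_subtype[s], _TIE_RANK[s]),
    )
    return ContentClass("partial_gene", best)


def format_pct_2sf(pct: float) -> str:
    """Render a percentage at 2 significant figures (e.g. 0.31%, 0.075%)."""
    if pct == 0:
        return "0.0%"
    if not math.isfinite(pct):
        return "NA"
    exponent = math.floor(math.log10(abs(pct)))
    rounded = round(pct, -exponent + 1)
    if exponent + 1 >= 2:
        return f"{rounded:.0f}%"
    return f"{rounded:.{max(0, 1 - exponent)}f}%"


def full_gene_report(n_full: int, n_total: int) -> tuple[int, int, str]:
    """(n_full, n_total, percentage string at 2 significant figures)."""
    if n_total == 0:
        return (n_full, 0, "NA")
    return (n_full, n_total, format_pct_2sf(100.0 * n_full / n_total))


@dataclass
class CatalogSummary:
    """Per-sample characterization of a circle catalog."""

    n_eccDNA: int
    mean_length: float | None
    bin_size: int
    histogram: dict[int, int]            # bin start (bp) -> count
    range_fraction: float | None         # fraction of lengths in size_range
    size_range: tuple[int, int]
    per_chrom: list[tuple[str, int, float | None]]  # (chrom, count, mean length)
    content_counts: dict[str, int]       # flattened class -> count
    full_gene_pct: str

    def validate(self) -> None:
        assert sum(self.histogram.values()) == self.n_eccDNA
        assert sum(self.content_counts.values()) == self.n_eccDNA
        assert sum(n for _, n, _ in self.per_chrom) == self.n_eccDNA
        if self.range_fraction is not None:
            assert 0.0 <= self.range_fraction <= 1.0


def content_label(cc: ContentClass) -> str:
    return cc.kind if cc.subtype is None else f"{cc.kind}:{cc.subtype}"


def summarize_catalog(
    catalog: CircleCatalog,
    annotation: AnnotationSet,
    bin_size: int = 200,
    size_range: tuple[int, int] = (400, 6000),
    known_chroms: set[str] | None = None,
) -> CatalogSummary:
    """Histogram (half-open bins [k*bin, (k+1)*bin)), size-range fraction
    (half-open [400, 6000) by default), per-chromosome counts and gene-content
    classification of every call.  An empty catalog yields defined zeros with
    undefined-marked means and percentages."""
    lengths = [c.length for c in catalog.calls]
    n = len(lengths)
    histogram: dict[int, int] = {}
    for length in lengths:
        b = (length // bin_size) * bin_size
        histogram[b] = histogram.get(b, 0) + 1
    in_range = sum(1 for length in lengths if size_range[0] <= length < size_range[1])
    per_chrom_map: dict[str, list[int]] = {}
    for c in catalog.calls:
        per_chrom_map.setdefault(c.chrom, []).append(c.length)
    per_chrom = [
        (chrom, len(ls), float(np.mean(ls)))
        for chrom, ls in sorted(per_chrom_map.items())
    ]
    content_counts: dict[str, int] = {}
    n_full = 0
    for c in catalog.calls:
        cc = classify_circle(c, annotation, known_chroms)
        label = content_label(cc)
        content_counts[label] = content_counts.get(label, 0) + 1
        n_full += int(cc.kind == "full_gene")
    _, _, pct = full_gene_report(n_full, n)
    summary = CatalogSummary(
        n_eccDNA=n,
        mean_length=float(np.mean(lengths)) if n else None,
        bin_size=bin_size,
        histogram=dict(sorted(histogram.items())),
        range_fraction=(in_range / n) if n else None,
        size_range=size_range,
        per_chrom=per_chrom,
        content_counts=dict(sorted(content_counts.items())),
        full_gene_pct=pct,
    )
    summary.validate()
    return summary


@dataclass
class ChromDistribution:
    chroms: list[str]
    observed: np.ndarray
    expected: np.ndarray           # proportional to chromosome length
    chi2: float
    p_value: float
    small_expected_warning: bool
    per_chrom_mean_length: dict[str, float | None]


def chromosome_distribution(
    catalog: CircleCatalog, assembly_lengths: dict[str, int]
) -> ChromDistribution:
    """Observed vs length-proportional expected circle counts per chromosome,
    with a chi-square goodness-of-fit test."""
    if len(assembly_lengths) < 2:
        raise ValueError("need at least 2 chromosomes for a distribution test")
    chroms = list(assembly_lengths)
    counts = {c: 0 for c in chroms}
    mean_lens: dict[str, list[int]] = {c: [] for c in chroms}
    for call in catalog.calls:
        if call.chrom not in counts:
            raise KeyError(f"unknown chromosome {call.chrom!r}")
        counts[call.chrom] += 1
        mean_lens[call.chrom].append(call.length)
    observed = np.array([counts[c] for c in chroms], dtype=float)
    total = observed.sum()
    w = np.array([assembly_lengths[c] for c in chroms], dtype=float)
    expected = total * w / w.sum()
    if total == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2, p = stats.chisquare(observed, expected)
    return ChromDistribution(
        chroms=chroms,
        observed=observed,
        expected=expected,
        chi2=float(chi2),
        p_value=float(p),
        small_expected_warning=bool((expected < 1).any()),
        per_chrom_mean_length={
            c: (float(np.mean(v)) if v else None) for c, v in mean_lens.items()
        },
    )


def brute_force_classify(
    call: CircleCall, annotation: AnnotationSet
) -> ContentClass:
    """Per-base reference classifier: scans every gene and feature base-by-base.

    Slow by design; the independent oracle for :func:`classify_circle`.
    """
    circle_bases = set(range(call.start, call.end))
    contained_gene = False
    any_overlap = False
    subtype_bases = {s: 0 for s in PARTIAL_SUBTYPES}
    for g in annotation.genes:
        if g.chrom != call.chrom:
            continue
        gene_bases = set(range(g.start, g.end))
        if gene_bases and gene_bases <= circle_bases:
            contained_gene = True
        if gene_bases & circle_bases:
            any_overlap = True
            for kind, (fs, fe) in g.features:
                subtype_bases[_SUBTYPE_OF_KIND[kind]] += len(
                    set(range(fs, fe)) & circle_bases
                )
    if contained_gene:
        return ContentClass("full_gene")
    if not any_overlap:
        return ContentClass("intergenic")
    best = max(PARTIAL_SUBTYPES, key=lambda s: (subtype_bases[s], _TIE_RANK[s]))
    return ContentClass("partial_gene", best)
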