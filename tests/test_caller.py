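"""Caller: SAM parsing, evidence extraction, clustering, calling, catalog I/O."""

import re

import numpy as np
import pytest

from eccpipe.caller import (
    AlignmentRecord,
    CallerConfig,
    CircleCall,
    CircleCatalog,
    CoverageProfile,
    JunctionEvidence,
    SAMParseError,
    _single_linkage_clusters,
    alignment_qc,
    brute_force_clusters,
    call_circles,
    cluster_and_call,
    coverage_profile,
    extract_discordant_pairs,
    extract_split_junctions,
    parse_alignments,
    read_catalog,
    write_catalog,
)
from eccpipe.evaluate import benchmark_calls

_OPS = {"M": 0, "I": 1, "D": 2, "S": 4, "H": 5}


def cig(s):
    return [(_OPS[op], int(n)) for n, op in re.findall(r"(\d+)([MIDSH])", s)]


def rec(
    qname, chrom, pos, strand, cigar, supp=False, read1=True,
    mate_chrom=None, mate_pos=0, mate_strand="+", proper=False,
):
    return AlignmentRecord(
        qname=qname, chrom=chrom, pos=pos, strand=strand, cigar=cig(cigar),
        is_supplementary=supp, is_read1=read1,
        mate_chrom=mate_chrom or chrom, mate_pos=mate_pos,
        mate_strand=mate_strand, is_proper_linear_pair=proper, mapped=True,
    )


# --- parsing ----------------------------------------------------------------


SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr1\tLN:100000\n"


def _sam_line(qname, flag, pos, cigar, seq="A" * 150):
    return f"{qname}\t{flag}\tchr1\t{pos}\t60\t{cigar}\t*\t0\t0\t{seq}\t*\n"


def test_parse_qc_mapped_fraction(tmp_path):
    body = "".join(_sam_line(f"r{i}", 0, 100 + i, "150M") for i in range(9))
    body += "r9\t4\t*\t0\t0\t*\t*\t0\t0\t" + "A" * 150 + "\t*\n"
    p = tmp_path / "a.sam"
    p.write_text(SAM_HEADER + body)
    records = list(parse_alignments(str(p)))
    qc = alignment_qc(records)
    assert qc["total_records"] == 10
    assert qc["mapped_fraction"] == pytest.approx(0.9)
    assert not records[-1].mapped


def test_parse_empty_body(tmp_path):
    p = tmp_path / "e.sam"
    p.write_text(SAM_HEADER)
    records = list(parse_alignments(str(p)))
    assert records == []
    assert alignment_qc(records)["total_records"] == 0


def test_parse_clip_structure(tmp_path):
    p = tmp_path / "c.sam"
    p.write_text(SAM_HEADER + _sam_line("r1", 0, 1000, "50M100S"))
    (r,) = parse_alignments(str(p))
    assert r.clip_structure == (0, 50, 100)
    assert r.ref_span == 50


def test_parse_rejects_unknown_cigar_op(tmp_path):
    p = tmp_path / "n.sam"
    p.write_text(SAM_HEADER + _sam_line("r1", 0, 1000, "50M1000N100M", seq="*"))
    with pytest.raises(SAMParseError):
        list(parse_alignments(str(p)))


# --- split junctions --------------------------------------------------------


def test_split_junction_circular_geometry():
    """Right-clipped leading segment downstream + left-clipped trailing
    segment upstream -> junction (upstream start, downstream end)."""
    records = [
        rec("q1", "chr1", 9950, "+", "50M100S"),
        rec("q1", "chr1", 1000, "+", "50S100M", supp=True),
    ]
    (j,) = extract_split_junctions(records)
    assert (j.chrom, j.start, j.end) == ("chr1", 1000, 10_000)
    assert j.source == "split_read"


def test_split_junction_fully_matched_read_yields_nothing():
    assert extract_split_junctions([rec("q1", "chr1", 500, "+", "150M")]) == []


def test_split_junction_linear_geometry_yields_nothing():
    """Deletion-like split (leading segment upstream) is not circle evidence."""
    tallies = {}
    records = [
        rec("q1", "chr1", 1000, "+", "100M50S"),
        rec("q1", "chr1", 9950, "+", "100S50M", supp=True),
    ]
    assert extract_split_junctions(records, tallies) == []
    assert tallies["linear_split"] == 1


def test_split_junction_cross_chrom_or_strand_tallied():
    tallies = {}
    records = [
        rec("q1", "chr1", 9950, "+", "50M100S"),
        rec("q1", "chr2", 1000, "+", "50S100M", supp=True),
        rec("q2", "chr1", 9950, "+", "50M100S"),
        rec("q2", "chr1", 1000, "-", "50S100M", supp=True),
    ]
    assert extract_split_junctions(records, tallies) == []
    assert tallies["non_circular_split"] == 2


def test_split_junction_reverse_strand_pair():
    records = [
        rec("q1", "chr1", 9950, "-", "50M100S"),
        rec("q1", "chr1", 1000, "-", "50S100M", supp=True),
    ]
    (j,) = extract_split_junctions(records)
    assert (j.start, j.end) == (1000, 10_000)


# --- discordant pairs -------------------------------------------------------


def test_discordant_rf_pair_detected():
    records = [
        rec("q1", "chr1", 5000, "-", "150M", read1=True, mate_pos=7850, mate_strand="+"),
        rec("q1", "chr1", 7850, "+", "150M", read1=False, mate_pos=5000, mate_strand="-"),
    ]
    (d,) = extract_discordant_pairs(records)
    assert (d.start, d.end) == (5000, 8000)
    assert d.source == "discordant_pair"


def test_fr_innie_pair_ignored():
    tallies = {}
    records = [
        rec("q1", "chr1", 5000, "+", "150M", read1=True, proper=True),
        rec("q1", "chr1", 7850, "-", "150M", read1=False, proper=True),
    ]
    assert extract_discordant_pairs(records, tallies=tallies) == []
    assert tallies["proper_fr_pairs"] == 1


def test_discordant_evidence_contains_true_junction(noiseless_run):
    """Every outward-facing evidence interval from the noiseless simulation
    lies inside the originating circle (it bounds the junction)."""
    circles, result, _, _ = noiseless_run
    by_id = {c.circle_id: c for c in circles}
    by_qname = {q: cid for q, cid, _ in result.truth.provenance}
    records = []
    for r1, r2 in result.reads:
        for read in (r1, r2):
            seg = read.segments[0]
            mate = r2 if read is r1 else r1
            records.append(
                AlignmentRecord(
                    qname=read.qname, chrom=seg.chrom, pos=seg.pos,
                    strand=read.strand,
                    cigar=cig(seg.cigar), is_supplementary=False,
                    is_read1=read.is_read1, mate_chrom=mate.segments[0].chrom,
                    mate_pos=mate.segments[0].pos, mate_strand=mate.strand,
                    is_proper_linear_pair=False, mapped=True,
                )
            )
    discs = extract_discordant_pairs(records)
    assert len(discs) >= 1
    for d in discs:
        c = by_id[by_qname[d.qname]]
        assert c.chrom == d.chrom
        assert c.start <= d.start and d.end <= c.end


# --- coverage ---------------------------------------------------------------


def test_coverage_mean_depth_uniform():
    rng = np.random.default_rng(0)
    records = [
        rec(f"r{i}", "chr1", int(rng.integers(0, 150_000 - 150)), "+", "150M")
        for i in range(100)
    ]
    prof = coverage_profile(records, {"chr1": 150_000}, bin_size=50)
    mean_depth = prof.mean_depth("chr1", 0, 150_000)
    assert mean_depth == pytest.approx(100 * 150 / 150_000, rel=0.01)


def test_coverage_empty_input():
    prof = coverage_profile([], {"chr1": 10_000}, background_pseudocount=0.01)
    assert prof.mean_depth("chr1", 0, 10_000) == 0.0
    assert prof.background_depth == pytest.approx(0.01)


# --- clustering and calling -------------------------------------------------


def flat_profile(chrom_len=100_000, depth=40.0, background=0.01):
    n = (chrom_len + 49) // 50
    return CoverageProfile(
        bin_size=50, depth={"chr1": np.full(n, depth)}, background_depth=background
    )


def test_three_identical_junctions_one_call():
    js = [
        JunctionEvidence("chr1", 1000, 10_000, "split_read", f"q{i}") for i in range(3)
    ]
    cat = cluster_and_call(js, [], flat_profile(), CallerConfig())
    assert cat.n_eccDNA == 1
    (call,) = cat.calls
    assert (call.start, call.end, call.length) == (1000, 10_000, 9000)
    assert call.split_support == 3
    assert call.enrichment > 2.0


def test_single_junction_rejected_under_defaults():
    js = [JunctionEvidence("chr1", 1000, 10_000, "split_read", "q0")]
    tallies = {}
    cat = cluster_and_call(js, [], flat_profile(), CallerConfig(), tallies=tallies)
    assert cat.n_eccDNA == 0
    assert tallies["rejected_support"] == 1


def test_single_junction_rescued_by_two_discordants():
    js = [JunctionEvidence("chr1", 1000, 10_000, "split_read", "q0")]
    ds = [
        JunctionEvidence("chr1", 1100, 9900, "discordant_pair", "d1"),
        JunctionEvidence("chr1", 1200, 9800, "discordant_pair", "d2"),
    ]
    cat = cluster_and_call(js, ds, flat_profile(), CallerConfig())
    assert cat.n_eccDNA == 1
    assert cat.calls[0].discordant_support == 2


def test_empty_evidence_empty_catalog():
    cat = cluster_and_call([], [], flat_profile(), CallerConfig())
    assert cat.n_eccDNA == 0 and cat.calls == []
    assert cat.mean_length is None


def test_low_enrichment_rejected():
    js = [
        JunctionEvidence("chr1", 1000, 10_000, "split_read", f"q{i}") for i in range(3)
    ]
    tallies = {}
    cat = cluster_and_call(
        js, [], flat_profile(depth=0.5, background=1.0), CallerConfig(),
        tallies=tallies,
    )
    assert cat.n_eccDNA == 0
    assert tallies["rejected_enrichment"] == 1


def test_clustering_matches_brute_force_oracle():
    """Single-linkage sweep == O(n^2) transitive closure, 100 random instances."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = int(rng.integers(1, 201))
        starts = rng.integers(0, 2000, size=n)
        ends = starts + rng.integers(300, 3000, size=n)
        js = [
            JunctionEvidence("chr1", int(s), int(e), "split_read", f"q{i}")
            for i, (s, e) in enumerate(zip(starts, ends))
        ]
        eps = int(rng.integers(1, 20))
        fast = {frozenset(j.qname for j in cl) for cl in _single_linkage_clusters(js, eps)}
        slow = {frozenset(j.qname for j in cl) for cl in brute_force_clusters(js, eps)}
        assert fast == slow


def test_truth_recovery_breakpoint_accuracy(noiseless_run):
    circles, _, catalog, _ = noiseless_run
    bench = benchmark_calls(circles, catalog, tol=5)
    assert bench.recall >= 0.95 and bench.precision >= 0.95


# --- catalog I/O ------------------------------------------------------------


def worked_example_call():
    return CircleCall(
        chrom="chr1", start=57_239_706, end=57_240_822,
        split_support=7, discordant_support=3, mean_depth=41.5, enrichment=4150.0,
    )


def test_worked_example_length_convention(tmp_path):
    """chr1:57,239,706-57,240,822 is a 1116-bp circle: length = end - start."""
    call = worked_example_call()
    assert call.length == 1116
    cat = CircleCatalog("mcl1_liver", [call])
    bed, tsv = str(tmp_path / "c.bed"), str(tmp_path / "c.tsv")
    write_catalog(cat, bed, tsv)
    fields = open(bed).readline().split("\t")
    assert (int(fields[1]), int(fields[2])) == (57_239_706, 57_240_822)
    line = open(tsv).readlines()[2].split("\t")
    assert int(line[3]) == 1116


def test_catalog_round_trip(tmp_path):
    rng = np.random.default_rng(1)
    calls = []
    for i in range(100):
        s = int(rng.integers(0, 1_000_000))
        calls.append(
            CircleCall(
                "chr1", s, s + int(rng.integers(300, 5000)),
                int(rng.integers(1, 20)), int(rng.integers(0, 10)),
                float(rng.uniform(1, 100)), float(rng.uniform(2, 500)),
            )
        )
    calls.sort(key=lambda c: (c.chrom, c.start, c.end))
    cat = CircleCatalog("s1", calls)
    bed, tsv = str(tmp_path / "c.bed"), str(tmp_path / "c.tsv")
    write_catalog(cat, bed, tsv)
    rt = read_catalog(tsv)
    assert rt.sample_id == "s1" and rt.calls == cat.calls


def test_overlapping_distinct_calls_both_kept(tmp_path):
    c1 = CircleCall("chr1", 1000, 5000, 3, 0, 10.0, 100.0)
    c2 = CircleCall("chr1", 1200, 5100, 2, 0, 10.0, 100.0)  # outside epsilon
    cat = CircleCatalog("s", [c1, c2])
    bed, tsv = str(tmp_path / "o.bed"), str(tmp_path / "o.tsv")
    write_catalog(cat, bed, tsv)
    assert read_catalog(tsv).n_eccDNA == 2


def test_malformed_catalog_tsv_reports_line(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text(
        "#sample_id=s\nchrom\tstart\tend\tlength\tsplit_support\t"
        "discordant_support\tmean_depth\tenrichment\n"
        "chr1\tx\t10\t5\t1\t0\t1.0\t2.0\n"
    )
    with pytest.raises(ValueError, match="line 3"):
        read_catalog(str(p))


def test_catalog_determinism(tmp_path, assembly, annotation):
    """Identical SAM and config produce byte-identical catalogs."""
    from eccpipe.simulate import SimConfig, sample_circles, simulate_reads, write_truth_sam

    cfg = SimConfig(n_circles=8, seed=77, n_read_pairs=2000)
    circles = sample_circles(assembly, annotation, cfg)
    result = simulate_reads(assembly, circles, cfg)
    sam = str(tmp_path / "d.sam")
    write_truth_sam(result, assembly, sam)
    outs = []
    for run in range(2):
        catalog, _ = call_circles(sam, assembly.lengths)
        bed, tsv = str(tmp_path / f"{run}.bed"), str(tmp_path / f"{run}.tsv")
        write_catalog(catalog, bed, tsv)
        outs.append(open(tsv, "rb").read())
    assert outs[0] == outs[1]
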