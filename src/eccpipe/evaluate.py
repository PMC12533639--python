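"""Benchmarking calls against simulation ground truth."""

from __future__ import annotations

from dataclasses import dataclass

from .caller import CircleCatalog
from .simulate import TrueCircle


@dataclass
class Benchmark:
    recall: float
    precision: float
    n_true: int
    n_called: int
    n_matched: int
    matches: list[tuple[str, int]]  # (circle_id, call index)


def benchmark_calls(
    truth: list[TrueCircle], catalog: CircleCatalog, tol: int = 5
) -> Benchmark:
    """Match calls to truth circles with both breakpoints within ``tol`` bp.

    Greedy one-to-one matching in catalog order; recall = matched truth /
    truth, precision = matched calls / calls.
    """
    unmatched = {c.circle_id: c for c in truth}
    matches: list[tuple[str, int]] = []
    for i, call in enumerate(catalog.calls):
        hit = None
        for cid, t in unmatched.items():
            if (
                t.chrom == call.chrom
                and abs(t.start - call.start) <= tol
                and abs(t.end - call.end) <= tol
            ):
                hit = cid
                break
        if hit is not None:
            matches.append((hit, i))
            del unmatched[hit]
    n_true, n_called, n_matched = len(truth), catalog.n_eccDNA, len(matches)
    return Benchmark(
        recall=(n_matched / n_true) if n_true else 1.0,
        precision=(n_matched / n_called) if n_called else 1.0,
        n_true=n_true,
        n_called=n_called,
        n_matched=n_matched,
        matches=matches,
    )
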