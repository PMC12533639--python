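import os

import pytest

from eccpipe import (
    SimConfig,
    call_circles,
    make_annotation,
    make_reference,
    sample_circles,
    simulate_reads,
    write_truth_sam,
)


@pytest.fixture(scope="session")
def assembly():
    """2-chromosome synthetic reference totaling 3 Mb."""
    return make_reference(2, [1_000_000, 2_000_000], 0.42, seed=7)


@pytest.fixture(scope="session")
def annotation(assembly):
    """40 non-overlapping genes, 2-10 kb, 2-5 exons."""
    return make_annotation(assembly, 40, (2000, 10_000), (2, 5), seed=3)


def run_pipeline(assembly, annotation, tmpdir, config, sample_id="sample"):
    """Simulate a library at ~40x per circle and call circles from it."""
    circles = sample_circles(assembly, annotation, config)
    if config.n_read_pairs == 0 and circles:
        config.n_read_pairs = int(sum(c.length for c in circles) * 40 / 300)
    result = simulate_reads(assembly, circles, config)
    sam = os.path.join(tmpdir, f"{sample_id}.sam")
    write_truth_sam(result, assembly, sam)
    catalog, qc = call_circles(sam, assembly.lengths, sample_id=sample_id)
    return circles, result, catalog, qc


@pytest.fixture(scope="session")
def noiseless_run(assembly, annotation, tmp_path_factory):
    """50 circles, error-free, no background, ~40x coverage per circle."""
    tmpdir = str(tmp_path_factory.mktemp("noiseless"))
    config = SimConfig(
        n_circles=50, seed=11, error_rate=0.0, background_frac=0.0, n_read_pairs=0
    )
    return run_pipeline(assembly, annotation, tmpdir, config)
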