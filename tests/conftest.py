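import numpy as np
import pytest

from tnpool.demux import BarcodeTable, GenomeIndex, demux_reads
from tnpool.layout import GridLayout
from tnpool.presence import build_table
from tnpool.simulate import (
    DEFAULT_TRANSPOSON_TAG,
    ReadCountModel,
    generate_genome,
    random_barcode_table,
    simulate_picking,
    simulate_pooled_reads,
)


@pytest.fixture(scope="session")
def small_layout():
    """Six 96-well plates on a 2 x 3 plate grid (25 pools)."""
    return GridLayout(n_rows=8, n_cols=12, n_plate_rows=2, n_plate_cols=3, n_plates=6)


@pytest.fixture(scope="session")
def default_layout():
    return GridLayout()


@pytest.fixture(scope="session")
def small_genome():
    return generate_genome(120, seed=1)


@pytest.fixture(scope="session")
def det_pipeline(tmp_path_factory, small_layout, small_genome):
    """Deterministic end-to-end run on the small fixture: reads through table.

    Shared by the integration and acceptance tests; everything downstream of
    the FASTQ pair is produced by the pipeline itself, not by the simulator.
    """
    out = tmp_path_factory.mktemp("detfix")
    truth = simulate_picking(
        small_genome,
        small_layout,
        n_picks=small_layout.n_plates * small_layout.usable_wells_per_plate,
        duplicate_rate=0.1,
        seed=2,
    )
    barcodes = random_barcode_table(small_layout, seed=3)
    model = ReadCountModel.deterministic(depth=20_000)
    truth_counts = simulate_pooled_reads(
        truth, model, barcodes, out / "main.fastq", out / "index.fastq", seed=4
    )
    table = BarcodeTable(barcodes)
    genome_index = GenomeIndex(small_genome.records)
    counts, stats = demux_reads(
        out / "main.fastq", out / "index.fastq", table, DEFAULT_TRANSPOSON_TAG,
        genome_index=genome_index,
    )
    return {
        "layout": small_layout,
        "genome": small_genome,
        "truth": truth,
        "truth_counts": truth_counts,
        "counts": counts,
        "stats": stats,
        "table": build_table(counts),
        "barcodes": barcodes,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
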