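import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from splicescape.core import (
    GenomeSequence,
    Interval,
    PipelineThresholds,
    TranscriptModel,
)


@pytest.fixture(scope="session")
def th() -> PipelineThresholds:
    return PipelineThresholds()


@pytest.fixture()
def toy_genome() -> GenomeSequence:
    # chr1: 1000 nt of A with a GT...AG intron planted at [200, 300)
    seq = list("A" * 1000)
    seq[200:202] = "GT"
    seq[298:300] = "AG"
    # a GC...AG intron at [500, 600)
    seq[500:502] = "GC"
    seq[598:600] = "AG"
    # minus-strand canonical intron at [700, 800): forward reads CT...AC
    seq[700:702] = "CT"
    seq[798:800] = "AC"
    return GenomeSequence({"chr1": "".join(seq)})


def tx(tid, exons, strand="+", cds=None, gene=None, chrom="chr1"):
    """Shorthand transcript builder used across the suite."""
    return TranscriptModel(
        id=tid,
        gene_id=gene or tid.split(".")[0],
        exons=[Interval(chrom, s, e, strand) for s, e in exons],
        cds=[Interval(chrom, s, e, strand) for s, e in cds] if cds else None,
    )


@pytest.fixture()
def make_tx():
    return tx
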