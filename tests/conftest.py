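import logging

import numpy as np
import pytest

from cnaevo.genome import CNAEvent, GenomeBuild, GenomicSegment

logging.getLogger("cnaevo").setLevel(logging.ERROR)


@pytest.fixture
def two_chrom_genome() -> GenomeBuild:
    return GenomeBuild.from_pairs([("chr1", 80_000_000), ("chr2", 60_000_000)])


@pytest.fixture
def small_genome() -> GenomeBuild:
    return GenomeBuild.from_pairs(
        [(f"chr{i}", 80_000_000) for i in range(1, 5)]
    )


def make_event(i: int, kind: str = "loss", chrom: str = "chr1",
               start: int | None = None, length: int = 1_000_000) -> CNAEvent:
    start = start if start is not None else i * 10_000_000
    delta = {"gain": 1, "loss": -1}.get(kind, 0)
    return CNAEvent(f"e{i}", kind, GenomicSegment(chrom, start, start + length),
                    delta)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
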