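import numpy as np
import pytest

from fusloc.io import PeakRecord, PeakSet
from fusloc.peaks import ScoredTranscript


@pytest.fixture
def toy_peak_file(tmp_path):
    """Minimal HOMER-dialect peak table: 2 data rows, 1-based inclusive."""
    path = tmp_path / "toy.peaks.txt"
    path.write_text(
        "# HOMER Peaks\n"
        "#PeakID\tchr\tstart\tend\tstrand\tTag Count\tGene Name\n"
        "peak1\tchr1\t100\t600\t+\t50\tGENE1\n"
        "peak2\tchr2\t1000\t4000\t-\t5\tGENE2\n"
    )
    return path


@pytest.fixture
def random_peak_set():
    """Randomized but reproducible PeakSet for round-trip properties."""
    rng = np.random.default_rng(42)
    records = []
    pos = 0
    for i in range(40):
        length = int(rng.integers(1, 5000))
        records.append(
            PeakRecord(
                peak_id=f"p{i}",
                gene_id=f"g{rng.integers(0, 20)}",
                chrom=f"chr{rng.integers(1, 5)}",
                start=pos,
                end=pos + length,
                strand="+" if rng.random() < 0.5 else "-",
                raw_reads=float(rng.integers(0, 10_000)),
            )
        )
        pos += length + 100
    return PeakSet(sample_label="rand", total_aligned_reads=50_000_000, records=records)


@pytest.fixture
def scored_transcripts():
    def make(scores_lengths):
        out = []
        for i, (s, l) in enumerate(scores_lengths):
            import math

            out.append(
                ScoredTranscript(
                    gene_id=f"g{i}",
                    peak_score=s,
                    length=l,
                    binding_surface_score=math.log2(s * l),
                )
            )
        return out

    return make
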