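import pandas as pd
import pytest

from cnvdrive.cnv_events import Segment, segments_to_events
from cnvdrive.formats_io import ExpressionMatrix, GeneModel


def make_segment(sample="s1", group="case", chromosome=1, start=0, end=10_000,
                 segment_mean=0.5):
    return Segment(sample=sample, group=group, chromosome=chromosome,
                   start=start, end=end, segment_mean=segment_mean)


@pytest.fixture
def toy_genes():
    return [
        GeneModel("GENE1", 1, 100, 500, "+"),
        GeneModel("GENE2", 1, 20_000, 25_000, "-"),
        GeneModel("GENE3", 2, 1_000, 4_000, "+"),
    ]


@pytest.fixture
def toy_expression():
    values = pd.DataFrame(
        {
            "t1": [3.0, 5.0, 8.0],
            "t2": [5.0, 5.0, 8.0],
            "n1": [2.0, 5.0, 8.0],
            "n2": [2.0, 5.0, 8.0],
        },
        index=["GENE1", "GENE2", "GENE3"],
    )
    groups = pd.Series(
        {"t1": "tumor", "t2": "tumor", "n1": "normal", "n2": "normal"}
    )
    return ExpressionMatrix(values=values, groups=groups)


@pytest.fixture
def toy_events():
    segments = [
        make_segment("case_a", "case", 1, 0, 10_000, 0.6),
        make_segment("case_b", "case", 1, 0, 10_000, 0.6),
        make_segment("ctrl_a", "control", 1, 50_000, 56_000, -0.6),
    ]
    return segments_to_events(segments)
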