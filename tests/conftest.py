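import numpy as np
import pytest

from flymb import IntervalSet


@pytest.fixture
def toy_intervals():
    return IntervalSet.from_records([
        ("chr2L", 100, 200, "a"),
        ("chr2L", 150, 250, "b"),
        ("chr2L", 300, 400, "c"),
        ("chr3R", 100, 200, "d"),
    ])


def brute_force_overlaps(a: IntervalSet, b: IntervalSet) -> list[int]:
    """Indices of a's records overlapping any record of b (all-pairs scan)."""
    hits = []
    for i, (ca, sa, ea, *_) in enumerate(a.records):
        for cb, sb, eb, *_ in b.records:
            if ca == cb and sa < eb and sb < ea:
                hits.append(i)
                break
    return hits
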