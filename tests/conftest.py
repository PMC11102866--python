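import numpy as np
import pandas as pd
import pytest

from nucseen.io_formats import SequenceRecord


@pytest.fixture
def backbone_601():
    from nucseen.synthetic_data import WIDOM_601

    return SequenceRecord("widom601", WIDOM_601)


def make_count_table(rows):
    """rows: (construct_id, replicate, fraction, count)"""
    return pd.DataFrame(rows, columns=["construct_id", "replicate", "fraction", "count"])


@pytest.fixture
def simple_counts():
    # one replicate, constructs c + spike in both fractions
    return make_count_table([
        ("pos1", 1, "bound", 20), ("widom601", 1, "bound", 10),
        ("pos1", 1, "unbound", 5), ("widom601", 1, "unbound", 10),
    ])


def rng(seed=0):
    return np.random.default_rng(seed)
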