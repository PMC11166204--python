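import numpy as np
import pandas as pd
import pytest

from proximap.io_formats import InteractionTable

CONTROLS = {"empty_vector": "CTRL_EMPTY", "gfp": "CTRL_GFP", "caax": "CTRL_CAAX"}


def make_table(rows, controls=CONTROLS):
    """rows: (bait, prey, cell_line, avg_spec, avg_p, replicate_specs)."""
    control_baits = set(controls.values())
    df = pd.DataFrame(
        [
            {
                "bait": b,
                "prey": p,
                "cell_line": line,
                "avg_spec": float(spec),
                "avg_p": float(avgp),
                "replicate_specs": reps,
                "is_control": b in control_baits,
            }
            for b, p, line, spec, avgp, reps in rows
        ]
    )
    return InteractionTable(df=df, controls=dict(controls))


@pytest.fixture
def small_table():
    """Two baits, one cell line, all three controls present."""
    rows = [
        ("ARF1", "GBF1", "HEK293", 8.0, 0.99, (8, 8)),
        ("ARF1", "COMMON", "HEK293", 9.0, 0.97, (9, 9)),
        ("ARF6", "COMMON", "HEK293", 9.0, 0.96, (9, 9)),
        ("ARF6", "SNX1", "HEK293", 17.0, 0.99, (16, 18)),
        ("CTRL_EMPTY", "COMMON", "HEK293", 3.0, 0.0, (3, 3)),
        ("CTRL_GFP", "COMMON", "HEK293", 5.0, 0.0, (5, 5)),
        ("CTRL_CAAX", "SNX1", "HEK293", 10.0, 0.0, (10, 10)),
        ("CTRL_CAAX", "COMMON", "HEK293", 6.0, 0.0, (6, 6)),
    ]
    return make_table(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20240514)
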