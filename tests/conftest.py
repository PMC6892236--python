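import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from fragswap.align_ss import align_parents
from fragswap.demarcation import DemarcationParams, partition_fragments
from fragswap.fixtures import make_parent_pair, ten_fragment_layout
from fragswap.formats_io import AssayTable


def make_aligned(seed=1, length=None, layout=None, divergence=30.0, indels=0):
    """Aligned parent pair from the synthetic generator."""
    layout = layout if layout is not None else "C" * (length or 40)
    length = len(layout)
    a, b, ss_a, ss_b, _ = make_parent_pair(seed, length, layout, divergence, indels)
    return align_parents(a, b, ss_a, ss_b)


def kinetics_table(s, v):
    return AssayTable(
        kind="kinetics",
        data=pd.DataFrame({"substrate_mg_per_mL": np.asarray(s, float), "rate": np.asarray(v, float)}),
    )


def synergy_table(t, cel, xyl, both, ctrl=None):
    data = {
        "time_h": np.asarray(t, float),
        "cellulase_only": np.asarray(cel, float),
        "xylanase_only": np.asarray(xyl, float),
        "both": np.asarray(both, float),
    }
    if ctrl is not None:
        data["control"] = np.asarray(ctrl, float)
    return AssayTable(kind="synergy", data=pd.DataFrame(data))


@pytest.fixture(scope="session")
def ten_frag_ap():
    """The pair designed so that a ten-fragment demarcation is feasible."""
    layout = ten_fragment_layout()
    a, b, ss_a, ss_b, _ = make_parent_pair(1, len(layout), layout, divergence_pct=47.0)
    return align_parents(a, b, ss_a, ss_b)


@pytest.fixture(scope="session")
def ten_frag_scheme(ten_frag_ap):
    return partition_fragments(
        ten_frag_ap, DemarcationParams(objective=("target_count", 10))
    )
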