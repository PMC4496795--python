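import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from regrewire.coexpression import RECORD_COLUMNS, CorrelatedGRN
from regrewire.grn import GRN, classify_edges, pair_key

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def build_grn(edges, kinds):
    """GRN from [(regulator, target), ...] plus {id: kind}, classified."""
    rows = [(r, kinds[r], t, kinds[t]) for r, t in edges]
    df = pd.DataFrame(
        rows, columns=["regulator_id", "regulator_kind", "target_id", "target_kind"]
    )
    return classify_edges(GRN(node_kinds=dict(kinds), edges=df))


def make_records(rows, condition="tumor", n=60):
    """Scored-record table from [(regulator, target, reg_class, z), ...]."""
    out = []
    for reg, tgt, cls, z in rows:
        pk = pair_key(reg, tgt)
        ek = pk if cls in ("BiTT", "BiTM") else f"{reg}>{tgt}"
        rkind = "miRNA" if reg.startswith("mir") else "TF"
        tkind = "miRNA" if tgt.startswith("mir") else ("TF" if tgt.startswith("TF") else "gene")
        out.append(
            (ek, pk, cls, reg, rkind, tgt, tkind, condition, n,
             float(np.tanh(z / np.sqrt(n - 3))), float(z), False)
        )
    return pd.DataFrame(out, columns=RECORD_COLUMNS)


def make_network(rows, condition="tumor", selection="top_0.1"):
    return CorrelatedGRN(
        condition=condition, selection=selection, records=make_records(rows, condition)
    )


@pytest.fixture
def tiny_kinds():
    return {
        "TF1": "TF", "TF2": "TF", "TF3": "TF",
        "mir1": "miRNA", "mir2": "miRNA",
        "g1": "gene", "g2": "gene", "g3": "gene",
    }


@pytest.fixture(scope="session")
def planted_dataset():
    """One seeded desk-scale simulated study with a planted feedback loop."""
    from regrewire.simulate import default_spec, generate_dataset, plant_dc_loop

    spec = plant_dc_loop(default_spec(seed=7))
    return generate_dataset(spec)
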