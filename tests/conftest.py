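import numpy as np
import pandas as pd
import pytest

from transcompr import ExpressionStudy, SimConfig, generate


def make_metadata(sample_ids, age=None, sex=None, labels=None, codes=None):
    n = len(sample_ids)
    meta = pd.DataFrame(
        {
            "age": age if age is not None else np.linspace(60, 80, n),
            "sex": sex if sex is not None else ["M", "F"] * (n // 2) + ["M"] * (n % 2),
            "disease_label": labels
            if labels is not None
            else ["control"] * (n // 2) + ["AD"] * (n - n // 2),
        },
        index=pd.Index(list(sample_ids), name="sample_id"),
    )
    if codes is not None:
        meta["disease_code"] = codes
    return meta


def make_study(values, species="human", **meta_kwargs):
    values = pd.DataFrame(values) if not isinstance(values, pd.DataFrame) else values
    if values.index.dtype != object:
        values.index = [f"g{i}" for i in range(values.shape[0])]
    if values.columns.dtype != object:
        values.columns = [f"s{i}" for i in range(values.shape[1])]
    return ExpressionStudy(
        values=values,
        metadata=make_metadata(values.columns, **meta_kwargs),
        species=species,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_bundle():
    """Reduced-scale planted-signal bundle shared by slower tests."""
    return generate(
        SimConfig(
            n_genes=400,
            n_human_per_class=15,
            n_mouse_per_group=3,
            planted_set_size=20,
            n_decoy_sets=5,
            seed=11,
        )
    )
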