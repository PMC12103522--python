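import numpy as np
import pandas as pd
import pytest

from meomics.me_core import MEModel, Reaction
from meomics.synthetic_data import CountMatrix, MinicellParams, make_minicell


@pytest.fixture(scope="session")
def minicell():
    """Default toy ME model and its stripped metabolism-only analog."""
    return make_minicell(MinicellParams())


@pytest.fixture(scope="session")
def minicell_me(minicell):
    return minicell[0]


@pytest.fixture(scope="session")
def minicell_m(minicell):
    return minicell[1]


@pytest.fixture()
def linear_chain_model():
    """Unbranched chain: uptake -> conversion -> biomass; the flux vector at
    any feasible growth rate is unique."""
    return MEModel(
        metabolite_ids=["s", "x", "bm"],
        reactions=[
            Reaction("EX_s", -5.0, 0.0, [("s", -1.0, 0.0)], "exchange"),
            Reaction("STEP1", 0.0, 1000.0, [("s", -1.0, 0.0), ("x", 1.0, 0.0)], "core"),
            Reaction("STEP2", 0.0, 1000.0, [("x", -1.0, 0.0), ("bm", 0.2, 0.0)], "core"),
            Reaction("BIOMASS", 0.0, 1000.0, [("bm", -1.0, 0.0)], "biomass"),
        ],
        growth_reaction_id="BIOMASS",
        mu_max_hint=2.0,
    )


@pytest.fixture()
def m_analog_simple():
    """Metabolism-only toy: yield 0.1 per substrate, uptake bound 5, so the
    optimum growth rate is exactly 0.5."""
    return MEModel(
        metabolite_ids=["s", "bm"],
        reactions=[
            Reaction("EX_s", -5.0, 0.0, [("s", -1.0, 0.0)], "exchange"),
            Reaction("CONV", 0.0, 1000.0, [("s", -1.0, 0.0), ("bm", 0.1, 0.0)], "core"),
            Reaction("BIOMASS", 0.0, 1000.0, [("bm", -1.0, 0.0)], "biomass"),
        ],
        growth_reaction_id="BIOMASS",
        mu_max_hint=2.0,
    )


def make_counts(df: pd.DataFrame) -> CountMatrix:
    """CountMatrix from a DataFrame with <assay>_<rep> columns."""
    return CountMatrix(
        counts=df,
        assay_of={c: c.rsplit("_", 1)[0] for c in df.columns},
        replicate_of={c: int(c.rsplit("_", 1)[1]) for c in df.columns},
    )


@pytest.fixture()
def tiny_counts():
    """Six genes, 2 replicates per assay, hand-set counts."""
    genes = [f"g{i}" for i in range(6)]
    rng = np.random.default_rng(42)
    base = np.array([10, 50, 200, 1000, 5000, 20000])
    data = {}
    for col in ("rna_1", "rna_2", "ribo_1", "ribo_2"):
        data[col] = rng.poisson(base)
    return make_counts(pd.DataFrame(data, index=genes))
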