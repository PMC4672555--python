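import numpy as np
import pandas as pd
import pytest

from screenkit import dropout, io, synthetic as syn


@pytest.fixture(scope="session")
def small_screen():
    """A small planted screen shared across tests: 300 genes, 8-line panel."""
    cfg = syn.SimScreenConfig(n_genes=300, depth=5e5, seed=11)
    library = syn.gen_library(cfg)
    counts, meta, truth = syn.gen_screen(cfg, library)
    cm = io.CountMatrix(values=counts, sample_meta=meta).validate(library)
    return {"cfg": cfg, "library": library, "cm": cm, "truth": truth}


@pytest.fixture(scope="session")
def small_stats(small_screen):
    stats_df, priors = dropout.depletion_stats(small_screen["cm"])
    return {"stats": stats_df, "priors": priors, **small_screen}


@pytest.fixture(scope="session")
def null_screen():
    """A single-line screen with no planted effects (null calibration)."""
    cfg = syn.SimScreenConfig(
        n_genes=500,
        hairpins_per_gene=3,
        frac_general=0.0,
        frac_subtype=0.0,
        frac_ibc=0.0,
        line_groups={"L1": "nonIBC"},
        subtype_map={},
        depth=1e6,
        seed=5,
    )
    library = syn.gen_library(cfg)
    counts, meta, _ = syn.gen_screen(cfg, library)
    cm = io.CountMatrix(values=counts, sample_meta=meta).validate(library)
    return {"cfg": cfg, "library": library, "cm": cm}


@pytest.fixture(scope="session")
def planted_expression():
    """Expression cohort with the default planted hub regulon (shift 1.5)."""
    cfg = syn.SimExprConfig(seed=7)
    expr, truth = syn.gen_expression(cfg)
    return {"cfg": cfg, "expr": expr, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def truth_regulon(truth):
    """Regulon object built from planted ground truth (modes = planted signs)."""
    from screenkit.regulon import Regulon

    targets = pd.DataFrame(
        {"mode": list(truth.regulon_truth.values()), "confidence": 1.0},
        index=pd.Index(list(truth.regulon_truth), name="target"),
    )
    return Regulon(hub="HUB", targets=targets)
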