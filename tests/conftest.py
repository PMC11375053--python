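import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", max_examples=25, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        yield


@pytest.fixture(scope="session")
def default_sim():
    """One default simulated spatial sample pushed through the full
    compartment pipeline; shared across tests that only read it."""
    import tlsniche as t

    cfg = t.simulate.default_spatial_config(seed=11)
    adata, truth = t.simulate.generate_spatial_sample(cfg)
    ln = t.scoring.log_normalize(adata)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = pd.DataFrame({
            r: t.scoring.module_score(ln, truth.signatures[r], seed=0)
            for r in ("malignant", "B", "T", "EBV", "plasma", "apoptosis")})
    regions = t.compartments.call_regions(scores[["malignant", "B", "T"]])
    grid = t.compartments.SpotGrid.from_anndata(adata)
    components = t.compartments.find_tca_components(regions, grid)
    spot_ebv, ebv_cls = t.compartments.stratify_ebv(components, scores["EBV"])
    plasma_cls = t.compartments.classify_plasma_cooccurrence(
        components, scores["plasma"], grid)
    return {
        "config": cfg, "adata": adata, "truth": truth, "lognorm": ln,
        "scores": scores, "regions": regions, "grid": grid,
        "components": components, "spot_ebv": spot_ebv,
        "ebv_class": ebv_cls, "plasma_class": plasma_cls,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
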