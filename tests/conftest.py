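import numpy as np
import pandas as pd
import pytest

from canopyqtl import PlotLayout, SimConfig, gen_founder_mosaic


@pytest.fixture(scope="session")
def layout():
    return PlotLayout()


@pytest.fixture(scope="session")
def small_haplo():
    """A small founder-mosaic population reused across GWAS tests."""
    cfg = SimConfig(n_lines=60, n_chroms=2, n_snps_per_chrom=40, breakpoint_rate=6.0, seed=11)
    return gen_founder_mosaic(cfg)


@pytest.fixture(scope="session")
def small_pheno(small_haplo):
    rng = np.random.default_rng(5)
    return pd.DataFrame(
        {
            "line_id": small_haplo.line_ids,
            "trait": "VF",
            "environment": 1,
            "value": rng.normal(30.0, 3.0, small_haplo.n_lines),
        }
    )
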