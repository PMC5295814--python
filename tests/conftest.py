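import pandas as pd
import pytest

from spinasym import (
    SyntheticConfig,
    ThresholdConfig,
    generate_week8_like,
    run_pipeline,
)


@pytest.fixture(scope="session")
def cfg():
    return ThresholdConfig()


@pytest.fixture(scope="session")
def small_bundle():
    """Small paired bundle for unit-level and I/O round-trip tests."""
    return generate_week8_like(
        SyntheticConfig(n_genes=120, n_mirnas=40, cpgs_per_gene=3,
                        frac_asym_expr=0.1, frac_meth_coupled=0.3,
                        frac_mirna_coupled=0.1, both_overlap=0.05,
                        right_bias=0.7, seed=7)
    )


@pytest.fixture(scope="session")
def default_bundle():
    """Study-condition bundle at the scaled working size (2000 genes)."""
    return generate_week8_like(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def default_report(default_bundle):
    b = default_bundle
    return run_pipeline(b.expression, b.mirna, b.targets, b.cpg, b.genes)


def swap_sides(df: pd.DataFrame) -> pd.DataFrame:
    """Relabel left<->right in any table with a side column."""
    out = df.copy()
    out["side"] = out["side"].map({"left": "right", "right": "left"})
    return out


@pytest.fixture(scope="session")
def swapped_report(default_bundle):
    b = default_bundle
    return run_pipeline(
        swap_sides(b.expression), swap_sides(b.mirna), b.targets,
        swap_sides(b.cpg), b.genes,
    )
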