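import numpy as np
import pandas as pd
import pytest

from coexmod import SimulationConfig, simulate_modular_expression


@pytest.fixture(scope="session")
def planted():
    """Default planted-module dataset: 5 modules x 50 genes, 250 background,
    40 samples in two classes, loading 0.9, noise sd 0.5."""
    cfg = SimulationConfig(seed=42, class_shifts={(0, "disease"): 1.0})
    expr, truth, ann = simulate_modular_expression(cfg)
    return expr, truth, ann


@pytest.fixture()
def small_expr():
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        rng.standard_normal((30, 10)),
        index=[f"G{i}" for i in range(30)],
        columns=[f"S{j}" for j in range(10)],
    )


@pytest.fixture()
def expression_tsv(tmp_path):
    path = tmp_path / "expr.tsv"
    path.write_text(
        "gene\tS1\tS2\tS3\tS4\n"
        "G1\t1.0\t2.0\t3.0\t4.0\n"
        "G2\t0.5\t0.5\t1.5\t1.5\n"
        "G3\t-1.0\t0.0\t1.0\t2.0\n"
    )
    return path
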