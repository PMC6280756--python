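import pandas as pd
import pytest
from hypothesis import settings

from drre_kit.pipeline import run_all
from drre_kit.simulate import SimConfig, simulate_study

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study shared across tests (read-only)."""
    return simulate_study(SimConfig(seed=11))


@pytest.fixture(scope="session")
def pipeline_out(bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("pipe")
    manifest = run_all(bundle, out, seed=11)
    return out, manifest


def make_expression(rows, reps=2):
    """Build an ExpressionMatrix from {gene: {(condition, timepoint): mean}}.

    Replicates are exact copies of the mean, so fold changes are exact.
    """
    from drre_kit.expression import CONDITIONS, TIMEPOINTS, ExpressionMatrix
    cols = {}
    for cond in CONDITIONS:
        for tp in TIMEPOINTS:
            for r in range(1, reps + 1):
                cols[f"{cond}_{tp}_{r}"] = [
                    rows[g].get((cond, tp), 1.0) for g in rows
                ]
    df = pd.DataFrame(cols, index=pd.Index(list(rows), name="gene_id"))
    return ExpressionMatrix(df)
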