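import pytest
from hypothesis import settings

from heteroseq import (
    AllelicImbalanceModel,
    SimulationParams,
    TrioExpressionModel,
    generate_dataset,
)
from heteroseq.iomod import truth_to_frame

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic dataset shared across the suite."""
    params = SimulationParams(n_genes=2000, seed=7)
    counts, alleles, truth, design = generate_dataset(params)
    return {
        "params": params,
        "counts": counts,
        "alleles": alleles,
        "truth": truth,
        "truth_df": truth_to_frame(truth),
        "design": design,
    }


@pytest.fixture(scope="session")
def trio_fit(default_sim):
    return TrioExpressionModel(default_sim["counts"], default_sim["design"]).fit()


@pytest.fixture(scope="session")
def ase_fit(default_sim, trio_fit):
    model = AllelicImbalanceModel(
        default_sim["alleles"], default_sim["counts"], default_sim["design"], "F1a"
    )
    return model.fit(expression=trio_fit)
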