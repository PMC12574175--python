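import numpy as np
import pandas as pd
import pytest

from cernet.expression import ExpressionMatrix, SampleDesign
from cernet.pipeline import PipelineConfig, run_pipeline
from cernet.simulate import default_paper_scenario, generate_scenario


def make_matrix(values, features=None, samples=None, **kw) -> ExpressionMatrix:
    arr = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    vals = pd.DataFrame(arr, index=features, columns=samples)
    mask = pd.DataFrame(False, index=features, columns=samples)
    return ExpressionMatrix(vals, mask, **kw)


def make_design(n_ref: int, n_alt: int, ref="ref", alt="alt", samples=None) -> SampleDesign:
    samples = samples or [f"s{j}" for j in range(n_ref + n_alt)]
    labels = {s: (ref if j < n_ref else alt) for j, s in enumerate(samples)}
    return SampleDesign(labels, (ref, alt))


@pytest.fixture(scope="session")
def paper_scenario_zero():
    """The reference scenario at sigma=0: ground truth holds exactly."""
    return generate_scenario(default_paper_scenario(seed=11, noise_sd=0.0))


@pytest.fixture(scope="session")
def paper_bundle_zero(tmp_path_factory, paper_scenario_zero):
    """Full pipeline run over the sigma=0 reference scenario."""
    outdir = tmp_path_factory.mktemp("bundle_zero")
    cfg = PipelineConfig(outdir=str(outdir), scenario=paper_scenario_zero.config, seed=11)
    return run_pipeline(cfg)
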