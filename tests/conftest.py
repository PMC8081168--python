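import numpy as np
import pytest
from hypothesis import settings

from clipcontext import pipeline, synthetic
from clipcontext.config import GeneratorConfig

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A scaled-down study: same stated world, fewer participants."""
    return GeneratorConfig(n_participants=40, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    """Situations + per-clip algorithmic ratings + raw annotator panels."""
    situations = synthetic.generate_situations(small_config)
    algo_df, panels = pipeline.extract_algo_ratings(situations, small_config)
    return situations, algo_df, panels


@pytest.fixture(scope="session")
def source_table(small_study, small_config):
    from clipcontext import descriptives

    situations, algo_df, panels = small_study
    sit_df = synthetic.situations_to_frame(situations)
    fused = pipeline.fuse_annotations(panels)
    return descriptives.assemble_source_table(sit_df, fused, algo_df)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
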