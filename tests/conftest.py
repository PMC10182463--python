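import dataclasses

import numpy as np
import pytest

from semscale.pipeline import RunConfig, run_pipeline
from semscale.synthetic import ConditionParams, StudyConfig


def make_orthonormal_space(words, seed=0):
    """Semantic space whose word embeddings are random orthonormal rows."""
    from semscale.space import SemanticSpace

    d = len(words)
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(d, d)))
    return SemanticSpace(
        vocab=list(words), embeddings=q, singular_values=np.linspace(2.0, 1.0, d)
    )


@pytest.fixture
def ortho_space():
    return make_orthonormal_space([f"w{i}" for i in range(8)], seed=42)


def small_study_config(seed=0, **overrides):
    """Reduced-scale study for fast pipeline tests (not the default regime)."""
    base = dict(n_events_per_condition=24, n_p2_raters=8, ngrams_per_bin=150, seed=seed)
    base.update(overrides)
    return StudyConfig(**base)


def small_run_config(tmp_dir, seed=0, **study_overrides):
    from semscale.space import SpaceConfig

    return RunConfig(
        output_dir=tmp_dir,
        seed=seed,
        study_config=small_study_config(seed=seed, **study_overrides),
        space=SpaceConfig(n_dims=96),
    )


@pytest.fixture(scope="session")
def default_scale_runs(tmp_path_factory):
    """20 full pipeline runs at the default (study-scale) generator settings."""
    base = tmp_path_factory.mktemp("default_runs")
    results = []
    for seed in range(20):
        cfg = RunConfig(output_dir=base / f"run{seed}", seed=seed)
        results.append(run_pipeline(cfg))
    return results


@pytest.fixture(scope="session")
def rater_noise_dominant_runs(tmp_path_factory):
    """20 runs in the regime where rating noise is >= 2x the keyword noise.

    Response noise is 2.0 in both conditions against keyword-channel noise
    0.75, the regime in which the model (which reads only the keywords)
    should out-rank the human raters.
    """
    base = tmp_path_factory.mktemp("noise_runs")
    results = []
    for seed in range(20):
        conditions = {
            "psychological": ConditionParams(mu=6.46, sigma=1.69, delta=-0.61, rating_noise_sd=2.0),
            "physical": ConditionParams(mu=6.59, sigma=1.81, delta=0.95, rating_noise_sd=2.0),
        }
        study = StudyConfig(conditions=conditions, keyword_noise_sd=0.75, seed=seed)
        cfg = RunConfig(output_dir=base / f"run{seed}", seed=seed, study_config=study)
        results.append(run_pipeline(cfg))
    return results
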