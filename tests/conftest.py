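import os

# pin BLAS threading before numpy initializes: keeps training trajectories
# reproducible across machines with different core counts
for _v in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_v, "1")

import numpy as np
import pytest

from mriclip.phantoms import generate_cohort, generate_study
from mriclip.tokenizer import TokenizerConfig, patch_volume, train_vqvae


@pytest.fixture(scope="session")
def desk_tok_config():
    return TokenizerConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """30 phantom studies with all four lesion classes represented."""
    return generate_cohort(30, [0.35] * 4, seed=11)


@pytest.fixture(scope="session")
def desk_codec(small_cohort, desk_tok_config):
    rng = np.random.default_rng(5)
    pool = [p for (s, _, _) in small_cohort[:8] for v in s.sequences
            for p in patch_volume(v, desk_tok_config)]
    take = rng.choice(len(pool), 300, replace=False)
    codec, trace = train_vqvae([pool[i] for i in take], desk_tok_config,
                               epochs=6, seed=5)
    return codec


@pytest.fixture(scope="session")
def tumor_study():
    return generate_study(7, ["tumor"])


@pytest.fixture(scope="session")
def trained_pipeline():
    """One desk-scale end-to-end training run shared by the tests that need
    a converged model (retrieval, transfer heads, LIME localization)."""
    from mriclip.pipeline import DeskSettings, run_desk_pipeline
    return run_desk_pipeline(seed=0, settings=DeskSettings())
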