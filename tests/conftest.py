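import numpy as np
import pytest

import sdetnet as sd


@pytest.fixture(scope="session")
def tiny_spec():
    return sd.PhantomSpec.tiny()


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free, confounder-free phantom family for exact-geometry checks."""
    return sd.PhantomSpec.tiny(confounder_count=0, noise_sd=0.0, blur_sigma=0.0)


@pytest.fixture(scope="session")
def recovery_runs(tmp_path_factory):
    """Three seeded end-to-end studies at dimorphism 1.6.

    Each run trains the segmentation stage once and the classifier twice
    (full preset and image-only), sharing the stage-1 output, so both the
    parameter-recovery and the ablation-direction properties read from the
    same computation.
    """
    results = {}
    for seed in (1, 2, 3):
        out = tmp_path_factory.mktemp(f"recovery_seed{seed}")
        cfg = sd.PipelineConfig.tiny(seed=seed, out_dir=str(out))
        results[seed] = sd.run_ablation(
            cfg, presets=("image_mask_agam", "image_only"))
    return results


@pytest.fixture(scope="session")
def null_run(tmp_path_factory):
    """One end-to-end study with the dimorphism switched off."""
    out = tmp_path_factory.mktemp("null_run")
    cfg = sd.PipelineConfig.tiny(seed=1, out_dir=str(out),
                                 dimorphism_factor=1.0)
    return sd.run_pipeline(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
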