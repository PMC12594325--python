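import pytest
from hypothesis import HealthCheck, settings

import kidneyct as kc

settings.register_profile(
    "kidneyct",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("kidneyct")


@pytest.fixture(scope="session")
def smoke_dataset():
    """300 binary phantoms at 64x64 with the default (stated) generator params."""
    return kc.generate_dataset(300, seed=11, task_mode="binary")


#: desk-scale smoke training recipe (see docs/methods.md for the rationale:
#: sharp high-density window start, small batches for step count, 1-epoch
#: warmup, final-model selection because the 46-image validation split is too
#: noisy for per-epoch checkpoint picking)
SMOKE_WINDOW_INIT = dict(alpha=6.0, wl2=0.8, ww2=0.15)
SMOKE_TRAIN = dict(epochs=5, batch_size=2, lr=3e-4, warmup_epochs=1,
                   selection="final", seed=7)


@pytest.fixture(scope="session")
def smoke_run(smoke_dataset):
    """Tiny-preset model trained 5 epochs on the smoke dataset (fixed seed).

    Shared session-wide: this is the desk-scale stand-in for a full training
    run, reused by the accuracy, robustness and checkpoint tests.
    """
    cfg = kc.ModelConfig.tiny_test(num_classes=2,
                                   window_init=dict(SMOKE_WINDOW_INIT))
    model = kc.build_classifier(cfg, seed=7)
    init_windows = model.windows.values()
    history, ckpt = kc.train(model, smoke_dataset,
                             kc.TrainConfig(**SMOKE_TRAIN))
    return dict(model=model, history=history, checkpoint=ckpt,
                dataset=smoke_dataset, init_windows=init_windows)
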