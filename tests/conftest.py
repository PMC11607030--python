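import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")

from laparosound.synth import default_channel_profiles, synth_adapter_ir  # noqa: E402


@pytest.fixture(scope="session")
def profiles():
    return default_channel_profiles()


@pytest.fixture(scope="session")
def reference_ir(profiles):
    return synth_adapter_ir(profiles["reference"])


@pytest.fixture(scope="session")
def dual_channel_ir(profiles):
    return synth_adapter_ir(profiles["dual_channel"])


@pytest.fixture(scope="session")
def tube_ir(profiles):
    return synth_adapter_ir(profiles["tube"])


def make_toy_patches(n_per_class: int = 30, n_classes: int = 5, seed: int = 0,
                     noise: float = 0.3, id_prefix: str = "toy"):
    """Linearly separable 96x64 toy patches: each class lights one band group."""
    from laparosound.data import PatchData

    rng = np.random.default_rng(seed)
    xs, ys, sids = [], [], []
    for c in range(n_classes):
        base = np.zeros((96, 64))
        base[:, c * 12: c * 12 + 8] = 1.0
        for i in range(n_per_class):
            xs.append(base + noise * rng.standard_normal((96, 64)))
            ys.append(c)
            sids.append(f"{id_prefix}-{c}-{i}")
    return PatchData(x=np.stack(xs).astype(np.float32), y=np.array(ys),
                     source_ids=np.array(sids, dtype=object),
                     classes=tuple(f"c{i}" for i in range(n_classes)))


@pytest.fixture(scope="session")
def channel_shift_result():
    """The full channel-shift experiment at the declared study conditions."""
    from laparosound.pipeline import run_channel_shift_experiment

    return run_channel_shift_experiment(seed=42, n_per_class=40)
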