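import numpy as np
import pytest

from stunflow.synthetic import ScenarioConfig, simulate_gondola


@pytest.fixture(scope="session")
def small_scene():
    """One rendered 3-pig gondola on a small arena (session-cached)."""
    cfg = ScenarioConfig(group_size=3, arena_width=96, arena_height=96, seed=11)
    return cfg, simulate_gondola(cfg, render=True)


@pytest.fixture()
def textured_blob():
    """A textured square blob on a dark background plus a shift helper."""
    rng = np.random.default_rng(42)
    img = np.zeros((64, 64), dtype=np.uint8)
    img[20:40, 20:40] = rng.integers(100, 256, (20, 20), dtype=np.uint8)

    def shifted(dx: int, dy: int) -> np.ndarray:
        out = np.zeros_like(img)
        out[20 + dy : 40 + dy, 20 + dx : 40 + dx] = img[20:40, 20:40]
        return out

    return img, shifted
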