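import numpy as np
import pytest

from thermorr import FaceBox, SceneConfig, SignalTrace, ThermalSequence, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sequence(rng):
    """A 20-frame 32x32 random uint16 stack at 8.6 fps."""
    frames = rng.integers(0, 65536, size=(20, 32, 32), dtype=np.uint16)
    return ThermalSequence(frames=frames, fps=8.6)


@pytest.fixture
def face_box():
    return FaceBox(x=10, y=5, w=40, h=60, frame_index="all")


@pytest.fixture
def clean_scene():
    """Noise-free, drift-free breathing scene at 20 bpm (cells 9 and 10)."""
    cfg = SceneConfig(rr_true_bpm=20.0, noise_sigma=0.0, drift_slope=0.0,
                      distortion=0.0, seed=7)
    return generate_scene(cfg)


@pytest.fixture
def default_scene():
    """Default-condition scene (drift, noise, 2nd harmonic) at 20 bpm."""
    cfg = SceneConfig(rr_true_bpm=20.0, seed=11)
    return generate_scene(cfg)


def sine_trace(freq_hz, fps=8.6, duration=15.0, amplitude=1.0, roi_index=0, phase=0.0):
    t = np.arange(int(round(duration * fps))) / fps
    return SignalTrace(values=amplitude * np.sin(2 * np.pi * freq_hz * t + phase),
                       fps=fps, roi_index=roi_index)
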