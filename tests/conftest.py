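"""Shared fixtures: synthetic clicks, scenes and feature tables.

Everything is generated programmatically with fixed seeds; the heavier
rendered scenes are session-scoped so detection, train-selection and
recovery tests share one synthesis pass.
"""

from __future__ import annotations

import numpy as np
import pytest

import clickpam as cp

FS = 576_000.0


@pytest.fixture(scope="session")
def fs() -> float:
    return FS


def embed_click(model: cp.ClickModel, n: int = 4096, at: int | None = None, fs: float = FS):
    """A quiet recording containing one Gabor click; returns (rec, peak_index)."""
    w = cp.make_click(model, fs)
    x = np.zeros(n)
    at = n // 2 if at is None else at
    half = w.size // 2
    x[at - half : at + half + 1] = w
    return cp.AudioRecording(x, fs, source_id="embedded"), at


@pytest.fixture(scope="session")
def gabor_97_5():
    """Recording with a single 97 kHz / 5 us Gabor click at a known sample."""
    return embed_click(cp.ClickModel(center_khz=97.0, sigma_us=5.0, amplitude_upa=1e6))


@pytest.fixture(scope="session")
def scene_30db():
    """10 trains x 10 clicks at 30 dB spectral SNR, band-passed, with truth."""
    spec = cp.detection_scene(n_trains=10, clicks_per_train=10, snr_db=30.0, seed=3)
    rec, truth = cp.render_scene(spec)
    return cp.bandpass(rec), truth


@pytest.fixture(scope="session")
def noise_10s():
    """10 s of click-free ambient noise, band-passed."""
    rec, _ = cp.render_scene(cp.SceneSpec(duration_s=10.0, seed=5))
    return cp.bandpass(rec)


@pytest.fixture(scope="session")
def feature_table():
    """Synthetic two-species feature table at the study sample sizes."""
    return cp.make_feature_table(seed=0)


def match_detections(detected_times: np.ndarray, truth_times: np.ndarray, tol_s: float = 5e-4):
    """(recall, n_false): detections within tol of a truth click count as hits."""
    if detected_times.size == 0:
        return 0.0, 0
    hits = sum(np.min(np.abs(detected_times - t)) < tol_s for t in truth_times)
    false = int(sum(np.min(np.abs(truth_times - t)) > tol_s for t in detected_times))
    return hits / truth_times.size, false
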