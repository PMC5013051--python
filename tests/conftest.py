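"""Shared fixtures: small synthetic recordings and the session-scoped
reduced benchmark runs used by the acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from semgkit import benchmark, pipeline, synthetic


@pytest.fixture(scope="session")
def small_raw_recording():
    """Small raw 2 kHz recording with ground truth (4 movements, 3 reps)."""
    proto = synthetic.ProtocolSpec(
        n_movement_classes=4,
        n_repetitions=3,
        movement_duration=5.0,
        rest_duration=3.0,
        sampling_rate=2000.0,
        n_channels=6,
        electrode_model="raw_2khz",
    )
    sig = synthetic.make_class_signatures(4, 6, 5.0, seed=11)
    noise = synthetic.NoiseSettings(powerline_amplitude=0.5)
    rec, truth = synthetic.generate_recording(proto, sig, noise, seed=12)
    return proto, sig, rec, truth


@pytest.fixture(scope="session")
def small_rect_recording():
    """Small pre-rectified 100 Hz recording (6 movements, 6 reps)."""
    proto = synthetic.ProtocolSpec(
        n_movement_classes=6,
        n_repetitions=6,
        movement_duration=2.0,
        rest_duration=1.0,
        sampling_rate=100.0,
        n_channels=4,
        electrode_model="rectified_100hz",
    )
    sig = synthetic.make_class_signatures(6, 4, 5.0, seed=21)
    noise = synthetic.NoiseSettings(lag_range=(0.05, 0.2))
    rec, truth = synthetic.generate_recording(proto, sig, noise, seed=22)
    return proto, sig, rec, truth


@pytest.fixture(scope="session")
def random_windows():
    """Seeded random windows for feature-oracle comparisons."""
    from semgkit.types import WindowSet

    rng = np.random.default_rng(2024)
    n, w, c = 120, 256, 3
    return WindowSet(
        samples=rng.standard_normal((n, w, c)),
        labels=rng.integers(0, 5, n),
        repetitions=rng.integers(1, 7, n),
        t_start=np.arange(n, dtype=float),
        sampling_rate=2000.0,
    )


# ---------------------------------------------------------------------------
# reduced 51-class benchmark (shared across acceptance tests)


@pytest.fixture(scope="session")
def bench_cnn_high():
    return pipeline.run_experiment(benchmark.benchmark_config("cnn", separation=5.0, seed=1))


@pytest.fixture(scope="session")
def bench_rf_high():
    return pipeline.run_experiment(benchmark.benchmark_config("baseline", separation=5.0, seed=1))


@pytest.fixture(scope="session")
def bench_cnn_zero():
    return pipeline.run_experiment(benchmark.benchmark_config("cnn", separation=0.0, seed=1))


@pytest.fixture(scope="session")
def bench_rf_zero():
    return pipeline.run_experiment(benchmark.benchmark_config("baseline", separation=0.0, seed=1))
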