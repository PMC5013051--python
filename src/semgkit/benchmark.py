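"""Desk-scale synthetic benchmark definitions.

The reference benchmark emulates a 12-electrode raw 2 kHz acquisition of
50 movements + rest over 6 repetitions (5 s movement / 3 s rest), with
power-line interference and uniform(0.1, 0.5) s reaction lags.  Window
strides are chosen to yield roughly 40 windows per movement class, which
keeps a full end-to-end run (simulate -> condition -> window -> train ->
score) to desk scale; the convolutional arm trains for 5 epochs at the
reference optimization settings.

``separation`` controls class discriminability: 5.0 is the
well-separated condition; 0 removes class information entirely, so any
classifier must fall to chance.
"""

from __future__ import annotations

HIGH_SEPARATION = 5.0

__all__ = ["benchmark_config", "smoke_config", "HIGH_SEPARATION"]


def benchmark_config(
    arm: str,
    separation: float = HIGH_SEPARATION,
    seed: int = 0,
    epochs: int = 5,
    output_dir: str | None = None,
) -> dict:
    """Experiment config dict for the reduced 51-class benchmark."""
    cfg: dict = {
        "seed": int(seed),
        "output_dir": output_dir,
        "synthetic": {
            "n_movement_classes": 50,
            "n_repetitions": 6,
            "movement_duration": 5.0,
            "rest_duration": 3.0,
            "sampling_rate": 2000.0,
            "n_channels": 12,
            "electrode_model": "raw_2khz",
            "separation": float(separation),
            "powerline_amplitude": 0.5,
            "lag_range": [0.1, 0.5],
        },
        "windows": {"cnn_ms": 150.0, "classical_ms": 200.0, "stride_ms": 700.0},
    }
    if arm == "cnn":
        cfg["cnn"] = {"training": {"epochs": int(epochs)}}
    elif arm == "baseline":
        cfg["baseline"] = {"kind": "random_forest", "features": "combined"}
    else:
        raise ValueError(f"unknown arm {arm!r}")
    return cfg


def smoke_config(arm: str = "cnn", seed: int = 0, output_dir: str | None = None) -> dict:
    """Tiny configuration (5 movements, 2 channels) for quick end-to-end runs."""
    cfg: dict = {
        "seed": int(seed),
        "output_dir": output_dir,
        "synthetic": {
            "n_movement_classes": 5,
            "n_repetitions": 6,
            "movement_duration": 2.0,
            "rest_duration": 1.0,
            "sampling_rate": 2000.0,
            "n_channels": 2,
            "electrode_model": "raw_2khz",
            "separation": HIGH_SEPARATION,
            "powerline_amplitude": 0.0,
            "lag_range": [0.1, 0.3],
        },
        "windows": {"cnn_ms": 150.0, "classical_ms": 200.0, "stride_ms": 50.0},
        "preprocess": {"relabel_margin": 0.4},
    }
    if arm == "cnn":
        # batch size scaled to the small window count so 2 epochs still
        # take a useful number of gradient steps
        cfg["cnn"] = {"training": {"epochs": 2, "batch_size": 64}}
    else:
        cfg["baseline"] = {"kind": "random_forest", "features": "rms"}
    return cfg
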