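"""Preset scaled-down experiments runnable on one CPU.

The headline study trains the full four-layer network on hundreds of
thousands of frames; that scale is out of reach without a GPU, so this
module packages a reduced version of the same protocol — a two-layer
network (stacks 3/16) on 48x48 frames, trained on a ~20K-frame synthetic
ego-motion/rotation corpus — whose purpose is direction recovery: do the
signs of the mean P1/P2 angular velocities for clockwise and
counter-clockwise 15-rpm propeller probes match the probe directions, and
does the static (0 rpm) probe yield a smaller magnitude than both?
"""

from __future__ import annotations

import numpy as np

from .flow import FlowParams
from .network import NetworkConfig
from .pipeline import ExperimentConfig, ProbeSpec, run_experiment
from .stimuli import EgoMotionCorpusSpec, PropellerSpec


def toy_direction_config(
    seed: int = 0,
    total_frames: int = 20000,
    size: int = 48,
    checkpoint_every: int = 2000,
) -> ExperimentConfig:
    """Reduced two-layer configuration for CPU-scale direction recovery."""
    net = NetworkConfig(
        n_layers=2,
        stack_sizes=(3, 16),
        input_shape=(size, size, 3),
        seed=seed,
    )
    corpus = EgoMotionCorpusSpec(
        seed=seed + 1,
        n_frames=4000,
        size=(size, size),
        clip_len=60,
        translation_range=(0.5, 2.5),
        rotation_range=(0.02, 0.12),
        rotation_fraction=0.35,
        disc_fraction=0.25,
    )
    prop = lambda **kw: PropellerSpec(size=(size, size), n_blades=3, **kw)
    probes = [
        ProbeSpec("propeller_cw", "propeller", prop(rpm=15.0, direction="cw"), +1),
        ProbeSpec("propeller_ccw", "propeller", prop(rpm=15.0, direction="ccw"), -1),
        ProbeSpec("propeller_static", "propeller", prop(rpm=0.0, direction="cw"), 0),
    ]
    n_ckpts = total_frames // checkpoint_every
    window_lo = checkpoint_every * (n_ckpts // 2 + 1)
    return ExperimentConfig(
        network=net,
        corpus=corpus,
        probes=probes,
        # toy-scale predictions are blurrier than full-scale ones, so the
        # corner threshold is relaxed and the window shrunk with the frame
        flow=FlowParams(window_size=21, quality_level=0.15,
                        max_features=50, min_distance=4),
        total_frames=total_frames,
        checkpoint_every=checkpoint_every,
        analysis_window=(window_lo, total_frames),
        seed=seed,
    )


def run_toy_direction_experiment(
    seed: int = 0,
    total_frames: int = 20000,
    out_dir=None,
) -> dict:
    """Train the reduced network and report P1/P2 direction recovery.

    Returns window-averaged mean angular velocities (rad/frame, cw
    positive) for the cw, ccw and static probes, plus the sign checks.
    """
    config = toy_direction_config(seed=seed, total_frames=total_frames)
    report = run_experiment(config, out_dir=out_dir)
    agg = report.aggregates
    p12 = agg[agg["pair"] == "P1/P2"].set_index("probe")["mean_omega"]
    cw = float(p12["propeller_cw"])
    ccw = float(p12["propeller_ccw"])
    static = float(p12["propeller_static"])
    return {
        "mean_omega_cw": cw,
        "mean_omega_ccw": ccw,
        "mean_omega_static": static,
        "cw_sign_correct": cw > 0,
        "ccw_sign_correct": ccw < 0,
        "static_below_both": abs(static) < abs(cw) and abs(static) < abs(ccw),
        "n_checkpoints_in_window": int(
            agg[agg["pair"] == "P1/P2"]["n"].iloc[0]) if len(agg) else 0,
        "final_batch_mse": float(report.losses[-1]),
        "report": report,
    }
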