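"""End-to-end experiment orchestration.

One seeded configuration drives the whole chain: generate a surrogate
ego-motion training corpus, train the predictive network with periodic
checkpoints, probe every checkpoint with each configured stimulus via a
three-frame closed-loop rollout, measure Lucas-Kanade flow between
consecutive predicted frames (P1/P2 and P2/P3), convert to angular
velocities about each stimulus's rotation centre, aggregate over an
analysis window of checkpoints, and run the group comparisons.  Rerunning
with the same configuration reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .flow import FlowParams, flow_between, render_overlay
from .frames import FrameSequence
from .motion import (
    AngularVelocitySummary,
    NoMotionError,
    NoUsableVectorsError,
    RotationCenter,
    angular_velocity_stats,
    checkpoint_summary,
    compare_groups,
    estimate_center,
)
from .network import NetworkConfig, PredNet, TrainingCheckpoint
from .stimuli import (
    EgoMotionCorpusSpec,
    PropellerSpec,
    SnakeRingSpec,
    make_propeller_video,
    make_snake_sequence,
    make_training_corpus,
)


@dataclasses.dataclass
class ProbeSpec:
    """One named test stimulus: a propeller video or a static ring image."""

    name: str
    kind: str  # "propeller" | "snake"
    spec: Any  # PropellerSpec | SnakeRingSpec
    expected_sign: float = 0.0  # expected omega sign (+cw / -ccw / 0 static)
    overlay_amplification: float = 30.0

    def render(self, n_frames: int) -> FrameSequence:
        if self.kind == "propeller":
            return make_propeller_video(
                dataclasses.replace(self.spec, n_frames=n_frames))
        return make_snake_sequence(self.spec, n_frames=n_frames)

    def rotation_center(self, video: FrameSequence) -> RotationCenter:
        if self.kind == "snake":
            # provisional centre of a ring stimulus is the geometric ring centre
            ring = self.spec.ring_layout()[0]
            return RotationCenter(*ring["center"], source="geometric-ring-center")
        try:
            return estimate_center(video)
        except NoMotionError:
            cx, cy = self.spec.center_xy
            return RotationCenter(cx, cy, source="user-supplied")


def paper_probe_set(size: tuple[int, int] = (160, 120), rpm: float = 15.0,
                    n_blades: int = 3) -> list[ProbeSpec]:
    """The canonical six test stimuli plus the non-illusion control:
    cw/ccw/static propellers, mirrored cw/ccw propellers, the single-ring
    illusion, and its negative control."""
    prop = lambda **kw: PropellerSpec(size=size, n_blades=n_blades, **kw)
    return [
        ProbeSpec("propeller_cw", "propeller", prop(rpm=rpm, direction="cw"), +1),
        ProbeSpec("propeller_ccw", "propeller", prop(rpm=rpm, direction="ccw"), -1),
        ProbeSpec("propeller_static", "propeller", prop(rpm=0.0, direction="cw"), 0),
        ProbeSpec("propeller_cw_mirrored", "propeller",
                  prop(rpm=rpm, direction="cw", mirror=True), -1),
        ProbeSpec("propeller_ccw_mirrored", "propeller",
                  prop(rpm=rpm, direction="ccw", mirror=True), +1),
        ProbeSpec("snake_illusion", "snake",
                  SnakeRingSpec(mode="illusion", size=size), -1,
                  overlay_amplification=60.0),
        ProbeSpec("snake_control", "snake",
                  SnakeRingSpec(mode="control", size=size), 0,
                  overlay_amplification=60.0),
    ]


@dataclasses.dataclass
class ExperimentConfig:
    """Everything one run needs; the seed propagates to every stage."""

    network: NetworkConfig
    corpus: EgoMotionCorpusSpec
    probes: list[ProbeSpec]
    flow: FlowParams = FlowParams()
    total_frames: int = 2000
    checkpoint_every: int = 500
    analysis_window: tuple[int, int] | None = None  # frames_seen range; None -> all
    coord_scale: float = 1.0
    min_radius: float = 5.0
    rollout_k: int = 3
    seed: int = 0
    write_overlays: bool = False
    dump_activation_layers: list[int] | None = None

    def reseeded(self, seed: int) -> "ExperimentConfig":
        return dataclasses.replace(
            self,
            seed=seed,
            network=dataclasses.replace(self.network, seed=seed),
            corpus=dataclasses.replace(self.corpus, seed=seed + 1),
        )

    @classmethod
    def from_yaml(cls, path: str | pathlib.Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        probes = []
        for p in raw.get("probes", []):
            kind = p["kind"]
            spec_fields = dict(p.get("spec", {}))
            for key in ("size", "center", "color_cycle"):
                if key in spec_fields and isinstance(spec_fields[key], list):
                    spec_fields[key] = tuple(
                        tuple(v) if isinstance(v, list) else v for v in spec_fields[key])
            spec = PropellerSpec(**spec_fields) if kind == "propeller" else SnakeRingSpec(**spec_fields)
            probes.append(ProbeSpec(p["name"], kind, spec,
                                    p.get("expected_sign", 0.0),
                                    p.get("overlay_amplification", 30.0)))
        net = dict(raw.get("network", {}))
        for key in ("stack_sizes", "input_shape"):
            if key in net:
                net[key] = tuple(net[key])
        corpus = dict(raw.get("corpus", {}))
        if "size" in corpus:
            corpus["size"] = tuple(corpus["size"])
        kwargs = {
            k: raw[k]
            for k in ("total_frames", "checkpoint_every", "coord_scale",
                      "min_radius", "rollout_k", "seed", "write_overlays")
            if k in raw
        }
        if "analysis_window" in raw and raw["analysis_window"] is not None:
            kwargs["analysis_window"] = tuple(raw["analysis_window"])
        return cls(
            network=NetworkConfig(**net),
            corpus=EgoMotionCorpusSpec(**corpus),
            probes=probes or paper_probe_set(),
            flow=FlowParams(**raw.get("flow", {})),
            **kwargs,
        )


@dataclasses.dataclass
class ExperimentReport:
    """Per-row flow summaries, window aggregates and group comparisons."""

    rows: pd.DataFrame  # probe, frames_seen, pair, n_vectors, mean_omega, se
    aggregates: pd.DataFrame  # probe, pair, window mean/se/n
    comparisons: pd.DataFrame
    losses: np.ndarray
    out_dir: pathlib.Path | None = None

    def plot_omega_vs_training(self, path: str | pathlib.Path,
                               pair: str = "P1/P2") -> None:
        """Mean angular velocity against training frames, one line per
        probe, error bars = per-pair SE."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        sub = self.rows[self.rows["pair"] == pair]
        for probe, grp in sub.groupby("probe"):
            grp = grp.sort_values("frames_seen")
            ax.errorbar(grp["frames_seen"], grp["mean_omega"], yerr=grp["se"],
                        marker="o", capsize=2, label=probe)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xlabel("training frames")
        ax.set_ylabel("mean angular velocity (rad/frame, cw+)")
        ax.set_title(pair)
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)

    def summary(self) -> str:
        lines = ["Experiment report", "=" * 60]
        if len(self.losses):
            lines.append(f"training updates: {len(self.losses)}  "
                         f"(batch MSE {self.losses[0]:.4f} -> {self.losses[-1]:.4f})")
        lines.append("\nWindow aggregates (mean omega, rad/frame, cw+):")
        for _, r in self.aggregates.iterrows():
            lines.append(f"  {r['probe']:<24} {r['pair']}: "
                         f"{r['mean_omega']:+.5f} ± {r['se']:.5f}  (n={int(r['n'])})")
        if len(self.comparisons):
            lines.append("\nGroup comparisons:")
            for _, r in self.comparisons.iterrows():
                lines.append(f"  {r['comparison']:<40} t={r['t']:+.3f} "
                             f"df={r['df']:.3g} p={r['p']:.4g} ({r['test']})")
        return "\n".join(lines)


def _probe_rollout_rows(
    net: PredNet,
    ckpt: TrainingCheckpoint,
    probe: ProbeSpec,
    video: FrameSequence,
    center: RotationCenter,
    cfg: ExperimentConfig,
    out_dir: pathlib.Path | None,
) -> list[dict]:
    rollout = net.rollout_closed_loop(video, k=cfg.rollout_k)
    rows = []
    preds = rollout.predictions
    for i in range(len(preds) - 1):
        pair = f"P{i + 1}/P{i + 2}"
        fvs = flow_between(preds[i], preds[i + 1], cfg.flow, pair=pair)
        try:
            summ = angular_velocity_stats(
                fvs, center, coord_scale=cfg.coord_scale,
                min_radius=cfg.min_radius, frames_seen=ckpt.frames_seen)
            mean, se, n_vec = summ.mean, summ.se, summ.n_vectors
        except NoUsableVectorsError:
            mean, se, n_vec = np.nan, np.nan, 0
        rows.append({
            "probe": probe.name, "frames_seen": ckpt.frames_seen, "pair": pair,
            "n_vectors": n_vec, "mean_omega": mean, "se": se,
            "center_x": center.x, "center_y": center.y, "center_source": center.source,
        })
        if out_dir is not None:
            pair_tag = pair.replace("/", "-")
            fdir = out_dir / "flow" / probe.name
            fdir.mkdir(parents=True, exist_ok=True)
            fvs.to_csv(fdir / f"ckpt{ckpt.frames_seen}_{pair_tag}.csv")
            if cfg.write_overlays:
                render_overlay(preds[i + 1], fvs,
                               fdir / f"ckpt{ckpt.frames_seen}_{pair_tag}.png",
                               amplification=probe.overlay_amplification)
    return rows


def run_experiment(config: ExperimentConfig,
                   out_dir: str | pathlib.Path | None = None) -> ExperimentReport:
    """Execute generate -> train -> rollout -> flow -> statistics."""
    out = pathlib.Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    stage = "generate-corpus"
    try:
        corpus = make_training_corpus(config.corpus)

        stage = "train"
        net = PredNet(config.network)
        result = net.fit(corpus, total_frames=config.total_frames,
                         checkpoint_every=config.checkpoint_every)

        stage = "probe"
        videos = {p.name: p.render(config.network.batch_len) for p in config.probes}
        centers = {p.name: p.rotation_center(videos[p.name]) for p in config.probes}
        rows: list[dict] = []
        for ckpt in result.checkpoints:
            pnet = PredNet.from_checkpoint(ckpt)
            for probe in config.probes:
                rows.extend(_probe_rollout_rows(
                    pnet, ckpt, probe, videos[probe.name], centers[probe.name],
                    config, out))
        rows_df = pd.DataFrame(rows)

        stage = "aggregate"
        window = config.analysis_window or (0, int(result.frames_seen))
        agg_rows = []
        per_group: dict[tuple[str, str], np.ndarray] = {}
        for (probe_name, pair), grp in rows_df.groupby(["probe", "pair"]):
            grp = grp.dropna(subset=["mean_omega"])
            summaries = [
                AngularVelocitySummary(np.array([m]), pair=pair, frames_seen=int(fs))
                for m, fs in zip(grp["mean_omega"], grp["frames_seen"])
            ]
            in_window = [s for s in summaries
                         if window[0] <= s.frames_seen <= window[1]]
            if not in_window:
                continue
            agg = checkpoint_summary(summaries, window)
            per_group[(probe_name, pair)] = np.array([s.mean for s in in_window])
            agg_rows.append({"probe": probe_name, "pair": pair,
                             "mean_omega": agg.mean, "se": agg.se, "n": agg.n})
        agg_df = pd.DataFrame(agg_rows)

        stage = "compare"
        comp_rows = []

        def add_comparison(name, key_a, key_b, absolute, alternative):
            a = per_group.get(key_a)
            b = per_group.get(key_b)
            if a is None or b is None or len(a) < 2 or len(b) < 2:
                return
            try:
                gc = compare_groups(a, b, test="auto", absolute=absolute,
                                    alternative=alternative)
            except ValueError:
                return
            comp_rows.append({"comparison": name, "t": gc.t, "df": gc.df,
                              "p": gc.p, "test": gc.test,
                              "alternative": gc.alternative,
                              "absolute": absolute})

        names = {p.name for p in config.probes}
        for pair in sorted({k[1] for k in per_group}):
            if {"propeller_cw", "propeller_ccw"} <= names:
                add_comparison(f"|cw| vs |ccw| ({pair})",
                               ("propeller_cw", pair), ("propeller_ccw", pair),
                               True, "greater")
            if {"propeller_cw", "propeller_static"} <= names:
                add_comparison(f"|cw| vs |static| ({pair})",
                               ("propeller_cw", pair), ("propeller_static", pair),
                               True, "greater")
            if {"propeller_ccw", "propeller_static"} <= names:
                add_comparison(f"|ccw| vs |static| ({pair})",
                               ("propeller_ccw", pair), ("propeller_static", pair),
                               True, "greater")
            if {"snake_illusion", "snake_control"} <= names:
                add_comparison(f"|illusion| vs |control| ({pair})",
                               ("snake_illusion", pair), ("snake_control", pair),
                               True, "greater")
        comp_df = pd.DataFrame(comp_rows)

        stage = "write-report"
        if out is not None:
            rows_df.to_csv(out / "flow_summaries.csv", index=False)
            agg_df.to_csv(out / "window_aggregates.csv", index=False)
            comp_df.to_csv(out / "comparisons.csv", index=False)
            np.savetxt(out / "batch_losses.csv", result.batch_losses,
                       header="batch_mse", comments="")
            for p in config.probes:
                videos[p.name].save(out / "stimuli" / p.name)
            if config.dump_activation_layers is not None and result.checkpoints:
                last = PredNet.from_checkpoint(result.checkpoints[-1])
                for p in config.probes:
                    last.dump_activations(videos[p.name],
                                          out / "activations" / p.name,
                                          layers=config.dump_activation_layers)
            log = {
                "seed": config.seed,
                "network": config.network.to_dict(),
                "corpus": dataclasses.asdict(config.corpus),
                "total_frames": config.total_frames,
                "checkpoint_every": config.checkpoint_every,
                "analysis_window": list(window),
                "n_checkpoints": len(result.checkpoints),
                "final_batch_mse": float(result.batch_losses[-1]),
            }
            (out / "run_log.json").write_text(json.dumps(log, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    return ExperimentReport(rows_df, agg_df, comp_df, result.batch_losses, out)
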