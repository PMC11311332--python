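"""End-to-end pipeline: simulate -> extract -> call -> normalize -> concentration."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as pio
from .concentration import calibrate
from .normalize import build_profile
from .phases import CallerConfig, call_phases
from .scene import SceneSpec, generate_scene
from .traces import extract_traces

logger = logging.getLogger("pcnatrace")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; schema-validated before computing."""

    scene: SceneSpec = field(default_factory=SceneSpec)
    # real-data inputs; when stack_path is set the simulate stage is skipped
    stack_path: str | None = None
    masks_path: str | None = None
    mitosis_path: str | None = None
    caller: CallerConfig = field(default_factory=CallerConfig)
    grid_size: int = 64
    mean_cycle_duration_h: float | None = None  # None -> cohort mean
    ms_concentration: float | None = None
    ms_units: str = "nM"
    seed: int = 0
    write_images: bool = True
    log_level: str = "INFO"

    def __post_init__(self):
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if self.mean_cycle_duration_h is not None and self.mean_cycle_duration_h <= 0:
            raise ValueError("mean_cycle_duration_h must be > 0")
        if self.ms_concentration is not None and self.ms_concentration <= 0:
            raise ValueError("ms_concentration must be > 0")
        if self.log_level not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ValueError(f"unknown log level {self.log_level!r}")
        if self.stack_path is not None:
            for fieldname in ("masks_path", "mitosis_path"):
                if getattr(self, fieldname) is None:
                    raise ValueError(f"{fieldname} is required for real-data input")
            for fieldname in ("stack_path", "masks_path", "mitosis_path"):
                if not Path(getattr(self, fieldname)).exists():
                    raise ValueError(f"{fieldname}: no such file "
                                     f"{getattr(self, fieldname)!r}")
        # the seed flows into the scene so one number controls everything
        self.scene = dataclasses.replace(self.scene, seed=int(self.seed))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scene"] = pio.spec_to_dict(self.scene)
        d["caller"] = dataclasses.asdict(self.caller)
        return pio._listify(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "scene" in d:
            d["scene"] = pio.spec_from_dict(d["scene"])
        if "caller" in d:
            c = dict(d["caller"])
            if "fallback_fractions" in c:
                c["fallback_fractions"] = tuple(c["fallback_fractions"])
            d["caller"] = CallerConfig(**c)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # re-raise with the stage name attached
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Run all stages on a synthetic scene and write the artifact directory.

    Outputs: scene files (``ground_truth.csv``, ``masks.tif``,
    ``scene_spec.yaml``, optionally ``stack.tif``), ``traces.csv``,
    ``mitosis.csv``, ``phase_calls.csv``, ``profile.csv`` (green-channel mean
    intensity), ``sobel_profile.csv`` (red-channel Sobel), ``profile.png``
    and, when a mass-spec scalar is configured, ``concentration.csv``.
    Identical configs (same hash, same seed) give identical outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    handler = logging.FileHandler(out_dir / "run.log")
    logger.addHandler(handler)
    try:
        return _run(config, out_dir)
    finally:
        logger.removeHandler(handler)


def _run(config: RunConfig, out_dir: Path) -> Path:
    h = pio.config_hash(config.to_dict())
    seed = config.seed
    logger.info("config hash %s, seed %d", h, seed)
    config.to_yaml(out_dir / "run_config.yaml")

    if config.stack_path is not None:
        import tifffile

        stack = tifffile.imread(config.stack_path)
        masks = tifffile.imread(config.masks_path)
        mitosis = pio.read_csv(config.mitosis_path)
    else:
        scene = _stage("simulate")(generate_scene)(config.scene)
        pio.write_scene(scene, out_dir, write_stack=config.write_images)
        stack, masks = scene.stack, scene.masks
        mitosis = pio.mitosis_from_timelines(scene.timelines)

    traces = _stage("extract")(extract_traces)(
        stack, masks, config.scene.frame_interval_min)
    pio.write_csv(traces, out_dir / "traces.csv", cfg_hash=h, seed=seed)
    pio.write_csv(mitosis, out_dir / "mitosis.csv", cfg_hash=h, seed=seed)

    calls, undetected = _stage("call")(call_phases)(traces, mitosis, config.caller)
    if undetected:
        logger.warning("no S phase detected for cells %s", undetected)
    if not calls:
        raise RuntimeError("stage 'call' failed: no cell yielded a phase call")
    pio.write_csv(pio.calls_to_frame(calls), out_dir / "phase_calls.csv",
                  cfg_hash=h, seed=seed)

    profile = _stage("normalize")(build_profile)(
        traces, calls, channel="green", value="mean_intensity",
        grid_size=config.grid_size,
        mean_cycle_duration_h=config.mean_cycle_duration_h)
    pio.write_csv(profile.to_frame(), out_dir / "profile.csv", cfg_hash=h, seed=seed)

    sobel_profile = build_profile(
        traces, calls, channel="red", value="sobel_mean",
        grid_size=config.grid_size,
        mean_cycle_duration_h=config.mean_cycle_duration_h)
    pio.write_csv(sobel_profile.to_frame(), out_dir / "sobel_profile.csv",
                  cfg_hash=h, seed=seed)

    _plot_profiles(profile, sobel_profile, config.scene, out_dir / "profile.png")

    if config.ms_concentration is not None:
        conc = _stage("concentration")(calibrate)(
            profile, config.ms_concentration, config.ms_units)
        import pandas as pd
        pio.write_csv(
            pd.DataFrame({"time_h": conc.time_h,
                          f"concentration_{conc.units}": conc.concentration}),
            out_dir / "concentration.csv", cfg_hash=h, seed=seed)
    return out_dir


def _plot_profiles(profile, sobel_profile, spec: SceneSpec, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    for ax, prof, label, color in (
            (ax1, profile, f"{spec.green_archetype.name} mean intensity", "tab:green"),
            (ax2, sobel_profile, "PCNA Sobel mean", "tab:red")):
        ax.plot(prof.time_h, prof.mean, color=color, label=label)
        ax.fill_between(prof.time_h, prof.mean - prof.sd, prof.mean + prof.sd,
                        color=color, alpha=0.2)
        ax.set_ylabel("intensity (counts)")
        ax.legend(loc="best", frameon=False)
    ax2.set_xlabel("cell-cycle time (h)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
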