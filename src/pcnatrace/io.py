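"""Readers/writers for scenes, traces, phase calls and profiles.

Conventions: multi-page TIFF stacks in TZCYX order (16-bit), labelled-mask
TIFF, and tidy long-format CSV throughout, with times in minutes internally
and hours only in reported profiles.  Every CSV carries comment-line
provenance headers (tool version, config hash, seed) and is written with a
fixed float format so that write -> read -> write round-trips byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import archetypes as _arch
from .archetypes import ControlPoint, ExpressionArchetype
from .cycle import CyclePopulationParams, PhaseTimeline
from .normalize import NormalizedProfile
from .scene import FociModel, FociSubphaseParams, Scene, SceneSpec

FLOAT_FORMAT = "%.10g"

STACK_FILE = "stack.tif"
MASKS_FILE = "masks.tif"
GROUND_TRUTH_FILE = "ground_truth.csv"
SPEC_FILE = "scene_spec.yaml"


def _package_version() -> str:
    from . import __version__
    return __version__


def config_hash(obj) -> str:
    """Short stable hash of any JSON-serializable configuration object."""
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"unhashable config element {type(o)}")

    payload = json.dumps(obj, sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# CSV with provenance headers
# ---------------------------------------------------------------------------

def write_csv(df: pd.DataFrame, path, *, cfg_hash: str = "", seed=None) -> None:
    path = Path(path)
    header = [f"# pcnatrace {_package_version()}"]
    if cfg_hash:
        header.append(f"# config_hash={cfg_hash}")
    if seed is not None:
        header.append(f"# seed={seed}")
    buf = _io.StringIO()
    df.to_csv(buf, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")
    path.write_text("\n".join(header) + "\n" + buf.getvalue())


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# SceneSpec <-> YAML
# ---------------------------------------------------------------------------

def _archetype_to_dict(a: ExpressionArchetype) -> dict:
    if a.name in _arch.BUNDLED_ARCHETYPES and _arch.BUNDLED_ARCHETYPES[a.name] == a:
        return {"bundled": a.name}
    return {
        "name": a.name,
        "control_points": [[cp.phase, cp.fraction, cp.level] for cp in a.control_points],
        "mitotic_dilution": a.mitotic_dilution,
        "chromatin_pattern": a.chromatin_pattern,
    }


def _archetype_from_dict(d: dict) -> ExpressionArchetype:
    if "bundled" in d:
        return _arch.BUNDLED_ARCHETYPES[d["bundled"]]
    return ExpressionArchetype(
        name=d["name"],
        control_points=tuple(ControlPoint(p, f, l) for p, f, l in d["control_points"]),
        mitotic_dilution=d.get("mitotic_dilution", 0.5),
        chromatin_pattern=d.get("chromatin_pattern", "none"),
    )


def spec_to_dict(spec: SceneSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["cycle_params"] = dataclasses.asdict(spec.cycle_params)
    d["foci"] = None if spec.foci is None else {
        name: dataclasses.asdict(spec.foci.subphase(name))
        for name in ("early", "mid", "late")
    }
    d["red_archetype"] = _archetype_to_dict(spec.red_archetype)
    d["green_archetype"] = _archetype_to_dict(spec.green_archetype)
    d["image_shape"] = None if spec.image_shape is None else list(spec.image_shape)
    return d


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, list):
        return [_listify(v) for v in obj]
    return obj


def spec_from_dict(d: dict) -> SceneSpec:
    d = dict(d)
    d["cycle_params"] = CyclePopulationParams(**d["cycle_params"])
    if d.get("foci") is not None:
        subs = {}
        for name in ("early", "mid", "late"):
            s = dict(d["foci"][name])
            s["count_range"] = tuple(s["count_range"])
            s["radius_px_range"] = tuple(s["radius_px_range"])
            subs[name] = FociSubphaseParams(**s)
        d["foci"] = FociModel(**subs)
    d["red_archetype"] = _archetype_from_dict(d["red_archetype"])
    d["green_archetype"] = _archetype_from_dict(d["green_archetype"])
    if d.get("image_shape") is not None:
        d["image_shape"] = tuple(d["image_shape"])
    return SceneSpec(**d)


def write_spec_yaml(spec: SceneSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(_listify(spec_to_dict(spec)), sort_keys=False))


def read_spec_yaml(path) -> SceneSpec:
    return spec_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------

def timelines_to_frame(timelines) -> pd.DataFrame:
    rows = []
    for i, tl in enumerate(timelines, start=1):
        for boundary, t in tl.boundaries().items():
            rows.append({"cell_id": i, "boundary": boundary, "time_min": t})
    return pd.DataFrame(rows, columns=["cell_id", "boundary", "time_min"])


def timelines_from_frame(df: pd.DataFrame, provenance: str = "ground-truth"
                         ) -> dict[int, PhaseTimeline]:
    out = {}
    for cell_id, group in df.groupby("cell_id"):
        b = dict(zip(group["boundary"], group["time_min"]))
        out[int(cell_id)] = PhaseTimeline(
            s_start=b["s_start"], early_mid=b["early_mid"], mid_late=b["mid_late"],
            s_end=b["s_end"], m_start=b["m_start"], cycle_end=b["cycle_end"],
            provenance=provenance)
    return out


def mitosis_from_timelines(timelines) -> pd.DataFrame:
    """``cell_id, m_start_min, cycle_end_min`` annotations from timelines."""
    if isinstance(timelines, dict):
        items = sorted(timelines.items())
    else:
        items = list(enumerate(timelines, start=1))
    return pd.DataFrame(
        [{"cell_id": cid, "m_start_min": tl.m_start, "cycle_end_min": tl.cycle_end}
         for cid, tl in items])


def write_scene(scene: Scene, out_dir, write_stack: bool = True) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if write_stack:
        tifffile.imwrite(out_dir / STACK_FILE, scene.stack,
                         metadata={"axes": "TZCYX"})
    tifffile.imwrite(out_dir / MASKS_FILE, scene.masks, metadata={"axes": "TYX"})
    h = config_hash(spec_to_dict(scene.spec))
    write_csv(timelines_to_frame(scene.timelines), out_dir / GROUND_TRUTH_FILE,
              cfg_hash=h, seed=scene.spec.seed)
    write_spec_yaml(scene.spec, out_dir / SPEC_FILE)


def read_scene(scene_dir) -> Scene:
    scene_dir = Path(scene_dir)
    spec = read_spec_yaml(scene_dir / SPEC_FILE)
    stack = tifffile.imread(scene_dir / STACK_FILE)
    masks = tifffile.imread(scene_dir / MASKS_FILE)
    gt = read_csv(scene_dir / GROUND_TRUTH_FILE)
    timelines = timelines_from_frame(gt)
    return Scene(stack=stack, masks=masks,
                 timelines=tuple(timelines[k] for k in sorted(timelines)),
                 spec=spec)


# ---------------------------------------------------------------------------
# phase calls and profiles
# ---------------------------------------------------------------------------

def calls_to_frame(calls: dict) -> pd.DataFrame:
    rows = []
    for cell_id, call in sorted(calls.items()):
        tl = call.timeline
        methods = getattr(call, "methods", {})
        for boundary, t in tl.boundaries().items():
            rows.append({"cell_id": cell_id, "boundary": boundary, "time_min": t,
                         "method": methods.get(boundary, "changepoint")})
    return pd.DataFrame(rows, columns=["cell_id", "boundary", "time_min", "method"])


def calls_from_frame(df: pd.DataFrame) -> dict[int, PhaseTimeline]:
    return timelines_from_frame(df, provenance="called")


def profile_to_frame(profile: NormalizedProfile) -> pd.DataFrame:
    return profile.to_frame()
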