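"""File formats: 16-bit grayscale PNG scene pairs, scenes.csv metadata,
control-point CSVs, homography/crop JSON sidecars, and the JSON-lines event
log used for exclusion accounting.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .preprocess import Homography, RawCapture, SceneMetadata
from .synthetic import GroundTruth

__all__ = [
    "read_png16",
    "write_png16",
    "read_scenes_csv",
    "append_scene_row",
    "read_scene_pair",
    "write_scene_pair",
    "read_control_points",
    "write_control_points",
    "EventLog",
]

SCENES_CSV_COLUMNS = [
    "stem", "elevation", "exposure_s", "nd_od", "weather", "distance", "objects",
]


def read_png16(path: str | Path) -> np.ndarray:
    """Read a single-channel 16-bit grayscale PNG as a uint16 array."""
    img = iio.imread(path)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel grayscale PNG")
    if img.dtype != np.uint16:
        raise ValueError(f"{path}: expected 16-bit depth, got {img.dtype}")
    return img


def write_png16(path: str | Path, image: np.ndarray) -> None:
    img = np.asarray(image)
    if img.dtype != np.uint16:
        if img.min() < 0 or img.max() > 65535:
            raise ValueError("image values do not fit a 16-bit container")
        img = np.rint(img).astype(np.uint16)
    iio.imwrite(path, img)


def read_scenes_csv(root: str | Path) -> pd.DataFrame:
    path = Path(root) / "scenes.csv"
    if not path.exists():
        raise FileNotFoundError(f"no scenes.csv under {root}")
    return pd.read_csv(path, dtype={"stem": str})


def append_scene_row(root: str | Path, meta: SceneMetadata) -> None:
    path = Path(root) / "scenes.csv"
    row = pd.DataFrame(
        [
            {
                "stem": meta.stem,
                "elevation": meta.elevation,
                "exposure_s": meta.exposure_s,
                "nd_od": meta.nd_od,
                "weather": meta.weather,
                "distance": meta.distance,
                "objects": meta.objects,
            }
        ],
        columns=SCENES_CSV_COLUMNS,
    )
    row.to_csv(path, mode="a", header=not path.exists(), index=False)


def read_scene_pair(
    stem: str, root: str | Path
) -> tuple[RawCapture, RawCapture, np.ndarray, SceneMetadata]:
    """Read <stem>_uv.png, <stem>_green.png, <stem>_ref.png and metadata.

    Metadata is joined from scenes.csv by stem; a missing row or a PNG with
    the wrong bit depth or channel count is an error.
    """
    root = Path(root)
    df = read_scenes_csv(root)
    rows = df[df["stem"] == stem]
    if rows.empty:
        raise ValueError(f"no metadata row for stem {stem!r} in {root / 'scenes.csv'}")
    r = rows.iloc[0]
    meta = SceneMetadata(
        stem=stem,
        elevation=str(r["elevation"]),
        exposure_s=float(r["exposure_s"]),
        nd_od=float(r["nd_od"]),
        weather=str(r.get("weather", "")),
        distance=str(r.get("distance", "")),
        objects=str(r.get("objects", "")),
    )
    uv = read_png16(root / f"{stem}_uv.png")
    green = read_png16(root / f"{stem}_green.png")
    ref = read_png16(root / f"{stem}_ref.png").astype(float)
    for name, img in (("uv", uv), ("green", green)):
        if img.max() > 4095:
            raise ValueError(f"{stem}_{name}.png exceeds the 12-bit range")
    return (
        RawCapture(uv, "UV", meta),
        RawCapture(green, "Green", meta),
        ref,
        meta,
    )


def write_scene_pair(
    root: str | Path,
    meta: SceneMetadata,
    raw_uv: np.ndarray,
    raw_green: np.ndarray,
    reference: np.ndarray,
    truth: GroundTruth | None = None,
) -> None:
    """Write the PNG triplet, append the scenes.csv row, dump truth JSON."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    write_png16(root / f"{meta.stem}_uv.png", raw_uv)
    write_png16(root / f"{meta.stem}_green.png", raw_green)
    write_png16(root / f"{meta.stem}_ref.png", reference)
    append_scene_row(root, meta)
    if truth is not None:
        sidecar = {
            "homography": truth.homography.tolist(),
            "clip_fraction_uv": truth.clip_fraction_uv,
            "clip_fraction_green": truth.clip_fraction_green,
            "clip_warning": truth.clip_warning,
            "params": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in asdict(truth.params).items()
            },
        }
        (root / f"{meta.stem}_truth.json").write_text(json.dumps(sidecar, indent=2))


def write_control_points(path: str | Path, src: np.ndarray, dst: np.ndarray) -> None:
    df = pd.DataFrame(
        {
            "x_src": src[:, 0], "y_src": src[:, 1],
            "x_dst": dst[:, 0], "y_dst": dst[:, 1],
        }
    )
    df.to_csv(path, index=False)


def read_control_points(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    src = df[["x_src", "y_src"]].to_numpy(float)
    dst = df[["x_dst", "y_dst"]].to_numpy(float)
    return src, dst


def write_homography(path: str | Path, h: Homography) -> None:
    Path(path).write_text(json.dumps({"matrix": h.matrix.tolist()}, indent=2))


def read_homography(path: str | Path) -> Homography:
    d = json.loads(Path(path).read_text())
    return Homography(np.asarray(d["matrix"], dtype=float))


class EventLog:
    """JSON-lines event log (scene, stage, event, counts) for exclusions."""

    def __init__(self, path: str | Path | None):
        self.path = Path(path) if path is not None else None
        self.events: list[dict] = []
        if self.path is not None:
            self.path.parent.mkdir(parents=True, exist_ok=True)
            self.path.write_text("")

    def record(self, scene: str, stage: str, event: str, **counts) -> None:
        entry = {"scene": scene, "stage": stage, "event": event, **counts}
        self.events.append(entry)
        if self.path is not None:
            with open(self.path, "a") as fh:
                fh.write(json.dumps(entry) + "\n")
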