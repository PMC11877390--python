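"""Run configuration, provenance records, and on-disk formats.

All tabular artifacts are CSV with documented headers, videos are multi-page
grayscale TIFF with a JSON sidecar (fps, seed, parameters, ground truth),
and reports are JSON.  One master seed fans out deterministically to every
stage so a whole run is replayable from its manifest chain.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .simulate import CardiacParams, OpticsParams, SpeckleVideo
from .vibrometry import DisplacementTrace

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ("frame_index", "dx", "dy", "x_cum", "y_cum", "peak_height")


@dataclass
class RunConfig:
    """Every stage's parameters, with study defaults.

    Defaults mirror the study protocol: 500 fps recordings of 6 s (3000
    frames), 256-frame chunks with a 32-frame stride, feature filtering at
    alpha = 0.05 without multiplicity correction, and all six label schemes.
    """

    duration_s: float = 6.0
    fps: float = 500.0
    n_subjects: int = 5
    recordings_per_state: int = 5
    optics: OpticsParams = field(default_factory=OpticsParams)
    subpixel: bool = True
    chunk_length: int = 256
    chunk_stride: int = 32
    alpha: float = 0.05
    correction: str = "none"
    schemes: tuple[str, ...] = (
        "five", "three_case1", "three_case2", "binary_A", "binary_B", "binary_C"
    )
    trials: int = 50
    seed: int = 0
    validation_subject: str = "S5"
    render: bool = True

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fps <= 0:
            raise ValueError("duration_s and fps must be > 0")
        if self.chunk_length < 2:
            raise ValueError("chunk_length must be >= 2")
        if self.chunk_stride < 1:
            raise ValueError("chunk_stride must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.correction not in ("none", "fdr"):
            raise ValueError("correction must be 'none' or 'fdr'")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if self.recordings_per_state < 1:
            raise ValueError("recordings_per_state must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schemes"] = list(self.schemes)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; valid keys: {sorted(known)}"
            )
        if "optics" in data and isinstance(data["optics"], dict):
            opt_known = {f.name for f in dataclasses.fields(OpticsParams)}
            opt_unknown = set(data["optics"]) - opt_known
            if opt_unknown:
                raise ValueError(
                    f"unknown optics keys {sorted(opt_unknown)}; "
                    f"valid keys: {sorted(opt_known)}"
                )
            data["optics"] = OpticsParams(**data["optics"])
        if "schemes" in data:
            data["schemes"] = tuple(data["schemes"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run configuration; an empty file means defaults."""
    path = Path(path)
    data = yaml.safe_load(path.read_text())  # YAML is a superset of JSON
    return RunConfig.from_dict(data or {})


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def stage_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed: master seed + CRC32(stage name) + index."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode()), index])
    return int(ss.generate_state(1)[0] % 2**31)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def write_provenance(
    stage: str,
    inputs: list[str | Path],
    outputs: list[str | Path],
    seed: int,
    config_hash: str,
    path: str | Path | None = None,
) -> dict:
    """Record what a stage consumed and produced; optionally write as JSON."""
    record = {
        "stage": stage,
        "inputs": {str(p): file_sha256(p) for p in inputs if Path(p).exists()},
        "outputs": [str(p) for p in outputs],
        "seed": int(seed),
        "config_hash": config_hash,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    if path is not None:
        Path(path).write_text(json.dumps(record, indent=2))
    return record


def check_provenance(artifact_path: str | Path) -> bool:
    """Warn (and return False) if an artifact has no provenance sidecar."""
    sidecar = Path(str(artifact_path) + ".prov.json")
    if not sidecar.exists():
        logger.warning("no provenance record found for %s", artifact_path)
        return False
    return True


# ---------------------------------------------------------------------------
# video I/O


def write_video(video: SpeckleVideo, path: str | Path, extra_meta: dict | None = None) -> None:
    """Multi-page grayscale TIFF plus a JSON sidecar with fps and ground truth."""
    path = Path(path)
    tifffile.imwrite(path, video.frames, photometric="minisblack")
    sidecar = {
        "fps": video.fps,
        "n_frames": video.n_frames,
        "ground_truth": None
        if video.ground_truth is None
        else np.asarray(video.ground_truth).tolist(),
    }
    sidecar.update(extra_meta or {})
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_video(path: str | Path, fps: float | None = None) -> SpeckleVideo:
    """Read a multi-page TIFF or a directory of frames (lexicographic order)."""
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff"))
        if not files:
            raise ValueError(f"no frame images found in directory {path}")
        frames = np.stack([np.asarray(iio.imread(f)) for f in files])
        sidecar_path = path / "meta.json"
    else:
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        sidecar_path = path.with_suffix(path.suffix + ".json")
    ground_truth = None
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        fps = fps or meta.get("fps")
        if meta.get("ground_truth") is not None:
            ground_truth = np.asarray(meta["ground_truth"], dtype=float)
    if fps is None:
        raise ValueError(f"fps not given and no JSON sidecar found for {path}")
    return SpeckleVideo(frames=frames, fps=float(fps), ground_truth=ground_truth)


# ---------------------------------------------------------------------------
# trace I/O


def write_trace(trace: DisplacementTrace, path: str | Path) -> None:
    """CSV with columns frame_index, dx, dy, x_cum, y_cum, peak_height.

    Row *i* holds the pair shift and peak height of pair (i-1, i); row 0 has
    empty pair fields.  fps goes into a JSON sidecar.
    """
    path = Path(path)
    n = trace.n_frames
    df = pd.DataFrame(
        {
            "frame_index": np.arange(n),
            "dx": np.r_[np.nan, trace.pair_shift[:, 0]],
            "dy": np.r_[np.nan, trace.pair_shift[:, 1]],
            "x_cum": trace.cum_position[:, 0],
            "y_cum": trace.cum_position[:, 1],
            "peak_height": np.r_[np.nan, trace.peak_height],
        }
    )
    df.to_csv(path, index=False)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps({"fps": trace.fps}))


def read_trace(path: str | Path, fps: float | None = None) -> DisplacementTrace:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV {path} is missing columns {missing}")
    sidecar = path.with_suffix(path.suffix + ".json")
    if fps is None:
        if not sidecar.exists():
            raise ValueError(f"fps not given and no JSON sidecar found for {path}")
        fps = float(json.loads(sidecar.read_text())["fps"])
    return DisplacementTrace(
        fps=fps,
        pair_shift=df[["dx", "dy"]].to_numpy(dtype=float)[1:],
        cum_position=df[["x_cum", "y_cum"]].to_numpy(dtype=float),
        peak_height=df["peak_height"].to_numpy(dtype=float)[1:],
    )


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
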