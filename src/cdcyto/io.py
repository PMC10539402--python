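"""Readers/writers: frame sequences, cell-record tables, configs.

Records are plain CSV (human-inspectable, diff-able) with a versioned schema
and provenance carried in ``#``-comment header lines (schema version, seed,
config hash).  Frames are numbered PNGs or a multi-page TIFF; lazy access is
provided so a long video never needs to be resident at once.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .errors import InputError, SchemaError
from .measure import RECORD_COLUMNS

RECORD_SCHEMA_VERSION = "cdcyto-records-v1"

_FRAME_EXTENSIONS = (".png", ".tif", ".tiff")


def _numeric_key(name: str):
    parts = re.split(r"(\d+)", name)
    return [int(p) if p.isdigit() else p for p in parts]


class FrameSequence:
    """Lazy, index-ordered view of a directory of numbered images.

    Supports ``len``, integer indexing and iteration; frames are read on
    access, never all held at once.  All frames must share one shape/dtype
    (checked lazily against the first frame).
    """

    def __init__(self, paths: list[Path]):
        if not paths:
            raise InputError("no frames found")
        self._paths = paths
        self._shape = None

    def __len__(self) -> int:
        return len(self._paths)

    def __getitem__(self, i: int) -> np.ndarray:
        try:
            frame = iio.imread(self._paths[i])
        except (OSError, ValueError) as exc:
            raise InputError(f"unreadable frame file {self._paths[i]}: {exc}") from exc
        if self._shape is None:
            self._shape = frame.shape
        elif frame.shape != self._shape:
            raise InputError(
                f"mixed frame shapes: {self._paths[i]} is {frame.shape}, "
                f"expected {self._shape}"
            )
        return frame

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]


def read_frames(path: str | Path):
    """Read a frame sequence from a directory of PNG/TIFF or a multi-page TIFF.

    Directory entries are ordered by natural (numeric-aware) filename sort.
    Returns a lazy :class:`FrameSequence` for directories; a (T, H, W) array
    for a single multi-page file.
    """
    path = Path(path)
    if path.is_dir():
        paths = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTENSIONS),
            key=lambda p: _numeric_key(p.name),
        )
        if not paths:
            raise InputError(f"no image files in {path}")
        return FrameSequence(paths)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    frames = iio.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return frames


def write_frames(frames, out_dir: str | Path, prefix: str = "frame") -> list[Path]:
    """Write frames as numbered PNGs; round-trips bit-identically."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(len(frames)):
        p = out_dir / f"{prefix}_{i:06d}.png"
        iio.imwrite(p, np.asarray(frames[i]))
        paths.append(p)
    return paths


def config_hash(config: dict) -> str:
    """Short stable hash of a JSON-serializable config."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_records(
    df: pd.DataFrame,
    path: str | Path,
    seed=None,
    cfg_hash: str | None = None,
) -> Path:
    """Write a cell-record table with schema/provenance header comments.

    Floats are written at 12 significant digits, so write->read round-trips
    agree to well below 1e-9 relative.
    """
    unknown = [c for c in df.columns if c not in RECORD_COLUMNS]
    if unknown:
        raise SchemaError(f"unknown record columns: {unknown}")
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing record columns: {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# schema={RECORD_SCHEMA_VERSION}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        if cfg_hash is not None:
            fh.write(f"# config_hash={cfg_hash}\n")
        df[RECORD_COLUMNS].to_csv(fh, index=False, float_format="%.12g")
    return path


def read_records(path: str | Path) -> pd.DataFrame:
    """Read a cell-record table, validating the schema.

    Raises :class:`SchemaError` listing offending columns on any mismatch.
    Header ``#`` comments (schema, seed, config hash) are exposed via
    ``df.attrs``.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
        df = pd.read_csv(fh)
    unknown = [c for c in df.columns if c not in RECORD_COLUMNS]
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if unknown or missing:
        raise SchemaError(
            f"record schema mismatch: unknown columns {unknown}, missing {missing}"
        )
    df.attrs.update(meta)
    # normalize pandas' reading of empty strings in flags
    df["flags"] = df["flags"].fillna("")
    return df


def load_config(path: str | Path) -> dict:
    """Load a JSON or YAML configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}
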