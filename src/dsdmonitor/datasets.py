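"""Reading and writing frame datasets and score tables.

Two on-disk layouts are supported:

``manifest``
    Image files plus a ``manifest.csv`` with header
    ``index,label,timestamp_ms`` (label 1 = descending duodenum).

``threepart`` (three-part naming)
    Each image's filename encodes its ground truth, position and score as
    ``<label>-<index>-<score>`` (two hyphens): label 0 = stomach/duodenal
    bulb, 1 = DSD; index is the consecutive frame number; score is the
    classifier's probability, written with two decimals by default.

Score tables are CSVs with header ``index,label,score``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .synth import FrameStream

__all__ = [
    "write_dataset",
    "read_dataset",
    "three_part_name",
    "parse_three_part_name",
    "write_scores_csv",
    "read_scores_csv",
]

_THREE_PART_RE = re.compile(r"^([01])-(\d+)-([0-9.]+)$")


def three_part_name(label: int, index: int, score: float, decimals: int = 2) -> str:
    """Three-part filename stem, e.g. ``1-1466-0.97``."""
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    return f"{label}-{index}-{score:.{decimals}f}"


def parse_three_part_name(stem: str) -> tuple[int, int, float]:
    """Inverse of :func:`three_part_name`: returns (label, index, score)."""
    m = _THREE_PART_RE.match(stem)
    if not m:
        raise ValueError(f"not a three-part dataset filename: {stem!r}")
    return int(m.group(1)), int(m.group(2)), float(m.group(3))


def write_dataset(
    stream: FrameStream,
    directory,
    naming: str = "manifest",
    scores=None,
    image_format: str = "png",
    score_decimals: int = 2,
) -> list[Path]:
    """Write a labelled stream to ``directory``.

    With ``naming="threepart"`` per-frame ``scores`` are required because the
    three-part filename embeds the probability score.  With
    ``naming="manifest"`` a ``manifest.csv`` (index, label, timestamp_ms)
    accompanies zero-padded image files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if naming not in ("manifest", "threepart"):
        raise ValueError(f"unknown naming scheme: {naming!r}")
    if stream.labels is None:
        raise ValueError("stream has no labels")
    ext = image_format.lower().lstrip(".")
    if ext == "jpeg":
        ext = "jpg"

    if naming == "threepart":
        if scores is None:
            raise ValueError("three-part naming requires per-frame scores")
        scores = np.asarray(scores, dtype=float)
        if len(scores) != len(stream):
            raise ValueError("scores and stream must have equal length")

    paths = []
    width = len(str(max(len(stream) - 1, 1)))
    for i, (img, label) in enumerate(zip(stream.frames, stream.labels)):
        if naming == "threepart":
            stem = three_part_name(int(label), i, float(scores[i]), score_decimals)
        else:
            stem = f"frame_{i:0{width}d}"
        p = directory / f"{stem}.{ext}"
        Image.fromarray(np.asarray(img, dtype=np.uint8), mode="L").save(p)
        paths.append(p)

    if naming == "manifest":
        manifest = pd.DataFrame(
            {
                "index": np.arange(len(stream)),
                "label": np.asarray(stream.labels, dtype=int),
                "timestamp_ms": stream.timestamps_ms,
            }
        )
        manifest.to_csv(directory / "manifest.csv", index=False)
    return paths


@dataclass
class Dataset:
    """An on-disk dataset pulled back into memory."""

    frames: np.ndarray
    labels: np.ndarray
    indices: np.ndarray
    scores: np.ndarray | None = None
    interval_ms: float = 500.0

    def __len__(self) -> int:
        return len(self.frames)


_IMAGE_EXTS = (".png", ".jpg", ".jpeg")


def read_dataset(directory) -> Dataset:
    """Read a dataset written by :func:`write_dataset` (either naming)."""
    directory = Path(directory)
    manifest_path = directory / "manifest.csv"
    image_paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in _IMAGE_EXTS
    )
    if not image_paths:
        raise ValueError(f"no images found in {directory}")

    if manifest_path.exists():
        manifest = pd.read_csv(manifest_path)
        frames = np.stack([np.asarray(Image.open(p).convert("L")) for p in image_paths])
        interval = 500.0
        ts = manifest["timestamp_ms"].to_numpy(dtype=float)
        if len(ts) > 1:
            interval = float(ts[1] - ts[0])
        return Dataset(
            frames=frames,
            labels=manifest["label"].to_numpy(dtype=np.int8),
            indices=manifest["index"].to_numpy(dtype=int),
            interval_ms=interval,
        )

    parsed = [(parse_three_part_name(p.stem), p) for p in image_paths]
    order = np.argsort([t[0][1] for t in parsed], kind="stable")
    labels, indices, scores, frames = [], [], [], []
    for k in order:
        (label, index, score), p = parsed[k]
        labels.append(label)
        indices.append(index)
        scores.append(score)
        frames.append(np.asarray(Image.open(p).convert("L")))
    return Dataset(
        frames=np.stack(frames),
        labels=np.asarray(labels, dtype=np.int8),
        indices=np.asarray(indices, dtype=int),
        scores=np.asarray(scores, dtype=float),
    )


def write_scores_csv(path, indices, labels, scores) -> None:
    pd.DataFrame(
        {"index": np.asarray(indices, dtype=int),
         "label": np.asarray(labels, dtype=int),
         "score": np.asarray(scores, dtype=float)}
    ).to_csv(path, index=False)


def read_scores_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"index", "label", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"score CSV missing columns: {sorted(missing)}")
    return df
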