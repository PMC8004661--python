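"""Reading view sequences and writing results.

Input is the segmented-view convention of inspection machines: a
directory of PNG frames of one object, ordered by filename, with every
background pixel set to pure black (RGB = {0,0,0}).  A pixel belongs to
the object iff any channel is non-zero.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["SequenceRecord", "SequenceError", "load_sequence",
           "mask_from_frame", "save_frames"]


class SequenceError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    """Ordered frames of one object plus their foreground masks."""

    frames: list
    masks: list
    paths: list

    @property
    def n_views(self) -> int:
        return len(self.frames)


def _natural_key(name: str):
    return [int(tok) if tok.isdigit() else tok.lower()
            for tok in re.split(r"(\d+)", name)]


def mask_from_frame(frame: np.ndarray) -> np.ndarray:
    """Foreground mask: any channel non-zero (black-background convention)."""
    frame = np.asarray(frame)
    if frame.ndim == 3:
        return (frame != 0).any(axis=-1)
    return frame != 0


def load_sequence(source) -> SequenceRecord:
    """Load an ordered sequence of views.

    ``source`` may be a directory containing PNG frames (sorted in
    natural filename order), an explicit list of file paths, or a list of
    in-memory arrays.  All frames must share the same dimensions and
    each must contain at least one foreground pixel.
    """
    paths: list = []
    if isinstance(source, (str, Path)):
        directory = Path(source)
        if not directory.is_dir():
            raise SequenceError(f"{directory} is not a directory")
        paths = sorted(
            (p for p in directory.iterdir() if p.suffix.lower() == ".png"),
            key=lambda p: _natural_key(p.name),
        )
        if not paths:
            raise SequenceError(f"no PNG frames found in {directory}")
        frames = [np.asarray(iio.imread(p)) for p in paths]
    elif len(source) and isinstance(source[0], (str, Path)):
        paths = [Path(p) for p in source]
        frames = [np.asarray(iio.imread(p)) for p in paths]
    else:
        frames = [np.asarray(f) for f in source]
        paths = [None] * len(frames)
    if len(frames) == 0:
        raise SequenceError("empty sequence")

    shape0 = frames[0].shape
    masks = []
    for i, frame in enumerate(frames):
        if frame.shape != shape0:
            raise SequenceError(
                f"view {i} has shape {frame.shape}, expected {shape0}"
            )
        mask = mask_from_frame(frame)
        if not mask.any():
            raise SequenceError(f"view {i} is entirely black (empty mask)")
        masks.append(mask)
    return SequenceRecord(frames=frames, masks=masks, paths=paths)


def save_frames(directory, frames) -> list:
    """Write frames as view_000.png, view_001.png, ... and return the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = directory / f"view_{i:03d}.png"
        iio.imwrite(p, np.asarray(frame))
        paths.append(p)
    return paths


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2))
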