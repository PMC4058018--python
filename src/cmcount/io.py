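"""Reading and writing cytospin slide image sets.

A slide is stored on disk as one 8-bit multi-page TIFF per fluorescence
channel (one page per field of view, FOV) plus a ``channels.json`` map from
channel name to file name.  The three channels are the DAPI nuclear stain
(blue), the CD45 leukocyte counterstain (red) and the melanoma marker,
Melan-A or S100B (green).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

#: canonical channel order: nuclear stain, leukocyte stain, melanoma marker
CHANNELS = ("dapi", "cd45", "marker")

_DEFAULT_FILES = {c: f"{c}.tif" for c in CHANNELS}


class SlideFormatError(ValueError):
    """Raised when slide files are missing, mismatched or not 8-bit."""


@dataclass
class FOVImage:
    """One field of view: a dict of equally shaped 2-D uint8 arrays."""

    channels: dict[str, np.ndarray]
    fov_index: int = 0
    grid_pos: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        shapes = {c: a.shape for c, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise SlideFormatError(f"channel shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class SlideImageSet:
    """Ordered FOVs covering one cytospin area of interest."""

    fovs: list[FOVImage] = field(default_factory=list)

    @property
    def n_fov(self) -> int:
        return len(self.fovs)

    def __iter__(self):
        return iter(self.fovs)

    def __getitem__(self, i: int) -> FOVImage:
        return self.fovs[i]


def grid_position(fov_index: int, n_fov: int) -> tuple[int, int]:
    """Row/column of a FOV on the (near-square) virtual acquisition grid."""
    ncols = max(1, int(np.ceil(np.sqrt(n_fov))))
    return (fov_index // ncols, fov_index % ncols)


def write_slide(slide: SlideImageSet, path: str | Path) -> Path:
    """Write per-channel multi-page TIFF stacks and the channel map.

    Returns the directory written.  Arrays must already be uint8.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for chan in CHANNELS:
        pages = []
        for fov in slide:
            if chan not in fov.channels:
                raise SlideFormatError(f"FOV {fov.fov_index} lacks channel {chan!r}")
            arr = fov.channels[chan]
            if arr.dtype != np.uint8:
                raise SlideFormatError(
                    f"channel {chan!r} of FOV {fov.fov_index} is {arr.dtype}, "
                    "expected uint8"
                )
            pages.append(arr)
        tifffile.imwrite(
            path / _DEFAULT_FILES[chan], np.stack(pages), photometric="minisblack"
        )
    (path / "channels.json").write_text(json.dumps(_DEFAULT_FILES, indent=1))
    return path


def read_slide(path: str | Path) -> SlideImageSet:
    """Read a slide directory written by :func:`write_slide`.

    Fails loudly on a missing channel, page-count mismatch between channels,
    shape mismatch, or non-8-bit data.
    """
    path = Path(path)
    chan_map_file = path / "channels.json"
    if chan_map_file.exists():
        chan_map = json.loads(chan_map_file.read_text())
    else:
        chan_map = dict(_DEFAULT_FILES)
    stacks: dict[str, np.ndarray] = {}
    for chan in CHANNELS:
        fname = chan_map.get(chan)
        if fname is None or not (path / fname).exists():
            raise SlideFormatError(f"missing channel {chan!r} (file {fname!r}) in {path}")
        arr = tifffile.imread(path / fname)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.dtype != np.uint8:
            raise SlideFormatError(
                f"channel {chan!r} in {path / fname} is {arr.dtype}; "
                "re-export the stack as 8-bit (0-255) before counting"
            )
        stacks[chan] = arr
    n_pages = {c: s.shape[0] for c, s in stacks.items()}
    if len(set(n_pages.values())) > 1:
        raise SlideFormatError(f"page-count mismatch between channels in {path}: {n_pages}")
    shapes = {c: s.shape[1:] for c, s in stacks.items()}
    if len(set(shapes.values())) > 1:
        raise SlideFormatError(f"FOV shape mismatch between channels in {path}: {shapes}")
    n = next(iter(n_pages.values()))
    fovs = [
        FOVImage(
            channels={c: stacks[c][i] for c in CHANNELS},
            fov_index=i,
            grid_pos=grid_position(i, n),
        )
        for i in range(n)
    ]
    return SlideImageSet(fovs)
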