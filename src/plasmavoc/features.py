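"""Block-grid segmentation, mean-RGB feature vectors, and reconstruction.

An image is partitioned into ``n_w x n_h`` equal rectangles (``n_w``
divisions across the width, ``n_h`` down the height); each block is
summarized by the arithmetic mean of its pixels per channel, and the block
triplets are concatenated row-major into a feature vector of length
``3 * n_w * n_h``.  At one extreme (1x1) the vector is the whole-image mean
color; at the other (one pixel per block) it is a flattening of the image
itself.  Reconstruction paints each block with its rounded mean color,
which is how the information kept by a given grid is visualized.

Grids are quoted ``"n_w x n_h"`` to match the convention that image sizes
are width x height; all grids used in practice divide their region's
dimensions exactly (strict mode), and a permissive mode that truncates
remainder rows/columns exists behind a flag.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .images import LabeledImage

__all__ = [
    "BlockGrid",
    "FeatureVector",
    "segment",
    "block_mean",
    "featurize",
    "reconstruct",
    "write_features",
    "read_features",
]

_GRID_RE = re.compile(r"^\s*(\d+)\s*[xX×]\s*(\d+)\s*$")


@dataclass(frozen=True)
class BlockGrid:
    """``n_w`` block columns across the width, ``n_h`` block rows down the
    height."""

    n_w: int
    n_h: int

    def __post_init__(self) -> None:
        if self.n_w < 1 or self.n_h < 1:
            raise ValueError(f"block counts must be >= 1, got {self.n_w}x{self.n_h}")

    @property
    def n_blocks(self) -> int:
        return self.n_w * self.n_h

    @property
    def vector_length(self) -> int:
        return 3 * self.n_blocks

    def render(self) -> str:
        return f"{self.n_w}x{self.n_h}"

    def __str__(self) -> str:  # pragma: no cover
        return self.render()

    @classmethod
    def from_string(cls, text: str) -> "BlockGrid":
        m = _GRID_RE.match(text)
        if m is None:
            raise ValueError(f'malformed grid {text!r}; expected "<n_w>x<n_h>"')
        return cls(int(m.group(1)), int(m.group(2)))


def _block_shape(image: LabeledImage, grid: BlockGrid, strict: bool
                 ) -> tuple[int, int]:
    """Block (height, width) in pixels; validates divisibility in strict mode."""
    rem_h = image.height % grid.n_h
    rem_w = image.width % grid.n_w
    if strict and (rem_h or rem_w):
        raise ValueError(
            f"grid {grid.render()} does not divide the {image.width}x"
            f"{image.height} image exactly (width remainder {rem_w}, "
            f"height remainder {rem_h}); use permissive mode to truncate"
        )
    bh = image.height // grid.n_h
    bw = image.width // grid.n_w
    if bh < 1 or bw < 1:
        raise ValueError(
            f"grid {grid.render()} is finer than the {image.width}x"
            f"{image.height} image"
        )
    return bh, bw


def segment(image: LabeledImage, grid: BlockGrid,
            strict: bool = True) -> list[np.ndarray]:
    """Partition ``image`` into ``n_w * n_h`` blocks in row-major order.

    Blocks tile the image without gap or overlap.  In strict mode (the
    default) the grid must divide the image dimensions exactly; permissive
    mode silently truncates remainder rows/columns on the bottom/right.
    """
    bh, bw = _block_shape(image, grid, strict)
    px = image.pixels[: grid.n_h * bh, : grid.n_w * bw]
    return [
        px[r * bh:(r + 1) * bh, c * bw:(c + 1) * bw]
        for r in range(grid.n_h)
        for c in range(grid.n_w)
    ]


def block_mean(block: np.ndarray) -> tuple[float, float, float]:
    """Per-channel arithmetic mean of a pixel block, in floating point."""
    arr = np.asarray(block)
    if arr.size == 0:
        raise ValueError("empty block has no mean color")
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (h, w, 3) block, got shape {arr.shape}")
    r, g, b = arr.reshape(-1, 3).mean(axis=0, dtype=np.float64)
    return float(r), float(g), float(b)


@dataclass
class FeatureVector:
    """Concatenated per-block mean-RGB triplets for one image.

    ``values`` has length ``3 * n_w * n_h`` when ``grid`` is set; a
    concatenation of vectors from several regions has ``grid=None``.
    Entries always lie in [0, 255] (they are means of 8-bit channels).
    """

    values: np.ndarray
    grid: BlockGrid | None = None
    region_name: str = ""
    source_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64).ravel()
        if self.grid is not None and vals.size != self.grid.vector_length:
            raise ValueError(
                f"vector length {vals.size} inconsistent with grid "
                f"{self.grid.render()} (expected {self.grid.vector_length})"
            )
        if vals.size and (vals.min() < 0.0 or vals.max() > 255.0):
            raise ValueError("feature entries must lie within [0, 255]")
        self.values = vals

    def __len__(self) -> int:
        return int(self.values.size)


def featurize(image: LabeledImage, grid: BlockGrid,
              region_name: str = "", strict: bool = True) -> FeatureVector:
    """Build the block-mean RGB feature vector for ``image`` under ``grid``.

    Blocks are traversed row-major, top-left to bottom-right, each
    contributing its (R̄, Ḡ, B̄) triplet consecutively; means are kept in
    double precision with no intermediate rounding.
    """
    bh, bw = _block_shape(image, grid, strict)
    px = image.pixels[: grid.n_h * bh, : grid.n_w * bw]
    means = px.reshape(grid.n_h, bh, grid.n_w, bw, 3).mean(
        axis=(1, 3), dtype=np.float64
    )
    return FeatureVector(
        means.ravel(),
        grid=grid,
        region_name=region_name,
        source_id=image.source_id,
        label=image.label,
    )


def reconstruct(vector: FeatureVector, out_height: int, out_width: int
                ) -> LabeledImage:
    """Paint each block of an ``out_height x out_width`` canvas with its
    (rounded) mean color.

    The output dimensions must be divisible by the vector's grid.  At a
    one-pixel-per-block grid the reconstruction reproduces the source
    image exactly (integer means round to themselves).
    """
    if vector.grid is None:
        raise ValueError("cannot reconstruct from a grid-less (concatenated) vector")
    grid = vector.grid
    if out_height % grid.n_h or out_width % grid.n_w:
        raise ValueError(
            f"output size {out_width}x{out_height} not divisible by grid "
            f"{grid.render()}"
        )
    bh = out_height // grid.n_h
    bw = out_width // grid.n_w
    means = vector.values.reshape(grid.n_h, grid.n_w, 3)
    canvas = np.repeat(np.repeat(means, bh, axis=0), bw, axis=1)
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return LabeledImage(pixels, label=vector.label,
                        source_id=vector.source_id)


# ---------------------------------------------------------------------------
# feature file I/O
#
# CSV layout: one row per image with columns source_id, label, region,
# grid ("8x10"), v_000 ... v_{n-1}; a JSON sidecar records grid/region
# metadata for the file as a whole.

def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_features(vectors: Sequence[FeatureVector], path: str | Path) -> Path:
    if not vectors:
        raise ValueError("no feature vectors to write")
    lengths = {len(v) for v in vectors}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent vector lengths {sorted(lengths)}")
    n = lengths.pop()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    width = max(3, len(str(n - 1)))
    cols = [f"v_{i:0{width}d}" for i in range(n)]
    df = pd.DataFrame(
        [v.values for v in vectors], columns=cols
    )
    df.insert(0, "grid", [v.grid.render() if v.grid else "" for v in vectors])
    df.insert(0, "region", [v.region_name for v in vectors])
    df.insert(0, "label", [v.label if v.label is not None else "" for v in vectors])
    df.insert(0, "source_id", [v.source_id for v in vectors])
    df.to_csv(path, index=False)
    meta = {
        "n_entries": n,
        "grids": sorted({v.grid.render() for v in vectors if v.grid}),
        "regions": sorted({v.region_name for v in vectors}),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_features(path: str | Path) -> list[FeatureVector]:
    path = Path(path)
    df = pd.read_csv(path)
    value_cols = [c for c in df.columns if c.startswith("v_")]
    vectors: list[FeatureVector] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        grid_text = d.get("grid")
        grid = (
            BlockGrid.from_string(str(grid_text))
            if isinstance(grid_text, str) and grid_text
            else None
        )
        label = d.get("label")
        label = None if (label is None or (isinstance(label, float) and np.isnan(label)) or label == "") else str(label)
        region = d.get("region")
        region = "" if (region is None or (isinstance(region, float) and np.isnan(region))) else str(region)
        vectors.append(
            FeatureVector(
                np.array([d[c] for c in value_cols], dtype=np.float64),
                grid=grid,
                region_name=region,
                source_id=str(d.get("source_id", "")),
                label=label,
            )
        )
    return vectors
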