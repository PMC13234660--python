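"""Image I/O, category labels, and region crops.

The classifier consumes still RGB frames of a helium dielectric-barrier-
discharge plasma, one frame per injection, each tagged with a category
identifier of the form ``"<analyte>-<pressure>"`` (e.g. ``"AC-24"``:
acetone + n-pentane injected at a gas-chromatograph inlet pressure of
24 Psi).  Six VOC/VOC-mixture codes crossed with four inlet pressures give
24 VOC categories; pure-helium baseline frames form four more (``He-17`` …
``He-27``).

Frames are cropped to fixed rectangular regions before feature extraction:
region 1 is the full plasma area including the faint bottom reflection,
region 2 the central plasma observation window only, and region 3 the
bottom reflection band alone.  Region sizes are fixed; their offsets within
the original camera frame are configuration, since they depend on how the
camera was framed.

Conventions: 0-based, row-major, top-left origin, half-open crop
rectangles.  Pixel arrays are ``(H, W, 3)`` uint8; note that region sizes
are conventionally quoted width x height.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

__all__ = [
    "VOC_ANALYTES",
    "HELIUM_ANALYTE",
    "ANALYTES",
    "PRESSURES_PSI",
    "CategoryLabel",
    "parse_label",
    "render_label",
    "category_sort_key",
    "enumerate_categories",
    "LabeledImage",
    "RegionSpec",
    "crop",
    "full_extent",
    "read_image",
    "write_image",
    "label_from_filename",
    "read_manifest",
    "write_manifest",
    "load_split",
    "load_regions",
    "save_regions",
    "FULL_FRAME_REGIONS",
    "SYNTHETIC_REGIONS",
]

#: VOC analyte codes in canonical (publication-table column) order:
#: n-pentane, benzene, acetone, benzene+C5, acetone+C5, acetone+benzene.
VOC_ANALYTES: tuple[str, ...] = ("C", "B", "A", "BC", "AC", "AB")
HELIUM_ANALYTE: str = "He"
ANALYTES: tuple[str, ...] = VOC_ANALYTES + (HELIUM_ANALYTE,)
#: GC inlet pressures (Psi) at which each analyte was injected.
PRESSURES_PSI: tuple[int, ...] = (17, 20, 24, 27)

_LABEL_RE = re.compile(r"^([A-Za-z]+)-(\d+)$")


@dataclass(frozen=True)
class CategoryLabel:
    """A structured ``"<analyte>-<pressure>"`` category identifier."""

    analyte: str
    pressure_psi: int

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise ValueError(
                f"unknown analyte code {self.analyte!r}; expected one of {ANALYTES}"
            )
        if self.pressure_psi not in PRESSURES_PSI:
            raise ValueError(
                f"unknown pressure {self.pressure_psi!r} Psi; "
                f"expected one of {PRESSURES_PSI}"
            )

    def render(self) -> str:
        return f"{self.analyte}-{self.pressure_psi}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def parse_label(identifier: str) -> CategoryLabel:
    """Parse an identifier like ``"AC-24"`` into a :class:`CategoryLabel`.

    Raises :class:`ValueError` naming the offending part for malformed
    strings, unknown analyte codes, or unknown pressures.
    """
    m = _LABEL_RE.match(identifier.strip())
    if m is None:
        raise ValueError(
            f"malformed category identifier {identifier!r}; "
            'expected "<analyte>-<pressure>" such as "AC-24"'
        )
    code, pressure = m.group(1), int(m.group(2))
    if code not in ANALYTES:
        raise ValueError(f"unknown analyte code {code!r} in {identifier!r}")
    if pressure not in PRESSURES_PSI:
        raise ValueError(f"unknown pressure {pressure} Psi in {identifier!r}")
    return CategoryLabel(code, pressure)


def render_label(label: CategoryLabel) -> str:
    return label.render()


def category_sort_key(identifier: str) -> tuple:
    """Canonical ordering key: analyte table-column order, then ascending
    pressure.  Unparseable labels sort after all valid ones, lexically."""
    try:
        lab = parse_label(identifier)
    except ValueError:
        return (1, identifier, 0)
    return (0, ANALYTES.index(lab.analyte), lab.pressure_psi)


def enumerate_categories(
    analytes: Sequence[str] = VOC_ANALYTES,
    pressures: Sequence[int] = PRESSURES_PSI,
) -> list[CategoryLabel]:
    """Cartesian product of analytes and pressures in canonical order.

    Analytes keep the table column order; within an analyte, pressures
    ascend.  Rejects empty input sets.
    """
    if not analytes:
        raise ValueError("empty analyte set")
    if not pressures:
        raise ValueError("empty pressure set")
    ordered_codes = [a for a in ANALYTES if a in set(analytes)]
    unknown = set(analytes) - set(ANALYTES)
    if unknown:
        raise ValueError(f"unknown analyte codes: {sorted(unknown)}")
    return [
        CategoryLabel(a, p)
        for a in ordered_codes
        for p in sorted(pressures)
    ]


@dataclass
class LabeledImage:
    """An 8-bit RGB pixel array with an optional category label.

    ``pixels`` is ``(H, W, 3)`` uint8; ``label`` is the rendered category
    string or ``None`` for an unlabeled test image; ``source_id`` records
    provenance (normally the file name).
    """

    pixels: np.ndarray
    label: str | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(
                f"expected an (H, W, 3) RGB array, got shape {arr.shape}"
            )
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"degenerate image shape {arr.shape}")
        if arr.dtype != np.uint8:
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("channel values must lie within [0, 255]")
            arr = arr.astype(np.uint8)
        self.pixels = arr

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class RegionSpec:
    """A named crop rectangle in original-frame pixel coordinates."""

    name: str
    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError(
                f"region {self.name!r} has non-positive size "
                f"{self.width}x{self.height}"
            )
        if self.top < 0 or self.left < 0:
            raise ValueError(
                f"region {self.name!r} has negative offset ({self.top}, {self.left})"
            )


def crop(image: LabeledImage, region: RegionSpec) -> LabeledImage:
    """Extract ``region`` from ``image``, preserving label and pixel values.

    The crop must lie fully inside the source image; an out-of-bounds
    region raises :class:`ValueError` reporting the overflow.
    """
    bottom = region.top + region.height
    right = region.left + region.width
    if bottom > image.height or right > image.width:
        raise ValueError(
            f"region {region.name!r} exceeds image bounds: needs rows "
            f"[{region.top}, {bottom}) and cols [{region.left}, {right}) "
            f"inside a {image.height}x{image.width} image "
            f"(overflow: {max(0, bottom - image.height)} rows, "
            f"{max(0, right - image.width)} cols)"
        )
    sub = image.pixels[region.top:bottom, region.left:right].copy()
    return LabeledImage(sub, label=image.label,
                        source_id=f"{image.source_id}")


def full_extent(image: LabeledImage, name: str = "full") -> RegionSpec:
    """The region covering the whole image (identity crop)."""
    return RegionSpec(name, 0, 0, image.height, image.width)


# ---------------------------------------------------------------------------
# image file I/O

_GRAY_MODES = {"1", "L", "LA", "I", "I;16", "F"}


def read_image(path: str | Path, label: str | None = None,
               infer_label: bool = True) -> LabeledImage:
    """Read a PNG/JPEG image file into a :class:`LabeledImage`.

    Alpha channels are dropped; grayscale inputs are rejected (the method
    is defined on RGB).  JPEG inputs trigger a warning because lossy
    compression perturbs block means.  If ``label`` is None and
    ``infer_label`` is set, the label is taken from a
    ``"<label>_<replicate>"`` file-name stem when it parses.
    """
    path = Path(path)
    with Image.open(path) as im:
        if im.format == "JPEG":
            warnings.warn(
                f"{path.name}: JPEG compression may perturb block means; "
                "prefer lossless PNG",
                UserWarning,
                stacklevel=2,
            )
        if im.mode in _GRAY_MODES:
            raise ValueError(
                f"{path.name}: grayscale image (mode {im.mode!r}) rejected; "
                "the method is defined on RGB"
            )
        if im.mode != "RGB":
            im = im.convert("RGB")
        arr = np.asarray(im, dtype=np.uint8)
    if label is None and infer_label:
        label = label_from_filename(path.name)
    return LabeledImage(arr, label=label, source_id=path.name)


def write_image(image: LabeledImage, path: str | Path) -> Path:
    """Write pixels to a (lossless) PNG file; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(image.pixels, mode="RGB").save(path)
    return path


def label_from_filename(name: str) -> str | None:
    """Extract the category label from a ``"<label>_<replicate>.png"`` file
    name; returns None if the stem does not carry a valid label."""
    stem = Path(name).stem
    candidate = stem.split("_")[0]
    try:
        return parse_label(candidate).render()
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# manifests

MANIFEST_COLUMNS = ("source_id", "label", "split")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a dataset manifest CSV with columns (source_id, label, split)."""
    df = pd.read_csv(path, dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns {sorted(missing)}")
    bad = set(df["split"].unique()) - {"train", "test"}
    if bad:
        raise ValueError(f"manifest split values must be train/test, got {sorted(bad)}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def load_split(manifest: pd.DataFrame, images_dir: str | Path
               ) -> tuple[list[LabeledImage], list[LabeledImage]]:
    """Load (train, test) image lists named by a manifest.

    Manifest labels override any label inferred from file names.
    """
    images_dir = Path(images_dir)
    out: dict[str, list[LabeledImage]] = {"train": [], "test": []}
    for row in manifest.itertuples(index=False):
        img = read_image(images_dir / row.source_id, label=row.label,
                         infer_label=False)
        out[row.split].append(img)
    return out["train"], out["test"]


# ---------------------------------------------------------------------------
# region configuration

def load_regions(path: str | Path) -> dict[str, RegionSpec]:
    """Load a YAML/JSON list of region entries into a name->spec mapping."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    if not isinstance(entries, list):
        raise ValueError(f"region config {path} must be a list of entries")
    regions: dict[str, RegionSpec] = {}
    for e in entries:
        spec = RegionSpec(
            name=str(e["name"]),
            top=int(e["top"]),
            left=int(e["left"]),
            height=int(e["height"]),
            width=int(e["width"]),
        )
        regions[spec.name] = spec
    return regions


def save_regions(regions: dict[str, RegionSpec], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    entries = [
        {"name": r.name, "top": r.top, "left": r.left,
         "height": r.height, "width": r.width}
        for r in regions.values()
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)
    return path


# Default crops for the original 1080x1920 portrait phone frame.  Sizes are
# fixed by the acquisition protocol (quoted width x height: region 1
# 1080x1350, region 2 360x324, region 3 540x400); the offsets below center
# region 1 vertically in the frame, region 2 on the plasma window, and
# region 3 on the bottom reflection band, and are configuration.
FULL_FRAME_REGIONS: dict[str, RegionSpec] = {
    "region1": RegionSpec("region1", top=285, left=0, height=1350, width=1080),
    "region2": RegionSpec("region2", top=798, left=360, height=324, width=360),
    "region3": RegionSpec("region3", top=1235, left=270, height=400, width=540),
}

# Analogous crops for the 216x270 synthetic canvas (1/5 of region 1).
# Region 2 uses 70x63 so the 10x9 grid divides it exactly.
SYNTHETIC_REGIONS: dict[str, RegionSpec] = {
    "region1": RegionSpec("region1", top=0, left=0, height=270, width=216),
    "region2": RegionSpec("region2", top=77, left=73, height=63, width=70),
    "region3": RegionSpec("region3", top=190, left=54, height=80, width=108),
}
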