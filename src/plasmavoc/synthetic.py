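"""Seeded synthetic plasma-image generator.

Emulates the visual structure of helium-plasma frames recorded during VOC
injection: a dark background, a bright central plasma area made of one or
two vertical light columns with a category-specific hue, a deterministic
hue shift with GC inlet pressure, a faint blurred reflection band at the
bottom of the frame, and i.i.d. per-replicate Gaussian pixel noise.  Every
image is a deterministic function of (config, label, seed), so full
datasets regenerate byte-for-byte.

The default canvas is 216x270 (width x height), an exact 1/5 scale of the
1080x1350 region-1 crop, so the block grids used at full scale all have
exact small-integer analogues.

Two deliberate study conditions are built into the default VOC
configuration:

* the analyte pairs (C, BC) and (A, AB) share hue and total luminous flux
  but differ in column layout.  Their whole-image mean colors therefore
  coincide, so the 1x1 (whole-image) grid cannot separate them under a
  cosine classifier, while any segmented grid separates them by tens of
  channel units — segmentation is what rescues classification;
* a helium configuration with a 10x smaller noise scale, whose
  within-category similarity spread is correspondingly orders of magnitude
  tighter than the VOC set's.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import (
    PRESSURES_PSI,
    CategoryLabel,
    LabeledImage,
    parse_label,
    write_image,
    write_manifest,
)

__all__ = [
    "CategorySpec",
    "SyntheticConfig",
    "default_voc_config",
    "helium_config",
    "render_noiseless",
    "generate_image",
    "SyntheticDataset",
    "generate_dataset",
]


@dataclass(frozen=True)
class CategorySpec:
    """One analyte's appearance: base hue and vertical-column layout.

    ``base_rgb`` is the emission hue (scaled by the spatial intensity
    field, so entries may exceed 255 as long as rendered pixels stay in
    range).  ``column_centers`` are horizontal positions as fractions of
    the canvas width; ``column_sigma`` is the Gaussian column width as a
    width fraction; ``amplitude`` is the total peak intensity, split
    equally over the columns so that total flux is independent of the
    column count.
    """

    analyte: str
    base_rgb: tuple[float, float, float]
    column_centers: tuple[float, ...] = (0.5,)
    column_sigma: float = 0.055
    amplitude: float = 0.9

    def __post_init__(self) -> None:
        if not 1 <= len(self.column_centers) <= 2:
            raise ValueError(
                f"{self.analyte}: expected 1 or 2 light columns, "
                f"got {len(self.column_centers)}"
            )
        if self.column_sigma <= 0 or not 0 < self.amplitude <= 1:
            raise ValueError(f"{self.analyte}: invalid column profile parameters")

    @property
    def n_columns(self) -> int:
        return len(self.column_centers)


@dataclass
class SyntheticConfig:
    """Full recipe for a synthetic dataset.

    Geometry defaults to the 216x270 desk-scale canvas; the plasma sits in
    the upper-central area (vertical Gaussian envelope) and the reflection
    band near the bottom.  ``pressure_shift_rgb`` is the additive hue shift
    per pressure step above 17 Psi.  ``mean_matched_pairs`` declares
    analyte pairs that intentionally share hue and flux (exempt from the
    color-separation check; must differ in column layout instead).
    """

    categories: list[CategorySpec]
    width: int = 216
    height: int = 270
    pressures: tuple[int, ...] = PRESSURES_PSI
    pressure_shift_rgb: tuple[float, float, float] = (7.0, 2.0, -6.0)
    background_level: float = 10.0
    plasma_center_frac: float = 0.40
    plasma_sigma_frac: float = 0.12
    reflection_center_frac: float = 0.90
    reflection_sigma_frac: float = 0.05
    reflection_scale: float = 0.15
    reflection_blur_px: float = 2.0
    noise_sigma: float = 2.0
    train_replicates: int = 5
    test_replicates: int = 1
    min_color_separation: float = 40.0
    mean_matched_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 <= self.reflection_scale < 1:
            raise ValueError("reflection_scale must lie in [0, 1)")
        if self.train_replicates < 1 or self.test_replicates < 1:
            raise ValueError("need at least one replicate per split")
        seen = set()
        for c in self.categories:
            if c.analyte in seen:
                raise ValueError(f"duplicate analyte spec {c.analyte!r}")
            seen.add(c.analyte)
        self._check_separation()

    def _check_separation(self) -> None:
        matched = {frozenset(p) for p in self.mean_matched_pairs}
        for pair in matched:
            a, b = sorted(pair)
            ca, cb = self.category(a), self.category(b)
            if ca.base_rgb != cb.base_rgb or ca.amplitude != cb.amplitude \
                    or ca.column_sigma != cb.column_sigma:
                raise ValueError(
                    f"mean-matched pair ({a}, {b}) must share hue, amplitude "
                    "and column width to have equal whole-image mean color"
                )
            if ca.column_centers == cb.column_centers:
                raise ValueError(
                    f"mean-matched pair ({a}, {b}) must differ in column "
                    "layout or the categories are indistinguishable"
                )
        for i, ca in enumerate(self.categories):
            for cb in self.categories[i + 1:]:
                if frozenset((ca.analyte, cb.analyte)) in matched:
                    continue
                d = float(np.linalg.norm(
                    np.subtract(ca.base_rgb, cb.base_rgb)))
                if d < self.min_color_separation:
                    raise ValueError(
                        f"base colors of ({ca.analyte}, {cb.analyte}) are only "
                        f"{d:.1f} channel units apart "
                        f"(minimum {self.min_color_separation}); separation "
                        "constraint violated"
                    )

    def category(self, analyte: str) -> CategorySpec:
        for c in self.categories:
            if c.analyte == analyte:
                return c
        raise KeyError(f"analyte {analyte!r} not in config")

    def labels(self) -> list[CategoryLabel]:
        """All category labels of this config, canonical order."""
        return [
            CategoryLabel(c.analyte, p)
            for c in self.categories
            for p in sorted(self.pressures)
        ]

    def matched_partner(self, analyte: str) -> str | None:
        """The analyte whose whole-image mean color this one shares."""
        for a, b in self.mean_matched_pairs:
            if analyte == a:
                return b
            if analyte == b:
                return a
        return None


def default_voc_config(**overrides) -> SyntheticConfig:
    """The 24-category VOC study condition.

    Six analyte codes x four pressures; hues pairwise separated by at
    least 40 channel units except the deliberate (C, BC) and (A, AB)
    matches; pixel noise sigma 2; 5 training + 1 test replicate per
    category.  Column layouts follow the observed morphology: benzene and
    benzene-containing mixtures light two columns, the others one.
    """
    categories = [
        CategorySpec("C", (70.0, 120.0, 235.0), (0.42,), 0.055),
        CategorySpec("B", (120.0, 235.0, 120.0), (0.38, 0.62), 0.045),
        CategorySpec("A", (235.0, 140.0, 60.0), (0.58,), 0.060),
        CategorySpec("BC", (70.0, 120.0, 235.0), (0.33, 0.67), 0.055),
        CategorySpec("AC", (210.0, 70.0, 210.0), (0.5,), 0.050),
        CategorySpec("AB", (235.0, 140.0, 60.0), (0.35, 0.70), 0.060),
    ]
    kwargs = dict(
        categories=categories,
        mean_matched_pairs=(("C", "BC"), ("A", "AB")),
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


def helium_config(**overrides) -> SyntheticConfig:
    """The pure-helium baseline condition: one lilac analyte whose hue
    drifts toward white with pressure, 10x tighter pixel noise, 6 training
    + 1 test replicate per pressure."""
    kwargs = dict(
        categories=[CategorySpec("He", (205.0, 185.0, 225.0), (0.5,), 0.055)],
        pressure_shift_rgb=(8.0, 12.0, 5.0),
        noise_sigma=0.2,
        train_replicates=6,
        test_replicates=1,
        min_color_separation=0.0,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


def _as_label(config: SyntheticConfig, label: CategoryLabel | str) -> CategoryLabel:
    lab = parse_label(label) if isinstance(label, str) else label
    config.category(lab.analyte)  # raises KeyError for unknown analytes
    if lab.pressure_psi not in config.pressures:
        raise KeyError(f"pressure {lab.pressure_psi} Psi not in config")
    return lab


def render_noiseless(config: SyntheticConfig,
                     label: CategoryLabel | str) -> np.ndarray:
    """The deterministic (float, unquantized) rendering of one category.

    Returns an (H, W, 3) float array in [0, 255]; the noisy generator adds
    Gaussian noise to exactly this field before quantization.
    """
    lab = _as_label(config, label)
    spec = config.category(lab.analyte)
    H, W = config.height, config.width
    x = np.arange(W, dtype=np.float64)
    y = np.arange(H, dtype=np.float64)

    sig_x = spec.column_sigma * W
    prof_x = np.zeros(W)
    for c in spec.column_centers:
        prof_x += (spec.amplitude / spec.n_columns) * np.exp(
            -0.5 * ((x - c * W) / sig_x) ** 2
        )

    env_plasma = np.exp(
        -0.5 * ((y - config.plasma_center_frac * H)
                / (config.plasma_sigma_frac * H)) ** 2
    )
    env_refl = config.reflection_scale * np.exp(
        -0.5 * ((y - config.reflection_center_frac * H)
                / (config.reflection_sigma_frac * H)) ** 2
    )
    intensity = np.outer(env_plasma, prof_x)
    if config.reflection_scale > 0:
        refl = np.outer(env_refl, prof_x)
        if config.reflection_blur_px > 0:
            refl = ndimage.gaussian_filter(
                refl, sigma=config.reflection_blur_px, mode="reflect"
            )
        intensity = intensity + refl

    step = sorted(config.pressures).index(lab.pressure_psi)
    hue = np.asarray(spec.base_rgb, dtype=np.float64) + step * np.asarray(
        config.pressure_shift_rgb, dtype=np.float64
    )
    field = config.background_level + intensity[:, :, None] * hue[None, None, :]
    return np.clip(field, 0.0, 255.0)


def generate_image(config: SyntheticConfig, label: CategoryLabel | str,
                   rng: np.random.Generator | int) -> LabeledImage:
    """One synthetic replicate: noiseless rendering + Gaussian pixel noise,
    clipped to [0, 255] and quantized to 8 bits."""
    lab = _as_label(config, label)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    field = render_noiseless(config, lab)
    if config.noise_sigma > 0:
        field = field + rng.normal(0.0, config.noise_sigma, field.shape)
    pixels = np.clip(np.rint(field), 0, 255).astype(np.uint8)
    return LabeledImage(pixels, label=lab.render(), source_id="")


@dataclass
class SyntheticDataset:
    train: list[LabeledImage]
    test: list[LabeledImage]
    manifest: pd.DataFrame


def generate_dataset(config: SyntheticConfig, seed: int,
                     out_dir: str | Path | None = None) -> SyntheticDataset:
    """Generate the full replicate set for every category in ``config``.

    The default split mimics the acquisition protocol: one test image per
    category, the remaining replicates as training data.  Identical
    (config, seed) pairs regenerate identical datasets byte-for-byte.
    When ``out_dir`` is given, images are written as
    ``"<label>_<replicate>.png"`` plus a ``manifest.csv``.
    """
    labels = config.labels()
    n_rep = config.train_replicates + config.test_replicates
    per_label = np.random.SeedSequence(seed).spawn(len(labels))
    train: list[LabeledImage] = []
    test: list[LabeledImage] = []
    rows = []
    for lab, seq in zip(labels, per_label):
        for r, child in enumerate(seq.spawn(n_rep)):
            img = generate_image(config, lab, np.random.default_rng(child))
            img.source_id = f"{lab.render()}_{r:02d}.png"
            split = "train" if r < config.train_replicates else "test"
            (train if split == "train" else test).append(img)
            rows.append((img.source_id, lab.render(), split))
    manifest = pd.DataFrame(rows, columns=["source_id", "label", "split"])
    if out_dir is not None:
        out_dir = Path(out_dir)
        for img in train + test:
            write_image(img, out_dir / img.source_id)
        write_manifest(manifest, out_dir / "manifest.csv")
    return SyntheticDataset(train=train, test=test, manifest=manifest)
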