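"""Block-count sweep orchestration.

Reproduces the structure of the accuracy-vs-segmentation experiment: for
each region crop and each block grid, featurize the training and test
images, fit per-category centroids, classify the test set, and record one
table row (region, grid, block count, block size, accuracy, wall time,
misclassifications).  Accuracy and misclassification columns are
deterministic given the inputs; the time column is hardware noise and is
reported but never asserted on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .classifier import concat_features, evaluate, fit_centroids
from .features import BlockGrid, featurize
from .images import (
    FULL_FRAME_REGIONS,
    SYNTHETIC_REGIONS,
    LabeledImage,
    RegionSpec,
    crop,
    load_split,
    read_manifest,
)

__all__ = [
    "ConcatCombo",
    "SweepSpec",
    "synthetic_sweep",
    "table2_sweep",
    "run_sweep",
    "load_sweep_inputs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConcatCombo:
    """A concatenated-feature test: (region_a @ grid_a) + (region_b @ grid_b)."""

    region_a: str
    grid_a: BlockGrid
    region_b: str
    grid_b: BlockGrid

    @property
    def name(self) -> str:
        return (f"{self.region_a}({self.grid_a.render()})+"
                f"{self.region_b}({self.grid_b.render()})")


@dataclass
class SweepSpec:
    """Regions, per-region grid schedules, and optional concat combos."""

    regions: dict[str, RegionSpec]
    grids: dict[str, list[BlockGrid]]
    concat: list[ConcatCombo] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, grid_list in self.grids.items():
            if name not in self.regions:
                raise ValueError(f"grids given for unknown region {name!r}")
            if not grid_list:
                raise ValueError(f"empty grid list for region {name!r}")
            region = self.regions[name]
            for g in grid_list:
                if region.width % g.n_w or region.height % g.n_h:
                    raise ValueError(
                        f"grid {g.render()} does not divide region "
                        f"{name!r} ({region.width}x{region.height})"
                    )
        if not self.grids:
            raise ValueError("sweep needs at least one region with grids")
        for combo in self.concat:
            for rname in (combo.region_a, combo.region_b):
                if rname not in self.regions:
                    raise ValueError(
                        f"concat combo references unknown region {rname!r}"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path,
                  base_regions: dict[str, RegionSpec] | None = None
                  ) -> "SweepSpec":
        """Load a sweep from YAML.

        Layout::

            regions:            # optional when base_regions given
              region1: {top: 0, left: 0, height: 270, width: 216}
            grids:
              region1: [1x1, 4x5, 8x10]
            concat:
              - [region2, 10x9, region3, 27x20]
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        regions = dict(base_regions or {})
        for name, r in (raw.get("regions") or {}).items():
            regions[name] = RegionSpec(name=name, top=int(r["top"]),
                                       left=int(r["left"]),
                                       height=int(r["height"]),
                                       width=int(r["width"]))
        grids = {
            name: [BlockGrid.from_string(str(g)) for g in gl]
            for name, gl in (raw.get("grids") or {}).items()
        }
        concat = [
            ConcatCombo(str(c[0]), BlockGrid.from_string(str(c[1])),
                        str(c[2]), BlockGrid.from_string(str(c[3])))
            for c in (raw.get("concat") or [])
        ]
        return cls(regions=regions, grids=grids, concat=concat)


def _grids(*texts: str) -> list[BlockGrid]:
    return [BlockGrid.from_string(t) for t in texts]


def synthetic_sweep() -> SweepSpec:
    """Default sweep for the 216x270 synthetic canvas: the desk-scale
    analogues of the published grid schedule."""
    return SweepSpec(
        regions=dict(SYNTHETIC_REGIONS),
        grids={
            "region1": _grids("1x1", "4x5", "8x10", "12x15", "24x30"),
            "region2": _grids("1x1", "10x9", "35x21", "70x63"),
            "region3": _grids("1x1", "27x20", "54x40", "108x80"),
        },
        concat=[ConcatCombo("region2", BlockGrid(10, 9),
                            "region3", BlockGrid(27, 20))],
    )


def table2_sweep() -> SweepSpec:
    """The full published grid schedule for real full-frame images
    (region 1 1080x1350, region 2 360x324, region 3 540x400).

    Optional path: requires the deposited plasma-image dataset; the finest
    grids run one block per pixel and are slow at full scale.
    """
    return SweepSpec(
        regions=dict(FULL_FRAME_REGIONS),
        grids={
            "region1": _grids(
                "1x1", "4x5", "8x10", "12x15", "20x25", "24x30", "36x45",
                "40x50", "60x75", "72x90", "108x135", "120x150", "180x225",
                "216x270", "360x450", "540x675", "1080x1350",
            ),
            "region2": _grids(
                "1x1", "10x9", "20x18", "30x27", "40x36", "60x54", "90x81",
                "120x108", "180x162", "360x324",
            ),
            "region3": _grids(
                "1x1", "27x20", "54x40", "108x80", "135x100", "270x200",
                "540x400",
            ),
        },
        concat=[ConcatCombo("region2", BlockGrid(10, 9),
                            "region3", BlockGrid(27, 20))],
    )


def load_sweep_inputs(manifest_path: str | Path, images_dir: str | Path
                      ) -> tuple[list[LabeledImage], list[LabeledImage]]:
    """Resolve a manifest CSV into (train, test) image lists."""
    manifest = read_manifest(manifest_path)
    return load_split(manifest, images_dir)


def _evaluate_features(train_feats, test_feats):
    model = fit_centroids(train_feats)
    return evaluate(test_feats, model)


def run_sweep(spec: SweepSpec, train: Sequence[LabeledImage],
              test: Sequence[LabeledImage]) -> pd.DataFrame:
    """Run the full accuracy-vs-block-count sweep.

    ``train``/``test`` are full-frame labeled images; every region of the
    spec is cropped from them.  Returns one row per (region, grid) plus
    one per concat combo, sorted by ascending block count within each
    region.  Columns: region, grid, n_blocks, block_w, block_h,
    accuracy, accuracy_pct, time_s, misidentified, predicted.
    """
    if not train or not test:
        raise ValueError("sweep needs nonempty train and test image sets")
    rows = []
    crops_cache: dict[str, tuple[list[LabeledImage], list[LabeledImage]]] = {}

    def cropped(name: str):
        if name not in crops_cache:
            region = spec.regions[name]
            crops_cache[name] = (
                [crop(im, region) for im in train],
                [crop(im, region) for im in test],
            )
        return crops_cache[name]

    for rname in spec.grids:
        region = spec.regions[rname]
        tr_imgs, te_imgs = cropped(rname)
        for grid in sorted(spec.grids[rname], key=lambda g: g.n_blocks):
            tr = [featurize(im, grid, region_name=rname) for im in tr_imgs]
            te = [featurize(im, grid, region_name=rname) for im in te_imgs]
            report = _evaluate_features(tr, te)
            logger.info(
                "sweep %s grid %s: n_blocks=%d accuracy=%.1f%% (%d/%d)",
                rname, grid.render(), grid.n_blocks,
                report.accuracy_percent, report.n_correct, report.n_test,
            )
            rows.append({
                "region": rname,
                "grid": grid.render(),
                "n_blocks": grid.n_blocks,
                "block_w": region.width // grid.n_w,
                "block_h": region.height // grid.n_h,
                "accuracy": report.accuracy,
                "accuracy_pct": report.accuracy_percent,
                "time_s": report.wall_time_s,
                "misidentified": ";".join(
                    m.source_id for m in report.misclassified),
                "predicted": ";".join(
                    m.predicted_label for m in report.misclassified),
            })

    for combo in spec.concat:
        tr_a, te_a = cropped(combo.region_a)
        tr_b, te_b = cropped(combo.region_b)
        def _concat_set(imgs_a, imgs_b, grid_a, grid_b, ra, rb):
            return [
                concat_features(
                    featurize(ia, grid_a, region_name=ra),
                    featurize(ib, grid_b, region_name=rb),
                )
                for ia, ib in zip(imgs_a, imgs_b)
            ]
        tr = _concat_set(tr_a, tr_b, combo.grid_a, combo.grid_b,
                         combo.region_a, combo.region_b)
        te = _concat_set(te_a, te_b, combo.grid_a, combo.grid_b,
                         combo.region_a, combo.region_b)
        report = _evaluate_features(tr, te)
        n_blocks = combo.grid_a.n_blocks + combo.grid_b.n_blocks
        logger.info("sweep %s: accuracy=%.1f%%", combo.name,
                    report.accuracy_percent)
        rows.append({
            "region": combo.name,
            "grid": f"{combo.grid_a.render()}+{combo.grid_b.render()}",
            "n_blocks": n_blocks,
            "block_w": pd.NA,
            "block_h": pd.NA,
            "accuracy": report.accuracy,
            "accuracy_pct": report.accuracy_percent,
            "time_s": report.wall_time_s,
            "misidentified": ";".join(
                m.source_id for m in report.misclassified),
            "predicted": ";".join(
                m.predicted_label for m in report.misclassified),
        })
    return pd.DataFrame(rows)
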