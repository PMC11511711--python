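"""File I/O and configuration for the morphometry pipeline.

Images travel as plain 2-D grayscale TIFFs (8- or 16-bit); masks as
single-bit TIFFs; fiber networks as JSON (fiber id → vertex list plus
cross-link coordinates); feature and summary tables as UTF-8 CSV.  The
physical pixel size comes from the configuration — TIFF resolution tags
are consulted only when the configuration omits it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .features import FEATURE_NAMES, FeatureSet
from .network import FiberNetwork
from .segmentation import BinaryMask, SHGImage, DEFAULT_PIXEL_SIZE_UM

__all__ = [
    "UnsupportedImageError",
    "PipelineConfig",
    "configure_logging",
    "read_image",
    "write_image",
    "write_mask",
    "read_mask",
    "network_to_json",
    "write_network",
    "feature_row",
    "write_feature_table",
]

logger = logging.getLogger("shgmorph")

CSV_COLUMNS = ("specimen", "group", "roi", "region") + FEATURE_NAMES


class UnsupportedImageError(ValueError):
    """Input TIFF is not a single-page 2-D grayscale image."""


def configure_logging(verbosity: int = 0) -> None:
    """0 = warnings only, 1 = info, 2+ = debug."""
    level = logging.WARNING if verbosity <= 0 else (
        logging.INFO if verbosity == 1 else logging.DEBUG
    )
    logging.basicConfig(format="%(levelname)s %(name)s: %(message)s")
    logger.setLevel(level)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the end-to-end run needs, loadable from YAML.

    ``inputs`` maps each group label to the image paths (or globs)
    belonging to it; every TIFF is treated as one ROI of one specimen
    (specimen id = file stem).
    """

    inputs: dict[str, list[str]] = field(default_factory=dict)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    seg_tol: float = 1e-6
    seg_max_iter: int = 500
    min_len_px: float = 5.0
    max_turn_deg: float = 60.0
    simplify_tol_px: float = 0.75
    region_size_um: float = 150.0
    n_regions: int = 6
    unit: str = "region"
    posthoc: bool = True
    out_dir: str = "shgmorph_out"
    seed: int = 0
    verbosity: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _pixel_size_from_tiff(path: Path) -> float | None:
    """Pixel pitch (μm) from TIFF resolution tags, if present and sane."""
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if xres is None:
                return None
            num, den = xres.value
            per_unit = float(Fraction(int(num), int(den)))
            if per_unit <= 0:
                return None
            unit_um = {2: 25_400.0, 3: 10_000.0}.get(
                getattr(unit, "value", None) and int(unit.value)
            )
            if unit_um is None:
                return None
            return unit_um / per_unit
    except Exception:  # malformed tags: fall back to config
        return None


def read_image(path: str | Path, pixel_size_um: float | None = None) -> SHGImage:
    """Load a 2-D grayscale TIFF as floating intensities.

    ``pixel_size_um`` (from the configuration) wins over TIFF metadata;
    RGB or multi-page files are rejected explicitly.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim != 2:
        raise UnsupportedImageError(
            f"{path.name}: expected a single-page 2-D grayscale TIFF, "
            f"got shape {data.shape} (RGB/multi-page unsupported)"
        )
    if pixel_size_um is None:
        pixel_size_um = _pixel_size_from_tiff(path)
    if pixel_size_um is None:
        raise UnsupportedImageError(
            f"{path.name}: pixel size missing from both config and TIFF tags"
        )
    return SHGImage(pixels=data.astype(float), pixel_size_um=pixel_size_um)


def write_image(path: str | Path, image: SHGImage, dtype: str = "uint16") -> None:
    """Write intensities as an 8- or 16-bit grayscale TIFF (values clipped
    and rounded to the target range)."""
    info = np.iinfo(dtype)
    data = np.clip(np.round(image.pixels), info.min, info.max).astype(dtype)
    tifffile.imwrite(path, data)


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    tifffile.imwrite(path, mask.labels)


def read_mask(path: str | Path, pixel_size_um: float) -> BinaryMask:
    data = tifffile.imread(path)
    if data.ndim != 2:
        raise UnsupportedImageError(f"{path}: mask must be 2-D")
    return BinaryMask(labels=data.astype(bool), pixel_size_um=pixel_size_um)


def network_to_json(network: FiberNetwork) -> dict:
    return {
        "pixel_size_um": network.pixel_size_um,
        "fibers": {
            str(f.id): [[float(r), float(c)] for r, c in f.vertices]
            for f in network.fibers
        },
        "crosslinks": sorted([int(r), int(c)] for r, c in network.crosslinks),
    }


def write_network(path: str | Path, network: FiberNetwork) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_json(network), fh)


def feature_row(
    specimen: str, group: str, roi: int, region: int, features: FeatureSet
) -> dict:
    row = {"specimen": specimen, "group": group, "roi": roi, "region": region}
    row.update(features.as_dict())
    return row


def write_feature_table(path: str | Path, rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    df.to_csv(path, index=False, encoding="utf-8")
    return df
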