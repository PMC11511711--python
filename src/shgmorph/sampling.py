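"""Region-of-interest geometry: random interception of interstitial
sub-regions from a larger ROI.

The quantification protocol marks ~2.2 × 2.2 mm ROIs and randomly crops
several non-overlapping 150 × 150 μm interstitial regions from each.
Pixels that must not be sampled (e.g. glands) can be barred with an
exclusion mask; gland detection itself is out of scope and the mask is
supplied by the user.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import SHGImage

__all__ = ["RegionSpec", "RegionPlacementError", "sample_regions"]

_MAX_ATTEMPTS = 10_000


class RegionPlacementError(RuntimeError):
    """Could not place the requested number of non-overlapping regions."""

    def __init__(self, placed: int, requested: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"placed only {placed} of {requested} non-overlapping regions "
            f"within {_MAX_ATTEMPTS} attempts"
        )


@dataclass(frozen=True)
class RegionSpec:
    """Geometry of the random region interception."""

    roi_size_um: float = 2200.0
    region_size_um: float = 150.0
    n_regions: int = 6
    seed: int = 0
    exclusion_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.region_size_um > self.roi_size_um:
            raise ValueError("region must not exceed the ROI")
        if self.n_regions < 1:
            raise ValueError("n_regions must be at least 1")


def sample_regions(
    image: SHGImage, spec: RegionSpec
) -> list[tuple[SHGImage, tuple[int, int]]]:
    """Randomly intercept ``n_regions`` pairwise non-overlapping square
    crops, uniformly by rejection sampling.

    Returns (sub-image, (row0, col0)) pairs; crop coordinates are 0-based
    and half-open.  Crops avoid any pixel set in ``spec.exclusion_mask``.
    """
    side = int(round(spec.region_size_um / image.pixel_size_um))
    h, w = image.shape
    if h < side or w < side:
        raise ValueError(
            f"image ({h}x{w}) smaller than one {side}-px region"
        )
    excl = spec.exclusion_mask
    if excl is not None and excl.shape != image.shape:
        raise ValueError("exclusion mask shape differs from image")
    rng = np.random.default_rng(spec.seed)
    placed: list[tuple[int, int]] = []
    best: list[tuple[int, int]] = []
    attempts = 0
    while len(placed) < spec.n_regions:
        if attempts >= _MAX_ATTEMPTS:
            raise RegionPlacementError(max(len(placed), len(best)),
                                       spec.n_regions)
        if attempts and attempts % 1000 == 0:
            # an unlucky early crop can block every later one; restart
            if len(placed) > len(best):
                best = list(placed)
            placed = []
        attempts += 1
        r0 = int(rng.integers(0, h - side + 1))
        c0 = int(rng.integers(0, w - side + 1))
        if any(
            abs(r0 - r) < side and abs(c0 - c) < side for r, c in placed
        ):
            continue
        if excl is not None and excl[r0 : r0 + side, c0 : c0 + side].any():
            continue
        placed.append((r0, c0))
    return [
        (
            SHGImage(
                pixels=image.pixels[r0 : r0 + side, c0 : c0 + side],
                pixel_size_um=image.pixel_size_um,
            ),
            (r0, c0),
        )
        for r0, c0 in placed
    ]
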