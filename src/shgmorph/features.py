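"""The eight collagen morphological features.

For one interstitial region, the features are

====================  =========  =================================================
feature               units      definition
====================  =========  =================================================
area_pct              %          collagen pixels / all pixels × 100
number_per_um2        1/μm²      extracted fibers per μm² of region
length_um             μm         mean fiber arclength (sum of inter-vertex steps)
width_um              μm         mean vertex-to-nearest-background distance
straightness          —          mean chord/arclength ratio per fiber, in (0, 1]
xlink_density_per_um  1/μm       cross-link points per μm of total fiber length
xlink_space_um        μm         mean along-fiber spacing of adjacent cross-links
orientation_index     —          1 − short/long axis of the FFT power spectrum
====================  =========  =================================================

Width is a radius-like quantity — the distance from a skeleton vertex to
the nearest background pixel — not a diameter.  The orientation index is
computed on the binary mask: 0 for isotropic fiber arrangements, 1 for
perfect alignment.  Fiber-level features are averaged over the fibers of a
region; features undefined for a region (e.g. cross-link spacing when no
fiber carries two cross-links) are reported as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as _dc_fields

import numpy as np
from scipy.ndimage import distance_transform_edt

from .network import Fiber, FiberNetwork
from .segmentation import BinaryMask, SHGImage

__all__ = [
    "FeatureSet",
    "FEATURE_NAMES",
    "proportionate_area",
    "fiber_number_density",
    "fiber_length",
    "fiber_width",
    "fiber_straightness",
    "crosslink_density",
    "crosslink_space",
    "orientation_index",
    "compute_feature_set",
]

FEATURE_NAMES = (
    "area_pct",
    "number_per_um2",
    "length_um",
    "width_um",
    "straightness",
    "xlink_density_per_um",
    "xlink_space_um",
    "orientation_index",
)


@dataclass(frozen=True)
class FeatureSet:
    """The eight scalar morphological features of one region (NaN where
    undefined)."""

    area_pct: float
    number_per_um2: float
    length_um: float
    width_um: float
    straightness: float
    xlink_density_per_um: float
    xlink_space_um: float
    orientation_index: float

    def __post_init__(self) -> None:
        if np.isfinite(self.area_pct) and not 0.0 <= self.area_pct <= 100.0:
            raise ValueError("area_pct must lie in [0, 100]")
        if np.isfinite(self.straightness) and not 0.0 < self.straightness <= 1.0:
            raise ValueError("straightness must lie in (0, 1]")
        if np.isfinite(self.orientation_index) and not (
            0.0 <= self.orientation_index <= 1.0
        ):
            raise ValueError("orientation_index must lie in [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in _dc_fields(self)}


def proportionate_area(mask: BinaryMask) -> float:
    """Percentage of collagen pixels in the segmented image."""
    return 100.0 * float(mask.labels.sum()) / mask.labels.size


def fiber_number_density(network: FiberNetwork, region_area_um2: float) -> float:
    """Extracted fibers per square micron of region."""
    if not region_area_um2 > 0:
        raise ValueError("region_area_um2 must be positive")
    return network.n_fibers / region_area_um2


def fiber_length(fiber: Fiber, pixel_size_um: float) -> float:
    """Fiber arclength: the sum of Euclidean distances between adjacent
    vertices, in μm."""
    if fiber.n_vertices < 2:
        raise ValueError("fiber length requires at least 2 vertices")
    return fiber.length_px * pixel_size_um


def _densify(vertices: np.ndarray, step_px: float = 1.0) -> np.ndarray:
    """Points at <= step_px arclength spacing along a polyline (keeps the
    original vertices)."""
    pts = [vertices[:1]]
    for a, b in zip(vertices[:-1], vertices[1:]):
        d = float(np.linalg.norm(b - a))
        n = max(int(np.ceil(d / step_px)), 1)
        t = np.linspace(0.0, 1.0, n + 1)[1:, None]
        pts.append(a + t * (b - a))
    return np.vstack(pts)


def fiber_width(fiber: Fiber, mask: BinaryMask, pixel_size_um: float,
                _edt: np.ndarray | None = None) -> float:
    """Mean distance from the fiber's skeleton to its nearest background
    pixel (exact Euclidean distance transform), in μm.

    Width is a property of the whole fiber path, so the vertex polyline is
    densified to <= 1 px arclength spacing before sampling the distance
    transform — otherwise sparse vertex chains would weight fiber ends
    (where clearance shrinks into the tip) disproportionately.
    """
    if not (~mask.labels).any():
        raise ValueError("width is undefined on a fully-foreground mask")
    edt = distance_transform_edt(mask.labels) if _edt is None else _edt
    vr = np.round(fiber.vertices[:, 0]).astype(int)
    vc = np.round(fiber.vertices[:, 1]).astype(int)
    if (edt[vr, vc] == 0).any():
        raise ValueError("fiber vertex lies on a background pixel")
    pts = _densify(fiber.vertices)
    rows = np.clip(np.round(pts[:, 0]).astype(int), 0, mask.shape[0] - 1)
    cols = np.clip(np.round(pts[:, 1]).astype(int), 0, mask.shape[1] - 1)
    d = edt[rows, cols]
    d = d[d > 0]  # interpolated samples may graze background at junctions
    return float(d.mean()) * pixel_size_um


def fiber_straightness(fiber: Fiber) -> float:
    """Chord between first and last vertices divided by arclength."""
    arc = fiber.length_px
    if arc <= 0:
        raise ValueError("straightness is undefined for zero-length fibers")
    chord = float(np.linalg.norm(fiber.vertices[-1] - fiber.vertices[0]))
    return min(chord / arc, 1.0)


def count_crosslink_points(network: FiberNetwork) -> int:
    """Number of distinct cross-link points.

    A fiber crossing on a digital skeleton leaves a small 8-connected
    patch of vertices shared by both fibers, not a single pixel; each
    maximal 8-connected component of shared vertices is one cross-link
    point, counted once.
    """
    coords = sorted(network.crosslinks)
    index = {p: i for i, p in enumerate(coords)}
    parent = list(range(len(coords)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for (r, c) in coords:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                q = (r + dr, c + dc)
                if q in index:
                    a, b = find(index[(r, c)]), find(index[q])
                    if a != b:
                        parent[max(a, b)] = min(a, b)
    return len({find(i) for i in range(len(coords))})


def crosslink_density(network: FiberNetwork, pixel_size_um: float) -> float:
    """Cross-link points per μm of total fiber length (each distinct point
    counted once); NaN on an empty network."""
    total_um = network.total_length_px * pixel_size_um
    if total_um <= 0:
        return float("nan")
    return count_crosslink_points(network) / total_um


def _crosslink_positions_um(fiber: Fiber, crosslinks, pixel_size_um: float) -> np.ndarray:
    """Arclength positions (μm) of this fiber's cross-link points, ordered
    along the fiber.

    Cross-links coinciding with a vertex are located exactly; points lying
    on an interior segment of the vertex polyline (possible when vertex
    chains are sparser than the pixel grid) are located by orthogonal
    projection onto the nearest segment.
    """
    v = fiber.vertices
    steps = np.sqrt((np.diff(v, axis=0) ** 2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    vert_key = {(int(round(r)), int(round(c))): i for i, (r, c) in enumerate(v)}

    pos = []
    leftover = []
    for link in crosslinks:
        i = vert_key.get(link)
        if i is not None:
            pos.append(cum[i])
        else:
            leftover.append(link)
    if leftover and len(v) >= 2:
        p = np.asarray(leftover, dtype=float)  # (L, 2)
        a, b = v[:-1], v[1:]
        ab = b - a
        denom = (ab**2).sum(axis=1)
        denom[denom == 0] = 1.0
        t = ((p[:, None, :] - a[None]) * ab[None]).sum(-1) / denom[None]
        t = np.clip(t, 0.0, 1.0)
        proj = a[None] + t[..., None] * ab[None]
        d = np.sqrt(((p[:, None, :] - proj) ** 2).sum(-1))
        j = d.argmin(axis=1)
        on_seg = d[np.arange(len(p)), j] <= 0.25
        for k in np.nonzero(on_seg)[0]:
            seg = j[k]
            pos.append(cum[seg] + t[k, seg] * steps[seg])
    return np.sort(np.asarray(pos)) * pixel_size_um


def crosslink_space(
    network: FiberNetwork, pixel_size_um: float, merge_gap_px: float = 3.0
) -> float:
    """Mean along-fiber distance between adjacent cross-link points,
    averaged over fibers carrying at least two cross-links; NaN when no
    fiber qualifies.

    Shared vertices closer than ``merge_gap_px`` along a fiber belong to
    the same junction traversal and collapse to their mean position, so a
    multi-pixel crossing counts as one cross-link (crossings nearer than
    the junction scale are below the method's resolution).
    """
    per_fiber = []
    gap_um = merge_gap_px * pixel_size_um
    for f in network.fibers:
        pos = _crosslink_positions_um(f, network.crosslinks, pixel_size_um)
        if len(pos) == 0:
            continue
        merged = [[pos[0]]]
        for p in pos[1:]:
            if p - merged[-1][-1] <= gap_um:
                merged[-1].append(p)
            else:
                merged.append([p])
        centres = [float(np.mean(g)) for g in merged]
        if len(centres) >= 2:
            per_fiber.append(float(np.diff(centres).mean()))
    return float(np.mean(per_fiber)) if per_fiber else float("nan")


def orientation_index(mask: BinaryMask, dc_radius_px: float = 2.0) -> float:
    """Anisotropy of the collagen arrangement from the 2-D power spectrum.

    The mean-subtracted mask is Hann-windowed, its power spectrum is
    centred, a small DC disc is zeroed, and the spectrum's second central
    moment matrix gives the squared axes of the equivalent ellipse.  The
    index is ``1 − short_axis/long_axis``: 0 for an isotropic arrangement,
    approaching 1 for parallel fibers.
    """
    m = mask.labels.astype(float)
    if m.sum() == 0:
        raise ValueError("orientation is undefined on an empty mask")
    h, w = m.shape
    win = np.outer(np.hanning(h), np.hanning(w))
    spec = np.fft.fftshift(np.abs(np.fft.fft2((m - m.mean()) * win)) ** 2)
    cy, cx = h // 2, w // 2
    yy, xx = np.mgrid[0:h, 0:w]
    yy = yy - cy
    xx = xx - cx
    spec[yy**2 + xx**2 <= dc_radius_px**2] = 0.0
    total = spec.sum()
    if total <= 0:
        return 0.0
    my = (spec * yy).sum() / total
    mx = (spec * xx).sum() / total
    cyy = (spec * (yy - my) ** 2).sum() / total
    cxx = (spec * (xx - mx) ** 2).sum() / total
    cxy = (spec * (yy - my) * (xx - mx)).sum() / total
    lam = np.linalg.eigvalsh(np.array([[cyy, cxy], [cxy, cxx]]))
    lo, hi = max(lam[0], 0.0), max(lam[1], 1e-300)
    return float(np.clip(1.0 - np.sqrt(lo / hi), 0.0, 1.0))


def compute_feature_set(
    image: SHGImage, network: FiberNetwork, mask: BinaryMask
) -> FeatureSet:
    """Assemble all eight features for one region.

    Fiber-level quantities are means over the extracted fibers; features
    that are undefined for the region propagate as NaN.
    """
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if abs(image.pixel_size_um - mask.pixel_size_um) > 1e-12:
        raise ValueError("image and mask pixel sizes differ")
    px = mask.pixel_size_um
    nan = float("nan")

    area = proportionate_area(mask)
    number = fiber_number_density(network, mask.area_um2)
    if network.n_fibers:
        edt = distance_transform_edt(mask.labels) if (~mask.labels).any() else None
        lengths = [fiber_length(f, px) for f in network.fibers]
        widths = (
            [fiber_width(f, mask, px, _edt=edt) for f in network.fibers]
            if edt is not None
            else [nan]
        )
        straights = [fiber_straightness(f) for f in network.fibers]
        length = float(np.mean(lengths))
        width = float(np.mean(widths))
        straight = float(np.mean(straights))
        xdens = crosslink_density(network, px)
        xspace = crosslink_space(network, px)
    else:
        length = width = straight = xdens = xspace = nan
    orient = orientation_index(mask) if mask.labels.any() else nan
    return FeatureSet(
        area_pct=area,
        number_per_um2=number,
        length_um=length,
        width_um=width,
        straightness=straight,
        xlink_density_per_um=xdens,
        xlink_space_um=xspace,
        orientation_index=orient,
    )
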