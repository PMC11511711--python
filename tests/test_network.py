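"""Skeletonization, fiber tracking through junctions, cross-link detection."""

import numpy as np
import pytest

from shgmorph import (
    BinaryMask,
    FieldSpec,
    detect_crosslinks,
    extract_fibers,
    render_field,
    sample_fibers,
    segment,
    skeletonize,
)
from shgmorph.features import count_crosslink_points
from shgmorph.network import _adjacency

from conftest import make_fiber, make_network


def _line_skel(shape, pts):
    sk = np.zeros(shape, dtype=bool)
    for r, c in pts:
        sk[r, c] = True
    return sk


def test_ribbon_skeletonizes_to_central_row():
    m = np.zeros((21, 60), dtype=bool)
    m[8:13, :] = True
    sk = skeletonize(BinaryMask(m, 1.0))
    rows, cols = np.nonzero(sk)
    interior = (cols > 5) & (cols < 54)  # away from end effects
    assert (rows[interior] == 10).all()


def test_empty_mask_gives_empty_skeleton_and_network():
    m = BinaryMask(np.zeros((10, 10), dtype=bool), 1.0)
    sk = skeletonize(m)
    assert sk.sum() == 0
    net = extract_fibers(sk)
    assert net.n_fibers == 0 and len(net.crosslinks) == 0


def test_plus_sign_skeleton_has_single_degree4_junction():
    m = np.zeros((41, 41), dtype=bool)
    m[18:23, 3:38] = True
    m[3:38, 18:23] = True
    sk = skeletonize(BinaryMask(m, 1.0))
    adj = _adjacency(sk)
    deg4 = [p for p, nbs in adj.items() if len(nbs) == 4]
    assert len(deg4) == 1


def test_perpendicular_crossing_tracks_straight_through():
    m = np.zeros((41, 41), dtype=bool)
    m[18:23, 3:38] = True
    m[3:38, 18:23] = True
    net = extract_fibers(skeletonize(BinaryMask(m, 1.0)), pixel_size_um=1.0)
    assert net.n_fibers == 2
    assert count_crosslink_points(net) == 1
    # each fiber connects opposite arm tips (passes through the junction)
    for f in net.fibers:
        span = np.abs(f.vertices[-1] - f.vertices[0])
        assert span.max() > 28 and span.min() < 4


def test_single_segment_keeps_every_skeleton_pixel_at_full_resolution():
    sk = _line_skel((20, 30), [(10, c) for c in range(4, 26)])
    net = extract_fibers(sk, simplify_tol_px=0.0)
    assert net.n_fibers == 1
    f = net.fibers[0]
    assert f.n_vertices == sk.sum()
    steps = np.sqrt((np.diff(f.vertices, axis=0) ** 2).sum(axis=1))
    assert set(np.round(steps, 6)) <= {1.0, np.round(np.sqrt(2), 6)}


def test_symmetric_junction_turns_of_60_degrees_do_not_join():
    """Three branches at mutual 120 deg all present a 60-deg continuation
    turn; under the 60-deg limit none may pair (checked with exact
    tangents, where rasterization cannot blur the angle)."""
    from shgmorph.network import _pair_ends

    ends = []
    for bid, ang in enumerate((90.0, 210.0, 330.0)):
        th = np.radians(ang)
        tangent = np.array([np.sin(th), np.cos(th)])  # away from junction
        ends.append((bid, 0, (25, 25), tangent))
    assert _pair_ends(ends, max_turn_deg=60.0) == []
    # a genuine straight-through pair (turn 0) does join
    opp = [
        (0, 0, (25, 25), np.array([0.0, 1.0])),
        (1, 0, (25, 25), np.array([0.0, -1.0])),
    ]
    assert len(_pair_ends(opp, max_turn_deg=60.0)) == 1


def test_y_junction_with_wide_turns_stays_three_fibers():
    centre = np.array([25.0, 25.0])
    sk = np.zeros((51, 51), dtype=bool)
    for ang in (90.0, 210.0, 330.0):
        th = np.radians(ang)
        for t in np.linspace(0, 18, 80):
            r = int(round(centre[0] + t * np.sin(th)))
            c = int(round(centre[1] + t * np.cos(th)))
            sk[r, c] = True
    sk = skeletonize(BinaryMask(sk, 1.0))  # re-thin the rasterized arms
    net = extract_fibers(sk, max_turn_deg=50.0, pixel_size_um=1.0)
    assert net.n_fibers == 3
    assert count_crosslink_points(net) == 1


def test_grid_of_three_by_three_has_nine_crosslinks():
    sk = np.zeros((40, 40), dtype=bool)
    for r in (5, 15, 25):
        sk[r, 2:36] = True
    for c in (8, 18, 28):
        sk[2:36, c] = True
    net = extract_fibers(sk, pixel_size_um=1.0)
    assert net.n_fibers == 6
    assert count_crosslink_points(net) == 9


def test_detect_crosslinks_shared_and_disjoint():
    a = make_fiber([(5, 0), (5, 5), (5, 10)], fid=0)
    b = make_fiber([(0, 5), (5, 5), (10, 5)], fid=1)
    net = detect_crosslinks(make_network([a, b]))
    assert net.crosslinks == frozenset({(5, 5)})
    c = make_fiber([(20, 0), (20, 10)], fid=2)
    net2 = detect_crosslinks(make_network([a, c]))
    assert net2.crosslinks == frozenset()


def test_rotating_mask_preserves_fiber_and_crosslink_counts():
    spec = FieldSpec(n_fibers=25, seed=9)
    truth = sample_fibers(spec)
    _, clean = render_field(truth, spec)
    net = extract_fibers(skeletonize(clean))
    rot = BinaryMask(np.rot90(clean.labels).copy(), clean.pixel_size_um)
    net_rot = extract_fibers(skeletonize(rot))
    assert net_rot.n_fibers == net.n_fibers
    assert count_crosslink_points(net_rot) == count_crosslink_points(net)


def test_every_skeleton_pixel_assigned_on_separated_field():
    spec = FieldSpec(n_fibers=20, crossing_rate=0.0, seed=21)
    truth = sample_fibers(spec)
    _, clean = render_field(truth, spec)
    sk = skeletonize(clean)
    net = extract_fibers(sk, min_len_px=0.0, simplify_tol_px=0.0)
    assigned = set()
    for f in net.fibers:
        assigned |= {(int(r), int(c)) for r, c in f.vertices}
    skel_px = set(map(tuple, np.argwhere(sk)))
    assert assigned == skel_px


def test_fiber_count_matches_truth_exactly_when_separated():
    spec = FieldSpec(n_fibers=30, crossing_rate=0.0, seed=4)
    truth = sample_fibers(spec)
    image, _ = render_field(truth, spec)
    net = extract_fibers(skeletonize(segment(image)))
    assert net.n_fibers == truth.n_fibers


def test_fiber_count_within_ten_percent_with_crossings():
    ratios = []
    for seed in range(1, 7):
        spec = FieldSpec(n_fibers=30, kappa=1.0, crossing_rate=2.0, seed=seed)
        truth = sample_fibers(spec)
        image, _ = render_field(truth, spec)
        net = extract_fibers(skeletonize(segment(image)))
        ratios.append(net.n_fibers / truth.n_fibers)
    assert abs(np.mean(ratios) - 1.0) <= 0.10
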