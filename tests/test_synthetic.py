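"""Ground-truth fiber-field generator."""

import numpy as np
import pytest

from shgmorph import (
    FieldSpec,
    FiberTruth,
    GroundTruthTable,
    analytic_features,
    grid_truth,
    render_field,
    sample_fibers,
)
from shgmorph.synthetic import _rasterize, solve_arch_amplitude


def test_empty_field():
    truth = sample_fibers(FieldSpec(n_fibers=0, seed=1))
    assert truth.n_fibers == 0
    assert truth.true_area_fraction == 0.0
    feats = analytic_features(truth, FieldSpec(n_fibers=0, seed=1))
    assert feats.number_per_um2 == 0.0
    assert np.isnan(feats.length_um)


def test_unit_waviness_gives_collinear_straight_fibers():
    spec = FieldSpec(n_fibers=8, waviness=1.0, seed=2)
    truth = sample_fibers(spec)
    for f in truth.fibers:
        assert f.true_straightness == pytest.approx(1.0, abs=1e-9)
        d = f.centerline - f.centerline[0]
        cross = d[:, 0] * d[-1, 1] - d[:, 1] * d[-1, 0]
        assert np.abs(cross).max() < 1e-6 * np.linalg.norm(d[-1])


def test_amplitude_solver_hits_semicircle_ratio():
    """chord/arc = 2/pi is the semicircle's ratio; the solved sinusoid must
    reproduce it on a densely sampled centerline."""
    target = 2.0 / np.pi
    spec = FieldSpec(n_fibers=1, waviness=target, seed=3)
    truth = sample_fibers(spec)
    f = truth.fibers[0]
    # independent dense-polyline check of chord/arc
    arc = np.sqrt((np.diff(f.centerline, axis=0) ** 2).sum(axis=1)).sum()
    chord = np.linalg.norm(f.centerline[-1] - f.centerline[0])
    assert chord / arc == pytest.approx(target, abs=1e-3)
    assert f.true_straightness == pytest.approx(target, abs=1e-3)
    # the solver itself meets its tolerance
    amp = solve_arch_amplitude(target)
    assert amp > 0


def test_truth_invariants_length_and_straightness():
    truth = sample_fibers(FieldSpec(n_fibers=12, seed=4))
    for f in truth.fibers:
        arc = np.sqrt((np.diff(f.centerline, axis=0) ** 2).sum(axis=1)).sum()
        assert f.true_length_um == pytest.approx(arc, rel=1e-9)
        assert 0 < f.true_straightness <= 1


def test_same_seed_bitwise_identical():
    spec = FieldSpec(n_fibers=20, seed=77)
    t1, t2 = sample_fibers(spec), sample_fibers(spec)
    img1, m1 = render_field(t1, spec)
    img2, m2 = render_field(t2, spec)
    assert (img1.pixels == img2.pixels).all()
    assert (m1.labels == m2.labels).all()
    for a, b in zip(t1.fibers, t2.fibers):
        assert (a.centerline == b.centerline).all()


def test_flat_cap_horizontal_ribbon_pixel_count():
    """A 50-px-long horizontal fiber rendered with flat caps and half-width
    2 px covers exactly 50 columns x 5 rows = 250 pixels."""
    spec = FieldSpec(n_fibers=1, seed=0, region_size_um=100.0, pixel_size_um=1.0)
    y = 40.5  # a pixel-centre row
    line = np.array([[10.0, y], [60.0, y]])  # arclength 50 px
    f = FiberTruth(centerline=line, width_px=2, true_length_um=50.0,
                   true_straightness=1.0, orientation_deg=0.0)
    mask = _rasterize((f,), spec, cap_style="flat")
    assert mask.sum() == 250
    rows = np.nonzero(mask.any(axis=1))[0]
    assert len(rows) == 5


def test_noiseless_render_is_two_valued():
    spec = FieldSpec(n_fibers=10, seed=5, noise_sd=0.0, noise_poisson_scale=0.0)
    truth = sample_fibers(spec)
    img, mask = render_field(truth, spec)
    vals = np.unique(img.pixels)
    assert set(vals) == {spec.noise_bg, spec.noise_bg + spec.signal}


def test_realized_area_fraction_near_geometric_request():
    """For separated straight ribbons the foreground fraction must match
    the area implied by (count, length, width) within 10%."""
    spec = FieldSpec(n_fibers=30, crossing_rate=0.0, waviness=1.0, seed=6,
                     width_px_values=(2,), width_px_probs=(1.0,))
    truth = sample_fibers(spec)
    px = spec.pixel_size_um
    w = 2
    expected_px = sum(
        (f.true_length_um / px) * (2 * w + 1) + np.pi * w**2
        for f in truth.fibers
    )
    realized = truth.true_area_fraction * spec.raster_px**2
    assert realized == pytest.approx(expected_px, rel=0.10)


def test_analytic_number_density_arithmetic():
    spec = FieldSpec(n_fibers=115, seed=7)
    feats = analytic_features(sample_fibers(spec), spec)
    assert feats.number_per_um2 == pytest.approx(115 / 22500, rel=1e-12)


def test_analytic_orientation_of_parallel_straight_fibers():
    spec = FieldSpec(n_fibers=15, waviness=1.0, kappa=500.0, seed=8)
    feats = analytic_features(sample_fibers(spec), spec)
    assert feats.orientation_index > 0.9


def test_analytic_crosslink_density_of_single_crossing():
    """Two straight 20 μm fibers crossing once: 1 point / 40 μm."""
    a = FiberTruth(np.array([[40.0, 50.0], [60.0, 50.0]]), 2, 20.0, 1.0, 0.0)
    b = FiberTruth(np.array([[50.0, 40.0], [50.0, 60.0]]), 2, 20.0, 1.0, 90.0)
    truth = GroundTruthTable(fibers=(a, b), true_area_fraction=0.01,
                             true_crosslink_points=((50.0, 50.0),))
    feats = analytic_features(truth, FieldSpec(n_fibers=2))
    assert feats.xlink_density_per_um == pytest.approx(0.025, rel=1e-9)
    assert np.isnan(feats.xlink_space_um)  # one cross-link per fiber


def test_grid_truth_exact_spacing_and_crossings():
    spec = FieldSpec(seed=13)
    truth = grid_truth(spec, spacing_um=10.0)
    feats = analytic_features(truth, spec)
    assert feats.xlink_space_um == pytest.approx(10.0, abs=1e-6)
    assert len(truth.true_crosslink_points) > 50


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        FieldSpec(region_size_um=-1.0)
    with pytest.raises(ValueError):
        FieldSpec(n_fibers=-2)
    with pytest.raises(ValueError):
        FieldSpec(waviness=0.0)
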