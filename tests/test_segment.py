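"""Thresholding (probability and histogram criteria), particles, network mask."""

import numpy as np
import pytest

import cristaseg as cs
from cristaseg.classifier import ProbabilityMap
from cristaseg.segment import (
    AUTO_THRESHOLD_METHODS,
    BinaryMask,
    auto_threshold,
    connected_particles,
    filter_particles,
    histogram_256,
    label_mask,
    scale_to_bins,
    segment_mito_network,
    threshold_intensity,
    threshold_probability,
)


def _prob_map(cristae_plane, pixel_size=0.04):
    p = np.asarray(cristae_plane, dtype=float)
    return ProbabilityMap(np.stack([p, 1 - p]), pixel_size)


# ---------------------------------------------------------------------------
# probability thresholding


def test_threshold_zero_selects_everything():
    prob = _prob_map(np.random.default_rng(0).uniform(0, 1, (16, 16)))
    assert threshold_probability(prob, 0.0).pixels.all()


def test_threshold_one_with_submaximal_map_selects_nothing():
    prob = _prob_map(np.full((16, 16), 0.97))
    assert not threshold_probability(prob, 1.0).pixels.any()


def test_raising_threshold_shrinks_mask_monotonically():
    prob = _prob_map(np.random.default_rng(1).uniform(0, 1, (32, 32)))
    previous = threshold_probability(prob, 0.1).pixels
    for t in (0.3, 0.5, 0.7, 0.9):
        current = threshold_probability(prob, t).pixels
        assert not np.any(current & ~previous)
        previous = current


@pytest.mark.parametrize("bad", [-0.1, 1.5])
def test_out_of_range_threshold_rejected(bad):
    with pytest.raises(ValueError):
        threshold_probability(_prob_map(np.zeros((8, 8))), bad)


# ---------------------------------------------------------------------------
# histogram criteria


def _random_histogram(rng):
    hist = np.zeros(256)
    n_modes = rng.integers(2, 5)
    for _ in range(n_modes):
        centre = rng.integers(0, 256)
        width = rng.integers(2, 40)
        count = rng.integers(50, 5000)
        samples = np.clip(rng.normal(centre, width, count), 0, 255).astype(int)
        hist += np.bincount(samples, minlength=256)
    return hist


def _kapur_oracle(hist):
    """Exhaustive loop over all candidate bins, written independently."""
    p = hist / hist.sum()
    best, best_t = -np.inf, None
    for t in range(256):
        pb = p[: t + 1].sum()
        pf = p[t + 1 :].sum()
        if pb <= 0 or pf <= 0:
            continue
        hb = -sum(q / pb * np.log(q / pb) for q in p[: t + 1] if q > 0)
        hf = -sum(q / pf * np.log(q / pf) for q in p[t + 1 :] if q > 0)
        if hb + hf > best:
            best, best_t = hb + hf, t
    return best_t


def _shanbhag_oracle(hist):
    p = hist / hist.sum()
    P1 = np.cumsum(p)
    P2 = 1.0 - P1
    eps = np.finfo(float).eps
    first = next(i for i in range(256) if abs(P1[i]) >= eps)
    last = next(i for i in range(255, -1, -1) if abs(P2[i]) >= eps)
    best, best_t = np.inf, None
    for t in range(first, last + 1):
        if P1[t] <= eps or P2[t] <= eps:
            continue
        term = 0.5 / P1[t]
        ent_back = -sum(p[i] * np.log(1.0 - term * P1[i - 1]) for i in range(1, t + 1)) * term
        term = 0.5 / P2[t]
        ent_obj = -sum(p[i] * np.log(1.0 - term * P2[i]) for i in range(t + 1, 256)) * term
        crit = abs(ent_back - ent_obj)
        if crit < best:
            best, best_t = crit, t
    return best_t


def _shanbhag_criterion(hist, t):
    p = hist / hist.sum()
    P1 = np.cumsum(p)
    P2 = 1.0 - P1
    term = 0.5 / P1[t]
    ent_back = -sum(p[i] * np.log(1.0 - term * P1[i - 1]) for i in range(1, t + 1)) * term
    term = 0.5 / P2[t]
    ent_obj = -sum(p[i] * np.log(1.0 - term * P2[i]) for i in range(t + 1, 256)) * term
    return abs(ent_back - ent_obj)


def assert_matches_oracles(hist):
    """Implementation bin equals the brute-force arg-optimum, allowing bins
    whose criterion values coincide to within summation round-off."""
    me, me_oracle = auto_threshold(hist, "max_entropy"), _kapur_oracle(hist)
    assert me == me_oracle
    sh, sh_oracle = auto_threshold(hist, "shanbhag"), _shanbhag_oracle(hist)
    if sh != sh_oracle:
        a, b = _shanbhag_criterion(hist, sh), _shanbhag_criterion(hist, sh_oracle)
        assert abs(a - b) <= 1e-12 * max(1.0, abs(a))


def test_bimodal_deltas_split_between_the_peaks():
    hist = np.zeros(256)
    hist[50] = 1000
    hist[200] = 1000
    for method in AUTO_THRESHOLD_METHODS:
        t = auto_threshold(hist, method)
        assert 50 <= t < 200, method


@pytest.mark.parametrize("seed", range(10))
def test_entropy_criteria_match_bruteforce_oracles(seed):
    rng = np.random.default_rng(seed)
    assert_matches_oracles(_random_histogram(rng))


def test_otsu_agrees_with_skimage():
    from skimage.filters import threshold_otsu

    rng = np.random.default_rng(3)
    for _ in range(10):
        hist = _random_histogram(rng)
        t = auto_threshold(hist, "otsu")
        expected = threshold_otsu(hist=(hist, np.arange(256)))
        assert abs(t - expected) <= 1


def test_single_bin_histogram_rejected():
    hist = np.zeros(256)
    hist[77] = 100
    for method in AUTO_THRESHOLD_METHODS:
        with pytest.raises(ValueError, match="degenerate"):
            auto_threshold(hist, method)


def test_unknown_method_rejected():
    with pytest.raises(ValueError, match="unknown"):
        auto_threshold(np.ones(256), "triangle")


def test_histogram_scaling_covers_256_bins():
    values = np.linspace(5.0, 9.0, 1000)
    hist = histogram_256(values)
    assert hist.sum() == 1000
    assert hist[0] > 0 and hist[255] > 0
    bins = scale_to_bins(values)
    assert bins.min() == 0 and bins.max() == 255


def test_manual_threshold_on_raw_intensities(small_image):
    mask, t = threshold_intensity(small_image, manual_threshold=50.0)
    assert t == 50.0
    assert np.array_equal(mask.pixels, small_image.pixels >= 50.0)
    with pytest.raises(ValueError):
        threshold_intensity(small_image)  # neither method nor manual
    with pytest.raises(ValueError):
        threshold_intensity(small_image, method="otsu", manual_threshold=1.0)


# ---------------------------------------------------------------------------
# particles


def _mask(bools, pixel_size=0.1):
    return BinaryMask(np.asarray(bools, dtype=bool), pixel_size)


def test_diagonal_pixels_connectivity():
    grid = np.zeros((8, 8), dtype=bool)
    grid[2, 2] = grid[3, 3] = True
    assert len(connected_particles(_mask(grid), connectivity=8)) == 1
    assert len(connected_particles(_mask(grid), connectivity=4)) == 2


def test_empty_mask_gives_empty_list():
    assert connected_particles(_mask(np.zeros((8, 8)))) == []


def _flood_fill_count(grid, connectivity):
    """Independent component counter via explicit BFS flood fill."""
    grid = grid.copy()
    if connectivity == 8:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    count = 0
    for r in range(grid.shape[0]):
        for c in range(grid.shape[1]):
            if not grid[r, c]:
                continue
            count += 1
            queue = [(r, c)]
            grid[r, c] = False
            while queue:
                cr, cc = queue.pop()
                for dr, dc in steps:
                    nr, nc = cr + dr, cc + dc
                    if 0 <= nr < grid.shape[0] and 0 <= nc < grid.shape[1] and grid[nr, nc]:
                        grid[nr, nc] = False
                        queue.append((nr, nc))
    return count


@pytest.mark.parametrize("connectivity", [4, 8])
def test_component_count_matches_flood_fill_oracle(connectivity):
    rng = np.random.default_rng(17)
    grid = rng.uniform(size=(64, 64)) < 0.3
    particles = connected_particles(_mask(grid), connectivity)
    assert len(particles) == _flood_fill_count(grid, connectivity)


def test_particle_ids_are_row_major_by_topleft_pixel():
    grid = np.zeros((10, 10), dtype=bool)
    grid[1, 7] = True
    grid[1, 2] = True
    grid[5, 0] = True
    particles = connected_particles(_mask(grid))
    firsts = [tuple(p.pixel_coords[0]) for p in particles]
    assert firsts == [(1, 2), (1, 7), (5, 0)]
    assert [p.id for p in particles] == [0, 1, 2]


def test_area_filter_boundary_inclusive():
    # pixel size 0.1 -> 1 px = 0.01 um^2; areas 0.010, 0.017, 0.020
    grid = np.zeros((12, 12), dtype=bool)
    grid[0, 0] = True  # 1 px = 0.010... scaled below
    particles = []
    for n, offset in ((1, 0), (2, 4), (3, 8)):
        g = np.zeros((12, 12), dtype=bool)
        g[offset, :n] = True
        particles += connected_particles(_mask(g, pixel_size=np.sqrt(0.010)))
    # areas are 0.010, 0.020, 0.030; rescale middle one to exactly 0.017
    areas = sorted(p.area_um2 for p in particles)
    assert areas == pytest.approx([0.010, 0.020, 0.030])
    import dataclasses

    synthetic = [
        dataclasses.replace(particles[0], area_um2=a) for a in (0.010, 0.017, 0.020)
    ]
    kept = filter_particles(synthetic, 0.017)
    assert [p.area_um2 for p in kept] == [0.017, 0.020]


def test_zero_min_area_is_identity_and_filter_is_monotone():
    rng = np.random.default_rng(23)
    grid = rng.uniform(size=(64, 64)) < 0.3
    particles = connected_particles(_mask(grid, pixel_size=0.04))
    assert filter_particles(particles, 0.0) == particles
    n_17 = len(filter_particles(particles, 0.017))
    n_30 = len(filter_particles(particles, 0.030))
    assert n_30 <= n_17 <= len(particles)
    with pytest.raises(ValueError):
        filter_particles(particles, -0.1)


# ---------------------------------------------------------------------------
# mitochondrial network


def test_network_mask_overlaps_truth_well(default_scene):
    truth_mask = default_scene["truth"].mito_labels > 0
    mask, area = segment_mito_network(default_scene["pre"])
    jaccard = (mask.pixels & truth_mask).sum() / (mask.pixels | truth_mask).sum()
    assert jaccard >= 0.8
    assert area == pytest.approx(mask.pixels.sum() * 0.04**2)


def test_network_area_bounds_summed_cristae_area(default_scene):
    truth = default_scene["truth"]
    mask, area = segment_mito_network(default_scene["pre"])
    assert area >= truth.per_crista.area_um2.sum()


def test_constant_image_yields_empty_network():
    image = cs.CalibratedImage(np.zeros((32, 32)), 0.04)
    with pytest.warns(UserWarning, match="empty"):
        mask, area = segment_mito_network(image)
    assert area == 0.0


def test_classifier_strategy_requires_model(small_image):
    with pytest.raises(ValueError, match="classifier"):
        segment_mito_network(small_image, strategy="classifier")
    with pytest.raises(ValueError, match="unknown"):
        segment_mito_network(small_image, strategy="watershed")


def test_label_mask_ids_match_component_count():
    grid = np.zeros((10, 10), dtype=bool)
    grid[1:3, 1:3] = True
    grid[6:9, 6:9] = True
    labels = label_mask(_mask(grid))
    assert labels.max() == 2


def test_particle_outlines_label_boundaries():
    from cristaseg.segment import particle_outlines

    grid = np.zeros((12, 12), dtype=bool)
    grid[2:7, 2:7] = True
    particles = connected_particles(_mask(grid))
    outlines = particle_outlines(particles, grid.shape)
    assert outlines[2, 2] == 1  # corner is boundary
    assert outlines[4, 4] == 0  # interior is not
    assert set(np.unique(outlines)) == {0, 1}
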