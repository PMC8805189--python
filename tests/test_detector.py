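"""Detection pipeline stages: rescaling, probability grid geometry, map
postprocessing, component labeling, peak counting, k-means splitting, size
thresholding and refinement."""

import numpy as np
import pytest

import vesiclepick as vp
from vesiclepick import nn
from vesiclepick.detector import (
    Cluster,
    Component,
    DetectorParams,
    ProbabilityMap,
    apply_size_threshold,
    compute_probability_grid,
    count_peaks,
    label_components,
    postprocess_map,
    refine_detections,
    split_component,
)

PARAMS = DetectorParams()


class StubModel:
    """Stand-in classifier: scores each patch by a supplied function."""

    def __init__(self, side, fn):
        self.meta = {"input_side_px": side}
        self.fn = fn
        self.seen = []

    def forward(self, x, train=False, rng=None):
        self.seen.append(np.array(x))
        p = np.array([self.fn(patch[0]) for patch in x], dtype=np.float64)
        p = np.clip(p, 1e-6, 1 - 1e-6)
        return np.stack([np.log(1 - p), np.log(p)], axis=1)


def constant_model(side, p):
    return StubModel(side, lambda patch: p)


class TestRescale:
    def test_native_pixel_size_is_identity(self):
        mg = vp.Micrograph(np.random.rand(64, 64), 2.27)
        out, factor = vp.rescale_to_native(mg)
        assert factor == 1.0
        assert out.pixels is mg.pixels

    def test_double_pixel_size_doubles_dimensions(self):
        mg = vp.Micrograph(np.random.rand(200, 300), 4.54)
        out, factor = vp.rescale_to_native(mg)
        assert factor == pytest.approx(2.0)
        assert out.shape == (400, 600)
        assert out.pixel_size_nm == 2.27

    def test_fine_pixel_size_shrinks(self):
        mg = vp.Micrograph(np.random.rand(400, 400), 0.69)
        out, factor = vp.rescale_to_native(mg)
        assert factor == pytest.approx(0.69 / 2.27)
        assert out.shape == (round(400 * 0.69 / 2.27),) * 2

    def test_too_small_result_rejected(self):
        mg = vp.Micrograph(np.random.rand(60, 60), 0.69)
        with pytest.raises(ValueError, match="40"):
            vp.rescale_to_native(mg)

    def test_mask_resampled_nearest(self):
        mask = np.zeros((100, 100), bool)
        mask[:50] = True
        mg = vp.Micrograph(np.random.rand(100, 100), 4.54, mask=mask)
        out, _ = vp.rescale_to_native(mg)
        assert out.mask.dtype == bool
        assert out.mask[:99].mean() > 0.95 or out.mask[:100].mean() > 0.45


class TestProbabilityGrid:
    def test_grid_dimensions_follow_stride(self):
        mg = vp.Micrograph(np.random.rand(40, 40), 2.27)
        grid = compute_probability_grid(mg, constant_model(40, 0.7))
        assert grid.values.shape == (10, 10)
        mg = vp.Micrograph(np.random.rand(41, 53), 2.27)
        grid = compute_probability_grid(mg, constant_model(40, 0.7))
        assert grid.values.shape == (11, 14)

    def test_constant_image_gives_constant_interior(self):
        mg = vp.Micrograph(np.full((80, 80), 0.5), 2.27)
        grid = compute_probability_grid(mg, StubModel(40, lambda p: p.mean()))
        interior = grid.values[6:-6, 6:-6]
        assert np.allclose(interior, interior[0, 0])

    def test_first_patch_covers_padded_origin(self):
        """The patch evaluated at pixel (0,0) spans -20..+19: 20 rows/cols
        of zero padding plus image rows/cols 0..19."""
        pixels = np.arange(40 * 40, dtype=np.float32).reshape(40, 40) / 1600
        mg = vp.Micrograph(pixels, 2.27)
        model = constant_model(40, 0.5)
        compute_probability_grid(mg, model)
        first_patch = np.concatenate(model.seen)[0, 0]
        assert first_patch.shape == (40, 40)
        assert np.all(first_patch[:20, :] == 0)
        assert np.all(first_patch[:, :20] == 0)
        assert np.array_equal(first_patch[20:, 20:], pixels[:20, :20])

    def test_values_in_unit_interval_and_mask_forces_zero(self):
        mask = np.zeros((60, 60), bool)
        mask[:20, :] = True
        mg = vp.Micrograph(np.random.rand(60, 60), 2.27, mask=mask)
        grid = compute_probability_grid(mg, constant_model(40, 0.9))
        assert grid.values.min() >= 0 and grid.values.max() <= 1
        assert np.all(grid.values[:5, :] == 0)  # grid rows 0,4,8,12,16
        assert np.all(grid.values[5:, :] > 0)

    def test_batched_evaluation_equals_per_patch(self):
        """Batch size is an optimization only: the grid is identical to
        patch-by-patch evaluation with a real CNN."""
        import vesiclepick as vp

        model = vp.build_classifier(
            vp.ClassifierConfig.desk_scale(40, conv_channels=(2, 2, 2, 2),
                                           fc_sizes=(8, 4, 2))
        )
        rng = np.random.default_rng(0)
        mg = vp.Micrograph(rng.random((48, 48)), 2.27)
        one = compute_probability_grid(mg, model, batch_size=1)
        many = compute_probability_grid(mg, model, batch_size=64)
        assert np.allclose(one.values, many.values, atol=1e-6)

    def test_side_mismatch_rejected(self):
        mg = vp.Micrograph(np.random.rand(60, 60), 2.27)
        with pytest.raises(ValueError, match="side"):
            compute_probability_grid(mg, constant_model(80, 0.5))


class TestPostprocess:
    def test_zero_grid_stays_zero(self):
        grid = ProbabilityMap(np.zeros((10, 10)), "grid")
        out = postprocess_map(grid, (40, 40))
        assert out.stage == "scaled255"
        assert np.all(out.values == 0)

    def test_constant_one_grid_becomes_constant_255(self):
        grid = ProbabilityMap(np.ones((10, 10)), "grid")
        out = postprocess_map(grid, (40, 40))
        assert np.allclose(out.values, 255.0)

    def test_subthreshold_values_are_cut(self):
        grid = ProbabilityMap(np.full((10, 10), 0.49), "grid")
        assert np.all(postprocess_map(grid, (40, 40)).values == 0)

    def test_interior_impulse_spreads_to_one_ninth(self):
        """Without resize, a single cell at 1.0 becomes 255/9 in the 3x3
        neighborhood after box filtering."""
        values = np.zeros((9, 9))
        values[4, 4] = 1.0
        out = postprocess_map(ProbabilityMap(values, "grid"), (9, 9))
        assert out.values[4, 4] == pytest.approx(255 / 9)
        assert out.values[3, 4] == pytest.approx(255 / 9)
        assert out.values[4, 4 + 2] == pytest.approx(0.0)

    def test_wrong_stage_rejected(self):
        pmap = ProbabilityMap(np.zeros((5, 5)), "scaled255")
        with pytest.raises(ValueError):
            postprocess_map(pmap, (5, 5))


def _flood_fill_components(binary):
    """Independent 4-connected labeling oracle: BFS flood fill."""
    visited = np.zeros_like(binary, bool)
    comps = []
    h, w = binary.shape
    for r in range(h):
        for c in range(w):
            if binary[r, c] and not visited[r, c]:
                stack, members = [(r, c)], []
                visited[r, c] = True
                while stack:
                    y, x = stack.pop()
                    members.append((y, x))
                    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and binary[ny, nx] \
                                and not visited[ny, nx]:
                            visited[ny, nx] = True
                            stack.append((ny, nx))
                comps.append(frozenset(members))
    return set(comps)


class TestComponents:
    def _map(self, binary):
        return ProbabilityMap(binary.astype(float) * 200.0, "scaled255")

    def test_diagonal_contact_does_not_join(self):
        binary = np.zeros((4, 4), bool)
        binary[0, 0] = binary[1, 1] = True
        assert len(label_components(self._map(binary))) == 2

    def test_edge_contact_joins(self):
        binary = np.zeros((4, 4), bool)
        binary[0, 0] = binary[0, 1] = binary[1, 1] = True
        comps = label_components(self._map(binary))
        assert len(comps) == 1 and comps[0].size == 3

    def test_matches_flood_fill_oracle_on_random_maps(self, rng):
        for _ in range(100):
            binary = rng.random((64, 64)) < 0.35
            ours = {
                frozenset(zip(c.rows.tolist(), c.cols.tolist()))
                for c in label_components(self._map(binary))
            }
            assert ours == _flood_fill_components(binary)


def _two_bump_map(separation_px, shape=(80, 80)):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    c = shape[0] // 2
    half = separation_px / 2
    bump = lambda cy, cx: 200 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 6.0 ** 2))
    values = bump(c, c - half) + bump(c, c + half)
    values[values < 5] = 0
    return ProbabilityMap(values, "scaled255")


class TestPeaks:
    def test_single_smooth_blob_has_one_peak(self):
        pmap = _two_bump_map(0)
        comp = label_components(pmap)[0]
        assert count_peaks(comp, pmap, 2.27) == 1

    def test_bumps_farther_than_34nm_count_as_two(self):
        pmap = _two_bump_map(20)  # 45.4 nm at 2.27 nm/px
        comp = label_components(pmap)[0]
        assert len(label_components(pmap)) == 1  # merged into one component
        assert count_peaks(comp, pmap, 2.27) == 2

    def test_bumps_closer_than_34nm_count_as_one(self):
        pmap = _two_bump_map(10)  # 22.7 nm
        comp = label_components(pmap)[0]
        assert count_peaks(comp, pmap, 2.27) == 1


def _wcss(points, assignment):
    total = 0.0
    for j in np.unique(assignment):
        members = points[assignment == j]
        total += ((members - members.mean(axis=0)) ** 2).sum()
    return total


def _exhaustive_two_means(points):
    """Global optimum of 2-means over all linearly separable bipartitions
    (the optimum is always linearly separable)."""
    n = len(points)
    best, best_assign = np.inf, None
    directions = [points[i] - points[j] for i in range(n) for j in range(i)]
    for d in directions:
        if not np.any(d):
            continue
        proj = points @ d
        order = np.argsort(proj, kind="stable")
        for cut in range(1, n):
            assignment = np.zeros(n, int)
            assignment[order[cut:]] = 1
            w = _wcss(points, assignment)
            if w < best:
                best, best_assign = w, assignment
    return best, best_assign


class TestSplit:
    def test_k1_returns_centroid_cluster(self):
        comp = Component(np.array([0, 0, 1]), np.array([0, 1, 1]))
        pmap = ProbabilityMap(np.full((2, 2), 100.0), "scaled255")
        clusters = split_component(comp, 1, pmap)
        assert len(clusters) == 1
        x, y = clusters[0].center_xy
        assert (x, y) == (pytest.approx(2 / 3), pytest.approx(1 / 3))

    def test_bridged_squares_split_matches_exhaustive_optimum(self):
        """Two 5x5 squares joined by a 1 px bridge: the peak-initialized
        k-means partition attains the global 2-means optimum."""
        rows, cols = [], []
        for r in range(4):
            for c in range(4):
                rows.append(r + 2)
                cols.append(c)
                rows.append(r + 2)
                cols.append(c + 16)
        for c in range(4, 16):
            rows.append(3)
            cols.append(c)
        assert len(rows) <= 51
        comp = Component(np.array(rows), np.array(cols))
        values = np.zeros((10, 22))
        values[comp.rows, comp.cols] = 100.0
        # peaks 16 px apart: farther than 34 nm at 2.27 nm/px
        values[3, 1] = 200.0
        values[3, 17] = 200.0
        pmap = ProbabilityMap(values, "scaled255")
        k = count_peaks(comp, pmap, 2.27)
        assert k == 2
        clusters = split_component(comp, k, pmap)
        points = np.stack([comp.rows, comp.cols], axis=1).astype(float)
        assignment = np.zeros(len(points), int)
        member_sets = [set(zip(c.rows.tolist(), c.cols.tolist())) for c in clusters]
        for i, (r, c) in enumerate(zip(rows, cols)):
            assignment[i] = 0 if (r, c) in member_sets[0] else 1
        best_wcss, _ = _exhaustive_two_means(points)
        assert _wcss(points, assignment) == pytest.approx(best_wcss)

    def test_split_is_deterministic(self):
        rng = np.random.default_rng(0)
        rows, cols = np.nonzero(rng.random((20, 20)) < 0.4)
        comp = Component(rows, cols)
        values = rng.random((20, 20)) * 200
        pmap = ProbabilityMap(values, "scaled255")
        k = count_peaks(comp, pmap, 2.27)
        a = split_component(comp, k, pmap)
        b = split_component(comp, k, pmap)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.rows, cb.rows)

    def test_k_clamped_to_component_size(self, caplog):
        comp = Component(np.array([0, 0]), np.array([0, 1]))
        comp.peaks = [(0.0, 0.0), (0.0, 1.0), (0.0, 2.0)]
        pmap = ProbabilityMap(np.full((1, 2), 9.0), "scaled255")
        with caplog.at_level("WARNING"):
            clusters = split_component(comp, 3, pmap)
        assert len(clusters) == 2


class TestSizeThreshold:
    def _cluster(self, n):
        return Cluster(np.zeros(n, int), np.arange(n))

    def test_63_pixels_removed_65_kept_at_native_resolution(self):
        # 63 * 2.27^2 = 324.6 < 330 <= 65 * 2.27^2 = 334.9
        kept = apply_size_threshold([self._cluster(63), self._cluster(65)], 2.27)
        assert [c.size for c in kept] == [65]

    @pytest.mark.parametrize(
        "pixel_size,threshold",
        [(2.27, 330.0), (2.3, 407.0), (3.3, 484.0), (4.5, 562.0), (5.3, 639.0),
         (6.3, 716.0), (10.0, 716.0)],
    )
    def test_threshold_table(self, pixel_size, threshold):
        assert PARAMS.area_threshold(pixel_size) == threshold


class TestRefinement:
    def test_accept_all_model_keeps_every_cluster(self):
        clusters = [Cluster(np.array([r]), np.array([r])) for r in range(5)]
        img = vp.Micrograph(np.random.rand(100, 100), 2.27)
        out = refine_detections(clusters, img, constant_model(80, 0.9), 1.0)
        assert len(out) == len(clusters)

    def test_reject_all_model_removes_everything(self):
        clusters = [Cluster(np.array([50]), np.array([50]))]
        img = vp.Micrograph(np.random.rand(100, 100), 2.27)
        assert refine_detections(clusters, img, constant_model(80, 0.1), 1.0) == []

    def test_corner_cluster_patch_is_complete(self):
        model = constant_model(80, 0.9)
        clusters = [Cluster(np.array([0]), np.array([0]))]
        img = vp.Micrograph(np.random.rand(100, 100), 2.27)
        refine_detections(clusters, img, model, 1.0)
        assert model.seen[0].shape[-2:] == (80, 80)


class TestPipeline:
    def test_blank_image_yields_no_detections(self):
        mg = vp.Micrograph(np.zeros((64, 64)), 2.27)
        detections = vp.detect(mg, constant_model(40, 0.05),
                               constant_model(80, 0.9))
        assert detections == []

    def test_detections_lie_within_image_bounds(self):
        rng = np.random.default_rng(1)
        mg = vp.Micrograph(rng.random((64, 64)), 2.27)
        model = StubModel(40, lambda p: 0.9 if p.mean() > 0.5 else 0.2)
        detections = vp.detect(mg, model, refine=False)
        for d in detections:
            assert 0 <= d.x_px < 64 and 0 <= d.y_px < 64

    def test_size_threshold_and_refinement_never_add_detections(self):
        rng = np.random.default_rng(2)
        mg = vp.Micrograph(rng.random((64, 64)), 2.27)
        first = StubModel(40, lambda p: float(p[18:22, 18:22].mean()))
        refine = StubModel(80, lambda p: float(p.std() * 4))
        base = vp.detect(mg, first, refine=False, size_threshold=False)
        with_threshold = vp.detect(mg, first, refine=False, size_threshold=True)
        with_refine = vp.detect(mg, first, refine, refine=True, size_threshold=True)
        assert len(with_threshold) <= len(base)
        assert len(with_refine) <= len(with_threshold)
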