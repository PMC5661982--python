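"""Fill-front extraction, priority terms, patch search, and the fill loop."""

import numpy as np
import pytest

from gpmrecon.geometry import VoxelGrid
from gpmrecon.holefill import (FillError, best_match, confidence_term,
                               copy_and_update, data_term, extract_front,
                               gradient_term, hole_fill, label_vacant_regions,
                               make_patch, priority, front_normal)


def grid_from(intensity, known):
    intensity = np.asarray(intensity, dtype=float)
    return VoxelGrid(intensity.shape, intensity=np.where(known, intensity, 0.0),
                     known_mask=np.asarray(known, bool).copy())


def full_grid(intensity):
    intensity = np.asarray(intensity, dtype=float)
    return VoxelGrid(intensity.shape, intensity=intensity,
                     known_mask=np.ones(intensity.shape, bool))


class TestLabelVacantRegions:
    def test_fully_known_has_no_regions(self):
        labels, sizes = label_vacant_regions(full_grid(np.zeros((6, 6, 6))))
        assert sizes == []

    def test_two_separated_cubes(self):
        known = np.ones((10, 10, 10), bool)
        known[1:3, 1:3, 1:3] = False
        known[6:9, 6:9, 6:9] = False
        labels, sizes = label_vacant_regions(grid_from(np.zeros((10,) * 3), known))
        assert sorted(sizes) == [8, 27]

    def test_matches_flood_fill_oracle_on_random_masks(self):
        rng = np.random.default_rng(2)
        known = rng.random((16, 16, 16)) > 0.4
        labels, sizes = label_vacant_regions(grid_from(np.zeros((16,) * 3), known))
        # independent BFS flood fill under 6-connectivity
        seen = np.zeros_like(known)
        comps = []
        vacant = ~known
        for start in np.argwhere(vacant):
            start = tuple(start)
            if seen[start]:
                continue
            stack, comp = [start], 0
            seen[start] = True
            while stack:
                x, y, z = stack.pop()
                comp += 1
                for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                          (0, 0, 1), (0, 0, -1)):
                    q = (x + d[0], y + d[1], z + d[2])
                    if all(0 <= q[i] < 16 for i in range(3)) and \
                            vacant[q] and not seen[q]:
                        seen[q] = True
                        stack.append(q)
            comps.append(comp)
        assert sorted(sizes) == sorted(comps)
        assert labels.max() == len(comps)


class TestExtractFront:
    def test_single_vacant_voxel(self):
        known = np.ones((7, 7, 7), bool)
        known[3, 3, 3] = False
        front = extract_front(grid_from(np.zeros((7,) * 3), known))
        assert front.voxels == [(3, 3, 3)]

    def test_half_space_front_is_the_plane(self):
        known = np.zeros((8, 8, 8), bool)
        known[:, :, :4] = True
        g = grid_from(np.full((8, 8, 8), 50.0), known)
        front = extract_front(g)
        assert set(front.voxels) == {(x, y, 4) for x in range(8) for y in range(8)}
        for p in [(3, 3, 4), (5, 2, 4)]:
            n = front.normal[p]
            assert abs(n[2]) == pytest.approx(1.0, abs=1e-9)

    def test_no_vacancy_gives_empty_front(self):
        front = extract_front(full_grid(np.zeros((5, 5, 5))))
        assert front.voxels == []

    def test_front_members_touch_known(self):
        rng = np.random.default_rng(3)
        known = rng.random((10, 10, 10)) > 0.5
        g = grid_from(np.zeros((10,) * 3), known)
        for p in extract_front(g).voxels:
            assert not known[p]
            touches = False
            for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                      (0, 0, 1), (0, 0, -1)):
                q = tuple(np.add(p, d))
                if all(0 <= q[i] < 10 for i in range(3)) and known[q]:
                    touches = True
            assert touches


class TestPriorityTerms:
    def test_confidence_fully_known_patch(self):
        g = full_grid(np.zeros((12, 12, 12)))
        conf = np.ones((12, 12, 12))
        assert confidence_term(g, conf, (6, 6, 6)) == pytest.approx(1.0)

    def test_confidence_counts_known_fraction(self):
        known = np.ones((12, 12, 12), bool)
        known[6:, :, :] = False  # half space vacant
        g = grid_from(np.zeros((12,) * 3), known)
        conf = known.astype(float)
        # patch at (6,6,6): x slices 2..10, of which x=2..5 known: 4*81=324
        assert confidence_term(g, conf, (6, 6, 6)) == pytest.approx(324 / 729)

    def test_confidence_364_of_729(self):
        known = np.zeros((9, 9, 9), bool)
        known.reshape(-1)[:364] = True
        g = grid_from(np.zeros((9, 9, 9)), known)
        c = confidence_term(g, known.astype(float), (4, 4, 4))
        assert c == pytest.approx(364 / 729)

    def test_data_term_floor_for_flat_region(self):
        g = full_grid(np.full((9, 9, 9), 80.0))
        assert data_term(g, (4, 4, 4), np.array([0.0, 0.0, 1.0])) == 1e-3

    def test_data_term_gradient_parallel_to_normal(self):
        X = np.indices((9, 9, 9))[0].astype(float)
        g = full_grid(255.0 * X / 8)
        n = np.array([1.0, 0.0, 0.0])
        assert data_term(g, (4, 4, 4), n) == 1e-3

    def test_data_term_perpendicular_gradient(self):
        X = np.indices((9, 9, 9))[0].astype(float)
        g = full_grid(255.0 * X)  # gradient (255, 0, 0)
        d = data_term(g, (4, 4, 4), np.array([0.0, 0.0, 1.0]))
        assert d == pytest.approx(1.0)

    def test_data_term_requires_unit_normal(self):
        g = full_grid(np.zeros((5, 5, 5)))
        with pytest.raises(ValueError):
            data_term(g, (2, 2, 2), np.array([0.0, 0.0, 2.0]))

    def test_gradient_term_constant_region(self):
        g = full_grid(np.full((11, 11, 11), 9.0))
        assert gradient_term(g, (5, 5, 5)) == 0.0

    def test_gradient_term_unit_ramp(self):
        X = np.indices((13, 13, 13))[0].astype(float)
        g = full_grid(X)
        assert gradient_term(g, (6, 6, 6)) == pytest.approx(1.0)

    def test_kernel_terms_match_python_reference(self):
        from gpmrecon import _kernels

        rng = np.random.default_rng(7)
        intensity = rng.integers(0, 255, (14, 14, 14)).astype(float)
        known = rng.random((14, 14, 14)) > 0.3
        g = grid_from(intensity, known)
        conf = known.astype(float) * rng.random((14, 14, 14))
        pts = np.argwhere(~known & np.ones((14,) * 3, bool))[:20].astype(np.int64)
        C, D, G = _kernels.priority_terms(g.intensity, known, conf, pts, 3,
                                          255.0, 1e-3)
        for i, p in enumerate(map(tuple, pts)):
            patch = make_patch(g, p, 7)
            assert C[i] == pytest.approx(
                confidence_term(g, conf, p, patch), abs=1e-12)
            assert G[i] == pytest.approx(gradient_term(g, p, patch), abs=1e-9)
            n = front_normal(g, p)
            assert D[i] == pytest.approx(data_term(g, p, n), abs=1e-12)

    def test_priority_is_commutative_product(self):
        assert priority(0.0, 3.0, 2.0) == 0.0
        assert priority(0.5, 1.0, 2.0) == 1.0
        assert priority(0.5, 2.0, 1.0) == priority(1.0, 0.5, 2.0)


def brute_force_best_match(grid, patch):
    """Exhaustive SAD scan; fully-known candidates, x-fastest tie-break."""
    nx, ny, nz = grid.dims
    lo, hi = patch.lo, patch.hi
    offs = np.argwhere(patch.known) + np.array(lo)
    tvals = patch.intensities[patch.known]
    best = None
    for cz in range(-lo[2], nz - hi[2]):
        for cy in range(-lo[1], ny - hi[1]):
            for cx in range(-lo[0], nx - hi[0]):
                sub = grid.known_mask[cx + lo[0]:cx + hi[0] + 1,
                                      cy + lo[1]:cy + hi[1] + 1,
                                      cz + lo[2]:cz + hi[2] + 1]
                if not sub.all():
                    continue
                s = float(sum(abs(grid.intensity[cx + o[0], cy + o[1], cz + o[2]] - t)
                              for o, t in zip(offs, tvals)))
                lin = cx + nx * (cy + ny * cz)
                if best is None or s < best[0] or (s == best[0] and lin < best[2]):
                    best = (s, (cx, cy, cz), lin)
    return best


class TestBestMatch:
    def test_exact_duplicate_has_zero_distance(self):
        rng = np.random.default_rng(4)
        vol = rng.integers(0, 255, (16, 16, 16)).astype(float)
        vol[10:13, 10:13, 10:13] = vol[2:5, 2:5, 2:5]
        known = np.ones((16,) * 3, bool)
        known[11, 11, 11] = False
        g = grid_from(vol, known)
        patch = make_patch(g, (11, 11, 11), 3)
        src, dist = best_match(g, patch)
        assert dist == 0.0
        assert src == (3, 3, 3)

    def test_tie_break_smallest_linearized_index(self):
        vol = np.zeros((12, 12, 12))
        known = np.ones((12,) * 3, bool)
        known[6, 6, 6] = False
        g = grid_from(vol, known)
        patch = make_patch(g, (6, 6, 6), 3)
        src, dist = best_match(g, patch)
        assert dist == 0.0
        assert src == (1, 1, 1)  # first center whose 3^3 patch avoids the hole

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        # small alphabet forces plenty of SAD ties
        vol = rng.integers(0, 4, (n, n, n)).astype(float) * 60
        known = np.ones((n, n, n), bool)
        c = tuple(int(x) for x in rng.integers(3, n - 3, 3))
        size = int(rng.choice([3, 5]))
        hole = 0 if size == 3 else 1  # keep some known support in the patch
        known[c[0] - hole:c[0] + hole + 1, c[1] - hole:c[1] + hole + 1,
              c[2] - hole:c[2] + hole + 1] = False
        g = grid_from(vol, known)
        patch = make_patch(g, c, size)
        src, dist = best_match(g, patch)
        sad, src_bf, _ = brute_force_best_match(g, patch)
        assert src == src_bf
        assert dist == pytest.approx(sad)

    def test_search_window_restricts_candidates(self):
        rng = np.random.default_rng(40)
        vol = rng.integers(0, 255, (20, 20, 20)).astype(float)
        known = np.ones((20,) * 3, bool)
        known[10, 10, 10] = False
        g = grid_from(vol, known)
        patch = make_patch(g, (10, 10, 10), 3)
        src, _ = best_match(g, patch, search_window=3)
        assert all(abs(src[a] - 10) <= 3 for a in range(3))

    def test_no_candidate_raises_fill_error(self):
        known = np.zeros((6, 6, 6), bool)
        known[0, 0, 0] = True  # nothing else known: no overlap candidates
        g = grid_from(np.zeros((6,) * 3), known)
        g.known_mask[3, 3, 3] = False
        patch = make_patch(g, (3, 3, 3), 5)
        with pytest.raises(FillError):
            best_match(g, patch)


class TestCopyAndUpdate:
    def test_vacant_target_voxels_filled_known_preserved(self):
        rng = np.random.default_rng(6)
        vol = rng.integers(0, 255, (14, 14, 14)).astype(float)
        known = np.ones((14,) * 3, bool)
        known[6:9, 6:9, 6:9] = False
        g = grid_from(vol, known)
        before = g.intensity.copy()
        conf = known.astype(float)
        conf[7, 7, 7] = 0.5
        patch = make_patch(g, (7, 7, 7), 5)
        filled = copy_and_update(g, conf, (7, 7, 7), (2, 2, 2), patch)
        assert len(filled) == 27
        assert g.known_mask[5:10, 5:10, 5:10].all()
        np.testing.assert_array_equal(g.intensity[known], before[known])
        for p in filled:
            assert conf[p] == 0.5
            src = tuple(np.add(p, (2 - 7, 2 - 7, 2 - 7)))
            assert g.intensity[p] == vol[src]


class TestHoleFill:
    def test_no_vacancy_returns_input_unchanged(self):
        g = full_grid(np.arange(125, dtype=float).reshape(5, 5, 5))
        before = g.intensity.copy()
        hole_fill(g)
        np.testing.assert_array_equal(g.intensity, before)

    def test_all_vacant_grid_raises(self):
        g = grid_from(np.zeros((5, 5, 5)), np.zeros((5, 5, 5), bool))
        with pytest.raises(ValueError):
            hole_fill(g)

    def _periodic(self, n=24, p=4, seed=0):
        rng = np.random.default_rng(seed)
        tile = rng.integers(0, 255, (p, p, p)).astype(float)
        return np.tile(tile, (n // p,) * 3)

    def test_periodic_texture_restored_exactly(self):
        vol = self._periodic()
        known = np.ones(vol.shape, bool)
        known[9:15, 9:15, 9:15] = False
        g = grid_from(vol, known)
        hole_fill(g)
        np.testing.assert_array_equal(g.intensity, vol)

    def test_two_disjoint_holes_both_filled(self):
        vol = self._periodic()
        known = np.ones(vol.shape, bool)
        known[3:6, 3:6, 3:6] = False
        known[16:20, 16:20, 16:20] = False
        g = grid_from(vol, known)
        hole_fill(g)
        assert g.known_mask.all()
        np.testing.assert_array_equal(g.intensity, vol)

    def test_known_voxels_bit_identical_after_fill(self):
        rng = np.random.default_rng(9)
        vol = rng.integers(0, 255, (16, 16, 16)).astype(float)
        known = np.ones((16,) * 3, bool)
        known[5:11, 5:11, 5:11] = False
        g = grid_from(vol, known)
        before = g.intensity.copy()
        hole_fill(g)
        np.testing.assert_array_equal(g.intensity[known], before[known])
        assert g.known_mask.all()

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(10)
        vol = rng.integers(0, 255, (16, 16, 16)).astype(float)
        known = np.ones((16,) * 3, bool)
        known[4:10, 6:12, 5:9] = False
        out = []
        for _ in range(2):
            g = grid_from(vol, known)
            hole_fill(g)
            out.append(g.intensity.copy())
        np.testing.assert_array_equal(out[0], out[1])

    def test_vacancy_strictly_decreases_each_iteration(self):
        rng = np.random.default_rng(11)
        vol = rng.integers(0, 255, (14, 14, 14)).astype(float)
        known = np.ones((14,) * 3, bool)
        known[4:10, 4:10, 4:10] = False
        g = grid_from(vol, known)
        counts = []

        def cb(grid, conf, state):
            counts.append(int((~grid.known_mask).sum()))
            return False

        hole_fill(g, callback=cb)
        assert all(b < a for a, b in zip([216] + counts, counts))
        assert counts[-1] == 0

    def test_confidence_bounded_and_inherited(self):
        rng = np.random.default_rng(12)
        vol = rng.integers(0, 255, (14, 14, 14)).astype(float)
        known = np.ones((14,) * 3, bool)
        known[4:10, 4:10, 4:10] = False
        g = grid_from(vol, known)
        conf = known.astype(float)
        hole_fill(g, confidence_field=conf)
        assert np.all(conf >= 0.0) and np.all(conf <= 1.0)
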