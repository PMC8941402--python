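import numpy as np
import pytest

from hairfield import (
    compute_metrics,
    coupling_parameter,
    directional_areas,
    extract_contours,
    kappa_profile,
    make_row_array,
    overlap_ratio,
    solve_equilibrium,
    total_sensory_area,
)
from hairfield.deflection import deflection_field, estimate_domain, solve_charges
from hairfield.metrics import _membership, contour_polygon_area

pytestmark = pytest.mark.filterwarnings(
    "ignore:.*narrowest contour lobe.*:UserWarning")


@pytest.fixture(scope="module")
def single_cfg():
    return make_row_array(1, K=1.0)


class TestTotalArea:
    def test_zero_charge(self, single_cfg):
        assert total_sensory_area(single_cfg, 0.0) == 0.0

    def test_matches_monte_carlo_membership(self, single_cfg):
        # independent oracle: uniform sampling + fresh membership solves
        eq = solve_equilibrium(single_cfg)
        bounds = estimate_domain(single_cfg, 10.0, 1e-3)
        area_grid = total_sensory_area(single_cfg, 10.0, bounds=bounds,
                                       nx=301, ny=301)
        rng = np.random.default_rng(7)
        M = 100_000
        pts = np.column_stack([
            rng.uniform(bounds[0], bounds[1], M),
            rng.uniform(bounds[2], bounds[3], M),
        ])
        delta, ok = solve_charges(single_cfg, eq, pts, 10.0)
        frac = np.mean((np.abs(delta[:, 0]) >= 1e-3) & ok)
        area_mc = frac * (bounds[1] - bounds[0]) * (bounds[3] - bounds[2])
        assert area_grid == pytest.approx(area_mc, rel=0.02)

    def test_matches_polygonized_contours(self, single_cfg):
        # cross-check cell counting against the polygon union of the
        # extracted closed branches
        eq = solve_equilibrium(single_cfg)
        fg = deflection_field(single_cfg, 10.0, nx=401, ny=401, equilibrium=eq)
        poly = contour_polygon_area(extract_contours(fg, 1e-3)[0])
        cells = float(_membership(fg, 1e-3)[0].sum()) * fg.cell_area
        assert poly == pytest.approx(cells, rel=0.01)

    def test_area_shrinks_with_spacing(self):
        a_close = total_sensory_area(make_row_array(2, delta=0.1, K=10.0), 10.0,
                                     nx=201, ny=201)
        a_far = total_sensory_area(make_row_array(2, delta=10.0, K=10.0), 10.0,
                                   nx=201, ny=201)
        assert a_close < a_far


class TestOverlapRatio:
    def test_bounded(self):
        r = overlap_ratio(make_row_array(2, delta=1.0, K=1.0), 10.0,
                          nx=201, ny=201)
        assert 0.0 <= r <= 1.0

    def test_interior_maximum_in_spacing(self):
        deltas = [0.01, 0.1, 1.0, 3.0, 10.0]
        ratios = [overlap_ratio(make_row_array(2, delta=d, K=1.0), 10.0,
                                nx=201, ny=201) for d in deltas]
        peak = int(np.argmax(ratios))
        assert 0 < peak < len(deltas) - 1

    def test_overall_decrease_with_K(self):
        deltas = [0.1, 1.0, 10.0]
        mean_small = np.mean([overlap_ratio(make_row_array(2, delta=d, K=0.1),
                                            10.0, nx=201, ny=201) for d in deltas])
        mean_large = np.mean([overlap_ratio(make_row_array(2, delta=d, K=10.0),
                                            10.0, nx=201, ny=201) for d in deltas])
        assert mean_large < mean_small

    def test_decoupled_pair_matches_isolated_hairs(self):
        # delta = 100 with K = 0.1: each hair behaves as if alone
        cfg = make_row_array(2, delta=100.0, K=0.1)
        eq = solve_equilibrium(cfg)
        bounds = estimate_domain(cfg, 10.0, 1e-3)
        fg = deflection_field(cfg, 10.0, bounds=bounds, nx=301, ny=301,
                              equilibrium=eq)
        member = _membership(fg, 1e-3)
        XX, YY = np.meshgrid(fg.x_coords, fg.y_coords)
        pts = np.column_stack([XX.ravel(), YY.ravel()])
        for h in range(2):
            solo = cfg.single_hair(h)
            solo_eq = solve_equilibrium(solo)
            delta, ok = solve_charges(solo, solo_eq, pts, 10.0)
            solo_member = ((np.abs(delta[:, 0]) >= 1e-3) & ok).reshape(member[h].shape)
            a_pair = member[h].sum() * fg.cell_area
            a_solo = solo_member.sum() * fg.cell_area
            assert a_pair == pytest.approx(a_solo, rel=0.02)


class TestDirectionalAreas:
    def test_upright_uncoupled_symmetric(self, single_cfg):
        left, right = directional_areas(single_cfg, 0, 10.0,
                                        reference="uncoupled_rotated",
                                        nx=301, ny=301)
        assert left == pytest.approx(right, rel=0.01)

    def test_tilted_hair_mirror(self):
        lm, rm = directional_areas(make_row_array(1, K=1.0, resting_angles=-0.3),
                                   0, 10.0, nx=301, ny=301)
        lp, rp = directional_areas(make_row_array(1, K=1.0, resting_angles=0.3),
                                   0, 10.0, nx=301, ny=301)
        assert lm != rm  # tilt breaks the symmetry
        # mirror image case swaps the sides (up to the split-column cell row)
        assert lm == pytest.approx(rp, rel=0.02)
        assert rm == pytest.approx(lp, rel=0.02)

    def test_coupled_left_hair_prefers_right(self):
        left, right = directional_areas(make_row_array(2, delta=1.0, K=10.0),
                                        0, 10.0, reference="coupled",
                                        nx=301, ny=301)
        assert right > left


class TestCouplingParameter:
    def test_no_change(self):
        assert coupling_parameter(1e-3, 1e-3) == 0.0

    def test_enhancement(self):
        assert coupling_parameter(5e-4, 1e-3) == pytest.approx(-1.0)

    def test_inhibition(self):
        assert coupling_parameter(2e-3, 1e-3) == pytest.approx(0.5)

    def test_undefined(self):
        assert coupling_parameter(0.0, 1e-3) is None


class TestKappaProfile:
    def test_symmetric_pair_symmetric_profile(self):
        prof = kappa_profile(make_row_array(2, delta=1.0, K=1.0), 10.0,
                             nx=301, ny=301)
        ks = np.array([k for _, k in prof])
        diff = np.abs(ks - ks[::-1])
        assert np.nanmax(diff) <= 0.05

    def test_decoupled_limit_kappa_vanishes(self):
        # delta = 10, K = 1: off-axis bins show no coupling effect
        prof = kappa_profile(make_row_array(2, delta=10.0, K=1.0), 10.0,
                             nx=301, ny=301)
        arr = np.array(prof)
        far = np.abs(arr[:, 0]) > np.pi / 6
        ks = arr[far, 1]
        assert np.nanmax(np.abs(ks)) < 0.05

    def test_strong_coupling_mostly_enhancing(self):
        prof = kappa_profile(make_row_array(2, delta=0.01, K=1.0), 10.0,
                             nx=301, ny=301)
        ks = np.array([k for _, k in prof])
        fin = np.isfinite(ks)
        assert np.mean(ks[fin] < 0) > 0.5


class TestReport:
    def test_report_consistency(self):
        rep = compute_metrics(make_row_array(2, delta=1.0, K=1.0), 10.0,
                              nx=201, ny=201)
        assert 0 <= rep.overlap_area <= rep.total_area
        assert rep.overlap_ratio == pytest.approx(
            rep.overlap_area / rep.total_area)
        assert rep.left_area >= 0 and rep.right_area >= 0
        assert len(rep.kappa_profile) == 73
        assert rep.provenance["n_hairs"] == 2
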