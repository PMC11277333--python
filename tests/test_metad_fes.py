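import numpy as np
import pytest

from pkfunnel.fixtures import FixtureSpec, make_hills
from pkfunnel.metad_fes import (
    FESProfile,
    HillsFormatError,
    HillsRecord,
    KJ_PER_KCAL,
    accept_candidate,
    fes_from_hills,
    find_basins,
    read_hills,
    write_hills,
)


class TestReadHills:
    def test_three_line_fixture(self):
        text = "# header\n0.0 1.0 0.2 1.5\n1.0 1.1 0.2 1.5\n2.0 1.2 0.2 1.5 10.0\n"
        records = read_hills(text)
        assert len(records) == 3
        assert records[2].bias_factor == 10.0
        assert records[0].bias_factor is None

    def test_comments_only_raises(self):
        with pytest.raises(HillsFormatError):
            read_hills("# only\n# comments\n")

    def test_malformed_line_reports_line_number(self):
        with pytest.raises(HillsFormatError, match="line 2"):
            read_hills("0.0 1.0 0.2 1.5\n1.0 nan-ish x\n")

    def test_non_monotone_time_warns(self):
        with pytest.warns(UserWarning):
            read_hills("5.0 1.0 0.2 1.0\n1.0 1.0 0.2 1.0\n")

    def test_thousand_random_hills_against_line_parser(self):
        rng = np.random.default_rng(0)
        lines = []
        for t in range(1000):
            c, w, h = rng.uniform(0, 5), rng.uniform(0.1, 0.4), rng.uniform(0, 2)
            lines.append(f"{float(t)} {c} {w} {h}")
        text = "\n".join(lines)
        records = read_hills(text)
        assert len(records) == 1000
        # independent per-line split oracle for column order
        for line, rec in zip(text.splitlines(), records):
            cols = [float(x) for x in line.split()]
            assert (rec.time, rec.center, rec.width, rec.height) == tuple(cols)

    def test_invalid_hill_parameters_raise(self):
        with pytest.raises(ValueError):
            HillsRecord(time=0, center=0, width=-0.1, height=1.0)
        with pytest.raises(ValueError):
            HillsRecord(time=0, center=0, width=0.1, height=-1.0)
        with pytest.raises(ValueError):
            HillsRecord(time=0, center=0, width=0.1, height=1.0, bias_factor=0.5)

    def test_write_read_round_trip(self):
        fixture = make_hills(FixtureSpec(seed=2), basins=[(1.0, 10.0)])
        again = read_hills(write_hills(fixture.records))
        assert [r.center for r in again] == pytest.approx(
            [r.center for r in fixture.records]
        )


class TestFesFromHills:
    def test_single_hill_closed_form(self):
        h, c, sigma = 2.5, 1.0, 0.3
        profile = fes_from_hills(
            [HillsRecord(time=0, center=c, width=sigma, height=h)],
            grid_min=c - 3 * sigma, grid_max=c + 3 * sigma, n_points=601,
        )
        idx = np.argmin(profile.free_energy)
        assert profile.grid[idx] == pytest.approx(c, abs=1e-9)
        assert profile.free_energy[idx] == pytest.approx(0.0, abs=1e-12)
        edge = profile.free_energy[-1]
        assert edge == pytest.approx(h * (1 - np.exp(-4.5)), rel=1e-9)

    def test_no_hills_is_flat_zero(self):
        profile = fes_from_hills([], 0.0, 5.0, 100)
        np.testing.assert_array_equal(profile.free_energy, 0.0)

    def test_matches_high_precision_brute_force(self):
        rng = np.random.default_rng(1)
        hills = [
            HillsRecord(
                time=float(t),
                center=float(rng.uniform(0, 5)),
                width=float(rng.uniform(0.1, 0.5)),
                height=float(rng.uniform(0.1, 2.0)),
            )
            for t in range(200)
        ]
        grid_pts = np.sort(rng.uniform(0, 5, size=50))
        profile = fes_from_hills(hills, 0.0, 5.0, 400, shift_to_zero=False)
        # brute-force double loop in extended precision
        expected = np.zeros(400, dtype=np.longdouble)
        grid = np.linspace(0, 5, 400, dtype=np.longdouble)
        for hill in hills:
            expected -= np.longdouble(hill.height) * np.exp(
                -((grid - np.longdouble(hill.center)) ** 2)
                / (2 * np.longdouble(hill.width) ** 2)
            )
        rel = np.abs(profile.free_energy - expected.astype(float)) / np.abs(expected).max()
        assert rel.max() < 1e-10

    def test_well_tempered_rescaling(self):
        gamma = 10.0
        plain = fes_from_hills(
            [HillsRecord(time=0, center=1.0, width=0.2, height=1.0)],
            0.0, 2.0, 101, shift_to_zero=False,
        )
        wt = fes_from_hills(
            [HillsRecord(time=0, center=1.0, width=0.2, height=1.0, bias_factor=gamma)],
            0.0, 2.0, 101, shift_to_zero=False,
        )
        np.testing.assert_allclose(
            wt.free_energy, plain.free_energy * gamma / (gamma - 1), rtol=1e-12
        )

    def test_linearity_of_concatenated_hill_lists(self):
        rng = np.random.default_rng(2)
        mk = lambda n, salt: [
            HillsRecord(time=float(i), center=float(rng.uniform(0, 3)),
                        width=0.25, height=float(rng.uniform(0.2, 1.0)))
            for i in range(n)
        ]
        a, b = mk(30, 0), mk(40, 1)
        fa = fes_from_hills(a, 0, 3, 200, shift_to_zero=False).free_energy
        fb = fes_from_hills(b, 0, 3, 200, shift_to_zero=False).free_energy
        fab = fes_from_hills(a + b, 0, 3, 200, shift_to_zero=False).free_energy
        np.testing.assert_allclose(fab, fa + fb, rtol=1e-12, atol=1e-12)

    def test_min_shifted_to_zero_and_kcal_conversion(self):
        fixture = make_hills(FixtureSpec(seed=3), basins=[(1.0, 20.0)])
        profile = fes_from_hills(read_hills(fixture.text), -1, 3, 300)
        assert profile.free_energy.min() == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(
            profile.in_kcal() * KJ_PER_KCAL, profile.free_energy, rtol=1e-15
        )

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            fes_from_hills([], 1.0, 0.0, 100)
        with pytest.raises(ValueError):
            fes_from_hills([], 0.0, 1.0, 1)


def _brute_force_minima(f):
    """Exhaustive neighbor-comparison oracle (plateaus to leftmost point)."""
    out = []
    n = len(f)
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and f[j + 1] == f[j]:
            j += 1
        if f[i - 1] > f[i] and j + 1 < n and f[j + 1] > f[j]:
            out.append(i)
        i = j + 1
    return out


class TestFindBasins:
    def test_v_shaped_profile_single_basin(self):
        grid = np.linspace(-1, 1, 101)
        profile = FESProfile(grid=grid, free_energy=np.abs(grid) * 10)
        basins = find_basins(profile)
        interior = [b for b in basins if not b.is_boundary]
        assert len(interior) == 1
        assert interior[0].cv_location == pytest.approx(0.0, abs=1e-12)
        assert interior[0].is_global_minimum

    def test_monotone_profile_reports_boundary_minimum(self):
        grid = np.linspace(0, 1, 50)
        profile = FESProfile(grid=grid, free_energy=grid * 5)
        basins = find_basins(profile)
        assert len(basins) == 1
        assert basins[0].is_boundary
        assert basins[0].grid_index == 0
        assert basins[0].is_global_minimum

    def test_plateau_resolves_to_leftmost_point(self):
        f = np.array([3.0, 1.0, 1.0, 1.0, 3.0, 4.0])
        profile = FESProfile(grid=np.arange(6.0), free_energy=f - f.min())
        basins = find_basins(profile, include_boundary=False)
        assert [b.grid_index for b in basins] == [1]

    @pytest.mark.parametrize("seed", range(5))
    def test_random_smooth_profile_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        grid = np.linspace(0, 10, 300)
        f = np.zeros_like(grid)
        for _ in range(6):
            c, w, h = rng.uniform(0, 10), rng.uniform(0.3, 1.0), rng.uniform(1, 10)
            f -= h * np.exp(-((grid - c) ** 2) / (2 * w**2))
        f -= f.min()
        profile = FESProfile(grid=grid, free_energy=f)
        basins = find_basins(profile, include_boundary=False)
        assert [b.grid_index for b in basins] == _brute_force_minima(f)

    def test_min_depth_filters_shallow_interior_basins(self):
        grid = np.linspace(0, 4, 401)
        f = -10 * np.exp(-((grid - 1) ** 2) / 0.08) - 0.5 * np.exp(-((grid - 3) ** 2) / 0.08)
        profile = FESProfile(grid=grid, free_energy=f - f.min())
        deep = find_basins(profile, min_depth=2.0, include_boundary=False)
        assert len(deep) == 1
        assert deep[0].cv_location == pytest.approx(1.0, abs=0.02)


class TestAcceptCandidate:
    def _two_basin_profile(self, bound_depth, unbound_depth):
        grid = np.linspace(-0.5, 4, 500)
        f = -bound_depth * np.exp(-((grid - 2.0) ** 2) / 0.1)
        f -= unbound_depth * np.exp(-(grid**2) / 0.1)
        return FESProfile(grid=grid, free_energy=f - f.min())

    def test_unbound_global_minimum_rejected(self):
        decision = accept_candidate(self._two_basin_profile(5.0, 20.0), 0.5)
        assert not decision.accepted
        assert decision.basin_cv == pytest.approx(0.0, abs=0.05)

    def test_bound_global_minimum_accepted(self):
        decision = accept_candidate(self._two_basin_profile(20.0, 5.0), 0.5)
        assert decision.accepted
        assert decision.basin_cv == pytest.approx(2.0, abs=0.05)
        assert decision.margin == pytest.approx(decision.basin_cv - 0.5)

    def test_flipping_depths_flips_decision(self):
        a = accept_candidate(self._two_basin_profile(15.0, 3.0), 0.5)
        b = accept_candidate(self._two_basin_profile(3.0, 15.0), 0.5)
        assert a.accepted and not b.accepted

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_global_argmin_oracle_on_random_profiles(self, seed):
        rng = np.random.default_rng(seed)
        grid = np.linspace(0, 6, 400)
        f = np.zeros_like(grid)
        for _ in range(5):
            c, w, h = rng.uniform(0, 6), rng.uniform(0.2, 0.8), rng.uniform(2, 15)
            f -= h * np.exp(-((grid - c) ** 2) / (2 * w**2))
        profile = FESProfile(grid=grid, free_energy=f - f.min())
        threshold = rng.uniform(0.2, 3.0)
        decision = accept_candidate(profile, threshold)
        assert decision.accepted == (grid[np.argmin(f)] > threshold)


class TestRefinementStability:
    def test_doubling_resolution_moves_basins_less_than_coarse_cell(self):
        fixture = make_hills(FixtureSpec(seed=5), basins=[(2.0, 25.0), (0.3, 10.0)])
        hills = read_hills(fixture.text)
        coarse = fes_from_hills(hills, -0.5, 3.5, 200)
        fine = fes_from_hills(hills, -0.5, 3.5, 400)
        cell = coarse.grid[1] - coarse.grid[0]
        loc_c = next(b for b in find_basins(coarse) if b.is_global_minimum).cv_location
        loc_f = next(b for b in find_basins(fine) if b.is_global_minimum).cv_location
        assert abs(loc_c - loc_f) < cell
        assert abs(loc_c - 2.0) < 3 * cell
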