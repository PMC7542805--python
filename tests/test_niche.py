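"""Niche densities, background correction and Schoener's D.

The full density -> occupancy -> overlap chain is checked against a naive,
loop-based reimplementation that shares only the published formulas
(Gaussian product kernel with per-axis Silverman bandwidth floored at half a
bin width, ratio-to-background correction, D = 1 - 0.5 * sum |z1 - z2|).
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nichetrack.niche import (
    InsufficientDataError,
    build_grid,
    corrected_occupancy,
    kernel_density,
    occupancy,
    schoener_d,
    seasonal_overlaps,
)

AXES3 = ("temperature", "precipitation", "ndvi")


# ---------------------------------------------------------------- oracle ---

def naive_bandwidth(v, d):
    n = len(v)
    sd = np.std(v, ddof=1)
    q75, q25 = np.percentile(v, [75, 25])
    sigma = min(sd, (q75 - q25) / 1.34) if (q75 - q25) > 0 else sd
    if sigma <= 0:
        sigma = max(abs(np.max(v)), 1.0) * 1e-3
    return sigma * (4.0 / (d + 2)) ** (1.0 / (d + 4)) * n ** (-1.0 / (d + 4))


def naive_kde(values, edges_list):
    """Double-loop product-Gaussian KDE at cell midpoints, sum-normalized."""
    values = np.asarray(values, float)
    d = values.shape[1]
    mids = [0.5 * (e[:-1] + e[1:]) for e in edges_list]
    hs = []
    for a in range(d):
        h = naive_bandwidth(values[:, a], d)
        width = mids[a][1] - mids[a][0] if len(mids[a]) > 1 else 2e-12
        hs.append(max(h, 0.5 * width))
    shape = tuple(len(m) for m in mids)
    dens = np.zeros(shape)
    for idx in np.ndindex(shape):
        total = 0.0
        for p in range(len(values)):
            term = 1.0
            for a in range(d):
                u = (mids[a][idx[a]] - values[p, a]) / hs[a]
                term *= np.exp(-0.5 * u * u) / hs[a]
            total += term
        dens[idx] = total
    return dens / dens.sum()


def naive_chain_D(occ1, occ2, bkg, edges_list, floor):
    def correct(occ):
        lo = np.array([e[0] for e in edges_list])
        hi = np.array([e[-1] for e in edges_list])
        z_occ = naive_kde(np.clip(occ, lo, hi), edges_list)
        z_bkg = naive_kde(bkg, edges_list)
        ratio = np.divide(z_occ, z_bkg, out=np.zeros_like(z_occ), where=z_bkg > floor)
        z = np.where(z_bkg > floor, ratio, 0.0)
        return z / z.sum()

    z1, z2 = correct(occ1), correct(occ2)
    return 1.0 - 0.5 * np.abs(z1 - z2).sum()


# ----------------------------------------------------------------- tests ---

class TestBuildGrid:
    def test_integer_background_gives_unit_edges(self):
        bkg = pd.DataFrame({"temperature": np.arange(11, dtype=float)})
        grid = build_grid(bkg, ("temperature",), 10)
        np.testing.assert_allclose(grid.edges[0], np.arange(11.0))

    def test_constant_axis_rejected(self):
        bkg = pd.DataFrame({"temperature": np.ones(50)})
        with pytest.raises(ValueError, match="degenerate"):
            build_grid(bkg, ("temperature",), 10)

    def test_clamp_counts_out_of_range_values(self):
        bkg = pd.DataFrame({"temperature": np.linspace(0, 10, 50)})
        grid = build_grid(bkg, ("temperature",), 10)
        vals = np.array([[5.0], [10.0], [12.0], [-3.0]])
        clipped, n = grid.clamp(vals)
        assert n == 2
        assert clipped.max() == 10.0 and clipped.min() == 0.0


class TestKernelDensity:
    def test_sums_to_one(self, rng):
        bkg = pd.DataFrame({"temperature": rng.normal(0, 1, 200)})
        grid = build_grid(bkg, ("temperature",), 25)
        dens = kernel_density(bkg, grid)
        assert abs(dens.sum() - 1.0) < 1e-9

    def test_matches_bruteforce_1d(self, rng):
        bkg = pd.DataFrame({"temperature": rng.normal(5, 2, 60)})
        grid = build_grid(bkg, ("temperature",), 10)
        vals = rng.normal(5, 2, size=(10, 1))
        fast = kernel_density(vals, grid)
        slow = naive_kde(vals, [grid.edges[0]])
        np.testing.assert_allclose(fast, slow, atol=1e-9)

    def test_single_point_peaks_at_its_cell(self):
        bkg = pd.DataFrame({"temperature": np.linspace(0, 10, 100)})
        grid = build_grid(bkg, ("temperature",), 11)
        mid = grid.midpoints(0)[5]
        dens = kernel_density(np.full((5, 1), mid), grid)
        assert dens.argmax() == 5
        np.testing.assert_allclose(dens, dens[::-1], atol=1e-12)  # symmetric decay

    def test_too_few_points_raise(self):
        bkg = pd.DataFrame({"temperature": np.linspace(0, 1, 50)})
        grid = build_grid(bkg, ("temperature",), 10)
        with pytest.raises(InsufficientDataError):
            kernel_density(np.array([[0.5]]), grid)


class TestOccupancy:
    def test_occurrence_equal_background_gives_uniform(self, rng):
        z = rng.dirichlet(np.ones(30))
        out, _ = occupancy(z, z, floor=0.0)
        np.testing.assert_allclose(out, np.full(30, 1 / 30), atol=1e-12)

    def test_unsupported_cell_masked_and_counted(self):
        z_occ = np.array([0.5, 0.5])
        z_bkg = np.array([1.0, 0.0])
        z, n_unsupported = occupancy(z_occ, z_bkg, floor=0.0)
        np.testing.assert_allclose(z, [1.0, 0.0])
        assert n_unsupported == 1

    def test_two_cell_hand_example(self):
        z, _ = occupancy(np.array([0.8, 0.2]), np.array([0.5, 0.5]), floor=0.0)
        np.testing.assert_allclose(z, [0.8, 0.2])  # 1.6:0.4 renormalized

    def test_empty_niche_rejected(self):
        with pytest.raises(ValueError, match="empty niche"):
            occupancy(np.array([1.0, 0.0]), np.array([0.0, 1.0]), floor=0.0)


class TestSchoenerD:
    def test_analytic_cases(self):
        z = np.array([0.25, 0.5, 0.25])
        assert schoener_d(z, z) == pytest.approx(1.0)
        assert schoener_d(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0
        assert schoener_d(np.array([1.0, 0.0]), np.array([0.5, 0.5])) == pytest.approx(0.5)

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError):
            schoener_d(np.ones(3) / 3, np.ones(4) / 4)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_cell_permutation_invariance(self, seed):
        r = np.random.default_rng(seed)
        z1 = r.dirichlet(np.ones(20))
        z2 = r.dirichlet(np.ones(20))
        d = schoener_d(z1, z2)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(schoener_d(z2, z1))
        perm = r.permutation(20)
        assert d == pytest.approx(schoener_d(z1[perm], z2[perm]))


class TestChainEquivalence:
    @pytest.mark.parametrize("axes,R,n_occ", [(("temperature",), 10, 40), (AXES3, 6, 60)])
    def test_full_chain_matches_naive_reimplementation(self, rng, axes, R, n_occ):
        n_bkg = 200
        bkg = pd.DataFrame(
            {
                "temperature": rng.normal(15, 5, n_bkg),
                "precipitation": rng.gamma(2, 1.5, n_bkg),
                "ndvi": rng.uniform(0, 1, n_bkg),
            }
        )
        occ1 = bkg.iloc[:n_occ].reset_index(drop=True)
        occ2 = bkg.iloc[n_occ : 2 * n_occ].reset_index(drop=True)
        grid = build_grid(bkg, axes, R)
        floor = 1e-3 / np.prod([R] * len(axes))
        g1 = corrected_occupancy(occ1, bkg, grid)
        g2 = corrected_occupancy(occ2, bkg, grid)
        fast = schoener_d(g1.z, g2.z)
        slow = naive_chain_D(
            occ1[list(axes)].to_numpy(),
            occ2[list(axes)].to_numpy(),
            bkg[list(axes)].to_numpy(),
            [grid.edges[a] for a in range(len(axes))],
            floor,
        )
        assert fast == pytest.approx(slow, abs=1e-8)

    def test_refinement_stability(self, rng):
        """Doubling the grid resolution moves D by less than 0.05."""
        bkg = pd.DataFrame({"temperature": rng.normal(10, 4, 2000)})
        occ1 = pd.DataFrame({"temperature": rng.normal(8, 2, 300)})
        occ2 = pd.DataFrame({"temperature": rng.normal(12, 2, 300)})
        ds = []
        for R in (50, 100):
            grid = build_grid(bkg, ("temperature",), R)
            g1 = corrected_occupancy(occ1, bkg, grid)
            g2 = corrected_occupancy(occ2, bkg, grid)
            ds.append(schoener_d(g1.z, g2.z))
        assert abs(ds[1] - ds[0]) < 0.05


def test_population_density_uses_pooled_points(small_env, rng):
    """Population-level D equals the overlap of pooled-occupancy grids."""
    import nichetrack.background as bgmod

    pts = []
    for ind in ("E01", "E02"):
        for season, month in (("summer", 7), ("autumn", 9)):
            n = 40
            pts.append(
                pd.DataFrame(
                    {
                        "individual_id": ind,
                        "flyway": "eastern",
                        "cycle_year": 2015,
                        "season": season,
                        "x_km": rng.uniform(40, 260, n),
                        "y_km": rng.uniform(40, 260, n),
                        "timestamp": pd.Timestamp(f"2015-{month:02d}-10"),
                    }
                )
            )
    points = pd.concat(pts, ignore_index=True)
    bg = bgmod.build_background("eastern", points, small_env, n_background=1500, seed=3)
    res = seasonal_overlaps(
        points, {"eastern": bg}, small_env, levels=("population",),
        modes=("climate",), variable_sets=("all",), R_3d=12,
    )
    assert len(res) == 1
    row = res.iloc[0]
    # recompute directly from the pooled points of both individuals
    b1 = bg.annotation("summer", "climate")
    b2 = bg.annotation("autumn", "climate")
    grid = build_grid(pd.concat([b1, b2], ignore_index=True), AXES3, 12)
    occ1 = bgmod.annotate_occurrences(
        points[points["season"] == "summer"], small_env, "summer", "climate"
    )
    occ2 = bgmod.annotate_occurrences(
        points[points["season"] == "autumn"], small_env, "autumn", "climate"
    )
    g1 = corrected_occupancy(occ1, b1, grid)
    g2 = corrected_occupancy(occ2, b2, grid)
    assert row["D"] == pytest.approx(schoener_d(g1.z, g2.z))
    assert row["n1"] == 80 and row["n2"] == 80
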