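"""PMF estimation, rescaling, free energies, entropy and block errors."""

import numpy as np
import pytest

from crystalign import thermo as th
from crystalign.errors import ConvergenceError, CrystalignError
from crystalign.trajio import KB, BiasGrid, CVSeries

KT = KB * 300.0


def _uniform_cv(n_per_bin=50, n_bins=20, lo=0.0, hi=1.0):
    """CV series hitting every bin centre exactly n_per_bin times."""
    centers = np.linspace(lo, hi, n_bins, endpoint=False) + (hi - lo) / (2 * n_bins)
    s = np.tile(centers, n_per_bin)
    return CVSeries(time=np.arange(1.0, len(s) + 1), s=s)


def _zero_bias(lo=-0.1, hi=1.1):
    return BiasGrid(s_min=lo, s_max=hi, n_bins=10, values=np.zeros(11))


def test_pmf_uniform_density_zero_bias_is_flat():
    cv = _uniform_cv()
    prof = th.pmf_from_bias(cv, _zero_bias(), 20, 300.0)
    np.testing.assert_allclose(prof.values, 0.0, atol=1e-12)


def test_pmf_linear_in_temperature():
    rng = np.random.default_rng(0)
    s = rng.uniform(0, 1, 20000)
    cv = CVSeries(time=np.arange(1.0, len(s) + 1), s=s)
    p1 = th.pmf_from_bias(cv, _zero_bias(), 25, 300.0)
    p2 = th.pmf_from_bias(cv, _zero_bias(), 25, 600.0)
    np.testing.assert_allclose(p2.values, 2.0 * p1.values, atol=1e-10)


def test_pmf_anchoring_invariant_under_bias_offset():
    rng = np.random.default_rng(1)
    s = rng.uniform(0, 1, 20000)
    cv = CVSeries(time=np.arange(1.0, len(s) + 1), s=s)
    shifted = BiasGrid(s_min=-0.1, s_max=1.1, n_bins=10,
                       values=np.full(11, 123.456))
    p0 = th.pmf_from_bias(cv, _zero_bias(), 25, 300.0)
    p1 = th.pmf_from_bias(cv, shifted, 25, 300.0)
    np.testing.assert_allclose(p1.values, p0.values, atol=1e-9)


def test_pmf_too_many_empty_bins_is_unconverged():
    cv = CVSeries(time=[1.0, 2.0], s=[0.5, 0.52])
    with pytest.raises(ConvergenceError, match="empty"):
        th.pmf_from_bias(cv, _zero_bias(), np.linspace(0, 1, 51), 300.0)


def test_pmf_recovers_known_profile(flat_run_medium):
    """Flat-sampled run with bias = -W_true returns W_true (plus walls)."""
    run = flat_run_medium
    edges = np.linspace(run.cv.s.min(), run.cv.s.max(), 101)
    win = (1.1, 1.5)
    prof = th.pmf_from_bias(run.cv, run.bias, edges, 300.0, win)
    c = prof.bin_centers
    m = prof.defined & (c > -0.5) & (c < 1.5)
    truth = run.truth.pmf_total(c)
    inw = (c >= win[0]) & (c <= win[1]) & prof.defined
    truth = truth - truth[inw].mean()
    rmse = np.sqrt(np.mean((prof.values[m] - truth[m]) ** 2))
    assert rmse < 0.3


# ---------------------------------------------------------------------------
# densities and rescaling
# ---------------------------------------------------------------------------

def _density_pair(ratio_counts):
    """All-states density (100/bin) and an aligned density with given counts."""
    n_bins = len(ratio_counts)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2
    total = 100 * n_bins
    all_counts = np.full(n_bins, 100)
    dens_all = th.StateDensity(
        bin_centers=centers, rho=all_counts / total, counts=all_counts,
        total_frames=total,
    )
    r = np.asarray(ratio_counts)
    dens_r = th.StateDensity(
        bin_centers=centers, rho=r / total, counts=r, total_frames=total
    )
    return dens_all, dens_r, centers


def test_rescale_identity_and_half():
    dens_all, dens_half, centers = _density_pair([50] * 10)
    bias = _zero_bias(0.0, 1.0)
    full = th.PMFProfile(bin_centers=centers, values=np.zeros(10), anchor=0.0)
    # rho_r = rho: W_r = W on every defined bin
    same = th.rescale_pmf(dens_all, bias, full, 300.0)
    np.testing.assert_allclose(same.values, full.values + KT * np.log(10), atol=1e-12)
    # note: the approx form keeps the absolute normalization, hence the
    # constant -kT ln rho; the ratio test below is normalization-free
    half = th.rescale_pmf(dens_half, bias, full, 300.0)
    np.testing.assert_allclose(half.values - same.values, KT * np.log(2), atol=1e-12)
    exact_half = th.rescale_pmf(
        dens_half, bias, full, 300.0, form="exact", density_all=dens_all
    )
    np.testing.assert_allclose(exact_half.values, KT * np.log(2), atol=1e-12)


def test_rescale_never_below_full_pmf(analysis_medium):
    res = analysis_medium
    both = res.full.defined & res.rescaled.defined
    assert np.all(res.rescaled.values[both] >= res.full.values[both] - 1e-9)


def test_aligned_density_bernoulli_flags(rng):
    import pandas as pd

    n = 200_000
    s = rng.uniform(0, 1, n)
    cv = CVSeries(time=np.arange(1.0, n + 1), s=s)
    p = 0.3
    records = pd.DataFrame(
        {"frame_index": np.arange(n), "aligned": rng.random(n) < p}
    )
    dens = th.aligned_density(records, cv, n_bins=20)
    all_counts, _ = np.histogram(s, bins=20, range=(s.min(), s.max()))
    ratio = dens.counts / all_counts
    se = np.sqrt(p * (1 - p) / all_counts)
    assert np.all(np.abs(ratio - p) < 4.5 * se)
    # degenerate flag patterns
    records["aligned"] = True
    full_d = th.aligned_density(records, cv, n_bins=20)
    np.testing.assert_array_equal(full_d.counts, all_counts)
    records["aligned"] = False
    none_d = th.aligned_density(records, cv, n_bins=20)
    assert none_d.rho.sum() == 0.0


# ---------------------------------------------------------------------------
# free energy
# ---------------------------------------------------------------------------

def test_square_well_free_energy_exact():
    """A -w square well collapses the integral ratio to exactly -w."""
    for depth, width_bins in [(10.0, 15), (3.3, 40), (25.0, 5)]:
        centers = np.linspace(0.005, 1.995, 200)
        vals = np.zeros(200)
        vals[60 : 60 + width_bins] = -depth
        prof = th.PMFProfile(bin_centers=centers, values=vals)
        fe = th.free_energy_change(prof, 300.0)
        assert fe.dG == pytest.approx(-depth, abs=1e-12)


def test_flat_profile_has_no_bound_state():
    prof = th.PMFProfile(bin_centers=np.linspace(0, 1, 50), values=np.zeros(50))
    with pytest.warns(UserWarning, match="no bound state"):
        fe = th.free_energy_change(prof, 300.0)
    assert not fe.has_bound_state and np.isnan(fe.dG)


def test_triangular_well_matches_quadrature_oracle():
    def w(s):
        return np.where(np.abs(s - 1.0) < 0.3, -8.0 * (1 - np.abs(s - 1.0) / 0.3), 0.0)

    centers = np.linspace(0.005, 1.995, 200)
    prof = th.PMFProfile(bin_centers=centers, values=w(centers))
    fe = th.free_energy_change(prof, 300.0)
    # high-resolution quadrature on the same bound interval convention
    lo, hi = fe.bound_range
    s = np.linspace(lo, hi, 200_001)
    i_b = np.trapezoid(np.exp(-w(s) / KT), s)
    oracle = -KT * np.log(i_b / (hi - lo))
    assert fe.dG == pytest.approx(oracle, abs=0.05)


def test_free_energy_stable_under_bin_refinement():
    def w(s):
        return np.where(np.abs(s - 1.0) < 0.3, -8.0 * (1 - np.abs(s - 1.0) / 0.3), 0.0)

    out = []
    for n in (200, 400):
        centers = (np.linspace(0, 2, n + 1)[:-1] + np.linspace(0, 2, n + 1)[1:]) / 2
        fe = th.free_energy_change(
            th.PMFProfile(bin_centers=centers, values=w(centers)), 300.0
        )
        out.append(fe.dG)
    assert abs(out[1] - out[0]) < 0.02


# ---------------------------------------------------------------------------
# entropy plateau
# ---------------------------------------------------------------------------

def test_entropy_plateau_constant_and_nan_handling():
    centers = np.linspace(0, 2, 100)
    vals = np.full(100, 4.0)
    prof = th.PMFProfile(bin_centers=centers, values=vals)
    assert th.entropy_plateau(prof, (1.5, 2.0)) == pytest.approx(4.0)
    vals_nan = vals.copy()
    vals_nan[80:90] = np.nan
    prof_nan = th.PMFProfile(bin_centers=centers, values=vals_nan)
    assert th.entropy_plateau(prof_nan, (1.5, 2.0)) == pytest.approx(4.0)
    with pytest.raises(CrystalignError, match="defined bins"):
        sparse = vals.copy()
        sparse[:] = np.nan
        sparse[-2:] = 4.0
        th.entropy_plateau(
            th.PMFProfile(bin_centers=centers, values=sparse), (1.5, 2.0)
        )


# ---------------------------------------------------------------------------
# block errors
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n_blocks", [10, 50])
def test_block_error_white_noise_closed_form(n_blocks):
    """SEM of the mean of N iid samples must come out near sigma/sqrt(N).

    A single SE estimate from B blocks carries ~1/sqrt(2(B-1)) sampling
    spread of its own, so the closed form is checked on the average over
    independent series.
    """
    rng = np.random.default_rng(2024)
    block = 1000
    n = n_blocks * block
    sigma = 1.7
    ses = []
    for _ in range(20):
        x = rng.normal(0.0, sigma, n)
        _, se, nb = th.block_standard_error(
            n, block, lambda sl: float(x[sl].mean())
        )
        assert nb == n_blocks
        ses.append(se)
    expected = sigma / np.sqrt(n)
    assert abs(np.mean(ses) - expected) / expected < 0.2


def test_block_error_duplicated_blocks_is_zero():
    x = np.tile(np.arange(100.0), 10)
    _, se, _ = th.block_standard_error(1000, 100, lambda sl: float(x[sl].mean()))
    assert se == 0.0


def test_block_error_insensitive_to_block_size_on_white_noise():
    rng = np.random.default_rng(7)
    x = rng.normal(size=40_000)
    _, se_a, _ = th.block_standard_error(40_000, 1000, lambda sl: float(x[sl].mean()))
    _, se_b, _ = th.block_standard_error(40_000, 500, lambda sl: float(x[sl].mean()))
    assert se_b == pytest.approx(se_a, rel=0.35)


def test_block_error_requires_five_blocks():
    with pytest.raises(CrystalignError, match="blocks"):
        th.block_standard_error(100, 50, lambda sl: 0.0)


# ---------------------------------------------------------------------------
# bridge and diagnostics
# ---------------------------------------------------------------------------

def _rescaled_profile():
    centers = np.linspace(0.01, 1.99, 100)
    vals = np.where(np.abs(centers - 0.5) < 0.2, -6.0, np.nan)
    vals[centers > 1.2] = 4.0
    return th.PMFProfile(bin_centers=centers, values=vals)


def test_bridge_constant_and_monotone():
    prof = _rescaled_profile()
    flat = th.bridge_curve(prof, (0.3, 0.7), -6.0, 1.25)
    b = flat.values[np.isfinite(flat.values)]
    np.testing.assert_allclose(b, -6.0, atol=1e-9)
    rising = th.bridge_curve(prof, (0.3, 0.7), 4.0, 1.25)
    r = rising.values[np.isfinite(rising.values)]
    assert np.all(np.diff(r) > 0)
    assert r[0] == pytest.approx(-6.0, abs=1e-6)
    assert r[-1] == pytest.approx(4.0, abs=0.5)


def test_bridge_never_enters_free_energy():
    prof = _rescaled_profile()
    fe_before = th.free_energy_change(prof, 300.0)
    th.bridge_curve(prof, (0.3, 0.7), 4.0, 1.25)
    fe_after = th.free_energy_change(prof, 300.0)
    assert fe_before.dG == fe_after.dG


def test_sampling_diagnostics_sweep_and_frozen():
    # a dense sweep of the region covers (almost) every voxel
    g = np.stack(
        np.meshgrid(
            np.linspace(0.05, 1.95, 25),
            np.linspace(0.05, 1.95, 25),
            np.linspace(1.05, 2.45, 16),
            indexing="ij",
        ),
        axis=-1,
    ).reshape(-1, 3)
    cv = CVSeries(time=np.arange(1.0, len(g) + 1), s=np.linspace(0, 1.4, len(g)))
    cov, _ = th.sampling_diagnostics(
        g, cv, np.eye(2) * 2.0, (1.0, 2.5), voxel=0.1
    )
    assert cov > 0.95
    frozen = np.tile([[0.5, 0.5, 1.5]], (2000, 1))
    cv2 = CVSeries(time=np.arange(1.0, 2001), s=np.full(2000, 0.5))
    cov2, _ = th.sampling_diagnostics(
        frozen, cv2, np.eye(2) * 2.0, (1.0, 2.5), voxel=0.1
    )
    assert cov2 == pytest.approx(1.0 / (20 * 20 * 15))
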