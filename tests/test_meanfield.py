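"""Gaussian moment closure, mixture landscapes and probability flux."""

import numpy as np
import pytest
from scipy import sparse
from scipy.sparse.linalg import spsolve
from scipy.stats import spearmanr

import grnland as gl
from grnland.meanfield import (
    LandscapeGrid,
    flux_2d,
    mixture_probability,
    potential_from_probability,
    propagate_moments,
)

from conftest import classify_motif


def _isolated_gene():
    return gl.GeneNetwork([gl.GeneNode(1, "A")], [])


# ---------------------------------------------------------------------------
# moment propagation


def test_ou_stationary_variance_is_D_over_k():
    # dx/dt = -k x with <eta eta'> = 2D delta  =>  sigma_ss = D/k
    net = _isolated_gene()
    for k, D in [(1.0, 0.05), (2.0, 0.1)]:
        b = propagate_moments(net, gl.HillParams(k=k), np.array([0.5]), D=D)
        assert b.variance[0] == pytest.approx(D / k, rel=1e-8)
        assert b.mean[0] == pytest.approx(0.0, abs=1e-8)


def test_noiseless_moments_reduce_to_ode(motif_bistable, motif_bistable_attractors):
    net, p, _ = motif_bistable
    for att in motif_bistable_attractors:
        b = propagate_moments(net, p, att.state + 0.05, D=0.0)
        assert np.max(np.abs(b.mean - att.state)) < 1e-6
        assert np.all(b.variance == 0.0)


def test_moment_variance_matches_langevin_in_basin():
    """Stationary closure variances vs sample variances of a basin-confined
    Langevin run.  The deep progenitor basin at a=1.2 keeps the trajectory
    put and both genes far from the zero boundary, where the Gaussian
    closure is meaningful (near-zero genes are clamp-dominated and outside
    its remit)."""
    net, p, _ = gl.make_two_gene_motif(1.2)
    att_state = gl.find_attractors(net, p, n_starts=50, seed=0)[0].state
    assert abs(att_state[0] - att_state[1]) < 1e-8  # the central state
    D = 0.01
    basin = propagate_moments(net, p, att_state, D=D)
    traj = gl.simulate(
        net, p, att_state, gl.SimConfig(D=D, steps=200_000, record_every=5, seed=21)
    )
    states = traj.states[2000:]
    keep = states[np.abs(states[:, 0] - states[:, 1]) < 0.8]  # stayed central
    assert keep.shape[0] > 0.999 * states.shape[0]
    sample_var = keep.var(axis=0)
    assert np.all(np.abs(sample_var - basin.variance) / basin.variance < 0.15)


def test_variance_instability_reported():
    # a gene with strong self-activation poised at the unstable threshold
    net = gl.GeneNetwork([gl.GeneNode(1, "A")], [gl.RegEdge(1, 1, "act")])
    p = gl.HillParams(a=2.0)
    with pytest.raises(gl.meanfield.VarianceInstabilityError):
        # x0 at the unstable fixed point: A_11 > 0 there
        propagate_moments(net, p, np.array([0.5]), D=0.01, t_end=1e-6)


# ---------------------------------------------------------------------------
# mixture probability


def test_single_basin_peak_contains_mean():
    basin = gl.GaussianBasin(mean=np.array([1.2, 0.7]), variance=np.array([0.02, 0.02]))
    grid = mixture_probability([basin], (0, 1), bounds=((0, 2.5), (0, 2.5)))
    i, j = np.unravel_index(np.argmax(grid.P), grid.P.shape)
    assert abs(grid.x_centers[i] - 1.2) < 0.02
    assert abs(grid.y_centers[j] - 0.7) < 0.02
    assert grid.P.sum() == pytest.approx(1.0, abs=1e-6)


def test_basin_weights_set_mass_ratio():
    b1 = gl.GaussianBasin(np.array([0.5, 0.5]), np.array([0.01, 0.01]), weight=0.1)
    b2 = gl.GaussianBasin(np.array([2.0, 2.0]), np.array([0.01, 0.01]), weight=0.9)
    grid = mixture_probability([b1, b2], (0, 1), bounds=((0, 2.5), (0, 2.5)))
    half = len(grid.x_centers) // 2
    m1 = grid.P[:half, :half].sum()
    m2 = grid.P[half:, half:].sum()
    assert m2 / m1 == pytest.approx(9.0, rel=0.02)


def test_mixture_unknown_gene_axis(motif_bistable):
    net, _, _ = motif_bistable
    basin = gl.GaussianBasin(np.array([1.0, 1.0]), np.array([0.05, 0.05]))
    with pytest.raises(KeyError):
        mixture_probability([basin], ("GATA1", "NOPE"), net=net)


# ---------------------------------------------------------------------------
# potential


def test_potential_examples():
    xe = np.linspace(0, 1, 3)
    P = np.array([[np.e**-1, np.e**-1], [np.e**-1, np.e**-1]])
    P = P / P.sum() * (4 * np.e**-1)  # keep the e^-1 values
    grid = potential_from_probability(LandscapeGrid(("x", "y"), xe, xe, P))
    assert np.allclose(grid.U, 1.0)  # P = e^-1 -> U = 1; uniform P -> constant U


def test_potential_minimum_tracks_probability_maximum():
    rng = np.random.default_rng(3)
    P = rng.random((20, 20))
    P /= P.sum()
    xe = np.linspace(0, 1, 21)
    grid = potential_from_probability(LandscapeGrid(("x", "y"), xe, xe, P))
    assert np.argmin(grid.U) == np.argmax(grid.P)


# ---------------------------------------------------------------------------
# flux


def _boltzmann_grid(D, n):
    xe = np.linspace(-2, 2, n + 1)
    xc = 0.5 * (xe[:-1] + xe[1:])
    X, Y = np.meshgrid(xc, xc, indexing="ij")
    V = (X**2 - 1) ** 2 + Y**2
    P = np.exp(-V / D)
    P /= P.sum()
    F2 = np.stack([-4 * X * (X**2 - 1), -2 * Y], axis=-1)
    return potential_from_probability(LandscapeGrid(("x", "y"), xe, xe, P)), F2


def test_flux_vanishes_for_gradient_system_boltzmann():
    """F = -grad V with P ~ exp(-V/D) is detailed balance: J -> 0 as the
    grid is refined (central differences converge at second order)."""
    D = 0.2
    rel = {}
    for n in (80, 160):
        grid, F2 = _boltzmann_grid(D, n)
        fl = flux_2d(grid, F2, D)
        Jmag = np.hypot(fl.Jx, fl.Jy).max()
        scale = np.hypot(F2[..., 0] * grid.P, F2[..., 1] * grid.P).max()
        rel[n] = Jmag / scale
    assert rel[160] < 0.02
    assert 2.5 < rel[80] / rel[160] < 6.0  # O(h^2) convergence


def test_flux_decomposition_identity():
    grid, F2 = _boltzmann_grid(0.2, 160)
    fl = flux_2d(grid, F2, 0.2)
    mask = grid.P > grid.P.max() * 1e-2
    assert np.nanmax(fl.residual[mask]) < 0.05 * np.abs(F2).max()


def test_flux_shape_mismatch():
    grid, F2 = _boltzmann_grid(0.2, 40)
    with pytest.raises(ValueError, match="shape"):
        flux_2d(grid, F2[:-1], 0.2)


def _motif_fpe_steady_state(net, p, D, m, hi=3.0):
    """Steady state of the 2-D Fokker-Planck operator by sparse solve
    (finite-volume, reflecting boundaries) — an oracle independent of both
    the Langevin sampler and the Gaussian closure."""
    from grnland.network import force_from_matrices

    xe = np.linspace(0.0, hi, m + 1)
    xc = 0.5 * (xe[:-1] + xe[1:])
    h = xc[1] - xc[0]
    X, Y = np.meshgrid(xc, xc, indexing="ij")
    Wa, Wr = net.weight_matrices(p)
    Sn = p.S**p.n
    hx = X**p.n / (Sn + X**p.n)
    hy = Y**p.n / (Sn + Y**p.n)
    FX = -p.k * X + p.a * hx + p.b * (1 - hy)
    FY = -p.k * Y + p.a * hy + p.b * (1 - hx)
    N = m * m
    rows, cols, vals = [], [], []

    def idx(i, j):
        return i * m + j

    for i in range(m):
        for j in range(m):
            for di, dj, Ff in ((1, 0, FX), (0, 1, FY)):
                ni, nj = i + di, j + dj
                if ni >= m or nj >= m:
                    continue
                Fface = 0.5 * (Ff[i, j] + Ff[ni, nj])
                a1 = (0.5 * Fface + D / h) / h
                a2 = (0.5 * Fface - D / h) / h
                rows += [idx(i, j), idx(i, j), idx(ni, nj), idx(ni, nj)]
                cols += [idx(i, j), idx(ni, nj), idx(i, j), idx(ni, nj)]
                vals += [-a1, -a2, a1, a2]
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(N, N)).tolil()
    A[N - 1, :] = 1.0
    b = np.zeros(N)
    b[N - 1] = 1.0
    P = spsolve(A.tocsr(), b)
    P = np.maximum(P.reshape(m, m), 0)
    P /= P.sum()
    return (
        potential_from_probability(LandscapeGrid(("g1", "g2"), xe, xe, P)),
        np.stack([FX, FY], axis=-1),
        h,
    )


def test_motif_steady_state_flux_divergence_small(motif_tristable):
    net, p, _ = motif_tristable
    D = 0.05
    grid, F2, h = _motif_fpe_steady_state(net, p, D, m=70)
    fl = flux_2d(grid, F2, D)
    dJx = np.gradient(fl.Jx, h, axis=0)
    dJy = np.gradient(fl.Jy, h, axis=1)
    div = (dJx + dJy)[2:-2, 2:-2]
    Jmag = np.hypot(fl.Jx, fl.Jy)[2:-2, 2:-2]
    assert np.abs(div).sum() * h / Jmag.sum() < 0.02


def test_motif_nonequilibrium_flux_is_nonzero(motif_tristable):
    """The motif is non-gradient: its steady-state curl flux does not vanish
    (in contrast to the Boltzmann case above)."""
    net, p, _ = motif_tristable
    D = 0.05
    grid, F2, h = _motif_fpe_steady_state(net, p, D, m=70)
    fl = flux_2d(grid, F2, D)
    Jmag = np.hypot(fl.Jx, fl.Jy).max()
    scale = np.hypot(F2[..., 0] * grid.P, F2[..., 1] * grid.P).max()
    assert Jmag / scale > 0.05


# ---------------------------------------------------------------------------
# mean-field vs Langevin landscape


def test_meanfield_and_langevin_landscapes_agree(
    motif_tristable, motif_tristable_attractors
):
    """The Gaussian-mixture landscape preserves the global structure of the
    sampled Langevin landscape (rank correlation over populated cells)."""
    net, p, cfg = motif_tristable
    D = cfg.D
    basins = [
        propagate_moments(net, p, a.state, D, weight=a.weight)
        for a in motif_tristable_attractors
    ]
    mf = potential_from_probability(
        mixture_probability(basins, (0, 1), bounds=((0, 3), (0, 3)), resolution=60)
    )
    traj = gl.simulate(
        net,
        p,
        motif_tristable_attractors[0].state,
        gl.SimConfig(D=D, steps=4_000_000, record_every=10, seed=5),
    )
    lg = gl.histogram_landscape(traj, (0, 1), bins=60, bounds=((0, 3), (0, 3)))
    mask = lg.P >= np.quantile(lg.P[lg.P > 0], 0.10)
    rho = spearmanr(mf.P[mask], lg.P[mask]).statistic
    assert rho >= 0.7
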