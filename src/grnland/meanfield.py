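"""Gaussian mean-field landscape: moment closure, mixtures, flux.

For weak noise the probability of each basin is approximated by a Gaussian
whose mean follows the deterministic rate equations and whose (diagonal)
variances obey the linearised moment equation

    d sigma_i / dt = 2 A_ii(x(t)) sigma_i + 2 D,

with ``A`` the Jacobian of the force field.  Cross-covariances are dropped
(mean-field factorisation), which makes marginalising the mixture onto any
two coordinates exact: dropping a coordinate simply drops its Gaussian
factor.  The steady-state probability is the basin-weighted mixture and the
landscape is ``U = -ln P_ss``.  The steady-state probability flux on a 2-D
projection is ``J = F P - D grad P``; the non-gradient (curl) part of J is
what bends kinetic paths away from steepest descent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .network import (
    GeneNetwork,
    HillParams,
    force_from_matrices,
    jacobian_from_matrices,
)

__all__ = [
    "GaussianBasin",
    "LandscapeGrid",
    "FluxField",
    "VarianceInstabilityError",
    "propagate_moments",
    "mixture_probability",
    "potential_from_probability",
    "flux_2d",
]


class VarianceInstabilityError(RuntimeError):
    """The linearised variance equation diverges (positive diagonal A)."""


@dataclass
class GaussianBasin:
    """Mean, diagonal variance and basin weight of one attractor."""

    mean: np.ndarray
    variance: np.ndarray
    weight: float = 1.0

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if np.any(self.variance < 0):
            raise ValueError("variances must be nonnegative")
        if not 0 <= self.weight <= 1 + 1e-12:
            raise ValueError("weight must lie in [0, 1]")


@dataclass
class LandscapeGrid:
    """2-D probability / potential surface over two named coordinates."""

    axis_names: tuple[str, str]
    x_edges: np.ndarray
    y_edges: np.ndarray
    P: np.ndarray
    U: np.ndarray | None = None

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        i = int(np.clip(np.searchsorted(self.x_edges, x) - 1, 0, len(self.x_edges) - 2))
        j = int(np.clip(np.searchsorted(self.y_edges, y) - 1, 0, len(self.y_edges) - 2))
        return i, j

    def to_tsv(self, path) -> None:
        lines = [
            f"# axes: {self.axis_names[0]}, {self.axis_names[1]}",
            f"# x range [{self.x_edges[0]:g}, {self.x_edges[-1]:g}] "
            f"({len(self.x_centers)} cells)",
            f"# y range [{self.y_edges[0]:g}, {self.y_edges[-1]:g}] "
            f"({len(self.y_centers)} cells)",
            "x\ty\tP\tU",
        ]
        U = self.U if self.U is not None else -np.log(np.maximum(self.P, 1e-300))
        for i, x in enumerate(self.x_centers):
            for j, y in enumerate(self.y_centers):
                lines.append(f"{x:.6g}\t{y:.6g}\t{self.P[i, j]:.8e}\t{U[i, j]:.6f}")
        from pathlib import Path

        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class FluxField:
    Jx: np.ndarray
    Jy: np.ndarray
    residual: np.ndarray | None = None  # force-decomposition diagnostic


# ---------------------------------------------------------------------------


def propagate_moments(
    net: GeneNetwork,
    p: HillParams,
    x0: np.ndarray,
    D: float,
    t_end: float = 200.0,
    stat_tol: float = 1e-10,
    weight: float = 1.0,
) -> GaussianBasin:
    """Integrate mean and diagonal variance to stationarity from ``x0``.

    The mean follows the deterministic ODE; each variance follows
    ``dsigma_i/dt = 2 A_ii(xbar) sigma_i + 2 D`` along the mean trajectory.
    At a stable fixed point the stationary variance is ``-D / A_ii``.
    """
    if D < 0:
        raise ValueError("D must be nonnegative")
    x0 = np.asarray(x0, dtype=float)
    N = net.n_genes
    W_act, W_rep = net.weight_matrices(p)

    def rhs(t, y):
        x, s = y[:N], y[N:]
        xc = np.clip(x, 0.0, None)
        A = jacobian_from_matrices(W_act, W_rep, p, xc)
        return np.concatenate(
            [force_from_matrices(W_act, W_rep, p, xc), 2.0 * np.diag(A) * s + 2.0 * D]
        )

    y0 = np.concatenate([x0, np.zeros(N)])
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", rtol=1e-10, atol=1e-12)
    y = sol.y[:, -1]
    mean, var = np.clip(y[:N], 0.0, None), y[N:]
    A = jacobian_from_matrices(W_act, W_rep, p, mean)
    diagA = np.diag(A)
    if np.any(diagA >= 0):
        bad = int(np.argmax(diagA))
        raise VarianceInstabilityError(
            f"variance diverges: A_{bad}{bad} = {diagA[bad]:.3g} >= 0 "
            f"(gene {net.name_of(bad + 1)})"
        )
    drift = np.abs(2.0 * diagA * var + 2.0 * D)
    if np.any(drift > max(stat_tol, 1e-8 * max(D, 1.0))):
        # not yet stationary: land exactly on the fixed-point value
        var = -D / diagA
    if D == 0:
        var = np.zeros(N)
    return GaussianBasin(mean=mean, variance=var, weight=weight)


def mixture_probability(
    basins: list[GaussianBasin],
    axes: tuple[str, str] | tuple[int, int],
    net: GeneNetwork | None = None,
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 2.5), (0.0, 2.5)),
    resolution: int = 100,
) -> LandscapeGrid:
    """Weighted Gaussian-mixture probability on a 2-D grid.

    The diagonal covariance makes marginalisation onto the two kept
    coordinates exact; the grid is renormalised to sum to 1.
    """
    if not basins:
        raise ValueError("at least one basin required")
    idx = []
    names = []
    for a in axes:
        if isinstance(a, str):
            if net is None:
                raise ValueError("gene-name axes require the network")
            idx.append(net.index_of(a))  # KeyError if absent
            names.append(a)
        else:
            idx.append(int(a))
            names.append(f"x{a}")
    xe = np.linspace(bounds[0][0], bounds[0][1], resolution + 1)
    ye = np.linspace(bounds[1][0], bounds[1][1], resolution + 1)
    xc = 0.5 * (xe[:-1] + xe[1:])
    yc = 0.5 * (ye[:-1] + ye[1:])
    P = np.zeros((resolution, resolution))
    for b in basins:
        mx, my = b.mean[idx[0]], b.mean[idx[1]]
        vx, vy = b.variance[idx[0]], b.variance[idx[1]]
        gx = _gauss1d(xc, mx, vx)
        gy = _gauss1d(yc, my, vy)
        P += b.weight * np.outer(gx, gy)
    total = P.sum()
    if total <= 0:
        raise ValueError("mixture mass vanishes on the grid; widen the bounds")
    P /= total
    return LandscapeGrid(axis_names=(names[0], names[1]), x_edges=xe, y_edges=ye, P=P)


def _gauss1d(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    if var <= 0:
        # degenerate (noiseless) basin: all mass in the nearest cell
        out = np.zeros_like(x)
        out[np.argmin(np.abs(x - mean))] = 1.0
        return out
    return np.exp(-((x - mean) ** 2) / (2.0 * var)) / np.sqrt(2.0 * np.pi * var)


def potential_from_probability(
    grid: LandscapeGrid, floor_ratio: float = 1e-12
) -> LandscapeGrid:
    """Attach ``U = -ln max(P, floor)``; the floor is relative to max(P)."""
    floor = grid.P.max() * floor_ratio
    U = -np.log(np.maximum(grid.P, floor))
    return LandscapeGrid(
        axis_names=grid.axis_names,
        x_edges=grid.x_edges,
        y_edges=grid.y_edges,
        P=grid.P,
        U=U,
    )


def flux_2d(grid: LandscapeGrid, F2: np.ndarray, D: float) -> FluxField:
    """Projected steady-state probability flux ``J = F P - D grad P``.

    ``F2`` has shape (nx, ny, 2): the projected force at each cell center.
    Gradients are central differences on the cell grid.  The returned
    ``residual`` is ``|F - (J/P - D grad U)|`` wherever P is above floor —
    an algebraic identity of the decomposition, useful as a diagnostic.
    """
    P = grid.P
    if F2.shape != P.shape + (2,):
        raise ValueError(f"force field shape {F2.shape} != {P.shape + (2,)}")
    dx = float(np.mean(np.diff(grid.x_centers)))
    dy = float(np.mean(np.diff(grid.y_centers)))
    dPdx, dPdy = np.gradient(P, dx, dy)
    Jx = F2[..., 0] * P - D * dPdx
    Jy = F2[..., 1] * P - D * dPdy
    U = grid.U if grid.U is not None else -np.log(np.maximum(P, P.max() * 1e-12))
    dUdx, dUdy = np.gradient(U, dx, dy)
    with np.errstate(divide="ignore", invalid="ignore"):
        rx = F2[..., 0] - (Jx / P - D * dUdx)
        ry = F2[..., 1] - (Jy / P - D * dUdy)
    residual = np.hypot(rx, ry)
    residual[P <= P.max() * 1e-12] = np.nan
    return FluxField(Jx=Jx, Jy=Jy, residual=residual)
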