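"""Langevin simulation, histogram landscapes, MFPT and grid barriers.

The stochastic dynamics add Gaussian white noise with autocorrelation
``<eta_i(t) eta_j(t')> = 2 D delta_ij delta(t-t')`` to the deterministic
Hill force field, so the stationary variance of a linear 1-gene system
``dx/dt = -k x`` is ``D/k``.  Long trajectories yield the steady-state
distribution, hence a histogram landscape ``U = -ln P``.  Barrier heights
between basins are read off a 2-D grid of U: the saddle is the minimax
cell over all 8-connected paths between the two minima (a watershed
flooding construction), and barriers are ``U_saddle - U_min``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .meanfield import LandscapeGrid
from .network import Attractor, GeneNetwork, HillParams

__all__ = [
    "SimConfig",
    "Trajectory",
    "RMSDCoords",
    "MFPTResult",
    "BarrierResult",
    "DivergenceError",
    "PassageTimeoutError",
    "simulate",
    "histogram_landscape",
    "rmsd_coords",
    "estimate_mfpt",
    "barrier_heights",
    "barrier_between",
]


class DivergenceError(RuntimeError):
    """A simulated state became non-finite."""


class PassageTimeoutError(RuntimeError):
    """No first passage completed within the step budget."""


@dataclass(frozen=True)
class SimConfig:
    dt: float = 0.01
    steps: int = 100_000
    D: float = 0.05
    seed: int = 0
    record_every: int = 10

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.D < 0:
            raise ValueError("D must be nonnegative")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # (n_records, n_genes)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_genes(self) -> int:
        return self.states.shape[1]


@dataclass
class RMSDCoords:
    ref1: np.ndarray
    ref2: np.ndarray
    coords: np.ndarray  # (n_records, 2)


@dataclass
class MFPTResult:
    direction: str
    mean: float
    sem: float
    n_passages: int
    times: np.ndarray = field(repr=False, default=None)


@dataclass
class BarrierResult:
    U_min1: float
    U_min2: float
    U_saddle: float
    min1_idx: tuple[int, int]
    min2_idx: tuple[int, int]
    saddle_idx: tuple[int, int]

    @property
    def barrier1(self) -> float:
        return self.U_saddle - self.U_min1

    @property
    def barrier2(self) -> float:
        return self.U_saddle - self.U_min2


# ---------------------------------------------------------------------------


def simulate(
    net: GeneNetwork, p: HillParams, x0: np.ndarray, cfg: SimConfig
) -> Trajectory:
    """Euler-Maruyama trajectory of the network from ``x0``."""
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("initial state must be nonnegative")
    W_act, W_rep = net.weight_matrices(p)
    times, states, bad_step = _kernels.euler_maruyama(
        x0, W_act, W_rep, p.k, p.S**p.n, p.n, cfg.D, cfg.dt,
        cfg.steps, cfg.record_every, cfg.seed,
    )
    if bad_step >= 0:
        raise DivergenceError(f"non-finite state at step {bad_step}")
    return Trajectory(times=times, states=states)


def histogram_landscape(
    trajs: Trajectory | list[Trajectory],
    axes: tuple[int, int] | tuple[str, str],
    bins: int = 60,
    bounds: tuple[tuple[float, float], tuple[float, float]] | None = None,
    net: GeneNetwork | None = None,
    floor_ratio: float = 1e-12,
) -> LandscapeGrid:
    """Normalized 2-D histogram landscape over two coordinates.

    ``axes`` may be 0-based column indices or gene names (then ``net`` is
    required).  ``U = -ln max(P, floor)`` with the floor a fixed ratio of
    the maximum bin probability.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if not trajs or any(t.states.size == 0 for t in trajs):
        raise ValueError("empty trajectory")
    ax = []
    names = []
    for a in axes:
        if isinstance(a, str):
            if net is None:
                raise ValueError("gene-name axes require the network")
            ax.append(net.index_of(a))
            names.append(a)
        else:
            ax.append(int(a))
            names.append(f"x{a}")
    xs = np.concatenate([t.states[:, ax[0]] for t in trajs])
    ys = np.concatenate([t.states[:, ax[1]] for t in trajs])
    if bounds is None:
        bounds = ((xs.min(), xs.max()), ((ys.min(), ys.max())))
    H, xe, ye = np.histogram2d(xs, ys, bins=bins, range=bounds)
    P = H / H.sum()
    U = -np.log(np.maximum(P, P.max() * floor_ratio))
    return LandscapeGrid(
        axis_names=(names[0], names[1]),
        x_edges=xe,
        y_edges=ye,
        P=P,
        U=U,
    )


def rmsd_coords(traj: Trajectory, ref1: np.ndarray, ref2: np.ndarray) -> RMSDCoords:
    """Project states onto (RMSD to ref1, RMSD to ref2).

    RMSD_r(x) = sqrt( (1/N) sum_i (x_i - r_i)^2 ), the root-mean-squared
    distance used to reduce a high-dimensional trajectory to two
    attractor-anchored coordinates.
    """
    ref1 = np.asarray(ref1, dtype=float)
    ref2 = np.asarray(ref2, dtype=float)
    N = traj.n_genes
    if ref1.shape != (N,) or ref2.shape != (N,):
        raise ValueError("reference length does not match trajectory dimension")
    d1 = np.sqrt(np.mean((traj.states - ref1) ** 2, axis=1))
    d2 = np.sqrt(np.mean((traj.states - ref2) ** 2, axis=1))
    return RMSDCoords(ref1=ref1, ref2=ref2, coords=np.column_stack([d1, d2]))


def estimate_mfpt(
    net: GeneNetwork,
    p: HillParams,
    cfg: SimConfig,
    source: Attractor | np.ndarray,
    target: Attractor | np.ndarray | list,
    radius: float | None = None,
    n_passages: int = 100,
    max_steps_per_passage: int = 10_000_000,
    direction: str = "differentiation",
) -> MFPTResult:
    """Mean first passage time from the source state into the target ball.

    Passages restart independently from the source attractor state; a
    passage completes when the trajectory first enters the max-norm ball of
    ``radius`` around the target state (or any of several target states).
    Default radius is 10% of the max-norm separation of source and target.
    """
    src = source.state if isinstance(source, Attractor) else np.asarray(source, float)
    tgts = target if isinstance(target, list) else [target]
    T = np.array(
        [t.state if isinstance(t, Attractor) else np.asarray(t, float) for t in tgts]
    )
    if radius is None:
        radius = 0.1 * max(np.max(np.abs(src - t)) for t in T)
    if radius <= 0:
        raise ValueError("radius must be positive")
    if any(np.max(np.abs(src - t)) < radius for t in T):
        return MFPTResult(direction, 0.0, 0.0, n_passages, np.zeros(n_passages))
    W_act, W_rep = net.weight_matrices(p)
    times = _kernels.first_passages(
        src, T, radius, W_act, W_rep, p.k, p.S**p.n, p.n,
        cfg.D, cfg.dt, n_passages, max_steps_per_passage, cfg.seed,
    )
    ok = times[~np.isnan(times)]
    if ok.size == 0:
        raise PassageTimeoutError(
            f"no passage within {max_steps_per_passage} steps; "
            "increase the budget or the noise level D"
        )
    return MFPTResult(
        direction=direction,
        mean=float(ok.mean()),
        sem=float(ok.std(ddof=1) / np.sqrt(ok.size)) if ok.size > 1 else 0.0,
        n_passages=int(ok.size),
        times=ok,
    )


# ---------------------------------------------------------------------------
# grid barriers


def _local_minima(U: np.ndarray) -> list[tuple[int, int]]:
    nx, ny = U.shape
    out = []
    for i in range(nx):
        for j in range(ny):
            u = U[i, j]
            best = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    ni, nj = i + di, j + dj
                    if 0 <= ni < nx and 0 <= nj < ny and U[ni, nj] < u:
                        best = False
                        break
                if not best:
                    break
            if best:
                out.append((i, j))
    return out


class _DSU:
    def __init__(self, n):
        self.p = list(range(n))

    def find(self, i):
        while self.p[i] != i:
            self.p[i] = self.p[self.p[i]]
            i = self.p[i]
        return i

    def union(self, i, j):
        self.p[self.find(i)] = self.find(j)


def minimax_saddle(
    U: np.ndarray, cell1: tuple[int, int], cell2: tuple[int, int]
) -> tuple[float, tuple[int, int]]:
    """Minimax potential connecting two cells over 8-connected grid paths.

    Cells are flooded in order of increasing U; the first cell whose
    activation joins the components of ``cell1`` and ``cell2`` is the saddle
    (watershed construction — its U equals min over paths of max over the
    path of U).
    """
    nx, ny = U.shape
    flat = U.ravel()
    order = np.argsort(flat, kind="stable")
    dsu = _DSU(flat.size)
    active = np.zeros(flat.size, dtype=bool)
    c1 = cell1[0] * ny + cell1[1]
    c2 = cell2[0] * ny + cell2[1]
    for idx in order:
        active[idx] = True
        i, j = divmod(int(idx), ny)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                ni, nj = i + di, j + dj
                if 0 <= ni < nx and 0 <= nj < ny and active[ni * ny + nj]:
                    dsu.union(int(idx), ni * ny + nj)
        if dsu.find(c1) == dsu.find(c2):
            return float(flat[idx]), (i, j)
    raise RuntimeError("grid is disconnected")  # unreachable on a full grid


def barrier_heights(grid: LandscapeGrid) -> BarrierResult:
    """Barriers between the two deepest local minima of the landscape."""
    minima = _local_minima(grid.U)
    minima = sorted(minima, key=lambda c: grid.U[c])
    # merge plateau minima that sit in the same floor-level region
    distinct = []
    for c in minima:
        if all(max(abs(c[0] - d[0]), abs(c[1] - d[1])) > 1 for d in distinct):
            distinct.append(c)
    if len(distinct) < 2:
        raise ValueError("monostable landscape: fewer than 2 local minima")
    m1, m2 = distinct[0], distinct[1]
    return barrier_between(grid, m1, m2)


def barrier_between(
    grid: LandscapeGrid, cell1: tuple[int, int], cell2: tuple[int, int]
) -> BarrierResult:
    """Barriers between two specified minimum cells (minimax saddle)."""
    U = grid.U
    u_sad, sad = minimax_saddle(U, tuple(cell1), tuple(cell2))
    return BarrierResult(
        U_min1=float(U[tuple(cell1)]),
        U_min2=float(U[tuple(cell2)]),
        U_saddle=u_sad,
        min1_idx=tuple(cell1),
        min2_idx=tuple(cell2),
        saddle_idx=sad,
    )
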