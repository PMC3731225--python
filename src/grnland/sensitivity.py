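"""Global sensitivity analysis of links and genes.

Each regulatory link strength (or the global activation/repression
constant) is perturbed by a signed fraction, the landscape is recomputed
with common seeds, and the change in the two barrier heights (and
optionally the two mean first passage times) quantifies how critical that
link is for the stability of the stem and differentiated states.  Gene
knockdowns remove all production into a gene so its level decays to zero.
A slow anneal of the activation constant drives the differentiation
(downward sweep) and reprogramming (upward sweep) transitions; the
critical activations at the two jumps, a_c1 and a_c2, differ — the
hysteresis loop of a bistable switch.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .langevin import (
    SimConfig,
    barrier_between,
    estimate_mfpt,
    histogram_landscape,
    simulate,
)
from .network import GeneNetwork, HillParams

__all__ = [
    "SensitivityRecord",
    "stability_metrics",
    "AnnealSchedule",
    "AnnealResult",
    "JumpDetectionError",
    "perturb_link",
    "knockdown_gene",
    "sensitivity_scan",
    "rank_links",
    "anneal_activation",
]


class JumpDetectionError(RuntimeError):
    """No fate jump was detected within the annealing schedule."""


@dataclass
class SensitivityRecord:
    target: str                      # "SRC->TGT (act)", "a", "b" or "KD:GENE"
    perturbation: float              # signed fraction delta-p
    delta_barrier_stem: float = np.nan
    delta_barrier_diff: float = np.nan
    delta_mfpt_diff: float = np.nan
    delta_mfpt_repro: float = np.nan
    failed: bool = False
    note: str = ""


@dataclass(frozen=True)
class AnnealSchedule:
    a_start: float
    a_end: float
    rate: float                      # |da/dt|
    form: str = "linear"

    def __post_init__(self):
        if self.a_start == self.a_end:
            raise ValueError("a_start and a_end must differ")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.form not in ("linear", "exponential"):
            raise ValueError("form must be linear or exponential")

    def reversed(self) -> "AnnealSchedule":
        return AnnealSchedule(self.a_end, self.a_start, self.rate, self.form)


@dataclass
class AnnealResult:
    a_values: np.ndarray
    states: np.ndarray
    a_c1: float | None = None        # differentiation jump (downward sweep)
    a_c2: float | None = None        # reprogramming jump (upward sweep)


# ---------------------------------------------------------------------------
# perturbations


def perturb_link(net: GeneNetwork, source, target, sign: str, delta_p: float,
                 base: float | None = None) -> GeneNetwork:
    """Scale one link strength by ``(1 + delta_p)``.

    Links without an explicit strength are perturbed relative to ``base``
    (the global a or b that applies to them), which must then be given.
    """
    if delta_p <= -1:
        raise ValueError("delta_p must be > -1 (strength stays positive)")
    e = net.edge(source, target, sign)
    current = e.strength if e.strength is not None else base
    if current is None:
        raise ValueError("edge uses the global constant; pass base=a or base=b")
    from .network import set_link_strength

    return set_link_strength(net, source, target, sign, current * (1.0 + delta_p))


def knockdown_gene(net: GeneNetwork, gene) -> GeneNetwork:
    """Remove all production into a gene (its level decays to zero).

    Incoming activation and repression terms are deleted; outgoing edges
    remain and transmit the decayed level.
    """
    gid = net._resolve(gene)  # KeyError for unknown names
    new_edges = [e for e in net.edges if e.target != gid]
    return GeneNetwork(list(net.nodes), new_edges)


# ---------------------------------------------------------------------------
# scan


def stability_metrics(
    net,
    p,
    cfg,
    stem_ref,
    side_ref,
    bins: int = 60,
    bounds=((0.0, 3.0), (0.0, 3.0)),
    n_passages: int = 300,
    mfpt_radius: float = 0.2,
    n_starts: int = 150,
):
    """Barriers and MFPTs of a 2-gene system relative to reference states.

    The system's own attractors are located first; the stem state is the
    attractor nearest ``stem_ref`` and the differentiated reference is the
    attractor (among the rest) nearest ``side_ref`` — so a perturbed system
    is always measured at its own, relocated fixed points.  Returns
    ``(barrier_stem, barrier_diff, mfpt_diff, mfpt_repro)`` where the stem
    barrier/MFPT describe first exit from the stem basin to any other
    attractor and the diff barrier/MFPT describe the return from the paired
    differentiated state.  Landscape U comes from one long Langevin
    histogram started in the stem state.
    """
    from .network import find_attractors

    atts = find_attractors(net, p, n_starts=n_starts, seed=cfg.seed, box=(0.0, 3.0))
    if len(atts) < 2:
        raise ValueError("system is monostable; no barrier defined")
    stem_ref = np.asarray(stem_ref, float)
    side_ref = np.asarray(side_ref, float)
    stem = min(atts, key=lambda a: np.max(np.abs(a.state - stem_ref)))
    others = [a for a in atts if a is not stem]
    side = min(others, key=lambda a: np.max(np.abs(a.state - side_ref)))

    traj = simulate(net, p, stem.state, cfg)
    grid = histogram_landscape(traj, (0, 1), bins=bins, bounds=bounds)
    c_stem = _snap_to_min(grid.U, grid.cell_of(*stem.state[:2]))
    # first-exit barrier: lowest saddle from the stem basin to any attractor
    sad_stem = np.inf
    sad_side = None
    for o in others:
        c_o = _snap_to_min(grid.U, grid.cell_of(*o.state[:2]))
        bar = barrier_between(grid, c_stem, c_o)
        sad_stem = min(sad_stem, bar.U_saddle)
        if o is side:
            sad_side = bar
    barrier_stem = sad_stem - grid.U[c_stem]
    barrier_diff = sad_side.U_saddle - grid.U[sad_side.min2_idx]

    m_diff = estimate_mfpt(
        net, p, cfg, stem.state, [o.state for o in others],
        radius=mfpt_radius, n_passages=n_passages, direction="differentiation",
    )
    m_rep = estimate_mfpt(
        net, p, replace(cfg, seed=cfg.seed + 1), side.state, stem.state,
        radius=mfpt_radius, n_passages=n_passages, direction="reprogramming",
    )
    return float(barrier_stem), float(barrier_diff), m_diff.mean, m_rep.mean


def _snap_to_min(U, cell, r: int = 3):
    i0, j0 = cell
    best = (U[i0, j0], i0, j0)
    for i in range(max(i0 - r, 0), min(i0 + r + 1, U.shape[0])):
        for j in range(max(j0 - r, 0), min(j0 + r + 1, U.shape[1])):
            if U[i, j] < best[0]:
                best = (U[i, j], i, j)
    return best[1], best[2]


def sensitivity_scan(
    net: GeneNetwork,
    p: HillParams,
    targets: list,
    delta_p: float,
    cfg: SimConfig,
    stem_ref,
    side_ref,
    metrics: tuple[str, ...] = ("barrier", "mfpt"),
    bins: int = 60,
    bounds=((0.0, 3.0), (0.0, 3.0)),
    n_passages: int = 300,
    mfpt_radius: float = 0.2,
) -> list[SensitivityRecord]:
    """Perturb each target by ``delta_p`` and record metric deltas.

    ``targets`` entries are either edge tuples ``(source, target, sign)``,
    the strings ``"a"`` / ``"b"`` (global constants), or ``("KD", gene)``
    for a knockdown.  Each perturbed system is measured at its own
    relocated attractors (see :func:`stability_metrics`) with the same
    seeds as the cached baseline, so a zero perturbation gives exactly zero
    deltas.  Failures (e.g. a monostable landscape after a perturbation)
    flag the record and the scan continues.
    """
    if not targets:
        raise ValueError("no targets to scan")
    base_vals = stability_metrics(
        net, p, cfg, stem_ref, side_ref, bins, bounds, n_passages, mfpt_radius
    )
    records = []
    for tg in targets:
        try:
            if tg == "a":
                net2, p2 = net, replace(p, a=p.a * (1 + delta_p))
                name = "a"
            elif tg == "b":
                net2, p2 = net, replace(p, b=p.b * (1 + delta_p))
                name = "b"
            elif isinstance(tg, tuple) and tg and tg[0] == "KD":
                net2, p2 = knockdown_gene(net, tg[1]), p
                name = f"KD:{tg[1]}"
            else:
                src, dst, sign = tg
                base = p.a if sign == "act" else p.b
                net2 = perturb_link(net, src, dst, sign, delta_p, base=base)
                p2 = p
                name = f"{src}->{dst} ({sign})"
            vals = stability_metrics(
                net2, p2, cfg, stem_ref, side_ref, bins, bounds,
                n_passages, mfpt_radius,
            )
            records.append(
                SensitivityRecord(
                    target=name,
                    perturbation=delta_p,
                    delta_barrier_stem=vals[0] - base_vals[0],
                    delta_barrier_diff=vals[1] - base_vals[1],
                    delta_mfpt_diff=vals[2] - base_vals[2],
                    delta_mfpt_repro=vals[3] - base_vals[3],
                )
            )
        except Exception as exc:  # metric failure: flag, continue
            records.append(
                SensitivityRecord(
                    target=str(tg), perturbation=delta_p, failed=True, note=str(exc)
                )
            )
    return records


def rank_links(records: list[SensitivityRecord], top_k: int | None = None):
    """Rank by total absolute barrier change, descending; ties by name."""
    ok = [r for r in records if not r.failed]
    if len({r.perturbation for r in ok}) > 1:
        raise ValueError("records mix different perturbation levels")
    ranked = sorted(
        ok,
        key=lambda r: (
            -(abs(r.delta_barrier_stem) + abs(r.delta_barrier_diff)),
            r.target,
        ),
    )
    return ranked[: top_k if top_k is not None else len(ranked)]


# ---------------------------------------------------------------------------
# activation annealing


def anneal_activation(
    net: GeneNetwork,
    p: HillParams,
    schedule: AnnealSchedule,
    cfg: SimConfig,
    x0,
    dest_codes: list[str],
    cutoffs=None,
    marker_idx: list[int] | None = None,
    debounce: int = 10,
    record_every: int = 100,
) -> AnnealResult:
    """Langevin run under a slow schedule of the activation constant.

    The activation matrix is scaled by ``a(t)/a``; links with explicit
    strengths scale proportionally.  The fate jump is the first time the
    thresholded marker code (per-gene cutoffs default to the Hill
    threshold S) matches one of ``dest_codes`` for ``debounce``
    consecutive recorded samples.  The detected critical activation is
    stored as ``a_c1`` for a downward sweep and ``a_c2`` for an upward
    sweep.
    """
    W_act, W_rep = net.weight_matrices(p)
    a_traj, states = _kernels.anneal_run(
        np.asarray(x0, float),
        W_act / p.a,
        W_rep,
        p.k,
        p.S**p.n,
        p.n,
        schedule.a_start,
        schedule.a_end,
        schedule.rate,
        schedule.form == "exponential",
        cfg.D,
        cfg.dt,
        record_every,
        cfg.seed,
    )
    if cutoffs is None:
        cutoffs = np.full(net.n_genes, p.S)
    cutoffs = np.asarray(cutoffs, float)
    cols = marker_idx if marker_idx is not None else list(range(net.n_genes))
    codes = (states[:, cols] >= cutoffs[cols]).astype(np.uint8)
    dest = {d for d in dest_codes}
    run = 0
    a_jump = None
    for i in range(codes.shape[0]):
        code = "".join(str(int(b)) for b in codes[i])
        if code in dest:
            run += 1
            if run >= debounce:
                a_jump = float(a_traj[i - debounce + 1])
                break
        else:
            run = 0
    if a_jump is None:
        raise JumpDetectionError(
            f"no jump onto {sorted(dest)} within a in "
            f"[{min(schedule.a_start, schedule.a_end):g}, "
            f"{max(schedule.a_start, schedule.a_end):g}]; widen the schedule"
        )
    downward = schedule.a_start > schedule.a_end
    return AnnealResult(
        a_values=a_traj,
        states=states,
        a_c1=a_jump if downward else None,
        a_c2=a_jump if not downward else None,
    )
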