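"""Regulatory network representation and Hill-kinetics dynamics.

A gene regulatory network is a signed directed graph: activation edges
contribute a Hill production term ``a * x_j^n / (S^n + x_j^n)`` to their
target and repression edges contribute ``b * S^n / (S^n + x_j^n)`` (a gene
is produced when its repressor is absent).  Every gene degrades linearly at
rate ``k``.  Regulation is additive across regulators and there is no basal
production term, so the rate equation for gene ``i`` reads

    dx_i/dt = -k x_i + sum_act a_ji x_j^n/(S^n + x_j^n)
                     + sum_rep b_ji S^n/(S^n + x_j^n)

with per-edge strengths ``a_ji``/``b_ji`` falling back to the global
constants of :class:`HillParams` when not set on the edge.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "GeneNode",
    "RegEdge",
    "GeneNetwork",
    "HillParams",
    "Attractor",
    "NetworkParseError",
    "NetworkValidationError",
    "ConvergenceError",
    "read_network",
    "write_network",
    "force",
    "jacobian",
    "find_attractors",
    "set_link_strength",
]

ROLES = ("stem_marker", "diff_marker", "stem_activated", "other")

ACTIVATION = "act"
REPRESSION = "rep"


class NetworkParseError(ValueError):
    """Raised when a network file cannot be parsed."""


class NetworkValidationError(ValueError):
    """Raised when a network violates a structural invariant."""


class ConvergenceError(RuntimeError):
    """Raised when no attractor could be located within the step budget."""


@dataclass(frozen=True)
class GeneNode:
    """A gene with its 1-based order number and marker role."""

    id: int
    name: str
    role: str = "other"

    def __post_init__(self):
        if self.id < 1:
            raise NetworkValidationError(f"node id must be positive, got {self.id}")
        if self.role not in ROLES:
            raise NetworkValidationError(
                f"role {self.role!r} not in {ROLES} for gene {self.name}"
            )


@dataclass(frozen=True)
class RegEdge:
    """A signed regulatory link; ``strength`` None means use the global a/b."""

    source: int
    target: int
    sign: str
    strength: float | None = None

    def __post_init__(self):
        if self.sign not in (ACTIVATION, REPRESSION):
            raise NetworkValidationError(f"edge sign must be act/rep, got {self.sign!r}")
        if self.strength is not None and self.strength <= 0:
            raise NetworkValidationError(
                f"edge strength must be positive, got {self.strength}"
            )

    @property
    def key(self) -> tuple[int, int, str]:
        return (self.source, self.target, self.sign)


@dataclass
class GeneNetwork:
    """Signed, optionally weighted regulatory graph."""

    nodes: list[GeneNode]
    edges: list[RegEdge]

    def __post_init__(self):
        ids = [nd.id for nd in self.nodes]
        if sorted(ids) != list(range(1, len(ids) + 1)):
            raise NetworkValidationError("node ids must be unique and contiguous from 1")
        names = [nd.name for nd in self.nodes]
        if len(set(names)) != len(names):
            raise NetworkValidationError("duplicate gene names")
        idset = set(ids)
        seen = set()
        for e in self.edges:
            if e.source not in idset or e.target not in idset:
                raise NetworkValidationError(
                    f"edge {e.source}->{e.target} references unknown node"
                )
            if e.key in seen:
                raise NetworkValidationError(f"duplicate edge {e.key}")
            seen.add(e.key)
        self.nodes = sorted(self.nodes, key=lambda nd: nd.id)

    # -- lookups ---------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.nodes)

    def node_by_name(self, name: str) -> GeneNode:
        for nd in self.nodes:
            if nd.name == name:
                return nd
        raise KeyError(f"gene {name!r} not in network")

    def name_of(self, node_id: int) -> str:
        return self.nodes[node_id - 1].name

    def index_of(self, gene: str | int) -> int:
        """0-based index of a gene given its name or 1-based id."""
        if isinstance(gene, str):
            return self.node_by_name(gene).id - 1
        return int(gene) - 1

    def edge(self, source, target, sign: str) -> RegEdge:
        s = self._resolve(source)
        t = self._resolve(target)
        for e in self.edges:
            if e.key == (s, t, sign):
                return e
        raise KeyError(f"no {sign} edge {source}->{target}")

    def _resolve(self, gene: str | int) -> int:
        if isinstance(gene, str):
            return self.node_by_name(gene).id
        return int(gene)

    def copy(self) -> "GeneNetwork":
        return GeneNetwork(list(self.nodes), list(self.edges))

    # -- compiled weight matrices ---------------------------------------
    def weight_matrices(self, p: "HillParams") -> tuple[np.ndarray, np.ndarray]:
        """(W_act, W_rep): entry [i, j] is the strength of the j -> i edge
        (0 when absent), with unset strengths replaced by global a / b."""
        N = self.n_genes
        W_act = np.zeros((N, N))
        W_rep = np.zeros((N, N))
        for e in self.edges:
            w = e.strength
            if e.sign == ACTIVATION:
                W_act[e.target - 1, e.source - 1] = p.a if w is None else w
            else:
                W_rep[e.target - 1, e.source - 1] = p.b if w is None else w
        return W_act, W_rep


@dataclass(frozen=True)
class HillParams:
    """Global kinetic constants of the Hill rate equations.

    a : activation strength (concentration / time)
    b : repression strength (concentration / time)
    k : degradation rate (1 / time)
    S : Hill threshold, the sigmoid inflection point (concentration)
    n : Hill coefficient (dimensionless steepness)
    """

    a: float = 0.35
    b: float = 0.4
    k: float = 1.0
    S: float = 0.5
    n: float = 4.0

    def __post_init__(self):
        if min(self.a, self.b, self.k, self.S) <= 0:
            raise ValueError("a, b, k, S must be positive")
        if self.n < 1:
            raise ValueError("Hill coefficient n must be >= 1")


@dataclass
class Attractor:
    """A stable fixed point with the fraction of random starts reaching it."""

    state: np.ndarray
    weight: float
    label: str | None = None

    def __post_init__(self):
        self.state = np.asarray(self.state, dtype=float)


# ---------------------------------------------------------------------------
# force field


def _check_state(x: np.ndarray, n_genes: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (n_genes,):
        raise ValueError(f"state has shape {x.shape}, expected ({n_genes},)")
    if np.any(x < 0):
        raise ValueError("state components must be nonnegative")
    return x


def force(net: GeneNetwork, p: HillParams, x: np.ndarray) -> np.ndarray:
    """Right-hand side of the Hill rate equations at state ``x``."""
    x = _check_state(x, net.n_genes)
    W_act, W_rep = net.weight_matrices(p)
    return force_from_matrices(W_act, W_rep, p, x)


def force_from_matrices(W_act, W_rep, p: HillParams, x: np.ndarray) -> np.ndarray:
    Sn = p.S**p.n
    xn = x**p.n
    act = xn / (Sn + xn)
    return -p.k * x + W_act @ act + W_rep @ (1.0 - act)


def jacobian(net: GeneNetwork, p: HillParams, x: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of :func:`force`; zero wherever j does not regulate i."""
    x = _check_state(x, net.n_genes)
    W_act, W_rep = net.weight_matrices(p)
    return jacobian_from_matrices(W_act, W_rep, p, x)


def jacobian_from_matrices(W_act, W_rep, p: HillParams, x: np.ndarray) -> np.ndarray:
    Sn = p.S**p.n
    # d/dx [x^n/(S^n+x^n)] = n S^n x^(n-1) / (S^n + x^n)^2 ; safe at x=0 for n>1
    with np.errstate(divide="ignore", invalid="ignore"):
        hp = p.n * Sn * x ** (p.n - 1) / (Sn + x**p.n) ** 2
    hp = np.where(np.isfinite(hp), hp, 0.0)
    J = (W_act - W_rep) * hp[None, :]
    J[np.diag_indices_from(J)] -= p.k
    return J


# ---------------------------------------------------------------------------
# attractors


def find_attractors(
    net: GeneNetwork,
    p: HillParams,
    n_starts: int = 500,
    box: tuple[float, float] = (0.0, 3.0),
    seed: int = 0,
    tol: float = 0.05,
    t_max: float = 200.0,
    stat_tol: float = 1e-8,
) -> list[Attractor]:
    """Locate stable fixed points by multi-start ODE integration.

    Uniform random initial states are integrated to stationarity, endpoints
    are polished by Newton root-finding, deduplicated within ``tol`` in
    max-norm, and weighted by the fraction of starts converging to each.
    Stability is verified through the Jacobian eigenvalues; endpoints that
    fail the stationarity test are discarded (a convergence error is raised
    if none passes).
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    lo, hi = box
    if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
        raise ValueError("sampling box must be finite with hi > lo")

    W_act, W_rep = net.weight_matrices(p)
    N = net.n_genes

    def F(x):
        return force_from_matrices(W_act, W_rep, p, np.clip(x, 0.0, None))

    def J(x):
        return jacobian_from_matrices(W_act, W_rep, p, np.clip(x, 0.0, None))

    rng = np.random.default_rng(seed)
    starts = rng.uniform(lo, hi, size=(n_starts, N))

    found: list[list] = []  # [state, count]
    n_failed = 0
    for x0 in starts:
        sol = solve_ivp(
            lambda t, x: F(x), (0.0, t_max), x0, method="LSODA", rtol=1e-8, atol=1e-10
        )
        xe = np.clip(sol.y[:, -1], 0.0, None)
        r = root(F, xe, jac=J, method="hybr")
        if r.success:
            xe = np.clip(r.x, 0.0, None)
        if np.max(np.abs(F(xe))) > stat_tol:
            n_failed += 1
            continue
        for rec in found:
            if np.max(np.abs(rec[0] - xe)) < tol:
                rec[1] += 1
                break
        else:
            found.append([xe, 1])

    if not found:
        raise ConvergenceError(
            f"no start converged to stationarity within t={t_max} "
            f"({n_failed}/{n_starts} failures)"
        )

    n_ok = sum(rec[1] for rec in found)
    attractors = []
    for state, count in found:
        ev = np.linalg.eigvals(jacobian_from_matrices(W_act, W_rep, p, state))
        if np.max(ev.real) >= 0:
            continue  # saddle or unstable point reached by chance
        attractors.append(Attractor(state=state, weight=count / n_ok))
    # renormalize in case unstable endpoints were dropped
    wsum = sum(a.weight for a in attractors)
    if wsum == 0:
        raise ConvergenceError("all converged endpoints were unstable")
    for a in attractors:
        a.weight /= wsum
    attractors.sort(key=lambda a: -a.weight)
    return attractors


def set_link_strength(
    net: GeneNetwork, source, target, sign: str, value: float
) -> GeneNetwork:
    """Return a copy of ``net`` with one edge's strength overridden."""
    if value <= 0:
        raise ValueError("strength must be positive")
    target_edge = net.edge(source, target, sign)  # raises KeyError if absent
    new_edges = [
        replace(e, strength=float(value)) if e.key == target_edge.key else e
        for e in net.edges
    ]
    return GeneNetwork(list(net.nodes), new_edges)


# ---------------------------------------------------------------------------
# file I/O

_SIGN_TOKENS = {"act": ACTIVATION, "rep": REPRESSION}


def read_network(
    path: str | Path,
    strengths_path: str | Path | None = None,
    annotations_path: str | Path | None = None,
) -> GeneNetwork:
    """Read a tab-separated edge list ``SOURCE<TAB>act|rep<TAB>TARGET``.

    Lines starting with ``#`` are comments.  An optional annotation sidecar
    (``name<TAB>id<TAB>role``) fixes node ids and roles; otherwise ids follow
    first appearance and roles default to ``other``.  An optional strengths
    file (``SOURCE<TAB>act|rep<TAB>TARGET<TAB>value``) overrides per-edge
    strengths.
    """
    path = Path(path)
    raw_edges: list[tuple[str, str, str, int]] = []
    order: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) not in (3, 4):  # optional 4th column: provenance note
            raise NetworkParseError(
                f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
            )
        src, sign_tok, tgt = (s.strip() for s in parts[:3])
        if sign_tok not in _SIGN_TOKENS:
            raise NetworkParseError(
                f"{path}:{lineno}: unknown interaction sign {sign_tok!r} "
                f"(expected act or rep)"
            )
        for nm in (src, tgt):
            if nm not in order:
                order.append(nm)
        raw_edges.append((src, sign_tok, tgt, lineno))

    if annotations_path is not None:
        nodes = _read_annotations(annotations_path)
        known = {nd.name for nd in nodes}
        for src, _, tgt, lineno in raw_edges:
            for nm in (src, tgt):
                if nm not in known:
                    raise NetworkValidationError(
                        f"{path}:{lineno}: gene {nm!r} not in annotation file"
                    )
    else:
        nodes = [GeneNode(id=i + 1, name=nm) for i, nm in enumerate(order)]

    ids = {nd.name: nd.id for nd in nodes}
    edges = [
        RegEdge(source=ids[src], target=ids[tgt], sign=_SIGN_TOKENS[tok])
        for src, tok, tgt, _ in raw_edges
    ]
    net = GeneNetwork(nodes, edges)

    if strengths_path is not None:
        for lineno, line in enumerate(
            Path(strengths_path).read_text().splitlines(), start=1
        ):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise NetworkParseError(
                    f"{strengths_path}:{lineno}: expected 4 fields"
                )
            src, tok, tgt, val = parts
            try:
                value = float(val)
            except ValueError as exc:
                raise NetworkParseError(
                    f"{strengths_path}:{lineno}: bad strength {val!r}"
                ) from exc
            net = set_link_strength(net, src, tgt, _SIGN_TOKENS[tok], value)
    return net


def _read_annotations(path: str | Path) -> list[GeneNode]:
    nodes = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise NetworkParseError(f"{path}:{lineno}: expected name<TAB>id<TAB>role")
        name, id_s, role = parts
        nodes.append(GeneNode(id=int(id_s), name=name, role=role))
    return nodes


def write_network(
    net: GeneNetwork,
    path: str | Path,
    annotations_path: str | Path | None = None,
    strengths_path: str | Path | None = None,
    provenance: dict[tuple[int, int, str], str] | None = None,
) -> None:
    """Write the edge list (and optionally annotations / strengths) as TSV."""
    lines = ["# source\tsign\ttarget" + ("\tprovenance" if provenance else "")]
    for e in net.edges:
        row = f"{net.name_of(e.source)}\t{e.sign}\t{net.name_of(e.target)}"
        if provenance:
            row += f"\t{provenance.get(e.key, '')}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")

    if annotations_path is not None:
        ann = ["# name\tid\trole"] + [
            f"{nd.name}\t{nd.id}\t{nd.role}" for nd in net.nodes
        ]
        Path(annotations_path).write_text("\n".join(ann) + "\n")

    if strengths_path is not None:
        rows = ["# source\tsign\ttarget\tstrength"]
        for e in net.edges:
            if e.strength is not None:
                rows.append(
                    f"{net.name_of(e.source)}\t{e.sign}\t"
                    f"{net.name_of(e.target)}\t{e.strength!r}"
                )
        Path(strengths_path).write_text("\n".join(rows) + "\n")
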