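"""Synthetic fixtures and analytic oracles.

Four generators cover every pipeline stage without any external download:

* the two-gene GATA1/PU1-style motif with the printed kinetic constants,
* a 52-gene stem-cell network reconstruction (all text-named links are
  exact; the remaining wiring is a SYNTHETIC reconstruction that reproduces
  the printed totals and the network's architecture, see
  :func:`make_stemcell_fixture`),
* random toggle-switch networks of configurable size, and
* a 1-D double-well system with closed-form potential, barrier and
  quadrature mean first passage time.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .langevin import SimConfig
from .network import (
    ACTIVATION,
    REPRESSION,
    GeneNetwork,
    GeneNode,
    HillParams,
    RegEdge,
    write_network,
)

__all__ = [
    "STEM_MARKERS",
    "DIFF_MARKERS",
    "MARKER_IDS_22",
    "STEM_CODE_22",
    "DIFF_CODE_22",
    "BALANCED_PARAMS",
    "FixtureIntegrityError",
    "make_two_gene_motif",
    "make_stemcell_fixture",
    "make_random_toggle_network",
    "make_double_well_oracle",
    "write_fixture_files",
]


class FixtureIntegrityError(RuntimeError):
    """The packaged fixture does not match its frozen checksum."""


# ---------------------------------------------------------------------------
# two-gene motif

def make_two_gene_motif(a: float = 1.0) -> tuple[GeneNetwork, HillParams, SimConfig]:
    """GATA1/PU1-style fate-decision motif.

    Each gene activates itself (strength ``a``) and represses the other
    (strength ``b = 1``); kinetic constants k=1, S=0.5, n=4 and noise
    D=0.05.  Depending on ``a`` the system is bistable (two mirror
    lineage states, e.g. a=0.2..0.5) or tristable with an additional
    central progenitor state in which both genes are co-expressed at
    intermediate level (a around 1 and above).  In the developmental
    reading the central basin is the multipotent (stem-like) state and the
    side basins are the committed fates.
    """
    if a <= 0:
        raise ValueError("activation strength a must be positive")
    nodes = [GeneNode(1, "GATA1"), GeneNode(2, "PU1")]
    edges = [
        RegEdge(1, 1, ACTIVATION),
        RegEdge(2, 2, ACTIVATION),
        RegEdge(1, 2, REPRESSION),
        RegEdge(2, 1, REPRESSION),
    ]
    return (
        GeneNetwork(nodes, edges),
        HillParams(a=a, b=1.0, k=1.0, S=0.5, n=4.0),
        SimConfig(D=0.05),
    )


# ---------------------------------------------------------------------------
# 52-gene stem-cell network reconstruction

STEM_MARKERS = [
    "OCT4", "SOX2", "NANOG", "OCT4SOX2", "KLF4", "FOXD3",
    "ZIC3", "ZFP42", "GDF3", "TDGF1", "PBX1",
]
DIFF_MARKERS = [
    "FOXA2", "AFP", "SOX17", "GATA4", "GATA6", "T",
    "GATA2", "GATA3", "HCGA", "HCGB", "CDX2",
]
_NAMED_OTHER = ["PRDM14", "LMCD1"]
_SYNTH = [f"G{i}" for i in range(25, 53)]

MARKER_IDS_22 = list(range(1, 23))
STEM_CODE_22 = "1" * 11 + "0" * 11
DIFF_CODE_22 = "0" * 11 + "1" * 11

#: kinetic constants giving two relatively balanced basins on this fixture
BALANCED_PARAMS = HillParams(a=0.35, b=0.4, k=1.0, S=0.5, n=4.0)

# core regulatory links named in the source text: the six critical
# repression links R1..R6, the fourteen activation links A1..A14, the
# NANOG/GATA6 and OCT4/CDX2 mutual repressions and the self-activations of
# NANOG, GATA6, CDX2
_ACT_TEXT = [
    ("NANOG", "OCT4"),      # A1
    ("OCT4SOX2", "OCT4"),   # A2
    ("NANOG", "SOX2"),      # A3
    ("OCT4SOX2", "SOX2"),   # A4
    ("NANOG", "NANOG"),     # A5 (self)
    ("OCT4SOX2", "NANOG"),  # A6
    ("KLF4", "NANOG"),      # A7
    ("ZIC3", "NANOG"),      # A8
    ("PBX1", "NANOG"),      # A9
    ("OCT4", "OCT4SOX2"),   # A10
    ("SOX2", "OCT4SOX2"),   # A11
    ("SOX2", "ZIC3"),       # A12
    ("NANOG", "ZIC3"),      # A13
    ("NANOG", "PBX1"),      # A14
    ("GATA6", "GATA6"),     # self-activation
    ("CDX2", "CDX2"),       # self-activation
]
_REP_TEXT = [
    ("CDX2", "OCT4"),    # R1
    ("OCT4", "GATA6"),   # R2
    ("NANOG", "GATA6"),  # R3
    ("GATA4", "GATA6"),  # R4
    ("LMCD1", "GATA6"),  # R5
    ("PRDM14", "GATA6"), # R6
    ("GATA6", "NANOG"),  # NANOG/GATA6 antagonism
    ("OCT4", "CDX2"),    # OCT4/CDX2 antagonism
]


def _synthetic_edges():
    """Synthetic filler wiring: 68 activations + 31 repressions.

    Engineered to the architecture described for the real network —
    mutual activation among embryonic-stem markers, orange genes activated
    by the stem markers, a differentiation cascade fed by GATA6/CDX2/GATA4
    and stem-versus-differentiation cross-repression — while keeping every
    non-core gene free of feedback cycles so the attractor structure is
    carried by the core toggle.
    """
    act = [
        # stem satellites driven by the core markers
        ("OCT4SOX2", "KLF4"), ("OCT4", "KLF4"),
        ("OCT4", "FOXD3"), ("NANOG", "FOXD3"),
        ("OCT4", "ZFP42"), ("SOX2", "ZFP42"),
        ("OCT4", "GDF3"), ("NANOG", "GDF3"),
        ("OCT4", "TDGF1"), ("NANOG", "TDGF1"),
        ("OCT4", "PRDM14"), ("NANOG", "PRDM14"),
        ("OCT4", "LMCD1"), ("SOX2", "LMCD1"),
        # differentiation cascade
        ("GATA6", "GATA4"), ("GATA6", "FOXA2"), ("GATA4", "AFP"),
        ("FOXA2", "AFP"), ("GATA6", "SOX17"), ("GATA4", "SOX17"),
        ("CDX2", "T"), ("CDX2", "GATA2"), ("GATA6", "GATA2"),
        ("CDX2", "GATA3"), ("GATA2", "HCGA"), ("GATA3", "HCGA"),
        ("GATA2", "HCGB"), ("GATA3", "HCGB"),
    ]
    stem_src = ["OCT4", "SOX2", "NANOG", "OCT4SOX2", "KLF4", "FOXD3", "ZIC3"]
    for i, g in enumerate(_SYNTH[:12]):       # G25..G36: stem-activated, 2 inputs
        act.append((stem_src[i % 7], g))
        act.append((stem_src[(i + 3) % 7], g))
    for i, g in enumerate(_SYNTH[12:14]):     # G37, G38: stem-activated, 1 input
        act.append((stem_src[i], g))
    other_src = [
        "GATA6", "CDX2", "GATA4", "T", "GATA2", "GATA3", "SOX17",
        "G25", "G26", "G27", "G28", "G29", "G30", "G31",
    ]
    for g, s in zip(_SYNTH[14:], other_src):  # G39..G52: one input each
        act.append((s, g))

    rep = [
        ("NANOG", "CDX2"), ("SOX2", "CDX2"),
        ("OCT4", "GATA4"), ("NANOG", "GATA4"),
        ("OCT4", "FOXA2"), ("NANOG", "FOXA2"),
        ("OCT4", "AFP"), ("SOX2", "AFP"),
        ("OCT4", "SOX17"), ("NANOG", "SOX17"),
        ("NANOG", "T"), ("SOX2", "T"),
        ("OCT4", "GATA2"), ("NANOG", "GATA2"),
        ("OCT4", "GATA3"), ("SOX2", "GATA3"),
        ("NANOG", "HCGA"), ("SOX2", "HCGA"),
        ("NANOG", "HCGB"), ("OCT4", "HCGB"),
        ("GATA6", "SOX2"), ("CDX2", "NANOG"), ("CDX2", "KLF4"),
        ("GATA6", "FOXD3"), ("CDX2", "PBX1"), ("GATA6", "ZFP42"),
        ("OCT4SOX2", "CDX2"), ("KLF4", "GATA6"), ("SOX17", "NANOG"),
        ("GATA4", "OCT4"), ("T", "TDGF1"),
    ]
    return act, rep


#: sha256 of the canonical edge list, frozen at fixture creation
_FIXTURE_SHA256 = "c1efe242847f8ee7b4d1464a154c42c4a3f62853df14440a6b9a8d6c92dcec38"


def _canonical_edge_text(net: GeneNetwork) -> str:
    rows = [
        f"{net.name_of(e.source)}\t{e.sign}\t{net.name_of(e.target)}"
        for e in net.edges
    ]
    return "\n".join(rows)


def make_stemcell_fixture(
    check_integrity: bool = True,
) -> tuple[GeneNetwork, dict]:
    """Packaged 52-gene stem-cell network reconstruction.

    The 22 marker genes carry their order numbers from the source text
    (stem markers 1-11, differentiation markers 12-22; NANOG=3, GATA6=16,
    CDX2=22), PRDM14 and LMCD1 are the text-named repressors of GATA6, and
    G25..G52 are SYNTHETIC placeholder genes standing in for the supplement
    table that is not available.  All text-named links are included
    verbatim; the rest of the wiring is a synthetic reconstruction matching
    the printed totals: 123 links = 84 activations + 39 repressions over 52
    genes, with 11 stem and 11 differentiation markers.

    Returns the network and a metadata dict with marker ids/codes and
    per-edge provenance ("text" or "synthetic").
    """
    names = STEM_MARKERS + DIFF_MARKERS + _NAMED_OTHER + _SYNTH
    roles = (
        ["stem_marker"] * 11
        + ["diff_marker"] * 11
        + ["stem_activated"] * 2        # PRDM14, LMCD1
        + ["stem_activated"] * 14       # G25..G38
        + ["other"] * 14                # G39..G52
    )
    nodes = [
        GeneNode(i + 1, nm, role) for i, (nm, role) in enumerate(zip(names, roles))
    ]
    ids = {nm: i + 1 for i, nm in enumerate(names)}
    act_syn, rep_syn = _synthetic_edges()
    edges = []
    provenance = {}
    for pairs, sign, prov in (
        (_ACT_TEXT, ACTIVATION, "text"),
        (_REP_TEXT, REPRESSION, "text"),
        (act_syn, ACTIVATION, "synthetic"),
        (rep_syn, REPRESSION, "synthetic"),
    ):
        for s, t in pairs:
            e = RegEdge(ids[s], ids[t], sign)
            edges.append(e)
            provenance[e.key] = prov
    net = GeneNetwork(nodes, edges)

    if check_integrity:
        digest = hashlib.sha256(_canonical_edge_text(net).encode()).hexdigest()
        if digest != _FIXTURE_SHA256:
            raise FixtureIntegrityError(
                f"fixture checksum mismatch: {digest} != {_FIXTURE_SHA256}"
            )

    meta = {
        "marker_ids": MARKER_IDS_22,
        "stem_code": STEM_CODE_22,
        "diff_code": DIFF_CODE_22,
        "stem_markers": STEM_MARKERS,
        "diff_markers": DIFF_MARKERS,
        "provenance": provenance,
        "balanced_params": BALANCED_PARAMS,
    }
    return net, meta


def write_fixture_files(directory) -> None:
    """Write the 52-gene fixture as network + annotation TSVs."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    net, meta = make_stemcell_fixture()
    write_network(
        net,
        d / "stemcell52_network.tsv",
        annotations_path=d / "stemcell52_annotations.tsv",
        provenance=meta["provenance"],
    )


# ---------------------------------------------------------------------------
# random toggle networks

def make_random_toggle_network(
    n_per_side: int, n_extra: int = 0, seed: int = 0
) -> GeneNetwork:
    """Random bistable toggle-style network.

    Two hub genes self-activate and mutually repress (the core switch);
    ``n_per_side`` satellite genes per side mutually activate with their
    hub, and ``n_extra`` downstream genes each receive one activation from
    a random hub.  No gene is isolated and no edge is duplicated; the
    layout of satellites and extras is shuffled deterministically by
    ``seed``.
    """
    if n_per_side < 1:
        raise ValueError("n_per_side must be >= 1")
    if n_extra < 0:
        raise ValueError("n_extra must be >= 0")
    rng = np.random.default_rng(seed)
    names = ["HUB_A", "HUB_B"]
    side_of = {}
    sat_names = []
    for s, side in ((0, "A"), (1, "B")):
        for i in range(n_per_side):
            nm = f"SAT_{side}{i + 1}"
            sat_names.append(nm)
            side_of[nm] = s
    rng.shuffle(sat_names)
    extra_names = [f"EXT{i + 1}" for i in range(n_extra)]
    names += sat_names + extra_names
    nodes = [GeneNode(i + 1, nm) for i, nm in enumerate(names)]
    ids = {nm: i + 1 for i, nm in enumerate(names)}
    edges = [
        RegEdge(ids["HUB_A"], ids["HUB_A"], ACTIVATION),
        RegEdge(ids["HUB_B"], ids["HUB_B"], ACTIVATION),
        RegEdge(ids["HUB_A"], ids["HUB_B"], REPRESSION),
        RegEdge(ids["HUB_B"], ids["HUB_A"], REPRESSION),
    ]
    for nm in sat_names:
        hub = ids["HUB_A"] if side_of[nm] == 0 else ids["HUB_B"]
        edges.append(RegEdge(hub, ids[nm], ACTIVATION))
        edges.append(RegEdge(ids[nm], hub, ACTIVATION))
    for nm in extra_names:
        hub = ids["HUB_A"] if rng.random() < 0.5 else ids["HUB_B"]
        edges.append(RegEdge(hub, ids[nm], ACTIVATION))
    return GeneNetwork(nodes, edges)


# ---------------------------------------------------------------------------
# double-well oracle

@dataclass
class DoubleWellOracle:
    """1-D quartic double well ``V(x) = h (x^2 - 1)^2`` with noise ``D``.

    Minima at x = -1 and +1, barrier exactly ``h`` at x = 0.  The
    quadrature MFPT uses the exact double-integral formula
    ``tau(a -> b) = (1/D) int_a^b dy e^{V(y)/D} int_{-inf}^y dz e^{-V(z)/D}``.
    """

    h: float
    D: float

    def potential(self, x):
        return self.h * (np.asarray(x) ** 2 - 1.0) ** 2

    def force(self, x):
        x = np.asarray(x)
        return -4.0 * self.h * x * (x**2 - 1.0)

    @property
    def force_coeffs(self) -> np.ndarray:
        """Polynomial coefficients of F(x), lowest order first."""
        return np.array([0.0, 4.0 * self.h, 0.0, -4.0 * self.h])

    @property
    def barrier(self) -> float:
        return self.h

    def mfpt_quadrature(
        self, a: float = -1.0, b: float = 1.0, lo: float = -6.0, n_grid: int = 4001
    ) -> float:
        ys = np.linspace(a, b, n_grid)
        zs = np.linspace(lo, b, 2 * n_grid)
        inner_all = np.exp(-self.potential(zs) / self.D)
        cum = np.concatenate([[0.0], np.cumsum(
            0.5 * (inner_all[1:] + inner_all[:-1]) * np.diff(zs)
        )])
        inner_at_y = np.interp(ys, zs, cum)
        outer = np.exp(self.potential(ys) / self.D) * inner_at_y
        return float(np.trapezoid(outer, ys) / self.D)


def make_double_well_oracle(h: float, D: float) -> DoubleWellOracle:
    if h <= 0 or D <= 0:
        raise ValueError("h and D must be positive")
    return DoubleWellOracle(h=h, D=D)
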