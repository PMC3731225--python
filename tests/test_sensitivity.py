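"""Link perturbations, knockdowns, sensitivity ranking and annealing."""

import numpy as np
import pytest
from scipy.optimize import brentq

import grnland as gl
from grnland.fixtures import BALANCED_PARAMS
from grnland.network import force
from grnland.sensitivity import (
    AnnealSchedule,
    SensitivityRecord,
    anneal_activation,
    knockdown_gene,
    perturb_link,
    rank_links,
    sensitivity_scan,
    stability_metrics,
)

from conftest import classify_motif


# ---------------------------------------------------------------------------
# perturb / knockdown


def test_perturb_link_zero_is_identity(motif_bistable):
    net, p, _ = motif_bistable
    net2 = perturb_link(net, "GATA1", "PU1", "rep", 0.0, base=p.b)
    rng = np.random.default_rng(1)
    for _ in range(5):
        x = rng.uniform(0, 2, 2)
        assert np.array_equal(force(net, p, x), force(net2, p, x))


def test_perturb_link_scales_single_term(motif_bistable):
    net, p, _ = motif_bistable
    net2 = perturb_link(net, "GATA1", "GATA1", "act", 0.5, base=p.a)
    x = np.array([1.0, 0.2])
    hill = x[0] ** 4 / (p.S**4 + x[0] ** 4)
    d = force(net2, p, x) - force(net, p, x)
    assert d[0] == pytest.approx(0.5 * p.a * hill)
    assert d[1] == 0.0


def test_perturb_link_full_removal_rejected(motif_bistable):
    net, p, _ = motif_bistable
    with pytest.raises(ValueError, match="-1"):
        perturb_link(net, "GATA1", "PU1", "rep", -1.0, base=p.b)


def test_knockdown_removes_production(motif_bistable):
    net, p, _ = motif_bistable
    kd = knockdown_gene(net, "GATA1")
    x = np.array([1.0, 0.0])
    f = force(kd, p, x)
    assert f[0] == pytest.approx(-p.k * 1.0)  # pure exponential decay
    # outgoing repression of GATA1 onto PU1 still transmitted
    assert any(e.source == 1 and e.target == 2 for e in kd.edges)
    with pytest.raises(KeyError):
        knockdown_gene(net, "NOPE")


def test_knockdown_stem_marker_promotes_differentiation(motif_bistable):
    """Knocking down the stem-marker analog removes its basin entirely: the
    system becomes monostable at the differentiated state."""
    net, p, _ = motif_bistable
    kd = knockdown_gene(net, "GATA1")
    atts = gl.find_attractors(kd, p, n_starts=100, seed=3)
    assert len(atts) == 1
    assert atts[0].state[0] < 0.1 and atts[0].state[1] > 1.0


def test_knockdown_directions_on_stemcell_network(stemcell):
    """GATA6 knockdown leaves only the stem state (reprogramming promoted);
    NANOG knockdown leaves only the differentiated state."""
    net, _ = stemcell
    iN, iG = net.index_of("NANOG"), net.index_of("GATA6")
    for gene, keep_high in (("GATA6", iN), ("NANOG", iG)):
        atts = gl.find_attractors(
            knockdown_gene(net, gene), BALANCED_PARAMS, n_starts=100, seed=3
        )
        assert len(atts) == 1
        assert atts[0].state[keep_high] > 1.0
        knocked = iG if gene == "GATA6" else iN
        assert atts[0].state[knocked] < 1e-6


# ---------------------------------------------------------------------------
# scan


def _motif_refs(attractors):
    stem = max(attractors, key=lambda a: a.state[0])
    diff = max(attractors, key=lambda a: a.state[1])
    return stem.state, diff.state


FAST = dict(n_passages=60, bins=40)


def test_scan_zero_perturbation_all_zero(motif_bistable, motif_bistable_attractors):
    net, p, _ = motif_bistable
    stem, diff = _motif_refs(motif_bistable_attractors)
    cfg = gl.SimConfig(D=0.05, steps=400_000, record_every=10, seed=11)
    recs = sensitivity_scan(net, p, [("GATA1", "PU1", "rep"), "a"], 0.0, cfg,
                            stem, diff, **FAST)
    for r in recs:
        assert not r.failed
        assert r.delta_barrier_stem == 0.0
        assert r.delta_barrier_diff == 0.0
        assert r.delta_mfpt_diff == 0.0
        assert r.delta_mfpt_repro == 0.0


def test_baseline_recomputation_bit_identical(motif_bistable, motif_bistable_attractors):
    net, p, _ = motif_bistable
    stem, diff = _motif_refs(motif_bistable_attractors)
    cfg = gl.SimConfig(D=0.05, steps=200_000, record_every=10, seed=5)
    v1 = stability_metrics(net, p, cfg, stem, diff, n_passages=30)
    v2 = stability_metrics(net, p, cfg, stem, diff, n_passages=30)
    assert v1 == v2


def test_strengthened_repression_deepens_target_basin(
    motif_bistable, motif_bistable_attractors
):
    """Strengthening GATA1 -| PU1 adds production to PU1 when GATA1 is low,
    so the PU1-dominant (differentiated) basin deepens and the GATA1
    (stem) basin shallows — the repression-as-derepression arithmetic of
    the Hill equations."""
    net, p, _ = motif_bistable
    stem, diff = _motif_refs(motif_bistable_attractors)
    cfg = gl.SimConfig(D=0.05, steps=2_000_000, record_every=10, seed=11)
    recs = sensitivity_scan(
        net, p, [("GATA1", "PU1", "rep")], 0.2, cfg, stem, diff, n_passages=200
    )
    r = recs[0]
    assert not r.failed
    assert r.delta_barrier_diff > 0
    assert r.delta_barrier_stem < 0


def test_scan_flags_failures_and_continues(motif_bistable, motif_bistable_attractors):
    net, p, _ = motif_bistable
    stem, diff = _motif_refs(motif_bistable_attractors)
    cfg = gl.SimConfig(D=0.05, steps=200_000, record_every=10, seed=11)
    # knocking down GATA1 makes the system monostable -> flagged, not raised
    recs = sensitivity_scan(
        net, p, [("KD", "GATA1"), ("GATA1", "PU1", "rep")], 0.0, cfg, stem, diff, **FAST
    )
    assert recs[0].failed and "monostable" in recs[0].note
    assert not recs[1].failed


# ---------------------------------------------------------------------------
# ranking


def test_rank_links_by_total_barrier_change():
    mk = lambda name, bs, bd: SensitivityRecord(
        target=name, perturbation=0.2, delta_barrier_stem=bs, delta_barrier_diff=bd
    )
    recs = [mk("L1", 0.5, 0.0), mk("L2", 0.1, 0.0), mk("L3", -0.3, 0.0)]
    ranked = rank_links(recs)
    assert [r.target for r in ranked] == ["L1", "L3", "L2"]
    assert [r.target for r in rank_links(recs, top_k=1)] == ["L1"]
    assert rank_links([recs[0]]) == [recs[0]]


def test_rank_links_mixed_perturbations_rejected():
    r1 = SensitivityRecord("L1", 0.2, 0.1, 0.0)
    r2 = SensitivityRecord("L2", 0.3, 0.1, 0.0)
    with pytest.raises(ValueError, match="perturbation"):
        rank_links([r1, r2])


def test_strong_link_outranks_weak_link(motif_bistable, motif_bistable_attractors):
    """With one cross-repression pre-strengthened, its +20% perturbation
    moves the barriers more than the weak link's +20%."""
    net, p, _ = motif_bistable
    strong = gl.set_link_strength(net, "GATA1", "PU1", "rep", 1.5)
    strong = gl.set_link_strength(strong, "PU1", "GATA1", "rep", 0.5)
    atts = gl.find_attractors(strong, p, n_starts=200, seed=0)
    assert len(atts) == 2
    stem, diff = _motif_refs(atts)
    cfg = gl.SimConfig(D=0.05, steps=2_000_000, record_every=10, seed=11)
    recs = sensitivity_scan(
        strong, p,
        [("GATA1", "PU1", "rep"), ("PU1", "GATA1", "rep")],
        0.2, cfg, stem, diff, n_passages=150,
    )
    ranked = rank_links(recs)
    assert ranked[0].target == "GATA1->PU1 (rep)"


# ---------------------------------------------------------------------------
# annealing


def test_anneal_constant_schedule_rejected():
    with pytest.raises(ValueError, match="differ"):
        AnnealSchedule(0.5, 0.5, 0.001)


def test_anneal_detects_differentiation_jump(motif_tristable):
    net, p, _ = motif_tristable
    res = anneal_activation(
        net, p, AnnealSchedule(1.8, 0.3, 0.001),
        gl.SimConfig(D=0.008, seed=1), np.array([1.6, 1.6]), ["10", "01"],
    )
    assert res.a_c1 is not None and 0.3 <= res.a_c1 <= 1.8
    assert res.a_c2 is None


def test_anneal_missing_jump_raises(motif_tristable):
    net, p, _ = motif_tristable
    with pytest.raises(gl.sensitivity.JumpDetectionError, match="widen"):
        # ramp entirely inside the stem-dominant regime: no jump to a side
        anneal_activation(
            net, p, AnnealSchedule(1.8, 1.6, 0.001),
            gl.SimConfig(D=0.001, seed=1), np.array([1.6, 1.6]), ["10", "01"],
        )


def test_anneal_slow_limit_approaches_deterministic_fold(motif_tristable):
    """In the small-noise limit the differentiation jump converges to the
    fold where the progenitor state loses stability (continuation oracle:
    zero crossing of the leading eigenvalue of the symmetric fixed point)."""
    net, p, _ = motif_tristable
    S, n = p.S, p.n

    def central_leading_eig(a):
        eq = lambda x: a * x**n / (S**n + x**n) + p.b * S**n / (S**n + x**n) - x
        xc = brentq(eq, 0.3, 3.0)
        hp = n * S**n * xc ** (n - 1) / (S**n + xc**n) ** 2
        return -p.k + (a + p.b) * hp

    a_fold = brentq(central_leading_eig, 0.5, 1.0)

    jumps = []
    for rate in (0.002, 0.0005):
        res = anneal_activation(
            net, p, AnnealSchedule(1.2, 0.3, rate),
            gl.SimConfig(D=1e-4, seed=3), np.array([1.19, 1.19]), ["10", "01"],
        )
        jumps.append(res.a_c1)
    assert jumps[0] < jumps[1] < a_fold + 0.01
    assert a_fold - jumps[1] < 0.05


def test_anneal_hysteresis_single_seed(motif_tristable):
    net, p, _ = motif_tristable
    cfg = gl.SimConfig(D=0.008, seed=1)
    down = anneal_activation(
        net, p, AnnealSchedule(1.8, 0.3, 0.0005), cfg, np.array([1.6, 1.6]),
        ["10", "01"],
    )
    up = anneal_activation(
        net, p, AnnealSchedule(0.3, 1.8, 0.0005),
        gl.SimConfig(D=0.008, seed=101), np.array([2.3, 0.0]), ["11"],
    )
    assert down.a_c1 < up.a_c2
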