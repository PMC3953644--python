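"""hp-discontinuous-Galerkin stepping: basis, step systems, stability
and convergence orders on closed-form fixtures."""

import numpy as np
import pytest

from qttcme.assembly import assemble_operator
from qttcme.dg import (
    DGStepConfig,
    TimeMesh,
    assemble_step_system,
    hpdg_solve,
    temporal_basis,
    truncate_solution,
)
from qttcme.models import birth_death
from qttcme.network import FSPWindow, PropensityFactor, Reaction, ReactionNetwork
from qttcme.tt import (
    TTMatrix,
    effective_rank,
    tt_mat_to_dense,
    tt_to_dense,
    tt_unit,
)
from qttcme.validate import birth_death_analytic, densify_pdf


def _decay_model(k=1.0):
    """One species, two states, pure death at rate k, started at 1."""
    net = ReactionNetwork(
        ["X"],
        [Reaction((-1,), {0: PropensityFactor("poly", {"coeffs": [0.0, k]})})],
        initial=(1,),
    )
    return net, FSPWindow((2,))


# -- temporal basis ----------------------------------------------------


def test_order_zero_basis():
    b = temporal_basis(0)
    assert b["G"][0, 0] == 0.0
    assert b["M"][0, 0] == pytest.approx(2.0)  # reference length of [-1, 1]
    assert b["K"][0, 0] == pytest.approx(1.0)  # jump term only


def test_legendre_orthogonality_and_endpoints():
    b = temporal_basis(4)
    assert np.allclose(b["M"], np.diag([2 / (2 * l + 1) for l in range(5)]))
    assert np.allclose(b["phi_right"], 1.0)
    assert np.allclose(b["phi_left"], [(-1.0) ** l for l in range(5)])
    # derivative couplings against numerical quadrature
    from numpy.polynomial import legendre as npleg

    tau = np.linspace(-1, 1, 4001)
    for lp in range(5):
        for l in range(5):
            Pl = npleg.Legendre.basis(l)
            Plp = npleg.Legendre.basis(lp)
            val = np.trapezoid(Plp(tau) * Pl.deriv()(tau), tau)
            assert b["G"][lp, l] == pytest.approx(val, abs=1e-4)


# -- step systems ------------------------------------------------------


def test_order_zero_step_is_backward_euler(bd1_small):
    net, win = bd1_small
    op = assemble_operator(net, win)
    y0 = tt_unit((2, 2, 2), (0, 0, 0))
    h = 0.3
    B, rhs = assemble_step_system(op.matrix, h, 0, y0)
    Bd = tt_mat_to_dense(B)
    Ad = tt_mat_to_dense(op.matrix)
    # single temporal function: (I - h A) c = y_prev
    assert np.allclose(Bd, np.eye(8) - h * Ad, atol=1e-12)


def test_zero_operator_reproduces_previous_endpoint(rng):
    from qttcme.dmrg import DMRGOptions, dmrg_solve
    from qttcme.dg import _endpoint

    Z = TTMatrix([np.zeros((1, 2, 2, 1)) for _ in range(3)])
    y0 = tt_unit((2, 2, 2), (1, 0, 1))
    for p in (0, 1, 3):
        B, rhs = assemble_step_system(Z, 0.7, p, y0)
        c, rep = dmrg_solve(B, rhs, 1e-10, DMRGOptions(seed=0))
        y1 = _endpoint(c, p)
        assert np.allclose(tt_to_dense(y1), tt_to_dense(y0), atol=1e-9)


def test_step_system_rank_bound(bd1_small):
    net, win = bd1_small
    op = assemble_operator(net, win, tol=1e-12)
    y0 = tt_unit((2, 2, 2), (0, 0, 0))
    B, _ = assemble_step_system(op.matrix, 0.1, 3, y0)
    assert all(rb <= ra + 1 for rb, ra in zip(B.ranks[2:], op.matrix.ranks[1:]))


# -- convergence on the 2-state decay model ---------------------------


def test_p_convergence_is_exponential():
    net, win = _decay_model()
    op = assemble_operator(net, win)
    y0 = tt_unit((2,), (1,))
    T = 1.0
    errors = []
    for p in range(6):
        cfg = DGStepConfig(order=p, eps=1e-14, eps_dmrg=1e-13, kick=0.0)
        res = hpdg_solve(op, y0, TimeMesh.uniform(T, 1), cfg)
        sol = densify_pdf(res.final, op.qmap)
        errors.append(abs(sol[1] - np.exp(-T)))
    # each additional order gains at least a factor 2 until the floor
    for a, b in zip(errors, errors[1:]):
        assert b <= a / 2 or b < 1e-12


def test_h_convergence_rate_at_p1():
    net, win = _decay_model()
    op = assemble_operator(net, win)
    y0 = tt_unit((2,), (1,))
    T = 1.0
    steps = [2, 4, 8, 16]
    errors = []
    for M in steps:
        cfg = DGStepConfig(order=1, eps=1e-14, eps_dmrg=1e-13, kick=0.0)
        res = hpdg_solve(op, y0, TimeMesh.uniform(T, M), cfg)
        errors.append(abs(densify_pdf(res.final, op.qmap)[1] - np.exp(-T)))
    slope = np.polyfit(np.log(steps), np.log(errors), 1)[0]
    # nodal superconvergence: order 2p+1 = 3
    assert abs(-slope - 3.0) < 0.3


def test_unconditional_stability_on_stiff_step():
    # a single step as long as the whole horizon with ||A|| h >> 1
    net, win = birth_death(1, 2**6, b=5.0, delta=2.0)
    op = assemble_operator(net, win, tol=1e-12)
    y0 = tt_unit((2,) * 6, (0,) * 6)
    cfg = DGStepConfig(order=3, eps=1e-8, seed=1)
    res = hpdg_solve(op, y0, TimeMesh.uniform(50.0, 1), cfg)
    from qttcme.tt import tt_norm

    assert tt_norm(res.final) <= 1.0 + 1e-6
    assert res.diagnostics.deficiency.iloc[-1] < 1e-3


def test_birth_death_endpoint_matches_analytic():
    net, win = birth_death(1, 2**8)
    op = assemble_operator(net, win, tol=1e-12)
    y0 = tt_unit((2,) * 8, (0,) * 8)
    T = 10.0
    cfg = DGStepConfig(order=4, eps=1e-6, seed=7)
    res = hpdg_solve(op, y0, TimeMesh.geometric(T, 12, ratio=1.6), cfg)
    sol = densify_pdf(res.final, op.qmap)
    ref = birth_death_analytic(1.0, 0.1, T, 2**8)
    assert np.linalg.norm(sol - ref) / np.linalg.norm(ref) < 1e-4
    # diagnostics present and finite for every step
    d = res.diagnostics
    assert d.converged.all()
    assert np.isfinite(d[["r_eff", "deficiency", "rel_deriv"]].to_numpy()).all()


def test_truncate_solution_only_reduces_ranks():
    net, win = birth_death(1, 2**8)
    op = assemble_operator(net, win, tol=1e-12)
    y0 = tt_unit((2,) * 8, (0,) * 8)
    cfg = DGStepConfig(order=3, eps=1e-8, seed=2)
    res = hpdg_solve(op, y0, TimeMesh.geometric(2.0, 6, ratio=1.5), cfg)
    y = res.final
    tr = truncate_solution(y, 10 * cfg.eps)
    assert all(a <= b for a, b in zip(tr.ranks, y.ranks))
    assert effective_rank(tr).r_eff <= effective_rank(y).r_eff + 1e-12
    # kappa = 1 is plain rounding at eps
    from qttcme.tt import tt_round

    t1 = truncate_solution(y, cfg.eps)
    t2 = tt_round(y, cfg.eps)
    assert t1.ranks == t2.ranks


def test_stationarity_detection_on_toggle_reduced():
    # relative derivative norm stagnates once the bimodal quasi-steady
    # state is reached
    from qttcme.models import toggle_switch
    from qttcme.quantization import quantize

    net, win = toggle_switch(n=32)
    op = assemble_operator(net, win, tol=1e-10)
    p0 = np.zeros(win.sizes)
    p0[net.initial] = 1.0
    y0 = quantize(p0, op.qmap, 0.0)
    cfg = DGStepConfig(order=3, eps=1e-5, seed=4)
    res = hpdg_solve(op, y0, TimeMesh.geometric(40.0, 10, ratio=1.8), cfg)
    rd = res.diagnostics.rel_deriv.to_numpy()
    # after the transient the derivative norm is small and stops falling
    assert rd[-1] < 1e-2 * rd[0]
    assert rd[-1] > 0  # stagnates at the accuracy floor, not at zero
    late = rd[-3:]
    assert late.max() / max(late.min(), 1e-300) < 50
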