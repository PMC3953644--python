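"""Oracles: dense FSP reference, analytic birth-death law, SSA, and the
discrepancy metrics."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from qttcme.models import (
    birth_death,
    futile_cycle,
    futile_cycle_invariants,
    toggle_switch,
)
from qttcme.network import FSPWindow, PropensityFactor, Reaction, ReactionNetwork
from qttcme.quantization import QuantizationMap, quantize
from qttcme.validate import (
    birth_death_analytic,
    dense_fsp_solve,
    discrepancy,
    marginal,
    ssa_simulate,
)


def _null_network(d=2):
    """A network whose single reaction never fires."""
    return ReactionNetwork(
        [f"X{k}" for k in range(d)],
        [Reaction((1,) * d, {0: PropensityFactor("poly", {"coeffs": [0.0]})})],
        initial=(1,) * d,
    )


def test_zero_propensity_network_is_constant():
    net = _null_network()
    win = FSPWindow((4, 4))
    traj = dense_fsp_solve(net, win, [0.5, 2.0])
    p0 = np.zeros((4, 4))
    p0[1, 1] = 1.0
    assert np.allclose(traj[0], p0, atol=1e-12)
    assert np.allclose(traj[1], p0, atol=1e-12)


def test_pure_death_closed_form():
    net = ReactionNetwork(
        ["X"],
        [Reaction((-1,), {0: PropensityFactor("poly", {"coeffs": [0.0, 0.8]})})],
        initial=(1,),
    )
    win = FSPWindow((2,))
    for t in (0.3, 1.0, 2.5):
        p = dense_fsp_solve(net, win, [t])[0]
        assert p[1] == pytest.approx(np.exp(-0.8 * t), abs=1e-10)


def test_dense_solver_matches_analytic_birth_death():
    net, win = birth_death(1, 2**8)
    p = dense_fsp_solve(net, win, [7.0])[0]
    ref = birth_death_analytic(1.0, 0.1, 7.0, 2**8)
    assert np.linalg.norm(p - ref) < 1e-8


def test_expm_and_stiff_integrator_agree():
    net, win = toggle_switch(n=16)
    a = dense_fsp_solve(net, win, [1.5], method="expm")[0]
    b = dense_fsp_solve(net, win, [1.5], method="ode")[0]
    assert np.linalg.norm(a - b) < 1e-8


def test_total_probability_nonincreasing_under_fsp():
    # birth process reaching the window boundary: mass leaks out
    net, win = birth_death(1, 8)
    times = np.linspace(0.0, 20.0, 21)
    traj = dense_fsp_solve(net, win, times)
    sums = traj.reshape(len(times), -1).sum(axis=1)
    assert np.all(np.diff(sums) <= 1e-10)
    assert sums[-1] < 0.9  # the leak is substantial on this window


def test_birth_death_analytic_limits():
    assert birth_death_analytic(1.0, 1.0, 0.0, 16)[0] == pytest.approx(1.0)
    p_inf = birth_death_analytic(1.0, 1.0, 200.0, 32)
    assert p_inf[0] == pytest.approx(np.exp(-1.0), rel=1e-10)
    # lambda(t) from the closed form matches quadrature of the rate ODE
    b, d, T = 2.0, 0.3, 4.0
    sol = solve_ivp(
        lambda t, lam: b - d * lam, (0, T), [0.0], rtol=1e-12, atol=1e-12
    )
    lam_T = sol.y[0, -1]
    assert (b / d) * (1 - np.exp(-d * T)) == pytest.approx(lam_T, rel=1e-9)


# -- SSA ---------------------------------------------------------------


def test_ssa_zero_propensity_paths_stay_put():
    net = _null_network()
    res = ssa_simulate(net, (1, 1), 5.0, 64, seed=0, record_times=[1.0, 5.0])
    assert np.all(res.states == 1)


def test_ssa_birth_death_mean_within_error_bars():
    net, _ = birth_death(1, 2**8)
    n_paths = 20000
    res = ssa_simulate(net, (0,), 10.0, n_paths, seed=42, record_times=[5.0, 10.0])
    for i, t in enumerate((5.0, 10.0)):
        lam = 10.0 * (1.0 - np.exp(-0.1 * t))
        m = res.states[i, :, 0].mean()
        se = res.states[i, :, 0].std() / np.sqrt(n_paths)
        assert abs(m - lam) < 3 * se


def test_ssa_futile_cycle_conserves_invariants_exactly():
    net, _ = futile_cycle(s_total=15)
    res = ssa_simulate(
        net, net.initial, 3.0, 2000, seed=7, record_times=[0.5, 1.5, 3.0]
    )
    for w, c in futile_cycle_invariants(net, net.initial):
        vals = res.states.astype(float) @ w
        assert np.all(vals == c)


def test_ssa_seeded_reproducibility():
    net, _ = birth_death(1, 64)
    a = ssa_simulate(net, (0,), 2.0, 500, seed=5, record_times=[2.0])
    b = ssa_simulate(net, (0,), 2.0, 500, seed=5, record_times=[2.0])
    assert np.array_equal(a.states, b.states)


# -- metrics -----------------------------------------------------------


def test_discrepancy_of_identical_pdfs_is_zero(rng):
    p = rng.random((8, 8))
    p /= p.sum()
    rep = discrepancy(p, p)
    assert rep.l2 == 0.0 and rep.l1 == 0.0 and rep.chebyshev == 0.0
    assert rep.chebyshev <= rep.l1


def test_marginal_of_product_form_is_factor(rng):
    a = rng.random(8)
    a /= a.sum()
    b = rng.random(16)
    b /= b.sum()
    joint = np.multiply.outer(a, b)
    assert np.allclose(marginal(joint, (0,)), a)
    assert np.allclose(marginal(joint, (1,)), b)
    # TT route through either ordering
    for ordering in ("natural", "transposed"):
        qmap = QuantizationMap((8, 16), ordering=ordering)
        q = quantize(joint, qmap, 0.0)
        assert np.allclose(marginal(q, (0,), qmap), a, atol=1e-12)
        assert np.allclose(marginal(q, (1,), qmap), b, atol=1e-12)


def test_tt_l2_discrepancy_matches_dense(rng):
    p = rng.random((32, 32))
    q = p + 1e-3 * rng.standard_normal((32, 32))
    qmap = QuantizationMap((32, 32))
    rep_tt = discrepancy(quantize(p, qmap, 0.0), quantize(q, qmap, 0.0))
    rep_dense = discrepancy(p, q)
    assert rep_tt.l2 == pytest.approx(rep_dense.l2, rel=1e-10)


def test_sparse_generator_rejects_oversized_windows():
    net, _ = birth_death(1, 2**12)
    with pytest.raises(MemoryError):
        dense_fsp_solve(net, FSPWindow((2**12,)), [1.0], budget=2**10)


# -- solver vs SSA on the toggle switch --------------------------------


@pytest.fixture(scope="module")
def toggle_reduced_run():
    from qttcme.assembly import assemble_operator
    from qttcme.dg import DGStepConfig, TimeMesh, hpdg_solve

    net, win = toggle_switch(n=32)
    op = assemble_operator(net, win, tol=1e-10)
    p0 = np.zeros(win.sizes)
    p0[net.initial] = 1.0
    y0 = quantize(p0, op.qmap, 0.0)
    cfg = DGStepConfig(order=3, eps=1e-5, seed=9)
    res = hpdg_solve(op, y0, TimeMesh.geometric(10.0, 8, ratio=1.6), cfg)
    return net, win, op, res


def test_toggle_solver_marginals_within_ssa_error_bars(toggle_reduced_run):
    net, win, op, res = toggle_reduced_run
    n_paths = 20000
    ssa = ssa_simulate(net, net.initial, 10.0, n_paths, seed=13, record_times=[10.0])
    emp = ssa.marginals(win.sizes)[0]
    se = ssa.marginal_stderr(win.sizes)[0]
    for k in range(net.d):
        sol_m = marginal(res.final, (k,), op.qmap)
        l1 = np.abs(sol_m - emp[k, : win.sizes[k]]).sum()
        mc = se[k, : win.sizes[k]].sum()
        assert l1 <= 3 * mc


def test_toggle_endpoint_marginals_are_bimodal(toggle_reduced_run):
    net, win, op, res = toggle_reduced_run
    for k in range(2):
        m = marginal(res.final, (k,), op.qmap)
        maxima = [
            i
            for i in range(len(m))
            if (i == 0 or m[i] >= m[i - 1])
            and (i == len(m) - 1 or m[i] > m[i + 1])
            and m[i] > 1e-3
        ]
        assert len(maxima) >= 2, f"species {net.species[k]} marginal not bimodal: {maxima}"
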