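"""Oracles and metrics for validating tensor-format CME solutions.

The dense finite-state-projection solver builds the sparse generator
directly from the reaction transitions and evolves it with the action
of the matrix exponential (cross-checkable against a stiff implicit
integrator); the independent birth-death process admits a closed-form
truncated-Poisson solution; the stochastic simulation algorithm
(Gillespie's direct method, vectorized over paths) provides an
empirical reference with binomial error bars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import expm_multiply
from scipy.stats import poisson

from .network import FSPWindow, ReactionNetwork
from .quantization import QuantizationMap
from .tt import TTVector, tt_add, tt_norm, tt_scale, tt_to_dense

__all__ = [
    "DiscrepancyReport",
    "build_sparse_generator",
    "dense_fsp_solve",
    "birth_death_analytic",
    "ssa_simulate",
    "SSAResult",
    "discrepancy",
    "marginal",
    "densify_pdf",
]

DENSE_STATE_BUDGET = 2**14


def _lin_index(X, sizes):
    """Fortran-order linear index (first species fastest)."""
    idx = np.zeros(X.shape[0], dtype=np.int64)
    scale = 1
    for k, n in enumerate(sizes):
        idx += X[:, k].astype(np.int64) * scale
        scale *= n
    return idx


def build_sparse_generator(net: ReactionNetwork, window: FSPWindow) -> sp.csr_matrix:
    """Sparse FSP generator built state-by-state from the reaction
    transitions (the independent oracle for the tensor assembly).
    Column sums vanish for interior states; outgoing transitions that
    leave the window are dropped, leaving nonpositive column sums."""
    sizes = window.sizes
    N = window.n_states
    if N > DENSE_STATE_BUDGET * 4:
        raise MemoryError(f"state count {N} exceeds sparse-oracle budget")
    grids = np.meshgrid(*[np.arange(n) for n in sizes], indexing="ij")
    X = np.stack([g.flatten(order="F") for g in grids], axis=1)  # (N, d)
    cols = _lin_index(X, sizes)
    rows_all, cols_all, data_all = [], [], []
    diag = np.zeros(N)
    for r in net.reactions:
        a = r.propensity(X)
        diag -= a
        target = X + np.asarray(r.stoich, dtype=np.int64)
        ok = window.contains(target)
        rows_all.append(_lin_index(target[ok], sizes))
        cols_all.append(cols[ok])
        data_all.append(a[ok])
    rows = np.concatenate(rows_all + [cols])
    colsc = np.concatenate(cols_all + [cols])
    data = np.concatenate(data_all + [diag])
    return sp.csr_matrix((data, (rows, colsc)), shape=(N, N))


def dense_fsp_solve(net: ReactionNetwork, window: FSPWindow, times,
                    p0=None, method: str = "expm",
                    budget: int = DENSE_STATE_BUDGET) -> np.ndarray:
    """Reference PDF trajectory on the window: returns an array of
    shape ``(len(times),) + window.sizes``.

    method 'expm' uses the action of the matrix exponential;
    method 'ode' integrates with an implicit stiff solver at 1e-10
    tolerances (the two cross-check each other)."""
    N = window.n_states
    if N > budget:
        raise MemoryError(f"state count {N} exceeds dense budget {budget}")
    A = build_sparse_generator(net, window)
    times = np.atleast_1d(np.asarray(times, dtype=np.float64))
    if p0 is None:
        p = np.zeros(N)
        p[_lin_index(np.asarray([net.initial]), window.sizes)[0]] = 1.0
    else:
        p = np.asarray(p0, dtype=np.float64).flatten(order="F")
    out = np.empty((len(times), N))
    if method == "expm":
        order = np.argsort(times)
        t_prev, cur = 0.0, p.copy()
        for i in order:
            dt = times[i] - t_prev
            if dt > 0:
                cur = expm_multiply(A * dt, cur)
            out[i] = cur
            t_prev = times[i]
    elif method == "ode":
        from scipy.integrate import solve_ivp

        sol = solve_ivp(
            lambda t, y: A @ y,
            (0.0, float(np.max(times))),
            p,
            t_eval=times,
            method="BDF",
            jac=A,
            rtol=1e-10,
            atol=1e-12,
        )
        if not sol.success:
            raise RuntimeError(f"stiff integration failed: {sol.message}")
        out = sol.y.T
    else:
        raise ValueError("method must be 'expm' or 'ode'")
    return out.reshape((len(times),) + window.sizes, order="F")


def birth_death_analytic(b_rate: float, d_rate: float, t: float, n: int) -> np.ndarray:
    """Marginal PDF of a birth-death species started at zero copies:
    Poisson(lambda(t)) truncated to {0..n-1}, with
    lambda(t) = (b/d)(1 - exp(-d t)) solving lambda' = b - d*lambda."""
    if d_rate > 0:
        lam = (b_rate / d_rate) * (1.0 - np.exp(-d_rate * t))
    else:
        lam = b_rate * t
    return poisson.pmf(np.arange(n), lam)


# ---------------------------------------------------------------------------
# stochastic simulation (direct method), vectorized over paths


@dataclass
class SSAResult:
    record_times: np.ndarray
    states: np.ndarray        # (n_times, n_paths, d) recorded states
    window: FSPWindow = None

    def marginals(self, sizes) -> np.ndarray:
        """Empirical per-species marginal PDFs, shape
        (n_times, d, max(sizes)); counts outside [0, n_k) are clipped
        into the boundary bins."""
        T, P, d = self.states.shape
        nmax = max(sizes)
        out = np.zeros((T, d, nmax))
        for ti in range(T):
            for k in range(d):
                xs = np.clip(self.states[ti, :, k], 0, sizes[k] - 1)
                out[ti, k, : sizes[k]] = np.bincount(xs, minlength=sizes[k]) / P
        return out

    def marginal_stderr(self, sizes) -> np.ndarray:
        """Per-bin binomial standard errors of the marginals."""
        m = self.marginals(sizes)
        P = self.states.shape[1]
        return np.sqrt(np.maximum(m * (1.0 - m), 0.0) / P)


def ssa_simulate(net: ReactionNetwork, x0, T: float, n_paths: int, seed,
                 record_times=None) -> SSAResult:
    """Gillespie direct method, all paths advanced in lockstep.

    Propensities are evaluated from the separable factors at arbitrary
    copy numbers (no truncation), so the simulation is on the full
    state space."""
    rng = np.random.default_rng(seed)
    d = net.d
    if record_times is None:
        record_times = np.array([T])
    record_times = np.atleast_1d(np.asarray(record_times, dtype=np.float64))
    X = np.tile(np.asarray(x0, dtype=np.int64), (n_paths, 1))
    t = np.zeros(n_paths)
    stoich = np.stack([np.asarray(r.stoich, dtype=np.int64) for r in net.reactions])
    recorded = np.zeros((len(record_times), n_paths, d), dtype=np.int64)
    ptr = np.zeros(n_paths, dtype=np.int64)  # next record index per path
    n_rec = len(record_times)
    active = np.ones(n_paths, dtype=bool)
    while np.any(active):
        idx = np.nonzero(active)[0]
        a = net.propensities(X[idx])  # (n_active, M)
        a = np.maximum(a, 0.0)
        a0 = a.sum(axis=1)
        # absorbing states: jump straight past all remaining records
        dead = a0 <= 0.0
        tau = np.full(len(idx), np.inf)
        tau[~dead] = rng.exponential(1.0, size=int((~dead).sum())) / a0[~dead]
        t_new = t[idx] + tau
        # record crossings
        for i_local, i in enumerate(idx):
            while ptr[i] < n_rec and record_times[ptr[i]] <= t_new[i_local]:
                if record_times[ptr[i]] >= t[i]:
                    recorded[ptr[i], i] = X[i]
                ptr[i] += 1
        # fire reactions for paths still below T
        fire = t_new <= T
        if np.any(fire):
            sub = idx[fire]
            asub = a[fire]
            u = rng.random(len(sub)) * asub.sum(axis=1)
            choice = (np.cumsum(asub, axis=1) < u[:, None]).sum(axis=1)
            choice = np.minimum(choice, stoich.shape[0] - 1)
            X[sub] += stoich[choice]
        t[idx] = t_new
        active[idx] = (t_new <= T) & (ptr[idx] < n_rec)
        # paths past T with records left: fill remaining records
        done = idx[(t_new > T)]
        for i in done:
            while ptr[i] < n_rec:
                recorded[ptr[i], i] = X[i]
                ptr[i] += 1
        active[done] = False
    return SSAResult(record_times=record_times, states=recorded)


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class DiscrepancyReport:
    l2: float
    l1: float = None
    chebyshev: float = None
    deficiency_p: float = None
    deficiency_q: float = None
    which: str = "joint"
    relative: bool = True


def densify_pdf(p: TTVector, qmap: QuantizationMap) -> np.ndarray:
    """Dense physical-shape array of a quantized PDF (small windows
    only)."""
    full = tt_to_dense(p)
    if qmap.ordering == "transposed":
        inv = np.argsort(qmap.permutation)
        full = full.transpose(tuple(inv))
    return full.flatten(order="F").reshape(qmap.mode_sizes, order="F")


def marginal(p, axes, qmap: QuantizationMap = None) -> np.ndarray:
    """Marginal over the species in ``axes`` (kept), others summed.

    ``p`` may be a dense physical array or a quantized TTVector with
    its QuantizationMap; summation contracts the all-ones vector over
    the dropped virtual modes."""
    axes = tuple(int(a) for a in axes)
    if isinstance(p, TTVector):
        if qmap is None:
            raise ValueError("marginal of a TTVector needs its QuantizationMap")
        slots = qmap.slots
        if len(slots) != p.d:
            raise ValueError("quantization map does not match TT modes")
        keep_sizes = tuple(qmap.mode_sizes[a] for a in axes)
        # sweep left to right: sum dropped slots with the ones vector,
        # expand kept slots densely (kept windows are small)
        kept = np.ones((1, 1))  # (prod kept sizes so far, bond rank)
        kept_slots = []
        for core, (k, lam) in zip(p.cores, slots):
            if k in axes:
                r0, n, r1 = core.shape
                kept = np.einsum("pa,anb->pnb", kept, core, optimize=True)
                kept = kept.reshape(kept.shape[0] * n, r1)
                kept_slots.append((k, lam, n))
            else:
                kept = kept @ core.sum(axis=1)
        flat = kept[:, 0]
        # flat index: earlier kept slots vary slowest; map each slot
        # (little-endian level lam of species k) to its species value
        coords = np.array(list(np.ndindex(*[n for (_, _, n) in kept_slots])))
        lin = np.zeros(coords.shape[0], dtype=np.int64)
        scale_out = np.cumprod([1] + list(keep_sizes[:-1]))
        for pos, (k, lam, n) in enumerate(kept_slots):
            ai = axes.index(k)
            weight = int(np.prod([qmap.factors[k][l] for l in range(lam)], dtype=np.int64))
            lin += coords[:, pos] * weight * scale_out[ai]
        out_flat = np.zeros(int(np.prod(keep_sizes)))
        np.add.at(out_flat, lin, flat)
        return out_flat.reshape(keep_sizes, order="F")
    # dense input: sum dropped axes, then order kept axes as requested
    p = np.asarray(p, dtype=np.float64)
    drop = tuple(i for i in range(p.ndim) if i not in axes)
    m = p.sum(axis=drop)
    kept_order = sorted(axes)
    return m.transpose([kept_order.index(a) for a in axes])


def discrepancy(p, q, relative: bool = True, which: str = "joint") -> DiscrepancyReport:
    """Norms of the difference of two PDFs (TT or dense).

    The l2 norm is computed in TT arithmetic when both operands are
    TTVectors; l1 and Chebyshev require dense operands (use marginals
    for large windows)."""
    if isinstance(p, TTVector) and isinstance(q, TTVector):
        diff = tt_add(p, tt_scale(q, -1.0))
        l2 = tt_norm(diff)
        ref = tt_norm(q) if relative else 1.0
        return DiscrepancyReport(
            l2=l2 / ref if ref > 0 else l2, which=which, relative=relative
        )
    pd = tt_to_dense(p) if isinstance(p, TTVector) else np.asarray(p, float)
    qd = tt_to_dense(q) if isinstance(q, TTVector) else np.asarray(q, float)
    if pd.shape != qd.shape:
        raise ValueError("shape mismatch between PDFs")
    diff = pd - qd
    l2 = float(np.linalg.norm(diff))
    l1 = float(np.abs(diff).sum())
    cheb = float(np.abs(diff).max())
    if relative:
        l2 /= max(float(np.linalg.norm(qd)), 1e-300)
        l1 /= max(float(np.abs(qd).sum()), 1e-300)
        cheb /= max(float(np.abs(qd).max()), 1e-300)
    return DiscrepancyReport(
        l2=l2,
        l1=l1,
        chebyshev=cheb,
        deficiency_p=float(1.0 - pd.sum()),
        deficiency_q=float(1.0 - qd.sum()),
        which=which,
        relative=relative,
    )
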