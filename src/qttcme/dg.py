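"""hp-discontinuous-Galerkin time stepping for the projected CME.

On each mesh interval the solution is sought as a polynomial of order
``p_m`` in time with TT-vector coefficients, coupled to the previous
endpoint through the upwind jump term.  With Legendre shape functions
on the reference interval [-1, 1] the weak form of ``y' = A y`` yields,
per interval of length ``h``, the linear system

    sum_l [ K_{l'l} I - (h/2) M_{l'l} A ] c_l = (-1)^{l'} y_prev,

where ``M`` is the (diagonal) Legendre mass matrix, and
``K_{l'l} = int P_{l'} P_l' + (-1)^{l'+l}`` collects the stiffness and
jump contributions -- all integrals in closed form.  The endpoint value
is ``sum_l c_l`` since ``P_l(1) = 1``.  The temporal coefficient index
is attached as one extra unquantized TT mode in front of the first
virtual mode, so the system matrix inherits the operator's TT structure
with every interior rank increased by at most one.

The scheme is A-stable at every order and, the CME evolution being
analytic in time, converges exponentially in the polynomial order.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assembly import CMEOperator, fsp_deficiency
from .dmrg import DMRGOptions, dmrg_solve
from .tt import (
    TTMatrix,
    TTVector,
    effective_rank,
    tt_add,
    tt_matvec,
    tt_norm,
    tt_round,
    tt_scale,
)

__all__ = [
    "TimeMesh",
    "DGStepConfig",
    "SolveResult",
    "temporal_basis",
    "assemble_step_system",
    "hpdg_solve",
    "truncate_solution",
]


@dataclass(frozen=True)
class TimeMesh:
    """Partition 0 = t_0 < t_1 < ... < t_M = T."""

    breakpoints: tuple

    def __post_init__(self):
        bp = tuple(float(t) for t in self.breakpoints)
        if len(bp) < 2 or bp[0] != 0.0 or any(b <= a for a, b in zip(bp, bp[1:])):
            raise ValueError("breakpoints must start at 0 and strictly increase")
        object.__setattr__(self, "breakpoints", bp)

    @property
    def n_steps(self) -> int:
        return len(self.breakpoints) - 1

    @property
    def step_sizes(self) -> tuple:
        return tuple(b - a for a, b in zip(self.breakpoints, self.breakpoints[1:]))

    @property
    def T(self) -> float:
        return self.breakpoints[-1]

    @staticmethod
    def uniform(T: float, n_steps: int) -> "TimeMesh":
        return TimeMesh(tuple(np.linspace(0.0, T, n_steps + 1)))

    @staticmethod
    def geometric(T: float, n_steps: int, ratio: float = 1.5) -> "TimeMesh":
        """First step small, each subsequent step ``ratio`` times
        longer; useful for resolving the initial transient."""
        w = np.cumsum(ratio ** np.arange(n_steps, dtype=float))
        return TimeMesh((0.0,) + tuple(T * w / w[-1]))

    @staticmethod
    def explicit(breakpoints) -> "TimeMesh":
        return TimeMesh(tuple(breakpoints))


@dataclass
class DGStepConfig:
    """Time-discretization and solver configuration."""

    order: int = 3              # temporal polynomial order p_m (uniform)
    eps: float = 1e-6           # end-of-step rounding tolerance
    kappa: float = 10.0         # truncation factor: eps_trunc = kappa * eps
    eps_dmrg: float = None      # solver tolerance (default eps / 2: the
                                # endpoint is rounded at eps, so residual
                                # far below eps is effort wasted)
    max_sweeps: int = 20
    rank_cap: int = 200
    kick: float = 1e-2
    max_bisections: int = 6     # adaptive halving of steps the solver rejects
    seed: int = 0
    store_endpoints: bool = True

    def __post_init__(self):
        if self.eps_dmrg is None:
            self.eps_dmrg = self.eps / 2.0
        if self.order < 0 or self.eps <= 0 or self.eps_dmrg <= 0 or self.kappa < 1:
            raise ValueError("invalid DG configuration")


def temporal_basis(p: int):
    """Closed-form Legendre data on the reference interval [-1, 1].

    Returns a dict with the mass matrix ``M`` (diag 2/(2l+1)), the
    derivative couplings ``G[l',l] = int P_{l'} P_l'``, the combined
    stiffness-plus-jump matrix ``K``, and the endpoint values
    ``phi_left = (-1)^l``, ``phi_right = 1``."""
    if p < 0:
        raise ValueError("order must be >= 0")
    n = p + 1
    M = np.diag([2.0 / (2 * l + 1) for l in range(n)])
    G = np.zeros((n, n))
    for lp in range(n):
        for l in range(n):
            if lp < l and (l - lp) % 2 == 1:
                G[lp, l] = 2.0
    phi_left = np.array([(-1.0) ** l for l in range(n)])
    phi_right = np.ones(n)
    K = G + np.outer(phi_left, phi_left)
    return {"M": M, "G": G, "K": K, "phi_left": phi_left, "phi_right": phi_right}


def _prepend_mode(A: TTMatrix, T: np.ndarray) -> TTMatrix:
    """Attach a temporal matrix block as a leading unquantized mode."""
    n = T.shape[0]
    first = T.reshape(1, n, n, 1)
    return TTMatrix([first] + [c.copy() for c in A.cores])


def assemble_step_system(A, h: float, p: int, y_prev: TTVector):
    """Per-step linear system (system matrix, right-hand side) over
    (temporal index) x (virtual state modes).  Interior TT ranks of the
    matrix exceed those of ``A`` by at most one (asserted)."""
    if h <= 0:
        raise ValueError("step size must be positive")
    Amat = A.matrix if isinstance(A, CMEOperator) else A
    if Amat.col_sizes != y_prev.mode_sizes:
        raise ValueError("operator/state mode mismatch")
    basis = temporal_basis(p)
    part_I = _prepend_mode(
        TTMatrix([np.eye(n).reshape(1, n, n, 1) for n in Amat.row_sizes]), basis["K"]
    )
    part_A = _prepend_mode(tt_scale(Amat, -h / 2.0), basis["M"])
    B = tt_add(part_I, part_A)
    rA = Amat.ranks
    rB = B.ranks
    assert all(rb <= ra + 1 for rb, ra in zip(rB[2:], rA[1:])), (
        "step-system ranks exceed the additive bound"
    )
    rhs = TTVector(
        [basis["phi_left"].reshape(1, p + 1, 1)] + [c.copy() for c in y_prev.cores]
    )
    return B, rhs


def _taylor_predictor(Amat, y: TTVector, h: float, p: int, round_tol: float,
                      max_order: int = 3) -> TTVector:
    """Warm start for the per-step solve: the truncated expansion
    ``U(t) = sum_q (t A)^q / q! y`` projected on the Legendre basis.
    Besides approximating the solution for moderate ``h |A|``, this
    seeds the alternating solver's basis with the Krylov directions
    ``y, Ay, A^2 y, ...`` along which the step actually moves -- the
    two-site sweeps are poor at discovering those from scratch."""
    from math import factorial

    from numpy.polynomial import legendre as npleg
    from numpy.polynomial import polynomial as nppoly

    Q = min(p, max_order)
    guess = None
    Aq_y = y
    for q in range(Q + 1):
        # Legendre coefficients of (1 + tau)^q on [-1, 1]
        coef = npleg.poly2leg(nppoly.polypow([1.0, 1.0], q) if q else [1.0])
        tvec = np.zeros((1, p + 1, 1))
        tvec[0, : len(coef), 0] = coef * (h / 2.0) ** q / factorial(q)
        term = TTVector([tvec] + [c.copy() for c in Aq_y.cores])
        guess = term if guess is None else tt_round(tt_add(guess, term), round_tol)
        if q < Q:
            Aq_y = tt_round(tt_matvec(Amat, Aq_y), round_tol)
    return guess


def _endpoint(coeffs: TTVector, p: int) -> TTVector:
    """Evaluate sum_l c_l P_l(1) = sum_l c_l by contracting the
    temporal mode."""
    first = coeffs.cores[0]  # (1, p+1, r)
    w = first.sum(axis=1)  # (1, r)
    rest = [c.copy() for c in coeffs.cores[1:]]
    rest[0] = np.einsum("r,rnb->nb", w[0], rest[0])[None, :, :]
    return TTVector(rest)


def _sample_min_entry(v: TTVector, rng, n_samples: int = 128) -> float:
    """Smallest entry found on randomly sampled fibers (the TT format
    does not preserve nonnegativity; this is a cheap diagnostic, not a
    guarantee)."""
    lo = np.inf
    sizes = v.mode_sizes
    idx = np.stack([rng.integers(0, n, size=n_samples) for n in sizes], axis=1)
    for row in idx:
        m = v.cores[0][:, row[0], :]
        for k in range(1, v.d):
            m = m @ v.cores[k][:, row[k], :]
        lo = min(lo, float(m[0, 0]))
    return lo


@dataclass
class SolveResult:
    """Per-step endpoint PDFs and diagnostics of an hp-DG-QTT run."""

    mesh: TimeMesh
    config: DGStepConfig
    endpoints: list
    diagnostics: pd.DataFrame
    qmap: object = None

    @property
    def final(self) -> TTVector:
        return self.endpoints[-1]


def hpdg_solve(A: CMEOperator, y0: TTVector, mesh: TimeMesh, cfg: DGStepConfig = None,
               callback=None) -> SolveResult:
    """March the projected CME over the mesh, solving one TT-structured
    linear system per step with the DMRG solver and rounding the
    endpoint at ``cfg.eps``.

    Raises RuntimeError if the solver fails to converge on any step
    (the partial diagnostics are attached to the exception)."""
    cfg = cfg or DGStepConfig()
    Amat = A.matrix if isinstance(A, CMEOperator) else A
    qmap = A.qmap if isinstance(A, CMEOperator) else None
    y = tt_round(y0, cfg.eps)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    endpoints = []
    p = cfg.order

    def _substep(y, t_left, h, depth):
        """One DG solve over [t_left, t_left + h]; on solver failure
        the interval is bisected (the alternating solver converges for
        small enough steps), up to ``cfg.max_bisections`` levels."""
        t0 = time.perf_counter()
        B, rhs = assemble_step_system(Amat, h, p, y)
        guess = _taylor_predictor(Amat, y, h, p, cfg.eps / 10.0)
        opts = DMRGOptions(
            max_sweeps=cfg.max_sweeps,
            rank_cap=cfg.rank_cap,
            kick=cfg.kick,
            seed=int(rng.integers(0, 2**31 - 1)),
            x0=guess,
        )
        coeffs, rep = dmrg_solve(B, rhs, cfg.eps_dmrg, opts)
        if not rep.converged:
            if depth < cfg.max_bisections:
                y_mid = _substep(y, t_left, h / 2.0, depth + 1)
                return _substep(y_mid, t_left + h / 2.0, h / 2.0, depth + 1)
            diag = pd.DataFrame(rows)
            err = RuntimeError(
                f"DMRG did not converge at t = {t_left + h:.4g} even after "
                f"{cfg.max_bisections} bisections: {rep.message}"
            )
            err.diagnostics = diag
            raise err
        ynew = tt_round(_endpoint(coeffs, p), cfg.eps)
        ny = tt_norm(ynew)
        if not np.isfinite(ny) or ny == 0.0:
            raise RuntimeError(f"non-finite endpoint at t = {t_left + h:.4g}")
        Ay = tt_round(tt_matvec(Amat, ynew), cfg.eps)
        prof = effective_rank(ynew)
        rows.append(
            {
                "t": t_left + h,
                "h": h,
                "order": p,
                "depth": depth,
                "r_max": prof.r_max,
                "r_eff": prof.r_eff,
                "deficiency": fsp_deficiency(ynew),
                "rel_deriv": tt_norm(Ay) / ny,
                "residual": rep.residuals[-1] if rep.residuals else np.nan,
                "sweeps": rep.sweeps,
                "converged": rep.converged,
                "min_sampled": _sample_min_entry(ynew, rng),
                "wall_time": time.perf_counter() - t0,
            }
        )
        return ynew

    for m, h in enumerate(mesh.step_sizes):
        y = _substep(y, mesh.breakpoints[m], h, 0)
        rows[-1]["step"] = m
        if cfg.store_endpoints:
            endpoints.append(y)
        if callback is not None:
            callback(m, y, rows[-1])
    if not cfg.store_endpoints:
        endpoints = [y]
    return SolveResult(
        mesh=mesh,
        config=cfg,
        endpoints=endpoints,
        diagnostics=pd.DataFrame(rows),
        qmap=qmap,
    )


def truncate_solution(p: TTVector, eps_trunc: float) -> TTVector:
    """End-of-run re-approximation at ``eps_trunc = kappa * eps``: the
    discrepancy from a reference grows by at most a factor tied to
    kappa while the ranks typically drop."""
    return tt_round(p, eps_trunc)
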