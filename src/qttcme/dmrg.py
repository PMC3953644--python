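"""Alternating two-site (DMRG-type) solver for TT-structured linear
systems ``A x = b``.

The solution is swept core pair by core pair: with all other cores
fixed and orthogonalized around the active pair, the problem restricts
to a small local linear system obtained by Galerkin projection of A
onto the current solution basis.  Solving it, re-splitting the merged
pair by a truncated SVD, and moving on adapts both the ranks and the
"basis" of the solution as the sweeps progress.  A small, seeded
random rank enrichment ("kick") guards against stagnation in a
too-small basis.  The scheme has no global convergence guarantee;
non-convergence is a reportable outcome carrying the best iterate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tt import (
    TTMatrix,
    TTVector,
    tt_add,
    tt_mat_transpose,
    tt_matmat,
    tt_matvec,
    tt_norm,
    tt_round,
    tt_scale,
)

__all__ = ["DMRGOptions", "DMRGReport", "dmrg_solve", "residual"]


@dataclass
class DMRGOptions:
    max_sweeps: int = 20
    rank_cap: int = 200
    kick: float = 1e-2          # relative magnitude of the per-bond enrichment
    kick_rank: int = 1
    enrich: float = 1e-2        # relative magnitude of the initial-guess
    enrich_rank: int = 2        # random-rank enrichment (0 disables)
    method: str = "normal"      # 'normal': sweep on the Gram system
                                # A^T A x = A^T b, each local solve then
                                # minimizes the true residual (monotone);
                                # 'galerkin': oblique projection of A
    gram_round: float = 1e-13   # rounding of A^T A / A^T b ('normal')
    seed: int = 0
    dense_cap: int = 4096       # largest local system solved directly
    x0: TTVector = None
    verbose: bool = False


@dataclass
class DMRGReport:
    converged: bool
    residuals: list = field(default_factory=list)  # per-sweep global residuals
    sweeps: int = 0
    message: str = ""
    max_rank: int = 0


def residual(A: TTMatrix, x: TTVector, b: TTVector, round_tol: float = 1e-12) -> float:
    """Relative residual ||Ax - b|| / ||b|| computed in TT arithmetic,
    with one rounding of the difference at ``round_tol``."""
    r = tt_add(tt_matvec(A, x), tt_scale(b, -1.0))
    if round_tol > 0:
        r = tt_round(r, round_tol)
    nb = tt_norm(b)
    if nb == 0.0:
        raise ValueError("zero right-hand side")
    return tt_norm(r) / nb


def _orthogonalize_rl(cores):
    """Right-to-left orthogonalization (every core right-orthogonal
    except the first, which carries the norm)."""
    for k in range(len(cores) - 1, 0, -1):
        r0, n, r1 = cores[k].shape
        M = cores[k].reshape(r0, n * r1)
        Q, R = np.linalg.qr(M.T)
        rk = Q.shape[1]
        cores[k] = Q.T.reshape(rk, n, r1)
        cores[k - 1] = np.tensordot(cores[k - 1], R.T, axes=(2, 0))
    return cores


def _env_A(L, Xc, Ac, Yc):
    """Extend a left environment (rx, rA, ry) by one site."""
    # L[p,a,q], X[p,i,p'], A[a,i,j,a'], Y[q,j,q'] -> (p',a',q')
    t = np.tensordot(L, Xc, axes=(0, 0))          # (a,q,i,p')
    t = np.tensordot(t, Ac, axes=([0, 2], [0, 1]))  # (q,p',j,a')
    return np.tensordot(t, Yc, axes=([0, 2], [0, 1]))  # (p',a',q')


def _env_A_right(R, Xc, Ac, Yc):
    """Extend a right environment (rx, rA, ry) by one site leftwards."""
    # R[p,a,q], X[p',i,p], A[a',i,j,a], Y[q',j,q] -> (p',a',q')
    t = np.tensordot(R, Xc, axes=(0, 2))          # (a,q,p',i)
    t = np.tensordot(t, Ac, axes=([0, 3], [3, 1]))  # (q,p',a',j)
    return np.tensordot(t, Yc, axes=([0, 3], [2, 1]))  # (p',a',q')


def _env_b(L, Xc, Bc):
    # L[p,c], X[p,i,p'], B[c,i,c'] -> (p',c')
    t = np.tensordot(L, Xc, axes=(0, 0))  # (c,i,p')
    return np.tensordot(t, Bc, axes=([0, 1], [0, 1]))  # (p',c')


def _env_b_right(R, Xc, Bc):
    # R[p,c], X[p',i,p], B[c',i,c] -> (p',c')
    t = np.tensordot(R, Xc, axes=(0, 2))  # (c,p',i)
    return np.tensordot(t, Bc, axes=([0, 2], [2, 1]))  # (p',c')


def _local_operator(Lenv, A1, A2, Renv):
    """Dense local matrix over (rxl, n1, n2, rxr) row/col indices."""
    # Lenv[p,a,q], A1[a,i,u,m], A2[m,j,v,c], Renv[r,c,s]
    t = np.einsum("paq,aium->piqum", Lenv, A1, optimize=True)
    t2 = np.einsum("piqum,mjvc->piqujvc", t, A2, optimize=True)
    out = np.einsum("piqujvc,rcs->pijrquvs", t2, Renv, optimize=True)
    # rows (p,i,j,r), cols (q,u,v,s)
    sh = out.shape
    return out.reshape(sh[0] * sh[1] * sh[2] * sh[3], sh[4] * sh[5] * sh[6] * sh[7])


def _local_rhs(Lb, b1, b2, Rb):
    # Lb[p,c], b1[c,i,m], b2[m,j,e], Rb[q,e]
    t = np.einsum("pc,cim->pim", Lb, b1, optimize=True)
    t = np.einsum("pim,mje->pije", t, b2, optimize=True)
    out = np.einsum("pije,qe->pijq", t, Rb, optimize=True)
    return out.reshape(-1)


def _svd_split(W, rxl, n1, n2, rxr, delta, rank_cap):
    M = W.reshape(rxl * n1, n2 * rxr)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    if s[0] == 0.0:
        r = 1
    else:
        tail = np.sqrt(np.cumsum(s[::-1] ** 2))[::-1]
        r = max(1, int(np.sum(tail >= delta)))
    r = min(r, rank_cap)
    return U[:, :r], s[:r], Vt[:r]


def dmrg_solve(A: TTMatrix, b: TTVector, tol: float, opts: DMRGOptions = None):
    """Solve ``A x = b`` to relative residual ``tol``.

    Returns ``(x, report)``; ``report.converged`` is False when the
    sweep budget is exhausted, in which case ``x`` is the best iterate
    seen (smallest residual)."""
    opts = opts or DMRGOptions()
    rng = np.random.default_rng(opts.seed)
    D = b.d
    if A.col_sizes != b.mode_sizes or A.row_sizes != b.mode_sizes:
        raise ValueError("operator/right-hand-side mode mismatch")
    nb = tt_norm(b)
    if nb == 0.0:
        raise ValueError("zero right-hand side")
    if D == 1:
        M = A.cores[0][0, :, :, 0]
        x = np.linalg.solve(M, b.cores[0][0, :, 0])
        xv = TTVector([x.reshape(1, -1, 1)])
        rep = DMRGReport(True, [residual(A, xv, b)], 1, "single-mode dense solve", 1)
        return xv, rep

    if opts.method == "normal":
        At = tt_mat_transpose(A)
        Aw = tt_round(tt_matmat(At, A), opts.gram_round)
        bw = tt_round(tt_matvec(At, b), opts.gram_round)
    elif opts.method == "galerkin":
        Aw, bw = A, b
    else:
        raise ValueError("method must be 'normal' or 'galerkin'")

    if opts.x0 is not None:
        xv0 = opts.x0
    else:
        xv0 = TTVector([rng.standard_normal((1, n, 1)) for n in b.mode_sizes])
    if opts.enrich > 0 and opts.enrich_rank > 0:
        # low-rank starts stall the alternating sweeps (the oblique
        # local projections cannot see directions outside the frozen
        # bases); a small random additive component opens every bond
        from .tt import tt_random

        pert = tt_random(xv0.mode_sizes, (opts.enrich_rank,) * (D - 1), rng)
        n0 = tt_norm(xv0)
        npert = tt_norm(pert)
        if npert > 0:
            scale = opts.enrich * (n0 if n0 > 0 else 1.0) / npert
            xv0 = tt_add(xv0, tt_scale(pert, scale))
    x = [c.copy() for c in xv0.cores]
    _orthogonalize_rl(x)
    if np.linalg.norm(x[0]) == 0.0:
        x[0] = rng.standard_normal(x[0].shape)

    # environments: LA[k] covers cores < k ; RA[k] covers cores > k
    LA = [np.ones((1, 1, 1))] * (D + 1)
    Lb = [np.ones((1, 1))] * (D + 1)
    RA = [np.ones((1, 1, 1))] * (D + 1)
    Rb = [np.ones((1, 1))] * (D + 1)
    for k in range(D - 1, 0, -1):
        RA[k] = _env_A_right(RA[k + 1], x[k], Aw.cores[k], x[k])
        Rb[k] = _env_b_right(Rb[k + 1], x[k], bw.cores[k])

    # the 0.3 safety factor keeps the per-bond truncation floor below
    # the requested residual; tightened further if the sweeps plateau
    # above tol (the floor scales with the operator norm)
    delta_fac = 0.3 * tol / np.sqrt(max(D - 1, 1))
    delta_floor = delta_fac * 1e-4
    best = None
    best_res = np.inf
    report = DMRGReport(False)

    def solve_bond(k, direction):
        rxl = x[k].shape[0]
        rxr = x[k + 1].shape[2]
        n1, n2 = x[k].shape[1], x[k + 1].shape[1]
        m = rxl * n1 * n2 * rxr
        rhs = _local_rhs(Lb[k], bw.cores[k], bw.cores[k + 1], Rb[k + 2])
        if m <= opts.dense_cap:
            Bloc = _local_operator(LA[k], Aw.cores[k], Aw.cores[k + 1], RA[k + 2])
            try:
                W = np.linalg.solve(Bloc, rhs)
            except np.linalg.LinAlgError:
                W = np.linalg.lstsq(
                    Bloc + 1e-12 * np.linalg.norm(Bloc) * np.eye(m), rhs, rcond=None
                )[0]
                report.message = "regularized singular local system"
        else:
            from scipy.sparse.linalg import LinearOperator, cg, gmres

            Lenv, A1, A2, Renv = LA[k], Aw.cores[k], Aw.cores[k + 1], RA[k + 2]

            def mv(vec):
                V = vec.reshape(rxl, n1, n2, rxr)
                # contract Lenv[p,a,q] V[q,u,v,s] A1[a,i,u,m] A2[m,j,v,c]
                # Renv[r,c,s] via tensordot (no einsum-path overhead)
                t = np.tensordot(Lenv, V, axes=(2, 0))        # (p,a,u,v,s)
                t = np.tensordot(t, A1, axes=([1, 2], [0, 2]))  # (p,v,s,i,m)
                t = np.tensordot(t, A2, axes=([1, 4], [2, 0]))  # (p,s,i,j,c)
                t = np.tensordot(t, Renv, axes=([4, 1], [1, 2]))  # (p,i,j,r)
                return t.reshape(-1)

            x0loc = np.einsum("aib,bjc->aijc", x[k], x[k + 1]).reshape(-1)
            lop = LinearOperator((m, m), matvec=mv)
            if opts.method == "normal":
                # local Gram operator is symmetric positive definite
                W, info = cg(lop, rhs, rtol=max(tol * 0.03, 1e-12),
                             maxiter=1000, x0=x0loc)
            else:
                W, info = gmres(lop, rhs, rtol=max(tol * 0.1, 1e-12),
                                maxiter=400, x0=x0loc)
            if info != 0:
                report.message = f"local iterative solve not converged (info={info})"
        Wn = np.linalg.norm(W)
        delta = delta_fac * Wn
        U, s, Vt = _svd_split(W, rxl, n1, n2, rxr, delta, opts.rank_cap)
        r = U.shape[1]
        if direction > 0:
            # left core orthogonal; carry S V^T right; enrich basis
            left = U
            right = s[:, None] * Vt
            if opts.kick > 0 and not polishing and r < opts.rank_cap:
                kcols = min(opts.kick_rank, opts.rank_cap - r)
                K = rng.standard_normal((left.shape[0], kcols))
                K -= left @ (left.T @ K)
                norms = np.linalg.norm(K, axis=0)
                keep = norms > 1e-12
                if np.any(keep):
                    K = K[:, keep] / norms[keep] * (opts.kick * max(Wn, 1e-300))
                    left = np.concatenate([left, K], axis=1)
                    right = np.concatenate(
                        [right, np.zeros((K.shape[1], right.shape[1]))], axis=0
                    )
                    r = left.shape[1]
            x[k] = left.reshape(rxl, n1, r)
            x[k + 1] = right.reshape(r, n2, rxr)
            LA[k + 1] = _env_A(LA[k], x[k], Aw.cores[k], x[k])
            Lb[k + 1] = _env_b(Lb[k], x[k], bw.cores[k])
        else:
            x[k] = (U * s).reshape(rxl, n1, r)
            x[k + 1] = Vt.reshape(r, n2, rxr)
            RA[k + 1] = _env_A_right(RA[k + 2], x[k + 1], Aw.cores[k + 1], x[k + 1])
            Rb[k + 1] = _env_b_right(Rb[k + 2], x[k + 1], bw.cores[k + 1])

    polishing = False
    for sweep in range(opts.max_sweeps + 1):
        for k in range(D - 1):
            solve_bond(k, +1)
        for k in range(D - 2, -1, -1):
            solve_bond(k, -1)
        # after the backward half-sweep the center sits at core 0; the
        # left environments are stale beyond it, which is fine
        LA[1:] = [np.ones((1, 1, 1))] * D
        Lb[1:] = [np.ones((1, 1))] * D
        xv = TTVector([c.copy() for c in x])
        res = residual(A, xv, b, round_tol=min(tol * 0.1, 1e-12))
        report.residuals.append(res)
        report.sweeps = sweep + 1
        report.max_rank = max(xv.ranks)
        if opts.verbose:
            print(f"  dmrg sweep {sweep + 1}: residual {res:.3e} rmax {report.max_rank}")
        if res < best_res or (polishing and res <= tol):
            best_res = min(res, best_res)
            best = xv
        if polishing:
            report.converged = best_res <= tol
            return best, report
        if res <= tol:
            # one final sweep without random enrichment cleans the
            # spurious rank the kicks left in the iterate
            if opts.kick <= 0:
                report.converged = True
                return xv, report
            polishing = True
            continue
        if len(report.residuals) >= 2 and res > 0.5 * report.residuals[-2]:
            # plateau above tol: the truncation floor dominates
            delta_fac = max(delta_fac * 0.3, delta_floor)
    report.message = report.message or (
        f"no convergence after {opts.max_sweeps} sweeps; best residual {best_res:.3e}"
    )
    return best, report
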