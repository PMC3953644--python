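"""Tensor-train (TT) vectors and matrices.

A d-way array ``v[i_1, ..., i_d]`` is held as a chain of 3-way cores
``G_k`` of shape ``(r_{k-1}, n_k, r_k)`` with boundary ranks
``r_0 = r_d = 1``; the entry at a multi-index is the product of the
matrix slices selected from each core.  Minimal TT ranks equal the ranks
of the unfolding matrices of the array, which is what makes an SVD-based
construction (:func:`tt_from_dense`) and a stable, quasi-optimal
rounding procedure (:func:`tt_round`) possible.  Matrices carry 4-way
cores ``(r_{k-1}, m_k, n_k, r_k)`` and are handled by vectorizing and
merging the row/column index pairs.

All scalars are double precision.  Zero vectors are represented with
all-rank-one zero cores and rounding leaves them untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TTVector",
    "TTMatrix",
    "RankProfile",
    "tt_from_dense",
    "tt_to_dense",
    "tt_mat_to_dense",
    "tt_kron",
    "tt_unit",
    "tt_round",
    "tt_add",
    "tt_scale",
    "tt_matvec",
    "tt_matmat",
    "tt_dot",
    "tt_norm",
    "tt_ones",
    "tt_identity",
    "tt_rank_one",
    "tt_random",
    "effective_rank",
    "memory_count",
]

_EPS = np.finfo(np.float64).eps

# Guard against accidentally materializing, e.g., a 2^60-entry array.
DENSE_BUDGET = 2**24


def _as_float_cores(cores):
    out = []
    for c in cores:
        c = np.ascontiguousarray(np.asarray(c, dtype=np.float64))
        if not np.all(np.isfinite(c)):
            raise ValueError("non-finite entries in TT core")
        out.append(c)
    return out


@dataclass
class TTVector:
    """Tensor-train representation of a d-way array."""

    cores: list = field(default_factory=list)

    def __post_init__(self):
        self.cores = _as_float_cores(self.cores)
        if not self.cores:
            raise ValueError("TTVector needs at least one core")
        for c in self.cores:
            if c.ndim != 3:
                raise ValueError("vector cores must be 3-way")
        if self.cores[0].shape[0] != 1 or self.cores[-1].shape[-1] != 1:
            raise ValueError("boundary ranks must be 1")
        for a, b in zip(self.cores[:-1], self.cores[1:]):
            if a.shape[-1] != b.shape[0]:
                raise ValueError("mismatched bond ranks between cores")

    @property
    def d(self) -> int:
        return len(self.cores)

    @property
    def mode_sizes(self) -> tuple:
        return tuple(c.shape[1] for c in self.cores)

    @property
    def ranks(self) -> tuple:
        return (1,) + tuple(c.shape[-1] for c in self.cores)

    def copy(self) -> "TTVector":
        return TTVector([c.copy() for c in self.cores])


@dataclass
class TTMatrix:
    """Tensor-train representation of a (row multi-index, column
    multi-index) matrix; core k is ``(r_{k-1}, m_k, n_k, r_k)``."""

    cores: list = field(default_factory=list)

    def __post_init__(self):
        self.cores = _as_float_cores(self.cores)
        if not self.cores:
            raise ValueError("TTMatrix needs at least one core")
        for c in self.cores:
            if c.ndim != 4:
                raise ValueError("matrix cores must be 4-way")
        if self.cores[0].shape[0] != 1 or self.cores[-1].shape[-1] != 1:
            raise ValueError("boundary ranks must be 1")
        for a, b in zip(self.cores[:-1], self.cores[1:]):
            if a.shape[-1] != b.shape[0]:
                raise ValueError("mismatched bond ranks between cores")

    @property
    def d(self) -> int:
        return len(self.cores)

    @property
    def row_sizes(self) -> tuple:
        return tuple(c.shape[1] for c in self.cores)

    @property
    def col_sizes(self) -> tuple:
        return tuple(c.shape[2] for c in self.cores)

    @property
    def ranks(self) -> tuple:
        return (1,) + tuple(c.shape[-1] for c in self.cores)

    def copy(self) -> "TTMatrix":
        return TTMatrix([c.copy() for c in self.cores])

    def as_vector(self) -> TTVector:
        """Merge row/column modes: core ``(r, m, n, r')`` becomes
        ``(r, m*n, r')``."""
        return TTVector([c.reshape(c.shape[0], -1, c.shape[3]) for c in self.cores])

    @staticmethod
    def from_vector(v: TTVector, row_sizes, col_sizes) -> "TTMatrix":
        cores = []
        for c, m, n in zip(v.cores, row_sizes, col_sizes):
            if c.shape[1] != m * n:
                raise ValueError("mode size does not factor into (row, col) pair")
            cores.append(c.reshape(c.shape[0], m, n, c.shape[2]))
        return TTMatrix(cores)


@dataclass(frozen=True)
class RankProfile:
    """Rank diagnostics: the rank tuple, its maximum, and the effective
    rank -- the uniform rank whose TT storage equals the given one."""

    ranks: tuple
    r_max: int
    r_eff: float


# ---------------------------------------------------------------------------
# construction / expansion


def _svd_trunc(M: np.ndarray, delta: float):
    """SVD of ``M`` truncated so the discarded tail has Frobenius norm
    strictly below ``delta``.  With ``delta == 0`` only the numerical
    nullspace (relative to machine precision) is discarded, so ranks
    equal the exact matrix rank.  Singular values whose removal would
    make the tail exactly ``delta`` are retained (tie toward larger
    rank)."""
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    if s.size == 0 or s[0] == 0.0:
        return U[:, :1] * 0.0, np.zeros(1), Vt[:1] * 0.0
    if delta <= 0.0:
        tol = s[0] * max(M.shape) * _EPS
        r = int(np.sum(s > tol))
    else:
        tail = np.sqrt(np.cumsum(s[::-1] ** 2))[::-1]  # tail[r] = ||s[r:]||
        keep = tail >= delta  # discard only if tail < delta
        r = int(np.sum(keep))
    r = max(r, 1)
    return U[:, :r], s[:r], Vt[:r]


def tt_from_dense(full: np.ndarray, tol: float) -> TTVector:
    """TT-SVD of a dense array: successive truncated SVDs of the
    unfoldings, per-unfolding threshold ``tol * ||v|| / sqrt(d-1)``
    (Frobenius quasi-optimality)."""
    full = np.asarray(full, dtype=np.float64)
    if full.size == 0:
        raise ValueError("empty array")
    if not np.all(np.isfinite(full)):
        raise ValueError("non-finite entries")
    if tol < 0:
        raise ValueError("tol must be >= 0")
    shape = full.shape if full.ndim > 0 else (1,)
    d = len(shape)
    nrm = np.linalg.norm(full)
    delta = tol * nrm / np.sqrt(max(d - 1, 1))
    cores = []
    C = full.reshape(1, *shape)
    r = 1
    for k in range(d - 1):
        M = C.reshape(r * shape[k], -1)
        U, s, Vt = _svd_trunc(M, delta)
        rk = U.shape[1]
        cores.append(U.reshape(r, shape[k], rk))
        C = (s[:, None] * Vt).reshape(rk, *shape[k + 1 :])
        r = rk
    cores.append(C.reshape(r, shape[-1], 1))
    return TTVector(cores)


def tt_to_dense(v: TTVector, budget: int = DENSE_BUDGET) -> np.ndarray:
    """Contract all cores into the full array (refuses above ``budget``
    entries)."""
    total = int(np.prod([float(n) for n in v.mode_sizes]))
    if np.prod([float(n) for n in v.mode_sizes]) > budget:
        raise MemoryError(
            f"dense expansion of {total} entries exceeds budget {budget}"
        )
    out = v.cores[0]  # (1, n_1, r_1)
    for c in v.cores[1:]:
        out = np.tensordot(out, c, axes=(-1, 0))
    return out.reshape(v.mode_sizes)


def tt_mat_to_dense(A: TTMatrix, budget: int = DENSE_BUDGET) -> np.ndarray:
    """Dense 2-D matrix of a TTMatrix (rows = merged row modes, Fortran
    order over modes to match the state enumeration used throughout)."""
    full = tt_to_dense(A.as_vector(), budget=budget)
    d = A.d
    rs, cs = A.row_sizes, A.col_sizes
    full = full.reshape(sum(([m, n] for m, n in zip(rs, cs)), []))
    # axes (m1, n1, m2, n2, ...) -> (m_d..m_1? ) we want standard kron-F:
    # row index i = i_1 + m_1 i_2 + ... (first species fastest)
    perm = list(range(0, 2 * d, 2)) + list(range(1, 2 * d, 2))
    full = full.transpose(perm)
    M = int(np.prod(rs))
    N = int(np.prod(cs))
    return full.reshape(M, N, order="F").copy()


# ---------------------------------------------------------------------------
# arithmetic


def tt_scale(a: TTVector | TTMatrix, c: float):
    out = a.copy()
    out.cores[0] = out.cores[0] * float(c)
    return out


def tt_add(a, b):
    """Exact TT sum via block-diagonal cores; interior ranks add."""
    mat = isinstance(a, TTMatrix)
    if mat != isinstance(b, TTMatrix):
        raise ValueError("cannot add TTVector and TTMatrix")
    av = a.as_vector() if mat else a
    bv = b.as_vector() if mat else b
    if av.mode_sizes != bv.mode_sizes:
        raise ValueError(f"mode-size mismatch: {av.mode_sizes} vs {bv.mode_sizes}")
    d = av.d
    if d == 1:
        out = TTVector([av.cores[0] + bv.cores[0]])
    else:
        cores = []
        for k in range(d):
            A, B = av.cores[k], bv.cores[k]
            n = A.shape[1]
            if k == 0:
                cores.append(np.concatenate([A, B], axis=2))
            elif k == d - 1:
                cores.append(np.concatenate([A, B], axis=0))
            else:
                ra0, _, ra1 = A.shape
                rb0, _, rb1 = B.shape
                C = np.zeros((ra0 + rb0, n, ra1 + rb1))
                C[:ra0, :, :ra1] = A
                C[ra0:, :, ra1:] = B
                cores.append(C)
        out = TTVector(cores)
    if mat:
        return TTMatrix.from_vector(out, a.row_sizes, a.col_sizes)
    return out


def tt_dot(a: TTVector, b: TTVector) -> float:
    if a.mode_sizes != b.mode_sizes:
        raise ValueError("mode-size mismatch")
    W = np.ones((1, 1))
    for A, B in zip(a.cores, b.cores):
        # W[p, q] ; A[p, i, p'] ; B[q, i, q'] -> W'[p', q']
        W = np.einsum("pq,pir,qis->rs", W, A, B, optimize=True)
    return float(W[0, 0])


def tt_norm(v: TTVector) -> float:
    return float(np.sqrt(max(tt_dot(v, v), 0.0)))


def tt_matvec(A: TTMatrix, v: TTVector) -> TTVector:
    """Exact TT matrix-vector product; ranks multiply elementwise."""
    if A.col_sizes != v.mode_sizes:
        raise ValueError("mode-size mismatch between matrix columns and vector")
    cores = []
    for M, V in zip(A.cores, v.cores):
        C = np.einsum("amnb,cnd->acmbd", M, V, optimize=True)
        ra, rc = M.shape[0], V.shape[0]
        rb, rd = M.shape[3], V.shape[2]
        cores.append(C.reshape(ra * rc, M.shape[1], rb * rd))
    return TTVector(cores)


def tt_mat_transpose(A: TTMatrix) -> TTMatrix:
    return TTMatrix([c.transpose(0, 2, 1, 3).copy() for c in A.cores])


def tt_matmat(A: TTMatrix, B: TTMatrix) -> TTMatrix:
    if A.col_sizes != B.row_sizes:
        raise ValueError("inner mode-size mismatch")
    cores = []
    for M, N in zip(A.cores, B.cores):
        C = np.einsum("amnb,cnkd->acmkbd", M, N, optimize=True)
        cores.append(
            C.reshape(M.shape[0] * N.shape[0], M.shape[1], N.shape[2], M.shape[3] * N.shape[3])
        )
    return TTMatrix(cores)


# ---------------------------------------------------------------------------
# rounding


def tt_round(v, tol: float):
    """Round a TT object: left-to-right QR orthogonalization followed by
    a right-to-left sweep of truncated SVDs with per-bond threshold
    ``tol * ||v|| / sqrt(d-1)``.  Ranks never increase; the relative
    Frobenius error is at most ``tol``."""
    if tol < 0:
        raise ValueError("tol must be >= 0")
    mat = isinstance(v, TTMatrix)
    w = v.as_vector() if mat else v
    d = w.d
    if d == 1:
        return v.copy()
    cores = [c.copy() for c in w.cores]
    # left-to-right QR
    for k in range(d - 1):
        r0, n, r1 = cores[k].shape
        Q, R = np.linalg.qr(cores[k].reshape(r0 * n, r1))
        cores[k] = Q.reshape(r0, n, Q.shape[1])
        cores[k + 1] = np.tensordot(R, cores[k + 1], axes=(1, 0))
    nrm = np.linalg.norm(cores[-1])
    if nrm == 0.0:
        out = TTVector([np.zeros((1, c.shape[1], 1)) for c in cores])
        return TTMatrix.from_vector(out, v.row_sizes, v.col_sizes) if mat else out
    delta = tol * nrm / np.sqrt(d - 1)
    # right-to-left SVD truncation
    for k in range(d - 1, 0, -1):
        r0, n, r1 = cores[k].shape
        U, s, Vt = _svd_trunc(cores[k].reshape(r0, n * r1), delta)
        rk = Vt.shape[0]
        cores[k] = Vt.reshape(rk, n, r1)
        cores[k - 1] = np.tensordot(cores[k - 1], U * s, axes=(2, 0))
    out = TTVector(cores)
    if mat:
        return TTMatrix.from_vector(out, v.row_sizes, v.col_sizes)
    return out


# ---------------------------------------------------------------------------
# simple constructors


def tt_rank_one(factors) -> TTVector:
    """Rank-one TT from per-mode factor vectors."""
    return TTVector([np.asarray(f, dtype=np.float64).reshape(1, -1, 1) for f in factors])


def tt_ones(mode_sizes) -> TTVector:
    return tt_rank_one([np.ones(n) for n in mode_sizes])


def tt_identity(mode_sizes) -> TTMatrix:
    return TTMatrix([np.eye(n).reshape(1, n, n, 1) for n in mode_sizes])


def tt_unit(mode_sizes, index) -> TTVector:
    """Point mass (canonical basis vector) at a multi-index."""
    fac = []
    for n, i in zip(mode_sizes, index):
        e = np.zeros(n)
        e[i] = 1.0
        fac.append(e)
    return tt_rank_one(fac)


def tt_random(mode_sizes, ranks, rng) -> TTVector:
    """Random TT with prescribed interior ranks (for tests/initial
    guesses)."""
    d = len(mode_sizes)
    rr = [1] + list(ranks) + [1] if len(ranks) == d - 1 else list(ranks)
    cores = [rng.standard_normal((rr[k], mode_sizes[k], rr[k + 1])) for k in range(d)]
    return TTVector(cores)


def tt_kron(a, b):
    """TT Kronecker-type concatenation: modes of ``a`` followed by modes
    of ``b`` (exact, ranks unchanged; boundary ranks are 1)."""
    if isinstance(a, TTMatrix) != isinstance(b, TTMatrix):
        raise ValueError("operands must both be vectors or both matrices")
    cls = TTMatrix if isinstance(a, TTMatrix) else TTVector
    return cls([c.copy() for c in a.cores] + [c.copy() for c in b.cores])


# ---------------------------------------------------------------------------
# diagnostics


def memory_count(v) -> int:
    """Total number of stored core parameters."""
    return int(sum(c.size for c in v.cores))


def effective_rank(v) -> RankProfile:
    """Effective rank: positive root of the quadratic equating the
    stored parameter count with that of a uniform-rank representation
    over the same mode sizes."""
    if isinstance(v, TTMatrix):
        sizes = [m * n for m, n in zip(v.row_sizes, v.col_sizes)]
    else:
        sizes = list(v.mode_sizes)
    ranks = v.ranks
    mem = memory_count(v)
    d = len(sizes)
    if d == 1:
        return RankProfile(ranks=tuple(ranks), r_max=max(ranks), r_eff=1.0)
    # uniform memory: n_1 r + (sum interior n_k) r^2 + n_d r
    a = float(sum(sizes[1:-1]))
    b = float(sizes[0] + sizes[-1])
    if a == 0.0:
        r_eff = mem / b
    else:
        r_eff = (-b + np.sqrt(b * b + 4.0 * a * mem)) / (2.0 * a)
    return RankProfile(ranks=tuple(ranks), r_max=int(max(ranks)), r_eff=float(r_eff))
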