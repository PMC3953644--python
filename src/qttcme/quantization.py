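"""Quantized indexing: folding physical copy-number indices into binary
virtual levels, and the two virtual-index orderings.

A species index ``x_k`` in ``{0 .. n_k - 1}`` with ``n_k = 2^{l_k}`` is
expanded in positional notation with the least-significant level first
(little-endian).  Under the *natural* ordering the virtual slots are
grouped by species, ``(i_{1,1} .. i_{1,l_1}, i_{2,1} .. )``; under the
*transposed* ordering (QT3) slots of the same level across species are
adjacent, ``(i_{1,1}, i_{2,1}, .., i_{1,2}, i_{2,2}, ..)``.  When the
level counts differ, species are padded with void (size-one) slots at
their most-significant end, permuted, and the voids dropped -- an exact
operation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tt import TTMatrix, TTVector, tt_from_dense, tt_round, _svd_trunc

__all__ = [
    "QuantizationMap",
    "fold_index",
    "unfold_index",
    "quantize",
    "reorder_dimensions",
    "transpose_permutation",
]


def fold_index(i: int, bases) -> tuple:
    """Positional-notation digits of ``i``, least-significant first."""
    bases = tuple(int(b) for b in bases)
    total = int(np.prod(bases))
    if not 0 <= i < total:
        raise ValueError(f"index {i} out of range for bases {bases}")
    digits = []
    for b in bases:
        digits.append(i % b)
        i //= b
    return tuple(digits)


def unfold_index(digits, bases) -> int:
    bases = tuple(int(b) for b in bases)
    if len(digits) != len(bases):
        raise ValueError("digit/base length mismatch")
    i, scale = 0, 1
    for t, b in zip(digits, bases):
        if not 0 <= t < b:
            raise ValueError("digit out of range")
        i += t * scale
        scale *= b
    return i


@dataclass(frozen=True)
class QuantizationMap:
    """Bookkeeping between physical species indices and virtual slots.

    ``factors[k]`` are the per-level bases of species ``k`` (all 2 by
    default); their product is the mode size ``n_k``.  ``slots`` lists,
    in TT core order, which ``(species, level)`` each virtual mode
    represents.
    """

    mode_sizes: tuple
    factors: tuple = None
    ordering: str = "natural"

    def __post_init__(self):
        object.__setattr__(self, "mode_sizes", tuple(int(n) for n in self.mode_sizes))
        if self.factors is None:
            fac = []
            for n in self.mode_sizes:
                if n < 2 or n & (n - 1):
                    raise ValueError(f"mode size {n} is not a power of two")
                fac.append((2,) * (int(n).bit_length() - 1))
            object.__setattr__(self, "factors", tuple(fac))
        else:
            fac = tuple(tuple(int(b) for b in f) for f in self.factors)
            for n, f in zip(self.mode_sizes, fac):
                if int(np.prod(f)) != n:
                    raise ValueError(f"factors {f} do not multiply to mode size {n}")
            object.__setattr__(self, "factors", fac)
        if self.ordering not in ("natural", "transposed"):
            raise ValueError("ordering must be 'natural' or 'transposed'")

    @property
    def physical_dims(self) -> int:
        return len(self.mode_sizes)

    @property
    def levels_per_dim(self) -> tuple:
        return tuple(len(f) for f in self.factors)

    @property
    def natural_slots(self) -> tuple:
        return tuple(
            (k, lam)
            for k in range(self.physical_dims)
            for lam in range(len(self.factors[k]))
        )

    @property
    def slots(self) -> tuple:
        """(species, level) per virtual mode, in TT core order."""
        if self.ordering == "natural":
            return self.natural_slots
        lmax = max(self.levels_per_dim)
        out = []
        for lam in range(lmax):
            for k in range(self.physical_dims):
                if lam < len(self.factors[k]):
                    out.append((k, lam))
        return tuple(out)

    @property
    def permutation(self) -> tuple:
        """Position in the natural ordering of each slot of this
        ordering: ``slots[j] == natural_slots[permutation[j]]``."""
        nat = {s: i for i, s in enumerate(self.natural_slots)}
        return tuple(nat[s] for s in self.slots)

    @property
    def virtual_sizes(self) -> tuple:
        return tuple(self.factors[k][lam] for k, lam in self.slots)


def transpose_permutation(qmap: QuantizationMap) -> tuple:
    """Permutation taking natural-order virtual modes to transposed
    order (void slots already dropped)."""
    return QuantizationMap(qmap.mode_sizes, qmap.factors, "transposed").permutation


# ---------------------------------------------------------------------------


def _quantize_dense(v: np.ndarray, qmap: QuantizationMap) -> np.ndarray:
    """Reshape a dense physical array to the natural-order virtual
    array.  Little-endian levels make this a Fortran-order reshape."""
    shape = tuple(qmap.mode_sizes)
    v = np.asarray(v, dtype=np.float64).reshape(shape, order="F") if v.ndim == 1 else v
    if tuple(v.shape) != shape:
        raise ValueError(f"array shape {v.shape} does not match window {shape}")
    nat_sizes = tuple(b for f in qmap.factors for b in f)
    return v.flatten(order="F").reshape(nat_sizes, order="F")


def quantize(v, qmap: QuantizationMap, tol: float = 0.0) -> TTVector:
    """Quantize a dense per-species array (or 1-D vector) into a
    TTVector over virtual modes in the map's ordering."""
    if isinstance(v, TTVector):
        return _quantize_tt(v, qmap, tol)
    full = _quantize_dense(np.asarray(v, dtype=np.float64), qmap)
    if qmap.ordering == "transposed":
        perm = qmap.permutation
        full = full.transpose(perm)
    return tt_from_dense(full, tol)


def _quantize_tt(v: TTVector, qmap: QuantizationMap, tol: float) -> TTVector:
    """Split each physical core into per-level cores by exact SVDs."""
    if v.mode_sizes != qmap.mode_sizes:
        raise ValueError("mode sizes do not match quantization map")
    cores = []
    for c, bases in zip(v.cores, qmap.factors):
        r0, n, r1 = c.shape
        # little-endian: reshape mode with first base fastest
        C = c.transpose(1, 0, 2).reshape(tuple(bases) + (r0, r1), order="F")
        # now axes (b_1..b_L, r0, r1); bring r0 first
        L = len(bases)
        C = np.moveaxis(C, L, 0)  # (r0, b_1..b_L, r1)
        r = r0
        for lam in range(L - 1):
            M = C.reshape(r * bases[lam], -1)
            U, s, Vt = _svd_trunc(M, 0.0)
            rk = U.shape[1]
            cores.append(U.reshape(r, bases[lam], rk))
            C = (s[:, None] * Vt).reshape((rk,) + tuple(bases[lam + 1 :]) + (r1,))
            r = rk
        cores.append(C.reshape(r, bases[-1], r1))
    out = TTVector(cores)
    if qmap.ordering == "transposed":
        out = reorder_dimensions(out, qmap.permutation, tol)
    if tol > 0:
        out = tt_round(out, tol)
    return out


# ---------------------------------------------------------------------------


def _swap_adjacent(cores, k, delta, nrm):
    """Swap TT modes k and k+1 in place via merge + truncated SVD."""
    A, B = cores[k], cores[k + 1]
    r0, n0, _ = A.shape
    _, n1, r2 = B.shape
    W = np.einsum("aib,bjc->ajic", A, B, optimize=True)  # swapped mode order
    M = W.reshape(r0 * n1, n0 * r2)
    U, s, Vt = _svd_trunc(M, delta)
    r = U.shape[1]
    # keep the norm on the right-hand core; scale-invariant either way
    cores[k] = U.reshape(r0, n1, r)
    cores[k + 1] = (s[:, None] * Vt).reshape(r, n0, r2)


def _permutation_swaps(perm):
    """Adjacent-transposition schedule (bubble sort) realizing ``perm``:
    after applying the swaps, mode j holds former mode perm[j]."""
    p = list(perm)
    swaps = []
    for i in range(len(p)):
        for j in range(len(p) - 1, i, -1):
            if p[j - 1] > p[j]:
                p[j - 1], p[j] = p[j], p[j - 1]
                swaps.append(j - 1)
    # bubble sort sorts p; applying the recorded swaps in order to the
    # identity arrangement produces perm^{-1}; we need the inverse
    # schedule, so replay reversed on the TT from the sorted state.
    return swaps


def reorder_dimensions(v, permutation, tol: float = 0.0):
    """Permute TT modes so that new mode ``j`` is old mode
    ``permutation[j]``, via adjacent transpositions each followed by an
    SVD re-truncation at ``tol / n_swaps``; total relative error is at
    most ``tol``.  Works for TTVector (modes) and TTMatrix (row/column
    mode pairs move together)."""
    perm = tuple(int(j) for j in permutation)
    mat = isinstance(v, TTMatrix)
    w = v.as_vector() if mat else v
    d = w.d
    if sorted(perm) != list(range(d)):
        raise ValueError("not a permutation of the TT modes")
    if perm == tuple(range(d)):
        return v.copy()
    from .tt import tt_norm

    # schedule: sort `perm` by bubble sort; the swaps applied to the TT
    # in the same order move old mode perm[j] into position j.
    p = list(perm)
    swaps = []
    changed = True
    while changed:
        changed = False
        for j in range(d - 1):
            if p[j] > p[j + 1]:
                p[j], p[j + 1] = p[j + 1], p[j]
                swaps.append(j)
                changed = True
    # applying recorded swaps in reverse order to the identity-ordered
    # TT produces the desired arrangement
    swaps = swaps[::-1]
    nrm = tt_norm(w)
    delta = 0.0 if tol == 0.0 else tol * nrm / max(len(swaps), 1)
    cores = [c.copy() for c in w.cores]
    for j in swaps:
        _swap_adjacent(cores, j, delta, nrm)
    out = TTVector(cores)
    if mat:
        rs = tuple(v.row_sizes[j] for j in perm)
        cs = tuple(v.col_sizes[j] for j in perm)
        return TTMatrix.from_vector(out, rs, cs)
    return out
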