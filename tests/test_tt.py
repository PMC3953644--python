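"""Tensor-train core: construction, rounding, arithmetic, diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qttcme.io_h5 import load_tt, save_tt
from qttcme.tt import (
    TTMatrix,
    TTVector,
    effective_rank,
    memory_count,
    tt_add,
    tt_dot,
    tt_from_dense,
    tt_identity,
    tt_matvec,
    tt_norm,
    tt_rank_one,
    tt_round,
    tt_scale,
    tt_to_dense,
)


@pytest.mark.parametrize("shape", [(4, 3, 5, 2), (2,) * 10, (8, 8), (5,)])
def test_roundtrip_exact(rng, shape):
    x = rng.standard_normal(shape)
    v = tt_from_dense(x, 0.0)
    assert np.allclose(tt_to_dense(v), x, atol=1e-12)


def test_ranks_equal_unfolding_ranks(rng):
    x = rng.standard_normal((4, 4, 4, 4))
    # force low-rank structure in the middle unfolding
    x = x + np.multiply.outer(
        rng.standard_normal((4, 4)), rng.standard_normal((4, 4))
    )
    v = tt_from_dense(x, 0.0)
    expected = tuple(
        np.linalg.matrix_rank(x.reshape(4 ** (k + 1), -1)) for k in range(3)
    )
    assert v.ranks == (1,) + expected + (1,)


def test_constant_vector_is_rank_one():
    v = tt_from_dense(np.ones((2,) * 10), 1e-13)
    assert set(v.ranks) == {1}
    assert memory_count(v) == 20  # 10 binary modes, 2 parameters each


def test_sine_vector_has_qtt_ranks_two():
    # a sampled sinusoid separates into two trigonometric terms at
    # every binary cut, hence all interior ranks are exactly 2
    i = np.arange(2**10)
    x = np.sin(0.37 * i + 0.2).reshape((2,) * 10, order="F")
    v = tt_from_dense(x, 1e-12)
    assert v.ranks == (1,) + (2,) * 9 + (1,)
    # parameter count: 2*2 + 8 middle cores of 2*2*2 + 2*2
    assert memory_count(v) == 4 + 8 * 8 + 4


def test_round_recompresses_inflated_rank_one(rng):
    v = tt_rank_one([rng.standard_normal(4) for _ in range(5)])
    inflated = tt_scale(tt_add(v, v), 0.5)
    assert max(inflated.ranks) == 2
    back = tt_round(inflated, 1e-12)
    assert set(back.ranks) == {1}
    assert np.allclose(tt_to_dense(back), tt_to_dense(v))


def test_round_zero_tolerance_is_exact(rng):
    x = rng.standard_normal((3, 4, 5))
    v = tt_from_dense(x, 0.0)
    w = tt_round(v, 0.0)
    assert np.allclose(tt_to_dense(w), x, atol=1e-13)
    assert all(rw <= rv for rw, rv in zip(w.ranks, v.ranks))


@pytest.mark.parametrize("tol", [1e-1, 1e-3, 1e-6])
def test_round_respects_relative_tolerance(rng, tol):
    x = rng.standard_normal((2,) * 8)
    v = tt_from_dense(x, 0.0)
    w = tt_round(v, tol)
    err = np.linalg.norm(tt_to_dense(w) - x) / np.linalg.norm(x)
    assert err <= tol


def test_round_structured_corpus_quasi_optimal(rng):
    i = np.arange(2**8, dtype=float)
    corpus = [
        np.sin(0.11 * i + 1.0),
        (i - 100.0) ** 3,
        np.exp(-0.05 * i),
        rng.standard_normal(2**8),
    ]
    for x in corpus:
        v = tt_from_dense(x.reshape((2,) * 8, order="F"), 0.0)
        for tol in (1e-2, 1e-5):
            w = tt_round(v, tol)
            err = np.linalg.norm(tt_to_dense(w).flatten(order="F") - x)
            assert err <= tol * np.linalg.norm(x)


def test_add_is_exact_and_ranks_add(rng):
    a = tt_from_dense(rng.standard_normal((3, 4, 5)), 0.0)
    b = tt_from_dense(rng.standard_normal((3, 4, 5)), 0.0)
    s = tt_add(a, b)
    assert np.allclose(tt_to_dense(s), tt_to_dense(a) + tt_to_dense(b))
    assert s.ranks[1:-1] == tuple(
        ra + rb for ra, rb in zip(a.ranks[1:-1], b.ranks[1:-1])
    )
    assert s.ranks[0] == s.ranks[-1] == 1
    # a + (-1) a vanishes (norm via inner products carries sqrt(eps)
    # cancellation noise)
    z = tt_add(a, tt_scale(a, -1.0))
    assert tt_norm(z) < 1e-6 * tt_norm(a)


def test_add_rejects_mode_mismatch(rng):
    a = tt_from_dense(rng.standard_normal((3, 4)), 0.0)
    b = tt_from_dense(rng.standard_normal((4, 3)), 0.0)
    with pytest.raises(ValueError, match="mode-size"):
        tt_add(a, b)


def test_matvec_matches_dense_and_multiplies_ranks(rng):
    shape = (2, 3, 4)
    Ad = rng.standard_normal((24, 24))
    T = Ad.reshape(shape + shape, order="F")
    T = T.transpose(0, 3, 1, 4, 2, 5).reshape(4, 9, 16)
    A = TTMatrix.from_vector(tt_from_dense(T, 0.0), shape, shape)
    v = tt_from_dense(rng.standard_normal(shape), 0.0)
    w = tt_matvec(A, v)
    assert np.allclose(
        tt_to_dense(w).flatten(order="F"),
        Ad @ tt_to_dense(v).flatten(order="F"),
    )
    assert w.ranks == tuple(ra * rv for ra, rv in zip(A.ranks, v.ranks))


def test_identity_matvec_preserves_vector(rng):
    v = tt_from_dense(rng.standard_normal((2, 2, 2, 2)), 0.0)
    I = tt_identity((2, 2, 2, 2))
    assert max(I.ranks) == 1
    assert np.allclose(tt_to_dense(tt_matvec(I, v)), tt_to_dense(v))


def test_dot_and_norm_consistent(rng):
    v = tt_from_dense(rng.standard_normal((3, 3, 3)), 0.0)
    assert tt_dot(v, v) == pytest.approx(tt_norm(v) ** 2, rel=1e-12)
    assert tt_norm(v) == pytest.approx(np.linalg.norm(tt_to_dense(v)), rel=1e-12)


def test_effective_rank_uniform_is_r(rng):
    cores = [
        rng.standard_normal((1, 3, 4)),
        rng.standard_normal((4, 3, 4)),
        rng.standard_normal((4, 3, 4)),
        rng.standard_normal((4, 3, 1)),
    ]
    prof = effective_rank(TTVector(cores))
    assert prof.r_eff == pytest.approx(4.0, rel=1e-12)
    assert prof.r_max == 4


def test_effective_rank_quadratic_root():
    # 3 binary modes, ranks (1,1,2,1): memory 10; 2 r^2 + 4 r = 10
    v = TTVector(
        [np.ones((1, 2, 1)), np.ones((1, 2, 2)), np.ones((2, 2, 1))]
    )
    assert memory_count(v) == 10
    assert effective_rank(v).r_eff == pytest.approx(np.sqrt(6) - 1, rel=1e-12)


def test_memory_count_rank_one_binary():
    v = tt_rank_one([np.ones(2)] * 12)
    assert memory_count(v) == 24


def test_to_dense_budget_guard():
    v = tt_rank_one([np.ones(2)] * 30)
    with pytest.raises(MemoryError):
        tt_to_dense(v)


def test_non_finite_rejected():
    x = np.ones((2, 2))
    x[0, 0] = np.nan
    with pytest.raises(ValueError):
        tt_from_dense(x, 0.0)


def test_hdf5_roundtrip_bit_exact(rng, tmp_path):
    v = tt_from_dense(rng.standard_normal((4, 4, 4)), 0.0)
    path = tmp_path / "v.h5"
    save_tt(path, v)
    w = load_tt(path)
    assert all(np.array_equal(a, b) for a, b in zip(v.cores, w.cores))
    A = TTMatrix.from_vector(tt_from_dense(rng.standard_normal((4, 9)), 0.0), (2, 3), (2, 3))
    save_tt(tmp_path / "A.h5", A)
    B = load_tt(tmp_path / "A.h5")
    assert isinstance(B, TTMatrix)
    assert all(np.array_equal(a, b) for a, b in zip(A.cores, B.cores))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    st.lists(st.integers(min_value=2, max_value=4), min_size=2, max_size=5),
    st.integers(min_value=0, max_value=2**31 - 1),
    st.sampled_from([0.0, 1e-8, 1e-3]),
)
def test_roundtrip_and_rounding_property(shape, seed, tol):
    """tt_from_dense at any tolerance reproduces the array within that
    tolerance in the Frobenius norm, and rounding never raises ranks."""
    x = np.random.default_rng(seed).standard_normal(tuple(shape))
    v = tt_from_dense(x, tol)
    err = np.linalg.norm(tt_to_dense(v) - x)
    assert err <= max(tol, 1e-12) * np.linalg.norm(x) + 1e-13
    w = tt_round(v, tol)
    assert all(rw <= rv for rw, rv in zip(w.ranks, v.ranks))
    err2 = np.linalg.norm(tt_to_dense(w) - x)
    assert err2 <= (2 * max(tol, 1e-12)) * np.linalg.norm(x) + 1e-13
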