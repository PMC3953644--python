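# Methods

## Problem and model

A well-stirred biochemical reaction network with `d` species and `M`
reaction channels is modelled as a jump Markov process on copy-number
states `x ∈ N^d`. Its probability density `p(x, t)` obeys the chemical
master equation (CME)

    dp(x,t)/dt = Σ_j [ a_j(x − z_j) p(x − z_j, t) − a_j(x) p(x, t) ],

where `z_j` is the stoichiometric (net-change) vector and `a_j(x) ≥ 0`
the propensity of channel `j`. The state space is countably infinite;
all computation happens on a finite state projection (FSP): the
rectangular window `{0..n_1−1} × … × {0..n_d−1}`. On the window the CME
is a linear ODE `ṗ = A p` with the generator

    A = Σ_j (S_{z_j} − I) · diag(a_j),

`S_z` the shift by `z`. Probability that attempts to leave the window
is dropped, so `Σ_x p(x,t)` is nonincreasing and the *deficiency*
`1 − Σ_x p` bounds the l1 truncation error.

Two boundary conventions are implemented:

* `outflow` (default): transitions whose target leaves the window keep
  their diagonal loss term; the generator leaks and the deficiency
  tracks the truncation error. This is the projection used in all
  time-marching runs.
* `vanishing`: the propensity factors are zeroed at boundary-exiting
  states, giving a conservative generator. This is the hypothesis under
  which the construction rank bounds for the operator are exact, and
  the convention used by the operator-compression accounting (it is
  what makes the single-species birth-death operator on 2^12 states
  cost exactly 992 stored parameters; the leaky projection compresses
  further, to 672, because dropping the boundary modification lowers
  the exact unfolding ranks to 4).

Propensities must be *rank-one separable*, `a_j(x) = Π_k w_j^(k)(x_k)`,
which covers all elementary kinetics; the model schema only admits
per-species factors (polynomial coefficients, repressing Hill
functions, or tabulated values), so non-separable models are rejected
at the schema level.

## Tensor formats

Vectors on the window are folded into binary "virtual" levels
(little-endian per species: level 1 is the least significant bit) and
represented as tensor trains over the virtual modes (QTT). Two
orderings of the virtual modes are supported: *natural* (species-major)
and *transposed* (level-major, "QT3"), the latter obtained either by a
bubble-sort sequence of adjacent mode transpositions with per-swap SVD
re-truncation, or, for operators, assembled directly by interleaving
per-species Kronecker factors; species with fewer levels are padded
with void (size-one) slots which are dropped after interleaving —
exact operations. Level-major ordering pays off when species are
coupled scale-by-scale, e.g. through conservation relations that
anti-correlate copy numbers.

TT-SVD construction and rounding use the standard per-unfolding
threshold `ε‖v‖/√(d−1)`, giving a relative Frobenius error ≤ ε
(quasi-optimal). Singular values exactly at the threshold are kept
(tie-break toward larger rank) for reproducibility. With `ε = 0` the
ranks are the numerical unfolding ranks (machine-precision threshold).
Zero vectors are all-rank-one with zero cores and round to themselves.
Orthogonalization is left-to-right QR followed by right-to-left SVD
truncation. All floating point is double precision.

The *effective rank* `r_eff` of a decomposition is the positive root of
the quadratic that equates its stored parameter count with that of a
uniform-rank decomposition over the same modes; `memory_count` is the
raw parameter count.

## Operator assembly

Per reaction, the per-species shift (an explicit rank-2 QTT for ±1,
products of unit shifts re-compressed to minimal ranks otherwise) is
composed with the diagonal weight carrying the quantized propensity
factor (ranks ≤ degree+1 for polynomial factors; numeric factors are
evaluated densely per species — at most 2^14 points — quantized and
compressed at the assembly tolerance). Reaction terms are accumulated
by TT addition and rounded once per reaction at `ε_op/M`, bounding the
total assembly error by `ε_op`; the default `ε_op = 1e−10` keeps the
operator error negligible against all solver tolerances. Construction
rank bounds (reactions independent, per-reaction factor ranks summed;
products of open per-species bond ranks across a level-major cut) are
recorded with the operator and checked; violations warn rather than
fail, since propensities that do not vanish at the shifted window edge
void the exactness of the bound.

## Time discretization

The projected ODE is discretized by a discontinuous Galerkin method in
time: on each mesh interval the solution is a polynomial of order `p`
with TT coefficients, coupled upwind to the previous endpoint. With
Legendre shape functions on [−1, 1] all temporal integrals are closed
form, and one interval of length `h` requires solving

    Σ_l [ K_{l'l} I − (h/2) M_{l'l} A ] c_l = (−1)^{l'} y_prev,

with `M` the diagonal Legendre mass matrix and `K` the
stiffness-plus-jump matrix. `p = 0` reduces to backward Euler. The
temporal index is attached as a single unquantized TT mode before the
first virtual mode; the system matrix then has interior ranks at most
one above those of `A` (asserted at assembly). The scheme is A-stable
at every order; because the CME evolution is analytic in time the
endpoint error decays exponentially in `p` (observed: a factor ≥ 2 per
order on the 2-state decay model until the tolerance floor) and at the
superconvergent nodal order `2p+1` in `h`.

Meshes are uniform, geometric (ratio-growing steps, resolving the fast
transient), or explicit lists; there is no automatic hp-adaptivity.
When the alternating solver rejects a step (no convergence within the
sweep budget), the step is bisected and retried, up to
`max_bisections = 6` levels — the solver always converges for small
enough `h‖A‖`, so this makes the march robust without touching
tolerances.

After each step the endpoint `Σ_l c_l` is re-approximated at the
rounding tolerance `ε` (default 1e−6). A final *truncation* at
`κ·ε` (default `κ = 10`) strips ranks the target accuracy does not
support; the headline rank diagnostics (`r_eff`, `r_max`) refer to the
truncated solution, since those are the ranks a user would actually
store.

## The alternating linear solver

Each step system `Bx = b` is solved by a two-site DMRG-type sweep. By
default the sweeps run on the Gram (normal-equation) system
`BᵀB x = Bᵀb` (formed in TT arithmetic, rounded at 1e−13): each local
solve then *minimizes* the true residual over the local subspace, so
the per-sweep residual is monotone nonincreasing — a property the
oblique Galerkin projection of a nonsymmetric `B` does not have (it is
available as `method="galerkin"`). The conditioning is squared, which
is benign here because the DG matrices are well conditioned for
moderate `h‖A‖` (and the step-bisection fallback enforces that).

Local systems up to 4096 unknowns are solved densely; larger ones by
conjugate gradients on the (SPD) local Gram operator applied in factored
form. After each local solve the merged pair is re-split by an SVD
truncated at `0.3·tol/√(D−1)` relative (tightened adaptively if the
sweeps plateau above `tol`), with a seeded random rank-1 "kick"
appended to the outgoing basis to escape stagnation. Two warm-start
devices matter in practice:

* the initial guess for each step is the truncated expansion
  `Σ_q (tA)^q/q! · y_prev` (up to order min(p, 3)) projected on the
  Legendre basis — this seeds the solution basis with the Krylov
  directions `y, Ay, A²y, …` along which the step actually moves, which
  the alternating sweeps are poor at discovering from scratch;
* a small seeded random additive enrichment (rank 2, relative magnitude
  1e−2) of the initial guess opens every bond.

Once the residual target is met, one final sweep without kicks removes
the spurious rank the enrichment left behind. Non-convergence is a
first-class outcome: the report carries per-sweep residuals and the
best iterate; there is no global convergence guarantee. The default
solver tolerance is `ε/2`: the endpoint is rounded at `ε` immediately
afterwards, so residuals far below `ε` buy nothing.

All randomness (kicks, enrichment) flows from a single seed; repeated
runs are bit-identical.

## Oracles and what the fixtures do (and do not) show

* **Dense FSP solver**: the sparse generator is built state-by-state
  from the transition list (an implementation independent of the tensor
  assembly) and evolved with the action of the matrix exponential;
  a stiff implicit integrator (BDF at 1e−10) is the cross-check.
  Budget 2^14 states.
* **Analytic birth-death law**: from a zero initial state the marginal
  is Poisson(λ(t)) with `λ(t) = (b/δ)(1 − e^{−δt})`, truncated (not
  renormalized) to the window; the joint law is the product of
  marginals.
* **SSA**: Gillespie's direct method, vectorized across paths, on the
  *untruncated* state space, with per-bin binomial error bars. Desk
  scale (10^4–10^5 paths).

The three study systems are generated by the built-in model files:

* `birth_death` — d independent birth-death species, `b = 1`,
  `δ = 0.1` (stationary mean 10), window 2^12 (2^8 in reduced solver
  runs), zero initial state.
* `toggle_switch` — two mutually repressing species with Hill
  production (`vmax` 18 and 14, `K = 4`, Hill coefficient 3) and unit
  degradation on a 64×64 window; bistable, with deterministic fixed
  points near (18, 0) and (0, 14), so the PDF from the (0,0) start
  becomes bimodal.
* `futile_cycle` — the closed 6-species enzymatic cycle with one copy
  of each enzyme, unit-order rate constants, total substrate 127
  (15 in reduced runs). The conservation relations make S and P
  strongly anti-correlated, the structure the transposed ordering
  exploits.

Rate constants for the toggle and futile-cycle fixtures are this
package's defaults, chosen inside the bistable/conserved regimes of the
published model families; they are not fitted to any data. Passing
tests therefore demonstrate correctness of the numerics (assembly,
stepping, solving, compression) on these regimes — not biological
calibration, and not performance at cluster scale.

Problem sizes used by the validation runs: reduced windows of 2^6–2^8
states per species wherever a dense oracle is compared (≤ 2^12 total
states), the full 2^12-state window only for assembly and memory
accounting (never expanded densely); birth-death marches to T = 40
(λ = 9.8 of the stationary 10) with a 16-step geometric mesh (ratio
1.5) at order 4; the futile-cycle ordering comparison runs to T = 10
with 14 geometric steps at order 3.

## Known limitations

* The alternating solver can stall on large steps during strong
  transients; the bisection fallback trades wall time for robustness
  but cannot overcome a genuinely intractable rank structure.
* Nonnegativity of the PDF is not preserved by the format and not
  enforced; diagnostics report the most negative entry found on
  sampled fibers only.
* Rank bounds are construction bounds, exact only under the
  boundary-vanishing convention; with outflow boundaries they are
  conservative.
* Shifts with |z| > 1 are built as products of unit shifts; fine for
  elementary kinetics, wasteful for large jumps.
* No automatic hp-adaptivity, no cross/interpolation construction of
  propensities from black-box functions (per-species dense evaluation
  is always affordable at these window sizes), no non-separable
  propensities.
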