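"""Differentiable projection of pair scores onto a rule-satisfying matrix.

The scorer emits an unconstrained logit matrix S.  This layer solves (by a
fixed number of unrolled primal-dual steps) the relaxation

    max_A  <sigma(S) - b, A> + <y, A> - eta * ||A||_1   s.t.  A 1 <= 1,

where b is a score threshold, y is the label matrix during fine-tuning
(zero at inference), the L1 term promotes sparsity, and the row-sum
constraint encodes "at most one partner per base".  A Lagrange multiplier
vector lambda >= 0 enforces the constraint; both A and lambda take steps
with a self-decaying rate rho^t.  The primal iterate is multiplicatively
masked by the hard-rule matrix M, so forbidden entries are exactly zero at
every step, and each round ends with hard-threshold denoising that snaps
small-magnitude entries to zero.  After s rounds the iterate is masked and
symmetrized; a greedy one-partner-per-base discretization yields the final
binary pair matrix.

Nothing in the iteration prefers nested structures, so pseudoknots pass
through untouched.  During training the whole map is differentiated with
relu subgradients; the row-sum indicator and the multiplier trajectory are
treated as piecewise constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "ConstraintLayerConfig",
    "OptState",
    "grad_A",
    "update_A",
    "update_lambda",
    "denoise",
    "finalize",
    "postprocess",
    "binarize",
]


@dataclass
class ConstraintLayerConfig:
    b: float = 0.5          # score threshold on the sigmoid scale
    eta: float = 0.01       # L1 coefficient
    rho_alpha: float = 0.95  # primal step-size base
    rho_beta: float = 0.95   # dual step-size base
    s: int = 20             # unrolled rounds
    tau: float = 0.5        # final discretization threshold

    def __post_init__(self):
        if not (0 < self.rho_alpha < 1 and 0 < self.rho_beta < 1):
            raise ValueError("rho_alpha and rho_beta must lie in (0, 1)")
        if self.s < 1:
            raise ValueError("need at least one iteration")
        if self.eta < 0:
            raise ValueError("eta must be nonnegative")


@dataclass
class OptState:
    A: Tensor
    lam: Tensor  # length-L multipliers, >= 0
    t: int = 0


def _as2d(x) -> Tensor:
    t = ag.astensor(x)
    if t.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    return t


def grad_A(state: OptState, S, y, b: float) -> Tensor:
    """dL/dA = sigma(S) - b + y - (lambda o 1[A1 - 1 > 0]) 1^T.

    ``S`` here is already on the [0,1] sigmoid scale; ``y`` may be a zero
    matrix at inference.  The indicator is evaluated on the current row
    sums and treated as constant under differentiation.
    """
    S, y = _as2d(S), _as2d(y)
    if S.shape != y.shape:
        raise ValueError(f"shape mismatch: scores {S.shape}, labels {y.shape}")
    row_excess = state.A.data.sum(axis=1) - 1.0
    active = (row_excess > 0).astype(float)  # piecewise-constant indicator
    penalty = (state.lam.data * active)[:, None] * np.ones((1, S.shape[1]))
    return S - b + y - Tensor(penalty)


def update_A(state: OptState, grad: Tensor, M, cfg: ConstraintLayerConfig,
             clamp: bool = True) -> OptState:
    """A <- A + rho_a^t * A o M o (grad + grad^T); masked entries stay zero.

    The raw multiplicative ascent is unstable for generic inputs: once a
    row overshoots the constraint the multiplier chases the iterate and
    the coupled system grows super-exponentially.  The iterate is
    therefore clamped to [0, 1] — the range of both the squashed scores
    and the binary target — via relu(A) - relu(A - 1), which keeps the
    map differentiable (subgradient 0 outside the interval).
    """
    M = ag.astensor(M)
    step = cfg.rho_alpha ** state.t
    sym_grad = grad + grad.swapaxes(0, 1)
    A_new = state.A + (state.A * M * sym_grad) * step
    if clamp:
        A_new = ag.relu(A_new) - ag.relu(A_new - 1.0)
    return OptState(A=A_new, lam=state.lam, t=state.t)


def update_lambda(state: OptState, cfg: ConstraintLayerConfig) -> OptState:
    """lambda <- lambda + rho_b^t * relu(A1 - 1); nondecreasing, stays >= 0."""
    excess = ag.relu(state.A.sum(axis=1) - 1.0)
    lam_new = state.lam + excess * (cfg.rho_beta ** state.t)
    return OptState(A=state.A, lam=Tensor(lam_new.data), t=state.t)


def denoise(state: OptState, cfg: ConstraintLayerConfig) -> OptState:
    """Hard-threshold shrinkage: A <- relu(|A| - eta * rho_a^t)."""
    thresh = cfg.eta * (cfg.rho_alpha ** state.t)
    return OptState(A=ag.relu(state.A.abs() - thresh), lam=state.lam, t=state.t)


def finalize(state: OptState, M) -> Tensor:
    """A <- (A o M + (A o M)^T) / 2: masked symmetrization."""
    M = ag.astensor(M)
    masked = state.A * M
    return (masked + masked.swapaxes(0, 1)) * 0.5


def postprocess(S, M, y=None, cfg: ConstraintLayerConfig | None = None,
                scores_are_probabilities: bool = False):
    """Run the full unrolled projection.

    Parameters
    ----------
    S : (L, L) logit matrix (squashed internally), or probabilities if
        ``scores_are_probabilities`` is set.  May be a Tensor for a
        differentiable pass.
    M : (L, L) binary hard-rule mask.
    y : (L, L) binary label matrix during fine-tuning; None at inference.
    cfg : layer configuration.

    Returns
    -------
    (soft, hard): the symmetric nonnegative relaxation (Tensor if S was a
    Tensor, ndarray otherwise) and the greedy-discretized binary pair
    matrix (always ndarray).
    """
    cfg = cfg or ConstraintLayerConfig()
    traced = isinstance(S, Tensor)
    St = ag.astensor(S)
    Mt = ag.astensor(np.asarray(M, dtype=float))
    if St.shape != Mt.shape:
        raise ValueError(f"shape mismatch: scores {St.shape}, mask {Mt.shape}")
    probs = St if scores_are_probabilities else ag.sigmoid(St)
    yt = ag.astensor(np.zeros(St.shape) if y is None else np.asarray(y, dtype=float))
    A0 = probs * Mt
    # Start at a feasible point: rows of sigma(S) o M routinely sum far above 1
    # (early-training scorers flood positives), and an infeasible start makes the
    # multiplier overshoot in the very first round, wiping out whole rows before
    # any selection can happen.  The per-row scale is treated as a constant under
    # differentiation.
    row_sums = A0.data.sum(axis=1)
    scale = np.where(row_sums > 1.0, 1.0 / np.maximum(row_sums, 1e-12), 1.0)
    A0 = A0 * scale[:, None]
    state = OptState(A=A0, lam=Tensor(np.zeros(St.shape[0])), t=1)
    for t in range(1, cfg.s + 1):
        state.t = t
        g = grad_A(state, probs, yt, cfg.b)
        state = update_A(state, g, Mt, cfg)
        state = denoise(state, cfg)
        state = update_lambda(state, cfg)
    soft = finalize(state, Mt)
    hard = binarize(soft.data, cfg.tau)
    return (soft if traced else soft.data), hard


def binarize(A_soft: np.ndarray, tau: float = 0.5) -> np.ndarray:
    """Greedy discretization enforcing at most one partner per base.

    Candidate entries with A > tau are visited in descending score order
    (ties broken by smallest (i, j) lexicographically); a pair is kept only
    if both bases are still unpartnered.
    """
    A = np.asarray(A_soft, dtype=float)
    n = A.shape[0]
    out = np.zeros_like(A, dtype=np.int8)
    taken = np.zeros(n, dtype=bool)
    ii, jj = np.nonzero(np.triu(A > tau, k=1))
    order = sorted(range(len(ii)), key=lambda k: (-A[ii[k], jj[k]], ii[k], jj[k]))
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if not taken[i] and not taken[j]:
            taken[i] = taken[j] = True
            out[i, j] = out[j, i] = 1
    return out
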