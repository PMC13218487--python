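"""Binary covarion substitution model.

The model evolves a presence/absence character (cognate set absent or present
in a language) while the character itself switches between a *fast* and a
*slow* hidden rate class.  The state space therefore has four states, ordered

    0: absent-fast, 1: present-fast, 2: absent-slow, 3: present-slow.

Substitutions (absent <-> present) happen only *within* a hidden class, at a
rate proportional to the equilibrium frequency of the destination observed
state; the slow class is down-weighted by ``alpha`` in [0, 1].  Switches
between hidden classes never change the observed state, so the rate matrix has
structural zeros for every "double transition".

Three parameterisations of the hidden-class switching are supported, matching
the modes found in mainstream Bayesian phylogenetics software:

``beast``
    switch rate ``s`` in both directions, hidden frequencies fixed at
    (0.5, 0.5) and *excluded* from the rate matrix.  This is the default
    set-up prevalent in phylolinguistics.
``reversible``
    switch rates ``s * pi_hidden[dest]``; the chain is time-reversible with
    stationary distribution ``pi_obs (x) pi_hidden``.
``tuffley_steel``
    the original covarion parameterisation: ``alpha = 0`` (the slow class is
    completely frozen) and two free switch rates ``s_fast`` (fast -> slow) and
    ``s_slow`` (slow -> fast).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

STATE_ORDER = ("absent-fast", "present-fast", "absent-slow", "present-slow")

#: tip partial likelihoods for observed binary states: observed "absent" is
#: compatible with states {absent-fast, absent-slow}, "present" with the rest.
TIP_PARTIALS = np.array(
    [
        [1.0, 0.0, 1.0, 0.0],  # observed 0
        [0.0, 1.0, 0.0, 1.0],  # observed 1
    ]
)

MODES = ("beast", "reversible", "tuffley_steel")


@dataclass
class CovarionParams:
    """Parameters of the binary covarion process.

    Parameters
    ----------
    alpha:
        Relative rate of the slow class (0 ≤ alpha ≤ 1).
    s:
        Switch rate between hidden classes, in units of expected
        substitutions (ignored in ``tuffley_steel`` mode).
    pi_obs:
        Equilibrium frequencies of (absent, present).
    pi_hidden:
        Equilibrium frequencies of (fast, slow); must be (0.5, 0.5) in
        ``beast`` mode.
    mode:
        One of ``beast``, ``reversible``, ``tuffley_steel``.
    s_fast, s_slow:
        Fast->slow and slow->fast switch rates, ``tuffley_steel`` mode only.
    """

    alpha: float
    s: float
    pi_obs: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))
    pi_hidden: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))
    mode: str = "beast"
    s_fast: float | None = None
    s_slow: float | None = None

    @classmethod
    def unchecked(cls, alpha: float, s: float, pi_present: float) -> "CovarionParams":
        """Fast beast-mode constructor for callers that already guarantee the
        invariants (the MCMC hot path)."""
        obj = object.__new__(cls)
        obj.alpha = alpha
        obj.s = s
        obj.pi_obs = np.array([1.0 - pi_present, pi_present])
        obj.pi_hidden = np.array([0.5, 0.5])
        obj.mode = "beast"
        obj.s_fast = obj.s_slow = None
        return obj

    def __post_init__(self) -> None:
        self.pi_obs = np.asarray(self.pi_obs, dtype=float)
        self.pi_hidden = np.asarray(self.pi_hidden, dtype=float)
        if self.mode not in MODES:
            raise ValueError(f"unknown covarion mode {self.mode!r}")
        for name, vec in (("pi_obs", self.pi_obs), ("pi_hidden", self.pi_hidden)):
            if vec.shape != (2,) or not np.all(np.isfinite(vec)):
                raise ValueError(f"{name} must be a finite 2-vector")
            if not np.isclose(vec.sum(), 1.0) or np.any(vec <= 0) or np.any(vec >= 1):
                raise ValueError(f"{name} entries must lie in (0,1) and sum to 1")
        if not np.isfinite(self.alpha) or not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.mode == "tuffley_steel":
            if self.alpha != 0.0:
                raise ValueError("tuffley_steel mode requires alpha = 0")
            if self.s_fast is None or self.s_slow is None:
                raise ValueError("tuffley_steel mode requires s_fast and s_slow")
            if self.s_fast <= 0 or self.s_slow <= 0:
                raise ValueError("switch rates must be positive")
        else:
            if not np.isfinite(self.s) or self.s <= 0:
                raise ValueError("s must be positive and finite")
            if self.mode == "beast" and not np.allclose(self.pi_hidden, 0.5):
                raise ValueError("beast mode fixes pi_hidden at (0.5, 0.5)")


@dataclass
class RateMatrix:
    """A 4x4 instantaneous rate matrix over :data:`STATE_ORDER`."""

    q: np.ndarray
    state_order: tuple = STATE_ORDER
    normalized: bool = False


def build_q_matrix(params: CovarionParams, normalize: bool = True) -> RateMatrix:
    """Construct the covarion rate matrix.

    Within-class substitution rates equal the equilibrium frequency of the
    destination observed state (times ``alpha`` in the slow class); switch
    rates depend on the mode.  With ``normalize=True`` the matrix is rescaled
    so that the expected rate of *observable* (absent <-> present) events at
    equilibrium is 1, i.e. branch lengths are expected substitutions per
    cognate; hidden switches are excluded from that flux.
    """
    pi, ph, a = params.pi_obs, params.pi_hidden, params.alpha
    q = np.zeros((4, 4))
    # substitutions within a class
    q[0, 1] = pi[1]
    q[1, 0] = pi[0]
    q[2, 3] = a * pi[1]
    q[3, 2] = a * pi[0]
    # hidden-class switches
    if params.mode == "reversible":
        fs, sf = params.s * ph[1], params.s * ph[0]
    elif params.mode == "beast":
        fs = sf = params.s
    else:  # tuffley_steel
        fs, sf = params.s_fast, params.s_slow
    q[0, 2] = q[1, 3] = fs
    q[2, 0] = q[3, 1] = sf
    np.fill_diagonal(q, -q.sum(axis=1))
    if normalize:
        root = root_frequencies(params)
        flux = root[0] * q[0, 1] + root[1] * q[1, 0] + root[2] * q[2, 3] + root[3] * q[3, 2]
        if flux <= 0:
            raise ValueError("degenerate model: zero equilibrium substitution flux")
        q = q / flux
    if not np.all(np.isfinite(q)):
        raise ValueError("non-finite rate matrix")
    return RateMatrix(q=q, normalized=normalize)


def root_frequencies(params: CovarionParams) -> np.ndarray:
    """Root distribution over the four states: ``pi_obs (x) pi_hidden``.

    State order groups by hidden class, so this is
    ``kron(pi_hidden, pi_obs)``: (a-f, p-f, a-s, p-s).
    """
    pi, ph = params.pi_obs, params.pi_hidden
    return np.array([ph[0] * pi[0], ph[0] * pi[1], ph[1] * pi[0], ph[1] * pi[1]])


def stationary_distribution(q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a rate matrix via its left null space."""
    a = np.vstack([q.T, np.ones(q.shape[0])])
    b = np.zeros(q.shape[0] + 1)
    b[-1] = 1.0
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    return np.abs(sol) / np.abs(sol).sum()


class TransitionKernel:
    """Precomputed spectral form of ``exp(Q t)`` for many branch lengths.

    The covarion matrix in ``beast`` mode is non-reversible, so a general
    (complex) eigendecomposition is used; results are validated row-by-row and
    the dense Padé exponential is used as a fallback for the rare
    ill-conditioned draw.
    """

    def __init__(self, q: np.ndarray):
        self.q = q
        try:
            w, v = np.linalg.eig(q)
            vinv = np.linalg.inv(v)
            self._spectral = (w, v, vinv)
        except np.linalg.LinAlgError:
            self._spectral = None

    def __call__(self, t: np.ndarray | float, check: bool = True) -> np.ndarray:
        """Transition probability matrices for branch lengths ``t`` (>= 0).

        ``check=False`` skips input validation and row renormalisation (the
        MCMC hot path; the spectral solution is still verified against the
        stochastic-matrix invariants before use).
        """
        ts = np.atleast_1d(np.asarray(t, dtype=float))
        if check and (np.any(ts < 0) or not np.all(np.isfinite(ts))):
            raise ValueError("branch lengths must be finite and non-negative")
        p = None
        if self._spectral is not None:
            w, v, vinv = self._spectral
            e = np.exp(np.outer(ts, w))
            p = np.einsum("ij,tj,jk->tik", v, e, vinv).real
            bad = np.abs(p.sum(axis=2) - 1.0).max() > 1e-8 or p.min() < -1e-8
        if p is None or bad:
            p = np.array([expm(self.q * ti) for ti in ts])
        np.maximum(p, 0.0, out=p)
        if check:
            np.minimum(p, 1.0, out=p)
            p /= p.sum(axis=2, keepdims=True)
        if np.isscalar(t) or np.ndim(t) == 0:
            return p[0]
        return p


def transition_probabilities(q: RateMatrix | np.ndarray, t: float | np.ndarray) -> np.ndarray:
    """``exp(Q t)``; rows sum to 1, entries in [0, 1]."""
    mat = q.q if isinstance(q, RateMatrix) else np.asarray(q, dtype=float)
    return TransitionKernel(mat)(t)
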