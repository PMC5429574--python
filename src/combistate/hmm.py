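"""Categorical-emission hidden Markov model over the combinatorial alphabet.

The segmentation model is a univariate first-order HMM: each genomic bin emits
one symbol from the alphabet of mark combinations, and hidden states are
candidate chromatin states.  Training is Baum-Welch with per-position scaling
over multiple observation sequences (one per cell type and chromosome), a
probability floor to avoid numerical underflow, and a fixed iteration count.
Decoding is Viterbi; model comparison uses BIC.

:class:`CombinatorialHMM` is the estimator (sklearn conventions: ``fit`` /
``predict`` / ``score``, fitted attributes with a trailing underscore); the
module-level functions (:func:`forward`, :func:`baum_welch_step`, ...) are thin
wrappers over it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import _kernels
from .preprocess import SymbolSequence, stack_sequences

DEFAULT_FLOOR = 1e-6


def floor_normalize(rows: np.ndarray, floor: float) -> np.ndarray:
    """Renormalize each row to a distribution with every entry >= floor.

    Entries below the floor are raised to exactly the floor and the remaining
    mass is shared proportionally among the other entries; repeated until
    stable (the deficit shrinks each pass, so this terminates quickly).
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float)).copy()
    if floor * rows.shape[1] > 1.0:
        raise ValueError("floor too large for row length")
    for r in rows:
        total = r.sum()
        if total <= 0:
            r[:] = 1.0 / len(r)
            continue
        r /= total
        for _ in range(64):
            low = r < floor
            if not low.any():
                break
            free = 1.0 - floor * low.sum()
            r[~low] *= free / r[~low].sum()
            r[low] = floor
    return rows


def _as_obs(X, lengths=None) -> list[np.ndarray]:
    """Normalize input to a list of int64 observation vectors.

    Accepts a list of :class:`SymbolSequence`, a single sequence, or an
    (X, lengths) pair in the hmmlearn style.
    """
    if isinstance(X, SymbolSequence):
        return [np.asarray(X.symbols, dtype=np.int64)]
    if isinstance(X, (list, tuple)) and (not X or isinstance(X[0], SymbolSequence)):
        return [np.asarray(s.symbols, dtype=np.int64) for s in X]
    arr = np.asarray(X, dtype=np.int64).ravel()
    if lengths is None:
        return [arr]
    lengths = list(lengths)
    if sum(lengths) != arr.size:
        raise ValueError("lengths do not sum to len(X)")
    out, pos = [], 0
    for L in lengths:
        out.append(arr[pos:pos + L])
        pos += L
    return out


@dataclass
class ForwardBackwardResult:
    """Scaled forward/backward variables for one sequence.

    ``alpha[t]`` sums to 1 at every position; ``scales[t]`` is the per-position
    normalizer, so ``log_likelihood == sum(log(scales))``.  ``beta`` is scaled
    consistently with the forward pass (``beta[T-1] = 1``).
    """

    alpha: np.ndarray
    beta: np.ndarray | None
    scales: np.ndarray
    log_likelihood: float


@dataclass
class PosteriorSet:
    """Posterior state occupancies gamma[t, i] and transitions xi[t, i, j]."""

    gamma: np.ndarray          # (T, n)
    xi: np.ndarray             # (T-1, n, n)


@dataclass
class TrainingTrace:
    """Per-iteration log-likelihood record of a Baum-Welch run."""

    log_likelihood: list[float] = field(default_factory=list)

    @property
    def n_iterations(self) -> int:
        return len(self.log_likelihood)


class CombinatorialHMM(BaseEstimator):
    """Univariate HMM with categorical emissions over mark-combination symbols.

    Parameters
    ----------
    n_states : int
        Number of hidden chromatin states.
    n_iter : int
        Baum-Welch iterations run by :meth:`fit` (no early stopping unless
        ``tol`` is set).
    floor : float
        Minimum probability enforced on every initial, transition and
        emission entry after each re-estimation.
    transition_bias : float
        Weight of the identity matrix in the random transition
        initialization.  Genomic bins are strongly autocorrelated, so a
        diagonal-dominant starting transition matrix keeps early EM
        iterations from mixing states along the sequence; with a uniform
        random start the emission rows collapse toward blends of the true
        states and the optimizer reproducibly lands in far inferior optima
        (see the methods note).  Set to 0 for a fully random start.
    tol : float or None
        Optional log-likelihood improvement threshold for early stopping;
        ``None`` (default) runs exactly ``n_iter`` iterations.
    random_state : int or None
        Seed for the Dirichlet random initialization.

    Attributes
    ----------
    startprob_ : (n_states,) initial state distribution.
    transmat_ : (n_states, n_states) transition matrix, rows sum to 1.
    emissionprob_ : (n_states, n_symbols) emission matrix, rows sum to 1.
    history_ : TrainingTrace of the last :meth:`fit`.
    n_symbols_ : alphabet size.
    """

    def __init__(self, n_states: int = 25, n_iter: int = 300,
                 floor: float = DEFAULT_FLOOR, tol: float | None = None,
                 transition_bias: float = 0.9,
                 random_state: int | None = None):
        self.n_states = n_states
        self.n_iter = n_iter
        self.floor = floor
        self.tol = tol
        self.transition_bias = transition_bias
        self.random_state = random_state

    # -- construction -----------------------------------------------------

    @classmethod
    def from_params(cls, startprob, transmat, emissionprob,
                    floor: float = DEFAULT_FLOOR, validate: bool = True
                    ) -> "CombinatorialHMM":
        """Build a ready-to-use model from explicit probability arrays."""
        startprob = np.asarray(startprob, dtype=float)
        transmat = np.asarray(transmat, dtype=float)
        emissionprob = np.asarray(emissionprob, dtype=float)
        n = startprob.shape[0]
        model = cls(n_states=n, floor=floor)
        model.startprob_ = startprob
        model.transmat_ = transmat
        model.emissionprob_ = emissionprob
        model.n_symbols_ = emissionprob.shape[1]
        model.history_ = TrainingTrace()
        if validate:
            model._check_params()
        return model

    def _check_params(self, atol: float = 1e-9):
        if self.transmat_.shape != (self.n_states, self.n_states):
            raise ValueError("transmat shape mismatch")
        if self.emissionprob_.shape[0] != self.n_states:
            raise ValueError("emissionprob shape mismatch")
        for name, arr, axis in (("startprob", self.startprob_, 0),
                                ("transmat", self.transmat_, 1),
                                ("emissionprob", self.emissionprob_, 1)):
            sums = arr.sum(axis=axis)
            if not np.allclose(sums, 1.0, atol=atol):
                raise ValueError(f"{name} rows do not sum to 1")
            if (arr < 0).any():
                raise ValueError(f"{name} has negative entries")

    def initialize(self, n_symbols: int, random_state: int | None = None
                   ) -> "CombinatorialHMM":
        """Random start: Dirichlet(1) rows for the initial and emission
        distributions, a diagonal-biased Dirichlet mixture for the
        transitions; everything floored and renormalized."""
        rng = np.random.default_rng(
            self.random_state if random_state is None else random_state)
        n, m = self.n_states, n_symbols
        self.startprob_ = floor_normalize(rng.dirichlet(np.ones(n)), self.floor)[0]
        A = (self.transition_bias * np.eye(n)
             + (1.0 - self.transition_bias) * rng.dirichlet(np.ones(n), size=n))
        self.transmat_ = floor_normalize(A, self.floor)
        self.emissionprob_ = floor_normalize(rng.dirichlet(np.ones(m), size=n), self.floor)
        self.n_symbols_ = m
        self.history_ = TrainingTrace()
        return self

    # -- inference ---------------------------------------------------------

    def _require_fitted(self):
        if not hasattr(self, "emissionprob_"):
            raise ValueError("model has no parameters; call fit or initialize first")

    def _check_obs(self, obs_list):
        if not obs_list:
            raise ValueError("no sequences")
        for o in obs_list:
            if o.size == 0:
                raise ValueError("empty observation sequence")
            if o.min() < 0 or o.max() >= self.n_symbols_:
                raise ValueError("observation symbol outside model alphabet")

    def score(self, X, lengths=None) -> float:
        """Total log-likelihood of the observations under the model."""
        self._require_fitted()
        obs_list = _as_obs(X, lengths)
        self._check_obs(obs_list)
        total = 0.0
        for o in obs_list:
            _, c = _kernels.forward_scaled(
                self.startprob_, self.transmat_, self.emissionprob_, o)
            total += float(np.log(c).sum())
        return total

    def predict(self, X, lengths=None) -> np.ndarray:
        """Viterbi state path (concatenated across sequences)."""
        self._require_fitted()
        obs_list = _as_obs(X, lengths)
        self._check_obs(obs_list)
        with np.errstate(divide="ignore"):   # zero prob -> -inf is fine here
            log_start = np.log(self.startprob_)
            log_trans = np.log(self.transmat_)
            log_emit = np.log(self.emissionprob_)
        return np.concatenate(
            [_kernels.viterbi_path(log_start, log_trans, log_emit, o)[0]
             for o in obs_list])

    def fit(self, X, lengths=None, warm_start: bool = False) -> "CombinatorialHMM":
        """Run Baum-Welch for ``n_iter`` iterations over all sequences.

        With ``warm_start=True`` the current parameters are the starting
        point; otherwise a fresh random initialization is drawn.
        """
        obs_list = _as_obs(X, lengths)
        if not obs_list:
            raise ValueError("no sequences")
        if any(len(o) < 2 for o in obs_list):
            raise ValueError("every sequence must have length >= 2")
        if not (warm_start and hasattr(self, "emissionprob_")):
            n_symbols = int(max(o.max() for o in obs_list)) + 1
            if isinstance(X, SymbolSequence):
                n_symbols = max(n_symbols, X.alphabet_size)
            elif isinstance(X, (list, tuple)) and X and isinstance(X[0], SymbolSequence):
                n_symbols = max(n_symbols, max(s.alphabet_size for s in X))
            self.initialize(n_symbols)
        self._check_obs(obs_list)
        trace = TrainingTrace()
        prev = -np.inf
        for _ in range(self.n_iter):
            ll = self._em_step(obs_list)
            trace.log_likelihood.append(ll)
            if self.tol is not None and ll - prev < self.tol:
                break
            prev = ll
        self.history_ = trace
        return self

    def _em_step(self, obs_list) -> float:
        """One Baum-Welch re-estimation; returns pre-update log-likelihood."""
        n, m = self.n_states, self.n_symbols_
        pi_acc = np.zeros(n)
        trans_num = np.zeros((n, n))
        gamma_nolast = np.zeros(n)
        emit_num = np.zeros((n, m))
        gamma_sum = np.zeros(n)
        total_ll = 0.0
        for o in obs_list:
            ll, g1, tn, gnl, en, gs = _kernels.bw_accumulate(
                self.startprob_, self.transmat_, self.emissionprob_, o)
            total_ll += ll
            pi_acc += g1
            trans_num += tn
            gamma_nolast += gnl
            emit_num += en
            gamma_sum += gs
        self.startprob_ = floor_normalize(pi_acc / len(obs_list), self.floor)[0]
        self.transmat_ = floor_normalize(
            trans_num / np.maximum(gamma_nolast, 1e-300)[:, None], self.floor)
        self.emissionprob_ = floor_normalize(
            emit_num / np.maximum(gamma_sum, 1e-300)[:, None], self.floor)
        return total_ll

    def bic(self, X, lengths=None) -> float:
        """BIC = -2 lnL + k ln(T_total) with k = n(n-1) + n(m-1) + (n-1)."""
        obs_list = _as_obs(X, lengths)
        total_t = sum(len(o) for o in obs_list)
        n, m = self.n_states, self.n_symbols_
        k = n * (n - 1) + n * (m - 1) + (n - 1)
        return -2.0 * self.score(X, lengths) + k * np.log(total_t)


# ---------------------------------------------------------------------------
# functional surface (thin wrappers over the estimator)


def init_random_model(n_states: int, alphabet_size: int,
                      seed: int | None = None,
                      floor: float = DEFAULT_FLOOR,
                      transition_bias: float = 0.9) -> CombinatorialHMM:
    """Random model: Dirichlet(1) initial/emission rows and a diagonal-biased
    transition start, floored and renormalized; reproducible from the seed."""
    if n_states < 1 or alphabet_size < 1:
        raise ValueError("n_states and alphabet_size must be >= 1")
    return CombinatorialHMM(n_states=n_states, floor=floor,
                            transition_bias=transition_bias,
                            random_state=seed).initialize(alphabet_size)


def forward(model: CombinatorialHMM, seq) -> ForwardBackwardResult:
    """Scaled forward pass and sequence log-likelihood."""
    model._require_fitted()
    (o,) = _as_obs(seq)
    model._check_obs([o])
    alpha, c = _kernels.forward_scaled(
        model.startprob_, model.transmat_, model.emissionprob_, o)
    return ForwardBackwardResult(alpha, None, c, float(np.log(c).sum()))


def backward(model: CombinatorialHMM, seq) -> ForwardBackwardResult:
    """Scaled backward pass (scales taken from the forward pass)."""
    model._require_fitted()
    (o,) = _as_obs(seq)
    model._check_obs([o])
    alpha, c = _kernels.forward_scaled(
        model.startprob_, model.transmat_, model.emissionprob_, o)
    beta = _kernels.backward_scaled(model.transmat_, model.emissionprob_, o, c)
    return ForwardBackwardResult(alpha, beta, c, float(np.log(c).sum()))


def forward_backward(model: CombinatorialHMM, seq) -> ForwardBackwardResult:
    return backward(model, seq)


def posteriors(model: CombinatorialHMM, seq,
               fb: ForwardBackwardResult | None = None) -> PosteriorSet:
    """Posterior occupancies and transition posteriors from forward/backward."""
    if fb is None or fb.beta is None:
        fb = forward_backward(model, seq)
    (o,) = _as_obs(seq)
    alpha, beta, c = fb.alpha, fb.beta, fb.scales
    if alpha.shape[0] != len(o):
        raise ValueError("forward/backward result does not match sequence")
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    b_next = model.emissionprob_[:, o[1:]].T * beta[1:]          # (T-1, n)
    xi = alpha[:-1, :, None] * model.transmat_[None] * b_next[:, None, :]
    xi /= c[1:, None, None]
    return PosteriorSet(gamma=gamma, xi=xi)


def baum_welch_step(model: CombinatorialHMM,
                    sequences) -> CombinatorialHMM:
    """One Baum-Welch re-estimation over all sequences (returns a new model)."""
    obs_list = _as_obs(sequences)
    if not obs_list:
        raise ValueError("no sequences")
    if any(len(o) < 2 for o in obs_list):
        raise ValueError("every sequence must have length >= 2")
    model._check_obs(obs_list)
    new = CombinatorialHMM.from_params(
        model.startprob_, model.transmat_, model.emissionprob_, floor=model.floor)
    new._em_step(obs_list)
    return new


def train(model: CombinatorialHMM, sequences, n_iter: int
          ) -> tuple[CombinatorialHMM, TrainingTrace]:
    """Run exactly ``n_iter`` Baum-Welch iterations from the given model."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    out = CombinatorialHMM.from_params(
        model.startprob_, model.transmat_, model.emissionprob_, floor=model.floor)
    out.n_iter = n_iter
    out.fit(sequences, warm_start=True)
    return out, out.history_


def viterbi(model: CombinatorialHMM, seq) -> np.ndarray:
    """Most probable state path; ties break toward the lower state index."""
    return model.predict(seq)


def bic(model: CombinatorialHMM, sequences) -> float:
    return model.bic(sequences)
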