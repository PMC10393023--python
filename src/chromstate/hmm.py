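"""K-state hidden Markov model with independent Bernoulli emissions per mark.

This is the state-discovery core: given binarized mark tracks, learn initial,
transition, and per-mark emission probabilities by Baum-Welch
expectation-maximization, then assign each genomic bin a state by posterior
mode (default) or Viterbi decoding.  Chromosomes are independent sequences,
each restarted from the initial distribution; concatenated multi-condition
fitting simply pools all conditions' chromosomes as sequences sharing one
parameter set.

Numerics: the forward/backward recursions are scaled per position (the
per-position log emission maximum is factored out first), so sequences of
millions of bins do not underflow.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .genome_io import BinaryTrackSet, Segmentation

logger = logging.getLogger(__name__)

__all__ = [
    "ChromatinModel",
    "FitConfig",
    "FitReport",
    "log_likelihood",
    "fit_model",
    "segment",
    "marginal_segment",
    "save_model",
    "load_model",
]


@dataclass
class ChromatinModel:
    """HMM parameters: initial ``pi`` (K), transitions ``A`` (K×K), emissions ``E`` (K×M).

    ``E[k, m]`` is the probability that mark ``m`` is called present in a bin
    of state ``k``.
    """

    marks: list[str]
    pi: np.ndarray
    A: np.ndarray
    E: np.ndarray
    state_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        K = self.pi.shape[0]
        if self.A.shape != (K, K):
            raise ValueError("A must be K×K")
        if self.E.shape != (K, len(self.marks)):
            raise ValueError("E must be K×M")
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must sum to 1")
        if np.abs(self.A.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("rows of A must sum to 1")
        if self.E.min() < 0.0 or self.E.max() > 1.0:
            raise ValueError("E entries must lie in [0, 1]")
        if not self.state_names:
            self.state_names = [f"S{k+1}" for k in range(K)]

    @property
    def K(self) -> int:
        return self.pi.shape[0]

    @property
    def M(self) -> int:
        return len(self.marks)

    def permuted(self, perm: Sequence[int]) -> "ChromatinModel":
        """Relabel states by ``perm`` (new state k is old state perm[k])."""
        p = np.asarray(perm)
        return ChromatinModel(
            self.marks, self.pi[p], self.A[np.ix_(p, p)], self.E[p],
            [self.state_names[i] for i in p],
        )


@dataclass
class FitConfig:
    K: int = 8
    seed: int = 0
    init: Literal["information", "random"] = "information"
    max_iter: int = 200
    tol: float = 1e-3  # minimum relative log-likelihood improvement to continue
    emission_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class FitReport:
    log_likelihoods: list[float]
    n_iter: int
    converged: bool
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# core recursions
# ---------------------------------------------------------------------------


def _log_emissions(model: ChromatinModel, X: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """(T, K) log P(x_t | state k); marks where ``mask`` is False are marginalized out."""
    E = model.E
    if mask is not None:
        E = E[:, mask]
        X = X[:, mask]
    with np.errstate(divide="ignore"):
        logE = np.log(E)
        log1mE = np.log1p(-E)
    Xf = X.astype(float)
    logB = Xf @ logE.T + (1.0 - Xf) @ log1mE.T
    # 0*log(0) terms: where emission is exactly 0/1 and the observation agrees
    if not np.isfinite(logB).all():
        contrib = np.where(X[:, None, :].astype(bool), logE[None], log1mE[None])
        logB = np.where(np.isnan(contrib), -np.inf, contrib).sum(axis=2)
        logB = np.nan_to_num(logB, nan=-np.inf, posinf=-np.inf)
    return logB


def _forward_backward(pi: np.ndarray, A: np.ndarray, logB: np.ndarray):
    """Scaled forward/backward.

    Returns (log_likelihood, gamma, xi_sum) where gamma[t] is the posterior
    state distribution at t and xi_sum is the expected transition-count matrix.
    """
    T, K = logB.shape
    shift = logB.max(axis=1)
    shift = np.where(np.isfinite(shift), shift, 0.0)
    B = np.exp(logB - shift[:, None])

    alpha = np.empty((T, K))
    c = np.empty(T)
    a = pi * B[0]
    c[0] = a.sum()
    if c[0] == 0.0:
        return -np.inf, np.full((T, K), 1.0 / K), np.zeros((K, K))
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        if c[t] == 0.0:
            return -np.inf, np.full((T, K), 1.0 / K), np.zeros((K, K))
        alpha[t] = a / c[t]
    ll = float(np.log(c).sum() + shift.sum())

    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        bb = B[t + 1] * beta[t + 1]
        beta[t] = (A @ bb) / c[t + 1]
        xi_sum += np.outer(alpha[t], bb / c[t + 1]) * A
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return ll, gamma, xi_sum


def _forward_ll(pi: np.ndarray, A: np.ndarray, logB: np.ndarray) -> float:
    T, K = logB.shape
    shift = logB.max(axis=1)
    shift = np.where(np.isfinite(shift), shift, 0.0)
    B = np.exp(logB - shift[:, None])
    a = pi * B[0]
    ll = 0.0
    for t in range(T):
        if t:
            a = (a @ A) * B[t]
        s = a.sum()
        if s == 0.0:
            return -np.inf
        ll += np.log(s)
        a /= s
    return float(ll + shift.sum())


def _sequences(tracks: BinaryTrackSet | Sequence[BinaryTrackSet]) -> tuple[list[str], list[np.ndarray]]:
    """Pool chromosomes of one or several conditions into independent sequences."""
    tsets = [tracks] if isinstance(tracks, BinaryTrackSet) else list(tracks)
    marks = tsets[0].marks
    for t in tsets[1:]:
        if t.marks != marks:
            raise ValueError(f"mark sets differ across conditions: {t.marks} vs {marks}")
    seqs = [t.calls[c] for t in tsets for c in t.genome.chrom_names]
    return list(marks), seqs


def _check_marks(model: ChromatinModel, tracks: BinaryTrackSet) -> None:
    if model.marks != tracks.marks:
        missing = set(model.marks) - set(tracks.marks)
        extra = set(tracks.marks) - set(model.marks)
        raise ValueError(f"mark mismatch: missing {sorted(missing)}, extra {sorted(extra)}")


def log_likelihood(model: ChromatinModel, tracks: BinaryTrackSet | Sequence[BinaryTrackSet]) -> float:
    """Total scaled-forward log-likelihood; chromosomes are independent sequences."""
    if isinstance(tracks, BinaryTrackSet):
        _check_marks(model, tracks)
    _, seqs = _sequences(tracks)
    return sum(_forward_ll(model.pi, model.A, _log_emissions(model, X)) for X in seqs)


# ---------------------------------------------------------------------------
# initialization and EM
# ---------------------------------------------------------------------------


def _init_model(seqs: list[np.ndarray], marks: list[str], config: FitConfig) -> ChromatinModel:
    rng = np.random.default_rng(config.seed)
    K, M = config.K, len(marks)
    X = np.concatenate(seqs, axis=0)
    col_mean = X.mean(axis=0)

    if config.init == "random":
        E = rng.uniform(0.2, 0.8, size=(K, M))
    else:
        # seed emissions from the K most frequent observation patterns blended
        # with the column means, plus seeded jitter so equal-frequency states split
        patterns, counts = np.unique(X, axis=0, return_counts=True)
        order = np.argsort(-counts)
        E = np.tile(col_mean, (K, 1))
        for k in range(K):
            if k < len(patterns):
                E[k] = 0.3 * col_mean + 0.7 * patterns[order[k]]
        E = E + rng.uniform(-0.05, 0.05, size=(K, M))
        E = np.clip(E, 0.05, 0.95)

    pi = np.full(K, 1.0 / K)
    A = np.full((K, K), 0.5 / max(K - 1, 1))
    np.fill_diagonal(A, 0.5 if K > 1 else 1.0)
    A /= A.sum(axis=1, keepdims=True)
    return ChromatinModel(marks, pi, A, np.clip(E, config.emission_floor, 1 - config.emission_floor))


def fit_model(
    tracks: BinaryTrackSet | Sequence[BinaryTrackSet],
    config: FitConfig | None = None,
) -> tuple[ChromatinModel, FitReport]:
    """Baum-Welch EM.  Passing several track sets fits one concatenated model.

    The fit report carries the per-iteration log-likelihood (guaranteed
    non-decreasing up to numerical tolerance), iteration count, and a
    convergence flag (relative improvement below ``config.tol``).
    """
    config = config or FitConfig()
    marks, seqs = _sequences(tracks)
    warn: list[str] = []

    X_all = np.concatenate(seqs, axis=0)
    n_unique = len(np.unique(X_all, axis=0))
    if config.K > n_unique:
        msg = f"K={config.K} exceeds the {n_unique} distinct observation rows"
        warn.append(msg)
        logger.warning("fit_model: %s", msg)

    model = _init_model(seqs, marks, config)
    eps = config.emission_floor
    ll_history: list[float] = []
    converged = False

    for it in range(config.max_iter):
        K, M = model.K, model.M
        pi_acc = np.zeros(K)
        xi_acc = np.zeros((K, K))
        gocc = np.zeros(K)          # total state occupancy
        gocc_trans = np.zeros(K)    # occupancy excluding each sequence's last bin
        ex_acc = np.zeros((K, M))   # expected presence counts
        ll = 0.0
        for X in seqs:
            logB = _log_emissions(model, X)
            ll_s, gamma, xi = _forward_backward(model.pi, model.A, logB)
            ll += ll_s
            pi_acc += gamma[0]
            xi_acc += xi
            gocc += gamma.sum(axis=0)
            gocc_trans += gamma[:-1].sum(axis=0) if len(X) > 1 else 0.0
            ex_acc += gamma.T @ X
        ll_history.append(ll)

        if len(ll_history) > 1 and ll < ll_history[-2] - 1e-8 * abs(ll_history[-2]):
            warn.append(f"log-likelihood decreased at iteration {it}")
            logger.warning("fit_model: log-likelihood decreased at iteration %d", it)
        if len(ll_history) > 1:
            prev = ll_history[-2]
            rel_gain = (ll - prev) / max(abs(prev), 1.0)
            if rel_gain < config.tol:
                converged = True
                break

        # M-step
        pi = pi_acc / len(seqs)
        A = np.where(gocc_trans[:, None] > 0, xi_acc / np.maximum(gocc_trans[:, None], 1e-300), model.A)
        A = np.clip(A, 1e-12, None)
        A /= A.sum(axis=1, keepdims=True)
        E = np.where(gocc[:, None] > 0, ex_acc / np.maximum(gocc[:, None], 1e-300), model.E)
        E = np.clip(E, eps, 1.0 - eps)
        model = ChromatinModel(marks, pi / pi.sum(), A, E, model.state_names)

    report = FitReport(ll_history, len(ll_history), converged, warn)
    return model, report


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def _viterbi(pi: np.ndarray, A: np.ndarray, logB: np.ndarray) -> np.ndarray:
    T, K = logB.shape
    with np.errstate(divide="ignore"):
        logpi = np.log(pi)
        logA = np.log(A)
    delta = logpi + logB[0]
    back = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        scores = delta[:, None] + logA
        back[t] = scores.argmax(axis=0)
        delta = scores[back[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = int(delta.argmax())
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def posterior_marginals(
    model: ChromatinModel, tracks: BinaryTrackSet, observed_mask: np.ndarray | None = None
) -> dict[str, np.ndarray]:
    """Per-bin posterior state distributions, per chromosome."""
    out = {}
    for chrom in tracks.genome.chrom_names:
        logB = _log_emissions(model, tracks.calls[chrom], observed_mask)
        _, gamma, _ = _forward_backward(model.pi, model.A, logB)
        out[chrom] = gamma
    return out


def segment(
    model: ChromatinModel,
    tracks: BinaryTrackSet,
    method: Literal["posterior", "viterbi"] = "posterior",
) -> Segmentation:
    """Per-bin state assignment: posterior mode (ties to the lower state index) or Viterbi."""
    _check_marks(model, tracks)
    return _segment_masked(model, tracks, None, method)


def marginal_segment(
    model: ChromatinModel,
    tracks: BinaryTrackSet,
    observed_mask: Sequence[bool] | np.ndarray,
    method: Literal["posterior", "viterbi"] = "posterior",
) -> Segmentation:
    """Segment using only the marks selected by ``observed_mask``.

    Hidden marks are marginalized out of the emission term (their Bernoulli
    factor sums to one over the unseen outcome), so the same model is
    evaluated on a mark subset — the subset-evaluation primitive.
    """
    _check_marks(model, tracks)
    mask = np.asarray(observed_mask, dtype=bool)
    if mask.shape != (model.M,):
        raise ValueError(f"mask must have length {model.M}")
    if not mask.any():
        raise ValueError("observed_mask must select at least one mark")
    return _segment_masked(model, tracks, mask, method)


def _segment_masked(model, tracks, mask, method) -> Segmentation:
    state_of_bin: dict[str, np.ndarray] = {}
    for chrom in tracks.genome.chrom_names:
        logB = _log_emissions(model, tracks.calls[chrom], mask)
        if method == "viterbi":
            path = _viterbi(model.pi, model.A, logB)
        elif method == "posterior":
            _, gamma, _ = _forward_backward(model.pi, model.A, logB)
            path = gamma.argmax(axis=1)
        else:
            raise ValueError(f"unknown method {method!r}")
        state_of_bin[chrom] = path + 1
    return Segmentation(tracks.genome, tracks.condition, state_of_bin, list(model.state_names))


# ---------------------------------------------------------------------------
# model file round-trip
# ---------------------------------------------------------------------------


def save_model(model: ChromatinModel, path: str | Path) -> None:
    """Tab-separated text with pi / A / E sections; deterministic output."""
    fmt = "%.10g"
    with open(path, "w") as fh:
        fh.write(f"K\t{model.K}\n")
        fh.write("marks\t" + "\t".join(model.marks) + "\n")
        fh.write("states\t" + "\t".join(model.state_names) + "\n")
        fh.write("[pi]\n")
        fh.write("\t".join(fmt % v for v in model.pi) + "\n")
        fh.write("[A]\n")
        for row in model.A:
            fh.write("\t".join(fmt % v for v in row) + "\n")
        fh.write("[E]\n")
        fh.write("\t".join(model.marks) + "\n")
        for row in model.E:
            fh.write("\t".join(fmt % v for v in row) + "\n")


def load_model(path: str | Path) -> ChromatinModel:
    lines = Path(path).read_text().splitlines()
    K = int(lines[0].split("\t")[1])
    marks = lines[1].split("\t")[1:]
    state_names = lines[2].split("\t")[1:]
    assert lines[3] == "[pi]"
    pi = np.array([float(v) for v in lines[4].split("\t")])
    assert lines[5] == "[A]"
    A = np.array([[float(v) for v in lines[6 + k].split("\t")] for k in range(K)])
    assert lines[6 + K] == "[E]"
    E = np.array([[float(v) for v in lines[8 + K + k].split("\t")] for k in range(K)])
    # renormalize away round-off from the text representation
    pi = pi / pi.sum()
    A = A / A.sum(axis=1, keepdims=True)
    return ChromatinModel(marks, pi, A, E, state_names)
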