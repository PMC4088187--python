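"""Discrete-emission hidden Markov modelling of labeled GPS sequences.

State count is chosen by minimizing AIC + BIC over a candidate range; the
free-parameter count of a k-state model over a K-letter alphabet is
``(k-1) + k(k-1) + k(K-1)`` (initial distribution, transitions, emissions).
Group membership is decided in a leave-one-out scheme: one HMM per group is
fitted on the remaining participants (re-selecting the state count per fold
from training data only) and the held-out sequence is assigned to the group
with the higher per-symbol log-likelihood.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from hmmlearn.hmm import CategoricalHMM
from scipy.stats import binom

logger = logging.getLogger(__name__)

DEFAULT_STATE_CANDIDATES = tuple(range(1, 9))

#: Emission floor applied when scoring held-out sequences, so a symbol
#: unseen in training does not yield -inf likelihood.
_EMISSION_FLOOR = 1e-6


@dataclass
class DiscreteHMM:
    """A fitted k-state HMM over a K-letter alphabet."""

    startprob: np.ndarray
    transmat: np.ndarray
    emissionprob: np.ndarray
    log_likelihood: float

    @property
    def n_states(self) -> int:
        return self.transmat.shape[0]

    @property
    def n_symbols(self) -> int:
        return self.emissionprob.shape[1]

    def _model(self, smoothed: bool = False) -> CategoricalHMM:
        m = CategoricalHMM(
            n_components=self.n_states, n_features=self.n_symbols, init_params=""
        )
        m.startprob_ = self.startprob
        m.transmat_ = self.transmat
        emission = self.emissionprob
        if smoothed:
            emission = np.clip(emission, _EMISSION_FLOOR, None)
            emission = emission / emission.sum(axis=1, keepdims=True)
        m.emissionprob_ = emission
        return m

    def score(self, sequences: list[np.ndarray], smoothed: bool = True) -> float:
        """Total log-likelihood of the sequences (emission-floored by default)."""
        x, lengths = _concat(sequences)
        return float(self._model(smoothed=smoothed).score(x, lengths=lengths))


def _concat(sequences: list[np.ndarray]) -> tuple[np.ndarray, list[int]]:
    seqs = [np.asarray(s, dtype=int).ravel() for s in sequences]
    if not seqs or any(len(s) == 0 for s in seqs):
        raise ValueError("sequences must be non-empty")
    x = np.concatenate(seqs)[:, None]
    return x, [len(s) for s in seqs]


def n_parameters(k: int, n_symbols: int) -> int:
    return (k - 1) + k * (k - 1) + k * (n_symbols - 1)


def _random_stochastic(rng: np.random.Generator, shape) -> np.ndarray:
    m = rng.uniform(size=shape)
    return m / m.sum(axis=-1, keepdims=True)


def fit_hmm(
    sequences: list[np.ndarray],
    k: int,
    n_symbols: int,
    seed: int = 0,
    n_restarts: int = 5,
    n_iter: int = 500,
    tol: float = 1e-4,
) -> DiscreteHMM:
    """Baum-Welch fit with uniform-random row-stochastic initializations.

    ``n_restarts`` independent seeded initializations are run and the one
    with the best final training log-likelihood is kept.  Within each
    restart the EM log-likelihood is non-decreasing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x, lengths = _concat(sequences)
    if x.min() < 0 or x.max() >= n_symbols:
        raise ValueError(
            f"symbols must lie in [0, {n_symbols}); got range "
            f"[{x.min()}, {x.max()}]"
        )
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        m = CategoricalHMM(
            n_components=k,
            n_features=n_symbols,
            init_params="",
            params="ste",
            n_iter=n_iter,
            tol=tol,
        )
        m.startprob_ = _random_stochastic(rng, (k,))
        m.transmat_ = _random_stochastic(rng, (k, k))
        m.emissionprob_ = _random_stochastic(rng, (k, n_symbols))
        m.fit(x, lengths=lengths)
        ll = float(m.score(x, lengths=lengths))
        if best is None or ll > best[0]:
            best = (ll, m)
    ll, m = best
    return DiscreteHMM(
        startprob=m.startprob_.copy(),
        transmat=m.transmat_.copy(),
        emissionprob=m.emissionprob_.copy(),
        log_likelihood=ll,
    )


def information_criteria(
    ll: float, k: int, n_symbols: int, n_obs: int
) -> tuple[float, float]:
    p = n_parameters(k, n_symbols)
    aic = -2.0 * ll + 2.0 * p
    bic = -2.0 * ll + p * math.log(n_obs)
    return aic, bic


def select_states(
    sequences: list[np.ndarray],
    n_symbols: int,
    candidates: tuple[int, ...] = DEFAULT_STATE_CANDIDATES,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[int, DiscreteHMM]:
    """Pick the state count minimizing AIC + BIC (ties -> smaller k)."""
    x, lengths = _concat(sequences)
    n_obs = int(sum(lengths))
    best = None
    for k in sorted(candidates):
        model = fit_hmm(sequences, k, n_symbols, seed=seed, **fit_kwargs)
        aic, bic = information_criteria(model.log_likelihood, k, n_symbols, n_obs)
        crit = aic + bic
        if best is None or crit < best[0] - 1e-12:
            best = (crit, k, model)
    _, k, model = best
    return k, model


@dataclass
class LOOResult:
    accuracy: float
    p_value: float
    assignments: list[str]
    truths: list[str]
    llr: np.ndarray  # per-participant normalized LL(A) - LL(B)
    folds: list[dict]


def classification_significance(accuracy: float, n_participants: int) -> float:
    """One-sided exact binomial tail against chance-level assignment."""
    if n_participants < 1:
        raise ValueError("need at least one participant")
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    n_correct = int(round(accuracy * n_participants))
    return float(binom.sf(n_correct - 1, n_participants, 0.5))


def loo_classify(
    sequences: list[np.ndarray],
    groups: list[str],
    n_symbols: int,
    candidates: tuple[int, ...] = DEFAULT_STATE_CANDIDATES,
    seed: int = 0,
    **fit_kwargs,
) -> LOOResult:
    """Leave-one-out two-group classification of symbol sequences.

    For each held-out participant one HMM per group is trained on the
    remaining participants (state count re-selected per fold), and the
    held-out sequence goes to the group with the higher per-symbol
    log-likelihood.  Likelihoods are normalized by sequence length to
    remove trial-count bias; exact ties are broken by a seeded fair coin.
    """
    groups = list(groups)
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    n = len(sequences)
    if n != len(groups):
        raise ValueError("one group label per sequence required")
    for lab in labels:
        if sum(g == lab for g in groups) < 2:
            raise ValueError(f"group {lab!r} needs at least 2 participants")
    rng = np.random.default_rng(seed)
    assignments, llrs, folds = [], [], []
    for held in range(n):
        train = {lab: [] for lab in labels}
        for i, (s, g) in enumerate(zip(sequences, groups)):
            if i != held:
                train[g].append(s)
        scores, ks = {}, {}
        for lab in labels:
            if not train[lab]:
                raise ValueError(f"fold {held}: empty training group {lab!r}")
            k, model = select_states(
                train[lab], n_symbols, candidates=candidates, seed=seed, **fit_kwargs
            )
            ks[lab] = k
            scores[lab] = model.score([sequences[held]]) / len(sequences[held])
        a, b = labels
        llr = scores[a] - scores[b]
        if llr > 0:
            assigned = a
        elif llr < 0:
            assigned = b
        else:
            assigned = a if rng.random() < 0.5 else b
            logger.warning("fold %d: exact likelihood tie, assigned by coin", held)
        assignments.append(assigned)
        llrs.append(llr)
        folds.append(
            {
                "fold": held,
                "truth": groups[held],
                "assigned": assigned,
                "k_" + a: ks[a],
                "k_" + b: ks[b],
                "ll_" + a: scores[a],
                "ll_" + b: scores[b],
            }
        )
    correct = sum(a == t for a, t in zip(assignments, groups))
    accuracy = correct / n
    return LOOResult(
        accuracy=accuracy,
        p_value=classification_significance(accuracy, n),
        assignments=assignments,
        truths=groups,
        llr=np.array(llrs),
        folds=folds,
    )
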