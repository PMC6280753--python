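"""Copy-number segmentation from binned coverage.

Two stages, run on median-normalized per-bin coverage:

1. A scaling factor s is found that aligns coverage with integer copy
   states by minimizing  sum_bins | s*c_b - round(s*c_b) |  (the coverage
   of a pure subclone is proportional to integer local copy number).
2. A hidden Markov model over integer copy states {0..5} with Cauchy
   emissions centred on the state value (one shared scale parameter,
   learned) is fitted by EM; the Viterbi path segments the genome and the
   copy-weighted genome size G = sum_bins state * bin_length is the
   denominator for per-bp mutation rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from scipy.stats import cauchy

from .core import IntervalTrack

logger = logging.getLogger(__name__)

STATES = np.arange(6)


@dataclass(frozen=True)
class CoverageScaling:
    s: float
    objective: float


def _scaling_objective(coverage: np.ndarray, s_values: np.ndarray) -> np.ndarray:
    out = np.empty(len(s_values))
    for k in range(0, len(s_values), 256):
        chunk = s_values[k:k + 256]
        scaled = chunk[:, None] * coverage[None, :]
        out[k:k + 256] = np.abs(scaled - np.round(scaled)).sum(axis=1)
    return out


def fit_scaling(
    coverage: np.ndarray,
    s_range: tuple[float, float] = (0.25, 4.0),
    coarse_step: float = 1e-3,
    fine_step: float = 1e-5,
) -> CoverageScaling:
    """Grid-plus-refine search for the integer-alignment scaling factor.

    The objective is scale-periodic, so the smallest minimizer in the
    search range is returned on ties.
    """
    coverage = np.asarray(coverage, dtype=float)
    if coverage.size == 0 or np.allclose(coverage, 0):
        raise ValueError("all-zero coverage")
    lo, hi = s_range
    grid = np.arange(lo, hi + coarse_step / 2, coarse_step)
    obj = _scaling_objective(coverage, grid)
    best = float(grid[int(np.argmin(np.round(obj, 12)))])
    fine = np.arange(
        max(lo, best - 2 * coarse_step),
        min(hi, best + 2 * coarse_step) + fine_step / 2,
        fine_step,
    )
    fobj = _scaling_objective(coverage, fine)
    # round to suppress float jitter so the *smallest* near-tied minimizer wins
    i = int(np.argmin(np.round(fobj, 9)))
    return CoverageScaling(float(fine[i]), float(fobj[i]))


# ---------------------------------------------------------------------------
# HMM
# ---------------------------------------------------------------------------


@dataclass
class CnvHmm:
    """HMM over integer copy states with shared-scale Cauchy emissions."""

    transitions: np.ndarray = field(
        default_factory=lambda: _default_transitions()
    )
    startprob: np.ndarray = field(default_factory=lambda: np.full(6, 1 / 6))
    gamma: float = 0.1
    states: np.ndarray = field(default_factory=lambda: STATES.copy())
    log_likelihood_: Optional[float] = None
    n_iter_: int = 0

    def _log_emissions(self, x: np.ndarray, gamma: Optional[float] = None) -> np.ndarray:
        g = self.gamma if gamma is None else gamma
        return cauchy.logpdf(x[:, None], loc=self.states[None, :], scale=g)

    def fit(
        self, x: np.ndarray, tol: float = 1e-6, max_iter: int = 500
    ) -> "CnvHmm":
        """Baum-Welch EM: closed-form transition updates, numerical
        optimization of the Cauchy scale.  Errors if the log-likelihood
        decreases beyond tolerance (implementation bug guard)."""
        x = np.asarray(x, dtype=float)
        prev_ll = -np.inf
        for it in range(max_iter):
            log_b = self._log_emissions(x)
            log_alpha, log_beta, ll = _forward_backward(
                np.log(self.startprob), np.log(self.transitions), log_b
            )
            if ll < prev_ll - 1e-8 * max(1.0, abs(prev_ll)):
                raise RuntimeError(
                    f"EM log-likelihood decreased: {prev_ll} -> {ll}"
                )
            post = log_alpha + log_beta
            post -= logsumexp(post, axis=1, keepdims=True)
            gamma_post = np.exp(post)
            # transition expected counts
            log_A = np.log(self.transitions)
            xi = (
                log_alpha[:-1, :, None]
                + log_A[None, :, :]
                + log_b[1:, None, :]
                + log_beta[1:, None, :]
            )
            xi -= logsumexp(xi, axis=(1, 2), keepdims=True)
            xi_sum = np.exp(logsumexp(xi, axis=0))
            A = xi_sum / np.maximum(xi_sum.sum(axis=1, keepdims=True), 1e-300)
            A = np.maximum(A, 1e-12)
            A /= A.sum(axis=1, keepdims=True)
            pi = np.maximum(gamma_post[0], 1e-12)
            pi /= pi.sum()

            def neg_q(log_g):
                lb = cauchy.logpdf(
                    x[:, None], loc=self.states[None, :], scale=np.exp(log_g)
                )
                return -float((gamma_post * lb).sum())

            res = minimize_scalar(
                neg_q, bounds=(np.log(1e-4), np.log(2.0)), method="bounded"
            )
            self.transitions = A
            self.startprob = pi
            self.gamma = float(np.exp(res.x))
            self.n_iter_ = it + 1
            self.log_likelihood_ = ll
            if ll - prev_ll < tol and it > 0:
                break
            prev_ll = ll
        return self

    def viterbi(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        log_b = self._log_emissions(x)
        return viterbi_path(
            np.log(self.startprob), np.log(self.transitions), log_b
        )

    def posteriors(self, x: np.ndarray) -> np.ndarray:
        log_b = self._log_emissions(np.asarray(x, dtype=float))
        log_alpha, log_beta, _ = _forward_backward(
            np.log(self.startprob), np.log(self.transitions), log_b
        )
        post = log_alpha + log_beta
        post -= logsumexp(post, axis=1, keepdims=True)
        return np.exp(post)


def _default_transitions() -> np.ndarray:
    # long constant segments at 10-kb bins: strong self-transition prior
    A = np.full((6, 6), 0.001 / 5)
    np.fill_diagonal(A, 0.999)
    return A


def _forward_backward(log_pi, log_A, log_b):
    T, S = log_b.shape
    log_alpha = np.empty((T, S))
    log_alpha[0] = log_pi + log_b[0]
    for t in range(1, T):
        log_alpha[t] = log_b[t] + logsumexp(
            log_alpha[t - 1][:, None] + log_A, axis=0
        )
    log_beta = np.zeros((T, S))
    for t in range(T - 2, -1, -1):
        log_beta[t] = logsumexp(
            log_A + log_b[t + 1][None, :] + log_beta[t + 1][None, :], axis=1
        )
    ll = float(logsumexp(log_alpha[-1]))
    return log_alpha, log_beta, ll


def viterbi_path(log_pi, log_A, log_b) -> np.ndarray:
    T, S = log_b.shape
    delta = log_pi + log_b[0]
    back = np.empty((T, S), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, None] + log_A
        back[t] = np.argmax(cand, axis=0)
        delta = log_b[t] + np.max(cand, axis=0)
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def brute_force_viterbi(log_pi, log_A, log_b) -> np.ndarray:
    """Exhaustive best-path enumeration (test oracle; tiny inputs only)."""
    import itertools

    T, S = log_b.shape
    best_path, best_score = None, -np.inf
    for path in itertools.product(range(S), repeat=T):
        score = log_pi[path[0]] + log_b[0, path[0]]
        for t in range(1, T):
            score += log_A[path[t - 1], path[t]] + log_b[t, path[t]]
        if score > best_score:
            best_score, best_path = score, path
    return np.array(best_path, dtype=np.int64)


# ---------------------------------------------------------------------------
# Track
# ---------------------------------------------------------------------------


@dataclass
class CopyNumberTrack:
    """Viterbi copy states per coverage bin, with the effective genome
    size G = sum_bins state * bin_length."""

    chroms: np.ndarray
    starts: np.ndarray
    states: np.ndarray
    bin_length: int
    scaling: Optional[CoverageScaling] = None
    hmm: Optional[CnvHmm] = None

    @property
    def effective_genome_size(self) -> int:
        return int(self.states.sum()) * self.bin_length

    def segments(self) -> list[tuple[str, int, int, int]]:
        """(chrom, start0, end0, state) runs of constant copy state."""
        out = []
        for chrom in pd_unique(self.chroms):
            mask = self.chroms == chrom
            starts = self.starts[mask]
            states = self.states[mask]
            run_start = 0
            for i in range(1, len(states) + 1):
                if i == len(states) or states[i] != states[run_start]:
                    out.append(
                        (
                            str(chrom),
                            int(starts[run_start]),
                            int(starts[i - 1]) + self.bin_length,
                            int(states[run_start]),
                        )
                    )
                    run_start = i
        return out

    def to_interval_track(self) -> IntervalTrack:
        if not hasattr(self, "_track") or self._track is None:
            self._track = IntervalTrack(self.segments())
        return self._track

    def state_at(self, chrom: str, pos: int) -> Optional[int]:
        state = self.to_interval_track().lookup(chrom, pos)
        return None if state is None else int(state)


def pd_unique(arr):
    seen, out = set(), []
    for a in arr:
        if a not in seen:
            seen.add(a)
            out.append(a)
    return out


def fit_cnv_hmm(
    coverage,
    bin_length: int = 10_000,
    scaling: Optional[CoverageScaling] = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> CopyNumberTrack:
    """Scale median-normalized coverage onto integer states and segment it.

    ``coverage`` is a DataFrame with columns chrom/start/coverage or a bare
    array (treated as one contiguous chromosome).
    """
    import pandas as pd

    if isinstance(coverage, pd.DataFrame):
        chroms = coverage["chrom"].to_numpy()
        starts = coverage["start"].to_numpy()
        values = coverage["coverage"].to_numpy(dtype=float)
    else:
        values = np.asarray(coverage, dtype=float)
        chroms = np.array(["chr1"] * len(values))
        starts = np.arange(len(values)) * bin_length
    if scaling is None:
        scaling = fit_scaling(values)
    scaled = scaling.s * values
    hmm = CnvHmm().fit(scaled, tol=tol, max_iter=max_iter)
    states = hmm.viterbi(scaled)
    return CopyNumberTrack(chroms, starts, states, bin_length, scaling, hmm)
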