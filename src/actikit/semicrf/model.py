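"""Semi-Markov CRF potentials, partition function, gradients and decoding.

The model scores a segmentation ``S = [(y_1,b_1,e_1), ...]`` of an observed
discrete symbol sequence ``x_1..x_T`` with three weighted potentials per
segment transition ``(s_{i-1} -> s_i)``:

* transition   ``Q_tr = w_tr(y', y)`` (a distinguished START label feeds the
  first segment),
* duration     ``Q_d  = w_d(y) (d - m_y)^2 / (2 sigma_y^2)`` with
  ``d = e - b + 1`` and per-label duration statistics ``(m_y, sigma_y^2)``
  estimated from training data,
* observation  ``Q_o  = sum_{t=b..e} w_o(y, x_t)
  + sum_{t in gap before the segment} w_o(IA, x_t)``.

Gaps (time steps not covered by any segment, including leading and
trailing stretches and the whole sequence for the empty segmentation)
are charged with the inactivity (IA) observation weights, which is what
makes eliminated null activities first-class.  The conditional
probability of ``S`` is ``exp(score(S)) / Z_X`` with ``Z_X`` the sum over
every valid segmentation whose segments all have duration ``<= D``.

All internal computations are in log-space; labels are integer indices
``0..M-1`` here (the estimator layer maps arbitrary labels to indices).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from ..errors import ContractError
from .segments import SemiSegment

#: Sentinel for "no previous segment" in :func:`potentials`.
START = "START"

_NEG_INF = -np.inf


def _lse(a: np.ndarray, axis=None) -> np.ndarray:
    """log-sum-exp with max-shift; tolerates all -inf slices."""
    a = np.asarray(a, dtype=float)
    m = np.max(a, axis=axis, keepdims=True)
    m_safe = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(divide="ignore"):
        out = np.log(np.sum(np.exp(a - m_safe), axis=axis)) + np.squeeze(m_safe, axis=axis)
    if axis is None:
        return float(out)
    bad = ~np.isfinite(np.squeeze(m, axis=axis))
    if np.any(bad):
        out = np.where(bad, _NEG_INF, out)
    return out


@dataclass
class ModelParams:
    """Weight vectors of the semi-Markov CRF.

    ``w_tr`` has shape ``(M+1, M)`` — row ``M`` is the START label.
    ``w_o`` has shape ``(M+1, n_symbols)`` — row ``M`` is the IA label.
    ``w_d`` has shape ``(M,)``.
    """

    w_tr: np.ndarray
    w_d: np.ndarray
    w_o: np.ndarray

    @property
    def n_labels(self) -> int:
        return self.w_d.shape[0]

    @property
    def n_symbols(self) -> int:
        return self.w_o.shape[1]

    @classmethod
    def zeros(cls, n_labels: int, n_symbols: int) -> "ModelParams":
        return cls(
            w_tr=np.zeros((n_labels + 1, n_labels)),
            w_d=np.zeros(n_labels),
            w_o=np.zeros((n_labels + 1, n_symbols)),
        )

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.w_tr.ravel(), self.w_d.ravel(), self.w_o.ravel()])

    @classmethod
    def from_vector(cls, vec: np.ndarray, n_labels: int, n_symbols: int) -> "ModelParams":
        m, s = n_labels, n_symbols
        n_tr = (m + 1) * m
        return cls(
            w_tr=vec[:n_tr].reshape(m + 1, m).copy(),
            w_d=vec[n_tr : n_tr + m].copy(),
            w_o=vec[n_tr + m :].reshape(m + 1, s).copy(),
        )

    def copy(self) -> "ModelParams":
        return ModelParams(self.w_tr.copy(), self.w_d.copy(), self.w_o.copy())


@dataclass
class ArrayDurationStats:
    """Index-aligned duration statistics (means ``m`` and variances ``s2``)."""

    m: np.ndarray
    s2: np.ndarray


@dataclass
class OpCounter:
    """Counts elementary potential evaluations (one scalar psi-term each).

    Increments may be applied in bulk when the surrounding computation is
    vectorized; the count always reflects the number of elementary terms
    combined.
    """

    potential_evals: int = 0

    def add(self, n: int) -> None:
        self.potential_evals += int(n)


# ---------------------------------------------------------------------------
# Per-sequence precomputations
# ---------------------------------------------------------------------------


@dataclass
class _Tables:
    T: int
    M: int
    D: int
    cum_ia: np.ndarray  # (T+1,)  prefix sums of w_o[IA, x_t]
    cum_w: np.ndarray   # (M, T+1) prefix sums of w_o[y, x_t]
    durf: np.ndarray    # (M, D+1) duration features (d-m)^2 / (2 s2)


def _tables(x: np.ndarray, w: ModelParams, stats: ArrayDurationStats, D: int) -> _Tables:
    x = np.asarray(x, dtype=int)
    T = x.shape[0]
    M = w.n_labels
    if T < 1:
        raise ContractError("observation sequence must have length >= 1")
    if x.min(initial=0) < 0 or x.max(initial=0) >= w.n_symbols:
        raise ContractError("symbol outside alphabet")
    if D < 1:
        raise ContractError("max duration D must be >= 1")
    cum_ia = np.zeros(T + 1)
    cum_ia[1:] = np.cumsum(w.w_o[M, x])
    cum_w = np.zeros((M, T + 1))
    cum_w[:, 1:] = np.cumsum(w.w_o[:M, x], axis=1)
    d = np.arange(D + 1, dtype=float)
    durf = (d[None, :] - stats.m[:, None]) ** 2 / (2.0 * stats.s2[:, None])
    durf[:, 0] = 0.0
    return _Tables(T=T, M=M, D=D, cum_ia=cum_ia, cum_w=cum_w, durf=durf)


def _check_segmentation(segs, T: int, M: int, D: int | None = None) -> None:
    prev_end = 0
    for seg in segs:
        if not (0 <= seg.y < M):
            raise ContractError(f"label index {seg.y} out of range")
        if not (1 <= seg.b <= seg.e <= T):
            raise ContractError(f"segment {seg} outside [1, {T}]")
        if seg.b <= prev_end:
            raise ContractError(f"segment {seg} violates b > previous e")
        if D is not None and seg.duration > D:
            raise ContractError(f"segment {seg} longer than max duration {D}")
        prev_end = seg.e


# ---------------------------------------------------------------------------
# Potentials and sequence scores
# ---------------------------------------------------------------------------


def potentials(prev, cur: SemiSegment, x, w: ModelParams, stats: ArrayDurationStats):
    """Evaluate ``(Q_tr, Q_d, Q_o, log_psi)`` for one segment transition.

    ``prev`` is either :data:`START` or the preceding segment; the gap
    ``prev.e+1 .. cur.b-1`` (or ``1 .. cur.b-1`` after START) contributes
    IA observation terms to ``Q_o``.
    """
    x = np.asarray(x, dtype=int)
    T = x.shape[0]
    M = w.n_labels
    if not (1 <= cur.b <= cur.e <= T):
        raise ContractError(f"segment {cur} outside [1, {T}]")
    if prev is START:
        prev_label_idx = M
        gap_start = 1
    else:
        if prev.e >= cur.b:
            raise ContractError("segments must satisfy prev.e < cur.b")
        prev_label_idx = prev.y
        gap_start = prev.e + 1
    q_tr = float(w.w_tr[prev_label_idx, cur.y])
    d = cur.duration
    q_d = float(w.w_d[cur.y]) * (d - stats.m[cur.y]) ** 2 / (2.0 * stats.s2[cur.y])
    q_o = float(np.sum(w.w_o[cur.y, x[cur.b - 1 : cur.e]]))
    if gap_start <= cur.b - 1:
        q_o += float(np.sum(w.w_o[M, x[gap_start - 1 : cur.b - 1]]))
    return q_tr, q_d, q_o, q_tr + q_d + q_o


def sequence_score(segs, x, w: ModelParams, stats: ArrayDurationStats) -> float:
    """Unnormalized log-score of a full segmentation, trailing IA included."""
    x = np.asarray(x, dtype=int)
    T = x.shape[0]
    M = w.n_labels
    _check_segmentation(segs, T, M)
    total = 0.0
    prev = START
    for seg in segs:
        total += potentials(prev, seg, x, w, stats)[3]
        prev = seg
    tail_start = 1 if prev is START else prev.e + 1
    if tail_start <= T:
        total += float(np.sum(w.w_o[M, x[tail_start - 1 : T]]))
    return total


# ---------------------------------------------------------------------------
# Forward / backward recursions
# ---------------------------------------------------------------------------


def _forward(tb: _Tables, w: ModelParams, counter: OpCounter | None = None):
    """Forward pass.

    Returns ``(log_z, alpha, seg_start, acc_a)`` where

    * ``alpha[e, y]`` sums over segmentations whose last segment ends at
      ``e`` with label ``y`` (IA charged through ``e``),
    * ``seg_start[b, y]`` is the log-mass of everything before a segment
      beginning at ``b`` with label ``y`` (START term or any predecessor,
      transition weight and gap IA included),
    * ``acc_a[t, y] = lse_{e' <= t} (alpha[e', y] - cum_ia[e'])``.
    """
    T, M, D = tb.T, tb.M, tb.D
    alpha = np.full((T + 1, M), _NEG_INF)
    seg_start = np.full((T + 1, M), _NEG_INF)
    acc_a = np.full((T + 1, M), _NEG_INF)
    w_tr = w.w_tr
    for e in range(1, T + 1):
        prev_term = _lse(w_tr[:M, :] + acc_a[e - 1][:, None], axis=0)
        seg_start[e] = np.logaddexp(w_tr[M], prev_term) + tb.cum_ia[e - 1]
        if counter is not None:
            counter.add(M * (M + 1))
        dmax = min(D, e)
        ds = np.arange(1, dmax + 1)
        bs = e - ds + 1
        for y in range(M):
            vals = (
                seg_start[bs, y]
                + w.w_d[y] * tb.durf[y, ds]
                + (tb.cum_w[y, e] - tb.cum_w[y, bs - 1])
            )
            alpha[e, y] = _lse(vals)
        if counter is not None:
            counter.add(M * dmax)
        acc_a[e] = np.logaddexp(acc_a[e - 1], alpha[e] - tb.cum_ia[e])
    log_z = np.logaddexp(tb.cum_ia[T], tb.cum_ia[T] + _lse(acc_a[T]))
    return float(log_z), alpha, seg_start, acc_a


def _backward(tb: _Tables, w: ModelParams, counter: OpCounter | None = None):
    """Backward pass.

    Returns ``(beta, seg_in, suffix)`` where

    * ``beta[e, y]`` sums over completions after a segment ending at
      ``(e, y)`` (empty tail and all further segments, gap IA included),
    * ``seg_in[b, y]`` sums segment bodies starting at ``b`` with label
      ``y`` times their completions,
    * ``suffix[t, y] = lse_{b >= t} (cum_ia[b-1] + seg_in[b, y])``.
    """
    T, M, D = tb.T, tb.M, tb.D
    beta = np.full((T + 2, M), _NEG_INF)
    seg_in = np.full((T + 2, M), _NEG_INF)
    suffix = np.full((T + 2, M), _NEG_INF)
    for e in range(T, 0, -1):
        trans = _lse(w.w_tr[:M, :] + suffix[e + 1][None, :], axis=1)
        beta[e] = np.logaddexp(tb.cum_ia[T] - tb.cum_ia[e], trans - tb.cum_ia[e])
        if counter is not None:
            counter.add(M * M)
        dmax = min(D, T - e + 1)
        ds = np.arange(1, dmax + 1)
        es = e + ds - 1
        for y in range(M):
            vals = (
                w.w_d[y] * tb.durf[y, ds]
                + (tb.cum_w[y, es] - tb.cum_w[y, e - 1])
                + beta[es, y]
            )
            seg_in[e, y] = _lse(vals)
        if counter is not None:
            counter.add(M * dmax)
        suffix[e] = np.logaddexp(suffix[e + 1], tb.cum_ia[e - 1] + seg_in[e])
    return beta, seg_in, suffix


def log_partition(x, w: ModelParams, stats: ArrayDurationStats, D: int,
                  counter: OpCounter | None = None) -> float:
    """``log Z_X``: log-sum of exp(score) over all valid segmentations.

    The empty segmentation is included (it contributes
    ``exp(sum_t w_o(IA, x_t))``).
    """
    tb = _tables(x, w, stats, D)
    log_z, *_ = _forward(tb, w, counter)
    return log_z


def log_likelihood(s, x, w: ModelParams, stats: ArrayDurationStats, D: int) -> float:
    """``L(S|X) = score(S) - log Z_X``; always <= 0."""
    x = np.asarray(x, dtype=int)
    tb = _tables(x, w, stats, D)
    _check_segmentation(s, tb.T, tb.M, D)
    return sequence_score(s, x, w, stats) - log_partition(x, w, stats, D)


# ---------------------------------------------------------------------------
# Feature counts and gradients
# ---------------------------------------------------------------------------


def observed_counts(s, x, w: ModelParams, stats: ArrayDurationStats) -> ModelParams:
    """Feature counts of a fixed segmentation, in ModelParams layout.

    IA observation counts are the symbols on every time step not covered
    by a segment.
    """
    x = np.asarray(x, dtype=int)
    T = x.shape[0]
    M = w.n_labels
    out = ModelParams.zeros(M, w.n_symbols)
    covered = np.zeros(T, dtype=bool)
    prev_idx = M
    for seg in s:
        out.w_tr[prev_idx, seg.y] += 1.0
        d = seg.duration
        out.w_d[seg.y] += (d - stats.m[seg.y]) ** 2 / (2.0 * stats.s2[seg.y])
        np.add.at(out.w_o[seg.y], x[seg.b - 1 : seg.e], 1.0)
        covered[seg.b - 1 : seg.e] = True
        prev_idx = seg.y
    np.add.at(out.w_o[M], x[~covered], 1.0)
    return out


def expected_counts(x, w: ModelParams, stats: ArrayDurationStats, D: int,
                    counter: OpCounter | None = None):
    """Model-expected feature counts via segment-marginal forward-backward.

    Returns ``(expected, log_z)``.  Work is ``O(T M (M + D))`` plus
    ``O(T M D)`` for the segment marginals — the "fast" path.
    """
    x = np.asarray(x, dtype=int)
    tb = _tables(x, w, stats, D)
    T, M = tb.T, tb.M
    log_z, alpha, seg_start, acc_a = _forward(tb, w, counter)
    beta, seg_in, suffix = _backward(tb, w, counter)

    exp = ModelParams.zeros(M, w.n_symbols)

    # transition expectations
    exp.w_tr[M] = np.exp(w.w_tr[M] + suffix[1] - log_z)
    # G[b, y] = cum_ia[b-1] + seg_in[b, y];  A1[b, y'] = acc_a[b-1, y']
    bs = np.arange(1, T + 1)
    G = tb.cum_ia[bs - 1][:, None] + seg_in[1 : T + 1]   # (T, M)
    A1 = acc_a[bs - 1]                                   # (T, M)
    for yp in range(M):
        for y in range(M):
            exp.w_tr[yp, y] = np.exp(w.w_tr[yp, y] + _lse(A1[:, yp] + G[:, y]) - log_z)
    if counter is not None:
        counter.add(M * M * T + M)

    # segment marginals -> duration expectations and occupancy
    occ_diff = np.zeros((M, T + 2))
    for e in range(1, T + 1):
        dmax = min(D, e)
        ds = np.arange(1, dmax + 1)
        b_arr = e - ds + 1
        for y in range(M):
            logm = (
                seg_start[b_arr, y]
                + w.w_d[y] * tb.durf[y, ds]
                + (tb.cum_w[y, e] - tb.cum_w[y, b_arr - 1])
                + beta[e, y]
                - log_z
            )
            m = np.exp(logm)
            exp.w_d[y] += float(np.dot(m, tb.durf[y, ds]))
            np.add.at(occ_diff[y], b_arr, m)
            occ_diff[y, e + 1] -= m.sum()
        if counter is not None:
            counter.add(M * dmax)

    occ = np.cumsum(occ_diff[:, : T + 1], axis=1)[:, 1:]  # (M, T)
    occ = np.clip(occ, 0.0, None)
    for y in range(M):
        np.add.at(exp.w_o[y], x, occ[y])
    occ_ia = np.clip(1.0 - occ.sum(axis=0), 0.0, None)
    np.add.at(exp.w_o[M], x, occ_ia)
    if counter is not None:
        counter.add((M + 1) * T)
    return exp, log_z


def gradients_fast(x, s, w: ModelParams, stats: ArrayDurationStats, D: int,
                   counter: OpCounter | None = None) -> ModelParams:
    """``d L(S|X) / d w`` = observed counts minus expected counts.

    Asymptotic work follows the fast recursion: ``O(T M (M + D))``
    shared across all gradients (a single forward-backward), versus the
    naive path that re-runs an ``O(T M^2 D)`` recursion per parameter.
    """
    x = np.asarray(x, dtype=int)
    tb = _tables(x, w, stats, D)
    _check_segmentation(s, tb.T, tb.M, D)
    obs = observed_counts(s, x, w, stats)
    exp, _ = expected_counts(x, w, stats, D, counter)
    return ModelParams(obs.w_tr - exp.w_tr, obs.w_d - exp.w_d, obs.w_o - exp.w_o)


# ---------------------------------------------------------------------------
# Brute-force enumeration oracle
# ---------------------------------------------------------------------------


def enumerate_segmentations(T: int, M: int, D: int):
    """Yield every valid segmentation (lists of :class:`SemiSegment`
    with integer labels) of a length-``T`` sequence.  Exponential; used
    as a testing oracle for small ``T``."""

    def rec(t0: int):
        yield []
        for b in range(t0, T + 1):
            for d in range(1, min(D, T - b + 1) + 1):
                e = b + d - 1
                for y in range(M):
                    head = SemiSegment(y, b, e)
                    for tail in rec(e + 1):
                        yield [head] + tail

    yield from rec(1)


def gradients_bruteforce(x, s, w: ModelParams, stats: ArrayDurationStats, D: int) -> ModelParams:
    """Gradient via explicit enumeration of every valid segmentation.

    Guarded to ``T <= 10``; the independent oracle for
    :func:`gradients_fast`.
    """
    x = np.asarray(x, dtype=int)
    T = x.shape[0]
    if T > 10:
        raise ContractError("brute-force gradients are guarded to T <= 10")
    tb = _tables(x, w, stats, D)
    _check_segmentation(s, T, tb.M, D)
    M = w.n_labels
    scores = []
    counts = []
    for cand in enumerate_segmentations(T, M, D):
        scores.append(sequence_score(cand, x, w, stats))
        counts.append(observed_counts(cand, x, w, stats))
    scores = np.asarray(scores)
    log_z = _lse(scores)
    probs = np.exp(scores - log_z)
    exp = ModelParams.zeros(M, w.n_symbols)
    for p, c in zip(probs, counts):
        exp.w_tr += p * c.w_tr
        exp.w_d += p * c.w_d
        exp.w_o += p * c.w_o
    obs = observed_counts(s, x, w, stats)
    return ModelParams(obs.w_tr - exp.w_tr, obs.w_d - exp.w_d, obs.w_o - exp.w_o)


# ---------------------------------------------------------------------------
# Naive per-parameter gradient (instrumented reference path)
# ---------------------------------------------------------------------------


def _expectation_forward(tb: _Tables, w: ModelParams, feature, counter: OpCounter | None):
    """Expectation-semiring forward pass for a single feature.

    ``feature`` is ``("tr", yp, y)``, ``("d", y)`` or ``("o", y, o)`` with
    ``y`` an expected-activity label.  Returns ``(log_z, log_E_hat)``
    where ``E[f] = exp(log_E_hat - log_z)``.  Every pass re-runs the full
    recursion with an explicit inner sum over predecessor labels, i.e.
    ``O(T M^2 D)`` elementary potential evaluations per parameter — the
    per-gradient cost of the reference algorithm this package improves on.
    """
    T, M, D = tb.T, tb.M, tb.D
    kind = feature[0]
    alpha = np.full((T + 1, M), _NEG_INF)
    alpha_hat = np.full((T + 1, M), _NEG_INF)
    acc_a = np.full((T + 1, M), _NEG_INF)
    acc_ah = np.full((T + 1, M), _NEG_INF)
    seg_start = np.full((T + 1, M), _NEG_INF)
    seg_start_hat = np.full((T + 1, M), _NEG_INF)
    w_tr = w.w_tr
    for e in range(1, T + 1):
        # predecessor sums, explicitly over the M+1 possible previous labels
        prev = _lse(w_tr[:M, :] + acc_a[e - 1][:, None], axis=0)
        seg_start[e] = np.logaddexp(w_tr[M], prev) + tb.cum_ia[e - 1]
        prev_hat = _lse(w_tr[:M, :] + acc_ah[e - 1][:, None], axis=0)
        seg_start_hat[e] = prev_hat + tb.cum_ia[e - 1]
        if kind == "tr":
            yp, y2 = feature[1], feature[2]
            if yp == M:  # START transition feature
                seg_start_hat[e, y2] = np.logaddexp(
                    seg_start_hat[e, y2], w_tr[M, y2] + tb.cum_ia[e - 1]
                )
            else:
                seg_start_hat[e, y2] = np.logaddexp(
                    seg_start_hat[e, y2],
                    w_tr[yp, y2] + acc_a[e - 1, yp] + tb.cum_ia[e - 1],
                )
        dmax = min(D, e)
        ds = np.arange(1, dmax + 1)
        bs = e - ds + 1
        for y in range(M):
            body = w.w_d[y] * tb.durf[y, ds] + (tb.cum_w[y, e] - tb.cum_w[y, bs - 1])
            alpha[e, y] = _lse(seg_start[bs, y] + body)
            hat_terms = seg_start_hat[bs, y] + body
            if kind == "d" and feature[1] == y:
                fval = tb.durf[y, ds]
            elif kind == "o" and feature[1] == y:
                cnt = _symbol_counts(tb, feature[2])
                fval = cnt[e] - cnt[bs - 1]  # count of symbol o in x[b..e]
            else:
                fval = None
            if fval is not None:
                with np.errstate(divide="ignore"):
                    add = seg_start[bs, y] + body + np.log(np.maximum(fval, 0.0))
                add = np.where(fval > 0, add, _NEG_INF)
                hat_terms = np.logaddexp(hat_terms, add)
            alpha_hat[e, y] = _lse(hat_terms)
        if counter is not None:
            # M predecessor psi-terms per (e, y, d), for value and hat channel
            counter.add(2 * M * dmax * M)
        acc_a[e] = np.logaddexp(acc_a[e - 1], alpha[e] - tb.cum_ia[e])
        acc_ah[e] = np.logaddexp(acc_ah[e - 1], alpha_hat[e] - tb.cum_ia[e])
    log_z = np.logaddexp(tb.cum_ia[T], tb.cum_ia[T] + _lse(acc_a[T]))
    log_e_hat = tb.cum_ia[T] + _lse(acc_ah[T])
    return float(log_z), float(log_e_hat)


def _symbol_counts(tb: _Tables, o: int) -> np.ndarray:
    """Prefix counts of symbol ``o`` (cached on the tables object)."""
    cache = getattr(tb, "_sym_counts", None)
    if cache is None:
        cache = {}
        tb._sym_counts = cache  # type: ignore[attr-defined]
    if o not in cache:
        x = getattr(tb, "_x")
        cnt = np.zeros(tb.T + 1)
        cnt[1:] = np.cumsum(x == o)
        cache[o] = cnt
    return cache[o]


def gradients_naive(x, s, w: ModelParams, stats: ArrayDurationStats, D: int,
                    params: list | None = None,
                    counter: OpCounter | None = None) -> dict:
    """Reference gradient: one expectation-semiring recursion per parameter.

    ``params`` is a list of feature tuples ``("tr", yp, y)`` /
    ``("d", y)`` / ``("o", y, o)``; ``yp`` may equal ``M`` for the START
    row and ``("o", M, o)`` (the IA row) is derived by complementarity
    (total symbol count minus the in-segment expectations of every
    expected label, each computed with its own pass).  When ``params`` is
    None, all parameters are computed.  Returns ``{feature: gradient}``.
    """
    x = np.asarray(x, dtype=int)
    tb = _tables(x, w, stats, D)
    tb._x = x  # type: ignore[attr-defined]
    T, M = tb.T, tb.M
    _check_segmentation(s, T, M, D)
    if params is None:
        params = (
            [("tr", yp, y) for yp in range(M + 1) for y in range(M)]
            + [("d", y) for y in range(M)]
            + [("o", y, o) for y in range(M + 1) for o in range(w.n_symbols)]
        )
    obs = observed_counts(s, x, w, stats)
    out = {}
    ia_cache: dict[int, float] = {}
    for feat in params:
        if feat[0] == "o" and feat[1] == M:
            o = feat[2]
            if o not in ia_cache:
                total = float(np.sum(x == o))
                exp_in = 0.0
                for y in range(M):
                    lz, lh = _expectation_forward(tb, w, ("o", y, o), counter)
                    exp_in += np.exp(lh - lz) if np.isfinite(lh) else 0.0
                ia_cache[o] = total - exp_in
            expected = ia_cache[o]
        else:
            lz, lh = _expectation_forward(tb, w, feat, counter)
            expected = np.exp(lh - lz) if np.isfinite(lh) else 0.0
        if feat[0] == "tr":
            observed = obs.w_tr[feat[1], feat[2]]
        elif feat[0] == "d":
            observed = obs.w_d[feat[1]]
        else:
            observed = obs.w_o[feat[1], feat[2]]
        out[feat] = float(observed - expected)
    return out


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------


def infer(x, w: ModelParams, stats: ArrayDurationStats, D: int) -> list[SemiSegment]:
    """Maximum-score segmentation by semi-Markov Viterbi with gap
    transitions.

    Exact ties are broken deterministically: fewer segments first, then
    lexicographically earlier ``(b, y)`` sequences (earlier begins, then
    smaller label index).
    """
    x = np.asarray(x, dtype=int)
    tb = _tables(x, w, stats, D)
    T, M, D = tb.T, tb.M, tb.D

    # cell: (score, key, segments) with key = (n_segments, (b1, y1, b2, y2, ...))
    def better(sc, key, best):
        if best is None:
            return True
        bsc, bkey, _ = best
        if sc > bsc:
            return True
        return sc == bsc and key < bkey

    V = [[None] * M for _ in range(T + 1)]  # V[e][y]
    # bp[t][y] = best over e' <= t of (V[e'][y] - cum_ia[e']); bp[0] all None
    bp = [[None] * M for _ in range(T + 1)]
    for e in range(1, T + 1):
        for y in range(M):
            cell = None
            for d in range(1, min(D, e) + 1):
                b = e - d + 1
                body = (
                    w.w_d[y] * tb.durf[y, d]
                    + (tb.cum_w[y, e] - tb.cum_w[y, b - 1])
                    + tb.cum_ia[b - 1]
                )
                # from START
                sc = float(w.w_tr[M, y] + body)
                key = (1, (b, y))
                if better(sc, key, cell):
                    cell = (sc, key, ((y, b, e),))
                # from a previous segment ending at any e' <= b-1
                for yp in range(M):
                    pv = bp[b - 1][yp]
                    if pv is None:
                        continue
                    psc, pkey, psegs = pv
                    sc = float(psc + w.w_tr[yp, y] + body)
                    key = (pkey[0] + 1, pkey[1] + (b, y))
                    if better(sc, key, cell):
                        cell = (sc, key, psegs + ((y, b, e),))
            V[e][y] = cell
        for y in range(M):
            cand = bp[e - 1][y]
            cell = V[e][y]
            if cell is not None:
                folded = (cell[0] - tb.cum_ia[e], cell[1], cell[2])
                if cand is None or better(folded[0], folded[1], cand):
                    cand = folded
            bp[e][y] = cand

    best = (float(tb.cum_ia[T]), (0, ()), ())  # empty segmentation
    for e in range(1, T + 1):
        for y in range(M):
            cell = V[e][y]
            if cell is None:
                continue
            sc = float(cell[0] + tb.cum_ia[T] - tb.cum_ia[e])
            if better(sc, cell[1], best):
                best = (sc, cell[1], cell[2])
    return [SemiSegment(y, b, e) for (y, b, e) in best[2]]
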