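"""Scikit-learn style estimator wrapping the semi-Markov CRF core."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from ..errors import ContractError
from . import model as _m
from .segments import SemiSegment, duration_stats, encode_segments


class SemiMarkovCRF(BaseEstimator):
    """Null-activity-aware semi-Markov conditional random field.

    Training maximizes the L2-regularized conditional log-likelihood of
    the true segmentations by full-batch gradient ascent with a
    backtracking line search; decoding is exact semi-Markov Viterbi over
    (end time, label, duration) with gap transitions.

    Parameters
    ----------
    max_duration : int
        Maximum segment duration ``D`` supported by the model.
    l2 : float
        L2 regularization strength (lambda).
    max_iter : int
        Maximum gradient-ascent iterations.
    tol : float
        Relative objective-change convergence threshold.
    null_labels : iterable
        Labels in training sequences to treat as null activities
        (eliminated into gaps).
    random_state : int or None
        Kept for API symmetry; training is deterministic (zero
        initialization, batch updates).

    Attributes
    ----------
    classes_ : ndarray
        Sorted expected (non-null) labels.
    params_ : ModelParams
        Learned weight vectors (transition / duration / observation).
    duration_stats_ : ArrayDurationStats
        Per-label duration means/variances estimated from training data.
    objective_trace_ : list of float
        Regularized objective after each accepted step (non-decreasing).
    """

    def __init__(self, max_duration=256, l2=0.1, max_iter=100, tol=1e-6,
                 null_labels=(), random_state=None):
        self.max_duration = max_duration
        self.l2 = l2
        self.max_iter = max_iter
        self.tol = tol
        self.null_labels = null_labels
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------

    def _encode_corpus(self, X, y):
        nulls = set(self.null_labels)
        truths = [encode_segments(labels, nulls) for labels in y]
        label_set = sorted({seg.y for s in truths for seg in s})
        if not label_set:
            raise ContractError("training corpus contains no non-null segments")
        self.classes_ = np.asarray(label_set)
        idx = {lab: i for i, lab in enumerate(label_set)}
        enc = [[SemiSegment(idx[s.y], s.b, s.e) for s in segs] for segs in truths]
        n_symbols = int(max(int(np.max(xi)) for xi in X)) + 1
        return [np.asarray(xi, dtype=int) for xi in X], enc, n_symbols

    def _objective_and_grad(self, X, S, w, stats, D):
        # one forward-backward per sequence yields both log Z and the
        # expected counts, so likelihood and gradient share the work
        vec = w.as_vector()
        obj = -0.5 * self.l2 * float(vec @ vec)
        grad = _m.ModelParams.zeros(w.n_labels, w.n_symbols)
        for xi, si in zip(X, S):
            exp, log_z = _m.expected_counts(xi, w, stats, D)
            obs = _m.observed_counts(si, xi, w, stats)
            obj += _m.sequence_score(si, xi, w, stats) - log_z
            grad.w_tr += obs.w_tr - exp.w_tr
            grad.w_d += obs.w_d - exp.w_d
            grad.w_o += obs.w_o - exp.w_o
        grad.w_tr -= self.l2 * w.w_tr
        grad.w_d -= self.l2 * w.w_d
        grad.w_o -= self.l2 * w.w_o
        return obj, grad

    def _objective(self, X, S, w, stats, D):
        vec = w.as_vector()
        obj = -0.5 * self.l2 * float(vec @ vec)
        for xi, si in zip(X, S):
            obj += _m.log_likelihood(si, xi, w, stats, D)
        return obj

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        """Fit from symbol sequences ``X`` and per-time label sequences ``y``.

        Each ``y[i]`` has the same length as ``X[i]`` and may contain
        null labels; those stretches become gaps charged to IA.
        """
        if len(X) == 0 or len(X) != len(y):
            raise ContractError("need a non-empty corpus with matching X and y")
        for xi, yi in zip(X, y):
            if len(xi) != len(yi):
                raise ContractError("each label sequence must match its observations")
        X_enc, S_enc, n_symbols = self._encode_corpus(X, y)
        M = len(self.classes_)
        D = int(self.max_duration)
        for segs in S_enc:
            for seg in segs:
                if seg.duration > D:
                    raise ContractError(
                        f"training segment duration {seg.duration} exceeds max_duration {D}"
                    )
        ds = duration_stats(S_enc, labels=range(M))
        stats = _m.ArrayDurationStats(
            m=np.asarray([ds.mean(i) for i in range(M)]),
            s2=np.asarray([ds.var(i) for i in range(M)]),
        )
        self.duration_stats_ = stats
        w = _m.ModelParams.zeros(M, n_symbols)

        obj, grad = self._objective_and_grad(X_enc, S_enc, w, stats, D)
        trace = [obj]
        step = 0.5
        stall = 0
        for _ in range(int(self.max_iter)):
            gvec = grad.as_vector()
            gnorm2 = float(gvec @ gvec)
            if np.sqrt(gnorm2) < 1e-4:
                break
            accepted = False
            for _bt in range(30):
                cand_vec = w.as_vector() + step * gvec
                cand = _m.ModelParams.from_vector(cand_vec, M, n_symbols)
                cand_obj = self._objective(X_enc, S_enc, cand, stats, D)
                if cand_obj >= obj + 1e-4 * step * gnorm2:
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                break
            rel = abs(cand_obj - obj) / max(1.0, abs(obj))
            w = cand
            obj, grad = self._objective_and_grad(X_enc, S_enc, w, stats, D)
            trace.append(obj)
            step *= 1.5
            stall = stall + 1 if rel < self.tol else 0
            if stall >= 3:
                break
        self.params_ = w
        self.objective_trace_ = trace
        self.n_symbols_ = n_symbols
        return self

    def predict_segments(self, X):
        """Decode each sequence into a list of segments with original labels."""
        self._check_fitted()
        labels = self.classes_.tolist()
        out = []
        for xi in X:
            segs = _m.infer(np.asarray(xi, dtype=int), self.params_,
                            self.duration_stats_, int(self.max_duration))
            out.append([SemiSegment(labels[s.y], s.b, s.e) for s in segs])
        return out

    def predict(self, X, ia_label="IA"):
        """Decode each sequence into a per-time label sequence; gaps get
        ``ia_label``."""
        from .segments import decode_segments

        segs = self.predict_segments(X)
        return [decode_segments(s, len(xi), ia_label=ia_label) for s, xi in zip(segs, X)]

    def score_sequence(self, x, labels):
        """Conditional log-likelihood of a labelled sequence."""
        self._check_fitted()
        idx = {lab: i for i, lab in enumerate(self.classes_)}
        segs = [
            SemiSegment(idx[s.y], s.b, s.e)
            for s in encode_segments(labels, set(self.null_labels))
        ]
        return _m.log_likelihood(segs, np.asarray(x, dtype=int), self.params_,
                                 self.duration_stats_, int(self.max_duration))

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise ContractError("estimator is not fitted")


def segment_f1(predicted, truth, min_iou: float = 0.5):
    """Segment-level F1: greedy 1-to-1 matching of same-label segments
    with interval IoU >= ``min_iou``.

    ``predicted`` and ``truth`` are lists of segments for ONE sequence,
    or lists of such lists for a corpus.
    """
    if predicted and isinstance(predicted[0], SemiSegment):
        predicted, truth = [predicted], [truth]
    elif not predicted:
        predicted, truth = [list(predicted)], [list(truth)]
    tp = fp = fn = 0
    for pred, tru in zip(predicted, truth):
        used = [False] * len(tru)
        for p in pred:
            best = -1
            best_iou = min_iou
            for j, t in enumerate(tru):
                if used[j] or t.y != p.y:
                    continue
                inter = max(0, min(p.e, t.e) - max(p.b, t.b) + 1)
                union = (p.e - p.b + 1) + (t.e - t.b + 1) - inter
                iou = inter / union
                if iou >= best_iou:
                    best_iou = iou
                    best = j
            if best >= 0:
                used[best] = True
                tp += 1
            else:
                fp += 1
        fn += used.count(False)
    denom_p = tp + fp
    denom_r = tp + fn
    precision = tp / denom_p if denom_p else 1.0
    recall = tp / denom_r if denom_r else 1.0
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
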