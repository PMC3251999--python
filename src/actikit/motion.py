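"""Silhouette-sequence activity classification.

Pipeline: binary silhouette frames -> consecutive-frame difference
images -> ICA projection (motion features) -> vector quantization
against a k-means codebook -> one discrete HMM per activity; a test
sequence is assigned the label of the model with the highest forward
log-likelihood, or ``"Unknown"`` when even the best per-frame
log-likelihood falls below a floor.

Frames are resized to 100x70 (nearest neighbour, re-binarized at 0.5)
before feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from hmmlearn.hmm import CategoricalHMM
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import FastICA

from .errors import ContractError

__all__ = [
    "FRAME_SHAPE",
    "MotionBasis",
    "Codebook",
    "DiscreteHMM",
    "ActivityModelBank",
    "resize_silhouette",
    "fit_motion_basis",
    "project_features",
    "build_codebook",
    "quantize",
    "train_hmm",
    "forward_loglik",
    "default_unknown_threshold",
    "calibrated_unknown_threshold",
    "classify",
    "SilhouetteActivityClassifier",
]

#: Canonical silhouette frame size (rows, cols).
FRAME_SHAPE = (100, 70)


@dataclass
class MotionBasis:
    """ICA basis over vectorized frame differences.

    ``components`` (k, n_pixels) is the unmixing matrix applied after
    centering by ``mean``; ``mixing`` (n_pixels, k) reconstructs.
    """

    components: np.ndarray
    mixing: np.ndarray
    mean: np.ndarray
    k: int
    frame_shape: tuple
    use_differences: bool = True


@dataclass
class Codebook:
    """K feature-space centroids for vector quantization."""

    centroids: np.ndarray

    @property
    def K(self) -> int:
        return self.centroids.shape[0]


@dataclass
class DiscreteHMM:
    """Discrete-emission HMM parameters (all rows stochastic)."""

    initial: np.ndarray      # (n_states,)
    transitions: np.ndarray  # (n_states, n_states)
    emissions: np.ndarray    # (n_states, n_symbols)

    @property
    def n_states(self) -> int:
        return self.initial.shape[0]

    @property
    def n_symbols(self) -> int:
        return self.emissions.shape[1]


@dataclass
class ActivityModelBank:
    """Label -> HMM map plus the per-frame log-likelihood floor below
    which a sequence is declared ``"Unknown"``."""

    models: dict
    unknown_threshold: float = -np.inf


def resize_silhouette(frame: np.ndarray, shape: tuple = FRAME_SHAPE) -> np.ndarray:
    """Nearest-neighbour resize then re-binarize at 0.5."""
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    rows = np.minimum((np.arange(shape[0]) * h / shape[0]).astype(int), h - 1)
    cols = np.minimum((np.arange(shape[1]) * w / shape[1]).astype(int), w - 1)
    return frame[np.ix_(rows, cols)] >= 0.5


def _as_frame_stack(seq) -> np.ndarray:
    frames = np.asarray(seq, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ContractError("a silhouette sequence needs >= 2 frames of equal shape")
    return frames


def _difference_vectors(frames: np.ndarray, use_differences: bool) -> np.ndarray:
    flat = frames.reshape(frames.shape[0], -1)
    if use_differences:
        return np.diff(flat, axis=0)
    return flat[1:]


def fit_motion_basis(training, k: int = 10, seed=None, use_differences: bool = True) -> MotionBasis:
    """Fit an ICA basis to vectorized consecutive-frame differences.

    ``training`` is an iterable of silhouette sequences (T_i, H, W).
    Deterministic given ``seed``.  Raises :class:`ContractError` when
    fewer than ``k + 1`` difference vectors are available or their rank
    is below ``k`` (e.g. a static video).
    """
    if k < 1:
        raise ContractError("k must be >= 1")
    stacks = [_as_frame_stack(s) for s in training]
    shape = stacks[0].shape[1:]
    for s in stacks:
        if s.shape[1:] != shape:
            raise ContractError("all training frames must share one shape")
    X = np.vstack([_difference_vectors(s, use_differences) for s in stacks])
    if X.shape[0] < k + 1:
        raise ContractError(f"need >= {k + 1} difference vectors, got {X.shape[0]}")
    centered = X - X.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    rank = int(np.sum(sv > max(centered.shape) * np.finfo(float).eps * sv[0])) if sv.size else 0
    if rank < k:
        raise ContractError(f"training differences have rank {rank} < k={k}")
    ica = FastICA(n_components=k, random_state=seed, whiten="unit-variance",
                  max_iter=1000, tol=1e-4)
    ica.fit(X)
    return MotionBasis(
        components=ica.components_.copy(),
        mixing=ica.mixing_.copy(),
        mean=ica.mean_.copy(),
        k=k,
        frame_shape=shape,
        use_differences=use_differences,
    )


def project_features(seq, basis: MotionBasis) -> np.ndarray:
    """Project one sequence onto the motion basis: (T-1, k) features."""
    frames = _as_frame_stack(seq)
    if frames.shape[1:] != tuple(basis.frame_shape):
        raise ContractError(
            f"frame shape {frames.shape[1:]} does not match basis {basis.frame_shape}"
        )
    X = _difference_vectors(frames, basis.use_differences)
    return (X - basis.mean) @ basis.components.T


def reconstruct_features(sources: np.ndarray, basis: MotionBasis) -> np.ndarray:
    """Inverse projection (for variance-accounting diagnostics)."""
    return sources @ basis.mixing.T + basis.mean


def build_codebook(features: np.ndarray, K: int = 16, seed=None) -> Codebook:
    """Seeded k-means codebook over feature vectors."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise ContractError("features must be 2-D (n_vectors, dim)")
    if K < 1:
        raise ContractError("K must be >= 1")
    n_distinct = np.unique(features, axis=0).shape[0]
    if K > n_distinct:
        raise ContractError(f"K={K} exceeds the {n_distinct} distinct feature vectors")
    km = KMeans(n_clusters=K, n_init=10, random_state=seed)
    km.fit(features)
    return Codebook(centroids=km.cluster_centers_.copy())


def quantize(features: np.ndarray, codebook: Codebook) -> np.ndarray:
    """Nearest-centroid symbol per vector; ties break to the lowest index."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != codebook.centroids.shape[1]:
        raise ContractError("feature dimension does not match the codebook")
    d2 = ((features[:, None, :] - codebook.centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def _smooth_rows(mat: np.ndarray, smoothing: float) -> np.ndarray:
    mat = mat + smoothing
    return mat / mat.sum(axis=1, keepdims=True)


def train_hmm(sequences, n_states: int = 4, n_symbols: int | None = None,
              seed=None, n_iter: int = 50, smoothing: float = 1e-3):
    """Baum–Welch fit of an ergodic discrete HMM with additive smoothing.

    Fitting runs one EM iteration at a time so the per-iteration training
    log-likelihood history can be returned (and checked for
    monotonicity).  Returns ``(DiscreteHMM, history)``.
    """
    seqs = [np.asarray(s, dtype=int).ravel() for s in sequences]
    if not seqs or any(s.size == 0 for s in seqs):
        raise ContractError("need at least one non-empty symbol sequence")
    max_sym = max(int(s.max()) for s in seqs)
    if n_symbols is None:
        n_symbols = max_sym + 1
    if max_sym >= n_symbols:
        raise ContractError("symbol outside declared alphabet")
    X = np.concatenate(seqs)[:, None]
    lengths = [len(s) for s in seqs]
    hmm = CategoricalHMM(
        n_components=n_states, n_features=n_symbols, random_state=seed,
        n_iter=1, tol=-np.inf, init_params="ste",
    )
    history = []
    for it in range(n_iter):
        hmm.fit(X, lengths)
        hmm.init_params = ""  # keep learned parameters across iterations
        history.append(float(hmm.monitor_.history[-1]))
        if len(history) >= 2 and abs(history[-1] - history[-2]) < 1e-8:
            break
    model = DiscreteHMM(
        initial=_smooth_rows(hmm.startprob_[None, :], smoothing)[0],
        transitions=_smooth_rows(hmm.transmat_, smoothing),
        emissions=_smooth_rows(hmm.emissionprob_, smoothing),
    )
    return model, history


def forward_loglik(model: DiscreteHMM, symbols) -> float:
    """Forward-algorithm log-likelihood of a symbol sequence."""
    symbols = np.asarray(symbols, dtype=int).ravel()
    if symbols.size == 0:
        raise ContractError("empty symbol sequence")
    if symbols.min() < 0 or symbols.max() >= model.n_symbols:
        raise ContractError("symbol outside alphabet")
    hmm = CategoricalHMM(n_components=model.n_states, n_features=model.n_symbols,
                         init_params="", params="")
    hmm.startprob_ = model.initial
    hmm.transmat_ = model.transitions
    hmm.emissionprob_ = model.emissions
    return float(hmm.score(symbols[:, None]))


def default_unknown_threshold(n_symbols: int) -> float:
    """Fixed per-frame log-likelihood floor: log(1/K) - 2 nats.

    A smoothed ergodic HMM over a shared codebook rarely scores any
    quantized sequence this low, so the fitted classifier calibrates its
    floor from training data instead (see
    :meth:`SilhouetteActivityClassifier.fit`); this fixed rule remains
    for banks assembled by hand.
    """
    return float(np.log(1.0 / n_symbols) - 2.0)


def calibrated_unknown_threshold(bank_models: dict, symbol_seqs, labels,
                                 margin: float = 0.75) -> float:
    """Training-calibrated floor: the worst per-frame log-likelihood any
    training sequence achieves under its own class model, minus
    ``margin`` nats."""
    worst = np.inf
    for seq, lab in zip(symbol_seqs, labels):
        ll = forward_loglik(bank_models[lab], seq) / len(seq)
        worst = min(worst, ll)
    return float(worst - margin)


def classify(symbols, bank: ActivityModelBank):
    """Label a symbol sequence against a bank of per-activity HMMs.

    Returns ``(label, scores)`` with ``scores`` the per-model forward
    log-likelihoods; ``label`` is ``"Unknown"`` when the best per-frame
    log-likelihood is below ``bank.unknown_threshold``.  Ties break to
    the lexicographically smallest label.
    """
    if not bank.models:
        raise ContractError("the model bank is empty")
    symbols = np.asarray(symbols, dtype=int).ravel()
    scores = {lab: forward_loglik(m, symbols) for lab, m in bank.models.items()}
    best = max(sorted(scores), key=lambda lab: scores[lab])
    if scores[best] / symbols.size < bank.unknown_threshold:
        return "Unknown", scores
    return best, scores


class SilhouetteActivityClassifier(BaseEstimator, ClassifierMixin):
    """End-to-end silhouette-video activity classifier.

    ``fit`` learns, from labelled silhouette sequences: a shared ICA
    motion basis, a shared k-means codebook, and one discrete HMM per
    activity label.  ``predict`` quantizes each test sequence and
    returns the label of the best-scoring HMM (or ``"Unknown"``).

    Parameters
    ----------
    ica_k : int               — number of ICA motion components
    codebook_size : int       — vector-quantization alphabet size K
    n_states : int            — hidden states per activity HMM
    unknown_threshold : float or None
        Per-frame log-likelihood floor; None uses ``log(1/K) - 2``.
    smoothing : float         — additive smoothing on HMM rows
    use_differences : bool    — ICA on frame differences (default) or raw frames
    random_state : int or None
    """

    def __init__(self, ica_k=10, codebook_size=16, n_states=4,
                 unknown_threshold=None, smoothing=1e-3, n_iter=50,
                 use_differences=True, random_state=None):
        self.ica_k = ica_k
        self.codebook_size = codebook_size
        self.n_states = n_states
        self.unknown_threshold = unknown_threshold
        self.smoothing = smoothing
        self.n_iter = n_iter
        self.use_differences = use_differences
        self.random_state = random_state

    def fit(self, X, y):
        if len(X) != len(y) or not X:
            raise ContractError("need matching non-empty sequences and labels")
        X = [np.asarray(s) for s in X]
        self.basis_ = fit_motion_basis(X, k=self.ica_k, seed=self.random_state,
                                       use_differences=self.use_differences)
        feats = [project_features(s, self.basis_) for s in X]
        self.codebook_ = build_codebook(np.vstack(feats), K=self.codebook_size,
                                        seed=self.random_state)
        symbol_seqs = [quantize(f, self.codebook_) for f in feats]
        labels = sorted(set(y))
        models = {}
        self.em_histories_ = {}
        for lab in labels:
            seqs = [s for s, lab_i in zip(symbol_seqs, y) if lab_i == lab]
            models[lab], self.em_histories_[lab] = train_hmm(
                seqs, n_states=self.n_states, n_symbols=self.codebook_.K,
                seed=self.random_state, n_iter=self.n_iter, smoothing=self.smoothing,
            )
        threshold = (
            calibrated_unknown_threshold(models, symbol_seqs, y)
            if self.unknown_threshold is None
            else self.unknown_threshold
        )
        self.bank_ = ActivityModelBank(models=models, unknown_threshold=threshold)
        self.classes_ = np.asarray(labels)
        return self

    def _symbols(self, seq) -> np.ndarray:
        return quantize(project_features(np.asarray(seq), self.basis_), self.codebook_)

    def predict(self, X):
        return np.asarray([classify(self._symbols(s), self.bank_)[0] for s in X],
                          dtype=object)

    def score_sequences(self, X):
        """Per-model forward log-likelihoods for each sequence."""
        return [classify(self._symbols(s), self.bank_)[1] for s in X]
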