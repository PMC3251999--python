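import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from actikit.motion import SilhouetteActivityClassifier
from actikit.semicrf import SemiMarkovCRF, encode_segments
from actikit.synthetic import NULL_LABEL, make_sensor_corpus, make_silhouette_video

VIDEO_KINDS = ["wave", "jump", "bend"]


@pytest.fixture(scope="session")
def silhouette_corpus():
    """Labelled train/test silhouette videos for three separable activities."""
    X_train, y_train, X_test, y_test = [], [], [], []
    for j, kind in enumerate(VIDEO_KINDS):
        for i in range(8):
            X_train.append(make_silhouette_video(kind, n_frames=20, seed=1000 + 37 * i + j))
            y_train.append(kind)
        for i in range(6):
            X_test.append(make_silhouette_video(kind, n_frames=20, seed=5000 + 11 * i + j))
            y_test.append(kind)
    return X_train, y_train, X_test, y_test


@pytest.fixture(scope="session")
def trained_classifier(silhouette_corpus):
    X_train, y_train, _, _ = silhouette_corpus
    return SilhouetteActivityClassifier(random_state=0).fit(X_train, y_train)


@pytest.fixture(scope="session")
def sensor_split():
    """Train/test split of the synthetic wearable-sensor corpus."""
    corpus = make_sensor_corpus(M=3, alphabet=8, emission_sharpness=0.9,
                                null_rate=0.3, T=120, n_seqs=24, seed=42)
    train, test = corpus[:16], corpus[16:]
    return train, test


@pytest.fixture(scope="session")
def trained_crf(sensor_split):
    train, _ = sensor_split
    crf = SemiMarkovCRF(max_duration=32, l2=0.1, max_iter=30,
                        null_labels=(NULL_LABEL,), random_state=0)
    crf.fit([s for s, _ in train], [l for _, l in train])
    return crf


def truth_segments(test_seqs):
    return [encode_segments(labels, {NULL_LABEL}) for _, labels in test_seqs]
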