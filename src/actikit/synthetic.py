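"""Seeded synthetic fixtures for every pipeline stage.

Each generator emulates the statistical structure its consumer assumes —
inhomogeneous bimodal bodies on noisy backgrounds for the segmenter,
class-specific periodic silhouette deformations for the video
classifier, label-segmented symbol streams with Gaussian durations and
interleaved null activities for the semi-Markov CRF, and scripted event
streams with ground-truth decisions for the rule engine.  Identical
parameters and seed reproduce byte-identical output, and ground truth
always accompanies the data.
"""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np

from .errors import ContractError
from .rules import ActivityEvent, Decision
from .semicrf.segments import SemiSegment, encode_segments

__all__ = [
    "make_body_image",
    "make_silhouette_video",
    "SILHOUETTE_KINDS",
    "make_sensor_corpus",
    "make_event_log",
    "default_scenario",
    "NULL_LABEL",
]


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------


def make_body_image(w: int = 64, h: int = 64, fg_intensities=(0.3, 0.8),
                    bg_intensity: float = 0.05, noise_sigma: float = 0.02,
                    seed=None, area_frac: float = 0.25):
    """Inhomogeneous body-shaped blob on a noisy background.

    The blob is a torso ellipse with a head circle; its upper part takes
    ``fg_intensities[0]`` and its lower part ``fg_intensities[1]``, so
    the foreground is bimodal (the regime where pure within-region
    variance minimization fails).  Returns ``(image, truth_mask)``.
    """
    if w < 8 or h < 8:
        raise ContractError("image must be at least 8x8")
    f1, f2 = fg_intensities
    if abs(f1 - bg_intensity) < 0.05 or abs(f2 - bg_intensity) < 0.05:
        raise ContractError("foreground intensities must be distinct from background")
    if not 0.05 <= area_frac <= 0.6:
        raise ContractError("area_frac must be in [0.05, 0.6]")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    target = area_frac * w * h
    # torso ellipse (85% of target) + head circle (15%), head tangent on top
    aspect = 1.6  # vertical elongation
    b_ax = np.sqrt(0.85 * target / (np.pi * aspect))
    a_ax = aspect * b_ax
    head_r = np.sqrt(0.15 * target / np.pi)
    cy, cx = h * 0.55, w * 0.5
    torso = ((yy - cy) / a_ax) ** 2 + ((xx - cx) / b_ax) ** 2 <= 1.0
    head_cy = cy - a_ax - head_r * 0.6
    head = (yy - head_cy) ** 2 + (xx - cx) ** 2 <= head_r**2
    mask = torso | head
    image = np.full((h, w), float(bg_intensity))
    upper = mask & (yy < cy)
    lower = mask & ~upper
    image[upper] = f1
    image[lower] = f2
    if noise_sigma > 0:
        image = image + rng.normal(0.0, noise_sigma, size=image.shape)
    return np.clip(image, 0.0, 1.0), mask


# ---------------------------------------------------------------------------
# Silhouette videos
# ---------------------------------------------------------------------------

SILHOUETTE_KINDS = ("wave", "jump", "bend", "stretch", "static", "noise")


def _draw_body(shape, cy, cx, torso_a, torso_b, tilt=0.0, arm_angle=None):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    y0, x0 = yy - cy, xx - cx
    if tilt:
        c, s = np.cos(tilt), np.sin(tilt)
        y0, x0 = c * y0 - s * x0, s * y0 + c * x0
    torso = (y0 / torso_a) ** 2 + (x0 / torso_b) ** 2 <= 1.0
    head_r = 0.45 * torso_b
    head = (y0 + torso_a + head_r * 0.7) ** 2 + x0**2 <= head_r**2
    frame = torso | head
    if arm_angle is not None:
        # a straight arm of length ~ torso_a from the shoulder
        sy, sx = -0.55 * torso_a, 0.0
        ay, ax = y0 - sy, x0 - sx
        along = ax * np.cos(arm_angle) + ay * np.sin(arm_angle)
        perp = -ax * np.sin(arm_angle) + ay * np.cos(arm_angle)
        arm = (along >= 0) & (along <= 1.1 * torso_a) & (np.abs(perp) <= 0.18 * torso_b + 1.0)
        frame |= arm
    return frame


def make_silhouette_video(activity_kind: str, n_frames: int = 20, seed=None,
                          shape=(100, 70)):
    """Binary silhouette sequence with a class-specific periodic motion.

    Kinds: ``wave`` (oscillating raised arm), ``jump`` (vertical body
    oscillation), ``bend`` (torso tilt oscillation), ``stretch``
    (width oscillation), ``static`` (identical frames), ``noise``
    (incoherent junk motion, for unknown-activity tests).  Phase and
    small frequency jitter are drawn per sequence from ``seed``.
    """
    if activity_kind not in SILHOUETTE_KINDS:
        raise ContractError(f"unknown activity kind {activity_kind!r}")
    if n_frames < 2:
        raise ContractError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    h, w = shape
    cy, cx = h * 0.55, w * 0.5
    torso_a, torso_b = 0.28 * h, 0.14 * w
    phase = rng.uniform(0, 2 * np.pi)
    freq = (2 * np.pi / 8.0) * rng.uniform(0.9, 1.1)
    frames = np.zeros((n_frames, h, w), dtype=bool)
    for t in range(n_frames):
        ph = phase + freq * t
        if activity_kind == "static":
            frames[t] = _draw_body(shape, cy, cx, torso_a, torso_b,
                                   arm_angle=-np.pi / 2)
        elif activity_kind == "wave":
            ang = -np.pi / 2 + 0.9 * np.sin(ph)  # arm sweeps overhead
            frames[t] = _draw_body(shape, cy, cx, torso_a, torso_b, arm_angle=ang)
        elif activity_kind == "jump":
            dy = 0.12 * h * np.sin(ph)
            frames[t] = _draw_body(shape, cy + dy, cx, torso_a, torso_b)
        elif activity_kind == "bend":
            tilt = 0.5 * np.sin(ph)
            frames[t] = _draw_body(shape, cy, cx, torso_a, torso_b, tilt=tilt)
        elif activity_kind == "stretch":
            scale = 1.0 + 0.45 * np.sin(ph)
            frames[t] = _draw_body(shape, cy, cx, torso_a, torso_b * scale)
        elif activity_kind == "noise":
            # incoherent junk motion: several ellipses at fresh random poses
            yy, xx = np.mgrid[0:h, 0:w]
            junk = np.zeros((h, w), dtype=bool)
            for _ in range(int(rng.integers(3, 7))):
                ncy, ncx = rng.uniform(0.1 * h, 0.9 * h), rng.uniform(0.1 * w, 0.9 * w)
                na, nb = rng.uniform(0.05 * h, 0.25 * h), rng.uniform(0.05 * w, 0.25 * w)
                junk |= ((yy - ncy) / na) ** 2 + ((xx - ncx) / nb) ** 2 <= 1.0
            frames[t] = junk
    return frames


# ---------------------------------------------------------------------------
# Sensor corpora
# ---------------------------------------------------------------------------

#: Per-time label used for null (not-to-be-recognized) stretches.
NULL_LABEL = -1


def make_sensor_corpus(M: int = 3, alphabet: int = 8, emission_sharpness: float = 0.9,
                       duration_means=None, duration_sds=None, null_rate: float = 0.3,
                       T: int = 120, n_seqs: int = 20, seed=None):
    """Labelled symbol sequences with Gaussian segment durations and
    interleaved null activities.

    Each sequence alternates activity segments (label ``0..M-1``,
    duration ``~ round(N(m_y, s_y))`` clipped to ``>= 1``) with null
    stretches inserted at probability ``null_rate`` (label
    :data:`NULL_LABEL`).  Label ``y`` emits its preferred symbol ``y``
    with probability ``emission_sharpness`` (remainder uniform over the
    other symbols); null stretches prefer symbol ``M`` the same way.

    Returns a list of ``(symbols, labels)`` arrays of length ``T``.
    """
    if M < 2:
        raise ContractError("need M >= 2 activity labels")
    if alphabet < M + 1:
        raise ContractError("alphabet must exceed the label count (nulls need a symbol)")
    if not 0.0 <= null_rate <= 1.0:
        raise ContractError("null_rate must be in [0, 1]")
    if not 0.0 < emission_sharpness <= 1.0:
        raise ContractError("emission_sharpness must be in (0, 1]")
    if duration_means is None:
        duration_means = np.linspace(6.0, 12.0, M)
    if duration_sds is None:
        duration_sds = np.full(M, 1.5)
    duration_means = np.asarray(duration_means, dtype=float)
    duration_sds = np.asarray(duration_sds, dtype=float)
    rng = np.random.default_rng(seed)

    def emit(pref: int, n: int) -> np.ndarray:
        p = np.full(alphabet, (1.0 - emission_sharpness) / (alphabet - 1))
        p[pref] = emission_sharpness
        return rng.choice(alphabet, size=n, p=p)

    corpus = []
    for _ in range(n_seqs):
        symbols = np.empty(T, dtype=int)
        labels = np.empty(T, dtype=int)
        t = 0
        prev_y = None
        while t < T:
            if rng.random() < null_rate:
                d = int(np.clip(np.rint(rng.normal(4.0, 1.0)), 1, T - t))
                symbols[t : t + d] = emit(M, d)
                labels[t : t + d] = NULL_LABEL
                prev_y = None
            else:
                # never repeat the previous activity: adjacent same-label
                # runs would silently merge into one long segment
                choices = [y for y in range(M) if y != prev_y]
                y = int(rng.choice(choices))
                prev_y = y
                d = int(np.clip(np.rint(rng.normal(duration_means[y], duration_sds[y])),
                                1, T - t))
                symbols[t : t + d] = emit(y, d)
                labels[t : t + d] = y
            t += d
        corpus.append((symbols, labels))
    return corpus


# ---------------------------------------------------------------------------
# Event logs
# ---------------------------------------------------------------------------


def default_scenario():
    """The morning-routine script: enter kitchen, sit, watch TV, eat
    (without having taken medicine), then read — with the decision list
    the rules must produce (lights on, medicine reminder, TV off)."""
    return [
        {"offset_min": 0, "name": "Entering Kitchen", "type": "Motion", "location": "kitchen"},
        {"offset_min": 2, "name": "Sitting", "type": "Posture", "location": "kitchen"},
        {"offset_min": 5, "name": "Watching TV", "type": "Posture", "location": "kitchen"},
        {"offset_min": 10, "name": "Eating", "type": "Gesture", "location": "kitchen"},
        {"offset_min": 30, "name": "Reading", "type": "Gesture", "location": "bedroom"},
        {"expect": {"kind": "device_command", "payload": "turnOn(lights:kitchen)",
                    "offset_min": 0}},
        {"expect": {"kind": "reminder", "payload": "take medicine", "offset_min": 10}},
        {"expect": {"kind": "device_command", "payload": "turnOff(TV)", "offset_min": 30}},
    ]


def make_event_log(scenario_script, seed=None, person: str = "patient-1",
                   start: datetime | None = None):
    """Turn a script into ``(events, expected_decisions)``.

    Script entries are dicts with ``offset_min`` and ``name`` (plus
    optional ``type``/``location``/``person``), or ``{"expect": ...}``
    entries declaring a ground-truth decision; expected decisions come
    from the script itself, independent of the rule engine.
    """
    start = start or datetime(2026, 3, 2, 7, 0, 0)
    events, expected = [], []
    counter = 0
    for entry in scenario_script:
        if not isinstance(entry, dict):
            raise ContractError("script entries must be dicts")
        if "expect" in entry:
            ex = entry["expect"]
            expected.append(Decision(
                kind=ex["kind"], payload=ex["payload"],
                triggers=tuple(ex.get("triggers", ())),
                time=start + timedelta(minutes=float(ex["offset_min"])),
            ))
            continue
        if "name" not in entry or "offset_min" not in entry:
            raise ContractError("event entries need 'name' and 'offset_min'")
        counter += 1
        events.append(ActivityEvent(
            id=f"ev-{counter:04d}",
            name=entry["name"],
            type=entry.get("type", "Motion"),
            time=start + timedelta(minutes=float(entry["offset_min"])),
            person=entry.get("person", person),
            location=entry.get("location", ""),
        ))
    events.sort(key=lambda e: e.time)
    expected.sort(key=lambda d: d.time)
    return events, expected
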