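# actikit

Building blocks for sensor-based human activity recognition in
smart-home health monitoring: body segmentation from video frames,
silhouette-sequence activity classification, wearable-sensor sequence
labelling with a null-activity-aware semi-Markov CRF, and an executable
rule engine that turns recognized low-level activities into high-level
activities, reminders and device commands.

The intended users are researchers and engineers prototyping
activities-of-daily-living (ADL) monitoring pipelines — e.g. for elder
care — who need each recognition stage as a tested, seedable component
with synthetic data generators standing in for cameras, wearables and
event streams.

## The models

**Bhattacharyya-augmented Chan–Vese segmentation.** The classic
Chan–Vese active contour minimizes the within-region variance
F(C) = ∫_in |I − c_in|² + ∫_out |I − c_out|², which fails on
inhomogeneous foregrounds such as a clothed human body. The energy here
adds a separation term, the Bhattacharyya coefficient
B = Σ_z √(p_in(z) p_out(z)) of the inside/outside intensity
distributions, scaled by the image area |Ω| so the two terms are
commensurate:

    E(C) = γ·Perimeter + η·Area_in + β·F(C) + (1−β)·B(C)·|Ω|,  β ∈ [0,1].

Minimizing E both homogenizes each region (F) and pushes the two
intensity distributions apart (B); β = 1 recovers pure Chan–Vese. The
curve is evolved as a level set φ (inside = {φ < 0}) by monotone
backtracking gradient flow.

**Silhouette HMM classifier.** Segmented silhouettes (resized to
100×70) are turned into motion features by ICA on consecutive-frame
difference images, vector-quantized against a shared k-means codebook,
and scored by one discrete HMM per activity (Baum–Welch training,
forward-algorithm likelihood). A sequence whose best per-frame
log-likelihood falls below a training-calibrated floor is labelled
`"Unknown"`.

**Null-activity-aware semi-Markov CRF.** A wearable-sensor symbol
sequence x₁..x_T is labelled with *segments* s_i = (y_i, b_i, e_i). Null
activities (present in the data, not targeted for recognition) are
eliminated, so consecutive segments satisfy b_{i+1} > e_i and the gaps
carry inactivity (IA) observation weights. Each segment transition is
scored by

    Q_tr = w_tr(y', y),
    Q_d  = w_d(y)·(d − m_y)² / (2σ_y²),      d = e − b + 1,
    Q_o  = Σ_{t=b..e} w_o(y, x_t) + Σ_{t∈gap} w_o(IA, x_t),

with P(S|X) = exp(Σ_i Q_tr+Q_d+Q_o) / Z_X. The partition function,
exact gradients (observed minus expected feature counts) and the
maximum-probability segmentation are computed by forward–backward and
Viterbi recursions over (end time, label, duration) whose work grows as
O(T·M·(M+D)) — instrumented operation counters document the >10×
saving over the O(T·M²·D)-per-parameter reference recursion. Windowed
features for raw signals (mean, standard deviation, mean-crossing rate
per axis; 512-sample windows, 50 % overlap) are included.

**Rule engine.** Events outside the 18-activity catalog are diverted to
an unknown log (never dropped); the remaining stream passes through
five rules (exercise sessions, medicine reminders, TV-off on reading,
wrong-movement alerts, lights-on when entering rooms) gated by a
per-day knowledge base, plus a greedy match-making precision/recall
harness for comparing predicted and ground-truth event streams.

## Worked example

```python
import numpy as np
from actikit import BhattacharyyaChanVese
from actikit.semicrf import SemiMarkovCRF, encode_segments, segment_f1
from actikit.synthetic import NULL_LABEL, make_body_image, make_sensor_corpus

# 1. segment an inhomogeneous body image (two foreground intensities)
img, truth = make_body_image(seed=7)
full = BhattacharyyaChanVese().fit(img)          # beta = 0.5 default
cv   = BhattacharyyaChanVese(beta=1.0).fit(img)  # pure Chan-Vese
iou = lambda a, b: (a & b).sum() / (a | b).sum()
print(f"full model IoU  = {iou(full.mask_, truth):.3f}")
print(f"beta=1 (CV) IoU = {iou(cv.mask_, truth):.3f}")

# 2. null-activity elimination
print(encode_segments(["eating", "eating", "cleaning", "cleaning",
                       "having tea", "having tea"], null_labels={"cleaning"}))

# 3. train and evaluate the semi-Markov CRF on a synthetic wearable corpus
corpus = make_sensor_corpus(M=3, alphabet=8, emission_sharpness=0.9,
                            null_rate=0.3, T=120, n_seqs=24, seed=42)
train, test = corpus[:16], corpus[16:]
crf = SemiMarkovCRF(max_duration=32, l2=0.1, max_iter=30,
                    null_labels=(NULL_LABEL,))
crf.fit([x for x, _ in train], [labels for _, labels in train])
pred = crf.predict_segments([x for x, _ in test])
truth_segs = [encode_segments(labels, {NULL_LABEL}) for _, labels in test]
print(f"held-out segment F1 = {segment_f1(pred, truth_segs):.3f}")
```

prints

```
full model IoU  = 0.999
beta=1 (CV) IoU = 0.772
[SemiSegment(y='eating', b=1, e=2), SemiSegment(y='having tea', b=5, e=6)]
held-out segment F1 = 0.957
```

The first two lines show the separation term rescuing the segmentation
where within-region variance alone splits the body (β = 1 captures only
one of the two clothing intensities). The encoding shows the cleaning
run eliminated into a gap (the next segment begins at 5 > 2 + 1). The
last line is segment-level F1 (greedy one-to-one matching of same-label
segments at interval-IoU ≥ 0.5) of the decoded against the generating
segmentation on held-out sequences.

A command-line interface mirrors the library:
`actikit segment|hmm-train|hmm-classify|scrf-train|scrf-infer|scrf-gradcheck|rules-run|synth-*|eval`
(all subcommands take `--seed`; see `actikit --help`).

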