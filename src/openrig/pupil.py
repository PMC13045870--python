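"""Two-stage pupillometry: open/occluded classification, then segmentation.

Stage 1 classifies each eye frame as *open* or *occluded* (lids closed).
Stage 2 segments the pupil in open frames with a circular-Hough
accumulator over the binarized dark region, refining the radius from
the mean distance of mask-boundary pixels to the detected center.
Radii are normalized to the session median.  Frames classified as open
in which no circle is found are flagged *ambiguous* for user review; a
user-supplied seed point (a click near the pupil center) drives a
constrained local re-segmentation.

The classifier is a deliberately lightweight, pluggable feature-based
model (intensity statistics, dark-pixel fraction, spatial contrast ->
regularized logistic decision rule): downstream stages only need a
binary label with a confidence, and the model trains in milliseconds on
the 70 + 70 frame regime used for the deep-learning stage it stands in
for.  Trained parameters persist as JSON, so predictions are pure
functions of (frame, model).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Any, Sequence

import numpy as np
from scipy.ndimage import binary_erosion, uniform_filter
from skimage.transform import hough_circle, hough_circle_peaks

FEATURE_VERSION = "v1"


@dataclass
class PupilConfig:
    """Segmentation parameters (pixel units, uint8 intensities)."""

    min_radius_px: int = 5
    max_radius_px: int = 25
    dark_threshold: float = 90.0
    sensitivity: float = 0.4  # minimum normalized Hough accumulator value
    min_mask_fill: float = 0.4  # minimum dark area as a fraction of a min-radius disk
    seed_search_px: int = 3
    seed_min_contrast: float = 25.0


@dataclass
class FrameResult:
    frame: int
    label: str  # "open" | "occluded"
    confidence: float
    segmentation: tuple[float, float, float] | None = None  # (cx, cy, r)
    status: str = "no_pupil"  # segmented | no_pupil | occluded | ambiguous | manually_seeded
    normalized_radius: float | None = None


# ---------------------------------------------------------------------------
# stage 1: open/occluded classifier
# ---------------------------------------------------------------------------

def frame_features(frame: np.ndarray) -> np.ndarray:
    """Feature vector for the open/occluded decision rule."""
    img = np.asarray(frame, dtype=float)
    dark = float(np.mean(img < 90.0))
    p10, p50, p90 = np.percentile(img, [10, 50, 90])
    h = img.shape[0]
    top_bottom = float(img[: h // 2].mean() - img[h // 2 :].mean())
    smooth_min = float(uniform_filter(img, size=5).min())
    return np.array([img.mean(), img.std(), dark, p10, p50, p90, top_bottom, smooth_min])


@dataclass
class ClassifierModel:
    """Persisted linear decision rule: standardized features -> logit."""

    feature_version: str
    scaler_mean: list[float]
    scaler_scale: list[float]
    coef: list[float]
    intercept: float
    classes: list[str]
    training: dict[str, Any] = field(default_factory=dict)

    def predict(self, frame: np.ndarray) -> tuple[str, float]:
        x = (frame_features(frame) - np.array(self.scaler_mean)) / np.array(self.scaler_scale)
        logit = float(np.dot(x, self.coef) + self.intercept)
        p1 = 1.0 / (1.0 + np.exp(-logit))
        label = self.classes[1] if p1 >= 0.5 else self.classes[0]
        confidence = max(p1, 1.0 - p1)
        return label, confidence


def train_classifier(
    frames: Sequence[np.ndarray], labels: Sequence[str], seed: int = 0
) -> ClassifierModel:
    """Fit the open/occluded decision rule; deterministic given ``seed``.

    Requires at least two examples per class.  The default regime
    mirrors a 70/70 train + 15/15 validation split on synthetic frames.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.preprocessing import StandardScaler

    labels = list(labels)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("training set must contain both classes")
    for c in classes:
        if labels.count(c) < 2:
            raise ValueError(f"need at least 2 examples of class {c!r}")
    X = np.array([frame_features(f) for f in frames])
    scaler = StandardScaler()
    scale_ok = X.std(axis=0) > 0
    Xs = np.where(scale_ok, X, 0.0)
    scaler.fit(Xs)
    scaler.scale_[scaler.scale_ == 0] = 1.0
    Z = scaler.transform(Xs)
    y = np.array([classes.index(l) for l in labels])
    clf = LogisticRegression(C=1.0, random_state=seed, max_iter=2000)
    clf.fit(Z, y)
    return ClassifierModel(
        feature_version=FEATURE_VERSION,
        scaler_mean=scaler.mean_.tolist(),
        scaler_scale=scaler.scale_.tolist(),
        coef=clf.coef_[0].tolist(),
        intercept=float(clf.intercept_[0]),
        classes=classes,
        training={"n_per_class": {c: labels.count(c) for c in classes}, "seed": seed},
    )


def classify_frame(frame: np.ndarray, model: ClassifierModel) -> tuple[str, float]:
    """Label one frame; total over frames of the configured size."""
    return model.predict(frame)


def save_model(model: ClassifierModel, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(model), fh, indent=1)


def load_model(path: str | os.PathLike) -> ClassifierModel:
    with open(path) as fh:
        return ClassifierModel(**json.load(fh))


# ---------------------------------------------------------------------------
# stage 2: segmentation
# ---------------------------------------------------------------------------

def segment_pupil(
    frame: np.ndarray, config: PupilConfig | None = None
) -> tuple[float, float, float] | None:
    """Detect the darkest circular region within the radius bounds.

    Returns ``(cx, cy, r)`` in pixels, or None when no sufficiently
    circular dark region exists (a valid result, not an error).
    """
    config = config or PupilConfig()
    img = np.asarray(frame, dtype=float)
    mask = img < config.dark_threshold
    min_area = np.pi * config.min_radius_px**2 * config.min_mask_fill
    if mask.sum() < min_area:
        return None
    edges = mask & ~binary_erosion(mask)
    radii = np.arange(config.min_radius_px, config.max_radius_px + 1)
    accum = hough_circle(edges, radii, normalize=True)
    accums, cxs, cys, rs = hough_circle_peaks(accum, radii, total_num_peaks=1)
    if len(accums) == 0 or accums[0] < config.sensitivity:
        return None
    cx, cy = float(cxs[0]), float(cys[0])
    # sub-pixel radius: mean distance of boundary pixels from the center
    ey, ex = np.nonzero(edges)
    d = np.hypot(ex - cx, ey - cy)
    near = d[(d >= config.min_radius_px - 1.5) & (d <= config.max_radius_px + 1.5)]
    r = float(near.mean()) if near.size else float(rs[0])
    return (cx, cy, r)


def seeded_segment(
    frame: np.ndarray, click: tuple[float, float], config: PupilConfig | None = None
) -> tuple[tuple[float, float, float], bool]:
    """Circle fit constrained near a user seed point.

    Scans centers within a small window around the click and radii
    within the configured bounds, maximizing the inside/outside
    intensity contrast.  Always returns a circle, plus a low-confidence
    flag when the best contrast is below threshold (e.g. the seed lies
    in flat background).
    """
    config = config or PupilConfig()
    img = np.asarray(frame, dtype=float)
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    best = (-np.inf, (float(click[0]), float(click[1]), float(config.min_radius_px)))
    s = config.seed_search_px
    for cy in np.arange(click[1] - s, click[1] + s + 1):
        for cx in np.arange(click[0] - s, click[0] + s + 1):
            d = np.hypot(xx - cx, yy - cy)
            for r in np.arange(config.min_radius_px, config.max_radius_px + 0.5, 0.5):
                inside = img[d <= r]
                ring = img[(d > r + 1) & (d <= r + 4)]
                if inside.size == 0 or ring.size == 0:
                    continue
                contrast = float(ring.mean() - inside.mean())
                if contrast > best[0]:
                    best = (contrast, (float(cx), float(cy), float(r)))
    contrast, circle = best
    return circle, contrast < config.seed_min_contrast


# ---------------------------------------------------------------------------
# session-level pipeline
# ---------------------------------------------------------------------------

def process_frames(
    frames: Sequence[np.ndarray],
    model: ClassifierModel,
    config: PupilConfig | None = None,
    seeds: dict[int, tuple[float, float]] | None = None,
) -> list[FrameResult]:
    """Classify then segment every frame of a session.

    ``seeds`` maps frame number to a user click for re-segmenting
    ambiguous frames.  Segmentation is present iff status is
    ``segmented`` or ``manually_seeded``.
    """
    config = config or PupilConfig()
    seeds = seeds or {}
    results: list[FrameResult] = []
    for i, frame in enumerate(frames):
        label, conf = classify_frame(frame, model)
        if label == "occluded":
            results.append(FrameResult(i, label, conf, None, "occluded"))
            continue
        seg = segment_pupil(frame, config)
        if seg is not None:
            results.append(FrameResult(i, label, conf, seg, "segmented"))
            continue
        if i in seeds:
            circle, low_conf = seeded_segment(frame, seeds[i], config)
            if not low_conf:
                results.append(FrameResult(i, label, conf, circle, "manually_seeded"))
                continue
        results.append(FrameResult(i, label, conf, None, "ambiguous"))
    return results


def normalize_radii(results: Sequence[FrameResult]) -> list[FrameResult]:
    """Divide each segmented radius by the session median radius.

    Frames without a segmentation carry no normalized value.  Returns
    the same result objects with ``normalized_radius`` filled in.
    """
    radii = [r.segmentation[2] for r in results if r.segmentation is not None]
    if radii:
        med = float(np.median(radii))
        for r in results:
            r.normalized_radius = r.segmentation[2] / med if r.segmentation is not None else None
    return list(results)


def flag_ambiguous(results: Sequence[FrameResult]) -> list[FrameResult]:
    """Open-labelled frames with no circle, ordered by frame number."""
    return sorted(
        (r for r in results if r.label == "open" and r.segmentation is None),
        key=lambda r: r.frame,
    )
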