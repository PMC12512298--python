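"""Dominant-color extraction and green/brown labeling of masked segments.

Each segmented organism is reduced to a single RGB value — the centroid of
the largest k-means cluster of its masked pixels — which is then labeled
``green``, ``brown`` or ``unclear`` by a fixed channel-threshold rule and
summarised chromatically by the greenness fraction G/(R+G+B).  A Chebyshev
ring just outside the mask supplies the immediate visual background for
crypsis comparisons.

Color math operates on raw 8-bit RGB; no white-balance or color-constancy
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numba
import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from anolechroma.errors import DegenerateInputError, InvalidInputError

__all__ = [
    "RGBTriple",
    "SegmentSample",
    "DominantColorResult",
    "SegmentColorOutcome",
    "classify_color",
    "greenness_index",
    "quantize_dominant_color",
    "background_ring",
    "process_segment",
    "extract_colors",
    "load_segment",
]

#: strict-inequality margins of the threshold rule: green iff G > R + 2,
#: brown iff R > G + 5.
GREEN_MARGIN = 2
BROWN_MARGIN = 5

_STRUCT_3X3 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class RGBTriple:
    """One color as three 8-bit channel intensities."""

    r: int
    g: int
    b: int

    def __post_init__(self) -> None:
        for name, v in (("r", self.r), ("g", self.g), ("b", self.b)):
            if not (0 <= int(v) <= 255):
                raise InvalidInputError(f"channel {name}={v} outside [0, 255]")

    def as_tuple(self) -> tuple[int, int, int]:
        return (int(self.r), int(self.g), int(self.b))


def _coerce_rgb(color) -> tuple[int, int, int]:
    if isinstance(color, RGBTriple):
        return color.as_tuple()
    seq = tuple(int(c) for c in color)
    if len(seq) != 3:
        raise InvalidInputError(f"expected 3 channels, got {len(seq)}")
    if any(c < 0 or c > 255 for c in seq):
        raise InvalidInputError(f"channel values {seq} outside [0, 255]")
    return seq


@dataclass
class SegmentSample:
    """An image, its binary organism mask, and optional planted truth."""

    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) bool, True = organism pixel
    id: str = ""
    planted_color: tuple[int, int, int] | None = None
    planted_label: str | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise InvalidInputError(f"segment {self.id}: image must be HxWx3")
        if self.mask.shape != self.image.shape[:2]:
            raise InvalidInputError(f"segment {self.id}: mask/image shape mismatch")
        if not self.mask.any():
            raise InvalidInputError(f"segment {self.id}: mask has no foreground pixel")


@dataclass(frozen=True)
class DominantColorResult:
    """Dominant color of a pixel set plus its label and greenness index."""

    color: RGBTriple
    proportion: float
    label: str
    greenness: float


@dataclass(frozen=True)
class SegmentColorOutcome:
    """Per-segment color results for organism and background ring."""

    id: str
    anole: DominantColorResult
    background: DominantColorResult
    excluded: bool  # True when the organism label is 'unclear'


def classify_color(color) -> str:
    """Label a color ``green``, ``brown`` or ``unclear``.

    Green iff G > R + 2; brown iff R > G + 5; otherwise unclear.  Both
    inequalities are strict and cannot hold simultaneously.
    """
    r, g, _b = _coerce_rgb(color)
    if g > r + GREEN_MARGIN:
        return "green"
    if r > g + BROWN_MARGIN:
        return "brown"
    return "unclear"


def greenness_index(color) -> float:
    """Greenness fraction G/(R+G+B) in [0, 1].

    Raises
    ------
    DegenerateInputError
        For (0, 0, 0), whose index is undefined.
    """
    r, g, b = _coerce_rgb(color)
    total = r + g + b
    if total == 0:
        raise DegenerateInputError("greenness undefined for (0, 0, 0)")
    return g / total


def _round_centroid(center: np.ndarray) -> RGBTriple:
    c = np.clip(np.rint(center), 0, 255).astype(int)
    return RGBTriple(int(c[0]), int(c[1]), int(c[2]))


def _kmeans_pp_init(px: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: D^2-weighted sampling of initial centers."""
    n = px.shape[0]
    centers = np.empty((k, px.shape[1]))
    centers[0] = px[rng.integers(n)]
    d2 = ((px - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:  # all points coincide with chosen centers
            centers[j:] = px[rng.integers(n, size=k - j)]
            break
        centers[j] = px[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((px - centers[j]) ** 2).sum(axis=1))
    return centers


@numba.njit(cache=True)
def _lloyd(px, centers, max_iter, tol):  # pragma: no cover - jitted
    """One Lloyd run; mutates ``centers``, returns (labels, inertia)."""
    n, d = px.shape
    k = centers.shape[0]
    labels = np.zeros(n, dtype=np.int64)
    dist_own = np.zeros(n)
    for _it in range(max_iter):
        for i in range(n):
            best = 0
            best_d = np.inf
            for j in range(k):
                dist = 0.0
                for c in range(d):
                    diff = px[i, c] - centers[j, c]
                    dist += diff * diff
                if dist < best_d:
                    best_d = dist
                    best = j
            labels[i] = best
            dist_own[i] = best_d
        counts = np.zeros(k, dtype=np.int64)
        sums = np.zeros((k, d))
        for i in range(n):
            counts[labels[i]] += 1
            for c in range(d):
                sums[labels[i], c] += px[i, c]
        shift = 0.0
        for j in range(k):
            if counts[j] == 0:  # re-seed an empty cluster at the farthest point
                far = int(np.argmax(dist_own))
                for c in range(d):
                    sums[j, c] = px[far, c]
                counts[j] = 1
                dist_own[far] = 0.0
            sh = 0.0
            for c in range(d):
                new_c = sums[j, c] / counts[j]
                diff = new_c - centers[j, c]
                sh += diff * diff
                centers[j, c] = new_c
            if sh > shift:
                shift = sh
        if shift < tol:
            break
    inertia = 0.0
    for i in range(n):
        for c in range(d):
            diff = px[i, c] - centers[labels[i], c]
            inertia += diff * diff
    return labels, inertia


def _kmeans(
    px: np.ndarray, k: int, seed: int, n_init: int = 10, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Lloyd's k-means with ``n_init`` k-means++ restarts; deterministic in
    ``seed``.  The inner loop is jitted because this pipeline runs k-means
    on thousands of small pixel sets, where generic implementations spend
    most of their time in per-call overhead.  Returns (centers, labels) of
    the lowest-inertia run.
    """
    rng = np.random.default_rng(seed)
    # center-shift^2 convergence tolerance relative to data scale
    tol = 1e-4 * float(px.var(axis=0).mean()) + 1e-12
    best_inertia = np.inf
    best: tuple[np.ndarray, np.ndarray] | None = None
    for _ in range(n_init):
        centers = _kmeans_pp_init(px, k, rng)
        labels, inertia = _lloyd(px, centers, max_iter, tol)
        if inertia < best_inertia:
            best_inertia = inertia
            best = (centers, labels)
    assert best is not None
    return best


def quantize_dominant_color(
    pixels, k: int = 4, seed: int = 0
) -> tuple[RGBTriple, float]:
    """Dominant color of a pixel set by k-means quantization.

    Pixels are clustered on raw channel values into at most ``k`` groups
    (fewer when the set holds fewer distinct colors); the centroid of the
    most populous cluster is returned, rounded to integer channels,
    together with its pixel share.  Ties in cluster size are broken toward
    the lexicographically smallest centroid; the k-means uses 10 restarts
    with a fixed seed so results are deterministic.
    """
    px = np.asarray(pixels, dtype=float)
    if px.ndim == 1 and px.size == 3:
        px = px[None, :]
    if px.ndim != 2 or px.shape[1] != 3 or px.shape[0] == 0:
        raise InvalidInputError("pixels must be a non-empty (n, 3) array")
    if k < 1:
        raise InvalidInputError(f"k must be >= 1, got {k}")

    distinct = np.unique(px, axis=0)
    n_clusters = min(int(k), distinct.shape[0])
    if n_clusters == 1:
        return _round_centroid(px.mean(axis=0)), 1.0

    centers, labels = _kmeans(px, n_clusters, seed=int(seed))
    counts = np.bincount(labels, minlength=n_clusters)

    order = np.lexsort((centers[:, 2], centers[:, 1], centers[:, 0]))
    winner = order[int(np.argmax(counts[order]))]  # first max after lex sort
    return _round_centroid(centers[winner]), float(counts[winner] / px.shape[0])


def background_ring(mask, width: int = 20) -> np.ndarray:
    """Pixels at Chebyshev distance 1..``width`` outside the mask.

    Implemented as ``width`` iterations of 3x3 binary dilation minus the
    mask, which is exactly the set of background pixels whose Chebyshev
    distance to the mask is at most ``width``; clipped to the frame.
    """
    m = np.asarray(mask).astype(bool)
    if m.ndim != 2:
        raise InvalidInputError("mask must be 2-D")
    if not m.any():
        raise InvalidInputError("mask has no foreground pixel")
    if width < 1:
        raise InvalidInputError(f"ring width must be >= 1, got {width}")
    dilated = ndimage.binary_dilation(m, structure=_STRUCT_3X3, iterations=int(width))
    ring = dilated & ~m
    if not ring.any():
        raise DegenerateInputError("ring empty: mask fills the frame")
    return ring


def process_segment(
    sample: SegmentSample, k: int = 4, width: int = 20, seed: int = 0
) -> SegmentColorOutcome:
    """Dominant color, label and greenness for a segment and its background ring.

    Segments whose organism label is ``unclear`` are flagged ``excluded``
    (they are removed from downstream models but retained in output).
    """
    try:
        anole_color, anole_prop = quantize_dominant_color(
            sample.image[sample.mask], k=k, seed=seed
        )
        ring = background_ring(sample.mask, width=width)
        bg_color, bg_prop = quantize_dominant_color(
            sample.image[ring], k=k, seed=seed
        )
        anole = DominantColorResult(
            anole_color, anole_prop, classify_color(anole_color), greenness_index(anole_color)
        )
        background = DominantColorResult(
            bg_color, bg_prop, classify_color(bg_color), greenness_index(bg_color)
        )
    except (InvalidInputError, DegenerateInputError) as exc:
        raise type(exc)(f"segment {sample.id!r}: {exc}") from exc
    return SegmentColorOutcome(
        id=sample.id, anole=anole, background=background,
        excluded=(anole.label == "unclear"),
    )


def extract_colors(
    samples: Iterable[SegmentSample], k: int = 4, width: int = 20, seed: int = 0
) -> pd.DataFrame:
    """Process many segments into the per-segment color table.

    Columns: id, dom_R, dom_G, dom_B, proportion, label, greenness,
    bg_R, bg_G, bg_B, bg_greenness, excluded_flag.
    """
    rows = []
    for sample in samples:
        out = process_segment(sample, k=k, width=width, seed=seed)
        rows.append(
            {
                "id": out.id,
                "dom_R": out.anole.color.r,
                "dom_G": out.anole.color.g,
                "dom_B": out.anole.color.b,
                "proportion": out.anole.proportion,
                "label": out.anole.label,
                "greenness": out.anole.greenness,
                "bg_R": out.background.color.r,
                "bg_G": out.background.color.g,
                "bg_B": out.background.color.b,
                "bg_greenness": out.background.greenness,
                "excluded_flag": out.excluded,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id", "dom_R", "dom_G", "dom_B", "proportion", "label", "greenness",
            "bg_R", "bg_G", "bg_B", "bg_greenness", "excluded_flag",
        ],
    )


def load_segment(image_path, mask_path, id: str | None = None) -> SegmentSample:
    """Read a PNG/JPEG image and a PNG mask (nonzero = foreground)."""
    image_path = Path(image_path)
    img = np.asarray(Image.open(image_path).convert("RGB"))
    mask = np.asarray(Image.open(mask_path).convert("L")) > 0
    return SegmentSample(image=img, mask=mask, id=id or image_path.stem)
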