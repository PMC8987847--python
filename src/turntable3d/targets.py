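"""Circular coded-target detection and ring-code decoding.

A target is a white central disc surrounded by a dark gap and a 12-sector
binary code ring, printed white-on-black.  Target identity is the cyclic
equivalence class of the 12-bit ring word, so decoding is rotation
invariant by construction.  The code book keeps only classes whose minimum
cyclic Hamming distance to every other class is at least 3; a single
corrupted sector therefore never matches another class and is rejected
rather than mis-decoded.

Detection pipeline: global Otsu threshold → connected components → ellipse
from second-order moments → gap/ring verification → ring sampling and
decoding.  The subpixel center is the intensity-weighted centroid of the
central disc (the area centroid of the projected ellipse), refined by the
moment ellipse; for the small targets used here the perspective
eccentricity of the projected circle center is far below the quoted 0.1 px
accuracy and no explicit eccentricity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

RING_BITS = 12

# radial layout of the target, in units of the central disc radius
R_DISC = 1.0
R_GAP_OUTER = 1.5
R_RING_OUTER = 2.1
R_RING_MID = 0.5 * (R_GAP_OUTER + R_RING_OUTER)


def _rotate_word(w: int, k: int) -> int:
    k %= RING_BITS
    mask = (1 << RING_BITS) - 1
    return ((w << k) & mask) | (w >> (RING_BITS - k))


def canonical_word(w: int) -> int:
    """Smallest integer among all cyclic rotations of the 12-bit word."""
    return min(_rotate_word(w, k) for k in range(RING_BITS))


def cyclic_hamming(a: int, b: int) -> int:
    """Minimum Hamming distance between ``a`` and any rotation of ``b``."""
    return min(bin(a ^ _rotate_word(b, k)).count("1") for k in range(RING_BITS))


@lru_cache(maxsize=1)
def build_codebook(min_distance: int = 3) -> dict[int, int]:
    """Deterministic code book: canonical word → 1-based target ID.

    Greedy scan over canonical 12-bit words in ascending order, keeping a
    word only if its cyclic Hamming distance to every accepted word is at
    least ``min_distance``.  The all-zero and all-ones words are reserved
    as invalid.
    """
    accepted: list[int] = []
    full = (1 << RING_BITS) - 1
    for w in range(1, full):
        if canonical_word(w) != w:
            continue
        if all(cyclic_hamming(w, a) >= min_distance for a in accepted):
            accepted.append(w)
    return {w: i + 1 for i, w in enumerate(accepted)}


@lru_cache(maxsize=1)
def _id_to_word() -> dict[int, int]:
    return {i: w for w, i in build_codebook().items()}


def num_codes() -> int:
    return len(build_codebook())


def encode_target(target_code: int) -> np.ndarray:
    """Ring bits (length 12, MSB = sector 0) for a target ID."""
    words = _id_to_word()
    if target_code not in words:
        raise KeyError(f"target ID {target_code} outside code book (1..{num_codes()})")
    w = words[target_code]
    return np.array([(w >> (RING_BITS - 1 - i)) & 1 for i in range(RING_BITS)], dtype=bool)


def decode_ring_code(bits: np.ndarray) -> int | None:
    """Decode 12 ring bits to a target ID; ``None`` when rejected.

    Exact canonical lookup only: any word not in the code book (including
    every Hamming-distance-1 corruption of a valid word) is rejected.
    """
    bits = np.asarray(bits, dtype=bool)
    if bits.shape != (RING_BITS,):
        raise ValueError(f"expected {RING_BITS} ring bits")
    w = 0
    for b in bits:
        w = (w << 1) | int(b)
    return build_codebook().get(canonical_word(w))


def decode_sampled_ring(
    samples: np.ndarray, *, ambiguity_band: float = 0.2
) -> tuple[int | None, float]:
    """Decode a densely sampled binary ring (values in [0, 1]).

    The sector phase is unknown, so all sub-sector phase offsets are tried
    and the one with the purest sector means is kept.  Returns
    ``(target_id_or_None, purity)`` where purity ∈ [0, 1] measures how
    binary the best sectorization was.
    """
    samples = np.asarray(samples, dtype=float)
    m = len(samples)
    per = m / RING_BITS
    best = (None, -1.0, None)
    for frac in np.linspace(0.0, 1.0, 16, endpoint=False):
        idx = ((np.arange(m) + frac * per) // per).astype(int) % RING_BITS
        means = np.array([samples[idx == s].mean() for s in range(RING_BITS)])
        purity = float(np.mean(np.abs(means - 0.5)) * 2.0)
        if purity > best[1]:
            best = (means, purity, frac)
    means, purity, _ = best
    if np.any(np.abs(means - 0.5) < ambiguity_band / 2.0):
        return None, purity
    return decode_ring_code(means > 0.5), purity


@dataclass
class TargetDetection:
    target_code: int
    center_px: np.ndarray  # (x, y) subpixel
    semi_axes_px: tuple[float, float]  # (major, minor)
    orientation_rad: float
    quality: float


def _moment_ellipse(ys, xs, weights):
    """Weighted centroid and moment ellipse (A maps unit circle → ellipse)."""
    w = weights / weights.sum()
    cy, cx = (ys * w).sum(), (xs * w).sum()
    dy, dx = ys - cy, xs - cx
    cov = np.array(
        [
            [(dx * dx * w).sum(), (dx * dy * w).sum()],
            [(dx * dy * w).sum(), (dy * dy * w).sum()],
        ]
    )
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 1e-12, None)
    # uniform ellipse has second moment a²/4 along each principal axis
    A = evecs @ np.diag(2.0 * np.sqrt(evals)) @ evecs.T
    orientation = float(np.arctan2(evecs[1, 1], evecs[0, 1]))  # major-axis direction
    return np.array([cx, cy]), A, evals, orientation


def detect_targets(
    image: np.ndarray,
    *,
    min_diameter_px: float = 12.0,
    quality_threshold: float = 0.6,
    n_ring_samples: int = 180,
) -> list[TargetDetection]:
    """Detect and decode circular coded targets in an 8-bit grayscale image.

    Returns at most one detection per decoded ID (the highest-quality one).
    A blank image yields an empty list.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a single-channel grayscale image")
    imgf = img.astype(float) / (255.0 if img.dtype == np.uint8 else max(1.0, img.max()))
    if imgf.max() - imgf.min() < 0.1:
        return []
    thr = threshold_otsu(imgf)
    binary = imgf > thr
    lab = label(binary, connectivity=2)
    h, w = imgf.shape
    min_area = np.pi * (min_diameter_px / 2.0 / (R_RING_OUTER / R_DISC)) ** 2 * 0.5
    detections: dict[int, TargetDetection] = {}
    for region in regionprops(lab):
        if region.area < max(min_area, 9):
            continue
        if region.solidity < 0.85:  # code-ring arcs are non-convex; the disc is
            continue
        ys, xs = region.coords[:, 0].astype(float), region.coords[:, 1].astype(float)
        weights = imgf[region.coords[:, 0], region.coords[:, 1]]
        center, A, evals, orientation = _moment_ellipse(ys, xs, weights)
        a, b = 2.0 * np.sqrt(evals[1]), 2.0 * np.sqrt(evals[0])  # major, minor semi-axes
        if b < 1.5:  # too thin / too small to be a disc
            continue
        theta = np.linspace(0.0, 2.0 * np.pi, n_ring_samples, endpoint=False)
        # clockwise in image coordinates (y down) = counterclockwise as
        # printed on the target face, matching the encoder's sector order
        circ = np.stack([np.cos(theta), -np.sin(theta)])  # (2, M) in (x, y)
        # grow the region ellipse slightly: thresholding erodes the AA boundary
        def sample(rho):
            pts = center[:, None] + rho * (A @ circ)
            inb = (
                (pts[0] >= 0) & (pts[0] <= w - 1) & (pts[1] >= 0) & (pts[1] <= h - 1)
            )
            vals = np.zeros(n_ring_samples)
            if inb.any():
                vals[inb] = ndimage.map_coordinates(
                    imgf, np.stack([pts[1][inb], pts[0][inb]]), order=1
                )
            return vals, inb

        gap_vals, gap_in = sample((R_GAP_OUTER - 0.15) / R_DISC)
        if not gap_in.all() or gap_vals.mean() > 0.35:
            continue  # not a coded disc (no dark gap around it)
        ring_vals, ring_in = sample(R_RING_MID / R_DISC)
        if not ring_in.all():
            continue
        lo, hi = gap_vals.mean(), max(weights.mean(), 0.5)
        norm = np.clip((ring_vals - lo) / max(hi - lo, 1e-6), 0.0, 1.0)
        code, purity = decode_sampled_ring(norm)
        if code is None:
            continue
        quality = float(np.clip(purity * (1.0 - gap_vals.mean()), 0.0, 1.0))
        if quality < quality_threshold:
            continue
        if not (0 <= center[0] <= w - 1 and 0 <= center[1] <= h - 1):
            continue
        det = TargetDetection(
            target_code=code,
            center_px=center,
            semi_axes_px=(float(a), float(b)),
            orientation_rad=orientation,
            quality=quality,
        )
        if code not in detections or detections[code].quality < quality:
            detections[code] = det
    return sorted(detections.values(), key=lambda d: d.target_code)


def detections_to_dataframe(image_id: str, dets: list[TargetDetection]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "image_id": image_id,
                "target_code": d.target_code,
                "x_px": d.center_px[0],
                "y_px": d.center_px[1],
                "quality": d.quality,
            }
            for d in dets
        ],
        columns=["image_id", "target_code", "x_px", "y_px", "quality"],
    )


def save_detections_csv(path: str | Path, image_id: str, dets: list[TargetDetection]) -> None:
    detections_to_dataframe(image_id, dets).to_csv(path, index=False)
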