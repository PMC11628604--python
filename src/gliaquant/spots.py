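"""Single-molecule pulldown (SiMPull) spot counting.

Diffraction-limited aggregates in TIRF frames are counted with one shared
size and brightness rule across all frames: difference-of-Gaussians
band-pass, threshold at median + k*MAD of the filtered frame, connected
components restricted to a plausible spot-area window, and local-maxima
deduplication at a minimum separation. Counts aggregate as mean of means:
frames -> technical replicate -> mouse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max

from .core import ConfigurationError


@dataclass
class SpotDetectionConfig:
    dog_sigma_px: float = 1.5
    brightness_k: float = 5.0   # threshold = median + k * MAD of the DoG frame
    min_area_px: int = 2
    max_area_px: int = 50
    min_separation_px: float = 3.0
    border_px: int | None = None  # None: 4 * dog_sigma_px (DoG edge artifacts)

    def __post_init__(self):
        if self.min_area_px > self.max_area_px:
            raise ConfigurationError("min_area_px must be <= max_area_px")
        if self.brightness_k <= 0:
            raise ConfigurationError("brightness_k must be > 0")


@dataclass
class SpotCountRecord:
    frame_id: object
    n_spots: int
    centroids: np.ndarray  # (K, 2) as (x, y) pixel coords
    replicate_id: object = None
    mouse_id: object = None


def detect_spots(frame: np.ndarray, cfg: SpotDetectionConfig | None = None, *,
                 frame_id=None, replicate_id=None, mouse_id=None
                 ) -> SpotCountRecord:
    """Count spots in a single frame under the shared thresholds."""
    cfg = cfg or SpotDetectionConfig()
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("frame must be a single-channel 2D image")
    dog = (ndi.gaussian_filter(img, cfg.dog_sigma_px)
           - ndi.gaussian_filter(img, 1.6 * cfg.dog_sigma_px))
    med = float(np.median(dog))
    # sigma-consistent MAD (x1.4826), the usual robust noise scale
    mad = 1.4826 * float(np.median(np.abs(dog - med)))
    thr = med + cfg.brightness_k * max(mad, 1e-9)  # MAD=0 (flat frame) floor
    bw = dog > thr
    # boundary reflection inflates the DoG near edges; exclude a margin
    m = int(np.ceil(4 * cfg.dog_sigma_px)) if cfg.border_px is None \
        else int(cfg.border_px)
    if m > 0:
        bw[:m, :] = bw[-m:, :] = False
        bw[:, :m] = bw[:, -m:] = False
    lab, _ = ndi.label(bw, structure=np.ones((3, 3), int))
    sizes = np.bincount(lab.ravel())
    keep = ((sizes >= cfg.min_area_px) & (sizes <= cfg.max_area_px))
    keep[0] = False
    lab = np.where(keep[lab], lab, 0)
    # one detection per local maximum: partially merged neighbours at
    # >= min_separation resolve into separate spots
    peaks = peak_local_max(dog, labels=lab,
                           min_distance=max(int(round(cfg.min_separation_px)), 1),
                           threshold_abs=thr, exclude_border=False)
    kept = []
    for r, c in peaks:
        sl = (slice(max(r - 1, 0), r + 2), slice(max(c - 1, 0), c + 2))
        w = np.clip(dog[sl] - thr, 0.0, None)
        tot = float(w.sum())
        if tot > 0:
            yy, xx = np.mgrid[sl[0], sl[1]]
            kept.append((float((xx * w).sum() / tot),
                         float((yy * w).sum() / tot)))
        else:
            kept.append((float(c), float(r)))
    cents = np.asarray(kept, float).reshape(-1, 2)
    return SpotCountRecord(frame_id=frame_id, n_spots=len(cents),
                           centroids=cents, replicate_id=replicate_id,
                           mouse_id=mouse_id)


def records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([dict(mouse_id=r.mouse_id, replicate_id=r.replicate_id,
                              frame_id=r.frame_id, n_spots=r.n_spots)
                         for r in records])


def aggregate_counts(records, min_frames: int = 9
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean-of-means aggregation: frame counts -> replicate mean -> mouse
    value. Warns when a replicate holds fewer than `min_frames` frames."""
    df = records_to_frame(records)
    rep = (df.groupby(["mouse_id", "replicate_id"])["n_spots"]
             .agg(mean_spots="mean", n_frames="count").reset_index())
    short = rep[rep["n_frames"] < min_frames]
    for _, row in short.iterrows():
        warnings.warn(
            f"replicate {row['replicate_id']!r} of mouse {row['mouse_id']!r} "
            f"has {int(row['n_frames'])} < {min_frames} frames", stacklevel=2)
    mouse = (rep.groupby("mouse_id")["mean_spots"]
                .agg(mean_spots="mean", n_replicates="count").reset_index())
    return rep, mouse


def match_spots(detected: np.ndarray, truth: np.ndarray,
                radius_px: float = 2.0) -> tuple[int, int, int]:
    """Greedy 1:1 matching of detections to ground-truth positions.

    Returns (true positives, false positives, false negatives); a detection
    matches an unused truth spot within `radius_px`.
    """
    det = np.asarray(detected, float).reshape(-1, 2)
    tru = np.asarray(truth, float).reshape(-1, 2)
    used = np.zeros(len(tru), bool)
    tp = 0
    for d in det:
        if len(tru) == 0:
            break
        dist = np.hypot(tru[:, 0] - d[0], tru[:, 1] - d[1])
        dist[used] = np.inf
        j = int(np.argmin(dist))
        if dist[j] <= radius_px:
            used[j] = True
            tp += 1
    return tp, len(det) - tp, len(tru) - tp
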