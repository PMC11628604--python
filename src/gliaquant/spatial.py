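"""Per-cell microglia morphometrics, clustering and plaque association.

Territory is the convex-hull area of a cell's pixel centres; process length
is the 8-connected skeleton length of the instance minus its body
(orthogonal step 1 px, diagonal sqrt(2) px); clustering is each cell's mean
distance to its three nearest neighbouring centroids; a cell is
plaque-associated when its centroid lies inside the thresholded plaque mask
or within 5 um of a plaque edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError, cKDTree
from skimage.morphology import skeletonize

ASSOCIATION_THRESHOLD_UM = 5.0

_SQRT2 = float(np.sqrt(2.0))


@dataclass
class FovMicrogliaSummary:
    n_total: int
    n_plaque_associated: int
    n_non_plaque_associated: int
    plaque_area_fraction: float


def measure_territory(instance, pixel_size_um: float) -> float:
    """Convex-hull area (um^2) of the instance's pixel centres.

    Accepts a boolean mask or an (N, 2) array of (row, col) pixel coords;
    degenerate (collinear or < 3 px) instances have area 0.
    """
    arr = np.asarray(instance)
    pts = np.argwhere(arr) if arr.dtype == bool else arr
    pts = np.asarray(pts, float).reshape(-1, 2)
    if len(pts) < 3:
        return 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return 0.0
    return float(hull.volume) * pixel_size_um**2  # 2D: volume is the area


def skeleton_length_um(skel: np.ndarray, pixel_size_um: float) -> float:
    """Length of a skeleton: orthogonal adjacencies count 1 px, diagonal
    adjacencies sqrt(2) px, skipping a diagonal when either orthogonal
    intermediate is itself skeleton (avoids double-counting staircases)."""
    s = np.asarray(skel).astype(bool)
    if not s.any():
        return 0.0
    length = 0.0
    h, w = s.shape
    # orthogonal pairs
    length += float((s[:, :-1] & s[:, 1:]).sum())           # (0, +1)
    length += float((s[:-1, :] & s[1:, :]).sum())           # (+1, 0)
    # diagonal pairs
    d1 = s[:-1, :-1] & s[1:, 1:]    # (+1, +1)
    d1 &= ~(s[:-1, 1:] | s[1:, :-1])
    d2 = s[:-1, 1:] & s[1:, :-1]    # (+1, -1)
    d2 &= ~(s[:-1, :-1] | s[1:, 1:])
    length += _SQRT2 * float(d1.sum() + d2.sum())
    return length * pixel_size_um


def measure_process_length(instance_mask, body_mask,
                           pixel_size_um: float) -> float:
    """Total process length: skeletonize (instance - body), sum step lengths."""
    inst = np.asarray(instance_mask).astype(bool)
    body = np.asarray(body_mask).astype(bool)
    proc = inst & ~body
    if not proc.any():
        return 0.0
    return skeleton_length_um(skeletonize(proc), pixel_size_um)


def nn3_distance(centroids) -> np.ndarray:
    """Per-cell mean Euclidean distance to the 3 nearest neighbours (same
    units as the coordinates). Needs >= 4 centroids, else all-NaN."""
    pts = np.asarray(centroids, float).reshape(-1, 2)
    if len(pts) < 4:
        warnings.warn("nn3 needs at least 4 centroids; returning NaN",
                      stacklevel=2)
        return np.full(len(pts), np.nan)
    d, _ = cKDTree(pts).query(pts, k=4)
    return d[:, 1:].mean(axis=1)


def classify_association(centroids_um, plaque_mask, pixel_size_um: float,
                         threshold_um: float = ASSOCIATION_THRESHOLD_UM
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Plaque-association of each centroid plus its signed edge distance.

    Distance to the plaque set is the exact EDT of the mask complement,
    sampled at the centroid's pixel; signed distance is negative inside the
    mask (depth to the edge). A cell is plaque-associated iff its centroid
    is inside the mask or within `threshold_um` of it. With an empty plaque
    mask everything is non-associated and the distance is +inf.
    """
    pts = np.asarray(centroids_um, float).reshape(-1, 2)  # (x, y) in um
    mask = np.asarray(getattr(plaque_mask, "mask", plaque_mask)).astype(bool)
    n = len(pts)
    if not mask.any():
        return np.zeros(n, bool), np.full(n, np.inf)
    d_out = ndi.distance_transform_edt(~mask) * pixel_size_um
    d_in = ndi.distance_transform_edt(mask) * pixel_size_um
    assoc = np.zeros(n, bool)
    signed = np.zeros(n)
    for i, (x_um, y_um) in enumerate(pts):
        r = int(np.clip(round(y_um / pixel_size_um), 0, mask.shape[0] - 1))
        c = int(np.clip(round(x_um / pixel_size_um), 0, mask.shape[1] - 1))
        if mask[r, c]:
            assoc[i] = True
            signed[i] = -d_in[r, c]
        else:
            signed[i] = d_out[r, c]
            assoc[i] = signed[i] <= threshold_um
    return assoc, signed


def measure_microglia(instance_labels: np.ndarray, body_mask,
                      plaque_mask, pixel_size_um: float, *,
                      threshold_um: float = ASSOCIATION_THRESHOLD_UM
                      ) -> pd.DataFrame:
    """Per-cell record table for one FOV: centroid, territory, process
    length, 3-NN clustering distance, association and border flag."""
    labels = np.asarray(instance_labels)
    body = np.asarray(body_mask).astype(bool) if body_mask is not None \
        else np.zeros(labels.shape, bool)
    ids = [i for i in np.unique(labels) if i != 0]
    rows = []
    h, w = labels.shape
    for i in ids:
        inst = labels == i
        coords = np.argwhere(inst)
        cy, cx = coords.mean(axis=0)
        rows.append(dict(
            cell_id=int(i),
            centroid_x_um=cx * pixel_size_um,
            centroid_y_um=cy * pixel_size_um,
            convex_area_um2=measure_territory(coords, pixel_size_um),
            process_length_um=measure_process_length(inst, body, pixel_size_um),
            border_touching=bool(coords[:, 0].min() == 0 or coords[:, 1].min() == 0
                                 or coords[:, 0].max() == h - 1
                                 or coords[:, 1].max() == w - 1)))
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    cents = df[["centroid_x_um", "centroid_y_um"]].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        df["nn3_mean_dist_um"] = nn3_distance(cents)
    assoc, signed = classify_association(cents, plaque_mask, pixel_size_um,
                                         threshold_um)
    df["plaque_associated"] = assoc
    df["dist_to_plaque_edge_um"] = signed
    return df


def summarize_fov_microglia(records: pd.DataFrame,
                            plaque_summary) -> FovMicrogliaSummary:
    """Counts joined with the FOV's plaque area fraction (regression key)."""
    n = len(records)
    n_pa = int(records["plaque_associated"].sum()) if n else 0
    af = getattr(plaque_summary, "area_fraction", float(plaque_summary or 0.0))
    return FovMicrogliaSummary(n_total=n, n_plaque_associated=n_pa,
                               n_non_plaque_associated=n - n_pa,
                               plaque_area_fraction=float(af))
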