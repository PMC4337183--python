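"""Spot detection, cross-gel matching and volume normalization.

This stage replaces interactive 2DE software: spots are detected on a
raster gel image by background subtraction + local maxima + watershed,
every gel is registered to a reference gel (the one with the most spots)
by a RANSAC-estimated affine transform over mutual-nearest-neighbour
candidate pairs, and matched spots are tracked across gels as
:class:`MatchedSpotCluster` objects.  Spot volumes are normalized per gel
to a total of 100 so that staining-intensity differences between gels
cancel out.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.measure import ransac
from skimage.segmentation import watershed
from skimage.transform import AffineTransform

__all__ = [
    "GelSpotTable",
    "MatchedSpotCluster",
    "DegenerateGelError",
    "RegistrationError",
    "detect_spots",
    "select_reference",
    "match_spots",
    "normalize_volumes",
    "write_clusters_csv",
    "read_clusters_csv",
]

SPOT_COLUMNS = ["spot_id", "x", "y", "volume", "normalized_volume"]


class DegenerateGelError(ValueError):
    """Gel whose total spot volume is zero cannot be normalized."""


class RegistrationError(RuntimeError):
    """Too few candidate pairs to estimate an affine registration."""


@dataclass
class GelSpotTable:
    """Detected spots of a single gel.

    ``spots`` columns: ``spot_id`` (unique within the gel), ``x``/``y``
    (continuous gel coordinates, origin top-left, x acidic→basic),
    ``volume`` (integrated background-subtracted intensity, ≥ 0) and
    ``normalized_volume`` (percent of gel total, NaN until normalized).
    """

    gel_id: str
    spots: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=SPOT_COLUMNS))

    def __post_init__(self):
        df = pd.DataFrame(self.spots).copy()
        if "normalized_volume" not in df.columns:
            df["normalized_volume"] = np.nan
        df = df[SPOT_COLUMNS]
        df["spot_id"] = df["spot_id"].astype(str)
        if df["spot_id"].duplicated().any():
            raise ValueError(f"duplicate spot_ids in gel {self.gel_id}")
        if (df["volume"] < 0).any():
            raise ValueError(f"negative volumes in gel {self.gel_id}")
        self.spots = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.spots)

    def to_csv(self, path) -> None:
        out = self.spots.copy()
        out.insert(0, "gel_id", self.gel_id)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GelSpotTable":
        df = pd.read_csv(path, dtype={"spot_id": str, "gel_id": str})
        gel_ids = df["gel_id"].unique()
        if len(gel_ids) != 1:
            raise ValueError(f"{path} holds {len(gel_ids)} gels, expected 1")
        return cls(gel_id=str(gel_ids[0]),
                   spots=df.drop(columns=["gel_id"]))


@dataclass
class MatchedSpotCluster:
    """One physical spot tracked across gels.

    ``members`` maps gel_id → spot_id for every gel where the spot was
    found; gels missing from the map did not show the spot.  The centroid
    is expressed in reference-gel coordinates.
    """

    cluster_id: str
    members: dict[str, str]
    x_ref: float
    y_ref: float

    def presence(self, gel_ids) -> int:
        return sum(1 for g in gel_ids if g in self.members)


def detect_spots(
    image,
    min_volume: float = 50.0,
    min_separation: int = 3,
    *,
    k_sigma: float = 5.0,
    background_radius: int = 15,
    threshold_floor: float = 1.0,
    gel_id: str = "gel",
) -> GelSpotTable:
    """Detect and quantify spots on a grayscale gel image.

    Background is estimated by a large-window grayscale opening; local
    maxima of the background-subtracted image above
    ``max(k_sigma * noise_sigma, threshold_floor)`` seed a watershed
    segmentation, and each segment's volume is its summed
    background-subtracted intensity.  Sub-pixel centroids are
    intensity-weighted.  A constant image yields an empty table.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if min_volume <= 0 or min_separation <= 0:
        raise ValueError("min_volume and min_separation must be positive")

    size = 2 * background_radius + 1
    background = ndi.grey_opening(img, size=(size, size))
    # the opening tracks the noise-floor minimum, so the residual has a
    # positive offset in flat regions; re-zero it at its median
    sub = img - background
    med = np.median(sub)
    noise_sigma = 1.4826 * np.median(np.abs(sub - med))
    sub = sub - med
    threshold = max(k_sigma * noise_sigma, threshold_floor)

    coords = peak_local_max(sub, min_distance=int(min_separation),
                            threshold_abs=threshold, exclude_border=False)
    if len(coords) == 0:
        return GelSpotTable(gel_id=gel_id)

    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    mask = sub > min(threshold / 2.0,
                     max(2.5 * noise_sigma, threshold_floor / 2.0))
    labels = watershed(-sub, markers=markers, mask=mask)

    index = np.arange(1, len(coords) + 1)
    volumes = ndi.sum_labels(np.clip(sub, 0, None), labels, index)
    centroids = ndi.center_of_mass(np.clip(sub, 0, None), labels, index)
    centroids = np.asarray(centroids, dtype=float)

    keep = volumes >= min_volume
    rows = {
        "spot_id": [f"s{i:04d}" for i in range(int(keep.sum()))],
        "x": centroids[keep, 1],
        "y": centroids[keep, 0],
        "volume": volumes[keep],
    }
    return GelSpotTable(gel_id=gel_id, spots=pd.DataFrame(rows))


def select_reference(gels: list[GelSpotTable]) -> str:
    """Reference gel id: maximum spot count, ties to the smallest gel_id."""
    if not gels:
        raise ValueError("cannot select a reference from an empty gel list")
    return min(gels, key=lambda g: (-len(g), g.gel_id)).gel_id


def normalize_volumes(gel: GelSpotTable) -> GelSpotTable:
    """Scale spot volumes to percent of the gel total (sums to 100).

    Raw volumes are retained; the operation is idempotent and invariant
    to a global intensity scaling of the gel.
    """
    total = float(gel.spots["volume"].sum())
    if not total > 0:
        raise DegenerateGelError(
            f"gel {gel.gel_id} has zero total volume")
    spots = gel.spots.copy()
    spots["normalized_volume"] = 100.0 * spots["volume"] / total
    return replace(gel, spots=spots)


def _greedy_pairs(src_xy, dst_tree, radius, k=4):
    """Distance-sorted one-to-one pairing of src points to dst tree points."""
    if len(src_xy) == 0 or dst_tree.n == 0:
        return []
    k = min(k, dst_tree.n)
    dists, idxs = dst_tree.query(src_xy, k=k)
    dists = np.atleast_2d(dists.T).T
    idxs = np.atleast_2d(idxs.T).T
    cand = [(dists[i, j], i, int(idxs[i, j]))
            for i in range(len(src_xy)) for j in range(k)
            if dists[i, j] <= radius]
    cand.sort()
    used_src, used_dst, pairs = set(), set(), []
    for d, i, jdst in cand:
        if i in used_src or jdst in used_dst:
            continue
        used_src.add(i)
        used_dst.add(jdst)
        pairs.append((i, jdst))
    return pairs


def _estimate_affine(xy, ref_xy, gel_id):
    """RANSAC affine from mutual-nearest-neighbour candidate pairs."""
    tree_ref = cKDTree(ref_xy)
    tree_g = cKDTree(xy)
    _, nn_ref = tree_ref.query(xy)       # gel spot -> nearest ref spot
    _, nn_gel = tree_g.query(ref_xy)     # ref spot -> nearest gel spot
    mutual = [(i, int(nn_ref[i])) for i in range(len(xy))
              if int(nn_gel[int(nn_ref[i])]) == i]
    if len(mutual) < 3:
        raise RegistrationError(
            f"gel {gel_id}: only {len(mutual)} candidate pairs, need >= 3")
    src = xy[[i for i, _ in mutual]]
    dst = ref_xy[[j for _, j in mutual]]
    model, _ = ransac((src, dst), AffineTransform, min_samples=3,
                      residual_threshold=2.0, max_trials=100, rng=0)
    if model is None:
        raise RegistrationError(f"gel {gel_id}: RANSAC failed")
    return model


def match_spots(
    gels: list[GelSpotTable],
    reference: str,
    radius: float = 3.0,
) -> list[MatchedSpotCluster]:
    """Register every gel to the reference and track spots as clusters.

    Each non-reference gel is registered by an affine transform (RANSAC
    over mutual-nearest-neighbour pairs) and its spots greedily matched,
    in ascending distance order, to unclaimed reference spots within
    ``radius`` (reference-gel coordinate units).  Reference spots missing
    from a gel record that gel as absent.  Spots of non-reference gels
    with no reference partner seed new clusters, which are themselves
    linked across gels by the same greedy rule so that a spot absent from
    the reference gel's group can still be tracked.

    The result is independent of the input ordering of ``gels`` apart
    from cluster labels (gels are processed in gel_id order).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    by_id = {g.gel_id: g for g in gels}
    if reference not in by_id:
        raise ValueError(f"reference gel {reference!r} not among inputs")
    ref = by_id[reference]
    ref_xy = ref.spots[["x", "y"]].to_numpy(dtype=float)
    ref_ids = ref.spots["spot_id"].to_numpy()

    clusters = [
        MatchedSpotCluster(cluster_id=f"c{i:04d}",
                           members={reference: str(sid)},
                           x_ref=float(xy[0]), y_ref=float(xy[1]))
        for i, (sid, xy) in enumerate(zip(ref_ids, ref_xy))
    ]
    ref_tree = cKDTree(ref_xy) if len(ref_xy) else cKDTree(np.empty((0, 2)))
    leftovers: list[tuple[str, str, float, float]] = []

    for gel_id in sorted(by_id):
        if gel_id == reference:
            continue
        gel = by_id[gel_id]
        if len(gel) == 0:
            continue
        xy = gel.spots[["x", "y"]].to_numpy(dtype=float)
        sids = gel.spots["spot_id"].to_numpy()
        model = _estimate_affine(xy, ref_xy, gel_id)
        txy = model(xy)
        pairs = _greedy_pairs(txy, ref_tree, radius)
        matched_src = set()
        for i, j in pairs:
            clusters[j].members[gel_id] = str(sids[i])
            matched_src.add(i)
        for i in range(len(xy)):
            if i not in matched_src:
                leftovers.append((gel_id, str(sids[i]),
                                  float(txy[i, 0]), float(txy[i, 1])))

    # second pass: cluster spots that have no reference partner
    new: list[MatchedSpotCluster] = []
    counts: list[int] = []
    next_id = len(clusters)
    for gel_id in sorted({g for g, *_ in leftovers}):
        pts = [(s, x, y) for g, s, x, y in leftovers if g == gel_id]
        xy = np.array([(x, y) for _, x, y in pts])
        tree = (cKDTree(np.array([(c.x_ref, c.y_ref) for c in new]))
                if new else cKDTree(np.empty((0, 2))))
        pairs = _greedy_pairs(xy, tree, radius)
        matched_src = set()
        for i, j in pairs:
            c = new[j]
            c.members[gel_id] = pts[i][0]
            n = counts[j]
            c.x_ref = (c.x_ref * n + xy[i, 0]) / (n + 1)
            c.y_ref = (c.y_ref * n + xy[i, 1]) / (n + 1)
            counts[j] = n + 1
            matched_src.add(i)
        for i in range(len(pts)):
            if i not in matched_src:
                new.append(MatchedSpotCluster(
                    cluster_id=f"c{next_id:04d}",
                    members={gel_id: pts[i][0]},
                    x_ref=float(xy[i, 0]), y_ref=float(xy[i, 1])))
                counts.append(1)
                next_id += 1
    return clusters + new


def write_clusters_csv(clusters: list[MatchedSpotCluster], path) -> None:
    rows = [
        {"cluster_id": c.cluster_id, "gel_id": g, "spot_id": s,
         "x_ref": c.x_ref, "y_ref": c.y_ref}
        for c in clusters for g, s in sorted(c.members.items())
    ]
    pd.DataFrame(rows, columns=["cluster_id", "gel_id", "spot_id",
                                "x_ref", "y_ref"]).to_csv(path, index=False)


def read_clusters_csv(path) -> list[MatchedSpotCluster]:
    df = pd.read_csv(path, dtype={"cluster_id": str, "gel_id": str,
                                  "spot_id": str})
    clusters = []
    for cid, grp in df.groupby("cluster_id", sort=True):
        clusters.append(MatchedSpotCluster(
            cluster_id=str(cid),
            members=dict(zip(grp["gel_id"], grp["spot_id"])),
            x_ref=float(grp["x_ref"].iloc[0]),
            y_ref=float(grp["y_ref"].iloc[0])))
    return clusters
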