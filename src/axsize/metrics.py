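"""Diameter indices and comparison utilities.

The fitted cylinder coefficients of a streamline form its volume-weighted
cylinder diameter distribution.  The streamline axon diameter index (sADI)
is the weighted mean of that distribution over the *included* grid bins —
by default the smallest (1.5 um) and largest (7 um) diameters are excluded
because they act as catch bins for axons outside the sensitive range of the
acquisition.  A bundle's distribution is the column-by-column sum of its
member streamlines' distributions, and the bundle ADI is the weighted mean
of that summed distribution.

Also provided: the tractometry baseline (averaging a voxel-wise map along
streamlines), skeleton-based sectorization of a 2-D ROI mask, and the
count-to-volume-weighted conversion used to compare against histological
diameter histograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dictionary import DiameterGrid, DictionaryOperator

__all__ = [
    "CylinderDistribution",
    "UndefinedSADIError",
    "streamline_sadi",
    "streamline_distributions",
    "bundle_distribution",
    "ADIReport",
    "tractometry_mean",
    "sectorize_mask",
    "count_to_volume_weighted",
]


class UndefinedSADIError(ValueError):
    """All weight lies in the excluded end bins; the index is undefined."""


@dataclass(frozen=True)
class CylinderDistribution:
    """Non-negative weights over a diameter grid (volume fractions)."""

    grid: DiameterGrid
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != self.grid.values.shape:
            raise ValueError("weights must match the diameter grid")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "weights", w)

    @property
    def included_weight(self) -> float:
        return float(self.weights[self.grid.included].sum())


def streamline_sadi(dist: CylinderDistribution) -> float:
    """Weighted mean diameter over the included bins (um).

    Raises :class:`UndefinedSADIError` when the included bins carry no
    weight, so that such streamlines are flagged rather than silently
    averaged.
    """
    inc = dist.grid.included
    wsum = dist.weights[inc].sum()
    if wsum <= 0:
        raise UndefinedSADIError("no weight in the included diameter bins")
    return float(np.sum(dist.grid.values[inc] * dist.weights[inc]) / wsum)


def streamline_distributions(x, operator: DictionaryOperator):
    """Per-streamline cylinder distributions from a coefficient vector."""
    table = operator.cylinder_weight_matrix(x)
    return [CylinderDistribution(operator.grid, row) for row in table]


def bundle_distribution(x, operator: DictionaryOperator, membership):
    """Column-by-column sum of member streamlines' cylinder signatures.

    ``membership`` assigns a hashable bundle label to every streamline.
    Returns ``{label: CylinderDistribution}``.
    """
    membership = np.asarray(membership)
    if len(membership) != operator.n_streamlines:
        raise ValueError("membership must label every streamline")
    table = operator.cylinder_weight_matrix(x)
    out = {}
    for label in dict.fromkeys(membership.tolist()):  # preserves order
        sel = membership == label
        out[label] = CylinderDistribution(operator.grid, table[sel].sum(axis=0))
    return out


@dataclass
class ADIReport:
    """Per-streamline sADI plus per-bundle distributions and ADIs.

    ``streamline_sadi`` holds NaN for streamlines whose index is undefined;
    those are excluded from bundle sums only through their (zero) included
    weight and are counted in ``n_undefined``.
    """

    streamline_sadi: np.ndarray
    bundle_distributions: dict
    bundle_adi: dict
    membership: np.ndarray
    n_undefined: int

    @classmethod
    def from_fit(cls, x, operator: DictionaryOperator, membership):
        dists = streamline_distributions(x, operator)
        sadi = np.full(len(dists), np.nan)
        n_undef = 0
        for i, d in enumerate(dists):
            try:
                sadi[i] = streamline_sadi(d)
            except UndefinedSADIError:
                n_undef += 1
        bdists = bundle_distribution(x, operator, membership)
        badi = {}
        for label, d in bdists.items():
            try:
                badi[label] = streamline_sadi(d)
            except UndefinedSADIError:
                badi[label] = np.nan
        return cls(sadi, bdists, badi, np.asarray(membership), n_undef)


def tractometry_mean(voxel_map, streamlines, voxel_size=2.0, membership=None):
    """Average a voxel-wise map along streamline trajectories.

    Per streamline, the unweighted mean of the map over the voxels it
    traverses.  If ``membership`` is given, also returns per-bundle means
    computed over the union of voxels traversed by the bundle's streamlines
    (each voxel counted once), the conventional tractometry statistic.

    Returns ``per_streamline`` or ``(per_streamline, per_bundle)``.
    """
    from .dictionary import voxel_segments

    voxel_map = np.asarray(voxel_map, dtype=float)
    shape = voxel_map.shape
    per_sl = np.full(len(streamlines), np.nan)
    traversed = []
    for i, sl in enumerate(streamlines):
        vox, lens, _ = voxel_segments(sl, voxel_size, shape)
        if len(vox) == 0:
            traversed.append(set())
            continue
        uniq = set(map(tuple, vox.tolist()))
        traversed.append(uniq)
        vals = np.array([voxel_map[v] for v in uniq])
        vals = vals[np.isfinite(vals)]
        if len(vals):
            per_sl[i] = vals.mean()
    if membership is None:
        return per_sl
    membership = np.asarray(membership)
    per_bundle = {}
    for label in dict.fromkeys(membership.tolist()):
        union = set().union(*(traversed[i] for i in np.nonzero(membership == label)[0]))
        vals = np.array([voxel_map[v] for v in union])
        vals = vals[np.isfinite(vals)]
        per_bundle[label] = vals.mean() if len(vals) else np.nan
    return per_sl, per_bundle


def _skeleton_path(skel):
    """Order the skeleton pixels of a thin 2-D curve along its length."""
    pts = [tuple(p) for p in np.argwhere(skel)]
    pset = set(pts)

    def neighbors(p):
        out = []
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                q = (p[0] + di, p[1] + dj)
                if q in pset:
                    out.append(q)
        return out

    deg = {p: len(neighbors(p)) for p in pts}
    ends = [p for p in pts if deg[p] <= 1] or [pts[0]]

    def walk(start):
        path = [start]
        seen = {start}
        cur = start
        while True:
            nxt = [q for q in neighbors(cur) if q not in seen]
            if not nxt:
                return path
            # prefer continuing in the current direction
            if len(path) >= 2:
                d = np.subtract(cur, path[-2])
                nxt.sort(key=lambda q: -float(np.dot(np.subtract(q, cur), d)))
            cur = nxt[0]
            seen.add(cur)
            path.append(cur)

    # longest walk over all endpoints approximates the principal curve
    best = max((walk(e) for e in ends), key=len)
    return np.asarray(best)


def sectorize_mask(mask_2d, n_sectors):
    """Subdivide a 2-D ROI mask into ``n_sectors`` along its skeleton.

    The mask is thinned to its longitudinal centerline, the centerline is
    ordered along the principal curve and cut into ``n_sectors`` equal
    arclength segments, and every mask pixel is assigned to the segment of
    its nearest centerline point, so sector boundaries run roughly
    perpendicular to the skeleton.  Returns an int label map (0 outside,
    1..n inside).
    """
    from scipy.ndimage import label as cc_label
    from scipy.spatial import cKDTree
    from skimage.morphology import skeletonize

    mask = np.asarray(mask_2d, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("sectorize_mask expects a 2-D mask")
    if n_sectors < 1:
        raise ValueError("n_sectors must be >= 1")
    lab, ncomp = cc_label(mask)
    if ncomp != 1:
        sizes = [int((lab == k).sum()) for k in range(1, ncomp + 1)]
        raise ValueError(
            f"mask must be a single connected component; found {ncomp} "
            f"components of sizes {sizes}"
        )
    skel = skeletonize(mask)
    path = _skeleton_path(skel)
    if len(path) < n_sectors:
        raise ValueError(
            f"skeleton has {len(path)} points, fewer than {n_sectors} sectors"
        )
    # arclength position of each ordered skeleton point
    steps = np.linalg.norm(np.diff(path, axis=0).astype(float), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(steps)])
    seg_of_point = np.minimum(
        (arc / (arc[-1] + 1e-12) * n_sectors).astype(int), n_sectors - 1
    )
    tree = cKDTree(path)
    pix = np.argwhere(mask)
    _, nearest = tree.query(pix)
    labels = np.zeros(mask.shape, dtype=int)
    labels[tuple(pix.T)] = seg_of_point[nearest] + 1
    return labels


def count_to_volume_weighted(diameters, counts):
    """Convert a diameter count histogram to volume weights.

    For cylinders of equal length the volume of a diameter class scales
    with the cross-sectional area, so ``w_i ~ count_i * d_i^2``, normalized
    to sum to one.
    """
    d = np.asarray(diameters, dtype=float)
    c = np.asarray(counts, dtype=float)
    if d.shape != c.shape:
        raise ValueError("diameters and counts must have the same shape")
    if np.any(d <= 0) or np.any(c < 0):
        raise ValueError("diameters must be positive and counts non-negative")
    w = c * d**2
    total = w.sum()
    if total <= 0:
        raise ValueError("histogram has no mass")
    return w / total
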