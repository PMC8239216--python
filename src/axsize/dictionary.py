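"""Assembly of the sparse forward operator A.

The linear model expresses the DW signal of every white-matter voxel as a
non-negative combination of per-streamline cylinder signatures and per-voxel
zeppelin/ball signatures:

* for each streamline and each diameter of the grid, one column holding the
  cylinder signal oriented along the streamline's local tangent, weighted in
  every traversed voxel by the intersection length normalized by voxel size;
* for each voxel and each principal diffusion direction, one column per
  perpendicular diffusivity of the zeppelin set;
* one isotropic (ball) column per voxel.

Rows are ordered voxel-major: the block of measurement rows of the i-th
masked voxel starts at ``i * n_meas``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sps

from .scheme import AcquisitionScheme
from .signals import (
    BallSpec,
    D_ISO,
    D_PARALLEL,
    ZeppelinSpec,
    ball_signal,
    cylinder_attenuation,
    zeppelin_signal,
)

log = logging.getLogger(__name__)

__all__ = [
    "DiameterGrid",
    "DictionaryConfig",
    "DictionaryOperator",
    "build_dictionary",
    "principal_directions",
    "voxel_segments",
]

KIND_CYLINDER, KIND_ZEPPELIN, KIND_BALL = 0, 1, 2


@dataclass(frozen=True)
class DiameterGrid:
    """Ordered cylinder diameters (um) with end bins excluded from the index.

    The default is 12 equally spaced diameters from 1.5 to 7.0 um.  The
    smallest and largest diameters act as catch bins for axons outside the
    sensitive range and are excluded when averaging to a diameter index.
    """

    values: np.ndarray
    included: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        inc = np.asarray(self.included, dtype=bool)
        if v.ndim != 1 or len(v) < 3 or np.any(np.diff(v) <= 0):
            raise ValueError("diameter grid must be strictly increasing, length >= 3")
        if inc.shape != v.shape:
            raise ValueError("included mask must match grid length")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "included", inc)

    @classmethod
    def default(cls, n=12, lo=1.5, hi=7.0):
        v = np.linspace(lo, hi, n)
        inc = np.ones(n, dtype=bool)
        inc[0] = inc[-1] = False
        return cls(v, inc)

    def __len__(self):
        return len(self.values)


@dataclass(frozen=True)
class DictionaryConfig:
    """Fixed diffusivities of the Cylinder-Zeppelin-Ball dictionary (m^2/s).

    ``d_perp_values`` defaults to four equally spaced perpendicular
    diffusivities from 0.5e-9 to 1.0e-9 m^2/s.  ``zeppelin_mode`` selects
    the extra-axonal decomposition: ``"tensor"`` builds one full zeppelin per
    d_perp; ``"stick+perp"`` builds one axial (stick-like) column plus one
    perpendicular-only column per d_perp.
    """

    d_par: float = D_PARALLEL
    d_iso: float = D_ISO
    d_perp_values: tuple = (0.5e-9, 0.5e-9 + 1e-9 / 6, 0.5e-9 + 2e-9 / 6, 1.0e-9)
    zeppelin_mode: str = "tensor"

    def __post_init__(self):
        if self.zeppelin_mode not in ("tensor", "stick+perp"):
            raise ValueError("zeppelin_mode must be 'tensor' or 'stick+perp'")


class DictionaryError(ValueError):
    pass


def _merge_collinear(pts, tol=1e-9):
    """Drop interior points that do not change the polyline direction."""
    if len(pts) < 3:
        return pts
    d = np.diff(pts, axis=0)
    norms = np.linalg.norm(d, axis=1)
    ok = norms > 1e-12
    d[ok] /= norms[ok, None]
    turn = np.linalg.norm(np.diff(d, axis=0), axis=1) > tol
    keep = np.concatenate([[True], turn, [True]])
    return pts[keep]


def voxel_segments(points_mm, voxel_size, shape):
    """Exact polyline-voxel intersection.

    Clips the polyline against the axis-aligned voxel grid (voxel ``i``
    spans ``[i*vs, (i+1)*vs)`` mm) and returns arrays ``(voxels, lengths,
    tangents)`` where ``voxels`` is (m, 3) int, ``lengths`` (m,) mm and
    ``tangents`` (m, 3) unit vectors, one row per traversed sub-segment.
    Sub-segments outside the grid are dropped.
    """
    pts = np.asarray(points_mm, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("polyline must be an (n >= 2, 3) array")
    pts = _merge_collinear(pts)
    shape = np.asarray(shape, dtype=int)
    vox_list, len_list, tan_list = [], [], []
    for p0, p1 in zip(pts[:-1], pts[1:]):
        d = p1 - p0
        seg_len = np.linalg.norm(d)
        if seg_len < 1e-12:
            continue
        tangent = d / seg_len
        # parameters of all grid-plane crossings within (0, 1)
        ts = [0.0, 1.0]
        for ax in range(3):
            if abs(d[ax]) < 1e-12:
                continue
            lo = int(np.floor(min(p0[ax], p1[ax]) / voxel_size))
            hi = int(np.ceil(max(p0[ax], p1[ax]) / voxel_size))
            planes = np.arange(lo + 1, hi) * voxel_size
            tcross = (planes - p0[ax]) / d[ax]
            ts.extend(tcross[(tcross > 0) & (tcross < 1)])
        ts = np.unique(ts)
        mids = p0[None, :] + (0.5 * (ts[:-1] + ts[1:]))[:, None] * d[None, :]
        vox = np.floor(mids / voxel_size).astype(int)
        lens = np.diff(ts) * seg_len
        ok = np.all((vox >= 0) & (vox < shape[None, :]), axis=1) & (lens > 1e-9)
        if ok.any():
            vox_list.append(vox[ok])
            len_list.append(lens[ok])
            tan_list.append(np.tile(tangent, (int(ok.sum()), 1)))
    if not vox_list:
        return np.empty((0, 3), int), np.empty(0), np.empty((0, 3))
    return np.vstack(vox_list), np.concatenate(len_list), np.vstack(tan_list)


def principal_directions(source, mask=None):
    """Per-voxel principal diffusion directions.

    ``source`` is either a :class:`~axsize.phantom.PhantomVolume` (the
    ground-truth bundle orientations of every tissue voxel are used) or a
    peaks array of shape (nx, ny, nz, k, 3) / (nx, ny, nz, 3*k) of unit
    vectors, zero rows meaning "no direction".  Returns an
    (nx, ny, nz, k, 3) array with NaN rows where no direction exists.
    """
    from .phantom import PhantomVolume

    if isinstance(source, PhantomVolume):
        nx, ny, nz = source.shape
        out = np.full((nx, ny, nz, 2, 3), np.nan)
        for bi, bundle in enumerate(source.bundles):
            has = source.intra_fractions[..., bi] > 0
            out[has, bi, :] = np.asarray(bundle.orientation)
        return out
    peaks = np.asarray(source, dtype=float)
    if peaks.ndim == 4:
        if peaks.shape[-1] % 3:
            raise ValueError("flat peaks array must have 3*k components")
        peaks = peaks.reshape(peaks.shape[:3] + (-1, 3))
    if peaks.ndim != 5 or peaks.shape[-1] != 3:
        raise ValueError("peaks must have shape (nx, ny, nz, k, 3)")
    out = np.full(peaks.shape, np.nan)
    norms = np.linalg.norm(peaks, axis=-1)
    ok = norms > 1e-8
    out[ok] = peaks[ok] / norms[ok][..., None]
    if mask is not None:
        out[~np.asarray(mask, dtype=bool)] = np.nan
    return out


@dataclass
class DictionaryOperator:
    """Sparse operator plus per-column metadata.

    ``A`` has ``n_voxels * n_meas`` rows (voxel-major blocks following
    ``voxel_index``) and one column per dictionary atom, described by the
    parallel arrays ``col_kind`` (0 cylinder / 1 zeppelin / 2 ball),
    ``col_streamline``, ``col_voxel`` (index into ``voxel_index``),
    ``col_diam_idx`` (index into the diameter grid) and ``col_value``
    (diameter in um for cylinders, d_perp or d_iso in m^2/s otherwise).
    """

    A: sps.csr_matrix
    n_meas: int
    voxel_index: np.ndarray         # (n_voxels, 3) int voxel coordinates
    grid: DiameterGrid
    config: DictionaryConfig
    col_kind: np.ndarray
    col_streamline: np.ndarray
    col_voxel: np.ndarray
    col_diam_idx: np.ndarray
    col_value: np.ndarray
    n_streamlines: int
    skipped_streamlines: int = 0

    @property
    def shape(self):
        return self.A.shape

    @property
    def n_voxels(self):
        return len(self.voxel_index)

    def voxel_row_block(self, i):
        return slice(i * self.n_meas, (i + 1) * self.n_meas)

    def cylinder_weight_matrix(self, x):
        """Scatter coefficients into an (n_streamlines, n_diameters) table."""
        x = np.asarray(x, dtype=float)
        out = np.zeros((self.n_streamlines, len(self.grid)))
        cyl = self.col_kind == KIND_CYLINDER
        np.add.at(out, (self.col_streamline[cyl], self.col_diam_idx[cyl]), x[cyl])
        return out

    def save(self, path):
        import h5py

        with h5py.File(path, "w") as fh:
            g = fh.create_group("A")
            g.create_dataset("data", data=self.A.data)
            g.create_dataset("indices", data=self.A.indices)
            g.create_dataset("indptr", data=self.A.indptr)
            g.attrs["shape"] = self.A.shape
            fh.create_dataset("voxel_index", data=self.voxel_index)
            fh.create_dataset("col_kind", data=self.col_kind)
            fh.create_dataset("col_streamline", data=self.col_streamline)
            fh.create_dataset("col_voxel", data=self.col_voxel)
            fh.create_dataset("col_diam_idx", data=self.col_diam_idx)
            fh.create_dataset("col_value", data=self.col_value)
            fh.create_dataset("grid_values", data=self.grid.values)
            fh.create_dataset("grid_included", data=self.grid.included)
            fh.attrs["n_meas"] = self.n_meas
            fh.attrs["n_streamlines"] = self.n_streamlines
            fh.attrs["skipped_streamlines"] = self.skipped_streamlines
            fh.attrs["d_par"] = self.config.d_par
            fh.attrs["d_iso"] = self.config.d_iso
            fh.attrs["d_perp_values"] = self.config.d_perp_values
            fh.attrs["zeppelin_mode"] = self.config.zeppelin_mode

    @classmethod
    def load(cls, path):
        import h5py

        with h5py.File(path, "r") as fh:
            g = fh["A"]
            A = sps.csr_matrix(
                (g["data"][:], g["indices"][:], g["indptr"][:]), shape=tuple(g.attrs["shape"])
            )
            grid = DiameterGrid(fh["grid_values"][:], fh["grid_included"][:].astype(bool))
            config = DictionaryConfig(
                d_par=float(fh.attrs["d_par"]),
                d_iso=float(fh.attrs["d_iso"]),
                d_perp_values=tuple(fh.attrs["d_perp_values"]),
                zeppelin_mode=str(fh.attrs["zeppelin_mode"]),
            )
            return cls(
                A=A, n_meas=int(fh.attrs["n_meas"]), voxel_index=fh["voxel_index"][:],
                grid=grid, config=config,
                col_kind=fh["col_kind"][:], col_streamline=fh["col_streamline"][:],
                col_voxel=fh["col_voxel"][:], col_diam_idx=fh["col_diam_idx"][:],
                col_value=fh["col_value"][:],
                n_streamlines=int(fh.attrs["n_streamlines"]),
                skipped_streamlines=int(fh.attrs["skipped_streamlines"]),
            )


def build_dictionary(
    streamlines,
    mask,
    scheme: AcquisitionScheme,
    grid: DiameterGrid | None = None,
    directions=None,
    config: DictionaryConfig | None = None,
    voxel_size=2.0,
) -> DictionaryOperator:
    """Assemble the sparse operator from a tractogram and per-voxel peaks.

    Parameters
    ----------
    streamlines : sequence of (P, 3) arrays, mm coordinates.
    mask : (nx, ny, nz) bool array of white-matter voxels.
    directions : (nx, ny, nz, k, 3) array of principal directions (NaN/zero
        rows ignored) used for the zeppelin/ball columns; see
        :func:`principal_directions`.  Voxels with streamline traffic but no
        direction fall back to the mean streamline tangent in that voxel.
    voxel_size : float, mm (isotropic).
    """
    if grid is None:
        grid = DiameterGrid.default()
    if config is None:
        config = DictionaryConfig()
    streamlines = list(streamlines)
    if len(streamlines) == 0:
        raise DictionaryError("empty tractogram")
    mask = np.asarray(mask, dtype=bool)
    shape = mask.shape
    n_meas = len(scheme)
    voxel_index = np.argwhere(mask)
    flat_to_row = -np.ones(mask.size, dtype=np.int64)
    flat_ids = np.ravel_multi_index(voxel_index.T, shape)
    flat_to_row[flat_ids] = np.arange(len(voxel_index))

    diam_m = grid.values * 1e-6
    n_d = len(grid)

    rows_parts, cols_parts, data_parts = [], [], []
    col_kind, col_sl, col_vox, col_didx, col_val = [], [], [], [], []
    n_cols = 0
    skipped = 0
    meas_arange = np.arange(n_meas, dtype=np.int64)

    tangent_traffic = {}  # voxel row -> [sum of tangents, total weight]

    for si, sl in enumerate(streamlines):
        vox, lens, tans = voxel_segments(sl, voxel_size, shape)
        if len(vox) == 0:
            skipped += 1
            continue
        rows_v = flat_to_row[np.ravel_multi_index(vox.T, shape)]
        ok = rows_v >= 0
        if not ok.any():
            skipped += 1
            continue
        rows_v, lens, tans = rows_v[ok], lens[ok], tans[ok]
        weights = lens / voxel_size
        for rv, w, t in zip(rows_v, weights, tans):
            acc = tangent_traffic.setdefault(int(rv), [np.zeros(3), 0.0])
            acc[0] += w * t
            acc[1] += w
        # group segments by tangent so each unique orientation costs one
        # signal evaluation (straight streamlines have a single tangent)
        tkey = np.round(tans, 6)
        _, first_idx, tangent_ids = np.unique(
            tkey, axis=0, return_index=True, return_inverse=True
        )
        blocks = cylinder_attenuation(
            np.repeat(diam_m, len(first_idx)),
            np.tile(tans[first_idx], (n_d, 1)),
            scheme,
            d_par=config.d_par,
        ).reshape(n_d, len(first_idx), n_meas)
        # entries: (segment, diameter, measurement)
        seg_data = weights[:, None, None] * np.transpose(blocks, (1, 0, 2))[tangent_ids]
        seg_rows = (rows_v[:, None] * n_meas + meas_arange[None, :])[:, None, :]
        seg_cols = (n_cols + np.arange(n_d, dtype=np.int64))[None, :, None]
        rows_parts.append(
            np.broadcast_to(seg_rows, seg_data.shape).ravel()
        )
        cols_parts.append(np.broadcast_to(seg_cols, seg_data.shape).ravel())
        data_parts.append(seg_data.ravel())
        col_kind.extend([KIND_CYLINDER] * n_d)
        col_sl.extend([si] * n_d)
        col_vox.extend([-1] * n_d)
        col_didx.extend(range(n_d))
        col_val.extend(grid.values)
        n_cols += n_d

    if skipped:
        log.info("skipped %d streamlines entirely outside the mask", skipped)
    if n_cols == 0:
        raise DictionaryError("no streamline intersects the mask")

    # zeppelin and ball columns, one set per voxel
    if directions is not None:
        directions = np.asarray(directions, dtype=float)
    ball_sig = ball_signal(BallSpec(config.d_iso), scheme)
    zep_cache = {}

    def zeppelin_set(direction):
        key = tuple(np.round(direction, 6))
        if key not in zep_cache:
            sigs = []
            if config.zeppelin_mode == "tensor":
                for dp in config.d_perp_values:
                    sigs.append(
                        (zeppelin_signal(ZeppelinSpec(config.d_par, dp, key), scheme), dp)
                    )
            else:  # stick + perpendicular-only decomposition
                cos2 = (scheme.directions @ np.asarray(key)) ** 2
                sigs.append((np.exp(-scheme.b * config.d_par * cos2), config.d_par))
                for dp in config.d_perp_values:
                    sigs.append((np.exp(-scheme.b * dp * (1 - cos2)), dp))
            zep_cache[key] = sigs
        return zep_cache[key]

    fallback = 0
    for vi, vox in enumerate(voxel_index):
        dirs_here = []
        if directions is not None:
            cand = directions[tuple(vox)]
            for d in np.atleast_2d(cand):
                if np.all(np.isfinite(d)) and np.linalg.norm(d) > 1e-8:
                    dirs_here.append(d / np.linalg.norm(d))
        if not dirs_here and vi in tangent_traffic:
            acc = tangent_traffic[vi]
            mean_t = acc[0] / max(acc[1], 1e-12)
            if np.linalg.norm(mean_t) > 1e-8:
                dirs_here.append(mean_t / np.linalg.norm(mean_t))
                fallback += 1
        rows_blk = vi * n_meas + meas_arange
        for di, d in enumerate(dirs_here):
            for sig, dp in zeppelin_set(d):
                rows_parts.append(rows_blk)
                cols_parts.append(np.full(n_meas, n_cols, dtype=np.int64))
                data_parts.append(sig)
                col_kind.append(KIND_ZEPPELIN)
                col_sl.append(-1)
                col_vox.append(vi)
                col_didx.append(-1)
                col_val.append(dp)
                n_cols += 1
        rows_parts.append(rows_blk)
        cols_parts.append(np.full(n_meas, n_cols, dtype=np.int64))
        data_parts.append(ball_sig)
        col_kind.append(KIND_BALL)
        col_sl.append(-1)
        col_vox.append(vi)
        col_didx.append(-1)
        col_val.append(config.d_iso)
        n_cols += 1
    if fallback:
        log.info("%d voxels used mean streamline tangent as direction fallback", fallback)

    A = sps.coo_matrix(
        (np.concatenate(data_parts), (np.concatenate(rows_parts), np.concatenate(cols_parts))),
        shape=(len(voxel_index) * n_meas, n_cols),
    ).tocsr()

    return DictionaryOperator(
        A=A, n_meas=n_meas, voxel_index=voxel_index, grid=grid, config=config,
        col_kind=np.asarray(col_kind, dtype=np.uint8),
        col_streamline=np.asarray(col_sl, dtype=np.int64),
        col_voxel=np.asarray(col_vox, dtype=np.int64),
        col_diam_idx=np.asarray(col_didx, dtype=np.int64),
        col_value=np.asarray(col_val, dtype=float),
        n_streamlines=len(streamlines),
        skipped_streamlines=skipped,
    )
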