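"""Model/Results interface to the streamline and voxel-wise estimators.

``BundleDiameterModel`` holds the data (signal volume, mask, tractogram,
acquisition scheme) and the dictionary configuration; ``fit()`` assembles
the sparse operator, solves the non-negative least-squares problem and
returns a ``BundleDiameterResults`` carrying coefficients, per-streamline
and per-bundle diameter indices, residual diagnostics and a ``summary()``
table.  ``VoxelwiseDiameterModel`` mirrors the interface for the per-voxel
baseline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dictionary import (
    DiameterGrid,
    DictionaryConfig,
    DictionaryOperator,
    build_dictionary,
    principal_directions,
)
from .metrics import ADIReport
from .phantom import PhantomVolume
from .scheme import AcquisitionScheme
from .solver import FitResult, fit as nnls_fit
from .voxelwise import VoxelFitMap, fit_volume

__all__ = [
    "BundleDiameterModel",
    "BundleDiameterResults",
    "VoxelwiseDiameterModel",
    "VoxelwiseDiameterResults",
]


class BundleDiameterModel:
    """Streamline-anchored Cylinder-Zeppelin-Ball model of a DW volume.

    Parameters
    ----------
    signal : (nx, ny, nz, n_meas) array
        DW attenuations (b=0-normalized).
    mask : (nx, ny, nz) bool array
    streamlines : sequence of (P, 3) arrays, mm
    scheme : AcquisitionScheme
    membership : sequence of hashable bundle labels per streamline, optional
    directions : (nx, ny, nz, k, 3) principal directions for the
        zeppelin/ball columns; defaults to mean streamline tangents.
    """

    def __init__(self, signal, mask, streamlines, scheme: AcquisitionScheme,
                 membership=None, grid: DiameterGrid | None = None,
                 directions=None, config: DictionaryConfig | None = None,
                 voxel_size=2.0):
        self.signal = np.asarray(signal, dtype=float)
        self.mask = np.asarray(mask, dtype=bool)
        self.streamlines = list(streamlines)
        self.scheme = scheme
        self.grid = grid if grid is not None else DiameterGrid.default()
        self.config = config if config is not None else DictionaryConfig()
        self.directions = directions
        self.voxel_size = float(voxel_size)
        if membership is None:
            membership = np.zeros(len(self.streamlines), dtype=int)
        self.membership = np.asarray(membership)
        if len(self.membership) != len(self.streamlines):
            raise ValueError("membership must label every streamline")
        if self.signal.shape[:3] != self.mask.shape:
            raise ValueError("signal and mask grids disagree")
        if self.signal.shape[3] != len(scheme):
            raise ValueError("signal and scheme measurement counts disagree")
        self._operator: DictionaryOperator | None = None

    @classmethod
    def from_phantom(cls, phantom: PhantomVolume, signal=None, streamlines=None,
                     membership=None, grid=None, config=None):
        """Build the model from a phantom, defaulting to its ground truth.

        ``signal`` overrides the phantom's noise-free volume (e.g. a noisy
        realization); ``streamlines`` overrides the ground-truth tractogram
        (e.g. surrogate-tracked trajectories), in which case ``membership``
        must be supplied.
        """
        if streamlines is None:
            streamlines = phantom.all_streamlines()
            membership = phantom.bundle_membership()
        elif membership is None:
            raise ValueError("membership is required with external streamlines")
        return cls(
            signal=phantom.signal if signal is None else signal,
            mask=phantom.mask,
            streamlines=streamlines,
            scheme=phantom.scheme,
            membership=membership,
            grid=grid,
            directions=principal_directions(phantom),
            config=config,
            voxel_size=phantom.voxel_size,
        )

    @property
    def operator(self) -> DictionaryOperator:
        """The sparse dictionary operator (assembled once, cached)."""
        if self._operator is None:
            self._operator = build_dictionary(
                self.streamlines, self.mask, self.scheme, self.grid,
                directions=self.directions, config=self.config,
                voxel_size=self.voxel_size,
            )
        return self._operator

    @property
    def endog(self) -> np.ndarray:
        """Concatenated masked voxel signals (the y of the linear model)."""
        op = self.operator
        sig = self.signal[tuple(op.voxel_index.T)]
        return sig.ravel()

    def fit(self, signal=None, **solver_options) -> "BundleDiameterResults":
        """Solve the NNLS problem; ``signal`` overrides the model volume."""
        op = self.operator
        if signal is not None:
            signal = np.asarray(signal, dtype=float)
            y = signal[tuple(op.voxel_index.T)].ravel()
        else:
            y = self.endog
        res = nnls_fit(op, y, **solver_options)
        return BundleDiameterResults(self, res, y)


class BundleDiameterResults:
    """Fitted coefficients, diameter indices and diagnostics."""

    def __init__(self, model: BundleDiameterModel, fit_result: FitResult, y):
        self.model = model
        self.fit_result = fit_result
        self._y = y
        self.report = ADIReport.from_fit(fit_result.x, model.operator, model.membership)

    @property
    def params(self) -> np.ndarray:
        return self.fit_result.x

    @property
    def streamline_sadi(self) -> np.ndarray:
        """Per-streamline diameter index (um, NaN where undefined)."""
        return self.report.streamline_sadi

    @property
    def bundle_adi(self) -> dict:
        return self.report.bundle_adi

    @property
    def bundle_distributions(self) -> dict:
        return self.report.bundle_distributions

    @property
    def relative_residual(self) -> float:
        ynorm = np.linalg.norm(self._y)
        return float(self.fit_result.residual_norm / ynorm) if ynorm else 0.0

    def compartment_fractions(self) -> dict:
        """Summed coefficients per compartment kind."""
        op = self.model.operator
        x = self.params
        return {
            "cylinder": float(x[op.col_kind == 0].sum()),
            "zeppelin": float(x[op.col_kind == 1].sum()),
            "ball": float(x[op.col_kind == 2].sum()),
        }

    def summary(self) -> str:
        op = self.model.operator
        rows = []
        for label, adi in self.bundle_adi.items():
            sel = self.report.membership == label
            sl = self.streamline_sadi[sel]
            rows.append(
                {
                    "bundle": label,
                    "n streamlines": int(sel.sum()),
                    "bundle ADI [um]": round(adi, 3) if np.isfinite(adi) else np.nan,
                    "median sADI [um]": round(float(np.nanmedian(sl)), 3)
                    if np.isfinite(sl).any() else np.nan,
                    "undefined sADI": int(np.isnan(sl).sum()),
                }
            )
        table = pd.DataFrame(rows).to_string(index=False)
        head = (
            "Streamline axon diameter index (NNLS dictionary fit)\n"
            f"  voxels: {op.n_voxels}  measurements/voxel: {op.n_meas}  "
            f"columns: {op.shape[1]}\n"
            f"  solver: {self.fit_result.method}, {self.fit_result.iterations} iter, "
            f"converged: {self.fit_result.converged}\n"
            f"  relative residual ||Ax-y||/||y||: {self.relative_residual:.4f}\n"
        )
        return head + table

    def plot_bundle_distributions(self, ax=None):
        """Bar plot of the per-bundle volume-weighted diameter distributions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = self.model.operator.grid
        n = len(self.bundle_distributions)
        width = 0.8 * (grid.values[1] - grid.values[0]) / max(n, 1)
        for k, (label, dist) in enumerate(self.bundle_distributions.items()):
            w = dist.weights / max(dist.weights.sum(), 1e-300)
            ax.bar(grid.values + (k - (n - 1) / 2) * width, w, width=width, label=str(label))
        ax.set_xlabel("cylinder diameter [um]")
        ax.set_ylabel("volume fraction")
        ax.legend()
        return ax


class VoxelwiseDiameterModel:
    """Per-voxel single-population Cylinder-Zeppelin-Ball baseline."""

    def __init__(self, signal, mask, directions, scheme: AcquisitionScheme,
                 grid: DiameterGrid | None = None,
                 config: DictionaryConfig | None = None):
        self.signal = np.asarray(signal, dtype=float)
        self.mask = np.asarray(mask, dtype=bool)
        self.directions = np.asarray(directions, dtype=float)
        self.scheme = scheme
        self.grid = grid if grid is not None else DiameterGrid.default()
        self.config = config if config is not None else DictionaryConfig()

    @classmethod
    def from_phantom(cls, phantom: PhantomVolume, signal=None, grid=None, config=None):
        """Single-direction baseline on a phantom.

        In crossing voxels the direction of the stronger bundle (larger
        intra fraction) is used — the baseline deliberately assumes one
        fiber population per voxel.
        """
        dirs2 = principal_directions(phantom)
        stronger = np.nanargmax(
            np.where(phantom.intra_fractions > 0, phantom.intra_fractions, -1), axis=-1
        )
        single = np.take_along_axis(
            dirs2, stronger[..., None, None], axis=3
        )[..., 0, :]
        return cls(
            signal=phantom.signal if signal is None else signal,
            mask=phantom.mask,
            directions=single,
            scheme=phantom.scheme,
            grid=grid,
            config=config,
        )

    def fit(self, voxels=None, **options) -> "VoxelwiseDiameterResults":
        vmap = fit_volume(
            self.signal, self.directions, self.mask, self.scheme,
            self.grid, self.config, voxels=voxels, **options
        )
        return VoxelwiseDiameterResults(self, vmap)


class VoxelwiseDiameterResults:
    """ADI map and summaries of the voxel-wise baseline."""

    def __init__(self, model: VoxelwiseDiameterModel, vmap: VoxelFitMap):
        self.model = model
        self.map = vmap

    @property
    def adi_map(self) -> np.ndarray:
        return self.map.adi

    def region_mean(self, labels, label) -> float:
        return self.map.region_mean(labels, label)

    def summary(self) -> str:
        finite = np.isfinite(self.map.adi)
        vals = self.map.adi[finite]
        head = (
            "Voxel-wise axon diameter index (single fiber population)\n"
            f"  fitted voxels: {self.map.n_fitted}  undefined ADI: {self.map.n_undefined}\n"
        )
        if len(vals):
            head += (
                f"  ADI [um]: mean {vals.mean():.3f}  median {np.median(vals):.3f}  "
                f"range [{vals.min():.3f}, {vals.max():.3f}]\n"
            )
        return head

    def to_nifti(self, affine=None):
        import nibabel as nib

        if affine is None:
            affine = np.eye(4)
        return nib.Nifti1Image(self.map.adi.astype(np.float32), affine)
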