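"""Pulsed-gradient spin-echo (PGSE) acquisition schemes.

A measurement is described by a unit gradient direction, the gradient
amplitude ``G``, the pulse duration ``delta`` and the pulse separation
``Delta``.  The diffusion weighting follows the Stejskal-Tanner relation

    b = (gamma * G * delta)**2 * (Delta - delta / 3)

All quantities are kept in SI units internally (T/m, s, s/m^2); helper
properties convert to the conventional mT/m, ms and s/mm^2 for display.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GYROMAGNETIC_RATIO = 2.6752e8

__all__ = [
    "GYROMAGNETIC_RATIO",
    "Measurement",
    "AcquisitionScheme",
    "compute_bvalue",
    "connectom_protocol",
    "read_scheme",
    "write_scheme",
    "sphere_directions",
]


class SchemeError(ValueError):
    """Raised for invalid or inconsistent acquisition protocols."""


def compute_bvalue(G, delta, Delta, gamma=GYROMAGNETIC_RATIO):
    """b-value (s/m^2) of a rectangular PGSE pulse pair.

    Parameters
    ----------
    G : float or array
        Gradient amplitude in T/m.  ``G = 0`` gives ``b = 0``.
    delta, Delta : float or array
        Pulse duration and separation in seconds; requires ``delta < Delta``.
    gamma : float
        Gyromagnetic ratio in rad s^-1 T^-1.
    """
    G = np.asarray(G, dtype=float)
    delta = np.asarray(delta, dtype=float)
    Delta = np.asarray(Delta, dtype=float)
    if np.any(delta <= 0) or np.any(Delta <= 0):
        raise SchemeError("pulse timings must be positive")
    if np.any(delta >= Delta):
        raise SchemeError("pulse duration delta must be shorter than separation Delta")
    if np.any(G < 0):
        raise SchemeError("gradient amplitude must be non-negative")
    return (gamma * G * delta) ** 2 * (Delta - delta / 3.0)


@dataclass(frozen=True)
class Measurement:
    """One DW measurement: direction (unit 3-vector), G (T/m), delta/Delta (s)."""

    direction: np.ndarray
    G: float
    delta: float
    Delta: float

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        object.__setattr__(self, "direction", d)
        if self.G > 0:
            n = np.linalg.norm(d)
            if abs(n - 1.0) > 1e-3:
                raise SchemeError("gradient direction must be a unit vector for b > 0")
            object.__setattr__(self, "direction", d / n)
        compute_bvalue(self.G, self.delta, self.Delta)  # validates timings

    @property
    def b(self) -> float:
        """b-value in s/m^2."""
        return float(compute_bvalue(self.G, self.delta, self.Delta))


class AcquisitionScheme:
    """Ordered collection of PGSE measurements.

    Parameters
    ----------
    directions : (n, 3) array
        Gradient directions; ignored (zeroed) where ``G == 0``.
    G, delta, Delta : (n,) arrays
        Amplitudes (T/m) and timings (s).
    gamma : float
        Gyromagnetic ratio, rad s^-1 T^-1.
    """

    def __init__(self, directions, G, delta, Delta, gamma=GYROMAGNETIC_RATIO):
        directions = np.atleast_2d(np.asarray(directions, dtype=float))
        G = np.asarray(G, dtype=float).ravel()
        delta = np.asarray(delta, dtype=float).ravel()
        Delta = np.asarray(Delta, dtype=float).ravel()
        n = len(G)
        if directions.shape != (n, 3) or len(delta) != n or len(Delta) != n:
            raise SchemeError("directions, G, delta, Delta must have matching lengths")
        compute_bvalue(G, delta, Delta, gamma)
        dw = G > 0
        norms = np.linalg.norm(directions, axis=1)
        if np.any(np.abs(norms[dw] - 1.0) > 1e-3):
            bad = int(np.nonzero(dw & (np.abs(norms - 1.0) > 1e-3))[0][0])
            raise SchemeError(f"non-unit gradient direction at row {bad}")
        directions = directions.copy()
        # renormalize only real deviations; keep file-precision vectors
        # byte-stable under write -> read -> write round trips
        renorm = dw & (np.abs(norms - 1.0) > 5e-6)
        directions[renorm] /= norms[renorm, None]
        directions[~dw] = 0.0
        if not np.any(~dw):
            raise SchemeError("scheme must contain at least one b=0 measurement")
        self.directions = directions
        self.G = G
        self.delta = delta
        self.Delta = Delta
        self.gamma = float(gamma)

    def __len__(self):
        return len(self.G)

    @property
    def b(self) -> np.ndarray:
        """b-values in s/m^2."""
        return compute_bvalue(self.G, self.delta, self.Delta, self.gamma)

    @property
    def b_smm2(self) -> np.ndarray:
        """b-values in the conventional s/mm^2."""
        return self.b * 1e-6

    @property
    def b0_mask(self) -> np.ndarray:
        return self.G == 0

    @property
    def b0_indices(self) -> np.ndarray:
        return np.nonzero(self.b0_mask)[0]

    def shells(self, b_rtol=0.05):
        """Group DW measurements into shells by (b, Delta).

        Returns a list of ``(b_mean, Delta, indices)`` tuples, b0 excluded.
        """
        out = []
        b = self.b
        taken = np.zeros(len(self), dtype=bool)
        for i in np.argsort(b):
            if taken[i] or self.G[i] == 0:
                continue
            same = (
                ~taken
                & (self.G > 0)
                & (np.abs(b - b[i]) <= b_rtol * max(b[i], 1.0))
                & (np.abs(self.Delta - self.Delta[i]) < 1e-6)
            )
            idx = np.nonzero(same)[0]
            taken[idx] = True
            out.append((float(b[idx].mean()), float(self.Delta[i]), idx))
        return out

    @property
    def measurements(self):
        return [
            Measurement(self.directions[i], float(self.G[i]), float(self.delta[i]), float(self.Delta[i]))
            for i in range(len(self))
        ]


def sphere_directions(n, offset=0):
    """``n`` roughly uniform unit vectors from a golden-spiral lattice."""
    i = np.arange(n) + 0.5
    polar = np.arccos(1.0 - 2.0 * i / n)
    azim = np.pi * (1.0 + np.sqrt(5.0)) * (i + offset)
    return np.column_stack(
        [np.sin(polar) * np.cos(azim), np.sin(polar) * np.sin(azim), np.cos(polar)]
    )


#: (b [s/mm^2], delta [ms], Delta [ms], G [mT/m], n directions) per shell of the
#: 300 mT/m Connectom protocol used throughout: two b-values at four diffusion
#: times.  The printed b-values are nominal; b is always recomputed from
#: (G, delta, Delta).
CONNECTOM_SHELLS = (
    (1000, 7.0, 17.3, 138.0, 30),
    (4000, 7.0, 17.3, 276.0, 60),
    (1000, 7.0, 30.0, 102.0, 30),
    (4000, 7.0, 30.0, 203.0, 60),
    (1000, 7.0, 42.0, 85.0, 30),
    (4000, 7.0, 42.0, 169.0, 60),
    (1000, 7.0, 55.0, 74.0, 30),
    (4000, 7.0, 55.0, 175.0, 60),
)


def connectom_protocol(n_b0=5, gamma=GYROMAGNETIC_RATIO):
    """The 8-shell, 4-diffusion-time protocol plus ``n_b0`` b=0 images.

    30 directions per b=1000 shell and 60 per b=4000 shell (365 measurements
    for the default ``n_b0 = 5``).  Directions are deterministic golden-spiral
    point sets, rotated per shell so that shells do not share directions.
    """
    dirs, G, delta, Delta = [], [], [], []
    for k, (_b, d_ms, D_ms, g_mt, ndir) in enumerate(CONNECTOM_SHELLS):
        dirs.append(sphere_directions(ndir, offset=0.37 * k))
        G.append(np.full(ndir, g_mt * 1e-3))
        delta.append(np.full(ndir, d_ms * 1e-3))
        Delta.append(np.full(ndir, D_ms * 1e-3))
    dirs.append(np.zeros((n_b0, 3)))
    G.append(np.zeros(n_b0))
    delta.append(np.full(n_b0, 7e-3))
    Delta.append(np.full(n_b0, 17.3e-3))
    return AcquisitionScheme(
        np.vstack(dirs), np.concatenate(G), np.concatenate(delta), np.concatenate(Delta), gamma
    )


# ---------------------------------------------------------------------------
# I/O: Camino-style text and FSL bval/bvec + JSON timing sidecar
# ---------------------------------------------------------------------------

def write_scheme(scheme: AcquisitionScheme, path):
    """Write a Camino-style scheme file (x y z G Delta delta TE, SI units)."""
    path = Path(path)
    te = scheme.Delta + 2 * scheme.delta  # nominal echo time lower bound
    with open(path, "w") as fh:
        fh.write("VERSION: STEJSKALTANNER\n")
        for i in range(len(scheme)):
            d = scheme.directions[i]
            fh.write(
                f"{d[0]:.6g} {d[1]:.6g} {d[2]:.6g} "
                f"{scheme.G[i]:.6g} {scheme.Delta[i]:.6g} {scheme.delta[i]:.6g} {te[i]:.6g}\n"
            )


def read_scheme(path, gamma=GYROMAGNETIC_RATIO) -> AcquisitionScheme:
    """Read a Camino-style scheme file written by :func:`write_scheme`."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh):
            line = line.strip()
            if not line or line.upper().startswith("VERSION"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SchemeError(f"{path}: row {ln}: expected 7 columns, got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise SchemeError(f"{path}: row {ln}: {exc}") from None
    if not rows:
        raise SchemeError(f"{path}: empty scheme file")
    arr = np.asarray(rows)
    try:
        return AcquisitionScheme(arr[:, :3], arr[:, 3], arr[:, 5], arr[:, 4], gamma)
    except SchemeError as exc:
        raise SchemeError(f"{path}: {exc}") from None


def write_bval_bvec(scheme: AcquisitionScheme, prefix):
    """Write FSL ``<prefix>.bval``/``.bvec`` plus ``<prefix>.timing.json``.

    bvals are in s/mm^2; bvecs one column per measurement in the image frame.
    The sidecar stores per-shell (b, delta, Delta) in ms so that the timing
    information lost by the bval/bvec convention can be recovered.
    """
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".bval"), scheme.b_smm2[None], fmt="%.6g")
    np.savetxt(prefix.with_suffix(".bvec"), scheme.directions.T, fmt="%.6g")
    shells = []
    shell_of = np.full(len(scheme), -1, dtype=int)
    for k, (bm, _D, idx) in enumerate(scheme.shells()):
        shell_of[idx] = k
        shells.append(
            {
                "b_smm2": round(bm * 1e-6, 6),
                "delta_ms": scheme.delta[idx[0]] * 1e3,
                "Delta_ms": scheme.Delta[idx[0]] * 1e3,
                "G_mTm": scheme.G[idx[0]] * 1e3,
            }
        )
    sidecar = {
        "gamma": scheme.gamma,
        "shells": shells,
        # shells sharing b (same b at two diffusion times) cannot be told apart
        # from the bval file, so the shell of every measurement is stored
        "shell_per_measurement": shell_of.tolist(),
        "b0": {
            "delta_ms": float(scheme.delta[scheme.b0_indices[0]] * 1e3),
            "Delta_ms": float(scheme.Delta[scheme.b0_indices[0]] * 1e3),
        },
    }
    with open(prefix.with_suffix(".timing.json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_bval_bvec(prefix, gamma=GYROMAGNETIC_RATIO) -> AcquisitionScheme:
    """Read a scheme written by :func:`write_bval_bvec`."""
    prefix = Path(prefix)
    bval = np.loadtxt(prefix.with_suffix(".bval")).ravel()
    bvec = np.loadtxt(prefix.with_suffix(".bvec"))
    if bvec.shape[0] != 3:
        raise SchemeError(f"{prefix}.bvec: expected 3 rows, got {bvec.shape[0]}")
    if bvec.shape[1] != len(bval):
        raise SchemeError(f"{prefix}: bval/bvec length mismatch")
    with open(prefix.with_suffix(".timing.json")) as fh:
        sidecar = json.load(fh)
    g = sidecar.get("gamma", gamma)
    n = len(bval)
    shell_of = np.asarray(sidecar["shell_per_measurement"], dtype=int)
    if len(shell_of) != n:
        raise SchemeError(f"{prefix}: sidecar shell map length mismatch")
    G = np.zeros(n)
    delta = np.full(n, sidecar["b0"]["delta_ms"] * 1e-3)
    Delta = np.full(n, sidecar["b0"]["Delta_ms"] * 1e-3)
    for k, sh in enumerate(sidecar["shells"]):
        sel = shell_of == k
        G[sel] = sh["G_mTm"] * 1e-3
        delta[sel] = sh["delta_ms"] * 1e-3
        Delta[sel] = sh["Delta_ms"] * 1e-3
    scheme = AcquisitionScheme(bvec.T, G, delta, Delta, g)
    mismatch = np.abs(scheme.b_smm2 - bval) > 0.01 * np.maximum(bval, 1.0)
    if np.any(mismatch):
        raise SchemeError(
            f"{prefix}: stored b-values disagree with sidecar timings at "
            f"{int(mismatch.sum())} measurements (first row {int(np.nonzero(mismatch)[0][0])})"
        )
    return scheme
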