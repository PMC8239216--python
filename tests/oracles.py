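"""Independent oracles used by the test suite.

These implementations deliberately avoid the code paths they check: the
cylinder attenuation is re-derived by brute-force Monte-Carlo random walk,
the Watson second moment by 1-D quadrature, and the ground-truth
coefficient vector by direct geometric construction from the phantom's
generating parameters.
"""

import numpy as np
from scipy.integrate import quad

from axsize.scheme import GYROMAGNETIC_RATIO as GAMMA
from axsize.signals import D_PARALLEL


def mc_cylinder_perp_attenuation(diameter_m, G, delta, Delta, D=D_PARALLEL,
                                 n_walkers=100_000, dt=2e-5, seed=0):
    """PGSE attenuation perpendicular to an impermeable cylinder by a
    reflecting 2-D Brownian walk (>= 1e5 walkers).

    Phase accrues as ``gamma * G * x(t) * dt`` with +G during the first
    pulse and -G during the second; walkers leaving the disk are mirrored
    radially (adequate for steps much smaller than the radius).
    """
    rng = np.random.default_rng(seed)
    R = diameter_m / 2.0
    u = rng.random(n_walkers)
    th = rng.random(n_walkers) * 2.0 * np.pi
    r0 = R * np.sqrt(u)
    pos = np.column_stack([r0 * np.cos(th), r0 * np.sin(th)])
    sigma = np.sqrt(2.0 * D * dt)
    n_steps = int(np.ceil((Delta + delta) / dt))
    phase = np.zeros(n_walkers)
    for k in range(n_steps):
        t = k * dt
        pos += rng.standard_normal((n_walkers, 2)) * sigma
        rad = np.hypot(pos[:, 0], pos[:, 1])
        out = rad > R
        if out.any():
            pos[out] *= ((2.0 * R - rad[out]) / rad[out])[:, None]
        if t < delta:
            phase += GAMMA * G * pos[:, 0] * dt
        elif Delta <= t < Delta + delta:
            phase -= GAMMA * G * pos[:, 0] * dt
    return float(np.mean(np.cos(phase)))


def watson_second_moment(kappa):
    """E[(mu.n)^2] of the Watson distribution by 1-D quadrature."""
    num = quad(lambda t: t**2 * np.exp(kappa * t**2), 0.0, 1.0)[0]
    den = quad(lambda t: np.exp(kappa * t**2), 0.0, 1.0)[0]
    return num / den


def gamma_volume_weighted_mean_diameter(shape, scale):
    """2 E[r^3] / E[r^2] of a gamma radius law by numerical integration."""
    from scipy.stats import gamma as gamma_dist

    pdf = gamma_dist(shape, scale=scale).pdf
    num = quad(lambda r: 2.0 * r * r**2 * pdf(r), 0.0, np.inf)[0]
    den = quad(lambda r: r**2 * pdf(r), 0.0, np.inf)[0]
    return num / den


def nearest_bin_projection(diameters, grid):
    """Histogram equal-weight diameter draws onto the grid's nearest bins."""
    edges = np.r_[0.0, (grid.values[:-1] + grid.values[1:]) / 2.0, np.inf]
    w = np.histogram(diameters, bins=edges)[0].astype(float)
    return w / w.sum()


def ground_truth_coefficients(phantom, model):
    """Construct a feasible x >= 0 from the phantom's generating truth.

    Cylinder coefficients: each streamline of a bundle carries the bundle's
    intra fraction divided by the mean per-voxel streamline traffic of the
    bundle, distributed over diameter bins by the nearest-bin projection of
    the generator's volume-weighted diameter draws.  Zeppelin/ball
    coefficients: per-voxel exact non-negative least squares on the residual
    after subtracting the cylinder part (an existence construction for the
    voxel compartments; the cylinder part is fixed by the ground truth).
    """
    from scipy.optimize import nnls

    from axsize.dictionary import KIND_CYLINDER, voxel_segments

    op = model.operator
    membership = model.membership
    x = np.zeros(op.shape[1])

    # per-bundle mean traffic (sum of length weights per voxel)
    traffic = {}
    for si, sl in enumerate(model.streamlines):
        vox, lens, _ = voxel_segments(sl, model.voxel_size, phantom.shape)
        label = membership[si]
        acc = traffic.setdefault(label, {})
        for v, ln in zip(map(tuple, vox), lens):
            acc[v] = acc.get(v, 0.0) + ln / model.voxel_size

    for bi, bundle in enumerate(phantom.bundles):
        label = bundle.name
        mean_traffic = np.mean(list(traffic[label].values()))
        w_bin = nearest_bin_projection(bundle.diameter_draws(), op.grid)
        coeff = bundle.intra_fraction * w_bin / mean_traffic
        members = np.nonzero(membership == label)[0]
        cyl = op.col_kind == KIND_CYLINDER
        for si in members:
            cols = np.nonzero(cyl & (op.col_streamline == si))[0]
            x[cols] = coeff[op.col_diam_idx[cols]]

    # voxel compartments: restricted NNLS on the cylinder-part residual
    y = model.endog
    resid = y - op.A @ x
    n_meas = op.n_meas
    for vi in range(op.n_voxels):
        cols = np.nonzero((op.col_kind != KIND_CYLINDER) & (op.col_voxel == vi))[0]
        if len(cols) == 0:
            continue
        rows = slice(vi * n_meas, (vi + 1) * n_meas)
        Ad = op.A[rows][:, cols].toarray()
        xv, _ = nnls(Ad, resid[rows])
        x[cols] = xv
    return x
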