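"""Surface morphometry on the unfolded grid.

Three per-vertex features drive inter-sample registration: laminar
thickness (mm, streamline length through the laminar Laplace field),
gyrification (dimensionless native/unfolded area ratio — the extent of
tissue distortion between folded and unfolded space), and mean curvature
of the mid-thickness surface (1/mm, signed toward the outer side).
Features are z-scored per channel so that "equal weighting" across
heterogeneous units is meaningful during multi-channel registration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import UnfoldedMap
from .unfolding import CoordinateFields, SurfaceGrid, fill_nearest


def smooth_nan(values: np.ndarray, sigma_px) -> np.ndarray:
    """Gaussian smoothing that ignores NaNs (normalized convolution)."""
    vals = np.asarray(values, float)
    mask = np.isfinite(vals)
    if not mask.any():
        return vals.copy()
    num = ndimage.gaussian_filter(np.where(mask, vals, 0.0), sigma_px,
                                  mode="nearest")
    den = ndimage.gaussian_filter(mask.astype(float), sigma_px,
                                  mode="nearest")
    out = np.where(den > 1e-12, num / np.maximum(den, 1e-12), np.nan)
    out[~mask & (den <= 1e-12)] = np.nan
    return out


# ---------------------------------------------------------------------------
# thickness

def compute_thickness(coords: CoordinateFields, grid: SurfaceGrid,
                      step_frac: float = 0.25,
                      max_factor: float = 10.0) -> UnfoldedMap:
    """Streamline thickness through the laminar Laplace field.

    From each mid-thickness vertex the gradient of the laminar field is
    integrated (RK4) toward both boundaries; the sum of the two arc
    lengths is the local thickness in mm.  Runaway streamlines (longer
    than ``max_factor`` times the slab-average thickness estimate) are
    marked invalid.
    """
    if not np.isfinite(coords.io).any():
        raise ValueError("laminar (io) field has no finite values")
    affine = np.asarray(coords.affine)
    spacing = coords.spacing
    step_mm = step_frac * float(spacing.min())

    io_filled = np.clip(fill_nearest(coords.io, coords.mask), 0.0, 1.0)
    grad = np.stack(np.gradient(io_filled), axis=0)  # voxel units
    inv3 = np.linalg.inv(affine)[:3, :3]
    gray = coords.mask.astype(np.float64)

    def world_to_vox(p):
        return p @ inv3.T + np.linalg.inv(affine)[:3, 3]

    def unit_grad_world(p_world):
        vox = world_to_vox(p_world)
        g = np.stack([ndimage.map_coordinates(grad[k], vox.T, order=1,
                                              mode="nearest")
                      for k in range(3)], axis=-1)
        gw = g @ inv3  # A^{-T} g_vox
        n = np.linalg.norm(gw, axis=-1, keepdims=True)
        n[n < 1e-12] = 1.0
        return gw / n

    def in_gray(p_world):
        vox = world_to_vox(p_world)
        return ndimage.map_coordinates(gray, vox.T, order=0,
                                       mode="constant", cval=0.0) > 0.5

    def io_at(p_world):
        vox = world_to_vox(p_world)
        return ndimage.map_coordinates(io_filled, vox.T, order=1,
                                       mode="nearest")

    start = grid.native_xyz.reshape(-1, 3)
    # slab estimate: gray volume / mid-surface area
    areas = _native_quad_areas(grid)
    total_area = np.nansum(areas)
    gray_vol = coords.mask.sum() * float(np.prod(spacing))
    slab_est = gray_vol / max(total_area, 1e-9)
    max_len = max_factor * max(slab_est, float(spacing.min()))
    max_steps = int(np.ceil(max_len / step_mm)) + 2

    def trace(direction: float) -> np.ndarray:
        pos = start.copy()
        length = np.zeros(len(pos))
        active = in_gray(pos)
        length[~active] = np.nan
        for _ in range(max_steps):
            if not active.any():
                break
            p = pos[active]
            h = step_mm * direction
            k1 = unit_grad_world(p)
            k2 = unit_grad_world(p + 0.5 * h * k1)
            k3 = unit_grad_world(p + 0.5 * h * k2)
            k4 = unit_grad_world(p + h * k3)
            newp = p + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            io_new = io_at(newp)
            inside = in_gray(newp) & (io_new > 0.01) & (io_new < 0.99)
            # bisect the exit point to sub-step precision
            exited = ~inside
            if exited.any():
                lo = p[exited]
                hi_ = newp[exited]
                for _b in range(4):
                    mid = 0.5 * (lo + hi_)
                    mio = io_at(mid)
                    min_ = in_gray(mid) & (mio > 0.01) & (mio < 0.99)
                    lo = np.where(min_[:, None], mid, lo)
                    hi_ = np.where(min_[:, None], hi_, mid)
                seg = np.linalg.norm(0.5 * (lo + hi_) - p[exited], axis=1)
            act_idx = np.flatnonzero(active)
            length[act_idx[exited]] += seg if exited.any() else 0.0
            length[act_idx[inside]] += step_mm
            pos[act_idx] = newp
            nxt = np.zeros_like(active)
            nxt[act_idx[inside]] = True
            active = nxt
        length[active] = np.nan  # never terminated within the cap
        return length

    thick = trace(+1.0) + trace(-1.0)
    thick = np.where(thick > max_len, np.nan, thick)
    return UnfoldedMap(values=thick.reshape(grid.shape),
                       spacing=grid.spacing, channel="thickness", units="mm")


# ---------------------------------------------------------------------------
# gyrification

def _smoothed_xyz(grid: SurfaceGrid, presmooth_mm: float) -> np.ndarray:
    """Denoise node coordinates (scattered-interpolation jitter inflates
    native areas and curvature); NaN-aware smoothing in unfolded space."""
    if presmooth_mm <= 0:
        return grid.native_xyz
    sig = (presmooth_mm / grid.spacing[0], presmooth_mm / grid.spacing[1])
    P = np.where(grid.valid[..., None], grid.native_xyz, np.nan)
    sm = np.stack([smooth_nan(P[..., k], sig) for k in range(3)], axis=-1)
    return np.where(np.isfinite(sm).all(axis=-1, keepdims=True), sm,
                    grid.native_xyz)


def _native_quad_areas(grid: SurfaceGrid,
                       presmooth_mm: float = 0.0) -> np.ndarray:
    """Area (mm^2) of each native grid quad; NaN if any corner invalid."""
    P = _smoothed_xyz(grid, presmooth_mm)
    V = grid.valid
    a, b = P[:-1, :-1], P[1:, :-1]
    c, d = P[1:, 1:], P[:-1, 1:]
    t1 = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=-1)
    t2 = 0.5 * np.linalg.norm(np.cross(c - a, d - a), axis=-1)
    area = t1 + t2
    ok = V[:-1, :-1] & V[1:, :-1] & V[1:, 1:] & V[:-1, 1:]
    return np.where(ok, area, np.nan)


def compute_gyrification(grid: SurfaceGrid, sigma_mm: float = 1.0,
                         presmooth_mm: float = 0.5) -> UnfoldedMap:
    """Native/unfolded area ratio per vertex (folding = values > 1).

    Each quad's native area is split equally among its four corners; the
    matching unfolded dual-cell area is the same quarter-count of unfolded
    pixels, so boundary vertices are handled consistently.
    """
    areas = _native_quad_areas(grid, presmooth_mm)
    na, npd = grid.shape
    native = np.zeros((na, npd))
    count = np.zeros((na, npd))
    ok = np.isfinite(areas)
    q = np.where(ok, areas, 0.0)
    for di, dj in ((0, 0), (1, 0), (0, 1), (1, 1)):
        native[di:na - 1 + di, dj:npd - 1 + dj] += q / 4.0
        count[di:na - 1 + di, dj:npd - 1 + dj] += ok / 4.0
    pixel_area = grid.spacing[0] * grid.spacing[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        gi = native / (count * pixel_area)
    gi[count == 0] = np.nan
    degenerate = np.isfinite(gi) & (gi <= 0)
    gi[degenerate] = np.nan
    sigma_px = (sigma_mm / grid.spacing[0], sigma_mm / grid.spacing[1])
    return UnfoldedMap(values=smooth_nan(gi, sigma_px),
                       spacing=grid.spacing, channel="gyrification",
                       units="")


# ---------------------------------------------------------------------------
# curvature

def compute_curvature(grid: SurfaceGrid, sigma_mm: float = 1.0,
                      half_width: int = 2,
                      presmooth_mm: float = 0.75,
                      h_max: float = 1.0) -> UnfoldedMap:
    """Mean curvature H by quadric fitting over 5x5 grid neighborhoods.

    Each vertex's neighbors are expressed in a local frame whose z axis is
    the outward (io = 1) normal; a quadric z = ax^2 + bxy + cy^2 + dx +
    ey + f is fit and H = a + c.  Positive H: the surface bends toward the
    outer side.  Neighbors whose outward normal disagrees with the
    center's (tight curls fold the grid neighborhood back on itself) are
    excluded, and |H| > ``h_max`` (1/mm) is treated as a failed fit.
    """
    P = _smoothed_xyz(grid, presmooth_mm)
    n_hat = grid.normals
    na, npd = grid.shape
    k = 2 * half_width + 1

    def windows(arr3):
        pad = np.full((na + 2 * half_width, npd + 2 * half_width, 3), np.nan)
        pad[half_width:half_width + na, half_width:half_width + npd] = arr3
        win = np.lib.stride_tricks.sliding_window_view(pad, (k, k),
                                                       axis=(0, 1))
        # (na, npd, 3, k, k) -> (na, npd, k*k, 3)
        return win.transpose(0, 1, 3, 4, 2).reshape(na, npd, k * k, 3)

    nb = windows(np.where(grid.valid[..., None], P, np.nan))
    nb_n = windows(np.where(grid.valid[..., None], n_hat, np.nan))

    d = nb - P[:, :, None, :]
    # local tangent frame orthogonal to the outward normal
    ref = np.zeros_like(n_hat)
    ref[..., 0] = 1.0
    swap = np.abs(n_hat[..., 0]) > 0.9
    ref[swap] = [0.0, 1.0, 0.0]
    t1 = np.cross(n_hat, ref)
    t1 /= np.maximum(np.linalg.norm(t1, axis=-1, keepdims=True), 1e-12)
    t2 = np.cross(n_hat, t1)

    x = np.einsum("ijkl,ijl->ijk", d, t1)
    y = np.einsum("ijkl,ijl->ijk", d, t2)
    z = np.einsum("ijkl,ijl->ijk", d, n_hat)
    agree = np.einsum("ijkl,ijl->ijk", np.nan_to_num(nb_n), n_hat) > 0.3
    w = np.isfinite(z) & np.isfinite(x) & np.isfinite(y) & agree
    x = np.nan_to_num(x)
    y = np.nan_to_num(y)
    z = np.nan_to_num(z)

    A = np.stack([x ** 2, x * y, y ** 2, x, y, np.ones_like(x)], axis=-1)
    A = A * w[..., None]
    zw = z * w
    AtA = np.einsum("ijkm,ijkn->ijmn", A, A)
    Atz = np.einsum("ijkm,ijk->ijm", A, zw)
    AtA += 1e-10 * np.eye(6)
    coef = np.linalg.solve(AtA, Atz[..., None])[..., 0]
    H = coef[..., 0] + coef[..., 2]
    H[w.sum(axis=-1) < 8] = np.nan
    H[np.abs(H) > h_max] = np.nan
    H[~grid.valid] = np.nan

    sigma_px = (sigma_mm / grid.spacing[0], sigma_mm / grid.spacing[1])
    return UnfoldedMap(values=smooth_nan(H, sigma_px),
                       spacing=grid.spacing, channel="curvature",
                       units="1/mm")


# ---------------------------------------------------------------------------
# feature stacks

@dataclass
class FeatureStack:
    """Named, co-registered unfolded feature channels.

    After standardization every channel is z-scored over originally valid
    pixels (mean 0, sd 1); the record allows inversion back to physical
    units.
    """

    channels: dict  # name -> UnfoldedMap
    standardization: dict = field(default_factory=dict)  # name -> (mean, sd)
    valid: np.ndarray | None = None

    @property
    def names(self) -> list[str]:
        return list(self.channels)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def as_array(self) -> np.ndarray:
        return np.stack([np.asarray(m.values, float)
                         for m in self.channels.values()])

    def subset(self, names) -> "FeatureStack":
        return FeatureStack(
            channels={n: self.channels[n] for n in names},
            standardization={n: self.standardization[n] for n in names
                             if n in self.standardization},
            valid=self.valid)


def prepare_feature_stack(maps: dict, sigma_mm: float = 0.0,
                          standardize: bool = True) -> FeatureStack:
    """Fill, optionally smooth, and z-score feature channels.

    NaN pixels are filled from the nearest valid pixel before
    standardization so registration sees finite values everywhere; the
    per-channel (mean, sd) over originally valid pixels is retained.
    """
    shapes = {m.shape for m in maps.values()}
    if len(shapes) != 1:
        raise ValueError(f"channel grids differ: {shapes}")
    out = {}
    record = {}
    valid_all = None
    for name, m in maps.items():
        vals = np.asarray(m.values, float)
        finite = np.isfinite(vals)
        if not finite.any():
            raise ValueError(f"channel {name!r} has no valid pixels")
        valid_all = finite if valid_all is None else (valid_all & finite)
        filled = fill_nearest(vals)
        if sigma_mm > 0:
            sig = (sigma_mm / m.spacing[0], sigma_mm / m.spacing[1])
            filled = ndimage.gaussian_filter(filled, sig, mode="nearest")
        mu = float(filled[finite].mean())
        sd = float(filled[finite].std())
        if standardize:
            if sd < 1e-12:
                raise ValueError(f"channel {name!r} has zero variance")
            filled = (filled - mu) / sd
        record[name] = (mu, sd)
        out[name] = UnfoldedMap(values=filled, spacing=m.spacing,
                                channel=m.channel, units=m.units)
    return FeatureStack(channels=out, standardization=record, valid=valid_all)


def compute_features(coords: CoordinateFields, grid: SurfaceGrid,
                     sigma_mm: float = 1.0) -> dict:
    """Convenience: the three standard morphometric channels."""
    return {"thickness": compute_thickness(coords, grid),
            "gyrification": compute_gyrification(grid, sigma_mm=sigma_mm),
            "curvature": compute_curvature(grid, sigma_mm=sigma_mm)}
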