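"""Dimension-generic multi-channel diffeomorphic registration.

A greedy demons-style optimizer over a stationary velocity field drives
both the 2D unfolded registration (multi-channel morphometric features)
and the 3D volumetric control (single-channel binary masks).  The
displacement field is obtained from the velocity by scaling and squaring,
which keeps the transform invertible (positive Jacobian determinant).
Sampling clamps at the domain boundary: the unfolded rectangle has four
true edges and nothing wraps.

Also provides transform algebra (composition, inversion, Jacobians),
moment-based rigid initialization for binary masks, and iterative
groupwise template building.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import LabelVolume, TransformRecord


@dataclass
class RegParams:
    """Optimizer settings for the diffeomorphic engine.

    ``fluid_sigma`` smooths each per-iteration update (px); ``elastic_sigma``
    smooths the accumulated velocity (px).  These play the role of the
    fluidity/elasticity knobs of conventional packages: larger values give
    smaller, smoother deformation fields.
    """

    levels: tuple[int, ...] = (4, 2, 1)
    iterations: tuple[int, ...] = (200, 150, 100)
    step: float = 1.0
    fluid_sigma: float = 3.5
    elastic_sigma: float = 2.0
    #: "ssd" on standardized channels, or "lncc" (local normalized
    #: cross-correlation, robust to local amplitude differences but
    #: blind to smooth global profiles)
    metric: str = "ssd"
    cc_sigma: float = 3.0  # window of the local correlation (px)
    conv_window: int = 10
    conv_tol: float = 1e-7
    divergence_patience: int = 20

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.iterations):
            raise ValueError("levels and iterations must have equal length")
        if self.fluid_sigma < 0 or self.elastic_sigma < 0:
            raise ValueError("smoothing sigmas must be >= 0")


# ---------------------------------------------------------------------------
# field utilities (fields are (ndim, *shape) arrays in pixel units)

def _warp_field(field: np.ndarray, disp: np.ndarray,
                order: int = 1) -> np.ndarray:
    """Sample each component of ``field`` at x + disp (clamped)."""
    ndim = disp.shape[0]
    coords = np.stack(np.meshgrid(*[np.arange(s) for s in disp.shape[1:]],
                                  indexing="ij"), axis=0) + disp
    return np.stack([ndimage.map_coordinates(field[k], coords, order=order,
                                             mode="nearest")
                     for k in range(ndim)], axis=0)


def warp_image(image: np.ndarray, disp: np.ndarray, order: int = 1) -> np.ndarray:
    """Pull ``image`` through a displacement field: out(x) = image(x + u(x))."""
    coords = np.stack(np.meshgrid(*[np.arange(s) for s in disp.shape[1:]],
                                  indexing="ij"), axis=0) + disp
    return ndimage.map_coordinates(image, coords, order=order, mode="nearest")


def exp_velocity(vel: np.ndarray) -> np.ndarray:
    """Exponentiate a stationary velocity field by scaling and squaring."""
    maxv = float(np.abs(vel).max()) if vel.size else 0.0
    if maxv == 0:
        return np.zeros_like(vel)
    n = max(0, int(np.ceil(np.log2(maxv / 0.5))))
    disp = vel / (2.0 ** n)
    for _ in range(n):
        disp = disp + _warp_field(disp, disp)
    return disp


class DiffeoTransform:
    """Invertible dense deformation over a regular grid.

    Internally a point map T(x) = x + u(x) with a cached inverse; built
    either from a stationary velocity field (exactly invertible by
    exponentiating -v) or from a displacement field (inverted by
    fixed-point iteration).  All fields are in pixel/voxel units of the
    grid they live on.
    """

    def __init__(self, disp: np.ndarray, disp_inv: np.ndarray | None = None,
                 velocity: np.ndarray | None = None):
        self.disp = np.asarray(disp, dtype=np.float64)
        self.ndim = self.disp.shape[0]
        self.shape = self.disp.shape[1:]
        self.velocity = velocity
        self._disp_inv = disp_inv

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls, shape: tuple[int, ...]) -> "DiffeoTransform":
        return cls(np.zeros((len(shape), *shape)))

    @classmethod
    def from_velocity(cls, vel: np.ndarray) -> "DiffeoTransform":
        vel = np.asarray(vel, dtype=np.float64)
        return cls(exp_velocity(vel), velocity=vel)

    # -- basic maps --------------------------------------------------------
    @property
    def disp_inv(self) -> np.ndarray:
        """Inverse displacement, computed lazily by fixed-point iteration
        (seeded with exp(-v) when the velocity is known, then polished:
        exp(-v) alone carries interpolation error where the field is
        rough)."""
        if self._disp_inv is None:
            init = (exp_velocity(-self.velocity)
                    if self.velocity is not None else None)
            self._disp_inv = invert_displacement(self.disp, init=init)
        return self._disp_inv

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        """Forward point map: pts (N, ndim) -> pts + u(pts)."""
        return pts + _sample_field(self.disp, pts)

    def map_points_inverse(self, pts: np.ndarray) -> np.ndarray:
        return pts + _sample_field(self.disp_inv, pts)

    def to_record(self, spacing=None) -> TransformRecord:
        return TransformRecord("diffeo", self.ndim,
                               {"displacement": self.disp,
                                "spacing": list(spacing) if spacing is not None
                                else [1.0] * self.ndim})


def _sample_field(field: np.ndarray, pts: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
    return np.stack([ndimage.map_coordinates(field[k], pts.T, order=1,
                                             mode="nearest")
                     for k in range(field.shape[0])], axis=-1)


def invert_displacement(disp: np.ndarray, n_iter: int = 40,
                        init: np.ndarray | None = None) -> np.ndarray:
    """Fixed-point inversion: v(x) = -u(x + v(x)).

    Damped (factor 1/2) iterations with cubic sampling: undamped cubic
    updates can oscillate where the field is rough, while damping keeps
    both composition residuals at interpolation-noise level.
    """
    inv = -disp.copy() if init is None else init.copy()
    for _ in range(n_iter):
        new = 0.5 * inv - 0.5 * _warp_field(disp, inv, order=3)
        delta = float(np.abs(new - inv).max())
        inv = new
        if delta < 1e-4:
            break
    return inv


def compose(a: DiffeoTransform, b: DiffeoTransform) -> DiffeoTransform:
    """Chain two transforms: the returned point map applies ``a`` first.

    compose(a, b).map_points(x) == b.map_points(a.map_points(x)).
    """
    if a.shape != b.shape:
        raise ValueError(f"domain mismatch: {a.shape} vs {b.shape}")
    u = a.disp + _warp_field(b.disp, a.disp, order=3)
    u_inv = b.disp_inv + _warp_field(a.disp_inv, b.disp_inv, order=3)
    return DiffeoTransform(u, u_inv)


def invert(t: DiffeoTransform) -> DiffeoTransform:
    return DiffeoTransform(t.disp_inv.copy(), t.disp.copy(),
                           velocity=None if t.velocity is None
                           else -t.velocity)


def apply_transform(image, t: DiffeoTransform, interp: str = "linear"):
    """Warp an image (array or UnfoldedMap) through a transform (pull).

    Integer label images must use nearest-neighbor interpolation; the
    output label set is then a subset of the input's.
    """
    from .io import UnfoldedMap
    if isinstance(image, UnfoldedMap):
        warped = apply_transform(image.values, t, interp)
        return UnfoldedMap(values=warped, spacing=image.spacing,
                           channel=image.channel, units=image.units)
    arr = np.asarray(image)
    is_int = np.issubdtype(arr.dtype, np.integer)
    if is_int and interp == "linear":
        raise ValueError("linear interpolation requested for integer label map; "
                         "use interp='nearest'")
    if arr.shape != t.shape:
        raise ValueError(f"image shape {arr.shape} does not match transform "
                         f"domain {t.shape}")
    order = 0 if (interp == "nearest" or is_int) else 1
    out = warp_image(arr.astype(np.float64), t.disp, order=order)
    if is_int:
        out = np.rint(out).astype(arr.dtype)
    return out


def jacobian_determinant(t: DiffeoTransform) -> np.ndarray:
    """det(I + grad u) of the forward displacement, central differences."""
    ndim = t.ndim
    jac = np.empty(t.shape + (ndim, ndim))
    for i in range(ndim):
        grads = np.gradient(t.disp[i])
        for j in range(ndim):
            jac[..., i, j] = grads[j] + (1.0 if i == j else 0.0)
    return np.linalg.det(jac)


# ---------------------------------------------------------------------------
# multi-channel demons

def _downsample(img: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return img
    sm = ndimage.gaussian_filter(img, sigma=factor / 2.0, mode="nearest")
    slicer = tuple(slice(None, None, factor) for _ in img.shape)
    return sm[slicer]


def _resize_field(field: np.ndarray, shape: tuple[int, ...],
                  scale: float) -> np.ndarray:
    out = np.empty((field.shape[0], *shape))
    zoom = [t / s for t, s in zip(shape, field.shape[1:])]
    for k in range(field.shape[0]):
        out[k] = ndimage.zoom(field[k], zoom, order=1, mode="nearest",
                              grid_mode=True) * scale
    return out


def _as_channels(obj) -> np.ndarray:
    """Accept a FeatureStack, (C, *shape) array, or plain image."""
    if hasattr(obj, "as_array"):
        return obj.as_array()
    arr = np.asarray(obj, dtype=np.float64)
    return arr


def _default_mask(fixed, moving) -> np.ndarray | None:
    masks = [getattr(obj, "valid", None) for obj in (fixed, moving)]
    masks = [m for m in masks if m is not None]
    if not masks:
        return None
    out = masks[0]
    for m in masks[1:]:
        out = out & m
    return np.asarray(out, dtype=float)


def register_multichannel(fixed, moving, params: RegParams | None = None,
                          mask: np.ndarray | None = None) -> DiffeoTransform:
    """Register ``moving`` onto ``fixed`` (both (C, *shape) channel arrays
    or FeatureStacks with matching channels).

    Greedy optimization of mean per-channel SSD: each iteration computes a
    demons force from the warped moving image, smooths it (fluid), adds it
    to the stationary velocity, and smooths the velocity (elastic).  The
    returned transform maps fixed-domain points into the moving domain
    (pull semantics: warped(x) = moving(T(x))).

    ``mask`` restricts the similarity and forces to reliable pixels;
    when both inputs are FeatureStacks it defaults to the intersection of
    their valid masks, so imputed pixels never drive the deformation.
    """
    params = params or RegParams()
    if mask is None:
        mask = _default_mask(fixed, moving)
    F = _as_channels(fixed)
    M = _as_channels(moving)
    if F.ndim == 2 and M.ndim == 2:
        # single 2D image without a channel axis; 3D inputs must carry one
        F, M = F[None], M[None]
    if F.shape != M.shape:
        raise ValueError(f"channel/shape mismatch: {F.shape} vs {M.shape}")
    for c in range(F.shape[0]):
        if not np.isfinite(F[c]).any() or not np.isfinite(M[c]).any():
            raise ValueError(f"channel {c} contains no finite values")
    F = np.nan_to_num(F)
    M = np.nan_to_num(M)
    shape = F.shape[1:]
    ndim = len(shape)
    if mask is not None and mask.shape != shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {shape}")

    vel = None
    for factor, n_iter in zip(params.levels, params.iterations):
        Fl = np.stack([_downsample(F[c], factor) for c in range(F.shape[0])])
        Ml = np.stack([_downsample(M[c], factor) for c in range(M.shape[0])])
        Wl = None if mask is None else _downsample(
            np.asarray(mask, float), factor)
        lshape = Fl.shape[1:]
        if vel is None:
            vel = np.zeros((ndim, *lshape))
        elif vel.shape[1:] != lshape:
            prev_factor = vel_factor
            vel = _resize_field(vel, lshape, prev_factor / factor)
        vel_factor = factor
        vel = _demons_level(Fl, Ml, vel, n_iter, params, weight=Wl)
    if vel.shape[1:] != shape:
        vel = _resize_field(vel, shape, vel_factor)
    return DiffeoTransform.from_velocity(vel)


def _lncc_force(F: np.ndarray, Mw: np.ndarray, sigma: float):
    """Per-pixel force magnitude along the moving gradient that increases
    the local (Gaussian-windowed) normalized cross-correlation, and the
    local dissimilarity 1 - CC^2 for monitoring."""
    def G(x):
        return ndimage.gaussian_filter(x, sigma, mode="nearest")
    Fb = F - G(F)
    Mb = Mw - G(Mw)
    A = G(Fb * Mb)
    B = G(Fb * Fb)
    C = G(Mb * Mb)
    eps = 1e-5 * max(float(B.max()), float(C.max()), 1e-12)
    denom = B * C + eps
    s = 2.0 * A / denom * (Fb - (A / (C + eps)) * Mb)
    cc2 = np.clip(A * A / denom, 0.0, 1.0)
    return s, 1.0 - cc2


def _demons_level(F: np.ndarray, M: np.ndarray, vel: np.ndarray,
                  n_iter: int, params: RegParams,
                  weight: np.ndarray | None = None) -> np.ndarray:
    ndim = vel.shape[0]
    grad_f = [np.stack(np.gradient(F[c]), axis=0) for c in range(F.shape[0])]
    best_vel = vel.copy()
    best_sim = np.inf
    history: list[float] = []
    worse = 0
    use_lncc = params.metric == "lncc"
    cc_sigma = max(1.0, params.cc_sigma)
    for _ in range(n_iter):
        disp = exp_velocity(vel)
        Mw = np.stack([warp_image(M[c], disp) for c in range(M.shape[0])])
        diff = F - Mw
        if use_lncc:
            forces = []
            dissim = np.zeros(F.shape[1:])
            for c in range(F.shape[0]):
                s, dc = _lncc_force(F[c], Mw[c], cc_sigma)
                forces.append(s)
                dissim += dc
            dissim /= F.shape[0]
        else:
            dissim = np.mean(diff ** 2, axis=0)
        if weight is None:
            sim = float(np.mean(dissim))
        else:
            wsum = max(float(weight.sum()), 1e-9)
            sim = float((weight * dissim).sum() / wsum)
        history.append(sim)
        if sim < best_sim - 1e-12:
            best_sim = sim
            best_vel = vel.copy()
        if len(history) > 1 and sim > history[-2] + 1e-12:
            worse += 1
            if worse >= params.divergence_patience:
                raise RuntimeError(
                    f"registration diverged: similarity increased for "
                    f"{worse} consecutive iterations (best {best_sim:.4g}, "
                    f"last {sim:.4g})")
        else:
            worse = 0
        if (len(history) > params.conv_window and
                history[-params.conv_window - 1] - sim
                < params.conv_tol * max(history[0], 1e-12)):
            break
        update = np.zeros_like(vel)
        for c in range(F.shape[0]):
            gm = np.stack(np.gradient(Mw[c]), axis=0)
            J = 0.5 * (grad_f[c] + gm)
            if use_lncc:
                update += forces[c] * J
            else:
                gnorm2 = np.sum(J ** 2, axis=0)
                denom = gnorm2 + diff[c] ** 2
                with np.errstate(divide="ignore", invalid="ignore"):
                    w = np.where(denom > 1e-9, diff[c] / denom, 0.0)
                update += w * J
        update /= F.shape[0]
        if weight is not None:
            update = update * weight
        if params.fluid_sigma > 0:
            update = np.stack([ndimage.gaussian_filter(update[k],
                                                       params.fluid_sigma,
                                                       mode="nearest")
                               for k in range(ndim)])
        maxu = float(np.abs(update).max())
        if maxu > 0:
            update *= params.step / max(maxu, params.step)
        vel = vel + update
        if params.elastic_sigma > 0:
            vel = np.stack([ndimage.gaussian_filter(vel[k],
                                                    params.elastic_sigma,
                                                    mode="nearest")
                            for k in range(ndim)])
    return best_vel


# ---------------------------------------------------------------------------
# groupwise template building

@dataclass
class TemplateResult:
    template: np.ndarray  # (C, *shape) mean of warped inputs
    transforms: list  # per-sample DiffeoTransform, sample -> template
    history: list = field(default_factory=list)  # per-iter mean similarity
    variance: list = field(default_factory=list)  # per-iter mean cross-sample var


def build_template(stacks, n_iter: int = 4, params: RegParams | None = None,
                   shape_update: bool = True) -> TemplateResult:
    """Iterative groupwise template construction.

    Starts from the arithmetic mean, then repeatedly registers every
    sample to the template and averages the warped samples; a shape-update
    step (inverse of the mean displacement applied to the average) keeps
    the template centered between iterations.
    """
    arrs = [_as_channels(s) for s in stacks]
    if len(arrs) < 2:
        raise ValueError("template building needs at least 2 samples")
    shape = arrs[0].shape
    for i, a in enumerate(arrs):
        if a.shape != shape:
            raise ValueError(f"stack {i} shape {a.shape} != {shape}")
    arrs = [np.nan_to_num(a) for a in arrs]
    # drive every registration only from pixels valid in all samples
    valids = [getattr(s, "valid", None) for s in stacks]
    mask = None
    if all(v is not None for v in valids):
        mask = np.ones(shape[1:], bool)
        for v in valids:
            mask &= np.asarray(v, bool)
        mask = mask.astype(float)
    template = np.mean(arrs, axis=0)
    transforms = [DiffeoTransform.identity(shape[1:]) for _ in arrs]
    history: list[float] = []
    variance: list[float] = [float(np.mean(np.var(arrs, axis=0)))]

    for it in range(n_iter):
        warped = []
        for i, a in enumerate(arrs):
            try:
                t = register_multichannel(template, a, params, mask=mask)
            except RuntimeError as e:
                raise RuntimeError(f"template iteration {it}: sample {i} "
                                   f"registration failed: {e}") from e
            transforms[i] = t
            warped.append(np.stack([warp_image(a[c], t.disp)
                                    for c in range(a.shape[0])]))
        new_template = np.mean(warped, axis=0)
        history.append(float(np.mean([(w - new_template) ** 2
                                      for w in warped])))
        variance.append(float(np.mean(np.var(warped, axis=0))))
        if shape_update and it < n_iter - 1:
            mean_disp = np.mean([t.disp for t in transforms], axis=0)
            inv_mean = invert_displacement(mean_disp)
            new_template = np.stack([warp_image(new_template[c], inv_mean)
                                     for c in range(new_template.shape[0])])
        template = new_template
    return TemplateResult(template=template, transforms=transforms,
                          history=history, variance=variance)


# ---------------------------------------------------------------------------
# moment-based rigid initialization

def _mask_moments(vol: LabelVolume) -> tuple[np.ndarray, np.ndarray]:
    mask = np.asarray(vol.voxels) > 0
    if not mask.any():
        raise ValueError("empty mask")
    ijk = np.argwhere(mask).astype(float)
    xyz = vol.world_coords(ijk)
    c = xyz.mean(axis=0)
    d = xyz - c
    cov = d.T @ d / len(d)
    return c, cov


def moment_rigid_init(fixed: LabelVolume, moving: LabelVolume,
                      warn: list | None = None) -> TransformRecord:
    """Two-moment rigid initialization of binary masks.

    Translation aligns world centroids; rotation aligns principal axes of
    the second-moment matrices.  Among the four proper (det = +1) axis-sign
    assignments, the one maximizing mask overlap wins.  The returned rigid
    maps fixed-world points into moving-world (pull semantics).
    """
    cf, covf = _mask_moments(fixed)
    cm, covm = _mask_moments(moving)
    wf, vf = np.linalg.eigh(covf)
    wm, vm = np.linalg.eigh(covm)
    # make both eigenbases right-handed so the sign enumeration spans
    # exactly the proper rotations
    if np.linalg.det(vf) < 0:
        vf[:, 0] *= -1
    if np.linalg.det(vm) < 0:
        vm[:, 0] *= -1

    ratio_f = np.sqrt(max(wf) / max(min(wf), 1e-12))
    if ratio_f < np.sqrt(1.05):
        if warn is not None:
            warn.append("near-isotropic moments; translation-only fallback")
        return TransformRecord("rigid", 3, {"matrix": np.eye(3),
                                            "translation": cm - cf})

    best = None
    best_overlap = -1.0
    for signs in ([1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]):
        R = vm @ np.diag(signs) @ vf.T
        if np.linalg.det(R) < 0:  # defensive; these sign patterns keep det=+1
            continue
        t = cm - R @ cf
        overlap = _rigid_overlap(fixed, moving, R, t)
        if overlap > best_overlap:
            best_overlap = overlap
            best = (R, t)
    R, t = best
    return TransformRecord("rigid", 3, {"matrix": R, "translation": t})


def _rigid_overlap(fixed: LabelVolume, moving: LabelVolume,
                   R: np.ndarray, t: np.ndarray) -> float:
    resampled = resample_rigid(moving, fixed, R, t, order=0)
    a = np.asarray(fixed.voxels) > 0
    b = resampled > 0
    return 2.0 * np.sum(a & b) / max(1, a.sum() + b.sum())


def resample_rigid(moving: LabelVolume, fixed: LabelVolume,
                   R: np.ndarray, t: np.ndarray, order: int = 0,
                   out_shape=None, out_affine=None) -> np.ndarray:
    """Resample ``moving`` onto the fixed grid through a world rigid map."""
    shape = fixed.voxels.shape if out_shape is None else tuple(out_shape)
    affine = fixed.affine if out_affine is None else np.asarray(out_affine)
    ii = np.indices(shape).reshape(3, -1).T.astype(float)
    world = ii @ affine[:3, :3].T + affine[:3, 3]
    mworld = world @ R.T + t
    inv = np.linalg.inv(moving.affine)
    mvox = mworld @ inv[:3, :3].T + inv[:3, 3]
    vals = ndimage.map_coordinates(np.asarray(moving.voxels, dtype=float),
                                   mvox.T, order=order, mode="constant",
                                   cval=0.0)
    return vals.reshape(shape)
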