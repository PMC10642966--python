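"""Synthetic folded-sheet phantoms with known intrinsic coordinates.

The phantom emulates a hippocampal gray-matter sheet: a parametric surface
S(u, v) whose cross-section (v, proximal-distal) is a variable-curvature
curl — flat on the subicular side, tight around the CA4 end — and whose
long axis (u, anterior-posterior) carries sinusoidal gyral waves,
thickened by a per-subfield thickness profile.  Because the
surface is analytic, every voxel has ground-truth (u, v, laminar) intrinsic
coordinates and a ground-truth subfield label, which makes the phantom a
full oracle for unfolding, morphometry, and registration.

A cohort generator adds seeded per-sample variation (gyral count and
amplitude, subfield proportions, thickness scale, hemisphere) emulating
anatomical variability between specimens.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import (DEFAULT_GRID, SRLM, ANTERIOR, POSTERIOR, PROXIMAL, DISTAL,
                 LabelVolume, UnfoldedMap, unfolded_spacing)
from .registration import DiffeoTransform, exp_velocity, jacobian_determinant
from .unfolding import CoordinateFields

from scipy import ndimage


@dataclass
class PhantomParams:
    """Geometry of one synthetic hippocampal sheet.

    Defaults give a 40 mm long, 20 mm wide sheet curled through most of a
    turn with three longitudinal gyral waves — canonical adult hippocampal
    scale.  Subfield thicknesses (mm) follow the anatomical pattern of a
    thick subiculum and thin CA2; each morphometric feature is a partial
    boundary cue (thickness is blind at Sub|CA1, dentation fades
    distally, the curl tightens distally).
    """

    length_mm: float = 40.0
    arc_mm: float = 20.0
    #: the sheet curls nearly a full turn so the distal (CA3/CA4) tip
    #: faces the proximal sheet across a narrow vestigial sulcus
    curl_angle_rad: float = 1.6 * np.pi
    #: relative curvature density per subfield (Sub..CA4): the subicular
    #: side is nearly flat and the curl tightens through the CA fields
    #: around the dentate gyrus, so curl features track subfield layout
    curl_profile: tuple[float, ...] = (0.2, 0.8, 0.8, 1.2, 1.6)
    n_gyri: int = 3
    gyral_amplitude_mm: float = 0.8  # dentation depth; subtle vs the curl
    #: relative dentation amplitude per subfield: strongest over Sub/CA1,
    #: absent in the tight distal curl
    gyral_profile: tuple[float, ...] = (1.0, 0.8, 0.3, 0.1, 0.0)
    thickness_smooth_mm: float = 1.0
    thickness_profile: tuple[float, ...] = (2.0, 2.0, 1.4, 1.7, 2.0)
    #: fractional anterior->posterior thinning (the sheet is thickest
    #: anteriorly), applied multiplicatively as 1 - taper * u
    thickness_ap_taper: float = 0.2
    subfield_fractions: tuple[float, ...] = (0.30, 0.30, 0.08, 0.12, 0.20)
    voxel_mm: float = 0.5
    hemisphere: str = "left"
    phase: float | None = None  # gyral phase; None -> seeded
    grid_shape: tuple[int, int] = DEFAULT_GRID

    def __post_init__(self) -> None:
        fr = np.asarray(self.subfield_fractions, float)
        if fr.size != 5 or (fr <= 0).any():
            raise ValueError("subfield_fractions must be 5 positive values")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("subfield_fractions must sum to 1")
        if self.length_mm <= 0 or self.arc_mm <= 0 or self.voxel_mm <= 0:
            raise ValueError("lengths must be positive")
        if self.n_gyri < 0:
            raise ValueError("n_gyri must be >= 0")
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")


@dataclass
class CohortVariation:
    """Seeded jitter applied per cohort member.

    Gyral count/amplitude/phase and the overall curl, length and width
    jitter emulate the gross morphological variability between specimens
    (folding configuration differs sample to sample); subfield-fraction
    and thickness jitter emulate cytoarchitectonic variability.
    """

    n_gyri_delta: int = 1
    amplitude_frac: float = 0.3
    fraction_conc: float = 70.0  # Dirichlet concentration; inf-like = none
    thickness_frac: float = 0.0  # per-subfield thickness jitter; zero by
    # default: thickness contrasts are a registration feature, and jitter
    # here is local amplitude noise no deformation can explain
    phase_jitter: float = 0.25  # fraction of +-pi around the base phase;
    # partial gyral correspondence across samples, like real dentations
    curl_frac: float = 0.08
    length_frac: float = 0.1
    arc_frac: float = 0.1
    min_fraction: float = 0.03


@dataclass
class PhantomSample:
    labels: LabelVolume
    truth_coords: CoordinateFields
    truth_unfolded_labels: UnfoldedMap
    params: PhantomParams


def _subfield_of(v: np.ndarray, fractions) -> np.ndarray:
    cum = np.cumsum(np.asarray(fractions, float))[:-1]
    return 1 + np.searchsorted(cum, np.clip(v, 0.0, 1.0 - 1e-12),
                               side="right").astype(np.int16)


def _thickness_of(v: np.ndarray, params: PhantomParams) -> np.ndarray:
    """Laminar thickness (mm) at P-D position v: per-subfield plateau
    values with smooth transitions (cortical thickness varies smoothly)."""
    prof = np.asarray(params.thickness_profile, float)
    if params.thickness_smooth_mm <= 0:
        return prof[_subfield_of(v, params.subfield_fractions) - 1]
    n = 2048
    vf = np.linspace(-0.3, 1.3, n)
    raw = prof[_subfield_of(vf, params.subfield_fractions) - 1]
    sigma = params.thickness_smooth_mm / params.arc_mm * (n / 1.6)
    sm = ndimage.gaussian_filter1d(raw, sigma, mode="nearest")
    return np.interp(np.asarray(v, float), vf, sm)


def _cross_section(params: PhantomParams, n: int = 4097,
                   v_lo: float = -0.3, v_hi: float = 1.3):
    """Tabulate the P-D cross-section curve (arc-length parameterized).

    The tangent angle grows as curl_angle * c(v), where the curvature
    density c'(v) follows the per-subfield curl profile (smoothed like
    the thickness profile): curl features shift with the subfield
    boundaries, as they do anatomically.  Returns the v table, positions
    (x, z), and tangent angle phi.
    """
    v = np.linspace(v_lo, v_hi, n)
    if params.curl_angle_rad < 1e-6:
        phi = np.zeros(n)
    else:
        prof = np.asarray(params.curl_profile, float)
        d = prof[_subfield_of(v, params.subfield_fractions) - 1]
        if params.thickness_smooth_mm > 0:
            sigma = params.thickness_smooth_mm / params.arc_mm * (
                n / (v_hi - v_lo))
            d = ndimage.gaussian_filter1d(d, sigma, mode="nearest")
        dv = v[1] - v[0]
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (d[1:] + d[:-1]) * dv)])
        i0 = np.searchsorted(v, 0.0)
        i1 = np.searchsorted(v, 1.0)
        cum -= cum[i0]
        cum /= cum[i1] - 0.0
        phi = params.curl_angle_rad * cum
    dv = v[1] - v[0]
    cx = np.cos(phi) * params.arc_mm
    cz = np.sin(phi) * params.arc_mm
    x = np.concatenate([[0.0], np.cumsum(0.5 * (cx[1:] + cx[:-1]) * dv)])
    z = np.concatenate([[0.0], np.cumsum(0.5 * (cz[1:] + cz[:-1]) * dv)])
    i0 = np.searchsorted(v, 0.0)
    x -= x[i0]
    z -= z[i0]
    return v, x, z, phi


def _gyral_taper(v: np.ndarray, params: PhantomParams) -> np.ndarray:
    """Relative gyral amplitude at P-D position v.

    Follows the per-subfield gyral profile (smoothed like thickness):
    dentation is strongest on the subicular/CA1 side and dies out toward
    the tightly curled distal end — which also keeps the modulated sheet
    from self-intersecting inside the curl.
    """
    prof = np.asarray(params.gyral_profile, float)
    if params.thickness_smooth_mm <= 0:
        return prof[_subfield_of(v, params.subfield_fractions) - 1]
    n = 2048
    vf = np.linspace(-0.3, 1.3, n)
    raw = prof[_subfield_of(vf, params.subfield_fractions) - 1]
    sigma = params.thickness_smooth_mm / params.arc_mm * (n / 1.6)
    sm = ndimage.gaussian_filter1d(raw, sigma, mode="nearest")
    return np.interp(np.asarray(v, float), vf, sm)


def _surface(u: np.ndarray, v: np.ndarray, params: PhantomParams,
             phase: float, table=None):
    """Return surface points S(u,v) and unit normals (toward the outer,
    convex side) for broadcastable u, v."""
    L = params.length_mm
    if table is None:
        table = _cross_section(params)
    vt, xt, zt, phit = table

    def against(uu, vv):
        g = (params.gyral_amplitude_mm * _gyral_taper(vv, params)
             * np.sin(2.0 * np.pi * params.n_gyri * uu + phase))
        vvf = np.asarray(vv, float)
        cx = np.interp(vvf, vt, xt)
        cz = np.interp(vvf, vt, zt)
        phi = np.interp(vvf, vt, phit)
        # outward cross-section normal (away from the curl center)
        nx, nz = np.sin(phi), -np.cos(phi)
        x = cx + nx * g
        z = cz + nz * g
        y = uu * L
        return np.stack(np.broadcast_arrays(x, y, z), axis=-1)

    S = against(u, v)
    # numeric tangents -> normal (robust to the tabulated cross-section)
    eu, ev = 1e-4, 1e-4
    Su = (against(u + eu, v) - against(u - eu, v)) / (2 * eu)
    Sv = (against(u, v + ev) - against(u, v - ev)) / (2 * ev)
    N = np.cross(Su, Sv)
    N /= np.maximum(np.linalg.norm(N, axis=-1, keepdims=True), 1e-12)
    phi = np.interp(np.asarray(np.broadcast_to(v, S.shape[:-1]), float),
                    vt, phit)
    ref = np.stack([np.sin(phi), np.zeros_like(phi), -np.cos(phi)], axis=-1)
    flip = np.sum(N * ref, axis=-1) < 0
    N[flip] *= -1.0
    return S, N


def generate_phantom(params: PhantomParams, seed: int = 0) -> PhantomSample:
    """Voxelize one folded-sheet phantom with ground-truth coordinates."""
    prof = np.asarray(params.thickness_profile, float)
    if prof.min() < 2.0 * params.voxel_mm:
        raise ValueError(
            f"voxel size {params.voxel_mm} mm too coarse to resolve the "
            f"thinnest subfield ({prof.min()} mm < 2 voxels); use a finer "
            "resolution")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi) if params.phase is None else params.phase

    vox = params.voxel_mm
    ds = 0.4 * vox
    n_u = int(np.ceil(params.length_mm / ds)) + 1
    n_v = int(np.ceil(params.arc_mm / ds)) + 1
    n_w = int(np.ceil(prof.max() / ds)) + 1
    eps_u = 1.2 * vox / params.length_mm
    eps_v = 1.2 * vox / params.arc_mm
    n_eu = max(2, int(np.ceil(eps_u * n_u)))
    n_ev = max(2, int(np.ceil(eps_v * n_v)))
    srlm_w = vox  # 1-voxel SRLM shell on the inner side

    u = np.linspace(0.0, 1.0, n_u)
    v = np.linspace(0.0, 1.0, n_v)
    # cell-centered laminar samples strictly inside (-1/2, 1/2) so boundary
    # samples never splat into voxels beyond the half-thickness band
    w = (np.arange(n_w) + 0.5) / n_w - 0.5

    table = _cross_section(params)
    S, N = _surface(u[:, None], v[None, :], params, phase, table)  # (nu, nv, 3)
    taper_u = 1.0 - params.thickness_ap_taper * np.clip(u, 0.0, 1.0)
    th = (_thickness_of(v, params)[None, :, None]
          * taper_u[:, None, None])  # (nu, nv, 1)

    def _points(wvals):
        # (nu, nv, nw, 3)
        return S[:, :, None, :] + N[:, :, None, :] * (
            wvals[None, None, :, None] * th[..., None])

    pts_gray = _points(w)
    uu = np.broadcast_to(u[:, None, None], pts_gray.shape[:3])
    vv = np.broadcast_to(v[None, :, None], pts_gray.shape[:3])
    ww = np.broadcast_to(w[None, None, :], pts_gray.shape[:3])
    lab_gray = np.broadcast_to(_subfield_of(v, params.subfield_fractions)
                               [None, :, None], pts_gray.shape[:3])

    # SRLM shell just inside the inner (concave, w=-1/2) boundary,
    # ~1 voxel thick in mm regardless of the local laminar thickness
    n_s = max(2, int(np.ceil(srlm_w / ds)))
    srlm_off = -srlm_w * (np.arange(n_s) + 0.5) / n_s
    w_srlm_pts = S[:, :, None, :] + N[:, :, None, :] * (
        (-0.5 * th[..., None]) + srlm_off[None, None, :, None])

    # terminus caps on the four sheet edges, spanning the full thickness
    u_ant = -eps_u * (np.arange(n_eu) + 0.5) / n_eu
    u_post = 1.0 + eps_u * (np.arange(n_eu) + 0.5) / n_eu
    v_prox = -eps_v * (np.arange(n_ev) + 0.5) / n_ev
    v_dist = 1.0 + eps_v * (np.arange(n_ev) + 0.5) / n_ev

    def _edge_points(ue, ve):
        Se, Ne = _surface(ue[:, None], ve[None, :], params, phase, table)
        te = 1.0 - params.thickness_ap_taper * np.clip(ue, 0.0, 1.0)
        the = _thickness_of(ve, params)[None, :, None] * te[:, None, None]
        return Se[:, :, None, :] + Ne[:, :, None, :] * (
            w[None, None, :, None] * the[..., None])

    cap_pts = [(_edge_points(u_ant, v), ANTERIOR),
               (_edge_points(u_post, v), POSTERIOR),
               (_edge_points(u, v_prox), PROXIMAL),
               (_edge_points(u, v_dist), DISTAL)]

    # bounding grid
    all_pts = [pts_gray.reshape(-1, 3), w_srlm_pts.reshape(-1, 3)]
    all_pts += [p.reshape(-1, 3) for p, _ in cap_pts]
    stacked = np.concatenate(all_pts, axis=0)
    sign = -1.0 if params.hemisphere == "right" else 1.0
    stacked_x = stacked[:, 0] * sign
    lo = np.array([stacked_x.min(), stacked[:, 1].min(), stacked[:, 2].min()])
    hi = np.array([stacked_x.max(), stacked[:, 1].max(), stacked[:, 2].max()])
    # place voxel faces on integer multiples of the voxel size in world
    # coordinates: axis-aligned sheet faces (e.g. the flat slab at z = 0)
    # then coincide with voxel faces and voxelized thickness is exact
    origin = (np.floor(lo / vox) - 2.0 - 0.5) * vox
    shape = tuple(np.ceil((hi - origin) / vox).astype(int) + 3)
    affine = np.diag([vox, vox, vox, 1.0])
    affine[:3, 3] = origin

    def _to_idx(p):
        q = p.reshape(-1, 3).copy()
        q[:, 0] *= sign
        return np.rint((q - origin) / vox).astype(int)

    labels = np.zeros(shape, dtype=np.int16)
    t_u = np.full(shape, np.nan)
    t_v = np.full(shape, np.nan)
    t_io = np.full(shape, np.nan)

    # gray matter: each voxel takes the surface sample nearest its center,
    # so the stored truth coordinates are unbiased within the voxel
    idx = _to_idx(pts_gray)
    flat = np.ravel_multi_index(idx.T, shape)
    q = pts_gray.reshape(-1, 3).copy()
    q[:, 0] *= sign
    dist_c = np.linalg.norm(q - (origin + idx * vox), axis=1)
    order = np.argsort(dist_c, kind="stable")
    flat_o = flat[order]
    uniq, first = np.unique(flat_o, return_index=True)
    sel = order[first]
    labels.ravel()[uniq] = lab_gray.ravel()[sel]
    t_u.ravel()[uniq] = uu.ravel()[sel]
    t_v.ravel()[uniq] = vv.ravel()[sel]
    t_io.ravel()[uniq] = ww.ravel()[sel] + 0.5

    def _paint(points, value):
        i = _to_idx(points)
        f = np.ravel_multi_index(i.T, shape)
        tgt = labels.ravel()
        empty = tgt[f] == 0
        tgt[f[empty]] = value

    _paint(w_srlm_pts, SRLM)
    for p, value in cap_pts:
        _paint(p, value)

    gray = (labels >= 1) & (labels <= 5)
    coords = CoordinateFields(ap=np.where(gray, t_u, np.nan),
                              pd=np.where(gray, t_v, np.nan),
                              io=np.where(gray, t_io, np.nan),
                              mask=gray, affine=affine)

    gs = params.grid_shape
    col_v = (np.arange(gs[1]) + 0.5) / gs[1]
    truth_cols = _subfield_of(col_v, params.subfield_fractions)
    truth_map = UnfoldedMap(values=np.tile(truth_cols, (gs[0], 1)),
                            spacing=unfolded_spacing(gs), channel="labels")

    return PhantomSample(labels=LabelVolume(labels, affine),
                         truth_coords=coords,
                         truth_unfolded_labels=truth_map, params=params)


def generate_cohort(n: int, base: PhantomParams | None = None,
                    variation: CohortVariation | None = None,
                    seed: int = 0) -> list[PhantomSample]:
    """Generate a cohort of jittered phantoms (4 left / 3 right at n = 7).

    Each member perturbs gyral count (+-1), gyral amplitude, subfield
    fractions (Dirichlet resampling around the base), global thickness
    scale, and gyral phase.  Invalid fraction draws are resampled.
    """
    if n < 2:
        raise ValueError("cohort needs n >= 2")
    base = base or PhantomParams()
    variation = variation or CohortVariation()
    rng = np.random.default_rng(seed)
    base_phase = base.phase if base.phase is not None else rng.uniform(
        0, 2 * np.pi)
    n_left = int(np.ceil(n * 4 / 7)) if n == 7 else (n + 1) // 2

    samples = []
    base_fr = np.asarray(base.subfield_fractions, float)
    base_th = np.asarray(base.thickness_profile, float)
    for i in range(n):
        dg = int(rng.integers(-variation.n_gyri_delta,
                              variation.n_gyri_delta + 1)) \
            if variation.n_gyri_delta else 0
        amp = base.gyral_amplitude_mm * (
            1.0 + variation.amplitude_frac * rng.uniform(-1, 1))
        if np.isfinite(variation.fraction_conc):
            for _ in range(100):
                fr = rng.dirichlet(base_fr * variation.fraction_conc)
                if fr.min() >= variation.min_fraction:
                    break
            else:  # pragma: no cover - practically unreachable
                fr = base_fr
        else:
            fr = base_fr
        th = base_th * (1.0 + variation.thickness_frac
                        * rng.uniform(-1, 1, size=base_th.size))
        phase = base_phase + variation.phase_jitter * rng.uniform(
            -np.pi, np.pi)
        params = replace(
            base,
            n_gyri=max(0, base.n_gyri + dg),
            gyral_amplitude_mm=amp,
            subfield_fractions=tuple(fr / fr.sum()),
            thickness_profile=tuple(th),
            phase=phase,
            curl_angle_rad=base.curl_angle_rad * (
                1.0 + variation.curl_frac * rng.uniform(-1, 1)),
            length_mm=base.length_mm * (
                1.0 + variation.length_frac * rng.uniform(-1, 1)),
            arc_mm=base.arc_mm * (
                1.0 + variation.arc_frac * rng.uniform(-1, 1)),
            hemisphere="left" if i < n_left else "right")
        samples.append(generate_phantom(params, seed=int(rng.integers(2**31))))
    return samples


def make_synthetic_warp(shape: tuple[int, ...], amplitude_px: float,
                        smoothness_px: float, seed: int = 0
                        ) -> DiffeoTransform:
    """Smooth random diffeomorphic warp with known dense displacement.

    A Gaussian-smoothed random stationary velocity is rescaled so the
    exponentiated displacement's maximum magnitude matches ``amplitude_px``
    (within 10%); positivity of the Jacobian is verified and violation
    raises an error.
    """
    ndim = len(shape)
    if amplitude_px == 0:
        return DiffeoTransform.identity(shape)
    rng = np.random.default_rng(seed)
    vel = np.stack([ndimage.gaussian_filter(rng.standard_normal(shape),
                                            smoothness_px, mode="nearest")
                    for _ in range(ndim)])
    # taper to zero at the rectangle edges: no flux through true edges
    taper = max(2.0, smoothness_px)
    window = np.ones(shape)
    for ax, n in enumerate(shape):
        d = np.minimum(np.arange(n), n - 1 - np.arange(n)) / taper
        w1 = np.clip(d, 0.0, 1.0)
        w1 = w1 * w1 * (3 - 2 * w1)  # smoothstep
        window *= w1.reshape([-1 if a == ax else 1 for a in range(ndim)])
    vel *= window
    mag = np.sqrt(np.sum(vel ** 2, axis=0)).max()
    vel *= amplitude_px / mag
    for _ in range(3):
        disp = exp_velocity(vel)
        dmax = np.sqrt(np.sum(disp ** 2, axis=0)).max()
        vel *= amplitude_px / dmax
    t = DiffeoTransform.from_velocity(vel)
    if jacobian_determinant(t).min() <= 0:
        raise ValueError(
            f"amplitude {amplitude_px} px incompatible with positive Jacobian "
            f"at smoothness {smoothness_px} px")
    return t
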