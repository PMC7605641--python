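"""Head-motion estimation, framewise displacement, scrubbing, correction.

Framewise displacement follows the rodent-adapted Power convention:
rigid-body parameters of each frame are estimated relative to the first
frame, differenced between consecutive frames, and combined as

    FD_i = |dx_i| + |dy_i| + |dz_i| + r * (|da_i| + |db_i| + |dg_i|)

with r = 5 mm, roughly the cortex-to-head-centre distance in the adult
rat.  Frames with FD > 0.2 mm are scrubbed together with both temporal
neighbours; the first 10 frames are always dropped (steady-state
magnetisation); scans retaining under 90% of frames are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from ratfc.io_core import ValidationError, Volume4D

logger = logging.getLogger(__name__)

DEFAULT_RADIUS_MM = 5.0
DEFAULT_FD_THRESH_MM = 0.2
DEFAULT_N_DROP_FIRST = 10
DEFAULT_MIN_KEEP_FRACTION = 0.9


@dataclass
class RigidTransform:
    """Six-parameter rigid-body map in world (mm) coordinates.

    A point p maps to ``R @ (p - center) + center + t`` where R is the
    rotation Rz(az) @ Ry(ay) @ Rx(ax) and t = (tx, ty, tz) in mm.
    """

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    ax: float = 0.0
    ay: float = 0.0
    az: float = 0.0
    center_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.center_mm = np.asarray(self.center_mm, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.params)) or not np.all(np.isfinite(self.center_mm)):
            raise ValidationError("rigid transform parameters must be finite")

    @property
    def params(self) -> np.ndarray:
        """(tx, ty, tz, ax, ay, az) — mm and radians."""
        return np.array([self.tx, self.ty, self.tz, self.ax, self.ay, self.az])

    @classmethod
    def from_params(cls, params, center_mm=(0, 0, 0)) -> "RigidTransform":
        p = np.asarray(params, dtype=float).reshape(6)
        return cls(*p, center_mm=np.asarray(center_mm, dtype=float))

    def rotation_matrix(self) -> np.ndarray:
        cx, sx = np.cos(self.ax), np.sin(self.ax)
        cy, sy = np.cos(self.ay), np.sin(self.ay)
        cz, sz = np.cos(self.az), np.sin(self.az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return rz @ ry @ rx

    def apply_points(self, pts_mm: np.ndarray) -> np.ndarray:
        r = self.rotation_matrix()
        return (pts_mm - self.center_mm) @ r.T + self.center_mm + self.params[:3]

    def inverse(self) -> "RigidTransform":
        """Exact inverse as a new transform about the same centre.

        The inverse rotation R^T generally does not factor into the same
        Euler-angle order with negated angles, so the angles are
        re-extracted from R^T.
        """
        r_inv = self.rotation_matrix().T
        ax, ay, az = _euler_from_matrix(r_inv)
        t_inv = -r_inv @ self.params[:3]
        return RigidTransform(*t_inv, ax, ay, az, center_mm=self.center_mm.copy())

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first); centre taken from self."""
        r1, r2 = self.rotation_matrix(), other.rotation_matrix()
        r = r1 @ r2
        c = self.center_mm
        # full map: p -> r@(p-c)+c+t  with t solved from composing both maps
        t = (r1 @ (other.apply_points(c[None, :])[0] - c)
             + self.params[:3] + c) - (r @ (c - c) + c)
        ax, ay, az = _euler_from_matrix(r)
        return RigidTransform(*t, ax, ay, az, center_mm=c.copy())


def _euler_from_matrix(r: np.ndarray):
    """Angles (ax, ay, az) with R = Rz Ry Rx; valid away from gimbal lock."""
    ay = np.arcsin(np.clip(-r[2, 0], -1.0, 1.0))
    ax = np.arctan2(r[2, 1], r[2, 2])
    az = np.arctan2(r[1, 0], r[0, 0])
    return ax, ay, az


@dataclass
class MotionTrace:
    """Per-frame frame-to-reference transforms and the derived FD series."""

    transforms: list
    fd_mm: np.ndarray
    r_mm: float = DEFAULT_RADIUS_MM

    def __post_init__(self):
        self.fd_mm = np.asarray(self.fd_mm, dtype=float)
        if len(self.fd_mm) != len(self.transforms):
            raise ValidationError("FD length must equal number of frames")
        if self.fd_mm[0] != 0:
            raise ValidationError("FD of the first frame is 0 by convention")
        if np.any(self.fd_mm < 0):
            raise ValidationError("FD must be nonnegative")

    def params_array(self) -> np.ndarray:
        return np.stack([t.params for t in self.transforms])


@dataclass
class ScrubDecision:
    keep: np.ndarray
    n_dropped_first: int
    scrubbed_fraction: float
    scan_excluded: bool


def apply_rigid(frame: np.ndarray, t: RigidTransform, voxel_size_mm) -> np.ndarray:
    """Resample a 3D frame under the transform (trilinear, zeros outside).

    The output at voxel x holds the input value at T^{-1}(x), so applying
    the transform moves image content the way T moves points.
    """
    voxel = np.asarray(voxel_size_mm, dtype=float).reshape(3)
    r = t.rotation_matrix()
    # voxel-space matrix/offset for the inverse map T^{-1}(y) = R^T (y - c - t) + c
    s = np.diag(voxel)
    s_inv = np.diag(1.0 / voxel)
    matrix = s_inv @ r.T @ s
    offset = s_inv @ (t.center_mm - r.T @ (t.center_mm + t.params[:3]))
    return ndimage.affine_transform(frame, matrix, offset=offset, order=1,
                                    mode="constant", cval=0.0)


def _residual_vector(params, moving, fixed, voxel, center, mask):
    """Intensity residual with out-of-field samples excluded.

    The moving image is resampled with zero fill, and a ones-volume is
    resampled alongside to flag voxels whose sample position left the
    FOV; those entries are zeroed so boundary crossings neither penalise
    a candidate (which would bias the fit toward the identity) nor
    reward it.
    """
    t = RigidTransform.from_params(params, center_mm=center)
    voxel = np.asarray(voxel, dtype=float)
    r = t.rotation_matrix()
    s = np.diag(voxel)
    s_inv = np.diag(1.0 / voxel)
    matrix = s_inv @ r.T @ s
    offset = s_inv @ (t.center_mm - r.T @ (t.center_mm + t.params[:3]))
    res = ndimage.affine_transform(moving, matrix, offset=offset, order=1,
                                   mode="constant", cval=0.0)
    valid = ndimage.affine_transform(np.ones(moving.shape), matrix, offset=offset,
                                     order=1, mode="constant", cval=0.0)
    diff = (res - fixed) * (valid > 0.999)
    return (diff[mask] if mask is not None else diff).ravel()


def _mse_objective(params, moving, fixed, voxel, center, mask):
    d = _residual_vector(params, moving, fixed, voxel, center, mask)
    return float(np.mean(d * d))


def estimate_rigid(moving: np.ndarray, fixed: np.ndarray, voxel_size_mm,
                   mask: np.ndarray = None, n_levels: int = 1,
                   init_params=None, xtol: float = 1e-6,
                   rot_penalty: float = 0.0, trans_penalty: float = 0.0,
                   refine: bool = True) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` onto ``fixed``.

    Levenberg-Marquardt least squares on the (optionally masked)
    intensity difference over the six rigid parameters.  A cold start
    (no ``init_params``) first runs a short derivative-free capture
    sweep; the finest level ends with a small-step refinement pass; an
    optional Gaussian pyramid (``n_levels`` > 1) extends the capture
    range further.  The returned transform satisfies
    ``apply_rigid(moving, t) ≈ fixed``.  Initialised at the centre-of-mass
    translation unless ``init_params`` is given.

    ``rot_penalty`` adds a Tikhonov small-rotation prior: on a
    low-resolution slab the rotation axes are weakly identifiable and an
    unpenalised fit drifts along them; the penalty is scaled so it only
    matters where the data carry little rotation information.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValidationError("moving and fixed must share a grid")
    voxel = np.asarray(voxel_size_mm, dtype=float).reshape(3)
    center = (np.array(fixed.shape) - 1) / 2.0 * voxel

    # the outermost FOV shell never enters the residual: its samples flip
    # between valid and out-of-field with sub-voxel shifts, which would
    # make the objective discontinuous exactly at integer alignments
    interior = np.zeros(fixed.shape, dtype=bool)
    interior[1:-1, 1:-1, 1:-1] = True
    mask = interior if mask is None else (np.asarray(mask, dtype=bool) & interior)

    if init_params is None:
        com_fix = ndimage.center_of_mass(np.abs(fixed))
        com_mov = ndimage.center_of_mass(np.abs(moving))
        t0 = (np.array(com_fix) - np.array(com_mov)) * voxel
        params = np.array([*t0, 0.0, 0.0, 0.0])
    else:
        params = np.asarray(init_params, dtype=float).copy()

    levels = []
    for lev in range(n_levels - 1, -1, -1):
        factor = 2 ** lev
        if factor > 1:
            if min(moving.shape) // factor < 4:
                continue
            sigma = factor / 2.0
            mov_l = ndimage.zoom(ndimage.gaussian_filter(moving, sigma), 1 / factor, order=1)
            fix_l = ndimage.zoom(ndimage.gaussian_filter(fixed, sigma), 1 / factor, order=1)
            mask_l = None
            if mask is not None:
                mask_l = ndimage.zoom(mask.astype(float), 1 / factor, order=0) > 0.5
                if mask_l.shape != mov_l.shape or not mask_l.any():
                    mask_l = None
            levels.append((mov_l, fix_l, voxel * factor, mask_l))
        else:
            levels.append((moving, fixed, voxel, mask))

    scale = np.array([1.0] * 3 + [0.02] * 3)  # balance mm against radians
    cold_start = init_params is None
    result = None
    for i_lev, (mov_l, fix_l, vox_l, mask_l) in enumerate(levels):
        is_finest = i_lev == len(levels) - 1
        center_l = (np.array(fix_l.shape) - 1) / 2.0 * vox_l
        n_res = int(mask_l.sum()) if mask_l is not None else fix_l.size
        pen = np.array([trans_penalty] * 3 + [rot_penalty] * 3) * np.sqrt(n_res) / 100.0

        def res_fn(x):
            data = _residual_vector(x * scale, mov_l, fix_l, vox_l, center_l, mask_l)
            if pen.any():
                return np.concatenate([data, pen * x])
            return data

        if cold_start and i_lev == 0:
            # short derivative-free capture sweep: a cold start can sit
            # outside the quadratic basin for rotations of a few degrees
            cap = optimize.minimize(lambda x: float(np.sum(res_fn(x) ** 2)),
                                    params / scale, method="Powell",
                                    options={"xtol": 1e-2, "ftol": 1e-7, "maxiter": 6})
            params = cap.x * scale
        result = optimize.least_squares(res_fn, params / scale, method="lm",
                                        xtol=xtol, ftol=1e-12, gtol=1e-12,
                                        diff_step=1e-3, max_nfev=150)
        if is_finest and refine:
            # refinement pass: smaller finite-difference step resolves the
            # sub-voxel structure of the interpolated objective
            result = optimize.least_squares(res_fn, result.x, method="lm",
                                            xtol=xtol * 1e-2, ftol=1e-14,
                                            gtol=1e-14, diff_step=1e-4,
                                            max_nfev=80)
        params = result.x * scale
    if result is not None and result.status <= 0:
        logger.warning("rigid registration did not fully converge: %s", result.message)
    return RigidTransform.from_params(params, center_mm=center)


def compute_fd(transforms, r_mm: float = DEFAULT_RADIUS_MM) -> np.ndarray:
    """Framewise displacement from per-frame (frame-to-reference) transforms.

    Consecutive differences of the six parameters; translations in mm,
    rotation angles (radians) scaled by ``r_mm``.  FD of the first frame
    is zero by convention.
    """
    if isinstance(transforms, np.ndarray):
        params = np.asarray(transforms, dtype=float)
    else:
        params = np.stack([t.params for t in transforms])
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValidationError("expected a T x 6 parameter array or transform list")
    if not np.all(np.isfinite(params)):
        raise ValidationError("non-finite motion parameters")
    fd = np.zeros(len(params))
    if len(params) > 1:
        delta = np.abs(np.diff(params, axis=0))
        fd[1:] = delta[:, :3].sum(axis=1) + r_mm * delta[:, 3:].sum(axis=1)
    return fd


def scrub_mask(fd: np.ndarray, fd_thresh_mm: float = DEFAULT_FD_THRESH_MM,
               n_drop_first: int = DEFAULT_N_DROP_FIRST,
               neighbors: str = "both") -> np.ndarray:
    """Boolean keep-vector for the scrubbing rules (no exclusion decision)."""
    fd = np.asarray(fd, dtype=float)
    n = len(fd)
    keep = np.ones(n, dtype=bool)
    keep[:min(n_drop_first, n)] = False
    bad = np.flatnonzero(fd > fd_thresh_mm)
    keep[bad] = False
    if neighbors in ("both", "before"):
        keep[np.clip(bad - 1, 0, n - 1)] = False
    if neighbors in ("both", "after"):
        keep[np.clip(bad + 1, 0, n - 1)] = False
    return keep


def scrub(vol: Volume4D, fd, fd_thresh_mm: float = DEFAULT_FD_THRESH_MM,
          n_drop_first: int = DEFAULT_N_DROP_FIRST,
          min_keep_fraction: float = DEFAULT_MIN_KEEP_FRACTION,
          neighbors: str = "both"):
    """Drop steady-state and high-motion frames.

    Returns the scrubbed volume and a :class:`ScrubDecision`.  A scan
    keeping fewer than ``min_keep_fraction`` of its frames is flagged
    excluded (the scrubbed volume is still returned for inspection).
    """
    fd = np.asarray(fd, dtype=float)
    if len(fd) != vol.n_frames:
        raise ValidationError("FD length must equal frame count")
    keep = scrub_mask(fd, fd_thresh_mm, n_drop_first, neighbors)
    if not keep.any():
        raise ValidationError("scrubbing would drop every frame")
    kept_fraction = keep.mean()
    decision = ScrubDecision(keep=keep, n_dropped_first=min(n_drop_first, len(fd)),
                             scrubbed_fraction=float(1.0 - kept_fraction),
                             scan_excluded=bool(kept_fraction < min_keep_fraction))
    return vol.with_data(vol.data[..., keep]), decision


def estimate_motion(vol: Volume4D, dilated_mask: np.ndarray = None,
                    r_mm: float = DEFAULT_RADIUS_MM, n_levels: int = 1,
                    presmooth_vox: float = 1.0, rot_penalty: float = 50.0,
                    trans_penalty: float = 10.0, refine: bool = True,
                    xtol: float = 1e-6) -> MotionTrace:
    """Register every frame to the first frame without resampling.

    Frames are lightly Gaussian-smoothed (``presmooth_vox`` voxels)
    before estimation to stabilise the intensity objective against
    thermal noise; the data themselves are untouched.  Registrations are
    warm-started from the previous frame's solution (physiological
    motion is temporally smooth).  Returns the per-frame frame-to-first
    transforms and the FD series they imply.
    """
    if vol.n_frames < 2:
        raise ValidationError("motion estimation needs at least 2 frames")

    def prep(frame):
        if presmooth_vox > 0:
            return ndimage.gaussian_filter(frame, presmooth_vox)
        return frame

    fixed = prep(vol.frame(0))
    center = (np.array(fixed.shape) - 1) / 2.0 * vol.voxel_size_mm
    transforms = [RigidTransform(center_mm=center)]
    prev = np.zeros(6)
    for t_idx in range(1, vol.n_frames):
        try:
            t = estimate_rigid(prep(vol.frame(t_idx)), fixed, vol.voxel_size_mm,
                               mask=dilated_mask, n_levels=n_levels, init_params=prev,
                               rot_penalty=rot_penalty, trans_penalty=trans_penalty,
                               refine=refine, xtol=xtol)
        except Exception as exc:
            raise RuntimeError(f"registration failed on frame {t_idx}: {exc}") from exc
        prev = t.params.copy()
        transforms.append(t)
    fd = compute_fd(transforms, r_mm=r_mm)
    return MotionTrace(transforms=transforms, fd_mm=fd, r_mm=r_mm)


def resample_with_trace(vol: Volume4D, trace: MotionTrace,
                        reference_index: int = 0):
    """Resample every frame into the space of ``reference_index``.

    Frame-to-reference transforms are composed from the trace's
    frame-to-first transforms (registration is transitive), so changing
    the reference — e.g. to the first retained frame after scrubbing —
    needs no re-registration.  Returns (corrected volume, re-referenced
    MotionTrace).
    """
    if len(trace.transforms) != vol.n_frames:
        raise ValidationError("trace length must match frame count")
    t_ref_inv = trace.transforms[reference_index].inverse()
    rel = [t_ref_inv.compose(t) for t in trace.transforms]
    corrected = np.empty_like(vol.data)
    for i, t in enumerate(rel):
        if i == reference_index:
            corrected[..., i] = vol.frame(i)
        else:
            corrected[..., i] = apply_rigid(vol.frame(i), t, vol.voxel_size_mm)
    new_trace = MotionTrace(transforms=rel, fd_mm=compute_fd(rel, r_mm=trace.r_mm),
                            r_mm=trace.r_mm)
    return vol.with_data(corrected), new_trace


def motion_correct(vol: Volume4D, dilated_mask: np.ndarray = None,
                   r_mm: float = DEFAULT_RADIUS_MM, n_levels: int = 1):
    """Co-register every frame to the first frame (rigid, masked MSE).

    Returns the corrected volume and a :class:`MotionTrace` whose
    parameters are the six motion regressors used downstream.
    """
    trace = estimate_motion(vol, dilated_mask=dilated_mask, r_mm=r_mm, n_levels=n_levels)
    return resample_with_trace(vol, trace, reference_index=0)


def write_motion_params(trace: MotionTrace, path) -> None:
    """Six-column whitespace text file: tx ty tz ax ay az per frame."""
    np.savetxt(path, trace.params_array(), fmt="%.8f")
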