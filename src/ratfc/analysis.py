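"""Group-level functional-connectivity analyses and QC.

ROI FC is the Fisher-z transformed Pearson correlation of regionally
averaged time courses.  Group inference treats subject as the random
unit: per-entry one-sample t statistics are computed on per-subject mean
z values (for one scan per subject this is exactly the classical
one-sample t; for balanced designs it equals the random-intercept
mixed-model test of the group mean).  Family-wise error over the matrix
is controlled with a max-t permutation null in which ROI labels are
shuffled independently for each scan.

Scans of unequal length are truncated to common 540-frame segments
before FC so every scan contributes the same degrees of freedom; 1200-
frame scans yield two disjoint segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import FastICA

from ratfc.denoise import ic_timecourses
from ratfc.io_core import ROIAtlas, ValidationError, Volume4D

logger = logging.getLogger(__name__)

T_CAP = 1e6          # reported in place of infinite t (zero residual variance)
Z_CLIP = 1.0 - 1e-7  # |r| clip before the Fisher transform
TRUNCATION_LENGTH = 540


@dataclass
class FCMatrix:
    """Per-scan Fisher-z ROI connectivity matrix (diagonal zero)."""
    z: np.ndarray
    roi_ids: list
    scan_id: str = ""
    subject_id: str = ""

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise ValidationError("FC matrix must be square")
        if not np.allclose(self.z, self.z.T, equal_nan=True):
            raise ValidationError("FC matrix must be symmetric")


@dataclass
class GroupFCResult:
    t: np.ndarray
    sig: np.ndarray = None
    t_crit: float = np.nan
    n_perm: int = 0
    density: float = np.nan
    capped: np.ndarray = None


@dataclass
class SpecificityOutcome:
    category: str
    z_specific: float
    z_nonspecific: float
    threshold: float


@dataclass
class SNRMaps:
    ssnr: np.ndarray
    tsnr: np.ndarray
    mean_ssnr: float
    mean_tsnr: float


@dataclass
class GroupICAResult:
    maps: np.ndarray        # K x V z-scored group spatial maps
    timecourses: list       # per scan: T x K
    brain: np.ndarray


def truncate_to_common_length(scans: list, target: int = TRUNCATION_LENGTH):
    """Cut scans into fixed-length segments for equal degrees of freedom.

    Scans with >= 2 * target frames contribute two disjoint segments;
    scans shorter than target are dropped with a warning.  Returns
    (segments, scan_index) where scan_index maps each segment back to its
    source scan position.
    """
    segments, origin = [], []
    for idx, vol in enumerate(scans):
        t = vol.n_frames
        if t < target:
            logger.warning("scan %d has %d < %d frames; dropped", idx, t, target)
            continue
        segments.append(vol.with_data(vol.data[..., :target]))
        origin.append(idx)
        if t >= 2 * target:
            segments.append(vol.with_data(vol.data[..., target:2 * target]))
            origin.append(idx)
    return segments, origin


def roi_timecourses(vol: Volume4D, atlas: ROIAtlas):
    """Mean time course per atlas ROI; empty ROIs are excluded with a warning.

    Returns (N x T array, list of the ROI ids actually used).
    """
    ids, rows = [], []
    flat = vol.data.reshape(-1, vol.n_frames)
    labels = atlas.labels.reshape(-1)
    for lab in atlas.roi_ids:
        sel = labels == lab
        if not sel.any():
            logger.warning("ROI %d is empty on this grid; excluded", lab)
            continue
        rows.append(flat[sel].mean(axis=0))
        ids.append(lab)
    return np.array(rows), ids


def scan_fc(tc: np.ndarray, roi_ids=None, scan_id: str = "",
            subject_id: str = "") -> FCMatrix:
    """Fisher-z Pearson correlation matrix of the N x T time-course array."""
    tc = np.asarray(tc, dtype=float)
    if tc.ndim != 2 or tc.shape[1] < 3:
        raise ValidationError("need an N x T array with T >= 3")
    sd = tc.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning("%d zero-variance ROI time courses; entries set missing",
                       int(degenerate.sum()))
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(tc)
    z = np.arctanh(np.clip(r, -Z_CLIP, Z_CLIP))
    z[degenerate, :] = np.nan
    z[:, degenerate] = np.nan
    np.fill_diagonal(z, 0.0)
    if roi_ids is None:
        roi_ids = list(range(1, tc.shape[0] + 1))
    return FCMatrix(z=z, roi_ids=list(roi_ids), scan_id=scan_id, subject_id=subject_id)


def _subject_means(z_stack: np.ndarray, subject_labels) -> np.ndarray:
    """Average the stacked matrices within subject -> (n_subjects, ...)."""
    subject_labels = np.asarray(subject_labels)
    uniq = np.unique(subject_labels)
    return np.stack([z_stack[subject_labels == s].mean(axis=0) for s in uniq])


def _one_sample_t(x: np.ndarray):
    """Entrywise one-sample t across axis 0 with zero-variance capping."""
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    capped = (sd == 0) & (mean != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(sd == 0, np.where(mean == 0, 0.0, np.sign(mean) * T_CAP), t)
    return t, capped


def group_fc(fc: list, subjects=None, method: str = "subject-mean") -> GroupFCResult:
    """Group-level t matrix from per-scan Fisher-z matrices.

    ``subjects`` maps scan position to a subject identifier (defaults to
    one subject per scan).  The default estimator computes per-subject
    mean matrices and a one-sample t across subjects, which reduces
    exactly to the classical one-sample t when every subject contributes
    one scan and equals the balanced random-intercept mixed-model test
    otherwise.  ``method='reml'`` fits a per-entry random-intercept
    mixed model (statsmodels), falling back to the subject-mean t on
    non-convergence.
    """
    if subjects is None:
        subjects = [f.subject_id or str(i) for i, f in enumerate(fc)]
    subjects = np.asarray([str(s) for s in subjects])
    if len(np.unique(subjects)) < 2:
        raise ValidationError("group inference needs at least 2 subjects")
    z_stack = np.stack([f.z for f in fc])
    if method == "reml":
        t = _reml_t(z_stack, subjects)
        capped = ~np.isfinite(t)
        t = np.clip(np.nan_to_num(t, posinf=T_CAP, neginf=-T_CAP), -T_CAP, T_CAP)
    else:
        t, capped = _one_sample_t(_subject_means(z_stack, subjects))
    t = (t + t.T) / 2.0
    np.fill_diagonal(t, 0.0)
    return GroupFCResult(t=t, capped=capped)


def _reml_t(z_stack, subjects):
    import statsmodels.formula.api as smf
    import pandas as pd
    n = z_stack.shape[1]
    t = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            df = pd.DataFrame({"z": z_stack[:, i, j], "subject": subjects})
            try:
                fit = smf.mixedlm("z ~ 1", df, groups=df["subject"]).fit(reml=True)
                t[i, j] = t[j, i] = fit.tvalues["Intercept"]
            except Exception:
                sm_t, _ = _one_sample_t(_subject_means(z_stack[:, i, j][:, None, None],
                                                       subjects))
                t[i, j] = t[j, i] = float(sm_t.squeeze())
                logger.warning("mixed model failed at entry (%d, %d); subject-mean t used",
                               i, j)
    return t


def permutation_fwer(fc: list, subjects=None, n_perm: int = 1000,
                     alpha: float = 0.05, seed: int = 0) -> GroupFCResult:
    """Max-t permutation FWER control over the group FC matrix.

    Each permutation independently shuffles the ROI labels of every scan
    (rows and columns of its z matrix), the group t matrix is recomputed,
    and its off-diagonal maximum enters the null distribution.  An entry
    is significant when its real t exceeds the (1 - alpha) quantile of
    the null maxima.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is small; the null tail will be coarse", n_perm)
    res = group_fc(fc, subjects)
    if subjects is None:
        subjects = [f.subject_id or str(i) for i, f in enumerate(fc)]
    subjects = np.asarray([str(s) for s in subjects])
    z_stack = np.stack([f.z for f in fc])
    n = z_stack.shape[1]
    rng = np.random.default_rng(seed)
    offdiag = ~np.eye(n, dtype=bool)
    null_max = np.empty(n_perm)
    for p in range(n_perm):
        permuted = np.empty_like(z_stack)
        for s in range(z_stack.shape[0]):
            perm = rng.permutation(n)
            permuted[s] = z_stack[s][np.ix_(perm, perm)]
        t_perm, _ = _one_sample_t(_subject_means(permuted, subjects))
        null_max[p] = t_perm[offdiag].max()
    t_crit = float(np.quantile(null_max, 1.0 - alpha))
    sig = (res.t > t_crit) & offdiag
    if alpha >= 1.0:
        sig = offdiag.copy()
    density = float(sig[offdiag].mean())
    return GroupFCResult(t=res.t, sig=sig, t_crit=t_crit, n_perm=n_perm,
                         density=density, capped=res.capped)


def seed_map(scans: list, seed_box, brain: np.ndarray, subjects=None,
             n_perm: int = 1000, alpha: float = 0.05, seed: int = 0):
    """Group seed-based connectivity t map from a small seed cube.

    ``seed_box`` is ((x0, x1), (y0, y1), (z0, z1)) half-open voxel
    ranges — conventionally a 3 x 3 x 2 cube.  Per scan, every brain
    voxel is correlated with the seed-mean time course and Fisher-z
    transformed; group t is the one-sample t on per-subject mean maps.
    Voxelwise FWER uses a sign-flipping max-t permutation across
    subjects.  Returns (t_map, sig_map, t_crit); out-of-mask maps are 0.
    """
    brain = np.asarray(brain, dtype=bool)
    (x0, x1), (y0, y1), (z0, z1) = seed_box
    seed_mask = np.zeros(brain.shape, dtype=bool)
    seed_mask[x0:x1, y0:y1, z0:z1] = True
    if not (seed_mask & brain).any():
        raise ValidationError("seed cube lies outside the brain mask")
    if subjects is None:
        subjects = [str(i) for i in range(len(scans))]
    subjects = np.asarray([str(s) for s in subjects])

    z_maps = []
    for vol in scans:
        x = vol.data[brain]                       # V x T
        seed_tc = vol.data[seed_mask & brain].mean(axis=0)
        seed_sd = seed_tc.std()
        if seed_sd == 0:
            raise ValidationError("seed time course has zero variance")
        xc = x - x.mean(axis=1, keepdims=True)
        sc = (seed_tc - seed_tc.mean())
        denom = np.sqrt((xc ** 2).sum(axis=1)) * np.sqrt((sc ** 2).sum())
        denom[denom == 0] = np.inf
        r = (xc @ sc) / denom
        z_maps.append(np.arctanh(np.clip(r, -Z_CLIP, Z_CLIP)))
    z_stack = np.stack(z_maps)                    # S x V
    subj_means = _subject_means(z_stack, subjects)
    t_vec, _ = _one_sample_t(subj_means)

    rng = np.random.default_rng(seed)
    n_subj = subj_means.shape[0]
    null_max = np.empty(n_perm)
    for p in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_subj)
        t_perm, _ = _one_sample_t(subj_means * signs[:, None])
        null_max[p] = t_perm.max()
    t_crit = float(np.quantile(null_max, 1.0 - alpha))

    t_map = np.zeros(brain.shape)
    t_map[brain] = t_vec
    sig_map = np.zeros(brain.shape, dtype=bool)
    sig_map[brain] = t_vec > t_crit
    return t_map, sig_map, t_crit


def _upper(mat: np.ndarray) -> np.ndarray:
    n = mat.shape[0]
    iu = np.triu_indices(n, k=1)
    return mat[iu]


def fc_vs_distance(fc_mat: np.ndarray, centroids_mm: np.ndarray):
    """Pearson correlation between off-diagonal FC and ROI centroid distance."""
    fc_mat = np.asarray(fc_mat, dtype=float)
    centroids = np.asarray(centroids_mm, dtype=float)
    n = fc_mat.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 ROIs")
    d = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=-1)
    dv, fv = _upper(d), _upper(fc_mat)
    if dv.std() == 0:
        raise ValidationError("all ROI distances identical")
    r, p = stats.pearsonr(fv, dv)
    return float(r), float(p)


def jaccard_fc_sc(sig_fc: np.ndarray, sc: np.ndarray, n_perm: int = 1000,
                  seed: int = 0):
    """Jaccard overlap of binary FC and SC edge sets, with a permutation p.

    The null rewires the SC edge set as an Erdos-Renyi graph at matched
    density; p is the fraction of rewired graphs reaching at least the
    observed Jaccard.
    """
    a, b = _upper(np.asarray(sig_fc, dtype=bool)), _upper(np.asarray(sc, dtype=bool))
    union = (a | b).sum()
    if union == 0:
        raise ValidationError("both edge sets are empty")
    jac = float((a & b).sum() / union)
    rng = np.random.default_rng(seed)
    m = len(b)
    k = int(b.sum())
    null = np.empty(n_perm)
    for p_i in range(n_perm):
        rewired = np.zeros(m, dtype=bool)
        rewired[rng.choice(m, size=k, replace=False)] = True
        u = (a | rewired).sum()
        null[p_i] = (a & rewired).sum() / u if u else 0.0
    p = float((np.sum(null >= jac) + 1) / (n_perm + 1))
    return jac, p


def _regress_out(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(x)), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def reproducibility(fc: list, subjects=None, mode: str = "split_half",
                    centroids_mm: np.ndarray = None, seed: int = 0):
    """Between-group similarity of FC matrices after distance regression.

    split_half: subjects are split into two random halves; r is the
    Pearson correlation between the halves' mean-z off-diagonal entries
    after regressing Euclidean ROI distance out of both.  leave_one_out:
    each subject's mean matrix is correlated with the remaining group's
    mean; returns (mean r, list of per-subject r).
    """
    if subjects is None:
        subjects = [f.subject_id or str(i) for i, f in enumerate(fc)]
    subjects = np.asarray([str(s) for s in subjects])
    uniq = np.unique(subjects)
    z_stack = np.stack([f.z for f in fc])
    subj_mats = _subject_means(z_stack, subjects)

    dist = None
    if centroids_mm is not None:
        c = np.asarray(centroids_mm, dtype=float)
        dist = _upper(np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1))

    def _sim(m1, m2):
        v1, v2 = _upper(m1), _upper(m2)
        if dist is not None and dist.std() > 0:
            v1, v2 = _regress_out(v1, dist), _regress_out(v2, dist)
        return float(stats.pearsonr(v1, v2)[0])

    if mode == "split_half":
        if len(uniq) < 4:
            raise ValidationError("split-half needs at least 4 subjects")
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(uniq))
        half = len(uniq) // 2
        g1 = subj_mats[order[:half]].mean(axis=0)
        g2 = subj_mats[order[half:]].mean(axis=0)
        return _sim(g1, g2)
    if mode == "leave_one_out":
        if len(uniq) < 3:
            raise ValidationError("leave-one-out needs at least 3 subjects")
        rs = []
        for i in range(len(uniq)):
            rest = np.delete(np.arange(len(uniq)), i)
            rs.append(_sim(subj_mats[i], subj_mats[rest].mean(axis=0)))
        return float(np.mean(rs)), rs
    raise ValidationError(f"unknown reproducibility mode: {mode}")


def specificity_classify(z_specific: float, z_nonspecific: float,
                         thresh: float = 0.1) -> SpecificityOutcome:
    """Four-way seed-FC specificity call from two reference-ROI z values.

    specific:   z_specific > thresh >= z_nonspecific
    unspecific: both above threshold
    none:       both at or below threshold
    spurious:   only the non-specific ROI above threshold
    """
    if not (np.isfinite(z_specific) and np.isfinite(z_nonspecific)):
        raise ValidationError("specificity inputs must be finite")
    s, n = z_specific > thresh, z_nonspecific > thresh
    category = {(True, False): "specific", (True, True): "unspecific",
                (False, False): "none", (False, True): "spurious"}[(s, n)]
    return SpecificityOutcome(category=category, z_specific=float(z_specific),
                              z_nonspecific=float(z_nonspecific), threshold=thresh)


def group_ica(scans: list, brain: np.ndarray, k: int = 30, seed: int = 0,
              per_scan_dim: int = None, max_iter: int = 1000) -> GroupICAResult:
    """Spatial group ICA by temporal concatenation.

    Each scan is voxelwise demeaned and PCA-reduced along time to
    ``per_scan_dim`` components (default min(2k, T - 1)); the reduced
    matrices are stacked and decomposed with fixed-point ICA into K group
    spatial maps (z-scored, skewness-positive).  Per-scan time courses
    come from spatial regression of the group maps onto each scan's
    frames.
    """
    if len(scans) < 2:
        raise ValidationError("group ICA needs at least 2 scans")
    brain = np.asarray(brain, dtype=bool)
    reduced = []
    for vol in scans:
        x = vol.data[brain].T  # T x V
        x = x - x.mean(axis=0)
        m = per_scan_dim or min(2 * k, x.shape[0] - 1)
        if m < 1:
            raise ValidationError("scan too short for the requested reduction")
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        reduced.append(s[:m, None] * vt[:m])  # m x V
    cat = np.vstack(reduced)
    if k > min(cat.shape):
        raise ValidationError(f"k={k} too large for the reduced dimension {min(cat.shape)}")
    ica = FastICA(n_components=k, random_state=seed, whiten="unit-variance",
                  max_iter=max_iter, tol=1e-4)
    sources = ica.fit_transform(cat.T)  # V x K
    maps = sources.T
    maps = (maps - maps.mean(axis=1, keepdims=True)) / maps.std(axis=1, keepdims=True)
    sign = np.where(stats.skew(maps, axis=1) < 0, -1.0, 1.0)
    maps *= sign[:, None]
    tcs = [ic_timecourses(maps, vol, brain) for vol in scans]
    return GroupICAResult(maps=maps, timecourses=tcs, brain=brain)


def ward_linkage(dist: np.ndarray) -> np.ndarray:
    """Ward linkage on a square distance matrix (scipy, condensed form)."""
    from scipy.spatial.distance import squareform
    return hierarchy.linkage(squareform(dist, checks=False), method="ward")


def ic_modules(tc_per_scan: list, subjects=None, n_perm: int = 1000,
               alpha: float = 0.05, seed: int = 0, n_modules: int = None,
               cut_height: float = None):
    """Between-IC group connectivity, Ward dendrogram, and module labels.

    Per scan, IC-to-IC Pearson correlations are Fisher-z transformed;
    group t and max-t FWER significance use the ROI-FC machinery.  The
    linkage metric is d = (max t - t) off-diagonal.  Modules come from an
    explicit cut: component count (``n_modules``) or height.
    Returns (GroupFCResult, linkage matrix, module-label array).
    """
    fc = []
    for i, tc in enumerate(tc_per_scan):
        sd = tc.std(axis=0)
        if np.any(sd == 0):
            logger.warning("scan %d: %d constant IC time courses flagged",
                           i, int((sd == 0).sum()))
        fc.append(scan_fc(tc.T, scan_id=str(i)))
    res = permutation_fwer(fc, subjects=subjects, n_perm=n_perm, alpha=alpha, seed=seed)
    t = res.t.copy()
    d = t.max() - t
    np.fill_diagonal(d, 0.0)
    link = ward_linkage(d)
    if n_modules is not None:
        labels = hierarchy.fcluster(link, t=n_modules, criterion="maxclust")
    elif cut_height is not None:
        labels = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    else:
        labels = np.ones(t.shape[0], dtype=int)
    return res, link, labels


def snr_maps(vol: Volume4D, brain: np.ndarray, cube: int = 5,
             frame_index: int = 9) -> SNRMaps:
    """Spatial and temporal SNR maps.

    sSNR divides each voxel's value in the 10th frame (index 9, 0-based)
    by the standard deviation of an out-of-brain noise pool: two
    ``cube`` x ``cube`` squares at the left and right top corners of
    every slice.  tSNR is the voxel's temporal mean over its temporal
    standard deviation; voxels with zero temporal variance are flagged
    infinite and excluded from the brain average.
    """
    if vol.n_frames <= frame_index:
        raise ValidationError(f"need more than {frame_index} frames for sSNR")
    nx, ny, _ = vol.data.shape[:3]
    if nx < 2 * cube or ny < cube:
        raise ValidationError("grid too small for the corner noise cubes")
    brain = np.asarray(brain, dtype=bool)
    frame = vol.frame(frame_index)
    corners = np.zeros(frame.shape, dtype=bool)
    corners[:cube, -cube:, :] = True
    corners[-cube:, -cube:, :] = True
    noise_sd = frame[corners].std()
    if noise_sd == 0:
        raise ValidationError("corner noise pool has zero variance")
    ssnr = frame / noise_sd
    mean_img = vol.data.mean(axis=3)
    sd_img = vol.data.std(axis=3)
    with np.errstate(divide="ignore", invalid="ignore"):
        tsnr = mean_img / sd_img
    finite_brain = brain & np.isfinite(tsnr)
    if finite_brain.sum() < brain.sum():
        logger.warning("%d constant voxels excluded from the tSNR brain mean",
                       int(brain.sum() - finite_brain.sum()))
    return SNRMaps(ssnr=ssnr, tsnr=tsnr,
                   mean_ssnr=float(ssnr[brain].mean()),
                   mean_tsnr=float(tsnr[finite_brain].mean()))
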