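"""Synthetic rsfMRI phantoms with known ground truth.

A phantom emulates the geometry of a rodent EPI acquisition (64x64
in-plane matrix, 20 slices, TR = 1 s in the full-size configuration; a
32x32x10x300 desk-scale grid by default): an ellipsoidal brain with a
grey-matter shell, white-matter shell and central CSF ventricle, plus

* low-frequency (0.01-0.1 Hz) network signals planted into ROI groups,
* artefact components whose spatial patterns (boundary ring, WM blob,
  slice banding) and time courses (spikes, high-frequency, slow drift)
  deliberately violate the signal-component feature profile,
* a per-frame rigid motion schedule (jitter and spike displacements),
* iid Gaussian thermal noise.

Everything is reproducible from a single spec-level seed; per-scan
substreams are spawned with numpy ``SeedSequence``.  The returned truth
object carries the planted maps, time courses, motion parameters, FD
series, compartment masks, ROI atlas and binary structural-connectivity
matrix, sufficient to score every pipeline stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from ratfc.io_core import MaskSet, ROIAtlas, ScanRecord, ValidationError, Volume4D, write_sidecar, write_volume
from ratfc.motion import RigidTransform, apply_rigid, compute_fd


@dataclass
class NetworkSpec:
    """A functional network: a set of atlas ROIs sharing one time course."""
    rois: tuple
    amplitude: float = 3.0
    band_hz: tuple = (0.01, 0.1)


@dataclass
class ArtefactSpec:
    """A planted artefact component.

    pattern: 'edge_ring' | 'wm_blob' | 'slice_banding'
    tc_kind: 'spikes' | 'high_freq' | 'drift'
    """
    pattern: str
    tc_kind: str
    amplitude: float = 3.0


@dataclass
class MotionSpec:
    """Per-frame rigid jitter plus optional displacement spikes."""
    jitter_mm: float = 0.0
    jitter_rad: float = 0.0
    spike_frames: tuple = ()
    spike_mm: float = 0.5


DEFAULT_NETWORK_ROIS = ((1, 2), (4, 5), (7, 8), (10, 11))


def default_networks(n: int = 4) -> list:
    """Contiguous double-wedge networks separated by quiet sectors.

    No sector of one network touches a sector of another: adjacency
    (plus spatial smoothing) couples network supports and measurably
    hurts ICA separability, as does tiling the whole grey matter.
    """
    return [NetworkSpec(rois=DEFAULT_NETWORK_ROIS[i]) for i in range(n)]


def default_artefacts() -> list:
    return [
        ArtefactSpec("edge_ring", "high_freq"),
        ArtefactSpec("wm_blob", "drift"),
        ArtefactSpec("slice_banding", "spikes"),
    ]


@dataclass
class PhantomSpec:
    """Full description of one synthetic scan; same spec + seed => identical data."""
    nx: int = 32
    ny: int = 32
    nz: int = 10
    nt: int = 300
    voxel_size_mm: tuple = (0.5, 0.5, 1.0)
    tr_s: float = 1.0
    n_rois: int = 12
    networks: list = field(default_factory=default_networks)
    artefacts: list = field(default_factory=default_artefacts)
    motion: MotionSpec = field(default_factory=MotionSpec)
    noise_sigma: float = 2.0
    baseline: dict = field(default_factory=lambda: {"gm": 100.0, "wm": 80.0, "csf": 120.0})
    smoothness_vox: float = 1.5   # intrinsic anatomy smoothness (PSF of the acquisition)
    texture_amp: float = 0.15     # multiplicative anatomical texture (fraction of baseline)
    texture_scale_vox: float = 1.5
    network_interior_erosion: int = 1  # keep network signal off the brain boundary
    seed: int = 0

    def __post_init__(self):
        if min(self.nx, self.ny, self.nz, self.nt) < 1:
            raise ValidationError("phantom grid dimensions must be positive")
        for net in self.networks:
            if max(net.rois, default=0) > self.n_rois:
                raise ValidationError("network references a ROI beyond n_rois")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom scan."""
    masks: MaskSet
    atlas: ROIAtlas
    network_maps: list          # 3D weight maps, one per network
    network_tcs: np.ndarray     # T x n_networks
    artefact_maps: list
    artefact_tcs: np.ndarray    # T x n_artefacts
    motion_params: np.ndarray   # T x 6 (tx ty tz ax ay az)
    fd_mm: np.ndarray
    sc: np.ndarray              # N x N binary structural connectivity
    spec: PhantomSpec = None


def _ellipsoid_level(shape, voxel, semi_frac=(0.40, 0.34, 0.33), center_shift=(0, 0, 0)):
    """Normalised squared radius w.r.t. an ellipsoid on the grid.

    semi_frac are semi-axes as fractions of the grid extent; center_shift
    is in the same fractional units.  The default in-plane anisotropy
    breaks rotational symmetry so rigid rotations are identifiable.
    """
    shape = np.asarray(shape)
    voxel = np.asarray(voxel, dtype=float)
    semi = np.asarray(semi_frac) * shape * voxel
    center = ((shape - 1) / 2.0 + np.asarray(center_shift) * shape) * voxel
    grid = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
    pos = grid * voxel
    return (((pos - center) / semi) ** 2).sum(axis=-1)


def make_masks(spec: PhantomSpec) -> MaskSet:
    """Ellipsoidal brain with an off-centre core: CSF ventricle, WM shell, GM rind.

    The ventricle/WM core sits anterior of the brain centre so the
    anatomy has no rotational symmetry axis.
    """
    shape = (spec.nx, spec.ny, spec.nz)
    level = _ellipsoid_level(shape, spec.voxel_size_mm)
    brain = level <= 1.0
    core = _ellipsoid_level(shape, spec.voxel_size_mm,
                            semi_frac=(0.20, 0.17, 0.25), center_shift=(0, 0.08, 0))
    csf = (core <= 0.15) & brain
    wm = (core > 0.15) & (core <= 1.0) & brain
    dilated = ndimage.binary_dilation(brain, iterations=2)
    return MaskSet(brain=brain, wm=wm, csf=csf, dilated_brain=dilated)


def make_atlas(spec: PhantomSpec, masks: MaskSet) -> ROIAtlas:
    """Partition grey matter into ``n_rois`` angular sectors around the z axis."""
    labels = np.zeros((spec.nx, spec.ny, spec.nz), dtype=np.int32)
    gm = masks.gm
    cx, cy = (spec.nx - 1) / 2.0, (spec.ny - 1) / 2.0
    xs, ys, zs = np.nonzero(gm)
    theta = np.arctan2(ys - cy, xs - cx)  # [-pi, pi)
    sector = np.floor((theta + np.pi) / (2 * np.pi) * spec.n_rois).astype(int)
    sector = np.clip(sector, 0, spec.n_rois - 1)
    labels[xs, ys, zs] = sector + 1
    names = {i + 1: f"ROI-{i + 1:02d}" for i in range(spec.n_rois)}
    systems = {i + 1: "phantom" for i in range(spec.n_rois)}
    return ROIAtlas(labels=labels, names=names, systems=systems,
                    voxel_size_mm=np.asarray(spec.voxel_size_mm))


def bandlimited_timecourse(nt: int, tr_s: float, band_hz, rng) -> np.ndarray:
    """Unit-variance Gaussian time course band-limited to ``band_hz`` (FFT mask)."""
    white = rng.standard_normal(nt)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(nt, d=tr_s)
    keep = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not keep.any():
        keep[1] = True  # lowest nonzero bin if the band resolves to nothing
    spec[~keep] = 0
    tc = np.fft.irfft(spec, nt)
    sd = tc.std()
    return tc / sd if sd > 0 else tc


def artefact_timecourse(kind: str, nt: int, tr_s: float, rng) -> np.ndarray:
    if kind == "spikes":
        tc = 0.3 * rng.standard_normal(nt)
        lo, hi = (5, nt - 5) if nt > 12 else (1, max(2, nt - 1))
        n_spk = min(max(2, nt // 100), hi - lo)
        pos = rng.choice(np.arange(lo, hi), size=n_spk, replace=False)
        tc[pos] += rng.choice([-1, 1], size=n_spk) * 8.0
    elif kind == "high_freq":
        nyq = 0.5 / tr_s
        tc = bandlimited_timecourse(nt, tr_s, (0.25, 0.9 * nyq), rng)
    elif kind == "drift":
        slow = bandlimited_timecourse(nt, tr_s, (1.0 / (nt * tr_s), 0.008), rng)
        tc = slow + np.linspace(-1, 1, nt)
    else:
        raise ValidationError(f"unknown artefact time-course kind: {kind}")
    sd = tc.std()
    return tc / sd if sd > 0 else tc


def artefact_map(pattern: str, masks: MaskSet, rng) -> np.ndarray:
    """Spatial artefact patterns.

    Supports are kept compact (half-shell, half of the WM) so that after
    z-scoring over brain voxels the pattern clears the |z| > 2 feature
    threshold the classifier applies.
    """
    brain = masks.brain
    ny = brain.shape[1]
    if pattern == "edge_ring":
        shell = brain & ~ndimage.binary_erosion(brain, iterations=1)
        quarter = np.zeros(brain.shape, dtype=bool)
        quarter[brain.shape[0] // 2:, ny // 2:, :] = True
        return (shell & quarter).astype(float)
    if pattern == "wm_blob":
        nx = brain.shape[0]
        half = np.zeros(brain.shape, dtype=bool)
        half[nx // 2:, :, :] = True
        return (masks.wm & half).astype(float)
    if pattern == "slice_banding":
        m = np.zeros(brain.shape)
        m[:, :, ::2] = 1.0
        return m * brain
    raise ValidationError(f"unknown artefact pattern: {pattern}")


def motion_schedule(spec: PhantomSpec, rng) -> np.ndarray:
    """T x 6 parameter schedule; frame 0 is the identity reference."""
    params = np.zeros((spec.nt, 6))
    m = spec.motion
    if m.jitter_mm > 0 or m.jitter_rad > 0:
        params[1:, :3] = rng.normal(0, m.jitter_mm, size=(spec.nt - 1, 3))
        params[1:, 3:] = rng.normal(0, m.jitter_rad, size=(spec.nt - 1, 3))
    for f in m.spike_frames:
        if 0 < f < spec.nt:
            params[f, 0] += m.spike_mm
    return params


def make_phantom(spec: PhantomSpec, rng=None):
    """Build one synthetic raw scan plus its ground truth.

    Construction order: static anatomy + planted network and artefact
    signals, rigid resampling of each frame under the motion schedule,
    then iid Gaussian noise (scanner noise is unaffected by head motion).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    masks = make_masks(spec)
    atlas = make_atlas(spec, masks)
    shape3 = (spec.nx, spec.ny, spec.nz)
    voxel = np.asarray(spec.voxel_size_mm, dtype=float)

    anat = np.zeros(shape3)
    anat[masks.gm] = spec.baseline["gm"]
    anat[masks.wm] = spec.baseline["wm"]
    anat[masks.csf] = spec.baseline["csf"]
    if spec.texture_amp > 0:
        # static anatomical texture: real brains are not piecewise constant,
        # and the structure is what makes rigid rotations identifiable
        tex = ndimage.gaussian_filter(rng.standard_normal(shape3), spec.texture_scale_vox)
        anat *= 1.0 + spec.texture_amp * tex / tex.std()
    # partial-volume-like softening: hard compartment edges would make the
    # trilinear-interpolation objective of rigid registration non-smooth
    anat = ndimage.gaussian_filter(anat, spec.smoothness_vox)

    net_maps, net_tcs = [], []
    # network signal stays off the brain boundary: fluctuating intensity on
    # the high-gradient outer shell leaks into rigid motion estimates (and
    # real BOLD is partial-volume diluted at the brain surface anyway)
    if spec.network_interior_erosion > 0:
        interior = ndimage.binary_erosion(masks.brain,
                                          iterations=spec.network_interior_erosion)
    else:
        interior = masks.brain
    for net in spec.networks:
        m = np.isin(atlas.labels, net.rois).astype(float) * interior
        net_maps.append(m)
        net_tcs.append(bandlimited_timecourse(spec.nt, spec.tr_s, net.band_hz, rng))
    net_tcs = np.array(net_tcs).T if net_tcs else np.zeros((spec.nt, 0))

    art_maps, art_tcs = [], []
    for art in spec.artefacts:
        art_maps.append(artefact_map(art.pattern, masks, rng))
        art_tcs.append(artefact_timecourse(art.tc_kind, spec.nt, spec.tr_s, rng))
    art_tcs = np.array(art_tcs).T if art_tcs else np.zeros((spec.nt, 0))

    params = motion_schedule(spec, rng)
    center = (np.array(shape3) - 1) / 2.0 * voxel

    data = np.empty((*shape3, spec.nt))
    for t in range(spec.nt):
        frame = anat.copy()
        for k, net in enumerate(spec.networks):
            frame += net.amplitude * net_tcs[t, k] * net_maps[k]
        for k, art in enumerate(spec.artefacts):
            frame += art.amplitude * art_tcs[t, k] * art_maps[k]
        if np.any(params[t] != 0):
            transform = RigidTransform.from_params(params[t], center_mm=center)
            frame = apply_rigid(frame, transform, voxel)
        data[..., t] = frame
    if spec.noise_sigma > 0:
        data += rng.normal(0, spec.noise_sigma, size=data.shape)

    fd = compute_fd(params)
    n = spec.n_rois
    sc = np.zeros((n, n), dtype=bool)
    for net in spec.networks:
        for a in net.rois:
            for b in net.rois:
                if a != b:
                    sc[a - 1, b - 1] = True

    vol = Volume4D(data=data, voxel_size_mm=voxel, tr_s=spec.tr_s)
    truth = PhantomTruth(masks=masks, atlas=atlas, network_maps=net_maps,
                         network_tcs=net_tcs, artefact_maps=art_maps,
                         artefact_tcs=art_tcs, motion_params=params, fd_mm=fd,
                         sc=sc, spec=spec)
    return vol, truth


def make_group(root, n_subjects: int = 20, scans_per_subject: int = 1,
               spec: PhantomSpec = None, subject_sigma: float = 0.1,
               seed: int = 0, write: bool = True):
    """Generate a group dataset with subject-level amplitude random effects.

    Every scan shares the group network structure; each subject j scales
    all network amplitudes by ``1 + subject_sigma * z_j`` (z_j standard
    normal, clipped at ±2), exercising the random-effect structure the
    group model assumes.  With ``write=True`` the scans are written in the
    package dataset layout with sidecars, masks, atlas and a truth JSON.

    Returns (records, volumes, truths, group_truth_dict).
    """
    if n_subjects < 2:
        raise ValidationError("need at least 2 subjects")
    if spec is None:
        spec = PhantomSpec()
    root = Path(root) if root is not None else None
    ss = np.random.SeedSequence(seed)
    subj_streams = ss.spawn(n_subjects + 1)
    eff_rng = np.random.default_rng(subj_streams[-1])
    subj_effect = np.clip(eff_rng.standard_normal(n_subjects), -2, 2) * subject_sigma

    records, volumes, truths = [], [], []
    for j in range(n_subjects):
        scan_streams = np.random.SeedSequence(subj_streams[j].entropy,
                                              spawn_key=subj_streams[j].spawn_key).spawn(scans_per_subject)
        for s in range(scans_per_subject):
            sub_spec = PhantomSpec(**{**spec.__dict__})
            sub_spec.networks = [
                NetworkSpec(rois=net.rois,
                            amplitude=net.amplitude * (1.0 + subj_effect[j]),
                            band_hz=net.band_hz)
                for net in spec.networks]
            rng = np.random.default_rng(scan_streams[s])
            vol, truth = make_phantom(sub_spec, rng=rng)
            sub_id = f"sub-{j + 1:02d}"
            scan_id = f"{sub_id}_run-{s + 1:02d}"
            if write and root is not None:
                func_dir = root / sub_id / "func"
                func_dir.mkdir(parents=True, exist_ok=True)
                img_path = func_dir / f"{scan_id}_bold.nii.gz"
                write_volume(vol, img_path)
                rec = ScanRecord(scan_id=scan_id, subject_id=sub_id,
                                 n_volumes=vol.n_frames, image_path=img_path)
                write_sidecar(rec, fd=truth.fd_mm, qc={"phantom": True})
            else:
                rec = ScanRecord(scan_id=scan_id, subject_id=sub_id,
                                 n_volumes=vol.n_frames, image_path=None)
            records.append(rec)
            volumes.append(vol)
            truths.append(truth)

    group_truth = {
        "n_subjects": n_subjects,
        "scans_per_subject": scans_per_subject,
        "subject_effect": subj_effect.tolist(),
        "sc": truths[0].sc.astype(int).tolist(),
        "networks": [list(net.rois) for net in spec.networks],
    }
    if write and root is not None:
        _write_common(root, truths[0])
        with open(root / "truth.json", "w") as fh:
            json.dump(group_truth, fh, indent=1)
    return records, volumes, truths, group_truth


def _write_common(root: Path, truth: PhantomTruth):
    mask_dir = root / "masks"
    mask_dir.mkdir(parents=True, exist_ok=True)
    voxel = np.asarray(truth.spec.voxel_size_mm)
    for name in ("brain", "wm", "csf", "dilated_brain"):
        arr = getattr(truth.masks, name).astype(np.float64)
        write_volume(Volume4D(arr, voxel, truth.spec.tr_s), mask_dir / f"{name}.nii.gz")
    atlas_dir = root / "atlas"
    atlas_dir.mkdir(parents=True, exist_ok=True)
    write_volume(Volume4D(truth.atlas.labels.astype(np.float64), voxel, truth.spec.tr_s),
                 atlas_dir / "atlas.nii.gz")
    with open(atlas_dir / "atlas.csv", "w") as fh:
        fh.write("label,name,system\n")
        for lab in truth.atlas.roi_ids:
            fh.write(f"{lab},{truth.atlas.names[lab]},{truth.atlas.systems.get(lab, '')}\n")
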