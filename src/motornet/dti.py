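"""Diffusion-tensor analysis: tensor fitting, FA, deterministic tractography,
ROI-pair tract selection and along-tract FA profiles.

The tracking scheme is fibre assignment by continuous tracking (FACT):
within each voxel the streamline follows that voxel's principal diffusion
eigenvector (sign-aligned with the incoming direction) in a straight segment
to the voxel boundary, and terminates on low anisotropy, a sharp turn, or
grid exit.  Tracts such as the corticospinal tract (precentral gyrus to
brainstem) or callosal motor fibres (left to right precentral gyrus) are then
selected as the streamlines touching both of a pair of ROI masks, and white
matter integrity is summarised as mean fractional anisotropy at normalized
arc-length positions along the tract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .synth import DWIDataset, GradientScheme

__all__ = [
    "TensorField",
    "FAMap",
    "Streamline",
    "Tract",
    "FAProfile",
    "TrackingParams",
    "fit_tensor_loglinear",
    "fractional_anisotropy",
    "fa_from_tensor_invariants",
    "fa_map",
    "principal_directions",
    "fact_track",
    "select_tract_by_rois",
    "tract_fa_profile",
    "mean_tract_fa",
    "segment_fa",
    "load_dwi",
    "load_mask",
    "save_streamlines_trk",
    "save_profile_csv",
]

SEGMENTS = ("rostral", "middle", "caudal")


@dataclass(frozen=True)
class TensorField:
    """Per-voxel symmetric diffusion tensors with a validity mask."""

    data: np.ndarray    # (x, y, z, 3, 3), symmetric
    affine: np.ndarray  # (4, 4) voxel -> world mm
    mask: np.ndarray    # (x, y, z) bool, False where the fit was invalid


@dataclass(frozen=True)
class FAMap:
    data: np.ndarray    # (x, y, z) in [0, 1]
    affine: np.ndarray


@dataclass(frozen=True)
class Streamline:
    points: np.ndarray  # (n, 3) world mm
    seed: tuple[int, int, int]

    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass(frozen=True)
class Tract:
    """Labelled streamline set with the ROI-A centroid fixing its orientation
    convention (the streamline end nearer roi_a is arc position t = 0)."""

    label: str
    streamlines: tuple[Streamline, ...]
    roi_a_centroid: np.ndarray  # world mm

    def __len__(self) -> int:
        return len(self.streamlines)


@dataclass(frozen=True)
class FAProfile:
    positions: np.ndarray   # (n,) strictly increasing in [0, 1]
    mean_fa: np.ndarray     # (n,)
    n_streamlines: np.ndarray  # (n,) int


@dataclass(frozen=True)
class TrackingParams:
    """FACT parameters (field-standard defaults; none are data-derived)."""

    seed_fa: float = 0.2
    stop_fa: float = 0.2
    max_angle_deg: float = 45.0
    min_length_mm: float = 10.0
    max_steps: int = 10000

    def validate(self) -> None:
        if not 0 <= self.stop_fa <= 1 or not 0 <= self.seed_fa <= 1:
            raise ValueError("FA thresholds must be in [0, 1]")
        if not 0 < self.max_angle_deg <= 90:
            raise ValueError("max turning angle must be in (0, 90] degrees")
        if self.min_length_mm < 0:
            raise ValueError("min length must be non-negative")


# ---------------------------------------------------------------------------
# Tensor estimation and FA
# ---------------------------------------------------------------------------

def _design_matrix(scheme: GradientScheme) -> np.ndarray:
    g, b = scheme.directions, scheme.bvalues
    return np.column_stack([
        np.ones(len(b)),
        -b * g[:, 0] ** 2, -b * g[:, 1] ** 2, -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1], -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
    ])


def fit_tensor_loglinear(dwi: DWIDataset) -> TensorField:
    """Ordinary least squares on log-signals for the single-tensor model.

    log S_i = log S0 - b_i g_i^T D g_i is linear in (log S0, D's 6 unique
    components).  Weighted signals exceeding the voxel's mean b=0 signal are
    clamped to it (log attenuation <= 0) before the fit; voxels whose mean
    b=0 signal is non-positive are flagged invalid.
    """
    scheme = dwi.scheme
    if not scheme.weighted.any() or scheme.weighted.all():
        raise ValueError("need both weighted and unweighted acquisitions")
    rank = scheme.design_rank()
    if rank < 6:
        raise ValueError(
            f"gradient scheme is degenerate: quadratic-form design has rank "
            f"{rank} < 6 (need >= 6 non-collinear weighted directions)"
        )

    shape = dwi.data.shape[:3]
    signals = dwi.data.reshape(-1, dwi.data.shape[3]).astype(float)
    s0 = signals[:, ~scheme.weighted].mean(axis=1)
    valid = s0 > 0

    sig = signals.copy()
    w = scheme.weighted
    cap = np.where(valid, s0, 1.0)[:, None]
    sig[:, w] = np.minimum(sig[:, w], cap)          # attenuation <= 1
    sig = np.clip(sig, 1e-12 * np.maximum(cap, 1e-300), None)  # log-safe

    X = _design_matrix(scheme)
    coef = np.log(sig) @ np.linalg.pinv(X).T        # (n_vox, 7)
    dxx, dyy, dzz, dxy, dxz, dyz = coef[:, 1], coef[:, 2], coef[:, 3], coef[:, 4], coef[:, 5], coef[:, 6]
    tensors = np.empty((len(signals), 3, 3))
    tensors[:, 0, 0], tensors[:, 1, 1], tensors[:, 2, 2] = dxx, dyy, dzz
    tensors[:, 0, 1] = tensors[:, 1, 0] = dxy
    tensors[:, 0, 2] = tensors[:, 2, 0] = dxz
    tensors[:, 1, 2] = tensors[:, 2, 1] = dyz
    tensors[~valid] = 0.0
    return TensorField(data=tensors.reshape(shape + (3, 3)),
                       affine=np.asarray(dwi.affine, float),
                       mask=valid.reshape(shape))


def fractional_anisotropy(eigenvalues: np.ndarray) -> np.ndarray | float:
    """FA from the three diffusion-tensor eigenvalues.

    FA = sqrt(1/2) * sqrt((l1-l2)^2 + (l2-l3)^2 + (l1-l3)^2) / sqrt(l1^2+l2^2+l3^2),
    in [0, 1]; an all-zero tensor is defined to have FA 0.  Negative eigenvalues
    are rejected — clamping is the caller's responsibility.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.shape[-1] != 3:
        raise ValueError("expected eigenvalue triples (..., 3)")
    if np.any(lam < 0):
        raise ValueError("eigenvalues must be non-negative")
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l1 - l3) ** 2
    den = l1 ** 2 + l2 ** 2 + l3 ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(0.5) * np.sqrt(num) / np.sqrt(den)
    fa = np.where(den > 0, fa, 0.0)
    out = np.clip(fa, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def fa_from_tensor_invariants(D: np.ndarray) -> np.ndarray | float:
    """FA from rotational invariants, FA = sqrt(3/2 * ||D - (tr D/3) I||_F^2 / ||D||_F^2),
    without eigendecomposition (used as an independent equivalence check)."""
    D = np.asarray(D, dtype=float)
    tr = np.trace(D, axis1=-2, axis2=-1)
    iso = tr[..., None, None] / 3.0 * np.eye(3)
    dev2 = ((D - iso) ** 2).sum(axis=(-2, -1))
    norm2 = (D ** 2).sum(axis=(-2, -1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * dev2 / norm2)
    fa = np.where(norm2 > 0, fa, 0.0)
    out = np.clip(fa, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def fa_map(tensors: TensorField) -> FAMap:
    """Per-voxel FA; eigenvalues are clamped at zero first, invalid voxels get 0."""
    evals = np.linalg.eigvalsh(tensors.data)
    fa = fractional_anisotropy(np.clip(evals, 0.0, None))
    fa = np.where(tensors.mask, fa, 0.0)
    return FAMap(data=fa, affine=tensors.affine)


def principal_directions(tensors: TensorField) -> np.ndarray:
    """Unit principal eigenvector per voxel (world frame), shape (x, y, z, 3)."""
    _, vecs = np.linalg.eigh(tensors.data)
    return vecs[..., :, -1]


# ---------------------------------------------------------------------------
# FACT tractography
# ---------------------------------------------------------------------------

def _propagate(start_vox: np.ndarray, d_world: np.ndarray, fa: np.ndarray,
               pev: np.ndarray, params: TrackingParams, A3: np.ndarray,
               inv3: np.ndarray) -> list[np.ndarray]:
    """Follow the field from a voxel center in one direction.

    Positions are continuous voxel coordinates (voxel i spans [i-0.5, i+0.5));
    recorded points are the voxel-boundary crossings.  On termination the
    endpoint is retracted to the center of the last valid voxel, so every
    recorded point stays inside the tracking mask (sampled quantities such as
    FA are never read off a face shared with an invalid voxel).  Directions
    live in world space; steps are converted through the affine.
    """
    shape = np.asarray(fa.shape)
    cos_max = np.cos(np.radians(params.max_angle_deg))
    pos = start_vox.astype(float).copy()
    cur = np.round(pos).astype(int)
    dirw = d_world / np.linalg.norm(d_world)
    pts: list[np.ndarray] = []
    for _ in range(params.max_steps):
        dvox = inv3 @ dirw
        ndv = np.linalg.norm(dvox)
        if ndv == 0:
            break
        # parametric distance (in units of dvox) to the exit face of voxel `cur`
        with np.errstate(divide="ignore"):
            bound = cur + 0.5 * np.sign(dvox)
            s = np.where(dvox != 0, (bound - pos) / np.where(dvox == 0, 1, dvox), np.inf)
        step = s.min()
        if not np.isfinite(step) or step < 0:
            break
        edge = pos + step * dvox
        nxt_pos = edge + (1e-4 / ndv) * dvox  # nudge past the face to avoid stalls
        nxt = np.round(nxt_pos).astype(int)
        if np.any(nxt < 0) or np.any(nxt >= shape):
            pts.append(cur.astype(float))
            break
        if fa[tuple(nxt)] < params.stop_fa:
            pts.append(cur.astype(float))
            break
        v = pev[tuple(nxt)]
        if np.dot(v, dirw) < 0:
            v = -v
        if np.dot(v, dirw) < cos_max:
            pts.append(cur.astype(float))
            break
        pts.append(nxt_pos)
        pos, cur, dirw = nxt_pos, nxt, v
    return pts


def fact_track(tensors: TensorField, fa: FAMap, params: TrackingParams | None = None,
               seeds: np.ndarray | None = None) -> list[Streamline]:
    """Deterministic FACT streamlines, launched bidirectionally from each seed.

    Seeds default to every valid voxel with FA >= ``params.seed_fa`` (one seed
    at the voxel center, both eigenvector signs).  Returns world-mm polylines of
    at least ``min_length_mm``.
    """
    params = params or TrackingParams()
    params.validate()
    if tensors.data.shape[:3] != fa.data.shape or not np.allclose(tensors.affine, fa.affine):
        raise ValueError("tensor field and FA map must share grid and affine")
    famap = np.where(tensors.mask, fa.data, 0.0)
    pev = principal_directions(tensors)
    A = np.asarray(tensors.affine, float)
    A3, inv3 = A[:3, :3], np.linalg.inv(A[:3, :3])

    if seeds is None:
        seeds = np.argwhere(famap >= params.seed_fa)
    else:
        seeds = np.asarray(seeds, int).reshape(-1, 3)
    if len(seeds) == 0:
        warnings.warn("no seed voxels meet the FA seed threshold", stacklevel=2)
        return []

    def to_world(p_vox: np.ndarray) -> np.ndarray:
        return p_vox @ A3.T + A[:3, 3]

    out: list[Streamline] = []
    for seed in seeds:
        v0 = pev[tuple(seed)]
        fwd = _propagate(seed, v0, famap, pev, params, A3, inv3)
        bwd = _propagate(seed, -v0, famap, pev, params, A3, inv3)
        pts = bwd[::-1] + [seed.astype(float)] + fwd
        arr = to_world(np.asarray(pts))
        keep = np.ones(len(arr), bool)
        keep[1:] = np.linalg.norm(np.diff(arr, axis=0), axis=1) > 1e-9
        arr = arr[keep]
        if len(arr) < 2:
            continue
        sl = Streamline(points=arr, seed=tuple(int(i) for i in seed))
        if sl.length() >= params.min_length_mm:
            out.append(sl)
    return out


# ---------------------------------------------------------------------------
# ROI selection and along-tract profiles
# ---------------------------------------------------------------------------

def _world_to_voxel(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    A = np.asarray(affine, float)
    return (points - A[:3, 3]) @ np.linalg.inv(A[:3, :3]).T


def _touches(points: np.ndarray, mask: np.ndarray, affine: np.ndarray) -> bool:
    idx = np.round(_world_to_voxel(points, affine)).astype(int)
    shape = np.asarray(mask.shape)
    ok = np.all((idx >= 0) & (idx < shape), axis=1)
    if not ok.any():
        return False
    i = idx[ok]
    return bool(mask[i[:, 0], i[:, 1], i[:, 2]].any())


def select_tract_by_rois(streamlines: list[Streamline], roi_a: np.ndarray,
                         roi_b: np.ndarray, affine: np.ndarray,
                         label: str = "tract") -> Tract:
    """Keep exactly the streamlines with >= 1 point in each of two ROI masks.

    "Touching" means some point's nearest voxel lies in the mask.  The ROI-A
    centroid is stored so profiles can be oriented (ROI A end = t = 0, e.g. the
    precentral gyrus for a corticospinal tract).
    """
    roi_a = np.asarray(roi_a).astype(bool)
    roi_b = np.asarray(roi_b).astype(bool)
    if not roi_a.any() or not roi_b.any():
        raise ValueError("ROI masks must be non-empty")
    kept = tuple(s for s in streamlines
                 if _touches(s.points, roi_a, affine) and _touches(s.points, roi_b, affine))
    A = np.asarray(affine, float)
    centroid_vox = np.argwhere(roi_a).mean(axis=0)
    centroid = centroid_vox @ A[:3, :3].T + A[:3, 3]
    return Tract(label=label, streamlines=kept, roi_a_centroid=centroid)


def _resample(points: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    tgt = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(tgt, s, points[:, k]) for k in range(3)])


def tract_fa_profile(tract: Tract, fa: FAMap, n_points: int = 100) -> FAProfile:
    """Mean FA at ``n_points`` equidistant arc-length positions along the tract.

    Each streamline is resampled to the common normalized axis, oriented so its
    ROI-A-proximal end is t = 0, and FA is read off by trilinear interpolation;
    positions are averaged across streamlines.
    """
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    if len(tract) == 0:
        raise ValueError("tract is empty")
    samples = np.empty((len(tract), n_points))
    for i, sl in enumerate(tract.streamlines):
        pts = sl.points
        if (np.linalg.norm(pts[-1] - tract.roi_a_centroid)
                < np.linalg.norm(pts[0] - tract.roi_a_centroid)):
            pts = pts[::-1]
        res = _resample(pts, n_points)
        vox = _world_to_voxel(res, fa.affine)
        samples[i] = map_coordinates(fa.data, vox.T, order=1, mode="nearest")
    return FAProfile(positions=np.linspace(0.0, 1.0, n_points),
                     mean_fa=samples.mean(axis=0),
                     n_streamlines=np.full(n_points, len(tract), dtype=int))


def mean_tract_fa(tract: Tract, fa: FAMap, n_points: int = 100) -> float:
    """Mean of the along-tract profile over all positions."""
    return float(tract_fa_profile(tract, fa, n_points).mean_fa.mean())


def segment_fa(profile: FAProfile, segment: str) -> float:
    """Mean profile FA over a third of the tract: rostral (t < 1/3), middle, or
    caudal (t >= 2/3), in the profile's own orientation (cortex at t = 0)."""
    if segment not in SEGMENTS:
        raise ValueError(f"unknown segment {segment!r}; expected one of {SEGMENTS}")
    t = profile.positions
    lo, hi = {"rostral": (0.0, 1 / 3), "middle": (1 / 3, 2 / 3),
              "caudal": (2 / 3, 1.0 + 1e-12)}[segment]
    mask = (t >= lo) & (t < hi)
    return float(profile.mean_fa[mask].mean())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_dwi(nifti_path: str, bvec_path: str, bval_path: str) -> DWIDataset:
    """Read a 4D NIfTI plus FSL-style bvec/bval text files."""
    import nibabel as nib

    img = nib.load(nifti_path)
    bvec = np.loadtxt(bvec_path)
    if bvec.shape[0] == 3:
        bvec = bvec.T
    bval = np.atleast_1d(np.loadtxt(bval_path)).ravel()
    scheme = GradientScheme(directions=bvec, bvalues=bval)
    return DWIDataset(data=np.asarray(img.dataobj, dtype=float),
                      scheme=scheme, affine=img.affine)


def load_mask(path: str) -> tuple[np.ndarray, np.ndarray]:
    import nibabel as nib

    img = nib.load(path)
    return np.asarray(img.dataobj) > 0, img.affine


def save_streamlines_trk(streamlines: list[Streamline] | Tract, fa: FAMap,
                         path: str) -> None:
    """Write streamlines in TrackVis TRK format (world-mm coordinates)."""
    import nibabel as nib
    from nibabel.streamlines import Tractogram

    sls = streamlines.streamlines if isinstance(streamlines, Tract) else streamlines
    tg = Tractogram([s.points for s in sls], affine_to_rasmm=np.eye(4))
    hdr = {"voxel_to_rasmm": np.asarray(fa.affine, float),
           "dimensions": np.asarray(fa.data.shape, np.int16)}
    nib.streamlines.save(nib.streamlines.TrkFile(tg, hdr), path)


def save_profile_csv(profile: FAProfile, path: str) -> None:
    pd.DataFrame({"t": profile.positions, "mean_fa": profile.mean_fa,
                  "n_streamlines": profile.n_streamlines}).to_csv(path, index=False)
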