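"""Synthetic inputs for the motor-network pipeline, with known ground truth.

Everything the downstream stages consume can be generated here: diffusion-weighted
volumes from a tube-shaped anisotropic phantom (a stand-in for the corticospinal
tract or callosal motor fibres), motor-ROI BOLD time series with a prescribed
inter-regional correlation matrix, and two-group clinical cohorts with planted
effects (a precentral-gyrus thickness deficit, a linear relation between local
functional connectedness and disease-progression rate).

All randomness flows through :class:`numpy.random.Generator` objects derived from
the spec seeds, so identical specs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GradientScheme",
    "PhantomSpec",
    "BoldSpec",
    "CohortSpec",
    "DWIDataset",
    "ROITimeSeries",
    "PhantomDataset",
    "default_gradient_scheme",
    "simulate_dwi_signal",
    "tensor_from_fa",
    "make_tract_phantom",
    "make_bold_dataset",
    "make_cohort_tables",
    "save_dwi",
    "save_mask",
    "save_timeseries_csv",
    "save_spec_yaml",
    "DK_REGIONS",
    "DEFAULT_MOTOR_NODES",
]

# Desikan-Killiany cortical parcellation: 34 regions per hemisphere.
DK_REGIONS: tuple[str, ...] = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal", "middletemporal",
    "paracentral", "parahippocampal", "parsopercularis", "parsorbitalis",
    "parstriangularis", "pericalcarine", "postcentral", "posteriorcingulate",
    "precentral", "precuneus", "rostralanteriorcingulate",
    "rostralmiddlefrontal", "superiorfrontal", "superiorparietal",
    "superiortemporal", "supramarginal", "temporalpole", "transversetemporal",
)

# Default motor-network node set: primary motor, supplementary motor and
# premotor cortex in each hemisphere.
DEFAULT_MOTOR_NODES: tuple[tuple[str, str], ...] = (
    ("precentral_L", "L"), ("precentral_R", "R"),
    ("sma_L", "L"), ("sma_R", "R"),
    ("premotor_L", "L"), ("premotor_R", "R"),
)


# ---------------------------------------------------------------------------
# Gradient scheme and the single-tensor signal model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradientScheme:
    """Diffusion gradient table: unit directions and b-values (s/mm^2).

    b = 0 rows are unweighted acquisitions; their direction is ignored.
    """

    directions: np.ndarray  # (m, 3)
    bvalues: np.ndarray     # (m,)

    def __post_init__(self) -> None:
        d = np.asarray(self.directions, dtype=float)
        b = np.asarray(self.bvalues, dtype=float)
        if d.ndim != 2 or d.shape[1] != 3 or b.shape != (d.shape[0],):
            raise ValueError("directions must be (m, 3) with matching bvalues (m,)")
        weighted = b > 0
        if weighted.any():
            norms = np.linalg.norm(d[weighted], axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("weighted gradient directions must be unit vectors")
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "bvalues", b)

    def __len__(self) -> int:
        return len(self.bvalues)

    @property
    def weighted(self) -> np.ndarray:
        return self.bvalues > 0

    def design_rank(self) -> int:
        """Rank of the 6-column quadratic-form design of the weighted rows."""
        g = self.directions[self.weighted]
        if len(g) == 0:
            return 0
        q = np.column_stack([
            g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
        ])
        return int(np.linalg.matrix_rank(q))


def _fibonacci_sphere(n: int) -> np.ndarray:
    # Quasi-uniform spherical point set (golden-angle spiral).
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + 5.0 ** 0.5) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def default_gradient_scheme(n_directions: int = 30, b: float = 1000.0,
                            n_b0: int = 5) -> GradientScheme:
    """30 quasi-uniformly distributed directions at b=1000 plus 5 b=0 scans."""
    dirs = np.vstack([np.zeros((n_b0, 3)), _fibonacci_sphere(n_directions)])
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(b))])
    return GradientScheme(dirs, bvals)


def simulate_dwi_signal(D: np.ndarray, scheme: GradientScheme, S0: float,
                        noise_sigma: float = 0.0,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Single-tensor diffusion signal S_i = S0 * exp(-b_i g_i^T D g_i).

    ``D`` may be one tensor ``(3, 3)`` or a field ``(..., 3, 3)``; the result has
    shape ``(..., m)``.  When ``noise_sigma > 0`` Rician noise is added (the
    magnitude of the complex Gaussian-corrupted signal), which is the noise
    distribution of scanner magnitude images.
    """
    D = np.asarray(D, dtype=float)
    if D.shape[-2:] != (3, 3):
        raise ValueError("D must have shape (..., 3, 3)")
    if not np.allclose(D, np.swapaxes(D, -1, -2), atol=1e-10):
        raise ValueError("diffusion tensor must be symmetric")
    if S0 <= 0:
        raise ValueError("S0 must be positive")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    g = scheme.directions
    quad = np.einsum("mi,...ij,mj->...m", g, D, g)
    signal = S0 * np.exp(-scheme.bvalues * quad)
    if noise_sigma > 0:
        if rng is None:
            raise ValueError("rng is required when noise_sigma > 0")
        re = signal + rng.normal(0.0, noise_sigma, signal.shape)
        im = rng.normal(0.0, noise_sigma, signal.shape)
        signal = np.hypot(re, im)
    return signal


def tensor_from_fa(direction: np.ndarray, fa: float,
                   mean_diffusivity: float = 0.7e-3) -> np.ndarray:
    """Prolate tensor with given principal axis, FA and mean diffusivity.

    For an axially symmetric tensor with eigenvalues ``m(1+2a), m(1-a), m(1-a)``
    the anisotropy is ``FA = sqrt(3) a / sqrt(1 + 2 a^2)``, which inverts to
    ``a = FA / sqrt(3 - 2 FA^2)`` — valid for FA in [0, 1).
    """
    if not 0.0 <= fa < 1.0:
        raise ValueError("fa must be in [0, 1)")
    v = np.asarray(direction, dtype=float)
    v = v / np.linalg.norm(v)
    a = fa / np.sqrt(3.0 - 2.0 * fa ** 2)
    m = mean_diffusivity
    lam_par = m * (1.0 + 2.0 * a)
    lam_perp = m * (1.0 - a)
    return lam_perp * np.eye(3) + (lam_par - lam_perp) * np.outer(v, v)


# ---------------------------------------------------------------------------
# Tube phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Tube-shaped anisotropic tract in an isotropic-ish background.

    ``fa_profile`` maps normalized arc position t in [0, 1] (t=0 at the
    "cortex" end) to the planted FA of in-tube voxels.  ``background_fa`` > 0
    is realised as mildly prolate tensors with random (seeded) orientation so
    a noise-free fit recovers it exactly; 0 gives perfectly isotropic voxels.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 36)
    voxel_size: float = 2.0  # mm, isotropic
    centerline: Callable[[np.ndarray], np.ndarray] | np.ndarray | None = None
    radius_mm: float = 4.0
    fa_profile: Callable[[np.ndarray], np.ndarray] | float = 0.7
    background_fa: float = 0.05
    S0: float = 1000.0
    noise_sigma: float = 0.0
    seed: int = 0
    scheme: GradientScheme = field(default_factory=default_gradient_scheme)
    mean_diffusivity: float = 0.7e-3
    end_roi_mm: float = 5.0  # end-slab ROI depth along the tube

    def centerline_points(self, n: int = 200) -> np.ndarray:
        """World-mm sample points of the tube axis (default: straight, long axis)."""
        if self.centerline is None:
            shape = np.asarray(self.grid_shape, dtype=float)
            axis = int(np.argmax(shape))
            margin = 1.0  # voxels kept clear of the grid faces
            t = np.linspace(0.0, 1.0, n)
            pts_vox = np.tile((shape - 1) / 2.0, (n, 1))
            pts_vox[:, axis] = margin + t * (shape[axis] - 1 - 2 * margin)
            return pts_vox * self.voxel_size
        if callable(self.centerline):
            return np.asarray(self.centerline(np.linspace(0.0, 1.0, n)), float)
        pts = np.asarray(self.centerline, dtype=float)
        # densify a user-supplied polyline by linear interpolation
        s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        s = s / s[-1]
        t = np.linspace(0.0, 1.0, n)
        return np.column_stack([np.interp(t, s, pts[:, k]) for k in range(3)])

    def profile(self, t: np.ndarray) -> np.ndarray:
        if callable(self.fa_profile):
            vals = np.asarray(self.fa_profile(np.asarray(t, float)), float)
        else:
            vals = np.full(np.shape(t), float(self.fa_profile))
        if np.any(vals < 0) or np.any(vals >= 1):
            raise ValueError("fa_profile values must lie in [0, 1)")
        return vals


@dataclass(frozen=True)
class DWIDataset:
    """4D diffusion-weighted signals plus gradient table and voxel->world affine."""

    data: np.ndarray  # (x, y, z, m)
    scheme: GradientScheme
    affine: np.ndarray  # (4, 4)

    def __post_init__(self) -> None:
        if self.data.ndim != 4 or self.data.shape[3] != len(self.scheme):
            raise ValueError("data must be 4D with last axis matching the scheme")
        if np.any(self.data < 0):
            raise ValueError("signals must be non-negative")


@dataclass(frozen=True)
class PhantomDataset:
    """A generated phantom: the DWI data plus all ground truth."""

    dwi: DWIDataset
    masks: dict[str, np.ndarray]          # cortex / brainstem / contralateral, uint8
    centerline: np.ndarray                # (n, 3) world mm
    tube_mask: np.ndarray                 # bool, in-tube voxels
    true_fa: np.ndarray                   # planted FA per voxel
    arc_position: np.ndarray              # normalized t of nearest axis point


def make_tract_phantom(spec: PhantomSpec) -> PhantomDataset:
    """Build the tube phantom and simulate its DWI acquisition.

    In-tube voxels receive prolate tensors whose principal axis is tangent to
    the centerline and whose FA follows ``spec.fa_profile`` of the normalized
    arc position; ROI masks cover the tube ends (plus a third mask mirrored
    through the mid-sagittal plane, standing in for the contralateral cortex).
    """
    if spec.radius_mm <= spec.voxel_size / 2.0:
        raise ValueError("tube radius must exceed half a voxel")
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.grid_shape)
    affine = np.diag([spec.voxel_size] * 3 + [1.0])

    cl = spec.centerline_points()
    cl_vox = cl / spec.voxel_size
    if np.any(cl_vox < -0.5) or np.any(cl_vox > np.asarray(shape) - 0.5):
        raise ValueError(
            "tube centerline leaves the voxel grid: centerline (voxel units) "
            f"spans {cl_vox.min(axis=0)}..{cl_vox.max(axis=0)} for grid {shape}"
        )
    seg = np.diff(cl, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    t_axis = arc / arc[-1]
    tangents = np.vstack([seg, seg[-1:]])
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)

    centers = (np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"),
                        axis=-1).reshape(-1, 3).astype(float)) * spec.voxel_size
    # nearest centerline sample per voxel center
    d2 = ((centers[:, None, :] - cl[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    dist = np.sqrt(d2[np.arange(len(centers)), nearest])
    t_map = t_axis[nearest]
    tube = dist <= spec.radius_mm
    # finite cylinder: cut the spherical caps that a nearest-point distance
    # test would add beyond the centerline ends
    axial = np.einsum("ij,ij->i", centers - cl[nearest], tangents[nearest])
    tube &= ~((nearest == 0) & (axial < 0))
    tube &= ~((nearest == len(cl) - 1) & (axial > 0))

    fa_planted = np.where(tube, spec.profile(t_map), spec.background_fa)
    tensors = np.empty((len(centers), 3, 3))
    bg_dirs = rng.normal(size=(len(centers), 3))
    bg_dirs /= np.linalg.norm(bg_dirs, axis=1, keepdims=True)
    for i in range(len(centers)):
        axis = tangents[nearest[i]] if tube[i] else bg_dirs[i]
        tensors[i] = tensor_from_fa(axis, fa_planted[i], spec.mean_diffusivity)

    signals = simulate_dwi_signal(tensors, spec.scheme, spec.S0,
                                  spec.noise_sigma, rng)
    data = signals.reshape(shape + (len(spec.scheme),))

    end_t = spec.end_roi_mm / arc[-1]
    cortex = (tube & (t_map <= end_t)).reshape(shape)
    brainstem = (tube & (t_map >= 1.0 - end_t)).reshape(shape)
    contralateral = cortex[::-1, :, :].copy()  # mirror across mid-sagittal (x) plane

    return PhantomDataset(
        dwi=DWIDataset(data=data, scheme=spec.scheme, affine=affine),
        masks={
            "cortex": cortex.astype(np.uint8),
            "brainstem": brainstem.astype(np.uint8),
            "contralateral": contralateral.astype(np.uint8),
        },
        centerline=cl,
        tube_mask=tube.reshape(shape),
        true_fa=fa_planted.reshape(shape),
        arc_position=t_map.reshape(shape),
    )


# ---------------------------------------------------------------------------
# BOLD time series with a prescribed correlation matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoldSpec:
    """Resting-state BOLD generator spec.

    The defaults emulate an 8-minute acquisition sampled every 0.5 s
    (960 time points) over the six-node motor network.
    """

    nodes: tuple[str, ...] = tuple(n for n, _ in DEFAULT_MOTOR_NODES)
    hemispheres: tuple[str, ...] = tuple(h for _, h in DEFAULT_MOTOR_NODES)
    target_corr: np.ndarray | None = None  # defaults to identity
    n_timepoints: int = 960
    dt: float = 0.5           # s
    noise_frac: float = 0.1   # white measurement noise amplitude, fraction of signal SD
    cutoff_hz: float = 0.1    # low-pass corner of the haemodynamic band
    seed: int = 0

    def target(self) -> np.ndarray:
        k = len(self.nodes)
        if self.target_corr is None:
            return np.eye(k)
        m = np.asarray(self.target_corr, dtype=float)
        if m.shape != (k, k):
            raise ValueError("target correlation matrix shape mismatch")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("target correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValueError("target correlation matrix must have unit diagonal")
        return m


@dataclass(frozen=True)
class ROITimeSeries:
    """Per-ROI signal matrix (samples x nodes) with hemisphere labels."""

    nodes: tuple[str, ...]
    hemispheres: tuple[str, ...]
    data: np.ndarray  # (n_samples, n_nodes)
    dt: float         # sampling interval, s

    def __post_init__(self) -> None:
        if len(self.nodes) < 2:
            raise ValueError("need at least 2 nodes")
        if len(self.hemispheres) != len(self.nodes):
            raise ValueError("hemisphere labels must cover all nodes")
        if self.data.ndim != 2 or self.data.shape[1] != len(self.nodes):
            raise ValueError("data must be (samples, nodes)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains missing/non-finite samples")


def _psd_factor(m: np.ndarray) -> np.ndarray:
    """Factor L with L L^T = m for a symmetric PSD matrix (eigh-based).

    Rejects matrices with a meaningfully negative eigenvalue, naming it, so the
    caller learns which prescription was infeasible.  Zero eigenvalues (e.g. a
    duplicated node at r = 1) are allowed.
    """
    w, v = np.linalg.eigh(m)
    if w.min() < -1e-8:
        raise ValueError(
            f"target correlation matrix is not positive semi-definite: "
            f"eigenvalue {w.min():.6g} < 0"
        )
    return v * np.sqrt(np.clip(w, 0.0, None))


def make_bold_dataset(spec: BoldSpec) -> ROITimeSeries:
    """Generate band-limited BOLD-like series with the prescribed correlations.

    Gaussian innovations are low-pass filtered below ``cutoff_hz`` (zero-phase
    Butterworth), empirically whitened, and mixed through a factor of the target
    matrix, so the sample correlation of the noise-free signals equals the target
    exactly; white measurement noise (``noise_frac``) then perturbs it slightly.
    """
    from scipy.signal import butter, filtfilt

    k = len(spec.nodes)
    n = spec.n_timepoints
    if n < 2 * k:
        raise ValueError("n_timepoints must be at least twice the node count")
    target = spec.target()
    L = _psd_factor(target)

    rng = np.random.default_rng(spec.seed)
    pad = 200
    innov = rng.standard_normal((n + 2 * pad, k))
    nyq = 0.5 / spec.dt
    b, a = butter(2, spec.cutoff_hz / nyq, btype="low")
    filt = filtfilt(b, a, innov, axis=0)[pad:-pad]
    filt = filt - filt.mean(axis=0)
    # empirical whitening: exact unit sample covariance before mixing
    cov = filt.T @ filt / (n - 1)
    filt = filt @ np.linalg.inv(np.linalg.cholesky(cov)).T
    signal = filt @ L.T
    if spec.noise_frac > 0:
        signal = signal + spec.noise_frac * rng.standard_normal((n, k))
    return ROITimeSeries(nodes=spec.nodes, hemispheres=spec.hemispheres,
                         data=signal, dt=spec.dt)


def motor_network_target(within_r: float = 0.6, between_r: float = 0.2,
                         homotopic_r: float | None = None,
                         nodes: Sequence[tuple[str, str]] = DEFAULT_MOTOR_NODES,
                         ) -> np.ndarray:
    """Convenience correlation matrix: within-hemisphere vs cross-hemisphere blocks.

    ``homotopic_r`` (same region, opposite hemisphere) defaults to ``within_r``.
    """
    names = [n for n, _ in nodes]
    hemi = [h for _, h in nodes]
    k = len(names)
    if homotopic_r is None:
        homotopic_r = within_r
    m = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            if hemi[i] == hemi[j]:
                r = within_r
            elif names[i].rsplit("_", 1)[0] == names[j].rsplit("_", 1)[0]:
                r = homotopic_r
            else:
                r = between_r
            m[i, j] = m[j, i] = r
    w = np.linalg.eigvalsh(m)
    if w.min() < -1e-8:
        raise ValueError(f"requested block structure is not positive "
                         f"semi-definite (eigenvalue {w.min():.4g})")
    return m


# ---------------------------------------------------------------------------
# Clinical cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort generator (patients vs controls).

    Planted effects: a thickness deficit on the precentral gyrus in patients and
    a linear dependence of the functional clustering ratio gamma on the implied
    disease-progression rate.  The progression-rate column itself is left to the
    stats stage (derived from ALSFRS-R and duration), so the planted gamma
    relation is built from the same quantities that stage will compute.
    """

    n_per_group: int = 12
    age_mean: float = 49.0
    age_sd: float = 10.0
    age_range: tuple[float, float] = (33.0, 65.0)
    regions: tuple[str, ...] = DK_REGIONS
    region_mean: float = 2.5            # mm, generic cortical thickness
    precentral_mean: float = 2.68       # mm, control precentral gyrus
    thickness_sd: float = 0.1           # mm, between-subject SD per region
    precentral_deficit: float = 0.09    # mm, planted patient deficit
    alsfrs_range: tuple[float, float] = (30.0, 46.0)
    duration_range: tuple[float, float] = (7.0, 30.0)  # months
    gamma_base: float = 1.6
    gamma_slope: float = 0.6            # gamma per (ALSFRS-R point / month)
    gamma_noise: float = 0.12
    fa_cst_rostral_mean: float = 0.55
    fa_cc_mean: float = 0.60
    fa_sd: float = 0.03
    fa_patient_deficit: float = 0.05
    n_connections_mean: float = 10.0
    n_interhemispheric_mean: float = 5.0
    seed: int = 0


def make_cohort_tables(spec: CohortSpec) -> pd.DataFrame:
    """Per-subject cohort table with planted group and clinical effects.

    Columns: id, group, age, affected_side, thickness_{lh,rh}_<region> (all
    parcellation regions), thickness_whole_brain, alsfrs_r,
    disease_duration_months, fa_cst_rostral, fa_cc, n_connections,
    n_interhemispheric, gamma.  The progression-rate column is intentionally
    absent (a downstream derivation).
    """
    if len(spec.regions) == 0:
        raise ValueError("region list must not be empty")
    if spec.n_per_group < 3:
        raise ValueError("need at least 3 subjects per group")
    if spec.thickness_sd < 0 or spec.fa_sd < 0 or spec.gamma_noise < 0:
        raise ValueError("noise SDs must be non-negative")
    if spec.duration_range[0] <= 0:
        raise ValueError("disease durations must be positive")

    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_group
    groups = ["patient"] * n + ["control"] * n
    n_total = 2 * n
    cols = [f"thickness_{h}_{r}" for h in ("lh", "rh") for r in spec.regions]
    base = np.full(len(cols), spec.region_mean)
    for i, c in enumerate(cols):
        if c.endswith("_precentral"):
            base[i] = spec.precentral_mean

    rows: list[dict] = []
    ages = np.clip(rng.normal(spec.age_mean, spec.age_sd, n_total), *spec.age_range)
    for i in range(n_total):
        is_patient = groups[i] == "patient"
        thick = base + rng.normal(0.0, spec.thickness_sd, len(cols))
        if is_patient:
            for j, c in enumerate(cols):
                if c.endswith("_precentral"):
                    thick[j] -= spec.precentral_deficit
        row = {
            "id": f"{'P' if is_patient else 'C'}{i % n + 1:02d}",
            "group": groups[i],
            "age": ages[i],
            "affected_side": rng.choice(["L", "R"]) if is_patient else "",
        }
        row.update(dict(zip(cols, thick)))
        row["thickness_whole_brain"] = float(np.mean(thick))
        if is_patient:
            score = rng.uniform(*spec.alsfrs_range)
            duration = rng.uniform(*spec.duration_range)
            rate = (48.0 - score) / duration  # same derivation the stats stage applies
        else:
            score, duration, rate = np.nan, np.nan, np.nan
        row["alsfrs_r"] = score
        row["disease_duration_months"] = duration
        fa_shift = spec.fa_patient_deficit if is_patient else 0.0
        row["fa_cst_rostral"] = rng.normal(spec.fa_cst_rostral_mean - fa_shift, spec.fa_sd)
        row["fa_cc"] = rng.normal(spec.fa_cc_mean - fa_shift, spec.fa_sd)
        n_inter = int(np.clip(round(rng.normal(
            spec.n_interhemispheric_mean - (1.0 if is_patient else 0.0), 1.5)), 0, 9))
        row["n_interhemispheric"] = n_inter
        row["n_connections"] = n_inter + int(np.clip(round(rng.normal(
            spec.n_connections_mean - spec.n_interhemispheric_mean, 1.5)), 0, 6))
        # controls get the patient-mean offset so the group means of gamma match
        rate_for_gamma = rate if is_patient else _mean_rate(spec)
        row["gamma"] = (spec.gamma_base + spec.gamma_slope * rate_for_gamma
                        + rng.normal(0.0, spec.gamma_noise))
        rows.append(row)
    return pd.DataFrame(rows)


def _mean_rate(spec: CohortSpec) -> float:
    # E[(48 - score)/duration] for uniform score and duration
    lo_s, hi_s = spec.alsfrs_range
    lo_d, hi_d = spec.duration_range
    return (48.0 - (lo_s + hi_s) / 2.0) * np.log(hi_d / lo_d) / (hi_d - lo_d)


# ---------------------------------------------------------------------------
# On-disk formats
# ---------------------------------------------------------------------------

def save_dwi(dwi: DWIDataset, prefix: str) -> None:
    """Write ``<prefix>.nii.gz`` plus FSL-style ``<prefix>.bvec``/``.bval``."""
    import nibabel as nib

    nib.save(nib.Nifti1Image(dwi.data.astype(np.float32), dwi.affine),
             f"{prefix}.nii.gz")
    np.savetxt(f"{prefix}.bvec", dwi.scheme.directions.T, fmt="%.8f")
    np.savetxt(f"{prefix}.bval", dwi.scheme.bvalues[None, :], fmt="%.1f")


def save_mask(mask: np.ndarray, affine: np.ndarray, path: str) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), path)


def save_timeseries_csv(ts: ROITimeSeries, path: str) -> None:
    """One row per node: node, hemisphere, then the samples."""
    df = pd.DataFrame(ts.data.T)
    df.insert(0, "hemisphere", ts.hemispheres)
    df.insert(0, "node", ts.nodes)
    df.to_csv(path, index=False)


def _yaml_safe(obj):
    if isinstance(obj, dict):
        return {k: _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if callable(obj):
        return repr(obj)
    return obj


def save_spec_yaml(spec, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_yaml_safe(dataclasses.asdict(spec)), fh, sort_keys=True)
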