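"""Synthetic multiparametric prostate MRI phantom.

Generates cohorts of mpMRI "studies" (T2W volume, multi-b DWI stack, dynamic
DCE concentration stack, lesion/healthy-tissue segmentations) with known
voxel-wise ground truth, emulating the statistical structure of a
single-centre PI-RADS 4-5 vs healthy-tissue dataset:

* DWI follows the diffusion-kurtosis signal model
  ``S(b) = S0 * exp(-b*D + b^2*D^2*K/6)`` with Rician (magnitude) noise;
  multiple averages per b-value are emulated by dividing the noise sd by
  sqrt(n_averages), which gives the mean of repeats its exact distribution
  up to the small Rician-bias difference.
* DCE works directly in tissue-concentration units: the standard Tofts model
  ``Ct(t) = Ktrans * int_0^t Cp(tau) exp(-kep (t - tau)) dtau`` driven by a
  bi-exponential population arterial input function (Weinmann constants by
  default), with additive Gaussian noise.
* T2W is a Gaussian texture with class-specific mean, sd and spatial
  correlation length.
* Lesions and healthy-tissue reference regions are axis-aligned ellipsoidal
  VOIs placed without overlap; the same physical ellipsoid is rasterized on
  the anatomical and on the coarser functional grids, so the pipeline's grid
  resampling step is exercised exactly as on real data.

Class parameter defaults (lesion: lower D, higher K, higher Ktrans; distinct
T2W intensity/texture) are typical peripheral-zone values from the prostate
DKI/DCE literature and are fully configurable through :class:`TissueParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grid import Volume, VolumeGrid
from .roi import HEALTHY, LESION, SegmentationRecord

__all__ = [
    "TissueParams",
    "AifParams",
    "CohortSpec",
    "SyntheticStudy",
    "SyntheticCohort",
    "LESION_PARAMS",
    "HEALTHY_PARAMS",
    "WEINMANN_AIF",
    "PROTOCOL_BVALS",
    "PROTOCOL_BVAL_AVERAGES",
    "default_dce_times",
    "simulate_dwi_signal",
    "population_aif",
    "tofts_convolve",
    "simulate_dce_curve",
    "generate_cohort",
]


# --------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class TissueParams:
    """Per-class generative parameters.

    s0        baseline DWI signal (a.u., > 0)
    d         diffusion coefficient D (mm^2/s)
    k         diffusional kurtosis K (dimensionless, >= 0)
    ktrans    volume transfer constant (1/min)
    kep       rate constant (1/min)
    t2w_mean  T2W intensity mean (a.u.)
    t2w_sd    T2W intensity sd (a.u.)
    t2w_smooth  T2W texture correlation length (voxels); 0 = white noise
    """

    s0: float = 1000.0
    d: float = 1.6e-3
    k: float = 0.7
    ktrans: float = 0.15
    kep: float = 0.45
    t2w_mean: float = 400.0
    t2w_sd: float = 50.0
    t2w_smooth: float = 0.0

    def __post_init__(self) -> None:
        if self.s0 <= 0:
            raise ValueError("s0 must be > 0")
        if self.d <= 0:
            raise ValueError("d must be > 0")
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.ktrans < 0:
            raise ValueError("ktrans must be >= 0")
        if self.kep <= 0:
            raise ValueError("kep must be > 0")
        if not (0.0 <= self.ve <= 1.0):
            raise ValueError(f"ve = ktrans/kep = {self.ve:.3f} outside (0, 1]")
        if self.t2w_sd < 0:
            raise ValueError("t2w_sd must be >= 0")

    @property
    def ve(self) -> float:
        """Extravascular extracellular volume fraction, ktrans / kep."""
        return self.ktrans / self.kep


@dataclass(frozen=True)
class AifParams:
    """Bi-exponential population arterial input function.

    Cp(t) = 0 for t < onset, else
    Cp(t) = dose * (a1*exp(-m1*(t-onset)) + a2*exp(-m2*(t-onset)))
    with t in minutes, amplitudes in kg/L, rates in 1/min, dose in mM.
    """

    dose: float = 0.1
    a1: float = 3.99
    a2: float = 4.78
    m1: float = 0.144
    m2: float = 0.0111
    onset: float = 0.15

    def __post_init__(self) -> None:
        if min(self.dose, self.a1, self.a2, self.m1, self.m2) < 0:
            raise ValueError("AIF amplitudes, rates and dose must be >= 0")


#: Weinmann population AIF (dose in mmol/kg-equivalent scale); onset at the
#: end of the first dynamic phase, matching the injection protocol emulated.
WEINMANN_AIF = AifParams()

#: Acquisition b-value scheme of the emulated protocol (s/mm^2).
PROTOCOL_BVALS = (0.0, 250.0, 500.0, 1000.0, 1500.0, 2000.0, 2500.0)

#: Signal averages per b-value (low/mid/high-b groups).
PROTOCOL_BVAL_AVERAGES = (4, 4, 4, 6, 6, 8, 8)

#: Lesion class: restricted diffusion (low D, high K), hypervascular
#: (high Ktrans), T2W-hypointense with smoother texture.
LESION_PARAMS = TissueParams(
    s0=1000.0, d=1.1e-3, k=1.0, ktrans=0.30, kep=0.70,
    t2w_mean=280.0, t2w_sd=40.0, t2w_smooth=1.0,
)

#: Healthy peripheral-zone tissue.
HEALTHY_PARAMS = TissueParams(
    s0=1000.0, d=1.9e-3, k=0.55, ktrans=0.08, kep=0.35,
    t2w_mean=430.0, t2w_sd=55.0, t2w_smooth=0.3,
)


def default_dce_times(n_phases: int = 60, dt_s: float = 9.0) -> np.ndarray:
    """Acquisition times (minutes) of the dynamic series: ``n_phases``
    consecutive phases at ``dt_s`` seconds per phase, first phase at t=0."""
    return np.arange(n_phases) * (dt_s / 60.0)


@dataclass(frozen=True)
class CohortSpec:
    """Full specification of a synthetic cohort (the study conditions)."""

    n_subjects: int = 65
    n_lesion_vois: int = 69
    n_ht_vois: int = 49
    lesion_params: TissueParams = LESION_PARAMS
    ht_params: TissueParams = HEALTHY_PARAMS
    aif: AifParams = WEINMANN_AIF
    bvals: tuple[float, ...] = PROTOCOL_BVALS
    bval_averages: tuple[int, ...] = PROTOCOL_BVAL_AVERAGES
    dce_times: tuple[float, ...] = tuple(float(t) for t in default_dce_times())
    noise_sd_dwi: float = 20.0          # SNR0 = 50 at s0 = 1000, before averaging
    noise_sd_dce: float = 0.02          # mM
    voi_axes_mm: tuple[float, float] = (3.0, 7.0)   # semi-axis range, in-plane
    voi_axes_z_mm: tuple[float, float] = (3.0, 6.0)  # semi-axis range, slice axis
    t2w_grid: VolumeGrid = VolumeGrid((48, 48, 16), (1.25, 1.25, 3.0))
    dwi_grid: VolumeGrid = VolumeGrid((24, 24, 16), (2.5, 2.5, 3.0))
    dce_grid: VolumeGrid = VolumeGrid((24, 24, 16), (2.5, 2.5, 3.0))
    voi_param_cv: float = 0.08          # between-VOI lognormal spread of class means
    voxel_param_cv: float = 0.12        # within-VOI voxel-wise lognormal spread
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lesion_vois + self.n_ht_vois < 2 or min(self.n_lesion_vois, self.n_ht_vois) < 1:
            raise ValueError("need at least one VOI of each class")
        b = np.asarray(self.bvals, dtype=float)
        if b.min() < 0 or not np.all(np.diff(b) > 0) or b[0] != 0:
            raise ValueError("bvals must be non-negative, strictly increasing, starting at 0")
        if len(self.bval_averages) != len(self.bvals):
            raise ValueError("bval_averages must match bvals")
        t = np.asarray(self.dce_times, dtype=float)
        if not np.all(np.diff(t) > 0):
            raise ValueError("dce_times must be strictly increasing")
        if self.noise_sd_dwi < 0 or self.noise_sd_dce < 0:
            raise ValueError("noise scales must be >= 0")


@dataclass
class SyntheticStudy:
    """One subject's simulated mpMRI examination + voxel-wise ground truth."""

    subject_id: str
    t2w: Volume
    dwi: Volume          # 4D, trailing axis = b-values
    dce: Volume          # 4D, trailing axis = dynamic phases (concentration, mM)
    bvals: np.ndarray
    dce_times: np.ndarray
    masks: list[SegmentationRecord]
    truth: dict[str, Volume] = field(default_factory=dict)


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    studies: list[SyntheticStudy]
    manifest: pd.DataFrame  # seg_id, subject_id, label, n_voxels

    @property
    def segmentations(self) -> list[SegmentationRecord]:
        return [m for s in self.studies for m in s.masks]


# --------------------------------------------------------------------------
# forward signal models


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _rician(signal: np.ndarray, sd, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of the signal after complex Gaussian perturbation."""
    re = signal + rng.normal(0.0, 1.0, signal.shape) * sd
    im = rng.normal(0.0, 1.0, signal.shape) * sd
    return np.sqrt(re**2 + im**2)


def dki_signal(s0, d, k, bvals) -> np.ndarray:
    """Noiseless diffusion-kurtosis signal S(b) = S0 exp(-bD + b^2 D^2 K / 6).

    Broadcasts: parameters may be arrays of shape (...); returns (..., n_b).
    """
    b = np.asarray(bvals, dtype=float)
    s0, d, k = (np.asarray(v, dtype=float)[..., None] for v in (s0, d, k))
    return s0 * np.exp(-b * d + (b * d) ** 2 * k / 6.0)


def simulate_dwi_signal(
    params: TissueParams,
    bvals,
    noise_sd: float = 0.0,
    seed=None,
    averages=None,
) -> np.ndarray:
    """DWI signal vector over b-values; Rician noise if ``noise_sd > 0``.

    ``averages`` (per-b repeat counts) reduce the effective noise sd by
    sqrt(n), emulating on-scanner averaging.
    """
    b = np.asarray(bvals, dtype=float)
    if b.min() < 0:
        raise ValueError("b-values must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    clean = dki_signal(params.s0, params.d, params.k, b)
    if noise_sd == 0:
        return clean
    sd = np.full(b.shape, float(noise_sd))
    if averages is not None:
        sd = sd / np.sqrt(np.asarray(averages, dtype=float))
    return _rician(clean, sd, _as_rng(seed))


def population_aif(times, aif: AifParams) -> np.ndarray:
    """Plasma concentration curve Cp(t) (mM) of the bi-exponential AIF."""
    t = np.asarray(times, dtype=float)
    tau = t - aif.onset
    cp = aif.dose * (aif.a1 * np.exp(-aif.m1 * tau) + aif.a2 * np.exp(-aif.m2 * tau))
    return np.where(tau < 0, 0.0, cp)


def tofts_convolve(cp: np.ndarray, times, ktrans, kep) -> np.ndarray:
    """Tofts tissue curve: Ktrans * (Cp (*) exp(-kep t)) on the given grid.

    The convolution treats Cp as piecewise linear between samples and
    integrates each interval in closed form, so it is exact for constant and
    linear inputs and recursively stable:

        Ct(t_{i+1}) = Ct(t_i) e^{-kep dt}
                      + Ktrans * int_{t_i}^{t_{i+1}} Cp(tau) e^{-kep (t_{i+1}-tau)} dtau

    Broadcasts over voxel dimensions: ``ktrans``/``kep`` may be arrays of
    shape (...); ``cp`` of shape (n_t,) or (..., n_t); returns (..., n_t).
    """
    t = np.asarray(times, dtype=float)
    ktrans = np.asarray(ktrans, dtype=float)
    kep = np.asarray(kep, dtype=float)
    if np.any(kep <= 0):
        raise ValueError("kep must be > 0")
    cp = np.asarray(cp, dtype=float)
    shape = np.broadcast_shapes(ktrans.shape, kep.shape, cp.shape[:-1])
    ct = np.zeros(shape + (len(t),))
    cp = np.broadcast_to(cp, shape + (len(t),))
    acc = np.zeros(shape)
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        u = kep * dt
        e = np.exp(-u)
        # int of the linear segment against the exponential kernel:
        #   c0 * (-E/kep + (1-E)/(kep^2 dt)) + c1 * (1/kep - (1-E)/(kep^2 dt))
        with np.errstate(divide="ignore", invalid="ignore"):
            w = (1.0 - e) / (kep**2 * dt)
            f0 = -e / kep + w
            f1 = 1.0 / kep - w
        # series expansion where kep*dt underflows the closed form
        small = u < 1e-6
        if np.any(small):
            f0 = np.where(small, dt * (0.5 - u / 3.0), f0)
            f1 = np.where(small, dt * (0.5 - u / 6.0), f1)
        acc = acc * e + cp[..., i] * f0 + cp[..., i + 1] * f1
        ct[..., i + 1] = acc
    return ktrans[..., None] * ct


def simulate_dce_curve(
    params: TissueParams,
    aif: AifParams,
    times,
    noise_sd: float = 0.0,
    seed=None,
) -> np.ndarray:
    """Tissue concentration curve Ct(t) (mM), with additive Gaussian noise."""
    if params.kep <= 0:
        raise ValueError("kep must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    cp = population_aif(times, aif)
    ct = tofts_convolve(cp, times, params.ktrans, params.kep)
    if noise_sd > 0:
        ct = ct + _as_rng(seed).normal(0.0, noise_sd, ct.shape)
    return ct


# --------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class _Ellipsoid:
    center_mm: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]

    def rasterize(self, grid: VolumeGrid) -> np.ndarray:
        idx = np.indices(grid.shape, dtype=float)
        rel = [
            (idx[a] * grid.spacing[a] + grid.origin[a] - self.center_mm[a]) / self.semiaxes_mm[a]
            for a in range(3)
        ]
        return rel[0] ** 2 + rel[1] ** 2 + rel[2] ** 2 <= 1.0


def _place_vois(
    n: int, spec: CohortSpec, rng: np.random.Generator, max_tries: int = 500
) -> list[_Ellipsoid]:
    """Sample n non-overlapping ellipsoids inside the T2W grid interior."""
    lo, hi = spec.t2w_grid.extent()
    placed: list[_Ellipsoid] = []
    for _ in range(n):
        for attempt in range(max_tries):
            ax = rng.uniform(*spec.voi_axes_mm)
            ay = rng.uniform(*spec.voi_axes_mm)
            az = rng.uniform(*spec.voi_axes_z_mm)
            margin = np.array([ax, ay, az])
            if np.any(lo + margin >= hi - margin):
                continue
            c = rng.uniform(lo + margin, hi - margin)
            # conservative separation: centre distance > sum of max semi-axes
            ok = all(
                np.linalg.norm(c - np.asarray(e.center_mm))
                > max(e.semiaxes_mm) + max(ax, ay, az) + 1.0
                for e in placed
            )
            if ok:
                placed.append(_Ellipsoid(tuple(c), (ax, ay, az)))
                break
        else:
            raise RuntimeError(
                f"could not place {n} non-overlapping VOIs in the grid "
                f"(placed {len(placed)}); enlarge the grid or shrink voi_axes_mm"
            )
    return placed


def _lognormal_field(mean, cv: float, shape, rng: np.random.Generator) -> np.ndarray:
    """Positive heterogeneity field with mean ``mean`` and coefficient of
    variation ``cv`` (exact lognormal moments)."""
    if cv <= 0:
        return np.full(shape, float(mean))
    s2 = np.log1p(cv**2)
    return mean * np.exp(rng.normal(-0.5 * s2, np.sqrt(s2), shape))


def _t2w_texture(
    grid: VolumeGrid, mean: float, sd: float, smooth: float, rng: np.random.Generator
) -> np.ndarray:
    noise = rng.normal(0.0, 1.0, grid.shape)
    if smooth > 0:
        noise = gaussian_filter(noise, smooth)
        std = noise.std()
        if std > 0:
            noise = noise / std
    return mean + sd * noise


def _study_param_fields(
    spec: CohortSpec,
    vois: list[_Ellipsoid],
    labels: list[str],
    rng: np.random.Generator,
) -> dict[str, dict[str, np.ndarray]]:
    """Voxel-wise generative parameter fields on each acquisition grid.

    Background is healthy-like tissue; each VOI overwrites its ellipsoid with
    parameters drawn around its class means (between-VOI lognormal shift of
    the mean, then within-VOI voxel-wise lognormal jitter).
    """
    fields: dict[str, dict[str, np.ndarray]] = {}
    # between-VOI multiplicative shifts, one per VOI per parameter
    shifts = [
        {
            p: _lognormal_field(1.0, spec.voi_param_cv, (), rng)
            for p in ("s0", "d", "k", "ktrans", "kep")
        }
        for _ in vois
    ]
    for name, grid in (("dwi", spec.dwi_grid), ("dce", spec.dce_grid)):
        ht = spec.ht_params
        f = {
            p: _lognormal_field(getattr(ht, p), spec.voxel_param_cv, grid.shape, rng)
            for p in ("s0", "d", "k", "ktrans", "kep")
        }
        for voi, label, shift in zip(vois, labels, shifts):
            cls = spec.lesion_params if label == LESION else spec.ht_params
            m = voi.rasterize(grid)
            if not m.any():
                continue
            nm = int(m.sum())
            for p in ("s0", "d", "k", "ktrans", "kep"):
                f[p][m] = _lognormal_field(
                    getattr(cls, p) * shift[p], spec.voxel_param_cv, nm, rng
                )
        fields[name] = f
    return fields


def generate_study(
    spec: CohortSpec,
    subject_id: str,
    labels: list[str],
    rng: np.random.Generator,
) -> SyntheticStudy:
    """Simulate one subject carrying ``len(labels)`` VOIs."""
    vois = _place_vois(len(labels), spec, rng)
    fields = _study_param_fields(spec, vois, labels, rng)

    # --- T2W: composite of class textures on the anatomical grid
    ht, les = spec.ht_params, spec.lesion_params
    t2w = _t2w_texture(spec.t2w_grid, ht.t2w_mean, ht.t2w_sd, ht.t2w_smooth, rng)
    lesion_tex = _t2w_texture(spec.t2w_grid, les.t2w_mean, les.t2w_sd, les.t2w_smooth, rng)
    masks: list[SegmentationRecord] = []
    for i, (voi, label) in enumerate(zip(vois, labels)):
        m_t2w = voi.rasterize(spec.t2w_grid)
        if label == LESION:
            t2w[m_t2w] = lesion_tex[m_t2w]
        masks.append(
            SegmentationRecord(
                seg_id=f"{subject_id}_voi{i}",
                subject_id=subject_id,
                label=label,
                mask=Volume(m_t2w, spec.t2w_grid),
            )
        )

    # --- DWI stack with Rician noise (averaging folded into the noise sd)
    fd = fields["dwi"]
    clean_dwi = dki_signal(fd["s0"], fd["d"], fd["k"], spec.bvals)
    if spec.noise_sd_dwi > 0:
        sd = spec.noise_sd_dwi / np.sqrt(np.asarray(spec.bval_averages, dtype=float))
        dwi = _rician(clean_dwi, sd, rng)
    else:
        dwi = clean_dwi

    # --- DCE concentration stack with Gaussian noise
    fc = fields["dce"]
    times = np.asarray(spec.dce_times, dtype=float)
    cp = population_aif(times, spec.aif)
    ct = tofts_convolve(cp, times, fc["ktrans"], fc["kep"])
    if spec.noise_sd_dce > 0:
        ct = ct + rng.normal(0.0, spec.noise_sd_dce, ct.shape)

    truth = {
        "D": Volume(fd["d"].astype(np.float32), spec.dwi_grid),
        "K": Volume(fd["k"].astype(np.float32), spec.dwi_grid),
        "Ktrans": Volume(fc["ktrans"].astype(np.float32), spec.dce_grid),
        "Kep": Volume(fc["kep"].astype(np.float32), spec.dce_grid),
    }
    return SyntheticStudy(
        subject_id=subject_id,
        t2w=Volume(t2w.astype(np.float32), spec.t2w_grid),
        dwi=Volume(dwi.astype(np.float32), spec.dwi_grid),
        dce=Volume(ct.astype(np.float32), spec.dce_grid),
        bvals=np.asarray(spec.bvals, dtype=float),
        dce_times=times,
        masks=masks,
        truth=truth,
    )


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate the full synthetic cohort, reproducibly from ``spec.seed``.

    VOIs (n_lesion_vois lesion + n_ht_vois healthy) are dealt round-robin to
    ``n_subjects`` subjects after a seeded shuffle, so most subjects carry
    one or two regions, as in a retrospective lesion/reference-tissue
    segmentation campaign.
    """
    root = np.random.SeedSequence(spec.seed)
    label_rng = np.random.default_rng(root.spawn(1)[0])
    labels = [LESION] * spec.n_lesion_vois + [HEALTHY] * spec.n_ht_vois
    order = label_rng.permutation(len(labels))
    labels = [labels[i] for i in order]

    per_subject: list[list[str]] = [[] for _ in range(spec.n_subjects)]
    for i, lab in enumerate(labels):
        per_subject[i % spec.n_subjects].append(lab)

    subject_seeds = root.spawn(spec.n_subjects + 1)[1:]
    studies = []
    for s, (labs, ss) in enumerate(zip(per_subject, subject_seeds)):
        if not labs:
            continue
        studies.append(
            generate_study(spec, f"sub{s:03d}", labs, np.random.default_rng(ss))
        )

    rows = [
        {
            "seg_id": m.seg_id,
            "subject_id": m.subject_id,
            "label": m.label,
            "n_voxels": m.n_voxels,
        }
        for st in studies
        for m in st.masks
    ]
    manifest = pd.DataFrame(rows)
    n_les = int((manifest["label"] == LESION).sum())
    if n_les != spec.n_lesion_vois or len(manifest) != spec.n_lesion_vois + spec.n_ht_vois:
        raise RuntimeError("cohort generation lost segmentation records")  # defensive
    return SyntheticCohort(spec=spec, studies=studies, manifest=manifest)
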