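"""Synthetic lifespan cohort generator.

Emulates the statistical structure of a multimodal aging study: an adult
lifespan sample (ages 20-79) whose centrolateral caudate coupling to a
fronto-parietal-like (FPN) cortical signal weakens with age while coupling
to a default-mode-like (DMN) signal strengthens; blocked n-back task runs
with load-dependent coupling gain applied at a fixed hemodynamic delay;
reference-tissue PET time-activity curves with age-declining binding
potential; bounded-random-walk motion traces with injected spikes; and six
memory scores driven by a single latent factor linked to connectivity
differentiation.

Every generator takes an explicit integer seed and emits ground truth
(planted labels, coupling profiles, kinetic parameters, path coefficients)
alongside the data so that downstream modules can be tested against exact
oracles.  Latent network signals are built by frequency-domain filtering of
white noise to the analysis passband (0.009-0.09 Hz), so the analysis-side
bandpass is approximately idempotent on clean signal, and hemodynamic
coupling in task runs is a pure delay rather than a full HRF convolution so
that the analysis-side lag shift inverts it exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .bold import MOTION_COLUMNS, BoldRun, mask_to_indices
from . import pet_srtm

# ---------------------------------------------------------------------------
# study-level constants (the conditions the generator emulates)

AGE_RANGE = (20.0, 79.0)
AGE_GROUP_BOUNDS = {"young": (20, 39), "middle": (40, 59), "old": (60, 79)}
N_SUBJECTS_DEFAULT = 180
REST_VOLUMES = 350
TASK_VOLUMES = 330
TR_DEFAULT = 2.0
ANALYSIS_BAND = (0.009, 0.09)
MEMORY_TASK_MAXIMA = (32, 20, 24, 48, 108, 30)
MEMORY_TASK_NAMES = (
    "word_recall",
    "number_word_recall",
    "object_location_recall",
    "letter_updating",
    "number_updating",
    "spatial_updating",
)


def age_group(age: float) -> str:
    """Deterministic age-group assignment (young 20-39, middle 40-59, old 60-79)."""
    if age < 40:
        return "young"
    if age < 60:
        return "middle"
    return "old"


# ---------------------------------------------------------------------------
# mediation path specification


@dataclass(frozen=True)
class MediationPaths:
    """Standardized path coefficients of the planted mediation triangle.

    ``a``: effect of age on binding potential; ``b``: effect of binding
    potential on connectivity differentiation given age; ``c_prime``: direct
    effect of age.  The planted indirect effect is ``a * b``.
    """

    a: float
    b: float
    c_prime: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c_prime"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"mediation path {name} must be finite, got {v}")

    @property
    def indirect(self) -> float:
        return self.a * self.b

    @property
    def total(self) -> float:
        return self.a * self.b + self.c_prime


# Default planted paths.  Chosen so the indirect effect and the share of the
# age effect it carries are of realistic size for a lifespan D1-receptor
# cohort: caudate binding declines steeply with age and carries a little
# under half of the age effect on rest differentiation; the prefrontal route
# carries roughly a quarter of the (larger) direct age effect on task
# differentiation.
REST_PATHS = MediationPaths(a=-0.55, b=0.25, c_prime=-0.18)
TASK_PATHS = MediationPaths(a=-0.60, b=0.17, c_prime=-0.24)


# ---------------------------------------------------------------------------
# toy atlas


@dataclass
class ToyAtlas:
    """Integer-label cortical atlas plus striatal/CSF/WM masks on a toy grid."""

    atlas_img: nib.Nifti1Image
    striatal_img: nib.Nifti1Image
    csf_img: nib.Nifti1Image
    wm_img: nib.Nifti1Image
    n_networks: int
    seed_box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    label_names: dict[int, str]

    @property
    def affine(self) -> np.ndarray:
        return self.atlas_img.affine

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.atlas_img.shape

    @property
    def labels(self) -> np.ndarray:
        return np.asarray(self.atlas_img.dataobj).astype(int)

    @property
    def striatal_mask(self) -> np.ndarray:
        return np.asarray(self.striatal_img.dataobj).astype(bool)

    @property
    def cortical_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def csf_mask(self) -> np.ndarray:
        return np.asarray(self.csf_img.dataobj).astype(bool)

    @property
    def wm_mask(self) -> np.ndarray:
        return np.asarray(self.wm_img.dataobj).astype(bool)

    def seed_box_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        (x0, x1), (y0, y1), (z0, z1) = self.seed_box
        m[x0:x1, y0:y1, z0:z1] = True
        return m

    def save(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        paths = {}
        for name, img in [
            ("atlas", self.atlas_img),
            ("striatum", self.striatal_img),
            ("csf", self.csf_img),
            ("wm", self.wm_img),
        ]:
            p = outdir / f"{name}.nii"
            nib.save(img, str(p))
            paths[name] = p
        return paths


DEFAULT_LABEL_NAMES = {1: "FPN", 2: "DMN", 3: "LIM", 4: "VIS", 5: "SMN", 6: "DAN", 7: "VAN"}


def make_toy_atlas(
    grid_dims: tuple[int, int, int] = (18, 18, 18),
    n_networks: int = 7,
    striatal_box: tuple = ((7, 11), (3, 15), (7, 11)),
    voxel_size_mm: float = 3.0,
    cortical_slab: tuple[int, int] = (0, 2),
    min_voxels_per_network: int = 25,
) -> ToyAtlas:
    """Build a toy integer-label cortical atlas and a disjoint striatal mask.

    The cortex is a slab of ``cortical_slab`` z-planes partitioned into
    ``n_networks`` strips along x; the striatum is an interior box.  Each
    network must own at least ``min_voxels_per_network`` cortical voxels
    (the winner-take-all voting pool size).
    """
    nx, ny, nz = grid_dims
    labels = np.zeros(grid_dims, dtype=np.int16)
    z0, z1 = cortical_slab
    strip_edges = np.linspace(0, nx, n_networks + 1).round().astype(int)
    for k in range(n_networks):
        labels[strip_edges[k] : strip_edges[k + 1], :, z0:z1] = k + 1
    counts = np.bincount(labels.ravel(), minlength=n_networks + 1)[1:]
    bad = [k + 1 for k, c in enumerate(counts) if c < min_voxels_per_network]
    if bad:
        raise ValueError(
            f"networks {bad} have fewer than {min_voxels_per_network} cortical "
            f"voxels; enlarge the grid or the cortical slab"
        )

    striatum = np.zeros(grid_dims, dtype=np.int16)
    (sx0, sx1), (sy0, sy1), (sz0, sz1) = striatal_box
    striatum[sx0:sx1, sy0:sy1, sz0:sz1] = 1
    if np.any((striatum > 0) & (labels > 0)):
        raise ValueError("striatal box overlaps cortical labels; masks must be disjoint")

    # background boxes for nuisance-signal masks, disjoint from cortex/striatum
    csf = np.zeros(grid_dims, dtype=np.int16)
    csf[0:2, 0:2, max(z1, 4) : max(z1, 4) + 3] = 1
    wm = np.zeros(grid_dims, dtype=np.int16)
    wm[nx - 2 : nx, ny - 2 : ny, max(z1, 4) : max(z1, 4) + 3] = 1
    for m, name in [(csf, "csf"), (wm, "wm")]:
        if np.any((m > 0) & ((labels > 0) | (striatum > 0))):
            raise ValueError(f"{name} box overlaps cortex or striatum")

    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -voxel_size_mm * (np.asarray(grid_dims) / 2.0)

    # seed box: a small lateral (low-y) corner of the striatal box
    seed_box = ((sx0 + 1, sx0 + 3), (sy0, sy0 + 2), (sz0 + 1, sz0 + 3))

    names = {k + 1: DEFAULT_LABEL_NAMES.get(k + 1, f"NET{k + 1}") for k in range(n_networks)}
    return ToyAtlas(
        atlas_img=nib.Nifti1Image(labels, affine),
        striatal_img=nib.Nifti1Image(striatum, affine),
        csf_img=nib.Nifti1Image(csf, affine),
        wm_img=nib.Nifti1Image(wm, affine),
        n_networks=n_networks,
        seed_box=seed_box,
        label_names=names,
    )


# ---------------------------------------------------------------------------
# coupling profile


@dataclass
class CouplingProfile:
    """Per-striatal-voxel coupling of BOLD signal to each cortical network.

    ``base`` holds target correlations with each network's latent signal at
    ``ref_age``; ``age_slope`` (per year) shifts them linearly with age.
    Voxels inside the atlas seed box are instead driven by the subject-level
    planted differentiation (see :func:`subject_rho`), realising the exact
    FPN-minus-DMN Fisher-z difference stored in the subject table.
    """

    voxels: np.ndarray  # (N, 3) striatal voxel indices
    base: np.ndarray  # (N, K) correlations at ref_age
    age_slope: np.ndarray  # (N, K) per-year slopes
    seed_mask: np.ndarray  # (N,) True for seed-box voxels
    ref_age: float = 20.0
    base_z: float = 0.35  # mean seed-to-network Fisher z around which d splits
    noise_sd_cortical: float = 0.3
    noise_sd_striatal: float = 0.3
    offtask_gain: float = 0.5
    load_gains: tuple[float, float, float] = (1.0, 1.3, 1.6)
    hemodynamic_delay_s: float = 4.0
    motion_artifact_gain: float = 0.4
    spike_rate: float = 2.0  # expected injected motion spikes per run
    spike_size_mm: float = 0.6
    # amplitude of the volume-wide nuisance fluctuation (the component the
    # global-signal regressor exists to remove); it dominates the global
    # mean so that nuisance regression removes nuisance, not network signal
    global_nuisance_sd: float = 2.0

    @property
    def n_networks(self) -> int:
        return self.base.shape[1]

    def weights(self, age: float) -> np.ndarray:
        """Target correlations for gradient voxels at a given age."""
        w = self.base + self.age_slope * (age - self.ref_age)
        return np.clip(w, 0.0, 0.85)

    def noiseless(self) -> "CouplingProfile":
        """Copy with all noise sources and motion switched off."""
        return replace(
            self,
            noise_sd_cortical=0.0,
            noise_sd_striatal=0.0,
            motion_artifact_gain=0.0,
            spike_rate=0.0,
            global_nuisance_sd=0.0,
        )


def default_coupling_profile(
    atlas: ToyAtlas,
    fpn_slope_per_year: float = -0.0022,
    dmn_slope_per_year: float = 0.0022,
    **overrides,
) -> CouplingProfile:
    """Medial-lateral coupling gradient with age-dependent FPN/DMN balance.

    Lateral (low medial coordinate) voxels couple preferentially with the
    FPN, medial voxels with the DMN, and the most medial band with a stable
    limbic-like network.  The FPN/DMN boundary drifts medially->laterally
    with age at the configured slopes, so the FPN-allocated territory
    shrinks and the DMN territory grows across age groups.
    """
    voxels = mask_to_indices(atlas.striatal_mask)
    n = len(voxels)
    k = atlas.n_networks
    ys = voxels[:, 1]
    y0, y1 = ys.min(), ys.max() + 1
    p = (ys - y0 + 0.5) / (y1 - y0)  # medial position in (0, 1)

    base = np.full((n, k), 0.08)
    slope = np.zeros((n, k))
    limbic = p >= 0.75
    grad = ~limbic
    pg = p[grad] / 0.75
    # gradient voxels: FPN (label 1) vs DMN (label 2); the steep slope keeps
    # planted winner margins well away from the analysis decision noise for
    # voxels off the moving FPN/DMN boundary
    base[grad, 0] = 0.60 - 0.40 * pg
    base[grad, 1] = 0.20 + 0.40 * pg
    slope[grad, 0] = fpn_slope_per_year
    slope[grad, 1] = dmn_slope_per_year
    # limbic-like band (label 3 when present): strong, age-stable coupling
    lim_col = 2 if k >= 3 else 1
    base[limbic, lim_col] = 0.55
    base[limbic, 0] = 0.15
    if lim_col != 1:
        base[limbic, 1] = 0.20

    seed = np.zeros(n, dtype=bool)
    (x0, x1), (sy0_, sy1_), (z0, z1) = atlas.seed_box
    inside = (
        (voxels[:, 0] >= x0)
        & (voxels[:, 0] < x1)
        & (voxels[:, 1] >= sy0_)
        & (voxels[:, 1] < sy1_)
        & (voxels[:, 2] >= z0)
        & (voxels[:, 2] < z1)
    )
    seed[inside] = True
    return CouplingProfile(voxels=voxels, base=base, age_slope=slope, seed_mask=seed, **overrides)


def subject_rho(
    profile: CouplingProfile, age: float, diff_rest: float
) -> np.ndarray:
    """Per-striatal-voxel target correlations for one subject.

    Gradient voxels follow the age-shifted profile weights; seed-box voxels
    realise Fisher-z correlations ``base_z +/- diff/2`` with the FPN and DMN
    latents so that the measured differentiation equals the planted value.
    """
    rho = profile.weights(age)
    if profile.seed_mask.any():
        r_f = np.tanh(profile.base_z + diff_rest / 2.0)
        r_d = np.tanh(profile.base_z - diff_rest / 2.0)
        rho[profile.seed_mask, :] = 0.08
        rho[profile.seed_mask, 0] = r_f
        rho[profile.seed_mask, 1] = r_d
    return rho


def planted_labels(
    profile: CouplingProfile, ages: np.ndarray, diffs: np.ndarray
) -> np.ndarray:
    """Ground-truth winner-take-all labels for a group of subjects.

    The truth for a group map is the argmax network of the group-mean
    coupling profile (coupling is linear in age, so this equals the profile
    at the mean age for gradient voxels, while seed voxels use the mean of
    the tanh-transformed planted differentiations).
    """
    rho = np.mean(
        [subject_rho(profile, a, d) for a, d in zip(ages, diffs)], axis=0
    )
    return np.argmax(rho, axis=1) + 1  # network labels are 1-based


# ---------------------------------------------------------------------------
# subject table


def generate_subject_table(
    n: int = N_SUBJECTS_DEFAULT,
    seed: int | None = None,
    mediation_rest: MediationPaths = REST_PATHS,
    mediation_task: MediationPaths = TASK_PATHS,
    diff_rest_mean: float = 0.10,
    diff_rest_sd: float = 0.18,
    diff_task_mean: float = 0.14,
    diff_task_sd: float = 0.18,
    bp_caudate_mean: float = 2.0,
    bp_caudate_sd: float = 0.45,
    bp_pfc_mean: float = 0.45,
    bp_pfc_sd: float = 0.12,
) -> pd.DataFrame:
    """Generate the per-subject covariate table with planted mediation paths.

    Ages are approximately uniform on 20-79 (stratified jittered grid).
    Standardized binding potential is ``a * age_z + noise`` and the latent
    differentiation is ``b * bp_z + c' * age_z + noise``, so the planted
    indirect effect of age on differentiation through binding is ``a * b``.
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    if n < 4:
        raise ValueError(f"n must be >= 4, got {n}")
    rng = np.random.default_rng(seed)

    lo, hi = AGE_RANGE
    ages = lo + (hi - lo) * (np.arange(n) + rng.uniform(0, 1, n)) / n
    rng.shuffle(ages)
    age_z = (ages - ages.mean()) / ages.std(ddof=1)

    def bp_block(paths: MediationPaths, d_mean, d_sd, bp_mean, bp_sd):
        a, b, cp = paths.a, paths.b, paths.c_prime
        bp_z = a * age_z + np.sqrt(max(1.0 - a**2, 1e-6)) * rng.standard_normal(n)
        resid_var = 1.0 - (b**2 + cp**2 + 2.0 * a * b * cp)
        d_z = b * bp_z + cp * age_z + np.sqrt(max(resid_var, 1e-6)) * rng.standard_normal(n)
        bp = np.clip(bp_mean + bp_sd * bp_z, 0.0, None)
        diff = d_mean + d_sd * d_z
        return bp_z, bp, d_z, diff

    bp_cau_z, bp_cau, d_rest_z, diff_rest = bp_block(
        mediation_rest, diff_rest_mean, diff_rest_sd, bp_caudate_mean, bp_caudate_sd
    )
    bp_pfc_z, bp_pfc, d_task_z, diff_task = bp_block(
        mediation_task, diff_task_mean, diff_task_sd, bp_pfc_mean, bp_pfc_sd
    )

    mean_fd = np.exp(rng.normal(np.log(0.11) + 0.0045 * (ages - 50.0), 0.40))
    sex = rng.integers(0, 2, n)
    acc = {
        f"nback_acc_{l}": np.clip(
            0.97 - 0.0025 * (ages - 20.0) - 0.04 * (l - 1) + rng.normal(0, 0.04, n),
            0.2,
            1.0,
        )
        for l in (1, 2, 3)
    }

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:03d}" for i in range(n)],
            "age": ages,
            "age_group": [age_group(a) for a in ages],
            "sex": sex,
            "mean_fd": mean_fd,
            "bp_caudate": bp_cau,
            "bp_pfc": bp_pfc,
            "bp_caudate_z": bp_cau_z,
            "bp_pfc_z": bp_pfc_z,
            "d_rest_z": d_rest_z,
            "d_task_z": d_task_z,
            "diff_rest_true": diff_rest,
            "diff_task_true": diff_task,
            **acc,
        }
    )
    df.attrs["mediation_rest"] = mediation_rest
    df.attrs["mediation_task"] = mediation_task
    df.attrs["diff_rest_scale"] = (diff_rest_mean, diff_rest_sd)
    df.attrs["seed"] = seed
    return df


# ---------------------------------------------------------------------------
# band-limited latent signals


def bandlimited_signals(
    n_volumes: int,
    n_signals: int,
    tr: float,
    rng: np.random.Generator,
    band: tuple[float, float] = ANALYSIS_BAND,
) -> np.ndarray:
    """Orthonormal zero-mean unit-variance signals band-limited to ``band``.

    White noise is filtered in the frequency domain (hard mask on rFFT bins
    inside the passband), then the columns are orthonormalized by QR so that
    sample correlations between latents are exactly zero.
    Returns an array of shape (n_volumes, n_signals).
    """
    freqs = np.fft.rfftfreq(n_volumes, d=tr)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if mask.sum() < n_signals:
        raise ValueError("run too short: fewer passband bins than requested signals")
    spec = rng.standard_normal((mask.sum(), n_signals)) + 1j * rng.standard_normal(
        (mask.sum(), n_signals)
    )
    full = np.zeros((len(freqs), n_signals), dtype=complex)
    full[mask] = spec
    x = np.fft.irfft(full, n=n_volumes, axis=0)
    q, r = np.linalg.qr(x)
    q *= np.sign(np.diag(r))  # fix QR sign convention for determinism
    return q * np.sqrt(n_volumes)


# ---------------------------------------------------------------------------
# motion traces


def generate_motion(
    n_volumes: int,
    target_mean_fd: float,
    rng: np.random.Generator,
    spike_rate: float = 2.0,
    spike_size_mm: float = 0.6,
    head_radius_mm: float = 50.0,
) -> tuple[pd.DataFrame, list[int]]:
    """Bounded random-walk rigid-body trace scaled to a target mean FD,
    with instantaneous translation spikes injected at recorded volumes."""
    params = np.zeros((n_volumes, 6))
    spikes: list[int] = []
    if target_mean_fd > 0:
        steps = rng.normal(0, 1.0, (n_volumes - 1, 6))
        steps[:, 3:] /= head_radius_mm  # rotations contribute arc length r*theta
        walk = np.vstack([np.zeros(6), np.cumsum(steps, axis=0)])
        d = np.abs(np.diff(walk, axis=0))
        fd = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
        walk *= target_mean_fd * n_volumes / fd.sum()
        params = walk
        # smooth saturation keeps the walk bounded without pinning
        # parameters at a constant (a hard clip makes the squared motion
        # regressors exactly collinear with the linear ones)
        params[:, :3] = 4.0 * np.tanh(params[:, :3] / 4.0)
        params[:, 3:] = 0.08 * np.tanh(params[:, 3:] / 0.08)
    if spike_rate > 0:
        n_spikes = int(rng.poisson(spike_rate))
        if n_spikes > 0:
            vols = rng.choice(np.arange(5, n_volumes), size=min(n_spikes, 5), replace=False)
            for v in sorted(vols):
                params[v:, 0] += spike_size_mm * rng.choice([-1.0, 1.0])
                spikes.append(int(v))
    return pd.DataFrame(params, columns=MOTION_COLUMNS), spikes


def _power_fd(params: np.ndarray, head_radius_mm: float = 50.0) -> np.ndarray:
    d = np.abs(np.diff(params, axis=0))
    fd = np.concatenate([[0.0], d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)])
    return fd


# ---------------------------------------------------------------------------
# BOLD runs


def _compose_run(
    profile: CouplingProfile,
    atlas: ToyAtlas,
    rho_t: np.ndarray,  # (N, K) static or (T, N, K) time-varying correlations
    n_volumes: int,
    tr: float,
    rng: np.random.Generator,
    motion: pd.DataFrame,
) -> np.ndarray:
    labels3d = atlas.labels
    k = atlas.n_networks
    latents = bandlimited_signals(n_volumes, k + 1, tr, rng)
    nets, eta = latents[:, :k], latents[:, k]

    data = np.zeros((*atlas.shape, n_volumes), dtype=np.float64)

    background = ~(atlas.cortical_mask | atlas.striatal_mask)
    data[background] = rng.standard_normal((int(background.sum()), n_volumes))

    cort_idx = mask_to_indices(atlas.cortical_mask)
    cort_lab = labels3d[cort_idx[:, 0], cort_idx[:, 1], cort_idx[:, 2]]
    cort = nets[:, cort_lab - 1].T.copy()
    if profile.noise_sd_cortical > 0:
        cort += profile.noise_sd_cortical * rng.standard_normal(cort.shape)
    data[cort_idx[:, 0], cort_idx[:, 1], cort_idx[:, 2]] = cort

    vox = profile.voxels
    n_stri = len(vox)
    # unique residuals: shared band-limited eta for seed-box voxels (keeps
    # the seed ROI mean exactly on the planted correlations), and per-voxel
    # white noise orthogonalized against the latents for all other voxels
    # (keeps per-voxel correlations exact in the noiseless limit without a
    # common component across the striatum)
    uniq = rng.standard_normal((n_stri, n_volumes))
    basis = latents / n_volumes  # latents columns orthonormal up to sqrt(T)
    uniq -= (uniq @ latents) @ basis.T
    uniq -= uniq.mean(axis=1, keepdims=True)  # latents are zero-mean, so this
    uniq /= uniq.std(axis=1)[:, None]         # preserves orthogonality

    uniq[profile.seed_mask] = eta[None, :]
    if rho_t.ndim == 2:
        stri = rho_t @ nets.T  # (N, T)
        e = np.sqrt(np.clip(1.0 - (rho_t**2).sum(axis=1), 0.0, None))
        stri += e[:, None] * uniq
    else:
        # time-varying coupling: rho_t is (T, N, K)
        stri = np.einsum("tnk,tk->nt", rho_t, nets)
        e = np.sqrt(np.clip(1.0 - (rho_t**2).sum(axis=2), 0.0, None))  # (T, N)
        stri += e.T * uniq
    if profile.noise_sd_striatal > 0:
        stri = stri + profile.noise_sd_striatal * rng.standard_normal(stri.shape)
    data[vox[:, 0], vox[:, 1], vox[:, 2]] = stri

    if profile.global_nuisance_sd > 0:
        data += profile.global_nuisance_sd * rng.standard_normal(n_volumes)[None, None, None, :]
    if profile.motion_artifact_gain > 0:
        art = profile.motion_artifact_gain * _power_fd(motion[MOTION_COLUMNS].to_numpy())
        brain = atlas.cortical_mask | atlas.striatal_mask
        data[brain] += art[None, :]
    return data


def generate_rest_bold(
    subject: pd.Series,
    atlas: ToyAtlas,
    profile: CouplingProfile,
    n_volumes: int = REST_VOLUMES,
    tr: float = TR_DEFAULT,
    seed: int | None = None,
) -> tuple[BoldRun, pd.DataFrame, dict]:
    """Resting-state run for one subject row of the subject table.

    Cortical voxels carry their own network's band-limited latent plus white
    noise; striatal voxels carry an age-adjusted correlation-weighted mix of
    network latents; seed-box voxels realise the subject's planted
    differentiation exactly in the noiseless limit.
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    if tr <= 0:
        raise ValueError("tr must be positive")
    if n_volumes < 10:
        raise ValueError("n_volumes must be >= 10")
    rng = np.random.default_rng(seed)
    motion, spikes = generate_motion(
        n_volumes,
        float(subject["mean_fd"]) if profile.motion_artifact_gain > 0 or profile.spike_rate > 0 else 0.0,
        rng,
        spike_rate=profile.spike_rate,
        spike_size_mm=profile.spike_size_mm,
    )
    rho = subject_rho(profile, float(subject["age"]), float(subject["diff_rest_true"]))
    data = _compose_run(profile, atlas, rho, n_volumes, tr, rng, motion)
    truth = {
        "rho": rho,
        "labels": np.argmax(rho, axis=1) + 1,
        "spike_volumes": spikes,
        "diff_rest_true": float(subject["diff_rest_true"]),
    }
    return BoldRun(data, atlas.affine, tr), motion, truth


# ---------------------------------------------------------------------------
# task design and task runs


@dataclass
class TaskDesign:
    """Blocked n-back design: cued blocks of 10 stimuli per load."""

    n_blocks_per_load: int = 9
    stimuli_per_block: int = 10
    stimulus_duration: float = 1.5
    isi: float = 0.5
    cue_duration: float = 2.0
    tr: float = TR_DEFAULT
    lead_in_volumes: int = 6
    interblock_rest_volumes: int = 1
    load_order: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.load_order is None:
            # randomized once, then fixed across participants
            order = np.repeat([1, 2, 3], self.n_blocks_per_load)
            np.random.default_rng(20240101).shuffle(order)
            self.load_order = tuple(int(v) for v in order)
        if len(self.load_order) != 3 * self.n_blocks_per_load:
            raise ValueError("load_order length must be 3 * n_blocks_per_load")

    @property
    def block_task_volumes(self) -> int:
        secs = self.stimuli_per_block * (self.stimulus_duration + self.isi)
        vols = secs / self.tr
        if abs(vols - round(vols)) > 1e-9:
            raise ValueError("block duration must be an integer number of volumes")
        return int(round(vols))

    @property
    def cue_volumes(self) -> int:
        return max(1, int(round(self.cue_duration / self.tr)))

    @property
    def n_volumes(self) -> int:
        per_block = self.cue_volumes + self.block_task_volumes + self.interblock_rest_volumes
        return self.lead_in_volumes + per_block * len(self.load_order)

    def labels(self) -> np.ndarray:
        out = ["rest"] * self.lead_in_volumes
        for load in self.load_order:
            out += ["cue"] * self.cue_volumes
            out += [f"{load}-back"] * self.block_task_volumes
            out += ["rest"] * self.interblock_rest_volumes
        return np.asarray(out)


def generate_task_bold(
    subject: pd.Series,
    atlas: ToyAtlas,
    profile: CouplingProfile,
    design: TaskDesign | None = None,
    seed: int | None = None,
) -> tuple[BoldRun, pd.DataFrame, pd.DataFrame, dict]:
    """Blocked n-back run with load-dependent coupling gain at a pure delay.

    The striatal-FPN coupling is multiplied by the load gain during each
    block, with the effective gain shifted later in time by the profile's
    hemodynamic delay, so the analysis-side lag correction realigns it
    exactly.  Returns (bold, labels table, motion, truth).
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    design = design or TaskDesign()
    rng = np.random.default_rng(seed)
    n_volumes = design.n_volumes
    labels = design.labels()

    gains = np.full(n_volumes, profile.offtask_gain)
    for load in (1, 2, 3):
        gains[labels == f"{load}-back"] = profile.load_gains[load - 1]
    shift = int(round(profile.hemodynamic_delay_s / design.tr))
    g_eff = np.concatenate([np.full(shift, profile.offtask_gain), gains])[:n_volumes]

    motion, spikes = generate_motion(
        n_volumes,
        float(subject["mean_fd"]) if profile.motion_artifact_gain > 0 or profile.spike_rate > 0 else 0.0,
        rng,
        spike_rate=profile.spike_rate,
        spike_size_mm=profile.spike_size_mm,
    )

    rho0 = subject_rho(profile, float(subject["age"]), float(subject["diff_task_true"]))
    rho_t = np.repeat(rho0[None, :, :], n_volumes, axis=0)
    # load gain modulates FPN coupling of every striatal voxel
    rho_t[:, :, 0] = np.clip(rho_t[:, :, 0] * g_eff[:, None], 0.0, 0.95)
    data = _compose_run(profile, atlas, rho_t, n_volumes, design.tr, rng, motion)

    labels_df = pd.DataFrame({"volume": np.arange(n_volumes), "condition": labels})
    truth = {
        "rho": rho0,
        "g_eff": g_eff,
        "spike_volumes": spikes,
        "diff_task_true": float(subject["diff_task_true"]),
        "delay_volumes": shift,
    }
    run = BoldRun(data, atlas.affine, design.tr, labels=labels_df["condition"])
    return run, labels_df, motion, truth


# ---------------------------------------------------------------------------
# PET TACs


@dataclass(frozen=True)
class GammaVariate:
    """Smooth gamma-variate reference-region input, C_R(t) = A t^alpha e^(-t/beta)
    with t in minutes.  Defaults give a curve peaking near 10 min at ~30
    activity units with a slow washout tail."""

    amplitude: float = 6.6
    alpha: float = 1.2
    beta: float = 8.0

    def __call__(self, t_min: np.ndarray) -> np.ndarray:
        t = np.clip(np.asarray(t_min, dtype=float), 0.0, None)
        return self.amplitude * t**self.alpha * np.exp(-t / self.beta)


def generate_tac(
    params: dict,
    schedule: "pet_srtm.FrameSchedule | None" = None,
    ref_shape: GammaVariate = GammaVariate(),
    noise_scale: float = 0.0,
    seed: int | None = None,
    dt_s: float = 0.5,
) -> "pet_srtm.TacPair":
    """Reference + target TAC pair from the reference-tissue forward model.

    ``params`` must provide R1, k2 (1/min) and BP_ND.  Frame noise has
    standard deviation ``noise_scale * sqrt(activity / frame_duration_min)``,
    applied to the target curve only (the reference is treated as the
    estimator's known input).
    """
    r1, k2, bp = float(params["R1"]), float(params["k2"]), float(params["BP_ND"])
    if r1 <= 0 or k2 <= 0:
        raise ValueError("R1 and k2 must be positive")
    if bp < 0:
        raise ValueError("BP_ND must be non-negative")
    schedule = schedule or pet_srtm.FrameSchedule.default_pet()
    t_min = np.arange(0.0, schedule.end_s / 60.0 + 1e-9, dt_s / 60.0)
    ref = ref_shape(t_min)
    target = pet_srtm.srtm_forward(r1, k2, bp, ref, t_min)
    ref_f = pet_srtm.frame_average(ref, t_min, schedule)
    tgt_f = pet_srtm.frame_average(target, t_min, schedule)
    if noise_scale > 0:
        if seed is None:
            raise ValueError("an explicit integer seed is required for noisy TACs")
        rng = np.random.default_rng(seed)
        dur_min = schedule.frame_duration / 60.0
        sd = noise_scale * np.sqrt(np.clip(tgt_f, 1e-6, None) / dur_min)
        tgt_f = tgt_f + rng.normal(0.0, sd)
    return pet_srtm.TacPair(
        schedule=schedule,
        reference=ref_f,
        target=tgt_f,
        truth={"R1": r1, "k2": k2, "BP_ND": bp},
    )


# ---------------------------------------------------------------------------
# memory battery


def generate_behavior(
    subjects: pd.DataFrame,
    loadings: tuple[float, ...] = (0.7,) * 6,
    task_maxima: tuple[int, ...] = MEMORY_TASK_MAXIMA,
    link: float = 0.25,
    link_x_age: float = 0.15,
    beta_age: float = -0.45,
    noise: float | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Append six bounded integer memory scores driven by one latent factor.

    The latent declines with age and carries the planted connectivity link
    (plus an age interaction, so the connectivity-memory association
    strengthens with age).  Each score is
    ``clamp(round(offset + loading * latent + noise), 0, maximum)``.
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    if len(loadings) != len(task_maxima):
        raise ValueError(
            f"{len(loadings)} loadings for {len(task_maxima)} tasks"
        )
    rng = np.random.default_rng(seed)
    n = len(subjects)
    age_z = (subjects["age"] - subjects["age"].mean()) / subjects["age"].std(ddof=1)
    d_z = subjects["d_rest_z"].to_numpy()
    sys_var = beta_age**2 + link**2 + link_x_age**2
    resid = np.sqrt(max(1.0 - sys_var, 0.05))
    latent = (
        beta_age * age_z.to_numpy()
        + link * d_z
        + link_x_age * d_z * age_z.to_numpy()
        + resid * rng.standard_normal(n)
    )
    out = subjects.copy()
    out["memory_latent_true"] = latent
    for j, (lam, mx) in enumerate(zip(loadings, task_maxima), start=1):
        if noise is None:
            eps_sd = np.sqrt(max(1.0 - lam**2, 0.0))
        else:
            eps_sd = noise
        z = lam * latent + eps_sd * rng.standard_normal(n)
        raw = np.round(0.55 * mx + 0.16 * mx * z)
        out[f"memory_task_{j}"] = np.clip(raw, 0, mx).astype(int)
    return out


# ---------------------------------------------------------------------------
# toy ROI table


def toy_roi_table(atlas: ToyAtlas) -> list[dict]:
    """ROI specifications (seed + 3 FPN + 3 DMN targets) on the toy grid.

    Target spheres are intersected with their network's cortical voxels so
    each target carries a single network's signal; the seed sphere is
    intersected with the striatal seed box.
    """
    aff = atlas.affine

    def vox_to_mm(i, j, k):
        return (aff @ np.array([i, j, k, 1.0]))[:3]

    labels = atlas.labels
    rois = []
    (x0, x1), (y0, y1), (z0, z1) = atlas.seed_box
    c = vox_to_mm((x0 + x1 - 1) / 2.0, (y0 + y1 - 1) / 2.0, (z0 + z1 - 1) / 2.0)
    rois.append(
        {"name": "caudate_seed", "network": "seed", "center_mm": list(c),
         "radius_mm": 3.5, "bilateral": False, "restrict": "striatum_seed_box"}
    )
    for net_label, net_name in [(1, "FPN"), (2, "DMN")]:
        vox = np.argwhere(labels == net_label)
        # three well-separated target centres along the strip
        picks = np.linspace(0, len(vox) - 1, 5).round().astype(int)[1:4]
        for t, p in enumerate(picks, start=1):
            c = vox_to_mm(*vox[p])
            rois.append(
                {"name": f"{net_name.lower()}_target_{t}", "network": net_name,
                 "center_mm": list(c), "radius_mm": 3.0, "bilateral": False,
                 "restrict": f"label_{net_label}"}
            )
    return rois
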