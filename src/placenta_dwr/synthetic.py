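"""Synthetic placental data: noise, phantoms and cohorts.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage can be exercised without scan data:

* voxel-wise two-compartment T2*-IVIM signal on the multi-echo multi-b
  protocol, with Rician (magnitude) noise;
* a control population whose T2* declines linearly with gestational age
  while ADC, perfusion fraction and FA stay flat;
* case groups (delivering before 32 weeks) with T2* reduced relative to
  controls — both compartments for PPROM, predominantly the slow
  compartment for intact membranes — plus an extra reduction of slow-
  compartment T2* and perfusion fraction as delivery approaches;
* a cohort of 23 cases (14 PPROM / 9 intact) versus 52 term controls
  with an MRI-to-delivery latency of mean 8 days, SD 8.7 days.

All ground-truth parameter levels live in :class:`GeneratorConfig` — they
are generator configuration consistent with placental literature, not
measured claims.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .models import IvimParams
from .protocol import AcquisitionScheme

__all__ = [
    "GeneratorConfig",
    "PlacentaPhantom",
    "SubjectRecord",
    "add_noise",
    "make_phantom",
    "make_cohort",
    "synthesise_volume",
    "latency_distribution_params",
    "sample_latencies",
]

GROUPS = ("control", "pprom", "intact")


@dataclass(frozen=True)
class GeneratorConfig:
    """Every tunable level of the synthetic generator, in one block.

    Tissue parameters are population means for a mid-gestation control
    placenta; the GA model is linear in gestational weeks with a floor.
    Group effects are multiplicative factors applied to case placentas.
    """

    # signal / tissue levels
    s0: float = 100.0                  # a.u., signal at TE_min, b = 0
    f_mean: float = 0.25               # perfusion fraction
    d_star: float = 0.05               # mm^2/s, pseudo-diffusion
    adc_mean: float = 2.0e-3           # mm^2/s, tissue diffusion
    fa_mean: float = 0.12              # dimensionless, GA-constant

    # gestational-age model for the slow-compartment T2* in controls
    t2_slow_at_20wk: float = 70.0      # ms at 20 weeks
    t2_slow_slope: float = -2.5        # ms per gestational week
    t2_slow_floor: float = 25.0        # ms, physiological floor
    t2_fast_offset: float = 40.0       # ms, t2_fast = t2_slow + offset

    # group effects (multiplicative on compartment T2*)
    pprom_t2_factor_fast: float = 0.75
    pprom_t2_factor_slow: float = 0.75
    intact_t2_factor_fast: float = 0.97
    intact_t2_factor_slow: float = 0.85

    # latency effect: reductions grow as delivery nears
    latency_t2_slow_max_reduction: float = 0.15
    latency_f_max_reduction: float = 0.30
    latency_scale_days: float = 8.0

    # variability and noise
    spatial_cv: float = 0.10           # voxel-wise low-frequency modulation
    subject_cv: float = 0.08           # between-subject multiplicative SD
    snr: float = 30.0                  # s0 / sigma for Rician noise

    # cohort structure
    n_cases: int = 23
    n_pprom: int = 14
    n_controls: int = 52
    latency_mean_days: float = 8.0
    latency_sd_days: float = 8.7

    def without_effects(self) -> "GeneratorConfig":
        """Null configuration: no GA trend, no group or latency effects.

        Used for type-I-error calibration of the cohort statistics.
        """
        return dataclasses.replace(
            self,
            t2_slow_slope=0.0,
            pprom_t2_factor_fast=1.0,
            pprom_t2_factor_slow=1.0,
            intact_t2_factor_fast=1.0,
            intact_t2_factor_slow=1.0,
            latency_t2_slow_max_reduction=0.0,
            latency_f_max_reduction=0.0,
        )


def latency_distribution_params(cfg: GeneratorConfig) -> tuple[float, float]:
    """Shape and scale of the gamma latency distribution.

    The MRI-to-delivery interval is modelled as gamma with the cohort's
    mean and SD as its realised moments (a lower-truncated normal cannot
    realise SD > mean on positive support, so gamma is used).
    """
    k = (cfg.latency_mean_days / cfg.latency_sd_days) ** 2
    theta = cfg.latency_sd_days**2 / cfg.latency_mean_days
    return k, theta


def sample_latencies(
    n: int,
    cfg: GeneratorConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw MRI-to-delivery intervals (days) from the latency distribution."""
    cfg = cfg or GeneratorConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k, theta = latency_distribution_params(cfg)
    return rng.gamma(k, theta, size=n)


# ---------------------------------------------------------------------------
# noise


def add_noise(
    signal: np.ndarray,
    sigma: float,
    model: Literal["rician", "gaussian"] = "rician",
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Add measurement noise to a noiseless signal.

    ``rician`` forms the magnitude of a complex signal with i.i.d.
    Gaussian noise of SD sigma on each channel: sqrt((S+n1)^2 + n2^2);
    ``gaussian`` adds n1 only.  sigma = 0 returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=signal.shape)
    if model == "gaussian":
        return signal + n1
    if model == "rician":
        n2 = rng.normal(0.0, sigma, size=signal.shape)
        return np.sqrt((signal + n1) ** 2 + n2**2)
    raise ValueError(f"unknown noise model {model!r}; expected 'rician' or 'gaussian'")


# ---------------------------------------------------------------------------
# ground-truth parameter models


def _control_t2_slow(ga_weeks: float, cfg: GeneratorConfig) -> float:
    t2 = cfg.t2_slow_at_20wk + cfg.t2_slow_slope * (ga_weeks - 20.0)
    return max(t2, cfg.t2_slow_floor)


def _latency_proximity(latency_days: float | None, cfg: GeneratorConfig) -> float:
    """0 far from delivery, -> 1 as the scan approaches delivery."""
    if latency_days is None or cfg.latency_scale_days <= 0:
        return 0.0
    return float(np.exp(-latency_days / cfg.latency_scale_days))


def _mean_proximity(cfg: GeneratorConfig) -> float:
    """E[exp(-L/tau)] under the gamma latency distribution (its MGF)."""
    if cfg.latency_scale_days <= 0:
        return 0.0
    k, theta = latency_distribution_params(cfg)
    return float((1.0 + theta / cfg.latency_scale_days) ** (-k))


def population_means(
    ga_weeks: float,
    group: str,
    cfg: GeneratorConfig,
    latency_days: float | None = None,
) -> dict[str, float]:
    """Population-mean tissue parameters for a given GA and group.

    Returns the IVIM ground truth plus the derived mono-exponential T2*
    (signal-fraction-weighted compartment mix) and a GA-constant FA.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    if not 20.0 <= ga_weeks <= 41.0:
        raise ValueError(f"ga_weeks must lie in [20, 41], got {ga_weeks}")
    t2s = _control_t2_slow(ga_weeks, cfg)
    t2f = t2s + cfg.t2_fast_offset
    f = cfg.f_mean
    if group == "pprom":
        t2f *= cfg.pprom_t2_factor_fast
        t2s *= cfg.pprom_t2_factor_slow
    elif group == "intact":
        t2f *= cfg.intact_t2_factor_fast
        t2s *= cfg.intact_t2_factor_slow
    if group != "control" and latency_days is not None:
        prox = _latency_proximity(latency_days, cfg)
        t2s *= 1.0 - cfg.latency_t2_slow_max_reduction * prox
        # the f trajectory is centred on the case mean proximity, so the
        # scan-to-delivery gradient exists within cases without shifting
        # the case-vs-control mean (the group f contrast stays null while
        # the latency split sees the reduction near delivery)
        f *= 1.0 - cfg.latency_f_max_reduction * (prox - _mean_proximity(cfg))
    t2_mono = f * t2f + (1.0 - f) * t2s
    return {
        "s0": cfg.s0,
        "f": f,
        "t2_star_fast": t2f,
        "t2_star_slow": t2s,
        "d_star": cfg.d_star,
        "adc": cfg.adc_mean,
        "t2_star": t2_mono,
        "fa": cfg.fa_mean,
    }


_SUBJECT_VARIED = ("f", "t2_star_fast", "t2_star_slow", "adc", "fa")


def subject_means(
    ga_weeks: float,
    group: str,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    latency_days: float | None = None,
) -> dict[str, float]:
    """Population means perturbed by a per-subject multiplicative effect."""
    means = population_means(ga_weeks, group, cfg, latency_days)
    for key in _SUBJECT_VARIED:
        scale = rng.lognormal(mean=0.0, sigma=cfg.subject_cv)
        means[key] *= scale
    means["f"] = float(np.clip(means["f"], 0.0, 1.0))
    means["t2_star"] = means["f"] * means["t2_star_fast"] + (1.0 - means["f"]) * means["t2_star_slow"]
    return means


# ---------------------------------------------------------------------------
# phantom


@dataclass
class PlacentaPhantom:
    """3D ground-truth parameter maps plus an ellipsoidal parenchyma mask.

    ``param_maps`` holds one 3D float array per IVIM parameter
    (s0, f, t2_star_fast, t2_star_slow, d_star, adc), defined wherever the
    mask is true (NaN outside).  ``true_means`` are the masked means of
    the generating maps.
    """

    shape: tuple[int, int, int]
    mask: np.ndarray
    param_maps: dict[str, np.ndarray]
    voxel_size: float = 3.0  # mm, isotropic
    true_means: dict[str, float] = field(default_factory=dict)

    def voxel_params(self) -> list[IvimParams]:
        """IVIM parameters of each masked voxel, in flat mask order."""
        idx = np.where(self.mask)
        out = []
        for i in range(len(idx[0])):
            vox = tuple(ax[i] for ax in idx)
            out.append(
                IvimParams(
                    s0=float(self.param_maps["s0"][vox]),
                    f=float(self.param_maps["f"][vox]),
                    t2_star_fast=float(self.param_maps["t2_star_fast"][vox]),
                    t2_star_slow=float(self.param_maps["t2_star_slow"][vox]),
                    d_star=float(self.param_maps["d_star"][vox]),
                    adc=float(self.param_maps["adc"][vox]),
                )
            )
        return out


def _ellipsoid_mask(shape: Sequence[int]) -> np.ndarray:
    """Ellipsoid inscribed in the grid with semi-axes 0.42 * extent."""
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    r2 = sum(
        ((g - (s - 1) / 2.0) / (0.42 * s)) ** 2 for g, s in zip(grids, shape)
    )
    return r2 <= 1.0


def _smooth_field(shape: Sequence[int], rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-SD low-frequency random field."""
    raw = rng.standard_normal(shape)
    smooth = gaussian_filter(raw, sigma=[max(s / 8.0, 1.0) for s in shape])
    sd = smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return (smooth - smooth.mean()) / sd


def make_phantom(
    ga_weeks: float,
    group: str = "control",
    shape: tuple[int, int, int] = (32, 32, 32),
    seed: int | None = 0,
    cfg: GeneratorConfig | None = None,
    latency_days: float | None = None,
    means: dict[str, float] | None = None,
    voxel_size: float = 3.0,
) -> PlacentaPhantom:
    """Build a ground-truth placental phantom.

    Voxel-wise IVIM parameters are the group/GA population means (or the
    supplied ``means``) modulated by smooth low-frequency fields of
    fractional SD ``cfg.spatial_cv``, inside an ellipsoidal parenchyma
    mask.  Deterministic for fixed arguments and seed.
    """
    cfg = cfg or GeneratorConfig()
    if means is None:
        means = population_means(ga_weeks, group, cfg, latency_days)
    rng = np.random.default_rng(seed)
    mask = _ellipsoid_mask(shape)
    maps: dict[str, np.ndarray] = {}
    modulated = {
        "f": (0.01, 0.99),
        "t2_star_fast": (5.0, None),
        "t2_star_slow": (5.0, None),
        "adc": (1e-5, None),
    }
    for key in ("s0", "f", "t2_star_fast", "t2_star_slow", "d_star", "adc"):
        level = np.full(shape, float(means[key]))
        if key in modulated and cfg.spatial_cv > 0:
            lo, hi = modulated[key]
            level = level * (1.0 + cfg.spatial_cv * _smooth_field(shape, rng))
            level = np.clip(level, lo, hi)
        level[~mask] = np.nan
        maps[key] = level
    true_means = {k: float(np.nanmean(v)) for k, v in maps.items()}
    true_means["t2_star"] = float(
        np.nanmean(
            maps["f"] * maps["t2_star_fast"] + (1.0 - maps["f"]) * maps["t2_star_slow"]
        )
    )
    return PlacentaPhantom(
        shape=tuple(shape), mask=mask, param_maps=maps,
        voxel_size=voxel_size, true_means=true_means,
    )


def synthesise_volume(
    phantom: PlacentaPhantom,
    scheme: AcquisitionScheme,
    snr: float | None = 30.0,
    noise_model: Literal["rician", "gaussian"] = "rician",
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate the 4D signal of a phantom on a scheme.

    Returns an array of shape ``phantom.shape + (len(scheme),)``; voxels
    outside the mask are zero.  ``snr`` is s0 / sigma; ``None`` or 0
    yields noiseless data.
    """
    te = scheme.echo_times
    b = scheme.b_values
    te_min = scheme.te_min
    m = phantom.mask
    p = phantom.param_maps
    # vectorised two-compartment forward model over masked voxels
    s0 = p["s0"][m][:, None]
    f = p["f"][m][:, None]
    fast = f * np.exp(-(te - te_min)[None, :] / p["t2_star_fast"][m][:, None]) * np.exp(
        -b[None, :] * p["d_star"][m][:, None]
    )
    slow = (1.0 - f) * np.exp(-(te - te_min)[None, :] / p["t2_star_slow"][m][:, None]) * np.exp(
        -b[None, :] * p["adc"][m][:, None]
    )
    sig = s0 * (fast + slow)
    if snr:
        sigma = float(np.nanmean(p["s0"][m])) / snr
        sig = add_noise(sig, sigma, model=noise_model, seed=seed)
    out = np.zeros(phantom.shape + (len(scheme),), dtype=float)
    out[m] = sig
    return out


# ---------------------------------------------------------------------------
# cohort


@dataclass
class SubjectRecord:
    """One pregnancy in the synthetic cohort.

    Gestational ages in weeks; cases (pprom/intact) deliver before 32
    weeks, controls at or after 37.  ``roi_means`` is filled either by
    the generator (ground-truth subject means) or by the imaging
    pipeline's ROI summaries.
    """

    subject_id: str
    group: str
    ga_mri: float
    ga_delivery: float
    ga_onset: float | None = None
    latency_days: float | None = None
    roi_means: dict[str, float] = field(default_factory=dict)

    @property
    def is_case(self) -> bool:
        return self.group in ("pprom", "intact")

    def validate(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.is_case:
            if self.ga_delivery >= 32:
                raise ValueError("cases must deliver before 32 weeks")
            if self.ga_onset is not None and not (
                self.ga_onset <= self.ga_mri <= self.ga_delivery
            ):
                raise ValueError("require ga_onset <= ga_mri <= ga_delivery")
        elif self.ga_delivery < 37:
            raise ValueError("controls must deliver at term (>= 37 weeks)")


def make_cohort(
    n_cases: int | None = None,
    n_pprom: int | None = None,
    n_controls: int | None = None,
    cfg: GeneratorConfig | None = None,
    seed: int | None = 0,
    attach_roi_means: bool = True,
) -> list[SubjectRecord]:
    """Simulate a case-control cohort.

    Cases deliver uniformly in [26, 31.9) weeks; the MRI precedes
    delivery by a gamma-distributed latency (mean 8 d, SD 8.7 d), and
    symptom onset precedes the MRI by 0.5-4 weeks.  Controls deliver in
    [37, 42) and are scanned in [20, 37).  Draws violating the minimum
    scan gestation of 20 weeks are resampled (retries counted in the
    module logger).  When ``attach_roi_means`` is true, each record
    carries its subject-level ground-truth parameter means.
    """
    cfg = cfg or GeneratorConfig()
    n_cases = cfg.n_cases if n_cases is None else n_cases
    n_pprom = cfg.n_pprom if n_pprom is None else n_pprom
    n_controls = cfg.n_controls if n_controls is None else n_controls
    if n_pprom > n_cases:
        raise ValueError("n_pprom cannot exceed n_cases")
    rng = np.random.default_rng(seed)
    k, theta = latency_distribution_params(cfg)
    records: list[SubjectRecord] = []
    retries = 0
    for i in range(n_cases):
        group = "pprom" if i < n_pprom else "intact"
        while True:
            ga_delivery = rng.uniform(26.0, 31.9)
            latency = rng.gamma(k, theta)
            ga_mri = ga_delivery - latency / 7.0
            onset_gap = rng.uniform(0.5, 4.0)
            ga_onset = ga_mri - onset_gap
            if ga_mri >= 20.0 and latency > 0:
                break
            retries += 1
        rec = SubjectRecord(
            subject_id=f"case{i:03d}", group=group, ga_mri=ga_mri,
            ga_delivery=ga_delivery, ga_onset=ga_onset, latency_days=latency,
        )
        if attach_roi_means:
            rec.roi_means = subject_means(ga_mri, group, cfg, rng, latency)
        rec.validate()
        records.append(rec)
    for i in range(n_controls):
        ga_mri = rng.uniform(20.0, 37.0)
        ga_delivery = rng.uniform(37.0, 42.0)
        rec = SubjectRecord(
            subject_id=f"ctrl{i:03d}", group="control", ga_mri=ga_mri,
            ga_delivery=ga_delivery,
        )
        if attach_roi_means:
            rec.roi_means = subject_means(ga_mri, "control", cfg, rng)
        rec.validate()
        records.append(rec)
    if retries:
        import logging

        logging.getLogger(__name__).info(
            "cohort generation resampled %d infeasible case draw(s)", retries
        )
    return records
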