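"""End-to-end synthetic study: simulate -> fit -> ROI -> cohort statistics.

``run_end_to_end`` composes the whole analysis the way it would run on a
real cohort: a subject table and per-subject 4D volumes are simulated,
each volume is fitted voxel-wise with the T2*-ADC, T2*-IVIM and tensor
models, parameter maps are thresholded and reduced to ROI means, and the
cohort comparisons are computed.  Everything is driven by one config and
one seed; per-subject seeds are derived with ``numpy.random.SeedSequence``
so results are reproducible and independent of execution order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_stats
from .fitting import FitConfig, fit_volume
from .io import write_cohort_table, write_manifest, write_nifti_map
from .protocol import AcquisitionScheme, build_protocol_scheme, write_scheme
from .roi import DEFAULT_T2_THRESHOLD_MS, roi_summary
from .synthetic import GeneratorConfig, SubjectRecord, make_cohort, make_phantom, synthesise_volume

__all__ = ["PipelineConfig", "PipelineResult", "run_subject", "run_end_to_end"]

#: parameters contrasted between cases and controls, by source model
CONTRAST_PARAMS = ("t2_star", "adc", "fa", "t2_star_fast", "t2_star_slow", "f", "d_star", "adc_slow")
TREND_PARAMS = ("t2_star", "adc", "fa", "t2_star_fast", "t2_star_slow", "f", "adc_slow")
SPLIT_PARAMS = ("t2_star", "t2_star_slow", "t2_star_fast", "f", "adc", "adc_slow", "fa")


@dataclass(frozen=True)
class PipelineConfig:
    """One document of defaults reproducing the study's settings.

    Cohort sizes 23 cases (14 PPROM) / 52 controls, the full multi-echo
    multi-b scheme, Rician noise at SNR 30, segmented IVIM fitting, the
    200 ms T2* exclusion and alpha = 0.05.
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    noise_model: str = "rician"
    fit_strategy: str = "segmented"
    phantom_shape: tuple[int, int, int] = (16, 16, 12)
    voxel_size: float = 3.0
    threshold_ms: float = DEFAULT_T2_THRESHOLD_MS
    alpha: float = 0.05
    seed: int = 0
    save_volumes: bool = False

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a config document, rejecting unknown or ill-typed keys.

        The document mirrors the dataclass: top-level pipeline fields
        plus an optional ``generator`` mapping for GeneratorConfig.
        """
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"{path}: config must be a mapping")
        gen_doc = doc.pop("generator", {}) or {}
        gen_fields = {f.name for f in dataclasses.fields(GeneratorConfig)}
        unknown = set(gen_doc) - gen_fields
        if unknown:
            raise ValueError(f"{path}: unknown generator key(s) {sorted(unknown)}")
        cfg_fields = {f.name for f in dataclasses.fields(cls)} - {"generator"}
        unknown = set(doc) - cfg_fields
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        if "phantom_shape" in doc:
            doc["phantom_shape"] = tuple(doc["phantom_shape"])
        return cls(generator=GeneratorConfig(**gen_doc), **doc)


@dataclass
class PipelineResult:
    """Cohort table, tidy statistics and bookkeeping of one full run."""

    cohort: pd.DataFrame
    reports: pd.DataFrame
    records: list[SubjectRecord]
    fit_summaries: list[dict]
    config: PipelineConfig


def run_subject(
    record: SubjectRecord,
    scheme: AcquisitionScheme,
    config: PipelineConfig,
    seed: int,
    out_dir=None,
) -> tuple[dict[str, float], list[dict]]:
    """Simulate and analyse one subject; returns (roi_means, fit summaries).

    The subject's phantom is built around the record's ground-truth means
    (so between-subject variability enters once), imaged on the scheme,
    fitted with all three models, thresholded and reduced to ROI means.
    """
    rng = np.random.default_rng(seed)
    phantom = make_phantom(
        ga_weeks=record.ga_mri,
        group=record.group,
        shape=config.phantom_shape,
        seed=int(rng.integers(2**31)),
        cfg=config.generator,
        latency_days=record.latency_days,
        means=record.roi_means or None,
        voxel_size=config.voxel_size,
    )
    data = synthesise_volume(
        phantom, scheme, snr=config.generator.snr,
        noise_model=config.noise_model, seed=int(rng.integers(2**31)),
    )
    # the simulator's noise level is known, so the fits use the exact
    # Rician expectation rather than the raw magnitude
    sigma = None
    if config.noise_model == "rician" and config.generator.snr:
        sigma = config.generator.s0 / config.generator.snr
    fit_cfg = FitConfig(strategy=config.fit_strategy, seed=int(rng.integers(2**31)),
                        sigma=sigma)
    affine = np.diag([config.voxel_size] * 3 + [1.0])
    if out_dir is not None and config.save_volumes:
        write_nifti_map(data, affine, Path(out_dir) / f"{record.subject_id}_dwi.nii.gz")
        write_nifti_map(phantom.mask.astype(float), affine,
                        Path(out_dir) / f"{record.subject_id}_mask.nii.gz")
    means: dict[str, float] = {}
    summaries = []
    # the IVIM slow-compartment diffusivity gets its own column so it never
    # shadows the mono-exponential ADC
    rename = {"t2ivim": {"adc": "adc_slow"}}
    for model in ("t2adc", "t2ivim", "fa"):
        fitted = fit_volume(data, phantom.mask, scheme, model, fit_cfg)
        summ = roi_summary(fitted, threshold_ms=config.threshold_ms)
        summaries.append({**fitted.summary, "subject_id": record.subject_id,
                          "n_retained": summ.n_voxels_retained})
        if out_dir is not None and config.save_volumes:
            for name, arr in fitted.maps.items():
                write_nifti_map(arr, affine,
                                Path(out_dir) / f"{record.subject_id}_{model}_{name}.nii.gz")
        for name, value in summ.means.items():
            if name == "s0":
                continue
            means[rename.get(model, {}).get(name, name)] = value
    return means, summaries


def _cohort_statistics(df: pd.DataFrame, records: list[SubjectRecord]) -> pd.DataFrame:
    """All trend, contrast and latency-split comparisons in one tidy frame."""
    rows = []
    for param in TREND_PARAMS:
        if param not in df.columns:
            continue
        rep = cohort_stats.ga_trend(df, param)
        rows.append({**rep.to_row(), "analysis": "ga_trend", "subgroup": "control"})
    for subgroup in ("all_cases", "pprom", "intact"):
        for param in CONTRAST_PARAMS:
            if param not in df.columns:
                continue
            rep = cohort_stats.group_contrast(df, param, subgroup=subgroup)
            rows.append({**rep.to_row(), "analysis": "group_contrast", "subgroup": subgroup})
    cases = [r for r in records if r.is_case and r.ga_onset is not None
             and r.roi_means and all(np.isfinite(v) for v in r.roi_means.values())]
    if len(cases) >= 4:
        scores = cohort_stats.standardise_and_split(cases)
        for param in SPLIT_PARAMS:
            if param not in df.columns:
                continue
            rep = cohort_stats.split_contrast(cases, param, scores)
            rows.append({**rep.to_row(), "analysis": "latency_split", "subgroup": "cases"})
    return pd.DataFrame(rows)


def run_end_to_end(config: PipelineConfig | None = None, out_dir=None) -> PipelineResult:
    """Run the full synthetic study described by ``config``.

    When ``out_dir`` is given, writes the scheme sidecars, the cohort
    TSV, the statistics TSV and a JSON manifest (plus per-subject NIfTI
    volumes when ``config.save_volumes``).  Deterministic for a fixed
    config.
    """
    config = config or PipelineConfig()
    gen = config.generator
    if gen.n_controls == 0:
        raise ValueError("cohort stage: control group is empty")
    if gen.n_cases == 0:
        raise ValueError("cohort stage: case group is empty")
    scheme = build_protocol_scheme()
    root = np.random.SeedSequence(config.seed)
    cohort_seed, *subject_seeds = root.spawn(1 + gen.n_cases + gen.n_controls)
    records = make_cohort(cfg=gen, seed=cohort_seed, attach_roi_means=True)

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        write_scheme(scheme, out / "scheme.bval", out / "scheme.bvec", out / "scheme.te")

    fit_summaries: list[dict] = []
    for record, sseq in zip(records, subject_seeds):
        truth = dict(record.roi_means)
        try:
            means, summaries = run_subject(
                record, scheme, config,
                seed=int(sseq.generate_state(1)[0] % 2**31), out_dir=out,
            )
        except Exception as exc:  # noqa: BLE001 - halt with context per contract
            raise RuntimeError(
                f"pipeline stage 'fit' failed for subject {record.subject_id}: {exc}"
            ) from exc
        record.roi_means = means
        fit_summaries.append({"subject_id": record.subject_id, "truth": truth})
        fit_summaries.extend(summaries)

    df = cohort_stats.cohort_frame(records)
    reports = _cohort_statistics(df, records)

    if out is not None:
        write_cohort_table(records, out / "cohort.tsv")
        reports.to_csv(out / "statistics.tsv", sep="\t", index=False, float_format="%.8g")
        write_manifest(
            out / "manifest.json",
            seed=config.seed,
            config=dataclasses.asdict(config),
            config_hash=config.config_hash(),
            n_subjects=len(records),
        )
    return PipelineResult(cohort=df, reports=reports, records=records,
                          fit_summaries=fit_summaries, config=config)
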