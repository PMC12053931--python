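"""Ten-stage DDA-PASEF processing pipeline.

Stages: (1) raw read-in, (2) refragmentation merging + top-N preprocessing,
(3) search-space generation (digest, fixed/variable mods, decoys),
(4) scorer configuration, (5) first PSM generation, (6) mass + collision-
energy calibration, (7) RT/ion-mobility predictor fine-tuning on confident
PSMs, (8) second search on corrected spectra, (9) feature assembly + LDA
rescoring, (10) target-decoy competition, filtering, and reports.

The first-pass search runs at twice the configured fragment tolerance so
the global median ppm estimate is not censored by the match window; the
second search on corrected spectra uses the configured tolerance.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io as mgf_io
from .calibration import (
    FineTuneConfig,
    IntensityPredictor,
    IonMobilityPredictor,
    MassCalibration,
    RetentionTimePredictor,
    apply_mass_calibration,
    calibrate_collision_energy,
    estimate_mass_calibration,
    fine_tune_predictor,
)
from .chemistry import (
    DigestConfig,
    read_fasta,
)
from .constants import (
    MOD_ACETYL,
    MOD_CARBAMIDOMETHYL,
    MOD_CYSTEINYLATION,
    MOD_OXIDATION,
)
from .fdr_tdc import (
    filter_and_report,
    tdc_double,
    tdc_psm,
)
from .rescoring import (
    PredictorBundle,
    RescoreConfig,
    feature_matrix,
    rescore,
)
from .search import (
    ProcessedSpectrum,
    Psm,
    ScorerConfig,
    merge_refragmented,
    search_chunked,
    top_n_filter,
)

logger = logging.getLogger(__name__)

CE_GRID = tuple(float(x) for x in range(-10, 11))


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    fasta_path: str | None = None
    mgf_path: str | None = None
    out_dir: str | None = None
    preset: str = "tryptic"
    digest: DigestConfig = field(default_factory=DigestConfig)
    scorer: ScorerConfig = field(default_factory=ScorerConfig)
    fixed_mods: dict = field(default_factory=lambda: {"C": MOD_CARBAMIDOMETHYL})
    variable_mods: tuple = (("N-term", MOD_ACETYL), ("M", MOD_OXIDATION))
    max_variable_mods: int = 3
    finetune: FineTuneConfig = field(default_factory=FineTuneConfig)
    rescore: RescoreConfig = field(default_factory=RescoreConfig)
    alpha: float = 0.01
    n_chunks: int = 1
    seed: int = 0
    merge_grid_resolution: int = 2
    first_pass_tol_factor: float = 2.0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def preset_config(name: str, **overrides) -> PipelineConfig:
    """The two fully specified presets: `tryptic` and `hla`."""
    if name == "tryptic":
        cfg = PipelineConfig(
            preset="tryptic",
            digest=DigestConfig("tryptic", missed_cleavages=2, min_len=7, max_len=30),
            scorer=ScorerConfig(precursor_tol_ppm=15.0),
            fixed_mods={"C": MOD_CARBAMIDOMETHYL},
            variable_mods=(("N-term", MOD_ACETYL), ("M", MOD_OXIDATION)),
            n_chunks=1,
        )
    elif name == "hla":
        cfg = PipelineConfig(
            preset="hla",
            digest=DigestConfig("unspecific", missed_cleavages=0, min_len=7, max_len=25),
            scorer=ScorerConfig(precursor_tol_ppm=20.0),
            fixed_mods={},
            variable_mods=(
                ("M", MOD_OXIDATION),
                ("N-term", MOD_ACETYL),
                ("C", MOD_CYSTEINYLATION),
            ),
            n_chunks=6,
        )
    else:
        raise ValueError(f"unknown preset {name!r}")
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


@dataclass
class PipelineResult:
    psms: list[Psm]
    q_psm: np.ndarray
    q_peptide: np.ndarray
    mass_cal_first: MassCalibration | None
    mass_cal_second: MassCalibration | None
    ce_offset: float
    first_pass_psms: list[Psm]
    report: dict
    stage_log: list[dict]
    predictors: PredictorBundle
    rescore_result: object = None  # RescoreResult with leave-one-out map


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _stage(stage_log: list[dict], name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                logger.error("stage %s: failed after %.2fs: %s", name, dt, exc)
                if not isinstance(exc, PipelineError):
                    raise PipelineError(name, str(exc)) from exc
                return False
            stage_log.append({"stage": name, "seconds": round(dt, 3)})
            logger.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Timer()


def preprocess_spectra(
    raw: Sequence[ProcessedSpectrum], top_n: int, grid_resolution: int = 2
) -> list[ProcessedSpectrum]:
    """Merge refragmented precursors, then keep the top-N peaks."""
    groups = mgf_io.group_by_precursor(raw)
    return [
        top_n_filter(merge_refragmented(groups[pid], grid_resolution), top_n)
        for pid in sorted(groups)
    ]


def run_pipeline(
    cfg: PipelineConfig,
    spectra: Sequence[ProcessedSpectrum] | None = None,
    records: Sequence[tuple[str, str]] | None = None,
) -> PipelineResult:
    """Execute all ten stages; inputs may be paths (in cfg) or in-memory."""
    stage_log: list[dict] = []

    with _stage(stage_log, "1-read-in"):
        if spectra is None:
            if cfg.mgf_path is None:
                raise ValueError("no spectra: provide mgf_path or in-memory spectra")
            spectra = mgf_io.read_mgf(cfg.mgf_path)
        if records is None:
            if cfg.fasta_path is None:
                raise ValueError("no database: provide fasta_path or records")
            records = read_fasta(cfg.fasta_path)
        spectra = list(spectra)
        records = list(records)
    stage_log[-1].update(n_spectra=len(spectra), n_proteins=len(records))

    with _stage(stage_log, "2-preprocess"):
        processed = preprocess_spectra(
            spectra, cfg.scorer.top_n_peaks, cfg.merge_grid_resolution
        )
    stage_log[-1]["n_merged_spectra"] = len(processed)

    # stages 3+4 (search space, scorer config) happen inside search_chunked,
    # per chunk; stage 5 is the wide first-pass search used for calibration
    search_kwargs = dict(
        cfg=cfg.scorer,
        digest_cfg=cfg.digest,
        fixed_mods=cfg.fixed_mods,
        variable_mods=cfg.variable_mods,
        max_mods=cfg.max_variable_mods,
        n_chunks=cfg.n_chunks,
        seed=cfg.seed,
    )
    with _stage(stage_log, "5-first-search"):
        first_psms = search_chunked(
            records,
            processed,
            fragment_tol_ppm=cfg.scorer.fragment_tol_ppm * cfg.first_pass_tol_factor,
            **search_kwargs,
        )
    stage_log[-1]["n_psms"] = len(first_psms)

    with _stage(stage_log, "6-calibration"):
        q_first = tdc_psm(first_psms, score=lambda p: p.hyperscore).q_of_psm
        confident = [
            p
            for p, q in zip(first_psms, q_first)
            if q <= cfg.finetune.q_threshold and not p.is_decoy
        ]
        mass_cal_first = (
            estimate_mass_calibration(confident) if confident else None
        )
        corrected = (
            apply_mass_calibration(processed, mass_cal_first)
            if mass_cal_first is not None
            else processed
        )
        intensity_predictor = IntensityPredictor()
        ce_offset = (
            calibrate_collision_energy(
                [p for p in first_psms if not p.is_decoy],
                intensity_predictor,
                CE_GRID,
            )
            if first_psms
            else 0.0
        )
    stage_log[-1]["median_ppm"] = (
        mass_cal_first.median_ppm if mass_cal_first else None
    )
    stage_log[-1]["ce_offset"] = ce_offset

    with _stage(stage_log, "7-fine-tuning"):
        rt_model = fine_tune_predictor(
            RetentionTimePredictor(), confident, cfg.finetune, seed=cfg.seed
        )
        im_model = fine_tune_predictor(
            IonMobilityPredictor(), confident, cfg.finetune, seed=cfg.seed
        )
        predictors = PredictorBundle(
            rt=rt_model, im=im_model, intensity=intensity_predictor,
            ce_offset=ce_offset,
        )

    with _stage(stage_log, "8-second-search"):
        psms = search_chunked(records, corrected, **search_kwargs)
    stage_log[-1]["n_psms"] = len(psms)
    mass_cal_second = None
    second_confident = [
        p
        for p, q in zip(psms, tdc_psm(psms, score=lambda p: p.hyperscore).q_of_psm)
        if q <= cfg.finetune.q_threshold and not p.is_decoy
    ]
    if second_confident:
        mass_cal_second = estimate_mass_calibration(second_confident)

    with _stage(stage_log, "9-rescoring"):
        features_df = feature_matrix(psms, predictors)
        feature_values = features_df.iloc[:, 4:].to_numpy()
        try:
            rescore_result = rescore(
                psms, features=feature_values, cfg=cfg.rescore
            )
        except ValueError as exc:
            # small runs may lack confident targets (the +1 pseudocount puts
            # a floor of 1/T on q-values); fall back to the search score
            logger.warning("rescoring skipped, keeping hyperscore: %s", exc)
            for p in psms:
                p.re_score = p.hyperscore
            rescore_result = None
    stage_log[-1]["n_rescored"] = len(psms)

    with _stage(stage_log, "10-tdc-report"):
        q_psm_table = tdc_psm(psms)
        q_pep_table = tdc_double(psms)
        report = filter_and_report(
            psms, q_psm_table, q_pep_table, alpha=cfg.alpha, out_dir=cfg.out_dir
        )
        if cfg.out_dir is not None:
            out = Path(cfg.out_dir)
            features_df.to_csv(out / "features.tsv", sep="\t", index=False)
            with open(out / "config_resolved.json", "w") as fh:
                json.dump(_config_json(cfg), fh, indent=2, sort_keys=True)
            with open(out / "run_log.txt", "w") as fh:
                for entry in stage_log:
                    fh.write(json.dumps(entry, sort_keys=True) + "\n")
    stage_log[-1]["n_accepted_psms"] = report["n_psms_accepted"]
    stage_log[-1]["n_accepted_peptides"] = report["n_peptides_accepted"]

    return PipelineResult(
        psms=psms,
        q_psm=q_psm_table.q_of_psm,
        q_peptide=q_pep_table.q_of_psm,
        mass_cal_first=mass_cal_first,
        mass_cal_second=mass_cal_second,
        ce_offset=ce_offset,
        first_pass_psms=first_psms,
        report=report,
        stage_log=stage_log,
        predictors=predictors,
        rescore_result=rescore_result,
    )


def _config_json(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["scorer"] = asdict(cfg.scorer)
    d["digest"] = asdict(cfg.digest)
    return d
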