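"""21-descriptor feature space and cross-validated LDA rescoring.

Each PSM is described by exactly 21 scalar features covering the search-engine
statistics (hyperscore, matched-ion counts, ppm errors), retention-time and
ion-mobility prediction deltas, and observed-vs-predicted fragment-intensity
similarity. PSMs are split into five nonoverlapping peptide-level batches;
each batch is scored by a linear discriminant trained on the other four
(all decoys, plus targets at initial q <= 0.01), so no PSM is ever scored by
a model that saw its peptide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import (
    IntensityPredictor,
    IonMobilityPredictor,
    RetentionTimePredictor,
    cosine_similarity,
    psm_spectral_angle,
    spectral_angle,
)
from .fdr_tdc import tdc_psm
from .search import Psm

FEATURE_NAMES = [
    "hyperscore",
    "rank",
    "delta_next",
    "ln_matched_intensity",
    "matched_intensity_fraction",
    "matched_b",
    "matched_y",
    "longest_b_series",
    "longest_y_series",
    "avg_ppm_error",
    "abs_avg_ppm_error",
    "precursor_ppm_error",
    "isotope_error",
    "charge",
    "peptide_length",
    "missed_cleavages",
    "delta_rt",
    "abs_delta_rt",
    "delta_im",
    "spectral_angle",
    "cosine_similarity",
]


@dataclass
class PredictorBundle:
    rt: RetentionTimePredictor | None = None
    im: IonMobilityPredictor | None = None
    intensity: IntensityPredictor | None = None
    ce_offset: float = 0.0


@dataclass(frozen=True)
class RescoreConfig:
    n_batches: int = 5
    q_train_threshold: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_batches < 2:
            raise ValueError("n_batches must be >= 2")


def assemble_features(psm: Psm, predictors: PredictorBundle | None = None) -> np.ndarray:
    """The 21 scalar descriptors of one PSM.

    Predictor-derived features are NaN when no predictor is available; the
    rescorer imputes them as 0 after z-scoring on the training fold. The
    definitions are identical for targets and decoys.
    """
    predictors = predictors or PredictorBundle()
    if predictors.rt is not None:
        psm.rt_predicted = float(predictors.rt.predict([psm.peptide])[0])
        delta_rt = psm.retention_time - psm.rt_predicted
    else:
        delta_rt = math.nan
    if predictors.im is not None:
        psm.im_predicted = float(
            predictors.im.predict([psm.peptide], [psm.charge])[0]
        )
        delta_im = psm.inv_ion_mobility - psm.im_predicted
    else:
        delta_im = math.nan
    if predictors.intensity is not None and psm.matched_ions:
        sa = psm_spectral_angle(psm, predictors.intensity, predictors.ce_offset)
        ions = [(s, o, z) for s, o, z, _ in psm.matched_ions]
        observed = np.array([i for _, _, _, i in psm.matched_ions])
        predicted = predictors.intensity.predict_ions(
            ions, psm.collision_energy + predictors.ce_offset
        )
        cos = cosine_similarity(observed, predicted)
    else:
        sa, cos = math.nan, math.nan
    psm.spectral_angle = sa
    psm.cosine_similarity = cos
    vec = np.array(
        [
            psm.hyperscore,
            psm.rank,
            psm.delta_next,
            math.log1p(max(psm.matched_intensity, 0.0)),
            psm.matched_intensity_fraction,
            psm.matched_b,
            psm.matched_y,
            psm.longest_b,
            psm.longest_y,
            psm.avg_ppm_error,
            abs(psm.avg_ppm_error),
            psm.precursor_ppm_error,
            psm.isotope_error,
            psm.charge,
            len(psm.peptide),
            psm.peptide.missed_cleavages(),
            delta_rt,
            abs(delta_rt) if not math.isnan(delta_rt) else math.nan,
            delta_im,
            sa,
            cos,
        ],
        dtype=float,
    )
    assert vec.size == len(FEATURE_NAMES)
    return vec


def feature_matrix(
    psms: list[Psm], predictors: PredictorBundle | None = None
) -> pd.DataFrame:
    """One row per PSM: ids + label + the 21 named features (TSV-exportable)."""
    rows = [assemble_features(p, predictors) for p in psms]
    df = pd.DataFrame(rows, columns=FEATURE_NAMES)
    df.insert(0, "spectrum_id", [p.spectrum_id for p in psms])
    df.insert(1, "peptide", [p.peptide.sequence for p in psms])
    df.insert(2, "peptide_key", [p.peptide_key for p in psms])
    df.insert(3, "is_decoy", [p.is_decoy for p in psms])
    return df


def _zscore_impute(X: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    Z = (X - mean) / std
    return np.where(np.isfinite(Z), Z, 0.0)


@dataclass
class RescoreResult:
    scores: np.ndarray
    batch_of_psm: np.ndarray
    # batch -> set of peptide keys the batch's model was trained on
    training_peptides: dict[int, set]


def rescore(
    psms: list[Psm],
    features: np.ndarray | None = None,
    cfg: RescoreConfig = RescoreConfig(),
    predictors: PredictorBundle | None = None,
) -> RescoreResult:
    """Assign every PSM a new score from a cross-validated LDA.

    Peptides are split into ``cfg.n_batches`` nonoverlapping seeded batches.
    Each batch is scored by an LDA (lsqr solver, automatic shrinkage of the
    within-class covariance) trained on the other batches using all decoy
    hits but only target hits with an initial hyperscore q-value at or below
    ``cfg.q_train_threshold``. Scores are signed distances from the decision
    boundary, oriented so targets score high. Features are z-scored on the
    training fold; non-finite entries impute to 0 after scaling. Results are
    written back to ``psm.re_score`` and also returned with leave-one-out
    bookkeeping.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    if features is None:
        features = np.vstack([assemble_features(p, predictors) for p in psms])
    features = np.asarray(features, dtype=float)
    if features.shape[0] != len(psms):
        raise ValueError("feature matrix and PSM list length mismatch")

    # Initial confidence from hyperscore-based PSM-level competition.
    q_initial = tdc_psm(psms, score=lambda p: p.hyperscore).q_of_psm
    is_decoy = np.array([p.is_decoy for p in psms])
    confident_target = np.array(
        [
            (not p.is_decoy) and q_initial[i] <= cfg.q_train_threshold
            for i, p in enumerate(psms)
        ]
    )

    keys = [p.peptide_key for p in psms]
    unique_keys = sorted(set(keys))
    rng = np.random.default_rng(cfg.seed)
    rng.shuffle(unique_keys)
    batch_of_key = {
        k: i % cfg.n_batches for i, k in enumerate(unique_keys)
    }
    batch_of_psm = np.array([batch_of_key[k] for k in keys])

    scores = np.empty(len(psms))
    training_peptides: dict[int, set] = {}
    for batch in range(cfg.n_batches):
        held_out = batch_of_psm == batch
        train = ~held_out & (is_decoy | confident_target)
        if not held_out.any():
            training_peptides[batch] = set()
            continue
        labels = is_decoy[train]
        if labels.all() or not labels.any():
            raise ValueError(
                f"training fold for batch {batch} has a single class "
                f"({int(train.sum())} rows, {int(labels.sum())} decoys); "
                "not enough confident targets or decoys to rescore"
            )
        X_train = features[train]
        finite = np.where(np.isfinite(X_train), X_train, np.nan)
        mean = np.nanmean(finite, axis=0)
        std = np.nanstd(finite, axis=0)
        mean = np.where(np.isfinite(mean), mean, 0.0)
        std = np.where((std > 0) & np.isfinite(std), std, 1.0)
        Z_train = _zscore_impute(X_train, mean, std)
        y_train = (~labels).astype(int)  # 1 = target
        # uniform priors: the target/decoy balance of the training fold is an
        # artifact of the q-value filter, not of the score distributions
        lda = LinearDiscriminantAnalysis(
            solver="lsqr", shrinkage="auto", priors=np.array([0.5, 0.5])
        )
        lda.fit(Z_train, y_train)
        sign = 1.0
        train_scores = lda.decision_function(Z_train)
        if train_scores[y_train == 1].mean() < train_scores[y_train == 0].mean():
            sign = -1.0
        scores[held_out] = sign * lda.decision_function(
            _zscore_impute(features[held_out], mean, std)
        )
        training_peptides[batch] = {k for k, m in zip(keys, train) if m}

    for p, s in zip(psms, scores):
        p.re_score = float(s)
    return RescoreResult(
        scores=scores,
        batch_of_psm=batch_of_psm,
        training_peptides=training_peptides,
    )
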