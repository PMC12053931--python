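"""Mass calibration, collision-energy calibration, and predictor fine-tuning.

The deep RT / ion-mobility / fragment-intensity predictors of a production
pipeline are replaced by closed-form baseline models so every calibration
stage is executable and testable:

* retention time — additive per-residue retention coefficients + intercept,
  fit by ridge-regularized least squares;
* ion mobility — per-charge linear model ``1/K0 = a_z + b_z * (m/z)``;
* fragment intensity — geometric decay over the ion ordinal with a
  collision-energy-dependent decay slope.

Fine-tuning splits confident PSMs 80/20 at the peptide level; because the
baselines are closed-form, a single refit replaces the epoch loop, but the
validation report (and the never-worse-than-input guarantee) is kept.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chemistry import Peptide, monoisotopic_mass
from .constants import IM_COEFFICIENTS, PROTON, RT_COEFFICIENTS
from .search import ProcessedSpectrum, Psm

logger = logging.getLogger(__name__)

AA_ORDER = sorted(RT_COEFFICIENTS)


@dataclass(frozen=True)
class MassCalibration:
    """Global median fragment ppm error of an experiment."""

    median_ppm: float
    n_psms_used: int


@dataclass(frozen=True)
class FineTuneConfig:
    q_threshold: float = 0.01
    train_fraction: float = 0.8
    lr_start: float = 1e-3
    lr_floor: float = 1e-6
    patience_epochs: int = 5
    min_peptides: int = 20

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def estimate_mass_calibration(psms: Sequence[Psm]) -> MassCalibration:
    """Median over per-PSM average fragment ppm errors."""
    if not psms:
        raise ValueError("need at least one confident PSM for mass calibration")
    errors = np.array([p.avg_ppm_error for p in psms])
    return MassCalibration(median_ppm=float(np.median(errors)), n_psms_used=len(psms))


def apply_mass_calibration(
    spectra: Sequence[ProcessedSpectrum], cal: MassCalibration
) -> list[ProcessedSpectrum]:
    """Correct fragment m/z by the global median ppm error."""
    factor = 1.0 - cal.median_ppm * 1e-6
    return [
        ProcessedSpectrum(
            spectrum_id=s.spectrum_id,
            precursor=s.precursor,
            mz=s.mz * factor,
            intensity=s.intensity.copy(),
            n_merged=s.n_merged,
        )
        for s in spectra
    ]


def spectral_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized spectral contrast angle: 1 - 2*arccos(cos)/pi, in [−1, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    cos = float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))
    return 1.0 - 2.0 * math.acos(cos) / math.pi


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


class RetentionTimePredictor:
    """Additive residue retention coefficients mapped onto the gradient."""

    kind = "rt"

    def __init__(self, coefficients: dict[str, float] | None = None,
                 intercept: float = 0.0, scale: float = 1.0):
        self.coefficients = dict(coefficients or RT_COEFFICIENTS)
        self.intercept = intercept
        self.scale = scale
        self.training_report: list[dict] = []

    def get_params(self) -> dict:
        return {
            "kind": self.kind,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "scale": self.scale,
        }

    def clone(self) -> "RetentionTimePredictor":
        return RetentionTimePredictor(
            dict(self.coefficients), self.intercept, self.scale
        )

    def _design(self, peptides: Sequence[Peptide]) -> np.ndarray:
        X = np.zeros((len(peptides), len(AA_ORDER)))
        idx = {aa: j for j, aa in enumerate(AA_ORDER)}
        for i, p in enumerate(peptides):
            for aa in p.sequence:
                X[i, idx[aa]] += 1
        return X

    def predict(self, peptides: Sequence[Peptide]) -> np.ndarray:
        X = self._design(peptides)
        coef = np.array([self.coefficients[aa] for aa in AA_ORDER])
        return self.intercept + self.scale * (X @ coef)

    def fit(self, peptides: Sequence[Peptide], rt: np.ndarray) -> "RetentionTimePredictor":
        from sklearn.linear_model import Ridge

        X = self._design(peptides)
        model = Ridge(alpha=1e-2).fit(X, np.asarray(rt, dtype=float))
        self.coefficients = dict(zip(AA_ORDER, model.coef_.tolist()))
        self.intercept = float(model.intercept_)
        self.scale = 1.0
        return self


class IonMobilityPredictor:
    """Per-charge linear model of reduced inverse mobility vs precursor m/z."""

    kind = "ion_mobility"

    def __init__(self, coefficients: dict[int, tuple[float, float]] | None = None):
        self.coefficients = {z: tuple(ab) for z, ab in (coefficients or IM_COEFFICIENTS).items()}
        self.training_report: list[dict] = []

    def get_params(self) -> dict:
        return {"kind": self.kind, "coefficients": {str(z): list(ab) for z, ab in self.coefficients.items()}}

    def clone(self) -> "IonMobilityPredictor":
        return IonMobilityPredictor(dict(self.coefficients))

    def _coeff(self, z: int) -> tuple[float, float]:
        if z in self.coefficients:
            return self.coefficients[z]
        nearest = min(self.coefficients, key=lambda c: abs(c - z))
        return self.coefficients[nearest]

    def predict(self, peptides: Sequence[Peptide], charges: Sequence[int]) -> np.ndarray:
        out = np.empty(len(peptides))
        for i, (p, z) in enumerate(zip(peptides, charges)):
            mz = (monoisotopic_mass(p) + z * PROTON) / z
            a, b = self._coeff(z)
            out[i] = a + b * mz
        return out

    def fit(
        self,
        peptides: Sequence[Peptide],
        charges: Sequence[int],
        im: np.ndarray,
    ) -> "IonMobilityPredictor":
        charges = np.asarray(charges)
        im = np.asarray(im, dtype=float)
        mz = np.array(
            [(monoisotopic_mass(p) + z * PROTON) / z for p, z in zip(peptides, charges)]
        )
        for z in np.unique(charges):
            mask = charges == z
            if mask.sum() >= 3:
                b, a = np.polyfit(mz[mask], im[mask], 1)
                self.coefficients[int(z)] = (float(a), float(b))
        return self


@dataclass(frozen=True)
class IntensityModelParams:
    b_base: float = 1.0
    y_base: float = 2.0
    b_decay0: float = 0.10
    b_decay_ce: float = 0.0030
    y_decay0: float = 0.06
    y_decay_ce: float = 0.0015
    charge2_factor: float = 0.30
    ce_ref: float = 30.0


class IntensityPredictor:
    """Geometric-decay fragment intensity model with a CE-dependent slope."""

    kind = "intensity"

    def __init__(self, params: IntensityModelParams | None = None):
        self.params = params or IntensityModelParams()
        self.training_report: list[dict] = []

    def get_params(self) -> dict:
        return {"kind": self.kind, **self.params.__dict__}

    def predict_ions(
        self,
        ions: Sequence[tuple[str, int, int]],
        collision_energy: float,
    ) -> np.ndarray:
        """Relative intensity for (series, ordinal, charge) ions at a CE."""
        p = self.params
        d_ce = collision_energy - p.ce_ref
        decay_b = max(p.b_decay0 + p.b_decay_ce * d_ce, 0.005)
        decay_y = max(p.y_decay0 + p.y_decay_ce * d_ce, 0.005)
        out = np.empty(len(ions))
        for i, (series, ordinal, charge) in enumerate(ions):
            base, decay = (
                (p.b_base, decay_b) if series == "b" else (p.y_base, decay_y)
            )
            out[i] = base * math.exp(-decay * ordinal)
            if charge >= 2:
                out[i] *= p.charge2_factor
        return out


def psm_spectral_angle(psm: Psm, predictor: IntensityPredictor, ce_offset: float = 0.0) -> float:
    """Spectral angle between observed and predicted matched-ion intensities."""
    if not psm.matched_ions:
        return 0.0
    ions = [(s, o, z) for s, o, z, _ in psm.matched_ions]
    observed = np.array([inten for _, _, _, inten in psm.matched_ions])
    predicted = predictor.predict_ions(ions, psm.collision_energy + ce_offset)
    return spectral_angle(observed, predicted)


def calibrate_collision_energy(
    psms: Sequence[Psm],
    predictor: IntensityPredictor,
    ce_grid: Sequence[float],
    n_top: int = 4096,
) -> float:
    """Grid offset maximizing the median spectral angle over the top PSMs.

    Uses the ``n_top`` highest-scoring PSMs (all, if fewer). Ties resolve to
    the lowest offset.
    """
    if len(ce_grid) == 0:
        raise ValueError("ce_grid must be nonempty")
    top = sorted(psms, key=lambda p: -p.hyperscore)[:n_top]
    best_offset, best_median = None, -np.inf
    for offset in ce_grid:
        angles = [psm_spectral_angle(p, predictor, offset) for p in top]
        med = float(np.median(angles)) if angles else -np.inf
        if med > best_median:
            best_median, best_offset = med, float(offset)
    return best_offset


def _validation_loss(predict, peptides, y) -> float:
    if len(peptides) == 0:
        return math.nan
    residual = predict(peptides) - np.asarray(y, dtype=float)
    return float(np.sqrt(np.mean(residual**2)))


def peptide_level_split(
    keys: Sequence[str], train_fraction: float, seed: int
) -> tuple[set[str], set[str]]:
    """Disjoint train/validation split over unique peptide keys (seeded)."""
    unique = sorted(set(keys))
    rng = np.random.default_rng(seed)
    rng.shuffle(unique)
    n_train = int(round(train_fraction * len(unique)))
    return set(unique[:n_train]), set(unique[n_train:])


def fine_tune_predictor(
    model,
    psms: Sequence[Psm],
    cfg: FineTuneConfig = FineTuneConfig(),
    seed: int = 0,
):
    """Refit a baseline predictor on confident PSMs with an 80/20 report.

    PSMs are reduced to their best-scoring instance per peptide, split 80/20
    at peptide level (training and validation peptides are disjoint), and the
    model is refit on the training part. The returned model is never worse
    than the input on the validation split; with fewer than
    ``cfg.min_peptides`` distinct peptides the input is returned unchanged.
    """
    best_by_peptide: dict[str, Psm] = {}
    for p in psms:
        cur = best_by_peptide.get(p.peptide_key)
        if cur is None or p.hyperscore > cur.hyperscore:
            best_by_peptide[p.peptide_key] = p
    if len(best_by_peptide) < cfg.min_peptides:
        logger.warning(
            "fine-tuning skipped: only %d distinct peptides (< %d)",
            len(best_by_peptide),
            cfg.min_peptides,
        )
        return model
    train_keys, val_keys = peptide_level_split(
        list(best_by_peptide), cfg.train_fraction, seed
    )
    train = [best_by_peptide[k] for k in sorted(train_keys)]
    val = [best_by_peptide[k] for k in sorted(val_keys)]

    if model.kind == "rt":
        def observed(items):
            return np.array([p.retention_time for p in items])

        def predict_with(m, items):
            return m.predict([p.peptide for p in items])

        def refit(m, items):
            return m.fit([p.peptide for p in items], observed(items))
    elif model.kind == "ion_mobility":
        def observed(items):
            return np.array([p.inv_ion_mobility for p in items])

        def predict_with(m, items):
            return m.predict([p.peptide for p in items], [p.charge for p in items])

        def refit(m, items):
            return m.fit(
                [p.peptide for p in items],
                [p.charge for p in items],
                observed(items),
            )
    else:
        raise ValueError(f"cannot fine-tune predictor kind {model.kind!r}")

    loss_before = _validation_loss(lambda it: predict_with(model, it), val, observed(val))
    tuned = refit(model.clone(), train)
    loss_after = _validation_loss(lambda it: predict_with(tuned, it), val, observed(val))
    report = [
        {"epoch": 0, "lr": cfg.lr_start, "val_loss": loss_before, "stage": "input"},
        {"epoch": 1, "lr": cfg.lr_floor, "val_loss": loss_after, "stage": "refit"},
    ]
    result = tuned if loss_after <= loss_before else model
    result.training_report = report
    return result


def predictor_params_to_json(model) -> str:
    return json.dumps(model.get_params(), sort_keys=True)
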