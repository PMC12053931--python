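"""Seeded generator of DDA-PASEF-like runs with full ground truth.

The generator emulates the structure of a timsTOF DDA-PASEF acquisition at
desk scale: a random proteome with realistic amino-acid frequencies, an
in-silico digest, sampled precursor events with charge, monoisotopic m/z,
retention time, reduced inverse ion mobility, quadrupole isolation window
and scan window, b/y fragment peaks from the baseline intensity model with
multiplicative ppm error, uniform noise peaks, and repeated targeting
(refragmentation) of a configurable fraction of precursors. Every emitted
spectrum maps to exactly one ground-truth event.

It does not emulate chimeric spectra, isotope-envelope peaks in MS2,
detector saturation, or vendor raw encodings; a green end-to-end test
therefore establishes pipeline correctness on clean single-peptide spectra,
not performance on real instrument data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calibration import IntensityModelParams, IntensityPredictor
from .chemistry import DigestConfig, Peptide, apply_fixed_mods, digest_fasta
from .constants import (
    AA_FREQUENCIES,
    IM_COEFFICIENTS,
    MOD_CARBAMIDOMETHYL,
    PROTON,
    RT_COEFFICIENTS,
)
from .core_model import TimsFrame
from .io import spectra_to_mgf
from .search import PrecursorEvent, ProcessedSpectrum


@dataclass(frozen=True)
class GeneratorConfig:
    """Stated world of the synthetic acquisition (all rates seeded)."""

    n_proteins: int = 120
    protein_length_range: tuple[int, int] = (150, 400)
    digest: DigestConfig = field(default_factory=DigestConfig)
    fixed_mods: tuple[tuple[str, float], ...] = (("C", MOD_CARBAMIDOMETHYL),)
    n_sampled_peptides: int = 2000
    charge_probabilities: tuple[tuple[int, float], ...] = (
        (1, 0.02),
        (2, 0.58),
        (3, 0.30),
        (4, 0.10),
    )
    rt_gradient_length: float = 1200.0  # 20-min gradient, s
    rt_sigma: float = 5.0  # s, jitter around the additive-coefficient model
    im_coefficients: tuple[tuple[int, tuple[float, float]], ...] = tuple(
        (z, ab) for z, ab in IM_COEFFICIENTS.items()
    )
    im_sigma: float = 0.008  # Vs/cm^2
    fragment_ppm_shift: float = 0.0
    ppm_sigma: float = 1.5
    max_fragment_charge: int = 2
    fragment_mz_range: tuple[float, float] = (150.0, 1700.0)
    noise_peaks_per_spectrum: int = 15
    refragmentation_probability: float = 0.15
    max_repeats: int = 2  # additional fragmentations of one precursor
    intensity_params: IntensityModelParams = field(default_factory=IntensityModelParams)
    ce_offset: float = 0.0  # true offset from the nominal CE ramp
    intensity_cv: float = 0.10  # lognormal noise on fragment intensities
    base_precursor_intensity: float = 5000.0
    seed: int = 0


@dataclass
class GroundTruthEvent:
    precursor_id: int
    peptide: str
    mods: tuple
    charge: int
    retention_time: float
    inv_ion_mobility: float
    spectrum_ids: list[str]
    ppm_shift: float


@dataclass
class GroundTruth:
    events: list[GroundTruthEvent]
    fasta: str
    config_seed: int

    @property
    def peptide_keys(self) -> set[str]:
        return {
            Peptide(e.peptide, mods=tuple((p, d) for p, d in e.mods)).key
            for e in self.events
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_seed": self.config_seed,
                "events": [
                    {
                        "precursor_id": e.precursor_id,
                        "peptide": e.peptide,
                        "mods": [[p, d] for p, d in e.mods],
                        "charge": e.charge,
                        "retention_time": e.retention_time,
                        "inv_ion_mobility": e.inv_ion_mobility,
                        "spectrum_ids": e.spectrum_ids,
                        "ppm_shift": e.ppm_shift,
                    }
                    for e in self.events
                ],
            },
            sort_keys=True,
        )


@dataclass
class SyntheticRun:
    spectra: list[ProcessedSpectrum]  # raw, pre-merge (one per fragmentation)
    ground_truth: GroundTruth
    fasta: str

    @property
    def mgf(self) -> str:
        return spectra_to_mgf(self.spectra)


def nominal_collision_energy(mz: float) -> float:
    """timsTOF-like linear CE ramp over the quadrupole m/z range (eV)."""
    return 20.0 + (np.clip(mz, 300.0, 1700.0) - 300.0) / 1400.0 * 40.0


def generate_proteome(cfg: GeneratorConfig, rng: np.random.Generator | None = None) -> str:
    """Random FASTA with UniProt-average residue frequencies (seeded)."""
    if cfg.n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = rng or np.random.default_rng(cfg.seed)
    letters = np.array(sorted(AA_FREQUENCIES))
    probs = np.array([AA_FREQUENCIES[aa] for aa in letters])
    probs = probs / probs.sum()
    lo, hi = cfg.protein_length_range
    lines = []
    for i in range(cfg.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(letters, size=length, p=probs))
        lines.append(f">protein_{i}")
        lines.extend(seq[j : j + 60] for j in range(0, length, 60))
    return "\n".join(lines) + "\n"


def fasta_records(fasta_text: str) -> list[tuple[str, str]]:
    records, pid, chunks = [], None, []
    for line in fasta_text.splitlines():
        if line.startswith(">"):
            if pid is not None:
                records.append((pid, "".join(chunks)))
            pid, chunks = line[1:].split()[0], []
        elif line.strip():
            chunks.append(line.strip())
    if pid is not None:
        records.append((pid, "".join(chunks)))
    return records


def _rt_model(peptides: Sequence[Peptide], gradient: float, rng, sigma: float):
    raw = np.array(
        [sum(RT_COEFFICIENTS[aa] for aa in p.sequence) for p in peptides]
    )
    lo, hi = raw.min(), raw.max()
    span = hi - lo if hi > lo else 1.0
    rt = (0.05 + 0.90 * (raw - lo) / span) * gradient
    return rt + rng.normal(0.0, sigma, size=len(peptides))


def generate_run(cfg: GeneratorConfig) -> SyntheticRun:
    """Generate one DDA-PASEF-like run plus its ground truth (seeded)."""
    rng = np.random.default_rng(cfg.seed)
    fasta = generate_proteome(cfg, rng)
    records = fasta_records(fasta)
    peptides = digest_fasta(records, cfg.digest)
    fixed = dict(cfg.fixed_mods)
    peptides = [apply_fixed_mods(p, fixed) for p in peptides]
    n = min(cfg.n_sampled_peptides, len(peptides))
    chosen_idx = rng.choice(len(peptides), size=n, replace=False)
    chosen = [peptides[i] for i in chosen_idx]

    charges, charge_p = zip(*cfg.charge_probabilities)
    charge_p = np.array(charge_p) / sum(charge_p)
    charge = rng.choice(charges, size=n, p=charge_p)
    rt = _rt_model(chosen, cfg.rt_gradient_length, rng, cfg.rt_sigma)
    im_coeff = dict(cfg.im_coefficients)
    predictor = IntensityPredictor(cfg.intensity_params)

    from .chemistry import monoisotopic_mass  # local to avoid cycle at import

    spectra: list[ProcessedSpectrum] = []
    events: list[GroundTruthEvent] = []
    frag_lo, frag_hi = cfg.fragment_mz_range
    for i, pep in enumerate(chosen):
        z = int(charge[i])
        mass = monoisotopic_mass(pep)
        prec_mz = (mass + z * PROTON) / z
        a, b = im_coeff.get(z, im_coeff[min(im_coeff, key=lambda c: abs(c - z))])
        im = a + b * prec_mz + rng.normal(0.0, cfg.im_sigma)
        ce = nominal_collision_energy(prec_mz)
        prec_intensity = cfg.base_precursor_intensity * rng.lognormal(0.0, 0.6)

        n_frag_events = 1
        if rng.random() < cfg.refragmentation_probability:
            n_frag_events += int(rng.integers(1, cfg.max_repeats + 1))
        shares = rng.dirichlet(np.full(n_frag_events, 5.0))

        ions = []
        L = len(pep.sequence)
        for zf in range(1, cfg.max_fragment_charge + 1):
            for ordinal in range(1, L):
                ions.append(("b", ordinal, zf))
                ions.append(("y", ordinal, zf))
        from .search import _fragment_arrays

        theo_mz, series_code, ordinals, frag_charge = _fragment_arrays(
            pep, cfg.max_fragment_charge
        )
        rel = predictor.predict_ions(
            [
                ("b" if s == 0 else "y", int(o), int(c))
                for s, o, c in zip(series_code, ordinals, frag_charge)
            ],
            ce + cfg.ce_offset,
        )
        in_range = (theo_mz >= frag_lo) & (theo_mz <= frag_hi)

        sids = []
        for rep in range(n_frag_events):
            ppm_err = cfg.fragment_ppm_shift + rng.normal(
                0.0, cfg.ppm_sigma, size=theo_mz.size
            )
            mz_obs = theo_mz * (1.0 + ppm_err * 1e-6)
            inten = (
                rel
                * prec_intensity
                * shares[rep]
                * rng.lognormal(0.0, cfg.intensity_cv, size=rel.size)
            )
            mz_obs, inten = mz_obs[in_range], inten[in_range]
            if cfg.noise_peaks_per_spectrum > 0:
                noise_mz = rng.uniform(frag_lo, frag_hi, cfg.noise_peaks_per_spectrum)
                noise_int = (
                    rng.exponential(0.03 * prec_intensity * shares[rep],
                                    cfg.noise_peaks_per_spectrum)
                )
                mz_obs = np.concatenate([mz_obs, noise_mz])
                inten = np.concatenate([inten, noise_int])
            sid = f"precursor_{i}_rep_{rep}"
            sids.append(sid)
            precursor = PrecursorEvent(
                precursor_id=i,
                mz=prec_mz,
                charge=z,
                retention_time=float(rt[i] + 0.6 * rep),
                inv_ion_mobility=float(im),
                isolation_window=(prec_mz - 1.5, prec_mz + 1.5),
                scan_window=(float(im) - 0.05, float(im) + 0.05),
                intensity=float(prec_intensity * shares[rep]),
                collision_energy=float(ce),
            )
            spectra.append(
                ProcessedSpectrum(
                    spectrum_id=sid,
                    precursor=precursor,
                    mz=mz_obs,
                    intensity=inten,
                )
            )
        events.append(
            GroundTruthEvent(
                precursor_id=i,
                peptide=pep.sequence,
                mods=pep.mods,
                charge=z,
                retention_time=float(rt[i]),
                inv_ion_mobility=float(im),
                spectrum_ids=sids,
                ppm_shift=cfg.fragment_ppm_shift,
            )
        )
    truth = GroundTruth(events=events, fasta=fasta, config_seed=cfg.seed)
    return SyntheticRun(spectra=spectra, ground_truth=truth, fasta=fasta)


def run_to_frames(
    run: SyntheticRun,
    frame_interval: float = 0.5,
    scan_intercept: float = 1.6,
    scan_slope: float = 1e-3,
) -> list[TimsFrame]:
    """Arrange the run's peaks into frames on a linear scan<->mobility map.

    mobility = scan_intercept - scan_slope * scan; spectra falling into the
    same retention-time bucket share a frame.
    """
    by_frame: dict[int, list[ProcessedSpectrum]] = {}
    for s in run.spectra:
        by_frame.setdefault(int(s.precursor.retention_time // frame_interval), []).append(s)
    frames = []
    for frame_id in sorted(by_frame):
        group = by_frame[frame_id]
        scan_list, im_list, mz_list, int_list = [], [], [], []
        for s in group:
            scan = int(round((scan_intercept - s.precursor.inv_ion_mobility) / scan_slope))
            mobility = scan_intercept - scan_slope * scan
            scan_list.append(np.full(len(s), scan))
            im_list.append(np.full(len(s), mobility))
            mz_list.append(s.mz)
            int_list.append(s.intensity)
        frames.append(
            TimsFrame(
                frame_id=frame_id,
                retention_time=frame_id * frame_interval,
                scan=np.concatenate(scan_list),
                inv_ion_mobility=np.concatenate(im_list),
                mz=np.concatenate(mz_list),
                intensity=np.concatenate(int_list),
            )
        )
    return frames


def entrapment_records(
    cfg: GeneratorConfig, n_extra: int | None = None, seed_offset: int = 104729
) -> list[tuple[str, str]]:
    """Irrelevant proteins (distinct seed) to append as an entrapment set."""
    extra_cfg = GeneratorConfig(
        n_proteins=n_extra if n_extra is not None else cfg.n_proteins,
        protein_length_range=cfg.protein_length_range,
        seed=(cfg.seed + seed_offset) % (2**31 - 1),
    )
    fasta = generate_proteome(extra_cfg)
    return [(f"entrap_{pid}", seq) for pid, seq in fasta_records(fasta)]
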