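"""Spectrum preprocessing, fragment-indexed database search, and PSM scoring.

The search follows the fragment-index strategy: theoretical b/y fragments of
all candidate peptides (targets + decoys) are stored in one flat table sorted
by fragment m/z, with candidate retrieval by precursor neutral mass. Scoring
uses the X!Tandem-style hyperscore

    ln(Nb!) + ln(Ny!) + ln(1 + sum of matched intensity)

with factorial arguments capped at 10 to prevent overflow.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np

from .chemistry import (
    DigestConfig,
    Peptide,
    apply_fixed_mods,
    apply_variable_mods,
    digest_fasta,
    generate_decoys,
    monoisotopic_mass,
)
from .constants import NEUTRON_DELTA, PROTON, RESIDUE_MASS, WATER

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PrecursorEvent:
    """One quadrupole-selected precursor from DDA-PASEF metadata."""

    precursor_id: int
    mz: float
    charge: int | None
    retention_time: float
    inv_ion_mobility: float
    isolation_window: tuple[float, float] = (0.0, 0.0)
    scan_window: tuple[float, float] = (0.0, 0.0)
    intensity: float = 0.0
    collision_energy: float = 30.0

    def __post_init__(self):
        for lo, hi in (self.isolation_window, self.scan_window):
            if lo > hi:
                raise ValueError("window bounds must satisfy low <= high")
        if self.charge is not None and self.charge < 1:
            raise ValueError("charge must be >= 1 or None")


@dataclass
class ProcessedSpectrum:
    """Fragment spectrum in search-ready form (merged, sorted by m/z)."""

    spectrum_id: str
    precursor: PrecursorEvent
    mz: np.ndarray
    intensity: np.ndarray
    n_merged: int = 1

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        order = np.argsort(self.mz, kind="stable")
        if not np.array_equal(order, np.arange(self.mz.size)):
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())


@dataclass(frozen=True)
class ScorerConfig:
    """Search parameters; defaults follow the tryptic configuration."""

    precursor_tol_ppm: float = 15.0
    fragment_tol_ppm: float = 20.0
    min_matched_peaks: int = 5
    min_fragment_mz: float = 150.0
    max_fragment_mz: float = 1700.0
    max_precursor_charge: int = 5
    max_fragment_charge: int = 2
    top_n_peaks: int = 150
    report_n_psms: int = 5
    isotope_errors: tuple[int, int] = (-1, 2)  # neutron offsets, inclusive

    def __post_init__(self):
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_ppm <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class Psm:
    """One candidate peptide-spectrum match with matched-ion statistics."""

    spectrum_id: str
    peptide: Peptide
    charge: int
    hyperscore: float
    rank: int = 0
    delta_next: float = 0.0
    matched_b: int = 0
    matched_y: int = 0
    longest_b: int = 0
    longest_y: int = 0
    matched_intensity: float = 0.0
    matched_intensity_fraction: float = 0.0
    avg_ppm_error: float = 0.0
    precursor_ppm_error: float = 0.0
    isotope_error: int = 0
    retention_time: float = 0.0
    inv_ion_mobility: float = 0.0
    collision_energy: float = 30.0
    # (series, ordinal, charge, observed intensity) for each matched ion
    matched_ions: list = field(default_factory=list)
    rt_predicted: float = math.nan
    im_predicted: float = math.nan
    spectral_angle: float = math.nan
    cosine_similarity: float = math.nan
    re_score: float = math.nan
    q_value: float = math.nan

    @property
    def is_decoy(self) -> bool:
        return self.peptide.is_decoy

    @property
    def peptide_key(self) -> str:
        return self.peptide.key


def merge_refragmented(
    spectra: Sequence[ProcessedSpectrum], grid_resolution: int = 2
) -> ProcessedSpectrum:
    """Merge repeated fragmentations of one precursor on a rounded m/z grid.

    Peaks sharing a grid cell sum; total intensity is conserved. The merged
    precursor record comes from the most intense event; precursor intensities
    add up.
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    ids = {s.precursor.precursor_id for s in spectra}
    if len(ids) > 1:
        raise ValueError(f"mixed precursor ids: {sorted(ids)}")
    if len(spectra) == 1:
        return spectra[0]
    best = max(spectra, key=lambda s: s.precursor.intensity)
    mz = np.round(np.concatenate([s.mz for s in spectra]), grid_resolution)
    intensity = np.concatenate([s.intensity for s in spectra])
    keys, inv = np.unique(mz, return_inverse=True)
    sums = np.bincount(inv, weights=intensity)
    precursor = replace(
        best.precursor, intensity=sum(s.precursor.intensity for s in spectra)
    )
    return ProcessedSpectrum(
        spectrum_id=best.spectrum_id,
        precursor=precursor,
        mz=keys,
        intensity=sums,
        n_merged=sum(s.n_merged for s in spectra),
    )


def top_n_filter(s: ProcessedSpectrum, n: int = 150) -> ProcessedSpectrum:
    """Keep the n most intense peaks; intensity ties keep the lower m/z."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(s) <= n:
        return s
    order = np.lexsort((s.mz, -s.intensity))[:n]
    keep = np.sort(order)
    return ProcessedSpectrum(
        spectrum_id=s.spectrum_id,
        precursor=s.precursor,
        mz=s.mz[keep],
        intensity=s.intensity[keep],
        n_merged=s.n_merged,
    )


_RESIDUE_LOOKUP = np.zeros(128)
for _aa, _m in RESIDUE_MASS.items():
    _RESIDUE_LOOKUP[ord(_aa)] = _m


@lru_cache(maxsize=4096)
def _ion_layout(n: int, max_charge: int):
    """(series, ordinal, charge) layout shared by all peptides of length n."""
    ordinals = np.arange(1, n)
    series, ords, charges = [], [], []
    for z in range(1, max_charge + 1):
        series.append(np.zeros(n - 1, dtype=np.int8))
        ords.append(ordinals)
        charges.append(np.full(n - 1, z, dtype=np.int8))
        series.append(np.ones(n - 1, dtype=np.int8))
        ords.append(ordinals)
        charges.append(np.full(n - 1, z, dtype=np.int8))
    return (
        np.concatenate(series),
        np.concatenate(ords),
        np.concatenate(charges),
    )


def _fragment_arrays(p: Peptide, max_charge: int):
    """Vectorized b/y fragment m/z computation for one peptide."""
    n = len(p.sequence)
    residue = _RESIDUE_LOOKUP[np.frombuffer(p.sequence.encode(), np.uint8)]
    nterm = 0.0
    if p.mods:
        residue = residue.copy()
        for pos, delta in p.mods:
            if pos == "N-term":
                nterm += delta
            else:
                residue[int(pos)] += delta
    prefix = np.cumsum(residue)
    b_neutral = prefix[:-1] + nterm
    y_neutral = prefix[-1] - prefix[:-1][::-1] + WATER  # ordinal-aligned
    mz_parts = []
    for z in range(1, max_charge + 1):
        mz_parts.append((b_neutral + z * PROTON) / z)
        mz_parts.append((y_neutral + z * PROTON) / z)
    series, ordinals, charges = _ion_layout(n, max_charge)
    return np.concatenate(mz_parts), series, ordinals, charges


class FragmentIndex:
    """Sorted theoretical-fragment table with precursor-mass retrieval.

    ``entries`` is a flat structure-of-arrays sorted by fragment m/z;
    per-peptide fragment arrays (already filtered to the configured m/z
    bounds) are kept for scoring.
    """

    def __init__(self, peptides: Sequence[Peptide], cfg: ScorerConfig):
        if not peptides:
            raise ValueError("peptide list must be nonempty")
        self.cfg = cfg
        self.peptides = list(peptides)
        self.neutral_mass = np.array([monoisotopic_mass(p) for p in self.peptides])
        self._mass_order = np.argsort(self.neutral_mass, kind="stable")
        self._sorted_mass = self.neutral_mass[self._mass_order]

        self._pep_fragments = []
        flat_mz, flat_pep, flat_series, flat_ord, flat_charge = [], [], [], [], []
        for i, p in enumerate(self.peptides):
            mz, series, ordinal, charge = _fragment_arrays(
                p, cfg.max_fragment_charge
            )
            keep = (mz >= cfg.min_fragment_mz) & (mz <= cfg.max_fragment_mz)
            mz, series, ordinal, charge = (
                mz[keep],
                series[keep],
                ordinal[keep],
                charge[keep],
            )
            self._pep_fragments.append((mz, series, ordinal, charge))
            flat_mz.append(mz)
            flat_pep.append(np.full(mz.size, i, dtype=np.int64))
            flat_series.append(series)
            flat_ord.append(ordinal)
            flat_charge.append(charge)
        mz = np.concatenate(flat_mz)
        order = np.argsort(mz, kind="stable")
        self.fragment_mz = mz[order]
        self.fragment_pep = np.concatenate(flat_pep)[order]
        self.fragment_series = np.concatenate(flat_series)[order]
        self.fragment_ordinal = np.concatenate(flat_ord)[order]
        self.fragment_charge = np.concatenate(flat_charge)[order]
        if self.fragment_mz.size == 0:
            logger.warning("fragment index is empty for the configured m/z bounds")

    def __len__(self) -> int:
        return int(self.fragment_mz.size)

    def query_fragments(self, mz: float, tol_ppm: float) -> np.ndarray:
        """Positions of index entries within ±tol_ppm of ``mz``."""
        tol = mz * tol_ppm * 1e-6
        lo = np.searchsorted(self.fragment_mz, mz - tol, side="left")
        hi = np.searchsorted(self.fragment_mz, mz + tol, side="right")
        return np.arange(lo, hi)

    def candidate_peptides(self, neutral_mass: float, tol_ppm: float) -> np.ndarray:
        """Indices of peptides whose neutral mass is within ±tol_ppm."""
        tol = neutral_mass * tol_ppm * 1e-6
        lo = np.searchsorted(self._sorted_mass, neutral_mass - tol, side="left")
        hi = np.searchsorted(self._sorted_mass, neutral_mass + tol, side="right")
        return self._mass_order[lo:hi]

    def fragments_of(self, pep_idx: int):
        return self._pep_fragments[pep_idx]


def build_index(peptides: Sequence[Peptide], cfg: ScorerConfig) -> FragmentIndex:
    return FragmentIndex(peptides, cfg)


def hyperscore(n_b: int, n_y: int, matched_intensity: float) -> float:
    """X!Tandem-style score; factorial arguments capped at 10."""
    return (
        math.lgamma(min(n_b, 10) + 1)
        + math.lgamma(min(n_y, 10) + 1)
        + math.log1p(max(matched_intensity, 0.0))
    )


def _longest_run(ordinals: np.ndarray) -> int:
    if ordinals.size == 0:
        return 0
    vals = np.unique(ordinals)
    best = run = 1
    for a, b in zip(vals, vals[1:]):
        run = run + 1 if b == a + 1 else 1
        best = max(best, run)
    return int(best)


def _match_candidate(spectrum: ProcessedSpectrum, theo, tol_ppm: float):
    """Match theoretical fragments to the nearest observed peak within ppm."""
    theo_mz, series, ordinal, charge = theo
    if theo_mz.size == 0 or len(spectrum) == 0:
        return None
    pos = np.searchsorted(spectrum.mz, theo_mz)
    left = np.clip(pos - 1, 0, len(spectrum) - 1)
    right = np.clip(pos, 0, len(spectrum) - 1)
    d_left = np.abs(spectrum.mz[left] - theo_mz)
    d_right = np.abs(spectrum.mz[right] - theo_mz)
    nearest = np.where(d_left <= d_right, left, right)
    delta = spectrum.mz[nearest] - theo_mz
    matched = np.abs(delta) <= theo_mz * tol_ppm * 1e-6
    if not matched.any():
        return None
    peak_idx = nearest[matched]
    ppm = delta[matched] / theo_mz[matched] * 1e6
    return {
        "series": series[matched],
        "ordinal": ordinal[matched],
        "charge": charge[matched],
        "peak_idx": peak_idx,
        "peak_intensity": spectrum.intensity[peak_idx],
        "ppm": ppm,
    }


def score_spectrum(
    spectrum: ProcessedSpectrum,
    index: FragmentIndex,
    cfg: ScorerConfig | None = None,
    fragment_tol_ppm: float | None = None,
) -> list[Psm]:
    """Score one spectrum against the index; top ``report_n_psms`` returned.

    Candidates are peptides whose neutral mass matches the precursor within
    the ppm tolerance for each assumed charge (2..max if unknown) and for
    isotope-error offsets. ``fragment_tol_ppm`` overrides the configured
    fragment tolerance (used by the wide first-pass calibration search).
    """
    cfg = cfg or index.cfg
    frag_tol = fragment_tol_ppm if fragment_tol_ppm is not None else cfg.fragment_tol_ppm
    prec = spectrum.precursor
    charges = (
        [prec.charge]
        if prec.charge is not None
        else list(range(2, cfg.max_precursor_charge + 1))
    )
    iso_lo, iso_hi = cfg.isotope_errors
    best_per_peptide: dict[int, Psm] = {}
    total_intensity = spectrum.total_intensity
    for z in charges:
        observed_neutral = z * (prec.mz - PROTON)
        for k in range(iso_lo, iso_hi + 1):
            neutral = observed_neutral - k * NEUTRON_DELTA
            for pep_idx in index.candidate_peptides(neutral, cfg.precursor_tol_ppm):
                theo_mass = index.neutral_mass[pep_idx]
                prec_ppm = (neutral - theo_mass) / theo_mass * 1e6
                m = _match_candidate(
                    spectrum, index.fragments_of(pep_idx), frag_tol
                )
                if m is None:
                    continue
                n_matched = int(m["series"].size)
                if n_matched < cfg.min_matched_peaks:
                    continue
                b_mask = m["series"] == 0
                n_b = int(b_mask.sum())
                n_y = n_matched - n_b
                unique_peaks = np.unique(m["peak_idx"])
                matched_int = float(spectrum.intensity[unique_peaks].sum())
                score = hyperscore(n_b, n_y, matched_int)
                prev = best_per_peptide.get(pep_idx)
                if prev is not None and (
                    prev.hyperscore > score
                    or (
                        prev.hyperscore == score
                        and abs(prev.precursor_ppm_error) <= abs(prec_ppm)
                    )
                ):
                    continue
                psm = Psm(
                    spectrum_id=spectrum.spectrum_id,
                    peptide=index.peptides[pep_idx],
                    charge=z,
                    hyperscore=score,
                    matched_b=n_b,
                    matched_y=n_y,
                    longest_b=_longest_run(m["ordinal"][b_mask]),
                    longest_y=_longest_run(m["ordinal"][~b_mask]),
                    matched_intensity=matched_int,
                    matched_intensity_fraction=(
                        matched_int / total_intensity if total_intensity > 0 else 0.0
                    ),
                    avg_ppm_error=float(np.mean(m["ppm"])),
                    precursor_ppm_error=float(prec_ppm),
                    isotope_error=k,
                    retention_time=prec.retention_time,
                    inv_ion_mobility=prec.inv_ion_mobility,
                    collision_energy=prec.collision_energy,
                    matched_ions=list(
                        zip(
                            np.where(m["series"] == 0, "b", "y").tolist(),
                            m["ordinal"].tolist(),
                            m["charge"].tolist(),
                            m["peak_intensity"].tolist(),
                        )
                    ),
                )
                best_per_peptide[pep_idx] = psm
    psms = sorted(
        best_per_peptide.values(),
        key=lambda p: (
            -p.hyperscore,
            abs(p.avg_ppm_error),
            p.peptide.sequence,
        ),
    )[: cfg.report_n_psms]
    for i, psm in enumerate(psms):
        psm.rank = i + 1
        psm.delta_next = (
            psms[i].hyperscore - psms[i + 1].hyperscore if i + 1 < len(psms) else 0.0
        )
    return psms


def score_spectra(
    spectra: Sequence[ProcessedSpectrum],
    index: FragmentIndex,
    cfg: ScorerConfig | None = None,
    fragment_tol_ppm: float | None = None,
) -> list[Psm]:
    out: list[Psm] = []
    for s in spectra:
        out.extend(score_spectrum(s, index, cfg, fragment_tol_ppm))
    return out


def build_search_space(
    records: Sequence[tuple[str, str]],
    digest_cfg: DigestConfig,
    fixed_mods: dict | None = None,
    variable_mods: Sequence[tuple[str, float]] = (),
    max_mods: int = 3,
) -> list[Peptide]:
    """Digest, modify, and append reversed decoys (collisions dropped)."""
    targets = [
        variant
        for pep in digest_fasta(records, digest_cfg)
        for variant in apply_variable_mods(
            apply_fixed_mods(pep, fixed_mods), variable_mods, max_mods
        )
    ]
    return targets + generate_decoys(targets)


def _rerank(psms: list[Psm], report_n: int) -> list[Psm]:
    psms = sorted(
        psms,
        key=lambda p: (-p.hyperscore, abs(p.avg_ppm_error), p.peptide.sequence),
    )[:report_n]
    for i, psm in enumerate(psms):
        psm.rank = i + 1
        psm.delta_next = (
            psms[i].hyperscore - psms[i + 1].hyperscore if i + 1 < len(psms) else 0.0
        )
    return psms


def search_chunked(
    records: Sequence[tuple[str, str]],
    spectra: Sequence[ProcessedSpectrum],
    cfg: ScorerConfig,
    digest_cfg: DigestConfig,
    fixed_mods: dict | None = None,
    variable_mods: Sequence[tuple[str, float]] = (),
    max_mods: int = 3,
    n_chunks: int = 1,
    seed: int = 0,
    fragment_tol_ppm: float | None = None,
) -> list[Psm]:
    """Search a proteome split into ``n_chunks`` random parts sequentially.

    Proteins are randomly assigned to chunks (seeded); per-chunk PSMs are
    merged by spectrum, re-ranked by score, and trimmed to ``report_n_psms``.
    With one chunk this is identical to a plain search.
    """
    if n_chunks < 1:
        raise ValueError("n_chunks must be >= 1")
    rng = np.random.default_rng(seed)
    assignment = rng.integers(0, n_chunks, size=len(records))
    by_spectrum: dict[str, list[Psm]] = {}
    for chunk in range(n_chunks):
        chunk_records = [r for r, a in zip(records, assignment) if a == chunk]
        if not chunk_records:
            continue
        peptides = build_search_space(
            chunk_records, digest_cfg, fixed_mods, variable_mods, max_mods
        )
        if not peptides:
            continue
        index = build_index(peptides, cfg)
        for psm in score_spectra(spectra, index, cfg, fragment_tol_ppm):
            by_spectrum.setdefault(psm.spectrum_id, []).append(psm)
    merged: list[Psm] = []
    for sid in sorted(by_spectrum):
        merged.extend(_rerank(by_spectrum[sid], cfg.report_n_psms))
    return merged
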