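"""Preprocessing, fragment index, hyperscore, and chunked search."""

import math

import numpy as np
import pytest

from timsdda.chemistry import DigestConfig, Peptide
from timsdda.constants import PROTON
from timsdda.search import (
    PrecursorEvent,
    ProcessedSpectrum,
    ScorerConfig,
    _fragment_arrays,
    build_index,
    build_search_space,
    hyperscore,
    merge_refragmented,
    score_spectrum,
    search_chunked,
    top_n_filter,
)
from timsdda.chemistry import monoisotopic_mass


def spectrum_for(peptide: Peptide, charge=2, spectrum_id="s0", precursor_id=0,
                 mz=None, intensity=None, cfg=None):
    """Noise-free spectrum containing the peptide's singly charged fragments."""
    cfg = cfg or ScorerConfig()
    if mz is None:
        theo, series, ordinal, z = _fragment_arrays(peptide, 1)
        keep = (theo >= cfg.min_fragment_mz) & (theo <= cfg.max_fragment_mz)
        mz = np.sort(theo[keep])
        intensity = np.full(mz.size, 100.0)
    prec_mz = (monoisotopic_mass(peptide) + charge * PROTON) / charge
    return ProcessedSpectrum(
        spectrum_id=spectrum_id,
        precursor=PrecursorEvent(
            precursor_id=precursor_id,
            mz=prec_mz,
            charge=charge,
            retention_time=100.0,
            inv_ion_mobility=0.9,
            intensity=1000.0,
        ),
        mz=np.asarray(mz, dtype=float),
        intensity=np.asarray(intensity, dtype=float),
    )


class TestMerge:
    def test_same_grid_cell_sums(self):
        base = spectrum_for(Peptide("ACDEFGHIK"))
        a = ProcessedSpectrum("a", base.precursor, [500.004], [10.0])
        b = ProcessedSpectrum("b", base.precursor, [500.001], [20.0])
        merged = merge_refragmented([a, b], grid_resolution=2)
        assert len(merged) == 1
        assert merged.intensity[0] == 30.0
        assert merged.n_merged == 2

    def test_single_spectrum_identity(self):
        s = spectrum_for(Peptide("ACDEFGHIK"))
        assert merge_refragmented([s]) is s
        assert s.n_merged == 1

    def test_total_intensity_conserved(self, rng):
        prec = spectrum_for(Peptide("ACDEFGHIK")).precursor
        group = [
            ProcessedSpectrum(
                f"s{i}", prec, np.sort(rng.uniform(200, 1200, 40)),
                rng.uniform(1, 100, 40),
            )
            for i in range(4)
        ]
        merged = merge_refragmented(group)
        assert merged.total_intensity == pytest.approx(
            sum(s.total_intensity for s in group), rel=1e-12
        )

    def test_mixed_precursor_ids_error(self):
        a = spectrum_for(Peptide("ACDEFGHIK"), precursor_id=1)
        b = spectrum_for(Peptide("ACDEFGHIK"), precursor_id=2)
        with pytest.raises(ValueError, match="mixed precursor"):
            merge_refragmented([a, b])


class TestTopN:
    def test_truncates_to_n(self, rng):
        prec = spectrum_for(Peptide("ACDEFGHIK")).precursor
        s = ProcessedSpectrum(
            "s", prec, np.sort(rng.uniform(200, 1200, 200)), rng.uniform(1, 100, 200)
        )
        assert len(top_n_filter(s, 150)) == 150

    def test_fewer_peaks_untouched(self):
        s = spectrum_for(Peptide("ACDEFGHIK"))
        assert len(top_n_filter(s, 150)) == len(s)

    def test_keeps_most_intense_sorted_by_mz(self):
        prec = spectrum_for(Peptide("ACDEFGHIK")).precursor
        s = ProcessedSpectrum("s", prec, [100.0, 200.0, 300.0], [5.0, 50.0, 10.0])
        out = top_n_filter(s, 2)
        assert out.mz.tolist() == [200.0, 300.0]

    def test_tie_keeps_lower_mz(self):
        prec = spectrum_for(Peptide("ACDEFGHIK")).precursor
        s = ProcessedSpectrum("s", prec, [100.0, 200.0, 300.0], [7.0, 9.0, 7.0])
        out = top_n_filter(s, 2)
        assert out.mz.tolist() == [100.0, 200.0]


class TestIndex:
    def test_entry_count_single_peptide(self):
        cfg = ScorerConfig(min_fragment_mz=0.0, max_fragment_mz=1e6)
        idx = build_index([Peptide("ACDEFGHK")], cfg)
        assert len(idx) == 4 * 7

    def test_bounds_can_exclude_everything(self):
        cfg = ScorerConfig(min_fragment_mz=5000.0, max_fragment_mz=6000.0)
        idx = build_index([Peptide("ACDEFGHK")], cfg)
        assert len(idx) == 0

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            build_index([], ScorerConfig())

    def test_query_equals_naive_scan(self, rng):
        from timsdda.chemistry import digest
        cfg = DigestConfig("tryptic", 1, 5, 25)
        peptides = []
        for _ in range(30):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
            peptides.extend(digest(seq, cfg))
        if not peptides:
            pytest.skip("random digest produced nothing")
        idx = build_index(peptides, ScorerConfig())
        for _ in range(50):
            mz = float(rng.uniform(150, 1700))
            tol = float(rng.uniform(5, 50))
            got = {
                (
                    int(idx.fragment_pep[i]),
                    int(idx.fragment_series[i]),
                    int(idx.fragment_ordinal[i]),
                    int(idx.fragment_charge[i]),
                    float(idx.fragment_mz[i]),
                )
                for i in idx.query_fragments(mz, tol)
            }
            naive = {
                (
                    int(idx.fragment_pep[i]),
                    int(idx.fragment_series[i]),
                    int(idx.fragment_ordinal[i]),
                    int(idx.fragment_charge[i]),
                    float(idx.fragment_mz[i]),
                )
                for i in range(len(idx))
                if abs(idx.fragment_mz[i] - mz) <= mz * tol * 1e-6
            }
            assert got == naive


class TestScoring:
    def test_hyperscore_formula(self):
        # 2 matched b ions (150, 50) + 1 y ion (50): ln(2!) + ln(1!) + ln(251)
        assert hyperscore(2, 1, 250.0) == pytest.approx(
            math.log(2) + math.log(251), abs=1e-9
        )

    def test_hyperscore_factorial_cap(self):
        assert hyperscore(25, 0, 0.0) == hyperscore(10, 0, 0.0)

    def test_hyperscore_monotone_in_matches(self, rng):
        for _ in range(50):
            nb, ny = rng.integers(0, 15, 2)
            inten = float(rng.uniform(0, 1e5))
            more = hyperscore(int(nb) + 1, int(ny), inten + 10.0)
            assert more >= hyperscore(int(nb), int(ny), inten)

    def test_min_matched_peaks_gate(self):
        pep = Peptide("ACDEFGHIK")
        s = spectrum_for(pep)
        # keep only 4 fragment peaks -> below the default gate of 5
        s4 = ProcessedSpectrum(s.spectrum_id, s.precursor, s.mz[:4], s.intensity[:4])
        idx = build_index([pep], ScorerConfig())
        assert score_spectrum(s4, idx) == []
        s5 = ProcessedSpectrum(s.spectrum_id, s.precursor, s.mz[:5], s.intensity[:5])
        assert len(score_spectrum(s5, idx)) == 1

    def test_true_peptide_rank_one_noise_free(self, rng):
        from timsdda.chemistry import digest
        cfg = DigestConfig("tryptic", 1, 7, 25)
        peptides = []
        for _ in range(40):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80))
            peptides.extend(digest(seq, cfg))
        peptides = list({p.sequence: p for p in peptides}.values())
        idx = build_index(peptides, ScorerConfig())
        hits = 0
        for pep in peptides[:25]:
            psms = score_spectrum(spectrum_for(pep), idx)
            assert psms, f"no PSM for {pep.sequence}"
            if psms[0].peptide.sequence == pep.sequence:
                hits += 1
        assert hits == 25

    def test_deterministic(self, rng):
        pep = Peptide("ACDEFGHIK")
        idx = build_index([pep, Peptide("ACDEFGHIR")], ScorerConfig())
        s = spectrum_for(pep)
        a = score_spectrum(s, idx)
        b = score_spectrum(s, idx)
        assert [(p.peptide.sequence, p.hyperscore) for p in a] == [
            (p.peptide.sequence, p.hyperscore) for p in b
        ]

    def test_matched_stats_populated(self):
        pep = Peptide("ACDEFGHIK")
        psm = score_spectrum(spectrum_for(pep), build_index([pep], ScorerConfig()))[0]
        assert psm.matched_b + psm.matched_y == len(psm.matched_ions)
        assert psm.matched_intensity_fraction == pytest.approx(1.0)
        assert abs(psm.avg_ppm_error) < 1e-6
        assert psm.rank == 1


class TestChunkedSearch:
    def _records_and_spectra(self, rng, n_proteins=12):
        records = [
            (
                f"p{i}",
                "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=70)),
            )
            for i in range(n_proteins)
        ]
        cfg = DigestConfig("tryptic", 1, 7, 25)
        from timsdda.chemistry import digest_fasta

        peptides = digest_fasta(records, cfg)
        spectra = [
            spectrum_for(p, spectrum_id=f"s{i}", precursor_id=i)
            for i, p in enumerate(peptides[:20])
        ]
        return records, cfg, spectra

    def test_single_chunk_identical_to_direct(self, rng):
        records, dcfg, spectra = self._records_and_spectra(rng)
        scfg = ScorerConfig()
        direct_index = build_index(build_search_space(records, dcfg), scfg)
        direct = [
            (p.spectrum_id, p.peptide.key, round(p.hyperscore, 9))
            for s in spectra
            for p in score_spectrum(s, direct_index)
        ]
        chunked = [
            (p.spectrum_id, p.peptide.key, round(p.hyperscore, 9))
            for p in search_chunked(records, spectra, scfg, dcfg, n_chunks=1)
        ]
        assert sorted(direct) == sorted(chunked)

    def test_six_chunks_same_rank_one(self, rng):
        records, dcfg, spectra = self._records_and_spectra(rng)
        scfg = ScorerConfig()
        plain = search_chunked(records, spectra, scfg, dcfg, n_chunks=1)
        chunked = search_chunked(records, spectra, scfg, dcfg, n_chunks=6, seed=5)
        top_plain = {p.spectrum_id: p for p in plain if p.rank == 1}
        top_chunked = {p.spectrum_id: p for p in chunked if p.rank == 1}
        for sid, p in top_plain.items():
            if p.delta_next > 1e-9:  # unique best score
                assert top_chunked[sid].peptide.key == p.peptide.key

    def test_partition_reproducible(self, rng):
        records, dcfg, spectra = self._records_and_spectra(rng)
        a = search_chunked(records, spectra, ScorerConfig(), dcfg, n_chunks=3, seed=9)
        b = search_chunked(records, spectra, ScorerConfig(), dcfg, n_chunks=3, seed=9)
        assert [(p.spectrum_id, p.peptide.key, p.hyperscore) for p in a] == [
            (p.spectrum_id, p.peptide.key, p.hyperscore) for p in b
        ]
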