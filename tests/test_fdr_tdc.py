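"""Target-decoy competition q-values against brute-force oracles."""

import numpy as np
import pytest

from timsdda.chemistry import Peptide, make_decoy
from timsdda.fdr_tdc import (
    qvalues,
    read_psms_jsonl,
    tdc_double,
    tdc_peptide,
    tdc_psm,
    filter_and_report,
    write_psms_jsonl,
)
from timsdda.search import Psm

from conftest import make_psm


def oracle_qvalues(scores, is_decoy):
    """O(n^2) all-cutoffs reference: FDR(c) = (D(c)+1)/max(T(c),1)."""
    scores = np.asarray(scores, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    q = np.empty(scores.size)
    for i, s in enumerate(scores):
        best = np.inf
        for c in scores[scores <= s]:
            at_least = scores >= c
            d = int((is_decoy & at_least).sum())
            t = int((~is_decoy & at_least).sum())
            best = min(best, (d + 1) / max(t, 1))
        q[i] = min(best, 1.0)
    return q


def random_psm_instance(rng, n_max=50):
    """Random target/decoy PSMs over a handful of spectra and peptides."""
    n = int(rng.integers(2, n_max + 1))
    psms = []
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    for i in range(n):
        seq = "".join(rng.choice(alphabet, size=7))
        target = Peptide(seq)
        use_decoy = bool(rng.random() < 0.5)
        pep = make_decoy(target) if use_decoy else target
        if pep.sequence == target.sequence and use_decoy:
            continue  # palindromic, skip
        psms.append(
            Psm(
                spectrum_id=f"spec{int(rng.integers(0, max(2, n // 2)))}",
                peptide=pep,
                charge=2,
                hyperscore=float(np.round(rng.uniform(0, 20), 1)),  # forces ties
            )
        )
    return psms


class TestQValueCore:
    def test_spec_worked_example(self):
        psms = [
            make_psm(f"t{i}", sequence=s, score=v)
            for i, (s, v) in enumerate(
                [("AAAAAAK", 10.0), ("CCCCCCK", 9.0), ("DDDDDDK", 8.0), ("EEEEEEK", 7.0)]
            )
        ] + [
            make_psm("d0", sequence="GGGGGGK", score=9.5, is_decoy=True),
            make_psm("d1", sequence="HHHHHHK", score=6.0, is_decoy=True),
        ]
        table = tdc_psm(psms, score=lambda p: p.hyperscore).table
        target_q = table.loc[~table.is_decoy, "q_value"]
        assert np.allclose(target_q, 0.5)

    def test_no_decoys_bounded_by_pseudocount(self):
        psms = [make_psm(f"s{i}", sequence=f"AAAAAA{aa}", score=float(i))
                for i, aa in enumerate("KRLMN")]
        q = tdc_psm(psms, score=lambda p: p.hyperscore).table.q_value
        assert np.allclose(q, 1 / 5)  # (0+1)/5 at the loosest cutoff

    def test_monotone_nonincreasing_in_score(self, rng):
        scores = rng.uniform(0, 10, 200)
        decoy = rng.random(200) < 0.5
        q = qvalues(scores, decoy)
        order = np.argsort(-scores)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_matches_oracle_random(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 40))
            scores = np.round(rng.uniform(0, 10, n), 1)
            decoy = rng.random(n) < 0.4
            assert np.allclose(qvalues(scores, decoy), oracle_qvalues(scores, decoy))


class TestCompetitionLevels:
    def test_psm_level_matches_oracle(self, rng):
        for _ in range(60):
            psms = random_psm_instance(rng)
            if not psms:
                continue
            # oracle: best per spectrum (ties -> decoy), then all-cutoffs q
            best = {}
            for i, p in enumerate(psms):
                key = p.spectrum_id
                cand = (p.hyperscore, p.is_decoy, p.peptide.sequence, i)
                if key not in best or cand > best[key]:
                    best[key] = cand
            idx = [v[3] for v in best.values()]
            expected = oracle_qvalues(
                [psms[i].hyperscore for i in idx], [psms[i].is_decoy for i in idx]
            )
            got = tdc_psm(psms, score=lambda p: p.hyperscore)
            lookup = dict(zip(got.table.id, got.table.q_value))
            for i, e in zip(idx, expected):
                assert lookup[psms[i].spectrum_id] == pytest.approx(e)

    def test_peptide_best_psm_aggregation(self):
        psms = [
            make_psm("s1", sequence="AAAAAAK", score=3.0),
            make_psm("s2", sequence="AAAAAAK", score=7.0),
        ]
        table = tdc_peptide(psms, score=lambda p: p.hyperscore).table
        assert len(table) == 1
        assert table.score.iloc[0] == 7.0

    def test_peptide_level_matches_oracle(self, rng):
        for _ in range(60):
            psms = random_psm_instance(rng)
            if not psms:
                continue
            best = {}
            for i, p in enumerate(psms):
                key = (p.is_decoy, p.peptide.key)
                cand = (p.hyperscore, i)
                if key not in best or cand > best[key]:
                    best[key] = cand
            idx = [v[1] for v in best.values()]
            expected = oracle_qvalues(
                [psms[i].hyperscore for i in idx], [psms[i].is_decoy for i in idx]
            )
            got = tdc_peptide(psms, score=lambda p: p.hyperscore)
            lookup = {
                (d, k): q
                for d, k, q in zip(got.table.is_decoy, got.table.id, got.table.q_value)
            }
            for i, e in zip(idx, expected):
                assert lookup[
                    (psms[i].is_decoy, psms[i].peptide_key)
                ] == pytest.approx(e)

    def test_interleaved_scores_give_high_q(self):
        # perfectly interleaved targets/decoys: decoys track targets closely
        psms = []
        for i in range(10):
            psms.append(make_psm(f"t{i}", sequence=f"AAAAA{'ACDEFGHILM'[i]}K",
                                 score=10.0 - i))
            psms.append(
                make_psm(f"d{i}", sequence=f"CCCCC{'ACDEFGHILM'[i]}K",
                         score=9.5 - i, is_decoy=True)
            )
        q = tdc_peptide(psms, score=lambda p: p.hyperscore).table.q_value
        assert q.min() >= 0.5

    def test_double_pair_picked_rule(self):
        target = Peptide("ACDEFGHIK")
        decoy = make_decoy(target)
        psms = [
            Psm("s1", target, 2, hyperscore=8.0),
            Psm("s2", decoy, 2, hyperscore=3.0),
        ]
        table = tdc_double(psms, score=lambda p: p.hyperscore).table
        assert len(table) == 1
        assert not table.is_decoy.iloc[0]
        assert table.score.iloc[0] == 8.0

    def test_double_all_decoys_win_no_targets_survive(self):
        psms = []
        for i, seq in enumerate(["ACDEFGHIK", "LMNPQRSTK", "VWYACDEFK"]):
            target = Peptide(seq)
            decoy = make_decoy(target)
            psms.append(Psm(f"t{i}", target, 2, hyperscore=1.0))
            psms.append(Psm(f"d{i}", decoy, 2, hyperscore=5.0))
        out = tdc_double(psms, score=lambda p: p.hyperscore)
        assert out.table.is_decoy.all()
        # targets did not survive the pair competition: q 1.0 assigned
        assert (out.q_of_psm[[0, 2, 4]] == 1.0).all()

    def test_double_null_controls_fdr(self):
        # exchangeable target/decoy scores: expected FDP at q<=0.05 small
        rng = np.random.default_rng(7)
        fdps = []
        alphabet = list("ACDEFGHILMNPQRSTVWY")
        for _ in range(50):
            psms = []
            for i in range(120):
                seq = "".join(rng.choice(alphabet, size=8)) + "K"
                target = Peptide(seq)
                decoy = make_decoy(target)
                if decoy.sequence == target.sequence:
                    continue
                psms.append(Psm(f"t{i}", target, 2, hyperscore=float(rng.normal())))
                psms.append(Psm(f"d{i}", decoy, 2, hyperscore=float(rng.normal())))
            out = tdc_double(psms, score=lambda p: p.hyperscore)
            accepted = out.table.query("~is_decoy and q_value <= 0.05")
            fdps.append(1.0 if len(accepted) else 0.0)  # every null hit is false
        assert np.mean(fdps) <= 0.08


class TestReporting:
    def _scored_psms(self):
        target = Peptide("ACDEFGHIK")
        psms = [
            Psm("s1", target, 2, hyperscore=9.0),
            Psm("s2", Peptide("LMNPQRSTK"), 2, hyperscore=5.0),
            Psm("s3", make_decoy(target), 2, hyperscore=2.0),
        ]
        return psms

    def test_threshold_and_decoy_removal(self, tmp_path):
        psms = self._scored_psms()
        qp = tdc_psm(psms, score=lambda p: p.hyperscore)
        qq = tdc_double(psms, score=lambda p: p.hyperscore)
        # force known q pattern
        qp.q_of_psm = np.array([0.005, 0.02, 0.005])
        qq.q_of_psm = np.array([0.005, 0.02, 0.005])
        out = filter_and_report(psms, qp, qq, alpha=0.01, out_dir=tmp_path)
        assert out["n_psms_accepted"] == 1
        df = out["psm_df"]
        assert df.peptide.tolist() == ["ACDEFGHIK"]
        assert (tmp_path / "results_psm.csv").exists()

    def test_jsonl_round_trip_exact(self, tmp_path):
        psms = self._scored_psms()
        psms[0].matched_ions = [("b", 2, 1, 150.0), ("y", 3, 1, 50.0)]
        psms[0].re_score = 1.25
        path = tmp_path / "psms.jsonl.gz"
        write_psms_jsonl(psms, np.zeros(3), np.zeros(3), path)
        back = read_psms_jsonl(path)
        assert len(back) == 3
        for a, b in zip(psms, back):
            assert a.spectrum_id == b.spectrum_id
            assert a.peptide == b.peptide
            assert a.hyperscore == b.hyperscore
            assert a.matched_ions == b.matched_ions

    def test_decoys_never_in_csv(self, tmp_path, rng):
        psms = random_psm_instance(rng, n_max=40)
        qp = tdc_psm(psms, score=lambda p: p.hyperscore)
        qq = tdc_peptide(psms, score=lambda p: p.hyperscore)
        out = filter_and_report(psms, qp, qq, alpha=1.0, out_dir=tmp_path)
        import pandas as pd

        df = pd.read_csv(tmp_path / "results_psm.csv") if len(out["psm_df"]) else None
        if df is not None:
            decoy_seqs = {p.peptide.sequence for p in psms if p.is_decoy} - {
                p.peptide.sequence for p in psms if not p.is_decoy
            }
            assert not df.peptide.isin(decoy_seqs).any()
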