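"""Target-decoy competition and q-value estimation.

Three competition levels are provided:

* **PSM level** — per spectrum, the single best-scoring candidate survives
  (target and decoy compete); q-values are computed over the survivors.
* **Peptide level** — the best PSM per peptide is retained first, then the
  same q-value machinery runs over peptides.
* **Double ("picked") competition** — each target peptide competes against
  its own reversal-generated decoy; only the higher-scoring member of the
  pair survives before q-value estimation.

Estimated FDR at score cutoff c is (D(c) + 1) / max(T(c), 1) over hits with
score >= c (the +1 pseudocount makes the estimator conservative);
q(s) = min over cutoffs c <= s of the estimated FDR, clipped to [0, 1].
Score ties between a target and a decoy always resolve in favor of the
decoy.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .chemistry import NTERM, Peptide
from .search import Psm

logger = logging.getLogger(__name__)


def default_score(psm: Psm) -> float:
    """Rescored value when available, hyperscore otherwise."""
    return psm.re_score if np.isfinite(psm.re_score) else psm.hyperscore


def qvalues(scores: np.ndarray, is_decoy: np.ndarray) -> np.ndarray:
    """q-values over competition survivors, aligned to the input order."""
    scores = np.asarray(scores, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    n = scores.size
    if n == 0:
        return np.empty(0)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    d = is_decoy[order]
    cum_decoys = np.cumsum(d)
    cum_targets = np.cumsum(~d)
    # at a cutoff equal to s[i], every hit tied at that score counts as >= c
    tie_end = np.empty(n, dtype=int)
    idx = n - 1
    for i in range(n - 1, -1, -1):
        if i == n - 1 or s[i] != s[i + 1]:
            idx = i
        tie_end[i] = idx
    fdr = (cum_decoys[tie_end] + 1) / np.maximum(cum_targets[tie_end], 1)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    out = np.empty(n)
    out[order] = q_sorted
    return out


@dataclass
class QValueTable:
    """Per-record q-values plus a map back to the input PSM list."""

    table: pd.DataFrame  # columns: id, score, is_decoy, q_value
    q_of_psm: np.ndarray  # aligned to the input PSMs; non-survivors get 1.0
    level: str = "psm"


def _competition_winner(group: list[tuple[int, float, bool, str]]) -> int:
    """Index of the winning record: best score; ties prefer the decoy."""
    return max(group, key=lambda t: (t[1], t[2], t[3]))[0]


def tdc_psm(
    psms: Sequence[Psm], score: Callable[[Psm], float] = default_score
) -> QValueTable:
    """PSM-level competition: one survivor per spectrum."""
    records: dict[str, list[tuple[int, float, bool, str]]] = {}
    for i, p in enumerate(psms):
        records.setdefault(p.spectrum_id, []).append(
            (i, score(p), p.is_decoy, p.peptide.sequence)
        )
    winners = [_competition_winner(g) for g in records.values()]
    w_scores = np.array([score(psms[i]) for i in winners])
    w_decoy = np.array([psms[i].is_decoy for i in winners])
    q = qvalues(w_scores, w_decoy)
    q_of_psm = np.ones(len(psms))
    for i, qi in zip(winners, q):
        q_of_psm[i] = qi
    table = pd.DataFrame(
        {
            "id": [psms[i].spectrum_id for i in winners],
            "peptide_key": [psms[i].peptide_key for i in winners],
            "score": w_scores,
            "is_decoy": w_decoy,
            "q_value": q,
        }
    )
    return QValueTable(table=table, q_of_psm=q_of_psm, level="psm")


def _best_psm_per_peptide(
    psms: Sequence[Psm],
    score: Callable[[Psm], float],
    modified_keys: bool = True,
) -> dict[str, int]:
    """Best-scoring PSM index per peptide key (decoys keyed separately)."""
    best: dict[str, int] = {}
    for i, p in enumerate(psms):
        key = p.peptide_key if modified_keys else p.peptide.sequence
        key = f"{'D' if p.is_decoy else 'T'}|{key}"
        cur = best.get(key)
        if cur is None or (score(p), not p.is_decoy, p.peptide.sequence) > (
            score(psms[cur]),
            not psms[cur].is_decoy,
            psms[cur].peptide.sequence,
        ):
            best[key] = i
    return best


def tdc_peptide(
    psms: Sequence[Psm],
    score: Callable[[Psm], float] = default_score,
    modified_keys: bool = True,
) -> QValueTable:
    """Peptide-level q-values: best PSM per peptide, then the q machinery.

    ``modified_keys`` treats modified sequences as distinct peptides; pass
    False to group by bare sequence.
    """
    best = _best_psm_per_peptide(psms, score, modified_keys)
    idx = sorted(best.values())
    p_scores = np.array([score(psms[i]) for i in idx])
    p_decoy = np.array([psms[i].is_decoy for i in idx])
    q = qvalues(p_scores, p_decoy)
    q_by_key = {}
    for i, qi in zip(idx, q):
        p = psms[i]
        key = p.peptide_key if modified_keys else p.peptide.sequence
        q_by_key[(p.is_decoy, key)] = qi
    q_of_psm = np.array(
        [
            q_by_key[
                (p.is_decoy, p.peptide_key if modified_keys else p.peptide.sequence)
            ]
            for p in psms
        ]
    )
    table = pd.DataFrame(
        {
            "id": [
                psms[i].peptide_key if modified_keys else psms[i].peptide.sequence
                for i in idx
            ],
            "score": p_scores,
            "is_decoy": p_decoy,
            "q_value": q,
        }
    )
    return QValueTable(table=table, q_of_psm=q_of_psm, level="peptide")


def decoy_source_peptide(p: Peptide) -> Peptide:
    """Invert reversal-with-fixed-C-terminus decoy generation."""
    n = len(p.sequence)
    source_seq = p.sequence[: n - 1][::-1] + p.sequence[-1]
    mods = []
    for pos, delta in p.mods:
        if pos == NTERM or int(pos) == n - 1:
            mods.append((pos, delta))
        else:
            mods.append((n - 2 - int(pos), delta))
    return Peptide(source_seq, mods=tuple(mods), is_decoy=False)


def tdc_double(
    psms: Sequence[Psm], score: Callable[[Psm], float] = default_score
) -> QValueTable:
    """Double ("picked") competition at peptide level.

    Each target peptide is paired with its own reversal decoy; within a
    pair only the higher-scoring member survives (ties prefer the decoy).
    Unpaired members survive alone. q-values run over the survivors.
    """
    best = _best_psm_per_peptide(psms, score, modified_keys=True)
    pairs: dict[str, dict[str, int]] = {}
    for key, i in best.items():
        p = psms[i]
        if p.is_decoy:
            source = decoy_source_peptide(p.peptide)
            if source.key == p.peptide.key:
                raise ValueError(
                    f"decoy {p.peptide.sequence} is its own source "
                    "(palindromic decoys must be excluded before search)"
                )
            pairs.setdefault(source.key, {})["decoy"] = i
        else:
            pairs.setdefault(p.peptide_key, {})["target"] = i
    survivors: list[int] = []
    for members in pairs.values():
        if len(members) == 1:
            survivors.append(next(iter(members.values())))
        else:
            t, d = members["target"], members["decoy"]
            survivors.append(d if score(psms[d]) >= score(psms[t]) else t)
    survivors.sort()
    s_scores = np.array([score(psms[i]) for i in survivors])
    s_decoy = np.array([psms[i].is_decoy for i in survivors])
    q = qvalues(s_scores, s_decoy)
    q_by_key = {
        (psms[i].is_decoy, psms[i].peptide_key): qi for i, qi in zip(survivors, q)
    }
    q_of_psm = np.array(
        [q_by_key.get((p.is_decoy, p.peptide_key), 1.0) for p in psms]
    )
    table = pd.DataFrame(
        {
            "id": [psms[i].peptide_key for i in survivors],
            "score": s_scores,
            "is_decoy": s_decoy,
            "q_value": q,
        }
    )
    return QValueTable(table=table, q_of_psm=q_of_psm, level="peptide_double")


def _psm_to_record(p: Psm, q_psm: float, q_peptide: float) -> dict:
    return {
        "spectrum_id": p.spectrum_id,
        "peptide": p.peptide.sequence,
        "mods": [[pos, delta] for pos, delta in p.peptide.mods],
        "protein_ids": list(p.peptide.protein_ids),
        "is_decoy": p.is_decoy,
        "charge": p.charge,
        "rank": p.rank,
        "hyperscore": p.hyperscore,
        "re_score": p.re_score,
        "delta_next": p.delta_next,
        "matched_b": p.matched_b,
        "matched_y": p.matched_y,
        "longest_b": p.longest_b,
        "longest_y": p.longest_y,
        "matched_intensity": p.matched_intensity,
        "matched_intensity_fraction": p.matched_intensity_fraction,
        "avg_ppm_error": p.avg_ppm_error,
        "precursor_ppm_error": p.precursor_ppm_error,
        "isotope_error": p.isotope_error,
        "retention_time": p.retention_time,
        "inv_ion_mobility": p.inv_ion_mobility,
        "collision_energy": p.collision_energy,
        "rt_predicted": p.rt_predicted,
        "im_predicted": p.im_predicted,
        "spectral_angle": p.spectral_angle,
        "cosine_similarity": p.cosine_similarity,
        "matched_ions": [[s, int(o), int(z), float(i)] for s, o, z, i in p.matched_ions],
        "q_psm": q_psm,
        "q_peptide": q_peptide,
    }


def _record_to_psm(rec: dict) -> Psm:
    peptide = Peptide(
        rec["peptide"],
        mods=tuple(
            (pos if pos == NTERM else int(pos), float(delta))
            for pos, delta in rec["mods"]
        ),
        protein_ids=tuple(rec["protein_ids"]),
        is_decoy=rec["is_decoy"],
    )
    psm = Psm(
        spectrum_id=rec["spectrum_id"],
        peptide=peptide,
        charge=rec["charge"],
        hyperscore=rec["hyperscore"],
        rank=rec["rank"],
        delta_next=rec["delta_next"],
        matched_b=rec["matched_b"],
        matched_y=rec["matched_y"],
        longest_b=rec["longest_b"],
        longest_y=rec["longest_y"],
        matched_intensity=rec["matched_intensity"],
        matched_intensity_fraction=rec["matched_intensity_fraction"],
        avg_ppm_error=rec["avg_ppm_error"],
        precursor_ppm_error=rec["precursor_ppm_error"],
        isotope_error=rec["isotope_error"],
        retention_time=rec["retention_time"],
        inv_ion_mobility=rec["inv_ion_mobility"],
        collision_energy=rec["collision_energy"],
        matched_ions=[(s, o, z, i) for s, o, z, i in rec["matched_ions"]],
        rt_predicted=rec["rt_predicted"],
        im_predicted=rec["im_predicted"],
        spectral_angle=rec["spectral_angle"],
        cosine_similarity=rec["cosine_similarity"],
        re_score=rec["re_score"],
    )
    psm.q_value = rec["q_psm"]
    return psm


def write_psms_jsonl(
    psms: Sequence[Psm],
    q_psm: np.ndarray,
    q_peptide: np.ndarray,
    path,
) -> None:
    """Serialize the full PSM set (with features) to gzipped JSON lines."""
    with gzip.open(path, "wt") as fh:
        for p, qp, qq in zip(psms, q_psm, q_peptide):
            fh.write(json.dumps(_psm_to_record(p, float(qp), float(qq))) + "\n")


def read_psms_jsonl(path) -> list[Psm]:
    with gzip.open(path, "rt") as fh:
        return [_record_to_psm(json.loads(line)) for line in fh if line.strip()]


def _mods_str(p: Peptide) -> str:
    return ";".join(f"{pos}:{delta:+.6f}" for pos, delta in p.mods)


def filter_and_report(
    psms: Sequence[Psm],
    q_psm_table: QValueTable,
    q_peptide_table: QValueTable,
    alpha: float = 0.01,
    out_dir=None,
    score: Callable[[Psm], float] = default_score,
) -> dict:
    """Write filtered CSV reports and the full serialized PSM set.

    ``results_psm.csv`` holds PSM-level survivors at q <= alpha,
    ``results_peptide.csv`` peptide-level survivors, decoys removed from
    both. ``psms.jsonl.gz`` keeps everything. Returns summary counts and
    paths.
    """
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    q_psm = q_psm_table.q_of_psm
    q_pep = q_peptide_table.q_of_psm

    def row(p: Psm, qp: float, qq: float) -> dict:
        return {
            "spectrum_id": p.spectrum_id,
            "peptide": p.peptide.sequence,
            "mods": _mods_str(p.peptide),
            "charge": p.charge,
            "score": p.hyperscore,
            "rescore": p.re_score,
            "q_psm": qp,
            "q_peptide": qq,
            "rt_obs": p.retention_time,
            "rt_pred": p.rt_predicted,
            "im_obs": p.inv_ion_mobility,
            "im_pred": p.im_predicted,
            "matched_b": p.matched_b,
            "matched_y": p.matched_y,
            "ppm_error": p.avg_ppm_error,
        }

    psm_rows = [
        row(p, q_psm[i], q_pep[i])
        for i, p in enumerate(psms)
        if not p.is_decoy and q_psm[i] <= alpha
    ]
    # peptide report: one row per surviving peptide at q <= alpha
    seen: set[str] = set()
    pep_rows = []
    for i, p in enumerate(psms):
        if p.is_decoy or q_pep[i] > alpha or p.peptide_key in seen:
            continue
        seen.add(p.peptide_key)
        pep_rows.append(row(p, q_psm[i], q_pep[i]))

    psm_df = pd.DataFrame(psm_rows)
    pep_df = pd.DataFrame(pep_rows)
    result = {
        "n_psms_total": len(psms),
        "n_psms_accepted": len(psm_rows),
        "n_peptides_accepted": len(pep_rows),
        "psm_df": psm_df,
        "peptide_df": pep_df,
    }
    if out_dir is not None:
        psm_path = out_dir / "results_psm.csv"
        pep_path = out_dir / "results_peptide.csv"
        jsonl_path = out_dir / "psms.jsonl.gz"
        psm_df.to_csv(psm_path, index=False)
        pep_df.to_csv(pep_path, index=False)
        write_psms_jsonl(psms, q_psm, q_pep, jsonl_path)
        result["paths"] = {
            "results_psm": str(psm_path),
            "results_peptide": str(pep_path),
            "psms_jsonl": str(jsonl_path),
        }
    logger.info(
        "FDR filter at alpha=%.3g: %d/%d PSMs, %d peptides",
        alpha,
        len(psm_rows),
        len(psms),
        len(pep_rows),
    )
    return result
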