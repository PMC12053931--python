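"""Peptide chemistry: masses, b/y fragments, isotope envelopes, digestion,
variable modifications, and decoy generation.

Modifications are mass deltas attached to a 0-based residue position or to
the peptide N-terminus (position ``"N-term"``). Fixed and variable mods use
Unimod-consistent monoisotopic deltas from :mod:`timsdda.constants`.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .constants import (
    ISOTOPE_ABUNDANCE,
    MOD_COMPOSITION,
    PROTON,
    RESIDUE_COMPOSITION,
    RESIDUE_MASS,
    VALID_RESIDUES,
    WATER,
)

logger = logging.getLogger(__name__)

NTERM = "N-term"


@dataclass(frozen=True)
class Peptide:
    """Peptide sequence with modifications and protein provenance."""

    sequence: str
    mods: tuple[tuple[object, float], ...] = ()
    protein_ids: tuple[str, ...] = ()
    is_decoy: bool = False

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("sequence must be nonempty")
        positions = [p for p, _ in self.mods]
        if len(positions) != len(set(positions)):
            raise ValueError("at most one modification per position")
        for p, delta in self.mods:
            if not np.isfinite(delta):
                raise ValueError("modification mass must be finite")
            if p != NTERM and not (0 <= int(p) < len(self.sequence)):
                raise ValueError(f"modification position {p} out of range")
        object.__setattr__(self, "mods", tuple(sorted(self.mods, key=_mod_sort_key)))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mod_dict(self) -> dict[object, float]:
        return dict(self.mods)

    @property
    def key(self) -> str:
        """Modified-sequence identity key (decoy status excluded)."""
        mods = ";".join(f"{p}:{delta:.6f}" for p, delta in self.mods)
        return f"{self.sequence}|{mods}"

    def missed_cleavages(self) -> int:
        """Number of internal tryptic sites (K/R not before P)."""
        return len(tryptic_sites(self.sequence))


def _mod_sort_key(item):
    p, _ = item
    return (-1, 0) if p == NTERM else (0, int(p))


@dataclass(frozen=True)
class FragmentIon:
    """A b- or y-series fragment ion."""

    series: str
    ordinal: int
    charge: int
    mz: float

    def __post_init__(self):
        if self.series not in ("b", "y"):
            raise ValueError("series must be 'b' or 'y'")
        if self.mz <= 0:
            raise ValueError("mz must be positive")


@dataclass(frozen=True)
class IsotopeDistribution:
    """Isotopologue probabilities indexed by neutron count from monoisotopic."""

    probabilities: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if np.any(p < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must sum to 1")


@dataclass(frozen=True)
class DigestConfig:
    mode: str = "tryptic"  # "tryptic" | "unspecific"
    missed_cleavages: int = 2
    min_len: int = 7
    max_len: int = 30

    def __post_init__(self):
        if self.mode not in ("tryptic", "unspecific"):
            raise ValueError("mode must be 'tryptic' or 'unspecific'")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")


def monoisotopic_mass(p: Peptide) -> float:
    """Neutral monoisotopic mass: residues + water + modification deltas."""
    mass = WATER
    for aa in p.sequence:
        try:
            mass += RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r}") from None
    mass += sum(delta for _, delta in p.mods)
    return mass


def fragment_mzs(p: Peptide, max_fragment_charge: int = 2) -> list[FragmentIon]:
    """All b_i / y_i ions, i in 1..len-1, charges 1..max_fragment_charge.

    N-terminal mods contribute to every b ion; a positional mod contributes
    to the fragments containing that residue.
    """
    n = len(p.sequence)
    if n < 2:
        return []
    residue = np.array([RESIDUE_MASS[aa] for aa in p.sequence])
    mod_at = np.zeros(n)
    nterm_delta = 0.0
    for pos, delta in p.mods:
        if pos == NTERM:
            nterm_delta += delta
        else:
            mod_at[int(pos)] += delta
    prefix = np.cumsum(residue + mod_at)
    total = prefix[-1]
    ions = []
    for i in range(1, n):
        b_neutral = prefix[i - 1] + nterm_delta
        y_neutral = total - prefix[n - i - 1] + WATER
        for z in range(1, max_fragment_charge + 1):
            ions.append(FragmentIon("b", i, z, (b_neutral + z * PROTON) / z))
            ions.append(FragmentIon("y", i, z, (y_neutral + z * PROTON) / z))
    return ions


def elemental_composition(p: Peptide) -> dict[str, int]:
    """Atom counts of the neutral peptide; known mods matched by mass delta."""
    comp = {"H": 2, "O": 1}  # water
    for aa in p.sequence:
        for e, c in RESIDUE_COMPOSITION[aa].items():
            comp[e] = comp.get(e, 0) + c
    for _, delta in p.mods:
        for known, mod_comp in MOD_COMPOSITION.items():
            if abs(delta - known) < 1e-3:
                for e, c in mod_comp.items():
                    comp[e] = comp.get(e, 0) + c
                break
        else:
            logger.warning(
                "no elemental composition for mod delta %.4f; "
                "ignored in isotope envelope",
                delta,
            )
    return comp


def _element_power(dist: np.ndarray, n: int, max_len: int) -> np.ndarray:
    """dist convolved with itself n times, truncated to max_len entries."""
    result = np.array([1.0])
    base = dist.copy()
    while n > 0:
        if n & 1:
            result = np.convolve(result, base)[:max_len]
        n >>= 1
        if n:
            base = np.convolve(base, base)[:max_len]
    return result


def isotope_distribution(p: Peptide, n_isotopes: int = 6) -> IsotopeDistribution:
    """Isotope envelope by convolving per-element natural abundances.

    Probabilities are indexed by neutron count above monoisotopic, truncated
    to ``n_isotopes`` entries and renormalized.
    """
    if n_isotopes < 1:
        raise ValueError("n_isotopes must be >= 1")
    comp = elemental_composition(p)
    max_len = n_isotopes + 4  # headroom before the final truncation
    envelope = np.array([1.0])
    for element, count in comp.items():
        envelope = np.convolve(
            envelope, _element_power(ISOTOPE_ABUNDANCE[element], count, max_len)
        )[:max_len]
    envelope = envelope[:n_isotopes]
    return IsotopeDistribution(envelope / envelope.sum())


def tryptic_sites(sequence: str) -> list[int]:
    """0-based indices i such that cleavage occurs after residue i."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(
    protein_sequence: str,
    cfg: DigestConfig,
    protein_id: str = "",
) -> list[Peptide]:
    """In-silico digest of one protein.

    Tryptic mode cleaves after K/R except before P, allowing up to
    ``cfg.missed_cleavages`` internal sites; unspecific mode emits every
    substring within the length bounds. Peptides containing non-standard
    letters are skipped with a warning.
    """
    if not protein_sequence:
        raise ValueError("protein sequence must be nonempty")
    seq = protein_sequence.upper().replace("*", "")
    candidates: set[str] = set()
    if cfg.mode == "tryptic":
        sites = tryptic_sites(seq)
        bounds = [0] + [s + 1 for s in sites] + [len(seq)]
        for i in range(len(bounds) - 1):
            for j in range(i + 1, min(i + 2 + cfg.missed_cleavages, len(bounds))):
                candidates.add(seq[bounds[i] : bounds[j]])
    else:
        for length in range(cfg.min_len, cfg.max_len + 1):
            for start in range(0, len(seq) - length + 1):
                candidates.add(seq[start : start + length])
    peptides = []
    skipped = 0
    for pep in candidates:
        if not (cfg.min_len <= len(pep) <= cfg.max_len):
            continue
        if not set(pep) <= VALID_RESIDUES:
            skipped += 1
            continue
        peptides.append(Peptide(pep, protein_ids=(protein_id,) if protein_id else ()))
    if skipped:
        logger.warning(
            "skipped %d peptides with non-standard residues in %s",
            skipped,
            protein_id or "<unnamed>",
        )
    return sorted(peptides, key=lambda p: p.sequence)


def digest_fasta(
    records: Iterable[tuple[str, str]], cfg: DigestConfig
) -> list[Peptide]:
    """Digest many proteins, deduplicating sequences and merging protein ids."""
    by_seq: dict[str, set[str]] = {}
    for protein_id, seq in records:
        for pep in digest(seq, cfg, protein_id=protein_id):
            by_seq.setdefault(pep.sequence, set()).update(pep.protein_ids)
    return [
        Peptide(seq, protein_ids=tuple(sorted(ids)))
        for seq, ids in sorted(by_seq.items())
    ]


def apply_fixed_mods(
    p: Peptide, fixed_mods: Mapping[str, float] | None = None
) -> Peptide:
    """Apply fixed mods (residue letter or ``"N-term"`` -> delta) everywhere."""
    if not fixed_mods:
        return p
    mods = list(p.mods)
    taken = {pos for pos, _ in mods}
    for target, delta in fixed_mods.items():
        if target == NTERM:
            if NTERM not in taken:
                mods.append((NTERM, delta))
        else:
            for i, aa in enumerate(p.sequence):
                if aa == target and i not in taken:
                    mods.append((i, delta))
    return replace(p, mods=tuple(mods))


def apply_variable_mods(
    p: Peptide,
    variable_mods: Sequence[tuple[str, float]],
    max_mods: int = 3,
) -> list[Peptide]:
    """Expand a peptide into all variants with 0..max_mods variable mods.

    ``variable_mods`` entries are (residue letter or ``"N-term"``, delta).
    Positions already carrying a (fixed) mod are not eligible. The unmodified
    input is always included, as the first element.
    """
    if max_mods < 0:
        raise ValueError("max_mods must be >= 0")
    taken = {pos for pos, _ in p.mods}
    sites: list[tuple[object, float]] = []
    for target, delta in variable_mods:
        if target == NTERM:
            if NTERM not in taken:
                sites.append((NTERM, delta))
        else:
            for i, aa in enumerate(p.sequence):
                if aa == target and i not in taken:
                    sites.append((i, delta))
    variants = [p]
    for k in range(1, max_mods + 1):
        for combo in itertools.combinations(sites, k):
            positions = [pos for pos, _ in combo]
            if len(positions) != len(set(positions)):
                continue
            variants.append(replace(p, mods=p.mods + tuple(combo)))
    return variants


def make_decoy(p: Peptide) -> Peptide:
    """Decoy by sequence reversal keeping the C-terminal residue fixed.

    Positional mods travel with their residues; N-terminal mods stay on the
    new N-terminus. Mass is invariant under this permutation.
    """
    n = len(p.sequence)
    body = p.sequence[: n - 1][::-1]
    decoy_seq = body + p.sequence[-1]
    new_mods = []
    for pos, delta in p.mods:
        if pos == NTERM or int(pos) == n - 1:
            new_mods.append((pos, delta))
        else:
            new_mods.append((n - 2 - int(pos), delta))
    return Peptide(
        decoy_seq,
        mods=tuple(new_mods),
        protein_ids=tuple(f"DECOY_{pid}" for pid in p.protein_ids),
        is_decoy=True,
    )


def generate_decoys(targets: Sequence[Peptide]) -> list[Peptide]:
    """Pairwise decoys; decoys colliding with any target sequence are dropped."""
    target_seqs = {t.sequence for t in targets}
    decoys = []
    for t in targets:
        d = make_decoy(t)
        if d.sequence in target_seqs:
            continue
        decoys.append(d)
    return decoys


_FASTA_HEADER = re.compile(r"^(\S+)")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a multi-FASTA; id is the header token before the first whitespace.

    Sequences are uppercased and '*' stripped; residue validation happens at
    digestion time.
    """
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _FASTA_HEADER.match(rec.description)
        pid = m.group(1) if m else rec.id
        records.append((pid, str(rec.seq).upper().replace("*", "")))
    return records
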