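"""MGF input/output in the project dialect.

Standard Mascot Generic Format headers (TITLE, PEPMASS, CHARGE, RTINSECONDS)
plus project extensions carrying the DDA-PASEF metadata the timsTOF reports
per precursor: ION_MOBILITY (1/K0), PRECURSOR_ID (for refragmentation
grouping), COLLISION_ENERGY, ISOLATION_WINDOW and SCAN_WINDOW.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .search import PrecursorEvent, ProcessedSpectrum


def spectra_to_mgf(spectra: Sequence[ProcessedSpectrum]) -> str:
    lines: list[str] = []
    for s in spectra:
        p = s.precursor
        lines.append("BEGIN IONS")
        lines.append(f"TITLE={s.spectrum_id}")
        lines.append(f"PEPMASS={p.mz:.6f} {p.intensity:.1f}")
        if p.charge is not None:
            lines.append(f"CHARGE={p.charge}+")
        lines.append(f"RTINSECONDS={p.retention_time:.3f}")
        lines.append(f"ION_MOBILITY={p.inv_ion_mobility:.5f}")
        lines.append(f"PRECURSOR_ID={p.precursor_id}")
        lines.append(f"COLLISION_ENERGY={p.collision_energy:.3f}")
        lines.append(
            f"ISOLATION_WINDOW={p.isolation_window[0]:.4f},{p.isolation_window[1]:.4f}"
        )
        lines.append(
            f"SCAN_WINDOW={p.scan_window[0]:.4f},{p.scan_window[1]:.4f}"
        )
        for mz, inten in zip(s.mz, s.intensity):
            lines.append(f"{mz:.6f} {inten:.4f}")
        lines.append("END IONS")
    return "\n".join(lines) + "\n"


def write_mgf(spectra: Sequence[ProcessedSpectrum], path) -> None:
    with open(path, "w") as fh:
        fh.write(spectra_to_mgf(spectra))


def _parse_window(value: str) -> tuple[float, float]:
    lo, hi = value.split(",")
    return float(lo), float(hi)


def parse_mgf(text: str) -> list[ProcessedSpectrum]:
    spectra: list[ProcessedSpectrum] = []
    headers: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    in_block = False
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "BEGIN IONS":
            in_block, headers, peaks = True, {}, []
        elif line == "END IONS":
            spectra.append(_finish_block(headers, peaks))
            in_block = False
        elif in_block:
            if "=" in line and not line[0].isdigit():
                key, value = line.split("=", 1)
                headers[key.upper()] = value.strip()
            else:
                parts = line.split()
                peaks.append((float(parts[0]), float(parts[1])))
    return spectra


def _finish_block(headers: dict[str, str], peaks) -> ProcessedSpectrum:
    pepmass = headers.get("PEPMASS", "0 0").split()
    charge_str = headers.get("CHARGE")
    charge = int(charge_str.rstrip("+-")) if charge_str else None
    precursor = PrecursorEvent(
        precursor_id=int(headers.get("PRECURSOR_ID", -1)),
        mz=float(pepmass[0]),
        charge=charge,
        retention_time=float(headers.get("RTINSECONDS", 0.0)),
        inv_ion_mobility=float(headers.get("ION_MOBILITY", 0.0)),
        isolation_window=_parse_window(headers["ISOLATION_WINDOW"])
        if "ISOLATION_WINDOW" in headers
        else (0.0, 0.0),
        scan_window=_parse_window(headers["SCAN_WINDOW"])
        if "SCAN_WINDOW" in headers
        else (0.0, 0.0),
        intensity=float(pepmass[1]) if len(pepmass) > 1 else 0.0,
        collision_energy=float(headers.get("COLLISION_ENERGY", 30.0)),
    )
    mz = np.array([m for m, _ in peaks])
    intensity = np.array([i for _, i in peaks])
    return ProcessedSpectrum(
        spectrum_id=headers.get("TITLE", f"precursor_{precursor.precursor_id}"),
        precursor=precursor,
        mz=mz,
        intensity=intensity,
    )


def read_mgf(path) -> list[ProcessedSpectrum]:
    with open(path) as fh:
        return parse_mgf(fh.read())


def group_by_precursor(
    spectra: Iterable[ProcessedSpectrum],
) -> dict[int, list[ProcessedSpectrum]]:
    groups: dict[int, list[ProcessedSpectrum]] = {}
    for s in spectra:
        groups.setdefault(s.precursor.precursor_id, []).append(s)
    return groups
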