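"""In-memory model of timsTOF frames, mobility-resolved spectra, and slices.

A *frame* is one retention-time point of acquisition holding peaks across the
ion-mobility scan dimension; decomposing a frame by scan number yields the
individual mobility-resolved mass spectra. Frames can be filtered, binned,
vectorized, summed on a rounded m/z grid, and scaled — the operator set needed
to aggregate refragmented DDA-PASEF spectra.

All m/z values are in Thomson, retention times in seconds, and ion mobility as
reduced inverse mobility 1/K0 in Vs/cm².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


def _round_half_even(values: np.ndarray, decimals: int) -> np.ndarray:
    # np.round implements round-half-to-even, which is the grid rule here.
    return np.round(values, decimals)


@dataclass(frozen=True)
class TimsSpectrum:
    """Single mobility-resolved mass spectrum (one scan of one frame)."""

    frame_id: int
    scan: int
    retention_time: float
    inv_ion_mobility: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)
        if mz.shape != intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if mz.size > 1 and not np.all(np.diff(mz) > 0):
            raise ValueError("mz must be strictly increasing")
        if np.any(intensity < 0):
            raise ValueError("intensity must be nonnegative")
        if self.scan < 0:
            raise ValueError("scan must be >= 0")

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass
class TimsFrame:
    """One retention-time point: parallel peak arrays across scans.

    Rows are kept sorted by (scan, mz); a scan maps to exactly one inverse
    ion mobility value.
    """

    frame_id: int
    retention_time: float
    scan: np.ndarray
    inv_ion_mobility: np.ndarray
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.scan = np.asarray(self.scan, dtype=np.int64)
        self.inv_ion_mobility = np.asarray(self.inv_ion_mobility, dtype=float)
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        n = self.scan.size
        for name in ("inv_ion_mobility", "mz", "intensity"):
            if getattr(self, name).size != n:
                raise ValueError("parallel arrays must have equal length")
        order = np.lexsort((self.mz, self.scan))
        if not np.array_equal(order, np.arange(n)):
            self.scan = self.scan[order]
            self.inv_ion_mobility = self.inv_ion_mobility[order]
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        self._check_scan_mobility_function()

    def _check_scan_mobility_function(self):
        if self.scan.size == 0:
            return
        df = pd.DataFrame({"scan": self.scan, "im": self.inv_ion_mobility})
        if (df.groupby("scan")["im"].nunique() > 1).any():
            raise ValueError("scan -> inv_ion_mobility mapping must be a function")

    def __len__(self) -> int:
        return int(self.scan.size)

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())

    def scan_mobility_map(self) -> dict[int, float]:
        return dict(zip(self.scan.tolist(), self.inv_ion_mobility.tolist()))


@dataclass
class TimsSlice:
    """Ordered collection of frames covering a retention-time window."""

    frames: list[TimsFrame] = field(default_factory=list)

    def __post_init__(self):
        rts = [f.retention_time for f in self.frames]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("frame retention times must be nondecreasing")

    def __len__(self) -> int:
        return len(self.frames)


def filter_frame(
    frame: TimsFrame,
    mz_range: tuple[float | None, float | None] = (None, None),
    scan_range: tuple[int | None, int | None] = (None, None),
    intensity_min: float | None = None,
) -> TimsFrame:
    """Select peaks inside closed bounds; any bound may be None (open)."""
    for lo, hi in (mz_range, scan_range):
        if lo is not None and hi is not None and lo > hi:
            raise ValueError("inverted range: min > max")
    mask = np.ones(len(frame), dtype=bool)
    lo, hi = mz_range
    if lo is not None:
        mask &= frame.mz >= lo
    if hi is not None:
        mask &= frame.mz <= hi
    lo, hi = scan_range
    if lo is not None:
        mask &= frame.scan >= lo
    if hi is not None:
        mask &= frame.scan <= hi
    if intensity_min is not None:
        mask &= frame.intensity >= intensity_min
    return TimsFrame(
        frame_id=frame.frame_id,
        retention_time=frame.retention_time,
        scan=frame.scan[mask],
        inv_ion_mobility=frame.inv_ion_mobility[mask],
        mz=frame.mz[mask],
        intensity=frame.intensity[mask],
    )


def frame_to_spectra(frame: TimsFrame) -> list[TimsSpectrum]:
    """Decompose a frame into one TimsSpectrum per distinct scan."""
    spectra: list[TimsSpectrum] = []
    if len(frame) == 0:
        return spectra
    scans, starts = np.unique(frame.scan, return_index=True)
    bounds = list(starts) + [len(frame)]
    for i, scan in enumerate(scans):
        sl = slice(bounds[i], bounds[i + 1])
        spectra.append(
            TimsSpectrum(
                frame_id=frame.frame_id,
                scan=int(scan),
                retention_time=frame.retention_time,
                inv_ion_mobility=float(frame.inv_ion_mobility[sl][0]),
                mz=frame.mz[sl],
                intensity=frame.intensity[sl],
            )
        )
    return spectra


def spectra_to_frame(spectra: Sequence[TimsSpectrum]) -> TimsFrame:
    """Inverse of :func:`frame_to_spectra` (spectra must share a frame)."""
    if not spectra:
        raise ValueError("need at least one spectrum")
    frame_ids = {s.frame_id for s in spectra}
    if len(frame_ids) > 1:
        raise ValueError("spectra belong to different frames")
    return TimsFrame(
        frame_id=spectra[0].frame_id,
        retention_time=spectra[0].retention_time,
        scan=np.concatenate([np.full(len(s), s.scan) for s in spectra]),
        inv_ion_mobility=np.concatenate(
            [np.full(len(s), s.inv_ion_mobility) for s in spectra]
        ),
        mz=np.concatenate([s.mz for s in spectra]),
        intensity=np.concatenate([s.intensity for s in spectra]),
    )


def _collapse_grid(
    scan: np.ndarray,
    im: np.ndarray,
    mz: np.ndarray,
    intensity: np.ndarray,
    resolution: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    mz_r = _round_half_even(mz, resolution)
    df = pd.DataFrame({"scan": scan, "im": im, "mz": mz_r, "intensity": intensity})
    grouped = (
        df.groupby(["scan", "mz"], sort=True)
        .agg(im=("im", "first"), intensity=("intensity", "sum"))
        .reset_index()
    )
    return (
        grouped["scan"].to_numpy(),
        grouped["im"].to_numpy(),
        grouped["mz"].to_numpy(),
        grouped["intensity"].to_numpy(),
    )


def add_frames(a: TimsFrame, b: TimsFrame, resolution: int = 2) -> TimsFrame:
    """Sum two frames on the rounded m/z grid.

    Peaks sharing (scan, rounded m/z) merge with summed intensity. The two
    frames must agree on the scan -> mobility mapping; retention time and
    frame id are taken from ``a``.
    """
    map_a, map_b = a.scan_mobility_map(), b.scan_mobility_map()
    for scan, im in map_b.items():
        if scan in map_a and not np.isclose(map_a[scan], im):
            raise ValueError(f"conflicting ion mobility for scan {scan}")
    scan, im, mz, intensity = _collapse_grid(
        np.concatenate([a.scan, b.scan]),
        np.concatenate([a.inv_ion_mobility, b.inv_ion_mobility]),
        np.concatenate([a.mz, b.mz]),
        np.concatenate([a.intensity, b.intensity]),
        resolution,
    )
    return TimsFrame(a.frame_id, a.retention_time, scan, im, mz, intensity)


def scale_frame(frame: TimsFrame, factor: float) -> TimsFrame:
    """Multiply all intensities by a nonnegative scalar; zeros are kept."""
    if factor < 0:
        raise ValueError("scale factor must be nonnegative")
    return TimsFrame(
        frame.frame_id,
        frame.retention_time,
        frame.scan.copy(),
        frame.inv_ion_mobility.copy(),
        frame.mz.copy(),
        frame.intensity * factor,
    )


def prune_zero_intensity(frame: TimsFrame) -> TimsFrame:
    """Drop zero-intensity peaks (separate from scaling, which keeps them)."""
    mask = frame.intensity > 0
    return TimsFrame(
        frame.frame_id,
        frame.retention_time,
        frame.scan[mask],
        frame.inv_ion_mobility[mask],
        frame.mz[mask],
        frame.intensity[mask],
    )


def vectorize_frame(frame: TimsFrame, resolution: int = 1) -> dict[int, float]:
    """Bin a frame onto an integer m/z grid.

    Index = round(mz * 10^resolution) with round-half-to-even; co-indexed
    intensities sum, so total intensity is conserved exactly.
    """
    if resolution < 0:
        raise ValueError("resolution must be >= 0")
    if len(frame) == 0:
        return {}
    idx = np.round(frame.mz * 10**resolution).astype(np.int64)
    keys, inv = np.unique(idx, return_inverse=True)
    sums = np.bincount(inv, weights=frame.intensity)
    return dict(zip(keys.tolist(), sums.tolist()))


def frames_to_tsv(frames: Iterable[TimsFrame], path) -> None:
    """Serialize frames to the tabular text format (TSV, one row per peak)."""
    rows = []
    for f in frames:
        rows.append(
            pd.DataFrame(
                {
                    "frame_id": f.frame_id,
                    "retention_time": f.retention_time,
                    "scan": f.scan,
                    "inv_ion_mobility": f.inv_ion_mobility,
                    "mz": f.mz,
                    "intensity": f.intensity,
                }
            )
        )
    df = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=[
                "frame_id",
                "retention_time",
                "scan",
                "inv_ion_mobility",
                "mz",
                "intensity",
            ]
        )
    )
    df.to_csv(path, sep="\t", index=False)


def frames_from_tsv(path) -> list[TimsFrame]:
    """Read frames back from the TSV format written by :func:`frames_to_tsv`."""
    df = pd.read_csv(path, sep="\t")
    frames = []
    for frame_id, g in df.groupby("frame_id", sort=True):
        frames.append(
            TimsFrame(
                frame_id=int(frame_id),
                retention_time=float(g["retention_time"].iloc[0]),
                scan=g["scan"].to_numpy(),
                inv_ion_mobility=g["inv_ion_mobility"].to_numpy(),
                mz=g["mz"].to_numpy(),
                intensity=g["intensity"].to_numpy(),
            )
        )
    return frames
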