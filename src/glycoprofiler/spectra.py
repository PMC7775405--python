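"""MS spectra containers, MGF I/O, extracted ion chromatograms and peak areas.

MS2 spectra travel as MGF (the minimal Mascot dialect: TITLE, PEPMASS, CHARGE,
RTINSECONDS, SCANS, plus a RAWFILE annotation carrying the raw-file name used
for joins); MS1 runs are centroided scan tables (scan, rt_s, mz, intensity)
in TSV. Retention times are seconds throughout; integration windows are
half-open in real time, evaluated on the piecewise-linear trace so that areas
are exactly additive over adjacent windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

__all__ = [
    "Ms2Spectrum",
    "Ms1Run",
    "Eic",
    "read_mgf",
    "write_mgf",
    "read_ms1_tsv",
    "write_ms1_tsv",
    "extract_eic",
    "integrate_area",
    "peak_window",
]


@dataclass
class Ms2Spectrum:
    """A centroided MS2 spectrum with its precursor metadata."""

    raw_file: str
    scan: int
    rt: float  # seconds
    precursor_mz: float
    precursor_charge: int | None = None
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))
    title: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative peak intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def has_peak_near(self, target_mz: float, tol_da: float) -> bool:
        return bool(np.any(np.abs(self.mz - target_mz) <= tol_da))


@dataclass
class Ms1Run:
    """An MS1 run: strictly increasing scan times with centroided peaks."""

    raw_file: str
    rts: np.ndarray
    peaks: list[tuple[np.ndarray, np.ndarray]]  # per scan: (mz, intensity)
    scan_numbers: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rts = np.asarray(self.rts, dtype=float)
        if len(self.rts) != len(self.peaks):
            raise ValueError("one peak list per scan required")
        if len(self.rts) and np.any(np.diff(self.rts) <= 0):
            raise ValueError("retention times must be strictly increasing")
        if self.scan_numbers is None:
            self.scan_numbers = np.arange(1, len(self.rts) + 1)

    @property
    def rt_span(self) -> tuple[float, float]:
        return float(self.rts[0]), float(self.rts[-1])


@dataclass
class Eic:
    """Extracted ion chromatogram: one summed-intensity point per MS1 scan."""

    target_mz: float
    tolerance_da: float
    rts: np.ndarray
    intensities: np.ndarray


def _spectrum_params(spectrum: Ms2Spectrum) -> dict:
    params = {
        "TITLE": spectrum.title
        or f"{spectrum.raw_file} scan={spectrum.scan}",
        "RAWFILE": spectrum.raw_file,
        "PEPMASS": spectrum.precursor_mz,
        "RTINSECONDS": spectrum.rt,
        "SCANS": spectrum.scan,
    }
    if spectrum.precursor_charge is not None:
        params["CHARGE"] = f"{spectrum.precursor_charge}+"
    return params


def write_mgf(spectra: list[Ms2Spectrum], path: str | Path) -> None:
    """Write spectra as Mascot-dialect MGF; inverse of :func:`read_mgf`."""
    entries = [
        {
            "m/z array": s.mz,
            "intensity array": s.intensity,
            "params": _spectrum_params(s),
        }
        for s in spectra
    ]
    with open(path, "w") as handle:
        _mgf.write(entries, handle)


def read_mgf(path: str | Path) -> list[Ms2Spectrum]:
    """Parse BEGIN IONS blocks; unknown headers are ignored as annotations.

    Missing CHARGE leaves the precursor charge unknown; missing RTINSECONDS
    defaults to 0. A malformed block raises naming the block index.
    """
    spectra: list[Ms2Spectrum] = []
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        for index, entry in enumerate(reader):
            params = entry.get("params", {})
            try:
                pepmass = params["pepmass"]
                precursor_mz = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
                charge_field = params.get("charge")
                charge = int(charge_field[0]) if charge_field else None
                raw_file = str(params.get("rawfile", params.get("title", ""))).split()[0]
                spectra.append(
                    Ms2Spectrum(
                        raw_file=raw_file,
                        scan=int(params.get("scans", index)),
                        rt=float(params.get("rtinseconds", 0.0)),
                        precursor_mz=precursor_mz,
                        precursor_charge=charge,
                        mz=entry["m/z array"],
                        intensity=entry["intensity array"],
                        title=str(params.get("title", "")),
                    )
                )
            except (KeyError, ValueError, IndexError) as exc:
                raise ValueError(f"malformed MGF block #{index}: {exc}") from exc
    seen: dict[tuple[str, int], int] = {}
    for s in spectra:
        key = (s.raw_file, s.scan)
        if key in seen:
            raise ValueError(f"duplicate scan number {s.scan} in raw file {s.raw_file!r}")
        seen[key] = 1
    return spectra


def write_ms1_tsv(run: Ms1Run, path: str | Path) -> None:
    """Long-format TSV: scan, rt_s, mz, intensity (one row per centroid)."""
    rows = []
    for scan, rt, (mz, inten) in zip(run.scan_numbers, run.rts, run.peaks):
        for m, i in zip(mz, inten):
            rows.append((scan, rt, m, i))
    pd.DataFrame(rows, columns=["scan", "rt_s", "mz", "intensity"]).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )


def read_ms1_tsv(path: str | Path, raw_file: str | None = None) -> Ms1Run:
    df = pd.read_csv(path, sep="\t")
    required = {"scan", "rt_s", "mz", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"MS1 TSV must have columns {sorted(required)}")
    rts, peaks, scans = [], [], []
    for (scan, rt), grp in df.groupby(["scan", "rt_s"], sort=True):
        scans.append(int(scan))
        rts.append(float(rt))
        peaks.append((grp["mz"].to_numpy(), grp["intensity"].to_numpy()))
    return Ms1Run(
        raw_file=raw_file or Path(path).stem,
        rts=np.asarray(rts),
        peaks=peaks,
        scan_numbers=np.asarray(scans),
    )


def extract_eic(
    run: Ms1Run,
    target_mz: float,
    tolerance_da: float | None = None,
    tolerance_ppm: float | None = None,
) -> Eic:
    """Per-scan summed intensity of centroids within |m/z - target| <= tol.

    Exactly one of ``tolerance_da`` / ``tolerance_ppm`` must be given; scans
    with no matching centroid contribute 0, so the trace covers the full run.
    """
    if (tolerance_da is None) == (tolerance_ppm is None):
        raise ValueError("give exactly one of tolerance_da or tolerance_ppm")
    tol = tolerance_da if tolerance_da is not None else target_mz * tolerance_ppm * 1e-6
    if tol <= 0:
        raise ValueError("tolerance must be > 0")
    if len(run.rts) == 0:
        raise ValueError("empty MS1 run")
    trace = np.zeros(len(run.rts))
    for i, (mz, inten) in enumerate(run.peaks):
        if len(mz):
            mask = np.abs(np.asarray(mz) - target_mz) <= tol
            if mask.any():
                trace[i] = float(np.sum(np.asarray(inten)[mask]))
    return Eic(target_mz, tol, run.rts.copy(), trace)


def integrate_area(eic: Eic, rt_start: float, rt_end: float) -> float:
    """Trapezoidal area (intensity * seconds) of the trace over [start, end).

    The piecewise-linear trace is clipped at the window bounds by linear
    interpolation, which makes areas additive over adjacent windows; the
    baseline is 0 and points outside the trace span contribute nothing.
    """
    if rt_end <= rt_start:
        raise ValueError("empty integration window")
    rts, ys = eic.rts, eic.intensities
    lo = max(rt_start, float(rts[0]))
    hi = min(rt_end, float(rts[-1]))
    if hi <= lo:
        return 0.0
    inner = (rts > lo) & (rts < hi)
    xs = np.concatenate(([lo], rts[inner], [hi]))
    vals = np.interp(xs, rts, ys)
    return float(np.trapezoid(vals, xs))


def peak_window(
    eic: Eic,
    around_rt: float | None = None,
    search_halfwidth: float = 30.0,
    threshold_fraction: float = 0.05,
) -> tuple[float, float]:
    """Automatic integration bounds for a chromatographic peak.

    The apex is the trace maximum (restricted to +-``search_halfwidth`` s of
    ``around_rt`` when given); the window is the contiguous region around it
    where intensity >= ``threshold_fraction`` of the apex intensity. The 5%
    rule is this package's convention for undocumented integration bounds.
    """
    rts, ys = eic.rts, eic.intensities
    if around_rt is None:
        apex = int(np.argmax(ys))
    else:
        mask = np.abs(rts - around_rt) <= search_halfwidth
        if not mask.any():
            raise ValueError("no trace points near requested retention time")
        idx = np.flatnonzero(mask)
        apex = int(idx[np.argmax(ys[idx])])
    if ys[apex] <= 0:
        raise ValueError("no signal at requested peak location")
    cut = threshold_fraction * ys[apex]
    left = apex
    while left > 0 and ys[left - 1] >= cut:
        left -= 1
    right = apex
    while right < len(ys) - 1 and ys[right + 1] >= cut:
        right += 1
    return float(rts[left]), float(rts[right])
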