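"""CSV / JSON dialects used across the package.

Traces: ``time,absorbance`` (minutes, mAU), header row mandatory.
Full DAD runs: long-form ``time,wavelength,absorbance``.
Peak tables: ``label,apex_time,start,end,height,area,snr``.
Spectra: ``wavelength,absorbance``.
Ground truth sidecar: JSON.
All floats are written at full precision (repr).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .identify import SpectrumUV
from .signal import Chromatogram, PeakRecord
from .simulate import SimulatedRun


def write_trace_csv(chrom: Chromatogram, path: str | Path) -> None:
    pd.DataFrame({"time": chrom.time, "absorbance": chrom.absorbance}).to_csv(
        path, index=False
    )


def read_trace_csv(path: str | Path, wavelength: float | None = None) -> Chromatogram:
    df = pd.read_csv(path)
    for col in ("time", "absorbance"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    t = df["time"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise ValueError(f"{path}: time not strictly increasing at row {int(bad[0]) + 2}")
    return Chromatogram(
        time=t,
        absorbance=df["absorbance"].to_numpy(dtype=float),
        wavelength=wavelength,
        meta={"source": str(path)},
    )


def write_run_long_csv(run: SimulatedRun, path: str | Path) -> None:
    t = run.time
    wl = run.wavelengths
    df = pd.DataFrame(
        {
            "time": np.repeat(t, wl.size),
            "wavelength": np.tile(wl, t.size),
            "absorbance": run.dad_matrix.ravel(),
        }
    )
    df.to_csv(path, index=False)


def write_ground_truth(run: SimulatedRun, path: str | Path) -> None:
    payload = {
        "seed": run.config.seed,
        "warnings": run.warnings,
        "peaks": {
            name: {
                "concentration": p.concentration,
                "apex_time": p.apex_time,
                "area": p.area,
                "nominal_area": p.nominal_area,
            }
            for name, p in run.ground_truth.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_peaks_csv(peaks: list[PeakRecord], path: str | Path) -> None:
    rows = [
        {
            "label": p.label or "",
            "apex_time": p.apex_time,
            "start": p.start_time,
            "end": p.end_time,
            "height": p.height,
            "area": p.area,
            "snr": p.snr,
        }
        for p in peaks
    ]
    pd.DataFrame(rows, columns=["label", "apex_time", "start", "end", "height", "area", "snr"]).to_csv(
        path, index=False
    )


def write_spectrum_csv(spec: SpectrumUV, path: str | Path) -> None:
    pd.DataFrame({"wavelength": spec.wavelength, "absorbance": spec.absorbance}).to_csv(
        path, index=False
    )


def read_spectrum_csv(path: str | Path, analyte: str | None = None) -> SpectrumUV:
    df = pd.read_csv(path)
    return SpectrumUV(
        wavelength=df["wavelength"].to_numpy(dtype=float),
        absorbance=df["absorbance"].to_numpy(dtype=float),
        analyte=analyte,
    )
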