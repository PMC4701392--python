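"""CSV readers/writers for spectra, denaturation curves and turbidity traces.

All files are plain CSV with ``#key=value`` metadata header lines followed by
a column header row, e.g.::

    #probe=trp
    #denaturant=urea
    #conc_M=1.5
    #excitation_nm=295
    wavelength_nm,intensity
    300.0,0.0123
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .aggregation import AggregationTrace
from .spectra import Condition, DenaturationCurve, EmissionSpectrum

__all__ = [
    "read_spectrum_csv", "write_spectrum_csv",
    "read_curve_csv", "write_curve_csv",
    "read_trace_csv", "write_trace_csv",
    "write_track_csv",
]

PathLike = Union[str, Path]


def _read_with_meta(path: PathLike):
    path = Path(path)
    meta = {}
    skip = 0
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                skip += 1
                if "=" in line:
                    key, _, val = line[1:].strip().partition("=")
                    meta[key.strip()] = val.strip()
            else:
                break
    df = pd.read_csv(path, skiprows=skip)
    return meta, df


def _write_with_meta(path: PathLike, meta: dict, df: pd.DataFrame) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for key, val in meta.items():
            fh.write(f"#{key}={val}\n")
        df.to_csv(fh, index=False)


def read_spectrum_csv(path: PathLike) -> EmissionSpectrum:
    """Read one emission spectrum (wavelength_nm, intensity columns)."""
    meta, df = _read_with_meta(path)
    cond = Condition(
        denaturant=meta.get("denaturant", "none"),
        conc_M=float(meta.get("conc_M", 0.0)),
        protein_mg_per_ml=float(meta.get("protein_mg_per_ml", 0.0)),
        timepoint_min=(float(meta["timepoint_min"]) if "timepoint_min" in meta else None),
    )
    return EmissionSpectrum(
        wavelengths=df["wavelength_nm"].to_numpy(dtype=float),
        intensities=df["intensity"].to_numpy(dtype=float),
        probe=meta.get("probe", "trp"),
        excitation_nm=float(meta.get("excitation_nm", 295.0)),
        condition=cond,
    )


def write_spectrum_csv(spectrum: EmissionSpectrum, path: PathLike) -> None:
    meta = {
        "probe": spectrum.probe,
        "denaturant": spectrum.condition.denaturant,
        "conc_M": spectrum.condition.conc_M,
        "excitation_nm": spectrum.excitation_nm,
    }
    if spectrum.condition.protein_mg_per_ml:
        meta["protein_mg_per_ml"] = spectrum.condition.protein_mg_per_ml
    if spectrum.condition.timepoint_min is not None:
        meta["timepoint_min"] = spectrum.condition.timepoint_min
    df = pd.DataFrame({
        "wavelength_nm": spectrum.wavelengths,
        "intensity": spectrum.intensities,
    })
    _write_with_meta(path, meta, df)


def read_curve_csv(path: PathLike) -> DenaturationCurve:
    """Read a reduced denaturation curve (conc_M, value columns)."""
    meta, df = _read_with_meta(path)
    return DenaturationCurve(
        denaturant=meta.get("denaturant", "unknown"),
        concentrations_M=df["conc_M"].to_numpy(dtype=float),
        values=df["value"].to_numpy(dtype=float),
        observable=meta.get("observable", "AEW"),
        direction=meta.get("direction", "unfolding"),
        protein_label=meta.get("protein_label", ""),
    )


def write_curve_csv(curve: DenaturationCurve, path: PathLike) -> None:
    meta = {
        "observable": curve.observable,
        "direction": curve.direction,
        "denaturant": curve.denaturant,
    }
    if curve.protein_label:
        meta["protein_label"] = curve.protein_label
    df = pd.DataFrame({"conc_M": curve.concentrations_M, "value": curve.values})
    _write_with_meta(path, meta, df)


def read_trace_csv(path: PathLike) -> AggregationTrace:
    """Read a turbidity time series (time_min, a360 columns)."""
    meta, df = _read_with_meta(path)
    return AggregationTrace(
        times_min=df["time_min"].to_numpy(dtype=float),
        a360=df["a360"].to_numpy(dtype=float),
        condition=meta.get("condition", ""),
    )


def write_trace_csv(trace: AggregationTrace, path: PathLike) -> None:
    meta = {"condition": trace.condition} if trace.condition else {}
    df = pd.DataFrame({"time_min": trace.times_min, "a360": trace.a360})
    _write_with_meta(path, meta, df)


def write_track_csv(track, path: PathLike) -> None:
    """Write a residue-pair distance track (time_ps, distance_A columns)."""
    (ca, ra), (cb, rb) = track.pair
    meta = {
        "pair": f"{ca}{ra}-{cb}{rb}",
        "atom": track.atom_name,
        "rate_A_per_ps": track.rate_A_per_ps,
    }
    df = pd.DataFrame({"time_ps": track.times_ps, "distance_A": track.distances_A})
    _write_with_meta(path, meta, df)
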