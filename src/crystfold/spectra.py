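"""Reduction of raw spectroscopic measurements to scalar observables.

Fluorescence emission scans are reduced to the average emission wavelength
(AEW, for tryptophan) or to an integrated band area (for ANS); circular
dichroism ellipticities are normalised to mean residue ellipticity (MRE);
fumarate-production absorbance traces are converted to specific argininosuccinate
lyase activity.  These scalars are what the unfolding and aggregation analyses
consume downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import (
    AmbiguousConditionError,
    DegenerateSpectrumError,
    InvalidGeometryError,
    WindowError,
)

__all__ = [
    "Condition",
    "EmissionSpectrum",
    "CDRecord",
    "ActivityAssay",
    "DenaturationCurve",
    "compute_aew",
    "integrate_ans",
    "mre_from_theta",
    "specific_activity",
    "build_curve",
    "subtract_blank",
]

#: probes with a defined analysis convention
PROBES = ("trp", "ANS", "ThT")

#: default ANS integration window (nm), matching the usual acquisition range
ANS_WINDOW = (450.0, 550.0)


@dataclass(frozen=True)
class Condition:
    """Solution condition under which a spectrum was recorded."""

    denaturant: str = "none"
    conc_M: float = 0.0
    protein_mg_per_ml: float = 0.0
    timepoint_min: Optional[float] = None


@dataclass
class EmissionSpectrum:
    """A single fluorescence emission scan at one solution condition.

    Parameters
    ----------
    wavelengths : array-like
        Emission wavelengths in nm, strictly increasing, length >= 2.
    intensities : array-like
        Fluorescence intensities (arbitrary units), same length.
    probe : str
        One of ``trp``, ``ANS``, ``ThT``.
    excitation_nm : float
        Excitation wavelength in nm.
    condition : Condition
        Denaturant / protein / timepoint metadata.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    probe: str
    excitation_nm: float
    condition: Condition = field(default_factory=Condition)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.size < 2:
            raise ValueError("spectrum needs at least 2 wavelength points")
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelengths and intensities differ in length")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if self.probe not in PROBES:
            raise ValueError(f"unknown probe {self.probe!r}; expected one of {PROBES}")


@dataclass
class CDRecord:
    """One observed ellipticity with the geometry needed to normalise it.

    theta_obs is in degrees, mrw in g/mol, path_cm in cm and conc_g_per_ml
    in g/mL — the units expected by the standard mean-residue-ellipticity
    conversion.
    """

    theta_obs: float
    mrw: float
    path_cm: float
    conc_g_per_ml: float
    wavelength_nm: float = 222.0

    def __post_init__(self) -> None:
        if self.mrw <= 0:
            raise InvalidGeometryError("invalid geometry: mrw must be > 0")


@dataclass
class ActivityAssay:
    """A240 time course of fumarate production for one assay.

    epsilon_M_cm defaults to 2440, the fumarate molar absorption
    coefficient at 240 nm.
    """

    times_min: np.ndarray
    a240: np.ndarray
    epsilon_M_cm: float = 2440.0
    path_cm: float = 1.0
    volume_ml: float = 1.0
    protein_mg: float = 1.0

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.a240 = np.asarray(self.a240, dtype=float)
        if self.times_min.size < 3:
            raise ValueError("activity assay needs at least 3 time points")
        if self.times_min.shape != self.a240.shape:
            raise ValueError("times and absorbances differ in length")
        if not np.all(np.diff(self.times_min) > 0):
            raise ValueError("times must be increasing")
        if self.epsilon_M_cm <= 0:
            raise ValueError("epsilon must be > 0")
        if self.protein_mg <= 0:
            raise ValueError("protein_mg must be > 0")


@dataclass
class DenaturationCurve:
    """Scalar observable versus denaturant concentration.

    ``observable`` names the reduction that produced the values
    (``AEW``, ``ANS_area`` or ``MRE``); ``direction`` distinguishes
    unfolding from refolding branches, which are always analysed
    separately.  ``meta`` carries generator ground truth when the curve
    is synthetic.
    """

    denaturant: str
    concentrations_M: np.ndarray
    values: np.ndarray
    observable: str = "AEW"
    direction: str = "unfolding"
    protein_label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concentrations_M = np.asarray(self.concentrations_M, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.concentrations_M.shape != self.values.shape:
            raise ValueError("concentrations and values differ in length")
        if np.any(self.concentrations_M < 0):
            raise ValueError("denaturant concentrations must be non-negative")
        if not np.all(np.diff(self.concentrations_M) > 0):
            order = np.argsort(self.concentrations_M)
            self.concentrations_M = self.concentrations_M[order]
            self.values = self.values[order]

    def __len__(self) -> int:
        return self.concentrations_M.size


def compute_aew(spectrum: EmissionSpectrum) -> float:
    """Average emission wavelength: the intensity-weighted mean wavelength.

    AEW = sum(lambda_i * F_i) / sum(F_i).  Red-shifts as tryptophans become
    solvent exposed, which is why it tracks unfolding.

    Raises
    ------
    DegenerateSpectrumError
        If the total intensity is zero or negative.
    """
    if spectrum.probe != "trp":
        raise ValueError(f"AEW is defined for trp spectra, got {spectrum.probe!r}")
    total = float(np.sum(spectrum.intensities))
    if total <= 0:
        raise DegenerateSpectrumError("degenerate spectrum: non-positive total intensity")
    aew = float(np.sum(spectrum.wavelengths * spectrum.intensities) / total)
    return aew


def integrate_ans(
    spectrum: EmissionSpectrum,
    window: tuple[float, float] = ANS_WINDOW,
) -> float:
    """Trapezoidal integral of ANS intensity over ``window`` (AU * nm).

    The integral runs on the recorded grid; window endpoints that fall
    between grid points are linearly interpolated so the integral is
    exactly additive over adjacent windows.
    """
    if spectrum.probe != "ANS":
        raise ValueError(f"band integration is defined for ANS spectra, got {spectrum.probe!r}")
    lo, hi = float(window[0]), float(window[1])
    if lo >= hi:
        raise WindowError("window out of range: empty window")
    wl, fi = spectrum.wavelengths, spectrum.intensities
    if lo < wl[0] or hi > wl[-1]:
        raise WindowError(
            f"window out of range: [{lo}, {hi}] not within [{wl[0]}, {wl[-1]}]"
        )
    inside = (wl > lo) & (wl < hi)
    xs = np.concatenate(([lo], wl[inside], [hi]))
    ys = np.concatenate(([np.interp(lo, wl, fi)], fi[inside], [np.interp(hi, wl, fi)]))
    return float(np.trapezoid(ys, xs))


def mre_from_theta(record: CDRecord) -> float:
    """Mean residue ellipticity in deg cm^2 dmol^-1.

    [theta] = theta * MRW / (10 * d * c) with d in cm and c in g/mL.
    """
    if record.path_cm <= 0 or record.conc_g_per_ml <= 0:
        raise InvalidGeometryError("invalid geometry: path and concentration must be > 0")
    return record.theta_obs * record.mrw / (10.0 * record.path_cm * record.conc_g_per_ml)


def specific_activity(
    assay: ActivityAssay,
    window: Optional[tuple[float, float]] = None,
    r2_min: float = 0.98,
) -> float:
    """Specific ASL activity in nmol fumarate min^-1 (mg protein)^-1.

    The initial rate is the least-squares slope of A240 versus time over
    ``window`` (default: the full trace).  Beer–Lambert converts the slope
    to a molar rate, the assay volume to moles per minute, and the protein
    mass normalises.  A fitted slope below zero returns 0 with a warning;
    poor linearity (R^2 < ``r2_min``) also warns.
    """
    t, a = assay.times_min, assay.a240
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        if np.count_nonzero(sel) < 3:
            raise ValueError("initial-rate window contains fewer than 3 points")
        t, a = t[sel], a[sel]
    res = stats.linregress(t, a)
    slope = float(res.slope)
    if np.ptp(a) > 0 and res.rvalue**2 < r2_min:
        warnings.warn(
            f"initial-rate region not linear (R^2 = {res.rvalue ** 2:.3f} < {r2_min})",
            stacklevel=2,
        )
    if slope < 0:
        warnings.warn("negative absorbance slope; reporting zero activity", stacklevel=2)
        return 0.0
    molar_per_min = slope / (assay.epsilon_M_cm * assay.path_cm)  # mol L^-1 min^-1
    nmol_per_min = molar_per_min * (assay.volume_ml * 1e-3) * 1e9
    return nmol_per_min / assay.protein_mg


def subtract_blank(spectrum: EmissionSpectrum, blank: EmissionSpectrum) -> EmissionSpectrum:
    """Blank-correct a spectrum by pointwise subtraction.

    If the blank was recorded on a different wavelength grid it is linearly
    interpolated onto the spectrum's grid first.
    """
    if np.array_equal(spectrum.wavelengths, blank.wavelengths):
        corrected = spectrum.intensities - blank.intensities
    else:
        corrected = spectrum.intensities - np.interp(
            spectrum.wavelengths, blank.wavelengths, blank.intensities
        )
    return EmissionSpectrum(
        wavelengths=spectrum.wavelengths.copy(),
        intensities=corrected,
        probe=spectrum.probe,
        excitation_nm=spectrum.excitation_nm,
        condition=spectrum.condition,
    )


def build_curve(
    spectra: Sequence[EmissionSpectrum],
    observable: str = "AEW",
    direction: str = "unfolding",
    protein_label: str = "",
    window: tuple[float, float] = ANS_WINDOW,
) -> DenaturationCurve:
    """Reduce one spectrum per denaturant concentration into a curve.

    ``observable`` selects the reduction: ``AEW`` (trp) or ``ANS_area``.
    Spectra are sorted by concentration; duplicate concentrations are an
    error because the condition would be ambiguous.
    """
    if not spectra:
        raise ValueError("no spectra given")
    probes = {s.probe for s in spectra}
    if len(probes) > 1:
        raise ValueError(f"mixed probes in one curve: {sorted(probes)}")
    denats = {s.condition.denaturant for s in spectra}
    if len(denats) > 1:
        raise ValueError(f"mixed denaturants in one curve: {sorted(denats)}")
    concs = np.array([s.condition.conc_M for s in spectra], dtype=float)
    if np.unique(concs).size != concs.size:
        raise AmbiguousConditionError("ambiguous condition: duplicate denaturant concentrations")
    if observable == "AEW":
        vals = np.array([compute_aew(s) for s in spectra])
    elif observable == "ANS_area":
        vals = np.array([integrate_ans(s, window=window) for s in spectra])
    else:
        raise ValueError(f"unknown observable {observable!r}")
    order = np.argsort(concs)
    return DenaturationCurve(
        denaturant=denats.pop(),
        concentrations_M=concs[order],
        values=vals[order],
        observable=observable,
        direction=direction,
        protein_label=protein_label,
    )
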