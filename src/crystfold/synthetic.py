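"""Synthetic data with embedded ground truth for every pipeline input.

Generates denaturation curves and Gaussian emission spectra that follow the
two-/three-/four-state LEM models, exponential turbidity rises, and toy
four-chain tetramer structures whose subunits separate linearly in time —
so that every reduction and fit in the package can be checked by parameter
recovery.  All generators are deterministic given their seed, and the truth
is recorded in the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np

from .aggregation import AggregationTrace
from .geometry import Atom, StructureModel, Trajectory
from .spectra import Condition, DenaturationCurve, EmissionSpectrum
from .unfolding import (
    FourStateParams,
    ThermoConstants,
    ThreeStateParams,
    TwoStateParams,
    _eval_sequential,
    _sequential_fractions,
    eval_two_state,
)

__all__ = [
    "GeneratorConfig",
    "PeakModel",
    "TetramerGeometry",
    "TABLE_TWO_STATE",
    "TABLE_FOUR_STATE",
    "FAST_AGGREGATION_RATE",
    "SLOW_AGGREGATION_RATE",
    "gen_unfolding_curve",
    "gen_emission_spectra",
    "gen_aggregation_trace",
    "gen_toy_tetramer",
    "gen_trajectory",
]

#: published two-state truth for the urea-driven tetramer->monomer transition
#: of the K315A mutant (dG0 kcal/mol, m kcal/mol/M; midpoint 6.5/3.8 ~ 1.7 M)
TABLE_TWO_STATE = TwoStateParams(dG0=6.5, m=3.8, yn=350.0, yu=355.0)

#: published four-state truth for GdmCl unfolding of the monomeric mutant
#: (midpoints 1.3/2.1 ~ 0.6, 2.6/1.2 ~ 2.2, 8.9/2.3 ~ 3.9 M)
TABLE_FOUR_STATE = FourStateParams(
    dG1=1.3, dG2=2.6, dG3=8.9, m1=2.1, m2=1.2, m3=2.3,
    yN=348.0, yI1=352.0, yI2=354.0, yU=357.0,
)

#: published aggregation rates for refolding of 0.84 and 3 M GdmCl denatured
#: monomer (min^-1)
FAST_AGGREGATION_RATE = 0.14
SLOW_AGGREGATION_RATE = 0.0004


@dataclass
class GeneratorConfig:
    """Ground truth and sampling scheme for unfolding-curve generation."""

    model: str  # two_state | three_state | four_state
    true_params: Union[TwoStateParams, ThreeStateParams, FourStateParams]
    grid_M: np.ndarray = field(default_factory=lambda: np.arange(0.0, 6.01, 0.25))
    noise_sigma: float = 0.0
    n_replicates: int = 1
    seed: int = 0
    denaturant: str = "GdmCl"
    constants: ThermoConstants = field(default_factory=ThermoConstants)

    def __post_init__(self) -> None:
        self.grid_M = np.asarray(self.grid_M, dtype=float)
        if not np.all(np.diff(self.grid_M) > 0):
            raise ValueError("denaturant grid must be ascending")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.model not in ("two_state", "three_state", "four_state"):
            raise ValueError(f"unknown model {self.model!r}")


def _truth_dict(p) -> dict:
    return {k: float(v) for k, v in asdict(p).items()}


def _eval_model(cfg: GeneratorConfig, D) -> np.ndarray:
    if cfg.model == "two_state":
        return np.asarray(eval_two_state(cfg.true_params, D, cfg.constants))
    return np.asarray(_eval_sequential(cfg.true_params, D, cfg.constants))


def gen_unfolding_curve(cfg: GeneratorConfig) -> list[DenaturationCurve]:
    """Model evaluation on the grid plus i.i.d. Gaussian noise, per replicate.

    Returns ``cfg.n_replicates`` curves; metadata embeds the model name,
    the complete true parameter set, the noise level and the seed.
    """
    clean = _eval_model(cfg, cfg.grid_M)
    rng = np.random.default_rng(cfg.seed)
    curves = []
    for rep in range(cfg.n_replicates):
        noise = rng.normal(0.0, cfg.noise_sigma, size=clean.shape) if cfg.noise_sigma else 0.0
        curves.append(DenaturationCurve(
            denaturant=cfg.denaturant,
            concentrations_M=cfg.grid_M.copy(),
            values=clean + noise,
            observable="AEW",
            direction="unfolding",
            protein_label="synthetic",
            meta={
                "model": cfg.model,
                "truth": _truth_dict(cfg.true_params),
                "noise_sigma": cfg.noise_sigma,
                "seed": cfg.seed,
                "replicate": rep,
            },
        ))
    return curves


@dataclass
class PeakModel:
    """Gaussian emission peak whose centre red-shifts on unfolding.

    One Gaussian per state; centres interpolate linearly from the native to
    the unfolded centre unless given explicitly.  Equal widths and unit
    amplitudes by default, so the intensity-weighted AEW of the composite
    spectrum equals the population-weighted mean of the state centres.
    """

    native_center_nm: float = 335.0
    unfolded_center_nm: float = 355.0
    sigma_nm: float = 10.0
    grid_nm: np.ndarray = field(default_factory=lambda: np.arange(300.0, 410.5, 0.5))
    amplitudes: Optional[Sequence[float]] = None
    centers_nm: Optional[Sequence[float]] = None

    def state_centers(self, n_states: int) -> np.ndarray:
        if self.centers_nm is not None:
            if len(self.centers_nm) != n_states:
                raise ValueError("one centre per state required")
            return np.asarray(self.centers_nm, dtype=float)
        return np.linspace(self.native_center_nm, self.unfolded_center_nm, n_states)


def gen_emission_spectra(
    cfg: GeneratorConfig, peak_model: PeakModel = None
) -> list[EmissionSpectrum]:
    """One trp spectrum per grid concentration, mixing per-state Gaussians.

    The composite intensity at concentration D is
    sum_i f_i(D) * A_i * G(lambda; c_i, sigma), with f_i the model's state
    fractions.  At zero noise the AEW of each spectrum matches the
    population-weighted mean centre to within the window-truncation error.
    """
    peak_model = peak_model or PeakModel()
    if cfg.model == "two_state":
        p = cfg.true_params
        n_states = 2
        fr = _sequential_fractions((p.dG0,), (p.m,), cfg.grid_M, cfg.constants.RT)
    else:
        p = cfg.true_params
        n_states = len(p.signals)
        fr = _sequential_fractions(p.dGs, p.ms, cfg.grid_M, cfg.constants.RT)
    centers = peak_model.state_centers(n_states)
    amps = (np.asarray(peak_model.amplitudes, dtype=float)
            if peak_model.amplitudes is not None else np.ones(n_states))
    wl = peak_model.grid_nm
    rng = np.random.default_rng(cfg.seed)
    spectra = []
    for j, D in enumerate(cfg.grid_M):
        intensity = np.zeros_like(wl)
        for i in range(n_states):
            intensity += fr[i, j] * amps[i] * np.exp(
                -0.5 * ((wl - centers[i]) / peak_model.sigma_nm) ** 2
            )
        if cfg.noise_sigma:
            intensity = intensity + rng.normal(0.0, cfg.noise_sigma, size=wl.shape)
        target_aew = float(np.sum(fr[:, j] * amps * centers) / np.sum(fr[:, j] * amps))
        spectra.append(EmissionSpectrum(
            wavelengths=wl.copy(), intensities=intensity, probe="trp",
            excitation_nm=295.0,
            condition=Condition(denaturant=cfg.denaturant, conc_M=float(D)),
        ))
        spectra[-1].target_aew = target_aew  # ground truth rider
    return spectra


def gen_aggregation_trace(
    rates: Sequence[float],
    amplitudes: Sequence[float],
    y_offset: float = 0.0,
    sigma: float = 0.0,
    seed: int = 0,
    grid_min: np.ndarray = None,
    condition: str = "synthetic",
) -> AggregationTrace:
    """Multi-phase exponential turbidity rise plus Gaussian noise.

    y(t) = y0 + sum_i y_i (1 - exp(-k_i t)); the truth is embedded in the
    trace metadata.
    """
    rates = np.asarray(rates, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if np.any(rates <= 0):
        raise ValueError("rates must be positive")
    if rates.shape != amplitudes.shape:
        raise ValueError("one amplitude per rate required")
    t = (np.asarray(grid_min, dtype=float) if grid_min is not None
         else np.arange(0.0, 30.01, 0.5))
    y = np.full_like(t, y_offset)
    for a, k in zip(amplitudes, rates):
        y = y + a * (1.0 - np.exp(-k * t))
    if sigma:
        y = y + np.random.default_rng(seed).normal(0.0, sigma, size=t.shape)
    return AggregationTrace(
        times_min=t, a360=y, condition=condition,
        meta={"rates": rates.tolist(), "amplitudes": amplitudes.tolist(),
              "y_offset": float(y_offset), "sigma": float(sigma), "seed": seed},
    )


@dataclass
class TetramerGeometry:
    """Placement rules for the toy double-dimer tetramer.

    Four chains A-D sit at the corners of a square of side ``side_A``;
    A-C and B-D are the primary dimers, A-B and C-D the diagonal pairs.
    Marker residues carry Calpha atoms placed symmetrically about the
    relevant interface midpoint so the prescribed pair distances hold by
    construction, each along a coordinate axis:

    * ``d_237_182`` — D237(A) to R182(C) across the primary interface (x axis)
    * ``d_302_330`` — R302(A) to E330(D) across the corner diagonal (x axis)
    * ``d_315_315`` — K315(A) to K315(B) across the diagonal interface (y axis)
    * ``d_contact`` — NZ of K315(A) to backbone O of M312(B), the
      hydrogen-bond fixture (y axis)
    """

    side_A: float = 40.0
    d_237_182: float = 6.0
    d_302_330: float = 10.0
    d_315_315: float = 8.0
    d_contact: float = 2.9
    marker_residues: tuple = (182, 237, 302, 312, 313, 315, 330)


def gen_toy_tetramer(geometry: TetramerGeometry = None) -> StructureModel:
    """Four-chain toy tetramer with interface marker atoms at known positions.

    Every chain carries a Calpha for each marker residue; residue 315 also
    carries a side-chain NZ and residues 312/313 a backbone O, so the
    contact listing has one engineered NZ-O pair at ``d_contact``.
    """
    g = geometry or TetramerGeometry()
    L = g.side_A
    centroids = {"A": np.array([0.0, 0.0, 0.0]), "B": np.array([0.0, L, 0.0]),
                 "C": np.array([L, 0.0, 0.0]), "D": np.array([L, L, 0.0])}
    atoms: list[Atom] = []

    def add(chain, resnum, resname, name, pos, element):
        atoms.append(Atom(chain=chain, resnum=resnum, icode="", resname=resname,
                          name=name, x=float(pos[0]), y=float(pos[1]),
                          z=float(pos[2]), element=element))

    resnames = {182: "ARG", 237: "ASP", 302: "ARG", 312: "MET",
                313: "VAL", 315: "LYS", 330: "GLU"}

    # interface-tuned markers (axis-aligned so rigid chain motion along the
    # axis changes the pair distance at exactly the chain speed)
    add("A", 237, "ASP", "CA", [L / 2 - g.d_237_182 / 2, 0.0, 0.0], "C")
    add("C", 182, "ARG", "CA", [L / 2 + g.d_237_182 / 2, 0.0, 0.0], "C")
    add("A", 302, "ARG", "CA", [L / 2 - g.d_302_330 / 2, L / 2, 0.0], "C")
    add("D", 330, "GLU", "CA", [L / 2 + g.d_302_330 / 2, L / 2, 0.0], "C")
    add("A", 315, "LYS", "CA", [0.0, L / 2 - g.d_315_315 / 2, 0.0], "C")
    add("B", 315, "LYS", "CA", [0.0, L / 2 + g.d_315_315 / 2, 0.0], "C")
    # engineered hydrogen-bond pair: NZ(A315) ... O(B312)
    nz_y = L / 2 - g.d_315_315 / 2 + 1.0
    add("A", 315, "LYS", "NZ", [0.0, nz_y, 0.0], "N")
    add("B", 312, "MET", "O", [0.0, nz_y + g.d_contact, 0.0], "O")
    add("B", 313, "VAL", "O", [1.5, nz_y + g.d_contact + 1.0, 0.0], "O")

    placed = {(a.chain, a.resnum, a.name) for a in atoms}
    for chain, centroid in centroids.items():
        for idx, resnum in enumerate(g.marker_residues):
            if (chain, resnum, "CA") not in placed:
                offset = np.array([1.0 + idx, 2.0, 1.0 + 0.5 * idx])
                add(chain, resnum, resnames[resnum], "CA", centroid + offset, "C")
            if resnum == 315 and (chain, resnum, "NZ") not in placed:
                offset = np.array([1.0 + idx, 3.2, 1.5])
                add(chain, resnum, "LYS", "NZ", centroid + offset, "N")
            if resnum in (312, 313) and (chain, resnum, "O") not in placed:
                offset = np.array([1.0 + idx, 0.8, 2.5])
                add(chain, resnum, resnames[resnum], "O", centroid + offset, "O")
    return StructureModel(atoms=atoms, label="toy-tetramer")


def gen_trajectory(
    base: StructureModel,
    per_chain_velocity: dict,
    n_frames: int = 11,
    dt_ps: float = 10.0,
    seed: int = 0,
    jitter: float = 0.0,
) -> Trajectory:
    """Rigidly translate chains at constant velocity, with optional jitter.

    ``per_chain_velocity`` maps chain id -> (vx, vy, vz) in Angstrom/ps;
    unlisted chains stay put.  Gaussian coordinate jitter of standard
    deviation ``jitter`` (Angstrom) is added independently per frame.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    times = np.arange(n_frames, dtype=float) * dt_ps
    frames = []
    for t in times:
        moved = []
        for a in base.atoms:
            v = np.asarray(per_chain_velocity.get(a.chain, (0.0, 0.0, 0.0)), dtype=float)
            pos = a.xyz + v * t
            if jitter:
                pos = pos + rng.normal(0.0, jitter, size=3)
            moved.append(Atom(chain=a.chain, resnum=a.resnum, icode=a.icode,
                              resname=a.resname, name=a.name,
                              x=float(pos[0]), y=float(pos[1]), z=float(pos[2]),
                              element=a.element))
        frames.append(StructureModel(atoms=moved, label=base.label))
    return Trajectory(frames=frames, times_ps=times)
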