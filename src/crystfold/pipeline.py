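"""Config-driven orchestration: reduce -> fit -> report.

Each ``run_*`` function takes a :class:`RunConfig`, executes one arm of the
analysis (equilibrium unfolding, aggregation kinetics, trajectory geometry)
and returns a JSON-serialisable report with provenance.  Errors are
re-raised as :class:`PipelineError` labelled with the failing stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import scipy
import yaml

from . import __version__
from .errors import PipelineError
from .geometry import interface_contacts, parse_structure, parse_trajectory, track_distances
from .io import read_curve_csv, read_spectrum_csv, read_trace_csv, write_track_csv
from .spectra import build_curve
from .aggregation import select_kinetic_model, fit_exponential
from .unfolding import (
    FitOptions,
    ThermoConstants,
    fit_four_state,
    fit_three_state,
    fit_two_state,
    model_select,
    total_free_energy,
)

__all__ = ["RunConfig", "run_unfolding_analysis", "run_aggregation_analysis",
           "run_structure_analysis"]


@dataclass
class RunConfig:
    """Inputs and options for one pipeline run.

    Paths are interpreted relative to ``base_dir`` (the config file's
    directory when loaded from disk).
    """

    curves: list = field(default_factory=list)        # curve CSV paths
    spectra: list = field(default_factory=list)       # lists of spectrum CSVs, one list per curve
    observable: str = "AEW"
    model: str = "auto"                               # two_state|three_state|four_state|auto
    traces: list = field(default_factory=list)        # turbidity CSV paths
    kinetic_model: str = "auto"                       # auto|exp1|exp2
    trajectory: Optional[str] = None                  # multi-MODEL PDB path
    frame_times_ps: Optional[list] = None
    pairs: list = field(default_factory=list)         # [[chainA, resA, chainB, resB], ...]
    contact_chains: Optional[list] = None             # [chainA, chainB]
    contact_cutoff_A: float = 3.5
    temperature_K: float = 298.15
    n_starts: int = 20
    seed: int = 0
    out_dir: Optional[str] = None
    base_dir: Path = field(default_factory=Path)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with path.open() as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
        known = {f for f in cls.__dataclass_fields__ if f != "base_dir"}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"[config] unknown keys: {sorted(unknown)}")
        return cls(**raw, base_dir=path.parent)

    def resolve(self, p) -> Path:
        p = Path(p)
        return p if p.is_absolute() else self.base_dir / p

    def fit_options(self) -> FitOptions:
        return FitOptions(n_starts=self.n_starts, seed=self.seed)

    def constants(self) -> ThermoConstants:
        return ThermoConstants(T=self.temperature_K)


def _provenance(cfg: RunConfig) -> dict:
    return {
        "crystfold": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "seed": cfg.seed,
        "temperature_K": cfg.temperature_K,
    }


def _load_curves(cfg: RunConfig):
    curves = []
    for p in cfg.curves:
        path = cfg.resolve(p)
        if not path.exists():
            raise PipelineError(f"[load] missing curve file: {path}")
        curves.append(read_curve_csv(path))
    for group in cfg.spectra:
        spectra = []
        for p in group:
            path = cfg.resolve(p)
            if not path.exists():
                raise PipelineError(f"[load] missing spectrum file: {path}")
            spectra.append(read_spectrum_csv(path))
        try:
            curves.append(build_curve(spectra, observable=cfg.observable))
        except Exception as exc:
            raise PipelineError(f"[reduce] {exc}") from exc
    if not curves:
        raise PipelineError("[load] no curves configured")
    return curves


def run_unfolding_analysis(cfg: RunConfig) -> dict:
    """Reduce, fit and report equilibrium unfolding for all configured curves.

    Unfolding and refolding branches are fitted independently; the report
    compares their midpoints as the reversibility check.
    """
    curves = _load_curves(cfg)
    k = cfg.constants()
    opts = cfg.fit_options()
    fitters = {"two_state": fit_two_state, "three_state": fit_three_state,
               "four_state": fit_four_state}

    by_direction: dict = {}
    for c in curves:
        by_direction.setdefault(c.direction, []).append(c)

    report = {"provenance": _provenance(cfg), "curves": [], "fits": {},
              "reversibility": {}}
    for c in curves:
        report["curves"].append({
            "denaturant": c.denaturant, "observable": c.observable,
            "direction": c.direction, "n_points": len(c),
            "conc_range_M": [float(c.concentrations_M[0]), float(c.concentrations_M[-1])],
        })
    for direction, group in by_direction.items():
        try:
            if cfg.model == "auto":
                sel = model_select(group[0], k, opts)
                fit = sel.fits[sel.chosen_states]
                entry = fit.to_dict()
                entry["model_selection"] = sel.to_dict()
            else:
                fit = fitters[cfg.model](group, k, opts)
                entry = fit.to_dict()
        except KeyError:
            raise PipelineError(f"[fit] unknown model {cfg.model!r}")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"[fit] {direction}: {exc}") from exc
        if fit.model == "four_state":
            entry["total_free_energy_kcal_mol"] = total_free_energy(fit.params_for_curve(0))
        report["fits"][direction] = entry

    if {"unfolding", "refolding"} <= set(report["fits"]):
        mu = report["fits"]["unfolding"]["midpoints_M"]
        mr = report["fits"]["refolding"]["midpoints_M"]
        n = min(len(mu), len(mr))
        report["reversibility"] = {
            "unfolding_midpoints_M": mu, "refolding_midpoints_M": mr,
            "midpoint_differences_M": [mu[i] - mr[i] for i in range(n)],
        }
    return report


def run_aggregation_analysis(cfg: RunConfig) -> dict:
    """Fit every configured turbidity trace; one record per trace."""
    if not cfg.traces:
        raise PipelineError("[load] no traces configured")
    report = {"provenance": _provenance(cfg), "traces": []}
    for p in cfg.traces:
        path = cfg.resolve(p)
        if not path.exists():
            raise PipelineError(f"[load] missing trace file: {path}")
        trace = read_trace_csv(path)
        try:
            if cfg.kinetic_model == "auto":
                fit = select_kinetic_model(trace)
            elif cfg.kinetic_model in ("exp1", "exp2"):
                fit = fit_exponential(trace, int(cfg.kinetic_model[-1]))
            else:
                raise PipelineError(f"[fit] unknown kinetic model {cfg.kinetic_model!r}")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"[fit] {path.name}: {exc}") from exc
        entry = fit.to_dict()
        entry["file"] = str(path.name)
        entry["condition"] = trace.condition
        report["traces"].append(entry)
    return report


def run_structure_analysis(cfg: RunConfig) -> dict:
    """Track residue-pair distances over a trajectory and list contacts."""
    if cfg.trajectory is None:
        raise PipelineError("[load] no trajectory configured")
    path = cfg.resolve(cfg.trajectory)
    if not path.exists():
        raise PipelineError(f"[load] missing trajectory file: {path}")
    try:
        traj = parse_trajectory(path, times_ps=cfg.frame_times_ps)
    except Exception as exc:
        raise PipelineError(f"[parse] {exc}") from exc

    report = {"provenance": _provenance(cfg), "n_frames": len(traj),
              "tracks": [], "contacts": []}
    if cfg.pairs:
        pairs = [((str(ca), int(ra)), (str(cb), int(rb))) for ca, ra, cb, rb in cfg.pairs]
        try:
            tracks = track_distances(traj, pairs)
        except Exception as exc:
            raise PipelineError(f"[track] pair spec {cfg.pairs}: {exc}") from exc
        report["tracks"] = [t.to_dict() for t in tracks]
        if cfg.out_dir:
            out = Path(cfg.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            for t in tracks:
                (ca, ra), (cb, rb) = t.pair
                write_track_csv(t, out / f"track_{ca}{ra}_{cb}{rb}.csv")
    if cfg.contact_chains:
        ca, cb = cfg.contact_chains
        try:
            contacts = interface_contacts(traj.frames[0], ca, cb, cfg.contact_cutoff_A)
        except Exception as exc:
            raise PipelineError(f"[contacts] chains {ca}-{cb}: {exc}") from exc
        report["contacts"] = [
            {"atom_a": f"{a.chain}/{a.resname}{a.resnum}/{a.name}",
             "atom_b": f"{b.chain}/{b.resname}{b.resnum}/{b.name}",
             "distance_A": float(d)}
            for a, b, d in contacts
        ]
    return report
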