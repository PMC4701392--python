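"""Structure and trajectory geometry: interface residue-pair distances.

Parses PDB text (via Bio.PDB) into a light-weight atom-list model, measures
Calpha-Calpha distances of named residue pairs across trajectory frames, fits
linear separation rates, and lists close cross-chain N/O contacts — the
post-processing applied to multi-chain dissociation trajectories of a
double-dimer tetramer.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning
from scipy import stats

from .errors import AtomNotFoundError, ChainNotFoundError, StructureParseError

__all__ = [
    "Atom",
    "StructureModel",
    "Trajectory",
    "ResiduePairTrack",
    "parse_structure",
    "parse_trajectory",
    "write_pdb",
    "pair_distance",
    "track_distances",
    "interface_contacts",
]


@dataclass(frozen=True)
class Atom:
    """One atom with its chain/residue identity and coordinates in Angstrom."""

    chain: str
    resnum: int
    icode: str
    resname: str
    name: str
    x: float
    y: float
    z: float
    element: str = ""

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class StructureModel:
    """A flat list of atoms with an index for selector lookup.

    Residue identity is (chain, residue number, insertion code) exactly as
    in the source file; author numbering is kept verbatim.
    """

    atoms: list
    label: str = ""
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for a in self.atoms:
            key = (a.chain, a.resnum, a.icode, a.name)
            if key in self._index:
                raise ValueError(f"duplicate atom {key}")
            if not all(np.isfinite([a.x, a.y, a.z])):
                raise ValueError(f"non-finite coordinates for {key}")
            self._index[key] = a

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list:
        seen = dict.fromkeys(a.chain for a in self.atoms)
        return list(seen)

    def get_atom(self, chain: str, resnum: int, name: str = "CA", icode: str = "") -> Atom:
        try:
            return self._index[(chain, int(resnum), icode, name)]
        except KeyError:
            raise AtomNotFoundError(
                f"atom not found: chain {chain} residue {resnum}{icode} atom {name}"
            ) from None

    def chain_atoms(self, chain: str) -> list:
        out = [a for a in self.atoms if a.chain == chain]
        if not out:
            raise ChainNotFoundError(f"chain not found: {chain}")
        return out


@dataclass
class Trajectory:
    """Ordered structure frames sharing one atom roster, with frame times (ps)."""

    frames: list
    times_ps: np.ndarray

    def __post_init__(self) -> None:
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        if len(self.frames) != self.times_ps.size:
            raise ValueError("one time per frame required")
        if self.times_ps.size >= 2 and not np.all(np.diff(self.times_ps) > 0):
            raise ValueError("frame times must be increasing")
        roster = set(self.frames[0]._index)
        for i, f in enumerate(self.frames[1:], start=1):
            if set(f._index) != roster:
                raise ValueError(f"frame {i} atom roster differs from frame 0")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class ResiduePairTrack:
    """Per-frame distance of one residue pair plus its fitted linear rate."""

    pair: tuple
    atom_name: str
    times_ps: np.ndarray
    distances_A: np.ndarray
    rate_A_per_ps: float
    intercept_A: float
    stderr_rate: float

    def to_dict(self) -> dict:
        (ca, ra), (cb, rb) = self.pair
        return {
            "pair": f"{ca}{ra}-{cb}{rb}",
            "atom": self.atom_name,
            "rate_A_per_ps": float(self.rate_A_per_ps),
            "intercept_A": float(self.intercept_A),
            "stderr_rate": float(self.stderr_rate),
            "distances_A": [float(d) for d in self.distances_A],
            "times_ps": [float(t) for t in self.times_ps],
        }


def _models_from_text(text: str, label: str):
    parser = PDBParser(QUIET=True, PERMISSIVE=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            structure = parser.get_structure(label or "model", io.StringIO(text))
        except (PDBConstructionException, ValueError) as exc:
            raise StructureParseError(f"parse error: {exc}") from exc
    models = []
    for model in structure:
        atoms = []
        for chain in model:
            for residue in chain:
                het, resnum, icode = residue.id
                for atom in residue:
                    x, y, z = atom.coord
                    atoms.append(Atom(
                        chain=chain.id, resnum=int(resnum),
                        icode=icode.strip(), resname=residue.resname.strip(),
                        name=atom.name.strip(),
                        x=float(x), y=float(y), z=float(z),
                        element=(atom.element or "").strip(),
                    ))
        if atoms:
            models.append(StructureModel(atoms=atoms, label=label))
    return models


def _check_coordinates(text: str) -> None:
    """Reject unparseable coordinate fields with the offending line number."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fragment = line[lo:hi].strip()
                try:
                    float(fragment)
                except ValueError:
                    raise StructureParseError(
                        f"parse error at line {lineno}: bad coordinate field {fragment!r}"
                    ) from None


def parse_structure(text: str, label: str = "") -> StructureModel:
    """Parse PDB-format text into a StructureModel (first MODEL if several).

    Raises ``StructureParseError`` for text without ATOM/HETATM records or
    with malformed coordinate fields (reported with its line number).
    """
    if isinstance(text, Path):
        text = text.read_text()
    if not any(line.startswith(("ATOM", "HETATM")) for line in text.splitlines()):
        raise StructureParseError("empty structure: no ATOM records")
    _check_coordinates(text)
    models = _models_from_text(text, label)
    if not models:
        raise StructureParseError("empty structure: no ATOM records")
    return models[0]


def parse_trajectory(
    source, times_ps: Optional[Sequence[float]] = None, label: str = ""
) -> Trajectory:
    """Parse a multi-MODEL PDB text, or a list of single-frame texts/paths.

    Frame times default to the 0-based frame index (in ps) when not given.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text() if isinstance(source, Path) else source
        if not any(line.startswith(("ATOM", "HETATM")) for line in text.splitlines()):
            raise StructureParseError("empty structure: no ATOM records")
        _check_coordinates(text)
        frames = _models_from_text(text, label)
    else:
        frames = [parse_structure(t if isinstance(t, str) else Path(t).read_text(), label)
                  for t in source]
    if not frames:
        raise StructureParseError("empty structure: no frames parsed")
    if times_ps is None:
        times_ps = np.arange(len(frames), dtype=float)
    return Trajectory(frames=frames, times_ps=np.asarray(times_ps, dtype=float))


def write_pdb(obj, path=None) -> str:
    """Serialise a StructureModel or Trajectory to PDB text (ATOM records).

    Multi-frame trajectories are written as MODEL/ENDMDL blocks.
    """
    def _model_lines(model: StructureModel, serial_start: int = 1) -> list:
        lines = []
        serial = serial_start
        for a in model.atoms:
            element = a.element or a.name[:1]
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} {a.resname:<3s} {a.chain:1s}"
                f"{a.resnum:4d}{a.icode or ' ':1s}   "
                f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {element:>2s}"
            )
            serial += 1
        return lines

    if isinstance(obj, Trajectory):
        lines = []
        for i, frame in enumerate(obj.frames, start=1):
            lines.append(f"MODEL     {i:4d}")
            lines.extend(_model_lines(frame))
            lines.append("ENDMDL")
        lines.append("END")
    else:
        lines = _model_lines(obj) + ["END"]
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def pair_distance(model: StructureModel, pair, atom_name: str = "CA") -> float:
    """Euclidean distance (Angstrom) between one atom of each residue in ``pair``.

    ``pair`` is ((chainA, resnumA), (chainB, resnumB)).
    """
    (ca, ra), (cb, rb) = pair
    a = model.get_atom(ca, ra, atom_name)
    b = model.get_atom(cb, rb, atom_name)
    return float(np.linalg.norm(a.xyz - b.xyz))


def track_distances(
    traj: Trajectory,
    pairs: Sequence,
    atom_name: str = "CA",
    time_window: Optional[tuple[float, float]] = None,
) -> list:
    """Per-frame pair distances plus a least-squares linear separation rate.

    The rate is fitted over ``time_window`` (ps) when given, else the full
    trajectory.  A pair missing from any frame raises, naming the frame.
    """
    tracks = []
    for pair in pairs:
        dists = np.empty(len(traj))
        for i, frame in enumerate(traj.frames):
            try:
                dists[i] = pair_distance(frame, pair, atom_name)
            except AtomNotFoundError as exc:
                raise AtomNotFoundError(f"frame {i}: {exc}") from exc
        t = traj.times_ps
        if time_window is not None:
            sel = (t >= time_window[0]) & (t <= time_window[1])
            if np.count_nonzero(sel) < 2:
                raise ValueError("time window selects fewer than 2 frames")
            tw, dw = t[sel], dists[sel]
        else:
            tw, dw = t, dists
        if tw.size >= 2 and np.ptp(tw) > 0:
            res = stats.linregress(tw, dw)
            rate, inter = float(res.slope), float(res.intercept)
            se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
        else:
            rate, inter, se = 0.0, float(dw[0]), 0.0
        tracks.append(ResiduePairTrack(
            pair=tuple(tuple(p) for p in pair), atom_name=atom_name,
            times_ps=t.copy(), distances_A=dists,
            rate_A_per_ps=rate, intercept_A=inter, stderr_rate=se,
        ))
    return tracks


def interface_contacts(
    model: StructureModel,
    chain_a: str,
    chain_b: str,
    cutoff_A: float = 3.5,
) -> list:
    """Cross-chain N/O atom pairs within ``cutoff_A``, sorted by distance.

    A distance-only donor/acceptor heuristic: every nitrogen or oxygen of
    one chain against every nitrogen or oxygen of the other, keeping pairs
    closer than the cutoff (default 3.5 Angstrom, a generous hydrogen-bond
    length).  Returns (atomA, atomB, distance) triples.
    """
    def _polar(atoms):
        return [a for a in atoms
                if (a.element or a.name[:1]).upper() in ("N", "O")]

    aa = _polar(model.chain_atoms(chain_a))
    bb = _polar(model.chain_atoms(chain_b))
    out = []
    for a in aa:
        for b in bb:
            d = float(np.linalg.norm(a.xyz - b.xyz))
            if d < cutoff_A:
                out.append((a, b, d))
    out.sort(key=lambda triple: triple[2])
    return out
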