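"""Coordinate I/O and rigid-body geometry.

Structures are plain atom lists read from fixed-width PDB records
(ATOM/HETATM/MODEL/ENDMDL, format v3.3).  Coordinates are ångström
throughout; trajectory times are nanoseconds.  Multi-model PDB is the
canonical trajectory container so that every fixture in the test-suite is
plain text.

Author residue numbering is preserved verbatim — no renumbering — because
published domain definitions (e.g. an N-terminus spanning residues 14-53)
refer to deposition numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import AnalysisError, GeometryError, PDBParseError, PDBWriteError

__all__ = [
    "Atom",
    "StructureModel",
    "Trajectory",
    "TimeSeries",
    "AtomSelection",
    "DomainDefinition",
    "parse_structure",
    "parse_trajectory",
    "write_structure",
    "write_trajectory",
    "resolve_selection",
    "superpose",
]


@dataclass
class Atom:
    """One atomic record.

    ``position`` is a length-3 float array in Å.  ``resid`` keeps the
    author's numbering; insertion codes are appended to ``icode``.
    """

    serial: int
    name: str
    resname: str
    resid: int
    chain: str
    position: np.ndarray
    element: str = ""
    record: str = "ATOM"
    occupancy: float = 1.0
    bfactor: float = 0.0
    altloc: str = ""
    icode: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("Atom position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("Atom position must be finite")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity within a model: (chain, resid, icode, name)."""
        return (self.chain, self.resid, self.icode, self.name)


class StructureModel:
    """An ordered, non-empty collection of atoms from one model.

    Atom order is stable across every operation; the coordinate array is
    a (n_atoms, 3) float view rebuilt on demand.
    """

    def __init__(self, atoms: Sequence[Atom], model_id: int = 0, source: str = ""):
        atoms = list(atoms)
        if not atoms:
            raise ValueError("StructureModel must contain at least one atom")
        seen: set[tuple] = set()
        for a in atoms:
            if a.key in seen:
                raise ValueError(f"duplicate atom {a.key} in model")
            seen.add(a.key)
        self.atoms: list[Atom] = atoms
        self.model_id = model_id
        self.source = source

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, model_id: int | None = None) -> "StructureModel":
        """Copy of this model with replaced coordinates (same identities)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        new_atoms = [
            Atom(
                serial=a.serial, name=a.name, resname=a.resname, resid=a.resid,
                chain=a.chain, position=coords[i].copy(), element=a.element,
                record=a.record, occupancy=a.occupancy, bfactor=a.bfactor,
                altloc=a.altloc, icode=a.icode,
            )
            for i, a in enumerate(self.atoms)
        ]
        return StructureModel(
            new_atoms,
            model_id=self.model_id if model_id is None else model_id,
            source=self.source,
        )

    def atom_index(self, chain: str, resid: int, name: str, icode: str = "") -> int:
        for i, a in enumerate(self.atoms):
            if a.chain == chain and a.resid == resid and a.name == name and a.icode == icode:
                return i
        raise KeyError(f"no atom {chain}/{resid}{icode}/{name}")


@dataclass
class Trajectory:
    """Ordered coordinate snapshots over a fixed atom set.

    ``frames`` has shape (n_frames, n_atoms, 3) in Å; ``times`` is ns,
    strictly increasing.
    """

    topology: StructureModel
    frames: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.topology):
            raise ValueError("frame atom count differs from topology")
        if self.times.shape != (self.frames.shape[0],):
            raise ValueError("times length differs from frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_model(self, i: int) -> StructureModel:
        return self.topology.with_coords(self.frames[i], model_id=i)


@dataclass
class TimeSeries:
    """Per-frame scalar values with their time stamps (ns)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class AtomSelection:
    """Declarative atom filter; all given criteria are AND-combined.

    ``residue_ranges`` are inclusive (start, end) pairs.  An empty result
    is valid; resolution is deterministic and order-stable.
    """

    chains: Sequence[str] | None = None
    residue_ranges: Sequence[tuple[int, int]] | None = None
    resnames: Sequence[str] | None = None
    names: Sequence[str] | None = None

    def matches(self, atom: Atom) -> bool:
        if self.chains is not None and atom.chain not in self.chains:
            return False
        if self.residue_ranges is not None and not any(
            lo <= atom.resid <= hi for lo, hi in self.residue_ranges
        ):
            return False
        if self.resnames is not None and atom.resname not in self.resnames:
            return False
        if self.names is not None and atom.name not in self.names:
            return False
        return True


@dataclass
class DomainDefinition:
    """A named protein domain as inclusive residue ranges."""

    name: str
    residue_ranges: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ranges = sorted(self.residue_ranges)
        for (a_lo, a_hi), (b_lo, b_hi) in zip(ranges, ranges[1:]):
            if b_lo <= a_hi:
                raise ValueError(
                    f"domain {self.name!r}: overlapping ranges "
                    f"({a_lo},{a_hi}) and ({b_lo},{b_hi})"
                )

    def selection(self, chains: Sequence[str] | None = None,
                  names: Sequence[str] | None = None) -> AtomSelection:
        return AtomSelection(chains=chains, residue_ranges=list(self.residue_ranges),
                             names=names)


# ---------------------------------------------------------------------------
# PDB fixed-width I/O
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> Atom:
    # PDB v3.3 column layout (1-based in the format spec, 0-based slices here)
    raw = line.rstrip("\n")
    if len(raw) < 54:
        raise PDBParseError("record shorter than coordinate fields", lineno)
    record = raw[0:6].strip()
    try:
        serial = int(raw[6:11])
    except ValueError as exc:
        raise PDBParseError(f"bad serial field {raw[6:11]!r}", lineno) from exc
    name = raw[12:16].strip()
    altloc = raw[16:17].strip()
    resname = raw[17:21].strip()
    chain = raw[21:22].strip() or " "
    try:
        resid = int(raw[22:26])
    except ValueError as exc:
        raise PDBParseError(f"bad residue number {raw[22:26]!r}", lineno) from exc
    icode = raw[26:27].strip()
    try:
        pos = np.array([float(raw[30:38]), float(raw[38:46]), float(raw[46:54])])
    except ValueError as exc:
        raise PDBParseError(f"bad coordinate fields {raw[30:54]!r}", lineno) from exc
    try:
        occupancy = float(raw[54:60]) if raw[54:60].strip() else 1.0
    except ValueError as exc:
        raise PDBParseError(f"bad occupancy field {raw[54:60]!r}", lineno) from exc
    try:
        bfactor = float(raw[60:66]) if len(raw) >= 61 and raw[60:66].strip() else 0.0
    except ValueError as exc:
        raise PDBParseError(f"bad B-factor field {raw[60:66]!r}", lineno) from exc
    element = raw[76:78].strip() if len(raw) >= 77 else ""
    if not element:
        element = "".join(c for c in name if c.isalpha())[:2].capitalize()
    return Atom(
        serial=serial, name=name, resname=resname, resid=resid, chain=chain,
        position=pos, element=element, record=record, occupancy=occupancy,
        bfactor=bfactor, altloc=altloc, icode=icode,
    )


def _split_models(text: str) -> list[list[tuple[int, str]]]:
    """Group ATOM/HETATM lines (with line numbers) by MODEL block."""
    models: list[list[tuple[int, str]]] = []
    current: list[tuple[int, str]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            if current:
                models.append(current)
                current = []
        elif rec == "ENDMDL":
            models.append(current)
            current = []
        elif rec in ("ATOM", "HETATM"):
            current.append((lineno, line))
    if current:
        models.append(current)
    return [m for m in models if m]


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one location per (chain, resid, icode, name): highest occupancy,
    first-encountered on ties."""
    best: dict[tuple, Atom] = {}
    order: list[tuple] = []
    for a in atoms:
        k = (a.chain, a.resid, a.icode, a.name)
        if k not in best:
            best[k] = a
            order.append(k)
        elif a.occupancy > best[k].occupancy:
            best[k] = a
    resolved = []
    for k in order:
        a = best[k]
        a.altloc = ""
        resolved.append(a)
    return resolved


def parse_structure(text: str, model_index: int = 0, source: str = "") -> StructureModel:
    """Parse one model out of PDB-format content.

    ``model_index`` is the 0-based ordinal of the MODEL block; content
    without MODEL records is a single model at index 0.  Alternate
    locations are resolved to the highest-occupancy conformer (ties keep
    the first encountered).
    """
    models = _split_models(text)
    if not models:
        raise PDBParseError("no ATOM/HETATM records found")
    if not 0 <= model_index < len(models):
        raise PDBParseError(
            f"model index {model_index} out of range (file has {len(models)} models)"
        )
    atoms = [_parse_atom_line(line, lineno) for lineno, line in models[model_index]]
    if not atoms:
        raise PDBParseError(f"model {model_index} contains no atoms")
    return StructureModel(_resolve_altlocs(atoms), model_id=model_index, source=source)


def parse_trajectory(text: str, times: Sequence[float] | None = None,
                     dt_ns: float = 1.0, source: str = "") -> Trajectory:
    """Parse a multi-model PDB as a trajectory over a fixed atom set.

    All models must share the topology of the first.  ``times`` overrides
    the default uniform time base ``0, dt_ns, 2*dt_ns, ...``.
    """
    models = _split_models(text)
    if not models:
        raise PDBParseError("no ATOM/HETATM records found")
    parsed = []
    for i, lines in enumerate(models):
        atoms = _resolve_altlocs([_parse_atom_line(line, n) for n, line in lines])
        parsed.append(StructureModel(atoms, model_id=i, source=source))
    topo = parsed[0]
    keys0 = [a.key for a in topo.atoms]
    frames = np.empty((len(parsed), len(topo), 3))
    for i, m in enumerate(parsed):
        if [a.key for a in m.atoms] != keys0:
            raise PDBParseError(f"model {i} atom identities differ from model 0")
        frames[i] = m.coords
    t = np.asarray(times, dtype=float) if times is not None else np.arange(len(parsed)) * dt_ns
    return Trajectory(topology=topo, frames=frames, times=t)


def _format_atom_line(a: Atom) -> str:
    for c in a.position:
        if not -999.999 <= c <= 9999.999:
            raise PDBWriteError(f"coordinate {c} exceeds PDB field width")
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    resname = f"{a.resname:>3s}" if len(a.resname) <= 3 else a.resname
    return (
        f"{a.record:<6s}{a.serial:>5d} {name:<4s}{(a.altloc or ' '):1s}"
        f"{resname:<4s}{a.chain:1s}{a.resid:>4d}{(a.icode or ' '):1s}   "
        f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
        f"{a.occupancy:6.2f}{a.bfactor:6.2f}          {a.element:>2s}"
    )


def write_structure(model: StructureModel) -> str:
    """Serialize a model to fixed-width PDB records (3-decimal Å).

    ``parse_structure(write_structure(m))`` round-trips atom identities
    and coordinates to the printed precision.
    """
    lines = [_format_atom_line(a) for a in model.atoms]
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_trajectory(traj: Trajectory) -> str:
    """Serialize a trajectory as multi-model PDB."""
    out = []
    for i in range(traj.n_frames):
        out.append(f"MODEL     {i + 1:>4d}")
        out.extend(_format_atom_line(a) for a in traj.frame_model(i).atoms)
        out.append("ENDMDL")
    out.append("END")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Selection and superposition
# ---------------------------------------------------------------------------

def resolve_selection(model: StructureModel, sel: AtomSelection) -> np.ndarray:
    """Resolve a selection to atom indices in model order (possibly empty)."""
    return np.array([i for i, a in enumerate(model.atoms) if sel.matches(a)], dtype=int)


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_indices: Sequence[int] | None = None,
) -> tuple[np.ndarray, float]:
    """Least-squares rigid-body superposition (Kabsch, no reflection).

    The optimal proper rotation + translation is computed over
    ``fit_indices`` (default: all atoms) and applied to *all* mobile
    atoms.  Returns the transformed coordinates and the RMSD over the
    fit atoms only.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    idx = np.arange(len(mobile)) if fit_indices is None else np.asarray(fit_indices, dtype=int)
    if len(idx) < 3:
        raise GeometryError("superposition needs at least 3 fit atoms")
    mob_fit = mobile[idx]
    ref_fit = reference[idx]
    mob_c = mob_fit.mean(axis=0)
    ref_c = ref_fit.mean(axis=0)
    a = mob_fit - mob_c
    if np.linalg.matrix_rank(a, tol=1e-8) < 2:
        raise GeometryError("fit atoms are collinear; rotation is underdetermined")
    rot, _ = Rotation.align_vectors(ref_fit - ref_c, a)
    transformed = rot.apply(mobile - mob_c) + ref_c
    d = transformed[idx] - ref_fit
    rmsd = float(np.sqrt(np.mean(np.sum(d * d, axis=1))))
    return transformed, rmsd


def rmsd_between(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD without any fitting."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise AnalysisError("coordinate arrays must have equal shape")
    d = a - b
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))
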