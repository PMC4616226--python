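"""Pigment extraction and transition-dipole assignment.

Each pigment residue in a structure becomes a :class:`PigmentInstance`
carrying the coordinates of the atoms its registry entry names.  Two
dipole constructors cover the chromophore classes:

* chlorophyll Qy — a fixed in-plane axis between two named tetrapyrrole
  nitrogens (NB → ND by default), centred on the Mg;
* carotenoid S2 — the dominant principal axis of the central portion of
  the conjugated polyene chain, signed from the first listed chain atom
  towards the last.

Both are equivariant under rigid motion, and the dipole magnitude is a
registry constant, independent of the coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, MissingAtomError
from .registry import PigmentRegistry, PigmentRegistryEntry
from .structure import StructureModel

__all__ = [
    "TransitionDipole",
    "PigmentInstance",
    "extract_pigment",
    "find_pigments",
    "chl_qy_dipole",
    "car_s2_dipole",
    "pigment_dipole",
]

PigmentId = tuple[str, int, str]  # (chain, resid, resname)


@dataclass(frozen=True)
class TransitionDipole:
    """A point transition dipole: center (Å), unit direction, |μ| (D)."""

    center: np.ndarray
    direction: np.ndarray
    magnitude_debye: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "direction", np.asarray(self.direction, dtype=float))
        n = np.linalg.norm(self.direction)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError(f"direction must be a unit vector (|d| = {n})")
        if self.magnitude_debye < 0:
            raise ValueError("magnitude_debye must be >= 0")

    @property
    def moment(self) -> np.ndarray:
        """μ as a Cartesian vector in Debye."""
        return self.magnitude_debye * self.direction


@dataclass
class PigmentInstance:
    """One pigment residue with the atoms its dipole definition needs."""

    pigment_id: PigmentId
    atom_map: dict[str, np.ndarray]
    registry: PigmentRegistryEntry

    @property
    def pigment_class(self) -> str:
        return self.registry.pigment_class

    def atom(self, name: str) -> np.ndarray:
        try:
            return self.atom_map[name]
        except KeyError:
            raise MissingAtomError(name, context=f"pigment {self.pigment_id}") from None


def extract_pigment(
    model: StructureModel,
    chain: str,
    resid: int,
    registry: PigmentRegistry,
) -> PigmentInstance:
    """Build the PigmentInstance for one residue.

    Raises :class:`MissingAtomError` (never silently substitutes) if any
    atom named by the registry dipole spec is absent — crystal models do
    drop disordered atoms.
    """
    atoms = {a.name: a for a in model.atoms if a.chain == chain and a.resid == resid}
    if not atoms:
        raise MissingAtomError("*", context=f"residue {chain}/{resid} not in model")
    resname = next(iter(atoms.values())).resname
    entry = registry.lookup(resname)
    if entry is None:
        raise MissingAtomError(
            "*", context=f"residue {chain}/{resid} ({resname}) is not in the registry"
        )
    atom_map: dict[str, np.ndarray] = {}
    for name in entry.dipole_atom_names:
        if name not in atoms:
            raise MissingAtomError(name, context=f"pigment {chain}/{resid} ({resname})")
        atom_map[name] = np.asarray(atoms[name].position, dtype=float)
    # keep all residue atoms too; descriptor code (H-bonds, centroids) uses them
    for name, a in atoms.items():
        atom_map.setdefault(name, np.asarray(a.position, dtype=float))
    return PigmentInstance(
        pigment_id=(chain, resid, resname), atom_map=atom_map, registry=entry
    )


def find_pigments(model: StructureModel, registry: PigmentRegistry,
                  classes: tuple[str, ...] | None = None) -> list[PigmentId]:
    """All registry-known pigment residues in model order."""
    seen: list[PigmentId] = []
    for a in model.atoms:
        entry = registry.lookup(a.resname)
        if entry is None:
            continue
        if classes is not None and entry.pigment_class not in classes:
            continue
        pid = (a.chain, a.resid, a.resname)
        if pid not in seen:
            seen.append(pid)
    return seen


def cofactor_census(model: StructureModel, registry: PigmentRegistry) -> dict[str, int]:
    """Count registry-known cofactor residues per pigment class.

    The standard sanity check on a parsed antenna monomer: a plant LHCII
    monomer carries 8 Chl a + 6 Chl b + 4 xanthophylls = 18 pigments.
    """
    counts = {c: 0 for c in ("chl_a", "chl_b", "carotenoid", "lipid")}
    for chain, resid, resname in find_pigments(model, registry):
        counts[registry.lookup(resname).pigment_class] += 1
    counts["pigments_total"] = counts["chl_a"] + counts["chl_b"] + counts["carotenoid"]
    return counts


def chl_qy_dipole(p: PigmentInstance) -> TransitionDipole:
    """Qy transition dipole of a chlorophyll.

    Direction: normalized axis-tail → axis-head vector (default NB → ND);
    center: the registry center atom (default Mg); magnitude from the
    registry.
    """
    if p.pigment_class not in ("chl_a", "chl_b"):
        raise ValueError(f"{p.pigment_id} is not a chlorophyll")
    tail, head = p.registry.axis_atoms
    v = p.atom(head) - p.atom(tail)
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise GeometryError(f"{p.pigment_id}: axis atoms coincide")
    return TransitionDipole(
        center=p.atom(p.registry.center_atom),
        direction=v / n,
        magnitude_debye=p.registry.magnitude_debye,
    )


def _central_chain(names: tuple[str, ...], fraction: float) -> tuple[str, ...]:
    n = len(names)
    keep = max(2, int(round(n * fraction)))
    lo = (n - keep) // 2
    return names[lo:lo + keep]


def car_s2_dipole(p: PigmentInstance) -> TransitionDipole:
    """S2 ← S0 transition dipole of a carotenoid.

    Direction: dominant principal axis (largest-variance direction) of
    the central portion of the conjugated-chain atoms, signed from the
    first listed atom towards the last; center: centroid of those atoms.
    """
    if p.pigment_class != "carotenoid":
        raise ValueError(f"{p.pigment_id} is not a carotenoid")
    names = _central_chain(p.registry.chain_atoms, p.registry.central_fraction)
    if len(names) < 2:
        raise GeometryError(f"{p.pigment_id}: need >=2 central-chain atoms")
    coords = np.array([p.atom(n) for n in names])
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    if np.allclose(centered, 0.0, atol=1e-9):
        raise GeometryError(f"{p.pigment_id}: chain atoms coincide (zero variance)")
    # principal axis = top right-singular vector of the centered coordinates
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    head_to_tail = coords[-1] - coords[0]
    if np.dot(axis, head_to_tail) < 0:
        axis = -axis
    return TransitionDipole(
        center=centroid,
        direction=axis / np.linalg.norm(axis),
        magnitude_debye=p.registry.magnitude_debye,
    )


def pigment_dipole(p: PigmentInstance) -> TransitionDipole:
    """Dispatch to the class-appropriate dipole constructor."""
    if p.pigment_class in ("chl_a", "chl_b"):
        return chl_qy_dipole(p)
    if p.pigment_class == "carotenoid":
        return car_s2_dipole(p)
    raise ValueError(f"{p.pigment_id}: class {p.pigment_class!r} has no dipole")
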