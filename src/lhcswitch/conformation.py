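"""Structural descriptors over single structures and trajectories.

Covers the standard comparison battery between a crystal reference and a
simulated membrane ensemble: carotenoid tilt angles against the protein
axis, per-atom B-factors (Debye–Waller), per-domain RMSD time series,
center-of-mass distances, and hydrogen-bond occupancy.

All trajectory descriptors first remove global rigid-body motion by
least-squares superposition onto a reference over an explicit fit
selection, so the reported numbers are internal deformations, not box
tumbling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AnalysisError, GeometryError, MissingAtomError
from .pigments import TransitionDipole
from .structure import (
    AtomSelection,
    DomainDefinition,
    StructureModel,
    TimeSeries,
    Trajectory,
    resolve_selection,
    superpose,
)

__all__ = [
    "ProteinAxis",
    "BFactorResult",
    "HBondSpec",
    "tilt_angle",
    "protein_axis",
    "per_atom_bfactor",
    "domain_rmsd_series",
    "com_distance_series",
    "hbond_occupancy",
    "tilt_angle_series",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")

# standard atomic masses for mass-weighted centroids; fallback 12.0
_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "MG": 24.305, "Mg": 24.305,
}


@dataclass(frozen=True)
class ProteinAxis:
    """The membrane-normal reference direction (pseudo-C2 axis)."""

    direction: np.ndarray
    definition: str = "inertia_principal"

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError("axis direction must be a unit vector")
        object.__setattr__(self, "direction", d)


@dataclass
class BFactorResult:
    """Per-atom Debye–Waller factors in Å²."""

    atom_indices: np.ndarray
    bfactor: np.ndarray

    def __post_init__(self) -> None:
        self.atom_indices = np.asarray(self.atom_indices, dtype=int)
        self.bfactor = np.asarray(self.bfactor, dtype=float)
        if self.atom_indices.shape != self.bfactor.shape:
            raise ValueError("index/value length mismatch")
        if np.any(self.bfactor < -1e-12):
            raise ValueError("B-factors must be non-negative")


@dataclass
class HBondSpec:
    """Geometric hydrogen-bond criterion.

    A frame is bond-positive iff donor–acceptor distance ≤ ``d_cut`` and,
    when a hydrogen is given, the H–donor–acceptor angle ≤ ``angle_cut``.
    Atom ids are (chain, resid, name) triples.
    """

    donor: tuple[str, int, str]
    acceptor: tuple[str, int, str]
    hydrogen: tuple[str, int, str] | None = None
    d_cut: float = 3.5
    angle_cut: float = 30.0

    def __post_init__(self) -> None:
        if self.d_cut <= 0:
            raise ValueError("d_cut must be positive")
        if not 0 < self.angle_cut <= 90:
            raise ValueError("angle_cut must be in (0, 90] degrees")


def tilt_angle(d: TransitionDipole, axis: ProteinAxis) -> float:
    """Angle (degrees) between a transition dipole and the protein axis.

    Folded to [0°, 90°]: a transition dipole has no physical sign, so θ
    and 180°−θ are the same tilt.
    """
    c = abs(float(np.dot(d.direction, axis.direction)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def protein_axis(
    model: StructureModel,
    selection: AtomSelection,
    mode: str = "inertia_principal",
    reference_atom: tuple[str, int, str] | None = None,
) -> ProteinAxis:
    """Protein z-axis from a transmembrane-helix atom selection.

    ``inertia_principal``: the largest-variance (smallest moment of
    inertia) principal axis of the selected atoms — the long axis of a
    TM helix bundle.  The sign is chosen to point from the selection
    centroid towards ``reference_atom`` (e.g. a stromal-side residue);
    without one the sign is the +z-dominant choice.

    ``lab_z_after_alignment``: literally (0, 0, 1) — for structures
    already superposed onto an axis-aligned reference.
    """
    if mode == "lab_z_after_alignment":
        return ProteinAxis(direction=np.array([0.0, 0.0, 1.0]), definition=mode)
    if mode != "inertia_principal":
        raise ValueError(f"unknown axis mode {mode!r}")
    idx = resolve_selection(model, selection)
    if len(idx) < 3:
        raise GeometryError("protein axis needs at least 3 selected atoms")
    coords = model.coords[idx]
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] - evals[-2] < 1e-9 * max(evals[-1], 1.0):
        raise GeometryError("degenerate inertia tensor: principal axis ill-defined")
    axis = evecs[:, -1]
    if reference_atom is not None:
        ch, resid, name = reference_atom
        i = model.atom_index(ch, resid, name)
        toward = model.atoms[i].position - coords.mean(axis=0)
        if np.dot(axis, toward) < 0:
            axis = -axis
    elif axis[2] < 0:
        axis = -axis
    return ProteinAxis(direction=axis / np.linalg.norm(axis),
                       definition="inertia_principal")


def per_atom_bfactor(
    traj: Trajectory,
    selection: AtomSelection | None = None,
    fit_selection: AtomSelection | None = None,
) -> BFactorResult:
    """Debye–Waller factors B_i = (8π²/3)·⟨|r_i − ⟨r_i⟩|²⟩ from a trajectory.

    Rigid-body motion is removed by superposing every frame onto the
    mean structure over ``fit_selection`` (one refinement pass: fit to
    frame 0, average, refit to the average).  Reported over ``selection``
    (default: all atoms).
    """
    if traj.n_frames < 2:
        raise AnalysisError("B-factors need at least 2 frames")
    sel = selection or AtomSelection()
    fit_sel = fit_selection or AtomSelection()
    idx = resolve_selection(traj.topology, sel)
    fit_idx = resolve_selection(traj.topology, fit_sel)
    if len(idx) == 0:
        raise AnalysisError("empty B-factor selection")

    def _fit_all(reference: np.ndarray) -> np.ndarray:
        fitted = np.empty_like(traj.frames)
        for i in range(traj.n_frames):
            fitted[i], _ = superpose(traj.frames[i], reference, fit_idx)
        return fitted

    fitted = _fit_all(traj.frames[0])
    fitted = _fit_all(fitted.mean(axis=0))
    mean = fitted.mean(axis=0)
    msd = np.mean(np.sum((fitted[:, idx] - mean[idx]) ** 2, axis=2), axis=0)
    return BFactorResult(atom_indices=idx, bfactor=(8.0 * np.pi**2 / 3.0) * msd)


def domain_rmsd_series(
    traj: Trajectory,
    reference: StructureModel,
    domain: DomainDefinition,
    fit_selection: AtomSelection,
    backbone_names: Sequence[str] = BACKBONE_NAMES,
) -> TimeSeries:
    """Per-frame RMSD of one domain's backbone after fitting elsewhere.

    Each frame is superposed onto the reference over ``fit_selection``
    (canonically the rigid TM-helix backbone) and the RMSD is then taken
    over the domain's backbone atoms *without refitting*, so peripheral
    domains report genuine displacement relative to the rigid core.
    """
    if len(reference) != traj.frames.shape[1]:
        raise AnalysisError("reference and trajectory atom counts differ")
    fit_idx = resolve_selection(reference, fit_selection)
    dom_sel = domain.selection(names=tuple(backbone_names))
    dom_idx = resolve_selection(reference, dom_sel)
    if len(dom_idx) == 0:
        raise MissingAtomError("*", context=f"domain {domain.name}: no backbone atoms")
    ref = reference.coords
    vals = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        fitted, _ = superpose(traj.frames[i], ref, fit_idx)
        d = fitted[dom_idx] - ref[dom_idx]
        vals[i] = np.sqrt(np.mean(np.sum(d * d, axis=1)))
    return TimeSeries(times=traj.times.copy(), values=vals, label=f"rmsd:{domain.name}")


def _centroid(model_coords: np.ndarray, idx: np.ndarray,
              elements: Sequence[str], mass_weighting: bool) -> np.ndarray:
    coords = model_coords[idx]
    if not mass_weighting:
        return coords.mean(axis=0)
    w = np.array([_MASSES.get(elements[i], 12.0) for i in idx])
    return (coords * w[:, None]).sum(axis=0) / w.sum()


def com_distance_series(
    traj: Trajectory,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
    mass_weighting: bool = True,
) -> TimeSeries:
    """Per-frame distance between the centroids of two selections."""
    idx_a = resolve_selection(traj.topology, sel_a)
    idx_b = resolve_selection(traj.topology, sel_b)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise AnalysisError("com_distance_series: empty selection")
    elements = [a.element for a in traj.topology.atoms]
    vals = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        ca = _centroid(traj.frames[i], idx_a, elements, mass_weighting)
        cb = _centroid(traj.frames[i], idx_b, elements, mass_weighting)
        vals[i] = np.linalg.norm(ca - cb)
    return TimeSeries(times=traj.times.copy(), values=vals, label="com_distance")


def _atom_idx(model: StructureModel, atom_id: tuple[str, int, str]) -> int:
    ch, resid, name = atom_id
    try:
        return model.atom_index(ch, resid, name)
    except KeyError:
        raise MissingAtomError(name, context=f"residue {ch}/{resid}") from None


def hbond_occupancy(traj: Trajectory, spec: HBondSpec) -> tuple[float, np.ndarray]:
    """Fraction of frames in which the hydrogen bond is formed.

    Returns (occupancy in [0, 1], per-frame boolean array).
    """
    d_i = _atom_idx(traj.topology, spec.donor)
    a_i = _atom_idx(traj.topology, spec.acceptor)
    h_i = _atom_idx(traj.topology, spec.hydrogen) if spec.hydrogen else None
    present = np.zeros(traj.n_frames, dtype=bool)
    for i in range(traj.n_frames):
        frame = traj.frames[i]
        dist = np.linalg.norm(frame[d_i] - frame[a_i])
        ok = dist <= spec.d_cut
        if ok and h_i is not None:
            dh = frame[h_i] - frame[d_i]
            da = frame[a_i] - frame[d_i]
            cosang = np.dot(dh, da) / (np.linalg.norm(dh) * np.linalg.norm(da))
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            ok = angle <= spec.angle_cut
        present[i] = ok
    return float(present.mean()), present


def tilt_angle_series(
    traj: Trajectory,
    pigment: tuple[str, int],
    registry,
    axis: ProteinAxis,
) -> TimeSeries:
    """Per-frame tilt of one carotenoid's S2 dipole against a fixed axis."""
    from .pigments import extract_pigment, pigment_dipole

    ch, resid = pigment
    vals = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        p = extract_pigment(traj.frame_model(i), ch, resid, registry)
        vals[i] = tilt_angle(pigment_dipole(p), axis)
    return TimeSeries(times=traj.times.copy(), values=vals,
                      label=f"tilt:{ch}/{resid}")
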