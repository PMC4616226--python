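"""Synthetic pigment–protein systems with analytic ground truth.

Everything the analysis pipeline measures on real structures can be
generated here with known answers: idealized chlorin rings and zigzag
polyene chains, a whole antenna-like complex with the plant-LHCII
cofactor complement, multi-frame trajectories with prescribed rigid-body
schedules plus Gaussian positional noise, and (Δstructure, ΔE) ensembles
with a known linear relation.

Templates use idealized geometry (Mg–N 2.05 Å, C–C 1.35 Å) rather than
crystallographic coordinates so that every expected value is analytic.
All randomness flows from one explicit integer seed through numpy's
PCG64 generator; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import AnalysisError
from .pigments import PigmentInstance
from .registry import PigmentRegistry, default_registry
from .structure import Atom, AtomSelection, DomainDefinition, StructureModel, Trajectory, resolve_selection

__all__ = [
    "SyntheticGroundTruth",
    "FrameTransformSchedule",
    "make_chlorin",
    "make_polyene",
    "chlorin_atoms",
    "polyene_atoms",
    "make_trajectory",
    "make_correlated_ensemble",
    "build_synthetic_antenna_complex",
    "make_switch_study",
]

MG_N_DISTANCE = 2.05       # Å, idealized chlorin Mg-N
POLYENE_BOND = 1.35        # Å, conjugated C-C
POLYENE_ANGLE = 120.0      # degrees


@dataclass
class SyntheticGroundTruth:
    """Everything needed to predict the analysis of a synthetic system."""

    seed: int | None = None
    noise_sigma: float = 0.0
    tilt_schedules_deg: dict[str, np.ndarray] = field(default_factory=dict)
    hbond_occupancy: float | None = None
    ensemble_slope: float | None = None
    ensemble_noise_sd: float | None = None
    ensemble_population_r: float | None = None
    extras: dict = field(default_factory=dict)


def _check_proper(orientation: Rotation) -> None:
    if np.linalg.det(orientation.as_matrix()) < 0:
        raise ValueError("orientation must be a proper rotation (det = +1)")


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

def _chlorin_template(variant: str) -> dict[str, np.ndarray]:
    d = MG_N_DISTANCE
    sites = {
        "MG": np.array([0.0, 0.0, 0.0]),
        "NA": np.array([0.0, d, 0.0]),
        "NB": np.array([-d, 0.0, 0.0]),
        "NC": np.array([0.0, -d, 0.0]),
        "ND": np.array([d, 0.0, 0.0]),
    }
    if variant == "chl_b":
        # 7-formyl oxygen off the B ring, slightly out of plane
        sites["OBD"] = np.array([-3.2, 1.6, 0.25])
    elif variant != "chl_a":
        raise ValueError(f"unknown chlorin variant {variant!r}")
    return sites


def chlorin_atoms(position, orientation: Rotation, variant: str, chain: str = "A",
                  resid: int = 601, serial_start: int = 1) -> list[Atom]:
    """Idealized chlorin as PDB atoms (HETATM records)."""
    _check_proper(orientation)
    resname = {"chl_a": "CLA", "chl_b": "CHL"}[variant]
    position = np.asarray(position, dtype=float)
    atoms = []
    for i, (name, site) in enumerate(_chlorin_template(variant).items()):
        atoms.append(Atom(
            serial=serial_start + i, name=name, resname=resname, resid=resid,
            chain=chain, position=orientation.apply(site) + position,
            element="Mg" if name == "MG" else name[0], record="HETATM",
        ))
    return atoms


def make_chlorin(position, orientation: Rotation, variant: str,
                 registry: PigmentRegistry | None = None,
                 chain: str = "A", resid: int = 601) -> PigmentInstance:
    """Idealized chlorin as a ready PigmentInstance.

    The NB→ND axis lies along the template x-axis before ``orientation``
    is applied, so the Qy direction equals ``orientation.apply([1,0,0])``.
    """
    registry = registry or default_registry()
    atoms = chlorin_atoms(position, orientation, variant, chain, resid)
    resname = atoms[0].resname
    entry = registry.lookup(resname)
    return PigmentInstance(
        pigment_id=(chain, resid, resname),
        atom_map={a.name: a.position for a in atoms},
        registry=entry,
    )


def _polyene_template(n_atoms: int, bond_length: float, bond_angle: float,
                      kink_deg: float = 0.0) -> np.ndarray:
    if n_atoms < 4:
        raise ValueError("polyene needs at least 4 atoms")
    if bond_length <= 0 or not 0 < bond_angle < 180:
        raise ValueError("invalid polyene geometry parameters")
    half = np.radians(bond_angle / 2.0)
    xs = np.arange(n_atoms) * bond_length * np.sin(half)
    ys = np.where(np.arange(n_atoms) % 2 == 0, 0.0, bond_length * np.cos(half))
    coords = np.column_stack([xs, ys, np.zeros(n_atoms)])
    coords -= coords.mean(axis=0)
    if kink_deg != 0.0:
        mid = n_atoms // 2
        pivot = coords[mid]
        rot = Rotation.from_euler("z", kink_deg, degrees=True)
        coords[mid:] = rot.apply(coords[mid:] - pivot) + pivot
    return coords


def polyene_atoms(position, orientation: Rotation, n_atoms: int = 22,
                  bond_length: float = POLYENE_BOND, bond_angle: float = POLYENE_ANGLE,
                  kink_deg: float = 0.0, resname: str = "LUT", chain: str = "A",
                  resid: int = 620, serial_start: int = 1) -> list[Atom]:
    """Planar zigzag polyene chain as PDB atoms; long axis = template x."""
    _check_proper(orientation)
    position = np.asarray(position, dtype=float)
    coords = _polyene_template(n_atoms, bond_length, bond_angle, kink_deg)
    return [
        Atom(serial=serial_start + i, name=f"C{i + 1}", resname=resname,
             resid=resid, chain=chain,
             position=orientation.apply(c) + position, element="C",
             record="HETATM")
        for i, c in enumerate(coords)
    ]


def make_polyene(position, orientation: Rotation, n_atoms: int = 22,
                 bond_length: float = POLYENE_BOND, bond_angle: float = POLYENE_ANGLE,
                 kink_deg: float = 0.0, registry: PigmentRegistry | None = None,
                 resname: str = "LUT", chain: str = "A",
                 resid: int = 620) -> PigmentInstance:
    """Idealized carotenoid chain as a ready PigmentInstance."""
    registry = registry or default_registry()
    atoms = polyene_atoms(position, orientation, n_atoms, bond_length, bond_angle,
                          kink_deg, resname, chain, resid)
    entry = registry.lookup(resname)
    # re-point the registry chain atoms at exactly the atoms generated
    from dataclasses import replace
    entry = replace(entry, chain_atoms=tuple(a.name for a in atoms))
    return PigmentInstance(
        pigment_id=(chain, resid, resname),
        atom_map={a.name: a.position for a in atoms},
        registry=entry,
    )


# ---------------------------------------------------------------------------
# Trajectories with prescribed motion
# ---------------------------------------------------------------------------

@dataclass
class FrameTransformSchedule:
    """Per-frame rigid transform applied to one atom selection.

    ``rotations`` (length n_frames, about ``pivot``) and/or
    ``translations`` (n_frames, 3).  ``truth_label``/``truth_values``
    let a schedule publish its intended observable (e.g. a tilt-angle
    course) into the ground-truth record.
    """

    selection: AtomSelection
    rotations: list[Rotation] | None = None
    pivot: np.ndarray | None = None
    translations: np.ndarray | None = None
    truth_label: str = ""
    truth_values: np.ndarray | None = None
    occupancy_truth: float | None = None

    def n_frames(self) -> int | None:
        if self.rotations is not None:
            return len(self.rotations)
        if self.translations is not None:
            return len(np.asarray(self.translations))
        return None


def make_trajectory(
    model: StructureModel,
    n_frames: int,
    noise_sigma: float = 0.0,
    schedules: tuple[FrameTransformSchedule, ...] = (),
    seed: int = 0,
    dt_ns: float = 1.0,
) -> tuple[Trajectory, SyntheticGroundTruth]:
    """Trajectory = scheduled rigid motion + i.i.d. Gaussian noise.

    Per frame, each schedule's rotation-about-pivot and translation are
    applied to its selection, then N(0, σ²) noise is added to every
    coordinate.  Reproducible from ``seed``; the ground truth records
    σ, the seed and every schedule's published observable.
    """
    if n_frames < 2:
        raise AnalysisError("a trajectory needs at least 2 frames")
    for s in schedules:
        n = s.n_frames()
        if n is not None and n != n_frames:
            raise AnalysisError(
                f"schedule length {n} != n_frames {n_frames}"
            )
    rng = np.random.default_rng(seed)
    base = model.coords
    frames = np.empty((n_frames, len(model), 3))
    sel_idx = [resolve_selection(model, s.selection) for s in schedules]
    for f in range(n_frames):
        coords = base.copy()
        for s, idx in zip(schedules, sel_idx):
            if len(idx) == 0:
                continue
            sub = coords[idx]
            if s.rotations is not None:
                pivot = np.zeros(3) if s.pivot is None else np.asarray(s.pivot, float)
                sub = s.rotations[f].apply(sub - pivot) + pivot
            if s.translations is not None:
                sub = sub + np.asarray(s.translations, float)[f]
            coords[idx] = sub
        if noise_sigma > 0:
            coords += rng.normal(0.0, noise_sigma, size=coords.shape)
        frames[f] = coords
    truth = SyntheticGroundTruth(seed=seed, noise_sigma=noise_sigma)
    for s in schedules:
        if s.truth_label and s.truth_values is not None:
            truth.tilt_schedules_deg[s.truth_label] = np.asarray(s.truth_values, float)
        if s.occupancy_truth is not None:
            truth.hbond_occupancy = s.occupancy_truth
    traj = Trajectory(topology=model, frames=frames,
                      times=np.arange(n_frames) * dt_ns)
    return traj, truth


# ---------------------------------------------------------------------------
# Correlated (Δstructure, ΔE) ensembles
# ---------------------------------------------------------------------------

def make_correlated_ensemble(
    n_sims: int,
    slope: float,
    noise_sd: float,
    seed: int = 0,
    x_range: tuple[float, float] = (0.5, 6.0),
):
    """Per-simulation (Δx, ΔE) points with ΔE = slope·Δx + N(0, noise_sd).

    Δx is uniform over ``x_range``.  The ground truth carries the
    population Pearson r implied by the generator:
    r = s·σ_x / sqrt(s²σ_x² + σ_ε²) with σ_x = range/√12.
    """
    from .switch import SwitchPoint

    if n_sims < 3:
        raise AnalysisError("an ensemble needs at least 3 simulations")
    rng = np.random.default_rng(seed)
    x = rng.uniform(x_range[0], x_range[1], size=n_sims)
    e = slope * x + rng.normal(0.0, noise_sd, size=n_sims)
    points = [
        SwitchPoint(sim_id=f"sim{chr(ord('A') + i) if i < 26 else i}",
                    delta_x=float(x[i]), delta_e=float(e[i]))
        for i in range(n_sims)
    ]
    sd_x = (x_range[1] - x_range[0]) / np.sqrt(12.0)
    denom = np.sqrt(slope**2 * sd_x**2 + noise_sd**2)
    pop_r = 0.0 if denom == 0 else slope * sd_x / denom
    truth = SyntheticGroundTruth(
        seed=seed, ensemble_slope=slope, ensemble_noise_sd=noise_sd,
        ensemble_population_r=float(pop_r),
    )
    return points, truth


# ---------------------------------------------------------------------------
# A whole antenna-like complex (synthetic stand-in)
# ---------------------------------------------------------------------------

# domain layout of the synthetic apoprotein (author-style numbering
# starting at 14, mirroring the published N-terminus definition 14-53)
SYNTHETIC_DOMAINS = {
    "nterm": DomainDefinition("nterm", [(14, 53)]),
    "helix_A": DomainDefinition("helix_A", [(54, 83)]),
    "helix_B": DomainDefinition("helix_B", [(88, 117)]),
    "helix_C": DomainDefinition("helix_C", [(122, 151)]),
}

TM_HELIX_SELECTION = AtomSelection(
    residue_ranges=[(54, 83), (88, 117), (122, 151)], names=("CA",)
)
NTERM_SELECTION = AtomSelection(residue_ranges=[(14, 53)], names=("CA",))


def _helix_ca(chain: str, start_resid: int, n_res: int, origin,
              serial_start: int, resnames: dict[int, str] | None = None) -> list[Atom]:
    """Ideal α-helix Cα trace along +z (rise 1.5 Å, 100°/residue, r 2.3 Å)."""
    origin = np.asarray(origin, dtype=float)
    resnames = resnames or {}
    atoms = []
    for i in range(n_res):
        ang = np.radians(100.0 * i)
        pos = origin + np.array([2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * i])
        resid = start_resid + i
        atoms.append(Atom(
            serial=serial_start + i, name="CA",
            resname=resnames.get(resid, "ALA"), resid=resid, chain=chain,
            position=pos, element="C", record="ATOM",
        ))
    return atoms


def _rot(axis: str, deg: float) -> Rotation:
    return Rotation.from_euler(axis, deg, degrees=True)


def build_synthetic_antenna_complex() -> tuple[StructureModel, dict]:
    """Synthetic idealized LHCII-monomer stand-in (not the deposited crystal).

    One chain carrying the published plant-antenna cofactor complement —
    8 Chl a (CLA 602-604, 610-614), 6 Chl b (CHL 601, 605-609), two
    luteins (LUT 620/621), violaxanthin (XAT 622), neoxanthin (NEX 623)
    and a DPPG lipid (LHG 624) — on a three-TM-helix Cα scaffold with an
    N-terminal tail (residues 14-53).  Geometry is idealized and fully
    deterministic: the protein axis is +z by construction, neoxanthin's
    polyene is laid at 60° to it, the luteins near-parallel to it, and
    Chla611/Chla612 form the closest, most strongly coupled chlorophyll
    pair.  Returns (model, metadata) where metadata records the intended
    ground-truth placements.
    """
    atoms: list[Atom] = []
    serial = 1

    def add(new_atoms: list[Atom]) -> None:
        nonlocal serial
        for a in new_atoms:
            a.serial = serial
            serial += 1
            atoms.append(a)

    # --- apoprotein scaffold ------------------------------------------------
    # N-terminal tail: extended arc on the stromal (+z) side
    for i, resid in enumerate(range(14, 54)):
        t = i / 39.0
        pos = np.array([
            -6.0 - 14.0 * t,                     # reaches out laterally
            4.0 * np.sin(3.0 * np.pi * t),       # gentle meander
            46.0 + 3.0 * np.sin(2.0 * np.pi * t),
        ])
        add([Atom(serial=0, name="CA", resname="GLY", resid=resid, chain="A",
                  position=pos, element="C", record="ATOM")])
    add(_helix_ca("A", 54, 30, origin=(0.0, 0.0, 0.0), serial_start=0))
    add(_helix_ca("A", 88, 30, origin=(10.0, 0.0, 0.0), serial_start=0))
    add(_helix_ca("A", 122, 30, origin=(5.0, 8.5, 0.0), serial_start=0,
                  resnames={131: "GLN"}))

    # --- chlorophylls -------------------------------------------------------
    chl_sites: dict[int, tuple[str, np.ndarray, Rotation]] = {
        # resid: (variant, Mg position, ring orientation)
        602: ("chl_a", np.array([-4.0, 6.0, 30.0]), _rot("y", 80) * _rot("z", 15)),
        603: ("chl_a", np.array([14.0, 9.0, 31.0]), _rot("y", 75) * _rot("z", -30)),
        604: ("chl_a", np.array([-6.0, -5.0, 27.0]), _rot("y", 95) * _rot("z", 60)),
        610: ("chl_a", np.array([-8.0, 3.0, 12.0]), _rot("y", 85) * _rot("z", 100)),
        611: ("chl_a", np.array([-2.0, -9.0, 9.0]), _rot("y", 70) * _rot("z", 10)),
        612: ("chl_a", np.array([5.5, -12.0, 12.0]), _rot("y", 78) * _rot("z", 25)),
        613: ("chl_a", np.array([16.0, -6.0, 8.0]), _rot("y", 88) * _rot("z", -45)),
        614: ("chl_a", np.array([20.0, 1.0, 14.0]), _rot("y", 92) * _rot("z", -70)),
        601: ("chl_b", np.array([-12.0, 8.0, 20.0]), _rot("y", 72) * _rot("z", 130)),
        605: ("chl_b", np.array([2.0, 14.0, 24.0]), _rot("y", 96) * _rot("z", 200)),
        606: ("chl_b", np.array([9.0, 13.0, 16.0]), _rot("y", 82) * _rot("z", 250)),
        607: ("chl_b", np.array([4.5, 11.0, 7.0]), _rot("y", 76) * _rot("z", 310)),
        608: ("chl_b", np.array([-14.0, -2.0, 16.0]), _rot("y", 90) * _rot("z", 40)),
        609: ("chl_b", np.array([-10.0, -10.0, 22.0]), _rot("y", 84) * _rot("z", 75)),
    }
    for resid, (variant, pos, orient) in chl_sites.items():
        add(chlorin_atoms(pos, orient, variant, chain="A", resid=resid))

    # --- carotenoids --------------------------------------------------------
    # luteins near-parallel to the protein axis (template x -> ~z)
    add(polyene_atoms((2.0, 3.0, 20.0), _rot("y", -82), resname="LUT",
                      resid=620, chain="A"))                       # Lut 1, tilt 8°
    add(polyene_atoms((11.0, 5.0, 21.0), _rot("y", -78), resname="LUT",
                      resid=621, chain="A"))                       # Lut 2, tilt 12°
    # violaxanthin moderately tilted
    add(polyene_atoms((-10.0, 12.0, 18.0), _rot("y", -70), resname="XAT",
                      resid=622, chain="A"))                       # Vio, tilt 20°
    # neoxanthin at 60° to the protein axis: template x -> (sin60, 0, cos60)
    add(polyene_atoms((18.0, 14.0, 22.0), _rot("y", -30), resname="NEX",
                      resid=623, chain="A"))                       # Neo, tilt 60°

    # --- DPPG lipid next to Chla611's Mg ------------------------------------
    lipid_origin = np.array([-3.5, -11.5, 6.0])
    lipid_sites = {
        "P": (0.0, 0.0, 0.0), "O1": (1.2, 0.9, 0.0), "O2": (-1.2, 0.9, 0.0),
        "O3": (0.0, -0.9, 1.2), "O4": (0.0, -0.9, -1.2),
        "C1": (0.0, 2.2, 0.6), "C2": (0.8, 3.4, 0.2), "C3": (0.4, 4.7, 0.9),
    }
    add([
        Atom(serial=0, name=name, resname="LHG", resid=624, chain="A",
             position=lipid_origin + np.array(off),
             element=name[0] if not name[0].isdigit() else "C", record="HETATM")
        for name, off in lipid_sites.items()
    ])

    # --- GLN131 side-chain donor 2.9 Å from the Chlb607 formyl oxygen -------
    b607 = chl_sites[607]
    formyl = b607[2].apply(_chlorin_template("chl_b")["OBD"]) + b607[1]
    ne2 = formyl + np.array([0.0, 2.9, 0.0])
    he2 = ne2 + (formyl - ne2) / np.linalg.norm(formyl - ne2) * 1.0  # H on the bond
    add([
        Atom(serial=0, name="NE2", resname="GLN", resid=131, chain="A",
             position=ne2, element="N", record="ATOM"),
        Atom(serial=0, name="HE2", resname="GLN", resid=131, chain="A",
             position=he2, element="H", record="ATOM"),
    ])

    meta = {
        "neo_tilt_deg": 60.0,
        "lut1_tilt_deg": 8.0,
        "lut2_tilt_deg": 12.0,
        "vio_tilt_deg": 20.0,
        "neo_id": ("A", 623), "lut1_id": ("A", 620), "lut2_id": ("A", 621),
        "vio_id": ("A", 622),
        "terminal_emitter_pair": (("A", 611), ("A", 612)),
        "b606_b607_pair": (("A", 606), ("A", 607)),
        "a603_lut2_pair": (("A", 603), ("A", 621)),
        "dppg_resid": 624,
        "hbond": {
            "donor": ("A", 131, "NE2"), "hydrogen": ("A", 131, "HE2"),
            "acceptor": ("A", 607, "OBD"),
        },
        "domains": SYNTHETIC_DOMAINS,
    }
    return StructureModel(atoms, source="synthetic antenna complex"), meta


# ---------------------------------------------------------------------------
# A six-simulation switch study at toy scale
# ---------------------------------------------------------------------------

def make_switch_study(
    n_sims: int = 6,
    n_frames: int = 40,
    noise_sigma: float = 0.03,
    seed: int = 0,
    dt_ns: float = 25.0,
):
    """Generate the full synthetic study: a crystal-like reference plus
    ``n_sims`` independent trajectories with prescribed conformational
    drifts, mirroring the study design of several ~µs simulations at toy
    scale.

    Per simulation s (amplitude factor a_s increasing across sims):

    * the N-terminal tail translates towards the DPPG lipid by a_s Å;
    * the terminal-emitter chlorophyll (resid 612) rotates about its Mg
      by 4°·a_s, weakening its coupling to resid 611;
    * chlorophyll 603 rotates by 3°·a_s about its Mg, strengthening its
      coupling to Lut 2 in proportion to the neoxanthin drive;
    * neoxanthin tilts linearly from 60° to 60° + 5°·a_s over the frames
      (kinking away from the protein axis);
    * the Chlb607-formyl⋯GLN131 hydrogen bond is broken in 70% of the
      frames (occupancy 0.3) by displacing the donor group.

    Returns (crystal_model, meta, dict sim_id -> (Trajectory, truth)).
    """
    crystal, meta = build_synthetic_antenna_complex()
    coords = crystal.coords

    def mg_of(resid: int) -> np.ndarray:
        return crystal.atoms[crystal.atom_index("A", resid, "MG")].position

    dppg_sel = AtomSelection(residue_ranges=[(624, 624)])
    dppg_idx = resolve_selection(crystal, dppg_sel)
    dppg_center = coords[dppg_idx].mean(axis=0)
    nterm_idx = resolve_selection(crystal, NTERM_SELECTION)
    nterm_center = coords[nterm_idx].mean(axis=0)
    toward_dppg = dppg_center - nterm_center
    toward_dppg /= np.linalg.norm(toward_dppg)

    neo_base = meta["neo_tilt_deg"]
    sims: dict[str, tuple] = {}
    rng = np.random.default_rng(seed)
    for s in range(n_sims):
        a = 1.0 + s  # amplitude factor 1..n_sims
        sim_id = f"sim{chr(ord('A') + s)}"
        # neoxanthin tilt ramp (rotation about y continues the -30° placement)
        neo_extra = np.linspace(0.0, 5.0 * a, n_frames)
        neo_sched = FrameTransformSchedule(
            selection=AtomSelection(residue_ranges=[(623, 623)]),
            rotations=[_rot("y", float(d)) for d in neo_extra],
            pivot=coords[resolve_selection(crystal, AtomSelection(
                residue_ranges=[(623, 623)]))].mean(axis=0),
            truth_label="neo_tilt_deg",
            truth_values=neo_base + neo_extra,
        )
        nterm_sched = FrameTransformSchedule(
            selection=AtomSelection(residue_ranges=[(14, 53)]),
            translations=np.tile(toward_dppg * a, (n_frames, 1)),
        )
        a612_sched = FrameTransformSchedule(
            selection=AtomSelection(residue_ranges=[(612, 612)]),
            rotations=[_rot("z", 4.0 * a)] * n_frames,
            pivot=mg_of(612),
        )
        a603_sched = FrameTransformSchedule(
            selection=AtomSelection(residue_ranges=[(603, 603)]),
            rotations=[_rot("z", 3.0 * a)] * n_frames,
            pivot=mg_of(603),
        )
        # hydrogen bond broken in 70% of frames, deterministic pattern
        broken = np.zeros(n_frames, dtype=bool)
        broken[int(round(0.3 * n_frames)):] = True
        donor_shift = np.where(broken[:, None], np.array([0.0, 2.0, 0.0]), 0.0)
        hbond_sched = FrameTransformSchedule(
            selection=AtomSelection(residue_ranges=[(131, 131)],
                                    names=("NE2", "HE2")),
            translations=donor_shift,
            occupancy_truth=float((~broken).mean()),
        )
        traj, truth = make_trajectory(
            crystal, n_frames, noise_sigma=noise_sigma,
            schedules=(neo_sched, nterm_sched, a612_sched, a603_sched, hbond_sched),
            seed=int(rng.integers(0, 2**31 - 1)), dt_ns=dt_ns,
        )
        truth.extras["amplitude"] = a
        sims[sim_id] = (traj, truth)
    return crystal, meta, sims
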