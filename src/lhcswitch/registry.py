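"""Pigment registry: which residue codes are pigments and how their
transition dipoles are defined.

Chlorophyll Qy dipoles follow the standard tetrapyrrole-nitrogen
convention: the axis runs from the B-ring nitrogen (NB) to the D-ring
nitrogen (ND), centred on the Mg.  Carotenoid S2 dipoles lie along the
conjugated polyene chain; only the central portion of the chain defines
the direction, because the chain ends bend with the binding pocket.

Defaults ship the het-codes used by the plant antenna depositions
(CLA = Chl a, CHL = Chl b, LUT = lutein, NEX = neoxanthin,
XAT = violaxanthin, LHG = phosphatidylglycerol) but every field is
configurable: het-code dialects vary between depositions, and effective
dipole magnitudes are a modelling choice, not an observable printed in
structure files.

Default magnitudes are literature-typical effective values:
μ(Chl a) = 4.0 D, μ(Chl b) = 3.4 D, μ(Car S2) = 13.0 D.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from .errors import RegistryError

__all__ = ["PigmentRegistryEntry", "PigmentRegistry", "default_registry"]

PIGMENT_CLASSES = ("chl_a", "chl_b", "carotenoid", "lipid")


@dataclass(frozen=True)
class PigmentRegistryEntry:
    """How one pigment species maps onto atoms and a transition dipole."""

    name: str
    resname_codes: tuple[str, ...]
    pigment_class: str
    magnitude_debye: float = 0.0
    # chlorophyll-type dipole: axis tail -> axis head, centred on center_atom
    axis_atoms: tuple[str, str] = ("NB", "ND")
    center_atom: str = "MG"
    # carotenoid-type dipole: ordered conjugated-chain atom names
    chain_atoms: tuple[str, ...] = ()
    # fraction of the chain (centred) used to define the S2 direction
    central_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.pigment_class not in PIGMENT_CLASSES:
            raise RegistryError(f"unknown pigment class {self.pigment_class!r}")
        if self.pigment_class in ("chl_a", "chl_b", "carotenoid"):
            if self.magnitude_debye <= 0:
                raise RegistryError(
                    f"{self.name}: chromophores need magnitude_debye > 0"
                )
        if self.pigment_class == "carotenoid" and len(self.chain_atoms) < 2:
            raise RegistryError(f"{self.name}: carotenoid needs >=2 chain atoms")
        if not 0.0 < self.central_fraction <= 1.0:
            raise RegistryError(f"{self.name}: central_fraction must be in (0, 1]")

    @property
    def dipole_atom_names(self) -> tuple[str, ...]:
        """Every atom name the dipole definition requires."""
        if self.pigment_class in ("chl_a", "chl_b"):
            return (*self.axis_atoms, self.center_atom)
        if self.pigment_class == "carotenoid":
            return self.chain_atoms
        return ()


class PigmentRegistry:
    """Lookup table from residue code to registry entry."""

    def __init__(self, entries: Iterable[PigmentRegistryEntry]):
        self.entries: dict[str, PigmentRegistryEntry] = {}
        self._by_resname: dict[str, PigmentRegistryEntry] = {}
        for e in entries:
            if e.name in self.entries:
                raise RegistryError(f"duplicate registry entry {e.name!r}")
            self.entries[e.name] = e
            for code in e.resname_codes:
                if code in self._by_resname:
                    raise RegistryError(f"residue code {code!r} claimed twice")
                self._by_resname[code] = e

    def lookup(self, resname: str) -> PigmentRegistryEntry | None:
        return self._by_resname.get(resname)

    def __getitem__(self, name: str) -> PigmentRegistryEntry:
        return self.entries[name]

    def replace_entry(self, name: str, **changes) -> "PigmentRegistry":
        """New registry with one entry's fields replaced."""
        if name not in self.entries:
            raise RegistryError(f"no registry entry {name!r}")
        new = [replace(e, **changes) if e.name == name else e
               for e in self.entries.values()]
        return PigmentRegistry(new)

    def classes_of(self, resname: str) -> str | None:
        e = self.lookup(resname)
        return e.pigment_class if e else None


# A ~40-carbon xanthophyll backbone: C1..C40 covers idealized chains; real
# depositions name the conjugated carbons C5..C15/C15'..C5' but the registry
# is always re-pointed at the file's own names at integration time.
_POLYENE_ATOMS = tuple(f"C{i}" for i in range(1, 23))


def default_registry() -> PigmentRegistry:
    """Registry for the standard plant-antenna cofactor complement."""
    return PigmentRegistry([
        PigmentRegistryEntry(
            name="chl_a", resname_codes=("CLA",), pigment_class="chl_a",
            magnitude_debye=4.0,
        ),
        PigmentRegistryEntry(
            name="chl_b", resname_codes=("CHL",), pigment_class="chl_b",
            magnitude_debye=3.4,
        ),
        PigmentRegistryEntry(
            name="lutein", resname_codes=("LUT",), pigment_class="carotenoid",
            magnitude_debye=13.0, chain_atoms=_POLYENE_ATOMS,
        ),
        PigmentRegistryEntry(
            name="neoxanthin", resname_codes=("NEX",), pigment_class="carotenoid",
            magnitude_debye=13.0, chain_atoms=_POLYENE_ATOMS,
        ),
        PigmentRegistryEntry(
            name="violaxanthin", resname_codes=("XAT",), pigment_class="carotenoid",
            magnitude_debye=13.0, chain_atoms=_POLYENE_ATOMS,
        ),
        PigmentRegistryEntry(
            name="dppg", resname_codes=("LHG", "DPG"), pigment_class="lipid",
        ),
    ])


def load_registry(path: str | Path) -> PigmentRegistry:
    """Read a registry from a TOML file.

    Layout: one ``[registry.<name>]`` table per entry with keys
    ``resnames``, ``class`` and the optional dipole fields.
    """
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    tables = data.get("registry")
    if not tables:
        raise RegistryError(f"{path}: no [registry.*] tables")
    entries = []
    for name, t in tables.items():
        entries.append(PigmentRegistryEntry(
            name=name,
            resname_codes=tuple(t["resnames"]),
            pigment_class=t["class"],
            magnitude_debye=float(t.get("magnitude_debye", 0.0)),
            axis_atoms=tuple(t.get("axis_atoms", ("NB", "ND"))),
            center_atom=t.get("center_atom", "MG"),
            chain_atoms=tuple(t.get("chain_atoms", ())),
            central_fraction=float(t.get("central_fraction", 0.5)),
        ))
    return PigmentRegistry(entries)
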