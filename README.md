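# lhcswitch

Structure-to-energetics analysis of plant light-harvesting complexes.

Antenna complexes such as LHCII, the major light-harvesting complex of
plants, regulate photosynthesis by switching between a light-harvesting
conformation and a quenched, photoprotective one. The switch is believed
to be structural: small rearrangements of the protein (notably the
disordered N-terminus) and of the xanthophylls (notably neoxanthin
kinking away from the membrane normal) modulate the excitonic coupling
between chlorophyll pairs — above all the terminal-emitter pair
Chla611–Chla612, the lowest-energy site from which excitation leaves
the complex. `lhcswitch` provides the complete analysis chain needed to
quantify that picture from coordinates: from a crystal structure or an
ordered trajectory it computes transition dipoles, pairwise excitonic
couplings, carotenoid tilt angles, B-factors, per-domain RMSD,
hydrogen-bond occupancy, and the cross-simulation correlations between
structural deltas and coupling deltas.

## The model

Each chlorophyll carries a Qy transition dipole along its NB→ND
tetrapyrrole axis, centred on the Mg (μ(Chl a) = 4.0 D,
μ(Chl b) = 3.4 D by default); each carotenoid carries an S2←S0 dipole
along the principal axis of the central portion of its conjugated
polyene chain (μ = 13.0 D). The excitonic coupling between two pigments
is computed in the point-dipole approximation

    V = f · C · κ · μ₁ μ₂ / R³ ,    κ = μ̂₁·μ̂₂ − 3 (μ̂₁·R̂)(μ̂₂·R̂)

with μ in Debye, R in Å, V in cm⁻¹, screening f (default 1), and
C = e²/(4πε₀) = 5034.12 cm⁻¹·Å³·D⁻². At short range the extended-dipole
model replaces each transition by charges ±q = ±μ/l separated by
l (default 8.7 Å) and sums the four Coulomb terms; the two models agree
as l/R → 0. Carotenoid tilt angles are measured against the protein's
pseudo-C2 axis (the membrane normal) and folded to [0°, 90°];
B-factors are B = (8π²/3)⟨|Δr|²⟩ after rigid-body superposition.

Per-simulation means are reduced to deltas against the crystal
reference — ΔE for couplings, Δd for the N-terminus–DPPG distance,
Δθ for the neoxanthin tilt — and a Pearson correlation with a trend
line is fitted over the ensemble of simulations, with the crystal at
the origin.

## Worked example

Structures are plain PDB text; the `lhcswitch.synthetic` module builds
a fully idealized antenna complex with the plant-LHCII cofactor
complement and known geometry:

```python
import lhcswitch as L
from lhcswitch.synthetic import build_synthetic_antenna_complex, TM_HELIX_SELECTION

model, meta = build_synthetic_antenna_complex()
reg = L.default_registry()

census = L.cofactor_census(model, reg)
print(f"cofactors: {census['chl_a']} Chl a + {census['chl_b']} Chl b "
      f"+ {census['carotenoid']} xanthophylls = {census['pigments_total']} pigments")

pair = meta["terminal_emitter_pair"]          # (("A", 611), ("A", 612))
v = L.crystal_couplings(model, [pair], reg)[pair]
print(f"Chla611-Chla612 point-dipole coupling: {v.energy_cm:.1f} cm^-1 "
      f"(kappa = {v.kappa:.2f}, R = {v.distance_R:.2f} A)")

d1 = L.pigment_dipole(L.extract_pigment(model, "A", 611, reg))
d2 = L.pigment_dipole(L.extract_pigment(model, "A", 612, reg))
ext = L.extended_dipole_coupling(d1, d2, L.ExtendedDipoleParams(length_l=8.7))
print(f"extended-dipole (l = 8.7 A):          {ext.energy_cm:.1f} cm^-1")

axis = L.protein_axis(model, TM_HELIX_SELECTION)
neo = L.car_s2_dipole(L.extract_pigment(model, *meta["neo_id"], reg))
print(f"neoxanthin S2 tilt vs protein axis:   {L.tilt_angle(neo, axis):.1f} deg")
```

prints

```
cofactors: 8 Chl a + 6 Chl b + 4 xanthophylls = 18 pigments
Chla611-Chla612 point-dipole coupling: 110.6 cm^-1 (kappa = 0.88, R = 8.62 A)
extended-dipole (l = 8.7 A):          70.9 cm^-1
neoxanthin S2 tilt vs protein axis:   59.9 deg
```

The terminal-emitter pair sits 8.6 Å apart, so the point-dipole value
(110.6 cm⁻¹) overestimates the coupling; the extended-dipole model
attenuates it to 70.9 cm⁻¹, the expected short-range behaviour. The
neoxanthin polyene is laid at 60° to the protein axis by construction
and the pipeline reads back 59.9°.

A shell interface wraps the same functions; every subcommand emits tidy
CSV:

```sh
lhcswitch synth --n-frames 40 --seed 1 --out-pdb traj.pdb --out-truth truth.json
lhcswitch couplings traj.pdb --pair A/611:A/612 -o couplings.csv
lhcswitch angles traj.pdb --carotenoid A/623 --axis-selection A/54-151/CA -o tilt.csv
lhcswitch distance traj.pdb --sel-a A/14-53/CA --sel-b A/624-624 -o dist.csv
lhcswitch switch points.csv          # ensemble Pearson fit, JSON out
```

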