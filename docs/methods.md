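# Methods

This note documents the models and numerical choices behind
`lhcswitch`, what the synthetic generators do and do not emulate, and
the limits of what the test battery demonstrates.

## Coordinates, units, numbering

Coordinates are ångström throughout; trajectory times are nanoseconds.
The canonical structure format is fixed-width PDB (v3.3
ATOM/HETATM/MODEL/ENDMDL); multi-model PDB is the canonical trajectory
container, chosen so that every input and fixture is plain text and the
whole pipeline is testable without binary readers (binary formats can
be adapted behind the same `Trajectory` contract). Author residue
numbering is preserved verbatim — published domain definitions refer to
deposition numbering (e.g. an N-terminus spanning residues 14–53; note
that range holds 40 residues even where it is conventionally described
as "the first 39"). Alternate locations are resolved to the
highest-occupancy conformer, ties keeping the first encountered, which
makes parsing deterministic. Atoms that a dipole definition needs but
that are absent (crystal structures do omit disordered tails) raise a
named `MissingAtomError`; nothing is ever silently substituted.

## Transition dipoles

**Chlorophyll Qy.** The Qy dipole runs from the B-ring nitrogen (NB) to
the D-ring nitrogen (ND), centred on the Mg. Both the axis atoms and
the centre are per-entry registry settings: the midpoint of NB–ND is a
one-line configuration change for users who prefer it, and the default
(Mg) was chosen because it is the coordination centre reported by
ligand analyses. Default magnitudes are literature-typical effective
values — μ(Chl a) = 4.0 D, μ(Chl b) = 3.4 D — and are explicitly
configuration, not physics derived here: absolute coupling values scale
with μ₁μ₂ and any comparison across parameter sets must state its μ.

**Carotenoid S2.** The S2←S0 dipole lies along the conjugated polyene
chain. Because the chain ends bend with the binding pocket, the
direction is the dominant principal axis (largest-variance
eigenvector, computed by SVD) of the *central portion* of the chain —
by default the middle 50 % of the registry's ordered chain-atom list —
signed from the first listed atom towards the last, centred on the
centroid of those atoms. The 50 % fraction is a design choice in the
absence of a universal convention; it is configurable per registry
entry, and the sign convention is irrelevant for tilt angles (folded
below) and enters couplings only as a global sign.

## Excitonic couplings

Point-dipole: V = f·C·κ·μ₁μ₂/R³ with κ = μ̂₁·μ̂₂ − 3(μ̂₁·R̂)(μ̂₂·R̂).
The conversion constant C = e²/(4πε₀) expressed in cm⁻¹·Å³·D⁻² is
fixed at 5034.1166, assembled from CODATA values
(14.399645 eV·Å × 0.20819433² × 8065.5439 cm⁻¹/eV); the test-suite
re-derives it independently. It is deliberately not a parameter —
published dialects differ in rounding (5.04 × 10³ is common) and a
fixed constant keeps results reproducible. Dielectric screening f
defaults to 1 (vacuum) and simply scales V.

Extended-dipole: each transition becomes ±q = ±μ/l at
centre ± (l/2)·μ̂ and V is the sum of the four inter-dipole Coulomb
terms with the same constant. Default l = 8.7 Å, a common literature
choice for the Chl Qy transition. The model converges to the
point-dipole value as l/R → 0 (verified as a monotone property) and
attenuates the coupling when R is comparable to l — the regime where
the point-dipole approximation overstates fluctuations at closely
coupled pairs such as the terminal emitter.

Crystal reference couplings are always recomputed from the reference
model with the active registry, never stored as numbers, so that every
Δ is internally consistent with the parameter set in force.

## Structural descriptors

**Protein axis.** The membrane-normal/pseudo-C2 reference is the
largest-variance principal axis of a transmembrane-helix Cα selection
(equivalently, the smallest-inertia axis), signed towards a
configurable reference atom on the stromal side; a
`lab_z_after_alignment` mode returns (0,0,1) for structures already
superposed to an axis-aligned reference. Degenerate inertia tensors
are rejected rather than tie-broken.

**Tilt angles** are arccos |μ̂·ẑ| folded to [0°, 90°], because a
transition dipole has no physical sign; a crystal-like ~60° placement
and a strongly kinked ~90° configuration are both representable either
way, and folding makes the series continuous under sign flips of the
principal axis.

**Superposition** is proper-rotation (Kabsch) least squares via
`scipy.spatial.transform.Rotation.align_vectors`; reflections are
never allowed, fewer than three or collinear fit atoms are errors.

**B-factors**: frames are fitted onto their mean structure over an
explicit fit selection, with one refinement pass (fit to frame 0 →
average → refit to the average) rather than a convergence loop — the
second pass is already within noise of the fixed point and keeps the
procedure deterministic. Then B = (8π²/3)·⟨|r − ⟨r⟩|²⟩ per atom. Note
the superposition estimates 6 rigid-body degrees of freedom from the
data, which biases B low by roughly 6/(3N) relative to the generative
σ (≈3 % for the 64-atom test system); the 5 % recovery tolerance in
the tests accounts for this, and for large selections the bias is
negligible.

**Domain RMSD**: each frame is superposed over a fit selection
(canonically the rigid TM-helix backbone) and the RMSD is evaluated
over the domain's backbone atoms *without refitting*, so a mobile
peripheral domain reports genuine displacement relative to the rigid
core instead of being partially absorbed into the fit.

**Hydrogen bonds**: a frame counts as bonded iff donor–acceptor
distance ≤ 3.5 Å and, when a hydrogen is given, the
H–donor–acceptor angle ≤ 30°. These are common MD-practice cutoffs,
exposed as parameters; occupancy is the bonded-frame fraction and is
monotone non-decreasing in the distance cutoff by construction.

## Ensemble (switch) analysis

Each simulation is reduced to the arithmetic mean of its series after
discarding a leading equilibration fraction (default 0.0 — full-series
averages — configurable). Deltas against the crystal support two
conventions: `signed` (sim − crystal, the default) and
`magnitude_decrease` (|crystal| − |sim|), because "the coupling
decreased by X" phrasings are ambiguous when couplings are signed; the
two conventions are reported explicitly and never mixed in one fit.
The ensemble Pearson r and least-squares trend line are computed over
the per-simulation points with the crystal contributing an exact
(0, 0) point by default (it is a real member of the ensemble, not a
fit constraint); duplicate points are legitimate and excluding the
origin changes n by exactly one, which the result records.

The synchronization scan pairs two same-length series frame by frame
and reports their Pearson r per trajectory, never pooled: pooling
across simulations would manufacture correlation out of
between-simulation offsets and is exactly the artefact the per-sim
design guards against. No significance test is attached to r.

## Synthetic data: what it emulates and what it does not

The generators produce idealized chlorin rings (Mg–N 2.05 Å, the four
nitrogens on the in-plane axes, a formyl oxygen on the b-variant),
planar zigzag polyenes (C–C 1.35 Å, 120° bond angle, optional midpoint
kink), an antenna-like complex carrying the full plant-LHCII cofactor
complement (8 Chl a + 6 Chl b + 2 luteins + violaxanthin + neoxanthin
+ a DPPG lipid) on a three-TM-helix Cα scaffold with an N-terminal
tail, and trajectories built from per-selection rigid-body schedules
(tilt ramps, displacements, H-bond toggles) plus i.i.d. Gaussian
positional noise. All randomness flows from one explicit seed through
numpy's PCG64 generator. The six-simulation study driver
(`make_switch_study`, defaults: 6 simulations × 40 frames, σ = 0.03 Å,
amplitude factors 1…6) prescribes, per simulation, an N-terminus
displacement towards the lipid, a proportional terminal-emitter
reorientation, a neoxanthin tilt ramp from 60° towards 90°, a
proportional Chla603 reorientation, and a 0.3-occupancy H-bond toggle —
so the ensemble correlations, the H-bond loss and the rigid-core /
mobile-periphery RMSD contrast all have generator-known answers. The
problem sizes are the package's chosen test conditions: large enough
for the analytic tolerances (e.g. 2000 frames for the 5 % B-factor
recovery), small enough that the whole battery runs in seconds.

What the synthetic data does **not** emulate: force-field dynamics,
solvent and membrane atoms, anharmonic or correlated thermal motion,
realistic pigment internal flexibility, or quantum-chemical site
energies. Passing the recovery tests therefore demonstrates that the
*analysis machinery* is correct against known ground truth — not that
any particular physical system behaves this way, and absolute coupling
magnitudes on real structures remain conditional on the registry's μ,
screening and dipole-placement choices. Microsecond-scale MD
observables (absolute coupling time courses, equilibrated solution
averages) are outside desk scale by design and are covered instead by
these prescribed-schedule recoveries.

## Degenerate inputs and tie-breaks

Coincident dipole centres, coincident extended-dipole charge sites,
zero-variance chains, collinear superposition sets, constant series in
a correlation, and empty selections where a non-empty one is required
are all hard errors, not warnings. Empty *results* of a selection are
valid (an empty index list); analyses that need atoms then fail loudly.
Sign tie-breaks: the carotenoid dipole takes its sign from the
first→last chain-atom ordering; the protein axis from the reference
atom (or +z when none is given).
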