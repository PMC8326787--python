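# Methods

This note documents the quantities pentagate computes, the conventions and
defaults behind them, what the synthetic generator does and does not emulate,
and the numerical choices a maintainer should know about. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The system and its observables

GLIC, the proton-gated channel of *Gloeobacter violaceus*, is a homopentamer
with fivefold (pseudo)symmetry about the membrane-normal pore axis. Each
subunit contributes an extracellular β-sandwich domain (ECD) and a
four-helix transmembrane domain (TMD) whose M2 helix lines the pore. Gating
couples protonation of interfacial glutamates (E35 in the β1–β2 loop, E243
on upper M2) to rearrangements of loop F (T158), the M2–M3 loop (E243–P250,
containing K248), quaternary contraction/untwisting of the ECD, and
expansion and wetting of the pore around the 9′ hydrophobic gate (I233).
The package turns these statements into numbers:

| observable | definition | key defaults |
|---|---|---|
| pore axis | total-least-squares line through per-residue Cα ring centroids | lining residues 222–247 |
| prime index | residue − 224 (233 → 9′, 237 → 13′) | M2 range 222–247 |
| pore profile | per-residue mean perpendicular distance of ring atoms to the axis | atom CA; ring kept if ≥ 4/5 chains |
| gate radius | mean distance of the five I233 Cβ atoms to the axis | residue 233, atom CB |
| hydration | water oxygens with axial coordinate in the closed interval between the 9′ and 13′ Cα-ring centroids and ≤ r_cut off-axis | r_cut = 6.0 Å |
| ECD spread | √⟨r⊥²⟩ over Cα of residues 20–190, unit weights | — |
| domain twist | circular mean over subunits of the dihedral (ECDᵢ COM, ECD COM, TMD COM, TMDᵢ COM) | ECD 20–190, TMD 197–313, Cα COMs |
| ion coordination | distinct Na⁺ within 5.0 Å (inclusive) of any E35 carboxylate O | stride 10 ns, last 300 ns |
| salt bridge | any K248 side-chain N within 4.0 Å of any E243 carboxylate O, intrasubunit | — |
| loop PCA | covariance eigendecomposition of per-subunit loop Cα coordinates | loop 243–250, core 222–242 ∪ 251–270 |

All distances are Ångström, plain Euclidean, atom-centre to atom-centre; no
van-der-Waals radius is subtracted from pore radii (the profile is a Cα/Cβ
centre-distance profile, not a solvent-accessible HOLE/CHAP profile — a
deliberate non-goal). No periodic-boundary imaging is applied: the
protein-internal distances used here are image-safe for the box sizes these
systems use, and the synthetic fixtures have no box.

## Conventions that were genuinely open

Several conventions are not fixed by common usage and had to be chosen; they
are configuration, not constants, and the choices are recorded here.

**Channel axis.** Deposited models carry no axis. The axis is the first
principal direction of the per-residue ring centroids of the pore-lining Cα
atoms (222–247): each residue present in all five chains contributes one
centroid, and the best-fit (total-least-squares) line through the centroids
is robust, parameter-free, and exact for C5-symmetric input. The direction
is oriented so the ECD centroid projects positively ("up" = extracellular),
which fixes profile ordering and the sign of axial coordinates.

**Twist sign.** Dihedrals use the standard IUPAC sign convention. With the
axis oriented toward the ECD, rotating the whole ECD by +δ about the axis
yields a twist of +δ; a mirror-image assembly yields −δ. The circular mean
over subunits avoids ±180° wraparound artifacts. COMs are computed from Cα
atoms with unit weights, consistent with every other Cα-based measure
(mass-weighting all-atom COMs is available but not the default).

**"Non-loop" Cα selection.** Backbone comparisons exclude the flexible
loops: the default is (17–192 ∪ 196–314) minus β1–β2 (30–36), loop F
(151–160), and M2–M3 (243–250). The exact loop windows are configurable
because no single enumeration is canonical.

**Chain correspondence between pentamers.** Deposited chain labels need not
correspond, so model-to-model RMSD orders each pentamer's chains
azimuthally about its own axis (counterclockwise viewed from the
extracellular side; the complementary neighbour of subunit i is i+1) and
takes the cyclic offset minimising the fitted RMSD. This makes the measure
label-independent and symmetric in its arguments.

**Loop-PCA observation frame.** Treating each subunit as one observation
requires a common frame; superposing whole pentamers would leave subunits
72° apart and PC1 would measure that rotation. Each subunit's flanking core
(M2 222–242 plus M3 251–270 Cα) is therefore superposed onto a designated
reference subunit (azimuthally first chain of the first model) before the
loop Cα coordinates are extracted. This is the main sensitivity of the
explained-variance fractions. Components are eigenvectors of the (n−1)-
normalised row covariance with no per-coordinate scaling (all coordinates
share units); each component's sign is fixed so its largest-magnitude
loading is positive, making results deterministic across eigensolvers.

**Bootstrap.** Replicate summaries are percentile bootstraps of the median:
`default_rng(seed).integers(0, n, (n_boot, n))` index draws, `np.percentile`
with linear interpolation, defaults level 0.95 and n_boot 10⁴. The CI level
is a parameter (not hard-coded) because different figures legitimately use
different levels. Degenerate inputs (single sample, zero spread) return a
zero-width interval.

## The synthetic generator

`SyntheticSpec`/`generate_pentamer`/`generate_trajectory` build stand-ins,
not chemically valid structures: Cα skeletons (residues 10–314 by default)
plus exactly the marker atoms the analyses touch (E35 OE1/OE2, T158 OG1,
I233 Cβ, A237 Cβ, E243 OE1/OE2, K248 Nζ), with waters and Na⁺ as labelled
heteroatoms. Default geometry: ECD Cα at radius 25 Å (a realistic ECD
spread for this fold), pore-lining Cα rings following a V-shaped radius
profile with its 2.9 Å minimum at residue 233 (the closed-gate Cβ radius),
other TMD Cα at 12 Å, and 0.8 Å of axial drop per residue.

Constructions are arranged so noiseless recovery is exact to machine
precision: every chain's Cα atoms share one azimuthal half-plane (ring
centroids land exactly on the axis); all extracellular Cα sit at the spread
target; the T158/159 stand-ins carry mutually cancelling azimuthal offsets
so the E35→complementary-T158 distances are exact without perturbing
subunit-COM azimuths; K248 Nζ toggles between poses at exact distances
(2.8 Å formed / 8.0 Å broken) from the E243 carboxylate.

Trajectories add, per frame: radial scaling of the ECD ("breathing", default
a sinusoid of the given amplitude, or an explicit per-frame series), ECD
rotation (twist drift or explicit series), a per-subunit two-state Markov
chain for the contact (P(on|off) = k_on, P(off|on) = k_off per frame, so the
stationary formed probability is k_on/(k_on+k_off)), Gaussian random-walk
ions (σ = 1 Å/frame, started in a 28–45 Å shell), waters jittered by ±0.05 Å
inside their region (pore cylinder r ≤ 2 Å between the 9′/13′ planes, or
bulk at r ≥ 30 Å), and optional Gaussian coordinate noise. One explicit
seeded generator drives all randomness; a seed is mandatory whenever any
stochastic field is active, and equal seeds give byte-identical DCD output.

What the generator does **not** emulate: real side-chain chemistry and
packing, membrane and solvent thermodynamics, correlated backbone motions,
B-factor/occupancy structure, or experimental coordinate error models.
Passing the synthetic suite therefore demonstrates that the *measurement
machinery* is correct (geometry, counting, statistics, determinism, I/O),
not that any scientific conclusion about real channels holds.

## Numerical choices and degenerate inputs

- Model coordinates are held in float64 (the annotation container stores
  float32; a separate float64 array is authoritative) so that exactness
  assertions at 1e-9–1e-12 are meaningful. PDB output has 3 decimals; DCD
  round-trips at float32 (~1e-4 Å here).
- DCD headers do not carry absolute times portably; trajectory times default
  to 1 ns/frame for DCD input and can be overridden (`frame_dt_ns`).
- Kabsch: SVD solution with the determinant sign fixed to exclude
  reflections; < 3 atoms is an error; near-collinear point sets warn but
  return (rotation about the line is unconstrained).
- Subunit ordering: azimuths are computed with a 1e-9 wraparound tolerance
  so a chain sitting exactly on azimuth 0 sorts first; two chains closer
  than 1e-6 rad in azimuth raise a degeneracy error.
- Symmetric selections: a residue/atom position missing from some chains is
  either an error (`symmetric="require"`) or dropped from all five chains
  with a warning (`symmetric="drop"`, default inside analyses) so per-chain
  counts stay equal. Pore-profile rings tolerate one missing chain (mean of
  four); more are excluded with a warning.
- Altloc records resolve to the highest-occupancy conformer (ties keep the
  first listed, conventionally "A"); insertion codes are rejected; water
  residue names HOH/WAT/SOL/TIP3 and cation names NA/SOD are recognised.
- KDE bandwidth: Scott's rule per dimension (σ·n^(−1/6)); 128² grid spanning
  the data ± 3 bandwidths; zero variance in a dimension is an error unless
  explicit bandwidths are supplied.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data sized
for a single CPU: default pentamers of 5 × 313 atoms; trajectories of tens
of frames for geometric checks and 10⁴ frames (5 subunit chains) for the
two-state contact recovery, whose tolerance is three standard errors with
the autocorrelation-corrected variance p(1−p)(1+ρ)/(1−ρ)/(5n), ρ =
1−k_on−k_off; bootstrap checks use n_boot up to 10⁴ with 200 replicate
datasets for the coverage check.

## Known limitations

- Analyses that quantify the deposited GLIC models (PDB 6ZGD/6ZGJ/6ZGK and
  references 4NPQ/4HFI) require those files; the repository cannot include
  them, and the corresponding acceptance tests fail with a clear message
  when the files are neither cached under `data/deposited/` nor fetchable.
  In particular, the expectation that the leading loop-PC motion has its
  largest loadings near residue 248 is asserted only on the deposits, not on
  synthetic data (whose PC structure is whatever was constructed).
- Pore radii are atom-centre distances; they are not comparable to
  solvent-probe radii from HOLE/CHAP-style methods.
- Contact criteria are heavy-atom cutoffs; no hydrogen positions or
  donor-angle criteria are applied, and no pKa/protonation prediction is
  performed — alternative protonation states enter only as alternative
  input topologies.
- Minimum-image handling is not applied; ion searches in very small periodic
  boxes would need it.
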