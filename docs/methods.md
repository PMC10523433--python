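# Methods

## Geometric conventions

**Torsions.** All angles are signed IUPAC torsions in degrees on the
half-open range (−180°, +180°], with +180° preferred over −180°. The
kernel uses the cross/dot atan2 formulation on the two bond-plane normals;
the sign convention (positive = clockwise rotation of the 3→4 bond
sighting down the 2→3 axis) was cross-checked against MDAnalysis, mdtraj
and biotite, which all return +90° for the canonical reference
configuration. Degenerate inputs — coincident central atoms or a collinear
triple — raise a structured geometry error; in per-frame series the error
names the frame.

**Superposition and RMSD.** Rigid fitting is the Kabsch algorithm via
`scipy.spatial.transform.Rotation.align_vectors`, which guarantees a
proper rotation (reflections excluded). Ligand RMSD is computed after
superposing each frame onto a reference frame **using receptor atoms
only** (alpha-carbons by default), then measuring the ligand deviation
with no further fitting. The reference defaults to frame 0, the initial
docked pose. The fitting protocol for this quantity is genuinely open —
raw simulation coordinates would also be defensible — but receptor-frame
RMSD is the standard choice for ligand pose analysis and is what the
bimodality of the two-pose signal requires; it is fixed as the package's
convention. No mass weighting and no periodic-boundary corrections are
applied (inputs are assumed whole and centered).

**Centroids and distances.** Aromatic ring centroids are unweighted
arithmetic means, the standard convention. Multi-candidate distances (a
dimethyl pair, Leu's two δ-carbons) reduce by the per-frame minimum over
all pairs, so one rule covers every pairing.

## State definitions

**Chain mode.** The ligand chain dihedral 1–2–3–4 classifies purely by
sign: MINUS_AC (−anticlinal, L-shape) for angles < 0°, PLUS_AC
(+anticlinal, I-shape) otherwise. Exactly 0° is assigned PLUS_AC so the
rule is total; this tie-break is documented rather than scientifically
meaningful (the two wells sit near ∓90°, so 0° is ~4.5 circular standard
deviations from either center at the generator's default concentration).

**Rotamer.** Chi1 uses the standard 120°-wide staggered windows centered
on the canonical rotamers: t (180°), g+ (−60°), g− (+60°). The windows
tile the circle exactly: g+ = [−120°, 0°), g− = [0°, +120°), t = the rest
including the ±180° seam. g− is included for completeness even though a
Leu/Val 6.51 side chain essentially never visits it. The chi1 atom
quartet is N, CA, CB plus the first side-chain γ atom present (CG for
Leu/Phe/Trp, CG1 for Val/Ile, OG/OG1/SG for Ser/Thr/Cys), the standard
chi1 convention.

**Summaries.** Occupancies are raw label frequencies; transitions are
adjacent-frame label changes; dwell times are mean run lengths. Circular
means use the resultant-vector method so angles straddling the seam
average correctly, and the resultant length R ∈ [0, 1] is reported as the
concentration measure. No minimum-occupancy threshold is imposed for a
state to count as "visited" — the summary reports raw numbers and leaves
interpretation to the caller. An optional minimum-dwell filter can
suppress single-frame classification flicker; it is **off by default**
because the upstream analysis this package systematizes describes no
smoothing.

**Histograms.** Circular histograms use equal-width half-open bins
(left, right] over (−180°, 180°], so the count total always equals the
frame count. The default is 72 bins (5°), a conventional resolution for
torsion distributions. Heatmap downsampling takes the modal label per
window, ties going to the earliest-occurring label.

## Coupling statistics

The chain-mode × rotamer association is reported as three standard effect
sizes on the frame contingency table: the odds ratio with the
Haldane–Anscombe +0.5 correction applied when any cell is zero (MD
trajectories commonly never visit one joint state), Cramér's V, and
mutual information in bits. The odds ratio is defined only when the table
is effectively 2×2 after dropping never-visited rows/columns; otherwise
it is reported as null. Frames are treated as exchangeable for counting:
MD frames are strongly autocorrelated, so no p-values are attached and no
block-bootstrap is attempted — these are descriptive effect sizes, and
association cannot resolve whether the rotamer change triggers or merely
stabilizes the chain switch. The distance gate reports, per chain state,
the fraction of frames with distance below a threshold (default 5 Å, the
contact criterion separating the engaged from the disengaged pose) plus
mean/min/max; a never-visited state reports missing values, not zeros.

## Selection model

Ballesteros–Weinstein positions are supplied as an explicit config table
(position → residue id and name), never computed by alignment: the
annotation is a single lookup in GPCRdb for any receptor, while computing
it would require sequence resources and add a failure mode. Ring atoms are
scoped to the residue at a configurable BW position (default 3.36, the
toggle-switch Phe) because bare atom names like CG collide with aliphatic
side chains; the ligand selections can be scoped to a chain id for the
same reason. These two scoping fields (`ring_bw`, `ligand_chain`) are
package design choices.

## The synthetic generator

The generator emulates the statistical structure of the MD observables,
not their physics: no excluded volume, no ligand topology, no membrane,
no energetics. Per replica,

1. the chain state evolves by a two-state first-order Markov chain
   (default self-transition 0.99 per frame → mean dwell ≈ 100 frames,
   giving a handful of clean switches per 1000-frame replica, the
   qualitative texture of the replica heatmaps it emulates); the chain
   starts in MINUS_AC, mirroring simulations started from the docked
   L-shape pose;
2. the rotamer state copies the chain state with probability `p_couple`
   (default 0.9 — strong but imperfect tracking) and otherwise resamples
   from the chain's stationary marginal, so `p_couple` spans exact
   independence (0, matched marginals) to lockstep (1) with one knob;
   per-frame probabilistic copying was chosen over a joint Markov chain
   as the simplest mechanism with that span, there being no kinetics to
   copy;
3. angles are emitted from von Mises distributions around the canonical
   centers (−90°/+90° chain, 180°/−60° chi1) with concentration κ = 8
   (circular SD ≈ 20°, a realistic torsion-well width; leakage across a
   classification boundary 90° from the center is far below 1%);
4. distances are Gaussian around state-dependent means (L-shape 7.0 Å,
   I-shape 4.0 Å, SD 0.5 Å). The means are generator conventions chosen
   to straddle the 5 Å gate criterion, not measurements; the Gaussian
   tail is truncated at a small positive value so distances stay
   physical (never triggered at the defaults).

The CB2-like variant locks the chain in MINUS_AC (and places Val, with
CG1, at 6.51); the CB1-like variant enables switching (Leu at 6.51).
Seeds are explicit and mandatory; replica r uses seed + r.

**Coordinate realization.** Each frame is built by internal-coordinate
(NeRF) placement with fixed bond lengths (1.53 Å) and angles (111°): a
4-atom ligand chain realizing the emitted chain dihedral exactly, a
side-chain quartet realizing chi1, a regular hexagon (1.39 Å
circumradius) placed with its centroid at the emitted distance from the
ligand terminal atom, and four static alpha-carbons for well-conditioned
superposition. Re-analyzing built coordinates reproduces the emitted
series to ~1e-6; after a PDB round trip (fixed 0.001 Å columns) torsions
move by ≲0.05°, far inside any classification window.

**What passing tests do and do not show.** The generator reproduces the
two-state switching, the angular well structure, the state-conditional
distances and the replica layout of real trajectories, so it validates
the full measurement chain (I/O → selection → geometry → classification →
statistics). It does not reproduce force-field correlations between the
observables, slow drifts, solvent/membrane artifacts or broken/imaged
molecules, so passing tests certify the analysis, not any simulation.

## Problem sizes and numerical choices

Statistical tests use 10^3–10^4 frames and up to 20 generator seeds,
sizes at which Monte Carlo error bands (3 standard errors across seeds)
are decisive for the properties checked; the end-to-end closure tests use
~1200-frame single replicas. Torsion degeneracy is detected at a 1e-10
relative tolerance; the acceptance constructions are exact to 1e-9°.
Analysis outputs are fully deterministic given inputs; the generator is
deterministic given its seed (byte-identical files on re-run).

## Known limitations

- No GROMACS XTC/TRR readers — text PDB/XYZ only; binary formats are an
  extension point behind `structures_io`.
- No chi2+ rotamer analysis and no rotamer-library scoring.
- Association statistics ignore frame autocorrelation by design (effect
  sizes only); occupancy comparisons across conditions should use
  replica-level spread, which the per-replica summaries provide.
- The exact ligand chain atom quartet is configuration, not inference:
  the analysis is agnostic to ligand topology.
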