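# Methods

## Model and assumptions

motifdock treats ligand binding as a problem of *congruence*: if a small
set of protein atoms that contact a ligand in one enzyme has a spatially
and electrostatically equivalent counterpart in another protein, the ligand
can be transplanted rigidly between the two sites. The method is "soft"
docking — receptor and ligand are rigid, there is no energy model, and the
pose is exactly determined by the anchor-atom superposition. This is a
strong assumption: it works when the template site genuinely resembles the
target site, and degrades when either the binding site or the ligand is
flexible. The package reports contact and clash diagnostics rather than
pretending to rank poses energetically.

## Motif extraction

Contacts are collected under an expanding-radius schedule: radius starts at
2.5 Å and grows in 0.1 Å increments; at each radius, protein atoms within
the radius of any ligand atom are considered in ascending exact distance
(ties broken by chain, residue number, atom name). A pair qualifies only if
its element pair is in the polar whitelist {O–N, N–O, O–O, N–N, O–H, H–O,
N–H, H–N, S–H, H–S}; carbon never qualifies, and because hydrogens are
stripped on parsing, sulfur (which only pairs with H) effectively drops out
too. At most one atom per residue is kept — the closest — since a motif is
meant to name *residues* that hold the ligand, not to enumerate every atom
of a carboxylate. Extraction stops at *n* atoms (default 5) or fails with a
count of what was found once the schedule passes 8.0 Å; beyond that
distance a "contact" is not a binding interaction. An equivalent
formulation — sort all whitelisted pairs by distance, deduplicate by
residue, take the first *n* — is used as an independent oracle in the test
suite; the two must agree on randomized scenes.

Contact *tables* for reporting purposes accept any protein partner
(including carbon) for a polar (N/O/S) ligand atom, matching how
binding-site tables are conventionally printed; the strict whitelist is
what feeds motif construction. Residue deduplication is on by default and
can be disabled when a per-atom listing is wanted.

## Feature matrices and potentials

A motif of k atoms carries a k×k pairwise distance matrix and, when
potentials are available, a k×k pairwise potential-difference matrix
PDᵢⱼ = φᵢ − φⱼ (kT/e, antisymmetric by construction). Three potential
sources are supported:

- **grid** — an OpenDX scalar field (the dialect written by
  Poisson-Boltzmann solvers), trilinearly interpolated at atom positions;
  queries outside the grid are errors, not extrapolations.
- **table** — per-atom TSV (chain, resseq, resname, atomname, potential);
  a missing atom is an error naming that atom.
- **surrogate** — screened Coulomb φᵢ = Σ_{j≠i} qⱼ e^(−κ rᵢⱼ)/(ε_r rᵢⱼ)
  over a bundled formal-charge table (Asp/Glu −1 split over the carboxylate
  oxygens, Lys +1 on NZ, Arg +1 split over NH1/NH2, His neutral), with
  κ = 0.1 Å⁻¹, ε_r = 10 and a 0.1 Å self-exclusion, all overridable.

The surrogate is not a Poisson-Boltzmann solution and its absolute values
are far smaller than solver output; it exists so that sign structure,
orderings and the full scoring pipeline are exercisable with no external
binary. Real applications should feed solver grids or tables. Because
published absolute PD values depend on solver settings that are rarely
recoverable, the scoring deliberately consumes |PD| deviations with a dead
zone rather than absolute levels.

## Candidate database and search

A target is reduced to *functional atoms* — one designated side-chain atom
per residue type (S:OG, T:OG1, D:OD1, E:OE1, Y:CZ, W:CZ2, K:NZ, R:NH1,
H:NE2, N:OD1, Q:OE1, C:SG, F:CZ) — and every k-subset whose pairwise
distances all fall within a cutoff (default 15 Å, a generous bound on
binding-site diameters) is stored. Enumeration is a neighbor-pruned
depth-first walk whose output provably equals brute-force combination
filtering; the test suite checks that equality directly.

Stored subsets are unordered. At query time each subset is expanded into
the orderings whose per-position residue type lies in the query's group at
that position — the groups default to {D,E}, {N,Q}, {S,T}, {K,R}, {Y,W,F},
{H}, {C}, {G,A}, with everything else matching only itself — and each
ordering is scored position-to-position; the best ordering represents the
subset. This realizes the per-position group test without assuming any
particular storage order, while keeping the scored correspondence strictly
positional (no permutation happens *inside* scoring).

The congruence score is

    CScore = Σ_{i<j} |d_q(ij) − d_c(ij)| / d_q(ij)
           + λ · Σ_{i<j} g(| |PD_q(ij)| − |PD_c(ij)| |)

with g(x) = 0 for x below the dead zone (default 100 kT/e) and
(x − dead_zone)/max(|PD_q(ij)|, dead_zone) above it; λ defaults to 1.
Normalizing by the reference distance makes a 1 Å error count more against
a 4 Å pair than an 11 Å pair; the dead zone ignores small electrostatic
deviations; dividing by the reference |PD| constrains large reference PDs
more loosely. A zero reference distance is rejected as degenerate.
Matches with CScore ≤ S_thresh (default 5.0) survive, ranked ascending with
deterministic tie-breaking on atom identity. Two complementary geometry
metrics accompany each match: optimal least-squares superposition RMSD
(Kabsch) and the maximum pairwise-distance deviation, which is not averaged
away and therefore exposes a single bad pair that a low RMSD can hide.

## Canonical frame and transplantation

The canonical frame of an anchor triplet (a₁, a₂, a₃) maps a₁ to the
origin, a₂ to (0, |a₂−a₁|, 0) and a₃ into the Z = 0 plane with positive x.
The rotation is built from the orthonormal triad (x̂, ŷ, ẑ = x̂ × ŷ), which
is always proper (det +1): reflections are forbidden because they would
invert molecular chirality. Coincident or collinear anchors are rejected
(tolerance 1e-8 on the normalized cross term).

Transforming the holoenzyme (with its ligand) and the target each by their
own anchors' canonical-frame transforms places all three in one unified
frame. The default output frame is the *target's original coordinates*
(apply T_target⁻¹ to the canonical-frame pose), which is what downstream
tools want; the shared canonical frame is available by flag. A k-point
least-squares (Kabsch) anchoring mode is offered for k ≥ 3 anchors as an
alternative to the 3-point frame. The pose records both transforms, the
anchor triplets, and the anchor superposition RMSD (computed as optimal
least-squares RMSD of the anchor sets, so it coincides with the congruence
metric on the same atoms).

Pose quality is reported, not enforced: the clash report counts target
heavy atoms within a cutoff (default 2.0 Å) of any ligand atom — all target
atoms counted, including the anchor residues' own — with the closest
approach; the contact report lists the nearest target residues in
reporting mode. Published transplantations sometimes show sub-H-bond
distances yet are described as clash-free, so flagging rather than failing
is the deliberate behavior.

## Synthetic fixtures: what they emulate and what they do not

The fixture generator builds a holo structure as simplified rigid residue
templates arranged around a small synthetic ligand: five binding residues
whose designated polar atom is placed at a designed distance (2.6–3.4 Å by
default) from a designated polar ligand atom, bodies pointing radially
outward, plus filler residues on an 8.5–13 Å shell. The apo form is the
same protein without the ligand; the target is a rigidly moved copy,
optionally with residue substitutions inside the default groups (e.g.
Glu→Asp rebuilt from the Asp template at the same contact-atom position and
axis, so motif geometry is preserved exactly). The ground-truth record
carries the applied transform, the true motif and the true docked
coordinates.

By default the applied motion is one of the 24 axis-aligned proper
rotations plus a 3-decimal translation. This makes the motion exact at the
PDB format's 3-decimal coordinate precision, so ground-truth pose recovery
can be asserted at 1e-6 Å *through a full file round-trip*; arbitrary
rotations are supported and used in-memory. Same seed, same bytes.

What the fixtures do **not** emulate: real backbone geometry, rotamers,
crystallographic disorder, solvent, cofactors, or genuinely perturbed
apo/holo conformations (the synthetic apo is geometrically identical to the
holo minus the ligand). Passing fixture tests therefore demonstrates the
correctness of the algorithms — extraction order, group matching, scoring
arithmetic, rigid geometry — not the biological accuracy of any particular
docking. Regression tests against published crystal structures exist
separately and require those structures to be present in the local PDB
cache.

## Numerical choices and degenerate inputs

- Alt-locs: one conformer per atom is kept at parse time (highest
  occupancy, ties to the earlier letter); waters and hydrogens are dropped
  by default. Residue numbering and insertion codes are as-authored.
- All distances are computed on raw coordinates in Å; no symmetry
  expansion.
- Grid interpolation is strict-bounds trilinear (scipy
  RegularGridInterpolator); the synthetic-ramp agreement tolerance in the
  tests is 1e-9.
- Ordering ties anywhere in extraction or search break on (chain, residue
  number, atom name), making all outputs deterministic for identical
  inputs; output headers echo the configuration and no timestamps are
  written.
- Degenerate cases raise typed errors: empty selections, ambiguous ligand
  copies, fewer than n qualifying contacts (with the count found), zero
  reference distances, collinear anchors, reflections.

## Known limitations

- Rigid ligand and receptor; a flexible ligand docked from a template in a
  different conformation inherits the template's conformation.
- The search is order-expanded per subset: for k = 4 that is at most 24
  orderings, but pathological groups (all positions accepting all types)
  cost k! per subset.
- The surrogate potential is qualitative; PD-based discrimination with the
  default dead zone effectively switches off when potentials are orders of
  magnitude smaller than solver output.
- Sequence order along the chain is ignored by design; motifs are purely
  spatial.
- mmCIF input, assembly generation and hydrogen placement are out of scope.
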