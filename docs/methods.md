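# Methods

This note documents the models, conventions and numerical choices behind
paircraft, in the spirit of a package reference manual. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Secondary structures and pseudoknot layering

A structure is a set of base pairs (i, j), 0-based with i < j, over L
nucleotides, optionally split into chains by recorded break indices.
Regions are half-open `[start, end)` throughout. By default each index may
appear in at most one pair; base triples and quadruplex-like pair sets
require the explicit `multi_partner_allowed` flag, and such sets cannot be
written as dot-bracket (the writer fails loudly rather than dropping
pairs).

Dot-bracket uses the community multi-bracket dialect, in layer order
`()`, `[]`, `{}`, `<>`, then `Aa` … `Zz`. Each layer is matched with its
own stack, so layers are mutually independent; `&` and `+` both separate
chains on input and `&` is emitted on output. Crossing pairs are assigned
to layers by greedy colouring of the pair-crossing conflict graph, pairs
processed by ascending opener index, each taking the lowest layer free of
crossings. This is deterministic and linear-ish, not a minimal colouring:
the *pseudoknot order* we report (layers − 1) is an upper bound on the
minimal one, is 0 exactly when no two pairs cross, and round-trips through
the writer, which is what the toolkit needs.

## The conditioning tensor

Constraints live in a symmetric L×L×3 one-hot array with channel
semantics unspecified / non-pairing / paired and the diagonal pinned to
unspecified (also across chain boundaries; no special inter-chain channel
exists). Internally a uint8 channel-index matrix is stored; `to_array`
expands the one-hot view. Conflicting writes to one cell (paired over
non-pairing or vice versa) raise an error instead of last-writer-wins:
silent overwrites corrupt templates. Re-writing the same state is
idempotent, which lets region pairs accumulate.

A `RegionPair` pairs two equal-width, non-overlapping regions base by
base: antiparallel maps `a_start+k ↔ b_end−1−k` (anti-diagonal submatrix),
parallel maps `a_start+k ↔ b_start+k` (diagonal). Orientation is thereby
a property of the submatrix pattern, not an extra feature. A base may be
paired in more than one region pair at the tensor level (triplex /
quadruplex support), even though dot-bracket export then refuses.

When converting a secondary structure to a tensor, unpaired positions may
optionally be encoded as mutually non-pairing (`unpaired_as_nonpairing`);
both readings are exposed because loop enforcement is a modelling choice,
not a property of the structure itself.

Serialization: a NumPy `.npz` container holding the uint8 channel matrix,
L and chain breaks (exact and portable), plus a sparse
`i <TAB> j <TAB> channel` text export for inspection.

## Pseudocycle templates

Topology specs name segments (5'→3' within one subunit) with inclusive
length bounds and roles (`helix_side`, `loop`, `hinge`), intra-subunit
edges, inter-subunit edges wired from subunit s to subunit (s+1) mod n,
and a symmetry order n. Edge partners must share bounds, because realized
partner lengths must match; a segment may appear in several edges only
when flagged multi-partner. Inter edges with n = 1 are rejected — they
reference a neighbouring subunit that does not exist. Hinge segments
belong to the subunit they terminate.

Length sampling draws one uniform value per tie group (segments connected
by edges), shared across all subunits, from a generator seeded by the
caller, so identical (spec, seed) give byte-identical templates. A target
total length is met by rejection sampling whole assignments (default
budget 10,000 tries) after an exact feasibility check against
[n·Σmin, n·Σmax]; rejection is simple and auditable at the scale of these
specs (tens of segments), and a target inside the range can still be
unreachable (e.g. parity constraints from tied segments), which surfaces
as a sampling error naming the budget. Realization lays segments onto
global intervals in 5'→3' order and converts every edge to a region pair
— antiparallel by default, the nucleic-acid norm; parallel must be
explicit. Because all subunits realize the same lengths and the edge set
is symmetric by construction, rotating indices by L/n is an automorphism
of the pair map; the tests assert this rather than assume it.

Only single-chain pseudocycles are generated; multi-chain symmetric
assemblies are out of scope (multi-chain *strand exchange* templates are
a separate, non-symmetric code path).

## Backbone geometry

### Internal-coordinate construction

Atoms are placed by NeRF: each from a bond length, bond angle and
dihedral (IUPAC sign convention, validated against Biopython/biotite)
relative to three placed atoms. The main chain threads
P → O5' → C5' → C4' → C3' → O3' using ε(i−1), ζ(i−1), α(i), β(i), γ(i),
δ(i); the 5'-terminal residue carries no phosphate group and is anchored
by a caller-supplied start frame (identity by default: O5' at the origin,
C5' along x, C4' in the xy plane), so its α and β — and the last
residue's ε and ζ — are undefined and held as NaN. The glycosidic χ is
carried as metadata: base atoms are out of scope, so nothing consumes it
and extraction returns NaN.

The furanose ring is closed with a fixed pucker template: O4' placed by a
chirality improper (C5'-C3'-C4'-O4'), C1' and C2' by the endocyclic
torsions ν4 and ν0, O2' (RNA only) by a fixed exocyclic dihedral. The
template constants were measured from least-squares-closed rings at the
canonical pseudorotation phases (C3'-endo P = 18°, C2'-endo P = 162°,
amplitude 38°) under the table's ideal bonds and angles; the chirality
sign was anchored on an RDKit-embedded β-D-nucleoside conformer. A closed
five-ring with all-ideal internal coordinates is overdetermined, so the
C2'-C3' closure bond is implied rather than constructed: it comes out at
the tabulated fit value (1.5217 Å C3'-endo, 1.5237 Å C2'-endo, vs the
1.525 Å ideal), while every constructed bond reproduces its table length
to 1e-6 Å. Defaults are C3'-endo for RNA and C2'-endo for DNA,
overridable per residue. Non-bridging phosphate oxygens are placed
symmetrically about the O3'-P-O5' plane with the ideal O-P-O angle.

Torsion extraction applies the standard dihedral quadruplets and is the
exact inverse of construction (round trip within 1e-6°, asserted on
random torsion sets); pucker labels are recovered from the sign of ν2.

### Frames

The per-residue frame is origin C1', x toward O4', y the orthogonalized
C2' direction, z their cross product. The atom triple is fixed; the axis
recipe is this package's convention, chosen for unambiguity, and the
tests check orthonormality, det +1 and rigid-motion equivariance.

### Ideal duplexes

A chain built from exactly repeating internal coordinates is an exact
helix, so the duplex generator works from the constants table alone:
reference torsions per polymer class were fitted (α and ζ adjusted, the
rest held at canonical values) so the repeat screw of the built chain has
exactly the canonical fibre parameters — twist 32.7°/rise 2.81 Å for
A-RNA, 36.0°/3.38 Å for B-DNA. At run time the interior residue of that
reference chain is re-expressed in the helix frame (z = axis) and gauged
so C1' sits at half the tabulated C1'-C1' pair distance (10.4 Å RNA,
10.5 Å DNA); residue k of the leading strand is the template under the
k-th helical operator, and the lagging strand is its dyad image (π about
x), listed 5'→3', pairing k ↔ n−1−k. Connectivity, constant interior
torsions and exact rise spacing are consequences, not tuning targets.
These fixtures are idealized regular helices for testing and scaffolding:
base atoms, sequence-dependent geometry, grooves and realistic
inclination are not modelled, and the emergent helix radius reflects the
generic table angles (C1' radius ≈ 8.9 Å RNA, ≈ 6.2 Å DNA) rather than
any fibre-diffraction refinement.

### Superposition metrics

Kabsch superposition is the SVD solution with the reflection excluded;
tests validate it against biotite and against a brute-force Euler-grid
oracle refined to 0.1° on small point sets. TM-score is
`(1/L_norm) Σ 1/(1+(dᵢ/d0)²)` over an *explicit* correspondence — this is
not an alignment search, so sequence-order questions do not arise. The
score-optimal superposition has no closed form; it is searched by
iterated Kabsch fits on shrinking inlier sets with distance cutoffs 8, 4,
2, 1 × d0 (each iterated to a fixed point from the full set, best score
kept). With fewer than three corresponded pairs no superposition is
defined and the points are scored in place, which makes the one-pair
closed-form case (score 0.5 at distance d0) meaningful. d0 follows the
published length-dependent normalizations — RNA mode
0.6·√(L−0.5) − 2.5, protein mode 1.24·∛(L−15) − 1.8 — floored at 1.0 Å
and 0.5 Å respectively (the floors are this package's documented
convention for short chains) and overridable per call. Coverage is
L_aligned / L_design.

## Screening metrics

Base-pair F1 matches pairs on exact (i, j) identity; precision
|∩|/|pred|, recall |∩|/|designed|, F1 = 2|∩|/(|pred|+|designed|). Two
empty sets score (1, 1, 1): they agree perfectly on "no pairs" (some
conventions use 0; the choice is documented here and asserted in tests).

Simulated reactivity emulates chemical-probing signal: paired positions
are protected (mean `mu_paired`, default 0.2), unpaired flexible (mean
`mu_unpaired`, default 1.0), with multiplicative log-normal noise
`mu · exp(σz − σ²/2)` so every draw's expectation is exactly its class
mean, reactivities are non-negative and right-skewed, and σ = 0
degenerates to the means. The defaults give well-separated classes at
moderate noise (σ = 0.3), which is the regime the concordance score is
meant for. The simulator does not model position-dependent normalization,
primer drop-off, adduct chemistry or correlated noise of real probing
data, so passing tests demonstrate correct bookkeeping and statistical
behaviour of the metric, not agreement with any experimental dataset.

Concordance is the balanced accuracy of thresholded
paired/unpaired classification (default threshold 0.5, between the two
default means): the mean of the per-class fractions correct, insensitive
to class imbalance; a degenerate structure uses its single defined class
fraction. It is a deliberately simple surrogate for proprietary
aggregate probing scores and is named differently to avoid conflation.

Design filtering applies strict inequalities, matching the printed forms
of the standard self-consistency screen: pLDDT > 0.87, backbone
RMSD < 2.2 Å, all-atom RMSD < 3.5 Å; a record exactly at a bound fails.
Confidence reported on a 0–100 scale is normalized to 0–1 on ingest.
Records missing a field fail only bounds referencing that field. The 5'
leader helper prepends unconditionally (default GG, +2 nt), with no
deduplication against an existing leader.

## Problem sizes and determinism

Every stochastic component (length sampling, reactivity simulation) takes
an explicit integer seed and is reproducible bit-for-bit. The test suite
runs property checks on small instances chosen for exhaustive or
closed-form verifiability — ≤ 40-nt structures, ≤ 6-residue chains,
≤ 8-point superpositions, 1000-seed sampling censuses against a 27-case
enumeration, a 10,000-position profile for standard-error bounds — and
the acceptance script's quantities are arithmetic worked examples; both
complete in well under a minute.

## Known limitations

- Greedy bracket layering can exceed the minimal pseudoknot order on
  adversarial pair sets (round-tripping, not minimality, is guaranteed).
- The loop-enforcement encoding is O(U²) in the number of unpaired
  positions; fine at template scale.
- Backbone building covers the sugar-phosphate backbone only; no bases,
  hydrogens or energetics. Ring closure is exact to the committed
  template fit, not to crystallographic ideality.
- The duplex fixtures are regular helices with a simplified base-pair
  dyad; do not use them as physical models of groove geometry.
- TM-score requires the caller to provide the correspondence; it will not
  discover alignments, by design.
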