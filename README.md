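# paircraft

A toolkit for the non-neural layers of generative nucleic-acid design:
specifying and encoding secondary-structure templates (including
arbitrary-order pseudoknots, strand-orientation control, symmetric
pseudocycles and multi-chain strand exchange), building full-atom
sugar–phosphate backbones from internal coordinates, and screening
candidate designs with the standard quantitative metrics.

It is aimed at people who condition diffusion- or inference-time structure
generators on base-pair constraints, and at anyone who needs clean,
validated bookkeeping for pseudoknotted pair maps and design-screening
pipelines.

## What it computes

**Pair maps and conditioning tensors.** A secondary structure is a set of
base pairs (i, j) over L nucleotides; pseudoknots are pairs that cross
(i < k < j < l). Multi-bracket dot-bracket strings are parsed and written
with per-layer stacks, and the pseudoknot *order* is the number of extra
bracket layers a greedy layering needs. Constraints are encoded in a
symmetric one-hot tensor A ∈ {0,1}^(L×L×3) with channels
[1,0,0] = unspecified, [0,1,0] = non-pairing, [0,0,1] = paired, and an
unspecified diagonal. Two equal-width regions paired base-by-base land on
the diagonal of their submatrix when the strands are parallel and on the
anti-diagonal when antiparallel, which is how orientation (triple helices,
G-quadruplexes, strand exchange) is expressed without extra channels.

**Pseudocycle templates.** A pseudocycle is a single chain whose fold
repeats a subunit n times with symmetric pairing between neighbours. From
a coarse graph — segments with length bounds, intra-subunit stems,
inter-subunit kissing edges, symmetry order n — the toolkit propagates the
subunit, samples segment lengths (optionally rejection-sampling to a fixed
total), and realizes a pair map whose pseudocyclic symmetry (invariance
under index rotation by L/n) holds by construction.

**Backbone geometry.** Full sugar–phosphate backbones are placed atom by
atom from bond lengths, bond angles and the standard torsions α–ζ (NeRF
internal-coordinate construction), with the furanose ring closed by a
fixed C3'-endo or C2'-endo pucker template and O2' added for RNA only.
Per-residue frames use the O4'-C1'-C2' atom triple. Ideal A-form/B-form
duplex fixtures, Kabsch superposition, TM-score
(Σ 1/(1+(dᵢ/d0)²) / L_norm) and alignment coverage
(L_aligned / L_design) round out the metric stack.

**Screening.** Base-pair F1 between designed and predicted structures,
simulated SHAPE-style reactivity profiles (paired positions protected,
low; unpaired flexible, high), a balanced-accuracy concordance between a
reactivity profile and a target structure, strict-threshold filtering of
design records (pLDDT > 0.87, backbone RMSD < 2.2 Å, all-atom
RMSD < 3.5 Å by default), and transcript preparation (5' GG leader).

## Worked example

A two-fold pseudocycle ("butterfly") with two stems, a kissing hairpin and
a hinge per 186-nt subunit, from a YAML topology:

```yaml
# topo.yaml
symmetry_order: 2
segments:
  - {name: h1a, length: [25, 25]}
  - {name: loop1, length: [12, 12], role: loop}
  - {name: h1b, length: [25, 25]}
  - {name: k5, length: [20, 20]}
  - {name: kiss, length: [16, 16]}
  - {name: k3, length: [20, 20]}
  - {name: hinge, length: [68, 68], role: hinge}
intra_edges:
  - [h1a, h1b, antiparallel]
  - [k5, k3, antiparallel]
inter_edges:
  - [kiss, kiss, antiparallel]
multi_partner: [kiss]
target_total: 372
seed: 0
```

```text
$ paircraft template topo.yaml --out-prefix butterfly
realized 372 nt, 106 pairs, symmetry order 2, seed 0
```

The realized template is a 372-nt chain (2 × 186) with 45 stem pairs per
subunit plus 16 kissing pairs, written as dot-bracket
(`butterfly.db`), a pair table (`butterfly.pairs.tsv`) and the
conditioning tensor (`butterfly.tensor.npz` / `.tsv`). The kissing
contacts cross the stems, so the export needs a second bracket layer
(pseudoknot order 1), and rotating every index by 186 maps the pair set
onto itself.

Screening a prediction against a designed pseudoknot:

```text
$ paircraft score-f1 "((..[[..))..]]" "((..[...))...]"
{"precision": 0.75, "recall": 1.0, "f1": 0.8571428571428571}
```

Three of the four predicted pairs are designed pairs (precision 0.75) and
every designed pair is recovered (recall 1.0). Geometry from the same
CLI:

```text
$ paircraft ideal-duplex --n-bp 10 --out duplex.pdb
wrote 10-bp RNA duplex to duplex.pdb
$ paircraft superpose duplex.pdb duplex.pdb
aligned 10 positions on C1'
rmsd: 0.000 A
tm_score: 1.000 (L_norm=10)
coverage: 1.00
```

## Layout

```
src/paircraft/secstruct.py     dot-bracket / pair-table structures, pseudoknot layering
src/paircraft/conditioning.py  L×L×3 constraint tensors, region pairs, strand exchange
src/paircraft/templates.py     pseudocycle topology specs -> realized templates
src/paircraft/geometry.py      internal-coordinate backbones, duplexes, RMSD/TM-score
src/paircraft/evaluate.py      F1, reactivity simulation/concordance, design filters
src/paircraft/cli.py           `paircraft` command-line interface
docs/methods.md                models, conventions, numerical choices, limitations
```
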