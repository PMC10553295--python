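# Methods

## Model

A protein sequence aligned to *P* columns over the alphabet of 20 standard
amino acids plus gap (`-`) and missing (`?`) symbols is encoded into a binary
string of *M* = 8·*P* cells: each symbol contributes one fixed 8-bit codeword.
The built-in table derives each amino acid's word from the molecular structure
of its side chain (counts of non-hydrogen C/N/O/S atoms, aromaticity, covalent
bonds), so chemically similar residues receive nearby codes — a substitution
between similar residues perturbs fewer bits than one between dissimilar
residues, which is the main way the method weights mutations differently from
a plain residue-identity count.  Gap and missing sites get the two remaining
all-but-saturated words (`11111111`, `11111110`).  The table is injective and
validated on load; alternative codings (e.g. hydrophobicity-based) can be
supplied as a two-column text file.

The encoded string is the initial row of a one-dimensional, two-state
elementary cellular automaton.  Rules are numbered by the Wolfram convention
(bit *k* of the rule number is the output for the neighborhood triple with
3-bit value *k*); the lattice is periodic, c₀ ≡ c_M and c_{M+1} ≡ c₁.  The
default rule is 84, whose closed form is `(left OR center) AND NOT right`; it
is treated as a free parameter since no optimality criterion for it is
established, and all 256 rules are available.  Evolution for *T* steps keeps
every intermediate row, yielding a (T+1) × M image with the initial condition
as row 0.

Two automata from the same alignment are compared by the per-step normalised
Hamming distance D_H(t) = (1/M) Σ|aᵢᵗ − bᵢᵗ| ∈ [0,1].  Under rule 84 the
trajectory reaches a plateau after a short transient.  How the plateau value
is extracted is a genuine design choice: this package defines the Stationary
Hamming Distance (SHD) as the arithmetic mean of the final `window` values,
with a saturation diagnostic (tail standard deviation ≤ `tol`); a single
final value would be noisier against the residual fluctuation the curves
show.  Trajectories include t = 0 (the distance between the raw encodings);
under the defaults the averaging window never reaches it.  Unsaturated pairs
are logged and reported, never rejected — an analyst should see them, not
lose them.

The pairwise SHD matrix (each unordered pair computed once and mirrored,
zero diagonal) is clustered by UPGMA: repeatedly merge the two clusters with
the smallest mean inter-cluster distance, the merge height being that mean.
The baseline p-distance matrix is the proportion of differing residues per
pair.  Dendrograms are compared by the cophenetic correlation coefficient:
Pearson correlation between the two trees' cophenetic distances over all leaf
pairs, aligned by label.  The tree-vs-tree reading is the default; the
classical tree-vs-source-matrix variant is available through the same
function.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `rule` | 84 | elementary rule (0–255, Wolfram numbering) |
| `steps` (*T*) | 500 | evolution steps; the image has T+1 rows |
| `window` | 100 | tail length averaged into the SHD |
| `tol` | 0.01 | max tail standard deviation to call a trajectory saturated |
| p-distance deletion | pairwise | gap/missing sites dropped per pair; `complete` drops the column everywhere |

T = 500 with a 100-step window is comfortably past the transient for the
lattice sizes of interest (M ≈ 1200–6000); the SHD is insensitive to modest
changes in either.  `tol` = 0.01 flags fluctuation above ~1% of the distance
scale.

## Numerical and structural choices

- **Rule numbering** cannot drift: the table constructor re-derives the
  decimal number from the eight outputs and rejects mismatches, and the test
  suite pins rules 0, 255 and the rule-84 closed form.
- **UPGMA ties** (several pairs at the minimal distance) are resolved by
  merging the pair earliest in the current (row, column) order, making output
  deterministic across runs and platforms.  This is why UPGMA is implemented
  in-package; scipy's average linkage is used as an independent cross-check
  in the tests, where random matrices make ties a measure-zero event.
- **Cophenetic distance convention**: the merge height itself, not twice the
  leaf-to-ancestor branch length.  Pearson correlation is scale-invariant, so
  the coefficient is unaffected; the printed matrices follow this convention.
- **Newick export** assigns each child a branch of (parent height − child
  height)/2, so the root-to-leaf path equals half the root height (the usual
  UPGMA layout), and orders siblings by their lexicographically smallest
  descendant leaf for byte-stable output.
- **Residues outside the code table** (B, J, O, U, X, Z) are encoded as the
  missing-information word with a warning; they are likewise excluded from
  p-distance site counts.  Input case is normalised to upper.
- **Degenerate inputs**: identical sequences give identically-zero
  trajectories and SHD 0; a pair with no comparable sites gets p-distance 0
  with a warning; cophenetic correlation on zero-variance height vectors is
  an error rather than a NaN.

## Synthetic data

The `fixtures` module simulates aligned protein sets along a known rooted
tree whose branch lengths are exact substitution counts: a uniform-random
ancestor of length *P*, per-branch point substitutions at uniform positions
(replacement ≠ original), and gap/missing symbols sprinkled on the leaves at
fixed per-site rates.  Substitution counts (not rates) give exact control of
divergence for recovery tests; applying gaps at the leaves emulates
post-alignment artifacts rather than indel evolution, which the tool does not
model.

The default scenario is a six-taxon, three-clade tree
`(((A:12,B:12):80,(C:12,D:12):80):80,(E:12,F:12):160);` on a 400-column
ancestor.  The SHD for a fixed substitution count has substantial sampling
spread on short lattices; 400 columns is the scale at which the inter-clade
SHD separation clearly exceeds that spread, so the recovery experiment tests
the method rather than the noise floor.  What passing recovery shows is that
SHD orders well-separated divergence levels correctly under uniform
substitutions; it does not show robustness to rate heterogeneity, convergent
evolution, saturation at deep divergences, or real substitution processes
(JTT/WAG), none of which the generator emulates.

## Complexity

For *n* taxa, evolution is linear in n (one image per taxon, T·M cell
updates each), the distance stage is quadratic (n(n−1)/2 image pairs), and
UPGMA as implemented is O(n³) on n ≤ 50-taxon matrices — negligible next to
the image work.  The pipeline's operation-count test pins the quadratic
pairwise law.

## Limitations

- The method requires a multiple alignment; it is not alignment-free, and
  aligning is out of scope for the package.
- No corrected evolutionary distances (Poisson, JTT, Kimura) and no bootstrap
  support; UPGMA's molecular-clock assumption applies.
- The SHD's variance at small M means short alignments (tens of columns) can
  scramble fine topology even when clades are real; the built-in 20-column
  `worked_example_set()` sits in exactly this regime (its SHD and p-distance
  trees correlate at only ~0.29).
- The choice of rule 84 is inherited practice, not optimised here.
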