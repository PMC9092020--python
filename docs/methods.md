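# Methods

## Problem and model

A peptide of length L with representative-atom coordinates (Cβ per residue,
Cα for glycine) defines a ground-truth contact map: label(i, j) = 1 iff the
Euclidean distance is strictly below γ = 8 Å ("less than" is taken
literally, so a pair at exactly γ is a non-contact; the diagonal is 1 by
distance zero). An upstream predictor supplies a rough L × L score map. The
refinement model treats the rough map in two ways at once: thresholded into
a residue graph that a GCN propagates over, and injected as pairwise
feature channels into a 2D convolutional classifier.

**Graph.** Edge (i, j) exists iff i ≠ j and rough(i, j) ≥ edge threshold
(default 0.5, the natural cut for probability-scaled maps; configurable).
Propagation uses the self-looped adjacency Ã = A + I_L without degree
normalization — the propagation rule is H ← ReLU(Ã · minmax(H) · W), and
the per-feature min-max normalization bounds the activations that degree
normalization would otherwise control. A probability-weighted adjacency
(edge scores + unit self-loops) is available behind `weighted_graph` but
off by default: binary Ã is the primary reading, the weighted variant an
opt-in because the two descriptions (binary adjacency vs edge weights as
contact probabilities) are both plausible and they differ numerically.

**Features.** X_seq (L × 26) = [20-column PSSM | 3-class secondary
structure | 3-class solvent accessibility]. Real PSI-BLAST ASCII PSSMs are
parsed when available; otherwise a documented stand-in computes
pseudocount-regularized log-odds from the alignment itself:
score_a = ln(((count_a + c·q_a)/(rows + c))/q_a) with pseudocount mass
c = 1 and uniform background q. This is *not* PSI-BLAST (no iteration, no
sequence weighting); it exists so the pipeline runs offline. SS/SA are
consumed as labels or probability triples, never predicted here.

X_pair (L × L × 5) = [rough map A, rough map B, MI, APC MI, contact
potential] in that fixed order. When only one rough source exists (the
synthetic pipeline), it fills both rough channels. Column statistics are
unweighted frequencies over 21 symbols (20 amino acids + gap; unknown
residues count as gap), no pseudocounts — MI sees gap covariation, matching
common alignment-statistics practice. MI is in nats. APC subtracts
(Sᵢ·Sⱼ)/S_total with all sums excluding the diagonal; a zero total maps to
zero correction. The contact potential averages a 20 × 20 pair-energy table
over alignment rows, skipping rows gapped in either column (zero if all
rows are skipped): the potential stays a pure amino-acid term. The bundled
default table is a synthetic hydrophobicity-derived quasi-chemical
surrogate, e_ab = −(h_a + h_b)/9 on the Kyte–Doolittle scale, chosen
because it is fully reproducible from a published scale and has the
qualitative structure of statistical contact potentials (hydrophobic pairs
favourable, range ≈ [−1, 1]); any symmetric 20 × 20 table in the same text
layout can be substituted, and no claim of equivalence to any particular
published potential is made.

**Network.** GCN: two layers, widths 26 → n → n. 1D ResNet: three residual
blocks over X_seq; a block is ReLU(conv(ReLU(conv(minmax(X))))) plus an
identity skip, with a width-1 convolution projecting the skip path exactly
when input/output channels differ (block 1: 26 → n). Kernel width 5. The
block input is min-max normalized once per block; "normalization to [0, 1]"
is implemented as per-feature min-max, the only reading consistent with a
[0, 1] target range, and its arg-min/arg-max dependence is differentiated
(subgradients at ties). Outer concatenation lifts [1D | GCN] (L × 2n) to
L × L × 4n and appends X_pair. 2D ResNet: width-1 entry projection to the
working width, residual 3 × 3 blocks of the same shape as the 1D blocks,
width-1 head to 2 logits, softmax, symmetrization (y + yᵀ)/2. Loss:
two-class cross-entropy over all L² ordered pairs (the one-hot encoding
makes the two-class form reduce to the single-term map loss), probabilities
clamped at 1e-12 inside the log. Optimizer: plain SGD, learning rate 0.01,
one protein per step, epoch order shuffled by the run seed; no momentum,
decay, or early stopping, since none is specified for the original model.

All arithmetic is float64 on a package-local reverse-mode autodiff core
(`rcmpm.nn`) — no tensor-framework dependency — which keeps the analytic
gradients checkable against central finite differences (the test suite
verifies every operation and the end-to-end loss gradient at relative
error < 1e-4).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| γ (`gamma`) | 8.0 Å | contact distance threshold |
| `edge_threshold` | 0.5 | rough score needed for a graph edge |
| `n` | 32 | GCN / 1D embedding width |
| `blocks_1d` | 3 | 1D residual blocks |
| `blocks_2d` | 4 | 2D residual blocks (full-scale depth: 30) |
| `width_2d` | 48 | 2D working channel width |
| `kernel_1d`, `kernel_2d` | 5, 3 | convolution kernels (odd) |
| `learning_rate` | 0.01 | SGD step size |

Kernel sizes and channel widths are this package's engineering choices —
the original description fixes the layer counts (2 GCN layers, 3 + 30
residual blocks) and the learning rate, not the widths. The desk
configuration `ModelConfig.desk()` (n = 16, 4 blocks, width 24) is sized so
that the 300-epoch, 5-protein experiments in the test suite and acceptance
script complete in roughly half a minute on one CPU core; depth up to the
full 30 blocks is a config switch. Min-max statistics are recomputed per
protein per layer at inference, matching how they are computed in training.

## Synthetic data generator

The generator emulates exactly the assumptions the method exploits:

- **Chains**: self-avoiding random walks with fixed 3.8 Å virtual bonds and
  a 3.5 Å clash distance. Each step samples 30 candidate directions and
  takes the most centroid-ward clash-free one with probability
  `compactness` (default 0.5, at which chains of L ≥ 30 reliably form
  medium/long-range contacts), otherwise a random clash-free one; bounded
  backtracking plus whole-chain sub-seed restarts keep generation total and
  deterministic per seed.
- **Alignments**: i.i.d. uniform background columns; a maximal disjoint set
  of contacting column pairs (separation ≥ 6, longest first) is coupled — a
  fraction ρ (default 0.8) of rows draws the pair jointly from a fixed
  two-state code. Disjointness matters: letting every contacting pair write
  its own code makes later pairs overwrite earlier ones (each column sits
  in several contacts) and empirically erases the MI signal entirely.
- **Rough maps**: clamp(label + N(0, ε), 0, 1), symmetric, default
  ε = 0.3.
- **SS/SA profiles**: geometric conventions, not DSSP — the span of a
  5-residue window classifies H/E/C, the 10 Å neighbour count classifies
  buried/medium/exposed.

What the generator does **not** emulate: real fold geometry, phylogenetic
correlation between alignment rows (no tree, no sequence reweighting is
therefore needed), gaps, alignment errors, or the systematic (rather than
Gaussian) error structure of real DCA maps. Tests passing on this generator
show the architecture, gradients, and evaluation machinery are correct and
that the network can extract the planted signal; they do not certify
benchmark-level accuracy on real proteins, which requires the full-scale
training data and externally computed features.

A consequence worth stating explicitly: with Gaussian-clamp corruption at
ε = 0.3, about half the true contacts clip to exactly 1.0 while a
non-contact needs a +3.3σ draw to get there, so the rough map's training-set
top-L/5 ranking is already saturated at precision 1.0 and a refined map can
tie but not strictly beat it. The strict refinement gain is therefore
demonstrated at ε = 0.7 (tests and the README example), where non-contacts
also clip to 1.0 and the rough top ranks contain genuine errors.

## Numerical and design notes

- Indices are 0-based internally; sparse score lists and RR files are
  1-based on disk, converted only at the I/O boundary.
- Asymmetric score matrices are symmetrized by (M + Mᵀ)/2 at load; contact
  distance is symmetric so downstream code assumes symmetry.
- Ranking ties are broken by ascending (i, j) so every report and RR file
  is byte-reproducible.
- Top-L/k selection uses m = ⌊L/k⌋; with fewer candidates than m, all
  candidates are used and the denominator is the candidate count; an empty
  candidate set yields precision 0 with a `no_candidates` flag.
- Relative improvement is 100 × (refined − baseline)/baseline to one
  decimal; a zero baseline is an error. The shipped long-range benchmark
  tables follow this convention; one benchmark's L/10–L/2 summary values in
  the literature follow a different (unstated) convention and are not
  reproduced, which `rcmpm.benchmarks` documents by simply recomputing
  everything from the precision cells.
- Residues lacking both Cβ and Cα are dropped at parse time with a warning;
  all downstream indices refer to the retained chain.
- He-normal weight initialization, biases zero; every source of randomness
  (init, epoch shuffling, generator) flows from explicit integer seeds.

## Known limitations

- Dense numpy convolutions keep desk-scale runs fast but do not scale to
  the full 30-block, L ≈ 300 training regime on one CPU.
- The PSSM stand-in and the surrogate potential table are documented
  substitutes with the right shape and qualitative behaviour, not
  re-implementations of PSI-BLAST or of any published contact potential.
- Only the 3-class SS/SA encoding is supported; no distogram targets, no
  Cα-only or heavy-atom contact definitions, no mmCIF input.
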