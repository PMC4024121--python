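# Methods

## Overview

`graphpac` asks whether the somatic missense mutations reported for a
protein are clustered more tightly than chance would allow — a classic
signature of activating driver mutations — while taking the protein's
tertiary structure into account. A mutation cluster test needs a
one-dimensional coordinate, but residues that are 80 positions apart in
sequence can be a few Angstrom apart once the chain folds. The package
therefore linearizes the folded protein first: each residue (represented
by its Cα atom) is a vertex of a complete Euclidean graph, a travelling-
salesman insertion heuristic finds a short Hamiltonian path through all
residues, and the path rank becomes the 1D coordinate. Spatially
neighboring residues receive nearby ranks regardless of their sequence
separation, and only local geometry influences a residue's placement (in
contrast to global embeddings such as multidimensional scaling, where
every residue pulls on every other).

The pipeline is: parse structure → reconcile numbering with the
canonical sequence → restrict mutations to residues with coordinates →
linearize → order-statistic scan → multiplicity adjustment → report
clusters in original residue numbering.

## Structure parsing

ATOM records are read with fixed PDB v3.3 columns, tolerant of absent
trailing fields. Selection rules for bulk processing: only the first
MODEL, only the first-listed altLoc of each residue, and — when no chain
is requested — the first chain containing the configured atom
(`atom_name="CA"` by default; any backbone atom works). HETATM records
are ignored. Residues with insertion codes are retained and keyed by
(res_seq, icode). Non-standard residues with a conventional one-letter
equivalent (MSE, SEC, PYL) are translated; others become 'X'.

## Numbering reconciliation

Mutation tables use canonical (UniProt-style) positions; PDB numbering
is arbitrary. The default reconciliation globally aligns the ATOM-derived
sequence against the canonical sequence (Biopython `PairwiseAligner`;
match 2, mismatch −1, gap open −2, gap extend −0.5 — standard protein
global-alignment scores, configurable). Aligned columns map one
structure residue to one canonical position; mismatched columns map only
when both letters are standard amino acids; alignments under 30 %
identity over aligned columns are rejected. A direct-numbering mode
trusts PDB numbers as canonical when they are positive, strictly
increasing and without insertion codes.

Mutations on residues without coordinates are removed and the surviving
residues re-indexed 1..N in structure order. This makes the null
hypothesis uniform over exactly the N observable residues, which is what
the Beta form below assumes. Structures retaining fewer than two
mutations are dropped (no pair of order statistics exists).

## Linearization

The tour objective is min_π Σ d(i, π(i)) over cyclic permutations, with
d the Euclidean Cα distance. Three insertion heuristics are implemented:

* **cheapest** — insert the (vertex, edge) pair with the minimal
  tour-length increase; starts from the globally shortest edge;
* **nearest** — insert the unvisited vertex closest to the tour at its
  minimal-increase position; starts from the globally shortest edge;
* **farthest** — insert the vertex whose distance to the tour is
  maximal; starts from the globally longest edge.

Ties are broken deterministically (lowest vertex index, then earliest
insertion position), so runs are reproducible without randomness. On
metric instances cheapest and nearest are within twice the optimal tour
length (the minimum-spanning-tree bound); the acceptance suite verifies
this on 200 random Euclidean instances against brute-force enumeration.

A tour becomes a Hamiltonian path through the standard reduction: a
dummy vertex at distance 0 to everything is added, the tour is built on
N+1 vertices, and cutting at the dummy yields the path (its two incident
edges contribute nothing, so path length equals augmented tour length).
Orientation is canonicalized (smaller endpoint index first); all cluster
p-values are invariant under path reversal since gaps are preserved.

One consequence of the reduction is worth knowing: once the dummy is on
the tour, every unvisited vertex is at distance 0 from it, so the
*nearest* rule's selection degenerates to the index tie-break and its
insertion order becomes sequential. Empirically (30-instance sweeps,
N ≤ 8) cheapest insertion recovers the exact brute-force shortest path
on colinear and convex-position instances, nearest does so on colinear
but not always convex instances, farthest on convex but not always
colinear ones; the best of the three matched the optimum on every
instance tried. Since the pipeline runs all three methods and keeps the
most significant result per structure, no single method's blind spot is
load-bearing.

The Kendall tau distance between the path and the identity order (number
of discordant pairs, i.e. bubble-sort swaps) is reported per structure ×
method as a rearrangement diagnostic, and a close/far test checks the
linearization preserves proximity: residue pairs under 5 Å apart in
space should have smaller rank separation along the path than pairs over
25 Å apart (one-sided Welch t-test across structures; thresholds
configurable). Rank separation is used rather than summed path length
because the clustering test lives entirely in rank space.

## The clustering test

With n mutations collapsed over samples onto path ranks, the order
statistics X(1) ≤ … ≤ X(n) are formed (recurrent positions stay as
duplicates). For each pair i < k, the scaled span

    c = (X(k) − X(i) + 1) / N

is compared against Beta(k−i, i+n−k+1): the p-value is the left tail
Pr(Beta ≤ c). A small span holding many mutations gives a small p. All
n(n−1)/2 pairs are tested and Bonferroni-multiplied by n(n−1)/2
(capped at 1). Clusters are reported back in the original canonical
numbering: the endpoints of the path segment and the mutated residues
inside it.

**Span convention.** The limiting argument suggests c = gap/N
("exclusive"), but that assigns p = 0 to recurrent mutations at a single
residue (gap 0), which are precisely the strongest hotspots; counting
residues inclusively (+1) keeps them finite and matches how reference
results for single-residue clusters behave. Both conventions are
exposed; inclusive is the default.

**Accuracy of the Beta form.** The Beta distribution is a continuum
limit of a discrete statistic on {1..N}. Against a Monte-Carlo oracle
that draws n positions i.i.d. uniform on {1..N} (implemented
independently of the closed form), the inclusive Beta tail is biased
*upward* — conservative — by O(pdf(c)/N). The bias is negligible for
spans holding several mutations (k−i ≥ 2) at N ≈ 200, but for adjacent
order statistics (k = i+1) it reaches ~n/2N (e.g. +0.03 at n = 10,
N = 100). Hotspot detection is unaffected (those p-values are orders of
magnitude below any threshold), and the direction of the bias means
type-I error is controlled: under a uniform null, the fraction of
structures with any Bonferroni-adjusted p ≤ 0.05 measured over 500
simulated structures is ~0.014. No anti-conservative regime was found.

## Multiplicity across structures

Analyzing many structures (× three insertion methods) multiplies the
test family. Each cluster's Bonferroni p is scaled to p* by a
structure-level multiplier — default s(s−1)/2 with s the number of
structure/chain combinations analyzed for the protein, configurable as
an explicit integer since conventions differ. Significance is then
declared at the rFDR threshold α(k+1)/(2k) with k the total number of
structure × method tests; the threshold lies in (α/2, α], decreases in
k, and is floored to three decimals by default (0.025007… → 0.025). At
α = 0.05 and k = 3300 the threshold is ≈ 0.025007.

## Synthetic data

The generators produce the two features the method's validation needs:

* `make_helix` — an ideal α-helix (radius 2.3 Å, rise 1.5 Å/residue,
  100°/residue), chosen to reproduce the canonical ~3.8 Å Cα–Cα virtual
  bond.
* `make_contact_domains` — a three-segment fold: the chain starts in one
  helical segment, leaves on a ~60 Å spatial excursion, and returns
  antiparallel beside the first segment so that a requested contact pair
  (a, b, t) sits within t Å despite a large sequence separation. The
  contact is placed exactly (0.9 t before a ±0.05 Å coordinate jitter
  keyed to the seed); every requested pair is verified against the final
  coordinates and unsatisfiable requests raise an error. All generators
  are bit-reproducible under a fixed seed.
* `plant_mutations` / `draw_uniform_mutations` — per-sample missense
  records (whitelisted somatic status, round-robin over samples) with
  planted per-residue counts, or positions drawn from the uniform null.

What the fixtures do *not* emulate: realistic secondary-structure
variety, side chains, crystallographic noise, missing loops with
non-trivial gap patterns, or sequence-dependent mutability (CpG
hotspots, tissue composition). Passing tests therefore demonstrate the
machinery — linearization reduces the rank span of spatially close
mutations and the test calibrates against its null — not biological
discovery on real data.

Problem sizes used in the validation suite are desk-scale by design: 20
structures of 100–150 residues for planted-recovery and close/far runs
(the close/far diagnostic samples 40 residues per structure), 500
simulated structures for type-I control, 200 random instances of 5–9
points for the tour bound. Larger runs are a matter of configuration,
not code.

## Known limitations

* The Beta closed form's conservative O(1/N) bias for adjacent order
  statistics (above); the exact combinatorial null is not implemented.
* Exact-tuple deduplication of mutation reports cannot recognize the
  same cell line sequenced by two studies; that requires metadata beyond
  the generic table.
* The p* multiplier convention across multiple structures of one protein
  is exposed rather than fixed, as published conventions are ambiguous.
* Uniform mutability across residues is assumed under the null; genes
  with strong sequence-context effects violate this.
* The heuristics give no optimality certificate for the path; only the
  tour-length bound and the empirical diagnostics above.
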