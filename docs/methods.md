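# Methods

## The system being modelled

Exon 12 of mouse *Prdm9* carries a minisatellite of 84-bp repeat units, each
encoding one C2H2 zinc finger of 28 residues. Fingers bind 3 bp of DNA each
through the residues at recognition-helix positions −1, +3 and +6; these
contact codons are hypervariable and under positive selection, while the
zinc-coordinating scaffold (two cysteines, two histidines) is conserved.
Alleles differ both by point mutation within units and by gain/loss of whole
units through recombination-driven duplication (slippage) and deletion.
The package treats an allele as a sequence of units and works at that level
throughout.

## Repeat decomposition and contact extraction

Decomposition tiles the allele left-to-right into 84-nt units. When the
length is not a multiple of 84, shortened units of 84 − d nt (d an in-frame
deletion size, default {9}) are allowed; all candidate segmentations are
enumerated and scored by total Levenshtein distance of their units to the
consensus of their own full-length units, preferring (1) fewest shortened
units, (2) best consensus fit, (3) leftmost placement of the shortened unit.
The only non-84 unit observed in practice is a first finger missing 9 nt
(removing one zinc-binding cysteine), which this rule places correctly.

Contact positions are anchored, not fixed: the first zinc-coordinating
histidine of the C2H2 pattern `C-x(2,4)-C-x(12)-H-x(3,5)-H` sits at helix
position +7, so helix offset p maps to amino-acid index h1 − 7 + p. This
resolves shortened units and nonstandard offsets consistently. Units whose
pattern cannot be matched yield the placeholder `---` and are dropped by the
default (pattern-mode) confidence filter. Profile mode scores a unit against
a user-supplied position-specific table and keeps it only strictly above the
threshold (default 17.7 bits, the gathering threshold used for the published
zinc-finger model); no profile is bundled, since reproducing the published
model's scores is out of scope.

## The repeat edit distance

Two unit arrays are compared by global alignment dynamic programming where

- substituting unit a by unit b costs `w_mut` × Hamming distance when the
  (masked) units have equal length, and `w_mut` × Levenshtein distance
  otherwise (Hamming is undefined for unequal lengths; shortened first units
  force this case);
- deleting/inserting a unit costs `w_slippage` when the unit is identical
  (≤ `slippage_max_mismatch` nucleotides, default 0) to an immediate
  neighbour **in its own array** — i.e. it looks like a tandem-duplication
  copy — and `w_indel` otherwise.

Defaults `w_mut = 1`, `w_indel = 3.5`, `w_slippage = 1.75` are the costs of
the repeat edit-distance model this metric follows. Judging slippage against
the unit's own array keeps the function symmetric; runs of k identical
inserted units are charged per unit, not per event. The result satisfies
non-negativity, identity and symmetry; the triangle inequality is *not*
guaranteed (the slippage discount can break it) and is deliberately not
asserted anywhere.

The masked variant removes the nine contact-codon nucleotides from each
unit before comparison, located per unit via the anchoring rule above. A
canonical-length unit whose C2H2 pattern is unresolvable (e.g. an anchor
residue was substituted) is masked at the canonical positions instead, so
masking stays uniform across 84-nt units and masked ≤ unmasked holds
pairwise; a shortened unresolvable unit is compared unmasked. Masking
removes positions only, which is the mechanism by which alleles differing
solely at hypervariable sites collapse onto one branch of the masked tree.

## BIONJ

The agglomeration is Gascuel's BIONJ: standard NJ Q-criterion for pair
selection and branch lengths, but the reduced distance row is the convex
combination λ·(row i) + (1−λ)·(row j) with λ chosen to minimize the variance
of the new row (variances initialized to the distances and reduced
alongside). On additive matrices λ has no effect and the generating tree is
recovered exactly (checked to 1e-9). Numerical choices: ties on Q broken by
the lexicographically smallest pair of cluster representative labels (makes
all-zero blocks deterministic); negative branch-length estimates clamped to
zero with the deficit moved to the sister branch; outgroup rooting splits
the pendant edge at its midpoint (root placement on that edge is otherwise
unidentifiable). One test cross-checks topologies against R `ape::bionj` on
a noisy (non-additive) matrix, where the variance weighting actually
matters.

## Binding motifs

Per-finger specificities are pluggable. The built-in fallback is a
simplified recognition code — Arg/Lys/His → G, Asn/Gln → A, Asp/Glu → C,
pseudocount 0.01, uniform columns for residues without a documented
preference — deliberately coarse: it exists so the assembly/scan/overlap
algebra is exercised end-to-end, not to reproduce any trained predictor.
Externally computed per-finger matrices (MEME- or JASPAR-style text) can be
supplied instead and are used verbatim after a normalization check. Array
PWMs are the N→C concatenation of per-finger matrices, reverse-complemented
(reverse column order, swap A↔T and C↔G), matching the convention in which
the published motifs are reported.

Motif similarity: best summed per-column Pearson correlation over all
offsets with ≥ `min_overlap` aligned columns and both orientations
(constant — e.g. uniform — columns contribute 0). The p-value is empirical:
the add-one-corrected fraction of column-shuffled targets whose best
alignment scores *strictly better* than the observed one — the probability
that a random motif would be better matched than the input. It is therefore
never 0 (floor 1/(n_shuffles+1), the value every self-comparison attains)
and never above 1. This is a permutation analogue of the TomTom null, not
TomTom's exact null distribution.

Scanning: windows on both strands are scored as log2 odds against a
zero-order background (estimated from the scanned FASTA in the pipeline,
floor 0.01 per base; uniform by default), with scores discretized to 1e-3
bits. The threshold for a requested match p-value comes from the exact
score distribution under the background, computed by DP convolution over
columns on the same 1e-3-bit grid — so empirical hit rates on i.i.d.
background match the requested p up to Monte-Carlo error. Windows containing
non-ACGT letters are skipped; minus-strand hits are reported in
forward-strand half-open coordinates; opposite-strand hits at one locus are
both reported. Overlap between hit sets counts ordered pairs sharing ≥ 1 bp
on the same chromosome (strand-agnostic, sweep over start-sorted intervals)
plus the Jaccard of merged base-pair coverage.

## The simulator

`simulate_allele_family` evolves an ancestral array of identical canonical
84-nt units (a synthetic C2H2 unit authored for this package, with contacts
S/D/T) along a Yule tree rescaled to unit height. Per branch, event counts
are Poisson: substitutions at `sub_rate` per unit per unit branch length
(the nine contact nucleotides weighted `contact_hypermut_factor`-fold to
mimic positive selection; substitutions creating in-frame stops are
rejected, as alleles are functional), tandem duplications at `dup_rate` and
unit deletions at `del_rate` per array, with a floor of one unit. Defaults —
8 leaves, 11 ancestral units, sub_rate 2, dup/del 0.3, hypermutation ×10 —
are the package's chosen study conditions: they give arrays of 9–12 units
and tens of nucleotide differences between alleles, the regime the real
allele panels occupy. Every event is logged and replay from the ancestor
reproduces each leaf exactly.

What the simulator does **not** emulate: within-unit indels, gene
conversion between non-adjacent units, biased gene conversion/hotspot
erosion, selection on binding phenotype, or population-level processes.
Passing tests therefore demonstrate the correctness of the pipeline's
algebra and its behaviour under unit-level tandem evolution — not that the
method is robust to every mutational process real minisatellites undergo.

## Phenotyping utilities

Sperm concentration: (A25 + B25) counts divided by the counted chamber
volume (default 25 squares × 0.02 cm × 0.02 cm × 0.01 cm = 0.0001 cm³ =
0.0001 ml) times the dilution factor (default 40), reported in million/ml.
Transmission-ratio distortion: two-sided binomial test against 0.5 — exact
(minimum-likelihood two-sided, via scipy) or the normal approximation with
continuity correction; the two agree within ~10% for n ≥ 200 near 50:50.

## Problem sizes

Default test and acceptance runs use 8-leaf families (50 replicates for
topology recovery), 400,000-position background scans for calibration,
500 random array pairs against the exhaustive edit-script oracle and 1,000
random interval sets against brute-force overlap counting; the analysis
drivers use a 19-allele panel and a 200-kb planted genome. These sizes give
stable statistics (Monte-Carlo checks pass at 3 standard errors) while the
whole suite runs in seconds.

## Known limitations

- The distance is not a true metric (no triangle inequality); downstream
  methods that require metricity should not consume it blindly.
- The recognition-code fallback is far coarser than a trained predictor;
  motif-level results with it are structural, not biological, statements.
  With it, many related arrays reach the permutation-null floor p-value.
- BIONJ guarantees exactness only on additive inputs; on real data it is a
  heuristic like any NJ variant.
- Profile-mode repeat filtering needs a user-supplied scoring table.
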