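# Methods

This note documents the models, conventions and numerical choices behind
`cactaintrons`, and what the simulation-based tests do and do not show.

## Coordinates and sentinels

All public coordinates are 1-based and inclusive: alignment columns,
alignment rows, and protein residue positions. Gap characters are `-`
and `.`; every other character (including `X` and other ambiguity
letters) is a residue and may carry a confidence score. A boundary whose
alignment column was removed by trimming is a distinguished null in
memory (`None`) and `0` on disk, mirroring how such boundaries are
conventionally printed. Regions without a label serialize as `.`.

## Boundary annotation

An exon model is an ordered list of non-overlapping nucleotide spans on
the coding strand. For the boundary after exon *i*, with `cum` the
cumulative coding length at that exon's end:

* `protein_pos = ceil(cum / 3)` — a boundary falling mid-codon is
  assigned to the *split codon's* residue. One residue per boundary is
  required so a boundary can project onto exactly one alignment column;
  whether published tables use the split-codon residue or the last fully
  encoded one is not stated anywhere we know of, so the choice is a
  convention and is recorded in the boundary's `phase` field
  (`cum mod 3`), from which the alternative can be recovered.
* `intron_len_aa = floor(intron_nt / 3)` — intron lengths on the protein
  scale, rounding down since no rounding convention is published.
* A trailing incomplete codon at the CDS end is dropped with a warning;
  consensus sequences of transposon families are often frame-imperfect
  and the trailing fragment carries no boundary information.

The implementation is verified against a brute-force oracle that tags
every coding nucleotide with its codon index and reads the boundary
residue off the tags (1,000 random exon models).

## Confidence trimming

Two rules, both operating on columns only (rows are never removed):

* **custom** (`trim_custom`, τ default 0.804): remove a column iff all
  its residues score strictly below τ, or it has ≤ 1 residue. "Below" is
  strict — a residue scoring exactly τ saves its column. Single-residue
  columns are removed unconditionally (they are not comparable and
  typically badly aligned); all-gap columns carry no signal and are
  removed with the same reason. The two sub-rules commute: the removed
  set does not depend on their order.
* **guidance_default** (`trim_default_guidance`, cutoff default 0.93):
  remove a column iff its column score is strictly below the cutoff.
  When no native column-score table is supplied the column score is the
  arithmetic mean of the residue scores in that column — the specific
  column statistic used by confidence tools is not always published, and
  the mean is the neutral choice; it is echoed in the run log.

Removal under the all-below rule is monotone in τ (tested); kept and
removed columns always partition the original set, and composing the
old→new and new→old column maps is the identity on kept columns.

## Projection

A boundary's residue is found via its sequence's gap structure (the
*i*-th non-gap character), then mapped through the trimming column map.
A boundary in a removed column is reported REMOVED rather than snapped
to the nearest kept column: clustering must not see fabricated
positions. Projection preserves the 5'→3' order of surviving boundaries
within each transposase.

## Region clustering

Distances are absolute differences of trimmed-MSA columns. Clustering
is agglomerative with two ingredients:

* **constraint** — a merge is allowed only if the merged cluster's
  diameter (maximum pairwise distance) stays ≤ `d_max`, *inclusively*: a
  region may span exactly `d_max`. The inclusive reading is forced by
  the data this method is designed for, where a published region spans
  exactly the threshold.
* **order** — among allowed merges, the pair with the smallest
  nearest-neighbour distance merges first; ties break by the smallest
  leftmost column of the merged pair, then lexicographically by member
  labels, making the outcome deterministic and invariant under input
  permutation.

Ordering merges by nearest-neighbour distance (rather than by the
complete-linkage distance itself) matters: with boundary columns at
895, 910, 920–936, diameter-ordered merging would attach 910 to the
920s before the 920s can reach the 930s, splitting a real region in
two. Nearest-first order lets tight cores form before borderline points
attach; the diameter cap still prevents chaining across distinct
regions, which plain single linkage would commit. The threshold itself
is `floor(min intron length / 2)` — the largest shift a boundary can
undergo while remaining nearer its own region than a neighbouring one.

Clusters with ≥ `min_region_size` (default 4) members are promoted to
regions labelled R1, R2, … by increasing mean column; smaller clusters
are classified `small_cluster` (2–3 members) or `singleton`. The
default of 4 reflects the smallest cluster the source analysis promoted
to a named region while leaving a 3-member chain unnamed. Per-region
gap statistics report the distance to the nearest boundary outside the
region on either side.

On the packaged boundary-table fixture the computed inter-region
distances are 96 (between the 771–783 and 879–895 regions) and 25
(between 879–895 and 920–936); they are reported as computed.

## Ancestral reconstruction

Each region is one binary character; a taxon scores 1 iff it has ≥ 1
boundary in the region. Boundaries outside regions ("unique") are
excluded from the matrix — with no second observation they cannot be
polarized as gain or loss — but remain reported in the classification
table. Taxa without boundaries must be declared intronless explicitly,
so silent data loss is impossible.

Ancestral states are computed per character with the Sankoff dynamic
program on the rooted (possibly multifurcating) tree, under gain cost 2
and loss cost 1 by default. The asymmetry encodes that intron loss
predominates in this family, while still letting one gain (cost 2)
out-compete ≥ 3 independent losses — exactly the trade-off needed to
recognise a clade-specific gained intron. Equal costs reduce to Fitch
parsimony; an effectively infinite gain cost gives Dollo behaviour
(at most one origin per character).

Tie handling is explicit: at the root, ties prefer presence
("intron-early" reading), are flagged `ambiguous`, and the policy is
configurable; below the root, a child keeps its parent's state whenever
that is among the optima, so no spurious events are emitted. The event
list replayed from the root provably reproduces every tip state
(tested), and the realized event costs sum to the DP minimum, which is
checked against exhaustive enumeration of all internal labelings on
trees with ≤ 8 tips over random cost pairs.

Clade-level consensus exon numbers use the modal count per clade; ties
take the larger count and are flagged.

The packaged clade-level tree and state table are *figure-derived*: the
topology and one clade's states are transcriptions/reconstructions from
a published figure rather than machine-readable data, and are labelled
as such in their filenames.

## Simulator

The simulator provides ground truth for every stage:

* **Tree**: supplied Newick, or a pure-birth tree (birth rate 1.0)
  sampled to `n_tips` (default 12).
* **Root protein**: uniform random sequence of `root_length` (default
  400) residues with three introns at positions 100/200/300 of lengths
  45/39/33 aa — so the derived clustering threshold is 16, matching the
  conditions of the dataset this generator emulates.
* **Substitutions**: uniform over the 20 amino acids, Poisson with rate
  0.5 per site per unit branch. The pipeline uses no substitution-model
  detail, only alignment/score structure, so richer models would add
  nothing testable.
* **Indels**: Poisson events at 0.02 per site per unit branch,
  insertion/deletion equiprobable, geometric lengths (mean 3). Every
  residue carries a homology token; the true alignment is the global
  token order, so stripping gaps from any row reproduces that tip's
  sequence exactly (tested). Deletions never erase a whole sequence.
* **Introns**: anchored to their boundary residue's token; loss with
  probability `1 − exp(−0.3 t)` per intron per branch (overridable per
  branch for targeted tests), gains Poisson at 0.1 per branch unit at a
  uniform residue, each gain a new character. If a deletion removes an
  anchor the intron re-anchors to the nearest surviving residue.
* **Scores**: residues score `0.95 ± 0.03` (Gaussian, clipped to [0,1]);
  columns created by insertion or flanking a deletion are depressed by
  0.35, emulating how alignment-confidence methods penalise indel-rich
  columns. By construction indel-affected columns score lower on
  average (tested).

A single seeded generator drives all sampling in a fixed, documented
order (tree; per branch: substitutions, indels, losses, gains; scores),
so identical configurations give byte-identical outputs. Rates are
applied to the sequence length at branch start — a standard
simplification that slightly underweights within-branch length changes.

**Recovery metrics.** Regions are matched to true characters by
greatest member overlap (greedy, deterministic). Recall is measured
over *eligible* characters — those with ≥ `min_region_size` boundaries
among the boundaries the clustering actually saw; a character whose
anchors were trimmed away below that size is unrecoverable by
construction and would only obscure the metric. Root-state and event
accuracies are computed over matched characters.

**What the benchmark shows.** At the default configuration (12 tips, 3
root introns, 20 seeds) mean region recall is ≥ 0.9 (measured 1.0) and
zero-rate simulations are recovered perfectly. The generator emulates
the statistical structure the analysis assumes — a conserved core,
indel-depressed confidence scores, clade-structured intron presence.
It does not emulate alignment *error* (the true alignment is given to
the pipeline), consensus-sequence artefacts, rate heterogeneity among
sites, or annotation mistakes, so passing recovery tests demonstrate
correctness of the pipeline's logic, not robustness of the upstream
alignment and annotation steps on real data. Exact per-event recovery
is not guaranteed at the default loss rate: deep loss histories admit
several equally parsimonious placements, and measured exact-event
recovery is about 0.89 on average across the benchmark seeds.

## Known limitations

* Confidence scores are consumed, never computed; the bootstrap
  machinery behind them is out of scope.
* Tree estimation is out of scope; trees are inputs.
* Boundary positions inherit any error in the upstream exon
  annotations; the mid-codon convention above can differ by one residue
  from tables produced with the last-full-codon convention.
* Parsimony reconstruction reports one optimal labelling (with
  documented tie policies) rather than the full set of optima; root
  ambiguities are flagged per character.
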