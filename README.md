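# cactaintrons

Tools for studying the evolution of exon/intron structure in a conserved
protein family, built around the DDE transposases of *CACTA* DNA
transposons in monocot and eudicot plants. Although these transposases are
ancient and functionally conserved, their genes carry anywhere from one to
six exons. `cactaintrons` asks where the exon/intron boundaries fall on a
common alignment, which boundaries are homologous, and whether the
observed diversity arose mainly through intron loss or intron gain.

## What the package does

1. **Boundary annotation** (`cactaintrons.annotate`): exon coordinates in
   nucleotide space are converted to protein-scale boundaries. The
   boundary after exon *i* is placed at residue `ceil(cum/3)` (the residue
   whose codon contains, or immediately precedes, the intron), with phase
   `cum mod 3`, where `cum` is the cumulative coding length at the exon's
   end; intron lengths are reported as `floor(nt/3)` amino acids.
2. **Confidence trimming** (`cactaintrons.trim`): a protein MSA with
   per-residue confidence scores in [0, 1] is trimmed column-wise. The
   boundary-preserving rule removes a column iff every residue in it
   scores strictly below a threshold τ (default 0.804) or the column holds
   at most one residue; the conventional column-score rule removes columns
   scoring below a cutoff (default 0.93). Bidirectional coordinate maps
   (residue ↔ original column ↔ trimmed column) are kept.
3. **Projection** (`cactaintrons.project`): each boundary is lifted onto
   its trimmed alignment column; boundaries whose columns were trimmed
   away are reported with a REMOVED sentinel (0 on disk), never snapped to
   a neighbouring column.
4. **Region clustering** (`cactaintrons.regions`): boundary columns are
   clustered by diameter-constrained agglomeration — nearest pairs merge
   first, but no cluster may ever span more than `d_max` columns
   (inclusive). The threshold is `floor(min intron length / 2)`; clusters
   with ≥ 4 members become named regions, interpreted as homologous intron
   positions.
5. **Ancestral reconstruction** (`cactaintrons.reconstruct`): region
   membership becomes a binary intron presence/absence matrix, and a
   weighted Sankoff parsimony (gain : loss = 2 : 1 by default) infers
   ancestral configurations and per-branch gain/loss events on a rooted
   phylogeny.
6. **Simulation** (`cactaintrons.simulate`): a sequence evolver with
   substitutions, tracked indels, and intron loss/gain emits true
   alignments, depressed confidence scores in indel-rich columns, and full
   event histories, so every stage can be scored against ground truth.

## Worked example

The package ships a transcription of the published boundary table (86
boundaries on 40 multi-exon transposases; 73 carry trimmed-MSA columns,
13 fall in trimmed-away columns) as `cactaintrons/data/table1.tsv`.
Clustering its projected columns:

```bash
cacta-introns cluster \
    --table src/cactaintrons/data/table1.tsv \
    --threshold auto --intron-lengths 33 \
    --min-region-size 4 --out regions.tsv --distances distances.tsv
```

prints

```
threshold 16: 13 clusters, 4 regions R1[563-568]x4, R2[771-783]x14, R3[879-895]x23, R4[920-936]x18
```

— the threshold is half the shortest annotated intron (33 aa → 16
columns), and four regions emerge: the clade-specific cluster G
(columns 563–568, 4 boundaries) and the three ancestral regions I
(771–783), II (879–895) and III (920–936). The nearest boundary upstream
of region I is 60 columns away and the nearest downstream of region III
is 36 away, so the regions are clearly separated; the boundary at column
910 joins neither flanking region (it would stretch either beyond 16) and
stays a singleton.

Reconstructing ancestral states on the clade-level consensus tree
(`data/clade_tree_figure_derived.nwk` + `clade_states_figure_derived.tsv`,
a figure-derived fixture):

```python
recon = parsimony_reconstruct(tree, matrix)
events, summary = enumerate_events(recon)
```

gives

```json
{"root_introns": ["I", "II", "III"], "root_exon_count": 4,
 "n_gains": 1, "n_losses": 11}
```

i.e. an ancestral transposase with four exons whose three introns
correspond to regions I–III, shaped afterwards predominantly by intron
loss, with a single gain (region G) on the stem of one clade.

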