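# Methods

## Analysis conventions

**Normalisation.** CPM scales each cell's counts to a library of 10⁶;
RPKM additionally divides by gene length in kilobases, so RPKM equals CPM
exactly for a 1000-bp gene. Logs are log₂ with pseudocount 1 (both are
conventional rather than canonical; the pseudocount and the
mean-of-logs vs log-of-means orderings are configurable in
`gene_summaries`). Library sizes exclude spike-in rows by default, since
spike-in content varies strongly between protocols.

**Per-gene summaries.** For each gene: mean over cells of log₂(CPM+1),
dropout rate (fraction of cells with zero count), and mean of
log₂(RPKM+1).

**Length bins.** Genes are sorted by (length, gene id) and cut into
`n_bins` (default 10) contiguous groups whose sizes differ by at most one;
when the division is uneven the *last* (longest) bins take one extra gene
each. The gene-id tiebreak makes binning deterministic under duplicated
lengths. Bin summaries report medians and linearly interpolated quartiles.

**Trend statistics.** The visual per-bin trend is condensed into Spearman
rank correlations of gene length against each per-gene statistic
(midranked ties, large-sample t p-values). A constant statistic has no
defined rank correlation and is reported as NaN.

**QC boundary semantics.** Every filter is phrased as a removal condition
("dropout greater than 80%", "fewer than half a million reads", "more
than 90% zeroes"), so observations exactly at a threshold are *retained*.
Per-cell dropout uses all matrix rows before gene filtering; per-gene zero
fractions use the cells that survive cell filtering (cell QC precedes gene
filtering). Spike-in rows are always removed from the analysis matrix.
Plate-level spike-in review (`batch_spikein_summary`) is a table for the
analyst, not an automatic rule — there is no defensible numeric criterion.

**Detection.** A gene is detected in a dataset when nonzero in at least
⌈f·n_cells⌉ cells (default f = 0.10); the ceiling makes the criterion
"at least". A protocol group's detected set is the intersection over its
member datasets; the comparison universe is the union of all per-dataset
detected sets. Combining datasets restricts each to the shared ordered
gene list and concatenates columns; PCA is an SVD of the column-centered
log-CPM matrix with each component's sign fixed so its largest-magnitude
loading is positive. No batch correction is applied — the dataset effect
is reported, not removed.

**Enrichment.** Categories come from user-supplied GMT files and are
intersected with the universe before a one-sided (upper tail)
hypergeometric test; Benjamini–Hochberg adjustment across tested
categories, significance at FDR ≤ 0.05. Category median lengths are
computed over universe members with known lengths. The spread comparison
of category median lengths is an F test on sample variances with a
two-sided p = 2·min(upper, lower tail); it is offered on raw and log
scales because a fold-difference in spread is scale-dependent — the log
scale is the default recommendation for lengths.

**Differential expression stand-in.** The DE stage preserves the design
of a count-based DE analysis (normalise → test → fold-change cutoff → BH)
while staying deliberately simple: median-of-ratios size factors
(reference = genes expressed in every cell; library-size fallback with a
warning), per-gene Wilcoxon rank-sum on log₂ normalised CPM, BH across
genes, and a post-hoc |log₂FC| cutoff (1.0 is a reasonable default for
full-length data, 0.5 for shallower UMI data). It is not a reimplementation
of any GLM-based method: no dispersion estimation, no moderation, no
formal thresholded testing. Its type-I error under a null simulation is
checked in the test suite.

## The protocol simulator

The generative model separates biology from protocol:

1. **Truth.** Gene lengths ~ LogNormal(ln 2500, 1.15²) bp, clipped to
   [200, 100000] — median 2.5 kb and a ~300 bp–30 kb bulk range, matching
   union-exon lengths of a mammalian annotation. Baseline expression
   ~ LogNormal(ln 20, 2.5²) molecules per cell — a median of ~20 molecules
   with ~4–5 orders of magnitude of dynamic range, so that sequencing
   depth (not molecule presence) limits detection for most genes, which is
   the regime in which dropout is depth-driven. A fraction (default 0.1)
   of ordinary genes gets a condition log₂ fold change ~ Normal(0, 1);
   92 spike-ins have fixed input per cell (no condition or capture
   effect) and short lengths (~250–2000 bp); 13 mitochondrial and 80
   ribosomal-protein genes carry conforming symbols so classification
   recognises them.

2. **Molecules.** M<sub>gc</sub> ~ NegBin with mean
   e<sub>g</sub>·2^(lfc<sub>g</sub>·cond<sub>c</sub>)·capture<sub>c</sub>
   and over-dispersion φ = 0.6 (var = μ + φμ²), sampled as gamma–Poisson;
   per-cell capture ~ LogNormal(0, 0.35²).

3. **Reads.** counts ~ Poisson(M · d · (max(ℓ − 300, 10)/1000)^α).
   α = 1 models fragmentation (full-length), α = 0 molecule counting
   (UMI). The length factor uses the *effective* length
   max(ℓ − fragment size, 10) with a 300 bp fragment size: fragment-based
   library preparation cannot draw an insert from a transcript shorter
   than the fragment, so very short genes yield disproportionately few
   reads. This term is what lets a shallow UMI protocol detect short genes
   that a much deeper full-length protocol misses — with a purely
   proportional ℓ^α factor, a 33× depth advantage would make the
   full-length mean exceed the UMI mean for every gene above ~150 bp and
   the observed UMI-only detection class could not exist. The depth factor
   d is calibrated so the expected mean library size equals `depth_scale`
   (defaults: 10⁶ for full-length, 3×10⁴ for UMI, echoing the typical gap
   between plate-based and shallow UMI libraries).

Dropout is emergent from this hierarchy; there is no zero-inflation
parameter. All draws derive from a single integer seed
(`numpy.random.default_rng` with stream separation between truth and
counts), so identical designs reproduce identical output files.

`mesc_like_pair` couples a deep full-length and a shallow UMI design to
one shared truth (same genes, same cells, independent sampling). The test
suite and acceptance script run it at 5000 genes × 200 cells, a size
chosen so the full analysis completes in seconds while keeping Monte-Carlo
noise on the trend correlations below ~0.01.

### What the simulator does and does not emulate

It reproduces: length-proportional counts and length-dependent dropout
under fragmentation, trend-free UMI counts, RPKM distortion of molecule
counts, depth-driven detection asymmetry between protocols, composition
bias visible in spike-ins when conditions shift total RNA, and
two-condition fold changes. It does not model: sequence-level effects
(GC, mappability, priming position), amplification-cycle noise, UMI
collision/saturation, isoform structure, doublets, ambient RNA, or
empty droplets. Passing tests therefore demonstrate that the analysis
machinery recovers the fragmentation/molecule-counting mechanism and its
consequences — not that any particular real dataset is free of the
unmodelled artefacts.

## Degenerate inputs and tie-breaks

Zero library sizes are errors naming the offending cell; all-zero cells
have dropout 1 and spike-in fraction defined as 0; removing every cell
yields a valid empty dataset plus a logged warning. Non-integer or
negative matrix entries are format errors naming the coordinate. Exon
intervals are merged as 1-based inclusive (adjacent intervals merge);
genes without exon features are absent from the length map. The Wilcoxon
implementation enumerates exactly for ≤16 pooled untied observations and
otherwise uses the tie- and continuity-corrected normal approximation.
Rank-sum p-values on constant genes (zero rank variance) are set to 1.

## Known limitations

Gene classification is by identifier/symbol prefix (ERCC-, mt-/MT-,
Rps/Rpl/RPS/RPL) with overridable patterns; prefix rules can misclassify
e.g. *Rps6ka* kinases as ribosomal. The DE stand-in is underpowered
relative to GLM methods at small group sizes and ignores dispersion
sharing. The enrichment module does no ontology-graph propagation and no
length-bias correction of enrichment itself. Combined-dataset PCA does not
correct batch effects by design.
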