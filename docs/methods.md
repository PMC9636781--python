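# Methods

`methmotif` implements the computational side of methyltransferase-based
epigenome mapping: determining an MTase's recognition sequence from
whole-genome bisulfite sequencing (WGBS), counting how densely a probe
motif samples a genome, analysing NOMe-seq accessibility data, and
simulating all of the above with known ground truth.

## The methylation-weighted PWM and M-logo

Given a genome and a per-cytosine table of methylated/unmethylated read
counts, every cytosine (both strands) with read depth at least `min_depth`
contributes a window of length 2l+1 centred on it. Minus-strand cytosines
contribute the reverse complement of the genomic slice, so all windows
read 5'→3' on the methylated strand; windows that would leave the contig
or contain an N are skipped.

Each matrix element is the methylation-weighted base frequency

    M[i, j] = (1/N) · Σ_k  m_k · 1[ S(K_k + j) = i ]

where k runs over the N windows, m_k = meth/(meth+unmeth) is the level of
window k's central cytosine, and S(K_k + j) the base at offset j from it.
Columns are normalised to frequencies f[i, j] = M[i, j] / Σ_i M[i, j];
columns that are all zero (no weighted observation — e.g. every column of
an unmethylated genome) are flagged degenerate. Per offset the Shannon
entropy and information content are

    H_j = −Σ_i f_ij log2 f_ij        (0·log 0 := 0)
    R_j = log2(4) − H_j − 0.541

with letter heights f_ij · R_j. The 0.541 is kept as a fixed literal
small-sample correction constant; R_j is not clamped, so negative values
appear at uninformative offsets (they never enter the consensus because
the calling threshold is positive).

The intuition: at offsets where methylated windows agree on a base, the
weighted frequencies are concentrated and R_j is large; at offsets with no
sequence preference the weighted frequencies converge to the genome's base
composition and R_j falls toward its minimum. Unmethylated windows
contribute (almost) nothing because their weight m_k is (almost) zero.

## Consensus calling

The collapse of a logo to an IUPAC string is this package's own procedure
(the statistic itself defines no consensus). Two parameters:

* `theta` (default 0.25 bits): an offset is informative when R_j ≥ theta.
  The reported span is the minimal contiguous interval containing the
  central C and all informative offsets; interior offsets below theta
  become N (this is what preserves the gap in C-N-G).
* `kappa` (default 0.85): at an informative offset, bases are accumulated
  in decreasing f_ij until their cumulative frequency reaches kappa (ties
  at the cutoff are all included); the accumulated base set maps to its
  IUPAC code. kappa > 0.5 guarantees the dominant base is always included.

The defaults were chosen so that the eight-motif synthetic battery (below)
is recovered exactly while background offsets remain N. Both are exposed
on the API and CLI. A fully degenerate logo (all-zero methylation) is an
error, not an empty string.

Two numerical notes. A two-base degenerate position (R, Y, …) has
H ≥ 1 even with zero noise, hence R_j ≤ 0.459; background methylation
pushes it lower. With the window set diluted by background at weight
w = (#cytosines × background) / (#targets × efficiency), such positions
stay above theta = 0.25 only for w ≲ 0.065. This is why the recognition
battery needs the low non-conversion floor that modern PBAT-class
protocols actually deliver (see synthetic data, below).

## Genome census and analytical resolution

`count_motif_targets` counts the target cytosine of every (possibly
overlapping) occurrence of a degenerate motif on both strands; a
palindromic motif therefore contributes two strand-resolved data points
per locus, which is the convention that makes a CG census even. The
analytical resolution of a probe is genome size divided by target count,
rounded half away from zero — the mean spacing of informative cytosines.
Coverage summaries count targets with read depth at least a threshold
(default 10) and report the percentage to one decimal.

## In-silico methylation-sensitive digestion

An `Enzyme` is a recognition site, a cut offset, and a set of blocking
positions — (site offset, strand) pairs whose 5-methylcytosine prevents
cleavage. Built-ins are HaeIII (GG^CC, blocked by the first C of the CC on
either strand) and HpaII (C^CGG, blocked by either plus-strand C or their
minus-strand mirrors); both are palindromic, so a plus-strand scan finds
every double-stranded site. A cytosine counts as methylated when its level
is at least `level_threshold` (default 0.5) — a population-level stand-in
for the molecule-level wet assay. Fragments always tile each (linear)
contig exactly.

## NOMe channel separation

For a GC-writing probe, intrinsic CG methylation is read at HCG sites and
induced methylation at GCH sites, and GCG sites — where either source
could have written the mark — are excluded. For a CC-writing probe the
induced channel is the first C of CC and the intrinsic channel is CG;
these are disjoint by their next base, so no site is discarded — the
analytical argument for a CC probe. `split_channels` classifies each
record from the genome sequence itself (never trusting the report's
context column) and partitions records into intrinsic / induced /
excluded / other.

## Tracks, profiles, periodicity, regions

* Binned tracks are coverage-weighted: level = Σ meth / Σ total within
  the bin (default 10 bp). Pooled counts are robust at low depth and are
  the standard convention for WGBS tracks; empty bins are omitted.
* Aggregation profiles use unweighted per-site means across anchors at
  strand-oriented offsets, so one deep site cannot dominate a position.
* The nucleosome repeat length is the argmax of the overlap-normalised
  autocorrelation of the mean-subtracted profile (missing offsets linearly
  interpolated) over a lag window; without overlap normalisation the
  shrinking overlap biases the argmax low by ~1 bp. A normalised peak
  below 0.1 flags the estimate low-confidence (white-noise profiles).
* `profile_peak` locates the profile maximum on a moving-average-smoothed
  profile (default 51 bp). Rationale: per-base aggregate levels are noisy,
  and with phased nucleosomes an 18-bp linker is as accessible per base as
  a nucleosome-depleted region — smoothing makes the widest open region
  the unambiguous maximum.
* `call_accessible_regions` is a deliberately simple threshold/merge/
  min-length segmenter standing in for a statistical peak caller; it is
  adequate for synthetic truth recovery and should not be mistaken for
  one.
* Track comparisons inner-join bins and require a per-track depth floor
  (default 5 reads) before computing Pearson/Spearman, which stabilises
  correlations on shallow bins. How bins covered in only one dataset are
  treated is a genuine choice; the inner join discards them.

## Synthetic data: what it emulates, what it does not

`simulate_genome` draws iid bases (default composition A/T 0.295, C/G
0.205 — human-like 41% GC), optionally first-order Markov.
`simulate_methylome` sets each cytosine's true level to the **max** of

* a bisulfite non-conversion background (default 0.001, i.e. ≥ 99.9%
  conversion, attainable with current PBAT-class library protocols —
  and required for the recognition battery's degenerate positions, see
  above),
* a Beta-distributed efficiency draw if the site is a planted MTase
  target (mean = efficiency, default concentration 50; per-context
  overrides support effects like weaker CCC methylation, off by default),
* a Beta draw around the local domain mean if the site is a CG target
  under an intrinsic landscape (alternating highly- and partially-
  methylated domains with geometric lengths; defaults 0.85 / 0.40, mean
  length 100 kb).

Max-combination is used because levels are probabilities of redundant
causes, not additive quantities. Read depth is iid Poisson per site
(default λ=20) and observed methylated counts are Binomial(depth, level).
The intrinsic landscape depends only on the genome and the intrinsic
seed, so treated and untreated runs of the same genome share an identical
intrinsic truth — the property the channel-fidelity checks rely on.

`simulate_nome` adds chromatin: bulk accessibility 1 − protection;
around each anchor, a fully open NDR (default offsets [−250, −100)) with
147-bp nucleosome footprints phased from both NDR edges at the repeat
length (default 165 bp; linkers open; optional Gaussian jitter, default
off so the periodicity recovery is sharp; partial footprints at the
phased-window edge are clamped, not skipped). Induced levels are the
efficiency draw scaled by locus accessibility; the intrinsic channel
ignores chromatin.

Not emulated: read-level autocorrelation, mapping and conversion biases,
PCR duplicates, CpG islands or any sequence-dependent intrinsic
structure, cell-to-cell heterogeneity, and remodeller-driven nucleosome
positioning. Passing tests therefore demonstrate correctness of the
statistics and the pipeline's recovery behaviour under the stated
generative model, not performance on real libraries.

## Problem sizes used in the test suite

The recovery battery plants each of the eight recognition sequences
(TCTG, CG, CC, CNG, TCG, GCY, GC, RGCA) on independent 1 Mb genomes at
efficiency 0.85 and 20× coverage, three seeds each; 1 Mb gives every
motif thousands of target sites, comfortably past the signal-to-background
threshold derived above. NOMe structure recovery uses a 320 kb genome
with 50 promoters; channel fidelity uses 1 Mb with 10-kb comparison bins
(~100 CG sites × 20 reads per bin, giving a per-bin standard error well
under the 0.02 acceptance band). These sizes are the package's default
verification scale; all generators accept larger specs.

## Known limitations

* The consensus caller is single-pass; it cannot represent motifs whose
  informative offsets disagree between subpopulations (mixtures of
  MTases need separate runs).
* The census convention (both strands, overlaps allowed, alternate
  contigs included) is the one that reproduces the published hg19 counts;
  other conventions will differ at the margin.
* The threshold segmenter has no statistical control of the false
  discovery rate.
* Periodicity estimation assumes an approximately stationary profile
  across the flank; strong trends should be detrended by the caller.
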