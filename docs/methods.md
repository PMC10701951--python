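# Methods

This note describes the models and procedures implemented in `gclipp`, the
assumptions behind them, the parameters that matter, and the known limits of
what the synthetic-data tests demonstrate.

## Input model

The package operates on per-nucleotide read-depth tracks over annotated
3′UTRs. Reads are UV-crosslinking protein-occupancy footprints (GCLiPP-style
libraries); before coverage is built, PCR duplicates are collapsed to one
read per (UMI, chromosome, start, end, strand) key, where the UMI is the
short random linker sequence ligated during library construction. Tracks are
stored transcript-oriented (index 0 is the 5′-most transcript base), so all
window arithmetic downstream is strand-agnostic. Coordinates are 0-based
half-open throughout, matching BED and bedGraph. Spliced UTRs (BED12) are
concatenated exon-wise into a single transcript-space vector. Reads crossing
a UTR boundary contribute only their in-UTR bases; a read overlapping two
annotated UTRs is counted in both (annotation overlap is rare and the
alternative — arbitrary assignment — is harder to reason about).

## Occupancy peak calling

Each nucleotide *i* is scored by the Pearson correlation *r(i)* between the
coverage window centred on *i* and a Gaussian template
*g(k) = exp(−(k−c)²/2σ²)* of the same width. Peaks are local maxima of
*r(i)* passing a depth rule.

Parameters:

* `window` (default 71 nt): the scanned window. An even 70-nt window has no
  centre nucleotide, so the odd 71 (±35 nt) is used; this preserves the
  intended footprint scale while keeping the centre well defined.
* `sigma` (default `window/6`): template spread, so ±3σ spans the window —
  the usual windowed-Gaussian convention. Pearson correlation is invariant
  to the template's amplitude, so only its shape matters.
* `min_frac` (default 0.2) and `min_depth` (default 10): a candidate centre
  must carry depth ≥ max(`min_frac` × UTR maximum depth, `min_depth`)
  deduplicated reads. Both clauses are enforced simultaneously.
* `min_sep` (default `window//2`): among candidates closer than this, only
  the highest-scoring survives (ties leftmost). This guards against ragged
  multi-summit profiles being reported as several peaks.

Numerical choices: windows truncated at UTR ends are scored as long as at
least `window//2` positions remain, which avoids dead zones at track edges
while keeping correlations stable; windows with zero variance (notably
all-zero coverage) have undefined correlation and are carried as NaN, which
can never become a peak. Plateaus in the score profile collapse to their
midpoint (leftmost of the two middle positions when even). Runs touching a
profile boundary count as maxima when their single interior neighbour is
strictly lower; the depth rule filters the spurious ones. The profile is
computed in a batched vectorised form for full windows and per-position at
the edges; tests verify equality with a naive per-position loop to 1e-9.

Each reported peak is a point (the centre) with an attached ±100 nt interval
(200-nt resized peaks) for overlap analyses.

## Biochemically shared peaks across species

Occupancy tracks of orthologous 3′UTRs from two species are projected onto
the columns of a pairwise alignment (consumed as a two-record gapped FASTA;
the package does not run an aligner). Depth is normalised within each UTR to
the fraction of its maximal depth, so the two species are comparable despite
library-size differences. Gap columns carry density 0 for the gapped
species: absent sequence cannot be occupied, and keeping gap columns in
place preserves window geometry.

Each column *c* is scored over the window centred on it by the sum of three
Spearman rank correlations: cross-species ρ(norm_a, norm_b), and each
species against the Gaussian template, ρ(norm_a, g) + ρ(norm_b, g). The
cross-species term rewards concordance; the template terms demand that the
concordant signal is actually a local peak in both species. Spearman uses
average ranks for ties (Pearson on ranks; oracle-tested against an
independent implementation).

Shared peaks are local maxima of the summed score passing all of, evaluated
at the peak column itself:

* cross-species ρ > 0.75 (strict);
* normalised density > 0.5 in one species and > 0.2 in the other
  (implemented as a max/min test, hence species-symmetric);
* raw depth > 10 deduplicated reads in both species (strict).

The window width for this scan is not independently constrained; the
default reuses the 71-nt peak-caller scale and is configurable. The template
terms use normalised density; because rank correlation ignores monotone
rescaling this matters only through tie structure.

## Overlap against a shuffled-within-UTR null

To ask whether an external peak set (e.g. one RBP's eCLIP peaks) coincides
with occupancy peaks beyond chance, the observed fraction of query peaks
with ≥1 nt intersection with any reference peak is compared with a null in
which every query peak is independently re-placed uniformly among all start
positions keeping it, length preserved, inside its own 3′UTR. The null is
the simplest one consistent with shuffling within the same UTR: peaks are
placed independently and may overlap each other. Default 500 iterations; the
summary is z = (observed − null mean)/null sd with the sample (n−1) sd. The
null vector is fully reproducible from the seed. Degenerate nulls (sd = 0)
report z as ±inf (or NaN when observed equals the degenerate null exactly)
with a warning rather than a number that would suggest precision. On
single-peak instances the Monte-Carlo mean is tested against exhaustive
enumeration of all placements.

## CRISPR 3′UTR dissection scoring

A dissection library is a pool of cells carrying one deletion each within a
3′UTR amplicon; a deletion's RNA/gDNA amplicon read ratio reads out the
deleted span's cis-regulatory activity. Scoring proceeds:

1. **Filters.** Deletions retained iff strictly 20 < length < 250 nt and
   ≥ 10 reads in both RNA and gDNA amplicons; after normalisation, mutants
   with median-normalised ratio > 10 are excluded as outliers. Counts are
   reported per rule in the order length → reads → outlier.
2. **Ratios.** Counts are library-size normalised within each experiment
   (ratio = (rna/ΣRNA)/(dna/ΣDNA), sums over the length/read-filtered
   mutants of that experiment), then divided by the median ratio. The
   normalisation is computed once and not recomputed after outlier removal
   (single-pass determinism; the alternative iterated scheme changes results
   only marginally and is harder to audit). Median convention everywhere:
   even *n* takes the mean of the two middle values.
3. **Effect track.** effect[i] = log2(median ratio of retained deletions
   spanning *i* / median ratio of all retained deletions), where a deletion
   spans *i* iff start ≤ i < end (deleted bases only). log2 makes 0 neutral
   and symmetric; the scale of the original display is not stated, so log2
   is this package's documented choice. Unspanned nucleotides are NaN.
4. **Significance track.** Per nucleotide, Welch's two-sample t-test
   (unequal variances, Welch–Satterthwaite df, two-sided) of spanning vs
   non-spanning normalised ratios, reported as unadjusted −log10 p.
   Replicate experiments are pooled by concatenating their self-normalised
   ratios. Groups under two observations yield NaN; when both groups have
   zero variance, equal means give p = 1 and unequal means p = 0.

**Resolution limit.** The spanning-median statistic localises an element
only to deletion-length scale: any deletion removing the element also spans
flanking nucleotides, so the flanks share the boosted spanning sets and tie
the element's effect, producing a plateau roughly one deletion length wide.
With few spanning deletions, the single-nucleotide argmax of the effect
track lands anywhere on that plateau — and, at realistic per-mutant ratio
noise, occasionally on sparsely-spanned positions elsewhere. Interpreting
the effect track therefore means reading regions, not single-nucleotide
maxima; the significance track, which borrows strength from all non-spanning
mutants, is the better localisation guide. The acceptance suite keeps an
intentionally failing test documenting that an exact-argmax-in-element
criterion is not attainable under these library conditions (60 deletions of
21–249 nt).

## Peak annotation

* **Conservation metaprofile**: per-base conservation scores (e.g. PhyloP)
  are averaged per offset over windows centred on peaks (offsets −100..+100
  around the centre; windows truncated by track ends contribute their
  defined offsets only), then standardised across offsets to mean 0 and
  sample sd 1 so that assays with different score scales are comparable.
  A constant profile is returned as zeros with a warning.
* **Motif-window enrichment**: an even 8-nt window has no centre, so the
  window is [site−4, site+4) with the site at index 4. A site counts as hit
  when the window contains ≥1 match of the IUPAC consensus (overlapping
  matches counted); the background rate is the fraction of all overlapping
  window-length substrings of the background UTR set containing a match.
  Enrichment is fold = site rate / background rate with a one-sided binomial
  tail p — the paper-scale analysis reports fold only, and the binomial test
  is this package's addition.
* **Variant intersection**: a variant is reported for every peak interval
  containing its position inside an annotated UTR (half-open convention:
  included at the interval start, excluded at the end).
* **Distance-to-stop CDF**: the stop codon abuts the 5′ end of the 3′UTR,
  so a region's distance is its start offset in transcript orientation
  (genomic-end arithmetic on − strands).

## Synthetic data

The generators emulate the statistical shape of the real inputs, not their
sequence content:

* **Coverage**: Gaussian bumps (default amplitude 50 reads, σ = 10 nt —
  footprint-scale occupancy well above background) plus per-base Poisson
  noise (mean 2), over UTRs of 300–1500 nt.
* **Species pairs**: a common ancestral UTR with independent per-column gap
  probability (default 5% total) emits a gapped alignment directly, so no
  aligner is needed; each planted peak is present in both species with
  probability `shared_frac`, else in one.
* **Deletion libraries**: uniform spans of 21–249 nt; a deletion that
  removes the planted element entirely has expected RNA/gDNA ratio equal to
  the element's multiplier, else 1; counts are negative-binomial
  (gamma–Poisson, shape 10 around depth 200 — per-mutant ratio CV ≈ 0.45,
  consistent with real libraries needing a ratio > 10 outlier filter).
* **Peak sets**: reference peaks placed uniformly in UTRs; a controlled
  fraction of query peaks centred on reference peaks, the rest re-drawn to
  avoid them where feasible.

All generators are pure functions of parameters + seed (byte-identical
outputs on re-run). What passing tests on these fixtures do **not** show:
behaviour under sequence-composition biases, crosslinking bias, multimodal
or overlapping real occupancy footprints, alignment errors between species,
or amplicon-position-dependent PCR efficiency in dissection libraries.

## Problem sizes used in the bundled checks

The test suite and `scripts/acceptance.py` run on desk-scale data chosen to
exercise every code path at comfortable statistical power: 100 simulated
UTRs for peak recovery, 40 aligned pairs (~85 shared / ~75 single-species
planted peaks) for shared-peak detection, 500–2000 shuffle iterations for
overlap nulls, 50–100 deletion libraries of 60 mutants, and 50-peak
conservation profiles.
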