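# Methods

`te-reguscan` implements the statistical chain used to ask whether
transposable elements (TEs) have been coopted into the regulatory
architecture of decidual stromal cells (DSCs): which regulatory peaks
contain TE-derived sequence, which TE families are over-represented in
those peaks, when the genes wired to TE-derived elements acquired
endometrial expression, whether those genes respond more strongly to
decidualization and progesterone signaling, and what consensus-TE
reporter constructs do in a dual-luciferase assay. This note records the
models, the parameters that matter, and the choices made where the
design was genuinely open.

## Coordinates and interval operations

All genomic coordinates are 0-based half-open (BED native); no other
dialect exists anywhere in the package, so a peak `[100,200)` and a TE
`[200,300)` do not overlap. Strand is ignored: regulatory peaks are
unstranded.

RepeatMasker-style annotations split single insertions into multiple
records. `merge_fragmented_copies` rejoins records sharing
(chromosome, family, copy id) whose gap is at most `max_gap` (default
100 bp, exposed as a flag); the merge is transitive and idempotent.
Peak-TE intersection records every pair with >= 1 bp overlap; a peak
counts once as "TE-containing" regardless of how many copies it hits,
and once per family in family counts. Percentages are rounded to one
decimal (5344/8510 -> 62.8). Both operations are verified against
quadratic all-pairs oracles in the test suite.

## Family enrichment (eTE calls)

For a peak set and a TE family, the observed statistic is the number of
peaks overlapping at least one copy. The null is a placement shuffle:
each replicate redraws every peak's start uniformly on its own
chromosome, preserving count, lengths, and chromosome assignment
(10,000 replicates by default; a mappability mask hook exists for real
genomes but synthetic genomes have no gaps). Two p-values are reported:

* empirical: `(1 + #{shuffles >= observed}) / (n_reps + 1)` — the +1
  pseudo-count keeps p > 0;
* exact binomial: two-sided (minimum-likelihood convention) with
  per-peak success probability `expected / n_peaks` estimated from the
  shuffles.

A family is an eTE when fold = observed/expected >= 1.5 and p <= 0.05;
the binomial p is used by default (`p_rule` selects the empirical p or
the minimum of the two). Counting is per peak; a per-bp unit is the
documented alternative. With ten families at ~5% genomic density each,
200 peaks and 200 shuffles per dataset, the per-family false-positive
rate over 1,000 null datasets stays below the binomial bound and a
planted 3-fold family is flagged in >= 95% of datasets (the acceptance
suite recomputes both).

TFBS enrichment contrasts a factor's peak density (peaks per bp) inside
TE-derived peak segments with its density inside wholly TE-free peaks;
the empirical p reshuffles the factor's peaks and BH correction is
applied across factors. When no factor peak falls in TE-free peaks the
ratio is reported as an `inf` sentinel with a finite p.

## Parsimony reconstruction of expression gains and losses

Genes are scored expressed when TPM >= 2 (the threshold is inclusive;
missing TPM becomes an unknown state). Characters are optimized on a
rooted species tree by unweighted parsimony. Rather than the classical
two-pass Fitch heuristic (whose common generalizations to
multifurcations are approximate), we compute, by unit-cost dynamic
programming, the exact *MPR state set* of every node — the states the
node takes in at least one most-parsimonious reconstruction: a down
pass gives the minimum subtree cost per node state, an up pass the
minimum rest-of-tree cost, and the MPR set is the argmin of their sum.
This is exact for bifurcating and multifurcating rooted trees and is
verified against exhaustive enumeration over all internal-state
assignments (50 random trees x 500 characters, exact equality).

A branch (u -> v) carries an unambiguous gain when MPR(u) = {0} and
MPR(v) = {1}, a loss in reverse; branches touching an ambiguous node
contribute nothing, and unknown tips never create events. A gene's
recruitment age for a focal taxon is the most tipward unambiguous gain
on the root-to-tip path, or "ancestral" when the root set is {1}.

Identifiability caveat: a single change on either branch incident to
the root always leaves the root MPR set as {0,1}, so such events are
invisible to parsimony. Averaging over all MPRs per gene is not
implemented; the unambiguous-event definition is the conservative
reading used throughout.

## Responsiveness F-tests and ORA

Genes are linked to regulatory elements through pcHiC-style links: a
gene is associated with an element when one link endpoint overlaps its
promoter interval (TSS +/- 1 kb by default when only TSS are given) and
the other endpoint overlaps the element; TE-derivation, age-category,
and PGR-binding flags propagate from the element. TE age classes bin
into `ancient_mammalian` = {Mammalia, Theria, Eutheria} and
`primate_specific` = {Primates, Catarrhini} (configurable); an element
hit by both bins counts as primate-specific.

Decidualization responsiveness is compared by a two-sample F-test on
log2 fold changes: F is the ratio of (n-1)-denominator sample variances
and the two-sided p is `2*min(P(F' >= F), P(F' <= F))` under the
F(nA-1, nB-1) distribution, computed per recruitment-age stratum for
genes with vs without TE-derived elements, with significance markers at
P < 0.01 (*) and P < 1e-5 (**). Over-representation analysis is the
hypergeometric upper tail of a hit set against GMT pathway sets over an
expressed-gene background (TPM >= 2), BH-corrected.

## Reporter assay statistics

Per well, firefly luminescence is divided by renilla (transfection
control) and by the mean empty-vector ratio of the same cell type and
treatment; summaries use log2. Wells with renilla <= 0 are dropped with
a log message. Each construct is compared with the empty-vector
replicates by a two-sided two-sample Wilcoxon rank-sum test — exact
null when both groups have <= 10 replicates and no ties, normal
approximation with tie correction otherwise; a fully tied sample gives
p = 1. BH correction runs across constructs within one cell type x
treatment (a pooled family is available); calls with q <= 0.05 are
enhancers or repressors by the direction of the median relative
activity. Control constructs (the empty vector and the
progesterone-responsive positive control) are excluded from the FDR
family and from downstream counts.

The repressor excess among constructs is tested by an exact two-sided
binomial against 0.5. TSA de-repression is the fraction of untreated
repressors that lose the repressor call under TSA, with the percent
rounded to integer. The activity landscape embeds the construct x
condition matrix of median log2 activities by classical (Torgerson)
MDS — double-center -D^2/2, eigendecompose, keep the top nonnegative
eigendirections (4 by default) — implemented directly because the
specified primitive is the classical eigendecomposition, not a stress
optimizer. K-means (50 restarts, fixed seed) runs on the embedding for
k = 2..6 scored by silhouette; k = 4 is the default fixed choice
matching the strong/moderate/weak-enhancer vs repressor structure of
the landscape, and `k=None` selects by silhouette.

## Synthetic data: what it emulates and what it does not

The generator produces every input with planted ground truth and is a
pure function of (config, seed): the global seed is split into fixed
per-generator substreams, so outputs are byte-identical across reruns.

* **TE annotation** — copies placed uniformly (overlaps allowed; real
  genomes nest TEs), lognormal length jitter (sigma 0.2) around the
  family mean, fragmentation emitted as two records with a gap <= 80 bp
  (below the 100 bp merge default so merging restores copies). More
  than 90% of the genome in requested TE bp is a capacity error.
* **Peaks** — a family with enrichment multiplier m receives a targeted
  fraction of peaks placed to overlap a random copy, such that the
  expected overlapping fraction is m times the uniform-placement
  overlap probability `(merged bp + n_intervals*(L-1))/G`. That
  baseline, not the bare genomic fraction, is what a shuffle null
  estimates, so the planted multiplier equals the measured fold.
  Multipliers implying a fraction > 1 are capped with a warning.
* **Expression histories** — per gene, a root state (P(expressed) =
  0.5) evolves by a two-state Markov jump process with gain and loss
  rates of 0.005 events per unit branch length (default tree total
  ~16.4 units), keeping planted events quasi-independent (< 10% share
  a gene) — the regime where parsimony polarization is identifiable.
  The default 10-taxon tree gives the two root-adjacent branches ~3% of
  total length because events there are unpolarizable in principle.
  Tip TPMs are lognormal with log-means ln(100) (expressed) and
  ln(0.1) (silent), log-SD 0.8, so the TPM >= 2 threshold misclassifies
  a tip with probability ~1e-4. These are design choices, not estimates
  of real transcriptome parameters.
* **Links and DE** — a configurable fraction of genes receives links to
  TE-overlapping peaks; log2FC is Normal(0, sd^2 r) for TE-linked genes
  vs Normal(0, sd^2) otherwise, r the planted variance ratio.
* **Reporter plates** — renilla is lognormal transfection noise (sigma
  0.3), firefly multiplies in the construct effect (0.3x repressors, 3x
  enhancers by default among 89 constructs), a lognormal measurement
  noise (sigma 0.1), and a TSA condition effect: each repressor is
  de-repressed (effect -> 1) with a per-construct probability recorded
  in the ground truth.

The generator emulates the *statistical* structure only: no sequence,
no read-level noise, no batch effects, no correlated genes, no
chromatin context. Passing tests therefore demonstrate that the
statistics do what they claim under their own assumptions — not that
those assumptions hold in real genomes.

## Problem sizes and numerical choices

Test and acceptance workloads are scaled to run comfortably on one CPU:
enrichment calibration uses 1,000 null datasets x 200 shuffles (200
peaks, 1 Mb genome), event recovery 2,000 genes on a 10-taxon tree,
reporter power 200 plates of 89 constructs, and the bundled demo
pipeline a 1 Mb genome with 400 peaks. Empirical p-values carry a +1
pseudo-count; binomial two-sidedness follows the minimum-likelihood
convention with the standard relative tie tolerance; BH q-values are
the monotone step-up; eigenvalues below zero (numerical noise in the
double-centered Gram matrix) are clipped before taking square roots;
k-means uses 50 restarts at a fixed seed.

## Known limitations

* Parsimony cannot polarize changes on root-adjacent branches, and
  equally parsimonious reconstructions are summarized by MPR sets
  rather than enumerated.
* The shuffle null preserves chromosome assignment but not local
  features (GC, gaps, clustering of annotations); on real genomes a
  mappability mask should be supplied.
* The F-test inherits normality sensitivity; it is applied to log2
  fold changes as in the original design, without a robust variant.
* The point estimate of a variance ratio from two groups of 200 genes
  is itself noisy: the estimator is distributed as r x F(199,199), so
  even a correct pipeline recovers a planted r = 4 within +/-20% in
  only ~88% of datasets. Tests of the estimator use calibration and
  median-recovery checks accordingly.
* Reporter classification assumes exchangeable replicates within a
  condition; plate-position and day effects are not modeled.
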