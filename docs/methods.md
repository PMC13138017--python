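# Methods

This note documents the models, algorithms and numerical choices behind
d4z4kit, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Coordinates and conventions

Internally every interval is 0-based half-open. Reported positions are
1-based inclusive so that unit-internal landmarks keep their
conventional coordinates: the DR1 window at unit positions 563–814 and
the *DUX4* TSS at unit position 1688 with a ±200 nt window. BED and
bedMethyl outputs follow their own 0-based half-open conventions; VCF is
1-based.

Repeat-unit counting is KpnI-defined: a *full* unit carries both KpnI
anchors; partial units at segment ends are annotated (with lengths) but
excluded from the count; an internally truncated unit — a gap between
two intact KpnI anchors that still aligns to the canonical unit minus a
contiguous deletion — is counted.

## Unit detection

Reads are anchored on the canonical unit with exact k-mers
(`seed_k = 15`). Each shared k-mer implies a diagonal — the read
coordinate at which a unit copy would start — and anchors are clustered
by that implied start (cluster gap 400 bp, well below the 3.3 kb spacing
of consecutive diagonals and well above the indel drift of a few percent
error). Each cluster is refined by banded edit-distance (edlib) infix
alignment of the full canonical unit in a ±300 bp window; hits are kept
at identity ≥ `min_unit_identity` (default 0.70, tolerant of older-pore
error profiles). Because an infix alignment of the full unit can absorb
unrelated flanking sequence at ~0.5 per-base identity — enough to lift a
long terminal partial above the acceptance threshold — a full unit must
additionally have its 400 bp prefix and suffix align locally at the same
identity: both KpnI anchors must really be present. Boundaries are taken
from the alignment of the unit's KpnI start, so a motif corrupted by a
read error does not move the boundary.

Candidate clusters that fail the full-unit test are reused: a cluster
continuing the unit register immediately distal (proximal) of a detected
run becomes the distal (proximal) partial unit, its length measured from
the k-mer extent. When a flanking feature (p13E-11, pLAM, qB) is found,
the partial length is re-measured exactly as the gap between the last
full unit and the feature — this is the length that drives subtype
calls. Both strands are scanned; minus-strand hits are mirrored into
read coordinates. The whole read is first oriented so the main array is
on the forward strand of the working frame, and all coordinates are
mapped back at the end, which makes every downstream call invariant to
read orientation.

Gaps of 0.8–4 kb between co-oriented intact units are tested for an
internally truncated unit by global alignment of the gap sequence to the
canonical unit: the edit distance minus the unavoidable length
difference, normalised by the aligned length, must clear
`min_unit_identity`.

## Segmentation and complex alleles

Ordered unit hits are split into segments where the inter-unit gap
reaches `spacer_min_gap` (default 4000 bp — observed duplication spacers
run ~6.5–20 kb while intra-array gaps are far below 1 kb) or the strand
flips. This yields the multi-segment structures of in-cis duplicated and
triplicated alleles (e.g. "15 + 2 + 5") and isolates inverted upstream
arrays. A minus-strand segment proximal to the main array, or a
standalone D4S2463 hit there, is reported as the upstream inverted
element.

## Haplotyping

Three chromosome evidence sources are combined with fixed precedence:
unique upstream flank > unique downstream flank > XapI/BlnI motif
majority within detected units. The precedence is a design choice: flank
sequence is locus-unique, while restriction-site motifs recur per unit
and are individually vulnerable to read error. Any disagreement among
available sources sets the conflict flag; a translocated allele (10q
flanks around XapI-carrying units) is therefore reported as 10q with
conflict. A/B comes from the distal feature (pLAM → A, qB → B). Distal
subtype bins (defaults): S ≤ 450 bp, M in (450, 1000] bp, L ≥ 1500 bp;
lengths in (1000, 1500) — between the known M and L archetypes — are
left unknown rather than forced into a bin.

Spanning reads are grouped by the exact key (chromosome, A/B, subtype,
per-segment RU structure); no ±1 merging is applied because spanning
reads of the same allele agree exactly under the KpnI counting rule.
Nonspanning reads attach to the unique group they are compatible with
(no contradiction on chromosome/A-B/subtype; observed unit count not
exceeding the allele's). Mosaic fractions are spanning-read shares per
chromosome with Wilson 95 % intervals. Note that with length-biased
sequencing the spanning-read share systematically over-represents short
alleles; the simulator reproduces this distortion deliberately.

## Consensus

The longest spanning read of a group is the backbone; every spanning
read is aligned to it end-to-end by optimal global alignment (edlib) and
per-column plurality voting — including the gap symbol — is applied for
2 rounds, ties favouring the backbone, gap-majority columns deleted, and
insertions emitted only on strict majority. Register safety on a
macrosatellite is the central concern: a generic polisher can slip the
alignment by a whole unit. Here every spanning read contains the unique
flanking anchors, so an optimal global alignment cannot slip the
register without paying a full unit of edits; this makes explicit
unit-by-unit partitioning unnecessary while achieving the same effect.
After polishing, the consensus is re-annotated and the run aborts if the
segment structure changed — a restructured consensus is never emitted. A
single-read group passes the (oriented) read through, flagged
unpolished. Mean column support below 0.8 flags a probable allele
mixture.

Units extracted from the consensus are compared to the canonical unit by
global alignment (terminal partials against the canonical prefix/suffix)
and stored losslessly as alignment ops (position, ref, alt); applying a
unit's ops to the canonical unit reconstructs the unit byte-exactly,
which the tests verify. The display filter that hides <4 nt indels not
shared between units is applied only at render time, never at storage.
Alignment scoring is edlib's unit-cost edit distance; where a scoring
choice existed (tie-breaks in voting) determinism won.

## Methylation

Per-read CpG calls (probability of 5mC at the CpG cytosine, read forward
strand) are lifted onto the allele reference through the read-to-
reference alignment, both strands pooling into one site per CpG. Calls
are binarised at `meth_call_threshold` (default 0.5); a call exactly at
the threshold counts methylated (the threshold is a ≥). Region rates are
pooled counts — total methylated over total called, never a mean of site
means — for per-unit DR1/TSS windows, the whole array and the final full
unit; a region with zero calls is missing, not 0. The coverage filter
(≥ 5 reads per site) applies to profile statistics (smoothed tracks,
ACF vectors), not to pooled region rates, which already weight by
coverage naturally.

Smoothing is a centred running mean over a 2000 bp window, weighted by
site coverage (a flag disables the weighting); LOESS at span 0.2 is
available for percent-methylation plots.

The autocorrelation operates on a reference-length vector holding the
fraction modified at coverage-passing CpG sites and NA elsewhere. The
estimator is pairwise-complete: mean and variance over all observed
entries, lag-ℓ covariance averaged over pairs with both entries
observed, normalised by the overall variance. This definition is
explicit because standard ACF routines do not document their NA action;
results can diverge from an NA-passing implementation. Two properties of
this estimator matter in practice: it is not bounded by 1, and at lags
where only a thin subset of site pairs is complete the estimate is both
high-variance and biased by which regions happen to pair up (on
unit-periodic data, same-window pairs dominate sparse lags and inflate
them). The peak-detection helper therefore can mask lags whose
complete-pair support falls below a fraction (default 0.25) of the
best-supported lag in the search range; with that rule the unit-scale
peak sits at the unit length and the nucleosome-scale peak at the
modulation period across seeds.

Cohort statistics are Pearson and Spearman correlations of RU count
against the global and final-unit rates per group, with linear-fit
parameters, computed only for groups of ≥ 3 alleles with non-degenerate
variance.

## The simulator

The generator's defaults are the study conditions the rest of the
package is verified under.

Alleles are concatenations of: chromosome-specific upstream flank,
optional inverted element (a D4S2463-like truncated inverted unit, or an
inverted array given as unit lengths), a homology spacer shared between
4q and 10q alleles, p13E-11, the array segments with spacers (each
spacer carries a distal-partial stub and a copy of the distal feature,
mimicking the subtelomeric origin of duplication spacers), the distal
partial unit (S/M/L/M lengths 300/600/1900 bp), pLAM (with the
chromosome's PAS motif) or qB, and the downstream flank. 4q-type units
carry a XapI-creating sequence at a fixed unit offset and 10q-type units
a BlnI site; a translocation flag swaps the unit motif identity while
keeping the flanks. Scale note: the real ~42 kb 4q/10q homology block
and the ~42 kb upstream offset of the inverted unit are represented by a
3 kb spacer by default so desk-scale runs stay fast; the logic exercised
(flank evidence beyond the homology, inverted element proximal to the
array) is unchanged, and both lengths are parameters.

Reads are sampled by mosaic fraction; with length bias enabled the
probability of emitting a spanning read decays exponentially with allele
length (scale 60 kb), reproducing the observed excess of spanning reads
for short arrays; fragments follow a lognormal length model. Errors are
injected per base (default 3 %: 1.5 % substitution, 0.75 % insertion,
0.75 % deletion — an older-pore-like profile) with a full
reference-to-read coordinate map kept as ground truth.

Methylation truth rates per CpG: contracted arrays (≤ 5 RU) are
uniformly hypomethylated at 0.08 with no intra-unit structure, as
observed for pathogenic short arrays; non-contracted arrays follow a
logistic proximal-to-distal gradient in the unit ordinal (low 0.35,
plateau 0.75, midpoint at unit 5, scale 1.5 — plateau after roughly ten
units), modulated within units by DR1 depression (−0.40) and TSS
elevation (+0.30) and optionally by a 180 bp-period cosine (amplitude
0.15 by default) for nucleosome-scale structure; an `smchd1_factor`
multiplies all rates for mutant cohorts; rates are clipped to
[0.01, 0.99]. The DR1/TSS amplitudes are plausible placeholders (no
quantitative amplitude is established) and are exposed in the model
config. Per read, each covered CpG is a Bernoulli draw from the site
rate, emitted as a probability near 0.98/0.02 with jitter so that
threshold handling is genuinely exercised. Synthetic units carry CpGs on
a jittered grid (default every 25 ± 10 bp; a dense 10 bp grid is used
for nucleosome-scale analyses); with a real reference bundle the unit's
actual CpG positions are used instead.

What the generator does not emulate: signal-level error structure
(homopolymer bias, modification-dependent miscalls), basecaller-specific
probability distributions, chimeric reads, and real population haplotype
diversity. Passing tests therefore demonstrate the correctness of the
algorithms under a realistic but idealised noise model, not performance
on any particular chemistry.

## Problem sizes used in verification

Desk-scale runs keep the full pipeline in seconds to minutes: structure
round-trips use single spanning reads up to 40 RU (~143 kb); consensus
tests use ~10 spanning reads of 4–6 RU alleles; methylome analyses use
coverage 20–40 on alleles of 2–30 RU (ACF vectors up to ~108 kb); the
cohort-separation check uses four alleles of 6–26 RU per cohort at
coverage 5; the mosaic-consistency property uses 200 replicates of small
two-allele mixtures. These sizes are the package's verification
conditions, chosen to keep round-trips exact where the model says they
must be exact.

## Known limitations

* Feature hits below `min_unit_identity` are dropped with no rescue
  step; heavily damaged flanks can demote a spanning read to
  nonspanning. The identity and gap thresholds are decisions, not
  established constants, and are exposed as parameters.
* Nonspanning-read attachment uses a conservative uniqueness rule
  (chromosome/subtype/motifs/RU upper bound); reads compatible with
  several groups stay unassigned rather than risk wrong methylation
  pooling.
* Two alleles identical in chromosome, haplotype, subtype and exact
  structure are inherently indistinguishable from reads and collapse
  into one group.
* The consensus engine assumes spanning reads; assembling an allele from
  nonspanning fragments (as phasing tools do) is out of scope.
* `annotate_assembly` annotates contigs as given; it does not attempt to
  stitch arrays split across contigs, only flags them.
* The curation of a real reference bundle (extracting the canonical
  unit, p13E-11, pLAM, qB and flanks from a reference assembly) is an
  operator recipe: load any multi-FASTA with the documented record ids.
  Exact feature boundary coordinates in public assemblies are not
  code-enforced.
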