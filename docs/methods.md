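# Methods

`ednameta` re-implements, as a tested library, the analysis chain of a
grid-sampled coastal eDNA metabarcoding survey: paired-end 12S amplicon reads
are quality-controlled, merged, dereplicated, assigned to species by
similarity against a reference barcode database, clustered into OTUs, curated
against a local species checklist, decontaminated against negative controls,
and summarised into community statistics.  Because raw survey reads are not
bundled, a first-class synthetic-data module generates the whole study — with
known ground truth — so that every stage is testable end to end.

## The simulated survey

The generator emulates a 47-station grid inside a ~4,000 × 3,000 m bay.  Each
station contributes a surface and a bottom water sample, each sample three
independently indexed PCR replicates (282 PCR samples), plus 30 equipment and
extraction blanks: 312 PCR samples in total.

**Reference database.** `n_species` (default 40) random inserts with lengths
drawn from a truncated normal (mean 170 bp, sd 8 bp) so that each amplicon —
insert plus the 127 bp of first-PCR primer flanks — falls in the 272–322 bp
window used by the length filter.  All species pairs diverge by at least 3%
except three designed exceptions:

* a *congeneric pair* at 0.5% divergence (one substitution over ~170 bp), to
  exercise LOW-confidence assignment and genus-rank demotion;
* a *ghost species*: a locally occurring species whose barcode is missing
  from the database, one substitution away from a non-local relative that
  **is** in the database — its reads are assigned to the relative and
  renamed by the checklist substitution rule;
* a *terrestrial contaminant* that never occurs in true communities and
  seeds the blanks.

Headers carry family/genus/species, a habitat class (marine, freshwater,
diadromous, terrestrial), and local-occurrence and fishery-target flags.

**Communities.** Each community species receives a 2-D Gaussian occupancy
kernel (centre uniform in the bay, width `range_scale`, default 800 m), a
surface/bottom bias (Beta-distributed; freshwater species are pinned near a
"river mouth" corner with bias 0.95), and a log-series base abundance
(`x = 0.95`).  A station/layer pool is the set of species whose kernel weight
exceeds `occupancy_threshold` (0.05); relative abundances are the renormalised
products of base abundance, kernel weight, and layer factor.  A layer bias of
exactly 1 removes a species from the bottom-layer truth entirely.  As
`range_scale → ∞` all stations share a single pool (between-station
Bray-Curtis of expected compositions is 0).

**Reads.** Each read pair covers a primer-flanked insert from a species drawn
proportionally to abundance.  Two primer-pair variants (differing by two
bases in the forward core and one in the reverse, mimicking the U/E
fish-universal sets) are mixed 50:50.  Default read length is 2 × 170 bp: with
127 bp of flank and inserts up to 195 bp, amplicons reach 322 bp, and 170 bp
reads span the whole window with 18–68 bp overlaps, whereas 150 bp reads
could never satisfy the strict >9 bp overlap rule beyond 290 bp — the read
length is therefore chosen so the published length window stays meaningful.
Substitution errors are applied per base (default 0.3%); with probability
`chimera_rate` (default 3%) a read is a two-parent bimera with a breakpoint
at least 30 bp from both insert ends; per-base Phred qualities follow
Normal(38 − 0.1·position, 3) clipped to [2, 40], so 3′ tails degrade and
tail-trimming is exercised.  Blanks receive only contaminant reads
(Binomial(`reads_per_sample`, 0.0135) — chosen so the derived read-fraction
cut-off lands near the 1.5% regime of a real run), and real samples receive a
faint contaminant trickle (rate 0.002) that the decontamination stage must
remove.  Every read is labelled with exactly one provenance (species, chimera
parents, or contaminant), and all outputs are byte-identical under a fixed
seed.

What the generator does **not** model: PCR amplification bias, indels,
index hopping, tag jumps, realistic mitogenome evolution, or a physical
eDNA-transport model.  Passing tests therefore demonstrate the pipeline's
logic and bookkeeping under substitution-error conditions, not its robustness
to indel-rich or bias-distorted real libraries.

## Read quality control

Stages run in a fixed order, each conserving read tallies exactly:

1. **Tail trimming** — 3′ bases removed while the terminal base quality is
   below 20.
2. **Pair merging** — the mate is reverse-complemented and every overlap of
   at least 10 bp (a strict "more than 9") is scored; the offset with the
   most matching bases wins, ties to the longer overlap, subject to at most
   25% overlap mismatches (the mismatch ceiling is a package choice, exposed
   in `QcConfig`).  Disagreements keep the higher-quality base (first read on
   ties); agreements take the larger quality.
3. **Ambiguity filter** — any `N` rejects the merged read.
4. **Length window** — merged length must lie in [272, 322] bp inclusive.
5. **Bimera removal** — de novo, per sample, on identical-sequence groups in
   decreasing abundance.  A candidate is flagged when a breakpoint splits it
   into a prefix matching one previously accepted parent and a suffix
   matching another (≤1 mismatch per side), with parents at ≥2× the
   candidate's abundance and ≥3 bases apart.  Two guards prevent
   sequencing-error or primer-variant copies of a single template from being
   misflagged: the two-parent model must beat either single parent strictly,
   and each side needs ≥2 diagnostic positions where the candidate follows
   its parent on a base where the parents disagree.  Because merged reads
   still carry primer flanks at this stage, the breakpoint margin is widened
   past the flank length (`chimera_margin_covers_primers`); without this, any
   abundant template can "donate" the near-invariant primer head and rare
   primer variants are systematically destroyed (~20% of reads on simulated
   data).
6. **Primer location and stripping** — the forward primer at the 5′ terminus
   and the reverse-complemented reverse primer at the 3′ terminus, each with
   at most 3 mismatches ("fewer than 4"); the best-matching variant is
   recorded and both flanks are removed.  Reads without both primers are
   discarded.

## Taxonomic assignment, OTUs, curation

Identical inserts are grouped across the whole run; sequences with fewer than
2 reads run-wide are discarded as singletons (the threshold is applied
run-wide, not per sample — a documented reading of an ambiguous convention).
Each surviving unique sequence is searched against the reference database by
an exact-word (k = 11) seed-and-extend scan; identity is ungapped matches
over the query length, so the measure is only adequate for substitution-type
errors (a documented limitation).  A query is assigned when the top hit
reaches ≥99% identity over ≥100 aligned bases.  The aligned-length floor
replaces a BLAST E-value criterion: for ~170 bp amplicons at ≥99% identity an
E-value threshold cannot bind, so re-implementing alignment statistics would
add no discrimination.  Confidence is LOW when the runner-up species also
reaches 99%, MODERATE when it comes within 1 percentage point of the top hit
(this boundary is a package choice, exposed in `SearchConfig`), else HIGH.
Exact top-hit ties collapse to genus rank (or family when the tied genera
differ) with LOW confidence.

Assigned sequences sharing a species form one OTU whose confidence is the
worst member's.  Curation applies two checklist rules, deterministically and
per OTU: (1) LOW-confidence species-rank OTUs are demoted to "Genus sp."
unless the checklist lists exactly one local congener, which is then adopted
at species rank; (2) OTUs assigned to species absent from the checklist are
renamed through the substitution map when an entry exists, otherwise kept
with a "non-local" note.  OTUs colliding on a curated name are merged.

## Decontamination and the detection matrix

Any unique sequence with at least one read in any blank is removed from every
sample.  The per-sample read-fraction cut-off is projected from the blank
load: `C = floor(R_neg / N_neg × N_tot)` possible contaminant reads, and
`p = round(C / R_tot, 3)` as a fraction of the clustered-read total.  An OTU
is absent from a sample when its reads are *less than* `p` of the sample
total — the boundary itself counts as present.  Raw counts are preserved in
the matrix; the cut-off only drives the detected flag, i.e. sub-threshold
reads are zeroed in incidence, not in the audit layer.

## Community statistics

* **Replicate accumulation** — mean detected species over all size-k subsets
  of the PCR replicates, averaged across stations.
* **Chao1** — incidence form over the three PCR replicates: singletons are
  species seen in exactly one replicate, doubletons in exactly two;
  bias-corrected `S_obs + f1(f1−1)/(2(f2+1))` by default (defined at
  `f2 = 0`), classic `f1²/(2 f2)` available.
* **Layer partition** — surface-only / bottom-only / both species sets (their
  sizes always sum to the species total) plus per-layer detection events.
* **Bray-Curtis** — `Σ|x−y| / Σ(x+y)`; the correlogram feeds it the
  per-station count of positive PCR detections per species (0–6 with two
  layers × three replicates); presence/absence or read counts are available
  alternatives.
* **Mantel correlogram** — equal-width distance classes (Sturges' rule on
  the pair count by default), per-class Mantel statistic between the
  Bray-Curtis matrix and the class-membership model matrix, sign-flipped so
  positive values mean *more similar than average* at that distance.
  Permutation p-values shuffle station labels (two-sided,
  `(exceedances+1)/(n_perm+1)`, 999 permutations by default; an exhaustive
  mode enumerates all permutations for small n).  The default multiple-test
  correction is step-down Holm, which controls the familywise error across
  the ~11 classes; the class-by-class progressive variant is available but
  lets the per-run false-positive rate grow to ~12–14% and is therefore not
  the default.  Classes with fewer than two pairs are dropped.
* **Species accumulation** — exact sample-based rarefaction
  `E[S(t)] = Σ_i 1 − C(T−T_i, t)/C(T, t)` with the closed-form variance
  including pairwise co-occurrence covariances; empty censuses still count
  as sampling effort.
* **Detection rate / efficiency** — share of visually censused species (with
  reference barcodes) recovered by metabarcoding, and the smallest census
  count whose expected accumulation reaches the metabarcoding species total.

## Numerical and design choices

* Station coordinates are planar metres (the bay spans ~4 km; curvature is
  negligible); the station layout is a deterministic grid.
* Reported percentages round half-up to one decimal.
* The projection `C` is floor-truncated; `p` is rounded to three decimals as
  a fraction before use.
* All randomness flows from a single integer seed through per-sample spawned
  generators, so results are independent of processing order and thread
  count.
* Ground-truth recovery is scored at the species level: a species enters the
  denominator when some PCR sample holds ≥10 of its clean (non-chimeric,
  non-contaminant) reads, and counts as recovered when its expected reported
  taxon — genus rank for the indistinguishable pair, the checklist substitute
  for the ghost species — appears anywhere in the final detection matrix.
* Default problem sizes in the test suite and the acceptance script (47
  stations, 1,000 read pairs per sample, 40 species) were chosen as the
  smallest design that exercises the full study geometry with stable
  statistics.

## Known limitations

Ungapped identity cannot absorb indels; the bimera detector is a simplified
two-parent rule (sensitivity on simulated data is roughly half of the planted
bimeras, with the escapees subsequently removed by the singleton and identity
filters); the spatial kernel is a stand-in for eDNA transport, not an
estimate of it; and the E-value surrogate assumes short, high-identity
amplicons.
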