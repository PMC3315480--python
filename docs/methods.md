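# Methods

## Splice-site grammar scanning

Introns are detected with a fixed grammar: one of four donor 6-mers, a
spacer of ≥30 unambiguous bases, one of five branchpoint 7-mers, a spacer
of 1–50 bases, and a `[tca]ag` acceptor.  Matching is case-insensitive
with lazy quantifiers, so at each donor the shortest completable intron is
reported; scanning resumes after each match end, making calls
non-overlapping.  The grammar gives no guidance on overlap policy, so
leftmost-shortest/non-overlapping — the native semantics of a backtracking
regex engine — was adopted and is what the brute-force oracle in the test
suite reimplements by explicit anchor enumeration (every donor position,
ascending spacer-1, ascending spacer-2).  The spacer character class is
`[acgt]`, not `.`: an N from an assembly gap can never support a call,
which is the conservative choice.

Scan windows cover 800 bp upstream and 100 bp downstream of the ORF start
(the window in which introns of misannotated short first exons hide), are
clipped at chromosome ends rather than erroring (edge genes are real), and
are reverse-complemented for minus-strand genes so the grammar always
reads 5'→3' of the transcript; coordinates are reported back in genomic
space, 0-based half-open.  `corrected_intron_count` adds to the annotated
count only those calls that do not overlap an already-annotated intron
interval, so a re-discovered annotated intron is never double-counted.

## Ancestral intron reconstruction

The species panel is fixed: six pre-WGD outgroups (C. albicans, L. waltii,
L. thermotolerans, L. kluyveri, E. gossypii, K. lactis), Z. rouxii as the
closest protoploid, and five post-WGD species (V. polyspora, N. castellii,
C. glabrata, S. bayanus, S. cerevisiae), the last five carrying a pair of
counts per gene.  The ancestor is PRESENT iff a strict majority of
non-missing outgroups have an intron AND (Z. rouxii has one OR a strict
majority of non-missing post-WGD species have ≥1 intron in either copy);
this conjunction-with-disjunction precedence separates Z. rouxii-specific
events from post-WGD events.  "Majority" is strict over non-missing
species only; an exact tie yields AMBIGUOUS, which excludes the pair from
loss and gain counting — exclusion being the conservative resolution of a
rule stated only as "majority of available".  S. cerevisiae participates
in the post-WGD majority for its own pair by default (its evidence is
"≥1 intron in either copy", like any other post-WGD species);
`include_self=False` drops it for sensitivity analysis.

Losses are counted per pair given a PRESENT ancestor: 0, 1 or 2 intronless
S. cerevisiae copies.  A gain is flagged for an intron-bearing copy when
the ancestor is ABSENT and a strict majority of the other non-missing
post-WGD species lack introns in both copies.

The class-bias test treats each loss event as a Bernoulli trial: under the
null, a loss lands on an RPG pair with probability equal to the RPG
fraction of at-risk pairs (ancestor PRESENT, S. cerevisiae pair observed).
The p-value is the lower-tail exact binomial probability of at most the
observed RPG losses.  A two-loss pair contributes two trials, because the
histogram being tested counts losses, not pairs.  The source analysis
names an exact binomial test without constructing it; this lower-tail
loss-event construction is one reasonable reading and is recorded in the
JSON output of the analysis driver.

## Spliced-EST analysis

Alignments are BED12-style blocked records.  Track qualification requires
≥1 gap of ≥32 nt with GT..AG flanks read strand-aware (on the minus strand
the genomic flanks are CT..AC).  Coverage is per-base block membership;
the 5%/95% lines are fractions of the per-gene maximum coverage (not
quantiles of the count distribution), matching the "rare = <5% of maximum"
reading.  Junction calls aggregate distinct gaps with GT/AG flanks and
count supporting alignments; non-GT/AG gaps are excluded from junction
output but their alignments still contribute coverage.  No length filter
is applied at the junction-calling step itself — the ≥32 nt rule is track
qualification — so short GT/AG gaps in qualifying alignments are still
reported.

Event classification compares the isoform's junction set to the gene
model's: cassette exon (an added exon inside a canonical intron, both
flanking junctions novel), alternative 5'/3' splice site (one novel
junction sharing exactly its acceptor/donor, strand-aware), retained
intron (canonical junction absent, intron fully inside one isoform exon),
else canonical.  Exon-skipping chains and chimeric inputs raise an
unclassifiable error rather than guessing.

PTC annotation translates the isoform's spliced sequence from the
annotated start codon (isoforms lacking it are rejected) and reports the
first stop lying transcript-upstream of the canonical stop's genomic
position.  NMD prediction uses the 50-nt last-junction convention for
multi-intron models; that rule is a stated assumption of this package, not
something the EST data define.  For single-intron yeast-style models the
rule is instead: retained intron with an in-frame stop.

## Expression feedback readouts

Probe triplets are replicate means (≥2 replicates enforced) of
log2(mutant/wild-type) ratios per probe class.  ΔIAI = intron − exon log2
change; the index is defined only for intron-containing genes.  The
underlying index formula is not restated by the source analysis, so the
intron-minus-exon operationalisation is declared here explicitly: on the
log2 scale it is exactly the change in the pre-mRNA:total-mRNA ratio.

Boxplot classification uses linear-interpolation quartiles and whiskers at
1.5·IQR; values exactly on a whisker are inside (UP/DOWN, not outliers),
and a degenerate population (IQR = 0) collapses the whiskers onto the
quartiles.  The population handed to the classifier is the caller's
choice — all array features or intron-containing genes only — since the
readout functions are population-agnostic.

qPCR uses standard-curve quantification rather than ΔΔCq because
calibration curves are fit per primer: Cq regressed on log10(amount) over
a dilution series spanning ≥2 log10 units (the generator uses the
100→0.16 ng five-point, 5-fold series), efficiency `10^(−1/slope) − 1`,
and a hard r² ≥ 0.96 usability gate.  Technical replicates collapse to a
median Cq per biological replicate before quantities are formed; ratios to
the reference gene are log2-transformed and re-expressed relative to the
mean wild-type log2 ratio.  Transcript accounting multiplies wild-type
shares (percent of the pool, summing to 100) by linear fold-changes;
negative folds are rejected.

## Synthetic data: what it emulates and what it does not

All generators are seeded `numpy` Generators; regenerating with the same
config is bit-identical.

**Intron evolution** (defaults: 95 pairs, RPG fraction 0.48, ancestor
intron probability 1.0, per-copy loss probability 0 for RPGs and 0.25 for
non-RPGs, 5% missing entries) emulates the observed scale of the WGD
analysis: ~95 pairs descended from intron-containing ancestors, roughly
half RPGs, no RPG losses and ~24 losses elsewhere.  Each descendant
lineage loses independently at its class rate; a loss collapses the copy's
intron count to 0, because fates are scored as presence/absence per copy.
The S. cerevisiae pair is never masked missing, keeping loss counts
observable.  Not emulated: phylogenetic branch lengths, rate
heterogeneity, intron gains, or correlated loss between paralogs — so
recovery tests certify the bookkeeping and the majority rule, not
robustness to model misspecification.

**Intron sequences** sample the grammar's signal sets with spacer lengths
in [30, 120] and [1, 50]; spacers avoid the base `a`, which makes it
impossible for a filler to spell a donor, branchpoint or premature
acceptor, so conformant sequences are recognised end-to-end by
construction and each violating sequence breaks exactly its one named
criterion.  Real intron sequence composition (A/U richness) is not
emulated; sensitivity on these sequences is by construction, and the
scanner's behaviour on arbitrary sequence is covered instead by the
brute-force equivalence tests.

**Spliced ESTs** sample windows uniformly over the spliced transcript of a
deterministic three-exon template gene (1 kb chromosome, GT..AG introns of
100 and 150 nt) whose minor isoform — drawn at 3% by default, under the
"rare = <5%" regime — uses an alternative donor 60 nt into intron 2.  The
60-nt extension carries an in-frame stop >50 nt upstream of the isoform's
last junction, so the minor isoform is a *bona fide* predicted NMD
substrate.  Because the minor transcript is longer than the canonical one,
the probability that a fixed-length EST spans the intron-2 junction
differs slightly between isoforms; the junction-count ratio is therefore a
slightly biased estimator of the isoform frequency, comfortably inside the
binomial tolerance used by the tests.  Not emulated: alignment error,
EST 3'-end bias, paralogous mapping.

**Expression feedback** (defaults: shares 6%/94%, derepression folds 4.2
and 1.55, feedback strength 1, noise SD 0.1, 3 replicates, 300 background
genes) encodes the cross-regulation hypothesis directly.  In a single
intron-deletion mutant the deleted copy's exon change is
+log2(derepression fold); the paralog compensates in linear transcript
space, fold = 1 − p_mut·(f−1)/p_other (scaled by the feedback strength and
floored at 1/16 — a pool cannot go negative, and a collapse beyond 16-fold
reports at the floor, which reproduces the >8-fold collapse of the minor
copy when the major copy derepresses).  The compensating paralog's intron
probe exceeds its exon probe by the feedback strength (splicing
inhibition); the deleted copy's intron probe reports a −5 signal floor.
The double mutant derepresses both copies with no compensation, so its
accounting total is exactly p_A·f_A + p_B·f_B = 6·4.2 + 94·1.55 ≈ 170.9%.
The derepression folds were chosen to satisfy the measured constraints on
the circuit (minor copy >4-fold up, major copy <2-fold up, double-mutant
total ≈170%).  qPCR chemistry is simulated at efficiency 1 (slope
−1/log10 2) to isolate the pipeline math from chemistry realism; per-primer
efficiencies can be set by editing the intercept/slope in the generator.
Not emulated: dye-swap structure, probe cross-hybridisation between
near-identical paralogs, fold-change compression of array platforms.

## Numerical choices and problem sizes

Quartiles use numpy's linear interpolation throughout; whisker boundaries
are inclusive-inside.  The enrichment p-value is a direct
`scipy.stats.binom.cdf` evaluation (no continuity correction).  Scanner
equivalence is checked on 10,000 random windows of ≤200 bases, parameter
recovery on 1,000 simulated pairs, the EST stage on 1,000 ESTs, and the
feedback stage noiselessly plus at noise SD 0.1 — sizes at which every
check completes in seconds while binomial tolerances are already tight.
Sub-seeds for the acceptance script's stages are derived from the
command-line seed by fixed offsets.

## Known limitations

The majority rule has no explicit phylogeny: a clade of correlated
outgroups counts as independent votes.  The exact binomial construction is
one reading of an under-specified test; at-risk fractions near 0.5 make it
insensitive to which class a loss lands in when totals are tiny.  The EST
event classifier does not model exon skipping or multi-event isoforms.
The NMD rules are conventions, not mechanistic predictions.  Passing the
closed-loop tests shows the inference inverts the generator, not that
either matches the full complexity of real genomes or arrays.
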