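# Methods

## The observation model

One sectored colony yields two samples (red and white sectors), each with a
pair of allele-specific normalized hybridization ratios per SNP marker.
Heterozygous markers sit near (1.0, 1.0); homozygosity raises the retained
allele to ~1.6 and drops the lost one to ~0.3. Measurement noise is modeled
as independent, additive, zero-mean Gaussian per probe (default sd 0.1 in
ratio units), clipped at zero. Clipping rather than resampling is used
because at the default sd the clip probability is negligible (the lowest
level is 3σ above zero).

Genotypes are called per marker by nearest-centroid assignment with a
rejection radius (default 0.45, roughly the midpoint between centroids,
which are 0.92–0.99 apart). Ties break toward UNCALLED. A heuristic flags
markers consistent with hemizygous loss (one allele essentially absent, the
other near single-copy level, nothing within the radius); hemizygous calls
are a QC signal, not a genotype: dosage QC scans the arm-wide mean of
w + y against 2.0 (±0.2) and reports contiguous low-dosage runs (rolling
median < 1.7 over ≥ 20 markers) as candidate deletion regions. Events whose
tract overlaps such a region are flagged and excluded from class statistics.

## Profile analysis

Combining the two sectors' calls gives per-marker four-chromatid allele
counts: HET22, RECIP22 (reciprocal homozygosity), W31/Y31, W40/Y40, or
UNKNOWN where either sector is uncalled. Runs are formed with two absorption
rules:

* UNKNOWN markers join the run of the nearest proximal labeled marker —
  missing data never splits a segment;
* a run supported by a single labeled marker whose two neighboring runs
  agree is absorbed into them. One marker (~500 bp resolution) cannot
  support a segment against two agreeing flanks; this is what makes class
  calls robust to isolated miscalls at realistic noise, at the cost of
  invisibility of genuine single-marker segments with agreeing flanks.

A crossover is declared where the profile switches from a proximal HET22
regime to a distal RECIP22 regime persisting ≥ K markers (default K = 10,
~4.7 kb) or to the arm end; regimes shorter than K are accepted at the arm
boundaries with a warning. Runs strictly between the regimes form the
conversion tract. Segment sequences are collapsed and mapped to classes
(SIMPLE_31, SIMPLE_40, the three hybrid orders, otherwise COMPLEX with a
canonical signature such as `W31-22-W31`). A long distal homozygous regime
that is not reciprocal is flagged and produces no event.

Donor = the homolog over-represented across tract segments by converted bp
(robust to short opposite-donor patches); ties are AMBIGUOUS. Timing uses
the 4:0-presence rule: any 4:0 segment implies the lesion preceded
replication (G1), otherwise G2. Curated timing assignments for specific
complex signatures can be supplied as an override table; none are hard-coded
because per-subclass assignments require expert judgment. Transition
coordinates are always reported as flanking-SNP pairs, acknowledging the
~500-bp resolution; tract lengths are reported as min/mid/max (outermost
converted markers / transition-interval midpoints / flanking unconverted
markers), with mid as the default summary. Point-analysis represents an
event by its tract midpoint (`tract_mid`, default) or the midpoint of the
DSB-localization interval (`dsb_mid`).

## The synthetic-data generator

Defaults emulate the study system: a 449–1520 kb arm carrying 2300 markers
(even grid plus ±150 bp jitter, mean spacing ~466 bp); per 139 events, 18
conversion-free crossovers and 39 complex tracts (drawn as unconditional
fractions 18/139 and 39/139); P(G1) = 2/3; ratio levels 1/1.6/0.3 with
noise sd 0.1.

Lesions are placed by first drawing timing and initiating homolog, then
drawing the DSB position from a mixture of a uniform background (weight
0.84) and triangular hotspot kernels (half-width 10 kb) restricted to
compatible timing/homolog classes. The default hotspots sit at 872 and
981 kb (weight 0.08 each), G1- and W-specific, mimicking the inverted-Ty
pairs of the real arm. At these weights the six-bin positional test detects
the planted non-uniformity in a default cohort; on the real arm the
bin-scale excess was within sampling noise, so users modeling that regime
should lower the weights.

Tract geometry: the observable tract span is drawn log-normal,
parameterized by its median (defaults 14.8 kb for G1, 4.7 kb for G2,
σ_log = 1.0 — only medians and CIs are reported for the real data, and
parameterizing the *observable* span keeps the configured median equal to
the median of what the pipeline measures). A G2 event converts the
crossover chromatid over the whole span, with the DSB uniform inside it.
A G1 event partitions the span between the two broken sisters: each extent
is anchored at one span end and covers a fraction f of the span (f = 1 with
probability 0.25, "fully processed", else uniform on (0.3, 1)), resampled
until the extents overlap; the overlap is the 4:0 segment and the DSB lies
inside it. This reproduces the observed preponderance of hybrid over pure
4:0 tracts. Complex tracts add 1–2 unrepaired-heteroduplex patches of
200–2000 bp (mismatch-repair patches are short) on the crossover chromatid,
yielding interior 2:2 or 3:1 segments. The crossover point is the distal
span end, capped at arm_end − 10 kb because the selectable markers of the
real assay sit ~10 kb proximal to the last SNPs — this also guarantees an
observable distal reciprocal regime.

The truth record stores both the mechanistic event (timing, lesion position,
extents, patch count) and the **observable** class/donor/timing: the labels
an ideal noise-free observer of the chromatid states at the marker positions
would assign, computed with the same profile-analysis rules the pipeline
uses. The two can differ — segments narrower than the marker spacing are
invisible, and a G1 event whose sister extents share no marker is
indistinguishable from G2 (the 4:0 rule is operational, not mechanistic).
End-to-end tests therefore measure recovery of the observable truth; the
analysis rules themselves are validated separately against hand-built
fixtures and enumeration oracles, so the end-to-end identity checks
inversion of the rendering/calling chain rather than the classifier against
itself.

What the generator does **not** model: sequence content (events are purely
positional), sister-chromatid exchanges (invisible to the assay),
chromosome-scale aneuploidy, spatially correlated array noise, and
hemizygous heterology between the homologs (e.g. Ty presence/absence
differences that terminate real tracts). Passing tests on synthetic cohorts
therefore demonstrate correctness of the inference logic under the stated
noise model, not robustness to every artifact of real arrays.

## Statistics

* Rates: crossover rate = 2 × sectored-colony frequency (only half of
  reciprocal exchanges segregate into a sectored colony); 1 µS = 10⁻⁶
  crossovers/division; genome extrapolation divides by the arm's genome
  fraction.
* Positional GOF: chi-square against bin lengths; default bins are five
  200-kb bins from 449 kb plus the ~71-kb remainder; df = bins − 1. Expected
  counts < 1 trigger a warning but not a failure.
* Genetic map: the arm split into n equal physical regions (default 20,
  ~53 kb); each region carries total µS × count/N, conserving the total
  exactly.
* Median CIs: exact order-statistic method — the tightest symmetric rank
  pair (r, n+1−r) with binomial coverage ≥ 0.95 (coverage
  P(r ≤ Bin(n, ½) ≤ s−1)); or normal-approximation ranks with half-up
  rounding. The exact method's true coverage lies in [0.95, ~0.97] by
  construction.
* Mann–Whitney U: exact when n·m ≤ 400 with no ties, otherwise normal
  approximation with tie correction (scipy backend; an enumeration oracle
  cross-checks the exact branch in the tests).
* Interval-rate test: two-sided exact binomial (minimum-likelihood method)
  of the inner-interval event fraction against the length ratio.

## Enrichment

The null re-places tracts (not elements): each permutation places every
tract uniformly at random on the arm preserving its length, conditioning on
the observed element map — the question asked is "are tracts where the
elements are". Overlap counting is configurable (any-overlap vs full
containment; per-tract occurrences vs distinct elements); terminus analysis
uses the two het↔hom transition windows per tract with width-preserving
placement. Empirical p = (1 + #{null ≥ obs})/(1 + n_perm) (mirrored for
under-representation), which is valid (conservative) by construction.
Strata (all, G1, G2, W-initiated, Y-initiated) are analyzed separately and
all (class × stratum × direction) rows are BH-adjusted together. A single
permutation framework with these switches stands in for the four related
counting methods of the original analysis, whose exact definitions are not
recoverable; exact significance calls for the real tables are out of scope.

## Numerical and design notes

* Coordinates are 1-based inclusive throughout; BED input is converted at
  the I/O boundary. Probe groups collapse to their span midpoint (floor).
* Strand pairs are averaged at read time (configurable to min/median).
* Marker placement resolves jitter collisions by +1 bp nudges, preserving
  strict monotonicity.
* Per-event random streams are spawned from one global SeedSequence, so
  cohorts are reproducible and insensitive to generation order.
* Ratio tables round-trip bit-exactly (`%.17g` on write, `round_trip`
  float parsing on read).
* Problem sizes used by the heavier statistical tests: 2000 replicates for
  type-I and CI-coverage calibration, 200 cohorts of 150 events for
  parameter recovery, 500 events per noise level for end-to-end recovery,
  2000 null datasets × 400 permutations for p-value validity. These sizes
  put Monte-Carlo error well inside the asserted bands while keeping the
  suite fast.

## Known limitations

* Double crossovers on one arm are detected and flagged via multiplicity,
  but the generator produces at most one event per colony; multi-event
  colonies are covered by constructed fixtures only.
* Sister-chromatid phasing of G1 sub-tracts is unobservable by design; only
  the combined profile is reconstructed.
* The hemizygous-loss detector targets extended deletions (≥ 20 markers);
  short deletions are indistinguishable from uncalled runs.
* The paper-scale positional p-values and exact enrichment calls depend on
  per-event supplementary coordinates and method details that are not
  desk-reproducible; the package instead validates its statistics by
  calibration (type-I error, coverage, power, p-value validity).
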