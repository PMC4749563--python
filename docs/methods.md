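# Methods

This note records the models, estimators, parameter defaults and
numerical choices behind `pericentro`, and what the synthetic-data tests
do and do not establish about real data.

## Tetrad model and map distance

A two-marker interval is simulated per bivalent: the crossover count
`k` is Poisson with mean `2·(d/100)` for a true distance of `d` cM (map
distance in Morgans is half the mean crossovers per bivalent), and each
crossover involves one of the four non-sister chromatid pairs uniformly
and independently — no crossover or chromatid interference.  For the
intervals of interest (≤ 10 kb, ≤ ~8 cM) interference is negligible at
the precision of these analyses.

The tetrad class after `k` crossovers depends only on the number of
recombinant chromatids `r ∈ {0, 2, 4}` (PD, TT, NPD), which evolves as
a three-state Markov chain under chromatid-pair swaps; the production
sampler draws the class from the exact `k`-conditional law, which is
distributionally identical to replaying the chromatid choices (an
explicit chromatid-level simulator is kept as a test oracle, along with
brute-force enumeration of all `4^k` assignments for `k ≤ 4`).  This
gives the closed form `P(TT|k) = (2/3)(1 − (−1/2)^k)`.

The Perkins estimator `cM = 100(TT/2 + 3·NPD)/n` is paired with a
multinomial delta-method SE,
`Var = [t(1−t)/4 + 9v(1−v) − 3tv]/n` with `t = TT/n`, `v = NPD/n`,
derived from `Var(t)`, `Var(v)` and `Cov(t,v) = −tv/n`.  A
10,000-resample bootstrap agrees within a few percent at `n ≥ 500` and
serves as the cross-check in the tests.

**Coverage-check convention.** Parameter-recovery tests ask whether the
estimate lands within 3 SE of the simulation truth, with the SE
evaluated at the *true* class probabilities.  The plug-in SE degenerates
in zero-recombinant samples (estimate 0, SE 0), which at 0.04 cM ×
5,000 tetrads happens in ~1.8% of samples; a z-score against the truth
is the appropriate check when the truth is known.

Strain comparison uses a two-sided Fisher's exact test on
recombinant-type (TT+NPD) vs parental (PD) tetrad counts.  NPD-weighted
alternatives exist (an NPD carries two crossovers); the tetrad-class
table is the simplest construction and is what the package reports.
Tetrads failing the all-spores-CFP filter, or with non-2:2 GFP or RFP
segregation (reporter conversion), are excluded and never enter `n`.
No multiple-testing correction is applied across strain panels.
A planning helper (`required_tetrads`) sizes experiments from the
delta-method SE under a normal approximation; it is documentation-grade,
not an exact power calculation.

## Two-zone suppression model

`SuppressionModel` separates break formation from repair outcome:

| parameter | meaning | default | rationale |
|---|---|---|---|
| `dsb_floor` (s0) | residual DSB intensity at the centromere | 0.1 | strong but incomplete suppression |
| `dsb_tau` | exponential recovery length (bp) | 1,500 | ~95% recovery by ~4.5 kb, i.e. a ~3 kb zone per side; the zone is reported in the literature, not its functional form — an exponential is the simplest one-scale shape |
| `co_halfwidth` | sister-bias zone half-width (bp) | 20,000 | matches the 20-kb window used for event classification; the cohesin-rich pericentromere spans ~20–50 kb |
| `sister_bias` (b) | P(DSB in zone repaired from sister) | 0.9 | strong repair-pathway bias; invisible in spore genotypes |

DSB intensity at distance `x` from the centromere midpoint is
`f(x) = s0 + (1−s0)(1−exp(−x/tau))`.  The sister-bias zone is a hard
window; the discard decision is made on the event's *recorded*
(marker-resolution) midpoint, so the visible-event zone boundary is
exact rather than fuzzy by one marker spacing.

## Whole-genome meiosis generator

The default toy genome is 16 chromosomes × 200 kb with markers every
500 bp (hybrid-like SNP density), hotspots as a homogeneous Poisson
process at 0.3/kb with exponential (gamma shape 1, mean 1) intensities,
and centromeres placed uniformly ≥ 25 kb from chromosome ends.

Per meiosis, candidate DSBs are drawn `Poisson(rate)` (default 30) from
the hotspot distribution weighted by `intensity × f(x)`.  Survivors of
sister-bias thinning become COs with probability 0.65, else NCOs with a
one-sided geometric conversion tract of mean 2 kb.  The default rate
and CO fraction scale the canonical ~90 CO + ~45 NCO per 12-Mb yeast
meiosis down to the 3.2-Mb toy genome; the tract-length law is a
literature-typical placeholder, not a measured quantity.

Two constraints keep every planted event individually resolvable, so
the truth log is an exact reference for the caller:

* an event's affected region must lie strictly inside the
  marker-covered span of its chromosome; and
* affected regions on the same chromosome of the same tetrad must be
  ≥ 6 kb apart (`min_event_separation`, chosen above the caller's 5-kb
  CO-absorption gap plus one marker spacing per side).

Candidates violating either are discarded.  Events are then replayed in
positional order: a CO exchanges the distal segments of one chromatid
of each homolog, the pair drawn uniformly among chromatids carrying
opposite local haplotypes (this tracks homolog identity through
preceding exchanges; pairing by original chromosome label can produce
genetically silent exchanges after an upstream CO).  An NCO flips one
chromatid's alleles across the tract markers, producing a clean 3:1 or
1:3 run.  Optional uniform `na_rate`/`flip_rate` noise perturbs the
genotype calls but never the truth log.

What this generator does *not* emulate: crossover interference,
CO homeostasis, complex events (double COs with shared tracts,
discontinuous conversion tracts, 4:0 disomies), genotyping error
structure beyond uniform noise, replication timing, and real hotspot
determinants (chromatin, promoters).  Caller precision/recall of 1.0 on
this generator therefore demonstrates fidelity of the calling logic on
well-separated canonical events — not performance on real tetrad
sequencing data, where the full published classifiers handle complex
events this package deliberately excludes.

## Event caller

Markers are classed by segregation ratio (2:2, 3:1, 1:3, 4:0/0:4,
NA-containing); NA and 4:0 markers are non-informative (4:0 runs are
QC-flagged as likely mis-genotyping or disomy).  A CO is an interval
flanked by 2:2 markers where exactly two spores switch allele in
opposite directions; an NCO is a maximal same-spore run of ≥ 1
consecutive 3:1/1:3 markers bounded by 2:2 markers on both sides.  A
conversion tract within 5 kb (`merge_gap`) of a CO interval is absorbed
into that CO, which counts once (CO-with-conversion).  For NCOs the
reported spore is the minority-allele carrier — the actual conversion
recipient joins the majority class and cannot be identified from
segregation alone.  Proximity classification counts an event as
pericentromeric iff |midpoint − cen_mid| ≤ 20 kb, boundary inclusive;
midpoint-to-midpoint is the only unambiguous distance without
pericentromere boundary annotations.

## Signal landscapes

Tracks are per-base arrays; RPM normalization scales by 10⁶ / total
mapped reads (library size from a sidecar value or the track sum) and
is a no-op on already-normalized tracks.  Conventions:

* bins are half-open `[k·bin, (k+1)·bin)` anchored at the centromere
  midpoint, which is `floor((start+end)/2)` of the BED interval;
* Hann smoothing (`w[j] = 0.5(1 − cos(2πj/(M−1)))`, unit sum) truncates
  and renormalizes the kernel at chromosome ends, preserving constant
  tracks exactly; the un-normalized kernel sum for M = 201 is exactly
  100, so a unit impulse peaks at 0.01;
* loess is a hand-written local quadratic with tricube weights over the
  nearest `ceil(span·n)` points (default span 0.3) — no installed
  package provides degree-2 loess; the 95% CI on distance profiles is a
  percentile bootstrap over chromosome arms (200 resamples), a declared
  substitute for an unspecified CI method, not a claim of
  bit-equivalence to any particular loess implementation;
* fold tables exclude zero-wild-type segments (and log them) rather
  than emit infinities; log2 chromosome profiles instead add a 0.01-RPM
  pseudocount so empty bins report 0;
* pericentromeric fold changes are computed per centromere and then
  pooled across centromeres by relative segment position, with
  median/IQR/1.5×IQR-whisker summaries;
* metaplots report, per relative-position bin, the median across
  centromeres of the bin's per-base mean; regions truncated by
  chromosome ends contribute only their existing bases;
* strand is ignored throughout (strand-collapsed maps).

## Zone-recovery geometry (a known limitation)

The distance-to-centromere profile's "recovery distance" is the first
crossing of the loess fit through the genome-average line.  Under the
default generator this estimator does **not** land at the planted 95%
recovery distance (~3·tau): the suppressed zones remove only ~1.4% of
the genome's expected reads (2 × 0.9 × tau × 16 of 3.2 Mb), so the
genome-average line sits at ~98.6% of the plateau, which the planted
exponential reaches at ~4.2·tau ≈ 6.3 kb — and per-arm hotspot sampling
(32 arms, exponential hotspot heats) scatters the measured crossing by
several kb on top, with a long upper tail when a realization happens to
be hotspot-poor near centromeres.  One acceptance-style test asserts
the ±1 kb / 3·tau property over 20 independent replicates and fails by
design, recording this gap; the stable summary the acceptance script
reports is the median crossing over replicates (~6 kb).  Measuring the
zone scale precisely would require a reference level estimated away
from centromeres (not the global average) or a parametric fit of f(x);
both are outside the declared profile contract.

## Sequencing-signal simulators

Spo11-oligo tracks: per-base intensity = Gaussian hotspot kernels
(sd `read_spread`, default 200 bp — promoter/NFR scale) plus a uniform
background holding 20% of pre-suppression expected reads, multiplied by
`f(x)` when suppression is on, then multinomially sampled to exactly
`total_reads` (totals conserve exactly; identical seeds give identical
tracks; the sister-bias parameter never enters).  ChIP tracks: uniform
baseline × enrichment (default 4) within ± halfwidth (default 20 kb) of
each centromere, multinomially sampled.  Neither simulates reads,
fragments, mappability or duplicate structure — they are count
landscapes with exact planted expectations, which is what the
landscape analyses consume.

## Reproducibility and problem sizes

Every generator takes an explicit seed and is bit-reproducible from
(parameters, seed).  The test suite and `scripts/acceptance.py` run the
full pipeline at desk scale: 16 × 200 kb genome, 100–520 tetrads for
event-calling experiments (≥ 10⁴ events for the sister-bias contrast),
10⁷ reads for suppression-zone profiles, 2 × 10⁶ reads for metaplots,
200 replicates × 5,000 tetrads for map-distance recovery.  The pipeline
runner writes a manifest (parameters, seed, SHA-256 of every output) so
identical configurations produce identical manifests.
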