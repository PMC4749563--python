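# pericentro

Analysis toolkit for **pericentromeric suppression of meiotic
recombination** in budding yeast, built around three experimental
readouts and one model:

* **Fluorescent-spore tetrad assay** — three-color (GFP/RFP/CFP)
  scoring of live tetrads into parental ditype (PD), non-parental
  ditype (NPD) and tetratype (TT); genetic map distance by the Perkins
  estimator with a delta-method standard error, and strain comparison by
  Fisher's exact test.
* **Genome-wide CO/NCO calling** — crossovers and gene-conversion
  (non-crossover) events from four-spore genotype matrices of hybrid
  meioses, classified by distance to the centromere, with chi-square
  (Yates) contrasts of pericentromeric event frequencies.
* **Signal landscapes** — Spo11-oligo (DSB) and ChIP-Seq coverage
  analyses around centromeres: RPM normalization, 3-kb fold-change
  segments, 201-bp Hann smoothing, distance-to-centromere profiles with
  loess fit and bootstrap 95% CI, per-centromere window folds, log2
  chromosome profiles, and median metaplots.
* **A synthetic meiosis generator** implementing a two-zone centromere
  suppression model, so every stage runs and is testable at desk scale
  with no external data.

## The model and statistics

For two markers flanking an interval, with tetrad fractions
`t = TT/n` and `v = NPD/n`, the Perkins map distance and its sampling
error are

    cM = 100 * (t/2 + 3v)
    SE = 100 * sqrt[ (t(1-t)/4 + 9v(1-v) - 3tv) / n ]

Crossovers per bivalent are Poisson with mean `2d` (d in Morgans); each
crossover involves one of the four non-sister chromatid pairs uniformly
(no chromatid interference), which fixes the class probabilities
`P(TT|k) = (2/3)(1 - (-1/2)^k)` etc.

The two-zone suppression model distinguishes where DSBs *form* from how
they are *repaired*:

1. **DSB damping** near the centromere: relative break intensity
   `f(x) = s0 + (1 - s0)(1 - exp(-x/tau))` at distance `x` from the
   centromere midpoint (defaults `s0 = 0.1`, `tau = 1.5 kb`, so ~95%
   recovery by ~4.5 kb — a zone of roughly 3 kb per side).
2. **Sister-biased repair** across the broader pericentromere: a DSB
   within ±20 kb of the centromere is repaired from the sister
   chromatid (genetically invisible) with probability `b = 0.9`.

Zone 2 suppresses COs and NCOs without touching the DSB landscape —
the dissociation the signal analyses are designed to expose.

## Worked example

```python
from pericentro import (simulate_interval_tetrads, perkins_map_distance,
                        compare_map_distance, accounting_percent,
                        make_toy_genome, SuppressionModel, simulate_meiosis,
                        call_events, classify_proximity)

wt  = simulate_interval_tetrads(0.04, 5000, seed=1)  # wild-type pericentromere
mut = simulate_interval_tetrads(2.4, 5000, seed=2)   # cohesin-loader mutant
for name, c in (("wt ", wt), ("mut", mut)):
    est = perkins_map_distance(c)
    print(f"{name} PD={c.pd} NPD={c.npd} TT={c.tt}  ->  {est.cm:.3f} +/- {est.se:.3f} cM")
print(f"Fisher p = {compare_map_distance(wt, mut):.3g}")
print(f"accounting: {accounting_percent(5, 21).percent:.1f}%")

genome = make_toy_genome(seed=7)          # 16 x 200 kb, markers every 500 bp
model = SuppressionModel()                # s0=0.1, tau=1.5 kb, b=0.9 over +/-20 kb
prod = simulate_meiosis(genome, model, n_tetrads=8, seed=1)
events = [e for i in range(8) for e in call_events(prod.genotypes[i])]
summary = classify_proximity(events, genome.centromere_table(), window=20_000)
print(f"{summary.co_total} COs, {summary.nco_total} NCOs; "
      f"{summary.pct_within:.1f}% within 20 kb of a centromere")
```

prints

```
wt  PD=4995 NPD=0 TT=5  ->  0.050 +/- 0.022 cM
mut PD=4780 NPD=1 TT=219  ->  2.250 +/- 0.156 cM
Fisher p = 1.66e-59
accounting: 23.8%
110 COs, 58 NCOs; 4.2% within 20 kb of a centromere
```

The wild-type pericentromeric interval is essentially CO-free
(0.05 cM); the cohesin-loader mutant recovers ~2.3 cM, and Fisher's
exact test on recombinant-vs-parental tetrads resolves the difference
decisively.  In the genome-wide simulation with full sister bias active,
only ~4% of visible events fall within 20 kb of a centromere even
though that window covers 20% of the genome.  The accounting line says a
5-fold DSB increase explains only ~24% of a 21-fold CO increase — the
rest must come from repair-pathway choice, not break formation.

A command-line surface wraps the same operations:

```sh
pericentro simulate tetrads --d-cm 7.5 --n-tetrads 5000 --seed 1 --out-dir out/
pericentro simulate spo11 --total-reads 1000000 --seed 1 --out-dir out/
pericentro spo11-profile out/spo11.bedgraph out/centromeres.bed --out out/profile.tsv
pericentro metaplot out/chip.bedgraph out/centromeres.bed
pericentro run --config config.yaml --seed 1
```

Formats are plain text throughout: bedGraph/BED (0-based half-open),
TSV genotype matrices (`chrom pos spore1..spore4` with P1/P2/NA), TSV
event tables (1-based inclusive, labeled in the header).

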