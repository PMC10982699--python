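# Methods

## The measurement being modeled

eSPAN (enrichment and sequencing of protein-associated nascent DNA) combines
chromatin immunoprecipitation of a histone mark with BrdU
immunoprecipitation of newly replicated single-stranded DNA. Because the two
daughter strands of a replication fork map to opposite reference strands,
the strand identity of each sequenced nascent fragment reports which
daughter it came from. Around a bidirectional origin the mapping flips
between the two sides: right of the origin the leading-strand daughter is
the Watson strand, left of the origin it is the Crick strand.

Two statistics are computed from strand-resolved coverage:

- **Partition bias.** In a window with Watson coverage `W` and Crick
  coverage `C`, the bias is `(W − C) / (W + C)`; NaN where `W + C = 0`.
  Profiles use 100-bp sliding windows (10-bp step by default) over
  ±10 kb around each origin. The same statistic computed on the matched
  BrdU-input library is subtracted element-wise to cancel technical
  Watson/Crick recovery asymmetries shared by the two libraries. Curves are
  aggregated across origins as the per-bin mean over finite values with a
  ribbon of ±2 standard errors.
- **Strand-resolved density.** For one origin and one strand class
  (leading = right-side Watson bins ∪ left-side Crick bins; lagging the
  complement), the density is the no-intercept least-squares coefficient
  `c = Σ(e·b) / Σ(b²)` fitting eSPAN bin signal `e` against matched BrdU
  bin signal `b` over 100-bp bins within ±2500 bp, clamped at zero, with
  bins of zero BrdU signal dropped. Expressing the mark in BrdU units
  cancels per-origin variation in BrdU incorporation and replication
  timing. Fold change is density relative to a reference genotype at the
  same origin and strand class; single-strand differences between genotypes
  are tested with Welch's two-sample t-test across origins (raw two-sided
  p-values; a Bonferroni column is reported for transparency but no
  correction is applied to the primary result).

A scalar **folded bias** summarizes each origin's sigmoidal profile:
`(right-side mean − left-side mean) / 2` over finite bins beyond ±300 bp
of the origin (leading/lagging identity is undefined at the initiation
point), with the sign convention that positive values mean leading-strand
preference.

## The segregation model behind the simulator

Each origin fires bidirectionally; each fork travels
`replicated_halfwidth` bp (default 5000). Nucleosome slots sit at
`±(k + ½)·spacing` (default spacing 160 bp) strictly inside the replicated
region. At each slot, per cell:

- with probability `r_recycle` the parental H3–H4 tetramer is recycled,
  landing on the leading-strand daughter with probability `p_lead`,
  otherwise on the lagging-strand daughter;
- every daughter slot without a parental tetramer receives a newly
  synthesized tetramer.

One tetramer per daughter per slot, no tetramer splitting. Closed forms
under the model (recorded in the simulation manifest as ground truth):

| quantity | value |
|---|---|
| parental occupancy, leading daughter | `r·p` |
| parental occupancy, lagging daughter | `r·(1−p)` |
| parental-mark bias, Watson-leading side | `2p − 1` |
| new-histone-mark bias, same side | `r(1−2p)/(2−r)` |

A sequencing library pools millions of cells, so the simulator marginalizes
segregation over `cells_per_locus` cells (default 1000) via a per-slot
multinomial draw, giving fractional occupancy weights per daughter. The
single-cell primitive (`segregate_histones`, Bernoulli per slot) is exposed
and equals the population model at `cells_per_locus = 1`. This matters for
window-level statistics: with one cell per locus every 100-bp window is
strand-pure (bias ±1 regardless of depth), which no sequencing experiment
exhibits.

Sequencing is emulated by Poisson draws: `reads_per_nucleosome` (default
400) expected fragments per fully occupied tetramer slot per daughter for
mark samples (H3K4me3/H3K9me3 report parental tetramers, H3K56ac reports
new ones, scaled by `density_scale_new`), and `brdu_reads_per_bp` (default
2.5) fragments per replicated bp, uniform over both strands, for the BrdU
input. Defaults give ≈5 million fragments per library — a typical mapped
sequencing depth — and matched local eSPAN/BrdU depth. Fragment lengths are
Normal(150, 15²) clamped at ≥50 bp, centered on the slot (mononucleosomal
ssDNA); Okazaki-fragment substructure is not modeled because the bias
depends only on strand identity. An optional multiplicative
Watson-recovery factor (`strand_recovery_w`) thins (or duplicates) Watson
fragments identically in every library of a run; its purpose is to emulate
the shared technical asymmetry that BrdU subtraction exists to remove.

Genotype presets (`WT` 0.5/1.0, `mcm2-2A` 0.85/0.6, `dpb4d` 0.25/0.8,
`mcm2-2A_dpb4d` 0.55/0.45, `pob3d` 0.5/0.35 as `(p_lead, r_recycle)`) are
qualitative phenotype classes — symmetric, leading-biased, lagging-biased,
recycling-impaired — not fitted estimates of any strain's biology.

Randomness flows from one master seed through label-addressed substreams
(keyed by CRC32 of genotype and mark names), so adding a genotype or mark
never perturbs another sample's draws, and a fixed seed reproduces every
output byte for byte.

## Normalization choices

- **Bias** is a ratio and needs no depth normalization.
- **Coverage tracks** are scaled counts-per-million fragments
  (`cpm_scale`); any fixed constant cancels in fold changes.
- **Density** (default `normalization="brdu-matched"`) scales both the
  eSPAN and the BrdU coverage of a genotype per million fragments of that
  genotype's *BrdU input*. The BrdU library size tracks the amount of
  replicated DNA and is genotype-independent in expectation, so densities
  retain the absolute mark yield per replicated DNA — the quantity the
  recycling efficiency `r` lives in. Normalizing each library by its *own*
  total (`normalization="self"`, the conventional per-library CPM) is also
  provided, but in a background-free library the parental-mark total is
  itself proportional to `r`, so self-normalization cancels `r` exactly and
  only the strand-choice ratio `p` survives; overall density shifts then
  become uninterpretable normalization artifacts. With the default, the
  per-strand fold change versus a `(0.5, 1.0)` reference recovers
  `r·p/0.5` (leading) and `r·(1−p)/0.5` (lagging).
- **Fold-change summaries** are reported two ways: the mean of per-origin
  fold changes, and the pooled ratio of mean densities. The pooled form
  estimates the ratio of expectations directly; the mean of ratios acquires
  an upward convexity bias of order `(σ/μ)²` of the reference's per-origin
  density noise and is retained for per-origin displays (violins,
  heatmaps).

## Numerical and edge-case policy

- Coordinates are 0-based half-open throughout; origins read from BED are
  interval midpoints, `floor((start+end)/2)`.
- Windows with zero coverage, or extending past a chromosome end, are NaN
  and are excluded from aggregates — never zero-filled, which would
  fabricate symmetry.
- When the analysis radius exceeds the replicated halfwidth (the default:
  ±10 kb windows over ±5 kb replication), bins outside the replicated
  region are NaN automatically; per-bin *aggregate* checks additionally
  mask the coverage taper at the fork boundary using
  `SimulationConfig.full_depth_radius` (= halfwidth − spacing − fragment
  length), inside which coverage is at full depth.
- Window sums use cached prefix sums; results equal naive summation exactly
  (integer-valued inputs are exact in float64 well beyond these depths).
- The density fit drops origins whose window has no BrdU signal
  ("unreplicated"), logs the count, and clamps negative coefficients to 0.
- The heatmap export orders origins by descending folded bias, ties broken
  stably by origin id.
- The 95% ribbon is exactly mean ± 2·SE (not a t quantile), matching the
  convention of the figure style it reproduces.

## What the simulator does and does not show

Passing tests demonstrate that the analysis recovers known segregation
parameters from data generated under the model above: idealized origins
that all fire once, synchronously, with deterministic fork travel, no
genomic background from non-nascent chromatin, no mappability or GC
structure, and no replication-timing gradient. Real nascent-chromatin data
violate all of these; in particular, genome-wide background compresses
observed bias amplitudes below the closed forms, and per-library depth
normalization of real data carries the self-normalization caveat above.
The pipeline is validated as *correct*, not as a guarantee that real
libraries satisfy its assumptions.

## Problem sizes used

Simulation-backed checks run at 200 origins (the default study condition)
with default depth; the bias/density estimates then carry standard errors
of ~0.001–0.005, far inside the tolerances tested. The end-to-end
determinism and pipeline smoke checks use 10–20 origins at reduced depth,
where byte-level identity is the assertion and precision is irrelevant.
t-test calibration uses 1000 random splits of the 200 wild-type origin
densities; power uses the documented Normal(0.5, 0.05²) vs Normal(0.2,
0.05²) contrast at n = 162 per group.

## Known limitations

- `p_lead`/`r_recycle` estimation from *real* data is deliberately out of
  scope; presets must not be read as estimates of the corresponding
  strains.
- Origin filtering ("consistent usage") is operationalized as BrdU
  enrichment ≥ 2 in ±1 kb in every reference replicate — simple, monotone
  and auditable, but not a reconstruction of any particular published
  origin list.
- Adjacent origins closer than twice the analysis radius contribute to each
  other's windows; each origin is computed independently without
  deduplication (the bundled genome geometry spaces origins 25 kb apart so
  replicated zones never overlap).
- BAM ingestion is a thin optional converter; upstream trimming, alignment
  and duplicate filtering are assumed done.
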