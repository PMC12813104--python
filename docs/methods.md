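# Methods

## The problem being modelled

Extracting microbial DNA from macroalgal biofilms is confounded by
(i) host plastid DNA — universal bacterial 16S primers amplify chloroplast
sequences, so a species-dependent fraction of reads is host-derived — and
(ii) the "kitome": microbial DNA resident in extraction-kit reagents,
measured by sequencing a no-input negative control per kit. Because the
kitome contributes a roughly fixed DNA mass, its share of reads rises as
the template mass falls. Kits additionally differ in yield, DNA integrity,
PCR-inhibitor carryover, capture bias and replicate reproducibility.
`kitbench` evaluates kits on all of these axes and aggregates them into a
single multi-criteria ranking, using synthetic data with known planted
effects as the test bed.

## Synthetic-data model

* **Base community.** Per species, bacterial OTU proportions are
  exp(N(µ, σ²)) renormalised (defaults µ = 0, σ = 1; σ = 1 gives the
  long-tailed rank-abundance curves typical of amplicon surveys).
  Chloroplast OTUs (order label `Chloroplast`) jointly receive the
  species' chloroplast fraction: 0.40 for the red alga, 0.10 and 0.075
  for the brown and green algae, following the reported ~40% versus 5–10%
  split.
* **Kit capture bias.** Per (species, kit), each OTU gets a multiplier
  exp(N(0, capture_bias_sd²)) shared by all replicates — a systematic
  compositional bias — plus per-replicate Bernoulli dropout at
  `dropout_rate`, the stochastic component that erodes reproducibility.
* **Kitome mixing.** The contaminant community (default 30 OTUs, its own
  log-normal profile, genus labels like `Staphylococcus-like` drawn from
  the genera typically reported in kitomes) is mixed in at mass fraction
  w = load / (load + template), the exact two-component mixing rule; the
  tests verify sampled counts converge to w. Kitome controls draw from the
  contaminant profile only, at `depth x kitome_read_factor` reads, so the
  M/C ratio (mean sample yield / kitome yield) is 1 / kitome_read_factor
  by construction.
* **Read sampling.** Multinomial at fixed depth (default 50,000 —
  the saturation-scale depth used throughout the acceptance checks; real
  per-sample depth distributions are not modelled).
* **QC table.** Concentration = template mass / 60 µL elution volume with
  multiplicative log-normal noise (sd 0.1), floored at the 0.1 ng/µL
  fluorometer detection limit; input mass ~ U(1.5, 5) g as in field
  collections; DIN and absorbance ratios are per-kit means plus small
  Gaussian noise; the PCR dilution factor (1 / 10 / 100 / `failed`) is a
  kit property.
* **Determinism.** One seed per dataset; RNG streams are split by hashing
  (seed, purpose, species, kit, replicate), so adding a kit or species
  leaves all other draws unchanged.

The default six kits encode the study's qualitative structure — yield
ordering (B&T, MonNEB, PowSoi high; QiaSto near the detection floor),
kitome read yields comparable to samples for B&T/PowFec/Thermo and low for
QiaSto/PowSoi/MonNEB, unmeasurable DIN for QiaSto, PCR dilution needed for
B&T and MonNEB, and the published simplicity/cost table. They do not
encode species-by-kit interactions (template mass is per-kit only), so a
green planted-effect test establishes that the pipeline recovers per-kit
structure, not that it reproduces any species-specific field result.

## Decontamination stand-in

The reference tool's mixture-model frequency test and chi-square prevalence
test are *not* reimplemented. The stand-in keeps the interface (two scores,
"either" combination, threshold 0.3, low score = contaminant-like) with
simpler, fully specified statistics:

* `score_p`: one-sided Fisher exact p for the 2x2 presence table
  (controls vs samples, presence = count >= 1), alternative "presence odds
  higher in controls".
* `score_f`: permutation p (default 999 permutations, seeded, shared
  permutations across OTUs) for negative Spearman correlation between an
  OTU's relative abundance and the floored sample DNA concentration;
  constant concentration or constant abundance gives p = 1.

Controls are kit-matched by default (samples from kits without a control
are excluded from the tests); `pooled=True` uses everything. No rarefaction
is applied before testing. At threshold 0.3 the caller is deliberately
permissive — on the default world it attains recall ~1.0 on planted
contaminants at the cost of flagging some genuine community OTUs (of the
order of the score threshold under the null, as for the reference tool at
the same threshold).

Filtering order follows the study: contaminants are removed first, then
chloroplast OTUs; chloroplast fractions and contamination levels are both
reported relative to raw per-sample read totals. An M/C ratio with a
zero-read kitome is reported as undefined and treated as best when ranked.

## Community metrics

* Shannon H = −Σ pᵢ ln pᵢ (natural log), on filtered counts.
* Bray–Curtis on raw counts (no rarefaction; the upstream study mentions
  none), d = 1 − 2Σmin/(Σx+Σy).
* PCoA = classical scaling: eigendecomposition of the double-centred
  Gower matrix; negative eigenvalues are reported but their axes dropped.
* PERMANOVA: pseudo-F from among/within sums of squared distances, free
  permutation of labels (single factor, no strata),
  p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
* Reproducibility = |intersection of replicate presence sets| / |union|
  (presence = 1 read). The union denominator is a choice — the source
  description leaves it open; `denominator="mean-richness"` divides by the
  mean per-replicate richness instead.
* OTU sharing: a kit detects an OTU if any replicate does; the histogram
  counts OTUs by the number of detecting kits, with universal (= all kits)
  and unique (= one kit) fractions.
* Taxon summaries keep taxa whose maximum per-sample relative abundance
  exceeds the display threshold (default 1%) and pool the rest as `other`.

## Ranking rules

All ranks use the minimum-rank-with-skip tie convention (1, 1, 3), so
integer ranks can be summed.

* **Mean-value rule** (DNA yield, DIN, Shannon, chloroplast content,
  simplicity, cost): rank by mean across replicates, direction per
  criterion. Ties are exact-equality only.
* **Contamination rule**: kits below 1% contamination in *all* replicates
  share rank 1; the rest rank by ascending mean starting at
  (#qualifying + 1).
* **Reproducibility rule**: the per-species [min, max] range is split into
  six equal bins (half-open from below, top bin closed); the top bin is
  rank 1 and empty bins still consume ranks. A zero-width range puts all
  kits at rank 1.
* **Dilution rule**: ascending dilution factor, `failed` strictly worst
  (non-amplifiable DNA is the worst inhibition outcome).
* **Aggregation**: Total = sum over all nine criteria; Quality excludes
  simplicity and cost. Tied sums share a position, reported explicitly.
* **Missing DIN**: kits with no measurable DIN are excluded from the DIN
  ranking and imputed at (worst measured rank + 1), mirroring how a kit
  whose samples all failed the integrity assay is treated.

Yield per gram = floored concentration x 60 µL elution / input mass (ng/g).
Purity windows: 260/280 in [1.7, 2.0] and 260/230 in [2.0, 2.2], both
bounds inclusive.

## Numerical choices and degenerate inputs

* Ranking ties are detected by exact float equality; measured criteria are
  continuous so accidental ties have measure zero.
* PCoA eigenvalues below 1e-10 are treated as zero.
* PERMANOVA with zero within-group sum of squares reports F = inf (or 0
  when the among-group part is also zero); groups of size 1 are rejected.
* A replicate with no detected OTUs makes reproducibility 0 with a
  warning; an all-zero sample has Shannon undefined (NaN downstream, the
  kit's Shannon mean then uses the remaining replicates).
* Dropout that would empty a community is skipped for that replicate
  (only reachable at extreme dropout rates).
* All permutation tests use the +1-corrected p-value, so p is never 0.

## Limitations

* Processed-table level only: no read-level error, chimera or PCR-cycle
  model, and no raw-read pipeline (trimming, denoising, clustering,
  taxonomy assignment are out of scope).
* The contaminant caller is a stand-in, not the reference algorithm;
  agreement with it on real data is not claimed.
* Per-kit scalars cannot express species-by-kit interactions, so findings
  like one kit excelling only for one alga are outside the generator's
  stated world.
* Criterion panels are configurable but default to the nine-criterion set;
  no criterion weighting or rank-aggregation optimality methods are
  provided — plain summation only.
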