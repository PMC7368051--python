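# Methods

## Scaling model

The package treats host chromosomal DNA as an inherent spike-in. For
sample *i*, let `P_i` be the number of reads mapped to the host (plant)
chromosomes and `p̂` the mean of `P_i` over all samples in the input
table. Raw microbial family counts `Xraw_i` are scaled to

    Xnorm_i = p̂ · Xraw_i / P_i ,

which makes columns comparable on an absolute per-host-DNA scale; `p̂` is
only a convenient global constant and is deliberately *not* recomputed if
samples are later dropped, so values never change retroactively. The
per-sample microbial load is `L_i = C_i / P_i` with `C_i` the classified
microbial read count (a `taxa_subset` argument restricts the numerator,
e.g. to bacterial families only). Samples with `P_i = 0` are an error,
not a silent skip: the scaling is undefined there.

Amplicon tables are corrected to the same scale per sample by one
multiplicative factor. The shared-taxa factor is `ΣMc_i / ΣAc_i`, where
the sums run over the families detected with at least one read by both
platforms in that sample (`Mc` from the plant-scaled metagenome, `Ac`
from the TSS-closed amplicon column). Because the factor is one scalar
per sample, within-sample ratios are untouched and the corrected
amplicon mass over common families equals the metagenome mass over the
same families *exactly* — this conservation identity is asserted in the
tests at 1e-9 and holds to machine precision. The closure constant used
for TSS (1 or 100) cancels in the factor. If a sample has no usable
common family, the default behaviour falls back to the total-load factor
`L_i · p̂` and flags the sample in the correction report; a strict mode
raises instead. Taxon exclusion (e.g. cyanobacteria, whose 16S signal is
confounded with chloroplasts) is applied to both tables *before* factor
computation.

## Correlation networks

All unordered pairs of the chosen taxa are scored with the Pearson
product–moment coefficient; `t = r·√((n−2)/(1−r²))` and a two-sided
p-value from the t distribution with `n−2` df. Edges survive iff
`r² ≥ 0.2` and `p < 0.05` (both thresholds are arguments; a flag switches
the strength threshold to |r|). Prevalence filtering — by default ≥1000
reads in ≥10 samples, boundaries inclusive — always operates on *raw*
counts regardless of the transform the correlations are computed on,
because a read-count threshold is only meaningful on reads. Constant
taxa are excluded with a warning before pairing. A permutation p-value
(`(1 + #{|r_perm| ≥ |r_obs|}) / (n_perm + 1)`) is provided as a
model-free oracle; note that for small n its exact conditional null
differs from the t approximation by O(1/n) for mid-range p-values, which
is why the oracle-agreement test uses a tight Monte-Carlo bound only
where the edge filter operates (p < 0.1) and a 0.25/n allowance
elsewhere.

The CLR transform is `ln(x_j / g(x))` with `g` the geometric mean of the
sample. Zero handling: integer count tables get +1 added to every cell
of zero-containing sample columns; non-count tables have zeros replaced
by half the smallest nonzero value in the table. The CLR network in the
analysis drivers is computed on the TSS-relative metagenome table (the
non-count path), i.e. on exactly the compositional information an
amplicon-style analysis would have.

## Synthetic study conditions

The generator emulates a host-associated survey with paired deep shotgun
and closed amplicon tables. Per sample:

* **Load** `L_i ~ LogNormal(ln 0.08, 0.48)` truncated to (0.005, 0.77) by
  rejection — right-skewed positive ratios spanning "under 1% to tens of
  percent of host reads", with the truncation bounds as the observed
  range. The log-sd is a free dispersion knob: it controls how strongly
  total load couples taxa on the absolute scale.
* **Composition** `c_i ~ Dirichlet(α)` over a 35-family universe with
  `α = conc · K · m`, `m_j ∝ j⁻²` and `conc = 3.8`. The rank-2 power law
  gives two dominant families (the bloom-prone Family01 and the stable
  Family02), a mid tail, and many rare families with tiny α — i.e. large
  log-scale dispersion. With probability 0.1 the sample blooms: Family01's
  share is multiplied by 3 and the vector re-closed, and the sample's
  load is multiplied by √3 (an infected, low-complexity, high-load
  sample). Mild per-family log-normal noise (sd 0.06) is applied and the
  vector re-closed.
* **Metagenome** (total depth 15·10⁶ reads, emulating the deep end of
  ~0.1–2 Gb libraries): plant reads ~ Binomial(D, 1/(1+L)); half of the
  non-plant reads are classifiable (Binomial, fraction 0.5) and are
  distributed multinomially over the 30 metagenome families ∝ `L·c`;
  the rest is reported unclassified. Plant + classified + unclassified
  equals the total depth exactly.
* **Amplicon** (depth 30,000): multinomial over the 25 amplicon families
  with probabilities ∝ `b_j · c_j`, where `b_j` is a per-family
  log-normal primer bias (sd 0.15). Twenty families are shared between
  platforms. Load never enters, so amplicon counts are compositional by
  construction.

One master seed spawns independent substreams per component, so adding a
component never perturbs earlier draws and every dataset is
bit-reproducible from (config, seed).

Free parameters without an external anchor (`dirichlet_alpha`, the rank
exponent, `load_log_sd`, `taxon_noise_sd`, bloom probability/factor)
were fixed once by a calibration sweep against the qualitative behaviour
the pipeline is meant to exhibit — load-driven positive absolute-scale
associations, closure-induced sign flips, and a CLR network that
recovers the bloom/stable edge but overestimates it — evaluated on
held-out seeds, and are not tuned per analysis.

### What the generator does and does not emulate

It reproduces the mechanisms: wide load variation, blooms that
simultaneously raise load and distort closed profiles, partial platform
overlap, primer bias, and a large unclassifiable read fraction. It does
**not** emulate several features of real surveys: the family profile is
steeper than a typical leaf community (Shannon-effective ~4 of 30
families rather than ~25 of ~47), because at this small family count the
CLR's geometric-mean artifact only manifests with a dominant-plus-noisy-
tail profile; there is no phylogenetic or functional structure, no
batch/site effect on composition (site labels are decorative), no
taxonomic misassignment, and no fungal genome-size/rDNA-copy-number
biases. Passing tests therefore demonstrate that the *methods* behave as
claimed under the stated mechanisms, not that any particular real
dataset will show effects of the same magnitude.

## Depth analyses

Downsampling is without replacement (multivariate hypergeometric), as
when subsampling real reads; a multinomial option exists for speed. The
taxonomic-profile curve downsamples classified counts, closes to a
relative profile, and records Bray–Curtis dissimilarity to the
full-depth profile (bounded in [0,1]; tolerance default 0.05). The
load-precision curve jointly downsamples the three-way
(plant, per-family classified, unclassified) totals — so the plant
denominator is resampled too, as in real shallow sequencing — and
records the relative error of the re-estimated load against the
full-depth estimate; the recommended depth is the smallest with
90th-percentile error below 20%. Load-curve evaluation is restricted to
samples with true load ≥ 0.05: near-zero loads cannot be pinned down by
a few thousand reads, and no sequencing-depth recommendation should
pretend otherwise. Monotonicity of both curves is a property of their
per-depth summaries (median / 90th percentile pooled over samples);
per-sample replicate medians at adjacent deep depths are Monte-Carlo
ties and are not asserted on.

Problem sizes used by the analysis drivers and checks: 150 samples, 50
replicate datasets for the network experiment, 20 for the monotonicity
curves, 3–5 downsampling replicates per sample × depth.

## Numerical choices

* Pearson r is clipped to [−1, 1]; |r| = 1 maps to p = 0, and p = 0 is
  written to edge files as the smallest positive double so outputs stay
  sortable.
* PCA is a taxon-centered SVD; each component's sign is fixed so its
  largest-magnitude loading is positive, making outputs platform-
  independent.
* Table round-trips are exact: integer counts are written as integers,
  floats with `repr` (17 significant digits), so read∘write is the
  identity bit-for-bit.
* Degenerate inputs fail loudly and specifically: zero plant reads,
  all-zero sample columns, empty taxon subsets, constant vectors, depth
  grids exceeding column totals, and missing/non-numeric cells are all
  errors naming the offending sample or cell, never silent repairs.

## Known limitations

The correction assumes family labels match as exact strings across
platforms; no taxonomy reconciliation is attempted. The load proxy
assumes host chromosomal read counts track host cell equivalents, which
holds within one host species and tissue but not across hosts with
different genome sizes. The two-taxon closure anticorrelation (r = −1)
and the conservation identity are exact in exact arithmetic and hold to
~1e-12 in doubles. The 0.2/0.05 network thresholds are conventions
inherited from the motivating analysis style, not optimized values.
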