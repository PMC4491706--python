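# Methods

## Measurement model

Each amplicon is a pair of homologous sequences — one from the target
species, one from the spiked-in competitor (neighbor) genome — that
co-amplify with a single primer pair and differ at a small number of
inter-species variation (ISV) positions.  For one amplicon in one
sample, let `f` be the true fraction of target molecules among the
competing templates.  The procedure (multiplex PCR rounds, purifications,
library construction) is modelled as a single multiplicative distortion
of the target:competitor odds by a per-amplicon **bias factor** β, so the
expected observed read fraction is

    γ = β·f / (β·f + 1 − f).

β is assumed constant for an amplicon across the samples of one
replication set (it is a property of the variant structure and the
reagents, not of the sample), which is exactly the property the
correction exploits.  No per-cycle chemistry is modelled; a bias that
accrues over cycles is indistinguishable from its end-to-end product at
the point of measurement.

## Bias correction

A reference sample with known composition `p` and observed fraction
`γ_ref` determines species weights `wA = p/γ_ref` and
`wB = (1−p)/(1−γ_ref)`; an observation γ corrects to

    γ_c = γ·wA / (γ·wA + (1−γ)·wB).

With `p = 1/2` this is the classical equi-molar-reference correction.
Several references are aggregated by **averaging wA and wB
arithmetically** across references before forming the ratio.  This form
was chosen over averaging the single-reference corrected values because
it is exact under the model: with a constant β and correct compositions
`p_j = f_j`, every reference contributes `wA_j = c_j/β` and `wB_j = c_j`
with the same `c_j = β·f_j + 1 − f_j`, so the ratio of the averages is
exactly `1/β` regardless of how many or which references enter.  (The
alternative aggregation is available behind
`correct_bias_multi(..., aggregate="corrected")`.)

gDNA mixture series are corrected **leave-one-out** — each sample is
corrected by all other samples; a sample never references itself — with
reference compositions self-estimated as the per-sample unweighted mean
of *raw* fractions over QC-passing amplicons, without iteration.  The
self-estimate rests on the assumption that biases toward either species
cancel on average across a large panel; under the default log-symmetric
bias distribution the estimate is accurate to about ±0.01 in absolute
fraction, which is the dominant residual of the whole chain.  cDNA
samples are corrected per amplicon against all gDNA samples of the same
replication set; amplicons absent from the gDNA reference data are
dropped with reason `no_reference`.

A consequence worth noting: any odds factor constant across the series is
absorbed as "bias", including genuine target-side copy ratios.  An
X-linked amplicon in a female target donor carries twice the copies of a
male competitor's X; the correction folds that 2× into β and maps the
corrected fraction onto the sample-consensus fraction.  The expected
standardized quantity of an amplicon in a gDNA mixture is therefore
`cc/2` (competitor copies per diploid genome: 1.0 autosomal, 0.5
X-linked vs a male competitor), independent of the target donor's sex —
`expected_stdqt_gdna` implements exactly this.

## Derived quantities

- `RA_H/P = γ_c/(1−γ_c) · cc/2` — the corrected odds, rescaled so the
  competitor side counts per-genome copies.  The copy adjustment is
  applied on the competitor side only; target-side sex effects live in
  the simulator/expectation layer.  `γ_c = 1` (no competitor reads) has
  no finite odds and propagates as missing; no pseudocounts are used
  anywhere, consistent with the hard depth filters.
- `StdQt = RA / mean(RA over the standard set, per sample)`.  The
  standard set is all autosomal amplicons for gDNA work and the full
  panel for cDNA; any amplicon list can be supplied (e.g. a housekeeping
  set), and by construction the standard set's mean StdQt is 1 in every
  sample.
- Spike-in copies: 1 ng of competitor gDNA is `1000/3.3 ≈ 303` haploid
  genome equivalents (3.3 pg per haploid genome, configurable), hence
  ~303 copies of an autosomal unique sequence and ~15 target copies
  behind `RA = 0.05` — the floor of the usable measurement window, where
  template-sampling noise dominates.

## Analysis thresholds (defaults)

| parameter | default | role |
|---|---|---|
| `min_aln_len` / `min_query_cov` | 75 bp / 90% | a read must contain an exact stretch of a reference of at least `min(75, ceil(0.9·L))` bases |
| `min_pos_frac` | 0.25 | consensus: bases below 25% of position coverage are noise; two retained bases mark heterozygosity and reject the call |
| `min_depth` | 100 | consensus calls below 100 reads are rejected (`>= 100` retained) |
| `min_mean_reads` | 200 | amplicons averaging strictly fewer than 200 reads per sample fail QC |
| `max_impurity` | 0.05 | amplicons with strictly more than 5% wrong-species reads in a pure sample fail QC |
| `haploid_mass_pg` | 3.3 | gDNA mass → genome equivalents |

Classification is an exhaustive exact substring search on both strands
(references are tens of bases, so this is tractable and reproduces a
100%-identity alignment contract without an external aligner); a k-mer
prefilter with a stride chosen so that no qualifying stretch can be
missed only reduces cost, never outcomes.  Species assignment
additionally requires an ISV inside the matched stretch; reads
compatible with both species are excluded from the totals, and reads
matching two amplicons are discarded rather than given to the best hit —
quantitation safety over yield.  Ties and degenerate inputs: empty reads
are unassigned; `γ_ref ∈ {0,1}` makes a reference unusable (skipped with
a warning, error if none remain); an amplicon observed at γ ∈ {0,1}
corrects to 0 or 1 exactly.

## What the simulator emulates — and what it does not

The generator reproduces the statistical structure the analysis relies
on: homolog pairs of ~67 bp (SD 10.4, clipped to [39, 100]) with mostly
single-nucleotide ISVs (1/2/3 ISVs with probability 0.75/0.20/0.05)
placed outside 18 bp primer margins; W/S variant classes by the
target-variant nucleotide with optional coupling of β to the class
(median β_S > β_W, off by default); per-gene X-linkage (5% of genes by
default); gDNA mixtures and cDNA samples with spike-in mass converted
through genome equivalents; log-normal per-amplicon depths (mean 5,000,
sd of log 0.5) and log-normal biases (median 1, sd of log 0.5) held
constant across samples; binomial read sampling; reads padded with
random adaptor-like sequence to 100 bp, half reverse-complemented, with
optional uniform substitution errors.  cDNA expression profiles are
log-normal with sd(log) = 1.2 around 1,500 copies so that relative
abundances span a few-hundred-fold window comparable to the assay's
usable 400-fold range.

It does **not** emulate: indels or quality-score structure, chimeric
reads, primer cross-talk between amplicons, PCR-cycle-resolved
stochasticity, sample-to-sample bias drift, or real sequence context
(sequences are i.i.d. random).  Passing tests therefore demonstrate the
correctness of the *computational* chain under the stated noise model —
classification exactness, correction algebra, copy accounting,
standardization — not robustness to every artifact of real libraries.
In particular, biases that vary across samples violate the constancy
assumption and are only attenuated, not removed.

## Benchmark study sizes

The turn-key studies (`singpcr.studies`) use 350 amplicon pairs, five
gDNA mixtures at target fractions {0.1, 0.3, 0.5, 0.7, 0.9} and three
cDNA spike-in replicates with sample-mean RA near {5, 2.5, 1} — panel
and series sizes representative of a single multiplexed experiment and
small enough that the complete counts-level analysis runs in seconds.
The exact mixture compositions of the original series are not published
at machine precision; the defaults keep them configurable.

## Numerical and design choices

- Coordinates are 0-based half-open throughout; FASTA pair records carry
  ISV offsets, gene and copy class in their descriptions.
- Pileups are gapless and anchored to the initial reference (indel ISVs
  out of scope); full-amplicon containment is preferred, shorter reads
  are placed at an offset when they still satisfy the length rule, and
  alignments implying indels are excluded.
- "Query coverage" is interpreted against the reference amplicon: the
  effective rule is an exact stretch of at least
  `min(75 bp, 90% of the reference length)`, since 67 bp amplicons can
  never satisfy a literal 75 bp criterion without adaptor context.
- Reference compositions are estimated from raw, never corrected,
  fractions — no iteration, so the estimator is simple, unbiased under
  the cancellation assumption, and cannot oscillate.
- Determinism: every stochastic step takes an explicit seed
  (`numpy.random.default_rng`); pipeline reruns with one config are
  byte-identical, recorded via SHA-256 in the run manifest.
- Floats in exported tables are written at 6 significant digits.

## Known limitations

- The self-estimated reference composition carries an O(0.01) systematic
  offset under strong symmetric bias spread; supplying known
  compositions (`correct_gdna_set(..., p_ref=...)`) removes it.
- Amplicons whose references share long exact stretches with another
  amplicon (paralogs, repeats) are systematically discarded as ambiguous.
- Depth-dependent error: amplicons measured deep in the target sample
  but shallow in the reference samples inherit the references' sampling
  noise, which the per-observation binomial error bar understates.
- The CLI's simulate stage covers the gDNA workflow; cDNA study designs
  are driven from Python (`singpcr.studies`, examples 02).
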