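# Methods

## Signal model and preprocessing

A peptide spot's readout is modeled as fluorescence intensity versus
camera exposure time.  For each peptide × sample series the package fits
ordinary least squares **with intercept** (the field's convention of
reporting a regression slope does not specify regression through the
origin; the intercept absorbs residual background) and takes the slope
(intensity per ms) as the phosphorylation signal.  R² is the standard
coefficient of determination; a residual-free fit — including a constant
series, whose total sum of squares vanishes — is assigned R² = 1, since
exclusion of flat signals is the detectability filter's job, not the
linearity filter's.

Filtering is applied **per sample**: a peptide is retained only if every
sample of the comparison has R² ≥ `r2_min` (default 0.90, inclusive) and
a detectable signal.  "Undetectable" is operationalized as slope ≤ 0 or
maximum intensity below a configurable floor (default 0); the source
methodology does not define it.  Internal-control peptides are never
carried into differential calling.  Filtering is monotone in `r2_min` by
construction.

Fold change pairs replicates by index (case replicate *i* over control
replicate *i*; pairing is not specified upstream, and index pairing keeps
the map one-to-one).  Per-replicate ratios are averaged on the ratio
scale — arithmetic mean by default, matching the description of FC being
averaged across replicates; a geometric-mean alternative is exposed as a
flag.  Peptides whose control slope is non-positive in any replicate are
routed to the exclusion set rather than raising.  Differential calls use
inclusive thresholds FC ≥ 1.30 or FC ≤ 0.70.

## Random-sampling kinase scoring

Kinase–peptide associations come from tabular database-style records
filtered by source-specific rules: scored predictions are kept when the
score strictly exceeds twice the per-site prediction threshold; ranked
predictions are kept for ranks 1–5 per peptide, with ties at rank 5 all
kept (least information loss); curated phosphosite records are kept
unconditionally.  Records are unioned with provenance and deduplicated;
every kinase carries exactly one family, taken from a packaged
assignment table, and family peptide sets are the union over member
kinases.  Family-level scores are broadcast identically to all members.

For a comparison with *m* differential peptides, the null for each
family is built from `iterations` (default 3000) uniform draws of *m*
peptides **without replacement** from the full chip list (all 196
peptides including internal controls by default; drawing from the
filter-surviving subset is a config option).  The empirical null mean
and SD (ddof = 1) standardize the observed hit count into a Z-score.
Under this scheme the per-family null count is exactly
hypergeometric(N, k, m), and the tests use the closed-form moments from
`scipy.stats.hypergeom` as an independent oracle against the sampling
implementation; the sampling is kept explicit because the resampling
procedure is itself the method being implemented.  The draw uses the
rank trick (the *m* smallest of *n* iid uniforms), fully vectorized, and
is bit-reproducible for a given seed.

Degenerate nulls (SD = 0, e.g. m = N) give Z = 0 when the observed count
equals the null mean and are otherwise flagged rather than scored.  A
family with no differential peptides has mean log2FC defined as 0 (no
directional evidence) and participates in percentile ranking at the
bottom of the |log2FC| scale.  Family percentiles are computed from the
**absolute** mean log2FC: the ranking expresses strength of differential
activity regardless of direction, consistent with the absolute-value
convention the analogous external tool uses; direction is reported
separately (increased iff mean log2FC > 0).  The default significance
flag is |Z| ≥ 2, configurable; no explicit cutoff is prescribed upstream.

## Percentile conversion and aggregation

"Inclusive percentile" is implemented as `100·(r−1)/(n−1)` on ascending
ranks with ties sharing the mean of their positional percentiles and a
single score ranking 100 — the endpoint-inclusive reading, consistent
with published maxima of 100% and minima of 0%.  The weighted average is
the **sum of reported percentiles divided by the total number of
pipelines**.  The literal description ("average divided by the number of
pipelines") contradicts every published row in which all pipelines
report (the weighted value equals the unweighted one there, not a
quarter of it); the adopted reading reproduces all published cells, and
equals the unweighted mean scaled by the reporting fraction, hence
weighted ≤ unweighted always.  Absence of a kinase from a pipeline's
output means "not reported" and is excluded from the unweighted
denominator — never treated as zero.

Group rankings average each pipeline's per-cell-line percentiles over
the member cell lines where the kinase is reported, then combine as for
a single cell line.  Recomputing pooled scores from raw data would be an
alternative; averaging percentiles is the only operation expressible
from the published per-cell-line columns and reproduces them.

Display rounding is half-to-even to integer percent, the unique rule
consistent with all published half-point cells (95.5→96, 64.5→64,
70.5→70, 89.5→90, 91.5→92).  Exact halves produced by float division are
snapped within 1e-9 before rounding.  Top-k tables sort descending and
break ties alphabetically by kinase identifier; the published tie order
is explicitly arbitrary, so agreement on tie order is not expected.

The external tools themselves (the upstream-kinase analysis suite, the
enrichment analysis, the kinase-enrichment web service) are out of
scope; only their published output transforms are implemented as
adapters, and their score tables enter as TSV files.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure of the assay: 196
peptides with 3 internal controls, five exposure times, two conditions ×
three replicates, linear signal `slope·t + intercept` with baseline
slopes uniform on [0.5, 3.0] intensity/ms and intercepts on [0, 20],
additive homoscedastic Gaussian noise (default SD 10 — roughly 3–7% of
the signal at the longest exposure, a moderate noise regime), and
differential activity injected **multiplicatively on the slope** (the
signal is defined as the slope, so a log2 effect of e makes case slopes
exactly 2^e × control).  When a peptide is mapped to several spiked
kinases the log2 effects add.

Designated "nonlinear" peptides receive a saturating curve
`a·(1 − exp(−t/τ))` with τ uniform on [10, 40] ms, which keeps the
noise-free linear-fit R² below 0.60 over the 10–200 ms window — safely
under the 0.90 filter without inventing chemistry.  Designated
"undetectable" peptides receive a small negative slope.  Both sets are
drawn disjoint from internal controls and from spiked peptides, so that
on noise-free data the filter exclusions and the differential set equal
the generated designations exactly; this disjointness is a test-design
choice, not a claim about real chips.  Internal controls get
condition-independent slopes and are never mapped to kinases.

The synthetic map assigns each of 60 kinases a Poisson(8)-sized peptide
set (≥ 1) from the non-control peptides and partitions kinases into
geometric-sized families (mean ≈ 2.5), exercising the family collapse.

Not emulated: image capture and spot segmentation, pump kinetics,
chip-to-chip or batch effects, heteroscedastic or multiplicative noise,
peptide-specific kinetics, and any biological correlation structure
between peptides beyond shared kinase membership.  Passing tests
therefore demonstrate correctness of the computational procedure under
the stated statistical model, not performance on patient-derived runs —
whose raw data are not publicly deposited, which is precisely why the
published per-kinase percentile values cannot be reproduced and the
aggregation layer is instead validated on the published tables' own
printed per-pipeline columns (rounded inputs make ±1 percentage point
the attainable fidelity).

## Problem sizes and runtime choices

The shipped demo runs three contexts at full chip size (196 peptides,
3 + 3 samples, 3000 resampling iterations) in about a second each.  The
spiked-family recovery experiment uses 100 seeded replicates at 500
resampling iterations per replicate — the null moments are already
stable to ~2% at 500 iterations, and the experiment measures top-rank
recovery, not tail probabilities.  The recovery experiment spikes every
member of one family (≥ 5 mapped peptides) at log2FC 1.5 with noise SD
10; under these conditions recovery is 100/100 in the shipped runs.

## Known limitations

* The kinase→family fixture table is authoritative; conflicting family
  nomenclature across sources is not resolved dynamically.
* The weighted-average definition and the inclusive-percentile formula
  are reconstructions from the published arithmetic (validated against
  all 200 published cells) rather than stated formulas.
* Fold-change averaging on the ratio scale is biased upward relative to
  the geometric mean under noise; the geometric option exists but the
  default follows the published procedure.
* The type-I sanity bound on null data (≤ 10% of families with |Z| ≥ 2)
  is a loose stochastic check, not a calibrated error rate: family hit
  counts are dependent (peptides are shared across families), and m
  varies between null replicates.
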