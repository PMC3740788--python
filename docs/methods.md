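# Methods

## Problem setting

Cancer expression markers are often activated in only a fraction of tumour
samples. Under this heterogeneous-activation model a feature's tumour values
are a mixture: most follow the baseline distribution, a subset is shifted.
Mean-difference tests average the shift away; the statistics implemented here
score the extreme tail of the tumour group instead. Because single-cohort
outlier lists are noisy, the pipeline aggregates evidence across cohorts and
across molecular levels: differential miRNAs must also look like active
regulators of deregulated target genes, and must recur across datasets.

## Outlier statistics

All five statistics operate per feature on a normal/tumour split; missing
values are ignored per feature. Conventions that the original methods leave
ambiguous are fixed package-wide: MAD carries the 1.4826 normal-consistency
factor, percentiles use linear interpolation, undefined statistics (zero MAD
or zero pooled variance) are flagged, ranked last and never selected, and
every statistic is evaluated on both tails (original and negated values) with
the larger value kept and its direction recorded.

* **t** — two-sample t with pooled variance (Welch by flag), sign = tumour
  minus normal.
* **COPA** — r-th percentile (default 90, 75/95 available) of tumour values
  standardized by the all-sample median and MAD.
* **OS** — sum of standardized tumour values above q75 + IQR of the combined
  standardized sample; 0 when the outlier set is empty.
* **ORT** — like OS but referenced to the normal group: cutoff q75 + IQR of
  the normal values, centering at the normal median, scale = 1.4826 × median
  of both groups' absolute residuals from their own group median.
* **MOST** — tumour values standardized by the normal median/MAD, sorted
  decreasingly; the statistic is max over k of the null-standardized top-k
  sum. Null moments (μ_k, σ_k) are Monte-Carlo estimates from B = 20,000
  draws of n_tumor standard normals under a fixed seed, cached per
  (n_tumor, B, seed). A `scale="pooled"` variant using the ORT scale is
  available; the normal-only MAD is the default and the tested contract.
  Note μ_k is not monotone in k: it peaks near k = n/2 and μ_n = 0.

Selection takes the top ⌈0.05·n⌉ features by rank (ties broken by feature id,
deterministically). The benchmark declares per dataset a putative list =
features selected by ≥ 3 of the 5 methods; a method's accuracy is the median
(across datasets) share of its selections that are putative. This measures
agreement with the method consensus, not truth recovery — on synthetic
heterogeneous data the t-test is reliably the most idiosyncratic method.

## Regulatory-activity filter

Per mRNA dataset, deregulated genes are the MOST top-5% calls. Within the
target network restricted to those genes, each miRNA gets β = number of its
deregulated targets, α = number of them targeted by no other miRNA, and
Z = α/β. Activity requires α ≥ 2, β ≥ 2 (the "α, β > 1" eligibility rule)
and Z ≥ 0.1, with the threshold inclusive so the printed boundary value is
usable. Exclusivity is evaluated inside the deregulated subnetwork, not the
full network: the score asks whether the *deregulated* evidence is
attributable to this miRNA alone. Active lists are combined by an
at-least-3-of-4-datasets consensus (a relaxed 2-of-4 variant is exposed),
intersected with each miRNA dataset's differential list, and the signature
keeps miRNAs in ≥ 4 of 5 filtered lists, sorted by support then id.

## Enrichment

Targets predicted for a miRNA are kept when ≥ 2 sources agree; sources
flagged experimental bypass the rule (on by default, switchable), since
validated interactions should not be vetoed by prediction disagreement.
Enrichment of a gene list against a collection uses the exact hypergeometric
upper tail P(X ≥ k) with the universe defaulting to the union of the
collection's sets (a configurable override exists because curated databases
rarely publish their true background), and BH step-up FDR across the
collection. The relevance screen flags pathways with hit ratio strictly
greater than 0.15 and p < 10⁻⁴.

## Consistency analysis

Cross-dataset overlap uses Jaccard |A∩B|/|A∪B| by default; an
intersection-over-minimum mode is provided because "overlapping percentage"
has no single convention, and the chosen mode is recorded in report metadata.
For five datasets all C(5,2) = 10 unordered pairs are compared, at any of the
levels (miRNA, target gene, functional category) supplied. The before/after
comparison uses a classical two-sided paired t-test on the 10 pair
differences; numerically constant differences are rejected as degenerate.

## Synthetic studies

The generator plants a shared core of `n_true_active_mirna` (default 11)
active miRNAs in all five miRNA datasets plus `noise_signature_size` (15)
dataset-specific false features; four mRNA datasets deregulate the targets of
the active miRNAs plus a few noise genes. Values are Normal(8, 1) on a
log2-like scale; each planted feature gains ±3 SD (sign Bernoulli(1/2)) in
⌈0.3 · n_tumor⌉ randomly chosen tumour samples; 2% of entries are missing
completely at random; groups are 15 normal + 15 tumour. All randomness flows
from one master seed through independent substreams keyed by dataset index,
so adding datasets never perturbs earlier ones.

The target network gives each miRNA an exact number of targets and exclusive
targets: exclusive genes are disjoint blocks of degree 1, every shared gene
is wired to at least two distinct miRNAs (greedy max-pairing), so realized
exclusivity equals the request and infeasible profiles raise. Active miRNAs
get 8 targets / 4 exclusive; 139 decoy miRNAs get 8 targets with 0–3
exclusive. These sizes follow a capacity argument fixed a priori: the union
of active targets plus noise genes (~96) must fit within the top-5% call
budget of an mRNA dataset (0.05 × 2000 = 100), otherwise the planted premise
"targets of active miRNAs are detectably deregulated" is incoherent by
construction.

What the generator does **not** emulate: platform/batch effects between
samples (columns are iid by construction), probe chemistry, correlated gene
modules, missing-not-at-random patterns, or realistic miRNA target-set
overlap structure. Consequently, passing synthetic tests demonstrates the
pipeline's logic and calibration under its own model assumptions, not
performance on real arrays. Because simulated columns share one distribution
already, the simulated-study runner skips quantile normalization by default
(it would only compress the signal-bearing tails); the full normexp →
quantile → probe-average → impute chain remains the documented order for real
array intensities and is enforced by `preprocess_pipeline`.

## Preprocessing details

* **Normexp**: observed intensity X = B + S, B ~ Normal(μ, σ²),
  S ~ Exponential(α). The correction is the posterior mean E[S|X=x] =
  m + σ·φ(m/σ)/Φ(m/σ) with m = x − μ − σ²/α, computed in log space so the
  deep-background tail stays finite and strictly positive; offset defaults
  to 0. Per-sample parameters are fitted by direct maximization of the
  convolution likelihood in (μ, log σ, log α) via Nelder–Mead, started from
  robust quantile-based values; at 5000 values the fit recovers parameters
  within ~10%.
* **Quantile normalization**: the reference is the across-sample mean of
  per-sample sorted observed values interpolated onto a grid of n_feature
  quantiles (exactly the classical sorted-mean reference on complete data);
  ties get stable first-occurrence ranks, making the operation deterministic
  and idempotent; missing entries are excluded and stay missing.
* **Probe handling**: probe-to-feature averaging ignores missing entries;
  the unique-probe gene filter keeps only genes measured by exactly one
  probe (removed counts are logged; an empty result warns).
* **kNN imputation** (k = 5) operates in feature space: the distance between
  two features is the root-mean-square difference over samples observed in
  both; candidates for a missing cell are features observed at that sample;
  fewer than k candidates fall back to all of them; observed cells are never
  modified and fully missing features raise.

## Known limitations

Per-feature robust statistics pay a substantial price for estimating
location and scale from small groups: at 15+15 samples, a 3-SD shift in 30%
of tumour samples is ranked into the top 5% only about half the time — with
*known* standardization the same statistic would succeed almost always, so
the gap is estimation noise, not algorithmic slack. Requiring a miRNA to
recur in 4 of 5 datasets therefore compounds to a low end-to-end recovery of
the planted core at these sample sizes; the consistency *gain* from the
activity filter is large and highly reproducible, but the absolute recall of
an 11-miRNA panel is sample-size-limited. Larger cohorts or stronger/broader
activation raise it steeply.

Problem sizes used throughout (800 miRNA features, 2000 genes, 15+15
samples, 50-replicate benchmarks at 1000 features) keep any single analysis
in the seconds-to-minutes range on one CPU.
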