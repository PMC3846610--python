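# Methods

## Model

An expression profile over n samples is a nonnegative vector
X = (x₁, …, xₙ). The package's statistics are all functions of the
direction of X, so any per-gene scaling (library size factors applied
uniformly, unit changes) leaves every score and every classification
unchanged. The geometry is the unit sphere: X is mapped to its SPM
profile X/‖X‖₂, and the four scores are

- SPMᵢ = xᵢ/‖X‖₂ — cosine between X and its one-sample projection;
- DPM = s(SPM profile) · √n, with s the sample standard deviation
  (divisor n−1);
- CTM(S) = √(Σ_{i∈S} SPMᵢ²) for a sample subset S — cosine between the
  subset projection of X and X;
- RPM(R) = max_{i∈R} SPMᵢ / min_{i∉R} SPMᵢ for a putative repressed
  group R.

The fractional baseline rᵢ = xᵢ/Σxⱼ and SUM(S) = Σ_{i∈S} rᵢ are provided
for comparison; SPMᵢ ≥ rᵢ holds elementwise because ‖X‖₂ ≤ ‖X‖₁, which is
the precise sense in which the cosine statistics are the more sensitive
detector of concentrated expression.

### Normalisation choices inside DPM, CTM and RPM

Three scores admit more than one plausible closed form and were fixed by
boundary behavior:

- **DPM**: among affine scalings of the SPM-profile standard deviation,
  s·√n is the unique one sending a uniform profile to 0 and a one-sample
  spike to exactly 1 for every n (population SD, divisor n, would cap
  below 1). Unit tests pin both anchors for n = 2…50.
- **CTM**: √(Σ subset SPM²) reduces to SPM for a singleton (the two scores
  are complementary views of the same projection), is bounded in [0, 1],
  is monotone as the subset grows, and reproduces the published
  one-decimal worked examples recomputed in `scripts/acceptance.py`.
- **RPM**: the max-over-min SPM ratio matches the stated operands and
  direction (near 0 = strong repression) and stays within [0, 1] whenever
  the repressed group truly holds the k lowest expressions; the library
  warns if a caller passes a group that does not.

Degenerate inputs: all-zero profiles leave every cosine statistic
undefined — the library raises a flagged error and the matrix classifier
skips the gene with a log record. A zero inside RPM's expression group
makes the ratio undefined; during classification such a k is passed over
(larger k may absorb the zeros into the repressed group), and a gene whose
zeros extend beyond the k range gets no repressed call, logged. Negative
values are rejected by default — they usually mean log-ratio data was
supplied — with an explicit clamp-at-zero option. Profiles of extreme
magnitude are pre-scaled by their maximum before norm computation so the
squared norm cannot under- or overflow (scores are scale-invariant, so
this is exact in effect).

## Classification

The four rules are evaluated independently per gene (no precedence), so a
gene may carry several calls; output order is deterministic (input gene
order, then specific / selective / housekeeping / repressed). All
threshold comparisons are strict, pinned by tests on profiles engineered
to land float-exactly on a threshold, e.g. (27, 11, 7, 1) whose leading
SPM is exactly 27/30 = 0.9.

Selective candidates are the top-k samples by SPM (descending, ties by
column order): any other size-k subset has a lower CTM, so top-k is
optimal for the CTM clause; the per-sample SPM clause is then also
hardest to fail there. Repressed candidates are the bottom-k by SPM
(ascending). For each class the smallest qualifying k is reported — the
most parsimonious sample set — with `report_all_k` exposing the rest.
k ranges are clipped to n−1 with a warning on very small matrices.

Two caveats a user should know. First, with few samples the selective
rule admits near-uniform profiles: at n = 6 a perfectly flat gene has
top-5 CTM = √(5/6) ≈ 0.91 > 0.9. This is a property of the criteria, not
of the implementation, and is one reason the dataset-quality warning asks
for at least 5 (ideally more) distinct samples. Second, housekeeping is
DPM-only by default; an optional `min_mean_expression` floor supports
reference-gene selection, where robustly detectable expression also
matters.

## Preprocessing

Pipeline order is fixed: missing-cell handling (drop the row, or impute 0
on request) → A/M/P zeroing (Absent/Marginal calls set the cell to 0) →
replicate averaging (arithmetic mean per group, first-appearance column
order) → probeset collapse (per gene, keep the probeset with the largest
ddof=1 standard deviation; ties keep file order, logged). The collapse SD
is computed on post-zeroing, post-averaging values so that the retained
probeset is the most variable one *as classification will see it*. Each
step is idempotent on its own output, and collapse only ever selects an
existing row. No cross-sample normalisation is applied: columns must
arrive comparably scaled.

The GDS SOFT reader handles the full-table dialect (ID_REF / IDENTIFIER /
per-sample value columns, optional detection-call columns recognised by a
header ending in "call", subset annotations retained as a candidate
replicate grouping) and refuses truncated files rather than silently
returning a partial matrix.

## Synthetic data

The generator plants the five gene types on a constant background b with
multiplicative lognormal noise (mean-1, coefficient of variation
`noise_cv`): specific genes carry b·fold in one random sample, selective
in k_selective samples, housekeeping are flat, repressed are background
with k_repressed exact zeros (optionally a small positive floor, to
exercise RPM away from 0), unpatterned genes are lognormal noise alone.
Defaults — 12 samples, 100 genes per pattern class, base 100, fold 20,
noise_cv 0.05, k_selective 3, k_repressed 2 — are the study conditions
for the recovery experiments: at these settings each planted class is
recovered at ≥ 95 % under default thresholds, and planted selective genes
pass CTM > 0.9 far more often than SUM > 0.9 at equal k. The lognormal
noise model is a deliberate idealisation: real arrays add probe effects,
batch structure, heavy-tailed outliers and correlated noise, none of
which are simulated — passing recovery tests demonstrates correctness of
the statistics and rules, not robustness to platform artifacts.

Recovery sizes were chosen to keep the whole validation suite desk-scale
(hundreds of genes, seconds of runtime) while leaving Monte-Carlo error
well below the 95 % recovery margin.

## Known limitations

- Criteria are tuned for series of ≥ 5 distinct samples; small-n
  behavior of the selective rule is degenerate (above).
- No differential-expression testing, no gene–gene correlation or
  profile-similarity analysis, no array normalisation (RMA/MAS5) or batch
  correction — inputs are assumed already summarised and comparably
  scaled.
- Accession fetching from GEO/ArrayExpress over the network is out of
  scope; the SOFT reader consumes local files.
- When several datasets disagree about a gene's pattern, the package
  reports each dataset's calls as-is; reconciling conflicting calls
  across datasets is left to the user.
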