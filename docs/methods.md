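# Methods

## Model and procedure

The pipeline treats a *study* as a set of independent case-control
*groups*: one normalized log2 expression matrix (probes × samples) per
group, each group measured on its own platform, in one tissue, under one
disease arm (T2DM or obesity). Case/control membership comes from an
explicit design table — never from sample naming — and each subgroup
must have ≥3 samples.

**Per-probe test.** Within a group, each probe is compared between
cases and controls with a two-sided two-sample t-test. The choice of
test is made by a variance-ratio F pretest: with the larger sample
variance on top, `F = s²max/s²min` with the corresponding (numerator,
denominator) degrees of freedom, and a two-sided P value equal to twice
the upper tail, capped at 1. If that P value is below `f_alpha`
(default 0.05) the variances are treated as unequal and Welch's t-test
is used (Welch–Satterthwaite df, computed through the normalized
variance weight so the df never under- or overflows on near-degenerate
data); otherwise the pooled-variance test (df = n₁+n₂−2). The boundary
`f_p == f_alpha` goes to the pooled branch. If both sample variances are
exactly zero, the probe is flagged *degenerate*: P = 1 if the means
agree, P = 0 if they differ, with a logged warning — this keeps constant
probes from silently crashing real public data.

Both t-tests, and the F pretest, are two-sided. One-sided variants are
not offered: the screen is direction-agnostic at the testing stage and
recovers direction separately (below).

**Probe → gene.** Probes annotated to no gene or to more than one gene
are excluded (ambiguous evidence); the counts of exclusions are logged
by reason. A gene's P value in a group is the minimum over its retained
probes, and both the probe count and the min-P probe are recorded, so
stricter aggregation readings (e.g. "any probe significant at 0.05")
can be reproduced from the same output. The gene's direction is the
sign of (case mean − control mean) *of the min-P probe*, keeping
direction and significance attached to the same evidence; exact P-value
ties resolve to the first probe in matrix order.

**Vote count.** Across groups, each gene's differential-expression
percentage is `100 · k/n` with `k` the number of groups where the gene's
P ≤ `p_threshold` (boundary inclusive, default 0.05) and `n` the number
of groups where the gene has at least one retained probe. The per-gene
denominator is essential: platforms differ in gene content, and a
total-group denominator would penalize genes merely for being
unmeasurable. Ranking is by descending percentage, ties broken by
larger `n` (more evidence first) then lexicographic gene id; ranks are
assigned 1..N over the sorted order. Selection thresholds are
configurable per arm — inclusive ≥50% (T2DM) and ≥60% (obesity) for the
genome-wide selection, strictly-greater >40% / >50% for the SNP-window
re-ranking — together with a minimum number of available P values
(`min_groups`, 10 for the smaller obesity arm, applied to `n`).
Percentages are reported with raw counts and rendered at one decimal,
rounding half-up.

**Multiplicity side-channel.** Per group, significant-gene counts at
raw, Benjamini–Hochberg, and Bonferroni criteria are reported side by
side. The counts are necessarily ordered raw ≥ BH ≥ Bonferroni.
Adjustment is never used as a selection gate: the vote count is a
cross-study replication criterion, and gating each small group at
FDR ≤ 0.05 empties most of them.

**SNP-window screen.** A gene qualifies for a SNP when its 1-based
inclusive interval intersects the closed window
`[pos − r, pos + r]` (default r = 1,000,000) on the same chromosome
("chr7" and "7" compare equal; strand is ignored). Any overlap of the
gene body counts — the weakest assumption consistent with the published
pairings — with midpoint and TSS modes available as options. Boundaries
are closed: a gene ending exactly r bp from the SNP qualifies. The
reported distance is 0 when the SNP lies inside the gene, else the gap
to the nearer gene end. SNP panels are filtered on association
P ≤ 5×10⁻⁸ at read time and matched to percentages only within their
disease arm. Assigned genes lacking any expression record are reported
in a separate "unranked" section and are never candidates.

**Direction summaries.** For each selected candidate and tissue, the
per-group directions are tallied and reconciled by majority vote: `up`
when up-groups outnumber down-groups, `down` symmetrically, `mixed` on a
non-zero tie, `flat` when nothing moved. By default all measuring
groups vote; `significant_only=True` restricts the vote to groups with
P ≤ 0.05. The default votes with all groups because per-tissue group
counts are small (often 1–3) and discarding non-significant directions
would leave many tissues uncallable.

## Synthetic data

The generator emulates the structure of a multi-tissue microarray
compendium, not its chemistry. Per group: a platform-specific gene
subset (i.i.d. dropout per gene, default 10%), 1–3 probes per gene
(uniform), a fraction (default 5%) of probes additionally tagged with a
second random gene (these must be excluded downstream; the truth ledger
records each such probe with its primary gene), and expression
`baseline + gene offset + Gaussian noise` on the log2 scale (default
baseline 7, noise SD 1, gene offsets N(0, 0.5²)) — RMA-normalized data
is approximately Gaussian, and a unit-variance Student-t(4) option
provides heavier tails for robustness checks. Planted genes (default
20 of 2000) receive a constant shift of `effect_sd_units · noise_sd`
(default 2) in the case samples of a `planted_group_fraction` share
(default 70%, rounded) of the groups that carry them, with the sign
fixed per gene and tissue so direction summaries have recoverable
truth. Designated groups can have case-subgroup variance inflated to
exercise the Welch branch. Everything — presence, probe counts, signs,
noise — derives from the single config seed, and the emitted files are
byte-identical across runs.

The default scenario (21 groups over 6 tissues, 2000 genes, 5v5
samples) mirrors the larger arm of the published compendium at desk
scale. What the generator does **not** model: probe-level intensity
effects (GC content, cross-hybridization), batch and lab effects,
correlated genes, and platform-specific probe quality. Passing recovery
tests therefore demonstrates that the statistics and plumbing behave as
specified under the stated noise model — not that the thresholds are
optimal for any particular real compendium.

Two calibration notes. First, with min-P aggregation over k probes the
per-gene null significance rate is 1 − 0.95ᵏ > 0.05 by construction, so
null-calibration checks use single-probe genes, where the t-test's
exactness under Gaussian noise puts the mean percentage at 5%. With the
default 1–3 probes per gene the null mean percentage is ≈ 9.7% — the
same selection effect that inflates any min-P screen, and one reason
the vote thresholds (≥50%) sit far above it. Second, the planted
scenario's expected sensitivity at the ≥50% threshold is ≈ 0.95 by
direct noncentral-t/binomial computation (per-group power ≈ 0.79 at
2 sd, 5v5, boosted by min-P for multi-probe genes), which is why the
recovery criterion of 0.9 is attainable with margin while null genes
(percentage ≈ 5–14%) essentially never cross 50%.

## Numerical and design choices

- **Coordinates** are stored 1-based inclusive (NCBI/CCDS style); BED
  input is converted on read (start+1) and back on write. Duplicate
  gene ids on one chromosome merge by union; on different chromosomes
  they are an error.
- **Determinism**: stage outputs are sorted on explicit keys, floats
  are written with fixed formatting, the manifest contains no
  timestamps; identical inputs and config give byte-identical reports,
  and the manifest's config echo reproduces the run.
- **Degenerate inputs**: constant probes (see above), empty candidate
  lists (header-only reports with a warning), genes measured in zero
  groups (excluded upstream of the vote count), empty P lists (zero
  counts) are all defined, logged behaviors rather than errors.
- **min-P vs alternatives**: Fisher/Stouffer combination and
  effect-size meta-analysis are deliberately out of scope; the vote
  count is the method under study, and min-P aggregation subsumes the
  "any probe significant" reading at every threshold.
- **Library choices**: t/F tail probabilities come from scipy's
  distribution functions with statistics computed in vectorized code
  here (scipy's own `ttest_ind` serves as an independent oracle in the
  tests); BH/Bonferroni adjustment delegates to statsmodels'
  `multipletests`; all tables go through pandas.
- **Problem sizes** in the test suite and acceptance script (21 groups
  × 2000 genes; 50 recovery replicates; 200 random window instances;
  100 random test oracles) were chosen as the smallest sizes at which
  the Monte-Carlo tolerances quoted in the tests are meaningful.

## Known limitations

- Vote counting discards effect sizes; a gene consistently but weakly
  perturbed ranks above one strongly perturbed in a minority of
  tissues. That is the method's stated intent, not an accident.
- The per-gene denominator makes percentages of sparsely measured genes
  high-variance; the obesity arm's `min_groups=10` mitigates but does
  not remove this.
- The min-P gene aggregation is anti-conservative for genes with many
  probes; cross-group replication, not per-group calibration, carries
  the error control.
- The window screen knows nothing of LD structure or eQTL effect
  direction; it is a pure proximity filter.
- Whether the original screen used gene body, CDS extent, or TSS for
  the window is not recoverable; the gene-body default is a documented
  choice, with the alternatives exposed.
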