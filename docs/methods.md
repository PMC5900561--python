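# Methods

## Kinetic model

At steady state, transcript i is synthesized at rate S_i per cell and lost
with decay constant λ_i (per hour). With cell growth at doubling time δ,
per-cell abundance is additionally diluted at γ = ln(2)/δ, so the steady
state is T_i = S_i/(λ_i+γ) and the labeled pool after labeling starts obeys

    A_i(t) = T_i · (1 − e^−(λ_i+γ)t).

A transcription-shutoff course instead decays as N_0·e^−λt. Half-life is
ln(2)/λ. These closed forms are the whole kinetic content of the package:
synthesis and decay rates are assumed constant (no induction, no
time-varying decay), which is the regime where approach-to-equilibrium
labeling is interpretable at all.

### Growth correction and normalization modes

Both normalization factors — the spike-in genome's read total and the summed
coverage of the selected intron set — scale with the sequencing library's
composition, and any ratio of labeled exon signal to such a factor
approaches its plateau at the combined rate λ+γ. Fitting therefore applies
γ = ln(2)/δ in spike-in mode. Intron mode follows the method's convention of
applying no growth correction (γ = 0): under that convention the fitted rate
absorbs γ, shortening apparent half-lives by at most γ (≈0.029/h at δ=24 h)
— negligible for unstable transcripts and a modest compression for very
stable ones. Consistent with this, the simulator's default truth models
non-dividing conditions (γ = 0), so both modes are exactly invertible and
validation separates normalization error from the growth convention; growth
is switched on explicitly (`make_truth(..., doubling_time=24)`) in the tests
that probe the direction and size of the correction.

## Fitting

Weighted nonlinear least squares (`scipy.optimize.least_squares`, bounded):

* weights: w(t) = 1/max(ŷ(t), 1e−8), a Poisson-like variance
  stabilization for count-derived signal, iterated twice (fit → reweight
  from the fitted curve → refit); `uniform` available via configuration.
* initialization (deterministic): N0 from the largest observation; λ from a
  through-origin regression of −ln(1 − y/(1.05·N0)) on t, falling back to
  ln(2)/median(t).
* bounds: λ ∈ [1e−5, 50]/h, N0 ∈ (0, 1e6·max(y)]; tolerances 1e−12; points
  at t ≤ 0 are excluded from bounded-growth fits (no labeling measurement
  exists at t = 0).
* exclusion rather than error: a gene is reported non-converged (no
  half-life) when the optimizer fails, λ lands on a bound, the curve
  reaches <5% of its plateau by the last time point (non-saturating, no
  plateau information), or >99.99% of the plateau by the *first* time point
  (already equilibrated; a constant series is fit perfectly by any
  sufficiently large rate, so such fits carry no kinetic information).
  Reported half-lives are written to 4 significant figures.

## Intron selection

Expressed introns (mean coverage across time points ≥ 0.5 reads) are scaled
by their own mean — clustering should capture profile shape, not magnitude —
and clustered with k-means (k = 4, 25 seeded restarts, Euclidean distance).
Rows are clustered in id-sorted order so results do not depend on input
order. Each centroid is scored for the expected non-increasing behavior:
primary score the Spearman correlation of centroid with time (more negative
is better), tie-broken by the total positive increment Σ max(0, Δc). The
best-scoring cluster is selected automatically; clusters whose scores tie it
exactly are merged (k-means may split one homogeneous decreasing population
into several clusters), and a `select_cluster` override preserves manual
choice. The normalization factor is the per-time-point sum of the selected
introns' coverages; a zero factor at any time point is a hard error naming
the time point.

## Spike-in QC thresholds

Spike-in factors require a minimum read total per time point, default
10,000, i.e. a relative sampling error of the factor ≤ 1/√n = 1%; the factor
divides every gene's series, so its noise floor bounds every half-life.
Data sets below the floor raise the "insufficient spike-in reads" failure
instead of producing silently unstable half-lives. Purification enrichment
QC reports (labeled/unlabeled in the purified library) ÷ (same ratio
unpurified); with the default 1% unlabeled carryover this is ≈100-fold for
a successful selection.

## The simulator

`druid.simulate` generates the full experiment from the closed forms above:
per-cell labeled pools for genes and introns, population growth e^{γt}, a
fully labeled exogenous spike-in at a constant mass fraction of extracted
RNA (default 20%, as in whole-organism spike-in protocols), an unlabeled
carrier (default 20%) that enters the purified library only through the
carryover fraction (default 1%), and fixed-depth multinomial read sampling
per time point (default 2×10⁶ reads) — the compositional constraint of
sequencing. Defaults: 500 genes with half-lives log-uniform on 0.25–36 h and
synthesis rates log-uniform on 1–20 (≈2 decades of expression); introns with
half-lives of 0.5–2 minutes (fully equilibrated before t = 1 h), optionally
mixed with a long-lived "misbehaving" subset emulating retained or
misannotated introns, which must be (and is) excluded by cluster selection.

With `sampling=False` the simulator returns expected counts and treats
purification as perfect; this deterministic core is exactly inverted by
intron normalization + bounded-growth fitting (validated to ≤1e−6 relative
error end to end). What the simulator does **not** model: read-level
sequence effects (GC, mappability), 4SU incorporation bias, biological
replicate variability beyond resampling, isoform structure, or time-varying
rates. Passing tests therefore demonstrate correctness of the estimator
under the stated generative model, not robustness to every artifact of real
libraries.

### Recalcitrant modes

* `few_spikein_reads`: spike-in mass fraction scaled down 100×, dropping
  spike totals below the QC floor — the "cannot normalize at all" failure.
* `biased_spikein`: the spike-in share drifts upward as e^{0.15t}
  (progressive sample loss relative to the standards). The drift deflates
  late time points of every spike-normalized series, which compresses and
  scrambles stable transcripts (rank correlation with truth falls to
  ≈0.15–0.6 across seeds, with many genes rejected by the fit), while
  intron normalization — computed from the same library — is untouched.
  A per-time-point wiggle shared across genes was deliberately not used: the
  fit maps λ through a nearly monotone deterministic function of such a
  distortion, leaving rank order misleadingly intact.

## Statistics

Table comparisons inner-join on gene id (≥4 shared genes required) and
report Spearman on half-lives plus Pearson on log10 half-lives (half-life
distributions are heavy-tailed; linear Pearson available). Fisher's r-to-z:
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)) with a two-sided normal
p-value. The test is formally defined for Pearson correlations; applying it
to Spearman coefficients follows common practice in the field and can emit
a warning.

## Problem sizes and determinism

Validation runs use 500 genes × 6 time points at 2×10⁶ reads/time point
(seconds per pipeline run), which already puts sampling noise well below the
effect sizes being checked; all randomness flows from explicit integer
seeds (NumPy `default_rng`, seeded k-means restarts), so identical inputs
give bit-identical outputs.

## Known limitations

* Steady state is assumed; systems with changing synthesis/decay rates are
  out of scope.
* Intron-mode half-lives inherit the no-growth-correction convention (see
  above); comparisons across growth conditions should use spike-in mode or
  a shared δ.
* Union exon counting discards gene-ambiguous reads; overlapping gene
  models lose signal rather than gaining noise.
* The intron overlap filter treats exons of *any* gene as disqualifying
  (strand-agnostic), the strictest reading; a `same_gene_only`-style
  relaxation is available by passing a restricted exon list.
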