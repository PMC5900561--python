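# druid-kinetics

Transcriptome-wide mRNA half-lives from approach-to-equilibrium
metabolic-labeling (4SU) RNA-seq time courses, using **DRUID** —
determination of rates using intron dynamics — with exogenous spike-in
normalization and transcription-shutoff exponential-decay fitting as
alternative and QC modes.

## The problem and the model

In an approach-to-equilibrium experiment, cells are incubated with
4-thiouridine and harvested at increasing times; the labeled pool of each
transcript rises toward its steady-state level at a rate set by that
transcript's stability. Sequencing reports only *fractions* of a fixed read
total, so recovering absolute kinetics requires a per-time-point
normalization factor. The classical factor is an exogenous spike-in added at
a constant ratio to extracted RNA; DRUID instead uses an endogenous one: the
summed signal of rapidly turned-over introns, which equilibrate before the
first time point and behave like a spike-in that experienced every
experimental step alongside the mRNA.

Per gene, the normalized labeled signal follows the bounded-growth form

    N(t) = N0 * (1 - exp(-(λ + γ) t)),        hl = ln(2) / λ,

where λ is the decay constant, N0 the plateau, and γ = ln(2)/δ the dilution
due to growth at doubling time δ (applied in spike-in mode; intron mode
applies no growth correction). Shutoff courses are fit with
N(t) = N0·exp(−λt). Fits are weighted nonlinear least squares with
Poisson-like weights w(t) = 1/max(ŷ(t), ε), iteratively reweighted.

The DRUID pipeline:

1. **annotate** — one longest transcript per gene from a GTF; introns are
   inter-exon gaps, discarding any intron that overlaps an exon of any
   isoform.
2. **quantify** — gene-level exon read counts (union counting, ambiguous
   reads discarded) and intron-level mean per-base coverage; per-genome read
   totals for merged multi-organism references.
3. **normalize** — gene filter (≥1 read at every time point, ≥5 at one or
   more); intron filter (mean coverage ≥ 0.5); k-means (k=4) on mean-scaled
   intron time profiles; the cluster with the most non-increasing centroid
   supplies the factor: the sum of its members' coverages. Spike-in mode
   uses the spike-in genome's read totals instead.
4. **fit** — per-gene weighted NLS; genes whose optimizer fails, lands on a
   rate bound, or whose curve carries no kinetic information are excluded
   rather than reported.
5. **stats** — replicate/method comparisons: Spearman, Pearson on log10
   half-lives, Fisher r-to-z.

A first-class simulator generates every input with known ground truth,
including "recalcitrant" data sets whose spike-ins are too sparse or biased
to use — the scenario DRUID rescues.

## Worked example

```python
from druid import (ExperimentDesign, make_truth, run_from_matrices,
                   simulate_labeling_experiment)

truth = make_truth(n_genes=500, n_introns=300, seed=1, misbehaving_fraction=0.4)
sim = simulate_labeling_experiment(truth, time_points=(1, 2, 4, 8, 12, 24))
result = run_from_matrices(ExperimentDesign(seed=1), sim.exon_counts,
                           sim.intron_coverage)
print(result.stage_counts)
```

Running `python examples/simulate_and_fit.py` prints:

```
stage counts: {'genes_input': 500, 'genes_after_filter': 500,
 'introns_input': 300, 'introns_after_filter': 263,
 'introns_selected': 180, 'genes_converged': 494}
          half_life_hours  true_half_life_hours
gene0000            3.123                 3.182
gene0002            0.468                 0.512
Spearman(estimated, true) = 0.9972; median |rel. error| = 8.0%
```

180 of 263 expressed introns fall in the selected (non-increasing) cluster —
the long-lived "misbehaving" introns are excluded automatically — and the
fitted half-lives rank-correlate 0.997 with the generating truth, with a
median error of a few percent from compositional sampling alone.

Other examples: `rescue_recalcitrant.py` (intron mode keeps Spearman ≈ 0.99
where biased spike-ins collapse to ≈ 0.15), `shutoff_decay.py`,
`annotation_to_counts.py`, `compare_replicates.py`.

The same pipeline is scriptable from the shell:

```sh
druid simulate --genes 500 --seed 1 --outdir sim/
druid run --config cfg.yaml --exon-counts sim/exon_counts.tsv \
          --intron-coverage sim/intron_coverage.tsv --outdir out/
druid compare out/half_lives.tsv other/half_lives.tsv
```

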