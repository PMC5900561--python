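"""Normalization of exon counts into per-gene relative-abundance time series.

Two normalization routes are supported:

* **Intron-sum (DRUID).** Introns of expressed genes turn over within
  minutes, so their labeled pools equilibrate before the first time point of
  an approach-to-equilibrium course and behave like an endogenous spike-in.
  Expressed introns are filtered by mean coverage, clustered on their scaled
  time profiles (k-means, k=4), and the cluster whose centroid is closest to
  the expected non-increasing behavior supplies the per-time-point
  normalization factor: the sum of its members' coverages.

* **Spike-in.** The factor is the total read count assigned to the spike-in
  genome at each time point (robust to single-transcript outliers).

Either way, normalized abundance is exon signal divided by the factor at the
same time point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.cluster import KMeans

from .matrix import EXON_COUNT, INTRON_COVERAGE, AbundanceMatrix, GenomePartition

INTRON_MODE = "intron"
SPIKEIN_MODE = "spikein"

#: minimum spike-in reads per time point for a usable normalization factor
#: (relative sampling error of the factor <= 1/sqrt(n) = 1%)
MIN_SPIKEIN_READS = 10_000


class NoFeaturesPassFilter(ValueError):
    """Raised when a filter empties the feature set; names the thresholds."""


class InsufficientSpikeInReads(ValueError):
    """Raised when spike-in totals are too sparse to normalize against —
    the signature of a recalcitrant data set."""


@dataclass
class IntronClusterReport:
    """Audit record of k-means intron selection.

    ``assignments`` maps intron id -> cluster index; ``centroids`` is a
    (k x T) DataFrame of mean scaled profiles; ``selection_scores`` holds per
    cluster the (monotonicity, positive-increment) score pair — smaller is
    better; ``selected_cluster`` is the arg-minimum, and ``selected_clusters``
    additionally includes any cluster whose score ties it (k-means may split
    one homogeneous decreasing population into several clusters with
    identical scores; the well-behaved set is their union).
    """

    assignments: pd.Series
    centroids: pd.DataFrame
    selection_scores: pd.DataFrame
    selected_cluster: int
    selected_clusters: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.selected_clusters:
            self.selected_clusters = [self.selected_cluster]

    @property
    def selected_introns(self) -> list[str]:
        return list(self.assignments.index[self.assignments.isin(self.selected_clusters)])

    def to_tsv(self, introns_path: str | Path, centroids_path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "cluster": self.assignments,
                "selected": self.assignments.isin(self.selected_clusters).astype(int),
            }
        )
        df.index.name = "intron_id"
        df.to_csv(introns_path, sep="\t")
        out = self.centroids.copy()
        out.index.name = "cluster"
        out.to_csv(centroids_path, sep="\t")


@dataclass
class NormalizedSeries:
    """Per-gene relative abundance through time plus the divisors used."""

    data: pd.DataFrame  # genes x time points
    factors: pd.Series  # per-time-point divisor actually applied
    mode: str

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            bad = [t for t, f in self.factors.items() if f <= 0]
            raise ValueError(f"normalization factors must be positive; bad at t={bad}")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("relative abundance must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time_points(self) -> np.ndarray:
        return np.asarray(self.data.columns, dtype=float)


def filter_genes(
    exon_counts: AbundanceMatrix,
    min_reads_all: float = 1,
    min_reads_any: float = 5,
) -> AbundanceMatrix:
    """Keep genes with >= ``min_reads_all`` reads at *every* time point and
    >= ``min_reads_any`` reads at *at least one* time point (defaults 1/5)."""
    if exon_counts.kind != EXON_COUNT:
        raise ValueError("filter_genes expects an exon_count matrix")
    vals = exon_counts.values
    keep = (vals >= min_reads_all).all(axis=1) & (vals >= min_reads_any).any(axis=1)
    if not keep.any():
        raise NoFeaturesPassFilter(
            f"no genes pass filters (>= {min_reads_all} at all time points, "
            f">= {min_reads_any} at one or more)"
        )
    return AbundanceMatrix(exon_counts.data.loc[keep], kind=EXON_COUNT)


def filter_introns(
    intron_cov: AbundanceMatrix,
    min_mean_coverage: float = 0.5,
) -> AbundanceMatrix:
    """Keep introns whose mean coverage across time points is >= 0.5 reads
    (default threshold; configurable)."""
    if intron_cov.kind != INTRON_COVERAGE:
        raise ValueError("filter_introns expects an intron_coverage matrix")
    keep = intron_cov.values.mean(axis=1) >= min_mean_coverage
    if not keep.any():
        raise NoFeaturesPassFilter(
            f"no introns pass filter (mean coverage >= {min_mean_coverage})"
        )
    return AbundanceMatrix(intron_cov.data.loc[keep], kind=INTRON_COVERAGE)


def _monotonicity_score(centroid: np.ndarray, time_points: np.ndarray) -> tuple[float, float]:
    """Score a centroid for non-increasing behavior.

    Primary: Spearman correlation of the centroid with time (more negative =
    more decreasing). Tie-break: total positive increment sum(max(0, diff)).
    Smaller (lexicographically) is better. Constant centroids score (0, 0).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = spearmanr(time_points, centroid).statistic
    if not np.isfinite(rho):
        rho = 0.0
    pos_inc = float(np.sum(np.maximum(0.0, np.diff(centroid))))
    return float(rho), pos_inc


def cluster_and_select_introns(
    intron_cov: AbundanceMatrix,
    k: int = 4,
    seed: int = 0,
    n_init: int = 25,
    select_cluster: int | None = None,
) -> IntronClusterReport:
    """K-means the scaled intron time profiles and pick the well-behaved set.

    Each profile is divided by its own mean so clustering captures shape, not
    magnitude (constant or zero-mean profiles are guarded). Rows are clustered
    in a canonical (id-sorted) order so the result is independent of input
    order for a fixed seed. Each centroid is scored for non-increasing
    behavior and the best-scoring cluster is selected automatically;
    ``select_cluster`` overrides the automatic choice (the manual option).
    With fewer than ``k`` introns, all introns fall in a single cluster and a
    warning is issued.
    """
    if intron_cov.kind != INTRON_COVERAGE:
        raise ValueError("cluster_and_select_introns expects an intron_coverage matrix")
    data = intron_cov.data.sort_index()
    tps = np.asarray(data.columns, dtype=float)
    vals = data.to_numpy(dtype=float)
    means = vals.mean(axis=1)
    safe = np.where(means > 0, means, 1.0)  # all-zero profiles stay all-zero
    scaled = vals / safe[:, None]

    if len(data) < k:
        warnings.warn(
            f"only {len(data)} introns for k={k}; treating all introns as one cluster"
        )
        labels = np.zeros(len(data), dtype=int)
        centroids = scaled.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(scaled)
        centroids = km.cluster_centers_

    scores = [_monotonicity_score(c, tps) for c in centroids]
    score_df = pd.DataFrame(scores, columns=["monotonicity", "positive_increment"])
    score_df.index.name = "cluster"
    if select_cluster is None:
        selected = int(min(range(len(scores)), key=lambda i: scores[i]))
        best = scores[selected]
        ties = [
            i
            for i, s in enumerate(scores)
            if abs(s[0] - best[0]) <= 1e-9 and abs(s[1] - best[1]) <= 1e-9
        ]
    else:
        if not 0 <= select_cluster < len(centroids):
            raise ValueError(f"select_cluster {select_cluster} out of range")
        selected = int(select_cluster)
        ties = [selected]

    return IntronClusterReport(
        assignments=pd.Series(labels, index=data.index, name="cluster"),
        centroids=pd.DataFrame(centroids, columns=tps),
        selection_scores=score_df,
        selected_cluster=selected,
        selected_clusters=ties,
    )


def intron_normalization_factors(
    intron_cov: AbundanceMatrix,
    selected: list[str],
) -> pd.Series:
    """Per-time-point factor = sum of selected introns' coverage at t."""
    if len(selected) == 0:
        raise ValueError("selected intron set is empty")
    missing = [i for i in selected if i not in intron_cov.data.index]
    if missing:
        raise KeyError(f"selected introns absent from matrix: {missing[:5]}")
    factors = intron_cov.data.loc[list(selected)].sum(axis=0)
    zero = [t for t, f in factors.items() if f <= 0]
    if zero:
        raise ValueError(f"intron normalization factor is zero at t={zero}")
    factors.name = "factor"
    return factors


def spikein_normalization_factors(
    partition: GenomePartition,
    spikein_label: str,
    min_reads: float = MIN_SPIKEIN_READS,
) -> pd.Series:
    """Per-time-point factor = total reads assigned to the spike-in genome.

    Raises :class:`InsufficientSpikeInReads` when any time point falls below
    ``min_reads`` (default 10,000, i.e. <=1% relative sampling error on the
    factor) — the recalcitrant-data signature; zero reads always fails.
    """
    factors = partition.label_totals(spikein_label).astype(float)
    low = [t for t, f in factors.items() if f < max(min_reads, 1)]
    if low:
        raise InsufficientSpikeInReads(
            f"insufficient spike-in reads for label {spikein_label!r} at t={low} "
            f"(minimum {min_reads} per time point)"
        )
    factors = factors.copy()
    factors.name = "factor"
    return factors


def normalize(exon_counts: AbundanceMatrix, factors: pd.Series, mode: str) -> NormalizedSeries:
    """Divide each gene's counts by the per-time-point factor."""
    tps = list(exon_counts.data.columns)
    fac = factors.copy()
    fac.index = [float(t) for t in fac.index]
    if sorted(fac.index) != sorted(tps):
        raise ValueError(
            f"factor time points {sorted(fac.index)} do not match matrix {sorted(tps)}"
        )
    fac = fac[tps]
    rel = exon_counts.data.div(fac, axis=1)
    return NormalizedSeries(data=rel, factors=fac, mode=mode)


def enrichment_qc(
    purified: GenomePartition,
    unpurified: GenomePartition,
    labeled_label: str,
    unlabeled_label: str,
) -> pd.Series:
    """Fold enrichment of labeled over unlabeled material by purification.

    Per time point: (labeled/unlabeled in the purified library) divided by
    (labeled/unlabeled in the unpurified library). Values >> 1 indicate the
    streptavidin selection worked.
    """
    pl = purified.label_totals(labeled_label)
    pu = purified.label_totals(unlabeled_label)
    ul = unpurified.label_totals(labeled_label)
    uu = unpurified.label_totals(unlabeled_label)
    if (pu <= 0).any() or (uu <= 0).any() or (ul <= 0).any():
        raise ValueError("enrichment undefined: zero denominator in a partition")
    fold = (pl / pu) / (ul / uu)
    fold.name = "enrichment_fold"
    return fold
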