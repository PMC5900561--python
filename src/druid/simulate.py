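"""Synthetic approach-to-equilibrium experiments with known ground truth.

The generative model mirrors the kinetics of a metabolic-labeling time
course. Each transcript species i is synthesized at rate S_i per cell and
decays with constant lambda_i; with growth dilution gamma the per-cell
steady state is T_i = S_i/(lambda_i+gamma) and the labeled pool approaches
it as

    A_i(t) = T_i * (1 - exp(-(lambda_i + gamma) * t)).

Introns are separate species with very large decay constants, so their
labeled pools equilibrate before the first time point and act as endogenous
standards. The cell population grows as exp(gamma*t); a labeled exogenous
spike-in is added at a constant mass fraction of the total extracted RNA, and
an unlabeled carrier (entering the purified library only through imperfect
purification) supports the enrichment QC. Sequencing is compositional: reads
are drawn as a fixed-depth multinomial over the purified library's
composition at each time point. With ``sampling=False`` the expected counts
are returned and purification is treated as perfect, giving the exact
deterministic core of the model.

Note that any ratio normalization (intron sum or spike-in) cancels the
population factor exp(gamma*t), so the normalized series approaches
equilibrium at rate lambda+gamma. The default truth therefore uses
``doubling_time=None`` (gamma=0, non-dividing conditions) so that intron-mode
fits, which apply no growth correction, recover lambda itself; growth enters
explicitly in designs that model dividing cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matrix import EXON_COUNT, INTRON_COVERAGE, AbundanceMatrix, GenomePartition

MAIN_GENOME = "main"
SPIKE_GENOME = "spike"
CARRIER_GENOME = "carrier"

RECALCITRANT_MODES = ("few_spikein_reads", "biased_spikein")

#: exponential drift rate (per hour) of the spike-in mass fraction used by
#: the "biased_spikein" recalcitrant mode: the spike-in share of the library
#: inflates through the course (e.g. progressive sample loss relative to the
#: standards), which deflates late time points of every normalized series and
#: skews long-lived transcripts — the signature of abnormal spike-in behavior.
BIASED_SPIKEIN_DRIFT = 0.15


@dataclass
class SimulationTruth:
    """Ground truth of one synthetic experiment.

    Rates are per hour; abundances are per-cell steady states in arbitrary
    units; ``spikein_fraction`` and ``carrier_fraction`` are mass fractions
    relative to total endogenous RNA (the experimental 20% w/w additions);
    ``carryover`` is the fraction of unlabeled material surviving
    purification (<1% nonspecific background).
    """

    gene_ids: list[str]
    synthesis: np.ndarray
    lam: np.ndarray
    intron_ids: list[str]
    intron_abundance: np.ndarray
    intron_lam: np.ndarray
    gamma: float = 0.0
    spikein_fraction: float = 0.2
    carrier_fraction: float = 0.2
    carryover: float = 0.01
    depth: int = 2_000_000
    seed: int = 0
    intron_length_divisor: float = 100.0

    @property
    def true_half_life(self) -> np.ndarray:
        return math.log(2) / self.lam

    def truth_table(self) -> pd.DataFrame:
        """gene_id, true_half_life_hours, synthesis_rate — written as truth.tsv."""
        return pd.DataFrame(
            {
                "true_half_life_hours": self.true_half_life,
                "synthesis_rate": self.synthesis,
                "lambda_per_hour": self.lam,
            },
            index=pd.Index(self.gene_ids, name="gene_id"),
        )


def make_truth(
    n_genes: int = 500,
    n_introns: int = 300,
    seed: int = 0,
    half_life_range: tuple[float, float] = (0.25, 36.0),
    synthesis_range: tuple[float, float] = (1.0, 20.0),
    intron_half_life_minutes: tuple[float, float] = (0.5, 2.0),
    intron_abundance_range: tuple[float, float] = (0.5, 5.0),
    misbehaving_fraction: float = 0.0,
    misbehaving_half_life_range: tuple[float, float] = (2.0, 24.0),
    doubling_time: float | None = None,
    depth: int = 2_000_000,
    **kwargs,
) -> SimulationTruth:
    """Draw a random ground truth.

    Gene decay constants are log-uniform over ``half_life_range`` (hours);
    synthesis rates log-uniform over ``synthesis_range``. Introns default to
    half-lives of 0.5-2 minutes so they fully equilibrate before t=1 h; a
    ``misbehaving_fraction`` of introns can instead be long-lived
    (retained/misannotated introns) to exercise cluster selection. Growth is
    off unless ``doubling_time`` (hours) is given.
    """
    rng = np.random.default_rng(seed)
    hl = np.exp(rng.uniform(*np.log(half_life_range), size=n_genes))
    lam = math.log(2) / hl
    synthesis = np.exp(rng.uniform(*np.log(synthesis_range), size=n_genes))

    intron_hl = rng.uniform(*intron_half_life_minutes, size=n_introns) / 60.0
    n_bad = int(round(misbehaving_fraction * n_introns))
    if n_bad:
        bad_idx = rng.choice(n_introns, size=n_bad, replace=False)
        intron_hl[bad_idx] = np.exp(
            rng.uniform(*np.log(misbehaving_half_life_range), size=n_bad)
        )
    intron_lam = math.log(2) / intron_hl
    intron_abundance = np.exp(rng.uniform(*np.log(intron_abundance_range), size=n_introns))

    gamma = math.log(2) / doubling_time if doubling_time else 0.0
    return SimulationTruth(
        gene_ids=[f"gene{i:04d}" for i in range(n_genes)],
        synthesis=synthesis,
        lam=lam,
        intron_ids=[f"intron{j:04d}" for j in range(n_introns)],
        intron_abundance=intron_abundance,
        intron_lam=intron_lam,
        gamma=gamma,
        depth=depth,
        seed=seed,
        **kwargs,
    )


@dataclass
class LabelingSimulation:
    exon_counts: AbundanceMatrix
    intron_coverage: AbundanceMatrix
    partition: GenomePartition  # purified library
    unpurified_partition: GenomePartition
    truth: SimulationTruth


def _labeled_weights(
    truth: SimulationTruth,
    t: np.ndarray,
    carryover: float,
    spike_distortion: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Expected composition weights (species x time) of the purified library
    and total endogenous mass, all including the population factor e^{gamma t}."""
    k_g = truth.lam + truth.gamma
    k_i = truth.intron_lam + truth.gamma
    t_gene = truth.synthesis / k_g
    growth = np.exp(truth.gamma * t)

    rise_g = 1.0 - np.exp(-np.outer(k_g, t))
    rise_i = 1.0 - np.exp(-np.outer(k_i, t))
    # labeled pool + unlabeled carryover, scaled to the growing population
    w_gene = growth * t_gene[:, None] * (rise_g + carryover * (1.0 - rise_g))
    w_intron = growth * truth.intron_abundance[:, None] * (rise_i + carryover * (1.0 - rise_i))

    mass = growth * (t_gene.sum() + truth.intron_abundance.sum())
    w_spike = truth.spikein_fraction * spike_distortion * mass  # fully labeled
    w_carrier = carryover * truth.carrier_fraction * mass  # unlabeled carrier
    return w_gene, w_intron, w_spike, w_carrier, mass


def _sample_columns(weights: np.ndarray, depth: int, rng, sampling: bool) -> np.ndarray:
    """Fixed-depth multinomial draw per column (time point) of a species x
    time weight matrix; expected counts when sampling is off."""
    p = weights / weights.sum(axis=0, keepdims=True)
    if not sampling:
        return depth * p
    out = np.empty_like(p)
    for m in range(p.shape[1]):
        out[:, m] = rng.multinomial(depth, p[:, m])
    return out


def simulate_labeling_experiment(
    truth: SimulationTruth,
    time_points=(1.0, 2.0, 4.0, 8.0, 12.0, 24.0),
    sampling: bool = True,
    spike_distortion: np.ndarray | None = None,
) -> LabelingSimulation:
    """Generate one approach-to-equilibrium experiment.

    With ``sampling=True``, reads at each time point are a fixed-depth
    multinomial over the purified library's composition (and purification
    retains ``truth.carryover`` of unlabeled material). With
    ``sampling=False`` expected counts are returned and purification is
    perfect — the deterministic generative core, which intron normalization
    plus bounded-growth fitting inverts exactly.
    """
    t = np.asarray(sorted(time_points), dtype=float)
    if len(t) < 3:
        raise ValueError("need >=3 time points")
    if t[0] <= 0:
        raise ValueError("labeling time points must be positive")
    rng = np.random.default_rng(truth.seed)
    carryover = truth.carryover if sampling else 0.0
    distortion = (
        np.ones_like(t) if spike_distortion is None else np.asarray(spike_distortion, float)
    )

    w_gene, w_intron, w_spike, w_carrier, mass = _labeled_weights(truth, t, carryover, distortion)
    stacked = np.vstack([w_gene, w_intron, w_spike[None, :], w_carrier[None, :]])
    counts = _sample_columns(stacked, truth.depth, rng, sampling)

    n_g, n_i = len(truth.gene_ids), len(truth.intron_ids)
    gene_counts = counts[:n_g]
    intron_counts = counts[n_g : n_g + n_i]
    spike_counts = counts[n_g + n_i]
    carrier_counts = counts[n_g + n_i + 1]

    exon = AbundanceMatrix(
        pd.DataFrame(gene_counts, index=truth.gene_ids, columns=t), kind=EXON_COUNT
    )
    intron = AbundanceMatrix(
        pd.DataFrame(
            intron_counts / truth.intron_length_divisor,
            index=truth.intron_ids,
            columns=t,
        ),
        kind=INTRON_COVERAGE,
    )
    partition = GenomePartition(
        pd.DataFrame(
            {
                MAIN_GENOME: gene_counts.sum(axis=0) + intron_counts.sum(axis=0),
                SPIKE_GENOME: spike_counts,
                CARRIER_GENOME: carrier_counts,
            },
            index=t,
        ).T
    )

    # unpurified (steady-state) library: everything sequenced before selection
    growth = np.exp(truth.gamma * t)
    t_gene = truth.synthesis / (truth.lam + truth.gamma)
    w_unpur = np.vstack(
        [
            t_gene[:, None] * growth,
            truth.intron_abundance[:, None] * growth,
            (truth.spikein_fraction * distortion * mass)[None, :],
            (truth.carrier_fraction * mass)[None, :],
        ]
    )
    counts_up = _sample_columns(w_unpur, truth.depth, rng, sampling)
    unpurified = GenomePartition(
        pd.DataFrame(
            {
                MAIN_GENOME: counts_up[: n_g + n_i].sum(axis=0),
                SPIKE_GENOME: counts_up[n_g + n_i],
                CARRIER_GENOME: counts_up[n_g + n_i + 1],
            },
            index=t,
        ).T
    )
    return LabelingSimulation(exon, intron, partition, unpurified, truth)


@dataclass
class ShutoffSimulation:
    exon_counts: AbundanceMatrix
    partition: GenomePartition
    truth: SimulationTruth


def simulate_shutoff_experiment(
    truth: SimulationTruth,
    time_points=(0.0, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0),
    sampling: bool = True,
) -> ShutoffSimulation:
    """Generate a transcription-shutoff decay course.

    After shutoff each pool decays as ``T_i * exp(-lambda_i t)`` (growth is
    arrested). A spike-in of constant absolute amount per sample is included,
    so dividing by the spike factor converts compositional counts back to
    absolute decay curves.
    """
    t = np.asarray(sorted(time_points), dtype=float)
    if len(t) < 3:
        raise ValueError("need >=3 time points")
    rng = np.random.default_rng(truth.seed + 1)
    t_gene = truth.synthesis / np.maximum(truth.lam, 1e-12)
    w_gene = t_gene[:, None] * np.exp(-np.outer(truth.lam, t))
    w_spike = np.full_like(t, truth.spikein_fraction * t_gene.sum())
    stacked = np.vstack([w_gene, w_spike[None, :]])
    counts = _sample_columns(stacked, truth.depth, rng, sampling)
    exon = AbundanceMatrix(
        pd.DataFrame(counts[: len(truth.gene_ids)], index=truth.gene_ids, columns=t),
        kind=EXON_COUNT,
    )
    partition = GenomePartition(
        pd.DataFrame(
            {MAIN_GENOME: counts[: len(truth.gene_ids)].sum(axis=0), SPIKE_GENOME: counts[-1]},
            index=t,
        ).T
    )
    return ShutoffSimulation(exon, partition, truth)


def simulate_recalcitrant(
    truth: SimulationTruth,
    time_points=(1.0, 2.0, 4.0, 8.0, 12.0, 24.0),
    mode: str = "few_spikein_reads",
    sampling: bool = True,
) -> LabelingSimulation:
    """Generate a labeling experiment whose spike-ins are unusable.

    ``few_spikein_reads`` scales the spike-in mass fraction down 100x (too
    few reads for a stable factor); ``biased_spikein`` multiplies the
    spike-in fraction by the time-dependent drift exp(BIASED_SPIKEIN_DRIFT*t).
    Endogenous intron signal is untouched in both modes, so intron
    normalization still works.
    """
    t = np.asarray(sorted(time_points), dtype=float)
    if mode == "few_spikein_reads":
        degraded = replace(truth, spikein_fraction=truth.spikein_fraction / 100.0)
        return simulate_labeling_experiment(degraded, t, sampling=sampling)
    if mode == "biased_spikein":
        distortion = np.exp(BIASED_SPIKEIN_DRIFT * t)
        return simulate_labeling_experiment(truth, t, sampling=sampling, spike_distortion=distortion)
    raise ValueError(f"mode must be one of {RECALCITRANT_MODES}, got {mode!r}")


ARCHETYPES = ("decreasing", "flat", "increasing", "hump")


def simulate_intron_archetypes(
    time_points=(1.0, 2.0, 4.0, 8.0, 12.0, 24.0),
    n_per_archetype: int = 50,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[AbundanceMatrix, pd.Series]:
    """Intron profiles drawn from four shape archetypes (decreasing, flat,
    increasing, hump) with per-intron magnitudes and small Gaussian noise —
    the controlled input for testing k-means cluster selection. Returns the
    coverage matrix and the true archetype of each intron."""
    t = np.asarray(sorted(time_points), dtype=float)
    n_t = len(t)
    x = np.linspace(0.0, 1.0, n_t)
    shapes = {
        "decreasing": np.linspace(2.0, 0.5, n_t),
        "flat": np.full(n_t, 1.25),
        "increasing": np.linspace(0.5, 2.0, n_t),
        "hump": 0.5 + 1.5 * np.sin(math.pi * x),
    }
    rng = np.random.default_rng(seed)
    rows, ids, members = [], [], []
    for name in ARCHETYPES:
        base = shapes[name]
        for j in range(n_per_archetype):
            mag = np.exp(rng.normal(0.0, 0.5))
            profile = np.maximum(mag * base * (1.0 + rng.normal(0.0, noise_sd, n_t)), 0.0)
            rows.append(profile)
            ids.append(f"{name}{j:03d}")
            members.append(name)
    cov = AbundanceMatrix(
        pd.DataFrame(np.array(rows), index=ids, columns=t), kind=INTRON_COVERAGE
    )
    return cov, pd.Series(members, index=ids, name="archetype")
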