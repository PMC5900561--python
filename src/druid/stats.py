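"""Replicate- and method-comparison statistics for half-life tables.

Rank agreement between tables is summarized by Spearman correlation;
magnitude agreement by Pearson correlation on log10 half-lives (half-life
distributions are heavy-tailed). Two correlations are compared with Fisher's
r-to-z test. Note the r-to-z test is formally defined for Pearson r; applying
it to Spearman coefficients reproduces the field's common (approximate)
practice, and a warning is emitted when requested.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class CorrelationComparison:
    r1: float
    r2: float
    n1: int
    n2: int
    z: float
    p: float


@dataclass
class TableComparison:
    n_shared: int
    spearman: float
    pearson_log: float
    joined: pd.DataFrame


def compare_half_life_tables(
    a: pd.DataFrame,
    b: pd.DataFrame,
    column: str = "half_life_hours",
    log_pearson: bool = True,
) -> TableComparison:
    """Inner-join two half-life tables on gene id and correlate.

    Returns Spearman on half-lives and Pearson on log10 half-lives (or
    linear values with ``log_pearson=False``). Requires >=4 shared genes with
    finite values.
    """
    xa = a[column] if column in a.columns else a.iloc[:, 0]
    xb = b[column] if column in b.columns else b.iloc[:, 0]
    joined = pd.concat({"a": xa, "b": xb}, axis=1, join="inner").dropna()
    if len(joined) < 4:
        raise ValueError(f"only {len(joined)} shared genes; need >=4")
    rs = sps.spearmanr(joined["a"], joined["b"]).statistic
    if log_pearson:
        rp = sps.pearsonr(np.log10(joined["a"]), np.log10(joined["b"])).statistic
    else:
        rp = sps.pearsonr(joined["a"], joined["b"]).statistic
    return TableComparison(len(joined), float(rs), float(rp), joined)


def fisher_r_to_z(
    r1: float, n1: int, r2: float, n2: int, warn_spearman: bool = False
) -> CorrelationComparison:
    """Two-sided Fisher r-to-z test for the difference of two correlations.

    ``z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))`` with a
    standard-normal two-sided p-value.
    """
    for r in (r1, r2):
        if not -1 < r < 1:
            raise ValueError(f"correlation {r} outside (-1, 1): transform undefined")
    for n in (n1, n2):
        if n < 4:
            raise ValueError(f"sample size {n} < 4")
    if warn_spearman:
        warnings.warn(
            "Fisher r-to-z is defined for Pearson correlations; applying it "
            "to Spearman coefficients is approximate"
        )
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = 2 * sps.norm.sf(abs(z))
    return CorrelationComparison(r1=r1, r2=r2, n1=n1, n2=n2, z=float(z), p=float(p))
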