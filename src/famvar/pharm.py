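"""Receptor/odorant screen statistics and odor-response scoring.

Screens record a log10 molar EC50 for positive receptor-odorant pairs
(bounded below by -9, i.e. 1 nM, the strongest potency represented) and a
missing value for negatives. Potency-weighted counting uses
``weight = -log10(EC50) / 9`` so the strongest response weighs 1 and a
threshold-level response weighs 0.

Per conserved alignment column, receptors are split by canonical vs.
non-canonical residue status and their positive rates are compared: the
fold enrichment is the ratio of positive rates, and significance is the
lower hypergeometric tail — the probability of seeing this many or fewer
positives among the non-canonical screens if positives were distributed
without regard to residue status.

Individual odor responses average per-allele contributions over every
receptor binding the odorant: a functional allele contributes the potency
weight, a loss-of-function allele (conserved-arginine missense, stop-gain
or frameshift) contributes zero, so heterozygous loss halves and
homozygous loss silences a receptor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from famvar.mapping import CANONICAL, NON_CANONICAL

__all__ = [
    "ec50_weight",
    "ActivityStats",
    "position_activity_stats",
    "ReceptorActivityModel",
    "ReceptorActivityResults",
    "individual_odor_response",
    "cohort_odor_responses",
    "population_odor_matrix",
]

#: strongest log10 molar EC50 represented; sets the weight scale
EC50_FLOOR = -9.0


def ec50_weight(log10_ec50: float | None) -> float:
    """Potency weight in [0, 1]; absent (negative screen) weighs 0."""
    if log10_ec50 is None or (isinstance(log10_ec50, float)
                              and np.isnan(log10_ec50)):
        return 0.0
    return float(np.clip(-log10_ec50 / -EC50_FLOOR, 0.0, 1.0))


@dataclass
class ActivityStats:
    """Canonical vs non-canonical contingency at one alignment column."""

    column: int
    n_canonical_screens: int
    n_canonical_positive: int
    n_noncanonical_screens: int
    n_noncanonical_positive: int
    weighted_canonical: float
    weighted_noncanonical: float
    fold_enrichment: float
    hypergeom_p: float

    @property
    def canonical_rate(self) -> float:
        return self.n_canonical_positive / self.n_canonical_screens

    @property
    def noncanonical_rate(self) -> float:
        return self.n_noncanonical_positive / self.n_noncanonical_screens


def _fold(rate_can: float, rate_non: float) -> float:
    if rate_non == 0:
        return float("inf") if rate_can > 0 else float("nan")
    return rate_can / rate_non


def position_activity_stats(screen: pd.DataFrame, status: dict[str, str],
                            column: int = 0,
                            weighted: bool = False) -> ActivityStats:
    """Contingency statistics for one column's canonical split.

    ``status`` maps receptor id to "canonical" / "non_canonical" (anything
    else, e.g. unknown, is dropped). ``hypergeom_p`` is the lower tail
    P(X <= k_noncanonical_positive) for X hypergeometric with population =
    all screens, successes = all positives, draws = non-canonical screens;
    it is always computed from unweighted counts. With ``weighted`` the
    fold enrichment uses potency-weighted positive sums instead of counts.
    """
    known = screen[screen["receptor"].map(status).isin(
        [CANONICAL, NON_CANONICAL])].copy()
    is_canon = known["receptor"].map(status) == CANONICAL
    positive = known["log10_ec50"].notna()
    weights = known["log10_ec50"].map(ec50_weight)

    n_can = int(is_canon.sum())
    n_non = int((~is_canon).sum())
    if n_can == 0 or n_non == 0:
        raise ValueError("need screens in both canonical groups")
    k_can = int((positive & is_canon).sum())
    k_non = int((positive & ~is_canon).sum())
    w_can = float(weights[is_canon].sum())
    w_non = float(weights[~is_canon].sum())

    if weighted:
        fold = _fold(w_can / n_can, w_non / n_non)
    else:
        fold = _fold(k_can / n_can, k_non / n_non)
    p = float(stats.hypergeom.cdf(k_non, n_can + n_non, k_can + k_non, n_non))
    return ActivityStats(column, n_can, k_can, n_non, k_non, w_can, w_non,
                         fold, p)


class ReceptorActivityModel:
    """Screen activity split by residue status at conserved columns.

    Parameters
    ----------
    screen : pandas.DataFrame
        Columns ``receptor``, ``odorant``, ``log10_ec50`` (NaN = negative).
    status_table : pandas.DataFrame
        Receptors x columns matrix of "canonical"/"non_canonical"/"unknown"
        strings, e.g. from :func:`famvar.mapping.canonical_status_table`.
    """

    def __init__(self, screen: pd.DataFrame, status_table: pd.DataFrame):
        self.screen = screen
        self.status_table = status_table

    def fit(self, weighted: bool = False) -> "ReceptorActivityResults":
        stats_by_col = {}
        for col in self.status_table.columns:
            status = self.status_table[col].to_dict()
            stats_by_col[col] = position_activity_stats(
                self.screen, status, column=int(col), weighted=weighted
            )
        return ReceptorActivityResults(self, stats_by_col)


class ReceptorActivityResults:
    """Per-column activity contingency statistics."""

    def __init__(self, model: ReceptorActivityModel,
                 stats_by_column: dict[int, ActivityStats]):
        self.model = model
        self.stats_by_column = stats_by_column

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for col, s in sorted(self.stats_by_column.items()):
            rows.append({
                "column": col,
                "n_canonical_screens": s.n_canonical_screens,
                "n_canonical_positive": s.n_canonical_positive,
                "n_noncanonical_screens": s.n_noncanonical_screens,
                "n_noncanonical_positive": s.n_noncanonical_positive,
                "weighted_canonical": s.weighted_canonical,
                "weighted_noncanonical": s.weighted_noncanonical,
                "fold_enrichment": s.fold_enrichment,
                "hypergeom_p": s.hypergeom_p,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        t = self.table
        lines = ["Receptor activity by residue status", "=" * 60]
        lines.append(t.to_string(index=False,
                                 float_format=lambda x: f"{x:.4g}"))
        return "\n".join(lines)


def individual_odor_response(lof_dosage: dict[str, int],
                             screen: pd.DataFrame) -> pd.Series:
    """Mean per-allele potency response of one individual to each odorant.

    ``lof_dosage`` maps receptor id to the individual's loss-of-function
    allele count (0 functional, 1 heterozygous, 2 homozygous). For each
    odorant, every (binding receptor, allele copy) pair contributes the
    receptor's potency weight if the allele is functional and 0 otherwise;
    the response is the mean contribution. Odorants with no binding
    receptor in the screen are NaN.
    """
    positives = screen[screen["log10_ec50"].notna()]
    out = {}
    for odorant in screen["odorant"].unique():
        binders = positives[positives["odorant"] == odorant]
        if binders.empty:
            out[odorant] = float("nan")
            continue
        total = 0.0
        n_pairs = 0
        for _, row in binders.iterrows():
            w = ec50_weight(row["log10_ec50"])
            lof = int(lof_dosage.get(row["receptor"], 0))
            total += w * (2 - lof)
            n_pairs += 2
        out[odorant] = total / n_pairs
    return pd.Series(out)


def cohort_odor_responses(lof_dosage_matrix: pd.DataFrame,
                          screen: pd.DataFrame) -> pd.DataFrame:
    """Individuals x odorants response matrix.

    ``lof_dosage_matrix`` is individuals (rows) x receptors (columns) of
    loss-of-function allele counts; receptors absent from the matrix are
    taken as fully functional.
    """
    positives = screen[screen["log10_ec50"].notna()]
    odorants = list(screen["odorant"].unique())
    n_ind = len(lof_dosage_matrix)
    out = np.full((n_ind, len(odorants)), np.nan)
    for j, odorant in enumerate(odorants):
        binders = positives[positives["odorant"] == odorant]
        if binders.empty:
            continue
        weights = binders["log10_ec50"].map(ec50_weight).to_numpy()
        dosage = np.zeros((n_ind, len(binders)))
        for k, rec in enumerate(binders["receptor"]):
            if rec in lof_dosage_matrix.columns:
                dosage[:, k] = lof_dosage_matrix[rec].to_numpy()
        contrib = weights[None, :] * (2 - dosage)
        out[:, j] = contrib.sum(axis=1) / (2 * len(binders))
    return pd.DataFrame(out, index=lof_dosage_matrix.index, columns=odorants)


def population_odor_matrix(responses: pd.DataFrame,
                           groups: pd.Series) -> pd.DataFrame:
    """Group-mean responses normalised per odorant by the maximum group.

    ``responses`` is individuals x odorants; ``groups`` assigns each
    individual (by index) a population label. Each odorant's group means
    are divided by their maximum, so the most responsive group scores 1
    unless every group scores 0.
    """
    means = responses.groupby(groups).mean()
    maxima = means.max(axis=0)
    scale = maxima.replace(0, np.nan)
    out = means.div(scale, axis=1)
    return out.fillna(means * 0.0)
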