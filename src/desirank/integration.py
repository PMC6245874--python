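"""Within-study and cross-study integration of desirability scores.

Variables are combined into a per-study composite d_study with a weighted
arithmetic mean (not the classical geometric/product desirability form:
the arithmetic mean keeps genes with a zero on one variable in the
analysis).  Study composites are then combined into d_overall with a
penalty for missingness: a gene observed in n_present studies and missing
from n_missing gets

    d_overall = weighted_mean(d_study over present) / (n_missing + 1)

so a gene with a perfect score of 1 in one study of K but absent from the
other K-1 scores exactly 1/K.  That value, ``soft_cutoff(K)``, is the
lower bound of the "desirable" set: any gene at or above it carries at
least as much cumulative evidence as a single-study perfect hit.

Two alternative normalisations are kept for comparison: ``literal_eq5``
divides the weighted sum by K*(n_missing+1) with K the total number of
studies, and ``raw_mean`` applies no missingness penalty at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "DesirabilityMatrix",
    "integrate_variables",
    "integrate_studies",
    "soft_cutoff",
    "rank_genes",
    "percentile_ranks",
]

INTEGRATION_MODES = ("normalized", "literal_eq5", "raw_mean")


class ConfigError(ValueError):
    """Invalid integration configuration (weights, modes, empty inputs)."""


@dataclass
class DesirabilityMatrix:
    """Genes x studies grid of within-study composite desirabilities.

    ``d_study`` is a float DataFrame indexed by gene_id with one column per
    study; NaN marks a gene missing from a study.  ``weights`` holds the
    per-study weights (default 1).
    """

    d_study: pd.DataFrame
    weights: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.weights is None:
            self.weights = pd.Series(1.0, index=self.d_study.columns)
        self.weights = self.weights.reindex(self.d_study.columns).astype(float)
        if self.weights.isna().any():
            raise ConfigError("every study needs a weight")
        if (self.weights < 0).any():
            raise ConfigError("study weights must be non-negative")
        vals = self.d_study.to_numpy(dtype=float)
        present = ~np.isnan(vals)
        if np.nanmin(vals, initial=0.0, where=present) < -1e-12 or np.nanmax(
            vals, initial=1.0, where=present
        ) > 1 + 1e-12:
            raise ValueError("d_study entries must lie in [0, 1]")

    @property
    def n_studies(self) -> int:
        return self.d_study.shape[1]


def integrate_variables(
    desirabilities: pd.DataFrame, weights=None
) -> pd.Series:
    """Weighted arithmetic mean of variable desirabilities per gene (d_study).

    Parameters
    ----------
    desirabilities
        Genes x variables frame of desirability scores in [0, 1], NaN for
        missing observations.
    weights
        Per-variable non-negative weights (sequence or Series aligned to the
        columns); default all 1.  Weights are renormalised per gene over the
        variables with data, which reduces to the plain arithmetic mean
        ``sum(w_i d_i)/N`` when all weights are 1 and all variables present.

    Returns
    -------
    pandas.Series
        d_study per gene; genes missing every variable are dropped.
    """
    if weights is None:
        w = pd.Series(1.0, index=desirabilities.columns)
    elif isinstance(weights, pd.Series):
        w = weights.reindex(desirabilities.columns).astype(float)
    else:
        w = pd.Series(np.asarray(weights, dtype=float), index=desirabilities.columns)
    if w.isna().any() or (w < 0).any():
        raise ConfigError("variable weights must be non-negative and complete")
    if not (w > 0).any():
        raise ConfigError("at least one variable weight must be positive")

    vals = desirabilities.to_numpy(dtype=float)
    wv = w.to_numpy()
    present = ~np.isnan(vals)
    wsum = present @ wv
    num = np.nansum(vals * wv, axis=1)
    with np.errstate(invalid="ignore"):
        d_study = num / wsum
    out = pd.Series(d_study, index=desirabilities.index, name="d_study")
    return out[wsum > 0]


def soft_cutoff(n_studies: int) -> float:
    """Desirability attained by a perfect single-study gene among K studies.

    Equals 1/K under the default missingness normalisation; genes scoring
    at or above it are called "desirable".
    """
    if n_studies < 1:
        raise ConfigError(f"need at least one study, got {n_studies}")
    return 1.0 / n_studies


def integrate_studies(
    matrix: DesirabilityMatrix, mode: str = "normalized"
) -> pd.DataFrame:
    """Combine per-study composites into a single d_overall per gene.

    Modes
    -----
    ``normalized`` (default)
        Weighted mean of the present d_study values divided by
        (n_missing + 1).  Study weights are renormalised per gene so their
        mean over the present studies is 1; a fully observed gene therefore
        scores its plain weighted mean, and a single-study perfect gene
        among K studies scores exactly 1/K.
    ``literal_eq5``
        Weighted sum divided by K*(n_missing + 1), K = total studies.
    ``raw_mean``
        Weighted mean of present studies, no missingness penalty.

    Returns a frame indexed by gene_id with columns ``d_overall_raw``
    (the pre-penalty weighted mean), ``d_overall``, ``n_present``,
    ``n_missing``, ``rank`` (dense, 1 = most desirable) and ``desirable``
    (d_overall >= soft_cutoff(K)).
    """
    if mode not in INTEGRATION_MODES:
        raise ConfigError(f"unknown integration mode {mode!r}")
    df = matrix.d_study
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ConfigError("empty desirability matrix")
    vals = df.to_numpy(dtype=float)
    wv = matrix.weights.to_numpy()
    present = ~np.isnan(vals)
    n_present = present.sum(axis=1)
    if (n_present == 0).any():
        raise ValueError("every gene must have data in at least one study")
    n_missing = df.shape[1] - n_present

    wsum = present @ wv
    wdsum = np.nansum(vals * wv, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = wdsum / wsum  # weighted mean over present studies
    if mode == "normalized":
        d_overall = raw / (n_missing + 1)
    elif mode == "literal_eq5":
        d_overall = wdsum / (df.shape[1] * (n_missing + 1))
    else:  # raw_mean
        d_overall = raw

    out = pd.DataFrame(
        {
            "d_overall_raw": raw,
            "d_overall": d_overall,
            "n_present": n_present,
            "n_missing": n_missing,
        },
        index=df.index.rename("gene_id"),
    )
    out["desirable"] = out["d_overall"] >= soft_cutoff(df.shape[1])
    return rank_genes(out)


def rank_genes(result: pd.DataFrame) -> pd.DataFrame:
    """Dense-rank genes by descending d_overall (1 = most desirable).

    Ties share a rank; the returned frame is sorted by (rank, gene_id) so
    listings are deterministic.
    """
    ranks = result["d_overall"].rank(method="dense", ascending=False)
    out = result.copy()
    out["rank"] = ranks.astype(int)
    # stable double sort: lexicographic gene_id breaks ties within a rank
    return out.sort_index(kind="mergesort").sort_values("rank", kind="mergesort")


def percentile_ranks(d_study: pd.DataFrame) -> pd.DataFrame:
    """Within-study percentile of each gene's d_study, from unique ranks.

    For each study the present values get dense ranks (descending) and
    percentile ``100 * (1 - (rank - 1)/n_unique)``: the top unique value
    maps to 100, ties share percentiles, and the grid spans (0, 100].
    Missing entries stay missing.
    """
    out = {}
    for col in d_study.columns:
        s = d_study[col]
        r = s.rank(method="dense", ascending=False)
        n_unique = s.nunique(dropna=True)
        out[col] = 100.0 * (1.0 - (r - 1.0) / n_unique) if n_unique else s
    return pd.DataFrame(out, index=d_study.index)
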