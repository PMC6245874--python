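"""Permutation null for overall desirability, and the hard-threshold baseline.

The permutation null asks what mean overall desirability would look like if
study-level scores bore no relation to gene identity: each study's column of
d_study values (missing cells included) is shuffled across the full gene
list, d_overall is recomputed, and the mean over genes is recorded.  Per-
study score distributions are preserved exactly; only the pairing of scores
(and missingness) with genes is broken.  With complete data the mean of
d_overall is a grand mean invariant under column shuffles, so the null is
degenerate at the observed value — the interesting regime is when high
scores co-occur with low missingness, which drags the null mean below the
observed one.

The hard-threshold baseline ("HardThresh") is the conventional practice the
desirability framework is an alternative to: dichotomise each study at a
significance cutoff (adjusted P < 0.1, else unadjusted P < 0.05) and
intersect the resulting significant-gene lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .integration import ConfigError, DesirabilityMatrix, INTEGRATION_MODES

__all__ = [
    "NullDistribution",
    "permutation_null",
    "hard_threshold",
    "intersection_counts",
]


@dataclass
class NullDistribution:
    """Permutation replicate means of d_overall and their summary."""

    n_permutations: int
    replicate_means: np.ndarray
    seed: int
    mean: float
    ci_low: float   # empirical 2.5th percentile
    ci_high: float  # empirical 97.5th percentile

    def summary(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "mean": self.mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


def permutation_null(
    matrix: DesirabilityMatrix,
    n_permutations: int = 1000,
    seed: int = 0,
    mode: str = "normalized",
) -> NullDistribution:
    """Null distribution of mean d_overall under within-study shuffling.

    Each replicate independently permutes every study column (values and
    missing cells together) over the whole gene list, recomputes d_overall
    for all genes under ``mode``, and records the mean over genes with at
    least one present study.  Per-replicate RNG substreams are derived
    deterministically from ``seed``, so results are reproducible and
    independent of replicate order.
    """
    if n_permutations < 1:
        raise ConfigError("need at least one permutation")
    if mode not in INTEGRATION_MODES:
        raise ConfigError(f"unknown integration mode {mode!r}")
    vals = matrix.d_study.to_numpy(dtype=float)
    n_genes, n_studies = vals.shape
    if n_genes == 0 or n_studies == 0:
        raise ConfigError("empty desirability matrix")
    wv = matrix.weights.to_numpy()

    streams = np.random.SeedSequence(seed).spawn(n_permutations)
    means = np.empty(n_permutations)
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        perm = np.empty_like(vals)
        for j in range(n_studies):
            perm[:, j] = vals[rng.permutation(n_genes), j]
        present = ~np.isnan(perm)
        wsum = present @ wv
        wdsum = np.nansum(perm * wv, axis=1)
        n_present = present.sum(axis=1)
        n_missing = n_studies - n_present
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = wdsum / wsum
            if mode == "normalized":
                d_overall = raw / (n_missing + 1)
            elif mode == "literal_eq5":
                d_overall = wdsum / (n_studies * (n_missing + 1))
            else:
                d_overall = raw
        # a shuffle can leave a gene with no data; it drops from the mean
        means[r] = np.nanmean(d_overall)

    return NullDistribution(
        n_permutations=n_permutations,
        replicate_means=means,
        seed=seed,
        mean=float(means.mean()),
        ci_low=float(np.percentile(means, 2.5)),
        ci_high=float(np.percentile(means, 97.5)),
    )


def hard_threshold(
    studies,
    adj_p_cut: float = 0.1,
    raw_p_cut: float = 0.05,
) -> pd.DataFrame:
    """Dichotomise each study at a significance cutoff.

    Parameters
    ----------
    studies
        Iterable of :class:`~desirank.io.StudyTable`; each must name an
        adjusted and/or unadjusted P-value variable (``p_adjusted`` /
        ``p_unadjusted``).  When both exist the adjusted rule is applied.
    adj_p_cut, raw_p_cut
        Strict thresholds: adjusted P < 0.1, unadjusted P < 0.05.

    Returns
    -------
    pandas.DataFrame
        Genes x studies grid with nullable-boolean significance calls (pd.NA
        where the gene is missing from the study) plus an ``n_significant``
        column counting significant studies per gene.
    """
    cols = {}
    for st in studies:
        var = st.p_adjusted or st.p_unadjusted
        if var is None or var not in st.data.columns:
            raise ConfigError(
                f"study {st.study_id!r}: no adjusted or unadjusted P-value "
                "variable configured for hard thresholding"
            )
        cut = adj_p_cut if st.p_adjusted else raw_p_cut
        p = st.data[var].astype(float)
        sig = pd.Series(pd.NA, index=p.index, dtype="boolean")
        obs = p.notna()
        sig[obs] = p[obs] < cut
        cols[st.study_id] = sig
    out = pd.DataFrame(cols)
    out.index.name = "gene_id"
    out = out.sort_index()
    out["n_significant"] = (
        out.fillna(False).astype(bool).sum(axis=1).astype(int)
    )
    return out


def intersection_counts(sig: pd.DataFrame) -> pd.DataFrame:
    """Tabulate how many genes are significant in exactly k studies.

    Returns one row per intersection level k = 0..K with the gene count and
    a comma-joined, sorted membership list (empty string at level 0 and any
    empty level).
    """
    counts = sig["n_significant"]
    k_max = sig.shape[1] - 1  # minus the n_significant column
    rows = []
    for k in range(k_max + 1):
        members = sorted(counts.index[counts == k])
        rows.append(
            {
                "n_studies_significant": k,
                "n_genes": len(members),
                "genes": ",".join(str(m) for m in members),
            }
        )
    return pd.DataFrame(rows)
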