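import numpy as np
import pandas as pd
import pytest

from desirank import DesirabilityMatrix


def scalar_d_low(y, a, b, s):
    """Pointwise piecewise reference for the small-is-desirable transform."""
    if not np.isfinite(y):
        return float("nan")
    if y < a:
        return 1.0
    if y > b:
        return 0.0
    return ((y - b) / (a - b)) ** s


def scalar_d_high(y, a, b, s):
    if not np.isfinite(y):
        return float("nan")
    if y < a:
        return 0.0
    if y > b:
        return 1.0
    return ((y - a) / (b - a)) ** s


def scalar_d_extreme(y, b_lo, a_lo, a_hi, b_hi, s):
    if not np.isfinite(y):
        return float("nan")
    if y <= b_lo or y >= b_hi:
        return 1.0
    if a_lo <= y <= a_hi:
        return 0.0
    if y < a_lo:
        return scalar_d_low(y, b_lo, a_lo, s)
    return scalar_d_high(y, a_hi, b_hi, s)


def scalar_d_target(y, a, c, b, s):
    if not np.isfinite(y):
        return float("nan")
    if y < a or y > b:
        return 0.0
    if y <= c:
        return ((y - a) / (c - a)) ** s
    return ((y - b) / (c - b)) ** s


def scalar_integrate(d_study_row, weights, n_studies, mode="normalized"):
    """Per-gene scalar reference for cross-study integration."""
    pairs = [(d, w) for d, w in zip(d_study_row, weights) if not np.isnan(d)]
    if not pairs:
        return float("nan")
    n_present = len(pairs)
    n_missing = n_studies - n_present
    wsum = sum(w for _, w in pairs)
    wdsum = sum(d * w for d, w in pairs)
    if mode == "normalized":
        return (wdsum / wsum) / (n_missing + 1)
    if mode == "literal_eq5":
        return wdsum / (n_studies * (n_missing + 1))
    return wdsum / wsum


def random_matrix(rng, max_genes=20, max_studies=6, p_missing=0.3):
    """A small random desirability matrix with every gene observed somewhere."""
    n_genes = rng.integers(2, max_genes + 1)
    n_studies = rng.integers(1, max_studies + 1)
    vals = rng.random((n_genes, n_studies))
    mask = rng.random((n_genes, n_studies)) < p_missing
    # guarantee at least one present entry per gene
    for i in range(n_genes):
        if mask[i].all():
            mask[i, rng.integers(n_studies)] = False
    vals[mask] = np.nan
    genes = [f"g{i:03d}" for i in range(n_genes)]
    cols = [f"s{j}" for j in range(n_studies)]
    weights = pd.Series(rng.uniform(0.2, 2.0, n_studies), index=cols)
    return DesirabilityMatrix(pd.DataFrame(vals, index=genes, columns=cols), weights)


@pytest.fixture
def toy_matrix():
    """Hand-checkable 4-gene x 3-study grid with missingness."""
    d = pd.DataFrame(
        {
            "s1": [1.0, 0.6, np.nan, 0.2],
            "s2": [0.8, 0.6, np.nan, np.nan],
            "s3": [0.9, 0.6, 1.0, np.nan],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
    )
    return DesirabilityMatrix(d)
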