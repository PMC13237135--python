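"""Label-free proteomics statistics: filter, impute, test.

The workflow mirrors the standard Perseus treatment of MaxQuant LFQ
intensities:

1. log2-transform and drop proteins missing in more than ``max_missing``
   samples (default 3, counted across all samples);
2. replace remaining missing values with draws from a down-shifted normal
   per sample column — mean shifted down by ``downshift`` and spread
   narrowed to ``width``, both expressed as multiples of that sample's
   observed SD (defaults 1.8 and 0.3) — so imputed values land in the
   low-intensity tail where undetected proteins are expected;
3. per-protein two-sample Student t tests (pooled variance) between
   groups, significant iff |log2 fold-change| > 1.5 and p < 0.05, with no
   multiple-testing correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MAX_MISSING = 3
DEFAULT_WIDTH = 0.3
DEFAULT_DOWNSHIFT = 1.8
DEFAULT_FC_THRESHOLD = 1.5
DEFAULT_ALPHA = 0.05


def preprocess(
    intensities: pd.DataFrame, max_missing: int = DEFAULT_MAX_MISSING
) -> pd.DataFrame:
    """log2-transform and filter by missingness.

    ``intensities`` is proteins x samples with NaN for missing.  Proteins
    missing in strictly more than ``max_missing`` samples are removed
    (exactly ``max_missing`` missing is retained).
    """
    if (intensities <= 0).any().any():
        raise ValueError("intensities must be positive where present")
    n_missing = intensities.isna().sum(axis=1)
    kept = intensities[n_missing <= max_missing]
    if kept.empty:
        raise ValueError("no proteins left after the missingness filter")
    return np.log2(kept)


def impute(
    log2_matrix: pd.DataFrame,
    width: float = DEFAULT_WIDTH,
    downshift: float = DEFAULT_DOWNSHIFT,
    seed: int = 0,
    mode: str = "sd_multiple",
) -> pd.DataFrame:
    """Down-shifted normal imputation of missing log2 intensities.

    Per sample column with observed mean ``mu`` and SD ``sigma`` (sample
    SD), missing entries are drawn from ``Normal(mu - downshift * sigma,
    (width * sigma)^2)`` (``mode="sd_multiple"``, the Perseus convention)
    or ``Normal(mu - downshift, width^2)`` with absolute log2 units
    (``mode="absolute"``).  Observed entries are never altered; output is
    deterministic given ``seed``.
    """
    if mode not in ("sd_multiple", "absolute"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    out = log2_matrix.copy()
    for col in out.columns:
        observed = out[col].dropna()
        if len(observed) < 2:
            raise ValueError(
                f"sample {col!r} has fewer than two observed values; "
                "cannot estimate its intensity distribution"
            )
        n_missing = int(out[col].isna().sum())
        if n_missing == 0:
            continue
        mu, sigma = observed.mean(), observed.std(ddof=1)
        if mode == "sd_multiple":
            loc, scale = mu - downshift * sigma, width * sigma
        else:
            loc, scale = mu - downshift, width
        draws = loc + scale * rng.standard_normal(n_missing)
        out.loc[out[col].isna(), col] = draws
    return out


def differential(
    matrix: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-protein two-sample t test between sample groups.

    ``l2fc = mean(group_a) - mean(group_b)`` in log2 space.  The default
    is the Student (pooled-variance) test; ``equal_var=False`` switches to
    Welch.  A protein is ``significant`` iff ``|l2fc| > fc_threshold`` and
    ``p < alpha`` (no multiple-testing correction).  Proteins with zero
    variance in both groups have no defined p value and carry the
    ``degenerate`` flag instead.
    """
    for cols, name in ((group_a, "group_a"), (group_b, "group_b")):
        if len(cols) < 2:
            raise ValueError(f"{name} needs at least two samples")
        missing = set(cols) - set(matrix.columns)
        if missing:
            raise ValueError(f"{name} columns not in matrix: {sorted(missing)}")
    a = matrix[group_a].to_numpy(dtype=float)
    b = matrix[group_b].to_numpy(dtype=float)
    l2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p = np.where(degenerate, np.nan, p)
    t = np.where(degenerate, np.nan, t)
    significant = (np.abs(l2fc) > fc_threshold) & (p < alpha)
    significant = np.where(np.isnan(p), False, significant)
    return pd.DataFrame(
        {
            "l2fc": l2fc,
            "t": t,
            "p": p,
            "significant": significant.astype(bool),
            "degenerate": degenerate,
        },
        index=matrix.index,
    )
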