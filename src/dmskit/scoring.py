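"""Functional scoring of deep-mutational-scanning screens.

The central statistic is a rolling silent-baseline z-score.  For each
variant the log2 fold-change (L2FC) of its read abundance between the end
and start of selection is compared with the L2FC distribution of silent
(synonymous) variants in a +/-2-codon window around its position:

    z = (L2FC_variant - rolling_mean_silents) / rolling_sd_silents

computed per replicate and then averaged across replicates.  Because the
baseline is local, block-constant regional artifacts in L2FC cancel
exactly, and the score is invariant under any global positive affine
transform of the L2FC scale.  Variants whose cross-replicate mean z exceeds
a threshold (default 2, the two-sided normal p < 0.0455 point) are called
loss-of-function: they enriched relative to their silent neighbours, i.e.
escaped the growth suppression the assayed protein imposes.

Per-residue intolerance summarises the 19 missense substitutions at each
position; residues whose mean missense z exceeds mean + 2 SD of the
per-residue averages are flagged mutation-intolerant.
"""

from __future__ import annotations

import logging
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .synthetic import MISSENSE, SILENT, VariantRecord, library_frame

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_WINDOW_RADIUS = 2  # +/- codons, i.e. a 5-codon window
DEFAULT_MIN_SILENT = 2
DEFAULT_SD_FLOOR = 1e-6
DEFAULT_LOF_THRESHOLD = 2.0
DEFAULT_K_SD = 2.0


def _as_variant_frame(variants) -> pd.DataFrame:
    if isinstance(variants, pd.DataFrame):
        return variants
    return library_frame(variants)


def _with_identity(scores: pd.DataFrame, variants, columns: list[str]) -> pd.DataFrame:
    """Join variant identity columns onto a score table unless already present."""
    if all(c in scores.columns for c in columns):
        return scores
    var = _as_variant_frame(variants)
    return scores.merge(var[["variant_id"] + columns], on="variant_id")


def compute_l2fc(
    counts: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-variant, per-replicate log2 fold-change of read abundance.

    With ``normalize`` (default), counts are converted to library
    proportions first::

        L2FC = log2((tend + pc) / libsize_tend) - log2((t0 + pc) / libsize_t0)

    without it the raw pseudocounted ratio is used.  The pseudocount keeps
    every L2FC finite.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    required = {"variant_id", "rep", "count_t0", "count_tend"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    if (counts["count_t0"] < 0).any() or (counts["count_tend"] < 0).any():
        raise ValueError("read counts must be non-negative")
    out = counts.copy()
    l2fc = np.log2(out["count_tend"] + pseudocount) - np.log2(
        out["count_t0"] + pseudocount
    )
    if normalize:
        if "libsize_t0" not in out.columns or "libsize_tend" not in out.columns:
            raise ValueError("library sizes required when normalize=True")
        l2fc = l2fc - np.log2(out["libsize_tend"]) + np.log2(out["libsize_t0"])
    out["l2fc"] = l2fc
    return out


def rolling_silent_baseline(
    l2fc_table: pd.DataFrame,
    variants: pd.DataFrame | Sequence[VariantRecord],
    window_radius: int = DEFAULT_WINDOW_RADIUS,
    min_silent: int = DEFAULT_MIN_SILENT,
) -> pd.DataFrame:
    """Rolling mean/SD of silent-variant L2FC per (codon, replicate).

    For each codon ``c`` the baseline pools every silent variant with codon
    in ``[c - r, c + r]`` (``r = window_radius``, window truncated at the
    gene ends, no wraparound).  A silent variant contributes to its own
    codon's baseline.  If fewer than ``min_silent`` silent variants fall in
    the window, the window is expanded symmetrically one codon at a time
    until the minimum is met (logged).  The SD is the sample SD (n - 1).

    Returns a table with columns ``codon, rep, rolling_mean, rolling_sd,
    n_silent, radius``.
    """
    if window_radius < 1:
        raise ValueError("window_radius must be >= 1")
    var = _as_variant_frame(variants)
    merged = l2fc_table.merge(
        var[["variant_id", "codon", "mutation_class"]], on="variant_id",
        suffixes=("", "_var"),
    )
    if "codon_var" in merged.columns:  # l2fc table already carried codon
        merged = merged.drop(columns=["codon", "mutation_class"]).rename(
            columns={"codon_var": "codon", "mutation_class_var": "mutation_class"}
        )
    silents = merged[merged["mutation_class"] == SILENT]
    if silents.empty:
        raise ValueError("no silent variants in the gene: baseline undefined")

    codons = np.arange(1, int(var["codon"].max()) + 1)
    rows = []
    for rep, group in silents.groupby("rep"):
        pos = group["codon"].to_numpy()
        vals = group["l2fc"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos, vals = pos[order], vals[order]
        for c in codons:
            radius = window_radius
            while True:
                mask = (pos >= c - radius) & (pos <= c + radius)
                n = int(mask.sum())
                window_covers_gene = c - radius < codons[0] and c + radius > codons[-1]
                if n >= min_silent or window_covers_gene:
                    break
                radius += 1
            if radius > window_radius:
                logger.info(
                    "codon %d rep %s: window expanded to +/-%d codons "
                    "(%d silent variants)", c, rep, radius, n,
                )
            window = vals[mask]
            mean = float(window.mean()) if n else np.nan
            sd = float(window.std(ddof=1)) if n >= 2 else np.nan
            rows.append((int(c), rep, mean, sd, n, radius))
    return pd.DataFrame(
        rows, columns=["codon", "rep", "rolling_mean", "rolling_sd", "n_silent",
                       "radius"]
    )


def zscore(
    l2fc,
    baseline_mean,
    baseline_sd,
    sd_floor: float = DEFAULT_SD_FLOOR,
):
    """Silent-baseline z-score: ``(l2fc - mean) / sd``.

    Baseline SDs below ``sd_floor`` are replaced by the floor (the caller
    is expected to flag these); an undefined (NaN) baseline yields NaN.
    Accepts scalars or aligned arrays.
    """
    sd = np.maximum(np.asarray(baseline_sd, dtype=float), sd_floor)
    return (np.asarray(l2fc, dtype=float) - np.asarray(baseline_mean, dtype=float)) / sd


def score_replicates(
    l2fc_table: pd.DataFrame,
    baseline: pd.DataFrame,
    variants: pd.DataFrame | Sequence[VariantRecord] | None = None,
    sd_floor: float = DEFAULT_SD_FLOOR,
) -> pd.DataFrame:
    """Attach per-replicate z-scores to an L2FC table.

    Rows whose baseline SD was floored carry ``sd_floored=True``; rows with
    no defined baseline get ``z = NaN`` (missing, rendered as gray in the
    heatmap convention).
    """
    table = l2fc_table
    if "codon" not in table.columns:
        if variants is None:
            raise ValueError("need a variants table to map variant_id -> codon")
        table = table.merge(
            _as_variant_frame(variants)[["variant_id", "codon"]], on="variant_id"
        )
    merged = table.merge(
        baseline[["codon", "rep", "rolling_mean", "rolling_sd"]],
        on=["codon", "rep"], how="left",
    )
    merged["sd_floored"] = merged["rolling_sd"].notna() & (
        merged["rolling_sd"] < sd_floor
    )
    if merged["sd_floored"].any():
        logger.warning(
            "%d variant/replicate rows had baseline SD below %g (floored)",
            int(merged["sd_floored"].sum()), sd_floor,
        )
    merged["z"] = zscore(
        merged["l2fc"], merged["rolling_mean"], merged["rolling_sd"], sd_floor
    )
    return merged


def aggregate_replicates(
    z_table: pd.DataFrame, min_replicates: int = 1
) -> pd.DataFrame:
    """Cross-replicate mean and sample SD of z per variant.

    Replicates with undefined z are dropped before averaging; variants with
    fewer than ``min_replicates`` defined replicates get ``mean_z = NaN``.
    ``sd_z`` is undefined (NaN) for a single replicate.
    """
    def _agg(group: pd.Series) -> pd.Series:
        vals = group.dropna()
        n = len(vals)
        return pd.Series(
            {
                "mean_z": vals.mean() if n >= min_replicates and n > 0 else np.nan,
                "sd_z": vals.std(ddof=1) if n >= 2 else np.nan,
                "n_replicates": n,
            }
        )

    out = z_table.groupby("variant_id", sort=False)["z"].apply(_agg).unstack()
    out["n_replicates"] = out["n_replicates"].astype(int)
    return out.reset_index()


def call_lof(
    scores: pd.DataFrame, threshold: float = DEFAULT_LOF_THRESHOLD
) -> pd.DataFrame:
    """Flag loss-of-function variants: ``mean_z > threshold`` (strict).

    A mean z of exactly ``threshold`` is not LOF; undefined means are never
    LOF.
    """
    out = scores.copy()
    out["lof"] = out["mean_z"] > threshold
    return out


class ResidueProfileResult(NamedTuple):
    table: pd.DataFrame
    cutoff: float


def residue_profile(
    scores: pd.DataFrame,
    variants: pd.DataFrame | Sequence[VariantRecord],
    k_sd: float = DEFAULT_K_SD,
    min_subs: int = 1,
    positive_only: bool = False,
) -> ResidueProfileResult:
    """Per-residue missense intolerance profile.

    ``residue_mean_z`` averages the mean z over the observed missense
    substitutions at each codon (nonsense/frameshift excluded).  The
    intolerance cutoff is ``mean + k_sd * SD`` of the residue averages over
    all residues with at least ``min_subs`` substitutions (or, with
    ``positive_only``, over only the residues with positive averages);
    ``intolerant`` uses a strict ``>``.
    """
    merged = _with_identity(scores, variants, ["codon", "alt_aa", "mutation_class"])
    mis = merged[merged["mutation_class"] == MISSENSE].dropna(subset=["mean_z"])
    if mis.empty:
        raise ValueError("no missense scores to profile")
    prof = (
        mis.groupby("codon")
        .agg(residue_mean_z=("mean_z", "mean"), n_substitutions=("alt_aa", "nunique"))
        .reset_index()
    )
    eligible = prof[prof["n_substitutions"] >= min_subs]
    pool = eligible[eligible["residue_mean_z"] > 0] if positive_only else eligible
    cutoff = float(pool["residue_mean_z"].mean()
                   + k_sd * pool["residue_mean_z"].std(ddof=1))
    prof["intolerant"] = (prof["n_substitutions"] >= min_subs) & (
        prof["residue_mean_z"] > cutoff
    )
    return ResidueProfileResult(prof, cutoff)


def substitution_summary(
    scores: pd.DataFrame,
    variants: pd.DataFrame | Sequence[VariantRecord],
    z_threshold: float = DEFAULT_LOF_THRESHOLD,
) -> pd.DataFrame:
    """Per substituted amino acid: mean z and number of residues above threshold.

    ``n_residues_above`` counts the distinct codons at which that
    substitution's mean z strictly exceeds ``z_threshold`` (the statistic
    behind "deleterious at the greatest number of residues").
    """
    merged = _with_identity(scores, variants, ["codon", "alt_aa", "mutation_class"])
    mis = merged[merged["mutation_class"] == MISSENSE].dropna(subset=["mean_z"])
    if mis.empty:
        raise ValueError("no missense scores to summarise")

    def _summarise(g: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "mean_z": g["mean_z"].mean(),
                "n_residues_above": int(
                    g.loc[g["mean_z"] > z_threshold, "codon"].nunique()
                ),
            }
        )

    out = (
        mis.groupby("alt_aa")[["mean_z", "codon"]].apply(_summarise).reset_index()
    )
    out["n_residues_above"] = out["n_residues_above"].astype(int)
    return out


def heatmap_matrix(
    scores: pd.DataFrame, variants: pd.DataFrame | Sequence[VariantRecord]
) -> pd.DataFrame:
    """Codon x substituted-amino-acid matrix of mean z (NaN = missing)."""
    merged = _with_identity(scores, variants, ["codon", "alt_aa"])
    return merged.pivot_table(
        index="codon", columns="alt_aa", values="mean_z", aggfunc="mean"
    )


def score_screen(
    counts: pd.DataFrame,
    variants: pd.DataFrame | Sequence[VariantRecord],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    normalize: bool = True,
    window_radius: int = DEFAULT_WINDOW_RADIUS,
    min_silent: int = DEFAULT_MIN_SILENT,
    sd_floor: float = DEFAULT_SD_FLOOR,
    lof_threshold: float = DEFAULT_LOF_THRESHOLD,
    min_replicates: int = 1,
) -> pd.DataFrame:
    """Full scoring pipeline: counts -> L2FC -> baseline -> z -> LOF calls.

    Returns one row per variant with per-replicate z columns (``z_rep<i>``),
    ``mean_z``, ``sd_z`` and the ``lof`` flag, joined to variant identity.
    """
    var = _as_variant_frame(variants)
    l2fc = compute_l2fc(counts, pseudocount=pseudocount, normalize=normalize)
    baseline = rolling_silent_baseline(
        l2fc, var, window_radius=window_radius, min_silent=min_silent
    )
    z_table = score_replicates(l2fc, baseline, var, sd_floor=sd_floor)
    scores = aggregate_replicates(z_table, min_replicates=min_replicates)
    scores = call_lof(scores, threshold=lof_threshold)
    wide = z_table.pivot_table(index="variant_id", columns="rep", values="z")
    wide.columns = [f"z_rep{c}" for c in wide.columns]
    out = var.merge(wide.reset_index(), on="variant_id", how="left").merge(
        scores, on="variant_id", how="left"
    )
    out["lof"] = out["lof"].fillna(False).astype(bool)
    return out
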