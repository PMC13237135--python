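"""Shared table readers/writers, run configuration and the pipeline driver.

All tabular interchange is plain TSV with a header row; genomic intervals
are BED (no header).  Every output table is written with a short ``#``
comment header naming units and conventions, and each pipeline run writes a
machine-readable manifest (parameters, seed, package version) alongside its
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import scoring, synthetic
from .predictors import THRESHOLDS

logger = logging.getLogger(__name__)

COUNTS_COLUMNS = [
    "variant_id", "codon", "ref_aa", "alt_aa", "mutation_class", "rep",
    "count_t0", "count_tend", "libsize_t0", "libsize_tend",
]

_MUTATION_CLASSES = {
    synthetic.SILENT, synthetic.MISSENSE, synthetic.NONSENSE,
    synthetic.FRAMESHIFT_CLASS,
}


@dataclass
class RunConfig:
    """End-to-end pipeline parameters; defaults are the study's values."""

    # simulation
    n_codons: int = 200
    depth: int = 1_000_000
    n_replicates: int = 3
    doublings: float = 6.0
    lof_effect: float = 1.0
    lof_fraction_missense: float = 0.05
    silents_per_codon: int = 1
    seed: int = 0
    # scoring
    pseudocount: float = 1.0
    window_radius: int = 2        # codons, i.e. a 5-codon window
    min_silent: int = 2
    sd_floor: float = 1e-6
    lof_threshold: float = 2.0    # two-sided normal p < 0.0455
    k_sd: float = 2.0             # residue-intolerance cutoff = mean + k_sd * SD
    min_replicates: int = 1
    # predictors (score >= threshold -> pathogenic)
    predictor_thresholds: dict = field(default_factory=lambda: dict(THRESHOLDS))
    # intervals
    merge_distance: int = 100     # bp, union of reproducible peaks
    # MD
    contact_cutoff: float = 4.0   # Angstrom, strict <
    vdw_threshold: float = 0.5    # kcal/mol
    elec_threshold: float = 1.0   # kcal/mol
    contact_loss_threshold: float = 0.20
    # proteomics
    ms_max_missing: int = 3
    ms_width: float = 0.3
    ms_downshift: float = 1.8
    ms_fc_threshold: float = 1.5
    alpha: float = 0.05

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a screen counts table, validating schema and values.

    Malformed rows are reported with their 1-based data line number.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    for col in ("count_t0", "count_tend"):
        bad = df.index[df[col] < 0]
        if len(bad):
            raise ValueError(
                f"{path}: negative {col} at line {int(bad[0]) + 2}"
            )
    bad_class = df.index[~df["mutation_class"].isin(_MUTATION_CLASSES)]
    if len(bad_class):
        raise ValueError(
            f"{path}: unknown mutation_class at line {int(bad_class[0]) + 2}"
        )
    dup = df.duplicated(subset=["variant_id", "rep"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (variant_id, rep) at line "
            f"{int(df.index[dup][0]) + 2}"
        )
    return df


def write_tsv(df: pd.DataFrame, path, comment: str | None = None) -> None:
    """Write a TSV with an optional ``#`` convention-note header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    write_tsv(
        counts[COUNTS_COLUMNS], path,
        comment="screen counts; reads per variant per replicate at t0/tend",
    )


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Simulate -> score -> classify, writing all artifacts to ``out_dir``.

    Stages: synthetic screen generation, L2FC/z scoring with the rolling
    silent baseline, LOF calls, residue intolerance profile, substitution
    summary and the codon x substitution heatmap matrix.  Returns the
    manifest dict (also written as ``manifest.json``).  Deterministic for a
    fixed config.
    """
    from importlib.metadata import version as _pkg_version

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        library = synthetic.generate_library(
            config.n_codons, config.seed, silents_per_codon=config.silents_per_codon
        )
        effects = synthetic.EffectModel(
            lof_effect=config.lof_effect,
            lof_fraction_missense=config.lof_fraction_missense,
            doublings=config.doublings,
            depth=config.depth,
            n_replicates=config.n_replicates,
            seed=config.seed,
        )
        counts, truth = synthetic.simulate_counts(library, effects)
        logger.info("simulated %d variants x %d replicates", len(library),
                    config.n_replicates)
        write_counts_tsv(counts, out / "counts.tsv")
        write_tsv(truth, out / "truth.tsv",
                  comment="ground truth; true_effect in log2 units per doubling")

        stage = "score"
        variants = synthetic.library_frame(library)
        scores = scoring.score_screen(
            counts, variants,
            pseudocount=config.pseudocount,
            window_radius=config.window_radius,
            min_silent=config.min_silent,
            sd_floor=config.sd_floor,
            lof_threshold=config.lof_threshold,
            min_replicates=config.min_replicates,
        )
        write_tsv(
            scores, out / "scores.tsv",
            comment=("functional scores; z dimensionless vs rolling silent "
                     "baseline, L2FC in log2 units; lof = mean_z > "
                     f"{config.lof_threshold} (strict)"),
        )

        stage = "classify"
        profile = scoring.residue_profile(scores, variants, k_sd=config.k_sd)
        write_tsv(
            profile.table, out / "residues.tsv",
            comment=(f"residue intolerance; cutoff mean + {config.k_sd}*SD = "
                     f"{profile.cutoff:.4f} (strict >)"),
        )
        subs = scoring.substitution_summary(scores, variants,
                                            z_threshold=config.lof_threshold)
        write_tsv(subs, out / "substitutions.tsv",
                  comment="per substituted amino acid; counts use strict z > "
                          f"{config.lof_threshold}")
        matrix = scoring.heatmap_matrix(scores, variants)
        matrix.to_csv(out / "heatmap_matrix.tsv", sep="\t")
    except Exception as exc:  # pragma: no cover - error path
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    try:
        pkg_version = _pkg_version("dmskit")
    except Exception:  # editable/source runs without metadata
        pkg_version = "unknown"
    defaults = RunConfig()
    manifest = {
        "package": "dmskit",
        "version": pkg_version,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "non_default_parameters": {
            f.name: getattr(config, f.name)
            for f in dataclasses.fields(config)
            if getattr(config, f.name) != getattr(defaults, f.name)
        },
        "n_variants": len(library),
        "n_lof_calls": int(scores["lof"].sum()),
        "residue_cutoff": profile.cutoff,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
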