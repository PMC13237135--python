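"""Synthetic saturation-mutagenesis screens with known ground truth.

Emulates a proliferation-based deep-mutational-scanning experiment: a pooled
library of programmed variants (silent, missense, nonsense, frameshift) is
introduced into cells, the population grows for a fixed number of doublings,
and variant abundance is read out by sequencing at the start and end of the
selection window.  Loss-of-function variants escape the growth suppression
imposed by the re-expressed protein and therefore *enrich* (positive log2
fold-change); silent variants are fitness-neutral by construction and serve
as the local baseline for scoring.

The generator plants a known truth table (which variants are LOF, and with
what per-doubling selection coefficient), optional block-constant regional
log2 artifacts, and multinomial sequencing noise at a configurable depth, so
that the scoring pipeline can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"
FRAMESHIFT = "fs"

#: mutation classes
SILENT = "silent"
MISSENSE = "missense"
NONSENSE = "nonsense"
FRAMESHIFT_CLASS = "frameshift"

#: truth classes
NEUTRAL = "neutral"
LOF = "lof"
PARTIAL = "partial"

#: fraction of the full LOF effect retained by truncating variants past the
#: terminal-escape boundary (when enabled)
PARTIAL_RETENTION = 0.5

MIN_CODONS = 5  # a rolling window of 5 codons is undefined below this


@dataclass(frozen=True)
class VariantRecord:
    """Identity of one programmed alteration.

    ``codon`` is 1-based.  ``alt_aa`` equals ``ref_aa`` for silent variants,
    ``"*"`` for nonsense and ``"fs"`` for frameshift records.
    """

    variant_id: str
    codon: int
    ref_aa: str
    alt_aa: str
    mutation_class: str

    def __post_init__(self) -> None:
        if self.codon < 1:
            raise ValueError(f"codon must be >= 1, got {self.codon}")
        if self.mutation_class == SILENT and self.ref_aa != self.alt_aa:
            raise ValueError("silent variants require ref_aa == alt_aa")
        if self.mutation_class == NONSENSE and self.alt_aa != STOP:
            raise ValueError("nonsense variants require alt_aa == '*'")


@dataclass(frozen=True)
class EffectModel:
    """Ground-truth selection model for a simulated screen.

    Parameters
    ----------
    lof_effect
        Selection coefficient of a true LOF variant, in log2 enrichment
        units per population doubling.
    lof_fraction_missense
        Proportion of missense variants planted as true LOF, in [0, 1].
    terminal_escape_start
        Codon index after which nonsense/frameshift variants retain partial
        function (effect scaled by ``PARTIAL_RETENTION``); ``None`` disables
        the escape model.
    doublings
        Number of population doublings over the selection window (the
        emulated screens span 4-8).
    artifact_blocks
        ``(codon_start, codon_end, shift)`` triples: every variant whose
        codon lies in the inclusive range receives the additive ``shift``
        (log2 units) on its end-timepoint log-scale expectation, emulating
        regional technical artifacts.
    depth
        Total reads per sample (multinomial size for each timepoint).
    n_replicates
        Number of independent replicate screens (replicate contexts).
    seed
        Master seed; every random draw derives from it, so a fixed seed
        yields bit-identical output.
    """

    neutral_effect: float = 0.0
    lof_effect: float = 1.0
    lof_fraction_missense: float = 0.05
    terminal_escape_start: int | None = None
    doublings: float = 6.0
    artifact_blocks: tuple[tuple[int, int, float], ...] = ()
    depth: int = 1_000_000
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lof_fraction_missense <= 1.0:
            raise ValueError("lof_fraction_missense must lie in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for block in self.artifact_blocks:
            lo, hi, _ = block
            if lo > hi or lo < 1:
                raise ValueError(f"invalid artifact block {block!r}")


def generate_library(
    n_codons: int, seed: int, silents_per_codon: int = 1
) -> list[VariantRecord]:
    """Generate a saturation library over ``n_codons`` positions.

    Per codon: 19 missense records (every non-reference amino acid), one
    nonsense, one frameshift, and ``silents_per_codon`` silent records.
    With the default of one silent per codon this is the 22-records-per-codon
    scheme (e.g. 385 codons -> 8470 records).  Real codon-replacement
    libraries typically program several synonymous codons per position;
    raising ``silents_per_codon`` emulates that and gives the rolling
    baseline more observations per window.

    Reference amino acids are assigned uniformly at random from ``seed``.
    """
    if n_codons < MIN_CODONS:
        raise ValueError(
            f"n_codons must be >= {MIN_CODONS} (rolling window of 5 codons "
            f"is undefined), got {n_codons}"
        )
    if silents_per_codon < 1:
        raise ValueError("silents_per_codon must be >= 1")
    rng = np.random.default_rng(seed)
    refs = rng.choice(list(AMINO_ACIDS), size=n_codons)
    records: list[VariantRecord] = []
    for codon in range(1, n_codons + 1):
        ref = refs[codon - 1]
        for k in range(silents_per_codon):
            suffix = "" if k == 0 else f".{k + 1}"
            records.append(
                VariantRecord(f"{ref}{codon}{ref}{suffix}", codon, ref, ref, SILENT)
            )
        for alt in AMINO_ACIDS:
            if alt != ref:
                records.append(
                    VariantRecord(f"{ref}{codon}{alt}", codon, ref, alt, MISSENSE)
                )
        records.append(VariantRecord(f"{ref}{codon}{STOP}", codon, ref, STOP, NONSENSE))
        records.append(
            VariantRecord(f"{ref}{codon}{FRAMESHIFT}", codon, ref, FRAMESHIFT,
                          FRAMESHIFT_CLASS)
        )
    return records


def library_frame(library: Sequence[VariantRecord]) -> pd.DataFrame:
    """Tabulate a variant library as a DataFrame."""
    return pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in library],
            "codon": [v.codon for v in library],
            "ref_aa": [v.ref_aa for v in library],
            "alt_aa": [v.alt_aa for v in library],
            "mutation_class": [v.mutation_class for v in library],
        }
    )


def assign_truth(library: Sequence[VariantRecord], effects: EffectModel) -> pd.DataFrame:
    """Assign each variant its true class and log2-per-doubling effect.

    Silent variants are neutral; a ``lof_fraction_missense`` random subset
    of missense variants is LOF at ``lof_effect``; nonsense and frameshift
    variants are LOF, except past ``terminal_escape_start`` where they are
    ``partial`` (effect scaled by ``PARTIAL_RETENTION``).  The truth classes
    partition the library.
    """
    rng = np.random.default_rng(np.random.SeedSequence([effects.seed, 1]))
    classes: list[str] = []
    true_effects: list[float] = []
    for v in library:
        if v.mutation_class == SILENT:
            cls, eff = NEUTRAL, effects.neutral_effect
        elif v.mutation_class == MISSENSE:
            if rng.random() < effects.lof_fraction_missense:
                cls, eff = LOF, effects.lof_effect
            else:
                cls, eff = NEUTRAL, effects.neutral_effect
        else:  # nonsense / frameshift
            escape = (
                effects.terminal_escape_start is not None
                and v.codon > effects.terminal_escape_start
            )
            if escape:
                cls, eff = PARTIAL, effects.lof_effect * PARTIAL_RETENTION
            else:
                cls, eff = LOF, effects.lof_effect
        classes.append(cls)
        true_effects.append(eff)
    return pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in library],
            "true_class": classes,
            "true_effect": true_effects,
        }
    )


def _artifact_shift(codons: np.ndarray, blocks) -> np.ndarray:
    shift = np.zeros(len(codons))
    for lo, hi, delta in blocks:
        shift[(codons >= lo) & (codons <= hi)] += delta
    return shift


def simulate_counts(
    library: Sequence[VariantRecord],
    effects: EffectModel,
    truth: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate sequencing counts for a screen under ``effects``.

    Start counts are multinomial over uniform library proportions at the
    configured depth.  The end-timepoint expected proportion of variant *v*
    is proportional to ``2**(doublings * true_effect + artifact_shift)``,
    i.e. selection acts multiplicatively on expected frequency and regional
    artifacts add in log2 space.  Each replicate draws from an independent
    RNG stream spawned from the master seed.

    A pre-built ``truth`` table (``variant_id, true_class, true_effect``,
    one row per library variant in library order) overrides the random
    truth assignment, allowing specific variants or residues to be planted
    with chosen effects.

    Returns ``(counts, truth)``: a long-format counts table (one row per
    variant x replicate, columns ``variant_id, codon, ref_aa, alt_aa,
    mutation_class, rep, count_t0, count_tend, libsize_t0, libsize_tend``)
    and the truth table.
    """
    if len(library) == 0:
        raise ValueError("library must be nonempty")
    max_codon = max(v.codon for v in library)
    for lo, hi, _ in effects.artifact_blocks:
        if hi > max_codon:
            raise ValueError(f"artifact block ({lo}, {hi}) extends beyond the gene")

    if truth is None:
        truth = assign_truth(library, effects)
    else:
        expected = [v.variant_id for v in library]
        if list(truth["variant_id"]) != expected:
            raise ValueError("truth table must list every library variant in order")
    codons = np.array([v.codon for v in library])
    n = len(library)
    log2_growth = effects.doublings * truth["true_effect"].to_numpy()
    log2_growth = log2_growth + _artifact_shift(codons, effects.artifact_blocks)
    end_weights = np.exp2(log2_growth)  # relative to uniform start proportions
    end_p = end_weights / end_weights.sum()
    start_p = np.full(n, 1.0 / n)

    rep_streams = np.random.SeedSequence([effects.seed, 2]).spawn(effects.n_replicates)
    frames = []
    base = library_frame(library)
    for rep_idx, stream in enumerate(rep_streams, start=1):
        rng = np.random.default_rng(stream)
        t0 = rng.multinomial(effects.depth, start_p)
        tend = rng.multinomial(effects.depth, end_p)
        frame = base.copy()
        frame["rep"] = rep_idx
        frame["count_t0"] = t0
        frame["count_tend"] = tend
        frame["libsize_t0"] = effects.depth
        frame["libsize_tend"] = effects.depth
        frames.append(frame)
    counts = pd.concat(frames, ignore_index=True)
    return counts, truth
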