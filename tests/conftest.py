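import numpy as np
import pandas as pd
import pytest

from dmskit import EffectModel, generate_library, library_frame, simulate_counts


@pytest.fixture(scope="session")
def small_library():
    return generate_library(10, seed=7)


@pytest.fixture(scope="session")
def null_screen():
    """A fully neutral 60-codon screen (no planted effects), 3 replicates."""
    library = generate_library(60, seed=11)
    effects = EffectModel(
        lof_effect=0.0, lof_fraction_missense=0.0, depth=200_000,
        n_replicates=3, seed=11,
    )
    counts, truth = simulate_counts(library, effects)
    return library, counts, truth


def random_l2fc_table(n_codons: int, seed: int, n_reps: int = 2):
    """A synthetic L2FC table with pure noise, paired with its library."""
    library = generate_library(n_codons, seed=seed)
    variants = library_frame(library)
    rng = np.random.default_rng(seed)
    frames = []
    for rep in range(1, n_reps + 1):
        frame = variants[["variant_id", "codon", "mutation_class"]].copy()
        frame["rep"] = rep
        frame["l2fc"] = rng.normal(size=len(frame))
        frames.append(frame)
    return pd.concat(frames, ignore_index=True), variants
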