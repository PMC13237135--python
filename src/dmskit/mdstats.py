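"""Post-trajectory statistics for molecular-dynamics mutant comparisons.

Consumes per-frame quantities exported from an MD engine (pairwise
interaction energies in kcal/mol, or atomic coordinates) and computes the
mutant-versus-wild-type difference statistics used to attribute structural
destabilisation to a mutation:

* per-replicate mean interaction energy, ``dE = E_mutant - E_WT`` and the
  control-variant-normalised ``ddE = dE_mutant - dE_control``;
* residue-pair contact frequencies ``f = n_contact / n_frames`` (a contact
  is any heavy-atom pair strictly within the cutoff, default 4.0 A), the
  wild-type-minus-mutant difference ``df = f_WT - f_mut`` and its
  control-normalised ``ddf``;
* one-sample significance against zero with the dual criterion used for
  reporting: two-tailed one-sample t test p < alpha AND an effect-size
  magnitude threshold (0.5 kcal/mol for van der Waals, 1.0 for
  electrostatics, 0.20 for contact loss).

Note the printed sign conventions differ between the two families and are
kept as such: energies are mutant minus wild type (positive =
destabilising), contact differences are wild type minus mutant (positive =
contact lost in the mutant).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

DEFAULT_CONTACT_CUTOFF = 4.0   # Angstrom, strict <
VDW_THRESHOLD = 0.5            # kcal/mol, |ddE| must exceed
ELEC_THRESHOLD = 1.0           # kcal/mol
CONTACT_LOSS_THRESHOLD = 0.20  # fraction of frames
DEFAULT_ALPHA = 0.05

FRAME_COLUMNS = ["frame", "residue", "atom", "element", "x", "y", "z"]


def _infer_element(atom_name: str) -> str:
    """Fallback element inference from an atom name's leading letter."""
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def read_frames_tsv(path) -> pd.DataFrame:
    """Read per-frame coordinates (frame, residue, atom, element, x, y, z)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(FRAME_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"frames table missing columns: {sorted(missing)}")
    return df


def read_frames_pdb(path) -> pd.DataFrame:
    """Read a multi-model PDB (MODEL/ENDMDL) into a frames table.

    Uses the ATOM record element column when populated, else infers the
    element from the atom name's leading letter.  Hydrogens are retained
    (filtered at contact time).
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("traj", path)
    rows = []
    for model in structure:
        for chain in model:
            for residue in chain:
                resseq = residue.id[1]
                for atom in residue:
                    element = (atom.element or "").strip() or _infer_element(
                        atom.get_name()
                    )
                    x, y, z = atom.coord
                    rows.append(
                        (model.id + 1, resseq, atom.get_name(), element.upper(),
                         float(x), float(y), float(z))
                    )
    if not rows:
        raise ValueError(f"no ATOM records found in {path}")
    return pd.DataFrame(rows, columns=FRAME_COLUMNS)


def contact_frequency(
    frames: pd.DataFrame,
    group_a: Iterable[int],
    group_b: Iterable[int],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> pd.DataFrame:
    """Residue-pair contact frequency over a trajectory.

    ``frames`` is a long table (columns ``frame, residue, atom, element,
    x, y, z``).  A residue pair (a in group_a, b in group_b) is in contact
    in a frame iff any pair of heavy atoms (element != H) lies strictly
    within ``cutoff`` Angstrom.  Returns one row per residue pair with
    ``f = n_contact / n_frames`` in [0, 1].
    """
    ga, gb = sorted(set(group_a)), sorted(set(group_b))
    if not ga or not gb:
        raise ValueError("residue groups must be nonempty")
    if set(ga) & set(gb):
        raise ValueError("residue groups must be disjoint")
    heavy = frames[frames["element"].str.upper() != "H"]
    frame_ids = sorted(frames["frame"].unique())
    n_frames = len(frame_ids)
    if n_frames == 0:
        raise ValueError("no frames supplied")
    counts: dict[tuple[int, int], int] = {(a, b): 0 for a in ga for b in gb}
    for _, snap in heavy.groupby("frame"):
        sub_a = snap[snap["residue"].isin(ga)]
        sub_b = snap[snap["residue"].isin(gb)]
        if sub_a.empty or sub_b.empty:
            continue
        dists = cdist(sub_a[["x", "y", "z"]], sub_b[["x", "y", "z"]])
        close = dists < cutoff  # strict: exactly at the cutoff is no contact
        if not close.any():
            continue
        res_a = sub_a["residue"].to_numpy()
        res_b = sub_b["residue"].to_numpy()
        ia, ib = np.nonzero(close)
        for pair in set(zip(res_a[ia], res_b[ib])):
            counts[pair] += 1
    out = pd.DataFrame(
        [(a, b, c / n_frames) for (a, b), c in sorted(counts.items())],
        columns=["res_a", "res_b", "f"],
    )
    return out


def delta_e(mean_condition: float, mean_reference: float) -> float:
    """Interaction-energy difference, condition minus reference (kcal/mol).

    With the mutant as condition and wild type as reference this is the
    printed convention: positive values are destabilising.
    """
    return mean_condition - mean_reference


class DDeltaResult(NamedTuple):
    per_replicate: pd.Series
    mean: float


def ddelta(
    delta_exp: Mapping | pd.Series, delta_control: Mapping | pd.Series
) -> DDeltaResult:
    """Control-normalised difference-in-differences, matched by replicate.

    ``ddE_i = dE_exp,i - dE_ctrl,i`` for each replicate id ``i``; the mean
    over replicates is also returned.  Replicate sets must match exactly.
    """
    exp = pd.Series(delta_exp, dtype=float)
    ctrl = pd.Series(delta_control, dtype=float)
    if set(exp.index) != set(ctrl.index):
        raise ValueError("replicate ids of experimental and control runs differ")
    per_rep = exp - ctrl.reindex(exp.index)
    return DDeltaResult(per_rep, float(per_rep.mean()))


@dataclass(frozen=True)
class DeltaResult:
    """Outcome of the dual-criterion significance assessment."""

    quantity: str
    values: tuple[float, ...]   # per-replicate values
    mean: float
    t_stat: float
    p_two_sided: float
    magnitude_threshold: float
    significant: bool
    degenerate: bool = False    # zero spread across replicates


def one_sample_significance(
    values: Sequence[float],
    magnitude_threshold: float,
    alpha: float = DEFAULT_ALPHA,
    quantity: str = "ddE",
) -> DeltaResult:
    """Two-tailed one-sample t test against zero with a dual criterion.

    ``t = mean / (SD / sqrt(n))`` with ``n - 1`` degrees of freedom (12
    replicates give df = 11); the result is significant iff ``p < alpha``
    AND ``|mean| > magnitude_threshold``.  Zero spread across replicates is
    degenerate: p is reported as 0 (or 1 when the mean is also 0) with the
    flag set.
    """
    vals = np.asarray(values, dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least two replicates")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if sd == 0.0:
        degenerate = True
        t = float("inf") if mean > 0 else (float("-inf") if mean < 0 else 0.0)
        p = 0.0 if mean != 0 else 1.0
    else:
        degenerate = False
        res = stats.ttest_1samp(vals, popmean=0.0)
        t, p = float(res.statistic), float(res.pvalue)
    significant = (p < alpha) and (abs(mean) > magnitude_threshold)
    return DeltaResult(
        quantity=quantity,
        values=tuple(vals),
        mean=mean,
        t_stat=t,
        p_two_sided=p,
        magnitude_threshold=magnitude_threshold,
        significant=significant,
        degenerate=degenerate,
    )


class ContactDiffResult(NamedTuple):
    ddf: pd.DataFrame     # per-pair per-replicate ddf plus mean column
    losses: pd.DataFrame  # pairs with mean ddf > loss_threshold
    gains: pd.DataFrame   # pairs with mean ddf < -loss_threshold


def contact_diff_map(
    f_wt: pd.DataFrame,
    f_mut: pd.DataFrame,
    f_wt_ctrl_run: pd.DataFrame,
    f_ctrl: pd.DataFrame,
    loss_threshold: float = CONTACT_LOSS_THRESHOLD,
) -> ContactDiffResult:
    """Control-normalised contact-frequency difference map.

    Each input is a per-replicate frequency table indexed by residue pair
    (``res_a``, ``res_b``) with one column per replicate; all four must
    share the same pair domain and replicate columns.  Per replicate,
    ``df_exp = f_WT - f_mut`` (from the experimental-mutant runs) and
    ``df_ctrl = f_WT - f_ctrl`` (from the control-variant runs);
    ``ddf = df_exp - df_ctrl`` is averaged over replicates.  Pairs with
    mean ddf above ``loss_threshold`` are the reported contact losses;
    pairs below ``-loss_threshold`` are gains, reported separately.
    """
    tables = [f_wt, f_mut, f_wt_ctrl_run, f_ctrl]
    domain = tables[0].index
    cols = list(tables[0].columns)
    for t in tables[1:]:
        if not t.index.equals(domain) or list(t.columns) != cols:
            raise ValueError("frequency maps must share residue pairs and replicates")
    df_exp = f_wt - f_mut
    df_ctrl = f_wt_ctrl_run - f_ctrl
    ddf = df_exp - df_ctrl
    ddf = ddf.copy()
    ddf["mean_ddf"] = ddf[cols].mean(axis=1)
    losses = ddf[ddf["mean_ddf"] > loss_threshold]
    gains = ddf[ddf["mean_ddf"] < -loss_threshold]
    return ContactDiffResult(ddf, losses, gains)
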