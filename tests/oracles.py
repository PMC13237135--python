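"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (direct re-selection, O(n^2) scans,
full hypergeometric enumeration) and shares no code with the package.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd


def brute_silent_baseline(
    l2fc_table: pd.DataFrame,
    variants: pd.DataFrame,
    window_radius: int = 2,
    min_silent: int = 2,
) -> pd.DataFrame:
    """Direct per-codon re-selection of window silents (mean, sample SD)."""
    merged = l2fc_table[["variant_id", "rep", "l2fc"]].merge(
        variants[["variant_id", "codon", "mutation_class"]], on="variant_id"
    )
    silents = merged[merged["mutation_class"] == "silent"]
    max_codon = int(variants["codon"].max())
    rows = []
    for rep in sorted(merged["rep"].unique()):
        rep_silents = silents[silents["rep"] == rep]
        for c in range(1, max_codon + 1):
            r = window_radius
            while True:
                window = rep_silents[
                    (rep_silents["codon"] >= c - r) & (rep_silents["codon"] <= c + r)
                ]["l2fc"]
                if len(window) >= min_silent or (c - r < 1 and c + r > max_codon):
                    break
                r += 1
            mean = window.mean() if len(window) else np.nan
            sd = window.std(ddof=1) if len(window) >= 2 else np.nan
            rows.append((c, rep, mean, sd, len(window), r))
    return pd.DataFrame(
        rows, columns=["codon", "rep", "rolling_mean", "rolling_sd", "n_silent",
                       "radius"]
    )


def overlaps(a: tuple, b: tuple) -> bool:
    """Half-open interval overlap on matching chromosomes."""
    return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]


def brute_merge(intervals: list[tuple], distance: int = 0) -> list[tuple]:
    """Union-find merge: i~j iff same chrom and gap <= distance."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ci, si, ei = intervals[i][:3]
            cj, sj, ej = intervals[j][:3]
            if ci == cj and max(si, sj) - min(ei, ej) <= distance:
                parent[find(i)] = find(j)
    groups: dict[int, list[tuple]] = {}
    for i, iv in enumerate(intervals):
        groups.setdefault(find(i), []).append(iv)
    out = [
        (g[0][0], min(iv[1] for iv in g), max(iv[2] for iv in g))
        for g in groups.values()
    ]
    return sorted(out)


def brute_reproducible(a: list[tuple], b: list[tuple]) -> list[tuple]:
    kept = [iv for iv in a if any(overlaps(iv, jv) for jv in b)]
    return brute_merge(kept, distance=0) if kept else []


def brute_partition(
    consensus: list[tuple], gained: list[tuple], lost: list[tuple]
) -> list[str]:
    labels = []
    for iv in consensus:
        if any(overlaps(iv, g) for g in gained):
            labels.append("gained")
        elif any(overlaps(iv, l) for l in lost):
            labels.append("lost")
        else:
            labels.append("persistent")
    return labels


def brute_contact_frequency(
    frames: pd.DataFrame, group_a, group_b, cutoff: float = 4.0
) -> dict[tuple[int, int], float]:
    """All-pairs heavy-atom distance scan, pure python loops."""
    frame_ids = sorted(frames["frame"].unique())
    freqs = {(a, b): 0 for a in group_a for b in group_b}
    for fid in frame_ids:
        snap = frames[frames["frame"] == fid]
        for a in group_a:
            atoms_a = snap[(snap["residue"] == a) & (snap["element"].str.upper() != "H")]
            for b in group_b:
                atoms_b = snap[
                    (snap["residue"] == b) & (snap["element"].str.upper() != "H")
                ]
                hit = False
                for _, ra in atoms_a.iterrows():
                    for _, rb in atoms_b.iterrows():
                        d = (
                            (ra.x - rb.x) ** 2 + (ra.y - rb.y) ** 2 + (ra.z - rb.z) ** 2
                        ) ** 0.5
                        if d < cutoff:
                            hit = True
                            break
                    if hit:
                        break
                if hit:
                    freqs[(a, b)] += 1
    return {k: v / len(frame_ids) for k, v in freqs.items()}


def fisher_exact_enumeration(table) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    denom = comb(n, col1)

    def prob(k: int) -> float:
        return comb(row1, k) * comb(row2, col1 - k) / denom

    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    p_obs = prob(a)
    return sum(p for k in range(lo, hi + 1) if (p := prob(k)) <= p_obs * (1 + 1e-9))
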