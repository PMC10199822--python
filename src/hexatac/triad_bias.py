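"""Ternary bias classification of homeolog triads.

Each triad's per-tissue value triple (A, B, D) is converted to fractions on
the 2-simplex and assigned to the nearest of seven centroids: Balanced at
(1/3, 1/3, 1/3), three single-subgenome Dominant corners, and three
Suppressed midpoints such as A-suppressed at (0, 1/2, 1/2).  Triads whose
value sum falls below ``min_sum`` are NotExpressed.  The module also builds
stage-transition count tables (Sankey input) and expression-vs-accessibility
concordance statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TriadRecord",
    "TriadProfile",
    "BIAS_CATEGORIES",
    "NOT_EXPRESSED",
    "CENTROIDS",
    "classify_triad",
    "classify_all",
    "transition_table",
    "bias_concordance",
    "read_triad_table",
]

# enumeration order doubles as the deterministic tie-break order
BIAS_CATEGORIES = [
    "Balanced",
    "ADominant",
    "BDominant",
    "DDominant",
    "ASuppressed",
    "BSuppressed",
    "DSuppressed",
]
NOT_EXPRESSED = "NotExpressed"
ALL_CATEGORIES = BIAS_CATEGORIES + [NOT_EXPRESSED]

CENTROIDS: dict[str, tuple[float, float, float]] = {
    "Balanced": (1 / 3, 1 / 3, 1 / 3),
    "ADominant": (1.0, 0.0, 0.0),
    "BDominant": (0.0, 1.0, 0.0),
    "DDominant": (0.0, 0.0, 1.0),
    "ASuppressed": (0.0, 0.5, 0.5),
    "BSuppressed": (0.5, 0.0, 0.5),
    "DSuppressed": (0.5, 0.5, 0.0),
}

MIN_SUM_DEFAULT = 0.5


@dataclass(frozen=True)
class TriadRecord:
    """Triple of homeologous gene IDs on the A, B and D subgenomes."""

    triad_id: str
    gene_a: str
    gene_b: str
    gene_d: str

    def __post_init__(self) -> None:
        if len({self.gene_a, self.gene_b, self.gene_d}) != 3:
            raise ValueError(f"triad {self.triad_id}: gene IDs must be distinct")

    @property
    def genes(self) -> tuple[str, str, str]:
        return (self.gene_a, self.gene_b, self.gene_d)


@dataclass
class TriadProfile:
    """Per-tissue ternary coordinates and category of one triad."""

    triad_id: str
    tissue: str
    values: tuple[float, float, float]
    fractions: tuple[float, float, float]
    category: str
    distance: float


def classify_triad(
    v_a: float,
    v_b: float,
    v_d: float,
    min_sum: float = MIN_SUM_DEFAULT,
    centroids: dict | None = None,
) -> tuple[str, tuple[float, float, float], float]:
    """Classify one (A, B, D) value triple.

    Returns ``(category, fractions, distance_to_winning_centroid)``.  Below
    ``min_sum`` total the triad is NotExpressed with zero fractions.  Ties go
    to Balanced first, then enumeration order — a rule that preserves A<->B
    permutation equivariance (see tests).
    """
    if v_a < 0 or v_b < 0 or v_d < 0:
        raise ValueError("triad values must be non-negative")
    total = v_a + v_b + v_d
    if total < min_sum:
        return NOT_EXPRESSED, (0.0, 0.0, 0.0), float("nan")
    fracs = (v_a / total, v_b / total, v_d / total)
    table = centroids if centroids is not None else CENTROIDS
    best_cat, best_d = None, math.inf
    for cat in BIAS_CATEGORIES:
        c = table[cat]
        d = math.dist(fracs, c)
        if d < best_d - 1e-12:
            best_cat, best_d = cat, d
    return best_cat, fracs, best_d


def classify_all(
    triads: list[TriadRecord],
    value_matrix: pd.DataFrame,
    min_sum: float = MIN_SUM_DEFAULT,
) -> pd.DataFrame:
    """Classify every triad in every tissue.

    ``value_matrix`` is genes x tissues (mean TPM over replicates for
    expression mode, promoter accessibility scores for accessibility mode —
    the classifier is identical).  Triads with a missing gene are skipped
    with a warning.  Returns a tidy frame: triad_id, tissue, vA..vD, fA..fD,
    category, distance.
    """
    rows = []
    skipped = 0
    for triad in triads:
        if any(g not in value_matrix.index for g in triad.genes):
            skipped += 1
            continue
        sub = value_matrix.loc[list(triad.genes)]
        for tissue in value_matrix.columns:
            va, vb, vd = (float(x) for x in sub[tissue])
            cat, fracs, dist = classify_triad(va, vb, vd, min_sum=min_sum)
            rows.append(
                {
                    "triad_id": triad.triad_id,
                    "tissue": tissue,
                    "vA": va, "vB": vb, "vD": vd,
                    "fA": fracs[0], "fB": fracs[1], "fD": fracs[2],
                    "category": cat,
                    "distance": dist,
                }
            )
    if skipped:
        warnings.warn(f"{skipped} triad(s) skipped: gene missing from matrix", stacklevel=2)
    return pd.DataFrame(rows)


def transition_table(
    profiles: pd.DataFrame, tissue_order: list[str]
) -> dict[tuple[str, str], pd.DataFrame]:
    """Category-transition counts for each adjacent tissue pair.

    Returns ``{(tissue_i, tissue_{i+1}): 8x8 frame}`` over all categories
    including NotExpressed; each row sum over a full table equals the number
    of classified triads.
    """
    for t in tissue_order:
        if t not in set(profiles["tissue"]):
            raise ValueError(f"tissue {t!r} missing from profiles")
    wide = profiles.pivot(index="triad_id", columns="tissue", values="category")
    out = {}
    for t_from, t_to in zip(tissue_order, tissue_order[1:]):
        table = pd.DataFrame(0, index=ALL_CATEGORIES, columns=ALL_CATEGORIES)
        counted = wide[[t_from, t_to]].dropna()
        for (c_from, c_to), n in counted.value_counts().items():
            table.loc[c_from, c_to] += int(n)
        out[(t_from, t_to)] = table
    return out


def transitions_tidy(tables: dict[tuple[str, str], pd.DataFrame]) -> pd.DataFrame:
    """Long-format transition table for Sankey rendering."""
    rows = []
    for (t_from, t_to), table in tables.items():
        for c_from in table.index:
            for c_to in table.columns:
                n = int(table.loc[c_from, c_to])
                if n:
                    rows.append(
                        {"from_tissue": t_from, "to_tissue": t_to,
                         "from_category": c_from, "to_category": c_to, "count": n}
                    )
    return pd.DataFrame(rows)


def bias_concordance(
    expr_profiles: pd.DataFrame, acc_profiles: pd.DataFrame
) -> pd.DataFrame:
    """Agreement between expression-based and accessibility-based bias.

    Per tissue: the category agreement rate over common triads, and the
    Pearson correlation between expression fractions and accessibility
    fractions pooled over triads (three values per triad).  NotExpressed
    profiles on either side are excluded from both statistics.
    """
    merged = expr_profiles.merge(
        acc_profiles, on=["triad_id", "tissue"], suffixes=("_expr", "_acc")
    )
    merged = merged[
        (merged["category_expr"] != NOT_EXPRESSED)
        & (merged["category_acc"] != NOT_EXPRESSED)
    ]
    if merged.empty:
        raise ValueError("no common classified triads between the two profiles")
    rows = []
    for tissue, sub in merged.groupby("tissue", sort=False):
        agree = float((sub["category_expr"] == sub["category_acc"]).mean())
        x = sub[["fA_expr", "fB_expr", "fD_expr"]].to_numpy().ravel()
        y = sub[["fA_acc", "fB_acc", "fD_acc"]].to_numpy().ravel()
        if np.std(x) == 0 or np.std(y) == 0:
            r, pval = float("nan"), float("nan")
        else:
            r, pval = stats.pearsonr(x, y)
        rows.append(
            {"tissue": tissue, "agreement": agree, "pearson_r": float(r),
             "pearson_p": float(pval), "n_triads": len(sub)}
        )
    return pd.DataFrame(rows)


def read_triad_table(path) -> list[TriadRecord]:
    """TSV with columns triad_id, gene_a, gene_b, gene_d (header optional)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    first = df.columns[0]
    if first not in ("triad_id", "triad"):  # headerless file: re-read
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["triad_id", "gene_a", "gene_b", "gene_d"],
        )
    df.columns = ["triad_id", "gene_a", "gene_b", "gene_d"]
    return [
        TriadRecord(str(r.triad_id), str(r.gene_a), str(r.gene_b), str(r.gene_d))
        for r in df.itertuples(index=False)
    ]
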