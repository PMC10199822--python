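"""Pairwise differential calling and eight-way tissue-specificity clustering.

Accessibility scores are CPM-in-peaks (integrations in a region, per million
in-region integrations of the sample).  Differential calls use a two-sample
t-test on log2(score + 1) with empirical-Bayes variance moderation (pooling
information across features rescues power at two replicates), Benjamini-
Hochberg adjustment per comparison, and a fold-change gate.  A feature's
per-tissue presence pattern is mapped onto the eight specificity clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .acr_refinement import ACR, AccessibilitySignal
from .genomic_core import GeneModel, GenomicInterval, promoter_region

__all__ = [
    "CLUSTERS",
    "UNASSIGNED",
    "cluster_patterns",
    "assign_specificity",
    "normalize_acr_scores",
    "pairwise_diff",
    "moderated_ttest",
    "all_pairwise",
    "presence_vector",
    "assign_clusters",
    "call_degs",
    "size_factors",
    "associate_acr_genes",
    "overlap_enrichment",
    "EnrichmentResult",
    "promoter_accessibility_matrix",
    "tissue_means",
]

# canonical cluster labels; index 0 of the tissue vector is the control
# tissue (leaf), 1..4 the four developmental stages.
CLUSTERS = [
    "Leafs",
    "DAP5s",
    "DAP9s",
    "DAP5and9s",
    "DAP15s",
    "DAP20s",
    "DAP15and20s",
    "AllGs",
]
UNASSIGNED = "Unassigned"

_PATTERNS: dict[frozenset, str] = {
    frozenset({0}): "Leafs",
    frozenset({1}): "DAP5s",
    frozenset({2}): "DAP9s",
    frozenset({1, 2}): "DAP5and9s",
    frozenset({3}): "DAP15s",
    frozenset({4}): "DAP20s",
    frozenset({3, 4}): "DAP15and20s",
    frozenset({1, 2, 3, 4}): "AllGs",
}


def cluster_patterns(tissues: list[str]) -> dict[str, frozenset]:
    """Map cluster label -> frozenset of tissue names for a 5-tissue panel."""
    if len(tissues) != 5:
        raise ValueError("specificity clustering expects exactly 5 tissues")
    return {
        label: frozenset(tissues[i] for i in idx) for idx, label in _PATTERNS.items()
    }


def assign_specificity(presence) -> str:
    """Exact-pattern map from a 5-long boolean presence vector to a cluster.

    Patterns outside the eight enumerated ones (including all-false and
    all-true) are Unassigned.
    """
    presence = list(presence)
    if len(presence) != 5:
        raise ValueError(f"presence vector must have length 5, got {len(presence)}")
    key = frozenset(i for i, flag in enumerate(presence) if flag)
    return _PATTERNS.get(key, UNASSIGNED)


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def normalize_acr_scores(
    acrs: list[ACR] | list[GenomicInterval],
    signals: list[AccessibilitySignal],
) -> pd.DataFrame:
    """CPM-in-peaks score matrix, features x samples.

    ``score(acr, sample) = 1e6 * integrations_in_acr / total_in_acr_integrations``.
    Doubling a sample's depth uniformly leaves scores unchanged.
    """
    intervals = [a.interval if isinstance(a, ACR) else a for a in acrs]
    ids = [
        iv.name or f"{iv.chrom}:{iv.start}-{iv.end}" for iv in intervals
    ]
    data = {}
    cpm_per_count = []
    for sig in signals:
        counts = np.array([sig.count_in(iv) for iv in intervals], dtype=float)
        total = counts.sum()
        if total == 0:
            raise ValueError(f"sample {sig.sample_id} has zero in-peak integrations")
        data[sig.sample_id] = counts * 1e6 / total
        cpm_per_count.append(1e6 / total)
    out = pd.DataFrame(data, index=ids)
    # CPM equivalent of a single integration: the natural pseudocount scale
    # for log-transforming these scores (carried for downstream tests)
    out.attrs["cpm_per_count"] = float(np.mean(cpm_per_count))
    return out


def tissue_means(scores: pd.DataFrame, sample_tissues: dict[str, str]) -> pd.DataFrame:
    """Collapse a features x samples matrix to features x tissues by mean."""
    tissues: list[str] = []
    for s in scores.columns:
        t = sample_tissues[s]
        if t not in tissues:
            tissues.append(t)
    return pd.DataFrame(
        {
            t: scores[[s for s in scores.columns if sample_tissues[s] == t]].mean(axis=1)
            for t in tissues
        }
    )


# ---------------------------------------------------------------------------
# Moderated two-sample test
# ---------------------------------------------------------------------------

def _inv_trigamma(y: float) -> float:
    # Newton iteration on trigamma(x) = y; y > 0, trigamma decreasing
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = (tri - y) / special.polygamma(2, x)
        if not np.isfinite(step):
            break
        x = max(x - step, 1e-8)
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of a scaled inverse-chi-square prior on residual
    variances (prior df d0 and prior variance s0^2).

    ``d0 = inf`` means the observed variances are no more dispersed than the
    chi-square sampling noise, i.e. a common variance is appropriate.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(s2[ok].mean()) if ok.any() else 1e-8
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2))
    if e_var <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(np.mean(e)))
    else:
        d0 = 2 * _inv_trigamma(e_var)
        if not np.isfinite(d0) or d0 <= 0:
            d0 = np.inf
            s0_2 = float(np.exp(np.mean(e)))
        else:
            s0_2 = float(
                np.exp(np.mean(e) + special.digamma(d0 / 2) - np.log(d0 / 2))
            )
    if not np.isfinite(s0_2) or s0_2 <= 0:
        d0, s0_2 = np.inf, max(float(np.mean(s2[ok])), 1e-12)
    return d0, s0_2


def moderated_ttest(
    group_a: np.ndarray, group_b: np.ndarray, moderation: str = "pool"
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample t-test per feature (rows) with optional variance moderation.

    Parameters
    ----------
    group_a, group_b : 2-D arrays, features x replicates.
    moderation : "pool" shrinks per-feature pooled variances toward an
        empirical-Bayes prior fitted across features (gaining degrees of
        freedom); "none" is the plain pooled-variance t-test.

    Returns
    -------
    (t, p) arrays; two-sided p-values.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 replicates per group for the t-test")
    df = na + nb - 2
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    ss = a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)
    s2 = ss / df
    if moderation == "pool":
        d0, s0_2 = _fit_variance_prior(s2, df)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_2)
            df_post = np.inf
        else:
            s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
            df_post = d0 + df
    elif moderation == "none":
        s2_post, df_post = s2, df
    else:
        raise ValueError(f"unknown moderation mode {moderation!r}")
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (mean_a - mean_b) / se, np.where(mean_a != mean_b, np.inf, 0.0))
    t = np.where((se == 0) & (mean_a < mean_b), -np.abs(t), t)
    if np.isinf(df_post):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_post)
    p = np.where(np.isinf(t), 0.0, p)
    return t, p


def pairwise_diff(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    min_fc: float = 2.0,
    alpha: float = 0.05,
    pseudo: float = 1.0,
    moderation: str = "pool",
    fc_strict: bool = False,
) -> pd.DataFrame:
    """Differential call between two tissues from replicate score matrices.

    log2FC is computed on pseudocounted replicate means; p-values come from a
    t-test on log2(score + pseudo) across replicates and are BH-adjusted
    across features.  ``call`` is +1 (A up), -1 (A down) or 0; it requires
    both the adjusted p below ``alpha`` and |log2FC| at (or, with
    ``fc_strict``, strictly above) log2(min_fc).

    With a single replicate per side, falls back to fold-change-only calls
    with a warning (p and padj are NaN).
    """
    a = np.atleast_2d(np.asarray(scores_a, dtype=float))
    b = np.atleast_2d(np.asarray(scores_b, dtype=float))
    if a.shape[0] != b.shape[0]:
        raise ValueError("feature sets differ between the two groups")
    log2fc = np.log2(a.mean(axis=1) + pseudo) - np.log2(b.mean(axis=1) + pseudo)
    fc_gate = (
        np.abs(log2fc) > np.log2(min_fc) if fc_strict else np.abs(log2fc) >= np.log2(min_fc)
    )
    if a.shape[1] < 2 or b.shape[1] < 2:
        warnings.warn("single replicate: fold-change-only calls", stacklevel=2)
        p = np.full(a.shape[0], np.nan)
        padj = p
        sig = np.ones(a.shape[0], dtype=bool)
    else:
        _, p = moderated_ttest(np.log2(a + pseudo), np.log2(b + pseudo), moderation)
        padj = multipletests(p, method="fdr_bh")[1]
        sig = padj < alpha
    call = np.where(fc_gate & sig, np.sign(log2fc).astype(int), 0)
    return pd.DataFrame({"log2fc": log2fc, "p": p, "padj": padj, "call": call})


def all_pairwise(
    rep_scores: pd.DataFrame,
    sample_tissues: dict[str, str],
    min_fc: float = 2.0,
    alpha: float = 0.05,
    pseudo: float | str = "auto",
    moderation: str = "pool",
    fc_strict: bool = False,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Run :func:`pairwise_diff` for every unordered tissue pair.

    ``pseudo="auto"`` uses the matrix's ``cpm_per_count`` annotation (the CPM
    value of one integration) when present, else 1 — on CPM scales a
    pseudocount of 1 is far below the granularity of the data and leaves the
    log-variance of near-empty features enormous.  Returns
    ``{(tissue_a, tissue_b): frame}`` with calls oriented as A vs B.
    """
    if pseudo == "auto":
        pseudo = float(rep_scores.attrs.get("cpm_per_count", 1.0))
    tissues: list[str] = []
    for s in rep_scores.columns:
        t = sample_tissues[s]
        if t not in tissues:
            tissues.append(t)
    groups = {
        t: rep_scores[[s for s in rep_scores.columns if sample_tissues[s] == t]].to_numpy()
        for t in tissues
    }
    out = {}
    for i, ta in enumerate(tissues):
        for tb in tissues[i + 1 :]:
            frame = pairwise_diff(
                groups[ta], groups[tb], min_fc, alpha, pseudo, moderation, fc_strict
            )
            frame.index = rep_scores.index
            out[(ta, tb)] = frame
    return out


def _call(pair_results, ta: str, tb: str, feature) -> int:
    """Signed call for tissue ``ta`` vs ``tb`` regardless of stored orientation."""
    if (ta, tb) in pair_results:
        return int(pair_results[(ta, tb)]["call"].loc[feature])
    return -int(pair_results[(tb, ta)]["call"].loc[feature])


def presence_vector(
    pair_results: dict[tuple[str, str], pd.DataFrame],
    tissues: list[str],
    feature,
    strict: bool = True,
) -> list[bool]:
    """Per-tissue presence flags for one feature.

    The candidate high set H holds every tissue never called down against any
    other tissue.  Presence requires (strict mode) every tissue in H to be
    called up against every tissue outside H; if that fails the vector is
    all-false.  Loose mode requires an up-call against at least one outside
    tissue per member.
    """
    high = []
    for t in tissues:
        if all(_call(pair_results, t, u, feature) >= 0 for u in tissues if u != t):
            high.append(t)
    outside = [t for t in tissues if t not in high]
    for t in high:
        calls = [_call(pair_results, t, u, feature) for u in outside]
        ok = all(c > 0 for c in calls) if strict else (not outside or any(c > 0 for c in calls))
        if not ok:
            return [False] * len(tissues)
    return [t in high for t in tissues]


def assign_clusters(
    pair_results: dict[tuple[str, str], pd.DataFrame],
    tissues: list[str],
    strict: bool = True,
) -> pd.DataFrame:
    """Cluster every feature that has at least one differential call.

    Returns a frame indexed by feature with per-tissue presence columns, a
    ``cluster`` column and ``n_calls`` (features with zero calls are dropped:
    they are not differential).
    """
    features = next(iter(pair_results.values())).index
    any_call = pd.Series(0, index=features)
    for frame in pair_results.values():
        any_call = any_call + frame["call"].abs()
    rows = []
    for feat in features:
        if any_call.loc[feat] == 0:
            continue
        pres = presence_vector(pair_results, tissues, feat, strict=strict)
        # the eight-cluster map is defined for the canonical 5-tissue panel
        label = assign_specificity(pres) if len(tissues) == 5 else UNASSIGNED
        rows.append(
            {"feature": feat, **{t: f for t, f in zip(tissues, pres)},
             "cluster": label, "n_calls": int(any_call.loc[feat])}
        )
    return pd.DataFrame(rows).set_index("feature") if rows else pd.DataFrame(
        columns=[*tissues, "cluster", "n_calls"]
    )


# ---------------------------------------------------------------------------
# Expression differential calls
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors (reference = per-gene geometric
    mean over samples, genes expressed everywhere only)."""
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample")
    log_ref = np.log(arr[positive]).mean(axis=1)
    sf = np.exp(np.median(np.log(arr[positive]) - log_ref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns)


def call_degs(
    counts: pd.DataFrame,
    sample_tissues: dict[str, str],
    min_fc: float = 2.0,
    alpha: float = 0.01,
    moderation: str = "pool",
    strict: bool = True,
    external_calls: dict[tuple[str, str], pd.DataFrame] | None = None,
) -> tuple[dict[tuple[str, str], pd.DataFrame], pd.DataFrame]:
    """Differential expression across all tissue pairs plus clustering.

    Counts are normalized by median-of-ratios size factors, then tested per
    pair exactly as accessibility scores (moderated t on log2(norm + 1), BH).
    Call thresholds default to adjusted p < 0.01 and |log2FC| > 1 (strict
    inequality on the fold gate).  ``external_calls`` — frames matching the
    :func:`pairwise_diff` output — bypass the internal test verbatim.

    Returns ``(pair_results, cluster_frame)``.
    """
    if external_calls is not None:
        tissues: list[str] = []
        for s in counts.columns:
            t = sample_tissues[s]
            if t not in tissues:
                tissues.append(t)
        return external_calls, assign_clusters(external_calls, tissues, strict=strict)
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            warnings.warn("non-integer counts rounded", stacklevel=2)
        arr = np.round(arr)
    counts = pd.DataFrame(arr.astype(np.int64), index=counts.index, columns=counts.columns)
    nonzero = counts.sum(axis=1) > 0
    counts = counts.loc[nonzero]
    sf = size_factors(counts)
    norm = counts / sf
    pair_results = all_pairwise(
        norm, sample_tissues, min_fc=min_fc, alpha=alpha,
        moderation=moderation, fc_strict=True,
    )
    tissues = list(dict.fromkeys(sample_tissues[s] for s in counts.columns))
    return pair_results, assign_clusters(pair_results, tissues, strict=strict)


# ---------------------------------------------------------------------------
# ACR-gene association and enrichment
# ---------------------------------------------------------------------------

def associate_acr_genes(
    acrs: list[ACR],
    genes: list[GeneModel],
    clusters: pd.Series | dict | None = None,
    window: int = 2000,
) -> dict[str, list[str]]:
    """Genes associated with each ACR cluster.

    A gene associates with an ACR when the gene body extended by ``window`` bp
    on both sides overlaps the ACR by >= 1 bp.  ``clusters`` maps ACR index or
    id to a cluster label; without it all ACRs go into one "all" group.
    Returns cluster -> sorted unique gene list.
    """
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    out: dict[str, set[str]] = {}
    for i, acr in enumerate(acrs):
        iv = acr.interval
        if clusters is None:
            label = "all"
        else:
            acr_id = iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"
            if acr_id in clusters:
                label = clusters[acr_id]
            elif i in clusters:
                label = clusters[i]
            else:
                continue  # unlabeled ACRs do not contribute
        hits = out.setdefault(label, set())
        for g in genes_by_chrom.get(iv.chrom, []):
            if g.interval.start - window < iv.end and iv.start < g.interval.end + window:
                hits.add(g.gene_id)
    return {label: sorted(members) for label, members in out.items()}


@dataclass
class EnrichmentResult:
    """Permutation overlap enrichment of two gene sets within a universe."""

    observed: int
    null: np.ndarray
    seed: int
    n_shuffles: int = field(init=False)
    p: float = field(init=False)
    fold: float = field(init=False)
    fold_infinite: bool = field(init=False)

    def __post_init__(self) -> None:
        self.n_shuffles = len(self.null)
        self.p = (1 + int(np.sum(self.null >= self.observed))) / (1 + self.n_shuffles)
        null_mean = float(np.mean(self.null)) if self.n_shuffles else 0.0
        self.fold_infinite = null_mean == 0
        self.fold = float("inf") if self.fold_infinite else self.observed / null_mean


def overlap_enrichment(
    set_a, set_b, universe, n_shuffles: int = 1000, seed: int = 0
) -> EnrichmentResult:
    """Empirical overlap enrichment: redraw |A| genes uniformly without
    replacement from the universe ``n_shuffles`` times and intersect with B.

    ``p = (1 + #{null >= observed}) / (1 + n_shuffles)``, deterministic under
    ``seed``.
    """
    universe = list(dict.fromkeys(universe))
    set_a, set_b = set(set_a), set(set_b)
    if not set_a <= set(universe) or not set_b <= set(universe):
        raise ValueError("set_a and set_b must be subsets of the universe")
    n_a = len(set_a)
    if n_a > len(universe):
        raise ValueError("|A| exceeds the universe size")
    observed = len(set_a & set_b)
    in_b = np.array([g in set_b for g in universe])
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles, dtype=np.int64)
    for i in range(n_shuffles):
        idx = rng.choice(len(universe), size=n_a, replace=False)
        null[i] = int(in_b[idx].sum())
    return EnrichmentResult(observed=observed, null=null, seed=seed)


def promoter_accessibility_matrix(
    genes: list[GeneModel],
    signals: list[AccessibilitySignal],
    chrom_lengths: dict[str, int] | None = None,
    upstream: int = 2000,
    downstream: int = 100,
) -> pd.DataFrame:
    """Promoter-window accessibility scores, genes x samples.

    The promoter is the strand-aware window around the TSS; scores are CPM
    within all promoter windows (same normalization as ACR scores).  Row
    order matches the input gene order.
    """
    windows = []
    for g in genes:
        clen = chrom_lengths.get(g.chrom) if chrom_lengths else None
        iv, _ = promoter_region(g, upstream, downstream, chrom_length=clen)
        windows.append(iv)
    data = {}
    cpm_per_count = []
    for sig in signals:
        counts = np.array([sig.count_in(iv) for iv in windows], dtype=float)
        total = counts.sum()
        data[sig.sample_id] = counts * 1e6 / total if total > 0 else counts
        if total > 0:
            cpm_per_count.append(1e6 / total)
    out = pd.DataFrame(data, index=[g.gene_id for g in genes])
    out.attrs["cpm_per_count"] = float(np.mean(cpm_per_count)) if cpm_per_count else 1.0
    return out
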