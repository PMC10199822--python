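"""Post-peak-calling refinement of accessible chromatin regions (ACRs).

Raw candidate peaks are split into sliding bins, bins are kept when their
transposase-integration density clears a cutoff, surviving bins are merged,
and merged regions overlapping a blacklist or organelle-homology mask are
discarded.  The module also annotates ACRs (genic / proximal / distal),
computes replicate-correlation QC and sequence-variation metaprofiles.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .genomic_core import (
    GeneModel,
    GenomeIndex,
    GenomicInterval,
    overlaps_any,
)

__all__ = [
    "AccessibilitySignal",
    "ACR",
    "split_into_bins",
    "integration_density",
    "density_cutoff",
    "merge_bins",
    "refine_peaks",
    "classify_acrs",
    "tissue_union_acrs",
    "replicate_correlation",
    "variation_metaprofile",
]

BIN_SIZE_DEFAULT = 150
BIN_STEP_DEFAULT = 50
MERGE_GAP_DEFAULT = 150
CLASS_CUTOFF_DEFAULT = 2000
CLASS_CUTOFF_SCAN = [2000, 4000, 5000, 6000, 8000, 10000]


@dataclass
class AccessibilitySignal:
    """Per-sample transposase integration sites ("TISs").

    ``positions`` maps chrom -> sorted int64 array of 0-based integration
    positions.  ``total`` is the grand total across chromosomes.
    """

    sample_id: str
    tissue: str
    replicate: int
    positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean = {}
        for chrom, pos in self.positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if arr.size and np.any(np.diff(arr) < 0):
                arr = np.sort(arr)
            clean[chrom] = arr
        self.positions = clean

    @property
    def total(self) -> int:
        return int(sum(p.size for p in self.positions.values()))

    def count_in(self, interval: GenomicInterval) -> int:
        pos = self.positions.get(interval.chrom)
        if pos is None or pos.size == 0:
            return 0
        lo = np.searchsorted(pos, interval.start, side="left")
        hi = np.searchsorted(pos, interval.end, side="left")
        return int(hi - lo)

    @classmethod
    def from_bed(cls, path, sample_id: str, tissue: str, replicate: int) -> "AccessibilitySignal":
        """Load integration positions from a BED of single-bp records (start used)."""
        from .genomic_core import read_bed

        by_chrom: dict[str, list[int]] = {}
        for iv in read_bed(path):
            by_chrom.setdefault(iv.chrom, []).append(iv.start)
        return cls(sample_id, tissue, replicate, {c: np.array(v) for c, v in by_chrom.items()})


@dataclass
class ACR:
    """A refined accessible chromatin region with annotation fields."""

    interval: GenomicInterval
    tissue_of_call: str | None = None
    acr_class: str | None = None  # genic / proximal / distal
    nearest_gene_id: str | None = None
    distance_to_gene: int | None = None
    source_peaks: list[str] = field(default_factory=list)
    scores: dict[str, float] = field(default_factory=dict)

    @property
    def center(self) -> int:
        return self.interval.center


# ---------------------------------------------------------------------------
# Refinement primitives
# ---------------------------------------------------------------------------

def split_into_bins(
    peak: GenomicInterval, bin_size: int = BIN_SIZE_DEFAULT, step: int = BIN_STEP_DEFAULT
) -> list[GenomicInterval]:
    """Sliding bins over a peak: starts at ``peak.start + k*step`` while the
    full bin fits inside the peak.  A peak shorter than ``bin_size`` yields a
    single peak-sized bin rather than being dropped.
    """
    if bin_size <= 0 or step <= 0:
        raise ValueError("bin_size and step must be positive")
    if len(peak) < bin_size:
        return [GenomicInterval(peak.chrom, peak.start, peak.end)]
    bins = []
    start = peak.start
    while start + bin_size <= peak.end:
        bins.append(GenomicInterval(peak.chrom, start, start + bin_size))
        start += step
    return bins


def integration_density(bin_iv: GenomicInterval, signal: AccessibilitySignal) -> float:
    """Integrations per bp inside ``bin_iv`` (binary-search count / length)."""
    return signal.count_in(bin_iv) / len(bin_iv)


def density_cutoff(
    signal: AccessibilitySignal,
    genome: GenomeIndex,
    alpha: float = 1e-4,
    bin_size: int = BIN_SIZE_DEFAULT,
    override: float | None = None,
) -> float:
    """Self-calibrating integration-density cutoff (integrations per bp).

    The genome-wide background rate is ``lambda = total / genome_length``; the
    cutoff is the smallest ``k / bin_size`` such that the Poisson upper tail
    ``P(X >= k)`` at mean ``bin_size * lambda`` falls below ``alpha``.  A
    user-supplied ``override`` short-circuits the rule.
    """
    if override is not None:
        return float(override)
    glen = genome.total_length
    if glen <= 0:
        raise ValueError("zero-length genome")
    total = signal.total
    if total <= 0:
        raise ValueError("signal has no integrations")
    mu = bin_size * total / glen
    # P(X >= k) = 1 - CDF(k - 1); find smallest such k
    k = int(stats.poisson.isf(alpha, mu)) + 1
    while k > 1 and stats.poisson.sf(k - 2, mu) < alpha:
        k -= 1
    while stats.poisson.sf(k - 1, mu) >= alpha:
        k += 1
    return k / bin_size


def merge_bins(
    bins: Sequence[GenomicInterval], gap: int = MERGE_GAP_DEFAULT
) -> list[GenomicInterval]:
    """bedtools-style merge: union intervals whose gap (next.start - cur.end)
    is ``<= gap``.  All bins must share one chromosome; output is sorted with
    pairwise gaps ``> gap``.
    """
    if not bins:
        return []
    chroms = {b.chrom for b in bins}
    if len(chroms) > 1:
        raise ValueError(f"merge_bins requires one chromosome, got {sorted(chroms)}")
    chrom = chroms.pop()
    spans = sorted((b.start, b.end) for b in bins)
    merged: list[list[int]] = [list(spans[0])]
    for start, end in spans[1:]:
        if start - merged[-1][1] <= gap:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [GenomicInterval(chrom, s, e) for s, e in merged]


def refine_peaks(
    raw_peaks: Sequence[GenomicInterval],
    signal: AccessibilitySignal,
    genome: GenomeIndex,
    blacklist: Sequence[GenomicInterval] = (),
    organelle_regions: Sequence[GenomicInterval] = (),
    bin_size: int = BIN_SIZE_DEFAULT,
    step: int = BIN_STEP_DEFAULT,
    merge_gap: int = MERGE_GAP_DEFAULT,
    alpha: float = 1e-4,
    cutoff_override: float | None = None,
    tissue: str | None = None,
) -> list[ACR]:
    """Full refinement: split -> density filter -> merge -> mask filter.

    Any merged interval overlapping the blacklist or an organelle-homology
    region by >= 1 bp is discarded.  Survivors carry source-peak provenance.
    """
    cutoff = density_cutoff(
        signal, genome, alpha=alpha, bin_size=bin_size, override=cutoff_override
    )
    passing: dict[str, list[GenomicInterval]] = {}
    peak_ids: dict[str, list[tuple[int, int, str]]] = {}
    for i, peak in enumerate(raw_peaks):
        pid = peak.name or f"peak{i}"
        peak_ids.setdefault(peak.chrom, []).append((peak.start, peak.end, pid))
        for b in split_into_bins(peak, bin_size, step):
            if integration_density(b, signal) >= cutoff:
                passing.setdefault(peak.chrom, []).append(b)

    masks = list(blacklist) + list(organelle_regions)
    acrs: list[ACR] = []
    for chrom in sorted(passing):
        merged = merge_bins(passing[chrom], gap=merge_gap)
        if masks:
            keep = ~overlaps_any(merged, masks)
        else:
            keep = np.ones(len(merged), dtype=bool)
        spans = peak_ids.get(chrom, [])
        for iv, ok in zip(merged, keep):
            if not ok:
                continue
            sources = [pid for s, e, pid in spans if s < iv.end and iv.start < e]
            acrs.append(ACR(interval=iv, tissue_of_call=tissue, source_peaks=sources))
    return acrs


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _gene_edge_distance(point: int, g: GeneModel) -> int:
    iv = g.interval
    if iv.start <= point < iv.end:
        return 0
    return min(abs(point - iv.start), abs(point - (iv.end - 1)))


def classify_acrs(
    acrs: Sequence[ACR],
    genes: Sequence[GeneModel],
    cutoff: int = CLASS_CUTOFF_DEFAULT,
) -> None:
    """Assign genic / proximal / distal classes in place (precedence in that
    order) and annotate the nearest gene.

    genic: center inside a gene body.  proximal: center within ``cutoff`` bp
    upstream of a TSS or downstream of a TES (strand-aware).  distal:
    everything else.  ACRs on chromosomes without genes stay unclassified with
    ``nearest_gene_id=None``.
    """
    if not genes:
        raise ValueError("gene set is empty")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda g: g.interval.start)

    for acr in acrs:
        center = acr.center
        chrom_genes = by_chrom.get(acr.interval.chrom)
        if not chrom_genes:
            acr.acr_class = None
            acr.nearest_gene_id = None
            acr.distance_to_gene = None
            continue
        best: tuple[int, str] | None = None
        genic = False
        proximal = False
        for g in chrom_genes:
            d = _gene_edge_distance(center, g)
            key = (d, g.gene_id)
            if best is None or key < best:
                best = key
            if d == 0:
                genic = True
                continue
            tss, tes = g.tss, g.tes
            if g.strand == "+":
                upstream_ok = tss - cutoff <= center < tss
                downstream_ok = tes < center <= tes + cutoff
            else:
                upstream_ok = tss < center <= tss + cutoff
                downstream_ok = tes - cutoff <= center < tes
            if upstream_ok or downstream_ok:
                proximal = True
        acr.nearest_gene_id = best[1]
        acr.distance_to_gene = best[0]
        acr.acr_class = "genic" if genic else ("proximal" if proximal else "distal")


def tissue_union_acrs(per_tissue: dict[str, Sequence[ACR]]) -> list[dict]:
    """Union ACR set across tissues: merge (gap 0) of all per-tissue ACRs,
    with per-tissue membership flagged by >= 1 bp overlap.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for acr_list in per_tissue.values():
        for acr in acr_list:
            by_chrom.setdefault(acr.interval.chrom, []).append(acr.interval)
    records = []
    for chrom in sorted(by_chrom):
        for iv in merge_bins(by_chrom[chrom], gap=0):
            membership = {
                t: bool(overlaps_any([iv], [a.interval for a in acr_list])[0])
                for t, acr_list in per_tissue.items()
            }
            records.append({"interval": iv, "membership": membership})
    return records


# ---------------------------------------------------------------------------
# QC & metaprofiles
# ---------------------------------------------------------------------------

def replicate_correlation(
    signal_a: AccessibilitySignal,
    signal_b: AccessibilitySignal,
    genome: GenomeIndex,
    bin_bp: int = 1000,
) -> float:
    """Pearson r between log2(count+1) genome-wide window counts of two samples.

    Returns NaN (with a warning) if either vector is constant.
    """
    va, vb = [], []
    for chrom, length in genome.chrom_lengths.items():
        n_bins = int(np.ceil(length / bin_bp))
        edges = np.arange(n_bins + 1) * bin_bp
        edges[-1] = length
        for sig, acc in ((signal_a, va), (signal_b, vb)):
            pos = sig.positions.get(chrom, np.empty(0, dtype=np.int64))
            counts, _ = np.histogram(pos, bins=edges)
            acc.append(counts)
    xa = np.log2(np.concatenate(va) + 1.0)
    xb = np.log2(np.concatenate(vb) + 1.0)
    if np.all(xa == xa[0]) or np.all(xb == xb[0]):
        warnings.warn("constant count vector; correlation undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(xa, xb)[0, 1])


def variation_metaprofile(
    acrs: Sequence[ACR],
    variants: dict[str, np.ndarray],
    genes: Sequence[GeneModel],
    flank: int = 2000,
    bin_bp: int = 50,
    min_gene_distance: int = 2000,
) -> np.ndarray:
    """Variant density around centers of gene-distal ACRs.

    Only ACRs whose center lies more than ``min_gene_distance`` bp from every
    gene are used.  Variant positions are counted in ``bin_bp`` offset bins
    spanning ``[center - flank, center + flank)``; density is variants per bp
    per ACR.  Returns a vector of length ``2 * flank / bin_bp`` (empty, with a
    warning, when no ACR qualifies).
    """
    n_bins = (2 * flank) // bin_bp
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    qualifying = []
    for acr in acrs:
        chrom_genes = genes_by_chrom.get(acr.interval.chrom, [])
        center = acr.center
        if all(_gene_edge_distance(center, g) > min_gene_distance for g in chrom_genes):
            qualifying.append(acr)
    if not qualifying:
        warnings.warn("no ACR centers beyond min_gene_distance; empty profile", stacklevel=2)
        return np.zeros(0)

    counts = np.zeros(n_bins)
    sorted_variants = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in variants.items()}
    for acr in qualifying:
        pos = sorted_variants.get(acr.interval.chrom)
        if pos is None or pos.size == 0:
            continue
        center = acr.center
        lo = np.searchsorted(pos, center - flank, side="left")
        hi = np.searchsorted(pos, center + flank, side="left")
        offsets = pos[lo:hi] - (center - flank)
        np.add.at(counts, offsets // bin_bp, 1)
    return counts / (bin_bp * len(qualifying))
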