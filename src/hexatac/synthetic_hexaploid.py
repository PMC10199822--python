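"""Synthetic three-subgenome genome with planted ground truth.

The generator lays out genes and accessible regions on A/B/D chromosomes,
draws transposase-integration pileups (Poisson: ``open_rate`` inside regions
open in a tissue, ``background_rate`` elsewhere), couples expression to
promoter accessibility, partitions triad expression by planted bias
categories, plants motif occurrences at configured per-cell densities, plants
stage-resolved TF->target edges, and thins variants near distal region
centers.  Every planted object is recorded in a :class:`GroundTruth` table so
downstream recovery can be scored.

All randomness flows from one ``numpy.random.default_rng(seed)`` (PCG64), so
a fixed seed reproduces byte-identical fixtures across runs and platforms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .acr_refinement import ACR, AccessibilitySignal
from .differential_accessibility import CLUSTERS, cluster_patterns
from .genomic_core import (
    GeneModel,
    GenomeIndex,
    GenomicInterval,
    tpm_from_counts,
    write_bed,
    write_gff3,
    write_matrix_tsv,
)
from .motif_regnet import MotifModel, write_motif_tsv
from .triad_bias import TriadRecord, classify_triad

__all__ = ["SimConfig", "GroundTruth", "SimResult", "simulate", "write_fixture"]

# planted bias fractions: well inside the centroid basins so noise is the
# only difficulty knob
BIAS_FRACTIONS = {
    "Balanced": (1 / 3, 1 / 3, 1 / 3),
    "ADominant": (0.8, 0.1, 0.1),
    "BDominant": (0.1, 0.8, 0.1),
    "DDominant": (0.1, 0.1, 0.8),
    "ASuppressed": (0.1, 0.45, 0.45),
    "BSuppressed": (0.45, 0.1, 0.45),
    "DSuppressed": (0.45, 0.45, 0.1),
}
BIAS_ORDER = list(BIAS_FRACTIONS)

DEFAULT_MOTIFS = [
    ("mARF", "ARF", "TGTCGGCTAA"),
    ("mNAC", "NAC", "ACGTGCATCC"),
    ("mBZIP", "bZIP", "TGACGTCATG"),
    ("mMYB", "MYB", "GGATAACGGT"),
    ("mDOF", "Dof", "AAAGCTTCCA"),
    ("mAGL", "AGL", "CCAAATAAGG"),
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Knobs of the synthetic genome; defaults give a ~6 Mb hexaploid toy."""

    seed: int = 0
    n_chroms_per_subgenome: int = 1
    chrom_length: int = 2_000_000
    n_triads: int = 300
    n_singletons: int = 100
    tissues: tuple = ("leaf", "DAP5", "DAP9", "DAP15", "DAP20")
    replicates: int = 2
    # accessibility
    acrs_per_pattern: int = 80
    acr_width: int = 300
    open_rate: float = 0.2
    background_rate: float = 0.005
    decoy_fraction: float = 0.10
    peak_pad: int = 200
    promoter_acr_fraction: float = 0.30
    genic_acr_fraction: float = 0.20
    # expression
    base_mean: float = 150.0
    deg_fold: float = 8.0
    coupling: float = 3.0
    dispersion: float = 0.1
    deg_fraction: float = 0.5
    gene_length_range: tuple = (1500, 2500)
    # triad bias: proportions over the seven categories (enumeration order)
    bias_proportions: tuple = (0.4, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1)
    n_switch_triads: int = 0
    switch_after: str = "DAP9"  # switching triads change category after this tissue
    # motifs
    enriched_density: float = 2.0  # hits/kb in planted (cluster, subgenome) cells
    background_density: float = 0.2
    # network
    n_network_tfs: int = 4
    targets_per_tf: int = 8
    network_stages: tuple = ("DAP9", "DAP15", "DAP20")
    expr_min: float = 1.0
    # variants
    variant_rate: float = 0.02
    variant_depletion: float = 0.2
    # masking
    blacklist_width: int = 1000

    def validate(self) -> None:
        if self.open_rate <= 0 or self.background_rate <= 0:
            raise ValueError("rates must be positive")
        if self.open_rate <= self.background_rate:
            raise ValueError("open_rate must exceed background_rate")
        if abs(sum(self.bias_proportions) - 1.0) > 1e-9:
            raise ValueError("bias category proportions must sum to 1")
        if len(self.bias_proportions) != 7:
            raise ValueError("bias_proportions must cover the 7 categories")
        if len(self.tissues) != 5:
            raise ValueError("the specificity-cluster layout expects 5 tissues")


@dataclass
class GroundTruth:
    """Planted labels for every recovery test downstream."""

    acrs: pd.DataFrame          # acr_id chrom start end cluster acr_class subgenome host_gene masked
    decoys: pd.DataFrame        # decoy_id chrom start end
    genes: pd.DataFrame         # gene_id chrom start end strand triad_id deg_cluster promoter_acr
    triad_bias: pd.DataFrame    # triad_id tissue category
    true_tpm: pd.DataFrame      # genes x tissues planted mean TPM
    motif_cells: pd.DataFrame   # motif_id cluster subgenome enriched
    network_edges: pd.DataFrame  # stage tf target
    tf_motifs: dict


@dataclass
class SimResult:
    config: SimConfig
    genome: GenomeIndex
    genes: list
    gene_lengths: pd.Series
    triads: list
    signals: list
    raw_peaks: dict
    blacklist: list
    organelle: list
    counts: pd.DataFrame
    sample_tissues: dict
    motifs: list
    variants: dict
    truth: GroundTruth

    @property
    def expression(self):
        from .genomic_core import ExpressionMatrix

        return ExpressionMatrix(self.counts, self.gene_lengths, dict(self.sample_tissues))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _place_blocks(rng, blocks, chrom_length):
    """Assign start coordinates to blocks (width list) with random gaps.

    Blocks keep their given order; leftover space is split into random gaps.
    Raises if the blocks cannot fit.
    """
    total = sum(blocks)
    slack = chrom_length - total
    if slack < 0:
        raise RuntimeError(
            f"cannot place {len(blocks)} blocks totalling {total} bp in a "
            f"{chrom_length} bp chromosome; shrink gene/ACR counts"
        )
    weights = rng.random(len(blocks) + 1)
    gaps = np.floor(weights / weights.sum() * slack).astype(int)
    starts = []
    cursor = 0
    for width, gap in zip(blocks, gaps):
        cursor += int(gap)
        starts.append(cursor)
        cursor += width
    return starts


def _nb_draw(rng, mean, dispersion):
    """Negative-binomial draw (variance mean + dispersion * mean^2)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + np.maximum(mean, 1e-12))
    return rng.negative_binomial(r, p)


def _pattern_cycle(labels, n_each):
    out = []
    for label in labels:
        out.extend([label] * n_each)
    return out


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def simulate(config: SimConfig) -> SimResult:
    """Generate the full synthetic data bundle with ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    tissues = list(config.tissues)
    patterns = cluster_patterns(tissues)  # cluster label -> tissue set
    stages = [s for s in config.network_stages if s in tissues]

    chroms = [
        f"chr{i + 1}{s}"
        for s in "ABD"
        for i in range(config.n_chroms_per_subgenome)
    ]
    chroms_by_subgenome = {s: [c for c in chroms if c.endswith(s)] for s in "ABD"}

    # ---- gene specs ------------------------------------------------------
    lo, hi = config.gene_length_range
    triad_ids = [f"tri{i:04d}" for i in range(config.n_triads)]
    triad_lengths = rng.integers(lo, hi + 1, size=config.n_triads)
    gene_specs: dict[str, list[dict]] = {c: [] for c in chroms}
    triads: list[TriadRecord] = []
    for i, tid in enumerate(triad_ids):
        ids = {}
        for s in "ABD":
            gid = f"g{i:04d}{s}"
            ids[s] = gid
            chrom = chroms_by_subgenome[s][i % len(chroms_by_subgenome[s])]
            gene_specs[chrom].append(
                {"gene_id": gid, "length": int(triad_lengths[i]),
                 "strand": "+" if rng.random() < 0.5 else "-", "triad_id": tid}
            )
        triads.append(TriadRecord(tid, ids["A"], ids["B"], ids["D"]))
    for j in range(config.n_singletons):
        gid = f"s{j:03d}"
        chrom = chroms[j % len(chroms)]
        gene_specs[chrom].append(
            {"gene_id": gid, "length": int(rng.integers(lo, hi + 1)),
             "strand": "+" if rng.random() < 0.5 else "-", "triad_id": None}
        )

    # ---- ACR pattern / class allocation ---------------------------------
    n_prom = int(round(config.promoter_acr_fraction * config.acrs_per_pattern))
    n_genic = int(round(config.genic_acr_fraction * config.acrs_per_pattern))
    n_distal = config.acrs_per_pattern - n_prom - n_genic
    prom_labels = _pattern_cycle(CLUSTERS, n_prom)
    genic_labels = _pattern_cycle(CLUSTERS, n_genic)
    distal_labels = _pattern_cycle(CLUSTERS, n_distal)
    n_planted = len(prom_labels) + len(genic_labels) + len(distal_labels)
    n_decoys = int(np.ceil(config.decoy_fraction * n_planted))

    # promoter hosts: singletons first, then one homeolog per unclaimed triad
    singleton_ids = [f"s{j:03d}" for j in range(config.n_singletons)]
    rng.shuffle(singleton_ids)
    spare_triads = list(triad_ids)
    rng.shuffle(spare_triads)
    prom_hosts: list[str] = list(singleton_ids[: len(prom_labels)])
    triad_pattern: dict[str, str | None] = {}
    ti = 0
    while len(prom_hosts) < len(prom_labels):
        tid = spare_triads[ti]
        ti += 1
        homeolog = "ABD"[rng.integers(0, 3)]
        prom_hosts.append(f"g{int(tid[3:]):04d}{homeolog}")
        triad_pattern[tid] = None  # claimed; pattern set below from the ACR
    rng.shuffle(prom_hosts)

    # genic hosts: triad homeologs not already hosting a promoter ACR
    all_gene_ids = [spec["gene_id"] for specs in gene_specs.values() for spec in specs]
    used_hosts = set(prom_hosts)
    genic_pool = [g for g in all_gene_ids if g not in used_hosts and g.startswith("g")]
    rng.shuffle(genic_pool)
    genic_hosts = genic_pool[: len(genic_labels)]

    host_of: dict[str, tuple[str, str]] = {}  # gene -> (kind, cluster)
    for gid, label in zip(prom_hosts, prom_labels):
        host_of[gid] = ("promoter", label)
    for gid, label in zip(genic_hosts, genic_labels):
        host_of[gid] = ("genic", label)

    # distal slots per chromosome: planted + decoys + one masked plant
    distal_assign: dict[str, list[tuple[str, str | None]]] = {c: [] for c in chroms}
    for k, label in enumerate(distal_labels):
        distal_assign[chroms[k % len(chroms)]].append(("acr", label))
    for k in range(n_decoys):
        distal_assign[chroms[k % len(chroms)]].append(("decoy", None))

    # ---- chromosome layout ----------------------------------------------
    # slot_gap must exceed merge_gap + 2 * max bin overhang past an ACR edge,
    # otherwise neighbouring planted ACRs fuse during refinement
    prom_margin, other_margin = 2300, 300
    slot_gap, distal_margin, group_size = 500, 2400, 4
    gene_rows: list[dict] = []
    acr_rows: list[dict] = []
    decoy_rows: list[dict] = []
    blacklist: list[GenomicInterval] = []
    masked_rows: list[dict] = []
    chrom_lengths = {c: config.chrom_length for c in chroms}

    for chrom in chroms:
        specs = gene_specs[chrom]
        rng.shuffle(specs)
        slots = distal_assign[chrom]
        groups = [slots[i : i + group_size] for i in range(0, len(slots), group_size)]
        blocks: list[tuple[str, object, int]] = []
        for spec in specs:
            blocks.append(("gene", spec, prom_margin + spec["length"] + other_margin))
        for grp in groups:
            width = 2 * distal_margin + len(grp) * config.acr_width + (len(grp) - 1) * slot_gap
            blocks.append(("distal", grp, width))
        blocks.append(("blacklist", None, config.blacklist_width + 2000))
        order = rng.permutation(len(blocks))
        blocks = [blocks[i] for i in order]
        starts = _place_blocks(rng, [b[2] for b in blocks], config.chrom_length)
        for (kind, payload, width), bstart in zip(blocks, starts):
            if kind == "gene":
                spec = payload
                gstart = bstart + (prom_margin if spec["strand"] == "+" else other_margin)
                gene_rows.append(
                    {"gene_id": spec["gene_id"], "chrom": chrom, "start": gstart,
                     "end": gstart + spec["length"], "strand": spec["strand"],
                     "triad_id": spec["triad_id"]}
                )
            elif kind == "distal":
                for si, (skind, label) in enumerate(payload):
                    astart = bstart + distal_margin + si * (config.acr_width + slot_gap)
                    row = {"chrom": chrom, "start": astart, "end": astart + config.acr_width}
                    if skind == "acr":
                        acr_rows.append({**row, "cluster": label, "acr_class": "distal",
                                         "host_gene": None})
                    else:
                        decoy_rows.append(row)
            else:  # blacklist
                bl_start = bstart + 1000
                blacklist.append(
                    GenomicInterval(chrom, bl_start, bl_start + config.blacklist_width)
                )
                mid = bl_start + (config.blacklist_width - config.acr_width) // 2
                masked_rows.append({"chrom": chrom, "start": mid, "end": mid + config.acr_width})

    gene_df = pd.DataFrame(gene_rows)
    genes = [
        GeneModel(r.gene_id, GenomicInterval(r.chrom, r.start, r.end, r.strand))
        for r in gene_df.itertuples(index=False)
    ]
    gene_by_id = {g.gene_id: g for g in genes}

    # promoter / genic ACRs anchored to their hosts
    for gid, (kind, label) in host_of.items():
        g = gene_by_id[gid]
        if kind == "promoter":
            if g.strand == "+":
                start = g.tss - 700
            else:
                start = g.tss + 401
            acr_class = "proximal"
        else:
            start = g.interval.start + (len(g.interval) - config.acr_width) // 2
            acr_class = "genic"
        acr_rows.append(
            {"chrom": g.chrom, "start": start, "end": start + config.acr_width,
             "cluster": label, "acr_class": acr_class, "host_gene": gid}
        )

    acr_df = pd.DataFrame(acr_rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    acr_df["acr_id"] = [f"acr{i:04d}" for i in range(len(acr_df))]
    acr_df["subgenome"] = [c[-1] for c in acr_df["chrom"]]
    acr_df["masked"] = False
    masked_df = pd.DataFrame(masked_rows)
    masked_df["acr_id"] = [f"mask{i:02d}" for i in range(len(masked_df))]
    decoy_df = pd.DataFrame(decoy_rows)
    decoy_df["decoy_id"] = [f"decoy{i:03d}" for i in range(len(decoy_df))]

    open_tissues = {
        r.acr_id: patterns[r.cluster] for r in acr_df.itertuples(index=False)
    }
    for r in masked_df.itertuples(index=False):
        open_tissues[r.acr_id] = frozenset(tissues)  # open everywhere, then masked

    # ---- integration signals --------------------------------------------
    open_regions = pd.concat(
        [acr_df[["acr_id", "chrom", "start", "end"]], masked_df[["acr_id", "chrom", "start", "end"]]],
        ignore_index=True,
    )
    signals = []
    sample_tissues: dict[str, str] = {}
    for tissue in tissues:
        for rep in range(1, config.replicates + 1):
            sample = f"{tissue}_r{rep}"
            sample_tissues[sample] = tissue
            positions: dict[str, np.ndarray] = {}
            for chrom in chroms:
                n_bg = rng.poisson(config.background_rate * config.chrom_length)
                pos = [rng.integers(0, config.chrom_length, size=n_bg)]
                sub = open_regions[open_regions["chrom"] == chrom]
                for r in sub.itertuples(index=False):
                    if tissue not in open_tissues[r.acr_id]:
                        continue
                    extra = rng.poisson(
                        (config.open_rate - config.background_rate) * (r.end - r.start)
                    )
                    pos.append(rng.integers(r.start, r.end, size=extra))
                positions[chrom] = np.sort(np.concatenate(pos))
            signals.append(AccessibilitySignal(sample, tissue, rep, positions))

    # ---- raw peaks per tissue -------------------------------------------
    raw_peaks: dict[str, list[GenomicInterval]] = {}
    for tissue in tissues:
        peaks = []
        for r in open_regions.itertuples(index=False):
            if tissue in open_tissues[r.acr_id]:
                peaks.append(
                    GenomicInterval(
                        r.chrom,
                        max(0, r.start - config.peak_pad),
                        min(config.chrom_length, r.end + config.peak_pad),
                        name=f"{tissue}_{r.acr_id}",
                    )
                )
        n_tissue_decoys = min(len(decoy_df), int(np.ceil(config.decoy_fraction * len(peaks))))
        picks = rng.choice(len(decoy_df), size=n_tissue_decoys, replace=False)
        for di in sorted(picks):
            r = decoy_df.iloc[int(di)]
            peaks.append(
                GenomicInterval(
                    r["chrom"],
                    max(0, int(r["start"]) - config.peak_pad),
                    min(config.chrom_length, int(r["end"]) + config.peak_pad),
                    name=f"{tissue}_{r['decoy_id']}",
                )
            )
        raw_peaks[tissue] = sorted(peaks, key=lambda p: (p.chrom, p.start))

    # ---- expression ------------------------------------------------------
    # deg pattern per gene: promoter-ACR hosts inherit their ACR's cluster;
    # hosts on triads force the whole triad; a deg_fraction of the remaining
    # triads gets a cluster round-robin; the rest stay flat.
    deg_cluster: dict[str, str | None] = {g.gene_id: None for g in genes}
    for gid, (kind, label) in host_of.items():
        if kind != "promoter":
            continue
        g = gene_by_id[gid]
        tid = gene_df.loc[gene_df["gene_id"] == gid, "triad_id"].iloc[0]
        if tid is None or (isinstance(tid, float) and np.isnan(tid)):
            deg_cluster[gid] = label
        else:
            triad_pattern[tid] = label
    unclaimed = [t for t in triad_ids if t not in triad_pattern]
    n_deg_triads = int(round(config.deg_fraction * len(unclaimed)))
    for k, tid in enumerate(unclaimed[:n_deg_triads]):
        triad_pattern[tid] = CLUSTERS[k % len(CLUSTERS)]
    for tid in unclaimed[n_deg_triads:]:
        triad_pattern[tid] = None
    for i, triad in enumerate(triads):
        for gid in triad.genes:
            deg_cluster[gid] = triad_pattern[triad.triad_id]

    # triad bias category per tissue
    cat_draw = rng.choice(
        len(BIAS_ORDER), size=config.n_triads, p=list(config.bias_proportions)
    )
    switch_idx = tissues.index(config.switch_after) if config.n_switch_triads else None
    switch_set = set(
        rng.choice(config.n_triads, size=min(config.n_switch_triads, config.n_triads),
                   replace=False).tolist()
        if config.n_switch_triads
        else []
    )
    planted_category: dict[tuple[str, str], str] = {}
    for i, tid in enumerate(triad_ids):
        base_cat = BIAS_ORDER[cat_draw[i]]
        if i in switch_set:
            alt = BIAS_ORDER[(cat_draw[i] + 1) % len(BIAS_ORDER)]
            for j, t in enumerate(tissues):
                planted_category[(tid, t)] = base_cat if j <= switch_idx else alt
        else:
            for t in tissues:
                planted_category[(tid, t)] = base_cat

    prom_open: dict[str, frozenset] = {}
    for gid, (kind, label) in host_of.items():
        if kind == "promoter":
            prom_open[gid] = patterns[label]

    gene_order = [g.gene_id for g in genes]
    mean = pd.DataFrame(0.0, index=gene_order, columns=tissues)
    for g in genes:
        gid = g.gene_id
        tid = None
        if gid.startswith("g"):
            tid = f"tri{int(gid[1:5]):04d}"
        for t in tissues:
            pattern = triad_pattern.get(tid) if tid else deg_cluster[gid]
            total = config.base_mean * (3.0 if tid else 1.0)
            if pattern is not None and t in patterns[pattern]:
                total *= config.deg_fold
            if tid:
                frac = BIAS_FRACTIONS[planted_category[(tid, t)]]["ABD".index(gid[-1])]
                value = total * frac
            else:
                value = total
            if gid in prom_open and t in prom_open[gid]:
                value *= config.coupling
            mean.loc[gid, t] = value

    counts = pd.DataFrame(index=gene_order, dtype=np.int64)
    for sample, tissue in sample_tissues.items():
        counts[sample] = _nb_draw(rng, mean[tissue].to_numpy(), config.dispersion)
    gene_lengths = pd.Series(
        {g.gene_id: len(g.interval) for g in genes}, name="length"
    ).loc[gene_order]

    true_tpm = pd.DataFrame(
        tpm_from_counts(mean.to_numpy(), gene_lengths.to_numpy()),
        index=gene_order, columns=tissues,
    )

    # planted bias truth from true mean TPM (accounts for coupling distortion)
    bias_rows = []
    for triad in triads:
        for t in tissues:
            vals = [float(true_tpm.loc[g, t]) for g in triad.genes]
            cat, _, _ = classify_triad(*vals)
            bias_rows.append({"triad_id": triad.triad_id, "tissue": t, "category": cat})
    triad_bias_df = pd.DataFrame(bias_rows)

    # ---- sequence + motif planting --------------------------------------
    seq_arrays = {
        c: _BASES[rng.integers(0, 4, size=config.chrom_length)] for c in chroms
    }
    motifs = [MotifModel(mid, fam, cons) for mid, fam, cons in DEFAULT_MOTIFS]
    motif_by_id = {m.motif_id: m for m in motifs}
    occupied: dict[str, list[tuple[int, int]]] = {}
    placements: dict[tuple[str, str], int] = {}  # (motif_id, acr_id) -> copies

    def plant(motif: MotifModel, acr) -> None:
        width = motif.width
        spans = occupied.setdefault(acr.acr_id, [])
        for _ in range(200):
            off = int(rng.integers(acr.start, acr.end - width + 1))
            if all(off + width <= s or off >= e for s, e in spans):
                spans.append((off, off + width))
                enc = np.frombuffer(motif.consensus.encode(), dtype=np.uint8)
                seq_arrays[acr.chrom][off : off + width] = enc
                placements[(motif.motif_id, acr.acr_id)] = (
                    placements.get((motif.motif_id, acr.acr_id), 0) + 1
                )
                return
        raise RuntimeError(
            f"cannot place motif {motif.motif_id} in {acr.acr_id}: region saturated"
        )

    # network edges first (their placements count toward cell densities)
    tf_pool = [g for g in singleton_ids if host_of.get(g, ("", ""))[0] != "promoter"]
    if len(tf_pool) < config.n_network_tfs:
        tf_pool = singleton_ids
    tf_genes = sorted(tf_pool)[: config.n_network_tfs]
    tf_motifs = {tf: motifs[i % len(motifs)].motif_id for i, tf in enumerate(tf_genes)}
    eligible = [
        r
        for r in acr_df.itertuples(index=False)
        if r.host_gene is not None
        and r.acr_class == "proximal"
        and r.host_gene not in tf_genes
        and patterns[r.cluster] & set(stages)
    ]
    placed_in_cell: dict[tuple[str, str, str], int] = {}
    for tf in tf_genes:
        motif = motif_by_id[tf_motifs[tf]]
        picks = rng.choice(len(eligible), size=min(config.targets_per_tf, len(eligible)),
                           replace=False)
        for pi in sorted(picks):
            r = eligible[int(pi)]
            plant(motif, r)
            key = (motif.motif_id, r.cluster, r.subgenome)
            placed_in_cell[key] = placed_in_cell.get(key, 0) + 1

    # per-cell density planting (deterministic totals, round-robin placement)
    enrichment = {
        m.motif_id: CLUSTERS[i] for i, m in enumerate(motifs) if i < len(CLUSTERS)
    }
    cell_rows = []
    members_by_cell: dict[tuple[str, str], list] = {}
    for r in acr_df.itertuples(index=False):
        members_by_cell.setdefault((r.cluster, r.subgenome), []).append(r)
    for m in motifs:
        for cluster in CLUSTERS:
            for subg in "ABD":
                members = members_by_cell.get((cluster, subg), [])
                kb = sum(r.end - r.start for r in members) / 1000.0
                enriched = enrichment.get(m.motif_id) == cluster
                density = config.enriched_density if enriched else config.background_density
                target = int(round(density * kb))
                target -= placed_in_cell.get((m.motif_id, cluster, subg), 0)
                for k in range(max(0, target)):
                    plant(m, members[k % len(members)])
                cell_rows.append(
                    {"motif_id": m.motif_id, "cluster": cluster, "subgenome": subg,
                     "enriched": enriched}
                )
    motif_cells_df = pd.DataFrame(cell_rows)

    # network ground truth from *all* planted copies: any TF-motif copy in an
    # accessible promoter of an expressed gene satisfies the four-gate rule
    acr_info = {r.acr_id: r for r in acr_df.itertuples(index=False)}
    edge_rows = []
    for tf in tf_genes:
        mid = tf_motifs[tf]
        for (m_id, acr_id), n_copies in placements.items():
            if m_id != mid or n_copies == 0:
                continue
            r = acr_info.get(acr_id)
            if r is None or r.host_gene is None or r.acr_class != "proximal":
                continue
            if r.host_gene == tf:
                continue
            for stage in stages:
                if (
                    stage in patterns[r.cluster]
                    and float(true_tpm.loc[tf, stage]) >= config.expr_min
                    and float(true_tpm.loc[r.host_gene, stage]) >= config.expr_min
                ):
                    edge_rows.append({"stage": stage, "tf": tf, "target": r.host_gene})
    network_df = pd.DataFrame(edge_rows, columns=["stage", "tf", "target"]).drop_duplicates()
    network_df = network_df.sort_values(["stage", "tf", "target"]).reset_index(drop=True)

    sequences = {c: arr.tobytes().decode() for c, arr in seq_arrays.items()}
    genome = GenomeIndex(chrom_lengths, {c: c[-1] for c in chroms}, sequences=sequences)

    # ---- variants --------------------------------------------------------
    variants: dict[str, np.ndarray] = {}
    half = config.acr_width // 2
    distal_centers = {
        c: np.array(
            sorted(
                (r.start + r.end) // 2
                for r in acr_df.itertuples(index=False)
                if r.chrom == c and r.acr_class == "distal"
            ),
            dtype=np.int64,
        )
        for c in chroms
    }
    for chrom in chroms:
        n = rng.poisson(config.variant_rate * config.chrom_length)
        pos = np.sort(rng.integers(0, config.chrom_length, size=n))
        centers = distal_centers[chrom]
        if centers.size:
            idx = np.searchsorted(centers, pos)
            near = np.full(pos.shape, False)
            for shift in (0, -1):
                j = np.clip(idx + shift, 0, centers.size - 1)
                near |= np.abs(pos - centers[j]) < half
            keep = ~near | (rng.random(pos.size) < config.variant_depletion)
            pos = pos[keep]
        variants[chrom] = pos

    # ---- ground truth ----------------------------------------------------
    gene_truth = gene_df.copy()
    gene_truth["deg_cluster"] = [deg_cluster[g] for g in gene_truth["gene_id"]]
    prom_acr_of = {
        r.host_gene: r.acr_id
        for r in acr_df.itertuples(index=False)
        if r.host_gene is not None and r.acr_class == "proximal"
    }
    gene_truth["promoter_acr"] = [prom_acr_of.get(g) for g in gene_truth["gene_id"]]

    truth = GroundTruth(
        acrs=pd.concat(
            [acr_df, masked_df.assign(cluster=None, acr_class=None, host_gene=None,
                                      subgenome=[c[-1] for c in masked_df["chrom"]],
                                      masked=True)],
            ignore_index=True,
        ),
        decoys=decoy_df,
        genes=gene_truth,
        triad_bias=triad_bias_df,
        true_tpm=true_tpm,
        motif_cells=motif_cells_df,
        network_edges=network_df,
        tf_motifs=tf_motifs,
    )

    return SimResult(
        config=config,
        genome=genome,
        genes=genes,
        gene_lengths=gene_lengths,
        triads=triads,
        signals=signals,
        raw_peaks=raw_peaks,
        blacklist=blacklist,
        organelle=[],
        counts=counts,
        sample_tissues=sample_tissues,
        motifs=motifs,
        variants=variants,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# fixture emission
# ---------------------------------------------------------------------------

def write_fixture(result: SimResult, outdir) -> pd.DataFrame:
    """Emit the full bundle as plain-text files plus a manifest.

    Layout: genome.fa, genes.gff3, triads.tsv, counts.tsv, gene_lengths.tsv,
    motifs.tsv, variants.bed, blacklist.bed, organelle.bed, tis/<sample>.bed,
    peaks/<tissue>_peaks.bed, truth/*.tsv, manifest.tsv.  Returns the
    manifest (file, n_records).
    """
    out = Path(outdir)
    (out / "tis").mkdir(parents=True, exist_ok=True)
    (out / "peaks").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    manifest: list[tuple[str, int]] = []

    def note(rel, n):
        manifest.append((rel, n))

    with open(out / "genome.fa", "w") as fh:
        for chrom, seq in result.genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    note("genome.fa", len(result.genome.sequences))

    write_gff3(out / "genes.gff3", result.genes)
    note("genes.gff3", len(result.genes))

    with open(out / "triads.tsv", "w") as fh:
        fh.write("triad_id\tgene_a\tgene_b\tgene_d\n")
        for t in result.triads:
            fh.write(f"{t.triad_id}\t{t.gene_a}\t{t.gene_b}\t{t.gene_d}\n")
    note("triads.tsv", len(result.triads))

    write_matrix_tsv(out / "counts.tsv", result.counts)
    note("counts.tsv", len(result.counts))
    result.gene_lengths.rename("length").to_csv(out / "gene_lengths.tsv", sep="\t")
    note("gene_lengths.tsv", len(result.gene_lengths))

    write_motif_tsv(out / "motifs.tsv", result.motifs)
    note("motifs.tsv", len(result.motifs))

    # the TF -> motif table is a pipeline *input* (curated TF list), not truth
    with open(out / "tf_table.tsv", "w") as fh:
        fh.write("tf\tmotif_id\n")
        for tf, mid in result.truth.tf_motifs.items():
            fh.write(f"{tf}\t{mid}\n")
    note("tf_table.tsv", len(result.truth.tf_motifs))

    for sig in result.signals:
        rel = f"tis/{sig.sample_id}.bed"
        with open(out / rel, "w") as fh:
            n = 0
            for chrom in sorted(sig.positions):
                for p in sig.positions[chrom]:
                    fh.write(f"{chrom}\t{p}\t{p + 1}\n")
                    n += 1
        note(rel, n)

    for tissue, peaks in result.raw_peaks.items():
        rel = f"peaks/{tissue}_peaks.bed"
        write_bed(out / rel, peaks)
        note(rel, len(peaks))

    write_bed(out / "blacklist.bed", result.blacklist)
    note("blacklist.bed", len(result.blacklist))
    write_bed(out / "organelle.bed", result.organelle)
    note("organelle.bed", len(result.organelle))

    with open(out / "variants.bed", "w") as fh:
        n = 0
        for chrom in sorted(result.variants):
            for p in result.variants[chrom]:
                fh.write(f"{chrom}\t{p}\t{p + 1}\n")
                n += 1
    note("variants.bed", n)

    truth = result.truth
    for name, frame in [
        ("acrs", truth.acrs), ("decoys", truth.decoys), ("genes", truth.genes),
        ("triad_bias", truth.triad_bias), ("motif_cells", truth.motif_cells),
        ("network_edges", truth.network_edges),
    ]:
        rel = f"truth/{name}.tsv"
        frame.to_csv(out / rel, sep="\t", index=False)
        note(rel, len(frame))
    truth.true_tpm.to_csv(out / "truth/true_tpm.tsv", sep="\t")
    note("truth/true_tpm.tsv", len(truth.true_tpm))
    pd.Series(truth.tf_motifs, name="motif_id").rename_axis("tf").to_csv(
        out / "truth/tf_motifs.tsv", sep="\t"
    )
    note("truth/tf_motifs.tsv", len(truth.tf_motifs))

    with open(out / "config.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        for f in dataclasses.fields(result.config):
            fh.write(f"{f.name}\t{getattr(result.config, f.name)}\n")
    note("config.tsv", len(dataclasses.fields(result.config)))

    mdf = pd.DataFrame(manifest, columns=["file", "n_records"])
    mdf.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return mdf
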