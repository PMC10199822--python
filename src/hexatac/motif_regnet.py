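"""Motif scanning, density tables, TFBS-ACR intersection and TF networks.

Motifs are either IUPAC consensus strings (exact degenerate matching) or
position weight matrices (log-odds against a uniform background, hit when the
score reaches a configurable fraction of the maximum attainable score).  Both
strands are scanned; a motif matching the same position on both strands (a
palindrome) counts once.  Densities are reported as hits per kilobase of
scanned sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_core import GeneModel, GenomeIndex, GenomicInterval
from .acr_refinement import ACR

__all__ = [
    "MotifModel",
    "MotifHit",
    "scan_motif",
    "motif_density_table",
    "tfbs_acr_intersection",
    "build_network",
    "promoter_motif_density",
    "read_motif_tsv",
    "read_pwm_file",
    "reverse_complement",
]

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifModel:
    """Scannable motif: IUPAC consensus or 4 x width probability matrix.

    ``pwm`` rows are A, C, G, T; columns must sum to 1 within 1e-6.
    ``threshold_fraction`` applies to PWM mode only: hits need a log-odds
    score of at least that fraction of the maximum attainable score.
    """

    motif_id: str
    family: str = ""
    consensus: str | None = None
    pwm: np.ndarray | None = None
    threshold_fraction: float = 0.8

    def __post_init__(self) -> None:
        if (self.consensus is None) == (self.pwm is None):
            raise ValueError("provide exactly one of consensus or pwm")
        if self.consensus is not None:
            self.consensus = self.consensus.upper()
            bad = set(self.consensus) - set(IUPAC)
            if bad:
                raise ValueError(f"{self.motif_id}: non-IUPAC symbols {sorted(bad)}")
        else:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.shape[0] != 4:
                raise ValueError(f"{self.motif_id}: PWM must have 4 rows (A,C,G,T)")
            sums = self.pwm.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise ValueError(f"{self.motif_id}: PWM columns must sum to 1")

    @property
    def width(self) -> int:
        return len(self.consensus) if self.consensus is not None else self.pwm.shape[1]


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    interval: GenomicInterval
    strand: str
    score: float


def _encode(sequence: str) -> np.ndarray:
    codes = np.full(len(sequence), 4, dtype=np.int8)  # 4 = N/other
    for base, code in _CODE.items():
        codes[np.frombuffer(sequence.encode(), dtype=np.uint8) == ord(base)] = code
    return codes


def _consensus_allowed(consensus: str) -> np.ndarray:
    # allowed[code, position]; N in the *sequence* (code 4) never matches
    allowed = np.zeros((5, len(consensus)), dtype=bool)
    for j, sym in enumerate(consensus):
        for base in IUPAC[sym]:
            allowed[_CODE[base], j] = True
    return allowed


def _scan_strand(codes: np.ndarray, motif: MotifModel, forward: bool) -> dict[int, float]:
    """Match offsets (and scores) of the motif on one strand of ``codes``."""
    w = motif.width
    n = codes.size - w + 1
    if n <= 0:
        return {}
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    if motif.consensus is not None:
        pattern = motif.consensus if forward else reverse_complement(motif.consensus)
        allowed = _consensus_allowed(pattern)
        ok = allowed[windows, np.arange(w)].all(axis=1)
        return {int(i): 1.0 for i in np.nonzero(ok)[0]}
    pwm = motif.pwm
    if not forward:
        pwm = pwm[::-1, ::-1]  # reverse complement: flip rows (A<->T, C<->G) and columns
    logodds = np.log2(np.maximum(pwm, 1e-9) / 0.25)
    score_matrix = np.vstack([logodds, np.full(w, -np.inf)])  # row 4: N never matches
    scores = score_matrix[windows, np.arange(w)].sum(axis=1)
    threshold = motif.threshold_fraction * logodds.max(axis=0).sum()
    ok = scores >= threshold
    return {int(i): float(scores[i]) for i in np.nonzero(ok)[0]}


def scan_motif(
    sequence: str,
    motif: MotifModel,
    chrom: str = ".",
    offset: int = 0,
) -> list[MotifHit]:
    """Scan both strands of ``sequence`` for ``motif``.

    Returns hits sorted by position.  When both strands hit the same position
    (palindrome, or a PWM scoring high both ways) a single hit is kept — the
    higher-scoring strand, ``+`` on ties — so palindromic motifs are not
    double-counted.  ``chrom``/``offset`` translate hit coordinates into
    genome space.
    """
    codes = _encode(sequence.upper())
    fwd = _scan_strand(codes, motif, forward=True)
    rev = _scan_strand(codes, motif, forward=False)
    hits = []
    for pos in sorted(set(fwd) | set(rev)):
        if pos in fwd and (pos not in rev or fwd[pos] >= rev[pos]):
            strand, score = "+", fwd[pos]
        else:
            strand, score = "-", rev[pos]
        hits.append(
            MotifHit(
                motif.motif_id,
                GenomicInterval(chrom, offset + pos, offset + pos + motif.width),
                strand,
                score,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# Density tables
# ---------------------------------------------------------------------------

def motif_density_table(
    motifs: Sequence[MotifModel],
    acrs: Sequence[ACR],
    clusters: Mapping[str, str] | pd.Series,
    genome: GenomeIndex,
    stratify_by_subgenome: bool = False,
    density_flag: float = 1.0,
) -> pd.DataFrame:
    """Hits-per-kb of every motif in every ACR cluster (optionally split by
    subgenome).

    ``clusters`` maps ACR id (interval name or "chrom:start-end") to a
    cluster label.  The returned long frame has one row per
    (motif, cluster, subgenome) cell: hits, kb scanned, density, ``flagged``
    (density > ``density_flag``) and n (member ACR count); empty cells keep
    ``n=0`` with NaN density.  Subgenome-stratified hits over {A, B, D} sum
    exactly to the unstratified "all" hits.
    """
    members: dict[tuple[str, str], list[ACR]] = {}
    labels: list[str] = []
    for acr in acrs:
        iv = acr.interval
        acr_id = iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"
        if acr_id not in clusters:
            continue
        label = clusters[acr_id]
        if label not in labels:
            labels.append(label)
        subg = genome.subgenomes.get(iv.chrom, "other")
        members.setdefault((label, "all"), []).append(acr)
        if stratify_by_subgenome:
            members.setdefault((label, subg), []).append(acr)

    subgenome_levels = ["all"] + (
        sorted({s for (_, s) in members if s != "all"}) if stratify_by_subgenome else []
    )
    rows = []
    seq_cache: dict[str, str] = {}
    hit_cache: dict[tuple[str, str], int] = {}
    for motif in motifs:
        for label in labels:
            for subg in subgenome_levels:
                cell = members.get((label, subg), [])
                total_bp = sum(len(a.interval) for a in cell)
                hits = 0
                for a in cell:
                    iv = a.interval
                    key = f"{iv.chrom}:{iv.start}-{iv.end}"
                    if (motif.motif_id, key) not in hit_cache:
                        seq = seq_cache.setdefault(key, genome.fetch(iv))
                        hit_cache[(motif.motif_id, key)] = len(scan_motif(seq, motif))
                    hits += hit_cache[(motif.motif_id, key)]
                kb = total_bp / 1000.0
                density = hits / kb if kb > 0 else float("nan")
                rows.append(
                    {
                        "motif_id": motif.motif_id,
                        "cluster": label,
                        "subgenome": subg,
                        "hits": hits,
                        "kb": kb,
                        "density": density,
                        "flagged": bool(kb > 0 and density > density_flag),
                        "n": len(cell),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TFBS intersection
# ---------------------------------------------------------------------------

def tfbs_acr_intersection(
    tfbs_peaks: Mapping[str, Sequence[GenomicInterval]],
    acrs_per_tissue: Mapping[str, Sequence[ACR] | Sequence[GenomicInterval]],
) -> dict:
    """In-vivo TFBS sets per (TF, tissue) and tissue-sharing statistics.

    A TFBS peak is "in vivo" in a tissue when it overlaps that tissue's ACRs
    by >= 1 bp.  Per TF the tissue x tissue Jaccard sharing matrix and the
    tissue-different fraction ``1 - |intersection over tissues| / |union|``
    are reported (fraction NaN when the union is empty).
    """
    from .genomic_core import overlaps_any

    tissues = list(acrs_per_tissue)
    acr_ivs = {
        t: [a.interval if isinstance(a, ACR) else a for a in acrs]
        for t, acrs in acrs_per_tissue.items()
    }
    result: dict = {"in_vivo": {}, "sharing": {}, "different_fraction": {}}
    for tf, peaks in tfbs_peaks.items():
        peaks = list(peaks)
        sets = {}
        for t in tissues:
            mask = overlaps_any(peaks, acr_ivs[t]) if acr_ivs[t] else np.zeros(len(peaks), bool)
            sets[t] = frozenset(np.nonzero(mask)[0].tolist())
            result["in_vivo"][(tf, t)] = [peaks[i] for i in sorted(sets[t])]
        share = pd.DataFrame(np.nan, index=tissues, columns=tissues)
        for ta in tissues:
            for tb in tissues:
                union = sets[ta] | sets[tb]
                share.loc[ta, tb] = (
                    len(sets[ta] & sets[tb]) / len(union) if union else float("nan")
                )
        result["sharing"][tf] = share
        all_union = frozenset().union(*sets.values()) if sets else frozenset()
        all_inter = (
            frozenset.intersection(*sets.values()) if sets else frozenset()
        )
        result["different_fraction"][tf] = (
            1.0 - len(all_inter) / len(all_union) if all_union else float("nan")
        )
    return result


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def _intersections(window: GenomicInterval, others: Iterable[GenomicInterval]):
    for iv in others:
        if iv.chrom != window.chrom:
            continue
        start, end = max(window.start, iv.start), min(window.end, iv.end)
        if start < end:
            yield GenomicInterval(window.chrom, start, end, name=iv.name)


def build_network(
    tf_motifs: Mapping[str, str],
    targets: Sequence[str],
    acrs_per_stage: Mapping[str, Sequence[ACR] | Sequence[GenomicInterval]],
    promoters: Mapping[str, GenomicInterval],
    motifs: Mapping[str, MotifModel],
    genome: GenomeIndex,
    tissue_tpm: pd.DataFrame,
    stages: Sequence[str] = ("DAP9", "DAP15", "DAP20"),
    expr_min: float = 1.0,
) -> pd.DataFrame:
    """Stage-resolved TF -> target edges under a four-gate evidence rule.

    An edge (TF, target, stage) exists iff (i) the TF's mean TPM at the stage
    is >= ``expr_min``; (ii) the target's mean TPM is >= ``expr_min``;
    (iii) the target's promoter window overlaps >= 1 ACR of that stage; and
    (iv) the TF's motif hits inside the promoter-ACR intersection.  Evidence
    (motif hit coordinates, ACR id, both TPMs) is recorded per edge; rows are
    stable-sorted by (stage, tf, target).  TFs lacking a motif are skipped
    with a warning.
    """
    rows = []
    for stage in stages:
        stage_acrs = [
            a.interval if isinstance(a, ACR) else a for a in acrs_per_stage.get(stage, [])
        ]
        # promoter-ACR intersections and their sequences, shared by all TFs
        accessible: dict[str, list[tuple[GenomicInterval, str]]] = {}
        for target in targets:
            window = promoters.get(target)
            if window is None:
                continue
            regions = list(_intersections(window, stage_acrs))
            if regions:
                accessible[target] = [(r, genome.fetch(r)) for r in regions]
        for tf, motif_id in tf_motifs.items():
            if motif_id not in motifs:
                warnings.warn(f"TF {tf}: motif {motif_id} unavailable; skipped", stacklevel=2)
                continue
            if tf not in tissue_tpm.index or stage not in tissue_tpm.columns:
                continue
            tf_tpm = float(tissue_tpm.loc[tf, stage])
            if tf_tpm < expr_min:
                continue
            motif = motifs[motif_id]
            for target in targets:
                if target == tf or target not in tissue_tpm.index:
                    continue
                target_tpm = float(tissue_tpm.loc[target, stage])
                if target_tpm < expr_min:
                    continue
                for region, seq in accessible.get(target, []):
                    hits = scan_motif(seq, motif, chrom=region.chrom, offset=region.start)
                    if hits:
                        hit = hits[0]
                        rows.append(
                            {
                                "stage": stage,
                                "tf": tf,
                                "target": target,
                                "motif_id": motif_id,
                                "hit_chrom": hit.interval.chrom,
                                "hit_start": hit.interval.start,
                                "hit_end": hit.interval.end,
                                "acr_id": region.name
                                or f"{region.chrom}:{region.start}-{region.end}",
                                "n_hits": len(hits),
                                "tf_tpm": tf_tpm,
                                "target_tpm": target_tpm,
                            }
                        )
                        break  # one evidence record per edge
    frame = pd.DataFrame(
        rows,
        columns=[
            "stage", "tf", "target", "motif_id", "hit_chrom", "hit_start",
            "hit_end", "acr_id", "n_hits", "tf_tpm", "target_tpm",
        ],
    )
    return frame.sort_values(["stage", "tf", "target"], kind="stable").reset_index(drop=True)


def promoter_motif_density(
    gene_set: Sequence[str],
    motifs: Sequence[MotifModel],
    acrs: Sequence[ACR] | Sequence[GenomicInterval],
    promoters: Mapping[str, GenomicInterval],
    genome: GenomeIndex,
) -> pd.DataFrame:
    """Motif densities over the pooled promoter-ACR sequence of a gene set.

    Density arithmetic matches :func:`motif_density_table` but is restricted
    to the intersections of the genes' promoter windows with ACRs.  Returns a
    frame ranked by density (empty, with a warning, if the gene set has no
    accessible promoter sequence).  Results are independent of gene order.
    """
    if not gene_set:
        raise ValueError("gene set is empty")
    acr_ivs = [a.interval if isinstance(a, ACR) else a for a in acrs]
    regions = []
    for gene in sorted(set(gene_set)):
        window = promoters.get(gene)
        if window is None:
            continue
        regions.extend(_intersections(window, acr_ivs))
    total_bp = sum(len(r) for r in regions)
    if total_bp == 0:
        warnings.warn("no accessible promoter sequence in the gene set", stacklevel=2)
        return pd.DataFrame(columns=["motif_id", "hits", "kb", "density"])
    seqs = [genome.fetch(r) for r in regions]
    rows = []
    for motif in motifs:
        hits = sum(len(scan_motif(s, motif)) for s in seqs)
        kb = total_bp / 1000.0
        rows.append(
            {"motif_id": motif.motif_id, "hits": hits, "kb": kb, "density": hits / kb}
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["density", "motif_id"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# Motif I/O
# ---------------------------------------------------------------------------

def read_motif_tsv(path) -> list[MotifModel]:
    """Multi-motif TSV: columns motif_id, family, consensus."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        MotifModel(motif_id=str(r.motif_id), family=str(r.family), consensus=str(r.consensus))
        for r in df.itertuples(index=False)
    ]


def write_motif_tsv(path, motifs: Sequence[MotifModel]) -> None:
    with open(path, "w") as fh:
        fh.write("motif_id\tfamily\tconsensus\n")
        for m in motifs:
            if m.consensus is None:
                raise ValueError(f"{m.motif_id}: TSV catalog holds consensus motifs only")
            fh.write(f"{m.motif_id}\t{m.family}\t{m.consensus}\n")


def read_pwm_file(path, threshold_fraction: float = 0.8) -> list[MotifModel]:
    """Plain-text PWMs: ``>motif_id [family]`` header, then 4 rows (A, C, G, T)
    of whitespace-separated column probabilities."""
    motifs = []
    header: list[str] | None = None
    rows: list[list[float]] = []

    def flush():
        if header is None:
            return
        if len(rows) != 4:
            raise ValueError(f"motif {header[0]}: expected 4 PWM rows, got {len(rows)}")
        motifs.append(
            MotifModel(
                motif_id=header[0],
                family=header[1] if len(header) > 1 else "",
                pwm=np.array(rows),
                threshold_fraction=threshold_fraction,
            )
        )

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                header, rows = line[1:].split(), []
            else:
                rows.append([float(x) for x in line.split()])
    flush()
    return motifs
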