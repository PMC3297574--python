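"""Sliding-window genome scoring, gene association, and enrichment testing.

Windows of 1000 bp advancing by 500 bp tile each chromosome; windows whose
coding overlap reaches 50% are excluded before scoring.  Surviving windows
are scored with the trained linear model and called predictions at the
calibrated false-positive-rate cutoff.  Predictions are associated with the
host gene when their midpoint falls in an intron, otherwise with the nearest
gene, and gene-level enrichment in a target gene set is assessed with an
exact binomial tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import binomtest

from .classifier import LinearModel, build_feature_matrix
from .motifs import Pwm
from .records import GeneAnnotation, Interval, SequenceRecord, merge_blocks


@dataclass
class ScanWindow:
    interval: Interval
    coding_overlap_fraction: float
    score: Optional[float] = None
    is_prediction: bool = False
    associated_gene: Optional[str] = None


@dataclass
class EnrichmentResult:
    observed: int
    tested: int
    background_rate: float
    fold: float
    p_value: float


def make_windows(
    genome: Sequence[SequenceRecord],
    annotations: Sequence[GeneAnnotation],
    window: int = 1000,
    step: int = 500,
    max_coding_overlap: float = 0.5,
) -> list[ScanWindow]:
    """Tile chromosomes with fixed windows; a trailing window flush with the
    chromosome end is added when the uncovered tail is >= window/2.  Windows
    overlapping coding sequence by >= ``max_coding_overlap`` are dropped."""
    if window <= 0 or not (0 < step <= window):
        raise ValueError("need window > 0 and 0 < step <= window")
    cds_blocks: dict[str, list[tuple[int, int]]] = {}
    for gene in annotations:
        for cds in gene.cds_intervals:
            cds_blocks.setdefault(cds.chrom, []).append((cds.start, cds.end))
    cds_blocks = {c: merge_blocks(b) for c, b in cds_blocks.items()}

    out = []
    for chrom in genome:
        length = len(chrom)
        starts = list(range(0, max(length - window, 0) + 1, step))
        if not starts and length >= window / 2:
            starts = [0]
        if starts:
            covered_to = starts[-1] + window
            if length - covered_to >= window / 2 and length >= window:
                starts.append(length - window)
        blocks = cds_blocks.get(chrom.id, [])
        for start in starts:
            end = min(start + window, length)
            iv = Interval(chrom.id, start, end)
            overlap = sum(
                max(0, min(end, be) - max(start, bs)) for bs, be in blocks
            )
            frac = overlap / (end - start)
            if frac >= max_coding_overlap:
                continue
            out.append(ScanWindow(interval=iv, coding_overlap_fraction=frac))
    return out


def score_windows(
    windows: Sequence[ScanWindow],
    genome: Sequence[SequenceRecord],
    model: LinearModel,
    pwms: Sequence[Pwm],
) -> list[ScanWindow]:
    """Score = w . features(window) + b; prediction flag set at the model's
    calibrated cutoff.  Windows are scored with the model's training-time
    scan background and match threshold."""
    by_id = {p.id: p for p in pwms}
    missing = [m for m in model.motif_ids if m not in by_id]
    if missing:
        raise ValueError(f"motifs missing from library: {missing}")
    ordered_pwms = [by_id[m] for m in model.motif_ids]
    chrom_by_id = {c.id: c for c in genome}
    seqs = []
    for i, win in enumerate(windows):
        chrom = chrom_by_id[win.interval.chrom]
        seqs.append(
            chrom.subsequence(
                win.interval.start, win.interval.end, sub_id=f"window_{i:06d}"
            )
        )
    fm = build_feature_matrix(
        seqs,
        ordered_pwms,
        p_threshold=model.p_threshold,
        background=model.background,
    )
    scores = model.decision(fm.values)
    cutoff = model.cutoff if model.cutoff is not None else 0.0
    for win, score in zip(windows, scores):
        win.score = float(score)
        win.is_prediction = bool(score >= cutoff)
    return list(windows)


def merge_predictions(windows: Sequence[ScanWindow]) -> list[Interval]:
    """Union of overlapping positive windows (optional merged track)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for w in windows:
        if w.is_prediction:
            by_chrom.setdefault(w.interval.chrom, []).append(
                (w.interval.start, w.interval.end)
            )
    out = []
    for chrom in sorted(by_chrom):
        for start, end in merge_blocks(by_chrom[chrom]):
            out.append(Interval(chrom, start, end))
    return out


def associate_genes(
    predictions: Sequence[ScanWindow],
    annotations: Sequence[GeneAnnotation],
) -> dict[int, Optional[str]]:
    """Map each prediction (by index) to a gene: the host gene when the
    window midpoint lies in one of its introns, else the gene at minimum
    edge-to-edge distance; ties broken by lexicographically smaller id."""
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for gene in annotations:
        by_chrom.setdefault(gene.interval.chrom, []).append(gene)
    mapping: dict[int, Optional[str]] = {}
    for i, win in enumerate(predictions):
        genes = by_chrom.get(win.interval.chrom, [])
        if not genes:
            mapping[i] = None
            continue
        mid = win.interval.midpoint
        host = sorted(
            g.gene_id
            for g in genes
            if any(iv.contains_point(win.interval.chrom, mid) for iv in g.intron_intervals)
        )
        if host:
            mapping[i] = host[0]
            continue
        best = min(genes, key=lambda g: (win.interval.distance_to(g.interval), g.gene_id))
        mapping[i] = best.gene_id
    for i, win in enumerate(predictions):
        win.associated_gene = mapping[i]
    return mapping


def enrichment_test(
    associated_genes: Sequence[str],
    target_gene_set: Sequence[str],
    background_rate: float,
) -> EnrichmentResult:
    """Exact upper binomial tail for the overlap between the distinct
    associated genes and a target gene set, at background hit rate p0."""
    if not (0 < background_rate < 1):
        raise ValueError("background_rate must lie in (0, 1)")
    genes = sorted(set(g for g in associated_genes if g is not None))
    n = len(genes)
    if n < 1:
        raise ValueError("no associated genes to test")
    k = len(set(genes) & set(target_gene_set))
    fold = (k / n) / background_rate
    p = float(binomtest(k, n, background_rate, alternative="greater").pvalue)
    return EnrichmentResult(
        observed=k, tested=n, background_rate=background_rate, fold=fold, p_value=p
    )


def predictions_to_bed(windows: Sequence[ScanWindow], path) -> None:
    with open(path, "w") as fh:
        for i, w in enumerate(windows):
            if not w.is_prediction:
                continue
            score = int(round((w.score or 0.0) * 100))
            fh.write(
                f"{w.interval.chrom}\t{w.interval.start}\t{w.interval.end}\t"
                f"pred_{i:06d}\t{score}\t+\n"
            )
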