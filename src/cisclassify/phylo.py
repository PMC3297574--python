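"""Ortholog selection by sequence-identity window, and redundancy removal.

Candidate orthologous regions are accepted when their global percent
identity to the source enhancer lies in [min_identity, max_identity) —
by default at least 50% but strictly below 80%, a window that excludes
both near-duplicates (overfitting risk) and sequences too diverged to
retain the regulatory signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .align import percent_identity
from .records import SequenceRecord


@dataclass
class OrthologHit:
    source_id: str
    target: SequenceRecord
    percent_identity: float
    aligned_length: int


def find_orthologs(
    enhancer: SequenceRecord,
    candidates: Sequence[SequenceRecord],
    min_identity: float = 50.0,
    max_identity_exclusive: float = 80.0,
    max_per_enhancer: Optional[int] = None,
    seed: int = 0,
) -> list[OrthologHit]:
    """Accepted hits in [min_identity, max_identity), best hit per species.

    When ``max_per_enhancer`` is set, that many accepted hits are sampled
    uniformly at random (seeded); otherwise all accepted hits are returned.
    """
    best_by_species: dict[str, OrthologHit] = {}
    unkeyed: list[OrthologHit] = []
    for cand in candidates:
        identity, aligned = percent_identity(enhancer, cand)
        if not (min_identity <= identity < max_identity_exclusive):
            continue
        hit = OrthologHit(enhancer.id, cand, identity, aligned)
        if cand.species is None:
            unkeyed.append(hit)
        else:
            prev = best_by_species.get(cand.species)
            if prev is None or hit.percent_identity > prev.percent_identity:
                best_by_species[cand.species] = hit
    hits = sorted(
        list(best_by_species.values()) + unkeyed,
        key=lambda h: (-h.percent_identity, h.target.id),
    )
    if max_per_enhancer is not None and len(hits) > max_per_enhancer:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(hits), size=max_per_enhancer, replace=False)
        hits = [hits[i] for i in sorted(idx)]
    return hits


def deduplicate_overlapping(
    enhancers: Sequence[SequenceRecord],
    max_length: int = 2000,
) -> list[SequenceRecord]:
    """Cluster genomically overlapping records (transitive closure) and keep
    the shortest member of each cluster; records longer than ``max_length``
    are dropped before clustering.  Ties go to the earlier start."""
    kept = []
    for rec in enhancers:
        if rec.origin is None:
            raise ValueError(f"record {rec.id!r} has no genomic origin")
        if len(rec) <= max_length:
            kept.append(rec)
    if not kept:
        return []
    assemblies = {rec.species for rec in kept}
    if len(assemblies) > 1:
        raise ValueError(f"records from mixed assemblies/species: {sorted(map(str, assemblies))}")

    # single sweep per chromosome: sorted intervals chain into clusters
    order = sorted(range(len(kept)), key=lambda i: (kept[i].origin.chrom, kept[i].origin.start))
    clusters: list[list[int]] = []
    cluster_end: dict[str, int] = {}
    for i in order:
        iv = kept[i].origin
        if (
            clusters
            and kept[clusters[-1][0]].origin.chrom == iv.chrom
            and iv.start < cluster_end[iv.chrom]
        ):
            clusters[-1].append(i)
            cluster_end[iv.chrom] = max(cluster_end[iv.chrom], iv.end)
        else:
            clusters.append([i])
            cluster_end[iv.chrom] = iv.end
    out = []
    for members in clusters:
        best = min(members, key=lambda i: (len(kept[i]), kept[i].origin.start))
        out.append(kept[best])
    return out
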