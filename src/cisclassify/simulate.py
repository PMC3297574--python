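"""Seeded synthetic data: background sequence, planted motif occurrences,
controlled ortholog divergence, and small annotated genomes.

Every generator is a pure function of its arguments including the seed, so
fixtures are reproducible byte-for-byte.  The generators emulate the study
conditions of a founder-cell-enhancer classification experiment: positives
are GC-matched background carrying occurrences of a small set of "signal"
PWMs, negatives are plain background, orthologs are positives diverged to a
target percent identity with the planted sites preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .align import percent_identity
from .io import write_bed, write_fasta, write_gff3
from .motifs import BASES, Pwm
from .records import (
    GeneAnnotation,
    Interval,
    SequenceRecord,
    SyntheticWorld,
    reverse_complement,
)


def _background_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def sample_background(length: int, gc: float, seed: int) -> SequenceRecord:
    """I.i.d. background with P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0.0 <= gc <= 1.0):
        raise ValueError(f"gc must lie in [0, 1], got {gc}")
    rng = np.random.default_rng(seed)
    codes = rng.choice(4, size=length, p=_background_probs(gc))
    residues = "".join(BASES[i] for i in codes)
    return SequenceRecord(id=f"bg_{seed}_{length}", residues=residues)


def insert_tandem_repeats(
    seq: SequenceRecord, n_runs: int, kmer: int, copies: int, seed: int
) -> SequenceRecord:
    """Overwrite stretches with lowercase tandem k-mer runs (soft-masked);
    the lowercase fraction is this package's repeat-content measure."""
    rng = np.random.default_rng(seed)
    residues = list(seq.residues)
    run_len = kmer * copies
    for _ in range(n_runs):
        unit = "".join(BASES[i] for i in rng.integers(0, 4, size=kmer))
        start = int(rng.integers(0, len(residues) - run_len + 1))
        residues[start : start + run_len] = (unit * copies).lower()
    return SequenceRecord(seq.id, "".join(residues), seq.origin, seq.species)


def plant_motifs(
    seq: SequenceRecord,
    pwms: Sequence[Pwm],
    count_per_pwm: int,
    seed: int,
    max_attempts: int = 200,
) -> tuple[SequenceRecord, list[tuple[str, int, str]]]:
    """Plant ``count_per_pwm`` sampled occurrences of each PWM at random
    non-overlapping offsets (random strand).  Returns the modified sequence
    and the placements as (pwm_id, offset, strand)."""
    if count_per_pwm < 0:
        raise ValueError("count_per_pwm must be >= 0")
    if count_per_pwm == 0 or not pwms:
        return seq, []
    total = count_per_pwm * sum(p.width for p in pwms)
    if total > len(seq):
        raise ValueError(
            f"cannot plant {total} bp of motifs into a {len(seq)} bp sequence"
        )
    rng = np.random.default_rng(seed)
    jobs = [pwm for pwm in pwms for _ in range(count_per_pwm)]
    for _ in range(max_attempts):
        taken: list[tuple[int, int]] = []
        placements: list[tuple[str, int, str]] = []
        ok = True
        for pwm in jobs:
            w = pwm.width
            placed = False
            for _ in range(200):
                offset = int(rng.integers(0, len(seq) - w + 1))
                if all(offset + w <= s or offset >= e for s, e in taken):
                    taken.append((offset, offset + w))
                    strand = "+" if rng.random() < 0.5 else "-"
                    placements.append((pwm.id, offset, strand))
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            residues = list(seq.residues)
            pwm_by_id = {p.id: p for p in pwms}
            for pwm_id, offset, strand in placements:
                site = pwm_by_id[pwm_id].sample(rng)
                if strand == "-":
                    site = reverse_complement(site)
                residues[offset : offset + len(site)] = site
            placements.sort(key=lambda p: p[1])
            return (
                SequenceRecord(seq.id, "".join(residues), seq.origin, seq.species),
                placements,
            )
    raise ValueError(
        f"could not pack {len(jobs)} motif occurrences into {len(seq)} bp "
        f"after {max_attempts} attempts"
    )


def diverge(
    seq: SequenceRecord,
    target_identity: float,
    seed: int,
    preserve: Optional[Sequence[tuple[int, int]]] = None,
    tolerance: float = 2.0,
    indel_fraction: float = 0.1,
    max_rounds: int = 2000,
) -> SequenceRecord:
    """Mutate a copy of ``seq`` (substitutions and short geometric indels,
    9:1) until its global percent identity to the original is within
    ``tolerance`` percentage points of ``target_identity`` x 100.
    Positions inside ``preserve`` intervals are copied verbatim."""
    if not (0.0 <= target_identity <= 1.0):
        raise ValueError("target_identity must lie in [0, 1]")
    preserve = list(preserve or [])
    for s, e in preserve:
        if not (0 <= s < e <= len(seq)):
            raise ValueError(f"preserve interval ({s}, {e}) outside sequence")
    out_id = f"{seq.id}_div{int(round(target_identity * 100))}"
    if target_identity >= 1.0:
        return SequenceRecord(out_id, seq.residues, None, seq.species)
    target = target_identity * 100.0
    rng = np.random.default_rng(seed)

    # mutable representation: (residue, protected) pairs
    state = [[c, False] for c in seq.residues]
    for s, e in preserve:
        for i in range(s, e):
            state[i][1] = True
    if all(p for _, p in state):
        raise ValueError("every position is preserved; target identity unreachable")

    def identity_now() -> float:
        cur = SequenceRecord("cur", "".join(c for c, _ in state))
        return percent_identity(seq, cur)[0]

    batch = max(1, len(seq) // 100)
    snapshot = [row[:] for row in state]
    for _ in range(max_rounds):
        ident = identity_now()
        if target - tolerance <= ident <= target + tolerance:
            return SequenceRecord(out_id, "".join(c for c, _ in state), None, seq.species)
        if ident < target - tolerance:
            # overshot: rewind and try smaller mutation batches
            state = [row[:] for row in snapshot]
            if batch == 1:
                raise ValueError(
                    f"target identity {target:.1f}% unreachable within +/- "
                    f"{tolerance} points (identity jumped past the window)"
                )
            batch = max(1, batch // 2)
            continue
        snapshot = [row[:] for row in state]
        free = [i for i, (_, p) in enumerate(state) if not p]
        if not free:
            raise ValueError("no mutable positions left; target identity unreachable")
        for _ in range(batch):
            if rng.random() < indel_fraction and len(state) > 10:
                length = min(int(rng.geometric(0.5)), 6)
                if rng.random() < 0.5:  # deletion of a free run
                    starts = [
                        i
                        for i in free
                        if i + length <= len(state)
                        and all(not state[j][1] for j in range(i, i + length))
                    ]
                    if starts:
                        i = starts[int(rng.integers(0, len(starts)))]
                        del state[i : i + length]
                else:  # insertion at a free boundary
                    i = free[int(rng.integers(0, len(free)))]
                    ins = [
                        [BASES[int(rng.integers(0, 4))], False] for _ in range(length)
                    ]
                    state[i:i] = ins
            else:
                i = free[int(rng.integers(0, len(free)))]
                current = state[i][0].upper()
                others = [b for b in BASES if b != current]
                state[i][0] = others[int(rng.integers(0, 3))]
            free = [i for i, (_, p) in enumerate(state) if not p]
    raise ValueError(f"failed to reach target identity {target:.1f}% in {max_rounds} rounds")


# ---------------------------------------------------------------------------
# PWM generators (study-condition defaults)

SIGNAL_WIDTH = 8
SIGNAL_DOMINANT = 0.9


def make_pwm(
    id: str, consensus_codes: np.ndarray, dominant: float = SIGNAL_DOMINANT, **kw
) -> Pwm:
    width = consensus_codes.size
    probs = np.full((width, 4), (1.0 - dominant) / 3.0)
    probs[np.arange(width), consensus_codes] = dominant
    return Pwm(id=id, probs=probs, **kw)


def make_random_pwms(
    n: int,
    seed: int,
    width: int = SIGNAL_WIDTH,
    dominant: float = SIGNAL_DOMINANT,
    prefix: str = "pwm",
) -> list[Pwm]:
    """Random-consensus PWMs with a fixed per-column dominant probability."""
    rng = np.random.default_rng(seed)
    return [
        make_pwm(f"{prefix}_{i:03d}", rng.integers(0, 4, size=width), dominant)
        for i in range(n)
    ]


def make_positives(
    n: int,
    signal_pwms: Sequence[Pwm],
    seed: int,
    length: int = 1000,
    gc: float = 0.43,
    min_copies: int = 1,
    max_copies: int = 2,
) -> tuple[list[SequenceRecord], list[list[tuple[str, int, str]]]]:
    """Positive training sequences: background with 1-2 planted occurrences
    of every signal PWM (counts drawn per sequence and per motif)."""
    rng = np.random.default_rng(seed)
    records, all_placements = [], []
    for i in range(n):
        rec = sample_background(length, gc, int(rng.integers(0, 2**31)))
        rec = SequenceRecord(f"pos_{i:03d}", rec.residues)
        placements: list[tuple[str, int, str]] = []
        for pwm in signal_pwms:
            copies = int(rng.integers(min_copies, max_copies + 1))
            rec, placed = plant_motifs(rec, [pwm], copies, int(rng.integers(0, 2**31)))
            placements.extend(placed)
        records.append(rec)
        all_placements.append(sorted(placements, key=lambda p: p[1]))
    return records, all_placements


def make_ortholog(
    positive: SequenceRecord,
    placements: Sequence[tuple[str, int, str]],
    target_identity: float,
    seed: int,
    pwm_widths: Optional[dict[str, int]] = None,
    default_width: int = SIGNAL_WIDTH,
    species: str = "synthetic_sp",
) -> SequenceRecord:
    """Diverged copy of a positive with the planted sites preserved."""
    preserve = [
        (off, off + (pwm_widths or {}).get(pid, default_width))
        for pid, off, _ in placements
    ]
    out = diverge(positive, target_identity, seed, preserve=preserve)
    out.species = species
    out.id = f"{positive.id}_{species}"
    return out


# ---------------------------------------------------------------------------
# Synthetic worlds


def build_synthetic_world(
    n_chromosomes: int,
    chrom_length: int,
    n_genes: int,
    n_enhancers: int,
    signal_pwms: Sequence[Pwm],
    decoy_pwms: Sequence[Pwm],
    seed: int,
    intron_fraction: float = 0.5,
    gc: float = 0.43,
    enhancer_length: int = 1000,
    copies_per_pwm: int = 2,
    gene_cds_length: int = 200,
    gene_intron_length: int = 1200,
) -> SyntheticWorld:
    """A toy genome: background chromosomes, non-overlapping two-exon gene
    models, and planted enhancers — a configurable fraction inside introns
    of designated "FC" genes, the rest intergenic.  Every planted enhancer
    contains ``copies_per_pwm`` occurrences of each signal PWM.

    Elements are laid out in shuffled equal slots per chromosome (genes and
    intergenic enhancers jittered within their slot), which keeps gene
    density realistic for a compact genome while guaranteeing that nothing
    overlaps."""
    rng = np.random.default_rng(seed)
    gene_span = 2 * gene_cds_length + gene_intron_length
    chroms = [
        SequenceRecord(
            f"chr{i + 1}",
            sample_background(chrom_length, gc, int(rng.integers(0, 2**31))).residues,
        )
        for i in range(n_chromosomes)
    ]

    n_intronic = int(round(n_enhancers * intron_fraction))
    n_intergenic = n_enhancers - n_intronic
    total_slots = n_genes + n_intergenic
    slots_per_chrom = -(-total_slots // n_chromosomes)
    slot_len = chrom_length // max(slots_per_chrom, 1)
    margin = 50
    if slot_len < gene_span + 2 * margin and n_genes > 0:
        raise ValueError(
            f"packing failure: gene_000 (span {gene_span} bp) does not fit a "
            f"{slot_len} bp slot"
        )
    if n_intergenic > 0 and slot_len < enhancer_length + 2 * margin:
        raise ValueError(
            f"packing failure: enhancer_000 ({enhancer_length} bp) does not fit a "
            f"{slot_len} bp slot"
        )
    if n_intronic > 0 and gene_intron_length < enhancer_length:
        raise ValueError(
            f"packing failure: enhancer_000 ({enhancer_length} bp) does not fit a "
            f"{gene_intron_length} bp intron"
        )
    if n_intronic > n_genes:
        raise ValueError("packing failure: more intronic enhancers than host genes")

    slots = [
        (chroms[c].id, s * slot_len)
        for c in range(n_chromosomes)
        for s in range(slots_per_chrom)
    ]
    order = rng.permutation(len(slots))
    gene_slots = [slots[i] for i in order[:n_genes]]
    intergenic_slots = [slots[i] for i in order[n_genes:total_slots]]

    annotations: list[GeneAnnotation] = []
    for g, (chrom_id, slot_start) in enumerate(gene_slots):
        jitter = int(rng.integers(margin, slot_len - gene_span - margin + 1))
        start = slot_start + jitter
        strand = "+" if rng.random() < 0.5 else "-"
        cds = [
            Interval(chrom_id, start, start + gene_cds_length, strand),
            Interval(
                chrom_id,
                start + gene_cds_length + gene_intron_length,
                start + gene_span,
                strand,
            ),
        ]
        annotations.append(
            GeneAnnotation(
                f"gene_{g:03d}", Interval(chrom_id, start, start + gene_span, strand), strand, cds
            )
        )

    planted: list[Interval] = []
    planted_motifs: list[list[str]] = []
    fc_gene_ids: list[str] = []
    host_order = list(rng.permutation(len(annotations)))
    for e in range(n_intronic):
        gene = annotations[host_order[e]]
        intron = gene.intron_intervals[0]
        offset = int(rng.integers(intron.start, intron.end - enhancer_length + 1))
        planted.append(Interval(intron.chrom, offset, offset + enhancer_length))
        planted_motifs.append([p.id for p in signal_pwms])
        fc_gene_ids.append(gene.gene_id)
    for chrom_id, slot_start in intergenic_slots:
        jitter = int(rng.integers(margin, slot_len - enhancer_length - margin + 1))
        start = slot_start + jitter
        planted.append(Interval(chrom_id, start, start + enhancer_length))
        planted_motifs.append([p.id for p in signal_pwms])

    # write planted enhancer content into the chromosomes
    residues = {c.id: list(c.residues) for c in chroms}
    for iv in planted:
        region = SequenceRecord("tmp", "".join(residues[iv.chrom][iv.start : iv.end]))
        region, _ = plant_motifs(
            region, signal_pwms, copies_per_pwm, int(rng.integers(0, 2**31))
        )
        residues[iv.chrom][iv.start : iv.end] = region.residues
    genome = [SequenceRecord(c.id, "".join(residues[c.id])) for c in chroms]

    # intergenic enhancers contribute their closest gene as an "FC gene"
    for iv, _gid in zip(planted[n_intronic:], range(n_enhancers - n_intronic)):
        same_chrom = [g for g in annotations if g.interval.chrom == iv.chrom]
        if same_chrom:
            closest = min(
                same_chrom, key=lambda g: (iv.distance_to(g.interval), g.gene_id)
            )
            fc_gene_ids.append(closest.gene_id)

    return SyntheticWorld(
        genome=genome,
        annotations=annotations,
        planted_enhancers=planted,
        planted_motif_ids=planted_motifs,
        fc_gene_ids=sorted(set(fc_gene_ids)),
        signal_pwms=list(signal_pwms),
        decoy_pwms=list(decoy_pwms),
        seed=seed,
    )


def write_world(world: SyntheticWorld, directory) -> dict[str, Path]:
    """Emit FASTA + GFF3 + BED for a synthetic world."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": directory / "genome.fa",
        "gff3": directory / "genes.gff3",
        "bed": directory / "planted_enhancers.bed",
    }
    write_fasta(world.genome, paths["fasta"])
    write_gff3(world.annotations, paths["gff3"])
    write_bed(
        world.planted_enhancers,
        paths["bed"],
        names=[f"enhancer_{i:03d}" for i in range(len(world.planted_enhancers))],
    )
    return paths
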