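"""De novo motif discovery with a collapsed Gibbs sampler (ZOOPS model).

Each sequence carries zero or one occurrence of the motif (site prior 0.5);
motif columns have Dirichlet(0.5) priors and the background is a fixed
mononucleotide model estimated from the input.  Discovered sites are masked
before the next motif is searched, so site sets of the returned motifs never
overlap.  The training set is optionally restricted so that each reference
enhancer contributes at most two orthologs, preventing enhancers with many
orthologs from dominating the discovered motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .motifs import BASES, Pwm
from .records import SequenceRecord

DEFAULT_WIDTHS = (6, 8, 10, 12)


@dataclass
class GibbsConfig:
    width: Optional[int] = None  # None: search DEFAULT_WIDTHS
    n_motifs: int = 5
    model: str = "zoops"  # zoops | oops
    n_restarts: int = 10
    max_iterations: int = 500
    no_improve_stop: int = 200
    site_prior: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width is not None and not (4 <= self.width <= 20):
            raise ValueError("motif width must lie in [4, 20]")
        if not (1 <= self.n_motifs <= 50):
            raise ValueError("n_motifs must lie in [1, 50]")
        if self.model not in ("zoops", "oops"):
            raise ValueError(f"unknown site model {self.model!r}")


@dataclass
class DiscoveredMotif:
    pwm: Pwm
    sites: dict[str, int]  # sequence id -> forward offset
    score: float = 0.0  # information content x site count


def restrict_training_set(
    enhancers: Sequence[SequenceRecord],
    orthologs: Mapping[str, Sequence[SequenceRecord]],
    max_orthologs: int = 2,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Every enhancer once, plus at most ``max_orthologs`` of its orthologs
    sampled without replacement (seeded)."""
    ids = {e.id for e in enhancers}
    unknown = set(orthologs) - ids
    if unknown:
        raise ValueError(f"ortholog keys without enhancers: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    out = list(enhancers)
    for enh in enhancers:
        pool = list(orthologs.get(enh.id, []))
        take = min(max_orthologs, len(pool))
        if take > 0:
            idx = rng.choice(len(pool), size=take, replace=False)
            out.extend(pool[i] for i in sorted(idx))
    return out


def _encode(residues: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.int64)
    for i, c in enumerate(BASES):
        table[ord(c)] = i
        table[ord(c.lower())] = i
    return table[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


def site_posterior(
    code: np.ndarray,
    valid: np.ndarray,
    counts_others: np.ndarray,
    n_other_sites: int,
    background: np.ndarray,
    site_prior: float,
    zoops: bool = True,
) -> tuple[np.ndarray, float]:
    """Predictive ZOOPS posterior over site placements for one sequence.

    Returns (p_offsets, p_none): probability of a site at each valid offset
    and of no site, given the sites currently assigned in the other
    sequences (collapsed over motif column parameters with Dirichlet(0.5)
    priors).  ``valid`` marks offsets whose window is free of N/mask.
    """
    width = counts_others.shape[0]
    theta = (counts_others + 0.5) / (n_other_sites + 2.0)
    n = code.size - width + 1
    weights = np.zeros(max(n, 0))
    if n > 0:
        windows = np.lib.stride_tricks.sliding_window_view(code, width)
        safe = np.minimum(windows, 3)
        ratio = theta[np.arange(width)[None, :], safe] / background[safe]
        weights = np.where(valid[:n], np.exp(np.log(ratio).sum(axis=1)), 0.0)
    n_valid = int(valid[:n].sum()) if n > 0 else 0
    if n_valid == 0:
        return weights, 1.0
    prior_per_offset = site_prior / n_valid
    unnorm_sites = prior_per_offset * weights
    unnorm_none = (1.0 - site_prior) if zoops else 0.0
    total = unnorm_sites.sum() + unnorm_none
    if total <= 0:
        return np.zeros_like(weights), 1.0
    return unnorm_sites / total, unnorm_none / total


def _state_score(sites: dict[int, int], codes: list[np.ndarray], width: int) -> float:
    """Information content (bits, vs uniform) times number of sites."""
    if len(sites) < 2:
        return 0.0
    counts = np.zeros((width, 4))
    for i, off in sites.items():
        window = codes[i][off : off + width]
        counts[np.arange(width), np.minimum(window, 3)] += 1
    probs = (counts + 0.5) / (counts.sum(axis=1, keepdims=True) + 2.0)
    ic = float(np.sum(probs * np.log2(probs / 0.25)))
    return ic * len(sites)


def _gibbs_single_width(
    seqs: Sequence[SequenceRecord],
    codes: list[np.ndarray],
    masks: list[np.ndarray],
    width: int,
    config: GibbsConfig,
    background: np.ndarray,
    rng: np.random.Generator,
) -> Optional[DiscoveredMotif]:
    zoops = config.model == "zoops"
    valid_all = []
    for code, mask in zip(codes, masks):
        n = code.size - width + 1
        if n <= 0:
            valid_all.append(np.zeros(0, dtype=bool))
            continue
        bad = (code == 4) | mask
        window_bad = np.lib.stride_tricks.sliding_window_view(bad, width).any(axis=1)
        valid_all.append(~window_bad)

    best_sites: Optional[dict[int, int]] = None
    best_score = -1.0
    for _ in range(config.n_restarts):
        sites: dict[int, int] = {}
        for i, valid in enumerate(valid_all):
            options = np.nonzero(valid)[0]
            if options.size and (not zoops or rng.random() < config.site_prior):
                sites[i] = int(options[rng.integers(0, options.size)])
        score, stale = 0.0, 0
        counts = np.zeros((width, 4))
        for i, off in sites.items():
            counts[np.arange(width), np.minimum(codes[i][off : off + width], 3)] += 1

        for _iter in range(config.max_iterations):
            for i in range(len(codes)):
                if i in sites:
                    off = sites.pop(i)
                    counts[
                        np.arange(width), np.minimum(codes[i][off : off + width], 3)
                    ] -= 1
                p_off, p_none = site_posterior(
                    codes[i], valid_all[i], counts, len(sites), background,
                    config.site_prior, zoops,
                )
                u = rng.random()
                if u >= p_none and p_off.sum() > 0:
                    off = int(rng.choice(p_off.size, p=p_off / p_off.sum()))
                    sites[i] = off
                    counts[
                        np.arange(width), np.minimum(codes[i][off : off + width], 3)
                    ] += 1
            new_score = _state_score(sites, codes, width)
            if new_score > score + 1e-12:
                score, stale = new_score, 0
            else:
                stale += 1
                if stale >= config.no_improve_stop:
                    break

        # deterministic polish: argmax reassignment to a fixed point
        for _ in range(20):
            changed = False
            for i in range(len(codes)):
                if i in sites:
                    off = sites.pop(i)
                    counts[
                        np.arange(width), np.minimum(codes[i][off : off + width], 3)
                    ] -= 1
                p_off, p_none = site_posterior(
                    codes[i], valid_all[i], counts, len(sites), background,
                    config.site_prior, zoops,
                )
                old = sites.get(i)
                if p_off.size and p_off.max() > p_none:
                    off = int(np.argmax(p_off))
                    sites[i] = off
                    counts[
                        np.arange(width), np.minimum(codes[i][off : off + width], 3)
                    ] += 1
                if sites.get(i) != old and not (old is None and i not in sites):
                    changed = True
            if not changed:
                break
        score = _state_score(sites, codes, width)
        if score > best_score:
            best_score, best_sites = score, dict(sites)

    if not best_sites or len(best_sites) < 2:
        return None
    counts = np.zeros((width, 4))
    for i, off in best_sites.items():
        counts[np.arange(width), np.minimum(codes[i][off : off + width], 3)] += 1
    pwm = Pwm.from_counts(
        f"denovo_w{width}", counts, pseudocount=0.5, source="de_novo"
    )
    return DiscoveredMotif(
        pwm=pwm,
        sites={seqs[i].id: off for i, off in best_sites.items()},
        score=best_score,
    )


def gibbs_motif_search(
    seqs: Sequence[SequenceRecord], config: GibbsConfig
) -> list[DiscoveredMotif]:
    """Sequential motif discovery: sample the best-scoring site configuration
    (information content x site count, best of ``n_restarts``), mask its
    sites, and repeat; with unset width, widths 6/8/10/12 all contribute
    candidates and the top ``n_motifs`` by score are kept."""
    widths = [config.width] if config.width is not None else list(DEFAULT_WIDTHS)
    if len(seqs) < 5:
        raise ValueError("need at least 5 sequences for motif discovery")
    for s in seqs:
        if len(s) < max(widths):
            raise ValueError(f"sequence {s.id!r} shorter than motif width")
    codes = [_encode(s.residues) for s in seqs]
    counts = np.full(4, 1.0)
    for code in codes:
        for b in range(4):
            counts[b] += np.sum(code == b)
    background = counts / counts.sum()

    seed_seq = np.random.SeedSequence(config.seed)
    candidates: list[DiscoveredMotif] = []
    for w_idx, width in enumerate(widths):
        masks = [np.zeros(c.size, dtype=bool) for c in codes]
        per_width = config.n_motifs if config.width is not None else max(
            1, -(-config.n_motifs // len(widths))
        )
        for k in range(per_width):
            rng = np.random.default_rng(seed_seq.spawn(1)[0])
            motif = _gibbs_single_width(
                seqs, codes, masks, width, config, background, rng
            )
            if motif is None:
                break
            motif.pwm.id = f"denovo_w{width}_{k}"
            motif.pwm.name = motif.pwm.id
            candidates.append(motif)
            id_to_idx = {s.id: i for i, s in enumerate(seqs)}
            for sid, off in motif.sites.items():
                masks[id_to_idx[sid]][off : off + width] = True
    candidates.sort(key=lambda m: -m.score)
    return candidates[: config.n_motifs]
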