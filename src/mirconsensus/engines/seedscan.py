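"""Seed-match scanning engine (`seedscan`).

Reports every exact complementary match of the miRNA seed in a UTR and
classifies it with the canonical site-type hierarchy:

* ``8mer``    — perfect match to miRNA positions 2-8 plus an A opposite position 1
* ``7mer-m8`` — perfect match to positions 2-8
* ``7mer-A1`` — perfect match to positions 2-7 plus the A1 anchor
* ``6mer``    — perfect match to positions 2-7 only

Because the miRNA pairs its target antiparallel, a seed match read 5'->3'
on the UTR is the reverse complement of the seed, and the A1 anchor sits
immediately 3' of the match.  The raw score is the sum of a site-type
score, the local A/U fraction in the 30 nt flanking the match, and a
positional term rewarding central placement within the UTR; the component
scores are this package's own, documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from ..sequence_space import MiRNARecord, UTRRecord, reverse_complement
from .sites import TargetSite, lift_seed, reduce_overlapping

_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}

TYPE_SCORES: Mapping[str, float] = {
    "8mer": 3.0,
    "7mer-m8": 2.0,
    "7mer-A1": 1.5,
    "6mer": 1.0,
}

#: hierarchy used when several classifications apply at nearby offsets
TYPE_RANK = {"8mer": 4, "7mer-m8": 3, "7mer-A1": 2, "6mer": 1, "non-canonical": 0}


@dataclass(frozen=True)
class SeedscanParams:
    au_flank: int = 30  # total flanking nt scanned for A/U content
    position_weight: float = 0.5
    min_score: float = 0.0
    type_scores: Mapping[str, float] = field(default_factory=lambda: dict(TYPE_SCORES))


def classify_match(utr_seq: str, p: int, mirna_seq: str) -> str:
    """Site type of a 6mer-core match starting at local position ``p``.

    ``p`` must be the start of an exact match to the reverse complement of
    miRNA positions 2-7.
    """
    has_m8 = p >= 1 and utr_seq[p - 1] == _COMP[mirna_seq[7]]
    has_a1 = p + 6 < len(utr_seq) and utr_seq[p + 6] == "A"
    if has_m8 and has_a1:
        return "8mer"
    if has_m8:
        return "7mer-m8"
    if has_a1:
        return "7mer-A1"
    return "6mer"


def canonical_type_in(
    utr_seq: str, lo: int, hi: int, mirna_seq: str
) -> tuple[str, int | None]:
    """Best canonical classification of any 6mer core inside [lo, hi).

    Returns (site_type, core start) or ("non-canonical", None).
    """
    core = reverse_complement(mirna_seq[1:7])
    best = ("non-canonical", None)
    p = utr_seq.find(core, max(lo, 0), min(hi, len(utr_seq)))
    while p != -1:
        st = classify_match(utr_seq, p, mirna_seq)
        if TYPE_RANK[st] > TYPE_RANK[best[0]]:
            best = (st, p)
        p = utr_seq.find(core, p + 1, min(hi, len(utr_seq)))
    return best


def au_context(utr_seq: str, lo: int, hi: int, flank: int = 30) -> float:
    """A/U fraction in the ``flank`` nt surrounding [lo, hi) (half per side)."""
    half = flank // 2
    window = utr_seq[max(0, lo - half) : lo] + utr_seq[hi : hi + half]
    if not window:
        return 0.0
    return sum(b in "AU" for b in window) / len(window)


def position_score(lo: int, hi: int, utr_len: int, weight: float = 0.5) -> float:
    """0 at the UTR edges, ``weight`` at the exact center."""
    center = (lo + hi) / 2 / utr_len
    return weight * (1.0 - abs(2.0 * center - 1.0))


def scan_seed_sites(
    mirna: MiRNARecord,
    utr: UTRRecord,
    params: SeedscanParams | None = None,
    conservation=None,
) -> list[TargetSite]:
    """All exact seed matches of ``mirna`` in ``utr`` as TargetSites.

    Overlapping matches are reduced to the best-scoring one per cluster.
    ``conservation`` is an optional track with a ``mean(chrom, start, end)``
    method; when absent the conservation field is left null.
    """
    p_ = params or SeedscanParams()
    seq = utr.sequence
    if len(seq) < 8:
        return []
    core = reverse_complement(mirna.sequence[1:7])
    sites: list[TargetSite] = []
    p = seq.find(core)
    while p != -1:
        site_type = classify_match(seq, p, mirna.sequence)
        if site_type in ("8mer", "7mer-m8"):
            seed_lo, seed_hi = p - 1, p + 6
        else:
            seed_lo, seed_hi = p, p + 6
        raw = (
            p_.type_scores[site_type]
            + au_context(seq, seed_lo, seed_hi, p_.au_flank)
            + position_score(seed_lo, seed_hi, len(seq), p_.position_weight)
        )
        if raw >= p_.min_score:
            g_seed = lift_seed(utr, seed_lo, seed_hi)
            cons = None
            if conservation is not None:
                cons = conservation.mean(g_seed.chrom, g_seed.start, g_seed.end)
            sites.append(
                TargetSite(
                    engine="seedscan",
                    mirna_id=mirna.mirna_id,
                    transcript_id=utr.transcript_id,
                    utr_start=seed_lo,
                    utr_end=seed_hi,
                    seed_start=seed_lo,
                    seed_end=seed_hi,
                    genomic_seed=g_seed,
                    site_type=site_type,
                    raw_score=raw,
                    conservation=cons,
                )
            )
        p = seq.find(core, p + 1)
    return reduce_overlapping(sites)
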