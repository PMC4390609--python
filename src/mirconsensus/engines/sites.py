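"""The TargetSite container shared by all prediction engines."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from ..sequence_space import GenomeInterval, UTRRecord

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer", "non-canonical")


@dataclass(frozen=True)
class TargetSite:
    """One engine's predicted binding event on a UTR.

    Local coordinates are 0-based half-open positions on the UTR sequence
    (5'->3').  ``genomic_seed`` is the genomic span of the seed-paired region
    (for spliced UTRs, the span of the mapped pieces).
    """

    engine: str
    mirna_id: str
    transcript_id: str
    utr_start: int
    utr_end: int
    seed_start: int
    seed_end: int
    genomic_seed: GenomeInterval
    site_type: str
    raw_score: float
    energy: float | None = None
    conservation: float | None = None
    ddg: float | None = None

    def __post_init__(self) -> None:
        if not (
            0 <= self.utr_start <= self.seed_start < self.seed_end <= self.utr_end
        ):
            raise ValueError(
                f"seed [{self.seed_start},{self.seed_end}) not inside "
                f"site [{self.utr_start},{self.utr_end})"
            )
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site_type {self.site_type!r}")


def lift_seed(utr: UTRRecord, seed_start: int, seed_end: int) -> GenomeInterval:
    """Genomic span of a local seed interval (span of spliced pieces)."""
    pieces = utr.local_to_genomic(seed_start, seed_end)
    return GenomeInterval(
        pieces[0].chrom,
        min(p.start for p in pieces),
        max(p.end for p in pieces),
        utr.strand,
    )


def reduce_overlapping(sites: Sequence[TargetSite]) -> list[TargetSite]:
    """Keep the best-scoring site per cluster of UTR-overlapping sites.

    Sites must belong to one (engine, miRNA, transcript) triple; clusters are
    the transitive closure of >=1 nt overlap on local coordinates.  Ties
    break toward the smaller start for determinism.
    """
    if not sites:
        return []
    ordered = sorted(sites, key=lambda s: (s.utr_start, s.utr_end, -s.raw_score))
    out: list[TargetSite] = []
    cluster: list[TargetSite] = [ordered[0]]
    cluster_end = ordered[0].utr_end
    for s in ordered[1:]:
        if s.utr_start < cluster_end:
            cluster.append(s)
            cluster_end = max(cluster_end, s.utr_end)
        else:
            out.append(max(cluster, key=lambda c: (c.raw_score, -c.utr_start)))
            cluster = [s]
            cluster_end = s.utr_end
    out.append(max(cluster, key=lambda c: (c.raw_score, -c.utr_start)))
    return sorted(out, key=lambda s: s.utr_start)


SITE_COLUMNS = (
    "engine",
    "mirna_id",
    "transcript_id",
    "utr_start",
    "utr_end",
    "seed_start",
    "seed_end",
    "chrom",
    "g_start",
    "g_end",
    "strand",
    "site_type",
    "raw_score",
    "energy",
    "conservation",
    "ddg",
)


def sites_to_frame(sites: Iterable[TargetSite]) -> pd.DataFrame:
    rows = [
        (
            s.engine,
            s.mirna_id,
            s.transcript_id,
            s.utr_start,
            s.utr_end,
            s.seed_start,
            s.seed_end,
            s.genomic_seed.chrom,
            s.genomic_seed.start,
            s.genomic_seed.end,
            s.genomic_seed.strand,
            s.site_type,
            s.raw_score,
            s.energy,
            s.conservation,
            s.ddg,
        )
        for s in sites
    ]
    return pd.DataFrame(rows, columns=list(SITE_COLUMNS))


def write_sites_tsv(sites: Iterable[TargetSite], path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False, float_format="%.6g")


def _opt(value) -> float | None:
    return None if pd.isna(value) else float(value)


def read_sites_tsv(path) -> list[TargetSite]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            TargetSite(
                engine=row.engine,
                mirna_id=row.mirna_id,
                transcript_id=row.transcript_id,
                utr_start=int(row.utr_start),
                utr_end=int(row.utr_end),
                seed_start=int(row.seed_start),
                seed_end=int(row.seed_end),
                genomic_seed=GenomeInterval(
                    row.chrom, int(row.g_start), int(row.g_end), row.strand
                ),
                site_type=row.site_type,
                raw_score=float(row.raw_score),
                energy=_opt(row.energy),
                conservation=_opt(row.conservation),
                ddg=_opt(row.ddg),
            )
        )
    return out
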