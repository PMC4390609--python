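"""Experimentally validated miRNA-gene pairs: ingest, dedup, tiering.

Validated interactions come from heterogeneous public exports (TSV), each
tagged with a source database and free-text evidence.  Sources map to
reliability tiers by provenance: manual curation -> high, partial curation
-> medium, text mining -> low.  Matching against predictions happens at
gene-symbol level, since the source databases rarely record isoforms;
predicted pairs absent from every source are treated as presumed
negatives downstream (a known bias, documented in the methods note).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

TIERS = ("high", "medium", "low")
_TIER_RANK = {"high": 2, "medium": 1, "low": 0}

DEFAULT_TIER_MAP: Mapping[str, str] = {
    "oncomirdb": "high",
    "mirecords": "medium",
    "tarbase": "low",
    "mirtarbase": "low",
    "other": "low",
}

_MIRNA_RE = re.compile(r"(mir|let|bart)[a-z]*[-_]?\d", re.IGNORECASE)
_PREFIXED_RE = re.compile(r"^(?!mir-|let-|bart)[a-z]{3,4}-")


def normalize_mirna_id(raw: str, default_organism: str = "hsa") -> str | None:
    """Canonical miRNA id: lower-cased, organism prefix ensured.

    ``"mir-21/PTEN"``-style bare names become ``hsa-mir-21``; strings with
    no recognizable miRNA token (a mir/let family name followed by a
    number) map to None (caller skips with a warning).
    """
    s = raw.strip().lower()
    if not s or not _MIRNA_RE.search(s):
        return None
    if not _PREFIXED_RE.match(s):
        s = f"{default_organism}-{s}"
    return s


def normalize_gene(raw: str) -> str:
    return raw.strip().upper()


@dataclass(frozen=True)
class ValidatedPair:
    mirna_id: str
    gene_symbol: str
    source_db: str
    evidence: str = ""
    tier: str = "low"

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")


@dataclass(frozen=True)
class UniquePair:
    """A deduplicated (miRNA, gene) pair with merged provenance."""

    mirna_id: str
    gene_symbol: str
    sources: frozenset[str]
    tier: str  # best supporting tier
    evidence: tuple[str, ...] = ()


def load_validated(
    tsv_paths: Sequence,
    tier_map: Mapping[str, str] | None = None,
    default_organism: str = "hsa",
) -> list[ValidatedPair]:
    """Load validated-pair tables (columns: mirna_id, gene_symbol[, source_db, evidence]).

    Missing ``source_db`` falls back to the file stem.  Rows whose miRNA id
    cannot be normalized are skipped with a warning count.
    """
    tiers = dict(DEFAULT_TIER_MAP)
    if tier_map:
        tiers.update({k.lower(): v for k, v in tier_map.items()})
    pairs: list[ValidatedPair] = []
    for path in tsv_paths:
        skipped = 0
        stem = Path(path).stem.replace("validated_", "").lower()
        with open(path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                gene = row.get("gene_symbol") or row.get("gene") or ""
                mirna = normalize_mirna_id(row.get("mirna_id", ""), default_organism)
                if mirna is None or not gene.strip():
                    skipped += 1
                    continue
                source = (row.get("source_db") or stem).lower()
                tier = tiers.get(source, tiers["other"])
                pairs.append(
                    ValidatedPair(
                        mirna_id=mirna,
                        gene_symbol=normalize_gene(gene),
                        source_db=source,
                        evidence=row.get("evidence", "") or "",
                        tier=tier,
                    )
                )
        if skipped:
            log.warning("%s: skipped %d unmappable rows", path, skipped)
    return pairs


def dedup_pairs(pairs: Iterable[ValidatedPair]) -> list[UniquePair]:
    """One record per unique (miRNA, gene); sources merged, best tier kept."""
    merged: dict[tuple[str, str], dict] = {}
    for p in pairs:
        key = (p.mirna_id, p.gene_symbol)
        slot = merged.setdefault(key, {"sources": set(), "tier": p.tier, "evidence": []})
        slot["sources"].add(p.source_db)
        if _TIER_RANK[p.tier] > _TIER_RANK[slot["tier"]]:
            slot["tier"] = p.tier
        if p.evidence and p.evidence not in slot["evidence"]:
            slot["evidence"].append(p.evidence)
    return [
        UniquePair(
            mirna_id=m,
            gene_symbol=g,
            sources=frozenset(slot["sources"]),
            tier=slot["tier"],
            evidence=tuple(slot["evidence"]),
        )
        for (m, g), slot in sorted(merged.items())
    ]


def pair_index(unique_pairs: Iterable[UniquePair]) -> dict[tuple[str, str], UniquePair]:
    """Lookup by (normalized miRNA id, gene symbol)."""
    return {(u.mirna_id, u.gene_symbol): u for u in unique_pairs}


def is_validated(
    mirna_id: str, gene_symbol: str, index: Mapping[tuple[str, str], UniquePair]
) -> UniquePair | None:
    key = (normalize_mirna_id(mirna_id) or mirna_id.lower(), normalize_gene(gene_symbol))
    return index.get(key)


def label_predictions(groups, unique_pairs: Iterable[UniquePair]) -> None:
    """Flag consensus groups whose (miRNA, gene) pair is experimentally supported.

    Matching is gene-level: every isoform of a validated gene is flagged.
    Mutates ``validated``/``validated_sources``/``validated_tier`` in place.
    """
    index = pair_index(unique_pairs)
    for g in groups:
        hit = is_validated(g.mirna_id, g.gene_symbol, index)
        if hit is not None:
            g.validated = True
            g.validated_sources = tuple(sorted(hit.sources))
            g.validated_tier = hit.tier
        else:
            g.validated = False
            g.validated_sources = ()
            g.validated_tier = None


def write_unique_pairs(unique_pairs: Sequence[UniquePair], path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tgene_symbol\tsources\ttier\n")
        for u in unique_pairs:
            fh.write(
                f"{u.mirna_id}\t{u.gene_symbol}\t{','.join(sorted(u.sources))}\t{u.tier}\n"
            )
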