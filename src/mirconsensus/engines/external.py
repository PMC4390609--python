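"""Import of externally precomputed prediction tables into TargetSites.

Allows predictions produced by third-party tools (run on the same UTR
space) to enter the standardization/consensus layer.  The TSV must carry
``mirna_id``, ``transcript_id``, ``start``, ``end`` and ``score`` columns;
an optional leading comment line ``#coords=1-based-inclusive`` (default
``0-based-half-open``) declares the coordinate convention.
"""

from __future__ import annotations

import logging
from typing import Mapping

from ..sequence_space import UTRRecord
from .seedscan import canonical_type_in
from .sites import TargetSite, lift_seed

log = logging.getLogger(__name__)

_REQUIRED = ("mirna_id", "transcript_id", "start", "end", "score")
CONVENTIONS = ("0-based-half-open", "1-based-inclusive")


def import_external_predictions(
    tsv_path,
    engine_name: str,
    utr_space: Mapping[str, UTRRecord],
) -> list[TargetSite]:
    """Read a prediction table and normalize it to internal TargetSites.

    Rows naming transcripts absent from ``utr_space`` are skipped (total
    logged); malformed rows raise with their line number.
    """
    convention = "0-based-half-open"
    sites: list[TargetSite] = []
    skipped = 0
    with open(tsv_path) as fh:
        lines = fh.read().splitlines()
    header_idx = 0
    for idx, line in enumerate(lines):
        if line.startswith("#"):
            directive = line.lstrip("#").strip()
            if directive.startswith("coords="):
                convention = directive.split("=", 1)[1].strip()
                if convention not in CONVENTIONS:
                    raise ValueError(f"unknown coordinate convention {convention!r}")
        else:
            header_idx = idx
            break
    header = lines[header_idx].split("\t")
    missing = [c for c in _REQUIRED if c not in header]
    if missing:
        raise ValueError(f"{tsv_path}: missing columns {missing}")
    col = {name: header.index(name) for name in _REQUIRED}
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        try:
            mirna_id = fields[col["mirna_id"]]
            transcript_id = fields[col["transcript_id"]]
            start = int(fields[col["start"]])
            end = int(fields[col["end"]])
            score = float(fields[col["score"]])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{tsv_path}:{lineno}: malformed row ({exc})") from None
        if convention == "1-based-inclusive":
            start, end = start - 1, end
        utr = utr_space.get(transcript_id)
        if utr is None:
            skipped += 1
            continue
        # external tables carry no miRNA sequence, so the site type stays unresolved
        sites.append(
            TargetSite(
                engine=engine_name,
                mirna_id=mirna_id,
                transcript_id=transcript_id,
                utr_start=start,
                utr_end=end,
                seed_start=start,
                seed_end=end,
                genomic_seed=lift_seed(utr, start, end),
                site_type="non-canonical",
                raw_score=score,
            )
        )
    if skipped:
        log.warning(
            "%s: skipped %d rows naming transcripts outside the UTR space",
            tsv_path,
            skipped,
        )
    return sites
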