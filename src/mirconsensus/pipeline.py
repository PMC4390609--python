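"""End-to-end orchestration of the prediction/consensus pipeline.

Thin functional layer over the stage modules; the CLI and the acceptance
script both drive the pipeline through these functions so that file-based
and in-memory runs share one code path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pyfaidx

from . import consensus as cns
from . import sequence_space as seqspace
from . import validated as val
from .engines import (
    AlignParams,
    DuplexParams,
    SeedscanParams,
    TargetSite,
    align_complementarity,
    default_model,
    hybridization_energy,
    scan_seed_sites,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EngineSettings:
    seedscan: SeedscanParams = field(default_factory=SeedscanParams)
    dpalign: AlignParams = field(default_factory=AlignParams)
    duplexfold: DuplexParams = field(default_factory=DuplexParams)
    engines: tuple[str, ...] = ("seedscan", "dpalign", "duplexfold")


def build_utrs(
    gtf_path,
    genome_path,
    proxy_length: int = 130,
    min_utr_length: int = 50,
) -> list[seqspace.UTRRecord]:
    transcripts = seqspace.load_annotation(gtf_path, genome_path)
    genome = pyfaidx.Fasta(str(genome_path))
    return seqspace.build_utr_space(
        transcripts, genome, proxy_length=proxy_length, min_utr_length=min_utr_length
    )


def predict_all(
    utrs: Sequence[seqspace.UTRRecord],
    mirnas: Sequence[seqspace.MiRNARecord],
    settings: EngineSettings | None = None,
    conservation=None,
) -> dict[str, list[TargetSite]]:
    """Run every configured engine over the full (miRNA x UTR) grid."""
    s = settings or EngineSettings()
    model = default_model()
    out: dict[str, list[TargetSite]] = {e: [] for e in s.engines}
    for utr in utrs:
        for mirna in mirnas:
            if "seedscan" in out:
                out["seedscan"].extend(
                    scan_seed_sites(mirna, utr, s.seedscan, conservation=conservation)
                )
            if "dpalign" in out:
                out["dpalign"].extend(align_complementarity(mirna, utr, s.dpalign))
            if "duplexfold" in out:
                out["duplexfold"].extend(
                    hybridization_energy(mirna, utr, model, s.duplexfold)
                )
    return out


def run_consensus(
    sites_by_engine: Mapping[str, Sequence[TargetSite]],
    utrs: Sequence[seqspace.UTRRecord],
    unique_pairs: Sequence[val.UniquePair],
    orientation_map: Mapping[str, bool] | None = None,
    eps: float = cns.EPSILON,
) -> tuple[list[cns.ConsensusGroup], dict[str, cns.CalibrationCurve]]:
    """Standardize, calibrate against validated pairs, group, score, rank."""
    gene_of = {u.transcript_id: u.gene_symbol for u in utrs}
    index = val.pair_index(unique_pairs)
    preds = cns.standardize(
        {e: s for e, s in sites_by_engine.items() if s}, orientation_map
    )
    labels = {
        engine: [
            val.is_validated(p.site.mirna_id, gene_of.get(p.site.transcript_id, ""), index)
            is not None
            for p in engine_preds
        ]
        for engine, engine_preds in preds.items()
    }
    curves = cns.calibrate_weights(preds, labels, eps=eps)
    all_preds = [p for engine_preds in preds.values() for p in engine_preds]
    groups = cns.group_overlapping(all_preds, gene_of)
    for g in groups:
        cns.compute_cws(g, curves, eps=eps)
    val.label_predictions(groups, unique_pairs)
    return cns.rank_predictions(groups), curves
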