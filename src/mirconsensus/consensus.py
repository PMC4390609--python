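"""Score standardization, precision calibration and the consensus weighted score.

Heterogeneous engine scores are made comparable by per-engine Z-scores
(population standard deviation over the engine's full prediction set,
oriented so that larger is always better).  Each engine additionally gets a
calibration curve W(s): the empirical probability that a prediction scoring
at or above s is not a false positive, estimated against validated pairs
from the complementary cumulative score distribution and made monotone by
pool-adjacent-violators (isotonic) regression weighted by the count above
each score knot.

Predictions from different engines that hit the same genomic seed position
for one (miRNA, transcript) are grouped, and each group receives the
consensus weighted score

    CWS = sum_i Z_i * W_i / sum_i W_i

a convex combination of the member Z-scores — so the CWS always lies
between the group's extreme Z values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .engines.sites import TargetSite
from .sequence_space import UTRRecord

log = logging.getLogger(__name__)

EPSILON = 1e-6

#: larger raw_score is better for every built-in engine (duplexfold stores
#: raw_score = -energy); imported engines may override.
DEFAULT_ORIENTATION: Mapping[str, bool] = {
    "seedscan": True,
    "dpalign": True,
    "duplexfold": True,
}


@dataclass(frozen=True)
class StandardizedPrediction:
    site: TargetSite
    oriented_score: float
    z: float


def standardize(
    sites_by_engine: Mapping[str, Sequence[TargetSite]],
    orientation_map: Mapping[str, bool] | None = None,
) -> dict[str, list[StandardizedPrediction]]:
    """Per-engine Z-scores over each engine's full prediction set.

    ``orientation_map[engine]`` is True when larger raw scores are better
    (default).  Engines with fewer than two predictions or zero score
    variance raise, naming the engine.
    """
    orient = dict(DEFAULT_ORIENTATION)
    if orientation_map:
        orient.update(orientation_map)
    out: dict[str, list[StandardizedPrediction]] = {}
    for engine, sites in sites_by_engine.items():
        if len(sites) < 2:
            raise ValueError(f"engine {engine!r}: need >=2 predictions to standardize")
        sign = 1.0 if orient.get(engine, True) else -1.0
        scores = np.array([sign * s.raw_score for s in sites], dtype=float)
        sd = scores.std()  # population sd
        if sd == 0:
            raise ValueError(f"engine {engine!r}: zero score variance")
        mean = scores.mean()
        out[engine] = [
            StandardizedPrediction(site=s, oriented_score=x, z=(x - mean) / sd)
            for s, x in zip(sites, scores)
        ]
    return out


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone map from (oriented) raw score to precision-above-score weight."""

    engine: str
    scores: np.ndarray  # knots, ascending
    weights: np.ndarray  # W in [eps, 1], non-decreasing

    def weight_at(self, score: float) -> float:
        """W at a score: the knot value of the smallest knot >= score.

        Predictions scoring at least s share the above-s set of the next
        observed knot; above the top knot the last weight applies.
        """
        idx = int(np.searchsorted(self.scores, score, side="left"))
        if idx >= len(self.weights):
            idx = len(self.weights) - 1
        return float(self.weights[idx])

    def weights_at(self, scores) -> np.ndarray:
        idx = np.searchsorted(self.scores, np.asarray(scores, dtype=float), side="left")
        idx = np.minimum(idx, len(self.weights) - 1)
        return self.weights[idx]


def calibration_curve(
    scores, labels, engine: str = "", eps: float = EPSILON
) -> CalibrationCurve:
    """Precision-above-score curve, isotonized and floored at ``eps``.

    For each observed score s, the raw weight is
    (# validated predictions scoring >= s) / (# predictions scoring >= s);
    pool-adjacent-violators regression (weighted by the above-s counts)
    enforces monotonicity, and weights are clipped to [eps, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.size == 0:
        raise ValueError(f"engine {engine!r}: no predictions to calibrate")
    order = np.argsort(scores)
    s_sorted, l_sorted = scores[order], labels[order]
    knots, first_idx = np.unique(s_sorted, return_index=True)
    n = scores.size
    n_ge = n - first_idx  # predictions scoring >= each knot
    cum_hits = np.cumsum(l_sorted[::-1])[::-1]
    k_ge = cum_hits[first_idx]
    raw = k_ge / n_ge
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    w = iso.fit_transform(knots, raw, sample_weight=n_ge)
    w = np.clip(w, eps, 1.0)
    return CalibrationCurve(engine=engine, scores=knots, weights=w)


def calibrate_weights(
    preds_by_engine: Mapping[str, Sequence[StandardizedPrediction]],
    labels_by_engine: Mapping[str, Sequence[bool]],
    eps: float = EPSILON,
) -> dict[str, CalibrationCurve]:
    """One calibration curve per engine; engines with no predictions are skipped."""
    curves: dict[str, CalibrationCurve] = {}
    for engine, preds in preds_by_engine.items():
        if not preds:
            log.warning("engine %s: no predictions, calibration skipped", engine)
            continue
        scores = [p.oriented_score for p in preds]
        curves[engine] = calibration_curve(scores, labels_by_engine[engine], engine, eps)
    return curves


def curves_to_frame(curves: Mapping[str, CalibrationCurve]) -> pd.DataFrame:
    rows = [
        (engine, float(s), float(w))
        for engine in sorted(curves)
        for s, w in zip(curves[engine].scores, curves[engine].weights)
    ]
    return pd.DataFrame(rows, columns=["engine", "score_knot", "W"])


def curves_from_frame(df: pd.DataFrame) -> dict[str, CalibrationCurve]:
    out = {}
    for engine, sub in df.groupby("engine"):
        sub = sub.sort_values("score_knot")
        out[engine] = CalibrationCurve(
            engine=str(engine),
            scores=sub["score_knot"].to_numpy(dtype=float),
            weights=sub["W"].to_numpy(dtype=float),
        )
    return out


@dataclass
class ConsensusGroup:
    """Engine predictions sharing one genomic seed position for a pair."""

    mirna_id: str
    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    g_start: int
    g_end: int
    members: list[StandardizedPrediction]
    agreement: int = 0
    agreement_exact: bool = False
    weights: list[float] = field(default_factory=list)
    cws: float | None = None
    validated: bool = False
    validated_sources: tuple[str, ...] = ()
    validated_tier: str | None = None

    @property
    def engines(self) -> tuple[str, ...]:
        return tuple(m.site.engine for m in self.members)


def group_overlapping(
    predictions: Iterable[StandardizedPrediction],
    gene_of: Mapping[str, str] | None = None,
) -> list[ConsensusGroup]:
    """Merge predictions whose genomic seed intervals overlap by >=1 nt.

    Grouping is per (miRNA, transcript, strand) with transitive closure;
    within a group at most one member per engine is kept (the best Z).
    ``agreement_exact`` flags groups where two or more engines coincide in
    both site type and exact seed coordinates.  The result is independent
    of input order.
    """
    by_key: dict[tuple[str, str, str], list[StandardizedPrediction]] = {}
    for p in predictions:
        key = (p.site.mirna_id, p.site.transcript_id, p.site.genomic_seed.strand)
        by_key.setdefault(key, []).append(p)
    groups: list[ConsensusGroup] = []
    for (mirna_id, transcript_id, strand), preds in sorted(by_key.items()):
        preds.sort(key=lambda p: (p.site.genomic_seed.start, p.site.genomic_seed.end, p.site.engine))
        cluster: list[StandardizedPrediction] = []
        cluster_end = -1
        def flush() -> None:
            if not cluster:
                return
            best: dict[str, StandardizedPrediction] = {}
            for p in cluster:
                cur = best.get(p.site.engine)
                if cur is None or p.z > cur.z:
                    best[p.site.engine] = p
            members = [best[e] for e in sorted(best)]
            exact = _has_exact_agreement(cluster)
            gene = ""
            if gene_of is not None:
                gene = gene_of.get(transcript_id, "")
            groups.append(
                ConsensusGroup(
                    mirna_id=mirna_id,
                    transcript_id=transcript_id,
                    gene_symbol=gene,
                    chrom=cluster[0].site.genomic_seed.chrom,
                    strand=strand,
                    g_start=min(p.site.genomic_seed.start for p in cluster),
                    g_end=max(p.site.genomic_seed.end for p in cluster),
                    members=members,
                    agreement=len(members),
                    agreement_exact=exact,
                )
            )
        for p in preds:
            if cluster and p.site.genomic_seed.start < cluster_end:
                cluster.append(p)
                cluster_end = max(cluster_end, p.site.genomic_seed.end)
            else:
                flush()
                cluster = [p]
                cluster_end = p.site.genomic_seed.end
        flush()
    return groups


def _has_exact_agreement(preds: Sequence[StandardizedPrediction]) -> bool:
    seen: dict[tuple[str, int, int], set[str]] = {}
    for p in preds:
        key = (p.site.site_type, p.site.genomic_seed.start, p.site.genomic_seed.end)
        seen.setdefault(key, set()).add(p.site.engine)
    return any(len(engines) >= 2 for engines in seen.values())


def compute_cws(
    group: ConsensusGroup,
    curves: Mapping[str, CalibrationCurve],
    eps: float = EPSILON,
) -> float:
    """CWS = sum_i Z_i W_i / sum_i W_i; fills the group's weights in place."""
    weights, zs = [], []
    for m in group.members:
        curve = curves.get(m.site.engine)
        w = curve.weight_at(m.oriented_score) if curve is not None else eps
        weights.append(max(w, eps))
        zs.append(m.z)
    total = sum(weights)
    group.weights = weights
    group.cws = float(sum(z * w for z, w in zip(zs, weights)) / total)
    return group.cws


def rank_predictions(groups: Sequence[ConsensusGroup]) -> list[ConsensusGroup]:
    """Descending CWS; ties by agreement desc, then ids and position."""
    return sorted(
        groups,
        key=lambda g: (
            -(g.cws if g.cws is not None else float("-inf")),
            -g.agreement,
            g.mirna_id,
            g.transcript_id,
            g.g_start,
        ),
    )


def groups_to_frame(
    groups: Sequence[ConsensusGroup],
    utr_by_tx: Mapping[str, UTRRecord] | None = None,
) -> pd.DataFrame:
    """Flat consensus table with per-engine raw/z/W triplets (fixed columns)."""
    engines = sorted({m.site.engine for g in groups for m in g.members})
    rows = []
    for g in groups:
        utr = utr_by_tx.get(g.transcript_id) if utr_by_tx else None
        row = {
            "mirna_id": g.mirna_id,
            "gene_symbol": g.gene_symbol,
            "transcript_id": g.transcript_id,
            "biotype": utr.biotype if utr else "",
            "utr_source": utr.utr_source if utr else "",
            "site_types": ";".join(
                sorted({m.site.site_type for m in g.members})
            ),
            "utr_start": min(m.site.utr_start for m in g.members),
            "utr_end": max(m.site.utr_end for m in g.members),
            "chrom": g.chrom,
            "g_start": g.g_start,
            "g_end": g.g_end,
            "strand": g.strand,
            "agreement": g.agreement,
            "agreement_exact": g.agreement_exact,
            "cws": g.cws,
            "validated": g.validated,
            "validated_sources": ",".join(g.validated_sources),
            "validated_tier": g.validated_tier or "",
        }
        member_by_engine = {m.site.engine: (m, w) for m, w in zip(g.members, g.weights)}
        for e in engines:
            if e in member_by_engine:
                m, w = member_by_engine[e]
                row[f"{e}_raw"] = m.site.raw_score
                row[f"{e}_z"] = m.z
                row[f"{e}_w"] = w
            else:
                row[f"{e}_raw"] = row[f"{e}_z"] = row[f"{e}_w"] = None
        rows.append(row)
    lead = [
        "mirna_id",
        "gene_symbol",
        "transcript_id",
        "biotype",
        "utr_source",
        "site_types",
        "utr_start",
        "utr_end",
        "chrom",
        "g_start",
        "g_end",
        "strand",
    ]
    engine_cols = [f"{e}_{suffix}" for e in engines for suffix in ("raw", "z", "w")]
    tail = [
        "agreement",
        "agreement_exact",
        "cws",
        "validated",
        "validated_sources",
        "validated_tier",
    ]
    return pd.DataFrame(rows, columns=lead + engine_cols + tail)


def ensemble_scores(
    score_table: pd.DataFrame,
    engine_columns: Sequence[str],
    labels,
    eps: float = EPSILON,
) -> tuple[pd.DataFrame, dict[str, CalibrationCurve]]:
    """Standardize + calibrate + combine a wide per-pair score table.

    Convenience path for benchmark tables where every row is one
    miRNA-gene pair scored by every engine (one implicit group per row).
    Returns the table with added ``z_<engine>``, ``w_<engine>`` and ``cws``
    columns, plus the per-engine calibration curves.
    """
    df = score_table.copy()
    labels = np.asarray(labels, dtype=bool)
    curves: dict[str, CalibrationCurve] = {}
    z_cols, w_cols = [], []
    for col in engine_columns:
        x = df[col].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            raise ValueError(f"engine {col!r}: zero score variance")
        df[f"z_{col}"] = (x - x.mean()) / sd
        curve = calibration_curve(x, labels, engine=col, eps=eps)
        curves[col] = curve
        df[f"w_{col}"] = curve.weights_at(x)
        z_cols.append(f"z_{col}")
        w_cols.append(f"w_{col}")
    Z = df[z_cols].to_numpy()
    W = df[w_cols].to_numpy()
    df["cws"] = (Z * W).sum(axis=1) / W.sum(axis=1)
    return df, curves
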