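"""ROC/AUC evaluation of engines and consensus against validated pairs.

The evaluation universe is the set of *predicted* pairs: negatives are
predictions absent from every validated source (presumed negatives), so
the resulting AUCs carry label noise from undiscovered true targets — a
property of the evaluation design, not of the methods.  By default each
(miRNA, gene) pair contributes its best score per method ("pair" mode); a
per-site mode is also exposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _metrics

from .consensus import ConsensusGroup
from .validated import TIERS, UniquePair, normalize_gene, normalize_mirna_id, pair_index

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROCResult:
    label: str
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    def points(self) -> pd.DataFrame:
        return pd.DataFrame({"method": self.label, "fpr": self.fpr, "tpr": self.tpr})


def roc_curve_result(scores, labels, label: str = "") -> ROCResult:
    """Threshold-sweep ROC with trapezoid AUC (ties get half credit).

    Requires at least one positive and one negative label.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"ROC for {label!r} needs both classes (pos={n_pos}, neg={n_neg})")
    fpr, tpr, _ = _metrics.roc_curve(labels, scores, drop_intermediate=False)
    return ROCResult(
        label=label,
        fpr=fpr,
        tpr=tpr,
        auc=float(_metrics.auc(fpr, tpr)),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def _pair_table(groups: Iterable[ConsensusGroup], per_site: bool = False) -> pd.DataFrame:
    """Best score per evaluation unit for every engine plus the consensus.

    Units are (miRNA, gene) pairs by default, individual groups in per-site
    mode.  Engines absent from a unit contribute their floor (the engine's
    minimum Z over the whole run).
    """
    rows = []
    for idx, g in enumerate(groups):
        unit = idx if per_site else (g.mirna_id, g.gene_symbol)
        for m in g.members:
            rows.append((unit, m.site.engine, m.z, g.cws, g.validated, g.validated_tier))
    if not rows:
        return pd.DataFrame(
            columns=["unit", "engine", "z", "cws", "validated", "tier"]
        )
    df = pd.DataFrame(rows, columns=["unit", "engine", "z", "cws", "validated", "tier"])
    engines = sorted(df["engine"].unique())
    floors = df.groupby("engine")["z"].min()
    best_z = df.pivot_table(index="unit", columns="engine", values="z", aggfunc="max")
    for e in engines:
        best_z[e] = best_z[e].fillna(floors[e])
    unit_info = df.groupby("unit").agg(
        cws=("cws", "max"), validated=("validated", "any")
    )
    tier = df.dropna(subset=["tier"]).groupby("unit")["tier"].first()
    out = best_z.join(unit_info)
    out["tier"] = tier
    return out.reset_index()


def evaluate_methods(
    groups: Sequence[ConsensusGroup], per_site: bool = False
) -> list[ROCResult]:
    """One ROC per engine plus one for the consensus, on a shared universe."""
    table = _pair_table(groups, per_site=per_site)
    if table.empty:
        return []
    labels = table["validated"].to_numpy(dtype=bool)
    results = []
    meta_cols = {"unit", "cws", "validated", "tier"}
    for engine in [c for c in table.columns if c not in meta_cols]:
        results.append(roc_curve_result(table[engine].to_numpy(), labels, engine))
    results.append(roc_curve_result(table["cws"].to_numpy(), labels, "consensus"))
    return results


def evaluate_by_tier(
    groups: Sequence[ConsensusGroup],
    unique_pairs: Iterable[UniquePair] | None = None,
    per_site: bool = False,
) -> dict[str, ROCResult]:
    """Consensus ROC per reliability tier.

    For each tier, positives are predicted pairs validated at that tier;
    negatives are predicted pairs validated nowhere.  Pairs validated at a
    different tier are excluded from that tier's universe.  Tiers without
    positives are skipped with a warning.
    """
    table = _pair_table(groups, per_site=per_site)
    if table.empty:
        return {}
    out: dict[str, ROCResult] = {}
    negatives = ~table["validated"].to_numpy(dtype=bool)
    for tier in TIERS:
        pos_mask = table["tier"].eq(tier).to_numpy(dtype=bool)
        mask = pos_mask | negatives
        if pos_mask.sum() == 0:
            log.warning("tier %s: no positive pairs, skipped", tier)
            continue
        out[tier] = roc_curve_result(
            table.loc[mask, "cws"].to_numpy(), pos_mask[mask], f"tier-{tier}"
        )
    return out


def auc_table(results: Iterable[ROCResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.label, r.auc, r.n_pos, r.n_neg) for r in results],
        columns=["method", "auc", "n_pos", "n_neg"],
    )
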