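"""Intermolecular duplex MFE engine (`duplexfold`).

Computes the minimum-free-energy hybridization of the miRNA against sliding
UTR windows by dynamic programming over base-pair stacks, bulges and
internal loops.  Intramolecular pairs are forbidden: a structure is a set of
miRNA-target pairs, monotone in both strands (antiparallel, non-crossing),
scored as

    E = initiation + sum over consecutive pairs of (stack | affine loop cost)

with energies from the nearest-neighbor :class:`~.energy.EnergyModel`.
Windows whose MFE falls below ``energy_threshold`` (default 0 kcal/mol)
yield sites with ``raw_score = -energy``.

A Pita-style accessibility adjustment is also provided: the duplex energy
is penalized by the energy that would be released by the target region
pairing with its own flanking sequence (a deliberate simplification of
unbound-structure opening cost).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..sequence_space import MiRNARecord, UTRRecord
from .energy import EnergyModel, PAIR_OK, default_model, encode
from .seedscan import canonical_type_in
from .sites import TargetSite, lift_seed, reduce_overlapping

INF = float("inf")


@dataclass(frozen=True)
class DuplexParams:
    window: int = 26
    step: int = 13
    energy_threshold: float = 0.0  # keep sites with MFE strictly below this
    accessibility_flank: int = 20


def duplex_mfe(
    mirna_seq: str, target_seq: str, model: EnergyModel | None = None
) -> tuple[float | None, list[tuple[int, int]]]:
    """MFE intermolecular duplex of two RNA strands.

    Returns ``(energy, pairs)`` where pairs are 0-based (miRNA index, target
    index) tuples with miRNA indices increasing and target indices
    decreasing (antiparallel).  ``(None, [])`` if no canonical pair exists.
    """
    mdl = model or default_model()
    n, m = len(mirna_seq), len(target_seq)
    if n == 0 or m == 0:
        return None, []
    a, b = encode(mirna_seq), encode(target_seq)
    ok = PAIR_OK[a[:, None], b[None, :]]  # (n, m) canonical-pair mask
    if not ok.any():
        return None, []
    E = np.full((n, m), INF)
    P_di = np.zeros((n, m), dtype=np.int8)  # 0 = structure starts here
    P_dj = np.zeros((n, m), dtype=np.int8)
    span = mdl.max_loop + 1
    for i in range(n):
        best = np.full(m, INF)
        bdi = np.zeros(m, dtype=np.int8)
        bdj = np.zeros(m, dtype=np.int8)
        for di in range(1, min(i, span) + 1):
            prev_row = E[i - di]
            for dj in range(1, span + 1):
                if dj >= m:
                    break
                cand = np.full(m, INF)
                cand[: m - dj] = prev_row[dj:]
                if di == 1 and dj == 1:
                    c1 = 4 * a[i - 1] + a[i]
                    c2 = np.empty(m, dtype=np.int64)
                    c2[: m - 1] = 4 * b[1:] + b[:-1]
                    c2[m - 1 :] = 0
                    step_cost = mdl.stack_array[c1, c2]
                    step_cost[m - 1 :] = INF
                else:
                    step_cost = mdl.loop_open + mdl.loop_extend * (di - 1 + dj - 1)
                cand = cand + step_cost
                better = cand < best
                best[better] = cand[better]
                bdi[better] = di
                bdj[better] = dj
        row = np.where(ok[i], np.minimum(best, 0.0), INF)
        E[i] = row
        started = ok[i] & (best >= 0.0)
        P_di[i] = np.where(started, 0, bdi)
        P_dj[i] = np.where(started, 0, bdj)
    flat = np.argmin(E)
    i, j = divmod(int(flat), m)
    if not np.isfinite(E[i, j]):
        return None, []
    energy = float(E[i, j] + mdl.initiation)
    pairs = []
    while True:
        pairs.append((i, j))
        di, dj = int(P_di[i, j]), int(P_dj[i, j])
        if di == 0:
            break
        i, j = i - di, j + dj
    return energy, pairs[::-1]


def hybridization_energy(
    mirna: MiRNARecord,
    utr: UTRRecord,
    model: EnergyModel | None = None,
    params: DuplexParams | None = None,
) -> list[TargetSite]:
    """MFE duplex sites of ``mirna`` over sliding windows of ``utr``.

    Windows shorter than 6 nt are skipped; sites are kept when the duplex
    energy is below ``energy_threshold`` and reduced to the best per
    overlap cluster.
    """
    mdl = model or default_model()
    p = params or DuplexParams()
    seq = utr.sequence
    n = len(mirna.sequence)
    sites: list[TargetSite] = []
    starts = list(range(0, max(len(seq) - 6 + 1, 1), p.step))
    for w0 in starts:
        wseq = seq[w0 : w0 + p.window]
        if len(wseq) < 6:
            continue
        energy, pairs = duplex_mfe(mirna.sequence, wseq, mdl)
        if energy is None or energy >= p.energy_threshold:
            continue
        t_cols = [w0 + j for _, j in pairs]
        utr_lo, utr_hi = min(t_cols), max(t_cols) + 1
        seed_cols = [w0 + j for i, j in pairs if 2 <= i + 1 <= 8]
        if seed_cols:
            seed_lo, seed_hi = min(seed_cols), max(seed_cols) + 1
        else:
            seed_lo, seed_hi = utr_lo, utr_hi
        site_type, _ = canonical_type_in(seq, seed_lo - 1, seed_hi + 1, mirna.sequence)
        sites.append(
            TargetSite(
                engine="duplexfold",
                mirna_id=mirna.mirna_id,
                transcript_id=utr.transcript_id,
                utr_start=utr_lo,
                utr_end=utr_hi,
                seed_start=seed_lo,
                seed_end=seed_hi,
                genomic_seed=lift_seed(utr, seed_lo, seed_hi),
                site_type=site_type,
                raw_score=-energy,
                energy=energy,
            )
        )
    return reduce_overlapping(sites)


def accessibility_adjusted_energy(
    site: TargetSite,
    utr: UTRRecord,
    model: EnergyModel | None = None,
    params: DuplexParams | None = None,
) -> float:
    """Pita-style ddG: duplex energy plus an unbound-site opening penalty.

    The penalty approximates the cost of melting competing local structure
    as the stability of the best duplex between the target region and
    either flank; it is never negative (opening can only cost energy).
    """
    if site.energy is None:
        raise ValueError("accessibility adjustment requires a duplex-energy site")
    mdl = model or default_model()
    p = params or DuplexParams()
    region = utr.sequence[site.utr_start : site.utr_end]
    left = utr.sequence[max(0, site.utr_start - p.accessibility_flank) : site.utr_start]
    right = utr.sequence[site.utr_end : site.utr_end + p.accessibility_flank]
    competing = 0.0
    for flank in (left, right):
        if len(flank) >= 2:
            e, _ = duplex_mfe(region, flank, mdl)
            if e is not None and e < competing:
                competing = e
    penalty = max(0.0, -competing)
    return site.energy + penalty
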