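"""Independent brute-force oracles used by the test suite.

These deliberately use different algorithmic formulations from the
production code: the alignment oracle recurses over consecutive aligned
columns with closed-form affine gap costs (quartic time, no 3-state
matrices); the duplex oracle exhaustively enumerates monotone pair sets;
the AUC oracle counts concordant pairs.
"""

from __future__ import annotations

import numpy as np

from mirconsensus.engines.dpalign import AlignParams, pair_score
from mirconsensus.engines.energy import CANONICAL_PAIRS, EnergyModel


def _gapcost(d: int, p: AlignParams) -> float:
    return 0.0 if d <= 0 else p.gap_open + (d - 1) * p.gap_extend


def oracle_alignment_score(mirna_seq: str, utr_seq: str, p: AlignParams) -> float:
    """Best local complementarity-alignment score by explicit recursion over
    consecutive aligned columns (miRNA reversed against the UTR)."""
    n, L = len(mirna_seq), len(utr_seq)
    rev = mirna_seq[::-1]
    best = -np.inf
    S: dict[tuple[int, int], float] = {}
    for i in range(n):
        pos = n - i  # 1-based miRNA position of reversed row i
        for j in range(L):
            s = pair_score(rev[i], utr_seq[j], pos, p)
            v = s
            for (i2, j2), prev in S.items():
                if i2 < i and j2 < j:
                    cand = prev - _gapcost(i - i2 - 1, p) - _gapcost(j - j2 - 1, p) + s
                    if cand > v:
                        v = cand
            S[(i, j)] = v
            if v > best:
                best = v
    return float(best)


def oracle_duplex_mfe(mirna_seq: str, target_seq: str, model: EnergyModel) -> float | None:
    """MFE by exhaustive enumeration of all legal intermolecular structures.

    A structure is a non-empty set of canonical pairs monotone in both
    strands (antiparallel); its energy is initiation plus stack or affine
    loop terms between consecutive pairs, loops capped at ``max_loop``
    unpaired nt per strand (same model rule as production).
    """
    m, t = mirna_seq, target_seq
    cells = [
        (i, j)
        for i in range(len(m))
        for j in range(len(t))
        if (m[i], t[j]) in CANONICAL_PAIRS
    ]
    best: float | None = None

    def extend(last: tuple[int, int], energy: float) -> None:
        nonlocal best
        if best is None or energy < best:
            best = energy
        li, lj = last
        for i, j in cells:
            if i <= li or j >= lj:
                continue
            di, dj = i - li - 1, lj - j - 1
            if di == 0 and dj == 0:
                step = model.stacks.get(f"{m[li]}{m[i]}/{t[lj]}{t[j]}")
                if step is None:
                    continue
            else:
                if di > model.max_loop or dj > model.max_loop:
                    continue
                step = model.loop_open + model.loop_extend * (di + dj)
            extend((i, j), energy + step)

    for cell in cells:
        extend(cell, model.initiation)
    return best


def oracle_auc(scores, labels) -> float:
    """AUC as the concordance statistic: P(score_pos > score_neg) + ties/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = ties = 0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def oracle_seed_sites(utr_seq: str, mirna_seq: str) -> list[tuple[int, str]]:
    """Regex-free seed-site oracle: all 6mer-core matches with type rules
    applied by direct string comparison."""
    comp = {"A": "U", "C": "G", "G": "C", "U": "A"}
    core = "".join(comp[b] for b in mirna_seq[1:7])[::-1]
    out = []
    for p in range(len(utr_seq) - 5):
        if utr_seq[p : p + 6] != core:
            continue
        has_m8 = p >= 1 and utr_seq[p - 1] == comp[mirna_seq[7]]
        has_a1 = p + 6 < len(utr_seq) and utr_seq[p + 6] == "A"
        if has_m8 and has_a1:
            st = "8mer"
        elif has_m8:
            st = "7mer-m8"
        elif has_a1:
            st = "7mer-A1"
        else:
            st = "6mer"
        out.append((p, st))
    return out
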