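"""Complementarity alignment engine (`dpalign`).

Local affine-gap dynamic programming of the miRNA (3'->5') against the UTR
(5'->3'), scoring *complementarity* rather than identity: Watson-Crick
pairs score ``match``, G.U wobbles score ``wobble``, everything else
``mismatch``.  Columns pairing miRNA positions 2-8 (the seed) are scaled by
``seed_scale``, mirroring the seed emphasis of alignment-based target
predictors.  A gap of length L costs ``gap_open + (L-1)*gap_extend``.
Alignments scoring at least ``score_threshold`` are reported as sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..sequence_space import MiRNARecord, UTRRecord
from .sites import TargetSite, lift_seed, reduce_overlapping
from .seedscan import canonical_type_in

_PAIR_SCORE_KIND = {
    ("A", "U"): "match",
    ("U", "A"): "match",
    ("C", "G"): "match",
    ("G", "C"): "match",
    ("G", "U"): "wobble",
    ("U", "G"): "wobble",
}

NEG = -1e30


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class AlignParams:
    match: float = 5.0
    wobble: float = 2.0
    mismatch: float = -3.0
    gap_open: float = 8.0
    gap_extend: float = 2.0
    seed_scale: float = 4.0
    seed_positions: tuple[int, int] = (2, 8)  # 1-based inclusive miRNA range
    score_threshold: float = 140.0

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ConfigError("match score must be positive")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ConfigError("gap penalties must be non-negative")


def pair_score(mirna_base: str, utr_base: str, position: int, params: AlignParams) -> float:
    """Score of aligning a miRNA base (1-based ``position``) to a UTR base."""
    kind = _PAIR_SCORE_KIND.get((mirna_base, utr_base))
    s = {"match": params.match, "wobble": params.wobble}.get(kind, params.mismatch)
    lo, hi = params.seed_positions
    if lo <= position <= hi:
        s *= params.seed_scale
    return s


def _score_matrix(mirna_seq: str, utr_seq: str, params: AlignParams) -> np.ndarray:
    """s[r, j]: score of aligning reversed-miRNA row r to UTR column j."""
    n, m = len(mirna_seq), len(utr_seq)
    rev = mirna_seq[::-1]
    s = np.empty((n, m))
    for r in range(n):
        pos = n - r  # 1-based miRNA position
        for j in range(m):
            s[r, j] = pair_score(rev[r], utr_seq[j], pos, params)
    return s


def _sw_fill(s: np.ndarray, params: AlignParams):
    """Vectorized 3-state local affine DP.  Returns (M, X, Y) matrices.

    State M: column aligns a miRNA and a UTR base; X: miRNA base in a gap;
    Y: UTR base in a gap.  Matrices are (n+1, m+1) with sentinel row/col 0.
    """
    n, m = s.shape
    go, ge = params.gap_open, params.gap_extend
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    cols = np.arange(1, m + 1)
    for i in range(1, n + 1):
        X[i, 1:] = np.maximum(M[i - 1, 1:] - go, X[i - 1, 1:] - ge)
        diag = np.maximum.reduce(
            [np.zeros(m), M[i - 1, :-1], X[i - 1, :-1], Y[i - 1, :-1]]
        )
        M[i, 1:] = s[i - 1, :] + diag
        # Y via running max: Y[i,j] = max_{k<j} max(M,X)[i,k] - go - (j-1-k)*ge
        B = np.maximum(M[i, 1:], X[i, 1:])
        run = np.maximum.accumulate(B + ge * cols)
        Y[i, 2:] = run[:-1] - go - ge * (cols[1:] - 1)
    return M, X, Y


def best_alignment_score(mirna_seq: str, utr_seq: str, params: AlignParams) -> float:
    """Optimal local complementarity-alignment score (>=1 aligned column)."""
    if not mirna_seq or not utr_seq:
        raise ValueError("empty sequence")
    s = _score_matrix(mirna_seq, utr_seq, params)
    M, _, _ = _sw_fill(s, params)
    return float(M[1:, 1:].max())


def _traceback(i, j, M, X, Y, s, params):
    """Aligned (miRNA_row, utr_col) pairs of the alignment ending at M[i,j]."""
    go, ge = params.gap_open, params.gap_extend
    pairs = []
    state = "M"
    tol = 1e-6
    while True:
        if state == "M":
            pairs.append((i, j))
            rest = M[i, j] - s[i - 1, j - 1]  # == max(0, M/X/Y diag)
            if rest < tol:
                break
            for prev, name in ((M, "M"), (X, "X"), (Y, "Y")):
                if abs(rest - prev[i - 1, j - 1]) < tol:
                    state = name
                    break
            else:
                break
            i, j = i - 1, j - 1
        elif state == "X":
            if abs(X[i, j] - (M[i - 1, j] - go)) < tol:
                state = "M"
            i = i - 1
        else:  # Y
            if abs(Y[i, j] - (M[i, j - 1] - go)) < tol:
                state = "M"
            elif abs(Y[i, j] - (X[i, j - 1] - go)) < tol:
                state = "X"
            j = j - 1
    return pairs[::-1]


def align_complementarity(
    mirna: MiRNARecord, utr: UTRRecord, params: AlignParams | None = None
) -> list[TargetSite]:
    """Local complementarity alignments of ``mirna`` against ``utr``.

    Every alignment endpoint reaching ``score_threshold`` is traced back;
    overlapping sites are reduced to the best per cluster.
    """
    p = params or AlignParams()
    n, m = len(mirna.sequence), len(utr.sequence)
    if m < 6:
        return []
    s = _score_matrix(mirna.sequence, utr.sequence, p)
    M, X, Y = _sw_fill(s, p)
    ii, jj = np.nonzero(M[1:, 1:] >= p.score_threshold)
    if ii.size == 0:
        return []
    scores = M[1:, 1:][ii, jj]
    order = np.argsort(-scores, kind="stable")
    sites: list[TargetSite] = []
    covered: list[tuple[int, int]] = []
    for k in order:
        i, j = int(ii[k]) + 1, int(jj[k]) + 1
        # endpoint's UTR column; skip if inside an already-traced site
        if any(lo - 2 <= j - 1 <= hi + 1 for lo, hi in covered):
            continue
        pairs = _traceback(i, j, M, X, Y, s, p)
        utr_cols = [c - 1 for _, c in pairs]
        utr_lo, utr_hi = min(utr_cols), max(utr_cols) + 1
        if any(utr_lo < hi and lo < utr_hi for lo, hi in covered):
            continue
        covered.append((utr_lo, utr_hi - 1))
        seed_lo_pos, seed_hi_pos = p.seed_positions
        seed_cols = [
            c - 1
            for r, c in pairs
            if seed_lo_pos <= (n - (r - 1)) <= seed_hi_pos
        ]
        if seed_cols:
            seed_lo, seed_hi = min(seed_cols), max(seed_cols) + 1
        else:
            seed_lo, seed_hi = utr_lo, utr_hi
        site_type, _ = canonical_type_in(utr.sequence, seed_lo - 1, seed_hi + 1, mirna.sequence)
        sites.append(
            TargetSite(
                engine="dpalign",
                mirna_id=mirna.mirna_id,
                transcript_id=utr.transcript_id,
                utr_start=utr_lo,
                utr_end=utr_hi,
                seed_start=seed_lo,
                seed_end=seed_hi,
                genomic_seed=lift_seed(utr, seed_lo, seed_hi),
                site_type=site_type,
                raw_score=float(M[i, j]),
            )
        )
    return reduce_overlapping(sites)
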