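"""Synthetic fixture generation: toy genomes with planted target sites.

Everything the pipeline consumes can be generated here deterministically
from a seed: a toy genome FASTA plus GTF annotation whose transcripts carry
annotated, short (<50 nt) or absent 3'-UTRs in stated proportions; a
mature-miRNA FASTA; validated-pair tables with tier-dependent label noise;
and truth tables recording every planted site and true pair.  A separate
generator produces labeled per-engine score tables from a latent-quality
model, used to exercise calibration, consensus and ROC behavior at scale.

Fixture genomes are uppercase DNA on contigs of a few kilobases, so the
whole pipeline runs in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_space import reverse_complement

_DNA = np.array(list("ACGT"))
_RNA2DNA = str.maketrans("U", "T")

SOURCES = ("oncomirdb", "mirecords", "tarbase", "mirtarbase")
_SOURCE_TIER = {"oncomirdb": "high", "mirecords": "medium", "tarbase": "low", "mirtarbase": "low"}


class InfeasibleSpec(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study fixture (seed mandatory)."""

    seed: int
    n_transcripts: int = 24
    n_mirnas: int = 6
    utr_absent_frac: float = 0.15
    utr_short_frac: float = 0.10
    utr_length_low: int = 80
    utr_length_high: int = 280
    planted_pairs: int = 12
    sites_per_pair: int = 1
    site_type: str = "8mer"
    decoy_pairs: int = 2
    tier_noise: Mapping[str, float] = field(
        default_factory=lambda: {"high": 0.0, "medium": 0.1, "low": 0.3}
    )
    organism: str = "hsa"

    def __post_init__(self) -> None:
        for name in ("utr_absent_frac", "utr_short_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for tier, v in self.tier_noise.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"tier_noise[{tier}]={v} outside [0, 1]")


@dataclass
class FixtureSet:
    genome_fasta: Path
    gtf: Path
    mirna_fasta: Path
    validated_tsvs: list[Path]
    truth_sites: pd.DataFrame
    truth_pairs: pd.DataFrame
    truth_sites_path: Path
    truth_pairs_path: Path


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_DNA[rng.integers(0, 4, n)])


def _dna(rna: str) -> str:
    return rna.translate(_RNA2DNA)


def _revcomp_dna(dna: str) -> str:
    return _dna(reverse_complement(dna))


_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}


def planted_site_sequence(mirna_seq: str, site_type: str) -> tuple[str, int]:
    """UTR-local sequence realizing ``site_type`` for the miRNA, plus the
    offset of the 6mer seed core within it.

    The flanking characters that decide the classification (the m8 match
    and the A1 anchor) are part of the returned string, so classification
    is pinned regardless of the random genomic context.
    """
    core = _dna(reverse_complement(mirna_seq[1:7]))  # pairs positions 2-7
    m8 = _dna(_COMP[mirna_seq[7]])
    not_m8 = "C" if m8 != "C" else "G"
    if site_type == "8mer":
        return m8 + core + "A", 1
    if site_type == "7mer-m8":
        return m8 + core + "G", 1
    if site_type == "7mer-A1":
        return not_m8 + core + "A", 1
    if site_type == "6mer":
        return not_m8 + core + "G", 1
    raise ValueError(f"cannot plant site_type {site_type!r}")


@dataclass
class _Tx:
    transcript_id: str
    gene_id: str
    gene_symbol: str
    biotype: str
    strand: str
    exons: list[tuple[int, int]]  # genomic 0-based half-open
    cds: tuple[int, int] | None
    category: str  # annotated | short | absent
    utr_region: tuple[int, int]  # genomic span where sites can be planted
    utr_len: int
    principal: bool


def _design_transcripts(spec: FixtureSpec, rng: np.random.Generator) -> tuple[list[_Tx], int]:
    n = spec.n_transcripts
    n_absent = int(round(spec.utr_absent_frac * n))
    n_short = int(round(spec.utr_short_frac * n))
    categories = ["absent"] * n_absent + ["short"] * n_short
    categories += ["annotated"] * (n - len(categories))
    rng.shuffle(categories)
    slot = 900
    txs: list[_Tx] = []
    nc_biotypes = ["lincRNA", "processed_pseudogene", "antisense"]
    for k, cat in enumerate(categories):
        base = 500 + slot * k
        strand = "+" if rng.random() < 0.5 else "-"
        tid, gid, sym = f"t{k:03d}", f"g{k:03d}", f"GENE{k:03d}"
        principal = bool(rng.random() < 0.5)
        if cat == "absent":
            biotype = nc_biotypes[int(rng.integers(0, len(nc_biotypes)))]
            if strand == "+":
                exons = [(base, base + 200)]
                utr_region = (base + 200, base + 330)
            else:
                exons = [(base + 130, base + 330)]
                utr_region = (base, base + 130)
            txs.append(
                _Tx(tid, gid, sym, biotype, strand, exons, None, cat, utr_region, 130, principal)
            )
            continue
        if cat == "short":
            utr_len = int(rng.integers(20, 50))
        else:
            utr_len = int(rng.integers(spec.utr_length_low, spec.utr_length_high + 1))
        two_exons = strand == "+" and rng.random() < 0.3
        if strand == "+":
            if two_exons:
                e1 = (base, base + 120)
                e2 = (base + 170, base + 170 + 60 + utr_len)
                exons = [e1, e2]
                cds = (base, base + 170 + 60 - 50)  # spans both exons, ends 60 into e2
                cds_boundary = base + 170 + 60
            else:
                exons = [(base, base + 100 + utr_len)]
                cds_boundary = base + 100
                cds = (base, cds_boundary)
            if cat == "short":
                last_end = exons[-1][1]
                utr_region = (last_end, last_end + 130)
                eff_len = 130
            else:
                utr_region = (cds_boundary, exons[-1][1])
                eff_len = utr_len
            if two_exons:
                cds = (base, cds_boundary)
        else:
            exons = [(base, base + 100 + utr_len)]
            cds_boundary = base + utr_len  # UTR genomically left of CDS
            cds = (cds_boundary, base + 100 + utr_len)
            if cat == "short":
                utr_region = (base - 130, base)
                eff_len = 130
            else:
                utr_region = (base, cds_boundary)
                eff_len = utr_len
        txs.append(
            _Tx(tid, gid, sym, "protein_coding", strand, exons, cds, cat, utr_region, eff_len, principal)
        )
    contig_len = 500 + slot * n + 800
    return txs, contig_len


def _plant(genome: np.ndarray, tx: _Tx, local_pos: int, site_dna: str) -> None:
    g0, g1 = tx.utr_region
    if local_pos + len(site_dna) > tx.utr_len:
        raise InfeasibleSpec(
            f"{tx.transcript_id}: planted site exceeds UTR of {tx.utr_len} nt"
        )
    if tx.strand == "+":
        s = g0 + local_pos
        genome[s : s + len(site_dna)] = list(site_dna)
    else:
        e = g1 - local_pos
        genome[e - len(site_dna) : e] = list(_revcomp_dna(site_dna))


def generate_fixture(spec: FixtureSpec, outdir) -> FixtureSet:
    """Write genome FASTA, GTF, miRNA FASTA, validated TSVs and truth tables.

    Output is byte-identical for identical specs (one seeded generator, no
    timestamps).  Raises :class:`InfeasibleSpec` when a planted site cannot
    fit its UTR.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    chrom = "chrT"

    # miRNAs
    mirnas: list[tuple[str, str]] = []
    seen_seeds: set[str] = set()
    for k in range(spec.n_mirnas):
        while True:
            seq = "".join(np.array(list("ACGU"))[rng.integers(0, 4, 22)])
            if seq[1:8] not in seen_seeds:
                seen_seeds.add(seq[1:8])
                break
        mirnas.append((f"{spec.organism}-miR-{901 + k}-5p", seq))

    txs, contig_len = _design_transcripts(spec, rng)
    genome = np.array(list(_random_seq(rng, contig_len)))

    # choose planted (miRNA, transcript) pairs: spread transcripts round-robin
    n_pairs = spec.planted_pairs + spec.decoy_pairs
    tx_order = rng.permutation(len(txs))
    pairs: list[tuple[int, int]] = []  # (mirna idx, tx idx)
    used: set[tuple[int, int]] = set()
    ti = 0
    while len(pairs) < n_pairs:
        tx_idx = int(tx_order[ti % len(txs)])
        mi = int(rng.integers(0, len(mirnas)))
        if (mi, tx_idx) not in used:
            used.add((mi, tx_idx))
            pairs.append((mi, tx_idx))
        ti += 1

    site_rows = []
    slots_used: dict[int, int] = {}
    for rank, (mi, tx_idx) in enumerate(pairs):
        tx = txs[tx_idx]
        mirna_id, mirna_seq = mirnas[mi]
        is_decoy = rank >= spec.planted_pairs
        for s in range(spec.sites_per_pair):
            slot = slots_used.get(tx_idx, 0)
            slots_used[tx_idx] = slot + 1
            local = 10 + 25 * slot
            site_dna, core_off = planted_site_sequence(mirna_seq, spec.site_type)
            _plant(genome, tx, local, site_dna)
            site_rows.append(
                dict(
                    mirna_id=mirna_id,
                    transcript_id=tx.transcript_id,
                    gene_symbol=tx.gene_symbol,
                    utr_source="annotated" if tx.category == "annotated" else "proxy",
                    local_start=local,
                    core_start=local + core_off,
                    site_type=spec.site_type,
                    is_decoy=is_decoy,
                )
            )
    truth_sites = pd.DataFrame(site_rows)
    pair_rows = [
        dict(mirna_id=mirnas[mi][0], gene_symbol=txs[ti].gene_symbol, is_decoy=(r >= spec.planted_pairs))
        for r, (mi, ti) in enumerate(pairs)
    ]
    truth_pairs = pd.DataFrame(pair_rows).drop_duplicates().reset_index(drop=True)

    # genome FASTA
    genome_fasta = outdir / "genome.fa"
    with open(genome_fasta, "w") as fh:
        fh.write(f">{chrom}\n")
        text = "".join(genome)
        for i in range(0, len(text), 60):
            fh.write(text[i : i + 60] + "\n")

    # GTF (1-based inclusive)
    gtf = outdir / "annotation.gtf"
    with open(gtf, "w") as fh:
        for tx in txs:
            attrs_gene = f'gene_id "{tx.gene_id}"; gene_name "{tx.gene_symbol}"; gene_biotype "{tx.biotype}";'
            attrs_tx = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                f'gene_name "{tx.gene_symbol}"; gene_biotype "{tx.biotype}"; '
                f'transcript_biotype "{tx.biotype}";'
            )
            if tx.principal:
                attrs_tx += ' tag "appris_principal_1";'
            span = (min(e[0] for e in tx.exons) + 1, max(e[1] for e in tx.exons))
            fh.write(
                f"{chrom}\tsynth\tgene\t{span[0]}\t{span[1]}\t.\t{tx.strand}\t.\t{attrs_gene}\n"
            )
            fh.write(
                f"{chrom}\tsynth\ttranscript\t{span[0]}\t{span[1]}\t.\t{tx.strand}\t.\t{attrs_tx}\n"
            )
            for e0, e1 in tx.exons:
                fh.write(
                    f"{chrom}\tsynth\texon\t{e0 + 1}\t{e1}\t.\t{tx.strand}\t.\t{attrs_tx}\n"
                )
            if tx.cds is not None:
                for e0, e1 in tx.exons:
                    c0, c1 = max(e0, tx.cds[0]), min(e1, tx.cds[1])
                    if c0 < c1:
                        fh.write(
                            f"{chrom}\tsynth\tCDS\t{c0 + 1}\t{c1}\t.\t{tx.strand}\t0\t{attrs_tx}\n"
                        )

    # miRNA FASTA
    mirna_fasta = outdir / "mirnas.fa"
    with open(mirna_fasta, "w") as fh:
        for k, (mid, seq) in enumerate(mirnas):
            fh.write(f">{mid} MIMAT{900000 + k} synthetic mature miRNA\n{seq}\n")

    # validated tables with tier-dependent corruption
    genes = [tx.gene_symbol for tx in txs]
    validated_paths = []
    rows_by_source: dict[str, list[tuple[str, str, str]]] = {s: [] for s in SOURCES}
    true_pairs = truth_pairs[~truth_pairs["is_decoy"]]
    for row in true_pairs.itertuples(index=False):
        k_sources = 1 + int(rng.integers(0, 3))
        chosen = rng.choice(len(SOURCES), size=k_sources, replace=False)
        for ci in sorted(chosen):
            source = SOURCES[ci]
            noise = spec.tier_noise.get(_SOURCE_TIER[source], 0.0)
            gene = row.gene_symbol
            if rng.random() < noise:
                gene = genes[int(rng.integers(0, len(genes)))]
            rows_by_source[source].append((row.mirna_id, gene, "luciferase assay"))
    for source in SOURCES:
        path = outdir / f"validated_{source}.tsv"
        with open(path, "w") as fh:
            fh.write("mirna_id\tgene_symbol\tsource_db\tevidence\n")
            for mirna_id, gene, evidence in rows_by_source[source]:
                fh.write(f"{mirna_id}\t{gene}\t{source}\t{evidence}\n")
        validated_paths.append(path)

    truth_sites_path = outdir / "truth_sites.tsv"
    truth_pairs_path = outdir / "truth_pairs.tsv"
    truth_sites.to_csv(truth_sites_path, sep="\t", index=False)
    truth_pairs.to_csv(truth_pairs_path, sep="\t", index=False)
    return FixtureSet(
        genome_fasta=genome_fasta,
        gtf=gtf,
        mirna_fasta=mirna_fasta,
        validated_tsvs=validated_paths,
        truth_sites=truth_sites,
        truth_pairs=truth_pairs,
        truth_sites_path=truth_sites_path,
        truth_pairs_path=truth_pairs_path,
    )


# ---------------------------------------------------------------------------
# latent-quality score benchmark


def generate_score_benchmark(
    n_pairs: int,
    seed: int,
    engine_coeffs: Sequence[float] = (1.0, 0.8, 0.6),
    noise_sd: float = 1.0,
    label_slope: float = 2.0,
    tier_noise: Mapping[str, float] | None = None,
    tier_fracs: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Labeled per-engine score table from a shared latent quality.

    Each pair draws a latent quality q ~ N(0, 1); engine e scores
    ``a_e * q + N(0, noise_sd)`` and the true label is
    Bernoulli(sigmoid(label_slope * q)).  When ``tier_noise`` is given,
    pairs are assigned to reliability tiers (proportions ``tier_fracs``,
    default uniform) and a corrupted ``validated`` column flips the true
    label with the tier's noise probability.
    """
    rng = np.random.default_rng(seed)
    q = rng.standard_normal(n_pairs)
    df = pd.DataFrame({"pair_id": np.arange(n_pairs), "q": q})
    for e, a in enumerate(engine_coeffs, start=1):
        df[f"sim{e}"] = a * q + noise_sd * rng.standard_normal(n_pairs)
    p = 1.0 / (1.0 + np.exp(-label_slope * q))
    df["label"] = rng.random(n_pairs) < p
    if tier_noise is not None:
        tiers = list(tier_noise)
        fracs = (
            np.array([tier_fracs[t] for t in tiers])
            if tier_fracs
            else np.full(len(tiers), 1.0 / len(tiers))
        )
        fracs = fracs / fracs.sum()
        df["tier"] = rng.choice(tiers, size=n_pairs, p=fracs)
        flip = rng.random(n_pairs) < df["tier"].map(tier_noise).to_numpy(dtype=float)
        df["validated"] = df["label"].to_numpy() ^ flip
    return df


def true_precision_above(
    q_scores: np.ndarray, labels: np.ndarray, eval_points: np.ndarray
) -> np.ndarray:
    """Monte-Carlo precision-above-score curve evaluated at given scores.

    Independent oracle for calibration recovery: the fraction of positives
    among items scoring at or above each evaluation point.
    """
    order = np.argsort(q_scores)
    s, l = q_scores[order], labels[order].astype(float)
    cum = np.cumsum(l[::-1])[::-1]
    idx = np.searchsorted(s, eval_points, side="left")
    n = s.size
    out = np.empty(eval_points.size)
    for i, j in enumerate(idx):
        out[i] = cum[j] / (n - j) if j < n else l[-1]
    return out
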