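"""Prediction engines: seed scanning, alignment, duplex folding, import."""

import numpy as np
import pytest

from mirconsensus.engines import (
    AlignParams,
    DuplexParams,
    SeedscanParams,
    accessibility_adjusted_energy,
    align_complementarity,
    best_alignment_score,
    default_model,
    duplex_mfe,
    hybridization_energy,
    import_external_predictions,
    read_sites_tsv,
    scan_seed_sites,
    write_sites_tsv,
)
from mirconsensus.engines.dpalign import ConfigError
from mirconsensus.engines.seedscan import au_context
from mirconsensus.sequence_space import GenomeInterval, MiRNARecord, UTRRecord

from oracles import oracle_alignment_score, oracle_duplex_mfe, oracle_seed_sites

LET7A = MiRNARecord("hsa-let-7a-5p", "UGAGGUAGUAGGUUGUAUAGUU")


def _utr(seq, tid="t1", strand="+", g0=1000):
    if strand == "+":
        iv = GenomeInterval("c1", g0, g0 + len(seq), "+")
    else:
        iv = GenomeInterval("c1", g0, g0 + len(seq), "-")
    return UTRRecord(tid, seq, (iv,), "annotated", gene_symbol="G1")


class TestSeedscan:
    def test_8mer_site_from_reverse_complement_of_seed(self):
        # revcomp(GAGGUAG) = CUACCUC; with A opposite position 1 -> 8mer
        utr = _utr("GGGG" + "CUACCUCA" + "GGGGGGGG")
        (site,) = scan_seed_sites(LET7A, utr)
        assert site.site_type == "8mer"
        assert (site.seed_start, site.seed_end) == (4, 11)

    def test_a_to_u_substitution_demotes_to_7mer_m8(self):
        utr = _utr("GGGG" + "CUACCUCU" + "GGGGGGGG")
        (site,) = scan_seed_sites(LET7A, utr)
        assert site.site_type == "7mer-m8"

    def test_no_complementary_window_yields_empty(self):
        utr = _utr("G" * 40)
        assert scan_seed_sites(LET7A, utr) == []

    def test_au_context_separates_polya_from_polyg_flanks(self):
        site = "CUACCUCA"
        rich = _utr("A" * 15 + site + "A" * 15)
        poor = _utr("G" * 15 + site + "G" * 15)
        (s_rich,) = scan_seed_sites(LET7A, rich)
        (s_poor,) = scan_seed_sites(LET7A, poor)
        assert au_context(rich.sequence, 15, 23) == 1.0
        assert au_context(poor.sequence, 15, 23) == 0.0
        assert s_rich.raw_score > s_poor.raw_score

    def test_site_detection_and_types_match_string_oracle(self, utrs, mirnas):
        params = SeedscanParams()
        for utr in utrs[:10]:
            for m in mirnas:
                expected = oracle_seed_sites(utr.sequence, m.sequence)
                got = scan_seed_sites(m, utr, params)
                # production reduces overlapping matches; every oracle match
                # must be covered by a reported site of equal-or-better type
                for p, st in expected:
                    assert any(
                        s.seed_start <= p < s.seed_end for s in got
                    ), (utr.transcript_id, m.mirna_id, p, st)
                for s in got:
                    assert (
                        s.site_type in [st for p, st in expected]
                        or s.site_type == "non-canonical"
                    )

    def test_planted_sites_all_recovered_with_correct_type(
        self, fixture_set, utrs, mirnas
    ):
        by_id = {u.transcript_id: u for u in utrs}
        mir = {m.mirna_id: m for m in mirnas}
        for row in fixture_set.truth_sites.itertuples():
            sites = scan_seed_sites(mir[row.mirna_id], by_id[row.transcript_id])
            hits = [
                s
                for s in sites
                if s.seed_start <= row.core_start < s.seed_end
                and s.site_type == row.site_type
            ]
            assert hits, f"planted site missed: {row}"


class TestDpalign:
    def test_seven_watson_crick_pairs_score_seven_matches(self):
        # seed multiplier 1 -> 7 * match
        p = AlignParams(seed_scale=1.0, score_threshold=0.0)
        score = best_alignment_score("GAGGUAG", "CUACCUCA", p)
        assert score == pytest.approx(7 * p.match)

    def test_wobble_beats_mismatch_by_parameter_difference(self):
        p = AlignParams(seed_scale=1.0)
        # G.U wobble vs A.C mismatch in otherwise identical duplexes
        wob = best_alignment_score("GGGGG", "CCCUC", p)  # one G.U
        mis = best_alignment_score("GGGGG", "CCCAC", p)  # one A.C... G vs A
        assert wob - mis == pytest.approx(p.wobble - p.mismatch)

    def test_non_positive_match_is_config_error(self):
        with pytest.raises(ConfigError):
            AlignParams(match=0.0)

    def test_optimum_equals_brute_force_on_200_random_instances(self):
        rng = np.random.default_rng(2024)
        p = AlignParams(score_threshold=0.0)
        bases = list("ACGU")
        for _ in range(200):
            n = int(rng.integers(4, 11))
            L = int(rng.integers(5, 13))
            m = "".join(rng.choice(bases, n))
            u = "".join(rng.choice(bases, L))
            assert best_alignment_score(m, u, p) == pytest.approx(
                oracle_alignment_score(m, u, p)
            ), (m, u)

    def test_planted_perfect_seed_crosses_default_threshold(self, utrs, mirnas):
        utr = _utr("G" * 20 + "CUACCUCA" + "G" * 20)
        sites = align_complementarity(LET7A, utr)
        assert sites and all(s.raw_score >= AlignParams().score_threshold for s in sites)


class TestDuplexfold:
    def test_fully_complementary_5mer_energy_is_stack_sum_plus_initiation(self):
        model = default_model()
        m = "ACGUG"
        t = "CACGU"  # reverse complement in RNA, antiparallel
        energy, pairs = duplex_mfe(m, t, model)
        expected = model.initiation
        for k in range(4):
            expected += model.stacks[f"{m[k]}{m[k+1]}/{t[4-k]}{t[3-k]}"]
        assert energy == pytest.approx(expected)
        assert pairs == [(0, 4), (1, 3), (2, 2), (3, 1), (4, 0)]

    def test_no_complementary_pairs_yields_no_site(self):
        model = default_model()
        energy, pairs = duplex_mfe("AAAA", "GGGG", model)  # no canonical A.G pairs
        assert energy is None
        utr = _utr("G" * 30)
        m = MiRNARecord("m", "G" * 22)  # G.G never pairs... G.U absent too
        assert hybridization_energy(m, utr) == []

    def test_mfe_equals_exhaustive_enumeration_on_100_random_instances(self):
        rng = np.random.default_rng(77)
        model = default_model()
        bases = list("ACGU")
        for _ in range(100):
            n = int(rng.integers(3, 9))
            L = int(rng.integers(3, 9))
            m = "".join(rng.choice(bases, n))
            t = "".join(rng.choice(bases, L))
            got, _ = duplex_mfe(m, t, model)
            want = oracle_duplex_mfe(m, t, model)
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want), (m, t)

    def test_mfe_lower_bounds_every_enumerated_structure(self):
        # spot-check the bound form of the equivalence on a fixed instance
        model = default_model()
        m, t = "GCACGU", "ACGUGC"
        got, _ = duplex_mfe(m, t, model)
        assert got <= oracle_duplex_mfe(m, t, model) + 1e-9

    def test_sites_respect_energy_threshold(self, sites_by_engine):
        thr = DuplexParams().energy_threshold
        for s in sites_by_engine["duplexfold"]:
            assert s.energy is not None and s.energy < thr
            assert s.raw_score == pytest.approx(-s.energy)


class TestAccessibility:
    def test_unpairable_flanks_leave_energy_unchanged(self):
        # poly-C flanks cannot pair with the poly-A target region
        utr2 = _utr("C" * 20 + "AAAAAAAA" + "C" * 20)
        m2 = MiRNARecord("m2", "UUUUUUUUUUUUUUUUUUUUUU")
        (site2,) = hybridization_energy(m2, utr2, params=DuplexParams(window=48))
        region = utr2.sequence[site2.utr_start : site2.utr_end]
        assert set(region) == {"A"}
        adjusted = accessibility_adjusted_energy(site2, utr2)
        assert adjusted == pytest.approx(site2.energy)

    def test_hairpin_prone_site_pays_opening_penalty(self):
        # site region GCGCGC with a flank that is its perfect complement
        seq = "A" * 10 + "GCGCGCGC" + "A" * 4 + "GCGCGCGC" + "A" * 10
        utr = _utr(seq)
        m = MiRNARecord("m", "A" * 7 + "CGCGCGCG" + "A" * 7)
        sites = hybridization_energy(m, utr, params=DuplexParams(window=len(seq)))
        assert sites
        site = max(sites, key=lambda s: s.raw_score)
        adjusted = accessibility_adjusted_energy(site, utr)
        assert adjusted > site.energy  # less favorable after opening penalty

    def test_adjustment_is_never_negative(self, utrs, mirnas):
        model = default_model()
        utr = utrs[0]
        for m in mirnas[:2]:
            for site in hybridization_energy(m, utr, model):
                assert accessibility_adjusted_energy(site, utr, model) >= site.energy


class TestExternalImport:
    def test_well_formed_rows_pass_through(self, tmp_path, utrs):
        utr_by_tx = {u.transcript_id: u for u in utrs}
        tid = utrs[0].transcript_id
        path = tmp_path / "ext.tsv"
        path.write_text(
            "mirna_id\ttranscript_id\tstart\tend\tscore\n"
            f"hsa-miR-901-5p\t{tid}\t5\t12\t1.5\n"
            f"hsa-miR-902-5p\t{tid}\t20\t27\t2.5\n"
            f"hsa-miR-903-5p\t{tid}\t30\t37\t3.5\n"
        )
        sites = import_external_predictions(path, "exttool", utr_by_tx)
        assert len(sites) == 3
        assert all(s.engine == "exttool" for s in sites)

    def test_one_based_inclusive_header_converts_coordinates(self, tmp_path, utrs):
        utr_by_tx = {u.transcript_id: u for u in utrs}
        tid = utrs[0].transcript_id
        path = tmp_path / "ext.tsv"
        path.write_text(
            "#coords=1-based-inclusive\n"
            "mirna_id\ttranscript_id\tstart\tend\tscore\n"
            f"hsa-miR-901-5p\t{tid}\t6\t12\t1.0\n"
        )
        (site,) = import_external_predictions(path, "x", utr_by_tx)
        assert (site.utr_start, site.utr_end) == (5, 12)

    def test_unknown_transcript_skipped_and_malformed_row_errors(self, tmp_path, utrs):
        utr_by_tx = {u.transcript_id: u for u in utrs}
        tid = utrs[0].transcript_id
        ok = tmp_path / "skip.tsv"
        ok.write_text(
            "mirna_id\ttranscript_id\tstart\tend\tscore\n"
            f"m\tNOT_A_TX\t1\t5\t1.0\nm\t{tid}\t1\t5\t1.0\n"
        )
        assert len(import_external_predictions(ok, "x", utr_by_tx)) == 1
        bad = tmp_path / "bad.tsv"
        bad.write_text(
            "mirna_id\ttranscript_id\tstart\tend\tscore\n" f"m\t{tid}\tfive\t9\t1.0\n"
        )
        with pytest.raises(ValueError, match=":2"):
            import_external_predictions(bad, "x", utr_by_tx)


class TestGenomicLift:
    def test_seed_interval_round_trips_through_the_utr_map(self, sites_by_engine, utrs):
        by_id = {u.transcript_id: u for u in utrs}
        checked = 0
        for engine_sites in sites_by_engine.values():
            for s in engine_sites[:50]:
                utr = by_id[s.transcript_id]
                pieces = utr.local_to_genomic(s.seed_start, s.seed_end)
                lo = min(utr.genomic_to_local(p)[0] for p in pieces)
                hi = max(utr.genomic_to_local(p)[1] for p in pieces)
                assert (lo, hi) == (s.seed_start, s.seed_end)
                assert s.genomic_seed.start == min(p.start for p in pieces)
                assert s.genomic_seed.end == max(p.end for p in pieces)
                checked += 1
        assert checked > 0


def test_sites_tsv_round_trip(tmp_path, sites_by_engine):
    sites = sites_by_engine["seedscan"]
    path = tmp_path / "s.tsv"
    write_sites_tsv(sites, path)
    back = read_sites_tsv(path)
    assert len(back) == len(sites)
    for a, b in zip(sites, back):
        assert (a.engine, a.mirna_id, a.transcript_id) == (b.engine, b.mirna_id, b.transcript_id)
        assert (a.utr_start, a.utr_end, a.seed_start, a.seed_end) == (
            b.utr_start,
            b.utr_end,
            b.seed_start,
            b.seed_end,
        )
        assert a.raw_score == pytest.approx(b.raw_score, rel=1e-5)
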