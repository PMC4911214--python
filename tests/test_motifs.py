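"""Motif enumeration, scanning semantics, and enrichment statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mitoflux import motifs
from mitoflux.motifs import (
    PromoterSet,
    adjust_multiplicity,
    canonical,
    consensus_binomial,
    delta_median,
    enumerate_motifs,
    iupac_match,
    kmer_presence_index,
    motif_mwu,
    revcomp,
    scan_presence,
)


def _ranked(ranks_by_gene: dict[str, int]) -> pd.DataFrame:
    frame = pd.DataFrame(
        {"gene_id": list(ranks_by_gene), "rank": list(ranks_by_gene.values())}
    ).sort_values("rank").reset_index(drop=True)
    n = len(frame)
    frame["norm_rank"] = (frame["rank"] - 0.5) / n
    return frame


class TestEnumeration:
    def test_ungapped_6_to_8_count(self):
        assert len(enumerate_motifs(6, 8)) == 4**6 + 4**7 + 4**8  # 86,016

    def test_gapped_9mer_count(self):
        with_g = len(enumerate_motifs(6, 8, include_gapped9=True))
        without = len(enumerate_motifs(6, 8))
        assert with_g - without == 7 * 4**8  # 458,752

    def test_canonical_6mer_count(self):
        assert len(enumerate_motifs(6, 6, canonicalize=True)) == (4**6 + 4**3) // 2

    def test_gap_positions_are_interior(self):
        gapped = [m for m in enumerate_motifs(1, 1, include_gapped9=True)
                  if len(m) == 9]
        assert all("N" in m[1:8] and not (m[0] == "N" or m[-1] == "N")
                   for m in gapped)


class TestIupacAndStrand:
    @pytest.mark.parametrize("base, code, expected", [
        ("C", "H", True), ("A", "H", True), ("T", "H", True),
        ("G", "H", False), ("N", "A", False), ("N", "N", False),
        ("G", "N", True), ("A", "A", True), ("A", "T", False),
    ])
    def test_iupac_match(self, base, code, expected):
        assert iupac_match(base, code) is expected

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError, match="invalid IUPAC"):
            iupac_match("A", "X")

    def test_revcomp_is_involution_on_iupac(self):
        for m in ["TGATGCAA", "TGATGHAAH", "ACNGT"]:
            assert revcomp(revcomp(m)) == m

    def test_canonical_collapses_strands(self):
        assert canonical("TGATGC") == canonical("GCATCA")


class TestScanning:
    def test_forward_match(self):
        promoters = PromoterSet({"g1": "AATGATGCAATT"})
        assert scan_presence(promoters, "TGATGCAA", bidirectional=False) == {"g1"}

    def test_reverse_complement_needs_bidirectional(self):
        # TTGCATCA is the reverse complement of TGATGCAA
        promoters = PromoterSet({"g1": "CCCTTGCATCACCC"})
        assert scan_presence(promoters, "TGATGCAA", bidirectional=True) == {"g1"}
        assert scan_presence(promoters, "TGATGCAA", bidirectional=False) == set()

    def test_all_masked_promoter_never_matches(self):
        promoters = PromoterSet({"g1": "N" * 30})
        assert scan_presence(promoters, "TGATGCAA") == set()
        assert scan_presence(promoters, "NNNNNN") == set()

    def test_masked_base_blocks_gap_wildcard(self):
        # gap N in the motif must not match a masked sequence position
        promoters = PromoterSet({"g1": "AAATGATNCAAAAA"})
        assert scan_presence(promoters, "TGATNCAA") == set()
        promoters2 = PromoterSet({"g2": "AAATGATGCAAAAA"})
        assert scan_presence(promoters2, "TGATNCAA") == {"g2"}

    def test_degenerate_consensus_matches(self):
        promoters = PromoterSet({
            "hit_c": "TTTGATGCAACTT",   # H := C ... H := C
            "hit_a": "TTTGATGAAAATT",   # H := A ... H := A
            "miss": "TTTGATGGAAGTT",    # G at the H position
        })
        assert scan_presence(promoters, "TGATGHAAH") == {"hit_c", "hit_a"}

    @given(st.data())
    @settings(deadline=None, max_examples=60)
    def test_bidirectional_scan_is_strand_symmetric(self, data):
        rng_seqs = data.draw(st.lists(
            st.text(alphabet="ACGTN", min_size=12, max_size=40),
            min_size=1, max_size=6))
        motif = data.draw(st.text(alphabet="ACGT", min_size=4, max_size=7))
        promoters = PromoterSet(
            {f"g{i}": s for i, s in enumerate(rng_seqs)}
        )
        assert scan_presence(promoters, motif) == \
            scan_presence(promoters, revcomp(motif))

    def test_kmer_index_agrees_with_direct_scan(self):
        rng = np.random.default_rng(4)
        seqs = {}
        for i in range(30):
            s = "".join(rng.choice(list("ACGT"), size=60))
            if rng.random() < 0.3:
                s = s[:10] + "NNNNN" + s[15:]
            seqs[f"g{i}"] = s
        promoters = PromoterSet(seqs)
        index = kmer_presence_index(promoters, 5, bidirectional=True)
        for motif in ["TGATG", "CCCCC", "ATAAT", "GCGCG"]:
            expected = scan_presence(promoters, motif, bidirectional=True)
            assert index.get(canonical(motif), set()) == expected


def brute_force_mwu_p(all_ranks: list[int], with_ranks: list[int]) -> float:
    """Exact two-sided Mann-Whitney p by enumeration of rank assignments."""
    m = len(with_ranks)
    u_obs = sum(with_ranks) - m * (m + 1) // 2
    us = [
        sum(comb) - m * (m + 1) // 2
        for comb in itertools.combinations(all_ranks, m)
    ]
    total = len(us)
    p_hi = sum(u >= u_obs for u in us) / total
    p_lo = sum(u <= u_obs for u in us) / total
    return min(1.0, 2.0 * min(p_hi, p_lo))


class TestMannWhitney:
    def test_top_three_of_six_hand_value(self):
        ranked = _ranked({f"g{i}": i for i in range(1, 7)})
        u, p = motif_mwu(ranked, {"g1", "g2", "g3"})
        # one-sided exact p = 1 / C(6,3) = 0.05; two-sided doubles it
        assert p == pytest.approx(0.10)

    def test_exact_matches_brute_force_enumeration(self):
        ranked = _ranked({f"g{i}": i for i in range(1, 8)})
        all_ranks = list(range(1, 8))
        for m in (1, 2, 3):
            for subset in itertools.combinations(all_ranks, m):
                with_set = {f"g{i}" for i in subset}
                _, p = motif_mwu(ranked, with_set)
                assert p == pytest.approx(
                    brute_force_mwu_p(all_ranks, list(subset)), abs=1e-12
                )

    def test_full_or_empty_set_flagged_untestable(self):
        ranked = _ranked({f"g{i}": i for i in range(1, 6)})
        u, p = motif_mwu(ranked, {f"g{i}" for i in range(1, 6)})
        assert math.isnan(u) and p == 1.0
        u, p = motif_mwu(ranked, set())
        assert math.isnan(u) and p == 1.0

    def test_unknown_gene_rejected(self):
        ranked = _ranked({"a": 1, "b": 2})
        with pytest.raises(ValueError, match="unranked"):
            motif_mwu(ranked, {"zzz"})

    def test_exact_and_asymptotic_agree_across_the_threshold(self):
        """The exact/asymptotic seam is smooth: for groups of 3-8 genes the
        continuity-corrected normal p stays within 0.02 of enumeration (the
        approximation is coarser still for groups of 1-2, which the exact
        path always covers at the default threshold)."""
        rng = np.random.default_rng(7)
        n = 40
        ranked = _ranked({f"g{i}": i for i in range(1, n + 1)})
        for _ in range(20):
            m = rng.integers(3, 9)
            subset = set(rng.choice(n, size=m, replace=False) + 1)
            with_set = {f"g{i}" for i in subset}
            _, p_exact = motif_mwu(ranked, with_set, exact_threshold=8)
            _, p_approx = motif_mwu(ranked, with_set, exact_threshold=0)
            assert abs(p_exact - p_approx) < 0.02


class TestDeltaMedian:
    def test_top_ranks_hand_value(self):
        ranked = _ranked({f"g{i}": i for i in range(1, 7)})
        assert delta_median(ranked, {"g1", "g2", "g3"}) == pytest.approx(-0.25)

    def test_whole_list_is_centered(self):
        ranked = _ranked({f"g{i}": i for i in range(1, 8)})
        assert delta_median(ranked, set(ranked["gene_id"])) == pytest.approx(0.0)

    def test_mirror_symmetry(self):
        n = 10
        ranked = _ranked({f"g{i}": i for i in range(1, n + 1)})
        top = delta_median(ranked, {"g1", "g2", "g3"})
        bottom = delta_median(ranked, {f"g{n}", f"g{n-1}", f"g{n-2}"})
        assert top == pytest.approx(-bottom)

    def test_bounds(self):
        n = 9
        ranked = _ranked({f"g{i}": i for i in range(1, n + 1)})
        assert -0.5 <= delta_median(ranked, {"g1"}) <= 0.5
        assert -0.5 <= delta_median(ranked, {f"g{n}"}) <= 0.5

    def test_empty_set_rejected(self):
        ranked = _ranked({"a": 1, "b": 2})
        with pytest.raises(ValueError):
            delta_median(ranked, set())


class TestMultiplicity:
    def test_bonferroni_scaling(self):
        assert adjust_multiplicity(1e-9, 86016) == pytest.approx(8.6016e-5)

    def test_cap_at_one(self):
        assert adjust_multiplicity(0.5, 4) == 1.0

    def test_single_motif_identity(self):
        assert adjust_multiplicity(0.123, 1) == pytest.approx(0.123)


class TestConsensusBinomial:
    def test_no_hits_gives_p_one(self):
        promoters = PromoterSet({f"g{i}": "A" * 30 for i in range(10)})
        k, n, p = consensus_binomial(promoters, list(promoters.sequences),
                                     "TGATGHAAH", 0.14)
        assert (k, n, p) == (0, 10, 1.0)

    def test_all_five_hit_at_background_half(self):
        promoters = PromoterSet(
            {f"g{i}": "CCTGATGCAACCC" for i in range(5)}
        )
        k, n, p = consensus_binomial(promoters, list(promoters.sequences),
                                     "TGATGHAAH", 0.5)
        assert (k, n) == (5, 5)
        assert p == pytest.approx(0.5 ** 5)

    def test_paper_scale_enrichment_is_below_1e9(self):
        # 26 of 50 genes with a 14% genome-wide background
        from scipy import stats

        p = float(stats.binom.sf(25, 50, 0.14))
        promoters = PromoterSet({f"g{i}": "CCTGATGCAACCC" for i in range(26)}
                                | {f"h{i}": "A" * 20 for i in range(24)})
        k, n, p_pkg = consensus_binomial(promoters, list(promoters.sequences),
                                        "TGATGHAAH", 0.14)
        assert (k, n) == (26, 50)
        assert p_pkg == pytest.approx(p, rel=1e-12)
        assert p_pkg < 1e-9


class TestEnrichmentScan:
    def test_planted_motif_wins_on_constructed_promoters(self):
        rng = np.random.default_rng(9)
        n = 120
        ranked = _ranked({f"g{i:03d}": i for i in range(1, n + 1)})
        seqs = {}
        for i in range(1, n + 1):
            s = "".join(rng.choice(list("ACGT"), size=80))
            if i <= 15:  # plant in the top ranks
                pos = rng.integers(0, 80 - 6)
                s = s[:pos] + "TGATGC" + s[pos + 6:]
            seqs[f"g{i:03d}"] = s
        records = motifs.enrichment_scan(ranked, PromoterSet(seqs),
                                         min_len=6, max_len=6)
        assert records.iloc[0]["motif"] == canonical("TGATGC")
        assert records.iloc[0]["delta_median"] < 0
        assert records.iloc[0]["p_adj"] < 0.05

    def test_report_sorted_by_adjusted_p(self):
        rng = np.random.default_rng(10)
        ranked = _ranked({f"g{i}": i for i in range(1, 41)})
        seqs = {f"g{i}": "".join(rng.choice(list("ACGT"), size=50))
                for i in range(1, 41)}
        records = motifs.enrichment_scan(ranked, PromoterSet(seqs),
                                         min_len=6, max_len=6)
        p = records["p_adj"].to_numpy()
        assert (np.diff(p) >= 0).all()
        assert set(records.columns) >= {"motif", "n_with", "n_total", "U",
                                        "p_raw", "p_adj", "delta_median"}
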