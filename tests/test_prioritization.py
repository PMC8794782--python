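import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ailqtl import prioritization as pr
from ailqtl.core_io import ValidationError


def _genes(rows):
    return pd.DataFrame(
        rows, columns=["gene", "name", "chrom", "start", "end", "biotype"]
    )


def _variants(rows):
    df = pd.DataFrame(
        rows,
        columns=["variant", "chrom", "pos", "gene", "consequence", "in_functional_domain", "sift_class"],
    )
    df["in_functional_domain"] = df["in_functional_domain"].astype(bool)
    return df


class TestCandidateGenes:
    def test_padded_abutment_counts_as_overlap(self):
        genes = _genes([("g1", "G1", "1", 8_000, 9_000, "protein_coding")])
        # gene ends exactly 1000 bp before the interval start
        hits = pr.candidate_genes(("1", 10_000, 20_000), genes, pad=1000)
        assert list(hits["gene"]) == ["g1"]
        # one bp further away: excluded
        assert len(pr.candidate_genes(("1", 10_001, 20_000), genes, pad=1000)) == 0

    def test_gene_inside_interval_included_and_non_coding_excluded(self):
        genes = _genes(
            [
                ("g1", "G1", "1", 12_000, 13_000, "protein_coding"),
                ("g2", "G2", "1", 12_000, 13_000, "lncRNA"),
                ("g3", "G3", "2", 12_000, 13_000, "protein_coding"),
            ]
        )
        hits = pr.candidate_genes(("1", 10_000, 20_000), genes)
        assert list(hits["gene"]) == ["g1"]

    def test_tiled_genes_match_brute_force_overlap_oracle(self):
        genes = _genes(
            [
                (f"g{k}", f"G{k}", "1", 1 + 5_000 * k, 3_000 + 5_000 * k, "protein_coding")
                for k in range(20)
            ]
        )
        interval, pad = ("1", 24_000, 61_000), 1000
        hits = set(pr.candidate_genes(interval, genes, pad=pad)["gene"])
        expected = {
            g["gene"]
            for _, g in genes.iterrows()
            if g["start"] - pad <= interval[2] and g["end"] + pad >= interval[1]
        }
        assert hits == expected

    def test_empty_gene_table_rejected(self):
        with pytest.raises(ValueError):
            pr.candidate_genes(("1", 1, 2), _genes([]))


class TestPolymorphicFilter:
    def test_variant_free_gene_removed_and_boundary_kept(self):
        genes = _genes(
            [
                ("g1", "G1", "1", 10_000, 20_000, "protein_coding"),
                ("g2", "G2", "1", 50_000, 60_000, "protein_coding"),
            ]
        )
        variants = _variants([("v1", "1", 9_000, "g1", "utr", False, "none")])
        kept = pr.polymorphic_filter(genes, variants, pad=1000)
        assert list(kept["gene"]) == ["g1"]  # variant at start - 1000 counts

    def test_random_placement_matches_membership_oracle(self, rng):
        genes = _genes(
            [
                (f"g{k}", f"G{k}", "1", 10_000 * k + 1, 10_000 * k + 4_000, "protein_coding")
                for k in range(15)
            ]
        )
        pos = rng.integers(1, 160_000, size=60)
        variants = _variants(
            [(f"v{j}", "1", int(p), "", "other", False, "none") for j, p in enumerate(pos)]
        )
        kept = set(pr.polymorphic_filter(genes, variants, pad=1000)["gene"])
        expected = {
            g["gene"]
            for _, g in genes.iterrows()
            if ((pos >= g["start"] - 1000) & (pos <= g["end"] + 1000)).any()
        }
        assert kept == expected


class TestFlags:
    def test_repeated_category_sets_flag_once(self):
        flags, counts = pr.flags_from_annotations(
            _variants(
                [
                    ("v1", "1", 10, "g", "promoter", False, "none"),
                    ("v2", "1", 20, "g", "promoter", False, "none"),
                ]
            )
        )
        assert flags.promoter_or_splice
        assert counts["promoter_or_splice"] == 2

    def test_fmo5_like_pattern(self):
        flags, _ = pr.flags_from_annotations(
            _variants(
                [
                    ("v1", "1", 10, "g", "missense", True, "tolerated"),
                    ("v2", "1", 20, "g", "utr", False, "none"),
                    ("v3", "1", 30, "g", "enhancer", False, "none"),
                    ("v4", "1", 40, "g", "promoter", False, "none"),
                ]
            )
        )
        assert flags.missense_in_domain and flags.sift_tolerated
        assert flags.promoter_or_splice and flags.utr and flags.enhancer
        assert not (flags.sift_deleterious or flags.ctcf or flags.stop_gain_or_loss)

    def test_most_severe_sift_class_dominates(self):
        flags, _ = pr.flags_from_annotations(
            _variants(
                [
                    ("v1", "1", 10, "g", "missense", False, "deleterious"),
                    ("v2", "1", 20, "g", "missense", True, "tolerated"),
                ]
            )
        )
        assert flags.missense_in_domain
        assert flags.sift_deleterious and not flags.sift_tolerated

    def test_rows_from_multiple_genes_rejected(self):
        with pytest.raises(ValueError):
            pr.flags_from_annotations(
                _variants(
                    [
                        ("v1", "1", 10, "g1", "utr", False, "none"),
                        ("v2", "1", 20, "g2", "utr", False, "none"),
                    ]
                )
            )


class TestScoring:
    def test_deleterious_domain_missense_with_de_and_kegg(self):
        # the Acat2 pattern: 3 (domain) + 3 (deleterious) + 2 (DE) + 1 (KEGG) = 9
        flags = pr.CategoryFlags(missense=True, missense_in_domain=True, sift_deleterious=True)
        assert pr.score_gene(flags, True, True).total == 9

    def test_no_evidence_scores_zero(self):
        assert pr.score_gene(pr.CategoryFlags(), False, False).total == 0

    def test_tolerated_domain_missense_plus_regulatory_categories(self):
        # the Fmo5 pattern: (3+1) + 3 + 1 + 1 + 2 + 1 = 12
        flags = pr.CategoryFlags(
            missense=True,
            missense_in_domain=True,
            sift_tolerated=True,
            promoter_or_splice=True,
            utr=True,
            enhancer=True,
        )
        assert pr.score_gene(flags, True, True).total == 12

    def test_tolerated_missense_outside_domain(self):
        # the Rrn3 pattern: 1 + 2 + 1 = 4
        flags = pr.CategoryFlags(missense=True, sift_tolerated=True)
        assert pr.score_gene(flags, True, True).total == 4

    def test_reference_fixture_reproduces_published_scores(self):
        cards = pr.load_reference_candidates()
        scores = {c.gene: c.total for c in cards}
        assert scores == {
            "Plg": 10,
            "Acat2": 9,
            "Fmo5": 12,
            "Notch2": 10,
            "Trap1": 7,
            "Rrn3": 4,
            "Trappc9": 9,
            "Zfat": 8,
        }

    def test_per_variant_mode_multiplies_by_counts(self):
        flags = pr.CategoryFlags(promoter_or_splice=True, utr=True)
        counts = {"promoter_or_splice": 2, "utr": 3}
        card = pr.score_gene(
            flags, False, False, scheme=pr.ScoringScheme(mode="per_variant"), counts=counts
        )
        assert card.total == 2 * 3 + 3 * 1

    def test_inconsistent_flags_rejected(self):
        with pytest.raises(ValidationError):
            pr.score_gene(pr.CategoryFlags(sift_deleterious=True), False, False)

    def test_removing_de_reduces_score_by_exactly_two(self):
        flags = pr.CategoryFlags(missense=True, sift_deleterious=True)
        with_de = pr.score_gene(flags, True, False).total
        without = pr.score_gene(flags, False, False).total
        assert with_de - without == 2

    @given(st.integers(0, 2**8 - 1))
    def test_adding_any_variant_category_never_decreases_score(self, bits):
        names = [
            "stop_gain_or_loss",
            "missense_in_domain",
            "sift_deleterious",
            "promoter_or_splice",
            "utr",
            "enhancer",
            "ctcf",
            "missense",
        ]
        kw = {name: bool(bits >> i & 1) for i, name in enumerate(names)}
        kw["missense"] |= kw["missense_in_domain"] or kw["sift_deleterious"]
        base = pr.score_gene(pr.CategoryFlags(**kw), False, False).total
        for extra in ("utr", "enhancer", "ctcf", "promoter_or_splice", "stop_gain_or_loss"):
            richer = dict(kw)
            richer[extra] = True
            assert pr.score_gene(pr.CategoryFlags(**richer), False, False).total >= base


class TestRanking:
    def test_reference_fixture_top_two_per_qtl(self):
        ranked = pr.rank_candidates(pr.load_reference_candidates())
        top = {
            qtl: {c.gene for c in ranked if c.qtl == qtl and c.top_candidate}
            for qtl in ("Gatlgq", "Gatq1", "Bwq26", "Gatq2")
        }
        assert top == {
            "Gatlgq": {"Plg", "Acat2"},
            "Gatq1": {"Fmo5", "Notch2"},
            "Bwq26": {"Trap1", "Rrn3"},
            "Gatq2": {"Trappc9", "Zfat"},
        }

    def test_single_gene_ranks_first_and_top(self):
        card = pr.score_gene(pr.CategoryFlags(utr=True), False, False, gene="g", qtl="q")
        (ranked,) = pr.rank_candidates([card])
        assert ranked.rank == 1 and ranked.top_candidate

    def test_all_equal_scores_ordered_alphabetically(self):
        cards = [
            pr.score_gene(pr.CategoryFlags(utr=True), False, False, gene=g, qtl="q")
            for g in ("Zeta", "Alpha", "Mid")
        ]
        ranked = pr.rank_candidates(cards)
        assert [c.gene for c in ranked] == ["Alpha", "Mid", "Zeta"]
        assert [c.top_candidate for c in ranked] == [True, True, False]
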