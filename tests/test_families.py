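"""Family clustering, non-metabolic filtering, Inferred promotion,
family-level scores and candidate ranking."""

import pytest

import metabolon as mb
from metabolon.families import Family, family_of_map


def key(org, gene):
    return (org, gene)


class TestNaiveFamilies:
    def test_pairwise_similar_genes_form_one_family(self):
        edges = [
            (key("o1", "a"), key("o2", "b"), 0.9),
            (key("o1", "a"), key("o3", "c"), 0.8),
            (key("o2", "b"), key("o3", "c"), 0.85),
        ]
        fams = mb.naive_families_from_similarity(edges, 0.7)
        assert len(fams) == 1
        assert next(iter(fams.values())).size == 3

    def test_threshold_above_all_scores_gives_singletons(self):
        edges = [(key("o1", "a"), key("o2", "b"), 0.5)]
        fams = mb.naive_families_from_similarity(edges, 0.9)
        assert sorted(f.size for f in fams.values()) == [1, 1]

    def test_single_linkage_chains_transitively(self):
        edges = [
            (key("o1", "a"), key("o2", "b"), 0.9),
            (key("o2", "b"), key("o3", "c"), 0.9),
            (key("o1", "a"), key("o3", "c"), 0.1),  # below threshold
        ]
        fams = mb.naive_families_from_similarity(edges, 0.5)
        assert len(fams) == 1 and next(iter(fams.values())).size == 3

    def test_conflicting_duplicate_scores_rejected(self):
        edges = [
            (key("o1", "a"), key("o2", "b"), 0.9),
            (key("o2", "b"), key("o1", "a"), 0.2),
        ]
        with pytest.raises(ValueError, match="conflicting"):
            mb.naive_families_from_similarity(edges, 0.5)

    def test_gene_in_two_families_rejected(self):
        fams = {
            "F1": Family("F1", {key("o", "a")}),
            "F2": Family("F2", {key("o", "a")}),
        }
        with pytest.raises(ValueError, match="belongs"):
            family_of_map(fams)


class TestPromotion:
    def test_family_known_promotes_and_prunes(self, promotion_data):
        result = mb.run_pipeline(promotion_data)
        by_key = {a.key: a for a in result.associations}
        assert by_key[("org3", "g3F", "r5")].category == mb.INFERRED
        # the promotion renders the other Potentials of g3F / r5 impossible
        assert ("org3", "g3F", "r4") not in by_key
        assert ("org3", "g3D", "r5") not in by_key
        # the untouched pair survives as Potential
        assert by_key[("org3", "g3D", "r4")].category == mb.POTENTIAL
        # promoted gene and reaction cease to be gaps
        m3 = next(m for m in result.metabolons if m.organism_id == "org3")
        assert not m3.gene_is_gap["g3F"] and not m3.reaction_is_gap["r5"]

    def test_inferred_weighs_like_known(self, promotion_data):
        result = mb.run_pipeline(promotion_data)
        a = next(x for x in result.associations if x.category == mb.INFERRED)
        assert a.weight == pytest.approx(1.0 / a.mpl)

    def test_no_family_support_stays_potential(self, promotion_data):
        # cut the family tie: g3F gets its own family
        promotion_data.genes["org3"]["g3F"].family_id = "F_alone"
        result = mb.run_pipeline(promotion_data)
        assert all(a.category != mb.INFERRED for a in result.associations)

    def test_promotion_is_idempotent(self, promotion_data):
        result = mb.run_pipeline(promotion_data)
        promoted, removed = mb.promote_inferred(
            result.metabolons, result.data.associations, result.families,
            result.config,
        )
        assert promoted == [] and removed == []

    def test_promotion_never_grows_the_potential_set(self, corpus_result):
        cats = [a.category for a in corpus_result.associations]
        assert cats.count(mb.POTENTIAL) >= 0  # structural: counts exist
        # rerunning promotion on the finished run changes nothing
        promoted, removed = mb.promote_inferred(
            corpus_result.metabolons, corpus_result.data.associations,
            corpus_result.families, corpus_result.config,
        )
        assert promoted == [] and removed == []


class TestDropNonMetabolic:
    def make_metabolon(self, assocs):
        return mb.Metabolon(
            "M1", "o",
            {a.gene_id: a.category != mb.KNOWN for a in assocs},
            {a.reaction_id: False for a in assocs}, [], [], list(assocs),
        )

    def test_potential_from_flagged_family_removed_known_kept(self):
        known = mb.Association("o", "g1", "r1")
        pot = mb.Association("o", "g2", "r2", mb.POTENTIAL)
        m = self.make_metabolon([known, pot])
        fams = {"F": Family("F", {("o", "g1"), ("o", "g2")}, non_metabolic=True)}
        removed = mb.drop_nonmetabolic([m], fams)
        assert removed == [pot]
        assert m.associations == [known]

    def test_unflagged_families_are_identity(self):
        pot = mb.Association("o", "g2", "r2", mb.POTENTIAL)
        m = self.make_metabolon([pot])
        assert mb.drop_nonmetabolic([m], {"F": Family("F", {("o", "g2")})}) == []
        assert m.associations == [pot]


def weighted(org, gene, rxn, category, mpl):
    return mb.Association(
        org, gene, rxn, category, mpl=mpl,
        weight=mb.association_weight(category, mpl, mb.Config()),
    )


class TestFamilyScores:
    def test_coverage_counts_member_fraction(self):
        fam = Family("F", {("o1", "a"), ("o2", "b"), ("o3", "c"), ("o4", "d")})
        assocs = [
            weighted("o1", "a", "r", mb.POTENTIAL, 3),
            weighted("o2", "b", "r", mb.KNOWN, 3),
        ]
        assert mb.family_coverage(fam, "r", assocs) == pytest.approx(0.5)

    def test_full_coverage_when_all_members_associated(self):
        fam = Family("F", {("o1", "a"), ("o2", "b")})
        assocs = [
            weighted("o1", "a", "r", mb.POTENTIAL, 3),
            weighted("o2", "b", "r", mb.POTENTIAL, 4),
        ]
        assert mb.family_coverage(fam, "r", assocs) == pytest.approx(1.0)

    def test_family_to_reaction_share(self):
        # weights {R: 0.5, R': 0.025} -> 0.5 / 0.525 = 0.9524
        fam = Family("F", {("o", "a")})
        assocs = [
            weighted("o", "a", "R", mb.KNOWN, 2),
            weighted("o", "a", "Rp", mb.POTENTIAL, 4),
        ]
        assert mb.family_to_reaction_score(fam, "R", assocs) == pytest.approx(
            0.5 / 0.525
        )

    def test_reaction_to_family_share_with_outside_gene(self):
        # family weight 0.1/3 + 0.1/4, one family-less gene with 0.1/3
        fam = Family("F", {("o1", "a"), ("o2", "b")})
        assocs = [
            weighted("o1", "a", "r", mb.POTENTIAL, 3),
            weighted("o2", "b", "r", mb.POTENTIAL, 4),
            weighted("o3", "z", "r", mb.POTENTIAL, 3),
        ]
        num = 0.1 / 3 + 0.1 / 4
        denom = num + 0.1 / 3
        assert mb.reaction_to_family_score(fam, "r", assocs) == pytest.approx(
            num / denom
        )

    def test_summed_weight_ordering_is_preserved(self):
        fams = {
            "F1": Family("F1", {("o1", "a")}),
            "F2": Family("F2", {("o2", "b")}),
            "F3": Family("F3", {("o3", "c")}),
        }
        assocs = [
            weighted("o1", "a", "r", mb.KNOWN, 2),
            weighted("o2", "b", "r", mb.POTENTIAL, 3),
            weighted("o3", "c", "r", mb.POTENTIAL, 5),
        ]
        scores = {
            f: mb.reaction_to_family_score(fams[f], "r", assocs) for f in fams
        }
        assert scores["F1"] > scores["F2"] > scores["F3"]

    def test_corpus_normalisation(self, corpus_result):
        rows = corpus_result.family_scores
        fam_sums: dict = {}
        rxn_sums: dict = {}
        for fs in rows:
            assert 0.0 < fs.coverage <= 1.0
            fam_sums[fs.family_id] = fam_sums.get(fs.family_id, 0.0) + fs.score_f_to_r
            rxn_sums[fs.reaction_id] = (
                rxn_sums.get(fs.reaction_id, 0.0) + fs.score_r_to_f
            )
        for total in fam_sums.values():
            assert total == pytest.approx(1.0, abs=1e-12)
        for total in rxn_sums.values():
            assert total <= 1.0 + 1e-12


class TestRanking:
    def build(self, scores):
        """Three family-scored candidates with given reaction-to-family scores."""
        assocs, fams, fss = [], {}, []
        for i, s in enumerate(scores):
            gene, fam = f"g{i}", f"F{i}"
            a = weighted("o", gene, "r", mb.POTENTIAL, 3)
            a.score_r_to_g = 1.0 / len(scores)
            assocs.append(a)
            fams[fam] = Family(fam, {("o", gene)})
            fss.append(
                mb.FamilyReactionScore(fam, "r", 1, 1.0, 1.0, s)
            )
        return assocs, fams, fss

    def test_descending_scores_rank_first_second_third(self):
        assocs, fams, fss = self.build([0.344, 0.334, 0.252])
        ranked = mb.rank_candidates(assocs, fams, fss, "o", "r", "r_to_f")
        assert [(c.gene_id, c.rank) for c in ranked] == [
            ("g0", 1), ("g1", 2), ("g2", 3)
        ]

    def test_ties_share_the_minimum_rank(self):
        assocs, fams, fss = self.build([0.4, 0.4, 0.2])
        ranked = mb.rank_candidates(assocs, fams, fss, "o", "r", "r_to_f")
        assert [c.rank for c in ranked] == [1, 1, 3]

    def test_single_candidate_is_rank_one(self):
        assocs, fams, fss = self.build([1.0])
        ranked = mb.rank_candidates(assocs, fams, fss, "o", "r", "r_to_f")
        assert [(c.gene_id, c.rank) for c in ranked] == [("g0", 1)]

    def test_family_less_genes_fall_back_behind_family_scored_ones(self):
        assocs, fams, fss = self.build([0.3])
        loner = weighted("o", "loner", "r", mb.POTENTIAL, 3)
        loner.score_r_to_g = 0.99  # high gene-level score must not jump the queue
        assocs.append(loner)
        ranked = mb.rank_candidates(assocs, fams, fss, "o", "r", "r_to_f")
        assert [(c.gene_id, c.rank) for c in ranked] == [("g0", 1), ("loner", 2)]
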