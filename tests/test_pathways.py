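"""Tests for pathway complementation classification and matrices."""

import itertools

import pytest

from symbioscreen.pathways import (
    GeneOption,
    GeneStatus,
    Origin,
    ProviderClass,
    Reaction,
    Status,
    StatusTable,
    build_complementarity_matrix,
    classify_reaction,
    cofactor_audit,
    htg_function_overlap,
    pathway_completeness,
)


def _reaction(options, rid="r1", pathway="p", position=1):
    return Reaction(id=rid, pathway=pathway, options=tuple(options), position=position)


class TestClassifyReaction:
    def test_host_insect_complements_missing_symbiont_gene(self):
        # ilvE missing from the primary symbiont, host BCAT enriched
        reaction = _reaction([
            GeneOption("ilvE", Origin.SYMBIONT_A),
            GeneOption("BCAT", Origin.HOST_INSECT),
        ])
        statuses = StatusTable([
            GeneStatus("ilvE", Origin.SYMBIONT_A, Status.ABSENT),
            GeneStatus("BCAT", Origin.HOST_INSECT, expression_enriched=True),
        ])
        a = classify_reaction(reaction, statuses)
        assert a.provider_class is ProviderClass.HOST_COMPLEMENT_INSECT

    def test_host_htg_beside_intact_secondary_symbiont_is_duplicated(self):
        reaction = _reaction([
            GeneOption("dapF", Origin.SYMBIONT_A),
            GeneOption("dapF", Origin.SYMBIONT_B),
            GeneOption("dapF", Origin.HOST_HTG),
        ])
        statuses = StatusTable([
            GeneStatus("dapF", Origin.SYMBIONT_A, Status.ABSENT),
            GeneStatus("dapF", Origin.SYMBIONT_B, Status.INTACT),
            GeneStatus("dapF", Origin.HOST_HTG, expression_enriched=True),
        ])
        a = classify_reaction(reaction, statuses)
        assert a.provider_class is ProviderClass.DUPLICATED
        assert {o for o, _ in a.providers} == {Origin.SYMBIONT_B, Origin.HOST_HTG}

    def test_sole_intact_symbiont_gene_is_symbiont_only(self):
        reaction = _reaction([GeneOption("argF", Origin.SYMBIONT_A)])
        statuses = StatusTable([GeneStatus("argF", Origin.SYMBIONT_A)])
        assert classify_reaction(reaction, statuses).provider_class is ProviderClass.SYMBIONT_ONLY

    def test_pseudogene_never_provides(self):
        reaction = _reaction([GeneOption("argH", Origin.SYMBIONT_A)])
        statuses = StatusTable([GeneStatus("argH", Origin.SYMBIONT_A, Status.PSEUDOGENE)])
        assert classify_reaction(reaction, statuses).provider_class is ProviderClass.UNFILLED

    def test_abundant_but_not_enriched_host_gene_provides(self):
        reaction = _reaction([GeneOption("bioB", Origin.HOST_HTG)])
        statuses = StatusTable([GeneStatus("bioB", Origin.HOST_HTG, abundant=True)])
        assert classify_reaction(reaction, statuses).provider_class is ProviderClass.HOST_COMPLEMENT_HTG

    def test_both_symbionts_without_host_is_shared_pair(self):
        reaction = _reaction([
            GeneOption("g", Origin.SYMBIONT_A), GeneOption("g", Origin.SYMBIONT_B),
        ])
        statuses = StatusTable([
            GeneStatus("g", Origin.SYMBIONT_A), GeneStatus("g", Origin.SYMBIONT_B),
        ])
        assert classify_reaction(reaction, statuses).provider_class is ProviderClass.SHARED_SYMBIONT_PAIR

    def test_missing_status_names_gene(self):
        reaction = _reaction([GeneOption("orphan", Origin.SYMBIONT_A)])
        with pytest.raises(KeyError, match="orphan"):
            classify_reaction(reaction, StatusTable([]))

    def test_enriched_pseudogene_is_contradictory(self):
        with pytest.raises(ValueError):
            GeneStatus("x", Origin.SYMBIONT_A, Status.PSEUDOGENE, expression_enriched=True)

    def test_precedence_is_total_over_status_grid(self):
        """Every status/enrichment combination for a three-option reaction
        maps to exactly one provider class."""
        reaction = _reaction([
            GeneOption("g", Origin.SYMBIONT_A),
            GeneOption("g", Origin.SYMBIONT_B),
            GeneOption("g", Origin.HOST_HTG),
        ])
        host_states = [
            GeneStatus("g", Origin.HOST_HTG, Status.ABSENT),
            GeneStatus("g", Origin.HOST_HTG, Status.INTACT),
            GeneStatus("g", Origin.HOST_HTG, Status.INTACT, expression_enriched=True),
        ]
        for sa, sb, host in itertools.product(list(Status), list(Status), host_states):
            statuses = StatusTable([
                GeneStatus("g", Origin.SYMBIONT_A, sa),
                GeneStatus("g", Origin.SYMBIONT_B, sb),
                host,
            ])
            a = classify_reaction(reaction, statuses)
            assert isinstance(a.provider_class, ProviderClass)
            assert (a.provider_class is ProviderClass.UNFILLED) == (not a.providers)


class TestPathwayCompleteness:
    def test_lysine_fixture_complete_with_three_way_providers(self, pathway_fixtures):
        verdict = pathway_completeness(
            list(pathway_fixtures.pathways["lysine"]), pathway_fixtures.statuses
        )
        assert verdict.complete and verdict.gaps == ()
        origins = {o for a in verdict.assignments for o, _ in a.providers}
        assert {Origin.SYMBIONT_A, Origin.SYMBIONT_B, Origin.HOST_HTG} <= origins

    def test_thiamine_fixture_fully_unfilled(self, pathway_fixtures):
        verdict = pathway_completeness(
            list(pathway_fixtures.pathways["thiamine"]), pathway_fixtures.statuses
        )
        assert not verdict.complete
        assert all(a.provider_class is ProviderClass.UNFILLED for a in verdict.assignments)
        assert list(verdict.gaps) == [a.reaction_id for a in verdict.assignments]

    def test_single_intact_reaction_complete(self):
        verdict = pathway_completeness(
            [_reaction([GeneOption("g", Origin.SYMBIONT_A)])],
            StatusTable([GeneStatus("g", Origin.SYMBIONT_A)]),
        )
        assert verdict.complete

    def test_all_symbiont_a_intact_means_symbiont_only_everywhere(self):
        reactions = [
            _reaction([GeneOption(f"g{i}", Origin.SYMBIONT_A)], rid=f"r{i}", position=i)
            for i in range(1, 5)
        ]
        statuses = StatusTable([GeneStatus(f"g{i}", Origin.SYMBIONT_A) for i in range(1, 5)])
        verdict = pathway_completeness(reactions, statuses)
        assert verdict.complete
        assert all(a.provider_class is ProviderClass.SYMBIONT_ONLY for a in verdict.assignments)

    def test_adding_a_provider_never_unfills(self):
        reaction = _reaction([GeneOption("g", Origin.SYMBIONT_A)])
        bare = StatusTable([GeneStatus("g", Origin.SYMBIONT_A)])
        extended_reaction = _reaction([
            GeneOption("g", Origin.SYMBIONT_A), GeneOption("g2", Origin.HOST_INSECT),
        ])
        extended = StatusTable([
            GeneStatus("g", Origin.SYMBIONT_A),
            GeneStatus("g2", Origin.HOST_INSECT, expression_enriched=True),
        ])
        before = classify_reaction(reaction, bare)
        after = classify_reaction(extended_reaction, extended)
        assert before.provider_class is not ProviderClass.UNFILLED
        assert after.provider_class is not ProviderClass.UNFILLED


class TestCofactorAudit:
    def test_fixture_provisioning(self, pathway_fixtures):
        audit = cofactor_audit(
            pathway_fixtures.cofactor_classes,
            pathway_fixtures.pathways,
            pathway_fixtures.statuses,
        )
        assert audit["folate"] == "joint(Hamiltonella, host)"
        assert audit["thiamine"] == "gap"
        assert audit["nicotinamide"] == "Hamiltonella"
        assert len(audit) == 8

    def test_unknown_cofactor_rejected(self, pathway_fixtures):
        with pytest.raises(ValueError, match="molybdopterin"):
            cofactor_audit(["molybdopterin"], pathway_fixtures.pathways,
                           pathway_fixtures.statuses)


class TestComplementarityMatrix:
    def test_whitefly_row_cells(self, pathway_fixtures):
        matrix = build_complementarity_matrix(list(pathway_fixtures.table2_rows))
        row = matrix.table.loc["whitefly"]
        expected = {"ilvE": "0", "BCAT": "+", "tyrB": "0", "GOT": "+", "ilvA": "+",
                    "TD": "+", "CGL": "+", "argABCDE": "0", "PCD": "+",
                    "PRODH": "+", "OAT": "+"}
        assert row.to_dict() == expected

    def test_psyllid_row_has_uncertain_bcat(self, pathway_fixtures):
        matrix = build_complementarity_matrix(list(pathway_fixtures.table2_rows))
        assert matrix.table.loc["psyllid", "BCAT"] == "?"

    def test_blank_cells_preserved(self, pathway_fixtures):
        matrix = build_complementarity_matrix(list(pathway_fixtures.table2_rows))
        assert matrix.table.loc["mealybug", "PRODH"] == ""

    def test_empty_input_gives_empty_matrix(self):
        assert build_complementarity_matrix([]).table.empty

    def test_schema_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            build_complementarity_matrix([("a", {"x": "+"}), ("b", {"y": "+"})])

    def test_tsv_round_trip(self, pathway_fixtures, tmp_path):
        matrix = build_complementarity_matrix(list(pathway_fixtures.table2_rows))
        path = tmp_path / "matrix.tsv"
        matrix.to_tsv(path)
        reread = type(matrix).from_tsv(path)
        assert reread.table.equals(matrix.table)


class TestHtgFunctionOverlap:
    def test_whitefly_shares_seven_of_ten_functions(self, pathway_fixtures):
        summary = htg_function_overlap(
            {k: set(v) for k, v in pathway_fixtures.htg_function_sets.items()}
        )
        assert summary["per_symbiosis_shared_fraction"]["whitefly"] == pytest.approx(0.7)
        assert summary["universal_functions"] == []

    def test_single_symbiosis_all_unique(self):
        summary = htg_function_overlap({"only": {"a", "b"}})
        assert summary["fraction_unique"] == 1.0

    def test_universal_function_flagged(self):
        summary = htg_function_overlap({"s1": {"f"}, "s2": {"f"}, "s3": {"f"}})
        assert summary["universal_functions"] == ["f"]
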