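"""Pathway-completeness auditing: parsing, matching, and reporting."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from prototroph.pathway import (
    AMINO_ACIDS,
    ESSENTIAL_AMINO_ACIDS,
    CatalogFormatError,
    CatalogValidationError,
    ECNumber,
    OrganismAnnotation,
    PathwayCatalog,
    audit,
    count_catalog_genes,
    load_packaged_catalog,
    missing_steps_for_host,
    parse_catalog,
    variant_complete,
    write_catalog,
)
from prototroph.simulate import gen_annotations

from conftest import make_chain_variant


class TestECNumber:
    @pytest.mark.parametrize("bad", ["1.2.3", "1.2.3.4.5", "0.1.1.1",
                                     "a.1.1.1", "1.1.1.0", "1.1.1.y"])
    def test_malformed_strings_rejected(self, bad):
        with pytest.raises(CatalogFormatError):
            ECNumber(bad)

    def test_wildcard_matches_within_subsubclass_only(self):
        wild = ECNumber("2.6.1.x")
        assert wild.matches(ECNumber("2.6.1.42"))
        assert wild.matches(ECNumber("2.6.1.1"))
        assert not wild.matches(ECNumber("2.6.2.42"))
        assert not ECNumber("2.6.1.42").matches(ECNumber("2.6.1.1"))


class TestCatalogIO:
    def test_packaged_catalog_covers_all_twenty_amino_acids(self, catalog):
        assert set(catalog.amino_acids) == set(AMINO_ACIDS)

    def test_write_then_parse_round_trips(self, catalog, tmp_path):
        out1 = tmp_path / "cat1.tsv"
        out2 = tmp_path / "cat2.tsv"
        write_catalog(catalog, out1)
        write_catalog(parse_catalog(out1), out2)
        assert out1.read_bytes() == out2.read_bytes()

    def test_malformed_ec_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "variant_id\tamino_acid\tstep_index\tstep_id\tec_options"
            "\tsubstrate\tproduct\tgene_symbols\n"
            "v1\tVal\t1\ts1\t1.2.3\ta\tb\tg1\n"
        )
        with pytest.raises(CatalogFormatError, match="line 2"):
            parse_catalog(path)

    def test_broken_chain_names_variant(self, tmp_path):
        path = tmp_path / "chain.tsv"
        path.write_text(
            "variant_id\tamino_acid\tstep_index\tstep_id\tec_options"
            "\tsubstrate\tproduct\tgene_symbols\n"
            "v1\tVal\t1\ts1\t1.1.1.1\ta\tb\tg1\n"
            "v1\tVal\t2\ts2\t2.2.2.2\tc\td\tg2\n"
        )
        with pytest.raises(CatalogValidationError, match="v1"):
            parse_catalog(path)


def brute_force_variant_complete(ec_subset, variant):
    """Independent oracle: per-step set membership, no shortcuts."""
    missing = []
    for step in variant.steps:
        hit = False
        for opt in step.ec_options:
            for ec in ec_subset:
                if opt.matches(ec):
                    hit = True
        if not hit:
            missing.append(step.step_id)
    return (len(missing) == 0, missing)


class TestVariantComplete:
    def test_superset_annotation_is_complete(self, toy_catalog):
        variant = toy_catalog.variants[1]
        ann = OrganismAnnotation("o", frozenset(
            ec for s in variant.steps for ec in s.ec_options
        ))
        assert variant_complete(ann, variant) == (True, [])

    def test_empty_annotation_misses_every_step(self):
        variant = make_chain_variant(
            "v", "Val", [["1.1.1.1"], ["2.2.2.2"], ["3.3.3.3"], ["4.4.4.4"]]
        )
        ok, missing = variant_complete(OrganismAnnotation("o"), variant)
        assert not ok
        assert missing == ["s0", "s1", "s2", "s3"]

    def test_all_ec_subsets_match_brute_force_oracle(self):
        pool = [ECNumber(f"{i}.{i}.{i}.{i}") for i in range(1, 6)]
        pool += [ECNumber(f"{i}.{i}.{i}.9") for i in range(1, 6)]
        variant = make_chain_variant(
            "v", "Val",
            [["1.1.1.1"], ["2.2.2.2", "2.2.2.9"], ["3.3.3.3"],
             ["4.4.4.4"], ["5.5.5.5", "5.5.5.9"]],
        )
        for bits in itertools.product([0, 1], repeat=len(pool)):
            subset = frozenset(ec for ec, b in zip(pool, bits) if b)
            ann = OrganismAnnotation("o", subset)
            assert variant_complete(ann, variant) == \
                brute_force_variant_complete(subset, variant)


class TestAudit:
    def test_metazoan_like_fixture_misses_exactly_nine_eaa(self, catalog):
        ann = gen_annotations(catalog, "metazoan_like")
        report = audit(ann, catalog)
        assert set(report.incomplete_amino_acids("metazoan_like")) \
            == ESSENTIAL_AMINO_ACIDS

    def test_union_annotation_completes_everything(self, catalog):
        ann = OrganismAnnotation("all", catalog.all_ecs())
        report = audit(ann, catalog)
        assert report.incomplete_amino_acids("all") == []

    def test_status_is_or_over_variants_exhaustively(self, toy_catalog):
        pool = sorted(toy_catalog.all_ecs())
        for bits in itertools.product([0, 1], repeat=len(pool)):
            subset = frozenset(ec for ec, b in zip(pool, bits) if b)
            ann = OrganismAnnotation("o", subset)
            report = audit(ann, toy_catalog)
            for aa in ("Val", "Ala"):
                expected = any(
                    brute_force_variant_complete(subset, v)[0]
                    for v in toy_catalog.variants_for(aa)
                )
                got = report.lookup("o", aa)["status"] == "complete"
                assert got == expected

    def test_amino_acid_without_variant_reported_undefined(self, toy_catalog):
        report = audit(OrganismAnnotation("o"), toy_catalog)
        assert report.lookup("o", "Trp")["status"] == "undefined"

    def test_report_independent_of_input_order(self, catalog):
        anns = [gen_annotations(catalog, p)
                for p in ("cho_like", "metazoan_like", "complete")]
        fwd = audit(anns, catalog).to_frame()
        rev = audit(list(reversed(anns)), catalog).to_frame()
        assert fwd.equals(rev)

    def test_duplicate_organism_ids_rejected(self, catalog):
        ann = gen_annotations(catalog, "complete")
        with pytest.raises(ValueError, match="unique"):
            audit([ann, ann], catalog)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        base=st.sets(st.sampled_from(range(10)), max_size=10),
        extra=st.sets(st.sampled_from(range(10)), max_size=10),
    )
    def test_adding_ecs_never_hurts(self, toy_catalog, base, extra):
        """Monotonicity: a richer annotation never loses completeness
        and never gains missing steps."""
        pool = sorted(toy_catalog.all_ecs()) + [
            ECNumber(f"9.9.9.{i + 1}") for i in range(4)
        ]
        small = frozenset(pool[i] for i in base if i < len(pool))
        big = small | frozenset(pool[i] for i in extra if i < len(pool))
        rep_small = audit(OrganismAnnotation("o", small), toy_catalog)
        rep_big = audit(OrganismAnnotation("o", big), toy_catalog)
        for aa in ("Val", "Ala"):
            row_s = rep_small.lookup("o", aa)
            row_b = rep_big.lookup("o", aa)
            if row_s["status"] == "complete":
                assert row_b["status"] == "complete"
            assert row_b["missing_count"] <= row_s["missing_count"]


class TestMissingSteps:
    def test_cho_like_needs_three_steps_for_valine(self, catalog):
        ann = gen_annotations(catalog, "cho_like")
        steps = missing_steps_for_host(ann, "Val", catalog)
        assert [s.step_id for s in steps] == ["ahas", "kari", "dhad"]

    def test_complete_annotation_needs_nothing(self, catalog):
        ann = gen_annotations(catalog, "complete")
        assert missing_steps_for_host(ann, "Val", catalog) == []

    def test_best_variant_minimizes_missing_count(self, toy_catalog):
        # valA misses 2 of 3 steps, valB misses only 1 of 2
        ann = OrganismAnnotation("o", frozenset({ECNumber("1.1.1.1")}))
        steps = missing_steps_for_host(ann, "Val", toy_catalog)
        assert [s.step_id for s in steps] == ["s1"]
        assert steps[0].ec_options == frozenset({ECNumber("4.4.4.4")})

    def test_minimality_against_brute_force(self, toy_catalog):
        pool = sorted(toy_catalog.all_ecs())
        for bits in itertools.product([0, 1], repeat=len(pool)):
            subset = frozenset(ec for ec, b in zip(pool, bits) if b)
            ann = OrganismAnnotation("o", subset)
            got = len(missing_steps_for_host(ann, "Val", toy_catalog))
            best = min(
                len(brute_force_variant_complete(subset, v)[1])
                for v in toy_catalog.variants_for("Val")
            )
            assert got == best

    def test_undefined_amino_acid_is_lookup_error(self, toy_catalog):
        with pytest.raises(KeyError):
            missing_steps_for_host(OrganismAnnotation("o"), "Trp", toy_catalog)


class TestGeneCount:
    def test_nine_eaa_pathways_exceed_forty_genes(self, catalog):
        assert count_catalog_genes(catalog, ESSENTIAL_AMINO_ACIDS) > 40

    def test_empty_set_counts_zero(self, catalog):
        assert count_catalog_genes(catalog, set()) == 0

    def test_shared_gene_counted_once(self):
        cat = PathwayCatalog(
            (
                make_chain_variant("a", "Val", [["1.1.1.1"]], genes=["g1", "g2"]),
                make_chain_variant("b", "Val", [["2.2.2.2"]], genes=["g2", "g3"]),
            )
        )
        assert count_catalog_genes(cat, {"Val"}) == 3
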