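import pytest
from hypothesis import given, settings, strategies as st

import interoscore as ic
from interoscore.ppi import EvidenceRecord

from conftest import make_interactome, make_ortholog_records

identities = st.lists(
    st.floats(min_value=1.0, max_value=100.0, allow_nan=False), min_size=1, max_size=8
)


class TestOrthoScore:
    @pytest.mark.parametrize(
        "ids,expected",
        [([92, 87, 72], 2.501), ([63], 1.0), ([80, 80], 2.0)],
    )
    def test_worked_examples(self, ids, expected):
        assert round(ic.ortho_score(ids), 3) == expected

    def test_empty_list_is_domain_error(self):
        with pytest.raises(ValueError):
            ic.ortho_score([])

    def test_rounding_modes_differ_as_documented(self):
        # 72/92 truncates to 0.782 at three decimals but floors to 0.780 at
        # half-percent granularity; only the latter reproduces 2.501
        assert round(ic.ortho_score([92, 87, 72], rounding="truncate3"), 3) == 2.505
        assert round(ic.ortho_score([92, 87, 72], rounding="none"), 3) == 2.507
        assert round(ic.ortho_score([92, 87, 72], rounding="half_percent"), 3) == 2.501

    @given(identities, st.floats(min_value=0.1, max_value=1.0))
    @settings(deadline=None)
    def test_scale_invariant(self, ids, factor):
        scaled = [i * factor for i in ids]
        assert ic.ortho_score(scaled) == pytest.approx(ic.ortho_score(ids))

    @given(identities)
    @settings(deadline=None)
    def test_bounds(self, ids):
        score = ic.ortho_score(ids)
        assert 0 < score <= len(ids) + 1e-9
        if len(set(ids)) == 1:
            assert score == pytest.approx(len(ids))
        if score == pytest.approx(len(ids)) and len(ids) > 1:
            # maximum is attained only when every identity ties the maximum
            m = max(ids)
            assert all(i / m > 0.995 for i in ids)


class TestSingleSpeciesScore:
    @pytest.mark.parametrize(
        "a,b,expected", [(1.0, 1.0, 1.0), (2.501, 1.0, 2.501), (2.0, 3.0, 6.0)]
    )
    def test_product(self, a, b, expected):
        assert ic.single_species_score(a, b) == pytest.approx(expected)


class TestSpeciesScore:
    def test_three_one2one_species(self):
        assert ic.species_score([1.0, 1.0, 1.0]) == pytest.approx(3.0)

    def test_mixed_one2many_support(self):
        assert ic.species_score({"cele": 1.0, "hsap": 2.501}) == pytest.approx(3.501)

    def test_known_without_interologues_scores_one(self):
        assert ic.species_score([], home_known=True) == 1.0

    def test_unsupported_prediction_is_domain_error(self):
        with pytest.raises(ValueError):
            ic.species_score([], home_known=False)


class TestExperimentScore:
    def test_bind_only_scores_one(self):
        ev = [EvidenceRecord("protein_protein", "bind:row0", "bind")]
        assert ic.experiment_score(ev) == 1

    def test_same_experiment_two_databases_counted_once(self):
        ev = [
            EvidenceRecord("MI:0018", "E1", "intact"),
            EvidenceRecord("MI:0018", "E1", "dip"),
        ]
        assert ic.experiment_score(ev) == 1

    def test_distinct_records_counted(self):
        ev = [
            EvidenceRecord("MI:0018", "E1", "intact"),
            EvidenceRecord("MI:0018", "E2", "intact"),
            EvidenceRecord("MI:0019", "E3", "dip"),
        ]
        assert ic.experiment_score(ev) == 3
        assert ic.experiment_score(ev, count_types=True) == 2


class TestQualityRatios:
    def test_planted_counts(self):
        # 8 interactions annotated by type A, 2 of them in the reference
        pairs = [(f"A{i}", f"B{i}") for i in range(8)]
        tome = make_interactome("hsap", pairs, etype="MI:0019")
        table = ic.quality_ratios(tome, {("A0", "B0"), ("A5", "B5")})
        assert table.get("MI:0019") == pytest.approx(0.25)
        assert table.annotated["MI:0019"] == 8

    def test_reference_ratio_arithmetic(self):
        table = ic.QualityRatioTable(
            ratios={"MI:0019": 813 / 4324, "MI:0398": 4287 / 5971}
        )
        assert round(table.get("MI:0019"), 3) == 0.188
        assert round(table.get("MI:0398"), 3) == 0.718

    def test_empty_reference_all_zero(self, pipeline):
        table = ic.quality_ratios(pipeline["known"]["hsap"], set())
        assert table.ratios
        assert all(q == 0.0 for q in table.ratios.values())

    def test_superset_invariance(self, pipeline):
        """Adding unannotated edges to the reference changes no ratio."""
        tome = pipeline["known"]["hsap"]
        truth = pipeline["truth"]
        import pandas as pd

        df = pd.read_csv(pipeline["dir"] / "reference_edges.tsv", sep="\t", dtype=str)
        ref = {tuple(x) for x in zip(df.interactor_a, df.interactor_b)}
        base = ic.quality_ratios(tome, ref)
        bigger = ref | {("ZZZ1", "ZZZ2"), ("ZZZ3", "ZZZ4")}
        again = ic.quality_ratios(tome, bigger)
        assert again.ratios == base.ratios
        assert base.ratios == truth.quality_ratios["ratios"]

    def test_round_trip_tsv(self, tmp_path):
        table = ic.QualityRatioTable(
            ratios={"MI:0019": 0.188, "MI:0398": 0.718},
            annotated={"MI:0019": 4324, "MI:0398": 5971},
            in_reference={"MI:0019": 813, "MI:0398": 4287},
        )
        path = tmp_path / "qr.tsv"
        table.to_tsv(path)
        back = ic.QualityRatioTable.from_tsv(path)
        assert back.ratios == pytest.approx(table.ratios)


class TestExperimentQualityScore:
    table = ic.QualityRatioTable(ratios={"MI:0019": 0.188, "MI:0398": 0.718})

    def test_two_types_summed(self):
        assert ic.experiment_quality_score(
            {"MI:0019", "MI:0398"}, self.table
        ) == pytest.approx(0.906)

    def test_empty_types(self):
        assert ic.experiment_quality_score(set(), self.table) == 0.0

    def test_duplicate_type_counted_once(self):
        assert ic.experiment_quality_score(
            ["MI:0019", "MI:0019"], self.table
        ) == pytest.approx(0.188)

    def test_unknown_type_contributes_zero(self):
        assert ic.experiment_quality_score({"MI:9999"}, self.table) == 0.0


class TestInteroScore:
    @pytest.mark.parametrize(
        "ss,es,eqs,expected",
        [(3.0, 2, 0.906, 6.906), (1.0, 1, 0.18, 1.18), (1.0, 1, 0.0, 1.0)],
    )
    def test_formula(self, ss, es, eqs, expected):
        assert ic.intero_score(ss, es, eqs) == pytest.approx(expected)

    @given(
        st.floats(min_value=1, max_value=10),
        st.integers(min_value=1, max_value=20),
        st.floats(min_value=0, max_value=5),
        st.floats(min_value=0, max_value=3),
        st.integers(min_value=0, max_value=3),
        st.floats(min_value=0, max_value=2),
    )
    @settings(deadline=None)
    def test_monotone_in_each_component(self, ss, es, eqs, dss, des, deqs):
        base = ic.intero_score(ss, es, eqs)
        assert ic.intero_score(ss + dss, es, eqs) >= base
        assert ic.intero_score(ss, es + des, eqs) >= base
        assert ic.intero_score(ss, es, eqs + deqs) >= base


def fly_prediction(support_map, target_known=()):
    """Prediction in fly from per-species known pairs; one2one orthologies.

    support_map: species -> list of (gene_a, gene_b, identity_a, identity_b)
    where each (gene_a, gene_b) is a known interacting pair whose partners are
    orthologues of fly FA / FB.
    """
    entries = []
    pairs = {}
    for sp, sups in support_map.items():
        pairs[sp] = []
        for a, b, ida, idb, htype in sups:
            entries.append(("FA", "dmel", a, sp, htype, ida))
            entries.append(("FB", "dmel", b, sp, "one2one", idb))
            pairs[sp].append((a, b))
    ortho = make_ortholog_records(entries)
    known = {sp: make_interactome(sp, p) for sp, p in pairs.items()}
    known["dmel"] = make_interactome("dmel", list(target_known))
    return known, ortho


class TestEndToEndScoring:
    def test_prediction_from_three_one2one_species(self, registry):
        known, ortho = fly_prediction(
            {
                "hsap": [("HA", "HB", 80, 75, "one2one")],
                "cele": [("CA", "CB", 60, 55, "one2one")],
                "scer": [("SA", "SB", 40, 45, "one2one")],
            }
        )
        (pred,) = ic.predict_interologues(known, ortho, "dmel", registry)
        bundle = ic.score_prediction(pred)
        assert bundle.species_score == pytest.approx(3.0)
        assert bundle.experiment_score == 3  # one distinct experiment per species
        assert bundle.intero_score == pytest.approx(9.0)
        assert pred.notation == "HdCS"

    def test_prediction_with_one2many_human_paralogues(self):
        known, ortho = fly_prediction(
            {
                "cele": [("CA", "CB", 60, 55, "one2one")],
                "hsap": [
                    ("HA1", "HB", 92, 75, "one2many"),
                    ("HA2", "HB", 87, 75, "one2many"),
                    ("HA3", "HB", 72, 75, "one2many"),
                ],
            }
        )
        (pred,) = ic.predict_interologues(known, ortho, "dmel")
        bundle = ic.score_prediction(pred)
        assert bundle.single_species_scores["cele"] == pytest.approx(1.0)
        assert bundle.single_species_scores["hsap"] == pytest.approx(2.501, abs=5e-4)
        assert bundle.species_score == pytest.approx(3.501, abs=5e-4)

    def test_known_interaction_without_interologues(self, registry):
        """Home species alone: InteroScore = 1 x N + quality, the 1.xx pattern."""
        known = {"dmel": make_interactome("dmel", [("FA", "FB")], etype="MI:0019")}
        table = ic.QualityRatioTable(ratios={"MI:0019": 0.27})
        bundle = ic.score_known(
            known["dmel"].get(("FA", "FB")), known, ic.OrthologyMap(), table, registry
        )
        assert bundle.species_score == pytest.approx(1.0)
        assert bundle.experiment_score == 1
        assert bundle.intero_score == pytest.approx(1.27)
        assert bundle.notation == "D"

    def test_k_species_zero_quality_scales_with_experiments(self):
        """k one2one supports, distinct experiments, quality 0: score = k x N."""
        known, ortho = fly_prediction(
            {
                "hsap": [("HA", "HB", 80, 75, "one2one")],
                "mmus": [("MA", "MB", 70, 65, "one2one")],
            }
        )
        (pred,) = ic.predict_interologues(known, ortho, "dmel")
        bundle = ic.score_prediction(
            pred, ic.QualityRatioTable(ratios={})
        )
        assert bundle.intero_score == pytest.approx(
            bundle.species_score * bundle.experiment_score
        )
        assert bundle.species_score == pytest.approx(2.0)
        assert bundle.experiment_score == 2

    def test_adding_supporting_species_never_lowers_score(self):
        known1, ortho1 = fly_prediction({"hsap": [("HA", "HB", 80, 75, "one2one")]})
        known2, ortho2 = fly_prediction(
            {
                "hsap": [("HA", "HB", 80, 75, "one2one")],
                "cele": [("CA", "CB", 60, 55, "one2one")],
            }
        )
        (p1,) = ic.predict_interologues(known1, ortho1, "dmel")
        (p2,) = ic.predict_interologues(known2, ortho2, "dmel")
        b1, b2 = ic.score_prediction(p1), ic.score_prediction(p2)
        assert b2.species_score >= b1.species_score
        assert b2.experiment_score >= b1.experiment_score
        assert b2.intero_score >= b1.intero_score
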