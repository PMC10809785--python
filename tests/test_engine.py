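import datetime as dt
import random

import pytest

from survplan import (
    K3,
    UNKNOWN,
    Modification,
    apply_modification,
    derive_facts,
    eval_predicate,
    generate_cohort,
    generate_plan,
    plan_to_dict,
    replay_audit_log,
)
from survplan.engine import FactSet
from survplan.rulebase import iter_leaves, parse_predicate

from conftest import AS_OF, chemo_course, make_patient, rt_course
from kleene_oracle import brute_force_eval, fact_assignments


def atom(fact, op, value, arg=None):
    d = {"fact": fact, "op": op, "value": value}
    if arg:
        d["arg"] = arg
    return parse_predicate(d)


def facts_with(**values):
    fs = FactSet()
    for key, v in values.items():
        fs.set(key, None, v, "recorded")
    return fs


class TestKleeneSemantics:
    def test_comparison_with_known_dose(self):
        p = atom("organ_mean_dose", ">=", 10, arg="breast")
        fs = FactSet()
        fs.set("organ_mean_dose", "breast", 0.4, "recorded")
        assert eval_predicate(p, fs) is K3.FALSE
        fs.set("organ_mean_dose", "breast", 12.0, "recorded")
        assert eval_predicate(p, fs) is K3.TRUE

    def test_comparison_with_unknown_is_unknown(self):
        p = atom("organ_mean_dose", ">=", 10, arg="breast")
        fs = FactSet()
        fs.set("organ_mean_dose", "breast", UNKNOWN, "missing")
        assert eval_predicate(p, fs) is K3.UNKNOWN

    def test_kleene_identities(self):
        assert ~K3.UNKNOWN is K3.UNKNOWN
        assert (K3.TRUE | K3.UNKNOWN) is K3.TRUE
        assert (K3.FALSE & K3.UNKNOWN) is K3.FALSE
        assert (K3.FALSE | K3.UNKNOWN) is K3.UNKNOWN
        assert (K3.TRUE & K3.UNKNOWN) is K3.UNKNOWN

    def test_random_predicates_agree_with_brute_force_oracle(self):
        """Random expression trees with <= 4 leaves, every 3^k fact
        assignment: the recursive evaluator must match the oracle that
        enumerates TRUE/FALSE substitutions of unknown leaves."""
        rng = random.Random(20240)
        leaves_pool = [
            {"fact": "cumulative_dose", "arg": "doxorubicin", "op": ">=", "value": 100},
            {"fact": "cumulative_dose", "arg": "cisplatin", "op": "<=", "value": 100},
            {"fact": "organ_mean_dose", "arg": "heart", "op": ">=", "value": 15},
            {"fact": "field_irradiated", "arg": "cervical", "op": "==", "value": True},
            {"fact": "sex", "op": "==", "value": "female"},
            {"fact": "hsct_received", "op": "!=", "value": False},
            {"fact": "organ_status", "arg": "kidney", "op": "in",
             "value": ["partially_removed", "removed"]},
        ]

        def random_tree(depth):
            if depth == 0 or rng.random() < 0.4:
                return dict(rng.choice(leaves_pool))
            kind = rng.choice(["all", "any", "not"])
            if kind == "not":
                return {"not": random_tree(depth - 1)}
            return {kind: [random_tree(depth - 1) for _ in range(rng.randint(2, 3))]}

        checked = 0
        for _ in range(60):
            tree = parse_predicate(random_tree(2))
            if len(list(iter_leaves(tree))) > 4:
                continue
            for facts in fact_assignments(tree):
                assert eval_predicate(tree, facts) is brute_force_eval(tree, facts)
                checked += 1
        assert checked > 500


class TestDeriveFacts:
    def test_recorded_organ_dose(self):
        p = make_patient(rt_courses=[rt_course(organ_doses=[("breast", 0.4)])])
        facts = derive_facts(p, as_of=AS_OF)
        assert facts.get("organ_mean_dose", "breast") == 0.4
        assert facts.provenance["organ_mean_dose(breast)"] == "recorded"

    def test_missing_dosimetry_gives_unknown_for_exposed_organ(self):
        p = make_patient(rt_courses=[rt_course()])  # no organ doses
        facts = derive_facts(p, as_of=AS_OF)
        assert facts.get("organ_mean_dose", "breast") is UNKNOWN
        assert facts.provenance["organ_mean_dose(breast)"] == "missing"

    def test_unexposed_organ_dose_is_zero(self):
        p = make_patient(rt_courses=[rt_course()])  # supra-diaphragmatic field
        facts = derive_facts(p, as_of=AS_OF)
        assert facts.get("organ_mean_dose", "kidney") == 0.0

    def test_cumulative_dose_sums_across_lines(self):
        p = make_patient(
            chemo_courses=[chemo_course([("doxorubicin", 150)])],
            extra_lines=[{
                "line_number": 2,
                "start_date": "2017-01-01",
                "end_date": "2017-06-01",
                "chemo_courses": [chemo_course([("doxorubicin", 150)],
                                               start="2017-01-01", end="2017-05-01")],
            }],
        )
        facts = derive_facts(p, as_of=AS_OF)
        assert facts.get("cumulative_dose", "doxorubicin") == 300.0

    def test_never_given_agent_defaults_to_zero(self):
        facts = derive_facts(make_patient(), as_of=AS_OF)
        assert facts.get("cumulative_dose", "bleomycin") == 0.0

    def test_unknown_field_code_in_exposure_map(self):
        p = make_patient(rt_courses=[rt_course(fields=("limb",))])
        with pytest.raises(ValueError, match="limb"):
            derive_facts(p, field_exposure_map={"cervical": frozenset({"thyroid"})}, as_of=AS_OF)


class TestGeneratePlan:
    def test_spared_breast_no_surveillance(self, rulebase):
        p = make_patient(rt_courses=[rt_course(organ_doses=[
            ("breast", 0.4), ("heart", 1.0), ("lung", 2.0), ("thyroid", 1.0)])])
        plan = generate_plan(p, rulebase, as_of=AS_OF)
        assert not plan.has_item("breast_imaging")

    def test_missing_dosimetry_degraded_breast_surveillance(self, rulebase):
        p = make_patient(rt_courses=[rt_course()])
        plan = generate_plan(p, rulebase, as_of=AS_OF)
        item = plan.item("breast_imaging")
        assert item.data_quality == "degraded"
        assert "organ_mean_dose(breast)" in item.missing_data_notes

    def test_cervical_rt_precise_thyroid_surveillance(self, rulebase):
        p = make_patient(rt_courses=[rt_course(
            fields=("cervical",), prescribed=30.0,
            organ_doses=[("thyroid", 25.0), ("salivary_glands", 10.0), ("carotid", 20.0)])])
        plan = generate_plan(p, rulebase, as_of=AS_OF)
        assert plan.item("thyroid_palpation_us").data_quality == "precise"

    def test_thyroidectomy_suppresses_thyroid_surveillance(self, rulebase):
        p = make_patient(
            rt_courses=[rt_course(fields=("cervical",), prescribed=30.0,
                                  organ_doses=[("thyroid", 25.0)])],
            follow_up_events=[{
                "date": "2020-06-01",
                "organ_category": "endocrine",
                "event_type": "organ_loss",
                "organ": "thyroid",
            }],
        )
        plan = generate_plan(p, rulebase, as_of=AS_OF)
        assert not plan.has_item("thyroid_palpation_us")
        assert any(s["endpoint_id"] == "thyroid_palpation_us" for s in plan.suppressed)
        # thyroid function monitoring continues after thyroidectomy
        assert plan.has_item("tsh_ft4")

    def test_untreated_patient_gets_empty_plan(self, rulebase):
        plan = generate_plan(make_patient(), rulebase, as_of=AS_OF)
        assert plan.items == []

    def test_shortest_interval_and_strongest_evidence_win(self, rulebase):
        # very high anthracycline dose matches both the P5Y moderate and the
        # P2Y high echocardiography strata; the merged item must be P2Y/high
        p = make_patient(chemo_courses=[chemo_course([("doxorubicin", 300)])])
        plan = generate_plan(p, rulebase, as_of=AS_OF)
        item = plan.item("echocardiography")
        assert str(item.frequency.interval) == "P2Y"
        assert item.evidence_level == "high"

    def test_determinism(self, rulebase):
        p = make_patient(rt_courses=[rt_course()])
        a = plan_to_dict(generate_plan(p, rulebase, as_of=AS_OF))
        b = plan_to_dict(generate_plan(p, rulebase, as_of=AS_OF))
        assert a == b

    def test_suppression_dominance_on_random_patients(self, rulebase):
        """Adding an organ-loss event never adds endpoints targeting that
        organ and always removes them."""
        cohort = generate_cohort("table1", n=40, seed=7)
        for patient in cohort:
            base = generate_plan(patient, rulebase, as_of=AS_OF)
            raw = patient.model_dump(mode="json")
            raw["follow_up_events"].append({
                "date": "2023-12-01",
                "organ_category": "endocrine",
                "event_type": "organ_loss",
                "organ": "thyroid",
            })
            from survplan import validate_patient

            mutated = generate_plan(validate_patient(raw), rulebase, as_of=AS_OF)
            targeted = {
                e.endpoint_id for e in rulebase.endpoints if e.target_organ == "thyroid"
            }
            assert not (targeted & {i.endpoint_id for i in mutated.items})
            # no new endpoints targeting the organ appear
            new_items = {i.endpoint_id for i in mutated.items} - {
                i.endpoint_id for i in base.items
            }
            assert not (new_items & targeted)

    def test_degraded_mode_is_conservative(self, rulebase):
        """Stripping organ dosimetry (keeping fields) only loses endpoints
        whose every matched condition referenced a dose fact, and those
        re-enter as degraded when their predicate can be unknown."""
        cohort = generate_cohort("table1", n=60, seed=11)
        from survplan import validate_patient

        for patient in cohort:
            has_dosimetry = any(
                rt.dosimetry_available
                for d in patient.diagnoses
                for ln in d.treatment_lines
                for rt in ln.rt_courses
            )
            if not has_dosimetry:
                continue
            raw = patient.model_dump(mode="json")
            for diag in raw["diagnoses"]:
                for line in diag["treatment_lines"]:
                    for rt in line["rt_courses"]:
                        rt["organ_doses"] = []
                        rt["dosimetry_available"] = False
            degraded_patient = validate_patient(raw)
            full = generate_plan(patient, rulebase, as_of=AS_OF)
            degraded = generate_plan(degraded_patient, rulebase, as_of=AS_OF)
            lost = {i.endpoint_id for i in full.items} - {
                i.endpoint_id for i in degraded.items
            }
            # dose-threshold-only endpoints may flip, but nothing else
            for endpoint_id in lost:
                item = full.item(endpoint_id)
                endpoint = rulebase.endpoint(endpoint_id)
                matched_ids = {cid for cid, _ in item.matched_conditions}
                for cond in endpoint.conditions:
                    if cond.condition_id in matched_ids:
                        facts = [a.fact for a in iter_leaves(cond.predicate)]
                        assert "organ_mean_dose" in facts


class TestModifications:
    @pytest.fixture()
    def plan(self, rulebase):
        p = make_patient(rt_courses=[rt_course()])
        return generate_plan(p, rulebase, as_of=AS_OF)

    def test_deselect_traces_one_audit_entry(self, plan):
        out = apply_modification(
            plan, Modification(action="deselect", endpoint_id="breast_imaging"), actor="dr_a"
        )
        assert out.item("breast_imaging").status == "removed"
        assert len(out.audit_log) == len(plan.audit_log) + 1
        entry = out.audit_log[-1]
        assert entry.before["status"] == "proposed" and entry.after["status"] == "removed"

    def test_add_endpoint_not_rule_triggered(self, plan):
        from survplan.rulebase import Duration, FrequencySpec

        out = apply_modification(
            plan,
            Modification(
                action="add_endpoint",
                endpoint_id="dermatology_consult",
                frequency=FrequencySpec(interval=Duration.parse("P1Y")),
                label="Dermatology consultation",
            ),
            actor="dr_a",
        )
        item = out.item("dermatology_consult")
        assert item.status == "accepted" and item.cause == "physician_added"

    def test_modify_nonexistent_item_fails(self, plan):
        with pytest.raises(KeyError):
            apply_modification(
                plan, Modification(action="deselect", endpoint_id="nope"), actor="dr_a"
            )

    def test_replay_reproduces_final_plan(self, plan):
        from survplan.rulebase import Duration, FrequencySpec

        ts = dt.datetime(2024, 2, 1, 9, 0)
        p1 = apply_modification(
            plan, Modification(action="deselect", endpoint_id="breast_imaging"),
            actor="dr_a", timestamp=ts)
        p2 = apply_modification(
            p1, Modification(action="modify_frequency", endpoint_id="echocardiography",
                             frequency=FrequencySpec(interval=Duration.parse("P6M"))),
            actor="dr_a", timestamp=ts)
        p3 = apply_modification(
            p2, Modification(action="accept", endpoint_id="tsh_ft4"),
            actor="dr_b", timestamp=ts)
        replayed = replay_audit_log(plan, p3.audit_log)
        assert plan_to_dict(replayed) == plan_to_dict(p3)

    def test_original_plan_not_mutated(self, plan):
        before = plan_to_dict(plan)
        apply_modification(
            plan, Modification(action="deselect", endpoint_id="breast_imaging"), actor="x"
        )
        assert plan_to_dict(plan) == before
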