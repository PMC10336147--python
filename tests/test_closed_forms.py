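"""Exact closed-form derivation and the errata audit.

Expected values were frozen from an independent symbolic computation
(summing frequency x contribution over the partition tables with exact
rationals/surds/logs) and cross-checked against the reported coefficients.
"""

import math

import pytest
import sympy as sp

from nanoirr import (
    INDEX_ORDER,
    build_nanotube,
    derive_all,
    derive_closed_form,
    errata_report,
    evaluate_all,
    evaluate_index,
    symbolic_partition,
)

# (family, index) -> exact p-coefficient (closed form from the published
# partitions; frozen from the independent oracle)
EXACT = {
    ("HAC5C7", "AL"): sp.Integer(10),
    ("HAC5C7", "IRRT"): sp.Integer(5),
    ("HAC5C7", "IRF"): sp.Integer(16),
    ("HAC5C7", "IRL"): sp.log(sp.Rational(63, 16)),
    ("HAC5C7", "IRDIF"): sp.Rational(697, 252),
    ("HAC5C7", "LA"): sp.Rational(8443, 6188),
    ("HAC5C7", "IRDI"): sp.log(432),
    ("HAC5C6C7", "AL"): sp.Integer(18),
    ("HAC5C6C7", "IRRT"): sp.Integer(9),
    ("HAC5C6C7", "IRF"): sp.Integer(26),
    ("HAC5C6C7", "IRL"): sp.log(sp.Rational(49, 4)),
    ("HAC5C6C7", "IRDIF"): sp.Rational(1273, 252),
    ("HAC5C6C7", "LA"): sp.Rational(57908, 23205),
    ("HAC5C6C7", "IRDI"): 10 * sp.log(2) + 4 * sp.log(3),
}

# floats frozen from the same oracle (30-digit evaluation, rounded here)
FLOATS = {
    ("HAC5C7", "IRA"): 0.0106269234,
    ("HAC5C7", "IRLF"): 1.3736355448,
    ("HAC5C7", "IRGA"): 0.0378944092,
    ("HAC5C7", "IRB"): 0.5485909219,
    ("HAC5C6C7", "IRA"): 0.0184617714,
    ("HAC5C6C7", "IRLF"): 2.5105797009,
    ("HAC5C6C7", "IRGA"): 0.0644948117,
    ("HAC5C6C7", "IRB"): 0.9129384824,
}


class TestDeriveClosedForm:
    @pytest.mark.parametrize("family", ["HAC5C7", "HAC5C6C7"])
    def test_pq_coefficient_vanishes(self, family):
        # the bulk (9,9) class carries all the pq dependence and every
        # irregularity contribution vanishes on equal weights
        for cf in derive_all(family):
            assert cf.pq_exact == 0
            assert cf.pq_coefficient == 0.0

    @pytest.mark.parametrize("key", sorted(EXACT), ids="-".join)
    def test_exact_coefficients(self, key):
        family, index = key
        cf = derive_closed_form(symbolic_partition(family), index)
        assert sp.simplify(cf.p_exact - EXACT[key]) == 0

    @pytest.mark.parametrize("key", sorted(FLOATS), ids="-".join)
    def test_float_coefficients(self, key):
        family, index = key
        cf = derive_closed_form(symbolic_partition(family), index)
        assert cf.p_coefficient == pytest.approx(FLOATS[key], abs=1e-9)

    @pytest.mark.parametrize("family", ["HAC5C7", "HAC5C6C7"])
    @pytest.mark.parametrize("variant", ["published", "realized"])
    @pytest.mark.parametrize("pq", [(1, 2), (2, 2), (3, 4)])
    def test_closed_form_equals_instantiated_partition(self, family, variant, pq):
        p, q = pq
        part = symbolic_partition(family, variant)
        inst = part.instantiate(p, q)
        for name in INDEX_ORDER:
            cf = derive_closed_form(part, name)
            assert cf.value(p, q) == pytest.approx(
                evaluate_index(inst, name).value, abs=1e-10
            )

    @pytest.mark.parametrize("family", ["HAC5C7", "HAC5C6C7"])
    def test_generated_graph_matches_realized_closed_form(self, family):
        # value = p_coefficient * p, constant in q, to 1e-9
        forms = {
            cf.index: cf for cf in derive_all(family, "realized")
        }
        for p, q in [(2, 2), (3, 2), (4, 3), (5, 2), (6, 2)]:
            g = build_nanotube(family, p, q)
            for iv in evaluate_all(g):
                assert iv.value == pytest.approx(
                    forms[iv.name].p_coefficient * p, abs=1e-9
                ), (family, p, q, iv.name)

    def test_partition_edge_totals(self):
        assert symbolic_partition("HAC5C7").edge_total(3, 4) == 12 * 12 - 3
        assert symbolic_partition("HAC5C6C7").edge_total(3, 4) == 12 * 12 + 21

    def test_instantiate_validates_parameters(self):
        with pytest.raises(ValueError, match="positive"):
            symbolic_partition("HAC5C7").instantiate(0, 2)

    def test_unknown_family_and_variant(self):
        with pytest.raises(ValueError, match="family"):
            symbolic_partition("HAC4C8")
        with pytest.raises(ValueError, match="variant"):
            symbolic_partition("HAC5C7", "imagined")


class TestErrataAudit:
    def test_hac5c7_flags_exactly_irga(self):
        report = errata_report("HAC5C7")
        verdicts = {e.index: e.verdict for e in report}
        assert [i for i, v in verdicts.items() if v == "erratum"] == ["IRGA"]
        assert all(v == "match" for i, v in verdicts.items() if i != "IRGA")
        irga = next(e for e in report if e.index == "IRGA")
        assert irga.computed == pytest.approx(0.0378944, abs=1e-6)
        assert irga.reported == pytest.approx(1.26918503)

    def test_hac5c6c7_flags_irdi_and_irl_conflict(self):
        report = errata_report("HAC5C6C7")
        verdicts = {e.index: e.verdict for e in report}
        assert [i for i, v in verdicts.items() if v == "erratum"] == ["IRDI"]
        assert verdicts["IRL"] == "statement_conflict"
        irdi = next(e for e in report if e.index == "IRDI")
        # the reported derivation stops one term short of 10 ln 2 + 4 ln 3
        assert irdi.computed == pytest.approx(10 * math.log(2) + 4 * math.log(3))
        irl = next(e for e in report if e.index == "IRL")
        assert irl.reported == 9.0
        assert irl.computed == pytest.approx(irl.reported_derivation, abs=1e-6)

    def test_match_counts(self):
        entries = errata_report("HAC5C7") + errata_report("HAC5C6C7")
        assert len(entries) == 22
        counts = {}
        for e in entries:
            counts[e.verdict] = counts.get(e.verdict, 0) + 1
        assert counts == {"match": 19, "erratum": 2, "statement_conflict": 1}

    def test_matches_are_tight(self):
        # genuine agreement is at the 1e-6..1e-4 level, far inside tolerance
        for e in errata_report("HAC5C7") + errata_report("HAC5C6C7"):
            if e.verdict == "match":
                assert e.discrepancy <= 1e-4
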