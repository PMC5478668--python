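"""Conversion percentages, chained assays, and the normalisation ratio."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fadskit.quant import (
    ND,
    AssayRecord,
    ConversionResult,
    PeakTable,
    UndefinedConversionError,
    UndefinedRatioError,
    build_activity_table,
    chain_conversions,
    conversion_percent,
    normalized_ratio,
    read_input_tsv,
    report_to_tsv,
    round_half_up,
)


class TestConversionPercent:
    @pytest.mark.parametrize(
        "s,p,expected", [(50, 50, 50.0), (657, 343, 34.3), (100, 0, 0.0)]
    )
    def test_examples(self, s, p, expected):
        assert conversion_percent(s, p) == pytest.approx(expected)

    def test_zero_zero_is_an_error_not_nd(self):
        with pytest.raises(UndefinedConversionError):
            conversion_percent(0, 0)

    @given(
        s=st.floats(0, 1e9),
        p=st.floats(0, 1e9),
        c=st.floats(1e-6, 1e6),
    )
    @settings(max_examples=300, derandomize=True)
    def test_scale_invariance_and_range(self, s, p, c):
        if s + p == 0:
            return
        v = conversion_percent(s, p)
        assert 0.0 <= v <= 100.0
        if (s * c) + (p * c) > 0:
            assert conversion_percent(s * c, p * c) == pytest.approx(v, rel=1e-9)


class TestChainConversions:
    def test_two_step_hand_computed(self, c24_route, fa):
        # a step's product term includes its downstream derivatives:
        # elongation moved 300 of 1000 onward, Δ6 then took 100 of that 300
        table = PeakTable(
            "a1", {"22:5n-3": 700, "24:5n-3": 200, "24:6n-3": 100}, fa("22:5n-3")
        )
        results = chain_conversions(table, c24_route)
        assert [(r.activity, r.percent) for r in results] == [
            ("elongation", pytest.approx(30.0)),
            ("Δ6", pytest.approx(100 / 3)),
        ]

    def test_no_products_yields_single_nd(self, c24_route, fa):
        table = PeakTable("a2", {"22:5n-3": 1000}, fa("22:5n-3"))
        results = chain_conversions(table, c24_route)
        assert len(results) == 1
        assert results[0].activity == "elongation"
        assert results[0].percent is ND

    def test_full_graph_adds_nd_for_untaken_direct_route(self, graph, fa):
        # on the full network the Δ4 edge out of 22:5n-3 is also reported (ND)
        table = PeakTable(
            "a3", {"22:5n-3": 700, "24:5n-3": 200, "24:6n-3": 100}, fa("22:5n-3")
        )
        results = {
            (r.substrate.label, r.product.label): r.percent
            for r in chain_conversions(table, graph)
        }
        assert results[("22:5n-3", "22:6n-3")] is ND
        assert results[("22:5n-3", "24:5n-3")] == pytest.approx(30.0)

    def test_each_edge_emitted_at_most_once(self, graph, fa):
        table = PeakTable(
            "a4",
            {"18:3n-3": 100, "18:4n-3": 50, "20:3n-3": 20, "20:4n-3": 30,
             "20:5n-3": 10},
            fa("18:3n-3"),
        )
        results = chain_conversions(table, graph)
        edges = [(r.substrate.label, r.product.label) for r in results]
        assert len(edges) == len(set(edges))

    def test_detection_floor_marks_nd(self, c24_route, fa):
        table = PeakTable(
            "a5", {"22:5n-3": 1000, "24:5n-3": 4}, fa("22:5n-3"),
            detection_floor=5.0,
        )
        (res,) = chain_conversions(table, c24_route)
        assert res.percent is ND

    def test_substrate_absent_from_graph(self, c24_route, fa):
        table = PeakTable("a6", {"18:3n-3": 10}, fa("18:3n-3"))
        with pytest.raises(ValueError, match="absent"):
            chain_conversions(table, c24_route)


class TestNormalizedRatio:
    @pytest.mark.parametrize(
        "num,den,expected",
        [(34.3, 41.9, 0.82), (6.4, 3.4, 1.88), (ND, 9.9, 0.00)],
    )
    def test_printed_examples(self, num, den, expected):
        assert normalized_ratio(num, den) == expected

    def test_half_up_rounding(self):
        assert normalized_ratio(1.25, 100.0) == 0.01
        assert round_half_up(0.825, 2) == 0.83
        assert round_half_up(0.815, 2) == 0.82

    @pytest.mark.parametrize("den", [ND, 0.0])
    def test_undefined_denominator(self, den):
        with pytest.raises(UndefinedRatioError):
            normalized_ratio(10.0, den)


class TestActivityTable:
    def _record(self, rid, num=10.0, den=10.0, fa_=None):
        from fadskit.fa import parse_fa_shorthand
        return AssayRecord(
            desaturase_id=rid,
            conv_24_4n6=5.0,
            conv_24_5n3=num,
            control_substrate=parse_fa_shorthand("18:3n-3"),
            control_product=parse_fa_shorthand("18:4n-3"),
            conv_control=den,
        )

    def test_identity_ratio(self):
        (rep,) = build_activity_table([self._record("x", 12.3, 12.3)])
        assert rep.ratio == 1.00

    def test_empty(self):
        assert build_activity_table([]) == []

    def test_duplicate_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_activity_table([self._record("x"), self._record("x")])

    def test_order_preserved_and_tsv_formats(self):
        reps = build_activity_table(
            [self._record("b", 6.4, 3.4), self._record("a", ND, 9.9)]
        )
        assert [r.desaturase_id for r in reps] == ["b", "a"]
        tsv = report_to_tsv(reps)
        lines = tsv.splitlines()
        assert lines[1].split("\t")[-1] == "1.88"
        assert lines[2].split("\t")[1:3] == ["5.0", "ND"]


class TestInputTsv:
    def test_wide_dialect(self, tmp_path):
        p = tmp_path / "wide.tsv"
        p.write_text(
            "desaturase_id\tconv_24_4n6\tconv_24_5n3\tcontrol_label\t"
            "control_product\tconv_control\n"
            "X1\t1.0\tND\t18:3n-3\t18:4n-3\t9.9\n"
        )
        (rec,) = read_input_tsv(p)
        assert isinstance(rec, AssayRecord)
        assert rec.conv_24_5n3 is ND
        assert rec.control_substrate.label == "18:3n-3"

    def test_long_dialect(self, tmp_path):
        p = tmp_path / "long.tsv"
        p.write_text(
            "assay_id\tdesaturase_id\tfa_label\tpeak_area\n"
            "a1\td1\t22:5n-3\t700\n"
            "a1\td1\t24:5n-3\t200\n"
            "a1\td1\t24:6n-3\t100\n"
        )
        (table,) = read_input_tsv(p)
        assert isinstance(table, PeakTable)
        assert table.exogenous_substrate.label == "22:5n-3"
        assert table.areas["24:6n-3"] == 100.0

    def test_unrecognized_header(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("foo\tbar\n1\t2\n")
        with pytest.raises(ValueError, match="dialect"):
            read_input_tsv(p)


def test_conversion_result_checks_activity(fa):
    with pytest.raises(ValueError, match="inconsistent"):
        ConversionResult(fa("18:3n-3"), fa("18:4n-3"), "Δ5", 10.0)
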