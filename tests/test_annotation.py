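import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quantdea.annotation import (
    AnnotationError,
    ContrastError,
    ContrastSet,
    compile_contrasts,
    contrasts_from_control,
    make_annotation_template,
    match_sample_ids,
    parse_annotation,
    parse_contrast_expression,
    sanitize_group_levels,
)

from .conftest import make_annotation

# the worked two-factor example: tumor (T) vs normal-adjacent tissue (NAT)
# crossed with age, merged into a single Group factor, subject as block
CCRCC_ROWS = [
    ("CPTAC_C3L-00004_NAT", "NAT_Old_4", "NAT_Old", "4"),
    ("CPTAC_C3L-00004_T", "T_Old_4", "T_Old", "4"),
    ("CPTAC_C3L-00010_NAT", "NAT_Young_10", "NAT_Young", "10"),
    ("CPTAC_C3L-00010_T", "T_Young_10", "T_Young", "10"),
    ("CPTAC_C3L-00011_NAT", "NAT_Old_11", "NAT_Old", "11"),
    ("CPTAC_C3L-00011_T", "T_Old_11", "T_Old", "11"),
    ("CPTAC_C3L-00026_NAT", "NAT_Old_26", "NAT_Old", "26"),
    ("CPTAC_C3L-00026_T", "T_Old_26", "T_Old", "26"),
    ("CPTAC_C3L-00079_NAT", "NAT_Young_79", "NAT_Young", "79"),
]

FOUR_GROUPS = ["NAT_Old", "T_Old", "NAT_Young", "T_Young"]


@pytest.fixture
def ccrcc_tsv(tmp_path):
    df = pd.DataFrame(CCRCC_ROWS, columns=["raw.file", "Name", "Group", "Subject"])
    df["control"] = ""
    df.loc[df["Group"].str.startswith("NAT"), "control"] = "C"
    path = tmp_path / "annotation.tsv"
    df.to_csv(path, sep="\t", index=False)
    return path


class TestParseAnnotation:
    def test_case_insensitive_aliases(self, tmp_path):
        df = pd.DataFrame(
            {"Raw.File": ["a", "b"], "Name": ["x", "y"], "GROUP": ["g1", "g2"],
             "Subject": ["1", "2"], "control": ["C", ""]}
        )
        path = tmp_path / "ann.tsv"
        df.to_csv(path, sep="\t", index=False)
        ann = parse_annotation(path)
        assert ann.sample_ids == ["a", "b"]
        assert ann.groups == ["g1", "g2"]
        assert ann.has_subject and ann.has_control

    def test_nine_sample_two_factor_design(self, ccrcc_tsv):
        ann = parse_annotation(ccrcc_tsv)
        assert len(ann.sample_ids) == 9
        assert set(ann.groups) == set(FOUR_GROUPS)
        assert set(ann.table["subject"]) == {"4", "10", "11", "26", "79"}

    def test_xlsx_round_trip(self, tmp_path):
        df = pd.DataFrame(CCRCC_ROWS, columns=["raw.file", "name", "group", "subject"])
        df["control"] = np.where(df["group"].str.startswith("NAT"), "C", "")
        path = tmp_path / "ann.xlsx"
        df.to_excel(path, index=False)
        ann = parse_annotation(path)
        assert len(ann.sample_ids) == 9

    def test_duplicate_sample_id_fatal(self, tmp_path):
        df = pd.DataFrame({"raw.file": ["a", "a"], "group": ["g1", "g2"],
                           "control": ["C", ""]})
        path = tmp_path / "ann.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(AnnotationError, match="duplicate"):
            parse_annotation(path)

    def test_mixed_design_modes_fatal(self, tmp_path):
        df = pd.DataFrame(
            {"raw.file": ["a", "b"], "group": ["g1", "g2"], "control": ["C", ""],
             "ContrastName": ["d", ""], "Contrast": ["G_g1 - G_g2", ""]}
        )
        path = tmp_path / "ann.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(AnnotationError, match="design modes"):
            parse_annotation(path)

    def test_no_design_fatal_with_guidance(self, tmp_path):
        df = pd.DataFrame({"raw.file": ["a"], "group": ["g1"]})
        path = tmp_path / "ann.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(AnnotationError, match="control"):
            parse_annotation(path)

    def test_values_whitespace_trimmed(self, tmp_path):
        df = pd.DataFrame({"raw.file": [" a "], "group": [" g1 "], "control": ["C"]})
        path = tmp_path / "ann.tsv"
        df.to_csv(path, sep="\t", index=False)
        ann = parse_annotation(path)
        assert ann.sample_ids == ["a"] and ann.groups == ["g1"]


class TestTemplate:
    def test_ids_preserved_verbatim(self, tmp_path):
        out = make_annotation_template(["a.raw", "b.raw"], tmp_path / "t.tsv", tsv=True)
        df = pd.read_csv(out, sep="\t")
        assert list(df["raw.file"]) == ["a.raw", "b.raw"]
        assert {"name", "group", "subject", "control"} <= set(df.columns)

    def test_empty_id_list_header_only(self, tmp_path):
        out = make_annotation_template([], tmp_path / "t.tsv", tsv=True)
        df = pd.read_csv(out, sep="\t")
        assert len(df) == 0

    def test_xlsx_default(self, tmp_path):
        out = make_annotation_template(["a.raw"], tmp_path / "t.xlsx")
        assert pd.read_excel(out)["raw.file"].tolist() == ["a.raw"]


class TestSanitize:
    def test_prefix_and_replacement(self):
        m = sanitize_group_levels(["T_Old", "dose 5%"])
        assert m["T_Old"] == "G_T_Old"
        assert m["dose 5%"] == "G_dose_5_"

    def test_collision_fatal(self):
        with pytest.raises(ContrastError, match="sanitize"):
            sanitize_group_levels(["a b", "a-b"])


class TestControlContrasts:
    def test_all_groups_vs_control(self):
        ann = make_annotation({"A": ["s1"], "B": ["s2"], "C": ["s3"]}, control="C")
        cs = contrasts_from_control(ann)
        assert cs.names() == ["A_vs_C", "B_vs_C"]
        a = cs.get("A_vs_C").coefficients
        assert a == {"A": 1.0, "B": 0.0, "C": -1.0}

    def test_single_treatment_group(self):
        ann = make_annotation({"A": ["s1"], "B": ["s2"]}, control="B")
        assert len(contrasts_from_control(ann)) == 1

    def test_control_in_two_groups_fatal(self):
        ann = make_annotation({"A": ["s1"], "B": ["s2"]})
        ann.table["control"] = ["C", "C"]
        with pytest.raises(ContrastError, match="multiple groups"):
            contrasts_from_control(ann)

    def test_coefficients_sum_to_zero_with_one_plus_minus(self):
        ann = make_annotation({g: [f"s{g}"] for g in "ABCDE"}, control="E")
        for c in contrasts_from_control(ann):
            vals = sorted(c.coefficients.values())
            assert sum(vals) == 0
            assert vals.count(1.0) == 1 and vals.count(-1.0) == 1


class TestContrastExpressions:
    def test_average_difference_expression(self):
        vec = parse_contrast_expression(
            "T_vs_NAT",
            "(G_T_Old + G_T_Young)/2 - (G_NAT_Old + G_NAT_Young)/2",
            None, FOUR_GROUPS,
        )
        assert vec.coefficients == {
            "T_Old": 0.5, "T_Young": 0.5, "NAT_Old": -0.5, "NAT_Young": -0.5,
        }

    def test_contrast_of_contrasts_expands(self):
        within_old = parse_contrast_expression(
            "T_vs_NAT_gv_Old", "G_T_Old - G_NAT_Old", None, FOUR_GROUPS)
        within_young = parse_contrast_expression(
            "T_vs_NAT_gv_Young", "G_T_Young - G_NAT_Young", None, FOUR_GROUPS)
        known = ContrastSet([within_old, within_young])
        inter = parse_contrast_expression(
            "DoesTvsNatDependsOnAge", "T_vs_NAT_gv_Old - T_vs_NAT_gv_Young",
            known, FOUR_GROUPS)
        assert inter.coefficients == {
            "T_Old": 1.0, "NAT_Old": -1.0, "T_Young": -1.0, "NAT_Young": 1.0,
        }

    def test_unreferenced_groups_get_zero(self):
        vec = parse_contrast_expression("d", "G_A - G_B", None, ["A", "B", "C"])
        assert vec.coefficients == {"A": 1.0, "B": -1.0, "C": 0.0}

    def test_unknown_identifier_fatal_and_lists_known(self):
        with pytest.raises(ContrastError, match="G_A"):
            parse_contrast_expression("d", "G_A - G_X", None, ["A", "B"])

    def test_nonlinear_product_fatal(self):
        with pytest.raises(ContrastError, match="nonlinear|linear"):
            parse_contrast_expression("d", "G_A * G_B", None, ["A", "B"])

    def test_division_by_group_fatal(self):
        with pytest.raises(ContrastError, match="linear"):
            parse_contrast_expression("d", "G_A / G_B", None, ["A", "B"])

    def test_forward_reference_rejected(self):
        ann = make_annotation(
            {"A": ["s1"], "B": ["s2"]},
            contrast_rows=[("later_ref", "first - G_B"), ("first", "G_A - G_B")],
        )
        with pytest.raises(ContrastError, match="unknown identifier"):
            compile_contrasts(ann)

    def test_evaluating_on_indicator_returns_coefficient(self):
        vec = parse_contrast_expression(
            "T_vs_NAT",
            "(G_T_Old + G_T_Young)/2 - (G_NAT_Old + G_NAT_Young)/2",
            None, FOUR_GROUPS,
        )
        for g in FOUR_GROUPS:
            indicator = {lvl: float(lvl == g) for lvl in FOUR_GROUPS}
            value = sum(vec.coefficients[lvl] * indicator[lvl] for lvl in FOUR_GROUPS)
            assert value == vec.coefficients[g]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        a=st.integers(-3, 3), b=st.integers(-3, 3),
        data=st.data(),
    )
    def test_linearity_of_parser(self, a, b, data):
        """parse(a*e1 + b*e2) == a*parse(e1) + b*parse(e2)."""
        groups = ["A", "B", "C"]
        e1 = data.draw(_expr_strategy(groups))
        e2 = data.draw(_expr_strategy(groups))
        combined = f"{a}*({e1}) + {b}*({e2})"
        try:
            v1 = parse_contrast_expression("e1", e1, None, groups).coefficients
            v2 = parse_contrast_expression("e2", e2, None, groups).coefficients
            vc = parse_contrast_expression("c", combined, None, groups).coefficients
        except ContrastError:
            # the linear combination may legitimately collapse to all-zero
            return
        for g in groups:
            assert vc[g] == pytest.approx(a * v1[g] + b * v2[g], abs=1e-12)


def _expr_strategy(groups):
    atoms = st.sampled_from([f"G_{g}" for g in groups])
    return st.recursive(
        atoms,
        lambda child: st.builds(
            lambda x, y, op: f"({x} {op} {y})",
            child, child, st.sampled_from(["+", "-"]),
        ) | st.builds(
            lambda x, k: f"({x} / {k})",
            child, st.integers(1, 4),
        ) | st.builds(
            lambda x, k: f"({k} * {x})",
            child, st.integers(-3, 3),
        ),
        max_leaves=6,
    )


class TestCompileContrasts:
    def test_control_mode(self):
        ann = make_annotation({"A": ["s1"], "B": ["s2"]}, control="A")
        assert compile_contrasts(ann).names() == ["B_vs_A"]

    def test_explicit_mode_order_dependent(self):
        ann = make_annotation(
            {"A": ["s1"], "B": ["s2"], "C": ["s3"]},
            contrast_rows=[("ab", "G_A - G_B"), ("ab_vs_c", "ab - G_C")],
        )
        cs = compile_contrasts(ann)
        assert cs.get("ab_vs_c").coefficients == {"A": 1.0, "B": -1.0, "C": -1.0}


class TestMatchSampleIds:
    def test_exact_match_preferred(self):
        m = match_sample_ids(["run1", "run2"], ["run1", "run2", "run1.raw"])
        assert m == {"run1": "run1", "run2": "run2"}

    def test_normalized_match_strips_path_and_extension(self):
        m = match_sample_ids(["run1"], ["/data/run1.raw"])
        assert m == {"run1": "/data/run1.raw"}

    def test_ambiguous_normalized_match_fatal(self):
        with pytest.raises(AnnotationError, match="ambiguous"):
            match_sample_ids(["a"], ["x/a.raw", "y/a.raw"])

    def test_unmatched_annotation_ids_fatal(self):
        with pytest.raises(AnnotationError, match="zzz"):
            match_sample_ids(["zzz"], ["a.raw"])
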