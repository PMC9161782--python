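"""Gating engine vs an independent brute-force rule evaluator; spatial gates."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

from mihckit.fixtures import MARKER_PANEL, default_archetypes, synth_cell_table
from mihckit.gating import (
    GatingTree,
    apply_gating_tree,
    biaxial_pair_count,
    default_gating_tree,
    spatial_gate,
    summarize_density_proportion,
)


def oracle_label(sign: dict[str, bool]) -> str:
    """Independent hand-written evaluation of the lineage hierarchy.

    Mirrors the marker combinations of the manual gating table as literal
    nested conditionals, written without reference to the engine.
    """
    if not sign["CD45"]:
        return "Non-immune cells"
    if sign["CD3"]:
        if sign["CD8"]:
            if sign["KI67"]:
                return "Proliferating CD8 T cells"
            return "CD8+ T cells"
        if sign["FOXP3"]:
            if sign["KI67"]:
                return "Proliferating T reg cells"
            return "T regulatory cells"
        return "Other Th cells"
    if sign["CD20"]:
        return "B cells"
    if sign["CD1C"]:
        return "CD1C+ myeloid dendritic cells"
    if sign["CD68"]:
        if sign["CSF1R"]:
            if sign["CD163"]:
                return "CD163+ myelomonocytic cells"
            return "CD163- myelomonocytic cells"
        return "Monocytes, macrophages, fibrocytes"
    return "Other immune cells"


def _cells_from_signs(signs: list[dict[str, bool]], tree: GatingTree) -> pd.DataFrame:
    rows = []
    for s in signs:
        rows.append(
            {
                m: (tree.thresholds[m] + 0.1 if s[m] else tree.thresholds[m] - 0.05)
                for m in MARKER_PANEL
            }
        )
    df = pd.DataFrame(rows)
    df.insert(0, "cell_id", np.arange(len(df)))
    df.insert(1, "roi_id", "R")
    return df


class TestGatingTree:
    def test_treg_combination(self):
        tree = default_gating_tree()
        sign = {m: False for m in MARKER_PANEL}
        sign.update({"CD45": True, "CD3": True, "FOXP3": True})
        cells = _cells_from_signs([sign], tree)
        assert apply_gating_tree(cells, tree).iloc[0] == "T regulatory cells"

    def test_cd163_myelomonocytic_combination(self):
        tree = default_gating_tree()
        sign = {m: False for m in MARKER_PANEL}
        sign.update({"CD45": True, "CD68": True, "CSF1R": True, "CD163": True})
        cells = _cells_from_signs([sign], tree)
        assert apply_gating_tree(cells, tree).iloc[0] == "CD163+ myelomonocytic cells"

    def test_cd45_negative_is_catch_all(self):
        tree = default_gating_tree()
        sign = {m: True for m in MARKER_PANEL}
        sign["CD45"] = False
        cells = _cells_from_signs([sign], tree)
        assert apply_gating_tree(cells, tree).iloc[0] == "Non-immune cells"

    def test_all_1024_sign_vectors_match_brute_force_oracle(self):
        tree = default_gating_tree()
        signs = [
            dict(zip(MARKER_PANEL, bits))
            for bits in product([False, True], repeat=len(MARKER_PANEL))
        ]
        cells = _cells_from_signs(signs, tree)
        got = apply_gating_tree(cells, tree)
        expected = [oracle_label(s) for s in signs]
        assert list(got) == expected

    def test_every_cell_gets_exactly_one_label(self, archetypes):
        tree = default_gating_tree()
        table = synth_cell_table(
            archetypes, {a.label: 50 for a in archetypes}, noise_seed=9
        )
        labels = apply_gating_tree(table, tree)
        assert labels.notna().all()
        assert labels.value_counts().sum() == len(table)

    def test_strict_positivity_at_cd45_threshold(self):
        tree = default_gating_tree()  # CD45 threshold 0.07
        cells = pd.DataFrame(
            {m: [0.0, 0.0, 0.0] for m in MARKER_PANEL} | {
                "CD45": [0.08, 0.07, 0.06]
            }
        )
        labels = apply_gating_tree(cells, tree)
        assert list(labels) == [
            "Other immune cells", "Non-immune cells", "Non-immune cells",
        ]

    def test_unknown_marker_in_rule_rejected(self):
        with pytest.raises(ValueError, match="no threshold"):
            GatingTree(
                rules=[("X", {"NOPE": "+"}), ("rest", {})],
                thresholds={m: 0.2 for m in MARKER_PANEL},
            )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        marker=st.sampled_from(["CD3", "CD8", "FOXP3"]),
        delta=st.floats(min_value=0.01, max_value=0.5),
        seed=st.integers(min_value=0, max_value=50),
    )
    def test_threshold_monotonicity(self, marker, delta, seed):
        # raising a marker's threshold never increases the count of any
        # phenotype whose rule requires that marker positive
        tree = default_gating_tree()
        table = synth_cell_table(
            default_archetypes(), {a.label: 40 for a in default_archetypes()},
            noise_seed=seed,
        )
        base = apply_gating_tree(table, tree).value_counts()
        raised = GatingTree(
            rules=tree.rules,
            thresholds={**tree.thresholds, marker: tree.thresholds[marker] + delta},
            groups=tree.groups,
        )
        after = apply_gating_tree(table, raised).value_counts()
        for label, rule in tree.rules:
            if rule.get(marker) == "+":
                assert after.get(label, 0) <= base.get(label, 0)


class TestSpatialGate:
    def test_containment_margin_and_exclusion(self):
        region = box(0, 0, 100, 100)
        cells = pd.DataFrame(
            {
                "cell_id": [1, 2, 3],
                "roi_id": "R",
                "x_um": [50.0, 250.0, 350.0],  # inside; 150 out; 250 out
                "y_um": [50.0, 50.0, 50.0],
            }
        )
        kept = spatial_gate(cells, region, margin_um=200)
        assert set(kept.cell_id) == {1, 2}

    def test_zero_margin_is_pure_containment(self):
        region = box(0, 0, 100, 100)
        cells = pd.DataFrame(
            {"cell_id": [1, 2], "roi_id": "R",
             "x_um": [50.0, 103.0], "y_um": [50.0, 50.0]}
        )
        kept = spatial_gate(cells, region, margin_um=0)
        assert set(kept.cell_id) == {1}

    def test_monotone_in_margin(self):
        rng = np.random.default_rng(5)
        region = box(100, 100, 200, 200)
        cells = pd.DataFrame(
            {
                "cell_id": np.arange(200),
                "roi_id": "R",
                "x_um": rng.uniform(0, 400, 200),
                "y_um": rng.uniform(0, 400, 200),
            }
        )
        kept_small = set(spatial_gate(cells, region, margin_um=50).cell_id)
        kept_big = set(spatial_gate(cells, region, margin_um=150).cell_id)
        assert kept_small <= kept_big

    def test_empty_region_rejected(self):
        from shapely.geometry import Polygon

        cells = pd.DataFrame({"cell_id": [1], "roi_id": "R",
                              "x_um": [1.0], "y_um": [1.0]})
        with pytest.raises(ValueError, match="empty region"):
            spatial_gate(cells, Polygon(), margin_um=10)


class TestSummaries:
    def test_density_arithmetic(self):
        cells = pd.DataFrame(
            {"roi_id": ["R"] * 100, "phenotype": ["B cells"] * 100}
        )
        s = summarize_density_proportion(cells, roi_area_mm2=0.5)
        assert s.loc[s.phenotype == "B cells", "density_per_mm2"].iloc[0] == 200.0

    def test_proportion_ratio_with_groups(self):
        tree = default_gating_tree()
        cells = pd.DataFrame(
            {
                "roi_id": ["R"] * 60,
                "phenotype": ["CD163+ myelomonocytic cells"] * 30
                + ["CD163- myelomonocytic cells"] * 30,
            }
        )
        s = summarize_density_proportion(
            cells, 1.0,
            denominators={"CD163+ myelomonocytic cells": "Myelomonocytic cells"},
            tree=tree,
        )
        row = s[s.phenotype == "CD163+ myelomonocytic cells"].iloc[0]
        assert row.proportion == 0.5 and row.proportion_defined

    def test_matches_planted_ground_truth_counts(self, archetypes):
        counts = {"B cells": 37, "CD8+ T cells": 21, "Epithelial cells": 42}
        table = synth_cell_table(archetypes, counts, noise_seed=11, roi_id="R9")
        table["phenotype"] = table["true_label"]
        s = summarize_density_proportion(table, roi_area_mm2=0.25)
        for label, n in counts.items():
            row = s[s.phenotype == label].iloc[0]
            assert row["count"] == n
            assert row.density_per_mm2 == n / 0.25

    def test_zero_denominator_flagged_undefined(self):
        cells = pd.DataFrame({"roi_id": ["R"], "phenotype": ["B cells"]})
        s = summarize_density_proportion(
            cells, 1.0, denominators={"B cells": "T cells"},
            tree=default_gating_tree(),
        )
        row = s[s.phenotype == "B cells"].iloc[0]
        assert not row.proportion_defined and np.isnan(row.proportion)


class TestBiaxialPairCount:
    @pytest.mark.parametrize("n,expected", [(10, 45), (2, 1), (5, 10)])
    def test_pair_counts(self, n, expected):
        assert biaxial_pair_count(n) == expected

    def test_below_two_rejected(self):
        with pytest.raises(ValueError):
            biaxial_pair_count(1)
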