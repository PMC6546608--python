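"""Heterogeneity statistics, DerSimonian-Laird pooling, and table assembly."""

import math
import random

import numpy as np
import pytest

from ppcmeta import (
    CATEGORIES,
    Dataset,
    EffectSize,
    cochran_q,
    dl_tau2,
    i_squared,
    pool_by_category,
    pool_effect_table,
    pool_random_effects,
    read_dataset,
    subgroup_by_control,
    write_dataset,
)
from ppcmeta.synthetic import SimConfig, generate_dataset


def _eff(d, v, study="s", comp="c", category="mindfulness"):
    return EffectSize(study_id=study, comparison_id=comp, category=category,
                      d=d, variance=v, n_total=40, n_measures_averaged=1)


TWO_EFFECTS = [_eff(0.0, 0.1, study="a"), _eff(1.0, 0.1, study="b")]


class TestCochranQ:
    def test_zero_dispersion(self):
        effs = [_eff(0.5, v, study=str(i)) for i, v in enumerate([0.1, 0.2, 0.3])]
        q, df, p = cochran_q(effs)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_hand_example(self):
        q, df, _ = cochran_q(TWO_EFFECTS)
        assert q == pytest.approx(5.0, abs=1e-12)
        assert df == 1

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        effs = [_eff(d, v, study=str(i)) for i, (d, v) in enumerate(
            zip(rng.normal(0.2, 0.4, 8), rng.uniform(0.02, 0.3, 8)))]
        q, df, _ = cochran_q(effs)
        # independent re-summation with plain Python floats
        w = [1.0 / e.variance for e in effs]
        dbar = sum(wi * e.d for wi, e in zip(w, effs)) / sum(w)
        q_oracle = sum(wi * (e.d - dbar) ** 2 for wi, e in zip(w, effs))
        assert q == pytest.approx(q_oracle, abs=1e-12)

    def test_requires_two_effects(self):
        with pytest.raises(ValueError):
            cochran_q([_eff(0.1, 0.1)])


class TestISquared:
    @pytest.mark.parametrize(
        "q, df, expected",
        [
            (21.00, 10, 52.38),   # negative-behaviour row, all trials
            (44.36, 12, 72.95),   # depression row, all trials
            (42.28, 10, 76.35),   # mindfulness row, all trials
            (4.21, 8, 0.00),      # anxiety/stress row, active controls: truncated
        ],
    )
    def test_printed_table_identities(self, q, df, expected):
        assert round(i_squared(q, df), 2) == expected

    def test_boundary_q_equals_df(self):
        assert i_squared(10.0, 10) == 0.0

    def test_zero_q(self):
        assert i_squared(0.0, 5) == 0.0


class TestDlTau2:
    def test_hand_example(self):
        # continues the Q = 5, df = 1 fixture: C = 20 - 200/20 = 10
        assert dl_tau2(TWO_EFFECTS) == pytest.approx(0.40, abs=1e-12)

    def test_truncated_at_zero(self):
        effs = [_eff(0.5, v, study=str(i)) for i, v in enumerate([0.1, 0.15, 0.2])]
        assert dl_tau2(effs) == 0.0

    def test_equal_variance_closed_form(self):
        rng = np.random.default_rng(4)
        ds = rng.normal(0.3, 0.3, 12)
        v = 0.05
        effs = [_eff(d, v, study=str(i)) for i, d in enumerate(ds)]
        # with equal v: Q = sum (d - mean)^2 / v, C = (k-1)/v
        k = len(ds)
        q = float(np.sum((ds - ds.mean()) ** 2) / v)
        expected = max(0.0, (q - (k - 1)) / ((k - 1) / v))
        assert dl_tau2(effs) == pytest.approx(expected, rel=1e-12)


class TestPoolRandomEffects:
    def test_single_effect_identity(self):
        e = _eff(0.37, 0.04)
        row = pool_random_effects([e], tau2=0.02)
        assert row.d_pooled == pytest.approx(0.37)
        assert row.se == pytest.approx(math.sqrt(0.06))
        assert row.Q is None and row.i2 is None

    def test_hand_example_with_tau2(self):
        row = pool_random_effects(TWO_EFFECTS, tau2=0.4)
        assert row.d_pooled == pytest.approx(0.5, abs=1e-12)
        assert row.se == pytest.approx(0.5, abs=1e-12)
        assert row.z == pytest.approx(1.0, abs=1e-12)
        assert row.ci_low == pytest.approx(-0.48, abs=5e-3)
        assert row.ci_high == pytest.approx(1.48, abs=5e-3)

    def test_tau2_zero_reduces_to_fixed_effect(self):
        rng = np.random.default_rng(5)
        effs = [_eff(d, v, study=str(i)) for i, (d, v) in enumerate(
            zip(rng.normal(0.2, 0.3, 6), rng.uniform(0.02, 0.2, 6)))]
        row = pool_random_effects(effs, tau2=0.0)
        w = np.array([1 / e.variance for e in effs])
        d = np.array([e.d for e in effs])
        assert row.d_pooled == pytest.approx(float(np.sum(w * d) / np.sum(w)), rel=1e-12)
        assert row.se == pytest.approx(float(np.sqrt(1 / np.sum(w))), rel=1e-12)

    def test_pooled_estimate_within_effect_range(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            k = int(rng.integers(2, 12))
            effs = [_eff(d, v, study=str(i)) for i, (d, v) in enumerate(
                zip(rng.normal(0, 0.5, k), rng.uniform(0.01, 0.3, k)))]
            row = pool_random_effects(effs)
            ds = [e.d for e in effs]
            assert min(ds) - 1e-12 <= row.d_pooled <= max(ds) + 1e-12

    def test_tau2_and_i2_vanish_together(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            k = int(rng.integers(3, 10))
            effs = [_eff(d, v, study=str(i)) for i, (d, v) in enumerate(
                zip(rng.normal(0.2, 0.4, k), rng.uniform(0.02, 0.3, k)))]
            q, df, _ = cochran_q(effs)
            tau2 = dl_tau2(effs)
            i2 = i_squared(q, df)
            assert (tau2 > 0) == (i2 > 0)


class TestTableAssembly:
    def test_three_categories_give_four_rows(self):
        probs = {"mindfulness": 1.0, "depression": 1.0, "attention": 1.0}
        ds = generate_dataset(SimConfig(n_studies=8, category_probs=probs, seed=9))
        rows = pool_by_category(ds)
        assert len(rows) == 4
        assert rows[0].label == "all_measures"

    def test_active_filter_semantics(self, dataset):
        rows = pool_by_category(dataset, control_filter="active_only")
        # only s2/c2 (active_intervention control) survives the filter
        assert {r.label for r in rows} == {"all_measures", "anxiety_stress"}
        assert all(r.n_comparisons == 1 for r in rows)

    def test_multi_arm_study_in_both_subgroup_rows(self, dataset):
        rows = {r.label: r for r in subgroup_by_control(dataset)}
        # study s2 has one no-contact and one active-intervention arm, so its
        # comparisons land in both subgroup rows
        assert rows["no_contact"].k_studies == 1
        assert rows["active_intervention"].k_studies == 1
        assert rows["no_contact"].n_comparisons == 1
        assert rows["active_intervention"].n_comparisons == 1
        # subgroup k's sum to at least the number of distinct studies
        assert sum(r.k_studies for r in rows.values()) >= len(dataset.studies)

    def test_shared_arm_not_double_counted(self, dataset):
        rows = {r.label: r for r in pool_by_category(dataset)}
        # s1: 20+20, s2: 30+25+28 -> the mbi arm of s2 is shared by c1/c2
        assert rows["all_measures"].total_n == 40 + 83
        assert rows["anxiety_stress"].total_n == 83

    def test_wait_list_inflation_ordering(self):
        base = dict(n_studies=25, tau2=0.0, seed=21,
                    category_probs={"anxiety_stress": 1.0}, multi_arm_prob=0.0)
        wl = generate_dataset(SimConfig(
            delta={"anxiety_stress": 0.6},
            control_type_probs={"no_contact": 0.0, "wait_list": 1.0,
                                "attention_placebo": 0.0, "active_intervention": 0.0},
            **base))
        nc = generate_dataset(SimConfig(
            delta={"anxiety_stress": 0.1},
            control_type_probs={"no_contact": 1.0, "wait_list": 0.0,
                                "attention_placebo": 0.0, "active_intervention": 0.0},
            **base))
        merged = Dataset(
            studies=wl.studies + tuple(
                s.model_copy(update={"study_id": "x" + s.study_id}) for s in nc.studies),
            measures=wl.measures + tuple(
                m.model_copy(update={"study_id": "x" + m.study_id}) for m in nc.measures),
        )
        rows = {r.label: r for r in subgroup_by_control(merged)}
        assert rows["wait_list"].d_pooled > rows["no_contact"].d_pooled

    def test_measure_row_order_is_irrelevant(self, csv_paths, tmp_path):
        ds = read_dataset(*csv_paths)
        shuffled_measures = list(ds.measures)
        random.Random(0).shuffle(shuffled_measures)
        ds2 = Dataset(studies=ds.studies, measures=tuple(shuffled_measures))
        rows1 = {r.label: r for r in pool_by_category(ds)}
        rows2 = {r.label: r for r in pool_by_category(ds2)}
        assert rows1.keys() == rows2.keys()
        for label in rows1:
            assert rows1[label].d_pooled == pytest.approx(
                rows2[label].d_pooled, abs=1e-12)
            assert rows1[label].se == pytest.approx(rows2[label].se, abs=1e-12)

    def test_permutation_invariance_of_pooling(self):
        rng = np.random.default_rng(8)
        effs = [_eff(d, v, study=str(i)) for i, (d, v) in enumerate(
            zip(rng.normal(0.2, 0.4, 9), rng.uniform(0.02, 0.3, 9)))]
        row1 = pool_random_effects(effs)
        row2 = pool_random_effects(list(reversed(effs)))
        for field in ("d_pooled", "se", "Q", "tau2", "i2"):
            assert getattr(row1, field) == pytest.approx(
                getattr(row2, field), abs=1e-12)


class TestEffectTableIngestion:
    def test_matches_direct_pooling(self, tmp_path):
        """Pooling a transcribed per-study effect-size listing reproduces the
        in-memory pooled estimate (the deposited-table reproduction path)."""
        import pandas as pd

        from ppcmeta.effect_sizes import compute_comparison_composites

        ds = generate_dataset(SimConfig(n_studies=12, seed=13))
        comps = compute_comparison_composites(ds)
        table = pd.DataFrame([{
            "study_id": e.study_id, "comparison_id": e.comparison_id,
            "category": e.category, "d": e.d, "se": e.se,
        } for e in comps])
        path = tmp_path / "transcribed_effects.tsv"
        table.to_csv(path, sep="\t", index=False)
        row = pool_effect_table(pd.read_csv(path, sep="\t", float_precision="round_trip"))
        direct = pool_random_effects(comps)
        assert row.d_pooled == pytest.approx(direct.d_pooled, rel=1e-9)
        assert row.tau2 == pytest.approx(direct.tau2, rel=1e-9)
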