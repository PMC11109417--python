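from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from triomix import (
    FeatureTable,
    LefseParams,
    ValidationError,
    confounder_screen,
    lefse,
    mann_whitney_screen,
    median_split,
    relative_abundance,
)


def _table(values, omic="bacteria", kind="count"):
    df = pd.DataFrame(
        values,
        index=[f"f{i}" for i in range(len(values))],
        columns=[f"s{j}" for j in range(len(values[0]))],
    )
    return FeatureTable(df, omic=omic, value_kind=kind)


def enumerate_mw_p(x, y):
    """Brute-force exact two-sided Mann-Whitney p by full enumeration."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    u_null = []
    for idx in combinations(range(len(pooled)), n1):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u_null.append(sum(1 for xi in xs for yj in ys if xi > yj))
    u_null = np.asarray(u_null)
    mu = len(x) * len(y) / 2
    return np.mean(np.abs(u_null - mu) >= abs(u_obs - mu))


class TestMannWhitneyScreen:
    def test_exact_p_matches_enumeration(self):
        x, y = np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
        assert enumerate_mw_p(x, y) == pytest.approx(0.1)
        table = _table([[1, 2, 3, 4, 5, 6]])
        labels = ["UC"] * 3 + ["CTRL"] * 3
        out = mann_whitney_screen(table, labels)
        assert out.loc[0, "p"] == pytest.approx(0.1)
        assert out.loc[0, "U"] == 0.0

    def test_exact_p_random_inputs_vs_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.permutation(np.arange(1.0, 7.0))[:3]
            y = rng.choice(np.setdiff1d(np.arange(1.0, 13.0), x), 4, replace=False)
            table = _table([np.concatenate([x, y]).tolist()])
            labels = ["UC"] * 3 + ["CTRL"] * 4
            out = mann_whitney_screen(table, labels)
            assert out.loc[0, "p"] == pytest.approx(enumerate_mw_p(x, y))

    def test_identical_groups_zero_log2fc(self):
        table = _table([[2, 3, 4, 2, 3, 4]])
        out = mann_whitney_screen(table, ["UC"] * 3 + ["CTRL"] * 3)
        assert out.loc[0, "log2fc"] == 0.0

    def test_bh_hand_example(self):
        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(q, 0.04)
        # and through the screen itself: craft features with those raw ps
        rng = np.random.default_rng(3)
        table = _table(rng.integers(1, 100, (4, 12)).tolist())
        out = mann_whitney_screen(table, ["UC"] * 6 + ["CTRL"] * 6)
        manual = multipletests(out["p"], method="fdr_bh")[1]
        np.testing.assert_allclose(out["q"], manual)

    def test_bh_monotone_in_p(self):
        rng = np.random.default_rng(5)
        table = _table(rng.integers(0, 40, (25, 16)).tolist())
        out = mann_whitney_screen(table, ["UC"] * 8 + ["CTRL"] * 8)
        ordered = out.sort_values("p")
        assert (np.diff(ordered["q"]) >= -1e-12).all()
        assert (out["q"] >= out["p"] - 1e-12).all()

    def test_one_group_too_small(self):
        table = _table([[1, 2, 3, 4]])
        with pytest.raises(ValidationError):
            mann_whitney_screen(table, ["UC", "UC", "CTRL", "CTRL"])


def _shifted_rel_table(rng, n_per=25, fold=10.0, p=20):
    counts = rng.lognormal(2, 1, size=(p, 2 * n_per))
    counts[0, :n_per] *= fold        # enriched in the first (UC) half
    counts[1, n_per:] *= fold        # enriched in the second (CTRL) half
    df = pd.DataFrame(
        counts,
        index=[f"f{i}" for i in range(p)],
        columns=[f"s{j}" for j in range(2 * n_per)],
    )
    table = FeatureTable(df, "bacteria", "concentration")
    return relative_abundance(table), ["UC"] * n_per + ["CTRL"] * n_per


class TestLefse:
    def test_constant_feature_excluded(self):
        rng = np.random.default_rng(0)
        rel, labels = _shifted_rel_table(rng)
        values = rel.values.copy()
        values[5] = values[:, :1].sum() * 0 + 0.01  # constant across samples
        rel2 = rel.with_values(values)
        out = lefse(rel2, labels, LefseParams(seed=0))
        assert "f5" not in set(out["feature_id"])

    def test_planted_tenfold_marker_scores_high(self):
        rng = np.random.default_rng(1)
        rel, labels = _shifted_rel_table(rng, fold=10.0)
        out = lefse(rel, labels, LefseParams(seed=1)).set_index("feature_id")
        assert "f0" in out.index
        assert abs(out.loc["f0", "lda_score"]) >= 2.0
        assert out.loc["f0", "enriched_group"] == "UC"
        assert out.loc["f0", "lda_score"] < 0  # case-enriched scores negative

    def test_label_swap_flips_signs(self):
        rng = np.random.default_rng(2)
        rel, labels = _shifted_rel_table(rng)
        swapped = ["CTRL" if l == "UC" else "UC" for l in labels]
        a = lefse(rel, labels, LefseParams(seed=3)).set_index("feature_id")
        b = lefse(rel, swapped, LefseParams(seed=3)).set_index("feature_id")
        common = a.index.intersection(b.index)
        np.testing.assert_allclose(
            a.loc[common, "lda_score"], -b.loc[common, "lda_score"], rtol=1e-10
        )

    def test_sample_scaling_invariance(self):
        """Scores are invariant to rescaling one sample's abundances: the
        per-sample renormalization inside the screen absorbs it."""
        rng = np.random.default_rng(4)
        rel, labels = _shifted_rel_table(rng)
        scaled = rel.values.copy()
        scaled[:, 0] *= 37.0
        a = lefse(rel, labels, LefseParams(seed=5))
        b = lefse(rel.with_values(scaled), labels, LefseParams(seed=5))
        np.testing.assert_allclose(a["lda_score"], b["lda_score"], rtol=1e-8)

    def test_too_few_survivors_empty(self):
        rng = np.random.default_rng(6)
        values = rng.lognormal(0, 1, (5, 12))  # no group signal, few features
        df = pd.DataFrame(values, index=[f"f{i}" for i in range(5)],
                          columns=[f"s{j}" for j in range(12)])
        rel = relative_abundance(FeatureTable(df, "fungi", "concentration"))
        out = lefse(rel, ["UC"] * 6 + ["CTRL"] * 6, LefseParams(seed=0))
        assert len(out) == 0


class TestConfounderScreen:
    def test_median_split_hand_case(self):
        ages = pd.Series([30, 40, 50, 60], index=list("abcd"))
        split = median_split(ages)
        assert list(split) == ["le_45", "le_45", "gt_45", "gt_45"]

    def test_group_identical_variable_flags(self, small_study):
        study, _ = small_study
        meta = study.metadata.copy()
        meta["shadow"] = meta["group"]
        from triomix.core_io import AlignedStudy

        study2 = AlignedStudy(study.blocks, meta, list(study.sample_ids))
        report = confounder_screen(study2, ["shadow"], n_perm=99, seed=0)
        assert report["potential_confounder"].all()
        assert (report["n_significant"] > 0).any()

    def test_independent_variable_mostly_clean(self, small_study):
        study, _ = small_study
        meta = study.metadata.copy()
        rng = np.random.default_rng(123)
        meta["coin"] = np.where(rng.random(len(meta)) < 0.5, "heads", "tails")
        from triomix.core_io import AlignedStudy

        study2 = AlignedStudy(study.blocks, meta, list(study.sample_ids))
        report = confounder_screen(study2, ["coin"], n_perm=99, seed=0)
        assert (report["n_significant"] == 0).all()

    def test_single_level_variable_skipped(self, small_study):
        study, _ = small_study
        meta = study.metadata.copy()
        meta["constant"] = "x"
        from triomix.core_io import AlignedStudy

        study2 = AlignedStudy(study.blocks, meta, list(study.sample_ids))
        report = confounder_screen(study2, ["constant"], n_perm=99, seed=0)
        assert len(report) == 0
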