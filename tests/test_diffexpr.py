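import dataclasses
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from andropipe import (
    DEFAULT_PAIRS,
    InvalidDesignError,
    InvalidInputError,
    bh_fdr,
    bonferroni_threshold,
    classify_specificity,
    de_analysis,
    fit_moderated_model,
    moderated_F_test,
    moderated_t,
    normalize_chain,
    pairwise_contrasts,
    simulate_experiment,
)
from andropipe.diffexpr import trigamma_inverse


def _groups(sizes):
    labels = []
    for g, n in sizes.items():
        labels += [g] * n
    samples = [f"s{i}" for i in range(len(labels))]
    return pd.Series(labels, index=samples)


def _null_data(rng, n_clones, sizes, sd=0.3):
    groups = _groups(sizes)
    values = pd.DataFrame(
        rng.normal(0.0, sd, size=(n_clones, len(groups))),
        index=[f"c{i}" for i in range(n_clones)],
        columns=groups.index,
    )
    return values, groups


STUDY_SIZES = {"control": 14, "T1d7": 5, "T2d7": 4, "T2d14": 5, "KTd7": 7}


class TestModeratedFit:
    def test_group_with_one_sample_rejected(self, rng):
        values, groups = _null_data(rng, 20, {"a": 3, "b": 1})
        with pytest.raises(InvalidDesignError):
            fit_moderated_model(values, groups)

    def test_common_variance_recovered(self, rng):
        # 5000 null clones, known common variance: s0^2 within 5%, d0 large
        true_var = 0.09
        values, groups = _null_data(rng, 5000, STUDY_SIZES, sd=np.sqrt(true_var))
        fit = fit_moderated_model(values, groups)
        assert fit.s0_2 == pytest.approx(true_var, rel=0.05)
        assert fit.d0 > 50

    def test_posterior_between_prior_and_sample(self, rng):
        values, groups = _null_data(rng, 200, {"a": 4, "b": 4, "c": 4})
        fit = fit_moderated_model(values, groups)
        lo = np.minimum(fit.s0_2, fit.s2)
        hi = np.maximum(fit.s0_2, fit.s2)
        assert ((fit.s2_post >= lo - 1e-12) & (fit.s2_post <= hi + 1e-12)).all()

    def test_d0_zero_limit_is_ordinary_t(self, rng):
        values, groups = _null_data(rng, 100, {"a": 5, "b": 6, "c": 4})
        fit = fit_moderated_model(values, groups)
        raw = dataclasses.replace(fit, d0=0.0, s2_post=fit.s2.rename("s2_post"))
        t_mod = moderated_t(raw, "a", "b")["t"]
        # ordinary t with the pooled residual variance of the one-way fit
        se = np.sqrt(fit.s2 * (1 / 5 + 1 / 6))
        t_ols = (fit.group_means["b"] - fit.group_means["a"]) / se
        np.testing.assert_allclose(t_mod.to_numpy(), t_ols.to_numpy(), atol=1e-10)

    def test_d0_inf_limit_collapses_variances(self, rng):
        values, groups = _null_data(rng, 100, {"a": 5, "b": 5})
        fit = fit_moderated_model(values, groups)
        inf = dataclasses.replace(
            fit, d0=np.inf,
            s2_post=pd.Series(np.full(100, fit.s0_2), index=fit.s2.index),
        )
        assert (inf.s2_post == fit.s0_2).all()
        res = moderated_F_test(inf)
        assert np.isfinite(res["p"]).all()

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma

        for x in (0.1, 1.0, 7.5, 200.0):
            assert trigamma_inverse(float(polygamma(1, x))) == pytest.approx(x, rel=1e-6)


class TestModeratedF:
    def test_two_groups_f_is_t_squared(self, rng):
        values, groups = _null_data(rng, 150, {"a": 6, "b": 9})
        fit = fit_moderated_model(values, groups)
        F = moderated_F_test(fit)["F"]
        t = moderated_t(fit, "a", "b")["t"]
        np.testing.assert_allclose(F.to_numpy(), t.to_numpy() ** 2, rtol=1e-10)

    def test_type_one_error_calibrated(self, rng):
        values, groups = _null_data(rng, 4000, STUDY_SIZES)
        fit = fit_moderated_model(values, groups)
        p = moderated_F_test(fit)["p"]
        assert p.lt(0.05).mean() == pytest.approx(0.05, abs=0.015)

    def test_power_for_eightfold_effect(self, rng):
        # 8-fold (3 log2 units) in all treated groups, the study group sizes
        values, groups = _null_data(rng, 2000, STUDY_SIZES, sd=0.43)
        planted = values.index[:500]
        treated = groups.index[groups != "control"]
        values.loc[planted, treated] += 3.0
        fit = fit_moderated_model(values, groups)
        p = moderated_F_test(fit)["p"]
        assert (p.loc[planted] < 1e-4).mean() >= 0.95


class TestBhFdr:
    def test_hand_example(self):
        q = bh_fdr([0.001, 0.02, 0.03, 0.5])
        np.testing.assert_allclose(q, [0.004, 0.04, 0.04, 0.5])

    def test_single_p(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_all_equal(self):
        np.testing.assert_allclose(bh_fdr([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            bh_fdr([0.1, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12))
    def test_matches_stepup_definition(self, pvals):
        p = np.asarray(pvals)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        brute = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, m * p[idx] / rank)
            brute[idx] = running
        np.testing.assert_allclose(bh_fdr(p), brute, atol=1e-12)


class TestPairwiseContrasts:
    def test_partitioned_threshold(self, rng):
        values, groups = _null_data(rng, 30, STUDY_SIZES)
        out = pairwise_contrasts(values, groups, alpha_global=0.01)
        for tab in out.values():
            assert tab.attrs["threshold"] == pytest.approx(0.01 / 3)
            pd.testing.assert_series_equal(
                tab["significant"], tab["p"] < 0.01 / 3, check_names=False
            )

    def test_threshold_values(self):
        assert bonferroni_threshold(0.01, 3) == pytest.approx(0.0033333333333)
        assert bonferroni_threshold(0.01, 1) == 0.01

    def test_empty_pairs_rejected(self, rng):
        values, groups = _null_data(rng, 10, {"a": 3, "b": 3})
        with pytest.raises(Exception):
            pairwise_contrasts(values, groups, pairs=[])


class TestSpecificity:
    SIG = {("control", "T2d7"): True, ("control", "KTd7"): True, ("KTd7", "T2d7"): True}

    @pytest.mark.parametrize(
        "flags, effects, expected",
        [
            ({("control", "T2d7"): True, ("control", "KTd7"): False,
              ("KTd7", "T2d7"): True}, {"T": 2, "KT": 0.1}, "T only"),
            ({("control", "T2d7"): False, ("control", "KTd7"): True,
              ("KTd7", "T2d7"): False}, {"T": 0.1, "KT": 2}, "11KT only"),
            (SIG, {"T": 3, "KT": 1}, "T >11KT"),
            (SIG, {"T": 1, "KT": 3}, "shared-equal"),
            ({("control", "T2d7"): True, ("control", "KTd7"): True,
              ("KTd7", "T2d7"): False}, {"T": 3, "KT": 1}, "shared-equal"),
            ({("control", "T2d7"): False, ("control", "KTd7"): False,
              ("KTd7", "T2d7"): False}, {"T": 0, "KT": 0}, "none"),
        ],
    )
    def test_rule_table(self, flags, effects, expected):
        assert classify_specificity(flags, effects) == expected

    def test_missing_pair_rejected(self):
        with pytest.raises(InvalidInputError):
            classify_specificity({("control", "T2d7"): True}, {"T": 1, "KT": 1})


class TestRecoveryProperties:
    def test_sensitivity_monotone_in_effect_size(self):
        sens = []
        for lo, hi in ((1.15, 1.2), (1.5, 1.6), (3.0, 3.2)):
            hits = total = 0
            for seed in range(3):
                sig, truth = simulate_experiment(
                    n_clones=1500, frac_de=0.05, effect_range=(lo, hi), seed=seed
                )
                expr = normalize_chain(sig)
                de = de_analysis(expr, sig.groups)
                called = set(de.index[de["de"]])
                hits += len(called & set(truth.de_clones))
                total += len(truth.de_clones)
            sens.append(hits / total)
        assert sens[0] <= sens[1] + 0.02 <= sens[2] + 0.04
        assert sens[2] > 0.9


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
def test_moderated_fit_matches_limma(tmp_path, rng):
    """Cross-check d0/s0^2 estimation and moderated F against Bioconductor limma."""
    sizes = {"a": 5, "b": 4, "c": 6}
    groups = _groups(sizes)
    n = 400
    d0_true, s0_true = 4.0, 0.05
    variances = s0_true * d0_true / rng.chisquare(d0_true, size=n)
    values = pd.DataFrame(
        rng.normal(0, np.sqrt(variances)[:, None], size=(n, len(groups))),
        index=[f"c{i}" for i in range(n)], columns=groups.index,
    )
    values.to_csv(tmp_path / "expr.tsv", sep="\t")
    pd.DataFrame({"group": groups}).to_csv(tmp_path / "groups.tsv", sep="\t")
    script = tmp_path / "oracle.R"
    script.write_text(
        """
suppressMessages(library(limma))
args <- commandArgs(trailingOnly=TRUE)
x <- as.matrix(read.delim(args[1], row.names=1))
g <- factor(read.delim(args[2], row.names=1)$group)
fit <- eBayes(lmFit(x, model.matrix(~g)))
# F over the group coefficients only (fit$F would include the intercept)
tt <- topTable(fit, coef=2:ncol(fit), number=Inf, sort.by="none")
write.table(data.frame(F=tt$F, p=tt$P.Value), args[3], sep="\t",
            quote=FALSE, row.names=FALSE)
cat(fit$df.prior, fit$s2.prior, sep="\n")
"""
    )
    proc = subprocess.run(
        ["Rscript", str(script), str(tmp_path / "expr.tsv"),
         str(tmp_path / "groups.tsv"), str(tmp_path / "limma.tsv")],
        capture_output=True, text=True, check=True,
    )
    d0_limma, s0_limma = [float(v) for v in proc.stdout.split()]
    limma = pd.read_csv(tmp_path / "limma.tsv", sep="\t")

    fit = fit_moderated_model(values, groups)
    res = moderated_F_test(fit)
    assert fit.d0 == pytest.approx(d0_limma, rel=1e-4)
    assert fit.s0_2 == pytest.approx(s0_limma, rel=1e-4)
    np.testing.assert_allclose(res["F"].to_numpy(), limma["F"].to_numpy(), rtol=1e-6)
    np.testing.assert_allclose(res["p"].to_numpy(), limma["p"].to_numpy(), rtol=1e-6)
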