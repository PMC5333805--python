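"""Group summaries, mixed-model inference and the strength back-correction."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given
from hypothesis import strategies as st

import twitchva as tv
from twitchva.errors import ParameterError, ValidationError
from twitchva.mixedmodel import fit_mixed_model
from twitchva.stats import bonferroni_posthoc, simulate_study_table

GROUPS = ("biceps", "deltoid")
POSTURES = ("horizontal", "overhead_reach", "pressure_relief")


def _table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "arm_id", "transfer_group", "posture",
            "voluntary_activation", "max_voluntary_moment", "qc_included",
        ],
    )


class TestGroupSummary:
    def test_two_point_cell(self):
        tab = _table(
            [
                ("s1", "a1", "biceps", "horizontal", 0.9, 7.0, True),
                ("s2", "a2", "biceps", "horizontal", 1.0, 8.0, True),
            ]
        )
        out = tv.group_summary(tab, "va")
        cell = out[(out.transfer_group == "biceps") & (out.posture == "horizontal")]
        assert cell["mean"].item() == pytest.approx(0.95)
        assert cell["se"].item() == pytest.approx(0.05)

    def test_identical_values_zero_se(self):
        rows = [
            (f"s{i}", f"a{i}", g, p, 0.8, 5.0, True)
            for i, (g, p) in enumerate((g, p) for g in GROUPS for p in POSTURES)
        ]
        out = tv.group_summary(_table(rows), "va")
        filled = out[out.n > 0]
        np.testing.assert_allclose(filled["mean"], 0.8)
        np.testing.assert_allclose(filled["se"], 0.0, atol=1e-12)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"s{i}", f"a{i}", rng.choice(GROUPS), rng.choice(POSTURES),
             rng.uniform(0.5, 1.0), rng.uniform(2, 12), True)
            for i in range(20)
        ]
        tab = _table(rows)
        shuffled = tab.sample(frac=1, random_state=1).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            tv.group_summary(tab, "moment"), tv.group_summary(shuffled, "moment")
        )

    def test_qc_excluded_va_dropped_but_moment_kept(self):
        tab = _table(
            [
                ("s1", "a1", "biceps", "horizontal", 0.9, 7.0, True),
                ("s2", "a2", "biceps", "horizontal", 0.2, 8.0, False),
            ]
        )
        va = tv.group_summary(tab, "va")
        mo = tv.group_summary(tab, "moment")
        cell = (va.transfer_group == "biceps") & (va.posture == "horizontal")
        assert va[cell]["n"].item() == 1
        assert mo[cell]["n"].item() == 2

    def test_empty_cell_reported_with_count_zero(self):
        tab = _table(
            [
                ("s1", "a1", "biceps", "horizontal", 0.9, 7.0, True),
                ("s2", "a2", "deltoid", "overhead_reach", 0.7, 3.0, True),
            ]
        )
        out = tv.group_summary(tab, "va")
        empty = out[(out.transfer_group == "biceps") & (out.posture == "overhead_reach")]
        assert empty["n"].item() == 0
        assert np.isnan(empty["mean"].item())

    def test_group_means_recovered_from_simulation(self):
        rng = np.random.default_rng(42)
        means = {("biceps", p): 0.96 for p in POSTURES}
        means.update({("deltoid", p): 0.70 for p in POSTURES})
        tab = simulate_study_table(
            means, {"biceps": 6, "deltoid": 6}, rng, arm_sd=0.03, resid_sd=0.02
        )
        out = tv.group_summary(tab, "va")
        b = out[(out.transfer_group == "biceps") & (out.posture == "all")]["mean"].item()
        d = out[(out.transfer_group == "deltoid") & (out.posture == "all")]["mean"].item()
        assert b == pytest.approx(0.96, abs=0.03)
        assert d == pytest.approx(0.70, abs=0.03)


class TestMixedModel:
    def _balanced_table(self, seed=11, effect=0.15):
        rng = np.random.default_rng(seed)
        means = {(g, p): 0.8 for g in GROUPS for p in POSTURES}
        means[("biceps", "horizontal")] += effect
        return simulate_study_table(
            means, {"biceps": 6, "deltoid": 6}, rng, arm_sd=0.08, resid_sd=0.05
        )

    def test_balanced_homoscedastic_equals_classical_anova(self):
        tab = self._balanced_table()
        fit = fit_mixed_model(
            tab, "voluntary_activation", heteroscedastic=False, nested_subject=False
        )
        aov = pg.mixed_anova(
            data=tab, dv="voluntary_activation", within="posture",
            subject="arm_id", between="transfer_group",
        ).set_index("Source")
        for effect, source in [
            ("transfer", "transfer_group"),
            ("posture", "posture"),
            ("interaction", "Interaction"),
        ]:
            f, q, df_den, _ = fit.wald_f(effect)
            assert f == pytest.approx(aov.loc[source, "F"], abs=1e-3)
            assert (q, df_den) == (aov.loc[source, "DF1"], aov.loc[source, "DF2"])

    def test_heteroscedastic_reduces_to_classical_on_balanced_data(self):
        tab = self._balanced_table()
        hom = fit_mixed_model(tab, "voluntary_activation", heteroscedastic=False)
        het = fit_mixed_model(tab, "voluntary_activation", heteroscedastic=True)
        # same fixed-effect structure; F statistics agree to leading order
        for effect in ("transfer", "posture", "interaction"):
            assert het.wald_f(effect)[0] == pytest.approx(
                hom.wald_f(effect)[0], rel=0.2
            )

    def test_matches_r_nlme_varident(self, tmp_path):
        rscript = shutil.which("Rscript")
        assert rscript, "Rscript expected on PATH"
        rng = np.random.default_rng(7)
        means = {
            ("biceps", "horizontal"): 0.96, ("biceps", "overhead_reach"): 0.95,
            ("biceps", "pressure_relief"): 0.96, ("deltoid", "horizontal"): 0.80,
            ("deltoid", "overhead_reach"): 0.69, ("deltoid", "pressure_relief"): 0.70,
        }
        tab = simulate_study_table(
            means, {"biceps": 5, "deltoid": 6}, rng,
            arm_sd=0.08, resid_sd={"biceps": 0.03, "deltoid": 0.07},
        )
        csv = tmp_path / "fix.csv"
        tab.to_csv(csv, index=False)
        fit = fit_mixed_model(tab, "voluntary_activation", heteroscedastic=True)
        script = textwrap.dedent(f"""
            library(nlme)
            d <- read.csv("{csv}")
            d$transfer_group <- factor(d$transfer_group)
            d$posture <- factor(d$posture)
            m <- lme(voluntary_activation ~ transfer_group * posture,
                     random = ~1 | arm_id,
                     weights = varIdent(form = ~1 | transfer_group),
                     data = d, method = "REML",
                     contrasts = list(transfer_group = "contr.sum",
                                      posture = "contr.sum"))
            a <- anova(m, type = "marginal")
            cat(a[["F-value"]][2:4], sep = "\\n")
        """)
        out = subprocess.run(
            [rscript, "-"], input=script, text=True, capture_output=True, check=True
        )
        f_r = [float(x) for x in out.stdout.split()]
        f_py = [fit.wald_f(e)[0] for e in ("transfer", "posture", "interaction")]
        np.testing.assert_allclose(f_py, f_r, rtol=1e-3)

    def test_singular_design_names_deficient_factor(self):
        tab = self._balanced_table()
        with pytest.raises(ValidationError, match="transfer group"):
            fit_mixed_model(
                tab[tab.transfer_group == "biceps"], "voluntary_activation"
            )
        with pytest.raises(ValidationError, match="posture"):
            fit_mixed_model(tab[tab.posture == "horizontal"], "voluntary_activation")

    def test_power_to_detect_paper_sized_group_difference(self):
        # VA offset of 0.26 between groups at study-like n: the transfer
        # effect should be detected in at least 80% of replicates
        rng = np.random.default_rng(21)
        means = {("biceps", p): 0.96 for p in POSTURES}
        means.update({("deltoid", p): 0.70 for p in POSTURES})
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            tab = simulate_study_table(
                means, {"biceps": 5, "deltoid": 6}, rng,
                arm_sd=0.10, resid_sd=0.05,
            )
            _, effects = tv.fit_group_model(tab, "va")
            transfer = next(e for e in effects if e.effect == "transfer")
            hits += transfer.p_value < 0.05
        assert hits / n_rep >= 0.8


class TestBonferroni:
    def _fit(self):
        rng = np.random.default_rng(5)
        means = {(g, p): (0.9 if g == "biceps" else 0.7) for g in GROUPS for p in POSTURES}
        tab = simulate_study_table(means, {"biceps": 5, "deltoid": 6}, rng)
        return fit_mixed_model(tab, "voluntary_activation")

    def test_adjustment_multiplies_and_caps(self):
        fit = self._fit()
        contrasts = [
            (f"b vs d | {p}", ("biceps", p), ("deltoid", p)) for p in POSTURES
        ]
        out = bonferroni_posthoc(fit, contrasts)
        for c in out:
            assert c.p_adjusted == pytest.approx(min(1.0, c.p_raw * 3))
            assert c.p_raw <= c.p_adjusted <= 1.0

    def test_identical_cell_means_give_p_one(self):
        rows = [
            (f"s{i}{p}", f"a{i}", g, p, 0.8 + 0.001 * (i % 3), 5.0, True)
            for i, g in enumerate(GROUPS * 3)
            for p in POSTURES
        ]
        fit = fit_mixed_model(_table(rows), "voluntary_activation")
        out = bonferroni_posthoc(
            fit, [("c", ("biceps", "horizontal"), ("deltoid", "horizontal"))]
        )
        assert out[0].p_adjusted == pytest.approx(1.0, abs=0.05)

    def test_unknown_contrast_rejected(self):
        with pytest.raises(ValidationError):
            bonferroni_posthoc(self._fit(), [("bad", ("biceps", "sitting"), ("deltoid", "sitting"))])

    @given(st.floats(1e-6, 1.0), st.integers(1, 10))
    def test_adjustment_monotone_and_bounded(self, p_raw, m):
        adjusted = min(1.0, p_raw * m)
        assert p_raw <= adjusted <= 1.0


class TestBackcorrection:
    def test_published_deltoid_example(self):
        assert tv.deterioration_backcorrect(2.74, 0.16) == pytest.approx(3.26, abs=0.005)

    def test_zero_fraction_identity(self):
        assert tv.deterioration_backcorrect(5.5, 0.0) == 5.5

    def test_half_deterioration_doubles(self):
        assert tv.deterioration_backcorrect(8.4, 0.5) == pytest.approx(16.8)

    @pytest.mark.parametrize("frac", [1.0, 1.5, -0.1])
    def test_invalid_fraction_rejected(self, frac):
        with pytest.raises(ParameterError):
            tv.deterioration_backcorrect(2.74, frac)
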