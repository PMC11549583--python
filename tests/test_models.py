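"""Mixed and cluster-robust logistic models: oracles and invariants."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

from pnavax.errors import ConfigError, SeparationError
from pnavax.filtering import ModelFrame, filter_networks, model_frame
from pnavax.models import (
    ATTRIBUTE_PREDICTORS, FULL_PREDICTORS, NETWORK_PREDICTORS, MixedFitResult,
    bivariate_suite, fit_cluster_robust_logit, fit_random_intercept_logit,
    icc_latent, model_suite, r2_nakagawa,
)
from pnavax.synthetic_data import GeneratorConfig, generate_study
from conftest import GEN_PREDICTORS, make_network, recovery_frame

PI2_3 = np.pi ** 2 / 3


def _study(seed, n_egos=50, **kw):
    base = dict(missing_alter_vaccination=0.0, missing_ego_media=0.0,
                missing_alter_education=0.0, tie_homophily=0.0,
                contagion_rounds=0)
    base.update(kw)
    return generate_study(GeneratorConfig(n_egos=n_egos, seed=seed, **base))[0]


# ---------------------------------------------------------------------- icc

def test_icc_printed_variance_gives_point_two():
    assert round(icc_latent(0.83), 1) == 0.2
    assert icc_latent(0.83) == pytest.approx(0.2015, abs=5e-4)


def test_icc_equal_variances_half_and_zero():
    assert icc_latent(PI2_3) == pytest.approx(0.5)
    assert icc_latent(0.0) == 0.0


def test_icc_rejects_negative():
    with pytest.raises(ValueError):
        icc_latent(-0.1)


@given(st.floats(0.001, 50), st.floats(0.001, 50))
def test_icc_strictly_increasing_and_bounded(a, b):
    lo, hi = sorted([a, b])
    assert 0 <= icc_latent(lo) < 1
    if hi > lo:
        assert icc_latent(hi) > icc_latent(lo)


# ------------------------------------------------------------------- R2

def _fake_fit(beta_by_term, sigma2, frame):
    terms = ["intercept", *beta_by_term]
    est = [0.0, *beta_by_term.values()]
    table = pd.DataFrame({"term": terms, "estimate": est})
    return MixedFitResult(
        predictors=tuple(beta_by_term), coef_table=table, sigma2_ego=sigma2,
        sigma_ego=np.sqrt(sigma2), icc=icc_latent(sigma2), loglik=0.0,
        n_obs=frame.n_obs, n_groups=frame.n_groups, converged=True)


def test_r2_zero_coefficients():
    frame = recovery_frame(_study(1, n_egos=10))
    fit = _fake_fit({p: 0.0 for p in GEN_PREDICTORS}, 0.0, frame)
    assert r2_nakagawa(fit, frame) == (0.0, 0.0)


def test_r2_reduces_to_icc_when_fixed_part_flat():
    frame = recovery_frame(_study(1, n_egos=10))
    fit = _fake_fit({p: 0.0 for p in GEN_PREDICTORS}, PI2_3, frame)
    r2m, r2c = r2_nakagawa(fit, frame)
    assert r2m == 0.0 and r2c == pytest.approx(0.5)


def test_r2_conditional_dominates_marginal_on_fit():
    frame = recovery_frame(_study(2, n_egos=40, sigma_ego=0.9))
    fit = fit_random_intercept_logit(frame, predictors=GEN_PREDICTORS)
    assert 0 <= fit.r2_marginal <= fit.r2_conditional < 1
    # grouping share positive when a real random intercept was generated
    assert fit.r2_conditional - fit.r2_marginal > 0.01


# ------------------------------------------------- mixed-model fit oracles

def test_sigma_zero_matches_plain_logistic():
    frame = recovery_frame(_study(7, n_egos=60, sigma_ego=0.0))
    fit = fit_random_intercept_logit(frame, predictors=GEN_PREDICTORS)
    X = sm.add_constant(frame.df[list(GEN_PREDICTORS)].astype(float))
    oracle = sm.Logit(frame.df["vaccinated"], X).fit(disp=0)
    assert fit.sigma2_ego < 0.1  # ML estimate hovers just above the truth 0
    np.testing.assert_allclose(fit.coefficients.to_numpy(),
                               oracle.params.to_numpy(), atol=0.02)


def test_or_table_consistency():
    frame = recovery_frame(_study(8, n_egos=40, sigma_ego=0.5))
    fit = fit_random_intercept_logit(frame, predictors=GEN_PREDICTORS)
    t = fit.coef_table
    np.testing.assert_allclose(t["or_"], np.exp(t["estimate"]), rtol=1e-12)
    assert (t["ci_low"] <= t["or_"]).all() and (t["or_"] <= t["ci_high"]).all()
    assert (t["ci_low"] > 0).all()
    # Wald p matches |z| two-sided
    from scipy import stats
    z = t["estimate"] / t["se"]
    np.testing.assert_allclose(t["p"], 2 * stats.norm.sf(np.abs(z)), rtol=1e-9)


def test_separation_diagnostic_names_predictor():
    df = pd.DataFrame({
        "ego_id": ["e1"] * 10 + ["e2"] * 10,
        "vaccinated": [1] * 10 + [0] * 10,
        "flag": [1] * 10 + [0] * 10,
    })
    with pytest.raises(SeparationError, match="flag"):
        fit_random_intercept_logit(ModelFrame(df=df), predictors=("flag",))


def test_single_group_rejected():
    df = pd.DataFrame({"ego_id": ["e1"] * 10,
                       "vaccinated": [0, 1] * 5, "x": range(10)})
    with pytest.raises(ConfigError):
        fit_random_intercept_logit(ModelFrame(df=df), predictors=("x",))


def test_lme4_cross_check(tmp_path):
    """Independent GLMM oracle: lme4::glmer on the same frame."""
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript unavailable")
    frame = recovery_frame(_study(9, n_egos=40, sigma_ego=0.9))
    fit = fit_random_intercept_logit(frame, predictors=GEN_PREDICTORS)
    csv = tmp_path / "frame.csv"
    frame.df.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(textwrap.dedent(f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- glmer(vaccinated ~ alter_education_z + alter_single + media_online
                   + media_both + ego_vaccinated + (1 | ego_id),
                   data = d, family = binomial, nAGQ = 15)
        cat(fixef(m), sqrt(unlist(VarCorr(m))), logLik(m), sep = "\\n")
    """))
    out = subprocess.run(["Rscript", str(script)], capture_output=True,
                         text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    vals = [float(v) for v in out.stdout.split()]
    r_beta, r_sigma, r_loglik = vals[:6], vals[6], vals[7]
    np.testing.assert_allclose(fit.coefficients.to_numpy(), r_beta, atol=0.01)
    assert fit.sigma_ego == pytest.approx(r_sigma, abs=0.02)
    assert fit.loglik == pytest.approx(r_loglik, abs=0.05)


def test_sigma_recovery_single_replicate():
    frame = recovery_frame(_study(10, n_egos=150, sigma_ego=0.9,
                                  alter_size_weights={25: 1}))
    fit = fit_random_intercept_logit(frame, predictors=GEN_PREDICTORS)
    assert 0.6 < fit.sigma_ego < 1.2


# -------------------------------------------------------- cluster-robust GLM

def test_loo_prop_within_ego_identities():
    net_all = make_network("e1", vaccination=tuple([1] * 16),
                           ties=tuple((i, (i + 1) % 16) for i in range(16)))
    net_mix = make_network("e2", vaccination=tuple([1, 0] * 8),
                           ties=tuple((i, (i + 1) % 16) for i in range(16)))
    from pnavax.network_model import StudyData
    frame = model_frame(StudyData(networks=(net_all, net_mix)))
    assert (frame.df.loc[frame.df["ego_id"] == "e1", "loo_prop"] == 1.0).all()


def test_cluster_robust_exceeds_classical_for_ego_level_terms():
    """Ego-level predictors carry the clustering, so sandwich SEs inflate."""
    ratios = []
    for seed in range(5):
        frame = recovery_frame(_study(20 + seed, n_egos=60, sigma_ego=1.2))
        glm = fit_cluster_robust_logit(frame, predictors=GEN_PREDICTORS)
        t = glm.coef_table.set_index("term")
        for term in ("media_online", "media_both", "ego_vaccinated"):
            ratios.append(t.loc[term, "se"] / glm.classical_se[term])
    assert np.mean(ratios) > 1.1


def test_cluster_robust_single_cluster_error():
    df = pd.DataFrame({"ego_id": ["e1"] * 10, "vaccinated": [0, 1] * 5,
                       "x": np.arange(10.0)})
    with pytest.raises(ConfigError):
        fit_cluster_robust_logit(ModelFrame(df=df), predictors=("x",))


# --------------------------------------------------------------- model suite

def test_model_suite_specs_and_null_model():
    study = _study(30, n_egos=25, sigma_ego=0.6)
    kept, _ = filter_networks(study)
    frame = model_frame(kept)
    suite = model_suite(frame)
    assert set(suite) == {"m1", "m2", "m3", "m4"}
    assert suite["m1"].coef_table["term"].tolist() == ["intercept"]
    assert set(suite["m4"].predictors) == (set(suite["m2"].predictors)
                                           | set(suite["m3"].predictors))
    for fit in suite.values():
        assert fit.n_obs == frame.n_obs and fit.n_groups == frame.n_groups


def test_network_only_signal_lands_on_assortativity():
    """With homophily as the only signal, assortativity is the predictor
    that matters in the network models, and attribute effects stay small."""
    cfg = GeneratorConfig(
        n_egos=60, seed=31, tie_homophily=0.2, sigma_ego=0.0,
        coef_alter_education=0.0, coef_alter_single=0.0,
        coef_media_online=0.0, coef_media_both=0.0, coef_ego_vaccinated=0.0,
        missing_alter_vaccination=0.0, missing_ego_media=0.0,
        missing_alter_education=0.0, contagion_rounds=0,
    )
    study, _ = generate_study(cfg)
    kept, _ = filter_networks(study)
    frame = model_frame(kept)
    suite = model_suite(frame)
    for m in ("m3", "m4"):
        t = suite[m].coef_table.set_index("term")
        assert t.loc["assortativity_z", "p"] < 0.05
        assert t.loc["assortativity_z", "estimate"] > 0
    t2 = suite["m2"].coef_table.set_index("term")
    attr_sig = (t2.loc[list(ATTRIBUTE_PREDICTORS), "p"] < 0.05).sum()
    assert attr_sig <= 3  # no systematic attribute signal was generated


# ------------------------------------------------------------ bivariate suite

def test_bivariate_concordance_detected_and_margins():
    study = _study(32, n_egos=40, sigma_ego=1.0, tie_homophily=0.22)
    kept, _ = filter_networks(study)
    frame = model_frame(kept)
    table = bivariate_suite(frame)
    assert set(table["test"]) == {
        "alter_vacc_by_ego_vacc", "alter_vacc_by_ego_media",
        "ego_vacc_by_ego_media", "assort_by_alter_vacc",
        "assort_by_ego_vacc", "assort_quartile_by_media_vacc",
    }
    # strong ego-alter concordance generated via ego_vaccinated coefficient
    row = table.set_index("test").loc["alter_vacc_by_ego_vacc"]
    assert row["p"] < 0.001
    # quartile margins: quartile counts sum to the frame size
    q = pd.qcut(frame.df["assortativity"], 4, labels=False, duplicates="drop")
    assert q.value_counts().sum() == frame.n_obs


def test_bivariate_type_one_error_not_inflated():
    """Under independence of ego and alter vaccination, the chi-square test
    rejects at roughly its nominal rate."""
    pvals = []
    for seed in range(15):
        study = _study(100 + seed, n_egos=20, sigma_ego=0.0,
                       coef_ego_vaccinated=0.0, coef_media_online=0.0,
                       coef_media_both=0.0)
        kept, _ = filter_networks(study)
        frame = model_frame(kept)
        table = bivariate_suite(frame).set_index("test")
        pvals.append(table.loc["alter_vacc_by_ego_vacc", "p"])
    assert np.mean(np.array(pvals) < 0.05) <= 0.4
    assert max(pvals) > 0.2
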