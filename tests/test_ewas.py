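"""Pair-level mixed model: design construction, REML fitting, FDR, tables."""

import warnings

import numpy as np
import pandas as pd
import pytest

from twinewas import GeneratorConfig, generate_cohort
from twinewas.containers import MethylationMatrix, TwinCohort, ValidationError
from twinewas.ewas import (EFFECTS, adjust_fdr, build_pair_design, compute_dbw_pct,
                           fit_cpg, manhattan_table, odds_ratio, run_ewas,
                           run_simulation_study, select_extreme)
from twinewas.preprocess import to_mvalues


# ---------------------------------------------------------------------------
# discordance and subsetting
# ---------------------------------------------------------------------------

def test_dbw_pct_examples(tiny_cohort):
    dbw = compute_dbw_pct(tiny_cohort)
    assert dbw["p1"] == pytest.approx(25.0)           # (2000, 1500)
    assert dbw["p2"] == pytest.approx(10.0)           # (3000, 2700)
    assert dbw["p3"] == pytest.approx(100 * 800 / 1700)  # ~47.06
    assert dbw["p4"] == pytest.approx(8.0)


def test_dbw_pct_relabel_invariant(tiny_cohort):
    swapped = tiny_cohort.data.copy()
    swapped["twin_role"] = swapped["twin_role"].map({"bigger": "smaller", "smaller": "bigger"})
    bw = swapped.groupby("pair_id")["birth_weight"].transform(lambda s: s.iloc[::-1].to_numpy())
    swapped["birth_weight"] = bw
    dbw2 = compute_dbw_pct(TwinCohort(swapped))
    pd.testing.assert_series_equal(compute_dbw_pct(tiny_cohort), dbw2)


def test_dbw_pct_rejects_nonpositive(tiny_cohort):
    bad = tiny_cohort.data.copy()
    bad.loc[0, "birth_weight"] = 0.0
    with pytest.raises(ValidationError):
        TwinCohort(bad)


def test_select_extreme_boundary(tiny_cohort):
    sub = select_extreme(tiny_cohort, threshold=25.0)
    assert sorted(sub.primary["pair_id"].unique()) == ["p1", "p3"]  # 25.0 retained (>=)
    strict = select_extreme(tiny_cohort, threshold=25.0, strict=True)
    assert sorted(strict.primary["pair_id"].unique()) == ["p3"]
    with pytest.warns(UserWarning):
        empty = select_extreme(tiny_cohort, threshold=99.0)
    assert len(empty.data) == 0


def test_extreme_count_plausible_at_default_scale(default_cohort):
    sub = select_extreme(default_cohort, threshold=25.0)
    assert 15 <= sub.n_pairs <= 45


# ---------------------------------------------------------------------------
# pair design
# ---------------------------------------------------------------------------

def _mvalue_matrix(cohort, arr):
    ids = cohort.primary["sample_id"].tolist()
    return MethylationMatrix(
        pd.DataFrame(arr, index=[f"cg{i}" for i in range(arr.shape[0])], columns=ids),
        scale="mvalue")


def test_design_zero_response_for_identical_twins(tiny_cohort):
    arr = np.tile(np.arange(4.0), (3, 2))  # each pair's two columns identical
    design = build_pair_design(_mvalue_matrix(tiny_cohort, np.repeat(arr, 2, axis=1)[:, :8]), tiny_cohort)
    np.testing.assert_allclose(design.response.to_numpy(), 0.0, atol=1e-15)
    assert list(design.covariates["pair_id"]) == ["p1", "p2", "p3", "p4"]
    assert design.X.shape == (4, 4)


def test_design_antisymmetry(tiny_cohort):
    rng = np.random.default_rng(0)
    arr = rng.normal(size=(5, 8))
    mat = _mvalue_matrix(tiny_cohort, arr)
    d1 = build_pair_design(mat, tiny_cohort)
    swapped = tiny_cohort.data.copy()
    swapped["twin_role"] = swapped["twin_role"].map({"bigger": "smaller", "smaller": "bigger"})
    bw = swapped.groupby("pair_id")["birth_weight"].transform(lambda s: s.iloc[::-1].to_numpy())
    swapped["birth_weight"] = bw
    d2 = build_pair_design(mat, TwinCohort(swapped))
    np.testing.assert_allclose(d2.response.to_numpy(), -d1.response.to_numpy(), atol=1e-15)


def test_planted_alpha_appears_in_mean_response(small_dataset):
    cohort = small_dataset["cohort"]
    truth = small_dataset["truth"]
    mv = to_mvalues(small_dataset["beta"].subset_samples(cohort.primary["sample_id"].tolist()))
    design = build_pair_design(mv, cohort)
    probes = list(truth.causal_alpha)
    means = design.response.loc[probes].mean(axis=1)
    assert means.mean() == pytest.approx(0.2, abs=0.08)


# ---------------------------------------------------------------------------
# per-probe fits
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def big_design(default_cohort):
    ids = default_cohort.primary["sample_id"].tolist()
    mat = MethylationMatrix(
        pd.DataFrame(np.zeros((1, len(ids))), index=["cg0"], columns=ids), scale="mvalue")
    return build_pair_design(mat, default_cohort)


def _simulate_response(design, rng, batch_sd=0.0, noise_sd=0.3,
                       beta=(0.1, -0.02, 0.005, 0.08)):
    y = design.X @ np.asarray(beta) + rng.normal(0, noise_sd, design.n_pairs)
    for f, Z in design.Z.items():
        y += Z @ rng.normal(0, batch_sd, Z.shape[1])
    return y


def test_reml_matches_mixedlm_oracle(big_design):
    """Dual route: our profiled REML vs statsmodels MixedLM on the same data."""
    from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec
    rng = np.random.default_rng(12)
    design = big_design
    names = [[[f"{f}{i}" for i in range(Z.shape[1])]] for f, Z in design.Z.items()]
    vcs = VCSpec(list(design.Z), names, [[Z] for Z in design.Z.values()])
    groups = np.zeros(design.n_pairs)
    checked = 0
    for trial in range(6):
        y = _simulate_response(design, rng, batch_sd=0.35, noise_sd=0.2)
        fit = fit_cpg(y, design, probe_id="cg0")
        if fit.fallback:
            continue  # a variance component hit the boundary; OLS path tested elsewhere
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sm_fit = MixedLM(y, design.X, groups=groups, exog_vc=vcs).fit(
                    reml=True, method=["lbfgs"])
        except np.linalg.LinAlgError:
            continue
        ours = np.array([fit.estimates[e] for e in EFFECTS])
        np.testing.assert_allclose(ours, sm_fit.fe_params, atol=2e-3)
        checked += 1
    assert checked >= 2


def test_mixed_equals_ols_under_zero_batch_variance(big_design):
    """GLS with all variance components at zero is OLS, and boundary fits
    fall back to OLS exactly."""
    from twinewas.ewas import _gls_estimates, _ols
    rng = np.random.default_rng(13)
    n, p = big_design.n_pairs, big_design.X.shape[1]
    Gs = [Z @ Z.T for Z in big_design.Z.values()]
    n_fallback = 0
    for _ in range(5):
        y = _simulate_response(big_design, rng, batch_sd=0.0)
        beta_g, se_g, _ = _gls_estimates(np.zeros(3), y, big_design.X, Gs, n, p)
        beta_o, se_o, _ = _ols(y, big_design.X, n, p)
        np.testing.assert_allclose(beta_g, beta_o, atol=1e-4)
        np.testing.assert_allclose(se_g, se_o, atol=1e-4)
        mixed = fit_cpg(y, big_design, reml=True)
        if mixed.fallback:
            n_fallback += 1
            ols = fit_cpg(y, big_design, reml=False)
            for e in EFFECTS:
                assert mixed.estimates[e] == pytest.approx(ols.estimates[e], abs=1e-12)
    assert n_fallback >= 1  # boundary fits are the typical case without batch signal


def test_fit_antisymmetry(big_design):
    rng = np.random.default_rng(14)
    y = _simulate_response(big_design, rng, batch_sd=0.3, noise_sd=0.2)
    f1 = fit_cpg(y, big_design)
    f2 = fit_cpg(-y, big_design)
    tol = 1e-6 if not f1.fallback else 1e-12
    for e in EFFECTS:
        assert f2.estimates[e] == pytest.approx(-f1.estimates[e], abs=tol)
        assert f2.p[e] == pytest.approx(f1.p[e], abs=1e-9)


def test_fit_skips_underpowered_probe(big_design):
    y = np.full(big_design.n_pairs, np.nan)
    y[:5] = 1.0
    fit = fit_cpg(y, big_design)
    assert fit.status.startswith("skipped")
    assert np.isnan(fit.estimates["alpha"])


def test_null_type1_error_calibrated(big_design):
    """With no signal, the alpha t-test rejects at ~nominal rate."""
    rng = np.random.default_rng(15)
    pvals = []
    for _ in range(300):
        y = rng.normal(0, 0.3, big_design.n_pairs)
        pvals.append(fit_cpg(y, big_design, reml=False).p["alpha"])
    rate = np.mean(np.asarray(pvals) < 0.05)
    # binomial 99.7% band around 0.05 for n=300
    assert 0.012 <= rate <= 0.088


# ---------------------------------------------------------------------------
# FDR, odds ratios, tables
# ---------------------------------------------------------------------------

def test_bh_hand_oracle():
    q = adjust_fdr([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)
    assert adjust_fdr([0.3])[0] == pytest.approx(0.3)


def test_bh_properties():
    rng = np.random.default_rng(16)
    p = rng.uniform(0.001, 1, size=50)
    q = adjust_fdr(p)
    assert (q >= p - 1e-15).all() and (q <= 1).all()
    perm = rng.permutation(50)
    np.testing.assert_allclose(adjust_fdr(p[perm]), q[perm], atol=1e-15)
    # step-up oracle by hand
    order = np.argsort(p)
    staircase = p[order] * len(p) / (np.arange(len(p)) + 1)
    expected = np.minimum.accumulate(staircase[::-1])[::-1]
    np.testing.assert_allclose(q[order], np.minimum(expected, 1), atol=1e-12)
    with pytest.raises(ValidationError):
        adjust_fdr([0.0, 0.5])
    nanq = adjust_fdr([0.5, np.nan])
    assert np.isnan(nanq[1]) and nanq[0] == pytest.approx(0.5)


def test_odds_ratio():
    assert odds_ratio(-0.018, 10) == pytest.approx(0.84, abs=0.005)
    assert odds_ratio(0.0, 10) == 1.0
    assert odds_ratio(0.3, 2) * odds_ratio(0.3, 5) == pytest.approx(odds_ratio(0.3, 7))
    with pytest.raises(ValidationError):
        odds_ratio(np.inf)


def test_run_ewas_stateless_and_chunk_invariant(small_dataset):
    cohort = small_dataset["cohort"]
    mv = to_mvalues(small_dataset["beta"].subset_samples(
        cohort.primary["sample_id"].tolist()))
    sub = mv.subset_probes(mv.probe_ids[:30])
    res = run_ewas(sub, cohort)
    # duplicate probe -> identical fit
    dup = MethylationMatrix(
        pd.concat([sub.values, sub.values.iloc[[3]].rename(index={sub.probe_ids[3]: "dup"})]),
        "mvalue",
        pd.concat([sub.mask, sub.mask.iloc[[3]].rename(index={sub.probe_ids[3]: "dup"})]))
    res_dup = run_ewas(dup, cohort)
    a = res_dup.table.loc[sub.probe_ids[3], [f"{e}_estimate" for e in EFFECTS] + [f"{e}_p" for e in EFFECTS]]
    b = res_dup.table.loc["dup", a.index]
    np.testing.assert_allclose(a.to_numpy(float), b.to_numpy(float), atol=1e-12)
    # chunking over probes does not change per-probe estimates or p-values
    half1 = run_ewas(sub.subset_probes(sub.probe_ids[:15]), cohort)
    half2 = run_ewas(sub.subset_probes(sub.probe_ids[15:]), cohort)
    merged = pd.concat([half1.table, half2.table])
    cols = [f"{e}_estimate" for e in EFFECTS] + [f"{e}_p" for e in EFFECTS]
    pd.testing.assert_frame_equal(res.table[cols], merged.loc[res.table.index, cols])


def test_manhattan_table(small_dataset):
    cohort = small_dataset["cohort"]
    mv = to_mvalues(small_dataset["beta"].subset_samples(
        cohort.primary["sample_id"].tolist()))
    res = run_ewas(mv.subset_probes(mv.probe_ids[:12]), cohort)
    empty = manhattan_table(res, None)
    assert empty["chr"].isna().all() and len(empty) == 12
    manifest = pd.DataFrame({
        "probe_id": list(mv.probe_ids[:6]),
        "chr": ["2", "1", "1", "3", "2", "1"],
        "pos": [50, 100, 10, 7, 5, 60],
        "gene": list("ABCDEF"),
    })
    tab = manhattan_table(res, manifest)
    known = tab.dropna(subset=["chr"])
    assert list(known.index) == ["cg00000002", "cg00000005", "cg00000001",
                                 "cg00000004", "cg00000000", "cg00000003"]
    assert tab.loc["cg00000000", "gene"] == "A"
    assert tab["alpha_p"].min() == pytest.approx(res.table["alpha_p"].min())


def test_simulation_study_power_monotone_in_effect():
    scenarios = [
        {"name": "null", "alpha_true": 0.0, "frac_causal_alpha": 0.1,
         "frac_causal_dbw": 0, "frac_causal_age": 0, "n_pairs": 40, "n_probes": 60,
         "n_reference_probes": 0, "n_bad_pairs": 0, "n_failing_probes": 0,
         "n_high_missing_probes": 0},
        {"name": "strong", "alpha_true": 0.5, "frac_causal_alpha": 0.1,
         "frac_causal_dbw": 0, "frac_causal_age": 0, "n_pairs": 40, "n_probes": 60,
         "n_reference_probes": 0, "n_bad_pairs": 0, "n_failing_probes": 0,
         "n_high_missing_probes": 0},
    ]
    out = run_simulation_study(scenarios, n_replicates=2, seed=1, reml=False)
    assert set(out["scenario"]) == {"null", "strong"}
    g = out.groupby("scenario")["alpha_power"].mean()
    assert g["strong"] > g["null"] + 0.3
    # deterministic given seed
    out2 = run_simulation_study(scenarios, n_replicates=2, seed=1, reml=False)
    pd.testing.assert_frame_equal(out, out2)
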