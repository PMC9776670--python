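"""eGFR slopes, eligibility filtering, standardized regression and VIF."""

import numpy as np
import pandas as pd
import pytest

from glomopipe import (
    CohortSpec,
    egfr_slope,
    filter_eligible,
    fit_prognosis_model,
    generate_cohort,
    patient_slopes,
    vif,
)
from glomopipe.errors import (
    InvalidInputError,
    MulticollinearityError,
    UndefinedResultError,
)


def _cohort_long(rows):
    return pd.DataFrame(
        rows,
        columns=["patient_id", "age", "sex", "hypertension", "egfr0", "upcr",
                 "sclerotic_prop", "visit_time_yr", "egfr"],
    )


def test_filter_eligible_criteria():
    rows = []
    # patient 1: fine; 2: minor; 3: end-stage eGFR; 4: short follow-up
    for pid, age, egfr0, followup in [(1, 40, 60, 2.0), (2, 17, 60, 2.0),
                                      (3, 40, 14.9, 2.0), (4, 40, 60, 0.9)]:
        for t in (0.0, followup):
            rows.append([pid, age, 1, 0, egfr0, 1.0, 0.1, t, egfr0 - t])
    long_df = _cohort_long(rows)
    kept, log = filter_eligible(long_df)
    assert sorted(kept["patient_id"].unique()) == [1]
    assert log["age_lt_min"] == 1
    assert log["end_stage_at_biopsy"] == 1
    assert log["followup_lt_min"] == 1
    assert log["eligible"] == 1


def test_filter_honours_explicit_end_stage_flag():
    rows = [[1, 40, 1, 0, 60, 1.0, 0.1, t, 60] for t in (0.0, 2.0)]
    long_df = _cohort_long(rows)
    long_df["end_stage"] = 1  # e.g. maintenance dialysis despite eGFR ≥ 15
    kept, log = filter_eligible(long_df)
    assert kept.empty and log["end_stage_at_biopsy"] == 1


@pytest.mark.parametrize(
    "series, expected",
    [
        ([(0, 60), (1, 58), (2, 56)], -2.0),
        ([(0, 50), (1, 55), (2, 48)], -1.0),   # Σ(t−t̄)(y−ȳ)/Σ(t−t̄)² = −2/2
        ([(0, 50), (1, 55), (3, 0)], 5.0),     # t=3 outside the 2-year window
        ([(0, 60), (2, 50)], -5.0),            # window closed at t = 2
    ],
)
def test_egfr_slope_closed_form(series, expected):
    t, y = zip(*series)
    assert egfr_slope(t, y, window_years=2.0) == pytest.approx(expected)


def test_egfr_slope_needs_two_distinct_times():
    with pytest.raises(UndefinedResultError):
        egfr_slope([0.5], [60.0])
    with pytest.raises(UndefinedResultError):
        egfr_slope([1.0, 1.0], [60.0, 55.0])
    with pytest.raises(UndefinedResultError):
        egfr_slope([0.0, 3.0], [60.0, 55.0], window_years=2.0)  # one point in window


def test_noise_free_cohort_recovers_beta_exactly():
    spec = CohortSpec(n_patients=50, betas=(0, 0, 0, 0, 0, -3.0),
                      slope_noise_sd=0.0, egfr_measure_noise_sd=0.0, seed=12)
    table = generate_cohort(spec)
    patients = patient_slopes(table.to_long())
    # the fitted per-patient slopes equal the construction slopes
    merged = patients.merge(table.patients[["patient_id", "true_slope"]], on="patient_id")
    assert np.allclose(merged["egfr_slope"], merged["true_slope"], atol=1e-10)

    report = fit_prognosis_model(patients)
    assert report.table.loc["sclerotic_prop", "beta"] == pytest.approx(-3.0, abs=1e-9)
    others = report.table.drop(index="sclerotic_prop")["beta"]
    assert np.allclose(others, 0.0, atol=1e-9)
    assert report.r_squared == pytest.approx(1.0)


def test_noisy_cohort_recovery_within_three_se():
    spec = CohortSpec(n_patients=500, betas=(0, 0, 0, 0, 0, -3.0), seed=21)
    patients = patient_slopes(generate_cohort(spec).to_long())
    report = fit_prognosis_model(patients)
    row = report.table.loc["sclerotic_prop"]
    assert abs(row.beta - (-3.0)) < 3 * row.se
    assert row.p < 0.05
    assert (report.table["vif"] < 3).all()


def test_duplicated_predictor_raises_naming_columns():
    spec = CohortSpec(n_patients=40, seed=5)
    patients = patient_slopes(generate_cohort(spec).to_long())
    patients["upcr"] = patients["age"] * 2.0  # exact linear duplicate
    with pytest.raises(MulticollinearityError) as err:
        fit_prognosis_model(patients)
    assert {"age", "upcr"} <= set(err.value.columns)


def test_standardized_beta_equals_pearson_r_for_orthogonal_pair(rng):
    n = 200
    raw = rng.standard_normal((n, 2))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    x1, x2 = q[:, 0], q[:, 1]  # exactly uncorrelated
    y = 2.0 * x1 - 1.0 * x2 + 0.3 * rng.standard_normal(n)
    df = pd.DataFrame({"x1": x1, "x2": x2, "egfr_slope": y})
    report = fit_prognosis_model(df, predictors=("x1", "x2"), standardize_outcome=True)
    for col in ("x1", "x2"):
        r = np.corrcoef(df[col], y)[0, 1]
        assert report.table.loc[col, "beta"] == pytest.approx(r, abs=1e-9)


def test_r_squared_equals_squared_correlation_of_fit(rng):
    spec = CohortSpec(n_patients=80, seed=31)
    patients = patient_slopes(generate_cohort(spec).to_long())
    report = fit_prognosis_model(patients)
    # recompute fitted values from the raw-scale table
    X = patients[list(report.raw_table.index)].to_numpy()
    coef = report.raw_table["beta"].to_numpy()
    y = patients["egfr_slope"].to_numpy()
    fitted = X @ coef
    r = np.corrcoef(fitted, y)[0, 1]
    assert report.r_squared == pytest.approx(r ** 2, abs=1e-9)


def _orthonormal_columns(rng, n, k):
    raw = rng.standard_normal((n, k))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    return q


@pytest.mark.parametrize("rho", [0.0, 0.6, 0.9])
def test_vif_closed_form_for_bivariate_correlation(rng, rho):
    q = _orthonormal_columns(rng, 500, 2)
    x1 = q[:, 0]
    x2 = rho * q[:, 0] + np.sqrt(1 - rho ** 2) * q[:, 1]  # empirical corr = rho
    out = vif(pd.DataFrame({"x1": x1, "x2": x2}))
    expected = 1.0 / (1.0 - rho ** 2)
    assert out["x1"] == pytest.approx(expected, abs=1e-9)
    assert out["x2"] == pytest.approx(expected, abs=1e-9)


def test_vif_flags_perfect_collinearity(rng):
    q = _orthonormal_columns(rng, 100, 3)
    df = pd.DataFrame({"a": q[:, 0], "b": q[:, 1], "c": q[:, 2], "dup": q[:, 0]})
    out = vif(df)
    assert np.isinf(out["a"]) and np.isinf(out["dup"])
    assert np.isfinite(out["b"]) and np.isfinite(out["c"])


def test_vif_invariant_to_affine_rescaling(rng):
    x = rng.standard_normal((120, 3))
    df = pd.DataFrame(x, columns=["a", "b", "c"])
    base = vif(df)
    df2 = df.copy()
    df2["b"] = 7.5 * df2["b"] - 3.0
    rescaled = vif(df2)
    assert np.allclose(base, rescaled, atol=1e-9)


def test_sclerosis_is_most_frequently_significant_at_cohort_scale():
    """At n = 46 with only sclerosis truly nonzero, it dominates significance counts."""
    sig_counts = {c: 0 for c in
                  ("age", "sex", "hypertension", "egfr0", "upcr", "sclerotic_prop")}
    for seed in range(100):
        spec = CohortSpec(n_patients=46, betas=(0, 0, 0, 0, 0, -2.9), seed=seed)
        patients = patient_slopes(generate_cohort(spec).to_long())
        report = fit_prognosis_model(patients)
        for var in sig_counts:
            if report.table.loc[var, "p"] < 0.05:
                sig_counts[var] += 1
    top = max(sig_counts, key=sig_counts.get)
    assert top == "sclerotic_prop"
    assert sig_counts["sclerotic_prop"] > max(
        v for k, v in sig_counts.items() if k != "sclerotic_prop"
    )


def test_model_requires_enough_complete_cases():
    df = pd.DataFrame(
        np.random.default_rng(0).standard_normal((5, 7)),
        columns=["age", "sex", "hypertension", "egfr0", "upcr",
                 "sclerotic_prop", "egfr_slope"],
    )
    with pytest.raises(InvalidInputError):
        fit_prognosis_model(df)
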