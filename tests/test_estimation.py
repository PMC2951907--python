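import numpy as np
import pytest

from mcuflux import (
    Case,
    FitPlan,
    generate_dataset,
    make_protocol,
    objective,
    packaged_params,
    parameter_sensitivity,
    staged_fit_present,
    staged_fit_previous,
)

PRESENT_SETS = {
    "heart_ca_titration": "present/model1/heart",
    "liver_ca_titration": "present/model1/liver",
    "liver_dpsi_titration": "present/model1/liver_dpsi",
}
PREVIOUS_SETS = {
    "heart_ca_titration": "previous/model1/case1/heart",
    "liver_ca_titration": "previous/model1/case1/liver",
    "liver_dpsi_titration": "previous/model1/case1/liver_dpsi",
}


def corpus(param_names, noise_cv, base_seed):
    return {
        key: generate_dataset(
            packaged_params(name), make_protocol(key),
            noise_cv=noise_cv, seed=base_seed + j,
        )
        for j, (key, name) in enumerate(param_names.items())
    }


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def test_objective_closed_form_for_proportional_offset(present_liver):
    # data = 1.1 x model everywhere: residuals are exactly 10% of the model,
    # normalized by the observed maximum rate
    spec = make_protocol("liver_ca_titration")
    ds = generate_dataset(present_liver, spec, noise_cv=0.0, seed=0)
    scaled = ds.frame.assign(rate=ds.rates * 1.1)
    ds_scaled = type(ds)(
        dataset_id=ds.dataset_id, protocol=ds.protocol, frame=scaled,
        provenance=dict(ds.provenance),
    )
    clean = ds.rates
    expected = np.mean((0.1 * clean) ** 2) / (1.1 * clean.max()) ** 2
    got = objective(present_liver, {"liver_ca_titration": ds_scaled})
    assert got == pytest.approx(expected, rel=1e-12)


def test_objective_zero_at_generating_parameters(present_liver):
    ds = generate_dataset(present_liver, make_protocol("liver_ca_titration"), noise_cv=0.0)
    assert objective(present_liver, {"liver_ca_titration": ds}) == pytest.approx(0.0, abs=1e-30)


def test_objective_averages_per_experiment(present_liver, present_heart):
    ds = {
        "liver_ca_titration": generate_dataset(
            present_liver, make_protocol("liver_ca_titration"), noise_cv=0.0),
        "heart_ca_titration": generate_dataset(
            present_heart, make_protocol("heart_ca_titration"), noise_cv=0.0),
    }
    params = {"liver_ca_titration": present_liver, "heart_ca_titration": present_liver}
    e_pair = objective(params, ds)
    e_heart = objective(present_liver, {"heart_ca_titration": ds["heart_ca_titration"]})
    assert e_pair == pytest.approx(e_heart / 2, rel=1e-12)  # liver term is 0


def test_global_normalization_differs_from_per_experiment(present_liver, present_heart):
    ds = {
        "liver_ca_titration": generate_dataset(
            present_liver, make_protocol("liver_ca_titration"), noise_cv=0.05, seed=8),
        "heart_ca_titration": generate_dataset(
            present_heart, make_protocol("heart_ca_titration"), noise_cv=0.05, seed=9),
    }
    params = {"liver_ca_titration": present_liver, "heart_ca_titration": present_heart}
    assert objective(params, ds, "per_experiment") != objective(params, ds, "global")


# ---------------------------------------------------------------------------
# Exact recovery (noise-free) and determinism
# ---------------------------------------------------------------------------

def test_exact_recovery_present_from_noise_free_data():
    datasets = corpus(PRESENT_SETS, 0.0, 100)
    result = staged_fit_present(datasets, FitPlan(formulation="present"))
    assert result.estimates["K0_liver"] == pytest.approx(45.6e-6, rel=1e-3)
    assert result.estimates["K0_heart"] == pytest.approx(87.6e-6, rel=1e-3)
    assert result.estimates["nH"] == pytest.approx(2.65, rel=1e-3)
    assert result.estimates["k0_liver"] == pytest.approx(0.0142, rel=1e-3)
    assert result.estimates["k0_heart"] == pytest.approx(0.0159, rel=1e-3)
    assert result.estimates["alpha"] == pytest.approx(0.0, abs=1e-4)
    assert result.objective < 1e-10


def test_exact_recovery_previous_from_noise_free_data():
    datasets = corpus(PREVIOUS_SETS, 0.0, 100)
    result = staged_fit_previous(datasets, FitPlan(formulation="previous"))
    assert result.estimates["K_liver"] == pytest.approx(45.9e-6, rel=1e-3)
    assert result.estimates["beta_e"] == pytest.approx(0.113, rel=1e-2)
    assert result.estimates["beta_x"] == pytest.approx(0.887, rel=1e-2)
    assert result.estimates["beta_e"] + result.estimates["beta_x"] + \
        2 * result.estimates["alpha"] == pytest.approx(1.0, rel=1e-12)
    assert result.objective < 1e-8


def test_staged_fit_is_deterministic():
    datasets = corpus(PRESENT_SETS, 0.05, 11)
    a = staged_fit_present(datasets, FitPlan(formulation="present"))
    b = staged_fit_present(datasets, FitPlan(formulation="present"))
    assert a.estimates == b.estimates
    assert a.objective == b.objective


def test_multistart_seed_does_not_change_the_winner():
    datasets = corpus(PRESENT_SETS, 0.05, 21)
    a = staged_fit_present(datasets, FitPlan(formulation="present", seed=0))
    b = staged_fit_present(datasets, FitPlan(formulation="present", seed=123))
    for key in a.estimates:
        assert a.estimates[key] == pytest.approx(b.estimates[key], rel=1e-4)


def test_alpha_bound_active_for_data_generated_without_displacement():
    datasets = corpus(PRESENT_SETS, 0.05, 41)
    result = staged_fit_present(datasets, FitPlan(formulation="present"))
    assert result.estimates["alpha"] == 0.0


# ---------------------------------------------------------------------------
# Statistical recovery (spec of the estimator, replicated)
# ---------------------------------------------------------------------------

def test_statistical_recovery_present_median_within_tolerance():
    reps = []
    for r in range(50):
        datasets = corpus(PRESENT_SETS, 0.05, 5000 + 10 * r)
        reps.append(staged_fit_present(
            datasets, FitPlan(formulation="present", multistart=4)).estimates)
    med = {k: np.median([e[k] for e in reps]) for k in reps[0]}
    assert med["K0_liver"] == pytest.approx(45.6e-6, rel=0.05)
    assert med["K0_heart"] == pytest.approx(87.6e-6, rel=0.05)
    assert med["k0_liver"] == pytest.approx(0.0142, rel=0.05)
    assert med["k0_heart"] == pytest.approx(0.0159, rel=0.05)
    assert med["k0_liver_dpsi"] == pytest.approx(1.99, rel=0.05)
    assert med["nH"] == pytest.approx(2.65, rel=0.10)


def test_statistical_recovery_previous_median_within_tolerance():
    reps = []
    for r in range(50):
        datasets = corpus(PREVIOUS_SETS, 0.05, 7000 + 10 * r)
        reps.append(staged_fit_previous(
            datasets, FitPlan(formulation="previous", multistart=4)).estimates)
    med = {k: np.median([e[k] for e in reps]) for k in reps[0]}
    assert med["beta_e"] == pytest.approx(0.113, rel=0.05)
    assert med["beta_x"] == pytest.approx(0.887, rel=0.05)
    assert med["K_liver"] == pytest.approx(45.9e-6, rel=0.05)
    assert med["k_liver"] == pytest.approx(0.30, rel=0.05)


# ---------------------------------------------------------------------------
# Error handling, plans, sensitivity
# ---------------------------------------------------------------------------

def test_missing_liver_dataset_rejected():
    datasets = corpus(PRESENT_SETS, 0.05, 61)
    del datasets["liver_dpsi_titration"]
    with pytest.raises(ValueError, match="liver_dpsi_titration"):
        staged_fit_present(datasets, FitPlan(formulation="present"))


def test_heart_dataset_is_optional():
    datasets = corpus(PRESENT_SETS, 0.05, 71)
    del datasets["heart_ca_titration"]
    result = staged_fit_present(datasets, FitPlan(formulation="present"))
    assert "K0_liver" in result.estimates
    assert "K0_heart" not in result.estimates


def test_plan_yaml_round_trip(tmp_path):
    plan = FitPlan(formulation="previous", case=Case.CASE2, multistart=4, seed=3,
                   bounds={"nH": (0.5, 6.0)})
    path = tmp_path / "plan.yaml"
    plan.to_yaml(path)
    back = FitPlan.from_yaml(path)
    assert back.formulation == plan.formulation
    assert back.case == plan.case
    assert back.multistart == plan.multistart
    assert back.bound("nH") == (0.5, 6.0)


def test_plan_validation():
    with pytest.raises(ValueError):
        FitPlan(formulation="future")
    with pytest.raises(ValueError):
        FitPlan(multistart=0)
    with pytest.raises(ValueError):
        FitPlan(normalization="sideways")


def test_sensitivity_positive_for_identified_parameters():
    datasets = corpus(PRESENT_SETS, 0.05, 81)
    result = staged_fit_present(datasets, FitPlan(formulation="present"))
    sens = parameter_sensitivity(result, datasets)
    for key in ("K0_liver", "K0_heart", "nH", "k0_liver", "k0_heart"):
        assert sens[key] > 0, key
    assert sens["alpha"] == 0.0  # estimated on its bound; relative step is a no-op


def test_sensitivity_flags_m_family_flatness():
    datasets = corpus(PREVIOUS_SETS, 0.05, 91)
    plan = FitPlan(formulation="previous", case=Case.CASE2)
    result = staged_fit_previous(datasets, plan)
    sens = parameter_sensitivity(result, datasets)
    assert sens["m"] < 1e-3 * sens["K_liver"]
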