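"""Synthetic-data generator: model inversion, noise structure, determinism."""

import math

import numpy as np
import pytest

from phytokin import (
    DegradationDesign,
    TrueKinetics,
    fit_first_order,
    generate_arrhenius_k,
    generate_degradation,
    generate_dose_response,
)
from phytokin import reference as ref
from phytokin.io import degradation_to_frame, dose_response_to_frame
from phytokin.errors import ConfigurationError, ValidationError


def test_noiseless_generation_is_exact_exponential():
    design = DegradationDesign(temperatures=(155.0,), noise_cv=0.0, replicates=1)
    truth = TrueKinetics({155.0: 0.1865}, c0=1.0)
    series = generate_degradation(design, truth)[0]
    at_60 = [o.response for o in series.observations if o.time_min == 60.0][0]
    assert at_60 == pytest.approx(math.exp(-0.1865 * 60.0), rel=1e-12)
    assert at_60 == pytest.approx(1.381e-5, rel=1e-3)


def test_zero_rate_keeps_response_at_c0():
    design = DegradationDesign(temperatures=(75.0,), noise_cv=0.0, replicates=2)
    series = generate_degradation(design, TrueKinetics({75.0: 0.0}, c0=3.5))[0]
    assert all(o.response == pytest.approx(3.5, rel=1e-15) for o in series.observations)


def test_noiseless_loglinearity_machine_precision():
    design = DegradationDesign(noise_cv=0.0, replicates=1)
    truth = TrueKinetics(dict(ref.TAC_RATE_CONSTANTS), c0=2.0)
    for s in generate_degradation(design, truth):
        k = ref.TAC_RATE_CONSTANTS[s.temperature_c]
        for o in s.observations:
            assert math.log(o.response / 2.0) == pytest.approx(
                -k * o.time_min, abs=1e-12
            )


def test_lognormal_noise_has_median_c0_exp_kt():
    """Monte-Carlo check: sample median within 1% of the clean curve."""
    design = DegradationDesign(
        temperatures=(115.0,), times=(0.0, 30.0), replicates=200,
        noise_cv=0.03, seed=7,
    )
    series = generate_degradation(design, TrueKinetics({115.0: 0.0253}, c0=1.0))[0]
    at_30 = np.array([o.response for o in series.observations if o.time_min == 30.0])
    clean = math.exp(-0.0253 * 30.0)
    assert float(np.median(at_30)) == pytest.approx(clean, rel=0.01)
    assert np.all(at_30 > 0)


def test_seed_determinism_bit_identical():
    design = DegradationDesign(noise_cv=0.05, seed=123)
    truth = TrueKinetics(dict(ref.TAC_RATE_CONSTANTS))
    f1 = degradation_to_frame(generate_degradation(design, truth))
    f2 = degradation_to_frame(generate_degradation(design, truth))
    assert f1.equals(f2)
    other = degradation_to_frame(
        generate_degradation(
            DegradationDesign(noise_cv=0.05, seed=124), truth
        )
    )
    assert not f1.equals(other)


def test_noiseless_fit_recovers_generator_truth_with_r2_one():
    design = DegradationDesign(noise_cv=0.0, replicates=3)
    truth = TrueKinetics(dict(ref.TAC_RATE_CONSTANTS))
    for s in generate_degradation(design, truth):
        fit = fit_first_order(s)
        assert fit.k == pytest.approx(ref.TAC_RATE_CONSTANTS[s.temperature_c], rel=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)


def test_k_recovery_unbiased_at_study_noise():
    """Mean fitted k over 500 noisy simulations within 2% of truth."""
    k_true = 0.1865
    fitted = []
    for seed in range(500):
        design = DegradationDesign(temperatures=(155.0,), noise_cv=0.03, seed=seed)
        series = generate_degradation(design, TrueKinetics({155.0: k_true}))[0]
        fitted.append(fit_first_order(series).k)
    assert float(np.mean(fitted)) == pytest.approx(k_true, rel=0.02)


def test_design_validation():
    with pytest.raises(ValidationError):
        DegradationDesign(temperatures=())
    with pytest.raises(ValidationError):
        DegradationDesign(temperatures=(95.0, 75.0))
    with pytest.raises(ValidationError):
        DegradationDesign(times=(15.0, 30.0))  # missing 0
    with pytest.raises(ValidationError):
        DegradationDesign(noise_cv=-0.01)
    with pytest.raises(ValidationError):
        DegradationDesign(replicates=0)
    with pytest.raises(ValidationError):
        TrueKinetics({75.0: -0.1})
    with pytest.raises(ValidationError):
        TrueKinetics({75.0: 0.1}, c0=0.0)


def test_missing_temperature_is_configuration_error():
    design = DegradationDesign(temperatures=(75.0, 95.0), noise_cv=0.0)
    with pytest.raises(ConfigurationError):
        generate_degradation(design, TrueKinetics({75.0: 0.01}))


def test_arrhenius_generator_flat_and_monotone():
    flat = generate_arrhenius_k(0.0, math.log(0.02), ref.STUDY_TEMPERATURES)
    assert all(v == pytest.approx(0.02, rel=1e-12) for v in flat.values())
    rising = generate_arrhenius_k(50.0, 10.0, ref.STUDY_TEMPERATURES)
    ordered = [rising[t] for t in ref.STUDY_TEMPERATURES]
    assert ordered == sorted(ordered)
    with pytest.raises(ValidationError):
        generate_arrhenius_k(math.inf, 1.0, [75.0])
    with pytest.raises(ValidationError):
        generate_arrhenius_k(50.0, 1.0, [])


def test_dose_response_midpoint_and_direct_evaluation():
    series = generate_dose_response(ic50=1.0, slope=20.0, concentrations=[1.0, 10.0],
                                    noise_sd=0.0, replicates=1)
    by_c = {p.concentration: p.inhibition_pct for p in series.points}
    assert by_c[1.0] == pytest.approx(50.0, abs=1e-12)   # c == ic50
    assert by_c[10.0] == pytest.approx(70.0, abs=1e-12)  # one decade above


def test_dose_response_clipping_and_validation():
    series = generate_dose_response(ic50=0.01, slope=500.0, noise_sd=0.0, replicates=1)
    assert max(p.inhibition_pct for p in series.points) == 100.0
    with pytest.raises(ValidationError):
        generate_dose_response(ic50=-1.0)
    with pytest.raises(ValidationError):
        generate_dose_response(ic50=1.0, concentrations=[0.0, 1.0])
    with pytest.raises(ValidationError):
        generate_dose_response(ic50=1.0, noise_sd=-1.0)


def test_dose_response_seed_determinism():
    a = dose_response_to_frame([generate_dose_response(2.4, noise_sd=3.0, seed=5)])
    b = dose_response_to_frame([generate_dose_response(2.4, noise_sd=3.0, seed=5)])
    assert a.equals(b)
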