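"""IC50 inference and Tukey compact-letter comparisons."""

import math

import numpy as np
import pytest

from phytokin import (
    DoseResponseSeries,
    GroupSummary,
    generate_dose_response,
    ic50_loglinear,
    inhibition_percent,
    tukey_letters,
)
from phytokin import reference as ref
from phytokin.errors import (
    InsufficientDataError,
    NoCrossingError,
    ValidationError,
)


def test_inhibition_percent_arithmetic():
    assert inhibition_percent(0.8, 0.8) == 0.0
    assert inhibition_percent(0.8, 0.0) == 100.0
    assert inhibition_percent(0.8, 0.2) == pytest.approx(75.0)


def test_inhibition_percent_clips_and_validates():
    assert inhibition_percent(0.5, 0.7) == 0.0  # sample darker than control
    with pytest.raises(ValidationError):
        inhibition_percent(0.0, 0.2)


def test_ic50_is_geometric_midpoint_of_symmetric_segment():
    series = DoseResponseSeries.from_arrays("lox", [0.5, 5.0], [30.0, 70.0])
    res = ic50_loglinear(series)
    assert res.ic50 == pytest.approx(math.sqrt(0.5 * 5.0), rel=1e-10)
    assert not res.extrapolated


def test_ic50_exact_at_a_50_percent_point():
    series = DoseResponseSeries.from_arrays(
        "lox", [0.5, 1.0, 2.0], [30.0, 50.0, 70.0]
    )
    assert ic50_loglinear(series).ic50 == pytest.approx(1.0, rel=1e-10)


def test_ic50_generator_round_trip_zero_noise():
    series = generate_dose_response(ic50=2.40, slope=25.0, noise_sd=0.0)
    res = ic50_loglinear(series)
    assert res.ic50 == pytest.approx(2.40, rel=1e-9)
    assert res.slope == pytest.approx(25.0, rel=1e-9)
    assert res.r2 == pytest.approx(1.0, abs=1e-12)


def test_ic50_extrapolation_flag():
    series = generate_dose_response(ic50=20.0, slope=25.0, noise_sd=0.0)
    res = ic50_loglinear(series)
    assert res.extrapolated
    inside = generate_dose_response(ic50=2.0, slope=25.0, noise_sd=0.0)
    assert not ic50_loglinear(inside).extrapolated


def test_ic50_errors():
    flat = DoseResponseSeries.from_arrays("lox", [0.5, 1.0, 5.0], [40.0, 40.0, 40.0])
    with pytest.raises(NoCrossingError):
        ic50_loglinear(flat)
    falling = DoseResponseSeries.from_arrays("lox", [0.5, 5.0], [70.0, 30.0])
    with pytest.raises(NoCrossingError):
        ic50_loglinear(falling)
    single = DoseResponseSeries.from_arrays("lox", [1.0, 1.0], [40.0, 60.0])
    with pytest.raises(InsufficientDataError):
        ic50_loglinear(single)
    with pytest.raises(ValidationError):
        DoseResponseSeries.from_arrays("lox", [0.0, 1.0], [40.0, 60.0])


def test_raising_all_inhibitions_lowers_ic50():
    base = generate_dose_response(ic50=2.40, noise_sd=2.0, seed=11)
    shifted = DoseResponseSeries(
        enzyme=base.enzyme,
        points=[
            type(p)(p.concentration, min(p.inhibition_pct + 10.0, 100.0), p.replicate)
            for p in base.points
        ],
    )
    assert ic50_loglinear(shifted).ic50 < ic50_loglinear(base).ic50


def test_ic50_recovery_median_within_5_percent():
    """500 noisy simulations at noise_sd = 3: median recovery error < 5%."""
    rng = np.random.default_rng(2026)
    errors = []
    for _ in range(500):
        series = generate_dose_response(
            ic50=2.40, noise_sd=3.0, seed=int(rng.integers(2**31))
        )
        errors.append(abs(ic50_loglinear(series).ic50 - 2.40) / 2.40)
    assert float(np.median(errors)) < 0.05


def test_identical_groups_share_one_letter():
    groups = [GroupSummary(f"g{i}", 2.0, 0.5, 3) for i in range(3)]
    out = tukey_letters(groups)
    assert all(g.letter == "a" for g in out)


@pytest.mark.parametrize("enzyme", sorted(ref.IC50_SUMMARIES))
def test_published_ic50_summaries_reproduce_letters(enzyme):
    rows = ref.IC50_SUMMARIES[enzyme]
    groups = [GroupSummary(label, m, sd, n) for label, m, sd, n, _ in rows]
    out = tukey_letters(groups)
    for got, (_, _, _, _, expected) in zip(out, rows):
        assert got.letter == expected


def test_letters_cross_checked_against_statsmodels_tukey():
    """Summary-statistic Tukey must agree with statsmodels on raw data.

    For n = 3, the sample (m - sd, m, m + sd) has exactly mean m and SD sd,
    so raw-data Tukey HSD is an independent oracle for the summary route.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    cases = [
        [("a", 1.0, 0.3), ("b", 1.4, 0.3), ("c", 4.0, 0.5)],
        [("a", 2.0, 0.8), ("b", 2.5, 0.9), ("c", 2.2, 0.7)],
        [("a", 1.02, 0.30), ("b", 4.49, 0.44)],
    ]
    for summaries in cases:
        groups = [GroupSummary(lbl, m, sd, 3) for lbl, m, sd in summaries]
        out = {g.label: g.letter for g in tukey_letters(groups)}
        values, labels = [], []
        for lbl, m, sd in summaries:
            values += [m - sd, m, m + sd]
            labels += [lbl] * 3
        hsd = pairwise_tukeyhsd(np.array(values), np.array(labels), alpha=0.05)
        for (lbl1, lbl2), reject in zip(
            [(a, b) for i, a in enumerate(sorted(out)) for b in sorted(out)[i + 1:]],
            hsd.reject,
        ):
            shares = bool(set(out[lbl1]) & set(out[lbl2]))
            assert shares == (not reject), (lbl1, lbl2, out)


def test_letters_form_a_valid_cover():
    """Every group lettered; significantly different pairs never share."""
    groups = [
        GroupSummary("w", 1.0, 0.2, 3),
        GroupSummary("x", 1.2, 0.2, 3),
        GroupSummary("y", 3.0, 0.2, 3),
        GroupSummary("z", 3.1, 0.2, 3),
    ]
    out = tukey_letters(groups)
    assert all(len(g.letter) >= 1 for g in out)
    by = {g.label: set(g.letter) for g in out}
    assert by["w"] & by["x"]
    assert by["y"] & by["z"]
    assert not (by["w"] & by["y"])


def test_small_groups_excluded_with_warning():
    groups = [
        GroupSummary("ok1", 1.0, 0.2, 3),
        GroupSummary("ok2", 4.0, 0.2, 3),
        GroupSummary("tiny", 2.0, 0.0, 1),
    ]
    out = tukey_letters(groups)
    assert {g.label: g.letter for g in out}["tiny"] == ""
    with pytest.raises(InsufficientDataError):
        tukey_letters([GroupSummary("only", 1.0, 0.2, 3), GroupSummary("n1", 2.0, 0.0, 1)])
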