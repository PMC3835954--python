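import math

import numpy as np
import pytest
from scipy import stats

from dsspectrum import (
    BioassaySpec,
    ConvergenceError,
    DoseResponseData,
    TwoGroupCounts,
    ValidationError,
    abbott_correct,
    fisher_exact,
    fit_probit,
    lc_p,
    levene_test,
    simulate_dose_response,
    two_sample_t,
)


# --- Abbott correction -----------------------------------------------------


def test_abbott_examples():
    assert abbott_correct(0.55, 0.10) == pytest.approx(0.50)
    assert abbott_correct(0.10, 0.10) == 0.0
    assert abbott_correct(0.3, 0.0) == 0.3
    assert abbott_correct(0.05, 0.10) == 0.0  # floored


def test_abbott_rejects_certain_control_mortality():
    with pytest.raises(ValidationError):
        abbott_correct(0.5, 1.0)


# --- probit fitting --------------------------------------------------------


def exact_data(a, b, c, doses, n=10000):
    """Noise-free proportions (rounded to huge-n counts) at the model."""
    p = c + (1 - c) * stats.norm.cdf(a + b * np.log10(doses))
    return DoseResponseData(
        doses=tuple(doses),
        n_exposed=(n,) * len(doses),
        n_dead=tuple(int(round(n * pi)) for pi in p),
        control_n=n if c > 0 else 0,
        control_dead=int(round(n * c)),
    )


def test_noise_free_recovery_at_generating_optimum():
    doses = [10.0**e for e in (-2, -1, 0, 1, 2)]
    fit = fit_probit(exact_data(0.0, 1.0, 0.0, doses))
    assert fit.converged
    assert fit.a == pytest.approx(0.0, abs=0.02)
    assert fit.b == pytest.approx(1.0, abs=0.02)
    assert fit.lc50 == pytest.approx(1.0, rel=0.02)
    assert fit.ci_low <= fit.lc50 <= fit.ci_high


def test_natural_mortality_recovered_as_low_dose_limit():
    doses = [10.0**e for e in (-2, -1, 0, 1, 2)]
    fit = fit_probit(exact_data(0.0, 1.0, 0.10, doses))
    assert fit.converged
    assert fit.c == pytest.approx(0.10, abs=0.01)
    # fitted mortality at dose -> 0 tends to c
    tiny = fit.c + (1 - fit.c) * stats.norm.cdf(fit.a + fit.b * math.log10(1e-9))
    assert tiny == pytest.approx(0.10, abs=0.01)


def test_estimate_c_returns_near_zero_when_generated_without():
    doses = [10.0**e for e in (-2, -1, 0, 1, 2)]
    fit = fit_probit(exact_data(0.0, 1.0, 0.0, doses), estimate_c=True)
    assert fit.c == pytest.approx(0.0, abs=0.005)


def test_fixed_c_reduces_to_standard_probit():
    doses = [10.0**e for e in (-2, -1, 0, 1, 2)]
    fit_free = fit_probit(exact_data(0.0, 1.0, 0.0, doses), estimate_c=False, c_fixed=0.0)
    assert fit_free.c == 0.0
    assert fit_free.lc50 == pytest.approx(1.0, rel=0.02)


def test_dose_unit_equivariance():
    data = simulate_dose_response(BioassaySpec(seed=11))[0]
    fit1 = fit_probit(data)
    scaled = DoseResponseData(
        doses=tuple(d * 7.0 for d in data.doses),
        n_exposed=data.n_exposed,
        n_dead=data.n_dead,
        control_n=data.control_n,
        control_dead=data.control_dead,
    )
    fit2 = fit_probit(scaled)
    assert fit2.lc50 == pytest.approx(7.0 * fit1.lc50, rel=1e-4)
    assert fit2.ci_low == pytest.approx(7.0 * fit1.ci_low, rel=1e-3)
    assert fit2.ci_high == pytest.approx(7.0 * fit1.ci_high, rel=1e-3)
    assert fit2.b == pytest.approx(fit1.b, rel=1e-4)


def test_degenerate_all_alive_reported_not_fabricated():
    data = DoseResponseData(
        doses=(1.0, 2.0, 4.0), n_exposed=(16, 16, 16), n_dead=(0, 0, 0)
    )
    fit = fit_probit(data)
    assert not fit.converged
    assert math.isnan(fit.lc50)
    with pytest.raises(ConvergenceError):
        lc_p(fit, 0.5)


def test_too_few_doses_rejected():
    with pytest.raises(ValidationError):
        fit_probit(
            DoseResponseData(doses=(1.0, 2.0), n_exposed=(16, 16), n_dead=(2, 9))
        )


def test_parameter_recovery_and_ci_coverage():
    """Across 500 simulated assays at the reciprocal-feeding design the
    median log10(LC50) bias stays below 0.05 and the delta-method 95% CI
    covers the true LC50 between 90 and 98% of the time."""
    spec = BioassaySpec(replicates=500, seed=101)
    datasets = simulate_dose_response(spec)
    logs, covered = [], 0
    n_conv = 0
    for data in datasets:
        fit = fit_probit(data)
        if not fit.converged or not np.isfinite(fit.lc50):
            continue
        n_conv += 1
        logs.append(math.log10(fit.lc50) - math.log10(spec.lc50))
        if fit.ci_low <= spec.lc50 <= fit.ci_high:
            covered += 1
    assert n_conv >= 480
    assert abs(np.median(logs)) < 0.05
    assert 0.90 <= covered / n_conv <= 0.98


# --- lc_p ------------------------------------------------------------------


def test_lc_p_examples():
    doses = [10.0**e for e in (-2, -1, 0, 1, 2)]
    fit = fit_probit(exact_data(0.0, 1.0, 0.0, doses))
    assert lc_p(fit, 0.5) == pytest.approx(fit.lc50)
    assert lc_p(fit, 0.975) == pytest.approx(10 ** stats.norm.ppf(0.975), rel=0.02)
    assert lc_p(fit, 0.975) == pytest.approx(91.2, rel=0.03)


def test_lc_p_rejects_boundary_p():
    doses = [10.0**e for e in (-2, -1, 0, 1, 2)]
    fit = fit_probit(exact_data(0.0, 1.0, 0.0, doses))
    with pytest.raises(ValidationError):
        lc_p(fit, 1.0)


# --- Fisher's exact test ---------------------------------------------------


def hypergeom_two_sided(e1, n1, e2, n2):
    """Oracle: sum over all tables with the observed margins of the
    hypergeometric probabilities <= that of the observed table."""
    K = e1 + e2
    N = n1 + n2
    obs = stats.hypergeom.pmf(e1, N, K, n1)
    total = 0.0
    for x in range(max(0, K - n2), min(K, n1) + 1):
        p = stats.hypergeom.pmf(x, N, K, n1)
        if p <= obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


def test_equal_proportions_give_p_one():
    t = TwoGroupCounts(("a", "b"), (10, 10), (3, 3))
    assert fisher_exact(t) == pytest.approx(1.0)


def test_total_mortality_contrast():
    # control 10/10 alive vs treatment 0/10 alive
    t = TwoGroupCounts(("control", "test"), (10, 10), (0, 10))
    p = fisher_exact(t)
    assert p == pytest.approx(2 / 184756, rel=1e-9)


def test_empty_margin_warns_and_returns_one():
    t = TwoGroupCounts(("a", "b"), (10, 10), (0, 0))
    with pytest.warns(UserWarning, match="empty margin"):
        assert fisher_exact(t) == 1.0


def test_fisher_matches_enumeration_for_all_small_tables():
    import warnings

    for n1 in range(1, 13):
        for n2 in range(1, 13):
            for e1 in range(n1 + 1):
                for e2 in range(n2 + 1):
                    t = TwoGroupCounts(("a", "b"), (n1, n2), (e1, e2))
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        got = fisher_exact(t)
                    want = hypergeom_two_sided(e1, n1, e2, n2)
                    assert got == pytest.approx(want, abs=1e-9), (n1, n2, e1, e2)


# --- t test and Levene -----------------------------------------------------


def test_identical_samples_give_t_zero():
    assert two_sample_t([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)


def test_pooled_t_matches_hand_formula():
    x, y = [10.0, 12.0, 14.0], [20.0, 22.0, 24.0]
    t, p = two_sample_t(x, y)
    # hand pooled-variance computation
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
    t_hand = (np.mean(x) - np.mean(y)) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    assert t == pytest.approx(t_hand)
    assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), nx + ny - 2))


def test_constant_groups_with_unequal_means():
    t, p = two_sample_t([5.0, 5.0], [1.0, 1.0])
    assert math.isinf(t) and p == 0.0


def test_levene_degenerate_identical_groups():
    assert levene_test([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]) == (0.0, 1.0)


def test_levene_null_rejection_rate(rng):
    rejections = 0
    reps = 2000
    for _ in range(reps):
        x = rng.normal(0, 1, 20)
        y = rng.normal(0, 1, 20)
        _, p = levene_test(x, y)
        rejections += p < 0.05
    assert rejections / reps == pytest.approx(0.05, abs=0.02)


def test_levene_detects_fivefold_scale_difference(rng):
    hits = 0
    for _ in range(100):
        x = rng.normal(0, 1, 20)
        y = rng.normal(0, 5, 20)
        w, p = levene_test(x, y)
        hits += p < 0.05
    assert hits >= 95
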