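"""Benchmark distribution specs: sampling, pdfs and reference values."""

import json
import math

import numpy as np
import pytest
from scipy import integrate

from npit import distributions as dist
from npit.distributions import (
    GammaExponential,
    InvalidSpecError,
    MultivariateNormal,
    Normal,
    NormalMixture,
    Uniform,
    analytic_reference,
    builtin_cases,
    get_case,
    numeric_reference,
    pdf,
    read_sample,
    sample,
    write_sample,
)


@pytest.mark.parametrize(
    "build",
    [
        lambda: Uniform(2.0, 0.5),
        lambda: Normal(0.0, -1.0),
        lambda: MultivariateNormal(mean=(0.0, 0.0), cov=((1.0, 2.0), (2.0, 1.0))),
        lambda: NormalMixture(weights=(0.7, 0.7), components=(Normal(0, 1), Normal(1, 1))),
        lambda: GammaExponential(theta=0.0),
    ],
    ids=["uniform-b<=a", "normal-sigma<=0", "cov-not-psd", "weights-sum", "theta<=0"],
)
def test_invalid_specs_rejected(build):
    with pytest.raises(InvalidSpecError):
        build()


def test_sample_support_and_determinism():
    spec = Uniform(0.5, 2.0)
    s1 = sample(spec, 5, seed=1)
    s2 = sample(spec, 5, seed=1)
    assert s1.shape == (5, 1)
    assert np.all((s1 >= 0.5) & (s1 <= 2.0))
    assert np.array_equal(s1, s2)
    assert not np.array_equal(s1, sample(spec, 5, seed=2))


def test_gamma_exponential_sample_positive_and_marginal_mean():
    spec = GammaExponential(theta=3.0)
    s = sample(spec, 100_000, seed=11)
    assert np.all(s > 0)
    # Gamma(shape theta, scale 1) marginal: E[x1] = theta
    assert s[:, 0].mean() == pytest.approx(3.0, rel=0.02)


def test_gamma_exponential_joint_beats_independence_factorization():
    """The sampler's dependence structure matches the joint pdf: the joint
    log-likelihood of a sample exceeds that of the product of marginals."""
    spec = GammaExponential(theta=3.0)
    s = sample(spec, 20_000, seed=3)
    joint_ll = np.log(pdf(spec, s)).sum()
    indep_ll = (
        np.log(spec.marginal_pdf(0)(s[:, 0])).sum()
        + np.log(spec.marginal_pdf(1)(s[:, 1])).sum()
    )
    assert joint_ll > indep_ll


def test_4d_normal_sample_covariance_converges():
    case7 = get_case(7)
    s = sample(case7.p, 200_000, seed=7)
    emp = np.cov(s, rowvar=False)
    assert np.max(np.abs(emp - case7.p.cov_arr)) < 0.02


@pytest.mark.parametrize(
    "spec, point, expected",
    [
        (Uniform(0.5, 2.0), [1.0], 1.0 / 1.5),
        (GammaExponential(3.0), [1.0, 1.0], math.exp(-2.0) / 2.0),  # e^-2 / Gamma(3)
    ],
)
def test_pdf_point_values(spec, point, expected):
    assert pdf(spec, np.array([point]))[0] == pytest.approx(expected, rel=1e-6)


def test_mv_normal_pdf_at_mean_is_normalizer():
    case4 = get_case(4)
    spec = case4.p
    expected = ((2 * math.pi) ** spec.dim * np.linalg.det(spec.cov_arr)) ** -0.5
    assert pdf(spec, spec.mean_arr[None, :])[0] == pytest.approx(expected, rel=1e-12)


def test_pdf_zero_outside_support():
    assert pdf(Uniform(0.5, 2.0), np.array([[0.4], [2.1]])).tolist() == [0.0, 0.0]
    assert pdf(GammaExponential(3.0), np.array([[-1.0, 1.0], [1.0, -1.0]])).tolist() == [0.0, 0.0]


def test_pdf_dimension_mismatch():
    with pytest.raises(ValueError, match="dimension"):
        pdf(Uniform(0, 1), np.zeros((3, 2)))


@pytest.mark.parametrize("case_id", [1, 2, 3, 4, 5, 6])
def test_pdf_integrates_to_one(case_id):
    spec = get_case(case_id).p
    if spec.dim == 1:
        lo, hi = spec.support[0]
        val, _ = integrate.quad(
            lambda x: float(pdf(spec, np.array([[x]]))[0]), lo, hi, epsabs=1e-9, epsrel=1e-9
        )
    else:
        val, _ = integrate.nquad(
            lambda *a: float(pdf(spec, np.array([a]))[0]),
            spec.support,
            opts={"epsabs": 1e-9, "epsrel": 1e-9},
        )
    assert val == pytest.approx(1.0, abs=1e-6)


class TestAnalyticReference:
    def test_uniform_entropy_zero_on_unit_interval(self):
        assert analytic_reference("entropy", Uniform(0, 1)).value == 0.0

    def test_uniform_kl(self):
        ref = analytic_reference("kl", Uniform(0.5, 2.0), Uniform(0.0, 2.0))
        assert ref.value == pytest.approx(math.log(4.0 / 3.0), abs=1e-12)

    def test_uniform_kl_support_violation(self):
        with pytest.raises(ValueError, match="support"):
            analytic_reference("kl", Uniform(0.0, 2.0), Uniform(0.5, 2.0))

    def test_normal_entropy_closed_form(self, case2):
        assert case2.reference("entropy").value == pytest.approx(2.33522, abs=1e-5)

    def test_bivariate_mi_from_correlation(self, case4):
        # rho = -0.5: I = -0.5 log(1 - rho^2)
        assert case4.reference("mi").value == pytest.approx(0.14384, abs=1e-5)

    def test_gamma_exponential_entropy(self):
        # 1 + theta - theta psi(theta) + ln Gamma(theta), theta = 3
        ref = analytic_reference("entropy", GammaExponential(3.0))
        assert ref.value == pytest.approx(1.92479, abs=1e-5)

    @pytest.mark.parametrize(
        "quantity, case_id",
        [("entropy", 3), ("kl", 3), ("entropy", 5), ("kl", 5), ("mi", 5), ("kl", 6)],
    )
    def test_unavailable_closed_forms(self, quantity, case_id):
        case = get_case(case_id)
        assert analytic_reference(quantity, case.p, case.q, case.mi_split) is None

    def test_mixture_weights_must_sum_to_one(self):
        with pytest.raises(InvalidSpecError, match="sum to 1"):
            NormalMixture(weights=(0.5, 0.4), components=(Normal(0, 1), Normal(1, 1)))


class TestNumericReference:
    @pytest.mark.parametrize("case_id", [1, 2, 4, 6])
    def test_quadrature_matches_closed_forms(self, case_id):
        case = get_case(case_id)
        for quantity in case.quantities:
            exact = analytic_reference(quantity, case.p, case.q, case.mi_split)
            if exact is None:
                continue
            quad = numeric_reference(quantity, case.p, case.q, case.mi_split)
            assert quad.value == pytest.approx(exact.value, abs=1e-6), (case_id, quantity)

    def test_kl_of_spec_against_itself_is_zero(self):
        spec = GammaExponential(3.0)
        assert numeric_reference("kl", spec, spec).value == pytest.approx(0.0, abs=1e-8)

    def test_rejects_high_dimension(self):
        with pytest.raises(ValueError, match="d <= 2"):
            numeric_reference("entropy", get_case(7).p)


class TestBuiltinCases:
    def test_registry_shape(self):
        cases = builtin_cases()
        assert [c.case_id for c in cases] == list(range(1, 9))
        assert [c.dim for c in cases] == [1, 1, 1, 2, 2, 2, 4, 10]
        for c in cases[:3]:
            assert c.quantities == ("entropy", "kl")
        for c in cases[3:]:
            assert c.quantities == ("entropy", "kl", "mi")

    def test_printed_parameters(self):
        c1, c6, c8 = get_case(1), get_case(6), get_case(8)
        assert (c1.p.a, c1.p.b) == (0.5, 2.0) and (c1.q.a, c1.q.b) == (0.0, 2.0)
        assert c6.p.theta == 3.0 and c6.q.theta == 4.0
        cov0, cov1 = c8.p.cov_arr, c8.q.cov_arr
        assert np.all(np.diag(cov0) == 1.0) and cov0[0, 1] == 0.9
        assert cov1[0, 1] == 0.1
        assert c8.mi_split == 9

    def test_config_serializable(self):
        blob = json.dumps([c.to_config() for c in builtin_cases()])
        roundtrip = json.loads(blob)
        assert len(roundtrip) == 8
        assert roundtrip[6]["p"]["mean"] == [0.1, 0.3, 0.6, 0.9]

    def test_maximum_entropy_of_uniform_on_shared_support(self):
        """Among distributions restricted to [0, 1] the uniform has the
        largest differential entropy."""
        h_uniform = analytic_reference("entropy", Uniform(0.0, 1.0)).value
        # a truncated-looking narrow normal inside [0,1] has lower entropy
        h_narrow = analytic_reference("entropy", Normal(0.5, 0.1)).value
        assert h_uniform > h_narrow


def test_sample_io_round_trip(tmp_path):
    s = sample(get_case(4).p, 50, seed=5)
    path = tmp_path / "sample.csv"
    write_sample(path, s, header=True)
    back = read_sample(path, header=True)
    assert np.allclose(back, s, atol=1e-12)
    assert back.shape == (50, 2)
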