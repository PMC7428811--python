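"""Risk-equation unit and property tests.

Independent literal implementations of the basic and single-policing
risk forms (written directly from their algebraic definitions, without
log-space tricks) serve as oracles for the unified generalized form.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petostage import (
    MultistageParams,
    lifetime_risk_approx,
    lifetime_risk_exact,
    per_cell_target,
    per_driver_prob,
)


# -- independent oracles: literal algebraic forms in 60-digit arithmetic,
#    so the comparison measures our implementation's error only ---------
from mpmath import mp, mpf

mp.dps = 60


def _risk_basic(C, k, u, M, t):
    x = 1 - mp.exp(-mpf(u) * k * t)
    return float(1 - (1 - x**M) ** mpf(C))


def _risk_policing_cancer(C, k, u, M, t, e_c):
    x = 1 - mp.exp(-mpf(u) * k * t)
    return float(1 - (1 - (1 - mpf(e_c)) * x**M) ** mpf(C))


def _risk_policing_driver(C, k, u, M, t, e_d):
    x = 1 - mp.exp(-mpf(u) * k * t)
    return float(1 - (1 - ((1 - mpf(e_d)) * x) ** M) ** mpf(C))


class TestPerDriverProb:
    def test_zero_mutation_rate_gives_zero(self):
        assert per_driver_prob(0.0, 73.0, 80.0) == 0.0

    def test_saturates_at_one(self):
        assert per_driver_prob(1e6, 73.0, 80.0) == pytest.approx(1.0)

    def test_known_value(self):
        # 1 - exp(-3.66e-5 * 73 * 2), evaluated to high precision
        got = per_driver_prob(3.66e-5, 73.0, 2.0)
        assert got == pytest.approx(5.329348365831e-3, rel=1e-9)

    def test_negative_arguments_rejected(self):
        with pytest.raises(ValueError):
            per_driver_prob(-1e-5, 73.0, 2.0)
        with pytest.raises(ValueError):
            per_driver_prob(1e-5, -1.0, 2.0)


class TestLifetimeRiskExact:
    def test_mouse_colorectal_baseline_is_one_percent(self):
        p = MultistageParams(C=2e8 * 0.02 / 60, k=73.0, u=3.66e-5, M=3, t=2.0)
        assert lifetime_risk_exact(p) == pytest.approx(0.01, rel=5e-3)

    def test_human_colorectal_with_mouse_u_is_certain(self):
        p = MultistageParams(C=2e8, k=73.0, u=3.66e-5, M=3, t=80.0)
        assert lifetime_risk_exact(p) > 0.9999

    def test_perfect_cancer_policing_eliminates_risk(self):
        p = MultistageParams(C=1e9, k=73.0, u=1e-4, M=2, t=80.0, e_c=1.0)
        assert lifetime_risk_exact(p) == 0.0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_literal_forms(self, seed):
        """The unified form reduces to each literal special case to 1e-12
        relative on a random moderate-scale grid."""
        rng = np.random.default_rng(seed)
        for _ in range(200):
            C = float(rng.uniform(1, 1e6))
            k = float(rng.uniform(0.1, 100))
            u = float(10 ** rng.uniform(-6, -3))
            M = int(rng.integers(1, 6))
            t = float(rng.uniform(0.5, 100))
            e = float(rng.uniform(0, 0.99))
            base = MultistageParams(C=C, k=k, u=u, M=M, t=t)
            assert lifetime_risk_exact(base) == pytest.approx(
                _risk_basic(C, k, u, M, t), rel=1e-12, abs=1e-300
            )
            assert lifetime_risk_exact(base.with_(e_c=e)) == pytest.approx(
                _risk_policing_cancer(C, k, u, M, t, e), rel=1e-12, abs=1e-300
            )
            assert lifetime_risk_exact(base.with_(e_d=e)) == pytest.approx(
                _risk_policing_driver(C, k, u, M, t, e), rel=1e-12, abs=1e-300
            )

    def test_whale_scale_does_not_underflow(self):
        """C ~ 7.5e11 with per-cell risk ~1e-14 must give a finite,
        nonzero risk (the naive power form returns 0 or 1 here)."""
        p = MultistageParams(C=7.525e11, k=0.2826, u=4.5e-9, M=2, t=90.0)
        risk = lifetime_risk_exact(p)
        assert 0.0 < risk < 1.0
        assert risk == pytest.approx(0.0098, rel=0.05)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        C=st.floats(1, 1e10),
        k=st.floats(0.01, 200),
        u=st.floats(1e-8, 1e-3),
        M=st.integers(1, 8),
        t=st.floats(0.1, 100),
        c=st.floats(0.01, 100),
    )
    def test_u_k_exchangeable(self, C, k, u, M, t, c):
        """Risk depends on u and k only through their product."""
        if u * c > 1.0:
            return
        a = lifetime_risk_exact(MultistageParams(C=C, k=k, u=u, M=M, t=t))
        b = lifetime_risk_exact(MultistageParams(C=C, k=k / c, u=u * c, M=M, t=t))
        assert a == pytest.approx(b, rel=1e-9, abs=1e-300)

    def test_monotonicity_on_random_grid(self):
        """Risk is nondecreasing in C, k, u, t; decreasing in M (for
        x < 1); nonincreasing in e_c and e_d."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = MultistageParams(
                C=float(rng.uniform(10, 1e8)),
                k=float(rng.uniform(0.5, 100)),
                u=float(10 ** rng.uniform(-7, -3)),
                M=int(rng.integers(1, 6)),
                t=float(rng.uniform(1, 90)),
                e_c=float(rng.uniform(0, 0.9)),
                e_d=float(rng.uniform(0, 0.9)),
            )
            p0 = lifetime_risk_exact(p)
            up = {
                "C": p.with_(C=p.C * 1.1),
                "k": p.with_(k=p.k * 1.1),
                "u": p.with_(u=min(p.u * 1.1, 1.0)),
                "t": p.with_(t=p.t * 1.1),
            }
            for name, q in up.items():
                assert lifetime_risk_exact(q) >= p0 - 1e-15, name
            assert lifetime_risk_exact(p.with_(M=p.M + 1)) <= p0 + 1e-15
            assert lifetime_risk_exact(p.with_(e_c=min(p.e_c + 0.05, 1))) <= p0 + 1e-15
            assert lifetime_risk_exact(p.with_(e_d=min(p.e_d + 0.05, 1))) <= p0 + 1e-15


class TestLifetimeRiskApprox:
    def test_mouse_baseline_close_to_exact(self):
        # the approximation overshoots the exact 1% baseline by ~1.3%
        # (inner-term error M*u*k*t/2 ~ 0.8%, outer ~ C*q/2 ~ 0.5%)
        p = MultistageParams(C=2e8 * 0.02 / 60, k=73.0, u=3.66e-5, M=3, t=2.0)
        approx = lifetime_risk_approx(p)
        assert approx == pytest.approx(0.01017, rel=1e-3)
        assert approx == pytest.approx(lifetime_risk_exact(p), rel=0.015)

    def test_zero_mutation_rate(self):
        p = MultistageParams(C=1e8, k=73.0, u=0.0, M=3, t=80.0)
        assert lifetime_risk_approx(p) == 0.0

    def test_small_p_agreement_sweep(self):
        """In the small-risk regime (exact p < 0.005, u*k*t < 0.05) the
        approximation error is bounded by its leading terms,
        M*u*k*t/2 + p/2, and drops below 1% once M*u*k*t < 0.015."""
        rng = np.random.default_rng(7)
        checked = tight = 0
        for _ in range(5000):
            p = MultistageParams(
                C=float(10 ** rng.uniform(0, 9)),
                k=float(rng.uniform(0.5, 100)),
                u=float(10 ** rng.uniform(-8, -4)),
                M=int(rng.integers(1, 6)),
                t=float(rng.uniform(1, 90)),
            )
            exact = lifetime_risk_exact(p)
            if not (0 < exact < 0.005 and p.u * p.k * p.t < 0.05):
                continue
            checked += 1
            rel = lifetime_risk_approx(p) / exact - 1.0
            assert 0 <= rel <= 0.55 * (p.M * p.u * p.k * p.t + exact) + 1e-9
            if p.M * p.u * p.k * p.t < 0.015:
                tight += 1
                assert rel < 0.01
        assert checked > 100 and tight > 50  # the regimes were exercised


class TestPerCellTarget:
    def test_single_cell_identity(self):
        assert per_cell_target(0.01, 1.0) == pytest.approx(0.01, rel=1e-12)

    def test_large_compartment(self):
        # -log1p(-0.01)/C limit, checked to high precision
        assert per_cell_target(0.01, 2e8) == pytest.approx(5.02517e-11, rel=1e-5)

    def test_round_trip(self):
        """1 - (1-q)^C recovers p_target to 1e-12 relative across scales."""
        for C in (1.0, 10.0, 1e4, 1e8, 1e12):
            for p in (1e-6, 0.01, 0.5, 0.99):
                q = per_cell_target(p, C)
                back = -math.expm1(C * math.log1p(-q))
                assert back == pytest.approx(p, rel=1e-12)

    def test_small_p_asymptote(self):
        assert per_cell_target(1e-9, 1e6) == pytest.approx(1e-15, rel=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            per_cell_target(0.0, 10.0)
        with pytest.raises(ValueError):
            per_cell_target(1.0, 10.0)


class TestParamsValidation:
    @pytest.mark.parametrize(
        "bad",
        [
            dict(C=0.5), dict(k=-1.0), dict(u=-1e-6), dict(u=1.5),
            dict(M=0.5), dict(t=-1.0), dict(e_c=1.1), dict(e_d=-0.1),
        ],
    )
    def test_invariants_enforced(self, bad):
        good = dict(C=100.0, k=10.0, u=1e-5, M=2, t=10.0)
        with pytest.raises(ValueError):
            MultistageParams(**{**good, **bad})
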