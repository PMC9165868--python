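from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hepatolip as hl
from hepatolip.model import (
    ModelError,
    SingularityError,
    Sources,
    rhs_dimensional,
    rhs_dimensionless,
    transcription_rate,
)
from hepatolip.states import MRNA_NAMES, N_STATES, STATE_INDEX


def _simple_q(params, **over):
    """Dimensionless parameters with unit gains for closed-form checks."""
    p = params.with_overrides(
        s0=1.0, rf0=1, sE0=1, pE0_ref=1, l0=1, v0=1, m0=1,
        mu_mh_star=1.0, kappa_mh=1.0, kc=1.0, xc=1, xh=1, **over,
    )
    return hl.nondimensionalize(p)


class TestTranscriptionRate:
    def test_forced_value_at_zero_cholesterol(self, params):
        q = _simple_q(params)
        assert transcription_rate(0.0, "HMGCR", q) == pytest.approx(0.5, abs=1e-15)

    def test_value_at_c_equal_kc_matches_exact_fraction(self, params):
        # independent arbitrary-precision oracle of the printed expression
        mu, kappa, kc, xc, xh, c = map(Fraction, (1, 1, 1, 1, 1, 1))
        exact = mu / (1 + (kappa * (1 + (c / kc) ** xc)) ** xh)
        assert exact == Fraction(1, 3)
        q = _simple_q(params)
        assert transcription_rate(1.0, "HMGCR", q) == pytest.approx(
            float(exact), rel=1e-15
        )

    def test_rate_vanishes_as_cholesterol_grows(self, qparams):
        rates = [transcription_rate(c, "LDLR", qparams) for c in (1e3, 1e6, 1e9)]
        assert rates[0] > rates[1] > rates[2]
        assert rates[-1] < 1e-12 * qparams.mu_mr

    @settings(max_examples=50, deadline=None)
    @given(c=st.floats(0.0, 20.0), gene=st.sampled_from(hl.model.GENES))
    def test_strictly_decreasing_in_cholesterol(self, qparams, c, gene):
        eps = 1e-3 * (1.0 + c)
        assert transcription_rate(c, gene, qparams) > transcription_rate(
            c + eps, gene, qparams
        )

    def test_bounded_above_by_value_at_zero(self, qparams):
        top = qparams.mu_mh / (1.0 + qparams.kappa_mh ** qparams.xh)
        assert transcription_rate(0.0, "HMGCR", qparams) == pytest.approx(top)
        assert transcription_rate(5.0, "HMGCR", qparams) < top

    def test_domain_errors(self, qparams, params):
        with pytest.raises(ModelError):
            transcription_rate(-1.0, "HMGCR", qparams)
        with pytest.raises(ModelError, match="unknown gene"):
            transcription_rate(1.0, "SREBP2", qparams)
        q0 = hl.nondimensionalize(params).__class__(
            **{**qparams.__dict__, "kc": 0.0}
        )
        with pytest.raises(ModelError, match="kc"):
            transcription_rate(1.0, "HMGCR", q0)


class TestRhsDimensionless:
    def test_zero_state_only_mrna_moves(self, qparams):
        dy = rhs_dimensionless(0.0, np.zeros(N_STATES), qparams)
        for name in MRNA_NAMES:
            assert dy[STATE_INDEX[name]] > 0
        others = [i for i in range(N_STATES)
                  if hl.STATE_NAMES[i] not in MRNA_NAMES]
        # VLDL source is a constant parameter; it alone may drive v_E
        v_e = STATE_INDEX["v_E"]
        assert dy[v_e] == pytest.approx(qparams.omega_V)
        assert all(dy[i] == 0 for i in others if i != v_e)

    def test_bit_identical_reevaluation(self, qparams, rng):
        y = rng.uniform(0, 2, N_STATES)
        y[STATE_INDEX["r_f"]] = 0.5
        a = rhs_dimensionless(0.0, y, qparams)
        b = rhs_dimensionless(0.0, y, qparams)
        assert np.array_equal(a, b)

    @settings(max_examples=40, deadline=None)
    @given(data=st.data())
    def test_antibody_subsystem_closure(self, qparams, data):
        vals = data.draw(
            st.lists(st.floats(0, 10), min_size=N_STATES, max_size=N_STATES)
        )
        y = np.array(vals)
        y[STATE_INDEX["r_f"]] = min(y[STATE_INDEX["r_f"]], 0.5)
        dy = rhs_dimensionless(0.0, y, qparams)
        closure = qparams.W * dy[STATE_INDEX["A_E"]] + dy[STATE_INDEX["p_AB"]]
        assert closure == pytest.approx(qparams.W * qparams.omega_A, abs=1e-12)

    def test_cholesterol_balance_termwise_oracle(self, qparams):
        # hand-picked state: l_I = v_I = h = c = 1, all else 0
        y = np.zeros(N_STATES)
        for name in ("l_I", "v_I", "h", "c"):
            y[STATE_INDEX[name]] = 1.0
        dy = rhs_dimensionless(0.0, y, qparams)
        q = qparams
        expected = (
            q.R_l_chol * q.sigma_l * q.gamma_l
            + q.R_v_chol * q.sigma_v * q.gamma_v
            + q.mu_c
            - q.delta_c
        )
        assert dy[STATE_INDEX["c"]] == pytest.approx(expected, rel=1e-14)

    def test_rejects_negative_and_nan(self, qparams):
        y = np.zeros(N_STATES)
        y[0] = -1.0
        with pytest.raises(Exception):
            rhs_dimensionless(0.0, y, qparams)
        y[0] = np.nan
        with pytest.raises(Exception):
            rhs_dimensionless(0.0, y, qparams)

    def test_occupancy_singularity_guard(self, qparams):
        y = np.zeros(N_STATES)
        y[STATE_INDEX["r_f"]] = 1.0
        y[STATE_INDEX["l_RB"]] = 0.5
        with pytest.raises(SingularityError):
            rhs_dimensionless(0.0, y, qparams, validate=False)
        y[STATE_INDEX["l_RB"]] = 0.0  # no bound material: no division needed
        rhs_dimensionless(0.0, y, qparams, validate=False)

    @settings(max_examples=60, deadline=None)
    @given(data=st.data())
    def test_nonnegativity_preserved_at_boundary(self, qparams, data):
        """Any component at zero has a non-negative derivative."""
        vals = data.draw(
            st.lists(st.floats(0, 5), min_size=N_STATES, max_size=N_STATES)
        )
        y = np.array(vals)
        y[STATE_INDEX["r_f"]] = min(y[STATE_INDEX["r_f"]], 0.9)
        i = data.draw(st.integers(0, N_STATES - 1))
        y[i] = 0.0
        dy = rhs_dimensionless(0.0, y, qparams)
        assert dy[i] >= 0.0


class TestRhsDimensional:
    def test_zero_state_only_mrna_and_source(self, params):
        p = params.with_overrides(omega_V=0.0)
        dy = rhs_dimensional(0.0, np.zeros(N_STATES), p)
        for name in MRNA_NAMES:
            assert dy[STATE_INDEX[name]] > 0
        rest = [i for i in range(N_STATES)
                if hl.STATE_NAMES[i] not in MRNA_NAMES]
        assert np.all(dy[rest] == 0)

    def test_statin_bookkeeping_closed(self, params, rng):
        assert params.omega_S == 0.0
        y = rng.uniform(0, 1, N_STATES) * 1e10
        dy = rhs_dimensional(0.0, y, params)
        i = STATE_INDEX
        total = params.W * dy[i["S_E"]] + dy[i["S_i"]] + dy[i["S_ih"]]
        scale = max(abs(dy[i["S_i"]]), abs(dy[i["S_ih"]]), 1.0)
        assert abs(total) <= 1e-12 * scale

    def test_antibody_bookkeeping_with_source(self, params, rng):
        p = params.with_overrides(omega_A=123.0)
        y = rng.uniform(0, 1, N_STATES) * 1e9
        dy = rhs_dimensional(0.0, y, p)
        i = STATE_INDEX
        total = p.W * dy[i["A_E"]] + dy[i["p_AB"]]
        assert total == pytest.approx(p.W * 123.0, rel=1e-9)

    def test_matches_dimensionless_pointwise(self, params, rng):
        """Chain rule check at random states (trajectory check lives in
        test_nondim)."""
        q = hl.nondimensionalize(params)
        scales = hl.model.state_scales(params.scales)
        y = rng.uniform(0, 0.5, N_STATES)
        dy_dimless = rhs_dimensionless(0.0, y, q)
        dy_bar = rhs_dimensional(0.0, y * scales, params)
        np.testing.assert_allclose(dy_bar / scales, dy_dimless, rtol=1e-10)


class TestSources:
    def test_rejects_negative(self):
        with pytest.raises(ModelError):
            Sources(omega_P=-1.0)

    def test_addition_and_scaling(self, params):
        s = Sources(omega_P=2.0) + Sources(omega_P=3.0, omega_S=1.0)
        assert s.omega_P == 5.0 and s.omega_S == 1.0
        scaled = s.scaled(params.scales)
        assert scaled.omega_P == pytest.approx(5.0 / params.scales.pE0_ref)
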