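"""Two-frequency inversion: closed-form init, Gauss-Newton refinement."""

import numpy as np
import pytest

from admitsense import (
    CalibrationSet,
    Channel,
    ModelForm,
    RegressionModel,
    admissible_roots,
    estimate,
    fit,
    linear_init,
    newton_refine,
)
from admitsense.inversion import candidate_starts
from admitsense.synthetic import GeneratorConfig, generate


def forward_responses(calibration, x1, x2):
    return {
        (f, c): calibration.model(f, c).predict(x1, x2)
        for f in calibration.frequencies
        for c in Channel
    }


def quadratic_models(calibration):
    return [
        calibration.model(f, c)
        for f in calibration.frequencies
        for c in (Channel.IN_PHASE, Channel.QUADRATURE)
    ]


class TestLinearInit:
    def test_round_trip_on_published_quadrature_models(self, linear_calibration):
        models = linear_calibration.channel_models(Channel.QUADRATURE)
        responses = [m.predict(1.0, 1.0) for m in models]
        assert responses == pytest.approx([0.876, 0.560])
        res = linear_init(models, responses)
        assert (res.x1, res.x2) == pytest.approx((1.0, 1.0), abs=1e-9)

    def test_intercept_responses_map_to_origin(self, linear_calibration):
        models = linear_calibration.channel_models(Channel.QUADRATURE)
        res = linear_init(models, [m.alpha[0] for m in models])
        assert (res.x1, res.x2) == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_published_slopes_flag_ill_conditioning(self, linear_calibration):
        # det ~ 6.2e-3 against entries ~0.5: condition number ~147
        models = linear_calibration.channel_models(Channel.QUADRATURE)
        res = linear_init(models, [0.5, 0.3])
        assert res.condition_warning
        assert res.condition_number == pytest.approx(146.6, rel=1e-2)

    def test_augmented_path_engages_when_inphase_supplied(self, linear_calibration):
        mq = linear_calibration.channel_models(Channel.QUADRATURE)
        mi = linear_calibration.channel_models(Channel.IN_PHASE)
        yq = [m.predict(1.5, 2.5) for m in mq]
        yi = [m.predict(1.5, 2.5) for m in mi]
        res = linear_init(mq, yq, inphase_models=mi, inphase_responses=yi)
        assert res.augmented
        # consistent responses: the 4x2 least-squares still recovers exactly
        assert (res.x1, res.x2) == pytest.approx((1.5, 2.5), abs=1e-9)

    def test_singular_slopes_direct_to_augmented_path(self):
        mk = lambda f, a: RegressionModel(
            alpha=a, frequency=f, channel=Channel.QUADRATURE, form=ModelForm.LINEAR
        )
        models = [mk(5000.0, (0.0, 0.4, 0, 0.8, 0)), mk(10000.0, (0.0, 0.2, 0, 0.4, 0))]
        with pytest.raises(np.linalg.LinAlgError, match="augmented"):
            linear_init(models, [1.0, 0.5])

    def test_requires_linear_form(self, quadratic_calibration):
        models = quadratic_calibration.channel_models(Channel.QUADRATURE)
        with pytest.raises(ValueError, match="linear-form"):
            linear_init(models, [0.5, 0.3])


class TestNewtonRefine:
    def test_noise_free_round_trip(self, quadratic_calibration):
        models = quadratic_models(quadratic_calibration)
        y = [m.predict(2.0, 3.0) for m in models]
        res = newton_refine(models, y, (1.0, 1.0))
        assert res.converged
        assert (res.x1_hat, res.x2_hat) == pytest.approx((2.0, 3.0), abs=1e-6)

    def test_fixed_point_needs_no_iterations(self, quadratic_calibration):
        models = quadratic_models(quadratic_calibration)
        y = [m.predict(0.0, 0.0) for m in models]
        res = newton_refine(models, y, (0.0, 0.0))
        assert res.converged
        assert res.iterations == 0

    def test_estimates_tighten_as_noise_shrinks(self, quadratic_calibration, rng):
        models = quadratic_models(quadratic_calibration)
        clean = np.array([m.predict(2.0, 2.0) for m in models])
        mean_abs = {}
        for sigma in (0.08, 0.01):
            errs = []
            for _ in range(150):
                y = clean + rng.normal(0.0, sigma, clean.size)
                res = newton_refine(models, y, (2.0, 2.0))
                errs.append(abs(res.x1_hat - 2.0) + abs(res.x2_hat - 2.0))
            mean_abs[sigma] = np.mean(errs)
        assert mean_abs[0.01] < mean_abs[0.08]

    def test_nonconvergence_reports_instead_of_raising(self, quadratic_calibration):
        models = quadratic_models(quadratic_calibration)
        y = [m.predict(1.0, 1.0) for m in models]
        res = newton_refine(models, y, (8.0, 8.0), max_iter=1)
        assert not res.converged

    def test_linear_init_beats_midpoint_start_on_average(self, rng):
        # self-consistent calibration: linear + quadratic forms fitted to
        # the same noise-free dataset, as in the real calibration workflow
        records = generate(GeneratorConfig(noise_sigma=0.0, replicates=1))
        freqs = (5000.0, 10000.0)
        linear = CalibrationSet.from_models(
            [fit(records, f, Channel.QUADRATURE, ModelForm.LINEAR) for f in freqs]
        )
        quadratic = CalibrationSet.from_models(
            [fit(records, f, c, ModelForm.QUADRATIC) for f in freqs for c in Channel]
        )
        models = quadratic_models(quadratic)
        lin_models = linear.channel_models(Channel.QUADRATURE)
        iters_lin, iters_mid = [], []
        for _ in range(100):
            x1, x2 = rng.uniform(0.0, 4.0, 2)
            y = [m.predict(x1, x2) for m in models]
            yq = [m.predict(x1, x2) for m in lin_models]
            init = linear_init(lin_models, yq)
            start = (np.clip(init.x1, 0, 8), np.clip(init.x2, 0, 8))
            iters_lin.append(newton_refine(models, y, start).iterations)
            iters_mid.append(newton_refine(models, y, (2.0, 2.0)).iterations)
        assert np.mean(iters_lin) <= np.mean(iters_mid)


class TestEstimate:
    def test_noise_free_round_trip(self, quadratic_calibration, linear_calibration):
        res = estimate(
            forward_responses(quadratic_calibration, 0.5, 0.5),
            quadratic=quadratic_calibration,
            linear=linear_calibration,
        )
        assert (res.x1_hat, res.x2_hat) == pytest.approx((0.5, 0.5), abs=1e-6)
        assert res.x1_init is not None  # audit trail of the linear stage

    def test_water_reference_maps_to_origin(
        self, quadratic_calibration, linear_calibration
    ):
        res = estimate(
            forward_responses(quadratic_calibration, 0.0, 0.0),
            quadratic=quadratic_calibration,
            linear=linear_calibration,
        )
        assert (res.x1_hat, res.x2_hat) == pytest.approx((0.0, 0.0), abs=1e-6)

    def test_missing_channels_named_in_error(
        self, quadratic_calibration, linear_calibration
    ):
        meas = forward_responses(quadratic_calibration, 1.0, 1.0)
        del meas[(10000.0, Channel.IN_PHASE)]
        del meas[(10000.0, Channel.QUADRATURE)]
        with pytest.raises(ValueError, match=r"10000.*in_phase"):
            estimate(meas, quadratic=quadratic_calibration, linear=linear_calibration)

    def test_alternate_refinement_modes_run(
        self, quadratic_calibration, linear_calibration
    ):
        meas = forward_responses(quadratic_calibration, 1.0, 2.0)
        for mode in ("quadrature_only", "mixed"):
            res = estimate(
                meas,
                quadratic=quadratic_calibration,
                linear=linear_calibration,
                mode=mode,
            )
            assert 0.0 <= res.x1_hat <= 8.0 and 0.0 <= res.x2_hat <= 8.0

    def test_unknown_mode_rejected(self, quadratic_calibration, linear_calibration):
        with pytest.raises(ValueError, match="mode"):
            estimate(
                forward_responses(quadratic_calibration, 1.0, 1.0),
                quadratic=quadratic_calibration,
                linear=linear_calibration,
                mode="bogus",
            )


class TestNonUniqueness:
    """Single-frequency inversion is ambiguous; two frequencies are not."""

    def test_single_channel_quadratic_has_two_admissible_roots(
        self, quadratic_calibration
    ):
        m = quadratic_calibration.model(5000.0, Channel.IN_PHASE)
        y = m.predict(6.0, 0.0)
        roots = admissible_roots(m, y, fixed_x2=0.0)
        assert len(roots) == 2
        assert roots[0] == pytest.approx(6.0, abs=1e-9)
        assert roots[1] > roots[0]

    def test_two_frequency_procedure_resolves_the_ambiguity(
        self, quadratic_calibration, linear_calibration
    ):
        models = quadratic_models(quadratic_calibration)
        y = [m.predict(6.0, 0.0) for m in models]
        m5 = quadratic_calibration.model(5000.0, Channel.IN_PHASE)
        roots = admissible_roots(m5, m5.predict(6.0, 0.0), fixed_x2=0.0)
        # refinement from either ambiguous root lands on the same solution
        for root in roots:
            res = newton_refine(models, y, (root, 0.0))
            assert (res.x1_hat, res.x2_hat) == pytest.approx((6.0, 0.0), abs=1e-6)
        full = estimate(
            forward_responses(quadratic_calibration, 6.0, 0.0),
            quadratic=quadratic_calibration,
            linear=linear_calibration,
        )
        assert (full.x1_hat, full.x2_hat) == pytest.approx((6.0, 0.0), abs=1e-6)

    def test_candidate_enumeration_sees_every_pairwise_root(
        self, quadratic_calibration
    ):
        models = quadratic_calibration.channel_models(Channel.QUADRATURE)
        y = [m.predict(2.0, 3.0) for m in models]
        cands = candidate_starts(models, y)
        assert any(
            abs(c1 - 2.0) < 1e-6 and abs(c2 - 3.0) < 1e-6 for c1, c2 in cands
        )
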