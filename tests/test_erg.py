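"""Pigment templates, the four-cone Hill model, fitting and spectra."""

import numpy as np
import pandas as pd
import pytest

from clccmap.erg import (
    CONE_CLASSES,
    DEFAULT_IRRADIANCES,
    DEFAULT_LAMBDA_MAX,
    DEFAULT_WAVELENGTHS,
    ConeParams,
    PigmentTemplate,
    default_templates,
    fit_cone_components,
    forward_model,
    group_depression,
    mean_sem_spectra,
    sensitivity_from_data,
    sensitivity_spectrum,
    template_absorbance,
)
from clccmap.simulate import ERGSimConfig, default_wt_cone_params, simulate_erg
from oracles import govardovskii_reference


def test_template_peaks_at_lambda_max():
    for cone, lmax in DEFAULT_LAMBDA_MAX.items():
        peak = template_absorbance(cone, lmax)
        assert peak == pytest.approx(1.0, abs=1e-6)
        for lam in (lmax - 60, lmax + 60):
            assert template_absorbance(cone, lam) < peak


def test_template_matches_hand_transcribed_govardovskii():
    """Peak-normalised template equals an independently transcribed
    Govardovskii (2000) formula."""
    for lmax in (362.0, 415.0, 480.0, 570.0):
        norm = govardovskii_reference(lmax, lmax)  # normalised at lambda_max
        for lam in (350.0, 420.0, 500.0, 630.0):
            expected = govardovskii_reference(lmax, lam) / norm
            got = template_absorbance(lmax, lam)
            assert got == pytest.approx(expected, rel=1e-9)
        # the value at lambda_max is within 0.1% of the true curve maximum
        grid = np.linspace(300.0, 700.0, 4001)
        true_max = max(govardovskii_reference(lmax, l) for l in grid)
        assert norm == pytest.approx(true_max, rel=1e-3)


def test_lognormal_template_is_supported_alternative():
    t = PigmentTemplate("UV", 362.0, form="lognormal")
    assert t.absorbance(362.0) == pytest.approx(1.0, abs=1e-9)
    assert t.absorbance(450.0) < 0.5


def test_template_support_enforced():
    t = default_templates()["UV"]
    with pytest.raises(ValueError):
        t.absorbance(250.0)


def test_cone_params_validation():
    with pytest.raises(ValueError):
        ConeParams({c: -1.0 for c in CONE_CLASSES}, {c: 1.0 for c in CONE_CLASSES})
    with pytest.raises(ValueError):
        ConeParams({c: 1.0 for c in CONE_CLASSES}, {c: 0.0 for c in CONE_CLASSES})


def test_forward_model_saturation_and_additivity():
    params = default_wt_cone_params()
    templates = default_templates()
    lam = 480.0
    # monotone in irradiance, saturating at sum of weighted V_c
    amps = [forward_model(params, templates, i, lam) for i in (1e2, 1e4, 1e8)]
    assert amps[0] < amps[1] < amps[2]
    ceiling = sum(
        params.amplitude_max[c] * templates[c].absorbance(lam)
        for c in CONE_CLASSES
    )
    assert amps[2] < ceiling
    assert amps[2] == pytest.approx(ceiling, rel=0.01)
    # half-saturation: a single-cone model at its K gives V/2
    single = ConeParams(
        {"UV": 0.0, "blue": 0.0, "green": 100.0, "red": 0.0},
        {c: 5000.0 for c in CONE_CLASSES},
    )
    v = forward_model(single, templates, 5000.0, DEFAULT_LAMBDA_MAX["green"])
    assert v == pytest.approx(50.0, rel=1e-9)


def test_fit_recovers_noiseless_parameters():
    params = default_wt_cone_params()
    cfg = ERGSimConfig(noise_sd_floor=0.0, noise_sd_frac=0.0, replicates=1)
    df = simulate_erg(cfg, {"wt": params})
    fit = fit_cone_components(df, n_starts=8, seed=0)
    for c in CONE_CLASSES:
        assert fit.params.amplitude_max[c] == pytest.approx(
            params.amplitude_max[c], rel=1e-3
        )
        assert fit.params.half_saturation[c] == pytest.approx(
            params.half_saturation[c], rel=1e-2
        )
    assert fit.sse < 1e-6


def test_fit_requires_enough_cells():
    df = pd.DataFrame(
        {
            "wavelength_nm": [400.0] * 4,
            "irradiance": [1e3, 1e4, 1e5, 1e6],
            "amplitude_uv": [1.0, 2.0, 3.0, 4.0],
        }
    )
    with pytest.raises(ValueError, match="cells"):
        fit_cone_components(df)


def test_fit_all_zero_amplitudes_warns():
    lam, irr = np.meshgrid(DEFAULT_WAVELENGTHS, DEFAULT_IRRADIANCES)
    df = pd.DataFrame(
        {
            "wavelength_nm": lam.ravel(),
            "irradiance": irr.ravel(),
            "amplitude_uv": 0.0,
        }
    )
    with pytest.warns(UserWarning):
        fit = fit_cone_components(df)
    assert all(v == 0.0 for v in fit.params.amplitude_max.values())


def test_sensitivity_spectrum_units_and_constant_quanta():
    params = default_wt_cone_params()
    spec = sensitivity_spectrum(params, q0=2500.0)
    v = np.array(
        [
            forward_model(params, default_templates(), 2500.0, l)
            for l in spec.wavelengths_nm
        ]
    )
    # S = V/Q0 in uV -> nV per quantum
    assert spec.mean_nv_per_quantum == pytest.approx(v / 2500.0 * 1000.0)
    assert np.all(spec.mean_nv_per_quantum > 0)


def test_sensitivity_from_data_uses_nearest_irradiance_and_sem():
    df = simulate_erg(ERGSimConfig(seed=4), {"wt": default_wt_cone_params()})
    spec = sensitivity_from_data(df, q0=2500.0)
    assert spec.n_eyes == 4
    assert np.all(spec.sem_nv_per_quantum >= 0)
    assert list(spec.wavelengths_nm) == list(DEFAULT_WAVELENGTHS)


def test_mean_sem_spectra():
    per_eye = [np.array([1.0, 2.0]), np.array([3.0, 4.0])]
    spec = mean_sem_spectra(per_eye, [400.0, 500.0])
    assert spec.mean_nv_per_quantum == pytest.approx([2.0, 3.0])
    # SEM = sd/sqrt(n): sd = sqrt(2), n = 2
    assert spec.sem_nv_per_quantum == pytest.approx([1.0, 1.0])


def test_group_depression_on_scaled_params():
    wt = sensitivity_spectrum(default_wt_cone_params())
    mut = sensitivity_spectrum(default_wt_cone_params().scaled(0.4))
    dep = group_depression(wt, mut)
    assert dep["percent_at_peak"] == pytest.approx(60.0, abs=1e-9)
    assert dep["mean_percent"] == pytest.approx(60.0, abs=1e-9)


def test_group_depression_requires_common_grid():
    wt = sensitivity_spectrum(default_wt_cone_params())
    mut = sensitivity_spectrum(
        default_wt_cone_params(), wavelengths_nm=[400.0, 500.0]
    )
    with pytest.raises(ValueError):
        group_depression(wt, mut)
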