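"""Four-cone spectral decomposition of zebrafish photopic ERG amplitudes.

The isolated cone (PIII) or ON-bipolar (b2) ERG amplitude evoked by a stimulus
of quantal irradiance I (hv.um^-2.s^-1) at wavelength lambda is modelled as a
sum of four spectrally weighted saturation (Hill, n = 1) functions, one per
cone class:

    V(I, lambda) = sum_c  V_c * I / (I + K_c) * A_c(lambda)

where V_c is the amplitude maximum of cone class c (uV), K_c its
half-saturation irradiance, and A_c the peak-normalised absorbance template
of its visual pigment, with lambda_max defaults 362 (UV), 415 (blue),
480 (green) and 570 nm (red).  Sensitivity spectra at constant quanta Q0
(default 2500 hv.um^-2.s^-1) are S(lambda) = V(Q0, lambda) / Q0, reported in
nV per quantum.

The default template is the Govardovskii et al. (2000) A1 alpha-band
template; a plain log-normal alternative is selectable.  The beta band is
omitted: it is negligible above 350 nm at these lambda_max values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

CONE_CLASSES = ("UV", "blue", "green", "red")
DEFAULT_LAMBDA_MAX = {"UV": 362.0, "blue": 415.0, "green": 480.0, "red": 570.0}

UV_TO_NV = 1000.0  # amplitudes are uV internally, sensitivities nV/quantum

DEFAULT_Q0 = 2500.0
DEFAULT_WAVELENGTHS = tuple(np.arange(350.0, 631.0, 35.0))  # 9 points
# 7 log-spaced irradiances spanning 4 decades, centred on Q0 so that the
# constant-quanta level is an actual grid point
DEFAULT_IRRADIANCES = tuple(DEFAULT_Q0 * 10.0 ** ((np.arange(7) - 3) * (2.0 / 3.0)))

LAMBDA_SUPPORT = (300.0, 700.0)


# ---------------------------------------------------------------------------
# pigment templates


def _govardovskii_alpha(lambda_max: float, lam: np.ndarray) -> np.ndarray:
    """A1-pigment alpha-band template (Govardovskii et al. 2000)."""
    x = lambda_max / lam
    A, B, C, D = 69.7, 28.0, -14.9, 0.674
    b, c = 0.922, 1.104
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    return 1.0 / (
        np.exp(A * (a - x)) + np.exp(B * (b - x)) + np.exp(C * (c - x)) + D
    )


def _lognormal(lambda_max: float, lam: np.ndarray, sigma: float = 0.07) -> np.ndarray:
    return np.exp(-0.5 * (np.log(lam / lambda_max) / sigma) ** 2)


@dataclass(frozen=True)
class PigmentTemplate:
    """Peak-normalised visual-pigment absorbance spectrum."""

    cone_class: str
    lambda_max_nm: float
    form: str = "govardovskii"  # or "lognormal"

    def absorbance(self, lam: float | np.ndarray) -> np.ndarray | float:
        lam_arr = np.asarray(lam, dtype=float)
        if np.any(lam_arr < LAMBDA_SUPPORT[0]) or np.any(lam_arr > LAMBDA_SUPPORT[1]):
            raise ValueError(
                f"wavelength outside template support {LAMBDA_SUPPORT}"
            )
        if self.form == "govardovskii":
            raw = _govardovskii_alpha(self.lambda_max_nm, lam_arr)
            peak = _govardovskii_alpha(
                self.lambda_max_nm, np.asarray([self.lambda_max_nm])
            )[0]
        elif self.form == "lognormal":
            raw = _lognormal(self.lambda_max_nm, lam_arr)
            peak = 1.0
        else:
            raise ValueError(f"unknown template form {self.form!r}")
        out = raw / peak
        return float(out) if np.isscalar(lam) else out


def default_templates(form: str = "govardovskii") -> dict[str, PigmentTemplate]:
    return {
        c: PigmentTemplate(c, DEFAULT_LAMBDA_MAX[c], form) for c in CONE_CLASSES
    }


def template_absorbance(
    cone_class_or_lambda_max: str | float, lam: float, form: str = "govardovskii"
) -> float:
    """Relative absorbance at wavelength `lam` for a cone class preset or an
    explicit lambda_max."""
    if isinstance(cone_class_or_lambda_max, str):
        t = PigmentTemplate(
            cone_class_or_lambda_max,
            DEFAULT_LAMBDA_MAX[cone_class_or_lambda_max],
            form,
        )
    else:
        t = PigmentTemplate("custom", float(cone_class_or_lambda_max), form)
    return float(t.absorbance(lam))


# ---------------------------------------------------------------------------
# forward model


@dataclass(frozen=True)
class ConeParams:
    """Amplitude maxima V_c (uV) and half-saturation irradiances K_c
    (hv.um^-2.s^-1) per cone class, plus the saturation exponent."""

    amplitude_max: Mapping[str, float]  # V_c >= 0
    half_saturation: Mapping[str, float]  # K_c > 0
    hill_exponent: float = 1.0

    def __post_init__(self) -> None:
        for c in CONE_CLASSES:
            if self.amplitude_max[c] < 0:
                raise ValueError(f"V_{c} must be >= 0")
            if self.half_saturation[c] <= 0:
                raise ValueError(f"K_{c} must be > 0")
        if self.hill_exponent <= 0:
            raise ValueError("hill_exponent must be > 0")

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.amplitude_max[c] for c in CONE_CLASSES]
            + [math.log10(self.half_saturation[c]) for c in CONE_CLASSES]
        )

    @staticmethod
    def from_vector(vec: np.ndarray, hill_exponent: float = 1.0) -> "ConeParams":
        return ConeParams(
            {c: float(vec[i]) for i, c in enumerate(CONE_CLASSES)},
            {c: float(10.0 ** vec[4 + i]) for i, c in enumerate(CONE_CLASSES)},
            hill_exponent,
        )

    def scaled(self, factor: float) -> "ConeParams":
        return ConeParams(
            {c: v * factor for c, v in self.amplitude_max.items()},
            dict(self.half_saturation),
            self.hill_exponent,
        )


def forward_model(
    params: ConeParams,
    templates: Mapping[str, PigmentTemplate],
    irradiance: float | np.ndarray,
    wavelength: float | np.ndarray,
) -> np.ndarray | float:
    """Model amplitude V(I, lambda); broadcasts over array inputs."""
    I = np.asarray(irradiance, dtype=float)
    if np.any(I < 0):
        raise ValueError("irradiance must be >= 0")
    lam = np.asarray(wavelength, dtype=float)
    n = params.hill_exponent
    out = np.zeros(np.broadcast_shapes(I.shape, lam.shape))
    for c in CONE_CLASSES:
        V = params.amplitude_max[c]
        K = params.half_saturation[c]
        out = out + V * (I**n) / (I**n + K**n) * templates[c].absorbance(lam)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    params: ConeParams
    sse: float
    n_starts: int
    best_start_index: int
    converged: bool
    residuals: pd.DataFrame | None = None


def fit_cone_components(
    data: pd.DataFrame,
    templates: Mapping[str, PigmentTemplate] | None = None,
    n_starts: int = 16,
    seed: int = 0,
    v_max_bound: float | None = None,
    log10_k_bounds: tuple[float, float] = (0.0, 8.0),
    hill_exponent: float = 1.0,
) -> FitResult:
    """Bounded multi-start least-squares fit of the four-cone model.

    `data` must have columns wavelength_nm, irradiance, amplitude_uv (one
    group and response type at a time).  V_c are bounded below by 0; K_c are
    optimised on a log10 scale within `log10_k_bounds`.  The best of
    `n_starts` seeded starts wins (tie-break: lowest SSE, then smallest
    sum of V_c).
    """
    templates = templates or default_templates()
    required = {"wavelength_nm", "irradiance", "amplitude_uv"}
    if not required <= set(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    lam = data["wavelength_nm"].to_numpy(float)
    irr = data["irradiance"].to_numpy(float)
    amp = data["amplitude_uv"].to_numpy(float)
    n_cells = len({(l, i) for l, i in zip(lam, irr)})
    if n_cells < 8:
        raise ValueError(
            f"only {n_cells} distinct (irradiance, wavelength) cells;"
            " need >= 8 (the parameter count)"
        )
    if np.allclose(amp, 0.0):
        warnings.warn("all amplitudes are zero; returning V_c = 0")
        params = ConeParams(
            {c: 0.0 for c in CONE_CLASSES},
            {c: 10.0 ** np.mean(log10_k_bounds) for c in CONE_CLASSES},
            hill_exponent,
        )
        return FitResult(params, 0.0, 0, -1, True, None)

    A = np.column_stack([templates[c].absorbance(lam) for c in CONE_CLASSES])
    upper_v = v_max_bound if v_max_bound is not None else np.inf

    def residual(vec: np.ndarray) -> np.ndarray:
        V = vec[:4]
        K = 10.0 ** vec[4:]
        n = hill_exponent
        sat = (irr[:, None] ** n) / (irr[:, None] ** n + K[None, :] ** n)
        model = (sat * A) @ V
        return model - amp

    lo = np.array([0.0] * 4 + [log10_k_bounds[0]] * 4)
    hi = np.array([upper_v] * 4 + [log10_k_bounds[1]] * 4)

    rng = np.random.default_rng(seed)
    amp_scale = max(np.max(np.abs(amp)), 1e-6)
    data_lo = math.log10(max(irr.min(), 10.0 ** log10_k_bounds[0]))
    data_hi = math.log10(min(irr.max(), 10.0 ** log10_k_bounds[1]))
    starts = [
        np.array([amp_scale] * 4 + [0.5 * (data_lo + data_hi)] * 4)
    ]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(
            np.concatenate(
                [
                    rng.uniform(0.0, 2.0 * amp_scale, 4),
                    rng.uniform(data_lo, data_hi, 4),
                ]
            )
        )

    best = None
    for k, s0 in enumerate(starts):
        s0 = np.clip(s0, lo, np.where(np.isfinite(hi), hi, s0 + 1.0))
        try:
            sol = least_squares(residual, s0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        sse = float(np.sum(sol.fun**2))
        vsum = float(np.sum(sol.x[:4]))
        key = (sse, vsum)
        if best is None or key < best[0]:
            best = (key, k, sol)
    if best is None:
        raise RuntimeError("all optimisation starts failed")
    (sse, _), best_idx, sol = best
    params = ConeParams.from_vector(sol.x, hill_exponent)
    resid = pd.DataFrame(
        {
            "wavelength_nm": lam,
            "irradiance": irr,
            "amplitude_uv": amp,
            "fitted_uv": amp + sol.fun,
            "residual_uv": sol.fun,
        }
    )
    return FitResult(params, sse, len(starts), best_idx, bool(sol.success), resid)


# ---------------------------------------------------------------------------
# sensitivity spectra


@dataclass
class SensitivitySpectrum:
    """Constant-quanta sensitivity (nV per quantum) across the spectrum."""

    wavelengths_nm: np.ndarray
    mean_nv_per_quantum: np.ndarray
    sem_nv_per_quantum: np.ndarray
    n_eyes: int
    quanta_level: float = DEFAULT_Q0

    def __post_init__(self) -> None:
        if self.quanta_level <= 0:
            raise ValueError("quanta level must be > 0")


def sensitivity_spectrum(
    params: ConeParams,
    templates: Mapping[str, PigmentTemplate] | None = None,
    q0: float = DEFAULT_Q0,
    wavelengths_nm: Sequence[float] = DEFAULT_WAVELENGTHS,
) -> SensitivitySpectrum:
    """S(lambda) = V(Q0, lambda)/Q0, converted uV -> nV per quantum."""
    templates = templates or default_templates()
    lam = np.asarray(wavelengths_nm, dtype=float)
    v = np.asarray(forward_model(params, templates, q0, lam))
    s = v / q0 * UV_TO_NV
    return SensitivitySpectrum(lam, s, np.zeros_like(s), n_eyes=0, quanta_level=q0)


def sensitivity_from_data(
    data: pd.DataFrame, q0: float = DEFAULT_Q0
) -> SensitivitySpectrum:
    """Per-eye constant-quanta sensitivities averaged across eyes, with SEM.

    Uses rows at the irradiance closest to Q0; each eye contributes the mean
    amplitude of its replicates at that level, per wavelength.
    """
    eye_col = "eye_id" if "eye_id" in data.columns else "replicate"
    irr = data["irradiance"].to_numpy(float)
    nearest = irr[np.argmin(np.abs(np.log10(irr) - np.log10(q0)))]
    sel = data[np.isclose(data["irradiance"], nearest)]
    per_eye = (
        sel.groupby([eye_col, "wavelength_nm"])["amplitude_uv"].mean().unstack()
    )
    s = per_eye / q0 * UV_TO_NV
    mean = s.mean(axis=0)
    n = len(s)
    sem = s.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else mean * 0.0
    return SensitivitySpectrum(
        mean.index.to_numpy(float),
        mean.to_numpy(float),
        np.nan_to_num(sem.to_numpy(float)),
        n_eyes=n,
        quanta_level=q0,
    )


def mean_sem_spectra(
    per_eye: Sequence[np.ndarray], wavelengths_nm: Sequence[float],
    q0: float = DEFAULT_Q0,
) -> SensitivitySpectrum:
    """Arithmetic mean and SEM (= sd/sqrt(n)) across per-eye spectra."""
    arr = np.asarray(per_eye, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("need at least one per-eye spectrum")
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    sem = arr.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros_like(mean)
    return SensitivitySpectrum(
        np.asarray(wavelengths_nm, float), mean, sem, n_eyes=n, quanta_level=q0
    )


def group_depression(
    wt: SensitivitySpectrum, mut: SensitivitySpectrum,
    floor_fraction: float = 0.05,
) -> dict[str, float]:
    """Percent depression of a mutant spectrum relative to wild type.

    percent_at_peak = 100*(1 - mut_max/wt_max); mean_percent averages the
    per-wavelength depression over wavelengths where the wild-type
    sensitivity exceeds `floor_fraction` of its maximum.
    """
    if wt.wavelengths_nm.shape != mut.wavelengths_nm.shape or np.any(
        wt.wavelengths_nm != mut.wavelengths_nm
    ):
        raise ValueError("spectra must share a common wavelength grid")
    wt_s = wt.mean_nv_per_quantum
    mut_s = mut.mean_nv_per_quantum
    peak = float(wt_s.max())
    keep = wt_s > floor_fraction * peak
    percent_at_peak = 100.0 * (1.0 - mut_s.max() / peak)
    mean_percent = float(np.mean(100.0 * (1.0 - mut_s[keep] / wt_s[keep])))
    return {"percent_at_peak": float(percent_at_peak), "mean_percent": mean_percent}
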