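"""Camera spectral response estimation and band-response / NDVI prediction.

A consumer camera channel integrates surface reflectance against its spectral
sensitivity.  Given a set of chart panels with known reflectance spectra
(measured by spectroradiometer) and the raw channel value each panel produced,
the per-channel sensitivity curve is recovered by a smoothness-regularised
non-negative linear inversion.  The estimated curves then predict the band
response any reflectance spectrum would produce in the camera, and from the
red and near-infrared predictions a predicted NDVI.

The colour body contributes red/green/blue channels; the near-infrared
converted body contributes a single channel read from its red Bayer sites
(the channel with the strongest response through the 720 nm long-pass filter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

CHANNELS = ("red", "green", "blue", "nir")

#: Peak sensitivities (nm) of the consumer camera pair the synthetic defaults
#: emulate: colour-body red/green/blue and the red Bayer channel of the
#: near-infrared converted body.
DEFAULT_PEAKS_NM = {"blue": 470.0, "green": 530.0, "red": 606.0, "nir": 740.0}


class IllPosedError(ValueError):
    """Raised when a response inversion has a rank-deficient panel design."""

    def __init__(self, message: str, condition: float | None = None, rank: int | None = None):
        super().__init__(message)
        self.condition = condition
        self.rank = rank


class DisjointSupportError(ValueError):
    """Raised when a spectrum and a response share no wavelength support."""


@dataclass
class Spectrum:
    """Reflectance spectrum on a monotone wavelength grid (nm)."""

    wavelength_nm: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelength_nm.ndim != 1 or self.wavelength_nm.size < 2:
            raise ValueError("wavelength grid must be 1-D with >= 2 samples")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.reflectance.shape != self.wavelength_nm.shape:
            raise ValueError("reflectance and wavelength grids differ in length")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance must be finite")
        if self.reflectance.min() < -0.05 or self.reflectance.max() > 1.05:
            raise ValueError("reflectance outside [0,1] beyond measurement tolerance")

    def resample(self, grid_nm: np.ndarray) -> "Spectrum":
        r = np.interp(grid_nm, self.wavelength_nm, self.reflectance, left=np.nan, right=np.nan)
        # clip the tiny negatives linear interpolation cannot create but
        # callers may have introduced within tolerance
        return Spectrum(np.asarray(grid_nm, dtype=float), np.nan_to_num(np.clip(r, 0.0, 1.0)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wavelength_nm": self.wavelength_nm, "reflectance": self.reflectance})


@dataclass
class SpectralResponse:
    """Per-channel camera sensitivity vs wavelength (arbitrary linear units)."""

    wavelength_nm: np.ndarray
    sensitivity: np.ndarray
    channel: str

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.sensitivity = np.asarray(self.sensitivity, dtype=float)
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.sensitivity.shape != self.wavelength_nm.shape:
            raise ValueError("sensitivity and wavelength grids differ in length")
        if np.any(self.sensitivity < -1e-12):
            raise ValueError("sensitivity must be non-negative")
        self.sensitivity = np.maximum(self.sensitivity, 0.0)

    @property
    def peak_nm(self) -> float:
        return float(self.wavelength_nm[int(np.argmax(self.sensitivity))])

    def integral(self) -> float:
        return float(np.trapezoid(self.sensitivity, self.wavelength_nm))


@dataclass(frozen=True)
class BandResponse:
    """Predicted camera-linear channel value for one spectrum."""

    channel: str
    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("band response must be non-negative")


def gaussian_response(
    peak_nm: float, sigma_nm: float, channel: str,
    grid_nm: np.ndarray | None = None, amplitude: float = 1.0,
) -> SpectralResponse:
    """Synthetic bell-shaped channel sensitivity (test/scene construction)."""
    if grid_nm is None:
        grid_nm = np.arange(400.0, 801.0, 5.0)
    grid_nm = np.asarray(grid_nm, dtype=float)
    s = amplitude * np.exp(-0.5 * ((grid_nm - peak_nm) / sigma_nm) ** 2)
    return SpectralResponse(grid_nm, s, channel)


def default_camera_responses(grid_nm: np.ndarray | None = None) -> dict[str, SpectralResponse]:
    """Bell-shaped responses at the consumer-camera peak wavelengths."""
    if grid_nm is None:
        grid_nm = np.arange(400.0, 801.0, 1.0)  # 1 nm so peaks sit on the grid
    sigmas = {"blue": 35.0, "green": 35.0, "red": 40.0, "nir": 35.0}
    return {
        ch: gaussian_response(DEFAULT_PEAKS_NM[ch], sigmas[ch], ch, grid_nm)
        for ch in CHANNELS
    }


# ---------------------------------------------------------------------------
# band-response prediction
# ---------------------------------------------------------------------------

def predict_band_response(spectrum: Spectrum, response: SpectralResponse) -> BandResponse:
    """Integrate reflectance x sensitivity over wavelength (trapezoidal).

    Both curves are linearly resampled onto the union grid restricted to the
    overlap of their supports.
    """
    lo = max(spectrum.wavelength_nm[0], response.wavelength_nm[0])
    hi = min(spectrum.wavelength_nm[-1], response.wavelength_nm[-1])
    if hi <= lo:
        raise DisjointSupportError(
            f"spectrum [{spectrum.wavelength_nm[0]:.0f},{spectrum.wavelength_nm[-1]:.0f}] nm and "
            f"response [{response.wavelength_nm[0]:.0f},{response.wavelength_nm[-1]:.0f}] nm do not overlap"
        )
    grid = np.union1d(spectrum.wavelength_nm, response.wavelength_nm)
    grid = grid[(grid >= lo) & (grid <= hi)]
    refl = np.interp(grid, spectrum.wavelength_nm, spectrum.reflectance)
    sens = np.interp(grid, response.wavelength_nm, response.sensitivity)
    value = float(np.trapezoid(refl * sens, grid))
    return BandResponse(response.channel, max(value, 0.0))


def ndvi(nir: float, red: float, eps: float = 1e-12) -> float:
    denom = nir + red
    if abs(denom) <= eps:
        raise ZeroDivisionError("NDVI undefined: red + NIR response is zero")
    return (nir - red) / denom


def predict_ndvi(
    spectrum: Spectrum,
    red_resp: SpectralResponse,
    nir_resp: SpectralResponse,
    wb_gains: tuple[float, float] | None = None,
    exposures_s: tuple[float, float] | None = None,
) -> float:
    """Predicted NDVI of a surface with the given reflectance spectrum.

    The predicted camera value of a channel is the band-response integral
    scaled by that body's exposure time (``exposures_s = (t_colour, t_nir)``)
    and the white-balance gain (``wb_gains = (g_red, g_nir)``, see
    :func:`shoremapper.texturing.white_balance_gains`).  With Spectralon
    gains and the survey exposures, a spectrally flat surface predicts NDVI
    exactly 0; with all factors at unity the raw band integrals are compared
    directly.
    """
    g_red, g_nir = (1.0, 1.0) if wb_gains is None else wb_gains
    t_col, t_nir = (1.0, 1.0) if exposures_s is None else exposures_s
    r = g_red * t_col * predict_band_response(spectrum, red_resp).value
    n = g_nir * t_nir * predict_band_response(spectrum, nir_resp).value
    return ndvi(n, r)


# ---------------------------------------------------------------------------
# response estimation (regularised inversion)
# ---------------------------------------------------------------------------

def estimate_response(
    panel_spectra: list[Spectrum],
    panel_values: np.ndarray,
    smoothness_weight: float = 30.0,
    channel: str = "red",
    grid_step_nm: float = 5.0,
    grid_range_nm: tuple[float, float] = (400.0, 800.0),
    min_effective_rank: int = 6,
) -> tuple[SpectralResponse, float]:
    """Estimate one channel's sensitivity curve from chart-panel data.

    Solves, for the sensitivity ``h`` on a ``grid_step_nm`` grid,

        min_h >= 0   sum_p ( value_p - sum_k spectrum_p(l_k) h(l_k) dl )^2
                     + smoothness_weight^2 * ||D1 h||^2

    via NNLS on the stacked system, with ``D1`` the first-difference operator.

    Returns the response and the data-residual norm.  A panel set whose
    spectra are (numerically) linearly dependent — e.g. all flat — cannot
    constrain the curve and raises :class:`IllPosedError`.
    """
    values = np.asarray(panel_values, dtype=float).ravel()
    if len(panel_spectra) != values.size:
        raise ValueError("one raw value per panel required")
    grid = np.arange(grid_range_nm[0], grid_range_nm[1] + 0.5 * grid_step_nm, grid_step_nm)
    A = np.vstack([s.resample(grid).reflectance for s in panel_spectra]) * grid_step_nm
    # conditioning diagnostics on the data matrix alone
    sv = np.linalg.svd(A, compute_uv=False)
    tol = sv[0] * 1e-8 if sv[0] > 0 else 0.0
    rank = int(np.sum(sv > tol))
    if rank < min_effective_rank:
        cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
        raise IllPosedError(
            f"panel design is rank-deficient (effective rank {rank} < {min_effective_rank}); "
            "spectra are too similar to constrain a response curve",
            condition=cond, rank=rank,
        )
    n = grid.size
    D1 = np.diff(np.eye(n), axis=0)
    A_aug = np.vstack([A, smoothness_weight * D1])
    b_aug = np.concatenate([values, np.zeros(n - 1)])
    h, _ = optimize.nnls(A_aug, b_aug)
    residual = float(np.linalg.norm(A @ h - values))
    return SpectralResponse(grid, h, channel), residual


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def read_spectrum_csv(path) -> Spectrum:
    df = pd.read_csv(path)
    return Spectrum(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    spectrum.to_frame().to_csv(path, index=False)


def write_responses_csv(responses: dict[str, SpectralResponse], path) -> None:
    grids = [r.wavelength_nm for r in responses.values()]
    grid = grids[0]
    for g in grids[1:]:
        if g.shape != grid.shape or not np.allclose(g, grid):
            raise ValueError("responses must share a wavelength grid for CSV export")
    df = pd.DataFrame({"wavelength_nm": grid})
    for ch, r in responses.items():
        df[ch] = r.sensitivity
    df.to_csv(path, index=False)


def read_responses_csv(path) -> dict[str, SpectralResponse]:
    df = pd.read_csv(path)
    grid = df["wavelength_nm"].to_numpy()
    return {
        ch: SpectralResponse(grid, df[ch].to_numpy(), ch)
        for ch in df.columns
        if ch != "wavelength_nm"
    }
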