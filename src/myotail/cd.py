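"""Circular-dichroism quantification: MRE conversion, helicity, melt fitting.

Mean residue ellipticity (MRE, deg·cm²·dmol⁻¹) is the per-residue-normalized
CD signal; α-helical coiled coils show characteristic negative bands at
~208 and ~222 nm, and an MRE(222)/MRE(208) ratio above 1 is the classic
diagnostic of coiled-coil (vs isolated-helix) structure.  Helical content is
estimated against a fully-helical reference magnitude of 36,000 at 222 nm.
Thermal melts are treated as two-state and fitted with a logistic in
temperature; melts are first normalized so the fraction folded is 100% at
10 °C and 0% at 80 °C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

#: |MRE(222 nm)| of a fully helical construct (deg·cm²·dmol⁻¹).
FULL_HELIX_MRE_222 = 36_000.0

#: Temperatures anchoring melt normalization (°C): 100% folded / 0% folded.
MELT_ANCHOR_FOLDED = 10.0
MELT_ANCHOR_UNFOLDED = 80.0


class DegenerateRangeError(ValueError):
    """Raised when a melt has no signal change between its anchors."""


class UndefinedRatioError(ZeroDivisionError):
    """Raised when MRE(208) is too close to zero for the 222/208 ratio."""


@dataclass
class CDSpectrum:
    """Wavelength-indexed mean-residue-ellipticity record."""

    wavelengths_nm: np.ndarray
    mre: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.mre = np.asarray(self.mre, dtype=float)
        if self.wavelengths_nm.shape != self.mre.shape:
            raise ValueError("wavelengths and MRE must be aligned")
        d = np.diff(self.wavelengths_nm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavelengths must be strictly monotone")

    def mre_at(self, wavelength: float, interpolate_off_grid: bool = True) -> float:
        """MRE at the nearest sampled wavelength (linear interpolation off-grid)."""
        w = self.wavelengths_nm
        i = int(np.argmin(np.abs(w - wavelength)))
        if np.isclose(w[i], wavelength, atol=0.5) or not interpolate_off_grid:
            return float(self.mre[i])
        order = np.argsort(w)
        return float(np.interp(wavelength, w[order], self.mre[order]))


@dataclass
class MeltCurve:
    """Temperature-indexed melt record (MRE at 222 nm or normalized % folded)."""

    temperatures_c: np.ndarray
    signal: np.ndarray
    normalized: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperatures_c = np.asarray(self.temperatures_c, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperatures_c.shape != self.signal.shape:
            raise ValueError("temperatures and signal must be aligned")


def to_mre(
    raw_mdeg: np.ndarray,
    concentration_g_per_l: float,
    path_cm: float,
    n_residues: int,
    mean_residue_weight: float | None = None,
    molecular_weight: float | None = None,
) -> np.ndarray:
    """Convert raw ellipticity (mdeg) to mean residue ellipticity.

    ``MRE = θ_mdeg × MRW / (10 × path_cm × conc_g/L)`` with the mean residue
    weight either given directly or as ``molecular_weight / n_residues``.
    """
    if concentration_g_per_l <= 0 or path_cm <= 0 or n_residues <= 0:
        raise ValueError("concentration, path length and residue count must be positive")
    if mean_residue_weight is None:
        if molecular_weight is None:
            raise ValueError("provide mean_residue_weight or molecular_weight")
        mean_residue_weight = molecular_weight / n_residues
    return np.asarray(raw_mdeg, dtype=float) * mean_residue_weight / (
        10.0 * path_cm * concentration_g_per_l
    )


def helical_content(mre_222: float) -> float:
    """Percent helix from MRE at 222 nm against the 36,000 full-helix reference.

    Uses the magnitude of the (negative) helical band; clipped to [0, 120]
    with a warning above 100%.
    """
    if not np.isfinite(mre_222):
        raise ValueError("MRE(222) must be finite")
    percent = 100.0 * abs(mre_222) / FULL_HELIX_MRE_222
    if percent > 100.0:
        warnings.warn(f"helical content {percent:.1f}% exceeds 100% — clipped to 120% max")
    return float(np.clip(percent, 0.0, 120.0))


def ratio_222_208(spectrum: CDSpectrum) -> float:
    """The MRE(222)/MRE(208) coiled-coil diagnostic ratio."""
    w = spectrum.wavelengths_nm
    if w.min() > 205 or w.max() < 225:
        raise ValueError("spectrum must cover 205–225 nm")
    m222 = spectrum.mre_at(222.0)
    m208 = spectrum.mre_at(208.0)
    if abs(m208) < 1e-9 * max(1.0, abs(m222)):
        raise UndefinedRatioError("MRE(208) is ~0; ratio undefined")
    return m222 / m208


def normalize_melt(curve: MeltCurve) -> MeltCurve:
    """Affine-map the melt signal to % folded: 100 at 10 °C, 0 at 80 °C."""
    t = curve.temperatures_c
    if t.min() > MELT_ANCHOR_FOLDED or t.max() < MELT_ANCHOR_UNFOLDED:
        raise ValueError(
            f"melt must span {MELT_ANCHOR_FOLDED}–{MELT_ANCHOR_UNFOLDED} °C"
        )
    s10 = float(np.interp(MELT_ANCHOR_FOLDED, t, curve.signal))
    s80 = float(np.interp(MELT_ANCHOR_UNFOLDED, t, curve.signal))
    if np.isclose(s10, s80):
        raise DegenerateRangeError("no signal change between 10 and 80 °C")
    frac = 100.0 * (curve.signal - s80) / (s10 - s80)
    return MeltCurve(t, frac, normalized=True, metadata=dict(curve.metadata))


def _two_state(t: np.ndarray, tm: float, width: float) -> np.ndarray:
    return 100.0 / (1.0 + np.exp((t - tm) / width))


def fit_melt(curve: MeltCurve) -> tuple[float, float]:
    """Fit the two-state logistic ``100 / (1 + exp((T − Tm)/w))``.

    Accepts raw or normalized curves (raw input is normalized first).
    Returns ``(Tm, width)`` in °C.
    """
    if len(curve.temperatures_c) < 10:
        raise ValueError("need at least 10 melt points spanning the transition")
    if not curve.normalized:
        curve = normalize_melt(curve)
    t, f = curve.temperatures_c, curve.signal
    tm0 = float(np.interp(50.0, f[np.argsort(f)], t[np.argsort(f)]))
    try:
        popt, _ = curve_fit(_two_state, t, f, p0=[tm0, 3.0], maxfev=10_000)
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise RuntimeError(
            f"melt fit did not converge (start Tm≈{tm0:.1f} °C, "
            f"signal range {f.min():.1f}–{f.max():.1f})"
        ) from exc
    tm, width = float(popt[0]), float(abs(popt[1]))
    return tm, width


def melt_to_frame(curve: MeltCurve):
    import pandas as pd

    col = "fraction_folded_pct" if curve.normalized else "mre_222"
    return pd.DataFrame({"temperature_C": curve.temperatures_c, col: curve.signal})


def spectrum_summary(spectrum: CDSpectrum) -> dict:
    """Helicity %, 222/208 ratio and band values for one spectrum."""
    m222 = spectrum.mre_at(222.0)
    return {
        "mre_222": m222,
        "mre_208": spectrum.mre_at(208.0),
        "helical_content_pct": helical_content(m222),
        "ratio_222_208": ratio_222_208(spectrum),
    }
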