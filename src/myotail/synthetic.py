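"""Synthetic-data generators emulating every input the pipeline consumes.

The generators stand in for molecular-dynamics trajectories, CD
spectropolarimeter output, negative-stain EM measurement tables and
sarcomeric fluorescence line scans, with the statistical structure the
analyses assume.  Scenario presets carry the study conditions per genotype
(wild type, the A1603P proline substitution, the K1617del deletion, the
canonical-register deletion variant, and 50:50 mixtures); preset values are
the published summary statistics where those exist and documented package
choices otherwise (see docs/methods.md).

Determinism: every generator takes a seed and uses numpy's PCG64
(``np.random.default_rng``); the same seed reproduces the data bit for bit.
Each generator emits its ground-truth parameters alongside the data (in
``metadata`` / ``DataFrame.attrs``) so closed-loop recovery tests can
compare analysis output against generator truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from myotail.builder import CoiledCoilModel
from myotail.cd import CDSpectrum, MeltCurve
from myotail.ensemble import Ensemble
from myotail.sarcomere import LineScan


# --------------------------------------------------------------------------
# Scenario presets
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FilamentPreset:
    """Mean, SEM and n of one measured quantity (population SD = SEM·√n)."""

    mean: float
    sem: float
    n: int

    @property
    def sd(self) -> float:
        return self.sem * np.sqrt(self.n)


@dataclass(frozen=True)
class ScenarioPreset:
    """All per-genotype generator parameters for one scenario."""

    mutation: str  # "" for WT
    mode: str = "skip-del"  # motif-schedule mode
    # conformational ensemble
    ee_mean_nm: Optional[float] = None
    ee_sd_nm: Optional[float] = None
    hinge_residue: int = 1603
    # CD / melt
    helix_fraction: Optional[float] = None
    melt_tm_c: Optional[float] = None
    melt_width_c: float = 2.5
    # EM morphometry
    length: Optional[FilamentPreset] = None
    width: Optional[FilamentPreset] = None
    bundle_p: Optional[float] = None
    # solubility
    solubility_midpoint_mm: Optional[float] = None
    solubility_width_mm: float = 25.0
    # cardiomyocyte integration (integrated, partial, aggregated)
    integration: Optional[tuple[float, float, float]] = None
    # sarcomere line scans
    sarcomere: dict = field(default_factory=dict)


PRESETS: "dict[str, ScenarioPreset]" = {
    "WT": ScenarioPreset(
        mutation="",
        ee_mean_nm=23.9, ee_sd_nm=0.5,
        helix_fraction=0.90, melt_tm_c=48.0,
        length=FilamentPreset(431.0, 34.0, 34),
        width=FilamentPreset(18.4, 0.4, 72),
        bundle_p=0.19,
        solubility_midpoint_mm=190.0,
        integration=(0.85, 0.10, 0.05),
        sarcomere=dict(peak_amplitude=1.0, peak_separation_um=0.70,
                       m_line_amplitude=0.15, n_myofibrils=24),
    ),
    "A1603P": ScenarioPreset(
        mutation="A1603P", hinge_residue=1603,
        ee_mean_nm=23.7, ee_sd_nm=0.5,
        helix_fraction=0.35, melt_tm_c=50.0,
        length=FilamentPreset(208.0, 16.0, 24),
        width=FilamentPreset(25.0, 1.0, 31),
        bundle_p=0.30,
        solubility_midpoint_mm=140.0,
        integration=(0.45, 0.30, 0.25),
        sarcomere=dict(peak_amplitude=0.95, peak_separation_um=0.70,
                       m_line_amplitude=0.55, n_myofibrils=12),
    ),
    "K1617del": ScenarioPreset(
        mutation="K1617del", hinge_residue=1616,
        ee_mean_nm=23.4, ee_sd_nm=0.5,
        helix_fraction=0.60, melt_tm_c=50.0,
        length=FilamentPreset(250.0, 40.0, 4),
        width=FilamentPreset(24.0, 1.5, 4),
        bundle_p=0.70,
        solubility_midpoint_mm=195.0,
        integration=(0.40, 0.30, 0.30),
        sarcomere=dict(peak_amplitude=0.75, peak_separation_um=0.60,
                       m_line_amplitude=0.35, n_myofibrils=13),
    ),
    "K1617del-c": ScenarioPreset(
        mutation="K1617del", mode="canonical-throughout", hinge_residue=1616,
        ee_mean_nm=23.7, ee_sd_nm=0.4,
    ),
    "WT:A1603P": ScenarioPreset(
        mutation="",
        length=FilamentPreset(390.0, 30.0, 11),
        width=FilamentPreset(22.0, 1.0, 11),
        bundle_p=0.20,
    ),
    "WT:K1617del": ScenarioPreset(
        mutation="",
        length=FilamentPreset(410.0, 30.0, 18),
        width=FilamentPreset(21.0, 1.0, 18),
        bundle_p=0.40,
    ),
}


# --------------------------------------------------------------------------
# Conformational ensembles
# --------------------------------------------------------------------------

def _model_axis_frame(model: CoiledCoilModel):
    """Supercoil axis direction, head/tail midpoints and hinge pivot helper."""
    ca = {c: model.ca(c) for c in model.chains}
    head = 0.5 * (ca["A"][0] + ca["B"][0])
    tail = 0.5 * (ca["A"][-1] + ca["B"][-1])
    axis = tail - head
    axis = axis / np.linalg.norm(axis)
    return axis, head, tail


def _rotation_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix."""
    k = axis / np.linalg.norm(axis)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def gen_ensemble(
    model: CoiledCoilModel,
    hinge_residue: int,
    mode: str = "end-to-end-target",
    *,
    ee_mean_nm: float | None = None,
    ee_sd_nm: float | None = None,
    bend_mean_deg: float = 0.0,
    bend_sd_deg: float = 0.0,
    jitter_sd: float = 0.08,
    n_frames: int = 100,
    time_per_frame_ns: float = 0.5,
    seed: int = 0,
) -> Ensemble:
    """Hinge-bend ensemble around a built model.

    Per frame the model's distal half (residues beyond ``hinge_residue``)
    is rigidly rotated about a random axis perpendicular to the supercoil
    axis through the hinge Cα midpoint, then all atoms receive isotropic
    Gaussian jitter of SD ``jitter_sd`` Å.

    ``mode="bend-distribution"`` draws the bend angle from
    N(bend_mean_deg, bend_sd_deg).  ``mode="end-to-end-target"`` draws a
    target end-to-end distance from N(ee_mean_nm, ee_sd_nm) — truncated to
    the achievable range, with the location parameter solved so the
    truncated mean equals the requested mean — and finds the bend angle
    reproducing it by bisection.  A requested mean at or beyond the straight
    length is an error.
    """
    if mode not in ("bend-distribution", "end-to-end-target"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    base = Ensemble.from_model(model)
    coords0 = base.coords[0]
    axis, head, tail = _model_axis_frame(model)

    # Hinge pivot: midpoint of the two chains' hinge Cα.
    pivots = []
    for c in model.chains:
        seq = model.sequences[c]
        if hinge_residue not in seq.numbering:
            raise ValueError(f"hinge residue {hinge_residue} absent from chain {c}")
        pivots.append(model.ca(c)[seq.numbering.index(hinge_residue)])
    pivot = np.mean(pivots, axis=0)
    distal = base.res_id > hinge_residue

    straight_nm = float(np.linalg.norm(tail - head)) / 10.0
    if mode == "end-to-end-target":
        if ee_mean_nm is None or ee_sd_nm is None:
            raise ValueError("end-to-end-target mode needs ee_mean_nm and ee_sd_nm")
        if ee_mean_nm >= straight_nm:
            raise ValueError(
                f"target mean {ee_mean_nm} nm exceeds straight length {straight_nm:.2f} nm"
            )
        if ee_sd_nm > 0:
            # Location parameter such that the upper-truncated normal has the
            # requested mean (draws can never exceed the straight length).
            def trunc_mean(loc: float) -> float:
                b = (straight_nm - loc) / ee_sd_nm
                return float(truncnorm.mean(-np.inf, b, loc=loc, scale=ee_sd_nm))

            lo = ee_mean_nm - 5 * ee_sd_nm
            loc = brentq(lambda m: trunc_mean(m) - ee_mean_nm, lo, straight_nm + 5 * ee_sd_nm)
            b = (straight_nm - loc) / ee_sd_nm
            targets = truncnorm.rvs(
                -np.inf, b, loc=loc, scale=ee_sd_nm, size=n_frames, random_state=rng
            )
        else:
            targets = np.full(n_frames, ee_mean_nm)

    # Frame orthonormal to the supercoil axis for random bend directions.
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)

    def bent_tail(angle_rad: float, bend_axis: np.ndarray) -> np.ndarray:
        R = _rotation_about(bend_axis, angle_rad)
        return (tail - pivot) @ R.T + pivot

    frames = np.empty((n_frames, base.n_atoms, 3))
    bend_angles = np.empty(n_frames)
    for i in range(n_frames):
        theta = rng.uniform(0, 2 * np.pi)
        bend_axis = np.cos(theta) * u + np.sin(theta) * v
        if mode == "bend-distribution":
            angle = np.deg2rad(rng.normal(bend_mean_deg, bend_sd_deg))
        else:
            target = targets[i]

            def gap(a: float) -> float:
                return np.linalg.norm(bent_tail(a, bend_axis) - head) / 10.0 - target

            angle = 0.0 if gap(0.0) <= 0 else brentq(gap, 0.0, 2.6)
        R = _rotation_about(bend_axis, angle)
        frame = coords0.copy()
        frame[distal] = (frame[distal] - pivot) @ R.T + pivot
        if jitter_sd > 0:
            frame += rng.normal(0.0, jitter_sd, frame.shape)
        frames[i] = frame
        bend_angles[i] = np.degrees(angle)

    return Ensemble(
        frames, base.atom_name, base.res_id, base.chain_id, base.res_name,
        base.element, (np.arange(n_frames) + 1) * time_per_frame_ns,
        metadata={
            "source": "gen_ensemble", "seed": seed, "mode": mode,
            "hinge_residue": hinge_residue, "jitter_sd": jitter_sd,
            "straight_length_nm": straight_nm,
            "truth": {
                "ee_mean_nm": ee_mean_nm, "ee_sd_nm": ee_sd_nm,
                "bend_mean_deg": bend_mean_deg, "bend_sd_deg": bend_sd_deg,
                "mean_bend_deg": float(bend_angles.mean()),
            },
        },
    )


# --------------------------------------------------------------------------
# Circular dichroism
# --------------------------------------------------------------------------

_HELIX_BANDS = ((193.0, 9.0), (208.0, 6.5), (222.0, 10.0))
_A193, _A208 = 65_000.0, 28_000.0
_COIL_BAND = (198.0, 8.0)
_COIL_AMP = 15_000.0


def _gauss(x, center, width):
    return np.exp(-(((x - center) / width) ** 2))


def helix_basis(wavelengths: np.ndarray) -> np.ndarray:
    """Fully-helical basis spectrum: MRE(222) = −36,000, 222/208 ratio > 1."""
    (c1, w1), (c2, w2), (c3, w3) = _HELIX_BANDS
    a222 = 36_000.0 + _A193 * _gauss(222.0, c1, w1) - _A208 * _gauss(222.0, c2, w2)
    return (
        _A193 * _gauss(wavelengths, c1, w1)
        - _A208 * _gauss(wavelengths, c2, w2)
        - a222 * _gauss(wavelengths, c3, w3)
    )


def coil_basis(wavelengths: np.ndarray) -> np.ndarray:
    """Random-coil basis: single negative band with minimum near 198 nm."""
    c, w = _COIL_BAND
    return -_COIL_AMP * _gauss(wavelengths, c, w)


def gen_cd(helix_fraction: float, noise_sd: float = 0.0, seed: int = 0) -> CDSpectrum:
    """Two-basis mixture CD spectrum over 190–260 nm (1 nm steps)."""
    if not 0.0 <= helix_fraction <= 1.0:
        raise ValueError("helix_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    w = np.arange(190.0, 260.5, 1.0)
    mre = helix_fraction * helix_basis(w) + (1.0 - helix_fraction) * coil_basis(w)
    if noise_sd > 0:
        mre = mre + rng.normal(0.0, noise_sd, w.shape)
    return CDSpectrum(
        w, mre,
        metadata={"source": "gen_cd", "seed": seed,
                  "truth": {"helix_fraction": helix_fraction, "noise_sd": noise_sd}},
    )


def gen_melt(
    tm_c: float, width_c: float = 2.5, noise_sd: float = 0.0, seed: int = 0
) -> MeltCurve:
    """Two-state melt, % folded at 1 °C steps from 10 to 85 °C."""
    if not 10.0 <= tm_c <= 80.0:
        raise ValueError("Tm must lie within the measured range 10–80 °C")
    rng = np.random.default_rng(seed)
    t = np.arange(10.0, 86.0, 1.0)
    f = 100.0 / (1.0 + np.exp((t - tm_c) / width_c))
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, t.shape)
    return MeltCurve(
        t, f, normalized=True,
        metadata={"source": "gen_melt", "seed": seed,
                  "truth": {"tm_c": tm_c, "width_c": width_c, "noise_sd": noise_sd}},
    )


# --------------------------------------------------------------------------
# Filaments, solubility, integration
# --------------------------------------------------------------------------

def _positive_normal(rng, mean, sd, n):
    """Normal draws truncated to > 0 (rejection; negligible bias here)."""
    out = rng.normal(mean, sd, n)
    while (bad := out <= 0).any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    return out


def gen_filaments(
    presets: "dict[str, ScenarioPreset] | None" = None,
    seed: int = 0,
    n_fields: int = 200,
) -> pd.DataFrame:
    """Filament measurement table: one row per image field, per group.

    Lengths and widths are Normal(mean, SEM·√n) truncated positive, present
    for the preset's measurement count and NaN beyond it; the per-field
    bundled flag is Bernoulli(bundle_p).  Ground truth is in ``.attrs``.
    """
    presets = {k: v for k, v in (presets or PRESETS).items() if v.length is not None}
    rng = np.random.default_rng(seed)
    rows = []
    truth = {}
    for group, p in presets.items():
        n_rows = max(n_fields, p.length.n, p.width.n if p.width else 0)
        lengths = _positive_normal(rng, p.length.mean, p.length.sd, p.length.n)
        widths = (
            _positive_normal(rng, p.width.mean, p.width.sd, p.width.n)
            if p.width else np.empty(0)
        )
        bundled = rng.random(n_rows) < (p.bundle_p or 0.0)
        for i in range(n_rows):
            rows.append(
                {
                    "group": group,
                    "field_id": f"{group}-f{i:03d}",
                    "length_nm": lengths[i] if i < len(lengths) else np.nan,
                    "width_nm": widths[i] if i < len(widths) else np.nan,
                    "bundled": bool(bundled[i]),
                }
            )
        truth[group] = {
            "length_mean": p.length.mean, "length_sem": p.length.sem, "n_length": p.length.n,
            "width_mean": p.width.mean if p.width else None,
            "bundle_p": p.bundle_p,
        }
    df = pd.DataFrame(rows)
    df.attrs["truth"] = truth
    df.attrs["seed"] = seed
    return df


#: NaCl concentrations of the five-aliquot solubility assay (mM).
SOLUBILITY_SALT_MM = (100.0, 150.0, 200.0, 250.0, 300.0)


def gen_solubility(
    presets: "dict[str, ScenarioPreset] | None" = None,
    noise_sd: float = 0.02,
    total: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Solubility assay table: supernatant/total vs NaCl per group."""
    presets = {
        k: v for k, v in (presets or PRESETS).items() if v.solubility_midpoint_mm is not None
    }
    rng = np.random.default_rng(seed)
    rows = []
    truth = {}
    for group, p in presets.items():
        for s in SOLUBILITY_SALT_MM:
            frac = 1.0 / (1.0 + np.exp(-(s - p.solubility_midpoint_mm) / p.solubility_width_mm))
            frac = float(np.clip(frac + rng.normal(0.0, noise_sd), 0.0, 1.0))
            rows.append(
                {"group": group, "NaCl_mM": s, "supernatant": frac * total, "total": total}
            )
        truth[group] = {"midpoint_mM": p.solubility_midpoint_mm, "width_mM": p.solubility_width_mm}
    df = pd.DataFrame(rows)
    df.attrs["truth"] = truth
    df.attrs["seed"] = seed
    return df


def gen_integration(
    presets: "dict[str, ScenarioPreset] | None" = None,
    n_cells: int = 30,
    n_experiments: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell integration categories, ``n_experiments`` independent repeats."""
    from myotail.morphometry import INTEGRATION_CATEGORIES

    presets = {k: v for k, v in (presets or PRESETS).items() if v.integration is not None}
    rng = np.random.default_rng(seed)
    rows = []
    truth = {}
    for group, p in presets.items():
        probs = np.asarray(p.integration, dtype=float)
        probs = probs / probs.sum()
        for e in range(n_experiments):
            cats = rng.choice(INTEGRATION_CATEGORIES, size=n_cells, p=probs)
            rows.extend(
                {"group": group, "experiment": f"exp{e + 1}", "cell_id": i, "category": c}
                for i, c in enumerate(cats)
            )
        truth[group] = {"probs": tuple(probs)}
    df = pd.DataFrame(rows)
    df.attrs["truth"] = truth
    df.attrs["seed"] = seed
    return df


# --------------------------------------------------------------------------
# Sarcomere line scans
# --------------------------------------------------------------------------

def gen_linescans(
    n_myofibrils: int = 12,
    n_sarcomeres: int = 5,
    sarcomere_length_um: float = 1.85,
    peak_separation_um: float = 0.70,
    m_line_amplitude: float = 0.15,
    noise_sd: float = 0.03,
    pixel_size_um: float = 0.065,
    peak_amplitude: float = 1.0,
    peak_sigma_um: float = 0.13,
    m_sigma_um: float = 0.20,
    baseline: float = 1.0,
    seed: int = 0,
) -> "tuple[list[LineScan], dict]":
    """Striated intensity line scans with a central bare-zone minimum.

    Per sarcomere: baseline + two Gaussian peaks at M ± separation/2 + a
    central Gaussian of amplitude ``m_line_amplitude`` at the M-line
    (elevated in mutant presets) + Gaussian noise.  Each myofibril's scan
    starts at a random phase.  Returns the scans and the truth dict.
    """
    if peak_separation_um >= sarcomere_length_um:
        raise ValueError("peak separation must be smaller than the sarcomere length")
    rng = np.random.default_rng(seed)
    scans = []
    for mf in range(n_myofibrils):
        shift = rng.uniform(0.0, sarcomere_length_um)
        length = (n_sarcomeres + 1) * sarcomere_length_um
        x = np.arange(0.0, length, pixel_size_um)
        y = np.full_like(x, baseline)
        m_positions = shift + (np.arange(n_sarcomeres + 1) + 0.5) * sarcomere_length_um
        for m in m_positions:
            for sign in (-1.0, 1.0):
                c = m + sign * peak_separation_um / 2.0
                y += peak_amplitude * np.exp(-(((x - c) / peak_sigma_um) ** 2) / 2.0)
            y += m_line_amplitude * np.exp(-(((x - m) / m_sigma_um) ** 2) / 2.0)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, y.shape)
        scans.append(LineScan(x, y, myofibril_id=f"mf{mf:02d}"))
    truth = {
        "sarcomere_length_um": sarcomere_length_um,
        "peak_separation_um": peak_separation_um,
        "m_line_amplitude": m_line_amplitude,
        "peak_amplitude": peak_amplitude,
        "baseline": baseline,
        "noise_sd": noise_sd,
        "pixel_size_um": pixel_size_um,
        "seed": seed,
    }
    return scans, truth


def gen_linescans_for_scenario(
    scenario: str, seed: int = 0, **overrides
) -> "tuple[list[LineScan], dict]":
    """Line scans using a scenario preset's sarcomere parameters."""
    p = PRESETS[scenario]
    if not p.sarcomere:
        raise ValueError(f"scenario {scenario!r} has no sarcomere preset")
    kwargs = dict(
        n_myofibrils=p.sarcomere["n_myofibrils"],
        peak_separation_um=p.sarcomere["peak_separation_um"],
        m_line_amplitude=p.sarcomere["m_line_amplitude"],
        peak_amplitude=p.sarcomere["peak_amplitude"],
        seed=seed,
    )
    kwargs.update(overrides)
    return gen_linescans(**kwargs)
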