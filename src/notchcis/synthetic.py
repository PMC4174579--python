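"""Synthetic single-cell datasets with known ground truth.

Every input the analysis pipeline consumes can be generated here: per-cell
availability tables across ligand-induction levels, saturation-binding
calibration curves, ligand-dilution time-lapse traces, and multi-channel
cell images with pixel-exact label masks.

The availability generator emulates the structure of a tet-inducible
ligand / constitutive receptor cell line: the induction dose sets the
median total-ligand fluorescence through a Hill curve, single cells spread
log-normally around that median, surface ligand is proportional to total
ligand, and the measured availability signal is the gain-scaled free
receptor (or ligand) at the cis-inhibition steady state, corrupted by
multiplicative log-normal noise and an additive Gaussian background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from notchcis.kinetics import (
    FringeConfig,
    KineticParams,
    apply_fringe,
    qss_free_levels,
)

__all__ = [
    "GeneratorConfig",
    "DilutionTrace",
    "generator_params",
    "generate_availability_dataset",
    "generate_calibration_dataset",
    "generate_dilution_timecourses",
    "render_synthetic_field",
    "half_inhibition_total_ligand",
]


def generator_params() -> KineticParams:
    """Default kinetics for the availability generator.

    Chosen so that ligand is in excess of receptor over the measured range
    (beta_N/gamma_N = 1 model unit, half-depletion kc*gamma_N = 10 units):
    in this regime free ligand tracks total ligand and the availability
    curve is close to the hyperbolic closed form used for fitting, as in
    the measured cell lines.  QSS holds (kI, kC- >> gamma_N).
    """
    return KineticParams(beta_N=0.1, beta_D=0.0, gamma_N=0.1, gamma_D=0.1,
                         kC_plus=0.02, kC_minus=5.0, kI=5.0,
                         kD_plus=1.0, kD_minus=4.0, kS=1.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic availability experiment.

    Induction levels are 4-epiTc doses in ng/ml; the dose->median
    total-ligand-fluorescence map is a Hill curve with coefficient
    ``hill_n`` and EC50 ``hill_ec50`` on top of a small basal level.
    ``surface_efficiency`` converts total-ligand fluorescence to surface
    ligand in model units (Jag1 reaches the surface more efficiently than
    Dll1 for the same total fluorescence).
    """

    n_cells_per_level: int = 500
    induction_levels: tuple[float, ...] = (0.0, 10.0, 30.0, 100.0)
    hill_max: float = 3000.0      # fluorescence units at saturating dose
    hill_ec50: float = 25.0       # ng/ml
    hill_n: float = 2.0
    basal_fluor: float = 20.0     # leaky expression at zero dose
    sigma: float = 0.5            # log-normal cell-to-cell spread (ln units)
    surface_efficiency: Mapping[str, float] = field(
        default_factory=lambda: {"Dll1": 0.010, "Jag1": 0.020})
    noise_cv: float = 0.10        # multiplicative measurement noise
    background_mean: float = 50.0
    background_sd: float = 10.0
    gain: float = 1000.0          # fluorescence units per model unit
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_per_level < 1:
            raise ValueError("n_cells_per_level must be >= 1")
        if self.sigma < 0 or self.noise_cv < 0 or self.gain <= 0:
            raise ValueError("require sigma >= 0, noise_cv >= 0, gain > 0")

    def median_fluor(self, dose) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        hill = dose ** self.hill_n / (dose ** self.hill_n + self.hill_ec50 ** self.hill_n)
        return self.basal_fluor + self.hill_max * np.where(np.isnan(hill), 0.0, hill)


def _noise_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    s = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=size)


def generate_availability_dataset(config: GeneratorConfig,
                                  params: KineticParams | None = None,
                                  fringe: FringeConfig | None = None,
                                  ligand: str = "Dll1",
                                  assay: str = "receptor_availability",
                                  seed: int | None = None) -> pd.DataFrame:
    """Per-cell availability table for one condition.

    For each cell, total-ligand fluorescence T is drawn from the induction
    model, surface ligand is ``efficiency * T`` model units (imposed as the
    cell's unopposed ligand level), the cis steady state gives free N and
    free L, and the recorded availability is

        receptor assay:  gain * detection_gain * N_free * noise + background
        ligand assay:    gain * L_free * noise + background

    (the detection-gain change applies to the receptor reagent, which binds
    Fringe-modified Notch).  Deterministic given the seed.
    """
    if len(config.induction_levels) == 0:
        raise ValueError("induction_levels must not be empty")
    if assay not in ("receptor_availability", "ligand_availability"):
        raise ValueError(f"unknown assay {assay!r}")
    params = generator_params() if params is None else params
    fringe = FringeConfig() if fringe is None else fringe
    if ligand not in config.surface_efficiency:
        raise KeyError(f"no surface_efficiency for ligand {ligand!r}")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    p_mod = apply_fringe(params, fringe, ligand)
    kc = p_mod.kc
    eff = float(config.surface_efficiency[ligand])

    frames = []
    n = config.n_cells_per_level
    for dose in config.induction_levels:
        median = float(config.median_fluor(dose))
        T = median * np.exp(config.sigma * rng.standard_normal(n))
        D_tot = eff * T                       # unopposed surface-ligand level
        beta_D = D_tot * params.gamma_D
        N_free, L_free = qss_free_levels(beta_D, params, kc=kc)
        if assay == "receptor_availability":
            clean = config.gain * fringe.detection_gain * N_free
        else:
            clean = config.gain * L_free
        signal = clean * _noise_factor(rng, config.noise_cv, n)
        bg = rng.normal(config.background_mean, config.background_sd, n)
        frames.append(pd.DataFrame({
            "induction_ngml": dose,
            "total_ligand_fluor": T,
            "availability_fluor": np.clip(signal + bg, 0.0, None),
        }))
    table = pd.concat(frames, ignore_index=True)
    table.insert(0, "cell_id", np.arange(len(table)))
    table.insert(1, "ligand", ligand)
    table.insert(2, "fringe", fringe.identity)
    table.insert(3, "assay", assay)
    table["area"] = rng.lognormal(np.log(500.0), 0.2, len(table))
    table["is_isolated"] = True
    return table


def half_inhibition_total_ligand(config: GeneratorConfig,
                                 params: KineticParams | None = None,
                                 fringe: FringeConfig | None = None,
                                 ligand: str = "Dll1") -> float:
    """Ground-truth half-inhibition point of the generator's forward model.

    Returns the total-ligand fluorescence at which the noise-free free-
    receptor signal is half its zero-ligand value (found by root finding on
    the same forward model the generator uses).  This is the quantity the
    cis-inhibition fit should recover as L50.
    """
    params = generator_params() if params is None else params
    fringe = FringeConfig() if fringe is None else fringe
    kc = apply_fringe(params, fringe, ligand).kc
    eff = float(config.surface_efficiency[ligand])
    n0 = params.beta_N / params.gamma_N

    def half(T):
        beta_D = eff * T * params.gamma_D
        N, _ = qss_free_levels(beta_D, params, kc=kc)
        return float(N) - 0.5 * n0

    hi = 10.0 * kc * params.gamma_N / eff + 1.0
    return brentq(half, 0.0, hi, xtol=1e-9)


def generate_calibration_dataset(a: float, K: float,
                                 concentrations: Sequence[float],
                                 replicates: int = 2,
                                 noise_cv: float = 0.1,
                                 seed: int = 0) -> pd.DataFrame:
    """Saturation-binding calibration curve: signal = a*D/(D+K) per replicate.

    Emulates titrating the soluble ligand-Fc detection reagent on receptor-
    expressing cells; D in µg/ml, signal in fluorescence units, with
    multiplicative log-normal noise of the given CV.
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    if a <= 0 or K <= 0:
        raise ValueError("require a > 0 and K > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(replicates):
        clean = a * conc / (conc + K)
        rows.append(pd.DataFrame({
            "concentration_ugml": conc,
            "replicate": rep,
            "signal": clean * _noise_factor(rng, noise_cv, conc.size),
        }))
    return pd.concat(rows, ignore_index=True)


@dataclass
class DilutionTrace:
    """One cell's ligand-dilution time-lapse (hours after washout)."""

    t: np.ndarray                 # hours, strictly increasing
    ligand_fluor: np.ndarray
    reporter_fluor: np.ndarray
    division_period: float        # hours
    cell_id: int = 0


def generate_dilution_timecourses(config: GeneratorConfig,
                                  params: KineticParams | None = None,
                                  fringe: FringeConfig | None = None,
                                  plate_ligand_density: float = 1.0,
                                  n_cells: int = 10,
                                  cis_ligand: str = "Jag1",
                                  plate_ligand: str = "Dll1",
                                  initial_ligand: float = 1000.0,
                                  duration_h: float = 60.0,
                                  frame_interval_min: float = 20.0,
                                  division_period_h: float = 18.0,
                                  seed: int | None = None) -> list[DilutionTrace]:
    """Simulated ligand-dilution videos.

    Cells start pre-induced at a high cis-ligand level (model units,
    log-normal across cells) on a plate coated with trans ligand at fixed
    density.  After washout, cell division halves the cis-ligand every
    ``division_period_h`` on top of degradation, so total ligand decays
    exponentially at rate ln2/T_div + gamma_D.  Free receptor follows the
    cis steady state at the instantaneous ligand level and the reporter
    accumulates at the trans signal rate against the plate ligand.
    """
    if division_period_h <= 0:
        raise ValueError("division_period_h must be positive")
    params = generator_params() if params is None else params
    fringe = FringeConfig() if fringe is None else fringe
    rng = np.random.default_rng(config.seed if seed is None else seed)

    kc_cis = apply_fringe(params, fringe, cis_ligand).kc
    p_trans = apply_fringe(params, fringe, plate_ligand)

    t = np.arange(0.0, duration_h + 1e-9, frame_interval_min / 60.0)
    decay = np.log(2.0) / division_period_h + params.gamma_D
    traces = []
    for i in range(n_cells):
        D0 = initial_ligand * np.exp(0.2 * rng.standard_normal())
        D_tot = D0 * np.exp(-decay * t)
        N_free, _ = qss_free_levels(D_tot * params.gamma_D, params, kc=kc_cis)
        rate = (p_trans.kS * p_trans.kD_plus * N_free * plate_ligand_density
                / (p_trans.kD_minus + p_trans.kS))
        dt = np.diff(t)
        S = np.concatenate([[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * dt)])
        lig = config.gain * D_tot * _noise_factor(rng, config.noise_cv, t.size)
        rep = config.gain * S * _noise_factor(rng, config.noise_cv, t.size)
        traces.append(DilutionTrace(t=t, ligand_fluor=lig, reporter_fluor=rep,
                                    division_period=division_period_h, cell_id=i))
    return traces


def render_synthetic_field(cells: Sequence[Mapping],
                           image_shape: tuple[int, int] = (256, 256),
                           channels: Sequence[str] = ("cyto",),
                           background_model: Mapping | None = None,
                           noise_sd: float = 0.0,
                           seed: int = 0):
    """Render cells as soft-edged disks into a multi-channel image.

    Each entry of ``cells`` is a mapping with keys ``center`` (row, col),
    ``radius`` (pixels) and ``intensity`` (channel -> value).  Pixels inside
    the radius carry exactly the specified intensity; a one-pixel soft rim
    outside the radius avoids unrealistically hard edges.  The first channel
    is conventionally the cytoplasmic stain used for segmentation.

    Background is added to every channel, either constant
    (``{"kind": "constant", "level": b}``) or a linear gradient
    (``{"kind": "gradient", "low": a, "high": b, "axis": 0|1}``), plus
    Gaussian read noise of sd ``noise_sd``.

    Returns ``(image, labels, truth)``: image of shape (n_channels, H, W),
    a pixel-exact int label mask (labels are 1-based cell indices; on
    overlap the later cell wins), and a ground-truth DataFrame with an
    ``overlaps`` flag per cell.
    """
    H, W = image_shape
    rng = np.random.default_rng(seed)
    img = np.zeros((len(channels), H, W), dtype=float)
    labels = np.zeros((H, W), dtype=np.uint16)
    yy, xx = np.mgrid[0:H, 0:W]

    masks = []
    for cell in cells:
        cy, cx = cell["center"]
        r = float(cell["radius"])
        if r <= 0:
            raise ValueError("cell radius must be positive")
        if not (0 <= cy < H and 0 <= cx < W):
            raise ValueError(f"cell center {(cy, cx)} outside image {image_shape}")
        d = np.hypot(yy - cy, xx - cx)
        core = d <= r
        rim = (d > r) & (d <= r + 1.0)
        weight = np.zeros((H, W))
        weight[core] = 1.0
        weight[rim] = (r + 1.0 - d[rim])
        masks.append(core)
        for ci, ch in enumerate(channels):
            img[ci] += float(cell["intensity"].get(ch, 0.0)) * weight

    overlaps = np.zeros(len(cells), dtype=bool)
    for i, m in enumerate(masks):
        taken = labels[m]
        hit = np.unique(taken[taken > 0])
        if hit.size:
            overlaps[i] = True
            overlaps[hit - 1] = True
        labels[m] = i + 1

    bg = np.zeros((H, W))
    if background_model:
        kind = background_model.get("kind", "constant")
        if kind == "constant":
            bg += float(background_model["level"])
        elif kind == "gradient":
            axis = int(background_model.get("axis", 0))
            ramp = np.linspace(float(background_model["low"]),
                               float(background_model["high"]),
                               image_shape[axis])
            bg += ramp[:, None] if axis == 0 else ramp[None, :]
        else:
            raise ValueError(f"unknown background kind {kind!r}")
    img += bg[None, :, :]
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, img.shape)

    truth = pd.DataFrame({
        "cell_id": np.arange(1, len(cells) + 1),
        "center_y": [c["center"][0] for c in cells],
        "center_x": [c["center"][1] for c in cells],
        "radius": [c["radius"] for c in cells],
        "overlaps": overlaps,
    })
    for ch in channels:
        truth[f"intensity_{ch}"] = [float(c["intensity"].get(ch, 0.0)) for c in cells]
    return img, labels, truth
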