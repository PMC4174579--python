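"""Kinetic model of mutual Notch-ligand cis-inactivation.

The model describes two reactions in a single cell: reversible binding of a
Notch receptor N and a DSL ligand D into a cis complex [ND] (rates kC+, kC-),
and irreversible inactivation of that complex (rate kI).  With production
(betaN, betaD) and first-order dilution/degradation (gammaN, gammaD) the
dynamics are

    dN/dt = betaN - gammaN*N - (kC+ * N*D - kC- * C)
    dD/dt = betaD - gammaD*D - (kC+ * N*D - kC- * C)
    dC/dt = kC+ * N*D - kC- * C - kI*C

Under a quasi-steady-state (QSS) assumption on the complex, the cis flux
collapses to N*D/kc with the lumped constant

    kc = (kC- + kI) / (kC+ * kI)

and free receptor at steady state obeys the closed form

    N_ss = (betaN/gammaN) / (1 + D_ss/(kc*gammaN)),

so kc*gammaN is the cis-ligand level that halves available Notch.

Trans-activation (receptor on one cell, ligand on a neighbour) is treated as
a fast bimolecular step with rates kD+/kD- and signal-production rate kS,
giving a quasi-steady signal flux kS*kD+*N*D/(kD- + kS).

All quantities are in dimensionless model units; conversion to fluorescence
happens only in :mod:`notchcis.synthetic`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
import yaml
from scipy.optimize import brentq

__all__ = [
    "KineticParams",
    "FringeConfig",
    "CellState",
    "EffectiveCisStrength",
    "effective_kc",
    "qss_available_notch",
    "cis_ode_rhs",
    "solve_cis_steady_state",
    "qss_free_levels",
    "apply_fringe",
    "trans_signal_rate",
    "fringe_preset",
    "load_params",
    "save_params",
]


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the cis/trans reaction scheme (model units).

    Defaults put the system in the strong-cis, QSS-valid regime
    (kI, kC- >= 10*gammaN and kc*gammaN << betaN/gammaN).
    """

    beta_N: float = 1.0     # Notch production (conc/time)
    beta_D: float = 1.0     # ligand production (conc/time)
    gamma_N: float = 0.1    # Notch degradation (1/time)
    gamma_D: float = 0.1    # ligand degradation (1/time)
    kC_plus: float = 10.0   # cis association (1/(conc*time))
    kC_minus: float = 4.0   # cis dissociation (1/time)
    kI: float = 4.0         # cis-complex inactivation (1/time)
    kD_plus: float = 1.0    # trans association (1/(conc*time))
    kD_minus: float = 4.0   # trans dissociation (1/time)
    kS: float = 1.0         # trans activation -> signal (1/time)

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.gamma_N <= 0 or self.gamma_D <= 0:
            raise ValueError("degradation rates gamma_N, gamma_D must be positive")
        if self.kC_plus > 0 and self.kC_minus + self.kI <= 0:
            raise ValueError("kC_minus + kI must be positive when kC_plus > 0")

    @property
    def kc(self) -> float:
        """Lumped cis constant kc = (kC- + kI)/(kC+ * kI)."""
        return effective_kc(self.kC_plus, self.kC_minus, self.kI).kc

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: Mapping) -> "KineticParams":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class FringeConfig:
    """Fringe glycosyltransferase modulation of Notch-ligand interactions.

    Fringes act on the receptor, re-weighting its cis and trans association
    with Delta-family versus Serrate-family ligands, and also change the
    binding of the soluble ligand-Fc detection reagent used by the
    availability assay (``detection_gain``).
    """

    identity: str = "none"
    cis_factor: Mapping[str, float] = field(default_factory=dict)
    trans_factor: Mapping[str, float] = field(default_factory=dict)
    detection_gain: float = 1.0

    def __post_init__(self) -> None:
        for m in (self.cis_factor, self.trans_factor):
            for lig, f in m.items():
                if f <= 0:
                    raise ValueError(f"fringe factor for {lig!r} must be > 0")
        if self.detection_gain <= 0:
            raise ValueError("detection_gain must be > 0")
        if self.identity == "none":
            bad = [f for f in (*self.cis_factor.values(),
                               *self.trans_factor.values(),
                               self.detection_gain) if f != 1.0]
            if bad:
                raise ValueError("identity='none' requires all factors == 1")

    def cis(self, ligand: str) -> float:
        return float(self.cis_factor.get(ligand, 1.0)) if self.identity != "none" else 1.0

    def trans(self, ligand: str) -> float:
        return float(self.trans_factor.get(ligand, 1.0)) if self.identity != "none" else 1.0


@dataclass
class CellState:
    """Concentrations of free and complexed species in one cell."""

    N: float
    D: dict[str, float]
    C_cis: dict[str, float]
    S: float = 0.0

    def __post_init__(self) -> None:
        vals = [self.N, self.S, *self.D.values(), *self.C_cis.values()]
        if any(v < 0 for v in vals):
            raise ValueError("cell state concentrations must be non-negative")


@dataclass(frozen=True)
class EffectiveCisStrength:
    """Lumped cis constant kc and the derived half-depletion ligand level."""

    kc: float
    half_depletion: float | None = None


def effective_kc(kC_plus: float, kC_minus: float, kI: float,
                 gamma_N: float | None = None) -> EffectiveCisStrength:
    """Lump the three cis rates into kc = (kC- + kI)/(kC+ * kI).

    kc has units of concentration*time; kc*gamma_N is the cis-ligand
    concentration at which free Notch is halved.  Raises if kC+ or kI is
    zero, since then there is no inactivation pathway and kc is infinite.
    """
    if kC_plus <= 0 or kI <= 0:
        raise ValueError("kc undefined: kC_plus and kI must both be positive "
                         "(no cis inactivation pathway otherwise)")
    if kC_minus < 0:
        raise ValueError("kC_minus must be non-negative")
    kc = (kC_minus + kI) / (kC_plus * kI)
    half = kc * gamma_N if gamma_N is not None else None
    return EffectiveCisStrength(kc=kc, half_depletion=half)


def qss_available_notch(D, beta_N: float, gamma_N: float, kc: float):
    """Steady-state free Notch at cis-ligand level ``D`` (closed form).

    N_ss = (beta_N/gamma_N) / (1 + D/(kc*gamma_N)); strictly decreasing in D,
    equal to beta_N/gamma_N at D=0 and halved at D = kc*gamma_N.
    Accepts scalars or arrays for ``D``.
    """
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("cis-ligand level D must be non-negative")
    if gamma_N <= 0 or kc <= 0 or beta_N < 0:
        raise ValueError("require beta_N >= 0, gamma_N > 0, kc > 0")
    out = (beta_N / gamma_N) / (1.0 + D / (kc * gamma_N))
    return float(out) if out.ndim == 0 else out


def cis_ode_rhs(state: CellState, params: KineticParams,
                ligand: str | None = None) -> tuple[float, float, float]:
    """Time derivatives (dN/dt, dD/dt, dC/dt) of the one-ligand cis system."""
    if ligand is None:
        if len(state.D) != 1:
            raise ValueError("state has multiple ligands; specify which")
        ligand = next(iter(state.D))
    N, D, C = state.N, state.D[ligand], state.C_cis[ligand]
    flux = params.kC_plus * N * D - params.kC_minus * C
    dN = params.beta_N - params.gamma_N * N - flux
    dD = params.beta_D - params.gamma_D * D - flux
    dC = flux - params.kI * C
    return (dN, dD, dC)


def _single_ligand_qss_notch(beta_N, gamma_N, beta_D, gamma_D, kc):
    """Vectorised positive root of the single-ligand QSS steady state.

    Eliminating D = beta_D/(gamma_D + N/kc) from
    beta_N = N*(gamma_N + D/kc) gives the quadratic
    gamma_N*N^2 + (gamma_N*kc*gamma_D + beta_D - beta_N)*N - beta_N*kc*gamma_D = 0.
    """
    b = gamma_N * kc * gamma_D + beta_D - beta_N
    disc = b * b + 4.0 * gamma_N * beta_N * kc * gamma_D
    return (-b + np.sqrt(disc)) / (2.0 * gamma_N)


def qss_free_levels(beta_D, params: KineticParams, kc: float | None = None):
    """Vectorised free (N, D) at QSS steady state for one ligand.

    ``beta_D`` may be an array of per-cell ligand production rates; the
    returned arrays match its shape.  Used by the synthetic-data generator
    where one steady state per cell is needed.
    """
    beta_D = np.asarray(beta_D, dtype=float)
    if np.any(beta_D < 0):
        raise ValueError("beta_D must be non-negative")
    kc = params.kc if kc is None else kc
    N = _single_ligand_qss_notch(params.beta_N, params.gamma_N,
                                 beta_D, params.gamma_D, kc)
    N = np.maximum(N, 0.0)
    D = beta_D / (params.gamma_D + N / kc)
    return N, D


def solve_cis_steady_state(params: Mapping[str, KineticParams] | KineticParams,
                           ligands: list[str] | None = None,
                           method: str = "auto",
                           tol: float = 1e-10) -> CellState:
    """Steady state of the QSS-reduced cis system for one or more ligands.

    For several cis-ligands competing for one Notch pool the reduced system is

        beta_N    = N * (gamma_N + sum_l D_l / kc_l)
        beta_D,l  = D_l * (gamma_D,l + N / kc_l)

    Eliminating each D_l leaves a monotone scalar equation in N which is
    solved exactly (closed-form quadratic) for one ligand and by bracketed
    root finding for more.  Parameters may be a single :class:`KineticParams`
    (ligand named "D") or a mapping ligand -> params; beta_N/gamma_N must
    agree across entries.
    """
    if isinstance(params, KineticParams):
        params = {"D": params}
    if ligands is None:
        ligands = list(params)
    if not ligands:
        raise ValueError("need at least one ligand")
    if tol <= 0:
        raise ValueError("tol must be positive")
    p0 = params[ligands[0]]
    for lig in ligands[1:]:
        p = params[lig]
        if not (math.isclose(p.beta_N, p0.beta_N) and math.isclose(p.gamma_N, p0.gamma_N)):
            raise ValueError("beta_N/gamma_N must agree across per-ligand parameter sets")
    beta_N, gamma_N = p0.beta_N, p0.gamma_N
    kcs = {lig: params[lig].kc for lig in ligands}

    if beta_N == 0:
        N = 0.0
    elif len(ligands) == 1:
        lig = ligands[0]
        p = params[lig]
        N = float(_single_ligand_qss_notch(beta_N, gamma_N, p.beta_D, p.gamma_D, kcs[lig]))
    else:
        def f(N):
            tot = gamma_N * N - beta_N
            for lig in ligands:
                p = params[lig]
                tot += N * p.beta_D / (kcs[lig] * p.gamma_D + N)
            return tot
        hi = beta_N / gamma_N
        N = brentq(f, 0.0, hi, xtol=1e-14 * max(hi, 1.0), rtol=8.9e-16, maxiter=200)

    N = max(N, 0.0)
    D = {lig: params[lig].beta_D / (params[lig].gamma_D + N / kcs[lig]) for lig in ligands}
    C = {}
    for lig in ligands:
        p = params[lig]
        denom = p.kC_minus + p.kI
        C[lig] = p.kC_plus * N * D[lig] / denom if denom > 0 else 0.0

    # residuals of the reduced balance equations
    res = abs(beta_N - N * (gamma_N + sum(D[lig] / kcs[lig] for lig in ligands)))
    scale = max(beta_N, 1.0)
    for lig in ligands:
        p = params[lig]
        res = max(res, abs(p.beta_D - D[lig] * (p.gamma_D + N / kcs[lig])))
        scale = max(scale, p.beta_D)
    if res > tol * scale:
        raise RuntimeError(f"steady-state solve did not converge: residual {res:.3e}")
    return CellState(N=N, D=D, C_cis=C, S=0.0)


def apply_fringe(params: KineticParams, fringe: FringeConfig,
                 ligand: str) -> KineticParams:
    """Return a copy of ``params`` with Fringe-modified association rates.

    Scales kC_plus by the cis factor and kD_plus by the trans factor for the
    given ligand; all other rates are untouched (Fringe is modelled on
    association, not dissociation).
    """
    if fringe.identity != "none":
        known = set(fringe.cis_factor) | set(fringe.trans_factor)
        if ligand not in known:
            raise KeyError(f"ligand {ligand!r} not in fringe factor mappings {sorted(known)}")
    return replace(params,
                   kC_plus=params.kC_plus * fringe.cis(ligand),
                   kD_plus=params.kD_plus * fringe.trans(ligand))


def trans_signal_rate(N_receiver: float, D_sender, params: KineticParams):
    """Quasi-steady signal production rate kS*kD+*N*D/(kD- + kS).

    The trans complex is assumed fast relative to signal accumulation;
    sender ligand is not depleted by this expression.
    """
    D_sender = np.asarray(D_sender, dtype=float)
    if N_receiver < 0 or np.any(D_sender < 0):
        raise ValueError("concentrations must be non-negative")
    denom = params.kD_minus + params.kS
    if params.kD_plus > 0 and denom <= 0:
        raise ValueError("kD_minus + kS must be positive when kD_plus > 0")
    if denom <= 0:
        out = np.zeros_like(D_sender)
        return float(out) if out.ndim == 0 else out
    out = params.kS * params.kD_plus * N_receiver * D_sender / denom
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# packaged presets and parameter I/O

def fringe_preset(name: str) -> FringeConfig:
    """Load a named Fringe preset shipped with the package.

    Available: ``none``/``default``, ``lfng``, ``mfng``, ``rfng`` (mammalian
    ligand names Dll1/Jag1) and ``fng`` (Drosophila Fringe; Delta/Serrate).
    """
    name = name.lower()
    if name == "default":
        name = "none"
    path = resources.files("notchcis.presets").joinpath(f"{name}.yaml")
    try:
        data = yaml.safe_load(path.read_text())
    except FileNotFoundError:
        raise KeyError(f"unknown fringe preset {name!r}") from None
    return FringeConfig(identity=data["identity"],
                        cis_factor=data.get("cis_factor", {}),
                        trans_factor=data.get("trans_factor", {}),
                        detection_gain=float(data.get("detection_gain", 1.0)))


def load_params(path) -> KineticParams:
    """Read kinetic parameters from a YAML or JSON file."""
    with open(path) as fh:
        return KineticParams.from_dict(yaml.safe_load(fh))


def save_params(params: KineticParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
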