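"""Two-phase dorsal-ventral boundary formation on a cell lattice.

Models the first signaling steps at the Drosophila wing-disc
dorsal-ventral interface.  Dorsal cells express Notch, Delta, Serrate and
Fringe; ventral cells express Notch and Delta only.  Fringe on dorsal
Notch strengthens Delta cis-inhibition (keeping dorsal Delta sequestered),
weakens Serrate cis-inhibition (leaving dorsal Serrate free to send), and
re-weights trans-activation (Delta enhanced, Serrate blocked on
Fringe-positive receivers).

Phase 1: dorsal cells trans-activate their ventral neighbours with free
Serrate; dorsal-to-dorsal Serrate signaling is blocked by Fringe.
Phase 2: accumulated signal in activated ventral cells up-regulates their
Delta production through a Hill feedback; these cells switch to a
Delta-sending state and trans-activate the adjacent dorsal row, whose
Fringe-modified Notch responds strongly to Delta.  Flanking ventral cells
receive the same Delta only through unenhanced trans interaction and stay
below the target-gene threshold within the simulated window.

Each cell's free receptor/ligand levels follow the quasi-steady cis
steady state at its current production rates; only the accumulated signal
S and the feedback-controlled Delta production are dynamic variables.
Coupling is between 4-neighbours on a rectangular grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from notchcis.kinetics import (
    KineticParams,
    apply_fringe,
    fringe_preset,
    solve_cis_steady_state,
)
from notchcis.states import classifier_params

__all__ = ["LatticeConfig", "LatticeResult", "simulate_dv_boundary"]

LIGANDS = ("Delta", "Serrate")


@dataclass(frozen=True)
class LatticeConfig:
    """Geometry, expression and feedback parameters of the boundary model.

    ``compartments`` assigns one compartment per row ("dorsal"/"ventral");
    production rates are steady-level * gamma as in the state classifier.
    The ventral Delta feedback multiplies basal production by
    ``1 + feedback_fold * S^n / (S^n + feedback_K^n)``.
    """

    shape: tuple[int, int] = (6, 4)
    compartments: tuple[str, ...] = ("dorsal",) * 3 + ("ventral",) * 3
    dorsal_production: Mapping[str, float] = field(default_factory=lambda: {
        "Notch": 3.0, "Delta": 0.05, "Serrate": 2.0})
    ventral_production: Mapping[str, float] = field(default_factory=lambda: {
        "Notch": 2.0, "Delta": 0.05, "Serrate": 0.0})
    dorsal_fringe: str = "fng"
    ventral_fringe: str = "none"
    feedback_fold: float = 30.0
    feedback_K: float = 25.0
    feedback_n: float = 2.0
    activation_threshold: float = 40.0
    t_end: float = 5.0
    dt: float = 0.02
    noise_sd: float = 0.0       # optional Gaussian noise on dS (per sqrt(dt))

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if len(self.compartments) != rows:
            raise ValueError("one compartment per row required")
        bad = set(self.compartments) - {"dorsal", "ventral"}
        if bad:
            raise ValueError(f"unknown compartments {sorted(bad)}")
        if not ({"dorsal", "ventral"} <= set(self.compartments)) or rows < 2:
            raise ValueError("grid needs >= 2 rows with both compartments present")


@dataclass
class LatticeResult:
    """Per-cell time courses and the end-state activation summary."""

    times: np.ndarray                      # (T,)
    signal: np.ndarray                     # (T, rows, cols) accumulated S
    free_notch: np.ndarray                 # (T, rows, cols)
    free_ligand: dict[str, np.ndarray]     # ligand -> (T, rows, cols)
    activated: np.ndarray                  # (rows, cols) bool at t_end
    crossing_time: np.ndarray              # (rows, cols), NaN if never
    config: LatticeConfig

    def to_long_dataframe(self) -> pd.DataFrame:
        """Long-format (cell, t, variable, value) table for export."""
        rows_, cols_ = self.signal.shape[1:]
        recs = {"signal": self.signal, "free_notch": self.free_notch}
        recs.update({f"free_{l}": v for l, v in self.free_ligand.items()})
        frames = []
        for name, arr in recs.items():
            t_idx, r_idx, c_idx = np.meshgrid(
                np.arange(arr.shape[0]), np.arange(rows_), np.arange(cols_),
                indexing="ij")
            frames.append(pd.DataFrame({
                "row": r_idx.ravel(), "col": c_idx.ravel(),
                "t": self.times[t_idx.ravel()],
                "variable": name, "value": arr.ravel()}))
        return pd.concat(frames, ignore_index=True)


def _neighbors(rows: int, cols: int):
    nbrs = {}
    for r in range(rows):
        for c in range(cols):
            nbrs[(r, c)] = [(r + dr, c + dc)
                            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1))
                            if 0 <= r + dr < rows and 0 <= c + dc < cols]
    return nbrs


def simulate_dv_boundary(config: LatticeConfig | None = None,
                         params: KineticParams | None = None,
                         t_end: float | None = None,
                         seed: int = 0) -> LatticeResult:
    """Integrate the two-phase boundary model.

    At each step every cell's cis steady state is re-solved at its current
    (feedback-dependent) production rates, trans signal fluxes are summed
    over 4-neighbours with the receiver's Fringe-modified trans strengths,
    and accumulated signal advances by forward Euler.  Deterministic for
    ``noise_sd == 0``; otherwise seeded.
    """
    config = LatticeConfig() if config is None else config
    params = classifier_params() if params is None else params
    t_end = config.t_end if t_end is None else t_end
    rows, cols = config.shape
    rng = np.random.default_rng(seed)

    fringes = {"dorsal": fringe_preset(config.dorsal_fringe),
               "ventral": fringe_preset(config.ventral_fringe)}
    productions = {"dorsal": dict(config.dorsal_production),
                   "ventral": dict(config.ventral_production)}
    comp = [config.compartments[r] for r in range(rows)]
    nbrs = _neighbors(rows, cols)

    # receiver-side trans strength per compartment and ligand
    trans_gain = {
        (cp, lig): (params.kS * params.kD_plus * fringes[cp].trans(lig)
                    / (params.kD_minus + params.kS))
        for cp in ("dorsal", "ventral") for lig in LIGANDS}

    times = np.arange(0.0, t_end + 1e-9, config.dt)
    T = times.size
    S = np.zeros((rows, cols))
    sig = np.zeros((T, rows, cols))
    fN = np.zeros((T, rows, cols))
    fL = {lig: np.zeros((T, rows, cols)) for lig in LIGANDS}
    crossing = np.full((rows, cols), np.nan)

    def cell_free_levels(cp: str, s_val: float):
        prod = productions[cp]
        beta_D = {lig: prod.get(lig, 0.0) for lig in LIGANDS}
        if cp == "ventral" and config.feedback_fold > 0:
            n = config.feedback_n
            hill = s_val ** n / (s_val ** n + config.feedback_K ** n) if s_val > 0 else 0.0
            beta_D["Delta"] *= 1.0 + config.feedback_fold * hill
        per_ligand = {}
        for lig in LIGANDS:
            if beta_D[lig] <= 0:
                continue
            p = replace(params, beta_N=prod["Notch"], beta_D=beta_D[lig])
            per_ligand[lig] = apply_fringe(p, fringes[cp], lig)
        if not per_ligand:
            return prod["Notch"] / params.gamma_N, {lig: 0.0 for lig in LIGANDS}
        st = solve_cis_steady_state(per_ligand)
        return st.N, {lig: st.D.get(lig, 0.0) for lig in LIGANDS}

    for ti, t in enumerate(times):
        # quasi-static free levels at current signal
        for r in range(rows):
            for c in range(cols):
                N_free, L_free = cell_free_levels(comp[r], S[r, c])
                fN[ti, r, c] = N_free
                for lig in LIGANDS:
                    fL[lig][ti, r, c] = L_free[lig]
        sig[ti] = S
        newly = (S >= config.activation_threshold) & np.isnan(crossing)
        crossing[newly] = t
        if ti == T - 1:
            break
        # trans input summed over neighbours
        dS = np.zeros((rows, cols))
        for (r, c), nb in nbrs.items():
            total = 0.0
            for (rn, cn) in nb:
                for lig in LIGANDS:
                    total += trans_gain[(comp[r], lig)] * fN[ti, r, c] * fL[lig][ti, rn, cn]
            dS[r, c] = total
        S = S + dS * config.dt
        if config.noise_sd > 0:
            S = S + rng.normal(0.0, config.noise_sd * np.sqrt(config.dt), S.shape)
        S = np.clip(S, 0.0, None)

    activated = sig[-1] >= config.activation_threshold
    return LatticeResult(times=times, signal=sig, free_notch=fN,
                         free_ligand=fL, activated=activated,
                         crossing_time=crossing, config=config)
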