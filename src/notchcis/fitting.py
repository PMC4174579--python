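"""Statistics layer: binned bootstrap profiles, dose-response fits,
per-bin rank-sum comparisons, and reporter-onset detection.

The availability analysis bins single cells along the log of the
effective-total-ligand axis, summarises each bin by its median with a
percentile-bootstrap confidence interval, and fits the single-cell points
(not the bin medians) with either a saturation curve a*D/(D+K) for the
reagent calibration, or the cis-inhibition closed form

    avail(L) = bg + A / (1 + L / L50)

where L50 is the fluorescence analogue of the half-depletion level
kc*gamma_N.  Condition comparisons use the two-sided Wilcoxon rank-sum
test per bin; time-lapse onset times t_on are defined as the first time
the smoothed reporter slope exceeds a fraction (default 10%) of its final
slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from notchcis.synthetic import DilutionTrace

__all__ = [
    "BinnedProfile",
    "SaturationFit",
    "CisFitResult",
    "TOnResult",
    "binned_median_profile",
    "normalize_effective_ligand",
    "normalize_to_uninduced",
    "fit_saturation",
    "fit_cis_inhibition",
    "half_inhibition_ratio",
    "compare_conditions",
    "detect_t_on",
]


@dataclass
class BinnedProfile:
    """Per-bin medians with bootstrap CIs along a log-spaced x axis."""

    bin_edges: np.ndarray
    n: np.ndarray
    median: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_min: int = 10

    @property
    def centers(self) -> np.ndarray:
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])

    @property
    def underpopulated(self) -> np.ndarray:
        return self.n < self.n_min


@dataclass
class SaturationFit:
    a: float
    K: float
    a_stderr: float | None
    K_stderr: float | None
    residual_norm: float
    identifiable: bool = True


@dataclass
class CisFitResult:
    amplitude: float            # availability at zero ligand (above bg)
    L50: float                  # half-inhibition effective-ligand level
    background: float
    amplitude_stderr: float | None
    L50_stderr: float | None
    background_stderr: float | None
    residual_norm: float
    identifiable: bool = True


@dataclass
class TOnResult:
    t_on: float | None
    final_slope: float
    threshold_fraction: float
    ligand_at_t_on: float | None
    onset_detected: bool = True


def binned_median_profile(x, y, n_bins: int = 12, n_boot: int = 1000,
                          level: float = 0.95, seed: int = 0,
                          bin_edges=None, n_min: int = 10) -> BinnedProfile:
    """Median and percentile-bootstrap CI of y in log-spaced bins of x.

    ``x`` must be positive (binning is on log10 x).  Empty bins are
    returned with n=0 and NaN statistics; bins below ``n_min`` are flagged
    via :attr:`BinnedProfile.underpopulated`.  Deterministic for a fixed
    seed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0):
        raise ValueError("x must be positive for log-scale binning")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if bin_edges is None:
        bin_edges = np.logspace(np.log10(x.min()), np.log10(x.max()), n_bins + 1)
    bin_edges = np.asarray(bin_edges, dtype=float)
    rng = np.random.default_rng(seed)
    nb = len(bin_edges) - 1
    idx = np.clip(np.digitize(x, bin_edges) - 1, 0, nb - 1)
    # points exactly at the upper edge belong to the last bin via clip
    n = np.zeros(nb, dtype=int)
    med = np.full(nb, np.nan)
    lo = np.full(nb, np.nan)
    hi = np.full(nb, np.nan)
    alpha = (1.0 - level) / 2.0
    for b in range(nb):
        yy = y[idx == b]
        n[b] = yy.size
        if yy.size == 0:
            continue
        med[b] = np.median(yy)
        if yy.size == 1:
            lo[b] = hi[b] = yy[0]
            continue
        boot = np.median(rng.choice(yy, size=(n_boot, yy.size), replace=True), axis=1)
        lo[b], hi[b] = np.quantile(boot, [alpha, 1.0 - alpha])
    return BinnedProfile(bin_edges=bin_edges, n=n, median=med,
                         ci_low=lo, ci_high=hi, n_min=n_min)


def normalize_effective_ligand(ligand_only_table: pd.DataFrame,
                               reference: str | None = None) -> dict[str, float]:
    """Per-ligand rescaling of the total-ligand axis from ligand-only data.

    For each ligand, the ligand-availability signal of cells expressing
    that ligand alone is regressed through the origin on total-ligand
    fluorescence; the slope measures how efficiently total ligand reaches
    the surface.  Returns ligand -> scale such that multiplying a ligand's
    total-ligand axis by its scale makes different ligands comparable
    ("effective total ligand"); the reference ligand (first by default)
    has scale 1.
    """
    slopes: dict[str, float] = {}
    for ligand, sub in ligand_only_table.groupby("ligand", sort=False):
        if len(sub) < 3:
            raise ValueError(f"need >= 3 ligand-only points for {ligand!r}")
        x = sub["total_ligand_fluor"].to_numpy(float)
        y = sub["availability_fluor"].to_numpy(float)
        slopes[ligand] = float(x @ y / (x @ x))
    if reference is None:
        reference = next(iter(slopes))
    ref = slopes[reference]
    return {lig: m / ref for lig, m in slopes.items()}


def normalize_to_uninduced(profile: BinnedProfile,
                           uninduced_level: float) -> BinnedProfile:
    """Divide a profile's medians and CIs by the uninduced availability level.

    Removes Fringe-dependent detection-gain differences so curves from
    different Fringe backgrounds can be overlaid; the uninduced bin maps
    to 1.
    """
    if uninduced_level <= 0:
        raise ValueError("uninduced_level must be positive")
    return BinnedProfile(bin_edges=profile.bin_edges.copy(), n=profile.n.copy(),
                         median=profile.median / uninduced_level,
                         ci_low=profile.ci_low / uninduced_level,
                         ci_high=profile.ci_high / uninduced_level,
                         n_min=profile.n_min)


def fit_saturation(concentrations, signals) -> SaturationFit:
    """Nonlinear least-squares fit of signal = a*D/(D+K).

    Flags the fit as non-identifiable when K falls outside the sampled
    concentration range (all points far above or below half-saturation)
    or the data carry no signal.
    """
    D = np.asarray(concentrations, dtype=float)
    y = np.asarray(signals, dtype=float)
    if np.unique(D).size < 3:
        raise ValueError("need >= 3 distinct concentrations")
    if not np.any(y > 0):
        return SaturationFit(a=0.0, K=np.nan, a_stderr=None, K_stderr=None,
                             residual_norm=float(np.linalg.norm(y)),
                             identifiable=False)
    model = lmfit.Model(lambda D, a, K: a * D / (D + K), independent_vars=["D"])
    pars = model.make_params(a=float(y.max()),
                             K=float(np.median(D[D > 0])))
    pars["a"].set(min=1e-12)
    pars["K"].set(min=1e-12)
    res = model.fit(y, pars, D=D)
    K = float(res.params["K"].value)
    pos = D[D > 0]
    identifiable = bool(pos.min() / 3 <= K <= pos.max() * 3)
    return SaturationFit(a=float(res.params["a"].value), K=K,
                         a_stderr=_stderr(res, "a"), K_stderr=_stderr(res, "K"),
                         residual_norm=float(np.linalg.norm(res.residual)),
                         identifiable=identifiable)


def fit_cis_inhibition(effective_ligand, availability,
                       log_residuals: bool = True) -> CisFitResult:
    """Fit single-cell availability with avail = bg + A/(1 + L/L50).

    Works on the single-cell points with equal weights.  By default the
    residuals are taken on log availability, which stabilises the
    multiplicative measurement noise typical of fluorescence data; set
    ``log_residuals=False`` for plain least squares.  The fit is flagged
    non-identifiable when L50 lands outside the sampled ligand range or
    the data show no ligand dependence.
    """
    L = np.asarray(effective_ligand, dtype=float)
    y = np.asarray(availability, dtype=float)
    if L.size < 4:
        raise ValueError("need >= 4 points to fit A, L50 and background")
    lo_q, hi_q = np.quantile(L, [0.1, 0.9])
    y_low = float(np.median(y[L <= lo_q]))
    y_high = float(np.median(y[L >= hi_q]))
    a0 = max(y_low - y_high, 1e-6 * max(abs(y_low), 1.0))
    bg0 = max(y_high, 1e-12)
    L500 = float(np.median(L))

    def model(pars):
        A, L50, bg = pars["A"], pars["L50"], pars["bg"]
        return bg + A / (1.0 + L / L50)

    def resid(pars):
        m = model(pars)
        if log_residuals:
            eps = 1e-12
            return np.log(np.clip(m, eps, None)) - np.log(np.clip(y, eps, None))
        return m - y

    pars = lmfit.Parameters()
    pars.add("A", value=a0, min=1e-12)
    pars.add("L50", value=L500, min=1e-12)
    pars.add("bg", value=bg0, min=0.0)
    out = lmfit.minimize(resid, pars)
    A = float(out.params["A"].value)
    L50 = float(out.params["L50"].value)
    bg = float(out.params["bg"].value)
    pos = L[L > 0]
    ident = bool(pos.size and pos.min() <= L50 <= pos.max())
    if y_low <= 0 or abs(y_low - y_high) < 0.05 * max(abs(y_low), 1e-12):
        ident = False  # no detectable ligand dependence
    return CisFitResult(amplitude=A, L50=L50, background=bg,
                        amplitude_stderr=_stderr(out, "A"),
                        L50_stderr=_stderr(out, "L50"),
                        background_stderr=_stderr(out, "bg"),
                        residual_norm=float(np.linalg.norm(out.residual)),
                        identifiable=ident)


def half_inhibition_ratio(fit_a: CisFitResult,
                          fit_b: CisFitResult) -> tuple[float, float]:
    """Ratio L50_a / L50_b with first-order error propagation."""
    if not (fit_a.identifiable and fit_b.identifiable):
        raise ValueError("both fits must be identifiable to form a ratio")
    r = fit_a.L50 / fit_b.L50
    rel = 0.0
    for f in (fit_a, fit_b):
        if f.L50_stderr is not None:
            rel += (f.L50_stderr / f.L50) ** 2
    return r, r * np.sqrt(rel)


def compare_conditions(table_a: pd.DataFrame, table_b: pd.DataFrame,
                       bin_edges, alpha: float = 0.05, n_min: int = 10,
                       x_col: str = "total_ligand_fluor",
                       y_col: str = "availability_fluor",
                       correction: str | None = None) -> pd.DataFrame:
    """Per-bin two-sided Wilcoxon rank-sum comparison of two conditions.

    Both tables are binned on shared log-spaced edges; each bin with at
    least ``n_min`` cells in both tables gets a rank-sum p-value, and bins
    with p < alpha are flagged significant.  ``correction="bh"`` applies
    Benjamini-Hochberg across the tested bins (none by default, matching
    per-bin starring).
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    nb = len(bin_edges) - 1
    rows = []
    for b in range(nb):
        lo, hi = bin_edges[b], bin_edges[b + 1]
        last = b == nb - 1
        sel = lambda t: t[(t[x_col] >= lo) & ((t[x_col] <= hi) if last
                                              else (t[x_col] < hi))][y_col].to_numpy()
        ya, yb = sel(table_a), sel(table_b)
        row = {"bin": b, "bin_low": lo, "bin_high": hi,
               "n_a": ya.size, "n_b": yb.size, "p_value": np.nan,
               "significant": False}
        if ya.size >= n_min and yb.size >= n_min:
            row["p_value"] = stats.mannwhitneyu(ya, yb,
                                                alternative="two-sided").pvalue
        rows.append(row)
    out = pd.DataFrame(rows)
    tested = out["p_value"].notna()
    if correction == "bh" and tested.any():
        adj = stats.false_discovery_control(out.loc[tested, "p_value"], method="bh")
        out.loc[tested, "p_adj"] = adj
        out.loc[tested, "significant"] = adj < alpha
    else:
        out.loc[tested, "significant"] = out.loc[tested, "p_value"] < alpha
    return out


def detect_t_on(trace: DilutionTrace, threshold_fraction: float = 0.10,
                smoothing_frames: int = 3,
                final_window_fraction: float = 0.20) -> TOnResult:
    """Onset time of reporter activity in a dilution trace.

    The reporter series is smoothed with a moving average, its slope
    estimated by centred finite differences, and the final slope averaged
    over the last ``final_window_fraction`` of frames; t_on is the first
    time the slope strictly exceeds ``threshold_fraction`` of the final
    slope.  Also reports the ligand fluorescence at t_on.  A non-positive
    final slope yields a flagged no-onset result.  The detection is
    invariant to rescaling the reporter by any positive constant.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    t = np.asarray(trace.t, dtype=float)
    if t.size < 5:
        raise ValueError("need >= 5 frames")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    y = np.asarray(trace.reporter_fluor, dtype=float)
    k = max(1, int(smoothing_frames))
    kernel = np.ones(k) / k
    pad = k // 2
    ypad = np.pad(y, pad, mode="edge")
    ys = np.convolve(ypad, kernel, mode="valid")[: t.size]
    slope = np.gradient(ys, t)
    n_final = max(2, int(np.ceil(final_window_fraction * t.size)))
    final_slope = float(slope[-n_final:].mean())
    if final_slope <= 0:
        return TOnResult(t_on=None, final_slope=final_slope,
                         threshold_fraction=threshold_fraction,
                         ligand_at_t_on=None, onset_detected=False)
    above = slope > threshold_fraction * final_slope
    if not above.any():
        return TOnResult(t_on=None, final_slope=final_slope,
                         threshold_fraction=threshold_fraction,
                         ligand_at_t_on=None, onset_detected=False)
    i = int(np.argmax(above))
    return TOnResult(t_on=float(t[i]), final_slope=final_slope,
                     threshold_fraction=threshold_fraction,
                     ligand_at_t_on=float(trace.ligand_fluor[i]))


def _stderr(result, name: str) -> float | None:
    p = result.params[name]
    return float(p.stderr) if p.stderr is not None else None
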