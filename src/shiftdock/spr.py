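"""1:1 single-site SPR analysis: kinetic and steady-state affinity fits.

The model is the ideal 1:1 Langmuir interaction A + B ⇌ AB with
association rate constant k_a (M⁻¹ s⁻¹), dissociation rate constant
k_d (s⁻¹) and surface capacity R_max (RU). For an analyte concentration C
the response follows

    association   R(t) = R_eq · (1 − exp(−(k_a·C + k_d)·t)),
                  R_eq = k_a·C·R_max / (k_a·C + k_d)
    dissociation  R(t) = R(t_assoc) · exp(−k_d·(t − t_assoc))

and the steady-state isotherm is R_eq(C) = R_max·C/(K_D + C) with
K_D = k_d/k_a. The kinetic fit is global: one (k_a, k_d, R_max) shared
across the whole concentration series. No mass-transport, bulk-shift or
drift terms are modelled.

Sensorgrams are read and written as CSV with columns
``conc_M,time_s,response_RU,phase`` (phase ``assoc`` or ``dissoc``).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "Sensorgram",
    "KineticFit",
    "SteadyStateFit",
    "FitError",
    "req_isotherm",
    "response_1to1",
    "fit_kinetic_1to1",
    "extract_steady_state",
    "fit_steady_state",
    "read_sensorgrams_csv",
    "write_sensorgrams_csv",
]


class FitError(RuntimeError):
    """Raised when a fit cannot be formulated or degenerates."""


@dataclass
class Sensorgram:
    """One analyte concentration's response time series.

    ``t_assoc_end`` marks the injection stop (start of dissociation).
    """

    concentration: float          # M
    times: np.ndarray             # s, strictly increasing
    responses: np.ndarray         # RU
    t_assoc_end: float            # s

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.responses = np.asarray(self.responses, float)
        if self.times.ndim != 1 or self.times.shape != self.responses.shape:
            raise ValueError("times and responses must be 1-D and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.isfinite(self.responses).all():
            raise ValueError("non-finite responses")
        if not (self.times[0] <= self.t_assoc_end <= self.times[-1]):
            raise ValueError("t_assoc_end outside the time range")
        if self.concentration <= 0:
            raise ValueError("analyte concentration must be positive")

    @property
    def assoc_mask(self) -> np.ndarray:
        return self.times <= self.t_assoc_end

    @property
    def dissoc_mask(self) -> np.ndarray:
        return self.times > self.t_assoc_end


def req_isotherm(conc: np.ndarray | float, kd_equilibrium: float, rmax: float):
    """Steady-state binding isotherm R_eq(C) = R_max·C/(K_D + C)."""
    conc = np.asarray(conc, float)
    return rmax * conc / (kd_equilibrium + conc)


def response_1to1(times: np.ndarray, conc: float, ka: float, kd: float,
                  rmax: float, t_assoc_end: float) -> np.ndarray:
    """Closed-form 1:1 response for one concentration over assoc+dissoc."""
    times = np.asarray(times, float)
    kobs = ka * conc + kd
    req = ka * conc * rmax / kobs
    r_assoc = req * (1.0 - np.exp(-kobs * np.minimum(times, t_assoc_end)))
    r_end = req * (1.0 - math.exp(-kobs * t_assoc_end))
    r_dissoc = r_end * np.exp(-kd * np.maximum(times - t_assoc_end, 0.0))
    return np.where(times <= t_assoc_end, r_assoc, r_dissoc)


@dataclass
class KineticFit:
    """Global 1:1 kinetic fit result. ``KD = kd/ka`` by construction."""

    ka: float                     # 1/(M s)
    kd: float                     # 1/s
    rmax: float                   # RU
    kd_equilibrium: float         # M (= kd/ka)
    se_ka: float
    se_kd: float
    se_rmax: float
    se_kd_equilibrium: float
    rss: float
    n_points: int
    converged: bool
    message: str = ""

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "ka": self.ka, "kd": self.kd, "Rmax": self.rmax,
            "KD": self.kd_equilibrium,
            "se_ka": self.se_ka, "se_kd": self.se_kd, "se_Rmax": self.se_rmax,
            "se_KD": self.se_kd_equilibrium,
            "rss": self.rss, "n_points": self.n_points,
            "converged": self.converged, "message": self.message,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class SteadyStateFit:
    """Isotherm fit of R_eq vs C."""

    kd_equilibrium: float         # M
    rmax: float                   # RU
    se_kd_equilibrium: float
    se_rmax: float
    rss: float
    n_points: int
    converged: bool
    warnings: tuple[str, ...] = ()
    message: str = ""

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "KD": self.kd_equilibrium, "Rmax": self.rmax,
            "se_KD": self.se_kd_equilibrium, "se_Rmax": self.se_rmax,
            "rss": self.rss, "n_points": self.n_points,
            "converged": self.converged, "warnings": list(self.warnings),
            "message": self.message,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


# ------------------------------------------------------------- kinetic fit


def _loglinear_slope(t: np.ndarray, y: np.ndarray) -> float:
    """Slope of ln(y) vs t over the samples with y > 0."""
    mask = y > 0
    if mask.sum() < 3:
        raise FitError("too few positive samples for log-linear regression")
    return float(np.polyfit(t[mask], np.log(y[mask]), 1)[0])


def _initial_guess(sensorgrams: Sequence[Sensorgram]) -> tuple[float, float, float]:
    """Data-driven (ka, kd, Rmax) start per the documented recipe.

    kd from the log-linear dissociation tail of the highest concentration;
    per-curve k_obs from log-linear regression of (R_eq_est − R) during
    association; ka from the slope of k_obs vs C; Rmax by rescaling the
    largest plateau through the isotherm.
    """
    top = max(sensorgrams, key=lambda s: s.concentration)
    td = top.times[top.dissoc_mask]
    rd = top.responses[top.dissoc_mask]
    kd0 = -_loglinear_slope(td - td[0], rd)
    kd0 = max(kd0, 1e-8)

    kobs_list, conc_list = [], []
    for s in sensorgrams:
        ta = s.times[s.assoc_mask]
        ra = s.responses[s.assoc_mask]
        n_tail = max(3, len(ra) // 10)
        req_est = float(ra[-n_tail:].mean())
        deficit = req_est - ra
        # keep the early, well-resolved part of the approach
        keep = deficit > max(1e-12, 0.05 * abs(req_est))
        if keep.sum() >= 3:
            try:
                kobs = -_loglinear_slope(ta[keep], deficit[keep])
            except FitError:
                continue
            if kobs > 0:
                kobs_list.append(kobs)
                conc_list.append(s.concentration)
    if len(kobs_list) >= 2:
        ka0 = float(np.polyfit(conc_list, kobs_list, 1)[0])
    else:
        ka0 = 0.0
    if ka0 <= 0:
        # fall back to the mean single-curve estimate
        if kobs_list:
            ka0 = max((np.mean(kobs_list) - kd0), 1e-3) / np.mean(conc_list)
        else:
            ka0 = 1e4
    ka0 = max(ka0, 1e-2)

    top_assoc = top.responses[top.assoc_mask]
    n_tail = max(3, len(top_assoc) // 10)
    req_top = float(top_assoc[-n_tail:].mean())
    kobs_top = ka0 * top.concentration + kd0
    sat = ka0 * top.concentration / kobs_top
    rmax0 = abs(req_top) / max(sat, 1e-6)
    rmax0 = max(rmax0, 1e-6)
    return ka0, kd0, rmax0


def fit_kinetic_1to1(sensorgrams: Sequence[Sensorgram]) -> KineticFit:
    """Globally fit (k_a, k_d, R_max) across a concentration series.

    Requires ≥2 distinct concentrations (a single curve cannot jointly
    identify k_a and R_max) and ≥10 samples in each phase of each curve.
    Parameters are optimized in log space, which enforces positivity and
    equilibrates scales; standard errors come from the Jacobian-based
    covariance at the optimum, mapped back by the delta method.

    Raises
    ------
    FitError
        If the optimizer fails to converge; the error carries the solver
        diagnostics rather than returning silent defaults.
    """
    if not sensorgrams:
        raise ValueError("no sensorgrams given")
    concs = sorted({s.concentration for s in sensorgrams})
    if len(concs) < 2:
        raise FitError(
            "kinetic 1:1 fit needs ≥2 distinct concentrations: ka and Rmax "
            "are not jointly identifiable from a single curve in general"
        )
    for s in sensorgrams:
        if s.assoc_mask.sum() < 10 or s.dissoc_mask.sum() < 10:
            raise ValueError(
                f"curve at {s.concentration:g} M needs ≥10 samples per phase"
            )

    theta0 = np.log(_initial_guess(sensorgrams))

    def residuals(theta: np.ndarray) -> np.ndarray:
        ka, kd, rmax = np.exp(theta)
        parts = [
            s.responses - response_1to1(s.times, s.concentration, ka, kd,
                                        rmax, s.t_assoc_end)
            for s in sensorgrams
        ]
        return np.concatenate(parts)

    result = least_squares(residuals, theta0, method="lm",
                           xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000)
    if not result.success:
        raise FitError(
            f"kinetic fit did not converge: status {result.status}, "
            f"{result.message}; final cost {result.cost:.3e}"
        )
    ka, kd, rmax = np.exp(result.x)
    n = result.fun.size
    rss = float(result.fun @ result.fun)
    se_log = _se_from_jacobian(result.jac, rss, n)
    se_ka, se_kd, se_rmax = np.array([ka, kd, rmax]) * se_log
    # KD = kd/ka; in log space var(log KD) = var + var − 2 cov
    cov_log = _cov_from_jacobian(result.jac, rss, n)
    var_log_kd_eq = cov_log[1, 1] + cov_log[0, 0] - 2 * cov_log[0, 1]
    kd_eq = kd / ka
    se_kd_eq = kd_eq * math.sqrt(max(var_log_kd_eq, 0.0))
    return KineticFit(
        ka=float(ka), kd=float(kd), rmax=float(rmax), kd_equilibrium=float(kd_eq),
        se_ka=float(se_ka), se_kd=float(se_kd), se_rmax=float(se_rmax),
        se_kd_equilibrium=float(se_kd_eq),
        rss=rss, n_points=n, converged=True, message=result.message,
    )


def _cov_from_jacobian(jac: np.ndarray, rss: float, n: int) -> np.ndarray:
    p = jac.shape[1]
    dof = max(n - p, 1)
    s2 = rss / dof
    jtj = jac.T @ jac
    try:
        return np.linalg.inv(jtj) * s2
    except np.linalg.LinAlgError:
        return np.full((p, p), np.nan)


def _se_from_jacobian(jac: np.ndarray, rss: float, n: int) -> np.ndarray:
    cov = _cov_from_jacobian(jac, rss, n)
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))


# -------------------------------------------------------- steady state


def extract_steady_state(sensorgrams: Sequence[Sensorgram], window: float,
                         plateau_rtol: float = 0.01) -> pd.DataFrame:
    """Average the last ``window`` seconds of association per curve.

    Returns a DataFrame with columns ``conc_M``, ``Req``, ``slope_RU_per_s``
    and ``equilibrated``. A curve is flagged not-at-equilibrium when the
    projected change over the window, |slope|·window, exceeds
    ``plateau_rtol`` of the plateau estimate.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    for s in sorted(sensorgrams, key=lambda s: s.concentration):
        if window > s.t_assoc_end - s.times[s.assoc_mask][0]:
            raise ValueError(
                f"window {window:g} s exceeds association phase "
                f"({s.t_assoc_end:g} s) at {s.concentration:g} M"
            )
        mask = s.assoc_mask & (s.times >= s.t_assoc_end - window)
        t, r = s.times[mask], s.responses[mask]
        req = float(r.mean())
        slope = float(np.polyfit(t, r, 1)[0]) if len(t) > 2 else 0.0
        scale = max(abs(req), 1e-12)
        rows.append({
            "conc_M": s.concentration,
            "Req": req,
            "slope_RU_per_s": slope,
            "equilibrated": bool(abs(slope) * window <= plateau_rtol * scale),
        })
    return pd.DataFrame(rows)


def fit_steady_state(conc: Sequence[float] | pd.DataFrame,
                     req: Sequence[float] | None = None) -> SteadyStateFit:
    """Fit R_eq(C) = R_max·C/(K_D + C) by nonlinear least squares.

    Accepts either the DataFrame from :func:`extract_steady_state` or two
    parallel sequences (concentrations in M, plateau responses in RU).
    Needs ≥4 concentrations. Attaches warnings when the concentration range
    spans less than 4-fold or does not bracket the fitted K_D.
    """
    if isinstance(conc, pd.DataFrame):
        table = conc
        c = np.asarray(table["conc_M"], float)
        r = np.asarray(table["Req"], float)
    else:
        c = np.asarray(conc, float)
        r = np.asarray(req, float)
    if c.size < 4:
        raise ValueError(f"steady-state fit needs ≥4 concentrations, got {c.size}")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    if np.allclose(r, r[0]):
        raise FitError("all responses equal: isotherm fit is degenerate")

    rmax0 = 1.05 * float(np.max(np.abs(r)))
    half = 0.5 * float(np.max(r))
    kd0 = float(np.interp(half, np.sort(r), c[np.argsort(r)]))
    kd0 = min(max(kd0, c.min() * 1e-3), c.max() * 1e3)
    theta0 = np.log([max(kd0, 1e-15), max(rmax0, 1e-12)])

    def residuals(theta):
        kd_eq, rmax = np.exp(theta)
        return r - req_isotherm(c, kd_eq, rmax)

    result = least_squares(residuals, theta0, method="lm",
                           xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20000)
    if not result.success:
        raise FitError(f"steady-state fit did not converge: {result.message}")
    kd_eq, rmax = np.exp(result.x)
    n = result.fun.size
    rss = float(result.fun @ result.fun)
    se_log = _se_from_jacobian(result.jac, rss, n)
    notes = []
    if c.max() / c.min() < 4.0:
        notes.append(
            f"concentration series spans only {c.max() / c.min():.2g}-fold "
            "(<4-fold): KD poorly constrained"
        )
    if not (c.min() <= kd_eq <= c.max()):
        notes.append(
            f"fitted KD {kd_eq:.3g} M outside the measured concentration "
            f"range [{c.min():.3g}, {c.max():.3g}] M"
        )
    for note in notes:
        warnings.warn(note, stacklevel=2)
    return SteadyStateFit(
        kd_equilibrium=float(kd_eq), rmax=float(rmax),
        se_kd_equilibrium=float(kd_eq * se_log[0]),
        se_rmax=float(rmax * se_log[1]),
        rss=rss, n_points=int(n), converged=True,
        warnings=tuple(notes), message=result.message,
    )


# --------------------------------------------------------------- CSV IO


def write_sensorgrams_csv(sensorgrams: Sequence[Sensorgram], path: str | Path) -> None:
    """Write the ``conc_M,time_s,response_RU,phase`` dialect."""
    frames = []
    for s in sorted(sensorgrams, key=lambda s: s.concentration):
        phase = np.where(s.times <= s.t_assoc_end, "assoc", "dissoc")
        frames.append(pd.DataFrame({
            "conc_M": np.repeat(s.concentration, s.times.size),
            "time_s": s.times,
            "response_RU": s.responses,
            "phase": phase,
        }))
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.10g")


def read_sensorgrams_csv(path: str | Path) -> list[Sensorgram]:
    """Read the sensorgram CSV dialect back into per-concentration curves."""
    try:
        table = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parse error types
        raise FitError(f"{path}: unreadable sensorgram CSV: {exc}") from exc
    required = {"conc_M", "time_s", "response_RU", "phase"}
    missing = required - set(table.columns)
    if missing:
        raise FitError(f"{path}: missing columns {sorted(missing)}")
    for col in ("conc_M", "time_s", "response_RU"):
        table[col] = pd.to_numeric(table[col], errors="coerce")
    bad = table[
        table["conc_M"].isna() | table["time_s"].isna()
        | table["response_RU"].isna() | ~table["phase"].isin(["assoc", "dissoc"])
    ]
    if not bad.empty:
        # +2: header line plus 1-based counting
        raise FitError(
            f"{path}: corrupted row at line {int(bad.index[0]) + 2}"
        )
    out = []
    for conc, grp in table.groupby("conc_M", sort=True):
        grp = grp.sort_values("time_s")
        assoc_times = grp.loc[grp["phase"] == "assoc", "time_s"]
        if assoc_times.empty:
            raise FitError(f"{path}: no association samples at {conc:g} M")
        out.append(Sensorgram(
            concentration=float(conc),
            times=grp["time_s"].to_numpy(),
            responses=grp["response_RU"].to_numpy(),
            t_assoc_end=float(assoc_times.max()),
        ))
    return out
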