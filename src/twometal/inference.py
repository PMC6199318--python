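"""Estimation pipeline: trace-level velocity measurement, velocity-curve
fitting, disorder-width estimation, log-velocity histogram prediction,
off-rate grid search, and pause statistics."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .master_equation import (
    DisorderSpec,
    disorder_average_pdf,
    logV_transform,
)
from .model_core import (
    ModelSpec,
    ModelVariant,
    RateConstants,
)
from .stochastic_simulator import FretTrace, PauseRecord

__all__ = [
    "VelocityDataset",
    "FitResult",
    "FitError",
    "SigmaEstimate",
    "LogVHistogram",
    "KAoffEstimate",
    "PauseSummary",
    "compute_fret",
    "measure_velocity_from_trace",
    "fit_velocity_curve",
    "estimate_sigma",
    "predict_logV_histogram",
    "estimate_kAoff",
    "pause_statistics",
]

LOG10E = math.log10(math.e)

_DATASET_COLUMNS = ("mg_mM", "velocity_nt_s", "trace_id")


class FitError(RuntimeError):
    """No optimizer start converged."""


@dataclass
class VelocityDataset:
    """Per-trace velocities tagged with their ion concentration.

    ``records`` has columns ``mg_mM``, ``velocity_nt_s``, ``trace_id``.
    Aggregates (mean, SEM, count) are always recomputed from the records,
    never stored.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _DATASET_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"velocity dataset is missing columns: {missing}")
        self.records = self.records.loc[:, list(_DATASET_COLUMNS)].reset_index(drop=True)
        bad = self.records.index[
            ~(self.records["velocity_nt_s"] > 0) | ~(self.records["mg_mM"] > 0)
        ].tolist()
        if bad:
            raise ValueError(
                f"velocities and concentrations must be positive; offending rows: {bad}"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def concentrations(self) -> np.ndarray:
        return np.sort(self.records["mg_mM"].unique())

    def velocities_at(self, c: float) -> np.ndarray:
        return self.records.loc[self.records["mg_mM"] == c, "velocity_nt_s"].to_numpy()

    def aggregates(self) -> pd.DataFrame:
        """Per-condition mean, SEM (= sd / sqrt(count)) and count."""
        g = self.records.groupby("mg_mM")["velocity_nt_s"]
        out = g.agg(mean="mean", count="count")
        out["sem"] = g.std(ddof=1).fillna(0.0) / np.sqrt(out["count"])
        return out


@dataclass(frozen=True)
class FitResult:
    """Converged nonlinear-least-squares fit of a velocity curve."""

    model: str
    params: dict
    units: dict
    rss: float
    converged: bool
    n_conditions: int
    param_se: dict | None = None

    def predict(self, c: float) -> float:
        from . import model_core as mc

        if self.model == "model1":
            p = self.params
            rates = RateConstants(
                k_B_off=p["k_B_off"],
                k_B_b=p["k_B_off"] / p["K_B"],
                k_A_off=1.0,
                k_A_b=1.0 / p["K_A"],
            )
            return mc.mean_velocity(ModelSpec(ModelVariant.MODEL1, rates), c)
        if self.model == "mm":
            return mc.mm_velocity(self.params["v_max"], self.params["K_m"], c)
        if self.model == "hill":
            return mc.hill_velocity(
                mc.HillParams(self.params["v_max"], self.params["K"], self.params["n"]), c
            )
        raise ValueError(f"unknown model {self.model!r}")


def compute_fret(donor, acceptor, crosstalk: float = 0.0):
    """Ratiometric FRET efficiency with optional donor-leakage correction.

    ``E = (A - x D) / (D + (A - x D))`` with the corrected acceptor clipped
    at 0.  Samples where both intensities are 0 yield NaN (an undefined
    sample, not an error).  Accepts scalars or arrays.
    """
    donor_a = np.asarray(donor, dtype=float)
    acceptor_a = np.asarray(acceptor, dtype=float)
    if np.any(donor_a < 0) or np.any(acceptor_a < 0):
        raise ValueError("intensities must be non-negative")
    if not 0 <= crosstalk < 1:
        raise ValueError("crosstalk must lie in [0, 1)")
    corrected = np.clip(acceptor_a - crosstalk * donor_a, 0.0, None)
    denom = donor_a + corrected
    with np.errstate(invalid="ignore", divide="ignore"):
        eff = np.where(denom > 0, corrected / np.where(denom > 0, denom, 1.0), np.nan)
    if np.isscalar(donor) and np.isscalar(acceptor):
        return float(eff)
    return eff


def measure_velocity_from_trace(
    trace: FretTrace,
    low_frac: float = 0.05,
    high_frac: float = 0.95,
    *,
    n_sites: int | None = None,
    e_min: float | None = None,
    e_max: float | None = None,
    smooth_frames: int = 3,
) -> float:
    """Degradation velocity (nt/s) from the rise of a FRET trace.

    The degradation time is the interval between the last sample at or below
    ``e_min + low_frac * range`` preceding the rise and the first sample at
    or above ``e_min + high_frac * range``.  That interval covers the
    degradation of ``(high_frac - low_frac) * n_sites`` nucleotides, so the
    velocity is scaled accordingly (for ``low_frac = 0, high_frac = 1`` this
    reduces to ``n_sites / time``).  Crossings are detected on a centered
    ``smooth_frames``-point moving average (1 disables smoothing); otherwise
    camera noise makes the first-crossing/last-crossing order statistics
    strongly biased.  Returns NaN when the thresholds are never crossed
    (no degradation event).
    """
    if not 0 <= low_frac < high_frac <= 1:
        raise ValueError("need 0 <= low_frac < high_frac <= 1")
    if smooth_frames < 1:
        raise ValueError("smooth_frames must be >= 1")
    meta = trace.metadata
    n_sites = n_sites if n_sites is not None else meta.get("n_sites", 20)
    e_min = e_min if e_min is not None else meta.get("e_min", 0.26)
    e_max = e_max if e_max is not None else meta.get("e_max", 0.53)
    span = e_max - e_min
    low_thr = e_min + low_frac * span
    high_thr = e_min + high_frac * span
    fret = trace.fret
    if smooth_frames > 1 and len(fret) > smooth_frames:
        kernel = np.ones(smooth_frames) / smooth_frames
        norm = np.convolve(np.ones_like(fret), kernel, mode="same")
        fret = np.convolve(fret, kernel, mode="same") / norm
    high_idx = np.nonzero(fret >= high_thr)[0]
    if len(high_idx) == 0:
        return math.nan
    hi = high_idx[0]
    low_idx = np.nonzero(fret[:hi] <= low_thr)[0]
    if len(low_idx) == 0:
        return math.nan
    lo = low_idx[-1]
    dt = trace.times[hi] - trace.times[lo]
    if dt <= 0:
        return math.nan
    return (high_frac - low_frac) * n_sites / dt


# ---------------------------------------------------------------------------
# velocity-curve fitting


def _model_functions(model: str):
    if model == "model1":
        names = ("k_B_off", "K_B", "K_A")
        units = {"k_B_off": "s^-1", "K_B": "mM", "K_A": "mM"}

        def f(c, p):
            kBoff, KB, KA = p
            return kBoff * c / (c + KB + KB * KA / c)

    elif model == "mm":
        names = ("v_max", "K_m")
        units = {"v_max": "nt s^-1", "K_m": "mM"}

        def f(c, p):
            vmax, Km = p
            return vmax * c / (c + Km)

    elif model == "hill":
        names = ("v_max", "K", "n")
        units = {"v_max": "nt s^-1", "K": "mM", "n": ""}

        def f(c, p):
            vmax, K, n = p
            cn = np.power(c, n)
            return vmax * cn / (cn + np.power(K, n))

    else:
        raise ValueError(f"unknown model {model!r}; choose model1, mm or hill")
    return names, units, f


def _initial_guesses(model: str, c: np.ndarray, v: np.ndarray) -> list[np.ndarray]:
    """MM-derived start plus deterministic +/-50% perturbations."""
    v_max0 = float(v.max()) * 1.05
    half = v_max0 / 2.0
    above = np.nonzero(v >= half)[0]
    K0 = float(c[above[0]]) if len(above) else float(np.median(c))
    K0 = max(K0, 1e-6)
    if model == "model1":
        base = np.array([v_max0, K0, K0 / 2.0])
    elif model == "mm":
        base = np.array([v_max0, K0])
    else:
        base = np.array([v_max0, K0, 1.5])
    starts = [base]
    for scale in (0.5, 1.5):
        starts.append(base * scale)
    starts.append(base * np.array([1.0] + [0.5] * (len(base) - 1)))
    starts.append(base * np.array([1.0] + [1.5] * (len(base) - 1)))
    starts.append(base * np.array([1.5] + [0.5] * (len(base) - 1)))
    return starts


def fit_velocity_curve(
    data: VelocityDataset,
    model: str = "model1",
    *,
    sem_weighted: bool = False,
) -> FitResult:
    """Bounded nonlinear least squares on per-condition mean velocities.

    Multi-start (6 deterministic initializations derived from an MM-style
    guess); the best converged residual sum of squares is kept.  Positivity
    is enforced through bounds.  ``sem_weighted=True`` divides residuals by
    the per-condition SEM (conditions with zero SEM get the smallest
    positive SEM observed).
    """
    names, units, f = _model_functions(model)
    agg = data.aggregates()
    c = agg.index.to_numpy(dtype=float)
    v = agg["mean"].to_numpy()
    if len(c) < len(names):
        raise ValueError(
            f"{model} needs at least {len(names)} distinct concentrations, got {len(c)}"
        )
    if sem_weighted:
        sem = agg["sem"].to_numpy().copy()
        positive = sem[sem > 0]
        sem[sem == 0] = positive.min() if len(positive) else 1.0
        weights = 1.0 / sem
    else:
        weights = np.ones_like(v)

    def residuals(p):
        return (f(c, p) - v) * weights

    lower = np.full(len(names), 1e-9)
    upper = np.full(len(names), np.inf)
    if model == "hill":
        upper[2] = 10.0
    best = None
    for start in _initial_guesses(model, c, v):
        start = np.clip(start, lower * 1.01, None)
        try:
            sol = least_squares(residuals, start, bounds=(lower, upper), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:  # singular jacobian from a pathological start
            continue
        if not sol.success:
            continue
        rss = float(np.sum((f(c, sol.x) - v) ** 2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        raise FitError(
            f"no start converged for model {model!r} on {len(c)} conditions"
        )
    rss, sol = best
    se = _gauss_newton_se(sol, residuals, len(c))
    return FitResult(
        model=model,
        params={name: float(val) for name, val in zip(names, sol.x)},
        units=units,
        rss=rss,
        converged=True,
        n_conditions=len(c),
        param_se=None if se is None else {n: float(s) for n, s in zip(names, se)},
    )


def _gauss_newton_se(sol, residuals, n_obs: int):
    dof = n_obs - len(sol.x)
    if dof <= 0:
        return None
    try:
        J = sol.jac
        cov = np.linalg.inv(J.T @ J) * (2 * sol.cost / dof)
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return None


# ---------------------------------------------------------------------------
# disorder width


@dataclass(frozen=True)
class SigmaEstimate:
    """Gaussian width of the log10-velocity distribution.

    ``sigma_zeta`` is in log10-velocity units; ``sigma_kbt`` is the
    corresponding activation-free-energy spread ``sigma_zeta / log10(e)``.
    When an intrinsic (disorder-free) width is supplied, the corrected value
    subtracts it in quadrature before converting.
    """

    sigma_zeta: float
    sigma_kbt: float
    sigma_kbt_corrected: float | None = None


def estimate_sigma(
    velocities: Sequence[float], *, intrinsic_sigma_zeta: float | None = None
) -> SigmaEstimate:
    """Fit a Gaussian to the log10 velocities and report its width.

    Requires at least 20 velocities.  A degenerate all-equal input yields
    zero with a warning rather than an error.
    """
    v = np.asarray(velocities, dtype=float)
    if len(v) < 20:
        raise ValueError(f"need at least 20 velocities, got {len(v)}")
    if np.any(v <= 0):
        raise ValueError("velocities must be positive")
    zeta = np.log10(v)
    sigma_zeta = float(np.std(zeta, ddof=1))
    if sigma_zeta == 0:
        warnings.warn("all velocities identical; sigma estimated as 0", stacklevel=2)
    corrected = None
    if intrinsic_sigma_zeta is not None:
        corrected = (
            math.sqrt(max(sigma_zeta**2 - intrinsic_sigma_zeta**2, 0.0)) / LOG10E
        )
    return SigmaEstimate(
        sigma_zeta=sigma_zeta,
        sigma_kbt=sigma_zeta / LOG10E,
        sigma_kbt_corrected=corrected,
    )


# ---------------------------------------------------------------------------
# log-velocity histograms and off-rate estimation


@dataclass(frozen=True)
class LogVHistogram:
    """Histogram over zeta = log10(velocity) with shared-edge semantics."""

    edges: np.ndarray
    probs: np.ndarray
    count: int | None = None

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        probs = np.asarray(self.probs, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be strictly increasing")
        if len(probs) != len(edges) - 1:
            raise ValueError("probs must have len(edges) - 1 entries")
        # 1e-6 headroom: model-predicted histograms carry trapezoid-quadrature
        # error; empirical ones are exact fractions
        if np.any(probs < 0) or probs.sum() > 1 + 1e-6:
            raise ValueError("probabilities must be non-negative and sum to <= 1")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "probs", probs)

    @classmethod
    def from_velocities(cls, velocities, edges) -> "LogVHistogram":
        v = np.asarray(velocities, dtype=float)
        if np.any(v <= 0):
            raise ValueError("velocities must be positive")
        counts, _ = np.histogram(np.log10(v), bins=np.asarray(edges, dtype=float))
        return cls(edges=edges, probs=counts / len(v), count=len(v))

    @staticmethod
    def default_edges(zeta_min: float, zeta_max: float, bin_width: float = 0.1):
        n = int(math.ceil((zeta_max - zeta_min) / bin_width))
        return zeta_min + bin_width * np.arange(n + 1)


def predict_logV_histogram(
    spec: ModelSpec,
    c,
    d: DisorderSpec,
    edges,
    grid: np.ndarray | None = None,
) -> LogVHistogram:
    """Bin probabilities of the disorder-averaged log10-velocity density.

    Integrates the zeta-space density over each bin via its cumulative
    trapezoid, so the probabilities sum to the mass captured by the edges.
    """
    pdf = disorder_average_pdf(spec, c, d, grid)
    zpdf = logV_transform(pdf, spec.n_sites)
    cum = np.concatenate(
        [[0.0], np.cumsum(np.diff(zpdf.grid) * (zpdf.density[1:] + zpdf.density[:-1]) / 2.0)]
    )
    cum = np.minimum(cum, 1.0)  # quadrature overshoot cannot exceed certainty
    edges = np.asarray(edges, dtype=float)
    cdf_at_edges = np.interp(edges, zpdf.grid, cum, left=0.0, right=cum[-1])
    return LogVHistogram(edges=edges, probs=np.clip(np.diff(cdf_at_edges), 0.0, None))


@dataclass(frozen=True)
class KAoffEstimate:
    """Grid-search result: selected off-rate and the full MSE table."""

    best: float
    mse: dict


def estimate_kAoff(
    candidates: Sequence[float],
    observed: Mapping[float, LogVHistogram],
    base_rates: RateConstants,
    d: DisorderSpec,
    *,
    n_sites: int = 20,
    variant: ModelVariant = ModelVariant.MODEL1,
) -> KAoffEstimate:
    """Select the A-site off-rate whose predicted histograms best match.

    For each candidate ``k``, the binding rate is set to ``k / K_A`` so the
    A-site equilibrium constant of ``base_rates`` is preserved, predicted
    histograms are computed on the observed bin edges at every condition, and
    the mean square error ``sum_c sum_bins (obs - pred)^2`` accumulated.
    Returns the argmin; ties break toward the smaller candidate.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate off-rates")
    K_A = base_rates.K_A
    mse_table: dict[float, float] = {}
    for k in sorted(candidates):
        rates = RateConstants(
            k_B_off=base_rates.k_B_off,
            k_B_b=base_rates.k_B_b,
            k_A_off=k,
            k_A_b=k / K_A,
        )
        spec = ModelSpec(variant, rates, n_sites)
        total = 0.0
        for conc, hist in observed.items():
            pred = predict_logV_histogram(spec, conc, d, hist.edges)
            total += float(np.sum((hist.probs - pred.probs) ** 2))
        mse_table[float(k)] = total
    best = min(mse_table, key=lambda k: (mse_table[k], k))
    return KAoffEstimate(best=best, mse={float(k): mse_table[float(k)] for k in candidates})


# ---------------------------------------------------------------------------
# pause statistics


@dataclass(frozen=True)
class PauseSummary:
    """Summary of pauses above the reporting threshold."""

    n_pauses: int
    mean_duration: float
    durations: np.ndarray
    state_fractions: dict
    fraction_traces_with_pause: float | None

    def histogram(self, bin_width: float = 5.0):
        if self.n_pauses == 0:
            return np.array([0.0, bin_width]), np.array([0])
        upper = bin_width * math.ceil(self.durations.max() / bin_width)
        edges = np.arange(0.0, upper + bin_width, bin_width)
        counts, _ = np.histogram(self.durations, bins=edges)
        return edges, counts


def pause_statistics(
    pauses: Sequence[PauseRecord] | Sequence[Sequence[PauseRecord]],
    report_threshold: float = 10.0,
) -> PauseSummary:
    """Filter pauses by the reporting threshold and summarize them.

    Accepts either a flat list of :class:`PauseRecord` or a list of
    per-trace lists; only the latter defines the fraction of traces
    containing at least one reported pause.  An empty input returns an empty
    summary, not an error.
    """
    per_trace: list[list[PauseRecord]] | None
    if len(pauses) > 0 and isinstance(pauses[0], PauseRecord):
        flat = list(pauses)  # type: ignore[arg-type]
        per_trace = None
    else:
        per_trace = [list(tr) for tr in pauses]  # type: ignore[union-attr]
        flat = [p for tr in per_trace for p in tr]
    reported = [p for p in flat if p.duration > report_threshold]
    durations = np.array([p.duration for p in reported])
    fractions = {name: 0.0 for name in ("E", "EM", "EMM")}
    for p in reported:
        fractions[p.majority_state] += 1.0
    if reported:
        fractions = {k: v / len(reported) for k, v in fractions.items()}
    frac_traces = None
    if per_trace is not None and per_trace:
        with_pause = sum(
            1 for tr in per_trace if any(p.duration > report_threshold for p in tr)
        )
        frac_traces = with_pause / len(per_trace)
    return PauseSummary(
        n_pauses=len(reported),
        mean_duration=float(durations.mean()) if len(durations) else math.nan,
        durations=durations,
        state_fractions=fractions,
        fraction_traces_with_pause=frac_traces,
    )
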