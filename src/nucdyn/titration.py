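"""FRET titration analysis: (ratio)_A efficiencies, midpoint fits and comparisons.

Salt titrations of FRET-labeled nucleosomes decay sigmoidally with ionic
strength; the midpoint ``C1/2`` is the operational nucleosome-stability
measure.  LexA titrations probe site exposure at the DNA entry/exit region
and are described by a non-competitive binding isotherm whose midpoint
``S1/2`` measures accessibility.  This module computes FRET efficiencies
from acceptor emission ratios, normalizes titration curves to percent,
fits both midpoint models with multi-start least squares, and provides the
replicate-level comparison statistics (percent decrease, pooled two-sample
t-test) used to contrast unmodified and modified nucleosomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

__all__ = [
    "FretSpectra",
    "TitrationSeries",
    "SigmoidFit",
    "IsothermFit",
    "GroupComparison",
    "DegenerateCurveError",
    "FitFailureError",
    "ratio_a_efficiency",
    "normalize_titration",
    "sigmoid_model",
    "isotherm_model",
    "fit_salt_sigmoid",
    "fit_lexa_isotherm",
    "fit_replicates",
    "percent_decrease",
    "two_sample_ttest",
]


class DegenerateCurveError(ValueError):
    """Raised when a titration curve has no dynamic range to normalize or fit."""


class FitFailureError(RuntimeError):
    """Raised when no optimizer start converges; carries the best partial fit."""

    def __init__(self, message, partial=None):
        super().__init__(message)
        self.partial = partial


@dataclass(frozen=True)
class FretSpectra:
    """Acceptor-channel intensities and photophysical constants for (ratio)_A.

    ``fa_donor_ex`` / ``fa_acceptor_ex`` are the acceptor-channel
    fluorescence upon donor and direct acceptor excitation; the ``eps_*``
    fields are molar extinction coefficients (M^-1 cm^-1) at the two
    excitation wavelengths; ``d_plus`` is the donor labeling fraction.
    ``prefactor`` multiplies the efficiency (1 = canonical single-donor
    form; 2 reproduces the alternative printed form).
    """

    fa_donor_ex: float
    fa_acceptor_ex: float
    eps_a_donor_ex: float
    eps_a_acceptor_ex: float
    eps_d_donor_ex: float
    d_plus: float = 1.0
    prefactor: float = 1.0

    def __post_init__(self):
        for name in ("fa_donor_ex", "fa_acceptor_ex"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fa_acceptor_ex <= 0:
            raise ValueError("fa_acceptor_ex must be > 0")
        for name in ("eps_a_donor_ex", "eps_a_acceptor_ex", "eps_d_donor_ex"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.d_plus <= 1:
            raise ValueError("d_plus must be in (0, 1]")


@dataclass
class TitrationSeries:
    """x-y titration measurements with replicate labels.

    ``kind`` is one of ``{"salt", "lexa", "elution"}``.  Points are sorted
    ascending in x on construction (stable, so replicate interleaving at
    equal x is preserved).
    """

    x: np.ndarray
    y: np.ndarray
    replicate: np.ndarray = None
    kind: str = "salt"

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if self.replicate is None:
            self.replicate = np.zeros(self.x.shape, dtype=object)
            self.replicate[:] = "r1"
        else:
            self.replicate = np.asarray(self.replicate, dtype=object)
            if self.replicate.shape != self.x.shape:
                raise ValueError("replicate labels must match x length")
        if self.kind not in ("salt", "lexa", "elution"):
            raise ValueError(f"unknown titration kind {self.kind!r}")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y must be finite")
        if np.any(self.x < 0):
            raise ValueError("concentrations must be non-negative")
        order = np.argsort(self.x, kind="stable")
        self.x = self.x[order]
        self.y = self.y[order]
        self.replicate = self.replicate[order]

    def for_replicate(self, label) -> "TitrationSeries":
        m = self.replicate == label
        return TitrationSeries(self.x[m], self.y[m], self.replicate[m], self.kind)

    @property
    def replicate_labels(self):
        seen = []
        for r in self.replicate:
            if r not in seen:
                seen.append(r)
        return seen


@dataclass
class SigmoidFit:
    c_half: float
    b: float
    y_min: float
    y_max: float
    se_c_half: float
    rss: float
    converged: bool = True


@dataclass
class IsothermFit:
    s_half: float
    e0: float
    ef: float
    se_s_half: float
    rss: float
    converged: bool = True


@dataclass
class GroupComparison:
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t_stat: float
    df: int
    p_value: float
    percent_change: float


def ratio_a_efficiency(spectra: FretSpectra) -> float:
    """FRET efficiency from the acceptor-emission excitation ratio.

    E = prefactor * [(F_A(donor ex)/F_A(acceptor ex)) * eps_A(acceptor ex)
    - eps_A(donor ex)] / (eps_D(donor ex) * d+).  Linear in the sensitized
    emission; exactly 0 when the emission ratio equals the direct-excitation
    extinction ratio.  No clamping to [0, 1] is applied.
    """
    s = spectra
    ratio = s.fa_donor_ex / s.fa_acceptor_ex
    return (
        s.prefactor
        * (ratio * s.eps_a_acceptor_ex - s.eps_a_donor_ex)
        / (s.eps_d_donor_ex * s.d_plus)
    )


def normalize_titration(series: TitrationSeries, n_plateau: int = 3) -> TitrationSeries:
    """Rescale a titration to percent between its plateaus.

    ``high`` is the mean of the ``n_plateau`` largest-y points (the maximum
    FRET plateau), ``low`` the mean of the ``n_plateau`` points at the
    highest concentrations (fully dissociated plateau); y' = 100 * (y -
    low) / (high - low).  Point order is preserved.
    """
    if n_plateau < 1:
        raise ValueError("n_plateau must be >= 1")
    if len(series.x) < 2 * n_plateau:
        raise ValueError("series must have at least 2 * n_plateau points")
    y = series.y
    high = np.mean(np.sort(y)[-n_plateau:])
    low = np.mean(y[-n_plateau:])  # x is sorted ascending
    if high == low:
        raise DegenerateCurveError("curve has zero dynamic range (high == low)")
    y_norm = 100.0 * (y - low) / (high - low)
    return TitrationSeries(series.x.copy(), y_norm, series.replicate.copy(), series.kind)


def sigmoid_model(x, c_half, b, y_min, y_max):
    """Y(X) = Ymin + (Ymax - Ymin) / (1 + exp((c_half - X)/b)).

    With b < 0 the curve decays from Ymax at low X to Ymin at high X
    (FRET/elution-bound orientation); b > 0 gives the rising mirror image.
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        z = np.exp(np.clip((c_half - x) / b, -700, 700))
    return y_min + (y_max - y_min) / (1.0 + z)


def isotherm_model(x, s_half, e0, ef):
    """Non-competitive binding curve E = E0 + (EF - E0)/(1 + S1/2/[L]).

    The x = 0 point is evaluated as the analytic limit E0.
    """
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, float(e0))
    pos = x > 0
    out[pos] = e0 + (ef - e0) / (1.0 + s_half / x[pos])
    return out if out.ndim else float(out)


def _check_distinct_x(series, minimum, nonzero=False):
    xs = series.x[series.x > 0] if nonzero else series.x
    if len(np.unique(xs)) < minimum:
        raise ValueError(
            f"need >= {minimum} distinct {'nonzero ' if nonzero else ''}x values"
        )


def _multistart_fit(model, x, y, starts, bounds, param_index):
    """Run curve_fit from every start; return (popt, se, rss) of the best.

    Best = lowest rss; ties broken by smallest |b| (second parameter).
    Raises FitFailureError (carrying the best failed start) if nothing
    converges.
    """
    best = None
    last_partial = None
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, pcov = optimize.curve_fit(
                    model, x, y, p0=p0, bounds=bounds, maxfev=20000
                )
        except (RuntimeError, ValueError):
            last_partial = p0
            continue
        rss = float(np.sum((model(x, *popt) - y) ** 2))
        key = (rss, abs(popt[1]) if len(popt) > 1 else 0.0)
        if best is None or key < (best[0], best[1]):
            se = float(np.sqrt(max(pcov[param_index, param_index], 0.0)))
            best = (rss, key[1], popt, se)
    if best is None:
        raise FitFailureError("no optimizer start converged", partial=last_partial)
    rss, _, popt, se = best
    return popt, se, rss


def fit_salt_sigmoid(series: TitrationSeries) -> SigmoidFit:
    """Least-squares sigmoid fit returning the midpoint C1/2.

    Multi-start initialization: c_half at the 0.25/0.5/0.75 interior x
    quantiles, asymptotes from the three lowest/highest-x point means, b
    tried with both signs.  The standard error of c_half comes from the
    local curvature (covariance) of the best-rss fit.
    """
    if series.kind not in ("salt", "elution"):
        raise ValueError("fit_salt_sigmoid requires a salt or elution series")
    _check_distinct_x(series, 5)
    x, y = series.x, series.y
    lo3 = float(np.mean(y[:3]))
    hi3 = float(np.mean(y[-3:]))
    y_hi, y_lo = max(lo3, hi3), min(lo3, hi3)
    if y_hi == y_lo:
        raise DegenerateCurveError("flat curve cannot define a midpoint")
    b0 = (x[-1] - x[0]) / 10.0
    starts = []
    for q in (0.25, 0.5, 0.75):
        c0 = float(np.quantile(x, q))
        for b in (b0, -b0):
            # orientation follows the sign of b: b<0 decays, b>0 rises
            starts.append((c0, b, y_lo, y_hi))
    popt, se, rss = _multistart_fit(
        sigmoid_model, x, y, starts,
        bounds=([-np.inf, -np.inf, -np.inf, -np.inf], [np.inf] * 4),
        param_index=0,
    )
    c_half, b, y_min, y_max = (float(v) for v in popt)
    if y_max < y_min:  # canonical orientation: y_max is the upper asymptote
        y_min, y_max = y_max, y_min
        b = -b
    return SigmoidFit(c_half, b, y_min, y_max, se, rss)


def fit_lexa_isotherm(series: TitrationSeries) -> IsothermFit:
    """Fit the LexA binding isotherm, returning the midpoint S1/2.

    The x = 0 anchor point is retained (it pins E0 through the analytic
    limit) but never enters a 1/[LexA] term.  s_half is optimized on a log
    scale for robustness across decades of concentration.
    """
    if series.kind != "lexa":
        raise ValueError("fit_lexa_isotherm requires a lexa series")
    if np.all(series.x == 0):
        raise ValueError("all-zero concentrations cannot constrain S1/2")
    _check_distinct_x(series, 5, nonzero=True)
    x, y = series.x, series.y
    xpos = x[x > 0]

    def model_log(xv, log_s, e0, ef):
        return isotherm_model(xv, np.exp(log_s), e0, ef)

    e0_init = float(y[np.argmin(x)])
    ef_init = float(y[np.argmax(x)])
    starts = [
        (float(np.log(np.quantile(xpos, q))), e0_init, ef_init)
        for q in (0.25, 0.5, 0.75)
    ]
    popt, se_log, rss = _multistart_fit(
        model_log, x, y, starts,
        bounds=([-np.inf] * 3, [np.inf] * 3),
        param_index=0,
    )
    log_s, e0, ef = (float(v) for v in popt)
    s_half = float(np.exp(log_s))
    return IsothermFit(s_half, e0, ef, s_half * se_log, rss)


def fit_replicates(series: TitrationSeries, model: str = "sigmoid"):
    """Fit each replicate independently; return {replicate label: fit}.

    Midpoint statistics across conditions (mean +/- s.e.m., t-tests) are
    computed over these replicate-level fits.
    """
    fit = {"sigmoid": fit_salt_sigmoid, "isotherm": fit_lexa_isotherm}[model]
    return {label: fit(series.for_replicate(label)) for label in series.replicate_labels}


def percent_decrease(value_unmod: float, value_mod: float, decimals: int = 1) -> float:
    """Percent decrease of the modified value relative to the unmodified one."""
    if value_unmod <= 0:
        raise ValueError("value_unmod must be > 0")
    return round((value_unmod - value_mod) / value_unmod * 100.0, decimals)


def two_sample_ttest(group_a, group_b) -> GroupComparison:
    """Pooled-variance two-tailed Student t-test with group summaries.

    df = n_a + n_b - 2.  Zero pooled variance with distinct means is
    reported as t = +/-inf, p = 0 with a warning.  percent_change is the
    percent decrease of mean_b relative to mean_a (nan if mean_a <= 0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    sem_a = float(np.std(a, ddof=1) / np.sqrt(len(a)))
    sem_b = float(np.std(b, ddof=1) / np.sqrt(len(b)))
    df = len(a) + len(b) - 2
    pooled = ((len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1)) / df
    if pooled == 0:
        if mean_a == mean_b:
            t_stat, p = 0.0, 1.0
        else:
            warnings.warn("degenerate (zero) within-group variance; p set to 0")
            t_stat = np.inf if mean_b > mean_a else -np.inf
            p = 0.0
    else:
        res = stats.ttest_ind(b, a, equal_var=True)
        t_stat, p = float(res.statistic), float(res.pvalue)
    try:
        pct = percent_decrease(mean_a, mean_b, decimals=12)
    except ValueError:
        pct = float("nan")
    return GroupComparison(mean_a, mean_b, sem_a, sem_b, t_stat, df, p, pct)
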