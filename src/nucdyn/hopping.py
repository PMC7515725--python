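"""Constant-position optical-tweezers hopping analysis and outer-wrap energetics.

A nucleosome tethered between two trapped beads and held near its
equilibrium force hops between a wrapped and a (partially) unwrapped state
of the outer DNA turn.  The pipeline implemented here mirrors the standard
workflow:

1. decimate the raw extension trace (boxcar mean, e.g. 1 kHz -> 250 Hz);
2. detect wrapped <-> unwrapped transitions with a two-adjacent-window
   Welch t-test statistic;
3. turn alternating segments into per-state dwell times and exponential
   maximum-likelihood rates k_u (unwrapping, from wrapped dwells) and k_w
   (rewrapping, from unwrapped dwells);
4. fit ln k versus force (Bell model: k(F) = k0 exp(+/- F x^#/kT)) to find
   the equilibrium force F_eq where k_u = k_w and the equilibrium rate
   K_eq = k(F_eq);
5. extract the zero-tension free energy of the outer wrap,
   dG0 = F_eq * dx - dG_stretch - kT ln K_eq, where dx is the observed
   hopping step near F_eq and dG_stretch is the worm-like-chain work of
   stretching the released DNA contour to F_eq.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

__all__ = [
    "HoppingTrace",
    "TransitionSet",
    "DwellSet",
    "RatePoint",
    "BellFit",
    "WLCParams",
    "EnergyResult",
    "HoppingAnalysis",
    "NoEquilibriumError",
    "KJ_PER_MOL_PER_PN_NM",
    "decimate_trace",
    "detect_transitions",
    "extract_dwells",
    "estimate_rates",
    "fit_force_dependence",
    "wlc_force",
    "wlc_extension_fraction",
    "stretch_energy",
    "outer_wrap_free_energy",
    "analyze_hopping_experiment",
]

#: 1 pN*nm = 1e-21 J; times Avogadro = 0.6022 kJ/mol.
KJ_PER_MOL_PER_PN_NM = 0.6022

WRAPPED = "wrapped"
UNWRAPPED = "unwrapped"


class NoEquilibriumError(RuntimeError):
    """Raised when the two Bell lines are parallel and never intersect."""


@dataclass
class HoppingTrace:
    """Uniformly sampled extension time series at constant mean force."""

    t: np.ndarray
    ext: np.ndarray
    force: float
    sample_rate: float
    label: str = ""

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.ext = np.asarray(self.ext, dtype=float)
        if self.t.shape != self.ext.shape or self.t.ndim != 1:
            raise ValueError("t and ext must be 1-D arrays of equal length")
        if len(self.t) >= 3:
            dt = np.diff(self.t)
            period = 1.0 / self.sample_rate
            if np.max(np.abs(dt - period)) > 0.01 * period:
                raise ValueError("sampling must be uniform (jitter < 1% of period)")

    def __len__(self):
        return len(self.ext)


@dataclass
class TransitionSet:
    """Detected change points with per-segment state labels.

    Segment i spans samples [change_points[i-1], change_points[i]) with the
    0-based half-open convention; segment 0 starts at 0 and the last ends
    at n_samples.  ``states`` has one label per segment, strictly
    alternating; ``t_stats`` holds the detection statistic of each change
    point.
    """

    change_points: np.ndarray
    states: list
    t_stats: np.ndarray
    n_samples: int

    def __post_init__(self):
        self.change_points = np.asarray(self.change_points, dtype=int)
        self.t_stats = np.asarray(self.t_stats, dtype=float)
        if len(self.states) != len(self.change_points) + 1:
            raise ValueError("need exactly one state per segment")
        if np.any(np.diff(self.change_points) <= 0):
            raise ValueError("change_points must be strictly increasing")
        for a, b in zip(self.states, self.states[1:]):
            if a == b:
                raise ValueError("adjacent segments must have different states")

    @property
    def segment_bounds(self):
        edges = np.concatenate(([0], self.change_points, [self.n_samples]))
        return list(zip(edges[:-1], edges[1:]))


@dataclass
class DwellSet:
    dwells_wrapped: np.ndarray
    dwells_unwrapped: np.ndarray
    censored_first_last: bool = True

    def __post_init__(self):
        self.dwells_wrapped = np.asarray(self.dwells_wrapped, dtype=float)
        self.dwells_unwrapped = np.asarray(self.dwells_unwrapped, dtype=float)
        if np.any(self.dwells_wrapped <= 0) or np.any(self.dwells_unwrapped <= 0):
            raise ValueError("dwell durations must be positive")


@dataclass
class RatePoint:
    force: float
    k_u: float
    k_w: float
    se_ku: float
    se_kw: float
    n_events: int


@dataclass
class BellFit:
    """Linear fits of ln k versus force and their intersection."""

    slope_u: float
    intercept_u: float
    slope_w: float
    intercept_w: float
    f_eq: float
    k_eq: float


@dataclass(frozen=True)
class WLCParams:
    """Worm-like-chain parameters for double-stranded DNA.

    ``stretch_modulus = inf`` selects the inextensible Marko-Siggia chain.
    Defaults: P = 50 nm, K = 1200 pN, kT = 4.114 pN nm (T = 298 K); DNA
    rise 0.338 nm/bp for contour conversions.
    """

    persistence_length: float = 50.0
    contour_length: float = 1.0
    stretch_modulus: float = 1200.0
    kT: float = 4.114
    rise_per_bp: float = 0.338

    def __post_init__(self):
        if self.persistence_length <= 0 or self.contour_length <= 0 or self.kT <= 0:
            raise ValueError("persistence_length, contour_length and kT must be > 0")
        if self.stretch_modulus <= 0:
            raise ValueError("stretch_modulus must be > 0 (inf for inextensible)")


@dataclass
class EnergyResult:
    f_eq: float
    delta_x: float
    dG_stretch: float
    k_eq: float
    dG0_pNnm: float
    dG0_kJmol: float


@dataclass
class HoppingAnalysis:
    """Audit trail of an end-to-end hopping analysis."""

    rate_points: list
    bell: BellFit
    energy: EnergyResult
    transitions: dict
    delta_x: float
    released_contour: float


def decimate_trace(trace: HoppingTrace, factor: int) -> HoppingTrace:
    """Boxcar-decimate: mean of non-overlapping blocks of ``factor`` samples.

    The trailing partial block is dropped; the new sample rate is
    old/factor.  Decimation by the block mean preserves the global mean
    when the length divides evenly.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return trace
    n = len(trace) // factor
    if n == 0:
        raise ValueError("factor exceeds trace length")
    ext = trace.ext[: n * factor].reshape(n, factor).mean(axis=1)
    t = trace.t[: n * factor].reshape(n, factor).mean(axis=1)
    return HoppingTrace(t, ext, trace.force, trace.sample_rate / factor, trace.label)


def _window_t_stats(x: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Welch t between adjacent windows [i-w, i) and [i, i+w) for each valid i.

    Returns (positions, t values); positions run from window to n-window
    inclusive.  Zero pooled variance (noiseless steps) maps to +/-inf.
    """
    n = len(x)
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def wsum(c, start, count):
        return c[start + count] - c[start]

    pos = np.arange(window, n - window + 1)
    s1 = wsum(c1, pos - window, window)
    s2 = wsum(c1, pos, window)
    q1 = wsum(c2, pos - window, window)
    q2 = wsum(c2, pos, window)
    m1, m2 = s1 / window, s2 / window
    v1 = np.maximum(q1 - s1 * m1, 0.0) / (window - 1)
    v2 = np.maximum(q2 - s2 * m2, 0.0) / (window - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m2 - m1) / np.sqrt((v1 + v2) / window)
    t[np.isnan(t)] = 0.0  # zero variance and zero difference
    return pos, t


def detect_transitions(
    trace: HoppingTrace,
    window: int = 25,
    t_threshold: float = 6.0,
    min_dwell: int = 10,
) -> TransitionSet:
    """Detect wrapped <-> unwrapped transitions by a two-window t-test scan.

    Candidate change points are local maxima of |t| above ``t_threshold``;
    candidates closer than ``min_dwell`` samples are merged keeping the
    larger |t|.  Segments are labeled by mean extension (higher mean =>
    unwrapped); where two candidates would produce adjacent same-state
    segments the weaker one is discarded.
    """
    if window < 4:
        raise ValueError("window must be >= 4")
    n = len(trace)
    if n < 2 * window:
        raise ValueError("trace shorter than two detection windows")
    pos, t = _window_t_stats(trace.ext, window)
    abs_t = np.abs(t)
    finite_max = np.max(abs_t[np.isfinite(abs_t)], initial=0.0)
    peak_input = np.where(np.isinf(abs_t), finite_max * 2 + 1.0, abs_t)
    peaks, _ = signal.find_peaks(peak_input, height=t_threshold)
    if len(peaks) == 0:
        return TransitionSet(np.empty(0, int), [WRAPPED], np.empty(0), n)

    cand = pos[peaks]
    strength = abs_t[peaks]
    # greedy strongest-first merge within min_dwell
    order = np.argsort(strength)[::-1]
    kept = []
    for idx in order:
        if all(abs(cand[idx] - cand[j]) >= min_dwell for j in kept):
            kept.append(idx)
    kept.sort(key=lambda j: cand[j])
    cps = [int(cand[j]) for j in kept]
    tvals = [float(strength[j]) for j in kept]

    # label segments and enforce alternation
    ext = trace.ext
    while True:
        edges = [0] + cps + [n]
        means = np.array([ext[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
        mid = 0.5 * (means.max() + means.min())
        states = [UNWRAPPED if m > mid else WRAPPED for m in means]
        clash = next(
            (i for i in range(len(states) - 1) if states[i] == states[i + 1]), None
        )
        if clash is None:
            break
        # drop the weaker of the two change points bounding the clashing pair
        bounding = [clash - 1, clash]
        bounding = [i for i in bounding if 0 <= i < len(cps)]
        weakest = min(bounding, key=lambda i: tvals[i])
        del cps[weakest], tvals[weakest]
        if not cps:
            return TransitionSet(np.empty(0, int), [WRAPPED], np.empty(0), n)
    return TransitionSet(np.array(cps), states, np.array(tvals), n)


def extract_dwells(
    ts: TransitionSet, sample_rate: float, drop_boundary: bool = True
) -> DwellSet:
    """Per-state dwell durations from an alternating transition set.

    The first and last segments are censored (their true start/end was not
    observed) and excluded when ``drop_boundary`` is set.
    """
    bounds = ts.segment_bounds
    if len(bounds) < 1:
        raise ValueError("TransitionSet has no segments")
    items = list(zip(ts.states, bounds))
    if drop_boundary:
        items = items[1:-1]
    wrapped, unwrapped = [], []
    for state, (a, b) in items:
        (wrapped if state == WRAPPED else unwrapped).append((b - a) / sample_rate)
    return DwellSet(np.array(wrapped), np.array(unwrapped), drop_boundary)


def estimate_rates(dwells: DwellSet, force: float) -> RatePoint:
    """Exponential MLE rates: k = 1/mean(dwell), se = k/sqrt(n).

    k_u (unwrapping) comes from wrapped-state dwells, k_w (rewrapping)
    from unwrapped-state dwells.
    """
    for name, d in (("wrapped", dwells.dwells_wrapped), ("unwrapped", dwells.dwells_unwrapped)):
        if len(d) == 0:
            raise ValueError(f"no dwells in the {name} state")
    k_u = 1.0 / float(np.mean(dwells.dwells_wrapped))
    k_w = 1.0 / float(np.mean(dwells.dwells_unwrapped))
    n_u = len(dwells.dwells_wrapped)
    n_w = len(dwells.dwells_unwrapped)
    return RatePoint(force, k_u, k_w, k_u / np.sqrt(n_u), k_w / np.sqrt(n_w), n_u + n_w)


def fit_force_dependence(points: list) -> BellFit:
    """Bell-model fit: OLS of ln k_u and ln k_w against force.

    F_eq solves intercept_u + slope_u F = intercept_w + slope_w F; the
    equilibrium rate is K_eq = exp(intercept_u + slope_u F_eq).  For a
    nucleosome slope_u > 0 and slope_w < 0; other signs raise a warning.
    """
    forces = np.array([p.force for p in points], dtype=float)
    if len(np.unique(forces)) < 2:
        raise ValueError("need >= 2 distinct forces")
    ln_ku = np.log([p.k_u for p in points])
    ln_kw = np.log([p.k_w for p in points])
    slope_u, intercept_u = np.polyfit(forces, ln_ku, 1)
    slope_w, intercept_w = np.polyfit(forces, ln_kw, 1)
    if slope_u <= 0 or slope_w >= 0:
        warnings.warn(
            "unexpected Bell slopes (expected slope_u > 0, slope_w < 0 for a nucleosome)"
        )
    if abs(slope_u - slope_w) < 1e-12:
        raise NoEquilibriumError("ln k_u and ln k_w lines are parallel")
    f_eq = (intercept_w - intercept_u) / (slope_u - slope_w)
    k_eq = float(np.exp(intercept_u + slope_u * f_eq))
    return BellFit(
        float(slope_u), float(intercept_u), float(slope_w), float(intercept_w),
        float(f_eq), k_eq,
    )


def _marko_siggia(z, params: WLCParams):
    """Inextensible Marko-Siggia interpolation force at fractional extension z."""
    return (params.kT / params.persistence_length) * (
        0.25 / (1.0 - z) ** 2 - 0.25 + z
    )


def wlc_force(extension_fraction, params: WLCParams = WLCParams()):
    """Worm-like-chain force at fractional extension x/L (scalar or array).

    Inextensible chains use the Marko-Siggia interpolation directly; with a
    finite stretch modulus K the enthalpic correction z -> z - F/K is
    solved self-consistently by bracketed root-finding to 1e-12 pN (the
    plain fixed-point map loses contraction above ~15 pN).
    """
    z = np.asarray(extension_fraction, dtype=float)
    scalar = z.ndim == 0
    z = np.atleast_1d(z)
    if np.any(z < 0) or np.any(z >= 1):
        raise ValueError("extension fraction must satisfy 0 <= x/L < 1")
    if not np.isfinite(params.stretch_modulus):
        out = _marko_siggia(z, params)
        out = np.where(z == 0, 0.0, out)
        return float(out[0]) if scalar else out
    K = params.stretch_modulus
    out = np.empty_like(z)
    for i, zi in enumerate(z):
        if zi == 0:
            out[i] = 0.0
            continue
        f_hi = _marko_siggia(zi, params)  # F <= MS(z) since z - F/K < z
        g = lambda f: f - _marko_siggia(max(zi - f / K, 0.0), params)
        out[i] = optimize.brentq(g, 0.0, f_hi + 1e-9, xtol=1e-12)
    return float(out[0]) if scalar else out


def wlc_extension_fraction(force, params: WLCParams = WLCParams()):
    """Fractional extension x/L at a given force (inverse of wlc_force).

    For the extensible chain this is exactly z = z_MS(F) + F/K where z_MS
    inverts the Marko-Siggia relation.
    """
    f = np.asarray(force, dtype=float)
    scalar = f.ndim == 0
    f = np.atleast_1d(f)
    if np.any(f < 0):
        raise ValueError("force must be >= 0")
    z = np.empty_like(f)
    for i, fi in enumerate(f):
        if fi == 0:
            z[i] = 0.0
            continue
        z[i] = optimize.brentq(
            lambda zz: _marko_siggia(zz, params) - fi, 0.0, 1.0 - 1e-12, xtol=1e-14
        )
    if np.isfinite(params.stretch_modulus):
        z = z + f / params.stretch_modulus
    return float(z[0]) if scalar else z


def stretch_energy(
    f_eq: float, released_contour: float, params: WLCParams = WLCParams()
) -> float:
    """WLC work to stretch ``released_contour`` nm of DNA from 0 to f_eq.

    Integrates F dx over x in [0, L z(f_eq)] by trapezoid refinement with
    successive interval halving until the relative change is below 1e-6.
    """
    if f_eq < 0:
        raise ValueError("f_eq must be >= 0")
    if released_contour <= 0:
        raise ValueError("released_contour must be > 0")
    if f_eq == 0:
        return 0.0
    z_max = wlc_extension_fraction(f_eq, params)
    # integrate over the Marko-Siggia coordinate; the enthalpic part adds
    # the elastic energy L*F^2/(2K) exactly
    z_ms_max = z_max - (
        f_eq / params.stretch_modulus if np.isfinite(params.stretch_modulus) else 0.0
    )
    inext = WLCParams(
        params.persistence_length, released_contour, np.inf, params.kT, params.rise_per_bp
    )
    n = 64
    zs = np.linspace(0.0, z_ms_max, n + 1)
    fs = _marko_siggia(zs, inext)
    fs[0] = 0.0
    total = np.trapezoid(fs, zs)
    while n < 2**20:
        mids = 0.5 * (zs[:-1] + zs[1:])
        f_mid = _marko_siggia(mids, inext)
        new_total = 0.5 * total + np.sum(f_mid) * (zs[1] - zs[0]) * 0.5
        zs = np.sort(np.concatenate([zs, mids]))
        fs = None
        n *= 2
        if abs(new_total - total) <= 1e-6 * abs(new_total):
            total = new_total
            break
        total = new_total
    work = released_contour * total
    if np.isfinite(params.stretch_modulus):
        work += released_contour * f_eq**2 / (2.0 * params.stretch_modulus)
    return float(work)


def outer_wrap_free_energy(
    f_eq: float,
    delta_x: float,
    dG_stretch: float,
    k_eq: float,
    kT: float = 4.114,
    k_reference: float = 1.0,
) -> EnergyResult:
    """Zero-tension free energy of the nucleosome outer DNA wrap.

    dG0 = F_eq dx - dG_stretch - kT ln(K_eq / k_reference), in pN nm, with
    the kJ/mol conversion 1 pN nm = 0.6022 kJ/mol.  K_eq is dimensionful
    (a rate), so the logarithm is taken against a reference rate of
    1 s^-1 by default.
    """
    if not all(np.isfinite([f_eq, delta_x, dG_stretch, k_eq])):
        raise ValueError("inputs must be finite")
    if k_eq <= 0:
        raise ValueError("k_eq must be > 0")
    dg0 = f_eq * delta_x - dG_stretch - kT * np.log(k_eq / k_reference)
    return EnergyResult(
        f_eq, delta_x, dG_stretch, k_eq, float(dg0), float(dg0 * KJ_PER_MOL_PER_PN_NM)
    )


def _step_amplitudes(trace: HoppingTrace, ts: TransitionSet) -> np.ndarray:
    """|difference of adjacent segment mean extensions| at each change point."""
    means = [trace.ext[a:b].mean() for a, b in ts.segment_bounds]
    return np.abs(np.diff(means))


def analyze_hopping_experiment(
    traces: list,
    decimate_factor: int = 4,
    window: int = 25,
    t_threshold: float = 6.0,
    min_dwell: int = 10,
    wlc: WLCParams = WLCParams(),
    drop_boundary: bool = True,
    k_reference: float = 1.0,
) -> HoppingAnalysis:
    """Full hopping pipeline: traces -> rates -> Bell fit -> outer-wrap dG0.

    Each trace is decimated, transitions detected, dwells and rates
    extracted; ln k vs force is fit to locate F_eq and K_eq.  The hopping
    step dx is the mean detected step amplitude in the trace(s) whose
    force is nearest F_eq; the released contour is the length whose WLC
    equilibrium extension at F_eq equals dx, and dG_stretch is the work of
    stretching it to F_eq.
    """
    if len({t.force for t in traces}) < 2:
        raise ValueError("need traces at >= 2 distinct forces")
    rate_points, transitions, decimated = [], {}, {}
    for trace in traces:
        try:
            dec = decimate_trace(trace, decimate_factor)
            ts = detect_transitions(dec, window, t_threshold, min_dwell)
            dwells = extract_dwells(ts, dec.sample_rate, drop_boundary)
            rate_points.append(estimate_rates(dwells, trace.force))
        except ValueError as err:
            raise ValueError(f"trace {trace.label!r}: {err}") from err
        transitions[trace.label] = ts
        decimated[trace.label] = dec
    bell = fit_force_dependence(rate_points)

    nearest = min({t.force for t in traces}, key=lambda f: abs(f - bell.f_eq))
    amps = np.concatenate(
        [
            _step_amplitudes(decimated[t.label], transitions[t.label])
            for t in traces
            if t.force == nearest
        ]
    )
    delta_x = float(np.mean(amps))
    z_eq = wlc_extension_fraction(bell.f_eq, wlc)
    released = delta_x / z_eq
    dg_stretch = stretch_energy(bell.f_eq, released, wlc)
    energy = outer_wrap_free_energy(
        bell.f_eq, delta_x, dg_stretch, bell.k_eq, wlc.kT, k_reference
    )
    return HoppingAnalysis(rate_points, bell, energy, transitions, delta_x, released)
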