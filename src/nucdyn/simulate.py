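"""Synthetic-data generators with emitted ground truth.

Every generator is a pure function of its parameters and seed and returns
``(data, truth)`` where ``truth`` is a plain dict sufficient to compute the
downstream quantities analytically (e.g. the Bell-model equilibrium force
F_eq = kT ln(k_w0/k_u0)/(x_u# + x_w#)).  Defaults emulate the study
conditions: a 19-point salt grid over 0.1-1.9 M with Gaussian noise, LexA
titrations 0-100 uM on a log grid, two-state Markov hopping sampled at
1 kHz with Bell rates and ~3 pN equilibrium force, 200 nm/s force ramps at
200 Hz with discrete rips, and log-normal (10%) intensity noise on gel
tables.

The Bell-rate trace generator shares no code with the analysis fitters, so
recovery tests are honest round trips.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gels import DIGESTION_COLUMNS, ELUTION_COLUMNS
from .hopping import (
    UNWRAPPED,
    WRAPPED,
    HoppingTrace,
    WLCParams,
    wlc_extension_fraction,
)
from .pulling import ForceExtensionCurve
from .titration import TitrationSeries, isotherm_model, sigmoid_model

__all__ = [
    "gen_titration",
    "gen_isotherm",
    "gen_hopping_trace",
    "gen_force_ramp",
    "gen_elution",
    "gen_digestion",
    "analytic_f_eq",
    "bell_rates",
]

DEFAULT_SALT_GRID = np.round(np.arange(0.1, 1.91, 0.1), 10)  # 19 points, M
DEFAULT_LEXA_GRID = np.concatenate(([0.0], np.logspace(-8, -4, 17)))  # M

#: Default Bell parameters for the hopping generator (chosen so that
#: F_eq ~ 3.0 pN and dG0 ~ 21 kJ/mol, the regime of a nucleosome outer wrap).
DEFAULT_BELL = {
    "k_u0": 0.25,  # s^-1, unwrapping rate at zero force
    "x_u_dagger": 2.0,  # nm, distance to barrier (unwrapping)
    "k_w0": 4.6,  # s^-1, rewrapping rate at zero force
    "x_w_dagger": 2.0,  # nm
}


def bell_rates(force, k_u0, x_u_dagger, k_w0, x_w_dagger, kT=4.114):
    """Bell-model rates at a given force: k_u grows, k_w shrinks with F."""
    k_u = k_u0 * np.exp(force * x_u_dagger / kT)
    k_w = k_w0 * np.exp(-force * x_w_dagger / kT)
    return k_u, k_w


def analytic_f_eq(k_u0, x_u_dagger, k_w0, x_w_dagger, kT=4.114):
    """Force at which the two Bell rates cross: kT ln(k_w0/k_u0)/(x_u# + x_w#)."""
    if x_u_dagger + x_w_dagger == 0 or k_u0 <= 0 or k_w0 <= 0:
        return float("nan")  # rates never cross
    return kT * np.log(k_w0 / k_u0) / (x_u_dagger + x_w_dagger)


def gen_titration(
    seed,
    c_half: float = 0.621,
    b: float = -0.05,
    y_min: float = 0.0,
    y_max: float = 100.0,
    x=None,
    sigma: float = 3.0,
    n_replicates: int = 1,
):
    """Sigmoidal salt titration: y = sigmoid(x) + N(0, sigma), per replicate."""
    x = DEFAULT_SALT_GRID if x is None else np.asarray(x, dtype=float)
    if len(np.unique(x)) < 5:
        raise ValueError("need >= 5 x points")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    xs, ys, reps = [], [], []
    for r in range(n_replicates):
        y = sigmoid_model(x, c_half, b, y_min, y_max) + rng.normal(0, sigma, len(x))
        xs.append(x)
        ys.append(y)
        reps.extend([f"r{r + 1}"] * len(x))
    series = TitrationSeries(
        np.concatenate(xs), np.concatenate(ys), np.array(reps, dtype=object), "salt"
    )
    truth = {"c_half": c_half, "b": b, "y_min": y_min, "y_max": y_max, "sigma": sigma}
    return series, truth


def gen_isotherm(
    seed,
    s_half: float = 2e-6,
    e0: float = 1.0,
    ef: float = 0.3,
    x=None,
    sigma: float = 0.02,
    n_replicates: int = 1,
):
    """Binding-isotherm titration on a log-spaced LexA grid including 0."""
    x = DEFAULT_LEXA_GRID if x is None else np.asarray(x, dtype=float)
    if len(np.unique(x[x > 0])) < 5:
        raise ValueError("need >= 5 nonzero x points")
    if sigma < 0 or s_half <= 0:
        raise ValueError("sigma must be >= 0 and s_half > 0")
    rng = np.random.default_rng(seed)
    xs, ys, reps = [], [], []
    for r in range(n_replicates):
        y = isotherm_model(x, s_half, e0, ef) + rng.normal(0, sigma, len(x))
        xs.append(x)
        ys.append(y)
        reps.extend([f"r{r + 1}"] * len(x))
    series = TitrationSeries(
        np.concatenate(xs), np.concatenate(ys), np.array(reps, dtype=object), "lexa"
    )
    truth = {"s_half": s_half, "e0": e0, "ef": ef, "sigma": sigma}
    return series, truth


def gen_hopping_trace(
    seed,
    force: float,
    k_u0: float = DEFAULT_BELL["k_u0"],
    x_u_dagger: float = DEFAULT_BELL["x_u_dagger"],
    k_w0: float = DEFAULT_BELL["k_w0"],
    x_w_dagger: float = DEFAULT_BELL["x_w_dagger"],
    step_amplitude: float = 21.0,
    noise_sigma: float = 6.0,
    duration: float = 200.0,
    sample_rate: float = 1000.0,
    kT: float = 4.114,
    baseline: float = 0.0,
    noise_corr_time: float = 0.0,
    label: str = "",
):
    """Two-state continuous-time Markov hopping trace with Bell rates.

    Dwell times are sampled exactly from the exponential distributions at
    the given force (continuous time), then discretized at ``sample_rate``;
    extension = baseline + step_amplitude in the unwrapped state + Gaussian
    bead noise.  ``noise_corr_time`` > 0 replaces the white noise by an
    AR(1) (exponentially autocorrelated) process of the same marginal
    standard deviation, emulating bead relaxation in a real trap.  Truth
    records the continuous-time transition times and per-state dwells
    (independent of the sampling rate) and the analytic rates and
    equilibrium force.
    """
    if not 0 <= force <= 10:
        raise ValueError("force must be within the physical 0-10 pN range")
    if duration <= 0 or sample_rate <= 0 or noise_sigma < 0:
        raise ValueError("duration, sample_rate must be > 0 and noise_sigma >= 0")
    k_u, k_w = bell_rates(force, k_u0, x_u_dagger, k_w0, x_w_dagger, kT)
    rng = np.random.default_rng(seed)
    states, dwells = [], []
    state = WRAPPED
    if k_u <= 0 or k_w <= 0:
        import warnings

        warnings.warn("zero rate: trace stays in a single state")
        trans_times = np.empty(0)
    else:
        total, trans = 0.0, []
        while total < duration:
            rate = k_u if state == WRAPPED else k_w
            d = rng.exponential(1.0 / rate)
            d_in = min(d, duration - total)
            states.append(state)
            dwells.append(d_in)
            total += d
            if total < duration:
                trans.append(total)
            state = UNWRAPPED if state == WRAPPED else WRAPPED
        trans_times = np.asarray(trans)

    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    state_idx = np.searchsorted(trans_times, t, side="right")  # 0-based segment
    is_unwrapped = (state_idx % 2) == 1  # starts wrapped
    if noise_corr_time > 0:
        a = np.exp(-1.0 / (noise_corr_time * sample_rate))
        innov = rng.normal(0, noise_sigma * np.sqrt(1 - a * a), n)
        noise = np.empty(n)
        prev = rng.normal(0, noise_sigma)
        for i in range(n):
            prev = a * prev + innov[i]
            noise[i] = prev
    else:
        noise = rng.normal(0, noise_sigma, n)
    ext = baseline + step_amplitude * is_unwrapped + noise
    trace = HoppingTrace(t, ext, force, sample_rate, label or f"F{force:g}pN")
    truth = {
        "force": force,
        "k_u": float(k_u),
        "k_w": float(k_w),
        "transition_times": trans_times,
        "states": states,
        "dwells": np.asarray(dwells),
        "step_amplitude": step_amplitude,
        "f_eq": float(analytic_f_eq(k_u0, x_u_dagger, k_w0, x_w_dagger, kT)),
        "occupancy_wrapped": float(k_w / (k_u + k_w)) if k_u + k_w > 0 else 1.0,
    }
    return trace, truth


def gen_force_ramp(
    seed,
    rips=((4.0, 25.0), (15.0, 22.0)),
    f_start: float = 0.5,
    f_end: float = 20.0,
    duration: float = 20.0,
    sample_rate: float = 200.0,
    noise_sigma: float = 2.0,
    tether_contour: float = 500.0,
    pull_rate: float = 200.0,
    wlc: WLCParams = WLCParams(),
    label: str = "",
    condition: str = "",
):
    """Force ramp over a WLC tether with discrete contour releases.

    The force rises linearly from ``f_start`` to ``f_end``; at each rip
    trigger force the tether contour increments by the specified release,
    so the extension jumps by release * z(F).  Truth lists the trigger
    forces and contour releases.
    """
    rips = sorted((float(f), float(dl)) for f, dl in rips)
    for f, dl in rips:
        if not f_start < f < f_end:
            raise ValueError(f"rip trigger force {f} outside ramp range")
        if dl <= 0:
            raise ValueError("contour release must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    force = np.linspace(f_start, f_end, n)
    contour = tether_contour + np.array(
        [sum(dl for f0, dl in rips if f >= f0) for f in force]
    )
    z = wlc_extension_fraction(force, wlc)
    ext = contour * z + rng.normal(0, noise_sigma, n)
    curve = ForceExtensionCurve(ext, force, pull_rate, sample_rate, label, condition)
    truth = {
        "rip_forces": [f for f, _ in rips],
        "rip_contours": [dl for _, dl in rips],
        "tether_contour": tether_contour,
    }
    return curve, truth


def gen_elution(
    seed,
    c_half: float = 0.50,
    b: float = -0.08,
    salts=None,
    total_intensity: float = 100.0,
    noise_cv: float = 0.10,
    n_replicates: int = 1,
    strain: str = "WT",
):
    """Hydroxyapatite elution table from a sigmoidal bound-fraction model.

    Bound fraction follows a sigmoid in salt with midpoint ``c_half``;
    bound and eluted band intensities get independent multiplicative
    log-normal noise (coefficient of variation ``noise_cv``).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    salts = (
        np.round(np.concatenate(([0.15], np.arange(0.25, 0.801, 0.05))), 10)
        if salts is None
        else np.asarray(salts, dtype=float)
    )
    rng = np.random.default_rng(seed)
    sig = np.sqrt(np.log(1 + noise_cv**2))
    rows = []
    for r in range(n_replicates):
        frac = sigmoid_model(salts, c_half, b, 0.0, 1.0)
        for s, fr in zip(salts, frac):
            noise = rng.lognormal(-sig**2 / 2, sig, 2) if noise_cv > 0 else np.ones(2)
            rows.append((s, "bound", total_intensity * fr * noise[0], strain, f"r{r + 1}"))
            rows.append(
                (s, "eluted", total_intensity * (1 - fr) * noise[1], strain, f"r{r + 1}")
            )
    table = pd.DataFrame(rows, columns=ELUTION_COLUMNS)
    truth = {"c_half": c_half, "b": b, "strain": strain, "noise_cv": noise_cv}
    return table, truth


def gen_digestion(
    seed,
    effects=None,
    sites=None,
    times=(0, 5, 10, 20, 40, 60),
    base_intensity: float = 100.0,
    rise_time_min: float = 20.0,
    noise_cv: float = 0.10,
    n_replicates: int = 4,
):
    """One-pot digestion table: per-site modified/unmodified effect multipliers.

    Unmodified intensities follow a saturating digestion time course
    I(t) = base * (1 - exp(-t/rise_time)); modified intensities multiply
    in the per-site effect; both get log-normal noise.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    sites = [f"dyad-{i}" for i in range(1, 9)] if sites is None else list(sites)
    effects = dict(effects or {})
    for site in effects:
        if site not in sites:
            raise ValueError(f"effect given for unknown site {site!r}")
    rng = np.random.default_rng(seed)
    sig = np.sqrt(np.log(1 + noise_cv**2))
    rows = []
    for site in sites:
        eff = float(effects.get(site, 1.0))
        for t in times:
            base = base_intensity * (1.0 - np.exp(-t / rise_time_min)) if t > 0 else 0.0
            for r in range(1, n_replicates + 1):
                if noise_cv > 0 and base > 0:
                    nz = rng.lognormal(-sig**2 / 2, sig, 2)
                else:
                    nz = np.ones(2)
                rows.append((site, t, "unmodified", base * nz[0], f"r{r}"))
                rows.append((site, t, "modified", base * eff * nz[1], f"r{r}"))
    table = pd.DataFrame(rows, columns=DIGESTION_COLUMNS)
    truth = {"effects": {s: float(effects.get(s, 1.0)) for s in sites}}
    return table, truth
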