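"""Constant-velocity force-extension analysis: unwrapping rip detection.

When a single tethered nucleosome is pulled at constant velocity the DNA
unwraps in two discrete steps: an outer rip at low force (entry/exit DNA
leaving the H2A-H2B dimer surface) and an inner rip at higher force (the
central wrap leaving the (H3-H4)2 tetramer).  A rip appears as a sudden
extension gain relative to the worm-like-chain baseline; inverting the WLC
at the rip force converts the extension jump into a released contour
length.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .hopping import WLCParams, wlc_extension_fraction
from .titration import two_sample_ttest

__all__ = [
    "ForceExtensionCurve",
    "RipEvent",
    "decimate_curve",
    "detect_rips",
    "classify_rips",
    "summarize_rip_forces",
]


@dataclass
class ForceExtensionCurve:
    """A pulling curve: extension and force versus time at fixed pull rate."""

    ext: np.ndarray
    force: np.ndarray
    pull_rate: float = 200.0
    sample_rate: float = 200.0
    label: str = ""
    condition: str = ""

    def __post_init__(self):
        self.ext = np.asarray(self.ext, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.ext.shape != self.force.shape or self.ext.ndim != 1:
            raise ValueError("ext and force must be 1-D arrays of equal length")
        if np.any(self.force < 0):
            raise ValueError("force must be >= 0")

    def __len__(self):
        return len(self.ext)


def decimate_curve(curve: ForceExtensionCurve, factor: int) -> ForceExtensionCurve:
    """Boxcar-decimate extension and force (e.g. 200 Hz -> 50 Hz at factor 4)."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return curve
    n = len(curve) // factor
    if n == 0:
        raise ValueError("factor exceeds curve length")
    return ForceExtensionCurve(
        curve.ext[: n * factor].reshape(n, factor).mean(axis=1),
        curve.force[: n * factor].reshape(n, factor).mean(axis=1),
        curve.pull_rate,
        curve.sample_rate / factor,
        curve.label,
        curve.condition,
    )


@dataclass
class RipEvent:
    force_at_rip: float
    delta_ext: float
    delta_contour: float
    kind: str = "other"


def _apparent_contour(curve: ForceExtensionCurve, wlc: WLCParams) -> np.ndarray:
    """Per-sample contour length ext / z(F); piecewise constant between rips."""
    z = wlc_extension_fraction(curve.force, wlc)
    z = np.maximum(z, 1e-6)
    return curve.ext / z


def detect_rips(
    curve: ForceExtensionCurve,
    jump_threshold: float = 5.0,
    window: int = 5,
    wlc: WLCParams = WLCParams(),
) -> list:
    """Locate discrete unwrapping rips on a force-extension curve.

    The extension is converted to an apparent contour length via the WLC at
    the instantaneous force; between rips this is constant, and a rip is a
    between-adjacent-window increase whose extension-space magnitude
    exceeds ``jump_threshold``.  ``force_at_rip`` is the force immediately
    before the jump and ``delta_contour`` the contour step itself.  Events
    are returned sorted by force.
    """
    if len(curve) == 0:
        raise ValueError("empty curve")
    if len(curve) < 2 * window + 1:
        return []
    l_app = _apparent_contour(curve, wlc)
    z = np.maximum(wlc_extension_fraction(curve.force, wlc), 1e-6)
    n = len(l_app)
    c = np.concatenate(([0.0], np.cumsum(l_app)))
    pos = np.arange(window, n - window + 1)
    left = (c[pos] - c[pos - window]) / window
    right = (c[pos + window] - c[pos]) / window
    jump_l = right - left  # contour units
    jump_x = jump_l * z[np.clip(pos, 0, n - 1)]  # extension units
    peaks, _ = signal.find_peaks(jump_x, height=jump_threshold)
    if len(peaks) == 0:
        return []
    # merge peaks closer than one window (same rip seen twice)
    order = np.argsort(jump_x[peaks])[::-1]
    kept = []
    for idx in order:
        if all(abs(peaks[idx] - peaks[j]) > window for j in kept):
            kept.append(idx)
    events = []
    for idx in kept:
        i = int(pos[peaks[idx]])
        # refine alignment to the single sample with the largest contour step,
        # then estimate the jump from windows flanking that boundary so a
        # one-sample misalignment does not attenuate the estimate
        lo = max(i - window, 1)
        hi = min(i + window, n - 1)
        local = np.diff(l_app[lo - 1 : hi + 1])
        j = lo + int(np.argmax(local))  # first sample after the jump
        # one-sample guard on each side: decimation leaves a mixed sample
        # straddling the jump which would otherwise attenuate the estimate
        a = max(j - 1 - window, 0)
        b = min(j + 1 + window, n)
        dl = float(l_app[j + 1 : b].mean() - l_app[a : j - 1].mean())
        f_before = float(curve.force[max(j - 1, 0)])
        events.append(RipEvent(f_before, dl * float(z[j]), dl))
    events.sort(key=lambda e: e.force_at_rip)
    return events


def classify_rips(events: list, boundary_force: float = 8.0) -> list:
    """Label rips outer (force <= boundary) or inner (force > boundary).

    A rip exactly at the boundary is outer (closed-lower convention).
    Input must be sorted by force; the input list is not mutated.
    """
    return [
        replace(e, kind="outer" if e.force_at_rip <= boundary_force else "inner")
        for e in events
    ]


def summarize_rip_forces(
    curves_by_condition: dict,
    jump_threshold: float = 5.0,
    window: int = 5,
    boundary_force: float = 8.0,
    wlc: WLCParams = WLCParams(),
) -> dict:
    """Per-condition outer/inner rip-force statistics and pairwise t-tests.

    Returns ``{"stats": {(condition, kind): {mean, sem, n, forces}},
    "comparisons": {(cond_a, cond_b, kind): GroupComparison | str}}``.
    Conditions or kinds with no detected rips are reported as missing;
    t-tests are declined with a message when either group has n < 2.
    """
    stats = {}
    for condition, curves in curves_by_condition.items():
        if len(curves) < 1:
            raise ValueError(f"condition {condition!r} has no curves")
        by_kind = {"outer": [], "inner": []}
        for curve in curves:
            for e in classify_rips(
                detect_rips(curve, jump_threshold, window, wlc), boundary_force
            ):
                if e.kind in by_kind:
                    by_kind[e.kind].append(e.force_at_rip)
        for kind, forces in by_kind.items():
            if forces:
                arr = np.asarray(forces)
                stats[(condition, kind)] = {
                    "mean": float(arr.mean()),
                    "sem": float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else float("nan"),
                    "n": len(arr),
                    "forces": arr,
                }
            else:
                stats[(condition, kind)] = {"mean": float("nan"), "sem": float("nan"), "n": 0, "forces": np.empty(0)}
    comparisons = {}
    conditions = list(curves_by_condition)
    for i, ca in enumerate(conditions):
        for cb in conditions[i + 1 :]:
            for kind in ("outer", "inner"):
                fa = stats[(ca, kind)]["forces"]
                fb = stats[(cb, kind)]["forces"]
                if len(fa) >= 2 and len(fb) >= 2:
                    comparisons[(ca, cb, kind)] = two_sample_ttest(fa, fb)
                else:
                    comparisons[(ca, cb, kind)] = (
                        "t-test declined: fewer than 2 rips in a group"
                    )
    return {"stats": stats, "comparisons": comparisons}
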