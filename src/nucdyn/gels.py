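"""Gel and blot band-intensity quantification.

Two assays are covered.  The "one-pot" restriction accessibility assay
digests a pool of nucleosomes carrying a HaeIII site at different dyad
distances; per-site digested-band intensities of modified nucleosomes are
expressed as a percentage of the unmodified ones.  The hydroxyapatite
elution assay salt-elutes H2A-H2B dimers from bead-bound chromatin; the
bound fraction versus salt is a sigmoidal stability curve whose midpoint
C1/2 is fit by :func:`nucdyn.titration.fit_salt_sigmoid`.

Intensities are assumed background-subtracted; no image processing is
performed here.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .titration import TitrationSeries, two_sample_ttest

__all__ = [
    "DIGESTION_COLUMNS",
    "ELUTION_COLUMNS",
    "digestion_normalize",
    "bound_fraction_profile",
]

DIGESTION_COLUMNS = ["site", "time_min", "condition", "intensity", "replicate"]
ELUTION_COLUMNS = ["salt_molar", "fraction", "intensity", "strain", "replicate"]


def _require_columns(table: pd.DataFrame, columns, name):
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"{name} table missing column(s): {', '.join(missing)}")


def digestion_normalize(table: pd.DataFrame, reference_time: float = 60) -> dict:
    """Per-site digested intensity of modified nucleosomes as % of unmodified.

    At ``reference_time`` each (site, replicate) pair yields
    modified% = 100 * I(modified)/I(unmodified); the unmodified condition is
    100% by construction.  Returns::

        {"per_replicate": DataFrame(site, replicate, percent),
         "summary": DataFrame(site, mean, sem, n, t_stat, p_value),
         "missing": [site, ...], "unquantifiable": [site, ...]}

    Sites lacking one condition are listed under ``missing``; sites with a
    zero unmodified intensity under ``unquantifiable``.  The per-site
    t-test compares the two conditions on the percent scale with the
    unmodified replicates scaled by their own mean (mean exactly 100,
    replicate scatter preserved).
    """
    _require_columns(table, DIGESTION_COLUMNS, "digestion")
    at_ref = table[table["time_min"] == reference_time]
    rows, missing, unquantifiable, summary = [], [], [], []
    for site, grp in at_ref.groupby("site", sort=True):
        unmod = grp[grp["condition"] == "unmodified"].set_index("replicate")["intensity"]
        mod = grp[grp["condition"] == "modified"].set_index("replicate")["intensity"]
        common = unmod.index.intersection(mod.index)
        if len(common) == 0:
            missing.append(site)
            continue
        if (unmod.loc[common] == 0).any():
            unquantifiable.append(site)
            continue
        pct = 100.0 * mod.loc[common] / unmod.loc[common]
        for rep, p in pct.items():
            rows.append({"site": site, "replicate": rep, "percent": float(p)})
        entry = {
            "site": site,
            "mean": float(pct.mean()),
            "sem": float(pct.std(ddof=1) / np.sqrt(len(pct))) if len(pct) > 1 else float("nan"),
            "n": len(pct),
            "t_stat": float("nan"),
            "p_value": float("nan"),
        }
        if len(common) >= 2:
            unmod_pct = 100.0 * unmod.loc[common] / unmod.loc[common].mean()
            mod_pct = 100.0 * mod.loc[common] / unmod.loc[common].mean()
            if unmod_pct.var(ddof=1) + mod_pct.var(ddof=1) > 0:
                cmp_ = two_sample_ttest(unmod_pct.to_numpy(), mod_pct.to_numpy())
                entry["t_stat"], entry["p_value"] = cmp_.t_stat, cmp_.p_value
            else:  # identical intensities in both conditions
                entry["t_stat"], entry["p_value"] = 0.0, 1.0
        summary.append(entry)
    return {
        "per_replicate": pd.DataFrame(rows, columns=["site", "replicate", "percent"]),
        "summary": pd.DataFrame(
            summary, columns=["site", "mean", "sem", "n", "t_stat", "p_value"]
        ),
        "missing": missing,
        "unquantifiable": unquantifiable,
    }


def bound_fraction_profile(
    table: pd.DataFrame, mode: str = "per_salt"
) -> TitrationSeries:
    """Bead-bound dimer fraction versus salt, as a fit-ready elution series.

    ``per_salt`` (default): bound/(bound + eluted) within each salt aliquot.
    ``total``: bound relative to the (bound + eluted) total of the
    lowest-salt aliquot of the same replicate, a cumulative-depletion view.
    Salt points where bound + eluted = 0 are dropped with a warning.  The
    resulting series feeds :func:`nucdyn.titration.fit_salt_sigmoid`, whose
    c_half is the chromatin stability C1/2.
    """
    _require_columns(table, ELUTION_COLUMNS, "elution")
    if mode not in ("per_salt", "total"):
        raise ValueError("mode must be 'per_salt' or 'total'")
    wide = table.pivot_table(
        index=["replicate", "salt_molar"], columns="fraction", values="intensity"
    )
    for frac in ("bound", "eluted"):
        if frac not in wide.columns or wide[frac].isna().any():
            raise ValueError(f"every (salt, replicate) needs a {frac!r} intensity")
    xs, ys, reps = [], [], []
    for rep, grp in wide.groupby(level="replicate"):
        grp = grp.droplevel("replicate").sort_index()
        total = grp["bound"] + grp["eluted"]
        if mode == "per_salt":
            denom = total
        else:
            denom = pd.Series(total.iloc[0], index=grp.index)
        ok = denom > 0
        if not ok.all():
            warnings.warn("dropping salt point(s) with zero total intensity")
        frac = (grp["bound"][ok] / denom[ok]).clip(0.0, 1.0)
        xs.extend(frac.index.to_numpy())
        ys.extend(frac.to_numpy())
        reps.extend([rep] * len(frac))
    return TitrationSeries(np.array(xs), np.array(ys), np.array(reps, dtype=object), "elution")
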