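"""Within-/between-block recollection and familiarity indices and hit rates.

The within-block analysis contrasts match trials whose sample was targeted
by rTMS (the "+" stratum) against match trials whose sample was not (the
"-" stratum), within beta- and random-stimulation blocks; the
no-stimulation condition has no targeted stratum and is excluded.  Both
strata share the same nonmatch (lure) trials of that condition's blocks as
their false-alarm base.

The between-block analysis compares conditions directly: for beta and
random blocks only targeted match trials enter the fit, for no-stimulation
blocks all match trials do, each against that condition's nonmatch trials.

Group-level inference (mixed repeated-measures ANOVA) is deliberately left
to external statistics packages; :func:`index_table` exports the tidy
long-format table they consume.
"""

from __future__ import annotations

import pandas as pd

from betarec.roc_dpsd import build_roc, fit_dpsd
from betarec.synthetic_behavior import records_frame

__all__ = [
    "within_block_indices",
    "between_block_indices",
    "hit_rate",
    "index_table",
]


def _fit_stratum(match: pd.DataFrame, lures: pd.DataFrame, label: str):
    if len(match) == 0:
        raise ValueError(f"empty stratum {label!r}: 0 match trials")
    if len(lures) == 0:
        raise ValueError(f"empty stratum {label!r}: 0 nonmatch trials")
    return fit_dpsd(build_roc(pd.concat([match, lures])))


def within_block_indices(records, site: str, condition: str) -> dict:
    """R+/R-/F+/F- for one participant, site and stimulated condition.

    Fits the DPSD model twice — targeted match trials plus the condition's
    nonmatch trials, and untargeted match trials plus the same nonmatch
    trials — and returns ``{"R_plus", "R_minus", "F_plus", "F_minus",
    "fit_plus", "fit_minus"}``.
    """
    if condition not in ("beta", "random"):
        raise ValueError(
            "within-block strata exist only for stimulated conditions, "
            f"not {condition!r}"
        )
    df = records_frame(records)
    df = df[(df["site"] == site) & (df["condition"] == condition)]
    lures = df[df["trial_type"] == "nonmatch"]
    match = df[df["trial_type"] == "match"]
    fit_plus = _fit_stratum(
        match[match["targeted"]], lures, f"{condition}/targeted"
    )
    fit_minus = _fit_stratum(
        match[~match["targeted"]], lures, f"{condition}/untargeted"
    )
    return {
        "R_plus": fit_plus.R,
        "R_minus": fit_minus.R,
        "F_plus": fit_plus.F,
        "F_minus": fit_minus.F,
        "fit_plus": fit_plus,
        "fit_minus": fit_minus,
    }


def between_block_indices(records, site: str) -> dict:
    """Per-condition R and F for one participant at one site.

    Beta and random conditions use targeted match trials only; the
    no-stimulation condition uses all its match trials.  Each fit draws
    false alarms from that condition's own nonmatch trials.
    """
    df = records_frame(records)
    df = df[df["site"] == site]
    out = {}
    for condition in ("beta", "random", "none"):
        sub = df[df["condition"] == condition]
        if len(sub) == 0:
            raise ValueError(f"no records for condition {condition!r}")
        lures = sub[sub["trial_type"] == "nonmatch"]
        match = sub[sub["trial_type"] == "match"]
        if condition != "none":
            match = match[match["targeted"]]
        fit = _fit_stratum(match, lures, condition)
        out[condition] = {"R": fit.R, "F": fit.F, "fit": fit}
    return out


def hit_rate(records, **filters) -> float:
    """Proportion of 'old' decisions among match trials in a stratum.

    Keyword filters restrict by column equality (e.g. ``condition="beta"``,
    ``targeted=True``).  Nonmatch trials never enter the denominator.
    """
    df = records_frame(records)
    for col, val in filters.items():
        df = df[df[col] == val]
    match = df[df["trial_type"] == "match"]
    if len(match) == 0:
        raise ValueError(f"empty stratum for filters {filters!r}: no match trials")
    return float((match["decision"] == "old").mean())


def index_table(records) -> pd.DataFrame:
    """Tidy long-format index table for external repeated-measures ANOVA.

    One row per (participant, site, condition, stratum) with the DPSD
    indices, hit rate and trial counts.  Strata: ``targeted``/``untargeted``
    within stimulated conditions plus ``all`` per condition (the
    between-block row).
    """
    df = records_frame(records).sort_values(
        ["participant", "site", "condition"], kind="stable"
    )
    rows = []
    for (pid, site), part in df.groupby(["participant", "site"], sort=True):
        between = between_block_indices(part, site)
        for condition in ("beta", "random", "none"):
            sub = part[part["condition"] == condition]
            n_lure = int((sub["trial_type"] == "nonmatch").sum())
            strata = [("all", between[condition]["fit"])]
            if condition != "none":
                w = within_block_indices(part, site, condition)
                strata += [("targeted", w["fit_plus"]), ("untargeted", w["fit_minus"])]
            for stratum, fit in strata:
                match = sub[sub["trial_type"] == "match"]
                if stratum == "targeted":
                    match = match[match["targeted"]]
                elif stratum == "untargeted":
                    match = match[~match["targeted"]]
                elif condition != "none":
                    match = match[match["targeted"]]  # between-block row
                rows.append(
                    {
                        "participant": pid,
                        "site": site,
                        "condition": condition,
                        "stratum": stratum,
                        "R": fit.R,
                        "F": fit.F,
                        "hit_rate": float((match["decision"] == "old").mean()),
                        "n_match": len(match),
                        "n_nonmatch": n_lure,
                        "refit_applied": fit.refit_applied,
                    }
                )
    return pd.DataFrame(rows)
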