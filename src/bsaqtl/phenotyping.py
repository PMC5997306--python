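"""Trait derivations for the aluminium-tolerance screen.

Raw measurements arrive as a long table of (accession, trait, condition,
replicate, value) records — shoot height (SH, cm), root length (RL, cm),
shoot fresh/dry weight (SFW/SDW, mg), root dry weight (RDW, mg) — under a
control and an Al-stress condition. From these the pipeline derives shoot
water content, the stress tolerance index (stress/control ratio), removes
per-trait outliers beyond three standard deviations, and averages
replicates. The fixed order is: outlier removal on raw per-accession
values, then replicate averaging, then derived traits.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "compute_swc",
    "stress_tolerance_index",
    "remove_outliers",
    "average_replicates",
    "derive_traits",
]


def compute_swc(sfw: float, sdw: float) -> float:
    """Shoot water content in percent: (SFW - SDW) / SFW x 100."""
    if sfw <= 0:
        raise ValueError(f"SFW must be > 0, got {sfw}")
    if not 0 <= sdw <= sfw:
        raise ValueError(f"SDW must be in [0, SFW], got {sdw}")
    return (sfw - sdw) / sfw * 100.0


def stress_tolerance_index(stress: float, control: float) -> float:
    """Stress/control trait ratio; NaN (with a warning) when control is 0."""
    if control == 0:
        log.warning("stress tolerance index undefined: control value is 0")
        return math.nan
    return stress / control


def remove_outliers(values, n_sd: float = 3.0) -> np.ndarray:
    """Mask of values within mean +/- n_sd standard deviations.

    Mean and sd are computed once over the non-missing inputs (the rule is
    not re-iterated); values exactly on the boundary are kept; missing
    inputs yield False.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return np.zeros(0, dtype=bool)
    ok = ~np.isnan(v)
    if not ok.any():
        return ok
    mean = v[ok].mean()
    sd = v[ok].std(ddof=0)
    keep = np.zeros(v.size, dtype=bool)
    keep[ok] = np.abs(v[ok] - mean) <= n_sd * sd
    return keep


def average_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Mean value per (accession, trait, condition) over non-missing replicates.

    All-missing groups come out missing. Input column order or record order
    never changes the result.
    """
    out = (
        table.groupby(["accession", "trait", "condition"], sort=True)["value"]
        .mean()
        .reset_index()
    )
    return out


def derive_traits(table: pd.DataFrame, n_sd: float = 3.0) -> pd.DataFrame:
    """Full trait pipeline: trim outliers, average replicates, derive SWC and indices.

    Outlier trimming is applied per trait x condition across accessions
    (the reference population for the +/- 3 sd rule is the full accession
    panel). SWC is computed from the averaged SFW and SDW; the stress
    tolerance index (condition ``ratio``) is the stress/control ratio of
    each averaged trait. Returns a tidy (accession, trait, condition,
    value) table.
    """
    work = table.copy()
    for (_, _), idx in work.groupby(["trait", "condition"], sort=False).groups.items():
        keep = remove_outliers(work.loc[idx, "value"].to_numpy(), n_sd=n_sd)
        drop = np.asarray(idx)[~keep]
        work.loc[drop, "value"] = np.nan
    avg = average_replicates(work)

    wide = avg.pivot_table(
        index=["accession", "condition"], columns="trait", values="value", aggfunc="first"
    )
    if {"SFW", "SDW"}.issubset(wide.columns):
        sfw = wide["SFW"]
        sdw = wide["SDW"]
        valid = (sfw > 0) & (sdw >= 0) & (sdw <= sfw)
        swc = pd.Series(np.nan, index=wide.index, name="value")
        swc[valid] = (sfw[valid] - sdw[valid]) / sfw[valid] * 100.0
        swc_long = swc.reset_index()
        swc_long["trait"] = "SWC"
        avg = pd.concat([avg, swc_long[["accession", "trait", "condition", "value"]]])

    cond = avg.pivot_table(
        index=["accession", "trait"], columns="condition", values="value", aggfunc="first"
    )
    if {"control", "stress"}.issubset(cond.columns):
        ctrl = cond["control"]
        ratio = pd.Series(np.nan, index=cond.index, name="value")
        nonzero = ctrl != 0
        ratio[nonzero] = cond.loc[nonzero, "stress"] / ctrl[nonzero]
        n_zero = int((~nonzero & ctrl.notna()).sum())
        if n_zero:
            log.warning("%d stress tolerance indices undefined (control = 0)", n_zero)
        ratio_long = ratio.reset_index()
        ratio_long["condition"] = "ratio"
        avg = pd.concat([avg, ratio_long[["accession", "trait", "condition", "value"]]])
    return avg.sort_values(["accession", "trait", "condition"], ignore_index=True)
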