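"""Quintile assignment, rhythm-impairment score, and biomarker abnormality.

Rest-activity parameters are grouped into survey-weighted quintiles; the
reference (presumed lowest-risk) quintile is Q1 for acrophase and IV and Q5
for the other five parameters.  The impaired-rhythmicity composite counts
how many of {pseudo-F, amplitude, mesor, acrophase} fall in their least
healthy quintile (Q1 for the first three, Q5 for acrophase), capped at 3
("3+").  Liver-biomarker abnormality uses fixed sex-specific clinical
cut-offs with strict inequalities, and the abnormal composite is the number
of abnormal markers capped at 3.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "BIOMARKERS", "THRESHOLDS", "RAR_PARAMETERS", "REFERENCE_QUINTILE",
    "LEAST_HEALTHY_QUINTILE", "assign_quintiles", "weighted_quantile",
    "impaired_rhythmicity_score", "abnormal_flags", "abnormal_from_level",
    "abnormal_composite", "score_participants",
]

BIOMARKERS = ["ALT", "AST", "ALP", "GGT", "albumin", "bilirubin"]

#: sex -> (direction, cut): abnormal iff level is strictly 'above'/'below' cut
THRESHOLDS = {
    "ALT": {"male": ("above", 47.0), "female": ("above", 30.0)},
    "AST": {"male": ("above", 33.0), "female": ("above", 33.0)},
    "ALP": {"male": ("above", 113.0), "female": ("above", 113.0)},
    "GGT": {"male": ("above", 65.0), "female": ("above", 36.0)},
    "albumin": {"male": ("below", 3.7), "female": ("below", 3.7)},
    "bilirubin": {"male": ("above", 1.3), "female": ("above", 1.3)},
}

RAR_PARAMETERS = ["pseudo_f", "amplitude", "mesor", "amp_mesor_ratio",
                  "acrophase", "IS", "IV"]

#: presumed lowest-risk quintile per parameter (the regression reference)
REFERENCE_QUINTILE = {"pseudo_f": 5, "amplitude": 5, "mesor": 5,
                      "amp_mesor_ratio": 5, "IS": 5, "acrophase": 1, "IV": 1}

#: quintile counted by the impaired-rhythmicity composite
LEAST_HEALTHY_QUINTILE = {"pseudo_f": 1, "amplitude": 1, "mesor": 1,
                          "acrophase": 5}


def weighted_quantile(values, weights, probs):
    """Left-continuous weighted-CDF quantile: smallest v with F(v) >= p.

    With equal weights on 1..100 this returns 20/40/60/80 at the quintile
    probabilities, and a value equal to a cut-point classifies into the lower
    quintile under :func:`assign_quintiles`' ``side='left'`` search.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    order = np.argsort(v, kind="mergesort")
    v, w = v[order], w[order]
    cdf = np.cumsum(w) / w.sum()
    probs = np.atleast_1d(np.asarray(probs, dtype=float))
    idx = np.searchsorted(cdf, probs - 1e-12, side="left")
    return v[np.minimum(idx, v.size - 1)]


def assign_quintiles(values, weights=None):
    """Survey-weighted quintile labels (1 = lowest fifth) and cut-points.

    Cut-points are the weighted 20/40/60/80th percentiles; values equal to a
    cut-point go to the lower quintile.  Missing values get a missing label.
    """
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v)
    if weights is None:
        w = np.ones(v.shape)
    else:
        w = np.asarray(weights, dtype=float)
    if np.unique(v[ok]).size < 5:
        raise ValueError("need at least 5 distinct values to form quintiles")
    cuts = weighted_quantile(v[ok], w[ok], [0.2, 0.4, 0.6, 0.8])
    labels = np.full(v.shape, np.nan)
    labels[ok] = np.searchsorted(cuts, v[ok], side="left") + 1
    return labels, cuts


def impaired_rhythmicity_score(quintiles: dict) -> float:
    """Count of {pseudo-F, amplitude, mesor} in Q1 plus acrophase in Q5, capped at 3.

    ``quintiles`` maps parameter name -> quintile label; a missing label for
    any of the four component parameters yields a missing score.
    """
    total = 0
    for param, worst in LEAST_HEALTHY_QUINTILE.items():
        q = quintiles.get(param, np.nan)
        if q is None or (isinstance(q, float) and np.isnan(q)):
            return np.nan
        total += int(q) == worst
    return min(total, 3)


def abnormal_from_level(biomarker: str, level: float, sex: str) -> bool:
    """Abnormality of one level under the strict sex-specific cut-off."""
    direction, cut = THRESHOLDS[biomarker][sex]
    if level < 0:
        raise ValueError(f"negative {biomarker} level: {level}")
    return level > cut if direction == "above" else level < cut


def abnormal_flags(panel: pd.DataFrame) -> pd.DataFrame:
    """Six abnormality flags from biomarker levels and sex.

    ``panel`` needs the six biomarker columns and a ``sex`` column with
    values in {male, female}.  Missing levels give missing flags.
    """
    sex = panel["sex"].to_numpy()
    out = {}
    for b in BIOMARKERS:
        level = panel[b].to_numpy(dtype=float)
        if np.any(level[np.isfinite(level)] < 0):
            raise ValueError(f"negative {b} level encountered")
        direction = THRESHOLDS[b]["male"][0]
        cut = np.where(sex == "male", THRESHOLDS[b]["male"][1],
                       THRESHOLDS[b]["female"][1])
        flag = level > cut if direction == "above" else level < cut
        out[f"{b}_abnormal"] = np.where(np.isfinite(level), flag, np.nan)
    return pd.DataFrame(out, index=panel.index)


def abnormal_composite(flags: pd.DataFrame) -> pd.Series:
    """Number of abnormal markers, capped at 3 ("3+"); missing if any flag missing."""
    cols = [c for c in flags.columns if c.endswith("_abnormal")]
    arr = flags[cols].to_numpy(dtype=float)
    total = arr.sum(axis=1)
    out = np.minimum(total, 3.0)
    out[np.isnan(arr).any(axis=1)] = np.nan
    return pd.Series(out, index=flags.index, name="abnormal_composite")


def score_participants(rar_table: pd.DataFrame, panel: pd.DataFrame,
                       weights=None, weighted: bool = True) -> pd.DataFrame:
    """Join RAR quintiles, the impaired score, abnormal flags and composite.

    ``rar_table`` holds one row per participant with the seven rhythm
    parameters; ``panel`` the biomarker levels + sex, aligned on
    ``participant_id``.  Quintiles are survey-weighted unless
    ``weighted=False`` (sensitivity switch).
    """
    df = rar_table.merge(panel, on="participant_id", how="inner")
    w = df[weights].to_numpy() if (weighted and weights is not None) else None
    for param in RAR_PARAMETERS:
        if param in df.columns:
            labels, _ = assign_quintiles(df[param].to_numpy(), w)
            df[f"{param}_q"] = labels
    df["impaired_score"] = [
        impaired_rhythmicity_score(
            {p: row.get(f"{p}_q", np.nan) for p in LEAST_HEALTHY_QUINTILE})
        for row in df.to_dict("records")
    ]
    flags = abnormal_flags(df)
    df = pd.concat([df, flags], axis=1)
    df["abnormal_composite"] = abnormal_composite(flags)
    return df
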