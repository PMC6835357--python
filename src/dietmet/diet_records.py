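"""Diet quality index, predominant-diet classification, nutrient deltas.

The score awards one Prudent point for each of: poly:sat fat ratio > 1.0,
saturated fat < 7% energy, total fiber > 28 g/day, fruits + vegetables
> 5 servings/day, potassium > 3500 mg/day; and one Western point for each
of: poly:sat < 0.5, saturated fat > 16%, total fiber < 9 g/day,
fruits + vegetables < 5 servings/day, potassium < 3500 mg/day. All
comparisons are strict, so boundary values earn no point. A participant is
"predominantly" Prudent (Western) when the Prudent minus Western score (or
the reverse) is >= 2; otherwise mixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ValidationError
from .synthetic import NUTRIENT_NAMES

#: the five scored fields, in daily units
SCORE_FIELDS = (
    "poly_sat_ratio",       # dimensionless
    "sat_fat_pct",          # % energy
    "total_fiber",          # g/day
    "fruits_veg_servings",  # servings/day
    "potassium",            # mg/day
)


@dataclass(frozen=True)
class DietScore:
    prudent_points: int
    western_points: int
    classification: str  # predominantly-prudent | predominantly-western | mixed


def score_diet(record: dict | pd.Series) -> DietScore:
    """Score one nutrient record (daily units) against the ten criteria."""
    missing = [f for f in SCORE_FIELDS if f not in record or pd.isna(record[f])]
    if missing:
        raise ValidationError(f"missing scored field(s): {missing}")
    ps = float(record["poly_sat_ratio"])
    sat = float(record["sat_fat_pct"])
    fib = float(record["total_fiber"])
    fv = float(record["fruits_veg_servings"])
    k = float(record["potassium"])
    prudent = sum([ps > 1.0, sat < 7.0, fib > 28.0, fv > 5.0, k > 3500.0])
    western = sum([ps < 0.5, sat > 16.0, fib < 9.0, fv < 5.0, k < 3500.0])
    return DietScore(prudent, western, classify_predominant(prudent, western))


def classify_predominant(prudent_points: int, western_points: int) -> str:
    """Difference rule: >= 2 points apart decides; otherwise mixed."""
    if prudent_points - western_points >= 2:
        return "predominantly-prudent"
    if western_points - prudent_points >= 2:
        return "predominantly-western"
    return "mixed"


def score_records(records: pd.DataFrame) -> pd.DataFrame:
    """Score every (participant, period) row of a nutrient-record table."""
    rows = []
    for _, rec in records.iterrows():
        s = score_diet(rec)
        rows.append({
            "participant_id": rec["participant_id"], "period": rec["period"],
            "prudent_points": s.prudent_points, "western_points": s.western_points,
            "classification": s.classification,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Summary t-test and Table-1-style deltas
# ---------------------------------------------------------------------------

def summary_ttest(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test from printed summary statistics.

    Returns (t, df, two-sided p). Equal means with zero pooled variance give
    t=0, p=1; unequal means with zero pooled variance give the degenerate
    limit (t=+/-inf, p reported as the smallest positive double).
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("summary_ttest needs n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValidationError("standard deviations must be >= 0")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    diff = mean1 - mean2
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, df, 1.0
        return float(np.sign(diff) * np.inf), df, float(np.nextafter(0.0, 1.0))
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    p = max(float(p), float(np.nextafter(0.0, 1.0)))
    return float(t), int(df), p


def nutrient_deltas(
    records: pd.DataFrame,
    arms: dict[str, str] | pd.Series,
    categories: list[str] | None = None,
    bonferroni_m: int | None = None,
) -> pd.DataFrame:
    """Per-category intervention-minus-baseline deltas, summarised per arm.

    Returns one row per category with per-arm mean/SD/n, the pooled-variance
    two-sample t between arms, and a Bonferroni flag at alpha=0.05 over
    ``bonferroni_m`` categories (default: the number tested).
    """
    arms = pd.Series(arms)
    categories = categories or [c for c in NUTRIENT_NAMES if c in records.columns]
    wide = records.pivot(index="participant_id", columns="period")
    deltas = {}
    dropped = []
    for pid in wide.index:
        ok = True
        for cat in categories:
            if pd.isna(wide.loc[pid, (cat, "baseline")]) or pd.isna(
                wide.loc[pid, (cat, "intervention")]
            ):
                ok = False
        if not ok:
            dropped.append(pid)
            continue
        deltas[pid] = {
            cat: wide.loc[pid, (cat, "intervention")] - wide.loc[pid, (cat, "baseline")]
            for cat in categories
        }
    ddf = pd.DataFrame(deltas).T
    m = bonferroni_m or len(categories)
    rows = []
    for cat in categories:
        x = ddf[cat]
        g1 = x[arms.loc[x.index] == "W-P"]
        g2 = x[arms.loc[x.index] == "P-W"]
        if len(g1) < 2 or len(g2) < 2:
            raise ValidationError(f"arm with <2 participants for category {cat!r}")
        t, df, p = summary_ttest(
            g1.mean(), g1.std(ddof=1), len(g1), g2.mean(), g2.std(ddof=1), len(g2)
        )
        rows.append({
            "category": cat,
            "mean_wp": g1.mean(), "sd_wp": g1.std(ddof=1), "n_wp": len(g1),
            "mean_pw": g2.mean(), "sd_pw": g2.std(ddof=1), "n_pw": len(g2),
            "t": t, "df": df, "p": p,
            "bonferroni_significant": p < 0.05 / m,
        })
    return pd.DataFrame(rows).set_index("category")


def participant_deltas(
    records: pd.DataFrame, categories: list[str] | None = None
) -> pd.DataFrame:
    """Participants x categories matrix of intervention - baseline deltas."""
    categories = categories or [c for c in NUTRIENT_NAMES if c in records.columns]
    wide = records.pivot(index="participant_id", columns="period")
    out = pd.DataFrame(index=wide.index)
    for cat in categories:
        out[cat] = wide[(cat, "intervention")] - wide[(cat, "baseline")]
    return out.dropna()
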