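"""Heaviness standardisation, illusion scoring, and presence scoring.

The size-weight illusion (SWI) score follows the regression-based index:
for each participant and lifting condition, raw heaviness ratings from the
32 test lifts are regressed (OLS, with intercept) onto lifted object mass
in grams and object volume in cm^3, and the score is

    SWI = -(bV / bW)   [g per cm^3]

i.e. the grams of perceived weight change produced by one cm^3 of volume
change, sign-flipped so a larger score means a larger illusion.  Because
the stimulus set is a balanced two-level design in both predictors, the
slopes equal simple cell-mean difference quotients and the score is
invariant to positive affine rescalings of a participant's rating scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .objects import ObjectSpec, make_object_set


class ZeroVarianceError(ValueError):
    """A participant's ratings have no variance, so they cannot be standardised."""


@dataclass(frozen=True)
class SWIResult:
    participant_id: int
    condition: str
    intercept: float
    bW: float  # rating units per gram
    bV: float  # rating units per cm^3
    swi_score: float  # g per cm^3


def zscore_ratings(trials: pd.DataFrame) -> pd.DataFrame:
    """Standardise test-trial ratings per participant, pooled across conditions.

    Washout trials are dropped.  Each participant's test ratings from both
    conditions are pooled and z-scored with the sample SD (n-1), so the
    per-participant pooled mean is 0 and SD is 1 while any real-vs-virtual
    rating difference survives standardisation.  Adds a ``z_rating`` column.
    """
    test = trials[trials["phase"] == "test"].copy()
    out = []
    for pid, group in test.groupby("participant_id", sort=True):
        r = group["rating"].to_numpy(dtype=float)
        sd = r.std(ddof=1)
        if len(np.unique(r)) < 2 or sd == 0:
            raise ZeroVarianceError(
                f"participant {pid}: zero rating variance, cannot z-score"
            )
        g = group.copy()
        g["z_rating"] = (r - r.mean()) / sd
        out.append(g)
    return pd.concat(out, ignore_index=True)


def fit_heaviness_regression(
    ratings: Iterable[float],
    object_labels: Iterable[str],
    objects: Iterable[ObjectSpec] | None = None,
) -> tuple[float, float, float]:
    """OLS of raw ratings on lifted mass (g) and volume (cm^3).

    Returns (intercept, bW, bV).  The design must contain both mass levels
    and both volume levels, otherwise the normal equations are singular.
    """
    if objects is None:
        objects = make_object_set()
    omap = {o.label: o for o in objects}
    y = np.asarray(list(ratings), dtype=float)
    labels = list(object_labels)
    if len(y) != len(labels):
        raise ValueError("ratings and object labels differ in length")
    X = np.column_stack(
        [
            np.ones(len(y)),
            [omap[l].total_mass_g for l in labels],
            [omap[l].volume_cm3 for l in labels],
        ]
    )
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design: need two mass and two volume levels")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(coef[0]), float(coef[1]), float(coef[2])


def swi_score(bW: float, bV: float) -> float:
    """Illusion score -(bV/bW) in g/cm^3; undefined when bW is zero."""
    if bW == 0:
        raise ZeroDivisionError("SWI score undefined: zero weight slope bW")
    return -(bV / bW)


def swi_scores_table(
    trials: pd.DataFrame, objects: Iterable[ObjectSpec] | None = None
) -> pd.DataFrame:
    """Per participant x condition regression slopes and SWI scores.

    Uses raw (not z-scored) test-trial ratings, as the score is invariant
    to each participant's private rating scale.
    """
    if objects is None:
        objects = make_object_set()
    test = trials[trials["phase"] == "test"]
    rows = []
    for (pid, cond), group in test.groupby(["participant_id", "condition"], sort=True):
        b0, bw, bv = fit_heaviness_regression(
            group["rating"], group["object"], objects
        )
        rows.append(SWIResult(int(pid), str(cond), b0, bw, bv, swi_score(bw, bv)))
    return pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "condition": r.condition,
                "intercept": r.intercept,
                "bW": r.bW,
                "bV": r.bV,
                "swi_score": r.swi_score,
            }
            for r in rows
        ]
    )


def presence_score(items: Iterable[int]) -> int:
    """Count of the six 1-7 questionnaire items answered 6 or 7."""
    vals = list(items)
    if len(vals) != 6:
        raise ValueError(f"expected 6 presence items, got {len(vals)}")
    for v in vals:
        if not (1 <= int(v) <= 7) or int(v) != v:
            raise ValueError(f"presence item {v!r} outside the 1..7 integer scale")
    return sum(1 for v in vals if v >= 6)


def presence_scores_table(presence: pd.DataFrame) -> pd.DataFrame:
    """Per-participant presence score from an item-level table."""
    item_cols = [f"item{i}" for i in range(1, 7)]
    rows = [
        {
            "participant_id": int(row["participant_id"]),
            "presence_score": presence_score([row[c] for c in item_cols]),
        }
        for _, row in presence.iterrows()
    ]
    return pd.DataFrame(rows)
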