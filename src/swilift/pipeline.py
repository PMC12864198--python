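"""End-to-end orchestration: simulate -> kinematics -> score -> analyze.

The analysis mirrors a paired real-vs-virtual lifting study:

1. z-score heaviness ratings per participant (pooled over conditions) and
   run the 2 (size) x 2 (weight) x 2 (condition) within-subjects ANOVA;
2. fit the per-participant, per-condition heaviness regressions, form SWI
   scores, and compare conditions with a paired t test (plus JZS BF10);
3. reduce tracker streams to per-trial MRV/MLV metrics, average valid test
   trials per participant x condition, winsorise each variable within
   condition, and compare conditions (Shapiro-Wilk gate deciding between
   the paired t and Wilcoxon signed-rank test);
4. regress the virtual-condition SWI score, and the real-minus-virtual
   difference, on the presence score.

Every stage records row and exclusion counts so each reported statistic is
traceable to its inputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .objects import size_of, weight_of
from .synth import (
    N_TEST,
    N_WASHOUT,
    StudyConfig,
    SyntheticStudy,
    config_to_dict,
    parse_trial_id,
    simulate_study,
)
from .kinematics import metrics_table
from .scoring import presence_scores_table, swi_scores_table, zscore_ratings
from .stats import (
    DegenerateInputError,
    paired_t,
    rm_anova_ratings,
    shapiro_wilk_gate,
    simple_regression,
    wilcoxon_signed_rank,
    winsorize,
)

RATINGS_COLUMNS = ["participant_id", "condition", "trial_index", "phase", "object", "rating"]
PRESENCE_COLUMNS = ["participant_id"] + [f"item{i}" for i in range(1, 7)]

KINEMATIC_VARS = {
    "mrv_m_s": "maximum reach velocity (m/s)",
    "t_mrv_pct": "time to maximum reach velocity (% of reach time)",
    "mlv_m_s": "maximum lift velocity (m/s)",
    "t_mlv_pct": "time to maximum lift velocity (% of lift time)",
}


# ---------------------------------------------------------------------------
# validation


def validate_inputs(
    ratings: pd.DataFrame,
    presence: pd.DataFrame | None = None,
    streams: pd.DataFrame | None = None,
) -> list[dict]:
    """Schema/range/count checks; returns a machine-readable issue list."""
    issues: list[dict] = []

    missing = [c for c in RATINGS_COLUMNS if c not in ratings.columns]
    if missing:
        issues.append({"code": "ratings_missing_columns", "detail": missing})
        return issues
    if (ratings["rating"] <= 0).any():
        bad = ratings.index[ratings["rating"] <= 0].tolist()[:5]
        issues.append({"code": "nonpositive_rating", "detail": f"rows {bad}"})
    for (pid, cond), block in ratings.groupby(["participant_id", "condition"]):
        n_wash = int((block["phase"] == "washout").sum())
        n_test = int((block["phase"] == "test").sum())
        if n_wash != N_WASHOUT or n_test != N_TEST:
            issues.append(
                {
                    "code": "trial_count_mismatch",
                    "detail": f"participant {pid} condition {cond}: "
                    f"{n_wash} washout (expected {N_WASHOUT}), "
                    f"{n_test} test (expected {N_TEST})",
                }
            )
        counts = block.loc[block["phase"] == "test", "object"].value_counts()
        if len(counts) and (counts != 8).any():
            issues.append(
                {
                    "code": "object_count_mismatch",
                    "detail": f"participant {pid} condition {cond}: {counts.to_dict()}",
                }
            )

    if presence is not None:
        missing = [c for c in PRESENCE_COLUMNS if c not in presence.columns]
        if missing:
            issues.append({"code": "presence_missing_columns", "detail": missing})
        else:
            items = presence[PRESENCE_COLUMNS[1:]].to_numpy()
            if ((items < 1) | (items > 7)).any():
                issues.append(
                    {
                        "code": "presence_item_out_of_range",
                        "detail": "items must lie in 1..7",
                    }
                )

    if streams is not None:
        for tid, g in streams.groupby("trial_id"):
            t = g["time_s"].to_numpy()
            if np.any(np.diff(t) <= 0):
                issues.append(
                    {"code": "nonmonotone_time", "detail": f"trial {tid}"}
                )
    return issues


# ---------------------------------------------------------------------------
# helpers


def _paired_block(real: np.ndarray, virtual: np.ndarray, gate: bool) -> dict:
    """One real-vs-virtual contrast; optionally Shapiro-routed to Wilcoxon.

    Degenerate inputs (too few pairs, zero-variance differences) yield an
    ``error`` entry next to the descriptive mean difference, not an
    exception, so one broken contrast cannot abort the whole report.
    """
    diffs = real - virtual
    out: dict = {"n": int(len(diffs)), "mean_diff": float(np.mean(diffs))}
    try:
        if gate:
            nonnormal, w, p_sw = shapiro_wilk_gate(diffs)
            out["shapiro"] = {"W": w, "p": p_sw, "nonnormal": nonnormal}
        else:
            nonnormal = False
        if nonnormal:
            v, p = wilcoxon_signed_rank(real, virtual)
            out["test"] = "wilcoxon_signed_rank"
            out["V"] = v
            out["p"] = p
        else:
            res = paired_t(real, virtual)
            out["test"] = "paired_t"
            out.update(
                {
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "d_z": res.d_z,
                    "ci95": list(res.ci95),
                    "bf10": res.bf10,
                }
            )
    except (DegenerateInputError, ValueError) as exc:
        out["error"] = str(exc)
    return out


def _condition_matrix(table: pd.DataFrame, value: str) -> tuple[np.ndarray, np.ndarray, list]:
    """Pivot participant x condition values into aligned (real, virtual) arrays."""
    wide = table.pivot(index="participant_id", columns="condition", values=value)
    wide = wide.dropna(subset=["real", "virtual"])
    return (
        wide["real"].to_numpy(float),
        wide["virtual"].to_numpy(float),
        wide.index.tolist(),
    )


def annotate_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    """Attach participant/condition/trial info parsed from trial ids."""
    parsed = metrics["trial_id"].map(parse_trial_id)
    out = metrics.copy()
    out["participant_id"] = [p for p, _, _ in parsed]
    out["condition"] = [c for _, c, _ in parsed]
    out["trial_index"] = [i for _, _, i in parsed]
    return out


def kinematic_condition_means(
    metrics: pd.DataFrame, ratings: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Mean valid test-trial metrics per participant x condition.

    Washout trials and trials failing segmentation are excluded; the second
    return value reports the exclusion counts.
    """
    m = annotate_metrics(metrics)
    phase = ratings.set_index(["participant_id", "condition", "trial_index"])["phase"]
    idx = pd.MultiIndex.from_frame(m[["participant_id", "condition", "trial_index"]])
    m["phase"] = phase.reindex(idx).to_numpy()
    test = m[m["phase"] == "test"]
    excl = {
        "n_trials": int(len(m)),
        "n_washout_excluded": int((m["phase"] == "washout").sum()),
        "n_invalid_excluded": int((~test["valid"]).sum()),
    }
    valid = test[test["valid"]].copy()
    valid["mrv_m_s"] = valid["mrv_mm_s"] / 1000.0
    valid["mlv_m_s"] = valid["mlv_mm_s"] / 1000.0
    means = (
        valid.groupby(["participant_id", "condition"], sort=True)[
            ["mrv_m_s", "t_mrv_pct", "mlv_m_s", "t_mlv_pct"]
        ]
        .mean()
        .reset_index()
    )
    return means, excl


def _winsorize_within_condition(table: pd.DataFrame, cols) -> tuple[pd.DataFrame, int]:
    """Winsorise each variable within each condition; count replaced values."""
    out = table.copy()
    n_replaced = 0
    for cond, idx in out.groupby("condition").groups.items():
        for col in cols:
            orig = out.loc[idx, col].to_numpy(float)
            if len(orig) < 3:  # nothing to bound; leave tiny groups alone
                continue
            w = winsorize(orig)
            n_replaced += int(np.sum(w != orig))
            out.loc[idx, col] = w
    return out, n_replaced


# ---------------------------------------------------------------------------
# the full analysis


def analyze_study(
    ratings: pd.DataFrame,
    presence: pd.DataFrame | None = None,
    metrics: pd.DataFrame | None = None,
) -> dict:
    """Run every statistical comparison; returns the report dict."""
    report: dict = {"software": {"package": "swilift", "version": __version__}}

    # --- ratings ANOVA on z-scores
    z = zscore_ratings(ratings)
    z["size"] = z["object"].map(size_of)
    z["weight"] = z["object"].map(weight_of)
    with np.errstate(divide="ignore", invalid="ignore"):
        anova = rm_anova_ratings(z)
    report["ratings_anova"] = anova.to_dict(orient="records")
    report["n_rating_trials"] = int(len(ratings))

    # --- SWI scores and the condition contrast
    scores = swi_scores_table(ratings)
    scores_w, n_winz = _winsorize_within_condition(scores, ["swi_score"])
    real, virtual, _ = _condition_matrix(scores_w, "swi_score")
    report["swi"] = {
        "per_condition_mean": {
            "real": float(np.mean(real)),
            "virtual": float(np.mean(virtual)),
        },
        "n_winsorized": n_winz,
        "contrast_real_minus_virtual": _paired_block(real, virtual, gate=False),
    }

    # --- kinematic contrasts
    if metrics is not None:
        means, excl = kinematic_condition_means(metrics, ratings)
        means_w, n_winz_k = _winsorize_within_condition(means, list(KINEMATIC_VARS))
        contrasts = {}
        for var, label in KINEMATIC_VARS.items():
            r, v, _ = _condition_matrix(means_w, var)
            try:
                contrasts[var] = {"label": label, **_paired_block(r, v, gate=True)}
            except DegenerateInputError as exc:
                contrasts[var] = {"label": label, "error": str(exc)}
        report["kinematics"] = {
            "exclusions": excl,
            "n_winsorized": n_winz_k,
            "contrasts": contrasts,
        }

    # --- presence regressions
    if presence is not None:
        pres = presence_scores_table(presence)
        merged = pres.merge(
            scores_w.pivot(index="participant_id", columns="condition", values="swi_score"),
            on="participant_id",
        )
        x = merged["presence_score"].to_numpy(float)
        report["presence"] = {"scores_mean": float(x.mean())}
        try:
            level = simple_regression(x, merged["virtual"].to_numpy(float))
            diff = simple_regression(
                x, (merged["real"] - merged["virtual"]).to_numpy(float)
            )
            report["presence"]["swi_on_presence"] = asdict(level)
            report["presence"]["swi_difference_on_presence"] = asdict(diff)
        except (DegenerateInputError, ValueError) as exc:
            report["presence"]["error"] = str(exc)

    return report


def run_pipeline(
    config: StudyConfig | None = None,
    out_dir: str | Path | None = None,
    include_streams: bool = True,
    study: SyntheticStudy | None = None,
) -> dict:
    """Simulate a study (unless one is supplied) and analyze it end to end.

    Writes the intermediate CSVs and the report JSON when ``out_dir`` is
    given.  Deterministic given the config seed; the report contains no
    timestamps so identical runs are byte-identical.
    """
    if study is None:
        if config is None:
            config = StudyConfig()
        study = simulate_study(config, include_streams=include_streams)
    config = study.config

    issues = validate_inputs(study.ratings, study.presence, None)
    if issues:
        raise ValueError(f"simulated inputs failed validation: {issues}")

    metrics = metrics_table(study.streams) if study.streams is not None else None
    report = analyze_study(study.ratings, study.presence, metrics)
    report["provenance"] = {
        "source": "synthetic",
        "seed": int(config.seed),
        "n_participants": int(config.n_participants),
        "config": config_to_dict(config),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        study.ratings.to_csv(out / "ratings.csv", index=False)
        study.presence.to_csv(out / "presence.csv", index=False)
        if study.streams is not None:
            study.streams.to_csv(out / "streams.csv", index=False)
        if metrics is not None:
            metrics.to_csv(out / "metrics.csv", index=False)
        swi_scores_table(study.ratings).to_csv(out / "swi_scores.csv", index=False)
        presence_scores_table(study.presence).to_csv(
            out / "presence_scores.csv", index=False
        )
        write_report(report, out / "report.json")
    return report


def write_report(report: dict, path: str | Path) -> None:
    """Serialise a report dict to JSON (numpy scalars coerced)."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, default=default, sort_keys=True))


def summarize_report(report: dict) -> str:
    """Short human-readable digest of the main comparisons."""
    lines = []
    swi = report.get("swi", {})
    c = swi.get("contrast_real_minus_virtual", {})
    if c:
        lines.append(
            "SWI real-virtual: mean diff = {:.3f} g/cm^3, t({}) = {:.2f}, "
            "p = {:.3f}, d_z = {:.2f}, BF10 = {:.2f}".format(
                c["mean_diff"], c.get("df", "?"), c.get("t", float("nan")),
                c.get("p", float("nan")), c.get("d_z", float("nan")),
                c.get("bf10", float("nan")),
            )
        )
    for var, blk in report.get("kinematics", {}).get("contrasts", {}).items():
        if "error" in blk:
            lines.append(f"{var}: {blk['error']}")
        elif blk["test"] == "paired_t":
            lines.append(
                "{}: mean diff = {:.3f}, t({}) = {:.2f}, p = {:.3f}, BF10 = {:.2f}".format(
                    var, blk["mean_diff"], blk["df"], blk["t"], blk["p"], blk["bf10"]
                )
            )
        else:
            lines.append(
                "{}: mean diff = {:.3f}, V = {:.0f}, p = {:.3f} (Wilcoxon)".format(
                    var, blk["mean_diff"], blk["V"], blk["p"]
                )
            )
    pres = report.get("presence", {})
    if "swi_on_presence" in pres:
        reg = pres["swi_on_presence"]
        lines.append(
            "presence -> virtual SWI: slope = {:.4f}, F(1, {}) = {:.2f}, "
            "p = {:.3f}, R^2 = {:.2f}, BF10 = {:.2f}".format(
                reg["slope"], reg["df_den"], reg["F"], reg["p"], reg["r_sq"], reg["bf10"]
            )
        )
    return "\n".join(lines)
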