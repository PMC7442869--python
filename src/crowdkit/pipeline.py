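"""End-to-end analysis orchestration: trials -> fits -> indices -> statistics.

Glue between the generator, the psychometric and BOLD estimators, and the
group-statistics battery.  All results are plain pandas frames / JSON-able
dicts so the CLI can persist them as CSV/JSON.
"""

from __future__ import annotations

import math

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import bold_pipeline as bp
from . import group_stats as gs
from . import psychophysics as psy
from .synthetic_data import BoldRun, SESSIONS


def behavioral_tables(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Psychometric fit table and crowding-zone table for a full trial table."""
    fits = psy.fit_day_thresholds(trials)
    zones = psy.crowding_zones(fits)
    return fits, zones


def bold_table(
    bold_runs: Mapping[tuple[str, str], Sequence[BoldRun]],
    hrf: bp.HRFParams = bp.HRFParams(),
    concatenate: bool = False,
) -> pd.DataFrame:
    """Per subject x session condition PSCs and crowding/anisotropy indices."""
    rows = []
    for (subject, session), runs in sorted(bold_runs.items()):
        idx = bp.analyze_session(runs, hrf=hrf, concatenate=concatenate)
        row = {"subject_id": subject, "session": session}
        row.update({f"psc_{c}": idx.psc[c] for c in bp.CONDITIONS})
        row.update(
            {
                "c_bold_rad": idx.c_bold_rad,
                "c_bold_tan": idx.c_bold_tan,
                "a_bold": idx.a_bold,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _t_dict(res: gs.PairedTResult) -> dict:
    return {k: (None if isinstance(v, float) and math.isnan(v) else v)
            for k, v in vars(res).items()}


def _anova_dict(res: gs.AnovaResult) -> dict:
    return {
        name: {
            k: (None if isinstance(v, float) and math.isnan(v) else v)
            for k, v in vars(eff).items()
        }
        for name, eff in res.effects.items()
    }


def _paired_by_subject(
    df: pd.DataFrame, value: str, cond_col: str, a, b, subject="subject_id"
) -> tuple[np.ndarray, np.ndarray]:
    wide = df.pivot_table(index=subject, columns=cond_col, values=value)
    wide = wide.dropna(subset=[a, b])
    return wide[a].to_numpy(), wide[b].to_numpy()


def statistics_battery(zones: pd.DataFrame, bold: pd.DataFrame) -> dict:
    """The study's inferential battery on fitted tables.

    Returns a JSON-serializable dict with the behavioral 2 x n_days ANOVA,
    pre/post paired t-tests, the BOLD 2x2x2 ANOVA, crowding-index tests,
    and the Spearman correlation between anisotropy-index changes.
    """
    out: dict = {}
    days = sorted(zones["day"].unique())
    first, last = days[0], days[-1]

    # behavioral: long table (subject, axis, day, critical spacing)
    long = zones.melt(
        id_vars=["subject_id", "day"],
        value_vars=["c_r", "c_t"],
        var_name="axis",
        value_name="critical_spacing",
    )
    long["axis"] = long["axis"].map({"c_r": "radial", "c_t": "tangential"})
    complete = ~long.groupby("subject_id")["critical_spacing"].transform(
        lambda s: s.isna().any()
    )
    long_ok = long[complete]
    out["n_subjects_behavioral"] = int(long_ok["subject_id"].nunique())
    if long_ok["subject_id"].nunique() >= 2 and len(days) >= 2:
        out["anova_axis_by_day"] = _anova_dict(
            gs.rm_anova(long_ok, "critical_spacing", within=["axis", "day"])
        )
    for axis, col in (("radial", "c_r"), ("tangential", "c_t")):
        sub = zones.dropna(subset=[col])
        pre, post = _paired_by_subject(sub, col, "day", first, last)
        out[f"paired_t_{axis}_day{first}_vs_day{last}"] = _t_dict(gs.paired_t(pre, post))
    zpre = zones[zones["day"] == first].set_index("subject_id")
    zpost = zones[zones["day"] == last].set_index("subject_id")
    common = zpre.index.intersection(zpost.index)
    out["mean_ratio_pre"] = float(zpre.loc[common, "ratio"].mean())
    out["mean_ratio_post"] = float(zpost.loc[common, "ratio"].mean())
    out["paired_t_ratio"] = _t_dict(
        gs.paired_t(zpre.loc[common, "ratio"], zpost.loc[common, "ratio"])
    )
    out["paired_t_a_psy"] = _t_dict(
        gs.paired_t(zpre.loc[common, "a_psy"], zpost.loc[common, "a_psy"])
    )
    out["day_means"] = {
        axis: {
            int(d): float(zones.loc[zones["day"] == d, col].mean())
            for d in days
        }
        for axis, col in (("radial", "c_r"), ("tangential", "c_t"))
    }

    # BOLD: 2x2x2 ANOVA on PSC
    psc_long = bold.melt(
        id_vars=["subject_id", "session"],
        value_vars=[f"psc_{c}" for c in bp.CONDITIONS],
        var_name="condition",
        value_name="psc",
    )
    psc_long["axis"] = psc_long["condition"].str.contains("radial").map(
        {True: "radial", False: "tangential"}
    )
    psc_long["target"] = psc_long["condition"].str.contains("present").map(
        {True: "present", False: "absent"}
    )
    if bold["subject_id"].nunique() >= 2:
        out["anova_axis_by_target_by_session"] = _anova_dict(
            gs.rm_anova(psc_long, "psc", within=["axis", "target", "session"])
        )
        cb_long = bold.melt(
            id_vars=["subject_id", "session"],
            value_vars=["c_bold_rad", "c_bold_tan"],
            var_name="axis",
            value_name="c_bold",
        )
        cb_long["axis"] = cb_long["axis"].map(
            {"c_bold_rad": "radial", "c_bold_tan": "tangential"}
        )
        out["anova_cbold_axis_by_session"] = _anova_dict(
            gs.rm_anova(cb_long, "c_bold", within=["axis", "session"])
        )
    for axis, col in (("radial", "c_bold_rad"), ("tangential", "c_bold_tan")):
        pre, post = _paired_by_subject(bold, col, "session", "pre", "post")
        out[f"paired_t_cbold_{axis}"] = _t_dict(gs.paired_t(pre, post))
    pre_a, post_a = _paired_by_subject(bold, "a_bold", "session", "pre", "post")
    out["paired_t_a_bold"] = _t_dict(gs.paired_t(pre_a, post_a))
    out["mean_psc"] = {
        session: {
            c: float(bold.loc[bold["session"] == session, f"psc_{c}"].mean())
            for c in bp.CONDITIONS
        }
        for session in SESSIONS
    }
    out["mean_cbold"] = {
        session: {
            "radial": float(bold.loc[bold["session"] == session, "c_bold_rad"].mean()),
            "tangential": float(bold.loc[bold["session"] == session, "c_bold_tan"].mean()),
        }
        for session in SESSIONS
    }

    # correlation of anisotropy-index changes
    delta_psy = (zpost["a_psy"] - zpre["a_psy"]).dropna()
    bwide = bold.pivot_table(index="subject_id", columns="session", values="a_bold")
    delta_bold = (bwide["post"] - bwide["pre"]).dropna()
    shared = sorted(set(delta_psy.index) & set(delta_bold.index))
    if len(shared) >= 4:
        corr = gs.anisotropy_change_correlation(
            delta_psy.loc[shared], delta_bold.loc[shared]
        )
        out["anisotropy_change_correlation"] = {
            "rs": corr.rs, "n": corr.n, "p": corr.p, "method": corr.method,
        }
        out["delta_a_psy"] = {s: float(delta_psy[s]) for s in shared}
        out["delta_a_bold"] = {s: float(delta_bold[s]) for s in shared}
    return out


def render_report(stats: dict) -> str:
    """Human-readable Markdown report of the full replication run."""

    def fmt_t(d: dict) -> str:
        if d.get("undefined"):
            return "undefined (zero-variance differences)"
        return f"t({d['df']}) = {d['t']:.3f}, p = {d['p']:.4g}"

    def fmt_anova(effects: dict) -> list[str]:
        lines = []
        for name, e in effects.items():
            if e.get("undefined"):
                lines.append(f"- {name}: undefined (zero error variance)")
            else:
                lines.append(
                    f"- {name}: F({e['df_num']}, {e['df_den']}) = {e['f']:.3f}, "
                    f"p = {e['p']:.4g}"
                )
        return lines

    lines = ["# Crowding training replication report", ""]
    lines += ["## Behavioral training (day-by-day critical spacing)", ""]
    for axis, by_day in stats["day_means"].items():
        series = ", ".join(f"day {d}: {v:.3f} deg" for d, v in by_day.items())
        lines.append(f"- {axis}: {series}")
    lines += [
        "",
        f"- radial-tangential ratio: pre {stats['mean_ratio_pre']:.3f} -> "
        f"post {stats['mean_ratio_post']:.3f} ({fmt_t(stats['paired_t_ratio'])})",
        f"- A_psy pre vs post: {fmt_t(stats['paired_t_a_psy'])}",
    ]
    if "anova_axis_by_day" in stats:
        lines += ["", "### 2 x day repeated-measures ANOVA (critical spacing)", ""]
        lines += fmt_anova(stats["anova_axis_by_day"])
    for key, label in (
        ("paired_t_radial_day1_vs_day4", "radial day 1 vs day 4"),
        ("paired_t_tangential_day1_vs_day4", "tangential day 1 vs day 4"),
    ):
        if key in stats:
            lines.append(f"- paired t, {label}: {fmt_t(stats[key])}")

    lines += ["", "## BOLD percent signal change", ""]
    for session, by_cond in stats["mean_psc"].items():
        vals = ", ".join(f"{c}: {v:.3f}" for c, v in by_cond.items())
        lines.append(f"- {session}: {vals}")
    lines += ["", "### Crowding index C_BOLD (present - absent)", ""]
    for session, by_axis in stats["mean_cbold"].items():
        lines.append(
            f"- {session}: radial {by_axis['radial']:.3f}, "
            f"tangential {by_axis['tangential']:.3f}"
        )
    for key, label in (
        ("paired_t_cbold_radial", "C_BOLD radial pre vs post"),
        ("paired_t_cbold_tangential", "C_BOLD tangential pre vs post"),
        ("paired_t_a_bold", "A_BOLD pre vs post"),
    ):
        if key in stats:
            lines.append(f"- {label}: {fmt_t(stats[key])}")
    if "anova_axis_by_target_by_session" in stats:
        lines += ["", "### 2 x 2 x 2 repeated-measures ANOVA (PSC)", ""]
        lines += fmt_anova(stats["anova_axis_by_target_by_session"])
    if "anova_cbold_axis_by_session" in stats:
        lines += ["", "### 2 x 2 repeated-measures ANOVA (C_BOLD)", ""]
        lines += fmt_anova(stats["anova_cbold_axis_by_session"])

    if "anisotropy_change_correlation" in stats:
        c = stats["anisotropy_change_correlation"]
        lines += [
            "",
            "## Anisotropy-change correlation",
            "",
            f"- Spearman rs = {c['rs']:.3f}, n = {c['n']}, p = {c['p']:.4g} "
            f"({c['method']})",
        ]
    lines.append("")
    return "\n".join(lines)
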