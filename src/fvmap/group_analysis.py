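"""Group-level statistics for longitudinal modulus studies.

One value per eye per tissue class (the typical modulus) enters:

* one-way fixed-effects ANOVA across duration-of-elevated-IOP groups,
* Fisher's least-significant-difference (LSD) pairwise post hoc tests —
  pairwise t tests on the ANOVA's pooled mean squared error, uncorrected for
  multiplicity by definition,
* Spearman rank correlation of typical modulus with duration (midrank ties,
  p from the t approximation t = r*sqrt((n-2)/(1-r^2))),
* percent decreases relative to the week-0 reference group,
  100 * (1 - E_t / E_0) on group means.

All tests are two-sided with significance at 0.05. ``study_report`` /
:class:`IOPDurationStudy` aggregate these per tissue class and eye side into
a JSON-serializable report, a Markdown rendering, and box/strip figures.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "LsdResult",
    "SpearmanResult",
    "PercentChange",
    "ZeroVarianceError",
    "one_way_anova",
    "lsd_posthoc",
    "spearman",
    "percent_change",
    "study_report",
    "IOPDurationStudy",
    "StudyResults",
]

ALPHA = 0.05


class ZeroVarianceError(RuntimeError):
    """All observations identical: the F statistic is 0/0-undefined."""


def _select(
    table: pd.DataFrame, tissue_class: Optional[str], side: Optional[str]
) -> pd.DataFrame:
    t = table
    if tissue_class is not None:
        t = t[t["tissue_class"] == tissue_class]
    if side is not None:
        t = t[t["side"] == side]
    if t.empty:
        raise ValueError(f"no rows for class={tissue_class!r}, side={side!r}")
    return t


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_means: dict
    group_sizes: dict
    mse_within: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def one_way_anova(
    table: pd.DataFrame,
    tissue_class: Optional[str] = None,
    side: Optional[str] = None,
    value_col: str = "typical_pa",
    group_col: str = "week",
) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA from sums of squares."""
    t = _select(table, tissue_class, side)
    groups = {k: np.asarray(v, dtype=float) for k, v in t.groupby(group_col)[value_col]}
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    for k, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    all_vals = np.concatenate(list(groups.values()))
    n_total = all_vals.size
    grand = all_vals.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(float(np.sum((v - v.mean()) ** 2)) for v in groups.values())
    df_b = len(groups) - 1
    df_w = n_total - len(groups)
    if ss_within == 0.0 and ss_between == 0.0:
        raise ZeroVarianceError("zero_variance: all observations identical")
    mse = ss_within / df_w
    if mse == 0.0:
        f = float("inf")
        p = 0.0
    else:
        f = (ss_between / df_b) / mse
        p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(
        f_statistic=float(f),
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        group_means={k: float(v.mean()) for k, v in groups.items()},
        group_sizes={k: int(v.size) for k, v in groups.items()},
        mse_within=float(mse),
    )


@dataclass
class LsdResult:
    """All pairwise LSD comparisons (uncorrected by definition)."""

    pairs: list  # (group_a, group_b, mean_diff, t, p, significant)
    df: int
    mse_within: float


def lsd_posthoc(anova: AnovaResult) -> LsdResult:
    """Fisher's LSD pairwise t tests using the ANOVA's pooled MSE.

    t = (mean_a - mean_b) / sqrt(MSE * (1/n_a + 1/n_b)), df = ANOVA's
    within-group df, two-sided p. No multiplicity correction is applied —
    that is the definition of the LSD procedure.
    """
    pairs = []
    for a, b in itertools.combinations(sorted(anova.group_means), 2):
        diff = anova.group_means[a] - anova.group_means[b]
        se = np.sqrt(anova.mse_within * (1.0 / anova.group_sizes[a] + 1.0 / anova.group_sizes[b]))
        if se == 0.0:
            t = 0.0 if diff == 0 else float("inf") * np.sign(diff)
        else:
            t = diff / se
        p = float(2.0 * stats.t.sf(abs(t), anova.df_within))
        pairs.append((a, b, float(diff), float(t), p, p < ALPHA))
    return LsdResult(pairs=pairs, df=anova.df_within, mse_within=anova.mse_within)


@dataclass
class SpearmanResult:
    r: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def spearman(
    table: pd.DataFrame,
    tissue_class: Optional[str] = None,
    side: Optional[str] = None,
    value_col: str = "typical_pa",
    x_col: str = "week",
) -> SpearmanResult:
    """Spearman rank correlation of typical modulus with IOP duration."""
    t = _select(table, tissue_class, side)
    x = t[x_col].to_numpy(dtype=float)
    y = t[value_col].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("Spearman correlation needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("zero_variance: a variable is constant")
    r, p = stats.spearmanr(x, y)
    return SpearmanResult(r=float(r), p_value=float(p), n=int(x.size))


@dataclass
class PercentChange:
    reference_group: object
    comparison_group: object
    tissue_class: str
    percent_decrease: float  # 100 * (1 - E_t / E_0) on group means


def percent_change(
    table: pd.DataFrame,
    tissue_class: str,
    side: str = "experimental",
    reference_week: int = 0,
    value_col: str = "typical_pa",
    group_col: str = "week",
) -> list[PercentChange]:
    """Percent decrease of each group's mean typical modulus vs the reference."""
    t = _select(table, tissue_class, side)
    means = t.groupby(group_col)[value_col].mean()
    if reference_week not in means.index:
        raise ValueError(f"reference group (week {reference_week}) missing")
    ref = means[reference_week]
    if ref <= 0:
        raise ValueError("reference mean modulus must be positive")
    out = []
    for wk, m in means.items():
        if wk == reference_week:
            continue
        out.append(
            PercentChange(
                reference_group=reference_week,
                comparison_group=wk,
                tissue_class=tissue_class,
                percent_decrease=float(100.0 * (1.0 - m / ref)),
            )
        )
    return out


def _anova_block(table, tissue_class, side, group_col: str = "week") -> dict:
    try:
        an = one_way_anova(table, tissue_class, side, group_col=group_col)
    except ZeroVarianceError:
        return {"outcome": "zero_variance"}
    except ValueError as exc:
        return {"outcome": "not_computed", "reason": str(exc)}
    lsd = lsd_posthoc(an)
    return {
        "outcome": "ok",
        "f": an.f_statistic,
        "df": [an.df_between, an.df_within],
        "p": an.p_value,
        "significant": an.significant,
        "group_means_pa": {str(k): v for k, v in an.group_means.items()},
        "group_sizes": {str(k): v for k, v in an.group_sizes.items()},
        "mse_within": an.mse_within,
        "lsd_pairs": [
            {
                "a": str(a),
                "b": str(b),
                "mean_diff_pa": d,
                "t": t,
                "p": p,
                "significant": sig,
            }
            for a, b, d, t, p, sig in lsd.pairs
        ],
        "lsd_note": "LSD pairwise p values are uncorrected for multiplicity by definition",
    }


def _spearman_block(table, tissue_class, side) -> dict:
    try:
        sp = spearman(table, tissue_class, side)
    except (ZeroVarianceError, ValueError) as exc:
        return {"outcome": "not_computed", "reason": str(exc)}
    return {"outcome": "ok", "r": sp.r, "p": sp.p_value, "n": sp.n, "significant": sp.significant}


def study_report(table: pd.DataFrame, out_dir=None, make_figures: bool = False) -> dict:
    """Full statistical report for a study table.

    Per tissue class: experimental-eye ANOVA + LSD across weeks, the same for
    contralateral eyes (both as their own week groups and pooled against the
    week-0 experimental controls), Spearman correlation per side, percent
    decreases vs week 0, and — when a drug-control arm is present — the
    two-group comparison of drug-control vs untreated week-0 eyes. Optionally
    writes ``report.json``, ``report.md`` and figures under ``out_dir``.
    """
    report: dict = {"classes": {}, "n_rows": int(len(table))}
    has_contra = (table["side"] == "contralateral").any()
    has_drug = (table["arm"] == "drug_control").any()
    model_table = table[table["arm"] != "drug_control"]

    for cls in sorted(table["tissue_class"].unique()):
        block: dict = {}
        block["experimental_anova"] = _anova_block(model_table, cls, "experimental")
        block["experimental_spearman"] = _spearman_block(model_table, cls, "experimental")
        block["percent_decrease_vs_week0"] = {
            str(pc.comparison_group): pc.percent_decrease
            for pc in percent_change(model_table, cls, side="experimental")
        }
        if has_contra:
            block["contralateral_anova"] = _anova_block(model_table, cls, "contralateral")
            block["contralateral_spearman"] = _spearman_block(model_table, cls, "contralateral")
            # alternative reading: contralateral weeks vs week-0 experimental controls
            contra_plus_ref = pd.concat(
                [
                    _select(model_table, cls, "contralateral"),
                    _select(model_table[model_table["week"] == 0], cls, "experimental"),
                ]
            )
            block["contralateral_vs_week0_anova"] = _anova_block(contra_plus_ref, None, None)
        if has_drug:
            week0 = table[(table["week"] == 0) & (table["tissue_class"] == cls)]
            blank = week0[week0["arm"] == "blank"]
            drug = week0[week0["arm"] == "drug_control"]
            if len(blank) >= 2 and len(drug) >= 2:
                block["drug_control_vs_blank"] = _anova_block(
                    pd.concat([blank, drug]), None, None, group_col="arm"
                )
        report["classes"][cls] = block

    if out_dir is not None:
        from . import io as _io

        _io.save_report(report, out_dir, table if make_figures else None)
    return report


def _render_markdown(report: dict) -> str:
    lines = ["# Longitudinal modulus study report", ""]
    for cls, block in report["classes"].items():
        lines.append(f"## Tissue class: {cls}")
        for key, val in block.items():
            lines.append(f"### {key}")
            if key == "percent_decrease_vs_week0":
                for wk, pc in val.items():
                    lines.append(f"- week {wk}: {pc:.1f} % decrease vs week 0")
            elif isinstance(val, dict) and val.get("outcome") == "ok":
                if "f" in val:
                    lines.append(
                        f"- F({val['df'][0]}, {val['df'][1]}) = {val['f']:.3f}, "
                        f"p = {val['p']:.3g} ({'significant' if val['significant'] else 'n.s.'})"
                    )
                    for pr in val.get("lsd_pairs", []):
                        star = "*" if pr["significant"] else " "
                        lines.append(
                            f"  - LSD {pr['a']} vs {pr['b']}: t = {pr['t']:.2f}, p = {pr['p']:.3g} {star}"
                        )
                if "r" in val:
                    lines.append(
                        f"- Spearman r = {val['r']:.3f}, p = {val['p']:.3g}, n = {val['n']}"
                    )
            else:
                lines.append(f"- {val.get('outcome', val)}")
            lines.append("")
    return "\n".join(lines)


@dataclass
class StudyResults:
    """Fitted study-level statistics with a printable summary."""

    report: dict
    table: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> str:
        return _render_markdown(self.report)


class IOPDurationStudy:
    """Model object for modulus-versus-IOP-duration group statistics.

    Wraps the study table; ``fit()`` computes all ANOVA/LSD/Spearman/percent-
    change blocks and returns a :class:`StudyResults`.
    """

    def __init__(self, table: pd.DataFrame) -> None:
        required = {"eye_id", "week", "side", "arm", "tissue_class", "typical_pa"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"study table missing columns: {sorted(missing)}")
        self.table = table

    @classmethod
    def from_records(cls, records) -> "IOPDurationStudy":
        from .modulus_summary import build_study_table

        return cls(build_study_table(records))

    def fit(self) -> StudyResults:
        return StudyResults(report=study_report(self.table), table=self.table)
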