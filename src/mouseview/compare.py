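"""Paired channel comparisons across scenes: sign tests and rank-sum tests.

Scenes are grouped by camera elevation into upper ("up") and lower ("down")
visual-field categories; horizontal scenes are excluded from hypothesis
tests (but kept for intensity profiles).  Per-scene parameters (Weibull
beta/gamma per filter width, power-law slope/intercept per direction,
autocorrelation at representative offsets) are compared between the UV and
green channels with an exact two-sided sign test on the per-scene
differences; the left/right chromatic-contrast Weibull parameters are
compared with a two-sided Wilcoxon rank-sum (Mann–Whitney) test.

Significance stars follow the usual convention: * p < 0.05, ** p < 0.01,
*** p < 0.001 (strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SceneStats",
    "ParamTable",
    "TestResult",
    "stars_for",
    "paired_sign_test",
    "ranksum_test",
    "build_param_table",
    "default_plan",
    "run_comparisons",
]

CATEGORIES = ("up", "down")


def stars_for(p_value: float) -> str:
    if p_value < 0.001:
        return "⋆⋆⋆"
    if p_value < 0.01:
        return "⋆⋆"
    if p_value < 0.05:
        return "⋆"
    return ""


@dataclass
class SceneStats:
    """Per-scene bundle of computed statistics.

    ``params`` maps (group, parameter) -> value, where group is a channel
    ("UV"/"Green") or a chromatic side ("left"/"right").
    """

    scene: str
    category: str
    params: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass(frozen=True)
class TestResult:
    parameter: str
    category: str
    test: str  # "sign" or "ranksum"
    n: int
    statistic: float
    p_value: float
    stars: str = ""
    n_ties_dropped: int = 0
    underpowered: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


@dataclass
class ParamTable:
    """Long-format (scene, category, group, parameter, value) table."""

    data: pd.DataFrame
    n_excluded_horizontal: int = 0

    def values_for(self, parameter: str, category: str, group: str) -> pd.Series:
        sel = self.data[
            (self.data["parameter"] == parameter)
            & (self.data["category"] == category)
            & (self.data["group"] == group)
        ]
        return sel.set_index("scene")["value"]


def paired_sign_test(
    values_uv: Sequence[float],
    values_green: Sequence[float],
    parameter: str = "",
    category: str = "",
) -> TestResult:
    """Exact two-sided sign test on per-scene UV - Green differences.

    The test statistic is the number of positive differences; exact zeros
    are dropped (classical sign test) and counted.  Fewer than 5 nonzero
    pairs flags the result as underpowered.
    """
    a = np.asarray(values_uv, dtype=float)
    b = np.asarray(values_green, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired value lists must be equal-length 1-D sequences")
    diff = a - b
    ties = int(np.count_nonzero(diff == 0))
    diff = diff[diff != 0]
    n = diff.size
    k = int(np.count_nonzero(diff > 0))
    if n == 0:
        return TestResult(
            parameter, category, "sign", 0, 0.0, 1.0,
            n_ties_dropped=ties, underpowered=True, note="all pairs tied",
        )
    p = stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue
    return TestResult(
        parameter, category, "sign", n, float(k), float(p),
        stars=stars_for(p), n_ties_dropped=ties, underpowered=n < 5,
    )


def ranksum_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    parameter: str = "",
    category: str = "",
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    Exact enumeration when both groups have <= 10 values and no ties;
    otherwise the normal approximation with tie correction and continuity
    correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 values")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 10 and b.size <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    return TestResult(
        parameter, category, "ranksum", int(a.size + b.size),
        float(res.statistic), p, stars=stars_for(p), note=f"method={method}",
    )


def build_param_table(scene_stats: Iterable[SceneStats]) -> ParamTable:
    """Assemble the long-format comparison table, restricted to up/down.

    Horizontal scenes are excluded (and counted), mirroring the study's
    exclusion of horizontal-elevation images from the channel comparisons.
    Scenes without a category and duplicate (scene, group, parameter) rows
    are errors.
    """
    rows = []
    n_horizontal = 0
    missing = []
    for s in scene_stats:
        if not s.category:
            missing.append(s.scene)
            continue
        if s.category == "horizontal":
            n_horizontal += 1
            continue
        if s.category not in CATEGORIES:
            raise ValueError(f"scene {s.scene!r}: unknown category {s.category!r}")
        for (group, parameter), value in s.params.items():
            rows.append(
                {
                    "scene": s.scene,
                    "category": s.category,
                    "group": group,
                    "parameter": parameter,
                    "value": value,
                }
            )
    if missing:
        raise ValueError(f"scenes missing category metadata: {missing}")
    df = pd.DataFrame(rows, columns=["scene", "category", "group", "parameter", "value"])
    if len(df) and df.duplicated(["scene", "group", "parameter"]).any():
        dup = df[df.duplicated(["scene", "group", "parameter"], keep=False)]
        raise ValueError(
            "duplicate (scene, group, parameter) rows: "
            f"{sorted(set(dup['scene']))}"
        )
    return ParamTable(df, n_excluded_horizontal=n_horizontal)


def default_plan(
    sigmas: Iterable[float] = (5, 10, 20, 40),
    acf_offsets: Iterable[tuple[int, int]] = ((50, 0), (0, 50)),
) -> list[dict]:
    """The standard comparison plan.

    Sign tests (UV vs Green, paired by scene): Weibull beta and gamma per
    LoG width, power-law slope a and intercept b per direction, RMS-contrast
    median, and R at the representative autocorrelation offsets.  Rank-sum
    tests (left vs right side): chromatic-contrast Weibull beta and gamma.
    """
    plan: list[dict] = []
    for s in sigmas:
        plan.append({"parameter": f"weibull_beta_sigma{s:g}", "test": "sign"})
        plan.append({"parameter": f"weibull_gamma_sigma{s:g}", "test": "sign"})
    for direction in ("horizontal", "vertical"):
        plan.append({"parameter": f"powerlaw_a_{direction}", "test": "sign"})
        plan.append({"parameter": f"powerlaw_b_{direction}", "test": "sign"})
    plan.append({"parameter": "rms_contrast_median", "test": "sign"})
    for d_h, d_v in acf_offsets:
        plan.append({"parameter": f"acf_r_{d_h}_{d_v}", "test": "sign"})
    plan.append({"parameter": "chromatic_beta", "test": "ranksum"})
    plan.append({"parameter": "chromatic_gamma", "test": "ranksum"})
    return plan


def run_comparisons(table: ParamTable, plan: Sequence[dict]) -> list[TestResult]:
    """Run the planned tests per category; absent parameters are skipped.

    Sign-test entries pair UV vs Green values scene by scene; rank-sum
    entries compare the "left" vs "right" groups.  Skipped parameters are
    reported as zero-n results with a note rather than raised.
    """
    results: list[TestResult] = []
    present = set(table.data["parameter"]) if len(table.data) else set()
    for entry in plan:
        param = entry["parameter"]
        test = entry["test"]
        for category in CATEGORIES:
            if param not in present:
                results.append(
                    TestResult(param, category, test, 0, 0.0, 1.0,
                               note="skipped: parameter absent")
                )
                continue
            if test == "sign":
                uv = table.values_for(param, category, "UV")
                green = table.values_for(param, category, "Green")
                common = uv.index.intersection(green.index)
                if len(common) == 0:
                    results.append(
                        TestResult(param, category, test, 0, 0.0, 1.0,
                                   note="skipped: no paired scenes")
                    )
                    continue
                results.append(
                    paired_sign_test(
                        uv.loc[common].to_numpy(), green.loc[common].to_numpy(),
                        parameter=param, category=category,
                    )
                )
            elif test == "ranksum":
                left = table.values_for(param, category, "left").to_numpy()
                right = table.values_for(param, category, "right").to_numpy()
                if left.size < 2 or right.size < 2:
                    results.append(
                        TestResult(param, category, test, int(left.size + right.size),
                                   0.0, 1.0, note="skipped: group too small")
                    )
                    continue
                results.append(
                    ranksum_test(left, right, parameter=param, category=category)
                )
            else:
                raise ValueError(f"unknown test {test!r}")
    return results


def results_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    """Tabulate TestResults for CSV export / reporting."""
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "category": r.category,
                "test": r.test,
                "n": r.n,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "stars": r.stars,
                "ties_dropped": r.n_ties_dropped,
                "underpowered": r.underpowered,
                "note": r.note,
            }
            for r in results
        ]
    )
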