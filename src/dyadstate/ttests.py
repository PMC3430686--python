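"""Paired-comparison battery on behavioural session summaries.

Two-tailed paired t-tests throughout: within-pair initiation asymmetries
(bolder vs shyer member, or focal vs partner), and pre/post-satiation
contrasts of time-out proportions and trip counts.  Counts are tested
untransformed; a Holm adjustment helper is available but off by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "paired_t_test",
    "initiation_asymmetry_tests",
    "pre_post_tests",
    "battery_records",
]

#: smallest positive subnormal double; reported when the difference variance
#: collapses to zero around a nonzero mean
_P_FLOOR = 5e-324


@dataclass
class TestResult:
    """A two-tailed paired t-test: t statistic, df = n - 1, p, mean difference."""

    t: float
    df: int
    p: float
    mean_diff: float
    n: int
    zero_variance: bool = False

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-tailed paired t-test of ``x`` versus ``y``.

    t = mean(d) / (sd(d) / sqrt(n)) with d = x - y and the n-1 denominator
    in sd; p is the two-sided tail of Student's t with n - 1 df.  A zero
    difference variance with nonzero mean yields ``p`` at the machine floor
    with ``zero_variance`` flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return TestResult(t=0.0, df=df, p=1.0, mean_diff=0.0, n=n)
        return TestResult(
            t=math.copysign(math.inf, mean),
            df=df,
            p=_P_FLOOR,
            mean_diff=mean,
            n=n,
            zero_variance=True,
        )
    t = mean / (sd / math.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult(t=t, df=df, p=p, mean_diff=mean, n=n)


def _category_of_pairs(sessions: pd.DataFrame) -> pd.Series:
    return sessions.groupby("pair_id")["category"].first()


def _pivot_counts(
    summaries: pd.DataFrame, session: str, column: str
) -> pd.DataFrame:
    """(pair_id x fish) table of ``column`` for one session label."""
    sub = summaries[summaries["session"] == session]
    return sub.pivot_table(
        index="pair_id", columns="fish", values=column, aggfunc="first"
    )


def initiation_asymmetry_tests(
    summaries: pd.DataFrame,
    sessions: pd.DataFrame,
    session: str = "control",
    framing: str = "bolder_vs_shyer",
) -> dict[str, TestResult]:
    """Per-category paired t-tests of within-pair joint-initiation counts.

    ``framing="bolder_vs_shyer"`` compares the bolder member's count against
    the shyer member's (ties broken toward the focal fish);
    ``framing="focal_vs_partner"`` compares focal against partner.  A
    category with fewer than 2 complete pairs raises.
    """
    if framing not in ("bolder_vs_shyer", "focal_vs_partner"):
        raise ValueError("framing must be 'bolder_vs_shyer' or 'focal_vs_partner'")
    counts = _pivot_counts(summaries, session, "n_joint_initiations")
    bold = sessions.groupby("pair_id")[["focal_boldness", "partner_boldness"]].first()
    categories = _category_of_pairs(sessions)
    results: dict[str, TestResult] = {}
    for cat, pair_ids in categories.groupby(categories).groups.items():
        pair_ids = [p for p in pair_ids if p in counts.index]
        if len(pair_ids) < 2:
            raise ValueError(f"category {cat}: fewer than 2 pairs with data")
        x, y = [], []
        for pid in pair_ids:
            focal_n = counts.loc[pid, "focal"]
            partner_n = counts.loc[pid, "partner"]
            if framing == "focal_vs_partner":
                x.append(focal_n)
                y.append(partner_n)
            else:
                focal_bolder = (
                    bold.loc[pid, "focal_boldness"] >= bold.loc[pid, "partner_boldness"]
                )
                x.append(focal_n if focal_bolder else partner_n)
                y.append(partner_n if focal_bolder else focal_n)
        results[str(cat)] = paired_t_test(x, y)
    return results


def pre_post_tests(
    summaries: pd.DataFrame,
    sessions: pd.DataFrame,
    metric: str = "n_trips",
    fish: str = "focal",
    control_label: str = "control",
    satiated_label: str = "satiated",
) -> dict[str, TestResult]:
    """Per-category paired t-tests of a metric before vs after satiation.

    Positive ``mean_diff`` means the metric was higher in the control
    session.  Pairs missing either session are dropped listwise with a
    logged warning.
    """
    if fish not in ("focal", "partner"):
        raise ValueError("fish must be 'focal' or 'partner'")
    if metric not in summaries.columns:
        raise ValueError(f"metric {metric!r} not in summaries")
    pre = _pivot_counts(summaries, control_label, metric)
    post = _pivot_counts(summaries, satiated_label, metric)
    categories = _category_of_pairs(sessions)
    results: dict[str, TestResult] = {}
    for cat, pair_ids in categories.groupby(categories).groups.items():
        x, y = [], []
        for pid in pair_ids:
            ok = (
                pid in pre.index
                and pid in post.index
                and not pd.isna(pre.loc[pid, fish])
                and not pd.isna(post.loc[pid, fish])
            )
            if not ok:
                logger.warning("dropping pair %s (%s): missing session", pid, cat)
                continue
            x.append(float(pre.loc[pid, fish]))
            y.append(float(post.loc[pid, fish]))
        if len(x) < 2:
            raise ValueError(f"category {cat}: fewer than 2 complete pairs")
        results[str(cat)] = paired_t_test(x, y)
    return results


def battery_records(
    summaries: pd.DataFrame, sessions: pd.DataFrame
) -> list[dict]:
    """Run the full comparison battery; one CSV-ready record per test.

    Comparisons: joint-initiation asymmetry (bolder vs shyer) in each
    session, plus pre/post-satiation contrasts of ``prop_time_out`` and
    ``n_trips`` for each fish.
    """
    rows: list[dict] = []

    def add(comparison: str, metric: str, fish: str, per_cat: Mapping[str, TestResult]):
        for cat, r in per_cat.items():
            rows.append(
                {
                    "category": cat,
                    "comparison": comparison,
                    "metric": metric,
                    "fish": fish,
                    "n": r.n,
                    "t": r.t,
                    "df": r.df,
                    "p": r.p,
                    "mean_diff": r.mean_diff,
                }
            )

    # pre-satiation asymmetry is framed bolder-vs-shyer; post-satiation is
    # framed focal-vs-partner (the satiated fish against the unfed one)
    for session, framing in (("control", "bolder_vs_shyer"), ("satiated", "focal_vs_partner")):
        if (summaries["session"] == session).any():
            add(
                f"asymmetry_{session}",
                "n_joint_initiations",
                framing,
                initiation_asymmetry_tests(
                    summaries, sessions, session=session, framing=framing
                ),
            )
    for metric in ("prop_time_out", "n_trips"):
        for fish in ("focal", "partner"):
            add(
                "pre_post",
                metric,
                fish,
                pre_post_tests(summaries, sessions, metric=metric, fish=fish),
            )
    return rows
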