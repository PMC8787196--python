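"""Pairwise group comparisons with Holm multiple-comparison correction.

For every unordered pair of groups and every one of the 42 action
transitions, per-fly transition probabilities are compared with

* a two-sided Wilcoxon rank-sum test (location: do the groups differ in
  typical transition probability?), and
* a Brown-Forsythe/Levene test centered at the median (variability: do
  the groups differ in spread?).

Bout-duration distributions are compared per action with a two-sample
Kolmogorov-Smirnov test on pooled durations. Each table is corrected as
one family with Holm's step-down method, so a 5-group, 42-transition
analysis is a single family of 420 comparisons.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ethogram import LABELS, LABEL_INDEX
from .features import SyntaxVector, TRANSITION_PAIRS

logger = logging.getLogger("groomsyntax")

ALPHA = 0.05
N_TRANSITION_FEATURES = len(TRANSITION_PAIRS)  # 42

COLUMNS = [
    "group_a", "group_b", "feature_id", "test_name",
    "statistic", "p_raw", "p_adjusted", "significant",
]


def comparison_count(n_groups: int, n_features: int = N_TRANSITION_FEATURES) -> int:
    """Number of pairwise comparisons: C(n_groups, 2) * n_features."""
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    return math.comb(n_groups, 2) * n_features


def holm_adjust(p: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in input order.

    Sort ascending; adjusted_(k) = max_{j<=k} (m-j+1) * p_(j), capped at 1.
    NaN entries (untestable rows) are passed through and do not count
    toward the family size.
    """
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    adj = np.minimum(1.0, np.maximum.accumulate((m - np.arange(m)) * pv[order]))
    restored = np.empty(m)
    restored[order] = adj
    out[valid] = restored
    return out


def _finish_table(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=COLUMNS[:-2])
    df["p_adjusted"] = holm_adjust(df["p_raw"].to_numpy())
    df["significant"] = df["p_adjusted"] < ALPHA
    return df


def _check_groups(groups: Mapping[str, Sequence], min_size: int = 2) -> list[str]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, members in groups.items():
        if len(members) < min_size:
            raise ValueError(f"group {name!r} has fewer than {min_size} flies")
    return sorted(groups)


def _transition_samples(
    syns: Sequence[SyntaxVector], src: str, dst: str
) -> np.ndarray:
    """Per-fly probabilities for one transition, excluding flies whose
    source action was never observed."""
    i, j = LABEL_INDEX[src], LABEL_INDEX[dst]
    return np.array([s.probs[i, j] for s in syns if s.observed[i]])


def _rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # Exact null distribution for small samples, normal approximation with
    # tie correction otherwise.
    method = "exact" if max(len(x), len(y)) <= 10 else "asymptotic"
    try:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    except ValueError:  # exact method refuses ties: fall back
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def pairwise_location_tests(
    groups: Mapping[str, Sequence[SyntaxVector]]
) -> pd.DataFrame:
    """Rank-sum tests on per-fly transition probabilities, all group pairs
    x all 42 transitions, Holm-corrected as one family."""
    names = _check_groups(groups)
    rows = []
    excluded = 0
    for ga, gb in itertools.combinations(names, 2):
        for src, dst in TRANSITION_PAIRS:
            xa = _transition_samples(groups[ga], src, dst)
            xb = _transition_samples(groups[gb], src, dst)
            excluded += (len(groups[ga]) - len(xa)) + (len(groups[gb]) - len(xb))
            feature = f"{src}->{dst}"
            if len(xa) < 2 or len(xb) < 2 or (np.ptp(np.concatenate([xa, xb])) == 0):
                stat, p = 0.0, 1.0 if len(xa) >= 2 and len(xb) >= 2 else np.nan
            else:
                stat, p = _rank_sum(xa, xb)
            rows.append(dict(group_a=ga, group_b=gb, feature_id=feature,
                             test_name="ranksum", statistic=stat, p_raw=p))
    if excluded:
        logger.info("location tests: %d fly-transition samples excluded (missing source)",
                    excluded)
    return _finish_table(rows)


def pairwise_variance_tests(
    groups: Mapping[str, Sequence[SyntaxVector]]
) -> pd.DataFrame:
    """Brown-Forsythe (median-centered Levene) tests on per-fly transition
    probabilities: does within-group variability differ between groups?"""
    names = _check_groups(groups)
    rows = []
    for ga, gb in itertools.combinations(names, 2):
        for src, dst in TRANSITION_PAIRS:
            xa = _transition_samples(groups[ga], src, dst)
            xb = _transition_samples(groups[gb], src, dst)
            feature = f"{src}->{dst}"
            if (len(xa) < 2 or len(xb) < 2
                    or (np.ptp(xa) == 0 and np.ptp(xb) == 0)):
                # constant samples: no variability difference to detect
                stat, p = 0.0, 1.0 if len(xa) >= 2 and len(xb) >= 2 else np.nan
            else:
                with np.errstate(divide="ignore", invalid="ignore"):
                    res = stats.levene(xa, xb, center="median")
                stat, p = float(res.statistic), float(res.pvalue)
                if math.isnan(p):
                    stat, p = 0.0, 1.0
            rows.append(dict(group_a=ga, group_b=gb, feature_id=feature,
                             test_name="levene_median", statistic=stat, p_raw=p))
    return _finish_table(rows)


def duration_ks_tests(
    groups: Mapping[str, Mapping[str, Sequence[float]]]
) -> pd.DataFrame:
    """Two-sample KS tests on pooled per-action bout durations.

    ``groups`` maps group -> action -> pooled duration samples. Actions
    with an empty sample in either group yield an untestable row
    (p_raw = NaN) that does not enter the Holm family.
    """
    names = _check_groups(groups, min_size=1)
    rows = []
    for ga, gb in itertools.combinations(names, 2):
        for action in LABELS:
            xa = np.asarray(groups[ga].get(action, []), dtype=float)
            xb = np.asarray(groups[gb].get(action, []), dtype=float)
            if len(xa) == 0 or len(xb) == 0:
                stat, p = np.nan, np.nan
            else:
                res = stats.ks_2samp(xa, xb)
                stat, p = float(res.statistic), float(res.pvalue)
            rows.append(dict(group_a=ga, group_b=gb, feature_id=action,
                             test_name="ks_2samp", statistic=stat, p_raw=p))
    return _finish_table(rows)


def significant_fraction(table: pd.DataFrame) -> float:
    """Fraction of testable rows flagged significant after Holm."""
    testable = table["p_raw"].notna()
    if testable.sum() == 0:
        return float("nan")
    return float(table.loc[testable, "significant"].mean())
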