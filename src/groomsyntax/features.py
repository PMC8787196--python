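"""Behavioral feature families extracted from ethograms.

Four per-fly summaries of a grooming recording:

* **action proportions** — fraction of frames spent in each of the 7
  actions (plus a grooming/walking/standing triplet for ternary-style
  summaries);
* **progression vector** — the 7 proportions recomputed in 10
  non-overlapping windows (2.78 min each for a 27.78-min recording),
  flattened to 70 entries; captures the anterior-to-posterior progression;
* **syntax vector** — first-order transition probabilities between bouts
  (self-transitions impossible by run-length encoding), 42 entries;
* **duration histograms** — per-action normalized histograms of bout
  durations, 20 equal-width bins per action with bin width set separately
  for grooming and non-grooming actions (140 entries).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ethogram import (
    ANTERIOR,
    DEFAULT_CUTOFF_S,
    Bout,
    Ethogram,
    GROOMING,
    LABELS,
    LABEL_INDEX,
    N_ACTIONS,
    to_bouts,
)

N_TRANSITIONS = N_ACTIONS * (N_ACTIONS - 1)  # 42
DEFAULT_N_WINDOWS = 10
DEFAULT_N_BINS = 20

#: (source, target) pairs indexing the 42-dimensional syntax vector.
TRANSITION_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (s, t) for s in LABELS for t in LABELS if s != t
)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class ProportionVector:
    p: np.ndarray  # (7,) fractions summing to 1, LABELS order

    @property
    def triplet(self) -> np.ndarray:
        """(grooming, walking, standing) aggregate for ternary plots."""
        g = sum(self.p[LABEL_INDEX[a]] for a in GROOMING)
        return np.array([g, self.p[LABEL_INDEX["Wk"]], self.p[LABEL_INDEX["S"]]])

    def __getitem__(self, code: str) -> float:
        return float(self.p[LABEL_INDEX[code]])


@dataclass
class ProgressionVector:
    w: np.ndarray  # (n_windows, 7); each row sums to 1

    @property
    def values(self) -> np.ndarray:
        return self.w.ravel()


@dataclass
class SyntaxVector:
    """Bout-level first-order transition probabilities.

    ``observed[i]`` is False for source actions never seen to transition;
    their outgoing probabilities are all zero and downstream consumers
    must honor the mask (tests exclude such flies per-transition;
    classification imputes per policy).
    """

    counts: np.ndarray  # (7, 7) int, zero diagonal
    probs: np.ndarray  # (7, 7), rows sum to 1 where observed
    source_totals: np.ndarray  # (7,) outgoing transition counts
    observed: np.ndarray  # (7,) bool

    @property
    def values(self) -> np.ndarray:
        """The 42 off-diagonal probabilities in TRANSITION_PAIRS order."""
        return np.array([
            self.probs[LABEL_INDEX[s], LABEL_INDEX[t]] for s, t in TRANSITION_PAIRS
        ])

    def get(self, src: str, dst: str) -> float:
        return float(self.probs[LABEL_INDEX[src], LABEL_INDEX[dst]])


@dataclass
class DurationHistogram:
    h: np.ndarray  # (7, n_bins); rows sum to 1 where the action occurs
    bin_edges: dict  # category -> (n_bins+1,) edges in seconds
    occurs: np.ndarray  # (7,) bool

    @property
    def values(self) -> np.ndarray:
        return self.h.ravel()


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def action_proportions(e: Ethogram) -> ProportionVector:
    """Fraction of frames spent in each action."""
    p = np.array([(e.labels == a).mean() for a in LABELS])
    return ProportionVector(p=p)


def progression_vector(e: Ethogram, n_windows: int = DEFAULT_N_WINDOWS) -> ProgressionVector:
    """Per-window action proportions over equal contiguous windows.

    Remainder frames (when n_frames is not a multiple of ``n_windows``)
    go to the last window.
    """
    n = e.n_frames
    if n < n_windows:
        raise ValueError(f"need at least {n_windows} frames, got {n}")
    size = n // n_windows
    rows = np.empty((n_windows, N_ACTIONS))
    for k in range(n_windows):
        lo = k * size
        hi = (k + 1) * size if k < n_windows - 1 else n
        chunk = e.labels[lo:hi]
        rows[k] = [(chunk == a).mean() for a in LABELS]
    return ProgressionVector(w=rows)


def syntax_vector(bouts: Sequence[Bout]) -> SyntaxVector:
    """First-order bout-transition probabilities (the grooming syntax).

    Counts consecutive bout pairs; run-length encoding guarantees no
    self-transitions, so the representation is 42-dimensional.
    """
    counts = np.zeros((N_ACTIONS, N_ACTIONS), dtype=int)
    if len(bouts) < 2:
        warnings.warn("fewer than 2 bouts: syntax is all-missing", stacklevel=2)
    else:
        for a, b in zip(bouts[:-1], bouts[1:]):
            counts[LABEL_INDEX[a.action], LABEL_INDEX[b.action]] += 1
    totals = counts.sum(axis=1)
    observed = totals > 0
    probs = np.zeros_like(counts, dtype=float)
    probs[observed] = counts[observed] / totals[observed, None]
    return SyntaxVector(counts=counts, probs=probs, source_totals=totals, observed=observed)


def empirical_transition_matrix(e: Ethogram) -> np.ndarray:
    """Convenience: bout-level transition probability matrix of an ethogram."""
    return syntax_vector(to_bouts(e)).probs


def cohort_category_max(bout_lists: Iterable[Sequence[Bout]]) -> dict[str, float]:
    """Pooled maximum bout duration per category (grooming / non-grooming)."""
    gmax, ngmax = 0.0, 0.0
    for bouts in bout_lists:
        for b in bouts:
            if b.action in GROOMING:
                gmax = max(gmax, b.duration_s)
            else:
                ngmax = max(ngmax, b.duration_s)
    return {"grooming": gmax, "non_grooming": ngmax}


def duration_histograms(
    bouts: Sequence[Bout],
    n_bins: int = DEFAULT_N_BINS,
    category_max: dict | None = None,
    cutoff_s: float = DEFAULT_CUTOFF_S,
) -> DurationHistogram:
    """Normalized per-action bout-duration histograms.

    Bin width is equal within a category and chosen independently for
    grooming and non-grooming actions (walking and standing have
    longer-tailed duration distributions). Bins span
    ``[cutoff_s, category_max]``; by default the maximum is taken from the
    bouts supplied, but a cohort-pooled maximum (see
    :func:`cohort_category_max`) can be passed for cross-fly
    comparability. Actions that never occur get a zero row and an
    ``occurs`` flag of False.
    """
    if category_max is None:
        category_max = cohort_category_max([bouts])
    edges = {}
    for cat in ("grooming", "non_grooming"):
        hi = max(float(category_max.get(cat, 0.0)), cutoff_s)
        if hi <= cutoff_s:
            hi = cutoff_s + 1.0  # degenerate: no bouts in this category
        edges[cat] = np.linspace(cutoff_s, hi, n_bins + 1)

    h = np.zeros((N_ACTIONS, n_bins))
    occurs = np.zeros(N_ACTIONS, dtype=bool)
    durs: dict[str, list[float]] = {a: [] for a in LABELS}
    for b in bouts:
        durs[b.action].append(b.duration_s)
    for a in LABELS:
        i = LABEL_INDEX[a]
        if not durs[a]:
            continue
        occurs[i] = True
        cat = "grooming" if a in GROOMING else "non_grooming"
        e = edges[cat]
        vals = np.clip(durs[a], e[0], e[-1])
        counts, _ = np.histogram(vals, bins=e)
        h[i] = counts / counts.sum()
    return DurationHistogram(h=h, bin_edges=edges, occurs=occurs)


def grooming_half_time(e: Ethogram) -> float:
    """Time (s) at which a fly completes 50% of its total grooming.

    Returns NaN (with a warning) when the fly never grooms.
    """
    is_groom = np.isin(e.labels, list(GROOMING))
    total = int(is_groom.sum())
    if total == 0:
        warnings.warn(f"fly {e.fly_id!r} has no grooming frames", stacklevel=2)
        return float("nan")
    cum = np.cumsum(is_groom)
    idx = int(np.searchsorted(cum, 0.5 * total))
    return idx / e.frame_rate_hz


def anterior_proportion(e: Ethogram, lo_frac: float = 0.0, hi_frac: float = 1.0) -> float:
    """Fraction of frames in the anterior motif within a slice of the recording."""
    n = e.n_frames
    chunk = e.labels[int(lo_frac * n):int(hi_frac * n)]
    return float(np.isin(chunk, list(ANTERIOR)).mean())


# ---------------------------------------------------------------------------
# Cohort feature tables
# ---------------------------------------------------------------------------

FEATURE_FAMILIES = (
    "proportions", "progression", "syntax", "durations", "non_grooming_only", "full",
)


def proportion_feature_names() -> list[str]:
    return [f"prop_{a}" for a in LABELS]


def progression_feature_names(n_windows: int = DEFAULT_N_WINDOWS) -> list[str]:
    return [f"prog_w{k + 1}_{a}" for k in range(n_windows) for a in LABELS]


def syntax_feature_names() -> list[str]:
    return [f"syn_{s}_to_{t}" for s, t in TRANSITION_PAIRS]


def duration_feature_names(n_bins: int = DEFAULT_N_BINS) -> list[str]:
    return [f"dur_{a}_bin{k + 1}" for a in LABELS for k in range(n_bins)]


def feature_table(
    ethograms: Sequence[Ethogram],
    family: str = "syntax",
    impute: str = "zero",
) -> pd.DataFrame:
    """Wide per-fly feature table for a cohort (one row per fly).

    ``family`` is one of proportions | progression | syntax | durations |
    non_grooming_only | full. Duration bins use the cohort-pooled
    per-category maximum. Missing syntax sources are imputed with zeros
    by default (``impute='uniform'`` spreads 1/6 over each missing row).
    Index is fly_id; group_id and session_id ride along as columns.
    """
    if family not in FEATURE_FAMILIES:
        raise ValueError(f"unknown feature family {family!r}; choose from {FEATURE_FAMILIES}")
    bout_lists = [to_bouts(e) for e in ethograms]
    cat_max = cohort_category_max(bout_lists)

    blocks: dict[str, list[np.ndarray]] = {}
    for e, bouts in zip(ethograms, bout_lists):
        row: dict[str, np.ndarray] = {}
        row["proportions"] = action_proportions(e).p
        row["progression"] = progression_vector(e).values
        syn = syntax_vector(bouts)
        v = syn.values
        if impute == "uniform":
            for i, (s, _) in enumerate(TRANSITION_PAIRS):
                if not syn.observed[LABEL_INDEX[s]]:
                    v[i] = 1.0 / (N_ACTIONS - 1)
        row["syntax"] = v
        row["durations"] = duration_histograms(bouts, category_max=cat_max).values
        for k, val in row.items():
            blocks.setdefault(k, []).append(val)

    names: list[str]
    if family == "non_grooming_only":
        prop = pd.DataFrame(blocks["proportions"], columns=proportion_feature_names())
        prog = pd.DataFrame(blocks["progression"], columns=progression_feature_names())
        cols = [c for c in prop.columns if c.endswith(("_Wk", "_S"))]
        pcols = [c for c in prog.columns if c.endswith(("_Wk", "_S"))]
        df = pd.concat([prop[cols], prog[pcols]], axis=1)
    elif family == "full":
        df = pd.concat(
            [
                pd.DataFrame(blocks["proportions"], columns=proportion_feature_names()),
                pd.DataFrame(blocks["progression"], columns=progression_feature_names()),
                pd.DataFrame(blocks["syntax"], columns=syntax_feature_names()),
                pd.DataFrame(blocks["durations"], columns=duration_feature_names()),
            ],
            axis=1,
        )
    else:
        names = {
            "proportions": proportion_feature_names(),
            "progression": progression_feature_names(),
            "syntax": syntax_feature_names(),
            "durations": duration_feature_names(),
        }[family]
        df = pd.DataFrame(blocks[family], columns=names)

    df.insert(0, "session_id", [e.session_id for e in ethograms])
    df.insert(0, "group_id", [e.group_id for e in ethograms])
    df.index = pd.Index([e.fly_id for e in ethograms], name="fly_id")
    return df
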