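"""Stereotypy metrics: syntax entropy rate and motif edit distance.

Two complementary notions of how stereotyped grooming is:

* **rule level** — the entropy rate of the bout-transition Markov chain.
  Zero means completely stereotyped (every observed source has a
  deterministic successor); ln 6 is the maximum for 7 states with
  self-transitions excluded. Natural logarithm throughout, so
  exp(-H) is the probability of correctly predicting the next action:
  H = 1 nat corresponds to ~37% predictability.

* **sequence level** — Levenshtein edit distance between anterior motif
  runs (continuous F/H stretches), normalized by the longer sequence
  length. This is far stricter than entropy: two flies can share
  identical transition rules yet realize entirely different sequences.
  The protocol compares the first continuous anterior run lasting at
  least 30 s, within flies across consecutive sessions or between flies
  within a session.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np
import pandas as pd

from .ethogram import ANTERIOR, Ethogram, N_ACTIONS, to_bouts
from .features import SyntaxVector, syntax_vector

logger = logging.getLogger("groomsyntax")

MAX_ENTROPY_NATS = math.log(N_ACTIONS - 1)  # ln 6
DEFAULT_MIN_RUN_S = 30.0

# edlib works on plain strings; collapse the two-character walking code.
_CHAR = {"F": "F", "H": "H", "A": "A", "B": "B", "W": "W", "Wk": "K", "S": "S"}


# ---------------------------------------------------------------------------
# Entropy rate
# ---------------------------------------------------------------------------


@dataclass
class EntropyResult:
    H: float  # nats
    weights: np.ndarray  # (7,) per-source weights, zero for unobserved

    @property
    def predictability(self) -> float:
        """exp(-H): probability of correctly guessing the next action."""
        return math.exp(-self.H)


def entropy_rate(syn: SyntaxVector, weighting: str = "source_frequency") -> EntropyResult:
    """Entropy rate of the syntax chain, H = -sum_i w_i sum_j p_ij ln p_ij.

    ``weighting`` chooses the per-source weights w_i:

    * ``source_frequency`` (default) — each observed source weighted by
      its share of outgoing transitions;
    * ``stationary`` — the stationary distribution of the observed
      transition matrix (falls back to source frequencies when the
      restricted chain is not well-posed).

    0*ln(0) is taken as 0. Raises on all-missing syntax.
    """
    if not syn.observed.any():
        raise ValueError("cannot compute entropy rate: no observed transitions")
    if weighting == "source_frequency":
        w = syn.source_totals / syn.source_totals.sum()
    elif weighting == "stationary":
        w = _stationary_weights(syn)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    P = syn.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    row_H = -plogp.sum(axis=1)
    return EntropyResult(H=float(np.dot(w, row_H)), weights=w)


def _stationary_weights(syn: SyntaxVector) -> np.ndarray:
    obs = np.flatnonzero(syn.observed)
    P = syn.probs[np.ix_(obs, obs)]
    sums = P.sum(axis=1)
    if (sums <= 0).any():
        logger.warning("stationary weighting ill-posed; falling back to source frequencies")
        return syn.source_totals / syn.source_totals.sum()
    P = P / sums[:, None]
    # Cesaro-averaged power iteration: robust to periodic chains.
    v = np.full(len(obs), 1.0 / len(obs))
    acc = np.zeros_like(v)
    for _ in range(500):
        v = v @ P
        acc += v
    acc /= acc.sum()
    w = np.zeros(N_ACTIONS)
    w[obs] = acc
    return w


def per_window_entropy(
    e: Ethogram, windows: Sequence[tuple[float, float]], weighting: str = "source_frequency"
) -> list[EntropyResult]:
    """Entropy rate of the syntax within each (start_s, end_s) window."""
    out = []
    fps = e.frame_rate_hz
    from dataclasses import replace

    for s0, e0 in windows:
        sub = replace(e, labels=e.labels[int(round(s0 * fps)):int(round(e0 * fps))])
        out.append(entropy_rate(syntax_vector(to_bouts(sub)), weighting=weighting))
    return out


# ---------------------------------------------------------------------------
# Anterior motif runs
# ---------------------------------------------------------------------------


@dataclass
class MotifRun:
    """A continuous frame-resolution stretch of anterior grooming (F/H)."""

    symbols: np.ndarray  # frame labels, all in {F, H}
    start_s: float
    duration_s: float
    fly_id: str
    session_id: str


def extract_anterior_run(
    e: Ethogram,
    min_duration_s: float = DEFAULT_MIN_RUN_S,
    within_s: tuple[float, float] | None = None,
    session_id: str | None = None,
) -> MotifRun | None:
    """First maximal run of consecutive anterior (F/H) frames lasting at
    least ``min_duration_s``; None when no run qualifies.

    ``within_s`` restricts the search to a time interval (used for
    optogenetic stimulation windows).
    """
    fps = e.frame_rate_hz
    labels = e.labels
    offset = 0
    if within_s is not None:
        lo, hi = (int(round(t * fps)) for t in within_s)
        labels = labels[lo:hi]
        offset = lo
    mask = np.isin(labels, list(ANTERIOR)).astype(np.int8)
    if mask.sum() == 0:
        return None
    padded = np.concatenate(([0], mask, [0]))
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    need = int(math.ceil(min_duration_s * fps - 1e-9))
    for s, t in zip(starts, ends):
        if t - s >= need:
            return MotifRun(
                symbols=labels[s:t].copy(),
                start_s=(s + offset) / fps,
                duration_s=(t - s) / fps,
                fly_id=e.fly_id,
                session_id=session_id if session_id is not None else e.session_id,
            )
    return None


def extract_window_runs(
    e: Ethogram,
    windows: Sequence[tuple[float, float]],
    min_duration_s: float = DEFAULT_MIN_RUN_S,
) -> list[MotifRun]:
    """One anterior run per stimulation window (skipping windows without a
    qualifying run); runs are tagged act1, act2, ... as pseudo-sessions."""
    runs = []
    for k, w in enumerate(windows, start=1):
        r = extract_anterior_run(e, min_duration_s, within_s=w, session_id=f"act{k}")
        if r is not None:
            runs.append(r)
    return runs


# ---------------------------------------------------------------------------
# Edit distance
# ---------------------------------------------------------------------------


def _as_string(seq) -> str:
    if isinstance(seq, str):
        return "".join(_CHAR.get(c, c) for c in seq)
    return "".join(_CHAR.get(str(c), str(c)) for c in seq)


def edit_distance(a, b) -> int:
    """Levenshtein distance (unit-cost substitutions, insertions,
    deletions) between two symbol sequences."""
    sa, sb = _as_string(a), _as_string(b)
    if not sa or not sb:
        return max(len(sa), len(sb))
    return int(edlib.align(sa, sb, task="distance")["editDistance"])


def normalized_edit_distance(a, b) -> float:
    """Edit distance divided by the longer sequence length, in [0, 1].

    0 for identical sequences; 1 for maximally different ones (an edit
    distance equal to the total sequence length).
    """
    sa, sb = _as_string(a), _as_string(b)
    m = max(len(sa), len(sb))
    if m == 0:
        raise ValueError("normalized edit distance undefined for two empty sequences")
    return edit_distance(sa, sb) / m


# ---------------------------------------------------------------------------
# Comparison protocols
# ---------------------------------------------------------------------------

DESIGNS = ("within_fly_across_sessions", "between_fly_same_session")


def pairwise_run_distances(runs: Sequence[MotifRun], design: str) -> pd.DataFrame:
    """Normalized edit distances between anterior runs under a design.

    * ``within_fly_across_sessions`` — for each fly, compare runs from
      consecutive sessions (sessions ordered by id);
    * ``between_fly_same_session`` — compare runs of distinct flies
      within each fly's earliest session (all pairs).
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; choose from {DESIGNS}")
    pairs: list[tuple[MotifRun, MotifRun]] = []
    if design == "within_fly_across_sessions":
        by_fly: dict[str, list[MotifRun]] = {}
        for r in runs:
            by_fly.setdefault(r.fly_id, []).append(r)
        for fly, rs in sorted(by_fly.items()):
            rs = sorted(rs, key=lambda r: r.session_id)
            pairs.extend(zip(rs[:-1], rs[1:]))
    else:
        first: dict[str, MotifRun] = {}
        for r in runs:
            if r.fly_id not in first or r.session_id < first[r.fly_id].session_id:
                first[r.fly_id] = r
        pairs.extend(itertools.combinations(
            [first[f] for f in sorted(first)], 2))
    if not pairs:
        raise ValueError(f"no eligible run pairs under design {design!r}")
    rows = [
        {
            "fly_a": a.fly_id, "session_a": a.session_id,
            "fly_b": b.fly_id, "session_b": b.session_id,
            "len_a": len(a.symbols), "len_b": len(b.symbols),
            "normalized_distance": normalized_edit_distance(a.symbols, b.symbols),
        }
        for a, b in pairs
    ]
    return pd.DataFrame(rows)


def summarize_distances(table: pd.DataFrame) -> dict:
    """Minimum and median percent difference across eligible pairs."""
    d = table["normalized_distance"].to_numpy()
    return {
        "n_pairs": int(len(d)),
        "min_percent": float(100.0 * d.min()),
        "median_percent": float(100.0 * np.median(d)),
    }


def stereotypy_comparison(
    ethograms: Sequence[Ethogram],
    design: str,
    min_duration_s: float = DEFAULT_MIN_RUN_S,
) -> tuple[pd.DataFrame, dict]:
    """Full protocol: extract the first qualifying anterior run per
    recording, pair runs per the design, and summarize percent
    differences. Flies without a qualifying run are skipped (count
    logged)."""
    runs = []
    skipped = 0
    for e in ethograms:
        r = extract_anterior_run(e, min_duration_s)
        if r is None:
            skipped += 1
        else:
            runs.append(r)
    if skipped:
        logger.info("stereotypy_comparison: %d/%d recordings had no anterior run >= %gs",
                    skipped, len(ethograms), min_duration_s)
    table = pairwise_run_distances(runs, design)
    return table, summarize_distances(table)
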