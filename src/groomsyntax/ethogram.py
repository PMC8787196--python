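"""Behavioral alphabet, ethogram and bout containers, file I/O, denoising.

An ethogram is a frame-by-frame categorical record of what a fly is doing,
here over a seven-action alphabet: five grooming actions — front leg
cleaning (F), head grooming (H), abdomen grooming (A), back leg cleaning
(B), wing grooming (W) — and two non-grooming actions, walking (Wk) and
standing (S). F and H form the anterior grooming motif (performed with the
front legs); A, B and W form the posterior motif. Recordings are sampled at
30 Hz by default.

Before any analysis, ethograms are denoised: grooming bouts shorter than
one complete leg sweep (150 ms by default) are treated as classifier
glitches and absorbed into the preceding bout.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("groomsyntax")

# ---------------------------------------------------------------------------
# Alphabet
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ActionLabel:
    """One behavioral state: its code, grooming category and motif."""

    code: str
    category: str  # "grooming" | "non_grooming"
    motif: str  # "anterior" | "posterior" | "none"


ACTIONS: tuple[ActionLabel, ...] = (
    ActionLabel("F", "grooming", "anterior"),
    ActionLabel("H", "grooming", "anterior"),
    ActionLabel("A", "grooming", "posterior"),
    ActionLabel("B", "grooming", "posterior"),
    ActionLabel("W", "grooming", "posterior"),
    ActionLabel("Wk", "non_grooming", "none"),
    ActionLabel("S", "non_grooming", "none"),
)

LABELS: tuple[str, ...] = tuple(a.code for a in ACTIONS)
LABEL_INDEX: dict[str, int] = {a.code: i for i, a in enumerate(ACTIONS)}
N_ACTIONS = len(ACTIONS)

GROOMING: frozenset[str] = frozenset(a.code for a in ACTIONS if a.category == "grooming")
NON_GROOMING: frozenset[str] = frozenset(a.code for a in ACTIONS if a.category == "non_grooming")
ANTERIOR: frozenset[str] = frozenset(a.code for a in ACTIONS if a.motif == "anterior")
POSTERIOR: frozenset[str] = frozenset(a.code for a in ACTIONS if a.motif == "posterior")

#: Default denoising cutoff: the approximate duration of one complete leg
#: sweep. Grooming bouts shorter than this are eliminated.
DEFAULT_CUTOFF_S = 0.150

#: Default video frame rate (Hz).
DEFAULT_FRAME_RATE = 30.0

#: Default recording length in frames (27.78 min at 30 Hz).
DEFAULT_RECORDING_FRAMES = 50_000


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class Ethogram:
    """A single fly's frame-resolution behavioral record plus metadata."""

    labels: np.ndarray  # 1-D array of label codes (str)
    fly_id: str = "fly0"
    group_id: str = "group0"
    session_id: str = "s0"
    frame_rate_hz: float = DEFAULT_FRAME_RATE
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="<U2")
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("ethogram labels must be a non-empty 1-D sequence")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        bad = set(np.unique(self.labels)) - set(LABELS)
        if bad:
            raise ValueError(f"unknown label code(s): {sorted(bad)}")

    @property
    def n_frames(self) -> int:
        return int(self.labels.size)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    @property
    def label_indices(self) -> np.ndarray:
        """Labels as integer indices into :data:`ACTIONS`."""
        idx = np.empty(self.labels.size, dtype=np.int8)
        for code, i in LABEL_INDEX.items():
            idx[self.labels == code] = i
        return idx

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Ethogram):
            return NotImplemented
        return (
            self.fly_id == other.fly_id
            and self.group_id == other.group_id
            and self.session_id == other.session_id
            and float(self.frame_rate_hz) == float(other.frame_rate_hz)
            and np.array_equal(self.labels, other.labels)
        )


@dataclass(frozen=True)
class Bout:
    """A maximal run of consecutive frames sharing one action label."""

    action: str
    start_frame: int
    n_frames: int
    duration_s: float

    def __post_init__(self) -> None:
        if self.n_frames <= 0:
            raise ValueError("bout must span at least one frame")
        if self.start_frame < 0:
            raise ValueError("start_frame must be non-negative")


# ---------------------------------------------------------------------------
# Run-length encoding
# ---------------------------------------------------------------------------


def to_bouts(e: Ethogram) -> list[Bout]:
    """Run-length encode an ethogram into bouts.

    The returned bouts tile the recording without gaps or overlaps, and
    consecutive bouts always carry distinct actions.
    """
    labels = e.labels
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [
        Bout(
            action=str(labels[s]),
            start_frame=int(s),
            n_frames=int(n),
            duration_s=float(n / e.frame_rate_hz),
        )
        for s, n in zip(starts, ends - starts)
    ]


def bouts_to_labels(bouts: Sequence[Bout]) -> np.ndarray:
    """Expand bouts back to a frame-resolution label array."""
    return np.concatenate([np.full(b.n_frames, b.action, dtype="<U2") for b in bouts])


# ---------------------------------------------------------------------------
# Denoising
# ---------------------------------------------------------------------------


def denoise(e: Ethogram, min_duration_s: float = DEFAULT_CUTOFF_S) -> Ethogram:
    """Eliminate grooming bouts shorter than ``min_duration_s``.

    A grooming bout must persist for longer than roughly one complete leg
    sweep (150 ms) to be believed; shorter grooming bouts are classifier
    glitches whose frames are absorbed by the preceding bout (the first
    bout, if short, merges rightward instead). Merging is iterative —
    shortest offending bout first, leftmost on ties — and merged bouts are
    re-evaluated, so a glitch splitting one real bout in two is healed
    rather than discarded (e.g. F/H/F with every piece under the cutoff
    collapses to a single, now-valid F bout). Walking and standing bouts
    are left untouched; bouts of exactly the cutoff duration are kept.

    Total frame count is always preserved: frames are relabeled, never
    dropped. The operation is idempotent. A single-bout ethogram below
    the cutoff is returned unchanged with a warning.
    """
    if min_duration_s < 0:
        raise ValueError("min_duration_s must be non-negative")
    fps = e.frame_rate_hz
    min_frames = min_duration_s * fps
    runs: list[list] = [[b.action, b.n_frames] for b in to_bouts(e)]
    removed = 0

    def short_idx() -> int | None:
        best, best_n = None, None
        for i, (a, n) in enumerate(runs):
            if a in GROOMING and n < min_frames and (best_n is None or n < best_n):
                best, best_n = i, n
        return best

    while len(runs) > 1:
        i = short_idx()
        if i is None:
            break
        a, n = runs.pop(i)
        removed += 1
        j = i - 1 if i > 0 else 0  # merge left; first bout merges right
        runs[j][1] += n
        # re-merge neighbors that now share an action
        if 0 < j < len(runs) and runs[j - 1][0] == runs[j][0]:
            runs[j - 1][1] += runs[j][1]
            runs.pop(j)
        elif j + 1 < len(runs) and runs[j][0] == runs[j + 1][0]:
            runs[j][1] += runs[j + 1][1]
            runs.pop(j + 1)

    if len(runs) == 1 and runs[0][0] in GROOMING and runs[0][1] < min_frames:
        warnings.warn(
            f"ethogram {e.fly_id!r}: a single grooming bout shorter than "
            f"{min_duration_s * 1e3:.0f} ms remains; cannot denoise further",
            stacklevel=2,
        )
    if removed:
        logger.debug(
            "denoise: removed %d bouts below %.0f ms for fly %s",
            removed, min_duration_s * 1e3, e.fly_id,
        )
    labels = np.concatenate([np.full(n, a, dtype="<U2") for a, n in runs])
    assert labels.size == e.n_frames
    return replace(e, labels=labels)


# ---------------------------------------------------------------------------
# File I/O — one fly per CSV, `# key: value` header comments
# ---------------------------------------------------------------------------

_META_FIELDS = ("fly_id", "group_id", "session_id", "frame_rate_hz")


def write_ethogram(e: Ethogram, path: str | Path) -> None:
    """Write an ethogram as a two-column CSV (frame_index, label).

    Metadata is stored in ``# key: value`` header comment lines.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        for k in _META_FIELDS:
            fh.write(f"# {k}: {getattr(e, k)}\n")
        for k, v in e.metadata.items():
            fh.write(f"# {k}: {v}\n")
        w = csv.writer(fh)
        w.writerow(["frame_index", "label"])
        w.writerows(enumerate(e.labels))


def read_ethogram(path: str | Path) -> Ethogram:
    """Read an ethogram CSV written by :func:`write_ethogram`.

    Raises ``ValueError`` naming the offending row on unknown label codes,
    and on non-contiguous frame indices.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[tuple[str, str]] = []
    with path.open() as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            if not header_seen:
                header_seen = True  # column header row
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            rows.append((parts[0].strip(), parts[1].strip()))
    if not rows:
        raise ValueError(f"{path}: no data rows")

    labels = np.empty(len(rows), dtype="<U2")
    for i, (frame, label) in enumerate(rows):
        if int(frame) != i:
            raise ValueError(
                f"{path}: non-contiguous frame index {frame!r} at data row {i} "
                "(expected contiguous indices from 0)"
            )
        if label not in LABEL_INDEX:
            raise ValueError(f"{path}: unknown label code {label!r} at data row {i}")
        labels[i] = label

    known = {k: meta.pop(k) for k in list(meta) if k in _META_FIELDS}
    return Ethogram(
        labels=labels,
        fly_id=known.get("fly_id", path.stem),
        group_id=known.get("group_id", "group0"),
        session_id=known.get("session_id", "s0"),
        frame_rate_hz=float(known.get("frame_rate_hz", DEFAULT_FRAME_RATE)),
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# Cohort manifests
# ---------------------------------------------------------------------------


def write_manifest(rows: Iterable[dict], path: str | Path) -> None:
    """Write a cohort manifest TSV (fly_id, group_id, session_id, path, ...)."""
    df = pd.DataFrame(list(rows))
    required = ["fly_id", "group_id", "session_id", "path"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"manifest rows missing column(s): {missing}")
    df.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["fly_id", "group_id", "session_id", "path"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing column(s): {missing}")
    return df


def load_cohort(manifest_path: str | Path) -> list[Ethogram]:
    """Load every ethogram listed in a manifest (paths relative to it)."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    out = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = manifest_path.parent / p
        e = read_ethogram(p)
        e.fly_id, e.group_id, e.session_id = row["fly_id"], row["group_id"], row["session_id"]
        out.append(e)
    return out
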