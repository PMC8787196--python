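"""Semi-Markov ethogram simulator.

Generates synthetic grooming ethograms with the statistical structure the
downstream analysis assumes, so every stage of the pipeline can be
exercised and validated without video-derived data:

* bout-structured sequences with no self-transitions at bout level
  (actions change between consecutive bouts; dwell time within a bout is
  drawn separately, making the process semi-Markov);
* grooming bout-duration distributions peaking between 500 and 750 ms
  (truncated log-normal dwell times; walking and standing heavier-tailed);
* high within-motif transition probabilities (anterior F<->H, posterior
  A/B/W);
* an anterior-then-posterior temporal progression, modeled as a sigmoid
  interpolation in bout-onset time between an early anterior-biased and a
  late posterior-biased transition matrix;
* group-specific matrices via per-transition divergence offsets, and
  per-fly heterogeneity via Dirichlet resampling of matrix rows;
* an optogenetic paradigm in which an anterior-dominant matrix replaces
  the baseline during three 3-minute stimulation windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .ethogram import (
    DEFAULT_CUTOFF_S,
    DEFAULT_FRAME_RATE,
    DEFAULT_RECORDING_FRAMES,
    Ethogram,
    LABELS,
    LABEL_INDEX,
    N_ACTIONS,
)

__all__ = [
    "GeneratorConfig",
    "GroupTemplate",
    "DEFAULT_OPTO_WINDOWS",
    "matrix_from_dict",
    "transition_matrix_at",
    "anterior_dominant_matrix",
    "dust_base_config",
    "opto_config",
    "simulate_ethogram",
    "simulate_population",
    "simulate_individual_sessions",
    "simulate_opto_session",
    "species_templates",
    "stock_templates",
    "variability_templates",
]

#: Three 3-minute stimulation windows (start_s, end_s), as in the
#: optogenetic paradigm the simulator emulates.
DEFAULT_OPTO_WINDOWS: tuple[tuple[float, float], ...] = (
    (180.0, 360.0),
    (660.0, 840.0),
    (1140.0, 1320.0),
)


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------


def matrix_from_dict(rows: Mapping[str, Mapping[str, float]]) -> np.ndarray:
    """Build a row-stochastic 7x7 transition matrix from nested dicts."""
    M = np.zeros((N_ACTIONS, N_ACTIONS))
    for src, targets in rows.items():
        for dst, p in targets.items():
            M[LABEL_INDEX[src], LABEL_INDEX[dst]] = p
    return _normalize_rows(M)


def _normalize_rows(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float).copy()
    np.fill_diagonal(M, 0.0)
    if (M < 0).any():
        raise ValueError("transition matrix has negative entries")
    sums = M.sum(axis=1)
    if (sums <= 0).any():
        bad = [LABELS[i] for i in np.flatnonzero(sums <= 0)]
        raise ValueError(f"degenerate transition matrix: row(s) {bad} have no mass")
    return M / sums[:, None]


def _check_matrix(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.shape != (N_ACTIONS, N_ACTIONS):
        raise ValueError(f"{name} must be {N_ACTIONS}x{N_ACTIONS}")
    if not np.allclose(np.diag(M), 0.0):
        raise ValueError(f"{name} must have a zero diagonal (no self-transitions)")
    if not np.allclose(M.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError(f"{name} rows must sum to 1")
    if (M < 0).any():
        raise ValueError(f"{name} has negative entries")
    return M


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: Log-normal dwell-time parameters (mu, sigma) in log-seconds. Grooming
#: modes sit at 0.6 s (mode = exp(mu - sigma^2)); walking and standing are
#: longer and heavier-tailed.
DEFAULT_DURATION_PARAMS: dict[str, tuple[float, float]] = {
    "F": (math.log(0.6) + 0.45**2, 0.45),
    "H": (math.log(0.6) + 0.45**2, 0.45),
    "A": (math.log(0.6) + 0.45**2, 0.45),
    "B": (math.log(0.6) + 0.45**2, 0.45),
    "W": (math.log(0.6) + 0.45**2, 0.45),
    "Wk": (math.log(1.2) + 0.9**2, 0.9),
    "S": (math.log(1.0) + 1.0**2, 1.0),
}


@dataclass
class GeneratorConfig:
    """Parameters of the semi-Markov ethogram generator.

    ``early_matrix`` governs bout transitions at the start of the
    recording, ``late_matrix`` at the end; at bout onset time *t* the
    effective matrix is the sigmoid-weighted convex combination of the two
    (midpoint ``phase_switch_s``, steepness ``phase_steepness_s``), with
    the diagonal re-zeroed and rows renormalized.
    """

    early_matrix: np.ndarray
    late_matrix: np.ndarray
    phase_switch_s: float = 400.0
    phase_steepness_s: float = 120.0
    duration_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DURATION_PARAMS)
    )
    min_bout_s: float = DEFAULT_CUTOFF_S
    recording_frames: int = DEFAULT_RECORDING_FRAMES
    frame_rate_hz: float = DEFAULT_FRAME_RATE

    def __post_init__(self) -> None:
        self.early_matrix = _check_matrix(self.early_matrix, "early_matrix")
        self.late_matrix = _check_matrix(self.late_matrix, "late_matrix")
        if self.recording_frames < 1:
            raise ValueError("recording_frames must be >= 1")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        missing = set(LABELS) - set(self.duration_params)
        if missing:
            raise ValueError(f"duration_params missing action(s): {sorted(missing)}")
        for a, (_, sigma) in self.duration_params.items():
            if sigma <= 0:
                raise ValueError(f"duration sigma for {a} must be positive")


def transition_matrix_at(cfg: GeneratorConfig, t_s: float) -> np.ndarray:
    """Phase-interpolated transition matrix at bout-onset time ``t_s``."""
    w = 1.0 / (1.0 + math.exp(-(t_s - cfg.phase_switch_s) / cfg.phase_steepness_s))
    return _normalize_rows((1.0 - w) * cfg.early_matrix + w * cfg.late_matrix)


# ---------------------------------------------------------------------------
# Default matrices and configs
# ---------------------------------------------------------------------------


def _early_dust_matrix() -> np.ndarray:
    return matrix_from_dict({
        "F": {"H": 0.75, "A": 0.04, "B": 0.03, "W": 0.03, "Wk": 0.08, "S": 0.07},
        "H": {"F": 0.75, "A": 0.04, "B": 0.03, "W": 0.03, "Wk": 0.08, "S": 0.07},
        "A": {"F": 0.10, "H": 0.10, "B": 0.50, "W": 0.15, "Wk": 0.08, "S": 0.07},
        "B": {"F": 0.10, "H": 0.10, "A": 0.50, "W": 0.15, "Wk": 0.08, "S": 0.07},
        "W": {"F": 0.15, "H": 0.10, "A": 0.30, "B": 0.30, "Wk": 0.08, "S": 0.07},
        "Wk": {"F": 0.30, "H": 0.25, "A": 0.10, "B": 0.10, "W": 0.05, "S": 0.20},
        "S": {"F": 0.30, "H": 0.25, "A": 0.10, "B": 0.10, "W": 0.05, "Wk": 0.20},
    })


def _late_dust_matrix() -> np.ndarray:
    return matrix_from_dict({
        "F": {"H": 0.55, "A": 0.15, "B": 0.10, "W": 0.05, "Wk": 0.08, "S": 0.07},
        "H": {"F": 0.55, "A": 0.15, "B": 0.10, "W": 0.05, "Wk": 0.08, "S": 0.07},
        "A": {"F": 0.05, "H": 0.05, "B": 0.55, "W": 0.20, "Wk": 0.08, "S": 0.07},
        "B": {"F": 0.05, "H": 0.05, "A": 0.50, "W": 0.25, "Wk": 0.08, "S": 0.07},
        "W": {"F": 0.05, "H": 0.05, "A": 0.35, "B": 0.35, "Wk": 0.10, "S": 0.10},
        "Wk": {"F": 0.10, "H": 0.10, "A": 0.25, "B": 0.20, "W": 0.15, "S": 0.20},
        "S": {"F": 0.10, "H": 0.10, "A": 0.25, "B": 0.20, "W": 0.15, "Wk": 0.20},
    })


def anterior_dominant_matrix() -> np.ndarray:
    """Matrix concentrating transition mass on the anterior motif (F<->H).

    Used inside optogenetic stimulation windows: from F nearly all mass
    goes to H and vice versa; every other action funnels straight back
    into the anterior motif.
    """
    base = {"F": 0.4925, "H": 0.4925, "A": 0.006, "B": 0.004, "W": 0.003,
            "Wk": 0.001, "S": 0.001}
    M = np.zeros((N_ACTIONS, N_ACTIONS))
    for src in LABELS:
        row = dict(base)
        if src == "F":
            row["H"] = 0.985
        elif src == "H":
            row["F"] = 0.985
        row.pop(src, None)
        for dst, p in row.items():
            M[LABEL_INDEX[src], LABEL_INDEX[dst]] = p
    return _normalize_rows(M)


def dust_base_config(recording_frames: int = DEFAULT_RECORDING_FRAMES) -> GeneratorConfig:
    """Baseline dust-response configuration: anterior-biased early phase
    giving way to posterior grooming, melanogaster-like motif coupling."""
    return GeneratorConfig(
        early_matrix=_early_dust_matrix(),
        late_matrix=_late_dust_matrix(),
        recording_frames=recording_frames,
    )


def opto_config(recording_frames: int = DEFAULT_RECORDING_FRAMES) -> GeneratorConfig:
    """Baseline config for optogenetic sessions (no dust progression:
    early and late phases are both the early-phase matrix)."""
    M = _early_dust_matrix()
    return GeneratorConfig(
        early_matrix=M, late_matrix=M.copy(), recording_frames=recording_frames
    )


# ---------------------------------------------------------------------------
# Simulation core
# ---------------------------------------------------------------------------


def _dwell_frames(
    rng: np.random.Generator, mu: float, sigma: float, min_s: float, fps: float
) -> int:
    """Draw one dwell time (truncated log-normal, >= min_s) in frames."""
    for _ in range(200):
        d = rng.lognormal(mu, sigma)
        if d >= min_s:
            break
    else:
        d = min_s
    return max(int(math.ceil(d * fps - 1e-9)), 1)


def _simulate_frames(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    matrix_for: "callable",
    boundaries_f: Sequence[int] = (),
) -> np.ndarray:
    """Draw bouts until the recording is full; return frame labels.

    ``matrix_for(t_s)`` supplies the transition matrix in force at a bout
    onset. ``boundaries_f`` are frame positions (regime changes) at which
    a running bout is truncated and the chain re-draws under the new
    regime.
    """
    fps = cfg.frame_rate_hz
    total = cfg.recording_frames
    bounds = sorted(int(b) for b in boundaries_f if 0 < b < total)

    labels = np.empty(total, dtype="<U2")
    pos = 0
    P = matrix_for(0.0)
    # Initial action: one Markov step from a uniform start, so the first
    # bout already respects the matrix's support.
    p0 = np.full(N_ACTIONS, 1.0 / N_ACTIONS) @ P
    current = int(rng.choice(N_ACTIONS, p=p0))
    while pos < total:
        mu, sigma = cfg.duration_params[LABELS[current]]
        n = _dwell_frames(rng, mu, sigma, cfg.min_bout_s, fps)
        nxt_bound = next((b for b in bounds if pos < b), total)
        n = min(n, total - pos, nxt_bound - pos)
        labels[pos:pos + n] = LABELS[current]
        pos += n
        if pos >= total:
            break
        P = matrix_for(pos / fps)
        current = int(rng.choice(N_ACTIONS, p=P[current]))
    return labels


def simulate_ethogram(
    cfg: GeneratorConfig,
    seed: int | np.random.SeedSequence,
    fly_id: str = "fly0",
    group_id: str = "group0",
    session_id: str = "s0",
) -> Ethogram:
    """Simulate one semi-Markov ethogram under the two-phase dust model.

    Deterministic for a given (config, seed); output length is exactly
    ``cfg.recording_frames``.
    """
    rng = np.random.default_rng(seed)
    labels = _simulate_frames(cfg, rng, lambda t: transition_matrix_at(cfg, t))
    return Ethogram(
        labels=labels,
        fly_id=fly_id,
        group_id=group_id,
        session_id=session_id,
        frame_rate_hz=cfg.frame_rate_hz,
    )


def simulate_opto_session(
    cfg: GeneratorConfig,
    windows: Sequence[tuple[float, float]] | None = DEFAULT_OPTO_WINDOWS,
    seed: int | np.random.SeedSequence = 0,
    anterior_matrix: np.ndarray | None = None,
    fly_id: str = "fly0",
    group_id: str = "opto",
    session_id: str = "s0",
) -> Ethogram:
    """Simulate an optogenetic session: inside each stimulation window the
    transition matrix is replaced by an anterior-dominant one.

    Bouts are truncated at window boundaries (stimulation onset/offset
    interrupts ongoing behavior). With an empty window list this is
    identical in distribution to :func:`simulate_ethogram`.
    """
    windows = tuple(windows or ())
    fps = cfg.frame_rate_hz
    total_s = cfg.recording_frames / fps
    ws = sorted(windows)
    for (s0, e0), (s1, _) in zip(ws, ws[1:]):
        if s1 < e0:
            raise ValueError(f"overlapping stimulation windows: ({s0},{e0}) and onset {s1}")
    for s0, e0 in ws:
        if s0 < 0 or e0 > total_s or e0 <= s0:
            raise ValueError(f"window ({s0},{e0}) outside recording [0,{total_s:.2f}]")

    A = anterior_dominant_matrix() if anterior_matrix is None else _check_matrix(
        np.asarray(anterior_matrix), "anterior_matrix"
    )

    def matrix_for(t_s: float) -> np.ndarray:
        for s0, e0 in ws:
            if s0 <= t_s < e0:
                return A
        return transition_matrix_at(cfg, t_s)

    bounds = [int(round(t * fps)) for w in ws for t in w]
    rng = np.random.default_rng(seed)
    labels = _simulate_frames(cfg, rng, matrix_for, boundaries_f=bounds)
    meta = {"stim_windows": ";".join(f"{s0:g}-{e0:g}" for s0, e0 in ws)}
    return Ethogram(
        labels=labels, fly_id=fly_id, group_id=group_id,
        session_id=session_id, frame_rate_hz=fps, metadata=meta,
    )


# ---------------------------------------------------------------------------
# Group templates and populations
# ---------------------------------------------------------------------------


@dataclass
class GroupTemplate:
    """A named group: base config + per-transition divergence offsets and
    a Dirichlet jitter concentration for per-fly heterogeneity.

    ``divergence`` maps (source, target) label pairs to additive offsets;
    offset rows are clipped at zero and renormalized, so group matrices
    stay row-stochastic with a zero diagonal. ``jitter_concentration`` is
    the Dirichlet precision used to resample each fly's matrix rows around
    the group matrix (higher = milder jitter; ``None`` disables jitter).
    """

    name: str
    config: GeneratorConfig
    divergence: dict[tuple[str, str], float] = field(default_factory=dict)
    jitter_concentration: float | None = 150.0

    def group_config(self) -> GeneratorConfig:
        """Config with divergence offsets applied to both phase matrices."""
        return replace(
            self.config,
            early_matrix=apply_divergence(self.config.early_matrix, self.divergence),
            late_matrix=apply_divergence(self.config.late_matrix, self.divergence),
        )


def apply_divergence(
    matrix: np.ndarray, divergence: Mapping[tuple[str, str], float]
) -> np.ndarray:
    M = np.asarray(matrix, dtype=float).copy()
    for (src, dst), off in divergence.items():
        if src == dst:
            raise ValueError("divergence on a self-transition is meaningless")
        M[LABEL_INDEX[src], LABEL_INDEX[dst]] += off
    return _normalize_rows(np.clip(M, 0.0, None))


def jitter_matrix(
    matrix: np.ndarray, concentration: float, rng: np.random.Generator
) -> np.ndarray:
    """Resample each row from Dirichlet(concentration * row) on its support."""
    M = np.asarray(matrix, dtype=float).copy()
    for i in range(M.shape[0]):
        support = np.flatnonzero(M[i] > 0)
        M[i, support] = rng.dirichlet(concentration * M[i, support])
    return _normalize_rows(M)


def _fly_config(
    template: GroupTemplate, rng: np.random.Generator
) -> GeneratorConfig:
    cfg = template.group_config()
    if template.jitter_concentration is None:
        return cfg
    k = float(template.jitter_concentration)
    return replace(
        cfg,
        early_matrix=jitter_matrix(cfg.early_matrix, k, rng),
        late_matrix=jitter_matrix(cfg.late_matrix, k, rng),
    )


def simulate_population(
    template: GroupTemplate,
    n: int,
    seed: int | np.random.SeedSequence,
    session_id: str = "s0",
) -> list[Ethogram]:
    """Simulate ``n`` independent flies from a group template.

    Each fly gets its own jittered matrix (if jitter is enabled) and an
    independent stream; outputs are reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    out = []
    for i, child in enumerate(ss.spawn(n)):
        rng = np.random.default_rng(child)
        cfg = _fly_config(template, rng)
        labels = _simulate_frames(cfg, rng, lambda t: transition_matrix_at(cfg, t))
        out.append(Ethogram(
            labels=labels,
            fly_id=f"{template.name}_f{i:02d}",
            group_id=template.name,
            session_id=session_id,
            frame_rate_hz=cfg.frame_rate_hz,
        ))
    return out


def simulate_individual_sessions(
    template: GroupTemplate,
    n_flies: int,
    n_sessions: int,
    seed: int | np.random.SeedSequence,
) -> list[Ethogram]:
    """Simulate the same flies over consecutive sessions (days).

    Each fly keeps one jittered matrix across sessions; sequence
    realizations differ between days, emulating repeated dusting of the
    same individuals.
    """
    if n_flies < 1 or n_sessions < 1:
        raise ValueError("n_flies and n_sessions must be >= 1")
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    out = []
    for i, fly_ss in enumerate(ss.spawn(n_flies)):
        cfg_rng_ss, *day_ss = fly_ss.spawn(n_sessions + 1)
        cfg = _fly_config(template, np.random.default_rng(cfg_rng_ss))
        for d, child in enumerate(day_ss, start=1):
            rng = np.random.default_rng(child)
            labels = _simulate_frames(cfg, rng, lambda t: transition_matrix_at(cfg, t))
            out.append(Ethogram(
                labels=labels,
                fly_id=f"{template.name}_f{i:02d}",
                group_id=template.name,
                session_id=f"day{d}",
                frame_rate_hz=cfg.frame_rate_hz,
            ))
    return out


# ---------------------------------------------------------------------------
# Named presets
# ---------------------------------------------------------------------------


def species_templates(
    recording_frames: int = DEFAULT_RECORDING_FRAMES,
) -> list[GroupTemplate]:
    """Five templates with species-scale syntax divergence, strongest in
    within-motif coupling (anterior coupling highest in the base,
    melanogaster-like group)."""
    base = dust_base_config(recording_frames)
    # Anterior (F<->H) coupling strongest in the melanogaster-like base
    # group; each template differs from every other by >= 0.15 on at least
    # one within-motif transition. Offsets are balanced within each row
    # (mass removed from the motif target is parked on named alternatives)
    # so renormalization does not wash the divergence out.
    divs: list[dict[tuple[str, str], float]] = [
        {},
        {("F", "H"): -0.15, ("F", "Wk"): 0.075, ("F", "S"): 0.075,
         ("H", "F"): -0.15, ("H", "Wk"): 0.075, ("H", "S"): 0.075},
        {("F", "H"): -0.30, ("F", "A"): 0.10, ("F", "Wk"): 0.10, ("F", "S"): 0.10,
         ("H", "F"): -0.30, ("H", "A"): 0.10, ("H", "Wk"): 0.10, ("H", "S"): 0.10},
        {("A", "B"): -0.20, ("A", "F"): 0.10, ("A", "Wk"): 0.10,
         ("B", "A"): -0.20, ("B", "F"): 0.10, ("B", "Wk"): 0.10},
        {("F", "H"): -0.15, ("F", "W"): 0.15,
         ("H", "F"): -0.15, ("H", "W"): 0.15,
         ("A", "B"): -0.20, ("A", "W"): 0.20,
         ("B", "A"): -0.20, ("B", "W"): 0.20},
    ]
    names = ["melanogaster-like", "species-b", "species-c", "species-d", "species-e"]
    return [
        GroupTemplate(name=nm, config=base, divergence=dv) for nm, dv in zip(names, divs)
    ]


def stock_templates(
    recording_frames: int = DEFAULT_RECORDING_FRAMES,
) -> list[GroupTemplate]:
    """Four templates differing mostly in activity level: each stock adds
    increasing mass on transitions into walking."""
    base = dust_base_config(recording_frames)
    names = ["stock-cs", "stock-or", "stock-bk", "stock-w"]
    # Mass moved onto walking is taken from each source's dominant motif
    # target, keeping rows stochastic without renormalization distortion.
    donor = {"F": "H", "H": "F", "A": "B", "B": "A", "W": "A"}
    out = []
    for i, nm in enumerate(names):
        d = 0.06 * i
        dv: dict[tuple[str, str], float] = {}
        for src, tgt in donor.items():
            dv[(src, "Wk")] = d
            dv[(src, tgt)] = -d
        dv[("S", "Wk")] = d
        dv[("S", "F")] = -d / 2
        dv[("S", "H")] = -d / 2
        out.append(GroupTemplate(name=nm, config=base, divergence=dv))
    return out


def variability_templates(
    recording_frames: int = DEFAULT_RECORDING_FRAMES,
) -> list[GroupTemplate]:
    """Four groups sharing one matrix but differing in within-group
    heterogeneity: stock-like, interbred (high-jitter, MaxVar-like) and
    two isogenized (low-jitter) groups."""
    base = dust_base_config(recording_frames)
    spec = [("stock-like", 150.0), ("maxvar-like", 25.0),
            ("iso-1", 600.0), ("iso-2", 600.0)]
    return [GroupTemplate(name=nm, config=base, jitter_concentration=k) for nm, k in spec]
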