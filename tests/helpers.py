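"""Independent oracles and small builders shared across tests.

Everything here is deliberately naive (brute force, closed form, direct
construction) and independent of the code paths it checks.
"""

from __future__ import annotations

import numpy as np

from groomsyntax.ethogram import Ethogram, LABELS, LABEL_INDEX, N_ACTIONS
from groomsyntax.features import SyntaxVector


def make_ethogram(codes, frame_rate=30.0, **meta) -> Ethogram:
    """Ethogram from an iterable of label codes (each one frame)."""
    return Ethogram(labels=np.array(list(codes), dtype="<U2"),
                    frame_rate_hz=frame_rate, **meta)


def expand(pairs, frame_rate=30.0, **meta) -> Ethogram:
    """Ethogram from (code, n_frames) run pairs."""
    labels = []
    for code, n in pairs:
        labels.extend([code] * n)
    return make_ethogram(labels, frame_rate=frame_rate, **meta)


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook full-table dynamic-programming Levenshtein distance."""
    n, m = len(a), len(b)
    D = np.zeros((n + 1, m + 1), dtype=int)
    D[:, 0] = np.arange(n + 1)
    D[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i, j] = min(
                D[i - 1, j] + 1,
                D[i, j - 1] + 1,
                D[i - 1, j - 1] + (a[i - 1] != b[j - 1]),
            )
    return int(D[n, m])


def syntax_from_probs(P: np.ndarray, n_per_source: int = 10_000) -> SyntaxVector:
    """SyntaxVector whose empirical probabilities equal P (deterministic
    rounded counts; rows of P must sum to 1 with zero diagonal)."""
    counts = np.rint(np.asarray(P, dtype=float) * n_per_source).astype(int)
    np.fill_diagonal(counts, 0)
    totals = counts.sum(axis=1)
    observed = totals > 0
    probs = np.zeros_like(counts, dtype=float)
    probs[observed] = counts[observed] / totals[observed, None]
    return SyntaxVector(counts=counts, probs=probs,
                        source_totals=totals, observed=observed)


def syntax_from_multinomial(
    P: np.ndarray, n_per_source: int, rng: np.random.Generator
) -> SyntaxVector:
    """SyntaxVector with multinomially sampled counts per source row."""
    counts = np.zeros((N_ACTIONS, N_ACTIONS), dtype=int)
    for i in range(N_ACTIONS):
        counts[i] = rng.multinomial(n_per_source, P[i])
    np.fill_diagonal(counts, 0)
    totals = counts.sum(axis=1)
    observed = totals > 0
    probs = np.zeros_like(counts, dtype=float)
    probs[observed] = counts[observed] / totals[observed, None]
    return SyntaxVector(counts=counts, probs=probs,
                        source_totals=totals, observed=observed)


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (eigen oracle)."""
    vals, vecs = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def truncated_lognormal_mean_frames(
    mu: float, sigma: float, min_s: float, fps: float,
    n: int = 200_000, seed: int = 12345,
) -> float:
    """Monte-Carlo mean of ceil(d * fps) for d ~ LogNormal(mu, sigma)
    truncated below at min_s (rejection, like the generator's dwell law
    but sampled independently)."""
    rng = np.random.default_rng(seed)
    d = rng.lognormal(mu, sigma, size=n)
    d = d[d >= min_s]
    return float(np.ceil(d * fps - 1e-9).mean())
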