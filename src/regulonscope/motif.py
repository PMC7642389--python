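"""EM motif discovery at fixed width, information content, palindrome scoring.

A ZOOPS ("zero or one occurrence per sequence") EM learns a fixed-width PWM
from peak-site sequences, scanning both strands. Each iteration's expected
complete-data likelihood is non-decreasing (asserted). Multi-start with the
best final likelihood kept; fully deterministic under a seed.

Per-position information content against a uniform background is
``2 + sum_b p_b log2 p_b`` bits (0 log 0 = 0), range [0, 2]; the consensus
string upper-cases positions with IC above a threshold (default 1 bit).
Palindromicity is the mean per-position total-variation distance between the
PWM and its reverse complement (0 = perfect palindrome, 1 = maximal).
"""

from __future__ import annotations

import logging

import numpy as np

from .config import RunConfig
from .models import BASES, Genome, MotifReport, Peak, PWM, revcomp

log = logging.getLogger("regulonscope.motif")

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def extract_site_sequences(
    genome: Genome,
    peaks: list[Peak],
    width: int = 20,
    extension: int = 20,
) -> list[str]:
    """Sequence windows around peak summits for motif discovery.

    Each window spans ``width + 2 * extension`` bp centered on the summit
    (the site itself extended by ``extension`` bp at each end); windows
    running off the genome are clipped with a warning.
    """
    half = width // 2 + extension
    out = []
    for p in peaks:
        lo, hi = p.summit - half, p.summit + half
        if lo < 0 or hi > genome.length:
            log.warning("peak %s window clipped at genome boundary", p.peak_id)
            lo, hi = max(0, lo), min(genome.length, hi)
        out.append(genome.sequence[lo:hi])
    return out


def _one_hot(seq: str) -> np.ndarray:
    arr = np.zeros((len(seq), 4))
    for i, b in enumerate(seq):
        arr[i, _BASE_INDEX[b]] = 1.0
    return arr


def em_motif(
    sequences: list[str],
    width: int = 20,
    seed: int = 0,
    n_starts: int = 10,
    max_iter: int = 200,
    tol: float = 1e-6,
    pseudocount: float = 0.25,
    gamma_init: float = 0.8,
) -> PWM:
    """Learn a PWM by ZOOPS EM over both strands.

    Each sequence contains at most one site; the E-step computes posteriors
    over (offset, strand, no-site), the M-step re-estimates base
    probabilities with ``pseudocount`` per base per column and the
    site-occurrence rate gamma. ``n_starts`` restarts are seeded from
    ``seed``; the run with the best final log-likelihood wins.
    """
    sequences = [s.upper() for s in sequences]
    # canonical orientation: both strands are scanned anyway, so choosing the
    # lexicographically smaller of (seq, revcomp) makes the result exactly
    # invariant to reverse-complementing the input
    sequences = [min(s, revcomp(s)) for s in sequences]
    usable = [s for s in sequences if len(s) >= width]
    if not usable:
        raise ValueError(f"all sequences shorter than width {width}")
    bg = np.full(4, 0.25)
    onehots = [_one_hot(s) for s in usable]
    onehots_rc = [_one_hot(revcomp(s)) for s in usable]

    ss = np.random.SeedSequence(seed)
    best: tuple[float, np.ndarray] | None = None
    for child in ss.spawn(n_starts):
        rng = np.random.default_rng(child)
        probs, ll = _em_single(
            onehots, onehots_rc, width, rng, max_iter, tol, pseudocount, gamma_init, bg
        )
        if best is None or ll > best[0]:
            best = (ll, probs)
    assert best is not None
    return PWM(probs=best[1], n_sites=len(usable), background=bg)


def _window_ratios(onehot: np.ndarray, log_ratio: np.ndarray) -> np.ndarray:
    """exp(sum of log(p/bg)) for every offset of the motif along one strand."""
    L, w = onehot.shape[0], log_ratio.shape[1]
    n_off = L - w + 1
    per_pos = onehot @ log_ratio  # (L, w): log ratio if window column k sits here
    scores = np.zeros(n_off)
    for k in range(w):  # diagonal sums
        scores += per_pos[k : k + n_off, k]
    return np.exp(scores)


def _weighted_counts(onehot: np.ndarray, weights: np.ndarray, width: int) -> np.ndarray:
    """Posterior-weighted base counts, summed over offsets: (4, width)."""
    n_off = weights.size
    out = np.empty((4, width))
    for k in range(width):
        out[:, k] = onehot[k : k + n_off].T @ weights
    return out


def _em_single(
    onehots: list[np.ndarray],
    onehots_rc: list[np.ndarray],
    width: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    pseudocount: float,
    gamma: float,
    bg: np.ndarray,
) -> tuple[np.ndarray, float]:
    # init: a random window from a random sequence, heavily smoothed
    si = rng.integers(len(onehots))
    L = onehots[si].shape[0]
    off = rng.integers(L - width + 1)
    window = onehots[si][off : off + width].T  # (4, w)
    probs = (window + 1.0) / (window + 1.0).sum(axis=0, keepdims=True)

    prev_obj = -np.inf
    ll = -np.inf
    for _ in range(max_iter):
        log_ratio = np.log(probs) - np.log(bg)[:, None]  # (4, w)
        new_counts = np.zeros((4, width))
        gamma_acc = 0.0
        ll = 0.0
        for oh, oh_rc in zip(onehots, onehots_rc):
            r_fwd = _window_ratios(oh, log_ratio)
            r_rev = _window_ratios(oh_rc, log_ratio)
            n_off = r_fwd.size
            prior = gamma / (2 * n_off)
            denom = (1.0 - gamma) + prior * (r_fwd.sum() + r_rev.sum())
            ll += np.log(denom) + np.log(bg[0]) * oh.shape[0]
            w_fwd = prior * r_fwd / denom
            w_rev = prior * r_rev / denom
            gamma_acc += w_fwd.sum() + w_rev.sum()
            new_counts += _weighted_counts(oh, w_fwd, width)
            new_counts += _weighted_counts(oh_rc, w_rev, width)
        # With pseudo-counts the M-step maximizes a Dirichlet-penalized
        # likelihood; EM guarantees this objective never decreases.
        obj = ll + pseudocount * np.log(probs).sum()
        assert obj >= prev_obj - 1e-8 * max(1.0, abs(prev_obj)), (
            "EM objective decreased"
        )
        if np.isfinite(prev_obj) and obj - prev_obj < tol:
            prev_obj = obj
            break
        prev_obj = obj
        probs = (new_counts + pseudocount) / (new_counts + pseudocount).sum(
            axis=0, keepdims=True
        )
        gamma = min(0.99, max(0.01, gamma_acc / len(onehots)))
    return probs, ll


def information_content(pwm: PWM) -> np.ndarray:
    """Per-position IC in bits against a uniform background; 0 log 0 = 0."""
    p = pwm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return 2.0 + plogp.sum(axis=0)


def consensus_string(pwm: PWM, ic_threshold: float = 1.0) -> str:
    """Most-probable base per position, upper-case iff IC > threshold.

    Ties on the column maximum break alphabetically (A < C < G < T).
    """
    ic = information_content(pwm)
    out = []
    for j in range(pwm.width):
        col = pwm.probs[:, j]
        base = BASES[int(np.argmax(col))]  # argmax takes first max: alphabetical
        out.append(base if ic[j] > ic_threshold else base.lower())
    return "".join(out)


def palindrome_distance(pwm: PWM) -> float:
    """Mean per-position total-variation distance to the reverse complement.

    0 for a perfectly palindromic PWM (equal to its own reverse complement);
    1 when every column is a point mass disjoint from its mirror.
    """
    rc = pwm.reverse_complement()
    tv = 0.5 * np.abs(pwm.probs - rc.probs).sum(axis=0)
    return float(tv.mean())


def motif_report(pwm: PWM, ic_threshold: float = 1.0) -> MotifReport:
    return MotifReport(
        consensus=consensus_string(pwm, ic_threshold),
        ic=information_content(pwm),
        palindrome_distance=palindrome_distance(pwm),
    )


def discover_motif(
    genome: Genome,
    peaks: list[Peak],
    config: RunConfig | None = None,
    seed: int = 0,
) -> tuple[PWM, MotifReport]:
    """extract -> EM -> report, at the configured width and extension."""
    cfg = config or RunConfig()
    seqs = extract_site_sequences(genome, peaks, cfg.motif_width, cfg.site_extension)
    pwm = em_motif(seqs, width=cfg.motif_width, seed=seed)
    return pwm, motif_report(pwm)
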