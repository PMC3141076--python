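"""Position weight matrices, exact score p-values, motif scanning, bipartite
ChoRE (tandem E-box) detection, and ZOOPS-EM de novo motif discovery.

Scores come in two kinds.  The *normalized* score of a window is the sum of
the matched per-position probabilities divided by the sum of the per-position
maxima, so every consensus window scores exactly 1; this is the "PWM score"
used for E-box calls (a perfect CACGTG scores 1).  The *log-odds* score is
the usual log2 probability ratio against the background and is used for
combined scores and discovery.

The ChoRE (carbohydrate response element) is modelled as two E-box-like
hexamers separated by a fixed spacer (default 5 nt): a direct PWM match
followed, after the spacer, by a reverse-complement PWM match — the
head-to-head tandem arrangement of the CAYGNG-n5-CNCRTG consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map ACGT -> 0..3, anything else (N) -> 4."""
    table = np.full(128, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PWM:
    """A letter-probability matrix: rows A,C,G,T; columns sum to 1."""

    matrix: np.ndarray  # (4, w)
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.0

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)
        if m.ndim != 2 or m.shape[0] != 4:
            raise ValueError("PWM matrix must be 4 x width")
        if (m < 0).any():
            raise ValueError("PWM entries must be non-negative")
        if not np.allclose(m.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def reverse_complement(self) -> "PWM":
        return PWM(self.matrix[::-1, ::-1], self.background, self.pseudocount)

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=0))

    def max_normalizer(self) -> float:
        return float(self.matrix.max(axis=0).sum())

    def log_odds_matrix(self, floor: float = 1e-10) -> np.ndarray:
        m = np.maximum(self.matrix, floor)
        return np.log2(m / self.background[:, None])

    def relative_entropy(self) -> float:
        """Total information content in bits against the background."""
        m = self.matrix
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(m > 0, m * np.log2(m / self.background[:, None]), 0.0)
        return float(term.sum())

    @classmethod
    def from_consensus(
        cls,
        iupac: str,
        pseudocount: float = 0.0,
        background: Sequence[float] | None = None,
    ) -> "PWM":
        """Each column uniform over the IUPAC code's bases, pseudocount-smoothed."""
        cols = []
        for ch in iupac.upper():
            if ch not in IUPAC:
                raise ValueError(f"non-IUPAC character {ch!r}")
            col = np.full(4, pseudocount, dtype=float)
            allowed = IUPAC[ch]
            col[[_BASE_INDEX[b] for b in allowed]] += 1.0 / len(allowed)
            cols.append(col / col.sum())
        bg = np.full(4, 0.25) if background is None else np.asarray(background)
        return cls(np.column_stack(cols), bg, pseudocount)

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        pseudocount: float = 0.01,
        background: Sequence[float] | None = None,
    ) -> "PWM":
        c = np.asarray(counts, dtype=float) + pseudocount
        bg = np.full(4, 0.25) if background is None else np.asarray(background)
        return cls(c / c.sum(axis=0, keepdims=True), bg, pseudocount)

    def to_meme(self, path: str | Path, name: str = "motif") -> None:
        with open(path, "w") as fh:
            fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
            fh.write(
                "Background letter frequencies\n"
                + " ".join(
                    f"{b} {f:.6f}" for b, f in zip(ALPHABET, self.background)
                )
                + "\n\n"
            )
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {self.width}\n"
            )
            for col in self.matrix.T:
                fh.write(" ".join(f"{x:.6f}" for x in col) + "\n")

    @classmethod
    def from_meme(cls, path: str | Path) -> "PWM":
        bg = np.full(4, 0.25)
        rows: list[list[float]] = []
        in_matrix = False
        lines = Path(path).read_text().splitlines()
        for i, line in enumerate(lines):
            s = line.strip()
            if s.startswith("Background letter frequencies"):
                parts = lines[i + 1].split()
                bg = np.array([float(parts[k]) for k in (1, 3, 5, 7)])
            if s.startswith("letter-probability matrix"):
                in_matrix = True
                continue
            if in_matrix:
                if not s:
                    break
                rows.append([float(x) for x in s.split()])
        if not rows:
            raise ValueError(f"no letter-probability matrix in {path}")
        return cls(np.array(rows).T, bg)


def consensus_to_pwm(
    iupac: str,
    pseudocount: float = 0.0,
    background: Sequence[float] | None = None,
) -> PWM:
    """Build a PWM from an IUPAC consensus (see ``PWM.from_consensus``)."""
    return PWM.from_consensus(iupac, pseudocount, background)


def normalized_score(pwm: PWM, window: str) -> float | None:
    """Probability-sum score scaled so consensus windows score exactly 1.

    Returns ``None`` for windows containing N (skipped in scans).
    """
    if len(window) != pwm.width:
        raise ValueError("window length must equal PWM width")
    idx = encode(window)
    if (idx == 4).any():
        return None
    return float(
        pwm.matrix[idx, np.arange(pwm.width)].sum() / pwm.max_normalizer()
    )


def log_odds_score(pwm: PWM, window: str) -> float | None:
    if len(window) != pwm.width:
        raise ValueError("window length must equal PWM width")
    idx = encode(window)
    if (idx == 4).any():
        return None
    lom = pwm.log_odds_matrix()
    return float(lom[idx, np.arange(pwm.width)].sum())


def _column_scores(pwm: PWM, score_kind: str) -> np.ndarray:
    """Per-column per-base score contributions, shape (4, w)."""
    if score_kind == "normalized":
        return pwm.matrix / pwm.max_normalizer()
    if score_kind == "log-odds":
        return pwm.log_odds_matrix()
    raise ValueError(f"unknown score kind {score_kind!r}")


def score_distribution(
    pwm: PWM,
    score_kind: str = "normalized",
    method: str = "enumerate",
    grid_size: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact background distribution of window scores.

    ``enumerate`` combines per-column score values exactly (the result is the
    same as scoring all 4^w windows; identical sums are collapsed as they
    accumulate, so it is feasible for w <= 12).  ``dp`` convolves column
    distributions on a discretised score grid of ``grid_size`` points.
    Returns ``(values ascending, probabilities)``.
    """
    cols = _column_scores(pwm, score_kind)
    bg = pwm.background
    if method == "enumerate":
        if pwm.width > 12:
            raise ValueError("exact enumeration limited to width <= 12")
        values = np.zeros(1)
        probs = np.ones(1)
        for j in range(pwm.width):
            v = (values[:, None] + cols[:, j][None, :]).ravel()
            p = (probs[:, None] * bg[None, :]).ravel()
            # collapse exactly identical sums to keep the state small
            uniq, inv = np.unique(v, return_inverse=True)
            values = uniq
            probs = np.bincount(inv, weights=p)
        return values, probs
    if method == "dp":
        lo = float(cols.min(axis=0).sum())
        hi = float(cols.max(axis=0).sum())
        if hi <= lo:
            return np.array([lo]), np.array([1.0])
        delta = (hi - lo) / (grid_size - 1)
        dist = np.zeros(1)
        dist[0] = 1.0
        offset = 0.0
        for j in range(pwm.width):
            col_idx = np.round((cols[:, j] - cols[:, j].min()) / delta).astype(int)
            offset += cols[:, j].min()
            new = np.zeros(dist.size + col_idx.max() + 1)
            for b in range(4):
                new[col_idx[b]: col_idx[b] + dist.size] += bg[b] * dist
            dist = new
        values = offset + delta * np.arange(dist.size)
        keep = dist > 0
        return values[keep], dist[keep]
    raise ValueError(f"unknown method {method!r}")


def exceedance_probability(
    values: np.ndarray, probs: np.ndarray, threshold: float, tol: float = 1e-9
) -> float:
    """P(score >= threshold) under the background distribution."""
    return float(probs[values >= threshold - tol].sum())


def pvalue_threshold(
    pwm: PWM,
    alpha: float,
    score_kind: str = "normalized",
    method: str = "auto",
    grid_size: int = 10_000,
) -> float:
    """Smallest attainable threshold t with P_background(score >= t) <= alpha.

    Raises if even the maximal score has background probability above alpha.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if method == "auto":
        method = "enumerate" if pwm.width <= 12 else "dp"
    values, probs = score_distribution(pwm, score_kind, method, grid_size)
    desc = np.argsort(values)[::-1]
    v_desc = values[desc]
    cum = np.cumsum(probs[desc])
    ok = np.flatnonzero(cum <= alpha + 1e-12)
    if ok.size == 0:
        raise ValueError(
            f"no attainable threshold: P(max score) = {cum[0]:.3g} > alpha = {alpha}"
        )
    return float(v_desc[ok[-1]])


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    offset: int
    strand: str
    score: float
    log_odds: float
    pvalue: float


def _window_scores(enc: np.ndarray, col: np.ndarray) -> np.ndarray:
    """Scores of all windows of an encoded sequence; NaN where the window has N."""
    w = col.shape[1]
    n = enc.size - w + 1
    if n <= 0:
        return np.empty(0)
    wins = np.lib.stride_tricks.sliding_window_view(enc, w)
    ext = np.vstack([col, np.full((1, w), np.nan)])
    return ext[wins, np.arange(w)].sum(axis=1)


def scan_sequences(
    sequences: Mapping[str, str],
    pwm: PWM,
    alpha: float = 0.001,
    score_kind: str = "normalized",
) -> tuple[list[MotifHit], dict[str, int]]:
    """Scan both strands of each sequence at the exact p-value threshold.

    Overlapping hits are allowed; windows containing N are skipped.  Returns
    the hits and per-sequence hit counts (for motif-per-peak histograms and
    the fraction of sequences with at least one hit).
    """
    threshold = pvalue_threshold(pwm, alpha, score_kind)
    values, probs = score_distribution(
        pwm, score_kind, "enumerate" if pwm.width <= 12 else "dp"
    )
    order = np.argsort(values)
    v_sorted = values[order]
    # P(score >= v) for each attainable v
    tail = np.cumsum(probs[order][::-1])[::-1]
    col = _column_scores(pwm, score_kind)
    col_rc = col[::-1, ::-1]
    lom = pwm.log_odds_matrix()
    lom_rc = lom[::-1, ::-1]
    hits: list[MotifHit] = []
    counts: dict[str, int] = {}
    for seq_id, seq in sequences.items():
        enc = encode(seq)
        n_hits = 0
        for strand, c, lo in (("+", col, lom), ("-", col_rc, lom_rc)):
            scores = _window_scores(enc, c)
            lods = _window_scores(enc, lo)
            idx = np.flatnonzero(scores >= threshold - 1e-12)
            for i in idx:
                s = float(scores[i])
                k = np.searchsorted(v_sorted, s - 1e-9, side="left")
                p = float(tail[min(k, tail.size - 1)])
                hits.append(
                    MotifHit(seq_id, int(i), strand, s, float(lods[i]), p)
                )
                n_hits += 1
        counts[seq_id] = n_hits
    return hits, counts


def hit_count_histogram(counts: Mapping[str, int]) -> dict[int, int]:
    """Number of sequences with 0, 1, 2, ... hits."""
    hist: dict[int, int] = {}
    for n in counts.values():
        hist[n] = hist.get(n, 0) + 1
    return dict(sorted(hist.items()))


@dataclass(frozen=True)
class ChorePair:
    """Two E-box-like hexamers with a fixed inner spacer (tandem ChoRE)."""

    seq_id: str
    start: int  # 0-based start of the first hexamer
    spacer: int
    orientation: str  # '+' if the stronger direct match is on the left
    strands: tuple[str, str]
    score: float  # sum of the two site log-odds


def find_chore_pairs(
    sequence: str,
    ebox_pwm: PWM,
    spacer: int = 5,
    site_alpha: float = 0.002,
    seq_id: str = "",
) -> list[ChorePair]:
    """Find bipartite ChoRE elements: a direct E-box PWM match and, exactly
    ``spacer`` nt downstream, a reverse-complement match.

    Orientation follows the perfect E-box: the ChoRE pairs a perfect and an
    imperfect E-box, so the element is oriented '+' when the left hexamer is
    at least as close to CACGTG as the right hexamer's reverse complement,
    '-' otherwise; the reverse complement of a detected element is therefore
    detected with the opposite orientation.
    """
    w = ebox_pwm.width
    if w != 6:
        raise ValueError("the E-box PWM must have width 6")
    threshold = pvalue_threshold(ebox_pwm, site_alpha)
    enc = encode(sequence)
    col = _column_scores(ebox_pwm, "normalized")
    col_rc = col[::-1, ::-1]
    lom = ebox_pwm.log_odds_matrix()
    lom_rc = lom[::-1, ::-1]
    fwd = _window_scores(enc, col)
    rev = _window_scores(enc, col_rc)
    lo_f = _window_scores(enc, lom)
    lo_r = _window_scores(enc, lom_rc)
    perfect = _column_scores(PWM.from_consensus("CACGTG"), "normalized")
    pf = _window_scores(enc, perfect)
    pr = _window_scores(enc, perfect[::-1, ::-1])
    pairs: list[ChorePair] = []
    step = w + spacer
    for p in range(0, len(sequence) - (2 * w + spacer) + 1):
        q = p + step
        if np.isnan(fwd[p]) or np.isnan(rev[q]):
            continue
        if fwd[p] >= threshold - 1e-12 and rev[q] >= threshold - 1e-12:
            plus = (pf[p], fwd[p]) >= (pr[q], rev[q])
            pairs.append(
                ChorePair(
                    seq_id=seq_id,
                    start=p,
                    spacer=spacer,
                    orientation="+" if plus else "-",
                    strands=("+", "-") if plus else ("-", "+"),
                    score=float(lo_f[p] + lo_r[q]),
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# ZOOPS-EM de novo discovery
# ---------------------------------------------------------------------------

@dataclass
class MotifDiscoveryResult:
    """Best ZOOPS-EM fit.  ``loglik_history`` records the EM objective (data
    log-likelihood plus the Dirichlet smoothing term of the pseudocounted
    M-step), which is non-decreasing across iterations; ``log_likelihood`` is
    the final data log-likelihood."""

    pwm: PWM
    site_posterior: np.ndarray  # per sequence, P(sequence contains a site)
    relative_entropy: float
    log_likelihood: float
    loglik_history: np.ndarray
    converged: bool
    gamma: float


def _em_run(
    window_idx: np.ndarray,      # (n_windows, w) encoded windows, pooled
    seq_of_window: np.ndarray,   # (n_windows,) owning sequence index
    n_seqs: int,
    m_per_seq: np.ndarray,       # windows per sequence
    bg: np.ndarray,
    init_matrix: np.ndarray,
    pseudocount: float,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, bool, float]:
    w = window_idx.shape[1]
    matrix = init_matrix
    gamma = 0.5
    log_bg_win = np.log(bg)[window_idx].sum(axis=1)
    onehot = np.zeros((window_idx.shape[0], 4, w))
    rows = np.arange(window_idx.shape[0])[:, None]
    onehot[rows, window_idx, np.arange(w)[None, :]] = 1.0
    loglik_hist: list[float] = []
    converged = False
    loglik = -np.inf
    for _ in range(max_iter):
        log_matrix = np.log(np.maximum(matrix, 1e-300))
        log_ratio = log_matrix[window_idx, np.arange(w)].sum(axis=1) - log_bg_win
        # per-sequence mixture: (1 - gamma) + (gamma / m) * sum_j exp(lr_j)
        shift = np.zeros(n_seqs)
        np.maximum.at(shift, seq_of_window, log_ratio)
        shift = np.maximum(shift, 0.0)
        exp_shifted = np.exp(log_ratio - shift[seq_of_window])
        sum_exp = np.zeros(n_seqs)
        np.add.at(sum_exp, seq_of_window, exp_shifted)
        site_term = gamma / m_per_seq * sum_exp       # scaled by exp(-shift)
        bg_term = (1.0 - gamma) * np.exp(-shift)
        denom = bg_term + site_term
        loglik = float((np.log(denom) + shift).sum())
        # the EM-monotone objective: data log-likelihood plus the Dirichlet
        # smoothing term the pseudocounted M-step maximises
        objective = loglik + pseudocount * float(log_matrix.sum())
        loglik_hist.append(objective)
        post = (gamma / m_per_seq[seq_of_window]) * exp_shifted / denom[seq_of_window]
        # M-step
        gamma = float(np.clip((site_term / denom).mean(), 1e-4, 1 - 1e-4))
        counts = np.tensordot(post, onehot, axes=(0, 0)) + pseudocount
        matrix = counts / counts.sum(axis=0, keepdims=True)
        if len(loglik_hist) > 1 and abs(loglik_hist[-1] - loglik_hist[-2]) < tol:
            converged = True
            break
    seq_post = site_term / denom
    return matrix, seq_post, loglik, np.array(loglik_hist), converged, gamma


def discover_motif_em(
    sequences: Mapping[str, str] | Sequence[str],
    width: int,
    n_starts: int = 5,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    pseudocount: float = 0.01,
    both_strands: bool = True,
) -> MotifDiscoveryResult:
    """ZOOPS (zero-or-one-occurrence-per-sequence) EM motif discovery.

    Each sequence contains at most one site; the E-step computes per-offset
    site posteriors under the current PWM against an iid background estimated
    from the input, and the M-step re-estimates the letter probabilities with
    a pseudocount.  The best of ``n_starts`` seeded restarts (by final
    log-likelihood) is returned.  The log-likelihood is non-decreasing within
    every run; non-convergence returns the best iterate with a flag.
    """
    seqs = list(sequences.values()) if isinstance(sequences, Mapping) else list(sequences)
    if len(seqs) < 5:
        raise ValueError("need at least 5 sequences")
    if any(len(s) <= width for s in seqs):
        raise ValueError("every sequence must be longer than the motif width")
    enc_list = [encode(s) for s in seqs]
    if both_strands:
        enc_list = [
            np.concatenate([e, [4], 3 - np.where(e == 4, -1, e)[::-1]])
            for e in enc_list
        ]  # forward [4-spacer] revcomp; the 4 blocks cross-boundary windows
    all_windows = []
    seq_of = []
    for i, e in enumerate(enc_list):
        wins = np.lib.stride_tricks.sliding_window_view(e, width)
        keep = ~(wins == 4).any(axis=1)
        wins = wins[keep]
        all_windows.append(wins)
        seq_of.append(np.full(wins.shape[0], i))
    window_idx = np.concatenate(all_windows)
    seq_of_window = np.concatenate(seq_of)
    n_seqs = len(seqs)
    m_per_seq = np.bincount(seq_of_window, minlength=n_seqs).astype(float)
    if (m_per_seq == 0).any():
        raise ValueError("a sequence has no valid windows (too many Ns)")
    counts = np.bincount(window_idx.ravel(), minlength=4)[:4].astype(float)
    bg = np.maximum(counts / counts.sum(), 1e-6)
    bg = bg / bg.sum()

    rng = np.random.default_rng(seed)

    def run(init_matrix):
        return _em_run(
            window_idx, seq_of_window, n_seqs, m_per_seq, bg,
            init_matrix, pseudocount, max_iter, tol,
        )

    def shifted(matrix, s):
        """Slide the motif window by s columns, padding with background."""
        pad = np.tile(bg[:, None], (1, abs(s)))
        if s > 0:
            return np.hstack([matrix[:, s:], pad])
        return np.hstack([pad, matrix[:, :s]])

    best: tuple | None = None
    for _ in range(n_starts):
        k = int(rng.integers(window_idx.shape[0]))
        init = np.full((4, width), 0.5 / 3)
        init[window_idx[k], np.arange(width)] = 0.5
        result = run(init)
        # phase-shift moves: EM locks into column-shifted local optima, so
        # retry from slid copies of the converged matrix until no shift wins
        improved = True
        while improved:
            improved = False
            for s in (-3, -2, -1, 1, 2, 3):
                cand = run(shifted(result[0], s))
                if cand[2] > result[2] + 1e-9:
                    result = cand
                    improved = True
        if best is None or result[2] > best[2]:
            best = result
    matrix, seq_post, loglik, hist, converged, gamma = best
    pwm = PWM(matrix, bg, pseudocount)
    return MotifDiscoveryResult(
        pwm=pwm,
        site_posterior=seq_post,
        relative_entropy=pwm.relative_entropy(),
        log_likelihood=loglik,
        loglik_history=hist,
        converged=converged,
        gamma=gamma,
    )
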