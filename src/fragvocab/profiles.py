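"""Sequence profiles and profile-profile comparison.

A :class:`Profile` summarizes a multiple sequence alignment as per-column
amino-acid probability distributions (Henikoff position-based weighting plus
background-mixture pseudocounts).  Pairs of profiles are compared by
Smith-Waterman local alignment over the log-odds column score

    s(p, q) = log2 sum_a p_a * q_a / f_a          [bits]

which is symmetric in the two columns.  Statistical significance is
calibrated empirically: local scores of shuffled-column profile pairs are
fitted with a Gumbel (extreme-value) distribution, and p-values are mapped
onto a 0-100 "probability" scale through a logistic anchored so that
p = 5e-05 corresponds to a probability of exactly 70 — the working point at
which matches are considered significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._dp import sw_affine
from .data import AA_ALPHABET, AA_INDEX, BACKGROUND_FREQS

#: Logistic slope (per decade of p-value) of the probability scale.
PROB_LOGISTIC_SLOPE = 1.0
#: Anchor: this uncorrected p-value maps to probability 70.
PROB_ANCHOR_P = 5e-5
PROB_ANCHOR_VALUE = 70.0

DEFAULT_GAP_OPEN = 4.5  # bits
DEFAULT_GAP_EXTEND = 0.75  # bits


@dataclass
class Profile:
    """Per-column amino-acid probabilities derived from an MSA."""

    columns: np.ndarray  # (L, 20)
    neff: np.ndarray  # (L,) effective sequence count per column
    background: np.ndarray  # (20,)

    def __len__(self) -> int:
        return len(self.columns)

    def slice(self, start: int, end: int) -> "Profile":
        """Sub-profile over a 1-based closed residue interval."""
        return Profile(
            columns=self.columns[start - 1 : end],
            neff=self.neff[start - 1 : end],
            background=self.background,
        )


@dataclass
class NullModel:
    """Gumbel null for local profile-profile scores.

    ``p(raw) = 1 - exp(-exp(-lam * (raw - mu(La, Lb))))`` — the survival
    function of the extreme-value distribution of maxima, with a location
    that grows with the search space, ``mu(La, Lb) = mu + c * ln(La * Lb)``
    (the standard local-alignment length dependence).  Fitted from at
    least 500 shuffled-pair scores.
    """

    mu: float
    lam: float
    n_samples: int
    seed: int
    length_coef: float = 0.0

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("Gumbel scale parameter must be positive")
        if self.n_samples < 500:
            raise ValueError("null model requires >= 500 samples")

    def location(self, len_a: int | None = None, len_b: int | None = None) -> float:
        if len_a is None or len_b is None or self.length_coef == 0.0:
            return self.mu
        return self.mu + self.length_coef * np.log(len_a * len_b)

    def pvalue(
        self, raw_score: float, len_a: int | None = None, len_b: int | None = None
    ) -> float:
        z = self.lam * (raw_score - self.location(len_a, len_b))
        # survival function of Gumbel(max): 1 - exp(-exp(-z))
        return float(-np.expm1(-np.exp(-z)))


@dataclass
class ProfileMatch:
    query_id: str
    target_id: str
    alignment: list[tuple[int, int]]  # 0-based column pairs
    raw_score: float
    p_value: float
    probability: float


def _msa_match_columns(msa: list[str]) -> list[str]:
    """Reduce an A3M-style alignment to match-state rows.

    Lowercase letters and '.' are insertions relative to row 1 and are
    removed per row; the result is rectangular with '-' marking deletions.
    """
    rows = []
    for row in msa:
        rows.append("".join(c for c in row if c == "-" or c.isupper()))
    L = len(rows[0])
    for k, r in enumerate(rows):
        if len(r) != L:
            raise ValueError(f"MSA row {k + 1} has {len(r)} match columns, expected {L}")
    return rows


def henikoff_weights(rows: list[str]) -> np.ndarray:
    """Position-based sequence weights (normalized to sum 1)."""
    n = len(rows)
    w = np.zeros(n)
    L = len(rows[0])
    for j in range(L):
        col = [r[j] for r in rows]
        counts: dict[str, int] = {}
        for c in col:
            if c in AA_INDEX:
                counts[c] = counts.get(c, 0) + 1
        r_distinct = len(counts)
        if r_distinct == 0:
            continue
        for i, c in enumerate(col):
            if c in AA_INDEX:
                w[i] += 1.0 / (r_distinct * counts[c])
    if w.sum() == 0:
        w[:] = 1.0
    return w / w.sum()


def build_profile(
    msa: list[str],
    pseudocount_weight: float = 0.5,
    pseudocount_a: float = 1.0,
    background: np.ndarray | None = None,
) -> Profile:
    """Build a profile from an MSA (row 1 = the domain sequence).

    Column probabilities mix observed weighted frequencies ``g`` with the
    background ``f``:  ``p = (1 - tau) g + tau f`` where the mixture weight
    decays with the column's effective sequence count,
    ``tau = pseudocount_weight * a / (a + neff - 1)``.  A single-sequence
    column (neff = 1) therefore gets exactly ``pseudocount_weight`` of
    background mass.
    """
    if not msa:
        raise ValueError("empty MSA")
    f = BACKGROUND_FREQS if background is None else np.asarray(background, float)
    rows = _msa_match_columns(msa)
    for r in rows:
        for c in r:
            if c != "-" and c != "X" and c not in AA_INDEX:
                raise ValueError(f"invalid residue symbol {c!r} in MSA")
    L = len(rows[0])
    w = henikoff_weights(rows)
    columns = np.zeros((L, 20))
    neff = np.zeros(L)
    for j in range(L):
        g = np.zeros(20)
        wcol = []
        for i, r in enumerate(rows):
            c = r[j]
            if c in AA_INDEX:
                g[AA_INDEX[c]] += w[i]
                wcol.append(w[i])
        if not wcol:
            columns[j] = f
            neff[j] = 1.0
            continue
        g = g / g.sum()
        wn = np.asarray(wcol) / np.sum(wcol)
        neff[j] = 1.0 / np.sum(wn**2)
        tau = pseudocount_weight * pseudocount_a / (pseudocount_a + neff[j] - 1.0)
        columns[j] = (1.0 - tau) * g + tau * f
    return Profile(columns=columns, neff=neff, background=f)


def column_score(p: np.ndarray, q: np.ndarray, f: np.ndarray) -> float:
    """Log-odds co-emission score of two profile columns, in bits."""
    return float(np.log2(np.dot(p, q / f)))


def score_matrix(qp: Profile, tp: Profile) -> np.ndarray:
    """All-pairs column scores, shape (len(qp), len(tp))."""
    return np.log2(qp.columns @ (tp.columns / tp.background).T)


def align_profiles_local(
    qp: Profile,
    tp: Profile,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> tuple[list[tuple[int, int]], float]:
    """Best-scoring Smith-Waterman local alignment of two profiles."""
    S = score_matrix(qp, tp)
    return sw_affine(S, gap_open, gap_extend)


def calibrate_null(
    profiles: list[Profile],
    n_pairs: int = 1000,
    seed: int = 0,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> NullModel:
    """Fit the score null from shuffled-column profile pairs.

    Column shuffling preserves each profile's composition while destroying
    positional signal, giving an empirical null for local alignment scores
    of unrelated domains.  Scores are fitted with a Gumbel distribution by
    maximum likelihood.
    """
    if len(profiles) < 10:
        raise ValueError("need at least 10 profiles to calibrate")
    if n_pairs < 500:
        raise ValueError("need at least 500 null samples")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_pairs)
    log_mn = np.empty(n_pairs)
    for k in range(n_pairs):
        i, j = rng.choice(len(profiles), size=2, replace=False)
        a, b = profiles[i], profiles[j]
        pa = Profile(a.columns[rng.permutation(len(a))], a.neff, a.background)
        pb = Profile(b.columns[rng.permutation(len(b))], b.neff, b.background)
        _, scores[k] = align_profiles_local(pa, pb, gap_open, gap_extend)
        log_mn[k] = np.log(len(a) * len(b))
    if np.std(scores) < 1e-9:
        raise ValueError(
            "degenerate null score variance; use more/longer profiles or more samples"
        )
    # location depends on search space: regress out the ln(m*n) trend, then
    # fit the Gumbel to the residual scores
    if np.std(log_mn) > 1e-9:
        coef = float(stats.linregress(log_mn, scores).slope)
    else:
        coef = 0.0
    mu, beta = stats.gumbel_r.fit(scores - coef * log_mn)
    return NullModel(
        mu=float(mu),
        lam=float(1.0 / beta),
        n_samples=n_pairs,
        seed=seed,
        length_coef=coef,
    )


def probability_from_pvalue(p_value: float) -> float:
    """Map an uncorrected p-value to the 0-100 probability scale.

    Logistic in x = -log10(p), anchored so p = 5e-05 gives exactly 70.
    """
    x = -np.log10(max(p_value, 1e-300))
    x0 = -np.log10(PROB_ANCHOR_P) - np.log(
        PROB_ANCHOR_VALUE / (100.0 - PROB_ANCHOR_VALUE)
    ) / PROB_LOGISTIC_SLOPE
    return float(100.0 / (1.0 + np.exp(-PROB_LOGISTIC_SLOPE * (x - x0))))


def match_significance(
    raw_score: float,
    null: NullModel,
    n_comparisons: int = 1,
    len_a: int | None = None,
    len_b: int | None = None,
) -> tuple[float, float]:
    """(corrected p-value, probability) for a raw local score.

    The p-value carries a Bonferroni-style factor for the number of
    comparisons (capped at 1); the probability scale uses the uncorrected
    p-value, matching how the 70-percent working point is defined.  Profile
    lengths, when given, feed the null's length correction.
    """
    p_unc = null.pvalue(raw_score, len_a, len_b)
    p = min(1.0, p_unc * max(1, n_comparisons))
    return p, probability_from_pvalue(p_unc)


def score_fixed_alignment(
    qp: Profile, tp: Profile, alignment: list[tuple[int, int]]
) -> float:
    """Mean column score (bits per aligned column) over a fixed alignment.

    Used for sequence scoring of structure-based alignments, where the
    pairing comes from the structural superposition rather than sequence DP;
    gapped positions contribute nothing.
    """
    if not alignment:
        raise ValueError("empty alignment")
    qi = np.array([a for a, _ in alignment])
    ti = np.array([b for _, b in alignment])
    s = np.log2(
        np.sum(qp.columns[qi] * (tp.columns[ti] / tp.background), axis=1)
    )
    return float(np.mean(s))


__all__ = [
    "AA_ALPHABET",
    "Profile",
    "NullModel",
    "ProfileMatch",
    "build_profile",
    "column_score",
    "score_matrix",
    "align_profiles_local",
    "calibrate_null",
    "match_significance",
    "probability_from_pvalue",
    "score_fixed_alignment",
]
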