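"""Sequence-vs-structure correlation: the homolog/analog contrast.

For each fragment query, the domain library is scanned for structural
matches (TM-score normalized by the query length).  Each structural hit is
then scored in sequence space with the profile score of the *fixed*
structural alignment — no sequence-driven realignment — so structure and
sequence similarity are measured independently.  Hits are partitioned into
presumed homologs (superfamilies where the fragment was detected) and
presumed analogs (all other folds), and sequence score is regressed on
TM-score per partition.

The expectation under common descent: homolog pairs started identical and
diverged together, so sequence and structure similarity correlate; under
convergence there is no such coupling unless structure itself constrains
the sequence.  The regression slope t-test (alpha 1e-10) makes the
contrast quantitative; Gaussian fits of the score distributions above
TM 0.5 summarize the separation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import ClassificationLabel, DomainRecord, SegmentInterval
from .profiles import Profile, score_fixed_alignment
from .structure import struct_align, tm_score

logger = logging.getLogger(__name__)

SLOPE_ALPHA = 1e-10


@dataclass
class ScanHit:
    query_fragment_id: str
    target_domain_id: str
    target_interval: SegmentInterval
    tm: float  # query-length normalized
    seq_score: float  # bits per aligned column
    partition: str = "unassigned"  # homolog | analog | excluded
    alignment: list[tuple[int, int]] | None = None


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p_slope: float
    n: int
    significant: bool


def scan_fragment(
    query_coords: np.ndarray,
    query_profile: Profile,
    library: list[DomainRecord],
    profiles: dict[str, Profile],
    query_fragment_id: str = "query",
    tm_min: float = 0.5,
) -> list[ScanHit]:
    """Scan a fragment against every library domain; keep the best window.

    Windows of 1.2x the query length slide along each domain (step L/4);
    each is structurally aligned to the query and the best window's hit is
    kept if its query-normalized TM reaches ``tm_min``.  The sequence score
    of the hit is the mean profile column score over the fixed structural
    alignment.
    """
    L = len(query_coords)
    if L < 9:
        raise ValueError("query must have at least 9 residues")
    win = int(round(1.2 * L))
    step = max(3, L // 4)
    hits = []
    for rec in library:
        n = len(rec)
        best = None  # (tm, start0, alignment)
        starts = list(range(0, max(1, n - win + 1), step))
        if starts and starts[-1] != max(0, n - win):
            starts.append(max(0, n - win))
        for s0 in starts:
            wcoords = rec.coords[s0 : s0 + win]
            if len(wcoords) < 5:
                continue
            try:
                sa = struct_align(query_coords, wcoords)
            except ValueError:
                continue
            tm_q = tm_score(query_coords, wcoords, sa.pairs, L)
            if best is None or tm_q > best[0]:
                best = (tm_q, s0, sa.pairs)
        if best is None or best[0] < tm_min:
            continue
        tm_q, s0, pairs = best
        t_idx = [s0 + b for _, b in pairs]
        interval = SegmentInterval(rec.domain_id, min(t_idx) + 1, max(t_idx) + 1)
        aln = [(a, s0 + b) for a, b in pairs]
        seq = score_fixed_alignment(query_profile, profiles[rec.domain_id], aln)
        hits.append(
            ScanHit(
                query_fragment_id=query_fragment_id,
                target_domain_id=rec.domain_id,
                target_interval=interval,
                tm=tm_q,
                seq_score=seq,
                alignment=aln,
            )
        )
    return hits


def partition_hits(
    hits: list[ScanHit],
    occurrence_map: dict[str, set[str]],
    labels: dict[str, ClassificationLabel],
    query_superfamily: str | None = None,
) -> list[ScanHit]:
    """Assign each hit to exactly one of homolog / analog / excluded.

    ``occurrence_map`` lists, per fragment, the superfamilies in which it
    was detected.  A hit is homologous if the target superfamily is listed
    (and differs from the query's own), analogous if the target fold lies
    entirely outside the listed superfamilies' folds, and excluded
    otherwise (the query's own superfamily, or an unlisted superfamily of a
    listed fold, where neither call is safe).
    """
    for hit in hits:
        lab = labels.get(hit.target_domain_id)
        if lab is None:
            logger.warning("no label for %s; hit excluded", hit.target_domain_id)
            hit.partition = "excluded"
            continue
        listed_sfs = occurrence_map.get(hit.query_fragment_id, set())
        listed_folds = {sf.rsplit(".", 1)[0] for sf in listed_sfs}
        if lab.superfamily_id in listed_sfs and lab.superfamily_id != query_superfamily:
            hit.partition = "homolog"
        elif lab.fold_id not in listed_folds:
            hit.partition = "analog"
        else:
            hit.partition = "excluded"
    return hits


def regress_seq_vs_struct(hits: list[ScanHit]) -> RegressionResult:
    """OLS of sequence score on TM-score with a slope t-test (n-2 df)."""
    if len(hits) < 3:
        raise ValueError("need at least 3 hits to regress")
    x = np.array([h.tm for h in hits])
    y = np.array([h.seq_score for h in hits])
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_slope=float(res.pvalue),
        n=len(hits),
        significant=bool(res.pvalue < SLOPE_ALPHA),
    )


def fit_score_gaussian(
    hits: list[ScanHit], tm_min: float = 0.5
) -> tuple[float, float]:
    """Maximum-likelihood Gaussian fit of sequence scores at TM >= tm_min."""
    scores = np.array([h.seq_score for h in hits if h.tm >= tm_min])
    if len(scores) < 10:
        raise ValueError("need at least 10 hits above the TM cutoff")
    mean, sd = stats.norm.fit(scores)
    return float(mean), float(sd)


__all__ = [
    "SLOPE_ALPHA",
    "ScanHit",
    "RegressionResult",
    "scan_fragment",
    "partition_hits",
    "regress_seq_vs_struct",
    "fit_score_gaussian",
]
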