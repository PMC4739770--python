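"""Reference set of frequent supersecondary motifs.

The correlation analysis needs a baseline fragment set whose homology
status is uncontroversial: representatives of the most frequent
supersecondary-structure motifs (two consecutive secondary structures
joined by a loop).  The module consumes any motif library in a simple JSON
schema — ``[{cluster_id, frequency, members: [{domain_id, start, end, sse,
coords}]}]`` — ordered selection rules pick the representatives:

* one seeded-random eligible member per cluster, scanning clusters in
  descending frequency;
* eligibility: exact target length (24 residues by default, the typical
  consensus-fragment length), at least 6 residues in each secondary
  structure element, connecting loop of at most 6 residues;
* non-compact representatives are eliminated, and the ``n_final`` most
  frequent survivors form the reference set.

Compactness has no universally agreed criterion; here a fragment is
compact when at least 3 C-alpha pairs between its two SSEs lie within
8 A (flagged as a stand-in rule in the output metadata).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .data import DomainRecord, SegmentInterval
from .structure import struct_align

COMPACT_PAIR_DIST = 8.0
COMPACT_MIN_PAIRS = 3


@dataclass
class MotifMember:
    domain_id: str
    interval: SegmentInterval
    sse: str
    coords: np.ndarray


@dataclass
class MotifClusterEntry:
    cluster_id: str
    frequency: int
    members: list[MotifMember]


@dataclass
class ReferenceMotif:
    cluster_id: str
    frequency: int
    member: MotifMember
    compactness_rule: str = "inter-SSE CA pairs within 8 A >= 3 (stand-in rule)"


def load_motif_library(source) -> list[MotifClusterEntry]:
    """Load a motif library from a JSON path or an already-parsed list."""
    if isinstance(source, (str, bytes)) or hasattr(source, "read"):
        with open(source) as fh:
            raw = json.load(fh)
    else:
        raw = source
    entries = []
    for c in raw:
        members = [
            MotifMember(
                domain_id=m["domain_id"],
                interval=SegmentInterval(m["domain_id"], m["start"], m["end"]),
                sse=m["sse"],
                coords=np.asarray(m["coords"], float),
            )
            for m in c["members"]
        ]
        if int(c["frequency"]) < 1:
            raise ValueError(f"cluster {c['cluster_id']}: frequency must be >= 1")
        entries.append(
            MotifClusterEntry(
                cluster_id=c["cluster_id"],
                frequency=int(c["frequency"]),
                members=members,
            )
        )
    return entries


def _sse_runs(sse: str) -> list[tuple[str, int, int]]:
    """Maximal runs as (letter, start0, end0)."""
    runs = []
    i = 0
    while i < len(sse):
        j = i
        while j < len(sse) and sse[j] == sse[i]:
            j += 1
        runs.append((sse[i], i, j - 1))
        i = j
    return runs


def motif_eligible(
    member: MotifMember,
    target_len: int = 24,
    min_sse: int = 6,
    max_loop: int = 6,
) -> bool:
    """Exact length, two SSEs of >= min_sse residues, loop of <= max_loop."""
    if len(member.sse) != target_len or len(member.coords) != target_len:
        return False
    runs = _sse_runs(member.sse)
    sse_runs = [r for r in runs if r[0] in "HE"]
    if len(sse_runs) != 2:
        return False
    (l1, s1a, s1b), (l2, s2a, s2b) = sse_runs
    if (s1b - s1a + 1) < min_sse or (s2b - s2a + 1) < min_sse:
        return False
    loop = s2a - s1b - 1
    return 0 <= loop <= max_loop


def is_compact(member: MotifMember) -> bool:
    """>= 3 C-alpha pairs between the two SSEs within 8 A."""
    runs = [r for r in _sse_runs(member.sse) if r[0] in "HE"]
    if len(runs) < 2:
        raise ValueError("compactness needs at least 2 SSE runs")
    a = member.coords[runs[0][1] : runs[0][2] + 1]
    b = member.coords[runs[-1][1] : runs[-1][2] + 1]
    d = np.sqrt(np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=2))
    return int(np.sum(d <= COMPACT_PAIR_DIST)) >= COMPACT_MIN_PAIRS


def select_reference_set(
    motif_library: list[MotifClusterEntry],
    n_clusters: int = 50,
    target_len: int = 24,
    min_sse: int = 6,
    max_loop: int = 6,
    n_final: int = 40,
    seed: int = 0,
) -> list[ReferenceMotif]:
    """Pick the reference motifs by the ordered selection rules."""
    rng = np.random.default_rng(seed)
    ordered = sorted(motif_library, key=lambda c: (-c.frequency, c.cluster_id))
    picked: list[ReferenceMotif] = []
    for cluster in ordered[:n_clusters]:
        eligible = [
            m
            for m in cluster.members
            if motif_eligible(m, target_len, min_sse, max_loop)
        ]
        if not eligible:
            continue
        member = eligible[int(rng.integers(len(eligible)))]
        if not is_compact(member):
            continue
        picked.append(
            ReferenceMotif(
                cluster_id=cluster.cluster_id,
                frequency=cluster.frequency,
                member=member,
            )
        )
    if len(picked) < n_final:
        raise ValueError(
            f"only {len(picked)} eligible compact representatives; {n_final} required"
        )
    picked.sort(key=lambda p: (-p.frequency, p.cluster_id))
    return picked[:n_final]


def pick_prototype(
    motif_coords: np.ndarray, library: list[DomainRecord]
) -> tuple[str, SegmentInterval, float]:
    """The library occurrence with the best query-normalized TM-score.

    Ties are broken by lexicographic domain id.  Returns
    (domain_id, interval, tm).
    """
    if not library:
        raise ValueError("empty domain library")
    L = len(motif_coords)
    best = None
    for rec in sorted(library, key=lambda r: r.domain_id):
        try:
            sa = struct_align(np.asarray(motif_coords, float), rec.coords)
        except ValueError:
            continue
        from .structure import tm_score

        tm_q = tm_score(motif_coords, rec.coords, sa.pairs, L)
        t_idx = [b for _, b in sa.pairs]
        interval = SegmentInterval(rec.domain_id, min(t_idx) + 1, max(t_idx) + 1)
        if best is None or tm_q > best[2] + 1e-12:
            best = (rec.domain_id, interval, tm_q)
    if best is None:
        raise ValueError("no alignable domain in library")
    return best


__all__ = [
    "MotifMember",
    "MotifClusterEntry",
    "ReferenceMotif",
    "load_motif_library",
    "motif_eligible",
    "is_compact",
    "select_reference_set",
    "pick_prototype",
]
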