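"""End-to-end fragment-vocabulary detection.

Stage order: all-vs-all profile search (reciprocal matches, averaged
probabilities) -> structural verification of the aligned segments ->
thresholding (probability >= 70, TM >= 0.5, both segments spanning >= 2
secondary-structure elements) -> pruning of single connections between
well-populated superfamilies -> single-linkage pooling of fragment
instances by >= 80% mutual interval overlap -> global-similarity triage ->
optional curation -> consensus trimming and census.

Only matches between domains of *different folds* enter the verified set:
shared family or superfamily implies homology and shared fold implies
possible analogy, so the inter-fold matches are the ones whose sequence
similarity is evidence of unrecognized common descent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations

import networkx as nx
import numpy as np

from .data import ClassificationLabel, DomainRecord, SegmentInterval
from .profiles import (
    NullModel,
    Profile,
    align_profiles_local,
    build_profile,
    calibrate_null,
    match_significance,
)
from .structure import assign_sse, count_sse_elements, struct_align

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    prob_min: float = 70.0
    tm_min: float = 0.5
    overlap_min: float = 0.8
    min_sse: int = 2
    sparse_prune_min_size: int = 2
    global_coverage_flag: float = 0.8
    reciprocal_overlap_min: float = 0.5
    null_pairs: int = 600
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.prob_min <= 100):
            raise ValueError("prob_min must be a percentage")
        if not (0 < self.tm_min <= 1):
            raise ValueError("tm_min must be in (0, 1]")
        if not (0 < self.overlap_min <= 1):
            raise ValueError("overlap_min must be a fraction")
        if self.min_sse < 1 or self.sparse_prune_min_size < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class PairMatch:
    a_id: str
    b_id: str
    seg_a: SegmentInterval
    seg_b: SegmentInterval
    prob_ab: float
    prob_ba: float
    relation: str  # intra_family | intra_superfamily | intra_fold | inter_fold
    tm: float | None = None
    n_sse_a: int | None = None
    n_sse_b: int | None = None

    @property
    def prob_avg(self) -> float:
        return 0.5 * (self.prob_ab + self.prob_ba)


@dataclass
class FragmentCluster:
    cluster_id: str
    instances: list[SegmentInterval]
    n_folds: int = 0
    n_superfamilies: int = 0
    repetition_flag: bool = False
    global_flag: bool = False
    consensus_len: int = 0
    ligand_categories: dict[str, str] = field(default_factory=dict)  # category -> provenance
    provenance: list[str] = field(default_factory=list)


def classify_relation(a: ClassificationLabel, b: ClassificationLabel) -> str:
    if a.family_id == b.family_id:
        return "intra_family"
    if a.superfamily_id == b.superfamily_id:
        return "intra_superfamily"
    if a.fold_id == b.fold_id:
        return "intra_fold"
    return "inter_fold"


def build_profiles(domains: list[DomainRecord]) -> dict[str, Profile]:
    return {d.domain_id: build_profile(d.msa) for d in domains}


def _alignment_segments(
    a_id: str, b_id: str, aln: list[tuple[int, int]]
) -> tuple[SegmentInterval, SegmentInterval]:
    qi = [p[0] for p in aln]
    ti = [p[1] for p in aln]
    return (
        SegmentInterval(a_id, qi[0] + 1, qi[-1] + 1),
        SegmentInterval(b_id, ti[0] + 1, ti[-1] + 1),
    )


def all_vs_all_search(
    domains: list[DomainRecord],
    config: PipelineConfig,
    profiles: dict[str, Profile] | None = None,
    null: NullModel | None = None,
) -> list[PairMatch]:
    """Compare every unordered domain pair in both directions.

    Comparisons are always made with full domains, never fragments.  A pair
    is kept only if both directions report a local alignment and the two
    alignments mutually cover at least half of each other's segment (the
    reciprocal-match requirement); the pair is assigned the average of the
    two probabilities.
    """
    if len(domains) < 2:
        raise ValueError("need at least 2 domains")
    profiles = profiles or build_profiles(domains)
    if null is None:
        null = calibrate_null(
            list(profiles.values()), n_pairs=config.null_pairs, seed=config.seed
        )
    matches: list[PairMatch] = []
    for a, b in combinations(domains, 2):
        aln_ab, raw_ab = align_profiles_local(profiles[a.domain_id], profiles[b.domain_id])
        aln_ba, raw_ba = align_profiles_local(profiles[b.domain_id], profiles[a.domain_id])
        if not aln_ab or not aln_ba:
            continue
        seg_a, seg_b = _alignment_segments(a.domain_id, b.domain_id, aln_ab)
        seg_b2, seg_a2 = _alignment_segments(b.domain_id, a.domain_id, aln_ba)
        ov = config.reciprocal_overlap_min
        if not (
            seg_a.overlap(seg_a2) >= ov * min(seg_a.length, seg_a2.length)
            and seg_b.overlap(seg_b2) >= ov * min(seg_b.length, seg_b2.length)
        ):
            continue
        _, prob_ab = match_significance(raw_ab, null, len_a=len(a), len_b=len(b))
        _, prob_ba = match_significance(raw_ba, null, len_a=len(b), len_b=len(a))
        matches.append(
            PairMatch(
                a_id=a.domain_id,
                b_id=b.domain_id,
                seg_a=seg_a,
                seg_b=seg_b,
                prob_ab=prob_ab,
                prob_ba=prob_ba,
                relation=classify_relation(a.label, b.label),
            )
        )
    return matches


def verify_and_filter(
    matches: list[PairMatch],
    domains: list[DomainRecord],
    config: PipelineConfig,
) -> list[PairMatch]:
    """Keep inter-fold matches that pass all three evidence filters.

    Probability >= prob_min; TM-score of the aligned segments (normalized by
    the shorter segment) >= tm_min; both segments spanning at least min_sse
    secondary-structure elements.  A match arriving with its ``tm`` already
    set is not re-superposed (allows verification to be staged).
    """
    by_id = {d.domain_id: d for d in domains}
    out: list[PairMatch] = []
    for m in matches:
        if m.relation != "inter_fold":
            continue
        if m.prob_avg < config.prob_min:
            continue
        a, b = by_id[m.a_id], by_id[m.b_id]
        if m.tm is None:
            try:
                sa = struct_align(a.segment_coords(m.seg_a), b.segment_coords(m.seg_b))
            except ValueError:
                continue
            tm = sa.tm_query if m.seg_a.length <= m.seg_b.length else sa.tm_target
            m = replace(m, tm=tm)
            # Trim the match to its structurally coherent core: residues of
            # the sequence alignment's flanks that do not superpose (the
            # surrounding scaffolds belong to different folds) are shed, so
            # downstream interval pooling sees the fragment itself.
            Xa = a.segment_coords(m.seg_a)
            Yb = b.segment_coords(m.seg_b)
            idx = np.asarray(sa.pairs, int)
            d = np.sqrt(
                np.sum(
                    (sa.superposition.apply(Yb[idx[:, 1]]) - Xa[idx[:, 0]]) ** 2,
                    axis=1,
                )
            )
            close = idx[d <= 5.0]
            if len(close) >= 8:
                m = replace(
                    m,
                    seg_a=SegmentInterval(
                        m.a_id,
                        m.seg_a.start + int(close[:, 0].min()),
                        m.seg_a.start + int(close[:, 0].max()),
                    ),
                    seg_b=SegmentInterval(
                        m.b_id,
                        m.seg_b.start + int(close[:, 1].min()),
                        m.seg_b.start + int(close[:, 1].max()),
                    ),
                )
        if m.tm < config.tm_min:
            continue
        if m.n_sse_a is None or m.n_sse_b is None:
            sse_a = a.sse if a.sse is not None else assign_sse(a.coords)
            sse_b = b.sse if b.sse is not None else assign_sse(b.coords)
            m = replace(
                m,
                n_sse_a=count_sse_elements(sse_a, m.seg_a),
                n_sse_b=count_sse_elements(sse_b, m.seg_b),
            )
        if m.n_sse_a < config.min_sse or m.n_sse_b < config.min_sse:
            continue
        out.append(m)
    return out


def prune_sparse_connections(
    matches: list[PairMatch],
    labels: dict[str, ClassificationLabel],
    config: PipelineConfig,
) -> list[PairMatch]:
    """Drop single matches between well-populated superfamilies.

    A lone connection between two superfamilies that each have at least
    ``sparse_prune_min_size`` member domains in the library is more likely a
    false positive than a lone connection involving a singleton superfamily,
    which has no opportunity to make a second one.
    """
    sf_size: dict[str, int] = {}
    for lab in labels.values():
        sf_size[lab.superfamily_id] = sf_size.get(lab.superfamily_id, 0) + 1
    by_sf_pair: dict[tuple[str, str], list[PairMatch]] = {}
    for m in matches:
        key = tuple(sorted((labels[m.a_id].superfamily_id, labels[m.b_id].superfamily_id)))
        by_sf_pair.setdefault(key, []).append(m)
    out = []
    for (sf1, sf2), ms in by_sf_pair.items():
        if (
            len(ms) == 1
            and sf_size.get(sf1, 0) >= config.sparse_prune_min_size
            and sf_size.get(sf2, 0) >= config.sparse_prune_min_size
        ):
            logger.info("pruned single connection between %s and %s", sf1, sf2)
            continue
        out.extend(ms)
    out.sort(key=lambda m: (m.a_id, m.b_id, m.seg_a.start))
    return out


def pool_fragments(
    matches: list[PairMatch], config: PipelineConfig
) -> list[FragmentCluster]:
    """Single-linkage pooling of fragment instances.

    Nodes are the fragment instances (domain, interval) on either side of a
    verified match.  The two sides of every match are linked; additionally,
    instances in the same domain are linked when their intervals mutually
    overlap by at least ``overlap_min`` of each one's length (the shared-B
    rule: A-B and B-C matches combine when the boundaries in B agree).
    Connected components become clusters.
    """
    g = nx.Graph()
    for m in matches:
        na = (m.seg_a.domain_id, m.seg_a.start, m.seg_a.end)
        nb = (m.seg_b.domain_id, m.seg_b.start, m.seg_b.end)
        g.add_edge(na, nb)
    nodes = sorted(g.nodes)
    for u, v in combinations(nodes, 2):
        if u[0] != v[0]:
            continue
        iu = SegmentInterval(u[0], u[1], u[2])
        iv = SegmentInterval(v[0], v[1], v[2])
        if iu.mutual_overlap_ge(iv, config.overlap_min):
            g.add_edge(u, v)
    comps = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    clusters = []
    for k, comp in enumerate(comps):
        instances = _merge_same_domain(
            [SegmentInterval(*n) for n in sorted(comp)], config.overlap_min
        )
        clusters.append(FragmentCluster(cluster_id=f"c{k + 1:03d}", instances=instances))
    return clusters


def _merge_same_domain(
    instances: list[SegmentInterval], overlap_min: float
) -> list[SegmentInterval]:
    """Union same-domain instances that mutually overlap.

    Several matches report near-identical intervals for one occurrence of a
    fragment; collapsing them leaves one instance per genuine copy, so a
    repetition flag really means two copies in one domain.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(instances)))
    for i, j in combinations(range(len(instances)), 2):
        if instances[i].mutual_overlap_ge(instances[j], overlap_min):
            g.add_edge(i, j)
    merged = []
    for comp in nx.connected_components(g):
        members = [instances[i] for i in comp]
        merged.append(
            SegmentInterval(
                members[0].domain_id,
                min(m.start for m in members),
                max(m.end for m in members),
            )
        )
    merged.sort(key=lambda s: (s.domain_id, s.start, s.end))
    return merged


def flag_global_similarity(
    cluster: FragmentCluster,
    domains: dict[str, DomainRecord],
    config: PipelineConfig,
) -> bool:
    """True when the cluster reflects global fold similarity, not a fragment.

    Automatic proxy for the survey's manual triage of globally similar
    folds (homologous fold change: circular permutation, hairpin swaps):
    the median fraction of domain length covered by the instances.
    """
    cov = [
        inst.length / len(domains[inst.domain_id]) for inst in cluster.instances
    ]
    return bool(np.median(cov) >= config.global_coverage_flag)


def apply_curation(
    clusters: list[FragmentCluster], curation: dict | None
) -> list[FragmentCluster]:
    """Apply a curation config: ``{"merge": [[id, id, ...]], "drop": [id]}``.

    The survey's per-cluster interactive merging and dropping is replaced by
    this explicit, recorded mechanism; provenance notes every action.
    """
    if not curation:
        return clusters
    by_id = {c.cluster_id: c for c in clusters}
    known = set(by_id)
    for group in curation.get("merge", []):
        for cid in group:
            if cid not in known:
                raise ValueError(f"unknown cluster id in curation: {cid}")
    for cid in curation.get("drop", []):
        if cid not in known:
            raise ValueError(f"unknown cluster id in curation: {cid}")
    dropped = set(curation.get("drop", []))
    merged_away: set[str] = set()
    for group in curation.get("merge", []):
        head = by_id[group[0]]
        for cid in group[1:]:
            head.instances.extend(by_id[cid].instances)
            merged_away.add(cid)
        head.instances.sort(key=lambda s: (s.domain_id, s.start, s.end))
        head.provenance.append("curated:merge:" + "+".join(group))
    out = []
    for c in clusters:
        if c.cluster_id in dropped:
            logger.info("curation dropped cluster %s", c.cluster_id)
            continue
        if c.cluster_id in merged_away:
            continue
        out.append(c)
    return out


def consensus_boundaries(
    cluster: FragmentCluster, domains: dict[str, DomainRecord]
) -> FragmentCluster:
    """Trim instances to majority-occupancy consensus columns.

    Each instance is structurally aligned to the longest instance of the
    cluster; reference columns present in at least half of the instances
    define the consensus, and every instance is trimmed to its residues
    aligned within the consensus span.  ``consensus_len`` is the number of
    consensus columns.
    """
    insts = cluster.instances
    if len(insts) < 2:
        cluster.consensus_len = insts[0].length if insts else 0
        return cluster
    ref = max(insts, key=lambda s: (s.length, s.domain_id))
    ref_coords = domains[ref.domain_id].segment_coords(ref)
    occupancy = np.zeros(ref.length)
    maps = []
    for inst in insts:
        if inst == ref:
            maps.append({i: i for i in range(ref.length)})
            occupancy += 1
            continue
        coords = domains[inst.domain_id].segment_coords(inst)
        try:
            sa = struct_align(ref_coords, coords)
        except ValueError:
            maps.append({})
            continue
        m = {ri: qi for ri, qi in sa.pairs}
        maps.append(m)
        for ri in m:
            occupancy[ri] += 1
    consensus = occupancy >= 0.5 * len(insts)
    if not consensus.any():
        cluster.consensus_len = ref.length
        return cluster
    lo = int(np.argmax(consensus))
    hi = int(len(consensus) - np.argmax(consensus[::-1]) - 1)
    cluster.consensus_len = hi - lo + 1
    trimmed = []
    for inst, m in zip(insts, maps):
        cols = [qi for ri, qi in m.items() if lo <= ri <= hi]
        if not cols:
            trimmed.append(inst)
            continue
        trimmed.append(
            SegmentInterval(
                inst.domain_id, inst.start + min(cols), inst.start + max(cols)
            )
        )
    cluster.instances = trimmed
    return cluster


def census(
    cluster: FragmentCluster, labels: dict[str, ClassificationLabel]
) -> tuple[int, int, bool]:
    """(distinct folds, distinct superfamilies, repetition flag)."""
    folds = {labels[i.domain_id].fold_id for i in cluster.instances}
    sfs = {labels[i.domain_id].superfamily_id for i in cluster.instances}
    per_domain: dict[str, int] = {}
    for i in cluster.instances:
        per_domain[i.domain_id] = per_domain.get(i.domain_id, 0) + 1
    rep = any(v >= 2 for v in per_domain.values())
    cluster.n_folds = len(folds)
    cluster.n_superfamilies = len(sfs)
    cluster.repetition_flag = rep
    return len(folds), len(sfs), rep


def run_detection(
    domains: list[DomainRecord],
    config: PipelineConfig | None = None,
    curation: dict | None = None,
) -> dict:
    """Run the full detection chain; returns clusters plus stage counts."""
    config = config or PipelineConfig()
    by_id = {d.domain_id: d for d in domains}
    labels = {d.domain_id: d.label for d in domains}
    searched = all_vs_all_search(domains, config)
    verified = verify_and_filter(searched, domains, config)
    pruned = prune_sparse_connections(verified, labels, config)
    clusters = pool_fragments(pruned, config)
    for c in clusters:
        c.global_flag = flag_global_similarity(c, by_id, config)
    clusters = apply_curation(clusters, curation)
    for c in clusters:
        consensus_boundaries(c, by_id)
        census(c, labels)
    summary = {
        "n_domains": len(domains),
        "n_searched": len(searched),
        "n_verified": len(verified),
        "n_pruned": len(pruned),
        "n_clusters": len(clusters),
        "n_clusters_unflagged": sum(1 for c in clusters if not c.global_flag),
    }
    return {"clusters": clusters, "summary": summary, "config": config}


__all__ = [
    "PipelineConfig",
    "PairMatch",
    "FragmentCluster",
    "classify_relation",
    "build_profiles",
    "all_vs_all_search",
    "verify_and_filter",
    "prune_sparse_connections",
    "pool_fragments",
    "flag_global_similarity",
    "apply_curation",
    "consensus_boundaries",
    "census",
    "run_detection",
]
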