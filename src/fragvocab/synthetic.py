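"""Synthetic fold libraries with planted fragments and full ground truth.

The generator emulates the inputs of a classification-database survey at
desk scale: several "folds" of idealized secondary-structure scaffolds, a
subset of which share a planted sub-domain fragment (common template,
controlled sequence identity and coordinate noise), analog decoys (same
backbone, background-resampled sequence), per-domain MSAs under a
BLOSUM62-derived substitution model, and pseudo-ligand atoms placed at
controlled contact distances.

Default parameters are the benchmark study conditions: 5 folds of 4 domains
each, 3 planted fragments of subdomain size (~24 residues, the typical
consensus-fragment length) at 40% sequence identity to their template and
0.5 A coordinate noise, one instance per target fold.

Randomness: one root seed; per-domain child streams are derived by stable
hashing of the domain id, so any subset of the library regenerates
identically.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .data import (
    AA_ALPHABET,
    AA_INDEX,
    BACKGROUND_FREQS,
    ClassificationLabel,
    DomainRecord,
    LigandAtomSet,
    SegmentInterval,
)

CHAIN_STEP = 3.8  # consecutive C-alpha distance, Angstrom
CLASH_MIN = 3.0  # minimum allowed non-adjacent C-alpha distance
#: Minimum clearance (A) for a deliberately non-contacting ligand atom.
CONTACT_CLEAR_MIN = 3.5
#: MSA mutation rates at the conserved-core / fast-evolving positions of
#: planted fragments (rate heterogeneity: constrained sites change slowly,
#: unconstrained sites faster than the chain average).
CONSERVED_MSA_RATE = 0.05
VARIABLE_MSA_RATE = 0.5

#: Representative chemical component code per ligand category.
CATEGORY_HET_CODES = {
    "nucleic_acid": "DA",
    "metal": "ZN",
    "iron_sulfur": "SF4",
    "nucleotide_cofactor": "ATP",
}


# ---------------------------------------------------------------------------
# substitution model

def _blosum_conditional() -> np.ndarray:
    """P(b | a) from BLOSUM62 target frequencies q_ab = f_a f_b 2^(s_ab/2)."""
    mat = substitution_matrices.load("BLOSUM62")
    f = BACKGROUND_FREQS
    q = np.zeros((20, 20))
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            q[i, j] = f[i] * f[j] * 2.0 ** (mat[a, b] / 2.0)
    return q / q.sum(axis=1, keepdims=True)


_COND = _blosum_conditional()
_COND_NO_SELF = _COND * (1.0 - np.eye(20))
_COND_NO_SELF = _COND_NO_SELF / _COND_NO_SELF.sum(axis=1, keepdims=True)


def child_seed(root_seed: int, name: str) -> int:
    """Stable per-entity seed below 2^31."""
    h = hashlib.sha256(f"{root_seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") & 0x7FFFFFFF


def random_sequence(length: int, rng: np.random.Generator) -> str:
    idx = rng.choice(20, size=length, p=BACKGROUND_FREQS)
    return "".join(AA_ALPHABET[i] for i in idx)


def mutate_sequence(
    sequence: str, n_mutations: int, rng: np.random.Generator
) -> str:
    """Mutate exactly ``n_mutations`` uniformly chosen positions.

    Substitutions are drawn from the BLOSUM62-conditional distribution,
    excluding the original residue, so mutated positions stay chemically
    plausible.
    """
    seq = list(sequence)
    pos = rng.choice(len(seq), size=min(n_mutations, len(seq)), replace=False)
    for p in pos:
        a = AA_INDEX.get(seq[p])
        if a is None:
            continue
        seq[p] = AA_ALPHABET[rng.choice(20, p=_COND_NO_SELF[a])]
    return "".join(seq)


def synthesize_msa(
    sequence: str,
    depth: int,
    mutation_rate: float,
    rng: np.random.Generator,
    rates: np.ndarray | None = None,
) -> list[str]:
    """Simulated MSA: row 1 is the sequence, rows 2..depth diverge under the
    conditional substitution model.

    ``rates`` optionally gives a per-position mutation rate (length L),
    modelling rate heterogeneity: functionally constrained positions evolve
    more slowly than the rest of the chain.  Without it the scalar
    ``mutation_rate`` applies everywhere.
    """
    rows = [sequence]
    L = len(sequence)
    r = np.full(L, mutation_rate) if rates is None else np.asarray(rates, float)
    if len(r) != L:
        raise ValueError("rates length must match sequence length")
    for _ in range(depth - 1):
        row = list(sequence)
        hit = rng.random(L) < r
        for p in np.nonzero(hit)[0]:
            a = AA_INDEX.get(row[p])
            if a is None:
                continue
            row[p] = AA_ALPHABET[rng.choice(20, p=_COND_NO_SELF[a])]
        rows.append("".join(row))
    return rows


# ---------------------------------------------------------------------------
# geometry

def make_ideal_sse(kind: str, length: int) -> np.ndarray:
    """Idealized C-alpha trace of a helix or strand along +z.

    Helix: 1.5 A rise and 100 degrees per residue on a 2.3 A radius.
    Strand: extended zigzag, 3.4 A axial spacing, ~3.8 A consecutive C-alpha.
    """
    if length < 3:
        raise ValueError("SSE length must be >= 3")
    if kind == "H":
        i = np.arange(length)
        ang = np.deg2rad(100.0 * i)
        return np.column_stack([2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * i])
    if kind == "E":
        i = np.arange(length)
        return np.column_stack(
            [0.85 * (-1.0) ** i, np.zeros(length), 3.4 * i]
        )
    raise ValueError(f"unknown SSE kind {kind!r}")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n > 1e-6:
            return v / n


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _min_dist(points: np.ndarray, cloud: np.ndarray) -> float:
    if len(cloud) == 0:
        return np.inf
    d2 = np.sum((points[:, None, :] - cloud[None, :, :]) ** 2, axis=2)
    return float(np.sqrt(d2.min()))


def _grow_chain(elements: list[tuple], rng: np.random.Generator):
    """Grow a C-alpha chain from coil and rigid-body elements.

    ``elements`` entries are ``("coil", length)`` or ``("rigid", coords)``.
    Rigid bodies keep their internal geometry; placement is clash-avoiding
    (no two non-adjacent C-alpha closer than 3.0 A, best of 40 attempts).
    Returns (coords, spans) with 0-based [start, end] per element.
    """
    coords: list[np.ndarray] = []
    spans: list[tuple[int, int]] = []
    direction = _random_unit(rng)
    for elem in elements:
        start = len(coords)
        if elem[0] == "coil":
            for _ in range(elem[1]):
                best, best_md = None, -1.0
                for _try in range(40):
                    d = direction * 0.7 + _random_unit(rng)
                    d /= np.linalg.norm(d)
                    pos = coords[-1] + d * CHAIN_STEP if coords else np.zeros(3)
                    md = _min_dist(pos[None, :], np.asarray(coords[:-1]))
                    if md >= CLASH_MIN:
                        best, best_md = (pos, d), md
                        break
                    if md > best_md:
                        best, best_md = (pos, d), md
                pos, direction = best
                coords.append(pos)
        else:
            body = np.asarray(elem[1], float)
            best, best_md = None, -1.0
            for _try in range(40):
                R = _random_rotation(rng)
                d = direction * 0.7 + _random_unit(rng)
                d /= np.linalg.norm(d)
                anchor = coords[-1] + d * CHAIN_STEP if coords else np.zeros(3)
                pts = anchor + (body - body[0]) @ R
                md = min(
                    _min_dist(pts, np.asarray(coords[:-1])),
                    _min_dist(pts[1:], np.asarray(coords[-1:])) if coords else np.inf,
                )
                if md >= CLASH_MIN:
                    best, best_md = pts, md
                    break
                if md > best_md:
                    best, best_md = pts, md
            pts = best
            coords.extend(pts)
            direction = pts[-1] - pts[-2]
            direction = direction / np.linalg.norm(direction)
        spans.append((start, len(coords) - 1))
    return np.asarray(coords), spans


def pseudo_side_chains(coords: np.ndarray) -> np.ndarray:
    """One pseudo C-beta per residue, 1.5 A outward from the local backbone."""
    n = len(coords)
    cb = np.empty_like(coords)
    for i in range(n):
        lo, hi = max(0, i - 1), min(n - 1, i + 1)
        mid = 0.5 * (coords[lo] + coords[hi])
        v = coords[i] - mid
        nv = np.linalg.norm(v)
        if nv < 1e-6:
            v = coords[i] - coords[lo] if i > 0 else coords[hi] - coords[i]
            v = np.array([v[1], -v[0], v[2] * 0 + 1e-3]) if np.linalg.norm(v) < 1e-6 else v
            nv = np.linalg.norm(v)
        cb[i] = coords[i] + 1.5 * v / nv
    return cb


def add_coordinate_noise(
    coords: np.ndarray, noise_rmsd: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian perturbation calibrated so the expected RMSD ~ noise_rmsd."""
    if noise_rmsd <= 0:
        return coords.copy()
    sigma = noise_rmsd / np.sqrt(3.0)
    return coords + rng.normal(scale=sigma, size=coords.shape)


# ---------------------------------------------------------------------------
# configuration and ground truth

@dataclass
class PlantedFragmentSpec:
    fragment_id: str
    length: int
    target_folds: list[int]
    sequence_identity: float = 0.4
    coord_noise: float = 0.5
    topology: list[tuple[str, int]] | None = None  # [('H', 10), ('C', 4), ...]

    def __post_init__(self):
        if not (0.0 < self.sequence_identity <= 1.0):
            raise ValueError("sequence_identity must be in (0, 1]")
        if self.coord_noise < 0:
            raise ValueError("coord_noise must be >= 0")
        if len(self.target_folds) < 2:
            raise ValueError("a planted fragment must target >= 2 folds")


@dataclass
class LigandPlacementSpec:
    fragment_id: str
    category: str
    n_contact_atoms: int = 3
    distance: float = 2.9


def _default_fragments() -> list[PlantedFragmentSpec]:
    return [
        PlantedFragmentSpec(
            "frag1", 24, [0, 1, 2], topology=[("H", 10), ("C", 4), ("H", 10)]
        ),
        PlantedFragmentSpec(
            "frag2", 28, [1, 2, 3], topology=[("E", 12), ("C", 4), ("E", 12)]
        ),
        PlantedFragmentSpec(
            "frag3", 26, [2, 3, 4], topology=[("E", 8), ("C", 4), ("H", 14)]
        ),
    ]


def _default_ligands() -> list[LigandPlacementSpec]:
    return [
        LigandPlacementSpec("frag1", "nucleic_acid"),
        LigandPlacementSpec("frag2", "iron_sulfur"),
        LigandPlacementSpec("frag3", "metal"),
    ]


@dataclass
class SyntheticConfig:
    """Study conditions of the desk-scale benchmark (defaults)."""

    n_folds: int = 5
    domains_per_fold: int = 4
    fold_topologies: list[str] = field(
        default_factory=lambda: ["H-H-H", "E-E-E-E", "H-E-E-H", "E-H-E", "H-E-H-E"]
    )
    planted_fragments: list[PlantedFragmentSpec] = field(
        default_factory=_default_fragments
    )
    n_decoys: int = 3
    msa_depth: int = 20
    msa_mutation_rate: float = 0.3
    ligand_placements: list[LigandPlacementSpec] = field(
        default_factory=_default_ligands
    )
    seed: int = 1


@dataclass
class PlantedInstance:
    fragment_id: str
    interval: SegmentInterval
    kind: str  # "homolog" or "decoy"


@dataclass
class GroundTruth:
    instances: list[PlantedInstance] = field(default_factory=list)
    #: fragment_id -> (coords, sequence, mutable position indices)
    templates: dict[str, tuple] = field(default_factory=dict)
    ligands: list[dict] = field(default_factory=list)

    def homolog_instances(self, fragment_id: str | None = None):
        return [
            pi
            for pi in self.instances
            if pi.kind == "homolog"
            and (fragment_id is None or pi.fragment_id == fragment_id)
        ]

    def decoy_instances(self):
        return [pi for pi in self.instances if pi.kind == "decoy"]

    def fragment_ids(self) -> list[str]:
        return sorted({pi.fragment_id for pi in self.instances if pi.kind == "homolog"})


# ---------------------------------------------------------------------------
# fragment templates, planting, decoys

def make_fragment_template(
    spec: PlantedFragmentSpec, rng: np.random.Generator
) -> tuple[np.ndarray, str]:
    """Template coordinates and sequence for a planted fragment."""
    topo = spec.topology
    if topo is None:
        sse_len = (spec.length - 4) // 2
        topo = [("H", sse_len), ("C", spec.length - 2 * sse_len), ("H", sse_len)]
    if len(topo) == 3 and topo[0][0] in "HE" and topo[1][0] == "C" and topo[2][0] in "HE":
        coords = _explicit_hairpin(
            topo[0][0], topo[0][1], topo[1][1], topo[2][0], topo[2][1], compact=True
        )
    else:
        elements = []
        for kind, ln in topo:
            if kind == "C":
                elements.append(("coil", ln))
            else:
                elements.append(("rigid", make_ideal_sse(kind, ln)))
        coords, _ = _grow_chain(elements, rng)
    if len(coords) != spec.length:
        raise ValueError(
            f"{spec.fragment_id}: topology length {len(coords)} != {spec.length}"
        )
    seq = random_sequence(spec.length, rng)
    # Divergence model: a fragment has a fixed mutable complement — the same
    # positions vary in every descendant copy while the conserved core is
    # shared, as in real homologous motifs.  Instance identity to the
    # template is the configured fraction; pairwise identity between
    # instances is approximately the same.
    n_mut = int(round((1.0 - spec.sequence_identity) * spec.length))
    mutable = np.sort(rng.choice(spec.length, size=n_mut, replace=False))
    return coords, seq, mutable


def plant_fragment_instance(
    template_coords: np.ndarray,
    template_seq: str,
    identity: float,
    noise: float,
    rng: np.random.Generator,
    mutable_positions: np.ndarray | None = None,
) -> tuple[np.ndarray, str]:
    """One diverged copy of a template: noised coordinates, mutated sequence.

    If ``mutable_positions`` is given (the fragment's fixed mutable
    complement), exactly those positions are substituted; otherwise
    positions are chosen uniformly to hit the target identity.
    """
    coords = add_coordinate_noise(template_coords, noise, rng)
    if mutable_positions is not None:
        seq = list(template_seq)
        for p in mutable_positions:
            a = AA_INDEX.get(seq[p])
            if a is None:
                continue
            seq[p] = AA_ALPHABET[rng.choice(20, p=_COND_NO_SELF[a])]
        return coords, "".join(seq)
    n_mut = int(round((1.0 - identity) * len(template_seq)))
    seq = mutate_sequence(template_seq, n_mut, rng)
    return coords, seq


def make_analog_decoy(
    template_coords: np.ndarray,
    template_seq: str,
    rng: np.random.Generator,
    jitter: float = 0.3,
) -> tuple[np.ndarray, str]:
    """Same backbone (lightly jittered), unrelated background sequence."""
    coords = add_coordinate_noise(template_coords, jitter, rng)
    seq = random_sequence(len(template_seq), rng)
    return coords, seq


# ---------------------------------------------------------------------------
# domain assembly

def build_domain(
    topology: str, rng: np.random.Generator, insert: tuple | None = None
):
    """Grow one domain from a scaffold topology like ``"H-E-E-H"``.

    SSE lengths are drawn per element (H: 9-13, E: 6-9), joined by 3-5
    residue coil linkers.  ``insert``, if given, is ``(coords, seq)`` of a
    fragment spliced in after the first linker, flanked by a fresh linker.
    Returns (coords, sequence, fragment_interval_or_None).
    """
    kinds = topology.split("-")
    elements: list[tuple] = []
    seqs: list[str] = []
    markers: list[bool] = []

    def add(elem, seq, is_frag=False):
        elements.append(elem)
        seqs.append(seq)
        markers.append(is_frag)

    for i, kind in enumerate(kinds):
        ln = int(rng.integers(9, 14)) if kind == "H" else int(rng.integers(6, 10))
        add(("rigid", make_ideal_sse(kind, ln)), random_sequence(ln, rng))
        if i < len(kinds) - 1:
            cl = int(rng.integers(3, 6))
            add(("coil", cl), random_sequence(cl, rng))
    if insert is not None:
        frag_coords, frag_seq = insert
        cl = int(rng.integers(3, 6))
        pos = 2 if len(elements) > 2 else len(elements)
        elements.insert(pos, ("coil", cl))
        seqs.insert(pos, random_sequence(cl, rng))
        markers.insert(pos, False)
        elements.insert(pos, ("rigid", np.asarray(frag_coords)))
        seqs.insert(pos, frag_seq)
        markers.insert(pos, True)
    coords, spans = _grow_chain(elements, rng)
    sequence = "".join(seqs)
    interval = None
    for (s0, e0), is_frag in zip(spans, markers):
        if is_frag:
            interval = (s0 + 1, e0 + 1)
    return coords, sequence, interval


# ---------------------------------------------------------------------------
# ligand placement

def place_ligand(
    record: DomainRecord,
    instance: SegmentInterval,
    category: str,
    n_contact_atoms: int,
    distance: float,
    rng: np.random.Generator,
) -> LigandAtomSet:
    """Position ligand atoms so exactly ``n_contact_atoms`` (fragment atom,
    ligand atom) pairs fall within ``distance`` and nothing else within
    ``distance + 0.5``."""
    het = CATEGORY_HET_CODES.get(category, "UNL")
    all_atoms = (
        record.atoms if record.atoms is not None else record.coords
    )
    centroid = record.coords.mean(axis=0)
    if n_contact_atoms == 0:
        # one atom held clear of the contact cutoff: probe outward from the
        # most exposed side-chain atom at the requested distance
        gap = max(distance, 5.0)
        best_atom, best_margin = None, -1.0
        for r in range(instance.start, instance.end + 1):
            if record.atoms is not None:
                anchor = record.atoms[record.atom_res == r][-1]
                out = anchor - record.coords[r - 1]
            else:
                anchor = record.coords[r - 1]
                out = anchor - centroid
            nrm = np.linalg.norm(out)
            if nrm < 1e-6:
                continue
            probe = anchor + out / nrm * gap
            margin = _min_dist(probe[None, :], all_atoms)
            if margin > best_margin:
                best_atom, best_margin = probe, margin
        if best_atom is None or best_margin <= CONTACT_CLEAR_MIN:
            raise ValueError("could not place non-contacting ligand")
        return LigandAtomSet(het_code=het, atoms=best_atom[None, :])
    # For each instance residue, extend a probe from its outermost atom
    # along the backbone->side-chain direction; keep residues whose probe
    # clears every other atom by > 0.5 A beyond the contact distance.
    candidates = []
    for r in range(instance.start, instance.end + 1):
        if record.atoms is not None:
            anchor = record.atoms[record.atom_res == r][-1]  # pseudo C-beta
            out = anchor - record.coords[r - 1]
        else:
            anchor = record.coords[r - 1]
            out = anchor - centroid
        nrm = np.linalg.norm(out)
        if nrm < 1e-6:
            continue
        probe = anchor + out / nrm * distance
        d = np.sqrt(np.sum((all_atoms - probe) ** 2, axis=1))
        own = np.argmin(np.sum((all_atoms - anchor) ** 2, axis=1))
        margin = np.min(np.delete(d, own))
        if margin > distance + 0.5:
            candidates.append((margin, r, probe))
    candidates.sort(key=lambda c: -c[0])
    if len(candidates) < n_contact_atoms:
        raise ValueError(
            f"could not satisfy exact contact-count placement for {category}"
        )
    lig = np.asarray([c[2] for c in candidates[:n_contact_atoms]])
    d = np.sqrt(np.sum((all_atoms[:, None, :] - lig[None, :, :]) ** 2, axis=2))
    n_in = int(np.sum(d <= distance + 1e-9))
    n_margin = int(np.sum(d <= distance + 0.5))
    if not (n_in == n_contact_atoms and n_margin == n_contact_atoms):
        raise ValueError(
            f"could not satisfy exact contact-count placement for {category}"
        )
    return LigandAtomSet(het_code=het, atoms=lig)


# ---------------------------------------------------------------------------
# library generation

def _sccs(fold_idx: int, dom_idx: int) -> str:
    return f"s.{fold_idx + 1}.{dom_idx + 1}.1"


def generate_library(
    config: SyntheticConfig | None = None,
) -> tuple[list[DomainRecord], GroundTruth]:
    """Generate the full synthetic domain library plus ground truth."""
    config = config or SyntheticConfig()
    if len(config.fold_topologies) < config.n_folds:
        raise ValueError("need one topology per fold")
    truth = GroundTruth()
    templates: dict[str, tuple[np.ndarray, str]] = {}
    for spec in config.planted_fragments:
        rng = np.random.default_rng(
            child_seed(config.seed, f"template:{spec.fragment_id}")
        )
        templates[spec.fragment_id] = make_fragment_template(spec, rng)
    truth.templates = templates

    # map (fold, domain) -> (fragment spec, kind)
    placements: dict[tuple[int, int], tuple[PlantedFragmentSpec, str]] = {}
    for k, spec in enumerate(config.planted_fragments):
        dom_idx = k % config.domains_per_fold
        for fold in spec.target_folds:
            placements[(fold, dom_idx)] = (spec, "homolog")
    for k in range(config.n_decoys):
        spec = config.planted_fragments[k % len(config.planted_fragments)]
        fold = (max(spec.target_folds) + 1 + k) % config.n_folds
        dom_idx = config.domains_per_fold - 1
        if (fold, dom_idx) not in placements:
            placements[(fold, dom_idx)] = (spec, "decoy")

    records: list[DomainRecord] = []
    for fold in range(config.n_folds):
        for dom in range(config.domains_per_fold):
            domain_id = f"f{fold}d{dom}"
            rng = np.random.default_rng(child_seed(config.seed, domain_id))
            insert = None
            planted = placements.get((fold, dom))
            if planted is not None:
                spec, kind = planted
                tc, ts, mut = templates[spec.fragment_id]
                if kind == "homolog":
                    insert = plant_fragment_instance(
                        tc,
                        ts,
                        spec.sequence_identity,
                        spec.coord_noise,
                        rng,
                        mutable_positions=mut,
                    )
                else:
                    insert = make_analog_decoy(tc, ts, rng)
            coords, sequence, interval = build_domain(
                config.fold_topologies[fold], rng, insert=insert
            )
            # Rate heterogeneity: the conserved core of a planted homologous
            # fragment is under constraint and evolves slowly in the MSA.
            rates = np.full(len(sequence), config.msa_mutation_rate)
            if planted is not None and planted[1] == "homolog" and interval:
                spec = planted[0]
                mut = templates[spec.fragment_id][2]
                conserved = np.setdiff1d(np.arange(spec.length), mut)
                rates[interval[0] - 1 + conserved] = CONSERVED_MSA_RATE
                rates[interval[0] - 1 + mut] = VARIABLE_MSA_RATE
            msa = synthesize_msa(
                sequence, config.msa_depth, config.msa_mutation_rate, rng, rates=rates
            )
            cb = pseudo_side_chains(coords)
            atoms = np.concatenate([coords, cb])
            atom_res = np.concatenate(
                [np.arange(1, len(coords) + 1), np.arange(1, len(coords) + 1)]
            )
            rec = DomainRecord(
                domain_id=domain_id,
                sequence=sequence,
                coords=coords,
                msa=msa,
                label=ClassificationLabel.from_sccs(_sccs(fold, dom)),
                atoms=atoms,
                atom_res=atom_res,
            )
            records.append(rec)
            if planted is not None and interval is not None:
                truth.instances.append(
                    PlantedInstance(
                        fragment_id=planted[0].fragment_id,
                        interval=SegmentInterval(domain_id, *interval),
                        kind=planted[1],
                    )
                )

    by_id = {r.domain_id: r for r in records}
    for lp in config.ligand_placements:
        homs = truth.homolog_instances(lp.fragment_id)
        if not homs:
            continue
        inst = homs[0]
        rec = by_id[inst.interval.domain_id]
        rng = np.random.default_rng(
            child_seed(config.seed, f"ligand:{lp.fragment_id}:{lp.category}")
        )
        lig = place_ligand(
            rec, inst.interval, lp.category, lp.n_contact_atoms, lp.distance, rng
        )
        rec.ligands.append(lig)
        truth.ligands.append(
            {
                "domain_id": rec.domain_id,
                "fragment_id": lp.fragment_id,
                "category": lp.category,
                "het_code": lig.het_code,
                "n_contact_atoms": lp.n_contact_atoms,
                "distance": lp.distance,
            }
        )
    return records, truth


# ---------------------------------------------------------------------------
# motif library (reference-set baseline input)

#: Loop step budget (A per residue).  Deliberately shorter than the chain
#: step so connecting loops curl into tight turns whose local geometry does
#: not mimic an extended strand.
LOOP_STEP = 2.8


def _arc_points(start, end, n_points, v):
    """Circular-arc loop between two anchors, bulging along unit vector v."""
    from scipy.optimize import brentq

    chord_vec = end - start
    chord = np.linalg.norm(chord_vec)
    total = max((n_points + 1) * LOOP_STEP, chord * 1.05)
    if chord >= total:  # nearly straight: interpolate
        ts = np.linspace(0, 1, n_points + 2)[1:-1]
        return start + ts[:, None] * chord_vec[None, :]
    u = chord_vec / chord

    def gap(phi):
        return 2.0 * (total / phi) * np.sin(phi / 2.0) - chord

    phi = brentq(gap, 1e-6, 2.0 * np.pi - 1e-6)
    R = total / phi
    mid = 0.5 * (start + end)
    center = mid - v * R * np.cos(phi / 2.0)
    e1 = start - center
    e1 /= np.linalg.norm(e1)
    e2_full = np.cross(np.cross(e1, u), e1)
    e2 = e2_full / np.linalg.norm(e2_full)
    endpt = center + R * (np.cos(phi) * e1 + np.sin(phi) * e2)
    if np.linalg.norm(endpt - end) > 1e-3:
        e2 = -e2
    thetas = np.linspace(0.0, phi, n_points + 2)[1:-1]
    return center + R * (
        np.cos(thetas)[:, None] * e1[None, :] + np.sin(thetas)[:, None] * e2[None, :]
    )


def _arc_loop(
    start: np.ndarray, end: np.ndarray, n_points: int, context: np.ndarray
) -> np.ndarray:
    """Loop residues on a circular arc with ~3.8 A steps.

    The arc length matches (n_points + 1) * 3.8; among candidate bulge
    directions perpendicular to the chord, the one with the largest
    clearance from the ``context`` atoms is used.
    """
    chord_vec = end - start
    chord = np.linalg.norm(chord_vec)
    if chord < 1e-9:
        u = np.array([1.0, 0.0, 0.0])
    else:
        u = chord_vec / chord
    base = np.cross(u, np.array([0.0, 0.0, 1.0]))
    if np.linalg.norm(base) < 1e-6:
        base = np.cross(u, np.array([0.0, 1.0, 0.0]))
    base /= np.linalg.norm(base)
    other = np.cross(u, base)
    other /= np.linalg.norm(other)
    best, best_clear = None, -1.0
    for a, b in [(1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (1, -1), (-1, 1), (-1, -1)]:
        v = a * base + b * other
        v /= np.linalg.norm(v)
        pts = _arc_points(start, end, n_points, v)
        clear = _min_dist(pts, context)
        if clear > best_clear:
            best, best_clear = pts, clear
    return best


def _explicit_hairpin(
    kind1: str, len1: int, loop: int, kind2: str, len2: int, compact: bool
) -> np.ndarray:
    """Two SSEs joined by a loop; antiparallel packed if compact, colinear
    end-to-end otherwise."""
    s1 = make_ideal_sse(kind1, len1)
    s2 = make_ideal_sse(kind2, len2)
    if compact:
        # pack s2 antiparallel next to s1; wider axis offset when a helix
        # is involved (helix radius 2.3 A on each side)
        offset = 5.0 if (kind1 == "E" and kind2 == "E") else 9.0
        flip = np.diag([1.0, -1.0, -1.0])  # proper rotation, reverses z
        # align the SSE axes (both run along z at x = 0): shift the flipped
        # element to x = offset and start it at the z height of s1's end
        s2p = s2 @ flip + np.array([offset, 0.0, s1[-1, 2]])
    else:
        s2p = s2 - s2[0] + s1[-1] + np.array([0.0, 0.0, CHAIN_STEP * (loop + 1)])
    parts = [s1]
    if loop > 0:
        context = np.concatenate([s1[:-1], s2p[1:]])
        parts.append(_arc_loop(s1[-1], s2p[0], loop, context))
    parts.append(s2p)
    return np.concatenate(parts)


def make_motif_library(
    n_clusters: int = 12, seed: int = 7, target_len: int = 24
) -> list[dict]:
    """Synthetic supersecondary-motif library in the documented JSON schema.

    Clusters are ordered by descending frequency; members carry coordinates,
    an SSE string, and a source (domain_id, interval).  A mix of eligible
    (two >= 6-residue SSEs, loop <= 6, exact target length) and ineligible
    geometries is produced so selection rules have something to reject.
    """
    rng = np.random.default_rng(seed)
    library = []
    shapes = [("H", "H"), ("E", "E"), ("H", "E"), ("E", "H")]
    for k in range(n_clusters):
        kind1, kind2 = shapes[k % len(shapes)]
        members = []
        for j in range(2):
            if k % 4 == 3 and j == 0:
                # ineligible representative: over-long loop
                loop = 7
                len1 = (target_len - loop) // 2
                len2 = target_len - loop - len1
            else:
                loop = int(rng.integers(3, 7))
                len1 = int(rng.integers(6, target_len - loop - 6 + 1))
                len2 = target_len - loop - len1
            compact = not (k % 5 == 4 and j == 0)
            coords = _explicit_hairpin(kind1, len1, loop, kind2, len2, compact)
            sse = kind1 * len1 + "C" * loop + kind2 * len2
            members.append(
                {
                    "domain_id": f"m{k}_{j}",
                    "start": 1,
                    "end": len(sse),
                    "sse": sse,
                    "coords": coords.round(3).tolist(),
                }
            )
        library.append(
            {
                "cluster_id": f"smc{k:03d}",
                "frequency": int(1000 - 50 * k),
                "members": members,
            }
        )
    return library


# ---------------------------------------------------------------------------
# synthetic correlation hits (divergence gradient vs independent noise)

def make_correlation_hits(
    n_per_partition: int = 500, seed: int = 0
) -> list:
    """Synthetic (tm, seq_score) hit sets for the correlation contrast.

    Homolog hits follow a divergence gradient: sequence score decays
    linearly with structural divergence plus Gaussian scatter.  Analog hits
    have sequence scores independent of tm.
    """
    from .correlation import ScanHit

    rng = np.random.default_rng(seed)
    hits = []
    tm_h = rng.uniform(0.5, 0.95, size=n_per_partition)
    seq_h = -0.6 + 1.6 * tm_h + rng.normal(scale=0.3, size=n_per_partition)
    tm_a = rng.uniform(0.5, 0.95, size=n_per_partition)
    seq_a = rng.normal(loc=-0.2, scale=0.3, size=n_per_partition)
    for i in range(n_per_partition):
        hits.append(
            ScanHit(
                query_fragment_id="sim",
                target_domain_id=f"h{i}",
                target_interval=SegmentInterval(f"h{i}", 1, 24),
                tm=float(tm_h[i]),
                seq_score=float(seq_h[i]),
                partition="homolog",
            )
        )
        hits.append(
            ScanHit(
                query_fragment_id="sim",
                target_domain_id=f"a{i}",
                target_interval=SegmentInterval(f"a{i}", 1, 24),
                tm=float(tm_a[i]),
                seq_score=float(seq_a[i]),
                partition="analog",
            )
        )
    return hits
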