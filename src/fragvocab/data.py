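"""Core domain types shared across the pipeline.

Residue indexing convention: residues are numbered 1..L, contiguous within a
domain; all intervals are 1-based and closed on both ends, matching the
residue-range conventions of structural classification databases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical amino-acid alphabet (alphabetical one-letter order). 'X' is
#: accepted in sequences but carries no profile counts.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

#: Robinson & Robinson amino-acid background frequencies.
BACKGROUND_FREQS = np.array(
    [
        0.07805,  # A
        0.01925,  # C
        0.05364,  # D
        0.06295,  # E
        0.03856,  # F
        0.07377,  # G
        0.02199,  # H
        0.05142,  # I
        0.05744,  # K
        0.09019,  # L
        0.02243,  # M
        0.04487,  # N
        0.05203,  # P
        0.04264,  # Q
        0.05129,  # R
        0.07120,  # S
        0.05841,  # T
        0.06441,  # V
        0.01330,  # W
        0.03216,  # Y
    ]
)
BACKGROUND_FREQS = BACKGROUND_FREQS / BACKGROUND_FREQS.sum()


@dataclass(frozen=True)
class ClassificationLabel:
    """Hierarchical structural classification of a domain.

    The hierarchy is single-valued: a family belongs to exactly one
    superfamily, which belongs to exactly one fold, which belongs to one
    class.  Family- and superfamily-level agreement implies homology; shared
    fold alone implies only structural similarity.
    """

    family_id: str
    superfamily_id: str
    fold_id: str
    class_id: str

    @classmethod
    def from_sccs(cls, sccs: str) -> "ClassificationLabel":
        """Split a dotted classification code, e.g. ``d.41.5.1``."""
        parts = sccs.split(".")
        if len(parts) != 4:
            raise ValueError(f"expected 4 dotted fields in sccs code, got {sccs!r}")
        c, f, sf, fam = parts
        return cls(
            family_id=f"{c}.{f}.{sf}.{fam}",
            superfamily_id=f"{c}.{f}.{sf}",
            fold_id=f"{c}.{f}",
            class_id=c,
        )

    @property
    def sccs(self) -> str:
        return self.family_id


@dataclass(frozen=True)
class SegmentInterval:
    """A residue interval within one domain (1-based, closed)."""

    domain_id: str
    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid interval {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap(self, other: "SegmentInterval") -> int:
        """Number of residues shared with ``other`` (0 if different domain)."""
        if self.domain_id != other.domain_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def mutual_overlap_ge(self, other: "SegmentInterval", frac: float) -> bool:
        """True if the overlap covers at least ``frac`` of BOTH intervals."""
        ov = self.overlap(other)
        return ov >= frac * self.length and ov >= frac * other.length


@dataclass
class LigandAtomSet:
    """A bound chemical entity: 3-letter component code or a polymer tag.

    ``het_code`` is either a chemical component code (``SF4``, ``ZN``,
    ``FAD`` ...) or one of the polymer class tags ``DNA`` / ``RNA``.
    """

    het_code: str
    atoms: np.ndarray  # (n_atoms, 3) in Angstrom

    def __post_init__(self):
        self.atoms = np.asarray(self.atoms, dtype=float).reshape(-1, 3)
        if len(self.atoms) == 0:
            raise ValueError("ligand atom set must be non-empty")


@dataclass
class DomainRecord:
    """One classified domain: sequence, coordinates, MSA and labels.

    ``coords`` holds one C-alpha position per residue.  ``atoms`` optionally
    holds all atoms (e.g. C-alpha plus pseudo side-chain atoms) as an
    (n_atoms, 3) array with a parallel ``atom_res`` array of 1-based residue
    numbers; contact detection uses these when present.
    """

    domain_id: str
    sequence: str
    coords: np.ndarray  # (L, 3) C-alpha
    msa: list[str]
    label: ClassificationLabel
    sse: str | None = None
    atoms: np.ndarray | None = None
    atom_res: np.ndarray | None = None
    ligands: list[LigandAtomSet] = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        L = len(self.sequence)
        if len(self.coords) != L:
            raise ValueError(
                f"{self.domain_id}: sequence length {L} != {len(self.coords)} residues"
            )
        if self.msa:
            row1 = ungapped(self.msa[0])
            if len(row1) != L:
                raise ValueError(
                    f"{self.domain_id}: MSA row 1 ungapped length "
                    f"{len(row1)} != sequence length {L}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def segment_coords(self, seg: SegmentInterval) -> np.ndarray:
        return self.coords[seg.start - 1 : seg.end]

    def fragment_atoms(self, seg: SegmentInterval) -> np.ndarray:
        """All atoms of the residues in ``seg`` (falls back to C-alpha)."""
        if self.atoms is None:
            return self.segment_coords(seg)
        mask = (self.atom_res >= seg.start) & (self.atom_res <= seg.end)
        return self.atoms[mask]


def ungapped(row: str) -> str:
    """Strip alignment gap characters ('-', '.') and lowercase insertions."""
    return "".join(c for c in row if c.isupper())
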