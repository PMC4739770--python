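"""Ligand-contact annotation of fragment instances.

A fragment is deemed to interact with a bound entity (nucleic acid, metal,
iron-sulfur cluster, nucleotide or nucleotide-derived cofactor) if it makes
at least three inter-atomic contacts to it within 3 A.  The rule presumes
all-atom coordinates; with C-alpha-only structures the cutoff is widened to
5 A and a warning logged.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial.distance import cdist

from .data import DomainRecord, LigandAtomSet, SegmentInterval
from .pipeline import FragmentCluster

logger = logging.getLogger(__name__)

CONTACT_DIST = 3.0  # Angstrom
MIN_CONTACTS = 3
CA_ONLY_DIST = 5.0  # widened cutoff when side chains are absent

#: Chemical component code -> interaction category.  Codes cover the
#: entities annotated in the fragment survey; extensible via config.
LIGAND_CATEGORIES: dict[str, str] = {
    # nucleic-acid polymer residues and tags
    **{c: "nucleic_acid" for c in ["DNA", "RNA", "A", "C", "G", "U", "DA", "DC", "DG", "DT"]},
    # metals and metal-carrying groups
    **{
        c: "metal"
        for c in ["ZN", "CA", "FE", "FE2", "FEC", "MG", "MN", "NI", "CU", "HEM", "HEC"]
    },
    # iron-sulfur clusters
    **{c: "iron_sulfur" for c in ["SF4", "FES", "F3S"]},
    # nucleotides and nucleotide-derived cofactors
    **{
        c: "nucleotide_cofactor"
        for c in [
            "ATP", "ADP", "AMP", "ANP", "GTP", "GDP", "DGP", "DCP", "CTP", "CTD",
            "TMP", "UMP", "FAD", "FMN", "NAD", "NAP", "NAI", "NAJ", "NEA", "NDP",
            "NMN", "APR", "LNC", "A3D", "ODP", "UMA", "SAH", "SAM", "COA",
        ]
    },
}


def detect_contacts(
    fragment_atoms: np.ndarray,
    ligand: LigandAtomSet,
    dist_max: float = CONTACT_DIST,
    min_contacts: int = MIN_CONTACTS,
) -> tuple[bool, int]:
    """Count (fragment atom, ligand atom) pairs within ``dist_max``.

    Returns ``(interacting, n_contacts)`` with ``interacting`` true when the
    pair count reaches ``min_contacts``.
    """
    fragment_atoms = np.asarray(fragment_atoms, float).reshape(-1, 3)
    if len(fragment_atoms) == 0:
        raise ValueError("empty fragment atom set")
    d = cdist(fragment_atoms, ligand.atoms)
    n = int(np.sum(d <= dist_max))
    return n >= min_contacts, n


def categorize_ligand(
    het_code: str, table: dict[str, str] | None = None
) -> str:
    """Interaction category for a chemical component code; unknown -> other."""
    table = LIGAND_CATEGORIES if table is None else table
    return table.get(het_code.upper(), "other")


def annotate_clusters(
    clusters: list[FragmentCluster],
    structures: dict[str, DomainRecord],
    manual_includes: list[tuple[str, str]] | None = None,
    dist_max: float = CONTACT_DIST,
    min_contacts: int = MIN_CONTACTS,
    category_table: dict[str, str] | None = None,
) -> list[FragmentCluster]:
    """Assign ligand categories to clusters by the contact rule.

    A cluster receives a category when ANY of its instances passes the
    contact test against a ligand of that category.  ``manual_includes``
    adds (cluster_id, category) pairs with provenance "curated" — the
    mechanism for interactions known from evidence outside the coordinate
    files, such as complexes solved only at low resolution or by NMR.
    """
    for cluster in clusters:
        for inst in cluster.instances:
            rec = structures.get(inst.domain_id)
            if rec is None:
                logger.warning(
                    "no structure for %s; instance skipped", inst.domain_id
                )
                continue
            atoms = rec.fragment_atoms(inst)
            cutoff = dist_max
            if rec.atoms is None:
                logger.warning(
                    "%s has C-alpha only; widening contact cutoff to %.1f A",
                    inst.domain_id,
                    CA_ONLY_DIST,
                )
                cutoff = CA_ONLY_DIST
            for lig in rec.ligands:
                ok, _ = detect_contacts(atoms, lig, cutoff, min_contacts)
                if ok:
                    cat = categorize_ligand(lig.het_code, category_table)
                    cluster.ligand_categories.setdefault(cat, "contact")
    if manual_includes:
        by_id = {c.cluster_id: c for c in clusters}
        for cid, cat in manual_includes:
            if cid not in by_id:
                raise ValueError(f"unknown cluster id in manual includes: {cid}")
            by_id[cid].ligand_categories[cat] = "curated"
            by_id[cid].provenance.append(f"curated:ligand:{cat}")
    return clusters


__all__ = [
    "LIGAND_CATEGORIES",
    "detect_contacts",
    "categorize_ligand",
    "annotate_clusters",
]
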