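"""Readers and writers for the formats the pipeline touches.

FASTA and aligned FASTA (A3M-convention lowercase insertions) via
Biopython; PDB coordinates and HET records via gemmi (first model, single
chain, altloc A preferred); classification tables and cluster reports as
TSV; ground-truth manifests and motif libraries as JSON.
"""

from __future__ import annotations

import json
import logging
import os
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .data import ClassificationLabel, DomainRecord, LigandAtomSet, SegmentInterval
from .pipeline import FragmentCluster
from .profiles import Profile

logger = logging.getLogger(__name__)

AA_3TO1 = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F", "GLY": "G",
    "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L", "MET": "M", "ASN": "N",
    "PRO": "P", "GLN": "Q", "ARG": "R", "SER": "S", "THR": "T", "VAL": "V",
    "TRP": "W", "TYR": "Y", "UNK": "X",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}


# ---------------------------------------------------------------------------
# FASTA / MSA

def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_msa(msa: list[str], path, name: str = "seq") -> None:
    records = [
        SeqRecord(Seq(row), id=f"{name}_{i}" if i else name, description="")
        for i, row in enumerate(msa)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_msa(path) -> list[str]:
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# PDB structures

def write_structure(record: DomainRecord, path) -> None:
    """Write a domain (C-alpha, optional pseudo side chains, ligands) as PDB."""
    st = gemmi.Structure()
    st.name = record.domain_id
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, aa in enumerate(record.sequence):
        res = gemmi.Residue()
        res.name = AA_1TO3.get(aa, "UNK")
        res.seqid = gemmi.SeqId(i + 1, " ")
        ca = gemmi.Atom()
        ca.name = "CA"
        ca.element = gemmi.Element("C")
        ca.pos = gemmi.Position(*record.coords[i])
        res.add_atom(ca)
        if record.atoms is not None:
            extra = record.atoms[record.atom_res == i + 1]
            for k, pos in enumerate(extra[1:], start=1):  # first is CA itself
                cb = gemmi.Atom()
                cb.name = "CB" if k == 1 else f"C{k + 1}"
                cb.element = gemmi.Element("C")
                cb.pos = gemmi.Position(*pos)
                res.add_atom(cb)
        chain.add_residue(res)
    model.add_chain(chain)
    lig_chain = gemmi.Chain("L")
    for j, lig in enumerate(record.ligands):
        res = gemmi.Residue()
        res.name = lig.het_code
        res.seqid = gemmi.SeqId(j + 1, " ")
        res.het_flag = "H"
        for k, pos in enumerate(lig.atoms):
            at = gemmi.Atom()
            at.name = f"X{k + 1}"
            at.element = gemmi.Element("C")
            at.pos = gemmi.Position(*pos)
            res.add_atom(at)
        lig_chain.add_residue(res)
    if len(record.ligands):
        model.add_chain(lig_chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def read_structure(path):
    """Read (sequence, CA coords, all atoms, atom residue ids, ligands).

    Uses the first model only; altloc A (or blank) preferred; residues with
    non-amino-acid names are collected as ligands.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    seq = []
    ca = []
    atoms = []
    atom_res = []
    ligands = []
    for chain in model:
        for res in chain:
            if res.name in AA_3TO1:
                sel = [a for a in res if a.altloc in ("", "A", "\x00")]
                ca_atom = next((a for a in sel if a.name == "CA"), None)
                if ca_atom is None:
                    continue
                seq.append(AA_3TO1[res.name])
                ca.append([ca_atom.pos.x, ca_atom.pos.y, ca_atom.pos.z])
                for a in sel:
                    atoms.append([a.pos.x, a.pos.y, a.pos.z])
                    atom_res.append(len(seq))
            else:
                pts = [[a.pos.x, a.pos.y, a.pos.z] for a in res]
                if pts:
                    ligands.append(LigandAtomSet(het_code=res.name, atoms=np.asarray(pts)))
    return (
        "".join(seq),
        np.asarray(ca),
        np.asarray(atoms) if atoms else None,
        np.asarray(atom_res) if atom_res else None,
        ligands,
    )


# ---------------------------------------------------------------------------
# classification table and domain library

def write_classification(records: list[DomainRecord], path) -> None:
    rows = [
        {
            "domain_id": r.domain_id,
            "sccs": r.label.sccs,
            "range": f"1-{len(r)}",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_classification(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"domain_id", "sccs", "range"}
    if not required.issubset(df.columns):
        raise ValueError(f"classification table must have columns {sorted(required)}")
    return df


def write_domain_library(records: list[DomainRecord], outdir) -> None:
    outdir = Path(outdir)
    (outdir / "msas").mkdir(parents=True, exist_ok=True)
    (outdir / "structs").mkdir(parents=True, exist_ok=True)
    write_fasta({r.domain_id: r.sequence for r in records}, outdir / "seqs.fasta")
    for r in records:
        write_msa(r.msa, outdir / "msas" / f"{r.domain_id}.fasta", name=r.domain_id)
        write_structure(r, outdir / "structs" / f"{r.domain_id}.pdb")
    write_classification(records, outdir / "classification.tsv")


def read_domain_library(
    seq_path, msa_dir, struct_dir, classification_path
) -> list[DomainRecord]:
    """Assemble DomainRecords from on-disk pieces cross-referenced by id.

    The top-level inputs must exist (fatal otherwise); records whose
    per-domain files are missing or whose sequence/structure lengths
    disagree are skipped with a logged warning.
    """
    for p in (seq_path, classification_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    seqs = read_fasta(seq_path)
    table = read_classification(classification_path)
    records = []
    for _, row in table.iterrows():
        did = row["domain_id"]
        struct_path = Path(struct_dir) / f"{did}.pdb"
        msa_path = Path(msa_dir) / f"{did}.fasta"
        if not struct_path.exists():
            logger.warning("%s: structure file missing; record skipped", did)
            continue
        if did not in seqs:
            logger.warning("%s: sequence missing from FASTA; record skipped", did)
            continue
        msa = read_msa(msa_path) if msa_path.exists() else [seqs[did]]
        seq_pdb, coords, atoms, atom_res, ligs = read_structure(struct_path)
        if len(coords) != len(seqs[did]):
            logger.warning(
                "%s: sequence length %d != %d residues in structure; skipped",
                did,
                len(seqs[did]),
                len(coords),
            )
            continue
        try:
            rec = DomainRecord(
                domain_id=did,
                sequence=seqs[did],
                coords=coords,
                msa=msa,
                label=ClassificationLabel.from_sccs(row["sccs"]),
                atoms=atoms,
                atom_res=atom_res,
                ligands=ligs,
            )
        except ValueError as exc:
            logger.warning("%s: %s; record skipped", did, exc)
            continue
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# curated fragment source data (per-fragment alignment blocks)

def read_fragment_source_data(path) -> list[dict]:
    """Parse per-fragment blocks of aligned members.

    Dialect: blocks separated by blank lines.  Each block starts with a
    header line ``# fragment <id>``; member lines are
    ``<accession>/<start>-<end>[*] <aligned sequence>`` where a trailing
    ``*`` on the range marks an additional within-domain copy.  Returns one
    dict per fragment: ``{"fragment_id", "members": [{"accession",
    "interval", "duplicate", "alignment"}]}``.
    """
    with open(path) as fh:
        text = fh.read()
    entries = []
    for block in [b for b in text.split("\n\n") if b.strip()]:
        lines = [ln for ln in block.strip().splitlines() if ln.strip()]
        header = lines[0].strip()
        if not header.startswith("# fragment"):
            raise ValueError(f"malformed block header: {header!r}")
        frag_id = header.split(None, 2)[2]
        members = []
        for ln in lines[1:]:
            try:
                acc_range, aln = ln.split(None, 1)
                acc, rng = acc_range.split("/")
                dup = rng.endswith("*")
                rng = rng.rstrip("*")
                start, end = (int(x) for x in rng.split("-"))
            except ValueError as exc:
                raise ValueError(
                    f"malformed member line in fragment {frag_id}: {ln!r}"
                ) from exc
            members.append(
                {
                    "accession": acc,
                    "interval": SegmentInterval(acc, start, end),
                    "duplicate": dup,
                    "alignment": aln.strip(),
                }
            )
        if not members:
            raise ValueError(f"fragment {frag_id}: no members")
        entries.append({"fragment_id": frag_id, "members": members})
    return entries


# ---------------------------------------------------------------------------
# cluster reports

REPORT_COLUMNS = [
    "cluster_id",
    "n_folds",
    "n_superfamilies",
    "repetition",
    "global_flag",
    "consensus_len",
    "ligand_categories",
    "members",
]


def write_cluster_report(clusters: list[FragmentCluster], path) -> None:
    """One TSV row per cluster, ordered by cluster id."""
    rows = []
    for c in sorted(clusters, key=lambda c: c.cluster_id):
        cats = ",".join(
            f"{cat}:{prov}" for cat, prov in sorted(c.ligand_categories.items())
        )
        members = ";".join(
            f"{i.domain_id}:{i.start}-{i.end}" for i in c.instances
        )
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "n_folds": c.n_folds,
                "n_superfamilies": c.n_superfamilies,
                "repetition": int(c.repetition_flag),
                "global_flag": int(c.global_flag),
                "consensus_len": c.consensus_len,
                "ligand_categories": cats,
                "members": members,
            }
        )
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_cluster_report(path) -> list[FragmentCluster]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    clusters = []
    for _, row in df.iterrows():
        instances = []
        if row["members"]:
            for tok in row["members"].split(";"):
                dom, rng = tok.rsplit(":", 1)
                s, e = (int(x) for x in rng.split("-"))
                instances.append(SegmentInterval(dom, s, e))
        cats = {}
        if row["ligand_categories"]:
            for tok in row["ligand_categories"].split(","):
                cat, prov = tok.split(":")
                cats[cat] = prov
        clusters.append(
            FragmentCluster(
                cluster_id=row["cluster_id"],
                instances=instances,
                n_folds=int(row["n_folds"]),
                n_superfamilies=int(row["n_superfamilies"]),
                repetition_flag=bool(int(row["repetition"])),
                global_flag=bool(int(row["global_flag"])),
                consensus_len=int(row["consensus_len"]),
                ligand_categories=cats,
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# profiles and manifests

def write_profile(profile: Profile, path) -> None:
    """Tabular text: one row per column, 20 probability fields plus neff."""
    from .data import AA_ALPHABET

    df = pd.DataFrame(profile.columns, columns=list(AA_ALPHABET))
    df.insert(0, "neff", profile.neff)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_profile(path, background=None) -> Profile:
    from .data import BACKGROUND_FREQS

    df = pd.read_csv(path, sep="\t")
    neff = df.pop("neff").to_numpy()
    cols = df.to_numpy(float)
    cols = cols / cols.sum(axis=1, keepdims=True)
    return Profile(
        columns=cols,
        neff=neff,
        background=BACKGROUND_FREQS if background is None else background,
    )


def write_manifest(truth, config, path) -> None:
    """Ground-truth manifest as JSON (fully regenerable from config+seed)."""
    payload = {
        "config": {
            "n_folds": config.n_folds,
            "domains_per_fold": config.domains_per_fold,
            "fold_topologies": config.fold_topologies,
            "seed": config.seed,
            "msa_depth": config.msa_depth,
            "msa_mutation_rate": config.msa_mutation_rate,
            "n_decoys": config.n_decoys,
            "planted_fragments": [
                {
                    "fragment_id": s.fragment_id,
                    "length": s.length,
                    "target_folds": s.target_folds,
                    "sequence_identity": s.sequence_identity,
                    "coord_noise": s.coord_noise,
                }
                for s in config.planted_fragments
            ],
        },
        "instances": [
            {
                "fragment_id": pi.fragment_id,
                "domain_id": pi.interval.domain_id,
                "start": pi.interval.start,
                "end": pi.interval.end,
                "kind": pi.kind,
            }
            for pi in truth.instances
        ],
        "ligands": truth.ligands,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def emit_dataset(config=None, outdir="dataset"):
    """Generate and write the full synthetic dataset plus manifest.

    Writes FASTA sequences, per-domain MSAs, PDB structures with ligand HET
    records, the classification TSV, a motif-library JSON and the
    ground-truth manifest; byte-identical across runs with the same config.
    """
    from .synthetic import SyntheticConfig, generate_library, make_motif_library

    config = config or SyntheticConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truth = generate_library(config)
    write_domain_library(records, outdir)
    with open(outdir / "motifs.json", "w") as fh:
        json.dump(make_motif_library(seed=config.seed), fh, indent=1, sort_keys=True)
        fh.write("\n")
    write_manifest(truth, config, outdir / "manifest.json")
    return records, truth


__all__ = [
    "read_fasta",
    "write_fasta",
    "read_msa",
    "write_msa",
    "read_structure",
    "write_structure",
    "read_classification",
    "write_classification",
    "read_domain_library",
    "write_domain_library",
    "read_fragment_source_data",
    "read_cluster_report",
    "write_cluster_report",
    "read_profile",
    "write_profile",
    "write_manifest",
    "emit_dataset",
]
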