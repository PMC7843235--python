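"""Tabular and sequence I/O for the pipeline.

All tables are TSV with headers; contexts/candidates can also be written
as FASTA (record ids encode ``snv_id|start|len|mut`` or ``|wt``); count
matrices are read from Matrix-Market triplets with gene/barcode TSVs or
from dense TSV; fitted models and pool designs are JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.io import mmread

from .affinity_dai import AffinityPair, DaiPoint, ScalingParams
from .sc_cluster import CountMatrix
from .screen_sim import GrowthCurve, PoolDesign
from .variant_peptides import CandidateEpitope, ContextPeptide, SnvRecord

SNV_COLUMNS = ["snv_id", "gene", "protein_pos", "ref_aa", "alt_aa", "expressed", "validated"]
AFFINITY_COLUMNS = ["snv_id", "allele", "peptide", "ic50_mut_nM", "ic50_wt_nM", "verified_epitope"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required columns {missing}")


def read_snv_table(path: str | Path) -> list[SnvRecord]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, SNV_COLUMNS, "SNV table")
    return [
        SnvRecord(
            snv_id=str(r.snv_id),
            gene=str(r.gene),
            protein_pos=int(r.protein_pos),
            ref_aa=str(r.ref_aa),
            alt_aa=str(r.alt_aa),
            expressed=bool(r.expressed),
            validated=bool(r.validated),
        )
        for r in df.itertuples()
    ]


def read_proteins_fasta(path: str | Path) -> dict[str, str]:
    """Protein FASTA keyed by record id (gene name)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_contexts_fasta(path: str | Path, contexts: Sequence[ContextPeptide]) -> None:
    records = []
    for c in contexts:
        records.append(SeqRecord(Seq(c.mut_seq), id=f"{c.snv_id}|{c.mut_offset}|mut", description=""))
        records.append(SeqRecord(Seq(c.wt_seq), id=f"{c.snv_id}|{c.mut_offset}|wt", description=""))
    SeqIO.write(records, str(path), "fasta")


def write_candidates(path: str | Path, candidates: Sequence[CandidateEpitope],
                     fmt: str = "tsv") -> None:
    if fmt == "tsv":
        pd.DataFrame([asdict(c) for c in candidates]).to_csv(path, sep="\t", index=False)
    elif fmt == "fasta":
        records = []
        for c in candidates:
            stem = f"{c.snv_id}|{c.start}|{c.length}"
            records.append(SeqRecord(Seq(c.mut_kmer), id=f"{stem}|mut", description=""))
            records.append(SeqRecord(Seq(c.wt_kmer), id=f"{stem}|wt", description=""))
        SeqIO.write(records, str(path), "fasta")
    else:
        raise ValueError(f"unknown candidate format {fmt!r}")


def read_affinity_table(path: str | Path) -> list[AffinityPair]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, AFFINITY_COLUMNS, "affinity table")
    return [
        AffinityPair(
            snv_id=str(r.snv_id),
            allele=str(r.allele),
            peptide=str(r.peptide),
            ic50_mut=float(r.ic50_mut_nM),
            ic50_wt=float(r.ic50_wt_nM),
            verified_epitope=bool(r.verified_epitope),
        )
        for r in df.itertuples()
    ]


def affinity_pairs_from_frame(df: pd.DataFrame) -> list[AffinityPair]:
    """Build AffinityPairs from a landscape-style DataFrame."""
    _require_columns(df, AFFINITY_COLUMNS, "affinity frame")
    return [
        AffinityPair(
            snv_id=str(r.snv_id), allele=str(r.allele), peptide=str(r.peptide),
            ic50_mut=float(r.ic50_mut_nM), ic50_wt=float(r.ic50_wt_nM),
            verified_epitope=bool(r.verified_epitope),
        )
        for r in df.itertuples()
    ]


def read_labels(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["snv_id", "label"], "label table")
    return dict(zip(df["snv_id"].astype(str), df["label"].astype(str)))


def write_dai_points(path: str | Path, points: Sequence[DaiPoint],
                     scaling: ScalingParams | None = None) -> None:
    """DaiPoint TSV; scaling parameters go to a JSON sidecar for reuse."""
    pd.DataFrame([asdict(p) for p in points]).to_csv(path, sep="\t", index=False)
    if scaling is not None:
        sidecar = Path(str(path) + ".scaling.json")
        sidecar.write_text(json.dumps(asdict(scaling), indent=2))


def read_points_tsv(path: str | Path) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Read scaled points (columns snv_id, x, y[, label]) for fitting."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["snv_id", "x", "y"], "points table")
    ids = df["snv_id"].astype(str).tolist()
    labels = {}
    if "label" in df.columns:
        labels = dict(zip(ids, df["label"].astype(str)))
    return df[["x", "y"]].to_numpy(dtype=float), ids, labels


def write_pool_design(path: str | Path, design: PoolDesign) -> None:
    Path(path).write_text(
        json.dumps({"seed": design.seed, "pools": [list(p) for p in design.pools]}, indent=2)
    )


def read_pool_design(path: str | Path) -> PoolDesign:
    d = json.loads(Path(path).read_text())
    return PoolDesign(pools=tuple(tuple(p) for p in d["pools"]), seed=int(d["seed"]))


def write_growth_curves(path: str | Path, curves: Sequence[GrowthCurve]) -> None:
    rows = [
        {"subject_id": c.subject_id, "group": c.group, "day": t, "volume_mm3": v}
        for c in curves
        for t, v in zip(c.times, c.volumes)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_growth_curves(path: str | Path) -> list[GrowthCurve]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["subject_id", "group", "day", "volume_mm3"], "growth table")
    curves = []
    for (sid, grp), sub in df.groupby(["subject_id", "group"], sort=True):
        sub = sub.sort_values("day")
        curves.append(
            GrowthCurve(
                subject_id=str(sid), group=str(grp),
                times=tuple(float(t) for t in sub["day"]),
                volumes=tuple(float(v) for v in sub["volume_mm3"]),
            )
        )
    return curves


def read_count_matrix_mtx(mtx: str | Path, genes: str | Path, barcodes: str | Path) -> CountMatrix:
    """Matrix-Market counts (genes × cells) with one-column id files."""
    counts = np.asarray(mmread(str(mtx)).todense()).astype(np.int64)
    gene_ids = tuple(pd.read_csv(genes, sep="\t", header=None)[0].astype(str))
    cell_ids = tuple(pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str))
    return CountMatrix(counts=counts, gene_ids=gene_ids, cell_ids=cell_ids)


def read_count_matrix_tsv(path: str | Path) -> CountMatrix:
    """Dense TSV, genes in rows (index), cells in columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(
        counts=df.to_numpy(dtype=np.int64),
        gene_ids=tuple(df.index.astype(str)),
        cell_ids=tuple(df.columns.astype(str)),
    )


def write_count_matrix_tsv(path: str | Path, m: CountMatrix) -> None:
    pd.DataFrame(m.counts, index=list(m.gene_ids), columns=list(m.cell_ids)).to_csv(
        path, sep="\t"
    )


def load_config(path: str | Path) -> dict:
    """Load a YAML run config and check the basic shape."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def write_provenance(out_dir: str | Path, cfg: dict, seed: int | None) -> None:
    from . import __version__

    Path(out_dir, "provenance.json").write_text(
        json.dumps(
            {"config_hash": config_hash(cfg), "seed": seed, "neoclust_version": __version__},
            indent=2,
        )
    )
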