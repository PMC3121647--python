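"""Readers and writers for the package's plain-text interfaces.

Gene tables and pair tables are tab-separated with a header line, UTF-8,
``#`` comment lines allowed.  Gene order may alternatively come from GFF3
(ranks assigned by start coordinate).  BLAST input is NCBI tabular
(outfmt-6-like) plus a two-column protein-length table, since the tabular
hit line does not carry sequence lengths.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import (
    BlastHit,
    CorrespondenceRelation,
    Genome,
    InputError,
    LayeredDataGraph,
)
from .pnam import Partition
from .postprocess import PairSizeRecord, ProjectionRecord
from .spines import DONT_CARE, Spine

_BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except FileNotFoundError:
        raise InputError(f"no such file: {path}") from None
    except pd.errors.EmptyDataError:
        raise InputError(f"empty table: {path}") from None


def read_gene_table(
    path: str | Path,
    circular: Iterable[str] = (),
) -> list[Genome]:
    """Read a gene table (columns ``genome``, ``gene``, ``rank`` optional,
    ``strand`` optional and ignored by all algorithms).

    Genomes are numbered 1..n in order of first appearance; ``circular``
    names the genomes to treat as circular.  Missing ranks are assigned
    from row order within each genome.
    """
    df = _read_tsv(path)
    required = {"genome", "gene"}
    if not required <= set(df.columns):
        raise InputError(
            f"gene table {path} must have columns 'genome' and 'gene' "
            f"(found {list(df.columns)})"
        )
    circular_set = set(circular)
    genomes: list[Genome] = []
    order = list(dict.fromkeys(df["genome"]))
    for idx, name in enumerate(order, start=1):
        sub = df[df["genome"] == name]
        ids = list(sub["gene"])
        if "rank" in df.columns and sub["rank"].notna().all():
            ranked = sorted(zip(sub["rank"].astype(int), ids))
            ids = [gid for _, gid in ranked]
        genomes.append(
            Genome.from_ids(
                idx, ids, circular=(name in circular_set), name=str(name)
            )
        )
    unknown = circular_set - set(map(str, order))
    if unknown:
        raise InputError(f"--circular names unknown genomes: {sorted(unknown)}")
    return genomes


def read_gff_genome(
    path: str | Path,
    index: int,
    *,
    name: str | None = None,
    circular: bool = False,
    feature_type: str = "gene",
) -> Genome:
    """Build a genome from a GFF3 file: one rank per ``feature_type``
    feature, ordered by start coordinate (ties broken by id)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    feats = []
    for f in db.features_of_type(feature_type):
        gid = f.attributes.get("ID", [f.id])[0]
        feats.append((f.start, gid))
    if not feats:
        raise InputError(f"no {feature_type!r} features in {path}")
    feats.sort()
    return Genome.from_ids(
        index, [gid for _, gid in feats], circular=circular, name=name
    )


def read_pair_table(path: str | Path) -> CorrespondenceRelation:
    """Read an S pair table: first two columns are gene ids."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise InputError(f"pair table {path} needs at least two columns")
    rel = CorrespondenceRelation()
    for a, b in df.iloc[:, :2].itertuples(index=False):
        rel.add(str(a), str(b))
    return rel


def read_length_table(path: str | Path) -> dict[str, int]:
    """Two-column table: gene id, protein length."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise InputError(f"length table {path} needs two columns")
    return {
        str(gid): int(length)
        for gid, length in df.iloc[:, :2].itertuples(index=False)
    }


def read_blast_tabular(
    path: str | Path, lengths: Mapping[str, int]
) -> list[BlastHit]:
    """Read NCBI tabular (outfmt 6) hits, attaching protein lengths."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 12:
        raise InputError(
            f"BLAST tabular {path} needs the 12 standard outfmt-6 columns"
        )
    df.columns = _BLAST_COLUMNS + list(df.columns[12:])
    hits: list[BlastHit] = []
    for row in df.itertuples(index=False):
        q, s = str(row.qseqid), str(row.sseqid)
        for gid in (q, s):
            if gid not in lengths:
                raise InputError(f"no protein length for gene {gid!r}")
        hits.append(
            BlastHit(
                query_id=q,
                subject_id=s,
                p_value=float(row.evalue),
                percent_identity=float(row.pident),
                alignment_length=int(row.length),
                query_length=lengths[q],
                subject_length=lengths[s],
            )
        )
    return hits


# -- writers ----------------------------------------------------------------


def write_gene_table(genomes: Sequence[Genome], path: str | Path) -> None:
    rows = [
        {"genome": g.name, "gene": gene.gene_id, "rank": gene.rank}
        for g in genomes
        for gene in g
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_pair_table(S: CorrespondenceRelation, path: str | Path) -> None:
    pd.DataFrame(sorted(S.pairs), columns=["gene_a", "gene_b"]).to_csv(
        path, sep="\t", index=False
    )


def spine_row(spine: Spine) -> list[str]:
    return [s for s in spine.as_strings()]


def write_spines_tsv(spines: Iterable[Spine], n: int, path: str | Path) -> None:
    cols = [f"genome_{i}" for i in range(1, n + 1)]
    rows = sorted(spine_row(s) for s in spines)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_synton_tsv(
    P: Partition, D: LayeredDataGraph, path: str | Path
) -> None:
    """Synton report: id, spine count, cover, per-genome gene lists/spans."""
    from .postprocess import project_synton

    rows = []
    for idx, synton in enumerate(P, start=1):
        projections = {
            rec.genome_index: rec
            for rec in project_synton(synton, D, synton_id=idx)
        }
        row: dict[str, object] = {
            "synton_id": idx,
            "n_spines": synton.size,
            "cover": ",".join(map(str, synton.cover_layers)),
        }
        for i in range(1, D.n + 1):
            rec = projections.get(i)
            row[f"genes_{i}"] = ";".join(rec.genes) if rec else DONT_CARE
            row[f"span_{i}"] = (
                f"{rec.span[0]}-{rec.span[1]}" if rec else DONT_CARE
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def partition_payload(P: Partition, D: LayeredDataGraph) -> dict:
    from .postprocess import project_synton

    syntons = []
    for idx, synton in enumerate(P, start=1):
        syntons.append(
            {
                "id": idx,
                "n_spines": synton.size,
                "cover": list(synton.cover_layers),
                "spines": [list(s.as_strings()) for s in synton.sorted_spines()],
                "projections": [
                    {
                        "genome": rec.genome_index,
                        "genes": list(rec.genes),
                        "span": list(rec.span),
                        "gap_genes": rec.gap_genes,
                    }
                    for rec in project_synton(synton, D, synton_id=idx)
                ],
            }
        )
    return {"schema": "syntons/1", "n_genomes": D.n, "syntons": syntons}


def write_synton_json(
    P: Partition, D: LayeredDataGraph, path: str | Path
) -> None:
    Path(path).write_text(
        json.dumps(partition_payload(P, D), indent=1, sort_keys=True) + "\n"
    )


def write_projection_tsv(
    records: Iterable[ProjectionRecord], path: str | Path
) -> None:
    rows = [
        {
            "synton_id": r.synton_id,
            "genome": r.genome_index,
            "genes": ";".join(r.genes),
            "span_start": r.span[0],
            "span_end": r.span[1],
            "gap_genes": r.gap_genes,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_pair_sizes_tsv(
    records: Iterable[PairSizeRecord], path: str | Path
) -> None:
    rows = [
        {"gene_a": r.gene_a, "gene_b": r.gene_b, "max_size": r.max_size}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_bed_like(
    P: Partition, D: LayeredDataGraph, path: str | Path
) -> None:
    """Per-genome interval export (1-based ranks, inclusive)."""
    from .postprocess import project_synton

    lines = []
    for idx, synton in enumerate(P, start=1):
        for rec in project_synton(synton, D, synton_id=idx):
            lines.append(
                f"{D.genome(rec.genome_index).name}\t{rec.span[0]}\t"
                f"{rec.span[1]}\tsynton_{idx}"
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
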