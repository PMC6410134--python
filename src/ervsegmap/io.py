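"""Readers and writers for the pipeline's on-disk formats.

Alignment dialect
-----------------
ERV-associated mate pairs are exchanged as a tab-separated table with one
row per read pair. Columns::

    read_id        unique pair identifier
    line_id        pooled line (H, L or W)
    erv_id         ERV-library sequence hit by the ERV-side read
    erv_score      mapper score of that hit (integer, mapper scale)
    erv_orientation  sense/antisense of the read relative to the consensus
    erv_pos        0-based start of the read on the ERV consensus
    chrom          chromosome of the mate's unique anchor
    pos            0-based leftmost base of the anchor
    strand         anchor strand (+/-)
    anchor_quality "top" for a unique best placement, else "secondary"

BED output is written natively 0-based half-open; GFF3 input is converted
from 1-based closed on parse.
"""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

ALIGNMENT_COLUMNS = [
    "read_id",
    "line_id",
    "erv_id",
    "erv_score",
    "erv_orientation",
    "erv_pos",
    "chrom",
    "pos",
    "strand",
    "anchor_quality",
]

LOCI_COLUMNS = [
    "chrom",
    "start",
    "end",
    "locus_id",
    "score",
    "strand",
    "count_H",
    "count_L",
    "count_W",
    "relaxed_H",
    "relaxed_L",
    "relaxed_W",
    "erv_ids",
]


def write_alignments(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False, columns=ALIGNMENT_COLUMNS)


def read_alignments(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"erv_score": int, "erv_pos": int, "pos": int},
    )
    missing = set(ALIGNMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"alignment table {path} lacks columns: {sorted(missing)}")
    return df


def write_loci(loci, path) -> None:
    """Write candidate loci as a BED6+ table (strand column = orientation)."""
    rows = []
    for loc in loci:
        rows.append(
            {
                "chrom": loc.chromosome,
                "start": loc.start,
                "end": loc.end,
                "locus_id": loc.locus_id,
                "score": sum(loc.per_line_counts),
                "strand": "+" if loc.orientation == "sense" else "-",
                "count_H": loc.per_line_counts[0],
                "count_L": loc.per_line_counts[1],
                "count_W": loc.per_line_counts[2],
                "relaxed_H": loc.per_line_counts_relaxed[0],
                "relaxed_L": loc.per_line_counts_relaxed[1],
                "relaxed_W": loc.per_line_counts_relaxed[2],
                "erv_ids": ",".join(sorted(loc.erv_ids)),
            }
        )
    pd.DataFrame(rows, columns=LOCI_COLUMNS).to_csv(path, sep="\t", index=False)


def read_loci_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_stats(stats: dict, path) -> None:
    """Write a flat key=value stats file (e.g. per-line read-pair totals)."""
    with open(path, "w") as fh:
        for key in sorted(stats):
            fh.write(f"{key}={stats[key]}\n")


def read_stats(path) -> dict:
    out: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            try:
                out[key] = int(value)
            except ValueError:
                try:
                    out[key] = float(value)
                except ValueError:
                    out[key] = value
    return out


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta_lengths(path) -> dict[str, int]:
    from Bio import SeqIO

    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_bed3(intervals, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bed3(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_genes_bed12(genes, path) -> None:
    """Write gene models as single-block BED12 records."""
    with open(path, "w") as fh:
        for g in genes:
            size = g.end - g.start
            fh.write(
                "\t".join(
                    [
                        g.chromosome,
                        str(g.start),
                        str(g.end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(g.start),
                        str(g.end),
                        "0",
                        "1",
                        f"{size},",
                        "0,",
                    ]
                )
                + "\n"
            )


def read_genes_bed12(path):
    from ervsegmap.landscape import GeneModel

    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            genes.append(
                GeneModel(
                    gene_id=parts[3],
                    chromosome=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    strand=parts[5],
                )
            )
    return genes


def read_genes_gff3(path):
    """Collapse GFF3 gene/mRNA features to gene-level extremes.

    GFF3 is 1-based closed; converted to 0-based half-open.
    """
    from ervsegmap.landscape import GeneModel

    spans: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] not in ("gene", "mRNA", "transcript"):
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("Parent") or attrs.get("Name")
            if gid is None:
                continue
            start, end = int(parts[3]) - 1, int(parts[4])
            cur = spans.get(gid)
            if cur is None:
                spans[gid] = [parts[0], start, end, parts[6]]
            else:
                cur[1] = min(cur[1], start)
                cur[2] = max(cur[2], end)
    return [
        GeneModel(gene_id=gid, chromosome=c, start=s, end=e, strand=st)
        for gid, (c, s, e, st) in spans.items()
    ]


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
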