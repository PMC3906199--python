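"""Readers and writers for the formats the pipeline touches.

Expression matrices are tab-separated (genes in rows, arrays in columns,
header row of sample IDs); the sample design is a TSV with sample_id,
condition, timepoint_h, replicate, is_control.  Promoters are extracted
strand-aware from a genome FASTA + GFF3 gene models, or read from FASTA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

DESIGN_COLUMNS = ["sample_id", "condition", "timepoint_h", "replicate", "is_control"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PromoterSet:
    """Gene -> upstream sequence, with truncation flags at contig edges."""

    sequences: dict[str, str]
    provenance: str = "extracted"  # 'extracted' | 'synthetic'
    truncated: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, gene: str) -> str:
        return self.sequences[gene]


def read_expression(
    matrix_path: str | Path, design_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validated (expression matrix, sample design) pair.

    Samples present in the matrix but absent from the design are an error;
    design rows without a matrix column are dropped with a warning.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if matrix.index.duplicated().any():
        dup = matrix.index[matrix.index.duplicated()][0]
        raise ValueError(f"duplicate gene ID {dup!r} in {matrix_path}")
    if matrix.columns.duplicated().any():
        dup = matrix.columns[matrix.columns.duplicated()][0]
        raise ValueError(f"duplicate sample ID {dup!r} in {matrix_path}")
    for col in matrix.columns:
        if not np.issubdtype(matrix[col].dtype, np.number):
            bad = matrix[col][pd.to_numeric(matrix[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric value {bad.iloc[0]!r} at gene {bad.index[0]!r}, sample {col!r}"
            )
    if not np.isfinite(matrix.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")
    design = pd.read_csv(design_path, sep="\t")
    missing_cols = set(DESIGN_COLUMNS) - set(design.columns)
    if missing_cols:
        raise ValueError(f"design file missing columns {sorted(missing_cols)}")
    if design["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in design")
    design["is_control"] = design["is_control"].astype(bool)
    in_matrix_only = set(matrix.columns) - set(design["sample_id"])
    if in_matrix_only:
        raise ValueError(f"samples missing from design: {sorted(in_matrix_only)}")
    extra = set(design["sample_id"]) - set(matrix.columns)
    if extra:
        warnings.warn(f"dropping {len(extra)} design rows without matrix columns")
        design = design[design["sample_id"].isin(matrix.columns)].reset_index(drop=True)
    return matrix, design


def write_expression(
    matrix: pd.DataFrame, design: pd.DataFrame, matrix_path: str | Path, design_path: str | Path
) -> None:
    matrix.to_csv(matrix_path, sep="\t", index_label="gene")
    design[DESIGN_COLUMNS].to_csv(design_path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene ID per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: list[str] | set[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Plain FASTA reader returning uppercase sequences keyed by record ID."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks).upper()
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _parse_gff3_genes(gff3_path: str | Path) -> pd.DataFrame:
    rows = []
    with open(gff3_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", attrs.get("Name", parts[8]))
            rows.append(
                {
                    "gene": gene_id,
                    "seqid": parts[0],
                    "start": int(parts[3]),  # 1-based inclusive
                    "end": int(parts[4]),
                    "strand": parts[6],
                }
            )
    return pd.DataFrame(rows, columns=["gene", "seqid", "start", "end", "strand"])


def extract_promoters(
    genome_fasta: str | Path, gff3: str | Path, length: int = 500
) -> PromoterSet:
    """Strand-aware upstream sequences of each GFF3 gene.

    For a + strand gene the promoter is the ``length`` bases ending
    immediately before the gene start; for a - strand gene, the ``length``
    bases starting immediately after the gene end, reverse-complemented.
    Promoters truncated at contig boundaries are flagged.
    """
    genes = _parse_gff3_genes(gff3)
    fasta = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)
    seqs: dict[str, str] = {}
    truncated: set[str] = set()
    for rec in genes.itertuples():
        if rec.seqid not in fasta:
            raise ValueError(f"gene {rec.gene!r} is on missing contig {rec.seqid!r}")
        if rec.strand not in "+-":
            raise ValueError(f"gene {rec.gene!r} has strand {rec.strand!r}")
        contig_len = len(fasta[rec.seqid])
        if rec.strand == "+":
            # 0-based half-open window [start-1-length, start-1)
            end0 = rec.start - 1
            start0 = max(0, end0 - length)
            seq = str(fasta[rec.seqid][start0:end0])
        else:
            start0 = rec.end  # first base after the gene
            end0 = min(contig_len, start0 + length)
            seq = str(fasta[rec.seqid][start0:end0]).translate(_COMPLEMENT)[::-1]
        if len(seq) < length:
            truncated.add(rec.gene)
        seqs[rec.gene] = seq
    return PromoterSet(sequences=seqs, provenance="extracted", truncated=truncated)
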