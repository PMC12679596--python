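"""Readers and writers for the standard formats the pipeline touches.

All coordinates are held 0-based half-open (BED convention) internally.
GFF3's 1-based closed coordinates are converted exactly once, on read.
Strand is carried but never used by distance computations.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Phylo

VALID_MECHANISMS = {"WGD", "TD", "PD", "TRD", "DSD"}


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending line."""


@dataclass(frozen=True)
class GeneModel:
    """One gene locus; start/end are 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError(f"gene {self.gene_id}: empty chrom")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class AcrInterval:
    """One accessible chromatin region; 0-based half-open."""

    acr_id: str
    chrom: str
    start: int
    end: int
    tissue: str = ""
    ct_label: Optional[str] = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"ACR {self.acr_id}: start {self.start} >= end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CountsTable:
    """Pseudobulk counts: genes x (cell_type, replicate) samples.

    Column labels encode the sample as ``celltype.rep`` (last dot splits).
    """

    df: pd.DataFrame  # index: gene ids, columns: "celltype.rep"

    def __post_init__(self):
        if (self.df.to_numpy() < 0).any():
            raise ValueError("counts contain negative entries")
        if self.df.columns.duplicated().any():
            raise ValueError("duplicate sample labels")
        # every cell type needs >=1 replicate by construction; parse eagerly
        self._parsed = [split_sample_label(c) for c in self.df.columns]

    @property
    def genes(self) -> pd.Index:
        return self.df.index

    @property
    def samples(self) -> list[tuple[str, str]]:
        return list(self._parsed)

    @property
    def cell_types(self) -> list[str]:
        seen: dict[str, None] = {}
        for ct, _ in self._parsed:
            seen.setdefault(ct)
        return list(seen)

    def replicates_of(self, cell_type: str) -> list[str]:
        return [c for c, (ct, _) in zip(self.df.columns, self._parsed) if ct == cell_type]

    def subset_cell_types(self, keep: Sequence[str]) -> "CountsTable":
        keep = set(keep)
        cols = [c for c, (ct, _) in zip(self.df.columns, self._parsed) if ct in keep]
        return CountsTable(self.df[cols])

    @classmethod
    def from_tsv(cls, path) -> "CountsTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t")

    @classmethod
    def from_mtx(cls, mtx_path, genes_path, samples_path) -> "CountsTable":
        from scipy.io import mmread

        mat = mmread(str(mtx_path)).toarray()
        genes = [ln.strip() for ln in Path(genes_path).read_text().splitlines() if ln.strip()]
        samples = [ln.strip() for ln in Path(samples_path).read_text().splitlines() if ln.strip()]
        df = pd.DataFrame(mat, index=genes, columns=samples)
        return cls(df)


def split_sample_label(label: str) -> tuple[str, str]:
    """Parse a ``celltype.rep`` sample label (split on the last dot)."""
    if "." not in label:
        raise ParseError(f"sample label {label!r} lacks a '.rep' suffix")
    ct, rep = label.rsplit(".", 1)
    if not ct or not rep:
        raise ParseError(f"sample label {label!r} malformed")
    return ct, rep


@dataclass
class FamilyTree:
    """A rooted gene-family tree (Newick), queryable for sister pairs."""

    tree: "Phylo.BaseTree.Tree"

    @property
    def leaves(self) -> list[str]:
        return [t.name for t in self.tree.get_terminals()]

    def cherries(self) -> list[frozenset[str]]:
        """Sister-leaf pairs: internal nodes whose children are two leaves."""
        out = []
        for clade in self.tree.get_nonterminals():
            kids = clade.clades
            if len(kids) == 2 and all(k.is_terminal() for k in kids):
                out.append(frozenset(k.name for k in kids))
        return out

    @classmethod
    def from_newick(cls, text: str) -> "FamilyTree":
        try:
            tree = Phylo.read(_io.StringIO(text), "newick")
        except Exception as exc:  # Bio raises several types on malformed input
            raise ParseError(f"malformed Newick: {exc}") from exc
        ft = cls(tree)
        names = ft.leaves
        if any(n is None for n in names):
            raise ParseError("Newick contains unnamed leaves")
        if len(set(names)) != len(names):
            raise ParseError("duplicate leaf labels in Newick")
        return ft


def read_newick(path) -> FamilyTree:
    return FamilyTree.from_newick(Path(path).read_text())


def write_newick(path, text: str) -> None:
    Path(path).write_text(text if text.endswith("\n") else text + "\n")


# ---------------------------------------------------------------------------
# GFF3 (gene features only)

def read_gff3(path) -> list[GeneModel]:
    """Read ``gene`` features from a GFF3 file.

    1-based closed coordinates are converted to 0-based half-open here and
    nowhere else. Returns genes sorted by (chrom, start). Malformed lines and
    duplicate gene ids raise :class:`ParseError` naming the line number.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 columns, got {len(fields)}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from None
            if start_i < 1 or end_i < start_i:
                raise ParseError(f"{path}: line {lineno}: bad coordinates {start}..{end}")
            gene_id = _gff3_attr(attrs, "ID")
            if gene_id is None:
                raise ParseError(f"{path}: line {lineno}: gene feature lacks ID attribute")
            if gene_id in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            genes.append(GeneModel(gene_id, chrom, start_i - 1, end_i, strand if strand in "+-" else "."))
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def _gff3_attr(attrs: str, key: str) -> Optional[str]:
    for kv in attrs.split(";"):
        kv = kv.strip()
        if kv.startswith(key + "="):
            return kv[len(key) + 1 :]
    return None


def write_gff3(path, genes: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(
                f"{g.chrom}\t.\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# BED (ACR intervals)

def read_bed(path, tissue: str = "") -> list[AcrInterval]:
    """Read BED3+ ACR intervals.

    Column 4 (optional) is the ACR name; a missing name is synthesized as
    ``chrom:start-end``. Column 5 (optional) carries the cell-type label for
    cell-type-specific ACRs ('.' means none).
    """
    acrs: list[AcrInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from None
            if start >= end:
                raise ParseError(f"{path}: line {lineno}: start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else f"{chrom}:{start}-{end}"
            ct = fields[4] if len(fields) > 4 and fields[4] != "." else None
            acrs.append(AcrInterval(name, chrom, start, end, tissue=tissue, ct_label=ct))
    return acrs


def write_bed(path, acrs: Iterable[AcrInterval]) -> None:
    with open(path, "w") as fh:
        for a in acrs:
            ct = a.ct_label if a.ct_label is not None else "."
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.acr_id}\t{ct}\n")


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(path, seqs: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_genome(path) -> dict[str, str]:
    """Load a FASTA into a plain chrom -> sequence dict via pyfaidx."""
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def get_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Fetch a 0-based half-open slice from a dict or pyfaidx.Fasta genome."""
    if isinstance(genome, dict):
        return genome[chrom][start:end]
    return str(genome[chrom][start:end])


# ---------------------------------------------------------------------------
# Pair / quad tables

def read_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene1", "gene2", "mechanism"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: pair table needs columns {sorted(required)}")
    bad = set(df["mechanism"]) - VALID_MECHANISMS
    if bad:
        raise ParseError(f"{path}: unknown duplication mechanisms {sorted(bad)}")
    return df


def write_pairs(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_quads(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"set_id", "gene1", "gene2", "gene3", "gene4"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: quad table needs columns {sorted(required)}")
    return df


def write_quads(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)
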