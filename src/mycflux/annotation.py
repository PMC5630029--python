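"""Gene annotation loading and promoter/gene-body/TES window definition.

Coordinates are 0-based half-open internally (BED convention); GTF input
(1-based, closed) is converted on load.  The TSS is always the start of
transcription: for a minus-strand gene it is numerically the larger
coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GeneAnnotation", "RegionSet", "load_annotation", "define_regions"]


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene (its longest transcript), strand-oriented.

    ``tss``/``tes`` are genomic coordinates with the TSS at the start of
    transcription; ``exons`` are sorted, disjoint, half-open genomic
    intervals.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"{self.gene_id}: plus-strand gene needs tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"{self.gene_id}: minus-strand gene needs tss > tes")
        exons = tuple(sorted((int(a), int(b)) for a, b in self.exons))
        for (a, b) in exons:
            if not (self.start <= a < b <= self.end):
                raise ValueError(f"{self.gene_id}: exon [{a},{b}) outside gene span")
        for (_, b0), (a1, _) in zip(exons, exons[1:]):
            if a1 < b0:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        object.__setattr__(self, "exons", exons)

    @property
    def start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def end(self) -> int:
        return max(self.tss, self.tes)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RegionSet:
    """Per-gene promoter / gene-body / TES windows (half-open, genomic).

    Genes whose body would have non-positive length are kept in the table
    but flagged; flagged genes are excluded from RNAPII modeling.
    """

    df: pd.DataFrame

    def __post_init__(self):
        ok = ~self.df["flagged"]
        d = self.df[ok]
        for col in ("promoter", "body", "tes"):
            if np.any(d[f"{col}_end"] <= d[f"{col}_start"]):
                raise ValueError(f"non-positive {col} window on an unflagged gene")

    @property
    def kept_genes(self) -> np.ndarray:
        return self.df.index[~self.df["flagged"]].to_numpy(dtype=object)


# --------------------------------------------------------------------- load

def _parse_bed12(path: Path) -> list[GeneAnnotation]:
    genes: dict[str, GeneAnnotation] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) == 1:
                f = line.split()
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: BED record needs >= 6 fields")
            try:
                chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
                if len(f) >= 12:
                    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                    starts = [int(x) for x in f[11].rstrip(",").split(",")]
                    exons = [(start + s, start + s + sz) for s, sz in zip(starts, sizes)]
                else:
                    exons = [(start, end)]
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: malformed BED record ({e})") from None
            tss, tes = (start, end) if strand == "+" else (end, start)
            gene = GeneAnnotation(name, chrom, strand, tss, tes, tuple(exons))
            prev = genes.get(name)
            # longest transcript wins; tie -> first by coordinate
            if prev is None or gene.length > prev.length or (
                gene.length == prev.length and gene.start < prev.start
            ):
                genes[name] = gene
    return list(genes.values())


def _gtf_attributes(attr: str) -> dict:
    out = {}
    for part in attr.strip().rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def _parse_gtf(path: Path) -> list[GeneAnnotation]:
    # exon records grouped by (gene_id, transcript_id); transcript extent is
    # the exon hull, which also covers minimal GTFs lacking transcript lines
    tx: dict[tuple, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}:{lineno}: GTF record needs 9 tab-separated fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attr = f
            if feature != "exon":
                continue
            try:
                # GTF is 1-based closed; convert to 0-based half-open
                iv = (int(start) - 1, int(end))
                attrs = _gtf_attributes(attr)
                key = (attrs["gene_id"], attrs.get("transcript_id", attrs["gene_id"]))
            except (ValueError, KeyError) as e:
                raise ValueError(f"{path}:{lineno}: malformed GTF record ({e})") from None
            rec = tx.setdefault(key, {"chrom": chrom, "strand": strand, "exons": []})
            rec["exons"].append(iv)
    best: dict[str, GeneAnnotation] = {}
    for (gene_id, _tid), rec in tx.items():
        exons = sorted(rec["exons"])
        start, end = exons[0][0], max(b for _, b in exons)
        tss, tes = (start, end) if rec["strand"] == "+" else (end, start)
        gene = GeneAnnotation(gene_id, rec["chrom"], rec["strand"], tss, tes, tuple(exons))
        prev = best.get(gene_id)
        if prev is None or gene.length > prev.length or (
            gene.length == prev.length and gene.start < prev.start
        ):
            best[gene_id] = gene
    return list(best.values())


def load_annotation(path) -> list[GeneAnnotation]:
    """Load a gene annotation from GTF or BED(12).

    One record per gene is retained (the longest transcript when several
    exist).  Returns genes in stable ``gene_id`` order.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".gtf", ".gff"):
        genes = _parse_gtf(path)
    elif suffix.startswith(".bed"):
        genes = _parse_bed12(path)
    else:  # sniff: GTF records carry 'gene_id "..."' attributes
        head = path.read_text().splitlines()
        is_gtf = any("gene_id" in ln and ln.count("\t") == 8 for ln in head[:50])
        genes = _parse_gtf(path) if is_gtf else _parse_bed12(path)
    if not genes:
        raise ValueError(f"{path}: no gene records found")
    return sorted(genes, key=lambda g: g.gene_id)


# ------------------------------------------------------------------ regions

def define_regions(
    genes: list[GeneAnnotation],
    promoter_up: int = 500,
    promoter_down: int = 500,
    tes_down: int = 1000,
) -> RegionSet:
    """Derive promoter / gene-body / TES windows for each gene.

    In transcription-direction offsets from the TSS the promoter is
    ``[-promoter_up, +promoter_down)``, the gene body runs from
    ``+promoter_down`` to the TES, and the TES window extends ``tes_down``
    past the TES.  Genes too short to host a positive-length body are
    flagged (not dropped) and excluded from RNAPII modeling downstream.
    """
    if min(promoter_up, promoter_down, tes_down) <= 0:
        raise ValueError("window sizes must be positive")
    rows = []
    for g in genes:
        if g.strand == "+":
            prom = (g.tss - promoter_up, g.tss + promoter_down)
            body = (g.tss + promoter_down, g.tes)
            tesw = (g.tes, g.tes + tes_down)
        else:
            prom = (g.tss - promoter_down, g.tss + promoter_up)
            body = (g.tes, g.tss - promoter_down)
            tesw = (g.tes - tes_down, g.tes)
        flagged = body[1] <= body[0]
        rows.append(
            dict(
                gene_id=g.gene_id,
                chrom=g.chrom,
                strand=g.strand,
                promoter_start=prom[0],
                promoter_end=prom[1],
                body_start=body[0],
                body_end=body[1],
                tes_start=tesw[0],
                tes_end=tesw[1],
                flagged=flagged,
            )
        )
    df = pd.DataFrame(rows).set_index("gene_id")
    return RegionSet(df)
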