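"""Gene-neighborhood statistics: signed intergenic distances and clustering.

Consecutive genes a, b ordered by start coordinate (1-based, inclusive, the
GFF3/GenBank convention) are separated by

    distance = b.start - a.end - 1,

so abutting genes have distance 0 and overlapping ORFs have negative distance
with overlap length = -distance.  Small or negative distances between genes
such as pipX-pipY-sepF-proC are evidence of operon structure and, for
overlaps, possible translational coupling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

__all__ = [
    "GeneRecord",
    "NeighborPair",
    "LinkageSummary",
    "intergenic_distance",
    "read_annotation",
    "neighbor_table",
    "linkage_summary",
]


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    genome_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: coordinates must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class NeighborPair:
    upstream: str  # gene id of the leftmost gene
    downstream: str
    genome_id: str
    distance: int  # signed nt; negative = overlap
    overlap: int  # nt, 0 if none
    same_strand: bool


class LinkageSummary(NamedTuple):
    n_below: int  # pairs with distance < threshold
    n_total: int
    n_overlapping: int  # pairs with distance < 0
    overlap_lengths: tuple[int, ...]


def intergenic_distance(a: GeneRecord, b: GeneRecord) -> NeighborPair:
    """Signed intergenic distance between two genes of the same genome.

    The pair is ordered by start coordinate internally, so the result does
    not depend on argument order.
    """
    if a.genome_id != b.genome_id:
        raise ValueError(
            f"genes from different genomes: {a.genome_id!r} vs {b.genome_id!r}"
        )
    if (b.start, b.end) < (a.start, a.end):
        a, b = b, a
    distance = b.start - a.end - 1
    return NeighborPair(
        upstream=a.gene_id,
        downstream=b.gene_id,
        genome_id=a.genome_id,
        distance=distance,
        overlap=max(0, -distance),
        same_strand=a.strand == b.strand,
    )


def _name_of_gff_feature(feature) -> str:
    for key in ("gene", "Name", "locus_tag", "ID"):
        vals = feature.attributes.get(key)
        if vals:
            return str(vals[0])
    return f"{feature.seqid}:{feature.start}-{feature.end}"


def _read_gff3(path: str) -> list[GeneRecord]:
    import gffutils
    from gffutils.exceptions import EmptyInputError

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except EmptyInputError:  # valid header-only annotation
        return []
    feats = list(db.all_features())
    genes = [f for f in feats if f.featuretype == "gene"] or [
        f for f in feats if f.featuretype == "CDS"
    ]
    return [
        GeneRecord(
            gene_id=_name_of_gff_feature(f),
            genome_id=f.seqid,
            start=int(f.start),
            end=int(f.end),
            strand=f.strand if f.strand in ("+", "-") else "+",
        )
        for f in genes
    ]


def _read_genbank(path: str) -> list[GeneRecord]:
    from Bio import SeqIO

    records: list[GeneRecord] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        feats = [f for f in rec.features if f.type == "gene"] or [
            f for f in rec.features if f.type == "CDS"
        ]
        for f in feats:
            quals = f.qualifiers
            name = (quals.get("gene") or quals.get("locus_tag") or ["?"])[0]
            records.append(
                GeneRecord(
                    gene_id=str(name),
                    genome_id=rec.id,
                    start=int(f.location.start) + 1,  # biopython is 0-based
                    end=int(f.location.end),
                    strand="-" if f.location.strand == -1 else "+",
                )
            )
    return records


def read_annotation(path, fmt: str | None = None) -> list[GeneRecord]:
    """Read gene records from a GFF3 or GenBank flat file.

    The format is inferred from the suffix (.gff/.gff3 vs .gb/.gbk/.gbff)
    unless given explicitly.
    """
    p = Path(path)
    if fmt is None:
        suffix = p.suffix.lower()
        fmt = "genbank" if suffix in (".gb", ".gbk", ".gbff", ".genbank") else "gff3"
    if fmt == "gff3":
        return _read_gff3(str(p))
    if fmt == "genbank":
        return _read_genbank(str(p))
    raise ValueError(f"unknown annotation format: {fmt!r}")


def neighbor_table(
    records: Iterable[GeneRecord] | str | Path,
    gene_names: Sequence[str] | None = None,
) -> list[NeighborPair]:
    """Neighbor pairs among the named genes, per genome, ordered by position.

    ``records`` may be parsed gene records or a path to an annotation file.
    Gene names match case-insensitively; genomes missing some of the named
    genes contribute the pairs among those present.  If none of the genes is
    found, an empty table is returned with a warning.
    """
    if isinstance(records, (str, Path)):
        records = read_annotation(records)
    recs = list(records)
    if gene_names is not None:
        wanted = {n.lower() for n in gene_names}
        recs = [r for r in recs if r.gene_id.lower() in wanted]
        if not recs:
            warnings.warn("none of the requested genes were found", stacklevel=2)
            return []

    pairs: list[NeighborPair] = []
    by_genome: dict[str, list[GeneRecord]] = {}
    for r in recs:
        by_genome.setdefault(r.genome_id, []).append(r)
    for genome in sorted(by_genome):
        ordered = sorted(by_genome[genome], key=lambda r: (r.start, r.end))
        pairs.extend(
            intergenic_distance(a, b) for a, b in zip(ordered, ordered[1:])
        )
    return pairs


def linkage_summary(
    pairs: Sequence[NeighborPair], threshold: int
) -> LinkageSummary:
    """Count pairs closer than ``threshold`` nt and tabulate overlaps.

    ``n_below`` counts strictly smaller distances, so threshold 0 counts only
    overlapping pairs.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    n_below = sum(1 for p in pairs if p.distance < threshold)
    overlaps = tuple(p.overlap for p in pairs if p.distance < 0)
    return LinkageSummary(
        n_below=n_below,
        n_total=len(pairs),
        n_overlapping=len(overlaps),
        overlap_lengths=overlaps,
    )
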