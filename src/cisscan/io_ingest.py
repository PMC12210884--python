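"""Readers and writers for the pipeline's external file dialects.

The pipeline consumes four kinds of tables: protein homology hits in
BLAST/DIAMOND tabular format (``-outfmt 6``, 12 columns), gene-family
membership tables in the Roary ``gene_presence_absence.csv`` dialect,
MAG metadata TSVs, and protein-domain annotation TSVs.  All readers
tolerate CRLF line endings and a UTF-8 BOM, never silently drop a data
line, and report parse errors with 1-based line numbers.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ParseError",
    "HomologyHit",
    "FamilyMembershipTable",
    "BiomeRecord",
    "DomainAnnotation",
    "BIOME_GROUPS",
    "parse_hit_table",
    "parse_family_table",
    "parse_metadata",
    "parse_domain_table",
    "parse_gene_contig_map",
    "write_hit_table",
    "write_family_table",
    "write_metadata",
    "write_domain_table",
]

#: Biome-group vocabulary used by MAG catalogs (isolation-source level).
BIOME_GROUPS = ("aquatic", "host-associated", "terrestrial", "engineered")

# Metadata columns Roary inserts between the family id and the genome columns.
_ROARY_META_COLUMNS = frozenset(
    {
        "Non-unique Gene name",
        "Annotation",
        "No. isolates",
        "No. sequences",
        "Avg sequences per isolate",
        "Genome Fragment",
        "Order within Fragment",
        "Accessory Fragment",
        "Accessory Order with Fragment",
        "QC",
        "Min group size nuc",
        "Max group size nuc",
        "Avg group size nuc",
    }
)


class ParseError(ValueError):
    """A malformed input table; the message names the offending line."""


@dataclass(frozen=True)
class HomologyHit:
    """One MAG-gene -> CGF-family alignment record (DIAMOND/BLAST hit)."""

    query_gene_id: str
    mag_id: str
    contig_id: str
    family_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        for name in ("query_gene_id", "mag_id", "contig_id", "family_id"):
            if not getattr(self, name):
                raise ValueError(f"HomologyHit.{name} must be non-empty")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent_identity {self.percent_identity} outside [0, 100]"
            )
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if self.bitscore <= 0:
            raise ValueError("bitscore must be positive")


@dataclass(frozen=True)
class FamilyMembershipTable:
    """Gene-family memberships across a fixed set of reference genomes.

    ``members[family_id][reference_id]`` is the tuple of member gene ids
    of that family in that reference genome (absent genomes omitted).
    """

    reference_ids: tuple[str, ...]
    members: Mapping[str, Mapping[str, tuple[str, ...]]]

    @property
    def n_references(self) -> int:
        return len(self.reference_ids)

    @property
    def family_ids(self) -> tuple[str, ...]:
        return tuple(self.members)

    def presence_count(self, family_id: str) -> int:
        """Number of reference genomes containing >= 1 member of the family."""
        return sum(1 for genes in self.members[family_id].values() if genes)

    def genes_of_reference(self, reference_id: str) -> tuple[tuple[str, str], ...]:
        """All (family_id, gene_id) pairs carried by one reference genome."""
        if reference_id not in self.reference_ids:
            raise KeyError(f"unknown reference genome {reference_id!r}")
        out: list[tuple[str, str]] = []
        for fam, per_ref in self.members.items():
            for gene in per_ref.get(reference_id, ()):
                out.append((fam, gene))
        return tuple(out)

    def __post_init__(self) -> None:
        if not self.reference_ids:
            raise ValueError("membership table needs >= 1 reference genome")
        seen: dict[str, str] = {}
        for fam, per_ref in self.members.items():
            n = sum(len(g) for g in per_ref.values())
            if n == 0:
                raise ValueError(f"family {fam!r} has no members")
            for genes in per_ref.values():
                for gene in genes:
                    if gene in seen:
                        raise ValueError(
                            f"gene {gene!r} belongs to both {seen[gene]!r} and {fam!r}"
                        )
                    seen[gene] = fam


@dataclass(frozen=True)
class BiomeRecord:
    """Metadata for one MAG: biome group, sub-biome and taxonomy."""

    mag_id: str
    biome_group: str
    sub_biome: str
    phylum: str
    species: str = ""

    def __post_init__(self) -> None:
        if self.biome_group not in BIOME_GROUPS:
            raise ValueError(
                f"unknown biome_group {self.biome_group!r}; "
                f"expected one of {', '.join(BIOME_GROUPS)}"
            )


@dataclass(frozen=True)
class DomainAnnotation:
    """A protein-domain annotation, 1-based inclusive residue coordinates."""

    gene_id: str
    domain_name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"invalid domain coordinates {self.start}..{self.end} "
                f"for {self.gene_id!r} (need 1 <= start <= end)"
            )


def _read_lines(path: str | Path) -> list[str]:
    # utf-8-sig strips a BOM if present; splitlines handles CRLF.
    text = Path(path).read_text(encoding="utf-8-sig")
    return text.splitlines()


def _split_qseqid(
    qseqid: str,
    gene_contig_map: Mapping[str, tuple[str, str]] | None,
    lineno: int,
) -> tuple[str, str]:
    """Resolve (mag_id, contig_id) for a query gene.

    Convention: qseqid is ``<mag>|<contig>|<gene>``.  An explicit
    gene -> (mag, contig) map overrides the convention for real data.
    """
    if gene_contig_map is not None and qseqid in gene_contig_map:
        return gene_contig_map[qseqid]
    parts = qseqid.split("|")
    if len(parts) != 3:
        raise ParseError(
            f"line {lineno}: cannot derive contig from qseqid {qseqid!r}; "
            "expected '<mag>|<contig>|<gene>' or a gene->contig map entry"
        )
    return parts[0], parts[1]


def parse_hit_table(
    path: str | Path,
    dialect: str = "blast6",
    gene_contig_map: Mapping[str, tuple[str, str]] | None = None,
) -> list[HomologyHit]:
    """Parse a 12-column BLAST/DIAMOND tabular hit file.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  Comment lines (leading ``#``) and blank
    lines are skipped; data-line order is preserved.
    """
    if dialect not in ("blast6", "diamond6"):
        raise ValueError(f"unsupported hit-table dialect {dialect!r}")
    hits: list[HomologyHit] = []
    for lineno, raw in enumerate(_read_lines(path), start=1):
        line = raw.rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise ParseError(
                f"line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
            )
        qseqid, sseqid = fields[0], fields[1]
        try:
            pident = float(fields[2])
            length = int(fields[3])
            evalue = float(fields[10])
            bitscore = float(fields[11])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-numeric field ({exc})") from None
        mag_id, contig_id = _split_qseqid(qseqid, gene_contig_map, lineno)
        try:
            hits.append(
                HomologyHit(
                    query_gene_id=qseqid,
                    mag_id=mag_id,
                    contig_id=contig_id,
                    family_id=sseqid,
                    percent_identity=pident,
                    alignment_length=length,
                    evalue=evalue,
                    bitscore=bitscore,
                )
            )
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
    return hits


def write_hit_table(hits: Iterable[HomologyHit], path: str | Path) -> None:
    """Write hits back to 12-column tabular format (round-trip safe).

    The mismatch/gap/coordinate columns are not part of the in-memory
    record; plausible placeholders consistent with the alignment length
    are emitted.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for h in hits:
            mismatch = round(h.alignment_length * (1 - h.percent_identity / 100))
            fh.write(
                "\t".join(
                    [
                        h.query_gene_id,
                        h.family_id,
                        f"{h.percent_identity:g}",
                        str(h.alignment_length),
                        str(mismatch),
                        "0",
                        "1",
                        str(h.alignment_length),
                        "1",
                        str(h.alignment_length),
                        f"{h.evalue:g}",
                        f"{h.bitscore:g}",
                    ]
                )
                + "\n"
            )


def parse_family_table(path: str | Path) -> FamilyMembershipTable:
    """Parse a Roary-style ``gene_presence_absence.csv`` table.

    First column is the family id ("Gene"); known Roary metadata columns
    are skipped; every remaining column is a reference genome.  Cells may
    hold several gene ids joined by tab or semicolon; empty cells mean
    absence.
    """
    text = Path(path).read_text(encoding="utf-8-sig")
    reader = csv.reader(io.StringIO(text))
    try:
        header = next(reader)
    except StopIteration:
        raise ParseError("empty family table") from None
    if not header:
        raise ParseError("family table has an empty header")
    genome_cols = [
        (i, name)
        for i, name in enumerate(header[1:], start=1)
        if name not in _ROARY_META_COLUMNS
    ]
    if not genome_cols:
        raise ParseError("family table has zero reference-genome columns")
    reference_ids = tuple(name for _, name in genome_cols)
    members: dict[str, dict[str, tuple[str, ...]]] = {}
    for lineno, row in enumerate(reader, start=2):
        if not row or not any(cell.strip() for cell in row):
            continue
        family_id = row[0].strip()
        if not family_id:
            raise ParseError(f"line {lineno}: empty family id")
        if family_id in members:
            raise ParseError(f"line {lineno}: duplicate family id {family_id!r}")
        per_ref: dict[str, tuple[str, ...]] = {}
        for i, ref in genome_cols:
            cell = row[i].strip() if i < len(row) else ""
            if not cell:
                continue
            genes = tuple(
                g.strip() for g in cell.replace(";", "\t").split("\t") if g.strip()
            )
            if genes:
                per_ref[ref] = genes
        members[family_id] = per_ref
    try:
        return FamilyMembershipTable(reference_ids=reference_ids, members=members)
    except ValueError as exc:
        raise ParseError(str(exc)) from None


def write_family_table(table: FamilyMembershipTable, path: str | Path) -> None:
    """Write a membership table in the quoted-CSV dialect read by
    :func:`parse_family_table` (multi-gene cells joined by semicolon)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_ALL)
        writer.writerow(["Gene", *table.reference_ids])
        for fam, per_ref in table.members.items():
            writer.writerow(
                [fam, *(";".join(per_ref.get(ref, ())) for ref in table.reference_ids)]
            )


def _parse_tsv(
    path: str | Path, required: Sequence[str]
) -> tuple[list[dict[str, str]], None]:
    lines = _read_lines(path)
    if not lines:
        raise ParseError("empty table (missing header)")
    header = lines[0].rstrip("\r").split("\t")
    missing = [c for c in required if c not in header]
    if missing:
        raise ParseError(f"missing required column(s): {', '.join(missing)}")
    rows: list[dict[str, str]] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ParseError(
                f"line {lineno}: expected {len(header)} columns, got {len(cells)}"
            )
        rows.append(dict(zip(header, cells)))
    return rows, None


def parse_metadata(path: str | Path) -> list[BiomeRecord]:
    """Parse a MAG metadata TSV (mag_id, biome_group, sub_biome, phylum,
    species)."""
    rows, _ = _parse_tsv(path, ["mag_id", "biome_group", "sub_biome", "phylum", "species"])
    records: list[BiomeRecord] = []
    seen: set[str] = set()
    for row in rows:
        if row["mag_id"] in seen:
            raise ParseError(f"duplicate mag_id {row['mag_id']!r}")
        seen.add(row["mag_id"])
        try:
            records.append(
                BiomeRecord(
                    mag_id=row["mag_id"],
                    biome_group=row["biome_group"],
                    sub_biome=row["sub_biome"],
                    phylum=row["phylum"],
                    species=row["species"],
                )
            )
        except ValueError as exc:
            raise ParseError(str(exc)) from None
    return records


def write_metadata(records: Iterable[BiomeRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("mag_id\tbiome_group\tsub_biome\tphylum\tspecies\n")
        for r in records:
            fh.write(f"{r.mag_id}\t{r.biome_group}\t{r.sub_biome}\t{r.phylum}\t{r.species}\n")


def parse_domain_table(path: str | Path) -> list[DomainAnnotation]:
    """Parse a protein-domain TSV (gene_id, domain_name, start, end)."""
    rows, _ = _parse_tsv(path, ["gene_id", "domain_name", "start", "end"])
    annotations: list[DomainAnnotation] = []
    for row in rows:
        try:
            annotations.append(
                DomainAnnotation(
                    gene_id=row["gene_id"],
                    domain_name=row["domain_name"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                )
            )
        except ValueError as exc:
            raise ParseError(str(exc)) from None
    return annotations


def write_domain_table(annotations: Iterable[DomainAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\tdomain_name\tstart\tend\n")
        for a in annotations:
            fh.write(f"{a.gene_id}\t{a.domain_name}\t{a.start}\t{a.end}\n")


def parse_gene_contig_map(path: str | Path) -> dict[str, tuple[str, str]]:
    """Parse an optional gene -> (mag, contig) map TSV used for real-data
    hit tables whose query ids do not follow the pipe convention."""
    rows, _ = _parse_tsv(path, ["gene_id", "mag_id", "contig_id"])
    return {row["gene_id"]: (row["mag_id"], row["contig_id"]) for row in rows}
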