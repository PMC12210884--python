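"""Ecological and taxonomic tabulation of final CIS calls.

All counts are MAG-level: a MAG with several CIS loci counts once, so
running on duplicated locus rows changes nothing.  Sub-biome relative
abundance is computed against the full MAG catalog (CIS-bearing MAGs in
a sub-biome divided by all catalog MAGs in that sub-biome), the way
catalog-wide enrichment is reported for environmental surveys.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .classification import STATUS_CIS, LocusResult
from .io_ingest import BIOME_GROUPS, BiomeRecord

__all__ = [
    "EcologySummary",
    "biome_group_counts",
    "subbiome_relative_abundance",
    "phylum_composition",
    "top_species",
    "summarize_ecology",
    "write_ecology_tables",
]

UNANNOTATED = "unannotated"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class EcologySummary:
    biome_group_counts: dict[str, int]
    subbiome_abundance: dict[str, tuple[int, int, float]]
    phylum_counts: dict[str, int]
    species_ranking: tuple[tuple[str, int], ...]
    n_unclassified_species: int


def _cis_mag_ids(loci: Iterable[LocusResult]) -> set[str]:
    return {l.mag_id for l in loci if l.status == STATUS_CIS}


def _metadata_index(metadata: Iterable[BiomeRecord]) -> dict[str, BiomeRecord]:
    return {r.mag_id: r for r in metadata}


def biome_group_counts(
    loci: Sequence[LocusResult], metadata: Sequence[BiomeRecord]
) -> dict[str, int]:
    """CIS-bearing MAGs per biome group; MAGs without metadata are
    counted under "unannotated" with a warning."""
    index = _metadata_index(metadata)
    counts: Counter[str] = Counter()
    missing = []
    for mag in sorted(_cis_mag_ids(loci)):
        record = index.get(mag)
        if record is None:
            missing.append(mag)
            counts[UNANNOTATED] += 1
        else:
            counts[record.biome_group] += 1
    if missing:
        warnings.warn(
            f"{len(missing)} CIS MAG(s) lack metadata and were counted as "
            f"'{UNANNOTATED}': {', '.join(missing[:5])}"
            + ("..." if len(missing) > 5 else ""),
            stacklevel=2,
        )
    out = {g: counts.get(g, 0) for g in BIOME_GROUPS}
    if counts.get(UNANNOTATED):
        out[UNANNOTATED] = counts[UNANNOTATED]
    return out


def subbiome_relative_abundance(
    loci: Sequence[LocusResult], catalog_metadata: Sequence[BiomeRecord]
) -> dict[str, tuple[int, int, float]]:
    """Per sub-biome: (CIS MAGs, catalog MAGs, percent).

    ``catalog_metadata`` must cover the full MAG catalog, not only CIS
    MAGs; percent = 100 x CIS MAGs / catalog MAGs in the sub-biome.
    """
    index = _metadata_index(catalog_metadata)
    totals: Counter[str] = Counter(r.sub_biome for r in index.values())
    cis: Counter[str] = Counter()
    for mag in _cis_mag_ids(loci):
        record = index.get(mag)
        if record is None:
            raise ValueError(
                f"CIS MAG {mag!r} absent from the catalog metadata; "
                "sub-biome denominators would be inconsistent"
            )
        cis[record.sub_biome] += 1
    out: dict[str, tuple[int, int, float]] = {}
    for sub in sorted(totals):
        total = totals[sub]
        if total == 0:
            continue
        k = cis.get(sub, 0)
        out[sub] = (k, total, 100.0 * k / total)
    return out


def phylum_composition(
    loci: Sequence[LocusResult], metadata: Sequence[BiomeRecord]
) -> dict[str, int]:
    """MAG-level CIS counts per phylum; empty phylum strings fall into
    the "unclassified" bucket.  Phylum strings are matched exactly (no
    case folding or fuzzy merging)."""
    index = _metadata_index(metadata)
    counts: Counter[str] = Counter()
    for mag in _cis_mag_ids(loci):
        record = index.get(mag)
        phylum = record.phylum if record and record.phylum else UNCLASSIFIED
        counts[phylum] += 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))


def top_species(
    loci: Sequence[LocusResult],
    metadata: Sequence[BiomeRecord],
    n: int = 10,
) -> tuple[tuple[tuple[str, int], ...], int]:
    """Top-n species by CIS-MAG count (descending, ties alphabetical)
    plus the number of CIS MAGs unclassified at species level."""
    if n < 1:
        raise ValueError("n must be >= 1")
    index = _metadata_index(metadata)
    counts: Counter[str] = Counter()
    unclassified = 0
    for mag in _cis_mag_ids(loci):
        record = index.get(mag)
        if record is None or not record.species:
            unclassified += 1
        else:
            counts[record.species] += 1
    ranking = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    return tuple(ranking), unclassified


def summarize_ecology(
    loci: Sequence[LocusResult],
    metadata: Sequence[BiomeRecord],
    catalog_metadata: Sequence[BiomeRecord] | None = None,
    n_top_species: int = 10,
) -> EcologySummary:
    """All four tabulations in one pass.  ``catalog_metadata`` defaults
    to ``metadata`` (i.e. the metadata already covers the catalog)."""
    catalog = catalog_metadata if catalog_metadata is not None else metadata
    ranking, unclassified = top_species(loci, metadata, n=n_top_species)
    return EcologySummary(
        biome_group_counts=biome_group_counts(loci, metadata),
        subbiome_abundance=subbiome_relative_abundance(loci, catalog),
        phylum_counts=phylum_composition(loci, metadata),
        species_ranking=ranking,
        n_unclassified_species=unclassified,
    )


def write_ecology_tables(summary: EcologySummary, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "biome_group_counts.tsv", "w", encoding="utf-8") as fh:
        fh.write("biome_group\tn_cis_mags\n")
        for group, count in summary.biome_group_counts.items():
            fh.write(f"{group}\t{count}\n")
    with open(out / "subbiome_abundance.tsv", "w", encoding="utf-8") as fh:
        fh.write("sub_biome\tn_cis_mags\tn_catalog_mags\tpercent\n")
        for sub, (k, total, pct) in sorted(
            summary.subbiome_abundance.items(), key=lambda kv: -kv[1][2]
        ):
            fh.write(f"{sub}\t{k}\t{total}\t{pct:.2f}\n")
    with open(out / "phylum_composition.tsv", "w", encoding="utf-8") as fh:
        fh.write("phylum\tn_cis_mags\n")
        for phylum, count in summary.phylum_counts.items():
            fh.write(f"{phylum}\t{count}\n")
    with open(out / "top_species.tsv", "w", encoding="utf-8") as fh:
        fh.write("species\tn_cis_mags\n")
        for species, count in summary.species_ranking:
            fh.write(f"{species}\t{count}\n")
        fh.write(f"{UNCLASSIFIED}\t{summary.n_unclassified_species}\n")
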