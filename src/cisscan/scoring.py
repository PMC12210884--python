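"""Per-contig CIS scoring, representative selection and threshold screening.

A contig's score is ``Multiplier x sum(3^freq - 1)``: the multiplier M is
the number of distinct CIS genes identified on the contig, and each gene
contributes an exponential base score of its best-hit family's
conservation frequency.  The exponential form rewards hits to highly
conserved families while keeping sporadic (cloud) hits nearly neutral.

The screening threshold is derived from the eight reference loci scored
against their own profile: the nearest-rank quantile covering the lowest
60% of the reference self-scores.  Candidates must score strictly above
the threshold.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .cgf_profile import CGFProfile
from .io_ingest import FamilyMembershipTable, HomologyHit

__all__ = [
    "ScoringConfig",
    "ScoreResult",
    "ThresholdSpec",
    "filter_hits",
    "base_score",
    "contig_score",
    "score_contigs",
    "select_representative",
    "select_representatives",
    "reference_self_scores",
    "reference_threshold",
    "screen_candidates",
    "write_score_table",
]


@dataclass(frozen=True)
class ScoringConfig:
    """Tunable parameters of hit filtering, scoring and thresholding.

    min_identity / max_evalue follow common practice for protein-level
    DIAMOND searches (25% identity is the identity floor used throughout
    the reference cluster comparisons; 1e-5 is the conventional e-value
    cap).  ``aggregation`` selects whether the multiplier scales the sum
    or the mean of the per-gene base scores; ``threshold_mode`` selects
    the reading of "lowest 60%" (nearest-rank quantile by default).
    """

    min_identity: float = 25.0
    max_evalue: float = 1e-5
    keep_ties: bool = False
    distinct_families_only: bool = False
    aggregation: str = "sum"  # or "mean"
    threshold_fraction: float = 0.6
    threshold_mode: str = "nearest_rank"  # or "fraction_of_min", "interpolated"

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_identity <= 100.0:
            raise ValueError("min_identity must be in [0, 100]")
        if not math.isfinite(self.max_evalue) or self.max_evalue < 0:
            raise ValueError("max_evalue must be finite and non-negative")
        if self.aggregation not in ("sum", "mean"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if self.threshold_mode not in ("nearest_rank", "fraction_of_min", "interpolated"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if not 0.0 < self.threshold_fraction <= 1.0:
            raise ValueError("threshold_fraction must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoringConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)


@dataclass(frozen=True)
class ScoreResult:
    """Score of one contig: multiplier, per-gene base scores and total."""

    mag_id: str
    contig_id: str
    multiplier: int
    base_scores: tuple[float, ...]
    score: float
    families_hit: frozenset[str]
    gene_ids: tuple[str, ...]
    aggregation: str = "sum"


@dataclass(frozen=True)
class ThresholdSpec:
    """Reference self-scores and the derived candidate-screening cutoff."""

    reference_scores: tuple[float, ...]
    fraction: float
    threshold: float
    mode: str = "nearest_rank"


def filter_hits(
    hits: Iterable[HomologyHit],
    min_identity: float = 25.0,
    max_evalue: float = 1e-5,
    keep_ties: bool = False,
) -> list[HomologyHit]:
    """Apply identity/e-value filters and keep the best hit per query gene.

    Best = highest bitscore; ties broken by lowest e-value, then by
    lexicographically smallest family id.  With ``keep_ties`` every hit
    tied on (bitscore, evalue) with the best is retained — the
    "non-mutually exclusive" counting mode used for gene count matrices.
    """
    if not 0.0 <= min_identity <= 100.0:
        raise ValueError("min_identity must be in [0, 100]")
    surviving: dict[str, list[HomologyHit]] = defaultdict(list)
    order: list[str] = []
    for h in hits:
        if h.percent_identity >= min_identity and h.evalue <= max_evalue:
            if h.query_gene_id not in surviving:
                order.append(h.query_gene_id)
            surviving[h.query_gene_id].append(h)
    out: list[HomologyHit] = []
    for gene in order:
        group = surviving[gene]
        best = min(group, key=lambda h: (-h.bitscore, h.evalue, h.family_id))
        if keep_ties:
            out.extend(
                h
                for h in group
                if h.bitscore == best.bitscore and h.evalue == best.evalue
            )
        else:
            out.append(best)
    return out


def base_score(freq: float) -> float:
    """Exponential base score 3^freq - 1 of a conservation frequency."""
    if not 0.0 <= freq <= 1.0:
        raise ValueError(f"freq {freq} outside [0, 1]")
    return 3.0**freq - 1.0


def contig_score(
    hits: Sequence[HomologyHit],
    profile: CGFProfile,
    aggregation: str = "sum",
    distinct_families_only: bool = False,
    mag_id: str = "",
    contig_id: str = "",
) -> ScoreResult:
    """Score one contig from its accepted hits.

    M = number of distinct query genes with accepted hits.  Each gene
    contributes the base score of its best-hit family (the highest-
    frequency family among retained ties); ``distinct_families_only``
    collapses genes hitting the same family into a single term.  The
    total is M x sum(base scores) ("sum") or M x mean ("mean", i.e. the
    plain sum of base scores).  An empty hit list yields M = 0, score 0.
    """
    if not hits:
        return ScoreResult(
            mag_id=mag_id,
            contig_id=contig_id,
            multiplier=0,
            base_scores=(),
            score=0.0,
            families_hit=frozenset(),
            gene_ids=(),
            aggregation=aggregation,
        )
    mags = {h.mag_id for h in hits}
    contigs = {h.contig_id for h in hits}
    if len(mags) != 1 or len(contigs) != 1:
        raise ValueError("hits passed to contig_score must share (mag_id, contig_id)")
    by_id = profile.by_id
    per_gene: dict[str, float] = {}
    gene_family: dict[str, str] = {}
    families: set[str] = set()
    for h in hits:
        fam = by_id.get(h.family_id)
        if fam is None:
            raise ValueError(f"hit references unknown family {h.family_id!r}")
        families.add(h.family_id)
        b = base_score(fam.frequency)
        if h.query_gene_id not in per_gene or b > per_gene[h.query_gene_id]:
            per_gene[h.query_gene_id] = b
            gene_family[h.query_gene_id] = h.family_id
    genes = tuple(sorted(per_gene))
    multiplier = len(genes)
    if distinct_families_only:
        best_per_family: dict[str, float] = {}
        for g in genes:
            fam = gene_family[g]
            best_per_family[fam] = max(best_per_family.get(fam, 0.0), per_gene[g])
        terms = tuple(best_per_family[f] for f in sorted(best_per_family))
    else:
        terms = tuple(per_gene[g] for g in genes)
    total = sum(terms)
    if aggregation == "sum":
        score = multiplier * total
    elif aggregation == "mean":
        score = multiplier * (total / len(terms)) if terms else 0.0
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return ScoreResult(
        mag_id=next(iter(mags)),
        contig_id=next(iter(contigs)),
        multiplier=multiplier,
        base_scores=terms,
        score=score,
        families_hit=frozenset(families),
        gene_ids=genes,
        aggregation=aggregation,
    )


def score_contigs(
    accepted_hits: Iterable[HomologyHit],
    profile: CGFProfile,
    config: ScoringConfig | None = None,
) -> list[ScoreResult]:
    """Group accepted hits by (mag, contig) and score every contig."""
    config = config or ScoringConfig()
    groups: dict[tuple[str, str], list[HomologyHit]] = defaultdict(list)
    for h in accepted_hits:
        groups[(h.mag_id, h.contig_id)].append(h)
    return [
        contig_score(
            group,
            profile,
            aggregation=config.aggregation,
            distinct_families_only=config.distinct_families_only,
        )
        for key, group in sorted(groups.items())
    ]


def _representative_key(r: ScoreResult) -> tuple[float, int, int, str]:
    # max score, then larger multiplier, then more families, then smallest
    # contig id — negate for use with min().
    return (-r.score, -r.multiplier, -len(r.families_hit), r.contig_id)


def select_representative(results: Sequence[ScoreResult]) -> ScoreResult:
    """The MAG's representative contig: its highest-scoring contig."""
    if not results:
        raise ValueError("select_representative needs >= 1 scored contig")
    if len({r.mag_id for r in results}) != 1:
        raise ValueError("results passed to select_representative span several MAGs")
    return min(results, key=_representative_key)


def select_representatives(results: Iterable[ScoreResult]) -> list[ScoreResult]:
    """One representative contig per MAG, MAG order sorted."""
    per_mag: dict[str, list[ScoreResult]] = defaultdict(list)
    for r in results:
        per_mag[r.mag_id].append(r)
    return [select_representative(per_mag[m]) for m in sorted(per_mag)]


def reference_self_scores(
    membership: FamilyMembershipTable,
    profile: CGFProfile,
    config: ScoringConfig | None = None,
) -> dict[str, float]:
    """Score each reference locus against its own profile.

    Every gene of a reference genome counts as an accepted hit to its own
    family, so M is the genome's gene count and each gene contributes its
    family's base score.
    """
    config = config or ScoringConfig()
    by_id = profile.by_id
    out: dict[str, float] = {}
    for ref in membership.reference_ids:
        genes = membership.genes_of_reference(ref)
        if not genes:
            out[ref] = 0.0
            continue
        if config.distinct_families_only:
            terms = [base_score(by_id[f].frequency) for f in sorted({f for f, _ in genes})]
        else:
            terms = [base_score(by_id[fam].frequency) for fam, _ in genes]
        m = len(genes)
        total = sum(terms)
        out[ref] = m * total if config.aggregation == "sum" else m * total / len(terms)
    return out


def reference_threshold(
    reference_scores: Sequence[float],
    fraction: float = 0.6,
    mode: str = "nearest_rank",
) -> ThresholdSpec:
    """Candidate-screening cutoff from the reference self-scores.

    nearest_rank (default): ascending-sorted scores at 1-based rank
    ceil(fraction * n) — the top of the lowest-``fraction`` block.
    fraction_of_min: fraction x min(scores).  interpolated: linear
    quantile (numpy default).
    """
    scores = sorted(float(s) for s in reference_scores)
    if not scores:
        raise ValueError("reference_threshold needs >= 1 reference score")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n = len(scores)
    if mode == "nearest_rank":
        rank = math.ceil(fraction * n)
        threshold = scores[rank - 1]
    elif mode == "fraction_of_min":
        threshold = fraction * scores[0]
    elif mode == "interpolated":
        import numpy as np

        threshold = float(np.quantile(scores, fraction))
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    return ThresholdSpec(
        reference_scores=tuple(scores), fraction=fraction, threshold=threshold, mode=mode
    )


def screen_candidates(
    representatives: Iterable[ScoreResult], spec: ThresholdSpec
) -> list[ScoreResult]:
    """Keep representatives scoring strictly above the threshold."""
    return [r for r in representatives if r.score > spec.threshold]


def write_score_table(
    results: Iterable[ScoreResult],
    path: str | Path,
    spec: ThresholdSpec | None = None,
) -> None:
    """TSV export: mag_id, contig_id, multiplier, score, candidate,
    families_hit (comma-joined, sorted).  Deterministic for identical
    inputs."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("mag_id\tcontig_id\tmultiplier\tscore\tcandidate\tfamilies_hit\n")
        for r in results:
            candidate = "" if spec is None else str(r.score > spec.threshold).lower()
            fh.write(
                f"{r.mag_id}\t{r.contig_id}\t{r.multiplier}\t{r.score!r}\t"
                f"{candidate}\t{','.join(sorted(r.families_hit))}\n"
            )
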