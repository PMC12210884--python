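"""Essential-class screening and rule-based exclusion of CIS look-alikes.

Candidate loci must carry at least one role from each of three essential
structural classes — baseplate (Cis8/Cis11/Cis12), tube (Cis1/Cis5/Cis7)
and sheath initiator (Cis4/Cis9) — single deletions of which abolish
syringe-particle production in model extracellular CISs.  Two rule-based
exclusions then remove look-alike systems:

* **T6SS-like** — intracellular type VI secretion systems (subtypes
  i–iii) carry the AAA+ ATPase Cis15 but no spike plug (Cis6), tail
  fiber (Cis13) or tape measure (Cis14) homologs.
* **Phage / R-type bacteriocin** — these carry tail fiber (Cis13) and
  tape measure (Cis14) proteins but lack Cis15 (and, in the stricter
  reading, Cis6).

Loci surviving both screens are called CIS, and their genes carrying a
DUF4157 domain — a marker of secretion-system toxin cargo — are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .cgf_profile import CGFProfile, UNKNOWN_ROLE, role_sort_key
from .io_ingest import DomainAnnotation, HomologyHit
from .scoring import ScoreResult, ThresholdSpec

__all__ = [
    "ESSENTIAL_CLASSES",
    "STATUS_CIS",
    "STATUS_BELOW_THRESHOLD",
    "STATUS_MISSING_ESSENTIAL",
    "STATUS_T6SS_LIKE",
    "STATUS_PHAGE_OR_BACTERIOCIN",
    "STATUSES",
    "LocusResult",
    "role_presence",
    "roles_from_families",
    "essential_screen",
    "exclusion_class",
    "classify_locus",
    "classify_representatives",
    "flag_cargo",
    "write_locus_table",
    "read_locus_table",
]

#: Essential structural classes; a locus needs >= 1 role from each.
ESSENTIAL_CLASSES: dict[str, frozenset[str]] = {
    "baseplate": frozenset({"Cis8", "Cis11", "Cis12"}),
    "tube": frozenset({"Cis1", "Cis5", "Cis7"}),
    "sheath_initiator": frozenset({"Cis4", "Cis9"}),
}

STATUS_CIS = "CIS"
STATUS_BELOW_THRESHOLD = "below_threshold"
STATUS_MISSING_ESSENTIAL = "excluded_missing_essential"
STATUS_T6SS_LIKE = "excluded_T6SS_like"
STATUS_PHAGE_OR_BACTERIOCIN = "excluded_phage_or_bacteriocin"
STATUSES = (
    STATUS_CIS,
    STATUS_BELOW_THRESHOLD,
    STATUS_MISSING_ESSENTIAL,
    STATUS_T6SS_LIKE,
    STATUS_PHAGE_OR_BACTERIOCIN,
)

CARGO_DOMAIN = "DUF4157"


@dataclass(frozen=True)
class LocusResult:
    """Final classification of one representative contig."""

    mag_id: str
    contig_id: str
    score: float
    roles_present: frozenset[str]
    families_hit: frozenset[str]
    status: str
    exclusion_reason: str = ""
    cargo_genes: frozenset[str] = frozenset()

    @property
    def locus_id(self) -> str:
        return f"{self.mag_id}|{self.contig_id}"


def roles_from_families(family_ids: Iterable[str], profile: CGFProfile) -> frozenset[str]:
    """Roles annotated on the given families; unknown-role families
    contribute nothing."""
    by_id = profile.by_id
    roles = set()
    for fam in family_ids:
        family = by_id.get(fam)
        if family is None:
            raise ValueError(f"unknown family {fam!r}")
        if family.role != UNKNOWN_ROLE:
            roles.add(family.role)
    return frozenset(roles)


def role_presence(hits: Iterable[HomologyHit], profile: CGFProfile) -> frozenset[str]:
    """Roles present on a locus: >= 1 accepted hit to a family with that
    role (set semantics — multiplicities are ignored)."""
    return roles_from_families((h.family_id for h in hits), profile)


def essential_screen(roles_present: Iterable[str]) -> tuple[bool, tuple[str, ...]]:
    """Check the three essential classes; returns (passed, missing classes)."""
    roles = set(roles_present)
    missing = tuple(
        cls for cls, members in ESSENTIAL_CLASSES.items() if not roles & members
    )
    return (not missing, missing)


def exclusion_class(roles_present: Iterable[str], variant: str = "results") -> str:
    """Apply the T6SS / phage-bacteriocin exclusion rules.

    T6SS-like: Cis15 present and Cis6, Cis13, Cis14 all absent.
    Phage/bacteriocin: Cis13 and Cis14 present, Cis15 absent; the
    ``results`` variant additionally requires Cis6 absent, the
    ``methods`` variant drops the Cis6 condition.  Assumes the essential
    screen already passed; returns the locus status.
    """
    if variant not in ("results", "methods"):
        raise ValueError(f"unknown exclusion variant {variant!r}")
    roles = set(roles_present)
    if "Cis15" in roles and not roles & {"Cis6", "Cis13", "Cis14"}:
        return STATUS_T6SS_LIKE
    if "Cis13" in roles and "Cis14" in roles and "Cis15" not in roles:
        if variant == "methods" or "Cis6" not in roles:
            return STATUS_PHAGE_OR_BACTERIOCIN
    return STATUS_CIS


def flag_cargo(
    gene_ids: Iterable[str], annotations: Iterable[DomainAnnotation]
) -> frozenset[str]:
    """Locus genes carrying >= 1 DUF4157 domain annotation
    (case-insensitive exact domain-name match)."""
    genes = set(gene_ids)
    return frozenset(
        a.gene_id
        for a in annotations
        if a.gene_id in genes and a.domain_name.casefold() == CARGO_DOMAIN.casefold()
    )


def classify_locus(
    score_result: ScoreResult,
    profile: CGFProfile,
    threshold_spec: ThresholdSpec,
    domain_annotations: Sequence[DomainAnnotation] = (),
    variant: str = "results",
) -> LocusResult:
    """Full screening cascade for one representative contig.

    Stages in order: score threshold (strict >), essential-class screen,
    exclusion rules; the first failing stage determines the status.
    Cargo genes are flagged only for loci called CIS.
    """
    roles = roles_from_families(score_result.families_hit, profile)
    common = dict(
        mag_id=score_result.mag_id,
        contig_id=score_result.contig_id,
        score=score_result.score,
        roles_present=roles,
        families_hit=score_result.families_hit,
    )
    if not score_result.score > threshold_spec.threshold:
        return LocusResult(
            **common,
            status=STATUS_BELOW_THRESHOLD,
            exclusion_reason=(
                f"score {score_result.score:.4g} <= threshold "
                f"{threshold_spec.threshold:.4g}"
            ),
        )
    passed, missing = essential_screen(roles)
    if not passed:
        return LocusResult(
            **common,
            status=STATUS_MISSING_ESSENTIAL,
            exclusion_reason="missing essential class(es): " + ", ".join(missing),
        )
    status = exclusion_class(roles, variant=variant)
    if status == STATUS_T6SS_LIKE:
        return LocusResult(
            **common,
            status=status,
            exclusion_reason="Cis15 present without Cis6/Cis13/Cis14 (typical T6SS i-iii)",
        )
    if status == STATUS_PHAGE_OR_BACTERIOCIN:
        return LocusResult(
            **common,
            status=status,
            exclusion_reason="Cis13+Cis14 present without Cis15 (phage or R-type bacteriocin)",
        )
    return LocusResult(
        **common,
        status=STATUS_CIS,
        cargo_genes=flag_cargo(score_result.gene_ids, domain_annotations),
    )


def classify_representatives(
    representatives: Iterable[ScoreResult],
    profile: CGFProfile,
    threshold_spec: ThresholdSpec,
    domain_annotations: Sequence[DomainAnnotation] = (),
    variant: str = "results",
) -> list[LocusResult]:
    """Classify every representative contig (one per MAG)."""
    return [
        classify_locus(r, profile, threshold_spec, domain_annotations, variant)
        for r in representatives
    ]


def write_locus_table(loci: Iterable[LocusResult], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "mag_id\tcontig_id\tscore\tstatus\troles_present\t"
            "families_hit\texclusion_reason\tcargo_genes\n"
        )
        for l in loci:
            roles = ",".join(sorted(l.roles_present, key=role_sort_key))
            fams = ",".join(sorted(l.families_hit))
            cargo = ",".join(sorted(l.cargo_genes))
            fh.write(
                f"{l.mag_id}\t{l.contig_id}\t{l.score!r}\t{l.status}\t"
                f"{roles}\t{fams}\t{l.exclusion_reason}\t{cargo}\n"
            )


def read_locus_table(path: str | Path) -> list[LocusResult]:
    lines = Path(path).read_text(encoding="utf-8-sig").splitlines()
    header = lines[0].split("\t")
    idx = {name: i for i, name in enumerate(header)}
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        cells = line.split("\t")

        def _set(col: str) -> frozenset[str]:
            return frozenset(x for x in cells[idx[col]].split(",") if x)

        out.append(
            LocusResult(
                mag_id=cells[idx["mag_id"]],
                contig_id=cells[idx["contig_id"]],
                score=float(cells[idx["score"]]),
                roles_present=_set("roles_present"),
                families_hit=_set("families_hit"),
                status=cells[idx["status"]],
                exclusion_reason=cells[idx["exclusion_reason"]],
                cargo_genes=_set("cargo_genes"),
            )
        )
    return out
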