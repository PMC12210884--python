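"""CIS Gene Family (CGF) profile construction.

A CGF profile assigns each orthologous gene family clustered from the
reference CIS loci a conservation *frequency* — the fraction of reference
systems carrying at least one member of the family — a pangenome-style
*category* (core / shell / cloud) derived from that frequency, and a
curated functional *role* (Cis1..Cis15, AIg19, or unknown).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .io_ingest import FamilyMembershipTable

__all__ = [
    "ROLES",
    "UNKNOWN_ROLE",
    "GeneFamily",
    "CGFProfile",
    "classify_family",
    "build_profile",
    "summarize_profile",
    "read_profile_tsv",
    "write_profile_tsv",
    "load_reference_role_map",
]

#: Standardized CIS component roles, in canonical order.
ROLES = (
    "Cis1", "Cis2", "Cis3", "Cis4", "Cis5", "Cis6", "Cis7", "Cis8",
    "Cis9", "Cis10", "Cis11", "Cis12", "Cis13", "Cis14", "Cis15", "AIg19",
)
UNKNOWN_ROLE = "unknown"

# Conservation bins. Attainable frequencies on an n=8 reference grid are
# k/8, so nothing ever lands in (0.95, 0.99); the function is total anyway:
# cloud [0, 0.15), shell [0.15, 0.95], core (0.95, 1].
_CLOUD_UPPER = 0.15
_SHELL_UPPER = 0.95


def role_sort_key(role: str) -> tuple[int, str]:
    """Canonical ordering: Cis1..Cis15, AIg19, then others alphabetically."""
    try:
        return (ROLES.index(role), "")
    except ValueError:
        return (len(ROLES), role)


def classify_family(frequency: float) -> str:
    """Map a conservation frequency to its core/shell/cloud category."""
    if not 0.0 <= frequency <= 1.0:
        raise ValueError(f"frequency {frequency} outside [0, 1]")
    if frequency < _CLOUD_UPPER:
        return "cloud"
    if frequency <= _SHELL_UPPER:
        return "shell"
    return "core"


@dataclass(frozen=True)
class GeneFamily:
    """One CGF family with its conservation frequency and functional role."""

    family_id: str
    role: str
    frequency: float
    category: str
    member_gene_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if classify_family(self.frequency) != self.category:
            raise ValueError(
                f"family {self.family_id!r}: category {self.category!r} "
                f"inconsistent with frequency {self.frequency}"
            )


@dataclass(frozen=True)
class CGFProfile:
    """The full CGF profile over a set of reference CIS loci."""

    families: tuple[GeneFamily, ...]
    n_references: int

    def __post_init__(self) -> None:
        if self.n_references < 1:
            raise ValueError("profile needs n_references >= 1")
        ids = [f.family_id for f in self.families]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate family ids in profile")

    @property
    def by_id(self) -> dict[str, GeneFamily]:
        return {f.family_id: f for f in self.families}

    def frequency(self, family_id: str) -> float:
        return self.by_id[family_id].frequency

    def role(self, family_id: str) -> str:
        return self.by_id[family_id].role

    def families_with_role(self, role: str) -> tuple[GeneFamily, ...]:
        return tuple(f for f in self.families if f.role == role)


def build_profile(
    membership: FamilyMembershipTable,
    role_map: Mapping[str, str] | None = None,
) -> CGFProfile:
    """Build a CGF profile from reference-genome family memberships.

    frequency(family) = (#reference genomes containing >= 1 member) / n;
    duplicate members within one genome do not change the frequency.
    Families absent from ``role_map`` get role ``unknown``.
    """
    role_map = dict(role_map or {})
    unknown = set(role_map) - set(membership.family_ids)
    if unknown:
        raise ValueError(
            f"role_map names unknown families: {', '.join(sorted(unknown))}"
        )
    n = membership.n_references
    if n == 0:
        raise ValueError("membership table has zero reference genomes")
    families = []
    for fam in membership.family_ids:
        freq = membership.presence_count(fam) / n
        members = frozenset(
            g for genes in membership.members[fam].values() for g in genes
        )
        families.append(
            GeneFamily(
                family_id=fam,
                role=role_map.get(fam, UNKNOWN_ROLE),
                frequency=freq,
                category=classify_family(freq),
                member_gene_ids=members,
            )
        )
    return CGFProfile(families=tuple(families), n_references=n)


def summarize_profile(profile: CGFProfile) -> dict[str, dict[str, int]]:
    """Counts of families per conservation category and per role."""
    categories = Counter(f.category for f in profile.families)
    roles = Counter(f.role for f in profile.families)
    return {
        "category_counts": {c: categories.get(c, 0) for c in ("core", "shell", "cloud")},
        "role_counts": dict(sorted(roles.items(), key=lambda kv: role_sort_key(kv[0]))),
    }


def write_profile_tsv(profile: CGFProfile, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("family_id\trole\tfrequency\tcategory\tmember_gene_ids\n")
        for f in profile.families:
            fh.write(
                f"{f.family_id}\t{f.role}\t{f.frequency!r}\t{f.category}\t"
                f"{','.join(sorted(f.member_gene_ids))}\n"
            )


def read_profile_tsv(path: str | Path) -> CGFProfile:
    """Read a profile written by :func:`write_profile_tsv`.

    n_references is recovered from the smallest positive frequency grid;
    it is stored explicitly in the JSON serialization, which is preferred
    when exact provenance matters.
    """
    lines = Path(path).read_text(encoding="utf-8-sig").splitlines()
    header = lines[0].split("\t")
    idx = {name: i for i, name in enumerate(header)}
    families = []
    denominators: set[int] = set()
    for line in lines[1:]:
        if not line.strip():
            continue
        cells = line.split("\t")
        freq = float(cells[idx["frequency"]])
        members = cells[idx["member_gene_ids"]] if "member_gene_ids" in idx else ""
        families.append(
            GeneFamily(
                family_id=cells[idx["family_id"]],
                role=cells[idx["role"]],
                frequency=freq,
                category=cells[idx["category"]],
                member_gene_ids=frozenset(m for m in members.split(",") if m),
            )
        )
        if freq > 0:
            # smallest n with freq*n integral, capped for safety
            for n in range(1, 1025):
                if abs(freq * n - round(freq * n)) < 1e-9:
                    denominators.add(n)
                    break
    n_references = 1
    for n in sorted(denominators):
        if all(abs(f.frequency * n - round(f.frequency * n)) < 1e-9 for f in families):
            n_references = n
            break
    else:
        if denominators:
            n_references = max(denominators)
    return CGFProfile(families=tuple(families), n_references=n_references)


def profile_to_json(profile: CGFProfile, path: str | Path) -> None:
    payload = {
        "n_references": profile.n_references,
        "families": [
            {
                "family_id": f.family_id,
                "role": f.role,
                "frequency": f.frequency,
                "category": f.category,
                "member_gene_ids": sorted(f.member_gene_ids),
            }
            for f in profile.families
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def profile_from_json(path: str | Path) -> CGFProfile:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return CGFProfile(
        families=tuple(
            GeneFamily(
                family_id=f["family_id"],
                role=f["role"],
                frequency=f["frequency"],
                category=f["category"],
                member_gene_ids=frozenset(f["member_gene_ids"]),
            )
            for f in payload["families"]
        ),
        n_references=payload["n_references"],
    )


def load_reference_role_map() -> dict[str, str]:
    """Curated role assignments for the published reference CGF clusters.

    Role annotation is a curation step (families were assigned to CIS
    component roles from prior functional reports), so the map ships as
    package data rather than being inferred.  Only the assignments
    documented for the reference catalog are included.
    """
    path = Path(__file__).parent / "data" / "reference_role_map.tsv"
    out: dict[str, str] = {}
    for line in path.read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("family_id"):
            continue
        fam, role = line.split("\t")[:2]
        out[fam] = role
    return out


def parse_role_map(path: str | Path) -> dict[str, str]:
    """Parse a two-column family_id -> role TSV (header optional)."""
    out: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8-sig").splitlines():
        line = line.rstrip("\r")
        if not line.strip() or line.startswith("#"):
            continue
        cells = line.split("\t")
        if cells[0] == "family_id":
            continue
        if len(cells) < 2:
            raise ValueError(f"role map line needs 2 columns: {line!r}")
        out[cells[0]] = cells[1]
    return out
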