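"""Seeded synthetic reference catalogs, MAG communities and truth labels.

The generator emulates the statistical structure the discovery pipeline
assumes, so every stage is testable without downloading MAG catalogs:

* a reference membership table over eight CIS loci whose per-family
  conservation frequencies sit exactly on the k/8 grid.  The default
  family plan mirrors a published-catalog-style partition — 84 families
  of which 2 are core (8/8), 18 shell and 64 cloud — with the sixteen
  component roles (Cis1..Cis15, AIg19) occupying the conserved end;
* per-MAG DIAMOND-style hit tables containing planted CIS loci, T6SS
  decoys (Cis15 without Cis6/Cis13/Cis14), phage/R-type-bacteriocin
  decoys (Cis13+Cis14 without Cis15/Cis6) and background contigs, with
  tunable gene dropout and spurious-hit noise;
* MAG metadata (biome group, sub-biome, phylum, species) and per-contig
  truth labels, plus recovery evaluation against those labels.

Planted loci are complete by default: they carry one gene for every
profile family (minus the roles their class must lack), the way a real
locus resembles the reference systems it is scored against.  This
guarantees that at zero noise every planted locus clears the
reference-derived score threshold.  ``minimal_rosters`` switches to
one-role-per-essential-class rosters for sharp rule-boundary tests;
those deliberately fall below the threshold.

All outputs are pure functions of (config, profile): the same seed gives
byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .cgf_profile import CGFProfile, ROLES, UNKNOWN_ROLE, build_profile
from .classification import ESSENTIAL_CLASSES, LocusResult, STATUS_CIS
from .io_ingest import (
    BiomeRecord,
    FamilyMembershipTable,
    HomologyHit,
    write_hit_table,
    write_metadata,
)

__all__ = [
    "PLANTED_CLASSES",
    "DEFAULT_FAMILY_PLAN",
    "DEFAULT_ACCESSORY",
    "SyntheticTruth",
    "GeneratorConfig",
    "Community",
    "EvaluationResult",
    "generate_reference_families",
    "default_reference_catalog",
    "generate_community",
    "truth_evaluation",
    "write_truth_table",
    "read_truth_table",
]

PLANTED_CLASSES = ("CIS", "T6SS_decoy", "phage_decoy", "background")

#: Default role -> conservation frequency plan on the k/8 grid.  Cis7 and
#: Cis8 are universal (the two core families); the essential-class roles
#: are highly conserved; Cis15 (AAA+ ATPase) and the tail-fiber AIg19 are
#: the least conserved, matching their restriction to a few reference
#: systems.
DEFAULT_FAMILY_PLAN: dict[str, float] = {
    "Cis7": 1.0,
    "Cis8": 1.0,
    "Cis1": 7 / 8,
    "Cis4": 7 / 8,
    "Cis9": 7 / 8,
    "Cis2": 6 / 8,
    "Cis5": 6 / 8,
    "Cis11": 6 / 8,
    "Cis12": 6 / 8,
    "Cis3": 5 / 8,
    "Cis10": 5 / 8,
    "Cis13": 5 / 8,
    "Cis14": 5 / 8,
    "Cis6": 4 / 8,
    "Cis15": 3 / 8,
    "AIg19": 1 / 8,
}

#: Unknown-role accessory families: 5 shell (2/8) + 63 cloud (1/8), so the
#: default catalog has 84 families partitioned 2 core / 18 shell / 64 cloud.
DEFAULT_ACCESSORY: tuple[float, ...] = (2 / 8,) * 5 + (1 / 8,) * 63

_SUB_BIOMES = {
    "aquatic": ("marine", "sediment", "freshwater"),
    "host-associated": ("digestive system", "plants", "skin"),
    "terrestrial": ("soil", "plant litter"),
    "engineered": ("solid waste", "wastewater"),
}
_PHYLA = ("Bacteroidota", "Proteobacteria", "Actinobacteriota", "Firmicutes", "Verrucomicrobiota")
_PHYLUM_WEIGHTS = (0.45, 0.25, 0.12, 0.10, 0.08)


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted class and role roster of one simulated contig."""

    contig_id: str
    mag_id: str
    planted_class: str
    planted_roles: frozenset[str]
    dropout_applied: frozenset[str]

    def __post_init__(self) -> None:
        if self.planted_class not in PLANTED_CLASSES:
            raise ValueError(f"unknown planted class {self.planted_class!r}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the community generator (all rates per contig/gene)."""

    seed: int = 0
    n_mags: int = 200
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "CIS": 0.4,
            "T6SS_decoy": 0.2,
            "phage_decoy": 0.2,
            "background": 0.2,
        }
    )
    dropout_rate: float = 0.0
    spurious_hit_rate: float = 0.0
    minimal_rosters: bool = False
    protect_essential: bool = False
    identity_range: tuple[float, float] = (60.0, 95.0)
    evalue_range: tuple[float, float] = (1e-50, 1e-10)
    spurious_identity_range: tuple[float, float] = (20.0, 40.0)
    spurious_evalue_range: tuple[float, float] = (1e-8, 1e-2)
    background_contigs_per_mag: int = 2

    def __post_init__(self) -> None:
        unknown = set(self.class_mix) - set(PLANTED_CLASSES)
        if unknown:
            raise ValueError(f"unknown planted class(es): {', '.join(sorted(unknown))}")
        total = sum(self.class_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"class_mix proportions sum to {total}, expected 1")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.spurious_hit_rate < 0 or not math.isfinite(self.spurious_hit_rate):
            raise ValueError("spurious_hit_rate must be finite and >= 0")
        if self.n_mags < 0:
            raise ValueError("n_mags must be >= 0")


@dataclass(frozen=True)
class Community:
    """A generated synthetic community and its ground truth."""

    hits: tuple[HomologyHit, ...]
    metadata: tuple[BiomeRecord, ...]
    truth: tuple[SyntheticTruth, ...]
    config: GeneratorConfig

    def hits_by_mag(self) -> dict[str, list[HomologyHit]]:
        out: dict[str, list[HomologyHit]] = {}
        for h in self.hits:
            out.setdefault(h.mag_id, []).append(h)
        return out

    def write(self, out_dir: str | Path) -> None:
        """Emit per-MAG outfmt-6 hit tables, metadata, truth, and the
        generator config echo for provenance."""
        out = Path(out_dir)
        hits_dir = out / "hits"
        hits_dir.mkdir(parents=True, exist_ok=True)
        for mag, hits in sorted(self.hits_by_mag().items()):
            write_hit_table(hits, hits_dir / f"{mag}.tsv")
        write_metadata(self.metadata, out / "metadata.tsv")
        write_truth_table(self.truth, out / "truth.tsv")
        cfg = asdict(self.config)
        cfg["class_mix"] = dict(cfg["class_mix"])
        for key in ("identity_range", "evalue_range", "spurious_identity_range", "spurious_evalue_range"):
            cfg[key] = list(cfg[key])
        (out / "generator_config.yaml").write_text(
            yaml.safe_dump(cfg, sort_keys=True), encoding="utf-8"
        )


@dataclass(frozen=True)
class EvaluationResult:
    """Recovery of planted classes by the pipeline."""

    sensitivity: float
    specificity: float
    confusion: "object"  # pandas DataFrame: planted class x status

    def __repr__(self) -> str:  # keep the DataFrame out of dataclass repr
        return (
            f"EvaluationResult(sensitivity={self.sensitivity:.4f}, "
            f"specificity={self.specificity:.4f})"
        )


# ---------------------------------------------------------------------------
# Reference catalog generation
# ---------------------------------------------------------------------------


def generate_reference_families(
    n_refs: int = 8,
    family_plan: Mapping[str, float] | None = None,
    seed: int = 0,
    accessory: Sequence[float] = (),
    ensure_essential_coverage: bool = True,
) -> tuple[FamilyMembershipTable, dict[str, str], dict[str, float]]:
    """Generate a membership table whose computed frequencies equal the
    plan exactly.

    ``family_plan`` maps roles to target frequencies on the k/n_refs
    grid (default: :data:`DEFAULT_FAMILY_PLAN`); ``accessory`` adds
    unknown-role families at the given frequencies.  With
    ``ensure_essential_coverage`` memberships are adjusted (keeping
    every frequency on plan) so that each reference genome carries at
    least one family of every essential class the plan covers.

    Returns (membership, role_map, true frequency per family).
    """
    if n_refs < 1:
        raise ValueError("n_refs must be >= 1")
    if family_plan is None:
        family_plan = DEFAULT_FAMILY_PLAN
        if not accessory:
            accessory = DEFAULT_ACCESSORY
    plan: list[tuple[str, str, float]] = []  # (family_id, role, freq)
    counter = 1
    for role in sorted(family_plan, key=lambda r: ROLES.index(r) if r in ROLES else 99):
        plan.append((f"CIS_cluster{counter}", role, family_plan[role]))
        counter += 1
    for freq in accessory:
        plan.append((f"CIS_cluster{counter}", UNKNOWN_ROLE, freq))
        counter += 1

    rng = np.random.default_rng(seed)
    refs = tuple(f"ref{i + 1}" for i in range(n_refs))
    membership_sets: dict[str, set[int]] = {}
    role_map: dict[str, str] = {}
    freqs: dict[str, float] = {}
    for fam, role, freq in plan:
        k = freq * n_refs
        if abs(k - round(k)) > 1e-9 or not 0 < round(k) <= n_refs:
            raise ValueError(
                f"target frequency {freq} for {fam!r} is off the k/{n_refs} grid"
            )
        k = int(round(k))
        membership_sets[fam] = set(rng.choice(n_refs, size=k, replace=False).tolist())
        freqs[fam] = freq
        if role != UNKNOWN_ROLE:
            role_map[fam] = role

    if ensure_essential_coverage:
        _repair_essential_coverage(membership_sets, role_map, n_refs, rng)

    members = {
        fam: {
            refs[r]: (f"{refs[r]}_{fam}",)
            for r in sorted(membership_sets[fam])
        }
        for fam, _, _ in plan
    }
    table = FamilyMembershipTable(reference_ids=refs, members=members)
    return table, role_map, freqs


def _repair_essential_coverage(
    membership_sets: dict[str, set[int]],
    role_map: Mapping[str, str],
    n_refs: int,
    rng: np.random.Generator,
) -> None:
    """Swap memberships so every reference covers each essential class
    that the plan includes, without changing any family's frequency."""
    for cls, roles in ESSENTIAL_CLASSES.items():
        fams = [f for f, r in role_map.items() if r in roles]
        if not fams:
            continue
        for _ in range(4 * n_refs):  # bounded repair loop
            coverage = {
                r: [f for f in fams if r in membership_sets[f]] for r in range(n_refs)
            }
            uncovered = [r for r, fs in coverage.items() if not fs]
            if not uncovered:
                break
            r = uncovered[0]
            # move one membership of the largest class family from a
            # multiply-covered reference to r
            donor_fam = max(fams, key=lambda f: len(membership_sets[f]))
            candidates = [
                s
                for s in sorted(membership_sets[donor_fam])
                if len(coverage[s]) >= 2
            ]
            if not candidates:
                break  # class too sparse to cover everyone; leave as sampled
            s = int(rng.choice(candidates))
            membership_sets[donor_fam].discard(s)
            membership_sets[donor_fam].add(r)


def default_reference_catalog(
    seed: int = 0,
) -> tuple[FamilyMembershipTable, CGFProfile, dict[str, str]]:
    """The default 84-family synthetic reference catalog plus its built
    profile and role map."""
    membership, role_map, _ = generate_reference_families(seed=seed)
    profile = build_profile(membership, role_map)
    return membership, profile, role_map


# ---------------------------------------------------------------------------
# Community generation
# ---------------------------------------------------------------------------


def _allocate_classes(mix: Mapping[str, float], n: int) -> list[str]:
    """Deterministic largest-remainder allocation of n MAGs to classes."""
    classes = [c for c in PLANTED_CLASSES if mix.get(c, 0.0) > 0]
    raw = {c: mix[c] * n for c in classes}
    counts = {c: int(math.floor(raw[c])) for c in classes}
    remainder = n - sum(counts.values())
    by_frac = sorted(classes, key=lambda c: (-(raw[c] - counts[c]), c))
    for c in by_frac[:remainder]:
        counts[c] += 1
    out: list[str] = []
    for c in classes:
        out.extend([c] * counts[c])
    return out


def _class_roster(
    planted_class: str, profile: CGFProfile, minimal: bool
) -> list[str]:
    """Family ids planted on a contig of the given class."""
    if planted_class == "background":
        return []
    if minimal:
        roles = {
            "CIS": ("Cis8", "Cis1", "Cis4"),
            "T6SS_decoy": ("Cis8", "Cis1", "Cis4", "Cis15"),
            "phage_decoy": ("Cis8", "Cis1", "Cis4", "Cis13", "Cis14"),
        }[planted_class]
        roster = []
        for role in roles:
            fams = profile.families_with_role(role)
            if not fams:
                raise ValueError(f"profile lacks a family for role {role!r}")
            roster.append(fams[0].family_id)
        return roster
    forbidden = {
        "CIS": frozenset(),
        "T6SS_decoy": frozenset({"Cis6", "Cis13", "Cis14", "AIg19"}),
        "phage_decoy": frozenset({"Cis6", "Cis15"}),
    }[planted_class]
    return [f.family_id for f in profile.families if f.role not in forbidden]


def _log_uniform(rng: np.random.Generator, low: float, high: float) -> float:
    return float(10 ** rng.uniform(math.log10(low), math.log10(high)))


def _make_hit(
    rng: np.random.Generator,
    mag: str,
    contig: str,
    gene: str,
    family: str,
    identity_range: tuple[float, float],
    evalue_range: tuple[float, float],
) -> HomologyHit:
    identity = float(rng.uniform(*identity_range))
    length = int(rng.integers(150, 601))
    evalue = _log_uniform(rng, *evalue_range)
    bitscore = round(max(2.0 * length * identity / 100.0, 25.0), 1)
    return HomologyHit(
        query_gene_id=f"{mag}|{contig}|{gene}",
        mag_id=mag,
        contig_id=contig,
        family_id=family,
        percent_identity=round(identity, 1),
        alignment_length=length,
        evalue=evalue,
        bitscore=bitscore,
    )


def generate_community(config: GeneratorConfig, profile: CGFProfile) -> Community:
    """Generate hit tables, metadata and truth for a synthetic community.

    Pre-dropout, planted CIS contigs cover all three essential classes
    and trigger no exclusion rule; T6SS decoys carry Cis15 without
    Cis6/Cis13/Cis14; phage decoys carry Cis13+Cis14 without Cis15/Cis6;
    background contigs carry only spurious hits.  Dropout removes each
    planted gene hit independently; ``protect_essential`` resurrects one
    family per essential class that dropout silenced entirely.
    """
    rng = np.random.default_rng(config.seed)
    assignment = _allocate_classes(config.class_mix, config.n_mags)
    rng.shuffle(assignment)

    by_role: dict[str, list[str]] = {}
    for f in profile.families:
        by_role.setdefault(f.role, []).append(f.family_id)
    all_families = [f.family_id for f in profile.families]

    hits: list[HomologyHit] = []
    truth: list[SyntheticTruth] = []
    metadata: list[BiomeRecord] = []

    for i, planted_class in enumerate(assignment):
        mag = f"MAG{i:04d}"
        metadata.append(_sample_metadata(rng, mag))

        contig_ids = (
            [f"ctg{i:04d}_{c + 1}" for c in range(config.background_contigs_per_mag)]
            if planted_class == "background"
            else [f"ctg{i:04d}_1"]
        )
        roster = _class_roster(planted_class, profile, config.minimal_rosters)
        planted_roles = frozenset(
            profile.role(f) for f in roster if profile.role(f) != UNKNOWN_ROLE
        )

        for c_idx, contig in enumerate(contig_ids):
            planted_here = roster if c_idx == 0 else []
            kept: dict[str, str] = {}  # family -> gene name
            dropped_families: list[str] = []
            for fam in planted_here:
                gene = f"g_{fam}"
                if config.dropout_rate > 0 and rng.random() < config.dropout_rate:
                    dropped_families.append(fam)
                else:
                    kept[fam] = gene
            if config.protect_essential and planted_here:
                for cls, roles in ESSENTIAL_CLASSES.items():
                    class_fams = [f for f in planted_here if profile.role(f) in roles]
                    if class_fams and not any(f in kept for f in class_fams):
                        revived = class_fams[int(rng.integers(len(class_fams)))]
                        kept[revived] = f"g_{revived}"
                        dropped_families.remove(revived)
            for fam, gene in kept.items():
                hits.append(
                    _make_hit(
                        rng, mag, contig, gene, fam,
                        config.identity_range, config.evalue_range,
                    )
                )
            n_spurious = (
                int(rng.poisson(config.spurious_hit_rate))
                if config.spurious_hit_rate > 0
                else 0
            )
            for s in range(n_spurious):
                fam = all_families[int(rng.integers(len(all_families)))]
                hits.append(
                    _make_hit(
                        rng, mag, contig, f"sp{s}", fam,
                        config.spurious_identity_range, config.spurious_evalue_range,
                    )
                )
            kept_roles = frozenset(
                profile.role(f) for f in kept if profile.role(f) != UNKNOWN_ROLE
            )
            truth.append(
                SyntheticTruth(
                    contig_id=contig,
                    mag_id=mag,
                    planted_class=planted_class if c_idx == 0 else "background",
                    planted_roles=planted_roles if c_idx == 0 else frozenset(),
                    dropout_applied=(planted_roles - kept_roles) if c_idx == 0 else frozenset(),
                )
            )

    return Community(
        hits=tuple(hits),
        metadata=tuple(metadata),
        truth=tuple(truth),
        config=config,
    )


def _sample_metadata(rng: np.random.Generator, mag: str) -> BiomeRecord:
    groups = tuple(_SUB_BIOMES)
    group = groups[int(rng.choice(len(groups), p=(0.3, 0.35, 0.2, 0.15)))]
    subs = _SUB_BIOMES[group]
    sub = subs[int(rng.integers(len(subs)))]
    phylum = _PHYLA[int(rng.choice(len(_PHYLA), p=_PHYLUM_WEIGHTS))]
    # ~15% of MAGs are unclassified at species level
    species = "" if rng.random() < 0.15 else f"{phylum} sp{int(rng.integers(1, 8))}"
    return BiomeRecord(
        mag_id=mag, biome_group=group, sub_biome=sub, phylum=phylum, species=species
    )


# ---------------------------------------------------------------------------
# Recovery evaluation
# ---------------------------------------------------------------------------


def truth_evaluation(
    loci: Sequence[LocusResult], truth: Sequence[SyntheticTruth]
) -> EvaluationResult:
    """Compare pipeline calls with planted truth.

    Sensitivity: fraction of planted-CIS contigs called CIS.
    Specificity: fraction of planted non-CIS contigs not called CIS.
    Truth contigs the pipeline produced no call for (no accepted hits,
    or not the MAG's representative) count as ``no_call`` — a negative.
    Calls referencing contigs absent from the truth are an error.
    """
    import pandas as pd

    truth_by_id = {(t.mag_id, t.contig_id): t for t in truth}
    orphans = [
        f"{l.mag_id}|{l.contig_id}"
        for l in loci
        if (l.mag_id, l.contig_id) not in truth_by_id
    ]
    if orphans:
        raise ValueError(
            "call set references contigs absent from truth: " + ", ".join(orphans)
        )
    call_by_id = {(l.mag_id, l.contig_id): l for l in loci}
    statuses = sorted({l.status for l in loci} | {"no_call"})
    confusion = pd.DataFrame(
        0, index=list(PLANTED_CLASSES), columns=statuses, dtype=int
    )
    for key, t in truth_by_id.items():
        call = call_by_id.get(key)
        status = call.status if call is not None else "no_call"
        confusion.loc[t.planted_class, status] += 1
    n_cis = int(confusion.loc["CIS"].sum())
    n_non = int(confusion.drop(index="CIS").to_numpy().sum())
    tp = int(confusion.loc["CIS", STATUS_CIS]) if STATUS_CIS in confusion else 0
    fp = (
        int(confusion.drop(index="CIS")[STATUS_CIS].sum())
        if STATUS_CIS in confusion
        else 0
    )
    sensitivity = tp / n_cis if n_cis else float("nan")
    specificity = (n_non - fp) / n_non if n_non else float("nan")
    return EvaluationResult(
        sensitivity=sensitivity, specificity=specificity, confusion=confusion
    )


def write_truth_table(truth: Iterable[SyntheticTruth], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("mag_id\tcontig_id\tplanted_class\tplanted_roles\tdropout_applied\n")
        for t in truth:
            fh.write(
                f"{t.mag_id}\t{t.contig_id}\t{t.planted_class}\t"
                f"{','.join(sorted(t.planted_roles))}\t"
                f"{','.join(sorted(t.dropout_applied))}\n"
            )


def read_truth_table(path: str | Path) -> list[SyntheticTruth]:
    lines = Path(path).read_text(encoding="utf-8-sig").splitlines()
    header = lines[0].split("\t")
    idx = {name: i for i, name in enumerate(header)}
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        cells = line.split("\t")
        out.append(
            SyntheticTruth(
                mag_id=cells[idx["mag_id"]],
                contig_id=cells[idx["contig_id"]],
                planted_class=cells[idx["planted_class"]],
                planted_roles=frozenset(
                    x for x in cells[idx["planted_roles"]].split(",") if x
                ),
                dropout_applied=frozenset(
                    x for x in cells[idx["dropout_applied"]].split(",") if x
                ),
            )
        )
    return out
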