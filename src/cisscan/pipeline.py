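"""End-to-end discovery convenience wrapper.

Chains hit filtering, per-contig scoring, representative selection,
reference-derived thresholding and classification into one call, the way
the CLI and the acceptance workflow drive the library.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .cgf_profile import CGFProfile
from .classification import LocusResult, classify_representatives
from .io_ingest import DomainAnnotation, FamilyMembershipTable, HomologyHit
from .scoring import (
    ScoreResult,
    ScoringConfig,
    ThresholdSpec,
    filter_hits,
    reference_self_scores,
    reference_threshold,
    score_contigs,
    select_representatives,
)

__all__ = ["DiscoveryResult", "run_discovery"]


@dataclass(frozen=True)
class DiscoveryResult:
    accepted_hits: tuple[HomologyHit, ...]
    contig_scores: tuple[ScoreResult, ...]
    representatives: tuple[ScoreResult, ...]
    threshold: ThresholdSpec
    loci: tuple[LocusResult, ...]

    @property
    def cis_loci(self) -> tuple[LocusResult, ...]:
        return tuple(l for l in self.loci if l.status == "CIS")

    def accepted_hits_by_locus(self) -> dict[str, list[HomologyHit]]:
        """Accepted hits grouped per representative contig, keyed by
        ``mag|contig`` locus id."""
        keys = {(r.mag_id, r.contig_id) for r in self.representatives}
        out: dict[str, list[HomologyHit]] = {
            f"{m}|{c}": [] for m, c in keys
        }
        for h in self.accepted_hits:
            if (h.mag_id, h.contig_id) in keys:
                out[f"{h.mag_id}|{h.contig_id}"].append(h)
        return out


def run_discovery(
    hits: Iterable[HomologyHit],
    profile: CGFProfile,
    membership: FamilyMembershipTable,
    config: ScoringConfig | None = None,
    domain_annotations: Sequence[DomainAnnotation] = (),
    variant: str = "results",
) -> DiscoveryResult:
    """Run the full screening cascade on a set of homology hits."""
    config = config or ScoringConfig()
    accepted = filter_hits(
        hits,
        min_identity=config.min_identity,
        max_evalue=config.max_evalue,
        keep_ties=config.keep_ties,
    )
    scores = score_contigs(accepted, profile, config)
    representatives = select_representatives(scores)
    ref_scores = reference_self_scores(membership, profile, config)
    spec = reference_threshold(
        list(ref_scores.values()),
        fraction=config.threshold_fraction,
        mode=config.threshold_mode,
    )
    loci = classify_representatives(
        representatives, profile, spec, domain_annotations, variant
    )
    return DiscoveryResult(
        accepted_hits=tuple(accepted),
        contig_scores=tuple(scores),
        representatives=tuple(representatives),
        threshold=spec,
        loci=tuple(loci),
    )
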