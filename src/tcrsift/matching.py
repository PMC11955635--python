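"""Cross-patient search for identical or homologous TCRs.

Given query TCRs (CDR3 amino-acid sequence plus V gene), independent subject
repertoires are scanned for perfect matches (identical CDR3 and V gene) and
near matches (Levenshtein distance 1..max_distance on the CDR3, same V gene).
For archival FFPE material, where sequencing artifacts abound, near matches
are only accepted when strongly supported (frequency > 0.001% and coverage
> 4 reads); perfect matches are accepted regardless.  V-gene comparison
collapses allele designations (TRBV6-5*01 == TRBV6-5) and J genes are not
compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib

from .repertoire import RepertoireProfile

__all__ = ["QueryTCR", "MatchHit", "match_tcr", "summarize_matches"]

_AA = set("ACDEFGHIKLMNPQRSTVWY")

FFPE_MIN_FREQUENCY_PCT = 0.001
FFPE_MIN_COVERAGE = 4


@dataclass(frozen=True)
class QueryTCR:
    name: str
    chain: str  # TRB or TRA
    cdr3_aa: str
    v_call: str
    j_call: str | None = None

    def __post_init__(self) -> None:
        if self.chain not in ("TRB", "TRA"):
            raise ValueError(f"{self.name}: chain must be TRB or TRA")
        if not self.cdr3_aa or not set(self.cdr3_aa) <= _AA:
            raise ValueError(f"{self.name}: cdr3_aa must be a non-empty "
                             "uppercase amino-acid string")


@dataclass(frozen=True)
class MatchHit:
    query_name: str
    subject_sample_id: str
    subject_key: tuple[str, str, str]
    match_class: str  # "perfect" | "near"
    edit_distance: int
    subject_frequency: float  # percent
    subject_coverage: int     # reads
    accepted: bool


def strip_allele(v_call: str) -> str:
    return v_call.split("*")[0]


def levenshtein(a: str, b: str) -> int:
    """Edit distance between two amino-acid strings."""
    if a == b:
        return 0
    return edlib.align(a, b, task="distance")["editDistance"]


def match_tcr(query: QueryTCR, subject: RepertoireProfile,
              max_distance: int = 2, ffpe_mode: bool = False,
              filter_perfect: bool = False) -> list[MatchHit]:
    """Find perfect and near matches of one query TCR in a subject repertoire.

    In ``ffpe_mode`` a hit is accepted when it is perfect, or when its
    subject frequency exceeds 0.001% and its coverage exceeds 4 reads (both
    strict); outside ``ffpe_mode`` every hit is accepted.  ``filter_perfect``
    subjects perfect matches to the same support filter (off by default:
    a perfect CDR3+V match is not an artifact candidate).  Hits are sorted by
    edit distance, then subject frequency descending.
    """
    qv = strip_allele(query.v_call)
    hits = []
    for clon in subject.clonotypes:
        if not clon.junction_aa or strip_allele(clon.v_call) != qv:
            continue
        dist = levenshtein(query.cdr3_aa, clon.junction_aa)
        if dist > max_distance:
            continue
        perfect = dist == 0
        if ffpe_mode:
            supported = (clon.frequency > FFPE_MIN_FREQUENCY_PCT
                         and clon.read_count > FFPE_MIN_COVERAGE)
            accepted = supported or (perfect and not filter_perfect)
        else:
            accepted = True
        hits.append(MatchHit(
            query_name=query.name,
            subject_sample_id=subject.sample_id,
            subject_key=(clon.junction_nt, clon.v_call, clon.j_call),
            match_class="perfect" if perfect else "near",
            edit_distance=dist,
            subject_frequency=clon.frequency,
            subject_coverage=clon.read_count,
            accepted=accepted,
        ))
    hits.sort(key=lambda h: (h.edit_distance, -h.subject_frequency))
    return hits


def summarize_matches(hits: Iterable[MatchHit],
                      samples: Sequence[str]) -> dict:
    """Per-sample accepted-hit summary plus the overall hit-sample count."""
    per_sample = {s: {"accepted_hits": 0, "best_edit_distance": None,
                      "max_subject_frequency": 0.0} for s in samples}
    for hit in hits:
        if not hit.accepted:
            continue
        entry = per_sample.setdefault(
            hit.subject_sample_id,
            {"accepted_hits": 0, "best_edit_distance": None,
             "max_subject_frequency": 0.0})
        entry["accepted_hits"] += 1
        if (entry["best_edit_distance"] is None
                or hit.edit_distance < entry["best_edit_distance"]):
            entry["best_edit_distance"] = hit.edit_distance
        entry["max_subject_frequency"] = max(entry["max_subject_frequency"],
                                             hit.subject_frequency)
    return {
        "per_sample": per_sample,
        "samples_with_hits": sum(1 for e in per_sample.values()
                                 if e["accepted_hits"] > 0),
    }
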