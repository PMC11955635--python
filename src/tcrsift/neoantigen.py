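"""Mutant peptide enumeration and binding-score filtering.

Coding variants in HGVS c. notation (single-base substitutions like
``c.183A>T`` or codon replacements like ``c.181-183CAT>CGC``) are applied to a
coding sequence; wild-type and mutant proteins are compared to derive the
protein-level change and to enumerate all 9- and 10-mer peptide windows that
contain a mutated residue (for truncating or frameshift changes: every window
overlapping the novel sequence through the new C-terminus).  Windows identical
to the wild-type protein are excluded — they cannot be neoepitopes.

HLA binding scores are injected from a predictor export (TSV with columns
``peptide``, ``allele``, ``ic50_nM``, ``percentile_rank``); a candidate passes
when IC50 < 500 nM and/or percentile rank < 6, survivors are ranked by
percentile rank (IC50 tiebreak) and the global top-N retained.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "CodingVariant",
    "PeptideCandidate",
    "apply_variant",
    "enumerate_mutant_peptides",
    "filter_and_rank",
]

_HGVS_C = re.compile(r"^c\.(\d+)(?:-(\d+))?([ACGT]+)>([ACGT]+)$")

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Ter",
}


@dataclass(frozen=True)
class CodingVariant:
    """A coding-sequence change in HGVS c. notation (1-based positions)."""

    transcript: str
    hgvs_c: str

    def parse(self) -> tuple[int, int, str, str]:
        """Return (start, end, ref, alt), positions 1-based inclusive."""
        m = _HGVS_C.match(self.hgvs_c)
        if m is None:
            raise ValueError(f"unsupported HGVS c. syntax: {self.hgvs_c}")
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start + len(m.group(3)) - 1
        ref, alt = m.group(3), m.group(4)
        if end - start + 1 != len(ref):
            raise ValueError(
                f"{self.hgvs_c}: reference length does not match positions")
        return start, end, ref, alt


@dataclass(frozen=True)
class AppliedVariant:
    variant: CodingVariant
    mutant_cds: str
    wt_protein: str
    mutant_protein: str
    hgvs_p: str
    truncating: bool
    frameshift: bool


@dataclass(frozen=True)
class PeptideCandidate:
    variant: CodingVariant
    window_start: int  # 1-based residue position in the mutant protein
    length: int
    sequence: str
    hla_allele: str | None = None
    ic50_nM: float | None = None
    percentile_rank: float | None = None
    passes_filter: bool = False
    rank_in_allele: int | None = None


def _translate_to_stop(cds: str) -> str:
    aa = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    stop = aa.find("*")
    return aa if stop == -1 else aa[:stop]


def _derive_hgvs_p(wt: str, mut: str, frameshift: bool) -> tuple[str, bool]:
    """Protein-level change from codon-by-codon comparison; one-letter codes."""
    if wt == mut:
        return "p.=", False
    # first differing residue
    i = 0
    while i < min(len(wt), len(mut)) and wt[i] == mut[i]:
        i += 1
    if frameshift:
        ref = wt[i] if i < len(wt) else "*"
        return f"p.{ref}{i + 1}fs", True
    if len(mut) < len(wt):
        # premature stop
        if i == len(mut):
            return f"p.{wt[i]}{i + 1}*", True
        return f"p.{wt[i]}{i + 1}{mut[i]}", len(mut) < len(wt)
    diffs = [j for j in range(len(wt)) if wt[j] != mut[j]]
    if len(diffs) == 1:
        j = diffs[0]
        return f"p.{wt[j]}{j + 1}{mut[j]}", False
    j, k = diffs[0], diffs[-1]
    return (f"p.{wt[j]}{j + 1}_{wt[k]}{k + 1}delins{mut[j:k + 1]}", False)


def apply_variant(cds: str, variant: CodingVariant) -> AppliedVariant:
    """Apply an HGVS c. substitution/codon replacement to a coding sequence.

    Validates the stated reference bases against the sequence, returns the
    mutant CDS, both translations (to the first stop codon) and the derived
    protein change.  A variant introducing a premature stop is flagged
    truncating; unequal ref/alt lengths are treated as frameshift when the
    length difference is not a multiple of three.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("coding sequence length must be a multiple of 3")
    start, end, ref, alt = variant.parse()
    if cds[start - 1:end] != ref:
        raise ValueError(
            f"{variant.hgvs_c}: reference is {cds[start - 1:end]!r} in the "
            f"sequence, not {ref!r}")
    mutant_cds = cds[: start - 1] + alt + cds[end:]
    frameshift = (len(alt) - len(ref)) % 3 != 0
    wt_protein = _translate_to_stop(cds)
    mut_protein = _translate_to_stop(mutant_cds)
    hgvs_p, truncating = _derive_hgvs_p(wt_protein, mut_protein, frameshift)
    return AppliedVariant(
        variant=variant,
        mutant_cds=mutant_cds,
        wt_protein=wt_protein,
        mutant_protein=mut_protein,
        hgvs_p=hgvs_p,
        truncating=truncating,
        frameshift=frameshift,
    )


def enumerate_mutant_peptides(
    wt_protein: str,
    mut_protein: str,
    lengths: Sequence[int] = (9, 10),
    variant: CodingVariant | None = None,
) -> list[PeptideCandidate]:
    """All mutation-covering peptide windows of the given lengths.

    For equal-length proteins (substitutions) every window containing at least
    one changed residue is emitted; for truncating/frameshift changes every
    window overlapping the novel C-terminal sequence is emitted.  Windows
    whose sequence also occurs at the same position in the wild type are
    dropped.  Window starts are 1-based on the mutant protein.
    """
    if not wt_protein or not mut_protein:
        raise ValueError("proteins must be non-empty")
    if wt_protein == mut_protein:
        return []
    if len(wt_protein) == len(mut_protein):
        changed = {i for i in range(len(wt_protein))
                   if wt_protein[i] != mut_protein[i]}
    else:
        i = 0
        while (i < min(len(wt_protein), len(mut_protein))
               and wt_protein[i] == mut_protein[i]):
            i += 1
        changed = set(range(i, len(mut_protein)))
    out = []
    n = len(mut_protein)
    for length in lengths:
        for start0 in range(0, n - length + 1):
            window = set(range(start0, start0 + length))
            if not window & changed:
                continue
            seq = mut_protein[start0:start0 + length]
            if wt_protein[start0:start0 + length] == seq:
                continue
            out.append(PeptideCandidate(
                variant=variant,
                window_start=start0 + 1,
                length=length,
                sequence=seq,
            ))
    return out


def filter_and_rank(
    candidates: Iterable[PeptideCandidate],
    top_n: int = 94,
    qc_peptides: Sequence[PeptideCandidate] = (),
    rank_by: str = "percentile_rank",
) -> list[PeptideCandidate]:
    """Binding filter (IC50 < 500 nM and/or percentile rank < 6) plus top-N.

    Each candidate must carry at least one of ``ic50_nM`` / ``percentile_rank``
    for its allele; candidates with neither score are excluded with a warning.
    Survivors are ordered by ``rank_by`` ascending (``percentile_rank`` default,
    ``ic50_nM`` selectable) with the other score then the sequence as
    tiebreaks; ``rank_in_allele`` records each survivor's rank among survivors
    of the same allele and the global top-N are retained.  QC peptides are
    appended unranked.
    """
    if rank_by not in ("percentile_rank", "ic50_nM"):
        raise ValueError("rank_by must be 'percentile_rank' or 'ic50_nM'")
    secondary = "ic50_nM" if rank_by == "percentile_rank" else "percentile_rank"
    scored = []
    for cand in candidates:
        if cand.ic50_nM is None and cand.percentile_rank is None:
            warnings.warn(
                f"peptide {cand.sequence} has no binding score; excluded",
                stacklevel=2)
            continue
        passes = ((cand.ic50_nM is not None and cand.ic50_nM < 500.0)
                  or (cand.percentile_rank is not None
                      and cand.percentile_rank < 6.0))
        scored.append(replace(cand, passes_filter=passes))
    survivors = [c for c in scored if c.passes_filter]

    inf = float("inf")

    def sort_key(c: PeptideCandidate):
        primary = getattr(c, rank_by)
        second = getattr(c, secondary)
        return (primary if primary is not None else inf,
                second if second is not None else inf,
                c.sequence)

    survivors.sort(key=sort_key)
    per_allele: dict = {}
    ranked = []
    for cand in survivors:
        r = per_allele.get(cand.hla_allele, 0) + 1
        per_allele[cand.hla_allele] = r
        ranked.append(replace(cand, rank_in_allele=r))
    return ranked[:top_n] + list(qc_peptides)


def candidates_to_frame(candidates: Sequence[PeptideCandidate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "transcript": c.variant.transcript if c.variant else None,
        "hgvs_c": c.variant.hgvs_c if c.variant else None,
        "window_start": c.window_start,
        "length": c.length,
        "peptide": c.sequence,
        "hla_allele": c.hla_allele,
        "ic50_nM": c.ic50_nM,
        "percentile_rank": c.percentile_rank,
        "passes_filter": c.passes_filter,
        "rank_in_allele": c.rank_in_allele,
    } for c in candidates])
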