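"""From paired TCR amplicon reads to clonotype tables.

Implements the bulk TCRseq preprocessing chain: quality-aware merging of
overlapping read pairs into consensus sequences spanning the CDR3 junction,
anchor-based V/J segment assignment with junction extraction, clustering of
junctions into clonotypes with per-sample frequencies, the productive-ORF
filter, and AIRR Rearrangement TSV input/output.

The junction convention is IMGT-style: from the conserved V-gene cysteine
codon through the conserved J-gene phenylalanine/tryptophan codon, inclusive
of both anchors.  Clonotype identity defaults to the triple
(junction_nt, v_call, j_call).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .segments import SegmentLibrary

__all__ = [
    "ReadPair",
    "ConsensusSequence",
    "Clonotype",
    "RepertoireProfile",
    "VJAssignment",
    "merge_read_pair",
    "assign_vj_and_extract_junction",
    "cluster_clonotypes",
    "filter_productive",
    "run_clonotyping",
    "read_fastq_pairs",
    "read_airr",
    "write_airr",
]

_NT = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

AIRR_REQUIRED_COLUMNS = (
    "junction", "junction_aa", "v_call", "j_call", "duplicate_count",
    "productive",
)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadPair:
    """One paired-end read; mate 2 is stored as sequenced (reverse strand)."""

    pair_id: str
    seq1: str
    seq2: str
    qual1: tuple[int, ...]
    qual2: tuple[int, ...]

    def __post_init__(self) -> None:
        for seq, qual, mate in ((self.seq1, self.qual1, 1),
                                (self.seq2, self.qual2, 2)):
            if len(seq) != len(qual):
                raise ValueError(
                    f"{self.pair_id}: mate {mate} sequence/quality length mismatch"
                )
            if not set(seq) <= _NT:
                raise ValueError(
                    f"{self.pair_id}: mate {mate} contains non-nucleotide characters"
                )


@dataclass(frozen=True)
class ConsensusSequence:
    pair_id: str
    sequence: str
    overlap_len: int
    mismatches_in_overlap: int


@dataclass(frozen=True)
class Clonotype:
    """One unique rearrangement with its abundance in a sample."""

    junction_nt: str
    junction_aa: str
    v_call: str
    j_call: str
    read_count: int
    frequency: float  # percent of sample reads
    productive: bool


@dataclass
class RepertoireProfile:
    """Ordered clonotype list for one sample/compartment."""

    sample_id: str
    compartment: str = "other"
    clonotypes: list[Clonotype] = field(default_factory=list)
    total_reads: int = 0

    COMPARTMENTS = ("tumor", "lung", "blood", "pd1_til", "plasma_cfdna",
                    "ffpe", "other")

    def __post_init__(self) -> None:
        if self.compartment not in self.COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [vars(c) for c in self.clonotypes],
            columns=["junction_nt", "junction_aa", "v_call", "j_call",
                     "read_count", "frequency", "productive"],
        )


@dataclass(frozen=True)
class VJAssignment:
    """Junction and segment calls extracted from one consensus sequence."""

    pair_id: str
    junction_nt: str
    v_call: str
    j_call: str


# ---------------------------------------------------------------------------
# read merging
# ---------------------------------------------------------------------------

def merge_read_pair(pair: ReadPair, min_overlap: int = 20,
                    max_mismatch_frac: float = 0.10) -> ConsensusSequence | None:
    """Merge a read pair over its best ungapped overlap.

    Mate 2 is reverse-complemented, then every overlap length between the 3'
    end of mate 1 and the 5' end of the flipped mate 2 is scored.  The overlap
    maximizing matches-minus-mismatches wins (ties go to the longer overlap).
    The pair is rejected (``None``) when the best overlap is shorter than
    ``min_overlap`` or its mismatch fraction exceeds ``max_mismatch_frac``.

    Disagreeing positions take the base with the higher Phred score; on a
    quality tie mate 1 wins.  ``N`` never wins a disagreement and counts as a
    mismatch, so an all-``N`` overlap is rejected.
    """
    if min_overlap < 10:
        raise ValueError("min_overlap must be >= 10")
    if not pair.seq1 or not pair.seq2:
        raise ValueError(f"{pair.pair_id}: empty mate sequence")

    s1 = np.frombuffer(pair.seq1.encode(), dtype="S1")
    s2 = np.frombuffer(revcomp(pair.seq2).encode(), dtype="S1")
    q1 = np.asarray(pair.qual1, dtype=np.int16)
    q2 = np.asarray(pair.qual2, dtype=np.int16)[::-1]

    n_pos = (s1 == b"N")
    best = None  # (score, L, mismatches)
    max_l = min(len(s1), len(s2))
    for L in range(1, max_l + 1):
        a = s1[len(s1) - L:]
        b = s2[:L]
        eq = (a == b) & (a != b"N")
        matches = int(eq.sum())
        score = 2 * matches - L  # matches - mismatches
        if best is None or score > best[0] or (score == best[0] and L > best[1]):
            best = (score, L, L - matches)
    _, L, mismatches = best
    if L < min_overlap or mismatches / L > max_mismatch_frac:
        return None

    off = len(s1) - L
    a, b = s1[off:], s2[:L]
    qa, qb = q1[off:], q2[:L]
    take_b = (qb > qa) | (a == b"N")
    take_b &= (b != b"N")
    merged_overlap = np.where(take_b, b, a)
    sequence = (pair.seq1[:off]
                + merged_overlap.tobytes().decode()
                + revcomp(pair.seq2)[L:])
    return ConsensusSequence(pair.pair_id, sequence, L, mismatches)


# ---------------------------------------------------------------------------
# V/J assignment
# ---------------------------------------------------------------------------

def _best_placement(consensus: np.ndarray, ref: np.ndarray,
                    min_identity: float, min_match_len: int):
    """Best ungapped placement of ``ref`` on ``consensus``.

    Returns (matches, overlap_len, shift) of the best qualifying placement or
    None.  ``shift`` is the consensus offset of ref position 0 (may be
    negative when only a suffix of the reference overlaps).
    """
    lc, lr = len(consensus), len(ref)
    best = None
    ref_bytes = ref.tobytes()
    cons_bytes = consensus.tobytes()
    # fast path: exact full-length occurrence
    idx = cons_bytes.find(ref_bytes)
    if idx != -1 and lr >= min_match_len:
        return (lr, lr, idx)
    for shift in range(-(lr - min_match_len), lc - min_match_len + 1):
        lo = max(0, shift)
        hi = min(lc, shift + lr)
        ov = hi - lo
        if ov < min_match_len:
            continue
        a = consensus[lo:hi]
        b = ref[lo - shift:hi - shift]
        matches = int((a == b).sum())
        if matches / ov < min_identity:
            continue
        key = (matches, ov, -shift)
        if best is None or key > best[0]:
            best = (key, shift, matches, ov)
    if best is None:
        return None
    return (best[2], best[3], best[1])


def assign_vj_and_extract_junction(
    consensus: ConsensusSequence,
    library: SegmentLibrary,
    min_identity: float = 0.9,
    min_match_len: int = 20,
) -> VJAssignment | None:
    """Assign V and J segments and cut out the junction, or return None.

    Each reference is slid ungapped along the consensus; the qualifying
    placement with the most matching bases wins (ties: longer overlap, then
    lexicographically smaller segment name).  The junction runs from the
    V-segment Cys codon through the J-segment Phe/Trp codon and both anchor
    codons must land inside the consensus.
    """
    cons = np.frombuffer(consensus.sequence.encode(), dtype="S1")

    def best_segment(segments):
        best = None
        for seg in segments:
            ref = np.frombuffer(seg.sequence.encode(), dtype="S1")
            hit = _best_placement(cons, ref, min_identity, min_match_len)
            if hit is None:
                continue
            matches, ov, shift = hit
            key = (matches, ov)
            if best is None or key > best[0] or (key == best[0]
                                                 and seg.name < best[1].name):
                best = (key, seg, shift)
        return best

    v_best = best_segment(library.v_segments)
    j_best = best_segment(library.j_segments)
    if v_best is None or j_best is None:
        return None
    _, v_seg, v_shift = v_best
    _, j_seg, j_shift = j_best
    jstart = v_shift + v_seg.anchor_start
    jend = j_shift + j_seg.anchor_start + 3
    if jstart < 0 or jend > len(cons) or jend - jstart < 6:
        return None
    return VJAssignment(
        pair_id=consensus.pair_id,
        junction_nt=consensus.sequence[jstart:jend],
        v_call=v_seg.name,
        j_call=j_seg.name,
    )


# ---------------------------------------------------------------------------
# clonotype clustering and productivity
# ---------------------------------------------------------------------------

def _translate(junction_nt: str) -> str:
    n = len(junction_nt) - len(junction_nt) % 3
    if n == 0:
        return ""
    return str(Seq(junction_nt[:n]).translate())


def is_productive(junction_nt: str) -> bool:
    """In-frame, no internal stop, Cys...Phe/Trp anchor residues."""
    if len(junction_nt) % 3 != 0 or len(junction_nt) < 6:
        return False
    aa = _translate(junction_nt)
    return (not aa.count("*")
            and aa.startswith("C")
            and aa[-1] in "FW")


def cluster_clonotypes(assignments: Iterable[VJAssignment],
                       sample_id: str = "sample",
                       compartment: str = "other") -> RepertoireProfile:
    """Group assigned records into unique clonotypes with frequencies.

    Identity key is (junction_nt, v_call, j_call); frequency is the percentage
    of clonotype reads among all assigned reads.  Clonotypes are ordered by
    frequency descending with ties broken by junction_nt.
    """
    counts: dict[tuple[str, str, str], int] = {}
    for rec in assignments:
        key = (rec.junction_nt, rec.v_call, rec.j_call)
        counts[key] = counts.get(key, 0) + 1
    total = sum(counts.values())
    clonotypes = [
        Clonotype(
            junction_nt=jnt,
            junction_aa=_translate(jnt),
            v_call=v,
            j_call=j,
            read_count=n,
            frequency=100.0 * n / total,
            productive=is_productive(jnt),
        )
        for (jnt, v, j), n in counts.items()
    ]
    clonotypes.sort(key=lambda c: (-c.frequency, c.junction_nt))
    return RepertoireProfile(sample_id, compartment, clonotypes, total)


def filter_productive(profile: RepertoireProfile) -> RepertoireProfile:
    """Drop non-productive clonotypes and renormalize frequencies to 100."""
    kept = [c for c in profile.clonotypes if c.productive]
    total = sum(c.read_count for c in kept)
    if total == 0:
        if profile.clonotypes:
            warnings.warn(
                f"{profile.sample_id}: all clonotypes non-productive",
                stacklevel=2,
            )
        return RepertoireProfile(profile.sample_id, profile.compartment, [], 0)
    out = [replace(c, frequency=100.0 * c.read_count / total) for c in kept]
    out.sort(key=lambda c: (-c.frequency, c.junction_nt))
    return RepertoireProfile(profile.sample_id, profile.compartment, out, total)


@dataclass
class ClonotypingResult:
    """Full pipeline output plus read accounting."""

    profile: RepertoireProfile          # after productivity filter
    raw_profile: RepertoireProfile      # before productivity filter
    n_input: int
    n_rejected_merge: int
    n_unassigned: int

    @property
    def n_assigned(self) -> int:
        return self.n_input - self.n_rejected_merge - self.n_unassigned


def run_clonotyping(pairs: Iterable[ReadPair], library: SegmentLibrary,
                    sample_id: str = "sample", compartment: str = "other",
                    min_overlap: int = 20, max_mismatch_frac: float = 0.10,
                    min_identity: float = 0.9,
                    min_match_len: int = 20) -> ClonotypingResult:
    """Merge, assign and cluster a stream of read pairs."""
    n_input = n_rej = n_unassigned = 0
    assignments = []
    for pair in pairs:
        n_input += 1
        cons = merge_read_pair(pair, min_overlap, max_mismatch_frac)
        if cons is None:
            n_rej += 1
            continue
        asg = assign_vj_and_extract_junction(cons, library, min_identity,
                                             min_match_len)
        if asg is None:
            n_unassigned += 1
            continue
        assignments.append(asg)
    raw = cluster_clonotypes(assignments, sample_id, compartment)
    return ClonotypingResult(
        profile=filter_productive(raw),
        raw_profile=raw,
        n_input=n_input,
        n_rejected_merge=n_rej,
        n_unassigned=n_unassigned,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> list[ReadPair]:
    """Read mate-synchronized FASTQ files (Phred+33) into ReadPair records."""
    from Bio import SeqIO

    pairs = []
    with open(r1_path) as f1, open(r2_path) as f2:
        for rec1, rec2 in zip(SeqIO.parse(f1, "fastq"), SeqIO.parse(f2, "fastq"),
                              strict=True):
            pairs.append(ReadPair(
                pair_id=rec1.id,
                seq1=str(rec1.seq).upper(),
                seq2=str(rec2.seq).upper(),
                qual1=tuple(rec1.letter_annotations["phred_quality"]),
                qual2=tuple(rec2.letter_annotations["phred_quality"]),
            ))
    return pairs


def write_airr(profile: RepertoireProfile, path: str | Path) -> None:
    """Write an AIRR Rearrangement TSV (with extension column frequency_pct)."""
    df = profile.to_frame().rename(columns={
        "junction_nt": "junction",
        "read_count": "duplicate_count",
        "frequency": "frequency_pct",
    })
    df.insert(0, "sequence_id", [f"{profile.sample_id}-{i}"
                                 for i in range(len(df))])
    df["productive"] = df["productive"].map({True: "T", False: "F"})
    df = df[["sequence_id", "junction", "junction_aa", "v_call", "j_call",
             "duplicate_count", "productive", "frequency_pct"]]
    df.to_csv(path, sep="\t", index=False)


def read_airr(path: str | Path, sample_id: str | None = None,
              compartment: str = "other") -> RepertoireProfile:
    """Read an AIRR Rearrangement TSV into a profile.

    Frequencies are recomputed from duplicate_count so that write -> read
    round-trips bit-exactly; unknown extra columns are ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype={"junction": str,
                                            "junction_aa": str})
    for col in AIRR_REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column {col}")
    total = int(df["duplicate_count"].sum())
    clonotypes = []
    for _, row in df.iterrows():
        count = int(row["duplicate_count"])
        clonotypes.append(Clonotype(
            junction_nt=row["junction"],
            junction_aa=(row["junction_aa"]
                         if isinstance(row["junction_aa"], str) else ""),
            v_call=row["v_call"],
            j_call=row["j_call"],
            read_count=count,
            frequency=100.0 * count / total,
            productive=str(row["productive"]).upper() in ("T", "TRUE", "1"),
        ))
    clonotypes.sort(key=lambda c: (-c.frequency, c.junction_nt))
    if sample_id is None:
        sample_id = Path(path).stem
    return RepertoireProfile(sample_id, compartment, clonotypes, total)
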