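"""V/J germline segment libraries with annotated junction anchor codons.

A segment library couples 3'-terminal V-gene sequences (with the position of
the conserved cysteine codon that opens the CDR3 junction) and 5'-terminal
J-gene sequences (with the position of the conserved phenylalanine/tryptophan
codon that closes it).  A small toy library is bundled so that every stage of
the pipeline runs without external downloads; real IMGT-derived libraries in
the same FASTA + sidecar-JSON layout can be dropped in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from Bio import SeqIO

__all__ = ["Segment", "SegmentLibrary", "load_library", "toy_library"]


@dataclass(frozen=True)
class Segment:
    """One germline segment with its junction anchor codon.

    ``anchor_start`` is the 0-based offset of the first base of the conserved
    Cys (V) or Phe/Trp (J) codon within ``sequence``.
    """

    name: str
    sequence: str
    anchor_start: int

    def __post_init__(self) -> None:
        if not 0 <= self.anchor_start <= len(self.sequence) - 3:
            raise ValueError(
                f"anchor codon of {self.name} falls outside the sequence"
            )


@dataclass(frozen=True)
class SegmentLibrary:
    """Paired V and J segment collections used for junction extraction."""

    v_segments: tuple[Segment, ...]
    j_segments: tuple[Segment, ...]

    def v_by_name(self, name: str) -> Segment:
        return _by_name(self.v_segments, name)

    def j_by_name(self, name: str) -> Segment:
        return _by_name(self.j_segments, name)


def _by_name(segments: tuple[Segment, ...], name: str) -> Segment:
    for seg in segments:
        if seg.name == name:
            return seg
    raise KeyError(name)


def _read_segments(fasta_path: Path, anchors: dict, key: str) -> tuple[Segment, ...]:
    out = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in anchors:
            raise ValueError(f"no anchor annotation for segment {rec.id}")
        out.append(Segment(rec.id, str(rec.seq).upper(), anchors[rec.id][key]))
    return tuple(out)


def load_library(v_fasta: str | Path, j_fasta: str | Path,
                 anchor_json: str | Path) -> SegmentLibrary:
    """Load a segment library from FASTA files plus an anchor sidecar JSON.

    The JSON maps segment names to ``{"cys_start": int}`` under ``"v"`` and
    ``{"phe_start": int}`` under ``"j"`` (0-based codon start offsets).
    """
    with open(anchor_json) as fh:
        anchors = json.load(fh)
    return SegmentLibrary(
        v_segments=_read_segments(Path(v_fasta), anchors["v"], "cys_start"),
        j_segments=_read_segments(Path(j_fasta), anchors["j"], "phe_start"),
    )


def toy_library() -> SegmentLibrary:
    """The bundled toy TRB segment library (4 V, 3 J segments)."""
    data = resources.files("tcrsift") / "data"
    return load_library(
        Path(str(data / "toy_trbv.fasta")),
        Path(str(data / "toy_trbj.fasta")),
        Path(str(data / "toy_anchors.json")),
    )
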