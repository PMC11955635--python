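"""Synthetic TCRseq study generator with declared ground truth.

Emulates the statistical structure the selection pipeline assumes, so every
stage can be exercised end-to-end without external data:

* heavy-tailed (Zipf-like) clone-size distributions shared between tumor and
  adjacent-lung compartments;
* a planted subset of tumor-enriched clonotypes (boosted further in the
  PD-1-positive fraction);
* paired 150 bp reads over known junctions with substitution errors, where an
  erroneous base call carries a reduced Phred score (sequencers flag most
  miscalls with low quality, which is what makes quality-aware consensus
  building work);
* an archival FFPE panel with query-TCR homologs planted in a declared subset
  of samples and low-coverage single-substitution artifacts elsewhere;
* a single-cell dataset where a designated cluster set carries clonotypes
  with shifted log tumor-to-nontumor ratios.

All generators are pure functions of (config, seed): per-operation random
streams are derived from the root seed, so outputs are identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .matching import QueryTCR
from .repertoire import Clonotype, ReadPair, RepertoireProfile, revcomp
from .scstats import CellRecord
from .segments import SegmentLibrary, toy_library

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_repertoire",
    "plant_tumor_specific",
    "simulate_read_pairs",
    "simulate_ffpe_panel",
    "simulate_sc_dataset",
    "default_queries",
]

# per-operation stream codes (second word of the derived seed)
_STREAM_REPERTOIRE = 1
_STREAM_PLANT = 2
_STREAM_READS = 3
_STREAM_FFPE = 4
_STREAM_SC = 5

_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SAFE_CODONS = [c for c in _CODONS if c not in ("TAA", "TAG", "TGA")]
_AA_TO_CODONS: dict[str, list[str]] = {}
for _c in _SAFE_CODONS:
    from Bio.Seq import Seq as _Seq

    _AA_TO_CODONS.setdefault(str(_Seq(_c).translate()), []).append(_c)

READ_LENGTH = 150
BASE_QUALITY = 37        # Phred of a correct base call
ERROR_QUALITY_RANGE = (10, 26)  # half-open range for erroneous calls


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generators.

    Defaults mirror the planted-truth designs the pipeline is evaluated on:
    a 2,000-clonotype background fully shared between compartments, 20
    clonotypes planted at 20-fold tumor enrichment, 150 bp paired reads with
    0.5% substitution error, a 29-sample FFPE panel with homologs in six
    samples, and a five-cluster single-cell dataset where clusters {0, 2, 3}
    carry a +1.0 shift in log tumor-to-nontumor ratio.
    """

    seed: int
    n_background_clonotypes: int = 2000
    clone_size_exponent: float = 1.0
    compartment_overlap_fraction: float = 1.0
    n_planted: int = 20
    enrichment_factor: float = 20.0
    pd1_boost_factor: float = 2.0
    read_error_rate: float = 0.005
    reads_per_sample: int = 50_000
    ffpe_artifact_rate: float = 0.05
    ffpe_n_samples: int = 29
    ffpe_n_hit_samples: int = 6
    ffpe_n_clonotypes: int = 300
    ffpe_reads_per_sample: int = 5000
    sc_effect_size: float = 1.0
    sc_ratio_sigma: float = 0.35
    sc_clonotypes_per_group: int = 30
    sc_offhome_rate: float = 0.05
    high_ratio_clusters: tuple[int, ...] = (0, 2, 3)
    cluster_sizes: Mapping[int, int] = field(
        default_factory=lambda: {0: 200, 1: 150, 2: 120, 3: 100, 4: 90})

    def __post_init__(self) -> None:
        for name in ("compartment_overlap_fraction", "read_error_rate",
                     "ffpe_artifact_rate", "sc_offhome_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.enrichment_factor <= 1.0:
            raise ValueError("enrichment_factor must be > 1")
        if self.n_background_clonotypes < 1:
            raise ValueError("n_background_clonotypes must be >= 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth recorded by the generators."""

    seed: int
    planted_keys: tuple = ()
    enrichment_factor: float | None = None
    homolog_placements: tuple = ()   # (sample_id, query_name, edit_distance)
    hit_sample_ids: tuple = ()
    high_ratio_clusters: tuple = ()
    clonotype_groups: dict = field(default_factory=dict)
    junctions_by_pair: dict = field(default_factory=dict)


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed % (2**31), stream])


def _random_junction(rng: np.random.Generator, v, j,
                     n_insert_codons: int) -> str:
    insert = "".join(rng.choice(_SAFE_CODONS) for _ in range(n_insert_codons))
    return v.sequence[v.anchor_start:] + insert + j.sequence[: j.anchor_start + 3]


def _translate(nt: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(nt).translate())


def _make_clonotype_pool(cfg: SimulationConfig, rng: np.random.Generator,
                         library: SegmentLibrary, n: int):
    """Distinct productive junctions with V/J calls."""
    pool = []
    seen = set()
    vs, js = library.v_segments, library.j_segments
    while len(pool) < n:
        v = vs[rng.integers(len(vs))]
        j = js[rng.integers(len(js))]
        jnt = _random_junction(rng, v, j, int(rng.integers(1, 5)))
        key = (jnt, v.name, j.name)
        if key in seen:
            continue
        seen.add(key)
        pool.append(key)
    return pool


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    w = np.arange(1, n + 1, dtype=float) ** (-exponent)
    return w / w.sum()


def _profile_from_counts(keys, counts, sample_id: str,
                         compartment: str) -> RepertoireProfile:
    from .repertoire import is_productive

    total = int(counts.sum())
    clonotypes = []
    for key, n in zip(keys, counts):
        if n == 0:
            continue
        jnt, v, j = key
        clonotypes.append(Clonotype(
            junction_nt=jnt,
            junction_aa=_translate(jnt),
            v_call=v,
            j_call=j,
            read_count=int(n),
            frequency=100.0 * int(n) / total,
            productive=is_productive(jnt),
        ))
    clonotypes.sort(key=lambda c: (-c.frequency, c.junction_nt))
    return RepertoireProfile(sample_id, compartment, clonotypes, total)


def simulate_repertoire(cfg: SimulationConfig,
                        sample_id: str = "sim",
                        compartment: str = "other",
                        library: SegmentLibrary | None = None) -> RepertoireProfile:
    """One repertoire with Zipf-distributed clone sizes."""
    library = library or toy_library()
    rng = _rng(cfg, _STREAM_REPERTOIRE)
    keys = _make_clonotype_pool(cfg, rng, library,
                                cfg.n_background_clonotypes)
    weights = _zipf_weights(len(keys), cfg.clone_size_exponent)
    counts = rng.multinomial(cfg.reads_per_sample, weights)
    return _profile_from_counts(keys, counts, sample_id, compartment)


def plant_tumor_specific(
    cfg: SimulationConfig,
    library: SegmentLibrary | None = None,
) -> tuple[dict[str, RepertoireProfile], SyntheticTruth]:
    """Tumor/lung/PD-1 profiles over a shared background with planted clones.

    Planted clonotypes are drawn from moderately abundant background ranks so
    that after an ``enrichment_factor``-fold boost they populate the tumor's
    top clonotypes; the PD-1-positive fraction boosts them further by
    ``pd1_boost_factor``.  Returns ``({"tumor": ..., "lung": ..., "pd1_til":
    ...}, truth)``.
    """
    library = library or toy_library()
    rng = _rng(cfg, _STREAM_PLANT)
    n = cfg.n_background_clonotypes
    keys = _make_clonotype_pool(cfg, rng, library, n)
    base = _zipf_weights(n, cfg.clone_size_exponent)

    if cfg.n_planted > n // 10:
        raise ValueError("n_planted must be <= n_background_clonotypes / 10")
    lo, hi = min(30, n // 4), min(500, n)
    planted_idx = rng.choice(np.arange(lo, hi), size=cfg.n_planted,
                             replace=False)
    planted_mask = np.zeros(n, dtype=bool)
    planted_mask[planted_idx] = True

    # compartment presence (1.0 => fully shared background)
    present_lung = np.ones(n, dtype=bool)
    present_tumor = np.ones(n, dtype=bool)
    if cfg.compartment_overlap_fraction < 1.0:
        shared = rng.random(n) < cfg.compartment_overlap_fraction
        private = ~shared & ~planted_mask
        side = rng.random(n) < 0.5
        present_lung = shared | (private & side) | planted_mask
        present_tumor = shared | (private & ~side) | planted_mask

    def draw(presence, boost):
        w = base * presence * boost
        w = w / w.sum()
        return rng.multinomial(cfg.reads_per_sample, w)

    boost_tumor = np.where(planted_mask, cfg.enrichment_factor, 1.0)
    boost_pd1 = np.where(planted_mask,
                         cfg.enrichment_factor * cfg.pd1_boost_factor, 1.0)
    profiles = {
        "tumor": _profile_from_counts(
            keys, draw(present_tumor, boost_tumor), "sim-tumor", "tumor"),
        "lung": _profile_from_counts(
            keys, draw(present_lung, np.ones(n)), "sim-lung", "lung"),
        "pd1_til": _profile_from_counts(
            keys, draw(present_tumor, boost_pd1), "sim-pd1", "pd1_til"),
    }
    truth = SyntheticTruth(
        seed=cfg.seed,
        planted_keys=tuple(keys[i] for i in sorted(planted_idx)),
        enrichment_factor=cfg.enrichment_factor,
    )
    return profiles, truth


def _amplicon(clonotype: Clonotype, library: SegmentLibrary) -> str:
    v = library.v_by_name(clonotype.v_call)
    j = library.j_by_name(clonotype.j_call)
    return (v.sequence[: v.anchor_start]
            + clonotype.junction_nt
            + j.sequence[j.anchor_start + 3:])


def _read_with_errors(rng: np.random.Generator, seq: str,
                      error_rate: float) -> tuple[str, tuple[int, ...]]:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    qual = np.full(len(arr), BASE_QUALITY, dtype=np.int64)
    if error_rate > 0:
        err = rng.random(len(arr)) < error_rate
        for i in np.flatnonzero(err):
            alts = [b for b in b"ACGT" if bytes([b]) != arr[i]]
            arr[i] = bytes([alts[rng.integers(3)]])
            qual[i] = rng.integers(*ERROR_QUALITY_RANGE)
    return arr.tobytes().decode(), tuple(int(q) for q in qual)


def simulate_read_pairs(
    profile: RepertoireProfile,
    cfg: SimulationConfig,
    library: SegmentLibrary | None = None,
) -> tuple[list[ReadPair], SyntheticTruth]:
    """Paired 150 bp reads over each clonotype's amplicon.

    Each clonotype emits exactly ``read_count`` pairs; mate 2 is emitted
    reverse-complemented.  Substitution errors occur per base at
    ``cfg.read_error_rate`` and carry reduced Phred scores.  Truth records the
    source junction of every pair.
    """
    library = library or toy_library()
    rng = _rng(cfg, _STREAM_READS)
    pairs = []
    truth_junctions = {}
    i = 0
    for clon in profile.clonotypes:
        amp = _amplicon(clon, library)
        if len(amp) < READ_LENGTH:
            raise ValueError("amplicon shorter than the read length")
        for _ in range(clon.read_count):
            pair_id = f"{profile.sample_id}-read{i:06d}"
            i += 1
            seq1, qual1 = _read_with_errors(rng, amp[:READ_LENGTH],
                                            cfg.read_error_rate)
            seq2, qual2 = _read_with_errors(rng, revcomp(amp[-READ_LENGTH:]),
                                            cfg.read_error_rate)
            pairs.append(ReadPair(pair_id, seq1, seq2, qual1, qual2))
            truth_junctions[pair_id] = clon.junction_nt
    return pairs, SyntheticTruth(seed=cfg.seed,
                                 junctions_by_pair=truth_junctions)


def synthetic_kras_like_cds() -> tuple[str, str]:
    """A synthetic KRAS-like coding sequence for worked examples.

    This is NOT the real KRAS transcript: it is a deterministic synthetic
    188-codon CDS whose residues 55-64 reproduce the RAS-family context
    ILDTAGQEEY with codon 61 = CAA, so that the recurrent hotspot changes
    c.183A>T / c.183A>C (Q61H) and the codon replacement c.181-183CAT>CGC
    (Q61H -> Q61R) behave exactly as on the real gene.  Returns
    ``(cds, transcript_id)``.
    """
    rng = np.random.default_rng(61)
    alphabet = list("ACDEFGHIKLNPQRSTVWY")
    protein = ("M"
               + "".join(rng.choice(alphabet) for _ in range(53))
               + "ILDTAGQEEY"
               + "".join(rng.choice(alphabet) for _ in range(124)))
    codons = [str(rng.choice(_AA_TO_CODONS[a])) for a in protein]
    codons[60] = "CAA"  # glutamine 61; position 183 is its third base
    cds = "".join(codons) + "TAA"
    return cds, "KRASLIKE-SYNTH-01"


def default_queries() -> list[QueryTCR]:
    """Synthetic query TCRs for panel matching demonstrations and tests."""
    return [
        QueryTCR("TCR-Q1", "TRB", "CASSLDRGNTEAFF", "TRBV-T1"),
        QueryTCR("TCR-Q2", "TRB", "CASSPGQGAYEQYF", "TRBV-T2"),
        QueryTCR("TCR-Q3", "TRB", "CAWSVGDEQFF", "TRBV-T3"),
    ]


def _backtranslate(rng: np.random.Generator, aa: str) -> str:
    return "".join(rng.choice(_AA_TO_CODONS[a]) for a in aa)


def _mutate_aa(rng: np.random.Generator, aa: str, n_changes: int) -> str:
    aa = list(aa)
    # keep the anchors; mutate interior residues only
    positions = rng.choice(np.arange(1, len(aa) - 1), size=n_changes,
                           replace=False)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    for pos in positions:
        choices = [a for a in alphabet if a != aa[pos]]
        aa[pos] = choices[rng.integers(len(choices))]
    return "".join(aa)


def simulate_ffpe_panel(
    cfg: SimulationConfig,
    queries: Sequence[QueryTCR] | None = None,
    library: SegmentLibrary | None = None,
) -> tuple[list[RepertoireProfile], SyntheticTruth]:
    """An archival panel with query homologs planted in a declared subset.

    ``ffpe_n_hit_samples`` of the ``ffpe_n_samples`` samples receive genuine
    query homologs: a perfect CDR3+V match (sometimes at low coverage — a
    perfect match needs no abundance support) and, in half of them, a near
    homolog (1-2 amino-acid changes) at supporting coverage.  The remaining
    samples carry only background clones plus FFPE-style artifacts:
    single-substitution derivatives of abundant clones at coverage <= 2, and
    in some samples a low-coverage query near-homolog mimicking an artifact,
    none of which survive the frequency/coverage filter.
    """
    library = library or toy_library()
    queries = list(queries) if queries is not None else default_queries()
    if not queries:
        raise ValueError("queries must be non-empty")
    rng = _rng(cfg, _STREAM_FFPE)

    hit_ids = rng.choice(cfg.ffpe_n_samples, size=cfg.ffpe_n_hit_samples,
                         replace=False)
    hit_set = set(int(s) for s in hit_ids)
    profiles = []
    placements = []
    for s in range(cfg.ffpe_n_samples):
        sample_id = f"ffpe-{s:02d}"
        keys = _make_clonotype_pool(cfg, rng, library, cfg.ffpe_n_clonotypes)
        weights = _zipf_weights(len(keys), cfg.clone_size_exponent)
        counts = list(rng.multinomial(
            cfg.ffpe_reads_per_sample, weights).astype(int))
        keys = list(keys)
        index = {k: i for i, k in enumerate(keys)}

        def add(jnt, v, j, n_reads):
            key = (jnt, v, j)
            if key in index:  # merge improbable collisions
                counts[index[key]] += n_reads
                return
            index[key] = len(keys)
            keys.append(key)
            counts.append(n_reads)

        if s in hit_set:
            query = queries[int(rng.integers(len(queries)))]
            # perfect match; coverage sometimes below the artifact threshold
            cov = int(rng.choice([2, 10, 50, 150]))
            add(_backtranslate(rng, query.cdr3_aa), query.v_call,
                library.j_segments[0].name, cov)
            placements.append((sample_id, query.name, 0))
            if rng.random() < 0.5:
                dist = int(rng.integers(1, 3))
                near_aa = _mutate_aa(rng, query.cdr3_aa, dist)
                add(_backtranslate(rng, near_aa), query.v_call,
                    library.j_segments[0].name, int(rng.integers(8, 40)))
                placements.append((sample_id, query.name, dist))
        else:
            if rng.random() < 0.4:
                # artifact-like near homolog of a query, below thresholds
                query = queries[int(rng.integers(len(queries)))]
                near_aa = _mutate_aa(rng, query.cdr3_aa, 1)
                add(_backtranslate(rng, near_aa), query.v_call,
                    library.j_segments[0].name, int(rng.integers(1, 3)))

        # generic FFPE artifacts: 1-nt derivatives of abundant clones
        n_artifacts = rng.binomial(cfg.ffpe_n_clonotypes,
                                   cfg.ffpe_artifact_rate)
        for _ in range(n_artifacts):
            src = keys[int(rng.integers(min(30, len(keys))))]
            jnt = list(src[0])
            pos = int(rng.integers(len(jnt)))
            alts = [b for b in "ACGT" if b != jnt[pos]]
            jnt[pos] = alts[int(rng.integers(3))]
            add("".join(jnt), src[1], src[2], int(rng.integers(1, 3)))

        profiles.append(_profile_from_counts(
            keys, np.asarray(counts), sample_id, "ffpe"))

    truth = SyntheticTruth(
        seed=cfg.seed,
        homolog_placements=tuple(placements),
        hit_sample_ids=tuple(sorted(f"ffpe-{s:02d}" for s in hit_set)),
    )
    return profiles, truth


def simulate_sc_dataset(
    cfg: SimulationConfig,
) -> tuple[list[CellRecord], dict, SyntheticTruth]:
    """Single-cell clonotype/cluster assignments with a planted ratio shift.

    Clonotypes homed in ``cfg.high_ratio_clusters`` draw their natural-log
    tumor-to-nontumor ratio from N(effect, sigma); the rest from
    N(0, sigma), with ``sigma = cfg.sc_ratio_sigma`` so the declared effect
    is a clear multiple of the within-group spread.  Cells
    land in their clonotype's home cluster except for a small off-home rate,
    which creates the dual-group memberships the scan must handle.
    """
    clusters = sorted(cfg.cluster_sizes)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    rng = _rng(cfg, _STREAM_SC)
    high = tuple(c for c in clusters if c in cfg.high_ratio_clusters)
    low = tuple(c for c in clusters if c not in cfg.high_ratio_clusters)
    if not high or not low:
        raise ValueError("high_ratio_clusters must split the cluster set")

    cells: list[CellRecord] = []
    ratios: dict = {}
    groups: dict = {}
    barcode = 0
    for group, members, shift in (("high", high, cfg.sc_effect_size),
                                  ("low", low, 0.0)):
        sizes = np.array([cfg.cluster_sizes[c] for c in members], dtype=float)
        sizes /= sizes.sum()
        for i in range(cfg.sc_clonotypes_per_group):
            key = (f"scclone-{group}-{i:03d}", "TRBV-T1", "TRBJ-T1")
            home = members[int(rng.choice(len(members), p=sizes))]
            ratios[key] = float(np.exp(rng.normal(shift, cfg.sc_ratio_sigma)))
            groups[key] = group
            for _ in range(1 + int(rng.poisson(2.0))):
                if rng.random() < cfg.sc_offhome_rate and len(clusters) > 1:
                    others = [c for c in clusters if c != home]
                    cluster = others[int(rng.integers(len(others)))]
                else:
                    cluster = home
                cells.append(CellRecord(f"BC{barcode:06d}-1", key, cluster))
                barcode += 1
    truth = SyntheticTruth(
        seed=cfg.seed,
        high_ratio_clusters=high,
        clonotype_groups=groups,
    )
    return cells, ratios, truth
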