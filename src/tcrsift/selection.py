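"""Cross-compartment frequency matrix and tumor-specificity calls.

The central statistic is the tumor-to-nontumor frequency ratio of a clonotype:
its frequency among tumor-infiltrating lymphocytes divided by its frequency in
adjacent normal tissue.  Clonotypes among the most frequent in the tumor whose
ratio exceeds a threshold (default >5, strict) are called candidate
tumor-specific; a stricter two-sided rule (frequency >0.2% and ratio >10)
grades candidates for single-cell follow-up, and abundant non-enriched
clonotypes (frequency >0.1%, ratio <1) are flagged as presumed bystanders.

When a clonotype is absent from the nontumor compartment its ratio would be
infinite; a depth-aware pseudocount floors the nontumor frequency at the
frequency of a single read (100/total nontumor reads), keeping ratios finite
and comparable across sequencing depths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .repertoire import RepertoireProfile

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "build_frequency_matrix",
    "select_candidates",
    "classify_for_sc",
]

Key = tuple[str, str, str]  # (junction_nt, v_call, j_call)


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds of the tiered tumor-specificity calls (all strict)."""

    top_n: int | None = 100
    ratio_threshold: float = 5.0
    sc_ratio_threshold: float = 10.0
    sc_freq_threshold_pct: float = 0.2
    bystander_ratio_max: float = 1.0
    bystander_freq_min_pct: float = 0.1
    pd1_support_min_pct: float = 0.1

    def __post_init__(self) -> None:
        for name in ("ratio_threshold", "sc_ratio_threshold",
                     "sc_freq_threshold_pct", "bystander_ratio_max",
                     "bystander_freq_min_pct", "pd1_support_min_pct"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sc_ratio_threshold < self.ratio_threshold:
            raise ValueError("sc_ratio_threshold must be >= ratio_threshold")


@dataclass(frozen=True)
class SelectionResult:
    key: Key
    tier: str  # candidate_tumor_specific | sc_grade_tumor_specific | bystander | unclassified
    tumor_freq: float
    nontumor_freq: float
    ratio: float
    pd1_supported: bool
    tumor_rank: int


def build_frequency_matrix(
    profiles: Mapping[str, RepertoireProfile],
    nontumor_compartment: str = "lung",
) -> pd.DataFrame:
    """Build the clonotype x compartment frequency matrix with ratios.

    ``profiles`` maps compartment labels to profiles and must include
    ``"tumor"`` plus at least one other compartment.  The result is indexed by
    the clonotype key with columns ``freq_<comp>`` and ``count_<comp>`` per
    compartment (0 where absent), ``ratio`` (tumor over ``nontumor_compartment``
    with the single-read pseudocount floor for empty nontumor cells) and
    ``tumor_rank`` (1 = most frequent in tumor; frequency ties broken by
    junction sequence).
    """
    if "tumor" not in profiles:
        raise ValueError("tumor compartment is required")
    if len(profiles) < 2:
        raise ValueError("at least one nontumor compartment is required")
    if nontumor_compartment not in profiles:
        raise ValueError(f"compartment {nontumor_compartment!r} not provided")

    frames = {}
    for comp, prof in profiles.items():
        df = prof.to_frame()
        frames[comp] = pd.DataFrame({
            f"freq_{comp}": df["frequency"].to_numpy(),
            f"count_{comp}": df["read_count"].to_numpy(),
        }, index=pd.MultiIndex.from_frame(
            df[["junction_nt", "v_call", "j_call"]]))

    mat = pd.concat(frames.values(), axis=1, join="outer").fillna(0.0)
    for comp in profiles:
        mat[f"count_{comp}"] = mat[f"count_{comp}"].astype(int)

    nt_total = profiles[nontumor_compartment].total_reads
    floor = 100.0 / nt_total if nt_total > 0 else np.nan
    nt_freq = mat[f"freq_{nontumor_compartment}"].to_numpy()
    denom = np.where(mat[f"count_{nontumor_compartment}"].to_numpy() > 0,
                     nt_freq, floor)
    mat["ratio"] = mat["freq_tumor"].to_numpy() / denom

    in_tumor = mat["count_tumor"] > 0
    order = mat[in_tumor].reset_index().sort_values(
        ["freq_tumor", "junction_nt"], ascending=[False, True])
    ranks = pd.Series(np.arange(1, len(order) + 1),
                      index=pd.MultiIndex.from_frame(
                          order[["junction_nt", "v_call", "j_call"]]))
    mat["tumor_rank"] = ranks.reindex(mat.index)
    return mat


def select_candidates(
    matrix: pd.DataFrame,
    cfg: SelectionConfig = SelectionConfig(),
    pd1_profile: RepertoireProfile | None = None,
) -> list[SelectionResult]:
    """Tiered tumor-specificity calls over the top-ranked tumor clonotypes.

    Only rows with ``tumor_rank <= cfg.top_n`` are evaluated (``top_n=None``
    evaluates every tumor row).  A row is ``candidate_tumor_specific`` iff its
    ratio strictly exceeds ``cfg.ratio_threshold``; the candidate additionally
    satisfying the single-cell-grade thresholds is ``sc_grade_tumor_specific``;
    an abundant non-enriched row is ``bystander``; anything else inside the
    evaluated window is ``unclassified``.  PD-1 support is annotative: the
    flag records whether the clonotype reaches ``pd1_support_min_pct`` in the
    PD-1-positive fraction, it never gates a tier.
    """
    if matrix.empty:
        raise ValueError("empty frequency matrix")
    pd1_freq: dict[Key, float] = {}
    if pd1_profile is not None:
        pd1_freq = {(c.junction_nt, c.v_call, c.j_call): c.frequency
                    for c in pd1_profile.clonotypes}

    nontumor_col = [c for c in matrix.columns
                    if c.startswith("freq_") and c != "freq_tumor"][0]
    results = []
    rows = matrix[matrix["tumor_rank"].notna()]
    if cfg.top_n is not None:
        rows = rows[rows["tumor_rank"] <= cfg.top_n]
    for key, row in rows.iterrows():
        ratio = row["ratio"]
        freq = row["freq_tumor"]
        if ratio > cfg.ratio_threshold:
            if (freq > cfg.sc_freq_threshold_pct
                    and ratio > cfg.sc_ratio_threshold):
                tier = "sc_grade_tumor_specific"
            else:
                tier = "candidate_tumor_specific"
        elif (ratio < cfg.bystander_ratio_max
                and freq > cfg.bystander_freq_min_pct):
            tier = "bystander"
        else:
            tier = "unclassified"
        results.append(SelectionResult(
            key=key,
            tier=tier,
            tumor_freq=freq,
            nontumor_freq=row[nontumor_col],
            ratio=ratio,
            pd1_supported=pd1_freq.get(key, 0.0) >= cfg.pd1_support_min_pct,
            tumor_rank=int(row["tumor_rank"]),
        ))
    results.sort(key=lambda r: (-r.tumor_freq, r.key[0]))
    return results


def classify_for_sc(matrix: pd.DataFrame,
                    cfg: SelectionConfig = SelectionConfig()) -> pd.Series:
    """Single-cell-grade tier labels over CD8-compartment frequencies.

    ``sc_grade_tumor_specific`` iff frequency > 0.2% and ratio > 10;
    ``bystander`` iff frequency > 0.1% and ratio < 1; else ``unclassified``.
    Returns a Series of labels aligned to the matrix index.
    """
    freq = matrix["freq_tumor"]
    ratio = matrix["ratio"]
    labels = pd.Series("unclassified", index=matrix.index, dtype=object)
    labels[(freq > cfg.sc_freq_threshold_pct)
           & (ratio > cfg.sc_ratio_threshold)] = "sc_grade_tumor_specific"
    labels[(freq > cfg.bystander_freq_min_pct)
           & (ratio < cfg.bystander_ratio_max)] = "bystander"
    return labels


def selection_to_frame(results: list[SelectionResult]) -> pd.DataFrame:
    """Flatten SelectionResults to a TSV-ready DataFrame."""
    return pd.DataFrame([{
        "junction_nt": r.key[0],
        "v_call": r.key[1],
        "j_call": r.key[2],
        "tumor_freq": r.tumor_freq,
        "nontumor_freq": r.nontumor_freq,
        "ratio": r.ratio,
        "tier": r.tier,
        "pd1_supported": r.pd1_supported,
        "tumor_rank": r.tumor_rank,
    } for r in results])
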