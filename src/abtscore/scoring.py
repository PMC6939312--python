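"""Per-IDR and per-protein charged-tract scores.

For each retained IDR the score is

    (sum of tract areas > 1) x (0.6 + kappa)^2

computed on the IDR subsequence alone (for merged IDRs the low-disorder gap
residues are part of the subsequence). The per-protein ABTscore is the sum
over IDRs, and ABTdensity is the ABTscore normalized by the number of
disordered residues analyzed — the quantity used to rank a proteome.

The multiplier (0.6 + kappa)^2 ranges over [0.36, 2.56]; since each IDR's
filtered area sum is at most its length, ABTdensity is bounded by 2.56.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .charge import (
    DEFAULT_NCPR_WINDOW,
    KappaResult,
    kappa,
    ncpr_profile,
    sum_filtered_areas,
)
from .segmentation import Segment, SegmentationParams, segment_idrs

__all__ = [
    "IDRScore",
    "ProteinABTResult",
    "ScoringParams",
    "score_idr",
    "score_protein",
]

logger = logging.getLogger("abtscore")

#: Multiplier applied when kappa is undefined but charged tracts exist
#: (pathological single-sign compositions): kappa is treated as 0.
_UNDEFINED_KAPPA_MULTIPLIER = 0.36


@dataclass(frozen=True)
class ScoringParams:
    """Charge-feature parameters: NCPR window length and the tract-area
    filter threshold (only tracts with area strictly greater than
    `min_area` contribute). `density_denominator` selects how ABTdensity
    normalizes the ABTscore: "total" divides the summed score by the total
    retained disordered residue count; "per-region" sums each IDR's
    score/length ratio."""

    ncpr_window: int = DEFAULT_NCPR_WINDOW
    min_area: float = 1.0
    density_denominator: str = "total"

    def __post_init__(self) -> None:
        if self.density_denominator not in ("total", "per-region"):
            raise ValueError("density_denominator must be 'total' or 'per-region'")


@dataclass(frozen=True)
class IDRScore:
    segment: Segment
    length: int
    kappa: KappaResult
    filtered_area_sum: float
    multiplier: float
    score: float


@dataclass(frozen=True)
class ProteinABTResult:
    accession: str
    idr_scores: list[IDRScore] = field(repr=False)
    abtscore: float
    n_disordered_residues: int
    abtdensity: float | None  # None marks a protein with no retained IDR
    group: int | None = None

    @property
    def has_idr(self) -> bool:
        return self.n_disordered_residues > 0

    @property
    def n_idrs(self) -> int:
        return len(self.idr_scores)

    def with_group(self, group: int | None) -> "ProteinABTResult":
        return ProteinABTResult(
            accession=self.accession,
            idr_scores=self.idr_scores,
            abtscore=self.abtscore,
            n_disordered_residues=self.n_disordered_residues,
            abtdensity=self.abtdensity,
            group=group,
        )


def score_idr(
    idr_seq: str,
    segment: Segment | None = None,
    params: ScoringParams | None = None,
) -> IDRScore:
    """Score one IDR subsequence: filtered tract-area sum times
    (0.6 + kappa)^2.

    When kappa is undefined and tracts nevertheless pass the area filter
    (e.g. an IDR that is 100% aspartate), kappa is treated as 0
    (multiplier 0.36) with a warning rather than dropping the region.
    """
    if not idr_seq:
        raise ValueError("IDR sequence must be non-empty")
    p = params or ScoringParams()
    seg = segment if segment is not None else Segment(0, len(idr_seq))
    profile = ncpr_profile(idr_seq, p.ncpr_window)
    area_sum = sum_filtered_areas(profile, p.min_area)
    kap = kappa(idr_seq)
    if kap.defined:
        multiplier = (0.6 + kap.value) ** 2
    else:
        multiplier = _UNDEFINED_KAPPA_MULTIPLIER
        if area_sum > 0:
            logger.warning(
                "kappa undefined for an IDR with charged tracts "
                "(single-sign composition?); treating kappa as 0"
            )
    return IDRScore(
        segment=seg,
        length=len(idr_seq),
        kappa=kap,
        filtered_area_sum=area_sum,
        multiplier=multiplier,
        score=area_sum * multiplier,
    )


def score_protein(
    accession: str,
    sequence: str,
    disorder_scores,
    seg_params: SegmentationParams | None = None,
    params: ScoringParams | None = None,
) -> ProteinABTResult:
    """Segment the disorder track into IDRs and score each one.

    ABTscore is the sum of per-IDR scores, accumulated in sequence order.
    A protein with no retained IDR gets abtdensity None and is excluded
    from percentile ranking downstream.
    """
    if len(disorder_scores) != len(sequence):
        raise ValueError(
            f"{accession}: disorder track length {len(disorder_scores)} "
            f"!= sequence length {len(sequence)}"
        )
    p = params or ScoringParams()
    segments = segment_idrs(disorder_scores, seg_params)
    idr_scores = [
        score_idr(sequence[seg.start : seg.end], segment=seg, params=p) for seg in segments
    ]
    abtscore = 0.0
    n_dis = 0
    for s in idr_scores:
        abtscore += s.score
        n_dis += s.length
    if n_dis == 0:
        density = None
    elif p.density_denominator == "total":
        density = abtscore / n_dis
    else:
        density = 0.0
        for s in idr_scores:
            density += s.score / s.length
    return ProteinABTResult(
        accession=accession,
        idr_scores=idr_scores,
        abtscore=abtscore,
        n_disordered_residues=n_dis,
        abtdensity=density,
    )
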