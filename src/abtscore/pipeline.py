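"""Proteome-scale batch scoring, percentile stratification and exports.

Proteins with at least one retained IDR are ranked by ABTdensity
(descending, stable input order on ties) and partitioned into four groups:
Group 1 is the top 5% of ranked proteins, Group 2 extends through 15%,
Group 3 through 30% and Group 4 holds the remainder. Group sizes use
floor() arithmetic on the rank cut-offs. Proteins without a retained IDR
are kept in the output but receive no group.

Group accession lists are exported one-per-line for pasting into external
enrichment or interaction-network web tools; the enrichment analyses
themselves are outside this package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .io import (
    DISORDER_SUFFIX,
    disorder_track_path,
    read_disorder_track,
    read_fasta,
)
from .scoring import ProteinABTResult, ScoringParams, score_protein
from .segmentation import SegmentationParams

__all__ = [
    "GroupCuts",
    "GroupSummary",
    "SubsetSummary",
    "SkipRecord",
    "score_proteome",
    "stratify",
    "summarize_groups",
    "subset_summary",
    "export_group_accessions",
]

logger = logging.getLogger("abtscore")


@dataclass(frozen=True)
class GroupCuts:
    """Percentile-rank cut fractions separating Groups 1/2, 2/3 and 3/4."""

    cuts: tuple[float, float, float] = (0.05, 0.15, 0.30)

    def __post_init__(self) -> None:
        if not all(0 < c < 1 for c in self.cuts):
            raise ValueError("cut fractions must lie in (0, 1)")
        if not all(a < b for a, b in zip(self.cuts, self.cuts[1:])):
            raise ValueError("cut fractions must be strictly increasing")


@dataclass(frozen=True)
class GroupSummary:
    group: int
    n: int
    abtscore_range: tuple[float, float]
    abtdensity_range: tuple[float, float]
    abtdensity_mean: float


@dataclass(frozen=True)
class SubsetSummary:
    n: int
    n_missing: int
    median_abtscore: float
    median_abtdensity: float


@dataclass(frozen=True)
class SkipRecord:
    accession: str
    reason: str


def score_proteome(
    fasta: str | Path,
    disorder_dir: str | Path,
    seg_params: SegmentationParams | None = None,
    params: ScoringParams | None = None,
    suffix: str = DISORDER_SUFFIX,
) -> tuple[list[ProteinABTResult], list[SkipRecord]]:
    """Score every FASTA record that has a matching disorder-track file.

    A protein with no track file (or an unparseable one) is skipped with a
    logged warning and a SkipRecord; zero scorable proteins is an error.
    """
    records = read_fasta(fasta)
    results: list[ProteinABTResult] = []
    skipped: list[SkipRecord] = []
    for rec in records:
        track_path = disorder_track_path(disorder_dir, rec.accession, suffix)
        if not track_path.exists():
            logger.warning("%s: no disorder track at %s; skipped", rec.accession, track_path)
            skipped.append(SkipRecord(rec.accession, f"missing track file {track_path.name}"))
            continue
        try:
            track = read_disorder_track(track_path, expected_length=len(rec), accession=rec.accession)
        except ValueError as exc:
            logger.warning("%s: unreadable disorder track (%s); skipped", rec.accession, exc)
            skipped.append(SkipRecord(rec.accession, str(exc)))
            continue
        results.append(
            score_protein(rec.accession, rec.sequence, track.scores, seg_params, params)
        )
    if not results:
        raise ValueError("no scorable proteins (every record lacked a usable disorder track)")
    return results, skipped


def stratify(
    results: Sequence[ProteinABTResult], cuts: GroupCuts | None = None
) -> list[ProteinABTResult]:
    """Assign Groups 1-4 by descending ABTdensity rank.

    Ranks use a stable sort, so boundary ties resolve in input order.
    Group g spans ranks (floor(c_{g-1} N), floor(c_g N)] with c_0 = 0 and
    c_4 = 1 over the N proteins with a defined density. Proteins without a
    retained IDR keep group None.
    """
    cuts = cuts or GroupCuts()
    ranked_idx = [i for i, r in enumerate(results) if r.abtdensity is not None]
    if not ranked_idx:
        raise ValueError("no protein has a defined ABTdensity; nothing to stratify")
    order = sorted(ranked_idx, key=lambda i: -results[i].abtdensity)
    n = len(order)
    bounds = [math.floor(c * n) for c in cuts.cuts] + [n]
    group_of: dict[int, int] = {}
    lo = 0
    for g, hi in enumerate(bounds, start=1):
        for i in order[lo:hi]:
            group_of[i] = g
        lo = hi
    return [r.with_group(group_of.get(i)) for i, r in enumerate(results)]


def summarize_groups(results: Sequence[ProteinABTResult]) -> list[GroupSummary]:
    """Per-group score/density ranges, mean density and count — the machine
    twin of a group-summary table. Empty groups (tiny proteomes) are
    omitted."""
    summaries: list[GroupSummary] = []
    for g in (1, 2, 3, 4):
        members = [r for r in results if r.group == g]
        if not members:
            continue
        scores = [r.abtscore for r in members]
        densities = [r.abtdensity for r in members]
        summaries.append(
            GroupSummary(
                group=g,
                n=len(members),
                abtscore_range=(min(scores), max(scores)),
                abtdensity_range=(min(densities), max(densities)),
                abtdensity_mean=sum(densities) / len(densities),
            )
        )
    return summaries


def _median(values: list[float]) -> float:
    vals = sorted(values)
    n = len(vals)
    mid = n // 2
    return vals[mid] if n % 2 else (vals[mid - 1] + vals[mid]) / 2


def subset_summary(
    results: Sequence[ProteinABTResult], accessions: Sequence[str]
) -> SubsetSummary:
    """Median ABTscore/ABTdensity over the intersection with an external
    accession list (e.g. a condensate proteome). Accessions absent from the
    scored set are counted as missing; proteins without a retained IDR are
    excluded, so the medians describe scored proteins only."""
    if not accessions:
        raise ValueError("accession list must be non-empty")
    wanted = set(accessions)
    hits = [r for r in results if r.accession in wanted and r.abtdensity is not None]
    if not hits:
        raise ValueError("no overlap between accession list and scored proteins")
    found_accessions = {r.accession for r in results}
    n_missing = len([a for a in wanted if a not in found_accessions])
    return SubsetSummary(
        n=len(hits),
        n_missing=n_missing,
        median_abtscore=_median([r.abtscore for r in hits]),
        median_abtdensity=_median([r.abtdensity for r in hits]),
    )


def export_group_accessions(
    results: Sequence[ProteinABTResult], outdir: str | Path
) -> list[Path]:
    """Write group1.txt .. group4.txt, one accession per line in input
    order; an empty group still produces an (empty) file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for g in (1, 2, 3, 4):
        path = outdir / f"group{g}.txt"
        with open(path, "w") as fh:
            for r in results:
                if r.group == g:
                    fh.write(r.accession + "\n")
        paths.append(path)
    return paths
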