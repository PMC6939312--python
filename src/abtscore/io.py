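"""Reading protein FASTA and per-residue disorder tracks; writing result
tables.

Disorder tracks arrive in IUPRED "long" three-column text format — comment
lines starting with '#', then whitespace-separated rows of
(1-based position, residue letter, score in [0, 1]) — one file per protein,
located in a directory as "<accession><suffix>" (default suffix
".iupred").

Results go to a TSV (accession, n_idrs, n_disordered_residues, abtscore,
abtdensity, group; floats at 6 significant digits, "NA" for proteins
without a retained IDR) and, optionally, a per-protein JSON sidecar with
per-IDR detail in 1-based inclusive coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .scoring import ProteinABTResult

__all__ = [
    "ProteinRecord",
    "DisorderTrack",
    "DISORDER_SUFFIX",
    "read_fasta",
    "read_disorder_track",
    "disorder_track_path",
    "write_results_tsv",
    "read_results_tsv",
    "write_json_detail",
]

DISORDER_SUFFIX = ".iupred"

RESULT_COLUMNS = ("accession", "n_idrs", "n_disordered_residues", "abtscore", "abtdensity", "group")


@dataclass(frozen=True)
class ProteinRecord:
    """An accession plus an upper-cased amino-acid sequence. Ambiguity
    letters (X, B, Z, U, O) are retained; they carry zero charge
    downstream."""

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DisorderTrack:
    """Per-residue disorder propensities in [0, 1], one per residue."""

    accession: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.size and (scores.min() < 0 or scores.max() > 1):
            raise ValueError(f"{self.accession}: disorder scores outside [0, 1]")

    def __len__(self) -> int:
        return self.scores.size


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """One record per FASTA header, wrapped lines concatenated, order
    preserved. The accession is the first whitespace-separated token of the
    header; duplicates are an error."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if acc in seen:
            raise ValueError(f"duplicate accession in FASTA: {acc}")
        seen.add(acc)
        records.append(ProteinRecord(accession=acc, sequence=str(rec.seq).upper()))
    return records


def disorder_track_path(directory: str | Path, accession: str, suffix: str = DISORDER_SUFFIX) -> Path:
    return Path(directory) / f"{accession}{suffix}"


def read_disorder_track(
    path: str | Path, expected_length: int, accession: str | None = None
) -> DisorderTrack:
    """Parse an IUPRED long-format file, verifying consecutive 1-based
    positions and the expected residue count."""
    path = Path(path)
    acc = accession if accession is not None else path.stem
    scores: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed row {line!r}")
            pos = int(fields[0])
            if pos != len(scores) + 1:
                raise ValueError(
                    f"{path}: non-consecutive position {pos} (expected {len(scores) + 1})"
                )
            score = float(fields[2])
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"{path}: score {score} at position {pos} outside [0, 1]")
            scores.append(score)
    if len(scores) != expected_length:
        raise ValueError(
            f"{path}: {len(scores)} scores but sequence has {expected_length} residues"
        )
    return DisorderTrack(accession=acc, scores=np.asarray(scores))


def _fmt(value: float | None) -> str:
    if value is None:
        return "NA"
    return f"{value:.6g}"


def write_results_tsv(results: Sequence[ProteinABTResult], path: str | Path) -> None:
    """Write the per-protein summary table; one row per protein in input
    order, floats at 6 significant digits. Rerunning on the same input
    yields a byte-identical file."""
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            group = "NA" if r.group is None else str(r.group)
            fh.write(
                f"{r.accession}\t{r.n_idrs}\t{r.n_disordered_residues}\t"
                f"{_fmt(r.abtscore)}\t{_fmt(r.abtdensity)}\t{group}\n"
            )


def read_results_tsv(path: str | Path) -> list[ProteinABTResult]:
    """Re-read a results TSV (per-IDR detail is not recoverable from the
    summary table and comes back empty)."""
    results: list[ProteinABTResult] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != RESULT_COLUMNS:
            raise ValueError(f"{path}: unexpected header {header}")
        for line in fh:
            acc, _n_idrs, n_dis, score, density, group = line.rstrip("\n").split("\t")
            results.append(
                ProteinABTResult(
                    accession=acc,
                    idr_scores=[],
                    abtscore=float(score),
                    n_disordered_residues=int(n_dis),
                    abtdensity=None if density == "NA" else float(density),
                    group=None if group == "NA" else int(group),
                )
            )
    return results


def write_json_detail(results: Iterable[ProteinABTResult], directory: str | Path) -> None:
    """Per-protein JSON sidecars exposing every per-IDR quantity for
    auditability. IDR coordinates are 1-based inclusive."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for r in results:
        detail = {
            "accession": r.accession,
            "abtscore": r.abtscore,
            "abtdensity": r.abtdensity,
            "n_disordered_residues": r.n_disordered_residues,
            "group": r.group,
            "idrs": [
                {
                    "start": s.segment.start + 1,
                    "end": s.segment.end,
                    "length": s.length,
                    "kappa": s.kappa.value,
                    "f_plus": s.kappa.f_plus,
                    "f_minus": s.kappa.f_minus,
                    "filtered_area_sum": s.filtered_area_sum,
                    "multiplier": s.multiplier,
                    "score": s.score,
                }
                for s in r.idr_scores
            ],
        }
        with open(directory / f"{r.accession}.json", "w") as fh:
            json.dump(detail, fh, indent=2, sort_keys=True)
            fh.write("\n")
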