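"""Synthetic proteins with controlled charge-tract architecture.

Every other module is testable without downloads: this module fabricates
sequences whose charge patterning is known by construction, together with
matching disorder tracks in IUPRED long format and a manifest recording
each protein's archetype.

Archetypes (neutral filler is glycine, a common linker residue):

* ``diblock``            — G-flank, D-block, K-block, G-flank: contiguous
                           oppositely charged tracts, the architecture the
                           score is designed to reward;
* ``alternating``        — strict DKDK... mixing: same composition as a
                           diblock core but no contiguous tract, scores 0;
* ``uncharged``          — all-G control, scores 0;
* ``scrambled``          — seeded uniform permutation of the diblock's
                           letters: charges present but tracts disrupted;
* ``npm1-like-multiblock`` — alternating acidic/basic blocks separated by
                           short neutral spacers, mimicking nucleolar
                           scaffold proteins with several charged tracts.

With the default fully disordered track, scores order as
diblock > scrambled >= alternating = uncharged = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import DISORDER_SUFFIX, DisorderTrack, ProteinRecord, disorder_track_path

__all__ = [
    "ARCHETYPES",
    "ArchitectureSpec",
    "make_sequence",
    "make_disorder_track",
    "write_disorder_track",
    "make_synthetic_proteome",
]

ARCHETYPES = ("diblock", "alternating", "uncharged", "scrambled", "npm1-like-multiblock")

#: Qualitative score ordering implied by construction; smaller = higher
#: score tier. Used in the proteome manifest.
SCORE_TIER = {
    "diblock": 0,
    "npm1-like-multiblock": 0,
    "scrambled": 1,
    "alternating": 2,
    "uncharged": 2,
}

NEUTRAL = "G"


@dataclass(frozen=True)
class ArchitectureSpec:
    archetype: str
    n_neg: int = 15
    n_pos: int = 15
    flank_len: int = 10
    block_len: int = 8
    spacer_len: int = 4
    seed: int = 0
    accession: str = ""

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if min(self.n_neg, self.n_pos, self.flank_len) < 0:
            raise ValueError("residue counts must be non-negative")


def _multiblock(n_neg: int, n_pos: int, block_len: int, spacer_len: int) -> str:
    """Alternate D-blocks and K-blocks of at most block_len residues,
    separated by neutral spacers, until both charge budgets are spent."""
    parts: list[str] = []
    remaining = {"D": n_neg, "K": n_pos}
    letter = "D"
    while remaining["D"] > 0 or remaining["K"] > 0:
        if remaining[letter] > 0:
            take = min(block_len, remaining[letter])
            if parts:
                parts.append(NEUTRAL * spacer_len)
            parts.append(letter * take)
            remaining[letter] -= take
        letter = "K" if letter == "D" else "D"
    return "".join(parts)


def make_sequence(spec: ArchitectureSpec) -> ProteinRecord:
    """Deterministically construct the archetype's sequence."""
    flank = NEUTRAL * spec.flank_len
    if spec.archetype == "diblock":
        core = "D" * spec.n_neg + "K" * spec.n_pos
    elif spec.archetype == "alternating":
        pairs = min(spec.n_neg, spec.n_pos)
        core = "DK" * pairs + "D" * (spec.n_neg - pairs) + "K" * (spec.n_pos - pairs)
    elif spec.archetype == "uncharged":
        core = NEUTRAL * (spec.n_neg + spec.n_pos)
    elif spec.archetype == "scrambled":
        letters = list(flank + "D" * spec.n_neg + "K" * spec.n_pos + flank)
        rng = np.random.default_rng(spec.seed)
        rng.shuffle(letters)
        seq = "".join(letters)
        if not seq:
            raise ValueError("zero-length sequence")
        return ProteinRecord(accession=spec.accession or "scrambled", sequence=seq)
    else:  # npm1-like-multiblock
        core = _multiblock(spec.n_neg, spec.n_pos, spec.block_len, spec.spacer_len)
    seq = flank + core + flank
    if not seq:
        raise ValueError("zero-length sequence")
    return ProteinRecord(accession=spec.accession or spec.archetype, sequence=seq)


def make_disorder_track(
    length: int,
    idr_spans: Sequence[tuple[int, int]],
    in_value: float = 0.9,
    out_value: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
    accession: str = "synthetic",
) -> DisorderTrack:
    """A step-function disorder track: `in_value` on the (0-based,
    half-open, non-overlapping) spans, `out_value` elsewhere, plus optional
    seeded Gaussian noise clipped back into [0, 1]."""
    scores = np.full(length, out_value, dtype=float)
    covered = np.zeros(length, dtype=bool)
    for start, end in idr_spans:
        if not (0 <= start < end <= length):
            raise ValueError(f"span [{start}, {end}) outside track of length {length}")
        if covered[start:end].any():
            raise ValueError("overlapping disorder spans")
        covered[start:end] = True
        scores[start:end] = in_value
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        scores = np.clip(scores + rng.normal(0.0, noise_sd, size=length), 0.0, 1.0)
    return DisorderTrack(accession=accession, scores=scores)


def write_disorder_track(track: DisorderTrack, sequence: str, path: str | Path) -> None:
    """Write IUPRED long-format text: a comment header then rows of
    (1-based position, residue, score)."""
    with open(path, "w") as fh:
        fh.write("# synthetic disorder track (IUPRED long format)\n")
        fh.write("# POS\tRES\tIUPRED2\n")
        for i, (aa, score) in enumerate(zip(sequence, track.scores), start=1):
            fh.write(f"{i}\t{aa}\t{score:.4f}\n")


DEFAULT_MIX = {"diblock": 0.4, "scrambled": 0.2, "alternating": 0.2, "uncharged": 0.2}


def _allocate(n: int, mix: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n proteins to archetype fractions."""
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("mix fractions must sum to 1")
    quotas = {a: n * f for a, f in mix.items() if f > 0}
    counts = {a: int(q) for a, q in quotas.items()}
    leftovers = sorted(quotas, key=lambda a: (counts[a] - quotas[a], a))
    for a in leftovers[: n - sum(counts.values())]:
        counts[a] += 1
    if any(c == 0 for c in counts.values()):
        raise ValueError(
            f"{n} proteins cannot cover the {len(counts)} requested archetypes"
        )
    return counts


def make_synthetic_proteome(
    n_proteins: int,
    seed: int,
    outdir: str | Path,
    mix: dict[str, float] | None = None,
    suffix: str = DISORDER_SUFFIX,
) -> tuple[Path, Path, Path]:
    """Write a self-consistent input set: proteins.fasta, one disorder
    track per protein (fully disordered), and manifest.tsv recording each
    protein's archetype, geometry and implied score tier.

    Charge-block sizes grow with the protein's index within its archetype
    so that, e.g., diblock proteins carry distinct ABTdensity values.
    Identical (n_proteins, seed, mix) regenerate byte-identical files.
    """
    mix = dict(mix) if mix is not None else dict(DEFAULT_MIX)
    counts = _allocate(n_proteins, mix)
    outdir = Path(outdir)
    tracks_dir = outdir / "tracks"
    tracks_dir.mkdir(parents=True, exist_ok=True)
    fasta_path = outdir / "proteins.fasta"
    manifest_path = outdir / "manifest.tsv"

    specs: list[ArchitectureSpec] = []
    idx = 0
    for archetype in sorted(counts):
        for j in range(counts[archetype]):
            size = 10 + j  # distinct geometry within each archetype
            specs.append(
                ArchitectureSpec(
                    archetype=archetype,
                    n_neg=size,
                    n_pos=size,
                    flank_len=10,
                    seed=seed + idx,
                    accession=f"SYN{idx:04d}",
                )
            )
            idx += 1

    with open(fasta_path, "w") as fa, open(manifest_path, "w") as mf:
        mf.write("accession\tarchetype\tn_neg\tn_pos\tflank_len\tlength\tscore_tier\n")
        for spec in specs:
            rec = make_sequence(spec)
            track = make_disorder_track(
                len(rec), [(0, len(rec))], accession=rec.accession
            )
            fa.write(f">{rec.accession}\n{rec.sequence}\n")
            write_disorder_track(
                track, rec.sequence, disorder_track_path(tracks_dir, rec.accession, suffix)
            )
            mf.write(
                f"{rec.accession}\t{spec.archetype}\t{spec.n_neg}\t{spec.n_pos}\t"
                f"{spec.flank_len}\t{len(rec)}\t{SCORE_TIER[spec.archetype]}\n"
            )
    return fasta_path, tracks_dir, manifest_path
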