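"""Charge-patterning features of IDR subsequences.

Three layers:

* a windowed net-charge-per-residue (NCPR) profile — per-residue mean charge
  over a centered 5-residue window that shrinks at the subsequence ends;
  K/R count +1, D/E count -1, everything else (including histidine and
  ambiguity codes) is neutral;
* charged tracts — maximal sign-constant nonzero runs of the NCPR profile,
  each with an area = |sum of NCPR over the tract| = length x mean |NCPR|;
* the Das-Pappu kappa parameter quantifying charge segregation: blob-wise
  charge asymmetry variance (delta) normalized by the maximum attainable
  over rearrangements of the same composition (delta_max), averaged over
  blob sizes 5 and 6. kappa ~ 0 for well-mixed charges (DKDKDK...), 1 for a
  fully segregated diblock (DDDDKKKK).

The NCPR window is computed on the IDR subsequence only; residues outside
the IDR are never read, so a tract may touch the IDR boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

__all__ = [
    "CHARGE",
    "NCPRProfile",
    "ChargeTract",
    "KappaResult",
    "residue_charge",
    "ncpr_profile",
    "find_tracts",
    "sum_filtered_areas",
    "charge_fractions",
    "delta",
    "delta_max",
    "kappa",
    "DEFAULT_NCPR_WINDOW",
    "KAPPA_BLOBS",
]

DEFAULT_NCPR_WINDOW = 5
KAPPA_BLOBS = (5, 6)

#: Per-residue charge at physiological pH as used throughout: only the two
#: basic (K, R) and two acidic (D, E) residues carry charge; histidine is
#: treated as neutral.
CHARGE: dict[str, int] = {"K": 1, "R": 1, "D": -1, "E": -1}

# Above this many distinct charge arrangements, delta_max switches from
# exhaustive enumeration to the constructive block-arrangement search.
_EXHAUSTIVE_PATTERN_BUDGET = 50_000


def residue_charge(aa: str) -> int:
    """+1 for K/R, -1 for D/E, 0 for every other letter."""
    return CHARGE.get(aa.upper(), 0)


def _charges(seq: str) -> np.ndarray:
    return np.array([CHARGE.get(a, 0) for a in seq.upper()], dtype=float)


@dataclass(frozen=True)
class NCPRProfile:
    """Windowed net-charge-per-residue values, one per residue."""

    values: np.ndarray
    window: int

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class ChargeTract:
    """Maximal sign-constant nonzero run of an NCPR profile.

    `area` is dimensionless: number of residues times the mean |NCPR|,
    i.e. |sum of the NCPR values over [start, end)|.
    """

    start: int
    end: int
    sign: int
    area: float


@dataclass(frozen=True)
class KappaResult:
    """Kappa charge-segregation parameter with the charge fractions it
    was computed from. `value` is None when kappa is undefined (no charged
    residues, or a composition whose arrangements are all equivalent)."""

    value: float | None
    f_plus: float
    f_minus: float

    @property
    def defined(self) -> bool:
        return self.value is not None


def ncpr_profile(seq: str, window: int = DEFAULT_NCPR_WINDOW) -> NCPRProfile:
    """NCPR at each residue: mean charge over the centered window,
    shrinking at the subsequence ends."""
    if not seq:
        raise ValueError("sequence must be non-empty")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    ch = _charges(seq)
    n = ch.size
    h = (window - 1) // 2
    csum = np.concatenate([[0.0], np.cumsum(ch)])
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h + 1, n)
    return NCPRProfile(values=(csum[hi] - csum[lo]) / (hi - lo), window=window)


def find_tracts(profile: NCPRProfile) -> list[ChargeTract]:
    """Split the profile into maximal runs of strictly positive or strictly
    negative NCPR; a zero value or a sign change terminates a tract."""
    vals = profile.values
    tracts: list[ChargeTract] = []
    start = None
    sign = 0
    for i, v in enumerate(vals):
        s = 0 if v == 0 else (1 if v > 0 else -1)
        if s != sign:
            if sign != 0:
                tracts.append(_tract(vals, start, i, sign))
            start, sign = (i, s) if s != 0 else (None, 0)
    if sign != 0:
        tracts.append(_tract(vals, start, vals.size, sign))
    return tracts


def _tract(vals: np.ndarray, start: int, end: int, sign: int) -> ChargeTract:
    return ChargeTract(start=start, end=end, sign=sign, area=float(abs(vals[start:end].sum())))


def sum_filtered_areas(profile: NCPRProfile, min_area: float = 1.0) -> float:
    """Sum of tract areas strictly greater than `min_area`, both signs.

    Accumulated in profile order so the result is bitwise deterministic.
    """
    total = 0.0
    for tract in find_tracts(profile):
        if tract.area > min_area:
            total += tract.area
    return total


def charge_fractions(seq: str) -> tuple[float, float]:
    """(fraction of K/R, fraction of D/E) over the full sequence."""
    if not seq:
        raise ValueError("sequence must be non-empty")
    ch = _charges(seq)
    return float((ch > 0).mean()), float((ch < 0).mean())


# --- kappa machinery -------------------------------------------------------
#
# sigma of a stretch with charge fractions (f+, f-) is (f+ - f-)^2/(f+ + f-),
# taken as 0 when the stretch has no charged residues. delta for a blob size
# g is the mean over all contiguous length-g windows of
# (sigma_window - sigma_sequence)^2.


def _sigma(fp: float, fm: float) -> float:
    tot = fp + fm
    return 0.0 if tot == 0 else (fp - fm) ** 2 / tot


def _delta_pattern(pattern: np.ndarray, blob: int) -> float:
    """delta of a +1/0/-1 charge pattern for one blob size (vectorized)."""
    n = pattern.size
    pos = (pattern > 0).astype(float)
    neg = (pattern < 0).astype(float)
    sg = _sigma(pos.mean(), neg.mean())
    cp = np.concatenate([[0.0], np.cumsum(pos)])
    cn = np.concatenate([[0.0], np.cumsum(neg)])
    wp = (cp[blob:] - cp[:-blob]) / blob
    wm = (cn[blob:] - cn[:-blob]) / blob
    tot = wp + wm
    sig = np.where(tot > 0, (wp - wm) ** 2 / np.where(tot > 0, tot, 1.0), 0.0)
    return float(np.mean((sig - sg) ** 2))


def delta(seq: str, blob: int) -> float:
    """Blob-wise charge asymmetry variance of the sequence."""
    if len(seq) < blob:
        raise ValueError(f"sequence shorter than blob size {blob}")
    return _delta_pattern(_charges(seq), blob)


def _n_patterns(n: int, npos: int, nneg: int) -> int:
    return comb(n, npos) * comb(n - npos, nneg)


def _block_candidates(npos: int, nneg: int, nneut: int):
    """Fully segregated charge blocks with the neutral residues split as
    blocks before / between / after — the arrangements among which the
    permutation-max delta lies once the sequence is long relative to the
    blob size."""
    for mid in range(nneut + 1):
        for head in range(nneut - mid + 1):
            tail = nneut - mid - head
            yield np.concatenate(
                [
                    np.zeros(head),
                    np.ones(npos),
                    np.zeros(mid),
                    -np.ones(nneg),
                    np.zeros(tail),
                ]
            )


def _exhaustive_patterns(n: int, npos: int, nneg: int):
    idx = range(n)
    for pos_at in combinations(idx, npos):
        rest = [i for i in idx if i not in pos_at]
        for neg_at in combinations(rest, nneg):
            pat = np.zeros(n)
            pat[list(pos_at)] = 1.0
            pat[list(neg_at)] = -1.0
            yield pat


def delta_max(seq: str, blob: int) -> float:
    """Maximum of delta over rearrangements of the sequence's composition.

    Exact by enumeration of distinct charge patterns when the composition is
    small enough; otherwise the maximum over the segregated block
    arrangements (which attain the permutation maximum for sequences long
    relative to the blob) and the input's own arrangement, so that
    delta <= delta_max always holds.
    """
    if len(seq) < blob:
        raise ValueError(f"sequence shorter than blob size {blob}")
    ch = _charges(seq)
    n = ch.size
    npos = int((ch > 0).sum())
    nneg = int((ch < 0).sum())
    if npos + nneg == 0:
        return 0.0
    if _n_patterns(n, npos, nneg) <= _EXHAUSTIVE_PATTERN_BUDGET:
        candidates = _exhaustive_patterns(n, npos, nneg)
    else:
        candidates = list(_block_candidates(npos, nneg, n - npos - nneg)) + [ch]
    return max(_delta_pattern(pat, blob) for pat in candidates)


def kappa(seq: str) -> KappaResult:
    """Charge segregation in [0, 1], averaged over blob sizes 5 and 6.

    A blob term is skipped when the sequence is shorter than the blob or
    its delta_max is 0 (all arrangements equivalent). With no usable blob
    term, kappa is undefined — a value, not an error.
    """
    if not seq:
        raise ValueError("sequence must be non-empty")
    fp, fm = charge_fractions(seq)
    terms: list[float] = []
    for blob in KAPPA_BLOBS:
        if len(seq) < blob:
            continue
        dmax = delta_max(seq, blob)
        if dmax > 0:
            terms.append(delta(seq, blob) / dmax)
    if not terms:
        return KappaResult(value=None, f_plus=fp, f_minus=fm)
    return KappaResult(value=sum(terms) / len(terms), f_plus=fp, f_minus=fm)
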