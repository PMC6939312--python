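"""Independent naive re-implementations used as oracles.

Everything here is deliberately written from the definitions in plain
Python, sharing no code with the package: per-position loops instead of
cumulative sums, pairwise merge loops run to a fixpoint, and exhaustive or
constructive enumeration for delta_max mirroring the documented convention.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

CHARGE = {"K": 1, "R": 1, "D": -1, "E": -1}

EXHAUSTIVE_PATTERN_BUDGET = 50_000


# --- segmentation ----------------------------------------------------------


def naive_smooth(scores, window):
    h = (window - 1) // 2
    out = []
    for i in range(len(scores)):
        window_vals = [scores[j] for j in range(max(0, i - h), min(len(scores), i + h + 1))]
        out.append(sum(window_vals) / len(window_vals))
    return out


def naive_runs(values, cutoff):
    runs = []
    start = None
    for i, v in enumerate(values):
        if v > cutoff:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(values)))
    return runs


def naive_merge(runs, max_gap):
    runs = list(runs)
    changed = True
    while changed:
        changed = False
        for i in range(len(runs) - 1):
            (s1, e1), (s2, e2) = runs[i], runs[i + 1]
            if s2 - e1 <= max_gap:
                runs[i : i + 2] = [(s1, e2)]
                changed = True
                break
    return runs


def naive_segment(scores, window=7, cutoff=0.45, max_gap=7, min_length=30):
    smoothed = naive_smooth(scores, window)
    runs = naive_merge(naive_runs(smoothed, cutoff), max_gap)
    return [(s, e) for s, e in runs if e - s >= min_length]


# --- charge features -------------------------------------------------------


def naive_ncpr(seq, window=5):
    charges = [CHARGE.get(a, 0) for a in seq.upper()]
    h = (window - 1) // 2
    out = []
    for i in range(len(charges)):
        vals = charges[max(0, i - h) : min(len(charges), i + h + 1)]
        out.append(sum(vals) / len(vals))
    return out


def naive_tracts(profile):
    tracts = []
    i = 0
    n = len(profile)
    while i < n:
        if profile[i] == 0:
            i += 1
            continue
        sign = 1 if profile[i] > 0 else -1
        j = i
        while j < n and (profile[j] > 0) == (sign > 0) and profile[j] != 0:
            j += 1
        tracts.append((i, j, sign, abs(sum(profile[i:j]))))
        i = j
    return tracts


def naive_area_sum(seq, window=5, min_area=1.0):
    total = 0.0
    for _s, _e, _sign, area in naive_tracts(naive_ncpr(seq, window)):
        if area > min_area:
            total += area
    return total


# --- kappa -----------------------------------------------------------------


def naive_sigma(stretch):
    fp = sum(1 for c in stretch if c > 0) / len(stretch)
    fm = sum(1 for c in stretch if c < 0) / len(stretch)
    if fp + fm == 0:
        return 0.0
    return (fp - fm) ** 2 / (fp + fm)


def naive_delta_pattern(pattern, blob):
    sigma_seq = naive_sigma(pattern)
    terms = [
        (naive_sigma(pattern[i : i + blob]) - sigma_seq) ** 2
        for i in range(len(pattern) - blob + 1)
    ]
    return sum(terms) / len(terms)


def naive_delta(seq, blob):
    return naive_delta_pattern([CHARGE.get(a, 0) for a in seq.upper()], blob)


def charge_pattern_permutations(npos, nneg, nneut):
    """All distinct +1/0/-1 arrangements of the composition."""
    n = npos + nneg + nneut
    for pos_at in combinations(range(n), npos):
        rest = [i for i in range(n) if i not in pos_at]
        for neg_at in combinations(rest, nneg):
            pat = [0] * n
            for i in pos_at:
                pat[i] = 1
            for i in neg_at:
                pat[i] = -1
            yield pat


def naive_delta_max_exhaustive(npos, nneg, nneut, blob):
    return max(
        naive_delta_pattern(p, blob) for p in charge_pattern_permutations(npos, nneg, nneut)
    )


def naive_delta_max_blocks(pattern, blob):
    """Constructive convention for large compositions: segregated charge
    blocks with neutral blocks before/between/after, plus the input's own
    arrangement."""
    npos = sum(1 for c in pattern if c > 0)
    nneg = sum(1 for c in pattern if c < 0)
    nneut = len(pattern) - npos - nneg
    best = naive_delta_pattern(pattern, blob)
    for mid in range(nneut + 1):
        for head in range(nneut - mid + 1):
            tail = nneut - mid - head
            cand = [0] * head + [1] * npos + [0] * mid + [-1] * nneg + [0] * tail
            best = max(best, naive_delta_pattern(cand, blob))
    return best


def naive_delta_max(seq, blob):
    pattern = [CHARGE.get(a, 0) for a in seq.upper()]
    npos = sum(1 for c in pattern if c > 0)
    nneg = sum(1 for c in pattern if c < 0)
    n = len(pattern)
    if npos + nneg == 0:
        return 0.0
    if comb(n, npos) * comb(n - npos, nneg) <= EXHAUSTIVE_PATTERN_BUDGET:
        return naive_delta_max_exhaustive(npos, nneg, n - npos - nneg, blob)
    return naive_delta_max_blocks(pattern, blob)


def naive_kappa(seq):
    terms = []
    for blob in (5, 6):
        if len(seq) < blob:
            continue
        dmax = naive_delta_max(seq, blob)
        if dmax > 0:
            terms.append(naive_delta(seq, blob) / dmax)
    if not terms:
        return None
    return sum(terms) / len(terms)


# --- end-to-end scoring ----------------------------------------------------


def naive_score_idr(seq, window=5, min_area=1.0):
    area_sum = naive_area_sum(seq, window, min_area)
    kap = naive_kappa(seq)
    multiplier = (0.6 + kap) ** 2 if kap is not None else 0.36
    return area_sum * multiplier


def naive_score_protein(sequence, disorder_scores, min_length=30):
    segments = naive_segment(disorder_scores, min_length=min_length)
    total = 0.0
    n_dis = 0
    for s, e in segments:
        total += naive_score_idr(sequence[s:e])
        n_dis += e - s
    density = total / n_dis if n_dis else None
    return total, n_dis, density
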