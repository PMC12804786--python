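"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by direct enumeration or textbook
formulas, sharing no code with the implementation paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np


# --- homozygosity bins ------------------------------------------------------


def _qualify(calls: dict, min_per_class: int):
    alt = frozenset(s for s, c in calls.items() if c == "1/1")
    ref = frozenset(s for s, c in calls.items() if c == "0/0")
    return len(alt) >= min_per_class and len(ref) >= min_per_class, alt, ref


def _evaluate_interval(recs, i, j, min_per_class, max_mismatch):
    """Validity of the candidate bin spanning record indices [i, j].

    Walks left to right keeping running intersections; returns
    (alt_set, ref_set, n_mismatches) when records i and j are consistent
    and the skipped-record count stays within budget, else None.
    """
    ok, A, R = _qualify(recs[i].calls, min_per_class)
    if not ok:
        return None
    skips = 0
    last = i
    for k in range(i + 1, j + 1):
        ok_k, alt_k, ref_k = _qualify(recs[k].calls, min_per_class)
        consistent = False
        if ok_k:
            A2, R2 = A & alt_k, R & ref_k
            if len(A2) >= min_per_class and len(R2) >= min_per_class:
                consistent = True
        if consistent:
            A, R = A2, R2
            last = k
        else:
            skips += 1
            if skips > max_mismatch:
                return None
    if last != j:
        return None
    return A, R, skips


def oracle_bins(records, min_per_class: int = 3, max_mismatch: int = 2):
    """Exhaustive candidate-interval enumeration, greedy leftmost-maximal
    selection of non-overlapping bins.  Returns comparable tuples."""
    out = []
    by_chrom: dict = {}
    for r in records:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, recs in by_chrom.items():
        i = 0
        n = len(recs)
        while i < n:
            best = None
            for j in range(i, n):
                v = _evaluate_interval(recs, i, j, min_per_class, max_mismatch)
                if v is not None:
                    best = (j, v)
            if best is None:
                i += 1
                continue
            j, (A, R, skips) = best
            out.append((
                chrom, recs[i].pos, recs[j].pos,
                tuple(sorted(A)[:3]), tuple(sorted(R)[:3]),
                j - i + 1, skips,
            ))
            i = j + 1
    return out


def bins_as_tuples(bins):
    return [
        (b.chrom, b.start, b.end, b.alt_trio, b.ref_trio,
         b.n_records, b.n_mismatches)
        for b in bins
    ]


# --- genic context ----------------------------------------------------------

_CONTEXT_ORDER = ("cds", "utr5", "utr3", "intron", "upstream2kb",
                  "downstream2kb")


def oracle_context(models, chrom: str, pos: int) -> tuple[str, tuple]:
    """Direct membership scan over every gene model (1-based point)."""
    hits = set()
    assoc = set()
    for m in models:
        if m.chrom != chrom:
            continue
        in_body = m.start <= pos <= m.end
        in_up = m.upstream2kb and m.upstream2kb[0] <= pos <= m.upstream2kb[1]
        in_down = (m.downstream2kb
                   and m.downstream2kb[0] <= pos <= m.downstream2kb[1])
        if in_body or in_up or in_down:
            assoc.add(m.gene_id)
        for cat in ("cds", "utr5", "utr3", "introns"):
            label = "intron" if cat == "introns" else cat
            if any(s <= pos <= e for s, e in getattr(m, cat)):
                hits.add(label)
        if in_up:
            hits.add("upstream2kb")
        if in_down:
            hits.add("downstream2kb")
    for cat in _CONTEXT_ORDER:
        if cat in hits:
            return cat, tuple(sorted(assoc))
    return "intergenic", ()


# --- chi-squared ------------------------------------------------------------


def textbook_chi2(obs: np.ndarray) -> tuple[float, int]:
    """Pearson chi-squared by the definition, with explicit loops."""
    obs = np.asarray(obs, dtype=float)
    total = obs.sum()
    rows, cols = obs.shape
    chi2 = 0.0
    for i in range(rows):
        for j in range(cols):
            exp = obs[i].sum() * obs[:, j].sum() / total
            chi2 += (obs[i, j] - exp) ** 2 / exp
    return chi2, (rows - 1) * (cols - 1)


# --- permutation ------------------------------------------------------------


def exhaustive_tail(is_deg, has_mite) -> float:
    """Pr(P >= P_obs) under the exact label-permutation null, by
    enumerating every possible DEG label placement."""
    is_deg = np.asarray(is_deg, dtype=bool)
    has_mite = np.asarray(has_mite, dtype=bool)
    n = is_deg.size
    k = int(is_deg.sum())
    p_obs = int((is_deg & has_mite).sum())
    total = 0
    ge = 0
    for combo in itertools.combinations(range(n), k):
        total += 1
        if sum(has_mite[list(combo)]) >= p_obs:
            ge += 1
    return ge / total
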