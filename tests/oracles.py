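"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity from first principles — per-base arrays,
quadratic dynamic programming, sort-and-step FDR — without touching the
implementation paths it checks.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

# ---------------------------------------------------------------------------
# per-base structural-difference event oracle


def _exon_array(t, lo, hi):
    arr = np.zeros(hi - lo, dtype=bool)
    for e in t.exons:
        s, eo = max(e.start, lo), min(e.end, hi)
        if s < eo:
            arr[s - lo : eo - lo] = True
    return arr


def _transitions(arr, lo):
    """Typed transitions of a boolean exon array: 'D' exon→intron, 'A' intron→exon."""
    sites = []
    for p in range(1, len(arr)):
        if arr[p - 1] and not arr[p]:
            sites.append(("D", lo + p))
        elif not arr[p - 1] and arr[p]:
            sites.append(("A", lo + p))
    return sites


def oracle_pairwise_events(a, b):
    """Brute-force variable regions + classes between two isoforms.

    Works entirely on per-base exonic-status arrays: difference runs are
    merged unless a transition shared by both isoforms (same position, same
    type) separates them; classes follow from the per-isoform transition
    patterns between the flanking shared transitions.
    Returns a sorted list of (region_start, region_end, klass).
    """
    lo, hi = max(a.start, b.start), min(a.end, b.end)
    if lo >= hi:
        return []
    arr_a, arr_b = _exon_array(a, lo, hi), _exon_array(b, lo, hi)
    diff = arr_a != arr_b
    if not diff.any():
        return []
    # maximal difference runs
    runs = []
    p = 0
    n = len(diff)
    while p < n:
        if diff[p]:
            q = p
            while q < n and diff[q]:
                q += 1
            runs.append((lo + p, lo + q))
            p = q
        else:
            p += 1
    sites_a = _transitions(arr_a, lo)
    sites_b = _transitions(arr_b, lo)
    common = sorted(set(sites_a) & set(sites_b), key=lambda s: s[1])
    common_pos = [p for _, p in common]

    groups = [[runs[0]]]
    for prev, cur in zip(runs, runs[1:]):
        if any(prev[1] <= p <= cur[0] for p in common_pos):
            groups.append([cur])
        else:
            groups[-1].append(cur)

    out = []
    for grp in groups:
        s, e = grp[0][0], grp[-1][1]
        fl = max((p for p in common_pos if p <= s), default=lo)
        fr = min((p for p in common_pos if p >= e), default=hi)
        sig_a = tuple(t for t in sites_a if fl < t[1] < fr)
        sig_b = tuple(t for t in sites_b if fl < t[1] < fr)
        out.append((s, e, _classify(sig_a, sig_b, (s, e), arr_a, arr_b, lo, a.strand)))
    return sorted(out)


def _classify(sig_a, sig_b, region, arr_a, arr_b, lo, strand):
    def exonic(arr, pos):
        return bool(arr[pos - lo])

    if bool(sig_a) != bool(sig_b):
        full = sig_a or sig_b
        other_arr = arr_b if sig_a else arr_a
        if (
            len(full) == 2
            and full[0] == ("D", region[0])
            and full[1] == ("A", region[1])
            and exonic(other_arr, region[0])
        ):
            return "IR"
        alternating = len(full) >= 2 and len(full) % 2 == 0 and all(
            t == "AD"[i % 2] for i, (t, _) in enumerate(full)
        )
        if alternating and not exonic(other_arr, region[0]):
            return "ES"
        return "complex"
    if len(sig_a) == 1 and len(sig_b) == 1 and sig_a[0][0] == sig_b[0][0]:
        if sig_a[0][0] == "D":
            return "Alt5" if strand != "-" else "Alt3"
        return "Alt3" if strand != "-" else "Alt5"
    return "complex"


# ---------------------------------------------------------------------------
# quadratic affine-gap global alignment (Gotoh)


def oracle_global_alignment_score(
    x: str, y: str, open_cost: float = 10.0, extend_cost: float = 0.5
) -> float:
    """Textbook Gotoh DP: BLOSUM62, affine gaps, end gaps penalised.

    A gap of length k costs open + extend*(k-1), matching an aligner whose
    first gap position scores -open and each further position -extend.
    """
    mat = substitution_matrices.load("BLOSUM62")
    n, m = len(x), len(y)
    NEG = -1e18

    def gap(k):
        return open_cost + extend_cost * (k - 1) if k else 0.0

    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in y (x advances)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in x (y advances)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -gap(i)
    for j in range(1, m + 1):
        Iy[0, j] = -gap(j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = mat[x[i - 1], y[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(
                M[i - 1, j] - open_cost,
                Ix[i - 1, j] - extend_cost,
                Iy[i - 1, j] - open_cost,
            )
            Iy[i, j] = max(
                M[i, j - 1] - open_cost,
                Iy[i, j - 1] - extend_cost,
                Ix[i, j - 1] - open_cost,
            )
    return float(max(M[n, m], Ix[n, m], Iy[n, m]))


# ---------------------------------------------------------------------------
# Benjamini–Hochberg sort-and-step oracle


def oracle_bh(pvalues) -> np.ndarray:
    """Step-up BH adjusted p-values: q_(i) = min_{j>=i} p_(j) * n / j."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
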