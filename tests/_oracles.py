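"""Independent oracles used only by the test suite.

These are deliberately implemented with different tools/algorithms than the
package: exact Smith-Waterman via Biopython's PairwiseAligner, brute-force
enumerations, a from-scratch Tajima's D evaluation, and a grid-search HKA
minimiser. None of them import the code paths they check.
"""

import itertools
import math

import numpy as np
from Bio import Align


def smith_waterman(a: str, b: str, match=1, mismatch=-2, gap_open=-5, gap_extend=-2):
    """Exact local alignment score and identity under the package's gap
    convention (gap of length g costs open + g*extend)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    score = aligner.score(a, b)
    aln = next(iter(aligner.align(a, b)))
    counts = aln.counts()
    aligned_cols = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / aligned_cols if aligned_cols else 0.0
    return score, identity


def brute_force_primers(template, window, min_len=18, max_len=25,
                        gc_min=0.20, gc_max=0.80,
                        self_any_max=6.0, self_3p_max=3.0):
    """Enumerate valid primer substrings by checking each constraint directly."""
    out = set()
    for start in range(window[0], window[1]):
        for length in range(min_len, max_len + 1):
            sub = template[start : start + length].upper()
            if len(sub) < length or any(ch not in "ACGT" for ch in sub):
                continue
            gc = (sub.count("G") + sub.count("C")) / length
            if not gc_min <= gc <= gc_max:
                continue
            if loop_complementarity(sub, sub, False) >= self_any_max:
                continue
            if loop_complementarity(sub, sub, True) >= self_3p_max:
                continue
            out.add((start, sub))
    return out


_WC = {"A": "T", "T": "A", "C": "G", "G": "C"}


def loop_complementarity(a, b, anchor):
    """Plain-loop ALIGN-style complementarity score."""
    br = b[::-1]
    na, nb = len(a), len(br)
    best = 0
    for o in range(-(nb - 1), na):
        lo, hi = max(0, o), min(na, o + nb)
        if hi <= lo or (anchor and hi != na):
            continue
        s = sum(1 if _WC[a[i]] == br[i - o] else -1 for i in range(lo, hi))
        best = max(best, s)
    return float(best)


def tajima_d_reference(S, k_hat, n):
    """Tajima's D evaluated from scratch (no shared code with the package)."""
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (k_hat - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def hka_x2_reference(thetas, T, loci):
    """HKA X2 at given parameters (loci as (S, n, D, L_poly, L_div) tuples)."""
    x2 = 0.0
    for theta, (S, n, D, L_poly, L_div) in zip(thetas, loci):
        a1 = sum(1.0 / i for i in range(1, n))
        a2 = sum(1.0 / i**2 for i in range(1, n))
        depth = (n + 1) / (2 * n)
        ES = theta * L_poly * a1
        VS = ES + (theta * L_poly) ** 2 * a2
        ED = theta * L_div * (T + depth)
        VD = ED + (theta * L_div * depth) ** 2
        x2 += (S - ES) ** 2 / VS + (D - ED) ** 2 / VD
    return x2


def hka_grid_minimum(loci, rounds=4, grid=15):
    """Coarse-to-fine grid search over (theta_1..theta_L, T) minimising X2."""
    L = len(loci)
    centers = []
    for S, n, D, L_poly, L_div in loci:
        a1 = sum(1.0 / i for i in range(1, n))
        centers.append(max(S / (a1 * L_poly), 1e-6))
    t_center = max(
        sum(D for _, _, D, _, _ in loci)
        / max(sum(th * ld for th, (_, _, _, _, ld) in zip(centers, loci)), 1e-12)
        - 0.55,
        1e-4,
    )
    centers.append(t_center)
    # generous initial box: moment estimates can be far from the optimum
    widths = [c * 4.0 for c in centers[:-1]] + [centers[-1] * 0.9 + 2.0]

    best_x2, best_params = math.inf, None
    for _ in range(rounds):
        axes = [
            np.linspace(max(c - w, 1e-10), c + w, grid)
            for c, w in zip(centers, widths)
        ]
        for params in itertools.product(*axes):
            x2 = hka_x2_reference(params[:L], params[L], loci)
            if x2 < best_x2:
                best_x2, best_params = x2, params
        centers = list(best_params)
        widths = [2.2 * (a[1] - a[0]) for a in axes]
    return best_x2, best_params


def random_additive_matrix(rng, n):
    """Distances realised on a random binary tree with random positive edges.

    Returns (matrix, labels, splits) where splits are the non-trivial
    bipartitions (side not containing the first label).
    """
    labels = [f"t{i}" for i in range(n)]
    dist = np.zeros((n, n))
    active = list(range(n))
    # random topology by sequential joining, with explicit parent edges
    next_id = n
    parent = {}
    while len(active) > 1:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        la, lb = float(rng.uniform(0.1, 1.0)), float(rng.uniform(0.1, 1.0))
        parent[a] = (next_id, la)
        parent[b] = (next_id, lb)
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1

    def path_to_root(leaf):
        out = {}
        node, acc = leaf, 0.0
        while node in parent:
            nxt, ln = parent[node]
            acc += ln
            node = nxt
            out[node] = acc
        return out

    paths = {i: path_to_root(i) for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            shared = set(paths[i]) & set(paths[j])
            mrca = min(shared, key=lambda x: paths[i][x])
            dist[i, j] = dist[j, i] = paths[i][mrca] + paths[j][mrca]

    # splits: for each internal node, the leaf set below it
    below = {i: {i} for i in range(n)}
    children = {}
    for child, (par, _) in parent.items():
        children.setdefault(par, []).append(child)

    def leaves_below(node):
        if node < n:
            return {node}
        out = set()
        for ch in children.get(node, []):
            out |= leaves_below(ch)
        return out

    full = frozenset(labels)
    splits = set()
    for node in children:
        side = frozenset(labels[x] for x in leaves_below(node))
        if 1 < len(side) < n - 1:
            if labels[0] in side:
                side = full - side
            splits.add(side)
    return dist, labels, splits
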