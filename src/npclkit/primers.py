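"""Constraint-based PCR primer-pair design over orthologous exon loci.

Primers are plain substrings of the sense template (the reverse primer is the
reverse complement of its template window). A valid primer is 18-25 nt with
GC content between 20% and 80%, a self-complementarity score below 6.00 and a
3'-anchored self score below 3.00; a valid pair amplifies a 700-1200 bp
product and the two primers' mutual 3'-anchored complementarity stays below
3.00. Among valid pairs the design prefers the pair whose primer-binding
windows are most conserved between the template and the query genome.

The complementarity score is an ungapped, antiparallel, Primer3 ALIGN-style
score: the maximum over all offsets of (+1 per Watson-Crick pair, -1
otherwise) in the overlap, floored at zero; the 3'-anchored variant only
considers offsets whose overlap includes the first sequence's 3' terminus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .align import ExonRecord, OrthologHit

logger = logging.getLogger(__name__)

_WC = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class PrimerConstraints:
    min_len: int = 18
    max_len: int = 25
    gc_min: float = 0.20
    gc_max: float = 0.80
    self_any_max: float = 6.00
    self_3prime_max: float = 3.00
    pair_3prime_max: float = 3.00
    product_min: int = 700
    product_max: int = 1200
    product_optimum: int = 950


@dataclass(frozen=True)
class Primer:
    """A primer bound to its template window (start, 0-based, on the sense strand)."""

    sequence: str
    start: int
    length: int
    gc_fraction: float
    tm_celsius: float
    self_any_score: float
    self_3prime_score: float


@dataclass
class MarkerCandidate:
    """A scored forward/reverse primer pair on one locus."""

    locus_id: str
    forward: Primer
    reverse: Primer
    product_length: int
    conservation_score: float | None
    pair_3prime_score: float

    @property
    def forward_window(self) -> tuple[int, int]:
        return (self.forward.start, self.forward.start + self.forward.length)

    @property
    def reverse_window(self) -> tuple[int, int]:
        return (self.reverse.start, self.reverse.start + self.reverse.length)


def _check_dna(seq: str) -> None:
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-DNA characters in primer sequence: {sorted(bad)}")


def _complementarity_scores(a: str, b: str) -> tuple[float, float]:
    """(any-offset score, 3'-anchored score) between oligos a and b.

    Offsets slide b (reversed, antiparallel) along a; each aligned position
    contributes +1 when Watson-Crick complementary, -1 otherwise; both
    scores are maxima over offsets, floored at 0. The anchored variant only
    admits offsets whose overlap includes a's 3' terminal base.
    """
    na, nb = len(a), len(b)
    x = np.frombuffer(a.encode("ascii"), dtype="S1")
    # a[i] pairs with b-reversed[i-o]; complementary iff a[i] == WC(brev[i-o])
    z = np.frombuffer(
        b[::-1].translate(str.maketrans("ACGT", "TGCA")).encode("ascii"), dtype="S1"
    )
    eq = np.zeros(na + nb - 1)
    for base in (b"A", b"C", b"G", b"T"):
        eq += np.correlate((x == base).astype(float), (z == base).astype(float), "full")
    offsets = np.arange(-(nb - 1), na)
    overlap = np.minimum(na, offsets + nb) - np.maximum(0, offsets)
    scores = 2.0 * eq - overlap
    best_any = max(0.0, float(scores.max()))
    anchored = scores[offsets + nb >= na]
    best_3p = max(0.0, float(anchored.max())) if anchored.size else 0.0
    return best_any, best_3p


def complementarity_score(a: str, b: str, anchor_3prime: bool = False) -> float:
    """Antiparallel ungapped complementarity score between two oligos.

    For every relative offset of b (reversed) against a, sum +1 for each
    Watson-Crick complementary pair and -1 otherwise over the overlap; the
    score is the maximum over offsets, floored at 0. With ``anchor_3prime``
    only offsets whose overlap includes a's 3' terminal base count. Self
    scores are obtained with b = a.
    """
    if not a or not b:
        raise ValueError("complementarity_score requires non-empty sequences")
    _check_dna(a)
    _check_dna(b)
    best_any, best_3p = _complementarity_scores(a, b)
    return best_3p if anchor_3prime else best_any


def melting_temperature(seq: str) -> float:
    """Closed-form Tm (Celsius): 64.9 + 41*(nGC - 16.4)/L. Reported, not filtered."""
    n_gc = seq.count("G") + seq.count("C")
    return 64.9 + 41.0 * (n_gc - 16.4) / len(seq)


def make_primer(seq: str, start: int) -> Primer:
    """Build a Primer record (computes GC, Tm and self scores; no filtering)."""
    _check_dna(seq)
    n_gc = seq.count("G") + seq.count("C")
    self_any, self_3p = _complementarity_scores(seq, seq)
    return Primer(
        sequence=seq,
        start=start,
        length=len(seq),
        gc_fraction=n_gc / len(seq),
        tm_celsius=melting_temperature(seq),
        self_any_score=self_any,
        self_3prime_score=self_3p,
    )


def primer_is_valid(p: Primer, c: PrimerConstraints) -> bool:
    return (
        c.min_len <= p.length <= c.max_len
        and c.gc_min <= p.gc_fraction <= c.gc_max
        and p.self_any_score < c.self_any_max
        and p.self_3prime_score < c.self_3prime_max
    )


def enumerate_primers(
    template: str,
    window: tuple[int, int] | None = None,
    constraints: PrimerConstraints | None = None,
) -> list[Primer]:
    """All valid primers whose start lies in ``window`` (default: whole template).

    Substrings containing N or gaps are skipped (no primer can be designed
    over ambiguity). Output is invariant to template case and to sequence
    outside the window except where a primer extends past the window end.
    """
    c = constraints or PrimerConstraints()
    template = template.upper()
    lo, hi = window if window is not None else (0, len(template))
    lo = max(0, lo)
    hi = min(hi, len(template))
    primers: list[Primer] = []
    for start in range(lo, hi):
        for length in range(c.min_len, c.max_len + 1):
            end = start + length
            if end > len(template):
                break
            sub = template[start:end]
            if any(ch not in "ACGT" for ch in sub):
                continue
            p = make_primer(sub, start)
            if primer_is_valid(p, c):
                primers.append(p)
    return primers


def conservation_score(
    pair_windows: tuple[tuple[int, int], tuple[int, int]],
    identity_profile: dict[int, bool],
) -> float | None:
    """Fraction of identical aligned columns over the union of primer windows.

    ``identity_profile`` maps template positions to whether the aligned
    column is identical between template and query (gap columns are False and
    template positions inside a query gap are absent). Returns None when any
    window position is not covered by the alignment (the pair is then demoted
    below all scored pairs).
    """
    positions: set[int] = set()
    for s, e in pair_windows:
        positions.update(range(s, e))
    if any(pos not in identity_profile for pos in positions):
        return None
    identical = sum(1 for pos in positions if identity_profile[pos])
    return identical / len(positions)


def design_pairs(
    locus: ExonRecord | str,
    hit: OrthologHit | None = None,
    constraints: PrimerConstraints | None = None,
    end_window: int | None = 200,
    max_pairs: int | None = 50,
) -> list[MarkerCandidate]:
    """Enumerate and rank primer pairs amplifying a 700-1200 bp product.

    Forward primers are drawn from the first ``end_window`` bp of the locus
    and reverse primers end within the last ``end_window`` bp (None searches
    the whole locus). Ranking: conservation score descending, then product
    length closest to the optimum, then leftmost forward start (further keys
    make the order total). Pairs whose 3'-anchored mutual complementarity
    reaches 3.00 are rejected. A locus shorter than the minimum product
    yields an empty list.
    """
    c = constraints or PrimerConstraints()
    if isinstance(locus, ExonRecord):
        template = locus.sequence
        locus_id = locus.exon_id
    else:
        template = locus.upper()
        locus_id = "locus"
    L = len(template)
    if L < c.product_min:
        logger.info("locus %s length %d < minimum product %d: no candidates",
                    locus_id, L, c.product_min)
        return []
    if end_window is None:
        fwd_window = (0, L)
        rev_window = (0, L)
    else:
        fwd_window = (0, min(end_window, L))
        rev_window = (max(0, L - end_window - c.max_len), L)
    from .align import revcomp

    forwards = enumerate_primers(template, fwd_window, c)
    # reverse primers are validated on the actual oligo (revcomp of the
    # template window): the 3'-anchored self score is not strand-symmetric
    reverses: list[Primer] = []
    for start in range(rev_window[0], rev_window[1]):
        for length in range(c.min_len, c.max_len + 1):
            end = start + length
            if end > L:
                break
            sub = template[start:end]
            if any(ch not in "ACGT" for ch in sub):
                continue
            rp = make_primer(revcomp(sub), start)
            if primer_is_valid(rp, c):
                reverses.append(rp)

    if not forwards or not reverses:
        return []
    identity_profile = hit.template_identity_profile() if hit is not None else None

    # vectorised pair generation: arrays over forwards x reverses, then a
    # lexsort by the ranking key; MarkerCandidate objects are materialised
    # lazily so the pair-complementarity filter only runs down the ranking
    fs = np.array([f.start for f in forwards])
    fl = np.array([f.length for f in forwards])
    rs = np.array([r.start for r in reverses])
    rl = np.array([r.length for r in reverses])
    fe, re_ = fs + fl, rs + rl

    product = re_[None, :] - fs[:, None]
    valid = (
        (product >= c.product_min)
        & (product <= c.product_max)
        & (rs[None, :] >= fe[:, None])  # windows must not overlap
    )
    if identity_profile is not None:
        ident = np.zeros(L)
        covered = np.zeros(L)
        for pos, m in identity_profile.items():
            if 0 <= pos < L:
                covered[pos] = 1.0
                ident[pos] = 1.0 if m else 0.0
        cum_ident = np.concatenate([[0.0], np.cumsum(ident)])
        cum_cov = np.concatenate([[0.0], np.cumsum(covered)])
        id_f = cum_ident[fe] - cum_ident[fs]
        id_r = cum_ident[re_] - cum_ident[rs]
        cov_full = ((cum_cov[fe] - cum_cov[fs]) == fl)[:, None] & (
            (cum_cov[re_] - cum_cov[rs]) == rl
        )[None, :]
        cons = (id_f[:, None] + id_r[None, :]) / (fl[:, None] + rl[None, :])
    else:
        cov_full = np.zeros_like(valid)
        cons = np.zeros(valid.shape)

    fi_all, ri_all = np.nonzero(valid)
    if fi_all.size == 0:
        return []
    demoted = ~cov_full[fi_all, ri_all]
    cons_v = np.where(demoted, 0.0, cons[fi_all, ri_all])
    prod_v = product[fi_all, ri_all]
    # np.lexsort sorts by the LAST key first
    order = np.lexsort(
        (
            rl[ri_all],
            rs[ri_all],
            fl[fi_all],
            fs[fi_all],
            np.abs(prod_v - c.product_optimum),
            -cons_v,
            demoted.astype(int),
        )
    )

    out: list[MarkerCandidate] = []
    for idx in order:
        fi, ri = int(fi_all[idx]), int(ri_all[idx])
        product_len = int(prod_v[idx])
        cons_val = None if demoted[idx] else float(cons_v[idx])
        f, r = forwards[fi], reverses[ri]
        pair_score = max(
            complementarity_score(f.sequence, r.sequence, anchor_3prime=True),
            complementarity_score(r.sequence, f.sequence, anchor_3prime=True),
        )
        if pair_score >= c.pair_3prime_max:
            continue
        out.append(
            MarkerCandidate(
                locus_id=locus_id,
                forward=f,
                reverse=r,
                product_length=product_len,
                conservation_score=cons_val,
                pair_3prime_score=pair_score,
            )
        )
        if max_pairs is not None and len(out) >= max_pairs:
            break
    return out


def pairs_table(pairs: list[MarkerCandidate]):
    """Primer report as a DataFrame, one row per candidate with every constraint value."""
    import pandas as pd

    columns = [
        "locus_id", "forward_seq", "forward_start", "forward_len", "forward_gc",
        "forward_tm", "forward_self_any", "forward_self_3p", "reverse_seq",
        "reverse_start", "reverse_len", "reverse_gc", "reverse_tm",
        "reverse_self_any", "reverse_self_3p", "product_length",
        "pair_3prime_score", "conservation_score",
    ]
    rows = []
    for cand in pairs:
        rows.append(
            {
                "locus_id": cand.locus_id,
                "forward_seq": cand.forward.sequence,
                "forward_start": cand.forward.start,
                "forward_len": cand.forward.length,
                "forward_gc": round(cand.forward.gc_fraction, 4),
                "forward_tm": round(cand.forward.tm_celsius, 2),
                "forward_self_any": cand.forward.self_any_score,
                "forward_self_3p": cand.forward.self_3prime_score,
                "reverse_seq": cand.reverse.sequence,
                "reverse_start": cand.reverse.start,
                "reverse_len": cand.reverse.length,
                "reverse_gc": round(cand.reverse.gc_fraction, 4),
                "reverse_tm": round(cand.reverse.tm_celsius, 2),
                "reverse_self_any": cand.reverse.self_any_score,
                "reverse_self_3p": cand.reverse.self_3prime_score,
                "product_length": cand.product_length,
                "pair_3prime_score": cand.pair_3prime_score,
                "conservation_score": (
                    round(cand.conservation_score, 6)
                    if cand.conservation_score is not None
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows, columns=columns)
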