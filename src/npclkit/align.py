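"""Seeded local alignment and the exon-mining / orthology-screening rules.

The aligner is a BLASTN-style heuristic: exact k-mer seeds on the subject
sequence are grouped into diagonal runs and extended in both directions by a
banded, affine-gap, X-drop dynamic program. A gap of length g costs
``gap_open + g * gap_extend`` (BLAST convention). The X-drop bound also
bounds the attainable diagonal drift, which is how the band half-width is
derived when not given explicitly.

Screening rules:

* exon candidates are single-copy exons longer than 600 bp mined from the
  annotated template genome;
* an exon survives the cross-genome orthology screen iff its best hit in the
  query genome has identity strictly above 80% and covers strictly more than
  50% of the template length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .io import AnnotationSet, SequenceSet

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")

NEG = -(1 << 30)


def revcomp(seq: str) -> str:
    """Reverse complement (N and gap characters map to themselves)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignParams:
    """Scoring and seeding parameters of the heuristic local aligner."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    k: int = 11
    xdrop: float = 20.0
    band: int | None = None
    max_candidates: int = 2000

    def band_halfwidth(self) -> int:
        if self.band is not None:
            return self.band
        # X-drop caps the scoring deficit, hence the reachable diagonal offset
        return int(self.xdrop / abs(self.gap_extend)) + 3


@dataclass
class OrthologHit:
    """A local-alignment match between a template exon and a subject sequence.

    ``columns`` records the alignment column-by-column as
    ``(template_pos, subject_pos, is_match)`` with ``None`` marking a gap, and
    template positions given on the sense strand of the template.
    """

    template_exon_id: str
    query_seq_id: str
    strand: str
    template_window: tuple[int, int]
    query_window: tuple[int, int]
    aligned_length: int
    matches: int
    identity: float
    template_coverage: float
    score: float
    columns: list[tuple[int | None, int | None, bool]] = field(default_factory=list, repr=False)

    def recompute_identity(self) -> float:
        """Identity recomputed from the stored alignment columns."""
        if not self.columns:
            return self.identity
        return sum(1 for _, _, m in self.columns if m) / len(self.columns)

    def template_identity_profile(self) -> dict[int, bool]:
        """Map template position -> aligned-column-is-identical, over the hit."""
        return {tp: m for tp, _, m in self.columns if tp is not None}


class KmerIndex:
    """Exact k-mer index of a subject sequence (kmers with N/- are skipped)."""

    def __init__(self, seq: str, k: int):
        self.seq = seq
        self.k = k
        table: dict[str, list[int]] = {}
        for j in range(len(seq) - k + 1):
            kmer = seq[j : j + k]
            if "N" in kmer or "-" in kmer:
                continue
            table.setdefault(kmer, []).append(j)
        self.table = table

    def lookup(self, kmer: str) -> list[int]:
        return self.table.get(kmer, ())


@dataclass
class _Extension:
    score: int
    a_used: int
    b_used: int
    ops: list[str]


def _xdrop_extend(a: str, b: str, p: AlignParams) -> _Extension:
    """Extend an alignment forward from (0, 0) between a and b.

    Banded affine DP with X-drop termination; returns the best-scoring
    extension endpoint and its operations ('M' match, 'X' mismatch,
    'I' gap in a, 'D' gap in b).
    """
    w = p.band_halfwidth()
    width = 2 * w + 1
    go = p.gap_open + p.gap_extend  # opening a gap column
    ge = p.gap_extend
    na, nb = len(a), len(b)

    H = [NEG] * width
    E = [NEG] * width
    F = [NEG] * width
    H[w] = 0
    ptrH_rows: list[list[int]] = [[-1] * width]
    ptrE_rows: list[list[int]] = [[-1] * width]
    ptrF_rows: list[list[int]] = [[-1] * width]
    # row 0: leading gaps in a (consume b) via E
    for d in range(w + 1, width):
        if d - w > nb:
            break
        open_score = H[d - 1] + go if H[d - 1] > NEG else NEG
        ext_score = E[d - 1] + ge if E[d - 1] > NEG else NEG
        if open_score >= ext_score:
            E[d], ptrE_rows[0][d] = open_score, 0
        else:
            E[d], ptrE_rows[0][d] = ext_score, 1
        if E[d] > NEG:
            H[d], ptrH_rows[0][d] = E[d], 1

    best = 0
    best_cell = (0, w)
    match, mismatch, xdrop = p.match, p.mismatch, p.xdrop

    for i in range(1, na + 1):
        Hp, Ep, Fp = H, E, F
        H = [NEG] * width
        E = [NEG] * width
        F = [NEG] * width
        ptrH = [-1] * width
        ptrE = [-1] * width
        ptrF = [-1] * width
        row_max = NEG
        ai = a[i - 1]
        for d in range(width):
            j = i + d - w
            if j < 0 or j > nb:
                continue
            # F: gap in b (consume a[i-1]); from row i-1, diagonal d+1
            if d + 1 < width:
                open_score = Hp[d + 1] + go if Hp[d + 1] > NEG else NEG
                ext_score = Fp[d + 1] + ge if Fp[d + 1] > NEG else NEG
                if open_score >= ext_score:
                    if open_score > NEG:
                        F[d], ptrF[d] = open_score, 0
                else:
                    F[d], ptrF[d] = ext_score, 1
            # E: gap in a (consume b[j-1]); same row, diagonal d-1
            if j >= 1 and d >= 1:
                open_score = H[d - 1] + go if H[d - 1] > NEG else NEG
                ext_score = E[d - 1] + ge if E[d - 1] > NEG else NEG
                if open_score >= ext_score:
                    if open_score > NEG:
                        E[d], ptrE[d] = open_score, 0
                else:
                    E[d], ptrE[d] = ext_score, 1
            # diagonal
            diag = NEG
            if j >= 1 and Hp[d] > NEG:
                diag = Hp[d] + (match if ai == b[j - 1] else mismatch)
            h, ptr = diag, 0
            if E[d] > h:
                h, ptr = E[d], 1
            if F[d] > h:
                h, ptr = F[d], 2
            if h > NEG:
                H[d], ptrH[d] = h, ptr
                if h > row_max:
                    row_max = h
                if h > best:
                    best = h
                    best_cell = (i, d)
        ptrH_rows.append(ptrH)
        ptrE_rows.append(ptrE)
        ptrF_rows.append(ptrF)
        if row_max < best - xdrop:
            break

    # traceback
    ops: list[str] = []
    i, d = best_cell
    state = "H"
    while not (i == 0 and d == w and state == "H"):
        if state == "H":
            ptr = ptrH_rows[i][d]
            if ptr == 0:
                j = i + d - w
                ops.append("M" if a[i - 1] == b[j - 1] else "X")
                i -= 1
            elif ptr == 1:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ptr = ptrE_rows[i][d]
            ops.append("I")
            d -= 1
            state = "H" if ptr == 0 else "E"
        else:
            ptr = ptrF_rows[i][d]
            ops.append("D")
            i -= 1
            d += 1
            state = "H" if ptr == 0 else "F"
    ops.reverse()
    bi, bd = best_cell
    return _Extension(score=best, a_used=bi, b_used=bi + bd - w, ops=ops)


def _seed_runs(tseq: str, index: KmerIndex, k: int) -> list[tuple[int, int, int]]:
    """Maximal exact diagonal runs (run_length, t_start, s_start) from seeds."""
    by_diag: dict[int, list[tuple[int, int]]] = {}
    for i in range(0, len(tseq) - k + 1):
        kmer = tseq[i : i + k]
        if "N" in kmer or "-" in kmer:
            continue
        for j in index.lookup(kmer):
            by_diag.setdefault(j - i, []).append((i, j))
    runs: list[tuple[int, int, int]] = []
    seq = index.seq
    for diag, seeds in by_diag.items():
        seeds.sort()
        covered_to = -1
        for i, j in seeds:
            if i < covered_to:
                continue
            # extend the exact run around the seed
            s, t = i, j
            while s > 0 and t > 0 and tseq[s - 1] == seq[t - 1] and tseq[s - 1] != "N":
                s -= 1
                t -= 1
            e_i, e_j = i + k, j + k
            while (
                e_i < len(tseq)
                and e_j < len(seq)
                and tseq[e_i] == seq[e_j]
                and tseq[e_i] != "N"
            ):
                e_i += 1
                e_j += 1
            runs.append((e_i - s, s, t))
            covered_to = e_i
    runs.sort(key=lambda r: (-r[0], r[1], r[2]))
    return runs


def _extend_run(
    tseq: str, sseq: str, t0: int, s0: int, p: AlignParams
) -> tuple[int, tuple[int, int], tuple[int, int], list[str]]:
    right = _xdrop_extend(tseq[t0:], sseq[s0:], p)
    left = _xdrop_extend(tseq[:t0][::-1], sseq[:s0][::-1], p)
    score = right.score + left.score
    t_win = (t0 - left.a_used, t0 + right.a_used)
    s_win = (s0 - left.b_used, s0 + right.b_used)
    ops = left.ops[::-1] + right.ops
    return score, t_win, s_win, ops


def local_align(
    template: str,
    subject: str,
    params: AlignParams | None = None,
    index: KmerIndex | None = None,
) -> list[OrthologHit]:
    """Heuristic local alignment of a template sequence against a subject.

    Both subject strands are scanned (the hit records which). Hits are
    k-mer-seeded gapped X-drop extensions, sorted by score descending;
    identity counts matching columns over all aligned columns, and coverage
    is the aligned template span over the template length. Sequences shorter
    than k yield an empty result.
    """
    p = params or AlignParams()
    if len(template) < p.k or len(subject) < p.k:
        return []
    if index is None:
        index = KmerIndex(subject, p.k)
    hits: list[OrthologHit] = []
    L = len(template)
    for strand in ("+", "-"):
        tseq = template if strand == "+" else revcomp(template)
        runs = _seed_runs(tseq, index, p.k)
        accepted: list[tuple[tuple[int, int], tuple[int, int]]] = []
        for run_len, t0, s0 in runs[: p.max_candidates]:
            anchor_covered = any(
                tw[0] <= t0 < tw[1] and sw[0] <= s0 < sw[1] for tw, sw in accepted
            )
            if anchor_covered:
                continue
            score, t_win, s_win, ops = _extend_run(tseq, subject, t0, s0, p)
            accepted.append((t_win, s_win))
            aligned_length = len(ops)
            if aligned_length < p.k:
                continue
            matches = ops.count("M")
            # column bookkeeping with template positions on the sense strand
            columns: list[tuple[int | None, int | None, bool]] = []
            ti, sj = t_win[0], s_win[0]
            for op in ops:
                if op in ("M", "X"):
                    sense = ti if strand == "+" else L - 1 - ti
                    columns.append((sense, sj, op == "M"))
                    ti += 1
                    sj += 1
                elif op == "I":
                    columns.append((None, sj, False))
                    sj += 1
                else:
                    sense = ti if strand == "+" else L - 1 - ti
                    columns.append((sense, None, False))
                    ti += 1
            span_t = t_win[1] - t_win[0]
            if strand == "+":
                template_window = t_win
            else:
                template_window = (L - t_win[1], L - t_win[0])
            hits.append(
                OrthologHit(
                    template_exon_id="",
                    query_seq_id="",
                    strand=strand,
                    template_window=template_window,
                    query_window=s_win,
                    aligned_length=aligned_length,
                    matches=matches,
                    identity=matches / aligned_length,
                    template_coverage=span_t / L,
                    score=score,
                    columns=columns,
                )
            )
    hits.sort(key=lambda h: (-h.score, h.query_window[0], h.template_window[0], h.strand))
    return hits


# ---------------------------------------------------------------------------
# exon mining and screening
# ---------------------------------------------------------------------------

@dataclass
class ExonRecord:
    """A candidate exon with genome coordinates and sense-strand sequence."""

    exon_id: str
    gene_id: str
    chromosome: str
    start0: int
    end0: int
    strand: str
    sequence: str
    single_copy: bool | None = None

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


class ExonSpanError(ValueError):
    pass


def mine_exons(
    genome: SequenceSet, annotation: AnnotationSet, min_len: int = 601
) -> list[ExonRecord]:
    """Extract annotated exons longer than 600 bp (i.e. length >= min_len).

    Sequences are strand-aware: minus-strand exons are reverse-complemented
    so every record carries the 5'->3' sense sequence.
    """
    contigs = dict(genome.records)
    exons: list[ExonRecord] = []
    for feat in annotation:
        if feat.seq_id not in contigs:
            raise ExonSpanError(f"exon {feat.exon_id}: contig {feat.seq_id!r} not in genome")
        contig = contigs[feat.seq_id]
        if feat.end0 > len(contig):
            raise ExonSpanError(
                f"exon {feat.exon_id}: span [{feat.start0}, {feat.end0}) exceeds "
                f"contig length {len(contig)}"
            )
        seq = contig[feat.start0 : feat.end0]
        if feat.strand == "-":
            seq = revcomp(seq)
        if len(seq) >= min_len:
            exons.append(
                ExonRecord(
                    exon_id=feat.exon_id,
                    gene_id=feat.gene_id,
                    chromosome=feat.seq_id,
                    start0=feat.start0,
                    end0=feat.end0,
                    strand=feat.strand,
                    sequence=seq,
                )
            )
    exons.sort(key=lambda e: (e.chromosome, e.start0, e.exon_id))
    return exons


def _windows_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def mark_single_copy(
    exons: list[ExonRecord],
    genome: SequenceSet,
    params: AlignParams | None = None,
    min_identity: float = 0.80,
    min_coverage: float = 0.50,
    indexes: dict[str, KmerIndex] | None = None,
) -> list[ExonRecord]:
    """Flag exons that have no second homologous copy in their own genome.

    An exon is single-copy iff every within-genome hit above the homology
    thresholds (identity > 0.80, template coverage > 0.50) overlaps its own
    locus; the self-hit is excluded by coordinate overlap on its chromosome.
    """
    p = params or AlignParams()
    if indexes is None:
        indexes = {cid: KmerIndex(seq, p.k) for cid, seq in genome.records}
    out: list[ExonRecord] = []
    for exon in exons:
        duplicated = False
        own_span = (exon.start0, exon.end0)
        for cid, seq in genome.records:
            for hit in local_align(exon.sequence, seq, p, index=indexes[cid]):
                if cid == exon.chromosome and _windows_overlap(hit.query_window, own_span):
                    continue  # self-hit
                if hit.identity > min_identity and hit.template_coverage > min_coverage:
                    duplicated = True
                    break
            if duplicated:
                break
        out.append(replace(exon, single_copy=not duplicated))
    return out


def passes_orthology(hit: OrthologHit, min_identity: float, min_coverage: float) -> bool:
    """Strict 'more than' thresholds: identity and coverage must exceed them."""
    return hit.identity > min_identity and hit.template_coverage > min_coverage


def screen_orthologs(
    exons: list[ExonRecord],
    query_genome: SequenceSet,
    min_identity: float = 0.80,
    min_coverage: float = 0.50,
    params: AlignParams | None = None,
) -> list[tuple[ExonRecord, OrthologHit]]:
    """Keep exons whose best query-genome hit passes the orthology filter.

    The best hit is the highest-scoring one, ties broken by lower query
    coordinate; only that hit is judged against the thresholds (strictly
    greater, per the 'more than 80% / more than 50%' rule).
    """
    p = params or AlignParams()
    indexes = {cid: KmerIndex(seq, p.k) for cid, seq in query_genome.records}
    retained: list[tuple[ExonRecord, OrthologHit]] = []
    for exon in exons:
        best: OrthologHit | None = None
        for cid, seq in query_genome.records:
            for hit in local_align(exon.sequence, seq, p, index=indexes[cid]):
                hit.template_exon_id = exon.exon_id
                hit.query_seq_id = cid
                if best is None or (hit.score, -hit.query_window[0]) > (
                    best.score,
                    -best.query_window[0],
                ):
                    best = hit
        if best is not None and passes_orthology(best, min_identity, min_coverage):
            retained.append((exon, best))
    return retained


def hits_table(pairs: list[tuple[ExonRecord, OrthologHit]]):
    """Ortholog-screen results as a DataFrame ready for TSV export."""
    import pandas as pd

    columns = [
        "exon_id", "query_id", "strand", "identity", "coverage", "score",
        "template_start", "template_end", "query_start", "query_end",
    ]
    rows = []
    for exon, hit in pairs:
        rows.append(
            {
                "exon_id": exon.exon_id,
                "query_id": hit.query_seq_id,
                "strand": hit.strand,
                "identity": round(hit.identity, 6),
                "coverage": round(hit.template_coverage, 6),
                "score": hit.score,
                "template_start": hit.template_window[0],
                "template_end": hit.template_window[1],
                "query_start": hit.query_window[0],
                "query_end": hit.query_window[1],
            }
        )
    return pd.DataFrame(rows, columns=columns)
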