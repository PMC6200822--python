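"""Synthetic inputs with planted truth for every pipeline stage.

Two generators:

* :func:`simulate_genome_pair` - an annotated template genome and a diverged
  query genome emulating a distant congeneric genome comparison. Ancestral
  exons are uniform random DNA separated by independent random introns; the
  query genome carries each surviving exon mutated by an independent
  per-site Jukes-Cantor substitution kernel at divergence d, with fresh
  random introns (so only exons align). Paralogs are diverged copies of
  chosen exons inserted elsewhere in the template genome; deletions remove
  whole loci from the query genome. A truth table records, per exon, the
  coordinates in both genomes, the single-copy flag, the orthology-survival
  flag and the realised divergence.

* :func:`simulate_coalescent_sample` - Hudson's neutral coalescent without
  recombination, time in units of 2N generations (coalescence rate C(k,2)),
  mutations Poisson with rate theta/2 per lineage per unit time under the
  infinite-sites model, mapped onto L distinct columns (an error if the
  mutation count exceeds L).

A single master seed spawns independent per-locus child streams so locus
subsets are reproducible in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import revcomp
from .io import AnnotationSet, Feature, SequenceSet
from .popgen import HaplotypeAlignment

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class GenomeSimConfig:
    """Study conditions for the genome-pair simulation.

    Defaults are the conditions the pipeline is evaluated under: 50 loci of
    800-1500 bp, 8% per-site divergence between the genomes, 5 planted
    paralog duplications and 5 loci deleted from the query genome.
    """

    n_exons: int = 50
    exon_len: tuple[int, int] = (800, 1500)
    divergence: float = 0.08
    n_paralogs: int = 5
    paralog_divergence: float = 0.05
    intron_len: tuple[int, int] = (200, 600)
    n_deletions: int | None = 5
    deletion_prob: float = 0.0
    minus_strand_prob: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for p, name in (
            (self.divergence, "divergence"),
            (self.paralog_divergence, "paralog_divergence"),
            (self.deletion_prob, "deletion_prob"),
            (self.minus_strand_prob, "minus_strand_prob"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for lo, hi, name in (
            (*self.exon_len, "exon_len"),
            (*self.intron_len, "intron_len"),
        ):
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid {name} range ({lo}, {hi})")
        if self.n_exons < 1:
            raise ValueError("n_exons must be positive")
        if self.n_deletions is not None and not 0 <= self.n_deletions <= self.n_exons:
            raise ValueError("n_deletions must be in [0, n_exons]")
        if self.n_paralogs < 0 or self.n_paralogs > self.n_exons:
            raise ValueError("n_paralogs must be in [0, n_exons]")


@dataclass
class SimulatedGenomePair:
    genome1: SequenceSet
    annotation: AnnotationSet
    genome2: SequenceSet
    truth: pd.DataFrame


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _jc_mutate(rng: np.random.Generator, seq: str, d: float) -> tuple[str, float]:
    """Substitute each site with probability d, uniformly to the 3 alternatives.

    Returns the mutated sequence and the realised per-site mismatch fraction.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1").copy()
    hit = rng.random(arr.size) < d
    idx = np.flatnonzero(hit)
    if idx.size:
        shift = rng.integers(1, 4, size=idx.size)
        codes = np.zeros(idx.size, dtype=np.int64)
        lookup = {b"A": 0, b"C": 1, b"G": 2, b"T": 3}
        for pos, i in enumerate(idx):
            codes[pos] = (lookup[arr[i].tobytes()] + shift[pos]) % 4
        arr[idx] = _BASES[codes]
    return arr.tobytes().decode("ascii"), idx.size / arr.size


def simulate_genome_pair(cfg: GenomeSimConfig) -> SimulatedGenomePair:
    """Simulate a template genome (FASTA + exon annotation), a diverged query
    genome, and the planted truth table. Byte-identical under a fixed seed.
    """
    cfg.validate()
    master = np.random.SeedSequence(cfg.seed)
    locus_seeds = master.spawn(cfg.n_exons)
    layout_rng = np.random.default_rng(master.spawn(1)[0])

    exon_lens = layout_rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1, size=cfg.n_exons)
    paralog_sources = set(
        layout_rng.choice(cfg.n_exons, size=cfg.n_paralogs, replace=False).tolist()
        if cfg.n_paralogs
        else []
    )
    if cfg.n_deletions is not None:
        deletable = [i for i in range(cfg.n_exons)]
        deleted = set(
            layout_rng.choice(deletable, size=cfg.n_deletions, replace=False).tolist()
            if cfg.n_deletions
            else []
        )
    else:
        deleted = {
            i for i in range(cfg.n_exons) if layout_rng.random() < cfg.deletion_prob
        }

    g1_parts: list[str] = []
    g2_parts: list[str] = []
    paralog_copies: list[str] = []
    features: list[Feature] = []
    truth_rows = []
    g1_pos = 0
    g2_pos = 0

    for i in range(cfg.n_exons):
        rng = np.random.default_rng(locus_seeds[i])
        intron1 = _random_dna(rng, int(rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1)))
        intron2 = _random_dna(rng, int(rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1)))
        exon = _random_dna(rng, int(exon_lens[i]))
        strand = "-" if rng.random() < cfg.minus_strand_prob else "+"

        g1_parts.append(intron1)
        g1_pos += len(intron1)
        start0, end0 = g1_pos, g1_pos + len(exon)
        # the genome carries the exon on the annotated strand
        g1_parts.append(exon if strand == "+" else revcomp(exon))
        g1_pos = end0
        features.append(
            Feature(
                seq_id="chr1",
                feature_type="exon",
                start0=start0,
                end0=end0,
                strand=strand,
                gene_id=f"gene{i:03d}",
                exon_id=f"exon{i:03d}",
            )
        )

        if i in paralog_sources:
            copy, _ = _jc_mutate(rng, exon, cfg.paralog_divergence)
            paralog_copies.append(copy)

        g2_start = g2_end = None
        realized_d = float("nan")
        if i not in deleted:
            mutated, realized_d = _jc_mutate(rng, exon, cfg.divergence)
            g2_parts.append(intron2)
            g2_pos += len(intron2)
            g2_start, g2_end = g2_pos, g2_pos + len(mutated)
            g2_parts.append(mutated)
            g2_pos = g2_end

        truth_rows.append(
            {
                "exon_id": f"exon{i:03d}",
                "gene_id": f"gene{i:03d}",
                "length": int(exon_lens[i]),
                "strand": strand,
                "g1_start": start0,
                "g1_end": end0,
                "g2_start": g2_start,
                "g2_end": g2_end,
                "is_long": int(exon_lens[i]) > 600,
                "single_copy": i not in paralog_sources,
                "deleted": i in deleted,
                "true_divergence": realized_d,
            }
        )

    tail_rng = np.random.default_rng(master.spawn(2)[1])
    g1_parts.append(_random_dna(tail_rng, int(tail_rng.integers(*cfg.intron_len))))
    g2_parts.append(_random_dna(tail_rng, int(tail_rng.integers(*cfg.intron_len))))

    chromosomes1 = [("chr1", "".join(g1_parts))]
    if paralog_copies:
        spacer_rng = np.random.default_rng(master.spawn(3)[2])
        chr2_parts = []
        for copy in paralog_copies:
            chr2_parts.append(_random_dna(spacer_rng, int(spacer_rng.integers(*cfg.intron_len))))
            chr2_parts.append(copy)
        chr2_parts.append(_random_dna(spacer_rng, int(spacer_rng.integers(*cfg.intron_len))))
        chromosomes1.append(("chr2", "".join(chr2_parts)))

    truth = pd.DataFrame(truth_rows)
    truth["survives_screen"] = (
        truth["is_long"].astype(bool)
        & truth["single_copy"].astype(bool)
        & ~truth["deleted"].astype(bool)
    )
    return SimulatedGenomePair(
        genome1=SequenceSet(records=chromosomes1),
        annotation=AnnotationSet(features=features),
        genome2=SequenceSet(records=[("q_chr1", "".join(g2_parts))]),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# coalescent sampler
# ---------------------------------------------------------------------------

@dataclass
class CoalescentConfig:
    n: int = 10
    theta: float = 5.0
    length: int = 1000
    n_loci: int = 1
    seed: int = 0
    locus_prefix: str = "locus"
    population_id: str = "pop1"

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError("sample size n must be >= 2")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.length < 1 or self.n_loci < 1:
            raise ValueError("length and n_loci must be positive")


class InfiniteSitesError(RuntimeError):
    """More mutations than available columns; increase the locus length."""


def _simulate_tree(rng: np.random.Generator, n: int) -> list[tuple[set[int], float]]:
    """Hudson coalescent: returns branches as (descendant leaf set, length)."""
    lineages: list[set[int]] = [{i} for i in range(n)]
    open_time = {i: 0.0 for i in range(n)}  # birth time of each current lineage
    branches: list[tuple[set[int], float]] = []
    ids = list(range(n))
    members = {i: {i} for i in range(n)}
    next_id = n
    t = 0.0
    while len(ids) > 1:
        k = len(ids)
        t += rng.exponential(2.0 / (k * (k - 1)))  # rate C(k,2), time in 2N units
        a, b = rng.choice(k, size=2, replace=False)
        ia, ib = ids[a], ids[b]
        for node in (ia, ib):
            branches.append((members[node], t - open_time[node]))
        merged = members[ia] | members[ib]
        members[next_id] = merged
        open_time[next_id] = t
        ids = [x for x in ids if x not in (ia, ib)] + [next_id]
        next_id += 1
    return branches


def simulate_coalescent_sample(cfg: CoalescentConfig) -> list[HaplotypeAlignment]:
    """Sample haplotype alignments from the neutral infinite-sites coalescent.

    Mutation count on each branch is Poisson(theta/2 * branch length);
    mutated sites are drawn without replacement from the locus columns, so S
    is exactly countable. E[S] = theta * a1(n).
    """
    cfg.validate()
    master = np.random.SeedSequence(cfg.seed)
    out: list[HaplotypeAlignment] = []
    for locus_idx, child in enumerate(master.spawn(cfg.n_loci)):
        rng = np.random.default_rng(child)
        branches = _simulate_tree(rng, cfg.n)
        n_mut = [int(rng.poisson(cfg.theta / 2.0 * length)) for _, length in branches]
        total = sum(n_mut)
        if total > cfg.length:
            raise InfiniteSitesError(
                f"{total} mutations exceed locus length {cfg.length}; increase length"
            )
        ancestral = rng.choice(_BASES, size=cfg.length)
        haplotypes = np.tile(ancestral, (cfg.n, 1))
        if total:
            sites = rng.choice(cfg.length, size=total, replace=False)
            cursor = 0
            for (carriers, _), m in zip(branches, n_mut):
                rows = sorted(carriers)
                for _ in range(m):
                    site = sites[cursor]
                    cursor += 1
                    old = ancestral[site]
                    alternatives = [b for b in _BASES if b != old]
                    new = alternatives[int(rng.integers(0, 3))]
                    haplotypes[rows, site] = new
        records = [
            (f"hap{h:03d}", haplotypes[h].tobytes().decode("ascii"))
            for h in range(cfg.n)
        ]
        out.append(
            HaplotypeAlignment(
                locus_id=f"{cfg.locus_prefix}{locus_idx:03d}",
                population_id=cfg.population_id,
                sequences=records,
            )
        )
    return out
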