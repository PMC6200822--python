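"""Per-locus genetic distances with bootstrap SE and cyt-b rate calibration.

The per-locus summary is the overall mean pairwise distance (mean over all
unordered sequence pairs) with a site-bootstrap standard error. Distances are
p-distance by default (uncorrected), with Jukes-Cantor (JC69) and Kimura
two-parameter (K2P) corrections selectable. Sites containing N or '-' are
pairwise-deleted.

A locus mutation rate is calibrated against cytochrome b: the ratio of the
locus distance to the cyt-b distance on the same taxa is multiplied by the
cyt-b reference rate of 0.01035 substitutions/site/My. All rates are
reported in substitutions per site per million years.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SequenceSet

logger = logging.getLogger(__name__)

MU_CYTB = 0.01035  # substitutions/site/My, cytochrome-b reference rate

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


class UndefinedDistanceError(ValueError):
    """Raised when a distance correction is undefined (saturation) or no sites compare."""


@dataclass
class DistanceSummary:
    locus_id: str
    model: str
    d_mean: float
    bootstrap_se: float
    n_taxa: int
    n_sites_used: int


@dataclass
class RateEstimate:
    locus_id: str
    ratio: float
    mu: float
    mu_se: float
    reference_rate: float = MU_CYTB


def _pair_counts(a: str, b: str) -> tuple[int, int, int]:
    """(comparable sites, transitions, transversions) after pairwise deletion."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    comparable = ts = tv = 0
    for x, y in zip(a, b):
        if x not in _VALID or y not in _VALID:
            continue
        comparable += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    return comparable, ts, tv


def _distance_from_counts(comparable: int, ts: int, tv: int, model: str) -> float:
    if comparable == 0:
        raise UndefinedDistanceError("zero comparable sites after pairwise deletion")
    p = (ts + tv) / comparable
    if model == "p":
        return p
    if model == "JC69":
        if p >= 0.75:
            raise UndefinedDistanceError(f"JC69 undefined for p = {p:.4f} >= 0.75")
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    if model == "K2P":
        P = ts / comparable
        Q = tv / comparable
        arg1 = 1.0 - 2.0 * P - Q
        arg2 = 1.0 - 2.0 * Q
        if arg1 <= 0.0 or arg2 <= 0.0:
            raise UndefinedDistanceError("K2P log argument <= 0 (saturation)")
        return -0.5 * math.log(arg1 * math.sqrt(arg2))
    raise ValueError(f"unknown model {model!r}; choose p, JC69 or K2P")


def pairwise_distance(a: str, b: str, model: str = "p") -> float:
    """Pairwise distance between two aligned sequences under the given model.

    p = mismatches/comparable sites; JC69 d = -(3/4) ln(1 - 4p/3);
    K2P d = -(1/2) ln((1-2P-Q) sqrt(1-2Q)) with transition/transversion
    proportions P and Q.
    """
    return _distance_from_counts(*_pair_counts(a, b), model)


def _encode(alignment: SequenceSet | list[tuple[str, str]]) -> tuple[list[str], np.ndarray]:
    records = alignment.records if isinstance(alignment, SequenceSet) else list(alignment)
    ids = [rid for rid, _ in records]
    lengths = {len(s) for _, s in records}
    if len(lengths) != 1:
        raise ValueError("alignment rows must have equal length")
    mat = np.frombuffer(
        "".join(seq for _, seq in records).encode("ascii"), dtype="S1"
    ).reshape(len(records), lengths.pop())
    return ids, mat


def overall_mean_distance(
    alignment: SequenceSet | list[tuple[str, str]],
    model: str = "p",
    bootstrap_reps: int = 1000,
    seed: int | None = None,
    locus_id: str = "locus",
    on_undefined: str = "error",
) -> DistanceSummary:
    """Overall mean pairwise distance with a site-bootstrap standard error.

    d_mean averages over all unordered pairs; the bootstrap resamples
    alignment columns with replacement and recomputes d_mean, the SE being
    the standard deviation over replicates (deterministic under a fixed
    seed). ``on_undefined='drop'`` drops pairs whose distance is undefined
    (with a warning) instead of raising.
    """
    ids, mat = _encode(alignment)
    n, L = mat.shape
    if n < 2:
        raise ValueError("overall mean distance requires at least 2 sequences")
    valid = np.isin(mat, [b"A", b"C", b"G", b"T"])
    purine = np.isin(mat, [b"A", b"G"])

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    both = np.empty((len(pairs), L), dtype=bool)
    ts = np.empty((len(pairs), L), dtype=bool)
    tv = np.empty((len(pairs), L), dtype=bool)
    for idx, (i, j) in enumerate(pairs):
        both[idx] = valid[i] & valid[j]
        diff = both[idx] & (mat[i] != mat[j])
        same_class = purine[i] == purine[j]
        ts[idx] = diff & same_class
        tv[idx] = diff & ~same_class

    def mean_over_pairs(weights: np.ndarray) -> float:
        comp = both @ weights
        n_ts = ts @ weights
        n_tv = tv @ weights
        dists = []
        for idx, (i, j) in enumerate(pairs):
            try:
                dists.append(
                    _distance_from_counts(int(comp[idx]), int(n_ts[idx]), int(n_tv[idx]), model)
                )
            except UndefinedDistanceError:
                if on_undefined == "drop":
                    logger.warning(
                        "%s: dropping pair (%s, %s) with undefined %s distance",
                        locus_id, ids[i], ids[j], model,
                    )
                    continue
                raise UndefinedDistanceError(
                    f"{locus_id}: undefined {model} distance for pair ({ids[i]}, {ids[j]})"
                )
        if not dists:
            raise UndefinedDistanceError(f"{locus_id}: all pairwise distances undefined")
        return float(np.mean(dists))

    ones = np.ones(L)
    d_mean = mean_over_pairs(ones)

    se = 0.0
    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        reps = np.empty(bootstrap_reps)
        for r in range(bootstrap_reps):
            cols = rng.integers(0, L, size=L)
            weights = np.bincount(cols, minlength=L).astype(float)
            reps[r] = mean_over_pairs(weights)
        se = float(np.std(reps, ddof=1))

    n_sites_used = int((valid.sum(axis=0) >= 2).sum())
    return DistanceSummary(
        locus_id=locus_id,
        model=model,
        d_mean=d_mean,
        bootstrap_se=se,
        n_taxa=n,
        n_sites_used=n_sites_used,
    )


def calibrate_rate(
    d_locus: DistanceSummary,
    d_cytb: DistanceSummary,
    mu_cytb: float = MU_CYTB,
) -> RateEstimate:
    """Calibrated locus mutation rate: mu = (d_locus / d_cytb) * mu_cytb.

    The SE of mu propagates the two bootstrap SEs through the ratio
    (first-order delta method).
    """
    if d_cytb.d_mean == 0:
        raise UndefinedDistanceError("calibration undefined: reference distance is zero")
    ratio = d_locus.d_mean / d_cytb.d_mean
    mu = ratio * mu_cytb
    if d_locus.d_mean > 0:
        rel = math.sqrt(
            (d_locus.bootstrap_se / d_locus.d_mean) ** 2
            + (d_cytb.bootstrap_se / d_cytb.d_mean) ** 2
        )
        mu_se = mu * rel
    else:
        mu_se = (d_locus.bootstrap_se / d_cytb.d_mean) * mu_cytb
    return RateEstimate(
        locus_id=d_locus.locus_id, ratio=ratio, mu=mu, mu_se=mu_se, reference_rate=mu_cytb
    )


def rank_rates(
    estimates: list[RateEstimate],
    references: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, dict[str, dict[str, int]]]:
    """Sort rate estimates ascending by mu (stable ties by locus_id).

    Returns the sorted table and, per reference rate, counts of loci that are
    slower, faster or tied.
    """
    ordered = sorted(estimates, key=lambda e: (e.mu, e.locus_id))
    table = pd.DataFrame(
        {
            "locus_id": [e.locus_id for e in ordered],
            "ratio": [e.ratio for e in ordered],
            "mu": [e.mu for e in ordered],
            "mu_se": [e.mu_se for e in ordered],
        }
    )
    comparisons: dict[str, dict[str, int]] = {}
    for name, ref_mu in (references or {}).items():
        comparisons[name] = {
            "slower": sum(1 for e in ordered if e.mu < ref_mu),
            "faster": sum(1 for e in ordered if e.mu > ref_mu),
            "tied": sum(1 for e in ordered if e.mu == ref_mu),
        }
    return table, comparisons
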