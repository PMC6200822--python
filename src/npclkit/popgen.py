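"""Intraspecific polymorphism statistics and neutrality tests.

Inputs are phased haplotype alignments (two haplotypes per diploid
individual for nuclear loci, one for mtDNA). Per locus and population the
module reports the number of segregating sites S, the number of distinct
haplotypes H, haplotype diversity Hd (Nei's n/(n-1) corrected expected
heterozygosity), the mean number of pairwise differences k_hat, and
nucleotide diversity pi = k_hat / L_used.

Neutrality tests:

* Tajima's D - the normalised difference between the pairwise (pi-based)
  and Watterson (S-based) estimators of theta, using the standard constants
  a1, a2, b1, b2, c1, c2, e1, e2 for sample size n. Undefined (NA) when
  S = 0.
* Multilocus HKA in the one-population + single-outgroup form: per locus,
  observed polymorphism S_i and divergence D_i are compared with their
  neutral expectations under fitted per-locus theta_i and a shared scaled
  divergence time T; the X2 goodness-of-fit statistic is referred to a
  chi-square with L - 1 degrees of freedom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

_VALID = frozenset("ACGT")


@dataclass
class HaplotypeAlignment:
    locus_id: str
    population_id: str
    sequences: list[tuple[str, str]]  # (haplotype id, sequence)
    haplotypes_per_individual: int = 2  # 1 for mtDNA

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("a haplotype alignment needs at least 2 sequences")
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("haplotypes must be aligned to equal length")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0][1])


@dataclass
class PopGenStats:
    locus_id: str
    population_id: str
    n: int
    S: int
    H: int
    Hd: float
    k_hat: float
    pi: float
    L_used: int
    tajima_D: float | None = None


@dataclass(frozen=True)
class TajimaComponents:
    """The Tajima (1989) normalising constants for sample size n."""

    n: int
    a1: float = field(init=False)
    a2: float = field(init=False)
    b1: float = field(init=False)
    b2: float = field(init=False)
    c1: float = field(init=False)
    c2: float = field(init=False)
    e1: float = field(init=False)
    e2: float = field(init=False)

    def __post_init__(self) -> None:
        n = self.n
        if n < 2:
            raise ValueError("Tajima constants require n >= 2")
        a1 = sum(1.0 / i for i in range(1, n))
        a2 = sum(1.0 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        for name, value in zip(
            ("a1", "a2", "b1", "b2", "c1", "c2", "e1", "e2"),
            (a1, a2, b1, b2, c1, c2, e1, e2),
        ):
            object.__setattr__(self, name, value)


def harmonic_a1(n: int) -> float:
    """Watterson's a1 = sum_{i=1}^{n-1} 1/i."""
    return sum(1.0 / i for i in range(1, n))


def harmonic_a2(n: int) -> float:
    return sum(1.0 / i**2 for i in range(1, n))


def _encode(haps: HaplotypeAlignment) -> np.ndarray:
    return np.frombuffer(
        "".join(seq for _, seq in haps.sequences).encode("ascii"), dtype="S1"
    ).reshape(haps.n, haps.length)


def summarize(haps: HaplotypeAlignment, compute_D: bool = True) -> PopGenStats:
    """Per-locus, per-population polymorphism summary.

    S counts columns with >= 2 distinct non-missing bases; H counts distinct
    haplotype sequences; Hd = n(1 - sum p_i^2)/(n-1) over haplotype
    frequencies; k_hat is the mean pairwise difference count under pairwise
    deletion; pi = k_hat / L_used with L_used the number of columns free of
    gaps and Ns in every haplotype.
    """
    mat = _encode(haps)
    n, L = mat.shape
    valid = np.isin(mat, [b"A", b"C", b"G", b"T"])

    S = 0
    for col in range(L):
        bases = set(mat[valid[:, col], col].tolist())
        if len(bases) >= 2:
            S += 1

    seqs = [seq for _, seq in haps.sequences]
    counts: dict[str, int] = {}
    for s in seqs:
        counts[s] = counts.get(s, 0) + 1
    H = len(counts)
    freqs = np.array(list(counts.values())) / n
    Hd = 0.0 if H == 1 else n * (1.0 - float(np.sum(freqs**2))) / (n - 1)

    total_diff = 0
    n_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            total_diff += int(((mat[i] != mat[j]) & both).sum())
            n_pairs += 1
    k_hat = total_diff / n_pairs

    L_used = int(valid.all(axis=0).sum())
    pi = k_hat / L_used if L_used else float("nan")

    stats_out = PopGenStats(
        locus_id=haps.locus_id,
        population_id=haps.population_id,
        n=n,
        S=S,
        H=H,
        Hd=Hd,
        k_hat=k_hat,
        pi=pi,
        L_used=L_used,
    )
    if compute_D:
        stats_out.tajima_D = tajimas_D(stats_out, n) if S >= 1 and n >= 4 else None
    return stats_out


def tajimas_D(stats_in: PopGenStats | tuple[int, float], n: int) -> float:
    """Tajima's D = (k_hat - S/a1) / sqrt(e1*S + e2*S*(S-1)).

    Undefined for S = 0 (the caller reports NA, as for a monomorphic locus).
    """
    if isinstance(stats_in, PopGenStats):
        S, k_hat = stats_in.S, stats_in.k_hat
    else:
        S, k_hat = stats_in
    if S < 1:
        raise ValueError("Tajima's D undefined for S = 0")
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    t = TajimaComponents(n)
    var = t.e1 * S + t.e2 * S * (S - 1)
    return (k_hat - S / t.a1) / math.sqrt(var)


_IUPAC_HET = {"R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC"}


def expand_iupac_haplotypes(
    records: list[tuple[str, str]], seed: int = 0
) -> list[tuple[str, str]]:
    """Approximate phasing for unphased diploid consensus sequences.

    Each input sequence with two-allele IUPAC heterozygote codes (R, Y, S,
    W, K, M) is expanded into two haplotypes, assigning the two alleles to
    the haplotypes at random (fixed seed). This does NOT recover real phase:
    linkage between heterozygous sites is randomised, so haplotype-based
    statistics (H, Hd) are approximate; site-based ones (S, pi) are not
    affected. Other characters pass through; unknown codes become N.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[str, str]] = []
    for rid, seq in records:
        h1: list[str] = []
        h2: list[str] = []
        for ch in seq.upper():
            if ch in _IUPAC_HET:
                a, b = _IUPAC_HET[ch]
                if rng.random() < 0.5:
                    a, b = b, a
                h1.append(a)
                h2.append(b)
            elif ch in "ACGTN-":
                h1.append(ch)
                h2.append(ch)
            else:
                h1.append("N")
                h2.append("N")
        out.append((f"{rid}_1", "".join(h1)))
        out.append((f"{rid}_2", "".join(h2)))
    return out


# ---------------------------------------------------------------------------
# multilocus HKA
# ---------------------------------------------------------------------------

@dataclass
class HKALocus:
    """Observed inputs for one locus: polymorphism and outgroup divergence.

    ``S`` segregating sites in a sample of ``n`` haplotypes over ``L_poly``
    sites; ``D`` the mean number of differences to a single outgroup sequence
    over ``L_div`` sites.
    """

    locus_id: str
    S: int
    n: int
    D: float
    L_poly: int
    L_div: int


@dataclass
class HKAResult:
    loci: list[str]
    thetas: list[float]  # per-site theta_i
    T: float
    X2: float
    df: int
    p_value: float
    expected_S: list[float]
    expected_D: list[float]


def _hka_x2(params: np.ndarray, loci: list[HKALocus]) -> float:
    *thetas, T = params
    x2 = 0.0
    for theta, loc in zip(thetas, loci):
        a1 = harmonic_a1(loc.n)
        a2 = harmonic_a2(loc.n)
        tL_poly = theta * loc.L_poly
        tL_div = theta * loc.L_div
        depth = (loc.n + 1) / (2.0 * loc.n)
        ES = tL_poly * a1
        VS = ES + tL_poly**2 * a2
        ED = tL_div * (T + depth)
        VD = ED + (tL_div * depth) ** 2
        if VS <= 0 or VD <= 0:
            return float("inf")
        x2 += (loc.S - ES) ** 2 / VS + (loc.D - ED) ** 2 / VD
    return x2


def hka_test(loci: list[HKALocus]) -> HKAResult:
    """Multilocus HKA goodness-of-fit test (one population + outgroup form).

    Expectations per locus i under neutrality:
    E[S_i] = theta_i a1(n_i) L_poly,  Var[S_i] = E[S_i] + (theta_i L_poly)^2 a2(n_i);
    E[D_i] = theta_i L_div (T + (n_i+1)/(2 n_i)),
    Var[D_i] = E[D_i] + (theta_i L_div (n_i+1)/(2 n_i))^2.
    The per-locus thetas and the shared scaled divergence time T are fitted
    by numerical minimisation of the X2 sum; the p-value refers X2 to a
    chi-square with 2L - (L + 1) = L - 1 degrees of freedom.
    """
    L = len(loci)
    if L < 2:
        raise ValueError("HKA requires at least 2 loci (df = L - 1 would be 0)")

    theta0 = []
    for loc in loci:
        a1 = harmonic_a1(loc.n)
        theta0.append(max(loc.S / (a1 * loc.L_poly), 1e-8))
    denom = sum(t * loc.L_div for t, loc in zip(theta0, loci))
    depth_bar = float(np.mean([(loc.n + 1) / (2.0 * loc.n) for loc in loci]))
    T0 = max(sum(loc.D for loc in loci) / denom - depth_bar, 1e-6) if denom > 0 else 1.0

    x0 = np.array(theta0 + [T0])
    bounds = [(1e-10, None)] * L + [(0.0, None)]
    best = None
    for scale in (1.0, 0.5, 2.0):
        res = optimize.minimize(
            _hka_x2,
            x0 * scale,
            args=(loci,),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    res = optimize.minimize(
        _hka_x2, best.x, args=(loci,), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
    )
    if res.fun > best.fun:
        res = best
    if not np.isfinite(res.fun):
        raise RuntimeError(f"HKA minimisation failed to converge: {res}")

    *thetas, T = [float(v) for v in res.x]
    exp_S, exp_D = [], []
    for theta, loc in zip(thetas, loci):
        a1 = harmonic_a1(loc.n)
        depth = (loc.n + 1) / (2.0 * loc.n)
        exp_S.append(theta * loc.L_poly * a1)
        exp_D.append(theta * loc.L_div * (T + depth))
    df = 2 * L - (L + 1)
    x2 = float(res.fun)
    return HKAResult(
        loci=[loc.locus_id for loc in loci],
        thetas=thetas,
        T=T,
        X2=x2,
        df=df,
        p_value=float(stats.chi2.sf(x2, df)),
        expected_S=exp_S,
        expected_D=exp_D,
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def per_population_report(dataset: list[HaplotypeAlignment]) -> pd.DataFrame:
    """One row per locus x population with S, H, Hd, pi (x10^-3 column too)
    and Tajima's D; plus a pooled row per locus across populations.
    """
    rows = []
    by_locus: dict[str, list[HaplotypeAlignment]] = {}
    for haps in dataset:
        by_locus.setdefault(haps.locus_id, []).append(haps)
        rows.append(summarize(haps))
    for locus_id, groups in by_locus.items():
        pooled_seqs = []
        for haps in groups:
            pooled_seqs.extend(
                (f"{haps.population_id}:{hid}", seq) for hid, seq in haps.sequences
            )
        pooled = HaplotypeAlignment(
            locus_id=locus_id,
            population_id="pooled",
            sequences=pooled_seqs,
            haplotypes_per_individual=groups[0].haplotypes_per_individual,
        )
        rows.append(summarize(pooled))
    frame = pd.DataFrame(
        {
            "locus": [r.locus_id for r in rows],
            "population": [r.population_id for r in rows],
            "n": [r.n for r in rows],
            "S": [r.S for r in rows],
            "H": [r.H for r in rows],
            "Hd": [round(r.Hd, 6) for r in rows],
            "k_hat": [round(r.k_hat, 6) for r in rows],
            "pi": [round(r.pi, 8) for r in rows],
            "pi_x1000": [round(r.pi * 1e3, 6) for r in rows],
            "tajima_D": [
                round(r.tajima_D, 6) if r.tajima_D is not None else np.nan for r in rows
            ],
        }
    )
    return frame.sort_values(["locus", "population"], kind="stable").reset_index(drop=True)
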