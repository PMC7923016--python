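"""Population-genetic statistics for two-population breed comparisons.

Contents, in pipeline order:

* allele / genotype frequency estimation (exact rationals from counts);
* Hardy–Weinberg tests — Pearson chi-square for any number of alleles and
  the full-enumeration conditional exact test for two alleles;
* the two-population, multi-allele, multi-locus Weir & Cockerham (1984)
  theta estimator of Fst, returned with its a/b/c variance components so the
  computation can be audited allele by allele;
* the exact test of genic differentiation on an alleles x populations table
  with fixed margins, evaluated by complete enumeration when the table space
  is small and otherwise by a Metropolis Markov chain over tables (the
  GENEPOP-style "exact G test", with dememorisation / batches / iterations
  controlling the chain and a batch-mean standard error on the estimate);
* Fisher's method for combining per-locus p-values;
* classical (Torgerson) metric MDS on Euclidean distances between
  allele-frequency vectors.

Notes on the Weir–Cockerham estimator
-------------------------------------
For each allele at each locus, with ``r`` populations of sizes ``n_i``,
allele frequencies ``p_i`` and observed frequencies ``h_i`` of heterozygotes
carrying the allele::

    nbar = mean(n)                      nc = (r*nbar - sum(n^2)/(r*nbar))/(r-1)
    pbar = sum(n*p)/(r*nbar)            s2 = sum(n*(p-pbar)^2)/((r-1)*nbar)
    hbar = sum(n*h)/(r*nbar)

    a = nbar/nc * (s2 - (pbar*(1-pbar) - s2*(r-1)/r - hbar/4)/(nbar-1))
    b = nbar/(nbar-1) * (pbar*(1-pbar) - s2*(r-1)/r - hbar*(2*nbar-1)/(4*nbar))
    c = hbar/2

and the multi-locus estimate is ``sum(a) / sum(a+b+c)`` over all alleles and
loci.  A locus monomorphic in both populations contributes (0, 0, 0).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

from .model import (
    AlleleFrequencyTable,
    Genotype,
    GenotypeCountTable,
    Locus,
    ValidationError,
)

__all__ = [
    "allele_frequencies",
    "genotype_frequencies",
    "HWEResult",
    "hwe_test",
    "FstResult",
    "wc_fst_pair",
    "MarkovChainConfig",
    "GTestPValue",
    "exact_g_test",
    "combine_pvalues_fisher",
    "DifferentiationResult",
    "differentiation_pair",
    "MDSResult",
    "classical_mds",
]

#: float tolerance used when comparing table probabilities for "as extreme"
_TIE_TOL = 1e-12


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------

def allele_frequencies(counts: GenotypeCountTable, locus: Locus | str) -> dict[str, Fraction]:
    """Allele frequencies ``count / (2 n)`` as exact rationals (sum to 1)."""
    locus_name = locus.name if isinstance(locus, Locus) else locus
    n = counts.n_animals(locus_name)
    if n < 1:
        raise ValidationError(f"{counts.name}/{locus_name}: no typed animals")
    allele_counts = counts.allele_counts(locus_name)
    return {a: Fraction(c, 2 * n) for a, c in allele_counts.items()}


def genotype_frequencies(counts: GenotypeCountTable, locus: Locus | str) -> dict[Genotype, Fraction]:
    """Genotype frequencies ``count / n`` as exact rationals (sum to 1)."""
    locus_name = locus.name if isinstance(locus, Locus) else locus
    n = counts.n_animals(locus_name)
    if n < 1:
        raise ValidationError(f"{counts.name}/{locus_name}: no typed animals")
    return {gt: Fraction(c, n) for gt, c in counts.counts[locus_name].items()}


# ---------------------------------------------------------------------------
# Hardy–Weinberg
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HWEResult:
    method: str  # "chi_square" | "exact"
    statistic: Optional[float]
    df: int
    p_value: float
    degenerate: bool = False  # monomorphic locus


def _hwe_chi_square(counts: GenotypeCountTable, locus_name: str) -> HWEResult:
    n = counts.n_animals(locus_name)
    alleles = counts.observed_alleles(locus_name)
    k = len(alleles)
    freqs = {a: f for a, f in allele_frequencies(counts, locus_name).items()}
    observed = counts.counts[locus_name]
    stat = 0.0
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            if a == b:
                expected = float(freqs[a] * freqs[a]) * n
            else:
                expected = 2.0 * float(freqs[a]) * float(freqs[b]) * n
            obs = observed.get(Genotype(locus_name, a, b), 0)
            stat += (obs - expected) ** 2 / expected
    df = k * (k - 1) // 2
    return HWEResult("chi_square", stat, df, float(chi2.sf(stat, df)))


def _hwe_exact_biallelic(counts: GenotypeCountTable, locus_name: str) -> HWEResult:
    """Conditional exact test: enumerate heterozygote counts given allele counts.

    P(n_ab = h | n, n_a) = n! / (n_aa! h! n_bb!) * 2^h * n_a! n_b! / (2n)!
    with the p-value summing probabilities <= that of the observed table.
    """
    alleles = counts.observed_alleles(locus_name)
    if len(alleles) != 2:
        raise ValidationError(
            f"exact HWE test implemented for 2 alleles, locus {locus_name} has "
            f"{len(alleles)}"
        )
    n = counts.n_animals(locus_name)
    allele_counts = counts.allele_counts(locus_name)
    na = allele_counts[alleles[0]]
    nb = allele_counts[alleles[1]]
    obs_het = counts.heterozygote_count(locus_name, alleles[0])

    const = (
        gammaln(n + 1) + gammaln(na + 1) + gammaln(nb + 1) - gammaln(2 * n + 1)
    )

    def log_prob(h: int) -> float:
        naa = (na - h) // 2
        nbb = (nb - h) // 2
        return float(
            const
            + h * math.log(2)
            - gammaln(naa + 1)
            - gammaln(h + 1)
            - gammaln(nbb + 1)
        )

    support = range(na % 2, min(na, nb) + 1, 2)
    lp_obs = log_prob(obs_het)
    p = sum(math.exp(lp) for h in support if (lp := log_prob(h)) <= lp_obs + _TIE_TOL)
    return HWEResult("exact", None, 0, min(p, 1.0))


def hwe_test(
    counts: GenotypeCountTable, locus: Locus | str, method: str = "chi_square"
) -> HWEResult:
    """Test genotype counts at one locus against Hardy–Weinberg proportions.

    ``method`` is ``"chi_square"`` (any allele number, no continuity
    correction, no pooling) or ``"exact"`` (biallelic full enumeration).
    A monomorphic locus returns a degenerate result with ``p = 1``.
    """
    locus_name = locus.name if isinstance(locus, Locus) else locus
    if counts.n_animals(locus_name) < 1:
        raise ValidationError(f"{counts.name}/{locus_name}: no typed animals")
    if len(counts.observed_alleles(locus_name)) < 2:
        return HWEResult(method, 0.0 if method == "chi_square" else None, 0, 1.0,
                         degenerate=True)
    if method == "chi_square":
        return _hwe_chi_square(counts, locus_name)
    if method == "exact":
        return _hwe_exact_biallelic(counts, locus_name)
    raise ValueError(f"unknown HWE method {method!r}")


# ---------------------------------------------------------------------------
# Weir–Cockerham Fst
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FstResult:
    """Pairwise theta with per-locus, per-allele variance components."""

    #: locus -> list of (allele, a, b, c)
    per_locus: dict[str, list[tuple[str, float, float, float]]]
    per_locus_theta: dict[str, Optional[float]]
    multi_locus_theta: float


def _wc_components(
    n: Sequence[float], p: Sequence[float], h: Sequence[float]
) -> tuple[float, float, float]:
    n = np.asarray(n, float)
    p = np.asarray(p, float)
    h = np.asarray(h, float)
    r = len(n)
    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return float(a), float(b), float(c)


def wc_fst_pair(
    sample_a: GenotypeCountTable,
    sample_b: GenotypeCountTable,
    loci: Optional[Sequence[Locus | str]] = None,
) -> FstResult:
    """Two-population Weir–Cockerham theta over the given loci.

    Loci monomorphic in both populations (or untyped in either) contribute
    zero components; if every locus is uninformative the estimate is
    undefined and a :class:`ValidationError` is raised.
    """
    if loci is None:
        loci = sample_a.loci
    locus_names = [l.name if isinstance(l, Locus) else l for l in loci]
    per_locus: dict[str, list[tuple[str, float, float, float]]] = {}
    per_locus_theta: dict[str, Optional[float]] = {}
    total_a = total_abc = 0.0
    for locus_name in locus_names:
        n1 = sample_a.n_animals(locus_name)
        n2 = sample_b.n_animals(locus_name)
        components: list[tuple[str, float, float, float]] = []
        if n1 == 0 or n2 == 0:
            per_locus[locus_name] = components
            per_locus_theta[locus_name] = None
            continue
        ac1 = sample_a.allele_counts(locus_name)
        ac2 = sample_b.allele_counts(locus_name)
        alleles = sorted(set(ac1) | set(ac2))
        if len(alleles) < 2:
            per_locus[locus_name] = [(alleles[0], 0.0, 0.0, 0.0)] if alleles else []
            per_locus_theta[locus_name] = None
            continue
        locus_a = locus_abc = 0.0
        for allele in alleles:
            p = (ac1.get(allele, 0) / (2 * n1), ac2.get(allele, 0) / (2 * n2))
            h = (
                sample_a.heterozygote_count(locus_name, allele) / n1,
                sample_b.heterozygote_count(locus_name, allele) / n2,
            )
            a, b, c = _wc_components((n1, n2), p, h)
            components.append((allele, a, b, c))
            locus_a += a
            locus_abc += a + b + c
        per_locus[locus_name] = components
        per_locus_theta[locus_name] = locus_a / locus_abc if locus_abc else None
        total_a += locus_a
        total_abc += locus_abc
    if total_abc == 0.0:
        raise ValidationError("theta undefined: no informative locus")
    return FstResult(per_locus, per_locus_theta, total_a / total_abc)


# ---------------------------------------------------------------------------
# exact test of genic differentiation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkovChainConfig:
    """Metropolis chain settings (GENEPOP-style defaults)."""

    dememorisation: int = 10_000
    batches: int = 100
    iterations_per_batch: int = 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dememorisation", "batches", "iterations_per_batch"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass(frozen=True)
class GTestPValue:
    p: Optional[float]
    se: Optional[float]  # None for exact enumeration (zero error)
    exact: bool
    informative: bool
    n_tables: Optional[int] = None  # enumeration only

    @property
    def standard_error(self) -> float:
        return 0.0 if self.exact else (self.se or 0.0)


def _table_margins(
    allele_counts_a: Mapping[str, int], allele_counts_b: Mapping[str, int]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    alleles = sorted(
        a
        for a in set(allele_counts_a) | set(allele_counts_b)
        if allele_counts_a.get(a, 0) + allele_counts_b.get(a, 0) > 0
    )
    row0 = np.array([allele_counts_a.get(a, 0) for a in alleles], dtype=np.int64)
    row1 = np.array([allele_counts_b.get(a, 0) for a in alleles], dtype=np.int64)
    return alleles, row0, row1


def _log_table_prob_const(r: np.ndarray, c: np.ndarray) -> float:
    N = int(r.sum())
    return float(gammaln(r + 1).sum() + gammaln(c + 1).sum() - gammaln(N + 1))


def _enumerate_exact(row0: np.ndarray, row1: np.ndarray) -> tuple[float, int]:
    """Complete enumeration of 2 x k tables with fixed margins.

    Returns (p, number of tables).  p sums the probabilities of all tables
    whose conditional probability is <= the observed one (tolerance 1e-12 on
    log-probabilities).
    """
    c = row0 + row1
    r = np.array([row0.sum(), row1.sum()])
    const = _log_table_prob_const(r, c)
    k = len(c)

    def logp(x: np.ndarray) -> float:
        return float(const - gammaln(x + 1).sum() - gammaln(c - x + 1).sum())

    lp_obs = logp(row0)
    suffix = np.concatenate([np.cumsum(c[::-1])[::-1][1:], [0]])
    total = 0.0
    count = 0
    x = np.zeros(k, dtype=np.int64)

    def rec(j: int, rem: int) -> None:
        nonlocal total, count
        if j == k - 1:
            if 0 <= rem <= c[j]:
                x[j] = rem
                count += 1
                lp = logp(x)
                if lp <= lp_obs + _TIE_TOL:
                    total += math.exp(lp)
            return
        lo = max(0, rem - int(suffix[j]))
        hi = min(int(c[j]), rem)
        for v in range(lo, hi + 1):
            x[j] = v
            rec(j + 1, rem - v)

    rec(0, int(r[0]))
    return min(total, 1.0), count


def _enumeration_size(row0: np.ndarray, row1: np.ndarray) -> float:
    c = row0 + row1
    r0 = int(row0.sum())
    size = 1.0
    for cj in c[:-1]:
        size *= min(int(cj), r0) + 1
        if size > 1e12:
            break
    return size


def _mc_exact(
    row0: np.ndarray, row1: np.ndarray, config: MarkovChainConfig
) -> tuple[float, float]:
    """Metropolis chain over 2 x k tables with fixed margins.

    Moves add +/-1 to a random 2x2 sub-table; acceptance uses the closed-form
    probability ratio, so no factorials are evaluated inside the loop.  The
    p-value is the chain-average of the indicator {P(table) <= P(observed)};
    its standard error is the batch-mean standard error.
    """
    rng = np.random.default_rng(config.seed)
    c = (row0 + row1).astype(np.int64)
    r = np.array([row0.sum(), row1.sum()], dtype=np.int64)
    const = _log_table_prob_const(r, c)
    k = len(c)

    def logp(x: np.ndarray) -> float:
        return float(const - gammaln(x + 1).sum() - gammaln(c - x + 1).sum())

    lp_obs = logp(row0)
    x = row0.copy()
    lp = lp_obs

    n_steps = config.dememorisation + config.batches * config.iterations_per_batch
    # pre-draw randomness in blocks for speed
    pair_j = rng.integers(0, k, size=n_steps)
    pair_l = rng.integers(0, k - 1, size=n_steps)
    pair_l = np.where(pair_l >= pair_j, pair_l + 1, pair_l)
    logu = np.log(rng.random(size=n_steps))

    def step(i: int, x: np.ndarray, lp: float) -> float:
        j = pair_j[i]
        l = pair_l[i]
        # move one allele from column l to column j in row 0 (and back in row 1)
        if x[l] < 1 or x[j] >= c[j]:
            return lp
        ratio = (x[l] * (c[j] - x[j])) / ((x[j] + 1) * (c[l] - x[l] + 1))
        log_ratio = math.log(ratio)
        if logu[i] < log_ratio:
            x[j] += 1
            x[l] -= 1
            return lp + log_ratio
        return lp

    for i in range(config.dememorisation):
        lp = step(i, x, lp)

    batch_means = np.empty(config.batches)
    i = config.dememorisation
    for b in range(config.batches):
        lp = logp(x)  # resynchronise against float drift once per batch
        hits = 0
        for _ in range(config.iterations_per_batch):
            lp = step(i, x, lp)
            i += 1
            if lp <= lp_obs + _TIE_TOL:
                hits += 1
        batch_means[b] = hits / config.iterations_per_batch
    p = float(batch_means.mean())
    se = float(batch_means.std(ddof=1) / math.sqrt(config.batches))
    return p, se


def exact_g_test(
    allele_counts_a: Mapping[str, int],
    allele_counts_b: Mapping[str, int],
    config: Optional[MarkovChainConfig] = None,
    method: str = "auto",
    enumeration_cap: int = 200_000,
) -> GTestPValue:
    """Exact test of genic differentiation between two populations.

    The null distribution conditions on the allele-count margins of the
    2 x k contingency table; the p-value is the total probability of tables
    as or less probable than the observed one.  ``method`` is ``"auto"``
    (enumerate when the table space is below ``enumeration_cap``, otherwise
    Markov chain), ``"enumeration"`` or ``"mc"``.  A locus monomorphic across
    both populations is uninformative (no p-value).
    """
    alleles, row0, row1 = _table_margins(allele_counts_a, allele_counts_b)
    if len(alleles) < 2:
        return GTestPValue(None, None, exact=True, informative=False)
    if method not in ("auto", "enumeration", "mc"):
        raise ValueError(f"unknown method {method!r}")
    if method == "enumeration" or (
        method == "auto" and _enumeration_size(row0, row1) <= enumeration_cap
    ):
        p, n_tables = _enumerate_exact(row0, row1)
        return GTestPValue(p, None, exact=True, informative=True, n_tables=n_tables)
    if config is None:
        raise ValidationError("Markov-chain method requires a MarkovChainConfig (with seed)")
    p, se = _mc_exact(row0, row1, config)
    return GTestPValue(p, se, exact=False, informative=True)


def combine_pvalues_fisher(p_list: Sequence[float]) -> float:
    """Fisher's method: -2 sum(ln p) ~ chi-square with 2k df.

    A single p-value is returned unchanged.
    """
    if not p_list:
        raise ValidationError("cannot combine an empty p-value list")
    for p in p_list:
        if not (0.0 < p <= 1.0):
            raise ValidationError(f"p-value {p} outside (0, 1]")
    if len(p_list) == 1:
        return float(p_list[0])
    stat = -2.0 * sum(math.log(p) for p in p_list)
    return float(chi2.sf(stat, 2 * len(p_list)))


@dataclass(frozen=True)
class DifferentiationResult:
    """Pairwise Fst plus per-locus and combined exact-test p-values."""

    pair: tuple[str, str]
    fst: FstResult
    g_per_locus: dict[str, GTestPValue]
    combined_p: Optional[float]
    chain_config: Optional[MarkovChainConfig]


def differentiation_pair(
    sample_a: GenotypeCountTable,
    sample_b: GenotypeCountTable,
    loci: Optional[Sequence[Locus | str]] = None,
    config: Optional[MarkovChainConfig] = None,
    method: str = "auto",
) -> DifferentiationResult:
    """Fst and exact genic-differentiation tests for one population pair.

    The combined p-value applies Fisher's method over informative loci only.
    """
    if loci is None:
        loci = sample_a.loci
    locus_names = [l.name if isinstance(l, Locus) else l for l in loci]
    fst = wc_fst_pair(sample_a, sample_b, locus_names)
    g_results: dict[str, GTestPValue] = {}
    informative_ps: list[float] = []
    for locus_name in locus_names:
        res = exact_g_test(
            dict(sample_a.allele_counts(locus_name)),
            dict(sample_b.allele_counts(locus_name)),
            config=config,
            method=method,
        )
        g_results[locus_name] = res
        if res.informative and res.p is not None:
            informative_ps.append(max(res.p, 1e-300))
    combined = combine_pvalues_fisher(informative_ps) if informative_ps else None
    return DifferentiationResult(
        (sample_a.name, sample_b.name), fst, g_results, combined, config
    )


# ---------------------------------------------------------------------------
# classical MDS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MDSResult:
    populations: tuple[str, ...]
    coordinates: dict[str, tuple[float, ...]]
    eigenvalues: tuple[float, ...]  # all eigenvalues, descending
    distance_matrix: np.ndarray
    explained_inertia: float  # share of positive inertia in the kept axes


def classical_mds(
    freq_table: AlleleFrequencyTable,
    dims: int = 2,
    loci: Optional[Sequence[str]] = None,
) -> MDSResult:
    """Torgerson metric MDS of populations from allele-frequency vectors.

    Euclidean distances between concatenated per-locus frequency vectors
    (absent allele = 0) are double-centred and eigendecomposed; coordinates
    are the top-``dims`` eigenvectors scaled by the square root of their
    eigenvalues.  Sign convention: within each axis the coordinate of largest
    absolute value is made positive.
    """
    breeds = freq_table.breeds()
    if len(breeds) < 2:
        raise ValidationError("classical MDS needs at least 2 populations")
    if loci is None:
        loci = freq_table.loci()
    allele_order: dict[str, tuple[str, ...]] = {}
    for locus in loci:
        symbols: list[str] = []
        for breed in breeds:
            for allele in freq_table.entries[breed].get(locus, ({}, 0))[0]:
                if allele not in symbols:
                    symbols.append(allele)
        allele_order[locus] = tuple(sorted(symbols))
    X = np.array([freq_table.frequency_vector(b, loci, allele_order) for b in breeds])
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2))
    n = len(breeds)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    tol = max(1e-12, 1e-9 * max(abs(eigval[0]), 1.0))
    n_pos = int((eigval > tol).sum())
    kept = min(dims, n_pos)
    if kept < dims:
        warnings.warn(
            f"requested {dims} MDS components but only {n_pos} positive "
            f"eigenvalues; truncating"
        )
    coords = np.zeros((n, max(kept, 1)))
    for j in range(kept):
        axis = eigvec[:, j] * math.sqrt(eigval[j])
        if axis[np.argmax(np.abs(axis))] < 0:
            axis = -axis
        coords[:, j] = axis
    pos_inertia = float(eigval[eigval > tol].sum())
    explained = float(eigval[:kept].sum() / pos_inertia) if pos_inertia else 1.0
    return MDSResult(
        populations=tuple(breeds),
        coordinates={b: tuple(coords[i]) for i, b in enumerate(breeds)},
        eigenvalues=tuple(float(v) for v in eigval),
        distance_matrix=D,
        explained_inertia=explained,
    )
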