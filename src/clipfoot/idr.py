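"""Reproducibility of scored peak sets via the Gaussian copula mixture IDR.

Workflow: peaks from two replicates are matched one-to-one by overlap
(:func:`match_peaks`); matched score pairs are rank-transformed and fitted
with a two-component Gaussian copula mixture (:func:`fit_idr`) — a null
component (independent standard bivariate normal) for irreproducible peaks
and a correlated signal component N((mu1, mu1), sigma1^2, rho1) for
reproducible ones.  The posterior null probability per pair is the local
idr; the cumulative mean of ascending local idr is the global IDR used for
thresholding.

On top of the two-replicate fit, ENCODE-style quality ratios are computed:
the rescue ratio compares peak counts passing IDR between the true
replicate pair and a pooled-then-pseudo-split pair, and the self-consistency
ratio compares the two replicates' own pseudo-replicate splits.  Both
ratios below 2 is the conventional acceptability bar; here a pair is
acceptable when either ratio is < 2 (strict inequality).

Pseudo-replicates are built by binomial thinning of integer peak support
counts — the peak-level analogue of read splitting.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata

from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "MatchedPeakPairs",
    "IDRModelParams",
    "IDRResult",
    "ReproReport",
    "GroupReproSummary",
    "match_peaks",
    "fit_idr",
    "count_passing",
    "pseudoreplicates",
    "ratios_from_counts",
    "reproducibility_report",
    "pairwise_group_reproducibility",
]

MIN_PAIRS = 50          # below this the mixture fit is refused as unstable
_EPS_P = 1e-4           # mixing-weight constraint box
_MAX_RHO = 0.999
_MIN_SIGMA = 1e-3
_MIN_MU = 1e-3
# Identifiability floor: on rank-transformed data the two components are
# distinguished only through the signal correlation, so a fitted rho1 at or
# below this value means the "reproducible" component is vacuous and every
# pair is reported irreproducible.
RHO_FLOOR = 0.05


@dataclass
class MatchedPeakPairs:
    """One-to-one matched peaks across two replicates, with provenance."""

    regions: list[GenomicInterval]
    scores1: np.ndarray
    scores2: np.ndarray
    idx1: list[int]              # index of source peak in replicate 1
    idx2: list[int]
    unmatched1: list[int] = field(default_factory=list)
    unmatched2: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.regions)


@dataclass
class IDRModelParams:
    pi1: float
    mu1: float
    sigma1: float
    rho1: float
    n_iter: int
    converged: bool


@dataclass
class IDRResult:
    params: IDRModelParams
    local_idr: np.ndarray        # posterior null probability per pair
    global_idr: np.ndarray       # cumulative mean of sorted local idr
    threshold: float | None = None
    signal_vacuous: bool = False  # fitted signal carries no correlation

    def __len__(self) -> int:
        return len(self.local_idr)


@dataclass
class ReproReport:
    """ENCODE-style reproducibility ratios for one replicate pair.

    ``n_t``: peaks passing IDR between the true replicates; ``n_p``: between
    the pooled pseudo-replicates; ``n_1``/``n_2``: between each replicate's
    own pseudo-replicate halves.  rescue = max(n_p, n_t)/min(n_p, n_t);
    self-consistency = max(n_1, n_2)/min(n_1, n_2); acceptable iff either
    ratio is strictly below 2.
    """

    pair_id: str
    n_t: int | None
    n_p: int | None
    n_1: int | None
    n_2: int | None
    rescue_ratio: float | None
    self_consistency_ratio: float | None
    acceptable: bool
    failures: dict[str, str] = field(default_factory=dict)


@dataclass
class GroupReproSummary:
    reports: dict[tuple[str, str], ReproReport]
    flagged: list[str]


# ---------------------------------------------------------------------------
# peak matching
# ---------------------------------------------------------------------------

def match_peaks(rep1: IntervalSet, rep2: IntervalSet,
                min_overlap: int = 1) -> MatchedPeakPairs:
    """Greedy one-to-one matching of overlapping peaks.

    Candidate pairs overlap by at least ``min_overlap`` nt; they are taken
    greedily in order of descending combined score (sum of the two peak
    scores), each peak used at most once.  The matched region is the union
    span of the two peaks.  Unmatched peak indices are reported per side.
    Requires both inputs to be scored.
    """
    for rep, tag in ((rep1, "rep1"), (rep2, "rep2")):
        if any(iv.score is None for iv in rep):
            raise ValueError(f"{tag} contains unscored peaks")

    by2: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for j, iv in enumerate(rep2):
        by2.setdefault(iv.chrom, []).append((j, iv))
    for lst in by2.values():
        lst.sort(key=lambda t: (t[1].start, t[1].end))

    candidates: list[tuple[float, int, int, int]] = []  # (-combined, ov, i, j)
    for i, a in enumerate(rep1):
        for j, b in by2.get(a.chrom, []):
            if b.start >= a.end:
                break
            ov = a.overlap(b)
            if ov >= min_overlap:
                candidates.append((-(a.score + b.score), -ov, i, j))
    candidates.sort()

    used1: set[int] = set()
    used2: set[int] = set()
    regions, s1, s2, idx1, idx2 = [], [], [], [], []
    for _, _, i, j in candidates:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        a, b = rep1[i], rep2[j]
        regions.append(GenomicInterval(
            a.chrom, min(a.start, b.start), max(a.end, b.end)))
        s1.append(a.score)
        s2.append(b.score)
        idx1.append(i)
        idx2.append(j)
    order = sorted(range(len(regions)),
                   key=lambda k: (regions[k].chrom, regions[k].start,
                                  regions[k].end))
    return MatchedPeakPairs(
        regions=[regions[k] for k in order],
        scores1=np.array([s1[k] for k in order], dtype=float),
        scores2=np.array([s2[k] for k in order], dtype=float),
        idx1=[idx1[k] for k in order],
        idx2=[idx2[k] for k in order],
        unmatched1=[i for i in range(len(rep1)) if i not in used1],
        unmatched2=[j for j in range(len(rep2)) if j not in used2],
    )


# ---------------------------------------------------------------------------
# copula mixture fit
# ---------------------------------------------------------------------------

def _log_bvn(z1: np.ndarray, z2: np.ndarray,
             mu: float, sigma: float, rho: float) -> np.ndarray:
    """Log density of the equicorrelated bivariate normal."""
    a = (z1 - mu) / sigma
    b = (z2 - mu) / sigma
    om = 1.0 - rho * rho
    return (-np.log(2 * np.pi) - 2 * np.log(sigma) - 0.5 * np.log(om)
            - (a * a - 2 * rho * a * b + b * b) / (2 * om))


def _pseudo_values(u: np.ndarray, pi1: float, mu: float,
                   sigma: float) -> np.ndarray:
    """Invert the mixture marginal CDF G on a monotone grid."""
    lo = min(-8.0, mu - 8.0 * sigma)
    hi = max(8.0, mu + 8.0 * sigma)
    grid = np.linspace(lo, hi, 4096)
    G = pi1 * norm.cdf((grid - mu) / sigma) + (1 - pi1) * norm.cdf(grid)
    # G is strictly increasing; np.interp inverts it on the grid
    return np.interp(u, G, grid)


def fit_idr(pairs: MatchedPeakPairs, tol: float = 1e-4,
            max_iter: int = 100) -> IDRResult:
    """Fit the two-component Gaussian copula mixture to matched score pairs.

    Scores are reduced to ranks per replicate (midranks on ties), mapped to
    uniforms with the n/(n+1) ECDF correction, and converted to pseudo-data
    by inverting the current mixture marginal CDF; pseudo-data are refreshed
    each outer iteration around an inner EM loop.  The fit is deterministic:
    initialization is fixed at (pi1, mu1, sigma1, rho1) = (0.5, 1, 1, 0.5).
    Estimates are clipped to their constraint boxes (pi1 in (0,1), mu1 > 0,
    sigma1 > 0, rho1 in [0, 0.999]); hitting a box edge is legitimate for
    degenerate inputs (e.g. duplicated replicates drive rho1 to the upper
    bound).

    When the fitted signal correlation collapses to (numerical) zero, the
    components are indistinguishable on rank data — the copula mixture is
    identified only through the signal dependence — so the reproducible
    component is declared vacuous: every pair gets local idr 1 and the
    result is flagged ``signal_vacuous``.

    Refuses inputs with fewer than 50 pairs — the mixture estimate is
    unstable below that.
    """
    n = len(pairs)
    if n < MIN_PAIRS:
        raise ValueError(
            f"need at least {MIN_PAIRS} matched pairs for a stable IDR fit, "
            f"got {n}")
    u1 = rankdata(pairs.scores1) / (n + 1)
    u2 = rankdata(pairs.scores2) / (n + 1)

    def posteriors(z1, z2, p, mu, sigma, rho):
        log_h1 = _log_bvn(z1, z2, mu, sigma, rho)
        log_h0 = _log_bvn(z1, z2, 0.0, 1.0, 0.0)
        a1 = log_h1 + np.log(p)
        a0 = log_h0 + np.log1p(-p)
        m = np.maximum(a1, a0)
        w1 = np.exp(a1 - m)
        w0 = np.exp(a0 - m)
        loglik = float((m + np.log(w1 + w0)).sum())
        return w1 / (w1 + w0), w0 / (w1 + w0), loglik

    p, mu, sigma, rho = 0.5, 1.0, 1.0, 0.5
    converged = False
    n_outer = 0
    for n_outer in range(1, max_iter + 1):
        z1 = _pseudo_values(u1, p, mu, sigma)
        z2 = _pseudo_values(u2, p, mu, sigma)
        outer_prev = (p, mu, sigma, rho)
        for _ in range(50):                       # inner EM on fixed pseudo-data
            prev = (p, mu, sigma, rho)
            K, _, _ = posteriors(z1, z2, p, mu, sigma, rho)
            sk = K.sum()
            p = float(np.clip(sk / n, _EPS_P, 1 - _EPS_P))
            if sk > 0:
                mu = float(max((K * (z1 + z2)).sum() / (2 * sk), _MIN_MU))
                var = float((K * ((z1 - mu) ** 2 + (z2 - mu) ** 2)).sum()
                            / (2 * sk))
                sigma = float(max(np.sqrt(max(var, 0.0)), _MIN_SIGMA))
                rho = float(np.clip(
                    (K * (z1 - mu) * (z2 - mu)).sum() / (sk * sigma ** 2),
                    0.0, _MAX_RHO))
            if max(abs(p - prev[0]), abs(mu - prev[1]),
                   abs(sigma - prev[2]), abs(rho - prev[3])) < tol:
                break
        # stability across a pseudo-data refresh = outer convergence; the
        # self-consistent scheme can crawl, in which case the capped result
        # is returned with converged=False
        if max(abs(p - outer_prev[0]), abs(mu - outer_prev[1]),
               abs(sigma - outer_prev[2]), abs(rho - outer_prev[3])) < tol:
            converged = True
            break

    z1 = _pseudo_values(u1, p, mu, sigma)
    z2 = _pseudo_values(u2, p, mu, sigma)
    _, local_idr, _ = posteriors(z1, z2, p, mu, sigma, rho)

    vacuous = rho <= RHO_FLOOR
    if vacuous:
        local_idr = np.ones(n)

    order = np.argsort(local_idr, kind="stable")
    cum = np.cumsum(local_idr[order]) / np.arange(1, n + 1)
    global_idr = np.empty(n)
    global_idr[order] = cum

    params = IDRModelParams(pi1=p, mu1=mu, sigma1=sigma, rho1=rho,
                            n_iter=n_outer, converged=converged)
    return IDRResult(params=params, local_idr=local_idr,
                     global_idr=global_idr, signal_vacuous=vacuous)


def count_passing(result: IDRResult, threshold: float = 0.05) -> int:
    """Number of matched pairs with global IDR at or below ``threshold``."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    return int((result.global_idr <= threshold).sum())


# ---------------------------------------------------------------------------
# pseudo-replicates and ratios
# ---------------------------------------------------------------------------

def pseudoreplicates(peaks: IntervalSet,
                     seed: int | np.random.Generator = 0
                     ) -> tuple[IntervalSet, IntervalSet]:
    """Split each peak's support count Binomial(count, 1/2) into two halves.

    Peaks landing on zero support in a half are dropped from that half; the
    total support is conserved across the two halves.  Scores in the halves
    are the half counts.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    h1: list[GenomicInterval] = []
    h2: list[GenomicInterval] = []
    from dataclasses import replace
    for iv in peaks:
        if iv.count is None:
            raise ValueError(
                f"peak {iv.name or f'{iv.chrom}:{iv.start}'} has no support "
                "count; pseudo-replicates need integer counts")
        c1 = int(rng.binomial(iv.count, 0.5))
        c2 = iv.count - c1
        if c1 > 0:
            h1.append(replace(iv, score=float(c1), count=c1))
        if c2 > 0:
            h2.append(replace(iv, score=float(c2), count=c2))
    sid = peaks.sample_id or "peaks"
    return (IntervalSet(h1, sample_id=f"{sid}_pr1", condition=peaks.condition),
            IntervalSet(h2, sample_id=f"{sid}_pr2", condition=peaks.condition))


def ratios_from_counts(n_t: int | None, n_p: int | None,
                       n_1: int | None, n_2: int | None
                       ) -> tuple[float | None, float | None, bool]:
    """(rescue, self-consistency, acceptable) from the four N-counts.

    rescue = max(n_p, n_t)/min(n_p, n_t); self-consistency likewise for
    (n_1, n_2); a ratio is None when either count is missing and infinite
    when the smaller count is zero.  Acceptable iff both ratios could be
    computed and either is strictly below 2 — a ratio of exactly 2 fails,
    and a pair whose sub-analyses failed is conservatively unacceptable.
    """
    def ratio(x: int | None, y: int | None) -> float | None:
        if x is None or y is None:
            return None
        if min(x, y) == 0:
            return float("inf")
        return max(x, y) / min(x, y)

    rescue = ratio(n_p, n_t)
    selfc = ratio(n_1, n_2)
    acceptable = (rescue is not None and selfc is not None
                  and (rescue < 2.0 or selfc < 2.0))
    return rescue, selfc, acceptable


def _pool(rep1: IntervalSet, rep2: IntervalSet) -> IntervalSet:
    """Pool two replicates: merged regions carrying summed support counts."""
    from .intervals import merge
    union = IntervalSet(list(rep1) + list(rep2))
    pooled = merge(union)
    out = []
    by_chrom = union.by_chrom()
    for region in pooled:
        total = sum(iv.count or 0 for iv in by_chrom.get(region.chrom, [])
                    if iv.overlap(region) > 0)
        out.append(GenomicInterval(region.chrom, region.start, region.end,
                                   region.strand, score=float(total),
                                   count=total))
    return IntervalSet(out, sample_id="pooled")


def _n_passing(repA: IntervalSet, repB: IntervalSet, threshold: float,
               min_overlap: int) -> int:
    pairs = match_peaks(repA, repB, min_overlap=min_overlap)
    res = fit_idr(pairs)
    return count_passing(res, threshold)


def reproducibility_report(rep1: IntervalSet, rep2: IntervalSet,
                           seed: int = 0, threshold: float = 0.05,
                           min_overlap: int = 1) -> ReproReport:
    """Rescue and self-consistency ratios for one replicate pair.

    Four IDR analyses are run: the true pair (-> n_t), the pooled peaks
    split into two pseudo-replicates (-> n_p), and each replicate split
    against itself (-> n_1, n_2).  A sub-analysis that cannot produce a fit
    (too few matched pairs) is recorded in ``failures`` and makes the pair
    unacceptable.
    """
    pair_id = f"{rep1.sample_id or 'rep1'}__vs__{rep2.sample_id or 'rep2'}"
    ns: dict[str, int | None] = {}
    failures: dict[str, str] = {}

    def attempt(tag: str, fn):
        try:
            ns[tag] = fn()
        except ValueError as exc:
            ns[tag] = None
            failures[tag] = str(exc)

    attempt("n_t", lambda: _n_passing(rep1, rep2, threshold, min_overlap))
    pooled = _pool(rep1, rep2)
    p1, p2 = pseudoreplicates(pooled, np.random.default_rng([seed, 1]))
    attempt("n_p", lambda: _n_passing(p1, p2, threshold, min_overlap))
    a1, a2 = pseudoreplicates(rep1, np.random.default_rng([seed, 2]))
    attempt("n_1", lambda: _n_passing(a1, a2, threshold, min_overlap))
    b1, b2 = pseudoreplicates(rep2, np.random.default_rng([seed, 3]))
    attempt("n_2", lambda: _n_passing(b1, b2, threshold, min_overlap))

    rescue, selfc, acceptable = ratios_from_counts(
        ns["n_t"], ns["n_p"], ns["n_1"], ns["n_2"])
    return ReproReport(pair_id=pair_id, n_t=ns["n_t"], n_p=ns["n_p"],
                       n_1=ns["n_1"], n_2=ns["n_2"], rescue_ratio=rescue,
                       self_consistency_ratio=selfc, acceptable=acceptable,
                       failures=failures)


def pairwise_group_reproducibility(group: list[IntervalSet],
                                   seed: int = 0, threshold: float = 0.05,
                                   min_overlap: int = 1) -> GroupReproSummary:
    """All within-group pairwise reproducibility reports plus outlier flags.

    The pairwise IDR machinery only compares two replicates at a time, so a
    group of n yields C(n, 2) reports.  A sample is flagged as "of concern"
    when more than half of the pairs it participates in are unacceptable.
    """
    if len(group) < 2:
        raise ValueError("need at least 2 replicates in a group")
    names = [rep.sample_id or f"rep{i + 1}" for i, rep in enumerate(group)]
    reports: dict[tuple[str, str], ReproReport] = {}
    fail_count = {name: 0 for name in names}
    pair_count = {name: 0 for name in names}
    for (i, a), (j, b) in itertools.combinations(enumerate(group), 2):
        rep = reproducibility_report(
            a, b, seed=int(np.random.default_rng([seed, i, j])
                           .integers(2 ** 31)),
            threshold=threshold, min_overlap=min_overlap)
        reports[(names[i], names[j])] = rep
        for name in (names[i], names[j]):
            pair_count[name] += 1
            if not rep.acceptable:
                fail_count[name] += 1
    flagged = [name for name in names
               if fail_count[name] > pair_count[name] / 2]
    return GroupReproSummary(reports=reports, flagged=flagged)
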