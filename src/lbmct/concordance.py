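"""Agreement statistics for paired response classifications and LBM methods.

Covers the comparison pipeline between two PERCIST read-outs (3x3
contingency table, Cohen's kappa, Wilcoxon signed-rank on the ordinal
codes, threshold-band discordance analysis) and between two continuous
LBM estimates (paired t test, Bland-Altman limits of agreement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import DegenerateInputError, DomainError
from .percist import ResponseClass

RESPONSE_ORDER = (ResponseClass.PMD, ResponseClass.SMD, ResponseClass.PMR)
_LABELS = tuple(c.name for c in RESPONSE_ORDER)


# --- contingency table and kappa -------------------------------------------


@dataclass(frozen=True)
class ContingencyTable3:
    """3x3 cross-classification, rows/cols ordered (PMD, SMD, PMR)."""

    counts: np.ndarray
    row_method: str = "A"
    col_method: str = "B"
    row_labels: tuple[str, ...] = _LABELS
    col_labels: tuple[str, ...] = _LABELS

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (3, 3) or (counts < 0).any():
            raise DomainError("counts must be a 3x3 array of non-negative integers")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_margins(self) -> tuple[int, ...]:
        return tuple(int(v) for v in self.counts.sum(axis=1))

    @property
    def col_margins(self) -> tuple[int, ...]:
        return tuple(int(v) for v in self.counts.sum(axis=0))

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    @property
    def discordant_n(self) -> int:
        return self.total - self.trace

    @property
    def discordant_pct(self) -> float:
        return 100.0 * self.discordant_n / self.total if self.total else float("nan")


def build_contingency(
    pairs: Iterable[tuple[ResponseClass, ResponseClass]],
    row_method: str = "A",
    col_method: str = "B",
) -> ContingencyTable3:
    """Count (classA, classB) pairs into a 3x3 table."""
    counts = np.zeros((3, 3), dtype=int)
    index = {c: i for i, c in enumerate(RESPONSE_ORDER)}
    n = 0
    for a, b in pairs:
        counts[index[ResponseClass(a)], index[ResponseClass(b)]] += 1
        n += 1
    if n == 0:
        raise DomainError("no pairs given")
    return ContingencyTable3(counts, row_method=row_method, col_method=col_method)


def cohens_kappa(table: ContingencyTable3 | np.ndarray, weights: Optional[str] = None) -> float:
    """Cohen's kappa, unweighted by default.

    kappa = (Po - Pe) / (1 - Pe) with Po the observed agreement (trace /
    total) and Pe the chance agreement from the margins.  ``weights`` may
    be "linear" or "quadratic" for weighted kappa.  Returns NaN with a
    warning when Pe = 1 (all mass in a single cell).
    """
    counts = table.counts if isinstance(table, ContingencyTable3) else np.asarray(table, dtype=float)
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise DomainError("empty table")
    k = counts.shape[0]
    if weights is None:
        w = 1.0 - np.eye(k)
    elif weights == "linear":
        i, j = np.indices((k, k))
        w = np.abs(i - j) / (k - 1)
    elif weights == "quadratic":
        i, j = np.indices((k, k))
        w = ((i - j) / (k - 1)) ** 2
    else:
        raise DomainError(f"unknown weights {weights!r}")
    p = counts / total
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    expected = np.outer(row, col)
    do = (w * p).sum()  # observed disagreement
    de = (w * expected).sum()  # chance disagreement
    if de == 0:
        warnings.warn("chance agreement is 1 (single-cell table); kappa undefined", stacklevel=2)
        return float("nan")
    return float(1.0 - do / de)


# --- Wilcoxon signed-rank on ordinal codes ---------------------------------


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ (sum of ranks of positive differences)
    z: Optional[float]
    p: float
    n_used: int
    n_zero: int
    zero_policy: str
    mode: str
    alternative: str
    note: str = ""


def _signed_rank_exact_p(ranks2: np.ndarray, w2_obs: int, alternative: str) -> float:
    """Exact signed-rank p by dynamic programming over the 2^m sign patterns.

    ``ranks2`` are doubled (mid)ranks so tied ranks stay integral; the pmf of
    the doubled statistic is built by convolution in O(m * sum(ranks2)).
    """
    total = int(ranks2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = pmf + shifted
    pmf /= pmf.sum()
    p_ge = float(pmf[w2_obs:].sum())
    p_le = float(pmf[: w2_obs + 1].sum())
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


def wilcoxon_ordinal(
    pairs: Sequence[tuple[int, int]],
    zero_policy: str = "discard",
    mode: str = "normal",
    alternative: str = "two-sided",
) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired ordinal codes (PMD=1<SMD=2<PMR=3).

    Differences are ``codeB - codeA``.  ``zero_policy``: "discard" drops
    zero differences before ranking (default); "pratt" ranks them and drops
    their contribution from the statistic.  ``mode``: "normal" uses the
    tie-corrected normal approximation without continuity correction;
    "exact" enumerates the sign-flip distribution (n <= 25).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise DomainError("pairs must be a non-empty (n, 2) sequence")
    if zero_policy not in ("discard", "pratt"):
        raise DomainError(f"unknown zero_policy {zero_policy!r}")
    if alternative not in ("two-sided", "greater", "less"):
        raise DomainError(f"unknown alternative {alternative!r}")
    d = arr[:, 1] - arr[:, 0]
    n_zero = int((d == 0).sum())

    if zero_policy == "discard":
        d_used = d[d != 0]
        if d_used.size == 0:
            return WilcoxonResult(0.0, None, 1.0, 0, n_zero, zero_policy, mode, alternative,
                                  note="all differences zero; no evidence of a shift")
        ranks = stats.rankdata(np.abs(d_used))
        w_plus = float(ranks[d_used > 0].sum())
        m = d_used.size
        mu = m * (m + 1) / 4.0
        var = m * (m + 1) * (2 * m + 1) / 24.0
        _, tie_counts = np.unique(np.abs(d_used), return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
    else:  # pratt: rank zeros, then drop them from the statistic
        ranks_all = stats.rankdata(np.abs(d))
        w_plus = float(ranks_all[d > 0].sum())
        m = d.size
        z0 = n_zero
        mu = (m * (m + 1) - z0 * (z0 + 1)) / 4.0
        var = (m * (m + 1) * (2 * m + 1) - z0 * (z0 + 1) * (2 * z0 + 1)) / 24.0
        nz = np.abs(d[d != 0])
        _, tie_counts = np.unique(nz, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        if d[d != 0].size == 0:
            return WilcoxonResult(0.0, None, 1.0, 0, n_zero, zero_policy, mode, alternative,
                                  note="all differences zero; no evidence of a shift")
        d_used = d[d != 0]
        ranks = ranks_all[d != 0]

    n_used = int(d_used.size)
    if mode == "exact":
        if zero_policy != "discard":
            raise DomainError("exact mode supports zero_policy='discard' only")
        if n_used > 25:
            raise DomainError(f"exact mode limited to n <= 25 non-zero differences, got {n_used}")
        ranks2 = np.rint(2 * ranks).astype(int)
        w2 = int(round(2 * w_plus))
        p = _signed_rank_exact_p(ranks2, w2, alternative)
        return WilcoxonResult(w_plus, None, p, n_used, n_zero, zero_policy, mode, alternative)
    if mode != "normal":
        raise DomainError(f"unknown mode {mode!r}")
    if var <= 0:
        return WilcoxonResult(w_plus, None, 1.0, n_used, n_zero, zero_policy, mode, alternative,
                              note="zero variance after tie correction")
    z = (w_plus - mu) / np.sqrt(var)
    if alternative == "two-sided":
        p = 2.0 * stats.norm.sf(abs(z))
    elif alternative == "greater":
        p = stats.norm.sf(z)
    else:
        p = stats.norm.cdf(z)
    return WilcoxonResult(w_plus, float(z), float(min(p, 1.0)), n_used, n_zero,
                          zero_policy, mode, alternative)


# --- continuous method comparison ------------------------------------------


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    mean_diff: float
    df: int


def paired_comparison(a: Sequence[float], b: Sequence[float]) -> PairedTResult:
    """Two-sided paired t test on a - b (e.g. LBM_PE vs LBM_WB)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise DomainError("a and b must be equal-length 1D sequences with n >= 2")
    d = a - b
    if np.std(d, ddof=1) == 0:
        raise DegenerateInputError("differences have zero variance; paired t is undefined")
    res = stats.ttest_rel(a, b)
    return PairedTResult(float(res.statistic), float(res.pvalue), float(d.mean()), int(a.size - 1))


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    means: np.ndarray  # per-pair means, for plotting
    diffs: np.ndarray


def bland_altman(method: Sequence[float], reference: Sequence[float]) -> BlandAltmanResult:
    """Bland-Altman agreement: bias = mean(method - reference), limits of
    agreement bias +/- 1.96 * sample SD of the differences."""
    m = np.asarray(method, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.shape != r.shape or m.ndim != 1 or m.size < 2:
        raise DomainError("method and reference must be equal-length 1D sequences with n >= 2")
    d = m - r
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=int(m.size),
        means=(m + r) / 2.0,
        diffs=d,
    )


# --- threshold-band discordance --------------------------------------------


@dataclass(frozen=True)
class BandStat:
    kind: str  # "band" (|dist| <= hi) or "shell" (lo < |dist| <= hi)
    lo: float
    hi: float
    n_in_band: int
    n_discordant: int
    discordant_pct: float  # to 1 decimal place


@dataclass(frozen=True)
class ThresholdBandReport:
    threshold_pct: float
    bands: tuple[BandStat, ...]
    n_total: int
    n_discordant_total: int


def threshold_band_analysis(
    results: Iterable[tuple[float, ResponseClass, ResponseClass]],
    band_half_widths: Sequence[float] = (5.0, 10.0),
    threshold_pct: float = 30.0,
) -> ThresholdBandReport:
    """Where do discordant classifications live relative to the +/-30% threshold?

    A patient with percent change p is "in band w" iff ``| |p| - 30 | <= w``
    (inclusive at the edge).  Reports cumulative bands for each half-width
    and the shells between consecutive half-widths, with the discordant
    fraction of each as a percentage to one decimal place.
    """
    if any(w <= 0 for w in band_half_widths):
        raise DomainError("band half-widths must be positive")
    rows = [(float(p), ResponseClass(a), ResponseClass(b)) for p, a, b in results]
    dist = np.array([abs(abs(p) - threshold_pct) for p, _, _ in rows])
    disc = np.array([a != b for _, a, b in rows], dtype=bool)
    widths = sorted(set(float(w) for w in band_half_widths))

    def _stat(kind: str, lo: float, hi: float, member: np.ndarray) -> BandStat:
        n = int(member.sum())
        nd = int((member & disc).sum())
        pct = round(100.0 * nd / n, 1) if n else 0.0
        return BandStat(kind, lo, hi, n, nd, pct)

    bands = [_stat("band", 0.0, w, dist <= w) for w in widths]
    edges = [0.0] + widths
    shells = [
        _stat("shell", lo, hi, (dist > lo) & (dist <= hi)) if lo > 0
        else _stat("shell", lo, hi, dist <= hi)
        for lo, hi in zip(edges[:-1], edges[1:])
    ]
    return ThresholdBandReport(
        threshold_pct=threshold_pct,
        bands=tuple(bands + shells),
        n_total=len(rows),
        n_discordant_total=int(disc.sum()),
    )
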