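"""Population-genetic statistics for allele-frequency skew and differentiation.

The core machinery behind the analyses:

* one-tailed two-sample Kolmogorov-Smirnov shift tests on derived-allele
  frequencies with a signed D (positive = distribution shifted toward the
  ancestral allele, i.e. toward low DAF) and the one-sided asymptotic
  p = exp(-2 D^2 mn/(m+n));
* Benjamini-Hochberg q-values and the "less than one expected false positive"
  discovery rule;
* the Scheirer-Ray-Hare extension of the Kruskal-Wallis test, a two-way ANOVA
  on ranks with interaction, reported as H statistics plus rank-difference
  coefficients relative to a chosen intercept cell;
* a paired Wilcoxon signed-rank comparison;
* Nei's Gst-style Fst from per-population allele frequencies;
* Fst-bin enrichment curves log(Pt/Pb);
* ordinary least squares of target-allele frequency on absolute latitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import (
    ConfigurationError,
    DegenerateDesignError,
    InsufficientDataError,
    NoInformationError,
)

KS_DIRECTIONS = ("toward-ancestral", "toward-derived")


@dataclass
class DAFTestResult:
    """One tissue-level DAF comparison against a background universe."""

    tissue: str
    background_kind: str
    polarity_tested: str
    n_target: int
    n_background: int
    D_signed: float
    p_value: float
    q_value: float = float("nan")


@dataclass
class SRHResult:
    """Two-way rank model: H statistic, df and p per effect, plus coefficients."""

    H: dict
    df: dict
    p: dict
    rank_coefficients: dict
    reference: tuple


@dataclass
class EnrichmentBin:
    """One Fst interval with target/background proportions and log(Pt/Pb)."""

    fst_lo: float
    fst_hi: float
    P_t: float
    P_b: float
    log_ratio: float
    defined: bool


@dataclass(frozen=True)
class FstRecord:
    snp_id: str
    fst: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst <= 1.0:
            raise ValueError(f"Fst {self.fst} outside [0,1] for {self.snp_id!r}")


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov shift test
# ---------------------------------------------------------------------------

def _ecdf_at(points: np.ndarray, sample: np.ndarray) -> np.ndarray:
    return np.searchsorted(np.sort(sample), points, side="right") / sample.size


def ks_one_tailed(
    target_dafs: Sequence[float],
    background_dafs: Sequence[float],
    direction: str = "toward-ancestral",
    corrected: bool = True,
) -> tuple[float, float]:
    """One-tailed two-sample KS test of a DAF shift, with signed D.

    ``direction='toward-ancestral'`` tests whether the target sample is
    shifted toward *low* DAF (an excess of rare derived alleles, the footprint
    of selection against the derived state); the statistic is
    D+ = sup_x [F_target(x) - F_background(x)] and is reported with positive
    sign.  ``'toward-derived'`` tests the opposite shift via
    D- = sup_x [F_background(x) - F_target(x)], reported as -D-.

    The p-value is the one-sided asymptotic tail.  By default Hodges'
    refinement exp(-2 z^2 - 2 z (m' + 2n')/(3 sqrt(m'n'(m'+n')))) with
    z = D sqrt(mn/(m+n)) and m' >= n' the sorted sample sizes is used, which
    stays close to uniform under the null at moderate sample sizes;
    ``corrected=False`` gives the leading term exp(-2 D^2 mn/(m+n)).  Either
    way the value is clipped into (0, 1].
    """
    if direction not in KS_DIRECTIONS:
        raise ConfigurationError(f"direction must be one of {KS_DIRECTIONS}")
    x = np.asarray(target_dafs, dtype=float)
    y = np.asarray(background_dafs, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InsufficientDataError("both DAF samples must be non-empty")
    grid = np.concatenate([x, y])
    diff = _ecdf_at(grid, x) - _ecdf_at(grid, y)
    d_plus = max(float(diff.max()), 0.0)
    d_minus = max(float(-diff.min()), 0.0)
    d = d_plus if direction == "toward-ancestral" else d_minus
    m, n = x.size, y.size
    if corrected:
        big, small = max(m, n), min(m, n)
        z = math.sqrt(big * small / (big + small)) * d
        expt = -2.0 * z * z - 2.0 * z * (big + 2 * small) / math.sqrt(
            big * small * (big + small)
        ) / 3.0
        p = math.exp(expt)
    else:
        p = math.exp(-2.0 * d * d * m * n / (m + n))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    d_signed = d_plus if direction == "toward-ancestral" else -d_minus
    return d_signed, p


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_qvalues(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-invariant)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise InsufficientDataError("empty p-value list")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def expected_fp_mask(q_values: Sequence[float], fdr_ceiling: float = 0.10) -> np.ndarray:
    """Discoveries within an FDR ceiling and with <1 expected false positive.

    A test is flagged when its q-value is within the ceiling *and* the
    expected number of false positives among all discoveries at that q cutoff
    (q times the number of discoveries) stays below one.
    """
    q = np.asarray(q_values, dtype=float)
    n_at_cut = np.array([(q <= qi).sum() for qi in q])
    return (q <= fdr_ceiling) & (q * n_at_cut < 1.0)


# ---------------------------------------------------------------------------
# Scheirer-Ray-Hare ranked two-way model
# ---------------------------------------------------------------------------

def _dummies(levels: np.ndarray, codes: np.ndarray) -> np.ndarray:
    out = np.zeros((codes.size, levels.size), dtype=float)
    out[np.arange(codes.size), codes] = 1.0
    return out


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def srh_test(
    y: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
    reference: tuple | None = None,
) -> SRHResult:
    """Scheirer-Ray-Hare test: two-way ANOVA with interaction on rank-transformed y.

    The response is ranked with average ranks on ties; type-II sums of squares
    are computed on the ranks, and each effect's H statistic is
    SS_effect / (SS_total / (N-1)), referred to a chi-square distribution with
    the effect's degrees of freedom.  ``rank_coefficients`` gives, for every
    (a, b) cell, the mean-rank difference from the ``reference`` cell (default:
    first level of each factor in sorted order); the reference cell itself is 0.
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    if not (y.size == a.size == b.size):
        raise ValueError("y, factor_a and factor_b must have equal length")
    lev_a, code_a = np.unique(a, return_inverse=True)
    lev_b, code_b = np.unique(b, return_inverse=True)
    if lev_a.size < 2 or lev_b.size < 2:
        raise DegenerateDesignError("each factor needs at least two levels")
    n_cells = lev_a.size * lev_b.size
    if y.size < n_cells:
        raise DegenerateDesignError(
            f"N={y.size} observations for {n_cells} cells; design underdetermined"
        )
    r = sps.rankdata(y)
    N = r.size
    ss_total = float(((r - r.mean()) ** 2).sum())

    ones = np.ones((N, 1))
    A = _dummies(lev_a, code_a)[:, 1:]  # drop one column; intercept spans it
    B = _dummies(lev_b, code_b)[:, 1:]
    AB = np.einsum("ij,ik->ijk", _dummies(lev_a, code_a), _dummies(lev_b, code_b))
    AB = AB.reshape(N, -1)
    rss_a = _rss(np.hstack([ones, A]), r)
    rss_b = _rss(np.hstack([ones, B]), r)
    rss_ab = _rss(np.hstack([ones, A, B]), r)
    rss_full = _rss(AB, r)  # cell-mean model == full interacted model
    ss = {
        "A": rss_b - rss_ab,
        "B": rss_a - rss_ab,
        "A:B": rss_ab - rss_full,
    }
    df = {
        "A": lev_a.size - 1,
        "B": lev_b.size - 1,
        "A:B": (lev_a.size - 1) * (lev_b.size - 1),
    }
    if ss_total == 0.0:
        H = {k: 0.0 for k in ss}
        p = {k: 1.0 for k in ss}
    else:
        ms_total = ss_total / (N - 1)
        H = {k: max(v, 0.0) / ms_total for k, v in ss.items()}
        p = {k: float(sps.chi2.sf(H[k], df[k])) if H[k] > 0 else 1.0 for k in ss}

    if reference is None:
        reference = (lev_a[0], lev_b[0])
    ref_a = np.nonzero(lev_a == reference[0])[0]
    ref_b = np.nonzero(lev_b == reference[1])[0]
    if ref_a.size == 0 or ref_b.size == 0:
        raise ConfigurationError(f"reference cell {reference} not among factor levels")
    cell_means = np.full((lev_a.size, lev_b.size), np.nan)
    for i in range(lev_a.size):
        for j in range(lev_b.size):
            mask = (code_a == i) & (code_b == j)
            if mask.any():
                cell_means[i, j] = r[mask].mean()
    ref_mean = cell_means[ref_a[0], ref_b[0]]
    coeffs = {}
    for i, la in enumerate(lev_a):
        for j, lb in enumerate(lev_b):
            if not np.isnan(cell_means[i, j]) and not np.isnan(ref_mean):
                coeffs[(la, lb)] = float(cell_means[i, j] - ref_mean)
    return SRHResult(H=H, df=df, p=p, rank_coefficients=coeffs, reference=tuple(reference))


# ---------------------------------------------------------------------------
# paired Wilcoxon
# ---------------------------------------------------------------------------

def wilcoxon_paired(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p for paired samples; zero differences dropped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size == 0:
        raise ValueError("paired samples must have equal, non-zero length")
    if np.all(x == y):
        raise NoInformationError("all paired differences are zero")
    return float(sps.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# population differentiation
# ---------------------------------------------------------------------------

def nei_fst(pop_freqs: Sequence[float]) -> float:
    """Nei's Gst from per-population allele frequencies (unweighted).

    Hs = mean within-population heterozygosity 2p(1-p); Ht = 2 pbar (1-pbar)
    with pbar the unweighted mean frequency; Fst = (Ht - Hs)/Ht, 0 when the
    locus is monomorphic overall.
    """
    p = np.asarray(pop_freqs, dtype=float)
    if p.size < 2:
        raise InsufficientDataError("need frequencies for at least two populations")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("frequencies must lie in [0,1]")
    hs = float(np.mean(2.0 * p * (1.0 - p)))
    pbar = float(p.mean())
    ht = 2.0 * pbar * (1.0 - pbar)
    if ht == 0.0:
        return 0.0
    return (ht - hs) / ht


def fst_enrichment(
    target_fsts: Sequence[float],
    background_fsts: Sequence[float],
    bin_width: float = 0.05,
    log_base: float = 10.0,
) -> list[EnrichmentBin]:
    """Per-bin log ratio of target vs background Fst proportions.

    Fst values are binned into fixed intervals [0,w), [w,2w), ..., [1-w,1]
    (last bin closed); within each sample the bin counts are normalised to
    proportions Pt and Pb and the enrichment is log(Pt/Pb) in ``log_base``.
    Bins with no background mass are flagged undefined rather than infinite;
    an occupied background bin with an empty target bin yields -inf.
    """
    t = np.asarray(target_fsts, dtype=float)
    b = np.asarray(background_fsts, dtype=float)
    if t.size == 0 or b.size == 0:
        raise InsufficientDataError("both Fst samples must be non-empty")
    n_bins = 1.0 / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ConfigurationError(f"bin width {bin_width} does not divide 1")
    n_bins = int(round(n_bins))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    ct, _ = np.histogram(t, bins=edges)
    cb, _ = np.histogram(b, bins=edges)
    pt = ct / ct.sum()
    pb = cb / cb.sum()
    out = []
    for i in range(n_bins):
        if pb[i] == 0.0:
            lr, defined = float("nan"), False
        elif pt[i] == 0.0:
            lr, defined = float("-inf"), True
        else:
            lr, defined = math.log(pt[i] / pb[i], log_base), True
        out.append(EnrichmentBin(edges[i], edges[i + 1], float(pt[i]), float(pb[i]), lr, defined))
    return out


def latitude_regression(
    target_freqs_by_population: Sequence[float],
    abs_latitudes: Sequence[float],
) -> tuple[float, float, float]:
    """OLS of per-population target-allele frequency on absolute latitude.

    Returns (slope, two-sided p for the slope, adjusted R^2).  Populations with
    recent long-range migration should be excluded by the caller before the
    fit, since their sampling location no longer reflects their selective
    environment.
    """
    import statsmodels.api as sm

    y = np.asarray(target_freqs_by_population, dtype=float)
    x = np.asarray(abs_latitudes, dtype=float)
    if y.size != x.size or y.size < 3:
        raise InsufficientDataError("need matched frequencies and latitudes for >=3 populations")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("latitude predictor is constant")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return float(model.params[1]), float(model.pvalues[1]), float(model.rsquared_adj)
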