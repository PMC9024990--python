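"""Agreement statistics: Bland-Altman, weighted Cohen kappa, cohort tests.

Bland-Altman summarises the agreement of two measurement methods by the
mean of their paired differences (bias) and the limits of agreement,
bias +/- 1.96 * SD of the differences.  Weighted Cohen kappa measures
chance-corrected agreement between two ordered classifications, with
linear weights w_ij = 1 - |i - j| / (k - 1) so distant disagreements cost
more.  The kappa standard error is the Fleiss-Cohen-Everitt large-sample
formula; a bootstrap CI is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

Z95 = 1.959963984540054  # two-sided 95% normal quantile


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

@dataclass
class BlandAltmanResult:
    pair_means: np.ndarray
    pair_diffs: np.ndarray  # expert - CAD
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float

    def plot(self, ax=None, xlabel="mean of methods", ylabel="difference (expert - CAD)"):
        """Scatter of differences vs means with bias and LoA lines."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.pair_means, self.pair_diffs, s=18, color="k")
        for y, style in ((self.bias, "-"), (self.loa_low, "--"), (self.loa_high, "--")):
            ax.axhline(y, linestyle=style, color="tab:red")
        ax.set_xlabel(xlabel)
        ax.set_ylabel(ylabel)
        return ax


def bland_altman(pairs: Sequence[tuple[float, float]] | np.ndarray) -> BlandAltmanResult:
    """Agreement summary of paired (expert, cad) measurements.

    Differences are expert - CAD; SD uses the n-1 denominator; limits of
    agreement are bias +/- 1.96 SD.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("bland_altman needs at least 2 (expert, cad) pairs")
    diffs = arr[:, 0] - arr[:, 1]
    means = arr.mean(axis=1)
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        pair_means=means,
        pair_diffs=diffs,
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
    )


# ---------------------------------------------------------------------------
# Weighted Cohen kappa
# ---------------------------------------------------------------------------

#: Landis-Koch adjective bands, emitted as annotation only.
_LANDIS_KOCH = (
    (0.0, "poor"),
    (0.01, "slight"),
    (0.21, "fair"),
    (0.41, "moderate"),
    (0.61, "substantial"),
    (0.81, "almost perfect"),
)


def agreement_adjective(kappa: float) -> str:
    adjective = "poor"
    for lo, word in _LANDIS_KOCH:
        if kappa >= lo:
            adjective = word
    return adjective


@dataclass
class KappaResult:
    kappa: float
    se: float
    ci95: tuple[float, float]
    weighting: Literal["linear", "unweighted"]
    p_observed: float
    p_expected: float

    @property
    def agreement(self) -> str:
        return agreement_adjective(self.kappa)


def linear_weights(k: int) -> np.ndarray:
    """w_ij = 1 - |i - j| / (k - 1); identity for k = 1."""
    idx = np.arange(k)
    if k == 1:
        return np.ones((1, 1))
    return 1.0 - np.abs(idx[:, None] - idx[None, :]) / (k - 1)


def weighted_kappa(
    table: np.ndarray,
    weighting: Literal["linear", "unweighted"] = "linear",
    ci: Literal["asymptotic", "bootstrap"] = "asymptotic",
    n_boot: int = 2000,
    seed: int | None = None,
) -> KappaResult:
    """Linearly weighted Cohen kappa with 95% CI from a k x k table.

    kappa = (p_o - p_e) / (1 - p_e) with p_o = sum w_ij f_ij / N and
    p_e = sum w_ij r_i c_j / N^2.  The asymptotic SE follows
    Fleiss, Cohen & Everitt; the CI is kappa +/- 1.96 SE clipped to [-1, 1].
    """
    f = np.asarray(table, dtype=float)
    if f.ndim != 2 or f.shape[0] != f.shape[1]:
        raise ValueError("contingency table must be square")
    if np.any(f < 0):
        raise ValueError("contingency table must be non-negative")
    n = f.sum()
    if n <= 0:
        raise ValueError("contingency table total must be > 0")
    k = f.shape[0]
    w = linear_weights(k) if weighting == "linear" else np.eye(k)

    p = f / n
    p_row = p.sum(axis=1)
    p_col = p.sum(axis=0)
    p_o = float((w * p).sum())
    p_e = float((w * np.outer(p_row, p_col)).sum())
    if np.isclose(p_e, 1.0):
        raise ValueError("degenerate marginals: expected agreement is 1, kappa undefined")
    kappa = (p_o - p_e) / (1.0 - p_e)

    if ci == "bootstrap":
        se, lo, hi = _bootstrap_ci(f, w, n_boot, seed)
    else:
        # expected weights of each row/col under the partner's marginal
        wbar_row = w @ p_col          # E_j[w_ij]
        wbar_col = p_row @ w          # E_i[w_ij]
        term = w - (wbar_row[:, None] + wbar_col[None, :]) * (1.0 - kappa)
        var = ((p * term**2).sum() - (kappa - p_e * (1.0 - kappa)) ** 2) / (
            n * (1.0 - p_e) ** 2
        )
        se = float(np.sqrt(max(var, 0.0)))
        lo, hi = kappa - Z95 * se, kappa + Z95 * se
    lo, hi = max(lo, -1.0), min(hi, 1.0)
    return KappaResult(
        kappa=float(kappa),
        se=float(se),
        ci95=(float(lo), float(hi)),
        weighting=weighting,
        p_observed=p_o,
        p_expected=p_e,
    )


def _bootstrap_ci(f: np.ndarray, w: np.ndarray, n_boot: int, seed: int | None):
    rng = np.random.default_rng(seed)
    n = int(f.sum())
    probs = (f / n).ravel()
    k = f.shape[0]
    vals = []
    for _ in range(n_boot):
        draw = rng.multinomial(n, probs).reshape(k, k).astype(float)
        p = draw / n
        p_e = float((w * np.outer(p.sum(1), p.sum(0))).sum())
        if np.isclose(p_e, 1.0):
            continue
        p_o = float((w * p).sum())
        vals.append((p_o - p_e) / (1.0 - p_e))
    vals = np.asarray(vals)
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(vals.std(ddof=1)), float(lo), float(hi)


def build_contingency(
    ratings1: Sequence[int], ratings2: Sequence[int], k: int = 4
) -> np.ndarray:
    """k x k table of paired class codes (rows = rater 1, cols = rater 2)."""
    r1 = np.asarray(ratings1, dtype=int)
    r2 = np.asarray(ratings2, dtype=int)
    if r1.shape != r2.shape:
        raise ValueError("rating vectors must have equal length")
    if r1.size == 0:
        raise ValueError("rating vectors are empty")
    if r1.min() < 0 or r1.max() >= k or r2.min() < 0 or r2.max() >= k:
        raise ValueError(f"class codes must lie in 0..{k - 1}")
    table = np.zeros((k, k), dtype=int)
    np.add.at(table, (r1, r2), 1)
    return table


# ---------------------------------------------------------------------------
# Demographic comparison tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSummary:
    """n, mean, SD of one variable in one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def t_test_from_summary(
    g1: GroupSummary,
    g2: GroupSummary,
    variant: Literal["pooled", "welch"] = "pooled",
) -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics; returns (t, df, p two-tailed)."""
    if g1.sd == 0 and g2.sd == 0:
        if g1.mean == g2.mean:
            return 0.0, float(g1.n + g2.n - 2), 1.0
        return float("inf"), float(g1.n + g2.n - 2), 0.0
    res = sps.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = float(g1.n + g2.n - 2)
    else:  # Welch-Satterthwaite
        v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def chi_square_2x2(
    counts: np.ndarray | Sequence[Sequence[int]],
    correction: Literal["none", "yates"] = "none",
) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table; returns (chi2, df=1, p).

    Uncorrected by default: chi2 = N (ad - bc)^2 / (r1 r2 c1 c2).  The
    Yates variant subtracts N/2 from |ad - bc| before squaring.
    """
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a non-negative 2x2 table")
    n = t.sum()
    if n <= 0:
        raise ValueError("table total must be > 0")
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    denom = r[0] * r[1] * c[0] * c[1]
    if denom == 0:
        raise ValueError("a zero marginal makes the chi-square statistic undefined")
    det = t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0]
    if correction == "yates":
        num = max(abs(det) - n / 2.0, 0.0) ** 2
    else:
        num = det**2
    chi2 = float(n * num / denom)
    p = float(sps.chi2.sf(chi2, df=1))
    return chi2, 1, p
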