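"""Cohort-level statistics of phase-dependent corticospinal excitability.

PHASE = (RMT_pos - RMT_neg) / RMT_rand is the per-hemisphere
phase-dependency index; positive PHASE means the negative peak of the mu
cycle is the higher-excitability state (lower threshold).  The cohort
analysis runs a Friedman test over the three phase conditions per
hemisphere with Bonferroni-corrected Wilcoxon pairwise comparisons
(significance at p < 0.017), Wilcoxon tests of interhemispheric RMT
differences, a Pearson correlation of PHASE across hemispheres, a paired
t-test on PHASE with Cohen's d and a default JZS Bayes factor, prevalence
counts of RMT_neg < RMT_pos, and an exploratory similar/dissimilar PHASE
split compared with Mann-Whitney U tests.  Shapiro-Wilk checks route
between parametric and non-parametric tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats as sps

HEMISPHERES = ("dominant", "non_dominant")
CONDITIONS = ("neg", "pos", "rand")

#: Bonferroni-corrected significance criterion for the three pairwise
#: comparisons, as conventionally rounded (0.017 rather than 0.05/3 exactly).
PAIRWISE_ALPHA = 0.017


def phase_metric(rmt_pos: float, rmt_neg: float, rmt_rand: float) -> float:
    """PHASE = (RMT_pos - RMT_neg) / RMT_rand."""
    if rmt_rand <= 0:
        raise ValueError("rmt_rand must be positive")
    return (rmt_pos - rmt_neg) / rmt_rand


def friedman_test(values) -> tuple[float, float]:
    """Friedman chi-square over k related samples (rows = subjects).

    Average ranks with the standard tie correction; df = k - 1.  When no
    row discriminates between conditions (all within-row values tied)
    the statistic is 0 and p = 1.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("values must be an (n_subjects >= 2, k >= 2) matrix")
    if np.isnan(x).any():
        raise ValueError("missing cells are not allowed")
    n, k = x.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, x)
    col_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    ties = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    correction = 1.0 - ties / (n * k * (k**2 - 1))
    if correction <= 0.0:
        return 0.0, 1.0
    stat /= correction
    return float(stat), float(sps.chi2.sf(stat, k - 1))


def wilcoxon_signed_rank(x, y, zero_method: str = "pratt",
                         mode: str = "auto") -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired vectors, reported as (Z, p).

    Zero differences are handled by Pratt's method by default.  With
    ``mode='auto'`` the p-value comes from the exact null distribution
    for n <= 25 without zeros or tied |differences|, and from the
    tie-corrected normal approximation otherwise; Z is always the
    normal-approximation statistic (the scale the study reports).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired vectors of equal length")
    d = x - y
    if np.all(d == 0):
        raise ValueError("all paired differences are zero")
    absd = np.abs(d[d != 0])
    exact_ok = (
        len(d) <= 25 and np.all(d != 0) and len(np.unique(absd)) == len(absd)
    )
    approx = sps.wilcoxon(x, y, zero_method=zero_method, method="approx",
                          correction=False)
    z = float(approx.zstatistic)
    if mode == "exact" or (mode == "auto" and exact_ok):
        p = float(sps.wilcoxon(x, y, method="exact").pvalue)
    else:
        p = float(approx.pvalue)
    return z, p


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with tie-corrected normal p (exact when
    both groups are small and tie-free)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    exact_ok = len(x) <= 25 and len(y) <= 25 and len(np.unique(pooled)) == len(pooled)
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="exact" if exact_ok else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def pairwise_bonferroni(ps, alpha: float = PAIRWISE_ALPHA) -> list[bool]:
    """Significance flags for the three pairwise p-values at the rounded
    Bonferroni criterion (strict p < 0.017)."""
    return [float(p) < alpha for p in ps]


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-tailed t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def jzs_bayes_factor(t: float, n: int, r: float = np.sqrt(2.0) / 2.0) -> float:
    """Default JZS Bayes factor (BF10) for a one-sample/paired t-test.

    Effect-size prior delta ~ Cauchy(0, r); equivalently delta | g ~
    N(0, g r^2) with g ~ InverseGamma(1/2, 1/2).  BF10 is the ratio of
    the marginal likelihood under that prior to the point-null
    likelihood, computed by adaptive quadrature over g.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    nu = n - 1

    def integrand(g):
        c = 1.0 + n * g * r**2
        return (
            c**-0.5
            * (1.0 + t**2 / (c * nu)) ** (-(nu + 1) / 2.0)
            * (2.0 * np.pi) ** -0.5
            * g**-1.5
            * np.exp(-1.0 / (2.0 * g))
        )

    m1, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    m0 = (1.0 + t**2 / nu) ** (-(nu + 1) / 2.0)
    return float(m1 / m0)


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    cohens_d: float
    bf10: float


def paired_t_with_bayes(x, y) -> PairedTResult:
    """Two-tailed paired t-test with Cohen's d and the JZS Bayes factor."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("need paired vectors of length >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences")
    n = len(d)
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return PairedTResult(t=t, df=n - 1, p=p, cohens_d=float(d.mean() / sd),
                         bf10=jzs_bayes_factor(t, n))


def prevalence(df: pd.DataFrame) -> dict:
    """Prevalence of RMT_neg < RMT_pos and of P(RMT_neg < RMT_pos) > 0.95.

    Strict inequalities throughout: exact ties do not count.  The
    probability P(RMT_neg < RMT_pos) equals the column
    ``p_pos_gt_neg_<hemi>`` (same event, read from the posterior pair).
    """
    n = len(df)
    out: dict = {"n_subjects": n}
    effect = {}
    high_p = {}
    for hemi in HEMISPHERES:
        effect[hemi] = np.asarray(df[f"rmt_neg_{hemi}"] < df[f"rmt_pos_{hemi}"])
        high_p[hemi] = np.asarray(df[f"p_pos_gt_neg_{hemi}"] > 0.95)
        out[f"neg_lt_pos_{hemi}"] = int(effect[hemi].sum())
        out[f"neg_lt_pos_{hemi}_frac"] = float(effect[hemi].mean()) if n else 0.0
        out[f"p_gt_095_{hemi}"] = int(high_p[hemi].sum())
    both = effect["dominant"] & effect["non_dominant"]
    out["neg_lt_pos_both"] = int(both.sum())
    out["neg_lt_pos_both_frac"] = float(both.mean()) if n else 0.0
    out["p_gt_095_both"] = int((high_p["dominant"] & high_p["non_dominant"]).sum())
    return out


def similarity_split(df: pd.DataFrame) -> dict:
    """Exploratory split into similar vs dissimilar PHASE across hemispheres.

    A subject is dissimilar iff P(RMT_pos > RMT_neg) straddles 0.5
    across hemispheres (one strictly below, one at or above; a
    probability of exactly 0.5 counts to the >= 0.5 side).  The two
    groups' interhemispheric absolute differences in RMT_rand, mu peak
    frequency, and mu SNR are compared with Mann-Whitney U tests.
    """
    p_dom = np.asarray(df["p_pos_gt_neg_dominant"], dtype=float)
    p_non = np.asarray(df["p_pos_gt_neg_non_dominant"], dtype=float)
    upper_dom = p_dom >= 0.5
    upper_non = p_non >= 0.5
    dissimilar = upper_dom != upper_non
    out: dict = {
        "labels": np.where(dissimilar, "dissimilar", "similar"),
        "n_dissimilar": int(dissimilar.sum()),
        "n_similar": int((~dissimilar).sum()),
    }
    diffs = {
        "rmt": np.abs(df["rmt_rand_dominant"] - df["rmt_rand_non_dominant"]),
        "peak_freq": np.abs(df["peak_freq_dominant"] - df["peak_freq_non_dominant"]),
        "snr": np.abs(df["snr_db_dominant"] - df["snr_db_non_dominant"]),
    }
    for name, vals in diffs.items():
        vals = np.asarray(vals, dtype=float)
        if dissimilar.any() and (~dissimilar).any():
            u, p = mann_whitney_u(vals[dissimilar], vals[~dissimilar])
        else:
            u, p = np.nan, np.nan
        out[f"u_{name}"], out[f"p_{name}"] = u, p
    return out


def shapiro_gate(values, alpha: float = 0.05) -> dict:
    """Shapiro-Wilk normality gate routing parametric vs non-parametric."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(values == values[0]):
        raise ValueError("constant input: normality test undefined")
    w, p = sps.shapiro(values)
    return {"w": float(w), "p": float(p), "nonparametric": bool(p < alpha),
            "route": "nonparametric" if p < alpha else "parametric"}


@dataclass
class CohortResult:
    """All cohort-level statistics plus the per-subject table used."""

    n_subjects: int
    friedman: dict = field(default_factory=dict)
    pairwise: dict = field(default_factory=dict)
    interhemispheric_rmt: dict = field(default_factory=dict)
    interhemispheric_power: dict = field(default_factory=dict)
    phase_summary: dict = field(default_factory=dict)
    paired_t: PairedTResult | None = None
    pearson_phase: tuple[float, float] | None = None
    diff_correlations: dict = field(default_factory=dict)
    prevalence: dict = field(default_factory=dict)
    similarity: dict = field(default_factory=dict)
    shapiro: dict = field(default_factory=dict)


_PAIRS = (("neg", "rand"), ("neg", "pos"), ("rand", "pos"))


def analyze_cohort(df: pd.DataFrame) -> CohortResult:
    """Full cohort analysis on a per-subject results table.

    Expected columns (per hemisphere suffix ``_dominant`` /
    ``_non_dominant``): ``rmt_neg``, ``rmt_pos``, ``rmt_rand``,
    ``p_pos_gt_neg``, ``snr_db``, ``peak_freq``; optionally
    ``power_<cond>`` pre-stimulus mu powers.
    """
    res = CohortResult(n_subjects=len(df))

    def _wilcoxon_or_nan(x, y):
        try:
            return wilcoxon_signed_rank(x, y)
        except ValueError:  # all differences zero (tiny/degenerate cohorts)
            return (np.nan, np.nan)

    phase = {}
    for hemi in HEMISPHERES:
        rmts = np.column_stack([df[f"rmt_{c}_{hemi}"] for c in CONDITIONS])
        chi2, p = friedman_test(rmts)
        res.friedman[hemi] = {"chi2": chi2, "df": 2, "p": p}
        pair_stats = {}
        for a, b in _PAIRS:
            z, pw = _wilcoxon_or_nan(df[f"rmt_{a}_{hemi}"], df[f"rmt_{b}_{hemi}"])
            pair_stats[f"{a}_vs_{b}"] = {"z": z, "p": pw}
        flags = pairwise_bonferroni([
            pair_stats[f"{a}_vs_{b}"]["p"]
            if np.isfinite(pair_stats[f"{a}_vs_{b}"]["p"]) else 1.0
            for a, b in _PAIRS
        ])
        for (a, b), sig in zip(_PAIRS, flags):
            pair_stats[f"{a}_vs_{b}"]["significant"] = sig
        res.pairwise[hemi] = pair_stats
        phase[hemi] = np.array([
            phase_metric(rp, rn, rr)
            for rp, rn, rr in zip(df[f"rmt_pos_{hemi}"], df[f"rmt_neg_{hemi}"],
                                  df[f"rmt_rand_{hemi}"])
        ])
        res.phase_summary[hemi] = {
            "mean": float(phase[hemi].mean()),
            "sd": float(phase[hemi].std(ddof=1)),
        }
        try:
            res.shapiro[f"phase_{hemi}"] = shapiro_gate(phase[hemi])
        except ValueError:
            res.shapiro[f"phase_{hemi}"] = None
        res.phase_summary[hemi].update({
            f"median_rmt_{c}": float(np.median(df[f"rmt_{c}_{hemi}"]))
            for c in CONDITIONS
        })

    for c in CONDITIONS:
        z, p = _wilcoxon_or_nan(df[f"rmt_{c}_dominant"], df[f"rmt_{c}_non_dominant"])
        res.interhemispheric_rmt[c] = {"z": z, "p": p}
        col = f"power_{c}_dominant"
        if col in df.columns:
            z, p = _wilcoxon_or_nan(df[col], df[f"power_{c}_non_dominant"])
            res.interhemispheric_power[c] = {"z": z, "p": p}

    # degenerate cohorts (n < 3, or zero-variance PHASE) simply skip the
    # correlational statistics rather than failing the whole analysis
    try:
        res.paired_t = paired_t_with_bayes(phase["dominant"], phase["non_dominant"])
    except ValueError:
        res.paired_t = None
    try:
        res.pearson_phase = pearson_r(phase["dominant"], phase["non_dominant"])
    except ValueError:
        res.pearson_phase = (np.nan, np.nan)

    dphase = phase["dominant"] - phase["non_dominant"]
    for name, col in (("rmt", "rmt_rand"), ("peak_freq", "peak_freq"),
                      ("snr", "snr_db")):
        diff = np.asarray(df[f"{col}_dominant"] - df[f"{col}_non_dominant"], float)
        try:
            res.diff_correlations[name] = pearson_r(dphase, diff)
        except ValueError:
            res.diff_correlations[name] = (np.nan, np.nan)

    res.prevalence = prevalence(df)
    res.similarity = similarity_split(df)
    return res


def render_report(result: CohortResult) -> str:
    """Plain-text results-style summary of a cohort analysis."""
    lines = [f"Cohort analysis: n = {result.n_subjects} subjects", ""]
    for hemi in HEMISPHERES:
        f = result.friedman[hemi]
        s = result.phase_summary[hemi]
        lines.append(f"[{hemi}] Friedman chi2(2) = {f['chi2']:.3f}, p = {f['p']:.3g}")
        lines.append(
            "  median RMT (neg/rand/pos): "
            f"{s['median_rmt_neg']:.2f} / {s['median_rmt_rand']:.2f} / "
            f"{s['median_rmt_pos']:.2f} %MSO"
        )
        lines.append(f"  PHASE mean (SD): {s['mean']:.3f} ({s['sd']:.3f})")
        for pair, st in result.pairwise[hemi].items():
            sig = "*" if st["significant"] else " "
            lines.append(f"  {pair}: Z = {st['z']:.3f}, p = {st['p']:.3g} {sig}")
    t = result.paired_t
    lines.append("")
    if t is not None:
        lines.append(
            f"PHASE dominant vs non-dominant: t({t.df}) = {t.t:.3f}, p = {t.p:.3g}, "
            f"d = {t.cohens_d:.2f}, BF10 = {t.bf10:.3f}"
        )
    if result.pearson_phase is not None:
        r, p = result.pearson_phase
        lines.append(f"PHASE interhemispheric correlation: r = {r:.3f}, p = {p:.3g}")
    pv = result.prevalence
    lines.append(
        "Prevalence RMT_neg < RMT_pos: "
        f"both {pv['neg_lt_pos_both']} ({100 * pv['neg_lt_pos_both_frac']:.0f}%), "
        f"dominant {pv['neg_lt_pos_dominant']}, "
        f"non-dominant {pv['neg_lt_pos_non_dominant']}"
    )
    sim = result.similarity
    lines.append(
        f"Similar/dissimilar PHASE split: {sim['n_similar']} / {sim['n_dissimilar']}"
    )
    return "\n".join(lines)
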