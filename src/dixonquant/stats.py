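"""Cohort statistics: paired nonparametric testing, reliability, power.

The longitudinal analysis of per-muscle fat fractions uses the Wilcoxon
signed-rank test on paired baseline / 12-month measurements (fat fractions
are bounded and typically non-normal, screened with Shapiro-Wilk), grade
changes are tested on integer ranks of the 6-point ordinal scale, and
inter-observer reliability is summarised by Bland-Altman bias and the
repeatability coefficient RC = 1.96 * SD of paired differences (95% of
comparisons fall within bias +/- RC).

:func:`wilcoxon_signed_rank` is implemented here rather than delegated:
the exact two-sided p-value is computed by enumerating the null
distribution of the positive-rank sum over all 2^n sign assignments (via
the standard subset-sum recursion for tie-free integer ranks, or direct
enumeration with midranks for small tied samples), with a tie- and
continuity-corrected normal approximation for larger n.  Zero differences
are dropped before ranking and their count reported.  Infinite paired
values (subjects unable to perform a timed test) participate through their
ranks: an infinite difference takes the largest rank, and a pair that is
infinite at both visits contributes a zero difference.

:func:`power_comparison` runs the simulation experiment comparing endpoint
sensitivities: the same latent 12-month progression is tested through the
continuous fat fraction, through its ordinal-grade coarsening, and through
functional tests, and the rejection rate at a given alpha estimates each
endpoint's power.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import TABLE_COLUMNS, CohortSpec, _simulate_arrays
from .grading import GRADES, grades_to_ranks

__all__ = [
    "WilcoxonResult",
    "BlandAltmanResult",
    "AgreementResult",
    "CorrelationResult",
    "PowerResult",
    "shapiro_wilk",
    "wilcoxon_signed_rank",
    "bland_altman",
    "grade_agreement",
    "change_correlation",
    "power_comparison",
    "holm_adjust",
    "LongitudinalModel",
    "LongitudinalResults",
]


# --------------------------------------------------------------------------
# elementary tests


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test (statistic, p-value).

    Used as a reporting gate for choosing median summaries, never to switch
    test methods silently.  Constant input has undefined W and raises.
    """
    x = np.asarray(values, float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("Shapiro-Wilk requires finite values")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk W is undefined for constant input")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


@dataclass
class WilcoxonResult:
    """Paired signed-rank test result.

    ``statistic`` is W+, the sum of ranks of positive differences among the
    ``n_used`` nonzero differences; ``method`` records whether the p-value
    came from exact enumeration, the normal approximation, or a degenerate
    all-zero sample (p = 1 by convention).
    """

    n_used: int
    statistic: float
    pvalue: float
    method: str
    n_zero: int
    n_ties: int


_EXACT_MAX_N = 25  # exact enumeration bound for tie-free ranks
_EXACT_TIES_MAX_N = 14  # direct 2^n enumeration bound with midranks


def _exact_p_integer_ranks(n: int, w_plus: float) -> float:
    """Exact two-sided p for tie-free ranks 1..n via subset-sum counts."""
    total = n * (n + 1) // 2
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] = counts[r:] + counts[:-r]
    w = int(round(w_plus))
    c_le = counts[: w + 1].sum()
    c_ge = counts[w:].sum()
    return min(1.0, 2.0 * min(c_le, c_ge) / 2.0**n)


def _exact_p_enumerate(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by enumerating all sign assignments (midranks ok)."""
    sums = np.zeros(1)
    for r in ranks:
        sums = np.concatenate([sums, sums + r])
    eps = 1e-9
    c_le = np.count_nonzero(sums <= w_plus + eps)
    c_ge = np.count_nonzero(sums >= w_plus - eps)
    return min(1.0, 2.0 * min(c_le, c_ge) / sums.size)


def wilcoxon_signed_rank(baseline, followup=None) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Call with two equal-length paired vectors (differences are
    followup - baseline) or a single vector of differences.  Zero
    differences are dropped before ranking (their count is ``n_zero``).
    The p-value is exact for n <= 25 without ties in |differences| (and for
    small tied samples by direct enumeration); otherwise a normal
    approximation with tie correction and continuity correction is used.
    Infinite values are permitted: differences of +/-inf rank largest, and
    inf - inf pairs count as zero differences.
    """
    if followup is None:
        d = np.asarray(baseline, float)
    else:
        b = np.asarray(baseline, float)
        f = np.asarray(followup, float)
        if b.shape != f.shape:
            raise ValueError("paired vectors must have equal length")
        with np.errstate(invalid="ignore"):
            d = f - b
        d[np.isnan(d) & ~np.isfinite(b) & ~np.isfinite(f)] = 0.0  # inf - inf
    if d.ndim != 1 or d.size < 1:
        raise ValueError("need a 1D paired sample of length >= 1")
    if np.isnan(d).any():
        raise ValueError("NaN differences are not interpretable")

    nonzero = d != 0
    n_zero = int(np.size(d) - nonzero.sum())
    d = d[nonzero]
    n = d.size
    if n == 0:
        return WilcoxonResult(0, 0.0, 1.0, "degenerate", n_zero, 0)

    absd = np.abs(d)
    ranks = sps.rankdata(absd)
    _, tie_counts = np.unique(absd, return_counts=True)
    n_ties = int(np.sum(tie_counts[tie_counts > 1]))
    has_ties = bool((tie_counts > 1).any())
    w_plus = float(ranks[d > 0].sum())

    if not has_ties and n <= _EXACT_MAX_N:
        p = _exact_p_integer_ranks(n, w_plus)
        method = "exact"
    elif has_ties and n <= _EXACT_TIES_MAX_N:
        p = _exact_p_enumerate(ranks, w_plus)
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
            tie_counts**3 - tie_counts
        ) / 48.0
        if var <= 0:
            return WilcoxonResult(n, w_plus, 1.0, "degenerate", n_zero, n_ties)
        dev = w_plus - mu
        z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var)
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        method = "approx"
    return WilcoxonResult(n, w_plus, float(p), method, n_zero, n_ties)


# --------------------------------------------------------------------------
# reliability


@dataclass
class BlandAltmanResult:
    """Paired-difference agreement: bias, SD, RC = 1.96*SD, limits."""

    bias: float
    sd: float
    repeatability_coefficient: float
    limits: tuple[float, float]
    n: int


def bland_altman(values_a, values_b) -> BlandAltmanResult:
    """Bland-Altman agreement between two paired observers.

    bias = mean(A - B); RC = 1.96 * sample SD of A - B (ddof 1); the limits
    of agreement are bias +/- RC and are expected to contain 95% of paired
    differences.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("observer vectors must be paired 1D arrays")
    if a.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    rc = 1.96 * sd
    return BlandAltmanResult(
        bias=bias,
        sd=sd,
        repeatability_coefficient=rc,
        limits=(bias - rc, bias + rc),
        n=a.size,
    )


@dataclass
class AgreementResult:
    """Exact-match agreement between two graders over the 6-point scale."""

    overall: float
    per_grade: dict[str, float]
    confusion: pd.DataFrame
    n: int


def grade_agreement(grades_a, grades_b) -> AgreementResult:
    """Observer agreement on ordinal grades.

    ``overall`` is the fraction of exact matches; ``per_grade`` conditions
    on observer A's grade (NaN for grades A never assigned).  The confusion
    table has A's grades as rows, B's as columns, counts as entries.
    """
    ra = grades_to_ranks(grades_a)
    rb = grades_to_ranks(grades_b)
    if ra.size != rb.size or ra.size == 0:
        raise ValueError("grade vectors must be paired and nonempty")
    k = len(GRADES)
    table = np.zeros((k, k), dtype=int)
    np.add.at(table, (ra, rb), 1)
    confusion = pd.DataFrame(table, index=list(GRADES), columns=list(GRADES))
    overall = float(np.mean(ra == rb))
    per_grade = {}
    for i, g in enumerate(GRADES):
        row = table[i]
        per_grade[g] = float(row[i] / row.sum()) if row.sum() else float("nan")
    return AgreementResult(
        overall=overall, per_grade=per_grade, confusion=confusion, n=int(ra.size)
    )


# --------------------------------------------------------------------------
# correlation


@dataclass
class CorrelationResult:
    """Spearman rank correlation with exact small-sample p-value."""

    rho: float
    pvalue: float
    n: int
    method: str
    degenerate: bool = False


def change_correlation(ff_changes, functional_changes, *, exact_max_n: int = 9):
    """Spearman correlation between paired change scores.

    Exact permutation p-value for n <= ``exact_max_n``; asymptotic
    otherwise.  A constant vector leaves rho undefined: the result is
    flagged degenerate with NaN rho.
    """
    x = np.asarray(ff_changes, float)
    y = np.asarray(functional_changes, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("change vectors must be paired 1D arrays")
    n = x.size
    if n < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if np.ptp(x[np.isfinite(x)]) == 0 or np.ptp(y[np.isfinite(y)]) == 0:
        return CorrelationResult(float("nan"), float("nan"), n, "degenerate", True)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if n <= exact_max_n:
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
        rho = float(rxc @ ryc / denom)
        perms = np.array(list(permutations(range(n))))
        rho_perm = (ryc[perms] @ rxc) / denom
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
        return CorrelationResult(rho, p, n, "exact")
    rho, p = sps.spearmanr(rx, ry)
    return CorrelationResult(float(rho), float(p), n, "asymptotic")


# --------------------------------------------------------------------------
# power simulation


@dataclass
class PowerResult:
    """Monte-Carlo power of one endpoint for one muscle or test."""

    endpoint: str
    name: str
    effect: float
    n: int
    replications: int
    power: float
    mc_se: float
    seed: int


def power_comparison(
    cspec: CohortSpec,
    *,
    alpha: float = 0.05,
    replications: int = 1000,
    seed: int = 0,
    endpoints: tuple[str, ...] = ("ff", "grade", "functional"),
) -> list[PowerResult]:
    """Estimate endpoint power by repeated cohort simulation.

    For each replication a fresh cohort is drawn from ``cspec`` and each
    endpoint is tested with the paired Wilcoxon signed-rank test at level
    ``alpha``: the continuous observed fat fraction and its ordinal-grade
    coarsening per muscle, and each functional test per cohort.  Power is
    the rejection fraction; ``mc_se`` its binomial Monte-Carlo standard
    error.  With all effects zero this estimates the attained type-I error.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if replications < 100:
        raise ValueError("use at least 100 replications for a stable estimate")
    rng = np.random.default_rng(seed)
    names = list(cspec.muscles)
    test_names = list(cspec.functional_tests)
    rej: dict[tuple[str, str], int] = {}
    for ep in endpoints:
        keys = test_names if ep == "functional" else names
        for k in keys:
            rej[(ep, k)] = 0

    for _ in range(replications):
        arr = _simulate_arrays(cspec, rng)
        if "ff" in endpoints or "grade" in endpoints:
            base_obs = arr["ff_observed"]["baseline"]
            fu_obs = arr["ff_observed"]["12month"]
            gb = arr["grade"]["baseline"]
            gf = arr["grade"]["12month"]
            for j, m in enumerate(names):
                if "ff" in endpoints:
                    r = wilcoxon_signed_rank(base_obs[:, j], fu_obs[:, j])
                    rej[("ff", m)] += r.pvalue < alpha
                if "grade" in endpoints:
                    r = wilcoxon_signed_rank(
                        grades_to_ranks(gb[:, j]).astype(float),
                        grades_to_ranks(gf[:, j]).astype(float),
                    )
                    rej[("grade", m)] += r.pvalue < alpha
        if "functional" in endpoints:
            for t in test_names:
                r = wilcoxon_signed_rank(
                    arr["functional"][t]["baseline"], arr["functional"][t]["12month"]
                )
                rej[("functional", t)] += r.pvalue < alpha

    out = []
    for (ep, name), count in rej.items():
        power = count / replications
        mc_se = float(np.sqrt(power * (1 - power) / replications))
        effect = (
            cspec.functional_tests[name].drift
            if ep == "functional"
            else cspec.muscles[name].progression_median
        )
        out.append(
            PowerResult(
                endpoint=ep,
                name=name,
                effect=float(effect),
                n=cspec.n_subjects,
                replications=replications,
                power=power,
                mc_se=mc_se,
                seed=seed,
            )
        )
    return out


# --------------------------------------------------------------------------
# multiple testing


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control).

    Emitted as a clearly labelled extension column; the primary analysis
    reports uncorrected per-muscle p-values.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, float)
    return multipletests(p, method="holm")[1]


# --------------------------------------------------------------------------
# longitudinal model


class LongitudinalModel:
    """Paired two-visit cohort analysis of per-muscle fat fractions.

    Built from a long-format CohortTable (columns ``subject_id, muscle,
    visit, ff_observed`` and optionally ``grade`` plus functional-test
    columns).  ``fit`` runs, per muscle, the paired Wilcoxon signed-rank
    test on observed fat fractions and on grade ranks, plus each functional
    test, and collects median/min/max summaries (medians because the
    Shapiro-Wilk screen typically rejects normality for bounded FF data;
    the per-muscle Shapiro-Wilk p-value is reported alongside).
    """

    def __init__(
        self,
        table: pd.DataFrame,
        *,
        value_col: str = "ff_observed",
        baseline: str = "baseline",
        followup: str = "12month",
    ):
        required = {"subject_id", "muscle", "visit", value_col}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
        visits = set(table["visit"].unique())
        if not {baseline, followup} <= visits:
            raise ValueError(
                f"cohort table must contain visits {baseline!r} and {followup!r}"
            )
        self.table = table.copy()
        self.value_col = value_col
        self.baseline = baseline
        self.followup = followup
        self.functional_tests = [
            c for c in table.columns if c not in TABLE_COLUMNS and c != value_col
        ]

    @classmethod
    def from_csv(cls, path, **kw) -> "LongitudinalModel":
        return cls(pd.read_csv(path), **kw)

    def _paired(
        self, col: str, table: pd.DataFrame | None = None
    ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        if table is None:
            table = self.table
        wide = table.pivot_table(
            index=["subject_id", "muscle"],
            columns="visit",
            values=col,
            aggfunc="first",
        )
        out = {}
        for muscle, grp in wide.groupby(level="muscle"):
            sub = grp.dropna(subset=[self.baseline, self.followup])
            out[str(muscle)] = (
                sub[self.baseline].to_numpy(float),
                sub[self.followup].to_numpy(float),
            )
        return out

    def fit(self, alpha: float = 0.05) -> "LongitudinalResults":
        ff_rows = []
        paired = self._paired(self.value_col)
        for muscle, (b, f) in paired.items():
            res = wilcoxon_signed_rank(b, f)
            try:
                _, sw_p = shapiro_wilk(np.concatenate([b, f]))
            except ValueError:
                sw_p = float("nan")
            ff_rows.append(
                {
                    "muscle": muscle,
                    "n": b.size,
                    "baseline_min": b.min(),
                    "baseline_max": b.max(),
                    "baseline_median": np.median(b),
                    "followup_min": f.min(),
                    "followup_max": f.max(),
                    "followup_median": np.median(f),
                    "median_change": np.median(f - b),
                    "pvalue": res.pvalue,
                    "significant": res.pvalue < alpha,
                    "shapiro_p": sw_p,
                    "wilcoxon_method": res.method,
                }
            )
        ff_table = pd.DataFrame(ff_rows).set_index("muscle")
        if len(ff_table):
            ff_table["pvalue_holm"] = holm_adjust(ff_table["pvalue"].to_numpy())

        grade_table = None
        if "grade" in self.table.columns:
            grade_rows = []
            tb = self.table.copy()
            tb["_grade_rank"] = grades_to_ranks(tb["grade"].to_numpy()).astype(float)
            for muscle, (b, f) in self._paired("_grade_rank", tb).items():
                res = wilcoxon_signed_rank(b, f)
                diff = f - b
                grade_rows.append(
                    {
                        "muscle": muscle,
                        "n": b.size,
                        "baseline_median_grade": _median_grade(b),
                        "followup_median_grade": _median_grade(f),
                        "n_same": int(np.sum(diff == 0)),
                        "n_increased": int(np.sum(diff > 0)),
                        "n_decreased": int(np.sum(diff < 0)),
                        "pvalue": res.pvalue,
                        "significant": res.pvalue < alpha,
                    }
                )
            grade_table = pd.DataFrame(grade_rows).set_index("muscle")

        func_rows = []
        for test in self.functional_tests:
            sub = self.table.drop_duplicates(subset=["subject_id", "visit"])
            wide = sub.pivot(index="subject_id", columns="visit", values=test)
            wide = wide.dropna(subset=[self.baseline, self.followup])
            b = wide[self.baseline].to_numpy(float)
            f = wide[self.followup].to_numpy(float)
            res = wilcoxon_signed_rank(b, f)
            func_rows.append(
                {
                    "test": test,
                    "n": b.size,
                    "baseline_min": b.min(),
                    "baseline_max": b.max(),
                    "baseline_median": np.median(b),
                    "followup_min": f.min(),
                    "followup_max": f.max(),
                    "followup_median": np.median(f),
                    "pvalue": res.pvalue,
                    "significant": res.pvalue < alpha,
                }
            )
        functional_table = (
            pd.DataFrame(func_rows).set_index("test") if func_rows else None
        )

        return LongitudinalResults(
            model=self,
            alpha=alpha,
            ff_table=ff_table,
            grade_table=grade_table,
            functional_table=functional_table,
        )


def _median_grade(ranks: np.ndarray) -> str:
    """Median of grade ranks mapped back to a symbol (lower of midpair)."""
    med = np.median(ranks)
    return GRADES[int(np.floor(med))]


@dataclass
class LongitudinalResults:
    """Per-muscle, per-grade and per-functional-test longitudinal results."""

    model: LongitudinalModel
    alpha: float
    ff_table: pd.DataFrame
    grade_table: pd.DataFrame | None
    functional_table: pd.DataFrame | None

    @property
    def significant_muscles(self) -> list[str]:
        """Muscles with a significant fat-fraction change at the set alpha."""
        return list(self.ff_table.index[self.ff_table["significant"]])

    def summary(self) -> str:
        lines = [
            "Longitudinal paired analysis (Wilcoxon signed-rank, two-sided)",
            "=" * 62,
            f"alpha = {self.alpha}; n muscles = {len(self.ff_table)}; "
            f"significant FF change in {len(self.significant_muscles)} "
            f"of {len(self.ff_table)} muscles",
            "",
            "Fat fraction (%) by muscle",
            "-" * 62,
        ]
        hdr = (
            f"{'muscle':<8}{'base med':>9}{'fu med':>8}{'change':>8}"
            f"{'p':>8}{'p(Holm)':>9}  sig"
        )
        lines.append(hdr)
        for muscle, r in self.ff_table.iterrows():
            lines.append(
                f"{muscle:<8}{r['baseline_median']:>9.1f}{r['followup_median']:>8.1f}"
                f"{r['median_change']:>8.1f}{r['pvalue']:>8.3f}"
                f"{r['pvalue_holm']:>9.3f}  {'*' if r['significant'] else ''}"
            )
        if self.grade_table is not None:
            lines += ["", "Ordinal grades by muscle", "-" * 62]
            lines.append(
                f"{'muscle':<8}{'base':>6}{'fu':>6}{'same/inc/dec':>14}{'p':>8}"
            )
            for muscle, r in self.grade_table.iterrows():
                lines.append(
                    f"{muscle:<8}{r['baseline_median_grade']:>6}"
                    f"{r['followup_median_grade']:>6}"
                    f"{r['n_same']:>6}/{r['n_increased']}/{r['n_decreased']:<4}"
                    f"{r['pvalue']:>8.3f}"
                )
        if self.functional_table is not None:
            lines += ["", "Functional tests", "-" * 62]
            for test, r in self.functional_table.iterrows():
                fmax = "inf" if np.isinf(r["followup_max"]) else f"{r['followup_max']:.1f}"
                lines.append(
                    f"{test:<22} base med {r['baseline_median']:.1f} "
                    f"-> fu med {r['followup_median']:.1f} (fu max {fmax}), "
                    f"p = {r['pvalue']:.3f}"
                )
        return "\n".join(lines)

    def plot_changes(self, ax=None):
        """Box plot of per-subject fat-fraction changes by muscle."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        paired = self.model._paired(self.model.value_col)
        data = [f - b for (b, f) in paired.values()]
        ax.boxplot(data, tick_labels=list(paired))
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_ylabel("12-month FF change (% points)")
        ax.tick_params(axis="x", rotation=60)
        return ax
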