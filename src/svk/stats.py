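"""Association statistics: slope ANOVA, compact letter displays, Tukey HSD,
and exponential growth regression of vitreousness on chain dispersity."""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

log = logging.getLogger("svk")


@dataclass
class SlopeTestResult:
    """OLS slope with the F-test of slope = 0 (equivalently the two-sided
    t-test on the slope)."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass
class LetterGrouping:
    """Compact letter display: groups sharing a letter are not significantly
    different at the chosen alpha."""

    letters: dict[str, str]
    p_values: pd.DataFrame
    means: dict[str, float]
    alpha: float

    def consistent(self) -> bool:
        """Check the share-letter <=> non-significant biconditional."""
        labels = list(self.letters)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                share = bool(set(self.letters[a]) & set(self.letters[b]))
                non_sig = self.p_values.loc[a, b] >= self.alpha
                if share != non_sig:
                    return False
        return True


@dataclass
class ExpGrowthFit:
    """Least-squares fit of y = a * exp(r * x) with a Wald CI on r."""

    amplitude: float
    growth_rate: float
    ci_lower: float
    ci_upper: float
    residual_se: float
    converged: bool
    iterations: int
    n: int

    @property
    def significant_positive(self) -> bool:
        return self.ci_lower > 0


def slope_anova(x, y) -> SlopeTestResult:
    """Ordinary least squares of y on x; p-value from the F(1, n-2) statistic
    for the slope, which equals the two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"slope_anova requires n >= 3, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = stats.linregress(x, y)
    return SlopeTestResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=n,
    )


def _validate_groups(groups: dict[str, list[float]]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out = {}
    for label, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {label!r} has n < 2")
        out[label] = arr
    return out


def _letters_from_pvalues(
    p: pd.DataFrame, means: dict[str, float], alpha: float
) -> dict[str, str]:
    """Insert-and-absorb compact-letter-display algorithm.

    Start with one letter column holding every group; for each significant
    pair split any column containing both; absorb redundant columns; assign
    letters with groups ordered by decreasing mean.
    """
    order = sorted(means, key=lambda g: -means[g])
    columns: list[set[str]] = [set(order)]
    for i, a in enumerate(order):
        for b in order[i + 1 :]:
            if p.loc[a, b] < alpha:
                for col in [c for c in columns if a in c and b in c]:
                    columns.remove(col)
                    for dropped in (a, b):
                        new = col - {dropped}
                        if not any(new <= other for other in columns):
                            columns.append(new)
    # absorb subsets (defensive; the insert step already avoids most)
    columns = [
        c for c in columns if not any(c < other for other in columns)
    ]
    # order columns by the best-ranked group they contain, assign letters
    rank = {g: i for i, g in enumerate(order)}
    columns.sort(key=lambda c: min(rank[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in order}
    for idx, col in enumerate(columns):
        for g in order:
            if g in col:
                letters[g] += alphabet[idx % len(alphabet)]
    return letters


def pairwise_t_letters(groups: dict[str, list[float]], alpha: float = 0.05) -> LetterGrouping:
    """All pairwise pooled-variance two-tailed t-tests (no multiplicity
    correction) with a compact letter display."""
    arrays = _validate_groups(groups)
    labels = list(arrays)
    p = pd.DataFrame(1.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            res = stats.ttest_ind(arrays[a], arrays[b], equal_var=True)
            p.loc[a, b] = p.loc[b, a] = float(res.pvalue)
    means = {g: float(arrays[g].mean()) for g in labels}
    return LetterGrouping(
        letters=_letters_from_pvalues(p, means, alpha),
        p_values=p,
        means=means,
        alpha=alpha,
    )


def tukey_hsd(groups: dict[str, list[float]], alpha: float = 0.05) -> LetterGrouping:
    """All-pairs Tukey HSD (studentized-range adjusted p) with letters."""
    arrays = _validate_groups(groups)
    labels = list(arrays)
    res = stats.tukey_hsd(*(arrays[g] for g in labels))
    p = pd.DataFrame(1.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                p.loc[a, b] = float(res.pvalue[i, j])
    means = {g: float(arrays[g].mean()) for g in labels}
    return LetterGrouping(
        letters=_letters_from_pvalues(p, means, alpha),
        p_values=p,
        means=means,
        alpha=alpha,
    )


def fit_exponential_growth(
    pdi,
    vitreousness,
    alpha: float = 0.05,
    max_iterations: int = 10000,
) -> ExpGrowthFit:
    """Fit V = a * exp(r * PDI) by Levenberg-Marquardt least squares.

    Initialization comes from a log-linear regression of log(max(V, eps)) on
    PDI.  The CI on the growth rate is the approximate (Wald) interval
    r_hat +- t(1 - alpha/2, n-2) * SE(r_hat) from the asymptotic covariance.
    """
    x = np.asarray(pdi, dtype=float)
    y = np.asarray(vitreousness, dtype=float)
    if x.shape != y.shape:
        raise ValueError("pdi and vitreousness must have equal length")
    n = x.size
    if n < 4:
        raise ValueError(f"fit_exponential_growth requires n >= 4, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("pdi values are all equal; growth rate undefined")

    eps = max(1e-12, 1e-9 * max(abs(float(y.max())), 1.0))
    logy = np.log(np.maximum(y, eps))
    r0, loga0 = np.polyfit(x, logy, 1)
    a0 = math.exp(loga0)

    def model(x_, a, r):
        return a * np.exp(r * x_)

    converged = True
    iterations = 0
    try:
        with warnings.catch_warnings():
            # an inestimable covariance is handled explicitly below
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov, infodict, _, ier = optimize.curve_fit(
                model, x, y, p0=[a0, r0], maxfev=max_iterations, full_output=True
            )
        iterations = int(infodict["nfev"])
        converged = ier in (1, 2, 3, 4)
    except RuntimeError:
        popt = np.array([a0, r0])
        pcov = np.full((2, 2), np.nan)
        converged = False
        iterations = max_iterations

    a_hat, r_hat = float(popt[0]), float(popt[1])
    residuals = y - model(x, a_hat, r_hat)
    dof = n - 2
    residual_se = float(np.sqrt(residuals @ residuals / dof))
    if converged and not np.isfinite(pcov).all():
        # curve_fit occasionally reports an inestimable covariance even at a
        # clean optimum (e.g. zero residuals); rebuild it from the analytic
        # Jacobian: cov = s^2 (J'J)^-1
        exp_term = np.exp(r_hat * x)
        jac = np.column_stack([exp_term, a_hat * x * exp_term])
        jtj = jac.T @ jac
        if np.linalg.matrix_rank(jtj) == 2:
            pcov = residual_se**2 * np.linalg.inv(jtj)
    if converged and np.isfinite(pcov).all():
        se_r = float(np.sqrt(pcov[1, 1]))
        tcrit = stats.t.ppf(1 - alpha / 2, dof)
        ci_lower, ci_upper = r_hat - tcrit * se_r, r_hat + tcrit * se_r
    else:
        ci_lower = ci_upper = math.nan
        converged = False
    return ExpGrowthFit(
        amplitude=a_hat,
        growth_rate=r_hat,
        ci_lower=ci_lower,
        ci_upper=ci_upper,
        residual_se=residual_se,
        converged=converged,
        iterations=iterations,
        n=n,
    )


@dataclass
class AssociationReport:
    """Bundle of every analysis the association stage produces."""

    pullulanase_vs_vitreousness: SlopeTestResult
    letters_t: dict[str, LetterGrouping] = field(default_factory=dict)
    letters_tukey: dict[str, LetterGrouping] = field(default_factory=dict)
    acl_vs_pdi: SlopeTestResult | None = None
    vitreousness_exp_fit: ExpGrowthFit | None = None
    extra_slopes: dict[str, SlopeTestResult] = field(default_factory=dict)

    def to_summary(self) -> dict:
        def slope_dict(s: SlopeTestResult | None):
            if s is None:
                return None
            return {
                "slope": s.slope,
                "intercept": s.intercept,
                "r_squared": s.r_squared,
                "p_value": s.p_value,
                "n": s.n,
            }

        summary = {
            "pullulanase_vs_vitreousness": slope_dict(self.pullulanase_vs_vitreousness),
            "acl_vs_pdi": slope_dict(self.acl_vs_pdi),
            "letters_t": {k: v.letters for k, v in self.letters_t.items()},
            "letters_tukey": {k: v.letters for k, v in self.letters_tukey.items()},
            "extra_slopes": {k: slope_dict(v) for k, v in self.extra_slopes.items()},
        }
        fit = self.vitreousness_exp_fit
        if fit is not None:
            summary["vitreousness_exp_fit"] = {
                "amplitude": fit.amplitude,
                "growth_rate": fit.growth_rate,
                "ci_lower": fit.ci_lower,
                "ci_upper": fit.ci_upper,
                "residual_se": fit.residual_se,
                "converged": fit.converged,
                "n": fit.n,
            }
        return summary


def run_association_suite(panel, summaries, alpha: float = 0.05) -> AssociationReport:
    """Run the full statistical battery on a joined panel.

    ``panel`` is a list of phenotype records (one per RIL x ear);
    ``summaries`` is a list of chain-length DistributionSummary whose
    sample_id matches ril_id.  Group means in letter displays are means over
    RIL means (each RIL first averaged over its ears).
    """
    if not panel:
        raise ValueError("empty phenotype panel")
    rows = []
    for rec in panel:
        rows.append(
            {
                "ril_id": rec.ril_id,
                "genotype": rec.genotype_class,
                "ear": rec.ear,
                "vitreousness": rec.vitreousness,
                "pullulanase_a490": rec.pullulanase_a490,
                "onset_c": rec.onset_c,
                "max_c": rec.max_c,
                "enthalpy": rec.enthalpy,
                "density": rec.density,
                "hardness": rec.hardness,
            }
        )
    df = pd.DataFrame(rows)
    required = ["vitreousness", "pullulanase_a490"]
    fully_missing = [c for c in required if df[c].isna().all()]
    if fully_missing:
        raise ValueError(f"panel is missing required measurements: {fully_missing}")

    chain = pd.DataFrame(
        {"ril_id": s.sample_id, "pdi": s.pdi, "acl": s.acl} for s in summaries
    )

    # RIL means over ears, then join per-RIL chain summaries
    ril = df.groupby(["ril_id", "genotype"], as_index=False).mean(numeric_only=True)
    if not chain.empty:
        ril = ril.merge(chain, on="ril_id", how="left")

    report = AssociationReport(
        pullulanase_vs_vitreousness=slope_anova(
            ril["vitreousness"], ril["pullulanase_a490"]
        )
    )

    letter_traits = ["pullulanase_a490", "onset_c", "max_c", "enthalpy"]
    if "acl" in ril.columns:
        letter_traits.append("acl")
    for trait in letter_traits:
        values = ril.dropna(subset=[trait])
        groups = {
            g: sub[trait].tolist() for g, sub in values.groupby("genotype")
        }
        groups = {g: v for g, v in groups.items() if len(v) >= 2}
        if len(groups) >= 2:
            report.letters_t[trait] = pairwise_t_letters(groups, alpha)
            report.letters_tukey[trait] = tukey_hsd(groups, alpha)

    if "pdi" in ril.columns and ril["pdi"].notna().sum() >= 4:
        sub = ril.dropna(subset=["pdi", "acl"])
        report.acl_vs_pdi = slope_anova(sub["pdi"], sub["acl"])
        sub = ril.dropna(subset=["pdi", "vitreousness"])
        report.vitreousness_exp_fit = fit_exponential_growth(
            sub["pdi"], sub["vitreousness"], alpha=alpha
        )

    for col in ("density", "hardness"):
        sub = ril.dropna(subset=[col, "pullulanase_a490"])
        if len(sub) >= 3 and np.ptp(sub[col].to_numpy()) > 0:
            report.extra_slopes[f"pullulanase_vs_{col}"] = slope_anova(
                sub[col], sub["pullulanase_a490"]
            )
    return report
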