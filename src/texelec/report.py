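"""Statistical comparison workflow, conductivity, and study report assembly.

Group comparisons follow a fixed decision tree.  First the assumptions are
checked: normality of the pooled group residuals (Shapiro-Wilk below 50
observations, Kolmogorov-Smirnov otherwise) and homoscedasticity (Levene),
both at alpha = 0.05.  If both hold, a parametric test is dispatched
(one-way ANOVA for independent groups, paired t for two paired groups,
repeated-measures ANOVA otherwise); if either fails, the nonparametric
counterpart runs instead (Kruskal-Wallis for more than two groups, Wilcoxon
rank-sum / signed-rank for two).  No multiple-testing correction is applied
by default; a Holm adjustment helper is available for users who want one.

Sheet conductivity converts a fabric sample's surface resistance
``R_s`` (ohm/square) and thickness ``t`` (meter) into a bulk conductivity:
``rho = R_s * t`` is the resistivity, so ``sigma = 1 / (R_s * t)``,
reported in S/cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SheetSample",
    "AssumptionCheck",
    "ComparisonResult",
    "assumption_check",
    "compare",
    "conductivity",
    "holm_adjust",
    "build_report",
]

ALPHA = 0.05


@dataclass(frozen=True)
class SheetSample:
    """Conductive-fabric sample: surface resistance (ohm/sq), thickness (m)."""

    surface_resistance: float
    thickness: float

    def __post_init__(self) -> None:
        if not (self.surface_resistance > 0 and self.thickness > 0):
            raise ValueError("surface resistance and thickness must be > 0")


def conductivity(sample: SheetSample) -> float:
    """Bulk conductivity in S/cm from sheet resistance and thickness.

    ``sigma = 1 / (R_s * t)`` in S/m, divided by 100 for S/cm.  (The product
    ``R_s * t`` itself is the resistivity in ohm-m, not a conductivity —
    the inverse is what carries the stated units.)
    """
    return 1.0 / (sample.surface_resistance * sample.thickness) / 100.0


# ----------------------------------------------------------------- statistics


@dataclass
class AssumptionCheck:
    normal: bool
    normality_p: float
    normality_test: str
    homoscedastic: bool
    levene_p: float
    degenerate: bool = False

    @property
    def parametric_ok(self) -> bool:
        return self.normal and self.homoscedastic and not self.degenerate


def _as_groups(groups) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    for g in out:
        if g.size < 3:
            raise ValueError("each group needs at least 3 observations")
    return out


def assumption_check(groups) -> AssumptionCheck:
    """Normality and homoscedasticity screen for a set of groups.

    Normality is tested on the pooled within-group residuals (each group
    centered on its own mean): Shapiro-Wilk when the pooled n is below 50,
    otherwise a Kolmogorov-Smirnov test against a normal with the residuals'
    moments.  Homoscedasticity uses Levene's test on the raw groups.  A
    group with zero variance makes the homoscedasticity question degenerate;
    the result is flagged and ``parametric_ok`` is False.
    """
    gs = _as_groups(groups)
    resid = np.concatenate([g - g.mean() for g in gs])
    n = resid.size
    if np.ptp(resid) == 0 or any(np.ptp(g) == 0 for g in gs):
        return AssumptionCheck(
            normal=False,
            normality_p=np.nan,
            normality_test="degenerate",
            homoscedastic=False,
            levene_p=np.nan,
            degenerate=True,
        )
    if n < 50:
        stat_name = "shapiro"
        p_norm = float(stats.shapiro(resid).pvalue)
    else:
        stat_name = "ks"
        p_norm = float(
            stats.kstest(resid, "norm", args=(resid.mean(), resid.std(ddof=1))).pvalue
        )
    p_lev = float(stats.levene(*gs).pvalue)
    return AssumptionCheck(
        normal=p_norm > ALPHA,
        normality_p=p_norm,
        normality_test=stat_name,
        homoscedastic=p_lev > ALPHA,
        levene_p=p_lev,
    )


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    pvalue: float
    assumptions: AssumptionCheck
    design: str
    n_groups: int


def select_test(parametric_ok: bool, n_groups: int, design: str) -> str:
    """The decision tree as a pure function of its inputs.

    ==============  ========  ===========  =====================
    parametric_ok   n_groups  design       test
    ==============  ========  ===========  =====================
    True            2         independent  anova (one-way)
    True            2         paired       t_paired
    True            >2        independent  anova (one-way)
    True            any       repeated     anova_rm
    False           2         independent  wilcoxon_ranksum
    False           2         paired       wilcoxon_signedrank
    False           >2        any          kruskal
    ==============  ========  ===========  =====================
    """
    if design not in ("independent", "paired", "repeated"):
        raise ValueError("design must be independent, paired or repeated")
    if parametric_ok:
        if design == "repeated":
            return "anova_rm"
        if design == "paired" and n_groups == 2:
            return "t_paired"
        return "anova"
    if n_groups == 2:
        if design in ("paired", "repeated"):
            return "wilcoxon_signedrank"
        return "wilcoxon_ranksum"
    return "kruskal"


def compare(groups, design: str = "independent", checks: AssumptionCheck | None = None) -> ComparisonResult:
    """Dispatch and run the comparison prescribed by the decision tree.

    Parameters
    ----------
    groups : sequence of sequences
        One array of observations per group (equal lengths required for
        paired/repeated designs).
    design : {"independent", "paired", "repeated"}
    checks : AssumptionCheck, optional
        Reuse a previously run assumption screen; computed here otherwise.
    """
    gs = _as_groups(groups)
    if checks is None:
        checks = assumption_check(gs)
    if design in ("paired", "repeated") and len({g.size for g in gs}) != 1:
        raise ValueError("paired/repeated designs require equal group sizes")
    name = select_test(checks.parametric_ok, len(gs), design)
    if name == "anova":
        res = stats.f_oneway(*gs)
    elif name == "t_paired":
        res = stats.ttest_rel(gs[0], gs[1])
    elif name == "anova_rm":
        res = _anova_rm(gs)
    elif name == "wilcoxon_ranksum":
        res = stats.ranksums(gs[0], gs[1])
    elif name == "wilcoxon_signedrank":
        res = stats.wilcoxon(gs[0], gs[1])
    else:
        res = stats.kruskal(*gs)
    return ComparisonResult(
        test=name,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        assumptions=checks,
        design=design,
        n_groups=len(gs),
    )


def _anova_rm(gs: list[np.ndarray]):
    """One-within-factor repeated-measures ANOVA via statsmodels."""
    from statsmodels.stats.anova import AnovaRM

    n = gs[0].size
    df = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), len(gs)),
            "condition": np.repeat(np.arange(len(gs)), n),
            "value": np.concatenate(gs),
        }
    )
    tab = AnovaRM(df, "value", "subject", within=["condition"]).fit().anova_table
    class _R:  # scipy-like result shim
        statistic = float(tab["F Value"].iloc[0])
        pvalue = float(tab["Pr > F"].iloc[0])
    return _R()


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (off by default in the workflow)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


# -------------------------------------------------------------------- report


@dataclass
class StudyReport:
    sections: dict = field(default_factory=dict)

    def to_markdown(self) -> str:
        lines = ["# Electrode characterization report", ""]
        for name, content in self.sections.items():
            lines.append(f"## {name}")
            lines.append("")
            if isinstance(content, pd.DataFrame):
                lines.append(content.to_markdown(index=False))
            elif isinstance(content, dict):
                for k, v in content.items():
                    lines.append(f"- **{k}**: {v}")
            else:
                lines.append(str(content))
            lines.append("")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {}
        for name, content in self.sections.items():
            if isinstance(content, pd.DataFrame):
                out[name] = content.to_dict(orient="records")
            else:
                out[name] = content
        return out


def build_report(
    impedance=None,
    polarization=None,
    noise=None,
    longterm=None,
    comparisons=None,
) -> StudyReport:
    """Assemble stage outputs into a deterministic study report.

    Each argument is optional; missing stages are marked absent and the run
    continues.  At least one stage must be present.

    Parameters
    ----------
    impedance : DataFrame or dict
        Per-material AUC scores / spectra summaries.
    polarization : DataFrame or dict
        Per-subject/material polarization level and exchange ratio.
    noise : DataFrame or dict
        Noise power, Pearson similarity and error-rate metrics.
    longterm : LongTermSummary or DataFrame
        Error distributions over wear time.
    comparisons : dict of ComparisonResult
        Statistical tests keyed by the question they answer.
    """
    stages = {
        "Contact impedance": impedance,
        "Polarization": polarization,
        "Noise and fidelity": noise,
        "Long-term performance": longterm,
    }
    if all(v is None for v in stages.values()) and not comparisons:
        raise ValueError("no stage outputs provided")
    report = StudyReport()
    for name, content in stages.items():
        if content is None:
            report.sections[name] = "absent"
            continue
        if hasattr(content, "table"):  # LongTermSummary
            content = content.table
        report.sections[name] = content
    if comparisons:
        report.sections["Statistical comparisons"] = {
            key: f"{r.test}: statistic={r.statistic:.4g}, p={r.pvalue:.4g}"
            for key, r in comparisons.items()
        }
    return report
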