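"""Group statistics over FOV-level metrics.

The experimental unit is the field of view; reported n values are FOV
counts.  Independent groups are compared with the Mann-Whitney U test,
matched samples with the Wilcoxon signed-rank test, and lesion-group × time
designs with a two-way mixed ANOVA whose significant interactions are
followed by Bonferroni-corrected within-group paired t-tests against
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ComparisonResult:
    test: str
    n1: int
    n2: int
    statistic: float
    p_value: float
    corrected_p: float | None = None
    direction: str = ""  # "a>b", "a<b", ""

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")
        if self.corrected_p is not None and self.corrected_p < self.p_value:
            raise ValueError("corrected_p must be >= p_value")


def significance_stars(p: float) -> str:
    """Figure nomenclature: * <0.05, ** <0.01, *** <0.005, **** <0.001."""
    if p < 0.001:
        return "****"
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def bonferroni(p_values) -> np.ndarray:
    """min(1, m·p) for a family of m comparisons."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(1.0, p * p.size)


def compare_independent(a, b) -> ComparisonResult:
    """Two-sided Mann-Whitney U test for independent groups."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs n >= 3")
    if np.unique(np.concatenate([a, b])).size == 1:
        raise ValueError("degenerate input: all values tied")
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    direction = "a>b" if np.median(a) > np.median(b) else (
        "a<b" if np.median(a) < np.median(b) else "")
    return ComparisonResult("mann-whitney", a.size, b.size,
                            float(res.statistic), float(res.pvalue),
                            direction=direction)


def compare_paired(before, after) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test for matched samples."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.size != after.size:
        raise ValueError("paired samples must have equal lengths")
    d = after - before
    nz = np.count_nonzero(d)
    if nz == 0:
        raise ValueError("degenerate input: all paired differences are zero")
    if nz < 5:
        raise ValueError("need >= 5 non-zero paired differences")
    res = sps.wilcoxon(after, before, alternative="two-sided")
    med = np.median(d)
    direction = "a<b" if med > 0 else ("a>b" if med < 0 else "")
    return ComparisonResult("wilcoxon", before.size, after.size,
                            float(res.statistic), float(res.pvalue),
                            direction=direction)


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    between: str,
    within: str,
    subject: str,
    baseline_level=None,
    alpha: float = 0.05,
) -> dict:
    """Two-way mixed ANOVA (between group × repeated time, FOV as subject).

    Reports the interaction F and p (Greenhouse-Geisser corrected when the
    repeated factor has more than two levels and sphericity is violated).
    When the interaction is significant at ``alpha``, runs within-group
    paired t-tests of each time level against ``baseline_level`` (default:
    first level in sorted order), Bonferroni-corrected over the whole family.
    """
    import pingouin as pg

    counts = data.groupby([between, within])[dv].count()
    if (counts < 2).any():
        raise ValueError("singleton or empty cell in the design")
    n_within = data[within].nunique()
    aov = pg.mixed_anova(data=data, dv=dv, between=between, within=within,
                         subject=subject, correction=n_within > 2)
    aov = aov.rename(columns={c: c.replace("-", "_") for c in aov.columns})
    inter = aov[aov.Source == "Interaction"].iloc[0]
    p_int = float(inter["p_unc"])
    if n_within > 2 and "p_GG_corr" in aov.columns:
        # GG correction applies to within/interaction terms when sphericity fails
        p_gg = inter.get("p_GG_corr", np.nan)
        if np.isfinite(p_gg):
            p_int = float(p_gg)
    result = {
        "anova": aov,
        "interaction_F": float(inter["F"]),
        "interaction_p": p_int,
        "posthoc": None,
    }
    if p_int < alpha:
        levels = sorted(data[within].unique())
        base = baseline_level if baseline_level is not None else levels[0]
        rows = []
        for g, sub in data.groupby(between):
            wide = sub.pivot_table(index=subject, columns=within, values=dv)
            for lvl in levels:
                if lvl == base:
                    continue
                pair = wide[[base, lvl]].dropna()
                t, p = sps.ttest_rel(pair[lvl], pair[base])
                rows.append({"group": g, "level": lvl, "vs": base,
                             "n": len(pair), "t": float(t), "p_unc": float(p)})
        ph = pd.DataFrame(rows)
        ph["p_bonf"] = bonferroni(ph["p_unc"].to_numpy())
        ph["stars"] = ph["p_bonf"].map(significance_stars)
        result["posthoc"] = ph
    return result


def turning_bias(ipsi: int, contra: int, straight: int = 0,
                 total_turns: int | None = None,
                 include_straight: bool = True) -> float:
    """Turning bias index: (ipsiversive − contraversive) / total turns.

    By default the denominator counts straight passes; set
    ``include_straight=False`` to restrict it to turns only.
    """
    if ipsi < 0 or contra < 0 or straight < 0:
        raise ValueError("counts must be non-negative")
    if total_turns is None:
        total_turns = ipsi + contra + (straight if include_straight else 0)
    if total_turns < ipsi + contra or ipsi + contra == 0:
        raise ValueError("need total_turns >= ipsi + contra > 0")
    return (ipsi - contra) / total_turns
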