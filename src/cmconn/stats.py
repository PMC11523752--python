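"""Group comparisons: assumption checks, ANOVA + Bonferroni, t-tests, and the
four connectivity studies.

Two levels are compared with a two-sample t-test; three or more with a
one-way ANOVA followed by all pairwise t-tests under Bonferroni correction
(corrected p = min(1, raw p x number of comparisons)).  The unit of analysis
for every study is the subject-level aggregate (mean over trials).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AssumptionReport",
    "GroupComparisonResult",
    "bonferroni",
    "check_assumptions",
    "compare_groups",
    "run_studies",
]

ALPHA = 0.05


def bonferroni(p: float, n_comparisons: int) -> float:
    return min(1.0, p * n_comparisons)


@dataclass
class AssumptionReport:
    normality_test: str
    normality_p: dict[str, float]
    levene_p: float

    @property
    def all_pass(self) -> bool:
        return self.levene_p > ALPHA and all(p > ALPHA for p in self.normality_p.values())


@dataclass
class GroupComparisonResult:
    factor: str
    levels: list[str]
    method: str  # "anova+bonferroni" or "two-sample t-test"
    statistic: float
    p_value: float
    pairwise: pd.DataFrame  # level_a, level_b, p_raw, p_corrected, significant
    assumptions: AssumptionReport | None = None
    group_means: dict[str, float] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _ks_normal(x: np.ndarray) -> float:
    """One-sample KS test against a normal fitted by moments."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(sps.kstest(x, "norm", args=(x.mean(), sd)).pvalue)


def check_assumptions(
    groups: dict[str, np.ndarray], normality: str = "shapiro"
) -> AssumptionReport:
    """Per-group normality (Shapiro-Wilk or one-sample KS) + Levene homogeneity."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, g in groups.items():
        if len(np.asarray(g)) < 3:
            raise ValueError(f"group {name!r} has fewer than 3 observations")
    norm_p: dict[str, float] = {}
    for name, g in groups.items():
        g = np.asarray(g, dtype=float)
        if normality == "shapiro":
            norm_p[name] = float(sps.shapiro(g).pvalue)
        elif normality == "ks":
            norm_p[name] = _ks_normal(g)
        else:
            raise ValueError("normality must be 'shapiro' or 'ks'")
    lev = float(sps.levene(*[np.asarray(g, dtype=float) for g in groups.values()]).pvalue)
    return AssumptionReport(normality_test=normality, normality_p=norm_p, levene_p=lev)


def compare_groups(
    values: np.ndarray,
    labels: np.ndarray,
    paired: bool = False,
    factor: str = "group",
    normality: str = "shapiro",
) -> GroupComparisonResult:
    """Omnibus + Bonferroni-corrected pairwise comparison across factor levels."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    levels = [str(l) for l in pd.unique(labels)]
    if len(levels) < 2:
        raise ValueError("need at least two levels to compare")
    groups = {lv: values[labels == lv] for lv in levels}
    for lv, g in groups.items():
        if len(g) == 0:
            raise ValueError(f"level {lv!r} has no observations")
    assumptions = None
    if all(len(g) >= 3 for g in groups.values()):
        assumptions = check_assumptions(groups, normality=normality)

    def _pair_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
        if paired:
            res = sps.ttest_rel(a, b)
        else:
            res = sps.ttest_ind(a, b)
        return float(res.statistic), float(res.pvalue)

    if len(levels) == 2:
        stat, p = _pair_test(groups[levels[0]], groups[levels[1]])
        pairwise = pd.DataFrame(
            [{"level_a": levels[0], "level_b": levels[1], "p_raw": p,
              "p_corrected": p, "significant": p < ALPHA}]
        )
        method = "two-sample t-test" if not paired else "paired t-test"
        omni_stat, omni_p = stat, p
    else:
        arrays = [groups[lv] for lv in levels]
        f = sps.f_oneway(*arrays)
        omni_stat, omni_p = float(f.statistic), float(f.pvalue)
        pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
        rows = []
        for a, b in pairs:
            _, p = _pair_test(groups[a], groups[b])
            pc = bonferroni(p, len(pairs))
            rows.append({"level_a": a, "level_b": b, "p_raw": p,
                         "p_corrected": pc, "significant": pc < ALPHA})
        pairwise = pd.DataFrame(rows)
        method = "anova+bonferroni"
    return GroupComparisonResult(
        factor=factor,
        levels=levels,
        method=method,
        statistic=omni_stat,
        p_value=omni_p,
        pairwise=pairwise,
        assumptions=assumptions,
        group_means={lv: float(g.mean()) for lv, g in groups.items()},
    )


def _result_rows(res: GroupComparisonResult, **keys) -> list[dict]:
    rows = []
    base = dict(keys)
    base.update(
        {
            "method": res.method,
            "omnibus_stat": res.statistic,
            "omnibus_p": res.p_value,
            "significant": res.significant,
        }
    )
    for lv, m in res.group_means.items():
        base[f"mean[{lv}]"] = m
    for _, pr in res.pairwise.iterrows():
        row = dict(base)
        row.update(
            {
                "level_a": pr["level_a"],
                "level_b": pr["level_b"],
                "p_corrected": pr["p_corrected"],
                "pair_significant": pr["significant"],
            }
        )
        rows.append(row)
    return rows


def run_studies(
    pbc_records: pd.DataFrame | None,
    mi_table: pd.DataFrame | None,
    normality: str = "shapiro",
    mi_task_window: tuple[float, float] = (2.0, 8.0),
) -> dict[str, pd.DataFrame]:
    """The four connectivity studies on tidy PBC / MI tables.

    1. per EEG channel (muscles averaged): surfaces compared per band;
    2. per muscle (channels averaged): surfaces compared per band;
    3. per (channel, muscle) pair in the broadband 8-50 Hz band: muscles
       compared per channel, and surfaces compared within each pair;
    4. per-muscle MI (channels averaged): muscles compared per surface.

    ``pbc_records`` columns: subject, trial_id, surface, eeg_channel, muscle,
    band, rho.  ``mi_table`` columns: subject, trial_id, surface, muscle, mi.
    """
    from .pbc import pbc_aggregate

    out: dict[str, pd.DataFrame] = {}
    if pbc_records is not None and len(pbc_records):
        if pbc_records["surface"].nunique() < 2:
            raise ValueError("studies need records from at least two surfaces")
        per_channel = pbc_aggregate(pbc_records, "per_channel")
        rows = []
        for (band, ch), grp in per_channel.groupby(["band", "eeg_channel"]):
            res = compare_groups(grp["rho"].to_numpy(), grp["surface"].to_numpy(),
                                 factor="surface", normality=normality)
            rows += _result_rows(res, band=band, eeg_channel=ch)
        out["study1"] = pd.DataFrame(rows)

        per_muscle = pbc_aggregate(pbc_records, "per_muscle")
        rows = []
        for (band, m), grp in per_muscle.groupby(["band", "muscle"]):
            res = compare_groups(grp["rho"].to_numpy(), grp["surface"].to_numpy(),
                                 factor="surface", normality=normality)
            rows += _result_rows(res, band=band, muscle=m)
        out["study2"] = pd.DataFrame(rows)

        per_pair = pbc_aggregate(pbc_records, "per_pair")
        rows = []
        for (ch, surf), grp in per_pair.groupby(["eeg_channel", "surface"]):
            res = compare_groups(grp["rho"].to_numpy(), grp["muscle"].to_numpy(),
                                 factor="muscle", normality=normality)
            rows += _result_rows(res, eeg_channel=ch, surface=surf, comparison="muscles")
        for (ch, m), grp in per_pair.groupby(["eeg_channel", "muscle"]):
            res = compare_groups(grp["rho"].to_numpy(), grp["surface"].to_numpy(),
                                 factor="surface", normality=normality)
            rows += _result_rows(res, eeg_channel=ch, muscle=m, comparison="surfaces")
        out["study3"] = pd.DataFrame(rows)

    if mi_table is not None and len(mi_table):
        task = mi_table[
            (mi_table["time"] >= mi_task_window[0]) & (mi_table["time"] <= mi_task_window[1])
        ]
        subj = (
            task.groupby(["subject", "surface", "muscle"])["mi"].mean().reset_index()
        )
        rows = []
        for surf, grp in subj.groupby("surface"):
            res = compare_groups(grp["mi"].to_numpy(), grp["muscle"].to_numpy(),
                                 factor="muscle", normality=normality)
            rows += _result_rows(res, surface=surf)
        out["study4"] = pd.DataFrame(rows)
    return out
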