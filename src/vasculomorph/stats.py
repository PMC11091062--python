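"""Group-comparison statistics and report tables.

Zone and resolution-group comparisons use one-way (single-factor) ANOVA
followed by the Tukey–Kramer test — the unequal-sample-size form of Tukey's
honestly-significant-difference procedure, which it reduces to when all
groups have the same n.  For a pair of groups (i, j),

    q_ij = |mean_i - mean_j| / sqrt( MS_within / 2 * (1/n_i + 1/n_j) ),

and the p-value comes from the studentized-range distribution with
parameters (k groups, df_within).  Significance is assessed at alpha = 0.05
and mapped to the star bands * (0.01 < p < 0.05), ** (0.001 < p < 0.01) and
*** (p < 0.001) in the report tables.

Descriptive errors for count-like parameters (segments, nodes, branching
nodes) use the standard error of the mean on observations pooled first
across the connected subnetworks ("graphs") of the skeletonized image.
The unit of analysis (per-specimen vs per-graph) is whatever the caller
puts into the GroupSample observations; nothing is pooled implicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "ComparisonResult",
    "one_way_anova",
    "tukey_kramer",
    "pooled_sem",
    "p_to_stars",
    "null_rejection_rate",
    "build_report",
]

ALPHA_DEFAULT = 0.05


@dataclass
class GroupSample:
    """Observations for one group (zone or resolution group)."""

    label: str
    observations: np.ndarray

    def __post_init__(self) -> None:
        self.observations = np.asarray(self.observations, float).ravel()
        if len(self.observations) < 1:
            raise ValueError(f"group {self.label!r} has no observations")
        if not np.all(np.isfinite(self.observations)):
            raise ValueError(f"group {self.label!r} has non-finite observations")

    @property
    def n(self) -> int:
        return len(self.observations)

    @property
    def mean(self) -> float:
        return float(self.observations.mean())


@dataclass
class ComparisonResult:
    F: float
    df_between: int
    df_within: int
    p_overall: float
    ms_within: float
    group_means: dict[str, float]
    pairwise: pd.DataFrame | None = None   # pair, q, p, significant
    degenerate: bool = False               # zero within-group variance


def _check_groups(groups: list[GroupSample]) -> None:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    total_n = sum(g.n for g in groups)
    if total_n <= len(groups):
        raise ValueError("total observations must exceed the number of groups")


def one_way_anova(groups: list[GroupSample]) -> ComparisonResult:
    """Classical between/within decomposition; F = MS_between / MS_within.

    Degenerate inputs are flagged: zero within-group variance with unequal
    means gives F = +inf, p = 0; all observations identical gives F = 0,
    p = 1.
    """
    _check_groups(groups)
    all_obs = np.concatenate([g.observations for g in groups])
    grand = all_obs.mean()
    ss_between = sum(g.n * (g.mean - grand) ** 2 for g in groups)
    ss_within = sum(((g.observations - g.mean) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_obs) - len(groups)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    means = {g.label: g.mean for g in groups}

    if ms_w == 0:
        if ms_b == 0:
            return ComparisonResult(0.0, df_b, df_w, 1.0, 0.0, means, degenerate=True)
        return ComparisonResult(float("inf"), df_b, df_w, 0.0, 0.0, means, degenerate=True)
    F = ms_b / ms_w
    p = float(sps.f.sf(F, df_b, df_w))
    return ComparisonResult(float(F), df_b, df_w, p, float(ms_w), means)


def tukey_kramer(groups: list[GroupSample], alpha: float = ALPHA_DEFAULT) -> pd.DataFrame:
    """All pairwise comparisons with studentized-range p-values.

    Returns a table with columns ``group_1, group_2, mean_diff, q, p,
    significant``; significant means ``p < alpha``.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    anova = one_way_anova(groups)
    k, df_w = len(groups), anova.df_within
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = groups[i], groups[j]
            diff = gi.mean - gj.mean
            se2 = anova.ms_within / 2.0 * (1.0 / gi.n + 1.0 / gj.n)
            if se2 == 0:
                q = 0.0 if diff == 0 else float("inf")
                p = 1.0 if diff == 0 else 0.0
            else:
                q = abs(diff) / np.sqrt(se2)
                p = float(sps.studentized_range.sf(q, k, df_w))
            rows.append(
                {
                    "group_1": gi.label,
                    "group_2": gj.label,
                    "mean_diff": diff,
                    "q": q,
                    "p": p,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)


def compare_groups(groups: list[GroupSample], alpha: float = ALPHA_DEFAULT) -> ComparisonResult:
    """ANOVA plus Tukey–Kramer pairwise table in one ComparisonResult."""
    res = one_way_anova(groups)
    res.pairwise = tukey_kramer(groups, alpha=alpha)
    return res


def pooled_sem(per_graph_values: list) -> float:
    """SEM of values pooled (concatenated) across graphs: sd / sqrt(n).

    Order-invariant across graphs.  A single pooled value has no dispersion
    estimate: NaN is returned with a warning.
    """
    if len(per_graph_values) < 1:
        raise ValueError("need at least one graph")
    pooled = np.concatenate([np.atleast_1d(np.asarray(v, float)) for v in per_graph_values])
    if len(pooled) < 2:
        warnings.warn("single pooled value: SEM undefined", stacklevel=2)
        return float("nan")
    return float(np.std(pooled, ddof=1) / np.sqrt(len(pooled)))


def p_to_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def null_rejection_rate(
    n_groups: int = 3,
    n_per_group: int = 3,
    reps: int = 1000,
    alpha: float = ALPHA_DEFAULT,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Empirical type-I error of the ANOVA under a common normal null."""
    rng = np.random.default_rng(rng)
    rejections = 0
    for _ in range(reps):
        data = rng.normal(size=(n_groups, n_per_group))
        groups = [GroupSample(str(i), row) for i, row in enumerate(data)]
        if one_way_anova(groups).p_overall < alpha:
            rejections += 1
    return rejections / reps


# ---------------------------------------------------------------------------
# report generation


def build_report(
    out_dir: str | Path,
    summaries: dict[str, "object"],
    circ_morphometry: pd.DataFrame | None = None,
    radial_morphometry: pd.DataFrame | None = None,
    contributions: pd.DataFrame | None = None,
    comparisons: dict[str, ComparisonResult] | None = None,
) -> dict[str, Path]:
    """Write CSV report tables.

    ``summaries`` maps a group label (e.g. a resolution preset) to a
    NetworkSummary; the per-group table mirrors the descriptive layout of
    resolution-comparison tables (total volume, segments, total length,
    mean diameter, nodes).  Zone tables and the contribution table are
    written when given; pairwise comparisons get significance stars.
    """
    missing = [name for name, val in [("summaries", summaries)] if not val]
    if missing:
        raise ValueError(f"missing upstream inputs: {', '.join(missing)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    table2 = pd.DataFrame({label: s.to_series() for label, s in summaries.items()})
    p = out_dir / "per_group_summary.csv"
    table2.to_csv(p, index_label="parameter")
    paths["per_group_summary"] = p

    if circ_morphometry is not None:
        p = out_dir / "circumferential_zones.csv"
        circ_morphometry.to_csv(p, index=False)
        paths["circumferential_zones"] = p
    if radial_morphometry is not None:
        p = out_dir / "radial_zones.csv"
        radial_morphometry.to_csv(p, index=False)
        paths["radial_zones"] = p
    if contributions is not None:
        p = out_dir / "zone_contributions.csv"
        contributions.to_csv(p, index=False)
        paths["zone_contributions"] = p

    if comparisons:
        frames = []
        for name, res in comparisons.items():
            if res.pairwise is None:
                continue
            t = res.pairwise.copy()
            t.insert(0, "comparison", name)
            t["stars"] = [p_to_stars(v) for v in t["p"]]
            frames.append(t)
        if frames:
            p = out_dir / "comparisons.csv"
            pd.concat(frames, ignore_index=True).to_csv(p, index=False)
            paths["comparisons"] = p
    return paths
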