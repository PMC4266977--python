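"""Body-region decay trajectories and their comparison.

Characters are grouped by body region and their aggregated ordinal decay
states (0-4) are pooled into one point cloud per region over log-transformed
time.  A linear regression per region summarises the region's decay
trajectory; the slope-heterogeneity F test asks whether regions decay at
different rates (separate-slopes ANCOVA vs common slope), and a one-way
ANOVA with Tukey HSD compares onset-of-loss times between regions.

Internal organs decay fastest and typically follow a separate trajectory
from all cuticular characters; characters that stay pristine throughout
(e.g. sclerotised jaws and claws) carry no trajectory information and are
excluded from the pools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .datamodel import CENSORED, CharacterDefinition, ValidationError
from .scoring import AggregatedStateSeries, MilestoneTimes

__all__ = [
    "RegionTrajectory",
    "SlopeHeterogeneityResult",
    "TukeyPair",
    "OnsetAnovaResult",
    "log_day",
    "build_region_trajectories",
    "slope_heterogeneity_test",
    "onset_anova_tukey",
]


def log_day(day, offset: float = 1.0, base: float = np.e):
    """Log transform of day with an offset so day 0 is representable."""
    return np.log(np.asarray(day, dtype=float) + offset) / np.log(base)


@dataclass
class RegionTrajectory:
    """Pooled (log day, ordinal state) points for one region, with OLS line."""

    body_region: str
    points: pd.DataFrame  # columns: character_id, day, log_day, state
    slope: float
    intercept: float

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class SlopeHeterogeneityResult:
    """F test of region x log-day interaction (separate vs common slopes)."""

    F: float
    df: tuple[int, int]  # (k-1, N-2k)
    p: float


@dataclass(frozen=True)
class TukeyPair:
    region_a: str
    region_b: str
    mean_diff: float
    p_adj: float
    significant: bool


@dataclass(frozen=True)
class OnsetAnovaResult:
    F: float
    df: tuple[int, int]  # (k-1, n-k)
    p: float
    tukey: tuple[TukeyPair, ...]


def build_region_trajectories(
    series: list[AggregatedStateSeries],
    characters: list[CharacterDefinition],
    log_offset: float = 1.0,
    log_base: float = np.e,
    min_points: int = 3,
) -> list[RegionTrajectory]:
    """Pool character series within each body region and fit one line each.

    Characters whose series is pristine (state 0) at every sampled day are
    excluded: they never enter a decay trajectory.  Regions left with fewer
    than ``min_points`` points are dropped with a warning.
    """
    region_of = {c.character_id: c.body_region for c in characters}
    rows = []
    for s in series:
        if s.character_id not in region_of:
            raise ValidationError(f"character {s.character_id!r} has no region")
        if all(state == 0 for state in s.states):
            continue  # pristine throughout: no trajectory
        for day, state in zip(s.days, s.states):
            rows.append(
                {
                    "character_id": s.character_id,
                    "body_region": region_of[s.character_id],
                    "day": day,
                    "log_day": float(log_day(day, log_offset, log_base)),
                    "state": state,
                }
            )
    if not rows:
        raise ValidationError("no non-pristine series to build trajectories from")
    df = pd.DataFrame(rows)
    out = []
    for region in sorted(df["body_region"].unique()):
        sub = df.loc[df["body_region"] == region].reset_index(drop=True)
        if len(sub) < min_points or sub["log_day"].nunique() < 2:
            warnings.warn(
                f"region {region!r} dropped: {len(sub)} usable points",
                stacklevel=2,
            )
            continue
        slope, intercept = np.polyfit(sub["log_day"], sub["state"], 1)
        out.append(
            RegionTrajectory(
                body_region=region,
                points=sub[["character_id", "day", "log_day", "state"]],
                slope=float(slope),
                intercept=float(intercept),
            )
        )
    return out


def slope_heterogeneity_test(
    trajectories: list[RegionTrajectory],
) -> SlopeHeterogeneityResult:
    """Do regions decay at different rates?  ANCOVA interaction F test.

    Compares the separate-slopes model ``state ~ region + log_day +
    region:log_day`` against the common-slope model ``state ~ region +
    log_day``; the numerator df is k-1 for k regions, the denominator
    N - 2k.
    """
    if len(trajectories) < 2:
        raise ValidationError("need at least 2 regions to compare slopes")
    df = pd.concat(
        [t.points.assign(body_region=t.body_region) for t in trajectories],
        ignore_index=True,
    )
    reduced = smf.ols("state ~ C(body_region) + log_day", data=df).fit()
    full = smf.ols("state ~ C(body_region) * log_day", data=df).fit()
    if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        raise ValidationError("singular design: cannot separate region slopes")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = anova_lm(reduced, full)
    F = float(tab["F"].iloc[1])
    df1 = int(tab["df_diff"].iloc[1])
    df2 = int(full.df_resid)
    p = float(tab["Pr(>F)"].iloc[1])
    return SlopeHeterogeneityResult(F=max(F, 0.0), df=(df1, df2), p=p)


def onset_anova_tukey(
    milestones: list[MilestoneTimes],
    characters: list[CharacterDefinition],
    log_transform: bool = True,
    log_offset: float = 1.0,
    alpha: float = 0.05,
) -> OnsetAnovaResult:
    """One-way ANOVA (plus Tukey HSD) of onset-of-loss times across regions.

    Characters whose onset of loss was never observed (censored) are
    excluded; regions left without any observed onset are dropped with a
    warning.  Onset days are log-transformed by default, which stabilises
    the strongly right-skewed decay time scale.
    """
    region_of = {c.character_id: c.body_region for c in characters}
    rows = []
    for m in milestones:
        if m.t_onset_loss == CENSORED:
            continue
        region = region_of.get(m.character_id)
        if region is None:
            raise ValidationError(f"character {m.character_id!r} has no region")
        t = m.t_onset_loss
        rows.append(
            {
                "character_id": m.character_id,
                "body_region": region,
                "onset": float(log_day(t, log_offset)) if log_transform else float(t),
            }
        )
    present = {r["body_region"] for r in rows}
    dropped = {region_of[m.character_id] for m in milestones} - present
    for region in sorted(dropped):
        warnings.warn(f"region {region!r} entirely censored; excluded", stacklevel=2)
    df = pd.DataFrame(rows)
    k = df["body_region"].nunique() if len(df) else 0
    if k < 2:
        raise ValidationError("need >= 2 regions with observed onset of loss")
    groups = [sub["onset"].to_numpy() for _, sub in df.groupby("body_region")]
    n = len(df)
    grand = df["onset"].mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_within == 0:
        # degenerate: identical values within groups (F is 0/0 or +inf)
        F = 0.0 if np.isclose(ss_between, 0.0) else np.inf
        p = 1.0 if F == 0.0 else 0.0
    else:
        F = (ss_between / (k - 1)) / (ss_within / (n - k))
        p = float(stats.f.sf(F, k - 1, n - k))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hsd = pairwise_tukeyhsd(df["onset"], df["body_region"], alpha=alpha)
    pairs = tuple(
        TukeyPair(
            region_a=str(row[0]),
            region_b=str(row[1]),
            mean_diff=float(row[2]),
            p_adj=float(row[3]),
            significant=bool(row[6]),
        )
        for row in hsd.summary().data[1:]
    )
    return OnsetAnovaResult(
        F=float(F), df=(k - 1, n - k), p=float(p), tukey=pairs
    )
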