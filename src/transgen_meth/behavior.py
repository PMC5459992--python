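"""Operant-behaviour scoring: progressive-ratio break points, combined
z-scores and Addict/Non-addict classification.

The cohort is a set of rats run through fixed-ratio (FR1/FR3/FR5) cocaine
self-administration sessions followed by one progressive-ratio (PR) session.
Under the PR schedule the press requirement for the i-th injection grows as
``floor(scale * exp(rate * i) - scale)`` (defaults 5 and 0.25); the break
point — the requirement satisfied for the last injection earned — indexes
the animal's motivation for the drug.  Each animal's mean FR5 active-lever
pressing and its break point are z-scored within the cohort and summed into
a combined drug-seeking score; the top fraction of the cohort is labelled
Addict and the bottom fraction Non-addict.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, DegenerateCohortError, DomainError

SCHEDULES = ("FR1", "FR3", "FR5", "PR")

SESSION_COLUMNS = [
    "animal_id",
    "session_index",
    "schedule",
    "active_presses",
    "inactive_presses",
    "injections",
    "break_point",
]


@dataclass(frozen=True)
class PRSchedule:
    """Progressive-ratio requirement ladder: requirement(i) = round(scale·e^{rate·i} − scale)."""

    scale: float = 5.0
    rate: float = 0.25
    rounding: str = "floor"  # "floor" (as printed) or "nearest"

    def __post_init__(self):
        if self.scale <= 0 or self.rate <= 0:
            raise ConfigurationError("PRSchedule scale and rate must be positive")
        if self.rounding not in ("floor", "nearest"):
            raise ConfigurationError(f"unknown rounding mode {self.rounding!r}")


@dataclass(frozen=True)
class ClassifierConfig:
    top_fraction: float = 0.25
    bottom_fraction: float = 0.40

    def __post_init__(self):
        if not (0.0 <= self.top_fraction <= 1.0 and 0.0 <= self.bottom_fraction <= 1.0):
            raise ConfigurationError("fractions must lie in [0, 1]")
        if self.top_fraction + self.bottom_fraction > 1.0 + 1e-12:
            raise ConfigurationError("top_fraction + bottom_fraction must not exceed 1")


def pr_requirement(i: int, sched: PRSchedule | None = None) -> int:
    """Press requirement for the i-th injection of a progressive-ratio session."""
    if i < 0:
        raise DomainError(f"injection index must be >= 0, got {i}")
    sched = sched or PRSchedule()
    raw = sched.scale * math.exp(sched.rate * i) - sched.scale
    if sched.rounding == "floor":
        return int(math.floor(raw))
    return int(round(raw))


def extract_break_point(log: pd.Series | dict, sched: PRSchedule | None = None) -> int:
    """Break point of a PR session log: the requirement of the last injection earned.

    A session with zero injections yields a break point of 0 (with a warning:
    the animal never earned an injection, so no requirement was satisfied).
    """
    schedule = log["schedule"]
    if schedule != "PR":
        raise DomainError(f"break point is defined for PR sessions, got {schedule}")
    injections = int(log["injections"])
    if injections < 0:
        raise DomainError("injection count must be non-negative")
    if injections == 0:
        warnings.warn("PR session with zero injections: break point set to 0", stacklevel=2)
        return 0
    return pr_requirement(injections, sched)


def combined_score(
    fr5_means,
    break_points,
    animal_ids=None,
    ddof: int = 1,
) -> pd.DataFrame:
    """Cohort z-scores and combined drug-seeking score.

    z_fr5 and z_bp standardise each metric within the cohort ((x − mean)/sd,
    sample sd by default); combined = z_fr5 + z_bp.  Labels are left unset.
    """
    fr5 = np.asarray(fr5_means, dtype=np.float64)
    bp = np.asarray(break_points, dtype=np.float64)
    if fr5.shape != bp.shape or fr5.ndim != 1:
        raise DomainError("fr5_means and break_points must be equal-length 1-D")
    n = fr5.size
    if n < 3:
        raise DegenerateCohortError(f"need at least 3 animals to z-score, got {n}")
    if animal_ids is None:
        animal_ids = [f"A{i:04d}" for i in range(n)]
    z = {}
    for name, x in (("fr5", fr5), ("bp", bp)):
        sd = x.std(ddof=ddof)
        if sd == 0:
            raise DegenerateCohortError(f"zero variance in {name}: cohort cannot be z-scored")
        z[name] = (x - x.mean()) / sd
    return pd.DataFrame(
        {
            "animal_id": list(animal_ids),
            "fr5_mean": fr5,
            "break_point": bp,
            "z_fr5": z["fr5"],
            "z_bp": z["bp"],
            "combined": z["fr5"] + z["bp"],
            "label": pd.Series(["Intermediate"] * n, dtype="object"),
        }
    )


def classify(scores: pd.DataFrame, cfg: ClassifierConfig | None = None) -> pd.DataFrame:
    """Label the top fraction of combined scores Addict and the bottom fraction Non-addict.

    Exactly ``floor(top_fraction·n)`` animals get the Addict label and
    ``floor(bottom_fraction·n)`` the Non-addict label; everyone else is
    Intermediate.  Ties are broken by (combined score, animal_id) so the
    labelling is deterministic.
    """
    cfg = cfg or ClassifierConfig()
    if not np.isfinite(scores["combined"]).all():
        raise DomainError("combined scores must be finite")
    n = len(scores)
    n_top = int(math.floor(cfg.top_fraction * n))
    n_bottom = int(math.floor(cfg.bottom_fraction * n))
    order = scores.sort_values(
        ["combined", "animal_id"], kind="mergesort"
    ).index.to_numpy()
    out = scores.copy()
    out["label"] = "Intermediate"
    if n_bottom:
        out.loc[order[:n_bottom], "label"] = "Non-addict"
    if n_top:
        out.loc[order[n - n_top :], "label"] = "Addict"
    return out


def score_cohort(sessions: pd.DataFrame, sched: PRSchedule | None = None) -> pd.DataFrame:
    """Score a session-log table into per-animal FR5 means and break points.

    fr5_mean is the mean of active presses over every FR5 session present;
    the break point is derived from the logged PR injection count via the
    requirement ladder (the scorer trusts the log's injection count — the
    PR termination rule is the chamber's business, not the scorer's).
    """
    missing = set(SESSION_COLUMNS[:6]) - set(sessions.columns)
    if missing:
        raise DomainError(f"session log missing columns: {sorted(missing)}")
    sched = sched or PRSchedule()
    fr5 = (
        sessions[sessions["schedule"] == "FR5"]
        .groupby("animal_id")["active_presses"]
        .mean()
    )
    pr = sessions[sessions["schedule"] == "PR"].set_index("animal_id")
    animals = sorted(fr5.index)
    if set(animals) - set(pr.index):
        raise DomainError("every animal with FR5 sessions needs a PR session")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-injection animals score bp=0
        bps = [extract_break_point(pr.loc[a], sched) for a in animals]
    return combined_score(fr5.loc[animals].to_numpy(), bps, animal_ids=animals)


def rank_sum_test(a, b) -> tuple[float, float]:
    """Mann–Whitney rank-sum test: (normal-approximation Z, two-sided p).

    The p-value comes from full enumeration of rank assignments when
    n_a + n_b <= 12 (midranks under ties), otherwise from the normal
    approximation with tie and continuity corrections.  Z is always the
    corrected normal statistic, reported alongside either p.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise DomainError("each group needs at least 2 observations")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = ranks[:na].sum()  # rank sum of group a
    mu = na * (na + nb + 1) / 2.0
    # tie-corrected variance of the rank sum
    _, counts = np.unique(pooled, return_counts=True)
    nn = na + nb
    tie_term = ((counts**3 - counts).sum()) / (nn * (nn - 1)) if nn > 1 else 0.0
    var = na * nb / 12.0 * (nn + 1 - tie_term)
    if var <= 0:
        z = 0.0
    else:
        z = (abs(w - mu) - 0.5) / math.sqrt(var) * (1 if w >= mu else -1)
        if abs(w - mu) <= 0.5:
            z = 0.0
    if nn <= 12:
        p = _exact_rank_sum_p(ranks, na, w)
    else:
        p = 2.0 * sps.norm.sf(abs(z)) if var > 0 else 1.0
    return float(z), float(min(p, 1.0))


def _exact_rank_sum_p(ranks: np.ndarray, na: int, w: float) -> float:
    """Two-sided exact p by enumeration of all C(n, na) rank assignments."""
    from itertools import combinations

    nn = ranks.size
    mu = na * (nn + 1) / 2.0
    total = 0
    le = ge = 0
    for idx in combinations(range(nn), na):
        s = ranks[list(idx)].sum()
        total += 1
        if s <= w + 1e-9:
            le += 1
        if s >= w - 1e-9:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)
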