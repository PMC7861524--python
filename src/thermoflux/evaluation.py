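"""Comparison of predictions against reference fluxes and metabolomics.

Predicted genome-scale fluxes are mapped onto the (smaller) reference
network through a mapping table with per-entry sign correction; agreement
is quantified with Pearson correlations, per-reaction direction calls and
flux-pattern-change detection, and candidate parameterizations are ranked
per criterion and jointly, with Kendall's W measuring concordance between
the criterion-wise rankings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .tfa import TFASolution

DIRECTION_TOL = 1e-9
_DIR_ORDER = {"-": 0, "0": 1, "+": 2}


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# mapping and correlation
# ---------------------------------------------------------------------------

def map_and_correct_fluxes(
    solution: TFASolution,
    mapping: pd.DataFrame,
    reference: pd.DataFrame,
) -> pd.DataFrame:
    """Aggregate predicted fluxes onto reference reactions.

    Each reference reaction's prediction is the signed sum of the mapped
    genome-scale fluxes (sign -1 flips reactions defined in the opposite
    direction).  Returns a frame with columns mfa_id/predicted/reference;
    reference entries without any mapping are kept with NaN predictions so
    the caller can report them."""
    predicted: Dict[str, float] = {}
    for _, row in mapping.iterrows():
        gsm, mfa, sign = row["gsm_id"], row["mfa_id"], int(row["sign"])
        if gsm not in solution.fluxes:
            raise EvaluationError(f"mapped reaction {gsm!r} missing from solution")
        predicted[mfa] = predicted.get(mfa, 0.0) + sign * solution.fluxes[gsm]
    out = reference[["mfa_id", "value"]].copy()
    out = out.rename(columns={"value": "reference"})
    out["predicted"] = [predicted.get(m, np.nan) for m in out["mfa_id"]]
    return out[["mfa_id", "predicted", "reference"]]


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Sample Pearson r; None when undefined (zero variance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise EvaluationError("need two equal-length vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise EvaluationError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def metabolomics_correlation(
    predicted_ln_conc: Mapping[str, float],
    measured: pd.DataFrame,
    scale: str = "log10",
) -> Optional[float]:
    """Pearson r between predicted and measured concentrations on the
    requested scale (log10 by default: concentrations span decades)."""
    sids = [s for s in measured["species_id"] if s in predicted_ln_conc]
    if len(sids) < 3:
        raise EvaluationError("fewer than 3 species in common")
    meas = measured.set_index("species_id")["concentration_M"]
    pred = np.array([math.exp(predicted_ln_conc[s]) for s in sids])
    obs = np.array([meas[s] for s in sids], dtype=float)
    if scale == "log10":
        pred, obs = np.log10(pred), np.log10(obs)
    elif scale != "linear":
        raise EvaluationError(f"unknown scale {scale!r}")
    return pearson_correlation(pred, obs)


# ---------------------------------------------------------------------------
# direction calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DirectionCall:
    """A non-empty subset of {+, -, 0}: the flux directions observed across
    one or more solutions, rendered in the compact "0/+" style."""

    calls: frozenset

    def __post_init__(self) -> None:
        if not self.calls or not self.calls <= {"+", "-", "0"}:
            raise EvaluationError(f"invalid direction call {set(self.calls)!r}")

    def render(self) -> str:
        return "/".join(sorted(self.calls, key=_DIR_ORDER.get))

    @classmethod
    def parse(cls, text: str) -> "DirectionCall":
        return cls(frozenset(text.split("/")))


def call_direction(values: Iterable[float], tol: float = DIRECTION_TOL) -> DirectionCall:
    """Direction of one or more flux values: + above tol, - below -tol,
    otherwise 0; multiple values yield the union of their calls."""
    if tol <= 0:
        raise EvaluationError("tolerance must be positive")
    values = list(values)
    if not values:
        raise EvaluationError("need at least one flux value")
    calls = set()
    for v in values:
        calls.add("+" if v > tol else "-" if v < -tol else "0")
    return DirectionCall(frozenset(calls))


@dataclass(frozen=True)
class PatternChange:
    reaction_id: str
    reference: str
    predicted: str


def detect_flux_pattern_changes(
    reference: Mapping[str, DirectionCall],
    predicted: Mapping[str, DirectionCall],
) -> List[PatternChange]:
    """Flag every reaction whose predicted direction call-set differs from
    the (corrected) reference call-set; any disagreeing member flags the
    reaction."""
    if set(reference) != set(predicted):
        raise EvaluationError("reference and prediction cover different reactions")
    changes = []
    for rid in sorted(reference):
        if reference[rid].calls != predicted[rid].calls:
            changes.append(
                PatternChange(
                    reaction_id=rid,
                    reference=reference[rid].render(),
                    predicted=predicted[rid].render(),
                )
            )
    return changes


# ---------------------------------------------------------------------------
# rankings
# ---------------------------------------------------------------------------

def rank_tests(values: Sequence[float], rounding_decimals: int = 2) -> np.ndarray:
    """Rank scores descending (rank 1 = best) with average ranks on ties,
    after rounding to the configured precision so near-identical
    correlations tie rather than order arbitrarily."""
    arr = np.asarray(values, dtype=float)
    if not np.isfinite(arr).all():
        raise EvaluationError("scores must be finite")
    rounded = np.round(arr, rounding_decimals)
    return stats.rankdata(-rounded, method="average")


def kendalls_w(rank_matrix: np.ndarray) -> Optional[float]:
    """Kendall's coefficient of concordance with tie correction.

    ``rank_matrix`` is m criteria x n tests of (possibly tied, average-rank)
    rankings.  W = 12 S / (m^2 (n^3 - n) - m sum(T)) where S is the sum of
    squared deviations of the per-test rank sums from their mean and T is
    the usual per-criterion tie term sum(t^3 - t).  Returns None when every
    criterion is fully tied (W undefined)."""
    ranks = np.asarray(rank_matrix, dtype=float)
    if ranks.ndim != 2 or ranks.shape[0] < 2 or ranks.shape[1] < 2:
        raise EvaluationError("need an m x n rank matrix with m, n >= 2")
    m, n = ranks.shape
    rank_sums = ranks.sum(axis=0)
    s = float(np.sum((rank_sums - rank_sums.mean()) ** 2))
    tie_term = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    denom = m**2 * (n**3 - n) - m * tie_term
    if denom <= 0:
        return None
    return 12.0 * s / denom


def joint_ranking(
    ranks_per_criterion: Sequence[Sequence[float]],
    n_tests: Optional[int] = None,
) -> np.ndarray:
    """Joint score per test: sum over criteria of (n - rank + 1), so the
    best-ranked test on every criterion scores m*n and ties (average ranks)
    produce half-integer scores.  Higher is better."""
    ranks = np.asarray(ranks_per_criterion, dtype=float)
    if ranks.ndim != 2:
        raise EvaluationError("need a criteria x tests rank matrix")
    n = n_tests if n_tests is not None else ranks.shape[1]
    return (n - ranks + 1.0).sum(axis=0)


def ranking_table(
    scores_per_criterion: Mapping[str, Sequence[float]],
    test_labels: Sequence,
    rounding_decimals: int = 2,
) -> pd.DataFrame:
    """Rank tests under each criterion, append the joint score and sort
    descending by it (stable on ties)."""
    n = len(test_labels)
    ranks = {
        crit: rank_tests(scores, rounding_decimals)
        for crit, scores in scores_per_criterion.items()
    }
    joint = joint_ranking(list(ranks.values()), n)
    df = pd.DataFrame({"test": list(test_labels)})
    for crit, scores in scores_per_criterion.items():
        df[f"score_{crit}"] = list(scores)
        df[f"rank_{crit}"] = ranks[crit]
    df["joint_score"] = joint
    return df.sort_values("joint_score", ascending=False, kind="stable").reset_index(
        drop=True
    )
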