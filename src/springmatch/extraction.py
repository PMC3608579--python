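"""Analysis pipeline: filtering, averaging, ΔF, sensory weights, accuracy.

Works on the tidy one-row-per-trial table produced by
:mod:`springmatch.cohort` (or an equivalent CSV).  The steps mirror the
measurement procedure:

1.  Average each trial's 0.6 s force window; discard invalid trials and
    force-task trials averaging below 5.0 N (accidental foot-switch presses).
2.  Average reference, blind and catch forces over repetitions per subject
    and stiffness.
3.  ΔF = mean catch force − mean blind force.  Because the catch/linear force
    gap grows with force level, ΔF is scaled by the force gap at the mean
    blind position to give the position weighting factor, and the
    blind-minus-catch position difference is scaled by the position gap at
    the mean blind force to give the force weighting factor.
4.  Sensor accuracy: SDs of blind force reproduction at infinite stiffness
    (sigma_f) and blind position reproduction at zero stiffness (sigma_x),
    and their ratio — the stiffness at which both cues are equally reliable.
5.  Group comparison by a seeded two-sided permutation test on subject-level
    statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .springs import CatchSpring, force_gap, position_gap

__all__ = [
    "FORCE_FLOOR",
    "SchemaError",
    "ConditionSummary",
    "WeightEstimate",
    "SensorAccuracy",
    "trial_mean_force",
    "filter_trials",
    "condition_summaries",
    "compute_delta_f",
    "estimate_weights",
    "weights_table",
    "sensor_accuracy",
    "accuracy_table",
    "group_permutation_test",
    "weight_slope_per_decade",
    "summarize",
]

#: exclusion threshold for accidental foot-switch presses (N, strict <)
FORCE_FLOOR = 5.0

REQUIRED_COLUMNS = (
    "subject",
    "group",
    "block",
    "stiffness",
    "type",
    "spring",
    "x_m",
    "mean_force_N",
    "valid",
)


class SchemaError(ValueError):
    """The trial table does not conform to the expected schema."""


def validate_schema(trials: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial table is missing column(s): {', '.join(missing)}")
    if len(trials) == 0:
        raise SchemaError("trial table is empty")
    return trials


@dataclass(frozen=True)
class ConditionSummary:
    subject: str
    stiffness: float
    trial_type: str
    mean_force: float
    mean_position: float
    n_trials: int


@dataclass(frozen=True)
class WeightEstimate:
    """Per subject × stiffness weighting estimate.

    Estimates are kept un-clipped (noise can push them slightly outside
    [0, 1]; clipping would bias group means) and flagged when outside
    [-0.2, 1.2].
    """

    subject: str
    stiffness: float
    delta_f: float
    delta_x: float
    w_p_hat: float
    w_f_hat: float

    @property
    def flagged(self) -> bool:
        return not (
            -0.2 <= self.w_p_hat <= 1.2 and -0.2 <= self.w_f_hat <= 1.2
        )


@dataclass(frozen=True)
class SensorAccuracy:
    subject: str
    sigma_f_hat: float  # N
    sigma_x_hat: float  # m

    @property
    def ratio(self) -> float:
        """sigma_f / sigma_x in N/m; nan/inf for degenerate zero SDs."""
        if self.sigma_x_hat == 0.0:
            return math.nan if self.sigma_f_hat == 0.0 else math.inf
        return self.sigma_f_hat / self.sigma_x_hat


def trial_mean_force(samples) -> float:
    """Arithmetic mean of one trial's force-sample window."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("cannot average an empty force-sample vector")
    return float(samples.mean())


def filter_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Drop invalid trials and trials averaging below the 5.0 N floor.

    The threshold is strict: a 5.0 N trial is kept.  Row order is preserved.
    Position-matching (zero-stiffness) trials should not be routed through
    this filter — their forces are ~0 by construction; the pipeline screens
    them on the validity flag alone.
    """
    if len(trials) == 0:
        return trials
    keep = trials["valid"].astype(bool) & (trials["mean_force_N"] >= FORCE_FLOOR)
    return trials[keep]


def _clean_force_trials(trials: pd.DataFrame) -> pd.DataFrame:
    force_task = trials[trials["stiffness"] != 0.0]
    return filter_trials(force_task)


def condition_summaries(trials: pd.DataFrame) -> list[ConditionSummary]:
    """Per subject × stiffness × trial-type means over filter-passing trials."""
    clean = _clean_force_trials(validate_schema(trials))
    out = []
    grouped = clean.groupby(["subject", "stiffness", "type"], sort=True)
    for (subject, stiffness, ttype), cell in grouped:
        out.append(
            ConditionSummary(
                subject=subject,
                stiffness=float(stiffness),
                trial_type=ttype,
                mean_force=float(cell["mean_force_N"].mean()),
                mean_position=float(cell["x_m"].mean()),
                n_trials=len(cell),
            )
        )
    return out


def compute_delta_f(
    summaries: list[ConditionSummary], subject: str, stiffness: float
) -> float | None:
    """Mean catch force minus mean blind force for one subject × stiffness.

    Returns ``None`` (absent, not zero) when either condition is missing.
    """
    blind = catch = None
    for s in summaries:
        if s.subject == subject and s.stiffness == stiffness:
            if s.trial_type == "blind":
                blind = s.mean_force
            elif s.trial_type == "catch":
                catch = s.mean_force
    if blind is None or catch is None:
        return None
    return catch - blind


def estimate_weights(
    delta_f: float,
    blind_position: float,
    blind_force: float,
    catch_position: float,
    stiffness: float,
    catch: CatchSpring,
    subject: str = "S00",
) -> WeightEstimate:
    """Scale ΔF and Δx into position/force weighting factors.

    ``w_p_hat`` scales the measured force difference by the catch/linear
    force gap at the position produced in the blind trials; ``w_f_hat``
    scales the blind-minus-catch position difference by the linear/catch
    position gap at the force produced in the blind trials.
    """
    f_gap = force_gap(stiffness, catch, blind_position)
    x_gap = position_gap(stiffness, catch, blind_force)
    if f_gap <= 0 or x_gap <= 0:
        raise ValueError(
            "degenerate spring pair: zero force/position gap at the blind "
            "operating point"
        )
    delta_x = blind_position - catch_position
    return WeightEstimate(
        subject=subject,
        stiffness=stiffness,
        delta_f=delta_f,
        delta_x=delta_x,
        w_p_hat=delta_f / f_gap,
        w_f_hat=delta_x / x_gap,
    )


def weights_table(
    trials: pd.DataFrame,
    target_force: float = 10.0,
    anchor_offset: float | None = None,
    exponent: float = 2.0,
) -> pd.DataFrame:
    """Per subject × finite-stiffness weighting estimates as a tidy table.

    Columns: subject, group, stiffness, delta_f_N, delta_x_m, w_p_hat,
    w_f_hat, flagged.  Cells missing blind or catch data are omitted.
    """
    clean = _clean_force_trials(validate_schema(trials))
    groups = dict(zip(trials["subject"], trials["group"]))
    rows = []
    finite = clean[np.isfinite(clean["stiffness"])]
    for (subject, stiffness), cell in finite.groupby(["subject", "stiffness"]):
        blind = cell[cell["type"] == "blind"]
        catch_trials = cell[cell["type"] == "catch"]
        if len(blind) == 0 or len(catch_trials) == 0:
            continue
        catch = CatchSpring(
            stiffness=float(stiffness),
            target_force=target_force,
            anchor_offset=anchor_offset,
            exponent=exponent,
        )
        est = estimate_weights(
            delta_f=float(catch_trials["mean_force_N"].mean() - blind["mean_force_N"].mean()),
            blind_position=float(blind["x_m"].mean()),
            blind_force=float(blind["mean_force_N"].mean()),
            catch_position=float(catch_trials["x_m"].mean()),
            stiffness=float(stiffness),
            catch=catch,
            subject=subject,
        )
        rows.append(
            {
                "subject": subject,
                "group": groups.get(subject, ""),
                "stiffness": est.stiffness,
                "delta_f_N": est.delta_f,
                "delta_x_m": est.delta_x,
                "w_p_hat": est.w_p_hat,
                "w_f_hat": est.w_f_hat,
                "flagged": est.flagged,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "subject",
            "group",
            "stiffness",
            "delta_f_N",
            "delta_x_m",
            "w_p_hat",
            "w_f_hat",
            "flagged",
        ],
    )


def sensor_accuracy(trials: pd.DataFrame, subject: str) -> SensorAccuracy | None:
    """Per-subject sigma_f / sigma_x estimates from the sentinel blocks.

    sigma_f_hat is the SD of blind mean forces on the infinitely stiff
    spring (after the 5 N filter); sigma_x_hat the SD of blind positions
    with no spring (validity-screened only).  Needs at least two valid
    repetitions of each; returns ``None`` otherwise.
    """
    sub = trials[(trials["subject"] == subject) & (trials["type"] == "blind")]
    inf_block = filter_trials(sub[np.isinf(sub["stiffness"])])
    zero_block = sub[(sub["stiffness"] == 0.0) & sub["valid"].astype(bool)]
    if len(inf_block) < 2 or len(zero_block) < 2:
        return None
    return SensorAccuracy(
        subject=subject,
        sigma_f_hat=float(inf_block["mean_force_N"].std(ddof=1)),
        sigma_x_hat=float(zero_block["x_m"].std(ddof=1)),
    )


def accuracy_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Sensor-accuracy table: subject, group, sigma_f_N, sigma_x_mm, ratio_N_per_m."""
    validate_schema(trials)
    groups = dict(zip(trials["subject"], trials["group"]))
    rows = []
    for subject in sorted(trials["subject"].unique()):
        acc = sensor_accuracy(trials, subject)
        if acc is None:
            continue
        rows.append(
            {
                "subject": subject,
                "group": groups.get(subject, ""),
                "sigma_f_N": acc.sigma_f_hat,
                "sigma_x_mm": acc.sigma_x_hat * 1000.0,
                "ratio_N_per_m": acc.ratio,
            }
        )
    return pd.DataFrame(
        rows, columns=["subject", "group", "sigma_f_N", "sigma_x_mm", "ratio_N_per_m"]
    )


def group_permutation_test(
    values, labels, n_perm: int = 10_000, seed: int = 0
) -> float:
    """Two-sided permutation p-value for the difference in group means.

    Labels are shuffled ``n_perm`` times (seeded); the p-value is
    ``(1 + #{|d_perm| >= |d_obs|}) / (1 + n_perm)``.  Identical values in
    both groups give p = 1.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    names = np.unique(labels)
    if len(names) != 2:
        raise ValueError(f"need exactly two groups, got {list(names)}")
    mask = labels == names[0]
    n1 = int(mask.sum())
    if n1 < 2 or len(values) - n1 < 2:
        raise ValueError("need at least 2 subjects per group")
    observed = values[mask].mean() - values[~mask].mean()
    rng = np.random.default_rng(seed)
    pool = np.broadcast_to(values, (n_perm, values.size)).copy()
    pool = rng.permuted(pool, axis=1)
    perm_diffs = pool[:, :n1].mean(axis=1) - pool[:, n1:].mean(axis=1)
    exceed = np.sum(np.abs(perm_diffs) >= abs(observed) - 1e-12)
    return float((1 + exceed) / (1 + n_perm))


def weight_slope_per_decade(
    weights: pd.DataFrame, group: str, column: str = "w_f_hat"
) -> float:
    """Weighted LS slope of a weight estimate versus log10(stiffness).

    Per-stiffness cell means are weighted by inverse squared standard error
    (heteroscedasticity grows strongly with stiffness because the position
    gap shrinks as 1/K).  Units: weight change per decade of stiffness.
    """
    sub = weights[weights["group"] == group]
    if sub["stiffness"].nunique() < 2:
        raise ValueError("need at least two stiffness levels to fit a slope")
    xs, ys, ws = [], [], []
    for stiffness, cell in sub.groupby("stiffness"):
        vals = cell[column].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            continue
        var = vals.var(ddof=1) / len(vals) if len(vals) > 1 else np.nan
        xs.append(math.log10(stiffness))
        ys.append(vals.mean())
        ws.append(1.0 / var if np.isfinite(var) and var > 0 else np.nan)
    xs, ys, ws = np.array(xs), np.array(ys), np.array(ws)
    if np.isnan(ws).any():  # single-subject cells: fall back to equal weights
        ws = np.ones_like(xs)
    xbar = np.average(xs, weights=ws)
    ybar = np.average(ys, weights=ws)
    return float(
        np.sum(ws * (xs - xbar) * (ys - ybar)) / np.sum(ws * (xs - xbar) ** 2)
    )


def _group_cell_stats(weights: pd.DataFrame, column: str) -> dict:
    out: dict = {}
    for (group, stiffness), cell in weights.groupby(["group", "stiffness"]):
        vals = cell[column].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            continue
        sem = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else None
        out.setdefault(group, {})[_kkey(stiffness)] = {
            "mean": float(vals.mean()),
            "sem": sem,
            "n": int(len(vals)),
        }
    return out


def _kkey(stiffness: float) -> str:
    if math.isinf(stiffness):
        return "inf"
    return f"{stiffness:g}"


def summarize(
    trials: pd.DataFrame,
    target_force: float = 10.0,
    anchor_offset: float | None = None,
    exponent: float = 2.0,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """Full cohort summary: group means, SEMs and permutation p-values.

    Returns a JSON-serialisable dict with per-stiffness group statistics for
    ΔF and both weighting factors, per-group weight-vs-stiffness slopes,
    sensor-accuracy group means and seeded permutation tests for every group
    contrast.
    """
    weights = weights_table(trials, target_force, anchor_offset, exponent)
    accuracy = accuracy_table(trials)
    groups = sorted(trials["group"].unique())
    summary = {
        "n_subjects": {
            g: int(trials.loc[trials["group"] == g, "subject"].nunique())
            for g in groups
        },
        "delta_f_N": _group_cell_stats(weights, "delta_f_N"),
        "w_p_hat": _group_cell_stats(weights, "w_p_hat"),
        "w_f_hat": _group_cell_stats(weights, "w_f_hat"),
        "slopes_per_decade": {},
        "accuracy": {},
        "permutation_p": {},
    }
    for group in groups:
        try:
            summary["slopes_per_decade"][group] = {
                "w_f_hat": weight_slope_per_decade(weights, group, "w_f_hat"),
                "w_p_hat": weight_slope_per_decade(weights, group, "w_p_hat"),
            }
        except ValueError:
            summary["slopes_per_decade"][group] = None
    for group in groups:
        cell = accuracy[accuracy["group"] == group]
        if len(cell):
            summary["accuracy"][group] = {
                "sigma_f_N": float(cell["sigma_f_N"].mean()),
                "sigma_x_mm": float(cell["sigma_x_mm"].mean()),
                "ratio_N_per_m": float(cell["ratio_N_per_m"].mean()),
            }

    if len(groups) == 2:
        tests: dict = {}
        for stiffness in sorted(weights["stiffness"].unique()):
            cell = weights[weights["stiffness"] == stiffness]
            if cell["group"].nunique() != 2 or cell.groupby("group").size().min() < 2:
                continue
            tests[_kkey(stiffness)] = {
                stat: group_permutation_test(
                    cell[col].to_numpy(), cell["group"].to_numpy(), n_perm, seed
                )
                for stat, col in (
                    ("delta_f", "delta_f_N"),
                    ("w_f_hat", "w_f_hat"),
                )
            }
        summary["permutation_p"]["per_stiffness"] = tests
        ratios = accuracy["ratio_N_per_m"].to_numpy() if len(accuracy) else np.array([])
        if (
            len(accuracy)
            and accuracy["group"].nunique() == 2
            and accuracy.groupby("group").size().min() >= 2
            and np.isfinite(ratios).all()
        ):
            summary["permutation_p"]["accuracy_ratio"] = group_permutation_test(
                ratios, accuracy["group"].to_numpy(), n_perm, seed
            )
    else:
        summary["permutation_p"]["note"] = (
            "group comparison skipped: need exactly two groups"
        )
    return summary
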