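"""Trajectory normalization, ANOVA comparisons, and parameter sensitivity.

The model's readouts (per-slice cell counts and CVHV over time) are compared
between rule sets the way the corresponding experimental readouts are
compared between cell types: series are first expressed as percentages of
their value at the first recorded time point, then a fixed-effects two-way
ANOVA with factors *group* and *time* tests for a group main effect
(significance at p < 0.05).

The sensitivity protocol perturbs one model parameter at a time by ±5%
(interval-valued parameters scale both endpoints), re-runs the model, records
CVHV at a probe time point, and tests each perturbation against the
unperturbed control with a one-way ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .rulesets import RuleSet
from .simulator import SimConfig, dataclass_replace, run

__all__ = [
    "normalize_trajectory",
    "normalize_replicates",
    "two_way_anova",
    "SensitivityReport",
    "sensitivity_analysis",
    "sensitivity_summary",
    "SENSITIVITY_PARAMETERS",
]

SENSITIVITY_PARAMETERS = ("N_crit", "c_amount", "c_envfactor", "T_life", "T_prol")


def normalize_trajectory(values) -> np.ndarray:
    """Express a per-time-point series as percent of its first value.

    The first element becomes 100; normalization is idempotent.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("expected a non-empty 1D series")
    if v[0] == 0:
        raise ValueError("cannot normalize a series whose first value is 0")
    return 100.0 * v / v[0]


def normalize_replicates(df: pd.DataFrame, value: str = "n_cells") -> pd.DataFrame:
    """Per-replicate normalization of a long-format trajectory table.

    Aggregates ``value`` over slices (mean) per replicate and time step, then
    normalizes each replicate's series to its first recorded time point.
    Returns a table with columns replicate, time_step, value (percent).
    """
    agg = (
        df.groupby(["replicate", "time_step"], as_index=False)[value]
        .mean()
        .sort_values(["replicate", "time_step"])
    )
    out = []
    for rep, g in agg.groupby("replicate"):
        out.append(
            pd.DataFrame(
                {
                    "replicate": rep,
                    "time_step": g["time_step"].to_numpy(),
                    "value": normalize_trajectory(g[value].to_numpy()),
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def two_way_anova(
    groups: dict[str, pd.DataFrame],
    response: str = "value",
) -> dict:
    """Fixed-effects two-way ANOVA (factors: group, time) on trajectories.

    ``groups`` maps a label to a table with columns replicate, time_step and
    the response.  Uses type-II sums of squares and reports the group main
    effect as the headline statistic (no interaction term).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if len(groups) < 2:
        raise ValueError("need at least two groups")
    frames = []
    for label, df in groups.items():
        if df.empty:
            raise ValueError(f"group {label!r} has no data")
        d = df.copy()
        d["group"] = str(label)
        frames.append(d[["group", "time_step", "replicate", response]])
    data = pd.concat(frames, ignore_index=True).rename(columns={response: "y"})
    counts = data.groupby(["group", "time_step"]).size()
    if (counts < 2).any():
        raise ValueError("every group x time cell needs at least 2 replicates")
    model = smf.ols("y ~ C(group) + C(time_step)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return {
        "F_group": float(table.loc["C(group)", "F"]),
        "p_group": float(table.loc["C(group)", "PR(>F)"]),
        "F_time": float(table.loc["C(time_step)", "F"]),
        "p_time": float(table.loc["C(time_step)", "PR(>F)"]),
        "table": table,
    }


@dataclass
class SensitivityReport:
    """Outcome of one ±5% perturbation against the unperturbed control."""

    parameter: str
    direction: str  # "+5%" or "-5%"
    perturbed_factor: float
    values: np.ndarray  # CVHV per replicate at the probe time point
    control_values: np.ndarray
    F: float
    p: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return bool(self.p < self.alpha)


def _probe_cvhv(
    rules: RuleSet,
    probe_step: int,
    replicates: int,
    seed_seq: np.random.SeedSequence,
    config: SimConfig,
) -> np.ndarray:
    """Mean per-slice CVHV at the probe step, one value per replicate run."""
    cfg = dataclass_replace(
        config, n_steps=int(probe_step), record_every=int(probe_step), record_cvhv=True
    )
    out = np.empty(replicates)
    for i, child in enumerate(seed_seq.spawn(replicates)):
        traj = run(rules, seed=np.random.default_rng(child), config=cfg)
        out[i] = float(traj.cvhv[-1].mean())
    return out


def sensitivity_analysis(
    base_rules: RuleSet,
    parameters: tuple[str, ...] = SENSITIVITY_PARAMETERS,
    delta: float = 0.05,
    probe_step: int = 40,
    replicates: int = 10,
    seed: int = 0,
    config: SimConfig | None = None,
    alpha: float = 0.05,
) -> list[SensitivityReport]:
    """±delta perturbation protocol with a one-way ANOVA per perturbation.

    For each parameter and direction the perturbed rule set is run
    ``replicates`` times, CVHV is measured at ``probe_step`` (mean over the
    recorded slices), and compared against the shared unperturbed control by
    one-way ANOVA.
    """
    if config is None:
        config = SimConfig()
    if probe_step > config.n_steps:
        raise ValueError("probe_step must not exceed the run length")
    ss = np.random.SeedSequence(seed)
    control_seq, *param_seqs = ss.spawn(1 + 2 * len(parameters))
    control = _probe_cvhv(base_rules, probe_step, replicates, control_seq, config)
    reports: list[SensitivityReport] = []
    k = 0
    for param in parameters:
        for sign in (+1, -1):
            factor = 1.0 + sign * delta
            label = ("+" if sign > 0 else "-") + f"{delta:.0%}"
            perturbed_rules = base_rules.perturbed(param, factor)
            values = _probe_cvhv(perturbed_rules, probe_step, replicates,
                                 param_seqs[k], config)
            k += 1
            F, p = sps.f_oneway(control, values)
            reports.append(
                SensitivityReport(
                    parameter=param,
                    direction=label,
                    perturbed_factor=factor,
                    values=values,
                    control_values=control,
                    F=float(F),
                    p=float(p),
                    alpha=alpha,
                )
            )
    return reports


def sensitivity_summary(reports: list[SensitivityReport]) -> pd.DataFrame:
    """Tabular view of a sensitivity run (one row per perturbation)."""
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "direction": r.direction,
                "factor": r.perturbed_factor,
                "mean_cvhv": float(np.mean(r.values)),
                "control_mean_cvhv": float(np.mean(r.control_values)),
                "F": r.F,
                "p": r.p,
                "significant": r.significant,
            }
            for r in reports
        ]
    )
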