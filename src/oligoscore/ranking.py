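"""Group-ranking statistics over score tables.

A score table holds one row per (group, target, phase, model, metric).
Ranking follows the CASP convention: per-target z-scores computed in two
rounds with outlier exclusion and a floor at -2, averaged with equal weight
over the metric profile, and summed across targets into a cumulative
z-score.  Head-to-head significance uses bootstrap resampling of the
targets common to a pair of groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ScoreTable",
    "RankingResult",
    "impute_missing",
    "two_round_z",
    "rank_groups",
    "bootstrap_h2h",
    "h2h_matrix",
    "first_pick_rate",
    "classify_difficulty",
    "quantile95",
    "phase_delta",
]

COLUMNS = ["group", "target", "phase", "model", "metric", "value"]
Z_FLOOR = -2.0


@dataclass
class ScoreTable:
    """Long-format (group, target, phase, model, metric, value) score table."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"score table missing columns: {missing}")
        key = ["group", "target", "phase", "model", "metric"]
        if self.df.duplicated(subset=key).any():
            raise ValueError("duplicate (group, target, phase, model, metric) rows")

    @classmethod
    def from_records(cls, records: list[dict]) -> "ScoreTable":
        return cls(pd.DataFrame.from_records(records, columns=None)[COLUMNS]
                   if records else pd.DataFrame(columns=COLUMNS))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ScoreTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"phase": str}))

    def write_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def subset(self, phases=None, metrics=None, max_model: int | None = 5
               ) -> pd.DataFrame:
        df = self.df
        if phases is not None:
            df = df[df["phase"].isin(list(phases))]
        if metrics is not None:
            df = df[df["metric"].isin(list(metrics))]
        if max_model is not None:
            df = df[df["model"] <= max_model]
        return df.copy()


def impute_missing(table: ScoreTable) -> ScoreTable:
    """Fill missing values with the lowest observed value for that
    (target, phase, metric); cells that stay missing trigger a warning."""
    df = table.df.copy()
    df["imputed"] = df["value"].isna()
    mins = df.groupby(["target", "phase", "metric"])["value"].transform("min")
    df["value"] = df["value"].fillna(mins)
    if df["value"].isna().any():
        bad = df.loc[df["value"].isna(), ["target", "metric"]].drop_duplicates()
        warnings.warn(
            "no observed values to impute from for: "
            + ", ".join(f"{t}/{m}" for t, m in bad.itertuples(index=False)),
            stacklevel=2,
        )
    return ScoreTable(df)


def two_round_z(values) -> np.ndarray:
    """Two-round z-scores with outlier exclusion and a floor at -2.

    Round 1 standardises against the mean/SD (population) of all values;
    values at or below z = -2 are treated as outliers and excluded.  Round 2
    recomputes mean/SD on the kept set and standardises everyone against it;
    final z-scores are floored at -2.  A zero SD yields all-zero z-scores.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        return np.zeros(n)

    def degenerate(sd: float, mu: float) -> bool:
        # a spread at round-off level relative to the mean is no spread at all
        return sd <= 1e-12 * max(1.0, abs(mu))

    mu, sd = x.mean(), x.std()
    if degenerate(sd, mu):
        return np.zeros(n)
    z1 = (x - mu) / sd
    kept = x[z1 > Z_FLOOR + 1e-12]
    if len(kept) < 2:
        kept = x
    mu2, sd2 = kept.mean(), kept.std()
    if degenerate(sd2, mu2):
        z2 = np.zeros(n)
        z2[~np.isin(x, kept)] = Z_FLOOR
        return z2
    return np.maximum((x - mu2) / sd2, Z_FLOOR)


@dataclass
class RankingResult:
    """Cumulative z ordering plus the per-target z of each selected model."""

    cumulative: pd.Series
    per_target: pd.DataFrame  # group, target, phase, model, z
    model_choice: str
    metric_profile: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    @property
    def ordering(self) -> list[str]:
        return list(self.cumulative.index)


def _model_z(table: ScoreTable, metric_profile=None, phases=None,
             exclude_model6: bool = True) -> pd.DataFrame:
    """Average z per (group, target, phase, model) over the metric profile."""
    df = impute_missing(table).df
    if phases is not None:
        df = df[df["phase"].isin(list(phases))]
    if metric_profile is None:
        metric_profile = tuple(sorted(df["metric"].unique()))
    df = df[df["metric"].isin(metric_profile)]
    if exclude_model6:
        df = df[df["model"] <= 5]
    df = df.dropna(subset=["value"]).copy()
    df["z"] = (
        df.groupby(["target", "phase", "metric"])["value"]
        .transform(lambda v: two_round_z(v.to_numpy()))
    )
    model_z = (
        df.groupby(["group", "target", "phase", "model"])["z"]
        .mean()
        .reset_index()
    )
    return model_z


def _select_models(model_z: pd.DataFrame, model_choice: str) -> pd.DataFrame:
    if model_choice == "first":
        idx = model_z.groupby(["group", "target", "phase"])["model"].idxmin()
    elif model_choice == "best":
        # argmax of z, ties broken by lowest model id
        ordered = model_z.sort_values(["z", "model"], ascending=[False, True])
        idx = ordered.groupby(["group", "target", "phase"], sort=False).head(1).index
    else:
        raise ValueError(f"unknown model_choice {model_choice!r}")
    return model_z.loc[idx].reset_index(drop=True)


def rank_groups(table: ScoreTable, model_choice: str = "best",
                metric_profile=None, phases=None) -> RankingResult:
    """Rank groups by cumulative z-score over their selected models.

    Missing (group, target) combinations contribute 0 to the cumulative z.
    """
    if metric_profile is not None:
        metric_profile = tuple(metric_profile)
    model_z = _model_z(table, metric_profile, phases)
    if model_z.empty:
        raise ValueError("no scores in the requested scope")
    selected = _select_models(model_z, model_choice)
    cumulative = (
        selected.groupby("group")["z"].sum().sort_values(ascending=False)
    )
    profile = metric_profile or tuple(sorted(table.df["metric"].unique()))
    return RankingResult(
        cumulative, selected, model_choice, tuple(profile),
        metadata={"missing_target_policy": "contributes 0",
                  "phases": list(phases) if phases is not None else "all"},
    )


def bootstrap_h2h(table: ScoreTable, a: str, b: str, n: int = 1000,
                  seed: int = 0, model_choice: str = "best",
                  metric_profile=None, phases=None) -> float:
    """Fraction of bootstrap replicates (over common targets) where group
    ``a``'s cumulative z strictly exceeds group ``b``'s."""
    model_z = _model_z(table, metric_profile, phases)
    selected = _select_models(model_z, model_choice)
    pivot = selected.pivot_table(index=["target", "phase"], columns="group",
                                 values="z")
    if a not in pivot.columns or b not in pivot.columns:
        raise ValueError(f"group(s) missing from table: {a!r}, {b!r}")
    common = pivot[[a, b]].dropna()
    if common.empty:
        raise ValueError(f"no common targets between {a!r} and {b!r}")
    za = common[a].to_numpy()
    zb = common[b].to_numpy()
    rng = np.random.default_rng(seed)
    k = len(za)
    idx = rng.integers(0, k, size=(n, k))
    return float(np.mean(za[idx].sum(axis=1) > zb[idx].sum(axis=1)))


def h2h_matrix(table: ScoreTable, groups=None, n: int = 1000, seed: int = 0,
               model_choice: str = "best", metric_profile=None,
               phases=None) -> pd.DataFrame:
    """All-pairs head-to-head fractions; one master seed, per-pair substreams."""
    if groups is None:
        groups = sorted(table.df["group"].unique())
    out = pd.DataFrame(np.nan, index=groups, columns=groups)
    for i, a in enumerate(groups):
        for j, b in enumerate(groups):
            if i == j:
                continue
            pair_seed = int(np.random.SeedSequence([seed, i, j]).generate_state(1)[0]
                            % (2**31))
            out.loc[a, b] = bootstrap_h2h(table, a, b, n, pair_seed,
                                          model_choice, metric_profile, phases)
    return out


def first_pick_rate(table: ScoreTable, group: str, metric_profile=None,
                    phases=None) -> float:
    """Fraction of targets where the group's first model is its best model.

    "First" is the lowest submitted model id; ties in average z count as
    success, as do single-model targets.
    """
    model_z = _model_z(table, metric_profile, phases)
    grp = model_z[model_z["group"] == group]
    if grp.empty:
        raise ValueError(f"group {group!r} has no scored models")
    successes, total = 0, 0
    for _, sub in grp.groupby(["target", "phase"]):
        first_z = sub.loc[sub["model"].idxmin(), "z"]
        if first_z >= sub["z"].max() - 1e-12:
            successes += 1
        total += 1
    return successes / total


def classify_difficulty(dockq_q95, tm_q95) -> str | None:
    """Difficult iff the 95% quantile of DockQ < 0.4 or of TM-score < 0.8."""
    if dockq_q95 is None or tm_q95 is None or \
            np.isnan(dockq_q95) or np.isnan(tm_q95):
        return None
    return "difficult" if (dockq_q95 < 0.4 or tm_q95 < 0.8) else "easy"


def quantile95(values) -> float | None:
    """95th percentile with linear interpolation between order statistics."""
    x = np.asarray(list(values), dtype=float)
    x = x[~np.isnan(x)]
    if len(x) == 0:
        return None
    return float(np.quantile(x, 0.95))


def phase_delta(table: ScoreTable, group: str, metric: str = "dockq",
                phase_from: str = "0", phase_to: str = "1") -> float | None:
    """Mean per-target first-model score change between two phases."""
    df = table.df
    df = df[(df["group"] == group) & (df["metric"] == metric) & (df["model"] <= 5)]
    firsts = {}
    for phase in (phase_from, phase_to):
        sub = df[df["phase"] == phase]
        if sub.empty:
            return None
        idx = sub.groupby("target")["model"].idxmin()
        firsts[phase] = sub.loc[idx].set_index("target")["value"]
    shared = firsts[phase_from].index.intersection(firsts[phase_to].index)
    if shared.empty:
        return None
    return float((firsts[phase_to][shared] - firsts[phase_from][shared]).mean())
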