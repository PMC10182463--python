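"""Calibration and accuracy biases of raters versus the computational model.

Two bias notions for severity ratings of the same events by different
parties:

* **Calibration bias** — the mean severity assigned by the receiving side
  (second-phase raters P2, or the model's predictions MP2) minus the mean
  severity assigned by the experiencing side (P1). The sign convention is
  receiver minus experiencer throughout.
* **Accuracy bias** — the inability of a receiver to rank events as the
  experiencers did: the Pearson correlation between paired P1 and P2 (or
  model) severities, computed per rater; lower r means larger bias.

Significance tests are two-sided independent two-sample t tests (pooled
variance by default, Welch optional). Calibration tests compare P1
per-event ratings against P2 per-rater means for humans and against
per-event mean model predictions for the model; accuracy tests compare the
per-rater r values of humans and the model on the raw r scale (a Fisher-z
option is available).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "SeveritySeries",
    "TestResult",
    "ConditionBias",
    "BiasReport",
    "ZeroVarianceError",
    "calibration_bias",
    "calibration_test",
    "accuracy_per_rater",
    "accuracy_by_rater",
    "accuracy_compare",
    "build_bias_report",
]

log = logging.getLogger(__name__)

CONDITIONS = ("both", "psychological", "physical")


class ZeroVarianceError(ValueError):
    """A correlation was requested on a constant vector."""


@dataclass
class SeveritySeries:
    """Severity values for one role (P1, P2, MP1 or MP2) and condition.

    ``values`` rows are (event_id, rater_id or None, severity). Severities
    live on the 0-10 scale; model predictions may exceed it slightly and
    are accepted with a warning rather than clipped.
    """

    role: str  # "P1" | "P2" | "MP1" | "MP2"
    condition: str  # "psychological" | "physical" | "both"
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(
                list(self.values), columns=["event_id", "rater_id", "severity"]
            )
        required = {"event_id", "rater_id", "severity"}
        if not required.issubset(self.values.columns):
            raise ValueError(f"SeveritySeries values need columns {sorted(required)}")
        sev = self.values["severity"].to_numpy(dtype=float)
        if self.role in ("P1", "P2") and ((sev < 0) | (sev > 10)).any():
            raise ValueError(f"{self.role} severities must lie in [0, 10]")

    @classmethod
    def from_values(
        cls,
        role: str,
        condition: str,
        severities: Iterable[float],
        event_ids: Iterable | None = None,
        rater_ids: Iterable | None = None,
    ) -> "SeveritySeries":
        sev = list(severities)
        events = list(event_ids) if event_ids is not None else list(range(len(sev)))
        raters = list(rater_ids) if rater_ids is not None else [None] * len(sev)
        return cls(
            role=role,
            condition=condition,
            values=pd.DataFrame(
                {"event_id": events, "rater_id": raters, "severity": sev}
            ),
        )

    @property
    def severities(self) -> np.ndarray:
        return self.values["severity"].to_numpy(dtype=float)

    def mean(self) -> float:
        return float(self.severities.mean())

    def sd(self) -> float:
        return float(self.severities.std(ddof=1))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p: float
    estimate: float

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p}")


def calibration_bias(p1: SeveritySeries, other: SeveritySeries) -> float:
    """Mean severity of the receiving side minus the P1 mean."""
    if len(p1.values) == 0 or len(other.values) == 0:
        raise ValueError("calibration_bias requires non-empty series")
    if p1.condition != other.condition:
        raise ValueError(
            f"condition mismatch: {p1.condition!r} vs {other.condition!r}"
        )
    return other.mean() - p1.mean()


def _two_sample_t(
    a: np.ndarray, b: np.ndarray, equal_var: bool = True
) -> TestResult:
    estimate = float(b.mean() - a.mean())
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        df = len(a) + len(b) - 2
        if np.isclose(a.mean(), b.mean()):
            return TestResult(statistic=0.0, df=df, p=1.0, estimate=estimate)
        warnings.warn("zero variance on both sides with unequal means", RuntimeWarning)
        return TestResult(statistic=float(np.inf) * np.sign(estimate), df=df, p=0.0, estimate=estimate)
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        warnings.warn("zero variance on one side of the t test", RuntimeWarning)
    res = scipy.stats.ttest_ind(b, a, equal_var=equal_var)
    df = int(round(float(res.df)))
    return TestResult(
        statistic=float(res.statistic), df=df, p=float(res.pvalue), estimate=estimate
    )


def calibration_test(
    p1: SeveritySeries,
    other: SeveritySeries,
    mode: str = "per-rater-means",
    equal_var: bool = True,
) -> TestResult:
    """Two-sided two-sample t test for a calibration shift.

    The P1 side always enters as its raw per-event ratings. The receiving
    side is aggregated per ``mode``: ``"per-rater-means"`` (one mean per
    rater; the human default), ``"per-event-means"`` (one mean per event;
    the model default, since model predictions have no rater), or
    ``"raw"``.
    """
    if p1.condition != other.condition:
        raise ValueError(
            f"condition mismatch: {p1.condition!r} vs {other.condition!r}"
        )
    a = p1.severities
    if mode == "per-rater-means":
        b = other.values.groupby("rater_id", sort=True)["severity"].mean().to_numpy()
    elif mode == "per-event-means":
        b = other.values.groupby("event_id", sort=True)["severity"].mean().to_numpy()
    elif mode == "raw":
        b = other.severities
    else:
        raise ValueError(f"unknown aggregation mode: {mode!r}")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("calibration_test needs at least 2 values per side")
    return _two_sample_t(a, b, equal_var=equal_var)


def accuracy_per_rater(
    p2_rater_values: SeveritySeries, p1: SeveritySeries
) -> float:
    """Pearson r between one rater's severities and the P1 ratings of the
    same events (matched by event id)."""
    p1_by_event = p1.values.set_index("event_id")["severity"]
    if p1_by_event.index.duplicated().any():
        p1_by_event = p1_by_event.groupby(level=0).mean()
    merged = p2_rater_values.values.dropna(subset=["severity"]).copy()
    merged["p1"] = merged["event_id"].map(p1_by_event)
    merged = merged.dropna(subset=["p1"])
    if len(merged) < 3:
        raise ValueError(
            f"need >= 3 shared events to correlate, got {len(merged)}"
        )
    x = merged["severity"].to_numpy(dtype=float)
    y = merged["p1"].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ZeroVarianceError("Pearson r undefined: zero variance in one vector")
    return float(scipy.stats.pearsonr(x, y).statistic)


def accuracy_by_rater(
    p2: SeveritySeries, p1: SeveritySeries
) -> dict:
    """Per-rater accuracy r for every rater present in a P2-style series."""
    out = {}
    for rater, sub in p2.values.groupby("rater_id", sort=True):
        series = SeveritySeries(role=p2.role, condition=p2.condition, values=sub)
        out[rater] = accuracy_per_rater(series, p1)
    return out


def accuracy_compare(
    human_rs: Sequence[float],
    model_rs: Sequence[float],
    fisher_z: bool = False,
    equal_var: bool = True,
) -> TestResult:
    """Two-sided t test of per-rater accuracy r, humans versus model.

    By default the comparison is on raw r values; with ``fisher_z`` both
    samples are arctanh-transformed first.
    """
    a = np.asarray(human_rs, dtype=float)
    b = np.asarray(model_rs, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("accuracy_compare needs at least 2 r values per group")
    if fisher_z:
        a, b = np.arctanh(a), np.arctanh(b)
    # statistic reported as human minus model, matching the sign of the
    # headline tests (negative t = humans less accurate)
    res = _two_sample_t(b, a, equal_var=equal_var)
    return res


def null_rejection_rate(
    n_replicates: int = 1000,
    n_per_side: int = 68,
    mu: float = 6.5,
    sigma: float = 2.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Monte-Carlo type-I error of the calibration t test under no shift.

    Each replicate draws two independent same-distribution severity samples
    through the generator's clip-and-round rating channel (the regime in
    which the pooled two-sample t is calibrated: independent events, equal
    variances) and tests at level ``alpha``. Note that on the real paired
    design — the same events rated by both sides, aggregated per rater —
    the test is conservative, so its size is checked here instead.
    """
    from semscale.synthetic import rating_channel

    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        a = rating_channel(rng.normal(mu, sigma, size=n_per_side))
        b = rating_channel(rng.normal(mu, sigma, size=n_per_side))
        res = calibration_test(
            SeveritySeries.from_values("P1", "both", a),
            SeveritySeries.from_values("P2", "both", b),
            mode="raw",
        )
        if res.p < alpha:
            rejections += 1
    return rejections / n_replicates


@dataclass
class ConditionBias:
    """One report row: the machine twin of a summary-table condition row."""

    condition: str
    n_points: int
    r_p1_p2: float
    r_p1_mp1: float | None
    r_p1_mp2: float | None
    p1_mean: float
    p1_sd: float
    p2_mean: float
    p2_sd: float
    mp2_mean: float | None
    mp2_sd: float | None
    human_bias: float
    computational_bias: float | None
    human_calibration: TestResult
    model_calibration: TestResult | None
    accuracy: TestResult | None
    human_accuracy_rs: dict = field(default_factory=dict)
    model_accuracy_rs: dict = field(default_factory=dict)


@dataclass
class BiasReport:
    rows: dict  # condition -> ConditionBias

    def to_frame(self) -> pd.DataFrame:
        records = []
        for cond in CONDITIONS:
            if cond not in self.rows:
                continue
            row = self.rows[cond]
            records.append(
                {
                    "condition": row.condition,
                    "n_points": row.n_points,
                    "r_p1_p2": row.r_p1_p2,
                    "r_p1_mp1": row.r_p1_mp1,
                    "r_p1_mp2": row.r_p1_mp2,
                    "p1_mean": row.p1_mean,
                    "p1_sd": row.p1_sd,
                    "p2_mean": row.p2_mean,
                    "p2_sd": row.p2_sd,
                    "mp2_mean": row.mp2_mean,
                    "mp2_sd": row.mp2_sd,
                    "human_bias": row.human_bias,
                    "computational_bias": row.computational_bias,
                    "human_calibration_t": row.human_calibration.statistic,
                    "human_calibration_df": row.human_calibration.df,
                    "human_calibration_p": round(row.human_calibration.p, 3),
                    "model_calibration_t": (
                        row.model_calibration.statistic if row.model_calibration else None
                    ),
                    "model_calibration_df": (
                        row.model_calibration.df if row.model_calibration else None
                    ),
                    "model_calibration_p": (
                        round(row.model_calibration.p, 3) if row.model_calibration else None
                    ),
                    "accuracy_t": row.accuracy.statistic if row.accuracy else None,
                    "accuracy_df": row.accuracy.df if row.accuracy else None,
                    "accuracy_p": round(row.accuracy.p, 3) if row.accuracy else None,
                    "mean_human_accuracy_r": (
                        float(np.mean(list(row.human_accuracy_rs.values())))
                        if row.human_accuracy_rs
                        else None
                    ),
                    "mean_model_accuracy_r": (
                        float(np.mean(list(row.model_accuracy_rs.values())))
                        if row.model_accuracy_rs
                        else None
                    ),
                }
            )
        return pd.DataFrame(records)

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "bias_report.tsv", sep="\t", index=False)
        payload = {}
        for cond, row in self.rows.items():
            payload[cond] = {
                "n_points": row.n_points,
                "human_bias": row.human_bias,
                "computational_bias": row.computational_bias,
                "human_calibration": row.human_calibration.__dict__,
                "model_calibration": (
                    row.model_calibration.__dict__ if row.model_calibration else None
                ),
                "accuracy": row.accuracy.__dict__ if row.accuracy else None,
                "human_accuracy_rs": {str(k): v for k, v in row.human_accuracy_rs.items()},
                "model_accuracy_rs": {str(k): v for k, v in row.model_accuracy_rs.items()},
            }
        (directory / "bias_report.json").write_text(
            json.dumps(payload, indent=2) + "\n", encoding="utf-8"
        )
        return directory / "bias_report.tsv"


def _pearson_pairs(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        raise ZeroVarianceError("Pearson r undefined: zero variance")
    return float(scipy.stats.pearsonr(x, y).statistic)


def build_bias_report(
    p1: pd.DataFrame,
    p2: pd.DataFrame,
    mp1: Mapping | None = None,
    mp2: Mapping | None = None,
    calibration_mode_human: str = "per-rater-means",
    calibration_mode_model: str = "per-event-means",
    fisher_z: bool = False,
) -> BiasReport:
    """Fill every summary-table column for both conditions and combined.

    ``p1`` needs columns event_id, condition, severity (one row per event);
    ``p2`` needs rater_id, event_id, condition, severity. ``mp1`` maps P1
    event_id to the model's predicted severity of the P1 response; ``mp2``
    maps (rater_id, event_id) to the model's prediction for that P2
    response. Missing model predictions yield a partial report with
    explicit gaps (None entries).
    """
    report_rows: dict[str, ConditionBias] = {}
    p1_by_event = p1.set_index("event_id")["severity"]

    for cond in CONDITIONS:
        p1_c = p1 if cond == "both" else p1[p1["condition"] == cond]
        p2_c = p2 if cond == "both" else p2[p2["condition"] == cond]
        if len(p1_c) == 0 or len(p2_c) == 0:
            continue

        p1_series = SeveritySeries(
            role="P1",
            condition=cond,
            values=p1_c.rename(columns={})[["event_id", "severity"]].assign(rater_id=None),
        )
        p2_series = SeveritySeries(
            role="P2", condition=cond, values=p2_c[["event_id", "rater_id", "severity"]]
        )

        paired_p1 = p2_c["event_id"].map(p1_by_event).to_numpy(dtype=float)
        r_p1_p2 = _pearson_pairs(paired_p1, p2_c["severity"].to_numpy(dtype=float))

        mp1_vals = r_p1_mp1 = None
        if mp1 is not None:
            mp1_vals = p1_c["event_id"].map(dict(mp1)).to_numpy(dtype=float)
            if np.isnan(mp1_vals).any():
                log.warning("missing MP1 predictions for condition %s", cond)
                mp1_vals = None
            else:
                r_p1_mp1 = _pearson_pairs(
                    p1_c["severity"].to_numpy(dtype=float), mp1_vals
                )

        mp2_vals = None
        r_p1_mp2 = mp2_mean = mp2_sd = computational_bias = None
        model_calibration = accuracy = None
        model_rs: dict = {}
        if mp2 is not None:
            keys = list(zip(p2_c["rater_id"], p2_c["event_id"]))
            mp2_map = dict(mp2)
            if all(k in mp2_map for k in keys):
                mp2_vals = np.array([mp2_map[k] for k in keys], dtype=float)
            else:
                log.warning("missing MP2 predictions for condition %s", cond)
        if mp2_vals is not None:
            r_p1_mp2 = _pearson_pairs(paired_p1, mp2_vals)
            mp2_mean = float(mp2_vals.mean())
            mp2_sd = float(mp2_vals.std(ddof=1))
            mp2_series = SeveritySeries(
                role="MP2",
                condition=cond,
                values=pd.DataFrame(
                    {
                        "event_id": p2_c["event_id"].to_numpy(),
                        "rater_id": p2_c["rater_id"].to_numpy(),
                        "severity": mp2_vals,
                    }
                ),
            )
            computational_bias = calibration_bias(p1_series, mp2_series)
            model_calibration = calibration_test(
                p1_series, mp2_series, mode=calibration_mode_model
            )
            model_rs = accuracy_by_rater(mp2_series, p1_series)

        human_rs = accuracy_by_rater(p2_series, p1_series)
        if model_rs:
            raters = sorted(human_rs)
            accuracy = accuracy_compare(
                [human_rs[r] for r in raters],
                [model_rs[r] for r in raters],
                fisher_z=fisher_z,
            )

        report_rows[cond] = ConditionBias(
            condition=cond,
            n_points=len(p2_c),
            r_p1_p2=r_p1_p2,
            r_p1_mp1=r_p1_mp1,
            r_p1_mp2=r_p1_mp2,
            p1_mean=p1_series.mean(),
            p1_sd=p1_series.sd(),
            p2_mean=p2_series.mean(),
            p2_sd=p2_series.sd(),
            mp2_mean=mp2_mean,
            mp2_sd=mp2_sd,
            human_bias=calibration_bias(p1_series, p2_series),
            computational_bias=computational_bias,
            human_calibration=calibration_test(
                p1_series, p2_series, mode=calibration_mode_human
            ),
            model_calibration=model_calibration,
            accuracy=accuracy,
            human_accuracy_rs=human_rs,
            model_accuracy_rs=model_rs,
        )
    return BiasReport(rows=report_rows)
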