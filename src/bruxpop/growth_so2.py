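"""Growth-curve parameter extraction and sulfite (SO2) tolerance calls.

OD600 time series measured under increasing molecular-SO2 doses are reduced
to three parameters per curve: lag phase (hours to 5% of the maximal OD
increase, linearly interpolated), maximal growth rate (largest log2 OD slope
between consecutive readings, in divisions per hour) and maximal OD.  A
strain is Sensitive when SO2 abolishes growth at some dose or significantly
depresses growth rate or plateau relative to dose 0 (Kruskal-Wallis across
doses, alpha = 5%); lag prolongation alone never makes a strain Sensitive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "GrowthCurve",
    "GrowthParams",
    "ToleranceCall",
    "growth_params",
    "kruskal_wallis",
    "classify_tolerance",
    "read_growth_csv",
    "params_table",
]

#: Minimum OD rise for a curve to count as growth.
DELTA_GROW = 0.2
#: Fraction of the maximal OD increase defining the end of the lag phase.
LAG_FRACTION = 0.05


@dataclass
class GrowthCurve:
    strain: str
    dose: float  # molecular SO2, mg/L
    replicate: str
    times: np.ndarray  # hours
    od: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if len(self.times) != len(self.od) or len(self.times) < 3:
            raise ValueError("need >= 3 paired (time, od) readings")
        if self.times[0] != 0:
            raise ValueError("first reading must be at inoculation (t = 0)")
        if (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if (self.od < 0).any():
            raise ValueError("negative OD readings")


@dataclass
class GrowthParams:
    strain: str
    dose: float
    replicate: str
    lag_h: Optional[float]
    r_max: float  # divisions per hour
    od_max: float
    grew: bool


@dataclass
class ToleranceCall:
    strain: str
    klass: Optional[str]  # "S" | "T" | None when undefined
    tests: dict = field(default_factory=dict)  # parameter -> (H, p)
    notes: str = ""
    effect_size_flag: bool = False  # monotone >=50% r_max decline (secondary)


def growth_params(
    curve: GrowthCurve,
    delta_grow: float = DELTA_GROW,
    lag_fraction: float = LAG_FRACTION,
) -> GrowthParams:
    """Reduce one OD600 trajectory to lag / max rate / max OD."""
    od = curve.od
    t = curve.times
    od0 = od[0]
    od_max = float(od.max())
    grew = od_max >= od0 + delta_grow
    if not grew:
        return GrowthParams(curve.strain, curve.dose, curve.replicate, None, 0.0, od_max, False)

    target = od0 + lag_fraction * (od_max - od0)
    lag = None
    for i in range(1, len(od)):
        if od[i] >= target:
            lo, hi = od[i - 1], od[i]
            if hi > lo:
                lag = t[i - 1] + (target - lo) / (hi - lo) * (t[i] - t[i - 1])
            else:
                lag = float(t[i])
            break
    if lag is None:
        lag = float(t[-1])
    lag = max(float(lag), 0.0)

    r_max = 0.0
    for i in range(len(od) - 1):
        if od[i] <= 0 or od[i + 1] <= 0:
            continue  # non-positive OD: skip pair
        rate = (np.log2(od[i + 1]) - np.log2(od[i])) / (t[i + 1] - t[i])
        r_max = max(r_max, rate)
    return GrowthParams(
        curve.strain, curve.dose, curve.replicate, lag, float(r_max), od_max, True
    )


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; (0, 1) when all values tie."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(flat) == 0:
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*groups)
    return float(h), float(p)


def classify_tolerance(
    params: list[GrowthParams], alpha: float = 0.05, min_decline: float = 0.10
) -> ToleranceCall:
    """Call a strain Sensitive (S) or Tolerant (T) from replicated parameters.

    S iff growth is absent in every replicate at some non-zero dose, or a
    Kruskal-Wallis test across doses is significant for r_max or od_max with
    the mean at some non-zero dose below the dose-0 mean by at least
    ``min_decline`` (relative; guards against rank tests flagging sub-noise
    dips at triplicate depth).  Otherwise T.  Undefined (None) when dose 0
    lacks >= 2 replicates or < 2 doses are replicated.  A secondary
    effect-size flag marks monotone >= 50% declines in mean r_max, kept
    separate from the test-based call.
    """
    strain = params[0].strain
    by_dose: dict[float, list[GrowthParams]] = {}
    for p in params:
        if p.strain != strain:
            raise ValueError("mixed strains in one classification call")
        by_dose.setdefault(p.dose, []).append(p)
    doses = sorted(by_dose)
    replicated = [d for d in doses if len(by_dose[d]) >= 2]
    if 0.0 not in by_dose or len(by_dose.get(0.0, [])) < 2 or len(replicated) < 2:
        return ToleranceCall(strain, None, notes="insufficient replication")

    tests: dict[str, tuple[float, float]] = {}
    notes = []

    # rule 1: total growth failure at a non-zero dose
    for d in doses:
        if d > 0 and all(not p.grew for p in by_dose[d]):
            notes.append(f"no growth at {d} mg/L in all replicates")

    sensitive = bool(notes)
    for attr in ("r_max", "od_max"):
        groups = [np.array([getattr(p, attr) for p in by_dose[d]]) for d in replicated]
        h, p_val = kruskal_wallis(groups)
        tests[attr] = (h, p_val)
        if p_val < alpha:
            mean0 = np.mean([getattr(p, attr) for p in by_dose[0.0]])
            for d in replicated:
                if d > 0 and np.mean(
                    [getattr(p, attr) for p in by_dose[d]]
                ) < (1.0 - min_decline) * mean0:
                    sensitive = True
                    notes.append(f"{attr} depressed at {d} mg/L (KW p={p_val:.3g})")
                    break
    # lag is tested and reported but never drives an S call
    lag_groups = [
        np.array([p.lag_h for p in by_dose[d] if p.lag_h is not None])
        for d in replicated
    ]
    if all(len(g) >= 2 for g in lag_groups):
        tests["lag_h"] = kruskal_wallis(lag_groups)

    r_means = [np.mean([p.r_max for p in by_dose[d]]) for d in replicated]
    effect = (
        all(b <= a + 1e-12 for a, b in zip(r_means, r_means[1:]))
        and r_means[0] > 0
        and r_means[-1] <= 0.5 * r_means[0]
    )
    return ToleranceCall(
        strain,
        "S" if sensitive else "T",
        tests=tests,
        notes="; ".join(notes),
        effect_size_flag=bool(effect),
    )


def read_growth_csv(path) -> list[GrowthCurve]:
    """Long-format CSV: strain, dose_mg_per_L, replicate, time_h, od600."""
    df = pd.read_csv(path)
    need = {"strain", "dose_mg_per_L", "replicate", "time_h", "od600"}
    if not need <= set(df.columns):
        raise ValueError(f"growth CSV must have columns {sorted(need)}")
    out = []
    for (strain, dose, rep), sub in df.groupby(
        ["strain", "dose_mg_per_L", "replicate"], sort=True
    ):
        sub = sub.sort_values("time_h")
        out.append(
            GrowthCurve(
                strain=str(strain),
                dose=float(dose),
                replicate=str(rep),
                times=sub["time_h"].to_numpy(float),
                od=sub["od600"].to_numpy(float),
            )
        )
    return out


def params_table(all_params: list[GrowthParams]) -> pd.DataFrame:
    """Per-strain mean lag / r_max / od_max per dose (wide summary)."""
    df = pd.DataFrame([vars(p) for p in all_params])
    agg = (
        df.groupby(["strain", "dose"])
        .agg(
            lag_h=("lag_h", "mean"),
            r_max=("r_max", "mean"),
            od_max=("od_max", "mean"),
            n_grew=("grew", "sum"),
            n=("grew", "size"),
        )
        .reset_index()
    )
    return agg
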