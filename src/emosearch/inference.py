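"""Posterior decision rules, standardized effect sizes, and report assembly.

Two conditions are deemed credibly different when their 95% credible
intervals do not overlap; a shared endpoint counts as overlap (the
conservative reading).  Standardized effect sizes use the delta_t index
for multilevel models: the posterior of the difference of group-level
means divided, draw by draw, by the square root of the summed variance
components of the model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "ComparisonResult",
    "ci_overlap_decision",
    "delta_t",
    "InferenceReport",
    "build_report",
]


@dataclass
class ComparisonResult:
    label: str
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    overlap: bool
    decision: str  # "credibly_different" | "not_distinguished"
    delta_t_median: float | None = None
    delta_t_ci: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def ci_overlap_decision(
    ci_a: tuple[float, float], ci_b: tuple[float, float], label: str = ""
) -> ComparisonResult:
    """Overlap test for two credible intervals (symmetric in its arguments)."""
    for ci in (ci_a, ci_b):
        lo, hi = ci
        if not (lo <= hi):
            raise ValueError(f"interval {ci} is not ordered")
    overlap = max(ci_a[0], ci_b[0]) <= min(ci_a[1], ci_b[1])
    return ComparisonResult(
        label=label,
        ci_a=(float(ci_a[0]), float(ci_a[1])),
        ci_b=(float(ci_b[0]), float(ci_b[1])),
        overlap=bool(overlap),
        decision="not_distinguished" if overlap else "credibly_different",
    )


def delta_t(
    draws_a: np.ndarray,
    draws_b: np.ndarray,
    sd_components: list[np.ndarray],
) -> dict:
    """Posterior of the standardized difference between two group means.

    Per draw: (a - b) / sqrt(sum of variance-component draws).  The
    components are the model's between-participant variance draws (plus a
    residual variance where the model has one); squaring is done here, so
    pass SD draws.  Scale-invariant: multiplying every input by k leaves
    delta_t unchanged.
    """
    a = np.asarray(draws_a, dtype=float).ravel()
    b = np.asarray(draws_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("draw vectors must be aligned and equal length")
    if not sd_components:
        raise ValueError("need at least one variance component")
    total_var = np.zeros_like(a)
    for comp in sd_components:
        comp = np.asarray(comp, dtype=float).ravel()
        if comp.shape != a.shape:
            raise ValueError("variance-component draws must align with the mean draws")
        if np.any(comp < 0):
            raise ValueError("variance components must be nonnegative")
        total_var = total_var + comp**2
    if np.any(total_var == 0):
        raise ValueError("zero total variance in at least one draw")
    d = (a - b) / np.sqrt(total_var)
    lo, med, hi = np.percentile(d, [2.5, 50, 97.5])
    return {
        "median": float(med),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "draws": d,
    }


@dataclass
class InferenceReport:
    """Machine-readable results: every posterior cell plus the comparisons."""

    rt_cells: list[dict] = field(default_factory=list)
    sdt_cells: list[dict] = field(default_factory=list)
    comparisons: list[dict] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "rt_cells": self.rt_cells,
            "sdt_cells": self.sdt_cells,
            "comparisons": self.comparisons,
            "diagnostics": self.diagnostics,
        }
        text = json.dumps(payload, indent=2, default=_jsonable)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "InferenceReport":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        return cls(
            rt_cells=payload["rt_cells"],
            sdt_cells=payload["sdt_cells"],
            comparisons=payload["comparisons"],
            diagnostics=payload.get("diagnostics", {}),
        )

    def rt_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.rt_cells)

    def sdt_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.sdt_cells)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def build_report(
    exg_posterior,
    sdt_posterior,
    comparisons: list[ComparisonResult] | None = None,
    rhat_threshold: float = 1.01,
    allow_unconverged: bool = False,
) -> InferenceReport:
    """Assemble posterior summaries and decisions into one report.

    Raises if any R-hat exceeds the threshold unless ``allow_unconverged``
    is set, and if any designed cell is missing from either posterior.
    """
    worst = max(exg_posterior.max_rhat, sdt_posterior.max_rhat)
    if worst > rhat_threshold and not allow_unconverged:
        raise RuntimeError(
            f"max R-hat {worst:.4f} exceeds {rhat_threshold}; "
            "pass allow_unconverged=True to override"
        )

    rt_cells = []
    exg = exg_posterior.summary
    groups = sorted(exg["group"].unique())
    conditions = sorted(exg["condition"].unique())
    for g in groups:
        for cond in conditions:
            for p in ("mu", "sigma", "tau"):
                row = exg[
                    (exg.group == g) & (exg.condition == cond) & (exg.parameter == p)
                ]
                if row.empty:
                    raise ValueError(f"missing RT cell {(g, cond, p)}")
                rt_cells.append(
                    dict(
                        group=g,
                        condition=cond,
                        parameter=p,
                        median=float(row["median"].iloc[0]),
                        ci_low=float(row.ci_low.iloc[0]),
                        ci_high=float(row.ci_high.iloc[0]),
                        rhat=float(row.rhat.iloc[0]),
                    )
                )

    sdt_cells = []
    sdt = sdt_posterior.summary
    for g in sorted(sdt["group"].unique()):
        for emo in sorted(sdt["emotion"].unique()):
            row = sdt[(sdt.group == g) & (sdt.emotion == emo) & (sdt.parameter == "d")]
            if row.empty:
                raise ValueError(f"missing sensitivity cell {(g, emo)}")
            sdt_cells.append(
                dict(
                    group=g,
                    emotion=emo,
                    parameter="d",
                    median=float(row["median"].iloc[0]),
                    ci_low=float(row.ci_low.iloc[0]),
                    ci_high=float(row.ci_high.iloc[0]),
                    rhat=float(row.rhat.iloc[0]),
                )
            )

    comp_dicts = []
    for c in comparisons or []:
        d = c.to_dict()
        comp_dicts.append(d)

    return InferenceReport(
        rt_cells=rt_cells,
        sdt_cells=sdt_cells,
        comparisons=comp_dicts,
        diagnostics={
            "max_rhat": worst,
            "rhat_threshold": rhat_threshold,
        },
    )
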