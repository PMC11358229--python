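"""Reaction-time outlier filtering and reduction to signal-detection counts.

Outliers follow Tukey's fence rule: a value is removed iff it lies
strictly above ``Q3 + 1.5*IQR`` or strictly below ``Q1 - 1.5*IQR``.
Quartiles use linear interpolation between order statistics (numpy's
default), the common convention in R/numpy; Tukey's original hinges
differ slightly on small samples.  Fences are computed per participant x
condition by default, respecting the large group- and condition-level RT
differences, and the pooled removed fraction is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterReport",
    "TukeyOutlierFilter",
    "tukey_filter",
    "filter_trials",
    "to_sdt_counts",
]


@dataclass
class FilterReport:
    n_total: int
    n_removed: int
    fences: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def fraction_removed(self) -> float:
        return self.n_removed / self.n_total if self.n_total else 0.0

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_removed": self.n_removed,
            "fraction_removed": self.fraction_removed,
            "fences": {k: list(v) for k, v in self.fences.items()},
        }


def _fences(values: np.ndarray) -> tuple[float, float]:
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return float(q1 - 1.5 * iqr), float(q3 + 1.5 * iqr)


def tukey_filter(rts) -> tuple[np.ndarray, FilterReport]:
    """Keep-mask and report for one sequence of RTs under the fence rule.

    Strict inequalities: values exactly on a fence are kept, so a
    zero-IQR sample (all values equal) removes nothing.
    """
    values = np.asarray(rts, dtype=float)
    if values.ndim != 1:
        raise ValueError("rts must be one-dimensional")
    if len(values) < 4 or not np.all(np.isfinite(values)):
        raise ValueError("need at least 4 finite values to place Tukey fences")
    lo, hi = _fences(values)
    keep = (values >= lo) & (values <= hi)
    report = FilterReport(
        n_total=len(values), n_removed=int((~keep).sum()), fences={"all": (lo, hi)}
    )
    return keep, report


class TukeyOutlierFilter:
    """Tukey-fence RT filter over a trial table (sklearn-style transformer).

    Parameters
    ----------
    scope : {"cell", "participant", "global"}
        Grouping within which fences are placed.  "cell" (default) is
        participant x condition.
    """

    _SCOPES = ("cell", "participant", "global")

    def __init__(self, scope: str = "cell"):
        self.scope = scope

    def get_params(self, deep: bool = True) -> dict:
        return {"scope": self.scope}

    def set_params(self, **params) -> "TukeyOutlierFilter":
        for k, v in params.items():
            if k != "scope":
                raise ValueError(f"unknown parameter {k!r}")
            self.scope = v
        return self

    def _group_keys(self, trials: pd.DataFrame):
        if self.scope == "cell":
            return [trials["participant_id"], trials["condition"]]
        if self.scope == "participant":
            return [trials["participant_id"]]
        if self.scope == "global":
            return [np.zeros(len(trials), dtype=int)]
        raise ValueError(f"scope must be one of {self._SCOPES}, got {self.scope!r}")

    def fit(self, trials: pd.DataFrame, y=None) -> "TukeyOutlierFilter":
        if "rt" not in trials.columns:
            raise ValueError("trial table must have an 'rt' column")
        self._group_keys(trials)  # validates scope
        keep = np.ones(len(trials), dtype=bool)
        fences: dict[str, tuple[float, float]] = {}
        rt = trials["rt"].to_numpy(dtype=float)
        for key, idx in trials.groupby(self._group_keys(trials), sort=True).indices.items():
            mask, rep = tukey_filter(rt[idx])
            keep[idx] = mask
            label = key if isinstance(key, str) else "/".join(map(str, np.atleast_1d(key)))
            fences[label] = rep.fences["all"]
        self.keep_mask_ = keep
        self.report_ = FilterReport(
            n_total=len(trials), n_removed=int((~keep).sum()), fences=fences
        )
        return self

    def transform(self, trials: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "keep_mask_") or len(self.keep_mask_) != len(trials):
            self.fit(trials)
        return trials.loc[self.keep_mask_].reset_index(drop=True)

    def fit_transform(self, trials: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(trials).transform(trials)


def filter_trials(
    trials: pd.DataFrame, scope: str = "cell"
) -> tuple[pd.DataFrame, FilterReport]:
    """Functional wrapper: filtered table plus its report."""
    f = TukeyOutlierFilter(scope=scope)
    out = f.fit_transform(trials)
    return out, f.report_


def to_sdt_counts(trials: pd.DataFrame) -> pd.DataFrame:
    """Reduce trials to per-participant hit / false-alarm counts.

    One row per participant x emotion.  Hits are target-present trials of
    that emotion answered "different"; false alarms are target-absent
    trials answered "different".  Target-absent trials are shared by both
    emotions of a participant, so both rows carry the same noise counts.
    """
    required = {"participant_id", "group", "condition", "response"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    rows = []
    for pid, pdf in trials.groupby("participant_id", sort=True):
        absent = pdf[pdf["condition"] == "target_absent"]
        if absent.empty:
            raise ValueError(f"participant {pid!r} has no target-absent trials")
        n_noise = len(absent)
        n_fa = int((absent["response"] == "different").sum())
        group = pdf["group"].iloc[0]
        for emo, cond in (("angry", "angry_target"), ("happy", "happy_target")):
            present = pdf[pdf["condition"] == cond]
            rows.append(
                dict(
                    participant_id=pid,
                    group=group,
                    emotion=emo,
                    n_signal=len(present),
                    n_hits=int((present["response"] == "different").sum()),
                    n_noise=n_noise,
                    n_false_alarms=n_fa,
                )
            )
    return pd.DataFrame(rows)
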