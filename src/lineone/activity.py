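"""Dual-luciferase retrotransposition assay: normalization and activity calls.

Each 96-well plate carries positive-control wells (a highly active reference
element) and negative-control wells (empty vector). Per well, the
transfection-normalized signal is the firefly/renilla ratio r; percent
activity anchors the plate's mean negative-control ratio at 0% and mean
positive-control ratio at 100%:

    percent = 100 * (r - mean(r_neg)) / (mean(r_pos) - mean(r_neg))

A construct is called active when its grand-mean percent exceeds the
threshold (default 5% of the positive control) AND a one-sided Welch t-test
against the pooled negative-control percents rejects at alpha (constructs
indistinguishable from the negative control are treated as 0% downstream).

Input is a tidy CSV/DataFrame with columns
``plate_id, well, construct_id, clone_id, role, firefly, renilla``
(role in {test, pos, neg}), plus an optional boolean ``excluded`` column for
clones disqualified by sequence deviations; excluded wells never enter any
mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

ACTIVITY_THRESHOLD = 5.0  # percent of positive control
ALPHA = 0.05
MIN_CONTROL_WELLS = 4
MIN_WELLS = 3


class PlateError(ValueError):
    pass


@dataclass(frozen=True)
class ActivityCall:
    construct_id: str
    percents: Tuple[float, ...]
    mean_pct: float
    p_value: float
    active: bool
    n_wells: int
    low_replicate: bool = False

    @property
    def effective_pct(self) -> float:
        """Percent used downstream: constructs not separable from the
        negative control count as 0."""
        return self.mean_pct if self.active or self.p_value < ALPHA else 0.0


def normalize_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Add a ``pct`` column of control-anchored percent activity for one plate.

    Raises PlateError when the positive-control mean ratio does not exceed
    the negative-control mean (a failed plate), and ValueError on
    non-positive renilla readings. Warns when fewer than 4 control wells of
    either kind are available.
    """
    df = plate.copy()
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    if (df["renilla"] <= 0).any():
        raise ValueError("renilla readings must be positive")
    if (df["firefly"] < 0).any():
        raise ValueError("firefly readings must be non-negative")
    df["ratio"] = df["firefly"] / df["renilla"]
    pos = df.loc[df["role"] == "pos", "ratio"]
    neg = df.loc[df["role"] == "neg", "ratio"]
    if len(pos) < 1 or len(neg) < 1:
        raise PlateError("plate lacks positive or negative control wells")
    if len(pos) < MIN_CONTROL_WELLS or len(neg) < MIN_CONTROL_WELLS:
        warnings.warn(
            f"plate {plate['plate_id'].iloc[0]!r}: fewer than "
            f"{MIN_CONTROL_WELLS} wells of each control"
        )
    r_pos, r_neg = pos.mean(), neg.mean()
    if r_pos <= r_neg:
        raise PlateError(
            f"plate failure: positive-control mean ratio {r_pos:.4g} <= "
            f"negative-control mean {r_neg:.4g}"
        )
    df["pct"] = 100.0 * (df["ratio"] - r_neg) / (r_pos - r_neg)
    return df


def call_active(
    percents: np.ndarray,
    negative_percents: np.ndarray,
    construct_id: str = "",
    threshold: float = ACTIVITY_THRESHOLD,
    alpha: float = ALPHA,
    min_wells: int = MIN_WELLS,
) -> ActivityCall:
    """Activity call for one construct from its pooled per-well percents."""
    percents = np.asarray(percents, dtype=float)
    negative_percents = np.asarray(negative_percents, dtype=float)
    if len(percents) < min_wells:
        warnings.warn(
            f"{construct_id}: only {len(percents)} wells (<{min_wells}); "
            "call made with low-replicate flag"
        )
    mean_pct = float(percents.mean())
    # one-sided Welch test: construct percents located above the negatives
    t_res = stats.ttest_ind(
        percents, negative_percents, equal_var=False, alternative="greater"
    )
    p = float(t_res.pvalue)
    active = bool(mean_pct > threshold and p < alpha)
    return ActivityCall(
        construct_id=construct_id,
        percents=tuple(percents),
        mean_pct=mean_pct,
        p_value=p,
        active=active,
        n_wells=len(percents),
        low_replicate=len(percents) < min_wells,
    )


def process_plates(
    plates: pd.DataFrame,
    threshold: float = ACTIVITY_THRESHOLD,
    alpha: float = ALPHA,
) -> Dict[str, ActivityCall]:
    """Normalize every plate and call activity per construct (pooled wells)."""
    normalized = pd.concat(
        [normalize_plate(g) for _, g in plates.groupby("plate_id")],
        ignore_index=True,
    )
    neg = normalized.loc[normalized["role"] == "neg", "pct"].to_numpy()
    calls: Dict[str, ActivityCall] = {}
    tests = normalized[normalized["role"] == "test"]
    for construct_id, grp in tests.groupby("construct_id"):
        calls[str(construct_id)] = call_active(
            grp["pct"].to_numpy(), neg, str(construct_id), threshold, alpha
        )
    return calls
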