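"""Summary statistics over per-position edit matrices.

Per-position average profiles (each member contributes its own target
position), the editing window (positions whose average clears 20% of the
peak average), flank-context matrices, and the C-over-A selectivity ratio
(geometric mean of per-position ratios, with denominators below the 0.1%
detection limit floored so censored results are lower bounds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError

DEFAULT_WINDOW_THRESHOLD = 0.20
DEFAULT_SELECTIVITY_POSITIONS = (4, 5, 6, 7, 8)
DEFAULT_LOD = 0.1  # percent of reads


@dataclass
class AggregateProfile:
    conversion: str
    values: dict  # position -> average efficiency (%)
    counts: dict  # position -> number of members averaged

    def positions(self) -> list:
        return sorted(self.values)


@dataclass
class EditingWindow:
    threshold: float
    peak_position: int
    peak_value: float
    window: tuple  # contiguous run containing the peak
    above_threshold: tuple  # full above-threshold position set

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "peak_position": self.peak_position,
            "peak_value": self.peak_value,
            "window": list(self.window),
            "above_threshold": list(self.above_threshold),
        }


@dataclass
class SelectivityResult:
    positions: tuple
    ratios: dict  # position -> C/A ratio after censoring
    geometric_mean: float
    censored: dict  # position -> bool (A average floored at LOD)
    lower_bound: bool
    lod: float

    def to_dict(self) -> dict:
        return {
            "positions": list(self.positions),
            "ratios": {str(k): v for k, v in self.ratios.items()},
            "geometric_mean": self.geometric_mean,
            "censored": {str(k): bool(v) for k, v in self.censored.items()},
            "lower_bound": self.lower_bound,
            "lod": self.lod,
        }


@dataclass
class ContextMatrix:
    conversion: str
    position: int
    values: dict  # (flank5, flank3) -> efficiency (possibly normalized)
    normalized: bool
    missing: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"flank5": k[0], "flank3": k[1], "value": v} for k, v in sorted(self.values.items())
        ]
        return pd.DataFrame(rows)


def _target_rows(edits: pd.DataFrame, manifest: pd.DataFrame, conversion: str) -> pd.DataFrame:
    """Rows where each member is scored at its own target position for `conversion`."""
    ref = conversion[0]
    members = manifest[manifest["target_base"] == ref][
        ["member_id", "target_position", "flank5", "flank3"]
    ]
    merged = edits.merge(members, on="member_id", how="inner")
    return merged[
        (merged["position"] == merged["target_position"])
        & (merged["conversion"] == conversion)
    ]


def position_profile(edits: pd.DataFrame, manifest: pd.DataFrame,
                     conversion: str) -> AggregateProfile:
    """Average efficiency per target position over members carrying that target.

    The target base is the conversion's reference base; positions without
    members are omitted.
    """
    rows = _target_rows(edits, manifest, conversion)
    if rows.empty:
        import warnings

        warnings.warn(f"no members for conversion {conversion}; empty profile")
        return AggregateProfile(conversion, {}, {})
    grouped = rows.groupby("position")["efficiency_pct"].agg(["mean", "count"])
    return AggregateProfile(
        conversion,
        {int(p): float(r["mean"]) for p, r in grouped.iterrows()},
        {int(p): int(r["count"]) for p, r in grouped.iterrows()},
    )


def editing_window(profile: AggregateProfile,
                   threshold: float = DEFAULT_WINDOW_THRESHOLD) -> EditingWindow:
    """Positions whose average clears threshold x peak; window is the
    contiguous above-threshold run containing the peak (ties -> smallest
    position)."""
    if not profile.values:
        raise DataError("empty profile; editing window undefined")
    vals = profile.values
    peak_val = max(vals.values())
    if peak_val <= 0:
        raise DataError("all-zero profile; editing window undefined")
    peak_pos = min(p for p, v in vals.items() if v == peak_val)
    cut = threshold * peak_val
    above = sorted(p for p, v in vals.items() if v >= cut)
    window = [peak_pos]
    p = peak_pos - 1
    while p in above:
        window.append(p)
        p -= 1
    p = peak_pos + 1
    while p in above:
        window.append(p)
        p += 1
    return EditingWindow(threshold, peak_pos, peak_val, tuple(sorted(window)), tuple(above))


def selectivity_ratio(c_profile: AggregateProfile, a_profile: AggregateProfile,
                      positions=DEFAULT_SELECTIVITY_POSITIONS,
                      lod: float = DEFAULT_LOD) -> SelectivityResult:
    """Geometric mean over positions of avg C editing / avg A editing.

    A averages below the detection limit are floored at `lod`; any censoring
    marks the geometric mean as a lower bound.
    """
    positions = tuple(int(p) for p in positions)
    if not positions:
        raise ValidationError("selectivity requires at least one position")
    for p in positions:
        if p not in c_profile.values or p not in a_profile.values:
            raise ValidationError(f"profiles undefined at position {p}")
    ratios, censored = {}, {}
    zero_c = False
    for p in positions:
        c = c_profile.values[p]
        a = a_profile.values[p]
        cen = a < lod
        denom = max(a, lod)
        censored[p] = cen
        if c <= 0:
            ratios[p] = 0.0
            zero_c = True
        else:
            ratios[p] = c / denom
    if zero_c:
        import warnings

        warnings.warn("zero C editing at some position; geometric mean reported as 0")
        gm = 0.0
    else:
        gm = math.exp(sum(math.log(r) for r in ratios.values()) / len(ratios))
    return SelectivityResult(
        positions=positions,
        ratios=ratios,
        geometric_mean=gm,
        censored=censored,
        lower_bound=any(censored.values()),
        lod=lod,
    )


def context_matrix(edits: pd.DataFrame, manifest: pd.DataFrame, position: int,
                   conversion: str, normalize: bool = False,
                   flank_alphabet: str = "ACGT") -> ContextMatrix:
    """16-entry (flank5, flank3) efficiency table at one target position."""
    rows = _target_rows(edits, manifest, conversion)
    rows = rows[rows["position"] == position]
    values, missing = {}, []
    for f5 in flank_alphabet:
        for f3 in flank_alphabet:
            sub = rows[(rows["flank5"] == f5) & (rows["flank3"] == f3)]
            if sub.empty:
                missing.append((f5, f3))
            else:
                values[(f5, f3)] = float(sub["efficiency_pct"].mean())
    if normalize and values:
        top = max(values.values())
        if top > 0:
            values = {k: v / top for k, v in values.items()}
    return ContextMatrix(conversion, position, values, normalize, missing)
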