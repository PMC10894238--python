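"""Editing-weighted flank-context frequencies and Kullback-Leibler logos.

For each side of the edited base, member efficiencies are summed per flank
base over all window positions and normalized by the total; letter heights
are f * log2(f / 0.25), so the column height equals the KL divergence from
the uniform background (0 for uniform input, 2 bits for a point mass).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import DataError, ValidationError
from .library_design import BASES
from .profile_stats import EditingWindow, _target_rows

BACKGROUND = 0.25
SUM_TOL = 1e-9


@dataclass
class LogoMatrix:
    side: str  # "5p" or "3p"
    frequencies: dict  # base -> f in [0, 1]
    information: dict  # base -> f * log(f / background), signed
    background: float = BACKGROUND
    log_base: float = 2.0

    @property
    def total_information(self) -> float:
        return sum(self.information.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "side": self.side,
                    "base": b,
                    "frequency": self.frequencies[b],
                    "information": self.information[b],
                }
                for b in BASES
            ]
        )


def context_frequencies(edits: pd.DataFrame, manifest: pd.DataFrame,
                        window, side: str, conversion: str) -> dict:
    """Editing-weighted flank-base frequencies over the window positions.

    f_b = sum of efficiencies of members whose `side` flank is b (over all
    window positions) / total editing over all contexts.
    """
    positions = list(window.window) if isinstance(window, EditingWindow) else list(window)
    if not positions:
        raise ValidationError("window must contain at least one position")
    if side not in ("5p", "3p"):
        raise ValidationError("side must be '5p' or '3p'")
    flank_col = "flank5" if side == "5p" else "flank3"
    rows = _target_rows(edits, manifest, conversion)
    rows = rows[rows["position"].isin(positions)]
    total = rows["efficiency_pct"].sum()
    if total <= 0:
        raise DataError("zero total editing over the window; frequencies undefined")
    sums = rows.groupby(flank_col)["efficiency_pct"].sum()
    return {b: float(sums.get(b, 0.0)) / total for b in BASES}


def information_content(frequencies: dict, background: float = BACKGROUND,
                        log_base: float = 2.0, side: str = "5p") -> LogoMatrix:
    """Letter heights f * log(f / background); f = 0 contributes 0."""
    if not 0.0 < background < 1.0:
        raise ValidationError("background must lie in (0, 1)")
    total = sum(frequencies.get(b, 0.0) for b in BASES)
    if abs(total - 1.0) > SUM_TOL:
        raise ValidationError(f"frequencies must sum to 1, got {total}")
    info = {}
    for b in BASES:
        f = frequencies.get(b, 0.0)
        info[b] = 0.0 if f == 0.0 else f * math.log(f / background, log_base)
    return LogoMatrix(side, {b: frequencies.get(b, 0.0) for b in BASES}, info,
                      background, log_base)


def compute_logo(edits: pd.DataFrame, manifest: pd.DataFrame, window,
                 conversion: str, background: float = BACKGROUND,
                 log_base: float = 2.0) -> pd.DataFrame:
    """Both-side logo matrix as a long-format frame (side, base, frequency, IC)."""
    frames = []
    for side in ("5p", "3p"):
        freqs = context_frequencies(edits, manifest, window, side, conversion)
        frames.append(information_content(freqs, background, log_base, side).to_frame())
    return pd.concat(frames, ignore_index=True)


def plot_logo(logo: pd.DataFrame, path=None):
    """Render letter heights as signed bars (one panel per side).

    Requires matplotlib; import deferred so headless use never pays for it.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#cc2222", "C": "#22aa22", "G": "#2244cc", "T": "#ccaa00"}
    sides = ["5p", "3p"]
    fig, axes = plt.subplots(1, 2, figsize=(6, 3), sharey=True)
    for ax, side in zip(axes, sides):
        sub = logo[logo["side"] == side]
        ax.bar(sub["base"], sub["information"],
               color=[colors[b] for b in sub["base"]])
        ax.axhline(0, color="black", lw=0.8)
        ax.set_title(f"{side} flank")
        ax.set_ylabel("bits")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
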