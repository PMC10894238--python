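"""Directed-evolution bookkeeping: plaque titers, fold enrichment, and
cumulative fold-dilution across serial-passage and continuous-flow segments.

Totals are accumulated in log10 space (campaign totals reach 1e61)."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import DataError, ValidationError

LN10 = math.log(10.0)


def plaque_titer(plaque_count: int, dilution_factor: float) -> float:
    """Titer in PFU/ml: plaques x dilution factor x 100."""
    if plaque_count < 0:
        raise ValidationError("plaque count must be non-negative")
    if dilution_factor <= 0:
        raise ValidationError("dilution factor must be positive")
    return plaque_count * dilution_factor * 100.0


def fold_enrichment(output_titer: float, input_titer: float) -> float:
    """Output titer over input titer after propagation."""
    if input_titer <= 0:
        raise DataError("fold enrichment undefined for non-positive input titer")
    return output_titer / input_titer


@dataclass(frozen=True)
class TiterMeasurement:
    plaque_count: int
    dilution_factor: float
    titer: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "titer", plaque_titer(self.plaque_count, self.dilution_factor))


@dataclass(frozen=True)
class DilutionSegment:
    """One campaign segment: discrete per-passage factors or continuous washout."""

    kind: str  # "discrete" | "continuous"
    label: str = ""
    factors: tuple = ()  # discrete: fold dilution per passage, each >= 1
    rate_per_hour: float = 0.0  # continuous: lagoon volumes / hour
    hours: float = 0.0

    def __post_init__(self):
        if self.kind not in ("discrete", "continuous"):
            raise ValidationError(f"unknown segment kind {self.kind!r}")
        if self.kind == "discrete":
            for f in self.factors:
                if f < 1:
                    raise ValidationError(f"fold dilution {f} < 1")
        else:
            if self.rate_per_hour < 0 or self.hours < 0:
                raise ValidationError("rate and duration must be >= 0")

    def log10_fold(self) -> float:
        if self.kind == "discrete":
            return sum(math.log10(f) for f in self.factors)
        # ideal well-mixed washout: fold = exp(rate * time)
        return self.rate_per_hour * self.hours / LN10


@dataclass(frozen=True)
class DilutionCampaign:
    segments: tuple
    label: str = ""

    def log10_fold(self) -> float:
        return sum(s.log10_fold() for s in self.segments)


def cumulative_fold_dilution(campaigns) -> dict:
    """Total fold-dilution across campaigns, reported in log10 space.

    Returns per-campaign and overall log10 folds; log10 is additive over
    segments, so segment order never changes the total.
    """
    per = []
    total = 0.0
    for c in campaigns:
        lg = c.log10_fold()
        per.append({"label": c.label, "log10_fold": lg})
        total += lg
    return {"campaigns": per, "total_log10_fold": total}


def campaign_from_dict(d: dict) -> DilutionCampaign:
    segments = []
    for s in d.get("segments", []):
        kind = s.get("type", s.get("kind"))
        if kind == "discrete":
            segments.append(DilutionSegment(
                kind="discrete", label=s.get("label", ""),
                factors=tuple(float(f) for f in s.get("factors", ())),
            ))
        elif kind == "continuous":
            segments.append(DilutionSegment(
                kind="continuous", label=s.get("label", ""),
                rate_per_hour=float(s.get("rate_per_hour", 0.0)),
                hours=float(s.get("hours", 0.0)),
            ))
        else:
            raise ValidationError(f"segment type must be discrete|continuous, got {kind!r}")
    return DilutionCampaign(segments=tuple(segments), label=d.get("label", ""))


def load_campaigns(path) -> list:
    """Read a campaign YAML: either one mapping or a list of mappings."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, dict):
        data = [data]
    return [campaign_from_dict(d) for d in data]
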