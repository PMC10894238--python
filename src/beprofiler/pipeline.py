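"""End-to-end orchestration: design -> simulate -> call -> stats -> logo.

One seed governs every stochastic stage; identical config + seed yields
byte-identical tables (checksummed in the run report).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import context_logo, edit_caller, library_design, profile_stats, synthetic_reads
from .errors import BeprofilerError, ValidationError

log = logging.getLogger("beprofiler")

EXIT_OK = 0
EXIT_CONFIG = 2
EXIT_DATA = 3


@dataclass
class LibraryConfig:
    targets: str = "AC"
    positions: tuple = tuple(range(1, 15))
    umi_length: int = 10
    min_umi_distance: int = 3


@dataclass
class SimulationConfig:
    p_target: float = 0.9
    p_cross: float = 0.0
    error_rate: float = 0.0
    indel_rate: float = 0.0
    depth: int = 500
    replicates: int = 2
    quality: int = 30


@dataclass
class CallerConfig:
    qmin: int = 20
    min_reads: int = 100
    max_umi_mismatch: int = 1


@dataclass
class StatsConfig:
    window_threshold: float = 0.20
    selectivity_positions: tuple = (4, 5, 6, 7, 8)
    lod: float = 0.1


@dataclass
class RunConfig:
    library: LibraryConfig = field(default_factory=LibraryConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    caller: CallerConfig = field(default_factory=CallerConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    outdir: str = "beprofiler_run"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["library"]["positions"] = list(d["library"]["positions"])
        d["stats"]["selectivity_positions"] = list(d["stats"]["selectivity_positions"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = {}
        for name, sub in (("library", LibraryConfig), ("simulation", SimulationConfig),
                          ("caller", CallerConfig), ("stats", StatsConfig)):
            if name in d:
                block = dict(d[name])
                if "positions" in block:
                    block["positions"] = tuple(block["positions"])
                if "selectivity_positions" in block:
                    block["selectivity_positions"] = tuple(block["selectivity_positions"])
                kw[name] = sub(**block)
        for name in ("outdir", "seed"):
            if name in d:
                kw[name] = d[name]
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def validate_config(config: RunConfig) -> list:
    """Return every violated invariant with its field path (empty list = ok)."""
    v = []
    lib = config.library
    if not lib.targets or any(b not in "AC" for b in lib.targets):
        v.append("library.targets: must be a nonempty subset of {A, C}")
    for p in lib.positions:
        if not 1 <= int(p) <= 20:
            v.append(f"library.positions: position {p} outside [1, 20]")
    if lib.umi_length < 1:
        v.append("library.umi_length: must be >= 1 for demultiplexing")
    sim = config.simulation
    for name in ("p_target", "p_cross", "error_rate", "indel_rate"):
        val = getattr(sim, name)
        if not 0.0 <= val <= 1.0:
            v.append(f"simulation.{name}: {val} outside [0, 1]")
    if sim.depth < 0:
        v.append("simulation.depth: must be >= 0")
    if sim.replicates < 1:
        v.append("simulation.replicates: must be >= 1")
    cal = config.caller
    if cal.qmin < 0:
        v.append("caller.qmin: must be >= 0")
    if cal.min_reads < 0:
        v.append("caller.min_reads: must be >= 0")
    if lib.min_umi_distance <= 2 * cal.max_umi_mismatch:
        v.append("caller.max_umi_mismatch: requires library.min_umi_distance "
                 f"> {2 * cal.max_umi_mismatch}")
    st = config.stats
    if not 0.0 < st.window_threshold <= 1.0:
        v.append("stats.window_threshold: must lie in (0, 1]")
    if st.lod <= 0:
        v.append("stats.lod: must be > 0")
    libpos = set(int(p) for p in lib.positions)
    for p in st.selectivity_positions:
        if int(p) not in libpos:
            v.append(f"stats.selectivity_positions: position {p} not scored by the library")
    return v


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, writing intermediate artifacts and a run report."""
    violations = validate_config(config)
    if violations:
        raise ValidationError("; ".join(violations))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {"config": config.to_dict(), "stages": {}, "files": {}, "headline": {}}
    t0 = time.time()

    def stage_done(name, **info):
        report["stages"][name] = {"seconds": round(time.time() - t0, 3), **info}
        log.info("stage %s done (%.2fs)", name, time.time() - t0)

    # design
    spec = library_design.ContextLibrarySpec(
        target_bases=tuple(config.library.targets),
        positions=tuple(config.library.positions),
        umi_length=config.library.umi_length,
        min_umi_distance=config.library.min_umi_distance,
    )
    table = library_design.enumerate_context_library(spec, seed=config.seed)
    paths = library_design.write_library(table, outdir)
    stage_done("design", members=len(table))

    # simulate
    sim_cfg = synthetic_reads.ReadSimConfig(
        p_target=config.simulation.p_target,
        p_cross=config.simulation.p_cross,
        error_rate=config.simulation.error_rate,
        indel_rate=config.simulation.indel_rate,
        depth=config.simulation.depth,
        replicates=config.simulation.replicates,
        quality=config.simulation.quality,
        seed=config.seed,
    )
    sim = synthetic_reads.simulate_reads(table, sim_cfg, outdir=outdir)
    stage_done("simulate", reads=sum(len(r) for r in sim.reads))

    # call, per replicate
    rep_frames = []
    summaries = []
    for rep, reads in enumerate(sim.reads, start=1):
        edits, summary = edit_caller.call_edits(
            reads, table, qmin=config.caller.qmin, min_reads=config.caller.min_reads,
            max_umi_mismatch=config.caller.max_umi_mismatch,
        )
        edits.to_csv(outdir / f"edits_rep{rep}.tsv", sep="\t", index=False)
        rep_frames.append(edits)
        summaries.append({k: v for k, v in summary.items() if k != "per_member"})
    agg = edit_caller.aggregate_replicates(rep_frames)
    agg.to_csv(outdir / "edits_mean.tsv", sep="\t", index=False)
    stage_done("call", replicates=len(rep_frames))

    # stats
    manifest = table.to_manifest()
    headline = {}
    c_profile = profile_stats.position_profile(agg, manifest, "C2T")
    a_profile = profile_stats.position_profile(agg, manifest, "A2G")
    profile_rows = []
    for prof in (c_profile, a_profile):
        for p in prof.positions():
            profile_rows.append({"conversion": prof.conversion, "position": p,
                                 "mean_efficiency_pct": prof.values[p],
                                 "n_members": prof.counts[p]})
    import pandas as pd

    pd.DataFrame(profile_rows).to_csv(outdir / "profiles.tsv", sep="\t", index=False)

    window = None
    if c_profile.values and max(c_profile.values.values()) > 0:
        window = profile_stats.editing_window(c_profile, config.stats.window_threshold)
        (outdir / "window.json").write_text(json.dumps(window.to_dict(), indent=2))
        headline["window"] = window.to_dict()

    sel_pos = [p for p in config.stats.selectivity_positions
               if p in c_profile.values and p in a_profile.values]
    if sel_pos:
        sel = profile_stats.selectivity_ratio(
            c_profile, a_profile, positions=sel_pos, lod=config.stats.lod)
        (outdir / "selectivity.json").write_text(json.dumps(sel.to_dict(), indent=2))
        headline["selectivity"] = sel.to_dict()
    stage_done("stats")

    # logo over the computed window
    if window is not None:
        logo = context_logo.compute_logo(agg, manifest, window, "C2T")
        logo.to_csv(outdir / "logo.tsv", sep="\t", index=False)
        headline["logo_total_information_bits"] = {
            side: float(logo[logo["side"] == side]["information"].sum())
            for side in ("5p", "3p")
        }
    stage_done("logo")

    report["headline"] = headline
    report["call_summaries"] = summaries
    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name != "report.json":
            report["files"][f.name] = _sha256(f)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
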