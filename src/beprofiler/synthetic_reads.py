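"""Synthetic amplicon read generation with known ground truth.

Reads are full-amplicon, single-end, fixed length. Target conversion (C→T on
C members, A→G on A members) is an independent Bernoulli draw per read;
optional cross-conversions hit every opposite-base position inside the
protospacer; sequencing errors are uniform substitutions. An optional indel
rate deletes one random base to exercise the caller's indel-exclusion path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .library_design import BASES, LibraryTable, protospacer_offset

_B2I = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _B2I[ord(_b)] = _i
_I2B = np.frombuffer(BASES.encode(), dtype=np.uint8)

CONVERSION_ALT = {"C": "T", "A": "G"}  # deamination products on the displayed strand


@dataclass(frozen=True)
class ReadSimConfig:
    """Simulation parameters; rates are per-read (target/cross) or per-base (error)."""

    p_target: float = 0.9
    p_target_per_member: dict = field(default_factory=dict)
    p_cross: float = 0.0
    error_rate: float = 0.0
    indel_rate: float = 0.0
    depth: int = 1000
    replicates: int = 1
    quality: int = 30
    seed: int = 0

    def __post_init__(self):
        for name in ("p_target", "p_cross", "error_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        for mid, v in self.p_target_per_member.items():
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"p_target for {mid} must lie in [0, 1], got {v}")
        if self.depth < 0:
            raise ValidationError("depth must be >= 0")
        if self.replicates < 1:
            raise ValidationError("replicate count must be >= 1")

    def rate_for(self, member_id: str) -> float:
        return self.p_target_per_member.get(member_id, self.p_target)


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    quality: str


@dataclass
class SimulationResult:
    reads: list  # list per replicate of list[SimulatedRead]
    ground_truth: pd.DataFrame
    fastq_paths: list = field(default_factory=list)


def _bystander_positions(member) -> list[int]:
    """1-based protospacer positions carrying the opposite target base."""
    other = "A" if member.target_base == "C" else "C"
    return [i + 1 for i, b in enumerate(member.protospacer) if b == other]


def expand_ground_truth(config: ReadSimConfig, library: LibraryTable) -> pd.DataFrame:
    """Explicit per-member, per-position, per-conversion generating rates."""
    rows = []
    for m in library:
        alt = CONVERSION_ALT[m.target_base]
        rows.append(
            {
                "member_id": m.member_id,
                "position": m.target_position,
                "conversion": f"{m.target_base}2{alt}",
                "rate": config.rate_for(m.member_id),
            }
        )
        if config.p_cross > 0:
            other = "A" if m.target_base == "C" else "C"
            for pos in _bystander_positions(m):
                rows.append(
                    {
                        "member_id": m.member_id,
                        "position": pos,
                        "conversion": f"{other}2{CONVERSION_ALT[other]}",
                        "rate": config.p_cross,
                    }
                )
    return pd.DataFrame(rows, columns=["member_id", "position", "conversion", "rate"])


def _simulate_member(member, config: ReadSimConfig, rng: np.random.Generator,
                     proto_off: int) -> np.ndarray:
    """Depth x amplicon-length uint8 matrix of reads for one member."""
    ref = np.frombuffer(member.amplicon.encode(), dtype=np.uint8)
    mat = np.tile(ref, (config.depth, 1))
    if config.depth == 0:
        return mat
    tcol = proto_off + member.target_position - 1
    alt = ord(CONVERSION_ALT[member.target_base])
    edited = rng.random(config.depth) < config.rate_for(member.member_id)
    mat[edited, tcol] = alt
    if config.p_cross > 0:
        other = "A" if member.target_base == "C" else "C"
        calt = ord(CONVERSION_ALT[other])
        for pos in _bystander_positions(member):
            hit = rng.random(config.depth) < config.p_cross
            mat[hit, proto_off + pos - 1] = calt
    if config.error_rate > 0:
        err = rng.random(mat.shape) < config.error_rate
        if err.any():
            idx = _B2I[mat[err]]
            shift = rng.integers(1, 4, size=idx.shape)
            mat[err] = _I2B[(idx + shift) % 4]
    return mat


def simulate_reads(library: LibraryTable, config: ReadSimConfig,
                   outdir=None) -> SimulationResult:
    """Generate reads for every member and replicate; deterministic under seed.

    Read count is exactly ``len(library) * depth * replicates``. Read ids
    encode member/replicate for debugging only; downstream code must assign
    reads via the UMI field.
    """
    if len(library) == 0:
        raise ValidationError("cannot simulate reads from an empty library")
    rng = np.random.default_rng(config.seed)
    proto_off = protospacer_offset()
    truth = expand_ground_truth(config, library)
    qual_cache: dict[int, str] = {}

    replicates: list[list[SimulatedRead]] = []
    for rep in range(1, config.replicates + 1):
        reads: list[SimulatedRead] = []
        for m in library:
            mat = _simulate_member(m, config, rng, proto_off)
            n = mat.shape[0]
            drop = np.zeros(n, dtype=bool)
            if config.indel_rate > 0:
                drop = rng.random(n) < config.indel_rate
                del_pos = rng.integers(0, mat.shape[1], size=n)
            L = mat.shape[1]
            if L not in qual_cache:
                qual_cache[L] = chr(config.quality + 33) * L
            qual = qual_cache[L]
            for i in range(n):
                if drop[i]:
                    row = mat[i]
                    seq = (row[: del_pos[i]].tobytes() + row[del_pos[i] + 1:].tobytes()).decode()
                    q = qual[:-1]
                else:
                    seq = mat[i].tobytes().decode()
                    q = qual
                reads.append(SimulatedRead(f"{m.member_id}|rep{rep}|{i}", seq, q))
        replicates.append(reads)

    result = SimulationResult(reads=replicates, ground_truth=truth)
    if outdir is not None:
        result.fastq_paths = write_fastq(result, outdir)
        truth.to_csv(Path(outdir) / "ground_truth.tsv", sep="\t", index=False)
    return result


def write_fastq(result: SimulationResult, outdir) -> list:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rep, reads in enumerate(result.reads, start=1):
        path = outdir / f"reads_rep{rep}.fastq"
        with open(path, "w") as fh:
            for r in reads:
                fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")
        paths.append(str(path))
    return paths


def read_fastq(path) -> list:
    """Load a FASTQ file into SimulatedRead records (phred+33 qualities kept raw)."""
    from Bio import SeqIO

    return [
        SimulatedRead(
            rec.id,
            str(rec.seq),
            "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]),
        )
        for rec in SeqIO.parse(str(path), "fastq")
    ]
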