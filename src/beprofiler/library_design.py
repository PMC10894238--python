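"""Combinatorial sequence-context substrate library design.

Enumerates every (target base, protospacer position, 5' flank, 3' flank)
combination, assigns minimum-distance UMI barcodes and materializes full
amplicon reference sequences. Protospacer coordinates are 1-based with the
PAM occupying positions 21-23.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import CapacityError, ValidationError

BASES = "ACGT"

#: Default protospacer backbone. Deliberately free of A and C so that, for a
#: C or A target member, the target base occurs in the protospacer only at
#: the target position (flanks aside), keeping bystander calls unambiguous.
DEFAULT_FILLER = "GTGTGTGTGTGTGTGTGTGT"

#: Constant amplicon arms. The last base of the left arm is "position 0" of
#: the protospacer and is overwritten by the 5' flank when the target sits at
#: position 1.
LEFT_ARM = "GCTAGTCGTG"
RIGHT_ARM = "GACGTTCGAA"
UMI_SPACER = "CT"
DEFAULT_PAM = "TGG"  # NGG representative


@dataclass(frozen=True)
class ContextLibrarySpec:
    """Parameters defining one combinatorial context library."""

    target_bases: tuple[str, ...] = ("A", "C")
    positions: tuple[int, ...] = (6,)
    flank_alphabet: str = BASES
    umi_length: int = 10
    min_umi_distance: int = 3
    protospacer_length: int = 20
    pam: str = DEFAULT_PAM
    filler: str = DEFAULT_FILLER

    def __post_init__(self):
        object.__setattr__(self, "target_bases", tuple(sorted(set(self.target_bases))))
        object.__setattr__(self, "positions", tuple(sorted(set(int(p) for p in self.positions))))
        for b in self.target_bases:
            if b not in ("A", "C"):
                raise ValidationError(f"target base must be A or C, got {b!r}")
        for p in self.positions:
            if not 1 <= p <= self.protospacer_length:
                raise ValidationError(
                    f"position {p} outside [1, {self.protospacer_length}]"
                )
        if not self.flank_alphabet:
            raise ValidationError("flank alphabet must be nonempty")
        if len(set(self.flank_alphabet)) != len(self.flank_alphabet):
            raise ValidationError("flank alphabet contains duplicates")
        for b in self.flank_alphabet:
            if b not in BASES:
                raise ValidationError(f"flank alphabet base {b!r} not in ACGT")
        if self.umi_length < 0:
            raise ValidationError("umi_length must be >= 0")
        if len(self.pam) != 3:
            raise ValidationError("PAM must be 3 bases")
        if len(self.filler) < self.protospacer_length:
            raise ValidationError("filler template shorter than protospacer")

    @property
    def size(self) -> int:
        return len(self.target_bases) * len(self.positions) * len(self.flank_alphabet) ** 2


@dataclass(frozen=True)
class LibraryMember:
    """One substrate: target base + position + flanks + UMI + amplicon."""

    member_id: str
    target_base: str
    target_position: int
    flank5: str
    flank3: str
    protospacer: str
    umi: str
    amplicon: str


@dataclass
class LibraryTable:
    """Ordered collection of members plus the spec and seed that produced it."""

    members: list[LibraryMember]
    spec: ContextLibrarySpec
    seed: int = 0
    _by_id: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._by_id = {m.member_id: m for m in self.members}
        if len(self._by_id) != len(self.members):
            raise ValidationError("duplicate member_id in library")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, member_id: str) -> LibraryMember:
        return self._by_id[member_id]

    def to_manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "member_id": m.member_id,
                    "target_base": m.target_base,
                    "target_position": m.target_position,
                    "flank5": m.flank5,
                    "flank3": m.flank3,
                    "umi": m.umi,
                    "protospacer": m.protospacer,
                    "amplicon": m.amplicon,
                }
                for m in self.members
            ]
        )

    @classmethod
    def from_manifest(cls, manifest: pd.DataFrame, spec: ContextLibrarySpec | None = None,
                      seed: int = 0) -> "LibraryTable":
        members = [
            LibraryMember(
                member_id=str(r.member_id),
                target_base=str(r.target_base),
                target_position=int(r.target_position),
                flank5=str(r.flank5),
                flank3=str(r.flank3),
                umi="" if pd.isna(r.umi) else str(r.umi),
                protospacer=str(r.protospacer),
                amplicon=str(r.amplicon),
            )
            for r in manifest.itertuples()
        ]
        if spec is None:
            positions = tuple(sorted({m.target_position for m in members})) or (1,)
            umi_len = len(members[0].umi) if members else 0
            spec = ContextLibrarySpec(
                target_bases=tuple(sorted({m.target_base for m in members})) or ("C",),
                positions=positions,
                umi_length=umi_len,
            )
        return cls(members=members, spec=spec, seed=seed)


def build_protospacer(target_base: str, target_position: int, flank5: str, flank3: str,
                      filler: str = DEFAULT_FILLER, length: int = 20) -> str:
    """Write target and flank bases into the filler backbone (1-based position)."""
    if len(filler) < length:
        raise ValidationError("filler template shorter than protospacer length")
    proto = list(filler[:length])
    proto[target_position - 1] = target_base
    if target_position - 2 >= 0:
        proto[target_position - 2] = flank5
    if target_position <= length - 1:
        proto[target_position] = flank3
    return "".join(proto)


def build_amplicon(member_core, filler_template: str = DEFAULT_FILLER,
                   pam: str = DEFAULT_PAM, umi: str | None = None) -> str:
    """Assemble the full reference amplicon for a member.

    Layout: left arm (10 nt, last base = protospacer position 0) + protospacer
    (20 nt) + PAM + spacer + UMI + right arm. A 5' flank falling at position 0
    (target at position 1) replaces the last base of the left arm.
    """
    proto = member_core.protospacer or build_protospacer(
        member_core.target_base, member_core.target_position,
        member_core.flank5, member_core.flank3, filler_template,
    )
    left = LEFT_ARM
    if member_core.target_position == 1:
        left = LEFT_ARM[:-1] + member_core.flank5
    u = member_core.umi if umi is None else umi
    return left + proto + pam + UMI_SPACER + u + RIGHT_ARM


def protospacer_offset() -> int:
    """Fixed 0-based offset of the protospacer within every amplicon."""
    return len(LEFT_ARM)


def umi_offset(spec: ContextLibrarySpec) -> int:
    """Fixed 0-based offset of the UMI within every amplicon."""
    return len(LEFT_ARM) + spec.protospacer_length + len(spec.pam) + len(UMI_SPACER)


def _random_umis(n: int, length: int, min_distance: int, rng: np.random.Generator,
                 max_tries: int = 200_000) -> list[str]:
    if length == 0:
        if n > 1:
            raise CapacityError("umi_length 0 cannot label more than one member")
        return [""] * n
    if 4 ** length < n:
        raise CapacityError(
            f"umi_length {length} yields only {4 ** length} barcodes for {n} members"
        )
    chosen: list[np.ndarray] = []
    tries = 0
    while len(chosen) < n:
        tries += 1
        if tries > max_tries:
            raise CapacityError(
                f"could not place {n} UMIs of length {length} at pairwise distance "
                f">= {min_distance}"
            )
        cand = rng.integers(0, 4, size=length)
        if all(int(np.sum(cand != c)) >= min_distance for c in chosen):
            chosen.append(cand)
    return ["".join(BASES[i] for i in arr) for arr in chosen]


def assign_umis(table: LibraryTable, umi_length: int | None = None,
                min_pairwise_distance: int | None = None, seed: int = 0) -> LibraryTable:
    """Assign random UMIs (pairwise Hamming distance floor) and rebuild amplicons."""
    spec = table.spec
    length = spec.umi_length if umi_length is None else umi_length
    dist = spec.min_umi_distance if min_pairwise_distance is None else min_pairwise_distance
    rng = np.random.default_rng(seed)
    umis = _random_umis(len(table), length, dist, rng)
    new_members = []
    for m, u in zip(table.members, umis):
        amp = build_amplicon(replace(m, umi=u), filler_template=spec.filler, pam=spec.pam)
        new_members.append(replace(m, umi=u, amplicon=amp))
    new_spec = replace(spec, umi_length=length, min_umi_distance=dist)
    return LibraryTable(members=new_members, spec=new_spec, seed=seed)


def enumerate_context_library(spec: ContextLibrarySpec, seed: int = 0) -> LibraryTable:
    """Materialize the full combinatorial library.

    One member per (target_base, position, flank5, flank3), ordered by target
    base, then position, then flanks in alphabet order; UMIs assigned
    deterministically from the seed.
    """
    members = []
    for base, pos, f5, f3 in itertools.product(
        spec.target_bases, spec.positions, spec.flank_alphabet, spec.flank_alphabet
    ):
        proto = build_protospacer(base, pos, f5, f3, spec.filler, spec.protospacer_length)
        member_id = f"{base}{pos:02d}_{f5}{f3}"
        core = LibraryMember(
            member_id=member_id, target_base=base, target_position=pos,
            flank5=f5, flank3=f3, protospacer=proto, umi="", amplicon="",
        )
        amp = build_amplicon(core, filler_template=spec.filler, pam=spec.pam)
        members.append(replace(core, amplicon=amp))
    table = LibraryTable(members=members, spec=spec, seed=seed)
    if spec.umi_length > 0 and len(table) > 0:
        table = assign_umis(table, seed=seed)
    return table


def write_library(table: LibraryTable, outdir) -> dict:
    """Write the library FASTA (amplicon references) and TSV manifest."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "library.fasta"
    with open(fasta, "w") as fh:
        for m in table.members:
            fh.write(f">{m.member_id}\n{m.amplicon}\n")
    manifest = outdir / "library_manifest.tsv"
    table.to_manifest().to_csv(manifest, sep="\t", index=False)
    return {"fasta": str(fasta), "manifest": str(manifest)}


def read_manifest(path) -> LibraryTable:
    df = pd.read_csv(path, sep="\t", dtype={"umi": str})
    return LibraryTable.from_manifest(df)
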