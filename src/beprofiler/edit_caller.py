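"""Demultiplexing and per-position substitution quantification.

Reads are assigned to library members by the UMI field at a fixed amplicon
offset (nearest UMI within ``max_umi_mismatch``, guaranteed unique by the
library's pairwise-distance floor), then compared gaplessly against the
member's reference amplicon. Reads with a length change or an excessive
mismatch load are excluded as indel/alignment failures; positions below the
quality floor are masked out of both numerator and denominator.

Conversions are reported on the protospacer-containing strand: a "C2T" row
means C→T at that displayed position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, ValidationError
from .library_design import BASES, LibraryTable, protospacer_offset, umi_offset

#: Efficiencies below this are reported but flagged as below the sequencing
#: limit of detection (0.1% of reads).
LOD_PCT = 0.1

#: Same-length reads whose mismatch fraction exceeds this are treated as
#: shifted/unalignable and excluded with the indel class.
MAX_MISMATCH_FRAC = 0.3

DEFAULT_QMIN = 20
DEFAULT_MIN_READS = 100


@dataclass
class ReadClassification:
    calls: list  # (position_1based, ref, alt) within the protospacer
    masked_positions: list  # 1-based protospacer positions below qmin
    indel: bool = False
    lowq: bool = False


@dataclass
class MemberReadGroup:
    member_id: str
    reads: list = field(default_factory=list)  # indices into the input read list
    n_total: int = 0
    n_indel: int = 0
    n_lowq: int = 0
    n_used: int = 0


def _seq_matrix(seqs: list[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)


def _min_pairwise_umi_distance(umis: list[str]) -> int:
    mat = _seq_matrix(umis)
    n = len(umis)
    best = mat.shape[1]
    for i in range(n - 1):
        d = (mat[i + 1:] != mat[i]).sum(axis=1).min()
        best = min(best, int(d))
    return best


def demultiplex(reads, library: LibraryTable, max_umi_mismatch: int = 1):
    """Assign each read to the unique member whose UMI is within tolerance.

    Returns ``(groups, unassigned)`` where groups maps member_id to a
    MemberReadGroup holding read indices. Totals are conserved:
    sum of group totals + unassigned == len(reads).
    """
    umis = [m.umi for m in library.members]
    if len(set(umis)) != len(umis) or (umis and umis[0] == ""):
        raise ConfigurationError("library UMIs must be nonempty and unique")
    if len(umis) > 1 and _min_pairwise_umi_distance(umis) <= 2 * max_umi_mismatch:
        raise ConfigurationError(
            f"min pairwise UMI distance must exceed {2 * max_umi_mismatch} "
            f"for max_umi_mismatch={max_umi_mismatch}"
        )
    ulen = len(umis[0])
    start = umi_offset(library.spec)
    exact = {u: i for i, u in enumerate(umis)}
    umi_mat = _seq_matrix(umis)

    groups = {m.member_id: MemberReadGroup(m.member_id) for m in library.members}
    member_ids = [m.member_id for m in library.members]
    unassigned = 0

    fuzzy_idx: list[int] = []
    fuzzy_umi: list[str] = []
    for i, read in enumerate(reads):
        u = read.sequence[start:start + ulen]
        j = exact.get(u)
        if j is not None:
            g = groups[member_ids[j]]
            g.reads.append(i)
            g.n_total += 1
        elif max_umi_mismatch > 0 and len(u) == ulen:
            fuzzy_idx.append(i)
            fuzzy_umi.append(u)
        else:
            unassigned += 1

    if fuzzy_idx:
        qmat = _seq_matrix(fuzzy_umi)
        # chunked broadcast keeps memory bounded for large read sets
        for lo in range(0, len(fuzzy_idx), 8192):
            chunk = qmat[lo:lo + 8192]
            dist = (chunk[:, None, :] != umi_mat[None, :, :]).sum(axis=2)
            best = dist.argmin(axis=1)
            bestd = dist[np.arange(len(chunk)), best]
            for k in range(len(chunk)):
                if bestd[k] <= max_umi_mismatch:
                    g = groups[member_ids[best[k]]]
                    g.reads.append(fuzzy_idx[lo + k])
                    g.n_total += 1
                else:
                    unassigned += 1
    return groups, unassigned


def classify_read(read, member, qmin: int = DEFAULT_QMIN) -> ReadClassification:
    """Per-read gapless classification against the member amplicon."""
    if not read.sequence:
        raise DataError("empty read")
    amp = member.amplicon
    quals = np.frombuffer(read.quality.encode(), dtype=np.uint8).astype(int) - 33
    if quals.mean() < qmin:
        return ReadClassification([], [], lowq=True)
    if len(read.sequence) != len(amp):
        return ReadClassification([], [], indel=True)
    seq = np.frombuffer(read.sequence.encode(), dtype=np.uint8)
    ref = np.frombuffer(amp.encode(), dtype=np.uint8)
    mism = seq != ref
    if mism.mean() > MAX_MISMATCH_FRAC:
        return ReadClassification([], [], indel=True)
    off = protospacer_offset()
    plen = len(member.protospacer)
    calls, masked = [], []
    for p in range(1, plen + 1):
        col = off + p - 1
        if quals[col] < qmin:
            masked.append(p)
        elif mism[col]:
            calls.append((p, chr(ref[col]), chr(seq[col])))
    return ReadClassification(calls, masked)


def quantify(group: MemberReadGroup, member, reads, qmin: int = DEFAULT_QMIN,
             min_reads: int = DEFAULT_MIN_READS) -> pd.DataFrame:
    """Per-position, per-conversion efficiencies for one member's read group.

    Vectorized over the group's reads. Efficiency = 100 * edited / aligned
    at each position, where the denominator counts non-indel, quality-passing
    reads whose base call at that position clears qmin.
    """
    off = protospacer_offset()
    plen = len(member.protospacer)
    amp = member.amplicon
    ref = np.frombuffer(amp.encode(), dtype=np.uint8)

    keep_seqs, keep_quals = [], []
    n_indel = n_lowq = 0
    for i in group.reads:
        r = reads[i]
        if not r.sequence:
            raise DataError("empty read")
        q = np.frombuffer(r.quality.encode(), dtype=np.uint8).astype(int) - 33
        if q.mean() < qmin:
            n_lowq += 1
            continue
        if len(r.sequence) != len(amp):
            n_indel += 1
            continue
        keep_seqs.append(r.sequence)
        keep_quals.append(q)

    if keep_seqs:
        seq_mat = _seq_matrix(keep_seqs)
        qual_mat = np.stack(keep_quals)
        mism_frac = (seq_mat != ref).mean(axis=1)
        shifted = mism_frac > MAX_MISMATCH_FRAC
        n_indel += int(shifted.sum())
        seq_mat = seq_mat[~shifted]
        qual_mat = qual_mat[~shifted]
    else:
        seq_mat = np.empty((0, len(amp)), dtype=np.uint8)
        qual_mat = np.empty((0, len(amp)), dtype=int)

    n_used = seq_mat.shape[0]
    group.n_indel, group.n_lowq, group.n_used = n_indel, n_lowq, n_used
    group.n_total = len(group.reads)

    low_coverage = n_used < min_reads
    rows = []
    cols = off + np.arange(plen)
    qok = qual_mat[:, cols] >= qmin if n_used else np.empty((0, plen), dtype=bool)
    for p in range(1, plen + 1):
        col = off + p - 1
        refb = chr(ref[col])
        ok = qok[:, p - 1]
        aligned = int(ok.sum())
        for alt in BASES:
            if alt == refb:
                continue
            edited = int(((seq_mat[:, col] == ord(alt)) & ok).sum()) if n_used else 0
            eff = 100.0 * edited / aligned if aligned > 0 else float("nan")
            flags = []
            if low_coverage:
                flags.append("low_coverage")
            if aligned == 0:
                flags.append("no_coverage")
            elif eff < LOD_PCT:
                flags.append("below_lod")
            rows.append(
                {
                    "member_id": member.member_id,
                    "position": p,
                    "ref": refb,
                    "alt": alt,
                    "conversion": f"{refb}2{alt}",
                    "edited": edited,
                    "aligned": aligned,
                    "efficiency_pct": eff,
                    "flags": ",".join(flags),
                }
            )
    df = pd.DataFrame(rows)
    df["indel_fraction"] = n_indel / group.n_total if group.n_total else float("nan")
    return df


def call_edits(reads, library: LibraryTable, qmin: int = DEFAULT_QMIN,
               min_reads: int = DEFAULT_MIN_READS, max_umi_mismatch: int = 1):
    """Full single-replicate pipeline: demultiplex then quantify every member.

    Returns ``(edits_df, summary)`` where summary carries the read accounting.
    """
    groups, unassigned = demultiplex(reads, library, max_umi_mismatch)
    frames = []
    accounting = {}
    for m in library.members:
        g = groups[m.member_id]
        df = quantify(g, m, reads, qmin=qmin, min_reads=min_reads)
        frames.append(df)
        accounting[m.member_id] = {
            "total": g.n_total, "indel": g.n_indel, "lowq": g.n_lowq, "used": g.n_used,
        }
    edits = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    assigned = sum(a["total"] for a in accounting.values())
    if assigned + unassigned != len(reads):
        raise DataError("read accounting does not conserve totals")
    summary = {
        "n_reads": len(reads),
        "assigned": assigned,
        "unassigned": unassigned,
        "qmin": qmin,
        "min_reads": min_reads,
        "max_umi_mismatch": max_umi_mismatch,
        "per_member": accounting,
    }
    return edits, summary


def aggregate_replicates(edit_frames: list, min_valid: int = 1) -> pd.DataFrame:
    """Unweighted mean of per-replicate efficiencies per (member, position, conversion).

    Low-coverage member-replicates are excluded before averaging; members with
    no valid replicate are dropped entirely (flagged via absence).
    """
    if not edit_frames:
        raise ValidationError("no replicate frames supplied")
    frames = []
    for rep, df in enumerate(edit_frames, start=1):
        d = df.copy()
        d["replicate"] = rep
        d["valid"] = ~d["flags"].fillna("").str.contains("low_coverage")
        frames.append(d)
    allreps = pd.concat(frames, ignore_index=True)
    valid = allreps[allreps["valid"]]
    if valid.empty:
        raise DataError("zero valid replicates for every member")
    keys = ["member_id", "position", "ref", "alt", "conversion"]
    agg = (
        valid.groupby(keys, sort=False)
        .agg(
            efficiency_pct=("efficiency_pct", "mean"),
            edited=("edited", "sum"),
            aligned=("aligned", "sum"),
            n_replicates=("replicate", "nunique"),
            indel_fraction=("indel_fraction", "mean"),
        )
        .reset_index()
    )
    total_reps = len(edit_frames)
    dropped = agg["n_replicates"] < total_reps
    lod = agg["efficiency_pct"] < LOD_PCT
    agg["flags"] = np.select(
        [dropped & lod, dropped, lod],
        ["replicates_dropped,below_lod", "replicates_dropped", "below_lod"],
        default="",
    )
    return agg
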