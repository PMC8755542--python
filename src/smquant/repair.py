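"""Cas9 amplicon repair-outcome classification.

Reads from an amplicon spanning a Cas9 break site are aligned globally to the
reference and classified by the edits they carry: NHEJ is a single 1-5 bp
deletion, MMEJ a single >5 bp deletion with at least 2 bp of junction
microhomology, SSTR exactly the three 1 bp donor-templated substitutions, and
anything else (insertions, compound edits, >5 bp deletions without
microhomology) is routed to "other".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import Align
from Bio.Seq import Seq

__all__ = [
    "RepairEvent",
    "AlignedRead",
    "make_aligner",
    "align_read",
    "microhomology_length",
    "left_align_deletion",
    "classify_event",
    "classify_reads",
    "summarize_classes",
]

_DNA = set("ACGTN")

CLASSES = ("intact", "NHEJ", "MMEJ", "SSTR", "other")


@dataclass(frozen=True)
class RepairEvent:
    """Classified repair outcome of one read."""

    label: str
    deletion: tuple[int, int] | None = None  # 0-based half-open on the reference
    deletion_length: int = 0
    microhomology: int = 0
    substitutions: tuple[tuple[int, str], ...] = ()
    insertion_length: int = 0


@dataclass
class AlignedRead:
    """Edits of a read relative to the reference, from a global alignment."""

    deletions: list[tuple[int, int]] = field(default_factory=list)
    insertions: list[tuple[int, int]] = field(default_factory=list)  # (ref pos, length)
    substitutions: list[tuple[int, str]] = field(default_factory=list)
    reverse_complement: bool = False
    score: float = 0.0


def make_aligner(
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> Align.PairwiseAligner:
    """Global DNA aligner with affine gaps (match +2 / mismatch -3 / open -5 /
    extend -2).  End gaps are penalised so deletions stay internal."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _validate(seq: str, name: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{name} must be non-empty")
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"{name} contains non-DNA characters: {sorted(bad)}")
    return seq


def align_read(
    reference: str, read: str, aligner: Align.PairwiseAligner | None = None
) -> AlignedRead:
    """Globally align a read to the reference and extract its edits.

    Both orientations are scored and the better one kept, so
    reverse-complemented reads are handled transparently.  Gaps in the read
    are deletions (reported as 0-based half-open reference intervals,
    left-aligned); gaps in the reference are insertions.
    """
    reference = _validate(reference, "reference")
    read = _validate(read, "read")
    aligner = aligner or make_aligner()

    fwd = aligner.align(reference, read)[0]
    rc_seq = str(Seq(read).reverse_complement())
    rev = aligner.align(reference, rc_seq)[0]
    if rev.score > fwd.score:
        aln, is_rc = rev, True
    else:
        aln, is_rc = fwd, False

    out = AlignedRead(reverse_complement=is_rc, score=float(aln.score))
    ref_blocks, read_blocks = aln.aligned  # aligned block coordinates
    qseq = rc_seq if is_rc else read

    # substitutions inside aligned blocks
    for (rs, re), (qs, _qe) in zip(ref_blocks, read_blocks):
        for off in range(re - rs):
            a, b = reference[rs + off], qseq[qs + off]
            if a != b and b != "N":
                out.substitutions.append((rs + off, b))

    # gaps between consecutive blocks
    for i in range(len(ref_blocks) - 1):
        ref_gap = ref_blocks[i + 1][0] - ref_blocks[i][1]
        read_gap = read_blocks[i + 1][0] - read_blocks[i][1]
        if ref_gap > 0:  # deletion from the read
            s, e = int(ref_blocks[i][1]), int(ref_blocks[i + 1][0])
            out.deletions.append(left_align_deletion(reference, (s, e)))
        if read_gap > 0:  # insertion into the read
            out.insertions.append((int(ref_blocks[i][1]), int(read_gap)))
    # leading/trailing unaligned reference (end gaps) count as deletions too
    if ref_blocks.size:
        if ref_blocks[0][0] > 0:
            out.deletions.insert(
                0, left_align_deletion(reference, (0, int(ref_blocks[0][0])))
            )
        if ref_blocks[-1][1] < len(reference):
            out.deletions.append(
                left_align_deletion(reference, (int(ref_blocks[-1][1]), len(reference)))
            )
    return out


def left_align_deletion(reference: str, interval: tuple[int, int]) -> tuple[int, int]:
    """Shift a deletion to its leftmost equivalent placement.

    Deleting [s, e) and [s-1, e-1) give the same sequence whenever
    ref[s-1] == ref[e-1]; repeated shifting yields the canonical placement
    used for microhomology calling.
    """
    s, e = interval
    while s > 0 and reference[s - 1] == reference[e - 1]:
        s -= 1
        e -= 1
    return (s, e)


def microhomology_length(reference: str, deletion: tuple[int, int]) -> int:
    """Junction microhomology of a deletion: the longest m such that the
    first m deleted bases equal the first m bases following the deletion.

    The deletion is left-aligned first so equivalent placements of the same
    deletion give the same answer; m is capped at the deletion length.
    """
    reference = _validate(reference, "reference")
    s, e = deletion
    if not 0 <= s < e <= len(reference):
        raise ValueError(f"deletion interval {deletion} outside reference")
    s, e = left_align_deletion(reference, (s, e))
    length = e - s
    m = 0
    n = len(reference)
    while m < length and e + m < n and reference[s + m] == reference[e + m]:
        m += 1
    return m


def classify_event(
    reference: str,
    aligned: AlignedRead,
    donor_subs: list[tuple[int, str]] | None = None,
) -> RepairEvent:
    """Apply the outcome rules to the edits of one aligned read.

    intact: no edits.  NHEJ: a single deletion of 1-5 bp.  MMEJ: a single
    deletion of >5 bp with microhomology >= 2 bp.  SSTR: exactly the three
    donor substitutions and no indel.  Everything else -- insertions,
    multiple indels, deletion+substitution compounds, long deletions without
    microhomology -- is "other".
    """
    n_del = len(aligned.deletions)
    n_ins = len(aligned.insertions)
    subs = tuple(aligned.substitutions)
    ins_len = sum(l for _, l in aligned.insertions)

    if n_del == 0 and n_ins == 0 and not subs:
        return RepairEvent(label="intact")

    if n_del == 1 and n_ins == 0 and not subs:
        s, e = aligned.deletions[0]
        dlen = e - s
        mh = microhomology_length(reference, (s, e))
        if 1 <= dlen <= 5:
            label = "NHEJ"
        elif dlen > 5 and mh >= 2:
            label = "MMEJ"
        else:
            label = "other"
        return RepairEvent(
            label=label,
            deletion=(s, e),
            deletion_length=dlen,
            microhomology=mh,
            substitutions=subs,
        )

    if donor_subs and n_del == 0 and n_ins == 0:
        expected = {(p, b.upper()) for p, b in donor_subs}
        if len(expected) == 3 and set(subs) == expected:
            return RepairEvent(label="SSTR", substitutions=subs)

    return RepairEvent(
        label="other",
        deletion=aligned.deletions[0] if n_del else None,
        deletion_length=sum(e - s for s, e in aligned.deletions),
        microhomology=0,
        substitutions=subs,
        insertion_length=ins_len,
    )


def classify_reads(
    reference: str,
    reads: list[tuple[str, str]],
    donor_subs: list[tuple[int, str]] | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> pd.DataFrame:
    """Classify a read set; returns one row per read.

    Columns: read_id, class, del_len, mh_len, n_subs, ins_len, revcomp.
    """
    reference = _validate(reference, "reference")
    aligner = aligner or make_aligner()
    rows = []
    for read_id, seq in reads:
        aligned = align_read(reference, seq, aligner)
        ev = classify_event(reference, aligned, donor_subs)
        rows.append(
            {
                "read_id": read_id,
                "class": ev.label,
                "del_len": ev.deletion_length,
                "mh_len": ev.microhomology,
                "n_subs": len(ev.substitutions),
                "ins_len": ev.insertion_length,
                "revcomp": aligned.reverse_complement,
            }
        )
    return pd.DataFrame(rows)


def summarize_classes(calls: pd.DataFrame) -> dict[str, float]:
    """Class fractions over all reads (keys ordered as CLASSES)."""
    n = len(calls)
    frac = calls["class"].value_counts(normalize=True) if n else pd.Series(dtype=float)
    return {c: float(frac.get(c, 0.0)) for c in CLASSES}
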