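"""Hairpin-bisulfite read processing.

Turns raw hairpin-bisulfite reads into per-read calls: quality trimming and
filtering, duplicate removal, strand-pair reconstitution of the original
randomized substrate sequence, methylation call of the central site, and CpN
classification with CCWGG (dcm-motif) exclusion.

A hairpin read is one continuous sequence: the bisulfite-converted upper
strand 5'->3', the converted hairpin linker, then the converted lower strand
read 5'->3' from the ligation point.  The aligned partner of upper position
``i`` (0-based, upper strand of length ``n``) is lower-read position
``n - 1 - i``.  Because both strands of the same molecule are present, the
original sequence can be reconstituted despite C->T conversion:

====== ====== ======================= =============
upper  lower  original                central call
====== ====== ======================= =============
A      T      A
G      C|T    G
C      G      C                       methylated
T      G      C                       unmethylated
T      A      T
other  other  inconsistent pair
====== ====== ======================= =============
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import c_to_t, revcomp

__all__ = [
    "ReadRecord",
    "HairpinCall",
    "read_fastq",
    "write_fastq",
    "qc_filter",
    "deduplicate",
    "reconstitute",
    "classify_site",
    "process_reads",
    "calls_to_frame",
]


@dataclass
class ReadRecord:
    """One sequencing read: identifier, sequence and per-base Phred scores."""

    id: str
    sequence: str
    qualities: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )


@dataclass
class HairpinCall:
    """Reconstituted substrate sequence and central-site methylation call.

    ``original_sequence`` covers the randomized region (positions -n_left..
    +n_right+1 around the central cytosine, which sits at index ``center``).
    """

    read_id: str
    original_sequence: str
    center: int
    central_meth: bool
    consistent: bool
    site_class: str | None = None
    ccwgg_flag: bool = False


def read_fastq(path) -> list[ReadRecord]:
    """Load a FASTQ file into ReadRecords (Phred qualities retained)."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            ReadRecord(rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"])
        )
    return out


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    recs = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def qc_filter(
    reads: Iterable[ReadRecord],
    target_length: int = 128,
    min_quality: int = 20,
    quality_mode: str = "min",
) -> tuple[list[ReadRecord], dict]:
    """Trim reads to ``target_length`` and drop low-quality ones.

    Reads shorter than ``target_length`` are dropped.  The quality criterion
    is applied to the trimmed read: in ``min`` mode every base must reach
    ``min_quality``; in ``mean`` mode the average must.  Order is preserved.
    """
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    if quality_mode not in ("min", "mean"):
        raise ValueError(f"unknown quality_mode {quality_mode!r}")
    kept: list[ReadRecord] = []
    n_short = n_lowq = 0
    for r in reads:
        if len(r.sequence) < target_length:
            n_short += 1
            continue
        seq = r.sequence[:target_length]
        qual = list(r.qualities[:target_length])
        q = np.asarray(qual, dtype=float)
        ok = (q.min() if quality_mode == "min" else q.mean()) >= min_quality
        if not ok:
            n_lowq += 1
            continue
        kept.append(ReadRecord(r.id, seq, qual))
    log = {"n_input": n_short + n_lowq + len(kept), "dropped_length": n_short,
           "dropped_quality": n_lowq, "n_kept": len(kept)}
    return kept, log


def deduplicate(reads: Sequence[ReadRecord]) -> list[ReadRecord]:
    """Keep one representative per distinct sequence string.

    Reads are sorted alphabetically by sequence (read id breaking ties) and
    the first of each run of identical sequences is kept, so the result is
    deterministic.  Reads differing only in their methylation pattern encode
    different strings and are therefore not duplicates.
    """
    out: list[ReadRecord] = []
    last = None
    for r in sorted(reads, key=lambda r: (r.sequence, r.id)):
        if r.sequence != last:
            out.append(r)
            last = r.sequence
    return out


def _find_linker(sequence: str, linker_conv: str) -> int:
    return sequence.find(linker_conv)


def reconstitute(read: ReadRecord, layout) -> tuple[HairpinCall | None, str | None]:
    """Rebuild the original randomized region from one hairpin read.

    ``layout`` provides ``five_prime_arm``, ``n_left``, ``central_site``,
    ``n_right`` and ``hairpin_linker`` (see SubstrateLayout).  Returns
    ``(call, None)`` on success, else ``(None, reason)``.  Both read
    orientations are tried since the sequenced strand is not guaranteed.
    """
    linker_conv = c_to_t(layout.hairpin_linker)
    seq = read.sequence
    pos = _find_linker(seq, linker_conv)
    if pos < 0:
        seq = revcomp(seq)
        pos = _find_linker(seq, linker_conv)
        if pos < 0:
            return None, "linker_not_found"
    upper = seq[:pos]
    lower = seq[pos + len(linker_conv):]
    n = len(upper)
    rs = len(layout.five_prime_arm)
    region_len = layout.n_left + len(layout.central_site) + layout.n_right
    if n < rs + region_len:
        return None, "upper_truncated"

    orig = []
    consistent = True
    central_meth = False
    ci = rs + layout.n_left  # upper index of the central cytosine
    for i in range(rs, rs + region_len):
        j = n - 1 - i  # aligned lower-read position
        if j >= len(lower) or j < 0:
            return None, "lower_truncated"
        u, v = upper[i], lower[j]
        if u == "A":
            b = "A"
            if v != "T":
                consistent = False
        elif u == "G":
            b = "G"
            if v not in "CT":
                consistent = False
        elif u == "C":
            b = "C"
            if i == ci:
                central_meth = True
            if v != "G":
                consistent = False
        elif u == "T":
            if v == "G":
                b = "C"
            elif v == "A":
                b = "T"
            else:
                b = "N"
                consistent = False
        else:
            b = "N"
            consistent = False
        orig.append(b)

    call = HairpinCall(
        read_id=read.id,
        original_sequence="".join(orig),
        center=layout.n_left,
        central_meth=central_meth,
        consistent=consistent,
    )
    if call.original_sequence[call.center] != "C":
        call.consistent = False
    return call, None


def classify_site(call: HairpinCall) -> HairpinCall:
    """Set ``site_class`` (CpG/CpA/CpT/CpC) and the CCWGG flag.

    The class follows from the base at +1.  ``ccwgg_flag`` is true iff the
    bases at (-1, +1, +2, +3) are (C, A|T, G, G), i.e. the central C sits in
    the E. coli dcm motif CCWGG; such CpA/CpT calls are excluded downstream
    because dcm methylation from the expression host overlaps them.
    """
    s, c = call.original_sequence, call.center
    if c + 3 >= len(s) or c < 1:
        call.consistent = False
        return call
    plus1 = s[c + 1]
    if plus1 not in "ACGT":
        call.consistent = False
        return call
    call.site_class = "Cp" + plus1
    call.ccwgg_flag = (
        s[c - 1] == "C" and plus1 in "AT" and s[c + 2] == "G" and s[c + 3] == "G"
    )
    return call


def calls_to_frame(calls: Iterable[HairpinCall]) -> pd.DataFrame:
    rows = [
        (c.read_id, c.original_sequence, c.center, c.central_meth,
         c.site_class, c.ccwgg_flag, c.consistent)
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=["read_id", "original_sequence", "center", "central_meth",
                 "site_class", "ccwgg_flag", "consistent"],
    )


def process_reads(
    reads: Sequence[ReadRecord],
    layout,
    target_length: int = 128,
    min_quality: int = 20,
    quality_mode: str = "min",
    dedup: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Full read pipeline: QC -> dedup -> reconstitute -> classify.

    Returns the call table for consistent reads plus a run log whose drop
    counters obey input = kept + dropped_length + dropped_quality +
    duplicates_removed + dropped_alignment + dropped_inconsistent.
    """
    n_input = len(reads)
    kept, qlog = qc_filter(reads, target_length, min_quality, quality_mode)
    n_dupes = 0
    if dedup:
        before = len(kept)
        kept = deduplicate(kept)
        n_dupes = before - len(kept)
    calls = []
    n_align = n_inconsistent = 0
    reasons: dict[str, int] = {}
    for r in kept:
        call, reason = reconstitute(r, layout)
        if call is None:
            n_align += 1
            reasons[reason] = reasons.get(reason, 0) + 1
            continue
        classify_site(call)
        if not call.consistent:
            n_inconsistent += 1
            continue
        calls.append(call)
    log = {
        "n_input": n_input,
        "dropped_length": qlog["dropped_length"],
        "dropped_quality": qlog["dropped_quality"],
        "duplicates_removed": n_dupes,
        "dropped_alignment": n_align,
        "alignment_reasons": reasons,
        "dropped_inconsistent": n_inconsistent,
        "n_calls": len(calls),
    }
    assert (log["n_input"] == log["n_calls"] + log["dropped_length"]
            + log["dropped_quality"] + log["duplicates_removed"]
            + log["dropped_alignment"] + log["dropped_inconsistent"])
    return calls_to_frame(calls), log
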