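"""CpG and CCCG/CGGG motif enrichment in repeat/consensus sequences.

Young retrotransposons targeted by a C(-2)/C(-1)-preferring enzyme are
expected to be enriched in CpG sites whose double-stranded context is CCCG
(equivalently CGGG on the other strand).  This module counts overlapping
CG, CCCG and CGGG occurrences, expresses them as observed/expected ratios
against the mononucleotide composition of the scanned sequence itself
(expected(CCCG) = n_pos * f_C^3 * f_G, etc.), profiles them in 50-bp tiles,
and compares element groups with a two-sided Welch t-test.

The *fraction* o/e mode asks what share of CpG sites sit in a CCCG or CGGG
context, normalized by its compositional expectation f_C^2 + f_G^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CompositionModel",
    "MotifScan",
    "motif_counts",
    "composition",
    "oe_element",
    "windowed_oe",
    "scan_element",
    "welch_ttest",
    "group_report",
]

MOTIF_CLASSES = ("CG", "CCCG+CGGG", "fraction")
_SINGLE_MOTIFS = ("CCCG", "CGGG")


@dataclass
class CompositionModel:
    """Mononucleotide frequencies of the scanned sequence (N ignored)."""

    f_A: float
    f_C: float
    f_G: float
    f_T: float

    def expected_per_position(self, motif: str) -> float:
        f = {"A": self.f_A, "C": self.f_C, "G": self.f_G, "T": self.f_T}
        out = 1.0
        for b in motif:
            out *= f[b]
        return out


@dataclass
class MotifScan:
    """Whole-element and windowed motif o/e of one repeat sequence."""

    element_id: str
    region: tuple[int, int]
    n_CG: int
    n_CCCG: int
    n_CGGG: int
    oe_CG: float
    oe_CCCG_CGGG: float
    oe_fraction: float
    composition: CompositionModel
    window_profile: pd.DataFrame = field(default_factory=pd.DataFrame)


def _resolve_region(sequence: str, region) -> tuple[int, int]:
    if region is None:
        return 0, len(sequence)
    start, end = region
    if not 0 <= start < end <= len(sequence):
        raise ValueError(f"region {region} outside sequence of length {len(sequence)}")
    return start, end


def motif_counts(sequence: str, region=None) -> dict:
    """Overlapping exact-match counts of CG, CCCG and CGGG in the region.

    A CCCGGG hexamer contributes one CCCG and one CGGG.  Windows containing
    an ambiguous base are skipped and counted per motif length.
    """
    start, end = _resolve_region(sequence.upper(), region)
    seq = sequence.upper()[start:end]
    out = {"n_CG": 0, "n_CCCG": 0, "n_CGGG": 0, "skipped_ambiguous": {2: 0, 4: 0}}
    clean = [b in "ACGT" for b in seq]
    for L in (2, 4):
        motifs = {"CG": "n_CG"} if L == 2 else {"CCCG": "n_CCCG", "CGGG": "n_CGGG"}
        for i in range(len(seq) - L + 1):
            if not all(clean[i: i + L]):
                out["skipped_ambiguous"][L] += 1
                continue
            key = motifs.get(seq[i: i + L])
            if key:
                out[key] += 1
    return out


def composition(sequence: str, region=None) -> CompositionModel:
    start, end = _resolve_region(sequence.upper(), region)
    seq = sequence.upper()[start:end]
    counts = {b: seq.count(b) for b in "ACGT"}
    n = sum(counts.values())
    if n == 0:
        raise ValueError("no unambiguous bases in region")
    return CompositionModel(*(counts[b] / n for b in "ACGT"))


def _n_positions(seq_len: int, motif_len: int, n_skipped: int) -> int:
    return max(seq_len - motif_len + 1 - n_skipped, 0)


def oe_element(sequence: str, region=None, motif_class: str = "CCCG+CGGG",
               comp: CompositionModel | None = None) -> float:
    """Whole-region o/e of a motif class against mononucleotide composition.

    expected(CG) = n_pos*f_C*f_G; expected(CCCG) = n_pos*f_C^3*f_G;
    expected(CGGG) = n_pos*f_C*f_G^3 (n_pos = motif start positions in the
    region); fraction mode: [(n_CCCG+n_CGGG)/n_CG] / (f_C^2 + f_G^2).
    The single-motif classes "CCCG" and "CGGG" are also accepted.
    """
    if motif_class not in MOTIF_CLASSES + _SINGLE_MOTIFS:
        raise ValueError(
            f"motif_class must be one of {MOTIF_CLASSES + _SINGLE_MOTIFS}")
    start, end = _resolve_region(sequence.upper(), region)
    cnt = motif_counts(sequence, (start, end))
    if comp is None:
        comp = composition(sequence, (start, end))
    fC, fG = comp.f_C, comp.f_G
    L = end - start
    if motif_class == "CG":
        exp = _n_positions(L, 2, cnt["skipped_ambiguous"][2]) * fC * fG
        if exp <= 0:
            raise ValueError("expected CG count is zero")
        return cnt["n_CG"] / exp
    if motif_class in _SINGLE_MOTIFS:
        npos = _n_positions(L, 4, cnt["skipped_ambiguous"][4])
        exp = npos * comp.expected_per_position(motif_class)
        if exp <= 0:
            raise ValueError(f"expected {motif_class} count is zero")
        return cnt[f"n_{motif_class}"] / exp
    if motif_class == "CCCG+CGGG":
        npos = _n_positions(L, 4, cnt["skipped_ambiguous"][4])
        exp = npos * (fC ** 3 * fG + fC * fG ** 3)
        if exp <= 0:
            raise ValueError("expected CCCG/CGGG count is zero")
        return (cnt["n_CCCG"] + cnt["n_CGGG"]) / exp
    # fraction of CpG sites in CCCG or CGGG context
    if cnt["n_CG"] == 0:
        return float("nan")
    denom = fC ** 2 + fG ** 2
    if denom <= 0:
        raise ValueError("expected fraction is zero")
    return ((cnt["n_CCCG"] + cnt["n_CGGG"]) / cnt["n_CG"]) / denom


def windowed_oe(sequence: str, motif_class: str = "CCCG+CGGG", window: int = 50,
                min_tail: int = 25, region=None) -> pd.DataFrame:
    """Per-tile motif o/e over non-overlapping ``window``-bp tiles.

    The expectation uses the whole-element composition; the final partial
    tile is kept when it is at least ``min_tail`` bp.  Returns a frame with
    columns start, end, oe.
    """
    start, end = _resolve_region(sequence.upper(), region)
    if end - start < window:
        raise ValueError("sequence shorter than one window")
    comp = composition(sequence, (start, end))
    rows = []
    s = start
    while s < end:
        e = min(s + window, end)
        if e - s < min_tail:
            break
        try:
            oe = oe_element(sequence, (s, e), motif_class, comp=comp)
        except ValueError:  # expectation zero in a degenerate tile
            oe = float("nan")
        rows.append((s, e, oe))
        s += window
    return pd.DataFrame(rows, columns=["start", "end", "oe"])


def scan_element(sequence: str, element_id: str = "", region=None,
                 window: int = 50) -> MotifScan:
    """All whole-element o/e values and the windowed profiles of one element."""
    start, end = _resolve_region(sequence.upper(), region)
    cnt = motif_counts(sequence, (start, end))
    comp = composition(sequence, (start, end))
    prof = []
    for cls in MOTIF_CLASSES:
        p = windowed_oe(sequence, cls, window, region=(start, end))
        p["motif_class"] = cls
        prof.append(p)
    return MotifScan(
        element_id=element_id, region=(start, end),
        n_CG=cnt["n_CG"], n_CCCG=cnt["n_CCCG"], n_CGGG=cnt["n_CGGG"],
        oe_CG=oe_element(sequence, (start, end), "CG", comp),
        oe_CCCG_CGGG=oe_element(sequence, (start, end), "CCCG+CGGG", comp),
        oe_fraction=oe_element(sequence, (start, end), "fraction", comp),
        composition=comp,
        window_profile=pd.concat(prof, ignore_index=True),
    )


def welch_ttest(group_a: Sequence[float], group_b: Sequence[float]
                ) -> tuple[float, float, float]:
    """Two-sided Welch t-test: (t, Welch-Satterthwaite df, p).

    With zero variance in both groups and equal means, returns t=0, p=1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, float(len(a) + len(b) - 2), 1.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def group_report(
    values: pd.DataFrame,
    target_groups: Sequence[str],
    control_groups: Sequence[str],
) -> dict:
    """Summarize element-level o/e by group and compare target vs control.

    ``values`` has columns element_id, group, value (typically the
    fraction-mode o/e of each element).  Groups with < 2 elements are
    reported but the pooled Welch comparison uses all target vs all control
    elements.
    """
    req = {"element_id", "group", "value"}
    if not req.issubset(values.columns):
        raise ValueError(f"values needs columns {sorted(req)}")
    groups = values.groupby("group")["value"]
    summary = groups.agg(n="count", mean="mean", sd="std").reset_index()
    tgt = values[values.group.isin(target_groups)].value.to_numpy()
    ctl = values[values.group.isin(control_groups)].value.to_numpy()
    report = {"summary": summary,
              "small_groups": summary[summary.n < 2].group.tolist()}
    if len(tgt) >= 2 and len(ctl) >= 2:
        t, df, p = welch_ttest(tgt, ctl)
        report["welch"] = {"t": t, "df": df, "p": p,
                           "n_target": int(len(tgt)), "n_control": int(len(ctl))}
    else:
        report["welch"] = None
        report["comparison_skipped"] = "fewer than 2 elements in a pool"
    return report
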