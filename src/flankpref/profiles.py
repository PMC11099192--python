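"""Flanking-sequence preference profiles from hairpin calls.

The product pool of a methylation reaction is compared with the total
analyzed pool: for every flank position the frequency of each base among
methylated reads is divided by its frequency among all reads, giving the
observed/expected (o/e) enrichment.  The analysis window is restricted to
-8..+8 around the central site, excluding the two central dinucleotide
positions (0 and +1), which are fixed by the site class.

By construction the o/e table satisfies, at every position p,
``sum_b f_total(b, p) * oe(b, p) = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import BASES

__all__ = [
    "DEFAULT_WINDOW",
    "FlankProfile",
    "ContextLevels",
    "base_frequencies",
    "oe_profile",
    "profile_from_calls",
    "merge_profiles",
    "correlate_profiles",
    "context_levels",
    "extreme_site_composition",
]

#: flank positions -8..+8 without the central dinucleotide (0 and +1)
DEFAULT_WINDOW: tuple[int, ...] = tuple(range(-8, 0)) + tuple(range(2, 9))


@dataclass
class FlankProfile:
    """Per-position, per-base o/e enrichment of the methylated-read pool."""

    oe: pd.DataFrame            # index: position, columns: A C G T
    f_meth: pd.DataFrame
    f_total: pd.DataFrame
    c_meth: pd.DataFrame        # raw counts behind the frequencies
    c_total: pd.DataFrame
    n_methylated: int
    n_total: int
    site_class: str
    pairwise_r: list[float] = field(default_factory=list)

    @property
    def positions(self) -> list[int]:
        return list(self.oe.index)

    def to_vector(self) -> pd.Series:
        """Flatten to a (position, base) -> o/e Series for correlations."""
        long = self.oe.stack()
        long.index = [f"{p}:{b}" for p, b in long.index]
        return long

    def to_long_frame(self) -> pd.DataFrame:
        rows = self.oe.stack().rename("oe").reset_index()
        rows.columns = ["position", "base", "oe"]
        return rows


@dataclass
class ContextLevels:
    """Per-6-mer methylation levels of one reaction.

    ``table`` is indexed by context with columns n_meth, n_total, level;
    contexts never observed are absent, not zero.
    """

    table: pd.DataFrame
    site_class: str = "CpG"
    metadata: dict = field(default_factory=dict)

    def levels(self) -> pd.Series:
        return self.table["level"]


def _char_matrix(seqs: Sequence[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), -1)


def _freq_counts(calls: pd.DataFrame, window: Sequence[int]) -> tuple[pd.DataFrame, np.ndarray]:
    seqs = calls["original_sequence"].tolist()
    center = int(calls["center"].iloc[0])
    mat = _char_matrix(seqs)
    cols = [center + p for p in window]
    if min(cols) < 0 or max(cols) >= mat.shape[1]:
        raise ValueError("window exceeds the reconstituted sequence")
    sub = mat[:, cols]
    counts = np.stack([(sub == b.encode()).sum(axis=0) for b in BASES], axis=1)
    return pd.DataFrame(counts, index=list(window), columns=list(BASES)), mat


def base_frequencies(
    calls: pd.DataFrame, window: Sequence[int] = DEFAULT_WINDOW
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-position base frequencies of the methylated and total pools.

    Returns ``(f_meth, f_total, c_meth, c_total)``; frequencies at each
    position sum to 1 in both tables.  Raises if no read is methylated.
    """
    if len(calls) == 0:
        raise ValueError("no calls")
    meth = calls[calls["central_meth"]]
    if len(meth) == 0:
        raise ValueError("no product pool: zero methylated calls")
    c_total, _ = _freq_counts(calls, window)
    c_meth, _ = _freq_counts(meth, window)
    f_total = c_total.div(c_total.sum(axis=1), axis=0)
    f_meth = c_meth.div(c_meth.sum(axis=1), axis=0)
    return f_meth, f_total, c_meth, c_total


def oe_profile(
    f_meth: pd.DataFrame,
    f_total: pd.DataFrame,
    c_meth: pd.DataFrame | None = None,
    c_total: pd.DataFrame | None = None,
    site_class: str = "CpG",
) -> FlankProfile:
    """o/e enrichment: f_meth / f_total, with the normalization invariant."""
    if not f_meth.index.equals(f_total.index):
        raise ValueError("windows of the two frequency tables differ")
    bad = (f_total.values == 0) & (f_meth.values > 0)
    if bad.any():
        raise ValueError("observed base absent from the total pool")
    with np.errstate(invalid="ignore"):
        oe = f_meth / f_total
    oe = oe.where(~((f_total == 0) & (f_meth == 0)), np.nan)
    n_m = int(c_meth.iloc[0].sum()) if c_meth is not None else 0
    n_t = int(c_total.iloc[0].sum()) if c_total is not None else 0
    if c_meth is None:
        c_meth = f_meth * np.nan
    if c_total is None:
        c_total = f_total * np.nan
    return FlankProfile(oe, f_meth, f_total, c_meth, c_total, n_m, n_t, site_class)


def profile_from_calls(
    calls: pd.DataFrame,
    window: Sequence[int] = DEFAULT_WINDOW,
    site_class: str = "CpG",
) -> FlankProfile:
    """Convenience: frequencies plus o/e in one step for one site class."""
    sel = calls[calls["site_class"] == site_class]
    if site_class in ("CpA", "CpT"):
        sel = sel[~sel["ccwgg_flag"]]
    return oe_profile(*base_frequencies(sel, window), site_class=site_class)


def merge_profiles(profiles: Sequence[FlankProfile]) -> FlankProfile:
    """Pool replicate profiles by summing raw counts and recomputing o/e.

    Pairwise Pearson correlations of the input o/e vectors are attached to
    the result (``pairwise_r``) as a replicate-consistency diagnostic.
    """
    if not profiles:
        raise ValueError("no profiles to merge")
    cls = {p.site_class for p in profiles}
    if len(cls) > 1:
        raise ValueError(f"mixed site classes: {sorted(cls)}")
    idx = profiles[0].oe.index
    for p in profiles[1:]:
        if not p.oe.index.equals(idx):
            raise ValueError("profiles cover different windows")
    c_meth = sum(p.c_meth for p in profiles)
    c_total = sum(p.c_total for p in profiles)
    f_meth = c_meth.div(c_meth.sum(axis=1), axis=0)
    f_total = c_total.div(c_total.sum(axis=1), axis=0)
    out = oe_profile(f_meth, f_total, c_meth, c_total, site_class=profiles[0].site_class)
    out.pairwise_r = [
        correlate_profiles(profiles[i], profiles[j])
        for i in range(len(profiles)) for j in range(i + 1, len(profiles))
    ]
    return out


def _as_vector(x) -> pd.Series:
    if isinstance(x, FlankProfile):
        return x.to_vector()
    if isinstance(x, ContextLevels):
        return x.levels()
    if isinstance(x, pd.Series):
        return x
    if isinstance(x, Mapping):
        return pd.Series(x)
    return pd.Series(np.asarray(x, dtype=float))


def correlate_profiles(a, b) -> float:
    """Pearson r between two profiles/level vectors, aligned on shared keys."""
    va, vb = _as_vector(a), _as_vector(b)
    joined = pd.concat([va, vb], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("fewer than 3 shared entries")
    return float(stats.pearsonr(joined.iloc[:, 0], joined.iloc[:, 1])[0])


def context_levels(
    calls: pd.DataFrame, site_class: str = "CpG", metadata: dict | None = None
) -> ContextLevels:
    """Per-context (-2..+3 6-mer) methylation levels of one reaction.

    For CpA/CpT the CCWGG-flagged calls are excluded first (dcm overlap).
    """
    sel = calls[calls["site_class"] == site_class]
    if site_class in ("CpA", "CpT"):
        sel = sel[~sel["ccwgg_flag"]]
    if len(sel) == 0:
        return ContextLevels(
            pd.DataFrame(columns=["n_meth", "n_total", "level"]), site_class,
            metadata or {})
    center = int(sel["center"].iloc[0])
    ctx = sel["original_sequence"].str.slice(center - 2, center + 4)
    g = pd.DataFrame({"context": ctx, "meth": sel["central_meth"].astype(int)})
    tab = g.groupby("context")["meth"].agg(n_meth="sum", n_total="count")
    tab["level"] = tab.n_meth / tab.n_total
    return ContextLevels(tab, site_class, metadata or {})


def extreme_site_composition(
    values: Mapping[str, float] | pd.Series, fraction: float = 0.10
) -> dict[str, pd.DataFrame]:
    """Base enrichment at the variable flank positions of the extreme deciles.

    Contexts are ranked by value; for the top and bottom ``ceil(fraction*N)``
    sets, per-position base frequencies are divided by the all-context
    frequencies (0.25 each for a complete NNCGNN set).  Ties across the
    decile boundary are broken by lexicographic context order.
    """
    s = pd.Series(values, dtype=float)
    if len(s) < 20:
        raise ValueError("need at least 20 contexts")
    m = int(np.ceil(fraction * len(s)))
    order = sorted(s.index, key=lambda c: (-s[c], c))
    top, bottom = order[:m], sorted(s.index, key=lambda c: (s[c], c))[:m]
    width = len(s.index[0])
    # variable positions of an NNCGNN 6-mer: -2 -1 +2 +3
    pos_labels = [-2, -1, 2, 3] if width == 6 else list(range(width))
    pos_idx = [0, 1, 4, 5] if width == 6 else list(range(width))

    def freqs(ctxs) -> pd.DataFrame:
        mat = _char_matrix(list(ctxs))[:, pos_idx]
        counts = np.stack([(mat == b.encode()).sum(axis=0) for b in BASES], axis=1)
        return pd.DataFrame(counts / len(ctxs), index=pos_labels, columns=list(BASES))

    base = freqs(s.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        return {
            "top": (freqs(top) / base).replace([np.inf], np.nan),
            "bottom": (freqs(bottom) / base).replace([np.inf], np.nan),
        }
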