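"""Genomic methylome analysis against biochemical flanking preferences.

Reads a bedGraph-like methylation-call table plus a genome FASTA, keeps CpG
cytosines with sufficient coverage, extracts their 22-nt sequence contexts,
and derives per-NNCGNN mean methylation levels and o/e ratios.  A sliding
window of consecutive CpG sites correlates local methylation with a
biochemical preference table, and a randomization test (permuting the 256
preference values among context keys) turns the window-correlation summary
into a Z statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import revcomp

__all__ = [
    "MethylomeSiteSet",
    "WindowCorrelation",
    "read_calls",
    "load_methylome",
    "mean_by_context",
    "genomic_oe",
    "local_correlation",
    "randomization_z",
]

CALL_COLUMNS = ["chrom", "pos", "strand", "methylated_count", "total_count"]


@dataclass
class MethylomeSiteSet:
    """Retained genomic cytosine records with 22-nt and 6-mer contexts."""

    sites: pd.DataFrame  # chrom, pos, strand, methylated_count, total_count,
                         # level, context22, context6
    log: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sites)

    def on_chrom(self, chrom: str) -> pd.DataFrame:
        return (self.sites[self.sites.chrom == chrom]
                .sort_values("pos").reset_index(drop=True))


@dataclass
class WindowCorrelation:
    """Sliding-window Pearson r values plus their summary statistics."""

    windows: pd.DataFrame  # chrom, start_site_index, start_pos, r
    window: int
    n_positive: int
    n_negative: int
    n_skipped_constant: int
    mean_r: float

    def statistic(self, kind: str = "mean_r") -> float:
        if kind == "mean_r":
            return self.mean_r
        if kind == "pos_excess":
            return float(self.n_positive - self.n_negative)
        raise ValueError(f"unknown statistic {kind!r}")


def read_calls(path) -> pd.DataFrame:
    """Read a methylation-call TSV: chrom, 0-based pos, strand, methylated
    count, total count.  A Bismark-coverage dialect (chrom, 1-based start,
    end, percentage, count_meth, count_unmeth) is auto-detected by column
    count and converted."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 5:
        df.columns = CALL_COLUMNS
        return df
    if df.shape[1] == 6:  # Bismark coverage file; strand unknown -> '+'
        df.columns = ["chrom", "start", "end", "pct", "n_meth", "n_unmeth"]
        out = pd.DataFrame({
            "chrom": df.chrom,
            "pos": df.start - 1,
            "strand": "+",
            "methylated_count": df.n_meth,
            "total_count": df.n_meth + df.n_unmeth,
        })
        return out
    raise ValueError("unrecognized methylation-call format")


def _genome_getter(genome):
    """Accept a {chrom: str} dict or a FASTA path (via pyfaidx)."""
    if isinstance(genome, Mapping):
        return lambda chrom: genome[chrom], set(genome)
    import pyfaidx

    fa = pyfaidx.Fasta(str(genome), as_raw=True, sequence_always_upper=True)
    return lambda chrom: str(fa[chrom][:]), set(fa.keys())


def load_methylome(
    calls: pd.DataFrame, genome, min_coverage: int = 5, flank: int = 10
) -> MethylomeSiteSet:
    """Filter calls to covered CpG cytosines and attach sequence contexts.

    Sites with ``total_count < min_coverage`` are dropped; each record must
    be a cytosine in a CpG on its stated strand, else it is rejected with a
    reason; sites within ``flank`` bp of a contig edge are dropped and
    counted.  Minus-strand records store the reverse-complemented context.
    """
    get, chroms = _genome_getter(genome)
    missing = set(calls.chrom.unique()) - chroms
    if missing:
        raise ValueError(f"contigs missing from genome: {sorted(missing)}")
    rows = []
    log = {"n_input": len(calls), "dropped_coverage": 0, "dropped_edge": 0,
           "rejected_not_cpg": 0}
    for chrom, sub in calls.groupby("chrom", sort=False):
        seq = get(chrom)
        L = len(seq)
        for pos, strand, m, t in sub[["pos", "strand", "methylated_count",
                                      "total_count"]].itertuples(index=False):
            if t < m or m < 0:
                raise ValueError(f"bad counts at {chrom}:{pos}")
            if strand == "+":
                ok = pos + 1 < L and seq[pos] == "C" and seq[pos + 1] == "G"
                lo, hi = pos - flank, pos + flank + 2
            else:
                ok = pos >= 1 and seq[pos] == "G" and seq[pos - 1] == "C"
                lo, hi = pos - flank - 1, pos + flank + 1
            if not ok:
                log["rejected_not_cpg"] += 1
                continue
            if t < min_coverage:
                log["dropped_coverage"] += 1
                continue
            if lo < 0 or hi > L:
                log["dropped_edge"] += 1
                continue
            ctx22 = seq[lo:hi]
            if strand == "-":
                ctx22 = revcomp(ctx22)
            rows.append((chrom, pos, strand, m, t, m / t, ctx22, ctx22[8:14]))
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "strand",
                                        "methylated_count", "total_count",
                                        "level", "context22", "context6"])
    log["n_retained"] = len(sites)
    return MethylomeSiteSet(sites, log)


def mean_by_context(sites: MethylomeSiteSet | pd.DataFrame,
                    weighted: bool = False) -> tuple[pd.Series, float]:
    """Per-NNCGNN mean methylation level and the overall mean.

    Unweighted across sites by default (each site's m/t counts once); the
    coverage-weighted alternative pools counts per context.
    """
    df = sites.sites if isinstance(sites, MethylomeSiteSet) else sites
    if len(df) == 0:
        raise ValueError("no sites")
    if weighted:
        g = df.groupby("context6")[["methylated_count", "total_count"]].sum()
        means = g.methylated_count / g.total_count
        overall = float(df.methylated_count.sum() / df.total_count.sum())
    else:
        means = df.groupby("context6")["level"].mean()
        overall = float(df.level.mean())
    return means.rename("mean_level"), overall


def genomic_oe(
    context_means: pd.Series,
    overall_mean: float,
    granularity: str = "NNCGNN",
    site_counts: pd.Series | None = None,
) -> pd.Series:
    """Context methylation expressed as o/e: mean(context) / overall mean.

    At ``NNCG`` granularity the 16 6-mers sharing the NN.CG prefix are
    aggregated over the +2/+3 positions, weighted by site counts when given.
    """
    if overall_mean <= 0:
        raise ValueError("overall mean must be > 0")
    if granularity == "NNCGNN":
        return (context_means / overall_mean).rename("oe")
    if granularity != "NNCG":
        raise ValueError("granularity must be 'NNCGNN' or 'NNCG'")
    key = context_means.index.str.slice(0, 4)
    if site_counts is None:
        agg = context_means.groupby(key).mean()
    else:
        w = site_counts.reindex(context_means.index).fillna(0.0)
        agg = (context_means * w).groupby(key).sum() / w.groupby(key).sum()
    return (agg / overall_mean).rename("oe")


def _windowed_pearson(x: np.ndarray, y: np.ndarray, W: int) -> np.ndarray:
    """Pearson r of all length-W sliding windows via cumulative sums.

    Windows where either vector is (numerically) constant get NaN.
    """
    def wsum(v):
        c = np.concatenate([[0.0], np.cumsum(v, dtype=float)])
        return c[W:] - c[:-W]

    sx, sy = wsum(x), wsum(y)
    sxx, syy, sxy = wsum(x * x), wsum(y * y), wsum(x * y)
    vx = W * sxx - sx * sx
    vy = W * syy - sy * sy
    num = W * sxy - sx * sy
    scale_x = np.maximum(W * sxx, 1e-300)
    scale_y = np.maximum(W * syy, 1e-300)
    const = (vx <= 1e-10 * scale_x) | (vy <= 1e-10 * scale_y)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / np.sqrt(vx * vy)
    r[const] = np.nan
    return np.clip(r, -1.0, 1.0)


def local_correlation(
    sites: MethylomeSiteSet | pd.DataFrame,
    preference: Mapping[str, float] | pd.Series,
    chrom: str | None = None,
    window: int = 22,
    step: int = 1,
) -> WindowCorrelation:
    """Sliding-window correlation of methylation with context preference.

    Over ``window`` consecutive retained CpG sites (genomic order, one
    chromosome), Pearson r between per-site level and the NNCGNN preference
    value; windows with a constant vector are skipped and counted.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    df = sites.sites if isinstance(sites, MethylomeSiteSet) else sites
    if chrom is not None:
        df = df[df.chrom == chrom]
    if df.chrom.nunique() > 1:
        raise ValueError("sites span multiple chromosomes; pass chrom=")
    df = df.sort_values("pos").reset_index(drop=True)
    pref = pd.Series(preference, dtype=float)
    known = df.context6.isin(pref.index)
    df = df[known].reset_index(drop=True)
    if len(df) < window:
        raise ValueError("fewer retained sites than the window size")
    x = df.level.to_numpy(float)
    y = pref.reindex(df.context6).to_numpy(float)
    r = _windowed_pearson(x, y, window)[::step]
    starts = np.arange(0, len(x) - window + 1)[::step]
    valid = ~np.isnan(r)
    out = pd.DataFrame({
        "chrom": df.chrom.iloc[0],
        "start_site_index": starts[valid],
        "start_pos": df.pos.to_numpy()[starts[valid]],
        "r": r[valid],
    })
    return WindowCorrelation(
        windows=out, window=window,
        n_positive=int((out.r > 0).sum()), n_negative=int((out.r < 0).sum()),
        n_skipped_constant=int((~valid).sum()), mean_r=float(out.r.mean()),
    )


def randomization_z(
    sites: MethylomeSiteSet | pd.DataFrame,
    preference: Mapping[str, float] | pd.Series,
    n_randomizations: int = 20,
    seed: int = 0,
    statistic: str = "mean_r",
    chrom: str | None = None,
    window: int = 22,
    step: int = 1,
) -> tuple[float, float, dict]:
    """Z test of the window-correlation statistic against permuted preferences.

    Each round permutes the preference values among the context keys and
    recomputes the statistic; Z = (observed - null mean) / null SD and the
    one-sided p is the upper normal tail.
    """
    if n_randomizations < 2:
        raise ValueError("need at least 2 randomizations")
    pref = pd.Series(preference, dtype=float)
    obs = local_correlation(sites, pref, chrom, window, step).statistic(statistic)
    if not np.isfinite(obs):
        raise ValueError("window statistic undefined (no valid windows)")
    rng = np.random.default_rng(seed)
    null = np.empty(n_randomizations)
    vals = pref.to_numpy(float)
    for i in range(n_randomizations):
        perm = pd.Series(rng.permutation(vals), index=pref.index)
        null[i] = local_correlation(sites, perm, chrom, window, step
                                    ).statistic(statistic)
    sd = float(null.std(ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("null statistic has zero spread")
    z = (obs - float(null.mean())) / sd
    p = float(stats.norm.sf(z))
    detail = {"observed": obs, "null_mean": float(null.mean()), "null_sd": sd,
              "n_randomizations": n_randomizations, "statistic": statistic}
    return float(z), p, detail
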