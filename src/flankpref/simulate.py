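"""Synthetic data generation for the whole pipeline.

Three generators stand in for the study's raw inputs so every downstream
stage is testable without downloads:

* hairpin-bisulfite reads from a randomized-flank substrate whose central-site
  methylation follows a monoexponential progress curve
  ``p = plateau * (1 - exp(-k(context) * tau))`` for a known 256-entry rate
  table and per-reaction virtual time ``tau``;
* a genomic methylome whose per-CpG methylation level tracks an NNCGNN
  preference table, observed through Poisson coverage and binomial sampling;
* repeat-like sequences with a planted number of motif copies on an i.i.d.
  background.

All randomness is driven by explicit integer seeds; the same seed yields
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import BASES, all_contexts, c_to_t, geometric_mean, revcomp
from .hairpin import ReadRecord

__all__ = [
    "SubstrateLayout",
    "TrueKinetics",
    "NoiseModel",
    "uniform_rate_table",
    "loguniform_rate_table",
    "dnmt3c_like_rate_table",
    "simulate_reaction_reads",
    "simulate_context_levels",
    "simulate_methylome",
    "simulate_repeat",
    "write_fasta",
]

# default fixed parts of the randomized-flank substrate; the hairpin linker
# is C-free so bisulfite conversion leaves it intact and searchable
_FIVE_PRIME = "TGTGAAGGATCAGT"
_THREE_PRIME = "ACTGATCCTTGAGTG"
_LINKER = "GGAATTAGGAGATTGAGGATAGGTTAG"


@dataclass
class SubstrateLayout:
    """Geometry of the randomized-flank hairpin substrate.

    The upper strand is ``five_prime_arm + N*n_left + central_site +
    N*n_right + three_prime_arm``; the sequenced molecule is the converted
    upper strand, the 27-mer hairpin linker, then the converted lower strand
    read 5'->3' from the ligation point.
    """

    five_prime_arm: str = _FIVE_PRIME
    n_left: int = 10
    central_site: str = "CG"
    n_right: int = 10
    three_prime_arm: str = _THREE_PRIME
    hairpin_linker: str = _LINKER

    def __post_init__(self) -> None:
        if not self.central_site or self.central_site[0] != "C":
            raise ValueError("central_site must start with C")
        if self.n_left < 0 or self.n_right < 0:
            raise ValueError("flank lengths must be non-negative")

    @property
    def region_length(self) -> int:
        return self.n_left + len(self.central_site) + self.n_right

    @property
    def upper_length(self) -> int:
        return len(self.five_prime_arm) + self.region_length + len(self.three_prime_arm)

    @property
    def read_length(self) -> int:
        return 2 * self.upper_length + len(self.hairpin_linker)


@dataclass
class TrueKinetics:
    """Ground-truth rate table, per-reaction virtual times and plateau."""

    rates: Mapping[str, float]
    virtual_times: Mapping[int, float]
    plateau: float = 1.0

    def __post_init__(self) -> None:
        for ctx, k in self.rates.items():
            if not math.isfinite(k) or k < 0:
                raise ValueError(f"rate for {ctx} must be finite and >= 0")
        for j, t in self.virtual_times.items():
            if t < 0:
                raise ValueError(f"virtual time for reaction {j} must be >= 0")
        if not 0 < self.plateau <= 1:
            raise ValueError("plateau must be in (0, 1]")


@dataclass
class NoiseModel:
    """Read-level noise switches; all off by default."""

    bisulfite_conversion_rate: float = 1.0
    inappropriate_conversion_rate: float = 0.0
    sequencing_error_rate: float = 0.0
    duplicate_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bisulfite_conversion_rate", "inappropriate_conversion_rate",
                     "sequencing_error_rate", "duplicate_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def clean(self) -> bool:
        return (self.bisulfite_conversion_rate == 1.0
                and self.inappropriate_conversion_rate == 0.0
                and self.sequencing_error_rate == 0.0)


def uniform_rate_table(value: float = 1.0, central: str = "CG") -> dict[str, float]:
    return {c: value for c in all_contexts(central)}


def loguniform_rate_table(
    seed: int, decades: float = 2.0, central: str = "CG"
) -> dict[str, float]:
    """Rates log-uniform over ``decades`` orders of magnitude, geometric mean 1."""
    rng = np.random.default_rng(seed)
    ctxs = all_contexts(central)
    k = 10.0 ** rng.uniform(-decades / 2, decades / 2, size=len(ctxs))
    k /= geometric_mean(k)
    return dict(zip(ctxs, k.tolist()))


# per-position log-weights emulating the DNMT3C-style preference pattern:
# strong C preference at -2 and -1, moderate A(-1), disfavor of T(-1),
# DNMT3B-like G(+2) preference
_DNMT3C_WEIGHTS = {
    -2: {"A": -0.2, "C": 1.2, "G": -0.4, "T": 0.4},
    -1: {"A": 0.7, "C": 1.0, "G": -0.5, "T": -1.2},
    2: {"A": 0.3, "C": -0.3, "G": 0.6, "T": -0.6},
    3: {"A": 0.1, "C": 0.2, "G": 0.3, "T": -0.6},
}


def dnmt3c_like_rate_table(central: str = "CG") -> dict[str, float]:
    """Deterministic rate table with a C(-2)/C(-1)-preferring profile.

    Additive per-position log-weights, exponentiated and gauge-normalized to
    geometric mean 1; spans roughly two decades like the measured tables.
    """
    ctxs = all_contexts(central)
    k = np.array([
        math.exp(_DNMT3C_WEIGHTS[-2][c[0]] + _DNMT3C_WEIGHTS[-1][c[1]]
                 + _DNMT3C_WEIGHTS[2][c[4]] + _DNMT3C_WEIGHTS[3][c[5]])
        for c in ctxs
    ])
    k /= geometric_mean(k)
    return dict(zip(ctxs, k.tolist()))


def _draw_flanks(rng, n_reads: int, n_bases: int, base_probs) -> np.ndarray:
    p = np.full(4, 0.25) if base_probs is None else np.asarray(
        [base_probs[b] for b in BASES], dtype=float)
    p = p / p.sum()
    idx = rng.choice(4, size=(n_reads, n_bases), p=p)
    return np.array(list(BASES))[idx]


def _convert_strand(seq: str, meth_positions: frozenset, noise: NoiseModel, rng) -> str:
    """Bisulfite-convert one strand; methylated Cs are protected."""
    if noise.clean:
        out = list(c_to_t(seq))
        for i in meth_positions:
            if seq[i] == "C":
                out[i] = "C"
        return "".join(out)
    out = []
    for i, b in enumerate(seq):
        if b == "C":
            if i in meth_positions:
                b = "T" if rng.random() < noise.inappropriate_conversion_rate else "C"
            else:
                b = "T" if rng.random() < noise.bisulfite_conversion_rate else "C"
        out.append(b)
    return "".join(out)


def simulate_reaction_reads(
    layout: SubstrateLayout,
    kinetics: TrueKinetics,
    reaction_index: int,
    n_reads: int,
    noise: NoiseModel | None = None,
    base_probs: Mapping[str, float] | None = None,
    flank_cpn_rate: float = 0.0,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate one methylation reaction as bisulfite-converted hairpin reads.

    Each read gets uniformly random flanks (or ``base_probs``-biased ones);
    its central-site methylation is Bernoulli with
    ``p = plateau * (1 - exp(-k(context) * tau))``.  ``flank_cpn_rate``
    optionally methylates flank cytosines at a low rate to stress-test the
    caller.  Returns the reads plus a truth table (read_id, flank_seq,
    context, methylated).
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if reaction_index not in kinetics.virtual_times:
        raise ValueError(f"reaction {reaction_index} has no virtual time")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    tau = kinetics.virtual_times[reaction_index]
    nc = len(layout.central_site)

    flanks = _draw_flanks(rng, n_reads, layout.n_left + layout.n_right, base_probs)
    lefts = ["".join(row[: layout.n_left]) for row in flanks]
    rights = ["".join(row[layout.n_left:]) for row in flanks]

    contexts = [
        lefts[i][-2:] + layout.central_site + rights[i][:2] for i in range(n_reads)
    ]
    try:
        k = np.array([kinetics.rates[c] for c in contexts])
    except KeyError as e:
        raise ValueError(f"context {e.args[0]} missing from rate table") from None
    p = kinetics.plateau * (1.0 - np.exp(-k * tau))
    meth = rng.random(n_reads) < p

    ci = len(layout.five_prime_arm) + layout.n_left  # central C, upper coords
    reads: list[ReadRecord] = []
    rows = []
    for i in range(n_reads):
        upper = (layout.five_prime_arm + lefts[i] + layout.central_site
                 + rights[i] + layout.three_prime_arm)
        meth_pos = {ci} if meth[i] else set()
        if flank_cpn_rate > 0:
            for j, b in enumerate(upper):
                if b == "C" and j != ci and rng.random() < flank_cpn_rate:
                    meth_pos.add(j)
        upper_conv = _convert_strand(upper, frozenset(meth_pos), noise, rng)
        # lower strand read 5'->3' from the ligation point; its central C is
        # emitted unmethylated (the call is read from the upper strand)
        lower_read = revcomp(upper)
        lower_conv = _convert_strand(lower_read, frozenset(), noise, rng)
        linker_conv = _convert_strand(layout.hairpin_linker, frozenset(), noise, rng)
        seq = upper_conv + linker_conv + lower_conv
        if noise.sequencing_error_rate > 0:
            chars = list(seq)
            hits = np.nonzero(rng.random(len(chars)) < noise.sequencing_error_rate)[0]
            for h in hits:
                alts = [b for b in BASES if b != chars[h]]
                chars[h] = alts[rng.integers(3)]
            seq = "".join(chars)
        rid = f"r{reaction_index}_{i}"
        reads.append(ReadRecord(rid, seq, [40] * len(seq)))
        rows.append((rid, lefts[i] + layout.central_site + rights[i],
                     contexts[i], bool(meth[i])))

    if noise.duplicate_fraction > 0:
        n_dup = int(round(noise.duplicate_fraction * n_reads))
        for di in rng.choice(n_reads, size=n_dup, replace=False):
            r = reads[di]
            reads.append(ReadRecord(r.id + ".dup", r.sequence, list(r.qualities)))
            rows.append((r.id + ".dup",) + rows[di][1:])

    truth = pd.DataFrame(rows, columns=["read_id", "flank_seq", "context", "methylated"])
    return reads, truth


def simulate_context_levels(
    kinetics: TrueKinetics,
    reaction_index: int,
    n_reads: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-context methylation counts for one reaction, sampled at the
    context-count level (equivalent to, and much faster than, full read
    simulation followed by calling).

    Returns a frame (context, n_meth, n_total, level).
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    tau = kinetics.virtual_times[reaction_index]
    ctxs = sorted(kinetics.rates)
    counts = rng.multinomial(n_reads, np.full(len(ctxs), 1.0 / len(ctxs)))
    k = np.array([kinetics.rates[c] for c in ctxs])
    p = kinetics.plateau * (1.0 - np.exp(-k * tau))
    m = rng.binomial(counts, p)
    df = pd.DataFrame({"context": ctxs, "n_meth": m, "n_total": counts})
    df = df[df.n_total > 0].reset_index(drop=True)
    df["level"] = df.n_meth / df.n_total
    return df


def simulate_methylome(
    genome_length: int,
    preference: Mapping[str, float],
    mean_level: float = 0.0146,
    coverage_mean: float = 10.0,
    seed: int = 0,
    gc: float = 0.42,
    chrom: str = "chr1",
) -> tuple[str, pd.DataFrame, pd.DataFrame]:
    """Random genome plus a preference-driven methylation-call table.

    Every CpG cytosine (both strands, away from contig edges) gets a true
    level proportional to its NNCGNN preference scaled so the table-average
    context has level ``mean_level`` (clipped to [0, 1]); observed counts are
    binomial at Poisson(``coverage_mean``) coverage.  Returns (genome
    sequence, call table, truth table).
    """
    if genome_length < 1000:
        raise ValueError("genome_length must be >= 1000")
    if not 0 < mean_level < 1:
        raise ValueError("mean_level must be in (0, 1)")
    if not preference:
        raise ValueError("preference map is empty")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(np.array(list(BASES)), size=genome_length, p=probs)
    genome = "".join(arr)

    scale = mean_level / float(np.mean(list(preference.values())))
    is_c = arr == "C"
    is_g = arr == "G"
    cpg_pos = np.nonzero(is_c[:-1] & is_g[1:])[0]
    # keep full 22-nt context available on both strands
    cpg_pos = cpg_pos[(cpg_pos >= 10) & (cpg_pos + 12 <= genome_length)]

    rows, truth_rows = [], []
    for i in cpg_pos:
        ctx6 = genome[i - 2: i + 4]
        if ctx6 not in preference:
            continue
        # per-cytosine de novo methylation: each strand's level follows its
        # own strand context (no maintenance coupling between the strands)
        for strand, pos, ctx in (("+", int(i), ctx6),
                                 ("-", int(i) + 1, revcomp(ctx6))):
            if ctx not in preference:
                continue
            level = min(1.0, max(0.0, scale * preference[ctx]))
            cov = rng.poisson(coverage_mean)
            truth_rows.append((pos, strand, ctx, level))
            if cov < 1:
                continue
            m = rng.binomial(cov, level)
            rows.append((chrom, pos, strand, int(m), int(cov)))
    calls = pd.DataFrame(rows, columns=["chrom", "pos", "strand",
                                        "methylated_count", "total_count"])
    truth = pd.DataFrame(truth_rows, columns=["pos", "strand", "context", "true_level"])
    return genome, calls, truth


def simulate_repeat(
    length: int,
    base_composition: Mapping[str, float] | None = None,
    planted_motif: str = "CCCG",
    planted_count: int = 0,
    seed: int = 0,
    max_tries: int = 100000,
) -> str:
    """i.i.d. background sequence with non-overlapping planted motif copies."""
    if planted_count * len(planted_motif) >= length:
        raise ValueError("planted motifs do not fit into the sequence")
    rng = np.random.default_rng(seed)
    if base_composition is None:
        p = np.full(4, 0.25)
    else:
        p = np.array([base_composition[b] for b in BASES], dtype=float)
        p /= p.sum()
    arr = rng.choice(np.array(list(BASES)), size=length, p=p)
    L = len(planted_motif)
    taken: list[tuple[int, int]] = []
    tries = 0
    while len(taken) < planted_count:
        tries += 1
        if tries > max_tries:
            raise ValueError("could not place all motif copies without overlap")
        s = int(rng.integers(0, length - L + 1))
        if any(s < e and s + L > b for b, e in taken):
            continue
        taken.append((s, s + L))
        arr[s: s + L] = list(planted_motif)
    return "".join(arr)


def write_fasta(path, sequences: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")
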