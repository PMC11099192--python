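"""Virtual-time kinetic fitting of per-context methylation levels.

Independent methylation reactions run with different enzyme concentrations
and incubation times sample different points of each context's reaction
progress curve.  Modelling every reaction ``j`` by a latent *virtual time*
``tau_j >= 0`` that absorbs concentration and duration, the level of context
``i`` in reaction ``j`` is

    m_ij = plateau * (1 - exp(-k_i * tau_j))

and the per-context relative rate constants ``k_i`` become comparable across
reactions.  The model is scale-degenerate (k -> c*k, tau -> tau/c leaves the
fit unchanged); the gauge is fixed by setting the geometric mean of the
fitted rates to 1, so rates are reported relative to the average context.

Fitting minimizes the count-weighted sum of squares
``sum_ij w_ij (m_ij - plateau*(1-exp(-k_i tau_j)))^2`` with ``w_ij`` the
per-context read counts, by alternating exact coordinate (Newton) updates of
all ``k`` given ``tau`` and vice versa ("serial fitting"), from multiple
jittered starts; convergence requires the restarts to agree in SSE.

Also here: the class-level CpN fit, initial-rate linear regression for
radioactive progress curves, the hemimethylated-minus-fully-methylated rate
difference, and substrate-level preference prediction from a rate table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import geometric_mean, revcomp

__all__ = [
    "VirtualTimeModel",
    "VirtualTimeResults",
    "fit_cpn_class_rates",
    "InitialRateResult",
    "initial_rate",
    "hm_fm_difference",
    "predict_substrate_preference",
]


def _row_sse(k, tau, m, w, P):
    E = np.exp(-np.outer(k, tau))
    r = m - P * (1.0 - E)
    return (w * r * r).sum(axis=1)


def _update_rows(k, tau, m, w, P, n_iter=40):
    """Per-row 1-D Newton minimization of the weighted SSE in k, vectorized
    over rows; ``tau`` is held fixed.  Rows with a single active observation
    are solved in closed form.  Safeguarded by backtracking; k stays >= 0."""
    k = k.copy()
    active = w > 0
    n_active = active.sum(axis=1)
    single = n_active == 1
    if single.any():
        idx = np.nonzero(single)[0]
        jj = np.argmax(active[idx], axis=1)
        mm = m[idx, jj] / P
        tt = tau[jj]
        with np.errstate(divide="ignore"):
            kk = np.where(mm >= 1.0, np.inf, -np.log1p(-np.minimum(mm, 1 - 1e-15)))
        k[idx] = np.where(tt > 0, np.where(np.isinf(kk), 1e6, kk) / np.maximum(tt, 1e-300), k[idx])
    rows = np.nonzero(~single)[0]
    if rows.size == 0:
        return k
    km = k[rows]
    mm, wm = m[rows], w[rows]
    sse = _row_sse(km, tau, mm, wm, P)
    for _ in range(n_iter):
        E = np.exp(-np.outer(km, tau))
        r = mm - P * (1.0 - E)
        g = (-2.0 * wm * r * P * tau[None, :] * E).sum(axis=1)
        h = (2.0 * wm * ((P * tau[None, :] * E) ** 2 + r * P * (tau[None, :] ** 2) * E)).sum(axis=1)
        newton = h > 0
        step = np.where(newton, g / np.where(newton, h, 1.0),
                        np.sign(g) * 0.5 * (km + 1e-3))
        alpha = np.ones_like(km)
        best_k, best_sse = km.copy(), sse.copy()
        pending = np.ones_like(km, dtype=bool)
        for _bt in range(30):
            trial = np.clip(km - alpha * step, 0.0, None)
            sse_t = _row_sse(trial, tau, mm, wm, P)
            improve = pending & (sse_t <= best_sse)
            best_k[improve] = trial[improve]
            best_sse[improve] = sse_t[improve]
            pending &= ~improve
            if not pending.any():
                break
            alpha[pending] *= 0.5
        moved = np.abs(best_k - km)
        km, sse = best_k, best_sse
        if np.max(moved / np.maximum(km, 1e-12)) < 1e-14:
            break
    k[rows] = km
    return k


def _fit_plateau(k, tau, m, w):
    """Closed-form weighted LS plateau given k and tau, clipped to (0, 1]."""
    F = 1.0 - np.exp(-np.outer(k, tau))
    num = (w * m * F).sum()
    den = (w * F * F).sum()
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1e-6, 1.0))


@dataclass
class VirtualTimeResults:
    """Fitted rate table with virtual times and fit diagnostics."""

    k: pd.Series
    tau: pd.Series
    plateau: float
    sse: float
    converged: bool
    n_restarts_agreeing: int
    k_se: pd.Series
    flags: dict = field(default_factory=dict)
    excluded: dict = field(default_factory=dict)
    restart_sse: list = field(default_factory=list)
    n_obs: int = 0

    @property
    def fitted_rates(self) -> pd.Series:
        """Rates excluding the 0 / inf sentinels of degenerate contexts."""
        return self.k[np.isfinite(self.k) & (self.k > 0)]

    def predict(self, contexts=None, reactions=None) -> pd.DataFrame:
        ctxs = list(self.k.index) if contexts is None else list(contexts)
        rxns = list(self.tau.index) if reactions is None else list(reactions)
        kk = self.k.loc[ctxs].to_numpy()
        tt = self.tau.loc[rxns].to_numpy()
        lv = self.plateau * (1.0 - np.exp(-np.outer(kk, tt)))
        return pd.DataFrame(lv, index=ctxs, columns=rxns)

    def rate_table(self) -> pd.DataFrame:
        """Rates with rank 1 = fastest; sentinel-flagged contexts included."""
        tab = pd.DataFrame({"k": self.k, "se": self.k_se})
        tab["rank"] = tab.k.rank(ascending=False, method="min").astype(int)
        tab["flag"] = [self.flags.get(c, "") for c in tab.index]
        return tab.sort_values("rank")

    def summary(self) -> str:
        fitted = self.k[np.isfinite(self.k) & (self.k > 0)]
        lines = [
            "Virtual-time kinetic fit",
            "=" * 60,
            f"contexts fitted: {len(fitted)}   reactions: {len(self.tau)}   "
            f"observations: {self.n_obs}",
            f"plateau: {self.plateau:.6g}   weighted SSE: {self.sse:.6g}",
            f"converged: {self.converged}   restarts agreeing: "
            f"{self.n_restarts_agreeing}/{len(self.restart_sse)}",
            f"rate range (max/min): {fitted.max() / fitted.min():.4g}"
            if len(fitted) > 1 else "",
            "",
            "virtual times:",
        ]
        for r, t in self.tau.items():
            lines.append(f"  reaction {r}: tau = {t:.6g}")
        top = fitted.sort_values(ascending=False)
        lines += ["", "fastest contexts:"]
        for c, v in top.head(5).items():
            lines.append(f"  {c}  k = {v:.4g} (se {self.k_se.get(c, float('nan')):.2g})")
        lines += ["slowest contexts:"]
        for c, v in top.tail(5).items():
            lines.append(f"  {c}  k = {v:.4g} (se {self.k_se.get(c, float('nan')):.2g})")
        if self.excluded.get("single_reaction"):
            lines.append(f"excluded (observed in <2 reactions): "
                         f"{len(self.excluded['single_reaction'])}")
        return "\n".join(s for s in lines if s is not None)


class VirtualTimeModel:
    """Shared-latent-time monoexponential model over contexts x reactions.

    Parameters
    ----------
    levels : DataFrame with columns ``reaction``, ``context``, ``n_meth``,
        ``n_total`` (one row per context per reaction).
    min_count : minimum reads per context per reaction for an observation
        to enter the fit.
    """

    def __init__(self, levels: pd.DataFrame, min_count: int = 10):
        req = {"reaction", "context", "n_meth", "n_total"}
        if not req.issubset(levels.columns):
            raise ValueError(f"levels needs columns {sorted(req)}")
        self.levels = levels.copy()
        self.levels["level"] = self.levels.n_meth / self.levels.n_total
        self.min_count = int(min_count)

    @classmethod
    def from_context_levels(cls, by_reaction: Mapping, min_count: int = 10
                            ) -> "VirtualTimeModel":
        """Build from {reaction_id: ContextLevels} as produced by the
        profiles module."""
        frames = []
        for rxn, cl in by_reaction.items():
            t = cl.table.reset_index().rename(columns={"index": "context"})
            t["reaction"] = rxn
            frames.append(t[["reaction", "context", "n_meth", "n_total"]])
        return cls(pd.concat(frames, ignore_index=True), min_count)

    def _matrices(self):
        lv = self.levels
        m = lv.pivot_table(index="context", columns="reaction", values="level",
                           aggfunc="mean")
        w = lv.pivot_table(index="context", columns="reaction", values="n_total",
                           aggfunc="sum").reindex_like(m)
        W = w.fillna(0.0).to_numpy(float)
        W[W < self.min_count] = 0.0
        M = np.nan_to_num(m.to_numpy(float), nan=0.0)
        return list(m.index), list(m.columns), M, W

    def fit(
        self,
        plateau_mode: str = "fixed",
        plateau: float = 1.0,
        n_restarts: int = 3,
        seed: int = 0,
        fix_tau: Mapping | None = None,
        tol: float = 1e-10,
        max_sweeps: int = 500,
        weighting: str = "gls",
    ) -> VirtualTimeResults:
        """Fit rates and virtual times.

        ``plateau_mode`` is ``fixed`` (default 1.0) or ``fitted`` (a single
        global plateau in (0, 1]).  ``fix_tau`` freezes the virtual times to
        the given {reaction: tau} map — in that mode single-reaction
        contexts are allowed and no gauge fixing is applied, so the
        one-reaction fit reproduces the closed form k = -ln(1-m/P)/tau.

        ``weighting``: with ``"counts"`` the SSE weights are the read counts
        throughout; the default ``"gls"`` adds one reweighted refinement pass
        with weights counts / max(p*(1-p), 1e-3) taken from the model-
        predicted levels of the first pass.  Count weights alone underweight
        near-saturated observations, whose binomial variance is small, and
        noticeably inflate the spread of the extreme fitted rates; on
        noise-free data both modes give the identical zero-residual fit.
        """
        if weighting not in ("counts", "gls"):
            raise ValueError("weighting must be 'counts' or 'gls'")
        if plateau_mode not in ("fixed", "fitted"):
            raise ValueError("plateau_mode must be 'fixed' or 'fitted'")
        ctxs, rxns, M, W = self._matrices()
        active = W > 0
        n_active = active.sum(axis=1)
        need = 1 if fix_tau is not None else 2
        flags: dict[str, str] = {}
        excluded = {"single_reaction": [c for c, n in zip(ctxs, n_active)
                                        if 0 < n < need]}
        P0 = plateau if plateau_mode == "fixed" else 1.0

        zero_rows = np.array([
            (n >= need) and np.all(M[i][active[i]] <= 0) for i, n in enumerate(n_active)])
        sat_rows = np.array([
            (n >= need) and np.all(M[i][active[i]] >= P0 - 1e-12)
            for i, n in enumerate(n_active)])
        fit_rows = (n_active >= need) & ~zero_rows & ~sat_rows
        if fit_rows.sum() == 0:
            raise ValueError("no context has enough observations to fit")
        Mi, Wi = M[fit_rows], W[fit_rows]
        fit_ctxs = [c for c, f in zip(ctxs, fit_rows) if f]

        if fix_tau is not None:
            tau0 = np.array([float(fix_tau[r]) for r in rxns])
        else:
            mc = np.clip(Mi / P0, 1e-9, 1 - 1e-9)
            L = -np.log1p(-mc)
            L[Wi == 0] = np.nan
            tau0 = np.nanmean(L, axis=0)
            tau0 = np.where(np.isfinite(tau0) & (tau0 > 0), tau0, 1.0)

        def alternate(k, tau, P, W):
            sse_prev = np.inf
            for _sweep in range(max_sweeps):
                k = _update_rows(k, tau, Mi, W, P)
                if fix_tau is None:
                    tau = _update_rows(tau, k, Mi.T, W.T, P)
                if plateau_mode == "fitted":
                    P = _fit_plateau(k, tau, Mi, W)
                sse = float(_row_sse(k, tau, Mi, W, P).sum())
                if sse < 1e-26 or abs(sse_prev - sse) <= tol * max(sse, 1e-30):
                    break
                sse_prev = sse
            return sse, k, tau, P

        rng = np.random.default_rng(seed)
        results = []
        for restart in range(max(1, n_restarts)):
            tau = tau0.copy()
            mc = np.clip(Mi / P0, 1e-9, 1 - 1e-9)
            with np.errstate(invalid="ignore", divide="ignore"):
                K0 = -np.log1p(-mc) / tau[None, :]
            K0[Wi == 0] = np.nan
            k = np.nanmean(K0, axis=1)
            k = np.where(np.isfinite(k) & (k > 0), k, 1e-6)
            if restart > 0:
                k = k * np.exp(rng.normal(0.0, 0.3, size=k.shape))
                if fix_tau is None:
                    tau = tau * np.exp(rng.normal(0.0, 0.3, size=tau.shape))
            results.append(alternate(k, tau.copy(), P0, Wi))

        results.sort(key=lambda t: t[0])
        best_sse, k, tau, P = results[0]
        agree = sum(1 for s, *_ in results
                    if s - best_sse <= 1e-6 * max(best_sse, 1e-15))
        converged = agree >= min(3, len(results))

        if weighting == "gls" and best_sse > 1e-26:
            pm = P * (1.0 - np.exp(-np.outer(k, tau)))
            Wg = np.where(Wi > 0, Wi / np.maximum(pm * (1.0 - pm), 1e-3), 0.0)
            best_sse, k, tau, P = alternate(k.copy(), tau.copy(), P, Wg)
            Wi = Wg  # diagnostics below use the final weights

        if fix_tau is None:
            pos = k[np.isfinite(k) & (k > 0)]
            if pos.size:
                g = geometric_mean(pos)
                k = k / g
                tau = tau * g

        # conditional (tau held fixed) Gauss-Newton standard errors
        dof = max(int((Wi > 0).sum()) - (len(k) + (0 if fix_tau is not None else len(tau))
                                         + (1 if plateau_mode == "fitted" else 0)), 1)
        sigma2 = best_sse / dof
        E = np.exp(-np.outer(k, tau))
        H = (2.0 * Wi * (P * tau[None, :] * E) ** 2).sum(axis=1)
        with np.errstate(divide="ignore"):
            se = np.sqrt(np.where(H > 0, 2.0 * sigma2 / np.maximum(H, 1e-300), np.inf))

        k_full = pd.Series(np.nan, index=ctxs, dtype=float)
        se_full = pd.Series(np.nan, index=ctxs, dtype=float)
        k_full.loc[fit_ctxs] = k
        se_full.loc[fit_ctxs] = se
        for c in np.array(ctxs)[zero_rows]:
            k_full.loc[c] = 0.0
            flags[c] = "all_zero"
        for c in np.array(ctxs)[sat_rows]:
            k_full.loc[c] = np.inf
            flags[c] = "saturated"
        k_full = k_full.dropna()
        se_full = se_full.reindex(k_full.index)

        return VirtualTimeResults(
            k=k_full, tau=pd.Series(tau, index=rxns), plateau=P, sse=best_sse,
            converged=converged, n_restarts_agreeing=agree, k_se=se_full,
            flags=flags, excluded=excluded,
            restart_sse=[s for s, *_ in results], n_obs=int((Wi > 0).sum()),
        )


def fit_cpn_class_rates(
    class_levels: pd.DataFrame,
    shared_tau: pd.Series | Mapping | None = None,
    seed: int = 0,
) -> tuple[pd.Series, VirtualTimeResults]:
    """Fit per-CpN-class rates (CpG/CpA/CpT/CpC), reported relative to CpG.

    ``class_levels`` has columns reaction, context (the class label), n_meth,
    n_total.  When ``shared_tau`` is given (e.g. from the CpG NNCGNN fit) the
    virtual times are frozen to it.
    """
    model = VirtualTimeModel(class_levels, min_count=1)
    fix = None
    if shared_tau is not None:
        fix = dict(shared_tau.items() if hasattr(shared_tau, "items") else shared_tau)
    res = model.fit(fix_tau=fix, seed=seed)
    if "CpG" not in res.k.index or res.k["CpG"] <= 0:
        raise ValueError("CpG class missing or has zero rate; cannot normalize")
    rel = res.k / res.k["CpG"]
    return rel, res


@dataclass
class InitialRateResult:
    """Initial-phase linear regression of a progress curve."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    slope_se: float

    def __repr__(self) -> str:  # compact, for summaries
        return (f"InitialRate(slope={self.slope:.4g} ± {self.slope_se:.2g}, "
                f"r²={self.r_squared:.4f}, n={self.n_points})")


def initial_rate(timepoints: Sequence[tuple[float, float]]) -> InitialRateResult:
    """OLS slope of signal vs time over the initial linear phase.

    Duplicate times are collapsed to their mean signal first; at least 3
    distinct, strictly increasing times are required.
    """
    df = pd.DataFrame(timepoints, columns=["t", "y"]).groupby("t", as_index=False).mean()
    if len(df) < 3:
        raise ValueError("need >= 3 distinct time points")
    t, y = df.t.to_numpy(float), df.y.to_numpy(float)
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    fit = stats.linregress(t, y)
    return InitialRateResult(float(fit.slope), float(fit.intercept),
                             float(fit.rvalue) ** 2, len(df), float(fit.stderr))


def hm_fm_difference(hm: InitialRateResult, fm: InitialRateResult
                     ) -> tuple[float, float, bool]:
    """Central-site methylation rate as hm.slope - fm.slope.

    The hemimethylated substrate exposes the central upper-strand cytosine,
    the fully methylated one does not, so the slope difference isolates that
    single site from non-CpG background activity.  Returns (rate, propagated
    SE, negative_flag).
    """
    rate = hm.slope - fm.slope
    se = math.hypot(hm.slope_se, fm.slope_se)
    return rate, se, rate < 0


def predict_substrate_preference(
    sequence: str, rates: Mapping[str, float] | pd.Series
) -> tuple[float, pd.DataFrame]:
    """Mean relative rate over all CpG strand-sites of a substrate.

    Every CpG contributes one site per strand; the lower-strand site is
    looked up with the reverse-complemented context.  CpGs lacking the full
    -2..+3 context are skipped and counted.  Returns (mean, per-site table).
    """
    seq = sequence.upper()
    rows, skipped = [], 0
    for i in range(len(seq) - 1):
        if seq[i: i + 2] != "CG":
            continue
        if i - 2 < 0 or i + 4 > len(seq):
            skipped += 1
            continue
        ctx = seq[i - 2: i + 4]
        for strand, c in (("+", ctx), ("-", revcomp(ctx))):
            if c not in rates:
                raise KeyError(f"context {c} missing from rate table")
            rows.append((i, strand, c, float(rates[c])))
    if not rows:
        raise ValueError("no CpG site with full -2..+3 context")
    tab = pd.DataFrame(rows, columns=["position", "strand", "context", "rate"])
    tab.attrs["skipped_edge_sites"] = skipped
    return float(tab.rate.mean()), tab
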