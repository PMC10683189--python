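"""Chance-corrected agreement between common- and rare-variant gene rankings.

The convergence signature is Cohen's kappa computed on the 2x2 table of
top-k membership of LD-clumped genes under the two variant classes; the
modified signature is Gwet's AC1, which replaces the product-margin chance
correction by p_gamma = 2 pi (1 - pi) with pi the average of the two
positive-call margins and is less sensitive to the proportion of associated
genes.  Uncertainty comes from a gene-resampling bootstrap and, optionally,
from the posterior of a multinomial model for the table with Beta priors on
the margins and a conditionally uniform prior on the joint probability.

``ConvergenceAnalysis`` wraps the full pipeline (clump -> rank -> table ->
statistics) in a model object whose ``fit`` returns a results object with a
``summary()`` table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConcordanceTable:
    """2x2 gene counts: a both top-ranked, b common-only, c rare-only,
    d neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.n < 1:
            raise ValueError("table must contain at least one gene")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class BayesPrior:
    """Beta(u s, u (1-s)) prior on p_1., Beta(v t, v (1-t)) on p_.1, and a
    conditionally uniform prior on p_11 over its feasible interval."""

    s: float
    t: float
    u: float = 2.0
    v: float = 2.0

    def __post_init__(self):
        if not (0.0 < self.s < 1.0 and 0.0 < self.t < 1.0):
            raise ValueError("prior means s, t must lie in (0, 1)")
        if self.u <= 0 or self.v <= 0:
            raise ValueError("prior concentrations must be positive")


def clump(genes: pd.DataFrame) -> pd.DataFrame:
    """One gene per LD block: the gene minimizing P_common * P_rare
    (computed as the sum of logs), ties broken by lexicographic gene id.

    Adds a boolean ``clump_tie`` column flagging blocks where the winning
    product was tied.
    """
    df = genes.copy()
    required = {"gene_id", "block_id", "p_common", "p_rare"}
    if not required <= set(df.columns):
        raise ValueError(f"gene table must have columns {sorted(required)}")
    if df[["p_common", "p_rare"]].isna().any().any():
        raise ValueError("clump requires non-missing p_common and p_rare")
    df["_score"] = np.log(df["p_common"].to_numpy()) + np.log(
        df["p_rare"].to_numpy()
    )
    df = df.sort_values(["block_id", "_score", "gene_id"], kind="stable")
    best = df.groupby("block_id", sort=True).head(1).copy()
    mins = df.groupby("block_id")["_score"].transform("min")
    tie_blocks = (
        df[df["_score"] == mins].groupby("block_id").size() > 1
    )
    best["clump_tie"] = best["block_id"].map(tie_blocks).fillna(False).to_numpy()
    return best.drop(columns="_score").reset_index(drop=True)


def _topk_mask(p: np.ndarray, gene_ids: np.ndarray, k: int) -> tuple[np.ndarray, bool]:
    """Boolean top-k membership by ascending p, ties by gene id; returns
    (mask, boundary-tie flag)."""
    order = np.lexsort((gene_ids, p))
    mask = np.zeros(len(p), dtype=bool)
    mask[order[:k]] = True
    tie = bool(k < len(p) and p[order[k - 1]] == p[order[k]])
    return mask, tie


def build_table(clumped: pd.DataFrame, k: int) -> ConcordanceTable:
    """Concordance table of top-k membership under the two rankings."""
    n = len(clumped)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} clumped genes")
    if k < 1:
        raise ValueError("k must be >= 1")
    gid = clumped["gene_id"].to_numpy()
    top_c, tie_c = _topk_mask(clumped["p_common"].to_numpy(), gid, k)
    top_r, tie_r = _topk_mask(clumped["p_rare"].to_numpy(), gid, k)
    if tie_c or tie_r:
        warnings.warn("tie at the top-k boundary broken by gene id", stacklevel=2)
    a = int((top_c & top_r).sum())
    return ConcordanceTable(a=a, b=k - a, c=k - a, d=n - 2 * k + a)


def cohen_kappa(table: ConcordanceTable) -> tuple[float, dict[str, float]]:
    """CORAC: kappa = (p_a - p_e) / (1 - p_e) with the product-margin chance
    agreement p_e = p_beta + p_delta.  Returns (kappa, intermediates)."""
    a, b, c, d = table.as_tuple()
    n = table.n
    p_alpha = (a + d) / n
    p1dot = (a + b) / n
    pdot1 = (a + c) / n
    p_beta = p1dot * pdot1
    p_delta = (c + d) / n * (b + d) / n
    p_eps = p_beta + p_delta
    inter = {
        "p_alpha_hat": p_alpha,
        "p_beta_hat": p_beta,
        "p_delta_hat": p_delta,
        "p_epsilon_hat": p_eps,
        "p_1dot": p1dot,
        "p_dot1": pdot1,
    }
    if p_eps >= 1.0:
        raise ZeroDivisionError("kappa undefined: chance agreement equals 1")
    return (p_alpha - p_eps) / (1.0 - p_eps), inter


def gwet_ac1(table: ConcordanceTable) -> float:
    """CORAC_modified: AC1 = (p_a - p_gamma)/(1 - p_gamma) with
    p_gamma = 2 pi (1 - pi), pi = (p_1. + p_.1)/2."""
    a, b, c, d = table.as_tuple()
    n = table.n
    p_alpha = (a + d) / n
    pi = ((a + b) / n + (a + c) / n) / 2.0
    p_gamma = 2.0 * pi * (1.0 - pi)
    if p_gamma >= 1.0:
        raise ZeroDivisionError("AC1 undefined: p_gamma equals 1")
    return (p_alpha - p_gamma) / (1.0 - p_gamma)


def odds_ratio(table: ConcordanceTable) -> tuple[float, bool]:
    """(a d)/(b c), with the Haldane–Anscombe +0.5 continuity correction to
    every cell when any cell is zero; the flag reports the correction."""
    a, b, c, d = (float(x) for x in table.as_tuple())
    corrected = min(a, b, c, d) == 0.0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c), corrected


@dataclass
class UncertaintySummary:
    point: float
    se: float
    ci_low: float
    ci_high: float
    n_dropped: int = 0


def bootstrap_agreement(
    clumped: pd.DataFrame,
    k: int,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, UncertaintySummary]:
    """Gene-resampling bootstrap of kappa and AC1.

    The n clumped genes are resampled with replacement; the two rankings and
    the top-k table are rebuilt within each replicate (preserving the
    coupling between the rankings).  Returns percentile 95% intervals and
    standard errors; replicates with an undefined statistic are dropped and
    counted (a warning fires above 10%).
    """
    rng = np.random.default_rng(seed)
    n = len(clumped)
    if k > n:
        raise ValueError("k exceeds the number of clumped genes")
    # dense, tie-broken rank keys (one pass; resamples reuse them)
    gid = clumped["gene_id"].to_numpy()
    rank_c = np.empty(n, dtype=np.int64)
    rank_c[np.lexsort((gid, clumped["p_common"].to_numpy()))] = np.arange(n)
    rank_r = np.empty(n, dtype=np.int64)
    rank_r[np.lexsort((gid, clumped["p_rare"].to_numpy()))] = np.arange(n)

    kappas = np.full(n_boot, np.nan)
    ac1s = np.full(n_boot, np.nan)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        rc = rank_c[idx]
        rr = rank_r[idx]
        top_c = np.zeros(n, dtype=bool)
        top_c[np.argsort(rc, kind="stable")[:k]] = True
        top_r = np.zeros(n, dtype=bool)
        top_r[np.argsort(rr, kind="stable")[:k]] = True
        a = int((top_c & top_r).sum())
        tab = ConcordanceTable(a=a, b=k - a, c=k - a, d=n - 2 * k + a)
        try:
            kappas[i], _ = cohen_kappa(tab)
            ac1s[i] = gwet_ac1(tab)
        except ZeroDivisionError:
            continue

    out = {}
    for name, vals in (("kappa", kappas), ("ac1", ac1s)):
        ok = vals[np.isfinite(vals)]
        dropped = n_boot - len(ok)
        if dropped > 0.1 * n_boot:
            warnings.warn(
                f"{dropped}/{n_boot} bootstrap replicates undefined for {name}",
                stacklevel=2,
            )
        lo, hi = np.percentile(ok, [2.5, 97.5])
        out[name] = UncertaintySummary(
            point=float(np.mean(ok)),
            se=float(np.std(ok, ddof=1)),
            ci_low=float(lo),
            ci_high=float(hi),
            n_dropped=dropped,
        )
    return out


def bootstrap_table(
    table: ConcordanceTable, n_boot: int = 1000, seed: int = 0
) -> dict[str, UncertaintySummary]:
    """Multinomial bootstrap for a raw concordance table (no rankings):
    resamples the n gene statuses with replacement."""
    rng = np.random.default_rng(seed)
    n = table.n
    probs = np.array(table.as_tuple(), dtype=float) / n
    draws = rng.multinomial(n, probs, size=n_boot)
    kappas = np.full(n_boot, np.nan)
    ac1s = np.full(n_boot, np.nan)
    for i, (a, b, c, d) in enumerate(draws):
        tab = ConcordanceTable(a=int(a), b=int(b), c=int(c), d=int(d))
        try:
            kappas[i], _ = cohen_kappa(tab)
            ac1s[i] = gwet_ac1(tab)
        except ZeroDivisionError:
            continue
    out = {}
    for name, vals in (("kappa", kappas), ("ac1", ac1s)):
        ok = vals[np.isfinite(vals)]
        dropped = n_boot - len(ok)
        if dropped > 0.1 * n_boot:
            warnings.warn(
                f"{dropped}/{n_boot} bootstrap replicates undefined for {name}",
                stacklevel=2,
            )
        lo, hi = np.percentile(ok, [2.5, 97.5])
        out[name] = UncertaintySummary(
            point=float(np.mean(ok)),
            se=float(np.std(ok, ddof=1)),
            ci_low=float(lo),
            ci_high=float(hi),
            n_dropped=dropped,
        )
    return out


def default_prior(table: ConcordanceTable, k: int | None = None) -> BayesPrior:
    """Weakly informative prior centred on the empirical margins."""
    n = table.n
    s = (table.a + table.b) / n
    t = (table.a + table.c) / n
    eps = 1.0 / (2.0 * n)
    return BayesPrior(
        s=float(np.clip(s, eps, 1 - eps)),
        t=float(np.clip(t, eps, 1 - eps)),
        u=2.0,
        v=2.0,
    )


def bayes_posterior(
    table: ConcordanceTable | tuple[int, int, int, int],
    prior: BayesPrior | None = None,
    grid_size: int = 101,
) -> dict[str, object]:
    """Grid posterior over (p_1., p_.1, p_11) under the multinomial
    likelihood p_11^a (p_1.-p_11)^b (p_.1-p_11)^c (1-p_1.-p_.1+p_11)^d.

    The last factor uses the multinomial cell 1 - p_1. - p_.1 + p_11 so the
    four cell probabilities sum to one.  Posterior mass outside the feasible
    region p_11 in [max(0, p_1.+p_.1-1), min(p_1., p_.1)] is exactly zero.
    ``table`` may be a raw (a, b, c, d) tuple, allowing the zero-data case
    (all counts 0), whose posterior is the prior itself.  Returns posterior
    means and equal-tailed 95% credible intervals for p_11, the p_1. margin,
    and kappa as a function of the three parameters.
    """
    if isinstance(table, ConcordanceTable):
        a, b, c, d = table.as_tuple()
    else:
        a, b, c, d = (int(x) for x in table)
        if min(a, b, c, d) < 0:
            raise ValueError("counts must be non-negative")
    if prior is None:
        if a + b + c + d == 0:
            raise ValueError("zero-data posterior needs an explicit prior")
        prior = default_prior(ConcordanceTable(a, b, c, d))

    g = grid_size
    p1 = ((np.arange(g) + 0.5) / g)[:, None, None]
    q1 = ((np.arange(g) + 0.5) / g)[None, :, None]
    p11 = ((np.arange(g) + 0.5) / g)[None, None, :]

    lo = np.maximum(0.0, p1 + q1 - 1.0)
    hi = np.minimum(p1, q1)
    feasible = np.broadcast_to((p11 > lo) & (p11 < hi), (g, g, g)).copy()

    # If the feasible p_11 interval is narrower than one grid cell no midpoint
    # falls strictly inside it; rescue that (p_1., p_.1) slice by marking the
    # midpoint nearest the interval centre as feasible, otherwise its prior
    # mass would be silently dropped and the margin posteriors tilted.
    n_feas = feasible.sum(axis=2)
    if np.any(n_feas == 0):
        centre = 0.5 * (lo + hi)[:, :, 0]
        j = np.clip(np.round(centre * g - 0.5).astype(int), 0, g - 1)
        ii, qq = np.nonzero(n_feas == 0)
        feasible[ii, qq, j[ii, qq]] = True
        n_feas = feasible.sum(axis=2)

    with np.errstate(divide="ignore", invalid="ignore"):
        # clamp cells at a tiny positive value: a zero count then contributes
        # exactly 0 to the log-likelihood while a positive count drives the
        # weight of an out-of-range midpoint to zero
        tiny = 1e-300
        cell10 = np.maximum(p1 - p11, tiny)
        cell01 = np.maximum(q1 - p11, tiny)
        cell00 = np.maximum(1.0 - p1 - q1 + p11, tiny)
        loglik = (
            a * np.log(p11)
            + b * np.log(cell10)
            + c * np.log(cell01)
            + d * np.log(cell00)
        )
        from scipy import stats as _st

        logprior = (
            _st.beta.logpdf(p1, prior.u * prior.s, prior.u * (1 - prior.s))
            + _st.beta.logpdf(q1, prior.v * prior.t, prior.v * (1 - prior.t))
            # conditional (discrete-)uniform p_11: weight 1/n_feasible per slice
            - np.log(n_feas)[:, :, None]
        )
        logpost = np.where(feasible, loglik + logprior, -np.inf)
    mx = logpost.max()
    if not np.isfinite(mx):
        raise FloatingPointError("posterior has no finite mass on the grid")
    w = np.exp(logpost - mx)
    total = w.sum()
    w = w / total

    kappa_grid = _kappa_of_probs(p1, q1, p11)
    out = {}
    for name, vals in (
        ("p11", np.broadcast_to(p11, w.shape)),
        ("p1dot", np.broadcast_to(p1, w.shape)),
        ("kappa", kappa_grid),
    ):
        flat_w = w.ravel()
        flat_v = np.broadcast_to(vals, w.shape).ravel()
        mean = float(flat_v @ flat_w)
        order = np.argsort(flat_v)
        cum = np.cumsum(flat_w[order])
        lo_q = flat_v[order][np.searchsorted(cum, 0.025)]
        hi_q = flat_v[order][np.searchsorted(cum, 0.975)]
        out[name] = UncertaintySummary(
            point=mean, se=float(np.sqrt(flat_w @ (flat_v - mean) ** 2)),
            ci_low=float(lo_q), ci_high=float(hi_q),
        )
    out["prior"] = prior
    return out


def _kappa_of_probs(p1, q1, p11):
    p_alpha = 1.0 - p1 - q1 + 2.0 * p11
    p_eps = p1 * q1 + (1.0 - p1) * (1.0 - q1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(p_eps < 1.0, (p_alpha - p_eps) / (1.0 - p_eps), np.nan)


@dataclass
class ConvergenceResults:
    """Fitted convergence signature with uncertainty."""

    table: ConcordanceTable
    kappa: float
    ac1: float
    odds_ratio: float
    or_corrected: bool
    intermediates: dict[str, float]
    k: int
    n_clumped: int
    n_clump_ties: int
    bootstrap: dict[str, UncertaintySummary] | None = None
    posterior: dict[str, object] | None = None

    def summary(self) -> str:
        lines = [
            "Convergence of common- and rare-variant gene signals",
            "=" * 56,
            f"clumped genes (LD blocks): {self.n_clumped:>6d}   top-k: {self.k}",
            f"table (a, b, c, d): {self.table.as_tuple()}",
            f"kappa (CORAC):      {self.kappa: .4f}",
            f"AC1 (modified):     {self.ac1: .4f}",
            f"odds ratio:         {self.odds_ratio: .4f}"
            + ("  [+0.5 correction]" if self.or_corrected else ""),
        ]
        if self.bootstrap:
            bk = self.bootstrap["kappa"]
            lines.append(
                f"bootstrap kappa SE: {bk.se: .4f}   "
                f"95% CI: [{bk.ci_low: .4f}, {bk.ci_high: .4f}]"
            )
        if self.posterior:
            pk = self.posterior["kappa"]
            lines.append(
                f"posterior kappa:    {pk.point: .4f}   "
                f"95% CrI: [{pk.ci_low: .4f}, {pk.ci_high: .4f}]"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "k": self.k,
            "n": self.n_clumped,
            "table": dict(zip("abcd", self.table.as_tuple())),
            "kappa": self.kappa,
            "ac1": self.ac1,
            "odds_ratio": self.odds_ratio,
            "odds_ratio_corrected": self.or_corrected,
            "n_clump_ties": self.n_clump_ties,
            **self.intermediates,
        }
        if self.bootstrap:
            d["bootstrap"] = {
                name: vars(s) for name, s in self.bootstrap.items()
            }
        if self.posterior:
            d["posterior"] = {
                name: vars(s)
                for name, s in self.posterior.items()
                if isinstance(s, UncertaintySummary)
            }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


class ConvergenceAnalysis:
    """Model object for the convergence analysis of a gene association table.

    Parameters
    ----------
    genes : DataFrame with columns gene_id, block_id, p_common, p_rare.
    k : number of top-ranked genes called significant under each ranking.
    apply_clump : reduce to one gene per LD block first (the default).
    """

    def __init__(self, genes: pd.DataFrame, k: int = 100, apply_clump: bool = True):
        self.genes = genes
        self.k = k
        self.apply_clump = apply_clump

    @classmethod
    def from_dataframe(cls, genes: pd.DataFrame, **kw) -> "ConvergenceAnalysis":
        return cls(genes, **kw)

    @classmethod
    def from_tsv(cls, path, **kw) -> "ConvergenceAnalysis":
        return cls(pd.read_csv(path, sep="\t"), **kw)

    def fit(
        self,
        n_boot: int = 1000,
        bayes: bool = False,
        prior: BayesPrior | None = None,
        seed: int = 0,
    ) -> ConvergenceResults:
        clumped = clump(self.genes) if self.apply_clump else self.genes.copy()
        if "clump_tie" not in clumped:
            clumped["clump_tie"] = False
        table = build_table(clumped, self.k)
        kappa, inter = cohen_kappa(table)
        ac1 = gwet_ac1(table)
        pi_hat = (inter["p_1dot"] + inter["p_dot1"]) / 2.0
        inter["pi_hat"] = pi_hat
        inter["p_gamma_hat"] = 2.0 * pi_hat * (1.0 - pi_hat)
        orat, corrected = odds_ratio(table)
        boot = (
            bootstrap_agreement(clumped, self.k, n_boot=n_boot, seed=seed)
            if n_boot
            else None
        )
        post = bayes_posterior(table, prior=prior) if bayes else None
        return ConvergenceResults(
            table=table,
            kappa=kappa,
            ac1=ac1,
            odds_ratio=orat,
            or_corrected=corrected,
            intermediates=inter,
            k=self.k,
            n_clumped=len(clumped),
            n_clump_ties=int(clumped["clump_tie"].sum()),
            bootstrap=boot,
            posterior=post,
        )
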