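"""Conditional (stratified) FDR between paired gene-level p-values.

For each gene with rare-variant p-value p_R and common-variant p-value p_C,
the conditional FDR of the rare signal given the common one is

    FDR(p_R | p_C) = pi0(p_C) * p_R / F(p_R | p_C)

where pi0 is the proportion of rare-null genes among those whose common
p-value is at least as small as the conditioning threshold, and F is the
empirical conditional CDF on that subset.  The mirrored direction swaps the
roles of the two columns.  The stratified Q-Q summary evaluates observed
versus expected -log10 quantiles of the target p-values within nested
conditioning strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

MIN_STRATUM = 20
DEFAULT_THRESHOLDS = (1.0, 0.1, 0.01, 0.001)

Direction = str  # "rare-given-common" or "common-given-rare"


def _split(pairs: pd.DataFrame, direction: Direction) -> tuple[np.ndarray, np.ndarray]:
    if direction == "rare-given-common":
        return pairs["p_rare"].to_numpy(float), pairs["p_common"].to_numpy(float)
    if direction == "common-given-rare":
        return pairs["p_common"].to_numpy(float), pairs["p_rare"].to_numpy(float)
    raise ValueError(f"unknown direction {direction!r}")


def storey_pi0(pvals: np.ndarray, lam: float = 0.5) -> float:
    """Storey estimator of the null proportion, clamped to [0, 1]."""
    m = len(pvals)
    if m == 0:
        raise ValueError("cannot estimate pi0 from an empty set")
    pi0 = (pvals > lam).sum() / ((1.0 - lam) * m)
    return float(np.clip(pi0, 0.0, 1.0))


@dataclass
class StratifiedFdrResult:
    """Per-gene conditional FDR table for one conditioning threshold."""

    table: pd.DataFrame
    threshold: float
    direction: Direction
    pi0_hat: float
    stratum_size: int


def conditional_fdr(
    pairs: pd.DataFrame,
    threshold: float = 1.0,
    direction: Direction = "rare-given-common",
    lam: float = 0.5,
    pi0: float | None = None,
) -> StratifiedFdrResult:
    """Conditional FDR for every gene in the conditioning stratum.

    ``pairs`` needs columns gene_id (optional), p_common, p_rare.  The
    stratum is the set of genes whose conditioning p-value is <= threshold;
    the empirical conditional CDF is floored at 1/|stratum| and the FDR is
    clamped at 1.  ``pi0`` overrides the Storey estimate (useful for worked
    examples and sensitivity checks).
    """
    target, cond = _split(pairs, direction)
    in_s = cond <= threshold
    m = int(in_s.sum())
    if m == 0:
        raise ValueError(f"no genes with conditioning p <= {threshold}")
    if m < MIN_STRATUM:
        warnings.warn(
            f"conditioning stratum has only {m} genes (< {MIN_STRATUM})",
            stacklevel=2,
        )
    t_sub = target[in_s]
    pi0_hat = storey_pi0(t_sub, lam) if pi0 is None else float(pi0)
    # empirical conditional CDF at each gene's own target p, floored
    f_hat = np.maximum(
        np.searchsorted(np.sort(t_sub), t_sub, side="right") / m, 1.0 / m
    )
    fdr = np.clip(pi0_hat * t_sub / f_hat, 0.0, 1.0)

    out = pd.DataFrame(
        {
            "p_target": t_sub,
            "p_conditioning": cond[in_s],
            "F_hat": f_hat,
            "fdr": fdr,
        }
    )
    if "gene_id" in pairs.columns:
        out.insert(0, "gene_id", pairs.loc[in_s, "gene_id"].to_numpy())
    out["pi0_hat"] = pi0_hat
    out["threshold"] = threshold
    out["direction"] = direction
    return StratifiedFdrResult(
        table=out,
        threshold=threshold,
        direction=direction,
        pi0_hat=pi0_hat,
        stratum_size=m,
    )


def pointwise_fdr(
    pairs: pd.DataFrame,
    direction: Direction = "rare-given-common",
    lam: float = 0.5,
) -> pd.DataFrame:
    """Eq.-style pointwise surface: each gene's FDR evaluated with its own
    conditioning p-value as the threshold."""
    target, cond = _split(pairs, direction)
    order = np.argsort(cond, kind="stable")
    fdr = np.empty(len(target))
    pi0s = np.empty(len(target))
    # genes sorted by conditioning p: stratum of gene i is order[: i+1]
    sorted_targets: list[float] = []
    import bisect

    for rank, idx in enumerate(order):
        bisect.insort(sorted_targets, target[idx])
        m = rank + 1
        n_gt = m - bisect.bisect_right(sorted_targets, lam)
        pi0 = np.clip(n_gt / ((1.0 - lam) * m), 0.0, 1.0)
        f_hat = max(
            bisect.bisect_right(sorted_targets, target[idx]) / m, 1.0 / m
        )
        fdr[idx] = min(pi0 * target[idx] / f_hat, 1.0)
        pi0s[idx] = pi0
    out = pairs.copy()
    out["fdr"] = fdr
    out["pi0_hat"] = pi0s
    out["direction"] = direction
    return out


def stratified_qq(
    pairs: pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
    direction: Direction = "rare-given-common",
    quantiles: np.ndarray | None = None,
) -> pd.DataFrame:
    """Observed vs expected -log10 quantiles of the target p-values within
    nested conditioning strata.

    Thresholds must be descending so each stratum is a subset of the
    previous.  Strata smaller than the minimum size are dropped with a
    warning.  Returns a long table (threshold, prob, expected_neglog10,
    observed_neglog10, stratum_size).
    """
    thresholds = list(thresholds)
    if sorted(thresholds, reverse=True) != thresholds:
        raise ValueError("thresholds must be in descending order")
    if quantiles is None:
        quantiles = np.linspace(0.005, 0.995, 199)
    target, cond = _split(pairs, direction)

    frames = []
    for th in thresholds:
        sub = target[cond <= th]
        if len(sub) < MIN_STRATUM:
            warnings.warn(
                f"stratum p <= {th} has {len(sub)} genes; dropped", stacklevel=2
            )
            continue
        obs = np.quantile(sub, quantiles)
        frames.append(
            pd.DataFrame(
                {
                    "threshold": th,
                    "prob": quantiles,
                    "expected_neglog10": -np.log10(quantiles),
                    "observed_neglog10": -np.log10(np.maximum(obs, 1e-300)),
                    "stratum_size": len(sub),
                }
            )
        )
    if not frames:
        raise ValueError("no stratum met the minimum size")
    return pd.concat(frames, ignore_index=True)
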