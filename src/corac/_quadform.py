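"""P-values for quadratic forms in Gaussian variables.

Used by the variance-component rare-variant tests: the null distribution of
Q = r' Z Z' r is a positively weighted sum of 1-df chi-squares, approximated
by moment matching to a (noncentral) chi-square (Liu-type).  The optimal
rho-combined test additionally needs quantiles of such distributions and a
one-dimensional integration over the shared burden component (Lee-style).
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats


def _chi2_sf(x, df):
    """Central chi-square survival function via the regularized upper gamma
    (identical to stats.chi2.sf, without the distribution-machinery overhead)."""
    return special.gammaincc(df / 2.0, np.maximum(x, 0.0) / 2.0)


def _chi2_isf(p, df):
    return 2.0 * special.gammainccinv(df / 2.0, p)


def _liu_params(lambdas: np.ndarray) -> tuple[float, float, float, float]:
    """(mu_Q, sigma_Q, df l, noncentrality delta) of the matched chi-square."""
    lam = np.asarray(lambdas, dtype=float)
    c1 = lam.sum()
    c2 = (lam**2).sum()
    c3 = (lam**3).sum()
    c4 = (lam**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2.0 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
    mu_q = c1
    sigma_q = np.sqrt(2.0 * c2)
    return mu_q, sigma_q, df, delta


def liu_sf(q: float, lambdas: np.ndarray) -> float:
    """P(sum_k lambda_k chi2_1 > q), Liu moment-matching approximation."""
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > 1e-12]
    if lam.size == 0:
        return 1.0
    mu_q, sigma_q, df, delta = _liu_params(lam)
    mu_x = df + delta
    sigma_x = np.sqrt(2.0 * (df + 2.0 * delta))
    x = (q - mu_q) / sigma_q * sigma_x + mu_x
    if delta > 0:
        p = stats.ncx2.sf(x, df, delta)
    else:
        p = _chi2_sf(x, df)
    return float(min(max(p, 0.0), 1.0))


def liu_quantile(p_upper: float, lambdas: np.ndarray) -> float:
    """Quantile q with P(sum lambda chi2 > q) = p_upper (Liu approximation)."""
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > 1e-12]
    if lam.size == 0:
        return 0.0
    mu_q, sigma_q, df, delta = _liu_params(lam)
    mu_x = df + delta
    sigma_x = np.sqrt(2.0 * (df + 2.0 * delta))
    if delta > 0:
        x = stats.ncx2.isf(p_upper, df, delta)
    else:
        x = _chi2_isf(p_upper, df)
    return float((x - mu_x) / sigma_x * sigma_q + mu_q)


def _rho_sqrt(rho: float, m: int) -> tuple[float, float]:
    """R_rho^(1/2) = a I + b 11' for R_rho = (1-rho) I + rho 11'."""
    a = np.sqrt(1.0 - rho)
    b = (np.sqrt(1.0 - rho + m * rho) - a) / m
    return a, b


def rho_lambdas(kernel: np.ndarray, rho: float) -> np.ndarray:
    """Eigenvalues of R_rho^(1/2) K R_rho^(1/2) for the combined statistic."""
    m = kernel.shape[0]
    a, b = _rho_sqrt(rho, m)
    rowsum = kernel.sum(axis=0)
    total = kernel.sum()
    k2 = (
        a**2 * kernel
        + a * b * (rowsum[:, None] + rowsum[None, :])
        + b**2 * total
    )
    lam = np.linalg.eigvalsh(k2)
    return lam[lam > 1e-10 * max(lam.max(), 1.0)]


def skato_omnibus_p(
    kernel: np.ndarray,
    scores: np.ndarray,
    rho_grid: np.ndarray,
    n_quad: int = 512,
) -> tuple[float, np.ndarray, bool]:
    """Min-p combined burden/variance-component p-value (Lee-style).

    ``kernel`` is Z'Z of the centered weighted genotypes scaled by the null
    residual variance; ``scores`` is Z'r on the same scale, so that
    Q_rho = (1-rho) |scores|^2 + rho (sum scores)^2 has the weighted
    chi-square null.  Returns (p_value, per-rho p-values, bonferroni_flag);
    when the integration degenerates the Bonferroni bound over the grid is
    returned with the flag set.
    """
    m = kernel.shape[0]
    rho_grid = np.asarray(rho_grid, dtype=float)
    q_skat = float(scores @ scores)
    q_burden = float(scores.sum() ** 2)

    if m == 1:
        # every rho reduces to the same single chi-square statistic
        p = liu_sf(q_skat, rho_lambdas(kernel, 0.0))
        return p, np.full(len(rho_grid), p), False

    p_each = np.empty(len(rho_grid))
    for i, rho in enumerate(rho_grid):
        q_rho = (1.0 - rho) * q_skat + rho * q_burden
        p_each[i] = liu_sf(q_rho, rho_lambdas(kernel, rho))
    p_min = float(p_each.min())

    if len(rho_grid) == 1:
        return p_min, p_each, False

    # Lee decomposition: Q_rho | eta ~ (1-rho)(sum lambda_k chi2 + zeta) + tau(rho) eta
    rho_c = np.minimum(rho_grid, 0.999)
    ksum = kernel.sum(axis=0)
    ktot = float(kernel.sum())  # = m^2 zbar'zbar
    if ktot <= 1e-12:
        return p_min, p_each, False
    zbar_sq = ktot / m**2  # zbar' zbar
    cof = ksum / m / zbar_sq  # (zbar' z_j) / (zbar' zbar)
    # K1 = Z'(I - M)Z with M the projection onto zbar
    k1 = kernel - np.outer(ksum, ksum) / ktot
    lam1 = np.linalg.eigvalsh(k1)
    lam1 = lam1[lam1 > 1e-10 * max(abs(lam1).max(), 1.0)]
    if lam1.size == 0:
        return p_min, p_each, False
    mu_kappa = lam1.sum()
    var_kappa = 2.0 * (lam1**2).sum()
    # variance of the cross term zeta: 4 tr[(MZ)'(MZ) (I-M)-part kernel]
    k_item1 = np.outer(cof, cof) * zbar_sq  # (MZ)'(MZ) = cof cof' * zbar'zbar
    var_zeta = 4.0 * float((k_item1 * k1).sum())
    var_q = var_kappa + var_zeta
    df = (lam1**2).sum() ** 2 / (lam1**4).sum()
    tau = m**2 * rho_c * zbar_sq + (cof**2).sum() * zbar_sq * (1.0 - rho_c)

    # per-rho quantiles of the null at level p_min
    q_min = np.array(
        [liu_quantile(p_min, rho_lambdas(kernel, rho)) for rho in rho_c]
    )

    # integrate over eta ~ chi2_1 via eta = t^2, t ~ half-normal
    t = np.linspace(0.0, 6.5, n_quad)
    eta = t**2
    num = q_min[:, None] - tau[:, None] * eta[None, :]
    den = 1.0 - rho_c[:, None]
    bound = (num / den).min(axis=0)
    # moment-adjusted survival of kappa + zeta at the bound
    x = (bound - mu_kappa) * np.sqrt(2.0 * df) / np.sqrt(var_q) + df
    cdf = special.gammainc(df / 2.0, np.maximum(x, 0.0) / 2.0)
    integrand = cdf * 2.0 * np.exp(-0.5 * t**2) / np.sqrt(2.0 * np.pi)
    prob_all_below = np.trapezoid(integrand, t)
    p_val = 1.0 - prob_all_below

    if not np.isfinite(p_val) or p_val <= 0.0 or p_val > 1.0:
        return float(min(1.0, p_min * len(rho_grid))), p_each, True
    # the omnibus p can never beat the best single-rho p
    return float(max(p_val, p_min)), p_each, False
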