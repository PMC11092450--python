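"""Dirichlet-multinomial differential transcript usage (DTU) testing.

For a gene with K isoforms, per-cell transcript counts are modeled as

    X_c | pi_c ~ Multinomial(n_c, pi_c),      pi_c ~ Dirichlet(alpha),

so marginally X_c is Dirichlet-multinomial.  The population-average usage is
pi_bar_k = alpha_k / sum(alpha) and phi = 1 / (1 + sum(alpha)) is a
mean-invariant over-dispersion: small phi means cells co-express isoforms at
similar proportions, large phi means each cell favors one isoform.

Differential usage between two cell populations A and B is tested with
likelihood-ratio tests.  At the gene level, H0 shares pi_bar across groups
while keeping group-specific phi (alpha_g = pi_bar * (1/phi_g - 1)), giving
K-1 degrees of freedom.  At the transcript level, H0 equates only component
k of pi_bar, leaving the remaining composition free per group (1 df; for
K = 2 this coincides with the gene test).  Rare isoforms (pooled count at
most 5% of the gene's pooled total) are aggregated into one column first,
and only genes with more than 20 reads are tested.  Isoform switching is
flagged when the dominant non-rare isoform differs between populations, with
effect size the absolute sum of the two dominant-isoform usage differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, expit, gammaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

RARE_FRACTION = 0.05
GENE_READ_FLOOR = 20  # strictly more than this many reads to test
ALPHA_MIN = 1e-8
ALPHA_MAX = 1e8
GRAD_TOL = 1e-6
MAX_ITER = 500
RARE_COLUMN = "rare"


class DTUError(ValueError):
    pass


@dataclass
class GeneUsageData:
    """Counts of one gene after rare-isoform aggregation."""

    X: np.ndarray  # cells x K
    group_labels: np.ndarray  # str array, "A"/"B"
    columns: list[str]
    rare_index: int | None = None
    excluded: bool = False
    exclusion_reason: str = ""

    @property
    def n(self) -> np.ndarray:
        return self.X.sum(axis=1)

    @property
    def K(self) -> int:
        return self.X.shape[1]

    def group(self, label: str) -> np.ndarray:
        return self.X[self.group_labels == label]


@dataclass
class DMFit:
    alpha: np.ndarray
    loglik: float
    converged: bool = True
    boundary: bool = False

    @property
    def pi_bar(self) -> np.ndarray:
        return self.alpha / self.alpha.sum()

    @property
    def phi(self) -> float:
        return 1.0 / (1.0 + self.alpha.sum())


@dataclass
class DTUResult:
    gene_id: str
    p_gene: float
    padj_gene: float = np.nan
    transcript_stats: pd.DataFrame | None = None
    switching: bool = False
    effect_size: float = np.nan
    dominant_A: str = ""
    dominant_B: str = ""
    fit_A: DMFit | None = None
    fit_B: DMFit | None = None
    statistic: float = np.nan
    notes: list[str] = field(default_factory=list)


def aggregate_rare(
    X: np.ndarray,
    group_labels: np.ndarray,
    columns: list[str] | None = None,
    rare_fraction: float = RARE_FRACTION,
    gene_read_floor: int = GENE_READ_FLOOR,
) -> GeneUsageData:
    """Merge rare isoform columns and apply the gene read floor.

    Columns whose pooled count (over both populations) is at most
    ``rare_fraction`` of the gene's pooled total are summed into one "rare"
    column.  Genes with pooled total <= ``gene_read_floor`` reads, or with
    fewer than two columns after aggregation, are flagged excluded.
    """
    X = np.asarray(X)
    if np.any(X < 0) or not np.issubdtype(X.dtype, np.number):
        raise DTUError("counts must be non-negative numbers")
    group_labels = np.asarray(group_labels)
    columns = list(columns) if columns is not None else [
        f"iso{i + 1}" for i in range(X.shape[1])
    ]
    total = X.sum()
    pooled = X.sum(axis=0)
    rare = pooled <= rare_fraction * total
    if rare.any():
        keep = ~rare
        newX = np.column_stack([X[:, keep], X[:, rare].sum(axis=1)])
        new_cols = [c for c, k in zip(columns, keep) if k] + [RARE_COLUMN]
        rare_index: int | None = newX.shape[1] - 1
    else:
        newX, new_cols, rare_index = X, columns, None
    data = GeneUsageData(newX, group_labels, new_cols, rare_index)
    if total <= gene_read_floor:
        data.excluded, data.exclusion_reason = True, "gene_read_floor"
    elif data.K < 2:
        data.excluded, data.exclusion_reason = True, "single_isoform"
    return data


def dm_loglik_grad(alpha: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray]:
    """Dirichlet-multinomial log-likelihood and its gradient in alpha."""
    n = X.sum(axis=1)
    A = alpha.sum()
    ll = float(
        np.sum(gammaln(A) - gammaln(n + A))
        + np.sum(gammaln(X + alpha) - gammaln(alpha))
    )
    g_common = np.sum(digamma(A) - digamma(n + A))
    grad = g_common + np.sum(digamma(X + alpha) - digamma(alpha), axis=0)
    return ll, grad


def dm_loglik(alpha: np.ndarray, X: np.ndarray) -> float:
    return dm_loglik_grad(np.asarray(alpha, dtype=float), X)[0]


def _moment_init(X: np.ndarray) -> np.ndarray:
    pooled = X.sum(axis=0).astype(float)
    p = (pooled + 0.5) / (pooled.sum() + 0.5 * len(pooled))
    # crude scale from the mean squared deviation of cell proportions
    n = X.sum(axis=1)
    expr = n > 0
    if expr.sum() >= 2:
        props = X[expr] / n[expr, None]
        v = props.var(axis=0).mean()
        v0 = (p * (1 - p)).mean()
        rho = min(max(v / max(v0, 1e-12), 1e-3), 0.999)
        A0 = max((1 - rho) / rho, 0.1)
    else:
        A0 = 10.0
    return p * A0


def fit_dm(X: np.ndarray, init: np.ndarray | None = None) -> DMFit:
    """Maximum-likelihood Dirichlet-multinomial fit.

    Optimizes in log-alpha (quasi-Newton, analytic gradient); concentrations
    are box-bounded away from zero, and a fit pinned at the lower bound is
    flagged ``boundary``.  The likelihood is very flat toward the
    multinomial limit (sum(alpha) -> infinity), where a single line search
    can overshoot and stall, so the default start is a small multi-start
    around the moment estimate and the best optimum is kept.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise DTUError("need a cells x K matrix with K >= 2")
    if X.sum() == 0:
        raise DTUError("degenerate all-zero counts")
    if int(np.sum(X.sum(axis=1) > 0)) < 2:
        raise DTUError("need at least 2 expressing cells")
    if init is not None:
        starts = [np.clip(init, 1e-4, 1e4)]
    else:
        m = _moment_init(X)
        starts = [np.clip(m * s, 1e-4, 1e4) for s in (1.0, 0.3, 3.0)]

    def neg(theta: np.ndarray) -> tuple[float, np.ndarray]:
        a = np.exp(theta)
        ll, g = dm_loglik_grad(a, X)
        return -ll, -g * a

    best = None
    for alpha0 in starts:
        res = minimize(
            neg,
            np.log(alpha0),
            jac=True,
            method="L-BFGS-B",
            bounds=[(np.log(ALPHA_MIN), np.log(ALPHA_MAX))] * X.shape[1],
            options={"maxiter": MAX_ITER, "gtol": GRAD_TOL, "ftol": 1e-12},
        )
        if best is None or -res.fun > -best.fun:
            best = res
    alpha = np.exp(best.x)
    boundary = bool(np.any(alpha <= ALPHA_MIN * 1.01))
    return DMFit(alpha=alpha, loglik=float(-best.fun), converged=bool(best.success),
                 boundary=boundary)


def _softmax(u: np.ndarray) -> np.ndarray:
    m = np.exp(u - u.max())
    return m / m.sum()


def _h0_starts(
    fit_A: DMFit, fit_B: DMFit, pooled: DMFit
) -> list[tuple[np.ndarray, float, float]]:
    """Candidate (pi_bar, r_A, r_B) starting points for the constrained fit."""
    def norm(p: np.ndarray) -> np.ndarray:
        p = np.clip(p, 1e-6, None)
        return p / p.sum()

    rA, rB, rp = fit_A.alpha.sum(), fit_B.alpha.sum(), pooled.alpha.sum()
    avg = (fit_A.pi_bar + fit_B.pi_bar) / 2
    return [
        (norm(pooled.pi_bar), rA, rB),
        (norm(avg), rA, rB),
        (norm(pooled.pi_bar), rp, rp),
        (norm(fit_A.pi_bar), rA, rB),
        (norm(fit_B.pi_bar), rA, rB),
    ]


def _fit_h0_gene_once(XA: np.ndarray, XB: np.ndarray,
                      pi0: np.ndarray, rA0: float, rB0: float) -> float:
    """Maximize the shared-pi_bar, group-specific-phi likelihood from one
    start; returns the constrained log-likelihood."""
    K = XA.shape[1]

    def neg(theta: np.ndarray) -> tuple[float, np.ndarray]:
        z = theta[: K - 1]
        rA, rB = np.exp(theta[K - 1]), np.exp(theta[K])
        pi = _softmax(np.append(z, 0.0))
        llA, gA = dm_loglik_grad(np.clip(pi * rA, ALPHA_MIN, None), XA)
        llB, gB = dm_loglik_grad(np.clip(pi * rB, ALPHA_MIN, None), XB)
        grad = np.empty(K + 1)
        # d/dz_j: sum_g pi_j * r_g * (g_gj - <g_g, pi>)
        gz = (pi[: K - 1] * (rA * (gA[: K - 1] - gA @ pi)
                             + rB * (gB[: K - 1] - gB @ pi)))
        grad[: K - 1] = gz
        grad[K - 1] = rA * (pi @ gA)
        grad[K] = rB * (pi @ gB)
        return -(llA + llB), -grad

    theta0 = np.concatenate([
        np.log(pi0[: K - 1] / pi0[-1]),
        [np.log(max(rA0, 1e-3)), np.log(max(rB0, 1e-3))],
    ])
    res = minimize(neg, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": MAX_ITER, "gtol": GRAD_TOL, "ftol": 1e-12})
    return float(-res.fun)


def _fit_h0_gene(
    XA: np.ndarray, XB: np.ndarray, fit_A: DMFit, fit_B: DMFit, pooled: DMFit
) -> float:
    """Constrained gene-level fit from several starts (the flat multinomial
    limit makes single starts unreliable); best log-likelihood wins."""
    return max(
        _fit_h0_gene_once(XA, XB, pi0, rA0, rB0)
        for pi0, rA0, rB0 in _h0_starts(fit_A, fit_B, pooled)
    )


def _fit_h0_transcript(XA: np.ndarray, XB: np.ndarray, k: int,
                       piA0: np.ndarray, piB0: np.ndarray,
                       rA0: float, rB0: float) -> float:
    """Constrained fit equating only component k of pi_bar across groups."""
    K = XA.shape[1]
    rest = [i for i in range(K) if i != k]

    def unpack(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = float(np.clip(expit(theta[0]), 1e-12, 1 - 1e-12))  # shared pi_bar_k
        alphas = []
        off = 1
        for r0_log in (theta[-2], theta[-1]):
            w = theta[off: off + K - 2]
            off += K - 2
            comp = _softmax(np.append(w, 0.0)) * (1 - p)
            pi = np.empty(K)
            pi[k] = p
            pi[rest] = comp
            alphas.append(np.clip(pi * np.exp(r0_log), ALPHA_MIN, None))
        return alphas[0], alphas[1]

    def neg(theta: np.ndarray) -> float:
        aA, aB = unpack(theta)
        return -(dm_loglik(aA, XA) + dm_loglik(aB, XB))

    p0 = float(np.clip((piA0[k] + piB0[k]) / 2, 1e-4, 1 - 1e-4))
    theta0 = [np.log(p0 / (1 - p0))]
    for pig in (piA0, piB0):
        comp = np.clip(pig[rest], 1e-6, None)
        theta0.extend(np.log(comp[:-1] / comp[-1]))
    theta0.extend([np.log(max(rA0, 1e-3)), np.log(max(rB0, 1e-3))])
    res = minimize(neg, np.array(theta0), method="L-BFGS-B",
                   options={"maxiter": MAX_ITER, "ftol": 1e-12})
    return float(-res.fun)


def lrt_gene(
    data: GeneUsageData,
    fit_A: DMFit | None = None,
    fit_B: DMFit | None = None,
) -> tuple[float, float]:
    """Gene-level likelihood-ratio test of equal average usage pi_bar across
    the two populations (chi-square, K-1 df)."""
    XA, XB = data.group("A"), data.group("B")
    fit_A = fit_A or fit_dm(XA)
    fit_B = fit_B or fit_dm(XB)
    ll1 = fit_A.loglik + fit_B.loglik
    pooled = fit_dm(np.vstack([XA, XB]))
    ll0 = _fit_h0_gene(XA, XB, fit_A, fit_B, pooled)
    stat = max(0.0, 2.0 * (ll1 - ll0))
    p = float(chi2.sf(stat, df=data.K - 1))
    return stat, p


def lrt_transcript(
    data: GeneUsageData,
    k: int,
    fit_A: DMFit | None = None,
    fit_B: DMFit | None = None,
) -> tuple[float, float]:
    """Transcript-level LRT equating only component k of pi_bar (1 df)."""
    XA, XB = data.group("A"), data.group("B")
    fit_A = fit_A or fit_dm(XA)
    fit_B = fit_B or fit_dm(XB)
    ll1 = fit_A.loglik + fit_B.loglik
    if data.K == 2:
        # constraining one of two components fixes the whole composition
        pooled = fit_dm(np.vstack([XA, XB]))
        ll0 = _fit_h0_gene(XA, XB, fit_A, fit_B, pooled)
    else:
        ll0 = _fit_h0_transcript(XA, XB, k, fit_A.pi_bar, fit_B.pi_bar,
                                 fit_A.alpha.sum(), fit_B.alpha.sum())
    stat = max(0.0, 2.0 * (ll1 - ll0))
    p = float(chi2.sf(stat, df=1))
    return stat, p


def detect_switching(
    fit_A: DMFit, fit_B: DMFit, columns: list[str], rare_index: int | None = None
) -> tuple[bool, float, str, str]:
    """Dominant-isoform switch between populations and its effect size.

    The aggregated rare column is excluded from dominance.  Effect size is
    |piA_a - piB_a| + |piA_b - piB_b| for the two dominant isoforms a (in A)
    and b (in B); reported only when a switch occurs.
    """
    piA, piB = fit_A.pi_bar, fit_B.pi_bar
    idx = [i for i in range(len(columns)) if i != rare_index]
    a = max(idx, key=lambda i: piA[i])
    b = max(idx, key=lambda i: piB[i])
    switching = a != b
    effect = float(abs(piA[a] - piB[a]) + abs(piA[b] - piB[b])) if switching else np.nan
    return switching, effect, columns[a], columns[b]


def adjust_fdr(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjustment; NaNs pass through untouched."""
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _bootstrap_sd(X: np.ndarray, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    """Nonparametric bootstrap sd of pi_bar over cell resamples."""
    if n_boot <= 0:
        return np.full(X.shape[1], np.nan)
    pis = []
    n_cells = X.shape[0]
    for _ in range(n_boot):
        idx = rng.integers(0, n_cells, n_cells)
        Xb = X[idx]
        if Xb.sum() == 0 or int(np.sum(Xb.sum(axis=1) > 0)) < 2:
            continue
        try:
            pis.append(fit_dm(Xb).pi_bar)
        except DTUError:
            continue
    if len(pis) < 2:
        return np.full(X.shape[1], np.nan)
    return np.std(np.array(pis), axis=0, ddof=1)


def test_gene(
    gene_id: str,
    X: np.ndarray,
    group_labels: np.ndarray,
    columns: list[str] | None = None,
    n_boot: int = 0,
    rng: np.random.Generator | None = None,
) -> DTUResult | None:
    """Run the full per-gene DTU analysis; None when the gene is excluded."""
    data = aggregate_rare(X, group_labels, columns)
    if data.excluded:
        return None
    XA, XB = data.group("A"), data.group("B")
    for Xg in (XA, XB):
        if int(np.sum(Xg.sum(axis=1) > 0)) < 2:
            return None
    fit_A, fit_B = fit_dm(XA), fit_dm(XB)
    stat, p_gene = lrt_gene(data, fit_A, fit_B)
    rows = []
    for k, col in enumerate(data.columns):
        st_k, p_k = lrt_transcript(data, k, fit_A, fit_B)
        rows.append({"isoform": col, "statistic": st_k, "p": p_k})
    tx = pd.DataFrame(rows)
    tx["pi_A"] = fit_A.pi_bar
    tx["pi_B"] = fit_B.pi_bar
    if n_boot:
        rng = rng or np.random.default_rng(0)
        tx["pi_A_sd"] = _bootstrap_sd(XA, n_boot, rng)
        tx["pi_B_sd"] = _bootstrap_sd(XB, n_boot, rng)
    switching, effect, dom_a, dom_b = detect_switching(
        fit_A, fit_B, data.columns, data.rare_index
    )
    return DTUResult(
        gene_id=gene_id, p_gene=p_gene, statistic=stat, transcript_stats=tx,
        switching=switching, effect_size=effect, dominant_A=dom_a,
        dominant_B=dom_b, fit_A=fit_A, fit_B=fit_B,
    )


def run_dtu(
    counts: pd.DataFrame,
    groups: pd.Series,
    n_boot: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DTU analysis over a transcript-by-cell counts frame.

    ``counts`` must carry ``gene_id`` and ``isoform_id`` columns followed by
    one column per cell barcode; ``groups`` maps barcodes to "A"/"B".
    Returns (gene table, transcript table) with BH-adjusted p-values, gene
    level adjusted across tested genes and transcript level across all
    gene x transcript tests.
    """
    barcodes = [c for c in counts.columns
                if c not in ("gene_id", "isoform_id", "feature_type")]
    barcodes = [b for b in barcodes if b in groups.index]
    labels = groups.loc[barcodes].to_numpy()
    rng = np.random.default_rng(seed)
    gene_rows, tx_rows = [], []
    for gene_id, sub in counts.groupby("gene_id", sort=True):
        X = sub[barcodes].to_numpy().T  # cells x isoforms
        res = test_gene(gene_id, X, labels, list(sub["isoform_id"]),
                        n_boot=n_boot, rng=rng)
        if res is None:
            continue
        gene_rows.append({
            "gene_id": gene_id, "statistic": res.statistic, "p": res.p_gene,
            "phi_A": res.fit_A.phi, "phi_B": res.fit_B.phi,
            "switching": res.switching, "effect_size": res.effect_size,
            "dominant_A": res.dominant_A, "dominant_B": res.dominant_B,
        })
        t = res.transcript_stats.copy()
        t.insert(0, "gene_id", gene_id)
        tx_rows.append(t)
    gene_table = pd.DataFrame(gene_rows)
    tx_table = pd.concat(tx_rows, ignore_index=True) if tx_rows else pd.DataFrame()
    if len(gene_table):
        gene_table["padj"] = adjust_fdr(gene_table["p"])
    if len(tx_table):
        tx_table["padj"] = adjust_fdr(tx_table["p"])
    return gene_table, tx_table
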