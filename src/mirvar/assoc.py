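"""Kinship mixed-model association and downstream statistics.

The association model is the univariate linear mixed model

    y = W a + x d + u + e,     u ~ MVN(0, lambda * tau^-1 * K),
                               e ~ MVN(0, tau^-1 * I)

where y is a phenotype (expression probe or lipid trait), W holds the
intercept and fixed covariates, x is the SNP dosage vector, d the allele
substitution effect, K the SNP-derived relatedness matrix and lambda the
ratio of genetic to residual variance.  Fitting follows the standard
eigendecomposition trick: K = U diag(s) U' is computed once, all vectors
are rotated by U', and for any trial lambda the model collapses to
weighted least squares with weights 1/(lambda*s_i + 1), leaving a
one-dimensional maximum-likelihood search over lambda.  Significance of
d comes from a likelihood-ratio test against the d = 0 null (chi-square,
1 df), with Benjamini-Hochberg control across tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LMMFit",
    "KinshipEigen",
    "filter_expressed_probes",
    "centered_kinship",
    "eigendecompose_kinship",
    "fit_lmm",
    "lrt",
    "bh_fdr",
    "association_scan",
    "candidate_targets",
    "hypergeom_enrichment",
    "welch_t",
    "ddct_quantify",
]

logger = logging.getLogger(__name__)

_LOG10_LAMBDA_RANGE = (-5.0, 5.0)
_GRID_STEP = 0.1
_PSD_TOL = 1e-8


def filter_expressed_probes(
    presence: pd.DataFrame, control_probes: Iterable[str] = ()
) -> list[str]:
    """Probes detected in at least 50% of samples.

    ``presence`` is a boolean probes x samples frame.  A probe below the
    detection threshold in more than half the samples is discarded, so a
    probe present in exactly half is retained.  Control probes are always
    dropped.
    """
    controls = set(control_probes)
    frac = presence.mean(axis=1)
    return [p for p in presence.index if frac[p] >= 0.5 and p not in controls]


def centered_kinship(genotypes: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Centered genomic relatedness matrix from a dosage matrix
    (individuals x SNPs, entries 0/1/2 with NaN for missing).

    Missing dosages are mean-imputed per SNP, columns are centered by
    their mean, and K = Xc Xc' / p over the p retained (non-constant,
    not-all-missing) SNPs.
    """
    X = np.asarray(genotypes, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D dosage matrix with >= 2 individuals")
    cols = []
    for j in range(X.shape[1]):
        col = X[:, j].copy()
        mask = np.isnan(col)
        if mask.all():
            logger.warning("kinship: SNP column %d all-missing, dropped", j)
            continue
        if mask.any():
            col[mask] = col[~mask].mean()
        col -= col.mean()
        cols.append(col)
    if not cols:
        raise ValueError("no usable SNP columns for kinship")
    Xc = np.column_stack(cols)
    return Xc @ Xc.T / Xc.shape[1]


@dataclass(frozen=True)
class KinshipEigen:
    """Cached eigendecomposition of a kinship matrix (reused across fits)."""

    values: np.ndarray  # eigenvalues, clipped at 0
    vectors: np.ndarray  # K = vectors @ diag(values) @ vectors.T


def eigendecompose_kinship(K: np.ndarray) -> KinshipEigen:
    K = np.asarray(K, dtype=float)
    if K.shape[0] != K.shape[1] or not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kinship matrix must be square and symmetric")
    vals, vecs = np.linalg.eigh(K)
    if vals.min() < -_PSD_TOL * max(1.0, abs(vals.max())):
        raise ValueError(f"kinship matrix not PSD: min eigenvalue {vals.min():.3g}")
    return KinshipEigen(np.clip(vals, 0.0, None), vecs)


@dataclass(frozen=True)
class LMMFit:
    """Maximum-likelihood fit of the mixed model at the optimal lambda."""

    lam: float  # variance ratio lambda
    sigma2: float  # residual variance tau^-1
    alpha: np.ndarray  # fixed-effect estimates (covariates)
    delta: float  # allele substitution effect (NaN if x absent/constant)
    se_delta: float
    log_likelihood: float
    n: int

    @property
    def has_snp(self) -> bool:
        return np.isfinite(self.delta)


def _ml_profile(yr, Xr, s, log10_lam):
    """Profiled ML log-likelihood and WLS solution at one lambda."""
    lam = 10.0 ** log10_lam
    v = lam * s + 1.0
    w = 1.0 / v
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(Xr * sw[:, None], yr * sw, rcond=None)
    resid = yr - Xr @ beta
    rss = float(np.dot(w * resid, resid))
    n = yr.shape[0]
    sigma2 = rss / n
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + np.log(v).sum() + n)
    return ll, beta, sigma2, w


def fit_lmm(
    y: np.ndarray,
    W: np.ndarray,
    x: np.ndarray | None = None,
    K: np.ndarray | None = None,
    eigen: KinshipEigen | None = None,
) -> LMMFit:
    """Fit the mixed model by ML with a 1-D search over lambda.

    The search runs over log10(lambda) in [-5, 5]: a coarse grid in 0.1
    steps followed by bounded Brent refinement to 1e-6.  Either ``K`` or a
    precomputed ``eigen`` must be given; passing ``eigen`` lets callers
    amortise the eigendecomposition over many phenotypes.  ``x=None`` fits
    the null (no-SNP) model; a constant ``x`` is flagged by NaN estimates.
    """
    y = np.asarray(y, dtype=float).ravel()
    W = np.atleast_2d(np.asarray(W, dtype=float))
    n = y.shape[0]
    if W.shape[0] != n:
        raise ValueError("W and y dimensions disagree")
    if eigen is None:
        if K is None:
            raise ValueError("either K or eigen must be supplied")
        eigen = eigendecompose_kinship(K)
    if eigen.values.shape[0] != n:
        raise ValueError("kinship dimension does not match y")

    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise ValueError("W is rank deficient; drop redundant columns first")
    snp_constant = False
    if x is not None:
        x = np.asarray(x, dtype=float).ravel()
        if np.ptp(x) == 0:
            logger.warning("constant SNP vector: substitution effect undefined")
            snp_constant = True
            x = None
    if n < W.shape[1] + (2 if x is not None else 1):
        raise ValueError("too few observations for the design")

    U = eigen.vectors
    s = eigen.values
    yr = U.T @ y
    Xr = U.T @ (W if x is None else np.column_stack([W, x]))

    lo, hi = _LOG10_LAMBDA_RANGE
    grid = np.arange(lo, hi + _GRID_STEP / 2, _GRID_STEP)
    lls = np.array([_ml_profile(yr, Xr, s, g)[0] for g in grid])
    g0 = grid[int(np.argmax(lls))]
    res = optimize.minimize_scalar(
        lambda g: -_ml_profile(yr, Xr, s, g)[0],
        bounds=(max(lo, g0 - _GRID_STEP), min(hi, g0 + _GRID_STEP)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    g_opt = float(res.x)
    if -res.fun < lls.max():  # grid point beat the refinement (flat boundary)
        g_opt = float(g0)
    ll, beta, sigma2, w = _ml_profile(yr, Xr, s, g_opt)

    if x is not None:
        XtWX = (Xr * w[:, None]).T @ Xr
        cov = sigma2 * np.linalg.inv(XtWX)
        delta = float(beta[-1])
        se_delta = float(np.sqrt(cov[-1, -1]))
        alpha = beta[:-1]
    else:
        delta = float("nan")
        se_delta = float("nan")
        alpha = beta
    if snp_constant:
        delta = float("nan")
        se_delta = float("nan")
    return LMMFit(10.0 ** g_opt, sigma2, alpha, delta, se_delta, float(ll), n)


def lrt(fit_alt: LMMFit, fit_null: LMMFit) -> float:
    """Likelihood-ratio test of H1: d != 0 vs H0: d = 0, chi-square 1 df.

    Both fits must be ML fits on the same data; the statistic is floored
    at zero (optimisation noise can make it marginally negative).
    """
    if fit_alt.n != fit_null.n:
        raise ValueError("fits are not on the same data (n differs)")
    stat = max(0.0, 2.0 * (fit_alt.log_likelihood - fit_null.log_likelihood))
    return float(stats.chi2.sf(stat, df=1))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_design(
    covariates: pd.DataFrame,
    factors: Sequence[str] = (),
    numeric: Sequence[str] = (),
) -> np.ndarray:
    """Incidence matrix: intercept + reference-coded factors + numeric
    covariates.  The first observed level of each factor is the baseline;
    columns that end up redundant are dropped with a warning."""
    n = len(covariates)
    cols = [np.ones(n)]
    for f in factors:
        levels = list(dict.fromkeys(covariates[f]))
        for lev in levels[1:]:
            cols.append((covariates[f] == lev).to_numpy(dtype=float))
    for c in numeric:
        cols.append(covariates[c].to_numpy(dtype=float))
    W = np.column_stack(cols)
    # drop rank-deficient columns greedily
    keep: list[int] = []
    for j in range(W.shape[1]):
        trial = W[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            logger.warning("design: dropping redundant column %d", j)
    return W[:, keep]


def association_scan(
    phenotypes: pd.DataFrame,
    genotypes: pd.DataFrame,
    W: np.ndarray,
    K: np.ndarray,
    fdr_family: str = "per-snp",
) -> pd.DataFrame:
    """LMM association of every SNP column against every phenotype column.

    Individuals with a missing dosage are excluded from that SNP's tests
    (with the null refit on the same subset).  q-values are computed per
    SNP (one family per SNP across phenotypes, the default) or globally.
    Returns a frame with columns snp, trait, delta, se, p, q sorted by
    (snp, p).
    """
    if fdr_family not in ("per-snp", "global"):
        raise ValueError(f"unknown fdr_family {fdr_family!r}")
    full_eigen = eigendecompose_kinship(K)
    rows = []
    for snp in genotypes.columns:
        dos = genotypes[snp].to_numpy(dtype=float)
        mask = ~np.isnan(dos)
        if mask.all():
            eig, Wm, dm = full_eigen, W, dos
        else:
            Km = K[np.ix_(mask, mask)]
            eig, Wm, dm = eigendecompose_kinship(Km), W[mask], dos[mask]
        for trait in phenotypes.columns:
            y = phenotypes[trait].to_numpy(dtype=float)[mask]
            alt = fit_lmm(y, Wm, dm, eigen=eig)
            null = fit_lmm(y, Wm, None, eigen=eig)
            rows.append(
                {
                    "snp": snp,
                    "trait": trait,
                    "delta": alt.delta,
                    "se": alt.se_delta,
                    "p": lrt(alt, null),
                }
            )
    df = pd.DataFrame(rows, columns=["snp", "trait", "delta", "se", "p"])
    if fdr_family == "global":
        df["q"] = bh_fdr(df["p"].to_numpy())
    else:
        df["q"] = np.nan
        for snp in df["snp"].unique():
            sel = df["snp"] == snp
            df.loc[sel, "q"] = bh_fdr(df.loc[sel, "p"].to_numpy())
    return df.sort_values(["snp", "p"]).reset_index(drop=True)


def candidate_targets(
    snp_arm_map: Mapping[str, str],
    target_pairs: pd.DataFrame,
    validated_interactions: pd.DataFrame,
    expressed_probes: Iterable[str],
    probe_gene: pd.DataFrame,
    require_site: bool = True,
    require_validated: bool = True,
) -> pd.DataFrame:
    """Build the per-SNP list of probes eligible for association testing.

    A probe is tested for a SNP iff (1) its gene's 3'UTR carries at least
    one 7mer-m8/8mer site for the SNP's miRNA arm, (2) the (miRNA, gene)
    interaction appears in the validated-interaction table, and (3) the
    probe passed the expression-presence filter.  Switching both
    ``require_*`` flags off yields the condition-free whole-transcriptome
    scan.
    """
    expressed = set(expressed_probes)
    site_genes: dict[str, set[str]] = {}
    for _, row in target_pairs.iterrows():
        site_genes.setdefault(row["mirna_arm_id"], set()).add(row["gene_id"])
    validated: dict[str, set[str]] = {}
    for _, row in validated_interactions.iterrows():
        validated.setdefault(row.iloc[0], set()).add(row.iloc[1])
    rows = []
    for _, prow in probe_gene.iterrows():
        probe, gene = prow.iloc[0], prow.iloc[1]
        if probe not in expressed:
            continue
        for snp, arm in snp_arm_map.items():
            if require_site and gene not in site_genes.get(arm, ()):
                continue
            if require_validated and gene not in validated.get(arm, ()):
                continue
            rows.append({"snp": snp, "probe": probe, "gene": gene})
    return pd.DataFrame(rows, columns=["snp", "probe", "gene"])


def hypergeom_enrichment(
    hit_genes: Iterable[str],
    pathway_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per pathway,
    BH-corrected across pathways."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    hits = set(hit_genes) & universe
    rows = []
    for name, genes in pathway_sets.items():
        genes = set(genes) & universe
        overlap = len(hits & genes)
        # P(X >= overlap), X ~ Hypergeom(|U|, |pathway|, |hits|)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(genes), len(hits)))
        rows.append(
            {"pathway": name, "pathway_size": len(genes), "overlap": overlap, "p": p}
        )
    df = pd.DataFrame(rows, columns=["pathway", "pathway_size", "overlap", "p"])
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
    else:
        df["q"] = []
    return df.sort_values("p").reset_index(drop=True)


def welch_t(xs: Sequence[float], ys: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Satterthwaite df, two-sided P)."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size < 2 or ys.size < 2:
        raise ValueError("need at least two observations per group")
    if xs.var(ddof=1) == 0 and ys.var(ddof=1) == 0:
        logger.warning("welch_t: both groups have zero variance")
        if xs.mean() == ys.mean():
            return 0.0, float(xs.size + ys.size - 2), 1.0
        return float("inf") * np.sign(xs.mean() - ys.mean()), float(
            xs.size + ys.size - 2
        ), 0.0
    res = stats.ttest_ind(xs, ys, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def ddct_quantify(
    ct_table: pd.DataFrame,
    target_gene: str,
    control_genes: Sequence[str],
    groups: Mapping[str, str],
    calibrator_group: str,
) -> tuple[pd.DataFrame, dict]:
    """Relative quantification by the 2^-ddCt method.

    ``ct_table`` has columns (sample, gene, ct) with one row per technical
    replicate.  Per sample: the target's mean Ct is normalised by the
    arithmetic mean of the control genes' mean Cts (dCt), then by the mean
    dCt of the calibrator group (ddCt); Rq = 2^-ddCt and log2 Rq = -ddCt.
    Groups are compared by Welch's t-test on log2 Rq against the
    calibrator.
    """
    if not control_genes:
        raise ValueError("at least one endogenous control gene is required")
    mean_ct = (
        ct_table.groupby(["sample", "gene"])["ct"].mean().unstack("gene")
    )
    missing = [g for g in (target_gene, *control_genes) if g not in mean_ct.columns]
    if missing:
        raise ValueError(f"missing Ct data for gene(s): {missing}")
    records = pd.DataFrame(
        {
            "sample": mean_ct.index,
            "group": [groups[s] for s in mean_ct.index],
            "ct_target": mean_ct[target_gene].to_numpy(),
            "ct_control": mean_ct[list(control_genes)].mean(axis=1).to_numpy(),
        }
    )
    records["dct"] = records["ct_target"] - records["ct_control"]
    calib = records.loc[records["group"] == calibrator_group, "dct"]
    if calib.empty:
        raise ValueError(f"no samples in calibrator group {calibrator_group!r}")
    records["ddct"] = records["dct"] - calib.mean()
    records["rq"] = 2.0 ** (-records["ddct"])
    records["log2_rq"] = -records["ddct"]

    comparison: dict = {"calibrator": calibrator_group, "groups": {}}
    base = records.loc[records["group"] == calibrator_group, "log2_rq"].to_numpy()
    for grp in records["group"].unique():
        sub = records.loc[records["group"] == grp]
        entry = {
            "n": int(len(sub)),
            "mean_rq": float(sub["rq"].mean()),
            "mean_log2_rq": float(sub["log2_rq"].mean()),
        }
        if grp != calibrator_group and len(sub) >= 2 and len(base) >= 2:
            t, df, p = welch_t(sub["log2_rq"].to_numpy(), base)
            entry.update({"t": t, "df": df, "p": p})
        comparison["groups"][grp] = entry
    return records, comparison
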