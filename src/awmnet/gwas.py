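"""Single-SNP mixed-model association scan with pedigree polygenic control.

Model per trait and SNP::

    y = sex + batch + beta * c + a_k * lambda_k + u + e,
    u ~ N(0, sigma_u^2 * A),   e ~ N(0, sigma_e^2 * I)

where lambda is the -1/0/+1 genotype indicator, c the trait-specific
covariate (carcass weight for the cut/fat traits, body weight at the
matching day for the ultrasound backfats, age for the weights), and A the
pedigree numerator relationship matrix.  Variance components are estimated
once per trait by REML on the null model (spectral decomposition of A,
one-dimensional optimization over the variance ratio) and reused for every
SNP — the standard two-stage approximation; an exact per-SNP refit is
available for small data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from statsmodels.stats.multitest import multipletests

from .qc import GenotypeMatrix, MISSING
from .simulate import TRAITS

__all__ = [
    "CovariateScheme", "default_scheme", "VarianceComponents", "GwasResult",
    "estimate_variance_components", "snp_association_scan", "fdr_qvalues",
]

# trait -> covariate column; "age" refers to the age column, None to no covariate
DEFAULT_COVARIATES = {
    "CL": "CW", "IMF": "CW", "BFTS": "CW", "HW": "CW", "SW": "CW", "BLW": "CW",
    "BFT155": "BW155", "BFT180": "BW180",
    "BW125": "age", "BW155": "age", "BW180": "age", "CW": "age",
}


@dataclass
class CovariateScheme:
    """Mapping of each analyzed trait to its model covariate."""

    covariates: dict

    def __post_init__(self):
        for t, c in self.covariates.items():
            if c == t:
                raise ValueError(f"trait {t} cannot be its own covariate")

    @property
    def traits(self) -> list:
        return list(self.covariates)


def default_scheme() -> CovariateScheme:
    """The 12-trait scheme: each trait covered exactly once."""
    return CovariateScheme(dict(DEFAULT_COVARIATES))


@dataclass
class VarianceComponents:
    sigma_u2: float
    sigma_e2: float
    reml_loglik: float

    @property
    def ratio(self) -> float:
        return self.sigma_u2 / self.sigma_e2 if self.sigma_e2 > 0 else np.inf


@dataclass
class GwasResult:
    """Per-(SNP, trait) additive effect, SE and Wald p; per-trait variance components."""

    effects: pd.DataFrame  # snp x trait
    se: pd.DataFrame
    pvalues: pd.DataFrame
    status: pd.DataFrame  # "ok" | "monomorphic"
    varcomps: dict  # trait -> VarianceComponents

    def trait_frame(self, trait: str, snp_map: pd.DataFrame | None = None) -> pd.DataFrame:
        out = pd.DataFrame({
            "snp_id": self.effects.index,
            "effect": self.effects[trait].to_numpy(),
            "se": self.se[trait].to_numpy(),
            "p": self.pvalues[trait].to_numpy(),
        })
        out["q"] = fdr_qvalues(out["p"].to_numpy())
        if snp_map is not None:
            m = snp_map.drop_duplicates("snp_id").set_index("snp_id")
            out.insert(1, "chrom", m.reindex(out["snp_id"])["chrom"].to_numpy())
            out.insert(2, "bp", m.reindex(out["snp_id"])["bp"].to_numpy())
        return out


def _design_matrix(pheno: pd.DataFrame, trait: str, covariate: str | None) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-effect design (intercept, sex, batch dummies, covariate) and row mask."""
    cols = [trait]
    if covariate is not None:
        cols.append(covariate)
    mask = pheno[cols].notna().all(axis=1).to_numpy()
    sub = pheno.loc[mask]
    parts = [np.ones(len(sub))]
    if "sex" in sub.columns and sub["sex"].nunique() > 1:
        parts.append((sub["sex"].to_numpy() == sub["sex"].iloc[0]).astype(float))
    if "batch" in sub.columns and sub["batch"].nunique() > 1:
        levels = sorted(sub["batch"].unique())[1:]
        for lv in levels:
            parts.append((sub["batch"].to_numpy() == lv).astype(float))
    if covariate is not None:
        c = sub[covariate].to_numpy(dtype=float)
        parts.append(c - c.mean())
    X = np.column_stack(parts)
    return X, mask


def reml_profile_loglik(y: np.ndarray, X: np.ndarray, A: np.ndarray,
                        ratio: float) -> float:
    """Restricted log-likelihood profiled over sigma_e^2 at a fixed
    variance ratio delta = sigma_u^2 / sigma_e^2."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    S, U = linalg.eigh(np.asarray(A, dtype=float))
    S = np.clip(S, 0.0, None)
    d = ratio * S + 1.0
    w = 1.0 / d
    ystar, Xstar = U.T @ y, U.T @ X
    XtWX = Xstar.T @ (Xstar * w[:, None])
    beta = np.linalg.solve(XtWX, Xstar.T @ (ystar * w))
    r = ystar - Xstar @ beta
    sigma_e2 = float(np.sum(r * r * w) / (n - p))
    _, logdet_xwx = np.linalg.slogdet(XtWX)
    _, logdet_xx = np.linalg.slogdet(X.T @ X)
    return float(-0.5 * ((n - p) * np.log(2 * np.pi * sigma_e2) + np.sum(np.log(d))
                         + logdet_xwx - logdet_xx + (n - p)))


def estimate_variance_components(y: np.ndarray, X: np.ndarray, A: np.ndarray,
                                 ngrid: int = 41) -> VarianceComponents:
    """REML estimates of (sigma_u^2, sigma_e^2) for y = Xb + u + e.

    Profiles the restricted likelihood over the ratio delta = sigma_u^2 /
    sigma_e^2 on the eigenbasis of A (EMMA-style): a log-spaced grid scan
    followed by bounded refinement around the best grid point.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    A = np.asarray(A, dtype=float)
    n, p = X.shape
    if n != len(y) or A.shape != (n, n):
        raise ValueError("dimension mismatch between y, X and A")
    if n < p + 2:
        raise ValueError("too few records to estimate variance components")
    S, U = linalg.eigh(A)
    S = np.clip(S, 0.0, None)
    if S.max() - S.min() < 1e-8:
        raise ValueError(
            "relationship matrix is proportional to identity: the variance "
            "ratio is not identifiable from one record per individual")
    ystar = U.T @ y
    Xstar = U.T @ X
    sign, logdet_xx = np.linalg.slogdet(X.T @ X)

    def reml_ll(log_delta: float) -> float:
        delta = np.exp(log_delta)
        d = delta * S + 1.0
        w = 1.0 / d
        XtWX = Xstar.T @ (Xstar * w[:, None])
        XtWy = Xstar.T @ (ystar * w)
        try:
            beta = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            return -np.inf
        r = ystar - Xstar @ beta
        rss = float(np.sum(r * r * w))
        if rss <= 0:
            return -np.inf
        sigma_e2 = rss / (n - p)
        s, logdet_xwx = np.linalg.slogdet(XtWX)
        ll = -0.5 * ((n - p) * np.log(2 * np.pi * sigma_e2) + np.sum(np.log(d))
                     + logdet_xwx - logdet_xx + (n - p))
        return ll

    grid = np.linspace(np.log(1e-6), np.log(1e6), ngrid)
    vals = np.array([reml_ll(g) for g in grid])
    k = int(np.argmax(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, ngrid - 1)]
    res = optimize.minimize_scalar(lambda g: -reml_ll(g), bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    best = res.x if -res.fun >= vals[k] else grid[k]
    delta = float(np.exp(best))
    d = delta * S + 1.0
    w = 1.0 / d
    XtWX = Xstar.T @ (Xstar * w[:, None])
    beta = np.linalg.solve(XtWX, Xstar.T @ (ystar * w))
    r = ystar - Xstar @ beta
    sigma_e2 = float(np.sum(r * r * w) / (n - p))
    return VarianceComponents(sigma_u2=delta * sigma_e2, sigma_e2=sigma_e2,
                              reml_loglik=float(reml_ll(best)))


def _whitening(A: np.ndarray, vc: VarianceComponents) -> np.ndarray:
    """W with W V W' = I for V = sigma_u^2 A + sigma_e^2 I."""
    S, U = linalg.eigh(A)
    S = np.clip(S, 0.0, None)
    d = vc.sigma_u2 * S + vc.sigma_e2
    return (U / np.sqrt(d)).T


def _impute_lambda(dos: np.ndarray) -> tuple[np.ndarray, bool]:
    """-1/0/+1 coding with per-SNP mean imputation; flags monomorphic columns."""
    lam = dos.astype(float) - 1.0
    obs = dos != MISSING
    if not obs.any():
        return np.zeros_like(lam), True
    mean = lam[obs].mean()
    lam[~obs] = mean
    mono = np.allclose(lam, lam[0])
    return lam, mono


def snp_association_scan(geno: GenotypeMatrix, pheno: pd.DataFrame,
                         scheme: CovariateScheme, A: pd.DataFrame,
                         refit_each_snp: bool = False,
                         varcomps: dict | None = None) -> GwasResult:
    """GLS association scan for every SNP and every trait in the scheme.

    ``pheno`` must contain one row per individual (``individual_id``), the
    traits, any covariate columns, and optionally sex/batch columns.  ``A``
    is the relationship matrix indexed by individual id.  Missing genotypes
    are mean-imputed on the -1/0/+1 scale; missing phenotypes/covariates are
    dropped per trait.  ``varcomps`` may pre-supply per-trait variance
    components (e.g. ``sigma_u2=0`` to reproduce ordinary least squares).
    """
    pheno = pheno.set_index("individual_id", drop=False).reindex(list(geno.individual_ids))
    n_snp = geno.n_snps
    traits = scheme.traits
    eff = np.full((n_snp, len(traits)), np.nan)
    se = np.full((n_snp, len(traits)), np.nan)
    pv = np.ones((n_snp, len(traits)))
    status = np.full((n_snp, len(traits)), "ok", dtype=object)
    vcs = {}

    lam_all = np.empty((n_snp, geno.n_individuals))
    mono_all = np.zeros(n_snp, bool)
    for i in range(n_snp):
        lam_all[i], mono_all[i] = _impute_lambda(geno.dosages[i])

    for j, trait in enumerate(traits):
        cov = scheme.covariates[trait]
        if cov is not None and cov not in pheno.columns:
            raise ValueError(f"covariate {cov!r} for trait {trait} missing from phenotypes")
        X, mask = _design_matrix(pheno, trait, cov)
        ids = pheno.index[mask]
        y = pheno.loc[mask, trait].to_numpy(dtype=float)
        Asub = A.loc[ids, ids].to_numpy()
        if varcomps is not None and trait in varcomps:
            vc = varcomps[trait]
        else:
            vc = estimate_variance_components(y, X, Asub)
        vcs[trait] = vc

        W = _whitening(Asub, vc)
        yt = W @ y
        Xt = W @ X
        Q, _ = np.linalg.qr(Xt)
        yr = yt - Q @ (Q.T @ yt)
        G = lam_all[:, mask.nonzero()[0]] @ W.T  # (n_snp, n)
        Gr = G - (G @ Q) @ Q.T
        denom = np.einsum("ij,ij->i", Gr, Gr)
        good = (denom > 1e-10) & ~mono_all
        a = np.zeros(n_snp)
        a[good] = (Gr[good] @ yr) / denom[good]
        s = np.full(n_snp, np.nan)
        s[good] = 1.0 / np.sqrt(denom[good])
        z = np.zeros(n_snp)
        z[good] = a[good] / s[good]
        p = np.ones(n_snp)
        p[good] = 2.0 * stats.norm.sf(np.abs(z[good]))

        if refit_each_snp:
            for i in np.flatnonzero(good):
                Xi = np.column_stack([X, lam_all[i, np.flatnonzero(mask)]])
                vci = estimate_variance_components(y, Xi, Asub)
                Wi = _whitening(Asub, vci)
                yti, Xti = Wi @ y, Wi @ Xi
                XtX = Xti.T @ Xti
                bi = np.linalg.solve(XtX, Xti.T @ yti)
                covb = np.linalg.inv(XtX)
                a[i] = bi[-1]
                s[i] = np.sqrt(covb[-1, -1])
                p[i] = 2.0 * stats.norm.sf(abs(a[i] / s[i]))

        eff[:, j] = np.where(good, a, np.nan)
        se[:, j] = s
        pv[:, j] = np.clip(p, np.finfo(float).tiny, 1.0)
        status[~good, j] = "monomorphic"

    idx = pd.Index(geno.snp_ids, name="snp_id")
    return GwasResult(
        effects=pd.DataFrame(eff, index=idx, columns=traits),
        se=pd.DataFrame(se, index=idx, columns=traits),
        pvalues=pd.DataFrame(pv, index=idx, columns=traits),
        status=pd.DataFrame(status, index=idx, columns=traits),
        varcomps=vcs,
    )


def fdr_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone in p-rank)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
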