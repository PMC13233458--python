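"""Repeat-abundance statistics.

Operates on an abundance table: genotypes x 14 repeat categories (SIRE, Ale,
other Ty1, Tekay, Retand, Athila, other Ty3, LINE, pararetrovirus,
EnSpm/CACTA, other DNA transposons, rDNA, satDNA, unclassified), entries in
percent of the genome. A transcription of the published 30-genotype table
ships with the package. On top of it: per-genotype totals and
superfamily sums, absolute repeat content in Mbp, Pearson correlations, PCA
of the category profiles, and OLS with adjusted R-squared, VIF and AIC.

Conventions: PCA defaults to the covariance matrix (all categories share the
percent unit; the correlation variant is available via ``scale=True``), with
component signs canonicalized so the largest-magnitude loading is positive.
AIC is the Gaussian profile form n*ln(RSS/n) + 2(k+2) — constant terms
differ between software conventions, so only differences between models fit
on the same data are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

CATEGORIES = [
    "SIRE", "Ale", "Ty1_other", "Tekay", "Retand", "Athila", "Ty3_other",
    "LINE", "Pararetrovirus", "EnSpm_CACTA", "DNA_other", "rDNA", "satDNA",
    "Unclassified",
]
TY1_CATEGORIES = ["SIRE", "Ale", "Ty1_other"]
TY3_CATEGORIES = ["Tekay", "Retand", "Athila", "Ty3_other"]


def load_table1() -> pd.DataFrame:
    """The packaged 30-genotype abundance fixture (includes the printed
    Total column)."""
    with resources.files("repeatomix.data").joinpath("table1.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return df


def load_metadata(path) -> pd.DataFrame:
    """Genome metadata table: genotype, genome_size_mbp, chromosome_number,
    ploidy. Genotype codes must match the abundance table rows."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    required = {"genome_size_mbp", "chromosome_number", "ploidy"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata table lacks columns: {sorted(missing)}")
    if (df[sorted(required)] <= 0).any().any():
        raise ValueError("metadata values must be positive")
    return df


def _require_categories(table: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"missing category columns: {missing}")


def totals(table: pd.DataFrame) -> pd.Series:
    """Per-genotype total repeat percent (sum of the 14 categories)."""
    _require_categories(table, CATEGORIES)
    return table[CATEGORIES].sum(axis=1)


def class_sums(table: pd.DataFrame) -> pd.DataFrame:
    """Ty1 and Ty3 superfamily totals per genotype."""
    _require_categories(table, TY1_CATEGORIES + TY3_CATEGORIES)
    return pd.DataFrame(
        {
            "Ty1": table[TY1_CATEGORIES].sum(axis=1),
            "Ty3": table[TY3_CATEGORIES].sum(axis=1),
        }
    )


def absolute_repeat_mbp(genome_size_mbp, total_percent):
    """Absolute repetitive content: genome size x (percent / 100)."""
    g = np.asarray(genome_size_mbp, dtype=float)
    t = np.asarray(total_percent, dtype=float)
    if (g < 0).any() or (t < 0).any():
        raise ValueError("inputs must be non-negative")
    return g * t / 100.0


def pearson_r2(x, y) -> float:
    """Squared Pearson product-moment correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector")
    r, _ = sps.pearsonr(x, y)
    return float(r * r)


@dataclass
class PCAResult:
    loadings: pd.DataFrame            # categories x components
    variance_percent: np.ndarray
    scores: pd.DataFrame              # genotypes x components
    scaled: bool


def pca(table: pd.DataFrame, scale: bool = False) -> PCAResult:
    """PCA of the repeat-category columns (or, for a table without the
    standard categories, of all numeric columns). Covariance by default,
    correlation with ``scale=True``; deterministic up to the documented sign
    convention."""
    if all(c in table.columns for c in CATEGORIES):
        cols = CATEGORIES
    else:
        cols = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
        if not cols:
            raise ValueError("no numeric columns to analyze")
    X = table[cols].to_numpy(float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError("constant column under scale=True")
        X = X / sd
    cov = np.cov(X, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0, None)
    # canonical signs: largest-magnitude loading positive
    for j in range(eigvec.shape[1]):
        i = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    var_pct = 100.0 * eigval / eigval.sum()
    comps = [f"PC{i + 1}" for i in range(len(eigval))]
    return PCAResult(
        loadings=pd.DataFrame(eigvec, index=list(cols), columns=comps),
        variance_percent=var_pct,
        scores=pd.DataFrame(X @ eigvec, index=table.index, columns=comps),
        scaled=scale,
    )


@dataclass
class OLSResult:
    params: pd.Series
    pvalues: pd.Series
    r2: float
    adj_r2: float
    aic: float
    vif: pd.Series
    n: int


def ols_fit(y, predictors: pd.DataFrame) -> OLSResult:
    """Ordinary least squares of y on the predictor columns (+ intercept).

    Reports adjusted R-squared, the documented AIC convention, and one VIF
    per predictor (1/(1 - R2_j) from regressing predictor j on the others).
    Rank-deficient designs raise instead of silently dropping columns.
    """
    y = np.asarray(y, float)
    X = predictors.to_numpy(float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError("need n > k + 1 observations")
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design (collinear predictors)")
    fit = sm.OLS(y, design).fit()
    rss = float(np.sum(fit.resid**2))
    aic = n * np.log(rss / n) + 2 * (k + 2)
    vifs = {}
    for j, name in enumerate(predictors.columns):
        if k == 1:
            vifs[name] = 1.0
            continue
        others = sm.add_constant(np.delete(X, j, axis=1))
        r2j = sm.OLS(X[:, j], others).fit().rsquared
        vifs[name] = float(1.0 / (1.0 - r2j)) if r2j < 1 else np.inf
    names = ["intercept"] + list(predictors.columns)
    return OLSResult(
        params=pd.Series(fit.params, index=names),
        pvalues=pd.Series(fit.pvalues, index=names),
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        aic=float(aic),
        vif=pd.Series(vifs),
        n=n,
    )


def correlation_report(table: pd.DataFrame, metadata: pd.DataFrame) -> dict:
    """Squared correlations of absolute repeat content (Mbp) with genome
    size, chromosome number and ploidy, given an SM1-style metadata table."""
    common = table.index.intersection(metadata.index)
    if len(common) < 3:
        raise ValueError("too few genotypes shared between tables")
    tot = totals(table.loc[common])
    meta = metadata.loc[common]
    absolute = absolute_repeat_mbp(meta["genome_size_mbp"], tot)
    return {
        "n": int(len(common)),
        "r2_genome_size": pearson_r2(meta["genome_size_mbp"], absolute),
        "r2_chromosome_number": pearson_r2(meta["chromosome_number"], absolute),
        "r2_ploidy": pearson_r2(meta["ploidy"], absolute),
    }
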