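"""Two-locus phenotype statistics for line panels and a per-gene negative
binomial interaction test for candidate-gene expression.

The panel design crosses two focal loci — one on 2R (alleles C/A, C tropical)
and one on X (alleles T/A, T tropical) — over inbred lines scored for
embryonic heat-shock survival. Epistasis is tested as the two-way interaction
in a linear model on per-line survival proportions (Type-III sums of squares,
since class counts are unbalanced). Expression counts are modelled per gene
with a negative binomial GLM using log normalization-factor offsets; the
background x temperature interaction is evaluated with Wald tests and BH
correction across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "genotype_class",
    "line_binom_ci",
    "survival_anova",
    "genotype_r2",
    "nb_interaction_test",
    "TROPICAL_ALLELES",
]

#: Tropical allele at each focal locus (2R: C tropical / A temperate;
#: X: T tropical / A temperate).
TROPICAL_ALLELES = {"2R": "C", "X": "T"}
_VALID = {"2R": {"C", "A"}, "X": {"T", "A"}}


def genotype_class(allele_2r: str, allele_x: str) -> str:
    """Map homozygous alleles at the two focal loci to a climate class.

    Returns one of ``tropical_tropical`` (C,T), ``tropical_temperate`` (C,A),
    ``temperate_tropical`` (A,T), ``temperate_temperate`` (A,A).
    """
    if allele_2r not in _VALID["2R"]:
        raise ValueError(f"unknown 2R allele {allele_2r!r}")
    if allele_x not in _VALID["X"]:
        raise ValueError(f"unknown X allele {allele_x!r}")
    first = "tropical" if allele_2r == TROPICAL_ALLELES["2R"] else "temperate"
    second = "tropical" if allele_x == TROPICAL_ALLELES["X"] else "temperate"
    return f"{first}_{second}"


def line_binom_ci(
    survived: int, assayed: int, level: float = 0.95
) -> tuple[float, float]:
    """Clopper-Pearson exact binomial confidence interval for line survival."""
    if assayed < 1:
        raise ValueError("assayed must be >= 1")
    if not (0 <= survived <= assayed):
        raise ValueError("require 0 <= survived <= assayed")
    alpha = 1.0 - level
    lower = 0.0 if survived == 0 else float(stats.beta.ppf(alpha / 2, survived, assayed - survived + 1))
    upper = 1.0 if survived == assayed else float(
        stats.beta.ppf(1 - alpha / 2, survived + 1, assayed - survived)
    )
    return lower, upper


def survival_anova(
    panel: pd.DataFrame,
    include_covariates: bool = True,
    weight_by_assayed: bool = False,
) -> pd.DataFrame:
    """Two-way ANOVA of line survival on the 2R and X focal genotypes.

    The response is the per-line survival proportion; the model holds both
    main effects, their interaction, and (optionally) any covariate columns
    present among ``wolbachia``, ``In2Lt``, ``In2RNS``. Sums of squares are
    Type III with sum-to-zero contrasts, appropriate for the unbalanced class
    counts. Set ``weight_by_assayed`` for a WLS variant weighting lines by
    embryos assayed. Returns the full ANOVA table (the epistasis row is
    ``locus_2r:locus_x``).
    """
    required = {"allele_2R", "allele_X", "survived", "assayed"}
    if not required.issubset(panel.columns):
        raise ValueError(f"panel needs columns {sorted(required)}")
    df = panel.copy()
    df["proportion"] = df["survived"] / df["assayed"]
    df["locus_2r"] = df["allele_2R"].astype(str)
    df["locus_x"] = df["allele_X"].astype(str)
    for locus, col in (("2R", "locus_2r"), ("X", "locus_x")):
        bad = set(df[col]) - _VALID[locus]
        if bad:
            raise ValueError(f"unknown {locus} alleles: {sorted(bad)}")
        if df[col].nunique() < 2:
            raise ValueError(f"locus {locus} is monomorphic in the panel")
    cells = df.groupby(["locus_2r", "locus_x"]).size()
    if len(cells) < 4:
        raise ValueError(f"empty genotype cells: only {len(cells)}/4 classes present")

    terms = ["C(locus_2r, Sum)", "C(locus_x, Sum)"]
    if include_covariates:
        for cov in ("wolbachia", "In2Lt", "In2RNS"):
            if cov in df.columns and df[cov].nunique() > 1:
                terms.append(f"C({cov}, Sum)")
    formula = "proportion ~ " + " + ".join(terms) + " + C(locus_2r, Sum):C(locus_x, Sum)"
    if weight_by_assayed:
        model = smf.wls(formula, data=df, weights=df["assayed"])
    else:
        model = smf.ols(formula, data=df)
    fit = model.fit()
    table = sm.stats.anova_lm(fit, typ=3)
    table = table.rename(
        index=lambda s: s.replace("C(locus_2r, Sum)", "locus_2r").replace(
            "C(locus_x, Sum)", "locus_x"
        )
    )
    return table


def interaction_test(panel: pd.DataFrame, **kwargs) -> tuple[float, float, tuple[int, int]]:
    """Convenience: (F, p, (df_num, df_den)) for the 2R-by-X interaction."""
    table = survival_anova(panel, **kwargs)
    row = table.loc["locus_2r:locus_x"]
    df_den = int(table.loc["Residual", "df"])
    return float(row["F"]), float(row["PR(>F)"]), (int(row["df"]), df_den)


def genotype_r2(geno_a: np.ndarray, geno_b: np.ndarray) -> float:
    """Squared Pearson correlation of allele dosages at two loci."""
    a = np.asarray(geno_a, dtype=float)
    b = np.asarray(geno_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("genotype vectors must have equal length")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("monomorphic genotype vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class ExpressionFit:
    gene: str
    contrast: str
    estimate: float
    se: float
    wald_stat: float
    p_value: float
    converged: bool


def _fit_nb_gene(
    y: np.ndarray, exog: np.ndarray, offset: np.ndarray
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Per-gene NB GLM: ML dispersion, with a moment-estimate fallback.

    Returns (params, standard errors, converged) for the mean model; the
    dispersion is profile-estimated by the discrete NegativeBinomial (NB2)
    likelihood and, on failure, by method of moments from Poisson residuals.
    """
    pois = sm.GLM(y, exog, offset=offset, family=sm.families.Poisson()).fit()
    try:
        model = sm.NegativeBinomial(y, exog, offset=offset)
        start = np.append(pois.params, 0.1)
        res = model.fit(start_params=start, disp=0, maxiter=200)
        alpha = float(res.params[-1])
        # boundary LR guard: if the NB likelihood barely improves on the
        # Poisson one, the dispersion is indistinguishable from zero and the
        # Poisson fit is the stable limit
        if np.isfinite(alpha) and (alpha <= 1e-4 or res.llf - pois.llf < 2.0):
            return pois.params, pois.bse, True
        if res.mle_retvals.get("converged", False) and np.all(np.isfinite(res.bse[:-1])):
            return res.params[:-1], res.bse[:-1], True
    except Exception:
        pass
    # fallback: moment estimate of alpha from the Poisson fit, then NB GLM
    mu = pois.fittedvalues
    dof = max(len(y) - exog.shape[1], 1)
    alpha = ((y - mu) ** 2 - mu).sum() / (mu ** 2).sum() * len(y) / dof
    if not np.isfinite(alpha) or alpha < 1e-8:
        return pois.params, pois.bse, False
    nb = sm.GLM(y, exog, offset=offset, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
    return nb.params, nb.bse, False


def nb_interaction_test(
    counts: pd.DataFrame,
    background: pd.Series | np.ndarray,
    temperature: pd.Series | np.ndarray,
    norm_factors: pd.Series | np.ndarray,
    reference_background: str | None = None,
) -> pd.DataFrame:
    """Gene-specific negative binomial GLM Wald test of background x temperature.

    ``counts`` is a gene x sample integer matrix; ``norm_factors`` enter the
    model as ``log`` offsets, so scaling a sample's counts and factor jointly
    leaves estimates unchanged. For each gene and each non-reference genetic
    background, the Wald p of that background's temperature-interaction
    coefficient is reported; BH adjustment is applied across genes within each
    contrast. All-zero genes are skipped.
    """
    background = pd.Categorical(np.asarray(background, dtype=object))
    temperature = pd.Categorical(np.asarray(temperature, dtype=object))
    norm_factors = np.asarray(norm_factors, dtype=float)
    if np.any(norm_factors <= 0):
        raise ValueError("normalization factors must be positive")
    if len(background.categories) < 2 or len(temperature.categories) < 2:
        raise ValueError("design needs >= 2 backgrounds and >= 2 temperatures")
    if reference_background is not None:
        cats = [reference_background] + [
            c for c in background.categories if c != reference_background
        ]
        background = background.reorder_categories(cats)

    bg = pd.get_dummies(background, drop_first=True).to_numpy(dtype=float)
    tmp = pd.get_dummies(temperature, drop_first=True).to_numpy(dtype=float)
    if tmp.shape[1] != 1:
        raise ValueError("exactly 2 temperature levels are supported")
    inter = bg * tmp
    exog = np.hstack([np.ones((len(background), 1)), bg, tmp, inter])
    n_base = 1 + bg.shape[1] + 1
    contrast_names = [f"{c}:temp" for c in background.categories[1:]]
    offset = np.log(norm_factors)

    rows: list[ExpressionFit] = []
    for gene, y in counts.iterrows():
        y = y.to_numpy(dtype=float)
        if y.sum() == 0:
            continue
        params, bse, converged = _fit_nb_gene(y, exog, offset)
        for j, cname in enumerate(contrast_names):
            est = float(params[n_base + j])
            se = float(bse[n_base + j])
            z = est / se if se > 0 else np.nan
            p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
            rows.append(ExpressionFit(str(gene), cname, est, se, float(z), p, converged))
    out = pd.DataFrame([r.__dict__ for r in rows]).rename(columns={"p_value": "p"})
    if len(out):
        out["q"] = np.nan
        for cname in contrast_names:
            mask = (out["contrast"] == cname) & out["p"].notna()
            if mask.any():
                out.loc[mask, "q"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    return out
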