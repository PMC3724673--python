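"""The analysis models: %AT on codon frequencies, phylum ANOVA of AAUB,
GAM of AAUB on CUB, hierarchical random-slope GAMMs, and AIC comparison.

The mixed models treat phylum / genus / species(strain) as strictly nested
grouping levels, each contributing a random intercept and a random slope on
genomic %AT ("AT content is more similar within species, then genera and
finally phyla").  Smooth terms are penalized cubic P-splines whose
smoothness is selected by REML (default) or ML on the mixed-model
representation; AIC comparisons always use ML likelihoods, since REML
likelihoods are not comparable across fixed-effect structures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.stats as st
import statsmodels.api as sm

from .errors import ContractViolation, DegenerateModelError
from .plmm import PLMM, PLMMFit, PSplineBasis, RandomBlock

logger = logging.getLogger(__name__)

HIERARCHY = ("phylum", "genus", "species")


@dataclass
class RandomStructure:
    """Nested random intercepts + slopes for the taxonomy hierarchy."""

    levels: tuple[str, ...] = HIERARCHY
    slope_on: str = "at_fraction"
    intercepts: bool = True
    slopes: bool = True


@dataclass
class ModelSpec:
    response: str
    linear_terms: list[str] = field(default_factory=list)
    smooth_terms: list[tuple[str, int]] = field(default_factory=list)
    random_structure: RandomStructure | None = None
    method: str = "REML"


@dataclass
class SmoothEstimate:
    """Fitted smooth on an evaluation grid with a pointwise 2-SE band."""

    curve: pd.DataFrame     # columns: x, fit, se, lower, upper
    edf: float


@dataclass
class ModelFit:
    """Coefficients, smooths, variance components and fit statistics."""

    response: str
    fixed: pd.DataFrame                      # estimate, se, t, p per term
    smooths: dict[str, SmoothEstimate]
    random_sd: pd.DataFrame                  # level, kind, sd (original units)
    dropped_levels: list[str]
    sigma2: float
    loglik: float
    aic: float
    r_squared: float
    edf_total: float
    method: str
    converged: bool
    n_obs: int
    fitted: np.ndarray
    residuals: np.ndarray
    y: np.ndarray

    @property
    def p_value(self) -> pd.Series:
        return self.fixed["p"]


@dataclass
class AicComparison:
    preferred: str | None
    delta_aic: float                         # AIC(a) - AIC(b)
    aic_a: float
    aic_b: float


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _nested_labels(tax: pd.DataFrame, level: str) -> pd.Series:
    """Concatenate labels down the hierarchy so nesting is explicit.

    Genomes with missing intermediate labels fall into singleton groups
    keyed by their genome id.
    """
    idx = HIERARCHY.index(level)
    parts = []
    for lvl in HIERARCHY[: idx + 1]:
        col = tax[lvl].astype(str).str.strip()
        col = col.where(col != "", tax["genome_id"].astype(str))
        parts.append(col)
    out = parts[0]
    for p in parts[1:]:
        out = out + "|" + p
    return out


def _indicator(labels: pd.Series) -> tuple[np.ndarray, list[str]]:
    cats = sorted(labels.unique())
    pos = {c: j for j, c in enumerate(cats)}
    Z = np.zeros((len(labels), len(cats)))
    Z[np.arange(len(labels)), [pos[v] for v in labels]] = 1.0
    return Z, cats


class _Design:
    """Internal: standardized fixed design + random blocks for one model."""

    def __init__(self, spec: ModelSpec, data: pd.DataFrame, taxonomy: pd.DataFrame | None):
        self.spec = spec
        if spec.response not in data.columns:
            raise ContractViolation(f"response {spec.response!r} not in data")
        df = data.reset_index(drop=True)
        if spec.random_structure is not None:
            if taxonomy is None:
                raise ContractViolation("random structure requires a taxonomy table")
            tax = taxonomy.set_index("genome_id")
            missing = set(df["genome_id"]) - set(tax.index)
            if missing:
                raise ContractViolation(f"taxonomy missing genomes: {sorted(missing)[:5]}")
            tax = tax.loc[df["genome_id"]].reset_index()
        else:
            tax = None
        self.y = df[spec.response].to_numpy(dtype=float)
        n = len(df)

        cols = [np.ones(n)]
        names = ["(Intercept)"]
        self.means: dict[str, float] = {}
        self.sds: dict[str, float] = {}
        smooth_vars = [v for v, _ in spec.smooth_terms]
        for var in list(spec.linear_terms) + smooth_vars:
            x = df[var].to_numpy(dtype=float)
            mu, sd = float(x.mean()), float(x.std(ddof=0))
            if sd == 0:
                raise DegenerateModelError(f"covariate {var!r} is constant")
            self.means[var], self.sds[var] = mu, sd
            cols.append((x - mu) / sd)
            names.append(var)
        self.X = np.column_stack(cols)
        self.names = names
        self.n = n

        self.blocks: list[RandomBlock] = []
        self.smooth_info: dict[str, dict] = {}
        for var, k in spec.smooth_terms:
            x = df[var].to_numpy(dtype=float)
            basis = PSplineBasis.build(x, k=k)
            Zs = basis.range_design(x)
            if n <= Zs.shape[1] + self.X.shape[1]:
                raise DegenerateModelError("fewer observations than basis dimension")
            self.blocks.append(RandomBlock(name=f"s({var})", Z=Zs, kind="smooth"))
            self.smooth_info[var] = {"basis": basis, "block": f"s({var})", "x": x}

        self.dropped_levels: list[str] = []
        if spec.random_structure is not None:
            rs = spec.random_structure
            w = df[rs.slope_on].to_numpy(dtype=float)
            w_sd = float(w.std(ddof=0))
            if w_sd == 0:
                raise DegenerateModelError(f"slope covariate {rs.slope_on!r} is constant")
            w_std = (w - w.mean()) / w_sd
            for level in rs.levels:
                labels = _nested_labels(tax, level)
                Z, cats = _indicator(labels)
                if len(cats) < 2:
                    raise DegenerateModelError(f"level {level!r} has fewer than 2 groups")
                sizes = Z.sum(axis=0)
                if sizes.max() <= 1:
                    # every group is a singleton: intercepts are confounded
                    # with the residual, slopes are unidentifiable in practice
                    logger.info("dropping all-singleton random level %r", level)
                    self.dropped_levels.append(level)
                    continue
                if rs.intercepts:
                    self.blocks.append(
                        RandomBlock(name=f"{level}:intercept", Z=Z, kind="intercept")
                    )
                if rs.slopes:
                    self.blocks.append(
                        RandomBlock(
                            name=f"{level}:slope", Z=Z * w_std[:, None],
                            kind="slope", scale=w_sd,
                        )
                    )


def _fixed_table(design: _Design, fit: PLMMFit) -> pd.DataFrame:
    """Back-transform standardized coefficients to original units."""
    names = design.names
    p = len(names)
    T = np.eye(p)
    for j, name in enumerate(names[1:], start=1):
        sd = design.sds[name]
        mu = design.means[name]
        T[j, j] = 1.0 / sd
        T[0, j] = -mu / sd
    beta = T @ fit.beta
    cov = T @ fit.beta_cov @ T.T
    se = np.sqrt(np.diag(cov))
    df = max(fit.n_obs - fit.edf_total, 1.0)
    t = beta / se
    pvals = 2.0 * st.t.sf(np.abs(t), df)
    return pd.DataFrame({"estimate": beta, "se": se, "t": t, "p": pvals}, index=names)


def _smooth_estimates(design: _Design, fit: PLMMFit, n_grid: int = 100) -> dict[str, SmoothEstimate]:
    out: dict[str, SmoothEstimate] = {}
    for var, info in design.smooth_info.items():
        basis: PSplineBasis = info["basis"]
        block = info["block"]
        sl = fit.block_slices[block]
        p = len(design.names)
        j_lin = design.names.index(var)
        idx = np.concatenate([[j_lin], np.arange(p + sl.start, p + sl.stop)])
        grid = np.linspace(basis.x_lo, basis.x_hi, n_grid)
        g_lin = ((grid - design.means[var]) / design.sds[var])[:, None]
        G = np.column_stack([g_lin, basis.range_design(grid)])
        coefs = np.concatenate([[fit.beta[j_lin]], fit.b[sl]])
        f = G @ coefs
        # centre the displayed curve over the data, mgcv-style
        x_data = info["x"]
        Gd = np.column_stack(
            [((x_data - design.means[var]) / design.sds[var])[:, None],
             basis.range_design(x_data)]
        )
        f -= float(np.mean(Gd @ coefs))
        C = fit.theta_cov[np.ix_(idx, idx)]
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", G, C, G), 0.0))
        edf = 1.0 + fit.edf_blocks[block]
        curve = pd.DataFrame(
            {"x": grid, "fit": f, "se": se, "lower": f - 2 * se, "upper": f + 2 * se}
        )
        out[var] = SmoothEstimate(curve=curve, edf=edf)
    return out


def _random_sd_table(fit: PLMMFit) -> pd.DataFrame:
    """Variance components per level.

    ``sd`` is in the response/covariate's original units (slopes are per
    unit of the raw slope covariate); ``var_ratio`` is the dimensionless
    ratio of the component's variance to the residual variance, with slopes
    taken on the *standardized* covariate so that intercept and slope
    components are comparable to sigma^2.
    """
    rows = []
    for blk in fit.blocks:
        if blk.kind == "smooth":
            continue
        level, kind = blk.name.split(":")
        tau = np.sqrt(fit.tau2(blk.name)) / blk.scale
        rows.append(
            {"level": level, "kind": kind, "sd": tau, "var_ratio": fit.gamma[blk.name]}
        )
    return pd.DataFrame(rows, columns=["level", "kind", "sd", "var_ratio"])


def _assemble(design: _Design, fit: PLMMFit, spec: ModelSpec) -> ModelFit:
    return ModelFit(
        response=spec.response,
        fixed=_fixed_table(design, fit),
        smooths=_smooth_estimates(design, fit),
        random_sd=_random_sd_table(fit),
        dropped_levels=design.dropped_levels,
        sigma2=fit.sigma2,
        loglik=fit.loglik,
        aic=fit.aic,
        r_squared=fit.r_squared,
        edf_total=fit.edf_total,
        method=fit.method,
        converged=fit.converged,
        n_obs=fit.n_obs,
        fitted=fit.fitted,
        residuals=fit.residuals,
        y=fit.y,
    )


# ---------------------------------------------------------------------------
# public model fits
# ---------------------------------------------------------------------------

def fit_gam(
    spec: ModelSpec,
    data: pd.DataFrame,
    fixed_loggamma: np.ndarray | None = None,
) -> ModelFit:
    """Penalized-spline additive model without random effects.

    ``fixed_loggamma`` pins the smoothing parameter(s) (log variance-ratio
    scale; large = wiggly, very negative = approaches the OLS line) for
    penalty-limit diagnostics.
    """
    if spec.random_structure is not None:
        raise ContractViolation("use fit_gamm for models with random structure")
    design = _Design(spec, data, None)
    model = PLMM(design.X, design.y, design.blocks, fixed_names=design.names)
    fit = model.fit(method=spec.method, fixed_loggamma=fixed_loggamma)
    return _assemble(design, fit, spec)


def fit_gamm(spec: ModelSpec, data: pd.DataFrame, taxonomy: pd.DataFrame) -> ModelFit:
    """Additive model with nested random intercepts and %AT slopes.

    The hierarchy (phylum ⊃ genus ⊃ species/strain) comes from the taxonomy
    table; levels whose groups are all singletons are dropped with a notice.
    Non-convergence is flagged on the returned fit rather than raised.
    """
    if spec.random_structure is None:
        raise ContractViolation("fit_gamm requires a random structure")
    design = _Design(spec, data, taxonomy)
    model = PLMM(design.X, design.y, design.blocks, fixed_names=design.names)
    fit = model.fit(method=spec.method)
    return _assemble(design, fit, spec)


def fit_at_on_codons(profiles: pd.DataFrame, codon_columns: list[str] | None = None) -> "LinearFit":
    """OLS of genomic %AT on the 64 codon frequencies.

    The codon columns are exactly collinear (they sum to one), so the fit
    uses a rank-revealing pivoted QR; aliased columns are reported as such
    and excluded from estimation.
    """
    if codon_columns is None:
        codon_columns = [c for c in profiles.columns if c.startswith("codon_")]
    y = profiles["at_fraction"].to_numpy(dtype=float)
    Xraw = profiles[codon_columns].to_numpy(dtype=float)
    n = len(y)
    X1 = np.column_stack([np.ones(n), Xraw])
    names = ["(Intercept)"] + list(codon_columns)
    _, R, piv = sla.qr(X1, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag[0] * max(X1.shape) * np.finfo(float).eps
    rank = int(np.sum(diag > tol))
    if n <= rank:
        raise DegenerateModelError("n <= rank of the design")
    keep = sorted(piv[:rank])
    aliased = [names[j] for j in piv[rank:]]
    if aliased:
        logger.info("aliased codon terms: %s", aliased)
    if n < 66:
        logger.warning("fewer than 66 genomes: full rank cannot be attempted")
    ols = sm.OLS(y, X1[:, keep]).fit()
    table = pd.DataFrame(
        {"estimate": np.nan, "se": np.nan, "p": np.nan, "aliased": False}, index=names
    )
    kept_names = [names[j] for j in keep]
    table.loc[kept_names, "estimate"] = ols.params
    table.loc[kept_names, "se"] = ols.bse
    table.loc[kept_names, "p"] = ols.pvalues
    table.loc[aliased, "aliased"] = True
    return LinearFit(
        coefficients=table,
        r_squared=float(ols.rsquared),
        f_pvalue=float(ols.f_pvalue),
        rank=rank,
        n_obs=n,
        residuals=np.asarray(ols.resid),
    )


@dataclass
class LinearFit:
    coefficients: pd.DataFrame
    r_squared: float
    f_pvalue: float
    rank: int
    n_obs: int
    residuals: np.ndarray


@dataclass
class AnovaFit:
    r_squared: float
    f_pvalue: float
    group_means: pd.DataFrame   # phylum, n, mean_aaub — sorted descending

    def ranked_means(self, min_size: int = 20) -> pd.DataFrame:
        """Per-phylum mean AAUB restricted to phyla above a size threshold
        (supports "highest and lowest AAUB" queries)."""
        out = self.group_means[self.group_means["n"] > min_size]
        return out.reset_index(drop=True)


def fit_anova_aaub_phylum(aaub: pd.Series, taxonomy: pd.DataFrame) -> AnovaFit:
    """Dummy-coded OLS of AAUB on phylum plus ranked per-phylum means."""
    tax = taxonomy.set_index("genome_id")["phylum"]
    phyla = tax.reindex(aaub.index)
    if phyla.isna().any():
        raise ContractViolation("taxonomy missing for some genomes")
    if phyla.nunique() < 2:
        raise DegenerateModelError("phylum ANOVA requires at least 2 phyla")
    y = aaub.to_numpy(dtype=float)
    X = pd.get_dummies(phyla, drop_first=True, dtype=float).to_numpy()
    ols = sm.OLS(y, sm.add_constant(X)).fit()
    means = (
        pd.DataFrame({"phylum": phyla.to_numpy(), "aaub": y})
        .groupby("phylum")["aaub"]
        .agg(n="size", mean_aaub="mean")
        .reset_index()
        .sort_values("mean_aaub", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    return AnovaFit(
        r_squared=float(ols.rsquared),
        f_pvalue=float(ols.f_pvalue),
        group_means=means,
    )


def compare_aic(fit_a: ModelFit, fit_b: ModelFit, name_a: str = "a", name_b: str = "b") -> AicComparison:
    """Compare two fits of the same response by (ML) AIC; lower wins.

    The stored AIC always comes from a maximum-likelihood evaluation of the
    variance parameters, so REML-fitted models are comparable here too.
    """
    if fit_a.n_obs != fit_b.n_obs or not np.allclose(fit_a.y, fit_b.y):
        raise ContractViolation("fits must share the same response observations")
    if not (fit_a.converged and fit_b.converged):
        raise ContractViolation("non-converged fits are excluded from AIC comparison")
    delta = fit_a.aic - fit_b.aic
    if delta == 0:
        preferred = None
    else:
        preferred = name_a if delta < 0 else name_b
    return AicComparison(preferred=preferred, delta_aic=delta, aic_a=fit_a.aic, aic_b=fit_b.aic)


def fit_kl_vs_size(
    profiles: pd.DataFrame,
    taxonomy: pd.DataFrame,
    random_structure: RandomStructure | None = None,
) -> ModelFit:
    """GAMM of KL on genome size with the standard random structure.

    Genome size enters as a linear fixed effect; the p-value reported for
    the size term is the Wald t-test against zero.
    """
    if len(profiles) < 10:
        raise ContractViolation("fit_kl_vs_size requires at least 10 genomes")
    if float(np.ptp(profiles["genome_size"].to_numpy(dtype=float))) == 0.0:
        raise DegenerateModelError("genome size is constant")
    spec = ModelSpec(
        response="kl",
        linear_terms=["genome_size"],
        random_structure=random_structure or RandomStructure(),
        method="REML",
    )
    return fit_gamm(spec, profiles, taxonomy)
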