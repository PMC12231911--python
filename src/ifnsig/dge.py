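"""Per-dataset differential expression with empirical-Bayes variance moderation.

Each stimulation study is analysed separately: genes are filtered for minimal
expression, a common set of highly variable genes (HVGs) is chosen across
studies by summing per-study variance ranks, and a single linear model per
gene (treatment indicators plus optional dose/time covariates) is fitted by
ordinary least squares on ``log2(x + 1)`` expression.  Residual variances are
then shrunk towards a mean-expression-dependent prior with the classical
hierarchical F-model (the "eBayes with trend" moderation), and per-study
treatment contrasts (logFC, moderated SE) are emitted as the input for the
downstream network meta-analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

#: canonical condition labels; "other" arms are modelled but never contrasted
CONTROL = "control"
TREATMENTS = ("IFNa", "IFNb", "IFNg")
CONDITIONS = (CONTROL,) + TREATMENTS + ("other",)

#: low-expression cutoffs: a gene's total across samples must reach the
#: cutoff to be kept (10 for raw counts, 1 for normalized expression)
RAW_COUNT_TOTAL_MIN = 10.0
NORMALIZED_TOTAL_MIN = 1.0

#: span of the locally weighted linear smooth used for the variance trend
TREND_SPAN = 0.5


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class StimulationDataset:
    """One study: genes x samples expression (linear scale) + annotations.

    ``annotations`` is indexed by sample id and must provide a ``condition``
    column with values from :data:`CONDITIONS`; ``dose`` and ``time`` columns
    are optional numeric covariates (missing columns are treated as constant).
    """

    expression: pd.DataFrame
    annotations: pd.DataFrame
    dataset_id: str
    is_raw_counts: bool = False

    def __post_init__(self) -> None:
        if self.expression.index.duplicated().any():
            dupes = self.expression.index[self.expression.index.duplicated()].unique()
            raise ValueError(
                f"{self.dataset_id}: duplicate gene symbols: {list(dupes[:5])}"
            )
        missing = self.expression.columns.difference(self.annotations.index)
        if len(missing):
            raise ValueError(
                f"{self.dataset_id}: samples without annotation: {list(missing[:5])}"
            )
        self.annotations = self.annotations.loc[list(self.expression.columns)]
        if "condition" not in self.annotations:
            raise ValueError(f"{self.dataset_id}: annotations lack a 'condition' column")
        bad = set(self.annotations["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"{self.dataset_id}: unknown conditions {sorted(bad)}")
        if (self.annotations["condition"] == CONTROL).sum() == 0:
            raise ValueError(f"{self.dataset_id}: no control samples")

    @property
    def conditions(self) -> list[str]:
        """Conditions present, in canonical order."""
        present = set(self.annotations["condition"])
        return [c for c in CONDITIONS if c in present]

    def subset_genes(self, genes: pd.Index | list[str]) -> "StimulationDataset":
        return StimulationDataset(
            expression=self.expression.loc[genes],
            annotations=self.annotations,
            dataset_id=self.dataset_id,
            is_raw_counts=self.is_raw_counts,
        )


@dataclass
class ModelFit:
    """Per-gene OLS results for one study (log2 scale)."""

    dataset_id: str
    coefficients: pd.DataFrame          # genes x design columns
    sigma2: pd.Series                   # residual variance s^2 per gene
    df_residual: int                    # d, shared across genes
    amean: pd.Series                    # A: mean log2 expression per gene
    unscaled_cov: pd.DataFrame          # (X'X)^-1, design columns x columns
    condition_columns: dict[str, str]   # treatment -> design column name


@dataclass
class ModeratedFit:
    """Empirical-Bayes moderated variances layered on a :class:`ModelFit`.

    The hierarchical model takes s^2 ~ s_true^2 * chi^2_d / d with prior
    s_true^2 ~ s0^2 * d0 / chi^2_d0, giving the posterior (shrunken)
    variance  s~^2 = (d0*s0^2 + d*s^2) / (d0 + d).
    """

    fit: ModelFit
    s2_prior: pd.Series                 # s0^2(A), per gene (trend) or constant
    df_prior: float                     # d0 (may be inf)
    s2_post: pd.Series                  # s~^2 per gene

    @property
    def df_total(self) -> float:
        return self.df_prior + self.fit.df_residual


@dataclass
class ContrastEstimate:
    """One study's moderated effect for one gene and one condition pair.

    ``effect`` is the log2 fold change of ``a`` relative to ``b``
    (expression in a minus expression in b, log2 scale).
    """

    gene: str
    study: str
    a: str
    b: str
    effect: float
    se: float
    t: float = field(default=np.nan)
    p: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"degenerate comparison ({self.a}, {self.b})")
        if not np.isfinite(self.effect):
            raise ValueError(f"non-finite effect for {self.gene} in {self.study}")
        if not (self.se > 0):
            raise ValueError(f"non-positive SE for {self.gene} in {self.study}")


def contrasts_to_table(contrasts: list[ContrastEstimate]) -> pd.DataFrame:
    """Long-format table (gene, study, a, b, effect, se, t, p)."""
    return pd.DataFrame(
        [(c.gene, c.study, c.a, c.b, c.effect, c.se, c.t, c.p) for c in contrasts],
        columns=["gene", "study", "a", "b", "effect", "se", "t", "p"],
    )


# ---------------------------------------------------------------------------
# filtering and HVG selection
# ---------------------------------------------------------------------------

def filter_low_expression(dataset: StimulationDataset) -> StimulationDataset:
    """Drop genes whose total expression across samples is below the cutoff.

    The cutoff is 10 for raw counts and 1 for normalized expression; samples
    are untouched.  Raises if no gene survives.
    """
    threshold = RAW_COUNT_TOTAL_MIN if dataset.is_raw_counts else NORMALIZED_TOTAL_MIN
    totals = dataset.expression.sum(axis=1)
    keep = totals >= threshold
    if not keep.any():
        raise ValueError(f"{dataset.dataset_id}: no genes pass the expression filter")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "%s: removed %d lowly expressed genes (< %g total), %d retained",
            dataset.dataset_id, n_dropped, threshold, int(keep.sum()),
        )
    return dataset.subset_genes(dataset.expression.index[keep])


def select_hvg(datasets: list[StimulationDataset], n: int = 5000) -> list[str]:
    """Cross-study highly-variable-gene selection by additive variance ranks.

    Genes common to all studies are ranked per study by the variance of their
    log2(x+1) expression (rank m = most variable of m genes; ties get average
    ranks), ranks are summed across studies, and the ``n`` genes with the
    largest rank sums are returned (ties on the sum broken alphabetically for
    determinism).  All common genes are returned when fewer than ``n`` exist.
    """
    if not datasets:
        raise ValueError("no datasets given")
    if n < 1:
        raise ValueError("n must be >= 1")
    common = datasets[0].expression.index
    for ds in datasets[1:]:
        common = common.intersection(ds.expression.index)
    if len(common) == 0:
        raise ValueError("datasets share no genes")
    common = common.sort_values()
    rank_sum = pd.Series(0.0, index=common)
    for ds in datasets:
        log_expr = np.log2(ds.expression.loc[common] + 1.0)
        variances = log_expr.var(axis=1, ddof=1)
        rank_sum += variances.rank(method="average", ascending=True)
    order = pd.DataFrame({"rank_sum": rank_sum}).sort_values(
        by="rank_sum", ascending=False, kind="mergesort"
    )
    return list(order.index[: min(n, len(common))])


# ---------------------------------------------------------------------------
# linear models
# ---------------------------------------------------------------------------

def build_design(dataset: StimulationDataset) -> tuple[pd.DataFrame, dict[str, str]]:
    """Design matrix: intercept (control baseline), one indicator per
    non-control condition, and centered dose/time covariates when the study
    has more than one distinct value among stimulated samples.

    Returns (design, condition -> column name map).  Raises on rank
    deficiency, naming the collinear columns.
    """
    ann = dataset.annotations
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(ann))}
    condition_columns: dict[str, str] = {}
    for cond in dataset.conditions:
        if cond == CONTROL:
            continue
        name = f"cond_{cond}"
        cols[name] = (ann["condition"] == cond).to_numpy(float)
        condition_columns[cond] = name
    treated = ann["condition"] != CONTROL
    for covar in ("dose", "time"):
        if covar not in ann:
            continue
        values = pd.to_numeric(ann[covar], errors="coerce").fillna(0.0)
        if values[treated].nunique() > 1:
            cols[covar] = (values - values.mean()).to_numpy(float)
    design = pd.DataFrame(cols, index=ann.index)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # pivoted QR: the trailing pivots index the dependent columns
        from scipy.linalg import qr as scipy_qr

        _, _, pivot = scipy_qr(design.to_numpy(), pivoting=True)
        dependent = sorted(design.columns[j] for j in pivot[rank:])
        raise ValueError(
            f"{dataset.dataset_id}: rank-deficient design "
            f"(rank {rank} < {design.shape[1]}); collinear columns: {dependent}"
        )
    return design, condition_columns


def fit_linear_models(
    dataset: StimulationDataset, genes: list[str] | pd.Index | None = None
) -> ModelFit:
    """OLS per gene on log2(expression + 1).

    All genes share one design matrix, so the fit is a single least-squares
    solve; residual df must be >= 1.
    """
    if genes is None:
        genes = dataset.expression.index
    missing = pd.Index(genes).difference(dataset.expression.index)
    if len(missing):
        raise ValueError(f"{dataset.dataset_id}: genes absent: {list(missing[:5])}")
    expr = dataset.expression.loc[genes]
    design, condition_columns = build_design(dataset)
    x = design.to_numpy()
    y = np.log2(expr.to_numpy(float) + 1.0)  # genes x samples
    n, p = x.shape
    df_residual = n - p
    if df_residual < 1:
        raise ValueError(
            f"{dataset.dataset_id}: zero residual degrees of freedom "
            f"({n} samples, {p} coefficients)"
        )
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = y @ x @ xtx_inv.T  # genes x p
    residuals = y - beta @ x.T
    sigma2 = (residuals**2).sum(axis=1) / df_residual
    return ModelFit(
        dataset_id=dataset.dataset_id,
        coefficients=pd.DataFrame(beta, index=expr.index, columns=design.columns),
        sigma2=pd.Series(sigma2, index=expr.index),
        df_residual=df_residual,
        amean=pd.Series(y.mean(axis=1), index=expr.index),
        unscaled_cov=pd.DataFrame(xtx_inv, index=design.columns, columns=design.columns),
        condition_columns=condition_columns,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def moderate_variances(fit: ModelFit, trend: bool = True) -> ModeratedFit:
    """Shrink per-gene residual variances towards an empirical prior.

    Moment matching on the log scale: with e = log(s^2) - digamma(d/2) +
    log(d/2), the prior location is a locally weighted linear smooth of e on
    mean log2 expression A (trend=True) or its mean (trend=False), and the
    prior df d0 solves trigamma(d0/2) = var(e - fit) - trigamma(d/2).  The
    posterior variance is the df-weighted convex combination of s^2 and
    s0^2.  Falls back to a constant prior with a warning when the moment
    equations fail.
    """
    n_genes = len(fit.sigma2)
    if n_genes < 10:
        raise ValueError("variance moderation needs at least 10 genes")
    d = float(fit.df_residual)
    s2 = fit.sigma2.to_numpy(float)
    # guard exact zeros (noiseless fixtures) before taking logs
    positive = s2[s2 > 0]
    floor = positive.min() * 1e-12 if len(positive) else 1e-300
    z = np.log(np.maximum(s2, floor))
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)

    if trend:
        a = fit.amean.to_numpy(float)
        if np.ptp(a) > 0:
            # no robustifying iterations: e is left-skewed (log chi-square),
            # and robust reweighting would bias the prior variance upwards
            efit = lowess(e, a, frac=TREND_SPAN, it=0, return_sorted=False)
        else:
            efit = np.full(n_genes, e.mean())
    else:
        efit = np.full(n_genes, e.mean())

    resid_var = float(np.mean((e - efit) ** 2)) * n_genes / max(n_genes - 1, 1)
    excess = resid_var - float(special.polygamma(1, d / 2.0))
    if excess > 0:
        df_prior = 2.0 * _trigamma_inverse(excess)
        if not np.isfinite(df_prior) or df_prior <= 0:
            logger.warning("%s: prior df estimation failed; using constant prior",
                           fit.dataset_id)
            df_prior = np.inf
    else:
        df_prior = np.inf

    use_trend = trend and np.ptp(fit.amean.to_numpy(float)) > 0
    if np.isfinite(df_prior):
        s2_prior = np.exp(
            efit + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0)
        )
        s2_post = (df_prior * s2_prior + d * s2) / (df_prior + d)
    else:
        # infinite prior df: the trend fit is already an average over many
        # genes, so exp(efit) is consistent for the true variance; without a
        # trend the arithmetic mean of s^2 is the natural scale estimate
        # (it is exact when every gene shares the same s^2)
        s2_prior = np.exp(efit) if use_trend else np.full(n_genes, s2.mean())
        s2_post = s2_prior.copy()

    return ModeratedFit(
        fit=fit,
        s2_prior=pd.Series(s2_prior, index=fit.sigma2.index),
        df_prior=df_prior,
        s2_post=pd.Series(s2_post, index=fit.sigma2.index),
    )


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

def compute_contrasts(
    moderated: ModeratedFit, dataset: StimulationDataset
) -> list[ContrastEstimate]:
    """Moderated effects for every condition pair present in the study.

    Emits each treatment vs control and each treatment vs treatment pair
    (among IFNa/IFNb/IFNg; "other" arms only stabilise the fit).  Effects are
    coefficient differences; SEs come from the unscaled coefficient
    covariance scaled by the posterior variance.  Moderated t uses d0 + d
    degrees of freedom.
    """
    fit = moderated.fit
    cond_cols = fit.condition_columns
    present = [c for c in dataset.conditions if c in (CONTROL,) + TREATMENTS]
    treatments = [c for c in present if c != CONTROL]
    p = fit.unscaled_cov.shape[0]
    col_index = {name: i for i, name in enumerate(fit.unscaled_cov.columns)}
    cov = fit.unscaled_cov.to_numpy()

    pairs: list[tuple[str, str]] = [(t, CONTROL) for t in treatments]
    pairs += [
        (treatments[i], treatments[j])
        for i in range(len(treatments))
        for j in range(len(treatments))
        if i != j
    ]

    df_total = moderated.df_total
    contrasts: list[ContrastEstimate] = []
    for a, b in pairs:
        c = np.zeros(p)
        if a != CONTROL:
            c[col_index[cond_cols[a]]] += 1.0
        if b != CONTROL:
            c[col_index[cond_cols[b]]] -= 1.0
        unscaled_var = float(c @ cov @ c)
        effects = fit.coefficients.to_numpy() @ c
        ses = np.sqrt(unscaled_var * moderated.s2_post.to_numpy())
        tvals = np.where(ses > 0, effects / np.where(ses > 0, ses, 1.0), np.nan)
        if np.isfinite(df_total):
            pvals = 2.0 * stats.t.sf(np.abs(tvals), df_total)
        else:
            pvals = 2.0 * stats.norm.sf(np.abs(tvals))
        for g, eff, se, t, pv in zip(
            fit.coefficients.index, effects, ses, tvals, pvals
        ):
            contrasts.append(
                ContrastEstimate(
                    gene=g, study=fit.dataset_id, a=a, b=b,
                    effect=float(eff), se=float(se), t=float(t), p=float(pv),
                )
            )
    return contrasts


def run_dge(
    datasets: list[StimulationDataset],
    n_hvg: int = 5000,
    trend: bool = True,
) -> pd.DataFrame:
    """Full DGE stage: filter, HVG-select, fit, moderate, contrast.

    Returns the pooled long-format contrast table across studies.
    """
    filtered = [filter_low_expression(ds) for ds in datasets]
    hvgs = select_hvg(filtered, n=n_hvg)
    logger.info("selected %d highly variable genes across %d studies",
                len(hvgs), len(filtered))
    all_contrasts: list[ContrastEstimate] = []
    for ds in filtered:
        fit = fit_linear_models(ds, hvgs)
        moderated = moderate_variances(fit, trend=trend)
        all_contrasts.extend(compute_contrasts(moderated, ds))
    return contrasts_to_table(all_contrasts)
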