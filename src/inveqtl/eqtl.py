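"""Allele-dosage cis-eQTL analysis.

Each expression probe in the cis window is regressed on the per-individual
H1-haplotype count (H1/H1 = 2, H1/H2 = 1, H2/H2 = 0) together with
covariates, by ordinary least squares. The dosage coefficient B is the
change in log2 expression per H1 copy; significance is controlled
family-wise by Bonferroni over the probes tested in a dataset. Tissues
(e.g. separate brain regions) are tested independently, each with its own
Bonferroni m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genio import ExpressionTable, GenomicInterval, select_region
from .invcall import InversionCalls

logger = logging.getLogger(__name__)

_RESID_TOL = 1e-10  # relative residual variance below this counts as a perfect fit


@dataclass
class AssociationResult:
    probe_id: str
    tissue: str
    n: int
    B: float
    SE: float
    t: float
    ci95: tuple[float, float]
    p: float
    significant: bool = False


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha/m; comparisons use full precision."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"m must be a positive integer, got {m}")
    return alpha / m


def format_threshold(threshold: float) -> str:
    """Display form, rounded to 2 significant figures (reporting only)."""
    return f"{threshold:.2g}"


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns (individuals) to a common distribution.

    Each column is mapped onto the reference distribution obtained by
    averaging the column-wise sorted values. Tied cells receive the mean of
    the reference quantiles their rank range spans. A single column is
    returned unchanged (its sorted values are the reference).
    """
    mat = values.to_numpy(float)
    n_rows, n_cols = mat.shape
    if n_rows == 0 or n_cols == 0:
        return values.copy()
    ref = np.sort(mat, axis=0).mean(axis=1)
    csum = np.concatenate([[0.0], np.cumsum(ref)])
    out = np.empty_like(mat)
    for j in range(n_cols):
        col = mat[:, j]
        rmin = stats.rankdata(col, method="min").astype(int)
        rmax = stats.rankdata(col, method="max").astype(int)
        out[:, j] = (csum[rmax] - csum[rmin - 1]) / (rmax - rmin + 1)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def preprocess_expression(
    raw: ExpressionTable,
    mode: str,
    detection_threshold: float | None = None,
    log2_transform: bool = True,
    quantile: bool = True,
) -> ExpressionTable:
    """Detection-filter, log2-transform and quantile-normalize expression.

    ``mode='blood'`` keeps probes with mean detection value above the
    threshold (default 0.90); ``mode='brain'`` keeps probes whose detection
    p-value is below the threshold (default 0.01), applied per region.
    Intensities must be positive before the log2 step; pass
    ``log2_transform=False`` for data already on the log2 scale and
    ``quantile=False`` for data already normalized across individuals.
    Quantile normalization assumes the probe set is large enough that no
    single probe shifts an individual's distribution — with only a handful
    of probes a strong genotype effect at one probe leaks into the others.
    """
    if mode == "blood":
        thr = 0.90 if detection_threshold is None else detection_threshold
        keep = (raw.detection > thr).to_numpy()
    elif mode == "brain":
        thr = 0.01 if detection_threshold is None else detection_threshold
        keep = (raw.detection < thr).to_numpy()
    else:
        raise ValueError(f"mode must be 'blood' or 'brain', got {mode!r}")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("preprocess_expression(%s): removed %d probes by detection filter",
                    mode, n_dropped)
    table = raw.subset_probes(keep)
    vals = table.values
    if log2_transform:
        if (vals.to_numpy() <= 0).any():
            raise ValueError("non-positive intensity encountered before log2 transform")
        vals = np.log2(vals)
    if quantile:
        vals = quantile_normalize(vals)
    return ExpressionTable(vals, table.probe_meta.copy(), table.detection.copy())


def _design_matrix(dosage: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    cols = [np.ones_like(dosage, dtype=float), dosage.astype(float)]
    if covariates is not None and covariates.size:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != dosage.size:
            cov = cov.T
        cols.extend(cov.T)
    return np.column_stack(cols)


def _drop_collinear(x: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Greedily drop trailing columns until the design has full column rank."""
    keep = list(range(x.shape[1]))
    while len(keep) > 2 and np.linalg.matrix_rank(x[:, keep]) < len(keep):
        for j in reversed(keep[2:]):  # never drop intercept or dosage
            trial = [c for c in keep if c != j]
            if np.linalg.matrix_rank(x[:, trial]) == np.linalg.matrix_rank(x[:, keep]):
                keep = trial
                break
        else:
            break
    dropped = [j for j in range(x.shape[1]) if j not in keep]
    return x[:, keep], dropped


def fit_dosage_model(
    y: np.ndarray,
    dosage: np.ndarray,
    covariates: np.ndarray | None = None,
    probe_id: str = "",
    tissue: str = "",
) -> AssociationResult:
    """OLS of expression on [intercept, H1 dosage, covariates].

    B is the dosage coefficient; the two-sided p comes from the t
    distribution with n - k - 1 residual degrees of freedom (k predictors
    beside the intercept) and the 95% CI is B +/- t_{0.975, df} * SE.
    A perfect fit (zero residual variance) reports SE = 0 and p = 0 with a
    logged warning. Collinear covariate columns are dropped with a warning
    and the model refit.
    """
    y = np.asarray(y, float)
    dosage = np.asarray(dosage, float)
    if np.unique(dosage).size < 2:
        raise ValueError("no genotype variance: dosage is constant")
    x = _design_matrix(dosage, covariates)
    n = y.size
    if n <= x.shape[1]:
        raise ValueError(f"n={n} too small for {x.shape[1]} model parameters")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        x, dropped = _drop_collinear(x)
        logger.warning("fit_dosage_model: dropped collinear covariate columns %s", dropped)
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    rss = float(resid @ resid)
    df = n - x.shape[1]
    b = float(beta[1])
    scale = max(float(y @ y), 1.0)
    if rss <= _RESID_TOL * scale:
        logger.warning("fit_dosage_model: zero residual variance (perfect fit) for %s",
                       probe_id or "probe")
        return AssociationResult(probe_id, tissue, n, b, 0.0,
                                 float(np.inf * np.sign(b)) if b != 0 else 0.0,
                                 (b, b), 0.0)
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(x.T @ x)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    t_stat = b / se
    p = float(2 * stats.t.sf(abs(t_stat), df))
    half = float(stats.t.ppf(0.975, df) * se)
    return AssociationResult(probe_id, tissue, n, b, se, float(t_stat),
                             (b - half, b + half), p)


def run_cis_eqtl(
    expr: ExpressionTable,
    calls: InversionCalls,
    covariates: pd.DataFrame | None,
    cis: GenomicInterval,
    tissue: str = "tissue",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every cis probe for an H1-dosage effect in one tissue.

    Individuals are joined by ID across the expression, call and covariate
    tables; EXCLUDED individuals and individuals with missing covariates are
    dropped (listwise). Categorical covariates are one-hot encoded with the
    first level dropped. Significance flags use the Bonferroni threshold
    alpha / m with m the number of probes tested in this dataset.
    """
    cis_expr = select_region(expr, cis)
    if cis_expr.values.shape[0] == 0:
        logger.warning("run_cis_eqtl: no probes overlap the cis interval")
        return pd.DataFrame(columns=[
            "probe_id", "gene", "tissue", "n", "B", "SE", "t",
            "CI_low", "CI_high", "p", "significant",
        ])

    call_df = pd.DataFrame(
        {"dosage": calls.dosage}, index=pd.Index(calls.individual_ids)
    )
    call_df = call_df[call_df["dosage"] >= 0]
    ids = [i for i in cis_expr.individual_ids if i in call_df.index]
    cov_mat = None
    if covariates is not None and len(covariates.columns):
        cov = covariates.apply(
            lambda c: c if np.issubdtype(c.dtype, np.number) else c.astype("category")
        )
        cov = pd.get_dummies(cov, drop_first=True, dtype=float)
        cov = cov.dropna()
        ids = [i for i in ids if i in cov.index]
        cov_mat = cov.loc[ids].to_numpy(float)
    dosage = call_df.loc[ids, "dosage"].to_numpy(float)
    if np.unique(dosage).size < 2:
        raise ValueError("calls contain fewer than 2 genotype classes among joined individuals")

    y_mat = cis_expr.values[ids].to_numpy(float)
    m = y_mat.shape[0]
    threshold = bonferroni_threshold(alpha, m)
    rows = []
    genes = cis_expr.probe_meta.set_index("probe_id")["gene"]
    for i, probe_id in enumerate(cis_expr.values.index):
        res = fit_dosage_model(y_mat[i], dosage, cov_mat, probe_id=probe_id, tissue=tissue)
        rows.append(
            {
                "probe_id": probe_id,
                "gene": genes.get(probe_id, ""),
                "tissue": tissue,
                "n": res.n,
                "B": res.B,
                "SE": res.SE,
                "t": res.t,
                "CI_low": res.ci95[0],
                "CI_high": res.ci95[1],
                "p": res.p,
                "significant": res.p < threshold,
            }
        )
    return pd.DataFrame(rows)
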