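"""Inferential layer: covariate-adjusted linear and mixed-effects models with
likelihood-ratio model selection, bias-corrected accelerated (BCa) bootstrap
mediation, the memory principal-component composite, and Holm-Bonferroni
multiple-comparison correction.

Mediation follows the product-of-coefficients approach for linear models:
``a`` from mediator ~ predictor + covariates, ``b`` and the direct effect
``c'`` from outcome ~ predictor + mediator + covariates; the indirect
effect is ``a*b`` and, with a common covariate set, satisfies the exact
identity ``total = c' + a*b``.  Confidence intervals are nonparametric
case-resampling bootstrap with BCa correction (bias term z0 from the share
of bootstrap draws below the point estimate; acceleration from the
jackknife skewness).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.special import ndtr, ndtri
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning


@dataclass
class ModelSpec:
    """Declarative model description used by the fitting front-ends."""

    outcome: str
    fixed_effects: list[str]
    random_intercept: str | None = None
    covariates: list[str] = field(default_factory=list)
    standardize: bool = False

    @property
    def formula(self) -> str:
        terms = list(self.fixed_effects) + list(self.covariates)
        return f"{self.outcome} ~ {' + '.join(terms) if terms else '1'}"

    def columns(self) -> list[str]:
        import re

        cols = {self.outcome}
        for term in self.fixed_effects + self.covariates:
            for piece in re.split(r"[\s*:+()]+", term):
                if piece and piece not in {"C", "1", "0"}:
                    cols.add(piece)
        if self.random_intercept:
            cols.add(self.random_intercept)
        return sorted(cols)


def _prepare(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    cols = [c for c in spec.columns() if c in data.columns]
    missing = [c for c in spec.columns() if c not in data.columns]
    if missing:
        raise KeyError(f"model references missing columns: {missing}")
    df = data[cols].dropna().copy()
    if len(df) < len(data):
        warnings.warn(
            f"dropped {len(data) - len(df)} incomplete cases for {spec.outcome}",
            stacklevel=3,
        )
    if spec.standardize:
        for c in cols:
            if c == spec.random_intercept:
                continue
            if pd.api.types.is_numeric_dtype(df[c]) and df[c].nunique() > 2:
                sd = df[c].std(ddof=1)
                if sd > 0:
                    df[c] = (df[c] - df[c].mean()) / sd
    return df


def _tidy(res, model_name: str = "") -> pd.DataFrame:
    out = pd.DataFrame(
        {
            "term": res.params.index,
            "estimate": res.params.to_numpy(),
            "se": res.bse.to_numpy(),
            "stat": res.tvalues.to_numpy(),
            "p": res.pvalues.to_numpy(),
        }
    )
    out.insert(0, "model", model_name)
    return out


def fit_linear_model(data: pd.DataFrame, spec: ModelSpec, name: str = "ols"):
    """OLS fit of a :class:`ModelSpec`; returns (tidy table, results object).

    When ``spec.standardize`` is set, the outcome and continuous predictors
    are z-scored before fitting, giving standardized coefficients.
    """
    if spec.random_intercept is not None:
        raise ValueError("use fit_mixed_model for random-intercept specs")
    df = _prepare(data, spec)
    res = smf.ols(spec.formula, data=df).fit()
    return _tidy(res, name), res


def fit_mixed_model(
    data: pd.DataFrame, spec: ModelSpec, reml: bool = True, name: str = "lme"
):
    """Random-intercept linear mixed model fitted by (RE)ML.

    Fixed-effect p-values are large-sample Wald z tests (the method is
    recorded on the tidy table); a singular random-effect fit is flagged on
    the table, not raised.
    """
    if spec.random_intercept is None:
        raise ValueError("spec has no random_intercept")
    df = _prepare(data, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = smf.mixedlm(spec.formula, data=df, groups=df[spec.random_intercept])
        res = None
        # the default optimizer occasionally under-converges on ML fits;
        # try a second one and keep the better likelihood
        for method in (None, "powell"):
            try:
                cand = model.fit(reml=reml, method=method)
            except Exception:
                continue
            if res is None or (np.isfinite(cand.llf) and cand.llf > res.llf):
                res = cand
        if res is None:
            raise RuntimeError(f"mixed model failed to fit: {spec.formula}")
    tidy = _tidy(res, name)
    tidy["p_method"] = "wald-z"
    tidy["singular"] = bool(res.cov_re.values.min() < 1e-8)
    return tidy, res


def _n_params(res) -> int:
    k = len(np.asarray(res.params))
    # MixedLM params exclude variance components; count them for the LRT df
    if hasattr(res, "cov_re"):
        k += res.cov_re.shape[0] + 1  # random-intercept variance + residual
    return k


def lrt_select(nested_res, full_res, alpha: float = 0.05) -> dict:
    """Likelihood-ratio test between nested model fits (plain ML).

    Returns the chi-square statistic, degrees of freedom, p-value, and
    ``keep_full`` (p < alpha).
    """
    df = _n_params(full_res) - _n_params(nested_res)
    if df < 0:
        raise ValueError("models are not nested (full model must add parameters)")
    if df == 0:
        return {"stat": 0.0, "df": 0, "p": 1.0, "keep_full": False}
    stat = 2.0 * (full_res.llf - nested_res.llf)
    note = None
    if stat < -1e-6:
        # the optimizer failed to improve on the nested solution (seen
        # occasionally with mixed-model ML fits); the evidence for the
        # added terms is nil, so clamp and flag rather than abort
        note = "full-model fit not better than nested; statistic clamped to 0"
        warnings.warn(note, stacklevel=2)
    stat = max(stat, 0.0)
    p = float(chi2.sf(stat, df))
    out = {"stat": float(stat), "df": int(df), "p": p, "keep_full": p < alpha}
    if note:
        out["note"] = note
    return out


# ---------------------------------------------------------------------------
# mediation


@dataclass
class MediationResult:
    a: float
    b: float
    c_prime: float
    indirect: float
    total: float
    ci: dict[str, tuple[float, float]]
    prop_mediated: float
    p_indirect: float
    n_boot: int
    seed: int
    n: int
    z0: dict[str, float]
    accel: dict[str, float]
    prop_mediated_warning: bool = False

    def as_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "c_prime": self.c_prime,
            "indirect": self.indirect, "total": self.total,
            "ci_indirect": list(self.ci["indirect"]),
            "ci_direct": list(self.ci["direct"]),
            "ci_total": list(self.ci["total"]),
            "prop_mediated": self.prop_mediated,
            "p_indirect": self.p_indirect,
            "n_boot": self.n_boot, "n": self.n,
        }


def _paths_from_xy(xa, ya, xb, yb) -> tuple[float, float, float, float]:
    """(a, b, c_prime, total) from precomputed design matrices."""
    beta_a = np.linalg.lstsq(xa, ya, rcond=None)[0]
    beta_b = np.linalg.lstsq(xb, yb, rcond=None)[0]
    a = beta_a[1]
    b = beta_b[2]
    c_prime = beta_b[1]
    return float(a), float(b), float(c_prime), float(a * b + c_prime)


def _batched_paths(xa, ya, xb, yb, idx: np.ndarray) -> np.ndarray:
    """Vectorized path estimates for bootstrap index matrix ``idx`` (B, n).

    Returns array (B, 3): a, b, c_prime per draw.
    """
    out = np.empty((idx.shape[0], 3))
    xa_b = xa[idx]  # (B, n, pa)
    xb_b = xb[idx]
    ya_b = ya[idx]
    yb_b = yb[idx]
    ga = np.einsum("bnp,bnq->bpq", xa_b, xa_b)
    gb = np.einsum("bnp,bnq->bpq", xb_b, xb_b)
    ra = np.einsum("bnp,bn->bp", xa_b, ya_b)
    rb = np.einsum("bnp,bn->bp", xb_b, yb_b)
    # pseudo-inverse: degenerate resamples (e.g. a constant binary covariate
    # in a bootstrap draw) get the minimum-norm solution instead of raising
    beta_a = (np.linalg.pinv(ga) @ ra[..., None])[..., 0]
    beta_b = (np.linalg.pinv(gb) @ rb[..., None])[..., 0]
    out[:, 0] = beta_a[:, 1]
    out[:, 1] = beta_b[:, 2]
    out[:, 2] = beta_b[:, 1]
    return out


def _bca_interval(theta_boot: np.ndarray, theta_hat: float, theta_jack: np.ndarray,
                  alpha: float) -> tuple[tuple[float, float], float, float]:
    b = len(theta_boot)
    below = np.sum(theta_boot < theta_hat) + 0.5 * np.sum(theta_boot == theta_hat)
    prop = np.clip(below / b, 1.0 / (b + 1), 1.0 - 1.0 / (b + 1))
    z0 = ndtri(prop)
    jm = theta_jack.mean()
    num = np.sum((jm - theta_jack) ** 3)
    den = 6.0 * np.sum((jm - theta_jack) ** 2) ** 1.5
    accel = num / den if den > 0 else 0.0
    lo_hi = []
    for z_alpha in (ndtri(alpha / 2), ndtri(1 - alpha / 2)):
        adj = z0 + (z0 + z_alpha) / (1.0 - accel * (z0 + z_alpha))
        q = np.clip(ndtr(adj), 0.0, 1.0)
        lo_hi.append(float(np.quantile(theta_boot, q)))
    return (lo_hi[0], lo_hi[1]), float(z0), float(accel)


def mediate_bca(
    data: pd.DataFrame,
    predictor: str,
    mediator: str,
    outcome: str,
    covariates: tuple[str, ...] = (),
    n_boot: int = 5000,
    seed: int | None = None,
    standardize: bool = True,
    alpha: float = 0.05,
) -> MediationResult:
    """Product-of-coefficients mediation with BCa bootstrap intervals.

    Case resampling at the subject (row) level; 5,000 bootstrap samples by
    default.  The proportion mediated is indirect / (indirect + direct) and
    is flagged (not suppressed) when outside [0, 1].
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    cols = [predictor, mediator, outcome, *covariates]
    df = data[cols].dropna()
    n = len(df)
    if n < 10:
        raise ValueError("too few complete cases for mediation")
    arr = df.to_numpy(dtype=float)
    if standardize:
        sd = arr.std(axis=0, ddof=1)
        binary = np.array([df[c].nunique() <= 2 for c in cols])
        scale = np.where(binary | (sd == 0), 1.0, sd)
        center = np.where(binary, 0.0, arr.mean(axis=0))
        arr = (arr - center) / scale

    x = arr[:, 0]
    m = arr[:, 1]
    y = arr[:, 2]
    cov = arr[:, 3:]
    ones = np.ones(n)
    xa = np.column_stack([ones, x, cov])  # mediator model design
    xb = np.column_stack([ones, x, m, cov])  # outcome model design

    a, b, c_prime, total = _paths_from_xy(xa, m, xb, y)
    indirect = a * b

    rng = np.random.default_rng(seed)
    # chunk the bootstrap to bound memory at large n
    chunk = max(1, int(4_000_000 / max(n, 1)))
    parts = []
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(b, n))
        parts.append(_batched_paths(xa, m, xb, y, idx))
        done += b
    paths = np.concatenate(parts, axis=0)
    boot = {
        "indirect": paths[:, 0] * paths[:, 1],
        "direct": paths[:, 2],
        "total": paths[:, 0] * paths[:, 1] + paths[:, 2],
    }
    if np.ptp(boot["indirect"]) == 0:
        raise RuntimeError("degenerate bootstrap: all indirect-effect draws identical")

    jack_idx = np.stack([np.delete(np.arange(n), i) for i in range(n)])
    jp = _batched_paths(xa, m, xb, y, jack_idx)
    jack = {
        "indirect": jp[:, 0] * jp[:, 1],
        "direct": jp[:, 2],
        "total": jp[:, 0] * jp[:, 1] + jp[:, 2],
    }
    point = {"indirect": indirect, "direct": c_prime, "total": total}
    ci, z0s, accels = {}, {}, {}
    for key in ("indirect", "direct", "total"):
        ci[key], z0s[key], accels[key] = _bca_interval(
            boot[key], point[key], jack[key], alpha
        )

    p_lower = np.mean(boot["indirect"] <= 0)
    p_indirect = float(2 * min(p_lower, 1 - p_lower))

    denom = indirect + c_prime
    prop = indirect / denom if denom != 0 else np.nan
    warn = not (0.0 <= prop <= 1.0) if np.isfinite(prop) else True
    if warn:
        warnings.warn(
            "proportion mediated outside [0, 1]; interpret with caution "
            "(effects of opposite sign or near-zero total)",
            stacklevel=2,
        )
    return MediationResult(
        a=a, b=b, c_prime=c_prime, indirect=indirect, total=total, ci=ci,
        prop_mediated=float(prop), p_indirect=p_indirect, n_boot=n_boot,
        seed=seed, n=n, z0=z0s, accel=accels, prop_mediated_warning=warn,
    )


# ---------------------------------------------------------------------------
# memory composite and multiple testing


@dataclass
class CompositeResult:
    scores: np.ndarray
    share: float
    loadings: np.ndarray
    columns: list[str]
    sign_flipped: bool


def pca_composite(scores: pd.DataFrame) -> CompositeResult:
    """First principal component of the z-scored memory battery.

    Eigendecomposition of the correlation matrix; loadings are the
    unit-norm first eigenvector with sign chosen so the mean loading is
    positive; the share is its eigenvalue over the number of tasks.
    """
    df = scores.dropna()
    if len(df) < 2:
        raise ValueError("need at least 2 complete rows")
    sd = df.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant columns: {constant}")
    z = (df - df.mean()) / sd
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    vals, vecs = np.linalg.eigh(corr)
    v = vecs[:, -1]
    flipped = v.mean() < 0
    if flipped:
        v = -v
    return CompositeResult(
        scores=z.to_numpy() @ v,
        share=float(vals[-1] / corr.shape[0]),
        loadings=v,
        columns=list(df.columns),
        sign_flipped=bool(flipped),
    )


def holm_correct(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Holm-Bonferroni adjustment.

    Returns (adjusted p-values, reject flags with adjusted p < alpha).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a nonempty 1D sequence")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return p_adj, p_adj < alpha


# ---------------------------------------------------------------------------
# the full model battery


def _connectivity_long(records: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    long = records.melt(
        id_vars=["subject_id", "condition"],
        value_vars=["z_fpn", "z_dmn"],
        var_name="target", value_name="z",
    )
    long["target"] = long["target"].str.replace("z_", "").str.upper()
    return long.merge(subjects, on="subject_id")


def run_paper_models(
    records: pd.DataFrame,
    subjects: pd.DataFrame,
    n_boot: int = 5000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> dict:
    """Execute the study's model battery on a connectivity-record table.

    Battery, in order: rest mixed model (age x target, LRT-selected
    interaction); task mixed model (age x target with load, LRT-selected);
    covariate-adjusted regressions of differentiation on binding potential;
    BCa mediation of the age effect through binding potential (rest via
    caudate, task via prefrontal); memory-composite regression on rest
    differentiation with an age interaction; Holm correction over the
    post-hoc coefficient block.  Returns a results bundle (dict of tidy
    tables and result objects).
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    bundle: dict = {}
    subjects = subjects.copy()
    subjects["age_z"] = (subjects["age"] - subjects["age"].mean()) / subjects["age"].std(ddof=1)

    rest = records[records["condition"] == "rest"]
    task = records[records["condition"] != "rest"]
    long = _connectivity_long(records, subjects)

    # --- rest mixed model: age x target, interaction kept on LRT
    rest_long = long[long["condition"] == "rest"]
    base_spec = ModelSpec("z", ["age_z", "target"], random_intercept="subject_id")
    full_spec = ModelSpec("z", ["age_z * target"], random_intercept="subject_id")
    _, base_ml = fit_mixed_model(rest_long, base_spec, reml=False)
    _, full_ml = fit_mixed_model(rest_long, full_spec, reml=False)
    rest_lrt = lrt_select(base_ml, full_ml, alpha)
    spec = full_spec if rest_lrt["keep_full"] else base_spec
    bundle["rest_lme"], _ = fit_mixed_model(rest_long, spec, name="rest_lme")
    bundle["rest_lme_lrt"] = rest_lrt

    # --- task mixed model: age x target with load, three-way tested by LRT
    task_long = long[long["condition"] != "rest"].copy()
    task_long["load"] = task_long["condition"].str.extract(r"(\d)").astype(int)
    base_spec = ModelSpec("z", ["age_z * target", "load"], random_intercept="subject_id")
    full_spec = ModelSpec("z", ["age_z * target * load"], random_intercept="subject_id")
    _, base_ml = fit_mixed_model(task_long, base_spec, reml=False)
    _, full_ml = fit_mixed_model(task_long, full_spec, reml=False)
    task_lrt = lrt_select(base_ml, full_ml, alpha)
    spec = full_spec if task_lrt["keep_full"] else base_spec
    bundle["task_lme"], _ = fit_mixed_model(task_long, spec, name="task_lme")
    bundle["task_lme_lrt"] = task_lrt

    # --- differentiation ~ binding potential + covariates
    rest_sub = rest.merge(subjects, on="subject_id")
    bundle["rest_diff_model"], _ = fit_linear_model(
        rest_sub,
        ModelSpec("differentiation", ["bp_caudate"],
                  covariates=["age", "sex", "mean_fd"], standardize=True),
        name="rest_diff~bp_caudate",
    )
    task_mean = (
        task.groupby("subject_id", as_index=False)["differentiation"].mean()
        .merge(subjects, on="subject_id")
    )
    bundle["task_diff_model"], _ = fit_linear_model(
        task_mean,
        ModelSpec("differentiation", ["bp_pfc"],
                  covariates=["age", "sex", "mean_fd"], standardize=True),
        name="task_diff~bp_pfc",
    )

    # --- mediation: age -> binding potential -> differentiation
    bundle["mediation_rest"] = mediate_bca(
        rest_sub, "age", "bp_caudate", "differentiation",
        covariates=("sex", "mean_fd"), n_boot=n_boot, seed=seed,
    )
    bundle["mediation_task"] = mediate_bca(
        task_mean, "age", "bp_pfc", "differentiation",
        covariates=("sex", "mean_fd"), n_boot=n_boot, seed=seed + 1,
    )

    # --- memory composite ~ rest differentiation x age
    mem_cols = [c for c in subjects.columns if c.startswith("memory_task_")]
    if mem_cols:
        comp = pca_composite(subjects[mem_cols])
        mem = subjects.loc[subjects[mem_cols].dropna().index].copy()
        mem["memory_pc1"] = comp.scores
        mem = mem.merge(rest[["subject_id", "differentiation"]], on="subject_id")
        bundle["memory_model"], _ = fit_linear_model(
            mem,
            ModelSpec("memory_pc1", ["differentiation * age"],
                      covariates=["sex", "mean_fd"], standardize=True),
            name="memory~rest_diff*age",
        )
        bundle["memory_composite"] = comp

    # --- Holm block over the key post-hoc coefficients
    posthoc = []
    for key, term in [
        ("rest_diff_model", "bp_caudate"),
        ("task_diff_model", "bp_pfc"),
        ("memory_model", "differentiation"),
    ]:
        if key in bundle:
            tab = bundle[key]
            row = tab[tab["term"] == term]
            if len(row):
                posthoc.append(
                    {"model": row.iloc[0]["model"], "term": term, "p": row.iloc[0]["p"]}
                )
    if posthoc:
        ph = pd.DataFrame(posthoc)
        ph["p_holm"], ph["reject"] = holm_correct(ph["p"].to_numpy(), alpha)
        bundle["posthoc_holm"] = ph
    return bundle


def bundle_to_frame(bundle: dict) -> pd.DataFrame:
    """Flatten a results bundle into one tidy coefficient table."""
    tables = [v for v in bundle.values() if isinstance(v, pd.DataFrame) and "term" in v]
    return pd.concat(tables, ignore_index=True)
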