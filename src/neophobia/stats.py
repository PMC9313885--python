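"""The assay's statistical chain.

Preference percentages are arcsine-square-root transformed and analysed by
weighted least squares with sequential (entry-order) sums of squares: age in
days post-fertilization enters as a numeric covariate, treatment as a fixed
factor, then their interaction, with each subject weighted by the raw total
(seconds in both sectors, or total approaches) that its percentage was
computed from.  Significant treatment effects are probed by pairwise
weighted t-tests.  Per-sector swimming velocity (two observations per
subject) is analysed on the log scale with a subject random intercept,
estimated by REML via numeric profiling of the between/within variance
ratio; F tests use the between-subject and within-subject error strata.
Nonchooser occurrence is compared across experiments with an uncorrected
Pearson chi-square and modelled across ages with a binomial GLM
likelihood-ratio test.  All p-values are two-sided; no multiplicity
correction is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .errors import SchemaError


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class TermTest:
    term: str
    statistic: float
    df_num: float
    df_den: float | None  # None for chi-square statistics
    p: float
    kind: str = "F"

    def as_dict(self) -> dict:
        return {
            "term": self.term,
            "kind": self.kind,
            "statistic": self.statistic,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "p": self.p,
        }


@dataclass
class ModelResult:
    """Per-term tests plus estimates and fit diagnostics."""

    tests: list[TermTest]
    params: pd.Series | None = None
    bse: pd.Series | None = None
    extra: dict = field(default_factory=dict)

    def __getitem__(self, term: str) -> TermTest:
        for t in self.tests:
            if t.term == term:
                return t
        raise KeyError(term)

    @property
    def terms(self) -> list[str]:
        return [t.term for t in self.tests]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.as_dict() for t in self.tests]).set_index("term")

    def to_json(self, **kwargs) -> str:
        payload = {"tests": [t.as_dict() for t in self.tests]}
        if self.params is not None:
            payload["params"] = self.params.to_dict()
        payload.update(
            {k: v for k, v in self.extra.items() if np.isscalar(v) or isinstance(v, str)}
        )
        return json.dumps(payload, indent=2, **kwargs)

    def summary(self) -> str:
        lines = [f"{'term':<28}{'stat':>14}{'df':>12}{'p':>10}"]
        for t in self.tests:
            df = f"{t.df_num:g}" if t.df_den is None else f"{t.df_num:g},{t.df_den:g}"
            stat = f"{t.kind}={t.statistic:.3f}"
            lines.append(f"{t.term:<28}{stat:>14}{df:>12}{t.p:>10.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------
def arcsine_sqrt(p) -> np.ndarray | float:
    """Variance-stabilising transform for proportions: asin(sqrt(p)), radians."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) else out


# ---------------------------------------------------------------------------
# design-matrix construction (treatment-coded, first level as reference)
# ---------------------------------------------------------------------------
def _is_categorical(col: pd.Series) -> bool:
    return (
        isinstance(col.dtype, pd.CategoricalDtype)
        or col.dtype == object
        or col.dtype == bool
    )


def _encode_var(table: pd.DataFrame, name: str) -> tuple[np.ndarray, list[str]]:
    if name not in table.columns:
        raise SchemaError(f"column {name!r} missing from the observation table")
    col = table[name]
    if _is_categorical(col):
        levels = sorted(pd.unique(col.astype(str)))
        mats = [(col.astype(str) == lev).to_numpy(float) for lev in levels[1:]]
        if not mats:
            raise SchemaError(f"factor {name!r} has a single level")
        return np.column_stack(mats), [f"{name}[{lev}]" for lev in levels[1:]]
    return col.to_numpy(float)[:, None], [name]


def _term_matrix(table: pd.DataFrame, term: str) -> np.ndarray:
    parts = [_encode_var(table, v)[0] for v in term.split(":")]
    out = parts[0]
    for p in parts[1:]:
        out = np.einsum("ij,ik->ijk", out, p).reshape(len(table), -1)
    return out


def _sequential_wls(
    y: np.ndarray,
    blocks: list[tuple[str, np.ndarray]],
    weights: np.ndarray,
) -> ModelResult:
    """Sequential (entry-order) sums of squares for a weighted linear model.

    Each term's SS is the drop in weighted residual SS when its block joins
    the design; F uses the full-model residual mean square.
    """
    n = y.size
    sw = np.sqrt(weights)
    yw = y * sw
    X = sw[:, None]  # intercept
    rank_prev = 1
    rss_prev = float(np.sum((yw - X @ np.linalg.lstsq(X, yw, rcond=None)[0]) ** 2))
    entries = []
    beta = None
    for term, block in blocks:
        X = np.column_stack([X, block * sw[:, None]])
        beta, _, rank, _ = np.linalg.lstsq(X, yw, rcond=None)
        if rank < rank_prev + block.shape[1]:
            raise np.linalg.LinAlgError(f"singular design: term {term!r} is aliased")
        rss = float(np.sum((yw - X @ beta) ** 2))
        entries.append((term, max(rss_prev - rss, 0.0), block.shape[1]))
        rss_prev, rank_prev = rss, rank
    df_resid = n - rank_prev
    if df_resid <= 0:
        raise SchemaError("no residual degrees of freedom")
    mse = rss_prev / df_resid
    tests = []
    for term, ss, df in entries:
        if mse > 0:
            f = (ss / df) / mse
        else:
            f = 0.0 if ss <= 1e-12 else np.inf
        tests.append(
            TermTest(term, float(f), df, df_resid, float(sps.f.sf(f, df, df_resid)))
        )
    # diagnostics on the weighted scale for outlier screening
    h = _hat_diag(X)
    resid_w = yw - X @ (beta if beta is not None else np.zeros(X.shape[1]))
    return ModelResult(
        tests=tests,
        extra={
            "rss": rss_prev,
            "df_resid": df_resid,
            "mse": mse,
            "residuals": resid_w,
            "hat": h,
            "rank": rank_prev,
        },
    )


def _hat_diag(Xw: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(Xw)
    return np.sum(q**2, axis=1)


# ---------------------------------------------------------------------------
# weighted ANCOVA and post-hoc t-tests
# ---------------------------------------------------------------------------
DEFAULT_TERMS = ("age_dpf", "treatment", "age_dpf:treatment")
POOLED_TERMS = (
    "age_dpf",
    "treatment",
    "experiment",
    "age_dpf:treatment",
    "age_dpf:experiment",
    "treatment:experiment",
)


def weighted_ancova(
    table: pd.DataFrame,
    response: str,
    terms: tuple[str, ...] = DEFAULT_TERMS,
    weights: str = "weight",
) -> ModelResult:
    """Weighted least-squares ANCOVA with sequential sums of squares.

    ``table`` carries one row per subject; factors are detected from dtype
    (strings become treatment-coded factors, numbers enter as covariates).
    Weights are raw totals (seconds or counts); F and p are invariant to
    rescaling them by any positive constant.
    """
    w = table[weights].to_numpy(float)
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise SchemaError("weights must be positive and finite")
    y = table[response].to_numpy(float)
    blocks = [(t, _term_matrix(table, t)) for t in terms]
    return _sequential_wls(y, blocks, w)


def weighted_t_test(
    table: pd.DataFrame,
    response: str,
    group: str,
    weights: str = "weight",
) -> ModelResult:
    """Pairwise weighted t-test (one-term WLS fit); t**2 equals the one-way
    weighted F, and with equal weights it reduces to the pooled-variance
    two-sample t-test."""
    levels = sorted(pd.unique(table[group].astype(str)))
    if len(levels) != 2:
        raise SchemaError(f"weighted_t_test needs exactly 2 groups, got {len(levels)}")
    counts = table[group].astype(str).value_counts()
    if counts.min() < 2:
        raise SchemaError("each group needs at least 2 observations")
    w = table[weights].to_numpy(float)
    y = table[response].to_numpy(float)
    g = (table[group].astype(str) == levels[1]).to_numpy(float)
    sw = np.sqrt(w)
    X = np.column_stack([np.ones_like(sw), g]) * sw[:, None]
    yw = y * sw
    beta, _, rank, _ = np.linalg.lstsq(X, yw, rcond=None)
    if rank < 2:
        raise np.linalg.LinAlgError("singular design in weighted t-test")
    resid = yw - X @ beta
    df = y.size - 2
    s2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(s2 * xtx_inv[1, 1]))
    t = float(beta[1] / se) if se > 0 else np.inf
    p = float(2.0 * sps.t.sf(abs(t), df))
    return ModelResult(
        tests=[TermTest(group, t, 1, df, p, kind="t")],
        params=pd.Series({f"{group}[{levels[1]}]": float(beta[1])}),
        bse=pd.Series({f"{group}[{levels[1]}]": se}),
        extra={"df": df, "groups": levels},
    )


# ---------------------------------------------------------------------------
# random-intercept model for per-sector velocity
# ---------------------------------------------------------------------------
def lmm_velocity(
    vtbl: pd.DataFrame,
    response: str = "velocity",
    subject: str = "subject_id",
    sector: str = "sector",
    treatment: str = "treatment",
    age: str = "age_dpf",
    log: bool = True,
) -> ModelResult:
    """Random-intercept model for log velocity, two observations per subject.

    Fixed effects are the full sector x treatment x age structure.  The
    between/within variance ratio is estimated by numerically minimising the
    profiled REML criterion; with two observations per subject the design
    splits into orthogonal error strata (subject means carry the
    between-subject terms, within-subject differences carry every
    sector-involving term), each tested against its own stratum residual.
    When the REML estimate of the between-subject variance hits the zero
    boundary the random intercept vanishes and the model collapses to
    ordinary least squares on all rows with a pooled residual.
    """
    for col in (response, subject, sector, treatment, age):
        if col not in vtbl.columns:
            raise SchemaError(f"velocity table lacks column {col!r}")
    counts = vtbl.groupby(subject, observed=True)[sector].agg(["count", "nunique"])
    if (counts["count"] != 2).any() or (counts["nunique"] != 2).any():
        bad = counts.index[(counts["count"] != 2) | (counts["nunique"] != 2)].tolist()
        raise SchemaError(f"subjects without exactly one row per sector: {bad[:5]}")
    v = vtbl[response].to_numpy(float)
    if log:
        if np.any(v <= 0):
            raise ValueError("velocities must be positive before log-transform")
        vtbl = vtbl.assign(**{response: np.log(v)})

    sectors = sorted(pd.unique(vtbl[sector].astype(str)))
    wide = vtbl.pivot_table(
        index=[subject, treatment, age], columns=sector, values=response, observed=True
    ).reset_index()
    m = 0.5 * (wide[sectors[0]] + wide[sectors[1]]).to_numpy(float)
    # difference oriented stimulus-minus-empty when those labels are present
    hi = "stimulus" if "stimulus" in sectors else sectors[1]
    lo = [s for s in sectors if s != hi][0]
    d = (wide[hi] - wide[lo]).to_numpy(float)
    btab = wide[[subject, treatment, age]].copy()
    n_subj = len(btab)

    bterms = [age, treatment, f"{age}:{treatment}"]
    ones = np.ones(n_subj)
    bblocks = [(t, _term_matrix(btab, t)) for t in bterms]

    def _ols_rss(y: np.ndarray, X: np.ndarray) -> float:
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        r = y - X @ beta
        return float(r @ r)

    Xb_full = np.column_stack([ones] + [b for _, b in bblocks])
    p_b = Xb_full.shape[1]
    p_w = p_b  # the d-regression reuses the between design
    ss_b = _ols_rss(m, Xb_full)  # residual SS of subject means
    ss_w = _ols_rss(d / np.sqrt(2.0), Xb_full)  # residual SS of scaled diffs
    df_b = n_subj - p_b
    df_w = n_subj - p_w
    if df_b <= 0 or df_w <= 0:
        raise SchemaError("too few subjects for the velocity model")
    N, p = 2 * n_subj, p_b + p_w

    def reml_criterion(lam: float) -> float:
        v_b = 0.5 + lam
        rss = ss_w + ss_b / v_b
        if rss <= 0:
            rss = 1e-300
        return (N - p) * np.log(rss) + (n_subj - p_b) * np.log(v_b)

    res = optimize.minimize_scalar(
        lambda u: reml_criterion(np.expm1(u)), bounds=(0.0, 15.0), method="bounded"
    )
    lam = float(max(np.expm1(res.x), 0.0))
    if reml_criterion(0.0) <= reml_criterion(lam) + 1e-9:
        lam = 0.0  # REML optimum on the zero-variance boundary
    sigma2_w = (ss_w + ss_b / (0.5 + lam)) / (N - p)
    sigma2_b = lam * sigma2_w

    tests: list[TermTest] = []
    if lam > 1e-8:
        # between stratum: subject means against the between design
        bres = _sequential_wls(m, bblocks, np.ones(n_subj))
        for t in bres.tests:
            tests.append(TermTest(t.term, t.statistic, t.df_num, df_b, t.p))
        # within stratum: differences; the constant is the sector effect and
        # each between column becomes its interaction with sector
        wnames = [sector, f"{sector}:{age}", f"{sector}:{treatment}", f"{sector}:{age}:{treatment}"]
        wblocks = [(wnames[0], ones[:, None])] + [
            (wnames[i + 1], b) for i, (_, b) in enumerate(bblocks)
        ]
        mse_w = ss_w * 2.0 / df_w  # residual MS of the raw differences
        rss_prev = float(d @ d)
        X = np.empty((n_subj, 0))
        for term, block in wblocks:
            X = np.column_stack([X, block])
            rss = _ols_rss(d, X)
            ss = max(rss_prev - rss, 0.0)
            if mse_w > 0:
                f = (ss / block.shape[1]) / mse_w
            else:
                f = 0.0 if ss <= 1e-12 else np.inf
            tests.append(
                TermTest(
                    term,
                    float(f),
                    block.shape[1],
                    df_w,
                    float(sps.f.sf(f, block.shape[1], df_w)),
                )
            )
            rss_prev = rss
        mode = "stratified"
    else:
        # boundary: random intercept vanished; pooled fixed-effects ANOVA
        tbl = vtbl.copy()
        tbl[sector] = tbl[sector].astype(str)
        pooled_terms = [
            sector,
            treatment,
            age,
            f"{sector}:{treatment}",
            f"{sector}:{age}",
            f"{treatment}:{age}",
            f"{sector}:{treatment}:{age}",
        ]
        blocks = [(t, _term_matrix(tbl, t)) for t in pooled_terms]
        pooled = _sequential_wls(
            tbl[response].to_numpy(float), blocks, np.ones(len(tbl))
        )
        tests = pooled.tests
        mode = "pooled"
    return ModelResult(
        tests=tests,
        extra={
            "sigma2_within": float(sigma2_w),
            "sigma2_between": float(sigma2_b),
            "variance_ratio": lam,
            "mode": mode,
            "n_subjects": n_subj,
        },
    )


# ---------------------------------------------------------------------------
# counts: chi-square and binomial GLM
# ---------------------------------------------------------------------------
def pearson_chi2(table) -> ModelResult:
    """Pearson chi-square on an r x c count table, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("counts must form a 2-D nonnegative integer table")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("degenerate table: a margin is zero")
    expected = np.outer(rows, cols) / obs.sum()
    chi2 = float(np.sum((obs - expected) ** 2 / expected))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(chi2, df))
    return ModelResult(
        tests=[TermTest("association", chi2, df, None, p, kind="chi2")],
        extra={"expected": expected},
    )


def pearson_chi2_2x2(table) -> ModelResult:
    obs = np.asarray(table)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    return pearson_chi2(obs)


def binomial_glm_lr(
    successes,
    totals,
    factors: pd.DataFrame,
    terms: tuple[str, ...] = ("age_dpf",),
) -> ModelResult:
    """Likelihood-ratio test from a binomial GLM on grouped counts.

    One row per group: ``successes`` of ``totals`` with the covariates in
    ``factors``.  The model with ``terms`` is compared against the
    intercept-only null; the statistic is the deviance drop with df equal to
    the added parameters.  Complete-separation cells are reported as the
    boundary fit rather than raising.
    """
    import warnings

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    y = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if np.any(n <= 0):
        raise ValueError("group sample sizes must be positive")
    if np.any(y < 0) or np.any(y > n):
        raise ValueError("successes must lie in [0, total] per group")
    endog = np.column_stack([y, n - y])
    k = len(y)
    X = np.ones((k, 1))
    names = ["intercept"]
    for t in terms:
        block, bnames = _encode_term_named(factors, t)
        X = np.column_stack([X, block])
        names.extend(bnames)
    df = X.shape[1] - 1
    with warnings.catch_warnings():
        # saturated/boundary fits are an expected, documented outcome here
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        null = sm.GLM(endog, np.ones((k, 1)), family=sm.families.Binomial()).fit()
        if df == 0:
            return ModelResult(
                tests=[
                    TermTest("+".join(terms) or "null", 0.0, 0, None, 1.0, kind="chi2")
                ],
                extra={"deviance_null": float(null.deviance)},
            )
        full = sm.GLM(endog, X, family=sm.families.Binomial()).fit(maxiter=200)
    lr = float(null.deviance - full.deviance)
    lr = max(lr, 0.0)
    p = float(sps.chi2.sf(lr, df))
    return ModelResult(
        tests=[TermTest("+".join(terms), lr, df, None, p, kind="chi2")],
        params=pd.Series(dict(zip(names, np.asarray(full.params, float)))),
        extra={
            "deviance_null": float(null.deviance),
            "deviance_model": float(full.deviance),
        },
    )


def _encode_term_named(table: pd.DataFrame, term: str) -> tuple[np.ndarray, list[str]]:
    mats = []
    for v in term.split(":"):
        mats.append(_encode_var(table, v))
    out, out_names = mats[0]
    for m, nm in mats[1:]:
        out = np.einsum("ij,ik->ijk", out, m).reshape(len(table), -1)
        out_names = [f"{a}:{b}" for a in out_names for b in nm]
    return out, out_names


# ---------------------------------------------------------------------------
# residual screening
# ---------------------------------------------------------------------------
def flag_outliers(
    residuals: np.ndarray,
    hat: np.ndarray | None = None,
    df_model: int = 1,
    threshold: float = 3.0,
) -> np.ndarray:
    """Flag observations with |externally studentized residual| > threshold.

    Residuals (and optional hat-matrix diagonal) come from a fitted model;
    flagged rows are only reported — removal is the caller's decision.
    Degenerate spreads (all residuals equal) flag nothing.
    """
    e = np.asarray(residuals, dtype=float)
    n = e.size
    h = np.zeros(n) if hat is None else np.asarray(hat, dtype=float)
    p = df_model
    if n - p - 1 <= 0:
        return np.zeros(n, dtype=bool)
    rss = float(e @ e)
    with np.errstate(divide="ignore", invalid="ignore"):
        # deletion formula: s2_(i) = (rss - e_i^2/(1-h_i)) / (n - p - 1)
        s2_loo = (rss - e**2 / (1.0 - h)) / (n - p - 1)
        t = e / np.sqrt(s2_loo * (1.0 - h))
    t[~np.isfinite(t)] = 0.0
    return np.abs(t) > threshold
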