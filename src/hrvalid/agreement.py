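"""Accuracy and agreement statistics for method-comparison of HR monitors.

Per-participant accuracy (MAE bpm, MAPE % of reference) summarised as
median and interquartile range across participants; Lin's concordance
correlation; repeated-measures concordance (rmCCC) and repeated-measures
Spearman correlation with subject-level bootstrap confidence intervals;
and Bland-Altman bias and 95 % limits of agreement estimated through a
linear mixed model with a subject random intercept, so the limits reflect
both between- and within-subject variation:

    d_ij = mu + u_i + e_ij,   u_i ~ N(0, s_u^2),  e_ij ~ N(0, s_e^2)
    bias = mu_hat,  LoA = mu_hat +/- 1.96 * sqrt(s_u^2 + s_e^2)

The random-intercept models are fitted by exact REML with the variance
ratio profiled out (a one-dimensional bounded optimisation), which makes
the subject-level bootstrap cheap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .pairing import PairedDataset

logger = logging.getLogger(__name__)

__all__ = [
    "AccuracySummary",
    "AgreementResult",
    "ThresholdVerdict",
    "accuracy_per_subject",
    "lin_ccc",
    "rm_ccc",
    "rm_spearman",
    "lmm_bland_altman",
    "classify_thresholds",
    "reml_random_intercept",
    "AgreementModel",
    "AgreementResults",
]

LOA_MULTIPLIER = 1.96  # 95 % limits of agreement


# --------------------------------------------------------------------------
# Random-intercept REML engine
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RandomInterceptFit:
    beta: np.ndarray
    se_beta: np.ndarray
    sigma_u2: float
    sigma_e2: float
    n_obs: int
    n_groups: int
    converged: bool = True
    boundary: bool = False


def _profile_reml(y: np.ndarray, X: np.ndarray, group_idx: np.ndarray, n_groups: int, lam: float):
    """GLS quantities for V_i = sigma_e^2 (I + lam * J) per group.

    Returns (beta, XtWX_inv, rss_w, logdet_v, logdet_xtwx) with W applied
    implicitly through group sums: W_i = I - c_i J, c_i = lam / (1 + lam n_i).
    """
    n, p = X.shape
    n_i = np.bincount(group_idx, minlength=n_groups).astype(float)
    c = lam / (1.0 + lam * n_i)  # per group

    Sx = np.zeros((n_groups, p))
    for j in range(p):
        Sx[:, j] = np.bincount(group_idx, weights=X[:, j], minlength=n_groups)
    Sy = np.bincount(group_idx, weights=y, minlength=n_groups)

    XtWX = X.T @ X - (Sx * c[:, None]).T @ Sx
    XtWy = X.T @ y - (Sx * c[:, None]).T @ Sy
    beta = np.linalg.solve(XtWX, XtWy)
    r = y - X @ beta
    Sr = np.bincount(group_idx, weights=r, minlength=n_groups)
    rss_w = float(r @ r - c @ (Sr**2))
    logdet_v = float(np.sum(np.log1p(lam * n_i)))
    sign, logdet_xtwx = np.linalg.slogdet(XtWX)
    return beta, np.linalg.inv(XtWX), rss_w, logdet_v, logdet_xtwx


def reml_random_intercept(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray
) -> RandomInterceptFit:
    """Exact REML for ``y = X beta + u_group + e`` with one random intercept.

    The variance ratio ``lam = s_u^2 / s_e^2`` is profiled: for fixed lam
    the GLS estimates and the residual variance are closed-form, leaving a
    one-dimensional REML criterion minimised on log(lam).  A boundary
    estimate ``s_u^2 = 0`` (the model collapses to ordinary least squares)
    is reported via ``boundary=True``.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    codes, _ = pd.factorize(np.asarray(groups))
    n_groups = int(codes.max()) + 1
    n, p = X.shape

    var_y = float(np.var(y))
    if var_y < 1e-14:
        # degenerate: all observations identical
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        return RandomInterceptFit(beta, np.zeros(p), 0.0, 0.0, n, n_groups, boundary=True)

    def neg2_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        _, _, rss_w, logdet_v, logdet_xtwx = _profile_reml(y, X, codes, n_groups, lam)
        sigma_e2 = rss_w / (n - p)
        return (n - p) * np.log(max(sigma_e2, 1e-300)) + logdet_v + logdet_xtwx

    res = minimize_scalar(neg2_reml, bounds=(-30.0, 30.0), method="bounded",
                          options={"xatol": 1e-10})
    lam = float(np.exp(res.x))
    # compare against the boundary lam -> 0 (pure OLS)
    boundary = False
    if neg2_reml(-30.0) <= res.fun + 1e-9 or lam < 1e-10:
        lam, boundary = 0.0, True
    beta, XtWX_inv, rss_w, _, _ = _profile_reml(y, X, codes, n_groups, lam)
    sigma_e2 = rss_w / (n - p)
    sigma_u2 = lam * sigma_e2
    se_beta = np.sqrt(np.clip(np.diag(XtWX_inv) * sigma_e2, 0.0, None))
    return RandomInterceptFit(beta, se_beta, float(sigma_u2), float(sigma_e2),
                              n, n_groups, converged=bool(res.success), boundary=boundary)


# --------------------------------------------------------------------------
# Accuracy
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AccuracySummary:
    """Per-participant MAE/MAPE with group median and IQR.

    Subjects contribute equally to the medians regardless of how many
    pairs they have.  The quantile rule is linear interpolation (the
    common default), configurable through ``accuracy_per_subject``.
    """

    per_subject: pd.DataFrame  # index subject_id, columns mae, mape
    median_mae: float
    iqr_mae: float
    median_mape: float
    iqr_mape: float
    n_subjects: int

    @property
    def mape_values(self) -> pd.Series:
        return self.per_subject["mape"]

    @property
    def mae_values(self) -> pd.Series:
        return self.per_subject["mae"]


def accuracy_per_subject(
    pd_set: PairedDataset,
    condition: Optional[str] = None,
    transition_id: Optional[int] = None,
    quantile_method: str = "linear",
) -> AccuracySummary:
    """MAE and MAPE per participant, summarised across participants.

    ``condition`` filters pairs by state ('steady' or 'transition'),
    optionally narrowed to one transition.  Subjects with no pairs after
    filtering are omitted (logged).
    """
    df = pd_set.data
    if condition is not None:
        dfq = pd_set.filter_state(condition, transition_id).data
    else:
        dfq = df
    if (dfq["ref_bpm"] <= 0).any():
        raise ValueError("reference HR must be positive for MAPE")
    if dfq.empty:
        raise ValueError("no pairs left after condition filtering")

    abs_err = (dfq["dev_bpm"] - dfq["ref_bpm"]).abs()
    rel_err = abs_err / dfq["ref_bpm"] * 100.0
    per = pd.DataFrame({
        "mae": abs_err.groupby(dfq["subject_id"]).mean(),
        "mape": rel_err.groupby(dfq["subject_id"]).mean(),
    })
    dropped = set(df["subject_id"].unique()) - set(per.index)
    if dropped:
        logger.info("accuracy_per_subject: %d subjects with no pairs after filtering omitted", len(dropped))

    def q(s, p):
        return float(np.quantile(s.to_numpy(), p, method=quantile_method))

    return AccuracySummary(
        per_subject=per,
        median_mae=q(per["mae"], 0.5),
        iqr_mae=q(per["mae"], 0.75) - q(per["mae"], 0.25),
        median_mape=q(per["mape"], 0.5),
        iqr_mape=q(per["mape"], 0.75) - q(per["mape"], 0.25),
        n_subjects=len(per),
    )


# --------------------------------------------------------------------------
# Concordance / correlation
# --------------------------------------------------------------------------

def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (moment form, n-1 moments).

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2).  Penalises both poor
    correlation and location/scale shift.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("lin_ccc needs equal-length inputs with n >= 3")
    sx, sy = np.var(x, ddof=1), np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    shift = (x.mean() - y.mean()) ** 2
    denom = sx + sy + shift
    if denom < 1e-14:
        # both constant at the same value: degenerate perfect agreement
        logger.warning("lin_ccc: both inputs constant and equal; returning 1 by convention")
        return 1.0
    if sx < 1e-14 and sy < 1e-14:
        return 0.0
    return float(2.0 * sxy / denom)


def _rmccc_arrays(x: np.ndarray, y: np.ndarray) -> float:
    """Variance-components rmCCC from paired arrays.

    Model: the stacked values carry a method fixed effect and a random
    intercept for every measurement occasion (the subject x timestamp
    pair, nested in subject), so the occasion variance s_a^2 — everything
    both methods track together, between- plus within-subject — sits in
    the numerator and only method disagreement stays in the residual:

        rmCCC = s_a^2 / (s_a^2 + s_e^2 + d^2 / 2)

    fitted by REML via :func:`reml_random_intercept` with one group per
    occasion.  With one pair per subject this is exactly the spec of
    Lin's CCC; device = reference gives 1.
    """
    n = x.size
    yy = np.empty(2 * n)
    yy[0::2], yy[1::2] = x, y
    X = np.empty((2 * n, 2))
    X[:, 0] = 1.0
    X[0::2, 1], X[1::2, 1] = 0.0, 1.0
    groups = np.repeat(np.arange(n), 2)
    fit = reml_random_intercept(yy, X, groups)
    d = fit.beta[1]
    denom = fit.sigma_u2 + fit.sigma_e2 + d**2 / 2.0
    if denom < 1e-14:
        return 1.0  # no variance anywhere and no method shift
    return float(fit.sigma_u2 / denom)


def _rm_corr_arrays(x: np.ndarray, y: np.ndarray, subj: np.ndarray, n_subj: int) -> float:
    """Repeated-measures correlation: Pearson r of subject-centred values
    (the common-slope ANCOVA estimate)."""
    cnt = np.bincount(subj, minlength=n_subj).astype(float)
    xc = x - (np.bincount(subj, weights=x, minlength=n_subj) / cnt)[subj]
    yc = y - (np.bincount(subj, weights=y, minlength=n_subj) / cnt)[subj]
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx < 1e-12 or sy < 1e-12:
        raise ValueError("repeated-measures correlation undefined for a within-subject-constant variable")
    return float(np.clip((xc @ yc) / np.sqrt(sx * sy), -1.0, 1.0))


def _rmscc_arrays(x: np.ndarray, y: np.ndarray, subj: np.ndarray, n_subj: int) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return _rm_corr_arrays(rx, ry, subj, n_subj)


def _subject_groups(pd_set: PairedDataset) -> list[tuple[np.ndarray, np.ndarray]]:
    df = pd_set.data
    return [
        (g["ref_bpm"].to_numpy(dtype=float), g["dev_bpm"].to_numpy(dtype=float))
        for _, g in df.groupby("subject_id", sort=True)
    ]


def _subject_bootstrap_ci(
    groups: list[tuple[np.ndarray, np.ndarray]],
    statistic: Callable[[np.ndarray, np.ndarray, np.ndarray, int], float],
    n_boot: int,
    seed: Optional[int],
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile CI from resampling subjects with replacement."""
    rng = np.random.default_rng(seed)
    k = len(groups)
    vals = []
    for _ in range(n_boot):
        pick = rng.integers(0, k, size=k)
        xs = np.concatenate([groups[i][0] for i in pick])
        ys = np.concatenate([groups[i][1] for i in pick])
        subj = np.repeat(np.arange(k), [groups[i][0].size for i in pick])
        try:
            vals.append(statistic(xs, ys, subj, k))
        except (ValueError, np.linalg.LinAlgError):
            continue
    if not vals:
        return (np.nan, np.nan)
    alpha = 1.0 - level
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def rm_ccc(
    pd_set: PairedDataset, n_boot: int = 1000, seed: Optional[int] = None
) -> tuple[float, tuple[float, float]]:
    """Repeated-measures concordance via variance components.

    The stacked (reference, device) values are modelled with a method
    fixed effect and a random intercept per measurement occasion (nested
    in subject); see :func:`_rmccc_arrays` for the estimator.  On
    balanced data with one pair per subject it reduces to Lin's CCC.
    The CI is a subject-level percentile bootstrap (default 1000
    resamples, seeded).
    """
    df = pd_set.data
    subjects = df["subject_id"].unique()
    x = df["ref_bpm"].to_numpy(dtype=float)
    y = df["dev_bpm"].to_numpy(dtype=float)
    if len(subjects) < 2:
        warnings.warn("rm_ccc: single subject; falling back to Lin's CCC", stacklevel=2)
        return lin_ccc(x, y), (np.nan, np.nan)
    counts = df.groupby("subject_id").size()
    if (counts < 2).any():
        logger.info("rm_ccc: %d subjects have a single pair", int((counts < 2).sum()))
    est = _rmccc_arrays(x, y)
    ci = (np.nan, np.nan)
    if n_boot > 0:
        ci = _subject_bootstrap_ci(_subject_groups(pd_set),
                                   lambda xs, ys, s, k: _rmccc_arrays(xs, ys), n_boot, seed)
    return est, ci


def rm_spearman(
    pd_set: PairedDataset, n_boot: int = 1000, seed: Optional[int] = None
) -> tuple[float, tuple[float, float]]:
    """Repeated-measures Spearman correlation.

    Ranks are computed on the pooled sample per variable; the
    repeated-measures (subject-centred) correlation is then applied to the
    ranks.  CI by subject-level bootstrap (ranks recomputed per resample).
    """
    df = pd_set.data
    if df["ref_bpm"].nunique() < 2 or df["dev_bpm"].nunique() < 2:
        raise ValueError("rm_spearman undefined for a constant variable")
    subj, _ = pd.factorize(df["subject_id"], sort=True)
    est = _rmscc_arrays(df["ref_bpm"].to_numpy(dtype=float),
                        df["dev_bpm"].to_numpy(dtype=float), subj, int(subj.max()) + 1)
    ci = (np.nan, np.nan)
    if n_boot > 0:
        ci = _subject_bootstrap_ci(_subject_groups(pd_set), _rmscc_arrays, n_boot, seed)
    return est, ci


# --------------------------------------------------------------------------
# Mixed-model Bland-Altman
# --------------------------------------------------------------------------

def lmm_bland_altman(pd_set: PairedDataset) -> tuple[float, float, float, float]:
    """Bias and 95 % limits of agreement from a random-intercept model.

    Differences d = device - reference are modelled as
    d_ij = mu + u_i + e_ij (REML).  Returns (bias, bias_p, loa_lower,
    loa_upper) with LoA = mu +/- 1.96 sqrt(s_u^2 + s_e^2) and a Wald test
    of mu = 0.  A boundary estimate s_u^2 = 0 reduces to ordinary
    Bland-Altman limits on the pooled SD (warned).
    """
    df = pd_set.data
    subjects = df["subject_id"].unique()
    counts = df.groupby("subject_id").size()
    if len(subjects) < 3 or (counts < 2).all():
        logger.info("lmm_bland_altman: few subjects/pairs (%d subjects); estimates may be unstable", len(subjects))
    d = (df["dev_bpm"] - df["ref_bpm"]).to_numpy(dtype=float)
    if np.ptp(d) < 1e-12:
        c = float(d[0]) if d.size else 0.0
        return c, (1.0 if c == 0.0 else 0.0), c, c
    X = np.ones((d.size, 1))
    fit = reml_random_intercept(d, X, df["subject_id"].to_numpy())
    if fit.boundary:
        warnings.warn("lmm_bland_altman: subject variance estimated at 0; limits reduce to pooled-SD Bland-Altman", stacklevel=2)
    bias = float(fit.beta[0])
    se = float(fit.se_beta[0])
    z = bias / se if se > 0 else np.inf * np.sign(bias)
    bias_p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    half = LOA_MULTIPLIER * np.sqrt(fit.sigma_u2 + fit.sigma_e2)
    return bias, bias_p, bias - half, bias + half


# --------------------------------------------------------------------------
# Thresholds and results containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementResult:
    rmccc: float
    rmccc_ci: tuple[float, float]
    rm_spearman: float
    rm_spearman_ci: tuple[float, float]
    bias: float
    bias_p: float
    loa_lower: float
    loa_upper: float
    n_pairs: int

    def __post_init__(self) -> None:
        if not (self.loa_lower - 1e-9 <= self.bias <= self.loa_upper + 1e-9):
            raise ValueError("limits of agreement must bracket the bias")


@dataclass(frozen=True)
class ThresholdVerdict:
    """Accept/band verdicts against the field's conventional cut-points:
    MAPE within +/-10 % or MAE within 5 bpm; correlation bands weak
    (cc <= 0.5) / moderate / strong (cc >= 0.7); concordance acceptability
    at 0.80."""

    mape_acceptable: bool
    cc_band: str
    cc_acceptable: bool


def classify_thresholds(acc: AccuracySummary, agr: AgreementResult) -> ThresholdVerdict:
    cc = agr.rmccc
    if cc <= 0.5:
        band = "weak"
    elif cc < 0.7:
        band = "moderate"
    else:
        band = "strong"
    return ThresholdVerdict(
        mape_acceptable=bool(acc.median_mape <= 10.0 or acc.median_mae <= 5.0),
        cc_band=band,
        cc_acceptable=bool(cc >= 0.80),
    )


# --------------------------------------------------------------------------
# Model / Results front end
# --------------------------------------------------------------------------

class AgreementModel:
    """Agreement analysis of one paired device/reference dataset.

    Follows the model/results pattern: construct from a ``PairedDataset``
    (or a tidy DataFrame via :meth:`from_dataframe`), call :meth:`fit`,
    inspect the returned :class:`AgreementResults`.

    Parameters
    ----------
    paired : PairedDataset
        Complete pairs at one resolution.
    condition : str, optional
        Restrict accuracy metrics to 'steady' or 'transition' pairs.
    n_boot : int
        Subject-bootstrap resamples for the correlation CIs.
    seed : int, optional
        Bootstrap seed.
    """

    def __init__(self, paired: PairedDataset, condition: Optional[str] = None,
                 n_boot: int = 1000, seed: Optional[int] = None):
        self.paired = paired.filter_state(condition) if condition else paired
        self.condition = condition
        self.n_boot = int(n_boot)
        self.seed = seed

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, resolution: str = "per_second",
                       device_id: str = "device", reference_id: str = "reference",
                       **kwargs) -> "AgreementModel":
        """Build from a tidy frame with columns subject_id, t_s, ref_bpm,
        dev_bpm (state and transition_id added as absent when missing)."""
        df = df.copy()
        for col in ("state", "transition_id"):
            if col not in df.columns:
                df[col] = pd.NA
        df["transition_id"] = df["transition_id"].astype("Int64")
        return cls(PairedDataset(resolution, df, device_id, reference_id), **kwargs)

    def fit(self) -> "AgreementResults":
        acc = accuracy_per_subject(self.paired)
        ccc, ccc_ci = rm_ccc(self.paired, n_boot=self.n_boot, seed=self.seed)
        scc, scc_ci = rm_spearman(self.paired, n_boot=self.n_boot, seed=self.seed)
        bias, bias_p, lo, hi = lmm_bland_altman(self.paired)
        agr = AgreementResult(ccc, ccc_ci, scc, scc_ci, bias, bias_p, lo, hi, len(self.paired))
        verdict = classify_thresholds(acc, agr)
        return AgreementResults(self, acc, agr, verdict)


class AgreementResults:
    """Fitted agreement statistics with a text summary table."""

    def __init__(self, model: AgreementModel, accuracy: AccuracySummary,
                 agreement: AgreementResult, verdict: ThresholdVerdict):
        self.model = model
        self.accuracy = accuracy
        self.agreement = agreement
        self.verdict = verdict

    # convenience accessors
    @property
    def bias(self) -> float:
        return self.agreement.bias

    @property
    def loa(self) -> tuple[float, float]:
        return (self.agreement.loa_lower, self.agreement.loa_upper)

    @property
    def rmccc(self) -> float:
        return self.agreement.rmccc

    @property
    def median_mape(self) -> float:
        return self.accuracy.median_mape

    def to_dict(self) -> dict:
        a, g, v = self.accuracy, self.agreement, self.verdict
        return {
            "device_id": self.model.paired.device_id,
            "reference_id": self.model.paired.reference_id,
            "resolution": self.model.paired.resolution,
            "condition": self.model.condition,
            "n_pairs": g.n_pairs,
            "n_subjects": a.n_subjects,
            "median_mape_pct": a.median_mape,
            "iqr_mape_pct": a.iqr_mape,
            "median_mae_bpm": a.median_mae,
            "iqr_mae_bpm": a.iqr_mae,
            "rmccc": g.rmccc,
            "rmccc_ci": list(g.rmccc_ci),
            "rm_spearman": g.rm_spearman,
            "rm_spearman_ci": list(g.rm_spearman_ci),
            "bias_bpm": g.bias,
            "bias_p": g.bias_p,
            "loa_lower_bpm": g.loa_lower,
            "loa_upper_bpm": g.loa_upper,
            "mape_acceptable": v.mape_acceptable,
            "cc_band": v.cc_band,
            "cc_acceptable": v.cc_acceptable,
        }

    def summary(self) -> str:
        d = self.to_dict()
        lines = [
            "Agreement analysis",
            "=" * 62,
            f"device:      {d['device_id']}   reference: {d['reference_id']}",
            f"resolution:  {d['resolution']}   condition: {d['condition'] or 'full protocol'}",
            f"pairs:       {d['n_pairs']}   subjects: {d['n_subjects']}",
            "-" * 62,
            f"median MAPE: {d['median_mape_pct']:8.2f} %   (IQR {d['iqr_mape_pct']:.2f})",
            f"median MAE:  {d['median_mae_bpm']:8.2f} bpm (IQR {d['iqr_mae_bpm']:.2f})",
            f"rmCCC:       {d['rmccc']:8.3f}   95% CI ({d['rmccc_ci'][0]:.3f}, {d['rmccc_ci'][1]:.3f})",
            f"rmSCC:       {d['rm_spearman']:8.3f}   95% CI ({d['rm_spearman_ci'][0]:.3f}, {d['rm_spearman_ci'][1]:.3f})",
            f"bias:        {d['bias_bpm']:8.2f} bpm (p = {d['bias_p']:.4f})",
            f"95% LoA:     ({d['loa_lower_bpm']:.2f}, {d['loa_upper_bpm']:.2f}) bpm",
            "-" * 62,
            f"MAPE acceptable (<=10% or MAE <=5 bpm): {d['mape_acceptable']}",
            f"correlation band: {d['cc_band']}   concordance >= 0.80: {d['cc_acceptable']}",
        ]
        return "\n".join(lines)

    def plot_bland_altman(self, ax=None):
        """Difference-vs-mean scatter with bias and limits of agreement."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        df = self.model.paired.data
        mean = (df["ref_bpm"] + df["dev_bpm"]) / 2.0
        diff = df["dev_bpm"] - df["ref_bpm"]
        ax.scatter(mean, diff, s=4, alpha=0.3)
        g = self.agreement
        for yv, style in ((g.bias, "-"), (g.loa_lower, "--"), (g.loa_upper, "--")):
            ax.axhline(yv, color="crimson", linestyle=style, linewidth=1)
        ax.set_xlabel("mean of device and reference (bpm)")
        ax.set_ylabel("device - reference (bpm)")
        ax.set_title(f"{self.model.paired.device_id} ({self.model.paired.resolution})")
        return ax
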