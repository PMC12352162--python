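"""Per-experiment covariate summaries and the normal-identity GLM that
explains across-experiment variance in decoder AUROC.

The six pre-defined covariates are: electrode type (``e_type``; depth = 0,
subdural = 1), number of contacts (``e_num``), mean high-gamma burst SNR
(``hg``), mean beta burst SNR (``beta``), correct recall probability
(``recall_p``) and number of word trials (``trials``).  The default design
is the curated set of 41 interaction terms used in the published analysis;
a full factorial (all 63 products) is available behind a flag.  With a
normal family and identity link the fit is ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ExperimentSummary",
    "GlmFit",
    "TABLE_TERMS",
    "full_factorial_terms",
    "summarize_experiment",
    "fit_glm",
    "simulate_summaries",
]

COVARIATES = ("e_type", "e_num", "hg", "beta", "recall_p", "trials")

#: default (curated) interaction design: 41 non-intercept terms
TABLE_TERMS: tuple[str, ...] = (
    "e_type", "e_num", "hg", "beta", "recall_p", "trials",
    "e_type:e_num", "e_type:hg", "e_num:hg", "e_type:beta", "e_num:beta",
    "hg:beta", "e_type:recall_p", "e_num:recall_p", "hg:recall_p",
    "beta:recall_p", "e_type:trials", "e_num:trials", "hg:trials",
    "beta:trials", "recall_p:trials",
    "e_type:e_num:hg", "e_type:e_num:beta", "e_num:hg:beta",
    "e_type:e_num:recall_p", "e_num:hg:recall_p", "hg:beta:recall_p",
    "e_type:e_num:trials", "e_num:hg:trials", "hg:recall_p:trials",
    "beta:recall_p:trials",
    "e_type:e_num:hg:beta", "e_type:e_num:hg:recall_p",
    "e_num:hg:beta:recall_p", "e_type:e_num:hg:trials",
    "e_num:hg:beta:trials", "hg:beta:recall_p:trials",
    "e_type:e_num:hg:beta:recall_p", "e_type:e_num:hg:beta:trials",
    "e_num:hg:beta:recall_p:trials",
    "e_type:e_num:hg:beta:recall_p:trials",
)

#: the headline four-way interaction
HEADLINE_TERM = "e_num:hg:beta:recall_p"


def full_factorial_terms() -> tuple[str, ...]:
    """All 63 products of the six covariates."""
    from itertools import combinations

    terms = []
    for r in range(1, len(COVARIATES) + 1):
        for combo in combinations(COVARIATES, r):
            terms.append(":".join(combo))
    return tuple(terms)


@dataclass(frozen=True)
class ExperimentSummary:
    """Covariates and response of one experiment for the explanatory model."""

    e_type: int
    e_num: int
    hg: float
    beta: float
    recall_p: float
    trials: int
    auroc: float

    def __post_init__(self):
        if self.e_type not in (0, 1):
            raise ValueError("e_type must be 0 (depth) or 1 (subdural)")
        if self.e_num < 1:
            raise ValueError("e_num must be >= 1")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if not 0.0 <= self.recall_p <= 1.0:
            raise ValueError("recall_p must lie in [0, 1]")
        if not 0.0 <= self.auroc <= 1.0:
            raise ValueError("auroc must lie in [0, 1]")


def summarize_experiment(session, predictions: pd.DataFrame,
                         hg_snrs, beta_snrs, electrode_type: int = 1) -> ExperimentSummary:
    """Assemble one experiment's GLM row from its session, pooled
    cross-validated predictions, and per-contact burst SNRs."""
    from .burst import mean_experiment_snr
    from .metrics import auroc as _auroc

    hg_mean, beta_mean = mean_experiment_snr(hg_snrs, beta_snrs)
    return ExperimentSummary(
        e_type=int(electrode_type),
        e_num=int(session.n_channels),
        hg=hg_mean,
        beta=beta_mean,
        recall_p=float(np.mean(session.recalled)),
        trials=int(session.schedule.n_words),
        auroc=_auroc(predictions.probability, predictions.label),
    )


@dataclass
class GlmFit:
    """Least-squares fit of the normal-identity GLM."""

    terms: list[str]
    estimates: np.ndarray
    se: np.ndarray
    tstats: np.ndarray
    pvalues: np.ndarray
    fvalue: float
    f_pvalue: float
    df_resid: int
    conf_int: np.ndarray  # (n_terms, 2), 95%
    fitted: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "Name": self.terms, "Estimate": self.estimates, "SE": self.se,
            "tStat": self.tstats, "p-value": self.pvalues})


def _design_matrix(frame: pd.DataFrame, terms) -> np.ndarray:
    cols = [np.ones(len(frame))]
    for term in terms:
        col = np.ones(len(frame))
        for name in term.split(":"):
            col = col * frame[name].to_numpy(dtype=float)
        cols.append(col)
    return np.column_stack(cols)


def fit_glm(summaries, term_spec=None, *, full_factorial: bool = False) -> GlmFit:
    """Fit the explanatory model by ordinary least squares (normal family,
    identity link, fixed intercept).

    Raises a singularity error naming the collinear terms when the design is
    rank deficient.
    """
    if isinstance(summaries, pd.DataFrame):
        frame = summaries
    else:
        frame = pd.DataFrame([vars(s) for s in summaries])
    terms = list(term_spec) if term_spec is not None else (
        list(full_factorial_terms()) if full_factorial else list(TABLE_TERMS))
    X = _design_matrix(frame, terms)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more experiments ({n}) than terms ({p})")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        from scipy.linalg import qr

        _, r, piv = qr(X, mode="economic", pivoting=True)
        tol = np.abs(r[0, 0]) * max(X.shape) * np.finfo(float).eps
        bad = sorted(piv[rank:])
        names = ["(Intercept)" if i == 0 else terms[i - 1] for i in bad]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear terms: {names} (tol={tol:.3g})")
    y = frame["auroc"].to_numpy(dtype=float)
    res = sm.OLS(y, X).fit()
    return GlmFit(
        terms=["(Intercept)"] + terms,
        estimates=np.asarray(res.params),
        se=np.asarray(res.bse),
        tstats=np.asarray(res.tvalues),
        pvalues=np.asarray(res.pvalues),
        fvalue=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        df_resid=int(res.df_resid),
        conf_int=np.asarray(res.conf_int()),
        fitted=np.asarray(res.fittedvalues),
    )


def simulate_summaries(n: int, seed: int, coefs: dict[str, float] | None = None,
                       noise_sd: float = 0.05, intercept: float = 0.5) -> pd.DataFrame:
    """Simulated experiment table with a known linear response, for
    calibration studies of the explanatory model."""
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame({
        "e_type": rng.integers(0, 2, n),
        "e_num": rng.integers(1, 9, n),
        "hg": rng.uniform(1.5, 6.0, n),
        "beta": rng.uniform(1.5, 30.0, n),
        "recall_p": rng.uniform(0.05, 0.6, n),
        "trials": rng.integers(96, 601, n),
    })
    y = np.full(n, float(intercept))
    for term, c in (coefs or {}).items():
        col = np.ones(n)
        for name in term.split(":"):
            col = col * frame[name].to_numpy(dtype=float)
        y = y + c * col
    y = y + rng.normal(0.0, noise_sd, n)
    frame["auroc"] = np.clip(y, 0.0, 1.0)
    return frame
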