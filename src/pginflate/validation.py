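"""Search-result validation: target-decoy, mixture-model and rescoring filters.

Implements the six validation methods compared in the inflation study plus
the two-stage FDR procedure, all at the peptide level (best PSM per
peptide):

* **TD** — target-decoy filtering of the pooled PSM list at a score
  threshold ``t``, estimating FDR as ``N_D / N_T`` (decoy hits over target
  hits above ``t``), monotonized into q-values.
* **BP** — TD applied to a recalibrated score from a self-boosted,
  Percolator-style semi-supervised rescorer (cross-validated linear
  classifier, positives re-drawn across boosting rounds).
* **MB** — a parametric two-component mixture model fitted by EM
  (incorrect component Gumbel, correct component Gaussian); each PSM gets a
  posterior error probability (PEP) and the FDR above a threshold is the
  mean PEP of the retained PSMs.
* **SepTD / SepBP / SepMB** — the same rankings, but known-group and
  novel-group PSMs are filtered separately, each with its own ``N_D / N_T``
  estimate. Any learning step (rescoring, mixture fitting) still runs once
  on the pooled PSMs, because the novel group alone is too small to train
  on.
* **Two-stage FDR** — spectra are first searched against the reference
  database and filtered at the target level; only unidentified spectra
  proceed to the proteogenomic database, with FDR controlled per stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import logsumexp
from scipy.stats import gumbel_r, norm
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .psm_simulator import empirical_fdr

logger = logging.getLogger(__name__)

_EULER = 0.5772156649015329


# ---------------------------------------------------------------------------
# Outcome containers
# ---------------------------------------------------------------------------


@dataclass
class FilterOutcome:
    """An accepted peptide/PSM set at a target FDR level."""

    method: str
    group: str
    threshold: float
    n_target: int
    n_decoy: int
    fdr_est: float
    accepted: pd.DataFrame
    fdr_emp: float | None = None


@dataclass
class MixtureModelFit:
    """Two-component score mixture: pi0 Gumbel (incorrect) + pi1 Normal (correct)."""

    pi0: float
    gumbel_mu: float
    gumbel_beta: float
    normal_mu: float
    normal_sigma: float
    loglik: float = float("-inf")
    n_iter: int = 0
    converged: bool = False
    loglik_history: list[float] = field(default_factory=list)

    @property
    def pi1(self) -> float:
        return 1.0 - self.pi0


@dataclass(frozen=True)
class BPConfig:
    """Self-boosted rescoring configuration."""

    n_boost_rounds: int = 5
    n_folds: int = 3
    init_fdr: float = 0.01
    max_inner_iter: int = 1000
    seed: int = 0
    subsample: float = 0.8  # fraction of positives kept in rounds > 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0 < self.init_fdr < 1:
            raise ValueError("init_fdr must be in (0, 1)")


# ---------------------------------------------------------------------------
# Elementary estimators
# ---------------------------------------------------------------------------


def td_fdr(n_decoy: int, n_target: int) -> float:
    """Target-decoy FDR estimate ``N_D / N_T`` (0 when ``N_T`` is 0)."""
    if n_decoy < 0 or n_target < 0:
        raise ValueError("counts must be non-negative")
    if n_target == 0:
        return 0.0
    return n_decoy / n_target


def mb_fdr(peps: Sequence[float]) -> float:
    """Model-based FDR above a threshold: the mean PEP of retained PSMs."""
    peps = np.asarray(peps, dtype=float)
    if peps.size == 0:
        raise ValueError("mb_fdr is undefined for an empty set")
    if peps.min() < 0 or peps.max() > 1:
        raise ValueError("PEPs must lie in [0, 1]")
    return float(peps.mean())


def peptide_level_collapse(psms: pd.DataFrame, key: str = "score") -> pd.DataFrame:
    """Keep the best record per distinct peptide (ties: lowest spectrum_id)."""
    if key not in psms.columns:
        raise KeyError(f"ranking field {key!r} missing from PSM table")
    d = psms.sort_values([key, "spectrum_id"], ascending=[False, True], kind="mergesort")
    return d.drop_duplicates("peptide_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Target-decoy filtering
# ---------------------------------------------------------------------------


def filter_at_fdr(records: pd.DataFrame, alpha: float, key: str = "score",
                  method: str = "TD", group: str = "pooled") -> FilterOutcome:
    """Accept all records with q-value <= alpha under ``N_D / N_T``.

    The FDR is computed at every observed threshold ``t`` (accept iff value
    >= t), converted to q-values by a cumulative minimum from the most
    permissive threshold to the strictest, and the largest acceptance set
    with q <= alpha is returned. Records tied on the ranking value are
    accepted or rejected together. Decoys are excluded from the accepted
    set.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    empty = FilterOutcome(method, group, float("inf"), 0, 0, 0.0,
                          records.iloc[0:0], None)
    if len(records) == 0:
        return empty
    d = records.sort_values([key, "spectrum_id"], ascending=[False, True],
                            kind="mergesort").reset_index(drop=True)
    vals = d[key].to_numpy(dtype=float)
    dec = d["is_decoy"].to_numpy(dtype=bool)
    n_t = np.cumsum(~dec)
    n_d = np.cumsum(dec)
    fdr = np.where(n_t > 0, n_d / np.maximum(n_t, 1), 0.0)
    # Valid thresholds fall on tie-group boundaries only (accept iff value
    # >= t); q-values are the running minimum of the boundary FDRs from the
    # most permissive threshold upward.
    group_last = np.ones(len(d), dtype=bool)
    group_last[:-1] = vals[:-1] != vals[1:]
    idx_last = np.flatnonzero(group_last)
    q_last = np.minimum.accumulate(fdr[idx_last][::-1])[::-1]
    ok = np.flatnonzero(q_last <= alpha)
    if ok.size == 0:
        return empty
    cut = int(idx_last[ok[-1]]) + 1
    q = np.empty(len(d))
    q[idx_last] = q_last  # only boundary rows are ever read below
    accepted = d.iloc[:cut]
    accepted = accepted[~dec[:cut]].reset_index(drop=True)
    fdr_emp = empirical_fdr(accepted) if "is_correct" in d.columns and len(accepted) else None
    return FilterOutcome(
        method=method, group=group, threshold=float(vals[cut - 1]),
        n_target=int(n_t[cut - 1]), n_decoy=int(n_d[cut - 1]),
        fdr_est=float(q[cut - 1]), accepted=accepted, fdr_emp=fdr_emp,
    )


# ---------------------------------------------------------------------------
# Mixture model (EM) and PEP
# ---------------------------------------------------------------------------


def _weighted_gumbel_mle(x: np.ndarray, w: np.ndarray,
                         beta_hint: float) -> tuple[float, float]:
    """Weighted maximum-likelihood Gumbel fit via 1-D root finding for beta."""
    sw = w.sum()
    xbar = float((w * x).sum() / sw)
    xmin = float(x.min())

    def score_eq(beta: float) -> float:
        z = np.exp(-(x - xmin) / beta)
        den = float((w * z).sum())
        if den == 0.0:
            # beta -> 0 limit: the exponential weight collapses onto x_min.
            return beta - xbar + xmin
        return beta - xbar + float((w * x * z).sum()) / den

    lo = 1e-8
    hi = max(beta_hint, 1e-3)
    for _ in range(200):
        if score_eq(hi) > 0:
            break
        hi *= 2.0
    else:
        raise RuntimeError("could not bracket the Gumbel scale equation")
    beta = float(brentq(score_eq, lo, hi, xtol=1e-10))
    z = np.exp(-(x - xmin) / beta)
    mu = xmin - beta * float(np.log((w * z).sum() / sw))
    return mu, beta


def _moment_init(scores: np.ndarray) -> MixtureModelFit:
    """Moment-based starting point: Gumbel on the bulk, Normal on the upper tail."""
    lo = np.quantile(scores, 0.6)
    lower = scores[scores <= lo]
    upper = scores[scores > np.quantile(scores, 0.8)]
    beta0 = max(float(lower.std()) * np.sqrt(6) / np.pi, 1e-3)
    mu0 = float(lower.mean()) - _EULER * beta0
    return MixtureModelFit(
        pi0=0.8,
        gumbel_mu=mu0, gumbel_beta=beta0,
        normal_mu=float(upper.mean()), normal_sigma=max(float(upper.std()), 1e-3),
    )


def fit_mixture_em(scores: Sequence[float], init: MixtureModelFit | None = None,
                   max_iter: int = 500, tol: float = 1e-8) -> MixtureModelFit:
    """Fit ``pi0 Gumbel + pi1 Normal`` to PSM scores by EM.

    The E-step computes per-score responsibilities; the M-step updates the
    Gaussian by weighted moments (closed form) and the Gumbel by weighted
    maximum likelihood with one-dimensional root finding for the scale. The
    log-likelihood is non-decreasing across iterations. A collapsing
    component (scale below 1e-6, or a vanishing mixing weight) is flagged
    ``converged=False``.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 50:
        raise ValueError("need at least 50 scores to fit the mixture")
    if tol <= 0:
        raise ValueError("tol must be positive")
    fit = init or _moment_init(x)
    pi0, mu_g, beta_g = fit.pi0, fit.gumbel_mu, fit.gumbel_beta
    mu_n, sigma_n = fit.normal_mu, fit.normal_sigma

    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lp0 = np.log(max(pi0, 1e-300)) + gumbel_r.logpdf(x, loc=mu_g, scale=beta_g)
        lp1 = np.log(max(1 - pi0, 1e-300)) + norm.logpdf(x, loc=mu_n, scale=sigma_n)
        lse = np.logaddexp(lp0, lp1)
        ll = float(lse.sum())
        history.append(ll)
        if len(history) > 1 and abs(history[-1] - history[-2]) < tol:
            converged = True
            break
        r1 = np.exp(lp1 - lse)
        r0 = 1.0 - r1
        w1 = float(r1.sum())
        w0 = float(r0.sum())
        if w0 < 1.0 or w1 < 1.0:
            logger.warning("mixture component collapsed (weights %.3g / %.3g)", w0, w1)
            break
        pi0 = w0 / x.size
        mu_n = float((r1 * x).sum() / w1)
        sigma_n = float(np.sqrt((r1 * (x - mu_n) ** 2).sum() / w1))
        if sigma_n < 1e-6:
            logger.warning("normal component degenerate (sigma -> 0)")
            sigma_n = 1e-6
            break
        mu_g, beta_g = _weighted_gumbel_mle(x, r0, beta_g)
        if beta_g < 1e-6:
            logger.warning("gumbel component degenerate (beta -> 0)")
            beta_g = 1e-6
            break

    return MixtureModelFit(
        pi0=pi0, gumbel_mu=mu_g, gumbel_beta=beta_g,
        normal_mu=mu_n, normal_sigma=sigma_n,
        loglik=history[-1] if history else float("-inf"),
        n_iter=it, converged=converged, loglik_history=history,
    )


def compute_pep(fit: MixtureModelFit, score) -> np.ndarray | float:
    """Posterior error probability: pi0 f0(S) / (pi0 f0(S) + pi1 f1(S))."""
    x = np.asarray(score, dtype=float)
    lp0 = np.log(max(fit.pi0, 1e-300)) + gumbel_r.logpdf(x, loc=fit.gumbel_mu, scale=fit.gumbel_beta)
    lp1 = np.log(max(fit.pi1, 1e-300)) + norm.logpdf(x, loc=fit.normal_mu, scale=fit.normal_sigma)
    lse = np.logaddexp(lp0, lp1)
    with np.errstate(invalid="ignore"):
        pep = np.exp(lp0 - lse)
    # Where both densities underflow, the score is in the far left tail:
    # treat it as certainly incorrect.
    pep = np.where(np.isfinite(lse), pep, 1.0)
    pep = np.clip(pep, 0.0, 1.0)
    return float(pep) if np.isscalar(score) else pep


def assign_peps(psms: pd.DataFrame, fit: MixtureModelFit | None = None,
                include_decoys: bool = False) -> tuple[pd.DataFrame, MixtureModelFit]:
    """Fit the mixture (targets only by default) and attach PEP columns."""
    if fit is None:
        pool = psms if include_decoys else psms[~psms["is_decoy"]]
        fit = fit_mixture_em(pool["score"].to_numpy())
    d = psms.copy()
    d["pep"] = compute_pep(fit, d["score"].to_numpy())
    d["one_minus_pep"] = 1.0 - d["pep"]
    return d, fit


def mb_filter(psms: pd.DataFrame, alpha: float, fit: MixtureModelFit | None = None,
              include_decoys: bool = False, collapse: bool = True) -> FilterOutcome:
    """Model-based filtering: threshold the mean-PEP FDR estimate at alpha.

    Fits the mixture, assigns PEPs, optionally collapses to peptide level,
    and selects the most permissive score threshold whose mean PEP (over
    retained target records) is <= alpha after monotonization.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    d, fit = assign_peps(psms, fit=fit, include_decoys=include_decoys)
    if collapse:
        d = peptide_level_collapse(d, key="one_minus_pep")
    targets = d[~d["is_decoy"]].sort_values(
        ["one_minus_pep", "spectrum_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    empty = FilterOutcome("MB", "pooled", float("inf"), 0, 0, 0.0, d.iloc[0:0], None)
    if len(targets) == 0:
        return empty
    peps = targets["pep"].to_numpy(dtype=float)
    vals = targets["one_minus_pep"].to_numpy(dtype=float)
    est = np.cumsum(peps) / np.arange(1, len(peps) + 1)
    group_last = np.ones(len(targets), dtype=bool)
    group_last[:-1] = vals[:-1] != vals[1:]
    idx_last = np.flatnonzero(group_last)
    q_last = np.minimum.accumulate(est[idx_last][::-1])[::-1]
    ok = np.flatnonzero(q_last <= alpha)
    if ok.size == 0:
        return empty
    cut = int(idx_last[ok[-1]]) + 1
    accepted = targets.iloc[:cut].reset_index(drop=True)
    thr = float(accepted["score"].min())
    n_decoy = int((d["is_decoy"] & (d["score"] >= thr)).sum())
    fdr_emp = empirical_fdr(accepted) if "is_correct" in d.columns else None
    return FilterOutcome(
        method="MB", group="pooled", threshold=thr, n_target=cut,
        n_decoy=n_decoy, fdr_est=float(q_last[ok[-1]]), accepted=accepted,
        fdr_emp=fdr_emp,
    )


# ---------------------------------------------------------------------------
# Self-boosted Percolator-style rescoring
# ---------------------------------------------------------------------------


def _feature_matrix(psms: pd.DataFrame) -> np.ndarray:
    return np.column_stack([
        psms["score"].to_numpy(dtype=float),
        psms["delta_next"].to_numpy(dtype=float),
        np.abs(psms["mass_error_like"].to_numpy(dtype=float)),
    ])


def boosted_rescore(psms: pd.DataFrame, cfg: BPConfig | None = None) -> pd.DataFrame:
    """Recalibrate PSM scores with a self-boosted semi-supervised classifier.

    Each boosting round labels as positives the target PSMs accepted at
    ``init_fdr`` under the current ranking (the raw score initially, the
    running average of recalibrated scores afterwards; rounds after the
    first subsample the positive set under a round-specific sub-seed so the
    procedure is less sensitive to the initial ranking). Decoys are the
    negatives. A linear classifier is trained per cross-validation fold and
    every PSM is scored only by classifiers that never saw it; the final
    recalibrated score is the average over rounds. Falls back to the raw
    score (with a warning) when there are no decoys or no positives.
    """
    cfg = cfg or BPConfig()
    d = psms.reset_index(drop=True)
    n = len(d)
    out = d.copy()
    dec = d["is_decoy"].to_numpy(dtype=bool)
    if n == 0 or not dec.any() or dec.all():
        logger.warning("rescoring needs both targets and decoys; returning raw scores")
        out["rescored"] = out["score"]
        return out

    X = StandardScaler().fit_transform(_feature_matrix(d))
    fold_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1_000_000,)))
    folds = fold_rng.permuted(np.arange(n) % cfg.n_folds)

    ranking = d["score"].to_numpy(dtype=float).copy()
    total = np.zeros(n)
    for rnd in range(cfg.n_boost_rounds):
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(rnd,)))
        tmp = d.assign(_rank=ranking)
        picked = filter_at_fdr(tmp, cfg.init_fdr, key="_rank")
        pos_spectra = set(picked.accepted["spectrum_id"])
        pos = d["spectrum_id"].isin(pos_spectra).to_numpy() & ~dec
        if rnd > 0 and pos.sum() > 1:
            pos_idx = np.flatnonzero(pos)
            keep = rng.choice(pos_idx, size=max(1, int(cfg.subsample * pos_idx.size)),
                              replace=False)
            pos = np.zeros(n, dtype=bool)
            pos[keep] = True
        if not pos.any():
            logger.warning("no positives at init_fdr=%.3g; returning raw scores", cfg.init_fdr)
            out["rescored"] = out["score"]
            return out
        train_mask = pos | dec
        y = pos.astype(int)
        round_scores = np.zeros(n)
        for k in range(cfg.n_folds):
            tr = train_mask & (folds != k)
            te = folds == k
            if y[tr].min() == y[tr].max():
                round_scores[te] = ranking[te]  # degenerate fold: keep ranking
                continue
            clf = LogisticRegression(max_iter=cfg.max_inner_iter, C=1.0)
            clf.fit(X[tr], y[tr])
            round_scores[te] = clf.decision_function(X[te])
        total += round_scores
        ranking = total / (rnd + 1)

    out["rescored"] = total / cfg.n_boost_rounds
    return out


# ---------------------------------------------------------------------------
# Separate (class-specific) filtering and the two-stage FDR
# ---------------------------------------------------------------------------

_METHOD_KEYS = {"TD": "score", "BP": "rescored", "MB": "one_minus_pep"}


def separate_filter(psms: pd.DataFrame, alpha: float,
                    method: Literal["TD", "BP", "MB"] = "TD",
                    bp_cfg: BPConfig | None = None,
                    mixture_fit: MixtureModelFit | None = None,
                    include_decoys_in_fit: bool = False,
                    collapse: bool = True) -> tuple[FilterOutcome, FilterOutcome]:
    """Filter known-group and novel-group records separately at level alpha.

    Learning steps run once on the pooled PSMs (rescoring for BP, mixture
    fitting for MB); the records — decoys included, each carrying the group
    of the database partition it was drawn from — are then partitioned by
    group and each group is thresholded independently with the ``N_D / N_T``
    estimator on the method's ranking field.
    """
    if "group" not in psms.columns:
        raise KeyError("separate filtering requires a 'group' column")
    if method == "BP":
        d = psms if "rescored" in psms.columns else boosted_rescore(psms, bp_cfg)
    elif method == "MB":
        d = psms if "one_minus_pep" in psms.columns else assign_peps(
            psms, fit=mixture_fit, include_decoys=include_decoys_in_fit)[0]
    elif method == "TD":
        d = psms
    else:
        raise ValueError(f"unknown method {method!r}")
    key = _METHOD_KEYS[method]
    if collapse:
        d = peptide_level_collapse(d, key=key)
    outcomes = []
    for grp in ("known", "novel"):
        sub = d[d["group"] == grp]
        if len(sub) and not sub["is_decoy"].any():
            logger.warning("group %r contains no decoy records; its N_D/N_T "
                           "estimate accepts every target", grp)
        outcomes.append(
            filter_at_fdr(sub, alpha, key=key, method=f"Sep{method}", group=grp)
        )
    return outcomes[0], outcomes[1]


def two_stage_filter(stage1_psms: pd.DataFrame,
                     stage2_provider: Callable[[Sequence[str]], pd.DataFrame],
                     alpha: float) -> tuple[FilterOutcome, FilterOutcome]:
    """Two-stage FDR: reference search first, proteogenomic search for the rest.

    Stage 1 filters the reference-only search at ``alpha`` (peptide level);
    spectra whose PSM was not accepted are handed to ``stage2_provider``,
    which returns their best matches against the full proteogenomic
    database, and the stage-2 result is filtered at ``alpha`` independently.
    """
    collapsed1 = peptide_level_collapse(stage1_psms, key="score")
    out1 = filter_at_fdr(collapsed1, alpha, key="score", method="TwoStage", group="stage1")
    accepted_peptides = set(out1.accepted["peptide_id"])
    targets1 = stage1_psms[~stage1_psms["is_decoy"]]
    confident = set(targets1.loc[targets1["peptide_id"].isin(accepted_peptides),
                                 "spectrum_id"])
    residual = [s for s in stage1_psms["spectrum_id"].unique() if s not in confident]
    stage2 = stage2_provider(residual)
    collapsed2 = peptide_level_collapse(stage2, key="score") if len(stage2) else stage2
    out2 = filter_at_fdr(collapsed2, alpha, key="score", method="TwoStage", group="stage2")
    return out1, out2
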