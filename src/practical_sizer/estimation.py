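"""Pattern-adjusted logistic ranking models for PRACTical trial data.

Single-stage model: ``logit(P_jk) = alpha_k + theta_j`` — one intercept per
randomization pattern plus additive treatment effects, no interaction.  This
respects the personalized randomization (comparisons are made within
pattern) while borrowing strength across patterns through the shared
treatment effects, exactly as a network meta-analysis would.

Two-stage (SMART) model: ``logit(P_jklm) = alpha_k + theta_j + psi_l`` fitted
by weighted maximum likelihood on the cloned records, with the record
weights from the simulator (inverse of the second-line list size).  The
"no second-line treatment" level is the reference for ``psi``.

Coding uses one global reference treatment (the canonical first, e.g. the
standard-of-care regimen) with a full set of pattern intercepts; fitted
probabilities are invariant to this choice.  Maximum-likelihood fitting goes
through statsmodels GLM, with exactly aliased columns dropped first (pivoted
QR), as R's ``glm`` does.  Separation — common at small n with many arms,
when some arm has no events — leaves large finite ML estimates that still
rank arms correctly; such fits are kept but flagged unconverged.  Only when
ML produces non-finite estimates or fails outright does the fit fall back
to a weak ridge penalty (Gaussian prior, sd 10, on non-intercept
coefficients), so a treatment ranking is always computable; those fits are
flagged ``penalized``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.linalg
import statsmodels.api as sm
from scipy.special import expit

from .practical_simulator import TrialData
from .scenario_model import RandomizationPattern, SingleStageScenario, SmartScenario
from .smart_simulator import SmartTrialData

__all__ = [
    "FitResult",
    "IdentifiabilityError",
    "fit_pattern_adjusted_logistic",
    "fit_two_stage_weighted_logistic",
    "predict_risks",
]

_COEF_BOUND = 15.0      # |coefficient| beyond this is treated as separation
_RIDGE_SD = 10.0        # Gaussian-prior sd for the penalized fallback
_MAX_ITER = 100
_SCORE_TOL = 1e-8
_LL_TOL = 1e-10


class IdentifiabilityError(ValueError):
    """Raised when the treatment-pattern design is disconnected."""


@dataclass(frozen=True)
class FitResult:
    """Estimated model coefficients plus convergence diagnostics.

    Reference levels (the reference treatment; "no second line" for ``psi``)
    have coefficient exactly 0 and are included in the mappings.  ``se``
    holds plain information-matrix standard errors keyed like the
    coefficients (0 for reference levels).
    """

    alpha: Mapping[int, float]
    theta: Mapping[str, float]
    psi: Mapping[str, float] | None
    reference: str
    converged: bool
    penalized: bool
    n_iter: int
    loglik: float
    se: Mapping[str, float] = field(default_factory=dict)
    aliased: tuple[str, ...] = ()

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha": {str(k): v for k, v in self.alpha.items()},
                "theta": dict(self.theta),
                "psi": dict(self.psi) if self.psi is not None else None,
                "reference": self.reference,
                "converged": self.converged,
                "penalized": self.penalized,
                "n_iter": self.n_iter,
                "loglik": self.loglik,
            }
        )


def _check_connected(pattern_idx: np.ndarray, treatment_idx: np.ndarray) -> None:
    g = nx.Graph()
    pairs = set(zip(pattern_idx.tolist(), treatment_idx.tolist()))
    for k, j in pairs:
        g.add_edge(("p", k), ("t", j))
    if g.number_of_nodes() and not nx.is_connected(g):
        raise IdentifiabilityError(
            "treatment-pattern design is disconnected; treatment effects are "
            "not comparable across components"
        )


def _wloglik(X: np.ndarray, y: np.ndarray, w: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log-likelihood via log1p(exp) for numerical stability
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def _newton_ridge(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, penalty: np.ndarray
) -> tuple[np.ndarray, np.ndarray, bool, int, float]:
    """Penalized weighted logistic fit by damped Newton iteration.

    ``penalty`` is the per-coefficient Gaussian-prior precision (0 for
    unpenalized coordinates).  Returns (beta, se, converged, n_iter, loglik).
    """
    p = X.shape[1]
    beta = np.zeros(p)
    obj = _wloglik(X, y, w, beta) - 0.5 * float(penalty @ beta**2)
    converged = False
    it = 0
    H = np.eye(p)
    for it in range(1, _MAX_ITER + 1):
        mu = expit(X @ beta)
        score = X.T @ (w * (y - mu)) - penalty * beta
        if np.max(np.abs(score)) < _SCORE_TOL:
            converged = True
            break
        wt = w * mu * (1.0 - mu)
        H = (X.T * wt) @ X + np.diag(penalty)
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, score, rcond=None)[0]
        # damped update: halve the step until the penalized loglik improves
        new_obj = None
        for _ in range(30):
            cand = beta + step
            cand_obj = _wloglik(X, y, w, cand) - 0.5 * float(penalty @ cand**2)
            if cand_obj >= obj - 1e-12:
                new_obj = cand_obj
                break
            step *= 0.5
        if new_obj is None:
            break
        beta = beta + step
        if abs(new_obj - obj) <= _LL_TOL * (abs(obj) + 1.0):
            obj = new_obj
            converged = True
            break
        obj = new_obj
    mu = expit(X @ beta)
    wt = w * mu * (1.0 - mu)
    H = (X.T * wt) @ X + np.diag(penalty)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return beta, se, converged, it, _wloglik(X, y, w, beta)


def _independent_columns(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (pivoted QR).

    Weighted designs can be exactly rank-deficient (aliased levels, e.g. a
    treatment observed only at one level of another factor, or an empty
    pattern).  Like R's ``glm``, aliased columns are dropped before fitting;
    their coefficients are reported as 0.  Fitted probabilities for any
    design row obeying the same structural constraints are unaffected.
    """
    A = np.sqrt(w)[:, None] * X
    _, R, piv = scipy.linalg.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(A.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    return np.sort(piv[:rank])


def _fit_design(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    n_intercepts: int,
) -> tuple[np.ndarray, np.ndarray, bool, bool, int, float, np.ndarray]:
    """ML fit with aliased-column dropping and penalized separation fallback.

    Returns (beta, se, converged, penalized, n_iter, loglik, kept_columns);
    beta and se are full-length with 0 / nan in dropped positions.
    """
    p = X.shape[1]
    keep = _independent_columns(X, w)
    Xk = X[:, keep] if len(keep) < p else X
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, Xk, family=sm.families.Binomial(), freq_weights=w)
            res = model.fit(maxiter=_MAX_ITER, tol=_LL_TOL)
        bk = np.asarray(res.params)
        if np.all(np.isfinite(bk)):
            # Separation (zero-event arms) leaves IRLS unconverged with large
            # finite coefficients.  Those estimates still order the arms the
            # way maximum likelihood would in the limit (zero-event arms
            # ranked best), which is what a standard glm analysis of each
            # simulated trial uses, so they are kept and only flagged.
            converged = bool(res.converged and np.max(np.abs(bk)) <= _COEF_BOUND)
            beta = np.zeros(p)
            se = np.full(p, np.nan)
            beta[keep] = bk
            se[keep] = np.asarray(res.bse)
            return beta, se, converged, False, int(res.fit_history["iteration"]), float(res.llf), keep
    except Exception:
        pass
    # separation: weak ridge on non-intercept terms; intercepts of patterns
    # never observed get the same weak prior so the fit stays finite.
    col_weight = np.abs(X).T @ w
    penalty = np.full(p, 1.0 / _RIDGE_SD**2)
    penalty[:n_intercepts] = 0.0
    penalty[:n_intercepts][col_weight[:n_intercepts] <= 0.0] = 1.0 / _RIDGE_SD**2
    beta, se, converged, it, ll = _newton_ridge(X, y, w, penalty)
    return beta, se, converged, True, it, ll, np.arange(p)


def _single_stage_design(
    data: TrialData, reference: str
) -> tuple[np.ndarray, list, list]:
    n = data.n
    K = len(data.patterns)
    others = [j for j in data.treatments if j != reference]
    t_col = {j: K + i for i, j in enumerate(others)}
    X = np.zeros((n, K + len(others)))
    X[np.arange(n), data.pattern_idx] = 1.0
    for j, c in t_col.items():
        X[data.treatment_idx == data.treatments.index(j), c] = 1.0
    return X, list(data.patterns), others


def fit_pattern_adjusted_logistic(
    data: TrialData, reference: str | None = None
) -> FitResult:
    """Fit ``logit(P_jk) = alpha_k + theta_j`` by maximum likelihood.

    ``reference`` names the treatment with ``theta = 0`` (default: the first
    in canonical order).  Predicted probabilities are invariant to this
    choice.  Raises :class:`IdentifiabilityError` if the observed
    treatment-pattern design is disconnected; separation falls back to the
    penalized fit (``penalized`` flag set), never an exception.
    """
    if data.n == 0:
        raise ValueError("empty data")
    reference = reference or data.treatments[0]
    if reference not in data.treatments:
        raise ValueError(f"unknown reference treatment {reference!r}")
    _check_connected(data.pattern_idx, data.treatment_idx)
    X, pattern_ids, others = _single_stage_design(data, reference)
    y = data.outcome.astype(float)
    w = np.ones(data.n)
    beta, se, converged, penalized, it, ll, keep = _fit_design(X, y, w, len(pattern_ids))
    K = len(pattern_ids)
    labels = [f"alpha:{k}" for k in pattern_ids] + [f"theta:{j}" for j in others]
    aliased = tuple(labels[i] for i in range(len(labels)) if i not in set(keep))
    theta = {reference: 0.0, **{j: float(b) for j, b in zip(others, beta[K:])}}
    theta_se = {reference: 0.0, **{j: float(s) for j, s in zip(others, se[K:])}}
    return FitResult(
        alpha={k: float(b) for k, b in zip(pattern_ids, beta[:K])},
        theta=theta,
        psi=None,
        reference=reference,
        converged=converged,
        penalized=penalized,
        n_iter=it,
        loglik=ll,
        se=theta_se,
        aliased=aliased,
    )


def fit_two_stage_weighted_logistic(
    data: SmartTrialData, reference: str | None = None
) -> FitResult:
    """Fit ``logit(P_jklm) = alpha_k + theta_j + psi_l`` by weighted ML.

    Records carry the simulator's inverse-probability weights; "no
    second-line treatment" is the reference level for ``psi``.  Separation
    policy as in :func:`fit_pattern_adjusted_logistic`.
    """
    if len(data.outcome) == 0:
        raise ValueError("empty data")
    if np.any(data.weight <= 0):
        raise ValueError("weights must be positive")
    reference = reference or data.treatments[0]
    if reference not in data.treatments:
        raise ValueError(f"unknown reference treatment {reference!r}")
    _check_connected(data.pattern_idx, data.treatment_idx)

    n_rec = len(data.outcome)
    K = len(data.patterns)
    others = [j for j in data.treatments if j != reference]
    second = list(data.second_line_treatments)
    p = K + len(others) + len(second)
    X = np.zeros((n_rec, p))
    X[np.arange(n_rec), data.pattern_idx] = 1.0
    for i, j in enumerate(others):
        X[data.treatment_idx == data.treatments.index(j), K + i] = 1.0
    base_col = K + len(others)
    has_second = data.second_idx >= 0
    X[np.where(has_second)[0], base_col + data.second_idx[has_second]] = 1.0

    y = data.outcome.astype(float)
    w = np.asarray(data.weight, dtype=float)
    beta, se, converged, penalized, it, ll, keep = _fit_design(X, y, w, K)
    labels = (
        [f"alpha:{k}" for k in data.patterns]
        + [f"theta:{j}" for j in others]
        + [f"psi:{l}" for l in second]
    )
    aliased = tuple(labels[i] for i in range(len(labels)) if i not in set(keep))
    theta = {reference: 0.0, **{j: float(b) for j, b in zip(others, beta[K:base_col])}}
    theta_se = {reference: 0.0, **{j: float(s) for j, s in zip(others, se[K:base_col])}}
    psi = {l: float(b) for l, b in zip(second, beta[base_col:])}
    psi_se = {f"psi:{l}": float(s) for l, s in zip(second, se[base_col:])}
    return FitResult(
        alpha={k: float(b) for k, b in zip(data.patterns, beta[:K])},
        theta=theta,
        psi=psi,
        reference=reference,
        converged=converged,
        penalized=penalized,
        n_iter=it,
        loglik=ll,
        se={**theta_se, **psi_se},
        aliased=aliased,
    )


def predict_risks(
    fit: FitResult,
    structure: SingleStageScenario | SmartScenario | Sequence[RandomizationPattern],
) -> dict:
    """Predicted adverse-outcome probabilities for every eligible option.

    For a single-stage structure returns ``{(j, k): P_hat_jk}`` over eligible
    treatment-pattern pairs; for a :class:`SmartScenario` returns
    ``{(k, j, l_or_None): P_hat}`` over eligible strategies, with the ``psi``
    term omitted for no-second-line strategies.
    """
    if isinstance(structure, SmartScenario):
        if fit.psi is None:
            raise ValueError("single-stage fit cannot predict strategy risks")
        out: dict[tuple[int, str, str | None], float] = {}
        for pat in structure.first_stage.patterns:
            for j in pat.members:
                eta = fit.alpha[pat.id] + fit.theta[j]
                lst = structure.second_line_list(pat.id, j)
                if not lst:
                    out[(pat.id, j, None)] = float(expit(eta))
                for l_id in lst:
                    out[(pat.id, j, l_id)] = float(expit(eta + fit.psi[l_id]))
        return out
    patterns = structure.patterns if isinstance(structure, SingleStageScenario) else structure
    res: dict[tuple[str, int], float] = {}
    for pat in patterns:
        for j in pat.members:
            if j not in fit.theta:
                raise KeyError(f"treatment {j!r} not in fitted model")
            res[(j, pat.id)] = float(expit(fit.alpha[pat.id] + fit.theta[j]))
    return res
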