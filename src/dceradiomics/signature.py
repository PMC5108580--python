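"""Leave-one-case-out phenotypic signatures: stepwise selection + linear
discriminant classification.

For each classification task (ER, PR, HER2, TN) every case is held out in
turn; on the remaining cases the features are z-scored, a classical stepwise
discriminant selection (forward inclusion / backward elimination on the
partial F of the Wilks'-lambda reduction) picks a small feature set, a
Fisher linear discriminant is fit on it, and the held-out case is scored.
The pooled held-out scores give the cross-validated empirical AUC, and the
most frequently selected feature combination across folds is reported as
the task's *phenotypic signature*.

Default entry/removal thresholds are family-wise corrected over the
candidate pool (see :class:`StepwiseConfig`), and at most 4 features may
enter — guards against overfitting when ~38 candidate phenotypes chase ~90
cases.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import TASKS, RocResult, empirical_auc

logger = logging.getLogger(__name__)

__all__ = [
    "StepwiseConfig",
    "LdaModel",
    "SignatureResult",
    "stepwise_select",
    "lda_fit",
    "lda_score",
    "loocv_signature",
]


@dataclass
class StepwiseConfig:
    """Stepwise selection thresholds.

    By default the F-to-enter / F-to-remove thresholds are *family-wise
    corrected*: the entry threshold is the F(1, dof) quantile at
    ``1 - alpha_enter / p`` where ``p`` is the number of candidate features
    (Bonferroni over the candidate pool), and the removal threshold uses the
    laxer ``alpha_remove``.  With dozens of candidate phenotypes a fixed
    per-test threshold (the textbook F=4, per-test p≈0.05) admits a spurious
    feature in most null fits, which both deflates the cross-validated AUC
    under a real effect and biases the pooled null AUC well below 0.5; the
    corrected threshold keeps the selection calibrated (≈``alpha_enter``
    family-wise spurious-entry rate) regardless of the candidate count.
    Explicit ``f_enter`` / ``f_remove`` override the adaptive rule.
    """

    alpha_enter: float = 0.05
    alpha_remove: float = 0.10
    f_enter: float | None = None
    f_remove: float | None = None
    max_features: int = 4
    ridge: float = 1e-6

    def __post_init__(self) -> None:
        if (self.f_enter is None) != (self.f_remove is None):
            raise ValueError("set both or neither of f_enter / f_remove")
        if self.f_enter is not None and self.f_remove >= self.f_enter:
            raise ValueError("f_remove must be < f_enter (else the loop can cycle)")
        if not 0 < self.alpha_enter <= self.alpha_remove < 1:
            raise ValueError("need 0 < alpha_enter <= alpha_remove < 1")
        if self.max_features < 1:
            raise ValueError("max_features must be >= 1")

    def thresholds(self, n_candidates: int, dof: int) -> tuple[float, float]:
        """(F-to-enter, F-to-remove) for the given pool size and error dof."""
        if self.f_enter is not None:
            return self.f_enter, self.f_remove
        from scipy.stats import f as f_dist

        dof = max(dof, 1)
        enter = float(f_dist.ppf(1.0 - self.alpha_enter / n_candidates, 1, dof))
        remove = float(f_dist.ppf(1.0 - self.alpha_remove / n_candidates, 1, dof))
        return enter, remove


@dataclass
class LdaModel:
    """Fisher discriminant: ``score = w @ x - threshold``, higher = positive."""

    weights: np.ndarray
    threshold: float
    feature_names: tuple[str, ...] = ()


@dataclass
class SignatureResult:
    task: str
    case_ids: list[str]
    per_case_scores: np.ndarray
    labels: np.ndarray
    auc: RocResult
    fold_selections: list[tuple[str, ...]]
    modal_signature: tuple[str, ...]
    modal_count: int
    fold_models: list[LdaModel] = field(repr=False, default_factory=list)

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "auc": self.auc.auc,
            "p_vs_chance": self.auc.p_vs_chance,
            "n_pos": self.auc.n_pos,
            "n_neg": self.auc.n_neg,
            "modal_signature": list(self.modal_signature),
            "modal_count": self.modal_count,
            "n_folds": len(self.fold_selections),
            "fold_selections": [list(s) for s in self.fold_selections],
            "per_case": [
                {"case_id": c, "score": float(s), "label": bool(l)}
                for c, s, l in zip(self.case_ids, self.per_case_scores, self.labels)
            ],
        }


def _scatter_matrices(x: np.ndarray, y: np.ndarray):
    """Total and pooled within-group scatter (cross-product) matrices."""
    xc = x - x.mean(axis=0)
    total = xc.T @ xc
    within = np.zeros_like(total)
    for g in (0, 1):
        xg = x[y == g]
        xg = xg - xg.mean(axis=0)
        within += xg.T @ xg
    return total, within


def _partial_f_candidates(total, within, selected, candidates, n, log_lambda_sel):
    """Partial F of adding each candidate to the selected set.

    Uses the block-determinant identity: with S the current set,
    ``Lambda(S+j) = Lambda(S) * (w_jj - w_Sj' W_SS^-1 w_Sj) /
    (t_jj - t_Sj' T_SS^-1 t_Sj)``, so one solve per scatter matrix prices
    all candidates.  Candidates with a (near-)singular residual are skipped.
    """
    g = 2
    cand = np.asarray(candidates)
    if selected:
        s = list(selected)
        w_ss = within[np.ix_(s, s)]
        t_ss = total[np.ix_(s, s)]
        w_sc = within[np.ix_(s, cand)]
        t_sc = total[np.ix_(s, cand)]
        try:
            res_w = within[cand, cand] - np.einsum(
                "ij,ij->j", w_sc, np.linalg.solve(w_ss, w_sc)
            )
            res_t = total[cand, cand] - np.einsum(
                "ij,ij->j", t_sc, np.linalg.solve(t_ss, t_sc)
            )
        except np.linalg.LinAlgError:
            return np.full(cand.size, np.nan)
    else:
        res_w = within[cand, cand]
        res_t = total[cand, cand]
    ok = (res_w > 1e-12) & (res_t > 1e-12)
    # partial Wilks lambda for j given S
    lam = np.full(cand.size, np.nan)
    np.divide(res_w, res_t, out=lam, where=ok)
    dof = n - g - len(selected)
    f = np.full(cand.size, np.nan)
    np.divide(1.0, lam, out=f, where=ok)
    return (f - 1.0) * dof / (g - 1)


def stepwise_select(
    features: np.ndarray,
    labels: np.ndarray,
    feature_names: list[str],
    config: StepwiseConfig | None = None,
) -> list[str]:
    """Stepwise discriminant feature selection (forward + backward).

    At each step the candidate maximizing the partial F of the
    Wilks'-lambda reduction enters if its F >= ``f_enter``; any included
    feature whose partial F (given the others) falls below ``f_remove`` is
    then removed.  The loop stops when nothing changes or ``max_features``
    is reached.  Ties are broken lexicographically on feature name, making
    the procedure fully deterministic.
    """
    config = config or StepwiseConfig()
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    n, p = x.shape
    if len(feature_names) != p:
        raise ValueError("feature_names length must match feature columns")
    for g in (0, 1):
        if (y == g).sum() < 2:
            raise ValueError("need at least 2 cases per class")

    total, within = _scatter_matrices(x, y)
    names = np.asarray(feature_names)
    selected: list[int] = []
    seen_states = set()
    max_rounds = 4 * config.max_features * p + 10
    for _ in range(max_rounds):
        state = frozenset(selected)
        if state in seen_states:
            break
        seen_states.add(state)
        changed = False

        f_enter, f_remove = config.thresholds(p, n - 2 - len(selected))

        if len(selected) < config.max_features:
            candidates = [j for j in range(p) if j not in selected]
            if candidates:
                f = _partial_f_candidates(
                    total, within, selected, candidates, n, None
                )
                finite = np.isfinite(f)
                if not finite.all():
                    skipped = names[np.asarray(candidates)[~finite]]
                    warnings.warn(
                        f"stepwise: skipped near-singular candidates {list(skipped)}",
                        stacklevel=2,
                    )
                if finite.any():
                    fmax = np.nanmax(f)
                    if fmax >= f_enter:
                        best = [
                            candidates[j]
                            for j in range(len(candidates))
                            if finite[j] and f[j] >= fmax - 1e-10
                        ]
                        entering = min(best, key=lambda j: names[j])
                        selected.append(entering)
                        changed = True

        # backward elimination
        while len(selected) > 1:
            fs = np.array([
                _partial_f_candidates(
                    total, within, [k for k in selected if k != j], [j], n, None
                )[0]
                for j in selected
            ])
            fs = np.where(np.isfinite(fs), fs, np.inf)
            fmin = fs.min()
            if fmin >= f_remove:
                break
            worst = [selected[i] for i in range(len(selected)) if fs[i] <= fmin + 1e-10]
            removing = min(worst, key=lambda j: names[j])
            selected.remove(removing)
            changed = True

        if not changed:
            break

    return [str(names[j]) for j in selected]


def lda_fit(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    feature_names=(),
    ridge: float = 1e-6,
) -> LdaModel:
    """Fisher linear discriminant ``w ∝ Sigma_w^-1 (mu1 - mu0)``.

    The pooled within-class covariance gets a ridge ``ridge * mean(diag)``
    on the diagonal if it is singular or ill-conditioned (logged).  The
    orientation guarantees a higher score for the positive class on the
    training data; the threshold is the midpoint of the projected means.
    """
    x = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels).astype(int)
    if x.ndim != 2:
        raise ValueError("train_features must be 2D")
    if (y == 0).sum() == 0 or (y == 1).sum() == 0:
        raise ValueError("one training class is empty")
    mu0 = x[y == 0].mean(axis=0)
    mu1 = x[y == 1].mean(axis=0)
    n = x.shape[0]
    _, within = _scatter_matrices(x, y)
    cov = within / max(n - 2, 1)
    diff = mu1 - mu0
    try:
        cond = np.linalg.cond(cov)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        bump = ridge * max(float(np.trace(cov)) / cov.shape[0], 1.0)
        cov = cov + bump * np.eye(cov.shape[0])
        logger.info("lda_fit: ridge %g added to ill-conditioned covariance", bump)
    w = np.linalg.solve(cov, diff)
    threshold = float(w @ (mu0 + mu1) / 2.0)
    return LdaModel(weights=w, threshold=threshold, feature_names=tuple(feature_names))


def lda_score(model: LdaModel, case_features) -> float:
    """Scalar discriminant score of one case (higher = positive class)."""
    return float(np.asarray(case_features, dtype=float) @ model.weights - model.threshold)


def _modal_signature(selections: list[tuple[str, ...]]):
    counts = Counter(selections)
    # most frequent; ties -> smaller set, then lexicographic
    best = min(counts.items(), key=lambda kv: (-kv[1], len(kv[0]), kv[0]))
    return best[0], best[1]


def loocv_signature(
    cohort: pd.DataFrame,
    task: str,
    features: list[str] | None = None,
    config: StepwiseConfig | None = None,
) -> SignatureResult:
    """Leave-one-case-out stepwise-LDA signature for one task.

    Each fold drops one case, z-scores the remaining features (training
    mean/sd), runs stepwise selection and LDA, and scores the held-out case
    with the fold's model — no information from the held-out case ever
    reaches its training fold.  Folds that select no feature score 0
    (uninformative tie).  Pooled held-out scores give the empirical AUC.
    """
    config = config or StepwiseConfig()
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; choose from {sorted(TASKS)}")
    col, pos_value = TASKS[task]
    if features is None:
        features = [
            c for c in cohort.columns
            if c not in ("case_id", "er", "pr", "her2", "tn", "subtype")
        ]
    labels_raw = cohort[col]
    if col == "tn":
        usable = labels_raw.notna()
    else:
        usable = labels_raw.isin(["+", "-"])
    usable &= cohort[features].notna().all(axis=1)
    sub = cohort.loc[usable].reset_index(drop=True)
    y = (sub[col] == pos_value).to_numpy().astype(int)
    x = sub[features].to_numpy(dtype=float)
    n = len(sub)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError(f"task {task}: need >= 2 cases in each class")
    if n < 10:
        logger.warning("task %s: only %d usable cases", task, n)

    scores = np.full(n, np.nan)
    fold_selections: list[tuple[str, ...]] = []
    fold_models: list[LdaModel] = []
    kept = np.ones(n, dtype=bool)
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        y_tr = y[train]
        if y_tr.min() == y_tr.max() or min((y_tr == 0).sum(), (y_tr == 1).sum()) < 2:
            logger.warning("task %s: fold %d lost a class; skipped", task, i)
            kept[i] = False
            fold_selections.append(())
            fold_models.append(LdaModel(np.zeros(0), 0.0))
            continue
        mean = x[train].mean(axis=0)
        sd = x[train].std(axis=0, ddof=1)
        sd = np.where(sd > 1e-12, sd, 1.0)
        x_tr = (x[train] - mean) / sd
        x_te = (x[i] - mean) / sd

        sel = stepwise_select(x_tr, y_tr, features, config)
        fold_selections.append(tuple(sorted(sel)))
        if not sel:
            scores[i] = 0.0
            fold_models.append(LdaModel(np.zeros(0), 0.0))
            continue
        idx = [features.index(s) for s in sel]
        model = lda_fit(x_tr[:, idx], y_tr, feature_names=sel, ridge=config.ridge)
        fold_models.append(model)
        scores[i] = lda_score(model, x_te[idx])

    auc = empirical_auc(scores[kept], y[kept].astype(bool))
    modal, count = _modal_signature([s for s, k in zip(fold_selections, kept) if k])
    return SignatureResult(
        task=task,
        case_ids=sub["case_id"].tolist(),
        per_case_scores=scores,
        labels=y.astype(bool),
        auc=auc,
        fold_selections=fold_selections,
        modal_signature=modal,
        modal_count=count,
        fold_models=fold_models,
    )
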