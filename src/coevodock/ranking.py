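"""Combined logistic scoring, decoy ranking and success-curve evaluation.

The per-decoy components are combined linearly,

    S = w0 + wN*S_N + wRP*S_RP + went*S_ent + wCT*S_CT + wCMM*S_CMM,

with the weights fitted by logistic regression of the near-native label on
the active components (S is the logit of the near-native probability, so
S > 0 means likelier near-native than not).  Weight fitting, complex-level
k-fold cross-validation and the top-k success curve (fraction of complexes
with a near-native decoy among the k best-scored poses) live here.

Decoy tables are plain pandas DataFrames with one row per (complex, decoy)
and the component columns ``S_N, S_RP, S_ent, S_CT, S_CMM`` plus
``near_native``; inactive terms are simply not listed in ``terms``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .structure import (
    ComplexStructure,
    InterfaceSet,
    interface_backbone_rmsd,
)

NEAR_NATIVE_RMSD = 3.0

#: canonical order of the component terms in Eq-style weight vectors
ALL_TERMS = ("S_N", "S_RP", "S_ent", "S_CT", "S_CMM")


class DegenerateFitError(ValueError):
    """Training labels contain a single class."""


class FitConvergenceError(RuntimeError):
    """The logistic fit failed to converge (e.g. separation without ridge)."""


@dataclass(frozen=True)
class ScoringWeights:
    """Fitted weights of the combined score; inactive terms are exactly 0."""

    w0: float
    weights: dict[str, float]
    active_terms: tuple[str, ...]
    standard_errors: dict[str, float] | None = None

    def weight(self, term: str) -> float:
        return self.weights.get(term, 0.0)

    def as_dict(self) -> dict[str, float]:
        d = {"w0": self.w0}
        d.update({t: self.weight(t) for t in ALL_TERMS})
        return d


def label_near_native(
    decoys: list[ComplexStructure],
    native: ComplexStructure,
    native_interface: InterfaceSet,
    threshold: float = NEAR_NATIVE_RMSD,
    fit: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Interface backbone RMSD and near-native labels (iRMSD strictly < 3 Å)."""
    rmsds = np.array(
        [
            interface_backbone_rmsd(d, native, native_interface, fit=fit)
            for d in decoys
        ]
    )
    return rmsds, rmsds < threshold


def fit_weights(
    table: pd.DataFrame,
    terms: tuple[str, ...],
    ridge: float = 1e-6,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> ScoringWeights:
    """Fit the combined score by ridge-stabilised logistic regression.

    Newton/IRLS maximisation of the binomial log-likelihood with an L2
    penalty ``ridge`` on every weight (intercept included).  The tiny
    default keeps separable training sets finite while leaving the
    estimates indistinguishable from the plain glm fit; ``ridge=0``
    reproduces unpenalised behaviour and raises
    :class:`FitConvergenceError` on separation.  Deterministic.  Standard
    errors come from the inverse curvature at the optimum.
    """
    unknown = [t for t in terms if t not in ALL_TERMS]
    if unknown:
        raise ValueError(f"unknown score terms: {unknown}")
    y = table["near_native"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise DegenerateFitError("training labels contain a single class")
    x = np.column_stack(
        [np.ones(len(table))] + [table[t].to_numpy(dtype=float) for t in terms]
    )
    if not np.isfinite(x).all():
        raise ValueError("non-finite score components in the training table")

    beta = np.zeros(x.shape[1])
    for _ in range(max_iter):
        eta = x @ beta
        p = expit(eta)
        w = np.clip(p * (1.0 - p), 1e-12, None)
        grad = x.T @ (y - p) - ridge * beta
        hess = (x * w[:, None]).T @ x + ridge * np.eye(x.shape[1])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if not np.isfinite(beta).all() or np.abs(beta).max() > 1e8:
            raise FitConvergenceError(
                "weights diverged (separable data without a ridge stabiliser?)"
            )
        if np.abs(step).max() < tol:
            break
    else:
        raise FitConvergenceError(
            f"IRLS did not converge within {max_iter} iterations"
        )

    p = expit(x @ beta)
    w = np.clip(p * (1.0 - p), 1e-12, None)
    cov = np.linalg.inv((x * w[:, None]).T @ x + ridge * np.eye(x.shape[1]))
    se = np.sqrt(np.diag(cov))
    names = ("w0",) + tuple(terms)
    return ScoringWeights(
        w0=float(beta[0]),
        weights={t: float(b) for t, b in zip(terms, beta[1:])},
        active_terms=tuple(terms),
        standard_errors={n: float(s) for n, s in zip(names, se)},
    )


def combined_score(components: dict | pd.Series, weights: ScoringWeights) -> float:
    """S = w0 + sum of active weights times components."""
    total = weights.w0
    for term in weights.active_terms:
        value = components[term]
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise ValueError(f"active component {term} is missing")
        total += weights.weight(term) * float(value)
    return float(total)


def score_table(table: pd.DataFrame, weights: ScoringWeights) -> np.ndarray:
    """Vectorised combined score for every row of a component table."""
    s = np.full(len(table), weights.w0)
    for term in weights.active_terms:
        col = table[term].to_numpy(dtype=float)
        if not np.isfinite(col).all():
            raise ValueError(f"active component {term} has missing values")
        s += weights.weight(term) * col
    return s


def assign_folds(complexes: list, k: int, seed: int) -> dict:
    """Deterministic complex-level fold assignment (seeded shuffle)."""
    if len(complexes) < k:
        raise ValueError(f"need at least {k} complexes, got {len(complexes)}")
    order = list(complexes)
    rng = np.random.default_rng(seed)
    rng.shuffle(order)
    return {c: i % k for i, c in enumerate(order)}


def cross_validate(
    table: pd.DataFrame,
    terms: tuple[str, ...],
    k: int = 3,
    seed: int = 0,
    ridge: float = 1e-6,
) -> tuple[pd.DataFrame, dict[int, ScoringWeights]]:
    """Complex-level k-fold cross-validation of the combined score.

    Complexes (never individual decoys) are partitioned into k folds by a
    seeded shuffle; each fold's decoys are scored with weights fitted on
    the other folds only.  Returns the table with ``fold`` and
    out-of-fold ``score`` columns added, plus the per-fold weights.
    """
    complexes = list(dict.fromkeys(table["complex"]))
    folds = assign_folds(complexes, k, seed)
    out = table.copy()
    out["fold"] = out["complex"].map(folds)
    out["score"] = np.nan
    fitted: dict[int, ScoringWeights] = {}
    for fold in range(k):
        train = out[out["fold"] != fold]
        test_mask = out["fold"] == fold
        w = fit_weights(train, terms, ridge=ridge)
        fitted[fold] = w
        out.loc[test_mask, "score"] = score_table(out[test_mask], w)
    return out, fitted


def rank_decoys(scores: np.ndarray) -> np.ndarray:
    """1-based ranks by descending score; ties keep input (stable) order."""
    order = np.argsort(-np.asarray(scores, float), kind="stable")
    ranks = np.empty(len(order), dtype=int)
    ranks[order] = np.arange(1, len(order) + 1)
    return ranks


def success_curve(table: pd.DataFrame, max_k: int) -> np.ndarray:
    """Fraction of complexes with a near-native decoy in the top k, k=1..max_k.

    Decoys are ranked per complex by the ``score`` column (descending,
    stable ties); the curve is non-decreasing in k by construction.
    """
    complexes = list(dict.fromkeys(table["complex"]))
    first_hit = []
    for c in complexes:
        sub = table[table["complex"] == c]
        ranks = rank_decoys(sub["score"].to_numpy())
        nn = sub["near_native"].to_numpy(dtype=bool)
        hits = ranks[nn]
        first_hit.append(hits.min() if hits.size else np.inf)
    first_hit = np.array(first_hit)
    ks = np.arange(1, max_k + 1)
    return (first_hit[None, :] <= ks[:, None]).mean(axis=1)


def best_near_native_rank(table: pd.DataFrame) -> dict:
    """Per complex, the rank of the best-ranked near-native decoy (inf if none)."""
    out = {}
    for c in dict.fromkeys(table["complex"]):
        sub = table[table["complex"] == c]
        ranks = rank_decoys(sub["score"].to_numpy())
        nn = sub["near_native"].to_numpy(dtype=bool)
        hits = ranks[nn]
        out[c] = int(hits.min()) if hits.size else float("inf")
    return out


def write_weights(weights: ScoringWeights, path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(weights.as_dict(), fh, indent=1)


def read_weights(path, terms: tuple[str, ...] | None = None) -> ScoringWeights:
    import json

    with open(path) as fh:
        d = json.load(fh)
    active = tuple(terms) if terms else tuple(
        t for t in ALL_TERMS if d.get(t, 0.0) != 0.0
    )
    return ScoringWeights(
        w0=float(d["w0"]),
        weights={t: float(d.get(t, 0.0)) for t in active},
        active_terms=active,
    )
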