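"""One-class novelty detection on expression profiles.

The question: which transcripts, not themselves TE-derived, behave like
HTT transcripts across experimental groups?  A one-class support vector
machine with an RBF kernel is trained on the expression profiles of HTT
transcripts whose max fold change exceeds a cut (default 4, chosen to keep
the training set comfortably above ~50 profiles), and every other
transcript is scored against the learned boundary.  With data from two
independent experiments, per-experiment models are fitted and the positive
sets intersected — a candidate must look HTT-like in both.

A profile is the vector of log2(1 + normalized mean count) per
experimental group, standardized feature-wise on the training set before
fitting; the log transform makes the boundary sensitive to expression
*pattern* rather than absolute abundance, and standardization is required
by any scale-sensitive kernel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import OneClassSVM

from .expression import ExpressionStats
from .io import CountMatrix


def build_profiles(group_values: pd.DataFrame,
                   center: bool = True) -> pd.DataFrame:
    """Expression profiles with a fixed group order; rows are transcripts.

    A profile is log2(1 + per-group summary count), and by default each
    profile is centered on its own mean (the per-gene centering standard in
    expression-pattern clustering): two transcripts with the same relative
    response across groups then have the same profile regardless of
    absolute abundance, which is exactly the notion of "similar expression
    pattern" the one-class boundary is asked to capture.  Pass
    ``center=False`` to keep absolute log abundance in the features.
    """
    logged = np.log2(1.0 + group_values)
    if center:
        return logged.sub(logged.mean(axis=1), axis=0)
    return logged


def select_training_set(stats_by_project: Mapping[str, ExpressionStats],
                        htt_ids: Iterable[str],
                        mfc_cut: float = 4.0) -> set[str]:
    """HTT transcripts with MFC strictly above ``mfc_cut`` in at least one
    project.  Empty result is an error; <= 50 emits a warning (one-class
    boundaries on tiny training sets are unstable)."""
    import warnings

    htt_ids = set(htt_ids)
    selected: set[str] = set()
    for stats in stats_by_project.values():
        mfc = stats.mfc
        hits = mfc[(mfc > mfc_cut) & mfc.index.isin(htt_ids)]
        selected |= set(hits.index)
    if not selected:
        raise ValueError("empty novelty training set")
    if len(selected) <= 50:
        warnings.warn(
            f"novelty training set has only {len(selected)} profiles",
            stacklevel=2)
    return selected


#: Decision values within this band of zero are on the boundary: margin
#: support vectors sit at exactly zero in exact arithmetic and the solver
#: leaves them within ~1e-8 of it; genuine outliers score orders of
#: magnitude lower.
BOUNDARY_EPS = 1e-6


@dataclass
class NoveltyModel:
    """Fitted one-class boundary: feature scaler + RBF one-class SVM."""

    scaler: StandardScaler
    svm: OneClassSVM
    n_features: int
    feature_names: tuple[str, ...]
    nu: float
    seed: int
    boundary_eps: float = BOUNDARY_EPS

    def decision_values(self, profiles: pd.DataFrame) -> pd.Series:
        if profiles.shape[1] != self.n_features:
            raise ValueError(
                f"profile dimension {profiles.shape[1]} != model "
                f"dimension {self.n_features}")
        x = self.scaler.transform(profiles.to_numpy(dtype=float))
        return pd.Series(self.svm.decision_function(x),
                         index=profiles.index)


def _median_heuristic_gamma(x: np.ndarray) -> float:
    """RBF width from the median pairwise squared distance of the
    (standardized) training set: gamma = 1 / (2 median ||xi - xj||^2).

    The median heuristic matches the kernel scale to the typical spacing
    of training points, giving a boundary smooth enough to generalize from
    modest training sets (~50-100 profiles) where the per-feature-variance
    default produces a boundary that hugs the sample."""
    from scipy.spatial.distance import pdist

    d2 = pdist(x, "sqeuclidean")
    med = float(np.median(d2))
    if med <= 0:
        return 1.0 / max(x.shape[1], 1)
    return 1.0 / (2.0 * med)


def fit_novelty(profiles: pd.DataFrame, nu: float = 0.1,
                gamma: float | str = "median",
                seed: int = 0) -> NoveltyModel:
    """Fit the one-class model on training profiles.

    ``nu`` bounds the training-outlier fraction.  ``gamma`` may be a
    number, ``'median'`` (default: median pairwise-distance heuristic on
    the standardized training set) or ``'scale'`` (scikit-learn's
    1/(n_features x feature variance)).  The fit itself is deterministic;
    the seed is recorded for provenance.
    """
    if not 0 < nu <= 1:
        raise ValueError("nu must be in (0, 1]")
    if profiles.shape[0] < 2:
        raise ValueError("need >= 2 training profiles")
    x = profiles.to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate training set: all profiles identical")
    scaler = StandardScaler().fit(x)
    if gamma == "median":
        gamma = _median_heuristic_gamma(scaler.transform(x))
    # guard constant features: zero-variance columns scale to 0 via scaler's
    # own epsilon handling, which is fine for the kernel.
    # tight solver tolerance keeps margin support vectors numerically at the
    # boundary instead of epsilon below it
    svm = OneClassSVM(kernel="rbf", nu=nu, gamma=gamma, tol=1e-9)
    svm.fit(scaler.transform(x))
    return NoveltyModel(scaler=scaler, svm=svm,
                        n_features=profiles.shape[1],
                        feature_names=tuple(map(str, profiles.columns)),
                        nu=nu, seed=seed)


def predict_similar(model: NoveltyModel, candidates: pd.DataFrame,
                    exclude: Iterable[str] = ()) -> set[str]:
    """Candidate ids scored inside (or numerically on) the boundary,
    minus the excluded ids (typically all TE/HTT transcripts)."""
    exclude = set(exclude)
    if candidates.empty:
        return set()
    values = model.decision_values(candidates)
    return {tid for tid, v in values.items()
            if v >= -model.boundary_eps and tid not in exclude}


def predict_similar_in_all(models: Mapping[str, NoveltyModel],
                           candidates: Mapping[str, pd.DataFrame],
                           exclude: Iterable[str] = ()) -> set[str]:
    """Intersection of per-project positive sets: a transcript must look
    HTT-like in every project to survive."""
    exclude = set(exclude)
    result: set[str] | None = None
    for project, model in models.items():
        positives = predict_similar(model, candidates[project], exclude)
        result = positives if result is None else result & positives
    return result or set()
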