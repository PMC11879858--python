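"""Ego-level features for random-forest mechanism classification.

Eight features, all evaluated at the ego's adoption time:

1. degree
2. proportion of infected neighbours
3. number of infected neighbours
4. sum of received stimuli
5. mean stimuli per neighbour
6. standard deviation of per-neighbour stimuli (population form, over all k
   neighbours including zero-stimulus ones)
7. time since the first infected neighbour
8. time since the last infected neighbour

Neighbours adopting at the same step as the ego are excluded — under a
synchronous update they could not have influenced the adoption.  For an
adoption with no previously infected neighbour (a spontaneous-looking
instance) features 2-8 are all zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import EgoObservation, count_stimuli

__all__ = [
    "FEATURE_NAMES",
    "extract_features",
    "features_frame",
    "top3_frequency",
    "ContagionFeatureExtractor",
]

FEATURE_NAMES = (
    "degree",
    "prop_infected_nb",
    "n_infected_nb",
    "stimuli_sum",
    "stimuli_mean",
    "stimuli_std",
    "time_since_first_nb",
    "time_since_last_nb",
)


def extract_features(obs: EgoObservation) -> np.ndarray:
    """The 8-feature vector of one adopted ego observation."""
    if not obs.adopted:
        raise ValueError("feature extraction requires an adopted ego")
    k = obs.degree
    t_a = obs.adoption_time
    stim = count_stimuli(obs).astype(np.float64)
    ts = obs.neighbor_adoption_times
    pre = ts[(ts >= 0) & (ts < t_a)]
    n_inf = len(pre)
    if n_inf == 0:
        return np.array([k, 0, 0, 0, 0, 0, 0, 0], dtype=np.float64)
    total = float(stim.sum())
    return np.array(
        [
            k,
            n_inf / k,
            n_inf,
            total,
            total / k,
            float(stim.std()),  # population (divide-by-n) form
            t_a - int(pre.min()),
            t_a - int(pre.max()),
        ],
        dtype=np.float64,
    )


def features_frame(observations: list[EgoObservation]) -> pd.DataFrame:
    """Feature table with true labels where available."""
    rows = [extract_features(o) for o in observations]
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    df["true_label"] = [o.true_label for o in observations]
    return df


def top3_frequency(importance_tables: list[np.ndarray]) -> np.ndarray:
    """Fraction of models in which each feature ranks among the top 3.

    ``importance_tables`` holds one importance vector per trained model
    (e.g. one per (beta, phi) pair); returns, per feature, the count of
    models where it is in the top 3 divided by the number of models.
    """
    tables = [np.asarray(t, dtype=np.float64) for t in importance_tables]
    if not tables:
        raise ValueError("need at least one importance table")
    n_feat = len(tables[0])
    if n_feat < 3:
        raise ValueError("top-3 frequency needs at least 3 features")
    counts = np.zeros(n_feat)
    for t in tables:
        if len(t) != n_feat:
            raise ValueError("importance tables have inconsistent lengths")
        top3 = np.argsort(t)[::-1][:3]
        counts[top3] += 1
    return counts / len(tables)


class ContagionFeatureExtractor(BaseEstimator, TransformerMixin):
    """Stateless transformer mapping ego observations to the 8-feature matrix.

    Composes with scikit-learn pipelines:
    ``make_pipeline(ContagionFeatureExtractor(), RandomForestClassifier())``.
    """

    def fit(self, X, y=None):
        self.feature_names_out_ = np.array(FEATURE_NAMES)
        return self

    def transform(self, X) -> np.ndarray:
        return np.vstack([extract_features(o) for o in X])

    def get_feature_names_out(self, input_features=None):
        return np.array(FEATURE_NAMES)
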