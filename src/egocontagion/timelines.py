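"""Adapter from timeline-style records to ego observations in event time.

A timeline is a user's ordered stream of posts, each carrying a global event
index and a hashtag-match flag.  For every ego with an identified first
hashtag post (its adoption), the adapter reconstructs the egocentric view:
the degree is the number of followees with at least one post in the window
preceding the adoption, the clock counts followee posts (event time), and
every followee hashtag post before the adoption is one stimulus.

The synthetic timeline generator turns an activity-driven simulation's post
log into Timeline records, so every adapter path is testable without any
external download; observations built from synthetic timelines reproduce the
simulator's own egocentric bookkeeping exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, extract_features
from .likelihood import estimate_params
from .simulate import EgoObservation
from .temporal import (
    DegreeGroupParams,
    ParamDistributions,
    TemporalResult,
    degree_group,
    filter_lowest,
    preclassify_instance,
)

__all__ = [
    "Timeline",
    "synthesize_timelines",
    "build_ego_observations",
    "preclassify_observation",
    "infer_param_distributions",
    "classify_and_stratify",
    "StratifiedClassification",
]


@dataclass
class Timeline:
    """One user's ordered post stream with hashtag flags."""

    user: int
    event_index: np.ndarray  # strictly increasing global indices
    hashtag: np.ndarray  # boolean flags

    def __post_init__(self) -> None:
        self.event_index = np.asarray(self.event_index, dtype=np.int64)
        self.hashtag = np.asarray(self.hashtag, dtype=bool)
        if len(self.event_index) != len(self.hashtag):
            raise ValueError("event_index and hashtag must have equal length")
        if len(self.event_index) > 1 and not np.all(np.diff(self.event_index) > 0):
            raise ValueError("posts must be strictly ordered")

    def first_hashtag_index(self) -> int | None:
        hits = self.event_index[self.hashtag]
        return int(hits[0]) if len(hits) else None


def synthesize_timelines(result: TemporalResult) -> dict[int, Timeline]:
    """Timeline records from an activity-driven run's post log."""
    if not result.post_log:
        raise ValueError("run_activity_driven must be called with keep_post_log=True")
    posts: dict[int, list[tuple[int, bool]]] = {}
    for t, node, flag in result.post_log:
        posts.setdefault(node, []).append((t, flag))
    out = {}
    for node, items in posts.items():
        idx, flags = zip(*items)
        out[node] = Timeline(user=node, event_index=np.array(idx), hashtag=np.array(flags))
    return out


def build_ego_observations(
    timelines: dict[int, Timeline],
    followees: dict[int, list[int]],
    window: int | None = None,
) -> tuple[list[EgoObservation], list[int], int]:
    """Event-time ego observations for every ego with an adoption post.

    ``window``, if given, restricts attention to the last ``window`` global
    event indices before the ego's adoption (the one-week lookback of
    calendar-time data).  Egos without an adoption or without any active
    followee in the window are dropped; the dropped count is returned.

    Returns ``(observations, ego_ids, n_dropped)``.
    """
    observations: list[EgoObservation] = []
    ego_ids: list[int] = []
    dropped = 0
    for ego, tl in timelines.items():
        t_adopt_global = tl.first_hashtag_index()
        if t_adopt_global is None:
            continue
        lo = -1 if window is None else t_adopt_global - window
        # gather followee posts in (lo, t_adopt_global)
        events = []  # (global index, followee slot, is_hashtag, is_first_hashtag)
        active = []
        for f in followees.get(ego, []):
            ftl = timelines.get(f)
            if ftl is None:
                continue
            mask = (ftl.event_index > lo) & (ftl.event_index < t_adopt_global)
            if not mask.any():
                continue
            slot = len(active)
            active.append(f)
            flags = ftl.hashtag[mask]
            idxs = ftl.event_index[mask]
            first_done = False
            for gi, fl in zip(idxs, flags):
                is_first = bool(fl) and not first_done
                if is_first:
                    first_done = True
                events.append((int(gi), slot, bool(fl), is_first))
        if not active:
            dropped += 1
            continue
        events.sort()
        k = len(active)
        stim_times: list[list[int]] = [[] for _ in range(k)]
        nb_first = np.full(k, -1, dtype=np.int64)
        for local_t, (gi, slot, fl, is_first) in enumerate(events, start=1):
            if fl:
                stim_times[slot].append(local_t)
                if is_first:
                    nb_first[slot] = local_t
        t_a_local = len(events)  # ego adopts right after the last followee post
        obs = EgoObservation(
            degree=k,
            adoption_time=t_a_local + 1,
            neighbor_adoption_times=nb_first,
            horizon=t_a_local + 1,
            stimulus_times=[np.array(s, dtype=np.int64) for s in stim_times],
        )
        observations.append(obs)
        ego_ids.append(ego)
    return observations, ego_ids, dropped


def preclassify_observation(obs: EgoObservation) -> str:
    """Apply the heuristic pre-classification rules to an event-time
    observation: St without infectious neighbours, Cx when the last
    pre-adoption influencing event is a neighbour's first hashtag post,
    Sm otherwise."""
    t_a = obs.adoption_time if obs.adopted else obs.horizon
    if obs.stimulus_times is None:
        raise ValueError("pre-classification needs event-time stimulus times")
    all_stims = [s[s < t_a] for s in map(np.asarray, obs.stimulus_times)]
    n_inf = sum(1 for s in all_stims if len(s) > 0)
    if n_inf == 0:
        return preclassify_instance(0, False)
    last_stim = max(int(s.max()) for s in all_stims if len(s) > 0)
    firsts = {int(s.min()) for s in all_stims if len(s) > 0}
    return preclassify_instance(n_inf, last_stim in firsts)


def infer_param_distributions(
    observations: list[EgoObservation],
    filter_frac: float = 0.8,
    min_group_size: int = 10,
    activity_sd: float = 0.1,
) -> ParamDistributions:
    """Empirical parameter distributions from pre-classified observations.

    beta_hat values (inverse stimulus counts) come from Sm-labelled
    instances, grouped by degree into logarithmic classes and fitted with a
    log-normal each (groups below ``min_group_size`` fall back to the global
    fit); phi_hat values (infected-neighbour proportions) come from
    Cx-labelled instances.  Both are cut at their lowest ``filter_frac``
    before fitting, and activities are proxied by the per-group mean post
    volume normalised to [0, 1].
    """
    beta_by_group: dict[int, list[float]] = {}
    phis: list[float] = []
    volume_by_group: dict[int, list[float]] = {}
    for obs in observations:
        lab = preclassify_observation(obs)
        est = estimate_params(obs)
        g = degree_group(obs.degree)
        volume_by_group.setdefault(g, []).append(float(obs.adoption_time or obs.horizon))
        if lab == "Sm" and not est.zero_stimulus:
            beta_by_group.setdefault(g, []).append(est.beta_hat)
        elif lab == "Cx":
            phis.append(est.phi_hat)
    if not beta_by_group or not phis:
        raise ValueError("need both Sm- and Cx-labelled instances to fit distributions")

    all_betas = filter_lowest(np.concatenate([np.array(v) for v in beta_by_group.values()]), filter_frac)
    glob_mu, glob_sigma = _lognorm_fit(all_betas)
    max_vol = max(float(np.mean(v)) for v in volume_by_group.values())
    groups: dict[int, DegreeGroupParams] = {}
    for g, vols in sorted(volume_by_group.items()):
        betas = np.array(beta_by_group.get(g, []))
        if len(betas) >= min_group_size:
            mu, sigma = _lognorm_fit(filter_lowest(betas, filter_frac))
        else:
            mu, sigma = glob_mu, glob_sigma
        groups[g] = DegreeGroupParams(
            activity_mean=float(np.mean(vols)) / max_vol if max_vol > 0 else 0.5,
            activity_sd=activity_sd,
            beta_log_mu=mu,
            beta_log_sigma=sigma,
        )
    return ParamDistributions(
        groups=groups, phi_samples=np.array(phis), filter_frac=filter_frac
    )


def _lognorm_fit(x: np.ndarray) -> tuple[float, float]:
    logs = np.log(np.asarray(x, dtype=np.float64))
    sigma = float(logs.std())
    return float(logs.mean()), max(sigma, 1e-6)


@dataclass
class StratifiedClassification:
    """Decile-stratified classification summary."""

    labels: np.ndarray
    counts: pd.Series
    beta_deciles: np.ndarray
    phi_deciles: np.ndarray
    dominant: np.ndarray  # (10, 10) object grid, phi deciles x beta deciles
    mean_certainty: np.ndarray  # (10, 10)
    cell_counts: np.ndarray = field(default=None)


def classify_and_stratify(model, observations: list[EgoObservation]) -> StratifiedClassification:
    """Classify observations and stratify the labels on the decile grid of
    their inferred (phi_hat, beta_hat) parameters.

    Each cell of the 10 x 10 grid reports the dominant predicted class and
    the mean classification certainty (fraction of trees voting for the
    assigned class) of the instances falling in it.
    """
    X = np.vstack([extract_features(o) for o in observations])
    labels = np.asarray(model.predict(X), dtype=object)
    cert = model.certainty(X)
    ests = [estimate_params(o) for o in observations]
    betas = np.array([e.beta_hat for e in ests])
    phis = np.array([e.phi_hat for e in ests])
    b_edges = np.quantile(betas, np.linspace(0, 1, 11))
    p_edges = np.quantile(phis, np.linspace(0, 1, 11))
    b_bin = np.clip(np.searchsorted(b_edges[1:-1], betas, side="right"), 0, 9)
    p_bin = np.clip(np.searchsorted(p_edges[1:-1], phis, side="right"), 0, 9)
    dominant = np.full((10, 10), "", dtype=object)
    mean_cert = np.full((10, 10), np.nan)
    cell_counts = np.zeros((10, 10), dtype=np.int64)
    for pi in range(10):
        for bi in range(10):
            mask = (p_bin == pi) & (b_bin == bi)
            cell_counts[pi, bi] = int(mask.sum())
            if mask.any():
                vals, cnts = np.unique(labels[mask].astype(str), return_counts=True)
                dominant[pi, bi] = vals[np.argmax(cnts)]
                mean_cert[pi, bi] = float(cert[mask].mean())
    return StratifiedClassification(
        labels=labels,
        counts=pd.Series(labels.astype(str)).value_counts(),
        beta_deciles=b_edges,
        phi_deciles=p_edges,
        dominant=dominant,
        mean_certainty=mean_cert,
        cell_counts=cell_counts,
    )
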