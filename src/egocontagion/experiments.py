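"""End-to-end experiment drivers over the (beta, phi) phase space.

Four experimental settings of increasing realism:

1. isolated ego stars with spontaneously adopting leaves, two-hypothesis
   likelihood classification with known parameters, plus the closed-form
   accuracy surface;
2. whole-network contagion on random graphs with coexisting mechanisms and a
   spontaneous channel, three-class likelihood and per-cell random forests
   with known parameters;
3. the same instances classified with estimated parameters (likelihood) or a
   single pooled random forest;
4. the activity-driven asynchronous model with data-driven (or synthetic
   stand-in) parameter distributions and a pooled random forest.

Bulk classification goes through the closed-form summary route
(:func:`egocontagion.likelihood.summary_logliks`), which the test-suite
cross-checks step-by-step against the generic trajectory likelihood.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import likelihood as llh
from .features import FEATURE_NAMES, top3_frequency
from .forest import RFProtocol, RandomForestMechanismClassifier, evaluate
from .networks import DegreeSampler, Network, make_random_network, reduce_by_neighbor_walk
from .simulate import (
    CX,
    SM,
    NodeConfig,
    SimConfig,
    Trajectory,
    run_static_contagion,
    simulate_ego_star_batch,
)
from .temporal import ParamDistributions, run_activity_driven, sample_node_parameters

__all__ = [
    "DEFAULT_GRID",
    "ExperimentConfig",
    "ego_star_cell",
    "run_experiment1",
    "analytic_surface",
    "compare_theory_vs_simulation",
    "trajectory_instances",
    "run_experiment2_cell",
    "likelihood_accuracy",
    "balanced_split",
    "rf_cell_accuracy",
    "run_experiment2_grid",
    "run_experiment4",
    "run_experiment",
]

DEFAULT_GRID = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass
class ExperimentConfig:
    """Single configuration object for the experiment drivers."""

    experiment: int
    beta_grid: tuple = DEFAULT_GRID
    phi_grid: tuple = DEFAULT_GRID
    r: float = 0.005
    r_nb: float = 0.05
    network: dict = field(default_factory=lambda: {"model": "er", "n": 1000, "mean_degree": 4.0})
    realisations: int = 5
    n_egos_per_cell: int = 1000
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2, 3, 4):
            raise ValueError("experiment must be 1-4")
        if self.realisations < 1:
            raise ValueError("realisations must be >= 1")
        for g in (self.beta_grid, self.phi_grid):
            if not all(0.0 <= v <= 1.0 for v in g):
                raise ValueError("grid values must lie in [0, 1]")

    def manifest(self) -> dict:
        d = asdict(self)
        blob = json.dumps(d, sort_keys=True).encode()
        return {"config": d, "config_hash": hashlib.sha256(blob).hexdigest()[:16]}


# ---------------------------------------------------------------------------
# Experiment 1: ego stars
# ---------------------------------------------------------------------------

def _star_summaries(t_a: np.ndarray, leaf_times: np.ndarray):
    """Trajectory summaries (s_total, s_last, s_prev) from leaf infection
    times, for adopted egos."""
    t_a = t_a[:, None].astype(np.int64)
    valid = leaf_times >= 0
    s_last = (valid & (leaf_times <= t_a - 1)).sum(axis=1)
    s_prev = (valid & (leaf_times <= t_a - 2)).sum(axis=1)
    s_total = np.where(valid, np.maximum(0, t_a - leaf_times), 0).sum(axis=1)
    return s_total, s_last, s_prev


def ego_star_cell(
    beta: float,
    phi: float,
    n_egos: int,
    sampler: DegreeSampler,
    r_nb: float,
    rng: np.random.Generator,
) -> dict:
    """Simulate one grid cell of the ego-star experiment and classify.

    Half the egos follow simple contagion with ``beta``, half the Watts
    threshold with ``phi``; leaves adopt spontaneously at rate ``r_nb``.
    Returns the cell accuracy and the per-class correct fractions.
    """
    n_sm = n_egos // 2
    n_cx = n_egos - n_sm
    out = {}
    correct = {}
    for mech, param, n_m in ((SM, beta, n_sm), (CX, phi, n_cx)):
        degrees = sampler.sample(n_m, rng)
        t_a, leaf_times = simulate_ego_star_batch(degrees, mech, param, r_nb, rng)
        adopted = t_a >= 0
        degrees, t_a, leaf_times = degrees[adopted], t_a[adopted], leaf_times[adopted]
        s_total, s_last, s_prev = _star_summaries(t_a, leaf_times)
        m_star = np.floor(degrees * phi).astype(np.int64) + 1
        lls = llh.summary_logliks(
            degrees, t_a, s_total, s_last, s_prev,
            beta=beta, m_star=m_star, r=0.0, mode="ego_star",
        )
        pred = llh.classify_summaries(lls, mode="ego_star")
        correct[mech] = float((pred == mech).mean()) if len(pred) else float("nan")
        out[f"n_{mech}"] = int(adopted.sum())
    out["p_correct_sm"] = correct[SM]
    out["p_correct_cx"] = correct[CX]
    out["accuracy"] = 0.5 * (correct[SM] + correct[CX])
    return out


def run_experiment1(
    n_egos_per_cell: int,
    rng: np.random.Generator,
    beta_grid=DEFAULT_GRID,
    phi_grid=DEFAULT_GRID,
    r_nb: float = 0.05,
    sampler: DegreeSampler | None = None,
) -> pd.DataFrame:
    """Likelihood accuracy surface over the (beta, phi) grid (ego stars)."""
    sampler = sampler or DegreeSampler()
    rows = []
    for beta in beta_grid:
        for phi in phi_grid:
            cell = ego_star_cell(beta, phi, n_egos_per_cell, sampler, r_nb, rng)
            rows.append({"beta": beta, "phi": phi, **cell})
    return pd.DataFrame(rows)


def analytic_surface(
    beta_grid=DEFAULT_GRID,
    phi_grid=DEFAULT_GRID,
    r_nb: float = 0.05,
    sampler: DegreeSampler | None = None,
) -> pd.DataFrame:
    """Closed-form accuracy surface, averaged over the degree distribution."""
    sampler = sampler or DegreeSampler()
    rows = [
        {
            "beta": beta,
            "phi": phi,
            "accuracy": llh.expected_accuracy_over_degrees(sampler, beta, phi, r_nb),
        }
        for beta in beta_grid
        for phi in phi_grid
    ]
    return pd.DataFrame(rows)


def compare_theory_vs_simulation(
    sim: pd.DataFrame, theory: pd.DataFrame
) -> tuple[float, pd.DataFrame]:
    """Elementwise |simulated - analytic| accuracy and its maximum."""
    merged = sim.merge(theory, on=["beta", "phi"], suffixes=("_sim", "_theory"))
    if len(merged) != len(sim) or len(merged) != len(theory):
        raise ValueError("accuracy surfaces are on different (beta, phi) grids")
    merged["abs_diff"] = (merged["accuracy_sim"] - merged["accuracy_theory"]).abs()
    return float(merged["abs_diff"].max()), merged


# ---------------------------------------------------------------------------
# Experiments 2 and 3: whole-network contagion
# ---------------------------------------------------------------------------

def trajectory_instances(traj: Trajectory) -> pd.DataFrame:
    """Per-adopter trajectory summaries and features from a network run.

    One row per infected non-seed node: the summary statistics feeding the
    closed-form likelihoods (t_a, s_total, s_last, s_prev) and the ego
    features, plus the node's true label.  Also carries the population
    r_hat estimate of the run.
    """
    adj = traj.net.adjacency_lists()
    t_all = traj.adoption_time
    rows = []
    r_fracs = []
    for i in range(traj.net.n_nodes):
        t_a = int(t_all[i])
        if t_a <= 0:  # seed (0) and never (-1) excluded
            continue
        nb_t = t_all[adj[i]]
        k = len(nb_t)
        pre = nb_t[(nb_t >= 0) & (nb_t < t_a)]
        stim = np.where((nb_t >= 0) & (nb_t < t_a), t_a - nb_t, 0).astype(np.float64)
        s_last = len(pre)
        s_prev = int(((nb_t >= 0) & (nb_t <= t_a - 2)).sum())
        t_first = int(pre.min()) if s_last else 0
        t_last = int(pre.max()) if s_last else 0
        r_fracs.append((t_a - t_first) / t_a if s_last else 0.0)
        rows.append(
            {
                "node": i,
                "degree": k,
                "t_a": t_a,
                "s_total": float(stim.sum()),
                "s_last": s_last,
                "s_prev": s_prev,
                "stimuli_std": float(stim.std()),
                "tsf": t_a - t_first if s_last else 0,
                "tsl": t_a - t_last if s_last else 0,
                "label": str(traj.label[i]),
            }
        )
    df = pd.DataFrame(rows)
    df["r_hat"] = float(np.mean(r_fracs)) if r_fracs else 0.0
    return df


def instances_features(df: pd.DataFrame) -> np.ndarray:
    """The 8-feature matrix from an instance summary table."""
    k = df["degree"].to_numpy(dtype=np.float64)
    n_inf = df["s_last"].to_numpy(dtype=np.float64)
    total = df["s_total"].to_numpy(dtype=np.float64)
    X = np.column_stack(
        [
            k,
            n_inf / k,
            n_inf,
            total,
            total / k,
            df["stimuli_std"].to_numpy(dtype=np.float64),
            df["tsf"].to_numpy(dtype=np.float64),
            df["tsl"].to_numpy(dtype=np.float64),
        ]
    )
    return X


def run_experiment2_cell(
    beta: float,
    phi: float,
    n_realisations: int,
    rng: np.random.Generator,
    network: dict | None = None,
    r: float = 0.005,
    horizon: int = 50_000,
    stop_frac: float = 1.0,
) -> pd.DataFrame:
    """Pooled instance table for one (beta, phi) cell.

    Each realisation draws a fresh giant component, assigns every node Sm
    (with ``beta``) or Cx (with ``phi``) with equal probability, seeds one
    random node and runs to ``stop_frac`` infection with spontaneous rate
    ``r``.
    """
    network = dict(network or {"model": "er", "n": 1000, "mean_degree": 4.0})
    model = network.pop("model", "er")
    frames = []
    for real in range(n_realisations):
        net = make_random_network(model, network, rng)
        mechs = rng.random(net.n_nodes) < 0.5
        configs = [
            NodeConfig(SM, beta=beta) if m else NodeConfig(CX, phi=phi) for m in mechs
        ]
        sim = SimConfig(r=r, horizon=horizon, stop_frac=stop_frac)
        traj = run_static_contagion(net, configs, sim, rng)
        inst = trajectory_instances(traj)
        inst["realisation"] = real
        frames.append(inst)
    df = pd.concat(frames, ignore_index=True)
    df["beta"] = beta
    df["phi"] = phi
    return df


def likelihood_accuracy(
    df: pd.DataFrame,
    beta: float | None = None,
    phi: float | None = None,
    r: float | None = None,
    estimated: bool = False,
) -> tuple[float, pd.DataFrame]:
    """Three-class likelihood classification accuracy on an instance table.

    Known-parameter mode uses the cell's (beta, phi, r) for every instance;
    estimated mode replaces them by the per-instance inverse stimulus count,
    the adoption-time infected-neighbour proportion (non-strict threshold)
    and the run-level population r_hat.
    """
    k = df["degree"].to_numpy(dtype=np.int64)
    if estimated:
        s_total = df["s_total"].to_numpy()
        beta_arr = np.where(s_total > 0, 1.0 / np.maximum(s_total, 1.0), 1.0)
        m_star = np.maximum(df["s_last"].to_numpy(dtype=np.int64), 1)
        r_use = float(df["r_hat"].mean())
    else:
        if beta is None or phi is None or r is None:
            raise ValueError("known-parameter mode requires beta, phi and r")
        beta_arr = beta
        m_star = np.floor(k * phi).astype(np.int64) + 1
        r_use = r
    lls = llh.summary_logliks(
        k,
        df["t_a"].to_numpy(),
        df["s_total"].to_numpy(),
        df["s_last"].to_numpy(),
        df["s_prev"].to_numpy(),
        beta=beta_arr,
        m_star=m_star,
        r=r_use,
        mode="network",
    )
    pred = llh.classify_summaries(lls, mode="network")
    out = df.copy()
    out["predicted"] = pred
    acc = float((out["predicted"] == out["label"]).mean())
    return acc, out


def balanced_split(
    y: np.ndarray,
    train_per_class: int,
    test_per_class: int,
    rng: np.random.Generator,
    classes=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint class-balanced train/test index sets.

    When a class has fewer instances than ``train+test`` the counts are
    scaled down proportionally (keeping the train:test ratio and balance).
    """
    y = np.asarray(y)
    classes = np.unique(y) if classes is None else classes
    avail = min(int((y == c).sum()) for c in classes)
    need = train_per_class + test_per_class
    if avail < need:
        frac = avail / need
        train_n = max(int(train_per_class * frac), 1)
        test_n = max(avail - train_n, 1)
        train_n = avail - test_n
    else:
        train_n, test_n = train_per_class, test_per_class
    tr, te = [], []
    for c in classes:
        rows = np.nonzero(y == c)[0]
        pick = rng.permutation(rows)[: train_n + test_n]
        tr.append(pick[:train_n])
        te.append(pick[train_n:])
    return np.concatenate(tr), np.concatenate(te)


def rf_cell_accuracy(
    df: pd.DataFrame,
    protocol: RFProtocol,
    rng: np.random.Generator,
    n_realisations: int = 1,
) -> dict:
    """Protocol random forest on one cell's instance table.

    Repeats the balanced sample / train / test cycle ``n_realisations``
    times and averages; also returns the last confusion matrix and the mean
    feature importances.
    """
    X = instances_features(df)
    y = df["label"].to_numpy(dtype=object)
    accs, cms, imps = [], [], []
    for _ in range(n_realisations):
        tr, te = balanced_split(
            y, protocol.train_per_class, protocol.test_per_class, rng
        )
        clf = RandomForestMechanismClassifier(
            protocol=protocol, random_state=int(rng.integers(2**31 - 1))
        )
        clf.fit(X[tr], y[tr])
        acc, cm = evaluate(clf, X[te], y[te])
        accs.append(acc)
        cms.append(cm)
        imps.append(clf.feature_importances_)
    return {
        "accuracy": float(np.mean(accs)),
        "confusion": cms[-1],
        "importances": np.mean(imps, axis=0),
        "n_train_per_class": int(len(tr) // len(np.unique(y))),
    }


def run_experiment2_grid(
    n_realisations: int,
    rng: np.random.Generator,
    beta_grid=DEFAULT_GRID,
    phi_grid=DEFAULT_GRID,
    r: float = 0.005,
    network: dict | None = None,
    rf_protocol: RFProtocol | None = None,
    rf_realisations: int = 1,
    with_rf: bool = True,
    with_estimated: bool = True,
) -> dict:
    """Full phase-space sweep for Experiments 2 and 3.

    For each grid cell: simulate, classify with known parameters
    (Experiment 2 likelihood), with estimated parameters (Experiment 3
    likelihood), and train/evaluate the per-cell random forest.  Returns the
    per-cell table, the grid means, and the per-cell feature importances.
    """
    rows = []
    importances = []
    for beta in beta_grid:
        for phi in phi_grid:
            df = run_experiment2_cell(
                beta, phi, n_realisations, rng, network=dict(network or {}), r=r
            )
            row = {"beta": beta, "phi": phi, "n_instances": len(df)}
            row["acc_llh_known"], _ = likelihood_accuracy(df, beta, phi, r)
            if with_estimated:
                row["acc_llh_estimated"], _ = likelihood_accuracy(df, estimated=True)
            if with_rf:
                rf = rf_cell_accuracy(
                    df, rf_protocol or RFProtocol(), rng, rf_realisations
                )
                row["acc_rf"] = rf["accuracy"]
                row["rf_train_per_class"] = rf["n_train_per_class"]
                importances.append(rf["importances"])
            rows.append(row)
    cells = pd.DataFrame(rows)
    out = {"cells": cells, "mean_llh_known": float(cells["acc_llh_known"].mean())}
    if with_estimated:
        out["mean_llh_estimated"] = float(cells["acc_llh_estimated"].mean())
    if with_rf:
        out["mean_rf"] = float(cells["acc_rf"].mean())
        out["top3_frequency"] = pd.Series(
            top3_frequency(importances), index=list(FEATURE_NAMES)
        )
    return out


# ---------------------------------------------------------------------------
# Experiment 4: activity-driven temporal model
# ---------------------------------------------------------------------------

def run_experiment4(
    rng: np.random.Generator,
    n_big: int = 5000,
    big_mean_degree: float = 8.0,
    target_size: int = 1500,
    dists: ParamDistributions | None = None,
    r: float = 0.005,
    stop_frac: float = 0.9,
    n_runs: int = 2,
    rf_protocol: RFProtocol | None = None,
    keep_post_log: bool = False,
):
    """Activity-driven experiment: reduce a large graph by the neighbour
    walk, sample data-driven node parameters, simulate to ``stop_frac``
    infection and train a pooled random forest on the observed adoptions.

    Returns ``(result dict, records, model)``.
    """
    dists = dists or ParamDistributions.synthetic_standin(rng=rng)
    big = make_random_network("er", {"n": n_big, "mean_degree": big_mean_degree}, rng)
    net = reduce_by_neighbor_walk(big, min(target_size, big.n_nodes), rng)
    degrees = net.degrees
    records = []
    results = []
    for _ in range(n_runs):
        nodes = [
            sample_node_parameters(
                int(degrees[i]), dists, SM if rng.random() < 0.5 else CX, rng
            )
            for i in range(net.n_nodes)
        ]
        res = run_activity_driven(
            net, nodes, r=r, stop_frac=stop_frac, rng=rng, keep_post_log=keep_post_log
        )
        records.extend(res.records)
        results.append(res)
    X = np.vstack([rec.features for rec in records])
    y = np.array([rec.true_label for rec in records], dtype=object)
    proto = rf_protocol or RFProtocol(train_per_class=6000, test_per_class=2000)
    tr, te = balanced_split(y, proto.train_per_class, proto.test_per_class, rng)
    clf = RandomForestMechanismClassifier(
        protocol=proto, random_state=int(rng.integers(2**31 - 1))
    )
    clf.fit(X[tr], y[tr])
    acc, cm = evaluate(clf, X[te], y[te])
    waiting = np.array([rec.waiting_time for rec in records], dtype=np.float64)
    out = {
        "accuracy": acc,
        "confusion": cm,
        "waiting_times": waiting,
        "test_idx": te,
        "X": X,
        "y": y,
        "results": results,
    }
    return out, records, clf


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

def run_experiment(config: ExperimentConfig) -> dict:
    """Run one experiment end-to-end from a config; optionally persist
    result tables and a reproducibility manifest to ``config.out_dir``."""
    rng = np.random.default_rng(config.seed)
    if config.experiment == 1:
        surface = run_experiment1(
            config.n_egos_per_cell,
            rng,
            beta_grid=config.beta_grid,
            phi_grid=config.phi_grid,
            r_nb=config.r_nb,
        )
        theory = analytic_surface(
            beta_grid=config.beta_grid, phi_grid=config.phi_grid, r_nb=config.r_nb
        )
        max_diff, merged = compare_theory_vs_simulation(
            surface[["beta", "phi", "accuracy"]], theory
        )
        result = {
            "surface": surface,
            "theory": theory,
            "mean_accuracy": float(surface["accuracy"].mean()),
            "max_theory_sim_diff": max_diff,
        }
    elif config.experiment in (2, 3):
        result = run_experiment2_grid(
            config.realisations,
            rng,
            beta_grid=config.beta_grid,
            phi_grid=config.phi_grid,
            r=config.r,
            network=config.network,
        )
    else:
        out, records, model = run_experiment4(rng, r=config.r)
        result = {"accuracy": out["accuracy"], "confusion": out["confusion"]}
    if config.out_dir:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(config.manifest(), fh, indent=2)
        for key, val in result.items():
            if isinstance(val, pd.DataFrame):
                val.to_csv(out_dir / f"{key}.csv", index=False)
            elif isinstance(val, (int, float)):
                with open(out_dir / f"{key}.json", "w") as fh:
                    json.dump({key: val}, fh)
    return result
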