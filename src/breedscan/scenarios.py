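"""Environmental scenario typing.

Experiments are clustered into temperature classes by PCA (retaining >= 90%
of the covariate variance) followed by partitioning around medoids (PAM,
BUILD + SWAP, Euclidean), then crossed with a soil-water classification at
the -0.1 MPa threshold (well-watered strictly above, water deficit at or
below).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .containers import EnvRecord, ScenarioLabel, TEMPERATURE_CLASSES

WATER_THRESHOLD_MPA = -0.1


def classify_water(psi: float) -> str:
    """WW iff mean soil water potential is strictly above -0.1 MPa, else WD."""
    return "WW" if psi > WATER_THRESHOLD_MPA else "WD"


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        current = D[:, medoids].min(axis=1)
        best_gain, best_j = -np.inf, None
        for j in range(n):
            if j in medoids:
                continue
            gain = np.maximum(current - D[:, j], 0.0).sum()
            if gain > best_gain + 1e-12:
                best_gain, best_j = gain, j
        medoids.append(int(best_j))
    return medoids


def _pam_cost(D: np.ndarray, medoids: Sequence[int]) -> float:
    return float(D[:, list(medoids)].min(axis=1).sum())


def _pam_swap(D: np.ndarray, medoids: list[int], max_iter: int = 1000) -> list[int]:
    n = D.shape[0]
    cost = _pam_cost(D, medoids)
    for _ in range(max_iter):
        best = None
        for mi, m in enumerate(sorted(medoids)):
            mi = medoids.index(m)
            for h in range(n):
                if h in medoids:
                    continue
                trial = list(medoids)
                trial[mi] = h
                c = _pam_cost(D, trial)
                if c < cost - 1e-12 and (best is None or c < best[0] - 1e-12):
                    best = (c, mi, h)
        if best is None:
            break
        cost, mi, h = best
        medoids[mi] = h
    return medoids


@dataclass
class ScenarioModel:
    """Fitted scenario classifier: standardization + PCA basis + PAM medoids."""

    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray  # (n_pc, n_covariates)
    medoid_coords: np.ndarray  # (k, n_pc)
    medoid_temp_labels: list[str]
    training_range: np.ndarray  # (2, n_covariates) min/max of raw covariates

    def project(self, x: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(x) - self.mean) / self.scale @ self.components.T

    def to_json(self, path) -> None:
        obj = {
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "components": self.components.tolist(),
            "medoid_coords": self.medoid_coords.tolist(),
            "medoid_temp_labels": self.medoid_temp_labels,
            "training_range": self.training_range.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ScenarioModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            mean=np.array(obj["mean"]),
            scale=np.array(obj["scale"]),
            components=np.array(obj["components"]),
            medoid_coords=np.array(obj["medoid_coords"]),
            medoid_temp_labels=list(obj["medoid_temp_labels"]),
            training_range=np.array(obj["training_range"]),
        )


def cluster_temperature(
    envs: Sequence[EnvRecord], k: int = 3, seed: int | None = None, min_var: float = 0.90
) -> tuple[list[str], ScenarioModel]:
    """Cluster experiments into k temperature classes.

    Covariates (phase-wise light, Tmin, Tmax) are standardized, projected on
    the principal components retaining >= min_var of the variance, and
    clustered by PAM. For k = 3 classes are renamed cool/warm/hot by
    ascending mean Tmax over phases. Deterministic: PAM BUILD is greedy and
    ties break toward the lowest experiment index (seed kept for interface
    symmetry).
    """
    n = len(envs)
    if k > n:
        raise ValueError(f"k = {k} exceeds the number of experiments ({n})")
    X = np.stack([e.covariates() for e in envs])
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale
    U, S, Vt = np.linalg.svd(Z - Z.mean(axis=0), full_matrices=False)
    var = S**2
    total = var.sum()
    if total == 0:
        n_pc = 1
    else:
        n_pc = int(np.searchsorted(np.cumsum(var) / total, min_var) + 1)
    comps = Vt[:n_pc]
    # deterministic sign
    for j in range(n_pc):
        i = np.argmax(np.abs(comps[j]))
        if comps[j, i] < 0:
            comps[j] *= -1
    P = Z @ comps.T
    D = np.linalg.norm(P[:, None, :] - P[None, :, :], axis=2)
    medoids = _pam_swap(D, _pam_build(D, k))
    assign = np.argmin(D[:, medoids], axis=1)
    # name clusters by ascending mean Tmax
    cluster_tmax = [
        np.mean([envs[i].mean_tmax() for i in np.flatnonzero(assign == c)]) for c in range(k)
    ]
    order = np.argsort(cluster_tmax, kind="stable")
    if k == 3:
        names = list(TEMPERATURE_CLASSES)
    else:
        names = [f"t{i + 1}" for i in range(k)]
    cluster_name = {int(order[i]): names[i] for i in range(k)}
    labels = [cluster_name[int(c)] for c in assign]
    model = ScenarioModel(
        mean=mean,
        scale=scale,
        components=comps,
        medoid_coords=P[medoids],
        medoid_temp_labels=[cluster_name[i] for i in range(k)],
        training_range=np.stack([X.min(axis=0), X.max(axis=0)]),
    )
    return labels, model


def assign_scenario(env: EnvRecord, model: ScenarioModel) -> ScenarioLabel:
    """Scenario of a new experiment: nearest PAM medoid in the stored PCA
    space for the temperature class, -0.1 MPa thresholding for water."""
    x = env.covariates()
    lo, hi = model.training_range
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    if np.any(x < lo - 10 * span) or np.any(x > hi + 10 * span):
        warnings.warn(
            f"experiment {env.experiment}: covariates far outside the training range",
            stacklevel=2,
        )
    p = model.project(x)[0]
    d = np.linalg.norm(model.medoid_coords - p, axis=1)
    temp = model.medoid_temp_labels[int(np.argmin(d))]
    return ScenarioLabel(temp, classify_water(env.psi))


def label_experiments(envs: Sequence[EnvRecord], k: int = 3, seed: int | None = None):
    """Cluster + water-classify a training set; returns (labels, model)."""
    temp_labels, model = cluster_temperature(envs, k=k, seed=seed)
    labels = [ScenarioLabel(t, classify_water(e.psi)) for t, e in zip(temp_labels, envs)]
    return labels, model
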