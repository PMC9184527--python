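"""Constrained Gaussian Bayesian-network structure learning.

Scoring uses the Bayesian Gaussian equivalent (BGe) marginal likelihood with
a minimally informative normal-Wishart prior (zero prior mean, identity
prior scale, imaginary sample sizes alpha_mu = 1 for the mean and
alpha_w = n_vars + 2 for the Wishart). The score decomposes over node
families and is identical across Markov-equivalent DAGs. Structure search is
a deterministic TABU hill climb over add/delete/reverse moves; arc strengths
come from nonparametric bootstrap model averaging.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln


# ------------------------------------------------------------------- DAGs


@dataclass
class DAGModel:
    """A directed acyclic graph over named nodes with per-family BGe scores."""

    nodes: tuple[str, ...]
    parents: dict[str, frozenset[str]]
    family_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for v in self.nodes:
            self.parents.setdefault(v, frozenset())
        if self._has_cycle():
            raise ValueError("graph contains a cycle")

    def _has_cycle(self) -> bool:
        state: dict[str, int] = {}

        def visit(v: str) -> bool:
            state[v] = 1
            for u in self.parents[v]:
                st = state.get(u, 0)
                if st == 1 or (st == 0 and visit(u)):
                    return True
            state[v] = 2
            return False

        return any(state.get(v, 0) == 0 and visit(v) for v in self.nodes)

    @property
    def arcs(self) -> set[tuple[str, str]]:
        return {(u, v) for v in self.nodes for u in self.parents[v]}

    @property
    def score(self) -> float:
        return float(sum(self.family_scores.values()))

    def copy(self) -> "DAGModel":
        return DAGModel(self.nodes, dict(self.parents), dict(self.family_scores))

    def key(self) -> frozenset:
        return frozenset((v, self.parents[v]) for v in self.nodes)

    def cpdag_key(self):
        """Skeleton + v-structures; identical for Markov-equivalent DAGs."""
        skel = frozenset(frozenset(a) for a in self.arcs)
        vstruct = set()
        for v in self.nodes:
            for a, b in combinations(sorted(self.parents[v]), 2):
                if (
                    b not in self.parents[a]
                    and a not in self.parents[b]
                ):
                    vstruct.add((a, b, v))
        return (skel, frozenset(vstruct))


# --------------------------------------------------------------- BGe score


class BGeScorer:
    """BGe log marginal likelihood, decomposed per node family and cached.

    Data columns are centered and scaled once at construction (unit-variance
    columns are what the score expects; constant columns raise).
    """

    def __init__(self, data: pd.DataFrame, iss: float | None = None, alpha_mu: float = 1.0):
        X = data.to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValueError("BGe requires complete data")
        self.columns = tuple(str(c) for c in data.columns)
        sd = X.std(axis=0, ddof=1)
        bad = [c for c, s in zip(self.columns, sd) if s == 0]
        if bad:
            raise ValueError(f"singular family covariance for node(s) {bad}")
        X = (X - X.mean(axis=0)) / sd
        self.n, self.d = X.shape
        self.aw = float(iss) if iss is not None else self.d + 2.0
        if self.aw <= self.d:
            raise ValueError("imaginary sample size must exceed the number of variables")
        self.am = float(alpha_mu)
        self.t = self.am * (self.aw - self.d - 1.0) / (self.am + 1.0)
        xbar = X.mean(axis=0)  # zero after centering; kept for generality
        S = (X - xbar).T @ (X - xbar)
        self.R = self.t * np.eye(self.d) + S + (self.n * self.am / (self.n + self.am)) * np.outer(
            xbar, xbar
        )
        self._col_index = {c: i for i, c in enumerate(self.columns)}
        self._cache: dict[tuple[str, frozenset[str]], float] = {}

    def _logdet(self, cols: tuple[int, ...]) -> float:
        if not cols:
            return 0.0
        sub = self.R[np.ix_(cols, cols)]
        sign, ld = np.linalg.slogdet(sub)
        if sign <= 0:
            raise ValueError("singular family covariance submatrix")
        return float(ld)

    def family_score(self, node: str, parents: frozenset[str]) -> float:
        key = (node, parents)
        if key in self._cache:
            return self._cache[key]
        p = len(parents)
        pa = tuple(sorted(self._col_index[u] for u in parents))
        fam = tuple(sorted(pa + (self._col_index[node],)))
        n, aw, d, t = self.n, self.aw, self.d, self.t
        score = (
            0.5 * np.log(self.am / (n + self.am))
            - 0.5 * n * np.log(np.pi)
            + gammaln((n + aw - d + p + 1) / 2.0)
            - gammaln((aw - d + p + 1) / 2.0)
            + ((aw - d + 2 * p + 1) / 2.0) * np.log(t)
            + ((n + aw - d + p) / 2.0) * self._logdet(pa)
            - ((n + aw - d + p + 1) / 2.0) * self._logdet(fam)
        )
        self._cache[key] = float(score)
        return self._cache[key]

    def score(self, dag: DAGModel) -> float:
        total = 0.0
        for v in dag.nodes:
            s = self.family_score(v, dag.parents[v])
            dag.family_scores[v] = s
            total += s
        return total


def bge_score(dag: DAGModel, data: pd.DataFrame, iss: float | None = None) -> float:
    """Convenience wrapper: total BGe score of `dag` given `data`."""
    return BGeScorer(data, iss=iss).score(dag)


# ------------------------------------------------------------- TABU search


def _normalize_constraints(arcs) -> set[tuple[str, str]]:
    return {(str(a), str(b)) for a, b in (arcs or ())}


def learn_structure(
    data: pd.DataFrame,
    blacklist=(),
    whitelist=(),
    tabu_length: int = 10,
    max_iter: int = 10_000,
    seed: int | None = None,
    scorer: BGeScorer | None = None,
) -> DAGModel:
    """TABU structure search maximizing the BGe score.

    Moves are arc addition, deletion and reversal; the search keeps a tabu
    list of recently visited structures and, when no improving move exists,
    takes the best non-tabu move to escape local optima, returning the best
    structure seen. Deterministic under a fixed column order (ties break on
    lexicographic move order); `seed` is accepted for interface symmetry.
    """
    blacklist = _normalize_constraints(blacklist)
    whitelist = _normalize_constraints(whitelist)
    if blacklist & whitelist:
        raise ValueError(f"contradictory constraints: {sorted(blacklist & whitelist)}")
    if scorer is None:
        scorer = BGeScorer(data)
    nodes = tuple(str(c) for c in data.columns)
    parents: dict[str, frozenset[str]] = {v: frozenset() for v in nodes}
    for a, b in sorted(whitelist):
        parents[b] = parents[b] | {a}
    dag = DAGModel(nodes, parents)
    scorer.score(dag)
    best = dag.copy()
    tabu: deque = deque(maxlen=tabu_length)
    tabu.append(dag.key())
    stagnation = 0
    for _ in range(max_iter):
        best_move = None  # (delta, new_parents_changes)
        current_score = dag.score
        for u in nodes:
            for v in nodes:
                if u == v:
                    continue
                has_uv = u in dag.parents[v]
                candidates = []
                if not has_uv and (u, v) not in blacklist:
                    candidates.append(("add", u, v))
                if has_uv and (u, v) not in whitelist:
                    candidates.append(("del", u, v))
                if (
                    has_uv
                    and (u, v) not in whitelist
                    and (v, u) not in blacklist
                    and v not in dag.parents[u]
                ):
                    candidates.append(("rev", u, v))
                for kind, a, b in candidates:
                    changes = _apply_move(dag, kind, a, b)
                    if changes is None:
                        continue
                    delta = 0.0
                    for node, newpar in changes.items():
                        delta += scorer.family_score(node, newpar) - dag.family_scores[node]
                    new_key = frozenset(
                        (w, changes.get(w, dag.parents[w])) for w in nodes
                    )
                    if new_key in tabu:
                        continue
                    if best_move is None or delta > best_move[0] + 1e-12:
                        best_move = (delta, changes)
        if best_move is None:
            break
        delta, changes = best_move
        for node, newpar in changes.items():
            dag.parents[node] = newpar
            dag.family_scores[node] = scorer.family_score(node, newpar)
        tabu.append(dag.key())
        if dag.score > best.score + 1e-12:
            best = dag.copy()
            stagnation = 0
        else:
            stagnation += 1
            if stagnation > tabu_length:
                break
    return best


def _apply_move(dag: DAGModel, kind: str, u: str, v: str):
    """Parent-set changes for a move, or None if it would create a cycle."""
    if kind == "add":
        changes = {v: dag.parents[v] | {u}}
    elif kind == "del":
        return {v: dag.parents[v] - {u}}
    else:  # reverse u->v to v->u
        changes = {v: dag.parents[v] - {u}, u: dag.parents[u] | {v}}
    trial = {w: changes.get(w, dag.parents[w]) for w in dag.nodes}
    if _cyclic(dag.nodes, trial):
        return None
    return changes


def _cyclic(nodes, parents) -> bool:
    state: dict[str, int] = {}

    def visit(v):
        state[v] = 1
        for u in parents[v]:
            st = state.get(u, 0)
            if st == 1 or (st == 0 and visit(u)):
                return True
        state[v] = 2
        return False

    return any(state.get(v, 0) == 0 and visit(v) for v in nodes)


# ------------------------------------------------------- bootstrap averaging


@dataclass
class ArcStrengths:
    """Bootstrap arc support: per ordered pair, the fraction of bootstrap
    networks containing the arc in either direction (strength) and, among
    those, the fraction oriented this way (direction)."""

    nodes: tuple[str, ...]
    strength: dict[tuple[str, str], float]
    direction: dict[tuple[str, str], float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "from": a,
                "to": b,
                "strength": self.strength[(a, b)],
                "direction": self.direction[(a, b)],
            }
            for a in self.nodes
            for b in self.nodes
            if a != b
        ]
        return pd.DataFrame(rows)


def l1_strength_threshold(strengths: np.ndarray) -> float:
    """Data-driven significance threshold on bootstrap arc strengths.

    Chooses the threshold whose induced {0,1} idealized strength CDF is
    closest in L1 to the empirical strength CDF (Scutari-Nagarajan style
    estimator).
    """
    s = np.sort(np.asarray(strengths, dtype=float))
    if len(s) == 0:
        return 0.5
    # candidate thresholds between observed values
    uniq = np.unique(s)
    candidates = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]]) if len(uniq) > 1 else np.array([0.5])
    grid = np.unique(np.concatenate([s, [0.0, 1.0]]))
    ecdf = np.searchsorted(s, grid, side="right") / len(s)
    widths = np.diff(np.concatenate([grid, [1.0]]))
    best_t, best_l1 = 0.5, np.inf
    for t in candidates:
        step = np.searchsorted(s, t, side="right") / len(s)
        l1 = float(np.sum(np.abs(ecdf - step) * widths))
        if l1 < best_l1 - 1e-15:
            best_l1, best_t = l1, t
    return float(best_t)


def bootstrap_average(
    data: pd.DataFrame,
    B: int = 500,
    blacklist=(),
    whitelist=(),
    threshold: float | str = "l1",
    tabu_length: int = 10,
    seed: int = 0,
) -> tuple[ArcStrengths, DAGModel]:
    """Nonparametric bootstrap model averaging of TABU/BGe networks.

    B row-resamples are each learned by `learn_structure`; arcs whose
    strength exceeds the threshold (data-driven L1 estimator by default, or a
    fixed value) are kept, oriented by majority direction. If the majority
    orientations conflict into a cycle, the weakest arcs in the cycle are
    dropped until the result is acyclic.
    """
    rng = np.random.default_rng(seed)
    nodes = tuple(str(c) for c in data.columns)
    und_counts: dict[frozenset, int] = {}
    dir_counts: dict[tuple[str, str], int] = {}
    n = len(data)
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        boot = data.iloc[idx].reset_index(drop=True)
        if (boot.std(ddof=1) == 0).any():
            continue  # degenerate resample
        dag = learn_structure(boot, blacklist=blacklist, whitelist=whitelist, tabu_length=tabu_length)
        for a, b in dag.arcs:
            und_counts[frozenset((a, b))] = und_counts.get(frozenset((a, b)), 0) + 1
            dir_counts[(a, b)] = dir_counts.get((a, b), 0) + 1
    strength = {}
    direction = {}
    for a in nodes:
        for b in nodes:
            if a == b:
                continue
            u = und_counts.get(frozenset((a, b)), 0)
            strength[(a, b)] = u / B
            direction[(a, b)] = (dir_counts.get((a, b), 0) / u) if u else 0.0
    arcs = ArcStrengths(nodes=nodes, strength=strength, direction=direction)
    uniq_strengths = np.array(
        [strength[(a, b)] for a, b in strength if a < b or (b, a) not in strength]
    )
    if threshold == "l1":
        thr = l1_strength_threshold(uniq_strengths)
    else:
        thr = float(threshold)
    kept = []
    seen = set()
    for (a, b), s in strength.items():
        if frozenset((a, b)) in seen:
            continue
        seen.add(frozenset((a, b)))
        if s > thr:
            if direction[(a, b)] >= direction[(b, a)]:
                kept.append((a, b, s))
            else:
                kept.append((b, a, s))
    kept.sort(key=lambda x: (-x[2], x[0], x[1]))
    parents: dict[str, frozenset[str]] = {v: frozenset() for v in nodes}
    for a, b, _s in kept:
        trial = dict(parents)
        trial[b] = trial[b] | {a}
        if not _cyclic(nodes, trial):
            parents = trial
    avg = DAGModel(nodes, parents)
    return arcs, avg


def consensus_network(dags: list[DAGModel]) -> DAGModel:
    """Arc intersection across per-scenario averaged networks."""
    if not dags:
        raise ValueError("no networks to intersect")
    nodes = dags[0].nodes
    common = set.intersection(*(d.arcs for d in dags))
    parents: dict[str, frozenset[str]] = {v: frozenset() for v in nodes}
    for a, b in common:
        parents[b] = parents[b] | {a}
    return DAGModel(nodes, parents)


# --------------------------------------------------------- cross-validation


def cv_predict(
    model: DAGModel,
    data: pd.DataFrame,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Repeated k-fold CV of the linear-Gaussian network.

    Each node is predicted on held-out rows from its parents' observed values
    using coefficients fitted on the training rows; the predicted/observed
    Pearson correlation is averaged over folds and repeats. Parentless nodes
    return NaN (a constant prediction has no correlation).
    """
    rng = np.random.default_rng(seed)
    n = len(data)
    X = data.to_numpy(dtype=float)
    cols = {str(c): i for i, c in enumerate(data.columns)}
    corrs: dict[str, list[float]] = {v: [] for v in model.nodes}
    for _ in range(repeats):
        perm = rng.permutation(n)
        fold_ids = np.array_split(perm, folds)
        for test_idx in fold_ids:
            mask = np.zeros(n, dtype=bool)
            mask[test_idx] = True
            train, test = X[~mask], X[mask]
            for v in model.nodes:
                pa = sorted(model.parents[v])
                if not pa:
                    continue
                j = cols[v]
                pj = [cols[u] for u in pa]
                A = np.hstack([np.ones((train.shape[0], 1)), train[:, pj]])
                beta, *_ = np.linalg.lstsq(A, train[:, j], rcond=None)
                At = np.hstack([np.ones((test.shape[0], 1)), test[:, pj]])
                pred = At @ beta
                obs = test[:, j]
                if np.std(pred) == 0 or np.std(obs) == 0:
                    corrs[v].append(0.0)
                else:
                    corrs[v].append(float(np.corrcoef(pred, obs)[0, 1]))
    return {v: (float(np.mean(c)) if c else float("nan")) for v, c in corrs.items()}


def default_constraints(nodes, year_node: str = "year", gn_node: str = "grain_number",
                        pre_gn_traits=("veg", "silk", "rh_pad", "ear_light")):
    """Blacklist per the temporal-order assumptions: no arcs into year of
    release, and no arcs from grain number back to traits determined during
    the vegetative and flowering periods."""
    nodes = [str(n) for n in nodes]
    bl = [(v, year_node) for v in nodes if v != year_node]
    bl += [(gn_node, t) for t in pre_gn_traits if t in nodes]
    return bl
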