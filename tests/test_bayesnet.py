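"""BGe scoring, TABU structure search, bootstrap averaging, CV prediction."""

from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest
from scipy.special import multigammaln

import breedscan as bs
from breedscan.bayesnet import DAGModel, l1_strength_threshold


def _standardized(df):
    return (df - df.mean()) / df.std(ddof=1)


def subset_log_marginal(X, cols, am, aw, t, d):
    """Closed-form normal-Wishart marginal likelihood of a variable subset.

    Independent route: the matrix-normal/Wishart closed form on the joint
    subset, using the multivariate gamma function directly.
    """
    n = X.shape[0]
    l = len(cols)
    if l == 0:
        return 0.0
    Xa = X[:, cols]
    Xc = Xa - Xa.mean(axis=0)
    xbar = Xa.mean(axis=0)
    R = t * np.eye(l) + Xc.T @ Xc + (n * am / (n + am)) * np.outer(xbar, xbar)
    nu = aw - d + l
    sign, logdet = np.linalg.slogdet(R)
    return (
        -0.5 * n * l * np.log(np.pi)
        + 0.5 * l * np.log(am / (am + n))
        + multigammaln((n + nu) / 2.0, l)
        - multigammaln(nu / 2.0, l)
        + (nu / 2.0) * l * np.log(t)
        - ((n + nu) / 2.0) * logdet
    )


def all_dags(nodes):
    """Enumerate every DAG over `nodes` (adjacency over ordered pairs)."""
    pairs = [(a, b) for a in nodes for b in nodes if a != b]
    for bits in product([0, 1], repeat=len(pairs)):
        arcs = [p for p, b in zip(pairs, bits) if b]
        parents = {v: frozenset(a for a, b in arcs if b == v) for v in nodes}
        try:
            yield DAGModel(tuple(nodes), parents)
        except ValueError:
            continue


class TestBGeScore:
    def test_markov_equivalence_two_nodes(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(25, 2)), columns=["A", "B"])
        sc = bs.BGeScorer(df)
        ab = sc.score(DAGModel(("A", "B"), {"B": frozenset("A")}))
        ba = sc.score(DAGModel(("A", "B"), {"A": frozenset("B")}))
        assert ab == pytest.approx(ba, abs=1e-10)

    def test_decomposability(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("ABCD"))
        sc = bs.BGeScorer(df)
        dag = DAGModel(
            ("A", "B", "C", "D"),
            {"B": frozenset("A"), "C": frozenset("AB"), "D": frozenset("C")},
        )
        total = sc.score(dag)
        assert total == pytest.approx(sum(dag.family_scores.values()), abs=1e-10)

    def test_matches_closed_form_oracle_3_nodes(self):
        rng = np.random.default_rng(2)
        raw = pd.DataFrame(rng.normal(size=(10, 3)), columns=["x", "y", "z"])
        df = _standardized(raw)
        sc = bs.BGeScorer(df)
        X = df.to_numpy()
        d, n = 3, 10
        am, aw = sc.am, sc.aw
        t = sc.t
        dag = DAGModel(("x", "y", "z"), {"y": frozenset("x"), "z": frozenset(["x", "y"])})
        total = sc.score(dag)
        # oracle: sum over families of joint-subset marginal ratios
        idx = {"x": 0, "y": 1, "z": 2}
        expected = 0.0
        for node, parents in [("x", []), ("y", ["x"]), ("z", ["x", "y"])]:
            fam = sorted(idx[c] for c in parents + [node])
            pa = sorted(idx[c] for c in parents)
            expected += subset_log_marginal(X, fam, am, aw, t, d) - subset_log_marginal(
                X, pa, am, aw, t, d
            )
        assert total == pytest.approx(expected, abs=1e-8)

    def test_equivalence_classes_all_4_node_dags(self):
        """BGe score is constant within every Markov-equivalence class."""
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("ABCD"))
        sc = bs.BGeScorer(df)
        by_class: dict = {}
        n_dags = 0
        for dag in all_dags(list("ABCD")):
            n_dags += 1
            by_class.setdefault(dag.cpdag_key(), []).append(sc.score(dag))
        assert n_dags == 543  # number of labeled DAGs on 4 nodes
        assert len(by_class) == 185  # number of Markov-equivalence classes
        for scores in by_class.values():
            assert max(scores) - min(scores) < 1e-10

    def test_constant_column_raises(self):
        df = pd.DataFrame({"A": [1.0, 1.0, 1.0, 1.0], "B": [0.1, 0.4, 0.2, 0.9]})
        with pytest.raises(ValueError, match="singular.*A"):
            bs.BGeScorer(df)


class TestLearnStructure:
    def test_blacklist_never_violated(self):
        rng = np.random.default_rng(4)
        bl = [("B", "A"), ("C", "A")]
        for _ in range(100):
            df = pd.DataFrame(rng.normal(size=(30, 3)), columns=["A", "B", "C"])
            df["B"] += 0.8 * df["A"]
            dag = bs.learn_structure(df, blacklist=bl)
            assert not (set(bl) & dag.arcs)

    def test_whitelist_present_and_conflict_detected(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=["A", "B", "C"])
        dag = bs.learn_structure(df, whitelist=[("A", "C")])
        assert ("A", "C") in dag.arcs
        with pytest.raises(ValueError, match="contradictory"):
            bs.learn_structure(df, blacklist=[("A", "C")], whitelist=[("A", "C")])

    def test_planted_chain_recovered(self):
        rng = np.random.default_rng(6)
        n = 500
        year = rng.normal(size=n)
        veg = 0.95 * year + 0.25 * rng.normal(size=n)
        gn = 0.95 * veg + 0.25 * rng.normal(size=n)
        df = pd.DataFrame({"year": year, "veg": veg, "gn": gn})
        dag = bs.learn_structure(df)
        skeleton = {frozenset(a) for a in dag.arcs}
        assert skeleton == {frozenset(("year", "veg")), frozenset(("veg", "gn"))}

    def test_score_at_least_empty_graph(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("ABCD"))
        df["D"] += df["A"] - df["B"]
        dag = bs.learn_structure(df)
        empty = DAGModel(tuple(df.columns), {})
        assert dag.score >= bs.BGeScorer(df).score(empty)

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("ABCD"))
        d1 = bs.learn_structure(df, seed=1)
        d2 = bs.learn_structure(df, seed=2)
        assert d1.arcs == d2.arcs


class TestBootstrap:
    def test_deterministic_arc_full_strength(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=80)
        df = pd.DataFrame({"x": x, "y": 2.0 * x})  # noiseless linear arc
        arcs, avg = bs.bootstrap_average(df, B=50, seed=0)
        assert arcs.strength[("x", "y")] == 1.0
        assert {frozenset(a) for a in avg.arcs} == {frozenset(("x", "y"))}

    def test_independent_variables_below_threshold(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("ABCD"))
        arcs, avg = bs.bootstrap_average(df, B=100, seed=1)
        assert len(avg.arcs) == 0

    def test_strength_symmetry_and_direction_sum(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("ABC"))
        df["B"] += df["A"]
        arcs, _ = bs.bootstrap_average(df, B=60, seed=2)
        for a in "ABC":
            for b in "ABC":
                if a == b:
                    continue
                assert arcs.strength[(a, b)] == arcs.strength[(b, a)]
                if arcs.strength[(a, b)] > 0:
                    assert arcs.direction[(a, b)] + arcs.direction[(b, a)] == pytest.approx(1.0)

    def test_bit_identical_under_seed(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("ABC"))
        df["C"] += df["B"]
        a1, avg1 = bs.bootstrap_average(df, B=40, seed=5)
        a2, avg2 = bs.bootstrap_average(df, B=40, seed=5)
        assert a1.strength == a2.strength and a1.direction == a2.direction
        assert avg1.arcs == avg2.arcs

    def test_l1_threshold_separates_bimodal_strengths(self):
        s = np.array([0.02, 0.04, 0.05, 0.9, 0.95, 1.0])
        thr = l1_strength_threshold(s)
        assert 0.05 < thr < 0.9


class TestCVPredict:
    def test_noiseless_functional_dag(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=100)
        df = pd.DataFrame({"x": x, "y": 3.0 * x, "z": -1.0 * x})
        model = DAGModel(("x", "y", "z"), {"y": frozenset("x"), "z": frozenset("x")})
        cv = bs.cv_predict(model, df, seed=0)
        assert cv["y"] == pytest.approx(1.0, abs=1e-10)
        assert cv["z"] == pytest.approx(1.0, abs=1e-10)
        assert np.isnan(cv["x"])  # root node: no parents to predict from

    def test_pure_noise_node_near_zero(self):
        rng = np.random.default_rng(14)
        n = 400
        df = pd.DataFrame({"x": rng.normal(size=n), "y": rng.normal(size=n)})
        model = DAGModel(("x", "y"), {"y": frozenset("x")})
        cv = bs.cv_predict(model, df, seed=1)
        assert abs(cv["y"]) < 2 / np.sqrt(n)


def test_default_constraints_block_year_and_gn_arcs():
    nodes = ["year", "veg", "silk", "rh_pad", "ear_light", "grain_number"]
    bl = bs.default_constraints(nodes)
    assert ("grain_number", "year") in bl and ("veg", "year") in bl
    assert ("grain_number", "veg") in bl
    assert ("year", "grain_number") not in bl
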