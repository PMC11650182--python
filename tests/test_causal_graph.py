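"""PC machinery: CI testing, skeleton, orientation, graph oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from stabnet.causal_graph import (
    Cpdag,
    SepsetMap,
    cpdag_of,
    d_separated,
    fisher_z_test,
    meek_closure,
    oracle_pc,
    orient_v_structures,
    partial_correlation,
    pc_skeleton,
    run_pc,
)
from stabnet.cohort_model import CohortTable, VariableRoster
from stabnet.errors import InsufficientSampleError, ValidationError
from stabnet.synthetic_data import (
    Dag,
    chain_sem,
    collider_sem,
    random_dag,
    sem_roster,
    simulate_cohort,
)


class TestPartialCorrelation:
    def test_empty_set_is_plain_correlation(self):
        corr = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert partial_correlation(corr, 0, 1, []) == pytest.approx(0.3)

    def test_chain_vanishes_given_mediator(self):
        corr = np.array([
            [1.0, 0.6, 0.36],
            [0.6, 1.0, 0.6],
            [0.36, 0.6, 1.0],
        ])
        assert partial_correlation(corr, 0, 2, [1]) == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_set_order(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(200, 5))
        corr = np.corrcoef(A.T)
        a = partial_correlation(corr, 0, 1, [2, 3, 4])
        b = partial_correlation(corr, 0, 1, [4, 2, 3])
        assert a == pytest.approx(b, abs=1e-12)

    def test_matches_regression_residual_definition(self):
        """Inversion formula agrees with the residual-correlation definition."""
        rng = np.random.default_rng(1)
        n = 5000
        z = rng.normal(size=(n, 2))
        x = z @ [0.5, 0.4] + rng.normal(size=n)
        y = z @ [0.3, 0.6] + 0.5 * x + rng.normal(size=n)
        data = np.column_stack([x, y, z])
        corr = np.corrcoef(data.T)
        got = partial_correlation(corr, 0, 1, [2, 3])
        Z = np.column_stack([np.ones(n), z])
        rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
        ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        assert got == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-6)


class TestFisherZ:
    def test_zero_correlation_is_independent(self):
        d = fisher_z_test(0.0, 100, 0, alpha=0.05)
        assert d.p == 1.0 and d.independent

    def test_closed_form_example(self):
        d = fisher_z_test(0.5, 103, 0, alpha=0.05)
        assert d.stat == pytest.approx(5.493061443340549, abs=1e-9)
        assert d.p == pytest.approx(3.950252784999203e-08, rel=1e-6)
        assert not d.independent

    def test_sample_too_small_raises(self):
        with pytest.raises(InsufficientSampleError):
            fisher_z_test(0.1, 5, 2, alpha=0.05)

    @pytest.mark.parametrize("alpha", [0.01, 0.05])
    def test_type_one_error_calibrated(self, alpha):
        rng = np.random.default_rng(13)
        reps, n = 1000, 200
        x = rng.normal(size=(reps, n))
        y = rng.normal(size=(reps, n))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (xc * yc).sum(axis=1) / np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
        rej = sum(not fisher_z_test(v, n, 0, alpha).independent for v in r)
        band = 3 * np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rej / reps - alpha) < band


def _cohort(sem, roster, n, seed):
    return simulate_cohort(sem, roster, n, seed)


class TestSkeleton:
    def test_independent_columns_empty_skeleton(self, make_table):
        rng = np.random.default_rng(3)
        t = make_table(rng.normal(size=(5000, 2)))
        skel, _ = pc_skeleton(t, alpha=0.05)
        assert not skel.undirected

    def test_chain_skeleton_and_sepset(self):
        sem, roster = chain_sem()
        skel, seps = pc_skeleton(_cohort(sem, roster, 5000, 4), alpha=0.01)
        assert skel.undirected == {frozenset("XY"), frozenset("YZ")}
        assert seps.get("X", "Z") == frozenset({"Y"})

    def test_invariant_under_column_permutation(self):
        sem, roster = chain_sem()
        t = _cohort(sem, roster, 3000, 5)
        perm = [2, 0, 1]
        roster_p = VariableRoster([roster.entries[i] for i in perm])
        t_p = CohortTable(t.values[:, perm], roster_p, t.participant_ids)
        g1 = run_pc(t, alpha=0.01)
        g2 = run_pc(t_p, alpha=0.01)
        assert g1 == g2


class TestOrientation:
    def test_collider_oriented(self):
        sem, roster = collider_sem()
        g = run_pc(_cohort(sem, roster, 5000, 6), alpha=0.01)
        assert g.directed == {("A", "C"), ("B", "C")}
        assert not g.undirected

    def test_chain_class_stays_undirected(self):
        sem, roster = chain_sem()
        g = run_pc(_cohort(sem, roster, 5000, 7), alpha=0.01)
        assert not g.directed
        assert g.undirected == {frozenset("XY"), frozenset("YZ")}

    def test_mediator_in_sepset_blocks_v_structure(self):
        skel = Cpdag(("X", "Y", "Z"),
                     undirected={frozenset("XY"), frozenset("YZ")})
        seps = SepsetMap()
        seps.set("X", "Z", {"Y"})
        out = orient_v_structures(skel, seps)
        assert not out.directed

    def test_conflicting_demands_stay_undirected(self, caplog):
        # star a-z, b-z, z-w, c-w, d-w with sepsets forcing both z->w and w->z
        nodes = ("a", "b", "c", "d", "z", "w")
        und = {frozenset(p) for p in
               (("a", "z"), ("b", "z"), ("z", "w"), ("c", "w"), ("d", "w"))}
        seps = SepsetMap()
        seps.set("a", "b", set())
        seps.set("a", "w", set())   # a-z-w unshielded, w not in sepset -> a->z<-w
        seps.set("c", "z", set())   # c-w-z unshielded -> c->w<-z
        seps.set("c", "d", set())
        seps.set("a", "c", set())
        seps.set("a", "d", set())
        seps.set("b", "c", set())
        seps.set("b", "d", set())
        seps.set("b", "w", set())
        seps.set("d", "z", set())
        with caplog.at_level("INFO"):
            out = orient_v_structures(Cpdag(nodes, undirected=und), seps)
        assert frozenset(("z", "w")) in out.undirected
        assert "conflict" in caplog.text.lower()


class TestMeek:
    def test_r1_orients_downstream_edge(self):
        g = Cpdag(("a", "b", "c"), undirected={frozenset("bc")},
                  directed={("a", "b")})
        out = meek_closure(g)
        assert ("b", "c") in out.directed

    def test_undirected_triangle_unchanged(self):
        tri = {frozenset(p) for p in (("a", "b"), ("b", "c"), ("a", "c"))}
        g = Cpdag(("a", "b", "c"), undirected=set(tri))
        out = meek_closure(g)
        assert out.undirected == tri and not out.directed

    def test_r2_closes_directed_chain(self):
        g = Cpdag(("a", "b", "c"), undirected={frozenset("ac")},
                  directed={("a", "b"), ("b", "c")})
        out = meek_closure(g)
        assert ("a", "c") in out.directed

    def test_idempotent(self, dag_enumerator):
        for dag in dag_enumerator(("a", "b", "c", "d"))[::25]:
            g = cpdag_of(dag)
            assert meek_closure(g) == g


class TestDSeparation:
    def test_chain_and_collider_textbook_cases(self):
        chain = Dag(("X", "Y", "Z"), frozenset({("X", "Y"), ("Y", "Z")}))
        assert d_separated(chain, "X", "Z", {"Y"})
        assert not d_separated(chain, "X", "Z", set())
        coll = Dag(("X", "Y", "Z"), frozenset({("X", "Z"), ("Y", "Z")}))
        assert d_separated(coll, "X", "Y", set())
        assert not d_separated(coll, "X", "Y", {"Z"})

    def test_descendant_of_collider_opens_path(self):
        dag = Dag(("X", "Y", "Z", "W"),
                  frozenset({("X", "Z"), ("Y", "Z"), ("Z", "W")}))
        assert not d_separated(dag, "X", "Y", {"W"})

    def test_unknown_node_rejected(self):
        chain = Dag(("X", "Y"), frozenset({("X", "Y")}))
        with pytest.raises(ValidationError):
            d_separated(chain, "X", "Q", set())

    def test_agreement_with_networkx_oracle(self):
        """200 random queries on random DAGs of up to 5 nodes, checked
        against networkx's independent d-separation implementation."""
        rng = np.random.default_rng(23)
        checked = 0
        k = 0
        while checked < 200:
            k += 1
            n = int(rng.integers(3, 6))
            dag = random_dag(n, 0.5, seed=int(rng.integers(1 << 30)))
            g = nx.DiGraph()
            g.add_nodes_from(dag.nodes)
            g.add_edges_from(dag.edges)
            names = list(dag.nodes)
            x, y = rng.choice(names, size=2, replace=False)
            rest = [v for v in names if v not in (x, y)]
            S = {v for v in rest if rng.random() < 0.4}
            assert d_separated(dag, x, y, S) == nx.is_d_separator(g, {x}, {y}, S)
            checked += 1


class TestOracles:
    def test_chain_cpdag_fully_undirected(self):
        chain = Dag(("X", "Y", "Z"), frozenset({("X", "Y"), ("Y", "Z")}))
        g = cpdag_of(chain)
        assert not g.directed and len(g.undirected) == 2

    def test_collider_cpdag_fully_directed(self):
        coll = Dag(("X", "Y", "Z"), frozenset({("X", "Z"), ("Y", "Z")}))
        g = cpdag_of(coll)
        assert g.directed == {("X", "Z"), ("Y", "Z")} and not g.undirected

    def test_oracle_pc_matches_cpdag_on_three_nodes(self, dag_enumerator):
        dags = dag_enumerator(("a", "b", "c"))
        assert len(dags) == 25  # labeled DAGs on 3 nodes
        for dag in dags:
            assert oracle_pc(dag) == cpdag_of(dag)

    def test_data_pc_matches_oracle_on_random_dags(self):
        """Large-sample consistency: PC from simulated data equals the
        exact equivalence class for random sparse 6-node DAGs."""
        from stabnet.synthetic_data import random_sem

        hits = 0
        for k in range(20):
            dag = random_dag(6, 0.25, seed=500 + k)
            sem = random_sem(dag, seed=600 + k, weight_range=(0.4, 0.6))
            t = simulate_cohort(sem, sem_roster(sem), 20_000, seed=700 + k)
            if run_pc(t, alpha=0.01) == cpdag_of(dag):
                hits += 1
        assert hits >= 16

    def test_skeleton_subset_of_marginal_dependence_graph(self):
        sem, roster = collider_sem()
        t = simulate_cohort(sem, roster, 4000, seed=31)
        corr = np.corrcoef(t.values.T)
        n = t.n_rows
        dep0 = set()
        names = roster.names
        for i, j in itertools.combinations(range(len(names)), 2):
            if not fisher_z_test(corr[i, j], n, 0, 0.05).independent:
                dep0.add(frozenset((names[i], names[j])))
        skel, _ = pc_skeleton(t, alpha=0.05)
        assert skel.undirected <= dep0


class TestCpdagType:
    def test_rejects_pair_in_both_parts(self):
        with pytest.raises(ValidationError):
            Cpdag(("a", "b"), undirected={frozenset("ab")}, directed={("a", "b")})

    def test_rejects_directed_cycle(self):
        with pytest.raises(ValidationError):
            Cpdag(("a", "b", "c"),
                  directed={("a", "b"), ("b", "c"), ("c", "a")})

    def test_edge_records_and_tsv(self, tmp_path):
        g = Cpdag(("a", "b", "c"), undirected={frozenset("bc")},
                  directed={("a", "b")})
        path = tmp_path / "g.tsv"
        g.write_tsv(path)
        lines = path.read_text().strip().split("\n")
        assert lines[0] == "source\ttarget\tkind"
        assert "a\tb\tdirected" in lines and "b\tc\tundirected" in lines

    def test_graphml_round_trip_kinds(self, tmp_path):
        g = Cpdag(("a", "b", "c"), undirected={frozenset("bc")},
                  directed={("a", "b")})
        path = tmp_path / "g.graphml"
        g.write_graphml(path)
        back = nx.read_graphml(path)
        kinds = nx.get_edge_attributes(back, "kind")
        assert set(kinds.values()) == {"directed", "undirected"}
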