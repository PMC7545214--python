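"""Mg-Mg distances, coupled pairs, EET steps, and pathway assembly."""

import itertools

import numpy as np
import pytest

from fcpinet import (
    ConfigError,
    CycleError,
    EETStep,
    LayerAssignment,
    Leaflet,
    ParameterError,
    PigmentClass,
    assemble_pathways,
    derive_eet_steps,
    find_coupled_pairs,
    mg_mg_distance,
    pathway_code,
    pathway_report,
    read_edge_list,
    round_half_up,
    write_edge_list,
)
from fcpinet.network import _subunit_roles
from fcpinet.synth import table2_fixture

from conftest import make_model, make_record


def step(donor, acceptor, distance, leaflet=Leaflet.STROMAL,
         donor_site=400, acceptor_site=401):
    return EETStep(donor_subunit=donor, acceptor_subunit=acceptor,
                   donor_site=donor_site, acceptor_site=acceptor_site,
                   distance=distance, leaflet=leaflet)


class TestMgMgDistance:
    def test_identical_points(self):
        p = make_record("A", 400, PigmentClass.CHL_A, (1, 2, 3))
        q = make_record("B", 401, PigmentClass.CHL_A, (1, 2, 3))
        assert mg_mg_distance(p, q) == 0.0

    def test_analytic_3_4_5(self):
        p = make_record("A", 400, PigmentClass.CHL_A, (0, 0, 0))
        q = make_record("A", 401, PigmentClass.CHL_A, (3, 4, 0))
        assert mg_mg_distance(p, q) == pytest.approx(5.0)
        assert mg_mg_distance(q, p) == pytest.approx(5.0)

    def test_non_chlorophyll_rejected(self):
        p = make_record("A", 400, PigmentClass.CHL_A, (0, 0, 0))
        q = make_record("A", 301, PigmentClass.FUCOXANTHIN, (1, 0, 0))
        with pytest.raises(TypeError):
            mg_mg_distance(p, q)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        recs = [make_record("A", 400 + i, PigmentClass.CHL_A, pos)
                for i, pos in enumerate(rng.uniform(-20, 20, size=(6, 3)))]
        for p, q, r in itertools.permutations(recs, 3):
            assert mg_mg_distance(p, r) <= \
                mg_mg_distance(p, q) + mg_mg_distance(q, r) + 1e-9


class TestCoupledPairs:
    def test_empty_model(self):
        assert find_coupled_pairs(make_model([])) == []

    def test_single_pair_within_cutoff(self):
        model = make_model([
            make_record("A", 403, PigmentClass.CHL_A, (0, 0, 0),
                        leaflet=Leaflet.STROMAL),
            make_record("A", 406, PigmentClass.CHL_A, (9, 0, 0),
                        leaflet=Leaflet.STROMAL),
            make_record("A", 410, PigmentClass.CHL_A, (30, 0, 0),
                        leaflet=Leaflet.STROMAL),
        ])
        pairs = find_coupled_pairs(model, pair_cutoff=12.0)
        assert len(pairs) == 1
        assert pairs[0].distance == pytest.approx(9.0)
        assert pairs[0].same_subunit
        assert pairs[0].leaflet is Leaflet.STROMAL

    def test_canonical_order_and_input_invariance(self):
        recs = [
            make_record("B", 406, PigmentClass.CHL_A, (9, 0, 0)),
            make_record("A", 403, PigmentClass.CHL_A, (0, 0, 0)),
        ]
        for perm in itertools.permutations(recs):
            pairs = find_coupled_pairs(make_model(list(perm)))
            assert pairs[0].pigment_a == ("A", 403)
            assert pairs[0].pigment_b == ("B", 406)

    def test_nonpositive_cutoff(self):
        with pytest.raises(ParameterError):
            find_coupled_pairs(make_model([]), pair_cutoff=-1.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        recs = [make_record("A", 400 + i, PigmentClass.CHL_A, pos)
                for i, pos in enumerate(rng.uniform(-25, 25, size=(40, 3)))]
        model = make_model(recs)
        got = {(c.pigment_a, c.pigment_b) for c in find_coupled_pairs(model, 12.0)}
        expected = set()
        for p, q in itertools.combinations(recs, 2):
            if np.linalg.norm(p.representative_point - q.representative_point) <= 12:
                a, b = sorted([p.pigment_id, q.pigment_id])
                expected.add((a, b))
        assert got == expected


def brute_force_min_steps(model, shells, cutoff):
    """Exhaustive minimal Chl-a pair per (donor, acceptor, leaflet)."""
    chls = [p for p in model.pigments if p.pigment_class is PigmentClass.CHL_A]
    best = {}
    for p, q in itertools.permutations(chls, 2):
        sd, sa = shells.get(p.subunit_label), shells.get(q.subunit_label)
        if sd is None or sa is None or not sd > sa or sd < 1:
            continue
        if p.leaflet is not q.leaflet:
            continue
        d = float(np.linalg.norm(p.representative_point - q.representative_point))
        key = (p.subunit_label, q.subunit_label, p.leaflet)
        if d <= cutoff and (key not in best or d < best[key][0]):
            best[key] = (d, p.residue_number, q.residue_number)
    return best


class TestDeriveSteps:
    def _random_two_subunit_model(self, seed):
        rng = np.random.default_rng(seed)
        recs = []
        for i in range(5):
            recs.append(make_record("D", 400 + i, PigmentClass.CHL_A,
                                    rng.uniform(0, 15, 3) + [20, 0, 0],
                                    subunit="FCPI-1", leaflet=Leaflet.STROMAL))
        for i in range(5):
            recs.append(make_record("C", 800 + i, PigmentClass.CHL_A,
                                    rng.uniform(0, 15, 3),
                                    subunit="PsaA", leaflet=Leaflet.STROMAL))
        return make_model(recs)

    @pytest.mark.parametrize("seed", range(4))
    def test_minimal_step_matches_brute_force(self, seed):
        model = self._random_two_subunit_model(seed)
        shells = {"FCPI-1": 1.0, "PsaA": 0.0}
        layers = LayerAssignment(shells=shells)
        steps = derive_eet_steps(model, layers, step_cutoff=26.0)
        oracle = brute_force_min_steps(model, shells, 26.0)
        got = {(s.donor_subunit, s.acceptor_subunit, s.leaflet):
               (s.distance, s.donor_site, s.acceptor_site) for s in steps}
        assert set(got) == set(oracle)
        for key in oracle:
            assert got[key][0] == pytest.approx(oracle[key][0])
            assert got[key][1:] == oracle[key][1:]

    def test_no_step_without_donor_chl_in_leaflet(self):
        model = make_model([
            make_record("D", 400, PigmentClass.CHL_A, (20, 0, 0),
                        subunit="FCPI-1", leaflet=Leaflet.LUMENAL),
            make_record("C", 800, PigmentClass.CHL_A, (0, 0, 0),
                        subunit="PsaA", leaflet=Leaflet.STROMAL),
        ])
        layers = LayerAssignment(shells={"FCPI-1": 1.0, "PsaA": 0.0})
        assert derive_eet_steps(model, layers, 26.0) == []

    def test_efficiency_flag_threshold(self):
        assert step("FCPI-1", "PsaA", 19.9).efficient
        assert not step("FCPI-1", "PsaA", 22.2).efficient

    def test_uphill_pairs_excluded(self):
        model = self._random_two_subunit_model(0)
        layers = LayerAssignment(shells={"FCPI-1": 1.0, "PsaA": 0.0})
        steps = derive_eet_steps(model, layers, 26.0)
        assert all(s.donor_subunit == "FCPI-1" for s in steps)


def brute_force_chains(steps):
    """Independent DFS enumeration of source -> core simple chains."""
    chains = []
    for leaflet in (Leaflet.STROMAL, Leaflet.LUMENAL):
        edges = {}
        for s in steps:
            if s.leaflet is leaflet:
                key = (s.donor_subunit, s.acceptor_subunit)
                if key not in edges or s.distance < edges[key].distance:
                    edges[key] = s
        out, inc = set(), set()
        for u, v in edges:
            out.add(u)
            inc.add(v)
        sources = out - inc

        def walk(node, path):
            if node.startswith("Psa"):
                chains.append((leaflet, tuple(path)))
                return
            nexts = [v for (u, v) in edges if u == node]
            if not nexts:
                return  # dead end off-core: not a complete chain
            for v in nexts:
                walk(v, path + [v])

        for src in sorted(sources):
            walk(src, [src])
    return chains


class TestAssembly:
    def test_empty_steps(self):
        assert assemble_pathways([]) == []

    def test_single_step_pathway(self):
        paths = assemble_pathways(
            [step("FCPI-11", "PsaB", 22.2, Leaflet.LUMENAL, 409, 815)])
        assert len(paths) == 1
        assert paths[0].code == "11-BL"
        assert paths[0].complete

    def test_branching_source_yields_two_pathways(self):
        steps = [
            step("FCPI-18", "FCPI-17", 14.7, Leaflet.LUMENAL),
            step("FCPI-17", "PsaA", 14.2, Leaflet.LUMENAL),
            step("FCPI-18", "FCPI-7", 20.4, Leaflet.LUMENAL),
            step("FCPI-7", "PsaJ", 11.8, Leaflet.LUMENAL),
        ]
        codes = sorted(p.code for p in assemble_pathways(steps))
        assert codes == ["18-17-AL", "18-7-JL"]

    def test_convergent_chains_count_separately(self):
        steps = [
            step("FCPI-19", "FCPI-8", 18.0, Leaflet.LUMENAL),
            step("FCPI-20", "FCPI-8", 18.9, Leaflet.LUMENAL),
            step("FCPI-8", "PsaB", 19.4, Leaflet.LUMENAL),
        ]
        codes = sorted(p.code for p in assemble_pathways(steps))
        assert codes == ["19-8-BL", "20-8-BL"]

    def test_cycle_detection(self):
        steps = [
            step("FCPI-1", "FCPI-2", 10.0),
            step("FCPI-2", "FCPI-1", 10.0),
        ]
        with pytest.raises(CycleError):
            assemble_pathways(steps)

    def test_dead_end_chain_flagged_incomplete(self):
        paths = assemble_pathways([step("FCPI-5", "FCPI-4", 10.0)])
        assert len(paths) == 1
        assert not paths[0].complete

    @pytest.mark.parametrize("seed", range(4))
    def test_counts_match_dfs_oracle(self, seed):
        """Assembly equals an independent brute-force DFS on random DAGs."""
        rng = np.random.default_rng(seed)
        antennas = [f"FCPI-{i}" for i in range(1, 9)]
        cores = ["PsaA", "PsaB"]
        shells = {a: 1 + i // 4 for i, a in enumerate(antennas)}
        steps = []
        for a in antennas:
            targets = [t for t in antennas if shells[t] < shells[a]] + cores
            for t in rng.choice(targets, size=min(2, len(targets)),
                                replace=False):
                steps.append(step(a, str(t), float(rng.uniform(5, 25))))
        paths = assemble_pathways(steps)
        complete = [p for p in paths if p.complete]
        oracle = brute_force_chains(steps)
        assert len(complete) == len(oracle)
        got = sorted((p.leaflet, tuple(p.subunits)) for p in complete)
        assert got == sorted(oracle)


class TestPathwayCode:
    def _roles(self, labels):
        return _subunit_roles(labels)

    def test_three_hop_code(self):
        steps = [
            step("FCPI-18", "FCPI-17", 14.7, Leaflet.LUMENAL),
            step("FCPI-17", "FCPI-6", 18.9, Leaflet.LUMENAL),
            step("FCPI-6", "PsaA", 14.2, Leaflet.LUMENAL),
        ]
        labels = {"FCPI-18", "FCPI-17", "FCPI-6", "PsaA"}
        assert pathway_code(steps, self._roles(labels)) == "18-17-6-AL"

    def test_single_hop_stromal_code(self):
        steps = [step("FCPI-2", "PsaL", 17.6, Leaflet.STROMAL)]
        assert pathway_code(steps, self._roles({"FCPI-2", "PsaL"})) == "2-LS"

    def test_empty_chain_is_error(self):
        from fcpinet import AnalysisError

        with pytest.raises(AnalysisError):
            pathway_code([], {})

    def test_terminal_without_core_letter(self):
        steps = [step("FCPI-2", "lipid", 17.6)]
        with pytest.raises(ConfigError):
            pathway_code(steps, self._roles({"FCPI-2", "lipid"}))


class TestPublishedStepTable:
    """The packaged edge-list encoding of the published step table."""

    CODES = {
        "18-17-6-AL", "18-7-JL", "19-8-BL", "20-8-BL", "21-9-10-BL", "11-BL",
        "1-IL", "2-IL", "13-3-IL", "24-15-4-AL", "21-9-8-RS", "11-BS", "2-LS",
        "12-3-AS", "13-4-AS", "14-4-AS", "22-15-5-AS", "16-6-AS",
    }

    def test_fixture_shape(self):
        steps = table2_fixture()
        assert len(steps) == 36  # printed step rows
        unique = {(s.donor_subunit, s.acceptor_subunit, s.donor_site,
                   s.acceptor_site, s.distance, s.leaflet) for s in steps}
        assert len(unique) == 34  # two hops are shared between pathways
        lumenal = [s for s in steps if s.leaflet is Leaflet.LUMENAL]
        assert len(lumenal) == 20

    def test_contains_published_examples(self):
        steps = table2_fixture()
        by_pair = {(s.donor_subunit, s.acceptor_subunit, s.leaflet): s
                   for s in steps}
        s = by_pair[("FCPI-9", "FCPI-10", Leaflet.LUMENAL)]
        assert s.distance == pytest.approx(9.5)
        s = by_pair[("FCPI-21", "FCPI-9", Leaflet.STROMAL)]
        assert s.distance == pytest.approx(9.8)
        assert (s.donor_site, s.acceptor_site) == (421, 401)
        s = by_pair[("FCPI-8", "PsaR", Leaflet.STROMAL)]
        assert s.distance == pytest.approx(11.0)

    def test_assembles_into_published_pathways(self):
        paths = assemble_pathways(table2_fixture())
        complete = [p for p in paths if p.complete]
        assert len(complete) == 18
        assert {p.code for p in complete} == self.CODES

    def test_long_step_flagged_inefficient(self):
        paths = assemble_pathways(table2_fixture())
        by_code = {p.code: p for p in paths}
        assert not by_code["11-BL"].steps[0].efficient  # 22.2 A > 20 A
        assert by_code["21-9-8-RS"].steps[-1].efficient  # 11.0 A

    def test_report_groups(self):
        report = pathway_report(assemble_pathways(table2_fixture()))
        assert report["code"].nunique() == 18
        row = report[(report.code == "11-BL")].iloc[0]
        assert row.distance_A == 22.2
        assert not row.efficient

    def test_edge_list_round_trip(self, tmp_path):
        steps = table2_fixture()
        out = tmp_path / "edges.tsv"
        write_edge_list(steps, out)
        again = read_edge_list(out)
        assert [(s.donor_subunit, s.acceptor_subunit, s.distance, s.leaflet)
                for s in steps] == \
            [(s.donor_subunit, s.acceptor_subunit, s.distance, s.leaflet)
             for s in again]


class TestRounding:
    @pytest.mark.parametrize("value, ndigits, expected", [
        (11.05, 1, 11.1),   # half rounds up, not to even
        (6.815, 2, 6.82),
        (1.94, 2, 1.94),
        (21.0, 1, 21.0),
        (1.4166, 1, 1.4),
    ])
    def test_half_up(self, value, ndigits, expected):
        assert round_half_up(value, ndigits) == expected
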