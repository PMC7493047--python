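"""c-SPK engine: oracle equivalence, conservation, symmetry, the four networks."""

from fractions import Fraction

import pytest

from lampspk.amplicons import (
    Amplicon,
    Category,
    Strand,
    classify,
    length_of,
    make_dumbbell,
    pds_highway_code,
    pds_linker_code,
    sl_code,
    ss_code,
)
from lampspk.brute import build_generation_matrix
from lampspk.cspk import (
    AmpliconCensus,
    CyclePacket,
    copies_curve,
    network_of,
    run_cspk,
    run_pds_linker,
    run_sl_pds_highway,
    run_ss_cycle,
    run_ssd_cycle,
)
from lampspk.rules import ContractViolation, KineticParams


def sense_seed(n0, exact=False):
    return [(ss_code(1, Strand.SENSE), Fraction(n0) if exact else float(n0))]


class TestOracleEquivalence:
    """The central correctness property: species-aggregated propagation must
    reproduce the exhaustive per-entry expansion exactly."""

    @pytest.mark.parametrize("t_R", [5.0, 12.0, 20.0, 28.0])
    def test_census_equals_brute_force_exactly(self, geometry, params, t_R):
        seeds = sense_seed(50, exact=True)
        brute = build_generation_matrix(50, t_R, params, geometry,
                                        seeds=seeds, exact=True)
        cspk = run_cspk(50, t_R, params, geometry, seeds=seeds, exact=True)
        assert brute.census == cspk.species

    def test_equivalence_holds_for_both_strand_seeding(self, reference):
        geometry, params, _ = reference
        seeds = [(ss_code(1, Strand.SENSE), Fraction(10)),
                 (ss_code(1, Strand.ANTISENSE), Fraction(10))]
        brute = build_generation_matrix(20, 25.0, params, geometry,
                                        seeds=seeds, exact=True)
        cspk = run_cspk(20, 25.0, params, geometry, seeds=seeds, exact=True)
        assert brute.census == cspk.species


class TestCensusProperties:
    def test_zero_time_census_is_just_the_seeds(self, geometry, params):
        census = run_cspk(20, 0.0, params, geometry)
        assert census.total_copies == pytest.approx(20.0)
        assert set(census.species) == {ss_code(1, Strand.SENSE),
                                       ss_code(1, Strand.ANTISENSE)}

    def test_total_copies_monotone_in_reaction_time(self, geometry, params):
        df = copies_curve(20, [0.0, 10.0, 20.0, 40.0, 80.0], params, geometry)
        totals = df["total_copies"].to_numpy()
        assert all(b >= a for a, b in zip(totals, totals[1:]))

    def test_strand_symmetry_of_the_census(self, geometry, params):
        sense = run_cspk(10, 30.0, params, geometry, seeds=sense_seed(10))
        anti = run_cspk(
            10, 30.0, params, geometry,
            seeds=[(ss_code(1, Strand.ANTISENSE), 10.0)],
        )
        mirrored = {code.complement(): copies for code, copies in anti.species.items()}
        assert mirrored == sense.species

    def test_determinism_bytes(self, geometry, params):
        a = run_cspk(20, 45.0, params, geometry).to_csv(geometry)
        b = run_cspk(20, 45.0, params, geometry).to_csv(geometry)
        assert a == b

    def test_one_displaced_ss_per_pds_event(self, geometry, params):
        audit = {}
        run_cspk(20, 60.0, params, geometry, audit=audit)
        assert audit["displaced_ss_copies"] == pytest.approx(audit["pds_event_copies"])

    def test_census_csv_roundtrip(self, geometry, params):
        census = run_cspk(20, 30.0, params, geometry)
        text = census.to_csv(geometry)
        back = AmpliconCensus.from_csv(text)
        assert set(back.species) == set(census.species)
        for code, copies in census.species.items():
            assert back.species[code] == pytest.approx(copies)


def packet(code, copies=1.0, t=0):
    return CyclePacket(code, copies, t)


class TestSsdCycle:
    def test_rejects_non_dumbbell_seed(self, geometry, params):
        sl = Amplicon(sl_code(1, Strand.SENSE),
                      length_of(sl_code(1, Strand.SENSE), geometry))
        with pytest.raises(ContractViolation):
            run_ssd_cycle(sl, 10.0, params, geometry)

    def test_no_emissions_before_one_self_extension(self, geometry, params):
        d = make_dumbbell(geometry)
        # the first event is the dumbbell's self-extension; a shorter horizon
        # leaves everything mid-event
        t_first = (geometry.loop_slack + params.init_self_nt) / params.v
        result = run_ssd_cycle(d, t_first * 0.5, params, geometry)
        assert result.to_highway == [] and result.terminated == []

    def test_first_two_highway_emissions_go_to_different_sisters(self, geometry, params):
        d = make_dumbbell(geometry)
        result = run_ssd_cycle(d, 60.0, params, geometry)
        assert len(result.to_highway) >= 2
        first, second = result.to_highway[0], result.to_highway[1]
        assert {first.origin, second.origin} == {"sister1", "sister2"}
        assert first.code.strand != second.code.strand

    def test_cycle_regenerates_complement_then_seed(self, geometry, params):
        d = make_dumbbell(geometry)
        result = run_ssd_cycle(d, 60.0, params, geometry)
        ss_stream = [p for p in result.internal
                     if classify(p.code) is Category.SS and p.time_nt > 0]
        assert ss_stream[0].code == d.code.complement()
        assert any(p.code == d.code for p in ss_stream[1:])


class TestSsCycle:
    def test_dumbbell_seed_delegates_to_the_ssd_cycle(self, geometry, params):
        d = make_dumbbell(geometry)
        a = run_ssd_cycle(d, 40.0, params, geometry)
        b = run_ss_cycle(d, 40.0, params, geometry)
        assert [(p.code, p.time_nt, p.copies) for p in a.internal] == [
            (p.code, p.time_nt, p.copies) for p in b.internal
        ]

    def test_regenerated_ss_matches_seed_length_and_period_two_closure(
        self, geometry, params
    ):
        code = ss_code(3, Strand.SENSE)
        seed = Amplicon(code, length_of(code, geometry))
        result = run_ss_cycle(seed, 120.0, params, geometry)
        regenerated = [p for p in result.internal
                       if classify(p.code) is Category.SS and p.time_nt > 0]
        assert regenerated, "cycle produced no regenerated SS"
        assert regenerated[0].code == code.complement()   # one period: complement
        assert any(p.code == code for p in regenerated[1:])  # two periods: the seed

    def test_regenerated_copies_follow_the_branch_product(self, geometry, params):
        code = ss_code(2, Strand.SENSE)
        seed = Amplicon(code, length_of(code, geometry), copies=1.0)
        result = run_ss_cycle(seed, 120.0, params, geometry)
        regenerated = [p for p in result.internal
                       if p.code == code.complement() and p.time_nt > 0]
        pol = params.branching
        expected = float(pol.pSS_I) * float(pol.pPDS_III)  # I-route x internal priming
        assert regenerated[0].copies == pytest.approx(expected)

    def test_rejects_non_ss_seed(self, geometry, params):
        sl = Amplicon(sl_code(2, Strand.SENSE),
                      length_of(sl_code(2, Strand.SENSE), geometry))
        with pytest.raises(ContractViolation):
            run_ss_cycle(sl, 10.0, params, geometry)


class TestHighway:
    def test_rejects_wrong_category_packet(self, geometry, params):
        with pytest.raises(ContractViolation):
            run_sl_pds_highway(packet(ss_code(2, Strand.SENSE)), 10.0, params, geometry)
        with pytest.raises(ContractViolation):
            run_sl_pds_highway(packet(pds_linker_code(3, 1, Strand.SENSE)),
                               10.0, params, geometry)

    def test_sl_lengths_strictly_increase_along_the_ladder(self, geometry, params):
        result = run_sl_pds_highway(packet(sl_code(2, Strand.SENSE)),
                                    60.0, params, geometry)
        sls = [p for p in result.internal if classify(p.code) is Category.SL]
        sizes = [p.code.size for p in sls]
        assert sizes == sorted(sizes)
        assert len(set(sizes)) == len(sizes)
        assert sizes[0] == 2

    def test_each_pds_reaction_displaces_exactly_one_ss(self, geometry, params):
        result = run_sl_pds_highway(packet(sl_code(2, Strand.SENSE)),
                                    60.0, params, geometry)
        pds_processed = [p for p in result.internal
                         if classify(p.code) is Category.PDS]
        displaced = result.to_ss_cycles
        total_pds = sum(p.copies for p in pds_processed)
        # a fraction of every PDS stays mid-event at the horizon
        frontier_pds = sum(v for c, v in result.frontier.items()
                           if classify(c) is Category.PDS)
        assert sum(p.copies for p in displaced) == pytest.approx(
            total_pds - frontier_pds
        )

    def test_time_gate_blocks_products_beyond_horizon(self, geometry, params):
        t_R = 30.0
        result = run_sl_pds_highway(packet(sl_code(2, Strand.SENSE)),
                                    t_R, params, geometry)
        horizon_nt = t_R * params.v
        for group in (result.internal, result.to_ss_cycles, result.to_linker,
                      result.terminated):
            for p in group:
                assert p.time_nt <= horizon_nt


class TestLinker:
    def test_rejects_non_linker_packet(self, geometry, params):
        with pytest.raises(ContractViolation):
            run_pds_linker(packet(pds_highway_code(3, Strand.SENSE)),
                           10.0, params, geometry)

    def test_emits_sl_to_highway_and_ss_to_a_new_cycle(self, geometry, params):
        result = run_pds_linker(packet(pds_linker_code(4, 1, Strand.SENSE)),
                                30.0, params, geometry)
        assert [p.code for p in result.to_highway] == [sl_code(4, Strand.SENSE)]
        assert [p.code for p in result.to_ss_cycles] == [
            ss_code(3, Strand.ANTISENSE)
        ]
        assert all(p.time_nt > 0 for p in result.to_highway)

    def test_linker_never_emits_a_deeper_cpds(self, geometry, params):
        result = run_pds_linker(packet(pds_linker_code(5, 1, Strand.SENSE)),
                                60.0, params, geometry)
        assert result.to_linker == []

    def test_emitted_ss_seeds_a_cycle_of_its_own_length(self, geometry, params):
        result = run_pds_linker(packet(pds_linker_code(4, 1, Strand.SENSE)),
                                30.0, params, geometry)
        (ss_packet,) = result.to_ss_cycles
        seed = Amplicon(ss_packet.code, length_of(ss_packet.code, geometry),
                        birth_time=ss_packet.time_nt / params.v,
                        copies=ss_packet.copies)
        cycle = run_ss_cycle(seed, 200.0, params, geometry)
        regen = [p for p in cycle.internal
                 if classify(p.code) is Category.SS and p.time_nt > ss_packet.time_nt]
        assert regen and all(p.code.size == ss_packet.code.size for p in regen)


class TestNetworkRouting:
    def test_species_route_to_their_owning_network(self):
        assert network_of(ss_code(1, Strand.SENSE)) == "ssd_cycle"
        assert network_of(ss_code(3, Strand.SENSE)) == "ss_cycle"
        assert network_of(sl_code(4, Strand.SENSE)) == "highway"
        assert network_of(pds_highway_code(4, Strand.SENSE)) == "highway"
        assert network_of(pds_linker_code(4, 1, Strand.SENSE)) == "linker"
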