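"""Cell behaviours: secretion, bystander, clearance, movement, division, death."""
import numpy as np
import pytest

from alveosim.agents import (
    BystanderParams,
    ClearanceParams,
    EpithelialHood,
    RateTable,
    apoptose,
    differentiate,
    enforce_min_separation,
    fibroblast_prolif_hazard,
    hazard_to_prob,
    mature_damaged,
    migrate_informed,
    migrate_random,
    phagocytose,
    proliferate,
    saturating,
    secrete,
    update_bystander,
)
from alveosim.population import CellType, Phenotype, Population, seed_cells

from conftest import make_fields


def tilt(theta, phi=0.0):
    """Unit vector at polar angle theta from +z, azimuth phi."""
    return np.array([np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)])


class TestHelpers:
    def test_hazard_to_prob(self):
        assert hazard_to_prob(0.0, 1.0) == 0.0
        assert hazard_to_prob(0.3, 1.0) == pytest.approx(1.0 - np.exp(-0.3))
        assert hazard_to_prob(1.0, 0.0) == 0.0

    def test_saturating_half_at_k(self):
        assert saturating(2.5e-8, 2.5e-8) == pytest.approx(0.5)
        assert saturating(0.0, 1e-8) == 0.0
        assert saturating(1e-2, 1e-8) == pytest.approx(1.0, abs=1e-5)


class TestSecretion:
    def test_fibroblast_ecm_shutoff_at_saturation(self, duct, rng):
        # [PAPER] no secretion above the saturation threshold
        pop = Population(duct)
        pop.add(CellType.FIBROBLAST, 0, np.array([0.0, 0.0, 1.0]))
        rt = RateTable()
        fields = make_fields()
        fields.fields["ECM"][...] = rt.ecm_sat
        before = fields.fields["ECM"].copy()
        secrete(pop, fields, rt, 1.0)
        assert np.array_equal(fields.fields["ECM"], before)

    def test_dt_zero_no_deposit(self, pop, fields):
        before = fields.data.copy()
        secrete(pop, fields, RateTable(), 0.0)
        assert np.array_equal(fields.data, before)

    def test_myofibroblast_half_rate_at_k(self, duct):
        # [DERIVED] h(K) = 1/2: deposit at [TGFb_active]=K is half the ceiling
        rt = RateTable()

        def deposit_at(conc):
            p = Population(duct)
            p.add(CellType.MYOFIBROBLAST, 0, np.array([0.0, 0.0, 1.0]))
            f = make_fields()
            f.fields["TGFb_active"][...] = conc
            before = f.total_mass("ECM")
            secrete(p, f, rt, 1.0)
            return f.total_mass("ECM") - before

        at_k = deposit_at(rt.k_half["TGFb_active"])
        at_inf = deposit_at(1.0)  # saturating concentration
        assert at_k == pytest.approx(0.5 * at_inf, rel=1e-6)

    def test_fgf2_only_from_senescent(self, pop, fields):
        # [PAPER] FGF2 present only in the presence of senescent AEC2
        secrete(pop, fields, RateTable(), 1.0)
        assert fields.total_mass("FGF2") == 0.0
        rows = pop.rows(CellType.AEC2)[:5]
        pop.phenotype[rows] = int(Phenotype.SENESCENT)
        fields.fields["TGFb_active"][...] = 1.0e-8
        secrete(pop, fields, RateTable(), 1.0)
        assert fields.total_mass("FGF2") > 0.0

    def test_healthy_epithelium_secretes_nothing(self, duct, rng):
        pop = Population(duct)
        pop.add(CellType.AEC1, 0, np.array([0.0, 0.0, 1.0]))
        pop.add(CellType.AEC2, 0, np.array([0.0, 1.0, 0.0]))
        fields = make_fields()
        before = fields.data.copy()
        secrete(pop, fields, RateTable(), 1.0)
        assert np.array_equal(fields.data, before)


class TestBystander:
    def make_cluster(self, duct, n_healthy, n_senescent, tau=0.0):
        """Healthy AEC2 packed around +z with senescent cells at the pole."""
        rng = np.random.default_rng(7)
        pop = Population(duct, capacity=n_healthy + n_senescent + 8)
        if n_senescent:
            pop.add(
                CellType.AEC2, 0, np.tile([0.0, 0.0, 1.0], (n_senescent, 1)),
                phenotype=Phenotype.SENESCENT,
            )
        # chord 60 um on a 125 um sphere subtends ~0.48 rad; stay well inside
        theta = rng.uniform(0.0, 0.2, n_healthy)
        phi = rng.uniform(0.0, 2 * np.pi, n_healthy)
        units = np.stack([tilt(t, p) for t, p in zip(theta, phi)])
        rows = pop.add(CellType.AEC2, 0, units)
        pop.tau[rows] = tau
        return pop, rows

    def test_below_threshold_tau_stays_zero_no_transition(self, duct):
        # [PAPER] at least 2 senescent cells needed
        pop, rows = self.make_cluster(duct, 50, n_senescent=1)
        n = update_bystander(pop, BystanderParams(threshold=2), np.random.default_rng(0), 1.0)
        assert n == 0
        assert np.all(pop.tau[rows] == 0.0)
        assert np.all(pop.phenotype[rows] == int(Phenotype.HEALTHY))

    def test_tau_zero_probability_exactly_zero(self, duct):
        # tau=0 after the update -> p = 1 - e^0 = 0 regardless of k
        pop, rows = self.make_cluster(duct, 200, n_senescent=0)
        n = update_bystander(
            pop, BystanderParams(k=10.0), np.random.default_rng(0), 1.0
        )
        assert n == 0

    def test_eq5_empirical_frequency(self, duct):
        # [DERIVED] k=0.1, tau(after update)=3 -> p = 1-e^{-0.3} ~ 0.2592,
        # checked against a binomial 3-sigma band over 1e5 cells
        n_cells = 100_000
        pop, rows = self.make_cluster(duct, n_cells, n_senescent=2, tau=2.0)
        params = BystanderParams(threshold=2, k=0.1)
        hits = update_bystander(pop, params, np.random.default_rng(11), 1.0)
        p = 1.0 - np.exp(-0.3)
        sigma = np.sqrt(n_cells * p * (1.0 - p))
        assert abs(hits - n_cells * p) < 3.0 * sigma

    def test_tau_ratchets_up_and_down(self, duct):
        pop, rows = self.make_cluster(duct, 10, n_senescent=2)
        params = BystanderParams(threshold=2, k=0.0)  # no transitions, pure tau
        rng = np.random.default_rng(0)
        update_bystander(pop, params, rng, 1.0)
        assert np.all(pop.tau[rows] == 1.0)
        update_bystander(pop, params, rng, 1.0)
        assert np.all(pop.tau[rows] == 2.0)
        pop.remove(pop.rows(CellType.AEC2, Phenotype.SENESCENT))
        rows = pop.rows(CellType.AEC2, Phenotype.HEALTHY)
        update_bystander(pop, params, rng, 1.0)
        assert np.all(pop.tau[rows] == 1.0)  # decays, floored at 0
        update_bystander(pop, params, rng, 1.0)
        update_bystander(pop, params, rng, 1.0)
        assert np.all(pop.tau[rows] == 0.0)

    def test_cross_alveolus_sensing(self, duct):
        # senescent cells just across the tangency point still count
        pop = Population(duct)
        c0, c1 = duct.centers[0], duct.centers[1]
        u01 = (c1 - c0) / np.linalg.norm(c1 - c0)
        pop.add(CellType.AEC2, 1, np.tile(-u01, (2, 1)), phenotype=Phenotype.SENESCENT)
        rows = pop.add(CellType.AEC2, 0, u01)
        update_bystander(pop, BystanderParams(k=0.0), np.random.default_rng(0), 1.0)
        assert pop.tau[rows[0]] == 1.0

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            BystanderParams(threshold=0)
        with pytest.raises(ValueError):
            BystanderParams(k=-1.0)


class TestMaturation:
    def test_senescent_after_exactly_24_evaluations(self, duct):
        pop = Population(duct)
        rows = pop.add(CellType.AEC2, 0, np.array([0.0, 0.0, 1.0]),
                       phenotype=Phenotype.DAMAGED)
        pop.damaged_timer[rows] = 24.0
        for step in range(24):
            assert pop.phenotype[rows[0]] == int(Phenotype.DAMAGED)
            mature_damaged(pop, 1.0)
        assert pop.phenotype[rows[0]] == int(Phenotype.SENESCENT)

    def test_timer_draw_uniform_mean(self):
        # [DERIVED] U[min,max]: empirical mean within 3 sigma of (min+max)/2
        from alveosim.agents import draw_damaged_timer

        params = BystanderParams(damaged_min_h=12.0, damaged_max_h=72.0)
        draws = draw_damaged_timer(params, np.random.default_rng(3), 10_000)
        assert draws.min() >= 12.0 and draws.max() <= 72.0
        sigma = (72.0 - 12.0) / np.sqrt(12.0) / np.sqrt(10_000)
        assert abs(draws.mean() - 42.0) < 3.0 * sigma

    def test_senescent_untouched(self, duct):
        pop = Population(duct)
        rows = pop.add(CellType.AEC2, 0, np.array([0.0, 0.0, 1.0]),
                       phenotype=Phenotype.SENESCENT)
        mature_damaged(pop, 100.0)
        assert pop.phenotype[rows[0]] == int(Phenotype.SENESCENT)
        assert pop.damaged_timer[rows[0]] == 0.0


class TestPhagocytosis:
    def setup_mac_and_senescent(self, duct, sen_units, mac_alv=0, sen_alv=0):
        pop = Population(duct)
        mac = pop.add(CellType.M1, mac_alv, np.array([0.0, 0.0, 1.0]),
                      phag_index=2, phag_capable=True)
        sen = pop.add(CellType.AEC2, sen_alv, np.atleast_2d(sen_units),
                      phenotype=Phenotype.SENESCENT)
        return pop, mac, sen

    def test_contact_removal_same_alveolus(self, duct):
        # mac on luminal shell (115 um) directly under a senescent cell (125 um):
        # separation 10 um < contact reach 1.1 * (10 + 15) = 27.5 um
        pop, mac, sen = self.setup_mac_and_senescent(duct, [0.0, 0.0, 1.0])
        removed = phagocytose(pop, ClearanceParams(), np.random.default_rng(0))
        assert list(removed) == [sen[0]]
        assert pop.eaten[mac[0]] == 1

    def test_other_alveolus_never_removed(self, duct):
        # [PAPER] phagocytosis acts within the same alveolus only
        c0, c1 = duct.centers[0], duct.centers[1]
        u01 = (c1 - c0) / np.linalg.norm(c1 - c0)
        pop = Population(duct)
        pop.add(CellType.M1, 0, u01, phag_index=2, phag_capable=True)
        pop.add(CellType.AEC2, 1, -u01, phenotype=Phenotype.SENESCENT)
        removed = phagocytose(pop, ClearanceParams(), np.random.default_rng(0))
        assert removed.size == 0

    def test_at_capacity_no_removal_and_frozen(self, duct):
        # [PAPER] macrophages over their phagocytic capacity stop eating & moving
        pop, mac, sen = self.setup_mac_and_senescent(duct, [0.0, 0.0, 1.0])
        pop.eaten[mac] = pop.phag_index[mac]
        removed = phagocytose(pop, ClearanceParams(), np.random.default_rng(0))
        assert removed.size == 0
        before = pop.positions(mac).copy()
        migrate_random(pop, RateTable(), np.random.default_rng(0), 1.0)
        assert np.array_equal(pop.positions(mac), before)

    def test_nearest_of_two_candidates(self, duct):
        # [DERIVED] both in contact: exactly one removed, the nearer
        pop, mac, sen = self.setup_mac_and_senescent(
            duct, [tilt(0.1), [0.0, 0.0, 1.0]]
        )
        removed = phagocytose(pop, ClearanceParams(), np.random.default_rng(0))
        assert list(removed) == [sen[1]]  # directly overhead, 10 um away

    def test_tie_broken_by_lower_uid(self, duct):
        pop, mac, sen = self.setup_mac_and_senescent(
            duct, [[0.0, 0.0, 1.0], [0.0, 0.0, 1.0]]
        )
        removed = phagocytose(pop, ClearanceParams(), np.random.default_rng(0))
        assert list(removed) == [sen[0]]

    def test_incapable_macrophage_never_eats(self, duct):
        pop = Population(duct)
        pop.add(CellType.M1, 0, np.array([0.0, 0.0, 1.0]), phag_index=2,
                phag_capable=False)
        pop.add(CellType.AEC2, 0, np.array([0.0, 0.0, 1.0]),
                phenotype=Phenotype.SENESCENT)
        removed = phagocytose(pop, ClearanceParams(), np.random.default_rng(0))
        assert removed.size == 0

    def test_one_engulfment_per_macrophage_per_evaluation(self, duct):
        pop, mac, sen = self.setup_mac_and_senescent(
            duct, [[0.0, 0.0, 1.0], tilt(0.05), tilt(0.1)]
        )
        removed = phagocytose(pop, ClearanceParams(), np.random.default_rng(0))
        assert removed.size == 1

    def test_eaten_counters_match_removals(self, duct, rng):
        # conservation: sum of eaten increments == number of removed rows
        pop = seed_cells(duct, rng=rng)
        rows = pop.rows(CellType.AEC2)
        sen = rng.choice(rows, size=300, replace=False)
        pop.phenotype[sen] = int(Phenotype.SENESCENT)
        eaten_before = pop.eaten[: pop.n].sum()
        removed = phagocytose(pop, ClearanceParams(), rng)
        assert pop.eaten[: pop.n].sum() - eaten_before == removed.size
        assert np.all(pop.phenotype[removed] == int(Phenotype.SENESCENT))


class TestRandomMigration:
    def test_speed_zero_no_motion(self, pop):
        rt = RateTable(mac_speed=0.0, mes_speed=0.0)
        before = pop.positions().copy()
        migrate_random(pop, rt, np.random.default_rng(0), 1.0)
        assert np.array_equal(pop.positions(), before)

    def test_stays_on_shell(self, pop, rng):
        migrate_random(pop, RateTable(), rng, 1.0)
        assert np.allclose(np.linalg.norm(pop.unit[: pop.n], axis=1), 1.0, atol=1e-9)

    def test_arc_length_matches_speed(self, duct):
        pop = Population(duct)
        rows = pop.add(CellType.M1, 0, np.array([0.0, 0.0, 1.0]), phag_index=2)
        rt = RateTable(mac_speed=20.0)
        u0 = pop.unit[rows[0]].copy()
        migrate_random(pop, rt, np.random.default_rng(0), 1.0)
        angle = np.arccos(np.clip(np.dot(u0, pop.unit[rows[0]]), -1, 1))
        shell_r = pop.shell_r[rows[0]]
        assert angle * shell_r == pytest.approx(20.0, rel=1e-9)

    def test_isotropy(self, duct):
        # [DERIVED] each tangent half-plane chosen ~50% (binomial 3 sigma)
        from alveosim.agents import _tangent_basis

        pop = Population(duct)
        rows = pop.add(CellType.M1, 0, np.array([0.0, 0.0, 1.0]), phag_index=2)
        rt = RateTable(mac_speed=5.0)
        rng = np.random.default_rng(21)
        east = 0
        n = 10_000
        for _ in range(n):
            u = pop.unit[rows].copy()
            e1, _ = _tangent_basis(u)
            p0 = pop.positions(rows).copy()
            migrate_random(pop, rt, rng, 1.0)
            east += int(np.dot(pop.positions(rows)[0] - p0[0], e1[0]) > 0)
        assert abs(east - n / 2) < 3.0 * np.sqrt(n * 0.25)

    def test_damaged_jitter_small_and_on_shell(self, duct):
        pop = Population(duct)
        rows = pop.add(CellType.AEC2, 0, tilt(1.0), phenotype=Phenotype.DAMAGED)
        rt = RateTable()
        u0 = pop.unit[rows[0]].copy()
        migrate_random(pop, rt, np.random.default_rng(0), 1.0)
        angle = np.arccos(np.clip(np.dot(u0, pop.unit[rows[0]]), -1, 1))
        assert angle <= 2 * rt.damaged_jitter_rad + 1e-9
        assert np.linalg.norm(pop.unit[rows[0]]) == pytest.approx(1.0)


class TestInformedMigration:
    def test_no_neighbours_no_motion(self, duct):
        pop = Population(duct)
        rows = pop.add(CellType.AEC1, 0, np.array([0.0, 0.0, 1.0]))
        before = pop.positions(rows).copy()
        migrate_informed(pop, RateTable(), 1.0)
        assert np.array_equal(pop.positions(rows), before)

    def test_single_east_neighbour_pushes_west(self, duct):
        # [DERIVED] one neighbour due east -> geodesic step due west
        pop = Population(duct)
        actor = pop.add(CellType.AEC1, 0, np.array([0.0, 0.0, 1.0]))
        pop.add(CellType.AEC1, 0, tilt(0.3))  # east = +x direction
        x0 = pop.unit[actor[0]][0]
        migrate_informed(pop, RateTable(), 1.0)
        assert pop.unit[actor[0]][0] < x0  # moved in -x
        assert abs(pop.unit[actor[0]][1]) < 1e-12  # no sideways drift

    def test_symmetric_neighbours_cancel(self, duct):
        # [TRIVIAL] four neighbours at symmetric compass points -> no move
        pop = Population(duct)
        actor = pop.add(CellType.AEC1, 0, np.array([0.0, 0.0, 1.0]))
        for phi in (0.0, np.pi / 2, np.pi, 3 * np.pi / 2):
            pop.add(CellType.AEC1, 0, tilt(0.3, phi))
        before = pop.unit[actor[0]].copy()
        migrate_informed(pop, RateTable(), 1.0)
        assert np.allclose(pop.unit[actor[0]], before, atol=1e-9)

    def test_healthy_aec2_sense_all_epithelium(self, duct):
        pop = Population(duct)
        actor = pop.add(CellType.AEC2, 0, np.array([0.0, 0.0, 1.0]))
        pop.add(CellType.AEC2, 0, tilt(0.3), phenotype=Phenotype.SENESCENT)
        x0 = pop.unit[actor[0]][0]
        migrate_informed(pop, RateTable(), 1.0)
        assert pop.unit[actor[0]][0] < x0

    def test_aec1_ignore_aec2(self, duct):
        pop = Population(duct)
        actor = pop.add(CellType.AEC1, 0, np.array([0.0, 0.0, 1.0]))
        pop.add(CellType.AEC2, 0, tilt(0.3))
        before = pop.unit[actor[0]].copy()
        migrate_informed(pop, RateTable(), 1.0)
        assert np.array_equal(pop.unit[actor[0]], before)


class TestEpithelialHood:
    def test_kernel_equals_numpy_fallback(self, pop):
        # [DERIVED] compiled kernel vs independent numpy tensor path
        fast = EpithelialHood(pop, use_numba=True)
        slow = EpithelialHood(pop, use_numba=False)
        assert np.array_equal(fast.aec1_count, slow.aec1_count)
        assert np.allclose(fast.disp, slow.disp, atol=1e-9)

    def test_local_counts_match_brute_force(self, pop):
        from alveosim.agents import local_aec1_counts

        hood = EpithelialHood(pop)
        reach = pop.duct.alveolus_radius
        pos = pop.positions()
        aec1 = pop.mask(CellType.AEC1)
        rows = pop.rows(CellType.AEC2)[:40]
        got = local_aec1_counts(pop, rows, hood)
        for r, g in zip(rows, got):
            d = np.linalg.norm(pos - pos[r], axis=1)
            same = pop.alveolus[: pop.n] == pop.alveolus[r]
            want = np.count_nonzero(aec1 & same & (d <= reach)) - (
                1 if aec1[r] else 0
            )
            assert g == want


class TestSeparation:
    def test_stacked_agents_pushed_apart(self, duct, rng):
        pop = Population(duct)
        pop.add(CellType.AEC2, 0, np.tile([0.0, 0.0, 1.0], (5, 1)))
        enforce_min_separation(pop, rng, passes=30)
        pos = pop.positions()
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
        d[np.diag_indices(5)] = np.inf
        assert d.min() >= 0.5 * (15.0 + 15.0) - 1e-6
        assert np.allclose(np.linalg.norm(pop.unit[:5], axis=1), 1.0)

    def test_different_shells_do_not_interact(self, duct, rng):
        pop = Population(duct)
        pop.add(CellType.AEC2, 0, np.array([0.0, 0.0, 1.0]))
        pop.add(CellType.M1, 0, np.array([0.0, 0.0, 1.0]), phag_index=2)
        before = pop.unit[:2].copy()
        enforce_min_separation(pop, rng)
        assert np.array_equal(pop.unit[:2], before)


class TestProliferation:
    def base_pop(self, duct, n_aec1):
        counts = {CellType.AEC1: n_aec1, CellType.AEC2: 69, CellType.M1: 0,
                  CellType.M2: 0, CellType.FIBROBLAST: 0, CellType.MYOFIBROBLAST: 0}
        return seed_cells(duct, counts, np.random.default_rng(5))

    def test_aec2_boost_when_aec1_depleted(self, duct):
        # [PAPER] doubling of the division rate under AEC1 shortage; with
        # zero AEC1 everywhere every cell is below the 80% threshold
        rt = RateTable()
        fields = make_fields()
        dt = 100.0
        n = 18 * 69
        pop = self.base_pop(duct, 0)
        born = proliferate(pop, fields, rt, np.random.default_rng(1), dt)
        p2 = 1.0 - np.exp(-2.0 * rt.aec2_proliferation * dt)
        assert abs(born - n * p2) < 3.0 * np.sqrt(n * p2 * (1 - p2))

    def test_aec2_base_rate_when_aec1_plentiful(self, duct):
        # with 120 AEC1/alveolus the local count never drops below threshold
        rt = RateTable()
        fields = make_fields()
        dt = 100.0
        n = 18 * 69
        pop = self.base_pop(duct, 120)
        born = proliferate(pop, fields, rt, np.random.default_rng(1), dt)
        p1 = 1.0 - np.exp(-rt.aec2_proliferation * dt)
        assert abs(born - n * p1) < 3.0 * np.sqrt(n * p1 * (1 - p1))

    def test_fibroblast_hazard_monotone_in_concentrations(self):
        # [DERIVED] monotonicity on a 3^3 grid of concentration triples
        rt = RateTable()
        levels = (0.0, 1.0e-8, 1.0e-6)
        vals = np.array([
            [[fibroblast_prolif_hazard(rt, a, b, c) for c in levels]
             for b in levels] for a in levels
        ])
        assert np.all(np.diff(vals, axis=0) >= 0)
        assert np.all(np.diff(vals, axis=1) >= 0)
        assert np.all(np.diff(vals, axis=2) >= 0)
        assert vals[0, 0, 0] == pytest.approx(rt.f_prolif_base)

    def test_daughter_placement(self, duct):
        rt = RateTable(aec2_proliferation=1.0e9)  # force division
        fields = make_fields()
        pop = Population(duct)
        parent = pop.add(CellType.AEC2, 0, np.array([0.0, 0.0, 1.0]))
        born = proliferate(pop, fields, rt, np.random.default_rng(0), 1.0)
        assert born == 1 and pop.n == 2
        d = np.linalg.norm(np.diff(pop.positions(), axis=0))
        # one diameter along the surface: chord slightly below arc 2*radius
        assert 0.8 * 2 * 15.0 <= d <= 2 * 15.0 + 1e-9
        assert pop.shell_r[1] == pop.shell_r[0]
        assert pop.alveolus[1] == pop.alveolus[0]


class TestDifferentiation:
    def test_m2_to_m1_zero_without_tnfa(self, duct):
        # [DERIVED] reverse polarisation is purely TNFa-driven (no base term)
        pop = Population(duct)
        pop.add(CellType.M2, 0, np.tile([0.0, 0.0, 1.0], (50, 1)), phag_index=2)
        fields = make_fields()
        fields.fields["TNFa"][...] = 0.0
        tally = differentiate(pop, fields, RateTable(m2_to_m1_coeff=100.0),
                              np.random.default_rng(0), 100.0)
        assert tally["m2_to_m1"] == 0

    def test_dt_zero_no_transitions(self, pop, fields):
        tally = differentiate(pop, fields, RateTable(), np.random.default_rng(0), 0.0)
        assert all(v == 0 for v in tally.values())

    def test_transitions_change_types(self, duct, fields):
        pop = Population(duct)
        pop.add(CellType.M1, 0, np.tile([0.0, 0.0, 1.0], (20, 1)), phag_index=2)
        tally = differentiate(pop, fields, RateTable(m1_to_m2=1.0e9),
                              np.random.default_rng(0), 1.0)
        assert tally["m1_to_m2"] == 20
        assert pop.rows(CellType.M2).size == 20

    def test_aec2_to_aec1_resets_tau_and_moves_shell(self, duct, fields):
        pop = Population(duct)
        rows = pop.add(CellType.AEC2, 0, np.array([0.0, 0.0, 1.0]))
        pop.tau[rows] = 5.0
        differentiate(pop, fields, RateTable(aec2_to_aec1=1.0e9),
                      np.random.default_rng(0), 1.0)
        assert pop.ctype[rows[0]] == int(CellType.AEC1)
        assert pop.tau[rows[0]] == 0.0


class TestApoptosis:
    def test_senescent_and_damaged_never_die(self, duct):
        # [PAPER] phenotypic resistance to apoptosis
        pop = Population(duct)
        pop.add(CellType.AEC2, 0, np.tile([0.0, 0.0, 1.0], (30, 1)),
                phenotype=Phenotype.SENESCENT)
        pop.add(CellType.AEC2, 0, np.tile([0.0, 1.0, 0.0], (30, 1)),
                phenotype=Phenotype.DAMAGED)
        rt = RateTable(aec2_apoptosis=1.0e9)
        doomed = apoptose(pop, rt, np.random.default_rng(0), 1.0)
        assert doomed.size == 0

    def test_exponential_decay_oracle(self, duct):
        # [DERIVED] 1000 AEC1 at hazard lambda: survivors ~ 1000 e^{-lambda t}
        lam, t = 0.01, 100.0
        rt = RateTable(aec1_apoptosis=lam)
        pop = Population(duct, capacity=1100)
        units = np.random.default_rng(0).standard_normal((1000, 3))
        units /= np.linalg.norm(units, axis=1, keepdims=True)
        pop.add(CellType.AEC1, 0, units)
        rng = np.random.default_rng(42)
        for _ in range(int(t)):
            pop.remove(apoptose(pop, rt, rng, 1.0))
        expect = 1000 * np.exp(-lam * t)
        sigma = np.sqrt(1000 * np.exp(-lam * t) * (1 - np.exp(-lam * t)))
        assert abs(pop.n - expect) < 3.0 * sigma

    def test_crowding_doubles_aec2_hazard(self, duct):
        # [PAPER] 20% AEC1 excess doubles AEC2 apoptosis; 200 AEC1/alveolus
        # puts every local count far above the 120% threshold
        counts = {CellType.AEC1: 200, CellType.AEC2: 69, CellType.M1: 0,
                  CellType.M2: 0, CellType.FIBROBLAST: 0,
                  CellType.MYOFIBROBLAST: 0}
        pop = seed_cells(duct, counts, np.random.default_rng(5))
        rt = RateTable(aec1_apoptosis=0.0)
        dt = 100.0
        doomed = apoptose(pop, rt, np.random.default_rng(1), dt)
        n = 18 * 69
        p2 = 1.0 - np.exp(-2.0 * rt.aec2_apoptosis * dt)
        assert abs(doomed.size - n * p2) < 3.0 * np.sqrt(n * p2 * (1 - p2))
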