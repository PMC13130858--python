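"""FEP accumulation, umbrella binning, aggregation and filtering."""

import numpy as np
import pytest

from evbtherm import CouplingModel
from evbtherm.evb_core import EVBModel
from evbtherm.fep_us import (
    FreeEnergyProfile,
    LambdaSchedule,
    NoBarrierError,
    WindowSamples,
    aggregate_replicates,
    coverage_filter,
    fep_accumulate,
    locate_stationary_points,
    umbrella_bin,
    windows_from_replicate,
)
from evbtherm.thermo import R_KCAL
from evbtherm.toy_system import Harmonic, ToySystemSpec, simulate_replicate
from tests.conftest import STANDARD_TEMPERATURE

T = 300.0
RT = R_KCAL * T
NOCOUPLE = EVBModel(delta_alpha=0.0, coupling=CouplingModel("constant", 0.0))


def make_window(lam, u1, u2, uss=None, model=NOCOUPLE):
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    z = np.zeros_like(u1)
    return WindowSamples(
        lam=lam,
        u1_rr=u1,
        u1_rs=z.copy(),
        u2_rr=u2,
        u2_rs=z.copy(),
        u_ss=z.copy() if uss is None else np.asarray(uss, dtype=float),
        model=model,
    )


class TestLambdaSchedule:
    def test_linear_schedule_endpoints(self):
        s = LambdaSchedule.linear(21)
        assert len(s) == 21 and s.values[0] == 0.0 and s.values[-1] == 1.0

    @pytest.mark.parametrize("values", [(0.0, 0.5), (0.1, 0.5, 1.0), (0.0, 0.5, 0.5, 1.0)])
    def test_invalid_schedules_rejected(self, values):
        with pytest.raises(ValueError):
            LambdaSchedule(values=values)


class TestFepAccumulate:
    def test_identical_diabats_give_zero_everywhere(self):
        u = np.array([1.0, -2.0, 5.0])
        wins = [make_window(l, u, u) for l in (0.0, 0.5, 1.0)]
        assert np.allclose(fep_accumulate(wins, T), 0.0)

    def test_zero_umap_differences_give_zero_increment(self):
        wins = [make_window(0.0, [3.0, 3.0], [3.0, 3.0]), make_window(1.0, [1.0], [1.0])]
        dg = fep_accumulate(wins, T)
        assert dg[1] == 0.0

    def test_harmonic_toy_reaches_analytic_free_energy_difference(self):
        """ΔG(1)−ΔG(0) for two harmonic diabats equals
        RT/2·ln(k2/k1) + Δα (closed-form partition functions)."""
        spec = ToySystemSpec(
            diabat1=Harmonic(k=100.0, r0=0.0),
            diabat2=Harmonic(k=150.0, r0=0.8),
            delta_alpha=2.0,
            coupling=CouplingModel("constant", 0.0),
            n_bath=0,
            bath_k=(),
            g1=0.0,
            g2=0.0,
        )
        exact = 0.5 * RT * np.log(150.0 / 100.0) + 2.0
        lams = LambdaSchedule.linear(21).values
        ends = []
        for rep in range(5):
            data = simulate_replicate(spec, lams, T, 15000, 2000, seed=500 + rep)
            wins = windows_from_replicate(data, spec.evb_model(), equil_fraction=0.1)
            ends.append(fep_accumulate(wins, T)[-1])
        ends = np.array(ends)
        sem = ends.std(ddof=1) / np.sqrt(len(ends))
        assert abs(ends.mean() - exact) < 3 * sem + 0.01

    def test_requires_ordered_nonempty_windows(self):
        w0, w1 = make_window(0.0, [1.0], [2.0]), make_window(1.0, [1.0], [2.0])
        with pytest.raises(ValueError):
            fep_accumulate([w1, w0], T)
        with pytest.raises(ValueError):
            fep_accumulate([w0], T)


class TestUmbrellaBin:
    def test_ground_state_equals_mapping_gives_histogram_free_energy(self):
        """With Eg ≡ Umap the umbrella factor is 1 and the profile is the
        window's own −RT·ln P(Xk) up to its reference."""
        rng = np.random.default_rng(1)
        u1 = -np.abs(rng.normal(5.0, 2.0, size=4000))  # X = u1 < 0, so Eg = Umap at λ=0
        win = make_window(0.0, u1, np.zeros_like(u1))
        edges = np.linspace(-12.0, 0.0, 9)
        prof = umbrella_bin([win], np.zeros(1), T, edges, min_count=1)
        counts, _ = np.histogram(win.x(), edges)
        ref = -RT * np.log(counts / counts.sum())
        ref -= ref.min()
        pop = counts > 0
        assert np.allclose(prof.dg[pop], ref[pop], atol=1e-9)

    def test_duplicating_samples_leaves_profile_unchanged(self, toy_windows):
        wins = toy_windows[0]
        dg_lam = fep_accumulate(wins, STANDARD_TEMPERATURE)
        edges = np.linspace(-80.0, 70.0, 41)
        p1 = umbrella_bin(wins, dg_lam, STANDARD_TEMPERATURE, edges)
        doubled = [
            WindowSamples(
                lam=w.lam,
                u1_rr=np.tile(w.u1_rr, 2),
                u1_rs=np.tile(w.u1_rs, 2),
                u2_rr=np.tile(w.u2_rr, 2),
                u2_rs=np.tile(w.u2_rs, 2),
                u_ss=np.tile(w.u_ss, 2),
                model=w.model,
            )
            for w in wins
        ]
        p2 = umbrella_bin(doubled, fep_accumulate(doubled, STANDARD_TEMPERATURE), STANDARD_TEMPERATURE, edges)
        pop = p1.populated
        assert np.allclose(p1.dg[pop], p2.dg[pop], atol=1e-9)

    def test_too_few_populated_bins_rejected(self):
        win = make_window(0.0, [-1.0] * 20, [0.0] * 20)
        with pytest.raises(ValueError, match="populated"):
            umbrella_bin([win], np.zeros(1), T, np.linspace(-2, 0, 10))


class TestAggregate:
    def _profile(self, dg, counts=100):
        dg = np.asarray(dg, dtype=float)
        return FreeEnergyProfile(
            bin_edges=np.arange(len(dg) + 1, dtype=float),
            dg=dg,
            counts=np.full(len(dg), counts, dtype=np.int64),
            low_count=np.zeros(len(dg), dtype=bool),
        )

    def test_identical_replicates_have_zero_sem(self):
        p = self._profile([0.0, 1.0, 2.0])
        agg = aggregate_replicates([p, p, p])
        assert np.allclose(agg.sem, 0.0)
        assert np.allclose(agg.dg, p.dg)

    def test_two_replicates_differing_in_one_bin(self):
        delta = 0.8
        a = self._profile([0.0, 1.0, 2.0])
        b = self._profile([0.0, 1.0 + delta, 2.0])
        agg = aggregate_replicates([a, b])
        assert agg.dg[1] == pytest.approx(1.0 + delta / 2)
        assert agg.sem[1] == pytest.approx(delta / 2)

    def test_sem_scales_inverse_sqrt_replicates(self, rng):
        base = np.array([0.0, 1.0, 2.0, 1.0])
        sigma = 0.2

        def sem_with(n):
            profs = [self._profile(base + rng.normal(0, sigma, base.size)) for _ in range(n)]
            return np.mean(aggregate_replicates(profs).sem)

        s16, s256 = sem_with(16), sem_with(256)
        assert s16 / s256 == pytest.approx(4.0, rel=0.35)

    def test_mismatched_bins_rejected(self):
        a = self._profile([0.0, 1.0, 2.0])
        b = FreeEnergyProfile(
            bin_edges=np.arange(4, dtype=float) * 2,
            dg=a.dg.copy(),
            counts=a.counts.copy(),
            low_count=a.low_count.copy(),
        )
        with pytest.raises(ValueError, match="mismatch"):
            aggregate_replicates([a, b])


class TestStationaryPoints:
    def _profile(self, dg, centers=None):
        dg = np.asarray(dg, dtype=float)
        if centers is None:
            edges = np.linspace(-2.5, 2.5, len(dg) + 1)
        else:
            half = (centers[1] - centers[0]) / 2
            edges = np.concatenate([[centers[0] - half], np.asarray(centers) + half])
        return FreeEnergyProfile(
            bin_edges=edges,
            dg=dg,
            counts=np.full(len(dg), 100, dtype=np.int64),
            low_count=np.zeros(len(dg), dtype=bool),
        )

    def test_enumerated_five_bin_profile(self):
        gact = locate_stationary_points(self._profile([3.0, 1.0, 4.0, 0.0, 2.0]))
        assert (gact.rs_idx, gact.ts_idx, gact.ps_idx) == (1, 2, 3)
        assert gact.dg_act == pytest.approx(3.0)
        assert gact.dg0 == pytest.approx(-1.0)

    def test_monotone_profile_raises_no_barrier(self):
        with pytest.raises(NoBarrierError):
            locate_stationary_points(self._profile([4.0, 3.0, 2.0, 1.0, 0.0]))

    def test_one_sided_profile_raises(self):
        prof = self._profile([0.0, 1.0, 0.5], centers=np.array([1.0, 2.0, 3.0]))
        with pytest.raises(NoBarrierError):
            locate_stationary_points(prof)

    def test_symmetric_double_well_barrier_equal_from_both_sides(self):
        dg = np.array([5.0, 0.0, 2.0, 6.0, 2.0, 0.0, 5.0])
        gact = locate_stationary_points(self._profile(dg))
        assert gact.dg0 == pytest.approx(0.0)
        assert gact.dg_act == pytest.approx(6.0)

    def test_smoothing_used_for_locating_not_reporting(self):
        # a noisy spike next to the true barrier: smoothing picks the broad
        # maximum, but the reported value is the raw bin value
        dg = np.array([2.0, 0.0, 3.0, 3.2, 3.1, 1.0, 0.5, 2.0])
        raw = locate_stationary_points(self._profile(dg))
        sm = locate_stationary_points(self._profile(dg), smooth_window=3)
        assert raw.dg_act == pytest.approx(dg[raw.ts_idx] - dg[raw.rs_idx])
        assert sm.dg_act == pytest.approx(dg[sm.ts_idx] - dg[sm.rs_idx])


class TestCoverageFilter:
    def _gact(self):
        prof = FreeEnergyProfile(
            bin_edges=np.linspace(-5.0, 5.0, 11),
            dg=np.array([3.0, 1.0, 0.0, 1.0, 2.0, 4.0, 2.0, 1.0, 0.5, 2.0]),
            counts=np.full(10, 50, dtype=np.int64),
            low_count=np.zeros(10, dtype=bool),
        )
        return locate_stationary_points(prof)

    def test_full_span_kept_trapped_dropped(self):
        gact = self._gact()
        xs = {
            0: np.linspace(-4.9, 4.9, 500),  # spans everything
            1: np.linspace(gact.x_ts + 0.6, 4.9, 500),  # confined beyond the TS
        }
        report = coverage_filter(xs, gact, required_span=0.9)
        assert report.kept == [0] and report.dropped == [1]
        assert report.fraction_dropped == pytest.approx(0.5)

    def test_all_dropped_is_an_error(self):
        gact = self._gact()
        xs = {0: np.array([4.9]), 1: np.array([4.8])}
        with pytest.raises(RuntimeError, match="every replicate"):
            coverage_filter(xs, gact)


class TestInvariances:
    def test_environment_offset_leaves_free_energies_bit_identical(self, toy_windows):
        wins = toy_windows[0]
        shifted = [
            WindowSamples(
                lam=w.lam,
                u1_rr=w.u1_rr,
                u1_rs=w.u1_rs,
                u2_rr=w.u2_rr,
                u2_rs=w.u2_rs,
                u_ss=w.u_ss + 1.0e6,
                model=w.model,
            )
            for w in wins
        ]
        dg_a = fep_accumulate(wins, STANDARD_TEMPERATURE)
        dg_b = fep_accumulate(shifted, STANDARD_TEMPERATURE)
        assert np.array_equal(dg_a, dg_b)  # X never touches u_ss
        edges = np.linspace(-80.0, 70.0, 41)
        pa = umbrella_bin(wins, dg_a, STANDARD_TEMPERATURE, edges)
        pb = umbrella_bin(shifted, dg_b, STANDARD_TEMPERATURE, edges)
        pop = pa.populated
        assert np.array_equal(pa.dg[pop], pb.dg[pop])

    def test_oracle_entropy_matches_free_energy_temperature_derivative(self, toy_spec):
        """Finite-difference −ΔΔG‡/ΔT against the oracle's ⟨E⟩-based
        entropy: the thermodynamic identity ΔS = (ΔH − ΔG)/T."""
        from evbtherm.toy_system import exact_profiles_oracle

        edges = np.linspace(-80.0, 70.0, 46)
        dT = 10.0
        barrier = {}
        for temp in (STANDARD_TEMPERATURE - dT, STANDARD_TEMPERATURE, STANDARD_TEMPERATURE + dT):
            orc = exact_profiles_oracle(toy_spec, temp, edges)
            prof = FreeEnergyProfile(
                bin_edges=edges,
                dg=orc.dg,
                counts=(orc.populated * 100).astype(np.int64),
                low_count=~orc.populated,
            )
            gact = locate_stationary_points(prof)
            barrier[temp] = (gact, orc)
        gact0, orc0 = barrier[STANDARD_TEMPERATURE]
        ds_fd = -(
            barrier[STANDARD_TEMPERATURE + dT][0].dg_act
            - barrier[STANDARD_TEMPERATURE - dT][0].dg_act
        ) / (2 * dT)
        dh = orc0.e_mean[gact0.ts_idx] - orc0.e_mean[gact0.rs_idx]
        ds_id = (dh - gact0.dg_act) / STANDARD_TEMPERATURE
        assert ds_fd == pytest.approx(ds_id, abs=2e-3)
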