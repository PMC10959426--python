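"""Monte Carlo engine: source sampling, stepping, splitting, tallies."""

import numpy as np
import pytest

import bolusdose as bd
from bolusdose.transport import (
    BeamSpec,
    DoseTally,
    ElectronState,
    TransportConfig,
    _highland_sigma,
    _sample_primaries,
    apply_importance,
    run_simulation,
    sample_primary,
    step,
    uncertainty,
)


def make_config(**kw):
    defaults = dict(n_histories=1000, seed=0, n_batches=2)
    defaults.update(kw)
    return TransportConfig(**defaults)


class TestBeamSampling:
    def test_central_ray_monoenergetic(self):
        beam = BeamSpec(nominal_energy=6.0, field_size=0.0)
        state = sample_primary(beam, np.random.default_rng(0))
        assert state.kinetic_energy == 6.0
        np.testing.assert_allclose(state.direction, [0, 0, 1])
        assert state.weight == 1.0

    def test_corner_tilt(self):
        # a ray through the corner of a 10x10 field at 100 cm is tilted by
        # atan(sqrt(50)/100) from the axis
        beam = BeamSpec(nominal_energy=6.0, field_size=10.0,
                        source_distance=100.0)
        pos, dirs, _ = _sample_primaries(beam, np.random.default_rng(1), 20000)
        tilt = np.arccos(dirs[:, 2])
        assert tilt.max() <= np.arctan(np.sqrt(50.0) / 100.0) + 1e-9
        corner = np.max(np.abs(pos[:, :2]).min(axis=1))
        assert corner <= 5.0

    def test_mean_lateral_position(self):
        beam = BeamSpec(nominal_energy=6.0)
        pos, _, _ = _sample_primaries(beam, np.random.default_rng(2), 10000)
        se = (10.0 / np.sqrt(12.0)) / np.sqrt(10000)
        assert abs(pos[:, 0].mean()) < 3 * se
        assert abs(pos[:, 1].mean()) < 3 * se


class TestStep:
    def test_deterministic_deposit_without_scatter_straggle(self, water):
        config = make_config(straggling=False, scattering=False)
        state = ElectronState([0, 0, 1.0], [0, 0, 1], 6.0)
        new, edep, erad = step(state, water, config,
                               np.random.default_rng(0), step_length=0.04)
        expected = bd.collision_stopping_power(water, 6.0) * water.density * 0.04
        assert edep == pytest.approx(expected, rel=1e-3)  # table interpolation
        np.testing.assert_allclose(new.direction, [0, 0, 1])
        assert new.position[2] == pytest.approx(1.04)
        assert new.kinetic_energy == pytest.approx(6.0 - edep - erad)

    def test_zero_length_step_is_identity(self, water):
        state = ElectronState([0, 0, 1.0], [0, 0, 1], 6.0)
        new, edep, erad = step(state, water, make_config(),
                               np.random.default_rng(0), step_length=0.0)
        assert edep == 0.0 and erad == 0.0
        assert new.kinetic_energy == 6.0
        np.testing.assert_allclose(new.position, state.position)

    def test_below_cutoff_rejected(self, water):
        state = ElectronState([0, 0, 0.0], [0, 0, 1], 0.05)
        with pytest.raises(ValueError):
            step(state, water, make_config(), np.random.default_rng(0))

    def test_highland_angle_grows_with_shorter_radiation_length(self, db):
        from bolusdose.materials import radiation_length
        e = np.array([6.0])
        path = np.array([0.05 * 1.1])
        sig_silica = _highland_sigma(e, path,
                                     np.array([radiation_length(db["silica-gel"])]))
        sig_poly = _highland_sigma(e, path,
                                   np.array([radiation_length(db["polystyrene"])]))
        assert sig_silica > sig_poly


class TestImportanceSplitting:
    def test_unit_ratio_identity(self):
        state = ElectronState([0, 0, 0], [0, 0, 1], 6.0, weight=0.5)
        out = apply_importance(state, 10.0, 10.0, np.random.default_rng(0))
        assert len(out) == 1 and out[0].weight == 0.5

    def test_integer_split(self):
        state = ElectronState([0, 0, 0], [0, 0, 1], 6.0, weight=1.0)
        out = apply_importance(state, 100.0, 1000.0, np.random.default_rng(0))
        assert len(out) == 10
        assert all(s.weight == pytest.approx(0.1) for s in out)

    def test_roulette_statistics(self):
        rng = np.random.default_rng(3)
        state = ElectronState([0, 0, 0], [0, 0, 1], 6.0, weight=1.0)
        survivors = [apply_importance(state, 1000.0, 100.0, rng)
                     for _ in range(100000)]
        n_alive = sum(len(s) for s in survivors)
        se = np.sqrt(0.1 * 0.9 * 100000)
        assert abs(n_alive - 10000) < 3 * se
        alive = next(s for s in survivors if s)
        assert alive[0].weight == pytest.approx(10.0)

    def test_invalid_weights(self):
        state = ElectronState([0, 0, 0], [0, 0, 1], 6.0)
        with pytest.raises(ValueError):
            apply_importance(state, 0.0, 1.0, np.random.default_rng(0))


class TestRunSimulation:
    def test_same_seed_bit_identical(self, water_slab):
        beam = BeamSpec(nominal_energy=6.0)
        config = make_config(n_histories=2000, seed=5, n_batches=4)
        t1 = run_simulation(water_slab, beam, config)
        t2 = run_simulation(water_slab, beam, config)
        np.testing.assert_array_equal(t1.energy, t2.energy)
        assert t1.ledger_totals() == t2.ledger_totals()

    def test_analog_energy_conservation(self, water_slab):
        beam = BeamSpec(nominal_energy=6.0)
        config = make_config(n_histories=3000, seed=9, n_batches=3,
                             importance_sampling=False)
        tally = run_simulation(water_slab, beam, config)
        led = tally.ledger_totals()
        residual = led["source"] - led["deposited"] - led["escaped"] - led["radiative"]
        assert abs(residual) < 1e-6 * led["source"]

    def test_water_curve_shape(self, pencil_water_run):
        """Non-negative, one interior maximum, monotone falloff past it."""
        d = pencil_water_run.dose_per_history()
        c = pencil_water_run.depths
        assert np.all(d >= 0)
        i = int(np.argmax(d))
        assert 0 < i < len(d) - 1
        smooth = np.convolve(d, np.ones(3) / 3, mode="same")
        falloff = smooth[i + 2:]
        falloff = falloff[falloff > 0.01 * smooth.max()]
        assert np.all(np.diff(falloff) < 1e-12)

    def test_zero_histories_rejected(self):
        with pytest.raises(ValueError):
            make_config(n_histories=0)


class TestUncertainty:
    def _tally_from_batches(self, batches, water):
        from bolusdose.phantoms import Layer, SlabPhantom, voxel_geometry
        grid = voxel_geometry(
            SlabPhantom(layers=(Layer(water, 0.2), Layer(water, 0.2))))
        b = np.asarray(batches, dtype=float)
        return DoseTally(
            grid=grid, energy=b, histories=np.full(b.shape[0], 10),
            source_energy=np.zeros(b.shape[0]), deposited=np.zeros(b.shape[0]),
            escaped=np.zeros(b.shape[0]), radiative=np.zeros(b.shape[0]))

    def test_identical_batches_zero_error(self, water):
        tally = self._tally_from_batches([[1.0, 2.0, 3.0, 4.0]] * 4, water)
        np.testing.assert_allclose(uncertainty(tally), 0.0)

    def test_single_batch_rejected(self, water):
        tally = self._tally_from_batches([[1.0, 2.0, 3.0, 4.0]], water)
        with pytest.raises(ValueError):
            uncertainty(tally)

    def test_error_shrinks_with_more_histories(self, water_slab):
        beam = BeamSpec(nominal_energy=6.0, field_size=0.0)
        errs = []
        for n in (2000, 8000):
            tally = run_simulation(
                water_slab, beam, make_config(n_histories=n, seed=13,
                                              n_batches=8))
            rel = uncertainty(tally)
            d = tally.dose_per_history()
            errs.append(np.median(rel[d > 0.2 * d.max()]))
        ratio = errs[0] / errs[1]
        assert 1.2 < ratio < 3.5   # ~2 expected for a 4x history increase

    def test_deep_voxels_noisier_than_peak(self, pencil_water_run):
        rel = uncertainty(pencil_water_run)
        d = pencil_water_run.dose_per_history()
        i = int(np.argmax(d))
        deep = (d > 0) & (d < 0.05 * d.max())
        assert np.median(rel[deep]) > rel[i]
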