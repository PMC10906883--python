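import numpy as np
import pytest

from pemscat import (make_singles, blur_energy, apply_dead_time,
                     sort_coincidences, digitize)
from pemscat.digitizer import DataError, SingleTable
from pemscat.transport import HitTable


def _hit_table(rows):
    """rows: (event, photon, order, (x,y,z), edep, interaction, elem, t)."""
    rows = list(rows)
    term = [r[5] == 1 for r in rows]
    return HitTable(
        event_id=np.array([r[0] for r in rows], np.int64),
        photon_index=np.array([r[1] for r in rows], np.int8),
        hit_order=np.array([r[2] for r in rows], np.int16),
        position=np.array([r[3] for r in rows], np.float32),
        energy_deposited=np.array([r[4] for r in rows], np.float32),
        interaction=np.array([r[5] for r in rows], np.int8),
        element_id=np.array([r[6] for r in rows], np.int64),
        time=np.array([r[7] for r in rows], float),
        terminal_pe=np.array(term))


def _single(time, block, panel=None, energy=511.0):
    panel = block // 9 if panel is None else panel
    z = 35.0 if panel else -35.0
    return dict(event_id=0, photon_index=0, ewp=[0.0, 0.0, z],
                fhp=[0.0, 0.0, z], energy_true=energy, energy_blurred=energy,
                panel=panel, n_hits=1, n_compton=0, terminal_pe=True,
                block=block, time=time)


def _single_table(dicts):
    cols = {}
    for k in dicts[0]:
        cols[k] = np.array([d[k] for d in dicts])
    cols["ewp"] = cols["ewp"].astype(float)
    cols["fhp"] = cols["fhp"].astype(float)
    for i, d in enumerate(dicts):
        cols["event_id"][i] = d.get("event_id", 0)
    return SingleTable(**cols)


class TestMakeSingles:
    def test_single_pe_hit(self, geom_mono):
        hits = _hit_table([(0, 0, 1, (3, 4, 35), 511.0, 1, 13, 0.0)])
        s = make_singles(hits, geom_mono)
        assert np.allclose(s.ewp[0], (3, 4, 35), atol=1e-5)
        assert np.allclose(s.ewp[0], s.fhp[0])
        assert s.n_hits[0] == 1 and s.terminal_pe[0]

    def test_energy_weighted_centroid(self, geom_mono):
        hits = _hit_table([
            (0, 0, 1, (0.0, 2.0, 35.0), 100.0, 0, 13, 0.0),
            (0, 0, 2, (10.0, 2.0, 35.0), 411.0, 1, 13, 0.01)])
        s = make_singles(hits, geom_mono)
        assert s.ewp[0, 0] == pytest.approx(4110.0 / 511.0, abs=1e-4)
        assert s.fhp[0, 0] == 0.0
        assert s.n_hits[0] == 2  # multiple interaction

    def test_chain_label_fields(self, geom_mono):
        hits = _hit_table([
            (0, 0, 1, (0, 0, 35), 100.0, 0, 13, 0.0),
            (0, 0, 2, (1, 0, 35), 100.0, 0, 13, 0.01),
            (0, 0, 3, (2, 0, 35), 311.0, 1, 13, 0.02)])
        s = make_singles(hits, geom_mono)
        assert s.n_compton[0] == 2 and s.terminal_pe[0]

    def test_centroid_inside_hit_hull(self, small_cuboid_mono):
        s = small_cuboid_mono.singles
        multi = s.n_hits >= 2
        # 1-hit singles: centroid is the hit itself
        assert np.allclose(s.ewp[~multi], s.fhp[~multi])

    def test_cross_panel_chain_flagged(self, geom_mono):
        hits = _hit_table([
            (0, 0, 1, (0, 0, 35), 100.0, 0, 13, 0.0),
            (0, 0, 2, (0, 0, -35), 411.0, 1, 4, 0.3)])
        with pytest.raises(DataError):
            make_singles(hits, geom_mono)


class TestBlurEnergy:
    def test_zero_resolution_identity(self, rng):
        E = np.array([511.0, 400.0])
        assert np.array_equal(blur_energy(E, 0.0, rng), E)

    def test_width_at_511(self, rng):
        E = blur_energy(np.full(100_000, 511.0), 0.13, rng)
        fwhm = 2.3548 * E.std()
        assert fwhm == pytest.approx(0.13 * 511.0, abs=1.0)
        assert E.mean() == pytest.approx(511.0, abs=0.5)

    def test_one_over_sqrt_e_scaling(self, rng):
        E = blur_energy(np.full(100_000, 255.5), 0.13, rng)
        expected_fwhm = 0.13 * np.sqrt(511.0 * 255.5)
        assert 2.3548 * E.std() == pytest.approx(expected_fwhm, rel=0.03)


class TestDeadTime:
    def test_same_block_within_tau_discarded(self):
        s = _single_table([_single(0.0, 3), _single(2_000.0, 3)])
        kept = apply_dead_time(s, tau_us=6.0)
        assert len(kept) == 1 and kept.time[0] == 0.0

    def test_different_blocks_both_kept(self):
        s = _single_table([_single(0.0, 3), _single(2_000.0, 4)])
        assert len(apply_dead_time(s, tau_us=6.0)) == 2

    def test_zero_tau_keeps_all(self):
        s = _single_table([_single(0.0, 3), _single(1.0, 3)])
        assert len(apply_dead_time(s, tau_us=0.0)) == 2

    def test_non_paralyzable_recovery(self):
        # 0, 4, 8 us in one block: 4 us is absorbed, 8 us is < 6 us after
        # the last ACCEPTED single (0 us) -> discarded too? No: 8 - 0 >= 6.
        s = _single_table([_single(0.0, 3), _single(4_000.0, 3),
                           _single(8_000.0, 3)])
        kept = apply_dead_time(s, tau_us=6.0)
        assert list(kept.time) == [0.0, 8_000.0]

    def test_unsorted_input_rejected(self):
        s = _single_table([_single(5.0, 3), _single(0.0, 3)])
        with pytest.raises(DataError):
            apply_dead_time(s, tau_us=6.0)


class TestCoincidenceSorting:
    def test_opposite_panel_pair_within_window(self):
        s = _single_table([_single(0.0, 3, panel=0), _single(3.0, 12, panel=1)])
        _, c = sort_coincidences(s)
        assert len(c) == 1
        assert not c.is_random[0]

    def test_energy_window_rejects_low_pulse(self):
        s = _single_table([_single(0.0, 3, panel=0),
                           _single(3.0, 12, panel=1, energy=340.0)])
        _, c = sort_coincidences(s)
        assert len(c) == 0

    def test_same_panel_pair_rejected(self):
        s = _single_table([_single(0.0, 3, panel=0), _single(3.0, 4, panel=0)])
        _, c = sort_coincidences(s)
        assert len(c) == 0

    def test_triple_cluster_discarded(self):
        s = _single_table([_single(0.0, 3, panel=0), _single(2.0, 12, panel=1),
                           _single(4.0, 13, panel=1)])
        _, c = sort_coincidences(s)
        assert len(c) == 0

    def test_random_flag_from_event_ids(self):
        a, b = _single(0.0, 3, panel=0), _single(3.0, 12, panel=1)
        b["event_id"] = 9
        _, c = sort_coincidences(_single_table([a, b]))
        assert len(c) == 1 and bool(c.is_random[0])

    def test_disabling_energy_window_only_adds_events(self, geom_mono, xs):
        from pemscat import run_study
        run = run_study("monolithic", "cuboid", 40_000, seed=31, xs=xs,
                        keep_hits=True)
        _, c_win = digitize(run.hits, geom_mono, np.random.default_rng(7))
        _, c_open = digitize(run.hits, geom_mono, np.random.default_rng(7),
                             energy_window=None)
        assert len(c_open) > len(c_win)


def test_si_singles_have_zero_positioning_error(small_cuboid_mono):
    s = small_cuboid_mono.singles
    si = s.n_hits == 1
    assert np.allclose(s.ewp[si], s.fhp[si])
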