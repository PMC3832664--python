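"""Simulator tests: event schedules against an independent enumeration
oracle, volume-trajectory identities, rendering geometry and truth-table
round trips."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import census_at, count_nebd_events, enumerate_deterministic

from nb4d.params import (
    CellType,
    LineageParams,
    ParamError,
    default_imaging,
    type_i_preset,
    type_ii_preset,
)
from nb4d.simulate import (
    TruthCell,
    make_bystanders,
    read_truth_tables,
    render_movie,
    simulate_lineage,
    sphere_radius,
    write_truth_tables,
)


def deterministic(preset, **kw):
    return preset(nb_cycle_cv=0.0, daughter_cycle_cv=0.0, **kw)


class TestLineageSchedule:
    def test_short_duration_single_cell_no_division(self):
        cells = simulate_lineage(type_i_preset(), duration=30.0)
        assert len(cells) == 1
        assert cells[0].nebd_times == []
        assert cells[0].cell_type is CellType.NB

    @pytest.mark.parametrize("mode,preset", [("typeI", type_i_preset), ("typeII", type_ii_preset)])
    @pytest.mark.parametrize("duration", [150.0, 600.0, 900.0])
    def test_deterministic_schedule_matches_enumeration_oracle(self, mode, preset, duration):
        p = deterministic(preset)
        cells = simulate_lineage(p, duration)
        oracle = enumerate_deterministic(
            mode, duration,
            nb_cycle=p.nb_cycle_mean, gmc_delay=p.gmc_division_delay_mean,
            inp_first=p.inp_first_cycle_mean, inp_mature=p.inp_mature_cycle_mean,
            mitosis=p.mitosis_duration,
        )
        assert len(cells) == len(oracle)
        assert sum(len(c.nebd_times) for c in cells) == count_nebd_events(oracle)
        got = sorted((c.cell_type.value, round(c.birth_time, 6)) for c in cells)
        want = sorted((c.ctype, round(c.birth, 6)) for c in oracle)
        assert got == want

    def test_deterministic_census_matches_oracle(self):
        for mode, preset in [("typeI", type_i_preset), ("typeII", type_ii_preset)]:
            p = deterministic(preset)
            cells = simulate_lineage(p, 600.0)
            oracle = enumerate_deterministic(
                mode, 600.0, p.nb_cycle_mean, p.gmc_division_delay_mean,
                p.inp_first_cycle_mean, p.inp_mature_cycle_mean, p.mitosis_duration,
            )
            for t in (150.0, 300.0, 597.0):
                sim = sum(1 for c in cells if c.alive_at(t))
                assert sim == census_at(oracle, t, p.mitosis_duration)

    def test_root_internebd_intervals_equal_cycle_mean_when_cv_zero(self):
        p = deterministic(type_i_preset)
        root = simulate_lineage(p, 600.0)[0]
        gaps = np.diff(root.nebd_times)
        assert np.allclose(gaps, p.nb_cycle_mean)
        assert root.nebd_times[0] == pytest.approx(p.nb_cycle_mean)

    def test_initial_phase_shortens_first_cycle_only(self):
        p = deterministic(type_i_preset, initial_phase=0.5)
        root = simulate_lineage(p, 400.0)[0]
        assert root.nebd_times[0] == pytest.approx(0.5 * p.nb_cycle_mean)
        assert np.allclose(np.diff(root.nebd_times), p.nb_cycle_mean)

    def test_type_ii_inp_first_cycle_and_asymmetry(self):
        p = deterministic(type_ii_preset)
        cells = simulate_lineage(p, 700.0)
        inps = [c for c in cells if c.cell_type is CellType.INP]
        assert inps
        for inp in inps:
            if inp.nebd_times:
                assert inp.nebd_times[0] - inp.birth_time == pytest.approx(
                    p.inp_first_cycle_mean
                )
        # renewed INP is larger at birth than its GMC sibling
        assert p.inp_birth_volume > p.gmc_volume

    def test_growth_fold_exact_on_trajectories(self):
        p = deterministic(type_ii_preset)
        cells = simulate_lineage(p, 700.0)
        for c in cells:
            for t0, t1, v0, v1 in c.volume_segments:
                if c.cell_type is CellType.NB:
                    assert v1 / v0 == pytest.approx(p.nb_growth_fold)
                elif c.cell_type is CellType.INP:
                    assert v1 / v0 == pytest.approx(p.inp_growth_fold)
                else:
                    assert v1 == pytest.approx(v0)  # GMC/neuron do not grow

    def test_daughter_birth_equals_parent_nebd_plus_mitosis(self):
        p = deterministic(type_i_preset)
        cells = simulate_lineage(p, 600.0)
        by_id = {c.cell_id: c for c in cells}
        for c in cells:
            if c.parent_id is not None:
                parent = by_id[c.parent_id]
                assert any(
                    c.birth_time == pytest.approx(n + p.mitosis_duration)
                    for n in parent.nebd_times
                )
                assert c.birth_time < (c.nebd_times[0] if c.nebd_times else np.inf)

    def test_volume_none_during_dispersal(self):
        p = deterministic(type_i_preset)
        root = simulate_lineage(p, 200.0)[0]
        nebd = root.nebd_times[0]
        assert root.volume_at(nebd - 0.1) is not None
        assert root.volume_at(nebd) is None
        assert root.volume_at(nebd + p.mitosis_duration - 0.1) is None
        assert root.volume_at(nebd + p.mitosis_duration) is not None

    def test_identical_seed_reproducible(self):
        a = simulate_lineage(type_i_preset(seed=9), 600.0)
        b = simulate_lineage(type_i_preset(seed=9), 600.0)
        assert [(c.cell_id, c.birth_time, tuple(c.nebd_times)) for c in a] == [
            (c.cell_id, c.birth_time, tuple(c.nebd_times)) for c in b
        ]

    def test_invalid_inputs_raise(self):
        with pytest.raises(ParamError):
            simulate_lineage(type_i_preset(), duration=-1.0)
        with pytest.raises(ParamError):
            LineageParams(nb_cycle_mean=-5.0)
        with pytest.raises(ParamError):
            LineageParams(initial_phase=1.5)
        with pytest.raises(ParamError):
            LineageParams(nb_growth_fold=0.8)


class TestScheduleProperties:
    """Invariants of the deterministic schedule over the parameter space."""

    @staticmethod
    def _oracle_kwargs(p):
        return dict(
            nb_cycle=p.nb_cycle_mean, gmc_delay=p.gmc_division_delay_mean,
            inp_first=p.inp_first_cycle_mean, inp_mature=p.inp_mature_cycle_mean,
            mitosis=p.mitosis_duration,
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        nb_cycle=st.floats(40.0, 150.0),
        duration=st.floats(50.0, 900.0),
        fold=st.floats(1.0, 2.5),
        mode=st.sampled_from(["typeI", "typeII"]),
    )
    def test_cell_count_and_fold_invariants(self, nb_cycle, duration, fold, mode):
        preset = type_i_preset if mode == "typeI" else type_ii_preset
        p = deterministic(preset, nb_cycle_mean=nb_cycle, nb_growth_fold=fold)
        cells = simulate_lineage(p, duration)
        oracle = enumerate_deterministic(mode, duration, **self._oracle_kwargs(p))
        assert len(cells) == len(oracle)
        root = cells[0]
        for t0, t1, v0, v1 in root.volume_segments:
            assert v1 / v0 == pytest.approx(p.nb_growth_fold)
        for c in cells:
            assert not c.nebd_times or c.birth_time < c.nebd_times[0]


class TestRendering:
    def test_empty_cell_list_renders_background_and_empty_labels(self):
        imaging = default_imaging(seed=1)
        movie, labels = render_movie([], imaging, 9.0)
        assert movie.data.shape[0] == 3
        assert labels.data.max() == 0
        # pure noise around the background level
        assert abs(movie.data.mean() - imaging.background_level) < 2.0

    def test_static_sphere_voxel_volume_within_ten_percent(self):
        # one static nucleus of 113.1 µm³ = (4/3)π·3³
        vol = 4.0 / 3.0 * math.pi * 27.0
        imaging = default_imaging(seed=1, psf_sigma_xy=0.0, psf_sigma_z=0.0)
        cell = TruthCell(cell_id=1, parent_id=None, cell_type=CellType.NB,
                         birth_time=0.0, dispersal_min=0.0, mobile=False)
        cell.volume_segments.append((0.0, 100.0, vol, vol))
        cell.positions[-1] = np.array([10.0, 10.0, 20.0])
        movie, labels = render_movie([cell], imaging, 3.0, noise=False, blur=False)
        measured = (labels.data[0] == 1).sum() * imaging.voxel_volume
        assert measured == pytest.approx(vol, rel=0.10)
        assert sphere_radius(vol) == pytest.approx(3.0)

    def test_interphase_nuclei_brighter_than_background(self, noisy_render):
        movie, labels = noisy_render["movie"], noisy_render["labels"]
        for t in range(0, movie.n_frames, 10):
            lab = labels.data[t]
            img = movie.data[t]
            bg = img[lab == 0].mean()
            for cid in np.unique(lab[lab > 0]):
                assert img[lab == cid].mean() > bg

    def test_labels_disjoint_and_subset_of_alive_cells(self, noisy_render):
        labels = noisy_render["labels"]
        cells = {c.cell_id: c for c in noisy_render["cells"]}
        interval = noisy_render["imaging"].frame_interval
        for t in range(labels.n_frames):
            ids = np.unique(labels.data[t])
            for cid in ids[ids > 0]:
                assert cells[cid].is_interphase_at(t * interval)

    def test_nebd_frames_have_no_label_for_dividing_cell(self, noisy_render):
        interval = noisy_render["imaging"].frame_interval
        labels = noisy_render["labels"]
        root = noisy_render["cells"][0]
        nebd = root.nebd_times[0]
        gap_frames = [t for t in range(labels.n_frames)
                      if nebd <= t * interval < nebd + root.dispersal_min]
        assert gap_frames
        for t in gap_frames:
            assert root.cell_id not in np.unique(labels.data[t])

    def test_render_deterministic_under_fixed_seed(self):
        p = type_i_preset(seed=5)
        imaging = default_imaging(seed=6)
        cells1 = simulate_lineage(p, 30.0)
        m1, l1 = render_movie(cells1, imaging, 30.0)
        cells2 = simulate_lineage(type_i_preset(seed=5), 30.0)
        m2, l2 = render_movie(cells2, default_imaging(seed=6), 30.0)
        assert np.array_equal(m1.data, m2.data)
        assert np.array_equal(l1.data, l2.data)


class TestTruthTables:
    def test_single_cell_lineage_one_row(self, tmp_path):
        cells = simulate_lineage(type_i_preset(), 30.0)
        imaging = default_imaging()
        render_movie(cells, imaging, 30.0, noise=False)
        write_truth_tables(cells, tmp_path, frame_interval=imaging.frame_interval)
        cells_df, frames_df = read_truth_tables(tmp_path)
        assert len(cells_df) == 1
        assert set(cells_df.columns) == {
            "cell_id", "parent_id", "cell_type", "birth_time_min", "nebd_times_min"
        }
        assert list(frames_df.columns) == [
            "frame", "cell_id", "x_um", "y_um", "z_um", "true_volume_um3"
        ]

    def test_round_trip_lossless(self, tmp_path, noisy_render):
        cells = noisy_render["cells"]
        interval = noisy_render["imaging"].frame_interval
        write_truth_tables(cells, tmp_path, frame_interval=interval)
        cells_df, frames_df = read_truth_tables(tmp_path)
        from nb4d.simulate import cells_table, frames_table, parse_nebd_times

        pd.testing.assert_frame_equal(cells_df, cells_table(cells))
        pd.testing.assert_frame_equal(frames_df, frames_table(cells, interval))
        # nebd times parse back to exact floats
        for c, row in zip(cells, cells_df.itertuples(index=False)):
            assert parse_nebd_times(row.nebd_times_min) == c.nebd_times

    def test_nebd_event_count_matches_oracle(self, tmp_path):
        p = deterministic(type_i_preset)
        cells = simulate_lineage(p, 600.0)
        imaging = default_imaging()
        render_movie(cells, imaging, 600.0, noise=False, blur=False)
        write_truth_tables(cells, tmp_path, frame_interval=imaging.frame_interval)
        cells_df, _ = read_truth_tables(tmp_path)
        from nb4d.simulate import parse_nebd_times

        n_events = sum(len(parse_nebd_times(s)) for s in cells_df.nebd_times_min)
        oracle = enumerate_deterministic(
            "typeI", 600.0, p.nb_cycle_mean, p.gmc_division_delay_mean,
            p.inp_first_cycle_mean, p.inp_mature_cycle_mean, p.mitosis_duration,
        )
        assert n_events == count_nebd_events(oracle)
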