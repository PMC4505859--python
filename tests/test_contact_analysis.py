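"""Binding criterion and contact statistics: minimum-image distances, the
strict 0.52 nm rule, occupancies, censuses, selection rule, sweeps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pipsites import benchmarks, contact_analysis as ca, trajectory_io as tio
from pipsites.contact_analysis import AnalysisParams, BindingTimeline
from pipsites.errors import ValidationError
from pipsites.topology import Frame, Trajectory

from conftest import make_topology, single_frame_traj


def brute_force_min_distance(coords_a, coords_b, box):
    best = np.inf
    for a in coords_a:
        for b in coords_b:
            d = a - b
            d = d - box * np.round(d / box)
            best = min(best, float(np.sqrt((d * d).sum())))
    return best


class TestMinDistance:
    def test_axis_aligned_pair(self):
        top = make_topology(["protein", "PIP2"])
        traj = single_frame_traj(top, [[0, 0, 0], [0, 0, 1]])
        assert ca.min_distance(traj[0], top, [0], [1]) == pytest.approx(1.0)

    def test_wraps_across_the_boundary(self):
        top = make_topology(["protein", "PIP2"])
        traj = single_frame_traj(top, [[0, 0, 0.2], [0, 0, 9.9]])
        assert ca.min_distance(traj[0], top, [0], [1]) == pytest.approx(0.3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        top = make_topology(["protein"] * 50 + ["PIP2"] * 50)
        coords = rng.uniform(0, 7, (100, 3))
        traj = single_frame_traj(top, coords, box=7.0)
        got = ca.min_distance(traj[0], top, np.arange(50), np.arange(50, 100))
        ref = brute_force_min_distance(coords[:50], coords[50:],
                                       np.full(3, 7.0))
        assert got == pytest.approx(ref, rel=1e-10)

    def test_empty_group_rejected(self):
        top = make_topology(["protein", "PIP2"])
        traj = single_frame_traj(top, [[0, 0, 0], [1, 1, 1]])
        with pytest.raises(ValidationError):
            ca.min_distance(traj[0], top, [], [1])


def _protein_over_phosphates(distances, n_pip2_far=0):
    """One protein bead at origin with one phosphate per given distance,
    plus optional distant PIP2 molecules."""
    n_phos = len(distances) + n_pip2_far
    top = make_topology(["protein"] + ["PIP2"] * n_phos)
    coords = [[0.0, 0.0, 0.0]]
    for d in distances:
        coords.append([0.0, 0.0, d])
    for k in range(n_pip2_far):
        coords.append([0.0, 2.0 * (k + 1), 25.0])
    return single_frame_traj(top, coords, box=50.0)


class TestBindingIndicator:
    def test_phosphate_just_inside_cutoff_binds(self):
        traj = _protein_over_phosphates([0.51])
        tl = ca.binding_indicator(traj)
        assert tl.bound[0] and tl.n_p[0] == 1

    def test_distance_exactly_at_cutoff_is_unbound(self):
        traj = _protein_over_phosphates([0.52])
        tl = ca.binding_indicator(traj)
        assert not tl.bound[0] and tl.n_p[0] == 0

    def test_counts_distinct_pip2_molecules(self):
        traj = _protein_over_phosphates([0.3, 0.4, 0.5], n_pip2_far=30)
        tl = ca.binding_indicator(traj)
        assert tl.n_p[0] == 3

    def test_requires_pip2(self):
        top = make_topology(["protein", "DOPC"])
        traj = single_frame_traj(top, [[0, 0, 0], [0, 0, 1]])
        with pytest.raises(ValidationError):
            ca.binding_indicator(traj)

    def test_equilibration_skip_drops_early_frames(self):
        top = make_topology(["protein", "PIP2"])
        frames = [Frame([[0, 0, 0], [0, 0, 0.4]], np.full(3, 10.0), time=t)
                  for t in (0.0, 1.0, 2.0, 3.0)]
        traj = Trajectory(top, frames)
        tl = ca.binding_indicator(traj, AnalysisParams(equilibration_skip=2.0))
        assert tl.n_frames == 2 and tl.time[0] == pytest.approx(2.0)


class TestBindingFraction:
    def test_always_bound_is_100(self):
        traj = _protein_over_phosphates([0.3])
        tl = ca.binding_indicator(traj)
        assert ca.binding_fraction(tl) == pytest.approx(100.0)

    def test_alternating_frames_give_50(self):
        tl = BindingTimeline(
            time=np.arange(10.0),
            bound=np.tile([True, False], 5),
            n_p=np.tile([1, 0], 5),
            min_dist=np.tile([0.4, 1.0], 5))
        assert ca.binding_fraction(tl) == pytest.approx(50.0)


class TestStoichiometry:
    def test_single_lipid_class_dominates(self):
        tl = BindingTimeline(np.arange(4.0), np.ones(4, bool),
                             np.ones(4, int), np.full(4, 0.4))
        dist = ca.stoichiometry_distribution(tl)
        assert dist.as_dict() == {"1": 100.0, "2": 0.0, "3": 0.0, "4-6": 0.0}

    def test_never_bound_flags_empty(self):
        tl = BindingTimeline(np.arange(3.0), np.zeros(3, bool),
                             np.zeros(3, int), np.ones(3))
        dist = ca.stoichiometry_distribution(tl)
        assert dist.empty and not np.isnan(dist.percent).any()

    def test_classes_partition_bound_frames(self, planted_battery):
        for tl in planted_battery["timelines"]:
            if tl.n_bound == 0:
                continue
            dist = ca.stoichiometry_distribution(tl)
            assert dist.percent.sum() == pytest.approx(100.0, abs=0.1)

    @given(st.lists(st.integers(0, 8), min_size=1, max_size=60))
    def test_partition_property_on_arbitrary_timelines(self, n_p):
        n_p = np.array(n_p)
        bound = n_p >= 1
        tl = BindingTimeline(np.arange(len(n_p), dtype=float), bound, n_p,
                             np.where(bound, 0.4, 1.0))
        dist = ca.stoichiometry_distribution(tl)
        if bound.any():
            assert dist.percent.sum() == pytest.approx(100.0, abs=1e-9)


class TestMeanBoundDistance:
    def test_constant_distance(self):
        tl = BindingTimeline(np.arange(3.0), np.ones(3, bool), np.ones(3, int),
                             np.full(3, 0.50))
        assert ca.mean_bound_distance(tl) == pytest.approx((0.50, 0.0))

    def test_two_value_mean(self):
        tl = BindingTimeline(np.arange(2.0), np.ones(2, bool), np.ones(2, int),
                             np.array([0.4, 0.5]))
        mean, sd = ca.mean_bound_distance(tl)
        assert mean == pytest.approx(0.45)

    def test_never_exceeds_cutoff(self, planted_battery):
        for tl in planted_battery["timelines"]:
            if tl.n_bound:
                mean, _ = ca.mean_bound_distance(tl)
                assert mean < tl.cutoff


class TestFirstBindingTime:
    def test_bound_from_start(self):
        traj = _protein_over_phosphates([0.3])
        assert ca.first_binding_time(ca.binding_indicator(traj)) == 0.0

    def test_never_bound_is_none(self):
        traj = _protein_over_phosphates([5.0])
        assert ca.first_binding_time(ca.binding_indicator(traj)) is None

    def test_closer_starts_bind_no_later(self, planted_battery):
        """Runs started at a 1.5 nm gap bind no earlier (in median) than the
        battery runs started at 0.5 nm — mirrors a staged-placement design."""
        near = [ca.first_binding_time(tl) for tl in planted_battery["timelines"]]
        far = []
        for seed in planted_battery["seeds"]:
            traj = benchmarks.run_planted(seed, gap=1.5, n_steps=3000)
            far.append(ca.first_binding_time(ca.binding_indicator(traj)))
        inf = float("inf")
        med = lambda xs: float(np.median([inf if x is None else x for x in xs]))
        assert med(near) <= med(far)


class TestResidueContactFraction:
    def test_single_residue_glued_in_range(self):
        # protein of 3 residues, only residue 2 within cutoff, every frame
        top = make_topology(["protein"] * 3 + ["PIP2"],
                            residue_ids=[1, 2, 3, 4])
        coords = [[5, 5, 3.0], [5, 5, 1.3], [5, 5, 5.0], [5, 5, 1.0]]
        frames = [Frame(coords, np.full(3, 10.0), time=float(t))
                  for t in range(3)]
        traj = Trajectory(top, frames)
        table = ca.residue_contact_fraction(traj)
        occ = table.residues.set_index("residue_id")["occupancy"]
        assert occ[2] == pytest.approx(1.0)
        assert occ[1] == 0.0 and occ[3] == 0.0
        assert table.n_bound_frames == 3

    def test_invariant_to_frame_order(self, planted_battery):
        traj = planted_battery["trajectories"][0]
        table = ca.residue_contact_fraction(traj)
        reversed_frames = [
            Frame(fr.coordinates, fr.box, time=float(k))
            for k, fr in enumerate(reversed(traj.frames))]
        table_rev = ca.residue_contact_fraction(
            Trajectory(traj.topology, reversed_frames))
        pd.testing.assert_frame_equal(table.residues, table_rev.residues)

    def test_occupancies_in_unit_interval(self, planted_battery):
        for traj in planted_battery["trajectories"][:3]:
            table = ca.residue_contact_fraction(traj)
            occ = table.residues["occupancy"]
            assert ((occ >= 0) & (occ <= 1)).all()
            assert (table.residues["n_contact"]
                    == (occ * table.n_bound_frames).round()).all()

    def test_undefined_when_never_bound(self):
        traj = _protein_over_phosphates([5.0])
        table = ca.residue_contact_fraction(traj)
        assert not table.defined
        assert table.residues["occupancy"].isna().all()

    def test_planted_residues_top_ranked(self, planted_battery):
        assert planted_battery["n_occupancy_runs"] >= 5
        top_k = ca.top_k_residues(planted_battery["mean_occupancy"],
                                  len(benchmarks.PLANTED_RESIDUES))
        assert top_k == set(benchmarks.PLANTED_RESIDUES)


class TestLipidCensus:
    def test_persistent_lipid_counted(self):
        traj = _protein_over_phosphates([0.3])
        table = ca.lipid_contact_census(traj)
        pip2 = table.census[table.census.lipid_class == "PIP2"]
        assert (pip2.n_lipids >= 1).all()

    def test_nested_thresholds(self, planted_battery):
        for traj in planted_battery["trajectories"][:3]:
            census = ca.lipid_contact_census(traj).census
            for cls, grp in census.groupby("lipid_class"):
                grp = grp.sort_values("threshold")
                assert (np.diff(grp.n_lipids.to_numpy()) <= 0).all()

    def test_zero_contact_trajectory(self):
        traj = _protein_over_phosphates([5.0])
        table = ca.lipid_contact_census(traj)
        assert (table.census.n_lipids == 0).all()


class TestSelectBindingResidues:
    def test_reproduces_published_fifteen(self):
        fix = tio.load_contact_fixture()
        selected = ca.select_binding_residues(fix.fractions())
        assert selected == ["K191", "K216", "K218", "R221", "K222", "R229",
                            "R508", "R514", "K515", "K578", "K621", "K627",
                            "R640", "K657", "R665"]

    def test_threshold_inequalities_are_strict(self):
        df = pd.DataFrame({"at_minor": [0.05, 0.05, 0.0],
                           "above_major": [0.101, 0.0, 0.0],
                           "at_major": [0.10, 0.10, 0.0]},
                          index=["I", "II", "III"])
        # exactly 5% twice: excluded; >10% once: included;
        # exactly 10% twice: excluded by major rule but passes minor rule
        selected = ca.select_binding_residues(df)
        assert "at_minor" not in selected
        assert "above_major" in selected
        assert "at_major" in selected  # 0.10 > 0.05 in two sims

    def test_minor_rule_needs_two_simulations(self):
        df = pd.DataFrame({"once": [0.06, 0.0, 0.0],
                           "twice": [0.06, 0.06, 0.0]})
        selected = ca.select_binding_residues(df)
        assert selected == ["twice"]


class TestCutoffSweep:
    CUTOFFS = (0.42, 0.47, 0.52, 0.57, 0.62)

    def test_monotone_in_cutoff(self, planted_battery):
        for traj in planted_battery["trajectories"][:3]:
            sweep = ca.cutoff_sweep(traj, self.CUTOFFS)
            diffs = np.diff(sweep.to_numpy(), axis=1)
            assert (diffs >= 0).all()

    def test_zero_cutoff_gives_zero_occupancy(self, planted_battery):
        sweep = ca.cutoff_sweep(planted_battery["trajectories"][0], [0.0])
        assert (sweep.to_numpy() == 0).all()

    def test_top_k_set_stable_across_cutoffs(self, planted_battery):
        sweeps = [ca.cutoff_sweep(traj, self.CUTOFFS)
                  for traj in planted_battery["trajectories"]]
        mean_sweep = sum(sweeps) / len(sweeps)
        k = len(benchmarks.PLANTED_RESIDUES)
        sets = [frozenset(ca.top_k_residues(mean_sweep[c], k))
                for c in self.CUTOFFS]
        assert len(set(sets)) == 1


class TestLeafletSeries:
    def test_contact_geometry(self):
        # protein bead 0.4 above upper leaflet; lower leaflet 4 nm below it
        top = make_topology(["protein", "PIP2", "DOPC"],
                            leaflets=["", "upper", "lower"])
        traj = single_frame_traj(top, [[5, 5, 6.4], [5, 5, 6.0], [5, 5, 2.0]])
        series = ca.leaflet_min_distance_series(traj)
        assert series.dist_upper[0] == pytest.approx(0.4)
        assert series.dist_lower[0] == pytest.approx(4.4)
        assert series.attrs["pip2_leaflet"] == "upper"

    def test_pip2_leaflet_preferred_by_charged_protein(self, planted_battery):
        """Charged runs spend more frames in contact with the PIP2-containing
        leaflet than with the bare one — leaflet preference at simulator level."""
        pip2_contact = bare_contact = 0
        for traj in planted_battery["trajectories"]:
            series = ca.leaflet_min_distance_series(traj)
            pip2_contact += int((series.dist_upper < 0.52).sum())
            bare_contact += int((series.dist_lower < 0.52).sum())
        assert pip2_contact > bare_contact
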