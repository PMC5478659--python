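"""Transect ordering, accumulation, skewness trajectories, label perturbation."""

import numpy as np
import pandas as pd
import pytest

from sadscale import (
    TransectTable,
    accumulate_sads,
    order_concentric,
    order_sequential,
    perturb_dispersal_labels,
    skewness_trajectory,
)


def _table(records):
    return TransectTable(pd.DataFrame(records))


def _collinear_table():
    rows = []
    for t, x in zip("PQRS", [0.0, 1.0, 3.0, 7.0]):
        rows.append(
            dict(
                transect_id=t,
                site="s",
                x=x,
                y=0.0,
                species_id="a",
                abundance=2,
                dispersal_class="high",
            )
        )
    return _table(rows)


class TestOrdering:
    def test_concentric_monotone_line(self):
        assert order_concentric(_collinear_table(), "P") == ["P", "Q", "R", "S"]

    def test_sequential_equals_concentric_on_monotone_line(self):
        assert order_sequential(_collinear_table(), "P") == ["P", "Q", "R", "S"]

    def test_concentric_hand_distances(self, small_table):
        # distances from A: B = 2, C = 2.5, D = 3
        assert order_concentric(small_table, "A") == ["A", "B", "C", "D"]

    def test_sequential_greedy_chain(self, small_table):
        # from B the nearest remaining is D (distance 1), then C
        assert order_sequential(small_table, "A") == ["A", "B", "D", "C"]

    def test_single_transect(self):
        t = _table(
            [
                dict(
                    transect_id="only",
                    site="s",
                    x=0.0,
                    y=0.0,
                    species_id="a",
                    abundance=1,
                    dispersal_class="low",
                )
            ]
        )
        assert order_concentric(t, "only") == ["only"]
        assert order_sequential(t, "only") == ["only"]

    def test_unknown_start_rejected(self, small_table):
        with pytest.raises(KeyError):
            order_concentric(small_table, "Z")
        with pytest.raises(KeyError):
            order_sequential(small_table, "Z")

    def test_both_methods_same_id_set_and_start(self, small_table):
        for start in small_table.transect_ids:
            oc = order_concentric(small_table, start)
            os_ = order_sequential(small_table, start)
            assert sorted(oc) == sorted(os_) == small_table.transect_ids
            assert oc[0] == os_[0] == start


class TestAccumulation:
    def test_additivity_single_species(self):
        rows = [
            dict(
                transect_id=f"t{i}",
                site="s",
                x=float(i),
                y=0.0,
                species_id="a",
                abundance=2,
                dispersal_class="high",
            )
            for i in range(3)
        ]
        traj = accumulate_sads(_table(rows), ["t0", "t1", "t2"], groups=("high",))
        totals = [v.total_individuals for v in traj.vectors["high"]]
        assert totals == [2, 4, 6]

    def test_disjoint_species_sets_add_richness(self, small_table):
        traj = accumulate_sads(small_table, ["A", "B", "C", "D"], groups=("all",))
        s_t = [v.species_count for v in traj.vectors["all"]]
        assert s_t[0] == 3 and s_t == sorted(s_t)

    def test_pooled_totals_match_groupby_oracle(self, sim_table):
        ordering = order_concentric(sim_table, sim_table.transect_ids[0])
        traj = accumulate_sads(sim_table, ordering, groups=("high", "low"))
        for group in ("high", "low"):
            df = sim_table.data
            expected = (
                df[df.dispersal_class == group]
                .groupby("species_id")["abundance"]
                .sum()
                .sort_values()
            )
            got = np.sort(traj.vectors[group][-1].abundances)
            assert np.array_equal(got, expected.to_numpy())

    def test_final_step_identical_for_all_orderings(self, small_table):
        finals = []
        for start in small_table.transect_ids:
            for order_fn in (order_concentric, order_sequential):
                traj = accumulate_sads(
                    small_table, order_fn(small_table, start), groups=("high",)
                )
                finals.append(np.sort(traj.vectors["high"][-1].abundances))
        assert all(np.array_equal(finals[0], f) for f in finals)

    def test_species_and_individuals_nondecreasing(self, small_table):
        traj = accumulate_sads(
            small_table, order_concentric(small_table, "C"), groups=("high", "low")
        )
        for group in ("high", "low"):
            s = [v.species_count for v in traj.vectors[group]]
            n = [v.total_individuals for v in traj.vectors[group]]
            assert s == sorted(s) and n == sorted(n)

    def test_non_permutation_rejected(self, small_table):
        with pytest.raises(ValueError):
            accumulate_sads(small_table, ["A", "B", "C"])
        with pytest.raises(ValueError):
            accumulate_sads(small_table, ["A", "A", "B", "C"])


class TestSkewnessTrajectory:
    def test_identical_transects_zero_sd(self):
        rows = []
        for i in range(4):
            for sp, n in [("a", 1), ("b", 2), ("c", 8)]:
                rows.append(
                    dict(
                        transect_id=f"t{i}",
                        site="s",
                        x=float(i),
                        y=0.0,
                        species_id=sp,
                        abundance=n,
                        dispersal_class="high",
                    )
                )
        traj = skewness_trajectory(_table(rows), groups=("high",))
        assert np.allclose(traj.sd_skewness.dropna(), 0.0, atol=1e-12)

    def test_one_ordering_per_start_transect(self, sim_table):
        traj = skewness_trajectory(sim_table, groups=("high",))
        contributing = traj.n_orderings + traj.n_excluded
        assert (contributing == sim_table.n_transects).all()

    def test_high_dispersal_skew_exceeds_low_at_intermediate_sizes(self, sim_table):
        """Well-mixed communities keep more singletons, hence larger skew."""
        traj = skewness_trajectory(sim_table)
        mid = traj[traj.n_transects.between(6, 18)]
        mean_by_group = mid.groupby("group")["mean_skewness"].mean()
        assert mean_by_group["high"] > mean_by_group["low"]

    def test_degenerate_steps_are_excluded_and_counted(self):
        # two transects holding a single singleton species each: skewness
        # is undefined at every step for them
        rows = [
            dict(
                transect_id=f"t{i}",
                site="s",
                x=float(i),
                y=0.0,
                species_id="only",
                abundance=1,
                dispersal_class="low",
            )
            for i in range(2)
        ]
        traj = skewness_trajectory(_table(rows), groups=("low",))
        assert (traj.n_orderings == 0).all()
        assert (traj.n_excluded == 2).all()


class TestPerturbation:
    def test_fraction_zero_is_identity(self, small_table):
        out = perturb_dispersal_labels(small_table, 0.0, seed=1)
        pd.testing.assert_frame_equal(out.data, small_table.data)

    def test_fraction_one_flips_everything(self, small_table):
        out = perturb_dispersal_labels(small_table, 1.0, seed=1)
        orig = small_table.dispersal_of()
        flipped = out.dispersal_of()
        assert (orig != flipped).all()

    def test_deterministic_given_seed(self, small_table):
        a = perturb_dispersal_labels(small_table, 0.5, seed=7)
        b = perturb_dispersal_labels(small_table, 0.5, seed=7)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_flip_count_is_rounded_fraction(self, sim_table):
        out = perturb_dispersal_labels(sim_table, 0.1, seed=3)
        n_flipped = (sim_table.dispersal_of() != out.dispersal_of()).sum()
        assert n_flipped == round(0.1 * len(sim_table.species_ids))

    def test_invalid_fraction_rejected(self, small_table):
        with pytest.raises(ValueError):
            perturb_dispersal_labels(small_table, 1.5, seed=0)


class TestTableValidation:
    def test_duplicate_records_summed(self):
        rows = [
            dict(
                transect_id="t0",
                site="s",
                x=0.0,
                y=0.0,
                species_id="a",
                abundance=n,
                dispersal_class="high",
            )
            for n in (2, 3)
        ]
        t = _table(rows)
        assert t.data.abundance.tolist() == [5]

    def test_inconsistent_dispersal_class_rejected(self):
        rows = [
            dict(
                transect_id=f"t{i}",
                site="s",
                x=float(i),
                y=0.0,
                species_id="a",
                abundance=1,
                dispersal_class=cls,
            )
            for i, cls in enumerate(["high", "low"])
        ]
        with pytest.raises(ValueError, match="inconsistent dispersal"):
            _table(rows)

    def test_nonpositive_abundance_rejected(self):
        with pytest.raises(ValueError, match="positive integers"):
            _table(
                [
                    dict(
                        transect_id="t0",
                        site="s",
                        x=0.0,
                        y=0.0,
                        species_id="a",
                        abundance=0,
                        dispersal_class="high",
                    )
                ]
            )
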