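"""Co-diffusion detection: pairing, gap closing, fractions, error rates."""

import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from conftest import make_trackset
from paintspt.codiffusion import (ColocErrorModel, PairingParams,
                                  chance_codiffusion, dimer_fraction,
                                  false_negative_rate, interaction_durations,
                                  link_codiffusion, pair_localizations,
                                  sample_apparent_separation)
from paintspt.linking import filter_tracks, link_frames
from paintspt.simulate import (DyeKinetics, SimulationConfig,
                               simulate_membrane)


def _frame_df(points, frame=0):
    df = pd.DataFrame(points, columns=["x", "y"])
    df["frame"] = frame
    return df


class TestPairing:
    def test_distance_just_outside_radius_not_paired(self):
        l1 = _frame_df([(0.0, 0.0)])
        l2 = _frame_df([(0.301, 0.0)])
        assert len(pair_localizations(l1, l2, R=0.300)) == 0

    def test_identical_coordinates_pair_at_zero_distance(self):
        l1 = _frame_df([(1.0, 2.0)])
        l2 = _frame_df([(1.0, 2.0)])
        pairs = pair_localizations(l1, l2, R=0.300)
        assert len(pairs) == 1
        assert pairs["distance"].iloc[0] == 0.0

    def test_three_by_three_matches_permutation_enumeration(self):
        rng = np.random.default_rng(0)
        p1 = rng.uniform(0, 0.5, size=(3, 2))
        p2 = rng.uniform(0, 0.5, size=(3, 2))
        l1, l2 = _frame_df(p1), _frame_df(p2)
        pairs = pair_localizations(l1, l2, R=10.0)
        got = sum(pairs["distance"])
        best = min(sum(np.linalg.norm(p1[i] - p2[perm[i]]) for i in range(3))
                   for perm in permutations(range(3)))
        assert got == pytest.approx(best)
        # one-to-one: no localization reused
        assert pairs["loc_id1"].is_unique and pairs["loc_id2"].is_unique

    def test_translation_equivariance(self):
        """Translating both channels by the same vector leaves pairs intact."""
        rng = np.random.default_rng(1)
        pts1 = rng.uniform(0, 5, size=(8, 2))
        pts2 = pts1[:5] + rng.normal(0, 0.05, size=(5, 2))
        a = pair_localizations(_frame_df(pts1), _frame_df(pts2), 0.3)
        b = pair_localizations(_frame_df(pts1 + 7.3), _frame_df(pts2 + 7.3), 0.3)
        assert a[["loc_id1", "loc_id2"]].equals(b[["loc_id1", "loc_id2"]])


def _coloc_fixture(frames_present):
    """One track pair, colocalized at the given frames (movie length 25)."""
    t1 = make_trackset({0: [(f, 0.0, 0.0) for f in range(25)]}, dt=0.1)
    t2 = make_trackset({10: [(f, 10.0, 10.0) for f in range(25)]}, dt=0.1,
                       channel=2)
    pairs = pd.DataFrame({
        "frame": list(frames_present),
        "loc_id1": [t1.table.set_index("frame").loc[f, "loc_id"]
                    for f in frames_present],
        "loc_id2": [t2.table.set_index("frame").loc[f, "loc_id"]
                    for f in frames_present],
        "distance": 0.0,
    })
    return pairs, t1, t2


class TestEventLinking:
    def test_no_pairs_no_events(self):
        pairs, t1, t2 = _coloc_fixture([])
        res = link_codiffusion(pairs, t1, t2, PairingParams())
        assert len(res.events) == 0

    def test_gap_of_three_closed_event_accepted(self):
        """Colocalized frames 0-4 and 8-14 (gap 3 <= 6): one event spanning
        0-14 with n_coloc = 12 >= 10, accepted."""
        pairs, t1, t2 = _coloc_fixture(list(range(5)) + list(range(8, 15)))
        res = link_codiffusion(pairs, t1, t2, PairingParams())
        assert len(res.events) == 1
        ev = res.events[0]
        assert (ev.start_frame, ev.end_frame, ev.n_coloc) == (0, 14, 12)
        assert ev.duration_s == pytest.approx(15 * 0.1)
        assert ev.gaps == [3]

    def test_gap_of_seven_splits_and_short_episodes_rejected(self):
        """Frames 0-4 and 12-20 (gap 7 > 6): two episodes with n_coloc 5 and
        9, both below 10, both rejected."""
        pairs, t1, t2 = _coloc_fixture(list(range(5)) + list(range(12, 21)))
        res = link_codiffusion(pairs, t1, t2, PairingParams())
        assert len(res.events) == 0
        assert res.n_rejected_episodes == 2

    def test_strict_duration_switch(self):
        pairs, t1, t2 = _coloc_fixture(list(range(10)))
        assert len(link_codiffusion(pairs, t1, t2, PairingParams()).events) == 1
        strict = PairingParams(strict_duration=True)
        assert len(link_codiffusion(pairs, t1, t2, strict).events) == 0

    def test_orphan_pairs_flagged_and_excluded(self):
        pairs, t1, t2 = _coloc_fixture(list(range(12)))
        pairs.loc[0, "loc_id1"] = 99999
        res = link_codiffusion(pairs, t1, t2, PairingParams())
        assert res.n_orphan_pairs == 1
        assert res.events[0].n_coloc == 11


class TestDurationsAndFractions:
    def test_median_of_constructed_durations(self):
        pairs, t1, t2 = _coloc_fixture(list(range(25)))
        res = link_codiffusion(pairs, t1, t2, PairingParams())
        stats = interaction_durations(res)
        assert stats.n == 1
        assert stats.median_s == stats.mean_s == pytest.approx(2.5)
        # order statistics on synthetic duration lists
        from paintspt.codiffusion import CoDiffusionEvent
        evs = [CoDiffusionEvent(i, 0, 0, np.arange(2), 0, 1, 2, d, [])
               for i, d in enumerate([5.0, 10.0, 20.0])]
        st = interaction_durations(evs, dt=0.1)
        assert st.median_s == pytest.approx(10.0)
        assert st.mean_s == pytest.approx(35.0 / 3.0)

    def test_empty_events_flagged(self):
        st = interaction_durations([], dt=0.1)
        assert st.empty and st.n == 0

    def test_dimer_fraction_counting(self):
        """2 accepted pairs among 10+10 visible tracks gives f = 0.2."""
        n_frames = 12
        t1 = make_trackset({i: [(f, 5.0 * i, 0.0) for f in range(n_frames)]
                            for i in range(10)}, dt=0.1)
        t2 = make_trackset({100 + i: [(f, 5.0 * i, 0.0) for f in range(n_frames)]
                            for i in range(10)}, dt=0.1, channel=2)
        rows = []
        for tid in (0, 1):  # two colocalized track pairs, all frames
            sub1 = t1.track(tid).set_index("frame")
            sub2 = t2.track(100 + tid).set_index("frame")
            for f in range(n_frames):
                rows.append((f, sub1.loc[f, "loc_id"], sub2.loc[f, "loc_id"], 0.0))
        pairs = pd.DataFrame(rows, columns=["frame", "loc_id1", "loc_id2",
                                            "distance"])
        res = link_codiffusion(pairs, t1, t2, PairingParams())
        assert len(res.events) == 2
        fr = dimer_fraction(res, t1, t2)
        assert fr.fraction == pytest.approx(2 * 2 / (10 + 10))
        assert fr.sd == pytest.approx(0.0)

    def test_no_events_zero_fraction(self):
        pairs, t1, t2 = _coloc_fixture([])
        res = link_codiffusion(pairs, t1, t2, PairingParams())
        assert dimer_fraction(res, t1, t2).fraction == 0.0


class TestFalseNegativeRate:
    def test_zero_noise_zero_rate(self):
        m = ColocErrorModel(0.0, 0.0, 0.0)
        assert false_negative_rate(m, R=0.3) == 0.0

    def test_paper_conditions_below_bound(self):
        """Worst printed precision (30 nm) plus 32 nm registration at the
        300 nm threshold misses far less than 0.001% of true pairs, in both
        registration conventions."""
        for conv in ("radial", "per_axis"):
            m = ColocErrorModel(0.030, 0.030, 0.032, reg_convention=conv)
            assert 100.0 * false_negative_rate(m, 0.300) < 0.001
        m = ColocErrorModel(0.030, 0.030, 0.032, reg_convention="per_axis")
        # Rayleigh tail exp(-R^2 / (2 sigma_ax^2)) with sigma_ax^2 = 0.002824
        assert false_negative_rate(m, 0.300) == pytest.approx(
            math.exp(-0.09 / (2 * 0.002824)), rel=1e-6)

    def test_monte_carlo_agrees_with_analytic_tail(self):
        """At a radius where the tail is measurable, 1e6 sampled pairs land
        within 3 binomial SE of the Rayleigh/Rice tail."""
        for sep in (0.0, 0.05):
            m = ColocErrorModel(0.030, 0.030, 0.032, true_sep=sep)
            r = 0.12
            p = false_negative_rate(m, r)
            n = 1_000_000
            d = sample_apparent_separation(m, n, seed=17)
            phat = (d > r).mean()
            se = math.sqrt(p * (1 - p) / n)
            assert abs(phat - p) < 3 * se

    def test_rice_tail_exceeds_rayleigh_for_separated_labels(self):
        base = ColocErrorModel(0.03, 0.03, 0.032)
        sep = ColocErrorModel(0.03, 0.03, 0.032, true_sep=0.05)
        assert false_negative_rate(sep, 0.3) > false_negative_rate(base, 0.3)


class TestChanceCoDiffusion:
    def test_zero_density_zero_rate(self):
        ch = chance_codiffusion(0.0, 0.1, seed=0)
        assert ch.events_per_track == 0.0

    def test_static_pair_rate_matches_area_law(self):
        """At D=0 the expected cross-channel pairs per molecule per frame is
        the Poisson area fraction pi R^2 rho (many independent geometries)."""
        ch = chance_codiffusion(0.1, 0.0, dt=0.08, n_frames=12, seed=3,
                                fov_side=30.0, n_reps=40, min_frames=1)
        expect = math.pi * 0.3 ** 2 * 0.1
        assert ch.analytic_static_pairs == pytest.approx(expect)
        # ~40 geometries x ~2.5 pairs: a few-percent MC check
        assert abs(ch.pairs_per_molecule_frame - expect) < 0.2 * expect

    def test_fast_diffusion_breaks_chance_colocalization(self):
        """Accepted false-positive events per track decrease with mobility on
        the mobile branch (residence inside R shrinks below N_min frames)."""
        rates = [chance_codiffusion(0.1, D, dt=0.08, n_frames=150, seed=4,
                                    fov_side=30.0, n_reps=2).events_per_track
                 for D in (0.01, 0.1, 1.0)]
        assert rates[0] >= rates[1] >= rates[2]


class TestPipelineEquivariance:
    def test_translation_of_both_channels_preserves_events(self):
        cfg = SimulationConfig(fov_side=15.0, n_frames=40, dt=0.08,
                               density_per_channel=0.15, dimer_fraction=0.4,
                               label_model="single_dye",
                               photophysics=DyeKinetics(0.0), seed=21)
        _, l1, l2 = simulate_membrane(cfg)
        shift = np.array([3.5, -2.0])

        def run(a, b):
            t1 = filter_tracks(link_frames(a, dt=cfg.dt))
            t2 = filter_tracks(link_frames(b, dt=cfg.dt))
            pr = pair_localizations(a, b, 0.3)
            res = link_codiffusion(pr, t1, t2, PairingParams())
            fr = dimer_fraction(res, t1, t2)
            return res.to_frame(), fr.fraction

        ev_a, f_a = run(l1, l2)
        l1s, l2s = l1.copy(), l2.copy()
        l1s[["x", "y"]] += shift
        l2s[["x", "y"]] += shift
        ev_b, f_b = run(l1s, l2s)
        assert ev_a.equals(ev_b)
        assert f_a == pytest.approx(f_b)

    def test_noiseless_static_dimers_fully_recovered(self):
        """With zero noise the FNR is exactly 0 and every hetero-labeled
        dimer is detected."""
        cfg = SimulationConfig(fov_side=20.0, n_frames=30, dt=0.08,
                               density_per_channel=0.1, dimer_fraction=0.5,
                               D_mono=0.05, sigma_loc=0.0,
                               sigma_reg_radial=0.0, label_model="single_dye",
                               photophysics=DyeKinetics(0.0), seed=22)
        truth, l1, l2 = simulate_membrane(cfg)
        t1 = filter_tracks(link_frames(l1, dt=cfg.dt), min_D=0.0)
        t2 = filter_tracks(link_frames(l2, dt=cfg.dt), min_D=0.0)
        pairs = pair_localizations(l1, l2, 0.3)
        res = link_codiffusion(pairs, t1, t2, PairingParams())
        # every true dimer is covered by accepted events (an event may split
        # if the tracker reassigns identities during a close encounter, but
        # coverage of the dimer is never lost)
        def truth_map(ts, locs):
            merged = ts.table.merge(locs[["loc_id", "truth_id"]], on="loc_id")
            return merged.groupby("track_id")["truth_id"].agg(
                lambda s: s.mode().iloc[0]).to_dict()

        map1, map2 = truth_map(t1, l1), truth_map(t2, l2)
        covered = set()
        for e in res.events:
            i = map1[e.track_ch1]
            j = map2[e.track_ch2]
            if truth.partner[i] == j:
                covered.add(min(i, j))
        dimer_ids = {min(i, truth.partner[i])
                     for i in np.flatnonzero(truth.partner >= 0)}
        assert covered == dimer_ids
        assert false_negative_rate(ColocErrorModel(0, 0, 0), 0.3) == 0.0
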