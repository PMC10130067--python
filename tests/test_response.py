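import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fnpgrange.config import ResolutionSection
from fnpgrange.constants import FN, FWHM_OVER_SIGMA, PG
from fnpgrange.geometry import DetectorGeometry, bar_center
from fnpgrange.response import (
    apply_energy_cuts,
    resolution_fraction,
    select_coincidences,
    smear_collisions,
)


def make_collisions(det, n=1000, species=FN, seed=0, edep=1.0, spacing_ns=1.0):
    """Synthetic collision table: hits at bar centers, fixed deposits."""
    rng = np.random.default_rng(seed)
    bars = rng.integers(0, det.n_bars, n)
    pos = (np.array([bar_center(b, det) for b in bars])
           if n else np.zeros((0, 3)))
    return pd.DataFrame({
        "event_id": np.arange(n) // 4,
        "species": species,
        "hit_index": np.arange(n) % 4,
        "bar_id": bars,
        "x_mm": pos[:, 0], "y_mm": pos[:, 1], "z_mm": pos[:, 2],
        "t_ns": spacing_ns * (np.arange(n) % 4),
        "edep_MeV": np.full(n, edep),
        "kind": "np_elastic" if species == FN else "compton",
    })


class TestResolutionFraction:
    def test_pg_at_one_mevee(self):
        expected = np.sqrt(0.0497 ** 2 + 0.0349 ** 2)
        assert resolution_fraction(1.0, PG) == pytest.approx(expected, abs=1e-9)
        assert resolution_fraction(1.0, PG) == pytest.approx(0.06073, abs=5e-5)

    def test_fn_scaled_by_two(self):
        assert resolution_fraction(1.0, FN) == pytest.approx(
            2 * resolution_fraction(1.0, PG), rel=1e-12)

    def test_high_light_limit_is_alpha(self):
        assert resolution_fraction(1e9, PG) == pytest.approx(0.0497, rel=1e-6)

    def test_nonpositive_light_rejected(self):
        with pytest.raises(ValueError):
            resolution_fraction(0.0, PG)


class TestEnergyCuts:
    def test_fn_cut_at_100_kev(self):
        det = DetectorGeometry()
        col = make_collisions(det, 2, FN)
        col["edep_MeV"] = [0.099, 0.101]
        kept = apply_energy_cuts(col)
        assert kept["edep_MeV"].tolist() == [0.101]

    def test_pg_cut_at_10_kev(self):
        det = DetectorGeometry()
        col = make_collisions(det, 2, PG)
        col["edep_MeV"] = [0.009, 0.011]
        assert apply_energy_cuts(col)["edep_MeV"].tolist() == [0.011]

    def test_empty_table(self):
        det = DetectorGeometry()
        empty = make_collisions(det, 0)
        assert len(apply_energy_cuts(empty)) == 0


class TestSmearing:
    def test_zero_resolution_is_identity(self):
        det = DetectorGeometry()
        col = make_collisions(det, 200)
        model = ResolutionSection(alpha=0.0, beta=0.0, gamma=0.0,
                                  time_fwhm_ps=0.0, doi_mm=0.0,
                                  segment_resample_mm=0.0, fn_scale=0.0)
        out = smear_collisions(col, det, model, 1)
        for c in ("x_mm", "y_mm", "z_mm", "t_ns", "edep_MeV"):
            assert np.allclose(out[c], col[c], atol=1e-9)

    def test_time_smear_sigma(self):
        det = DetectorGeometry()
        col = make_collisions(det, 100_000, spacing_ns=0.0)
        out = smear_collisions(col, det, rng_seed=2)
        sigma = out["t_ns"].std()
        assert sigma == pytest.approx(0.5 / FWHM_OVER_SIGMA, rel=0.01)

    def test_transverse_within_segment_resample_window(self):
        det = DetectorGeometry()
        col = make_collisions(det, 5000)
        out = smear_collisions(col, det, rng_seed=3)
        local = det.world_to_local(out[["x_mm", "y_mm", "z_mm"]].to_numpy())
        centers = np.array([bar_center(b, det) for b in out["bar_id"]])
        centers_l = det.world_to_local(centers)
        for axis in (1, 2):
            delta = np.abs(local[:, axis] - centers_l[:, axis])
            assert delta.max() <= 2.5 + 1e-9

    def test_counts_preserved_energies_positive_deterministic(self):
        det = DetectorGeometry()
        col = make_collisions(det, 3000, edep=0.02, species=PG)
        a = smear_collisions(col, det, rng_seed=4)
        b = smear_collisions(col, det, rng_seed=4)
        assert len(a) == len(col)
        assert (a["edep_MeV"] > 0).all()  # truncation by redraw
        assert a.equals(b)

    def test_time_order_swap_probability(self):
        # two hits dt apart; after independent Gaussian smears the swap
        # probability is Phi(-dt / (sigma * sqrt(2)))
        det = DetectorGeometry()
        dt = 0.2
        col = make_collisions(det, 2 * 20_000, spacing_ns=0.0)
        col["event_id"] = np.arange(len(col)) // 2
        col["hit_index"] = np.arange(len(col)) % 2
        col["t_ns"] = np.where(col["hit_index"] == 0, 0.0, dt)
        out = smear_collisions(col, det, rng_seed=5)
        t = out.sort_values(["event_id", "hit_index"])["t_ns"].to_numpy()
        swapped = (t[1::2] - t[::2] < 0).mean()
        sigma = 0.5 / FWHM_OVER_SIGMA
        expected = stats.norm.cdf(-dt / (sigma * np.sqrt(2)))
        assert swapped == pytest.approx(expected, abs=0.01)


class TestCoincidences:
    def _event(self, det, bars, times, species=FN, kinds=None):
        n = len(bars)
        pos = np.array([bar_center(b, det) for b in bars])
        return pd.DataFrame({
            "event_id": 0, "species": species, "hit_index": np.arange(n),
            "bar_id": bars,
            "x_mm": pos[:, 0], "y_mm": pos[:, 1], "z_mm": pos[:, 2],
            "t_ns": times, "edep_MeV": 1.0,
            "kind": kinds if kinds is not None
            else ("np_elastic" if species == FN else "compton"),
        })

    def test_single_collision_rejected(self):
        det = DetectorGeometry()
        sel, tally = select_coincidences(self._event(det, [0], [0.0]), FN)
        assert len(sel) == 0
        assert tally.n_rejected_multiplicity == 1

    def test_two_earliest_selected(self):
        det = DetectorGeometry()
        ev = self._event(det, [5, 9, 13], [2.0, 0.5, 1.0])
        sel, tally = select_coincidences(ev, FN)
        assert tally.n_selected == 1
        assert sel.sort_values("rank")["bar_id"].tolist() == [9, 13]

    def test_pg_same_bar_rejected(self):
        det = DetectorGeometry()
        ev = self._event(det, [4, 4, 7], [0.0, 1.0, 2.0], species=PG)
        sel, tally = select_coincidences(ev, PG)
        assert len(sel) == 0 and tally.n_rejected_same_bar == 1

    def test_tally_balances(self):
        det = DetectorGeometry()
        frames = []
        for i, bars in enumerate([[0], [1, 2], [3, 3], [4, 5, 6]]):
            f = self._event(det, bars, np.arange(len(bars), dtype=float))
            f["event_id"] = i
            frames.append(f)
        col = pd.concat(frames, ignore_index=True)
        sel, tally = select_coincidences(col, FN)
        assert tally.n_events == (tally.n_selected + tally.n_rejected_multiplicity
                                  + tally.n_rejected_same_bar)
        assert tally.n_selected == 2  # [1,2] and [4,5,...]
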