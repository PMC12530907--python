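"""Grid sweep and threshold detection along q-slices."""

import numpy as np
import pytest

from slnbcost.grid import (
    GridResult,
    GridSpec,
    Thresholds,
    default_grid,
    find_thresholds,
    run_grid,
)
from slnbcost.strategy import CellResult

from conftest import point_mass_params, table_params


class TestGridSpec:
    def test_default_dimensions(self):
        grid = default_grid()
        assert len(grid.p_values) == 92
        assert len(grid.q_values) == 13
        assert grid.n_cells == 1196
        assert grid.p_values[0] == 0.09 and grid.p_values[-1] == 1.0
        # the 5.7% endpoint is off-step and included explicitly
        assert grid.q_values[-1] == 0.057

    def test_validation(self):
        with pytest.raises(ValueError, match="p_values"):
            GridSpec(p_values=(0.5, 1.2), q_values=(0.0,))
        with pytest.raises(ValueError, match="increasing"):
            GridSpec(p_values=(0.5, 0.5), q_values=(0.0,))
        with pytest.raises(ValueError, match="non-empty"):
            GridSpec(p_values=(), q_values=(0.0,))


class TestRunGrid:
    def test_toy_grid_exact_point_mass_differences(self):
        # degenerate probabilities + point-mass costs: every pathway is
        # deterministic, so cell means equal the analytic expectations exactly
        grid = GridSpec(p_values=(0.0, 1.0), q_values=(0.0, 1.0))
        result = run_grid(grid, point_mass_params(0.0, 0.0), master_seed=1)
        assert len(result.cells) == 4
        for cell in result.cells:
            p, q = cell.p_occult, cell.q_notfound
            expected_slnb = (1 - q) * (100.0 + p * 50.0) + q * 200.0
            assert cell.mean_diff == pytest.approx(200.0 - expected_slnb)

    def test_cells_match_grid_positions(self):
        grid = GridSpec(p_values=(0.1, 0.3, 0.5), q_values=(0.0, 0.02))
        result = run_grid(grid, table_params(0.0, 0.0, n_per_arm=50), master_seed=3)
        coords = {(c.p_occult, c.q_notfound) for c in result.cells}
        assert coords == {(p, q) for p in grid.p_values for q in grid.q_values}

    def test_determinism(self):
        grid = GridSpec(p_values=(0.1, 0.6), q_values=(0.0,))
        params = table_params(0.0, 0.0, n_per_arm=100)
        assert run_grid(grid, params, 42) == run_grid(grid, params, 42)

    def test_frame_roundtrip(self, tmp_path):
        grid = GridSpec(p_values=(0.1, 0.6), q_values=(0.0,))
        result = run_grid(grid, table_params(0.0, 0.0, n_per_arm=50), 5)
        path = tmp_path / "grid.csv"
        result.to_csv(path)
        import pandas as pd

        back = pd.read_csv(path)
        assert len(back) == 2
        assert np.allclose(back["mean_diff"], [c.mean_diff for c in result.cells])


def _slice_result(flags, p_start=0.09):
    """Build a synthetic one-q GridResult from (significant, direction) flags."""
    p_values = tuple(round(p_start + 0.01 * i, 2) for i in range(len(flags)))
    cells = []
    for p, (sig, direction) in zip(p_values, flags):
        diff = 1.0 if direction == "slnb_cheaper" else -1.0 if direction == "snd_cheaper" else 0.0
        cells.append(CellResult(
            p_occult=p, q_notfound=0.0, n_per_arm=1000,
            mean_slnb=0.0, sd_slnb=1.0, mean_snd=diff, sd_snd=1.0,
            mean_diff=diff, test_statistic=0.0,
            p_value=0.01 if sig else 0.5, significant=sig, direction=direction,
        ))
    spec = GridSpec(p_values=p_values, q_values=(0.0,))
    return GridResult(spec=spec, cells=tuple(cells), master_seed=0,
                      n_per_arm=1000, alpha=0.05, test_method="welch")


def _scan_oracle(flags, run_length):
    """Exhaustive scan over all window starts (independent of the scan code)."""
    qualifying_ns = [not (s and d == "slnb_cheaper") for s, d in flags]
    qualifying_rev = [s and d == "snd_cheaper" for s, d in flags]

    def first(qual):
        for i in range(len(qual) - run_length + 1):
            if all(qual[i:i + run_length]):
                return i
        return None

    return first(qualifying_ns), first(qualifying_rev)


class TestFindThresholds:
    def test_printed_pattern(self):
        """A slice shaped like the published result: the SLNB advantage is
        significant below 56%, the difference non-significant in 56-71%, and
        reversed above 72%."""
        flags = []
        for i in range(92):
            p = round(0.09 + 0.01 * i, 2)
            if p < 0.56:
                flags.append((True, "slnb_cheaper"))
            elif p < 0.72:
                flags.append((False, "slnb_cheaper"))
            else:
                flags.append((True, "snd_cheaper"))
        thr = find_thresholds(_slice_result(flags), 0.0, run_length=3)
        assert thr.first_nonsignificant_p == pytest.approx(0.56)
        assert thr.first_reversal_p == pytest.approx(0.72)

    def test_always_cheaper_gives_none(self):
        flags = [(True, "slnb_cheaper")] * 30
        thr = find_thresholds(_slice_result(flags), 0.0, run_length=3)
        assert thr.first_nonsignificant_p is None
        assert thr.first_reversal_p is None

    def test_isolated_flip_is_ignored(self):
        """A single non-significant cell at p=40% must not set the threshold;
        the sustained band starting at 66% does."""
        flags = []
        for i in range(92):
            p = round(0.09 + 0.01 * i, 2)
            if p == 0.40:
                flags.append((False, "slnb_cheaper"))
            elif p < 0.66:
                flags.append((True, "slnb_cheaper"))
            else:
                flags.append((False, "slnb_cheaper"))
        result = _slice_result(flags)
        thr = find_thresholds(result, 0.0, run_length=3)
        assert thr.first_nonsignificant_p == pytest.approx(0.66)
        # first-occurrence detection disagrees by design
        thr1 = find_thresholds(result, 0.0, run_length=1)
        assert thr1.first_nonsignificant_p == pytest.approx(0.40)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_scan_oracle_on_random_slices(self, seed):
        rng = np.random.default_rng(seed)
        flags = []
        for _ in range(60):
            sig = bool(rng.random() < 0.5)
            direction = rng.choice(["slnb_cheaper", "snd_cheaper"])
            flags.append((sig, str(direction)))
        result = _slice_result(flags)
        for run_length in (1, 2, 3, 5):
            thr = find_thresholds(result, 0.0, run_length=run_length)
            i_ns, i_rev = _scan_oracle(flags, run_length)
            exp_ns = result.spec.p_values[i_ns] if i_ns is not None else None
            exp_rev = result.spec.p_values[i_rev] if i_rev is not None else None
            assert thr.first_nonsignificant_p == exp_ns
            assert thr.first_reversal_p == exp_rev

    def test_ordering_when_both_exist(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            flags = [(bool(rng.random() < 0.6),
                      str(rng.choice(["slnb_cheaper", "snd_cheaper"])))
                     for _ in range(50)]
            thr = find_thresholds(_slice_result(flags), 0.0, run_length=3)
            if thr.first_nonsignificant_p is not None and thr.first_reversal_p is not None:
                assert thr.first_nonsignificant_p <= thr.first_reversal_p

    def test_unknown_q_is_lookup_error(self):
        result = _slice_result([(True, "slnb_cheaper")] * 5)
        with pytest.raises(KeyError):
            find_thresholds(result, 0.01)


def test_plot_writes_figure(tmp_path):
    grid = GridSpec(p_values=(0.1, 0.5, 0.9), q_values=(0.0,))
    result = run_grid(grid, table_params(0.0, 0.0, n_per_arm=100), 2)
    from slnbcost.grid import plot_cost_curve

    out = tmp_path / "curve.png"
    plot_cost_curve(result, 0.0, out)
    assert out.stat().st_size > 0
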