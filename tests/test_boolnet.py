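"""Boolean engine: parser, CTMC statistics, fate readouts, fixture behaviour."""

import numpy as np
import pytest

from tumorpulse import _kernels
from tumorpulse.boolnet import (NetworkParseError, RandomStream, ctmc_step,
                                fate_readout, load_network, parse_network)


def run_many(net, dt, n, start_on=(), clamp=None, seed_base=0):
    """n independent trajectories advanced by dt; returns the value matrix."""
    vals = np.tile(net.initial_state(start_on).values, (n, 1))
    if clamp:
        for name, v in clamp.items():
            vals[:, net.index(name)] = v
    ids = np.arange(n, dtype=np.int64)
    keys = _kernels.make_keys(seed_base, ids, _kernels.PUR_CTMC)
    counters = np.zeros(n, dtype=np.uint64)
    _kernels.gillespie_window(vals, net.is_input, net.rate_up, net.rate_down,
                              net.code, net.arg, net.starts, net.ends,
                              float(dt), keys, counters)
    return vals


class TestParser:
    def test_single_node_document(self):
        net = parse_network("X : 1 : 0.1 : 0.2\n")
        assert net.names == ["X"]
        assert net.rate_up[0] == 0.1 and net.rate_down[0] == 0.2

    def test_surrogate_fixture_shape(self):
        net = load_network()
        assert net.n_nodes == 6
        assert set(net.readouts) == {"proliferation", "apoptosis", "nonacd"}
        assert net.is_input[net.index("TNF")]

    def test_unknown_identifier_named_in_error(self):
        with pytest.raises(NetworkParseError, match="Survivall"):
            parse_network("A : Survivall & B : 0.1 : 0\nB : 1 : 0.1 : 0\n")

    def test_malformed_rate_reports_line(self):
        with pytest.raises(NetworkParseError, match="line 2"):
            parse_network("A : 1 : 0.1 : 0\nB : A : fast : 0\n")

    def test_comments_and_feedback_loops_allowed(self):
        net = parse_network(
            "# a toggle\nX : !Y : 0.1 : 0.1\nY : !X : 0.1 : 0.1\n")
        assert net.n_nodes == 2

    def test_duplicate_node_rejected(self):
        with pytest.raises(NetworkParseError, match="duplicate"):
            parse_network("A : 1 : 0.1 : 0\nA : 0 : 0.1 : 0\n")


class TestCTMCStatistics:
    def test_one_node_activation_matches_analytic(self):
        """P(ON at t) = 1 - exp(-u*t) for a node with constant-true logic."""
        net = parse_network("X : 1 : 0.1 : 0\n")
        vals = run_many(net, 30.0, 10_000)
        frac = vals[:, 0].mean()
        assert frac == pytest.approx(1 - np.exp(-3.0), abs=0.01)

    def test_all_nodes_stable_identical_values(self):
        net = parse_network("X : X : 0.5 : 0.5\nY : Y : 0.5 : 0.5\n")
        s = net.initial_state(("X",))
        before = s.values.copy()
        ctmc_step(net, s, 1e4, RandomStream(0))
        assert np.array_equal(s.values, before)
        assert s.clock == 1e4

    def test_clock_advances_exactly(self):
        net = parse_network("X : 1 : 0.1 : 0\n")
        s = net.initial_state()
        ctmc_step(net, s, 12.5, RandomStream(1))
        assert s.clock == 12.5

    def test_two_node_toggle_absorbs_half_half(self):
        """Hand-solved chain: from (0,0) the toggle X=!Y, Y=!X absorbs in
        (1,0) or (0,1) with probability 1/2 each; (1,1) is transient."""
        net = parse_network("X : !Y : 0.1 : 0.1\nY : !X : 0.1 : 0.1\n")
        vals = run_many(net, 1e5, 10_000)
        x, y = vals[:, 0], vals[:, 1]
        assert np.all(x ^ y), "all trajectories reach an absorbing state"
        assert x.mean() == pytest.approx(0.5, abs=0.02)

    def test_rate_scaling_rescales_time(self):
        """Scaling all rates by c and time by 1/c leaves statistics alike."""
        net_slow = parse_network("X : 1 : 0.05 : 0\n")
        net_fast = parse_network("X : 1 : 0.5 : 0\n")
        f_slow = run_many(net_slow, 40.0, 10_000)[:, 0].mean()
        f_fast = run_many(net_fast, 4.0, 10_000, seed_base=1)[:, 0].mean()
        assert f_slow == pytest.approx(f_fast, abs=0.02)
        assert f_slow == pytest.approx(1 - np.exp(-2.0), abs=0.01)


class TestFateReadout:
    def test_all_off_is_quiescent(self, surrogate):
        s = surrogate.initial_state()
        assert fate_readout(surrogate, s) == "quiescent"

    def test_death_precedence_over_proliferation(self, surrogate):
        s = surrogate.initial_state(("Proliferation", "Apoptosis"))
        assert fate_readout(surrogate, s) == "apoptotic"

    def test_nonacd_maps_to_necrotic(self, surrogate):
        s = surrogate.initial_state(("NonACD",))
        assert fate_readout(surrogate, s) == "necrotic"

    def test_proliferation_only(self, surrogate):
        s = surrogate.initial_state(("Proliferation",))
        assert fate_readout(surrogate, s) == "proliferative"

    def test_both_death_nodes_on_is_error(self, surrogate):
        s = surrogate.initial_state(("Apoptosis", "NonACD"))
        with pytest.raises(ValueError, match="broken"):
            fate_readout(surrogate, s)


class TestSurrogateBehaviour:
    """Regression bounds frozen from calibration oracle runs of the shipped
    fixture (continuous-time Markov chain solved analytically where noted)."""

    def test_commitment_is_irreversible(self, surrogate):
        net = surrogate
        locked = [net.index(n) for n in ("Apoptosis", "NonACD", "Survival")]
        vals = np.tile(net.initial_state(("Proliferation",)).values, (400, 1))
        vals[:, net.index("TNF")] = 1
        ids = np.arange(400, dtype=np.int64)
        keys = _kernels.make_keys(7, ids, _kernels.PUR_CTMC)
        counters = np.zeros(400, dtype=np.uint64)
        prev = vals[:, locked].copy()
        for _ in range(200):  # 200 x 30 min = 100 h of TNF exposure
            _kernels.gillespie_window(
                vals, net.is_input, net.rate_up, net.rate_down, net.code,
                net.arg, net.starts, net.ends, 30.0, keys, counters)
            cur = vals[:, locked]
            assert np.all(cur >= prev), "a committed node switched off"
            prev = cur.copy()

    def test_sustained_tnf_breeds_survival_locked_resisters(self, surrogate):
        """Sustained exposure: the death race kills most cells, but the cells
        that activate NFkB first lock Survival and never die (analytic chain:
        death 0.889, locked 0.111)."""
        net = surrogate
        vals = run_many(net, 4640.0, 4000, start_on=("Proliferation",),
                        clamp={"TNF": 1})
        dead = ((vals[:, net.index("Apoptosis")] == 1)
                | (vals[:, net.index("NonACD")] == 1))
        locked = vals[:, net.index("Survival")] == 1
        assert dead.mean() == pytest.approx(0.889, abs=0.03)
        assert locked[~dead].mean() > 0.9

    def test_single_window_kills_without_locking(self, surrogate):
        """One 30-min TNF window commits >=25% to death and locks <10%."""
        net = surrogate
        vals = np.tile(net.initial_state(("Proliferation",)).values,
                       (4000, 1))
        vals[:, net.index("TNF")] = 1
        ids = np.arange(4000, dtype=np.int64)
        keys = _kernels.make_keys(3, ids, _kernels.PUR_CTMC)
        counters = np.zeros(4000, dtype=np.uint64)
        _kernels.gillespie_window(vals, net.is_input, net.rate_up,
                                  net.rate_down, net.code, net.arg,
                                  net.starts, net.ends, 30.0, keys, counters)
        vals[:, net.index("TNF")] = 0
        _kernels.gillespie_window(vals, net.is_input, net.rate_up,
                                  net.rate_down, net.code, net.arg,
                                  net.starts, net.ends, 300.0, keys, counters)
        dead = ((vals[:, net.index("Apoptosis")] == 1)
                | (vals[:, net.index("NonACD")] == 1)).mean()
        locked = (vals[:, net.index("Survival")] == 1).mean()
        assert dead >= 0.25
        assert locked < 0.10
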