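"""Viterbi-path kinetics: dwells, rates, entry conditioning, 4-state split."""

import numpy as np
import pytest

from porekin.hmm import HmmModel
from porekin.kinetics import (
    ESCAPE,
    build_four_state_model,
    dwell_segments,
    entry_conditioned_mid_stats,
    rate_voltage_dependence,
    segments_for_events,
    transition_rates,
    voltage_specific_refit,
)
from porekin.signals import Event
from porekin.synthetic import simulate_event


def _well_separated(A, pi=None):
    K = len(A)
    q = np.linspace(0.1, 0.9, K)
    return HmmModel(pi=np.full(K, 1 / K) if pi is None else pi,
                    A=np.asarray(A, dtype=float), q=q, b=np.full(K, 0.015))


def _events_from_chain(model, n_events, length, rng, dt=0.00299):
    out = []
    for i in range(n_events):
        _, values = simulate_event(model, np.zeros(model.K), rng, max_len=length)
        out.append(Event(values=values, voltage_mV=200.0, dt_s=dt, event_id=i))
    return out


# ---------------------------------------------------------------- dwells

def test_dwell_run_length_encoding():
    segs = dwell_segments(np.array([0, 0, 1, 1, 1, 0]), event_id=5, dt_s=1.0)
    assert [(s.state, s.duration_points, s.entry_state, s.exit_state)
            for s in segs] == [(0, 2, None, 1), (1, 3, 0, 0), (0, 1, 1, ESCAPE)]
    assert sum(s.duration_points for s in segs) == 6
    assert all(s.event_id == 5 for s in segs)


def test_dwell_constant_and_alternating_paths():
    only, = dwell_segments(np.zeros(7, dtype=int))
    assert (only.entry_state, only.exit_state) == (None, ESCAPE)
    segs = dwell_segments(np.array([0, 1, 0, 1]))
    assert len(segs) == 4 and all(s.duration_points == 1 for s in segs)


# ---------------------------------------------------------------- rates

def test_transition_rate_counting_single_event():
    segs = dwell_segments(np.array([0, 0, 1, 1, 1, 0]), dt_s=1.0)
    table = transition_rates(segs, K=2, n_boot=10,
                             rng=np.random.default_rng(0))
    # escape exit of the final dwell excluded from N, included in T
    assert table.N[0, 1] == 1 and table.N[1, 0] == 1
    assert table.T_s[0] == 3.0 and table.T_s[1] == 3.0
    assert table.rate_hz[0, 1] == pytest.approx(1 / 3)
    assert table.rate_hz[1, 0] == pytest.approx(1 / 3)


def test_rates_recover_generator_transition_probs(rng):
    dt = 0.00299
    A = np.array([[0.95, 0.04, 0.01],
                  [0.05, 0.90, 0.05],
                  [0.02, 0.08, 0.90]])
    model = _well_separated(A)
    events = _events_from_chain(model, 300, 200, rng, dt)
    segs = segments_for_events(events, model)
    table = transition_rates(segs, K=3, n_boot=300, rng=rng)
    for i in range(3):
        for j in range(3):
            if i == j:
                continue
            expected = A[i, j] / dt
            assert abs(table.rate_hz[i, j] - expected) <= \
                3 * max(table.se_hz[i, j], 1e-9)


def test_segment_conservation_invariant(rng):
    model = _well_separated([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])
    events = _events_from_chain(model, 50, 40, rng)
    segs = segments_for_events(events, model)
    table = transition_rates(segs, K=3, n_boot=1, rng=rng)
    for i in range(3):
        n_segments_i = sum(1 for s in segs if s.state == i)
        escapes_i = sum(1 for s in segs
                        if s.state == i and s.exit_state == ESCAPE)
        assert table.N[i].sum() + escapes_i == n_segments_i


def test_no_transition_gives_zero_rate():
    segs = dwell_segments(np.array([0, 0, 0]), dt_s=1.0)
    table = transition_rates(segs, K=2, n_boot=20,
                             rng=np.random.default_rng(0))
    assert table.rate_hz[0, 1] == 0.0
    assert table.se_hz[0, 1] >= 0.0
    assert table.undefined[1]          # state 1 never occupied
    assert np.isnan(table.rate_hz[1, 0])


def test_mean_dwell_matches_self_transition(rng):
    """Viterbi dwell times ~ dt/(1-a_ii) for well-separated emissions."""
    dt = 0.00299
    a_ii = 0.9
    model = _well_separated([[a_ii, 0.1], [0.1, a_ii]][:2])
    # long sequences: interior dwells are then nearly free of the
    # boundary-censoring bias against long dwells
    events = _events_from_chain(model, 60, 500, rng, dt)
    segs = segments_for_events(events, model)
    # interior dwells only: first/last are entry/exit censored
    durs = [s.duration_points for s in segs
            if s.entry_state is not None and s.exit_state != ESCAPE]
    assert len(durs) > 1000
    expected = 1 / (1 - a_ii)
    assert abs(np.mean(durs) - expected) / expected < 0.10


# ---------------------------------------------------------------- refit

def test_voltage_refit_freezes_emissions(rng, wt_model):
    events = [Event(values=simulate_event(wt_model, [0.02, 0.05, 0.05], rng)[1],
                    voltage_mV=200.0) for _ in range(40)]
    fit = voltage_specific_refit(events, wt_model, max_iter=20)
    assert fit.model.q.tobytes() == wt_model.q.tobytes()
    assert fit.model.b.tobytes() == wt_model.b.tobytes()


def test_voltage_refit_recovers_perturbed_A(rng):
    dt = 0.00299
    A_true = np.array([[0.90, 0.08, 0.02],
                       [0.06, 0.88, 0.06],
                       [0.02, 0.08, 0.90]])
    model_true = _well_separated(A_true)
    events = _events_from_chain(model_true, 500, 100, rng, dt)
    init = HmmModel(pi=np.full(3, 1 / 3), A=np.full((3, 3), 1 / 3),
                    q=model_true.q, b=model_true.b)
    fit = voltage_specific_refit(events, init)
    tv = 0.5 * np.abs(fit.model.A - A_true).sum(axis=1)
    assert np.max(tv) < 0.05


def test_refit_on_self_generated_data_gains_little(rng):
    model = _well_separated([[0.9, 0.05, 0.05], [0.05, 0.9, 0.05],
                             [0.05, 0.05, 0.9]])
    events = _events_from_chain(model, 200, 60, rng)
    fit = voltage_specific_refit(events, model)
    gain = (fit.loglik_trajectory[-1] - fit.loglik_trajectory[0]) / len(events)
    assert gain < 1e-1          # per-event gain is marginal on self data


# ------------------------------------------------- entry conditioning

def test_entry_conditioned_counting_example():
    # 0=H, 1=M, 2=L in this constructed path
    segs = dwell_segments(np.array([0, 1, 0, 1, 2, 1, 2]), dt_s=1.0)
    cond = entry_conditioned_mid_stats(segs, mid_state=1, high_state=0,
                                       low_state=2, n_boot=5,
                                       rng=np.random.default_rng(0))
    fh, fl = cond["from_high"], cond["from_low"]
    assert fh.n_segments == 2
    assert fh.N_out == {0: 1, 2: 1}
    assert fl.n_segments == 1
    assert fl.N_out == {0: 0, 2: 1}


def test_first_dwell_contributes_no_conditioned_segment():
    segs = dwell_segments(np.array([1, 1, 0]), dt_s=1.0)   # starts in mid
    cond = entry_conditioned_mid_stats(segs, mid_state=1, high_state=0,
                                       low_state=2, n_boot=2,
                                       rng=np.random.default_rng(0))
    assert cond["from_high"].n_segments == 0
    assert not cond["from_high"].defined
    assert cond["from_high"].rate_hz[0] is None


def _four_state_generator(ratio=30.0, p_exit=0.15):
    """(L, M_L, M_H, H) chain; the two mid states share emissions.

    M_H exits to H at p_exit and to L at p_exit/ratio (M_L mirrored), so a
    3-state analysis of this chain should see a ~ratio entry-conditioned
    asymmetry in the merged mid state.
    """
    p_small = p_exit / ratio
    stay = 1 - p_exit - p_small
    A = np.array([
        # L     M_L    M_H    H
        [0.90, 0.10, 0.00, 0.00],
        [p_exit, stay, 0.00, p_small],
        [p_small, 0.00, stay, p_exit],
        [0.00, 0.00, 0.10, 0.90],
    ])
    q = np.array([0.10, 0.45, 0.45, 0.80])
    b = np.array([0.015, 0.015, 0.015, 0.015])
    return HmmModel(pi=np.array([0.4, 0.1, 0.1, 0.4]), A=A, q=q, b=b)


def test_entry_conditioned_ratio_survives_3state_inference(rng):
    """A hidden mid-state split (30x exit asymmetry) shows up as a >=10x
    entry-conditioned rate ratio after 3-state Viterbi analysis."""
    gen = _four_state_generator(ratio=30.0)
    events = []
    for i in range(400):
        _, values = simulate_event(gen, np.zeros(4), rng, max_len=120)
        events.append(Event(values=values, voltage_mV=200.0, event_id=i))
    three = HmmModel(pi=np.array([1 / 3] * 3),
                     A=np.full((3, 3), 1 / 3),
                     q=np.array([0.10, 0.45, 0.80]),
                     b=np.array([0.015, 0.015, 0.015]))
    segs = segments_for_events(events, three)
    cond = entry_conditioned_mid_stats(segs, mid_state=1, high_state=2,
                                       low_state=0, n_boot=50, rng=rng)
    k_hh = cond["from_high"].rate_hz[2]      # M->H after entry from H
    k_lh = cond["from_low"].rate_hz[2]       # M->H after entry from L
    k_ll = cond["from_low"].rate_hz[0]
    k_hl = cond["from_high"].rate_hz[0]
    assert k_hh / max(k_lh, 1e-9) >= 10.0
    assert k_ll / max(k_hl, 1e-9) >= 10.0


def test_memoryless_negative_control(rng):
    """On genuinely 3-state data the conditioned rates agree within error."""
    A = np.array([[0.90, 0.09, 0.01],
                  [0.06, 0.88, 0.06],
                  [0.01, 0.09, 0.90]])
    model = _well_separated(A)
    events = _events_from_chain(model, 500, 120, rng)
    segs = segments_for_events(events, model)
    cond = entry_conditioned_mid_stats(segs, mid_state=1, high_state=2,
                                       low_state=0, n_boot=200, rng=rng)
    for to_state in (0, 2):
        r_h = cond["from_high"].rate_hz[to_state]
        r_l = cond["from_low"].rate_hz[to_state]
        se = np.hypot(cond["from_high"].se_hz[to_state],
                      cond["from_low"].se_hz[to_state])
        assert abs(r_h - r_l) < 3 * se


def test_unconditioned_rate_is_occupancy_weighted_average(rng):
    """k_M->j equals the T-weighted mean of the entry-conditioned rates
    (plus the entry-None dwells) — checked as an algebraic identity."""
    states = rng.integers(0, 3, 500)
    segs = dwell_segments(states, dt_s=1.0)
    mid = 1
    parts = {}
    for entry in (0, 2, None):
        p = [s for s in segs if s.state == mid and s.entry_state == entry]
        parts[entry] = p
    total_T = sum(s.duration_s for s in segs if s.state == mid)
    for to_state in (0, 2):
        total_N = sum(1 for s in segs if s.state == mid and s.exit_state == to_state)
        acc = 0.0
        for p in parts.values():
            T = sum(s.duration_s for s in p)
            if T == 0:
                continue
            k = sum(1 for s in p if s.exit_state == to_state) / T
            acc += k * T
        assert acc / total_T == pytest.approx(total_N / total_T, rel=1e-12)


# ---------------------------------------------------------------- 4-state

def test_four_state_degenerate_equals_three_state(rng):
    # conditioned exits identical by construction: memoryless generator
    A = np.array([[0.9, 0.1, 0.0], [0.05, 0.9, 0.05], [0.0, 0.1, 0.9]])
    model = _well_separated(A)
    events = _events_from_chain(model, 400, 100, rng)
    segs = segments_for_events(events, model)
    fsm = build_four_state_model(segs, model, mid_state=1)
    i_mh = fsm.state_names.index("M_H")
    i_ml = fsm.state_names.index("M_L")
    assert np.abs(fsm.A.sum(axis=1) - 1).max() < 1e-9
    # the two mid rows reproduce the same dynamics (exit-to-H, exit-to-L,
    # stay) within sampling error of the shared truth
    i_h = fsm.state_names.index("H")
    i_l = fsm.state_names.index("L")
    row_mh = (fsm.A[i_mh, i_h], fsm.A[i_mh, i_l], fsm.A[i_mh, i_mh])
    row_ml = (fsm.A[i_ml, i_h], fsm.A[i_ml, i_l], fsm.A[i_ml, i_ml])
    assert np.max(np.abs(np.subtract(row_mh, row_ml))) < 0.02
    assert fsm.q[i_mh] == fsm.q[i_ml] and fsm.b[i_mh] == fsm.b[i_ml]


def test_four_state_recovery_of_exit_probs(rng):
    gen = _four_state_generator(ratio=30.0, p_exit=0.15)
    events = []
    for i in range(2000):
        _, values = simulate_event(gen, np.zeros(4), rng, max_len=60)
        events.append(Event(values=values, voltage_mV=200.0, event_id=i))
    three = HmmModel(pi=np.array([1 / 3] * 3),
                     A=np.full((3, 3), 1 / 3),
                     q=np.array([0.10, 0.45, 0.80]),
                     b=np.array([0.015, 0.015, 0.015]))
    segs = segments_for_events(events, three)
    fsm = build_four_state_model(segs, three, mid_state=1)
    i_mh = fsm.state_names.index("M_H")
    i_ml = fsm.state_names.index("M_L")
    i_h = fsm.state_names.index("H")
    i_l = fsm.state_names.index("L")
    assert abs(fsm.A[i_mh, i_h] - 0.15) < 0.05
    assert abs(fsm.A[i_ml, i_l] - 0.15) < 0.05
    assert fsm.A[i_mh, i_l] < 0.05 and fsm.A[i_ml, i_h] < 0.05


def test_four_state_empty_partition_errors():
    segs = dwell_segments(np.array([2, 1, 2]), dt_s=1.0)  # never entered from low
    model = HmmModel(pi=[1 / 3] * 3, A=np.full((3, 3), 1 / 3),
                     q=[0.1, 0.45, 0.8], b=[0.02] * 3)
    with pytest.raises(ValueError, match="more data"):
        build_four_state_model(segs, model, mid_state=1)


# ---------------------------------------------------------------- V-dependence

def test_rate_voltage_dependence_exact_and_flat(rng):
    from porekin.kinetics import RateTable

    def table(v, k):
        r = np.array([[0.0, k], [0.5, 0.0]])
        return RateTable(K=2, N=np.ones((2, 2)), T_s=np.ones(2),
                         rate_hz=r, se_hz=np.zeros((2, 2)),
                         undefined=np.zeros(2, bool), voltage_mV=v)

    volts = [160.0, 180.0, 200.0, 220.0, 240.0]
    tables = [table(v, 2.0 * np.exp(v / 50.0)) for v in volts]
    fit, flat = rate_voltage_dependence(tables, (0, 1))
    assert not flat
    assert fit.voltage_scale_mV == pytest.approx(50.0, rel=1e-10)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    noisy = [table(v, 3.0 * np.exp(rng.normal(0, 0.02))) for v in volts]
    fit2, flat2 = rate_voltage_dependence(noisy, (0, 1))
    assert flat2 and np.isinf(fit2.voltage_scale_mV)
    assert abs(fit2.slope) < 2 * fit2.slope_se

    with pytest.raises(ValueError):
        rate_voltage_dependence([tables[0]], (0, 1))
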