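# porekin

Single-molecule nanopore analysis of protein capture events with
Gaussian-emission hidden Markov models.

When a single protein is captured electrophoretically in an α-hemolysin
nanopore, the ionic current through the pore drops from the open-pore level
I₀ to a fluctuating blockade level.  The normalized current I/I₀ during a
capture event carries detailed information about the conformational
dynamics of the trapped molecule: wild-type prion protein (PrP^C) and a
point mutant can show visibly different blockade histograms and kinetics.
`porekin` implements the full analysis chain for such recordings, plus a
synthetic-trace generator so every stage can be exercised and validated
without access to amplifier recordings:

1. **Signal processing** — median decimation of the 100 kHz trace to
   2.99 ms per datapoint, hysteresis event detection, normalization by the
   local open-pore current, capture-rate and event-lifetime statistics with
   bootstrap errors, and exponential voltage fits
   R(V) = R₀·exp(V/V_R).
2. **HMM core** — a K-state hidden Markov model with parameters
   (π, A, q, b): initial-state probabilities π, transition matrix A, and
   per-state Gaussian emissions with mean q and SD b in I/I₀ units.
   Provided: exact scaled forward likelihood log P(E|λ), Viterbi decoding,
   multi-sequence Baum–Welch EM with selective parameter freezing, and
   histogram-based initialization (uniform π and A; q, b from a 1-D
   clustering of the pooled event histogram).
3. **Protein calling** — a blind 50:50 mix of wild-type and mutant events
   is scored by maximum likelihood between the two class models trained on
   the remaining events; accuracy is reported as per-class predictive
   values.  Case 1 uses all events; Case 2 restricts to events of ≥1 s.
4. **Kinetics** — Viterbi paths are run-length encoded into dwell segments
   with entry/exit annotations; transition rates are estimated as
   k_{i→j} = N_{i→j}/T_i (event ends treated as right-censoring), with
   event-level bootstrap errors.  The mid state is analyzed conditioned on
   whether it was entered from the high or the low state; a clear
   asymmetry justifies splitting it into mid-high and mid-low states,
   yielding a four-state aggregated-Markov model {H, M_H, M_L, L}.

## Worked example

```python
import numpy as np
from porekin.synthetic import SyntheticConfig, simulate_event_pool
from porekin.classify import ProtocolOptions, run_case_protocol
from porekin.kinetics import segments_for_events, entry_conditioned_mid_stats

cfg = SyntheticConfig()                       # default wild-type/mutant fixtures
rng = np.random.default_rng(7)
wt  = simulate_event_pool(cfg, "wt",  1200, 200.0, rng)
mut = simulate_event_pool(cfg, "mut", 1200, 200.0, rng)

res, m_wt, m_mut = run_case_protocol(
    wt, mut, case=1, opts=ProtocolOptions(n_per_class=400, max_iter=50), rng=rng)
print(res.summary())
# {'mix_size': 800, 'n_called_wt': 394, 'n_called_mut': 406,
#  'ppv_wt': 0.9390862944162437, 'ppv_mut': 0.9261083743842364}

print(np.round(m_wt.q, 3))                    # recovered state levels (I/I0)
# [0.05  0.349 0.62 ]

segs = segments_for_events(wt[:400], m_wt)
cond = entry_conditioned_mid_stats(segs, mid_state=1, high_state=2,
                                   low_state=0, n_boot=200, rng=rng)
print(cond["from_high"].rate_hz)              # {2: 19.4, 0: 1.9}  (s^-1)
print(cond["from_low"].rate_hz)               # {2: 17.4, 0: 0.0}
```

Read: a blind 800-event mix is called at ~93–94% predictive value per
class; training recovers the generating wild-type state levels (0.05,
0.35, 0.62 in I/I₀); and the entry-conditioned mid-state exit rates show
the expected pattern — mid dwells entered from the high state rarely exit
to the low state (1.9 s⁻¹ vs 19.4 s⁻¹ back to high).  With the default
generator the mid state is genuinely memoryless, so the conditioned rates
toward the high state agree between partitions within error; a hidden
mid-state split (see `tests/test_kinetics.py`) produces order-of-magnitude
conditioned asymmetries instead.

A command-line interface mirrors the library
(`porekin simulate | detect | train | call | protocol | kinetics | run |
report`); `porekin run --config cfg.yaml --out rundir/` executes the whole
simulated experiment from one YAML file with full seed determinism, and
`porekin report --run-dir rundir/` renders tables and figures from the
artifacts.

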