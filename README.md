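# autobilayer

Simulation, detection, feedback control and analysis for **automated
artificial-bilayer single-channel recording**.

A gold probe carrying reconstituted ion channels is lowered through a lipid
solution into a recording chamber; a bilayer forms at the probe tip, channels
incorporate, and single-channel currents are measured. This package
re-implements that measurement system as pure software:

- **`autobilayer.simulate`** — generative model of the acquisition stream:
  two-state Markov channel gating (`i = g·(V − E_rev)`, exponential dwell
  times), zero-truncated-Poisson channel incorporation, recording noise
  (Gaussian baseline, linear drift, background spikes), probe-contact
  transient, bilayer formation depth and optional rupture. Four scenario
  presets ship as JSON (`kcsa_e71a_decane` 103.6 pS, `kcsa_e71a_hexadecane`
  127.6 pS, `kcsa_wt_control` 90.2 pS, `kcsa_wt_tea` 52.2 pS); gating
  kinetics and noise levels are synthetic defaults.
- **`autobilayer.detect`** — the rule-based channel-current recognizer on
  1 kHz streams: an excursion counts as a channel current when it changes by
  more than 2 pA within 10 ms and returns to baseline within 0.01–1 s.
  Also probe-contact and membrane-rupture detection.
- **`autobilayer.control`** — the feedback state machine: descend at
  260 µm/s until contact, pause 10 s, then step 10 µm every 2 s analyzing
  each window, halting on detection / rupture / maximum depth. Simulated
  time is owned by the controller, so runs are exactly reproducible.
- **`autobilayer.analysis`** — half-amplitude-threshold idealization with a
  drift-tracking baseline, unitary amplitudes, OLS I–V fits (slope
  conductance in pS), open-level counting, membrane area from capacitance
  (`area[mm²] = 0.1·C[nF]/c[µF/cm²]`), and Welch's-t condition comparisons.
- **`autobilayer.io`** — Axon Text Format (ATF 1.0) and a `#`-header TSV
  dialect for traces, JSON configs, and deterministic fixture generation.

## CLI

```sh
autobilayer simulate --scenario kcsa_e71a_decane --voltage 100 --duration 10 \
    --seed 1 --out trace.atf
autobilayer detect trace.atf --out events.tsv
autobilayer run --scenario kcsa_wt_control --seed 1 --out rundir/
autobilayer iv traces_dir/ --out iv.tsv
autobilayer area --capacitance-nf 1 --specific-uf-cm2 0.4
autobilayer compare control_dir/ tea_dir/
autobilayer fixtures --seed 0 --out fixtures/
```

`run` writes `log.tsv` (phase transitions), `events.tsv` and the per-window
analysis traces; `iv` writes the per-voltage unitary amplitudes with the
fitted slope conductance as footer comments.

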